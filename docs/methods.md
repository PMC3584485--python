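# Methods

## The model in one paragraph

Human mitochondrial DNA is haploid, maternally inherited and
non-recombining, so a sample of complete mt genomes is a single locus
with an unusually deep, well-resolved genealogy.  The package treats the
worldwide sample as three macro-haplogroup populations — African (AFR),
Asian (ASI) and European (EUR) — whose history is a piecewise
demographic model: an ancestral African expansion from 1,825 to 3,075
(haploid effective genomes) 8,800 generations ago, an out-of-Africa
bottleneck to 525 at the 5,600-generation split, and severe bottlenecks
128 (ASI) and 250 (EUR) 848 generations ago followed by exponential
growth to 13,403 and 7,381 today.  Sizes are mtDNA-scaled (about a
quarter of autosomal effective sizes at a 1:1 sex ratio) and stored as
final haploid numbers; no further scaling is applied.  Migration is
excluded: its expected effect on a non-recombining genome at these rates
is negligible, and the forward simulations treat the three populations
as isolated.

## SNV cataloguing rules

A column of the alignment is an SNV position when it shows at least two
distinct unambiguous bases.  Three deliberate strictness choices:

- **Indel sites.**  A single gap character anywhere in a column excludes
  the whole column (per-sample masking would change counts between
  samples); excluded positions are logged in the table's provenance.
- **Heteroplasmy.**  IUPAC two-base ambiguity codes are treated as
  missing calls.  A genome with an ambiguous call at an otherwise
  bi-allelic site leaves that site's denominator only, not the whole
  analysis.  A column variable only through ambiguity codes is not an
  SNV.
- **Multi-allelic positions.**  A column with *k* distinct bases counts
  as *k* − 1 SNVs, each paired against the majority base (ties broken
  alphabetically).  Singleton status is judged per allele (total copies
  across all samples equal to one), so a tri-allelic position can lose
  one allele to the Dataset-2 filter and keep the other.

Coordinates are 1-based on the ungapped designated reference row;
annotation BED input (0-based half-open) is converted on read.
Synonymous/non-synonymous status translates the reference vs variant
codon under the vertebrate mitochondrial genetic code (translation
table 2), with minus-strand genes (ND6) reverse-complemented.  When
intervals overlap, assignment priority is control region >
protein-coding > RNA gene, and within a class, annotation order (this
affects only the small ATP8/ATP6 and ND4L/ND4 overlaps).  A variant in a
gene's incomplete terminal codon raises a classification error rather
than guessing a completed codon.

Ancestral polarity is *not* decided during cataloguing: the majority
base is only a column-local reference.  Polarisation happens in
`candidate_detection` against an outgroup sequence; sites where the
outgroup base is ambiguous or unobserved among the alleles are excluded
from screening and counted, never majority-polarised.

## Diversity statistics

Π is the mean number of differing sites over sequence pairs (all
unordered pairs within a subset, or all cross pairs between two
subsets), with gap-excluded columns removed globally and
pairwise-complete deletion for ambiguous calls — this maximises the data
used, at the cost of slightly heterogeneous per-pair denominators.  π is
Π/L with L the number of retained columns.  Watterson's θ uses
a<sub>n−1</sub> = Σ 1/i.  On gap-free, ambiguity-free data the pairwise
Π equals the allele-frequency form Σ<sub>sites</sub>(1 −
Σ<sub>a</sub>C(c<sub>a</sub>,2)/C(n,2)) exactly; the test suite asserts
this identity, and the coalescent module uses the frequency form.  The
rare/common split (frequency ≤ 0.01 inclusive vs above) is applied to
the global frequency pooling copies across populations.

## Coalescent simulator

Backward-in-time, discrete generations: among *k* lineages in a
population of current size *N*, each pair coalesces with probability
1/*N* per generation.  Within constant-size stretches the waiting time
to the next merger is drawn geometrically (an exact shortcut); within
exponential-growth epochs the simulator steps generation by generation.
At most one merger happens per generation unless *k*(*k*−1)/2 ≥ *N*,
when single-pair mergers are applied sequentially within the generation
— a documented deviation from the strict Wright–Fisher multinomial that
only matters when the sample size approaches the population size.
Splits move all of a child population's lineages into the parent at the
split time.  Mutations are dropped on branches as
Poisson(length·μ·L) under infinite sites, positions drawn without
replacement from 1..L (L = 16,569, μ = 2.0e−7 per site per generation by
default).

Model comparison (`model_fit`) scores a candidate demography by the sum
over populations of squared relative errors of mean simulated
within-population Π against observed values, ranking ascending.  The
metric is a package choice (the source analysis states only that Π
values were compared); it is the natural scale-free least-squares
distance and is trivially replaceable.

## Forward tracked-mutation simulator and the threshold frequency

One mutation at a time is tracked in a population timeline: introduced
at carrier count 1; each generation its frequency is deterministically
reduced by haploid viability selection p′ = p(1−s)/(1−ps) and the next
count drawn Binomial(N<sub>next</sub>, p′), which also implements
bottlenecks (resampling at the new size) and growth.  Lost or fixed
mutations are replaced by a fresh count-1 mutation the following
generation (a fixed allele simply becomes background).  At the present
generation the frequency is recorded if at least one genome carries the
tracked mutation; fixation exactly at present records 1.0.  Collection
repeats until 10,000 records exist; the maximum is the threshold
frequency.  The mutation *rate* never enters: a tracked mutation starts
at count 1 however mutations arise.

**Recording window.**  Records are collected over the most recent 848
generations — the phase in which the three populations evolve
independently, and the phase whose contrast (constant African size vs
explosive non-African growth) the threshold is designed to probe.  The
demographic timelines themselves extend 8,800 generations (longer than
the 2N = 6,150-generation neutral fixation time at the African size),
and the window is a parameter (`span`).  This choice matters only for
the neutral thresholds: a tracked-mutation process left running for many
multiples of its renewal time approaches a stationary frequency
distribution whose upper tail (sojourn density ≈ 2/p per generation)
would place dozens of near-fixed records among 10,000 in the constant
African population, driving its neutral threshold to ~100%.  Restricting
records to mutations arising in the recent window yields the
qualitatively distinct African answer (threshold far below 1) that
motivates the analysis, and leaves the selected (s = 0.05) thresholds
unchanged, because under selection the renewal time is tens of
generations and the distribution is stationary within any window of a
few hundred generations.

Selection strength: s is a haploid fitness deficit, 0 ≤ s ≤ 0.1 in the
study design; s = 0.05 is the reference "deleterious enough" value.
Near-neutral behaviour (records statistically indistinguishable from
neutral) emerges when Ns ≲ 1, not at any fixed s: at these population
sizes s = 0.01 is already strongly selected.

RNG: replicates run in vectorized batches on `numpy` PCG64 substreams
keyed by (seed, population, s, batch index); results are
byte-deterministic for a fixed seed and independent across populations
and selection coefficients.

## Candidate screening and power

A variant is a candidate deleterious mutation in a population when its
derived (outgroup-polarised) frequency there is positive and *strictly*
below the population's threshold frequency; a frequency exactly at the
threshold is not a candidate.  Proportions are reported over each
population's polarised variants present in that population.  Catalog
intersection reports, per matched entry, the per-population frequency
and an above-threshold flag; catalog entries absent from the SNV table
are omitted (absent ≠ frequency zero).  The minimum-detection sample
size is ceil(population n / carriers).

`min_total_sample` scans equal-arm totals upward (step 200 by default,
matching the granularity at which such requirements are usually quoted)
using *expected* carrier counts rounded half-up and the package's own
two-sided Fisher's exact test (point-probability rule, relative
tie-tolerance 1e−9).  This is an expected-counts criterion, not a power
calculation integrating over binomial sampling of the counts — a known
simplification that makes the returned totals slightly optimistic.

## Synthetic data generator

`generate_study` emulates the real input: an alignment of complete mt
genomes with population labels, an ancestral outgroup, a functional
annotation and a pathogenic catalog.  Neutral background variation comes
from the coalescent under the default demographic model (default sample
sizes 68/266/376 — one tenth of the real per-haplogroup genome counts,
keeping proportions; L = 16,569; μ = 2.0e−7).  Planted features are
written after the background by overwriting whole columns (any colliding
background variant is erased first), so truth records are exact: indel
columns (a gap in one non-reference genome), heteroplasmic columns (an
IUPAC two-base code in one genome, matching how GenBank submissions
encode heteroplasmy), singletons, shared variants with fixed
per-population carrier counts, and catalogued pathogenic alleles at
target per-population frequencies (rounded half-up to counts).  The
outgroup is the genealogy's root sequence, perturbed at a configurable
rate (default 1%) only at sites carrying no variation, so polarisation
of every variant site remains exact.

What the generator does *not* emulate — and therefore what passing tests
do not establish about real data: the mtDNA mutational spectrum
(transition bias, hypervariable-site hotspots), sequencing and assembly
error, within-genome rate heterogeneity, site-specific selective
constraint, and realistic haplogroup structure beyond the three-deme
model.  Pipeline correctness (exclusion rules, counting identities,
polarisation, screening logic) is what the planted truth certifies.

## Numerical and scale choices

- Exponential epochs interpolate size as N(t) = round(N_end·e^{−rt}) with
  r recomputed from the endpoint sizes, so declared endpoint sizes are
  exact and the printed 0.55%/0.40% per-generation growth rates are
  recovered to two significant figures.
- At an epoch boundary the more recent epoch's size applies (a
  bottleneck acts before the first post-boundary generation).
- Thresholds in the test suite are checked across five independent seeds
  with tolerances sized for a maximum-order statistic (absolute bands for
  neutral, factor two for s = 0.05); unit simulations use small
  populations (N = 40–1,000) where closed-form expectations (E[T2] = N,
  E[Π] = 2NμL, neutral fixation probability 1/N, the diffusion fixation
  probability under selection) are sharp.
- All simulations are seeded; hypothesis-based property tests run
  derandomized.

## Known limitations

- The tracked-mutation design models exactly one deleterious mutation at
  a time: no interference, no reverse mutation, no linked selection.
- Frequency-only forward simulation: no sequence layer forward in time
  (none of the reported statistics needs one).
- The coalescent omits migration and recombination (appropriate for
  mtDNA; the model-comparison machinery therefore cannot represent
  migration-coupled demographies).
- Between-population Π uses cross pairs only, and the model-fit distance
  and power criterion are the simplest defensible choices, as noted
  above.
- Under the stationary renewal distribution at s = 0.05, the fraction of
  African records below 0.1% is about two thirds (frequencies of one to
  three copies at N = 3,075), not above 80% as in the growth populations;
  the bulk-rarity acceptance check therefore fails for AFR under this
  protocol while the AFR threshold itself is reproduced.  The two facts
  are coupled through the same sojourn distribution w(c) ∝ (2/c)e^{−2sc}.
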