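# mtpopgen

Population-genetic analysis of complete human mitochondrial genomes,
centred on one question: how does recent human population history — severe
out-of-Africa bottlenecks followed by exponential growth — limit the
frequency a deleterious mtDNA mutation can reach, and hence our ability to
recognise pathogenic variants among the flood of rare ones?

The package is aimed at population geneticists and mitochondrial-disease
researchers.  It provides, as plain library modules with a thin CLI:

- **`variant_catalog`** — SNV calling from aligned mt genomes with the
  classic exclusion rules (indel columns dropped, IUPAC ambiguity codes =
  missing calls, a *k*-allelic column = *k* − 1 SNVs), producing Dataset 1
  (all SNVs) and Dataset 2 (singletons removed) views, with functional
  classification (control region / RNA genes / synonymous /
  non-synonymous under the vertebrate mitochondrial code).
- **`diversity_stats`** — segregating sites *S*, Watterson's
  θ = *S*/(*a*<sub>*n*−1</sub>·*L*), nucleotide diversity Π (per genome)
  and π (per site), maximum pairwise difference, and rare/common
  (frequency ≤ 0.01 vs > 0.01) shared-variant classification.
- **`demography`** — piecewise population histories in generations before
  present, including the mtDNA-scaled three-population out-of-Africa
  model (African size constant at *N* = 3,075; non-African bottlenecks to
  525, then 128/250, growing exponentially to 13,403/7,381 over the last
  848 generations).
- **`coalescent_sim`** — a discrete-generation single-locus coalescent
  with splits and infinite-sites mutation, used for neutral background
  synthesis and for ranking demographic models against observed Π.
- **`forward_sim`** — the core: a forward Wright–Fisher tracked-mutation
  simulator.  One mutation at a time enters at count 1, experiences
  haploid viability selection *p*′ = *p*(1−*s*)/(1−*ps*) and binomial
  drift; the present-day frequency is recorded when at least one genome
  carries it.  The maximum of 10,000 such records is the population's
  **threshold frequency** — an empirical upper bound on the plausible
  frequency of a (deleterious) mutation.
- **`candidate_detection`** — outgroup polarisation of SNVs, derived
  allele frequencies per population, screening of below-threshold
  candidates, and intersection with a pathogenic-mutation catalog.
- **`association_power`** — the smallest case–control total sample at
  which doubling a threshold-frequency allele is detectable by a
  two-sided Fisher's exact test (implemented by hypergeometric
  enumeration).
- **`synthetic_data`** — a generator of fully self-contained study inputs
  (alignment, labels, outgroup, annotation BED, pathogenic catalog) with
  planted, exactly verifiable truth, backed by the coalescent.

## Worked example

```python
from mtpopgen import forward_sim as fwd
from mtpopgen.association_power import PowerQuery, min_total_sample

res = fwd.collect_records("EUR", 0.05, n_records=10_000, seed=1)
print(f"EUR threshold (s=0.05): {100*res.threshold:.2f}%")
print(f"records below 0.1%: {100*res.proportion_below(0.001):.1f}%")
print(f"replicates consumed: {res.runs_executed}")

out = min_total_sample(PowerQuery(freq=0.0198, ratio=2.0, alpha=0.01, step=200))
print("min total sample at f=1.98%:", out["min_total"])
```

prints

```
EUR threshold (s=0.05): 0.83%
records below 0.1%: 85.0%
replicates consumed: 11915
min total sample at f=1.98%: 2200
```

Reading: under purifying selection *s* = 0.05, none of 10,000 simulated
European-history mutations surviving to the present exceeded 0.83%
frequency — so a variant observed above that frequency is a poor
candidate for being deleterious at that strength — and 85% of them sat
below 0.1%, the rare-variant zone where association testing needs
thousands of samples (2,200 total at a control frequency of 1.98% for a
two-fold case enrichment at *P* < 0.01).

The same machinery is exposed on the command line:

```bash
mtpopgen make-synthetic --seed 1 --out study/
mtpopgen snv-call --alignment study/alignment.fasta --labels study/labels.tsv \
    --annotation study/annotation.bed --dataset 2 --out snv.tsv
mtpopgen simulate-threshold --pop ASI --s 0.05 --seed 1 --out asi.json
mtpopgen detect-candidates --alignment study/alignment.fasta \
    --labels study/labels.tsv --outgroup study/outgroup.fasta \
    --thresholds AFR=0.0198,ASI=0.0055,EUR=0.0092 \
    --catalog study/pathogenic.tsv --out report.json
```

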