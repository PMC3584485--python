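"""Self-contained synthetic study inputs with planted, verifiable truth.

The generator emulates the kind of input the real analysis consumed — a
multi-sequence alignment of complete mitochondrial genomes with
African/Asian/European population labels, an outgroup (ancestral)
sequence, a functional region annotation and a pathogenic-mutation
catalog — without downloading anything.  Neutral background variation
comes from the internal coalescent under a demographic model; study
features with known downstream behaviour (indel columns, heteroplasmic
ambiguity-code columns, singletons, shared common variants, pathogenic
alleles at controlled per-population frequencies) are planted afterwards
by overwriting whole columns, so the truth records are exact by
construction: any background variant colliding with a planted position is
erased first.

Heteroplasmy is encoded as IUPAC two-base ambiguity codes in individual
sequences, matching how mitochondrial GenBank submissions represent it.
The outgroup is the ancestral root sequence of the simulated genealogy,
optionally perturbed at sites that carry no variation, which keeps the
ancestral state at every variant site exact.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from Bio import SeqIO

from . import annotation as ann
from . import demography as dem
from .candidate_detection import CatalogEntry, PathogenicCatalog
from .coalescent_sim import MutationModel, simulate_genealogy, sprinkle_mutations
from .errors import ConfigurationError
from .variant_catalog import AlignedSet, read_alignment, write_alignment

__all__ = [
    "SynthConfig",
    "TruthRecord",
    "Study",
    "PlantedIndel",
    "PlantedHeteroplasmy",
    "PlantedSingleton",
    "PlantedVariant",
    "PlantedPathogenic",
    "generate_study",
    "write_study",
    "read_study",
    "example_config",
]

BASES = "ACGT"
_AMBIGUITY = {
    frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("CG"): "S",
    frozenset("AT"): "W", frozenset("GT"): "K", frozenset("AC"): "M",
}

# closed disposition vocabulary
EXCLUDED_INDEL = "excluded as indel site"
EXCLUDED_HETEROPLASMY = "excluded as heteroplasmic site"
DATASET1_ONLY = "dropped from Dataset 2"
RETAINED = "retained in Dataset 2"
DISPOSITIONS = (EXCLUDED_INDEL, EXCLUDED_HETEROPLASMY, DATASET1_ONLY, RETAINED)


@dataclass(frozen=True)
class PlantedIndel:
    """A gap character in one genome: the whole column is an indel site."""

    position: int
    kind: str = "indel"


@dataclass(frozen=True)
class PlantedHeteroplasmy:
    """An ambiguity-code call in one genome at an otherwise fixed column."""

    position: int
    kind: str = "heteroplasmy"


@dataclass(frozen=True)
class PlantedSingleton:
    """A variant allele carried by exactly one genome of one population."""

    position: int
    population: str = "AFR"
    kind: str = "singleton"


@dataclass(frozen=True)
class PlantedVariant:
    """A variant with fixed per-population carrier counts."""

    position: int
    counts: tuple[tuple[str, int], ...]  # ((pop, carriers), ...)
    kind: str = "variant"


@dataclass(frozen=True)
class PlantedPathogenic:
    """A catalogued pathogenic allele at target per-population frequencies."""

    position: int
    frequencies: tuple[tuple[str, float], ...]
    status: str = "Confirmed"
    disease: str = "synthetic disease"
    kind: str = "pathogenic"


@dataclass
class SynthConfig:
    """Study-generation settings.

    Default sample sizes are a tenth of the real study's per-haplogroup
    genome counts (685/2,658/3,755), keeping their proportions; the
    mutation rate and genome length are the study's values.
    """

    n_samples_per_pop: dict[str, int] = field(
        default_factory=lambda: {"AFR": 68, "ASI": 266, "EUR": 376}
    )
    L: int = 16_569
    mu: float = 2.0e-7
    demography: str | dict = "gutenkunst_mt"
    features: list = field(default_factory=list)
    seed: int = 0
    outgroup_divergence: float = 0.01

    def validate(self) -> None:
        positions = [f.position for f in self.features]
        if len(positions) != len(set(positions)):
            raise ConfigurationError("planted feature positions collide")
        for f in self.features:
            if not 1 <= f.position <= self.L:
                raise ConfigurationError(
                    f"feature position {f.position} outside [1, {self.L}]"
                )
            targets = []
            if isinstance(f, PlantedSingleton):
                targets = [f.population]
            elif isinstance(f, PlantedVariant):
                targets = [p for p, c in f.counts if c > 0]
            elif isinstance(f, PlantedPathogenic):
                targets = [p for p, q in f.frequencies if q > 0]
            for p in targets:
                if self.n_samples_per_pop.get(p, 0) == 0:
                    raise ConfigurationError(
                        f"feature at {f.position} targets empty population {p}"
                    )
        if any(n < 0 for n in self.n_samples_per_pop.values()):
            raise ConfigurationError("sample sizes must be >= 0")


@dataclass
class TruthRecord:
    """What was planted and how the pipeline must treat it."""

    kind: str
    position: int
    alleles: tuple[str, ...]
    expected_counts: dict[str, int]
    disposition: str

    def __post_init__(self) -> None:
        if self.disposition not in DISPOSITIONS:
            raise ConfigurationError(f"unknown disposition {self.disposition!r}")


@dataclass
class Study:
    aligned: AlignedSet
    outgroup: str
    annotation: object  # pandas DataFrame
    catalog: PathogenicCatalog
    truth: list[TruthRecord]


def _resolve_histories(spec) -> dict[str, dem.PopulationHistory]:
    if isinstance(spec, dict):
        return spec
    if spec == "gutenkunst_mt":
        return dem.gutenkunst_mt_model()
    raise ConfigurationError(f"unknown demography {spec!r}")


def constant_model(N: int, pops=("AFR", "ASI", "EUR")) -> dict[str, dem.PopulationHistory]:
    """An effectively panmictic constant-size model over the given labels.

    All labels merge into the first one generation before present, so the
    sample behaves as one constant-size population.
    """
    root = pops[0]
    out = {}
    for p in pops:
        epochs = [dem.DemographicEpoch(dem.ANCIENT, 0, N, N)]
        splits = [] if p == root else [dem.PopulationSplit(parent=root, time=1)]
        out[p] = dem.PopulationHistory(name=p, epochs=epochs, splits=splits)
    return out


def _other_base(rng: np.random.Generator, base: str) -> str:
    choices = [b for b in BASES if b != base]
    return choices[int(rng.integers(len(choices)))]


def generate_study(config: SynthConfig) -> Study:
    """Generate a full synthetic study; same config and seed give
    byte-identical output."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    sample_sizes = {p: n for p, n in config.n_samples_per_pop.items() if n > 0}
    n_total = sum(sample_sizes.values())
    if n_total == 0:
        raise ConfigurationError("no samples requested")

    histories = _resolve_histories(config.demography)
    ids, populations = [], []
    for p, n in sample_sizes.items():
        ids.extend(f"{p}_{i:04d}" for i in range(n))
        populations.extend([p] * n)

    root = rng.choice(list(BASES), size=config.L)
    matrix = np.tile(root.astype("S1"), (n_total, 1))

    variant_positions: set[int] = set()
    if n_total > 1:
        genealogy = simulate_genealogy(histories, sample_sizes, rng)
        variants = sprinkle_mutations(
            genealogy, MutationModel(mu=config.mu, L=config.L), rng
        )
        for v in variants:
            derived = _other_base(rng, str(root[v.position - 1]))
            matrix[list(v.carriers), v.position - 1] = derived.encode()
            variant_positions.add(v.position)

    pop_rows = {}
    offset = 0
    for p, n in sample_sizes.items():
        pop_rows[p] = np.arange(offset, offset + n)
        offset += n

    truth: list[TruthRecord] = []
    catalog_entries: list[CatalogEntry] = []
    feature_positions = {f.position for f in config.features}
    for feature in config.features:
        col = feature.position - 1
        anc = str(root[col])
        matrix[:, col] = anc.encode()  # erase background variation
        variant_positions.discard(feature.position)
        if isinstance(feature, PlantedIndel):
            row = 1 + int(rng.integers(n_total - 1))  # never the reference row
            matrix[row, col] = b"-"
            truth.append(TruthRecord(feature.kind, feature.position,
                                     (anc, "-"), {}, EXCLUDED_INDEL))
        elif isinstance(feature, PlantedHeteroplasmy):
            row = 1 + int(rng.integers(n_total - 1))
            other = _other_base(rng, anc)
            code = _AMBIGUITY[frozenset({anc, other})]
            matrix[row, col] = code.encode()
            truth.append(TruthRecord(feature.kind, feature.position,
                                     (anc, code), {}, EXCLUDED_HETEROPLASMY))
        elif isinstance(feature, PlantedSingleton):
            alt = _other_base(rng, anc)
            row = int(rng.choice(pop_rows[feature.population]))
            matrix[row, col] = alt.encode()
            truth.append(TruthRecord(feature.kind, feature.position,
                                     (anc, alt), {feature.population: 1},
                                     DATASET1_ONLY))
        elif isinstance(feature, (PlantedVariant, PlantedPathogenic)):
            alt = _other_base(rng, anc)
            if isinstance(feature, PlantedVariant):
                counts = {p: int(c) for p, c in feature.counts}
            else:
                counts = {
                    p: int(np.floor(q * len(pop_rows[p]) + 0.5))
                    for p, q in feature.frequencies
                }
            for p, c in counts.items():
                if c > len(pop_rows[p]):
                    raise ConfigurationError(
                        f"feature at {feature.position} wants {c} carriers in "
                        f"{p} but only {len(pop_rows[p])} samples exist"
                    )
                rows = rng.choice(pop_rows[p], size=c, replace=False)
                matrix[rows, col] = alt.encode()
            total = sum(counts.values())
            if total == 0:
                raise ConfigurationError(
                    f"feature at {feature.position} rounds to zero carriers"
                )
            truth.append(TruthRecord(
                feature.kind, feature.position, (anc, alt),
                {p: c for p, c in counts.items() if c > 0},
                RETAINED if total >= 2 else DATASET1_ONLY,
            ))
            if isinstance(feature, PlantedPathogenic):
                catalog_entries.append(CatalogEntry(
                    position=feature.position, ref=anc, derived=alt,
                    status=feature.status, disease=feature.disease,
                ))
        else:
            raise ConfigurationError(f"unknown feature type {type(feature)!r}")

    # outgroup: the ancestral root, perturbed only where nothing varies
    outgroup = root.copy()
    untouched = np.array([
        i for i in range(config.L)
        if (i + 1) not in variant_positions and (i + 1) not in feature_positions
    ], dtype=int)
    if config.outgroup_divergence > 0 and len(untouched):
        hit = untouched[rng.random(len(untouched)) < config.outgroup_divergence]
        for i in hit:
            outgroup[i] = _other_base(rng, str(outgroup[i]))

    aligned = AlignedSet(ids=ids, populations=populations, matrix=matrix,
                         ref_index=0)
    return Study(
        aligned=aligned,
        outgroup="".join(outgroup.tolist()),
        annotation=ann.default_annotation(config.L),
        catalog=PathogenicCatalog(catalog_entries),
        truth=truth,
    )


def example_config(seed: int = 0) -> SynthConfig:
    """A representative configuration exercising every feature kind."""
    return SynthConfig(
        seed=seed,
        features=[
            PlantedIndel(position=310),
            PlantedIndel(position=16189),
            PlantedHeteroplasmy(position=3243),
            PlantedSingleton(position=1555, population="AFR"),
            PlantedSingleton(position=8993, population="EUR"),
            PlantedVariant(position=7028, counts=(("AFR", 30), ("ASI", 120),
                                                  ("EUR", 150))),
            PlantedVariant(position=2706, counts=(("ASI", 40), ("EUR", 60))),
            # mirrors a confirmed pathogenic allele common in one population
            PlantedPathogenic(position=11778, frequencies=(("ASI", 0.02),),
                              status="Confirmed", disease="LHON-like"),
            PlantedPathogenic(position=14484, frequencies=(("EUR", 0.005),),
                              status="Confirmed", disease="LHON-like"),
            PlantedPathogenic(position=8344, frequencies=(("AFR", 0.015),
                                                          ("EUR", 0.002)),
                              status="Reported", disease="MERRF-like"),
        ],
    )


# -- disk round-trip ---------------------------------------------------

FILES = {
    "alignment": "alignment.fasta",
    "labels": "labels.tsv",
    "outgroup": "outgroup.fasta",
    "annotation": "annotation.bed",
    "catalog": "pathogenic.tsv",
    "truth": "truth.json",
}


def write_study(study: Study, outdir) -> None:
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_alignment(study.aligned, outdir / FILES["alignment"],
                    outdir / FILES["labels"])
    with open(outdir / FILES["outgroup"], "w") as fh:
        fh.write(f">outgroup ancestral\n{study.outgroup}\n")
    ann.write_annotation_bed(study.annotation, outdir / FILES["annotation"])
    study.catalog.write_tsv(outdir / FILES["catalog"])
    with open(outdir / FILES["truth"], "w") as fh:
        json.dump([asdict(t) for t in study.truth], fh, indent=1)


def read_study(outdir) -> Study:
    from pathlib import Path

    outdir = Path(outdir)
    aligned = read_alignment(outdir / FILES["alignment"], outdir / FILES["labels"])
    outgroup = str(next(SeqIO.parse(str(outdir / FILES["outgroup"]), "fasta")).seq)
    annotation = ann.read_annotation_bed(outdir / FILES["annotation"])
    catalog = PathogenicCatalog.read_tsv(outdir / FILES["catalog"])
    with open(outdir / FILES["truth"]) as fh:
        truth = [TruthRecord(**{**t, "alleles": tuple(t["alleles"])})
                 for t in json.load(fh)]
    return Study(aligned=aligned, outgroup=outgroup, annotation=annotation,
                 catalog=catalog, truth=truth)
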