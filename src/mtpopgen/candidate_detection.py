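"""Screening SNVs for deleterious-mutation candidates.

SNVs are polarized against an outgroup sequence (the ancestral state; the
original analysis used a Neanderthal mitochondrial genome), giving a
per-population derived-allele frequency for every variant.  A variant is a
candidate deleterious mutation in a population when its derived frequency
is positive but strictly below that population's threshold frequency (the
forward-simulation maximum).  Candidates are finally intersected with a
catalog of known pathogenic mutations.

Sites where the outgroup base is ambiguous or not among the observed
alleles cannot be polarized; they are excluded from screening and counted
separately rather than polarized by majority.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .errors import InputError
from .variant_catalog import BASES, SNVTable

__all__ = [
    "CatalogEntry",
    "PathogenicCatalog",
    "CandidateReport",
    "derived_frequencies",
    "classify_candidates",
    "match_pathogenic",
    "min_sample_for_detection",
]

STATUSES = ("Confirmed", "Reported", "Unclear", "Conflicting")


@dataclass(frozen=True)
class CatalogEntry:
    position: int
    ref: str
    derived: str
    status: str
    disease: str

    def __post_init__(self) -> None:
        if self.status not in STATUSES:
            raise InputError(f"unknown pathogenicity status {self.status!r}")


@dataclass
class PathogenicCatalog:
    """Disease-associated mutation annotations, MITOMAP style."""

    entries: list[CatalogEntry]

    def __post_init__(self) -> None:
        keys = [(e.position, e.derived) for e in self.entries]
        if len(keys) != len(set(keys)):
            raise InputError("duplicate (position, derived allele) in catalog")

    def __len__(self) -> int:
        return len(self.entries)

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for e in self.entries:
                fh.write(f"{e.position}\t{e.ref}\t{e.derived}\t{e.status}\t{e.disease}\n")

    @classmethod
    def read_tsv(cls, path) -> "PathogenicCatalog":
        df = pd.read_csv(path, sep="\t", header=None,
                         names=["position", "ref", "derived", "status", "disease"],
                         dtype={"position": int}, keep_default_na=False)
        return cls([CatalogEntry(int(r.position), r.ref, r.derived, r.status,
                                 r.disease) for r in df.itertuples()])


def derived_frequencies(table: SNVTable, outgroup: str) -> pd.DataFrame:
    """Per-population derived-allele frequency of every SNV record.

    ``outgroup`` is an ungapped sequence on the same coordinates as the
    table's reference.  The ancestral allele at a position is the outgroup
    base; the derived allele of a record is whichever of its two alleles
    is not ancestral.  One row per record with columns ``position, ref,
    alt, ancestral, derived, unpolarized`` and one ``freq_<pop>`` column
    per population.
    """
    outgroup = outgroup.upper()
    if len(outgroup) != len(table.reference):
        raise InputError(
            f"outgroup length {len(outgroup)} != reference length "
            f"{len(table.reference)}"
        )
    observed: dict[int, set[str]] = {}
    for r in table.records:
        observed.setdefault(r.position, {r.ref}).add(r.alt)
    pops = list(table.pop_sizes)
    rows = []
    for r in table.records:
        anc = outgroup[r.position - 1]
        unpolarized = anc not in BASES or anc not in observed[r.position]
        derived = None if unpolarized else (r.alt if r.alt != anc else r.ref)
        row = {"position": r.position, "ref": r.ref, "alt": r.alt,
               "ancestral": anc, "derived": derived, "unpolarized": unpolarized}
        for p in pops:
            rc, ac, nc = r.counts[p]
            if unpolarized or nc == 0:
                row[f"freq_{p}"] = float("nan") if unpolarized else 0.0
            else:
                row[f"freq_{p}"] = (ac if derived == r.alt else rc) / nc
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class CandidateReport:
    """Threshold screen over polarized SNVs, per population."""

    thresholds: dict[str, float]
    frequencies: pd.DataFrame  # derived_frequencies output + candidate flags
    candidates: dict[str, int]
    denominators: dict[str, int]  # polarized SNVs present in the population
    proportions: dict[str, float]
    n_unpolarized: int
    unpolarized_positions: list[int] = field(default_factory=list)


def classify_candidates(freqs: pd.DataFrame,
                        thresholds: dict[str, float]) -> CandidateReport:
    """Flag candidates: ``0 < derived frequency < threshold`` (strict).

    A frequency exactly equal to the threshold is not a candidate.
    Proportions are over each population's polarized SNVs with a positive
    derived frequency there.
    """
    pops = [c[len("freq_"):] for c in freqs.columns if c.startswith("freq_")]
    missing = [p for p in pops if p not in thresholds]
    if missing:
        raise InputError(f"missing thresholds for populations: {missing}")
    for p in pops:
        if not 0 < thresholds[p] <= 1:
            raise InputError(f"threshold for {p} must be in (0, 1]")
    out = freqs.copy()
    candidates: dict[str, int] = {}
    denominators: dict[str, int] = {}
    proportions: dict[str, float] = {}
    polarized = ~out["unpolarized"]
    for p in pops:
        f = out[f"freq_{p}"]
        flag = polarized & (f > 0) & (f < thresholds[p])
        out[f"candidate_{p}"] = flag
        candidates[p] = int(flag.sum())
        denominators[p] = int((polarized & (f > 0)).sum())
        proportions[p] = candidates[p] / denominators[p] if denominators[p] else 0.0
    unpol = sorted(out.loc[out["unpolarized"], "position"].unique().tolist())
    return CandidateReport(
        thresholds={p: thresholds[p] for p in pops}, frequencies=out,
        candidates=candidates, denominators=denominators,
        proportions=proportions, n_unpolarized=int(out["unpolarized"].sum()),
        unpolarized_positions=unpol,
    )


def match_pathogenic(report: CandidateReport,
                     catalog: PathogenicCatalog) -> pd.DataFrame:
    """Intersect the screen with a pathogenic-mutation catalog.

    Catalog entries absent from the SNV table are not reported (absent is
    not the same as frequency zero).  For present entries the result has,
    per population, the derived frequency and whether it reaches the
    threshold (``above_<pop>`` is true when frequency >= threshold).
    """
    pops = list(report.thresholds)
    by_key = {
        (int(r["position"]), r["derived"]): r
        for _, r in report.frequencies.iterrows()
        if not r["unpolarized"]
    }
    rows = []
    for e in catalog.entries:
        hit = by_key.get((e.position, e.derived))
        if hit is None:
            continue
        row = {"position": e.position, "derived": e.derived,
               "status": e.status, "disease": e.disease}
        for p in pops:
            f = float(hit[f"freq_{p}"])
            row[f"freq_{p}"] = f
            row[f"above_{p}"] = bool(f >= report.thresholds[p] and f > 0)
        rows.append(row)
    return pd.DataFrame(rows)


def min_sample_for_detection(carriers: int, population_n: int) -> int:
    """Smallest sample expected to include one carrier: ``ceil(n/carriers)``.

    ``carriers`` is the number of genomes carrying the mutation among the
    ``population_n`` surveyed genomes of that population.
    """
    if carriers < 1:
        raise InputError("a mutation with zero carriers is undetectable")
    if population_n < carriers:
        raise InputError("carriers cannot exceed the population sample")
    return math.ceil(population_n / carriers)
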