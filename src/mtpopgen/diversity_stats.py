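"""Diversity summaries: segregating sites, Watterson's theta, nucleotide
diversity (per genome and per site), and shared/rare-common variant
classification.

Nucleotide diversity follows Nei & Li: the mean number of differing sites
over pairs of sequences (per genome, capital Pi) or that value per site
(lower-case pi).  Columns containing a gap are excluded entirely, matching
the SNV-calling rule; ambiguity codes are handled by pairwise-complete
deletion, so each pair is compared only at sites where both calls are
unambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, product

import numpy as np
import pandas as pd

from .errors import InputError
from .variant_catalog import _BASE_BYTES, GAP, AlignedSet, SNVTable

__all__ = [
    "DiversitySummary",
    "harmonic_number",
    "watterson_theta",
    "pairwise_diversity",
    "pi_from_counts",
    "diversity_summary",
    "shared_variant_classes",
]


@dataclass(frozen=True)
class DiversitySummary:
    """Per-region diversity figures for one sample set."""

    n: int
    L: int
    S: int
    theta_w: float  # per site
    Pi: float  # mean pairwise differences per genome
    pi: float  # Pi / L
    max_diff: int
    a: float  # harmonic number sum_{i=1}^{n-1} 1/i, kept for audit

    def as_dict(self) -> dict:
        return {
            "n": self.n, "L": self.L, "S": self.S,
            "theta_w": self.theta_w, "Pi": self.Pi, "pi": self.pi,
            "max_diff": self.max_diff, "a": self.a,
        }


def harmonic_number(m: int) -> float:
    """``sum_{i=1}^{m} 1/i`` (0 for m <= 0)."""
    if m <= 0:
        return 0.0
    return float(np.sum(1.0 / np.arange(1, m + 1)))


def watterson_theta(S: int, n: int, L: int) -> float:
    """Watterson's per-site estimator ``S / (a_{n-1} L)``."""
    if n < 2:
        raise InputError("Watterson's theta requires n >= 2")
    if L <= 0 or S < 0:
        raise InputError("require L > 0 and S >= 0")
    return S / (harmonic_number(n - 1) * L)


def _resolve_rows(aligned: AlignedSet, subset) -> np.ndarray:
    if subset is None:
        return np.arange(aligned.n_samples)
    if isinstance(subset, str):
        rows = aligned.pop_rows(subset)
        if rows.size == 0:
            raise InputError(f"no samples labelled {subset!r}")
        return rows
    return np.asarray(list(subset), dtype=int)


def _pair_difference_matrix(aligned: AlignedSet, columns: np.ndarray | None):
    """Unambiguous-call mask and base codes over the retained columns."""
    M = aligned.matrix if columns is None else aligned.matrix[:, columns]
    keep = ~(M == GAP).any(axis=0)
    M = M[:, keep]
    codes = np.full(M.shape, -1, dtype=np.int8)
    for i, b in enumerate(_BASE_BYTES):
        codes[M == b] = i
    return codes


def pairwise_diversity(
    aligned: AlignedSet,
    subset_a=None,
    subset_b=None,
    columns: np.ndarray | None = None,
) -> tuple[float, float, int]:
    """Nucleotide diversity (Pi, pi, max pairwise difference).

    ``subset_a``/``subset_b`` are population labels or row-index sequences.
    With one subset, all unordered pairs within it are used; with two, all
    cross pairs (between-population diversity).  ``columns`` optionally
    restricts to a region (indices on the alignment).
    """
    rows_a = _resolve_rows(aligned, subset_a)
    codes = _pair_difference_matrix(aligned, columns)
    L = aligned.n_columns if columns is None else len(np.asarray(columns))
    if subset_b is None:
        if len(rows_a) < 2:
            raise InputError("within-population diversity needs >= 2 samples")
        pairs = list(combinations(rows_a, 2))
    else:
        rows_b = _resolve_rows(aligned, subset_b)
        pairs = [(i, j) for i, j in product(rows_a, rows_b) if i != j]
        if not pairs:
            raise InputError("no cross pairs between the two subsets")
    diffs = np.empty(len(pairs), dtype=np.int64)
    for k, (i, j) in enumerate(pairs):
        valid = (codes[i] >= 0) & (codes[j] >= 0)
        diffs[k] = int(((codes[i] != codes[j]) & valid).sum())
    Pi = float(diffs.mean())
    return Pi, Pi / L, int(diffs.max())


def pi_from_counts(allele_counts: np.ndarray, n: int) -> float:
    """Frequency-form nucleotide diversity per genome.

    ``allele_counts`` is (sites, alleles) of haploid counts per site (rows
    may be padded with zeros); for each site the probability that two of
    the ``n`` sampled genomes differ is ``1 - sum_a C(c_a,2)/C(n,2)``.
    """
    counts = np.atleast_2d(np.asarray(allele_counts, dtype=np.int64))
    if n < 2:
        raise InputError("need n >= 2")
    same = (counts * (counts - 1)).sum(axis=1) / (n * (n - 1))
    return float((1.0 - same).sum())


def region_columns(aligned: AlignedSet, annotation: pd.DataFrame,
                   region: str = "all") -> np.ndarray:
    """Alignment column indices whose reference position lies in ``region``.

    ``region`` is ``all``, ``control`` (control-region intervals) or
    ``remain`` (their complement).
    """
    from . import annotation as ann_mod

    ref_row = aligned.matrix[aligned.ref_index]
    positions = np.cumsum(ref_row != GAP)  # column -> 1-based ref position
    if region == "all":
        return np.arange(aligned.n_columns)
    ctrl = annotation[annotation["cls"] == ann_mod.CONTROL]
    in_ctrl = np.zeros(aligned.n_columns, dtype=bool)
    for _, row in ctrl.iterrows():
        in_ctrl |= (positions >= row["start"]) & (positions <= row["end"])
    if region == "control":
        return np.nonzero(in_ctrl)[0]
    if region == "remain":
        return np.nonzero(~in_ctrl)[0]
    raise InputError(f"unknown region {region!r}")


def diversity_summary(aligned: AlignedSet, S: int,
                      subset=None, columns: np.ndarray | None = None
                      ) -> DiversitySummary:
    """Assemble the per-region summary from an alignment and its SNV count."""
    rows = _resolve_rows(aligned, subset)
    n = len(rows)
    L = aligned.n_columns if columns is None else len(np.asarray(columns))
    Pi, pi, max_diff = pairwise_diversity(aligned, rows, columns=columns)
    return DiversitySummary(
        n=n, L=L, S=S, theta_w=watterson_theta(S, n, L),
        Pi=Pi, pi=pi, max_diff=max_diff, a=harmonic_number(n - 1),
    )


RARE_CUTOFF = 0.01  # global frequency; rare is inclusive of the boundary


def shared_variant_classes(table: SNVTable) -> pd.DataFrame:
    """Classify every SNV by population sharing and rarity.

    Global frequency pools variant copies across all populations
    (copies / called genomes); rare means frequency <= 0.01, common above.
    Returns one row per record with its membership pattern, plus the
    grouping is conveniently done on the result.
    """
    rows = []
    for r in table.records:
        total_called = sum(c[2] for c in r.counts.values())
        freq = r.total_alt / total_called if total_called else 0.0
        member = tuple(sorted(p for p, c in r.counts.items() if c[1] > 0))
        rows.append(
            {"position": r.position, "alt": r.alt, "frequency": freq,
             "populations": member, "n_populations": len(member),
             "rarity": "rare" if freq <= RARE_CUTOFF else "common"}
        )
    return pd.DataFrame(
        rows, columns=["position", "alt", "frequency", "populations",
                       "n_populations", "rarity"]
    )


def shared_variant_summary(per_snv: pd.DataFrame) -> pd.DataFrame:
    """Counts and proportions per (membership size, rarity class)."""
    total = len(per_snv)
    grouped = (
        per_snv.groupby(["rarity", "n_populations"]).size().rename("count").reset_index()
    )
    grouped["proportion"] = grouped["count"] / total if total else 0.0
    return grouped
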