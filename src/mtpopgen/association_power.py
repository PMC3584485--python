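"""Case-control sample-size requirements for threshold-frequency alleles.

Given a control-arm allele frequency (typically a population's threshold
frequency) and a case/control frequency ratio, find the smallest total
sample size, split into equal arms, at which the expected 2x2 table is
significant by a two-sided Fisher's exact test.  Expected carrier counts
per arm are rounded half-up; this is an expected-counts criterion, not a
power calculation integrating over binomial sampling.

The Fisher test is implemented directly (hypergeometric enumeration with
the point-probability rule: a two-sided p-value sums all tables at fixed
margins whose probability does not exceed the observed table's), so its
tie handling is pinned rather than delegated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.stats import hypergeom

from .errors import InputError

__all__ = [
    "PowerQuery",
    "fisher_exact_two_sided",
    "min_total_sample",
]

_REL_EPS = 1e-9  # tolerance when comparing hypergeometric point masses


def fisher_exact_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher's exact p-value for the table [[a, b], [c, d]].

    All tables with the observed margins whose hypergeometric probability
    is <= that of the observed table (within a relative tolerance for
    floating-point ties) are summed.  A table with an all-zero margin has
    p = 1 by convention.
    """
    if min(a, b, c, d) < 0:
        raise InputError("cell counts must be non-negative")
    r1, r2 = a + b, c + d
    n1 = a + c
    N = r1 + r2
    if r1 == 0 or r2 == 0 or n1 == 0 or n1 == N:
        return 1.0
    dist = hypergeom(N, n1, r1)
    p_obs = dist.pmf(a)
    lo, hi = max(0, n1 - r2), min(r1, n1)
    total = 0.0
    for x in range(lo, hi + 1):
        px = dist.pmf(x)
        if px <= p_obs * (1.0 + _REL_EPS):
            total += px
    return min(total, 1.0)


@dataclass(frozen=True)
class PowerQuery:
    """Sample-size scan settings.

    ``freq`` is the control-arm allele frequency; cases carry the allele
    at ``ratio * freq``.  The scan tries totals ``step, 2*step, ...`` up
    to ``maximum`` with equal arms.
    """

    freq: float
    ratio: float = 2.0
    alpha: float = 0.01
    step: int = 200
    maximum: int = 200_000

    def __post_init__(self) -> None:
        if not 0 < self.freq < 1:
            raise InputError("freq must be in (0, 1)")
        if self.ratio * self.freq >= 1:
            raise InputError("ratio * freq must stay below 1 for a valid "
                             "case-arm frequency")
        if not 0 < self.alpha < 1:
            raise InputError("alpha must be in (0, 1)")
        if self.step < 2 or self.maximum < self.step:
            raise InputError("need step >= 2 and maximum >= step")


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def min_total_sample(query: PowerQuery) -> dict:
    """Smallest total sample size whose expected table is significant.

    Returns the minimal total ``n`` (equal arms), the expected-count table
    and p-value there, and the full scan trace.  Raises
    :class:`InputError` if nothing up to ``query.maximum`` succeeds.
    """
    trace = []
    for n in range(query.step, query.maximum + 1, query.step):
        n_arm = n // 2
        a = _round_half_up(query.ratio * query.freq * n_arm)  # case carriers
        c = _round_half_up(query.freq * n_arm)  # control carriers
        p = fisher_exact_two_sided(a, n_arm - a, c, n_arm - c)
        trace.append({"total": n, "case_carriers": a, "control_carriers": c,
                      "p_value": p})
        if p < query.alpha:
            return {
                "min_total": n, "n_per_arm": n_arm,
                "case_carriers": a, "control_carriers": c,
                "p_value": p, "trace": trace,
            }
    raise InputError(
        f"no total sample size <= {query.maximum} reaches p < {query.alpha}; "
        f"scan trace has {len(trace)} entries"
    )
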