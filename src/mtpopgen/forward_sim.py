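"""Forward Wright-Fisher tracking of a single (possibly deleterious)
mutation, and the per-population "threshold frequency".

The protocol follows the tracked-mutation design: one mutation at a time
is introduced at carrier count 1 and followed forward through a
population's demographic timeline under haploid viability selection
(``p' = p(1-s)/(1-ps)``) and binomial resampling at the next generation's
size.  When the tracked allele is lost or fixed, a fresh mutation enters
at count 1 in the following generation (a fixed allele simply becomes
background).  At the present generation the allele frequency is recorded
if at least one genome carries the mutation; otherwise the run yields no
record.  Repeating until ``n_records`` (default 10,000) recorded
frequencies are collected and taking their maximum gives the threshold
frequency: an empirical upper bound on the present-day frequency of a
mutation with selection coefficient ``s`` in that population.

The three populations are simulated separately; the model has no
migration.  Records are collected over the window in which the three
populations evolve independently — the most recent 848 generations of
the default model, the growth phase for the non-African populations —
so the threshold characterizes population-specific new mutations under
each population's recent demography.  The demographic timelines
themselves span 8,800 generations (longer than the neutral fixation
time 2N = 6,150 at the African size), and a longer recording window can
be requested through the ``span`` argument.  The mutation rate plays no
role here because each tracked mutation enters at count 1 regardless of
how mutations arise.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import demography as dem
from .demography import DemographicEpoch, PopulationHistory
from .errors import InputError

__all__ = [
    "ThresholdResult",
    "selection_step",
    "population_timeline",
    "run_replicate",
    "collect_records",
    "frequency_histogram",
    "with_growth_rate_scaled",
]

#: Full length of the demographic timelines, generations before present.
TIMESPAN = 8_800

#: Default recording window: the phase over which the three populations
#: evolve independently in the default model.
RECORD_SPAN = 848


def selection_step(p, s: float):
    """Haploid viability selection: ``p' = p(1-s) / (1 - p s)``.

    Identity at ``s = 0``; the boundaries 0 and 1 are absorbing.  Accepts
    scalars or arrays.
    """
    p = np.asarray(p, dtype=float)
    out = p * (1.0 - s) / (1.0 - p * s)
    return float(out) if out.ndim == 0 else out


def population_timeline(history, span: int = TIMESPAN) -> np.ndarray:
    """Per-generation sizes ``sizes[t]`` for ``t = 0..span`` before present.

    ``history`` is a :class:`PopulationHistory` or a population name of the
    default model.  History older than ``span`` is ignored.
    """
    if isinstance(history, str):
        history = dem.gutenkunst_mt_model()[history]
    return np.array(
        [history.size_at(t) for t in range(span + 1)], dtype=np.int64
    )


@dataclass
class ThresholdResult:
    """Recorded present-day frequencies for one (population, s) pair."""

    population: str
    s: float
    records: np.ndarray  # in collection order, each in (0, 1]
    seed: int
    runs_executed: int

    def __post_init__(self) -> None:
        self.records = np.asarray(self.records, dtype=float)
        if len(self.records) and not (
            (self.records > 0).all() and (self.records <= 1).all()
        ):
            raise InputError("records must lie in (0, 1]")

    @property
    def n_records(self) -> int:
        return len(self.records)

    @property
    def threshold(self) -> float:
        """The maximum recorded frequency."""
        return float(self.records.max())

    def proportion_below(self, x: float) -> float:
        return float((self.records < x).mean())


def _step_batch(count: np.ndarray, pending: np.ndarray, N_now: int,
                N_next: int, s: float, final: bool,
                rng: np.random.Generator):
    """One generation for a batch of independent replicates."""
    p = selection_step(count / N_now, s)
    new = rng.binomial(N_next, p)
    new[pending] = 1  # fresh mutation enters the generation after absorption
    if final:
        return new, np.zeros_like(pending)
    absorbed = (~pending) & ((new == 0) | (new == N_next))
    new[absorbed] = 0
    return new, absorbed


def _simulate_batch(sizes: np.ndarray, s: float, m: int,
                    rng: np.random.Generator) -> np.ndarray:
    """Present-day carrier counts of ``m`` replicates (0 means no record)."""
    T = len(sizes) - 1
    count = np.ones(m, dtype=np.int64)  # first mutation introduced at t = T
    pending = np.zeros(m, dtype=bool)
    for t in range(T, 0, -1):
        count, pending = _step_batch(
            count, pending, int(sizes[t]), int(sizes[t - 1]), s,
            final=(t == 1), rng=rng,
        )
    return count


def run_replicate(history, s: float, rng,
                  span: int = RECORD_SPAN) -> float | None:
    """Run one replicate; return the present-day frequency or ``None``.

    ``None`` means the tracked mutation was lost exactly at the present
    generation, so no genome carries it.  Fixation at the present
    generation is recorded as 1.0.
    """
    if not 0.0 <= s < 1.0:
        raise InputError("selection coefficient must satisfy 0 <= s < 1")
    sizes = population_timeline(history, span=span)
    count = _simulate_batch(sizes, s, 1, rng)[0]
    return float(count / sizes[0]) if count >= 1 else None


def collect_records(history, s: float, n_records: int = 10_000,
                    seed: int = 0, span: int = RECORD_SPAN) -> ThresholdResult:
    """Collect ``n_records`` present-day frequencies and their threshold.

    Replicates run in vectorized batches on independent RNG substreams
    keyed by ``(seed, population, s, batch index)``; the result is
    deterministic for a fixed seed.  Replicates that end with the tracked
    mutation absent at present contribute no record and are simply not
    counted (``runs_executed`` reports how many replicates were consumed
    up to and including the one producing the final record).
    """
    if n_records < 1:
        raise InputError("n_records must be >= 1")
    if not 0.0 <= s < 1.0:
        raise InputError("selection coefficient must satisfy 0 <= s < 1")
    name = history if isinstance(history, str) else history.name
    sizes = population_timeline(history, span=span)
    N0 = int(sizes[0])
    s_key = int(round(s * 10_000))
    pop_key = sum(ord(c) for c in name) % 2**16

    records: list[np.ndarray] = []
    collected = 0
    runs_executed = 0
    batch_index = 0
    success_rate = 0.7  # refined from observed batches
    while collected < n_records:
        need = n_records - collected
        m = max(int(need / success_rate) + 64, 128)
        rng = np.random.default_rng([seed, pop_key, s_key, batch_index])
        counts = _simulate_batch(sizes, s, m, rng)
        success = np.nonzero(counts > 0)[0]
        if len(success) >= need:
            runs_executed += int(success[need - 1]) + 1
            success = success[:need]
        else:
            runs_executed += m
        records.append(counts[success] / N0)
        collected += len(success)
        batch_index += 1
        success_rate = max(len(np.nonzero(counts > 0)[0]) / m, 0.05)
    return ThresholdResult(
        population=name, s=s, records=np.concatenate(records),
        seed=seed, runs_executed=runs_executed,
    )


def fixation_fraction(N: int, s: float, n_introductions: int,
                      seed: int = 0) -> float:
    """Fraction of mutations introduced at count 1 that reach fixation.

    Each introduction starts an independent chain at count 1 in a
    constant-size population of ``N`` haploid genomes and is followed
    (selection then binomial drift) until absorption.  Under neutrality
    the expected value is ``1/N``; under selection it should match the
    diffusion fixation probability ``(1 - e^{2s}) / (1 - e^{2Ns})`` for a
    deleterious allele.
    """
    if N < 1 or n_introductions < 1:
        raise InputError("need N >= 1 and n_introductions >= 1")
    rng = np.random.default_rng([seed, N, int(round(s * 10_000))])
    fixed = 0
    remaining = n_introductions
    cap = 200 * N  # absorption beyond this is astronomically unlikely
    while remaining > 0:
        m = min(200_000, remaining)
        count = np.ones(m, dtype=np.int64)
        active = np.arange(m)
        for _ in range(cap):
            p = selection_step(count[active] / N, s)
            count[active] = rng.binomial(N, p)
            sub = count[active]
            fixed += int((sub == N).sum())
            active = active[(sub != 0) & (sub != N)]
            if not len(active):
                break
        remaining -= m
    return fixed / n_introductions


def frequency_histogram(result: ThresholdResult, bin_edges
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Occurrence counts per frequency bin and the cumulative curve.

    ``bin_edges`` must be strictly increasing and cover ``(0, 1]``.  The
    counts sum to ``n_records``; the cumulative curve rises monotonically
    to 1.
    """
    edges = np.asarray(bin_edges, dtype=float)
    if len(edges) < 2 or (np.diff(edges) <= 0).any():
        raise InputError("bin edges must be strictly increasing")
    if edges[0] > 0 or edges[-1] < 1:
        raise InputError("bin edges must cover (0, 1]")
    counts, _ = np.histogram(result.records, bins=edges)
    cumulative = np.cumsum(counts) / result.n_records
    return counts, cumulative


def with_growth_rate_scaled(history: PopulationHistory,
                            factor: float) -> PopulationHistory:
    """Scale the growth rate of the most recent (exponential) epoch.

    The endpoint size is raised so that ``r' = factor * r`` over the same
    duration, which is how a faster-growth scenario is specified when only
    the rate changes.  Used for sensitivity analyses of the threshold
    frequency to the assumed expansion speed.
    """
    last = history.epochs[-1]
    if last.mode != dem.EXPONENTIAL:
        raise InputError("most recent epoch is not exponential")
    span = last.t_start - last.t_end
    new_end = int(round(last.N_start * np.exp(factor * last.r * span)))
    epochs = list(history.epochs[:-1]) + [
        DemographicEpoch(last.t_start, last.t_end, last.N_start, new_end,
                         dem.EXPONENTIAL)
    ]
    return replace(history, epochs=epochs)
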