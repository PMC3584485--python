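"""Single-locus coalescent for non-recombining haploid genomes.

The genealogy of a sample is simulated backwards in discrete generations
under piecewise demographic histories with population splits and no
migration.  Within a generation, each pair among the *k* extant lineages
of a population coalesces with probability ``1/N(t)``; at most one merger
happens per generation unless ``k(k-1)/(2N)`` exceeds one, in which case
single-pair mergers are applied sequentially within the generation.  In
constant-size stretches the waiting time to the next merger is drawn
geometrically instead of stepping generation by generation, which is an
exact shortcut for this discrete model.

Mutations are dropped on the tree under the infinite-sites model: the
count on each branch is Poisson with mean ``branch length * mu * L`` and
positions are drawn without replacement from ``1..L``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .diversity_stats import pi_from_counts
from .demography import CONSTANT, PopulationHistory
from .errors import InputError, ModelError

__all__ = [
    "Genealogy",
    "MutationModel",
    "Variant",
    "simulate_genealogy",
    "sprinkle_mutations",
    "simulate_pi",
    "model_fit",
]


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass
class Genealogy:
    """A binary (possibly partially merged) genealogy over the sample.

    Nodes ``0..n_leaves-1`` are the sampled lineages at time 0; internal
    nodes follow in coalescence order.  ``parent`` is -1 for roots.
    """

    parent: np.ndarray
    time: np.ndarray  # generations before present
    n_leaves: int
    leaf_populations: list[str]

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def tmrca(self) -> float:
        return float(self.time.max())

    def leaf_sets(self) -> list[np.ndarray]:
        """Leaf indices below each node (nodes are in time order)."""
        sets: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for leaf in range(self.n_leaves):
            sets[leaf].append(leaf)
        for node in range(self.n_nodes):  # children always precede parents
            p = self.parent[node]
            if p >= 0:
                sets[p].extend(sets[node])
        return [np.array(sorted(s), dtype=int) for s in sets]

    def branch_lengths(self) -> np.ndarray:
        """Length of the branch above each node (0 for roots)."""
        out = np.zeros(self.n_nodes)
        has_parent = self.parent >= 0
        out[has_parent] = (
            self.time[self.parent[has_parent]] - self.time[has_parent]
        )
        return out


@dataclass(frozen=True)
class MutationModel:
    """Infinite-sites mutation process over ``L`` sites at rate ``mu``."""

    mu: float
    L: int = 16_569

    def __post_init__(self) -> None:
        if self.mu < 0 or self.L < 1:
            raise InputError("need mu >= 0 and L >= 1")


@dataclass(frozen=True)
class Variant:
    position: int  # 1-based
    carriers: tuple[int, ...]  # leaf indices


class _Builder:
    def __init__(self, n_leaves: int, leaf_populations: list[str]):
        self.parent = [-1] * n_leaves
        self.time = [0] * n_leaves
        self.n_leaves = n_leaves
        self.leaf_populations = leaf_populations

    def merge(self, a: int, b: int, t: int) -> int:
        node = len(self.parent)
        self.parent.append(-1)
        self.time.append(t)
        self.parent[a] = node
        self.parent[b] = node
        return node

    def finish(self) -> Genealogy:
        return Genealogy(
            parent=np.array(self.parent, dtype=int),
            time=np.array(self.time, dtype=np.int64),
            n_leaves=self.n_leaves,
            leaf_populations=self.leaf_populations,
        )


def _evolve_segment(lineages: list[int], history: PopulationHistory,
                    t0: int, t1: int, builder: _Builder,
                    rng: np.random.Generator) -> None:
    """Coalesce ``lineages`` between ``t0`` (recent) and ``t1`` (older)."""
    t = t0
    while len(lineages) > 1 and t < t1:
        k = len(lineages)
        # which epoch covers (t, t1]?  segments never straddle boundaries
        epoch = next(e for e in reversed(history.epochs)
                     if e.t_end <= t + 1 <= e.t_start)
        if epoch.mode == CONSTANT:
            N = epoch.N_start
            p = k * (k - 1) / (2 * N)
            if p >= 1.0:
                tau = t + 1
            else:
                tau = t + int(rng.geometric(p))
                if tau > t1:
                    break
            i, j = rng.choice(k, size=2, replace=False)
            a, b = lineages[int(i)], lineages[int(j)]
            node = builder.merge(a, b, tau)
            lineages[:] = [x for x in lineages if x not in (a, b)] + [node]
            # p >= 1 permits further sequential mergers within generation
            # tau, so that generation is revisited on the next iteration
            t = tau - 1 if p >= 1.0 else tau
        else:
            # exponential epoch: step one generation at a time
            t += 1
            N = history.size_at(t)
            while len(lineages) > 1:
                k = len(lineages)
                p = k * (k - 1) / (2 * N)
                if p >= 1.0 or rng.random() < min(p, 1.0):
                    i, j = rng.choice(k, size=2, replace=False)
                    a, b = lineages[int(i)], lineages[int(j)]
                    node = builder.merge(a, b, t)
                    lineages[:] = [x for x in lineages if x not in (a, b)] + [node]
                    if p < 1.0:
                        break
                else:
                    break


def simulate_genealogy(
    histories: dict[str, PopulationHistory],
    sample_sizes: dict[str, int],
    seed,
) -> Genealogy:
    """Simulate the genealogy of ``sample_sizes`` under ``histories``.

    Split annotations on the child histories define the merge topology;
    exactly one population must be the root (no split).  A single sampled
    lineage yields the degenerate one-node tree.
    """
    rng = _rng(seed)
    for pop, n in sample_sizes.items():
        if n < 1:
            raise InputError(f"sample size for {pop} must be >= 1")
        if pop not in histories:
            raise ModelError(f"no history for sampled population {pop}")
    roots = [p for p, h in histories.items() if not h.splits]
    if len(roots) != 1:
        raise ModelError("histories must have exactly one root population")

    leaf_populations = []
    active: dict[str, list[int]] = {p: [] for p in histories}
    idx = 0
    for pop, n in sample_sizes.items():
        for _ in range(n):
            active[pop].append(idx)
            leaf_populations.append(pop)
            idx += 1
    builder = _Builder(idx, leaf_populations)

    split_events = sorted(
        ((s.time, pop, s.parent) for pop, h in histories.items() for s in h.splits),
    )
    boundaries = sorted(
        {e.t_end for h in histories.values() for e in h.epochs if e.t_end > 0}
        | {e.t_start for h in histories.values() for e in h.epochs}
        | {t for t, _, _ in split_events}
    )
    t = 0
    for t1 in boundaries:
        for pop, lineages in active.items():
            if len(lineages) > 1:
                _evolve_segment(lineages, histories[pop], t, t1, builder, rng)
        for st, child, parent in split_events:
            if st == t1 and active[child]:
                if parent not in active:
                    raise ModelError(f"split parent {parent} has no history")
                active[parent].extend(active[child])
                active[child] = []
        t = t1
        if sum(len(x) for x in active.values()) <= 1:
            break

    remaining = [(p, l) for p, l in active.items() if l]
    lineages = [x for _, l in remaining for x in l]
    if len(lineages) > 1:
        if len(remaining) > 1:
            raise ModelError("lineages left in multiple populations past all splits")
        root_pop = remaining[0][0]
        # continue in the oldest (ancestral) size indefinitely
        oldest = histories[root_pop].epochs[0]
        N = oldest.N_start
        while len(lineages) > 1:
            k = len(lineages)
            p = k * (k - 1) / (2 * N)
            t = t + 1 if p >= 1.0 else t + int(rng.geometric(min(p, 1.0)))
            i, j = rng.choice(k, size=2, replace=False)
            a, b = lineages[int(i)], lineages[int(j)]
            node = builder.merge(a, b, t)
            lineages = [x for x in lineages if x not in (a, b)] + [node]
    return builder.finish()


def sprinkle_mutations(
    genealogy: Genealogy, model: MutationModel, seed
) -> list[Variant]:
    """Drop infinite-sites mutations on the genealogy.

    Each branch receives ``Poisson(length * mu * L)`` mutations; positions
    are unique across the whole variant set.  Carrier sets (the leaves
    below the mutated branch) are therefore nested or disjoint.
    """
    rng = _rng(seed)
    if model.mu == 0 or genealogy.n_nodes == 1:
        return []
    lengths = genealogy.branch_lengths()
    counts = rng.poisson(lengths * model.mu * model.L)
    total = int(counts.sum())
    if total > model.L:
        raise InputError(
            f"{total} mutations exceed the {model.L} available sites"
        )
    if total == 0:
        return []
    positions = rng.choice(model.L, size=total, replace=False) + 1
    leaf_sets = genealogy.leaf_sets()
    variants: list[Variant] = []
    cursor = 0
    for node in range(genealogy.n_nodes):
        for _ in range(int(counts[node])):
            variants.append(
                Variant(position=int(positions[cursor]),
                        carriers=tuple(int(x) for x in leaf_sets[node]))
            )
            cursor += 1
    return variants


def _pop_pi(variants: list[Variant], rows: np.ndarray, n: int) -> float:
    if n < 2:
        raise InputError("within-population diversity needs n >= 2")
    rowset = set(int(r) for r in rows)
    counts = []
    for v in variants:
        c = sum(1 for x in v.carriers if x in rowset)
        if 0 < c < n:
            counts.append((c, n - c))
    if not counts:
        return 0.0
    return pi_from_counts(np.array(counts), n)


def simulate_pi(
    model_histories: dict[str, PopulationHistory],
    sample_sizes: dict[str, int],
    mutation_model: MutationModel,
    n_reps: int,
    seed,
) -> dict[str, dict[str, float]]:
    """Replicate coalescent simulations and summarize within-population Pi.

    Returns ``{pop: {"mean": .., "sd": .., "n_reps": ..}}`` where the
    per-replicate Pi is computed from the simulated variant carrier counts
    (the frequency form of nucleotide diversity).
    """
    if n_reps < 1:
        raise InputError("n_reps must be >= 1")
    rng = _rng(seed)
    pops = list(sample_sizes)
    values = {p: np.empty(n_reps) for p in pops}
    for rep in range(n_reps):
        g = simulate_genealogy(model_histories, sample_sizes, rng)
        variants = sprinkle_mutations(g, mutation_model, rng)
        leaf_pops = np.array(g.leaf_populations)
        for p in pops:
            rows = np.nonzero(leaf_pops == p)[0]
            values[p][rep] = _pop_pi(variants, rows, len(rows))
    return {
        p: {
            "mean": float(values[p].mean()),
            "sd": float(values[p].std(ddof=1)) if n_reps > 1 else 0.0,
            "n_reps": n_reps,
        }
        for p in pops
    }


def model_fit(
    observed_pi: dict[str, float],
    candidate_models: dict[str, dict[str, PopulationHistory]],
    sample_sizes: dict[str, int],
    mutation_model: MutationModel,
    n_reps: int,
    seed,
) -> list[dict]:
    """Rank demographic models by distance between simulated and observed Pi.

    Distance is the sum over populations of the squared relative error of
    the mean simulated within-population Pi.  Models are returned ranked
    ascending by distance, with the per-population means attached.
    """
    if not candidate_models:
        raise InputError("at least one candidate model is required")
    for p, v in observed_pi.items():
        if v == 0:
            raise InputError(f"observed Pi for {p} is zero; distance undefined")
    results = []
    for k, (name, histories) in enumerate(candidate_models.items()):
        sims = simulate_pi(histories, sample_sizes, mutation_model, n_reps,
                           np.random.default_rng([_seed_int(seed), k]))
        distance = sum(
            ((sims[p]["mean"] - obs) / obs) ** 2 for p, obs in observed_pi.items()
        )
        results.append({"model": name, "distance": float(distance),
                        "simulated_pi": {p: sims[p]["mean"] for p in observed_pi}})
    results.sort(key=lambda r: r["distance"])
    for rank, r in enumerate(results, start=1):
        r["rank"] = rank
    return results


def _seed_int(seed) -> int:
    if isinstance(seed, np.random.Generator):
        return int(seed.integers(0, 2**31 - 1))
    return int(seed)
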