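"""Piecewise demographic histories for haploid (mitochondrial) populations.

A :class:`PopulationHistory` is an ordered list of epochs covering
``[t_oldest, 0]`` in generations before present.  Sizes are haploid genome
counts, i.e. mitochondrial effective sizes (about a quarter of the autosomal
effective size for a 1:1 sex ratio).  The named constructor
:func:`gutenkunst_mt_model` returns the three-population
African/Asian/European model scaled to mtDNA that this package uses as its
default demographic scenario: a single ancient African expansion, an
out-of-Africa bottleneck, and recent severe bottlenecks followed by
exponential growth in the non-African populations.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

from .errors import InputError

__all__ = [
    "DemographicEpoch",
    "PopulationSplit",
    "PopulationHistory",
    "gutenkunst_mt_model",
    "growth_rate",
    "size_at",
]

CONSTANT = "constant"
EXPONENTIAL = "exponential"

#: Age of the oldest (ancestral, effectively open-ended) epoch.  Far beyond
#: any coalescence time reachable at mitochondrial effective sizes.
ANCIENT = 2_000_000


@dataclass(frozen=True)
class DemographicEpoch:
    """One epoch of constant or exponentially changing size.

    Times are generations before present with ``t_start > t_end >= 0``;
    ``N_start`` is the size at the old end, ``N_end`` at the recent end.
    """

    t_start: int
    t_end: int
    N_start: int
    N_end: int
    mode: str = CONSTANT

    def __post_init__(self) -> None:
        if not self.t_start > self.t_end >= 0:
            raise InputError(f"epoch times must satisfy t_start > t_end >= 0, got {self}")
        if self.N_start < 1 or self.N_end < 1:
            raise InputError("population sizes must be >= 1")
        if self.mode == CONSTANT and self.N_start != self.N_end:
            raise InputError("constant epoch must have N_start == N_end")
        if self.mode not in (CONSTANT, EXPONENTIAL):
            raise InputError(f"unknown epoch mode {self.mode!r}")

    @property
    def r(self) -> float:
        """Per-generation exponential growth rate (0 for constant epochs)."""
        if self.mode == CONSTANT:
            return 0.0
        return math.log(self.N_end / self.N_start) / (self.t_start - self.t_end)

    def size_at(self, t: float) -> int:
        """Size at time ``t`` (generations bp) inside ``[t_end, t_start]``."""
        if not self.t_end <= t <= self.t_start:
            raise InputError(f"t={t} outside epoch [{self.t_end}, {self.t_start}]")
        if self.mode == CONSTANT:
            return self.N_start
        # anchor on the recent endpoint so that declared sizes are exact
        return int(round(self.N_end * math.exp(-self.r * (t - self.t_end))))


@dataclass(frozen=True)
class PopulationSplit:
    """This population's lineages derive from ``parent`` at ``time``."""

    parent: str
    time: int


@dataclass
class PopulationHistory:
    """Epochs (ordered past -> present) plus split annotations."""

    name: str
    epochs: list[DemographicEpoch]
    splits: list[PopulationSplit] = field(default_factory=list)

    def __post_init__(self) -> None:
        for older, newer in zip(self.epochs, self.epochs[1:]):
            if older.t_end != newer.t_start:
                raise InputError(
                    f"epochs of {self.name} must tile time without gaps: "
                    f"{older.t_end} != {newer.t_start}"
                )
        if self.epochs and self.epochs[-1].t_end != 0:
            raise InputError("most recent epoch must end at t=0")

    @property
    def t_oldest(self) -> int:
        return self.epochs[0].t_start

    def size_at(self, t: float) -> int:
        """Population size at ``t`` generations before present.

        At an epoch boundary the more-recent epoch's size is returned, so a
        bottleneck applies from the boundary generation onward.
        """
        if not 0 <= t <= self.t_oldest:
            raise InputError(f"t={t} outside [0, {self.t_oldest}] for {self.name}")
        for epoch in reversed(self.epochs):  # most recent first
            if epoch.t_end <= t <= epoch.t_start:
                return epoch.size_at(t)
        raise InputError(f"no epoch covers t={t}")  # pragma: no cover

    # -- serialization -------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "population": self.name,
            "epochs": [asdict(e) for e in self.epochs],
            "splits": [asdict(s) for s in self.splits],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PopulationHistory":
        return cls(
            name=d["population"],
            epochs=[DemographicEpoch(**e) for e in d["epochs"]],
            splits=[PopulationSplit(**s) for s in d["splits"]],
        )


def growth_rate(N0: float, Nf: float, dt: float) -> float:
    """Exponential growth rate ``r = ln(Nf/N0)/dt`` per generation."""
    if N0 < 1 or Nf < 1 or dt <= 0:
        raise InputError("growth_rate requires N0, Nf >= 1 and dt > 0")
    return math.log(Nf / N0) / dt


def size_at(history: PopulationHistory, t: float) -> int:
    """Module-level convenience wrapper for :meth:`PopulationHistory.size_at`."""
    return history.size_at(t)


# -- the default three-population mtDNA model --------------------------

#: Event times in generations before present.
T_AFR_EXPANSION = 8_800
T_OOA_SPLIT = 5_600
T_GROWTH_START = 848

#: Haploid (mtDNA-scaled) sizes.
N_AFR_ANCIENT = 1_825
N_AFR = 3_075
N_OOA = 525
N_ASI_BOTTLENECK = 128
N_EUR_BOTTLENECK = 250
N_ASI_PRESENT = 13_403
N_EUR_PRESENT = 7_381


def gutenkunst_mt_model() -> dict[str, PopulationHistory]:
    """The mtDNA-scaled three-population out-of-Africa model.

    Returns self-contained per-population timelines: each history carries
    the ancestral sizes on its own time axis, so the three can be simulated
    jointly (coalescent, using the split annotations) or separately
    (forward simulation, which treats the populations as isolated — the
    model has no migration).
    """
    afr = PopulationHistory(
        name="AFR",
        epochs=[
            DemographicEpoch(ANCIENT, T_AFR_EXPANSION, N_AFR_ANCIENT, N_AFR_ANCIENT),
            DemographicEpoch(T_AFR_EXPANSION, 0, N_AFR, N_AFR),
        ],
    )
    asi = PopulationHistory(
        name="ASI",
        epochs=[
            DemographicEpoch(ANCIENT, T_AFR_EXPANSION, N_AFR_ANCIENT, N_AFR_ANCIENT),
            DemographicEpoch(T_AFR_EXPANSION, T_OOA_SPLIT, N_AFR, N_AFR),
            DemographicEpoch(T_OOA_SPLIT, T_GROWTH_START, N_OOA, N_OOA),
            DemographicEpoch(
                T_GROWTH_START, 0, N_ASI_BOTTLENECK, N_ASI_PRESENT, EXPONENTIAL
            ),
        ],
        splits=[PopulationSplit(parent="EUR", time=T_GROWTH_START)],
    )
    eur = PopulationHistory(
        name="EUR",
        epochs=[
            DemographicEpoch(ANCIENT, T_AFR_EXPANSION, N_AFR_ANCIENT, N_AFR_ANCIENT),
            DemographicEpoch(T_AFR_EXPANSION, T_OOA_SPLIT, N_AFR, N_AFR),
            DemographicEpoch(T_OOA_SPLIT, T_GROWTH_START, N_OOA, N_OOA),
            DemographicEpoch(
                T_GROWTH_START, 0, N_EUR_BOTTLENECK, N_EUR_PRESENT, EXPONENTIAL
            ),
        ],
        splits=[PopulationSplit(parent="AFR", time=T_OOA_SPLIT)],
    )
    return {"AFR": afr, "ASI": asi, "EUR": eur}


def write_model(histories: dict[str, PopulationHistory], path) -> None:
    with open(path, "w") as fh:
        json.dump([h.to_dict() for h in histories.values()], fh, indent=1)


def read_model(path) -> dict[str, PopulationHistory]:
    with open(path) as fh:
        entries = json.load(fh)
    histories = [PopulationHistory.from_dict(d) for d in entries]
    return {h.name: h for h in histories}
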