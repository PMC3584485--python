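import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mtpopgen import synthetic_data as synth
from mtpopgen import variant_catalog as vc

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_aligned(seqs, pops=None, ids=None, ref_index=0):
    """Build an AlignedSet from plain sequence strings."""
    n = len(seqs)
    pops = pops or ["AFR"] * n
    ids = ids or [f"s{i}" for i in range(n)]
    matrix = np.array(
        [np.frombuffer(s.upper().encode(), dtype="S1") for s in seqs]
    )
    return vc.AlignedSet(ids=ids, populations=pops, matrix=matrix,
                         ref_index=ref_index)


STUDY_FEATURES = [
    synth.PlantedIndel(position=500),
    synth.PlantedHeteroplasmy(position=1200),
    synth.PlantedSingleton(position=100, population="AFR"),
    synth.PlantedSingleton(position=9000, population="EUR"),
    synth.PlantedVariant(position=7028, counts=(("AFR", 5), ("ASI", 12),
                                                ("EUR", 20))),
    synth.PlantedVariant(position=2706, counts=(("ASI", 2),)),
    synth.PlantedPathogenic(position=11778, frequencies=(("ASI", 0.2),),
                            status="Confirmed", disease="LHON-like"),
    synth.PlantedPathogenic(position=3460, frequencies=(("AFR", 0.10),),
                            status="Confirmed", disease="LHON-like"),
    synth.PlantedPathogenic(position=8344, frequencies=(("EUR", 0.05),),
                            status="Reported", disease="MERRF-like"),
]


def study_config(seed=42):
    return synth.SynthConfig(
        n_samples_per_pop={"AFR": 20, "ASI": 30, "EUR": 40},
        seed=seed,
        features=list(STUDY_FEATURES),
    )


@pytest.fixture(scope="session")
def study():
    """A fixed synthetic study exercising every planted feature kind."""
    return synth.generate_study(study_config())


@pytest.fixture(scope="session")
def dataset1(study):
    return vc.identify_snvs(study.aligned)


@pytest.fixture(scope="session")
def dataset2(dataset1):
    return vc.filter_singletons(dataset1)
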