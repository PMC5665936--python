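import numpy as np
import pytest
from hypothesis import settings, HealthCheck

from tandemcall import align_core as ac
from tandemcall import synthetic_locus as sl

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

# family seed chosen once so the mini repeat unit carries >= 2 CCNGG motif
# centers (needed by the hotspot tests); asserted at fixture build
MINI_SEED = 112


def mini_preset(copies: int = 5, cls: str = "A", family: str = "chr4",
                seed: int = MINI_SEED) -> sl.HaplotypePreset:
    return sl.HaplotypePreset(
        name=f"mini{copies}{cls}", flank5_len=600, flank3_len=300,
        unit_len=200, copy_number=copies, haplotype_class=cls,
        polya_motif_present=cls != "B", seed=seed, flank_family=family)


@pytest.fixture(scope="session")
def model() -> ac.ScoreModel:
    return ac.ScoreModel.default()


@pytest.fixture(scope="session")
def mini_locus() -> sl.LocusSequence:
    loc = sl.build_locus(mini_preset())
    centers = sl.find_motif_centers(loc.unit_seq)
    assert len(centers) >= 2, "mini family seed must give a motif-rich unit"
    return loc


@pytest.fixture(scope="session")
def bac13_locus() -> sl.LocusSequence:
    return sl.build_locus(sl.preset("BAC13", seed=1))


@pytest.fixture(scope="session")
def mini_trained(mini_locus) -> ac.ScoreModel:
    """Error model trained once on a 20x mini simulation (reused by tests)."""
    spec = sl.ErrorSpec(p_sub=0.10, ts_fraction=0.70, p_ins=0.01, p_del=0.01,
                        seed=5)
    reads = sl.simulate_reads(mini_locus, spec, mode="coverage", coverage=20,
                              length_median=800)
    return ac.train_error_model([r.sequence for r in reads],
                                mini_locus.sequence, max_iters=5)


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))
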