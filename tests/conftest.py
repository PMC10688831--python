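import numpy as np
import pytest

from lysogenkit import (
    FunctionalCategory,
    PipelineConfig,
    SynthSpec,
    forge_lysogen,
    jittered_candidate,
    refine_prophage,
)


@pytest.fixture(scope="session")
def config():
    return PipelineConfig()


@pytest.fixture(scope="session")
def forged_ser():
    """A full synthetic lysogen integrated into a serine tRNA gene, with a
    phage-carried Ile tRNA and an IS30 transposase in the tail module."""
    spec = SynthSpec(
        rng_seed=11,
        target_locus="tRNA-Ser",
        att_core_len=17,
        att_mutations=0,
        phage_trnas=[("Ile", "cat")],
        transposase_insert=(FunctionalCategory.tail, "IS30"),
        include_tils=True,
    )
    return forge_lysogen(spec)


@pytest.fixture(scope="session")
def refined_ser(forged_ser, config):
    genome, features, truth = forged_ser
    rng = np.random.default_rng(2024)
    cand = jittered_candidate(truth, genome, rng, max_jitter=500)
    return refine_prophage(genome, cand, features, config)


def overlaps(a_lo, a_hi, b_lo, b_hi) -> bool:
    return min(a_hi, b_hi) - max(a_lo, b_lo) > 0


def att_matches_truth(pair, truth) -> bool:
    """The reported pair is the planted repeat: its two cores overlap the
    planted cores (canonical trimming/extension shifts ends by a few bp)."""
    return overlaps(
        pair.left_start, pair.left_end, truth.left_core_start, truth.left_core_start + truth.core_len
    ) and overlaps(
        pair.right_start, pair.right_end, truth.right_core_start, truth.right_core_start + truth.core_len
    )
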