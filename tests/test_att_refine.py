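import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from att_oracle import oracle_pairs_numpy, oracle_pairs_python
from conftest import att_matches_truth
from lysogenkit import (
    AttPair,
    FunctionalCategory,
    GeneFeature,
    PipelineConfig,
    ProphageCandidate,
    SynthSpec,
    assign_locus,
    find_att_pair,
    forge_lysogen,
    jittered_candidate,
    refine_and_orient,
    refine_prophage,
    revcomp,
)
from lysogenkit.att_refine import scan_window_pair

ATT_L = "TATTCGTTGATGATATT"
ATT_R = "TATTCGTTGATCATTTT"


def truth_att(truth) -> AttPair:
    return AttPair(
        left_seq=truth.left_seq,
        right_seq=truth.right_seq,
        left_start=truth.left_core_start,
        right_start=truth.right_core_start,
        core_len=truth.core_len,
        mismatches=truth.mismatches,
        score=truth.core_len - 2 * truth.mismatches,
    )


# ---------------------------------------------------------------------------
# direct-repeat scanning
# ---------------------------------------------------------------------------


def test_exact_planted_pair_is_rank_one(config):
    """With identical planted cores and no mismatch budget, the top-ranked
    pair is the planted repeat."""
    genome, _, truth = forge_lysogen(SynthSpec(rng_seed=21, att_core_len=20, att_mutations=0))
    cand = jittered_candidate(truth, genome, np.random.default_rng(0), max_jitter=500)
    strict = PipelineConfig(att_max_mismatch=0)
    pairs = find_att_pair(genome.sequence(truth.contig_id), cand, strict)
    assert pairs and pairs[0].mismatches == 0
    assert att_matches_truth(pairs[0], truth)


def test_published_two_mismatch_pair_found():
    """The documented attL/attR pair differing at two positions is recovered
    with mismatches=2 under the default budget."""
    left_window = "C" * 20 + ATT_L + "C" * 20
    right_window = "G" * 20 + ATT_R + "G" * 20
    pairs = scan_window_pair(left_window, right_window, 0, 1000, PipelineConfig())
    assert pairs
    top = pairs[0]
    assert (top.left_seq, top.right_seq) == (ATT_L, ATT_R)
    assert top.mismatches == 2
    assert top.score == 17 - 2 * 2


def test_scan_scores_and_invariants(config):
    genome, _, truth = forge_lysogen(SynthSpec(rng_seed=22, att_core_len=22, att_mutations=1))
    cand = jittered_candidate(truth, genome, np.random.default_rng(1), max_jitter=500)
    pairs = find_att_pair(genome.sequence(truth.contig_id), cand, config)
    assert pairs
    for p in pairs[:50]:
        assert config.att_min_len <= p.core_len <= config.att_max_len
        assert p.mismatches <= config.att_max_mismatch
        assert p.left_start < p.right_start
        assert p.score == p.core_len - config.att_mismatch_penalty * p.mismatches
    scores = [p.score for p in pairs]
    assert scores == sorted(scores, reverse=True)


@settings(derandomize=True, deadline=None, max_examples=20)
@given(st.integers(0, 10_000))
def test_scanner_equals_bruteforce_oracle_small_windows(seed):
    """The run-based scanner reproduces the exhaustive triple-loop oracle on
    random windows, including planted repeats with mismatches."""
    rng = np.random.default_rng(seed)
    B = np.array(list("ACGT"))
    wl, wr = int(rng.integers(40, 110)), int(rng.integers(40, 110))
    left = "".join(B[rng.integers(0, 4, wl)])
    right = "".join(B[rng.integers(0, 4, wr)])
    if seed % 2 == 0:
        L = int(rng.integers(10, 26))
        core = "".join(B[rng.integers(0, 4, L)])
        i = int(rng.integers(0, wl - L + 1))
        j = int(rng.integers(0, wr - L + 1))
        mutated = list(core)
        for p in rng.choice(L, int(rng.integers(0, 3)), replace=False):
            mutated[p] = [b for b in "ACGT" if b != mutated[p]][int(rng.integers(3))]
        left = left[:i] + core + left[i + L :]
        right = right[:j] + "".join(mutated) + right[j + L :]
    cfg = PipelineConfig()
    got = [
        (p.left_start, p.right_start, p.core_len, p.mismatches)
        for p in scan_window_pair(left, right, 0, wl + 50, cfg)
    ]
    assert got == oracle_pairs_python(left, right, 0, wl + 50, cfg)


def test_scanner_equals_dense_oracle_kb_windows():
    """Oracle equivalence holds at kilobase windows (dense matrix oracle)."""
    rng = np.random.default_rng(7)
    B = np.array(list("ACGT"))
    w = 1200
    left = "".join(B[rng.integers(0, 4, w)])
    right = "".join(B[rng.integers(0, 4, w)])
    core = "".join(B[rng.integers(0, 4, 17)])
    left = left[:300] + core + left[317:]
    right = right[:900] + core + right[917:]
    cfg = PipelineConfig()
    got = [
        (p.left_start, p.right_start, p.core_len, p.mismatches)
        for p in scan_window_pair(left, right, 0, 2000, cfg)
    ]
    assert got == oracle_pairs_numpy(left, right, 0, 2000, cfg)


def test_circular_contig_wraps_origin(config):
    """An att pair whose flank windows straddle the origin of a circular
    contig is still recovered (virtual coordinates wrap modulo the length)."""
    genome, _, truth = forge_lysogen(SynthSpec(rng_seed=25, att_core_len=20))
    seq = genome.sequence(truth.contig_id)
    n = len(seq)
    # roll the sequence so the prophage midpoint sits at the origin: the
    # candidate then spans the origin in virtual coordinates
    mid = (truth.prophage_start + truth.prophage_end) // 2
    rolled = seq[mid:] + seq[:mid]
    start_v = n - (mid - truth.prophage_start)  # left boundary, virtual
    end_v = n + (truth.prophage_end - mid)  # right boundary, beyond n
    cand = ProphageCandidate(genome_id="g", contig_id="c", start=start_v, end=end_v)
    pairs = find_att_pair(rolled, cand, config, circular=True)
    assert pairs
    top = pairs[0]
    left_rolled = start_v % n  # planted attL core position on the rolled contig
    right_rolled = (end_v - truth.core_len) % n
    assert abs(top.left_start % n - left_rolled) <= 5
    assert abs(top.right_start % n - right_rolled) <= 5


# ---------------------------------------------------------------------------
# orientation
# ---------------------------------------------------------------------------


def test_forward_cassette_oriented_forward(refined_ser, forged_ser):
    _, _, truth = forged_ser
    assert refined_ser.att_status == "both"
    assert refined_ser.orientation == "forward"
    assert att_matches_truth(refined_ser.att, truth)
    assert refined_ser.locus is not None and refined_ser.locus.kind == "tRNA"


def test_reverse_complement_cassette_detected(config):
    spec = SynthSpec(rng_seed=31, orientation="reverse_complement", att_core_len=20)
    genome, features, truth = forge_lysogen(spec)
    cand = jittered_candidate(truth, genome, np.random.default_rng(3), max_jitter=500)
    refined = refine_prophage(genome, cand, features, config)
    assert refined.orientation == "reverse_complement"


def test_refine_and_orient_is_involution_under_revcomp(forged_ser):
    """Mirroring the genome flips the orientation and swaps att labels, and
    nothing else: the displayed attL sequence is unchanged."""
    genome, features, truth = forged_ser
    n = len(genome.sequence(truth.contig_id))
    att = truth_att(truth)
    cand = ProphageCandidate(
        genome_id=truth.genome_id, contig_id=truth.contig_id,
        start=truth.prophage_start, end=truth.prophage_end,
    )
    fwd = refine_and_orient(cand, att, features)
    assert fwd.orientation == "forward"

    mirrored_feats = [
        GeneFeature(
            feature_id=f.feature_id, contig_id=f.contig_id,
            start=n - f.end, end=n - f.start,
            strand="-" if f.strand == "+" else "+",
            kind=f.kind, product=f.product, name=f.name, category=f.category,
        )
        for f in features
    ]
    mirrored_att = AttPair(
        left_seq=revcomp(att.right_seq), right_seq=revcomp(att.left_seq),
        left_start=n - att.right_end, right_start=n - att.left_end,
        core_len=att.core_len, mismatches=att.mismatches, score=att.score,
    )
    mirrored_cand = ProphageCandidate(
        genome_id=truth.genome_id, contig_id=truth.contig_id,
        start=n - truth.prophage_end, end=n - truth.prophage_start,
    )
    rc = refine_and_orient(mirrored_cand, mirrored_att, mirrored_feats)
    assert rc.orientation == "reverse_complement"
    assert rc.attL_seq == fwd.attL_seq
    assert rc.attR_seq == fwd.attR_seq


def test_region_without_marker_genes_warns_and_defaults_forward(forged_ser):
    genome, _, truth = forged_ser
    att = truth_att(truth)
    cand = ProphageCandidate(
        genome_id="g", contig_id=truth.contig_id,
        start=truth.prophage_start, end=truth.prophage_end,
    )
    refined = refine_and_orient(cand, att, [])  # only hypothetical context
    assert refined.orientation == "forward"
    assert refined.warnings


# ---------------------------------------------------------------------------
# locus assignment
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "locus,kind,detail",
    [
        ("tRNA-Ser", "tRNA", "Ser"),
        ("tRNA-Leu", "tRNA", "Leu"),
        ("tmRNA", "tmRNA", "ssrA"),
        ("lepA", "coding_gene", "lepA"),
        ("noncoding", "noncoding", ""),
    ],
)
def test_assign_locus_by_target(locus, kind, detail):
    genome, features, truth = forge_lysogen(SynthSpec(rng_seed=41, target_locus=locus))
    label = assign_locus(truth_att(truth), features)
    assert label.kind == kind
    assert label.detail == detail
    if kind != "noncoding":
        assert label.disrupted_feature_id == truth.target_feature_id


def test_assign_locus_recognises_split_partial_pattern():
    """The partial tRNA copy at one junction and the restored full gene at
    the other resolve to a single unambiguous tRNA locus."""
    genome, features, truth = forge_lysogen(SynthSpec(rng_seed=43, target_locus="tRNA-Ser"))
    partials = [f for f in features if "(partial)" in f.product]
    assert partials, "forge should annotate the residual partial copy"
    label = assign_locus(truth_att(truth), features)
    assert label.kind == "tRNA" and label.detail == "Ser"
    assert not label.ambiguous
    assert label.disrupted_feature_id == truth.target_feature_id


def test_contig_edge_degrades_att_status(config):
    """A candidate flush against a linear contig edge degrades gracefully
    instead of failing."""
    genome, features, truth = forge_lysogen(SynthSpec(rng_seed=44))
    seq = genome.sequence(truth.contig_id)
    # truncate the contig right at the prophage end: attR side unsequenced
    cut = seq[: truth.prophage_end - truth.core_len]
    from lysogenkit import GenomeRecord

    g2 = GenomeRecord(id="cut", contigs={truth.contig_id: cut})
    cand = ProphageCandidate(
        genome_id="cut", contig_id=truth.contig_id,
        start=truth.prophage_start, end=len(cut),
    )
    feats = [f for f in features if f.end <= len(cut)]
    refined = refine_prophage(g2, cand, feats, config)
    assert refined.att_status in ("attL_only", "none")
    if refined.att_status == "attL_only":
        assert refined.warnings
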