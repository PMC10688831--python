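import math
from functools import lru_cache

import dendropy
import numpy as np
import pytest
from dendropy.calculate import treecompare
from hypothesis import given, settings
from hypothesis import strategies as st

from lysogenkit import (
    DistanceMatrix,
    SaturationError,
    assign_groups,
    bootstrap_support,
    forge_marker_family,
    global_align,
    identity_percent,
    jc69_distance,
    nj_tree,
    pairwise_p,
    random_tree,
)
from lysogenkit.io_core import LysogenKitError


# ---------------------------------------------------------------------------
# global alignment
# ---------------------------------------------------------------------------


def _affine_oracle(a: str, b: str, match=1, mismatch=-1, open_=-5, extend=-1) -> float:
    """Exhaustive affine-gap global alignment score by state DP (independent
    of the production aligner)."""

    @lru_cache(maxsize=None)
    def best(i: int, j: int, state: str) -> float:
        if i == len(a) and j == len(b):
            return 0.0
        options = []
        if i < len(a) and j < len(b):
            sub = match if a[i] == b[j] else mismatch
            options.append(sub + best(i + 1, j + 1, "m"))
        if i < len(a):
            cost = extend if state == "ga" else open_
            options.append(cost + best(i + 1, j, "ga"))
        if j < len(b):
            cost = extend if state == "gb" else open_
            options.append(cost + best(i, j + 1, "gb"))
        return max(options)

    return best(0, 0, "m")


def test_identical_sequences_are_100_percent():
    _, ident = global_align("ACGTACGT", "ACGTACGT")
    assert ident == 100.0


def test_single_substitution_identity():
    _, ident = global_align("ACGT", "ACGA")
    assert ident == 75.0


@settings(derandomize=True, deadline=None, max_examples=25)
@given(st.integers(0, 10_000))
def test_alignment_score_matches_exhaustive_oracle(seed):
    rng = np.random.default_rng(seed)
    B = np.array(list("ACGT"))
    a = "".join(B[rng.integers(0, 4, int(rng.integers(4, 12)))])
    b = "".join(B[rng.integers(0, 4, int(rng.integers(4, 12)))])
    alignment, _ = global_align(a, b)
    assert alignment.score == pytest.approx(_affine_oracle(a, b))


def test_non_dna_symbols_rejected():
    with pytest.raises(LysogenKitError):
        global_align("ACGT", "ACXU")


# ---------------------------------------------------------------------------
# JC69 distance
# ---------------------------------------------------------------------------


def test_jc69_closed_form_values():
    assert jc69_distance(0.0) == 0.0
    assert jc69_distance(0.3) == pytest.approx(-0.75 * math.log(0.6), abs=1e-12)
    assert jc69_distance(0.3) == pytest.approx(0.3831, abs=1e-4)


def test_jc69_saturation_raises():
    with pytest.raises(SaturationError):
        jc69_distance(0.75)


@settings(derandomize=True, deadline=None, max_examples=60)
@given(st.floats(0.0, 0.7499))
def test_jc69_monotone_and_dominates_p(p):
    d = jc69_distance(p)
    assert d >= p - 1e-12  # d(p) >= p, up to float rounding near 0
    assert jc69_distance(min(p + 1e-4, 0.7499)) >= d


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------


def _branch_lengths(tree: dendropy.Tree) -> dict[str, float]:
    return {lf.taxon.label: lf.edge.length for lf in tree.leaf_node_iter()}


def test_three_taxon_branch_lengths_closed_form():
    """d(A,B)=2, d(A,C)=3, d(B,C)=4 has the unique solution a=0.5, b=1.5,
    c=2.5 (three-point formulas)."""
    D = DistanceMatrix(taxa=["A", "B", "C"], d=np.array([[0, 2, 3], [2, 0, 4], [3, 4, 0.0]]))
    result = nj_tree(D)
    bl = _branch_lengths(result.tree)
    assert bl["A"] == pytest.approx(0.5, abs=1e-9)
    assert bl["B"] == pytest.approx(1.5, abs=1e-9)
    assert bl["C"] == pytest.approx(2.5, abs=1e-9)


def _quartet_split(d: np.ndarray) -> str:
    """Four-point-condition oracle: the split with the smallest pair-sum."""
    sums = {
        "AB|CD": d[0, 1] + d[2, 3],
        "AC|BD": d[0, 2] + d[1, 3],
        "AD|BC": d[0, 3] + d[1, 2],
    }
    return min(sums, key=sums.get)


def test_four_taxon_split_recovered():
    # tree ((A:1,B:2):1,(C:3,D:4))
    d = np.array(
        [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], dtype=float
    )
    assert _quartet_split(d) == "AB|CD"
    result = nj_tree(DistanceMatrix(taxa=["A", "B", "C", "D"], d=d))
    tree = result.tree
    tree.encode_bipartitions()
    labels = {
        frozenset(t.label for t in bip.leafset_taxa(tree.taxon_namespace))
        for bip in tree.bipartition_encoding
    }
    assert frozenset({"A", "B"}) in labels or frozenset({"C", "D"}) in labels


def test_equal_distances_give_star_like_tree():
    d = np.ones((4, 4)) - np.eye(4)
    result = nj_tree(DistanceMatrix(taxa=list("ABCD"), d=d))
    internal = [
        e.length
        for e in result.tree.preorder_edge_iter()
        if e.head_node and not e.head_node.is_leaf() and e.length is not None
    ]
    assert all(abs(x) < 1e-9 for x in internal)


def test_nj_rejects_asymmetric_input():
    with pytest.raises(LysogenKitError):
        DistanceMatrix(taxa=["A", "B", "C"], d=np.array([[0, 1, 2], [9, 0, 1], [2, 1, 0.0]]))


@settings(derandomize=True, deadline=None, max_examples=25)
@given(st.integers(0, 10_000), st.integers(4, 8))
def test_nj_exact_on_additive_matrices(seed, n):
    """NJ reconstructs the generating topology exactly from patristic
    distances of random trees."""
    rng = np.random.default_rng(seed)
    true_tree = random_tree(n, rng)
    D = DistanceMatrix.from_tree(true_tree)
    result = nj_tree(D)
    est = result.tree
    est.migrate_taxon_namespace(true_tree.taxon_namespace)
    true_tree.encode_bipartitions()
    est.encode_bipartitions()
    assert treecompare.symmetric_difference(true_tree, est, is_bipartitions_updated=True) == 0


def test_nj_matches_independent_reference_implementation():
    """Cross-check against dendropy's own NJ on an additive matrix."""
    rng = np.random.default_rng(123)
    true_tree = random_tree(7, rng)
    D = DistanceMatrix.from_tree(true_tree)
    mine = nj_tree(D).tree

    pdm = true_tree.phylogenetic_distance_matrix()
    ref = pdm.nj_tree()
    ref.migrate_taxon_namespace(mine.taxon_namespace)
    mine.encode_bipartitions()
    ref.encode_bipartitions()
    assert treecompare.symmetric_difference(mine, ref, is_bipartitions_updated=True) == 0


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------


def _two_clade_alignment(seq_len=500, seed=5):
    tree = "((a:0.05,b:0.05):0.5,(c:0.05,d:0.05):0.5);"
    return forge_marker_family(tree, seq_len=seq_len, rng_seed=seed)[0]


def test_bootstrap_single_replicate_supports_are_0_or_100():
    aln = _two_clade_alignment()
    result = bootstrap_support(aln, reps=1, rng_seed=0)
    supports = [
        int(n.label)
        for n in result.tree.preorder_node_iter()
        if n.label is not None and not n.is_leaf()
    ]
    assert supports and all(s in (0, 100) for s in supports)


def test_bootstrap_two_clades_high_support():
    aln = _two_clade_alignment()
    result = bootstrap_support(aln, reps=100, rng_seed=1)
    supports = [
        int(n.label)
        for n in result.tree.preorder_node_iter()
        if n.label is not None and not n.is_leaf()
    ]
    assert max(supports) >= 95


def test_bootstrap_identical_sequences_flagged_uninformative():
    aln = {t: "ACGTACGTAC" for t in "abcd"}
    result = bootstrap_support(aln, reps=5, rng_seed=0)
    assert result.uninformative


def test_bootstrap_is_deterministic_for_fixed_seed():
    aln = _two_clade_alignment()
    n1 = bootstrap_support(aln, reps=20, rng_seed=7).newick()
    n2 = bootstrap_support(aln, reps=20, rng_seed=7).newick()
    assert n1 == n2


def test_bootstrap_rejects_bad_inputs():
    aln = _two_clade_alignment()
    with pytest.raises(LysogenKitError):
        bootstrap_support(aln, reps=0)
    with pytest.raises(LysogenKitError):
        bootstrap_support({"a": "ACGT", "b": "ACGT"}, reps=10)


# ---------------------------------------------------------------------------
# insertion groups
# ---------------------------------------------------------------------------


def _identity_from(groups_spec):
    """Build taxa, identity matrix and locus labels from a simple spec:
    list of (taxon, cluster_key, locus); within-cluster identity 90, between 45."""
    taxa = [t for t, _, _ in groups_spec]
    cluster = {t: c for t, c, _ in groups_spec}
    loci = {t: l for t, _, l in groups_spec}
    n = len(taxa)
    ident = np.full((n, n), 45.0)
    for i in range(n):
        for j in range(n):
            if cluster[taxa[i]] == cluster[taxa[j]]:
                ident[i, j] = 90.0
        ident[i, i] = 100.0
    return taxa, ident, loci


def test_locus_discordant_member_is_outlier():
    """A taxon clustering with group II seeds while integrating into a
    serine tRNA gene is flagged (the integrase/locus discordance case)."""
    spec = [
        ("seed1", "g2", "tmRNA"),
        ("seed2", "g2", "tmRNA"),
        ("odd_one", "g2", "tRNA-Ser"),
        ("other", "x", "tRNA-Leu"),
    ]
    taxa, ident, loci = _identity_from(spec)
    res = assign_groups(taxa, ident, loci, seed_groups={"seed1": "II", "seed2": "II"})
    assert res.groups["odd_one"] == "II"
    assert "odd_one" in res.outliers
    assert "tRNA-Ser" in res.outliers["odd_one"]
    assert "seed1" not in res.outliers


def test_low_identity_cluster_becomes_new_group():
    """Taxa at ~45-47% identity to seeded integrases form their own group
    even when sharing the seeds' locus."""
    spec = [
        ("g1a", "g1", "tRNA-Leu"),
        ("g1b", "g1", "tRNA-Leu"),
        ("far1", "far", "tRNA-Leu"),
        ("far2", "far", "tRNA-Leu"),
    ]
    taxa, ident, loci = _identity_from(spec)
    res = assign_groups(taxa, ident, loci, seed_groups={"g1a": "I", "g1b": "I"})
    assert res.groups["far1"] == res.groups["far2"]
    assert res.groups["far1"].startswith("new-")
    assert "far1" not in res.outliers  # same locus as its own (new) group


def test_singleton_gets_its_own_group():
    taxa, ident, loci = _identity_from([("lonely", "a", "tRNA-Gln")])
    res = assign_groups(taxa, ident, loci)
    assert res.groups == {"lonely": "new-1"}
    assert res.outliers == {}


def test_taxon_without_locus_excluded_with_warning():
    spec = [("a", "c1", "tRNA-Ser"), ("b", "c1", "tRNA-Ser")]
    taxa, ident, _ = _identity_from(spec)
    res = assign_groups(taxa + ["nolocus"], np.pad(ident, ((0, 1), (0, 1)), constant_values=45.0),
                        {"a": "tRNA-Ser", "b": "tRNA-Ser"})
    assert "nolocus" not in res.groups
    assert any("nolocus" in w for w in res.warnings)


def test_group_assignment_invariant_under_taxon_permutation():
    spec = [
        ("t1", "c1", "tRNA-Ser"),
        ("t2", "c1", "tRNA-Ser"),
        ("t3", "c2", "tmRNA"),
        ("t4", "c2", "tRNA-Leu"),
        ("t5", "c3", "lepA"),
    ]
    taxa, ident, loci = _identity_from(spec)
    res1 = assign_groups(taxa, ident, loci, seed_groups={"t3": "II"})
    perm = [3, 0, 4, 2, 1]
    taxa_p = [taxa[i] for i in perm]
    ident_p = ident[np.ix_(perm, perm)]
    res2 = assign_groups(taxa_p, ident_p, loci, seed_groups={"t3": "II"})
    assert res1.groups == res2.groups
    assert res1.outliers == res2.outliers


def test_identity_percent_on_marker_genes():
    aln = _two_clade_alignment(seq_len=300)
    within = identity_percent(aln["a"], aln["b"])
    between = identity_percent(aln["a"], aln["c"])
    assert within > between
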