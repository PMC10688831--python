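"""Marker-gene phylogenetics: alignment, distances, NJ trees, bootstrap,
insertion-group assignment.

Integrase genes cluster by the chromosomal locus their phage integrates
into, so a distance tree of integrases doubles as an integration-locus
classifier; the terminase large subunit serves as a second, packaging-side
marker.  Distances are Jukes-Cantor (the one-parameter substitution model,
d = -(3/4) ln(1 - 4p/3)) or raw p-distances; trees are built with the
Saitou-Nei neighbor-joining algorithm, which recovers the generating tree
exactly on additive matrices, and node supports come from column-resampling
bootstrap replicates.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import dendropy
import numpy as np
from Bio import Align
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .io_core import DNA_ALPHABET, LysogenKitError


class SaturationError(LysogenKitError):
    """Observed mismatch fraction at or beyond the JC69 model ceiling (3/4)."""


def make_aligner(
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = -5.0,
    gap_extend: float = -1.0,
) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def global_align(
    a: str, b: str, aligner: Align.PairwiseAligner | None = None
) -> tuple[Align.Alignment, float]:
    """Needleman-Wunsch global alignment and percent identity.

    Default affine scoring: match +1, mismatch -1, gap of length k costs
    5 + (k - 1).  Identity = matching columns / total alignment columns x 100.
    """
    for name, s in (("first", a), ("second", b)):
        if not s:
            raise LysogenKitError(f"{name} sequence is empty")
        bad = set(s.upper()) - DNA_ALPHABET
        if bad:
            raise LysogenKitError(f"{name} sequence has non-ACGTN symbols: {sorted(bad)}")
    aligner = aligner or make_aligner()
    alignment = aligner.align(a.upper(), b.upper())[0]
    counts = alignment.counts()
    identity = 100.0 * counts.identities / alignment.length
    return alignment, identity


def identity_percent(a: str, b: str, aligner: Align.PairwiseAligner | None = None) -> float:
    return global_align(a, b, aligner)[1]


def pairwise_p(a: str, b: str) -> float:
    """Mismatch fraction between two aligned rows, gap columns ignored."""
    if len(a) != len(b):
        raise LysogenKitError("aligned rows differ in length")
    total = mism = 0
    for x, y in zip(a.upper(), b.upper()):
        if x == "-" or y == "-":
            continue
        total += 1
        if x != y:
            mism += 1
    if total == 0:
        raise LysogenKitError("no comparable (non-gap) columns")
    return mism / total


def jc69_distance(p: float) -> float:
    """Jukes-Cantor distance d = -(3/4) ln(1 - 4p/3) for mismatch fraction p.

    Corrects the observed proportion of differing sites for multiple hits;
    undefined at p >= 3/4 (saturation), where a SaturationError is raised so
    the caller may fall back to a capped, flagged distance.
    """
    if p < 0:
        raise LysogenKitError("mismatch fraction cannot be negative")
    if p >= 0.75:
        raise SaturationError(f"p={p} >= 0.75: JC69 distance undefined (saturated)")
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


#: capped stand-in distance used when a bootstrap replicate saturates
JC_SATURATION_CAP = jc69_distance(0.7499)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix with taxon labels."""

    taxa: list[str]
    d: np.ndarray
    saturated_pairs: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.taxa)
        if self.d.shape != (n, n):
            raise LysogenKitError("matrix shape does not match taxa")
        if not np.allclose(self.d, self.d.T):
            raise LysogenKitError("distance matrix not symmetric")
        if np.any(self.d < 0):
            raise LysogenKitError("negative distances")
        if np.any(np.diag(self.d) != 0):
            raise LysogenKitError("non-zero diagonal")

    @classmethod
    def from_alignment(
        cls,
        alignment: Mapping[str, str],
        model: str = "jc69",
        on_saturation: str = "error",
    ) -> "DistanceMatrix":
        """Distances between all rows of a (gapless or gapped) alignment.

        model is "jc69" or "p".  on_saturation: "error" raises, "cap" uses a
        fixed large distance and records the pair as saturated.
        """
        taxa = list(alignment)
        n = len(taxa)
        d = np.zeros((n, n))
        saturated = []
        for i in range(n):
            for j in range(i + 1, n):
                p = pairwise_p(alignment[taxa[i]], alignment[taxa[j]])
                if model == "p":
                    dij = p
                elif model == "jc69":
                    try:
                        dij = jc69_distance(p)
                    except SaturationError:
                        if on_saturation != "cap":
                            raise
                        dij = JC_SATURATION_CAP
                        saturated.append((taxa[i], taxa[j]))
                else:
                    raise LysogenKitError(f"unknown model {model!r}")
                d[i, j] = d[j, i] = dij
        return cls(taxa=taxa, d=d, saturated_pairs=saturated)

    @classmethod
    def from_tree(cls, tree: dendropy.Tree) -> "DistanceMatrix":
        """Patristic (path-length) distances of a tree — an additive matrix."""
        pdm = tree.phylogenetic_distance_matrix()
        taxa = sorted(t.label for t in tree.taxon_namespace)
        lookup = {t.label: t for t in tree.taxon_namespace}
        n = len(taxa)
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d[i, j] = d[j, i] = pdm.patristic_distance(lookup[taxa[i]], lookup[taxa[j]])
        return cls(taxa=taxa, d=d)

    def to_phylip(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{len(self.taxa)}\n")
            for i, t in enumerate(self.taxa):
                row = " ".join(f"{x:.6f}" for x in self.d[i])
                fh.write(f"{t[:10]:<10} {row}\n")


@dataclass
class PhyloTree:
    """An (unrooted) NJ tree with optional integer bootstrap supports."""

    tree: dendropy.Tree
    clamped_branches: int = 0
    uninformative: bool = False

    def newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.newick() + "\n")


def nj_tree(D: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbor joining with deterministic tie-breaking.

    At each step the pair minimising Q(i,j) = (n-2) d(i,j) - r_i - r_j is
    joined; ties go to the lowest index pair in the current matrix order.
    Negative branch lengths are clamped to zero and counted.  Exact on
    additive matrices; the final three lineages are joined at an unrooted
    trifurcation using the three-point formulas.
    """
    n = len(D.taxa)
    if n < 3:
        raise LysogenKitError("neighbor joining needs at least 3 taxa")
    if not np.all(np.isfinite(D.d)):
        raise LysogenKitError("non-finite distances")

    ns = dendropy.TaxonNamespace(D.taxa)
    nodes: list[dendropy.Node] = []
    for t in D.taxa:
        node = dendropy.Node()
        node.taxon = ns.get_taxon(t)
        nodes.append(node)
    d = D.d.astype(float).copy()
    clamped = 0

    def clamp(x: float) -> float:
        nonlocal clamped
        if x < 0:
            clamped += 1
            return 0.0
        return x

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        Q = (m - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        # lowest-index pair among minima
        best = None
        qmin = np.inf
        for i in range(m):
            for j in range(i + 1, m):
                if Q[i, j] < qmin - 1e-12:
                    qmin = Q[i, j]
                    best = (i, j)
        i, j = best
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = d[i, j] - li
        parent = dendropy.Node()
        nodes[i].edge.length = clamp(li)
        nodes[j].edge.length = clamp(lj)
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        dnew = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        d2 = np.zeros((m - 1, m - 1))
        d2[: m - 2, : m - 2] = d[np.ix_(keep, keep)]
        d2[m - 2, : m - 2] = dnew[keep]
        d2[: m - 2, m - 2] = dnew[keep]
        d = d2
        nodes = [nodes[k] for k in keep] + [parent]

    # unrooted trifurcation from the three-point formulas
    a, b, c = d[0, 1], d[0, 2], d[1, 2]
    la = clamp(0.5 * (a + b - c))
    lb = clamp(0.5 * (a + c - b))
    lc = clamp(0.5 * (b + c - a))
    root = dendropy.Node()
    for node, ln in zip(nodes, (la, lb, lc)):
        node.edge.length = ln
        root.add_child(node)
    tree = dendropy.Tree(taxon_namespace=ns)
    tree.seed_node = root
    tree.is_rooted = False
    return PhyloTree(tree=tree, clamped_branches=clamped)


def bootstrap_support(
    alignment: Mapping[str, str],
    reps: int,
    model: str = "jc69",
    rng_seed: int = 0,
) -> PhyloTree:
    """NJ tree with bootstrap supports from column resampling.

    Alignment columns are resampled with replacement ``reps`` times; each
    replicate's distances (under ``model``, saturation capped) feed the same
    deterministic NJ; the support of each internal bipartition of the
    original tree is the percentage of replicates containing it.
    Deterministic for a fixed ``rng_seed``.
    """
    if reps < 1:
        raise LysogenKitError("bootstrap needs at least one replicate")
    taxa = list(alignment)
    if len(taxa) < 3:
        raise LysogenKitError("bootstrap needs at least 3 sequences")
    lengths = {len(s) for s in alignment.values()}
    if len(lengths) != 1:
        raise LysogenKitError("alignment rows differ in length")
    (L,) = lengths
    if L == 0:
        raise LysogenKitError("zero-length alignment")

    base = nj_tree(DistanceMatrix.from_alignment(alignment, model=model, on_saturation="cap"))
    ns = base.tree.taxon_namespace
    base.tree.encode_bipartitions()
    uninformative = len(set(alignment.values())) == 1

    mat = np.array([np.frombuffer(alignment[t].encode(), dtype=np.uint8) for t in taxa])
    rng = np.random.default_rng(rng_seed)
    counts: Counter[int] = Counter()
    n = len(taxa)
    for _ in range(reps):
        cols = rng.integers(0, L, size=L)
        sub = mat[:, cols]
        d = np.zeros((n, n))
        for i in range(n):
            diff = (sub[i + 1 :] != sub[i]).mean(axis=1)
            for k, p in enumerate(diff):
                j = i + 1 + k
                if model == "p":
                    dij = float(p)
                else:
                    try:
                        dij = jc69_distance(float(p))
                    except SaturationError:
                        dij = JC_SATURATION_CAP
                d[i, j] = d[j, i] = dij
        rep_tree = nj_tree(DistanceMatrix(taxa=taxa, d=d)).tree
        rep_tree.migrate_taxon_namespace(ns)
        rep_tree.encode_bipartitions()
        for bip in rep_tree.bipartition_encoding:
            counts[bip.split_bitmask] += 1

    for edge in base.tree.preorder_edge_iter():
        node = edge.head_node
        if node.is_leaf() or node is base.tree.seed_node:
            continue
        support = round(100.0 * counts[edge.bipartition.split_bitmask] / reps)
        node.label = str(int(support))
    return PhyloTree(tree=base.tree, uninformative=uninformative)


# ---------------------------------------------------------------------------
# insertion groups
# ---------------------------------------------------------------------------


@dataclass
class GroupAssignment:
    """Insertion-group labels per taxon plus locus-discordance outliers."""

    groups: dict[str, str]
    outliers: dict[str, str] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    clusters: list[list[str]] = field(default_factory=list)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            [
                (t, g, t in self.outliers, self.outliers.get(t, ""))
                for t, g in sorted(self.groups.items())
            ],
            columns=["taxon", "group", "outlier", "reason"],
        )

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)


def pairwise_identity_matrix(
    seqs: Mapping[str, str], aligner: Align.PairwiseAligner | None = None
) -> tuple[list[str], np.ndarray]:
    """Percent-identity matrix from all-vs-all global alignments."""
    taxa = list(seqs)
    n = len(taxa)
    ident = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            ident[i, j] = ident[j, i] = identity_percent(seqs[taxa[i]], seqs[taxa[j]], aligner)
    return taxa, ident


def assign_groups(
    taxa: Sequence[str],
    identity: np.ndarray,
    locus_labels: Mapping[str, str],
    seed_groups: Mapping[str, str] | None = None,
    link_identity: float = 80.0,
) -> GroupAssignment:
    """Cluster marker genes into insertion groups and flag locus outliers.

    Taxa are joined by single linkage at pairwise identity >= link_identity.
    A cluster containing seed taxa of a known group inherits that label;
    unseeded clusters get fresh labels (new-1, new-2, ... ordered by their
    lexicographically smallest member, so the assignment is invariant to
    taxon order).  Each group's reference locus is the modal locus of its
    seeds (of all members when unseeded); a member whose own locus differs is
    flagged an outlier — the signature of a phage whose integrase clusters
    with one group while integrating elsewhere.
    """
    seed_groups = dict(seed_groups or {})
    taxa = list(taxa)
    identity = np.asarray(identity, dtype=float)
    warnings: list[str] = []

    included = [t for t in taxa if t in locus_labels]
    for t in taxa:
        if t not in locus_labels:
            warnings.append(f"{t}: no locus label; excluded from group assignment")
    idx = [taxa.index(t) for t in included]
    sub = identity[np.ix_(idx, idx)]
    n = len(included)
    if n == 0:
        return GroupAssignment(groups={}, warnings=warnings)

    adj = csr_matrix(sub >= link_identity)
    n_comp, labels = connected_components(adj, directed=False)
    comps: list[list[str]] = [[] for _ in range(n_comp)]
    for k, t in enumerate(included):
        comps[labels[k]].append(t)
    comps = sorted((sorted(c) for c in comps), key=lambda c: c[0])

    groups: dict[str, str] = {}
    outliers: dict[str, str] = {}
    new_counter = 0
    for comp in comps:
        seeds_here = [t for t in comp if t in seed_groups]
        if seeds_here:
            seed_labels = sorted({seed_groups[t] for t in seeds_here})
            label = Counter(seed_groups[t] for t in seeds_here).most_common(1)[0][0]
            if len(seed_labels) > 1:
                label = seed_labels[0]
                warnings.append(
                    f"cluster {comp[0]}...: seeds of groups {seed_labels} merged; using {label}"
                )
            reference = seeds_here
        else:
            new_counter += 1
            label = f"new-{new_counter}"
            reference = comp
        modal_locus = Counter(
            locus_labels[t] for t in reference
        ).most_common()
        top = modal_locus[0][1]
        modal = sorted(loc for loc, c in modal_locus if c == top)[0]
        for t in comp:
            groups[t] = label
            if locus_labels[t] != modal:
                outliers[t] = (
                    f"integrates at {locus_labels[t]} but clusters with group {label} "
                    f"(modal locus {modal})"
                )
    return GroupAssignment(groups=groups, outliers=outliers, warnings=warnings, clusters=comps)
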