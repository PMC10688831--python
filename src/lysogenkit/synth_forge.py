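"""Synthetic lysogen and marker-gene generators with known ground truth.

The forge emulates the genome of a lysogen: a bacterial chromosome with a
temperate-phage cassette integrated at a target locus (tRNA/tmRNA gene, a
conserved coding gene such as *lepA*, or a non-coding position).  Integration
follows the canonical site-specific mechanism: the att core — here the 3'
terminal stretch of the target gene — is duplicated so that near-identical
direct repeats (attL/attR) flank the prophage, the full-length target gene is
reconstituted at the downstream junction and only a partial copy remains
upstream.  The cassette carries ordered gene modules
(lysogeny -> replication -> packaging -> head -> tail -> fiber -> lysis),
optional internal tRNA genes and transposases, and CDS sequences drawn from a
controllable codon-usage bias so phage-vs-host codon propensities are known
by construction.

Every output is deterministic for a fixed ``rng_seed``, and the emitted
FASTA/GFF3 re-read through :mod:`lysogenkit.io_core` reproduces the truth
table coordinates exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import dendropy
import numpy as np
from Bio.Data import CodonTable

from .io_core import (
    FunctionalCategory,
    GeneFeature,
    GenomeRecord,
    LysogenKitError,
    ProphageCandidate,
    revcomp,
)

_TABLE = CodonTable.unambiguous_dna_by_id[1]
#: codon -> amino acid (one letter), stop codons excluded
CODON_TO_AA: dict[str, str] = dict(_TABLE.forward_table)
STOP_CODONS: tuple[str, ...] = tuple(_TABLE.stop_codons)
AA_TO_CODONS: dict[str, list[str]] = {}
for _codon, _aa in sorted(CODON_TO_AA.items()):
    AA_TO_CODONS.setdefault(_aa, []).append(_codon)
AA_LIST: list[str] = sorted(AA_TO_CODONS)

BASES = np.array(list("ACGT"))

#: common anticodons (DNA, 5'->3') used for planted tRNA genes
DEFAULT_ANTICODONS = {
    "Ile": "gat",
    "Ser": "gga",
    "Leu": "tag",
    "Gln": "ttg",
    "Glu": "ttc",
    "Phe": "gaa",
    "His": "gtg",
    "Met": "cat",
    "Arg": "acg",
    "Gly": "gcc",
}

_MODULE_PRODUCTS: dict[FunctionalCategory, list[str]] = {
    FunctionalCategory.lysogeny: [
        "site-specific integrase",
        "CI-like repressor",
        "antirepressor",
        "excisionase",
        "immunity repressor",
        "Cro-like protein",
    ],
    FunctionalCategory.replication: [
        "replication initiation protein",
        "replicative DNA helicase",
        "DNA primase",
        "DNA polymerase",
        "single-stranded DNA-binding protein",
        "DNA topoisomerase",
    ],
    FunctionalCategory.packaging: [
        "terminase large subunit",
        "terminase small subunit",
        "DNA packaging protein",
    ],
    FunctionalCategory.head: [
        "portal protein",
        "major capsid protein",
        "head maturation protease",
        "scaffolding protein",
        "head-tail connector protein",
    ],
    FunctionalCategory.tail: [
        "tail tape measure protein",
        "major tail protein",
        "tail assembly chaperone",
        "baseplate protein",
        "tail terminator protein",
    ],
    FunctionalCategory.fiber: [
        "receptor-binding protein",
        "fibre protein",
        "host recognition spike protein",
    ],
    FunctionalCategory.lysis: [
        "holin",
        "N-acetylmuramoyl-L-alanine amidase",
        "endolysin",
        "spanin",
    ],
}

_HOST_PRODUCTS = [
    "30S ribosomal protein S4",
    "elongation factor Tu",
    "ABC transporter ATP-binding protein",
    "phosphoglycerate kinase",
    "MFS transporter",
    "aminotransferase class I",
    "cell division protein FtsZ",
    "preprotein translocase subunit SecY",
    "50S ribosomal protein L2",
    "UDP-glucose 4-epimerase",
]

#: default module plan: ~43 CDS, giving a cassette close to the 29-51 kb
#: prophage size range typical of temperate siphoviruses
DEFAULT_MODULE_PLAN: tuple[tuple[FunctionalCategory, int], ...] = (
    (FunctionalCategory.lysogeny, 6),
    (FunctionalCategory.replication, 10),
    (FunctionalCategory.packaging, 3),
    (FunctionalCategory.head, 7),
    (FunctionalCategory.tail, 10),
    (FunctionalCategory.fiber, 3),
    (FunctionalCategory.lysis, 4),
)

_TARGET_GENES = {
    "lepA": ("lepA", "Translation elongation factor 4", 1800),
    "sufB-like": ("sufB", "Fe-S cluster assembly protein SufB", 1400),
    "GMP-synthase": ("guaA", "glutamine-hydrolyzing GMP synthase", 1500),
    "glucose-6-P-isomerase": ("pgi", "glucose-6-phosphate isomerase", 1300),
}


@dataclass
class SynthSpec:
    """Parameters of one synthetic lysogen.

    ``target_locus`` is one of ``tRNA-<Isotype>`` (e.g. ``tRNA-Ser``),
    ``tmRNA``, ``lepA``, ``sufB-like``, ``GMP-synthase``,
    ``glucose-6-P-isomerase`` or ``noncoding``.  ``phage_codon_bias`` and
    ``host_codon_bias`` map one-letter amino acids to probability vectors over
    their synonymous codons (unspecified amino acids use uniform synonymous
    usage).
    """

    host_length: int = 50_000
    host_gc: float = 0.42
    target_locus: str = "tRNA-Ser"
    att_core_len: int = 17
    att_mutations: int = 0
    module_plan: Sequence[tuple[FunctionalCategory, int]] = DEFAULT_MODULE_PLAN
    phage_trnas: Sequence[tuple[str, str]] = ()
    phage_codon_bias: dict[str, dict[str, float]] = field(default_factory=dict)
    host_codon_bias: dict[str, dict[str, float]] = field(default_factory=dict)
    transposase_insert: tuple[FunctionalCategory, str] | None = None
    internal_att_before_lysis: bool = False
    orientation: str = "forward"  # or "reverse_complement"
    host_cds_count: int = 30
    include_tils: bool = False
    truncated: bool = False
    decoy_repeats: int = 0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 10 <= self.att_core_len <= 25:
            raise LysogenKitError("att_core_len must be within [10, 25] bp")
        self.module_plan = tuple((FunctionalCategory(c), int(n)) for c, n in self.module_plan)
        if not self.truncated and self.module_plan:
            if self.module_plan[0][0] is not FunctionalCategory.lysogeny:
                raise LysogenKitError("module_plan must begin with lysogeny (or set truncated)")
            if self.module_plan[-1][0] is not FunctionalCategory.lysis:
                raise LysogenKitError("module_plan must end with lysis (or set truncated)")
        for bias in (self.phage_codon_bias, self.host_codon_bias):
            for aa, vec in bias.items():
                if set(vec) - set(AA_TO_CODONS.get(aa, [])):
                    raise LysogenKitError(f"bias for {aa} names non-synonymous codons")
                if abs(sum(vec.values()) - 1.0) > 1e-9:
                    raise LysogenKitError(f"bias vector for {aa} does not sum to 1")


@dataclass
class TruthTable:
    """Ground truth of one forged lysogen (coordinates on the emitted contig)."""

    genome_id: str
    contig_id: str
    prophage_start: int
    prophage_end: int
    core_len: int
    left_core_start: int
    right_core_start: int
    left_seq: str
    right_seq: str
    mismatches: int
    orientation: str
    locus_kind: str  # tRNA | tmRNA | coding_gene | noncoding
    locus_detail: str
    target_feature_id: str
    gene_categories: dict[str, FunctionalCategory]
    planted_trnas: list[tuple[str, str, str]]  # (feature_id, isotype, anticodon)
    transposases: list[tuple[str, str]]  # (feature_id, family label)
    notes: list[str]

    @property
    def attL_start(self) -> int:
        """Genomic start of the integrase-proximal repeat copy."""
        return self.left_core_start if self.orientation == "forward" else self.right_core_start

    @property
    def attR_start(self) -> int:
        return self.right_core_start if self.orientation == "forward" else self.left_core_start


def _random_dna(rng: np.random.Generator, length: int, gc: float) -> str:
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(BASES[rng.choice(4, size=length, p=probs)])


def _gene_sequence(
    rng: np.random.Generator, length_bp: int, bias: dict[str, dict[str, float]]
) -> str:
    """One CDS: ATG start, TAA stop, interior codons drawn per the bias."""
    n_inner = length_bp // 3 - 2
    aas = rng.choice(len(AA_LIST), size=n_inner)
    codons = np.empty(n_inner, dtype=object)
    for ai in np.unique(aas):
        aa = AA_LIST[ai]
        syn = AA_TO_CODONS[aa]
        if aa in bias:
            p = np.array([bias[aa].get(c, 0.0) for c in syn])
        else:
            p = np.full(len(syn), 1.0 / len(syn))
        idx = np.flatnonzero(aas == ai)
        codons[idx] = rng.choice(syn, size=len(idx), p=p)
    return "ATG" + "".join(codons) + "TAA"


def _gene_length(rng: np.random.Generator) -> int:
    # 300-1500 bp in multiples of 3
    return int(rng.integers(100, 501)) * 3


class _Assembler:
    """Accumulates sequence chunks and features with a running cursor."""

    def __init__(self) -> None:
        self.chunks: list[str] = []
        self.features: list[GeneFeature] = []
        self.cursor = 0

    def add_seq(self, seq: str) -> int:
        start = self.cursor
        self.chunks.append(seq)
        self.cursor += len(seq)
        return start

    def add_gene(self, seq: str, **feat_kwargs) -> GeneFeature:
        start = self.add_seq(seq)
        feat = GeneFeature(start=start, end=start + len(seq), **feat_kwargs)
        self.features.append(feat)
        return feat

    def sequence(self) -> str:
        return "".join(self.chunks)


def _build_cassette(
    spec: SynthSpec, rng: np.random.Generator, genome_id: str
) -> tuple[str, list[GeneFeature], dict]:
    """Build the phage cassette in its forward orientation (local coords)."""
    asm = _Assembler()
    truth: dict = {"gene_categories": {}, "planted_trnas": [], "transposases": [], "notes": []}
    gene_no = 0
    product_cycles = {cat: 0 for cat in _MODULE_PRODUCTS}
    internal_att_slot: int | None = None  # cursor offset placeholder

    plan = list(spec.module_plan)
    categories_planned = [c for c, _ in plan]
    for mod_idx, (category, count) in enumerate(plan):
        products = _MODULE_PRODUCTS[category]
        trans_at = count // 2 if (
            spec.transposase_insert and spec.transposase_insert[0] is category
        ) else None
        for g in range(count):
            asm.add_seq(_random_dna(rng, int(rng.integers(20, 121)), spec.host_gc))
            if g == trans_at:
                gene_no += 1
                fid = f"{genome_id}_p{gene_no:03d}"
                family = spec.transposase_insert[1]
                feat = asm.add_gene(
                    _gene_sequence(rng, _gene_length(rng), spec.phage_codon_bias),
                    feature_id=fid,
                    contig_id="",
                    strand="+",
                    kind="CDS",
                    product=f"{family} family transposase",
                    category=FunctionalCategory.transposase,
                )
                truth["gene_categories"][fid] = FunctionalCategory.transposase
                truth["transposases"].append((fid, family))
                if spec.internal_att_before_lysis:
                    asm.add_seq(_random_dna(rng, 40, spec.host_gc))
                    internal_att_slot = asm.add_seq("@" * spec.att_core_len)
            gene_no += 1
            fid = f"{genome_id}_p{gene_no:03d}"
            # first lysogeny gene is always the integrase, and the packaging
            # module always carries a terminase large subunit (marker genes)
            if category in (FunctionalCategory.lysogeny, FunctionalCategory.packaging) and g == 0:
                product = products[0]
            else:
                product_cycles[category] = (product_cycles[category] + 1) % (len(products) - 1)
                product = products[1 + product_cycles[category]]
            asm.add_gene(
                _gene_sequence(rng, _gene_length(rng), spec.phage_codon_bias),
                feature_id=fid,
                contig_id="",
                strand="+",
                kind="CDS",
                product=product,
                category=category,
            )
            truth["gene_categories"][fid] = category
        if category is FunctionalCategory.lysogeny:
            # phage-carried tRNAs sit just downstream of the lysogeny module
            for isotype, anticodon in spec.phage_trnas:
                asm.add_seq(_random_dna(rng, int(rng.integers(20, 81)), spec.host_gc))
                gene_no += 1
                fid = f"{genome_id}_p{gene_no:03d}"
                asm.add_gene(
                    _random_dna(rng, 76, spec.host_gc),
                    feature_id=fid,
                    contig_id="",
                    strand="+",
                    kind="tRNA",
                    product=f"tRNA-{isotype}({anticodon.lower()})",
                    category=FunctionalCategory.trna,
                )
                truth["planted_trnas"].append((fid, isotype, anticodon))
    asm.add_seq(_random_dna(rng, int(rng.integers(20, 121)), spec.host_gc))
    if FunctionalCategory.lysis not in categories_planned:
        truth["notes"].append("no lysis module")
    return asm.sequence(), asm.features, {**truth, "internal_att_slot": internal_att_slot}


def forge_lysogen(spec: SynthSpec) -> tuple[GenomeRecord, list[GeneFeature], TruthTable]:
    """Emit one synthetic lysogen genome with its truth table.

    The host background is i.i.d. nucleotides at ``host_gc`` carrying generic
    housekeeping CDS; the target gene sits mid-chromosome.  Integration
    inserts ``att_core + cassette`` immediately before the target gene, so the
    final layout is ``... attL-core | cassette | full target gene (ending in
    the attR core) ...`` — direct repeats flank the cassette and the restored
    full-length copy of the target lies downstream.  ``att_mutations``
    substitutions are applied to the upstream (partial) copy.
    """
    rng = np.random.default_rng(spec.rng_seed)
    genome_id = f"synthetic_lysogen_{spec.rng_seed}"
    contig_id = f"{genome_id}_c1"

    # --- pre-integration host -------------------------------------------------
    host = _Assembler()
    hg = 0

    def host_gene(product: str, name: str = "", kind: str = "CDS", length: int | None = None):
        nonlocal hg
        hg += 1
        host.add_seq(_random_dna(rng, int(rng.integers(100, 601)), spec.host_gc))
        if kind == "CDS":
            seq = _gene_sequence(rng, length or _gene_length(rng), spec.host_codon_bias)
        else:
            seq = _random_dna(rng, length or 76, spec.host_gc)
        return host.add_gene(
            seq,
            feature_id=f"{genome_id}_h{hg:03d}",
            contig_id=contig_id,
            strand="+",
            kind=kind,
            product=product,
            name=name,
            category=FunctionalCategory.trna if kind in ("tRNA", "tmRNA") else FunctionalCategory.unknown,
        )

    half = spec.host_cds_count // 2
    for i in range(half):
        host_gene(_HOST_PRODUCTS[i % len(_HOST_PRODUCTS)])
    if spec.include_tils:
        host_gene("tRNA(Ile)-lysidine synthetase TilS", name="tilS")

    # --- target locus ---------------------------------------------------------
    target_feat: GeneFeature | None = None
    if spec.target_locus.startswith("tRNA-"):
        isotype = spec.target_locus.split("-", 1)[1]
        anticodon = DEFAULT_ANTICODONS.get(isotype, "nnn")
        target_feat = host_gene(
            f"tRNA-{isotype}({anticodon})", kind="tRNA", length=max(76, spec.att_core_len + 20)
        )
        locus_kind, locus_detail = "tRNA", isotype
    elif spec.target_locus == "tmRNA":
        target_feat = host_gene("transfer-messenger RNA, SsrA", name="ssrA", kind="tmRNA", length=350)
        locus_kind, locus_detail = "tmRNA", "ssrA"
    elif spec.target_locus in _TARGET_GENES:
        name, product, length = _TARGET_GENES[spec.target_locus]
        target_feat = host_gene(product, name=name, length=length)
        locus_kind, locus_detail = "coding_gene", name
    elif spec.target_locus == "noncoding":
        host.add_seq(_random_dna(rng, 400, spec.host_gc))
        locus_kind, locus_detail = "noncoding", ""
    else:
        raise LysogenKitError(f"unknown target locus {spec.target_locus!r}")
    insertion_point = host.cursor  # 3' end of target gene (or intergenic point)

    for i in range(spec.host_cds_count - half):
        host_gene(_HOST_PRODUCTS[(half + i) % len(_HOST_PRODUCTS)])
    host.add_seq(_random_dna(rng, int(rng.integers(200, 801)), spec.host_gc))

    pre_seq = host.sequence()
    if len(pre_seq) < spec.host_length:
        # pad with extra background, split evenly around the midpoint so the
        # prophage stays roughly central
        pad = spec.host_length - len(pre_seq)
        left_pad = _random_dna(rng, pad // 2, spec.host_gc)
        right_pad = _random_dna(rng, pad - pad // 2, spec.host_gc)
        for f in host.features:
            f.start += len(left_pad)
            f.end += len(left_pad)
        insertion_point += len(left_pad)
        pre_seq = left_pad + pre_seq + right_pad
    pre_features = host.features

    # --- att core and cassette -------------------------------------------------
    L = spec.att_core_len
    if target_feat is not None:
        core = pre_seq[target_feat.end - L : target_feat.end]
        insertion_point = target_feat.start  # insert upstream of the gene
    else:
        core = _random_dna(rng, L, spec.host_gc)

    cassette_seq, cassette_feats, ctruth = _build_cassette(spec, rng, genome_id)
    if ctruth["internal_att_slot"] is not None:
        s = ctruth["internal_att_slot"]
        cassette_seq = cassette_seq[:s] + core + cassette_seq[s + L :]
    if len(cassette_seq) + L >= len(pre_seq):
        raise LysogenKitError("cassette longer than host background")

    mutated_core = list(core)
    mut_positions = rng.choice(L, size=spec.att_mutations, replace=False)
    for p in mut_positions:
        choices = [b for b in "ACGT" if b != mutated_core[p]]
        mutated_core[p] = choices[int(rng.integers(3))]
    left_core = "".join(mutated_core)

    block = left_core + cassette_seq
    if spec.orientation == "reverse_complement":
        # flip the phage interior; the repeats stay direct repeats
        interior = revcomp(cassette_seq)
        block = left_core + interior
        clen = len(cassette_seq)
        for f in cassette_feats:
            f.start, f.end = clen - f.end, clen - f.start
            f.strand = "-" if f.strand == "+" else "+"
        cassette_feats.sort(key=lambda f: f.start)

    gs = insertion_point
    final_seq = pre_seq[:gs] + block + pre_seq[gs:]
    for f in pre_features:
        if f.start >= gs:
            f.start += len(block)
            f.end += len(block)
    for f in cassette_feats:
        f.contig_id = contig_id
        f.start += gs + L
        f.end += gs + L

    features = pre_features + cassette_feats
    notes = list(ctruth["notes"])

    if target_feat is not None:
        right_core_start = target_feat.end - L
        prophage_end = target_feat.end
        # annotate the residual partial copy at the upstream junction
        if target_feat.kind in ("tRNA", "tmRNA"):
            features.append(
                GeneFeature(
                    feature_id=f"{genome_id}_attL_partial",
                    contig_id=contig_id,
                    start=gs,
                    end=gs + L,
                    strand=target_feat.strand,
                    kind=target_feat.kind,
                    product=f"{target_feat.product} (partial)",
                    category=FunctionalCategory.trna,
                )
            )
        disrupted = target_feat.feature_id
    else:
        # non-coding target: emit an explicit downstream repeat copy
        final_seq = final_seq[: gs + len(block)] + core + final_seq[gs + len(block) :]
        for f in features:
            if f.start >= gs + len(block):
                f.start += L
                f.end += L
        right_core_start = gs + len(block)
        prophage_end = right_core_start + L
        disrupted = ""

    if spec.decoy_repeats:
        # stress-test mode: plant identical decoy pairs in the flanks
        for _ in range(spec.decoy_repeats):
            dec = _random_dna(rng, L, spec.host_gc)
            lp = int(rng.integers(max(0, gs - 3000), max(1, gs - L - 200)))
            rp = int(rng.integers(prophage_end + 200, min(len(final_seq) - L, prophage_end + 3000)))
            final_seq = final_seq[:lp] + dec + final_seq[lp + L :]
            final_seq = final_seq[:rp] + dec + final_seq[rp + L :]
        notes.append(f"{spec.decoy_repeats} decoy repeat pair(s) planted")

    features.sort(key=lambda f: (f.start, f.end))
    genome = GenomeRecord(id=genome_id, contigs={contig_id: final_seq})
    truth = TruthTable(
        genome_id=genome_id,
        contig_id=contig_id,
        prophage_start=gs,
        prophage_end=prophage_end,
        core_len=L,
        left_core_start=gs,
        right_core_start=right_core_start,
        left_seq=final_seq[gs : gs + L],
        right_seq=final_seq[right_core_start : right_core_start + L],
        mismatches=hamming(final_seq[gs : gs + L], final_seq[right_core_start : right_core_start + L]),
        orientation=spec.orientation,
        locus_kind=locus_kind,
        locus_detail=locus_detail,
        target_feature_id=disrupted,
        gene_categories=ctruth["gene_categories"],
        planted_trnas=ctruth["planted_trnas"],
        transposases=ctruth["transposases"],
        notes=notes,
    )
    return genome, features, truth


def hamming(a: str, b: str) -> int:
    """Position-wise mismatch count between equal-length strings."""
    if len(a) != len(b):
        raise LysogenKitError("hamming: length mismatch")
    return sum(x != y for x, y in zip(a, b))


def jittered_candidate(
    truth: TruthTable,
    genome: GenomeRecord,
    rng: np.random.Generator,
    max_jitter: int = 1000,
    label: str = "intact",
) -> ProphageCandidate:
    """Derive a rough candidate region from the truth, emulating the inexact
    boundaries of an upstream prophage predictor."""
    clen = len(genome.sequence(truth.contig_id))
    start = truth.prophage_start + int(rng.integers(-max_jitter, max_jitter + 1))
    end = truth.prophage_end + int(rng.integers(-max_jitter, max_jitter + 1))
    start = max(0, start)
    end = min(clen, max(end, start + 1000))
    return ProphageCandidate(
        genome_id=truth.genome_id,
        contig_id=truth.contig_id,
        start=start,
        end=end,
        source_label=label,
    )


# ---------------------------------------------------------------------------
# Marker-gene family simulation (for phylogenetics tests)
# ---------------------------------------------------------------------------


def forge_marker_family(
    tree: "dendropy.Tree | str",
    seq_len: int,
    rng_seed: int,
    rate: float = 1.0,
) -> tuple[dict[str, str], dendropy.Tree]:
    """Evolve a gapless alignment along a rooted tree under Jukes-Cantor.

    Branch lengths are expected substitutions per site (scaled by ``rate``).
    Per branch of length *b* each site changes with probability
    ``(3/4) * (1 - exp(-4 b / 3))`` to one of the three other bases uniformly
    — the exact JC69 transition kernel.  Returns ``{taxon: sequence}`` and
    the (parsed) generating tree.
    """
    if isinstance(tree, str):
        tree = dendropy.Tree.get(data=tree, schema="newick")
    if seq_len < 1:
        raise LysogenKitError("zero-length alignment requested")
    rng = np.random.default_rng(rng_seed)
    root_seq = rng.integers(0, 4, size=seq_len)
    seqs: dict[str, str] = {}

    def descend(node, seq):
        for child in node.child_nodes():
            b = (child.edge.length or 0.0) * rate
            p_diff = 0.75 * (1.0 - np.exp(-4.0 * b / 3.0))
            child_seq = seq.copy()
            hit = rng.random(seq_len) < p_diff
            n_hit = int(hit.sum())
            if n_hit:
                # uniform among the three other bases
                child_seq[hit] = (child_seq[hit] + rng.integers(1, 4, size=n_hit)) % 4
            if child.is_leaf():
                seqs[child.taxon.label] = "".join(BASES[child_seq])
            else:
                descend(child, child_seq)

    descend(tree.seed_node, root_seq)
    if tree.seed_node.is_leaf():
        seqs[tree.seed_node.taxon.label] = "".join(BASES[root_seq])
    return seqs, tree


def random_tree(
    n_taxa: int,
    rng: np.random.Generator,
    bl_range: tuple[float, float] = (0.05, 0.5),
    labels: Sequence[str] | None = None,
) -> dendropy.Tree:
    """A random rooted binary tree with uniform branch lengths, for
    additive-matrix round trips and bootstrap simulations."""
    if n_taxa < 3:
        raise LysogenKitError("need at least 3 taxa")
    labels = list(labels) if labels else [f"t{i+1}" for i in range(n_taxa)]
    ns = dendropy.TaxonNamespace(labels)
    nodes = []
    for lab in labels:
        leaf = dendropy.Node()
        leaf.taxon = ns.get_taxon(lab)
        leaf.edge.length = float(rng.uniform(*bl_range))
        nodes.append(leaf)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = dendropy.Node()
        parent.edge.length = float(rng.uniform(*bl_range))
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    tree = dendropy.Tree(taxon_namespace=ns)
    tree.seed_node = nodes[0]
    tree.seed_node.edge.length = None
    return tree
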