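"""Core I/O, domain types and configuration.

All coordinates are held internally as 0-based half-open intervals on the
forward strand.  GFF3 input/output converts at the boundary (GFF3 is 1-based
inclusive); BED input is already 0-based half-open and is taken verbatim.

The functional-category vocabulary mirrors the standard temperate-phage gene
modules (lysogeny, replication, packaging, head, tail, fiber, lysis) plus the
accessory classes that matter for prophage curation (transposases,
methyltransferases, endonucleases, tRNAs).
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field, replace
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("lysogenkit")

DNA_ALPHABET = set("ACGTN")

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe)."""
    return seq.translate(COMPLEMENT)[::-1]


class LysogenKitError(Exception):
    """Base class for all package errors."""


class FeatureBoundsError(LysogenKitError):
    """A feature lies outside its contig."""


class FunctionalCategory(str, Enum):
    """Predicted task of a gene, used to colour/partition prophage maps."""

    lysogeny = "lysogeny"
    replication = "replication"
    packaging = "packaging"
    head = "head"
    tail = "tail"
    fiber = "fiber"
    lysis = "lysis"
    transposase = "transposase"
    methyltransferase = "methyltransferase"
    endonuclease = "endonuclease"
    trna = "trna"
    hypothetical = "hypothetical"
    unknown = "unknown"


#: The six gene modules a prophage needs to be called intact (fiber is optional).
ESSENTIAL_MODULES: tuple[FunctionalCategory, ...] = (
    FunctionalCategory.lysogeny,
    FunctionalCategory.replication,
    FunctionalCategory.packaging,
    FunctionalCategory.head,
    FunctionalCategory.tail,
    FunctionalCategory.lysis,
)

#: Canonical module order from attL to attR.
MODULE_ORDER: tuple[FunctionalCategory, ...] = (
    FunctionalCategory.lysogeny,
    FunctionalCategory.replication,
    FunctionalCategory.packaging,
    FunctionalCategory.head,
    FunctionalCategory.tail,
    FunctionalCategory.fiber,
    FunctionalCategory.lysis,
)


def _load_default_keywords() -> list[tuple[FunctionalCategory, tuple[str, ...]]]:
    raw = json.loads(
        resources.files("lysogenkit.data").joinpath("category_keywords.json").read_text()
    )
    return [(FunctionalCategory(cat), tuple(words)) for cat, words in raw]


#: Ordered keyword table: first matching category wins.  Shipped as editable
#: JSON so users can extend the vocabulary (see load_keyword_table).
DEFAULT_KEYWORDS: list[tuple[FunctionalCategory, tuple[str, ...]]] = _load_default_keywords()


def load_keyword_table(path: str | Path) -> list[tuple[FunctionalCategory, tuple[str, ...]]]:
    """Load a keyword->category priority table from a JSON file.

    The file holds a list of ``[category, [keyword, ...]]`` entries in priority
    order, same layout as the packaged default table.
    """
    raw = json.loads(Path(path).read_text())
    return [(FunctionalCategory(cat), tuple(words)) for cat, words in raw]


def categorize(
    product: str,
    keywords: Sequence[tuple[FunctionalCategory, Sequence[str]]] | None = None,
) -> FunctionalCategory:
    """Assign a functional category from a free-text product description.

    Case-insensitive substring lookup against an ordered keyword table; the
    first category with a matching keyword wins, so e.g. an "IS30 family
    transposase" inside a tail module is still a transposase.  Total function:
    anything unmatched is ``unknown`` (the empty product included).
    """
    if not product:
        return FunctionalCategory.unknown
    text = product.lower()
    table = DEFAULT_KEYWORDS if keywords is None else keywords
    for category, words in table:
        for word in words:
            if word in text:
                return category
    return FunctionalCategory.unknown


@dataclass
class GeneFeature:
    """One annotated feature on a contig (0-based half-open coordinates)."""

    feature_id: str
    contig_id: str
    start: int
    end: int
    strand: str = "+"
    kind: str = "CDS"  # CDS | tRNA | tmRNA | other
    product: str = ""
    name: str = ""  # gene symbol when annotated (e.g. lepA)
    category: FunctionalCategory = FunctionalCategory.unknown

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise FeatureBoundsError(
                f"feature {self.feature_id}: invalid interval [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0

    def overlap(self, start: int, end: int) -> int:
        """Length of overlap with [start, end)."""
        return max(0, min(self.end, end) - max(self.start, start))


@dataclass
class GenomeRecord:
    """A (possibly multi-contig) genome.

    ``contigs`` maps contig id -> uppercase DNA sequence; ``topology`` maps
    contig id -> "linear" or "circular" (default linear).
    """

    id: str
    contigs: dict[str, str]
    topology: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for cid, seq in self.contigs.items():
            if not seq:
                raise LysogenKitError(f"contig {cid} of genome {self.id} is empty")
        for cid in self.contigs:
            self.topology.setdefault(cid, "linear")

    def sequence(self, contig_id: str) -> str:
        return self.contigs[contig_id]

    def is_circular(self, contig_id: str) -> bool:
        return self.topology.get(contig_id, "linear") == "circular"


@dataclass
class ProphageCandidate:
    """A raw candidate prophage region (e.g. a PHASTER call) to be refined."""

    genome_id: str
    contig_id: str
    start: int
    end: int
    source_label: str = "user"  # intact | questionable | incomplete | user
    note: str = ""

    def __post_init__(self) -> None:
        if self.end - self.start < 1000:
            raise LysogenKitError(
                f"candidate {self.genome_id}:{self.contig_id}:{self.start}-{self.end} "
                "shorter than 1 kb"
            )


@dataclass
class PipelineConfig:
    """Tunable parameters of the curation pipeline.

    att_min_len/att_max_len
        Length bounds (bp) of the attachment-site core; att sites are short
        10-25 bp direct repeats.
    att_max_mismatch
        Substitutions tolerated between attL and attR ("identical, or almost
        identical" repeats; the printed two-mismatch pair motivates 2).
    att_mismatch_penalty
        Score = core_len - penalty * mismatches; with penalty 2 a longer core
        with one mismatch outranks a shorter exact core only when >= 2 bp longer.
    flank_window
        Width (bp) of the search window centred on each rough candidate
        boundary, so the scan reaches flank_window/2 bp into the bacterial
        genome beyond the rough bounds and the same distance inward.
    dereplication_ani / dereplication_aln_frac
        ANIb and aligned-fraction cutoffs (percent) above which two genomes
        are treated as duplicates.
    bootstrap_reps
        Bootstrap replicates for marker-gene trees.
    rm_proximity
        How many genes downstream of a methyltransferase to look for an
        endonuclease before calling it an orphan.
    group_link_identity
        Single-linkage identity (percent) joining integrases into insertion
        groups; chosen between observed within-group (>=88%) and between-group
        (<=48%) identities.
    """

    att_min_len: int = 10
    att_max_len: int = 25
    att_max_mismatch: int = 2
    att_mismatch_penalty: int = 2
    flank_window: int = 4000
    dereplication_ani: float = 99.00
    dereplication_aln_frac: float = 95.0
    bootstrap_reps: int = 1000
    rng_seed: int = 0
    rm_proximity: int = 2
    group_link_identity: float = 80.0

    def __post_init__(self) -> None:
        if not (0 < self.att_min_len <= self.att_max_len):
            raise LysogenKitError("require 0 < att_min_len <= att_max_len")
        for name in ("dereplication_ani", "dereplication_aln_frac", "group_link_identity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise LysogenKitError(f"{name} must be a percent in [0, 100]")

    @classmethod
    def from_toml(cls, path: str | Path) -> "PipelineConfig":
        import tomllib

        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        return cls(**data)


# ---------------------------------------------------------------------------
# FASTA / GFF3
# ---------------------------------------------------------------------------

_KIND_MAP = {"CDS": "CDS", "tRNA": "tRNA", "tmRNA": "tmRNA"}
_SKIP_FEATURETYPES = {"gene", "mRNA", "exon", "region", "source", "sequence_region"}


def read_genome(
    fasta_path: str | Path,
    gff_path: str | Path,
    genome_id: str | None = None,
    keywords: Sequence[tuple[FunctionalCategory, Sequence[str]]] | None = None,
) -> tuple[GenomeRecord, list[GeneFeature]]:
    """Read a FASTA + GFF3 pair into a GenomeRecord and categorized features.

    GFF3 coordinates (1-based inclusive) are converted to 0-based half-open.
    Product strings are preserved verbatim; a missing product yields category
    ``unknown`` (``trna`` for tRNA/tmRNA features, which are classified by
    feature type).  A feature extending beyond its contig raises
    FeatureBoundsError naming the feature.
    """
    fasta_path = Path(fasta_path)
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if not records:
        raise LysogenKitError(f"no FASTA records in {fasta_path}")
    contigs = {rec.id: str(rec.seq).upper() for rec in records}
    topology = {
        rec.id: "circular" if "circular" in (rec.description or "").lower() else "linear"
        for rec in records
    }
    genome = GenomeRecord(
        id=genome_id or fasta_path.stem, contigs=contigs, topology=topology
    )

    db = gffutils.create_db(
        str(gff_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    features: list[GeneFeature] = []
    counter = 0
    for feat in db.all_features():
        if feat.featuretype in _SKIP_FEATURETYPES:
            continue
        kind = _KIND_MAP.get(feat.featuretype, "other")
        counter += 1
        fid = feat.attributes.get("ID", [f"feature_{counter}"])[0]
        product = feat.attributes.get("product", [""])[0]
        name = feat.attributes.get("Name", feat.attributes.get("gene", [""]))[0]
        start = feat.start - 1  # GFF3 1-based inclusive -> 0-based half-open
        end = feat.end
        if feat.seqid not in genome.contigs:
            raise FeatureBoundsError(f"feature {fid}: unknown contig {feat.seqid}")
        clen = len(genome.contigs[feat.seqid])
        if start < 0 or end > clen:
            raise FeatureBoundsError(
                f"feature {fid}: interval {feat.start}..{feat.end} exceeds "
                f"contig {feat.seqid} length {clen}"
            )
        if kind in ("tRNA", "tmRNA"):
            category = FunctionalCategory.trna
        else:
            category = categorize(product, keywords)
        features.append(
            GeneFeature(
                feature_id=fid,
                contig_id=feat.seqid,
                start=start,
                end=end,
                strand=feat.strand if feat.strand in "+-" else "+",
                kind=kind,
                product=product,
                name=name,
                category=category,
            )
        )
    features.sort(key=lambda f: (f.contig_id, f.start, f.end))
    return genome, features


def write_genome(
    genome: GenomeRecord,
    features: Iterable[GeneFeature],
    fasta_path: str | Path,
    gff_path: str | Path,
    source: str = "lysogenkit",
) -> None:
    """Write a GenomeRecord + features as FASTA and GFF3 (inverse of read_genome)."""
    records = []
    for cid, seq in genome.contigs.items():
        desc = "circular" if genome.is_circular(cid) else ""
        records.append(SeqRecord(Seq(seq), id=cid, description=desc))
    SeqIO.write(records, str(fasta_path), "fasta")

    with open(gff_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for cid, seq in genome.contigs.items():
            fh.write(f"##sequence-region {cid} 1 {len(seq)}\n")
        for f in sorted(features, key=lambda f: (f.contig_id, f.start, f.end)):
            ftype = f.kind if f.kind in ("CDS", "tRNA", "tmRNA") else "misc_feature"
            attrs = [f"ID={_gff_escape(f.feature_id)}"]
            if f.name:
                attrs.append(f"Name={_gff_escape(f.name)}")
            if f.product:
                attrs.append(f"product={_gff_escape(f.product)}")
            fh.write(
                "\t".join(
                    [
                        f.contig_id,
                        source,
                        ftype,
                        str(f.start + 1),  # back to 1-based inclusive
                        str(f.end),
                        ".",
                        f.strand,
                        "0" if f.kind == "CDS" else ".",
                        ";".join(attrs),
                    ]
                )
                + "\n"
            )


def _gff_escape(text: str) -> str:
    return text.replace(";", "%3B").replace("=", "%3D").replace("\t", " ")


# ---------------------------------------------------------------------------
# BED candidate regions
# ---------------------------------------------------------------------------

_LABELS = {"intact", "questionable", "incomplete", "user"}


def read_candidates(
    path: str | Path, genome_id: str, genome: GenomeRecord | None = None
) -> list[ProphageCandidate]:
    """Read a BED3+ table of candidate prophage regions.

    Column 4, when present, carries the upstream classifier's label
    (intact/questionable/incomplete); anything else becomes ``user``.
    """
    candidates = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise LysogenKitError(f"malformed BED line: {line!r}")
        contig, start, end = parts[0], int(parts[1]), int(parts[2])
        label = parts[3] if len(parts) > 3 and parts[3] in _LABELS else "user"
        note = parts[4] if len(parts) > 4 else ""
        if genome is not None:
            clen = len(genome.contigs[contig])
            if start < 0 or end > clen:
                raise LysogenKitError(
                    f"candidate {contig}:{start}-{end} outside contig (length {clen})"
                )
        candidates.append(
            ProphageCandidate(
                genome_id=genome_id,
                contig_id=contig,
                start=start,
                end=end,
                source_label=label,
                note=note,
            )
        )
    return candidates


def write_candidates(candidates: Iterable[ProphageCandidate], path: str | Path) -> None:
    with open(path, "w") as fh:
        for c in candidates:
            fh.write(f"{c.contig_id}\t{c.start}\t{c.end}\t{c.source_label}\t{c.note}\n")


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )
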