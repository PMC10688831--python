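"""Codon-usage propensities and phage tRNA inventories.

Phage-carried tRNA genes are thought to compensate for codons the phage
uses more than its host.  This module computes per-amino-acid synonymous
codon fractions for a set of CDS (phage or host), compares phage against
host usage codon by codon, inventories the tRNA genes a prophage carries
(excluding the partial copies created by integration), and decodes
anticodons — including the lysidine rule by which tRNA-Ile2(CAU) reads the
minor AUA isoleucine codon after modification by TilS rather than the AUG
its anticodon naively implies.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .att_refine import AttPair
from .io_core import GeneFeature, LysogenKitError
from .synth_forge import AA_TO_CODONS, CODON_TO_AA, STOP_CODONS

_ALL_CODONS = sorted(list(CODON_TO_AA) + list(STOP_CODONS))


@dataclass
class CodonUsageTable:
    """Codon counts over a CDS set, with synonymous fractions per amino acid."""

    counts: dict[str, int]
    ambiguous_codons: int = 0
    warnings: list[str] = field(default_factory=list)

    @classmethod
    def from_cds(cls, cds_seqs: Iterable[str]) -> "CodonUsageTable":
        """Count codons over coding sequences.

        A CDS whose length is not a multiple of three is trimmed (with a
        warning); codons containing N are skipped and counted separately;
        an all-N CDS contributes nothing.
        """
        counts = {c: 0 for c in _ALL_CODONS}
        ambiguous = 0
        warnings = []
        for k, seq in enumerate(cds_seqs):
            seq = seq.upper()
            if set(seq) == {"N"}:
                warnings.append(f"CDS {k}: all-N sequence skipped")
                continue
            rem = len(seq) % 3
            if rem:
                warnings.append(f"CDS {k}: length {len(seq)} not divisible by 3; trimmed")
                seq = seq[: len(seq) - rem]
            for i in range(0, len(seq), 3):
                codon = seq[i : i + 3]
                if "N" in codon:
                    ambiguous += 1
                elif codon in counts:
                    counts[codon] += 1
                else:
                    ambiguous += 1
        return cls(counts=counts, ambiguous_codons=ambiguous, warnings=warnings)

    def fractions(self, amino_acid: str) -> dict[str, float]:
        """Synonymous fractions (percent, summing to 100) for one amino acid.

        Returns an empty dict when the amino acid has zero counts (fractions
        undefined).  Stop codons never enter amino-acid fractions.
        """
        syn = AA_TO_CODONS.get(amino_acid)
        if syn is None:
            raise LysogenKitError(f"unknown amino acid {amino_acid!r}")
        total = sum(self.counts[c] for c in syn)
        if total == 0:
            return {}
        return {c: 100.0 * self.counts[c] / total for c in syn}

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for codon in _ALL_CODONS:
            aa = CODON_TO_AA.get(codon, "*")
            frac = self.fractions(aa).get(codon, float("nan")) if aa != "*" else float("nan")
            rows.append((codon, aa, self.counts[codon], frac))
        return pd.DataFrame(rows, columns=["codon", "amino_acid", "count", "fraction"])

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)

    def __add__(self, other: "CodonUsageTable") -> "CodonUsageTable":
        return CodonUsageTable(
            counts={c: self.counts[c] + other.counts[c] for c in _ALL_CODONS},
            ambiguous_codons=self.ambiguous_codons + other.ambiguous_codons,
        )


def compare_phage_host(
    phage: CodonUsageTable, host: CodonUsageTable, amino_acid: str
) -> pd.DataFrame:
    """Per-codon phage vs host synonymous fractions and their difference.

    The host table conventionally includes the prophage CDS (the prophage is
    part of the host genome); pass an excised table for sensitivity analysis.
    Rows are NaN when either side has zero counts for the amino acid.
    """
    pf = phage.fractions(amino_acid)
    hf = host.fractions(amino_acid)
    rows = []
    for codon in AA_TO_CODONS[amino_acid]:
        p = pf.get(codon, float("nan")) if pf else float("nan")
        h = hf.get(codon, float("nan")) if hf else float("nan")
        rows.append((codon, p, h, p - h))
    return pd.DataFrame(rows, columns=["codon", "phage_pct", "host_pct", "delta"])


def cohort_compare(
    phage_tables: Sequence[CodonUsageTable],
    host_tables: Sequence[CodonUsageTable],
    amino_acid: str,
    ddof: int = 1,
) -> pd.DataFrame:
    """Mean +/- sd of synonymous fractions across a phage/host cohort.

    Fractions are computed per entity and then averaged (not pooled); the
    standard deviation uses the n-1 denominator by default.
    """
    if len(phage_tables) != len(host_tables):
        raise LysogenKitError("phage and host cohorts differ in size")
    codons = AA_TO_CODONS[amino_acid]
    pmat = np.array(
        [[t.fractions(amino_acid).get(c, np.nan) for c in codons] for t in phage_tables]
    )
    hmat = np.array(
        [[t.fractions(amino_acid).get(c, np.nan) for c in codons] for t in host_tables]
    )
    with np.errstate(invalid="ignore"):
        out = pd.DataFrame(
            {
                "codon": codons,
                "phage_mean": np.nanmean(pmat, axis=0),
                "phage_sd": np.nanstd(pmat, axis=0, ddof=ddof),
                "host_mean": np.nanmean(hmat, axis=0),
                "host_sd": np.nanstd(hmat, axis=0, ddof=ddof),
                "delta_mean": np.nanmean(pmat - hmat, axis=0),
            }
        )
    return out


# ---------------------------------------------------------------------------
# tRNA inventory
# ---------------------------------------------------------------------------

_RNA = str.maketrans("ACGTacgt", "ACGUacgu")
_RC_RNA = str.maketrans("ACGU", "UGCA")

_TRNA_PRODUCT_RE = re.compile(
    r"tRNA-([A-Za-z]{2,5})\s*\(\s*([ACGTUacgtu]{3})\s*\)"
)


@dataclass
class TRNARecord:
    feature_id: str
    isotype: str  # three-letter amino acid, or "Undet"
    anticodon: str  # RNA triplet 5'->3' ("" when unparseable)
    partial: bool = False
    decoded_codons: list[str] = field(default_factory=list)
    note: str = ""
    flagged: bool = False


def decode_anticodon(isotype: str, anticodon: str) -> tuple[list[str], str]:
    """Codons read by a tRNA with the given anticodon (RNA or DNA triplet).

    The primary codon is the reverse complement of the anticodon.  Two
    standard decoding notes are applied: a G at the anticodon wobble
    position (its 5' base) also reads the U-ending synonymous codon; and the
    isoleucine CAU anticodon is the Ile2 case — lysidine modification by
    TilS redirects it from AUG to the minor AUA codon.
    """
    ac = anticodon.upper().translate(_RNA)
    if len(ac) != 3 or set(ac) - set("ACGU"):
        raise LysogenKitError(f"invalid anticodon {anticodon!r}")
    primary = ac.translate(_RC_RNA)[::-1]
    if isotype == "Ile" and ac == "CAU":
        return ["AUA"], "Ile2/lysidine (TilS): reads AUA, not AUG"
    codons = [primary]
    note = ""
    if ac[0] == "G":
        codons.append(primary[:2] + "U")
        note = f"G34 wobble: also reads {primary[:2]}U"
    return codons, note


def trna_inventory(
    prophage_features: Sequence[GeneFeature],
    att: AttPair | None = None,
    host_features: Sequence[GeneFeature] | None = None,
) -> tuple[list[TRNARecord], int]:
    """List the tRNA genes a prophage carries and count the non-partial ones.

    A tRNA overlapping an att core (or annotated "(partial)") is the target
    gene used for integration, marked partial and excluded from the count.
    Isotype and anticodon come from the annotation text; when they cannot be
    parsed the record is flagged with isotype "Undet".  When host features
    are supplied, the note records whether the host encodes TilS (relevant
    for Ile2 tRNAs).
    """
    att_intervals = []
    if att is not None:
        att_intervals = [(att.left_start, att.left_end), (att.right_start, att.right_end)]
    tils = host_has_tils(host_features) if host_features is not None else None

    records: list[TRNARecord] = []
    for f in prophage_features:
        if f.kind != "tRNA":
            continue
        partial = "partial" in f.product.lower() or any(
            f.overlap(s, e) > 0 for s, e in att_intervals
        )
        m = _TRNA_PRODUCT_RE.search(f.product)
        if m:
            isotype = m.group(1).capitalize()
            anticodon = m.group(2).upper().translate(_RNA)
            codons, note = decode_anticodon(isotype, anticodon)
            flagged = False
        else:
            isotype = "Undet"
            anticodon, codons, note, flagged = "", [], "anticodon unparseable", True
        if tils is not None and isotype == "Ile" and anticodon == "CAU":
            note += f"; host TilS {'present' if tils else 'absent'}"
        records.append(
            TRNARecord(
                feature_id=f.feature_id,
                isotype=isotype,
                anticodon=anticodon,
                partial=partial,
                decoded_codons=codons,
                note=note.lstrip("; "),
                flagged=flagged,
            )
        )
    count = sum(1 for r in records if not r.partial)
    return records, count


def host_has_tils(features: Sequence[GeneFeature] | None) -> bool:
    """Does the host annotation include a tRNA(Ile)-lysidine synthetase?"""
    if not features:
        return False
    return any(
        "lysidine" in f.product.lower() or f.name.lower() == "tils" for f in features
    )


def inventory_to_dataframe(records: Sequence[TRNARecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (r.feature_id, r.isotype, r.anticodon, r.partial,
             ",".join(r.decoded_codons), r.note)
            for r in records
        ],
        columns=["feature_id", "isotype", "anticodon", "partial", "decoded_codons", "note"],
    )
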