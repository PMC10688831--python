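"""Cohort-level dereplication and summary statistics.

Before a prophage screen, near-identical genomes are dereplicated with an
ANIb / aligned-fraction rule (both thresholds met => duplicates; the
lexicographically later id is dropped unless a keep-list says otherwise).
After curation, per-strain verdict counts and per-prophage features (length,
GC, CDS and tRNA counts) are condensed into the headline cohort numbers:
prophage totals per verdict, intact-prophage incidence, mean prophage
sequences per strain, and the intact-size median +/- interquartile range.

ANIb itself (a BLAST-fragment pipeline) is out of scope: the identity table
is an input.  A deliberately simple collinear fragment estimator is included
for synthetic round trips only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_core import LysogenKitError
from .marker_phylo import global_align, make_aligner


@dataclass
class ProphageStats:
    """Per-prophage descriptive features, as reported per strain."""

    phage_id: str
    verdict: str  # intact | questionable | incomplete
    length_kb: float = 0.0
    gc_percent: float = 0.0
    cds_count: int = 0
    trna_count: int = 0


@dataclass
class StrainSummary:
    """All phage-related sequences detected in one strain."""

    genome_id: str
    prophages: list[ProphageStats] = field(default_factory=list)

    def count(self, verdict: str) -> int:
        return sum(1 for p in self.prophages if p.verdict == verdict)

    @property
    def total(self) -> int:
        return len(self.prophages)


class IdentityTable:
    """Symmetric lookup of pairwise (ANI %, aligned fraction %) values."""

    def __init__(self, pairs: Iterable[tuple[str, str, float, float]] = ()):
        self._d: dict[tuple[str, str], tuple[float, float]] = {}
        for a, b, ani, frac in pairs:
            self.add(a, b, ani, frac)

    def add(self, a: str, b: str, ani: float, frac: float) -> None:
        for v, name in ((ani, "ANI"), (frac, "aligned fraction")):
            if not 0.0 <= v <= 100.0:
                raise LysogenKitError(f"{name} {v} outside [0, 100]")
        self._d[self._key(a, b)] = (ani, frac)

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def get(self, a: str, b: str) -> tuple[float, float] | None:
        return self._d.get(self._key(a, b))

    @classmethod
    def from_tsv(cls, path) -> "IdentityTable":
        df = pd.read_csv(path, sep="\t")
        required = {"genome_a", "genome_b", "ani_percent", "aligned_fraction_percent"}
        if not required.issubset(df.columns):
            raise LysogenKitError(f"identity table needs columns {sorted(required)}")
        return cls(
            (r.genome_a, r.genome_b, float(r.ani_percent), float(r.aligned_fraction_percent))
            for r in df.itertuples()
        )

    def to_tsv(self, path) -> None:
        rows = [(a, b, ani, frac) for (a, b), (ani, frac) in sorted(self._d.items())]
        pd.DataFrame(
            rows, columns=["genome_a", "genome_b", "ani_percent", "aligned_fraction_percent"]
        ).to_csv(path, sep="\t", index=False)


def dereplicate(
    ids: Sequence[str],
    identity_table: IdentityTable,
    ani_thresh: float = 99.00,
    frac_thresh: float = 95.0,
    keep: Sequence[str] = (),
) -> tuple[list[str], list[str], list[str]]:
    """Drop near-duplicate genomes (ANI and aligned fraction both at/above
    threshold; ``>=`` semantics on both).

    Greedy and deterministic: pairs are visited in lexicographic order and
    the later id of a similar pair is excluded, unless it is on the keep
    list (then the earlier one goes, keep-list permitting).  A pair missing
    from the table is treated as dissimilar with a warning.  Never excludes
    both members of a pair; idempotent on its own output.
    """
    keep_set = set(keep)
    ids_sorted = sorted(ids)
    excluded: set[str] = set()
    warnings: list[str] = []
    for i, a in enumerate(ids_sorted):
        for b in ids_sorted[i + 1 :]:
            if a in excluded or b in excluded:
                continue
            entry = identity_table.get(a, b)
            if entry is None:
                warnings.append(f"pair ({a}, {b}) missing from identity table; treated as dissimilar")
                continue
            ani, frac = entry
            if ani >= ani_thresh and frac >= frac_thresh:
                if a in keep_set and b in keep_set:
                    warnings.append(f"similar pair ({a}, {b}) both on keep list; both retained")
                elif b in keep_set:
                    excluded.add(a)
                else:
                    excluded.add(b)
    retained = [g for g in ids_sorted if g not in excluded]
    return retained, sorted(excluded), warnings


def fragment_identity(
    seq_a: str, seq_b: str, frag_len: int = 1020, min_identity: float = 30.0
) -> tuple[float, float]:
    """Toy collinear ANI estimator for synthetic genome pairs.

    Chops genome A into ``frag_len`` fragments and globally aligns each to
    the same-coordinate fragment of B; fragments reaching ``min_identity``
    count as aligned, and ANI is their mean identity.  Assumes collinear
    genomes (true of the synthetic forge output); this is NOT ANIb and is
    meant only for exercising the dereplication rule in tests.
    """
    aligner = make_aligner()
    n_frag = min(len(seq_a), len(seq_b)) // frag_len
    if n_frag == 0:
        raise LysogenKitError("sequences shorter than one fragment")
    identities = []
    aligned = 0
    for k in range(n_frag):
        fa = seq_a[k * frag_len : (k + 1) * frag_len]
        fb = seq_b[k * frag_len : (k + 1) * frag_len]
        _, ident = global_align(fa, fb, aligner)
        if ident >= min_identity:
            aligned += 1
            identities.append(ident)
    ani = float(np.mean(identities)) if identities else 0.0
    return ani, 100.0 * aligned / n_frag


@dataclass
class CohortReport:
    """Headline numbers of a prophage screen across a strain cohort."""

    n_strains: int
    totals: dict[str, int]
    total_sequences: int
    incidence_percent: int
    mean_per_strain: float
    intact_size_median_kb: float | None
    intact_size_iqr_kb: float | None
    per_strain_min: int
    per_strain_max: int
    trna_histogram: dict[int, int]
    gc_min: float | None = None
    gc_max: float | None = None

    def to_json(self, path=None) -> str:
        payload = {
            **{k: v for k, v in self.__dict__.items() if k != "trna_histogram"},
            "trna_histogram": {str(k): v for k, v in sorted(self.trna_histogram.items())},
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


def summarize_cohort(summaries: Sequence[StrainSummary]) -> CohortReport:
    """Condense per-strain summaries into cohort statistics.

    Incidence = strains with >= 1 intact prophage / strains x 100, rounded
    to an integer percent; mean prophage sequences per strain to 1 decimal;
    intact sizes as median +/- interquartile range (1 decimal, kb, linear
    interpolation).  Invariant under strain reordering.
    """
    if not summaries:
        raise LysogenKitError("no strain summaries supplied")
    n = len(summaries)
    totals = {v: sum(s.count(v) for s in summaries) for v in ("intact", "questionable", "incomplete")}
    total_sequences = sum(s.total for s in summaries)
    with_intact = sum(1 for s in summaries if s.count("intact") >= 1)
    intact = [p for s in summaries for p in s.prophages if p.verdict == "intact"]
    sizes = np.array([p.length_kb for p in intact], dtype=float)
    gcs = np.array([p.gc_percent for p in intact], dtype=float)
    hist: dict[int, int] = {}
    for p in intact:
        hist[p.trna_count] = hist.get(p.trna_count, 0) + 1
    return CohortReport(
        n_strains=n,
        totals=totals,
        total_sequences=total_sequences,
        incidence_percent=int(round(100.0 * with_intact / n)),
        mean_per_strain=round(total_sequences / n, 1),
        intact_size_median_kb=round(float(np.median(sizes)), 1) if sizes.size else None,
        intact_size_iqr_kb=(
            round(float(np.percentile(sizes, 75) - np.percentile(sizes, 25)), 1)
            if sizes.size else None
        ),
        per_strain_min=min(s.total for s in summaries),
        per_strain_max=max(s.total for s in summaries),
        trna_histogram=hist,
        gc_min=round(float(gcs.min()), 1) if gcs.size else None,
        gc_max=round(float(gcs.max()), 1) if gcs.size else None,
    )


def summaries_to_tsv(summaries: Sequence[StrainSummary], path) -> None:
    rows = [
        (s.genome_id, p.phage_id, p.verdict, p.length_kb, p.gc_percent, p.cds_count, p.trna_count)
        for s in summaries
        for p in s.prophages
    ]
    pd.DataFrame(
        rows,
        columns=["genome_id", "phage_id", "verdict", "length_kb", "gc_percent", "cds_count", "trna_count"],
    ).to_csv(path, sep="\t", index=False)


def summaries_from_tsv(path) -> list[StrainSummary]:
    df = pd.read_csv(path, sep="\t")
    out: dict[str, StrainSummary] = {}
    for r in df.itertuples():
        s = out.setdefault(r.genome_id, StrainSummary(genome_id=r.genome_id))
        s.prophages.append(
            ProphageStats(
                phage_id=r.phage_id,
                verdict=r.verdict,
                length_kb=float(r.length_kb),
                gc_percent=float(r.gc_percent),
                cds_count=int(r.cds_count),
                trna_count=int(r.trna_count),
            )
        )
    return [out[k] for k in sorted(out)]
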