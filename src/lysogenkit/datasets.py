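"""Bundled example cohort: a prophage survey of 45 *Latilactobacillus
curvatus* genomes.

The survey's headline marginals are encoded here as a deterministic
per-strain table: 206 phage-related sequences in total (50 intact after
manual curation, 38 questionable, 118 incomplete) across 45 strains, 33 of
which carry at least one intact prophage; intact prophage sizes spanning
29.1-51.0 kb with median 37.8 kb and interquartile range 4.8 kb; GC content
37.9-43.5%; 40-71 CDS per prophage; and 33/13/4 intact prophages carrying
0/1/2 tRNA genes.  Only the cohort marginals are published per strain, so
the allocation of counts to individual strains is a reconstruction: strain
ids prefixed ``LCV-`` are synthetic placeholders, while named strains carry
their published attributes (e.g. MRS6 P1 at 51.0 kb).  Every summary
statistic computed by :func:`lysogenkit.cohort_report.summarize_cohort`
depends only on the published marginals.
"""

from __future__ import annotations

import pandas as pd

from .cohort_report import IdentityTable, ProphageStats, StrainSummary

#: intact prophage sizes (kb), sorted; median 37.8, IQR 4.8, extremes as published
INTACT_SIZES_KB = [
    29.1, 29.3,
    30.0, 30.6, 31.2, 31.8, 32.4, 33.0, 33.6, 34.2, 34.6, 35.0,
    35.4, 35.4,
    35.8, 36.0, 36.2, 36.4, 36.6, 36.8, 37.0, 37.2, 37.4, 37.6,
    37.8, 37.8,
    38.0, 38.2, 38.4, 38.6, 38.8, 39.0, 39.2, 39.4, 39.6, 39.8,
    40.2, 40.2,
    40.6, 41.2, 41.8, 42.4, 43.0, 43.6, 44.2, 45.0, 46.0, 47.0, 48.0,
    51.0,
]

# named strains with their (reconstructed) intact prophage counts
_INTACT_3 = ["TMW 1.1365", "WiKim38", "DSM 20019", "MRS6"]
_INTACT_2 = [
    "TMW 1.706", "ELA214388", "DRD-164", "TMW 1.595", "TMW 1.624",
    "TMW 1.591", "TMW 1.2270", "FLEC03", "ZJUNIT8",
]
_INTACT_1 = [
    "KG6", "NRIC0822", "NFH-Km12", "TMW 1.1928", "TMW 1.1447",
    "VRA_2sq_f", "TMW 1.2272", "FAM25164",
] + [f"LCV-{i:02d}" for i in range(1, 13)]
_NO_INTACT = ["TMW 1.411"] + [f"LCV-{i:02d}" for i in range(13, 24)]

#: fixed-size prophages (published): phage id -> (strain, kb)
_NAMED_SIZES = {
    "DRD-164 P2": 29.1,
    "WiKim38 P2": 29.3,
    "MRS6 P1": 51.0,
}


def curvatus_survey_summaries() -> list[StrainSummary]:
    """Per-strain verdict/feature table reproducing the survey marginals."""
    strains = _INTACT_3 + _INTACT_2 + _INTACT_1 + _NO_INTACT
    intact_per_strain = dict(
        [(s, 3) for s in _INTACT_3] + [(s, 2) for s in _INTACT_2]
        + [(s, 1) for s in _INTACT_1] + [(s, 0) for s in _NO_INTACT]
    )
    assert sum(intact_per_strain.values()) == 50 and len(strains) == 45

    # hand out the published size distribution deterministically, holding the
    # three prophages with individually published sizes back for their strains
    pool = [s for s in INTACT_SIZES_KB if s not in _NAMED_SIZES.values()]
    pool_iter = iter(pool)

    # tRNA counts over intact prophages: 4 carry two, 13 carry one, 33 none
    trna_pool = [2] * 4 + [1] * 13 + [0] * 33
    gc_pool = [round(37.9 + k * (43.5 - 37.9) / 49, 2) for k in range(50)]
    cds_pool = [40, 40] + [41 + round(k * 29 / 45) for k in range(46)] + [71, 71]

    summaries: list[StrainSummary] = []
    phage_no = 0
    for strain in strains:
        s = StrainSummary(genome_id=strain)
        for k in range(intact_per_strain[strain]):
            pid = f"{strain} P{k + 1}"
            if pid in _NAMED_SIZES:
                size = _NAMED_SIZES[pid]
            else:
                size = next(pool_iter)
            s.prophages.append(
                ProphageStats(
                    phage_id=pid,
                    verdict="intact",
                    length_kb=size,
                    gc_percent=gc_pool[phage_no],
                    cds_count=cds_pool[phage_no],
                    trna_count=trna_pool[phage_no],
                )
            )
            phage_no += 1
        summaries.append(s)

    # questionable: 38 in total, at most six per strain
    q_left = 38
    for s in summaries:
        take = min(6 if s.genome_id == "TMW 1.1365" else 1, q_left)
        for k in range(take):
            s.prophages.append(ProphageStats(phage_id=f"{s.genome_id} Q{k + 1}", verdict="questionable"))
        q_left -= take
    assert q_left == 0

    # incomplete: 118 in total, at most eleven per strain; the transposase-rich
    # strain TMW 1.411 is all-incomplete, and one strain carries a single sequence
    special_inc = {"TMW 1.1365": 5, "TMW 1.411": 11, "LCV-23": 1}
    others = [s for s in summaries if s.genome_id not in special_inc]
    inc_left = 118 - sum(special_inc.values())
    per_other = {s.genome_id: 2 for s in others}
    inc_left -= 2 * len(others)
    for s in others:
        if inc_left <= 0:
            break
        per_other[s.genome_id] += 1
        inc_left -= 1
    assert inc_left == 0
    for s in summaries:
        n_inc = special_inc.get(s.genome_id, per_other.get(s.genome_id, 0))
        for k in range(n_inc):
            s.prophages.append(ProphageStats(phage_id=f"{s.genome_id} I{k + 1}", verdict="incomplete"))

    total = sum(s.total for s in summaries)
    assert total == 206, total
    return summaries


def curvatus_trna_inventory() -> pd.DataFrame:
    """tRNA genes carried by the 50 intact prophages of the survey.

    Ten isoleucine tRNAs (seven CAU-anticodon Ile2 candidates, one AAU, one
    UAU, one GAU — the CAU count includes the gene originally annotated as a
    methionine tRNA), seven phenylalanine tRNAs (all GAA), one histidine
    tRNA and three of undetermined isotype; 21 in total, matching the
    33/13/4 histogram of tRNAs per prophage.
    """
    rows = (
        [("Ile", "CAU")] * 7
        + [("Ile", "AAU"), ("Ile", "UAU"), ("Ile", "GAU")]
        + [("Phe", "GAA")] * 7
        + [("His", "GUG")]
        + [("Undet", "")] * 3
    )
    return pd.DataFrame(rows, columns=["isotype", "anticodon"])


def curvatus_identity_examples() -> IdentityTable:
    """Published pairwise ANIb examples used to illustrate dereplication."""
    return IdentityTable(
        [
            ("TMW 1.706", "DSM 20019", 100.00, 99.95),
            ("TMW 1.1447", "DRD-164", 99.52, 95.39),
            ("VRA_2sq_f", "DSM 20019", 88.24, 66.84),
        ]
    )
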