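"""Gene-module tallies, completeness verdicts and split-prophage joining.

A temperate phage genome is organised as collinear functional modules running
from attL to attR: lysogeny, replication, packaging, head, tail, (fiber),
lysis.  A prophage is called *intact* when all six essential modules are
present and both att sites were recovered; exactly one defect (one essential
module missing, or one att side unresolved) yields *questionable*; anything
worse is *incomplete*.  Fiber/receptor genes are treated as optional.  These
rules codify the narrative criteria of manual prophage curation — upstream
predictors' completeness labels are inherited only as candidate annotations.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Sequence

from .att_refine import AttPair, RefinedProphage
from .io_core import (
    ESSENTIAL_MODULES,
    MODULE_ORDER,
    FunctionalCategory,
    GeneFeature,
    LysogenKitError,
    PipelineConfig,
    ProphageCandidate,
)

#: verdict order used by the monotonicity guarantee
VERDICT_RANK = {"incomplete": 0, "questionable": 1, "intact": 2}

_PHAGE_MODULES = set(MODULE_ORDER)


@dataclass
class ModuleProfile:
    """Per-module gene tallies for one prophage region."""

    counts: dict[FunctionalCategory, int]
    observed_order: list[FunctionalCategory]
    flags: list[tuple[str, str]] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def present(self) -> set[FunctionalCategory]:
        return {c for c, n in self.counts.items() if n > 0}


@dataclass
class CompletenessVerdict:
    verdict: str  # intact | questionable | incomplete
    reasons: list[str] = field(default_factory=list)


_FAMILY_RE = re.compile(r"(\S+)\s+family transposase", re.IGNORECASE)


def _transposase_family(product: str) -> str:
    m = _FAMILY_RE.search(product)
    return m.group(1) if m else "unclassified"


def profile_modules(
    refined: RefinedProphage,
    features: Sequence[GeneFeature],
    sequence: str | None = None,
    config: PipelineConfig | None = None,
) -> ModuleProfile:
    """Tally genes per functional category inside a refined prophage.

    The observed module order is recorded in prophage orientation (attL to
    attR), not forced into the canonical order.  Transposases are attributed
    to the module whose genes surround them; a transposase sitting between two
    modules belongs to the downstream one.  When the prophage sequence and att
    pair are available, a copy of the att core between a transposase and the
    lysis module raises ``internal_att_before_lysis`` — such an element may
    cut the lysis genes off the prophage.
    """
    config = config or PipelineConfig()
    region = [f for f in features if f.start >= refined.start and f.end <= refined.end]
    region.sort(key=lambda f: f.start)
    if refined.orientation == "reverse_complement":
        region = region[::-1]

    counts = {c: 0 for c in FunctionalCategory}
    for f in region:
        counts[f.category] += 1

    observed: list[FunctionalCategory] = []
    for f in region:
        if f.category in _PHAGE_MODULES and f.category is not FunctionalCategory.fiber:
            if not observed or observed[-1] is not f.category:
                observed.append(f.category)
        elif f.category is FunctionalCategory.fiber:
            if not observed or observed[-1] is not f.category:
                observed.append(f.category)

    profile = ModuleProfile(counts=counts, observed_order=observed)
    if not region:
        profile.warnings.append("empty region: all-zero profile")
        return profile

    # transposase attribution
    module_genes = [f for f in region if f.category in _PHAGE_MODULES]
    for idx, f in enumerate(region):
        if f.category is not FunctionalCategory.transposase:
            continue
        prev_mod = next(
            (g.category for g in reversed(region[:idx]) if g.category in _PHAGE_MODULES), None
        )
        next_mod = next(
            (g.category for g in region[idx + 1 :] if g.category in _PHAGE_MODULES), None
        )
        if prev_mod is not None and prev_mod == next_mod:
            host_module = prev_mod
        else:
            host_module = next_mod or prev_mod  # between modules: downstream wins
        family = _transposase_family(f.product)
        detail = f"{host_module.value}/{family}" if host_module else family
        profile.flags.append(("transposase_in_module", detail))

        if sequence is not None and refined.att is not None:
            lysis_genes = [g for g in region if g.category is FunctionalCategory.lysis]
            if lysis_genes:
                if refined.orientation == "forward":
                    seg_lo, seg_hi = f.end, min(g.start for g in lysis_genes)
                else:
                    seg_lo, seg_hi = max(g.end for g in lysis_genes), f.start
                if seg_hi - seg_lo >= refined.att.core_len:
                    core = refined.att.left_seq
                    pos = _find_near_copy(
                        sequence[seg_lo:seg_hi], core, config.att_max_mismatch
                    )
                    if pos >= 0:
                        profile.flags.append(
                            ("internal_att_before_lysis", f"position {seg_lo + pos}")
                        )
    return profile


def _find_near_copy(haystack: str, core: str, max_mm: int) -> int:
    """First position of a substring within Hamming distance max_mm of core."""
    L = len(core)
    for i in range(len(haystack) - L + 1):
        mm = 0
        for x, y in zip(haystack[i : i + L], core):
            if x != y:
                mm += 1
                if mm > max_mm:
                    break
        if mm <= max_mm:
            return i
    return -1


def assess_completeness(
    profile: ModuleProfile,
    att_status: str,
    essential: Sequence[FunctionalCategory] = ESSENTIAL_MODULES,
) -> CompletenessVerdict:
    """Issue the intact/questionable/incomplete verdict.

    intact       all essential modules present and both att sites found;
    questionable exactly one essential module missing (att complete), or all
                 modules present with one att side unresolved;
    incomplete   anything else.

    Total and monotone: deleting genes from a profile can only lower (never
    raise) the verdict.
    """
    present = profile.present()
    missing = [m for m in essential if m not in present]
    att_ok = att_status == "both"
    one_sided = att_status in ("attL_only", "attR_only")

    if not missing and att_ok:
        return CompletenessVerdict("intact")
    reasons = [f"{m.value} module absent" for m in missing]
    if not att_ok:
        reasons.append(f"att status {att_status}")
    if att_ok and len(missing) == 1:
        return CompletenessVerdict("questionable", reasons)
    if not missing and one_sided:
        return CompletenessVerdict("questionable", reasons)
    return CompletenessVerdict("incomplete", reasons)


_SPEC_RE = re.compile(r"(adenine|cytosine)", re.IGNORECASE)


def flag_mtase_rm(
    features: Sequence[GeneFeature], rm_proximity: int = 2
) -> list[tuple[str, str]]:
    """Classify methyltransferases as restriction-modification candidates or orphans.

    A methyltransferase with an endonuclease-category gene within
    ``rm_proximity`` genes downstream (along its own strand) is a plausible
    R-M system (``rm_candidate``); otherwise it is an ``mtase_orphan``.
    Adenine/cytosine specificity is parsed from the product text when present.
    """
    ordered = sorted(features, key=lambda f: f.start)
    flags: list[tuple[str, str]] = []
    for idx, f in enumerate(ordered):
        if f.category is not FunctionalCategory.methyltransferase:
            continue
        if f.strand == "-":
            downstream = ordered[max(0, idx - rm_proximity) : idx][::-1]
        else:
            downstream = ordered[idx + 1 : idx + 1 + rm_proximity]
        partner = next(
            (g for g in downstream if g.category is FunctionalCategory.endonuclease), None
        )
        m = _SPEC_RE.search(f.product)
        spec_txt = m.group(1).lower() if m else "unknown"
        if partner is not None:
            flags.append(("rm_candidate", f"{f.feature_id} specificity={spec_txt} partner={partner.feature_id}"))
        else:
            flags.append(("mtase_orphan", f"{f.feature_id} specificity={spec_txt}"))
    return flags


def join_split_prophage(
    parts: Sequence[RefinedProphage],
    features_by_part: Sequence[Sequence[GeneFeature]],
) -> tuple[RefinedProphage, list[GeneFeature]]:
    """Join prophage fragments scattered over several contigs.

    Fragments of one phage (e.g. split across assembly contigs) are
    concatenated in canonical module order (lysogeny -> ... -> lysis) on a
    virtual joined contig; the att status is recomputed from the outer parts
    and the result is flagged ``split_joined``.  Parts whose module sets
    conflict (the same essential module present in two parts) are refused.
    """
    if len(parts) != len(features_by_part):
        raise LysogenKitError("parts and features_by_part must be parallel")
    if len(parts) == 1:
        return parts[0], list(features_by_part[0])
    if len({p.candidate.genome_id for p in parts}) != 1:
        raise LysogenKitError("cannot join parts from different genomes")

    def part_modules(feats: Sequence[GeneFeature]) -> set[FunctionalCategory]:
        return {f.category for f in feats if f.category in set(ESSENTIAL_MODULES)}

    module_sets = [part_modules(feats) for feats in features_by_part]
    seen: dict[FunctionalCategory, int] = {}
    for k, mods in enumerate(module_sets):
        for m in mods:
            if m in seen:
                raise LysogenKitError(
                    f"conflicting duplicate module {m.value} in parts "
                    f"{parts[seen[m]].candidate.contig_id} and {parts[k].candidate.contig_id}"
                )
            seen[m] = k

    rank = {m: i for i, m in enumerate(MODULE_ORDER)}
    order = sorted(
        range(len(parts)),
        key=lambda k: min((rank[m] for m in module_sets[k]), default=len(MODULE_ORDER)),
    )

    joined_feats: list[GeneFeature] = []
    offset = 0
    contig_ids = []
    for k in order:
        part = parts[k]
        contig_ids.append(part.candidate.contig_id)
        span = part.end - part.start
        for f in features_by_part[k]:
            if part.orientation == "reverse_complement":
                new_start = offset + (part.end - f.end)
                new_end = offset + (part.end - f.start)
                strand = "-" if f.strand == "+" else "+"
            else:
                new_start = offset + (f.start - part.start)
                new_end = offset + (f.end - part.start)
                strand = f.strand
            joined_feats.append(
                GeneFeature(
                    feature_id=f.feature_id,
                    contig_id="joined:" + "+".join(contig_ids),
                    start=new_start,
                    end=new_end,
                    strand=strand,
                    kind=f.kind,
                    product=f.product,
                    name=f.name,
                    category=f.category,
                )
            )
        offset += span

    first, last = parts[order[0]], parts[order[-1]]
    has_attL = first.att_status in ("both", "attL_only")
    has_attR = last.att_status in ("both", "attR_only")
    att_status = {
        (True, True): "both",
        (True, False): "attL_only",
        (False, True): "attR_only",
        (False, False): "none",
    }[(has_attL, has_attR)]

    joined_contig = "joined:" + "+".join(contig_ids)
    for f in joined_feats:
        f.contig_id = joined_contig
    candidate = ProphageCandidate(
        genome_id=parts[0].candidate.genome_id,
        contig_id=joined_contig,
        start=0,
        end=max(offset, 1000),
        source_label="user",
        note="joined split prophage",
    )
    joined = RefinedProphage(
        candidate=candidate,
        att=None,
        start=0,
        end=offset,
        orientation="forward",
        att_status=att_status,
        flags=[("split_joined", "+".join(contig_ids))],
    )
    return joined, joined_feats
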