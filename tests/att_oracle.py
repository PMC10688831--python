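"""Independent exhaustive oracle for the direct-repeat pair semantics.

Enumerates every (i, j, L) triple outright — no anchor seeding, no run
arithmetic — then applies the documented canonicalisation: pairs start and
end on matches; same-diagonal overlapping placements with equal length and
mismatch count collapse to the leftmost; a pair contained (same diagonal) in
a surviving longer pair of equal-or-higher score is suppressed.  Two
routes are provided: a pure-Python triple loop for tiny windows and a dense
prefix-sum matrix version for windows up to ~2 kb.
"""

from __future__ import annotations

import numpy as np

from lysogenkit.io_core import PipelineConfig


def _rank_key(p):
    score, L, mm, i, j = p["score"], p["L"], p["mm"], p["i"], p["j"]
    return (-score, -L, mm, -(j + L - i), i, j)


def _postprocess(raw: list[dict]) -> list[dict]:
    # 1. drop left-slideable placements: if shifting a pair one position left
    #    still yields a qualifying pair, the pair is a sliding duplicate
    keys = {(p["i"], p["j"], p["L"]) for p in raw}
    survivors = [p for p in raw if (p["i"] - 1, p["j"] - 1, p["L"]) not in keys]
    # 2. suppress pairs contained in an equal-or-better surviving pair
    by_diag2: dict[int, list[dict]] = {}
    for p in survivors:
        by_diag2.setdefault(p["j"] - p["i"], []).append(p)
    kept = []
    for group in by_diag2.values():
        for p in group:
            dominated = any(
                q is not p
                and q["L"] > p["L"]
                and q["i"] <= p["i"]
                and q["i"] + q["L"] >= p["i"] + p["L"]
                and q["score"] >= p["score"]
                for q in group
            )
            if not dominated:
                kept.append(p)
    kept.sort(key=_rank_key)
    return kept


def oracle_pairs_python(
    left: str, right: str, loff: int, roff: int, config: PipelineConfig
) -> list[tuple[int, int, int, int]]:
    """Triple-loop enumeration; returns ranked (i_abs, j_abs, L, mm)."""
    raw = []
    for L in range(config.att_min_len, config.att_max_len + 1):
        for i in range(len(left) - L + 1):
            for j in range(len(right) - L + 1):
                if roff + j < loff + i + L:
                    continue
                x, y = left[i : i + L], right[j : j + L]
                if x[0] != y[0] or x[-1] != y[-1]:
                    continue
                mm = sum(a != b for a, b in zip(x, y))
                if mm <= config.att_max_mismatch:
                    raw.append(
                        {
                            "i": loff + i,
                            "j": roff + j,
                            "L": L,
                            "mm": mm,
                            "score": L - config.att_mismatch_penalty * mm,
                        }
                    )
    return [(p["i"], p["j"], p["L"], p["mm"]) for p in _postprocess(raw)]


def oracle_pairs_numpy(
    left: str, right: str, loff: int, roff: int, config: PipelineConfig
) -> list[tuple[int, int, int, int]]:
    """Dense prefix-sum enumeration for windows up to a couple of kb."""
    wa, wb = len(left), len(right)
    a = np.frombuffer(left.encode(), dtype=np.uint8)
    b = np.frombuffer(right.encode(), dtype=np.uint8)
    M = a[:, None] != b[None, :]
    P = np.zeros((wa + 1, wb + 1), dtype=np.int32)
    for i in range(wa):
        P[i + 1, 1:] = P[i, :-1] + M[i, :]
    raw = []
    for L in range(config.att_min_len, config.att_max_len + 1):
        if L > wa or L > wb:
            continue
        mm = P[L:, L:] - P[: wa - L + 1, : wb - L + 1]
        ok = mm <= config.att_max_mismatch
        ok &= ~M[: wa - L + 1, : wb - L + 1]  # first column matches
        ok &= ~M[L - 1 :, L - 1 :]  # last column matches
        ii, jj = np.nonzero(ok)
        for i, j in zip(ii.tolist(), jj.tolist()):
            if roff + j < loff + i + L:
                continue
            raw.append(
                {
                    "i": loff + i,
                    "j": roff + j,
                    "L": L,
                    "mm": int(mm[i, j]),
                    "score": L - config.att_mismatch_penalty * int(mm[i, j]),
                }
            )
    return [(p["i"], p["j"], p["L"], p["mm"]) for p in _postprocess(raw)]
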