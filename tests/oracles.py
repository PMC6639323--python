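"""Independent reference implementations used only by the test suite.

Each oracle is deliberately written with a different algorithmic structure than
the library path it checks (enumeration, recursion, brute-force matrices), so
agreement is evidence of correctness rather than of shared code.
"""

from __future__ import annotations

import itertools
import re
from functools import lru_cache

import numpy as np


def pcf_oracle(y, gamma: float, kmin: int = 2):
    """Top-down recursive exact segmentation: minimize SSE + gamma per segment."""
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n == 0:
        return [], 0.0
    if n < 2 * kmin:
        return [(0, n)], float(np.var(y) * n + gamma)

    def sse(i, j):
        seg = y[i:j]
        return float(((seg - seg.mean()) ** 2).sum())

    @lru_cache(maxsize=None)
    def solve(i):
        # best segmentation of y[i:]
        if i == n:
            return 0.0, ()
        best = (np.inf, ())
        for j in range(i + kmin, n + 1):
            if 0 < n - j < kmin:
                continue  # remainder too short to ever be covered
            tail_cost, tail = solve(j)
            cost = sse(i, j) + gamma + tail_cost
            if cost < best[0] - 1e-12:
                best = (cost, ((i, j),) + tail)
        return best

    cost, segs = solve(0)
    return list(segs), cost


def clustered_flags_oracle(positions, window: int, min_count: int):
    """O(n^2) anchored-window membership matrix."""
    pos = np.asarray(positions, dtype=np.int64)
    inside = (pos[None, :] >= pos[:, None]) & (pos[None, :] <= pos[:, None] + window)
    counts = inside.sum(axis=1)
    hot = counts >= min_count
    return (inside[hot].any(axis=0)) if hot.any() else np.zeros(len(pos), bool)


def simplex_ls_oracle(S: np.ndarray, m: np.ndarray):
    """Global optimum of min ||m - S^T e||^2, e >= 0, sum e = 1, by exhaustive
    enumeration of active sets (KKT systems on every support subset)."""
    K = S.shape[0]
    A = S.T
    best_e, best_obj = None, np.inf
    for r in range(1, K + 1):
        for support in itertools.combinations(range(K), r):
            As = A[:, list(support)]
            G = As.T @ As
            k = len(support)
            kkt = np.zeros((k + 1, k + 1))
            kkt[:k, :k] = 2 * G
            kkt[:k, k] = 1.0
            kkt[k, :k] = 1.0
            rhs = np.concatenate([2 * As.T @ m, [1.0]])
            try:
                sol = np.linalg.solve(kkt, rhs)
            except np.linalg.LinAlgError:
                continue
            es = sol[:k]
            if np.any(es < -1e-9):
                continue
            e = np.zeros(K)
            e[list(support)] = np.clip(es, 0.0, None)
            e = e / e.sum()
            obj = float(np.sum((A @ e - m) ** 2))
            if obj < best_obj - 1e-12:
                best_obj, best_e = obj, e
    return best_e, best_obj


def refit_threshold_oracle(S: np.ndarray, m: np.ndarray, min_prop: float = 0.10):
    """The <min_prop removal-and-reassignment rule driven by the enumeration QP."""
    K = S.shape[0]
    active = list(range(K))
    mh = m / m.sum()
    for _ in range(K):
        e, _ = simplex_ls_oracle(S[active], mh)
        low = [i for i, p in enumerate(e) if p < min_prop]
        if not low or len(active) == 1:
            full = np.zeros(K)
            full[active] = e
            return full
        if len(low) == len(active):
            best_i, best_obj = None, np.inf
            for i in active:
                obj = float(np.sum((mh - S[i]) ** 2))
                if obj < best_obj:
                    best_i, best_obj = i, obj
            active = [best_i]
            continue
        active = [a for j, a in enumerate(active) if j not in low]
    e, _ = simplex_ls_oracle(S[active], mh)
    full = np.zeros(K)
    full[active] = e
    return full


def tiered_filter_oracle(depth, alt, normal_alt):
    """Literal clause-by-clause transcription of the tiered exclusion rules."""
    vaf = alt / depth if depth > 0 else 0.0
    reasons = []
    if depth < 10:
        reasons.append("depth")
    if vaf < 0.20 and depth < 20:
        reasons.append("low_vaf_low_depth")
    if vaf < 0.05:
        reasons.append("very_low_vaf")
    if vaf > 0.15 and alt < 5:
        reasons.append("few_alt_reads")
    if vaf < 0.30 and normal_alt >= 3:
        reasons.append("normal_contamination_3")
    if normal_alt >= 2 and vaf < 0.20:
        reasons.append("normal_contamination_2")
    return tuple(reasons)


def motif_regex_oracle(read: str, motif: str, min_copies: int) -> bool:
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    rc = "".join(comp[b] for b in reversed(motif))
    pat = f"(?:{re.escape(motif)}){{{min_copies},}}|(?:{re.escape(rc)}){{{min_copies},}}"
    return re.search(pat, read.upper()) is not None
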