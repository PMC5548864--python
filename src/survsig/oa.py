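"""Two-level orthogonal arrays and main-effect estimation.

Shared machinery for the intelligent (orthogonal-array) crossover and for
the main-effect-difference (MED) ranking of features inside a signature.

An ``L_N(2^(N-1))`` array has N runs (rows) and up to N-1 two-level factors
(columns) such that every column is balanced (each level N/2 times) and
every column pair contains each of the four level combinations exactly N/4
times. This lets main effects of k factors be estimated from N = O(k)
experiments instead of 2^k.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import SchemaError


@dataclass
class OrthogonalArray:
    """N x k table of levels {1, 2} with balanced columns and column pairs."""

    levels: np.ndarray
    N: int
    k: int


@dataclass
class MainEffects:
    """Per-factor mean response at each level, and the absolute difference (MED)."""

    level_means: np.ndarray  # shape (k, 2)
    med: np.ndarray  # shape (k,), |mean@level1 - mean@level2|


def _bit_reverse(i: int, m: int) -> int:
    out = 0
    for _ in range(m):
        out = (out << 1) | (i & 1)
        i >>= 1
    return out


def build_oa(k: int) -> OrthogonalArray:
    """Smallest standard two-level OA with k columns: N = 2^ceil(log2(k+1)) rows.

    Construction is the canonical Hadamard-derived one (Taguchi column
    ordering): entry(i, j) = 1 + popcount(j & bitrev(i)) mod 2, giving e.g.
    L4 = [[1,1,1],[1,2,2],[2,1,2],[2,2,1]] for k = 3.
    """
    if k < 1:
        raise SchemaError("need at least one factor")
    m = max(1, int(np.ceil(np.log2(k + 1))))
    N = 1 << m
    levels = np.empty((N, k), dtype=np.int8)
    for i in range(N):
        ri = _bit_reverse(i, m)
        for j in range(1, k + 1):
            levels[i, j - 1] = 1 + (bin(ri & j).count("1") & 1)
    return OrthogonalArray(levels=levels, N=N, k=k)


def main_effects(oa: OrthogonalArray, response) -> MainEffects:
    """Estimate per-factor main effects from one response per OA row.

    For factor j the effect is the pair (mean response over rows at level 1,
    mean over rows at level 2); MED is the absolute difference. Linear in the
    response vector by construction.
    """
    r = np.asarray(response, dtype=float)
    if r.shape != (oa.N,):
        raise SchemaError(f"response has shape {r.shape}, expected ({oa.N},)")
    if not np.all(np.isfinite(r)):
        raise SchemaError("responses must be finite")
    at1 = oa.levels == 1
    mean1 = (r[:, None] * at1).sum(axis=0) / at1.sum(axis=0)
    mean2 = (r[:, None] * ~at1).sum(axis=0) / (~at1).sum(axis=0)
    return MainEffects(level_means=np.column_stack([mean1, mean2]),
                       med=np.abs(mean1 - mean2))
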