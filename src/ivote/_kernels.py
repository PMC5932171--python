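"""Compiled inner loops for vote casting and direction refinement.

Both kernels work on 3D arrays; 2D inputs are embedded as a singleton
leading axis with a zero direction component, which leaves the geometry
untouched.  Loops run in a fixed serial order, so accumulation and argmax
tie-breaking (first site in lexicographic array order) are deterministic.
The per-voter candidate window is the tight axis-aligned bounding box of
the cone-plus-cap solid, computed without trigonometric calls from the
direction components.
"""

import math

import numba
import numpy as np

__all__ = ["cast_votes_3d", "update_directions_3d"]


@numba.njit(inline="always", cache=True)
def _axis_bounds(pos, d_i, cos_half, sin_half, r, s_i, n_i):
    # support of the cone+cap solid along +/- this coordinate axis
    s = math.sqrt(max(0.0, 1.0 - d_i * d_i))
    hi_f = 1.0 if d_i >= cos_half else d_i * cos_half + s * sin_half
    lo_f = 1.0 if -d_i >= cos_half else -d_i * cos_half + s * sin_half
    hi_f = max(0.0, hi_f)
    lo_f = max(0.0, lo_f)
    lo = int(math.ceil(pos - r * lo_f / s_i - 1e-9))
    hi = int(math.floor(pos + r * hi_f / s_i + 1e-9))
    if lo < 0:
        lo = 0
    if hi > n_i - 1:
        hi = n_i - 1
    return lo, hi


@numba.njit(cache=True)
def cast_votes_3d(mag, vec, s0, s1, s2, r, cos_half, votes, counts):
    """Scatter each voter's magnitude into its vote cone.

    ``votes`` and ``counts`` are zero-initialized output arrays shaped like
    ``mag``; ``counts[t]`` records the member count of voter ``t`` so that
    the bookkeeping identity sum(votes) == sum(mag * counts) can be audited.
    """
    n0, n1, n2 = mag.shape
    sin_half = math.sqrt(max(0.0, 1.0 - cos_half * cos_half))
    ch2 = cos_half * cos_half
    r2 = r * r
    for i0 in range(n0):
        for i1 in range(n1):
            for i2 in range(n2):
                m = mag[i0, i1, i2]
                if m <= 0.0:
                    continue
                d0 = vec[i0, i1, i2, 0]
                d1 = vec[i0, i1, i2, 1]
                d2 = vec[i0, i1, i2, 2]
                lo0, hi0 = _axis_bounds(i0, d0, cos_half, sin_half, r, s0, n0)
                lo1, hi1 = _axis_bounds(i1, d1, cos_half, sin_half, r, s1, n1)
                lo2, hi2 = _axis_bounds(i2, d2, cos_half, sin_half, r, s2, n2)
                cnt = 0
                for j0 in range(lo0, hi0 + 1):
                    o0 = (j0 - i0) * s0
                    for j1 in range(lo1, hi1 + 1):
                        o1 = (j1 - i1) * s1
                        for j2 in range(lo2, hi2 + 1):
                            o2 = (j2 - i2) * s2
                            dot = o0 * d0 + o1 * d1 + o2 * d2
                            if dot <= 0.0:
                                continue
                            l2 = o0 * o0 + o1 * o1 + o2 * o2
                            if l2 >= r2:
                                continue
                            if dot * dot > ch2 * l2:
                                votes[j0, j1, j2] += m
                                cnt += 1
                counts[i0, i1, i2] = cnt


@numba.njit(cache=True)
def update_directions_3d(mag, vec, votes, s0, s1, s2, r, cos_half, out_vec):
    """Re-orient each voter toward the highest vote score in its cone.

    Magnitudes are untouched.  Voters with an empty cone or an all-zero
    cone score keep their previous direction.  Ties resolve to the first
    (lexicographically smallest) site visited.
    """
    n0, n1, n2 = mag.shape
    sin_half = math.sqrt(max(0.0, 1.0 - cos_half * cos_half))
    ch2 = cos_half * cos_half
    r2 = r * r
    for i0 in range(n0):
        for i1 in range(n1):
            for i2 in range(n2):
                out_vec[i0, i1, i2, 0] = vec[i0, i1, i2, 0]
                out_vec[i0, i1, i2, 1] = vec[i0, i1, i2, 1]
                out_vec[i0, i1, i2, 2] = vec[i0, i1, i2, 2]
                if mag[i0, i1, i2] <= 0.0:
                    continue
                d0 = vec[i0, i1, i2, 0]
                d1 = vec[i0, i1, i2, 1]
                d2 = vec[i0, i1, i2, 2]
                lo0, hi0 = _axis_bounds(i0, d0, cos_half, sin_half, r, s0, n0)
                lo1, hi1 = _axis_bounds(i1, d1, cos_half, sin_half, r, s1, n1)
                lo2, hi2 = _axis_bounds(i2, d2, cos_half, sin_half, r, s2, n2)
                best = 0.0
                b0 = -1
                b1 = -1
                b2 = -1
                for j0 in range(lo0, hi0 + 1):
                    o0 = (j0 - i0) * s0
                    for j1 in range(lo1, hi1 + 1):
                        o1 = (j1 - i1) * s1
                        for j2 in range(lo2, hi2 + 1):
                            o2 = (j2 - i2) * s2
                            dot = o0 * d0 + o1 * d1 + o2 * d2
                            if dot <= 0.0:
                                continue
                            l2 = o0 * o0 + o1 * o1 + o2 * o2
                            if l2 >= r2:
                                continue
                            if dot * dot > ch2 * l2:
                                v = votes[j0, j1, j2]
                                if v > best:
                                    best = v
                                    b0 = j0
                                    b1 = j1
                                    b2 = j2
                if b0 >= 0 and best > 0.0:
                    o0 = (b0 - i0) * s0
                    o1 = (b1 - i1) * s1
                    o2 = (b2 - i2) * s2
                    norm = math.sqrt(o0 * o0 + o1 * o1 + o2 * o2)
                    out_vec[i0, i1, i2, 0] = o0 / norm
                    out_vec[i0, i1, i2, 1] = o1 / norm
                    out_vec[i0, i1, i2, 2] = o2 / norm
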