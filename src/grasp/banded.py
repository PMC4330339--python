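"""Incremental banded Needleman-Wunsch with affine gaps.

Assembly paths are aligned to the query inside a diagonal band anchored
on the seed diagonal: cell (i, j) is in band iff |i - j| <= h, with
h = d/2 the band half-width.  A path extension appends p_ext to the path
and q_ext to the query window; only the L-shaped region of new cells is
filled, seeded from the stored boundary scores (the band's last row and
last column, O(d) cells).  The chain of incremental extensions reproduces,
exactly, the from-scratch banded global alignment of the final pair — the
correctness invariant the test suite checks against a brute-force DP.

Gap convention: a gap of length g costs gap_open + g * gap_extend
(NCBI-style, so 11/1 charges 12 for a length-1 gap).
"""

from __future__ import annotations

from dataclasses import dataclass

from .scoring import NEG_INF, ScoringScheme

# DP layers: M ends in a residue pair, X ends in a path-consuming gap
# (path residue vs gap), Y ends in a query-consuming gap.


@dataclass(frozen=True)
class BandBoundary:
    """Resumable state of a banded affine alignment of p (len I) vs q (len J).

    ``row*`` hold the three DP layers on row i = I for j starting at
    ``row_lo``; ``col*`` hold column j = J for i starting at ``col_lo``.
    ``p_tail``/``q_tail`` keep the trailing 2h characters of p and q,
    which is all the sequence context later extensions can touch.
    """

    h: int
    I: int
    J: int
    row_lo: int
    rowM: tuple
    rowX: tuple
    rowY: tuple
    col_lo: int
    colM: tuple
    colX: tuple
    colY: tuple
    p_tail: str
    q_tail: str
    score: int


def initial_boundary(h: int) -> BandBoundary:
    """State of the empty alignment (score 0 at the origin)."""
    if h < 1:
        raise ValueError("band half-width must be >= 1")
    cell = ((0,), (NEG_INF,), (NEG_INF,))
    return BandBoundary(h, 0, 0, 0, *cell, 0, *cell, "", "", 0)


def _get(values, lo: int, j: int) -> int:
    idx = j - lo
    if 0 <= idx < len(values):
        return values[idx]
    return NEG_INF


def banded_extend(
    state: BandBoundary,
    p_ext: str,
    q_ext: str,
    scheme: ScoringScheme,
) -> BandBoundary | None:
    """Extend the alignment by (p_ext, q_ext); None if the band breaks.

    The band breaks when the new end cell drifts off the diagonal band;
    callers treat that as rejection of the candidate, not an error.
    """
    if not p_ext and not q_ext:
        return state
    h = state.h
    I, J = state.I, state.J
    I2, J2 = I + len(p_ext), J + len(q_ext)
    if abs(I2 - J2) > h:
        return None
    go_ge = scheme.gap_open + scheme.gap_extend
    ge = scheme.gap_extend
    mat = scheme.matrix

    p_tail_off = I - len(state.p_tail)
    q_tail_off = J - len(state.q_tail)

    def pchar_ord(i: int) -> int:
        # 1-based row index -> path character
        if i > I:
            return ord(p_ext[i - I - 1])
        return ord(state.p_tail[i - 1 - p_tail_off])

    def qchar_ord(j: int) -> int:
        if j > J:
            return ord(q_ext[j - J - 1])
        return ord(state.q_tail[j - 1 - q_tail_off])

    colM, colX, colY, col_lo = state.colM, state.colX, state.colY, state.col_lo

    def col_cell(i: int) -> tuple[int, int, int]:
        idx = i - col_lo
        if 0 <= idx < len(colM):
            return colM[idx], colX[idx], colY[idx]
        return NEG_INF, NEG_INF, NEG_INF

    new_colM: dict[int, int] = {}
    new_colX: dict[int, int] = {}
    new_colY: dict[int, int] = {}
    if J2 == J:  # pure path extension: old column stays valid for i <= I
        for i in range(col_lo, min(I, J + h) + 1):
            cm, cx, cy = col_cell(i)
            new_colM[i], new_colX[i], new_colY[i] = cm, cx, cy

    # prev holds row i-1 as (lo, M, X, Y).  Rows i <= I ("phase 1") are
    # represented as the column-boundary head at j=J followed by their
    # newly computed tail j > J; rows i > I ("phase 2") are full in-band rows.
    prev: tuple[int, list, list, list] | None = None
    row_start = max(0, J + 1 - h)
    for i in range(row_start, I2 + 1):
        hi_i = min(J2, i + h)
        if i <= I:
            nlo = J + 1
            if nlo > hi_i:
                continue  # no new cells this row (monotone: earlier rows only)
            cm, cx, cy = col_cell(i)
            lo = J
            M, X, Y = [cm], [cx], [cy]
            um, ux, uy = col_cell(i - 1)
            pm, px, py = [um], [ux], [uy]
            if prev is not None:
                pm += prev[1][1:]
                px += prev[2][1:]
                py += prev[3][1:]
            plo = J
        else:
            nlo = max(0, i - h)
            if nlo > hi_i:
                return None  # band has no cells in this row
            lo = nlo
            M, X, Y = [], [], []
            if i == I + 1:
                plo = state.row_lo
                pm = list(state.rowM)
                px = list(state.rowX)
                py = list(state.rowY)
                if prev is not None:  # phase-1 tail of row I
                    pm += prev[1][1:]
                    px += prev[2][1:]
                    py += prev[3][1:]
            else:
                plo, pm, px, py = prev
        pord = pchar_ord(i) if i >= 1 else 0
        for j in range(nlo, hi_i + 1):
            if j == 0:
                um, ux, uy = _get(pm, plo, 0), _get(px, plo, 0), _get(py, plo, 0)
                best_u = um if um >= uy else uy
                m_val = NEG_INF
                x_val = max(best_u - go_ge, ux - ge)
                y_val = NEG_INF
            else:
                dm = _get(pm, plo, j - 1)
                dx = _get(px, plo, j - 1)
                dy = _get(py, plo, j - 1)
                diag = dm if dm >= dx else dx
                if dy > diag:
                    diag = dy
                m_val = diag + int(mat[pord, qchar_ord(j)]) if i >= 1 else NEG_INF
                um = _get(pm, plo, j)
                ux = _get(px, plo, j)
                uy = _get(py, plo, j)
                best_u = um if um >= uy else uy
                x_val = max(best_u - go_ge, ux - ge)
                lm = _get(M, lo, j - 1)
                lx = _get(X, lo, j - 1)
                ly = _get(Y, lo, j - 1)
                best_l = lm if lm >= lx else lx
                y_val = max(best_l - go_ge, ly - ge)
            M.append(m_val)
            X.append(x_val)
            Y.append(y_val)
            if j == J2:
                new_colM[i], new_colX[i], new_colY[i] = m_val, x_val, y_val
        prev = (lo, M, X, Y)

    # boundary row i = I2
    if I2 > I:
        row_lo2, rM, rX, rY = prev
        rM, rX, rY = list(rM), list(rX), list(rY)
    else:  # pure query extension: merge stored row I with its new tail
        row_lo2 = state.row_lo
        rM = list(state.rowM)
        rX = list(state.rowX)
        rY = list(state.rowY)
        if prev is not None:
            rM += prev[1][1:]
            rX += prev[2][1:]
            rY += prev[3][1:]
    lo_f = max(0, I2 - h)
    hi_f = min(J2, I2 + h)
    a, b = lo_f - row_lo2, hi_f - row_lo2 + 1
    if a < 0 or b > len(rM):
        return None
    rM, rX, rY = rM[a:b], rX[a:b], rY[a:b]

    col_lo2 = max(0, J2 - h)
    col_hi2 = min(I2, J2 + h)
    cM = [new_colM.get(i, NEG_INF) for i in range(col_lo2, col_hi2 + 1)]
    cX = [new_colX.get(i, NEG_INF) for i in range(col_lo2, col_hi2 + 1)]
    cY = [new_colY.get(i, NEG_INF) for i in range(col_lo2, col_hi2 + 1)]

    end_idx = J2 - lo_f
    if not (0 <= end_idx < len(rM)):
        return None
    score = max(rM[end_idx], rX[end_idx], rY[end_idx])
    if score <= NEG_INF // 2:
        return None
    p_tail = (state.p_tail + p_ext)[-2 * h :]
    q_tail = (state.q_tail + q_ext)[-2 * h :]
    return BandBoundary(
        h, I2, J2, lo_f,
        tuple(rM), tuple(rX), tuple(rY),
        col_lo2, tuple(cM), tuple(cX), tuple(cY),
        p_tail, q_tail, int(score),
    )


def banded_score(p: str, q: str, scheme: ScoringScheme) -> int | None:
    """Banded global alignment score of p vs q in one shot."""
    out = banded_extend(initial_boundary(scheme.half_band), p, q, scheme)
    return None if out is None else out.score
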