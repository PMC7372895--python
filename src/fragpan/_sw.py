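"""Affine-gap local alignment kernel (banded Smith-Waterman with traceback).

Bases are encoded A=0, C=1, G=2, T=3, N=4.  N never matches anything
(including another N) and scores as a mismatch.  A gap of length L costs
``gap_open + L * gap_extend``.  The band restricts computation to matrix
cells whose diagonal ``j - i`` lies in ``[dlo, dhi]``; passing
``dlo = -len(q), dhi = len(s)`` makes the kernel exact (full matrix).
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = -(10**9)

_BASE_TO_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _BASE_TO_CODE[ord(_b)] = _i
    _BASE_TO_CODE[ord(_b.lower())] = _i


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string as uint8 codes (non-ACGT -> 4)."""
    return _BASE_TO_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@njit(cache=True)
def sw_align(q, s, match, mismatch, gap_open, gap_extend, dlo, dhi):  # pragma: no cover
    """Banded local alignment of q vs s.

    Returns (score, q_start, q_end, s_start, s_end, n_match, n_columns)
    for the single best-scoring local alignment inside the band; all
    coordinates 0-based half-open.  Ties prefer the first-reached cell
    (smallest i, then j) so results are deterministic.
    """
    m = q.shape[0]
    n = s.shape[0]

    h_prev = np.full(n + 1, NEG, dtype=np.int64)
    f_prev = np.full(n + 1, NEG, dtype=np.int64)
    h_cur = np.full(n + 1, NEG, dtype=np.int64)
    f_cur = np.full(n + 1, NEG, dtype=np.int64)
    ptr_h = np.zeros((m + 1, n + 1), dtype=np.uint8)  # 0 stop, 1 diag, 2 E, 3 F
    ptr_e = np.zeros((m + 1, n + 1), dtype=np.uint8)  # 1 = extend from E
    ptr_f = np.zeros((m + 1, n + 1), dtype=np.uint8)  # 1 = extend from F

    go_ge = gap_open + gap_extend

    for j in range(n + 1):
        if dlo <= j <= dhi:
            h_prev[j] = 0

    best = 0
    bi = 0
    bj = 0
    for i in range(1, m + 1):
        for j in range(n + 1):
            h_cur[j] = NEG
            f_cur[j] = NEG
        if dlo <= -i <= dhi:
            h_cur[0] = 0
        e_run = NEG
        jlo = i + dlo
        if jlo < 1:
            jlo = 1
        jhi = i + dhi
        if jhi > n:
            jhi = n
        qc = q[i - 1]
        for j in range(jlo, jhi + 1):
            # E: gap in query (consumes s[j-1])
            e_open = h_cur[j - 1] - go_ge
            e_ext = e_run - gap_extend
            if e_ext > e_open:
                e_run = e_ext
                ptr_e[i, j] = 1
            else:
                e_run = e_open
                ptr_e[i, j] = 0
            # F: gap in subject (consumes q[i-1])
            f_open = h_prev[j] - go_ge
            f_ext = f_prev[j] - gap_extend
            if f_ext > f_open:
                f_cur[j] = f_ext
                ptr_f[i, j] = 1
            else:
                f_cur[j] = f_open
                ptr_f[i, j] = 0
            sc = s[j - 1]
            if qc == sc and qc < 4:
                diag = h_prev[j - 1] + match
            else:
                diag = h_prev[j - 1] - mismatch
            h = 0
            p = 0
            if diag > h:
                h = diag
                p = 1
            if e_run > h:
                h = e_run
                p = 2
            if f_cur[j] > h:
                h = f_cur[j]
                p = 3
            h_cur[j] = h
            ptr_h[i, j] = p
            if h > best:
                best = h
                bi = i
                bj = j
        for j in range(n + 1):
            h_prev[j] = h_cur[j]
            f_prev[j] = f_cur[j]

    if best <= 0:
        return 0, 0, 0, 0, 0, 0, 0

    # traceback
    i = bi
    j = bj
    state = 0  # 0=H, 1=E, 2=F
    n_match = 0
    n_cols = 0
    while True:
        if state == 0:
            p = ptr_h[i, j]
            if p == 0:
                break
            if p == 1:
                n_cols += 1
                if q[i - 1] == s[j - 1] and q[i - 1] < 4:
                    n_match += 1
                i -= 1
                j -= 1
            elif p == 2:
                state = 1
            else:
                state = 2
        elif state == 1:
            ext = ptr_e[i, j]
            n_cols += 1
            j -= 1
            if ext == 0:
                state = 0
        else:
            ext = ptr_f[i, j]
            n_cols += 1
            i -= 1
            if ext == 0:
                state = 0

    return best, i, bi, j, bj, n_match, n_cols


@njit(cache=True)
def seed_boxes(hq, hs, diag_gap, pos_gap, min_count):  # pragma: no cover
    """Group seed matches into diagonal clusters.

    ``hq``/``hs`` must be sorted by (diagonal, subject position).  Returns
    an (n, 7) int64 array of boxes [qlo, qhi, slo, shi, dlo, dhi, count]
    keeping only clusters with at least ``min_count`` seeds.
    """
    n = hq.shape[0]
    out = np.empty((n, 7), dtype=np.int64)
    n_out = 0
    if n == 0:
        return out[:0]
    band_start = 0
    for idx in range(1, n + 1):
        if idx == n or (hs[idx] - hq[idx]) - (hs[idx - 1] - hq[idx - 1]) > diag_gap:
            # one diagonal band: re-sort by subject position, split on gaps
            order = np.argsort(hs[band_start:idx], kind="mergesort") + band_start
            start = 0
            size = idx - band_start
            for j in range(1, size + 1):
                if j == size or hs[order[j]] - hs[order[j - 1]] > pos_gap:
                    count = j - start
                    if count >= min_count:
                        qlo = hq[order[start]]
                        qhi = qlo
                        slo = hs[order[start]]
                        shi = slo
                        dlo = slo - qlo
                        dhi = dlo
                        for t in range(start, j):
                            qv = hq[order[t]]
                            sv = hs[order[t]]
                            dv = sv - qv
                            if qv < qlo:
                                qlo = qv
                            if qv > qhi:
                                qhi = qv
                            if sv < slo:
                                slo = sv
                            if sv > shi:
                                shi = sv
                            if dv < dlo:
                                dlo = dv
                            if dv > dhi:
                                dhi = dv
                        out[n_out, 0] = qlo
                        out[n_out, 1] = qhi
                        out[n_out, 2] = slo
                        out[n_out, 3] = shi
                        out[n_out, 4] = dlo
                        out[n_out, 5] = dhi
                        out[n_out, 6] = count
                        n_out += 1
                    start = j
            band_start = idx
    return out[:n_out]


@njit(cache=True)
def kmer_hashes(codes, k):  # pragma: no cover
    """Rolling 2-bit k-mer hashes; positions containing N get hash -1."""
    n = codes.shape[0]
    out = np.full(max(n - k + 1, 0), -1, dtype=np.int64)
    if n < k:
        return out
    mask = (np.int64(1) << (2 * k)) - 1
    h = np.int64(0)
    n_run = 0  # positions since last N
    for i in range(n):
        c = codes[i]
        if c >= 4:
            n_run = 0
            h = 0
            continue
        h = ((h << 2) | c) & mask
        n_run += 1
        if n_run >= k:
            out[i - k + 1] = h
    return out
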