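"""Plain full-matrix Smith-Waterman score, used only as a test oracle.

Deliberately independent of the package's aligner: no seeding, no numba,
no traceback — just the textbook affine-gap local-alignment recurrence
computed row by row in pure Python.  A gap of length g costs
open + g * extend.
"""

NEG = -(10**9)


def sw_score(query: str, ref: str, match=1, mismatch=-4, gap_open=6, gap_extend=1) -> int:
    n, m = len(query), len(ref)
    go_ge = gap_open + gap_extend
    H_prev = [0] * (m + 1)
    F_prev = [NEG] * (m + 1)
    best = 0
    for i in range(1, n + 1):
        qc = query[i - 1]
        H_row = [0] * (m + 1)
        F_row = [NEG] * (m + 1)
        e = NEG
        for j in range(1, m + 1):
            e = max(H_row[j - 1] - go_ge, e - gap_extend)
            f = max(H_prev[j] - go_ge, F_prev[j] - gap_extend)
            F_row[j] = f
            h = H_prev[j - 1] + (match if qc == ref[j - 1] else mismatch)
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = 0
            H_row[j] = h
            if h > best:
                best = h
        H_prev, F_prev = H_row, F_row
    return best


def sw_score_both_strands(query: str, ref: str, **kw) -> int:
    comp = str.maketrans("ACGTN", "TGCAN")
    rc = query.translate(comp)[::-1]
    return max(sw_score(query, ref, **kw), sw_score(rc, ref, **kw))
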