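"""Independent brute-force affine-gap local alignment oracle.

A direct O(nm) Gotoh dynamic program over explicit Python lists, kept
deliberately separate from the package's alignment path so score agreement
between the two is a meaningful check.  Gap convention: a length-L gap
costs ``gap_open + L * gap_extend``.
"""

NEG = -(10 ** 9)


def local_affine_score(
    a: str,
    b: str,
    match: int = 2,
    mismatch: int = -3,
    gap_open: int = 5,
    gap_extend: int = 2,
) -> int:
    """Best local alignment score of a vs b (0 when nothing scores > 0)."""
    n, m = len(a), len(b)
    best = 0
    h_prev = [0] * (m + 1)
    f_prev = [NEG] * (m + 1)
    for i in range(1, n + 1):
        h_row = [0] * (m + 1)
        f_row = [NEG] * (m + 1)
        e = NEG
        ai = a[i - 1]
        for j in range(1, m + 1):
            e = max(e - gap_extend, h_row[j - 1] - gap_open - gap_extend)
            f_row[j] = max(
                f_prev[j] - gap_extend, h_prev[j] - gap_open - gap_extend
            )
            s = match if (ai == b[j - 1] and ai != "N") else mismatch
            h = max(0, h_prev[j - 1] + s, e, f_row[j])
            h_row[j] = h
            if h > best:
                best = h
        h_prev, f_prev = h_row, f_row
    return best
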