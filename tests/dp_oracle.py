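"""Brute-force Gotoh dynamic-programming scorer, independent of the
package's alignment engine.  A length-k gap costs ``-(open + (k-1) * extend)``
in magnitude, i.e. the opening penalty covers the first gapped base."""

import numpy as np

NEG = -(10**9)


def affine_global_score(
    ref: str,
    query: str,
    match: int = 2,
    mismatch: int = -4,
    gap_open: int = -10,
    gap_extend: int = -1,
) -> float:
    n, m = len(ref), len(query)
    q = np.frombuffer(query.encode(), dtype=np.uint8)

    M = np.full(m + 1, NEG, dtype=np.int64)
    X = np.full(m + 1, NEG, dtype=np.int64)  # gap in query (deletion)
    Y = np.full(m + 1, NEG, dtype=np.int64)  # gap in ref (insertion)
    M[0] = 0
    if m > 0:
        Y[1:] = gap_open + gap_extend * np.arange(m)

    for i in range(1, n + 1):
        s = np.where(q == ord(ref[i - 1]), match, mismatch)
        best_prev = np.maximum(np.maximum(M, X), Y)
        M_new = np.full(m + 1, NEG, dtype=np.int64)
        M_new[1:] = best_prev[:-1] + s
        X_new = np.maximum(np.maximum(M, Y) + gap_open, X + gap_extend)
        X_new[0] = gap_open + gap_extend * (i - 1)
        # Y_new[j] = max over k < j of max(M_new[k], X_new[k]) + open
        #            + (j-1-k)*extend  -> prefix-max scan
        Y_new = np.full(m + 1, NEG, dtype=np.int64)
        if m > 0:
            a = np.maximum(M_new[:-1], X_new[:-1]) + gap_open - gap_extend * np.arange(m)
            Y_new[1:] = np.maximum.accumulate(a) + gap_extend * np.arange(m)
        M, X, Y = M_new, X_new, Y_new

    return float(max(M[m], X[m], Y[m]))
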