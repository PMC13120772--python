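"""Independent reference computations used only by the tests.

The alignment oracle is a plain pure-Python Gotoh dynamic program (no numpy in
the recurrence, no prefilter) sharing only the published conventions with the
implementation under test: affine gap of length k costs open + k*extend,
traceback prefers diagonal, then gap-in-query, then gap-in-target, gap closure
over extension, and the endpoint is the maximal cell with the smallest query
index then target index.
"""

from __future__ import annotations

from ghannot.align import ALPHABET, AlignerConfig, substitution_matrix

NEG = -(10 ** 9)


def dp_align(query: str, target: str, config: AlignerConfig | None = None):
    """Full Smith-Waterman/Gotoh, returning (raw, qstart, qend, aln_len, n_ident).

    Returns None when no positive-scoring local alignment exists.
    """
    config = config or AlignerConfig()
    S = substitution_matrix(config.substitution_matrix)
    code = {aa: i for i, aa in enumerate(ALPHABET)}
    q = [code[c] for c in query.upper()]
    t = [code[c] for c in target.upper()]
    go, ge = config.gap_open, config.gap_extend
    gi = go + ge
    n, m = len(q), len(t)
    H = [[0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    best, bi, bj = 0, 0, 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            e = max(H[i][j - 1] - gi, E[i][j - 1] - ge)
            f = max(H[i - 1][j] - gi, F[i - 1][j] - ge)
            d = H[i - 1][j - 1] + S[q[i - 1], t[j - 1]]
            h = max(0, d, e, f)
            H[i][j], E[i][j], F[i][j] = h, e, f
            if h > best:
                best, bi, bj = h, i, j
    if best <= 0:
        return None
    i, j, state = bi, bj, "H"
    aln_len = n_ident = 0
    while i > 0 and j > 0:
        if state == "H":
            h = H[i][j]
            if h == 0:
                break
            if h == H[i - 1][j - 1] + S[q[i - 1], t[j - 1]]:
                aln_len += 1
                n_ident += q[i - 1] == t[j - 1]
                i -= 1
                j -= 1
            elif h == E[i][j]:
                state = "E"
            else:
                state = "F"
        elif state == "E":
            aln_len += 1
            closing = E[i][j] == H[i][j - 1] - gi
            j -= 1
            if closing:
                state = "H"
        else:
            aln_len += 1
            closing = F[i][j] == H[i - 1][j] - gi
            i -= 1
            if closing:
                state = "H"
    return best, i + 1, bi, aln_len, n_ident


def dp_best_target(query: str, references, config=None):
    """Brute-force best target: max raw score, ties by identity then id."""
    best = None
    for ref in references:
        res = dp_align(query, ref.sequence, config)
        if res is None:
            continue
        raw, qs, qe, aln_len, n_ident = res
        key = (-raw, -(n_ident / aln_len), ref.seq_id)
        if best is None or key < best[0]:
            best = (key, ref.seq_id, raw)
    return None if best is None else (best[1], best[2])


def percentile_oracle(values, q: float) -> float:
    """Sort-and-interpolate percentile (linear between closest ranks)."""
    xs = sorted(values)
    if not xs:
        raise ValueError("empty distribution")
    if len(xs) == 1:
        return float(xs[0])
    pos = q * (len(xs) - 1)
    lo = int(pos)
    frac = pos - lo
    if lo + 1 >= len(xs):
        return float(xs[-1])
    return float(xs[lo] + frac * (xs[lo + 1] - xs[lo]))
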