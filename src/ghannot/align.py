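"""Pairwise protein search: local affine-gap alignment, hit ranking, tabular I/O.

The annotator gates hits on three quantities only — percent identity (identical
aligned columns / alignment length), query coverage (aligned query span / query
length) and bitscore — so this module computes exactly those.  The aligner is a
Smith–Waterman/Gotoh dynamic program with a deterministic traceback convention
(diagonal before gap-in-query before gap-in-target; endpoint with the smallest
query index, then target index) so that identical inputs always yield identical
hits.  Raw scores are converted to bits with gapped Karlin–Altschul parameters.

A k-mer prefilter skips reference sequences that share no k-mer with the query;
it can only drop targets with which the query shares fewer than one k-mer, so
any biologically meaningful hit survives it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from Bio.Align import substitution_matrices
from numba import njit

#: canonical residues plus the ambiguity letter X
ALPHABET = "ACDEFGHIKLMNPQRSTVWYX"
_CODE = {aa: i for i, aa in enumerate(ALPHABET)}

_MATRIX_CACHE: dict[str, np.ndarray] = {}


def substitution_matrix(name: str = "BLOSUM62") -> np.ndarray:
    """Return an integer substitution matrix over :data:`ALPHABET`.

    Loaded from Biopython's matrix collection; the ambiguity letter X is
    rescored to 0 against everything (neutral handling of ambiguity).
    """
    key = name.upper()
    if key not in _MATRIX_CACHE:
        try:
            mat = substitution_matrices.load(key)
        except FileNotFoundError as exc:  # pragma: no cover - depends on name
            raise ValueError(f"unknown substitution matrix: {name!r}") from exc
        out = np.zeros((len(ALPHABET), len(ALPHABET)), dtype=np.int64)
        for i, a in enumerate(ALPHABET):
            for j, b in enumerate(ALPHABET):
                if a == "X" or b == "X":
                    out[i, j] = 0
                else:
                    out[i, j] = int(mat[a, b])
        _MATRIX_CACHE[key] = out
    return _MATRIX_CACHE[key]


@dataclass(frozen=True)
class AlignerConfig:
    """Scoring scheme for the internal search.

    Defaults follow the standard gapped BLOSUM62 parameterization (gap open 11,
    extend 1; lambda = 0.267, K = 0.041) so that the 200-bit reporting cutoff
    used downstream has its conventional meaning.
    """

    substitution_matrix: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1
    karlin_lambda: float = 0.267
    karlin_k: float = 0.041
    kmer_length: int = 5
    use_prefilter: bool = True

    def __post_init__(self) -> None:
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive")
        if self.gap_extend > self.gap_open:
            raise ValueError("gap_extend must not exceed gap_open")
        if self.karlin_lambda <= 0 or self.karlin_k <= 0:
            raise ValueError("Karlin-Altschul parameters must be positive")
        if self.kmer_length < 1:
            raise ValueError("kmer_length must be >= 1")

    def matrix(self) -> np.ndarray:
        return substitution_matrix(self.substitution_matrix)


@dataclass(frozen=True)
class SearchHit:
    """One scored pairwise match.

    ``percent_identity`` is identical aligned columns over alignment length;
    ``query_coverage`` is the aligned query span over the query length.
    ``query_start``/``query_end`` are 1-based inclusive.
    """

    query_id: str
    target_id: str
    percent_identity: float
    query_coverage: float
    bitscore: float
    alignment_length: int
    raw_score: int = 0
    query_start: int = 0
    query_end: int = 0
    query_length: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.percent_identity <= 100.0):
            raise ValueError("percent_identity must be in [0, 100]")
        if not (0.0 <= self.query_coverage <= 1.0 + 1e-12):
            raise ValueError("query_coverage must be in [0, 1]")
        if self.alignment_length < 1:
            raise ValueError("alignment_length must be >= 1")


def encode_sequence(sequence: str) -> np.ndarray:
    """Map an amino-acid string onto integer codes; rejects empty/non-canonical."""
    if not sequence:
        raise ValueError("empty sequence")
    seq = sequence.upper()
    try:
        return np.array([_CODE[aa] for aa in seq], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"non-canonical residue {exc.args[0]!r} in sequence") from exc


@njit(cache=True)
def _sw_core(q, t, S, gap_open, gap_extend):  # pragma: no cover - jitted
    n = q.shape[0]
    m = t.shape[0]
    NEG = -(10 ** 9)
    H = np.zeros((n + 1, m + 1), dtype=np.int64)
    E = np.full((n + 1, m + 1), NEG, dtype=np.int64)
    F = np.full((n + 1, m + 1), NEG, dtype=np.int64)
    best = 0
    bi = 0
    bj = 0
    gi = gap_open + gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            e = H[i, j - 1] - gi
            if E[i, j - 1] - gap_extend > e:
                e = E[i, j - 1] - gap_extend
            f = H[i - 1, j] - gi
            if F[i - 1, j] - gap_extend > f:
                f = F[i - 1, j] - gap_extend
            h = H[i - 1, j - 1] + S[q[i - 1], t[j - 1]]
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = 0
            H[i, j] = h
            E[i, j] = e
            F[i, j] = f
            if h > best:  # strict: keeps the smallest (i, j) endpoint
                best = h
                bi = i
                bj = j
    if best <= 0:
        return 0, 0, 0, 0, 0
    # traceback with fixed preference: diagonal, then gap-in-query (E), then F
    i = bi
    j = bj
    state = 0
    aln_len = 0
    n_ident = 0
    gi64 = gi
    while i > 0 and j > 0:
        if state == 0:
            h = H[i, j]
            if h == 0:
                break
            d = H[i - 1, j - 1] + S[q[i - 1], t[j - 1]]
            if h == d:
                aln_len += 1
                if q[i - 1] == t[j - 1]:
                    n_ident += 1
                i -= 1
                j -= 1
            elif h == E[i, j]:
                state = 1
            else:
                state = 2
        elif state == 1:
            aln_len += 1
            opened = H[i, j - 1] - gi64
            cur = E[i, j]
            j -= 1
            if cur == opened:  # prefer closing the gap
                state = 0
        else:
            aln_len += 1
            opened = H[i - 1, j] - gi64
            cur = F[i, j]
            i -= 1
            if cur == opened:
                state = 0
    return best, i + 1, bi, aln_len, n_ident


def align_pair(
    query: str, target: str, config: AlignerConfig | None = None
) -> SearchHit | None:
    """Optimal local alignment of ``query`` against ``target``.

    Returns ``None`` when no positive-scoring local alignment exists.
    """
    config = config or AlignerConfig()
    q = encode_sequence(query)
    t = encode_sequence(target)
    score, qs, qe, aln_len, n_ident = _sw_core(
        q, t, config.matrix(), config.gap_open, config.gap_extend
    )
    if score <= 0:
        return None
    return _make_hit("query", "target", score, qs, qe, aln_len, n_ident, len(q), config)


def bitscore_from_raw(raw_score: float, config: AlignerConfig) -> float:
    """Karlin–Altschul normalized score in bits."""
    return (config.karlin_lambda * raw_score - math.log(config.karlin_k)) / math.log(2.0)


def _make_hit(query_id, target_id, score, qs, qe, aln_len, n_ident, qlen, config):
    return SearchHit(
        query_id=query_id,
        target_id=target_id,
        percent_identity=100.0 * n_ident / aln_len,
        query_coverage=(qe - qs + 1) / qlen,
        bitscore=bitscore_from_raw(score, config),
        alignment_length=aln_len,
        raw_score=int(score),
        query_start=int(qs),
        query_end=int(qe),
        query_length=int(qlen),
    )


def _kmers(codes: np.ndarray, k: int) -> set[bytes]:
    b = codes.astype(np.uint8).tobytes()
    return {b[i : i + k] for i in range(len(b) - k + 1)}


def _rank_key(hit: SearchHit):
    return (-hit.bitscore, -hit.percent_identity, hit.target_id)


def search_best_hits(
    queries: Sequence[tuple[str, str]],
    references: Iterable,
    config: AlignerConfig | None = None,
) -> dict[str, list[SearchHit]]:
    """All positive hits per query against the reference set, ranked.

    No identity/coverage/bitscore filtering happens here — that is the
    annotator's job.  Ranking: bitscore desc, then percent identity desc, then
    target id asc.  ``references`` may be (id, sequence) pairs or any objects
    with ``seq_id`` and ``sequence`` attributes.
    """
    config = config or AlignerConfig()
    refs: list[tuple[str, str]] = []
    for r in references:
        if isinstance(r, tuple):
            refs.append(r)
        else:
            refs.append((r.seq_id, r.sequence))
    if not refs:
        raise ValueError("empty reference set")
    matrix = config.matrix()
    k = config.kmer_length
    ref_codes = [(rid, encode_sequence(rseq)) for rid, rseq in refs]
    ref_kmers = [_kmers(codes, k) for _, codes in ref_codes] if config.use_prefilter else None
    out: dict[str, list[SearchHit]] = {}
    for qid, qseq in queries:
        q = encode_sequence(qseq)
        qk = _kmers(q, k) if (config.use_prefilter and len(q) >= k) else None
        hits: list[SearchHit] = []
        for idx, (rid, rcodes) in enumerate(ref_codes):
            if qk is not None and ref_kmers is not None and not (qk & ref_kmers[idx]):
                continue
            score, qs, qe, aln_len, n_ident = _sw_core(
                q, rcodes, matrix, config.gap_open, config.gap_extend
            )
            if score <= 0:
                continue
            hits.append(
                _make_hit(qid, rid, score, qs, qe, aln_len, n_ident, len(q), config)
            )
        hits.sort(key=_rank_key)
        out[qid] = hits
    return out


_EXTERNAL_COLUMNS = ["query", "target", "fident", "alnlen", "qstart", "qend", "qlen", "bits"]


def export_hits(hits: dict[str, list[SearchHit]], path) -> None:
    """Write hits in the 8-column tabular exchange format (engine-compatible)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(_EXTERNAL_COLUMNS) + "\n")
        for qid in hits:
            for h in hits[qid]:
                fh.write(
                    "\t".join(
                        [
                            h.query_id,
                            h.target_id,
                            format(h.percent_identity / 100.0, ".17g"),
                            str(h.alignment_length),
                            str(h.query_start),
                            str(h.query_end),
                            str(h.query_length),
                            format(h.bitscore, ".17g"),
                        ]
                    )
                    + "\n"
                )


def import_external_hits(tabular_path) -> dict[str, list[SearchHit]]:
    """Read ranked hit lists from the 8-column tabular format.

    Compatible with MMseqs2 ``easy-search --format-output
    "query,target,fident,alnlen,qstart,qend,qlen,bits"`` so an external engine
    can stand in for the internal aligner.
    """
    out: dict[str, list[SearchHit]] = {}
    with open(tabular_path, encoding="utf-8") as fh:
        header = fh.readline()
        cols = header.rstrip("\n").split("\t")
        if cols != _EXTERNAL_COLUMNS:
            raise ValueError(
                f"line 1: expected columns {_EXTERNAL_COLUMNS}, got {cols}"
            )
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 8:
                raise ValueError(f"line {lineno}: expected 8 fields, got {len(parts)}")
            try:
                qid, tid = parts[0], parts[1]
                fident = float(parts[2])
                alnlen = int(parts[3])
                qstart = int(parts[4])
                qend = int(parts[5])
                qlen = int(parts[6])
                bits = float(parts[7])
                hit = SearchHit(
                    query_id=qid,
                    target_id=tid,
                    percent_identity=fident * 100.0,
                    query_coverage=(qend - qstart + 1) / qlen,
                    bitscore=bits,
                    alignment_length=alnlen,
                    query_start=qstart,
                    query_end=qend,
                    query_length=qlen,
                )
            except (ValueError, ZeroDivisionError) as exc:
                raise ValueError(f"line {lineno}: malformed row ({exc})") from exc
            out.setdefault(qid, []).append(hit)
    for qid in out:
        out[qid].sort(key=_rank_key)
    return out
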