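"""Local (Smith-Waterman) alignment with affine gaps, shared by the
screening, deduplication and probe-collapsing steps.

One scoring convention is used across the toolkit: match +1, mismatch -1,
gap open -2, gap extend -1 (a gap of length k costs 2 + (k - 1)).
Identity is counted over alignment columns, gaps scoring as non-matches.
Comparison is case-insensitive; ``N`` (and any other ambiguity code)
never counts as a match.

The traceback is fully deterministic: the best cell is the maximal-score
cell with the smallest (row, column); within a cell the preference order
is diagonal, then vertical gap, then horizontal gap. This convention is
part of the public contract so that independent re-implementations can
reproduce alignments exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

GAP_OPEN = 2.0
GAP_EXTEND = 1.0
MATCH = 1.0
MISMATCH = -1.0

_COMPLEMENT = str.maketrans("ACGTUacgtuNnRYSWKMrynswkm-", "TGCAAtgcaaNnYRSWMKyrnswmk-")

# traceback codes for the H matrix
_STOP, _DIAG, _UP, _LEFT = 0, 1, 2, 3


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def _encode(seq: str) -> np.ndarray:
    """Map residues to small integers; anything outside ACGT maps to a
    code that never matches (including against itself)."""
    table = np.full(256, 4, dtype=np.int8)
    for i, base in enumerate("ACGT"):
        table[ord(base)] = i
        table[ord(base.lower())] = i
    return table[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@njit(cache=True)
def _sw_kernel(a, b):  # pragma: no cover - exercised via sw_align
    n, m = a.shape[0], b.shape[0]
    H = np.zeros((n + 1, m + 1), dtype=np.float64)
    E = np.full((n + 1, m + 1), -1e18, dtype=np.float64)  # gap in a (left)
    F = np.full((n + 1, m + 1), -1e18, dtype=np.float64)  # gap in b (up)
    ptr = np.zeros((n + 1, m + 1), dtype=np.uint8)
    e_open = np.zeros((n + 1, m + 1), dtype=np.uint8)  # 1 = opened here
    f_open = np.zeros((n + 1, m + 1), dtype=np.uint8)
    best = 0.0
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            eo = H[i, j - 1] - GAP_OPEN
            ee = E[i, j - 1] - GAP_EXTEND
            if eo >= ee:
                E[i, j] = eo
                e_open[i, j] = 1
            else:
                E[i, j] = ee
            fo = H[i - 1, j] - GAP_OPEN
            fe = F[i - 1, j] - GAP_EXTEND
            if fo >= fe:
                F[i, j] = fo
                f_open[i, j] = 1
            else:
                F[i, j] = fe
            if a[i - 1] == b[j - 1] and a[i - 1] != 4:
                s = MATCH
            else:
                s = MISMATCH
            diag = H[i - 1, j - 1] + s
            h = 0.0
            p = _STOP
            if diag > 0.0:
                h = diag
                p = _DIAG
            if F[i, j] > h:
                h = F[i, j]
                p = _UP
            if E[i, j] > h:
                h = E[i, j]
                p = _LEFT
            H[i, j] = h
            ptr[i, j] = p
            if h > best:
                best = h
                bi = i
                bj = j
    return best, bi, bj, ptr, e_open, f_open


@njit(cache=True)
def _traceback(a, b, bi, bj, ptr, e_open, f_open):  # pragma: no cover
    i, j = bi, bj
    ncols = 0
    nmatch = 0
    state = 0  # 0 = H, 1 = E (left), 2 = F (up)
    while i > 0 and j > 0:
        if state == 0:
            p = ptr[i, j]
            if p == _STOP:
                break
            if p == _DIAG:
                ncols += 1
                if a[i - 1] == b[j - 1] and a[i - 1] != 4:
                    nmatch += 1
                i -= 1
                j -= 1
            elif p == _UP:
                state = 2
            else:
                state = 1
        elif state == 1:
            ncols += 1
            if e_open[i, j] == 1:
                state = 0
            j -= 1
        else:
            ncols += 1
            if f_open[i, j] == 1:
                state = 0
            i -= 1
    return i, j, ncols, nmatch


@dataclass(frozen=True)
class LocalAlignment:
    """Best local alignment between a query and a reference."""

    score: float
    query_start: int
    query_end: int  # half-open
    ref_start: int
    ref_end: int
    n_columns: int
    n_matches: int
    strand: str = "+"

    @property
    def identity(self) -> float:
        """Matches over alignment columns; 0 for an empty alignment."""
        if self.n_columns == 0:
            return 0.0
        return self.n_matches / self.n_columns


def sw_align(query: str, ref: str) -> LocalAlignment:
    """Best-scoring local alignment of ``query`` against ``ref`` (forward
    strand only) under the toolkit's scoring convention."""
    if not query or not ref:
        return LocalAlignment(0.0, 0, 0, 0, 0, 0, 0)
    a = _encode(query)
    b = _encode(ref)
    score, bi, bj, ptr, e_open, f_open = _sw_kernel(a, b)
    if score <= 0.0:
        return LocalAlignment(0.0, 0, 0, 0, 0, 0, 0)
    i0, j0, ncols, nmatch = _traceback(a, b, bi, bj, ptr, e_open, f_open)
    return LocalAlignment(score, i0, bi, j0, bj, ncols, nmatch)


def sw_align_both_strands(query: str, ref: str) -> LocalAlignment:
    """Best local alignment over both query strands.

    Ties in score prefer the forward strand. Minus-strand query
    coordinates are mapped back to the forward orientation.
    """
    fwd = sw_align(query, ref)
    rev = sw_align(revcomp(query), ref)
    if rev.score > fwd.score:
        L = len(query)
        return LocalAlignment(
            rev.score,
            L - rev.query_end,
            L - rev.query_start,
            rev.ref_start,
            rev.ref_end,
            rev.n_columns,
            rev.n_matches,
            strand="-",
        )
    return fwd


def meets_similarity(
    aln: LocalAlignment, min_identity: float, min_overlap_bp: int
) -> bool:
    """Does the alignment satisfy an identity/overlap criterion?"""
    return aln.n_columns >= min_overlap_bp and aln.identity >= min_identity


# High-identity criteria force a long exact match run: an alignment with
# identity >= 0.98 over >= 80 columns contains an exact run of >= 26
# matching bases (>= 99% over >= 100 columns forces >= 49), so a k-mer
# prefilter with k <= 26 is lossless for those checks.
PREFILTER_K = 20


def shared_kmer(a: str, b: str, k: int = PREFILTER_K) -> bool:
    """True if the two sequences share any exact k-mer on either strand."""
    au = a.upper()
    if len(au) < k or len(b) < k:
        return False
    kmers = {au[i : i + k] for i in range(len(au) - k + 1)}
    for probe in (b.upper(), revcomp(b).upper()):
        for i in range(len(probe) - k + 1):
            if probe[i : i + k] in kmers:
                return True
    return False


def _canonical_kmers(seq: str, k: int):
    su = seq.upper()
    rc = revcomp(su)
    n = len(su)
    for i in range(n - k + 1):
        f = su[i : i + k]
        r = rc[n - k - i : n - i]
        yield f if f <= r else r


def kmer_candidate_pairs(seqs: list[str], k: int = PREFILTER_K) -> set[tuple[int, int]]:
    """Index-based prefilter: pairs of sequences sharing a canonical
    (strand-independent) k-mer.

    Every pair that shares an exact k-mer on either strand is returned;
    spurious extra pairs (palindromic collisions) are harmless because
    the full alignment still decides.
    """
    index: dict[str, list[int]] = {}
    for idx, seq in enumerate(seqs):
        for kmer in set(_canonical_kmers(seq, k)):
            index.setdefault(kmer, []).append(idx)
    pairs: set[tuple[int, int]] = set()
    for members in index.values():
        if len(members) < 2:
            continue
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                pairs.add((members[i], members[j]))
    return pairs
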