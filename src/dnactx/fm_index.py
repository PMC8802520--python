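"""Burrows-Wheeler k-mer counting with a two-level checkpointed FM-index.

The index holds the concatenation of all genome records and (by default)
their reverse complements, each followed by a terminator. Occurrences of a
pattern are counted by the standard backward search; the size of the
resulting suffix interval is the occurrence count on both strands. Rank
queries use coarse absolute checkpoints (int64, default stride 65536) plus
fine relative checkpoints (uint16, default stride 256) and a short scan of
the BWT tail — the layout used by genome-scale indexes, here with
configurable strides.

Symbol order: terminator < A < C < G < T < N, so N-containing text never
matches an ACGT pattern and patterns containing N count 0 by definition.
"""

from __future__ import annotations

import numpy as np

from ._kmers import encode, revcomp_codes
from .sequence_io import Genome, reverse_complement

TERM = 0  # collapsed terminator symbol in the stored BWT
_NSYM = 6  # $, A, C, G, T, N


def suffix_array(sym: np.ndarray) -> np.ndarray:
    """Suffix array by prefix doubling (numpy lexsort)."""
    n = len(sym)
    rank = np.asarray(sym, dtype=np.int64)
    k = 1
    order = np.argsort(rank, kind="stable")
    while True:
        key2 = np.full(n, -1, np.int64)
        if k < n:
            key2[: n - k] = rank[k:]
        order = np.lexsort((key2, rank))
        r_ord, k_ord = rank[order], key2[order]
        changed = np.empty(n, bool)
        changed[0] = True
        changed[1:] = (r_ord[1:] != r_ord[:-1]) | (k_ord[1:] != k_ord[:-1])
        rank = np.empty(n, np.int64)
        rank[order] = np.cumsum(changed) - 1
        if rank[order[-1]] == n - 1:
            return order
        k *= 2


class SuffixInterval:
    """Half-open interval [lo, hi) into the suffix order."""

    __slots__ = ("lo", "hi")

    def __init__(self, lo: int, hi: int):
        self.lo, self.hi = lo, hi

    @property
    def count(self) -> int:
        return self.hi - self.lo

    def __repr__(self):
        return f"SuffixInterval({self.lo}, {self.hi})"


class FMIndex:
    def __init__(self, genome: Genome, include_revcomp: bool = True,
                 coarse_stride: int = 65536, fine_stride: int = 256):
        if coarse_stride % fine_stride or fine_stride < 1:
            raise ValueError("coarse stride must be a multiple of fine stride")
        if genome.total_length == 0:
            raise ValueError("empty genome")
        self.include_revcomp = include_revcomp
        self.coarse_stride = coarse_stride
        self.fine_stride = fine_stride

        # Build the symbol text; terminators get distinct, position-ordered
        # symbols during sorting so the suffix order (and hence the BWT) is
        # fully determined, then collapse to one terminator symbol.
        chunks = []
        for name in genome.names:
            chunks.append(genome.codes(name))
        if include_revcomp:
            for name in genome.names:
                chunks.append(revcomp_codes(genome.codes(name)))
        nterm = len(chunks)
        parts = []
        for i, c in enumerate(chunks):
            parts.append(c.astype(np.int64) + nterm)  # bases shifted past terminators
            parts.append(np.array([i], np.int64))
        sym = np.concatenate(parts)
        self._n = len(sym)
        sa = suffix_array(sym)
        bwt_distinct = sym[(sa - 1) % self._n]
        self._term_ids = bwt_distinct[bwt_distinct < nterm].astype(np.int64)
        self.bwt = np.where(bwt_distinct < nterm, TERM,
                            bwt_distinct - nterm + 1).astype(np.uint8)
        self._nterm = nterm

        counts = np.bincount(self.bwt, minlength=_NSYM)
        self.first_occurrence = np.concatenate(([0], np.cumsum(counts)))

        # Two-level rank checkpoints over the collapsed BWT.
        onehot = self.bwt[None, :] == np.arange(_NSYM, dtype=np.uint8)[:, None]
        occ = np.cumsum(onehot, axis=1, dtype=np.int64)
        occ = np.concatenate((np.zeros((_NSYM, 1), np.int64), occ), axis=1)
        self._coarse = occ[:, ::coarse_stride].copy()
        fine_pos = np.arange(0, self._n + 1, fine_stride)
        anchor = self._coarse[:, fine_pos // coarse_stride]
        delta = occ[:, fine_pos] - anchor
        if delta.max(initial=0) >= 2 ** 16:
            raise AssertionError("fine checkpoint overflow")
        self._fine = delta.astype(np.uint16)

    def __len__(self) -> int:
        return self._n

    def rank(self, symbol: int, i: int) -> int:
        """Occurrences of symbol in bwt[:i], via the checkpoints."""
        fs, cs = self.fine_stride, self.coarse_stride
        block = i // fs
        p0 = block * fs
        r = int(self._coarse[symbol, p0 // cs]) + int(self._fine[symbol, block])
        if i > p0:
            r += int(np.count_nonzero(self.bwt[p0:i] == symbol))
        return r

    def rank_scan(self, symbol: int, i: int) -> int:
        """Rank by direct scan (checkpoint-structure oracle)."""
        return int(np.count_nonzero(self.bwt[:i] == symbol))

    def backward_search(self, pattern: str) -> SuffixInterval:
        """Suffix interval of pattern; empty pattern covers the whole range."""
        codes = encode(pattern.upper())
        if np.any(codes >= 4):  # N never matches indexed ACGT text
            return SuffixInterval(0, 0)
        lo, hi = 0, self._n
        for c in codes[::-1]:
            s = int(c) + 1
            lo = int(self.first_occurrence[s]) + self.rank(s, lo)
            hi = int(self.first_occurrence[s]) + self.rank(s, hi)
            if lo >= hi:
                return SuffixInterval(lo, lo)
        return SuffixInterval(lo, hi)

    def count(self, pattern: str) -> int:
        return self.backward_search(pattern).count

    def reconstruct(self) -> str:
        """Invert the BWT by LF-mapping, recovering the indexed text.

        Terminators are disambiguated by their recorded text order, making
        the inversion exact; used as a construction self-check.
        """
        # rank among terminator occurrences -> distinct id
        term_pos = np.flatnonzero(self.bwt == TERM)
        id_of_termrank = {r: int(t) for r, t in enumerate(self._term_ids)}
        out = np.empty(self._n, np.uint8)
        # start from the suffix that is the whole text: its BWT char is the
        # final terminator (id nterm-1); walk backwards with LF.
        # Row 0 of the suffix order is the first terminator's suffix; instead
        # locate the row whose BWT char is terminator id nterm-1.
        want = self._nterm - 1
        row = None
        for r, t in enumerate(self._term_ids):
            if t == want:
                row = int(term_pos[r])
                break
        assert row is not None
        for i in range(self._n - 1, -1, -1):
            c = int(self.bwt[row])
            out[i] = c
            if c == TERM:
                trank = int(np.searchsorted(term_pos, row))
                tid = id_of_termrank[trank]
                # terminator symbols sort by text order: row of $_tid is tid
                row = tid
            else:
                row = int(self.first_occurrence[c]) + self.rank(c, row)
        sym = "$ACGTN"
        return "".join(sym[c] for c in out)


    _SAVE_VERSION = 1

    def save(self, path) -> None:
        """Serialize to an .npz container with a version field."""
        np.savez_compressed(
            path, version=self._SAVE_VERSION,
            bwt=self.bwt, term_ids=self._term_ids, nterm=self._nterm,
            coarse=self._coarse, fine=self._fine,
            first_occurrence=self.first_occurrence,
            strides=np.array([self.coarse_stride, self.fine_stride]),
            include_revcomp=np.array(self.include_revcomp))

    @classmethod
    def load(cls, path) -> "FMIndex":
        with np.load(path) as data:
            if int(data["version"]) != cls._SAVE_VERSION:
                raise ValueError("unsupported index file version")
            obj = cls.__new__(cls)
            obj.bwt = data["bwt"]
            obj._term_ids = data["term_ids"]
            obj._nterm = int(data["nterm"])
            obj._coarse = data["coarse"]
            obj._fine = data["fine"]
            obj.first_occurrence = data["first_occurrence"]
            obj.coarse_stride, obj.fine_stride = (int(x) for x in data["strides"])
            obj.include_revcomp = bool(data["include_revcomp"])
            obj._n = len(obj.bwt)
        return obj


def build_index(genome: Genome, include_revcomp: bool = True,
                coarse_stride: int = 65536, fine_stride: int = 256) -> FMIndex:
    return FMIndex(genome, include_revcomp, coarse_stride, fine_stride)


def naive_count(genome: Genome, pattern: str, include_revcomp: bool = True) -> int:
    """Exact occurrence count by sliding-window scan (overlaps counted)."""
    pattern = pattern.upper()
    m = len(pattern)
    total = 0
    for name in genome.names:
        seqs = [genome.sequence(name)]
        if include_revcomp:
            seqs.append(reverse_complement(seqs[0]))
        for seq in seqs:
            if m == 0:
                continue
            start = 0
            while True:
                i = seq.find(pattern, start)
                if i < 0:
                    break
                total += 1
                start = i + 1
    return total
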