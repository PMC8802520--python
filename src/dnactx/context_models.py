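"""Interpolated context models of nucleotide probabilities.

Two kinds of model share one estimation machinery:

* ``central`` — the probability of a base given k flanking bases on each
  side, estimated from strand-symmetrized (2k+1)-mer counts.
* ``markov`` — a 5' Markov model of order k (base conditioned on the k
  preceding bases), estimated from both strands; the bidirectional
  probability averages the forward prediction with the same model's
  prediction of the complementary base on the reverse strand.

Counts of order k are regularized by pseudo-counts gamma * P(b | s(k-1)),
applied recursively down to an unregularized base order k_min. With
leave-one-out estimation the query site's own contribution to the count
table is subtracted before normalization: the forward-strand occurrence
always, and the reverse-strand occurrence when it falls in the same count
row (for the central model that happens exactly when the context is its own
reverse complement).

Counts can come from precomputed tables (fast, vectorized) or from an
FM-index queried by backward search; both give identical probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from ._kmers import (BASES, int_to_kmer, kmer_to_int, revcomp_codes,
                     revcomp_int, window_codes, encode)
from .fm_index import FMIndex
from .sequence_io import Genome

__all__ = [
    "ContextSpec", "ContextCounts", "FMIndexCounter",
    "InterpolatedContextModel", "UndefinedDistributionError",
    "central_context", "fit", "free_parameters",
]


class UndefinedDistributionError(ValueError):
    """Raised when gamma=0 leaves a zero denominator for some context."""


@dataclass(frozen=True)
class ContextSpec:
    """Model family and interpolation range.

    kind   : "central" (k = half-width of the symmetric context) or
             "markov" (k = order, i.e. number of preceding bases)
    k      : highest (final) order
    k_min  : unregularized base order of the interpolation
    gamma  : pseudo-count strength (0 disables interpolation)
    """

    kind: str
    k: int
    k_min: int
    gamma: float = 100.0

    def __post_init__(self):
        if self.kind not in ("central", "markov"):
            raise ValueError(f"unknown model kind: {self.kind}")
        if not (0 <= self.k_min <= self.k):
            raise ValueError("need 0 <= k_min <= k")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")

    @classmethod
    def central_default(cls) -> "ContextSpec":
        """k=7 interpolated from k=4, gamma=100."""
        return cls("central", 7, 4, 100.0)

    @classmethod
    def markov_default(cls) -> "ContextSpec":
        """BM14: order 14 interpolated from 8, gamma=100."""
        return cls("markov", 14, 8, 100.0)

    def context_width(self, order: int) -> int:
        return 2 * order if self.kind == "central" else order


def free_parameters(spec: ContextSpec) -> int:
    """Free parameters at the top order: 3 per distinct context."""
    return 3 * 4 ** spec.context_width(spec.k)


def central_context(genome: Genome, chrom: str, pos: int, k: int
                    ) -> tuple[str, str] | None:
    """The (left, right) k-base flanks of a site, or None.

    None when the window crosses a record boundary or contains N.
    """
    codes = genome.codes(chrom)
    if pos - k < 0 or pos + k + 1 > len(codes):
        return None
    window = codes[pos - k : pos + k + 1]
    if np.any(window == 4):
        return None
    from ._kmers import decode
    return decode(window[:k]), decode(window[k + 1 :])


def _order_keys(codes: np.ndarray, kind: str, order: int
                ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(ctx_code, base, valid) for every window of one strand at one order."""
    if kind == "central":
        m = 2 * order + 1
        w, valid = window_codes(codes, m)
        base = (w // 4 ** order) % 4
        ctx = (w // 4 ** (order + 1)) * 4 ** order + (w % 4 ** order)
    else:
        m = order + 1
        w, valid = window_codes(codes, m)
        base = w % 4
        ctx = w // 4
    return ctx, base, valid


class ContextCounts:
    """Strand-symmetrized n(b|s) tables for orders k_min..k.

    Per order, contexts are stored as sorted packed codes with a (u, 4)
    count matrix; unseen contexts read as zero rows. Counting both strands
    makes n(b|s) = n(complement(b)|revcomp(s)) hold by construction.
    """

    backend = "table"

    def __init__(self, spec: ContextSpec, genome: Genome,
                 exclude_records: Sequence[str] = ()):
        self.spec = spec
        self._tables: dict[int, tuple[np.ndarray, np.ndarray]] = {}
        names = [n for n in genome.names if n not in set(exclude_records)]
        if not names:
            raise ValueError("no records left after exclusions")
        for order in range(spec.k_min, spec.k + 1):
            keys = []
            for name in names:
                arr = genome.codes(name)
                for strand in (arr, revcomp_codes(arr)):
                    ctx, base, valid = _order_keys(strand, spec.kind, order)
                    keys.append(ctx[valid] * 4 + base[valid])
            allk = np.concatenate(keys) if keys else np.zeros(0, np.int64)
            uk, cnt = np.unique(allk, return_counts=True)
            uctx, inv = np.unique(uk // 4, return_inverse=True)
            mat = np.zeros((len(uctx), 4), np.int64)
            mat[inv, uk % 4] = cnt
            self._tables[order] = (uctx, mat)

    def rows(self, order: int, ctx_codes: np.ndarray) -> np.ndarray:
        """(len(ctx_codes), 4) count rows; zeros for unseen contexts."""
        uctx, mat = self._tables[order]
        out = np.zeros((len(ctx_codes), 4), np.int64)
        if len(uctx) == 0:
            return out
        idx = np.searchsorted(uctx, ctx_codes)
        idx_c = np.clip(idx, 0, len(uctx) - 1)
        hit = uctx[idx_c] == ctx_codes
        out[hit] = mat[idx_c[hit]]
        return out

    def counts4(self, order: int, ctx_code: int) -> np.ndarray:
        return self.rows(order, np.array([ctx_code], np.int64))[0]

    # string-keyed conveniences for tests and small-scale inspection
    def n(self, context: str, base: str) -> int:
        order_width = len(context)
        order = order_width // 2 if self.spec.kind == "central" else order_width
        code = kmer_to_int(encode(context))
        return int(self.counts4(order, code)[BASES.index(base)])

    def N(self, context: str) -> int:
        order_width = len(context)
        order = order_width // 2 if self.spec.kind == "central" else order_width
        code = kmer_to_int(encode(context))
        return int(self.counts4(order, code).sum())


class FMIndexCounter:
    """Count backend answering n(b|s) by FM-index backward search."""

    backend = "fm_index"

    def __init__(self, spec: ContextSpec, genome: Genome,
                 exclude_records: Sequence[str] = (),
                 coarse_stride: int = 65536, fine_stride: int = 256):
        self.spec = spec
        names = [n for n in genome.names if n not in set(exclude_records)]
        if not names:
            raise ValueError("no records left after exclusions")
        self.index = FMIndex(genome.subset(names), include_revcomp=True,
                             coarse_stride=coarse_stride,
                             fine_stride=fine_stride)
        self._cache: dict[tuple[int, int], np.ndarray] = {}

    def counts4(self, order: int, ctx_code: int) -> np.ndarray:
        key = (order, int(ctx_code))
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        if self.spec.kind == "central":
            ctx = int_to_kmer(ctx_code, 2 * order)
            left, right = ctx[:order], ctx[order:]
            out = np.array([self.index.count(left + b + right) for b in BASES],
                           np.int64)
        else:
            ctx = int_to_kmer(ctx_code, order)
            out = np.array([self.index.count(ctx + b) for b in BASES], np.int64)
        self._cache[key] = out
        return out

    def rows(self, order: int, ctx_codes: np.ndarray) -> np.ndarray:
        uniq, inv = np.unique(ctx_codes, return_inverse=True)
        urows = np.stack([self.counts4(order, c) for c in uniq]) \
            if len(uniq) else np.zeros((0, 4), np.int64)
        return urows[inv] if len(uniq) else np.zeros((0, 4), np.int64)


class InterpolatedContextModel:
    """A fitted context model: spec + count backend."""

    def __init__(self, spec: ContextSpec, counter):
        self.spec = spec
        self.counter = counter

    # ---------------- vectorized evaluation ----------------

    def _forward_eval(self, codes: np.ndarray, leave_one_out: bool
                      ) -> tuple[np.ndarray, np.ndarray]:
        """Forward-strand probabilities for one sequence of codes.

        Returns (valid mask, P) of shapes (n,) and (n, 4); invalid
        positions hold NaN. For kind=central a site is valid when the full
        order-k window is inside the sequence and N-free; for kind=markov
        when the k-base left flank is N-free and the base itself is not N.
        """
        spec, g = self.spec, self.spec.gamma
        n = len(codes)
        valid = np.zeros(n, bool)
        P = np.full((n, 4), np.nan)
        k = spec.k
        if spec.kind == "central":
            w, wvalid = window_codes(codes, 2 * k + 1)
            pos = np.arange(k, n - k)
            ok = wvalid if len(pos) == len(wvalid) else wvalid[: len(pos)]
            sites = pos[ok]
        else:
            lw, lvalid = window_codes(codes, k) if k else (np.zeros(n + 1, np.int64), np.ones(n + 1, bool))
            pos = np.arange(k, n)
            sites = pos[lvalid[: n - k] & (codes[k:] != 4)] if n > k else np.zeros(0, int)
        if len(sites) == 0:
            return valid, P
        x = codes[sites].astype(np.int64)

        prob = None
        for order in range(spec.k_min, spec.k + 1):
            ctx = self._ctx_codes(codes, sites, order)
            rows = self.counter.rows(order, ctx).astype(np.float64)
            if leave_one_out:
                sub = np.zeros_like(rows)
                sub[np.arange(len(sites)), x] = 1.0
                mirror = self._mirror_mask(codes, sites, ctx, order)
                sub[mirror, 3 - x[mirror]] += 1.0
                rows = rows - sub
            tot = rows.sum(axis=1)
            if order == spec.k_min:
                zero = tot <= 0
                if np.any(zero):
                    if g == 0:
                        bad = int(np.flatnonzero(zero)[0])
                        raise UndefinedDistributionError(
                            "zero counts with gamma=0 for context "
                            f"{int_to_kmer(int(ctx[bad]), spec.context_width(order))!r}")
                    prob = np.where(zero[:, None], 0.25, rows / np.where(zero, 1.0, tot)[:, None])
                else:
                    prob = rows / tot[:, None]
            else:
                if g == 0:
                    zero = tot <= 0
                    if np.any(zero):
                        bad = int(np.flatnonzero(zero)[0])
                        raise UndefinedDistributionError(
                            "zero counts with gamma=0 for context "
                            f"{int_to_kmer(int(ctx[bad]), spec.context_width(order))!r}")
                    prob = rows / tot[:, None]
                else:
                    prob = (rows + g * prob) / (tot + g)[:, None]
        valid[sites] = True
        P[sites] = prob
        return valid, P

    def _ctx_codes(self, codes: np.ndarray, sites: np.ndarray, order: int
                   ) -> np.ndarray:
        """Packed context codes at the given sites (windows known N-free)."""
        x = np.where(codes == 4, 0, codes).astype(np.int64)
        if self.spec.kind == "central":
            ctx = np.zeros(len(sites), np.int64)
            for j in range(order, 0, -1):          # left flank, 5'->3'
                ctx = ctx * 4 + x[sites - j]
            for j in range(1, order + 1):          # right flank
                ctx = ctx * 4 + x[sites + j]
        else:
            ctx = np.zeros(len(sites), np.int64)
            for j in range(order, 0, -1):
                ctx = ctx * 4 + x[sites - j]
        return ctx

    def _mirror_mask(self, codes: np.ndarray, sites: np.ndarray,
                     ctx: np.ndarray, order: int) -> np.ndarray:
        """Sites whose reverse-strand reading falls in the same count row."""
        if self.spec.kind == "central":
            return revcomp_int(ctx, 2 * order) == ctx
        n = len(codes)
        right = np.zeros(len(sites), np.int64)
        rvalid = sites + order < n
        x = np.where(codes == 4, 0, codes).astype(np.int64)
        for j in range(1, order + 1):
            idx = np.minimum(sites + j, n - 1)
            right = right * 4 + x[idx]
            rvalid &= (sites + j < n) & (codes[np.minimum(sites + j, n - 1)] != 4)
        return rvalid & (revcomp_int(right, order) == ctx)

    def evaluate_record(self, genome: Genome, chrom: str,
                        leave_one_out: bool = False
                        ) -> tuple[np.ndarray, np.ndarray]:
        """Per-site distributions for a whole record.

        Returns (positions, P) where P has one normalized row per evaluable
        position. Central models return the central probability; Markov
        models return the bidirectional average.
        """
        codes = genome.codes(chrom)
        vf, Pf = self._forward_eval(codes, leave_one_out)
        if self.spec.kind == "central":
            sites = np.flatnonzero(vf)
            return sites, Pf[sites]
        vr, Pr = self._forward_eval(revcomp_codes(codes), leave_one_out)
        vr = vr[::-1]
        Pr = Pr[::-1, ::-1]          # map position and complement bases
        valid = vf & vr
        sites = np.flatnonzero(valid)
        return sites, 0.5 * (Pf[sites] + Pr[sites])

    # ---------------- single-site evaluation ----------------

    def _scalar_forward(self, codes: np.ndarray, pos: int,
                        leave_one_out: bool) -> np.ndarray | None:
        valid, P = self._forward_eval(codes, leave_one_out)
        return P[pos] if valid[pos] else None

    def probability(self, genome: Genome, chrom: str, pos: int,
                    leave_one_out: bool = False) -> np.ndarray | None:
        """Base distribution (A,C,G,T order) at one site, or None.

        For kind=markov this is the forward (5') probability; use
        :meth:`bidirectional_probability` for the strand-averaged one.
        """
        codes = genome.codes(chrom)
        k = self.spec.k
        lo = max(0, pos - k - 1)
        hi = min(len(codes), pos + k + 2)
        return self._scalar_forward(codes[lo:hi], pos - lo, leave_one_out)

    def bidirectional_probability(self, genome: Genome, chrom: str, pos: int,
                                  leave_one_out: bool = False
                                  ) -> np.ndarray | None:
        """Average of forward and reverse-complement Markov predictions."""
        if self.spec.kind != "markov":
            raise ValueError("bidirectional probability requires a markov model")
        codes = genome.codes(chrom)
        k = self.spec.k
        if pos - k < 0 or pos + k + 1 > len(codes):
            return None
        window = codes[pos - k : pos + k + 1]
        if np.any(window == 4):
            return None
        fwd = self._scalar_forward(window, k, leave_one_out)
        rev = self._scalar_forward(revcomp_codes(window), k, leave_one_out)
        if fwd is None or rev is None:
            return None
        return 0.5 * (fwd + rev[::-1])


def fit(spec: ContextSpec, genome: Genome, backend: str = "table",
        exclude_records: Sequence[str] = ()) -> InterpolatedContextModel:
    """Fit a model by building its count backend over the genome.

    ``exclude_records`` drops whole records from the counts (the chromosome
    cross-validation mechanism); queries remain possible on any sequence.
    """
    if backend == "table":
        counter = ContextCounts(spec, genome, exclude_records)
    elif backend == "fm_index":
        counter = FMIndexCounter(spec, genome, exclude_records)
    else:
        raise ValueError(f"unknown backend: {backend}")
    return InterpolatedContextModel(spec, counter)
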