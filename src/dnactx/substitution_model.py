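"""Context-dependent substitution models: the simple model and the alpha matrix.

The simple model estimates the probability of a mutation a->b directly from
observed variants in a small symmetric context s_hat of half-width k_hat:
P_simple(a->b|s_hat) = n(a->b|s_hat) / n(a|s_hat), with n(a|s_hat) counted
over the whole genome on both strands.

The factorized model writes per-site mutability as
mu_ab|s = alpha_ab|s_hat * P(b|s), where P(b|s) comes from a genome context
model with a (much) larger context s, and the alpha matrix is estimated as
alpha = P_simple / Z with the normalizer
Z_ab|s_hat = mean of P(b|s_i) over all sites i with reference a and small
context s_hat. The total mutability of a site uses the first-order rate
approximation with the exponential diagonal correction,
1 - exp(-sum_b mu_ab).

All counts and Z sums are strand-symmetrized: every variant and every
genome site also contributes its reverse-complement reading.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._kmers import BASES, encode, int_to_kmer, kmer_to_int, revcomp_int, window_codes
from .context_models import ContextSpec, ContextCounts, InterpolatedContextModel
from .sequence_io import Genome, VariantRecord

logger = logging.getLogger(__name__)

__all__ = [
    "SimpleSubModel", "ZTable", "AlphaMatrix",
    "fit_simple", "compute_z", "fit_alpha",
    "mutability_track", "site_mutability",
    "calibration_curve", "cumulative_mutability",
    "write_alpha_tsv", "read_alpha_tsv",
]

_B = np.arange(4)


def _central_ctx_arrays(codes: np.ndarray, k_hat: int
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Per-position small-context codes; -1 where undefined.

    Returns (ctx, ok): ctx[i] is the packed 2*k_hat-mer around position i,
    ok[i] False when the window leaves the record or contains N (the base
    itself included).
    """
    n = len(codes)
    ctx = np.full(n, -1, np.int64)
    ok = np.zeros(n, bool)
    m = 2 * k_hat + 1
    w, valid = window_codes(codes, m)
    if len(w) == 0:
        return ctx, ok
    pos = np.arange(k_hat, n - k_hat)
    c = (w // 4 ** (k_hat + 1)) * 4 ** k_hat + (w % 4 ** k_hat)
    ctx[pos[valid]] = c[valid]
    ok[pos[valid]] = True
    return ctx, ok


@dataclass
class SimpleSubModel:
    """Direct variant-frequency substitution model on a small context."""

    k_hat: int
    contexts: np.ndarray          # sorted packed 2*k_hat-mer codes
    n_ref: np.ndarray             # (u, 4) genome counts n(a|s_hat)
    n_mut: np.ndarray             # (u, 4, 4) variant counts, zero diagonal

    @property
    def p_simple(self) -> np.ndarray:
        """(u, 4, 4) probabilities; NaN rows where n_ref is zero."""
        denom = self.n_ref.astype(float)[:, :, None]
        with np.errstate(invalid="ignore", divide="ignore"):
            p = self.n_mut / denom
        p[np.broadcast_to(denom == 0, p.shape)] = np.nan
        return p

    def _ctx_index(self, context: str) -> int:
        code = kmer_to_int(encode(context))
        i = int(np.searchsorted(self.contexts, code))
        if i >= len(self.contexts) or self.contexts[i] != code:
            raise KeyError(f"context {context!r} not in model")
        return i

    def p(self, context: str, a: str, b: str) -> float:
        i = self._ctx_index(context)
        return float(self.p_simple[i, BASES.index(a), BASES.index(b)])


@dataclass
class ZTable:
    """Mean genome-model probability of b over sites with ref a, context s_hat."""

    k_hat: int
    contexts: np.ndarray          # sorted packed codes
    z: np.ndarray                 # (u, 4, 4) means; NaN where no sites
    n_sites: np.ndarray           # (u, 4) reading counts behind each mean

    def value(self, context: str, a: str, b: str) -> float:
        code = kmer_to_int(encode(context))
        i = int(np.searchsorted(self.contexts, code))
        if i >= len(self.contexts) or self.contexts[i] != code:
            raise KeyError(f"context {context!r} not in table")
        return float(self.z[i, BASES.index(a), BASES.index(b)])


@dataclass
class AlphaMatrix:
    """Context-indexed off-diagonal multipliers alpha_ab|s_hat.

    Diagonal entries and entries with no usable estimate are NaN (absent);
    scoring treats absent entries as mu=0 with a logged warning.
    """

    k_hat: int
    contexts: np.ndarray
    alpha: np.ndarray             # (u, 4, 4); NaN = absent, diagonal NaN
    z: np.ndarray                 # (u, 4, 4) normalizers used
    n_mut: np.ndarray             # (u, 4, 4) variant counts
    n_ref: np.ndarray             # (u, 4) genome counts

    def _ctx_index(self, context: str) -> int:
        code = kmer_to_int(encode(context))
        i = int(np.searchsorted(self.contexts, code))
        if i >= len(self.contexts) or self.contexts[i] != code:
            raise KeyError(f"context {context!r} not in matrix")
        return i

    def value(self, context: str, a: str, b: str) -> float:
        i = self._ctx_index(context)
        return float(self.alpha[i, BASES.index(a), BASES.index(b)])

    def rows_for(self, ctx_codes: np.ndarray, a: np.ndarray
                 ) -> tuple[np.ndarray, int]:
        """(len, 4) alpha rows for (context, ref) pairs; absent -> 0.

        Second return value is the number of absent off-diagonal entries
        that were zero-filled.
        """
        idx = np.searchsorted(self.contexts, ctx_codes)
        idx_c = np.clip(idx, 0, max(len(self.contexts) - 1, 0))
        hit = np.zeros(len(ctx_codes), bool)
        if len(self.contexts):
            hit = self.contexts[idx_c] == ctx_codes
        rows = np.full((len(ctx_codes), 4), np.nan)
        rows[hit] = self.alpha[idx_c[hit], a[hit], :]
        offdiag = np.ones_like(rows, bool)
        offdiag[np.arange(len(a)), a] = False
        n_absent = int(np.count_nonzero(np.isnan(rows) & offdiag))
        rows = np.nan_to_num(rows, nan=0.0)
        return rows, n_absent


def fit_simple(variants: Iterable[VariantRecord], genome: Genome,
               k_hat: int) -> SimpleSubModel:
    """Estimate the simple model from variants and whole-genome counts.

    Each variant is counted twice: as a->b in its context and as
    complement(a)->complement(b) in the reverse-complement context. Variants
    whose context window is undefined (N or record edge) are skipped.
    """
    counts = ContextCounts(ContextSpec("central", k_hat, k_hat, 0.0), genome)
    contexts, n_ref = counts._tables[k_hat]
    n_mut = np.zeros((len(contexts), 4, 4), np.int64)
    n_skipped = 0
    for v in variants:
        codes = genome.codes(v.chrom)
        pos = v.pos
        if pos - k_hat < 0 or pos + k_hat + 1 > len(codes):
            n_skipped += 1
            continue
        window = codes[pos - k_hat : pos + k_hat + 1]
        if np.any(window == 4):
            n_skipped += 1
            continue
        a, b = BASES.index(v.ref), BASES.index(v.alt)
        if int(window[k_hat]) != a:
            raise ValueError(
                f"variant REF {v.ref} disagrees with genome at {v.chrom}:{v.pos}")
        ctx = 0
        for c in window[:k_hat]:
            ctx = ctx * 4 + int(c)
        for c in window[k_hat + 1 :]:
            ctx = ctx * 4 + int(c)
        for cc, aa, bb in ((ctx, a, b),
                           (revcomp_int(ctx, 2 * k_hat), 3 - a, 3 - b)):
            i = int(np.searchsorted(contexts, cc))
            if i >= len(contexts) or contexts[i] != cc:
                raise ValueError(
                    f"variant context {int_to_kmer(cc, 2 * k_hat)!r} has "
                    "no genome occurrences (inconsistent inputs)")
            n_mut[i, aa, bb] += 1
    if n_skipped:
        logger.warning("fit_simple: %d variants skipped (N or record edge)",
                       n_skipped)
    bad = (n_ref == 0) & (n_mut.sum(axis=2) > 0)
    if np.any(bad):
        raise ValueError("mutation counts in a context with zero genome count")
    return SimpleSubModel(k_hat, contexts, n_ref, n_mut)


def compute_z(genome_model: InterpolatedContextModel, genome: Genome,
              k_hat: int, leave_one_out: bool = False) -> ZTable:
    """Mean model probability of each base, stratified by (s_hat, ref).

    Sites the genome model skips, and sites whose small context is
    undefined, are excluded from both the sums and the denominators. Both
    strand readings of every site contribute.
    """
    sums: dict[int, np.ndarray] = {}
    key_list = []
    p_list = []
    for name in genome.names:
        codes = genome.codes(name)
        sites, P = genome_model.evaluate_record(genome, name, leave_one_out)
        if len(sites) == 0:
            continue
        ctx, ok = _central_ctx_arrays(codes, k_hat)
        keep = ok[sites]
        s = sites[keep]
        P = P[keep]
        c = ctx[s]
        a = codes[s].astype(np.int64)
        key_list.append(c * 4 + a)
        p_list.append(P)
        key_list.append(revcomp_int(c, 2 * k_hat) * 4 + (3 - a))
        p_list.append(P[:, ::-1])
    if not key_list:
        raise ValueError("no scorable sites")
    keys = np.concatenate(key_list)
    probs = np.concatenate(p_list, axis=0)
    uk, inv = np.unique(keys, return_inverse=True)
    sum_mat = np.zeros((len(uk), 4))
    np.add.at(sum_mat, inv, probs)
    cnt = np.bincount(inv, minlength=len(uk))
    contexts = np.unique(uk // 4)
    z = np.full((len(contexts), 4, 4), np.nan)
    n_sites = np.zeros((len(contexts), 4), np.int64)
    ci = np.searchsorted(contexts, uk // 4)
    ai = uk % 4
    z[ci, ai, :] = sum_mat / cnt[:, None]
    n_sites[ci, ai] = cnt
    return ZTable(k_hat, contexts, z, n_sites)


def fit_alpha(simple: SimpleSubModel, ztab: ZTable) -> AlphaMatrix:
    """alpha = P_simple / Z, entry-wise, where both are defined and Z > 0."""
    if simple.k_hat != ztab.k_hat:
        raise ValueError("simple model and Z table use different k_hat")
    contexts = simple.contexts
    u = len(contexts)
    z = np.full((u, 4, 4), np.nan)
    idx = np.searchsorted(ztab.contexts, contexts)
    idx_c = np.clip(idx, 0, max(len(ztab.contexts) - 1, 0))
    hit = np.zeros(u, bool)
    if len(ztab.contexts):
        hit = ztab.contexts[idx_c] == contexts
    z[hit] = ztab.z[idx_c[hit]]
    p = simple.p_simple
    with np.errstate(invalid="ignore", divide="ignore"):
        alpha = p / z
    alpha[~(z > 0)] = np.nan
    alpha[:, _B, _B] = np.nan
    return AlphaMatrix(simple.k_hat, contexts, alpha, z,
                       simple.n_mut, simple.n_ref)


def mutability_track(alpha: AlphaMatrix, genome_model: InterpolatedContextModel,
                     genome: Genome, leave_one_out: bool = False
                     ) -> pd.DataFrame:
    """Per-site mutabilities mu_ab = alpha_ab|s_hat * P(b|s).

    Columns: chrom, pos, ref, muA..muT (mu toward each base, 0 for the
    reference base), total (1 - exp(-sum of off-diagonal mu)). Sites where
    the genome model or the small context is undefined are absent. Absent
    alpha entries contribute mu=0; their number is logged.
    """
    frames = []
    n_absent_total = 0
    for name in genome.names:
        codes = genome.codes(name)
        sites, P = genome_model.evaluate_record(genome, name, leave_one_out)
        if len(sites) == 0:
            continue
        ctx, ok = _central_ctx_arrays(codes, alpha.k_hat)
        keep = ok[sites]
        s = sites[keep]
        P = P[keep]
        a = codes[s].astype(np.int64)
        arows, n_absent = alpha.rows_for(ctx[s], a)
        n_absent_total += n_absent
        mu = arows * P
        mu[np.arange(len(s)), a] = 0.0
        total = 1.0 - np.exp(-mu.sum(axis=1))
        df = pd.DataFrame(mu, columns=[f"mu{b}" for b in BASES])
        df.insert(0, "chrom", name)
        df.insert(1, "pos", s)
        df.insert(2, "ref", [BASES[r] for r in a])
        df["total"] = total
        frames.append(df)
    if n_absent_total:
        logger.warning("mutability_track: %d absent alpha entries scored as 0",
                       n_absent_total)
    if not frames:
        return pd.DataFrame(columns=["chrom", "pos", "ref",
                                     *[f"mu{b}" for b in BASES], "total"])
    return pd.concat(frames, ignore_index=True)


def site_mutability(alpha: AlphaMatrix, genome_model: InterpolatedContextModel,
                    genome: Genome, chrom: str, pos: int,
                    leave_one_out: bool = False) -> dict | None:
    """Single-site mutability entry, or None when either context is undefined."""
    track = mutability_track(
        alpha, genome_model,
        genome,  # full-genome call kept simple; scalar use is test-scale
        leave_one_out)
    row = track[(track["chrom"] == chrom) & (track["pos"] == pos)]
    if len(row) == 0:
        return None
    r = row.iloc[0]
    return {"ref": r["ref"],
            "mu": {b: float(r[f"mu{b}"]) for b in BASES if b != r["ref"]},
            "total": float(r["total"])}


def calibration_curve(track: pd.DataFrame,
                      variants: Iterable[VariantRecord],
                      bin_width: float = 1e-4,
                      smooth: bool = False) -> pd.DataFrame:
    """Observed variant fraction per model-mutability bin.

    A site counts as variant when any SNV is observed at it. Bins of the
    given width span [0, max mutability]; empty bins report count 0 and a
    NaN fraction. With ``smooth`` a cubic smoothing spline over the
    non-empty bins is added as ``fraction_smooth`` (presentation only).
    Columns: bin_center, n_sites, n_variant, fraction[, fraction_smooth].
    """
    var_sites = {(v.chrom, v.pos) for v in variants}
    is_var = np.fromiter(
        ((c, p) in var_sites
         for c, p in zip(track["chrom"], track["pos"])),
        bool, count=len(track))
    total = track["total"].to_numpy()
    nbins = int(np.floor(total.max() / bin_width)) + 1 if len(total) else 1
    idx = np.minimum((total / bin_width).astype(int), nbins - 1)
    n_sites = np.bincount(idx, minlength=nbins)
    n_var = np.bincount(idx[is_var], minlength=nbins)
    with np.errstate(invalid="ignore"):
        frac = np.where(n_sites > 0, n_var / np.maximum(n_sites, 1), np.nan)
    out = pd.DataFrame({
        "bin_center": (np.arange(nbins) + 0.5) * bin_width,
        "n_sites": n_sites,
        "n_variant": n_var,
        "fraction": frac,
    })
    if smooth:
        from scipy.interpolate import UnivariateSpline
        okb = n_sites > 0
        if okb.sum() >= 4:
            sp = UnivariateSpline(out["bin_center"][okb], frac[okb],
                                  w=np.sqrt(n_sites[okb]))
            out["fraction_smooth"] = sp(out["bin_center"])
        else:
            out["fraction_smooth"] = frac
    return out


def cumulative_mutability(track: pd.DataFrame,
                          subset: set[tuple[str, int]] | None = None,
                          grid: np.ndarray | int = 201) -> pd.DataFrame:
    """Cumulative fraction of sites with total mutability <= p on a grid.

    ``subset`` restricts to the given (chrom, pos) sites (e.g. SNP sites).
    Columns: p, cum_fraction.
    """
    total = track["total"].to_numpy()
    if subset is not None:
        mask = np.fromiter(((c, p) in subset
                            for c, p in zip(track["chrom"], track["pos"])),
                           bool, count=len(track))
        total = total[mask]
    if len(total) == 0:
        raise ValueError("no sites to accumulate")
    if isinstance(grid, int):
        grid = np.linspace(0.0, float(total.max()), grid)
    total_sorted = np.sort(total)
    cum = np.searchsorted(total_sorted, grid, side="right") / len(total_sorted)
    return pd.DataFrame({"p": grid, "cum_fraction": cum})


def write_alpha_tsv(alpha: AlphaMatrix, path: str | Path) -> None:
    """Serialize as (context, ref, alt, alpha, z, n_mut, n_ref) rows."""
    with open(path, "w") as fh:
        fh.write("context\tref\talt\talpha\tz\tn_mut\tn_ref\n")
        w = 2 * alpha.k_hat
        for i, code in enumerate(alpha.contexts):
            ctx = int_to_kmer(int(code), w) if w else "."
            for a in range(4):
                for b in range(4):
                    if a == b:
                        continue
                    fh.write(f"{ctx}\t{BASES[a]}\t{BASES[b]}\t"
                             f"{alpha.alpha[i, a, b]:.10g}\t"
                             f"{alpha.z[i, a, b]:.10g}\t"
                             f"{alpha.n_mut[i, a, b]}\t{alpha.n_ref[i, a]}\n")


def read_alpha_tsv(path: str | Path) -> AlphaMatrix:
    df = pd.read_csv(path, sep="\t")
    ctxs = df["context"].astype(str).unique()
    k_hat = 0 if (len(ctxs) and ctxs[0] == ".") else len(ctxs[0]) // 2
    codes = np.array(sorted(0 if c == "." else kmer_to_int(encode(c))
                            for c in ctxs), np.int64)
    u = len(codes)
    alpha = np.full((u, 4, 4), np.nan)
    z = np.full((u, 4, 4), np.nan)
    n_mut = np.zeros((u, 4, 4), np.int64)
    n_ref = np.zeros((u, 4), np.int64)
    for _, row in df.iterrows():
        code = 0 if row["context"] == "." else kmer_to_int(encode(row["context"]))
        i = int(np.searchsorted(codes, code))
        a, b = BASES.index(row["ref"]), BASES.index(row["alt"])
        alpha[i, a, b] = row["alpha"]
        z[i, a, b] = row["z"]
        n_mut[i, a, b] = row["n_mut"]
        n_ref[i, a] = row["n_ref"]
    return AlphaMatrix(k_hat, codes, alpha, z, n_mut, n_ref)
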