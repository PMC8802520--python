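"""Prediction tracks and model evaluation summaries.

A prediction track holds, for every evaluable site, the model's base
distribution, the probability of the reference base (the "reference
probability"), and the argmax prediction. On top of tracks this module
computes the accuracy summaries (overall / per record / per region label),
the GC-accuracy correlation, reference-probability densities, splice-site
probability profiles and chromosome-held-out cross-validation.

Sites whose context window contains N or crosses a record boundary carry no
prediction and are excluded from all numerators and denominators. Argmax
ties are broken uniformly at random with a seeded generator, so runs are
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._kmers import BASES
from .context_models import ContextSpec, InterpolatedContextModel, fit
from .sequence_io import Genome, Region

__all__ = [
    "AccuracyReport", "predict_track", "accuracy", "chromosome_cv",
    "splice_profile", "gc_accuracy_correlation",
    "reference_probability_density", "write_track_tsv", "read_track_tsv",
    "write_track_bedgraph", "write_accuracy_tsv", "read_accuracy_tsv",
]

_PCOLS = [f"p{b}" for b in BASES]


def _argmax_with_ties(P: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Row argmax, uniform among tied maxima."""
    maxv = P.max(axis=1)
    ties = P == maxv[:, None]
    k = ties.sum(axis=1)
    out = P.argmax(axis=1)
    multi = k > 1
    if np.any(multi):
        # pick the r-th set bit of each tied row, r uniform
        r = rng.integers(0, k[multi])
        cum = np.cumsum(ties[multi], axis=1)
        out[multi] = (cum == (r + 1)[:, None]).argmax(axis=1)
    return out


def predict_track(model: InterpolatedContextModel, genome: Genome,
                  leave_one_out: bool = False, seed: int = 0) -> pd.DataFrame:
    """Per-site prediction track over all records of a genome.

    Columns: chrom, pos, ref, pA..pT, p_ref, pred. One row per evaluable
    site; skipped sites are absent, not zero-filled.
    """
    rng = np.random.default_rng(seed)
    frames = []
    for name in genome.names:
        sites, P = model.evaluate_record(genome, name, leave_one_out)
        if len(sites) == 0:
            continue
        refs = genome.codes(name)[sites].astype(np.int64)
        pred = _argmax_with_ties(P, rng)
        df = pd.DataFrame(P, columns=_PCOLS)
        df.insert(0, "chrom", name)
        df.insert(1, "pos", sites)
        df.insert(2, "ref", [BASES[r] for r in refs])
        df["p_ref"] = P[np.arange(len(sites)), refs]
        df["pred"] = [BASES[p] for p in pred]
        frames.append(df)
    if not frames:
        return pd.DataFrame(
            columns=["chrom", "pos", "ref", *_PCOLS, "p_ref", "pred"])
    return pd.concat(frames, ignore_index=True)


@dataclass
class AccuracyReport:
    """Fractions of sites where the argmax base equals the reference."""

    overall_accuracy: float
    n_sites: int
    per_record: dict[str, float] = field(default_factory=dict)
    per_record_n: dict[str, int] = field(default_factory=dict)
    per_label: dict[str, float] = field(default_factory=dict)
    per_label_n: dict[str, int] = field(default_factory=dict)


def _label_mask(track: pd.DataFrame, regions: Iterable[Region]) -> np.ndarray:
    """Boolean mask of track sites covered by any of the given regions."""
    mask = np.zeros(len(track), bool)
    by_chrom: dict[str, list[Region]] = {}
    for r in regions:
        by_chrom.setdefault(r.chrom, []).append(r)
    for chrom, regs in by_chrom.items():
        sel = np.flatnonzero(track["chrom"].to_numpy() == chrom)
        if len(sel) == 0:
            continue
        pos = track["pos"].to_numpy()[sel]
        # merge intervals so searchsorted membership is well-defined
        ivs = sorted((r.start, r.end) for r in regs)
        starts, ends = [], []
        for s, e in ivs:
            if ends and s <= ends[-1]:
                ends[-1] = max(ends[-1], e)
            else:
                starts.append(s)
                ends.append(e)
        starts_a = np.asarray(starts)
        ends_a = np.asarray(ends)
        idx = np.searchsorted(starts_a, pos, side="right") - 1
        ok = idx >= 0
        ok[ok] &= pos[ok] < ends_a[idx[ok]]
        mask[sel[ok]] = True
    return mask


def accuracy(track: pd.DataFrame, regions: Sequence[Region] | None = None
             ) -> AccuracyReport:
    """Fraction of evaluable sites predicted correctly, by stratum.

    With regions, per-label accuracy is computed over sites overlapping any
    region of that label; a site may count toward several labels.
    """
    if len(track) == 0:
        raise ValueError("empty prediction track")
    correct = (track["pred"] == track["ref"]).to_numpy()
    report = AccuracyReport(float(correct.mean()), len(track))
    for chrom, grp in track.groupby("chrom", sort=False):
        c = (grp["pred"] == grp["ref"]).to_numpy()
        report.per_record[str(chrom)] = float(c.mean())
        report.per_record_n[str(chrom)] = len(grp)
    if regions is not None:
        labels = sorted({r.label for r in regions})
        for label in labels:
            mask = _label_mask(track, [r for r in regions if r.label == label])
            n = int(mask.sum())
            if n == 0:
                continue
            report.per_label[label] = float(correct[mask].mean())
            report.per_label_n[label] = n
    return report


def chromosome_cv(spec: ContextSpec, genome: Genome, backend: str = "table",
                  seed: int = 0) -> dict[str, float]:
    """Held-out-record accuracy: fit on all other records, test on each.

    The held-out model never sees the test record, so leave-one-out
    correction is unnecessary on the test predictions.
    """
    if len(genome) < 2:
        raise ValueError("chromosome cross-validation needs >= 2 records")
    out: dict[str, float] = {}
    for name in genome.names:
        model = fit(spec, genome, backend=backend, exclude_records=[name])
        track = predict_track(model, genome.subset([name]),
                              leave_one_out=False, seed=seed)
        out[name] = accuracy(track).overall_accuracy
    return out


def gc_accuracy_correlation(per_record_accuracy: dict[str, float],
                            genome: Genome) -> float | None:
    """Pearson correlation of per-record GC fraction with accuracy.

    Returns None when either variable has zero variance.
    """
    names = list(per_record_accuracy)
    if len(names) < 3:
        raise ValueError("need >= 3 records for a correlation")
    gc = np.array([genome.gc_fraction(n) for n in names])
    acc = np.array([per_record_accuracy[n] for n in names])
    if np.ptp(gc) == 0 or np.ptp(acc) == 0:
        return None
    return float(stats.pearsonr(gc, acc).statistic)


def reference_probability_density(track: pd.DataFrame,
                                  regions: Sequence[Region] | None = None,
                                  bins: int = 100) -> pd.DataFrame:
    """Normalized histogram of p_ref, overall and per region label.

    Equal-width bins over [0, 1]; density integrates to 1 per label.
    Columns: label, bin_left, bin_right, count, density.
    """
    edges = np.linspace(0.0, 1.0, bins + 1)
    rows = []

    def add(label: str, values: np.ndarray):
        cnt, _ = np.histogram(values, bins=edges)
        dens, _ = np.histogram(values, bins=edges, density=True)
        for i in range(bins):
            rows.append((label, edges[i], edges[i + 1], int(cnt[i]),
                         float(dens[i]) if len(values) else np.nan))

    add("overall", track["p_ref"].to_numpy())
    if regions is not None:
        for label in sorted({r.label for r in regions}):
            mask = _label_mask(track, [r for r in regions if r.label == label])
            if mask.any():
                add(label, track["p_ref"].to_numpy()[mask])
    return pd.DataFrame(rows, columns=["label", "bin_left", "bin_right",
                                       "count", "density"])


def splice_profile(track: pd.DataFrame,
                   sites: Sequence[tuple[str, int, str, str]],
                   up: int = 500, down: int = 100) -> pd.DataFrame:
    """Mean p_ref around splice sites, oriented 5'->3' on the coding strand.

    ``sites`` holds (chrom, pos, side, strand) with side in {"3'", "5'"} and
    strand in {"+", "-"}; pos is the genomic coordinate of the boundary.
    Offsets run from -up to down-1 relative to the boundary along the
    transcript; for minus-strand sites the genomic window is mirrored.
    Missing track positions are dropped per offset. Columns: side, offset,
    mean_p_ref, n_sites.
    """
    pref: dict[str, pd.Series] = {}
    for chrom, grp in track.groupby("chrom", sort=False):
        pref[str(chrom)] = pd.Series(grp["p_ref"].to_numpy(),
                                     index=grp["pos"].to_numpy())
    offsets = np.arange(-up, down)
    acc: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, pos, side, strand in sites:
        if chrom not in pref:
            continue
        genomic = pos + offsets if strand == "+" else pos - offsets
        vals = pref[chrom].reindex(genomic).to_numpy()
        s, n = acc.setdefault(side, (np.zeros(len(offsets)),
                                     np.zeros(len(offsets), int)))
        ok = ~np.isnan(vals)
        s[ok] += vals[ok]
        n[ok] += 1
    rows = []
    for side, (s, n) in acc.items():
        for i, off in enumerate(offsets):
            mean = s[i] / n[i] if n[i] else np.nan
            rows.append((side, int(off), mean, int(n[i])))
    return pd.DataFrame(rows, columns=["side", "offset", "mean_p_ref",
                                       "n_sites"])


# ---------------- exports ----------------

def write_track_tsv(track: pd.DataFrame, path: str | Path) -> None:
    track.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_track_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_track_bedgraph(track: pd.DataFrame, path: str | Path,
                         column: str = "p_ref") -> None:
    """One bedGraph line per site (0-based half-open single-base spans)."""
    with open(path, "w") as fh:
        fh.write(f'track type=bedGraph name="{column}"\n')
        for chrom, pos, val in zip(track["chrom"], track["pos"], track[column]):
            fh.write(f"{chrom}\t{pos}\t{pos + 1}\t{val:.10g}\n")


def write_accuracy_tsv(report: AccuracyReport, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("stratum\tname\taccuracy\tn_sites\n")
        fh.write(f"overall\t.\t{report.overall_accuracy:.10g}\t{report.n_sites}\n")
        for name, acc in report.per_record.items():
            fh.write(f"record\t{name}\t{acc:.10g}\t{report.per_record_n[name]}\n")
        for name, acc in report.per_label.items():
            fh.write(f"label\t{name}\t{acc:.10g}\t{report.per_label_n[name]}\n")


def read_accuracy_tsv(path: str | Path) -> AccuracyReport:
    df = pd.read_csv(path, sep="\t")
    overall = df[df["stratum"] == "overall"].iloc[0]
    report = AccuracyReport(float(overall["accuracy"]), int(overall["n_sites"]))
    for _, row in df[df["stratum"] == "record"].iterrows():
        report.per_record[str(row["name"])] = float(row["accuracy"])
        report.per_record_n[str(row["name"])] = int(row["n_sites"])
    for _, row in df[df["stratum"] == "label"].iterrows():
        report.per_label[str(row["name"])] = float(row["accuracy"])
        report.per_label_n[str(row["name"])] = int(row["n_sites"])
    return report
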