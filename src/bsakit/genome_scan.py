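"""Genome scanning: smoothing, permutation thresholds, interval calling.

Per-SNP statistics are noisy at sequencing depths of 10–60x, so the scan
works on two smoothed summaries:

* **G′** — tricube-kernel weighted mean of the per-SNP G statistic over
  all SNPs within ``tricube_halfwidth`` bp on the same chromosome.
* **Sliding windows** — means of Δ, G, G′ and ED⁴ over windows of
  ``window_size`` bp advanced by ``step`` bp, anchored at coordinate 0 on
  every chromosome (0-based half-open membership internally; reported
  1-based inclusive).

Significance is empirical: bulk labels are permuted at every site, the
whole smoothing pipeline is recomputed, and the genome-wide quantiles of
the pooled null window values give one threshold per statistic per level.
Two permutation schemes are available:

* ``"reads"`` (default) — at each site the pooled reads of both bulks are
  re-partitioned between the bulks by a hypergeometric draw conditional
  on each bulk's coverage and the pooled allele counts.  This is the
  conditional (margin-preserving) null of the 2×2 table and perturbs all
  three statistics.
* ``"swap"`` — each site's two depth pairs are exchanged with probability
  1/2.  This flips the sign of Δ but leaves G and ED numerically
  invariant (both are symmetric in the bulks), so it is only informative
  for the signed ΔSNP-index.

Thresholding is window-level throughout: |mean Δ|, window-mean G′ and
window-mean ED⁴ are compared against the corresponding null quantiles,
and runs of significant windows are merged into candidate QTL intervals.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .bsa_stats import SQRT2, SnpStat, g_statistic_array, stats_frame
from .variant_io import BulkSnp, site_arrays

__all__ = [
    "ScanConfig",
    "WindowStat",
    "ThresholdSet",
    "QtlInterval",
    "tricube_weight",
    "gprime_smooth",
    "window_scan",
    "windows_frame",
    "permutation_thresholds",
    "call_intervals",
    "write_window_table",
    "write_threshold_table",
    "write_intervals_bed",
    "plot_scan",
]

SCAN_STATISTICS = ("delta", "gprime", "ed4")
_PERM_BATCH = 256  # fixed so the RNG stream depends only on the seed


@dataclass
class ScanConfig:
    """Parameters of the smoothing / thresholding pipeline.

    Defaults follow the headline analysis: 1 Mb windows advanced in
    100 kb steps, tricube halfwidth of half a window, and 100,000
    label permutations at the 95% and 99% levels.
    """

    window_size: int = 1_000_000
    step: int = 100_000
    tricube_halfwidth: Optional[int] = None  # defaults to window_size / 2
    n_permutations: int = 100_000
    levels: tuple[float, ...] = (0.95, 0.99)
    seed: int = 0
    min_snps_per_window: int = 1
    scheme: str = "reads"  # "reads" | "swap"
    pooling: str = "pooled"  # "pooled" | "max" (per-replicate genome-wide maximum)
    per_chromosome: bool = False
    null_cap: int = 10_000_000  # subsample the pooled null above this many values

    def __post_init__(self) -> None:
        if self.step > self.window_size:
            raise ValueError("step must be <= window_size")
        if self.step <= 0 or self.window_size <= 0:
            raise ValueError("window_size and step must be positive")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if not all(0.0 < lv < 1.0 for lv in self.levels):
            raise ValueError("levels must lie in (0, 1)")
        if self.scheme not in ("reads", "swap"):
            raise ValueError("scheme must be 'reads' or 'swap'")
        if self.pooling not in ("pooled", "max"):
            raise ValueError("pooling must be 'pooled' or 'max'")

    @property
    def halfwidth(self) -> int:
        return (
            self.tricube_halfwidth
            if self.tricube_halfwidth is not None
            else self.window_size // 2
        )


@dataclass(frozen=True)
class WindowStat:
    """Smoothed statistics over one genomic window (0-based half-open)."""

    chrom: str
    start: int
    end: int
    n_snps: int
    mean_delta: float
    mean_g: float
    gprime: float
    mean_ed4: float


@dataclass
class ThresholdSet:
    """Per-statistic empirical significance levels from permutation."""

    thresholds: dict  # statistic -> {level -> value}
    seed: int
    n_permutations: int

    def get(self, statistic: str, level: float) -> float:
        try:
            return self.thresholds[statistic][level]
        except KeyError:
            raise ValueError(
                f"no threshold for statistic {statistic!r} at level {level}"
            ) from None


@dataclass(frozen=True)
class QtlInterval:
    """A candidate interval: merged run of significant windows (1-based incl.)."""

    chrom: str
    start: int
    end: int
    peak_pos: int
    peak_value: float
    statistic: str
    level: float


def tricube_weight(distance, halfwidth):
    """Tricube kernel weight: (1 − (|d|/h)³)³ for |d| ≤ h, else 0."""
    if np.any(np.asarray(halfwidth) <= 0):
        raise ValueError("halfwidth must be positive")
    u = np.abs(np.asarray(distance, dtype=np.float64)) / halfwidth
    w = np.where(u <= 1.0, (1.0 - np.minimum(u, 1.0) ** 3) ** 3, 0.0)
    return float(w) if np.isscalar(distance) else w


def _tricube_kernel(pos: np.ndarray, halfwidth: int) -> sp.csr_matrix:
    """Row-normalized sparse tricube kernel over one chromosome's SNPs."""
    n = len(pos)
    lo = np.searchsorted(pos, pos - halfwidth, side="left")
    hi = np.searchsorted(pos, pos + halfwidth, side="right")
    lens = hi - lo
    indptr = np.concatenate(([0], np.cumsum(lens)))
    indices = np.concatenate([np.arange(a, b) for a, b in zip(lo, hi)]) if n else np.empty(0, int)
    centers = np.repeat(pos, lens)
    w = tricube_weight(pos[indices] - centers, halfwidth)
    mat = sp.csr_matrix((w, indices, indptr), shape=(n, n))
    rowsum = np.asarray(mat.sum(axis=1)).ravel()
    inv = sp.diags(1.0 / np.where(rowsum > 0, rowsum, 1.0))
    return (inv @ mat).tocsr()


def _smooth_chrom(pos: np.ndarray, values: np.ndarray, halfwidth: int) -> np.ndarray:
    """Tricube-weighted mean of ``values`` at every SNP position."""
    kernel = _tricube_kernel(np.asarray(pos, dtype=np.int64), halfwidth)
    vals = np.asarray(values, dtype=np.float64)
    ok = np.isfinite(vals)
    num = kernel @ np.where(ok, vals, 0.0)
    den = kernel @ ok.astype(np.float64)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(den > 0, num / den, np.nan)


def gprime_smooth(stats, halfwidth: int) -> np.ndarray:
    """G′ at every SNP: tricube-weighted mean of G within ``halfwidth`` bp.

    ``stats`` is a list of :class:`SnpStat` (or the equivalent DataFrame),
    sorted by position within chromosome; smoothing never crosses
    chromosome boundaries.
    """
    df = stats if isinstance(stats, pd.DataFrame) else stats_frame(stats)
    out = np.empty(len(df), dtype=np.float64)
    for _, idx in df.groupby("chrom", sort=False).groups.items():
        sub = df.loc[idx]
        out[df.index.get_indexer(idx)] = _smooth_chrom(
            sub["pos"].to_numpy() - 1, sub["g"].to_numpy(), halfwidth
        )
    return out


def _window_starts(pos0: np.ndarray, step: int) -> np.ndarray:
    if len(pos0) == 0:
        return np.empty(0, dtype=np.int64)
    last = (int(pos0.max()) // step) * step
    return np.arange(0, last + 1, step, dtype=np.int64)


def _membership(
    pos0: np.ndarray, starts: np.ndarray, window: int, min_snps: int
) -> tuple[sp.csr_matrix, np.ndarray, np.ndarray]:
    """Sparse (windows x SNPs) mean operator; rows below min_snps dropped."""
    lo = np.searchsorted(pos0, starts, side="left")
    hi = np.searchsorted(pos0, starts + window, side="left")
    counts = hi - lo
    keep = counts >= max(min_snps, 1)
    lo, hi, starts_k = lo[keep], hi[keep], starts[keep]
    lens = hi - lo
    indptr = np.concatenate(([0], np.cumsum(lens)))
    indices = (
        np.concatenate([np.arange(a, b) for a, b in zip(lo, hi)])
        if len(lo)
        else np.empty(0, int)
    )
    data = np.repeat(1.0 / np.maximum(lens, 1), lens)
    mat = sp.csr_matrix((data, indices, indptr), shape=(len(starts_k), len(pos0)))
    return mat, starts_k, lens


def window_scan(stats, config: ScanConfig) -> list[WindowStat]:
    """Sliding-window means of Δ, G, G′ and ED⁴ along each chromosome.

    Windows start at 0, step, 2·step, … per chromosome; a SNP at 1-based
    ``pos`` belongs to window [start, start+window) when
    ``start <= pos−1 < start+window``.  Windows holding fewer than
    ``min_snps_per_window`` SNPs are omitted.
    """
    df = stats if isinstance(stats, pd.DataFrame) else stats_frame(stats)
    out: list[WindowStat] = []
    for chrom, sub in df.groupby("chrom", sort=False):
        pos0 = sub["pos"].to_numpy(dtype=np.int64) - 1
        gp = _smooth_chrom(pos0, sub["g"].to_numpy(), config.halfwidth)
        starts = _window_starts(pos0, config.step)
        mat, starts_k, lens = _membership(
            pos0, starts, config.window_size, config.min_snps_per_window
        )
        cols = {
            "mean_delta": sub["delta"].to_numpy(dtype=np.float64),
            "mean_g": sub["g"].to_numpy(dtype=np.float64),
            "gprime": gp,
            "mean_ed4": sub["ed4"].to_numpy(dtype=np.float64),
        }
        means = {}
        for name, vals in cols.items():
            ok = np.isfinite(vals)
            num = mat @ np.where(ok, vals, 0.0)
            den = mat @ ok.astype(np.float64)
            with np.errstate(invalid="ignore", divide="ignore"):
                means[name] = np.where(den > 0, num / den, np.nan)
        for i, start in enumerate(starts_k):
            out.append(
                WindowStat(
                    chrom=str(chrom),
                    start=int(start),
                    end=int(start) + config.window_size,
                    n_snps=int(lens[i]),
                    mean_delta=float(means["mean_delta"][i]),
                    mean_g=float(means["mean_g"][i]),
                    gprime=float(means["gprime"][i]),
                    mean_ed4=float(means["mean_ed4"][i]),
                )
            )
    return out


def windows_frame(windows: Sequence[WindowStat]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [w.chrom for w in windows],
            "start": [w.start for w in windows],
            "end": [w.end for w in windows],
            "n_snps": [w.n_snps for w in windows],
            "mean_delta": [w.mean_delta for w in windows],
            "mean_g": [w.mean_g for w in windows],
            "gprime": [w.gprime for w in windows],
            "mean_ed4": [w.mean_ed4 for w in windows],
        }
    )


# ---------------------------------------------------------------------------
# permutation null

def _null_counts(rng, scheme, a_ref, a_alt, b_ref, b_alt, n_rep):
    """Draw permuted per-bulk counts, shape (n_rep, n_sites) each."""
    n_a = a_ref + a_alt
    n_b = b_ref + b_alt
    if scheme == "swap":
        mask = rng.random((n_rep, len(a_ref))) < 0.5
        pa = np.where(mask, b_alt, a_alt)
        pb = np.where(mask, a_alt, b_alt)
        na = np.where(mask, n_b, n_a)
        nb = np.where(mask, n_a, n_b)
        return pa, na - pa, pb, nb - pb
    # "reads": hypergeometric re-partition conditional on coverage and
    # pooled allele counts
    total = n_a + n_b
    if np.any(total <= 0):
        raise ValueError("permutation requires positive total depth at every site")
    alt_tot = a_alt + b_alt
    pa = rng.hypergeometric(
        alt_tot[None, :], (total - alt_tot)[None, :], n_a[None, :],
        size=(n_rep, len(a_ref)),
    )
    pb = alt_tot[None, :] - pa
    return pa, n_a[None, :] - pa, pb, n_b[None, :] - pb


class _NullPool:
    """Accumulates null values; reservoir-subsamples above a cap."""

    def __init__(self, cap: int, rng: np.random.Generator):
        self.cap = cap
        self.rng = rng
        self.chunks: list[np.ndarray] = []
        self.n = 0

    def add(self, values: np.ndarray) -> None:
        v = values[np.isfinite(values)].ravel()
        self.chunks.append(v)
        self.n += v.size
        if self.n > 2 * self.cap:
            self._shrink()

    def _shrink(self) -> None:
        pooled = np.concatenate(self.chunks)
        idx = self.rng.choice(pooled.size, size=self.cap, replace=False)
        self.chunks = [pooled[idx]]
        self.n = self.cap

    def values(self) -> np.ndarray:
        if not self.chunks:
            return np.empty(0)
        pooled = np.concatenate(self.chunks)
        if pooled.size > self.cap:
            idx = self.rng.choice(pooled.size, size=self.cap, replace=False)
            pooled = pooled[idx]
        return pooled


def permutation_thresholds(
    sites: Sequence[BulkSnp],
    config: ScanConfig,
    statistics: Sequence[str] = SCAN_STATISTICS,
) -> ThresholdSet:
    """Empirical genome-wide thresholds from Monte-Carlo label permutation.

    For every replicate the site labels are permuted (see module notes on
    the two schemes), the full smoothing pipeline is recomputed, and the
    window-level values are pooled; thresholds are the requested quantiles
    of the pooled null (``pooling="max"`` instead takes quantiles of each
    replicate's genome-wide maximum, a family-wise variant).  Results are
    reproducible for a fixed (seed, n_permutations, input).
    """
    for s in statistics:
        if s not in SCAN_STATISTICS:
            raise ValueError(f"unknown scan statistic {s!r}")
    arr = site_arrays(sites)
    rng = np.random.default_rng(config.seed)
    pool_rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])

    # per-chromosome fixed structures
    chrom_blocks = []
    chroms = pd.unique(arr["chrom"])
    for c in chroms:
        m = arr["chrom"] == c
        pos0 = arr["pos"][m] - 1
        order = np.argsort(pos0, kind="stable")
        pos0 = pos0[order]
        mat, _, _ = _membership(
            pos0, _window_starts(pos0, config.step), config.window_size,
            config.min_snps_per_window,
        )
        chrom_blocks.append(
            dict(
                kernel=_tricube_kernel(pos0, config.halfwidth),
                windows=mat,
                a_ref=arr["a_ref"][m][order],
                a_alt=arr["a_alt"][m][order],
                b_ref=arr["b_ref"][m][order],
                b_alt=arr["b_alt"][m][order],
            )
        )

    pools = {s: _NullPool(config.null_cap, pool_rng) for s in statistics}
    max_parts = {s: [] for s in statistics}  # per-replicate maxima, "max" pooling
    done = 0
    while done < config.n_permutations:
        n_rep = min(_PERM_BATCH, config.n_permutations - done)
        rep_max = {s: np.full(n_rep, -np.inf) for s in statistics}
        for blk in chrom_blocks:
            pa, ra, pb, rb = _null_counts(
                rng, config.scheme, blk["a_ref"], blk["a_alt"],
                blk["b_ref"], blk["b_alt"], n_rep,
            )
            na = (pa + ra).astype(np.float64)
            nb = (pb + rb).astype(np.float64)
            with np.errstate(invalid="ignore", divide="ignore"):
                delta = pa / na - pb / nb
            win = blk["windows"]
            for s in statistics:
                if s == "delta":
                    vals = np.abs((win @ delta.T).T)
                elif s == "ed4":
                    vals = (win @ ((SQRT2 * np.abs(delta)) ** 4).T).T
                else:  # gprime
                    g = g_statistic_array(ra, pa, rb, pb)
                    gp = (blk["kernel"] @ g.T).T
                    vals = (win @ gp.T).T
                pools[s].add(vals)
                if config.pooling == "max" and vals.size:
                    rep_max[s] = np.maximum(rep_max[s], np.nanmax(vals, axis=1))
        if config.pooling == "max":
            for s in statistics:
                max_parts[s].append(rep_max[s])
        done += n_rep

    thresholds: dict = {}
    for s in statistics:
        if config.pooling == "max":
            null_vals = np.concatenate(max_parts[s])
        else:
            null_vals = pools[s].values()
        thresholds[s] = {
            lv: float(np.quantile(null_vals, lv)) if null_vals.size else float("nan")
            for lv in sorted(config.levels)
        }
    return ThresholdSet(
        thresholds=thresholds, seed=config.seed, n_permutations=config.n_permutations
    )


# ---------------------------------------------------------------------------
# interval calling

def _window_value(w: WindowStat, statistic: str) -> float:
    if statistic == "delta":
        return abs(w.mean_delta)
    if statistic == "gprime":
        return w.gprime
    if statistic == "ed4":
        return w.mean_ed4
    if statistic == "g":
        return w.mean_g
    raise ValueError(f"unknown scan statistic {statistic!r}")


def call_intervals(
    windows: Sequence[WindowStat],
    thresholds: ThresholdSet,
    statistic: str,
    level: float = 0.95,
) -> list[QtlInterval]:
    """Merge runs of significant windows into candidate QTL intervals.

    Windows whose value (|mean Δ|, G′ or mean ED⁴) reaches the threshold
    are merged when their starts are at most two steps apart — i.e. runs
    of significant windows tolerating a single non-significant step
    between them (with overlapping 1 Mb / 100 kb windows a full-span
    overlap rule would bridge runs up to a whole window apart).  Bounds
    are the union of the merged windows, reported 1-based inclusive; the
    peak is the midpoint of the highest window.
    """
    thr = thresholds.get(statistic, level)
    sig = [w for w in windows if _window_value(w, statistic) >= thr]
    sig.sort(key=lambda w: (w.chrom, w.start))
    intervals: list[QtlInterval] = []
    run: list[WindowStat] = []

    step = _infer_step(windows)

    def flush(run):
        if not run:
            return
        peak = max(run, key=lambda w: _window_value(w, statistic))
        intervals.append(
            QtlInterval(
                chrom=run[0].chrom,
                start=run[0].start + 1,
                end=max(w.end for w in run),
                peak_pos=(peak.start + peak.end + 1) // 2,
                peak_value=_window_value(peak, statistic),
                statistic=statistic,
                level=level,
            )
        )

    for w in sig:
        if run and w.chrom == run[-1].chrom and w.start <= run[-1].start + 2 * step:
            run.append(w)
        else:
            flush(run)
            run = [w]
    flush(run)
    return intervals


def _infer_step(windows: Sequence[WindowStat]) -> int:
    starts = sorted({w.start for w in windows})
    diffs = [b - a for a, b in zip(starts, starts[1:]) if b > a]
    return min(diffs) if diffs else 0


# ---------------------------------------------------------------------------
# exports

def write_window_table(windows: Sequence[WindowStat], path: str | os.PathLike) -> None:
    df = windows_frame(windows)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_threshold_table(thresholds: ThresholdSet, path: str | os.PathLike) -> None:
    rows = [
        {"statistic": s, "level": lv, "threshold": v}
        for s, by_level in sorted(thresholds.thresholds.items())
        for lv, v in sorted(by_level.items())
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_intervals_bed(
    intervals: Sequence[QtlInterval], path: str | os.PathLike
) -> None:
    """BED export (0-based half-open per BED convention)."""
    with open(path, "w") as fh:
        for iv in intervals:
            name = f"{iv.statistic}:{iv.level:g}"
            fh.write(
                f"{iv.chrom}\t{iv.start - 1}\t{iv.end}\t{name}\t{iv.peak_value:.6g}\n"
            )


def plot_scan(
    windows: Sequence[WindowStat],
    thresholds: ThresholdSet,
    path: str | os.PathLike,
    statistics: Sequence[str] = SCAN_STATISTICS,
    levels: Optional[Sequence[float]] = None,
) -> None:
    """Per-chromosome panels of smoothed curves with threshold lines."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels = {"delta": "|ΔSNP-index|", "gprime": "G′", "ed4": "ED⁴"}
    chroms = list(dict.fromkeys(w.chrom for w in windows))
    if not chroms:
        raise ValueError("no windows to plot")
    if levels is None:
        levels = sorted(next(iter(thresholds.thresholds.values())).keys())
    fig, axes = plt.subplots(
        len(chroms), len(statistics),
        figsize=(4.0 * len(statistics), 2.2 * len(chroms)),
        squeeze=False,
    )
    for i, chrom in enumerate(chroms):
        ws = [w for w in windows if w.chrom == chrom]
        mids = [(w.start + w.end) / 2 / 1e6 for w in ws]
        for j, stat in enumerate(statistics):
            ax = axes[i][j]
            ax.plot(mids, [_window_value(w, stat) for w in ws], color="crimson", lw=1.2)
            for lv, style in zip(levels, ("--", ":")):
                ax.axhline(
                    thresholds.get(stat, lv), color="steelblue", ls=style, lw=1,
                    label=f"{lv:.0%}",
                )
            if i == 0:
                ax.set_title(labels.get(stat, stat))
            if j == 0:
                ax.set_ylabel(chrom)
            if i == len(chroms) - 1:
                ax.set_xlabel("position (Mb)")
    axes[0][-1].legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
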