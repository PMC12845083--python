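"""Per-SNP bulk-contrast statistics.

Three complementary statistics quantify the allele-frequency contrast
between two phenotypic bulks at a biallelic site with read counts
``(n_ref, n_alt)`` per bulk:

* **SNP-index / ΔSNP-index** — the alt-allele read fraction per bulk and
  the difference between the high- and low-trait bulk indices.  Near an
  unlinked locus Δ ≈ 0; near a causal locus under complete selection
  Δ → ±1.
* **G statistic** — the 2×2 log-likelihood-ratio statistic of the
  allele-by-bulk read count table, ``G = 2 Σ n_i ln(n_i / n̂_i)`` with
  expected counts ``n̂_i`` from the row/column marginals under
  independence (natural log; ``0·ln 0 = 0``).
* **ED / ED⁴** — the Euclidean distance between the bulks'
  allele-frequency vectors over both allele axes,
  ``ED = √(2 (f_A − f_B)²) = √2 |f_A − f_B|`` at a biallelic site, raised
  to the fourth power to suppress sampling noise.

Undefined values (zero total depth) are carried as NaN, never as zero.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .variant_io import BulkSnp, site_arrays

__all__ = [
    "SnpStat",
    "snp_index",
    "delta_snp_index",
    "g_statistic",
    "g_statistic_array",
    "euclidean_stats",
    "compute_snp_stats",
    "stats_frame",
    "write_stats_table",
]

SQRT2 = math.sqrt(2.0)


@dataclass(frozen=True)
class SnpStat:
    """The five per-SNP statistics at one site (NaN marks undefined)."""

    chrom: str
    pos: int
    snp_index_a: float
    snp_index_b: float
    delta: float
    g: float
    ed: float
    ed4: float


def snp_index(depth_ref: int, depth_alt: int) -> float:
    """Alt-allele read fraction; NaN when the site has no reads."""
    total = depth_ref + depth_alt
    if total <= 0:
        return float("nan")
    return depth_alt / total


def delta_snp_index(index_high: float, index_low: float) -> float:
    """Difference of SNP-indices, high-trait bulk minus low-trait bulk."""
    return index_high - index_low


def g_statistic_array(a_ref, a_alt, b_ref, b_alt) -> np.ndarray:
    """Vectorized G statistic of the 2x2 (allele x bulk) read-count table.

    Accepts scalars or arrays (broadcast together). Cells with observed or
    expected count zero contribute zero; an all-zero table yields NaN.
    """
    a_ref = np.asarray(a_ref, dtype=np.float64)
    a_alt = np.asarray(a_alt, dtype=np.float64)
    b_ref = np.asarray(b_ref, dtype=np.float64)
    b_alt = np.asarray(b_alt, dtype=np.float64)
    row_a = a_ref + a_alt
    row_b = b_ref + b_alt
    col_ref = a_ref + b_ref
    col_alt = a_alt + b_alt
    total = row_a + row_b

    with np.errstate(divide="ignore", invalid="ignore"):
        def term(obs, row, col):
            exp = row * col / np.where(total > 0, total, 1.0)
            ratio = np.where((obs > 0) & (exp > 0), obs / np.where(exp > 0, exp, 1.0), 1.0)
            return np.where(obs > 0, obs * np.log(ratio), 0.0)

        g = 2.0 * (
            term(a_ref, row_a, col_ref)
            + term(a_alt, row_a, col_alt)
            + term(b_ref, row_b, col_ref)
            + term(b_alt, row_b, col_alt)
        )
    g = np.where(total > 0, np.maximum(g, 0.0), np.nan)
    return g


def g_statistic(a_ref: int, a_alt: int, b_ref: int, b_alt: int) -> float:
    """G statistic for a single site; NaN for an all-zero table."""
    return float(g_statistic_array(a_ref, a_alt, b_ref, b_alt))


def euclidean_stats(freq_a_alt: float, freq_b_alt: float) -> tuple[float, float]:
    """(ED, ED⁴) from the two bulks' alt-allele frequencies.

    ED runs over both allele axes of the biallelic site, hence the √2
    factor relative to |Δ|: ED = √2·|f_A − f_B|, ED⁴ = 4·(f_A − f_B)⁴.
    """
    d = freq_a_alt - freq_b_alt
    ed = SQRT2 * abs(d)
    return ed, ed ** 4


def compute_snp_stats(
    sites: Sequence[BulkSnp], high_bulk: str = "a"
) -> list[SnpStat]:
    """All five statistics at every site; ``high_bulk`` fixes the Δ sign.

    Sites should already be depth-filtered; zero-total sites yield NaN
    statistics rather than zeros.
    """
    if high_bulk not in ("a", "b"):
        raise ValueError("high_bulk must be 'a' or 'b'")
    out = []
    for s in sites:
        ia = snp_index(s.depth_a_ref, s.depth_a_alt)
        ib = snp_index(s.depth_b_ref, s.depth_b_alt)
        delta = delta_snp_index(ia, ib) if high_bulk == "a" else delta_snp_index(ib, ia)
        g = g_statistic(s.depth_a_ref, s.depth_a_alt, s.depth_b_ref, s.depth_b_alt)
        ed, ed4 = euclidean_stats(ia, ib)
        out.append(SnpStat(s.chrom, s.pos, ia, ib, delta, g, ed, ed4))
    return out


def stats_frame(
    sites: Sequence[BulkSnp] | Iterable[SnpStat], high_bulk: str = "a"
) -> pd.DataFrame:
    """Per-SNP statistics as a DataFrame (vectorized over all sites)."""
    sites = list(sites)
    if sites and isinstance(sites[0], SnpStat):
        return pd.DataFrame(
            {
                "chrom": [s.chrom for s in sites],
                "pos": [s.pos for s in sites],
                "index_a": [s.snp_index_a for s in sites],
                "index_b": [s.snp_index_b for s in sites],
                "delta": [s.delta for s in sites],
                "g": [s.g for s in sites],
                "ed": [s.ed for s in sites],
                "ed4": [s.ed4 for s in sites],
            }
        )
    arr = site_arrays(sites)
    tot_a = (arr["a_ref"] + arr["a_alt"]).astype(np.float64)
    tot_b = (arr["b_ref"] + arr["b_alt"]).astype(np.float64)
    with np.errstate(divide="ignore", invalid="ignore"):
        ia = np.where(tot_a > 0, arr["a_alt"] / tot_a, np.nan)
        ib = np.where(tot_b > 0, arr["b_alt"] / tot_b, np.nan)
    delta = (ia - ib) if high_bulk == "a" else (ib - ia)
    g = g_statistic_array(arr["a_ref"], arr["a_alt"], arr["b_ref"], arr["b_alt"])
    ed = SQRT2 * np.abs(ia - ib)
    return pd.DataFrame(
        {
            "chrom": arr["chrom"],
            "pos": arr["pos"],
            "index_a": ia,
            "index_b": ib,
            "delta": delta,
            "g": g,
            "ed": ed,
            "ed4": ed ** 4,
        }
    )


def write_stats_table(stats, path: str | os.PathLike) -> None:
    """TSV export, one row per SNP, '.' for undefined values."""
    df = stats if isinstance(stats, pd.DataFrame) else stats_frame(stats)
    cols = ["chrom", "pos", "index_a", "index_b", "delta", "g", "ed4"]
    out = df[cols].copy()
    for c in cols[2:]:
        out[c] = [("." if not np.isfinite(v) else f"{v:.6g}") for v in out[c]]
    out.to_csv(path, sep="\t", index=False)
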