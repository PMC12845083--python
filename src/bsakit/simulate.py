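"""Synthetic bulk-segregant sequencing data with known truth.

The generator emulates the experimental design the scan statistics
assume: a recombinant inbred line (RIL) population from a biparental
cross, two bulks of phenotypically selected lines, and pooled short-read
sequencing of each bulk.

Model, per chromosome:

* Each line's genome is a two-state Markov chain along the marker grid.
  Between adjacent loci at map distance *d* cM (Haldane,
  ``r = (1 − e^(−2d/100})/2``) the chance that a RIL fixed by selfing is
  recombinant is ``R = 2r/(1 + 2r)``.
* Selection into bulks acts at the line level: a line sorted into the
  high bulk carries the high-trait allele at a QTL with probability
  ``effect`` (0.5 = no selection, 1.0 = complete selection); the low
  bulk is enriched for the low allele symmetrically.  Genotypes at the
  remaining markers follow from linkage to the QTL.
* Lines are fully inbred except for residual heterozygosity
  ``(1/2)^(generation−1)`` applied independently per locus (0.0625 at
  F5); a heterozygous locus contributes allele dosage 0.5.
* Reads: per-site per-bulk depth is fixed at ``mean_depth`` or Poisson
  distributed around it; alt reads are binomial(depth, bulk frequency).

Bulk A is the high-trait bulk and the simulated ALT allele is the
high-parent allele, so emitted sites are already polarized.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .variant_io import BulkSnp

__all__ = [
    "SimScenario",
    "SimTruth",
    "haldane_recomb_fraction",
    "ril_recomb_fraction",
    "simulate_bulks",
    "power_analysis",
    "write_truth",
]

POWER_PERMUTATION_CAP = 2_000_000  # scenarios x reps x permutations warn guard


@dataclass
class SimScenario:
    """One simulated BSA experiment.

    ``qtl`` entries are (chrom, pos, effect) with effect the probability
    that a line selected into the high bulk carries the high allele at
    that locus; at most one QTL per chromosome.
    """

    chromosomes: Sequence[tuple[str, int]] = (("Chr01", 25_000_000),)
    marker_spacing: int = 25_000
    recomb_rate: float = 1.0  # cM per Mb
    qtl: Sequence[tuple[str, int, float]] = ()
    n_lines_per_bulk: int = 20
    generation: int = 5  # F5: residual heterozygosity (1/2)^4
    mean_depth: float = 40.0
    depth_model: str = "fixed"  # "fixed" | "poisson"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.marker_spacing <= 0:
            raise ValueError("marker_spacing must be positive")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if self.depth_model not in ("fixed", "poisson"):
            raise ValueError("depth_model must be 'fixed' or 'poisson'")
        if self.generation < 2:
            raise ValueError("generation must be >= 2")
        names = [c[0] for c in self.chromosomes]
        lengths = dict(self.chromosomes)
        seen = set()
        for chrom, pos, effect in self.qtl:
            if chrom not in lengths:
                raise ValueError(f"QTL chromosome {chrom!r} not in scenario")
            if not 1 <= pos <= lengths[chrom]:
                raise ValueError(f"QTL position {chrom}:{pos} outside chromosome")
            if not 0.5 < effect <= 1.0:
                raise ValueError("QTL effect must lie in (0.5, 1]")
            if chrom in seen:
                raise ValueError("at most one QTL per chromosome is supported")
            seen.add(chrom)
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")

    @property
    def residual_het(self) -> float:
        return 0.5 ** (self.generation - 1)

    @classmethod
    def from_dict(cls, d: dict) -> "SimScenario":
        d = dict(d)
        if "chromosomes" in d:
            d["chromosomes"] = [(str(c[0]), int(c[1])) for c in d["chromosomes"]]
        if "qtl" in d:
            d["qtl"] = [(str(q[0]), int(q[1]), float(q[2])) for q in d["qtl"]]
        return cls(**d)


@dataclass
class SimTruth:
    """Ground truth: per-marker bulk allele frequencies and causal loci."""

    table: pd.DataFrame  # chrom, pos, freq_high, freq_low
    causal: list[tuple[str, int]]


def haldane_recomb_fraction(map_distance_cm: float) -> float:
    """Haldane map function: r = (1 − e^(−2d/100)) / 2."""
    if map_distance_cm < 0:
        raise ValueError("map distance must be >= 0")
    return 0.5 * (1.0 - math.exp(-2.0 * map_distance_cm / 100.0))


def ril_recomb_fraction(map_distance_cm: float) -> float:
    """Expected recombinant fraction among selfed-to-fixation RILs.

    With single-meiosis recombination fraction r, repeated selfing fixes
    a recombinant haplotype in R = 2r/(1+2r) of lines.
    """
    r = haldane_recomb_fraction(map_distance_cm)
    return 2.0 * r / (1.0 + 2.0 * r)


def _walk_genotypes(
    rng: np.random.Generator,
    n_lines: int,
    loci_bp: np.ndarray,
    anchor_idx: int,
    anchor_prob_high: float,
    recomb_rate: float,
) -> np.ndarray:
    """Markov-chain genotypes (n_lines x n_loci) anchored at one locus."""
    n = len(loci_bp)
    d_cm = np.diff(loci_bp) / 1e6 * recomb_rate
    flip_p = np.array([ril_recomb_fraction(d) for d in d_cm])
    g = np.empty((n_lines, n), dtype=np.int8)
    g[:, anchor_idx] = rng.random(n_lines) < anchor_prob_high
    if anchor_idx < n - 1:
        flips = rng.random((n_lines, n - 1 - anchor_idx)) < flip_p[anchor_idx:]
        g[:, anchor_idx + 1:] = g[:, [anchor_idx]] ^ (
            np.cumsum(flips, axis=1, dtype=np.int64) % 2
        ).astype(np.int8)
    if anchor_idx > 0:
        flips = rng.random((n_lines, anchor_idx)) < flip_p[:anchor_idx][::-1]
        left = g[:, [anchor_idx]] ^ (
            np.cumsum(flips, axis=1, dtype=np.int64) % 2
        ).astype(np.int8)
        g[:, :anchor_idx] = left[:, ::-1]
    return g


def simulate_bulks(scenario: SimScenario) -> tuple[list[BulkSnp], SimTruth]:
    """Simulate the two bulks' read counts at every marker.

    Deterministic for a fixed scenario seed.  Returns sorted, polarized
    :class:`BulkSnp` records (bulk A = high bulk, ALT = high allele) and
    the underlying true bulk allele frequencies.
    """
    rng = np.random.default_rng(scenario.seed)
    qtl_by_chrom = {q[0]: q for q in scenario.qtl}
    sites: list[BulkSnp] = []
    truth_rows = []

    for chrom, length in scenario.chromosomes:
        markers = np.arange(
            scenario.marker_spacing, length + 1, scenario.marker_spacing, dtype=np.int64
        )
        if len(markers) == 0:
            continue
        qtl = qtl_by_chrom.get(chrom)
        if qtl is not None:
            _, qpos, effect = qtl
            loci = np.unique(np.concatenate([markers, [qpos]]))
            anchor = int(np.searchsorted(loci, qpos))
            probs = {"high": effect, "low": 1.0 - effect}
        else:
            loci = markers
            anchor = 0
            probs = {"high": 0.5, "low": 0.5}

        freqs = {}
        for bulk in ("high", "low"):
            g = _walk_genotypes(
                rng, scenario.n_lines_per_bulk, loci, anchor, probs[bulk],
                scenario.recomb_rate,
            )
            het = rng.random(g.shape) < scenario.residual_het
            dosage = np.where(het, 0.5, g.astype(np.float64))
            keep = np.isin(loci, markers)
            freqs[bulk] = dosage[:, keep].mean(axis=0)

        n = len(markers)
        depths = {}
        for bulk in ("high", "low"):
            if scenario.depth_model == "fixed":
                depths[bulk] = np.full(n, int(round(scenario.mean_depth)), dtype=np.int64)
            else:
                depths[bulk] = rng.poisson(scenario.mean_depth, size=n)
        alt = {
            bulk: rng.binomial(depths[bulk], freqs[bulk]) for bulk in ("high", "low")
        }
        for i, pos in enumerate(markers):
            sites.append(
                BulkSnp(
                    chrom=chrom,
                    pos=int(pos),
                    ref_allele="A",
                    alt_allele="T",
                    depth_a_ref=int(depths["high"][i] - alt["high"][i]),
                    depth_a_alt=int(alt["high"][i]),
                    depth_b_ref=int(depths["low"][i] - alt["low"][i]),
                    depth_b_alt=int(alt["low"][i]),
                    polarized=True,
                )
            )
            truth_rows.append(
                {
                    "chrom": chrom,
                    "pos": int(pos),
                    "freq_high": float(freqs["high"][i]),
                    "freq_low": float(freqs["low"][i]),
                }
            )

    sites.sort(key=lambda s: (s.chrom, s.pos))
    truth = SimTruth(
        table=pd.DataFrame(truth_rows, columns=["chrom", "pos", "freq_high", "freq_low"]),
        causal=[(q[0], q[1]) for q in scenario.qtl],
    )
    return sites, truth


def write_truth(truth: SimTruth, path) -> None:
    truth.table.to_csv(path, sep="\t", index=False, float_format="%.6g")


def power_analysis(
    scenario_grid: Sequence[SimScenario],
    scan_config,
    n_reps: int,
    seed: int = 0,
    statistics: Sequence[str] = ("delta", "gprime", "ed4"),
    level: float = 0.95,
) -> pd.DataFrame:
    """Detection power and false-positive behaviour over a scenario grid.

    Per scenario and statistic: the fraction of replicates whose called
    intervals cover every true causal position, plus the rate of
    significant windows on QTL-free chromosomes (the false-positive
    side).  Scenario and scan seeds are derived from ``seed``.
    """
    from dataclasses import replace as dc_replace

    from .bsa_stats import stats_frame
    from .genome_scan import call_intervals, permutation_thresholds, window_scan

    total = len(scenario_grid) * n_reps * scan_config.n_permutations
    if total > POWER_PERMUTATION_CAP:
        warnings.warn(
            f"power grid requests {total:,} scenario x replicate x permutation "
            f"pipeline passes (cap {POWER_PERMUTATION_CAP:,}); expect a long run",
            stacklevel=2,
        )
    rows = []
    ss = np.random.SeedSequence(seed)
    for i_sc, scenario in enumerate(scenario_grid):
        covered = {s: 0 for s in statistics}
        fp_rates = {s: [] for s in statistics}
        for rep in range(n_reps):
            child = np.random.SeedSequence(entropy=seed, spawn_key=(i_sc, rep))
            sim_seed, scan_seed = (
                int(v) % (2 ** 31) for v in child.generate_state(2)
            )
            sites, truth = simulate_bulks(dc_replace(scenario, seed=sim_seed))
            stats = stats_frame(sites)
            cfg = dc_replace(scan_config, seed=scan_seed)
            windows = window_scan(stats, cfg)
            thresholds = permutation_thresholds(sites, cfg, statistics=statistics)
            qtl_chroms = {q[0] for q in scenario.qtl}
            for stat in statistics:
                intervals = call_intervals(windows, thresholds, stat, level)
                if truth.causal:
                    hit = all(
                        any(
                            iv.chrom == c and iv.start <= p <= iv.end
                            for iv in intervals
                        )
                        for c, p in truth.causal
                    )
                    covered[stat] += int(hit)
                null_windows = [w for w in windows if w.chrom not in qtl_chroms]
                if null_windows:
                    thr = thresholds.get(stat, level)
                    from .genome_scan import _window_value

                    n_sig = sum(
                        _window_value(w, stat) >= thr for w in null_windows
                    )
                    fp_rates[stat].append(n_sig / len(null_windows))
        for stat in statistics:
            rows.append(
                {
                    "scenario": i_sc,
                    "statistic": stat,
                    "n_reps": n_reps,
                    "n_qtl": len(scenario.qtl),
                    "coverage": (covered[stat] / n_reps) if (n_reps and scenario.qtl) else float("nan"),
                    "fp_window_rate": (
                        float(np.mean(fp_rates[stat])) if fp_rates[stat] else float("nan")
                    ),
                }
            )
    return pd.DataFrame(rows)
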