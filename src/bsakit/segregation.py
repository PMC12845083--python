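"""χ² goodness-of-fit tests for Mendelian segregation ratios.

Seed-coat phenotype counts from a segregating generation are tested
against the ratios expected when the trait is governed by *n* unlinked
genes acting as duplicates: a recessive phenotype class appears in
``1 : (4ⁿ − 1)`` of selfed progeny (1:3 for one gene, 1:15 for two
duplicate recessives, 1:63 for three, …), and symmetrically
``(4ⁿ − 1) : 1`` when the class of interest is dominant.

The Pearson statistic is used without continuity correction, with one
degree of freedom (two phenotype classes), and the p-value is the upper
tail of the χ²₁ distribution.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd
from scipy import stats as sps

__all__ = [
    "SegregationResult",
    "chi_square_ratio",
    "model_scan",
    "segregation_table",
]

CRITICAL_05_DF1 = float(sps.chi2.ppf(0.95, df=1))  # 3.841...


@dataclass(frozen=True)
class SegregationResult:
    observed: tuple[int, int]
    ratio: tuple[int, int]
    expected: tuple[float, float]
    chi2: float
    df: int
    p_value: float

    @property
    def significant_05(self) -> bool:
        return self.p_value < 0.05


def chi_square_ratio(
    observed: Sequence[int], ratio: Sequence[int]
) -> SegregationResult:
    """Pearson χ² of a two-class count against an a:b expected ratio.

    No Yates continuity correction is applied, df = 1.
    """
    obs = (int(observed[0]), int(observed[1]))
    rat = (int(ratio[0]), int(ratio[1]))
    total = obs[0] + obs[1]
    if total <= 0:
        raise ValueError("observed total must be positive")
    if rat[0] <= 0 or rat[1] <= 0:
        raise ValueError("ratio entries must be positive")
    denom = rat[0] + rat[1]
    expected = (total * rat[0] / denom, total * rat[1] / denom)
    chi2 = sum((o - e) ** 2 / e for o, e in zip(obs, expected))
    p = float(sps.chi2.sf(chi2, df=1))
    return SegregationResult(
        observed=obs, ratio=rat, expected=expected, chi2=float(chi2), df=1, p_value=p
    )


def model_scan(
    observed: Sequence[int],
    max_genes: int = 4,
    recessive_class: bool = True,
) -> list[SegregationResult]:
    """Test 1..max_genes duplicate-gene models for one count pair.

    With ``recessive_class`` the first observed count is the recessive
    class, expected in proportion 1 : (4ⁿ − 1); otherwise it is the
    dominant class, expected (4ⁿ − 1) : 1.
    """
    if not 1 <= max_genes <= 8:
        raise ValueError("max_genes must be in 1..8")
    out = []
    for n in range(1, max_genes + 1):
        rare = 4 ** n - 1
        ratio = (1, rare) if recessive_class else (rare, 1)
        out.append(chi_square_ratio(observed, ratio))
    return out


def segregation_table(
    entries: Sequence[tuple[str, tuple[int, int], bool]],
    max_genes: int = 4,
) -> pd.DataFrame:
    """Tabulate model scans for several phenotype contrasts.

    ``entries`` are (label, (count_of_interest, complement_count),
    recessive_class) triples; the result has one row per (label, n_genes)
    with the ratio, expected counts, χ², the 5% critical value and p.
    """
    rows = []
    for label, observed, recessive in entries:
        for n, res in enumerate(model_scan(observed, max_genes, recessive), start=1):
            rows.append(
                {
                    "phenotype": label,
                    "n_genes": n,
                    "observed": f"{res.observed[0]}:{res.observed[1]}",
                    "ratio": f"{res.ratio[0]}:{res.ratio[1]}",
                    "expected": f"{res.expected[0]:.4g}:{res.expected[1]:.4g}",
                    "chi2": res.chi2,
                    "chi2_crit_0.05": CRITICAL_05_DF1,
                    "p_value": res.p_value,
                }
            )
    return pd.DataFrame(rows)
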