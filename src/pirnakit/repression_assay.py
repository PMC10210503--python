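"""Egg-chamber silencing statistics.

Reporter silencing in the female germline is all-or-none per egg chamber
(ON/OFF variegation); repression is scored as the percentage of OFF chambers,
summarised per generation as the mean +/- SD across independent sublines.
Proportion uncertainty uses the Wilson score interval, which stays sensible
at the 0% and 100% extremes that actually occur in these assays.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint


@dataclass(frozen=True)
class EggChamberCount:
    """ON/OFF tally for one subline at one generation (stage-filtered upstream)."""

    lineage: str
    generation: int
    subline: str
    n_total: int
    n_repressed: int
    stage_window: tuple[int, int] | None = (8, 10)

    def __post_init__(self) -> None:
        if self.n_total <= 0:
            raise ValueError("n_total must be positive")
        if not 0 <= self.n_repressed <= self.n_total:
            raise ValueError("n_repressed must be within [0, n_total]")


def repression_percentage(
    c: EggChamberCount, alpha: float = 0.05
) -> tuple[float, tuple[float, float]]:
    """Percent repressed chambers with a Wilson 95% CI (both on the 0-100 scale)."""
    pct = 100.0 * c.n_repressed / c.n_total
    lo, hi = proportion_confint(c.n_repressed, c.n_total, alpha=alpha, method="wilson")
    return pct, (100.0 * lo, 100.0 * hi)


def subline_summary(counts: Iterable[EggChamberCount]) -> pd.DataFrame:
    """Per-generation mean and sample SD of subline repression percentages.

    With a single subline the mean is reported and the SD is NaN (flagged
    undefined rather than zero).
    """
    rows = []
    by_gen: dict[int, list[float]] = {}
    for c in counts:
        by_gen.setdefault(c.generation, []).append(
            100.0 * c.n_repressed / c.n_total
        )
    for g in sorted(by_gen):
        vals = np.asarray(by_gen[g])
        rows.append(
            {
                "generation": g,
                "n_sublines": vals.size,
                "mean_pct": float(vals.mean()),
                "sd_pct": float(vals.std(ddof=1)) if vals.size > 1 else math.nan,
            }
        )
    return pd.DataFrame(rows, columns=["generation", "n_sublines", "mean_pct", "sd_pct"])
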