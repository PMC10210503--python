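"""RT-qPCR and ChIP-qPCR quantification.

RT-qPCR: standard-curve quantities (Sq) are averaged over technical
triplicates (meanSq) and expressed as meanSq(gene)/meanSq(reference), with
RpL32 as the reference gene; group summaries are means of per-sample ratios.

ChIP-qPCR: the immunoprecipitated fraction is normalized against a diluted
input,

    dCt_normalized = meanCt[ChIP] - (meanCt[Input] - log2(input dilution factor)),

where the dilution factor is the reciprocal of the chromatin fraction set
aside as input (5% input -> factor 20).  Fold enrichment of the specific
antibody over the nonspecific (NS, IgG) control is

    fold_enrichment = 2 ** (dCt_ns - dCt_chip),

which is 1 for no enrichment and > 1 for specific signal.  Enrichments can
then be rescaled to a control region (42AB, a locus constitutively dense in
the assayed mark).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

REFERENCE_GENE = "RpL32"
CONTROL_REGION = "42AB"


@dataclass(frozen=True)
class RtQpcrSample:
    """One gene in one biological replicate, with a technical Sq triplicate."""

    sample_id: str
    gene: str
    sq: tuple[float, float, float]

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.sq):
            raise ValueError(f"{self.sample_id}/{self.gene}: Sq must be positive")

    @property
    def mean_sq(self) -> float:
        return sum(self.sq) / len(self.sq)


def rt_ratio(sample_gene: RtQpcrSample, sample_ref: RtQpcrSample) -> float:
    """meanSq(gene) / meanSq(reference) within one biological replicate."""
    if sample_gene.sample_id != sample_ref.sample_id:
        raise ValueError(
            f"replicate mismatch: {sample_gene.sample_id!r} vs {sample_ref.sample_id!r}"
        )
    return sample_gene.mean_sq / sample_ref.mean_sq


def rt_group_summary(ratios: Sequence[float]) -> tuple[float, float]:
    """Mean and sample SD of per-sample expression ratios."""
    arr = np.asarray(ratios, dtype=float)
    return float(arr.mean()), float(arr.std(ddof=1)) if arr.size > 1 else math.nan


@dataclass(frozen=True)
class ChipSample:
    """Mean Ct values for one target region in one ChIP biological sample."""

    sample_id: str
    target_region: str
    mean_ct_chip: float
    mean_ct_input: float
    mean_ct_ns: float
    input_fraction: float = 0.05

    def __post_init__(self) -> None:
        if not 0 < self.input_fraction <= 1:
            raise ValueError("input_fraction must be in (0, 1]")

    @property
    def dilution_factor(self) -> float:
        """Reciprocal of the chromatin fraction set aside for input."""
        return 1.0 / self.input_fraction


def chip_delta_ct(s: ChipSample, antibody: str = "target") -> float:
    """Input-normalized dCt for the specific ('target') or control ('ns') pulldown."""
    if antibody == "target":
        ct = s.mean_ct_chip
    elif antibody == "ns":
        ct = s.mean_ct_ns
    else:
        raise ValueError("antibody must be 'target' or 'ns'")
    return ct - (s.mean_ct_input - math.log2(s.dilution_factor))


def fold_enrichment(s: ChipSample) -> float:
    """2 ** (dCt_ns - dCt_chip): specific signal over the nonspecific control."""
    return 2.0 ** (chip_delta_ct(s, "ns") - chip_delta_ct(s, "target"))


def normalize_to_region(
    values: Mapping[str, float], control: str = CONTROL_REGION
) -> dict[str, float]:
    """Rescale per-region fold enrichments so the control region maps to 1."""
    if control not in values:
        raise KeyError(f"control region {control!r} missing")
    ref = values[control]
    if ref <= 0:
        raise ValueError(f"control region {control!r} has non-positive enrichment")
    return {region: v / ref for region, v in values.items()}


@dataclass
class GroupComparison:
    design: str
    statistic: float
    pvalue: float
    pairwise: "object | None" = None  # Tukey HSD results for the ANOVA design


def compare_groups(
    *groups: Sequence[float], design: str = "t_test_bilateral"
) -> GroupComparison:
    """Two-sided Welch t-test (two groups) or one-way ANOVA + Tukey HSD.

    The t-test deliberately does not assume equal variances; biological
    triplicates rarely justify that assumption.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size < 2 for a in arrays):
        raise ValueError("each group needs n >= 2")
    if design == "t_test_bilateral":
        if len(arrays) != 2:
            raise ValueError("t-test takes exactly two groups")
        a, b = arrays
        if np.array_equal(a, b) and a.std() == 0:
            # degenerate identical constant groups: no evidence of difference
            return GroupComparison(design, 0.0, 1.0)
        t, p = stats.ttest_ind(a, b, equal_var=False)
        return GroupComparison(design, float(t), float(p))
    if design == "anova_tukey":
        if len(arrays) < 2:
            raise ValueError("ANOVA needs at least two groups")
        pooled = np.concatenate(arrays)
        if np.ptp(pooled) == 0:
            # all observations identical: F is 0/0; report no difference
            return GroupComparison(design, 0.0, 1.0)
        f, p = stats.f_oneway(*arrays)
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        values = np.concatenate(arrays)
        labels = np.concatenate(
            [np.full(a.size, f"group{i}") for i, a in enumerate(arrays)]
        )
        tukey = pairwise_tukeyhsd(values, labels)
        return GroupComparison(design, float(f), float(p), pairwise=tukey)
    raise ValueError(f"unknown design {design!r}")
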