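"""Dual-luciferase reporter normalization and one-way ANOVA.

In a dual-luciferase assay each well co-expresses a firefly luciferase test
construct and a Renilla luciferase transfection control; the per-replicate
readout is the firefly/Renilla ratio, which cancels transfection efficiency.
Constructs (e.g. promoter-variant alleles) are then compared by one-way ANOVA
on the normalized ratios.  Each normalized ratio is treated as one
observation; how technical and biological replicates combine is left to the
caller.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError


@dataclass
class LuciferaseExperiment:
    """Per-replicate construct label, firefly and Renilla readings, ratio."""

    data: pd.DataFrame  # columns: construct, firefly, renilla, ratio

    def __post_init__(self) -> None:
        required = {"construct", "firefly", "renilla", "ratio"}
        if not required <= set(self.data.columns):
            raise ValidationError(f"experiment table needs columns {sorted(required)}")

    @property
    def constructs(self) -> list[str]:
        return list(dict.fromkeys(self.data["construct"]))

    def ratios_of(self, construct: str) -> np.ndarray:
        sel = self.data.loc[self.data["construct"] == construct, "ratio"]
        if sel.empty:
            raise ValidationError(f"no replicates for construct {construct!r}")
        return sel.to_numpy(dtype=float)

    def group_stats(self) -> pd.DataFrame:
        """Per-construct n, mean and SD of the normalized ratio."""
        return (
            self.data.groupby("construct", sort=False)["ratio"]
            .agg(n="count", mean="mean", sd="std")
            .reset_index()
        )


@dataclass
class AnovaResult:
    f_statistic: float
    p_value: float
    group_means: dict[str, float]


def normalize(raw: pd.DataFrame) -> LuciferaseExperiment:
    """Compute firefly/Renilla ratios from raw readings.

    ``raw`` must carry construct, firefly, renilla columns with positive
    readings; non-positive Renilla (or firefly) readings are a validation
    error because the ratio would be meaningless.
    """
    for col in ("construct", "firefly", "renilla"):
        if col not in raw.columns:
            raise ValidationError(f"raw readings lack column {col!r}")
    if (raw["renilla"] <= 0).any() or (raw["firefly"] <= 0).any():
        raise ValidationError("luciferase readings must be positive")
    data = raw.loc[:, ["construct", "firefly", "renilla"]].copy()
    data["ratio"] = data["firefly"] / data["renilla"]
    return LuciferaseExperiment(data)


def anova_oneway(exp: LuciferaseExperiment) -> AnovaResult:
    """One-way ANOVA on normalized ratios across constructs.

    F = MS_between / MS_within with p from the F(k-1, N-k) distribution.
    Requires >= 2 constructs with >= 2 replicates each.  If every group has
    zero within-group variance but the means differ, F is infinite and p = 0
    is reported with a warning; if the means are also equal, F = 0 and p = 1.
    """
    groups = [exp.ratios_of(c) for c in exp.constructs]
    if len(groups) < 2:
        raise ValidationError("ANOVA needs at least two constructs")
    if any(len(g) < 2 for g in groups):
        raise ValidationError("ANOVA needs >= 2 replicates per construct")

    means = {c: float(g.mean()) for c, g in zip(exp.constructs, groups)}
    grand = np.concatenate(groups).mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)

    if ss_within == 0.0:
        if ss_between == 0.0:
            return AnovaResult(0.0, 1.0, means)
        warnings.warn(
            "zero within-group variance with unequal means: p = 0", stacklevel=2
        )
        return AnovaResult(float("inf"), 0.0, means)

    f, p = stats.f_oneway(*groups)
    return AnovaResult(float(f), float(p), means)


def fold_change(
    exp: LuciferaseExperiment, reference_label: str, test_label: str
) -> float:
    """Ratio of group mean ratios, mean(test) / mean(reference)."""
    ref = exp.ratios_of(reference_label).mean()
    test = exp.ratios_of(test_label).mean()
    if ref == 0:
        raise ValidationError("reference group mean is zero; fold change undefined")
    return float(test / ref)
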