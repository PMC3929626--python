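"""Quantification conventions for isoform validation experiments.

Semi-quantitative RT-PCR / qPCR readouts are normalized to a
housekeeping reference (Gapdh or Hprt), compared between genotype or
treatment groups as signed linear folds (magnitude always >= 1, sign
giving direction), converted to percent splicing inclusion when two
isoform bands are measured, and tested with a two-sided pooled-variance
Student's t with the conventional star annotation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import ttest_ind


@dataclass
class IsoformMeasurement:
    sample_id: str
    group: str
    target_intensity: float
    reference_intensity: float
    isoform: str = ""

    def __post_init__(self) -> None:
        if self.target_intensity < 0:
            raise ValueError("intensities must be non-negative")
        if self.reference_intensity <= 0:
            raise ValueError("reference intensity must be positive")

    @property
    def normalized(self) -> float:
        return normalize_to_reference(self.target_intensity,
                                      self.reference_intensity)


def normalize_to_reference(target: float, reference: float) -> float:
    """Housekeeping normalization: target / reference."""
    if reference <= 0:
        raise ValueError("reference intensity must be positive")
    if target < 0:
        raise ValueError("target intensity must be non-negative")
    return target / reference


def signed_fold_change(group_a_mean: float, group_b_mean: float) -> float:
    """Signed linear fold of a vs b: +r when r = a/b >= 1, else -1/r."""
    if group_a_mean <= 0 or group_b_mean <= 0:
        raise ValueError("group means must be positive")
    r = group_a_mean / group_b_mean
    return r if r >= 1.0 else -1.0 / r


def percent_inclusion(included: float, skipped: float) -> float:
    """Percent splicing inclusion from two isoform intensities."""
    if included < 0 or skipped < 0:
        raise ValueError("intensities must be non-negative")
    total = included + skipped
    if total <= 0:
        raise ValueError("included + skipped must be positive")
    return 100.0 * included / total


def stars(p: float) -> str:
    """Significance stars: * p<0.05, ** p<0.01, *** p<0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def two_group_test(values_a, values_b, *, welch: bool = False,
                   ) -> tuple[float, float, str]:
    """Two-sided two-sample t-test with star annotation.

    Pooled-variance Student's t by default; ``welch=True`` drops the
    equal-variance assumption.  Identical groups give (0, 1, "").
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least two values per group")
    t, p = ttest_ind(a, b, equal_var=not welch)
    t, p = float(t), float(p)
    if np.isnan(t):  # zero variance in both groups, equal means
        t, p = 0.0, 1.0
    return t, p, stars(p)


def validation_report(measurements: list[IsoformMeasurement],
                      reference_group: str,
                      fold_of: str = "group_means") -> pd.DataFrame:
    """Per-group normalized means, s.e.m., signed folds vs the reference
    group, p-values and stars.

    ``fold_of`` chooses between the ratio of group means (default) and
    the mean of per-sample ratios.
    """
    df = pd.DataFrame(
        {
            "group": [m.group for m in measurements],
            "normalized": [m.normalized for m in measurements],
        }
    )
    ref_vals = df.loc[df["group"] == reference_group, "normalized"].to_numpy()
    if len(ref_vals) < 2:
        raise ValueError(f"reference group {reference_group!r} needs >= 2 samples")
    rows = []
    for grp, sub in df.groupby("group", sort=False):
        vals = sub["normalized"].to_numpy()
        mean = float(np.mean(vals))
        sem = float(np.std(vals, ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else np.nan
        if grp == reference_group:
            fold, p, star = 1.0, np.nan, ""
        else:
            if fold_of == "group_means":
                fold = signed_fold_change(mean, float(np.mean(ref_vals)))
            else:
                fold = float(np.mean(vals[:, None] / ref_vals[None, :]))
            _, p, star = two_group_test(vals, ref_vals)
        rows.append({"group": grp, "n": len(vals), "mean": mean, "sem": sem,
                     "fold_vs_ref": fold, "p_value": p, "stars": star})
    return pd.DataFrame(rows)
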