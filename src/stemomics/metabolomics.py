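"""Targeted-metabolite statistics: protein normalization, group comparison,
derived ratios and Z-score profiling.

Concentrations enter in pmol per 10^6 cells and are corrected by each
sample's protein mass (mg) before any statistic.  Group comparisons default
to the equal-variance Student t-test on untransformed normalized
concentrations (Welch and log2 transforms available by flag); the targeted
panel is reported with raw significance tiers (* p<0.05, ** p<0.01,
*** p<0.001) and Benjamini-Hochberg q-values only on request.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dataio import FeatureMatrix, SampleSheet

logger = logging.getLogger("stemomics")

__all__ = [
    "normalize_to_protein",
    "compare_groups",
    "metabolite_ratio",
    "zscore_profile",
    "ZScoreProfile",
    "significance_tier",
]

STATS_COLUMNS = ["mean_P", "mean_S", "fold_change", "t_stat", "p_value",
                 "significance_tier"]


def normalize_to_protein(raw: FeatureMatrix, sheet: SampleSheet) -> FeatureMatrix:
    """Divide each sample column by that sample's protein mass (mg)."""
    protein = []
    for s in raw.samples:
        try:
            protein.append(sheet.protein_for(s))
        except KeyError:
            raise ValueError(f"no protein mass for sample {s!r}") from None
    values = raw.values / np.asarray(protein)[None, :]
    return FeatureMatrix(list(raw.features), list(raw.samples), values, raw.kind)


def significance_tier(p: float) -> str:
    if np.isnan(p):
        return "ns"
    if p < 0.001:
        return "p<0.001"
    if p < 0.01:
        return "p<0.01"
    if p < 0.05:
        return "p<0.05"
    return "ns"


def _group_columns(mat: FeatureMatrix, sheet: SampleSheet, condition: str
                   ) -> np.ndarray:
    cols = [i for i, s in enumerate(mat.samples)
            if s in set(sheet.samples_in(condition))]
    if len(cols) < 2:
        raise ValueError(
            f"group {condition!r} has {len(cols)} samples in the matrix; "
            "need >= 2 for a comparison"
        )
    return mat.values[:, cols]


def compare_groups(
    norm: FeatureMatrix,
    sheet: SampleSheet,
    test: str = "student",
    *,
    log_transform: bool = False,
    fdr: bool = False,
) -> pd.DataFrame:
    """Two-sided S vs. P t-tests per metabolite.

    Returns a table indexed by metabolite with mean_P, mean_S,
    fold_change (= mean_S / mean_P), t_stat, p_value and the significance
    tier at 0.05 / 0.01 / 0.001.  ``test`` selects Student (equal-variance,
    default) or Welch.  Zero variance in both groups with equal means yields
    p = 1 by convention (logged).  ``fdr`` appends Benjamini-Hochberg
    q-values.
    """
    if test not in ("student", "welch"):
        raise ValueError(f"test must be 'student' or 'welch', got {test!r}")
    xp = _group_columns(norm, sheet, "P")
    xs = _group_columns(norm, sheet, "S")
    tvals = np.empty(len(norm.features))
    pvals = np.empty(len(norm.features))
    mean_p = xp.mean(axis=1)
    mean_s = xs.mean(axis=1)
    test_p, test_s = (np.log2(xp), np.log2(xs)) if log_transform else (xp, xs)
    for i in range(len(norm.features)):
        a, b = test_s[i], test_p[i]
        if np.isclose(a.var(ddof=1), 0) and np.isclose(b.var(ddof=1), 0):
            if np.isclose(a.mean(), b.mean()):
                tvals[i], pvals[i] = 0.0, 1.0
                logger.warning(
                    "metabolite %s: zero variance in both groups with equal "
                    "means; p = 1 by convention", norm.features[i],
                )
                continue
        t, p = stats.ttest_ind(a, b, equal_var=(test == "student"))
        tvals[i], pvals[i] = float(t), float(p)
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = mean_s / mean_p
    out = pd.DataFrame(
        {
            "mean_P": mean_p,
            "mean_S": mean_s,
            "fold_change": fold,
            "t_stat": tvals,
            "p_value": pvals,
            "significance_tier": [significance_tier(p) for p in pvals],
        },
        index=pd.Index(norm.features, name="metabolite"),
    )
    if fdr:
        from statsmodels.stats.multitest import multipletests

        out["q_value"] = multipletests(pvals, method="fdr_bh")[1]
    return out


def metabolite_ratio(norm: FeatureMatrix, numerator: str, denominator: str
                     ) -> pd.Series:
    """Per-sample ratio of two metabolites (e.g. NAAD+ / NAADP+)."""
    for m in (numerator, denominator):
        if m not in norm.features:
            raise ValueError(f"metabolite {m!r} not in matrix")
    num = norm.values[norm.features.index(numerator)]
    den = norm.values[norm.features.index(denominator)]
    zero = np.isclose(den, 0)
    if zero.any():
        bad = [s for s, z in zip(norm.samples, zero) if z]
        raise ValueError(f"denominator {denominator!r} is zero in samples {bad}")
    return pd.Series(num / den, index=pd.Index(norm.samples, name="sample_id"),
                     name=f"{numerator}/{denominator}")


@dataclass
class ZScoreProfile:
    """Per-metabolite standardization of every sample against a reference
    group's mean and SD; the reference group's own z-scores have mean 0 and
    sd 1 per metabolite by construction."""

    z: pd.DataFrame  # metabolites x samples
    reference_group: str
    excluded: list[str]  # zero-reference-sd metabolites, dropped


def zscore_profile(norm: FeatureMatrix, sheet: SampleSheet,
                   reference: str = "P") -> ZScoreProfile:
    if reference not in ("P", "S"):
        raise ValueError(f"reference must be 'P' or 'S', got {reference!r}")
    ref = _group_columns(norm, sheet, reference)
    mu = ref.mean(axis=1)
    sd = ref.std(axis=1, ddof=1)
    keep = ~np.isclose(sd, 0)
    excluded = [f for f, k in zip(norm.features, keep) if not k]
    for f in excluded:
        logger.warning("metabolite %s: zero reference-group sd; excluded from "
                       "z-score profile", f)
    z = (norm.values[keep] - mu[keep, None]) / sd[keep, None]
    frame = pd.DataFrame(
        z,
        index=pd.Index([f for f, k in zip(norm.features, keep) if k],
                       name="metabolite"),
        columns=norm.samples,
    )
    return ZScoreProfile(frame, reference, excluded)
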