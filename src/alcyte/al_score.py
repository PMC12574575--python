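"""Allostatic-load (AL) composite scoring and binary group assignment.

Two variants are implemented:

* **index** — each biomarker is dichotomized (0/1) against a clinical cutoff
  (optionally sex-stratified; risk may sit above or below the cutoff, e.g. low
  HDL cholesterol is the risky side) and the 0/1 values are summed. Samples
  with a score of at most two go to the low-AL group, above two to high-AL.
* **zscore** — the absolute z-scores of the configured biomarkers (the 14
  index markers plus additional panels, typically 25 in total) are summed;
  the high/low cutoff is the cohort's third quartile of summed scores.

Thresholds are data, supplied as a table (biomarker, sex, cutoff, risk_side);
the package ships no clinical cutoffs of its own.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

RISK_SIDES = ("above", "below")
ANY_SEX = "any"


@dataclass
class ALResult:
    """Per-sample AL scores and group labels.

    ``scores`` is indexed by sample; NaN marks samples with missing biomarkers
    (excluded from grouping). ``cutoff_used`` echoes the group cutoff so that
    alternative quantile conventions are auditable.
    """

    scores: pd.Series
    groups: pd.Series  # 'low' | 'high'; NaN-score samples absent
    method: str
    cutoff_used: float


def dichotomize(value: float, cutoff: float, risk_side: str, at_cutoff: int = 0) -> float:
    """Score one biomarker value against its clinical cutoff.

    Returns 1 iff the value is strictly on the risk side of the cutoff
    (``at_cutoff`` decides ties; the default 0 means a value exactly at the
    cutoff does not count as risk). Missing values propagate as NaN.
    """
    if risk_side not in RISK_SIDES:
        raise ValueError(f"risk_side must be one of {RISK_SIDES}, got {risk_side!r}")
    if not np.isfinite(cutoff):
        raise ValueError("cutoff must be numeric")
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return np.nan
    if value == cutoff:
        return float(at_cutoff)
    if risk_side == "above":
        return float(value > cutoff)
    return float(value < cutoff)


def _cutoff_for(thresholds: pd.DataFrame, biomarker: str, sex: str) -> pd.Series:
    rows = thresholds[thresholds["biomarker"] == biomarker]
    if rows.empty:
        raise ValueError(f"biomarker {biomarker!r} has no threshold entry")
    sexed = rows[rows["sex"] == sex]
    if len(sexed) == 1:
        return sexed.iloc[0]
    anyrow = rows[rows["sex"] == ANY_SEX]
    if len(anyrow) == 1:
        return anyrow.iloc[0]
    raise ValueError(f"no applicable cutoff for biomarker {biomarker!r}, sex {sex!r}")


def compute_index_score(
    panel: pd.DataFrame,
    thresholds: pd.DataFrame,
    biomarkers: list[str] | None = None,
    sex_column: str = "sex",
    at_cutoff: int = 0,
) -> pd.Series:
    """Sum of dichotomized biomarker values per sample (the index AL score).

    ``panel`` is samples × (biomarkers + covariates); ``thresholds`` has
    columns biomarker/sex/cutoff/risk_side with sex in {male, female, any}.
    Samples with any missing configured biomarker get a NaN score (they are
    excluded from grouping rather than imputed).
    """
    if biomarkers is None:
        biomarkers = [b for b in thresholds["biomarker"].unique() if b in panel.columns]
    missing_cols = [b for b in biomarkers if b not in panel.columns]
    if missing_cols:
        raise ValueError(f"panel lacks configured biomarkers: {missing_cols}")

    scores = pd.Series(0.0, index=panel.index)
    for sample, row in panel.iterrows():
        sex = row.get(sex_column, ANY_SEX)
        total = 0.0
        for b in biomarkers:
            t = _cutoff_for(thresholds, b, sex)
            d = dichotomize(row[b], float(t["cutoff"]), str(t["risk_side"]), at_cutoff)
            total += d  # NaN propagates through the sum
        scores[sample] = total
    return scores


def compute_zscore_al(
    panel: pd.DataFrame,
    biomarkers: list[str],
    reference_stats: pd.DataFrame | None = None,
) -> pd.Series:
    """Sum of absolute biomarker z-scores per sample.

    ``reference_stats`` (index=biomarker, columns mean/sd) defaults to the
    mean/SD of the supplied cohort, mirroring z-standardisation against the
    full study population. A zero SD is an error naming the biomarker.
    """
    missing_cols = [b for b in biomarkers if b not in panel.columns]
    if missing_cols:
        raise ValueError(f"panel lacks configured biomarkers: {missing_cols}")
    values = panel[biomarkers].astype(float)
    if reference_stats is None:
        reference_stats = pd.DataFrame(
            {"mean": values.mean(), "sd": values.std(ddof=1)}
        )
    zero_sd = [b for b in biomarkers if reference_stats.loc[b, "sd"] <= 0]
    if zero_sd:
        raise ValueError(f"zero standard deviation for biomarker(s): {zero_sd}")
    z = (values - reference_stats["mean"][biomarkers]) / reference_stats["sd"][biomarkers]
    return z.abs().sum(axis=1, skipna=False)


def assign_groups(
    scores: pd.Series,
    method: str = "index",
    index_cutoff: float = 2.0,
) -> ALResult:
    """Assign low/high AL groups.

    Index variant: low iff score ≤ ``index_cutoff`` (default two). Z-score
    variant: the cutoff is the third quartile of the cohort's scores (linear
    interpolation between order statistics); high iff score > cutoff. Samples
    with NaN scores are excluded from grouping.
    """
    if len(scores) == 0:
        raise ValueError("empty score vector")
    complete = scores.dropna()
    if method == "index":
        cutoff = float(index_cutoff)
    elif method == "zscore":
        cutoff = float(np.quantile(complete.to_numpy(), 0.75))
    else:
        raise ValueError(f"unknown method {method!r}")
    groups = pd.Series(
        np.where(complete > cutoff, "high", "low"), index=complete.index, name="group"
    )
    return ALResult(scores=scores, groups=groups, method=method, cutoff_used=cutoff)
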