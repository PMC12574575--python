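"""Methylation-matrix QC and expression-matrix gene mapping.

Probe filtering (sex chromosomes + blacklist), beta-based sex inference and
mismatch exclusion, probe-type-stratified quantile normalization, and
Ensembl-ID → symbol mapping/collapsing for the expression matrix.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, TransformerMixin

logger = logging.getLogger("alcyte")

SEX_CHROMS = {"X", "Y", "chrX", "chrY"}


def filter_probes(beta: pd.DataFrame, annotation: pd.DataFrame) -> pd.DataFrame:
    """Drop sex-chromosome and blacklisted probes from a CpG × sample matrix.

    Every probe must have an annotation row (columns ``chrom`` and
    ``blacklist``). A probe failing both filters is removed once but counted
    under both reasons.
    """
    missing = beta.index.difference(annotation.index)
    if len(missing):
        raise ValueError(f"probe missing annotation: {missing[0]!r}")
    ann = annotation.loc[beta.index]
    on_sex = ann["chrom"].astype(str).isin(SEX_CHROMS)
    blacklisted = ann["blacklist"].astype(bool)
    drop = on_sex | blacklisted
    logger.info(
        "filter_probes: removed %d (%d sex-chromosome, %d blacklisted), retained %d",
        int(drop.sum()), int(on_sex.sum()), int(blacklisted.sum()), int((~drop).sum()),
    )
    return beta.loc[~drop.to_numpy()]


def infer_sex(
    beta: pd.DataFrame,
    annotation: pd.DataFrame,
    female_window: tuple[float, float] = (0.35, 0.65),
) -> pd.DataFrame:
    """Predict sample sex from chrX beta values.

    X inactivation leaves female chrX probes at intermediate methylation, so a
    sample whose median chrX beta falls inside ``female_window`` is called
    female, otherwise male. Returns a frame with ``predicted_sex`` and the
    ``median_chrx_beta`` used for the call.
    """
    ann = annotation.loc[annotation.index.intersection(beta.index)]
    x_probes = ann.index[ann["chrom"].astype(str).isin({"X", "chrX"})]
    if len(x_probes) == 0:
        raise ValueError("no chrX probes available for sex inference")
    med = beta.loc[x_probes].median(axis=0)
    lo, hi = female_window
    sex = np.where((med >= lo) & (med <= hi), "female", "male")
    return pd.DataFrame({"predicted_sex": sex, "median_chrx_beta": med}, index=beta.columns)


def drop_sex_mismatches(predicted: pd.Series, reported: pd.Series) -> list[str]:
    """Return samples whose predicted sex matches the reported label.

    Samples present in only one of the two labelings are an error; an empty
    retention triggers a hard warning.
    """
    only = set(predicted.index).symmetric_difference(reported.index)
    if only:
        raise ValueError(f"sample present in only one sex labeling: {sorted(only)[0]!r}")
    reported = reported.loc[predicted.index]
    keep = [s for s in predicted.index if predicted[s] == reported[s]]
    n_drop = len(predicted) - len(keep)
    if n_drop:
        logger.info("drop_sex_mismatches: excluded %d sample(s) with sex mismatch", n_drop)
    if not keep:
        logger.warning("drop_sex_mismatches: ALL samples mismatched; retention is empty")
    return keep


class StratifiedQuantileNormalizer(BaseEstimator, TransformerMixin):
    """Quantile normalization within probe-type strata.

    Each probe belongs to exactly one stratum (e.g. Infinium type-I red/green
    vs type-II). Within a stratum, the reference distribution is the
    element-wise mean of the sorted values of the designated reference samples
    (all samples if none are designated); each sample's values are then mapped
    rank-for-rank onto that reference, so strata never influence one another
    and within-sample rank order is preserved. Strata with fewer than two
    probes pass through unchanged with a warning.

    Parameters
    ----------
    reference_samples : list of sample ids or None
        Samples whose averaged sorted values define the target distribution.
    """

    def __init__(self, reference_samples: list[str] | None = None):
        self.reference_samples = reference_samples

    def fit(self, beta: pd.DataFrame, annotation: pd.DataFrame | None = None):
        if annotation is None:
            raise ValueError("annotation with a 'stratum' column is required")
        missing = beta.index.difference(annotation.index)
        if len(missing):
            raise ValueError(f"probe missing annotation: {missing[0]!r}")
        strata = annotation.loc[beta.index, "stratum"]
        ref_cols = self.reference_samples or list(beta.columns)
        absent = [c for c in ref_cols if c not in beta.columns]
        if absent:
            raise ValueError(f"reference sample(s) not in matrix: {absent}")
        self.strata_ = strata
        self.targets_ = {}
        for stratum, probes in strata.groupby(strata).groups.items():
            if len(probes) < 2:
                logger.warning(
                    "stratum %r has <2 probes; passed through unchanged", stratum
                )
                self.targets_[stratum] = None
                continue
            ref = beta.loc[probes, ref_cols].to_numpy(float)
            self.targets_[stratum] = np.sort(ref, axis=0).mean(axis=1)
        return self

    def transform(self, beta: pd.DataFrame) -> pd.DataFrame:
        out = beta.copy().astype(float)
        for stratum, target in self.targets_.items():
            probes = self.strata_.index[self.strata_ == stratum]
            probes = probes.intersection(beta.index)
            if target is None or len(probes) < 2:
                continue
            sub = beta.loc[probes].to_numpy(float)
            m = len(target)
            for j in range(sub.shape[1]):
                col = sub[:, j]
                ranks = rankdata(col, method="average")
                # tie-aware mapping of ranks onto the sorted target distribution
                sub[:, j] = np.interp(ranks, np.arange(1, m + 1), target)
            out.loc[probes] = sub
        return out.clip(0.0, 1.0)


def quantile_normalize_stratified(
    beta: pd.DataFrame,
    annotation: pd.DataFrame,
    reference_samples: list[str] | None = None,
) -> pd.DataFrame:
    """Functional wrapper over :class:`StratifiedQuantileNormalizer`."""
    qn = StratifiedQuantileNormalizer(reference_samples=reference_samples)
    return qn.fit(beta, annotation).transform(beta)


def map_and_filter_genes(
    expr: pd.DataFrame,
    id_map: pd.Series,
    duplicate_policy: str = "sum",
) -> pd.DataFrame:
    """Map expression row ids to gene symbols; drop unmapped and empty rows.

    ``id_map`` maps source identifier → symbol (NaN/empty = unmapped). Rows
    mapping to the same symbol are collapsed (sum by default; ``first`` or
    ``max-mean`` alternatives). Rows with no observed value in any sample are
    dropped. All counts are logged.
    """
    missing = expr.index.difference(id_map.index)
    if len(missing):
        raise ValueError(f"expression identifier missing from gene-ID map: {missing[0]!r}")
    symbols = id_map.loc[expr.index]
    mapped = symbols.notna() & (symbols.astype(str).str.len() > 0)
    n_unmapped = int((~mapped).sum())
    expr = expr.loc[mapped.to_numpy()]
    symbols = symbols.loc[mapped.to_numpy()].astype(str)

    expr = expr.copy()
    expr.index = symbols.to_numpy()
    if duplicate_policy == "sum":
        expr = expr.groupby(level=0, sort=False).sum(min_count=1)
    elif duplicate_policy == "first":
        expr = expr[~expr.index.duplicated(keep="first")]
    elif duplicate_policy == "max-mean":
        order = expr.mean(axis=1, skipna=True)
        expr = expr.iloc[np.argsort(-order.to_numpy(), kind="stable")]
        expr = expr[~expr.index.duplicated(keep="first")]
        expr = expr.sort_index()
    else:
        raise ValueError(f"unknown duplicate_policy {duplicate_policy!r}")

    observed = expr.notna().any(axis=1)
    n_empty = int((~observed).sum())
    expr = expr.loc[observed]
    logger.info(
        "map_and_filter_genes: dropped %d unmapped, %d all-missing; %d genes retained",
        n_unmapped, n_empty, expr.shape[0],
    )
    return expr
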