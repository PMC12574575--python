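"""Per-cell-type methylation-state calling and methylation–expression association.

For each CpG, a 1–3 component beta mixture is fitted to the high-AL group's
(cell-type-resolved) beta values; components shifted by more than a beta-unit
threshold from the low-AL reference, and significantly so by rank-sum test,
label their member samples hypo- or hypermethylated. Each abnormal subset is
then tested for a coordinated shift in the linked gene's expression against
the normal-state high-AL samples pooled with the low-AL group — one-sided per
correlation mode (negative mode: hypermethylated subsets must be *lower* in
expression, hypomethylated subsets *higher*; positive mode reversed). P-values
are Benjamini–Hochberg adjusted jointly within one cell type × mode, and the
significant records are "functional CpG-gene pairs"; a CpG with both a passing
hypo and a passing hyper subset is *dual methylated*.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import betaln, polygamma, psi, zeta
from scipy.stats import mannwhitneyu
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger("alcyte")

_EPS = 1e-4
MODES = ("negative", "positive")
PAIR_COLUMNS = [
    "cpg", "gene", "cell_type", "mode", "state",
    "prev_hypo", "prev_hyper", "p_raw", "p_adj",
]


def _beta_logpdf(x: np.ndarray, a: float, b: float) -> np.ndarray:
    return (a - 1) * np.log(x) + (b - 1) * np.log1p(-x) - betaln(a, b)


def _moment_ab(mean: float, var: float) -> tuple[float, float]:
    mean = min(max(mean, _EPS), 1 - _EPS)
    var = max(min(var, mean * (1 - mean) * 0.99), 1e-6)
    common = mean * (1 - mean) / var - 1.0
    return max(mean * common, 0.01), max((1 - mean) * common, 0.01)


def _weighted_beta_mle(
    x: np.ndarray, r: np.ndarray, a0: float, b0: float, max_newton: int = 25
) -> tuple[float, float]:
    """Newton steps toward the weighted beta MLE from sufficient statistics.

    Warm-started from (a0, b0); inside EM a handful of steps per M-step is
    enough (generalized EM), which keeps the likelihood non-decreasing while
    avoiding a full inner solve.
    """
    wsum = r.sum()
    if wsum <= 0:
        return a0, b0
    s1 = float(r @ np.log(x)) / wsum
    s2 = float(r @ np.log1p(-x)) / wsum
    a, b = a0, b0
    for _ in range(max_newton):
        dg = psi(np.array([a, b, a + b]))
        g1 = dg[0] - dg[2] - s1
        g2 = dg[1] - dg[2] - s2
        tg = polygamma(1, np.array([a, b, a + b]))
        # Hessian [[tg_a - tg_ab, -tg_ab], [-tg_ab, tg_b - tg_ab]]
        h11 = tg[0] - tg[2]
        h22 = tg[1] - tg[2]
        h12 = -tg[2]
        det = h11 * h22 - h12 * h12
        if not np.isfinite(det) or abs(det) < 1e-300:
            break
        step_a = (h22 * g1 - h12 * g2) / det
        step_b = (h11 * g2 - h12 * g1) / det
        a_new = min(max(a - step_a, 0.01), 1e4)
        b_new = min(max(b - step_b, 0.01), 1e4)
        if not (np.isfinite(a_new) and np.isfinite(b_new)):
            break
        done = abs(a_new - a) < 1e-8 and abs(b_new - b) < 1e-8
        a, b = a_new, b_new
        if done:
            break
    return a, b


class BetaMixture(BaseEstimator):
    """Beta-component mixture fitted by expectation-maximization.

    Mixtures of 1..``max_components`` beta densities are fitted with
    ``n_starts`` quantile-anchored initialisations each; the model with the
    lowest Bayesian information criterion wins. Component means are reported
    sorted ascending. A constant input collapses to a single component.

    Attributes (after fit)
    ----------------------
    n_components_, weights_, means_, alphas_, betas_, bic_, loglik_,
    loglik_path_ (per-iteration log-likelihood of the winning run).
    """

    def __init__(self, max_components: int = 3, n_starts: int = 3,
                 max_iter: int = 50, tol: float = 1e-5):
        self.max_components = max_components
        self.n_starts = n_starts
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, values: np.ndarray):
        x = np.asarray(values, float)
        x = x[np.isfinite(x)]
        if len(x) < 10:
            raise ValueError(f"need ≥10 finite values, got {len(x)}")
        xc = np.clip(x, _EPS, 1 - _EPS)
        if np.ptp(x) < 1e-12:
            a, b = _moment_ab(float(xc[0]), 1e-6)
            self._adopt(np.array([1.0]), np.array([a]), np.array([b]), 0.0, [0.0], len(x))
            self.means_ = np.array([float(x[0])])
            return self

        # all component counts are fitted; BIC picks the order (a symmetric
        # dual CpG can look unimodal to k=2 yet resolve cleanly at k=3)
        best = None
        for k in range(1, self.max_components + 1):
            if k == 1:
                # single component: direct weighted MLE, no EM needed
                a0, b0 = _moment_ab(float(xc.mean()), float(xc.var() + 1e-9))
                a1, b1 = _weighted_beta_mle(xc, np.ones_like(xc), a0, b0)
                ll = float(_beta_logpdf(xc, a1, b1).sum())
                best_k = (-2 * ll + 2 * np.log(len(xc)), ll,
                          np.array([1.0]), np.array([a1]), np.array([b1]), [ll])
            else:
                best_k = None
                for start in range(self.n_starts):
                    fitres = self._em(xc, k, start)
                    if fitres is None:
                        continue
                    ll, w, a, b, path = fitres
                    npar = 3 * k - 1
                    bic = -2 * ll + npar * np.log(len(xc))
                    if best_k is None or bic < best_k[0]:
                        best_k = (bic, ll, w, a, b, path)
            if best_k is not None and (best is None or best_k[0] < best[0]):
                best = best_k
        bic, ll, w, a, b, path = best
        self._adopt(w, a, b, ll, path, len(xc))
        self.bic_ = bic
        return self

    def _adopt(self, w, a, b, ll, path, n):
        order = np.argsort(a / (a + b))
        self.weights_ = w[order]
        self.alphas_ = a[order]
        self.betas_ = b[order]
        self.means_ = (a / (a + b))[order]
        self.n_components_ = len(w)
        self.loglik_ = ll
        self.loglik_path_ = list(path)
        self.bic_ = -2 * ll + (3 * len(w) - 1) * np.log(n)

    def _em(self, x, k, start):
        n = len(x)
        lx = np.log(x)
        l1x = np.log1p(-x)
        # quantile-anchored start: contiguous blocks with shifted boundaries
        offsets = [0.0, 0.12, -0.12][start % 3]
        qs = np.clip((np.arange(1, k) / k) + offsets / k, 0.05, 0.95)
        cuts = np.quantile(x, qs) if k > 1 else np.array([])
        labels = np.searchsorted(cuts, x)
        a = np.empty(k)
        b = np.empty(k)
        w = np.empty(k)
        for c in range(k):
            sub = x[labels == c]
            if len(sub) < 2:
                sub = x
            a[c], b[c] = _moment_ab(float(sub.mean()), float(sub.var() + 1e-6))
            w[c] = max((labels == c).mean(), 1e-3)
        w /= w.sum()

        ll_prev = -np.inf
        path = []
        for _ in range(self.max_iter):
            logp = (
                np.log(w)[:, None]
                + (a - 1)[:, None] * lx[None, :]
                + (b - 1)[:, None] * l1x[None, :]
                - betaln(a, b)[:, None]
            )
            mx = logp.max(axis=0)
            lse = mx + np.log(np.exp(logp - mx).sum(axis=0))
            ll = float(lse.sum())
            path.append(ll)
            resp = np.exp(logp - lse)
            w = resp.mean(axis=1)
            w = np.clip(w, 1e-8, None)
            w /= w.sum()
            # M-step: a few vectorized Newton steps toward the weighted beta
            # MLE per component (generalized EM, warm-started)
            wsum = np.maximum(resp.sum(axis=1), 1e-12)
            s1 = (resp @ lx) / wsum
            s2 = (resp @ l1x) / wsum
            for _ in range(2):
                stacked = np.concatenate([a, b, a + b])
                dg = psi(stacked)
                tg = zeta(2, stacked)  # trigamma
                g1 = dg[:k] - dg[2 * k :] - s1
                g2 = dg[k : 2 * k] - dg[2 * k :] - s2
                h11 = tg[:k] - tg[2 * k :]
                h22 = tg[k : 2 * k] - tg[2 * k :]
                h12 = -tg[2 * k :]
                det = h11 * h22 - h12 * h12
                safe = np.where(np.abs(det) > 1e-300, det, 1.0)
                ok = np.isfinite(det) & (np.abs(det) > 1e-300)
                a = np.minimum(np.maximum(a - np.where(ok, (h22 * g1 - h12 * g2) / safe, 0.0), 0.01), 1e4)
                b = np.minimum(np.maximum(b - np.where(ok, (h11 * g2 - h12 * g1) / safe, 0.0), 0.01), 1e4)
            if np.isfinite(ll_prev) and abs(ll - ll_prev) <= self.tol * max(1.0, abs(ll_prev)):
                break
            ll_prev = ll
        if not np.isfinite(ll):
            return None
        return ll, w, a, b, path

    def predict(self, values: np.ndarray) -> np.ndarray:
        """Hard component assignment (index into ascending-mean components)."""
        x = np.clip(np.asarray(values, float), _EPS, 1 - _EPS)
        logp = np.stack([
            np.log(self.weights_[c]) + _beta_logpdf(x, self.alphas_[c], self.betas_[c])
            for c in range(self.n_components_)
        ])
        return logp.argmax(axis=0)


def fit_beta_mixture(values: np.ndarray, max_components: int = 3) -> BetaMixture:
    """Fit a 1–3 component beta mixture, choosing the order by BIC."""
    return BetaMixture(max_components=max_components).fit(values)


@dataclass
class StateCall:
    """Per-sample methylation states of one CpG in the high-AL group."""

    states: pd.Series  # high-AL sample → 'hypo' | 'normal' | 'hyper'
    prev_hypo: float
    prev_hyper: float
    dm_values: dict = field(default_factory=dict)  # component idx → mean − low reference
    low_reference: float = np.nan


def call_states(
    high_values: pd.Series,
    low_values: pd.Series,
    fit: BetaMixture | None = None,
    dm_threshold: float = 0.10,
    p_threshold: float = 0.05,
) -> StateCall:
    """Label each high-AL sample hypo/normal/hyper relative to the low-AL group.

    A mixture component is hypermethylated when its mean exceeds the low-AL
    mean by more than ``dm_threshold`` beta units *and* its member samples'
    betas are significantly higher than the low-AL betas by one-sided rank-sum
    test (hypomethylated symmetrically). Members of unlabeled components are
    'normal'. Prevalences are fractions of high-AL samples.
    """
    hv = high_values.dropna()
    lv = low_values.dropna().to_numpy(float)
    if fit is None:
        fit = fit_beta_mixture(hv.to_numpy(float))
    low_ref = float(lv.mean())
    assign = fit.predict(hv.to_numpy(float))
    labels = {}
    dm_values = {}
    for c in range(fit.n_components_):
        members = hv.to_numpy(float)[assign == c]
        if len(members) == 0:
            continue
        dm = fit.means_[c] - low_ref
        dm_values[c] = dm
        label = "normal"
        if dm > dm_threshold:
            p = mannwhitneyu(members, lv, alternative="greater").pvalue
            if p < p_threshold:
                label = "hyper"
        elif dm < -dm_threshold:
            p = mannwhitneyu(members, lv, alternative="less").pvalue
            if p < p_threshold:
                label = "hypo"
        labels[c] = label
    states = pd.Series(
        [labels.get(c, "normal") for c in assign], index=hv.index, name="state"
    )
    n = len(states)
    return StateCall(
        states=states,
        prev_hypo=float((states == "hypo").sum()) / n,
        prev_hyper=float((states == "hyper").sum()) / n,
        dm_values=dm_values,
        low_reference=low_ref,
    )


def pair_test(
    state: StateCall,
    expr_high: pd.Series,
    expr_low: pd.Series,
    mode: str,
    min_subset: int = 5,
) -> dict[str, float]:
    """One-sided expression tests for each abnormal methylation subset.

    Returns raw p-values keyed by state ('hypo'/'hyper') for subsets of at
    least ``min_subset`` samples. The baseline pools normal-state high-AL
    samples with all low-AL samples. Negative mode expects hypermethylated
    subsets to be LOWER in expression and hypomethylated subsets HIGHER;
    positive mode reverses both.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    expr_high = expr_high.reindex(state.states.index)
    normal_idx = state.states.index[state.states == "normal"]
    baseline = np.concatenate([
        expr_high.loc[normal_idx].dropna().to_numpy(float),
        expr_low.dropna().to_numpy(float),
    ])
    out: dict[str, float] = {}
    for st in ("hypo", "hyper"):
        idx = state.states.index[state.states == st]
        subset = expr_high.loc[idx].dropna().to_numpy(float)
        if len(subset) < min_subset or len(baseline) == 0:
            continue
        if mode == "negative":
            alternative = "less" if st == "hyper" else "greater"
        else:
            alternative = "greater" if st == "hyper" else "less"
        out[st] = float(
            mannwhitneyu(subset, baseline, alternative=alternative).pvalue
        )
    return out


def compute_states(
    cell_meth: pd.DataFrame,
    groups: pd.Series,
    dm_threshold: float = 0.10,
    p_threshold: float = 0.05,
) -> dict[str, StateCall]:
    """Fit mixtures and call states for every CpG of one cell type.

    Mode-independent, so the result can be shared between the negative and
    positive association passes.
    """
    high = groups.index[groups == "high"]
    low = groups.index[groups == "low"]
    high_mat = cell_meth[high]
    low_means = cell_meth[low].mean(axis=1)
    # screen: an abnormal component needs members beyond the shift threshold;
    # CpGs where <2 high-AL samples deviate from the low-AL mean by more than
    # dm_threshold are all-normal by construction and skip the mixture fit
    n_beyond = (high_mat.sub(low_means, axis=0).abs() > dm_threshold).sum(axis=1)
    calls: dict[str, StateCall] = {}
    for cpg in cell_meth.index:
        hv = high_mat.loc[cpg].dropna()
        lv = cell_meth.loc[cpg, low].dropna()
        if len(hv) < 10 or len(lv) < 10:
            continue
        if n_beyond[cpg] < 2:
            calls[cpg] = StateCall(
                states=pd.Series("normal", index=hv.index, name="state"),
                prev_hypo=0.0, prev_hyper=0.0,
                dm_values={}, low_reference=float(lv.mean()),
            )
            continue
        calls[cpg] = call_states(
            hv, lv, dm_threshold=dm_threshold, p_threshold=p_threshold
        )
    return calls


def _gene_links(probe_annotation: pd.DataFrame) -> list[tuple[str, str]]:
    links = []
    genes = probe_annotation["gene"].fillna("")
    for cpg, g in genes.items():
        for symbol in str(g).split(";"):
            symbol = symbol.strip()
            if symbol:
                links.append((cpg, symbol))
    return links


def run_mode(
    cell_meth: pd.DataFrame,
    cell_expr: pd.DataFrame,
    groups: pd.Series,
    probe_annotation: pd.DataFrame,
    mode: str,
    cell_type: str = "",
    alpha: float = 0.05,
    dm_threshold: float = 0.10,
    p_threshold: float = 0.05,
    min_subset: int | None = None,
    states: dict[str, StateCall] | None = None,
) -> pd.DataFrame:
    """All CpG-gene association tests of one cell type in one mode.

    P-values are Benjamini–Hochberg adjusted jointly across all subset tests
    of this cell type × mode; significant pairs are returned sorted by
    adjusted p. A CpG passing with both a hypo and a hyper subset gets state
    'dual'.
    """
    high = groups.index[groups == "high"]
    low = groups.index[groups == "low"]
    if min_subset is None:
        min_subset = max(5, int(np.ceil(0.05 * len(high))))
    if states is None:
        states = compute_states(cell_meth, groups, dm_threshold, p_threshold)

    links = [
        (cpg, gene) for cpg, gene in _gene_links(probe_annotation)
        if cpg in states and gene in cell_expr.index
    ]
    if not links:
        logger.warning("run_mode(%s, %s): no CpG-gene links to test", cell_type, mode)
        return pd.DataFrame(columns=PAIR_COLUMNS)

    records = []  # one per (cpg, gene, state) test
    for cpg, gene in links:
        sc = states[cpg]
        if sc.prev_hypo == 0 and sc.prev_hyper == 0:
            continue
        ps = pair_test(
            sc,
            cell_expr.loc[gene, high],
            cell_expr.loc[gene, low],
            mode,
            min_subset=min_subset,
        )
        for st, p in ps.items():
            records.append((cpg, gene, st, p, sc.prev_hypo, sc.prev_hyper))
    if not records:
        return pd.DataFrame(columns=PAIR_COLUMNS)

    rec = pd.DataFrame(records, columns=["cpg", "gene", "state", "p_raw", "prev_hypo", "prev_hyper"])
    rec["p_adj"] = multipletests(rec["p_raw"], method="fdr_bh")[1]
    sig = rec[rec["p_adj"] < alpha]

    rows = []
    for (cpg, gene), grp in sig.groupby(["cpg", "gene"], sort=False):
        passing = set(grp["state"])
        state = "dual" if {"hypo", "hyper"} <= passing else grp["state"].iloc[0]
        best = grp.loc[grp["p_adj"].idxmin()]
        rows.append({
            "cpg": cpg, "gene": gene, "cell_type": cell_type, "mode": mode,
            "state": state,
            "prev_hypo": best["prev_hypo"], "prev_hyper": best["prev_hyper"],
            "p_raw": best["p_raw"], "p_adj": best["p_adj"],
        })
    pairs = pd.DataFrame(rows, columns=PAIR_COLUMNS)
    return pairs.sort_values("p_adj", kind="stable").reset_index(drop=True)


def combine_modes(neg_pairs: pd.DataFrame, pos_pairs: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Concatenate negative- and positive-mode pairs, keeping the mode field.

    Returns the combined table plus summary counts (total pairs, unique CpGs,
    unique genes).
    """
    combined = pd.concat([neg_pairs, pos_pairs], ignore_index=True)
    summary = {
        "n_pairs": int(len(combined)),
        "n_unique_cpgs": int(combined["cpg"].nunique()) if len(combined) else 0,
        "n_unique_genes": int(combined["gene"].nunique()) if len(combined) else 0,
    }
    return combined, summary
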