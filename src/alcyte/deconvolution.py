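"""In-silico cell sorting of bulk signals.

Three estimators cover the deconvolution stage:

* :class:`CellProportionEstimator` — reference-based cell-fraction estimation
  from bulk expression against a gene × cell-type signature matrix (LM6-style,
  six peripheral-blood immune subsets) by non-negative least squares with
  renormalisation.
* :class:`ExpressionPurifier` — per-sample per-cell-type expression: shared
  cell-type profiles by per-gene NNLS on the proportion matrix, then
  proportion-weighted redistribution of each sample's residual.
* :class:`ReFACTor` — reference-free cell-composition surrogates: principal
  components of the sites best approximated by a low-rank structure.
* :class:`TCA` — tensor composition analysis: per-CpG model of bulk
  methylation as a proportion-weighted mixture of cell-type-level Gaussians,

      x_ij ~ N( Σ_h w_ih (μ_hj + c1_i·γ_hj) + c2_i·δ_j ,
                Σ_h w_ih² σ_hj² + τ_j² ),

  fitted by alternating weighted least squares on the mean parameters and
  bounded likelihood maximisation on the variances, then inverted per sample
  ("tensor") via the conditional expectation of the cell-level signal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize, nnls
from sklearn.base import BaseEstimator, TransformerMixin

logger = logging.getLogger("alcyte")


@dataclass
class CellTensor:
    """Feature × sample × cell-type signals as one frame per cell type."""

    values: dict[str, pd.DataFrame]
    modality: str  # 'methylation' | 'expression'

    def cell_types(self) -> list[str]:
        return list(self.values)

    def mixture(self, proportions: pd.DataFrame) -> pd.DataFrame:
        """Recombine the tensor into a bulk matrix: Σ_h w_ih ẑ_hij."""
        first = next(iter(self.values.values()))
        out = pd.DataFrame(0.0, index=first.index, columns=first.columns)
        for h, frame in self.values.items():
            out += frame * proportions[h].to_numpy()[None, :]
        return out


class CellProportionEstimator(BaseEstimator):
    """Estimate sample × cell-type fractions from bulk expression.

    Per sample, the bulk signature-gene vector is regressed on the signature
    columns by non-negative least squares; coefficients are renormalised to
    sum to one. At least ``min_overlap`` signature genes must be present in
    the bulk matrix (the intersection is taken and logged).

    Attributes (after fit)
    ----------------------
    proportions_ : DataFrame, samples × cell types, rows sum to 1
    residual_norms_ : Series, per-sample NNLS residual norm
    genes_used_ : list of signature genes found in the bulk matrix
    """

    def __init__(self, signature: pd.DataFrame | None = None, min_overlap: int = 10):
        self.signature = signature
        self.min_overlap = min_overlap

    def fit(self, bulk_expr: pd.DataFrame, y=None):
        sig = self.signature
        if sig is None:
            raise ValueError("a signature matrix is required")
        if sig.shape[1] < 2:
            raise ValueError("signature must cover at least two cell types")
        if (sig.sum(axis=1) == 0).any():
            raise ValueError("signature contains an all-zero gene row")
        genes = sig.index.intersection(bulk_expr.index)
        if len(genes) < self.min_overlap:
            raise ValueError(
                f"only {len(genes)} signature genes overlap the bulk matrix "
                f"(need ≥ {self.min_overlap})"
            )
        logger.info("estimate_proportions: %d/%d signature genes found", len(genes), len(sig))
        A = sig.loc[genes].to_numpy(float)
        B = bulk_expr.loc[genes].to_numpy(float)
        n_types = A.shape[1]
        props = np.zeros((B.shape[1], n_types))
        resid = np.zeros(B.shape[1])
        for i in range(B.shape[1]):
            coef, rnorm = nnls(A, B[:, i])
            total = coef.sum()
            props[i] = coef / total if total > 0 else np.full(n_types, 1.0 / n_types)
            resid[i] = rnorm
        self.genes_used_ = list(genes)
        self.proportions_ = pd.DataFrame(props, index=bulk_expr.columns, columns=sig.columns)
        self.residual_norms_ = pd.Series(resid, index=bulk_expr.columns)
        return self


def estimate_proportions(
    bulk_expr: pd.DataFrame, signature: pd.DataFrame, min_overlap: int = 10
) -> pd.DataFrame:
    """Functional wrapper over :class:`CellProportionEstimator`."""
    est = CellProportionEstimator(signature=signature, min_overlap=min_overlap)
    return est.fit(bulk_expr).proportions_


class ExpressionPurifier(BaseEstimator, TransformerMixin):
    """Per-sample per-cell-type expression from bulk + proportions.

    Step 1 fits, per gene, shared cell-type profiles g_h by NNLS of the gene's
    bulk values across samples on the proportion matrix. Step 2 redistributes
    each sample's residual x_ij − Σ_h w_ih g_hj to cell types proportionally
    to w_ih·g_hj (proportional to w_ih when all profiles are zero), which
    reduces to a per-sample multiplicative rescaling of the profiles; results
    are clamped at zero. The mixture Σ_h w_ih ẑ_hij reconstitutes the bulk
    (up to clamping).
    """

    def __init__(self):
        pass

    def fit(self, bulk_expr: pd.DataFrame, proportions: pd.DataFrame):
        if list(proportions.index) != list(bulk_expr.columns):
            proportions = proportions.loc[bulk_expr.columns]
        W = proportions.to_numpy(float)  # n × H
        X = bulk_expr.to_numpy(float)  # g × n
        X = np.nan_to_num(X, nan=0.0)
        H = W.shape[1]
        profiles = np.zeros((X.shape[0], H))
        for j in range(X.shape[0]):
            profiles[j], _ = nnls(W, X[j])
        self.profiles_ = pd.DataFrame(
            profiles, index=bulk_expr.index, columns=proportions.columns
        )
        silent = proportions.columns[(W.sum(axis=0) == 0)]
        for h in silent:
            logger.warning(
                "purify_expression: cell type %r has zero proportion everywhere; "
                "its slice equals the shared profile", h,
            )
        self._W = W
        self._columns = list(proportions.columns)
        return self

    def transform(self, bulk_expr: pd.DataFrame) -> CellTensor:
        W = self._W
        G = self.profiles_.to_numpy(float)  # g × H
        X = np.nan_to_num(bulk_expr.to_numpy(float), nan=0.0)
        fitted = G @ W.T  # g × n
        resid = X - fitted
        slices: dict[str, pd.DataFrame] = {}
        wsum = W.sum(axis=1)  # rows sum to 1 but stay robust
        for h, name in enumerate(self._columns):
            w_h = W[:, h]  # n
            g_h = G[:, [h]]  # g × 1
            z = np.tile(g_h, (1, X.shape[1]))
            pos = fitted > 0
            # share w_h·g_h of the residual, i.e. multiplicative rescaling
            np.divide(g_h * X, fitted, out=z, where=pos)
            # all-zero profiles: residual split proportionally to w alone
            zero_prof = ~pos & (w_h[None, :] > 0)
            if zero_prof.any():
                alloc = resid * (w_h / np.where(wsum > 0, wsum, 1.0))[None, :]
                z[zero_prof] = (g_h + alloc / np.where(w_h > 0, w_h, 1.0)[None, :])[zero_prof]
            # zero-weight samples carry no residual: slice = shared profile
            z[:, w_h == 0] = g_h
            slices[name] = pd.DataFrame(
                np.clip(z, 0.0, None), index=bulk_expr.index, columns=bulk_expr.columns
            )
        return CellTensor(values=slices, modality="expression")


def purify_expression(bulk_expr: pd.DataFrame, proportions: pd.DataFrame) -> CellTensor:
    """Functional wrapper over :class:`ExpressionPurifier`."""
    return ExpressionPurifier().fit(bulk_expr, proportions).transform(bulk_expr)


class ReFACTor(BaseEstimator, TransformerMixin):
    """Reference-free cell-composition components.

    Sites are standardised, technical covariates regressed out, and each site
    scored by the distance between its standardised vector and its rank-``k``
    principal-subspace reconstruction; the ``t`` lowest-error sites are
    selected and the first ``k`` principal components of the selected
    submatrix become per-sample composition surrogates.
    """

    def __init__(self, k: int = 6, t: int = 500):
        self.k = k
        self.t = t

    def fit(self, beta: pd.DataFrame, covariates: pd.DataFrame | None = None):
        n_sites, n_samples = beta.shape
        if self.k >= n_samples:
            raise ValueError(f"k={self.k} must be smaller than the number of samples")
        if self.k >= n_sites:
            raise ValueError(f"k={self.k} must be smaller than the number of sites")
        t = min(self.t, n_sites)

        X = beta.to_numpy(float)
        sd = X.std(axis=1, ddof=0)
        keep = sd > 0
        X = (X[keep] - X[keep].mean(axis=1, keepdims=True)) / sd[keep, None]
        site_ids = beta.index[keep]

        if covariates is not None and covariates.shape[1] > 0:
            C = np.column_stack(
                [np.ones(n_samples), covariates.loc[beta.columns].to_numpy(float)]
            )
            hat = C @ np.linalg.pinv(C)
            X = X - X @ hat.T

        U, s, Vt = np.linalg.svd(X, full_matrices=False)
        Xk = (U[:, : self.k] * s[: self.k]) @ Vt[: self.k]
        errors = np.linalg.norm(X - Xk, axis=1)
        order = np.argsort(errors, kind="stable")[:t]
        self.selected_sites_ = list(site_ids[order])
        self.site_errors_ = pd.Series(errors, index=site_ids)

        sel = X[order]  # t × n, already standardised/adjusted
        Us, ss, Vts = np.linalg.svd(sel - sel.mean(axis=1, keepdims=True), full_matrices=False)
        comps = (Vts[: self.k] * ss[: self.k, None]).T  # samples × k
        self.components_ = pd.DataFrame(
            comps, index=beta.columns, columns=[f"RC{i+1}" for i in range(self.k)]
        )
        return self

    def transform(self, beta: pd.DataFrame | None = None) -> pd.DataFrame:
        return self.components_


def refactor_components(
    beta: pd.DataFrame,
    k: int = 6,
    t: int = 500,
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Functional wrapper over :class:`ReFACTor`; returns sample × component scores."""
    return ReFACTor(k=k, t=t).fit(beta, covariates).components_


@dataclass
class TCAModel:
    """Per-CpG parameters of the tensor-composition model."""

    mu: pd.DataFrame  # CpG × cell type means, clipped to [0,1]
    sigma: pd.DataFrame  # CpG × cell type SDs (≥ 0)
    tau: pd.Series  # per-CpG residual noise scale (≥ 0)
    gamma: np.ndarray | None  # CpG × cell type × c1-covariate effects
    delta: np.ndarray | None  # CpG × c2-covariate effects
    cell_types: list[str] = field(default_factory=list)
    c1_names: list[str] = field(default_factory=list)
    c2_names: list[str] = field(default_factory=list)
    loglik: pd.Series | None = None


def _encode_covariates(cov: pd.DataFrame | None, samples: pd.Index) -> tuple[np.ndarray, list[str]]:
    if cov is None or cov.shape[1] == 0:
        return np.zeros((len(samples), 0)), []
    cov = cov.loc[samples]
    enc = pd.get_dummies(cov, drop_first=True, dtype=float)
    return enc.to_numpy(float), list(enc.columns)


class TCA(BaseEstimator):
    """Tensor composition analysis of bulk methylomes.

    Fits, independently per CpG, cell-type means/SDs plus cell-level (c1) and
    global (c2) covariate effects by alternating generalised least squares on
    the mean parameters and bounded likelihood maximisation on the variance
    parameters (σ_hj, τ_j), iterated to relative log-likelihood change below
    ``tol`` or ``max_iter`` alternations. Cell fractions are supplied
    externally (e.g. from expression-based deconvolution) and are not refit.
    """

    def __init__(self, max_iter: int = 100, tol: float = 1e-6, track_paths: bool = False):
        self.max_iter = max_iter
        self.tol = tol
        self.track_paths = track_paths

    def fit(
        self,
        beta: pd.DataFrame,
        proportions: pd.DataFrame,
        c1: pd.DataFrame | None = None,
        c2: pd.DataFrame | None = None,
    ):
        samples = beta.columns
        W = proportions.loc[samples].to_numpy(float)  # n × H
        n, H = W.shape
        C1, c1_names = _encode_covariates(c1, samples)
        C2, c2_names = _encode_covariates(c2, samples)
        P, Q = C1.shape[1], C2.shape[1]

        # shared design: [W | w_h·c1_p for each h,p | c2]
        blocks = [W]
        for p in range(P):
            blocks.append(W * C1[:, [p]])
        if Q:
            blocks.append(C2)
        X = np.column_stack(blocks)
        A = np.column_stack([W**2, np.ones(n)])  # var_i = A @ (σ²_1..σ²_H, τ²)

        n_cpg = beta.shape[0]
        mu = np.zeros((n_cpg, H))
        sigma = np.zeros((n_cpg, H))
        tau = np.zeros(n_cpg)
        gamma = np.zeros((n_cpg, H, P)) if P else None
        delta = np.zeros((n_cpg, Q)) if Q else None
        logliks = np.zeros(n_cpg)

        Y = beta.to_numpy(float)
        self.ll_paths_ = {} if self.track_paths else None
        for j in range(n_cpg):
            y = Y[j]
            if not np.all(np.isfinite(y)):
                raise ValueError(f"non-finite values at CpG {beta.index[j]!r}")
            coef, v, ll, path = self._fit_one(X, A, y, H)
            if self.track_paths:
                self.ll_paths_[beta.index[j]] = path
            if not np.isfinite(ll):
                raise ValueError(f"non-finite likelihood at CpG {beta.index[j]!r}")
            mu[j] = np.clip(coef[:H], 0.0, 1.0)
            if P:
                gamma[j] = coef[H : H + H * P].reshape(P, H).T
            if Q:
                delta[j] = coef[H + H * P :]
            sigma[j] = np.sqrt(v[:H])
            tau[j] = np.sqrt(v[H])
            logliks[j] = ll

        cts = list(proportions.columns)
        self.model_ = TCAModel(
            mu=pd.DataFrame(mu, index=beta.index, columns=cts),
            sigma=pd.DataFrame(sigma, index=beta.index, columns=cts),
            tau=pd.Series(tau, index=beta.index),
            gamma=gamma,
            delta=delta,
            cell_types=cts,
            c1_names=c1_names,
            c2_names=c2_names,
            loglik=pd.Series(logliks, index=beta.index),
        )
        self._W = W
        self._C1 = C1
        self._C2 = C2
        return self

    def _fit_one(self, X, A, y, H):
        n = len(y)
        var = np.full(n, max(y.var(), 1e-6))
        v = np.full(A.shape[1], max(y.var(), 1e-6) / A.shape[1])
        ll_prev = -np.inf
        coef = np.zeros(X.shape[1])
        path = []
        for _ in range(self.max_iter):
            sw = 1.0 / np.sqrt(var)
            coef, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
            e2 = (y - X @ coef) ** 2

            def nll(vv):
                var_i = A @ vv
                return 0.5 * np.sum(np.log(var_i) + e2 / var_i)

            def grad(vv):
                var_i = A @ vv
                g = 0.5 * (1.0 / var_i - e2 / var_i**2)
                return A.T @ g

            res = minimize(
                nll, v, jac=grad, method="L-BFGS-B",
                bounds=[(1e-10, None)] * A.shape[1],
            )
            v = res.x
            var = A @ v
            ll = -0.5 * np.sum(np.log(2 * np.pi * var) + e2 / var)
            path.append(ll)
            if ll_prev > -np.inf and abs(ll - ll_prev) <= self.tol * max(1.0, abs(ll_prev)):
                ll_prev = ll
                break
            ll_prev = ll
        return coef, v, ll_prev, path

    def tensor(self, beta: pd.DataFrame) -> CellTensor:
        """Per-sample per-cell-type methylomes from the fitted model.

        ẑ_hij is the conditional expectation of the cell-level signal given
        the bulk observation:

            ẑ_hij = μ′_hij + w_ih σ²_hj / (Σ_l w²_il σ²_lj + τ²_j) · (x_ij − m_ij)

        where μ′ folds in cell-level covariate effects and m_ij is the full
        model mean. Entries are clipped to [0, 1].
        """
        m = self.model_
        W = self._W  # n × H
        Y = beta.to_numpy(float)  # j × n
        n, H = W.shape
        mu = m.mu.to_numpy(float)  # j × H
        sig2 = m.sigma.to_numpy(float) ** 2
        tau2 = m.tau.to_numpy(float) ** 2

        slices = {h: np.zeros_like(Y) for h in range(H)}
        # μ′_hij = μ_hj + Σ_p γ_hjp c1_ip
        mu_prime = np.broadcast_to(mu[:, None, :], (Y.shape[0], n, H)).copy()
        if m.gamma is not None and self._C1.shape[1]:
            mu_prime += np.einsum("jhp,ip->jih", m.gamma, self._C1)
        mean_bulk = np.einsum("ih,jih->ji", W, mu_prime)
        if m.delta is not None and self._C2.shape[1]:
            mean_bulk += m.delta @ self._C2.T
        denom = (W**2) @ sig2.T + tau2[None, :]  # n × j
        resid = Y - mean_bulk  # j × n
        for h in range(H):
            shrink = (W[:, h][None, :] * sig2[:, [h]]) / denom.T  # j × n
            slices[h] = np.clip(mu_prime[:, :, h] + shrink * resid, 0.0, 1.0)
        values = {
            ct: pd.DataFrame(slices[h], index=beta.index, columns=beta.columns)
            for h, ct in enumerate(m.cell_types)
        }
        return CellTensor(values=values, modality="methylation")


def fit_tca(
    beta: pd.DataFrame,
    proportions: pd.DataFrame,
    c1: pd.DataFrame | None = None,
    c2: pd.DataFrame | None = None,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> TCA:
    """Fit the per-CpG tensor-composition model; returns the fitted estimator."""
    return TCA(max_iter=max_iter, tol=tol).fit(beta, proportions, c1=c1, c2=c2)


def tca_tensor(beta: pd.DataFrame, fitted: TCA) -> CellTensor:
    """Functional wrapper: generate the per-cell-type methylome tensor."""
    return fitted.tensor(beta)
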