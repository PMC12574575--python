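import itertools

import numpy as np
import pandas as pd
import pytest

from alcyte import deconvolution as dec
from alcyte.simulate import SimConfig, generate_cohort


@pytest.fixture(scope="module")
def signature(rng=np.random.default_rng(1)):
    genes = [f"G{i}" for i in range(40)]
    sig = pd.DataFrame(
        rng.lognormal(4, 1, size=(40, 3)), index=genes, columns=["A", "B", "C"]
    )
    return sig


class TestEstimateProportions:
    def test_pure_sample_gets_unit_vector(self, signature):
        bulk = signature[["A"]].rename(columns={"A": "s1"})
        props = dec.estimate_proportions(bulk, signature)
        assert props.loc["s1", "A"] == pytest.approx(1.0, abs=1e-8)
        assert props.loc["s1", ["B", "C"]].abs().max() < 1e-8

    def test_exact_mixture_recovered(self, signature):
        bulk = pd.DataFrame(
            {"s1": 0.5 * signature["A"] + 0.5 * signature["B"]}, index=signature.index
        )
        props = dec.estimate_proportions(bulk, signature)
        assert props.loc["s1", "A"] == pytest.approx(0.5, abs=1e-8)
        assert props.loc["s1", "B"] == pytest.approx(0.5, abs=1e-8)
        assert props.loc["s1", "C"] == pytest.approx(0.0, abs=1e-8)

    def test_rows_sum_to_one_nonnegative(self, signature, rng):
        mix = rng.dirichlet((2, 3, 4), size=8)
        bulk = pd.DataFrame(
            signature.to_numpy() @ mix.T * rng.lognormal(0, 0.1, (40, 8)),
            index=signature.index, columns=[f"s{i}" for i in range(8)],
        )
        props = dec.estimate_proportions(bulk, signature)
        assert (props.to_numpy() >= 0).all()
        assert np.allclose(props.sum(axis=1), 1.0, atol=1e-8)

    def test_matches_grid_search_on_noiseless_toys(self, signature, rng):
        """NNLS agrees with an exhaustive 0.01-step simplex grid search."""
        grid = [
            (a / 100, b / 100, 1 - a / 100 - b / 100)
            for a, b in itertools.product(range(101), range(101))
            if a + b <= 100
        ]
        A = signature.to_numpy()
        for true_w in [(0.2, 0.3, 0.5), (0.7, 0.1, 0.2), (0.0, 0.45, 0.55)]:
            y = A @ np.array(true_w)
            best = min(grid, key=lambda w: np.sum((y - A @ np.array(w)) ** 2))
            bulk = pd.DataFrame({"s": y}, index=signature.index)
            est = dec.estimate_proportions(bulk, signature).loc["s"].to_numpy()
            assert np.abs(est - np.array(best)).max() <= 0.01 + 1e-9

    def test_insufficient_overlap_errors(self, signature):
        bulk = pd.DataFrame({"s1": [1.0] * 5}, index=[f"G{i}" for i in range(5)])
        with pytest.raises(ValueError, match="signature genes"):
            dec.estimate_proportions(bulk, signature)


class TestPurifyExpression:
    def test_noiseless_shared_profiles_recovered(self, rng):
        genes = [f"G{i}" for i in range(30)]
        profiles = pd.DataFrame(rng.lognormal(3, 1, (30, 3)), index=genes,
                                columns=["A", "B", "C"])
        W = rng.dirichlet((3, 3, 3), size=12)
        props = pd.DataFrame(W, index=[f"s{i}" for i in range(12)],
                             columns=["A", "B", "C"])
        bulk = pd.DataFrame(profiles.to_numpy() @ W.T, index=genes,
                            columns=props.index)
        tensor = dec.purify_expression(bulk, props)
        for ct in ["A", "B", "C"]:
            assert np.allclose(
                tensor.values[ct].to_numpy(),
                np.tile(profiles[ct].to_numpy()[:, None], (1, 12)),
                atol=1e-6,
            )

    def test_zero_weight_sample_gets_shared_profile(self, rng):
        genes = [f"G{i}" for i in range(10)]
        profiles = rng.lognormal(3, 0.5, (10, 2))
        W = np.array([[1.0, 0.0], [0.0, 1.0], [0.5, 0.5]])
        props = pd.DataFrame(W, index=["s0", "s1", "s2"], columns=["A", "B"])
        bulk = pd.DataFrame(profiles @ W.T, index=genes, columns=props.index)
        tensor = dec.purify_expression(bulk, props)
        fitted_profile_B = dec.ExpressionPurifier().fit(bulk, props).profiles_["B"]
        # sample s0 has zero weight on B: its slice equals the shared profile
        assert np.allclose(tensor.values["B"]["s0"], fitted_profile_B, atol=1e-8)

    def test_mixture_reconstitutes_bulk(self, rng):
        genes = [f"G{i}" for i in range(25)]
        profiles = rng.lognormal(3, 1, (25, 3))
        W = rng.dirichlet((4, 2, 3), size=15)
        props = pd.DataFrame(W, index=[f"s{i}" for i in range(15)],
                             columns=["A", "B", "C"])
        bulk = pd.DataFrame(
            profiles @ W.T * rng.lognormal(0, 0.15, (25, 15)),
            index=genes, columns=props.index,
        )
        tensor = dec.purify_expression(bulk, props)
        recon = tensor.mixture(props)
        assert np.allclose(recon.to_numpy(), bulk.to_numpy(), rtol=1e-6, atol=1e-8)

    def test_planted_shift_direction_recovered(self, rng):
        """A sample-specific two-fold up-shift in an abundant cell type keeps
        its direction in the purified slice for most replicates."""
        hits = 0
        n_seeds = 20
        for seed in range(n_seeds):
            r = np.random.default_rng(seed)
            genes = [f"G{i}" for i in range(20)]
            profiles = r.lognormal(3, 1, (20, 3))
            W = r.dirichlet((8, 4, 4), size=50)  # cell A abundant (w >= 0.4 typical)
            cell = profiles[:, :, None] * np.exp(r.normal(0, 0.1, (20, 3, 50)))
            cell[5, 0, 7] *= 2.0  # plant: gene 5, cell A, sample 7
            bulk = pd.DataFrame(np.einsum("ih,ghi->gi", W, cell), index=genes,
                                columns=[f"s{i}" for i in range(50)])
            props = pd.DataFrame(W, index=bulk.columns, columns=["A", "B", "C"])
            tensor = dec.purify_expression(bulk, props)
            slice_a = tensor.values["A"]
            others = slice_a.loc["G5"].drop("s7")
            if slice_a.loc["G5", "s7"] > others.mean():
                hits += 1
        assert hits >= 0.9 * n_seeds


class TestReFACTor:
    def test_exact_low_rank_sites_have_tiny_error(self, rng):
        # rank-2 mixture: every site is exactly reconstructed at k=2
        n_sites, n_samples, k = 60, 30, 2
        basis = rng.random((k, n_samples))
        loads = rng.random((n_sites, k))
        beta = pd.DataFrame(loads @ basis, index=[f"cg{i}" for i in range(n_sites)],
                            columns=[f"s{i}" for i in range(n_samples)])
        model = dec.ReFACTor(k=k, t=20).fit(beta)
        assert model.site_errors_[model.selected_sites_].max() < 1e-8

    def test_sample_permutation_equivariance(self, rng):
        beta = pd.DataFrame(rng.random((50, 20)),
                            index=[f"cg{i}" for i in range(50)],
                            columns=[f"s{i}" for i in range(20)])
        comps = dec.refactor_components(beta, k=3, t=30)
        perm = rng.permutation(beta.columns)
        comps_p = dec.refactor_components(beta[perm], k=3, t=30)
        # same components (up to sign) in permuted row order
        for c in comps.columns:
            a = comps.loc[perm, c].to_numpy()
            b = comps_p[c].to_numpy()
            assert np.allclose(a, b, atol=1e-8) or np.allclose(a, -b, atol=1e-8)

    def test_components_track_cell_composition(self):
        cfg = SimConfig(n_samples=120, n_cpgs=400, n_genes=200, n_high=40,
                        n_signature_genes=60, meth_noise_sd=0.02, seed=9)
        cohort = generate_cohort(cfg)
        beta = cohort.beta.loc[[c for c in cohort.beta.index if not c.startswith("cgX")]]
        comps = dec.refactor_components(beta, k=6, t=150)
        W = cohort.truth.proportions.to_numpy()
        # first canonical correlations between components and true proportions
        from sklearn.cross_decomposition import CCA

        cca = CCA(n_components=2).fit(comps.to_numpy(), W)
        u, v = cca.transform(comps.to_numpy(), W)
        r1 = np.corrcoef(u[:, 0], v[:, 0])[0, 1]
        r2 = np.corrcoef(u[:, 1], v[:, 1])[0, 1]
        assert r1 > 0.9 and r2 > 0.9

    def test_k_too_large_errors(self, rng):
        beta = pd.DataFrame(rng.random((30, 5)))
        with pytest.raises(ValueError):
            dec.ReFACTor(k=5, t=10).fit(beta)


def _two_cell_toy(n=100, mu=(0.2, 0.8), seed=0, noise=0.0):
    r = np.random.default_rng(seed)
    w = np.linspace(0.1, 0.9, n)
    W = np.column_stack([w, 1 - w])
    probes = [f"cg{i}" for i in range(12)]
    mus = np.column_stack([np.full(12, mu[0]), np.full(12, mu[1])])
    x = mus @ W.T
    if noise:
        x = np.clip(x + r.normal(0, noise, x.shape), 0, 1)
    beta = pd.DataFrame(x, index=probes, columns=[f"s{i}" for i in range(n)])
    props = pd.DataFrame(W, index=beta.columns, columns=["A", "B"])
    return beta, props


class TestTCA:
    def test_single_cell_type_collapses_to_sample_mean(self, rng):
        beta = pd.DataFrame(rng.uniform(0.2, 0.8, (5, 40)),
                            index=[f"cg{i}" for i in range(5)],
                            columns=[f"s{i}" for i in range(40)])
        props = pd.DataFrame({"A": np.ones(40)}, index=beta.columns)
        tca = dec.fit_tca(beta, props)
        assert np.allclose(tca.model_.mu["A"], beta.mean(axis=1), atol=1e-8)

    def test_two_cell_noiseless_means_recovered(self):
        beta, props = _two_cell_toy()
        tca = dec.fit_tca(beta, props)
        assert np.abs(tca.model_.mu["A"] - 0.2).max() < 0.02
        assert np.abs(tca.model_.mu["B"] - 0.8).max() < 0.02

    def test_loglik_nondecreasing_per_iteration(self):
        beta, props = _two_cell_toy(noise=0.05, seed=3)
        tca = dec.TCA(track_paths=True).fit(beta, props)
        for path in tca.ll_paths_.values():
            diffs = np.diff(path)
            assert (diffs >= -1e-6 * np.maximum(1.0, np.abs(path[:-1]))).all()

    def test_null_covariate_effects_near_zero(self, rng):
        """With no planted covariate effect, fitted gamma stays small."""
        n, n_cpg = 100, 60
        w = rng.dirichlet((5, 5), size=n)
        mus = rng.uniform(0.3, 0.7, (n_cpg, 2))
        x = np.einsum("ih,jh->ji", w, mus) + rng.normal(0, 0.02, (n_cpg, n))
        beta = pd.DataFrame(np.clip(x, 0, 1),
                            index=[f"cg{i}" for i in range(n_cpg)],
                            columns=[f"s{i}" for i in range(n)])
        props = pd.DataFrame(w, index=beta.columns, columns=["A", "B"])
        c1 = pd.DataFrame({"cov": rng.normal(0, 1, n)}, index=beta.columns)
        tca = dec.fit_tca(beta, props, c1=c1)
        frac_small = (np.abs(tca.model_.gamma) < 0.05).mean()
        assert frac_small >= 0.95

    def test_tensor_degenerate_limits(self):
        beta, props = _two_cell_toy(n=30)
        tca = dec.fit_tca(beta, props)
        m = tca.model_
        # all sigma = 0: tensor collapses to the fitted means
        m.sigma.loc[:, :] = 0.0
        m.tau.loc[:] = 0.05
        tensor = tca.tensor(beta)
        for ct in ["A", "B"]:
            assert np.allclose(
                tensor.values[ct].to_numpy(),
                np.tile(m.mu[ct].to_numpy()[:, None], (1, 30)), atol=1e-10,
            )

    def test_tensor_identity_single_cell_zero_noise(self, rng):
        beta = pd.DataFrame(rng.uniform(0.2, 0.8, (4, 25)),
                            index=[f"cg{i}" for i in range(4)],
                            columns=[f"s{i}" for i in range(25)])
        props = pd.DataFrame({"A": np.ones(25)}, index=beta.columns)
        tca = dec.fit_tca(beta, props)
        tca.model_.tau.loc[:] = 0.0
        tca.model_.sigma.loc[:, :] = beta.std(axis=1, ddof=0).to_numpy()[:, None]
        tensor = tca.tensor(beta)
        assert np.allclose(tensor.values["A"].to_numpy(), beta.to_numpy(), atol=1e-8)

    def test_tensor_mixture_consistency(self):
        """Recombining the tensor reproduces bulk within 3·(tau + eps)."""
        beta, props = _two_cell_toy(n=80, noise=0.03, seed=5)
        tca = dec.fit_tca(beta, props)
        tensor = tca.tensor(beta)
        recon = tensor.mixture(props)
        err = (recon - beta).abs().to_numpy()
        bound = 3 * (tca.model_.tau.to_numpy()[:, None] + 0.01)
        assert (err <= bound).mean() >= 0.99

    def test_nonfinite_input_errors(self):
        beta = pd.DataFrame({"s1": [0.5], "s2": [np.nan]}, index=["cg0"])
        props = pd.DataFrame({"A": [1.0, 1.0]}, index=["s1", "s2"])
        with pytest.raises(ValueError, match="cg0"):
            dec.fit_tca(beta, props)
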