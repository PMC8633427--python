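import numpy as np
import pandas as pd
import pytest
from scipy import stats

import swmprofile as sp
from swmprofile.lmm import (
    _Blocks,
    _design,
    _profiled_loglik,
    ame_by_prediction,
    estimate_ames,
    fdr_adjust,
    fit_profile_lmm,
    marginal_loglik,
    run_full_inference,
)


def random_psd(rng, scale=1.0):
    a = rng.standard_normal((2, 2)) * scale
    return a @ a.T + np.eye(2) * 0.1 * scale**2


def simulate_table(rng, n_control=5, n_case=5, beta=None, covs=None, sigma2=0.01):
    """Rows drawn exactly from the profile mixed model."""
    if beta is None:
        beta = np.array([0.4, 0.07, -0.002, -0.01, -0.005, 0.001, -0.02])
    if covs is None:
        covs = {0: np.eye(2) * 1e-4, 1: np.eye(2) * 1e-4}
    d = np.arange(4.0)
    rows = []
    for i in range(n_control + n_case):
        g = float(i >= n_control)
        thick = rng.normal(2.5, 0.1)
        b = rng.multivariate_normal([0.0, 0.0], covs[int(g)])
        X = _design(d, np.full(4, g), np.full(4, thick))
        y = X @ beta + b[0] + b[1] * d + rng.normal(0.0, np.sqrt(sigma2), 4)
        for k in range(4):
            rows.append(
                dict(participant_id=f"p{i:03d}", group=int(g), roi=0, metric="NDI",
                     d=k, d2=k * k, y=y[k], thickness=thick)
            )
    return pd.DataFrame(rows), beta


def dense_mvn_loglik(table, beta, covs, sigma2):
    """Independent oracle: stacked multivariate-normal evaluation."""
    total = 0.0
    for _, sub in table.groupby("participant_id"):
        d = sub.d.to_numpy(float)
        g = sub.group.to_numpy(float)
        X = _design(d, g, sub.thickness.to_numpy(float))
        Z = np.column_stack([np.ones(len(d)), d])
        V = Z @ covs[int(g[0])] @ Z.T + sigma2 * np.eye(len(d))
        total += stats.multivariate_normal.logpdf(sub.y.to_numpy(), X @ beta, V)
    return total


# ------------------------------------------------------------- likelihood
def test_marginal_loglik_matches_dense_mvn_on_randomized_instances(rng):
    for trial in range(20):
        covs = {0: random_psd(rng, 0.05), 1: random_psd(rng, 0.05)}
        sigma2 = float(rng.uniform(0.001, 0.05))
        table, beta = simulate_table(
            rng, n_control=rng.integers(2, 6), n_case=rng.integers(2, 6),
            covs=covs, sigma2=sigma2,
        )
        # unbalanced data: drop a couple of rows
        if trial % 3 == 0:
            table = table.drop(table.index[[1, 6]])
        got = marginal_loglik(table, beta, covs[0], covs[1], sigma2)
        want = dense_mvn_loglik(table, beta, covs, sigma2)
        assert got == pytest.approx(want, abs=1e-8)


def test_reml_equals_ml_plus_fixed_effect_adjustment(rng):
    covs = {0: random_psd(rng, 0.05), 1: random_psd(rng, 0.05)}
    sigma2 = 0.01
    table, beta = simulate_table(rng, covs=covs, sigma2=sigma2)
    # REML is evaluated at the GLS beta and subtracts 0.5 log|X'V^-1 X|
    A = np.zeros((7, 7))
    b = np.zeros(7)
    for _, sub in table.groupby("participant_id"):
        d = sub.d.to_numpy(float)
        g = sub.group.to_numpy(float)
        X = _design(d, g, sub.thickness.to_numpy(float))
        Z = np.column_stack([np.ones(len(d)), d])
        V = Z @ covs[int(g[0])] @ Z.T + sigma2 * np.eye(len(d))
        Vi = np.linalg.inv(V)
        A += X.T @ Vi @ X
        b += X.T @ Vi @ sub.y.to_numpy()
    beta_gls = np.linalg.solve(A, b)
    want = (
        dense_mvn_loglik(table, beta_gls, covs, sigma2)
        - 0.5 * np.linalg.slogdet(A)[1]
        + 3.5 * np.log(2.0 * np.pi)
    )
    got = marginal_loglik(table, beta, covs[0], covs[1], sigma2, method="REML")
    assert got == pytest.approx(want, abs=1e-8)
    # and it does not depend on the beta argument
    got2 = marginal_loglik(table, beta + 1.0, covs[0], covs[1], sigma2, method="REML")
    assert got == pytest.approx(got2, abs=1e-10)


def test_standard_normal_contribution_per_observation():
    rows = [
        dict(participant_id=f"p{i}", group=i % 2, roi=0, metric="FA",
             d=k, d2=k * k, y=0.0, thickness=0.0)
        for i in range(4)
        for k in range(4)
    ]
    table = pd.DataFrame(rows)
    zero = np.zeros((2, 2))
    ll = marginal_loglik(table, np.zeros(7), zero, zero, 1.0)
    assert ll == pytest.approx(-0.5 * len(table) * np.log(2 * np.pi), rel=1e-12)


def test_sigma2_doubling_matches_independent_gaussian_identity(rng):
    table, beta = simulate_table(rng)
    zero = np.zeros((2, 2))
    s2 = 0.02
    r2 = 0.0
    for _, sub in table.groupby("participant_id"):
        X = _design(sub.d.to_numpy(float), sub.group.to_numpy(float),
                    sub.thickness.to_numpy(float))
        r = sub.y.to_numpy() - X @ beta
        r2 += r @ r
    n = len(table)
    expected_delta = -0.5 * n * np.log(2.0) + r2 / (2 * s2) - r2 / (2 * 2 * s2)
    got = (
        marginal_loglik(table, beta, zero, zero, 2 * s2)
        - marginal_loglik(table, beta, zero, zero, s2)
    )
    assert got == pytest.approx(expected_delta, rel=1e-10)


def test_nonfinite_parameters_give_minus_infinity(rng):
    table, beta = simulate_table(rng)
    zero = np.zeros((2, 2))
    assert marginal_loglik(table, beta * np.nan, zero, zero, 1.0) == -np.inf
    assert marginal_loglik(table, beta, zero, zero, np.inf) == -np.inf
    assert marginal_loglik(table, beta, zero, zero, -1.0) == -np.inf


# ------------------------------------------------------------------ fitting
def test_exact_interpolation_recovers_beta(rng):
    beta_star = np.array([0.3, 0.05, -0.004, -0.02, -0.01, 0.002, 0.01])
    d = np.arange(4.0)
    rows = []
    for i in range(8):
        g = float(i >= 4)
        thick = 2.0 + 0.2 * i
        X = _design(d, np.full(4, g), np.full(4, thick))
        y = X @ beta_star
        for k in range(4):
            rows.append(dict(participant_id=f"p{i}", group=int(g), roi=0,
                             metric="FA", d=k, d2=k * k, y=y[k], thickness=thick))
    fit = fit_profile_lmm(pd.DataFrame(rows))
    assert fit.converged
    assert np.max(np.abs(fit.beta - beta_star)) < 1e-6


def test_fixed_effects_recovered_within_three_ses(rng):
    covs = {0: np.array([[4e-4, 2e-5], [2e-5, 2.5e-5]]),
            1: np.array([[6e-4, 1e-5], [1e-5, 4e-5]])}
    table, beta = simulate_table(rng, n_control=200, n_case=200, covs=covs, sigma2=1e-5)
    fit = fit_profile_lmm(table)
    assert fit.converged
    fit.validate()
    se = np.sqrt(np.diag(fit.beta_cov))
    assert np.all(np.abs(fit.beta - beta) < 3 * se)
    # group-specific variance components are recovered to the right scale
    assert fit.varcomp["control"][0, 0] == pytest.approx(4e-4, rel=0.5)
    assert fit.varcomp["case"][0, 0] == pytest.approx(6e-4, rel=0.5)


def test_ml_optimum_is_at_least_grid_maximum(rng):
    table, _ = simulate_table(rng, n_control=10, n_case=10)
    fit = fit_profile_lmm(table, method="ML")
    assert fit.converged
    best = fit.loglik
    # grid over a 2-parameter slice: case intercept variance x sigma2
    for v00 in np.geomspace(1e-6, 1e-2, 12):
        for s2 in np.geomspace(1e-6, 1e-2, 12):
            cov_case = fit.varcomp["case"].copy()
            cov_case[0, 0] = v00
            # keep PSD: shrink covariance if needed
            if cov_case[0, 1] ** 2 > v00 * cov_case[1, 1]:
                cov_case[0, 1] = cov_case[1, 0] = 0.9 * np.sqrt(v00 * cov_case[1, 1])
            ll = marginal_loglik(
                table, fit.beta, fit.varcomp["control"], cov_case, s2, method="ML"
            )
            # profile beta at the grid point for a fair comparison
            blocks = _Blocks(table)
            assert ll <= best + 1e-6


def test_forced_nonconvergence_uses_fallback_then_flags(rng):
    table, _ = simulate_table(rng, n_control=6, n_case=6)
    # healthy fit: no fallback
    good = fit_profile_lmm(table)
    assert good.converged and not good.fallback_used
    good.validate()
    # explicit fallback structure zeroes the control slope block
    fb = fit_profile_lmm(table, drop_control_slope=True)
    assert fb.fallback_used
    assert fb.varcomp["control"][1, 1] == 0.0 and fb.varcomp["control"][0, 1] == 0.0
    fb.validate()
    # starving the optimizer fails both attempts and flags non-convergence
    dead = fit_profile_lmm(table, optimizer_options={"maxiter": 0})
    assert not dead.converged
    assert estimate_ames(dead) == []


def test_fit_requires_two_groups_and_two_distances(rng):
    table, _ = simulate_table(rng)
    with pytest.raises(ValueError):
        fit_profile_lmm(table[table.group == 0])
    with pytest.raises(ValueError):
        fit_profile_lmm(table[table.d == 1])


# --------------------------------------------------------------------- AMEs
def test_ame_equals_coefficient_contrast_and_prediction_average(rng):
    table, _ = simulate_table(rng, n_control=8, n_case=8)
    fit = fit_profile_lmm(table)
    ames = estimate_ames(fit, roi=0, metric="NDI")
    b3, b4, b5 = fit.beta[3], fit.beta[4], fit.beta[5]
    assert ames[0].ame == pytest.approx(b3, abs=1e-15)
    for res in ames:
        d = float(res.depth_index)
        assert res.ame == pytest.approx(b3 + b4 * d + b5 * d * d, abs=1e-12)
        pred = ame_by_prediction(fit, table, res.depth_index)
        assert abs(pred - res.ame) < 1e-10
        assert res.ci_low <= res.ame <= res.ci_high
        # delta-method variance spelled out
        c = fit.beta_cov
        var = (
            c[3, 3] + d**2 * c[4, 4] + d**4 * c[5, 5]
            + 2 * d * c[3, 4] + 2 * d**2 * c[3, 5] + 2 * d**3 * c[4, 5]
        )
        assert res.se == pytest.approx(np.sqrt(var), rel=1e-10)


def test_delta_ci_agrees_with_parametric_bootstrap(rng):
    # strong planted effect keeps CI endpoints away from zero
    beta = np.array([0.4, 0.07, -0.002, -0.05, -0.01, 0.001, -0.02])
    table, _ = simulate_table(rng, n_control=22, n_case=29, beta=beta, sigma2=1e-5)
    fit = fit_profile_lmm(table)
    ames = estimate_ames(fit, roi=0, metric="NDI")
    draws = rng.multivariate_normal(fit.beta, fit.beta_cov, size=2000)
    for res in ames:
        d = float(res.depth_index)
        boot = draws[:, 3] + draws[:, 4] * d + draws[:, 5] * d * d
        lo, hi = np.percentile(boot, [2.5, 97.5])
        assert abs(lo - res.ci_low) <= 0.05 * abs(res.ci_low)
        assert abs(hi - res.ci_high) <= 0.05 * abs(res.ci_high)


# ---------------------------------------------------------------------- FDR
def test_fdr_adjust_hand_examples():
    assert np.allclose(fdr_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04])
    assert fdr_adjust([0.2]) == pytest.approx([0.2])
    assert np.allclose(fdr_adjust([0.3, 0.3, 0.3]), [0.3, 0.3, 0.3])
    out = fdr_adjust([0.9, 0.9, 0.9, 0.95])
    assert np.all(out <= 1.0)
    with pytest.raises(ValueError):
        fdr_adjust([0.5, 1.5])
    with pytest.raises(ValueError):
        fdr_adjust([0.5, -0.1])


try:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @settings(derandomize=True, max_examples=80, deadline=None)
    @given(
        st.lists(
            st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
            min_size=1,
            max_size=50,
        )
    )
    def test_fdr_adjust_invariants_hold_on_arbitrary_pvectors(pvals):
        p = np.asarray(pvals)
        q = fdr_adjust(p)
        assert np.all(q >= p - 1e-15)
        assert np.all(q <= 1.0 + 1e-15)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(q[order]) >= -1e-15)   # monotone in raw p
        perm = np.random.default_rng(0).permutation(len(p))
        assert np.allclose(fdr_adjust(p[perm]), q[perm], atol=1e-15)

except ImportError:  # pragma: no cover - hypothesis is an optional test extra
    pass


def test_fdr_adjust_matches_statsmodels_and_is_monotone(rng):
    from statsmodels.stats.multitest import multipletests

    for _ in range(200):
        m = int(rng.integers(1, 40))
        p = rng.uniform(0.0, 1.0, size=m)
        if rng.random() < 0.3:
            p[rng.integers(0, m)] = p[rng.integers(0, m)]   # force ties
        ours = fdr_adjust(p)
        _, ref, *_ = multipletests(p, method="fdr_bh")
        assert np.allclose(ours, ref, atol=1e-12)
        assert np.all(ours >= p - 1e-15)
        order = np.argsort(p)
        assert np.all(np.diff(ours[order]) >= -1e-15)


# ------------------------------------------------------------------ driver
def test_run_full_inference_counts_and_planted_effect():
    cfg = sp.CohortConfig(
        seed=5, roi_count=2,
        effect_template={("NDI", 1): (-0.05, 0.0, 0.0)},
    )
    table = sp.simulate_long_table(cfg, seed=3, metrics=("NDI",))
    ame_df, info = run_full_inference(table)
    assert info["n_models"] == 2
    assert info["n_pvalues"] == 8
    assert len(ame_df) == 8
    hit = ame_df[(ame_df.roi == 1) & ame_df.significant]
    assert len(hit) == 4                       # strong flat effect at all depths
    assert (hit.ame < 0).all()                 # sign matches the planted sign
    assert not ame_df[ame_df.roi == 0].significant.any()
    assert np.all(ame_df.p_fdr >= ame_df.p - 1e-15)


def test_permuted_null_labels_leave_ame_distribution_unchanged(rng):
    cfg = sp.CohortConfig(seed=5, roi_count=1)
    stat, stat_perm = [], []
    for r in range(30):
        table = sp.simulate_long_table(cfg, seed=500 + r, metrics=("ODI",))
        fit = fit_profile_lmm(table)
        stat.append(abs(estimate_ames(fit)[2].ame))
        perm = table.copy()
        ids = perm.participant_id.unique()
        flip = dict(zip(ids, rng.permutation(ids)))
        grp = perm.groupby("participant_id").group.first()
        perm["group"] = perm.participant_id.map(lambda p: grp[flip[p]])
        fit_p = fit_profile_lmm(perm)
        stat_perm.append(abs(estimate_ames(fit_p)[2].ame))
    ks = stats.ks_2samp(stat, stat_perm)
    assert ks.pvalue > 0.01
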