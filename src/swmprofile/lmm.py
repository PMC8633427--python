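"""Mixed-model inference along the cortical profile.

One linear mixed model is fit per (ROI, metric).  Fixed effects: intercept,
distance, distance squared, group, group x distance, group x distance squared,
and mean ROI cortical thickness (a proxy for atrophy).  Distance counts model
depth points 0..3 with the GM sample as the intercept (distance = 0).  Random
effects: per-participant intercept and slope with a full 2x2 covariance that
is specific to each group; when the full model cannot be fit, the control
group's random slope is removed (intercept-only control covariance) and the
fit is flagged as a fallback.

Estimation maximizes the exact Gaussian marginal likelihood (REML by default)
over a log-Cholesky parameterization of the variance components, profiling
the fixed effects out by generalized least squares.  The average marginal
effect (AME) of group at depth d — the mean over observed covariate rows of
the predicted case-minus-control difference — reduces, because thickness
enters additively, to the coefficient contrast

    AME(d) = beta_group + beta_gxd * d + beta_gxd2 * d^2,

with a delta-method standard error, Wald 95% intervals and two-sided normal
p-values.  All AME p-values are adjusted jointly by Benjamini–Hochberg FDR.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .atlas import DEPTH_LABELS

log = logging.getLogger(__name__)

FIXED_EFFECTS = (
    "intercept",
    "distance",
    "distance2",
    "group",
    "group_x_distance",
    "group_x_distance2",
    "thickness",
)
N_FIXED = len(FIXED_EFFECTS)

#: depth-index -> model distance codings.  "standard" spaces the four sample
#: points one unit apart; "last4" codes the deepest point as 4 instead.
DISTANCE_CODINGS = {
    "standard": {0: 0.0, 1: 1.0, 2: 2.0, 3: 3.0},
    "last4": {0: 0.0, 1: 1.0, 2: 2.0, 3: 4.0},
}

_Z975 = stats.norm.ppf(0.975)


# ---------------------------------------------------------------- containers
@dataclass
class LMMFit:
    beta: np.ndarray                 # (7,) fixed effects in FIXED_EFFECTS order
    beta_cov: np.ndarray             # (7, 7)
    varcomp: dict                    # group label -> 2x2 random-effect covariance
    sigma2: float
    loglik: float
    method: str
    converged: bool
    fallback_used: bool
    n_obs: int
    n_participants: int
    distance_coding: str = "standard"

    def validate(self) -> None:
        for g, v in self.varcomp.items():
            if not np.allclose(v, v.T):
                raise ValueError(f"{g} covariance not symmetric")
            if np.min(np.linalg.eigvalsh(v)) < -1e-10:
                raise ValueError(f"{g} covariance not PSD")
        if self.sigma2 < 0:
            raise ValueError("sigma2 < 0")
        if self.fallback_used:
            vc = self.varcomp["control"]
            if abs(vc[0, 1]) > 1e-12 or abs(vc[1, 1]) > 1e-12:
                raise ValueError("fallback fit must zero the control slope variance")


@dataclass
class AMEResult:
    roi: int
    metric: str
    depth_index: int
    ame: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    p_fdr: float = np.nan
    significant: bool = False


# ------------------------------------------------------------- data plumbing
def _coded_distance(d: np.ndarray, coding: str) -> np.ndarray:
    table = DISTANCE_CODINGS[coding]
    return np.vectorize(table.__getitem__, otypes=[float])(np.asarray(d))


def _design(dist: np.ndarray, group: np.ndarray, thickness: np.ndarray) -> np.ndarray:
    return np.column_stack(
        [
            np.ones_like(dist),
            dist,
            dist**2,
            group,
            group * dist,
            group * dist**2,
            thickness,
        ]
    )


class _Blocks:
    """Participant data grouped by (group, depth pattern) for fast likelihood.

    Within a pattern every participant shares the random-effect design Z and
    hence the marginal covariance V, so log-determinants are computed once and
    the per-participant quadratic forms collapse into one precomputed tensor
    T[k, i, l, j] = sum_n G[n, k, i] G[n, l, j] with G = [X | y].
    """

    def __init__(self, table: pd.DataFrame, distance_coding: str = "standard"):
        tab = table[np.isfinite(table.y.to_numpy())]
        if tab.empty:
            raise ValueError("no usable rows")
        tab = tab.sort_values(["participant_id", "d"], kind="stable")
        self.n_obs = len(tab)
        self.scale = float(np.std(tab.y.to_numpy())) or 1.0
        self.patterns = []
        self.n_participants = tab.participant_id.nunique()
        counts = tab.groupby("group").participant_id.nunique()
        if counts.reindex([0, 1]).fillna(0).min() < 2:
            raise ValueError("need at least 2 participants per group")
        if tab.d.nunique() < 2:
            raise ValueError("need at least 2 distinct distances")
        pattern_of = tab.groupby("participant_id").d.apply(tuple)
        tab = tab.assign(_pattern=tab.participant_id.map(pattern_of))
        by_depths: dict[tuple, list] = {}
        for (g, dd), sub in tab.groupby(["group", "_pattern"], sort=True):
            k = len(dd)
            dist = _coded_distance(np.array(dd), distance_coding)
            n = sub.participant_id.nunique()
            y = sub.y.to_numpy().reshape(n, k) / self.scale
            X = _design(
                np.tile(dist, n),
                sub.group.to_numpy(dtype=float),
                sub.thickness.to_numpy(dtype=float),
            ).reshape(n, k, N_FIXED)
            G = np.concatenate([X, y[:, :, None]], axis=2)   # (n, k, 8)
            T = np.einsum("nki,nlj->kilj", G, G)
            # flattened (k*k, 8, 8) layout so M(Vinv) is a single tensordot
            T_flat = T.transpose(0, 2, 1, 3).reshape(k * k, N_FIXED + 1, N_FIXED + 1)
            self.patterns.append(
                {"group": int(g), "n": n, "k": k, "dist": dist, "X": X, "y": y}
            )
            by_depths.setdefault(dd, []).append((int(g), n, T_flat, dist))
        # stacks of same-depth-pattern groups so the likelihood is batched
        self.stacks = []
        for dd, entries in by_depths.items():
            dist = entries[0][3]
            self.stacks.append(
                {
                    "Z": np.column_stack([np.ones(len(dd)), dist]),
                    "k": len(dd),
                    "groups": np.array([e[0] for e in entries]),
                    "ns": np.array([e[1] for e in entries], dtype=float),
                    "T": np.ascontiguousarray(np.stack([e[2] for e in entries])),
                }
            )


def _chol_to_cov(params: np.ndarray, slope: bool) -> np.ndarray:
    """Log-Cholesky parameters -> 2x2 covariance (slope dropped if not slope)."""
    if slope:
        l11, l21, l22 = np.exp(params[0]), params[1], np.exp(params[2])
        L = np.array([[l11, 0.0], [l21, l22]])
        return L @ L.T
    v = np.exp(2.0 * params[0])
    return np.array([[v, 0.0], [0.0, 0.0]])


def _cov_to_chol(cov: np.ndarray, slope: bool, floor: float = 1e-6) -> np.ndarray:
    if not slope:
        return np.array([0.5 * np.log(max(cov[0, 0], floor**2))])
    v00 = max(cov[0, 0], floor**2)
    l11 = np.sqrt(v00)
    l21 = cov[0, 1] / l11
    rem = max(cov[1, 1] - l21**2, floor**2)
    return np.array([np.log(l11), l21, 0.5 * np.log(rem)])


def _profiled_loglik(
    theta: np.ndarray, blocks: _Blocks, method: str, control_slope: bool
):
    """Profiled (RE)ML log-likelihood of scaled data at variance parameters.

    Returns (loglik, beta_scaled, XtViX) or (-inf, None, None) on numerical
    failure.  theta = [control chol params, case chol params (3), log sigma].
    """
    if not np.all(np.isfinite(theta)):
        return -np.inf, None, None
    nc = 3 if control_slope else 1
    cov = np.stack(
        [_chol_to_cov(theta[:nc], control_slope), _chol_to_cov(theta[nc : nc + 3], True)]
    )
    sigma2 = np.exp(2.0 * theta[nc + 3])

    A = np.zeros((N_FIXED, N_FIXED))
    b = np.zeros(N_FIXED)
    c = 0.0
    logdet = 0.0
    for st in blocks.stacks:
        Z, k = st["Z"], st["k"]
        V = np.einsum("ka,mab,lb->mkl", Z, cov[st["groups"]], Z)
        V[:, np.arange(k), np.arange(k)] += sigma2
        try:
            L = np.linalg.cholesky(V)
        except np.linalg.LinAlgError:
            return -np.inf, None, None
        logdet += 2.0 * float(
            st["ns"] @ np.log(L[:, np.arange(k), np.arange(k)]).sum(axis=1)
        )
        Linv = np.linalg.inv(L)
        Vinv = np.einsum("mik,mil->mkl", Linv, Linv)
        M = np.einsum("mv,mvij->ij", Vinv.reshape(-1, k * k), st["T"])
        A += M[:N_FIXED, :N_FIXED]
        b += M[:N_FIXED, N_FIXED]
        c += M[N_FIXED, N_FIXED]
    try:
        beta = np.linalg.solve(A, b)
    except np.linalg.LinAlgError:
        return -np.inf, None, None
    q = c - beta @ b
    n, p = blocks.n_obs, N_FIXED
    if method == "ML":
        ll = -0.5 * (n * np.log(2.0 * np.pi) + logdet + q)
    else:
        sign, ld_a = np.linalg.slogdet(A)
        if sign <= 0:
            return -np.inf, None, None
        ll = -0.5 * ((n - p) * np.log(2.0 * np.pi) + logdet + ld_a + q)
    if not np.isfinite(ll):
        return -np.inf, None, None
    return ll, beta, A


def _start_values(blocks: _Blocks, control_slope: bool) -> np.ndarray:
    """Method-of-moments start from per-participant OLS intercepts/slopes."""
    coefs = {0: [], 1: []}
    resid_var = []
    for pat in blocks.patterns:
        Z = np.column_stack([np.ones(pat["k"]), pat["dist"]])
        if pat["k"] >= 2:
            zz = np.linalg.pinv(Z)
            bcoef = pat["y"] @ zz.T                      # (n, 2)
            coefs[pat["group"]].append(bcoef)
            res = pat["y"] - bcoef @ Z.T
            if pat["k"] > 2:
                resid_var.append(np.mean(res**2) * pat["k"] / (pat["k"] - 2))
    sigma2 = float(np.mean(resid_var)) if resid_var else 0.05
    sigma2 = min(max(sigma2, 1e-4), 1e4)
    theta = []
    for g in (0, 1):
        slope = control_slope if g == 0 else True
        if coefs[g]:
            bmat = np.concatenate(coefs[g], axis=0)
            cov = np.cov(bmat.T) if len(bmat) > 1 else np.eye(2) * 0.1
            cov = np.atleast_2d(cov)
        else:
            cov = np.eye(2) * 0.1
        theta.append(_cov_to_chol(cov + 1e-4 * np.eye(2), slope, floor=1e-3))
    theta.append([0.5 * np.log(sigma2)])
    return np.concatenate(theta)


def fit_profile_lmm(
    table: pd.DataFrame,
    method: str = "REML",
    distance_coding: str = "standard",
    drop_control_slope: bool = False,
    optimizer_options: dict | None = None,
) -> LMMFit:
    """Fit the profile mixed model for one (ROI, metric) table.

    The table needs columns (participant_id, group, d, y, thickness); rows
    with missing y are dropped.  On optimizer failure the model is refit with
    the control group's random slope removed and ``fallback_used`` set; if
    that also fails the fit is returned flagged unconverged.
    """
    if method not in ("REML", "ML"):
        raise ValueError("method must be REML or ML")
    blocks = _Blocks(table, distance_coding)
    degenerate = _deterministic_fit(blocks, method)
    if degenerate is not None:
        degenerate.distance_coding = distance_coding
        if drop_control_slope:
            degenerate.fallback_used = True
        return degenerate
    fit = _fit_once(blocks, method, not drop_control_slope, optimizer_options)
    fit_fb = None
    if not fit.converged and not drop_control_slope:
        fit_fb = _fit_once(blocks, method, False, optimizer_options)
        if fit_fb.converged:
            fit_fb.fallback_used = True
            fit = fit_fb
    if drop_control_slope and fit.converged:
        fit.fallback_used = True
    fit.distance_coding = distance_coding
    return fit


def _deterministic_fit(blocks: _Blocks, method: str) -> LMMFit | None:
    """Exact-interpolation shortcut for noise-free inputs.

    When the outcome is an exact linear function of the fixed-effect design,
    the marginal likelihood is maximized in the sigma^2 -> 0 boundary limit
    (handled by a 1e-12 variance floor on the standardized scale) with zero
    random-effect covariance, and the GLS solution reduces to OLS.  Interior
    optimizers stall on the flat ridge of this degenerate surface, so the
    limit is taken analytically.
    """
    X = np.concatenate([pat["X"].reshape(-1, N_FIXED) for pat in blocks.patterns])
    y = np.concatenate([pat["y"].reshape(-1) for pat in blocks.patterns])
    beta_s, *_ = np.linalg.lstsq(X, y, rcond=None)
    rss = float(np.sum((y - X @ beta_s) ** 2))
    if rss > 1e-18 * len(y):
        return None
    sigma2_s = 1e-12
    xtx = X.T @ X
    s = blocks.scale
    ll, _, _ = _profiled_loglik(
        np.array([-13.8, 0.0, -13.8, -13.8, 0.0, -13.8, 0.5 * np.log(sigma2_s)]),
        blocks, method, True,
    )
    n, p = blocks.n_obs, N_FIXED
    return LMMFit(
        beta=beta_s * s,
        beta_cov=np.linalg.inv(xtx) * sigma2_s * s**2,
        varcomp={"control": np.zeros((2, 2)), "case": np.zeros((2, 2))},
        sigma2=sigma2_s * s**2,
        loglik=float(ll - (n - p if method == "REML" else n) * np.log(s)),
        method=method,
        converged=True,
        fallback_used=False,
        n_obs=n,
        n_participants=blocks.n_participants,
    )


def _fit_once(
    blocks: _Blocks, method: str, control_slope: bool, optimizer_options: dict | None
) -> LMMFit:
    nc = 3 if control_slope else 1
    x0 = _start_values(blocks, control_slope)
    bounds = []
    offdiag_idx = []
    for i in range(nc + 3):
        is_offdiag = (control_slope and i == 1) or i == nc + 1
        if is_offdiag:
            offdiag_idx.append(i)
        bounds.append((-15.0, 15.0) if is_offdiag else (-12.0, 8.0))
    bounds.append((-13.8, 8.0))          # log sigma: sigma2 floored near 1e-12

    def nll(theta):
        ll, *_ = _profiled_loglik(theta, blocks, method, control_slope)
        return 1e12 if not np.isfinite(ll) else -ll

    def pathological(x):
        # an off-diagonal pinned at its bound, or a variance at its ceiling,
        # marks a runaway ridge rather than an optimum
        for i, (lo, hi) in enumerate(bounds):
            if i in offdiag_idx and (x[i] <= lo + 1e-6 or x[i] >= hi - 1e-6):
                return True
            if i not in offdiag_idx and x[i] >= hi - 1e-6:
                return True
        return False

    # convergence: relative loglik change < 1e-10 or projected gradient < 1e-6
    opts = {"maxiter": 500, "ftol": 1e-10, "gtol": 1e-6}
    if optimizer_options:
        opts.update(optimizer_options)
    # conservative second start: modest variances in standardized-y units
    x_safe = np.zeros(nc + 4)
    x_safe[: nc + 3] = -2.0
    for i in offdiag_idx:
        x_safe[i] = 0.0
    x_safe[-1] = -0.5
    res = optimize.minimize(nll, x0, method="L-BFGS-B", bounds=bounds, options=opts)
    if not res.success or pathological(res.x):
        # line searches occasionally stall on noisy finite-difference
        # gradients, and degenerate (near-noiseless) data has flat ridges;
        # deterministic restarts resolve both
        for start in (x_safe, x0 + 0.5, x0 - 0.5, x0 + 1.0):
            retry = optimize.minimize(
                nll, start, method="L-BFGS-B", bounds=bounds, options=opts
            )
            if retry.success and not pathological(retry.x):
                if (not res.success) or retry.fun <= res.fun + 1e-6:
                    res = retry
                    break
    ll, beta_s, A = _profiled_loglik(res.x, blocks, method, control_slope)
    converged = bool(res.success) and np.isfinite(ll)
    if not converged or beta_s is None:
        return LMMFit(
            beta=np.full(N_FIXED, np.nan),
            beta_cov=np.full((N_FIXED, N_FIXED), np.nan),
            varcomp={"control": np.full((2, 2), np.nan), "case": np.full((2, 2), np.nan)},
            sigma2=np.nan,
            loglik=-np.inf,
            method=method,
            converged=False,
            fallback_used=not control_slope,
            n_obs=blocks.n_obs,
            n_participants=blocks.n_participants,
        )
    s = blocks.scale
    cov_c = _chol_to_cov(res.x[:nc], control_slope) * s**2
    cov_y = _chol_to_cov(res.x[nc : nc + 3], True) * s**2
    sigma2 = float(np.exp(2.0 * res.x[nc + 3]) * s**2)
    n, p = blocks.n_obs, N_FIXED
    ll_true = ll - (n - p if method == "REML" else n) * np.log(s)
    return LMMFit(
        beta=beta_s * s,
        beta_cov=np.linalg.inv(A) * s**2,
        varcomp={"control": cov_c, "case": cov_y},
        sigma2=sigma2,
        loglik=float(ll_true),
        method=method,
        converged=True,
        fallback_used=not control_slope,
        n_obs=n,
        n_participants=blocks.n_participants,
    )


# -------------------------------------------------------- public likelihood
def marginal_loglik(
    table: pd.DataFrame,
    beta: np.ndarray,
    cov_control: np.ndarray,
    cov_case: np.ndarray,
    sigma2: float,
    method: str = "ML",
    distance_coding: str = "standard",
) -> float:
    """Exact Gaussian marginal log-likelihood of the profile mixed model.

    For participant i with fixed-effect design X_i and random-effect design
    Z_i = [1, distance], V_i = Z_i S_g(i) Z_i' + sigma2 I and the result is
    sum_i log N(y_i; X_i beta, V_i).  The REML variant is evaluated at the
    GLS beta for the given variance parameters (it does not depend on the
    ``beta`` argument) and subtracts the usual fixed-effect adjustment
    0.5 log|X' V^-1 X| with matching constants.  Non-finite parameters yield
    -inf by contract.
    """
    beta = np.asarray(beta, dtype=float)
    cov = {0: np.asarray(cov_control, dtype=float), 1: np.asarray(cov_case, dtype=float)}
    params = np.concatenate([beta, cov[0].ravel(), cov[1].ravel(), [sigma2]])
    if not np.all(np.isfinite(params)) or sigma2 < 0:
        return -np.inf

    tab = table[np.isfinite(table.y.to_numpy())]
    ll = 0.0
    A = np.zeros((N_FIXED, N_FIXED))
    b = np.zeros(N_FIXED)
    c = 0.0
    n_tot = 0
    logdet = 0.0
    for _, sub in tab.groupby("participant_id"):
        dist = _coded_distance(sub.d.to_numpy(), distance_coding)
        X = _design(dist, sub.group.to_numpy(dtype=float), sub.thickness.to_numpy(dtype=float))
        y = sub.y.to_numpy(dtype=float)
        Z = np.column_stack([np.ones(len(dist)), dist])
        V = Z @ cov[int(sub.group.iloc[0])] @ Z.T + sigma2 * np.eye(len(dist))
        try:
            L = np.linalg.cholesky(V)
        except np.linalg.LinAlgError:
            return -np.inf
        ld = 2.0 * np.log(np.diag(L)).sum()
        Vinv = np.linalg.inv(V)
        r = y - X @ beta
        ll += -0.5 * (len(y) * np.log(2.0 * np.pi) + ld + r @ Vinv @ r)
        logdet += ld
        A += X.T @ Vinv @ X
        b += X.T @ Vinv @ y
        c += y @ Vinv @ y
        n_tot += len(y)
    if method == "ML":
        return float(ll)
    beta_gls = np.linalg.solve(A, b)
    q = c - beta_gls @ b
    sign, ld_a = np.linalg.slogdet(A)
    if sign <= 0:
        return -np.inf
    return float(
        -0.5 * ((n_tot - N_FIXED) * np.log(2.0 * np.pi) + logdet + ld_a + q)
    )


# --------------------------------------------------------------------- AMEs
def estimate_ames(
    fit: LMMFit,
    roi: int = -1,
    metric: str = "",
    depths: tuple[int, ...] = (0, 1, 2, 3),
) -> list[AMEResult]:
    """Depth-wise AMEs with delta-method SEs, Wald CIs and normal p-values."""
    out = []
    if not fit.converged:
        return out
    coding = DISTANCE_CODINGS[fit.distance_coding]
    i3, i4, i5 = 3, 4, 5
    for depth in depths:
        d = coding[depth]
        contrast = np.zeros(N_FIXED)
        contrast[i3], contrast[i4], contrast[i5] = 1.0, d, d * d
        ame = float(contrast @ fit.beta)
        var = float(contrast @ fit.beta_cov @ contrast)
        se = float(np.sqrt(max(var, 0.0)))
        z = ame / se if se > 0 else np.inf * np.sign(ame or 1.0)
        p = float(2.0 * stats.norm.sf(abs(z))) if se > 0 else (1.0 if ame == 0 else 0.0)
        out.append(
            AMEResult(
                roi=roi,
                metric=metric,
                depth_index=depth,
                ame=ame,
                se=se,
                ci_low=ame - _Z975 * se,
                ci_high=ame + _Z975 * se,
                p=p,
            )
        )
    return out


def ame_by_prediction(fit: LMMFit, table: pd.DataFrame, depth: int) -> float:
    """AME by averaging predicted case-minus-control differences.

    For every observed covariate row, predictions are formed at the requested
    depth with group set to 1 and to 0, holding thickness at its observed
    value; the AME is the mean difference.  Thickness enters additively, so
    this equals the coefficient contrast exactly.
    """
    if not fit.converged:
        return np.nan
    d = DISTANCE_CODINGS[fit.distance_coding][depth]
    thick = table.thickness.to_numpy(dtype=float)
    dist = np.full(len(thick), d)
    x1 = _design(dist, np.ones(len(thick)), thick)
    x0 = _design(dist, np.zeros(len(thick)), thick)
    return float(np.mean((x1 - x0) @ fit.beta))


# ---------------------------------------------------------------------- FDR
def fdr_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order.

    q(i) = min_{j >= i} p(j) * m / j over the ascending sort, capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be one-dimensional")
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    q = np.empty(m)
    q[order] = q_sorted
    return q


# -------------------------------------------------------------- full driver
def run_full_inference(
    long_table: pd.DataFrame,
    method: str = "REML",
    distance_coding: str = "standard",
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, dict]:
    """Fit one mixed model per (ROI, metric) and FDR-adjust all AMEs jointly.

    Returns the AME table (one row per ROI x metric x depth) and a summary
    dict with model, fallback and p-value counts.  Unconverged cells keep
    their rows with missing estimates; the run continues.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    cells = sorted(
        long_table.groupby(["roi", "metric"]).groups.keys(), key=lambda t: (t[0], t[1])
    )
    rows = []
    n_fallback = 0
    n_unconverged = 0
    for roi, metric in cells:
        sub = long_table[(long_table.roi == roi) & (long_table.metric == metric)]
        fit = fit_profile_lmm(sub, method=method, distance_coding=distance_coding)
        if fit.fallback_used and fit.converged:
            n_fallback += 1
        if not fit.converged:
            n_unconverged += 1
            log.warning("model (roi=%s, metric=%s) did not converge", roi, metric)
            for depth in range(4):
                rows.append(
                    {
                        "roi": roi, "metric": metric, "depth_label": DEPTH_LABELS[depth],
                        "ame": np.nan, "se": np.nan, "ci_low": np.nan, "ci_high": np.nan,
                        "p": np.nan, "p_fdr": np.nan, "significant": False,
                        "fallback_used": fit.fallback_used, "converged": False,
                    }
                )
            continue
        for res in estimate_ames(fit, roi=roi, metric=metric):
            rows.append(
                {
                    "roi": roi, "metric": metric,
                    "depth_label": DEPTH_LABELS[res.depth_index],
                    "ame": res.ame, "se": res.se,
                    "ci_low": res.ci_low, "ci_high": res.ci_high,
                    "p": res.p, "p_fdr": np.nan, "significant": False,
                    "fallback_used": fit.fallback_used, "converged": True,
                }
            )
    ame_df = pd.DataFrame(rows)
    finite = np.isfinite(ame_df.p.to_numpy())
    if finite.any():
        adj = fdr_adjust(ame_df.p.to_numpy()[finite])
        ame_df.loc[finite, "p_fdr"] = adj
        ame_df.loc[finite, "significant"] = adj < alpha
    info = {
        "n_models": len(cells),
        "n_fallback": n_fallback,
        "n_unconverged": n_unconverged,
        "n_pvalues": int(finite.sum()),
        "n_significant": int(ame_df.significant.sum()),
        "alpha": alpha,
        "method": method,
        "distance_coding": distance_coding,
    }
    log.info(
        "fitted %(n_models)d models (%(n_fallback)d fallback, %(n_unconverged)d "
        "unconverged); %(n_pvalues)d p-values entered FDR", info,
    )
    return ame_df, info
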