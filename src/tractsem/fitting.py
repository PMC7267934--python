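"""Maximum-likelihood estimation of MIMIC/CFA models and fit statistics.

The normal-theory ML discrepancy between a sample covariance ``S`` and the
model-implied covariance ``Sigma(theta)`` is

    F_ML = ln|Sigma| + tr(S Sigma^-1) - ln|S| - m

minimized over the free parameters with a quasi-Newton method on a
transformed parameterization (log scale for the positive variances, raw
scale for loadings, regressions and covariances).  Gradients are analytic.

Fit statistics follow the conventions common to SEM software:

* chi^2 = (N-1) * F_ML  (classic Wishart convention; ``N * F_ML`` optional),
* RMSEA point sqrt(max(chi2-df,0)/(df (N-1))) with a noncentral-chi^2
  confidence interval,
* CFI against the independence baseline,
* SRMR over the lower triangle of the standardized residuals including the
  diagonal,
* BIC = -2 loglik + k ln N with the full multivariate-normal loglikelihood,
* the Satorra-Bentler scaling factor c = tr(U Gamma_N)/df from the raw data
  (fourth-order moments), reported separately from the unscaled chi^2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .model import (
    ModelSpec,
    ParameterSet,
    baseline_model,
    count_df,
    count_free_parameters,
    implied_moments,
)

__all__ = [
    "FitResult",
    "sample_moments",
    "f_ml",
    "fit_ml",
    "chi_square",
    "p_value",
    "rmsea",
    "cfi",
    "srmr",
    "bic",
    "loglikelihood",
    "satorra_bentler_c",
    "r_squared",
    "ParameterIndex",
]

_LOG_FLOOR = -30.0  # lower bound for log-variances (variance >= ~1e-13)


# ---------------------------------------------------------------------------
# parameter indexing


@dataclass(frozen=True)
class _Slot:
    block: str  # "lam" | "gamma" | "psi" | "theta" | "phi"
    i: int
    j: int
    log: bool
    penalized: bool
    name: str


class ParameterIndex:
    """Maps the free parameters of a :class:`ModelSpec` to a flat vector.

    Positive variances (Theta and Psi diagonals, Phi diagonal when free) are
    stored on the log scale so the optimizer works on an unconstrained
    vector; ``unpack`` returns natural-scale matrices.
    """

    def __init__(self, spec: ModelSpec):
        self.spec = spec
        slots: list[_Slot] = []
        for e in spec.measurement_edges:
            if e.fixed is None:
                i, j = spec.indicator_index(e.indicator), spec.latent_index(e.latent)
                slots.append(_Slot("lam", i, j, False, False, f"{e.indicator}~{e.latent}"))
        for e in spec.structural_edges:
            j, k = spec.latent_index(e.latent), spec.predictor_index(e.predictor)
            slots.append(_Slot("gamma", j, k, False, e.penalized, f"{e.latent}~{e.predictor}"))
        L = spec.n_latents
        if spec.identification != "unit_variance":
            for j in range(L):
                slots.append(_Slot("psi", j, j, True, False, f"psi[{spec.latents[j]}]"))
        if spec.latent_disturbance_mode == "full":
            for j in range(L):
                for k in range(j + 1, L):
                    slots.append(
                        _Slot("psi", j, k, False, False,
                              f"psi[{spec.latents[j]},{spec.latents[k]}]")
                    )
        if spec.indicator_residual_mode == "free":
            for i, ind in enumerate(spec.indicators):
                slots.append(_Slot("theta", i, i, True, False, f"theta[{ind}]"))
        if spec.exogenous_cov_mode == "free":
            q = spec.n_predictors
            for i in range(q):
                slots.append(_Slot("phi", i, i, True, False, f"phi[{spec.predictors[i]}]"))
            for i in range(q):
                for k in range(i + 1, q):
                    slots.append(
                        _Slot("phi", i, k, False, False,
                              f"phi[{spec.predictors[i]},{spec.predictors[k]}]")
                    )
        self.slots = tuple(slots)
        self.names = tuple(s.name for s in slots)
        self.penalized_mask = np.array([s.penalized for s in slots], dtype=bool)

    @property
    def n_free(self) -> int:
        return len(self.slots)

    def unpack(self, theta: np.ndarray, phi_fixed: np.ndarray | None = None) -> ParameterSet:
        spec = self.spec
        p, q, L = spec.n_indicators, spec.n_predictors, spec.n_latents
        lam = np.zeros((p, L))
        for e in spec.measurement_edges:
            if e.fixed is not None:
                lam[spec.indicator_index(e.indicator), spec.latent_index(e.latent)] = e.fixed
        gam = np.zeros((L, q))
        psi = np.eye(L) if spec.identification == "unit_variance" else np.zeros((L, L))
        th = np.zeros(p)
        if spec.exogenous_cov_mode == "fixed":
            if q and phi_fixed is None:
                raise ValueError("phi_fixed required when exogenous_cov_mode='fixed'")
            phi = np.asarray(phi_fixed, dtype=float) if q else np.zeros((0, 0))
        else:
            phi = np.zeros((q, q))
        for s, v in zip(self.slots, theta):
            val = np.exp(v) if s.log else v
            if s.block == "lam":
                lam[s.i, s.j] = val
            elif s.block == "gamma":
                gam[s.i, s.j] = val
            elif s.block == "psi":
                psi[s.i, s.j] = val
                psi[s.j, s.i] = val
            elif s.block == "theta":
                th[s.i] = val
            elif s.block == "phi":
                phi[s.i, s.j] = val
                phi[s.j, s.i] = val
        return ParameterSet(lam, gam, psi, th, phi)

    def pack(self, params: ParameterSet) -> np.ndarray:
        out = np.empty(self.n_free)
        mats = {"lam": params.lam, "gamma": params.gamma, "psi": params.psi,
                "phi": params.phi}
        for k, s in enumerate(self.slots):
            v = params.theta[s.i] if s.block == "theta" else mats[s.block][s.i, s.j]
            out[k] = np.log(max(v, np.exp(_LOG_FLOOR))) if s.log else v
        return out

    # -- start values --------------------------------------------------------

    def start_values(self, S: np.ndarray) -> np.ndarray:
        """Heuristic starts: each marker's observed variance split 50/50
        between latent disturbance and residual; other loadings from the
        covariance with the marker; regressions at 0."""
        spec = self.spec
        markers: dict[str, int] = {}
        for e in spec.measurement_edges:
            if e.fixed is not None:
                markers[e.latent] = spec.indicator_index(e.indicator)
        theta0 = np.empty(self.n_free)
        for k, s in enumerate(self.slots):
            if s.block == "lam":
                lat = spec.latents[s.j]
                if lat in markers:
                    mi = markers[lat]
                    v = S[s.i, mi] / (0.5 * S[mi, mi])
                else:  # unit-variance identification: start near sqrt(var/2)
                    v = np.sqrt(0.5 * S[s.i, s.i])
                theta0[k] = v
            elif s.block == "gamma":
                theta0[k] = 0.0
            elif s.block == "psi":
                if s.i == s.j:
                    lat = spec.latents[s.i]
                    v = 0.5 * S[markers[lat], markers[lat]] if lat in markers else 1.0
                    theta0[k] = np.log(v)
                else:
                    li, lj = spec.latents[s.i], spec.latents[s.j]
                    if li in markers and lj in markers:
                        theta0[k] = 0.5 * S[markers[li], markers[lj]]
                    else:
                        theta0[k] = 0.0
            elif s.block == "theta":
                theta0[k] = np.log(0.5 * S[s.i, s.i])
            elif s.block == "phi":
                p = spec.n_indicators
                sxx = S[p:, p:]
                theta0[k] = np.log(sxx[s.i, s.i]) if s.i == s.j else sxx[s.i, s.j]
        return theta0


# ---------------------------------------------------------------------------
# sample moments and the ML discrepancy


def sample_moments(table: pd.DataFrame, columns=None) -> tuple[pd.DataFrame, int]:
    """Sample covariance (divisor N-1) after listwise deletion.

    Returns ``(S, N)`` with ``S`` a labelled DataFrame.  Raises on zero
    variance or N <= number of variables; warns on a rank-deficient S.
    """
    df = table[list(columns)] if columns is not None else table
    df = df.dropna()
    n = len(df)
    m = df.shape[1]
    if n <= m:
        raise ValueError(f"need more observations ({n}) than variables ({m})")
    X = df.to_numpy(dtype=float)
    S = np.cov(X, rowvar=False, ddof=1)
    S = np.atleast_2d(S)
    variances = np.diag(S)
    tol = max(np.max(variances), 0.0) * 1e-12
    if np.any(variances <= tol):
        bad = df.columns[np.flatnonzero(variances <= tol)].tolist()
        raise ValueError(f"zero-variance column(s): {bad}")
    if np.linalg.matrix_rank(S) < m:
        warnings.warn("sample covariance matrix is singular", stacklevel=2)
    return pd.DataFrame(S, index=df.columns, columns=df.columns), n


def f_ml(S: np.ndarray, sigma: np.ndarray) -> float:
    """Normal-theory ML discrepancy; >= 0, zero iff Sigma == S."""
    S = np.asarray(S, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    m = S.shape[0]
    try:
        c = np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError as exc:
        raise ValueError("implied covariance is not positive definite") from exc
    logdet_sigma = 2.0 * np.sum(np.log(np.diag(c)))
    sign, logdet_s = np.linalg.slogdet(S)
    if sign <= 0:
        raise ValueError("sample covariance is not positive definite")
    sinv_S = np.linalg.solve(sigma, S)
    return float(logdet_sigma + np.trace(sinv_S) - logdet_s - m)


def _objective_pieces(theta, idx: ParameterIndex, S, phi_fixed):
    """F_ML and its gradient w.r.t. the transformed free vector.

    Returns (F, grad, params, sigma); F = inf (grad zeros) when the implied
    covariance is not positive definite, which the line search backtracks
    out of.
    """
    spec = idx.spec
    params = idx.unpack(theta, phi_fixed)
    sigma = implied_moments(spec, params)
    try:
        cho = np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError:
        return np.inf, np.zeros_like(theta), params, sigma
    m = sigma.shape[0]
    inv = np.linalg.inv(sigma)
    logdet_sigma = 2.0 * np.sum(np.log(np.diag(cho)))
    _, logdet_s = np.linalg.slogdet(S)
    F = logdet_sigma + np.trace(inv @ S) - logdet_s - m
    G = inv - inv @ S @ inv  # dF/dSigma (symmetric)
    p, q = spec.n_indicators, spec.n_predictors
    Gyy, Gyx, Gxx = G[:p, :p], G[:p, p:], G[p:, p:]
    lam, gam, psi, phi = params.lam, params.gamma, params.psi, params.phi
    M = gam @ phi @ gam.T + psi if q else psi
    dlam = 2.0 * (Gyy @ lam @ M)
    if q:
        dlam += 2.0 * (Gyx @ phi @ gam.T)
        dgam = 2.0 * (lam.T @ Gyy @ lam @ gam @ phi + lam.T @ Gyx @ phi)
    else:
        dgam = np.zeros_like(gam)
    dpsi = lam.T @ Gyy @ lam
    dtheta = np.diag(Gyy).copy()
    if q and spec.exogenous_cov_mode == "free":
        LG = lam @ gam
        cross = LG.T @ Gyx
        dphi = Gxx + cross + cross.T + LG.T @ Gyy @ LG
        dphi = (dphi + dphi.T) / 2.0
    else:
        dphi = None
    grad = np.empty_like(theta)
    for k, s in enumerate(idx.slots):
        if s.block == "lam":
            g = dlam[s.i, s.j]
        elif s.block == "gamma":
            g = dgam[s.i, s.j]
        elif s.block == "psi":
            g = dpsi[s.i, s.j] if s.i == s.j else 2.0 * dpsi[s.i, s.j]
        elif s.block == "theta":
            g = dtheta[s.i]
        else:  # phi
            g = dphi[s.i, s.j] if s.i == s.j else 2.0 * dphi[s.i, s.j]
        if s.log:
            g *= np.exp(theta[k])
        grad[k] = g
    return float(F), grad, params, sigma


def delta_matrix(theta, idx: ParameterIndex, phi_fixed=None, include_fixed_phi=False):
    """Jacobian d vech(Sigma) / d theta_k (lower-triangle vech, model order).

    With ``include_fixed_phi`` the entries of a fixed-at-sample Phi are
    appended as pseudo-parameters (used by the Satorra-Bentler factor, where
    the sample exogenous covariances are estimated quantities).
    """
    spec = idx.spec
    params = idx.unpack(theta, phi_fixed)
    p, q = spec.n_indicators, spec.n_predictors
    m = p + q
    lam, gam, psi, phi = params.lam, params.gamma, params.psi, params.phi
    M = gam @ phi @ gam.T + psi if q else psi
    rows_l, cols_l = np.tril_indices(m)
    cols = []

    def dsigma_to_vech(dsig):
        return dsig[rows_l, cols_l]

    def assemble(dyy=None, dyx=None, dxx=None):
        d = np.zeros((m, m))
        if dyy is not None:
            d[:p, :p] = dyy
        if dyx is not None:
            d[:p, p:] = dyx
            d[p:, :p] = dyx.T
        if dxx is not None:
            d[p:, p:] = dxx
        return d

    def basis(nr, nc, i, j):
        E = np.zeros((nr, nc))
        E[i, j] = 1.0
        return E

    for k, s in enumerate(idx.slots):
        if s.block == "lam":
            E = basis(p, spec.n_latents, s.i, s.j)
            dyy = E @ M @ lam.T
            dyy = dyy + dyy.T
            dyx = E @ gam @ phi if q else None
            d = assemble(dyy, dyx)
        elif s.block == "gamma":
            E = basis(spec.n_latents, q, s.i, s.j)
            dM = E @ phi @ gam.T
            dM = dM + dM.T
            d = assemble(lam @ dM @ lam.T, lam @ E @ phi)
        elif s.block == "psi":
            E = basis(spec.n_latents, spec.n_latents, s.i, s.j)
            if s.i != s.j:
                E[s.j, s.i] = 1.0
            d = assemble(lam @ E @ lam.T)
        elif s.block == "theta":
            d = assemble(basis(p, p, s.i, s.i))
        else:  # phi (free)
            E = basis(q, q, s.i, s.j)
            if s.i != s.j:
                E[s.j, s.i] = 1.0
            LG = lam @ gam
            d = assemble(LG @ E @ LG.T, LG @ E, E)
        if s.log:
            d = d * np.exp(theta[k])
        cols.append(dsigma_to_vech(d))
    if include_fixed_phi and q and spec.exogenous_cov_mode == "fixed":
        LG = lam @ gam
        for i in range(q):
            for j in range(i, q):
                E = basis(q, q, i, j)
                if i != j:
                    E[j, i] = 1.0
                d = assemble(LG @ E @ LG.T, LG @ E, E)
                cols.append(dsigma_to_vech(d))
    return np.column_stack(cols)


# ---------------------------------------------------------------------------
# fit indices


def chi_square(F: float, N: int, multiplier: str = "nm1") -> float:
    """Likelihood-ratio test statistic from the minimized discrepancy."""
    if multiplier == "nm1":
        return (N - 1) * F
    if multiplier == "n":
        return N * F
    raise ValueError("multiplier must be 'nm1' or 'n'")


def p_value(chi2: float, df: int) -> float:
    if df == 0:
        return 1.0
    return float(stats.chi2.sf(chi2, df))


def rmsea(chi2: float, df: int, N: int, level: float = 0.90):
    """RMSEA point estimate and noncentrality-based confidence interval.

    Endpoints solve the noncentral-chi^2 coverage equations; both are
    truncated at zero.  ``df == 0`` is undefined and raises.
    """
    if df <= 0:
        raise ValueError("RMSEA is undefined for df = 0")
    point = float(np.sqrt(max(chi2 - df, 0.0) / (df * (N - 1))))
    alpha = (1.0 - level) / 2.0

    def nc_solving(target):
        # noncentrality lam with P(chi2_df(lam) <= chi2_obs) = target
        f0 = stats.chi2.cdf(chi2, df)  # lam = 0
        if f0 < target:
            return 0.0
        hi = max(chi2, df) + 10.0
        while stats.ncx2.cdf(chi2, df, hi) > target:
            hi *= 2.0
            if hi > 1e8:
                break
        return float(optimize.brentq(
            lambda nc: stats.ncx2.cdf(chi2, df, nc) - target, 1e-12, hi))

    lam_lo = nc_solving(1.0 - alpha)
    lam_hi = nc_solving(alpha)
    lo = float(np.sqrt(lam_lo / (df * (N - 1))))
    hi = float(np.sqrt(lam_hi / (df * (N - 1))))
    return point, lo, hi


def cfi(chi2: float, df: int, chi2_base: float, df_base: int) -> float:
    num = max(chi2 - df, 0.0)
    den = max(chi2_base - df_base, chi2 - df, 0.0)
    if den == 0.0:
        return 1.0
    return float(1.0 - num / den)


def srmr(S: np.ndarray, sigma: np.ndarray) -> float:
    """Root mean square standardized residual, lower triangle incl. diagonal."""
    S = np.asarray(S, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    ds = np.sqrt(np.diag(S))
    dsig = np.sqrt(np.diag(sigma))
    Rs = S / np.outer(ds, ds)
    Rsig = sigma / np.outer(dsig, dsig)
    # each matrix standardized by its own diagonal, so diagonal residuals
    # vanish but still enter the element count
    resid = Rs - Rsig
    iu = np.tril_indices(S.shape[0])
    return float(np.sqrt(np.mean(resid[iu] ** 2)))


def loglikelihood(S: np.ndarray, sigma: np.ndarray, N: int) -> float:
    """Full multivariate-normal loglikelihood at the estimate (S divisor N-1)."""
    m = S.shape[0]
    s_ml = (N - 1) / N * np.asarray(S, dtype=float)
    sign, logdet = np.linalg.slogdet(sigma)
    if sign <= 0:
        raise ValueError("implied covariance is not positive definite")
    tr = np.trace(np.linalg.solve(sigma, s_ml))
    return float(-N / 2.0 * (m * np.log(2.0 * np.pi) + logdet + tr))


def bic(loglik: float, k_free: int, N: int) -> float:
    return float(-2.0 * loglik + k_free * np.log(N))


def r_squared(params: ParameterSet, spec: ModelSpec, sigma: np.ndarray | None = None):
    """Per indicator, 1 - Theta_ii / Sigma_ii (variance explained by its latent)."""
    if sigma is None:
        sigma = implied_moments(spec, params)
    out = {}
    for i, ind in enumerate(spec.indicators):
        out[ind] = float(1.0 - params.theta[i] / sigma[i, i])
    return out


# ---------------------------------------------------------------------------
# the fit result and the ML driver


@dataclass
class FitResult:
    """Estimates plus the fit-statistic battery for one fitted model."""

    spec: ModelSpec
    estimates: ParameterSet
    theta: np.ndarray
    names: tuple[str, ...]
    f_ml: float
    loglik: float
    chi_square: float
    df: int
    p_value: float
    rmsea: float
    rmsea_ci: tuple[float, float]
    cfi: float
    srmr: float
    bic: float
    n_free: int
    n_obs: int
    r_squared: dict[str, float]
    converged: bool
    n_iter: int
    grad_norm: float
    heywood: bool
    sb_scaling_factor: float | None = None
    sigma: np.ndarray | None = None
    S: np.ndarray | None = None

    def parameter_table(self) -> pd.DataFrame:
        return pd.DataFrame({"parameter": list(self.names), "estimate": self.theta_natural})

    @property
    def theta_natural(self) -> np.ndarray:
        idx = ParameterIndex(self.spec)
        out = self.theta.copy()
        for k, s in enumerate(idx.slots):
            if s.log:
                out[k] = np.exp(out[k])
        return out

    def to_dict(self) -> dict:
        d = {
            "f_ml": self.f_ml,
            "loglik": self.loglik,
            "chi_square": self.chi_square,
            "df": self.df,
            "p_value": self.p_value,
            "rmsea": self.rmsea,
            "rmsea_ci": list(self.rmsea_ci),
            "cfi": self.cfi,
            "srmr": self.srmr,
            "bic": self.bic,
            "n_free": self.n_free,
            "n_obs": self.n_obs,
            "r_squared": self.r_squared,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "grad_norm": self.grad_norm,
            "heywood": self.heywood,
            "sb_scaling_factor": self.sb_scaling_factor,
            "estimates": {n: float(v) for n, v in zip(self.names, self.theta_natural)},
        }
        return d

    def summary(self) -> str:
        lines = [
            f"chi2 = {self.chi_square:.3f}, df = {self.df}, p = {self.p_value:.3f}",
        ]
        if not np.isnan(self.rmsea):
            lines.append(
                f"RMSEA = {self.rmsea:.3f} ({self.rmsea_ci[0]:.3f}-{self.rmsea_ci[1]:.3f})"
            )
        lines += [
            f"CFI = {self.cfi:.3f}, SRMR = {self.srmr:.3f}",
            f"BIC = {self.bic:.3f} (k = {self.n_free}, N = {self.n_obs})",
        ]
        if self.sb_scaling_factor is not None:
            lines.append(f"Satorra-Bentler scaling factor = {self.sb_scaling_factor:.3f}")
        lines.append("R2: " + ", ".join(f"{k} = {v:.3f}" for k, v in self.r_squared.items()))
        if self.heywood:
            lines.append("warning: Heywood case (residual variance at the zero boundary)")
        if not self.converged:
            lines.append("warning: optimizer did not meet the convergence tolerance")
        return "\n".join(lines)


def _order_sample_cov(S, spec: ModelSpec) -> np.ndarray:
    if isinstance(S, pd.DataFrame):
        cols = list(spec.variables)
        missing = [c for c in cols if c not in S.columns]
        if missing:
            raise ValueError(f"sample covariance lacks columns {missing}")
        return S.loc[cols, cols].to_numpy(dtype=float)
    S = np.asarray(S, dtype=float)
    m = spec.n_indicators + spec.n_predictors
    if S.shape != (m, m):
        raise ValueError("sample covariance does not conform to the model")
    return S


def _newton_polish(fun, x, jac, bounds, gtol, max_iter=12):
    """Damped Newton steps on the transformed parameters.

    The Hessian comes from central differences of the analytic gradient
    (cheap at these dimensions) with a Levenberg-style shift when it is not
    positive definite; steps are backtracked on the objective and clipped to
    the variance bounds.
    """
    F, g = fun(x)
    n = len(x)
    lo = np.array([b[0] if b[0] is not None else -np.inf for b in bounds])
    hi = np.array([b[1] if b[1] is not None else np.inf for b in bounds])

    def proj_norm(xv, gv):
        p = np.abs(gv).copy()
        p[(xv <= lo + 1e-12) & (gv > 0)] = 0.0
        p[(xv >= hi - 1e-12) & (gv < 0)] = 0.0
        return float(np.max(p)) if n else 0.0

    for _ in range(max_iter):
        if proj_norm(x, g) < gtol / 5.0 or not np.isfinite(F):
            break
        h = 1e-5
        H = np.empty((n, n))
        for k in range(n):
            e = np.zeros(n)
            e[k] = h
            H[:, k] = (fun(x + e)[1] - fun(x - e)[1]) / (2 * h)
        H = (H + H.T) / 2.0
        w = np.linalg.eigvalsh(H)
        if w[0] < 1e-8:
            H = H + (1e-8 - w[0]) * np.eye(n)
        step = np.linalg.solve(H, -g)
        improved = False
        for _bt in range(30):
            x_new = np.clip(x + step, lo, hi)
            F_new, g_new = fun(x_new)
            if np.isfinite(F_new) and F_new <= F + 1e-14:
                improved = True
                break
            step *= 0.5
        if not improved:
            break
        x, F, g = x_new, F_new, g_new
    return x, F, g


def fit_ml(
    S,
    N: int,
    spec: ModelSpec,
    *,
    chi2_multiplier: str = "nm1",
    start: np.ndarray | None = None,
    max_iter: int = 500,
    gtol: float = 1e-7,
    compute_baseline: bool = True,
    n_restarts: int = 2,
) -> FitResult:
    """Fit ``spec`` to sample moments by maximum likelihood.

    ``S`` may be a labelled DataFrame (reordered to model order) or an
    ndarray already in model order (indicators then predictors).  Fixed
    parameters are never touched; Theta stays positive through the log
    transform.  Non-convergence is reported on the result, not raised; a
    Heywood case (residual variance at the zero boundary) is flagged.
    """
    S = _order_sample_cov(S, spec)
    idx = ParameterIndex(spec)
    p, q = spec.n_indicators, spec.n_predictors
    phi_fixed = S[p:, p:] if (q and spec.exogenous_cov_mode == "fixed") else None

    def fun(th):
        F, g, _, _ = _objective_pieces(th, idx, S, phi_fixed)
        return F, g

    theta0 = idx.start_values(S) if start is None else np.asarray(start, dtype=float)
    bounds = [(_LOG_FLOOR, 30.0) if s.log else (None, None) for s in idx.slots]

    def projected_gnorm(x, jac):
        # gradient components pushing into an active bound do not count:
        # the solution sits on the boundary (e.g. a Heywood case pinned at
        # the variance floor)
        g = np.abs(np.asarray(jac, dtype=float)).copy()
        for k, (lo, hi) in enumerate(bounds):
            if lo is not None and x[k] <= lo + 1e-12 and jac[k] > 0:
                g[k] = 0.0
            if hi is not None and x[k] >= hi - 1e-12 and jac[k] < 0:
                g[k] = 0.0
        return float(np.max(g)) if len(g) else 0.0

    best = None
    rng = np.random.default_rng(0)
    for attempt in range(n_restarts + 1):
        t0 = theta0 if attempt == 0 else theta0 + rng.normal(0, 0.1, size=theta0.shape)
        if idx.n_free == 0:
            res = optimize.OptimizeResult(x=np.zeros(0), nit=0, success=True)
            res.fun, res.jac = fun(res.x)[0], np.zeros(0)
        else:
            res = optimize.minimize(
                fun, t0, jac=True, method="L-BFGS-B", bounds=bounds,
                options={"maxiter": max_iter, "ftol": 1e-15, "gtol": gtol / 10.0},
            )
        if idx.n_free and np.isfinite(res.fun):
            # Newton polish with a finite-difference Hessian of the analytic
            # gradient; L-BFGS alone can stall marginally above tolerance
            x, Fx, jac = _newton_polish(fun, res.x, res.jac, bounds, gtol)
            res.x, res.fun, res.jac = x, Fx, jac
        gnorm = projected_gnorm(res.x, res.jac) if idx.n_free else 0.0
        if best is None or res.fun < best[0].fun - 1e-12:
            best = (res, gnorm)
        if np.isfinite(res.fun) and gnorm < gtol:
            break
    res, gnorm = best
    theta = res.x
    F, _, params, sigma = _objective_pieces(theta, idx, S, phi_fixed)
    if not np.isfinite(F):  # pathological: fall back to start
        theta = theta0
        F, _, params, sigma = _objective_pieces(theta, idx, S, phi_fixed)
    converged = bool(np.isfinite(F) and gnorm < gtol)
    heywood = bool(
        np.any(params.theta < 1e-6 * np.max(np.diag(S)))
        and spec.indicator_residual_mode == "free"
    )

    df = count_df(spec)
    chi2 = chi_square(F, N, chi2_multiplier)
    pv = p_value(chi2, df)
    if df > 0:
        rm, lo, hi = rmsea(chi2, df, N)
    else:
        rm, lo, hi = float("nan"), float("nan"), float("nan")
    if compute_baseline:
        base = fit_ml(S, N, baseline_model(spec), chi2_multiplier=chi2_multiplier,
                      compute_baseline=False, n_restarts=0)
        cfi_val = cfi(chi2, df, base.chi_square, base.df)
    else:
        cfi_val = float("nan")
    ll = loglikelihood(S, sigma, N)
    k_free = count_free_parameters(spec)
    bic_val = bic(ll, k_free, N) if converged else float("nan")
    return FitResult(
        spec=spec,
        estimates=params,
        theta=theta,
        names=idx.names,
        f_ml=float(F),
        loglik=ll,
        chi_square=float(chi2),
        df=df,
        p_value=pv,
        rmsea=rm,
        rmsea_ci=(lo, hi),
        cfi=cfi_val,
        srmr=srmr(S, sigma),
        bic=bic_val,
        n_free=k_free,
        n_obs=N,
        r_squared=r_squared(params, spec, sigma),
        converged=converged,
        n_iter=int(getattr(res, "nit", 0)),
        grad_norm=gnorm,
        heywood=heywood,
        sigma=sigma,
        S=S,
    )


# ---------------------------------------------------------------------------
# Satorra-Bentler scaling


def duplication_matrix(m: int) -> np.ndarray:
    """D_m with vec(A) = D_m vech(A) for symmetric A (lower-triangle vech)."""
    rows, cols = np.tril_indices(m)
    nvech = len(rows)
    D = np.zeros((m * m, nvech))
    for k, (i, j) in enumerate(zip(rows, cols)):
        D[i * m + j, k] = 1.0
        D[j * m + i, k] = 1.0
    return D


def satorra_bentler_c(table: pd.DataFrame, fit: FitResult, spec: ModelSpec) -> float:
    """Satorra-Bentler scaling factor from the raw data.

    c = tr(U Gamma_N)/df, with Gamma_N the empirical asymptotic covariance
    of vech(S), W the normal-theory weight matrix at the estimate, and U the
    residual weight after projecting out the model derivative space Delta.
    Requires df > 0 and the raw subject table (fourth-order moments).
    """
    df = fit.df
    if df == 0:
        raise ValueError("Satorra-Bentler factor is undefined for df = 0")
    cols = list(spec.variables)
    X = table[cols].dropna().to_numpy(dtype=float)
    N, m = X.shape
    Z = X - X.mean(axis=0)
    rows, colx = np.tril_indices(m)
    d = Z[:, rows] * Z[:, colx]  # N x nvech products
    dc = d - d.mean(axis=0)
    gamma_n = dc.T @ dc / N
    sigma = fit.sigma
    inv = np.linalg.inv(sigma)
    D = duplication_matrix(m)
    W = 0.5 * D.T @ np.kron(inv, inv) @ D
    idx = ParameterIndex(spec)
    p = spec.n_indicators
    phi_fixed = fit.estimates.phi if spec.n_predictors else None
    Delta = delta_matrix(fit.theta, idx, phi_fixed=phi_fixed, include_fixed_phi=True)
    WD = W @ Delta
    middle = Delta.T @ WD
    try:
        sol = np.linalg.solve(middle, WD.T)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular Delta' W Delta in Satorra-Bentler factor") from exc
    U = W - WD @ sol
    return float(np.trace(U @ gamma_n) / df)
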