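"""Scikit-learn style estimators wrapping the SEM machinery.

``MimicSEM`` fits a MIMIC (or plain CFA when ``predictors`` is empty) by
maximum likelihood; ``ElasticNetMimic`` fits the elastic-net penalized path
over the lambda grid and selects a sparse structural model by BIC.  Both
follow the fit / fitted-attribute / ``get_params`` conventions and accept a
subject-level :class:`pandas.DataFrame` with named columns.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.exceptions import NotFittedError

from .fitting import fit_ml, sample_moments, satorra_bentler_c
from .model import build_watershed_spec
from .penalized import RegConfig, export_trajectories, fit_path

__all__ = ["MimicSEM", "ElasticNetMimic", "DEFAULT_ASSIGNMENT"]

DEFAULT_ASSIGNMENT = {"FI": ["PO", "PS"], "CI": ["VC", "WM"]}


def _check_table(X, variables) -> pd.DataFrame:
    if not isinstance(X, pd.DataFrame):
        raise TypeError("X must be a pandas DataFrame with named columns")
    missing = [v for v in variables if v not in X.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    sub = X[list(variables)]
    bad = [c for c in sub.columns if not np.issubdtype(sub[c].dtype, np.number)]
    if bad:
        raise ValueError(f"non-numeric columns: {bad}")
    return sub


class MimicSEM(BaseEstimator):
    """Maximum-likelihood MIMIC / CFA estimator.

    Parameters
    ----------
    assignment : mapping latent -> list of indicators (default: the
        fluid/crystallized split ``{"FI": ["PO", "PS"], "CI": ["VC", "WM"]}``).
    predictors : observed exogenous causes of the latents (empty = CFA).
    identification : "marker" fixes the first loading per latent at 1;
        "unit_variance" fixes latent disturbance variances instead.
    chi2_multiplier : "nm1" for (N-1) F_ML (default) or "n" for N F_ML.
    exogenous_cov_mode : "fixed" (at the sample covariance) or "free".
    compute_sb : also compute the Satorra-Bentler scaling factor (needs the
        raw table; skipped when df = 0).

    Attributes (after ``fit``)
    --------------------------
    spec_, params_, result_ : model structure, estimates, full FitResult.
    chi_square_, df_, p_value_, rmsea_, rmsea_ci_, cfi_, srmr_, bic_,
    r_squared_, sb_scaling_, converged_, n_iter_, n_obs_ : fit statistics.
    """

    def __init__(self, assignment=None, predictors=(), identification="marker",
                 chi2_multiplier="nm1", exogenous_cov_mode="fixed",
                 compute_sb=True, max_iter=500, gtol=1e-7):
        self.assignment = assignment
        self.predictors = predictors
        self.identification = identification
        self.chi2_multiplier = chi2_multiplier
        self.exogenous_cov_mode = exogenous_cov_mode
        self.compute_sb = compute_sb
        self.max_iter = max_iter
        self.gtol = gtol

    def _build_spec(self):
        assignment = self.assignment or {k: list(v) for k, v in DEFAULT_ASSIGNMENT.items()}
        return build_watershed_spec(
            assignment, tuple(self.predictors),
            identification=self.identification,
            exogenous_cov_mode=self.exogenous_cov_mode,
        )

    def fit(self, X, y=None):
        spec = self._build_spec()
        table = _check_table(X, spec.variables)
        S, N = sample_moments(table)
        res = fit_ml(S, N, spec, chi2_multiplier=self.chi2_multiplier,
                     max_iter=self.max_iter, gtol=self.gtol)
        self.spec_ = spec
        self.result_ = res
        self.params_ = res.estimates
        self.f_ml_ = res.f_ml
        self.chi_square_ = res.chi_square
        self.df_ = res.df
        self.p_value_ = res.p_value
        self.rmsea_ = res.rmsea
        self.rmsea_ci_ = res.rmsea_ci
        self.cfi_ = res.cfi
        self.srmr_ = res.srmr
        self.bic_ = res.bic
        self.loglik_ = res.loglik
        self.r_squared_ = res.r_squared
        self.converged_ = res.converged
        self.n_iter_ = res.n_iter
        self.n_obs_ = N
        self.sb_scaling_ = None
        if self.compute_sb and res.df > 0:
            self.sb_scaling_ = satorra_bentler_c(table, res, spec)
            res.sb_scaling_factor = self.sb_scaling_
        return self

    def summary(self) -> str:
        if not hasattr(self, "result_"):
            raise NotFittedError("call fit first")
        return self.result_.summary()


class ElasticNetMimic(BaseEstimator):
    """Elastic-net penalized MIMIC path with BIC model selection.

    All structural regressions (tract FA and, unless exempted, age) carry
    the penalty; measurement and variance parameters stay free.  Variables
    are standardized internally before path fitting, so coefficients are on
    the standardized-predictor / marker-identified-latent scale.

    Attributes (after ``fit``): ``path_`` (full per-lambda results),
    ``selected_lambda_``, ``selected_edges_`` (standardized),
    ``selected_edges_raw_`` (back-transformed), ``coef_path_`` (DataFrame
    of trajectories), ``bic_path_``, ``n_nonzero_path_``, ``best_index_``.
    """

    def __init__(self, assignment=None, predictors=(), lambda_grid=None,
                 alpha=0.5, sparsify_tol=1e-3, penalize_age=True,
                 identification="marker", chi2_multiplier="nm1",
                 standardize=True):
        self.assignment = assignment
        self.predictors = predictors
        self.lambda_grid = lambda_grid
        self.alpha = alpha
        self.sparsify_tol = sparsify_tol
        self.penalize_age = penalize_age
        self.identification = identification
        self.chi2_multiplier = chi2_multiplier
        self.standardize = standardize

    def fit(self, X, y=None):
        assignment = self.assignment or {k: list(v) for k, v in DEFAULT_ASSIGNMENT.items()}
        exempt = () if self.penalize_age else ("age",)
        spec = build_watershed_spec(assignment, tuple(self.predictors),
                                    identification=self.identification,
                                    exempt=exempt)
        table = _check_table(X, spec.variables)
        kwargs = {"alpha": self.alpha, "sparsify_tol": self.sparsify_tol,
                  "standardize": self.standardize}
        if self.lambda_grid is not None:
            kwargs["lambda_grid"] = np.asarray(self.lambda_grid, dtype=float)
        config = RegConfig(**kwargs)
        path = fit_path(table, spec, config, chi2_multiplier=self.chi2_multiplier)
        self.spec_ = spec
        self.path_ = path
        self.best_index_ = path.selected_index
        self.selected_lambda_ = path.selected_lambda
        self.selected_edges_ = path.selected_edges()
        self.selected_edges_raw_ = path.selected_edges(unstandardized=True)
        self.coef_path_ = export_trajectories(path)
        self.bic_path_ = np.array([e.bic_reg for e in path.entries])
        self.n_nonzero_path_ = np.array([e.n_nonzero for e in path.entries])
        self.n_obs_ = path.n_obs
        return self

    @property
    def selected_support_(self):
        if not hasattr(self, "selected_edges_"):
            raise NotFittedError("call fit first")
        return {(p, l) for p, l, _ in self.selected_edges_}
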