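"""MIMIC / CFA model structure and model-implied covariance algebra.

The models handled here belong to the Multiple-Indicator, Multiple-Cause
(MIMIC) family of linear structural equation models: observed exogenous
causes ``x`` (e.g. mean tract-based FA of white-matter fascicles and age)
feed a small set of latent variables ``eta`` (fluid and crystallized
intelligence), which in turn produce observed indicators ``y`` (WAIS-III
index scores)::

    eta = Gamma x + zeta,      zeta ~ (0, Psi)
    y   = Lambda eta + eps,    eps  ~ (0, Theta)      Cov(x) = Phi

All analysis is on centered data: means/intercepts are not modeled.  The
model-implied second moments over the stacked vector (y, x) are

    Sigma_yy = Lambda (Gamma Phi Gamma' + Psi) Lambda' + Theta
    Sigma_yx = Lambda Gamma Phi
    Sigma_xx = Phi

A pure confirmatory factor analysis (CFA) is the special case with no
predictors (``x`` empty), where ``Psi`` is the latent covariance matrix.

By default the exogenous covariance ``Phi`` is fixed at the sample
covariance of the predictors (conditional-on-x formulation), and predictor
moments are excluded from both the moment count and the free-parameter
count, so CFA degrees of freedom follow the usual convention and MIMIC df
is well defined.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

__all__ = [
    "MeasurementEdge",
    "StructuralEdge",
    "ModelSpec",
    "ParameterSet",
    "UnderIdentifiedError",
    "build_watershed_spec",
    "baseline_model",
    "implied_moments",
    "count_free_parameters",
    "count_df",
]


class UnderIdentifiedError(ValueError):
    """Raised when a model has more free parameters than sample moments."""


@dataclass(frozen=True)
class MeasurementEdge:
    """A loading of ``indicator`` on ``latent``; ``fixed`` pins its value."""

    latent: str
    indicator: str
    fixed: float | None = None


@dataclass(frozen=True)
class StructuralEdge:
    """A regression of ``latent`` on exogenous ``predictor``.

    ``penalized`` marks the coefficient as subject to the elastic-net
    penalty during path fitting; it has no effect on plain ML estimation.
    """

    predictor: str
    latent: str
    penalized: bool = True


@dataclass(frozen=True)
class ModelSpec:
    """Declarative MIMIC/CFA structure.

    Invariants (checked on construction): unique names, congeneric
    measurement structure (every indicator loads on exactly one latent),
    every latent has at least one indicator, exactly one identification
    constraint active per latent, penalized flags only on structural edges
    (by construction).
    """

    indicators: tuple[str, ...]
    predictors: tuple[str, ...]
    latents: tuple[str, ...]
    measurement_edges: tuple[MeasurementEdge, ...]
    structural_edges: tuple[StructuralEdge, ...] = ()
    latent_disturbance_mode: str = "full"  # "full" | "diagonal"
    indicator_residual_mode: str = "free"  # "free" | "zero"
    exogenous_cov_mode: str = "fixed"  # "fixed" (at sample cov) | "free"
    identification: str = "marker"  # "marker" | "unit_variance"

    def __post_init__(self):
        names = list(self.indicators) + list(self.predictors) + list(self.latents)
        if len(set(names)) != len(names):
            raise ValueError("variable names must be unique across blocks")
        if self.latent_disturbance_mode not in ("full", "diagonal"):
            raise ValueError(f"bad latent_disturbance_mode {self.latent_disturbance_mode!r}")
        if self.indicator_residual_mode not in ("free", "zero"):
            raise ValueError(f"bad indicator_residual_mode {self.indicator_residual_mode!r}")
        if self.exogenous_cov_mode not in ("fixed", "free"):
            raise ValueError(f"bad exogenous_cov_mode {self.exogenous_cov_mode!r}")
        if self.identification not in ("marker", "unit_variance"):
            raise ValueError(f"bad identification {self.identification!r}")
        loaded = [e.indicator for e in self.measurement_edges]
        if sorted(loaded) != sorted(self.indicators):
            raise ValueError(
                "congeneric structure violated: every indicator must load on "
                "exactly one latent"
            )
        per_latent = {lat: 0 for lat in self.latents}
        for e in self.measurement_edges:
            if e.latent not in per_latent:
                raise ValueError(f"measurement edge names unknown latent {e.latent!r}")
            per_latent[e.latent] += 1
        if any(n == 0 for n in per_latent.values()):
            raise ValueError("every latent needs at least one indicator")
        if self.identification == "marker":
            fixed_per_latent = {lat: 0 for lat in self.latents}
            for e in self.measurement_edges:
                if e.fixed is not None:
                    fixed_per_latent[e.latent] += 1
            if any(n != 1 for n in fixed_per_latent.values()):
                raise ValueError(
                    "marker identification requires exactly one fixed loading "
                    "per latent"
                )
        for e in self.structural_edges:
            if e.predictor not in self.predictors:
                raise ValueError(f"structural edge names unknown predictor {e.predictor!r}")
            if e.latent not in self.latents:
                raise ValueError(f"structural edge names unknown latent {e.latent!r}")

    # -- convenience lookups -------------------------------------------------

    @property
    def n_indicators(self) -> int:
        return len(self.indicators)

    @property
    def n_predictors(self) -> int:
        return len(self.predictors)

    @property
    def n_latents(self) -> int:
        return len(self.latents)

    @property
    def variables(self) -> tuple[str, ...]:
        """Observed variables in model order: indicators then predictors."""
        return tuple(self.indicators) + tuple(self.predictors)

    def indicator_index(self, name: str) -> int:
        return self.indicators.index(name)

    def latent_index(self, name: str) -> int:
        return self.latents.index(name)

    def predictor_index(self, name: str) -> int:
        return self.predictors.index(name)

    # -- serialization -------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "indicators": list(self.indicators),
            "predictors": list(self.predictors),
            "latents": list(self.latents),
            "edges": {
                "measurement": [
                    {"latent": e.latent, "indicator": e.indicator, "fixed": e.fixed}
                    for e in self.measurement_edges
                ],
                "structural": [
                    {"predictor": e.predictor, "latent": e.latent, "penalized": e.penalized}
                    for e in self.structural_edges
                ],
            },
            "identification": self.identification,
            "latent_disturbance_mode": self.latent_disturbance_mode,
            "indicator_residual_mode": self.indicator_residual_mode,
            "exogenous_cov_mode": self.exogenous_cov_mode,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        edges = d.get("edges", {})
        return cls(
            indicators=tuple(d["indicators"]),
            predictors=tuple(d.get("predictors", [])),
            latents=tuple(d["latents"]),
            measurement_edges=tuple(
                MeasurementEdge(e["latent"], e["indicator"], e.get("fixed"))
                for e in edges.get("measurement", [])
            ),
            structural_edges=tuple(
                StructuralEdge(e["predictor"], e["latent"], bool(e.get("penalized", True)))
                for e in edges.get("structural", [])
            ),
            identification=d.get("identification", "marker"),
            latent_disturbance_mode=d.get("latent_disturbance_mode", "full"),
            indicator_residual_mode=d.get("indicator_residual_mode", "free"),
            exogenous_cov_mode=d.get("exogenous_cov_mode", "fixed"),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ModelSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class ParameterSet:
    """Numeric MIMIC parameter matrices conforming to a :class:`ModelSpec`.

    ``lam`` is (n_indicators, n_latents), ``gamma`` (n_latents,
    n_predictors), ``psi`` (n_latents, n_latents) symmetric, ``theta`` the
    diagonal of the indicator residual covariance, ``phi`` (n_predictors,
    n_predictors) symmetric.
    """

    lam: np.ndarray
    gamma: np.ndarray
    psi: np.ndarray
    theta: np.ndarray
    phi: np.ndarray

    def copy(self) -> "ParameterSet":
        return ParameterSet(
            self.lam.copy(), self.gamma.copy(), self.psi.copy(),
            self.theta.copy(), self.phi.copy(),
        )

    def validate(self, spec: ModelSpec, atol: float = 0.0) -> None:
        p, q, L = spec.n_indicators, spec.n_predictors, spec.n_latents
        if self.lam.shape != (p, L) or self.gamma.shape != (L, q):
            raise ValueError("parameter matrices do not conform to the model")
        if self.psi.shape != (L, L) or self.phi.shape != (q, q) or self.theta.shape != (p,):
            raise ValueError("parameter matrices do not conform to the model")
        if not np.allclose(self.psi, self.psi.T, atol=1e-12):
            raise ValueError("psi must be symmetric")
        if q and not np.allclose(self.phi, self.phi.T, atol=1e-12):
            raise ValueError("phi must be symmetric")
        # zero pattern / fixed values
        allowed = np.zeros((p, L), dtype=bool)
        for e in spec.measurement_edges:
            i, j = spec.indicator_index(e.indicator), spec.latent_index(e.latent)
            allowed[i, j] = True
            if e.fixed is not None and abs(self.lam[i, j] - e.fixed) > atol:
                raise ValueError(f"fixed loading {e.indicator}~{e.latent} was modified")
        if np.any(np.abs(self.lam[~allowed]) > atol):
            raise ValueError("lambda zero pattern violated")
        allowed_g = np.zeros((L, q), dtype=bool)
        for e in spec.structural_edges:
            allowed_g[spec.latent_index(e.latent), spec.predictor_index(e.predictor)] = True
        if q and np.any(np.abs(self.gamma[~allowed_g]) > atol):
            raise ValueError("gamma zero pattern violated")


# ---------------------------------------------------------------------------
# spec builders


def build_watershed_spec(
    assignment: dict[str, list[str]],
    predictors=(),
    *,
    identification: str = "marker",
    penalize: bool = True,
    exempt: tuple[str, ...] = (),
    exogenous_cov_mode: str = "fixed",
) -> ModelSpec:
    """Build the hierarchical (watershed) MIMIC structure.

    ``assignment`` maps each latent variable to its indicator list (e.g.
    ``{"FI": ["PO", "PS"], "CI": ["VC", "WM"]}``).  Every predictor gets one
    structural edge into every latent, flagged as penalized unless listed in
    ``exempt`` (use ``exempt=("age",)`` to shield age from the penalty).
    With ``predictors=()`` this is a plain CFA with correlated factors.

    Marker identification fixes the first listed indicator's loading per
    latent at 1; ``identification="unit_variance"`` instead fixes each
    latent disturbance variance at 1 and frees all loadings.
    """
    if not assignment:
        raise ValueError("assignment must name at least one latent")
    latents = tuple(assignment)
    indicators: list[str] = []
    med: list[MeasurementEdge] = []
    for lat, inds in assignment.items():
        if not inds:
            raise ValueError(f"latent {lat!r} has no indicators")
        for k, ind in enumerate(inds):
            fixed = 1.0 if (identification == "marker" and k == 0) else None
            med.append(MeasurementEdge(lat, ind, fixed))
            indicators.append(ind)
    sed = tuple(
        StructuralEdge(x, lat, penalized=penalize and x not in exempt)
        for x in predictors
        for lat in latents
    )
    return ModelSpec(
        indicators=tuple(indicators),
        predictors=tuple(predictors),
        latents=latents,
        measurement_edges=tuple(med),
        structural_edges=sed,
        identification=identification,
        exogenous_cov_mode=exogenous_cov_mode,
    )


def baseline_model(spec: ModelSpec) -> ModelSpec:
    """Independence baseline used by CFI.

    All indicators mutually uncorrelated (one latent per indicator carrying
    its full variance, residuals fixed at zero) and uncorrelated with the
    predictors; the predictor block is untouched.
    """
    latents = tuple(f"_{ind}" for ind in spec.indicators)
    med = tuple(
        MeasurementEdge(lat, ind, fixed=1.0)
        for lat, ind in zip(latents, spec.indicators)
    )
    return ModelSpec(
        indicators=spec.indicators,
        predictors=spec.predictors,
        latents=latents,
        measurement_edges=med,
        structural_edges=(),
        latent_disturbance_mode="diagonal",
        indicator_residual_mode="zero",
        exogenous_cov_mode=spec.exogenous_cov_mode,
        identification="marker",
    )


# ---------------------------------------------------------------------------
# moment algebra and counting


def implied_moments(spec: ModelSpec, params: ParameterSet) -> np.ndarray:
    """Model-implied covariance over (indicators, predictors), exactly symmetric."""
    params.validate(spec, atol=np.inf)  # shape check only
    p, q = spec.n_indicators, spec.n_predictors
    lam, gam, psi, phi = params.lam, params.gamma, params.psi, params.phi
    m = p + q
    sigma = np.empty((m, m))
    eta_cov = gam @ phi @ gam.T + psi if q else psi
    syy = lam @ eta_cov @ lam.T
    syy[np.diag_indices(p)] += params.theta
    sigma[:p, :p] = syy
    if q:
        syx = lam @ gam @ phi
        sigma[:p, p:] = syx
        sigma[p:, :p] = syx.T
        sigma[p:, p:] = phi
    sigma = (sigma + sigma.T) / 2.0
    return sigma


def _n_psi_free(spec: ModelSpec) -> int:
    L = spec.n_latents
    n_diag = L if spec.identification != "unit_variance" else 0
    n_off = L * (L - 1) // 2 if spec.latent_disturbance_mode == "full" else 0
    return n_diag + n_off


def count_free_parameters(spec: ModelSpec) -> int:
    """Free parameters under the conditional-on-x counting convention.

    Fixed-at-sample ``Phi`` entries are not counted; with
    ``exogenous_cov_mode="free"`` they are.
    """
    n = sum(1 for e in spec.measurement_edges if e.fixed is None)
    n += len(spec.structural_edges)
    n += _n_psi_free(spec)
    if spec.indicator_residual_mode == "free":
        n += spec.n_indicators
    if spec.exogenous_cov_mode == "free":
        q = spec.n_predictors
        n += q * (q + 1) // 2
    return n


def count_moments(spec: ModelSpec) -> int:
    """Distinct sample moments entering the discrepancy, conditional on x."""
    p, q = spec.n_indicators, spec.n_predictors
    n = p * (p + 1) // 2 + p * q
    if spec.exogenous_cov_mode == "free":
        n += q * (q + 1) // 2
    return n


def count_df(spec: ModelSpec) -> int:
    """Model degrees of freedom = moments − free parameters (must be ≥ 0)."""
    df = count_moments(spec) - count_free_parameters(spec)
    if df < 0:
        raise UnderIdentifiedError(
            f"model is under-identified: {count_free_parameters(spec)} free "
            f"parameters for {count_moments(spec)} moments"
        )
    return df


def permute_spec(spec: ModelSpec, indicators=None, predictors=None) -> ModelSpec:
    """Reorder observed variables (helper for equivariance checks and IO)."""
    new_ind = tuple(indicators) if indicators is not None else spec.indicators
    new_pred = tuple(predictors) if predictors is not None else spec.predictors
    if sorted(new_ind) != sorted(spec.indicators) or sorted(new_pred) != sorted(spec.predictors):
        raise ValueError("permutation must preserve the variable sets")
    return replace(spec, indicators=new_ind, predictors=new_pred)
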