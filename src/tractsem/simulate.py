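"""Synthetic study data: subject tables with known MIMIC structure and
diffusion-tensor phantoms with known tracts.

The subject-table generator draws 10 exchangeably correlated FA predictors
plus age (truncated normal over the study's 18-69 range), forms the two
latent intelligence variables from a sparse standardized structural layer,
and emits four indicator scores whose population R-squared values are
calibrated analytically to the requested targets (defaults PO 0.856,
PS 0.408, VC 0.756, WM 0.483).  The exact generating parameter matrices are
returned for recovery experiments.

The phantom generator lays prolate tensors with requested FA/trace along
polyline bundle paths inside an isotropic background that fails the
tracking start criteria, places a pair of inclusion ROIs per bundle at 25%
and 75% of arc length, and records each bundle's ground-truth mean FA
before any noise is added.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .model import ModelSpec, ParameterSet, build_watershed_spec
from .tractography import TensorVolume, TrackingParams

__all__ = [
    "TRACTS",
    "INDICATORS",
    "DEFAULT_ASSIGNMENT",
    "DEFAULT_TRUE_GAMMA",
    "SemSimConfig",
    "simulate_subject_table",
    "BundleSpec",
    "PhantomSpec",
    "Phantom",
    "make_dti_phantom",
    "prolate_tensor",
    "end_to_end_dataset",
]

TRACTS = ("ATR", "CGC", "CGH", "CST", "Fmj", "Fmn", "IFO", "ILF", "SLF", "UNC")
INDICATORS = ("PO", "PS", "VC", "WM")
DEFAULT_ASSIGNMENT = {"FI": ["PO", "PS"], "CI": ["VC", "WM"]}

# Sparse true structural layer for recovery experiments: standardized
# magnitude 0.3, signs matching the selected-edge pattern (age up on fluid,
# down on crystallized; forceps minor up on crystallized; superior
# longitudinal fasciculus down on fluid).
DEFAULT_TRUE_GAMMA = {
    ("age", "FI"): 0.3,
    ("age", "CI"): -0.3,
    ("Fmn", "CI"): 0.3,
    ("SLF", "FI"): -0.3,
}

DEFAULT_TARGET_R2 = {"PO": 0.856, "PS": 0.408, "VC": 0.756, "WM": 0.483}

# printed index scales used for output realism (analysis standardizes anyway)
INDICATOR_SCALE = {
    "PO": (27.71, 6.77),
    "PS": (16.63, 4.97),
    "VC": (29.39, 7.42),
    "WM": (26.17, 5.77),
}


@dataclass
class SemSimConfig:
    """Population for the subject-table generator.

    Effects in ``true_gamma`` are on the standardized scale (unit-variance
    predictors and unit-variance latents).  ``predictor_correlation`` is the
    exchangeable correlation of the 10 FA columns (age is independent of
    them); ``disturbance_correlation`` correlates the two latent residuals.
    """

    n: int = 1000
    true_gamma: dict = field(default_factory=lambda: dict(DEFAULT_TRUE_GAMMA))
    predictor_correlation: float = 0.3
    fa_mean: float = 0.45
    fa_sd: float = 0.03
    age_mean: float = 35.03
    age_sd: float = 10.27
    age_range: tuple[float, float] = (18.0, 69.0)
    target_r2: dict = field(default_factory=lambda: dict(DEFAULT_TARGET_R2))
    disturbance_correlation: float = 0.4
    assignment: dict = field(default_factory=lambda: {k: list(v) for k, v in
                                                      DEFAULT_ASSIGNMENT.items()})
    indicator_scale: dict = field(default_factory=lambda: dict(INDICATOR_SCALE))
    seed: int = 0

    def __post_init__(self):
        if self.n < 10:
            raise ValueError("need at least 10 subjects")
        rho = self.predictor_correlation
        if not -1.0 / 9.0 < rho < 1.0:
            raise ValueError("exchangeable correlation of 10 tracts needs rho in (-1/9, 1)")
        for k, v in self.target_r2.items():
            if not 0.0 < v < 1.0:
                raise ValueError(f"target R2 for {k} must lie in (0, 1)")

    @property
    def predictors(self) -> tuple[str, ...]:
        return TRACTS + ("age",)

    @property
    def latents(self) -> tuple[str, ...]:
        return tuple(self.assignment)

    @property
    def indicators(self) -> tuple[str, ...]:
        return tuple(i for inds in self.assignment.values() for i in inds)


def _truth_parameters(config: SemSimConfig) -> tuple[ParameterSet, ModelSpec]:
    """Analytic generating matrices on the standardized scale.

    Loadings and residual variances solve the population R-squared targets
    exactly given unit-variance latents: lambda_i = sqrt(r2_i),
    theta_i = 1 - r2_i.  Latent disturbance variances complete Var(eta)=1.
    The returned structure uses free loadings (no marker constraint), since
    the generative scale fixes the total latent variance instead.
    """
    spec = build_watershed_spec(config.assignment, config.predictors,
                                identification="unit_variance")
    q = len(config.predictors)
    L = len(config.latents)
    p = len(config.indicators)
    rho = config.predictor_correlation
    phi = np.eye(q)
    nt = len(TRACTS)
    phi[:nt, :nt] = rho + (1 - rho) * np.eye(nt)
    gamma = np.zeros((L, q))
    for (pred, lat), val in config.true_gamma.items():
        gamma[spec.latent_index(lat), spec.predictor_index(pred)] = val
    explained = np.diag(gamma @ phi @ gamma.T)
    if np.any(explained >= 1.0):
        raise ValueError("structural effects imply latent variance above 1")
    psi_d = 1.0 - explained
    psi = np.diag(psi_d)
    r = config.disturbance_correlation
    for j in range(L):
        for k in range(j + 1, L):
            psi[j, k] = psi[k, j] = r * np.sqrt(psi_d[j] * psi_d[k])
    lam = np.zeros((p, L))
    theta = np.zeros(p)
    for lat, inds in config.assignment.items():
        jl = spec.latent_index(lat)
        for ind in inds:
            r2 = config.target_r2[ind]
            i = spec.indicator_index(ind)
            lam[i, jl] = np.sqrt(r2)
            theta[i] = 1.0 - r2
    return ParameterSet(lam, gamma, psi, theta, phi), spec


def _age_draws(config: SemSimConfig, rng, n):
    lo, hi = config.age_range
    a = (lo - config.age_mean) / config.age_sd
    b = (hi - config.age_mean) / config.age_sd
    dist = stats.truncnorm(a, b, loc=config.age_mean, scale=config.age_sd)
    age = dist.rvs(size=n, random_state=rng)
    mu, sd = dist.mean(), dist.std()
    return age, (age - mu) / sd


def simulate_subject_table(config: SemSimConfig | None = None, *, extras: bool = False):
    """Draw a subject table from the generative MIMIC model.

    Returns ``(table, truth)`` where ``truth`` is the exact generating
    :class:`~tractsem.model.ParameterSet` on the standardized scale;
    ``extras=True`` appends a dict with the latent draws and the
    :class:`~tractsem.model.ModelSpec`, for calibration checks.
    """
    config = config or SemSimConfig()
    truth, spec = _truth_parameters(config)
    rng = np.random.default_rng(config.seed)
    n = config.n
    nt = len(TRACTS)
    chol_fa = np.linalg.cholesky(truth.phi[:nt, :nt])
    z_fa = rng.standard_normal((n, nt)) @ chol_fa.T
    age, z_age = _age_draws(config, rng, n)
    z = np.column_stack([z_fa, z_age])
    L = len(config.latents)
    chol_psi = np.linalg.cholesky(truth.psi)
    zeta = rng.standard_normal((n, L)) @ chol_psi.T
    eta = z @ truth.gamma.T + zeta
    eps = rng.standard_normal((n, len(config.indicators))) * np.sqrt(truth.theta)
    y = eta @ truth.lam.T + eps
    data = {}
    for k, tract in enumerate(TRACTS):
        data[tract] = config.fa_mean + config.fa_sd * z_fa[:, k]
    data["age"] = age
    for i, ind in enumerate(config.indicators):
        mu, sd = config.indicator_scale.get(ind, (0.0, 1.0))
        data[ind] = mu + sd * y[:, i]
    table = pd.DataFrame(data)
    if extras:
        return table, truth, {"spec": spec, "latents": eta, "z": z, "y_std": y}
    return table, truth


# ---------------------------------------------------------------------------
# DTI phantoms


def prolate_tensor(fa: float, trace: float, direction) -> np.ndarray:
    """Axially symmetric tensor with the requested FA, trace and axis."""
    if not 0.0 <= fa < 1.0 + 1e-12:
        raise ValueError("FA must lie in [0, 1]")
    d = np.asarray(direction, dtype=float)
    nd = np.linalg.norm(d)
    if nd == 0:
        raise ValueError("direction must be nonzero")
    d = d / nd
    # axial = T/3 (1 + 2 delta), radial = T/3 (1 - delta) with
    # FA = 3 delta / sqrt(3 + 6 delta^2)
    delta = np.sqrt(3.0 * fa**2 / (9.0 - 6.0 * fa**2))
    axial = trace / 3.0 * (1.0 + 2.0 * delta)
    radial = trace / 3.0 * (1.0 - delta)
    return radial * np.eye(3) + (axial - radial) * np.outer(d, d)


@dataclass
class BundleSpec:
    """A tube of prolate tensors along a polyline path (voxel coordinates)."""

    name: str
    path: np.ndarray  # (k, 3) polyline vertices
    radius: float = 1.5
    fa: float = 0.7
    trace: float = 0.0012

    def __post_init__(self):
        self.path = np.asarray(self.path, dtype=float)
        if self.path.ndim != 2 or self.path.shape[1] != 3 or len(self.path) < 2:
            raise ValueError("path must be a (k>=2, 3) polyline")


@dataclass
class PhantomSpec:
    """Grid, bundles, background and ROI-placement rule for one phantom."""

    shape: tuple[int, int, int] = (30, 30, 12)
    bundles: list[BundleSpec] = field(default_factory=list)
    background_fa: float = 0.05
    background_trace: float = 0.0021
    roi_fractions: tuple[float, float] = (0.25, 0.75)
    roi_radius: float | None = None  # default bundle radius + 1
    noise: float = 0.0
    allow_crossing: bool = False
    seed: int = 0


@dataclass
class Phantom:
    volume: TensorVolume
    fa_map: np.ndarray
    rois: dict[str, tuple[np.ndarray, ...]]
    bundle_masks: dict[str, np.ndarray]
    truth_mtbfa: dict[str, float]


def _densify(path: np.ndarray, step: float = 0.2):
    pts = [path[0]]
    tans = []
    for a, b in zip(path[:-1], path[1:]):
        seg = b - a
        length = np.linalg.norm(seg)
        if length == 0:
            continue
        nsub = max(int(np.ceil(length / step)), 1)
        t = seg / length
        for s in range(1, nsub + 1):
            pts.append(a + seg * s / nsub)
            tans.append(t)
    tans.insert(0, tans[0])
    return np.asarray(pts), np.asarray(tans)


def make_dti_phantom(spec: PhantomSpec) -> Phantom:
    """Construct the tensor volume, ROI masks and ground truth for a phantom.

    Bundle voxels (within ``radius`` of the path) carry prolate tensors
    aligned with the local path tangent; the ground-truth mTBFA per bundle
    is recorded before noise.  Overlapping bundles with incompatible
    orientations raise unless ``allow_crossing`` is set (first bundle wins
    inside the overlap).
    """
    from scipy.spatial import cKDTree

    rng = np.random.default_rng(spec.seed)
    shape = tuple(spec.shape)
    nx, ny, nz = shape
    tensors = np.broadcast_to(
        prolate_tensor(spec.background_fa, spec.background_trace, (1.0, 0.0, 0.0)),
        shape + (3, 3),
    ).copy()
    centers = np.stack(np.meshgrid(*[np.arange(s) + 0.5 for s in shape],
                                   indexing="ij"), axis=-1).reshape(-1, 3)
    owner_tangent: dict[tuple, np.ndarray] = {}
    bundle_masks = {}
    rois = {}
    truth = {}
    for bundle in spec.bundles:
        pts, tans = _densify(bundle.path)
        tree = cKDTree(pts)
        dist, nearest = tree.query(centers)
        inside = dist <= bundle.radius
        mask = inside.reshape(shape)
        idxs = np.flatnonzero(inside)
        for flat in idxs:
            vox = tuple(np.unravel_index(flat, shape))
            tan = tans[min(nearest[flat], len(tans) - 1)]
            if vox in owner_tangent:
                cosang = abs(float(owner_tangent[vox] @ tan))
                if cosang < 0.95 and not spec.allow_crossing:
                    raise ValueError(
                        f"bundle {bundle.name!r} crosses an existing bundle at "
                        f"{vox}; set allow_crossing=True if intended"
                    )
                continue  # first bundle keeps the voxel
            owner_tangent[vox] = tan
            tensors[vox] = prolate_tensor(bundle.fa, bundle.trace, tan)
        bundle_masks[bundle.name] = mask
        truth[bundle.name] = float(bundle.fa)
        # two inclusion ROIs along the arc
        arc = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(pts, axis=0), axis=1))])
        roi_r = spec.roi_radius if spec.roi_radius is not None else bundle.radius + 1.0
        masks = []
        for frac in spec.roi_fractions:
            target = frac * arc[-1]
            c = pts[int(np.searchsorted(arc, target))]
            d2 = np.sum((centers - c) ** 2, axis=1)
            masks.append((d2 <= roi_r**2).reshape(shape))
        rois[bundle.name] = tuple(masks)
    if spec.noise > 0:
        noise = rng.standard_normal(shape + (3, 3))
        noise = (noise + np.swapaxes(noise, 3, 4)) / 2.0
        tensors = tensors + spec.noise * spec.background_trace / 3.0 * noise
        # restore PSD by clipping eigenvalues at a small positive floor
        w, v = np.linalg.eigh(tensors)
        w = np.clip(w, 1e-7 * spec.background_trace, None)
        tensors = np.einsum("...ij,...j,...kj->...ik", v, w, v)
        tensors = (tensors + np.swapaxes(tensors, 3, 4)) / 2.0
    vol = TensorVolume(tensors)
    from .tractography import volume_metrics

    fa_map, _, _ = volume_metrics(vol)
    return Phantom(volume=vol, fa_map=fa_map, rois=rois,
                   bundle_masks=bundle_masks, truth_mtbfa=truth)


def straight_bundle_spec(name="bundle", shape=(30, 8, 8), fa=0.7, trace=0.0012,
                         radius=1.5, **kw) -> PhantomSpec:
    """Convenience: one straight x-aligned bundle through the grid middle."""
    nx, ny, nz = shape
    path = np.array([[0.5, ny / 2, nz / 2], [nx - 0.5, ny / 2, nz / 2]])
    return PhantomSpec(shape=shape,
                       bundles=[BundleSpec(name, path, radius=radius, fa=fa, trace=trace)],
                       **kw)


def quarter_circle_bundle_spec(name="arc", radius_vox=14.0, tube_radius=1.2,
                               fa=0.7, trace=0.0012, margin=4, **kw) -> PhantomSpec:
    """Convenience: a quarter-circle bundle in the xy-plane."""
    n = int(np.ceil(radius_vox + tube_radius + 2 * margin))
    nz = max(2 * int(tube_radius + 2) + 1, 7)
    angles = np.linspace(0.0, np.pi / 2.0, 60)
    cx, cy = margin, margin
    path = np.column_stack([
        cx + radius_vox * np.cos(angles[::-1]),
        cy + radius_vox * np.sin(angles[::-1]),
        np.full_like(angles, nz / 2.0),
    ])
    return PhantomSpec(shape=(n, n, nz),
                       bundles=[BundleSpec(name, path, radius=tube_radius,
                                           fa=fa, trace=trace)],
                       **kw)


# ---------------------------------------------------------------------------
# end-to-end bundle: phantoms per subject feeding the SEM table


def end_to_end_dataset(
    sem_config: SemSimConfig | None = None,
    phantom_specs: dict[str, PhantomSpec] | None = None,
    tracking: TrackingParams | None = None,
):
    """Generate a study-shaped dataset whose chosen FA columns come from
    tractography on per-subject phantoms.

    For each tract named in ``phantom_specs`` the subject's simulated FA
    value becomes the bundle FA of a per-subject phantom; brute-force FACT
    tracking, two-ROI selection and mTBFA extraction then replace that
    column of the subject table.  Remaining FA columns keep their simulated
    values.  Ground truth is retained at both levels.
    """
    from .tractography import brute_force_tracking, mean_tract_fa, select_tract

    sem_config = sem_config or SemSimConfig()
    tracking = tracking or TrackingParams()
    if phantom_specs is None:
        phantom_specs = {"Fmn": straight_bundle_spec("Fmn", shape=(24, 8, 8))}
    table, truth, extra = simulate_subject_table(sem_config, extras=True)
    simulated = table.copy()
    for tract, pspec in phantom_specs.items():
        if tract not in TRACTS:
            raise ValueError(f"unknown tract {tract!r}")
        extracted = np.empty(len(table))
        for s_i, fa_val in enumerate(table[tract].to_numpy()):
            subj_spec = replace(
                pspec,
                bundles=[replace(b, fa=float(fa_val)) for b in pspec.bundles],
                seed=pspec.seed + s_i,
            )
            ph = make_dti_phantom(subj_spec)
            streams = brute_force_tracking(ph.volume, tracking)
            name = subj_spec.bundles[0].name
            ts = select_tract(streams, ph.rois[name], name=tract)
            extracted[s_i] = mean_tract_fa(ts, ph.fa_map)
        table[tract] = extracted
    return table, truth, {"simulated_table": simulated, "spec": extra["spec"],
                          "latents": extra["latents"]}
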