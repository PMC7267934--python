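"""Deterministic streamline tractography (FACT) on diffusion-tensor volumes.

Fiber Assignment by Continuous Tracking propagates a fiber from a seed
voxel along each voxel's principal diffusion direction: the direction is
constant within a voxel, the fiber exits through the face the ray crosses,
and tracking continues in the neighbouring voxel with the sign of the new
eigenvector chosen to continue the previous heading.  Tracking starts only
where FA >= fa_start and trace <= tr_start, and stops when the fiber would
enter a voxel with FA < fa_stop or trace > tr_stop, when the turn between
successive voxel directions exceeds the angle threshold, on leaving the
grid, or on revisiting a voxel.  Streamlines shorter than the minimum
number of visited voxels are discarded.

Brute-force reconstruction seeds every qualifying voxel; tracts are then
selected by multi-ROI membership (a streamline must visit every inclusion
ROI and no exclusion ROI) and summarized by the mean FA over the union of
visited voxels (mean tract-based FA, mTBFA), optionally averaged between
bilateral homologues.

Coordinates are 0-based voxel indices; voxel ``(i, j, k)`` spans the unit
cube ``[i, i+1) x [j, j+1) x [k, k+1)`` and has center ``(i+.5, j+.5,
k+.5)``.  World coordinates are obtained through the volume affine.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = [
    "TensorVolume",
    "TensorMetrics",
    "TrackingParams",
    "Streamline",
    "TractSet",
    "tensor_metrics",
    "volume_metrics",
    "fact_track",
    "brute_force_tracking",
    "select_tract",
    "mean_tract_fa",
    "bilateral_average",
    "fractional_anisotropy",
]

# lower-triangular component order used for 4-D NIfTI tensor storage
_TENSOR_COMPONENTS = ((0, 0), (1, 0), (1, 1), (2, 0), (2, 1), (2, 2))


@dataclass
class TensorVolume:
    """A voxel grid of 3x3 symmetric diffusion tensors (units mm^2/s)."""

    tensors: np.ndarray  # (nx, ny, nz, 3, 3)
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = None

    def __post_init__(self):
        t = np.asarray(self.tensors, dtype=float)
        if t.ndim != 5 or t.shape[3:] != (3, 3):
            raise ValueError("tensors must have shape (nx, ny, nz, 3, 3)")
        if not np.allclose(t, np.swapaxes(t, 3, 4), atol=1e-12):
            raise ValueError("tensors must be symmetric")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel size must be positive")
        self.tensors = t
        if self.affine is None:
            self.affine = np.diag(list(self.voxel_size) + [1.0])

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.tensors.shape[:3]

    # -- NIfTI round trip (6 lower-triangular components, xx yx yy zx zy zz) --

    def to_nifti(self) -> nib.Nifti1Image:
        comp = np.stack(
            [self.tensors[..., i, j] for (i, j) in _TENSOR_COMPONENTS], axis=-1
        )
        return nib.Nifti1Image(comp.astype(np.float64), self.affine)

    @classmethod
    def from_nifti(cls, img) -> "TensorVolume":
        if isinstance(img, (str, bytes)) or hasattr(img, "__fspath__"):
            img = nib.load(img)
        comp = np.asarray(img.dataobj, dtype=float)
        if comp.ndim != 4 or comp.shape[-1] != 6:
            raise ValueError("expected a 4-D volume with 6 tensor components")
        t = np.zeros(comp.shape[:3] + (3, 3))
        for k, (i, j) in enumerate(_TENSOR_COMPONENTS):
            t[..., i, j] = comp[..., k]
            t[..., j, i] = comp[..., k]
        vs = tuple(float(v) for v in img.header.get_zooms()[:3])
        return cls(t, voxel_size=vs, affine=np.asarray(img.affine))

    def voxel_to_world(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.affine[:3, :3].T + self.affine[:3, 3]


@dataclass(frozen=True)
class TensorMetrics:
    """Eigenstructure summary of one tensor."""

    eigenvalues: tuple[float, float, float]  # descending
    principal_direction: tuple[float, float, float]  # unit norm
    fa: float
    trace: float


@dataclass(frozen=True)
class TrackingParams:
    """FACT start/stop criteria.

    Defaults: start where FA >= 0.15 and trace <= 0.0016 mm^2/s; stop on
    FA < 0.10 or trace > 0.002; turning angle threshold 53.1 degrees;
    minimum fiber length five voxels.
    """

    fa_start: float = 0.15
    tr_start: float = 0.0016
    fa_stop: float = 0.10
    tr_stop: float = 0.002
    angle_max: float = 53.1  # degrees
    min_length: int = 5
    max_steps: int = 100_000

    def __post_init__(self):
        if self.fa_stop > self.fa_start:
            raise ValueError("fa_stop must not exceed fa_start")
        if self.tr_start > self.tr_stop:
            raise ValueError("tr_start must not exceed tr_stop")
        if not 0.0 < self.angle_max < 90.0:
            raise ValueError("angle_max must lie in (0, 90) degrees")


@dataclass
class Streamline:
    """An ordered fiber trajectory through the voxel grid."""

    voxels: np.ndarray  # (k, 3) int visited voxel indices, in order
    points: np.ndarray  # (k, 3) float voxel-center coordinates
    seed: tuple[int, int, int] | None = None

    def __len__(self) -> int:
        return len(self.voxels)

    def canonical_key(self):
        fwd = tuple(map(tuple, self.voxels))
        rev = tuple(reversed(fwd))
        return min(fwd, rev)


@dataclass
class TractSet:
    """ROI-selected streamline bundle with a tract label."""

    name: str
    streamlines: list[Streamline]
    hemisphere: str | None = None

    def __len__(self) -> int:
        return len(self.streamlines)

    def visited_voxels(self) -> np.ndarray:
        """Union of voxels visited by any streamline (unique rows)."""
        if not self.streamlines:
            return np.zeros((0, 3), dtype=int)
        allv = np.vstack([s.voxels for s in self.streamlines])
        return np.unique(allv, axis=0)


# ---------------------------------------------------------------------------
# tensor metrics


def fractional_anisotropy(eigenvalues: np.ndarray) -> np.ndarray:
    """FA from eigenvalues (broadcasts over leading axes); 0 for null tensors."""
    ev = np.asarray(eigenvalues, dtype=float)
    l1, l2, l3 = ev[..., 0], ev[..., 1], ev[..., 2]
    num = (l1 - l2) ** 2 + (l2 - l3) ** 2 + (l3 - l1) ** 2
    den = l1**2 + l2**2 + l3**2
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(0.5) * np.sqrt(np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0))
    return np.where(den > 0, fa, 0.0)


def tensor_metrics(tensor: np.ndarray) -> TensorMetrics:
    """Eigen-decomposition of one symmetric tensor.

    The principal eigenvector sign convention makes its largest-magnitude
    component nonnegative.  An all-zero tensor has FA defined as 0.
    """
    t = np.asarray(tensor, dtype=float)
    if t.shape != (3, 3) or not np.allclose(t, t.T, atol=1e-10):
        raise ValueError("tensor must be symmetric 3x3")
    w, v = np.linalg.eigh(t)
    order = np.argsort(w)[::-1]
    w = w[order]
    e1 = v[:, order[0]]
    k = int(np.argmax(np.abs(e1)))
    if e1[k] < 0:
        e1 = -e1
    return TensorMetrics(
        eigenvalues=tuple(float(x) for x in w),
        principal_direction=tuple(float(x) for x in e1),
        fa=float(fractional_anisotropy(w)),
        trace=float(np.sum(w)),
    )


def volume_metrics(volume: TensorVolume):
    """Batched eigen-decomposition: (fa_map, trace_map, direction_map)."""
    t = volume.tensors
    w, v = np.linalg.eigh(t)  # ascending eigenvalues
    w = w[..., ::-1]
    e1 = v[..., :, -1]  # eigenvector of the largest eigenvalue
    # sign convention: largest-magnitude component nonnegative
    idx = np.argmax(np.abs(e1), axis=-1, keepdims=True)
    lead = np.take_along_axis(e1, idx, axis=-1)
    e1 = np.where(lead < 0, -e1, e1)
    fa = fractional_anisotropy(w)
    tr = np.sum(w, axis=-1)
    return fa, tr, e1


# ---------------------------------------------------------------------------
# FACT propagation


def _half_track(seed, direction, fa, tr, dirs, params: TrackingParams, shape):
    """Propagate one heading; returns visited voxels after the seed."""
    cos_max = np.cos(np.deg2rad(params.angle_max))
    pos = np.asarray(seed, dtype=float) + 0.5
    vox = tuple(int(x) for x in seed)
    d = np.asarray(direction, dtype=float)
    visited = {vox}
    out: list[tuple[int, int, int]] = []
    for _ in range(params.max_steps):
        # exit the current voxel along d
        t_exit = np.inf
        for ax in range(3):
            if d[ax] > 1e-12:
                t_ax = (vox[ax] + 1.0 - pos[ax]) / d[ax]
            elif d[ax] < -1e-12:
                t_ax = (vox[ax] - pos[ax]) / d[ax]
            else:
                continue
            t_exit = min(t_exit, t_ax)
        if not np.isfinite(t_exit):
            break
        pos = pos + (t_exit + 1e-9) * d
        nxt = tuple(int(np.floor(x)) for x in pos)
        if any(c < 0 or c >= s for c, s in zip(nxt, shape)):
            break
        if fa[nxt] < params.fa_stop or tr[nxt] > params.tr_stop:
            break
        e = dirs[nxt].copy()
        if float(e @ d) < 0:
            e = -e
        if float(e @ d) < cos_max:  # sharper turn than allowed
            break
        if nxt in visited:
            break
        visited.add(nxt)
        out.append(nxt)
        vox = nxt
        d = e
    return out


def fact_track(seed, volume_or_maps, params: TrackingParams | None = None):
    """Track bidirectionally from one seed voxel.

    ``volume_or_maps`` is a :class:`TensorVolume` or a precomputed
    ``(fa, tr, dirs)`` triple from :func:`volume_metrics`.  Returns a
    :class:`Streamline`, or ``None`` when the start criteria fail or fewer
    than ``min_length`` voxels are visited.
    """
    params = params or TrackingParams()
    if isinstance(volume_or_maps, TensorVolume):
        fa, tr, dirs = volume_metrics(volume_or_maps)
        shape = volume_or_maps.shape
    else:
        fa, tr, dirs = volume_or_maps
        shape = fa.shape
    seed = tuple(int(x) for x in seed)
    if any(c < 0 or c >= s for c, s in zip(seed, shape)):
        raise ValueError(f"seed {seed} outside the grid {shape}")
    if fa[seed] < params.fa_start or tr[seed] > params.tr_start:
        return None
    d0 = dirs[seed]
    fwd = _half_track(seed, d0, fa, tr, dirs, params, shape)
    bwd = _half_track(seed, -d0, fa, tr, dirs, params, shape)
    voxels = list(reversed(bwd)) + [seed] + fwd
    # a loop closing through the seed can duplicate voxels across the two
    # halves; keep the first pass only
    seen = set()
    unique = []
    for v in voxels:
        if v not in seen:
            seen.add(v)
            unique.append(v)
    if len(unique) < params.min_length:
        return None
    vox = np.array(unique, dtype=int)
    return Streamline(voxels=vox, points=vox + 0.5, seed=seed)


def brute_force_tracking(volume: TensorVolume, params: TrackingParams | None = None):
    """One tracking attempt per qualifying voxel; duplicate-free result.

    Deterministic: seeds are visited in lexicographic order and streamlines
    tracing the same voxel sequence (either orientation) are kept once.
    """
    params = params or TrackingParams()
    fa, tr, dirs = volume_metrics(volume)
    seeds = np.argwhere((fa >= params.fa_start) & (tr <= params.tr_start))
    out = []
    seen = set()
    for seed in seeds:
        s = fact_track(tuple(seed), (fa, tr, dirs), params)
        if s is None:
            continue
        key = s.canonical_key()
        if key in seen:
            continue
        seen.add(key)
        out.append(s)
    return out


# ---------------------------------------------------------------------------
# tract selection and mTBFA


def select_tract(streamlines, inclusion_rois, exclusion_rois=(), name: str = "tract",
                 hemisphere: str | None = None) -> TractSet:
    """Keep streamlines visiting every inclusion ROI and no exclusion ROI."""
    inclusion_rois = list(inclusion_rois)
    if not inclusion_rois:
        raise ValueError("at least one inclusion ROI is required")
    exclusion_rois = list(exclusion_rois)
    kept = []
    for s in streamlines:
        i, j, k = s.voxels[:, 0], s.voxels[:, 1], s.voxels[:, 2]
        if any(not roi[i, j, k].any() for roi in inclusion_rois):
            continue
        if any(roi[i, j, k].any() for roi in exclusion_rois):
            continue
        kept.append(s)
    return TractSet(name=name, streamlines=kept, hemisphere=hemisphere)


def mean_tract_fa(tract: TractSet, fa_map: np.ndarray, weighted: bool = False) -> float:
    """Mean FA over the tract's voxels.

    Default "superposition" semantics: the union of unique voxels visited
    by the tract's streamlines, each counted once.  ``weighted=True``
    instead weights voxels by visit count across streamlines.
    """
    if not tract.streamlines:
        raise ValueError(f"tract {tract.name!r} is empty")
    if weighted:
        allv = np.vstack([s.voxels for s in tract.streamlines])
        return float(np.mean(fa_map[allv[:, 0], allv[:, 1], allv[:, 2]]))
    vox = tract.visited_voxels()
    return float(np.mean(fa_map[vox[:, 0], vox[:, 1], vox[:, 2]]))


def bilateral_average(mtbfa_left: float | None, mtbfa_right: float | None) -> float:
    """Arithmetic mean of the two hemispheres' mTBFA.

    If one side is missing (None or NaN), returns the other with a warning.
    """
    def missing(x):
        return x is None or (isinstance(x, float) and np.isnan(x))

    if missing(mtbfa_left) and missing(mtbfa_right):
        raise ValueError("both hemispheres missing")
    if missing(mtbfa_left):
        warnings.warn("left mTBFA missing; returning right side only", stacklevel=2)
        return float(mtbfa_right)
    if missing(mtbfa_right):
        warnings.warn("right mTBFA missing; returning left side only", stacklevel=2)
        return float(mtbfa_left)
    return float((mtbfa_left + mtbfa_right) / 2.0)


# ---------------------------------------------------------------------------
# streamline IO (line-delimited JSON)


def write_streamlines(path, streamlines) -> None:
    with open(path, "w") as fh:
        for s in streamlines:
            rec = {"voxels": s.voxels.tolist(),
                   "seed": list(s.seed) if s.seed is not None else None}
            fh.write(json.dumps(rec) + "\n")


def read_streamlines(path):
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            rec = json.loads(line)
            vox = np.array(rec["voxels"], dtype=int)
            seed = tuple(rec["seed"]) if rec.get("seed") is not None else None
            out.append(Streamline(voxels=vox, points=vox + 0.5, seed=seed))
    return out
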