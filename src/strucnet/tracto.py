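"""Deterministic streamline tractography (FACT) and connectome construction.

The tracker is the textbook Fiber Assignment by Continuous Tracking rule on
a voxel grid: from every seed, step bidirectionally along the principal
diffusion direction of the *containing* voxel (no interpolation), flipping
the direction's sign to minimize turning, and stop when the next voxel's FA
falls below the FA threshold (default 0.2), the turn between successive
steps exceeds the angle threshold (default 45 degrees), the track leaves the
grid, or the step budget is exhausted.

Streamlines are converted to a region-by-region count matrix by endpoint
assignment: a streamline increments the count between the parcellation
labels of its two endpoints when both are nonzero and distinct. An edge of
the binary structural network exists where the count is strictly greater
than the fiber threshold (default 3, i.e. at least 4 streamlines).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "ScalarVolume",
    "DirectionVolume",
    "TrackingParams",
    "StreamlineSet",
    "Parcellation",
    "Connectome",
    "fact_track",
    "count_streamline_edges",
    "build_connectome",
    "default_seeds",
]


@dataclass(frozen=True)
class ScalarVolume:
    """3-D scalar grid (e.g. fractional anisotropy, values in [0, 1])."""

    data: np.ndarray
    voxel_size: float = 1.0  # mm, isotropic

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise ValueError(f"scalar volume must be 3-D, got {self.data.ndim}-D")
        if self.data.size and (self.data.min() < 0 or self.data.max() > 1):
            raise ValueError("FA values must lie in [0, 1]")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be > 0")


@dataclass(frozen=True)
class DirectionVolume:
    """3-D grid of principal diffusion directions (unit or zero vectors)."""

    data: np.ndarray  # shape (nx, ny, nz, 3)

    def __post_init__(self) -> None:
        if self.data.ndim != 4 or self.data.shape[-1] != 3:
            raise ValueError("direction volume must have shape (nx, ny, nz, 3)")
        norms = np.linalg.norm(self.data, axis=-1)
        ok = (np.abs(norms - 1.0) < 1e-9) | (norms == 0.0)
        if not np.all(ok):
            raise ValueError("directions must be unit vectors or zero")


@dataclass(frozen=True)
class TrackingParams:
    fa_threshold: float = 0.2
    angle_threshold_deg: float = 45.0
    step_size: float = 0.5  # in voxel units
    max_steps: int = 2000

    def __post_init__(self) -> None:
        if not 0 < self.fa_threshold < 1:
            raise ValueError("fa_threshold must be in (0, 1)")
        if not 0 < self.angle_threshold_deg < 180:
            raise ValueError("angle_threshold_deg must be in (0, 180)")
        if self.step_size <= 0:
            raise ValueError("step_size must be > 0")
        if self.max_steps < 1:
            raise ValueError("max_steps must be >= 1")


@dataclass
class StreamlineSet:
    """Polylines in continuous voxel space plus per-end termination reasons.

    ``reasons[k]`` is ``(reason_backward, reason_forward)`` for streamline k;
    reasons are one of ``"fa"``, ``"angle"``, ``"left_volume"``,
    ``"max_steps"``, ``"direction_undefined"``.
    """

    streamlines: list[np.ndarray] = field(default_factory=list)
    reasons: list[tuple[str, str]] = field(default_factory=list)
    step_size: float = 0.5


@dataclass(frozen=True)
class Parcellation:
    """Integer label grid: 0 = background, 1..n_regions = regions."""

    labels: np.ndarray
    region_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.labels.ndim != 3:
            raise ValueError("parcellation must be 3-D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("parcellation labels must be integers")
        if self.labels.size and self.labels.min() < 0:
            raise ValueError("labels must be >= 0")

    @property
    def n_regions(self) -> int:
        if self.region_names:
            return len(self.region_names)
        return int(self.labels.max())


@dataclass(frozen=True)
class Connectome:
    """Streamline-count matrix plus the binary adjacency of the >threshold rule."""

    counts: np.ndarray
    adjacency: np.ndarray
    labels: tuple[str, ...]
    fiber_threshold: int = 3

    def __post_init__(self) -> None:
        if not np.array_equal(self.adjacency, (self.counts > self.fiber_threshold)):
            raise ValueError("adjacency inconsistent with counts > fiber_threshold")


def _voxel(p: np.ndarray) -> tuple[int, int, int]:
    # voxel centers sit at integer coordinates; nearest-voxel lookup
    v = np.rint(p).astype(int)
    return int(v[0]), int(v[1]), int(v[2])


def _inside(v: tuple[int, int, int], shape: tuple[int, ...]) -> bool:
    return all(0 <= v[i] < shape[i] for i in range(3))


def _half_track(
    p0: np.ndarray,
    d0: np.ndarray,
    fa: np.ndarray,
    dirs: np.ndarray,
    params: TrackingParams,
) -> tuple[list[np.ndarray], str]:
    """Track one direction from the seed; returns (points beyond seed, reason)."""
    pts: list[np.ndarray] = []
    p = p0
    prev = d0
    for _ in range(params.max_steps):
        v = dirs[_voxel(p)]
        if np.linalg.norm(v) == 0:
            return pts, "direction_undefined"
        d = v if float(np.dot(v, prev)) >= 0 else -v
        cosang = float(np.clip(np.dot(d, prev), -1.0, 1.0))
        if np.degrees(np.arccos(cosang)) > params.angle_threshold_deg:
            return pts, "angle"
        p_new = p + params.step_size * d
        vox = _voxel(p_new)
        if not _inside(vox, fa.shape):
            return pts, "left_volume"
        if fa[vox] < params.fa_threshold:
            return pts, "fa"
        pts.append(p_new)
        p = p_new
        prev = d
    return pts, "max_steps"


def fact_track(
    fa: ScalarVolume,
    dirs: DirectionVolume,
    seeds: Sequence[Sequence[float]],
    params: TrackingParams = TrackingParams(),
) -> StreamlineSet:
    """Run deterministic FACT tracking from the given seed coordinates.

    Seeds outside the grid raise; seeds in sub-threshold or direction-free
    voxels are skipped with a warning. Each streamline is the concatenation
    of the backward and forward half-tracks through the seed.
    """
    if fa.data.shape != dirs.data.shape[:3]:
        raise ValueError("FA and direction grids have mismatched shapes")
    out = StreamlineSet(step_size=params.step_size)
    for seed in seeds:
        p0 = np.asarray(seed, dtype=float)
        vox = _voxel(p0)
        if not _inside(vox, fa.data.shape):
            raise ValueError(f"seed {tuple(p0)} outside grid {fa.data.shape}")
        if fa.data[vox] < params.fa_threshold:
            warnings.warn(
                f"seed {tuple(p0)} in sub-threshold voxel (FA "
                f"{fa.data[vox]:.3f} < {params.fa_threshold}); skipped",
                stacklevel=2,
            )
            continue
        v0 = dirs.data[vox]
        if np.linalg.norm(v0) == 0:
            warnings.warn(
                f"seed {tuple(p0)} has undefined direction; skipped", stacklevel=2
            )
            continue
        fwd, r_fwd = _half_track(p0, v0, fa.data, dirs.data, params)
        bwd, r_bwd = _half_track(p0, -v0, fa.data, dirs.data, params)
        poly = np.array([*reversed(bwd), p0, *fwd])
        if len(poly) < 2:
            continue  # degenerate: terminated immediately both ways
        out.streamlines.append(poly)
        out.reasons.append((r_bwd, r_fwd))
    return out


def default_seeds(fa: ScalarVolume, fa_threshold: float = 0.2) -> np.ndarray:
    """Default seeding policy: one seed at the center of every voxel whose FA
    meets the tracking threshold."""
    return np.argwhere(fa.data >= fa_threshold).astype(float)


def count_streamline_edges(s: StreamlineSet, parc: Parcellation) -> np.ndarray:
    """Endpoint tally: counts[a-1, b-1] += 1 for each streamline whose two
    endpoint voxels carry distinct nonzero labels a and b."""
    n = parc.n_regions
    counts = np.zeros((n, n), dtype=int)
    shape = parc.labels.shape
    for poly in s.streamlines:
        va = _voxel(poly[0])
        vb = _voxel(poly[-1])
        if not (_inside(va, shape) and _inside(vb, shape)):
            continue
        a = int(parc.labels[va])
        b = int(parc.labels[vb])
        if a > 0 and b > 0 and a != b:
            counts[a - 1, b - 1] += 1
            counts[b - 1, a - 1] += 1
    return counts


def build_connectome(
    counts: np.ndarray,
    fiber_threshold: int = 3,
    labels: Sequence[str] | None = None,
) -> Connectome:
    """Apply the edge rule: adjacency = 1 exactly where counts > fiber_threshold.

    The inequality is strict — a count of exactly 3 is *not* an edge; 4 is
    the minimum. Counts are retained unmodified alongside the adjacency.
    """
    counts = np.asarray(counts)
    if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
        raise ValueError("counts must be square")
    if not np.array_equal(counts, counts.T):
        raise ValueError("counts must be symmetric")
    if np.any(counts < 0):
        raise ValueError("counts must be nonnegative")
    if np.any(np.diagonal(counts) != 0):
        raise ValueError("counts diagonal must be zero")
    n = counts.shape[0]
    if labels is None:
        labels = tuple(f"node_{i + 1:02d}" for i in range(n))
    elif len(labels) != n:
        raise ValueError("label count does not match matrix size")
    adjacency = (counts > fiber_threshold).astype(np.int8)
    return Connectome(
        counts=counts,
        adjacency=adjacency,
        labels=tuple(labels),
        fiber_threshold=fiber_threshold,
    )
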