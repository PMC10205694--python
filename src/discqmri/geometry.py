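"""Disc-mask standardization and nucleus-pulposus (NP) extraction.

Each segmented disc is rotated into a standard in-plane frame defined by
the principal axes of the rotational inertia tensor (equivalently, the
second-moment matrix) of its voxel coordinates, pooled across the four
mid-sagittal slices.  In that frame the first axis is the disc's major
axis, which for a lumbar disc runs anterior-posterior (AP); the NP is
then defined geometrically as the central AP 40% of the disc.

Conventions
-----------
* Array axes are (slice, row, column) mapping to (left-right,
  superior-inferior, anterior-posterior) by default; the mapping is
  carried explicitly by :class:`DiscSegmentation`.
* Moments are computed on voxel *centers* (0-based indices scaled to mm);
  voxels are classified by their rotated center coordinates and no
  intensity resampling ever occurs, so downstream biomarkers are computed
  on original voxel values.
* The in-plane point for a voxel is (AP mm, SI mm); the major axis is
  reported first with the sign convention that it has a non-negative
  component along anatomical anterior->posterior.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "LEVELS",
    "LEVEL_LABELS",
    "DegenerateGeometryError",
    "DiscSegmentation",
    "StandardizedDisc",
    "NPRegion",
    "principal_axes",
    "standardize_disc",
    "extract_np",
    "np_mask_volume",
]

#: Disc levels in cranio-caudal order; label values 1..5 in segmentations.
LEVELS = ("L1L2", "L2L3", "L3L4", "L4L5", "L5S1")
LEVEL_LABELS = {name: i + 1 for i, name in enumerate(LEVELS)}

#: Eigenvalue ratio below which the tensor is considered isotropic
#: (circle-like disc): identity rotation is kept and the disc flagged.
_TIE_RATIO = 1.05

_DEFAULT_AXES = {"slice": "LR", "row": "SI", "col": "AP"}


class DegenerateGeometryError(ValueError):
    """Raised when a voxel set is too small or collinear to orient."""


@dataclass
class DiscSegmentation:
    """Labelled voxel masks over the mid-sagittal slices.

    ``labels`` is an integer volume (slice, row, column) with 0 background
    and values 1..5 for L1-L2 .. L5-S1.
    """

    labels: np.ndarray
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    axis_convention: dict | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3-D (slice, row, column) volume")
        present = set(np.unique(self.labels)) - {0}
        if not present <= set(LEVEL_LABELS.values()):
            raise ValueError(f"labels must be within 1..5, found {sorted(present)}")
        if self.axis_convention is None:
            self.axis_convention = dict(_DEFAULT_AXES)
        if set(self.axis_convention.values()) != {"LR", "SI", "AP"}:
            raise ValueError("axis_convention must map the three axes to LR, SI and AP")

    def levels_present(self) -> list[str]:
        present = np.unique(self.labels)
        return [name for name, lab in LEVEL_LABELS.items() if lab in present]

    def voxel_indices(self, level: str) -> tuple[np.ndarray, ...]:
        if level not in LEVEL_LABELS:
            raise KeyError(f"unknown disc level {level!r}")
        idx = np.nonzero(self.labels == LEVEL_LABELS[level])
        if idx[0].size == 0:
            raise KeyError(f"level {level} not present in segmentation")
        return idx


@dataclass
class StandardizedDisc:
    """A disc's voxels expressed in its principal-axis frame.

    ``coords_std`` is (n, 2): column 0 is the major (AP) axis, column 1
    the minor (SI) axis, in mm about the pooled centroid.  ``voxel_index``
    keeps the original (slice, row, col) of each point so intensities can
    be looked up without resampling.
    """

    level: str
    coords_std: np.ndarray
    voxel_index: tuple[np.ndarray, np.ndarray, np.ndarray]
    rotation: np.ndarray
    eigenvalues: np.ndarray
    centroid_mm: np.ndarray
    degenerate: bool

    @property
    def ap_extent_mm(self) -> tuple[float, float]:
        x = self.coords_std[:, 0]
        return float(x.min()), float(x.max())


@dataclass
class NPRegion:
    """The nucleus-pulposus subset of a disc's voxels."""

    level: str
    np_voxel_indices: tuple[np.ndarray, np.ndarray, np.ndarray]
    fraction: float
    in_np: np.ndarray  # boolean over the StandardizedDisc points

    @property
    def n_voxels(self) -> int:
        return int(self.in_np.sum())


def principal_axes(coords_mm: np.ndarray) -> tuple[np.ndarray, np.ndarray, bool]:
    """Principal axes of the in-plane second-moment (inertia) tensor.

    Parameters
    ----------
    coords_mm:
        (n, 2) voxel-center coordinates, columns ordered (AP, SI), mm.

    Returns
    -------
    rotation:
        2x2 proper rotation whose columns are the unit eigenvectors,
        major axis first.  Coordinates in the principal frame are
        ``(coords - centroid) @ rotation``.
    eigenvalues:
        The two second moments, descending.
    degenerate:
        True when the eigenvalue ratio is below the isotropy threshold;
        the identity rotation is returned in that case.

    Raises
    ------
    DegenerateGeometryError
        Fewer than 3 points, or a (near-)collinear point set.
    """
    coords = np.asarray(coords_mm, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 2:
        raise ValueError("coords_mm must be (n, 2)")
    if coords.shape[0] < 3:
        raise DegenerateGeometryError(f"need at least 3 voxels, got {coords.shape[0]}")
    centered = coords - coords.mean(axis=0)
    tensor = centered.T @ centered
    evals, evecs = np.linalg.eigh(tensor)  # ascending
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    if evals[0] <= 0 or evals[1] / evals[0] < 1e-9:
        raise DegenerateGeometryError("voxel set is collinear; principal frame undefined")
    if evals[0] / evals[1] < _TIE_RATIO:
        return np.eye(2), evals, True
    # Sign convention: major axis points along anatomical anterior->posterior.
    if evecs[0, 0] < 0:
        evecs[:, 0] = -evecs[:, 0]
    if np.linalg.det(evecs) < 0:
        evecs[:, 1] = -evecs[:, 1]
    return evecs, evals, False


def standardize_disc(seg: DiscSegmentation, level: str) -> StandardizedDisc:
    """Pool a disc's voxels across slices and rotate into its principal frame.

    The rotation is purely in-plane (SI x AP); the slice (left-right) axis
    is ignored beyond pooling.  Missing levels raise ``KeyError`` so the
    caller can decide whether missingness is expected (e.g. L1-L2 outside
    the field of view).
    """
    idx = seg.voxel_indices(level)
    ax = {v: k for k, v in seg.axis_convention.items()}
    axis_names = ["slice", "row", "col"]
    ap_axis = axis_names.index(ax["AP"])
    si_axis = axis_names.index(ax["SI"])
    spacing = seg.spacing_mm
    ap_mm = idx[ap_axis] * spacing[ap_axis]
    si_mm = idx[si_axis] * spacing[si_axis]
    coords = np.column_stack([ap_mm, si_mm]).astype(float)
    rotation, evals, degenerate = principal_axes(coords)
    centroid = coords.mean(axis=0)
    coords_std = (coords - centroid) @ rotation
    return StandardizedDisc(
        level=level,
        coords_std=coords_std,
        voxel_index=idx,
        rotation=rotation,
        eigenvalues=evals,
        centroid_mm=centroid,
        degenerate=degenerate,
    )


def extract_np(std: StandardizedDisc, fraction: float = 0.40) -> NPRegion:
    """Select the central anterior-posterior ``fraction`` of the disc.

    A voxel belongs to the NP when its major-axis coordinate lies within
    the central ``fraction`` of the disc's AP bounding interval:
    ``|x1 - midpoint| <= fraction * (ap_max - ap_min) / 2`` (boundary
    inclusive).
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    x = std.coords_std[:, 0]
    ap_min, ap_max = std.ap_extent_mm
    mid = 0.5 * (ap_min + ap_max)
    half = 0.5 * fraction * (ap_max - ap_min)
    in_np = np.abs(x - mid) <= half + 1e-9
    if not in_np.any():
        raise DegenerateGeometryError(f"empty NP region for level {std.level}")
    np_idx = tuple(axis[in_np] for axis in std.voxel_index)
    return NPRegion(level=std.level, np_voxel_indices=np_idx, fraction=fraction, in_np=in_np)


def np_mask_volume(seg: DiscSegmentation, region: NPRegion) -> np.ndarray:
    """Boolean volume marking the NP voxels of one disc."""
    vol = np.zeros(seg.labels.shape, dtype=bool)
    vol[region.np_voxel_indices] = True
    return vol
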