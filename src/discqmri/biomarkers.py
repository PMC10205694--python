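"""Per-disc biomarker aggregation over relaxation maps.

The primary biomarker is NP-T1rho: the mean T1rho relaxation time over
the valid voxels of a disc's nucleus-pulposus region.  The per-disc
record also carries the NP sample SD (a simple heterogeneity measure),
the whole-disc mean, and covariates used by the cohort statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import DiscSegmentation, NPRegion
from .relaxometry import RelaxationMap

__all__ = [
    "DEFAULT_MIN_VOXELS",
    "RoiSummary",
    "disc_biomarkers",
    "voxel_table",
    "DISC_TABLE_COLUMNS",
]

#: Minimum number of valid NP voxels for a usable NP mean.
DEFAULT_MIN_VOXELS = 10

#: Canonical column order of the disc-level table consumed by the
#: cohort statistics (see the data dictionary in the docs).
DISC_TABLE_COLUMNS = [
    "subject_id",
    "age",
    "sex",
    "group",
    "level",
    "np_t1rho_mean",
    "np_t1rho_sd",
    "wholedisc_t1rho_mean",
    "np_t2_mean",
    "wholedisc_t2_mean",
    "pfirrmann",
    "n_valid_voxels",
    "incomplete",
]


@dataclass
class RoiSummary:
    """NP and whole-disc summary of one relaxation map."""

    level: str
    np_mean: float
    np_sd: float
    wholedisc_mean: float
    n_valid_voxels: int
    n_valid_disc_voxels: int
    incomplete: bool


def _valid_values(rmap: RelaxationMap, indices: tuple[np.ndarray, ...]) -> np.ndarray:
    vals = rmap.t_ms[indices]
    ok = rmap.valid[indices] & np.isfinite(vals)
    return vals[ok]


def disc_biomarkers(
    rmap: RelaxationMap,
    np_region: NPRegion,
    seg: DiscSegmentation,
    min_voxels: int = DEFAULT_MIN_VOXELS,
) -> RoiSummary:
    """Mean +/- sample SD over valid NP voxels, and the whole-disc mean.

    Invalid voxels are excluded; their count is reflected in
    ``n_valid_voxels``.  Records with fewer than ``min_voxels`` valid NP
    voxels are flagged incomplete rather than raising.
    """
    disc_idx = seg.voxel_indices(np_region.level)
    np_vals = _valid_values(rmap, np_region.np_voxel_indices)
    disc_vals = _valid_values(rmap, disc_idx)
    n_np = int(np_vals.size)
    if n_np == 0:
        np_mean, np_sd = np.nan, np.nan
    elif n_np == 1:
        np_mean, np_sd = float(np_vals[0]), np.nan
    else:
        np_mean = float(np_vals.mean())
        np_sd = float(np_vals.std(ddof=1))
    wholedisc = float(disc_vals.mean()) if disc_vals.size else np.nan
    return RoiSummary(
        level=np_region.level,
        np_mean=np_mean,
        np_sd=np_sd,
        wholedisc_mean=wholedisc,
        n_valid_voxels=n_np,
        n_valid_disc_voxels=int(disc_vals.size),
        incomplete=n_np < min_voxels,
    )


def voxel_table(
    maps: dict[str, RelaxationMap],
    np_regions: dict[str, NPRegion],
    grades: dict[str, int],
    subject_id: str = "phantom",
    log: list[str] | None = None,
) -> pd.DataFrame:
    """Long per-voxel table (one row per valid NP voxel) for histogramming.

    ``maps``, ``np_regions`` and ``grades`` are keyed by disc level.
    Discs without a Pfirrmann grade are excluded and the exclusion is
    appended to ``log`` when given.
    """
    rows = []
    for level, region in np_regions.items():
        if level not in grades or grades[level] is None:
            if log is not None:
                log.append(f"{subject_id}/{level}: no Pfirrmann grade, voxels excluded")
            continue
        vals = _valid_values(maps[level], region.np_voxel_indices)
        rows.append(
            pd.DataFrame(
                {
                    "subject_id": subject_id,
                    "level": level,
                    "pfirrmann": int(grades[level]),
                    "t1rho_voxel": vals,
                }
            )
        )
    if not rows:
        return pd.DataFrame(columns=["subject_id", "level", "pfirrmann", "t1rho_voxel"])
    return pd.concat(rows, ignore_index=True)
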