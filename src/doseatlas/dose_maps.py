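"""Group dose maps, dose sub-range summaries and high-dose ROI statistics.

The sub-range convention follows the analysis display floor: voxels below
the first boundary (default 1.0 Gy) are uncounted, interior bins are
half-open ``[lo, hi)``, and the last bin is strictly ``> last boundary``
(the ">50 Gy" bin).  Laterality is split at world x = 0 (midline-centred
template).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from doseatlas.volume_io import AtlasVolume, MaskVolume, Volume

__all__ = [
    "DoseRangeSpec",
    "DoseRangeSummary",
    "RoiSet",
    "group_mean_dose",
    "dose_range_summary",
    "build_high_dose_rois",
    "roi_mean_dose",
    "roi_dose_table",
    "roi_technique_test",
]


@dataclass
class DoseRangeSpec:
    """Strictly increasing bin boundaries in Gy; final bin is open-ended."""

    boundaries: tuple[float, ...] = (1.0, 1.5, 10.0, 30.0, 50.0)

    def __post_init__(self) -> None:
        b = tuple(float(x) for x in self.boundaries)
        if len(b) < 2 or any(b[i] >= b[i + 1] for i in range(len(b) - 1)):
            raise ValueError(f"boundaries must be strictly increasing: {b}")
        self.boundaries = b

    @property
    def labels(self) -> list[str]:
        b = self.boundaries
        out = [f"{b[i]:g}-{b[i + 1]:g} Gy" for i in range(len(b) - 1)]
        out.append(f">{b[-1]:g} Gy")
        return out

    def bin_masks(self, dose: np.ndarray, mask: np.ndarray) -> list[np.ndarray]:
        """Boolean mask per bin, restricted to ``mask``."""
        b = self.boundaries
        out = []
        for i in range(len(b) - 1):
            out.append(mask & (dose >= b[i]) & (dose < b[i + 1]))
        out.append(mask & (dose > b[-1]))  # strict '>' for the open bin
        return out


@dataclass
class DoseRangeSummary:
    """Per-bin voxel counts and mm3 volumes (one row per group/technique)."""

    spec: DoseRangeSpec
    voxel_volume_mm3: float
    counts: dict[str, list[int]] = field(default_factory=dict)

    def volumes_mm3(self, group: str) -> list[float]:
        return [c * self.voxel_volume_mm3 for c in self.counts[group]]

    def to_frame(self) -> pd.DataFrame:
        rows = {}
        for group, counts in self.counts.items():
            rows[group] = dict(zip(self.spec.labels, counts))
        return pd.DataFrame(rows).T

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="technique")


@dataclass
class RoiSet:
    """Named binary ROIs on the template grid."""

    rois: dict[str, MaskVolume] = field(default_factory=dict)

    def __iter__(self):
        return iter(self.rois.items())

    def __len__(self) -> int:
        return len(self.rois)


def group_mean_dose(doses: list[Volume], mask: MaskVolume) -> Volume:
    """Voxel-wise arithmetic mean of template-space dose volumes.

    Zero outside the mask.  All inputs must share the template grid.
    """
    if not doses:
        raise ValueError("empty dose list")
    ref = doses[0]
    for d in doses[1:]:
        if not d.same_grid(ref):
            raise ValueError("dose volumes are not on a common grid")
    if not mask.same_grid(ref):
        raise ValueError("mask grid does not match the dose grid")
    acc = np.zeros(ref.shape, dtype=float)
    for d in doses:
        acc += d.data
    acc /= len(doses)
    acc[~mask.data.astype(bool)] = 0.0
    return Volume(data=acc, affine=ref.affine.copy(), space=ref.space)


def dose_range_summary(mean_doses: dict[str, Volume] | Volume,
                       mask: MaskVolume,
                       spec: DoseRangeSpec | None = None,
                       ) -> tuple[DoseRangeSummary, dict[str, list[MaskVolume]]]:
    """Voxel counts of the group mean dose per sub-range within the mask.

    Accepts either a single mean-dose volume (keyed ``"all"``) or a dict
    keyed by technique.  Returns the summary and the per-group bin masks.
    """
    spec = spec or DoseRangeSpec()
    if isinstance(mean_doses, Volume):
        mean_doses = {"all": mean_doses}
    summary = DoseRangeSummary(spec=spec,
                               voxel_volume_mm3=mask.voxel_volume_mm3)
    bin_masks: dict[str, list[MaskVolume]] = {}
    m = mask.data.astype(bool)
    for group, vol in mean_doses.items():
        if not vol.same_grid(mask):
            raise ValueError(f"grid mismatch for group {group!r}")
        masks = spec.bin_masks(vol.data, m)
        summary.counts[group] = [int(bm.sum()) for bm in masks]
        bin_masks[group] = [MaskVolume(data=bm.astype(np.uint8),
                                       affine=mask.affine.copy(),
                                       space=mask.space) for bm in masks]
    return summary, bin_masks


def build_high_dose_rois(mean_dose: Volume, atlas: AtlasVolume,
                         threshold: float = 50.0,
                         lobes: tuple[str, ...] = ("temporal", "limbic"),
                         ) -> RoiSet:
    """High-dose ROIs: {mean dose > threshold} within lobe and hemisphere.

    Produces one ROI per (side, lobe), e.g. ``left temporal``.  Hemispheres
    split at world x = 0 (x < 0 left, x > 0 right).  Unknown lobe names
    raise; a threshold above the maximum dose yields an empty RoiSet.
    """
    if not mean_dose.same_grid(atlas):
        raise ValueError("atlas and dose are not on the same grid")
    hot = mean_dose.data > threshold
    roi_set = RoiSet()
    if not hot.any():
        import warnings
        warnings.warn(f"no voxels above {threshold} Gy; ROI set is empty",
                      stacklevel=2)
        return roi_set
    nx = mean_dose.shape[0]
    xw = (np.arange(nx)[:, None, None] * mean_dose.affine[0, 0]
          + mean_dose.affine[0, 3])
    xw = np.broadcast_to(xw, mean_dose.shape)
    for lobe in lobes:
        labels = atlas.labels_for_lobe(lobe)  # raises on unknown lobes
        in_lobe = np.isin(atlas.data, labels)
        for side, sel in (("left", xw < 0), ("right", xw > 0)):
            data = hot & in_lobe & sel
            if data.any():
                roi_set.rois[f"{side} {lobe}"] = MaskVolume(
                    data=data.astype(np.uint8), affine=mean_dose.affine.copy(),
                    space=mean_dose.space)
    return roi_set


def roi_mean_dose(dose: Volume, roi: MaskVolume) -> float:
    """Mean dose (Gy) over the ROI voxels."""
    if not dose.same_grid(roi):
        raise ValueError("ROI grid does not match the dose grid")
    sel = roi.data.astype(bool)
    if not sel.any():
        raise ValueError("empty ROI")
    return float(dose.data[sel].mean())


def roi_dose_table(doses: dict[str, Volume], rois: RoiSet) -> pd.DataFrame:
    """Per-subject per-ROI mean doses as a long table (id, roi, mean_Gy)."""
    rows = []
    for sid, dose in doses.items():
        for name, roi in rois:
            rows.append({"id": sid, "roi": name,
                         "mean_Gy": roi_mean_dose(dose, roi)})
    return pd.DataFrame(rows)


def roi_technique_test(roi_table: pd.DataFrame, cohort: pd.DataFrame,
                       group_col: str = "technique") -> pd.DataFrame:
    """Two-sided pooled-variance t-test of ROI mean doses between groups.

    ``roi_table`` is the output of :func:`roi_dose_table`; ``cohort`` maps
    subject ids to group labels.  Returns one row per ROI with per-group
    mean +- SD, t and p (covariate-free by default; use the voxel_stats GLM
    machinery for covariate adjustment).
    """
    from scipy import stats

    merged = roi_table.merge(cohort[["id", group_col]], on="id")
    groups = sorted(merged[group_col].unique())
    if len(groups) != 2:
        raise ValueError(f"need exactly two groups, got {groups}")
    rows = []
    for roi, sub in merged.groupby("roi"):
        a = sub.loc[sub[group_col] == groups[0], "mean_Gy"].to_numpy()
        b = sub.loc[sub[group_col] == groups[1], "mean_Gy"].to_numpy()
        t, p = stats.ttest_ind(a, b, equal_var=True)
        rows.append({"roi": roi,
                     f"mean_{groups[0]}": a.mean(),
                     f"sd_{groups[0]}": a.std(ddof=1),
                     f"mean_{groups[1]}": b.mean(),
                     f"sd_{groups[1]}": b.std(ddof=1),
                     "t": float(t), "p": float(p)})
    return pd.DataFrame(rows)
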