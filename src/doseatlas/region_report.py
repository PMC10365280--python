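"""Atlas-based labelling of significant clusters and dose-range masks.

Emits per-region tables: region name, voxel count, peak t and the world
coordinate of the peak voxel, grouped by contrast direction.  Significant
voxels falling on atlas background are reported under "unlabeled".
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from doseatlas.volume_io import AtlasVolume, MaskVolume, Volume, voxel_to_world

__all__ = ["ClusterReport", "label_sig_map", "label_dose_bins",
           "save_ortho_png"]


class ClusterReport:
    """Per-region rows (direction, region, voxels, peak T, peak x/y/z)."""

    COLUMNS = ["direction", "region", "voxels", "peak_t", "x", "y", "z"]

    def __init__(self, frame: pd.DataFrame | None = None) -> None:
        self.frame = frame if frame is not None \
            else pd.DataFrame(columns=self.COLUMNS)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def empty(self) -> bool:
        return self.frame.empty

    def write_tsv(self, path: str | Path) -> None:
        """TSV with a 'None' marker row for directions with no clusters."""
        out = self.frame.copy()
        if out.empty:
            out = pd.DataFrame([{c: ("None" if c == "region" else "")
                                 for c in self.COLUMNS}])
        out.to_csv(path, sep="\t", index=False)


def label_sig_map(sig: MaskVolume, t_map: Volume, atlas: AtlasVolume,
                  direction: str) -> ClusterReport:
    """Intersect a significance mask with atlas regions.

    For each region with at least one significant voxel: voxel count, the
    signed t at the peak (max |t|) and its world coordinate.  Ties are
    broken by the first voxel in ascending scan order (np.argmax).  Rows
    are sorted by descending count.
    """
    if not sig.same_grid(atlas):
        raise ValueError("atlas and significance mask are not on one grid")
    if not sig.same_grid(t_map):
        raise ValueError("t map and significance mask are not on one grid")
    sel = sig.data.astype(bool)
    rows = []
    if sel.any():
        labels_present = np.unique(atlas.data[sel])
        for lab in labels_present:
            region_sel = sel & (atlas.data == lab)
            count = int(region_sel.sum())
            absmax = np.abs(np.where(region_sel, t_map.data, 0.0))
            idx = np.unravel_index(int(absmax.argmax()), t_map.shape)
            name = atlas.region_name(int(lab)) if lab != 0 else "unlabeled"
            xyz = voxel_to_world(idx, t_map.affine)
            rows.append({"direction": direction, "region": name,
                         "voxels": count,
                         "peak_t": float(t_map.data[idx]),
                         "x": float(xyz[0]), "y": float(xyz[1]),
                         "z": float(xyz[2])})
    frame = pd.DataFrame(rows, columns=ClusterReport.COLUMNS)
    if len(frame):
        frame = frame.sort_values("voxels", ascending=False,
                                  kind="stable").reset_index(drop=True)
    return ClusterReport(frame)


def label_dose_bins(bin_masks: list[MaskVolume], atlas: AtlasVolume,
                    bin_labels: list[str] | None = None) -> pd.DataFrame:
    """Region composition of each dose bin.

    Rows of (bin, region, voxels, fraction_of_region); fraction is the
    share of the whole atlas region covered by that bin.
    """
    rows = []
    region_sizes = np.bincount(atlas.data.ravel())
    for b, bm in enumerate(bin_masks):
        if not bm.same_grid(atlas):
            raise ValueError("bin mask grid does not match the atlas")
        name = bin_labels[b] if bin_labels else f"bin{b}"
        sel = bm.data.astype(bool)
        for lab in np.unique(atlas.data[sel]):
            if lab == 0:
                region, total = "unlabeled", int((atlas.data == 0).sum())
            else:
                region = atlas.region_name(int(lab))
                total = int(region_sizes[lab])
            count = int((sel & (atlas.data == lab)).sum())
            rows.append({"bin": name, "region": region, "voxels": count,
                         "fraction_of_region": count / total if total else 0.0})
    return pd.DataFrame(rows, columns=["bin", "region", "voxels",
                                       "fraction_of_region"])


def save_ortho_png(underlay: Volume, path: str | Path,
                   overlay: Volume | MaskVolume | None = None,
                   world_point=(0.0, 0.0, 0.0), cmap: str = "gray",
                   overlay_cmap: str = "hot") -> None:
    """Plain orthogonal-slice PNG export (axial/coronal/sagittal)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from doseatlas.volume_io import world_to_voxel

    vox = np.clip(np.rint(world_to_voxel(world_point, underlay.affine)),
                  0, np.asarray(underlay.shape) - 1).astype(int)
    fig, axes = plt.subplots(1, 3, figsize=(9, 3.2))
    planes = [(underlay.data[vox[0], :, :], "sagittal"),
              (underlay.data[:, vox[1], :], "coronal"),
              (underlay.data[:, :, vox[2]], "axial")]
    over = None
    if overlay is not None:
        over = [(overlay.data[vox[0], :, :]), (overlay.data[:, vox[1], :]),
                (overlay.data[:, :, vox[2]])]
    for a, (img, title) in enumerate(planes):
        axes[a].imshow(img.T, origin="lower", cmap=cmap)
        if over is not None:
            o = np.ma.masked_where(over[a] <= 0, over[a])
            axes[a].imshow(o.T, origin="lower", cmap=overlay_cmap, alpha=0.7)
        axes[a].set_title(title)
        axes[a].axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
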