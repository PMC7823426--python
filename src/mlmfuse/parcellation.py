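"""Atlas-level summarization of eigen-images.

A combined eigen-image is summarized per atlas region as the signed mean of
its voxel values over the in-mask voxels of that region, yielding a ranked
table of regional contributions to the brain signature (positive or
negative).  Any integer-labeled atlas volume is accepted (0 = background);
regions that fall entirely outside the analysis mask are flagged, never
silently dropped.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .grids import Mask, VolumeGrid

__all__ = ["AtlasLabels", "region_means", "rank_regions", "plot_region_bars"]


class AtlasLabels:
    """Integer-labeled atlas volume plus an id -> name table."""

    def __init__(self, label_volume: VolumeGrid, region_table: dict[int, str]):
        data = np.asarray(label_volume.data)
        if not np.issubdtype(data.dtype, np.integer):
            rounded = np.rint(data)
            if not np.allclose(data, rounded):
                raise ValueError("atlas label volume must hold integers")
            data = rounded.astype(int)
        if data.min() < 0:
            raise ValueError("atlas labels must be non-negative (0 = background)")
        self.label_volume = VolumeGrid(data=data, affine=label_volume.affine,
                                       units="atlas label")
        self.region_table = {int(k): str(v) for k, v in region_table.items()}
        present = set(np.unique(data)) - {0}
        unnamed = sorted(present - set(self.region_table))
        if unnamed:
            raise ValueError(f"atlas labels without a region name: {unnamed}")

    @property
    def region_ids(self) -> list[int]:
        return sorted(self.region_table)

    @classmethod
    def load(cls, volume_path, table_path) -> "AtlasLabels":
        vol = VolumeGrid.load(volume_path)
        table = pd.read_csv(table_path, sep=None, engine="python")
        mapping = dict(zip(table.iloc[:, 0].astype(int), table.iloc[:, 1].astype(str)))
        return cls(vol, mapping)

    def save(self, volume_path, table_path) -> None:
        self.label_volume.save(volume_path)
        pd.DataFrame(
            {"region_id": self.region_ids,
             "region_name": [self.region_table[i] for i in self.region_ids]}
        ).to_csv(table_path, index=False)


def region_means(map_volume: VolumeGrid, atlas: AtlasLabels, mask: Mask) -> pd.DataFrame:
    """Signed mean map value per atlas region over in-mask voxels.

    Returns one row per atlas region with columns ``region_id``,
    ``region_name``, ``n_voxels_in_mask`` and ``mean_contribution``
    (NaN, with a zero voxel count, for regions entirely outside the mask).
    """
    labels = atlas.label_volume
    if not (map_volume.congruent(labels) and map_volume.congruent(mask)):
        raise ValueError("map, atlas and mask must share one grid")
    lab = labels.data[mask.data].astype(int)
    val = np.asarray(map_volume.data, dtype=float)[mask.data]
    n_max = lab.max(initial=0) + 1
    counts = np.bincount(lab, minlength=n_max)
    sums = np.bincount(lab, weights=val, minlength=n_max)
    rows = []
    for rid in atlas.region_ids:
        n = int(counts[rid]) if rid < n_max else 0
        mean = sums[rid] / n if n > 0 else np.nan
        rows.append(
            {
                "region_id": rid,
                "region_name": atlas.region_table[rid],
                "n_voxels_in_mask": n,
                "mean_contribution": mean,
            }
        )
    return pd.DataFrame(rows)


def rank_regions(summary: pd.DataFrame, k: int, by: str = "absolute") -> pd.DataFrame:
    """Top-k regions by |mean| (default) or signed mean, sign retained.

    Ties break stably by ``region_id``; regions without in-mask voxels are
    excluded from the ranking.  ``k`` larger than the region count is clamped
    with a warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    valid = summary.dropna(subset=["mean_contribution"]).copy()
    if k > len(valid):
        warnings.warn(
            f"k={k} exceeds the {len(valid)} rankable regions; returning all",
            RuntimeWarning,
        )
        k = len(valid)
    if by == "absolute":
        valid["_key"] = -valid["mean_contribution"].abs()
    elif by == "signed":
        valid["_key"] = -valid["mean_contribution"]
    else:
        raise ValueError(f"unknown ranking mode: {by!r}")
    out = valid.sort_values(["_key", "region_id"], kind="mergesort").head(k)
    return out.drop(columns="_key").reset_index(drop=True)


def plot_region_bars(summary: pd.DataFrame, k: int = 20, by: str = "absolute", ax=None):
    """Horizontal bar plot of the top-k signed regional contributions."""
    import matplotlib.pyplot as plt

    top = rank_regions(summary, k, by=by).iloc[::-1]
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 0.3 * len(top) + 1))
    colors = np.where(top["mean_contribution"] >= 0, "tab:blue", "tab:red")
    ax.barh(top["region_name"], top["mean_contribution"], color=colors)
    ax.axvline(0, color="k", lw=0.8)
    ax.set_xlabel("mean regional contribution")
    return ax
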