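"""Channel-wise localization of workload-predictive cortex.

Per participant, each retained channel's HbR samples are correlated with
the induced n-back level (r_uvr); group maps average these across
participants weighted by each participant's multivariate decoding
correlation r_mvr:  r_avg(i) = sum_n r_uvr(i,n) r_mvr(n) / sum_n r_mvr(n).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .montage import Montage
from .preprocessing import LabeledSampleSet

__all__ = ["ChannelCorrelationMap", "GroupMap", "univariate_map",
           "group_weighted_map", "render_topomap"]


@dataclass
class ChannelCorrelationMap:
    channel_ids: list[int]
    r_uvr: np.ndarray          # NaN where undefined (constant channel)
    p_value: np.ndarray
    participant_id: int | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"channel_id": self.channel_ids,
                             "r": self.r_uvr, "p": self.p_value})


@dataclass
class GroupMap:
    channel_ids: list[int]
    r_avg: np.ndarray
    weights: np.ndarray        # per-participant r_mvr
    n_participants: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"channel_id": self.channel_ids, "r_avg": self.r_avg})


def univariate_map(samples: LabeledSampleSet) -> ChannelCorrelationMap:
    """Signed per-channel Pearson correlation with the induced level (for a
    single regressor, regression slope sign and correlation coincide)."""
    y = samples.labels.astype(float)
    if len(y) < 3:
        raise ValueError("need at least 3 samples")
    if np.ptp(y) == 0:
        raise ValueError("labels are constant")
    n_ch = samples.features.shape[1]
    r = np.full(n_ch, np.nan)
    p = np.full(n_ch, np.nan)
    for i in range(n_ch):
        x = samples.features[:, i]
        if np.ptp(x) == 0:
            continue               # undefined; reported missing
        res = stats.pearsonr(x, y)
        r[i], p[i] = res.statistic, res.pvalue
    return ChannelCorrelationMap(list(samples.channel_ids), r, p,
                                 samples.participant_id)


def group_weighted_map(
    maps: Sequence[ChannelCorrelationMap],
    weights: Sequence[float],
) -> GroupMap:
    """r_mvr-weighted average of per-participant correlation maps.

    Weights must be positive (negative decoding correlations would make the
    weighted mean uninterpretable); channels undefined for some participant
    are averaged over the remaining ones.
    """
    if len(maps) != len(weights) or not maps:
        raise ValueError("need one weight per map")
    w = np.asarray(weights, float)
    if np.any(w <= 0):
        raise ValueError("weights (r_mvr) must be positive")
    ids = list(maps[0].channel_ids)
    if any(list(m.channel_ids) != ids for m in maps):
        raise ValueError("all maps must share the same montage channels")
    r = np.vstack([m.r_uvr for m in maps])          # participant x channel
    valid = np.isfinite(r)
    wsum = (valid * w[:, None]).sum(axis=0)
    if np.any(wsum == 0):
        raise ValueError("channel with no valid participant data")
    r_avg = np.nansum(r * w[:, None], axis=0) / wsum
    return GroupMap(ids, r_avg, w, len(maps))


def render_topomap(
    cmap: ChannelCorrelationMap | GroupMap,
    montage: Montage,
    path: str | Path,
    title: str = "",
) -> Path:
    """Schematic 2-D head plot of a channel map, diverging color scale
    symmetric about zero; writes an image file and returns its path."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    values = cmap.r_avg if isinstance(cmap, GroupMap) else cmap.r_uvr
    idx = montage.subset_indices(cmap.channel_ids)
    pos = montage.positions()[idx]
    if len(pos) != len(values):
        raise ValueError("map channels missing montage coordinates")
    vmax = np.nanmax(np.abs(values)) or 1.0

    fig, ax = plt.subplots(figsize=(5, 5))
    head = plt.Circle((0, 0), 1.0, fill=False, lw=2)
    ax.add_patch(head)
    ax.plot([-0.1, 0, 0.1], [0.995, 1.08, 0.995], "k-", lw=2)  # nose
    sc = ax.scatter(pos[:, 0], pos[:, 1], c=values, s=60,
                    cmap="RdBu_r", vmin=-vmax, vmax=vmax,
                    edgecolors="k", linewidths=0.4)
    fig.colorbar(sc, ax=ax, shrink=0.8, label="Pearson r")
    ax.set_xlim(-1.25, 1.25)
    ax.set_ylim(-1.25, 1.25)
    ax.set_aspect("equal")
    ax.axis("off")
    if title:
        ax.set_title(title)
    path = Path(path)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return path
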