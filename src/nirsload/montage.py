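"""Channel geometry for the whole-head fNIRS montage.

The montage describes 78 emitter-detector channels laid out on schematic
2-D head coordinates (10-20 naming), split between a frontal optode set and
a parieto-temporo-occipital set with a gap over the somatomotor strip.  A
12-channel forehead subset (F5-F6 / AF7-AF8 / AFz / Fpz) is flagged for the
frontal-only decoding comparison, and region labels drive the default
placement of workload-sensitive loadings in the synthetic forward model.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

__all__ = ["Channel", "Montage", "default_montage"]


@dataclass(frozen=True)
class Channel:
    """One emitter-detector pair measured at both wavelengths."""

    channel_id: int          # 1-based
    emitter_label: str
    detector_label: str
    x: float                 # schematic head coordinates, unit circle
    y: float
    distance_cm: float       # source-detector separation
    region: str
    frontal: bool            # member of the 12-channel forehead subset


@dataclass
class Montage:
    channels: list[Channel] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.channels)

    @property
    def channel_ids(self) -> list[int]:
        return [c.channel_id for c in self.channels]

    @property
    def distances_cm(self):
        import numpy as np

        return np.array([c.distance_cm for c in self.channels])

    @property
    def frontal_ids(self) -> list[int]:
        return [c.channel_id for c in self.channels if c.frontal]

    def region_ids(self, *regions: str) -> list[int]:
        return [c.channel_id for c in self.channels if c.region in regions]

    def positions(self):
        import numpy as np

        return np.array([[c.x, c.y] for c in self.channels])

    def subset_indices(self, channel_ids: Iterable[int]) -> list[int]:
        """Positional indices (0-based) of the given 1-based channel ids."""
        lookup = {c.channel_id: i for i, c in enumerate(self.channels)}
        try:
            return [lookup[cid] for cid in channel_ids]
        except KeyError as exc:  # pragma: no cover - defensive
            raise KeyError(f"channel id {exc.args[0]} not in montage") from exc

    # ------------------------------------------------------------------ JSON
    def to_json(self, path: str | Path) -> None:
        records = [asdict(c) for c in self.channels]
        Path(path).write_text(json.dumps(records, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "Montage":
        records = json.loads(Path(path).read_text())
        return cls([Channel(**r) for r in records])


def _arc(n: int, y0: float, y1: float, x0: float, x1: float) -> list[tuple[float, float]]:
    if n == 1:
        return [((x0 + x1) / 2, (y0 + y1) / 2)]
    return [
        (x0 + (x1 - x0) * i / (n - 1), y0 + (y1 - y0) * i / (n - 1))
        for i in range(n)
    ]


def _distance(i: int) -> float:
    # deterministic spread around the 3.5 cm mean, all < 4 cm
    return round(3.5 + 0.38 * math.sin(2.399963 * i), 3)


# (region, count, label stem, rows of schematic coordinates)
_FOREHEAD_LABELS = [
    ("F5", "AF7"), ("AF7", "Fp1"), ("Fp1", "Fpz"), ("Fpz", "Fp2"),
    ("Fp2", "AF8"), ("AF8", "F6"), ("F5", "F3"), ("AF7", "AF3"),
    ("AF3", "AFz"), ("AFz", "AF4"), ("AF4", "AF8"), ("F6", "F4"),
]


def default_montage() -> Montage:
    """The 78-channel whole-head layout used throughout the package.

    36 channels cover the frontal cortex (12 of them the forehead subset,
    8 bilateral inferior-frontal) and 42 cover parietal and
    temporo-occipital cortex; nothing sits over the somatomotor strip
    (|y| < 0.12 band left empty).
    """
    channels: list[Channel] = []
    cid = 1

    def add(region: str, frontal: bool, pairs: Sequence[tuple[str, str]],
            coords: Sequence[tuple[float, float]]) -> None:
        nonlocal cid
        for (em, de), (x, y) in zip(pairs, coords):
            channels.append(
                Channel(cid, em, de, round(x, 3), round(y, 3),
                        _distance(cid), region, frontal)
            )
            cid += 1

    # ---- frontal system (36) -------------------------------------------
    add("prefrontal", True, _FOREHEAD_LABELS,
        _arc(6, 0.82, 0.82, -0.55, 0.55) + _arc(6, 0.68, 0.68, -0.45, 0.45))
    add("inferior_frontal_l", False,
        [("F7", "FT7"), ("F7", "F5"), ("FT7", "FC5"), ("F5", "FC5")],
        _arc(4, 0.45, 0.25, -0.85, -0.65))
    add("inferior_frontal_r", False,
        [("F8", "FT8"), ("F8", "F6"), ("FT8", "FC6"), ("F6", "FC6")],
        _arc(4, 0.45, 0.25, 0.85, 0.65))
    add("dorsal_frontal", False,
        [(f"F{1 + i % 4}", f"FC{1 + i % 4}") for i in range(16)],
        _arc(8, 0.52, 0.52, -0.5, 0.5) + _arc(8, 0.3, 0.3, -0.45, 0.45))

    # ---- posterior system (42), gap over somatomotor cortex ------------
    add("parietal", False,
        [(f"P{1 + i % 4}", f"CP{1 + i % 4}") for i in range(14)],
        _arc(7, -0.22, -0.22, -0.5, 0.5) + _arc(7, -0.4, -0.4, -0.55, 0.55))
    add("temporo_occipital_l", False,
        [("T7", "TP7"), ("TP7", "P7"), ("P7", "PO7"), ("PO7", "O1"),
         ("TP7", "CP5"), ("P7", "P5"), ("PO7", "PO3"), ("O1", "PO3")],
        _arc(8, -0.2, -0.75, -0.88, -0.5))
    add("temporo_occipital_r", False,
        [("T8", "TP8"), ("TP8", "P8"), ("P8", "PO8"), ("PO8", "O2"),
         ("TP8", "CP6"), ("P8", "P6"), ("PO8", "PO4"), ("O2", "PO4")],
        _arc(8, -0.2, -0.75, 0.88, 0.5))
    add("occipital", False,
        [(f"PO{3 + i % 2}", f"O{1 + i % 2}") for i in range(12)],
        _arc(6, -0.62, -0.62, -0.4, 0.4) + _arc(6, -0.78, -0.78, -0.3, 0.3))

    m = Montage(channels)
    assert len(m) == 78 and len(m.frontal_ids) == 12
    return m
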