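"""Published reference values from the whole-head fNIRS driving n-back study.

These are inputs, not results: the per-participant cross-validated decoding
correlations (r_mvr) printed for the 15 analyzed participants, the frontal
12-channel counterpart mean, and the peripheral (heart-rate) counterpart.
They parameterize summary checks and the r_mvr-weighted group maps.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "WHOLE_HEAD_RMVR", "FRONTAL_MEAN_RMVR", "PERIPHERAL_MEAN_RMVR",
    "rmvr_summary", "frontal_drop_percent",
]

#: whole-head r_mvr per participant (P1-P19, four excluded)
WHOLE_HEAD_RMVR: dict[str, float] = {
    "P1": 0.70, "P2": 0.69, "P3": 0.80, "P4": 0.54, "P5": 0.58,
    "P6": 0.32, "P9": 0.54, "P10": 0.72, "P11": 0.31, "P13": 0.57,
    "P14": 0.61, "P15": 0.77, "P16": 0.75, "P17": 0.72, "P19": 0.59,
}

FRONTAL_MEAN_RMVR: float = 0.38
PERIPHERAL_MEAN_RMVR: float = 0.21


def rmvr_summary(values=None) -> dict[str, float]:
    """Mean, standard error and maximum of the decoding correlations."""
    r = np.asarray(list((values or WHOLE_HEAD_RMVR).values())
                   if isinstance(values or WHOLE_HEAD_RMVR, dict)
                   else values, float)
    return {
        "mean": float(r.mean()),
        "se": float(r.std(ddof=1) / np.sqrt(len(r))),
        "max": float(r.max()),
        "n": len(r),
    }


def frontal_drop_percent(whole_mean: float | None = None,
                         frontal_mean: float | None = None) -> float:
    """Relative drop (%) of the mean decoding correlation when restricting
    to the forehead channel subset."""
    whole = round(whole_mean if whole_mean is not None
                  else rmvr_summary()["mean"], 2)
    frontal = FRONTAL_MEAN_RMVR if frontal_mean is None else frontal_mean
    return 100.0 * (whole - frontal) / whole
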