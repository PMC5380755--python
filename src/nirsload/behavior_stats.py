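"""Trial-wise behavioral / driving / cardiac parameters and their n-back
trend statistics.

Trends are tested with linear mixed models: the n-back level enters as a
fixed effect and participant, trial number and target speed as crossed
random intercepts; significance comes from a likelihood-ratio test of the
full against the level-free model and the standardized effect size is
r = sqrt(t^2 / (t^2 + df)), signed like the slope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DrivingStreams", "OutlierPolicy", "MixedModelResult", "PARAMETER_COLUMNS",
    "heart_rate_bpm", "rmssd_ms", "compute_trial_params", "remove_outliers",
    "effect_size_r", "lmm_trend",
]

PARAMETER_COLUMNS = (
    "time_in_correct_range", "reaction_time", "brake_variance",
    "throttle_variance", "steering_variance", "lane_deviation",
    "heart_rate", "rmssd",
)


def heart_rate_bpm(rr_ms: Sequence[float]) -> float:
    rr = np.asarray(rr_ms, float)
    if rr.size == 0:
        return float("nan")
    return 60_000.0 / rr.mean()


def rmssd_ms(rr_ms: Sequence[float]) -> float:
    """Root mean square of successive RR-interval differences."""
    rr = np.asarray(rr_ms, float)
    if rr.size < 2:
        return float("nan")
    return float(np.sqrt(np.mean(np.diff(rr) ** 2)))


@dataclass
class DrivingStreams:
    """Continuous simulator channels sampled on a common time base."""

    time: np.ndarray          # s
    speed: np.ndarray         # km/h
    brake: np.ndarray         # normalized pedal deflection [0, 1]
    throttle: np.ndarray
    steering: np.ndarray      # rad
    lane_offset: np.ndarray   # m, signed distance from lane center


def compute_trial_params(
    streams: DrivingStreams,
    rr_ms: Sequence[float],
    design,
    tolerance_kmh: float = 5.0,
    transition_s: float = 3.0,
    lane_halfwidth_m: float = 1.75,
    lane_hysteresis_m: float = 0.25,
    participant_id: int | None = None,
) -> pd.DataFrame:
    """One row per trial of task, driving and cardiac parameters.

    time_in_correct_range is the percentage of post-transition samples
    within +-tolerance of the target speed; reaction time is the latency
    from the sign passage until the speed enters the band and stays there
    for the rest of the trial (correct trials only).  Driving variances
    exclude +-transition_s around sign passages, lane deviation excludes
    lane-change phases (|offset| beyond the lane boundary minus
    hysteresis), and heart rate / RMSSD come from the RR intervals covering
    the trial; trials without RR coverage get missing cardiac fields.
    """
    t = np.asarray(streams.time, float)
    rr = np.asarray(rr_ms, float)
    beat_t = np.cumsum(rr) / 1000.0 if rr.size else np.array([])

    rows = []
    for tr in design.trials:
        t0, t1 = tr.sign_onset, tr.sign_onset + tr.duration
        win = (t >= t0) & (t < t1)
        if not win.any():
            raise ValueError(f"streams do not cover trial {tr.index}")
        post = win & (t >= t0 + transition_s)
        guard = post & (t < t1 - transition_s)

        in_band = np.abs(streams.speed - tr.target_speed) <= tolerance_kmh
        tir = 100.0 * in_band[post].mean() if post.any() else np.nan

        # reaction time: start of the suffix of the trial spent in-band
        rt = np.nan
        if tr.correct:
            wi = np.where(win)[0]
            band = in_band[wi]
            if band[-1]:
                j = len(band)
                while j > 0 and band[j - 1]:
                    j -= 1
                rt = float(t[wi[j]] - t0)

        lane = streams.lane_offset[guard] if guard.any() else np.array([])
        keeping = np.abs(lane) < lane_halfwidth_m - lane_hysteresis_m
        beats = rr[(beat_t >= t0) & (beat_t < t1)] if rr.size else np.array([])

        rows.append({
            "participant_id": participant_id,
            "trial_index": tr.index,
            "block_id": tr.block_id,
            "nback_level": tr.nback_level,
            "sign_speed": tr.sign_speed,
            "target_speed": tr.target_speed,
            "correct": bool(tr.correct),
            "time_in_correct_range": tir,
            "reaction_time": rt,
            "brake_variance": float(np.var(streams.brake[guard])) if guard.any() else np.nan,
            "throttle_variance": float(np.var(streams.throttle[guard])) if guard.any() else np.nan,
            "steering_variance": float(np.var(streams.steering[guard])) if guard.any() else np.nan,
            "lane_deviation": float(np.mean(np.abs(lane[keeping]))) if keeping.any() else np.nan,
            "heart_rate": heart_rate_bpm(beats) if beats.size else np.nan,
            "rmssd": rmssd_ms(beats) if beats.size >= 2 else np.nan,
        })
    return pd.DataFrame(rows)


# ------------------------------------------------------------- outliers ---

@dataclass
class OutlierPolicy:
    sd_threshold: float = 3.0

    def __post_init__(self):
        if self.sd_threshold <= 0:
            raise ValueError("sd_threshold must be positive")


def remove_outliers(
    table: pd.DataFrame,
    policy: OutlierPolicy = OutlierPolicy(),
    parameters: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per participant and parameter, blank out trials more than
    ``sd_threshold`` SDs from that participant's mean (the trial stays in
    the table for the other parameters).  Returns the cleaned table and an
    exclusion log with per-parameter removal fractions."""
    parameters = [p for p in (parameters or PARAMETER_COLUMNS)
                  if p in table.columns]
    out = table.copy()
    log_rows = []
    for param in parameters:
        removed = 0
        valid = 0
        for _, idx in table.groupby("participant_id").groups.items():
            vals = table.loc[idx, param]
            ok = vals.notna()
            valid += int(ok.sum())
            sd = vals[ok].std(ddof=1)
            if not np.isfinite(sd) or sd == 0:
                continue   # nothing removable; logged as zero removals
            mean = vals[ok].mean()
            mask = ok & ((vals - mean).abs() > policy.sd_threshold * sd)
            out.loc[vals.index[mask], param] = np.nan
            removed += int(mask.sum())
        log_rows.append({"parameter": param, "n_removed": removed,
                         "n_valid": valid,
                         "fraction_removed": removed / valid if valid else 0.0})
    return out, pd.DataFrame(log_rows)


# ------------------------------------------------------------ mixed model ---

def effect_size_r(t_value: float, df: float) -> float:
    """r = sqrt(t^2/(t^2+df)), carrying the sign of t."""
    if df <= 0:
        return float(np.sign(t_value)) or 1.0
    return float(np.sign(t_value) * np.sqrt(t_value**2 / (t_value**2 + df)))


@dataclass
class MixedModelResult:
    parameter: str
    slope: float
    slope_se: float
    t_value: float
    df: float
    df_method: str
    chi2: float | None
    p_value: float | None
    effect_r: float
    n_obs: int
    random_components: tuple[str, ...] = ()
    warnings_: list[str] = field(default_factory=list)


_VC_FORMULAS = {
    "participant": "0 + C(participant_id)",
    "trial": "0 + C(trial_index)",
    "speed": "0 + C(target_speed)",
}


def _fit(df: pd.DataFrame, formula: str, components: tuple[str, ...]):
    import statsmodels.formula.api as smf

    vc = {name: _VC_FORMULAS[name] for name in components}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(formula, df, groups=df["_one"],
                            vc_formula=vc, re_formula="0")
        return model.fit(reml=False, method=["lbfgs"])


def lmm_trend(
    table: pd.DataFrame,
    parameter: str,
    compute_lrt: bool = True,
    random_components: tuple[str, ...] = ("participant", "trial", "speed"),
) -> MixedModelResult:
    """Linear trend of one parameter over n-back level.

    Fits ``parameter ~ nback_level`` with crossed random intercepts for
    participant, trial number and target speed (a single spanning group
    with one variance component per factor).  The LRT compares against the
    level-free model; degrees of freedom use a residual approximation
    (N - fixed rank - number of random-intercept groups), labeled in the
    output.  Components whose fit fails are dropped with a warning note.
    """
    df = table.dropna(subset=[parameter, "nback_level"]).copy()
    if df["participant_id"].nunique() < 2:
        raise ValueError("need at least 2 participants")
    if np.ptp(df[parameter].to_numpy(float)) == 0:
        raise ValueError(f"{parameter} is constant")
    df["_one"] = 1
    notes: list[str] = []
    components = tuple(random_components)
    full = None
    while True:
        try:
            full = _fit(df, f"{parameter} ~ nback_level", components)
            if np.isfinite(full.bse["nback_level"]):
                break
            raise ValueError("non-finite slope SE")
        except Exception as exc:   # singular fit -> downgrade
            if len(components) <= 1:
                raise
            notes.append(f"dropped random component {components[-1]}: {exc}")
            components = components[:-1]

    slope = float(full.params["nback_level"])
    se = float(full.bse["nback_level"])
    t = slope / se
    n_groups = sum(df[col].nunique() for col, name in
                   [("participant_id", "participant"),
                    ("trial_index", "trial"),
                    ("target_speed", "speed")] if name in components)
    ddf = float(len(df) - 2 - n_groups)
    chi2 = p = None
    if compute_lrt:
        reduced = _fit(df, f"{parameter} ~ 1", components)
        chi2 = max(0.0, 2.0 * (full.llf - reduced.llf))
        p = float(stats.chi2.sf(chi2, 1))
    return MixedModelResult(parameter, slope, se, t, ddf, "residual",
                            chi2, p, effect_size_r(t, ddf), len(df),
                            components, notes)
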