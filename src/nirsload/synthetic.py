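"""Synthetic study generator: design, behavior, cardiac and fNIRS forward model.

Emulates a driving n-back speed-regulation session: five working-memory
levels (0-4-back), speed signs every ~20 s drawn from a 9-value grid
(60-140 km/h), 2 repetitions x 5 levels x 10 trials = 100 trials.  Trial-wise
behavioral and cardiac outcomes follow a linear per-level model with
participant random intercepts; multichannel fNIRS recordings are produced by
a linear hemodynamic forward model (boxcar workload regressor convolved with
a double-gamma HRF, channel loadings concentrated in bilateral
inferior-frontal and temporo-occipital cortex) plus cardiac, respiratory,
Mayer-wave and drift artifacts, white noise, and optional high-variance bad
channels, then mapped to two-wavelength raw intensities through the forward
modified Beer-Lambert relation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .montage import Montage, default_montage
from .preprocessing import BeerLambertConstants

__all__ = [
    "TrialSpec", "DesignSchedule", "ParamSpec", "SubjectParams",
    "HRFParams", "ForwardModelConfig", "SyntheticRecording",
    "generate_design", "generate_behavior", "generate_rr_series",
    "generate_fnirs", "double_gamma_hrf",
    "DEFAULT_SPEED_GRID", "DEFAULT_P_CORRECT", "BEHAVIOR_PARAMETERS",
]

DEFAULT_SPEED_GRID: tuple[int, ...] = tuple(range(60, 150, 10))  # 9 speeds
#: per-level probability of achieving the target speed; mean incorrect ~8%
DEFAULT_P_CORRECT: tuple[float, ...] = (0.99, 0.98, 0.95, 0.88, 0.80)
ANNOUNCEMENT_S = 5.0  # on-screen message before each block


@dataclass(frozen=True)
class TrialSpec:
    index: int
    block_id: int
    nback_level: int
    sign_onset: float          # s from session start
    duration: float            # s
    sign_speed: int            # km/h
    target_speed: int          # km/h, n-back rule
    correct: bool


@dataclass
class DesignSchedule:
    trials: list[TrialSpec]
    level_block_order: list[int]
    seed: int

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def duration(self) -> float:
        last = self.trials[-1]
        return last.sign_onset + last.duration

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trial_index": [t.index for t in self.trials],
                "block_id": [t.block_id for t in self.trials],
                "nback_level": [t.nback_level for t in self.trials],
                "onset_s": [t.sign_onset for t in self.trials],
                "duration_s": [t.duration for t in self.trials],
                "sign_speed_kmh": [t.sign_speed for t in self.trials],
                "target_speed_kmh": [t.target_speed for t in self.trials],
                "correct": [int(t.correct) for t in self.trials],
            }
        )


def _no_repeat_order(levels: Sequence[int], repetitions: int,
                     rng: np.random.Generator, allow_repeats: bool) -> list[int]:
    pool = [lv for lv in levels for _ in range(repetitions)]
    if len(set(levels)) == 1 and len(pool) > 1 and not allow_repeats:
        raise ValueError(
            "cannot order blocks without adjacent level repeats; "
            "pass allow_repeats=True to relax the constraint"
        )
    for _ in range(10_000):
        order = list(rng.permutation(pool))
        if allow_repeats or all(a != b for a, b in zip(order, order[1:])):
            return order
    raise ValueError("no adjacent-repeat-free block order found")


def generate_design(
    n_levels: int = 5,
    trials_per_level: int = 10,
    repetitions: int = 2,
    speed_grid: Sequence[int] = DEFAULT_SPEED_GRID,
    trial_interval: float = 20.0,
    seed: int = 0,
    p_correct_by_level: Sequence[float] | None = DEFAULT_P_CORRECT,
    allow_repeats: bool = False,
) -> DesignSchedule:
    """Randomized block schedule: ``repetitions x n_levels`` blocks of
    ``trials_per_level`` trials each, no level driven twice in a row.

    Sign speeds are drawn per block as a random permutation of the grid
    (topped up with extra draws when a block is longer than the grid);
    target speeds follow the n-back rule, with the block's first sign
    standing in for the first ``n`` fill-in trials.  Per-trial correctness
    is sampled from ``p_correct_by_level`` (pass ``None`` for all-correct).
    """
    if n_levels < 1 or trials_per_level < 1 or repetitions < 1:
        raise ValueError("n_levels, trials_per_level, repetitions must be >= 1")
    if not speed_grid:
        raise ValueError("speed_grid must be non-empty")
    rng = np.random.default_rng(seed)
    order = _no_repeat_order(range(n_levels), repetitions, rng, allow_repeats)

    grid = list(speed_grid)
    trials: list[TrialSpec] = []
    t = 0.0
    idx = 0
    for block_id, level in enumerate(order):
        t += ANNOUNCEMENT_S
        speeds: list[int] = []
        while len(speeds) < trials_per_level:
            speeds.extend(int(s) for s in rng.permutation(grid))
        speeds = speeds[:trials_per_level]
        if p_correct_by_level is not None:
            p = p_correct_by_level[min(level, len(p_correct_by_level) - 1)]
            correct = rng.random(trials_per_level) < p
        else:
            correct = np.ones(trials_per_level, bool)
        for j in range(trials_per_level):
            target = speeds[j - level] if j >= level else speeds[0]
            trials.append(
                TrialSpec(idx, block_id, level, t, trial_interval,
                          speeds[j], target, bool(correct[j]))
            )
            t += trial_interval
            idx += 1
    return DesignSchedule(trials, order, seed)


# --------------------------------------------------------------------------
# trial-wise behavioral / cardiac outcomes
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ParamSpec:
    """Linear per-level generating model for one trial-wise parameter."""

    baseline: float        # mean at 0-back
    slope: float           # change per n-back level
    intercept_sd: float    # between-participant SD
    residual_sd: float     # within-participant trial-to-trial SD
    lower: float | None = None
    upper: float | None = None

    def __post_init__(self):
        if self.intercept_sd < 0 or self.residual_sd < 0:
            raise ValueError("standard deviations must be >= 0")


#: generating values: baselines are the 0-back descriptive means, slopes the
#: reported per-level fixed effects of the driving n-back study
BEHAVIOR_PARAMETERS: dict[str, ParamSpec] = {
    "time_in_correct_range": ParamSpec(92.3, -6.6, 2.0, 3.0, 0.0, 100.0),
    "reaction_time": ParamSpec(1.35, 0.23, 0.4, 0.6, 0.0, None),
    "brake_variance": ParamSpec(0.12, 0.08, 0.04, 0.10, 0.0, None),
    "throttle_variance": ParamSpec(0.26, -0.01, 0.04, 0.09, 0.0, None),
    "steering_variance": ParamSpec(0.69, -0.008, 0.05, 0.14, 0.0, None),  # 1e-4 rad^2
    "lane_deviation": ParamSpec(0.15, -0.007, 0.01, 0.03, 0.0, None),
    "heart_rate": ParamSpec(73.8, 0.89, 12.0, 12.2, None, None),
    "rmssd": ParamSpec(39.5, -1.24, 12.0, 17.0, 0.0, None),
}


@dataclass
class SubjectParams:
    params: dict[str, ParamSpec] = field(
        default_factory=lambda: dict(BEHAVIOR_PARAMETERS))
    p_correct_by_level: Sequence[float] = DEFAULT_P_CORRECT

    def with_overrides(self, **overrides: ParamSpec) -> "SubjectParams":
        new = dict(self.params)
        new.update(overrides)
        return SubjectParams(new, self.p_correct_by_level)


def generate_behavior(
    design: DesignSchedule,
    params: SubjectParams | None = None,
    n_participants: int = 12,
    seed: int = 0,
) -> pd.DataFrame:
    """Trial table: each parameter = baseline + slope*level + participant
    intercept + residual noise, bounded parameters clipped to their range.

    Correctness is re-sampled per participant with the level-dependent
    probabilities in ``params``; reaction time is missing on incorrect
    trials (it is only defined when the target speed was reached).
    """
    params = params or SubjectParams()
    rng = np.random.default_rng(seed)
    levels = np.array([t.nback_level for t in design.trials])
    n_trials = len(design.trials)

    frames = []
    for pid in range(n_participants):
        p = np.array([params.p_correct_by_level[
            min(lv, len(params.p_correct_by_level) - 1)] for lv in levels])
        correct = rng.random(n_trials) < p
        row = {
            "participant_id": pid,
            "trial_index": [t.index for t in design.trials],
            "block_id": [t.block_id for t in design.trials],
            "nback_level": levels,
            "sign_speed": [t.sign_speed for t in design.trials],
            "target_speed": [t.target_speed for t in design.trials],
            "correct": correct,
        }
        for name, spec in params.params.items():
            b = rng.normal(0.0, spec.intercept_sd) if spec.intercept_sd else 0.0
            vals = (spec.baseline + b + spec.slope * levels
                    + rng.normal(0.0, spec.residual_sd, n_trials))
            if spec.lower is not None or spec.upper is not None:
                vals = np.clip(vals, spec.lower, spec.upper)
            row[name] = vals
        frame = pd.DataFrame(row)
        frame.loc[~frame["correct"], "reaction_time"] = np.nan
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)


def generate_rr_series(
    target_hr: float,
    target_rmssd: float,
    duration: float,
    seed: int = 0,
) -> np.ndarray:
    """RR-interval sequence (ms) with the requested mean heart rate and
    short-term variability.

    Successive differences of iid Gaussian jitter with SD sigma have RMS
    sigma*sqrt(2), so the jitter SD is set to ``target_rmssd / sqrt(2)``.
    Beats are emitted until their cumulative time reaches ``duration``.
    """
    if target_hr <= 0 or duration <= 0:
        raise ValueError("target_hr and duration must be positive")
    if target_rmssd < 0:
        raise ValueError("target_rmssd must be >= 0")
    mean_rr = 60_000.0 / target_hr
    sigma = target_rmssd / np.sqrt(2.0)
    if sigma > mean_rr / 4.0:
        raise ValueError(
            f"target_rmssd {target_rmssd} ms infeasible for mean RR "
            f"{mean_rr:.0f} ms (intervals would go nonpositive)")
    rng = np.random.default_rng(seed)
    n = int(np.ceil(duration * 1000.0 / mean_rr)) + 16
    rr = mean_rr + rng.normal(0.0, sigma, n) if sigma else np.full(n, mean_rr)
    keep = np.cumsum(rr) <= duration * 1000.0
    return rr[keep]


# --------------------------------------------------------------------------
# fNIRS forward model
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class HRFParams:
    """Canonical double-gamma hemodynamic response (SPM-style)."""

    peak_s: float = 6.0
    undershoot_s: float = 16.0
    ratio: float = 6.0          # peak/undershoot amplitude ratio
    length_s: float = 32.0


def double_gamma_hrf(sampling_rate: float, p: HRFParams = HRFParams()) -> np.ndarray:
    """Double-gamma HRF sampled at ``sampling_rate``, normalized to unit DC
    gain (taps sum to one) so a sustained boxcar of height L settles at L
    and ``amplitude_per_level`` reads as steady-state concentration change
    per n-back level."""
    from scipy.stats import gamma as gamma_dist

    t = np.arange(0.0, p.length_s, 1.0 / sampling_rate)
    h = (gamma_dist.pdf(t, p.peak_s, scale=1.0)
         - gamma_dist.pdf(t, p.undershoot_s, scale=1.0) / p.ratio)
    return h / h.sum()


@dataclass
class ForwardModelConfig:
    sampling_rate: float = 1.955          # Hz, tandem-system rate
    n_channels: int = 78
    montage: Montage | None = None        # defaults to default_montage()
    loading_map: np.ndarray | None = None  # per-channel weight (unitless)
    amplitude_per_level: float = 5e-8     # mol/l HbR decrease per n-back level
    hbo_hbr_ratio: float = 2.5            # |dHbO| / |dHbR| with activation
    hrf: HRFParams = HRFParams()
    cardiac_amp: float = 2e-8             # mol/l; ~1.1 Hz, aliased at 1.955 Hz
    cardiac_freq: float = 1.1
    resp_amp: float = 1.5e-8
    resp_freq: float = 0.3
    mayer_amp: float = 6e-8
    mayer_freq: float = 0.098
    drift_amp: float = 1.2e-7             # very-low-frequency drift
    white_noise_sd: float = 5e-8
    bad_channel_ids: tuple[int, ...] = (13, 57)   # 1-based
    bad_channel_od_sd: float = 0.35       # log-intensity SD -> CV ~36%
    baseline_intensity: tuple[float, float] = (2000.0, 2000.0)  # uV at 760/850
    constants: BeerLambertConstants | None = None
    seed: int = 0

    def resolved(self) -> "ForwardModelConfig":
        cfg = replace(self)
        if cfg.montage is None:
            cfg.montage = default_montage()
        if cfg.n_channels != len(cfg.montage):
            raise ValueError("n_channels does not match montage size")
        if cfg.loading_map is None:
            cfg.loading_map = default_loading_map(cfg.montage)
        cfg.loading_map = np.asarray(cfg.loading_map, float)
        if cfg.loading_map.shape != (cfg.n_channels,):
            raise ValueError("loading_map length must equal n_channels")
        if cfg.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        for a in (cfg.cardiac_amp, cfg.resp_amp, cfg.mayer_amp,
                  cfg.drift_amp, cfg.white_noise_sd):
            if a < 0:
                raise ValueError("artifact amplitudes must be >= 0")
        if cfg.constants is None:
            cfg.constants = BeerLambertConstants(
                distance_cm=cfg.montage.distances_cm)
        return cfg


def default_loading_map(montage: Montage) -> np.ndarray:
    """Workload loadings on bilateral inferior-frontal (weight 1) and
    temporo-occipital (weight 0.7) channels, a weaker 0.4 spill-over onto
    the forehead channels bordering F5/F6 (so frontal-only decoding is
    informative but inferior to whole-head), zero elsewhere."""
    w = np.zeros(len(montage))
    idx = montage.subset_indices(
        montage.region_ids("inferior_frontal_l", "inferior_frontal_r"))
    w[idx] = 1.0
    idx = montage.subset_indices(
        montage.region_ids("temporo_occipital_l", "temporo_occipital_r"))
    w[idx] = 0.7
    for i, ch in enumerate(montage.channels):
        if ch.frontal and {ch.emitter_label, ch.detector_label} & {"F5", "F6"}:
            w[i] = 0.4
    return w


@dataclass
class SyntheticRecording:
    raw_intensity: dict[int, np.ndarray]   # wavelength nm -> channel x time, uV
    truth_hbo: np.ndarray                  # channel x time, mol/l
    truth_hbr: np.ndarray
    time: np.ndarray                       # s
    induced_level: np.ndarray              # per-sample boxcar of n-back level
    workload_regressor: np.ndarray         # boxcar (*) HRF
    design: DesignSchedule
    config: ForwardModelConfig

    @property
    def sampling_rate(self) -> float:
        return self.config.sampling_rate

    @property
    def n_channels(self) -> int:
        return self.config.n_channels


def induced_level_trace(design: DesignSchedule, time: np.ndarray) -> np.ndarray:
    """Per-sample n-back level; half-open trial windows, 0 outside trials."""
    level = np.zeros(time.shape)
    for tr in design.trials:
        sel = (time >= tr.sign_onset) & (time < tr.sign_onset + tr.duration)
        level[sel] = tr.nback_level
    return level


def generate_fnirs(
    design: DesignSchedule,
    config: ForwardModelConfig | None = None,
) -> SyntheticRecording:
    """Forward-model a two-wavelength recording for one session.

    truth_hbr = -loading * (boxcar (*) HRF) + artifacts + noise (activation
    lowers HbR); truth_hbo is the sign-flipped, ``hbo_hbr_ratio``-scaled
    counterpart with its own artifact draws.  Raw intensities follow
    I = I0 * 10**(-dOD) with dOD from the forward modified Beer-Lambert
    relation; bad channels receive multiplicative log-intensity noise so
    they fail the coefficient-of-variation quality check downstream.
    """
    if not design.trials:
        raise ValueError("design has no trials")
    cfg = (config or ForwardModelConfig()).resolved()
    rng = np.random.default_rng(cfg.seed)
    fs = cfg.sampling_rate
    n = int(np.ceil((design.duration + 10.0) * fs))
    time = np.arange(n) / fs

    level = induced_level_trace(design, time)
    hrf = double_gamma_hrf(fs, cfg.hrf)
    regressor = np.convolve(level, hrf)[:n]

    nch = cfg.n_channels
    signal = (cfg.loading_map[:, None] * cfg.amplitude_per_level
              * regressor[None, :])

    def artifacts() -> np.ndarray:
        out = np.zeros((nch, n))
        for amp, freq in ((cfg.cardiac_amp, cfg.cardiac_freq),
                          (cfg.resp_amp, cfg.resp_freq),
                          (cfg.mayer_amp, cfg.mayer_freq)):
            if amp == 0:
                continue
            # systemic oscillations are spatially global: one common phase
            # per artifact, per-channel gain and a small phase jitter
            phase = rng.uniform(0, 2 * np.pi) + rng.normal(0, 0.5, nch)
            gain = rng.uniform(0.5, 1.5, nch)
            # point-sampling the continuous oscillation at the acquisition
            # times: above-Nyquist components (cardiac) alias exactly as a
            # real instantaneous-sampling system would fold them
            out += (amp * gain[:, None]
                    * np.sin(2 * np.pi * freq * time[None, :] + phase[:, None]))
        if cfg.drift_amp:
            for freq in (0.005, 0.0023):
                phase = rng.uniform(0, 2 * np.pi, nch)
                out += (cfg.drift_amp / 2
                        * np.sin(2 * np.pi * freq * time[None, :] + phase[:, None]))
        return out

    noise = (rng.normal(0.0, cfg.white_noise_sd, (nch, n))
             if cfg.white_noise_sd else np.zeros((nch, n)))
    truth_hbr = -signal + artifacts() + noise
    noise_o = (rng.normal(0.0, cfg.white_noise_sd * cfg.hbo_hbr_ratio, (nch, n))
               if cfg.white_noise_sd else np.zeros((nch, n)))
    truth_hbo = cfg.hbo_hbr_ratio * (signal + artifacts()) + noise_o

    const = cfg.constants
    raw: dict[int, np.ndarray] = {}
    bad_idx = cfg.montage.subset_indices(cfg.bad_channel_ids) \
        if cfg.bad_channel_ids else []
    for wl_i, wl in enumerate(const.wavelengths_nm):
        eps_hbo, eps_hbr = const.epsilon[wl_i]
        dod = (const.distance_cm[:, None] * const.dpf[wl_i]
               * (eps_hbo * truth_hbo + eps_hbr * truth_hbr))
        intensity = cfg.baseline_intensity[wl_i] * 10.0 ** (-dod)
        if bad_idx and cfg.bad_channel_od_sd:
            wob = np.exp(rng.normal(0.0, cfg.bad_channel_od_sd,
                                    (len(bad_idx), n)))
            intensity[bad_idx] *= wob
        raw[wl] = intensity

    return SyntheticRecording(raw, truth_hbo, truth_hbr, time, level,
                              regressor, design, cfg)
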