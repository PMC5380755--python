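"""Raw-intensity to labeled-sample preprocessing.

Mirrors the standard continuous-wave fNIRS chain: optical-density change
relative to a reference intensity, modified Beer-Lambert conversion to HbO /
HbR concentration changes, linear-phase least-squares FIR low-pass
filtering, coefficient-of-variation channel rejection, and extraction of
labeled per-sample feature matrices with transition and incorrect-trial
exclusion.

Concentrations are carried internally in mol/l; multiply by 1e3 for the
mmol/l convention used at I/O boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np
from scipy.signal import firls

if TYPE_CHECKING:  # pragma: no cover
    from .montage import Montage
    from .synthetic import DesignSchedule

__all__ = [
    "BeerLambertConstants", "OpticalDensity", "HemoTimeSeries",
    "ChannelQCReport", "LabeledSampleSet", "intensity_to_od", "mbll_convert",
    "design_lowpass_fir", "lowpass_filter", "channel_qc", "build_sample_set",
]


@dataclass
class BeerLambertConstants:
    """Extinction coefficients, path-length factors and channel distances.

    ``epsilon`` rows are wavelengths (760, 850 nm), columns (HbO, HbR), in
    M^-1 cm^-1 (Gratzer spectrum values).  The differential path-length
    factors 7.25 and 6.38 are bound to 760 and 850 nm respectively: DPF is
    physically a per-wavelength quantity even though instrument manuals
    sometimes tabulate it against the chromophores.
    """

    epsilon: np.ndarray = field(default_factory=lambda: np.array(
        [[1486.59, 3843.71],
         [2526.39, 1798.64]]))
    dpf: tuple[float, float] = (7.25, 6.38)
    distance_cm: np.ndarray | None = None   # per channel
    wavelengths_nm: tuple[int, int] = (760, 850)

    def __post_init__(self):
        self.epsilon = np.asarray(self.epsilon, float)
        if self.epsilon.shape != (2, 2):
            raise ValueError("epsilon must be 2x2 (wavelength x chromophore)")
        if abs(np.linalg.det(self.epsilon)) < 1e-12:
            raise ValueError("epsilon matrix is singular")
        if self.distance_cm is not None:
            self.distance_cm = np.asarray(self.distance_cm, float)


@dataclass
class OpticalDensity:
    """Optical-density change per wavelength, relative to a reference."""

    od: dict[int, np.ndarray]                    # nm -> channel x time
    reference_intensity: dict[int, np.ndarray]   # nm -> per channel


@dataclass
class HemoTimeSeries:
    hbo: np.ndarray            # channel x time, mol/l
    hbr: np.ndarray
    sampling_rate: float
    channel_ids: list[int]
    channel_mask: np.ndarray | None = None   # True = retained
    montage: "Montage | None" = None

    def __post_init__(self):
        if self.channel_mask is None:
            self.channel_mask = np.ones(self.hbo.shape[0], bool)

    @property
    def n_channels(self) -> int:
        return self.hbo.shape[0]

    def retained(self) -> "HemoTimeSeries":
        """Copy restricted to channels passing QC."""
        m = self.channel_mask
        return HemoTimeSeries(
            self.hbo[m], self.hbr[m], self.sampling_rate,
            [c for c, keep in zip(self.channel_ids, m) if keep],
            np.ones(int(m.sum()), bool), self.montage)


def intensity_to_od(
    raw: dict[int, np.ndarray],
    reference: dict[int, np.ndarray] | None = None,
) -> OpticalDensity:
    """dOD = -log10(I(t) / I_ref), I_ref defaulting to the whole-session
    temporal mean of each channel (so dOD has zero temporal mean)."""
    od, refs = {}, {}
    for wl, intensity in raw.items():
        intensity = np.asarray(intensity, float)
        if np.any(intensity <= 0):
            ch, t = np.argwhere(intensity <= 0)[0]
            raise ValueError(
                f"nonpositive intensity at wavelength {wl} nm, "
                f"channel index {ch}, sample {t}")
        ref = (intensity.mean(axis=-1) if reference is None
               else np.asarray(reference[wl], float))
        od[wl] = -np.log10(intensity / ref[..., None])
        refs[wl] = ref
    return OpticalDensity(od, refs)


def mbll_convert(
    od: OpticalDensity,
    constants: BeerLambertConstants,
    sampling_rate: float,
    channel_ids: list[int] | None = None,
    montage: "Montage | None" = None,
) -> HemoTimeSeries:
    """Invert the modified Beer-Lambert relation channel by channel.

    Solves dOD(lambda) = d * DPF(lambda) * (eps_HbO dHbO + eps_HbR dHbR)
    for the two chromophores via the analytic 2x2 inverse.
    """
    if constants.distance_cm is None:
        raise ValueError("constants.distance_cm is required for conversion")
    wls = constants.wavelengths_nm
    od0, od1 = (np.asarray(od.od[wl], float) for wl in wls)
    d = constants.distance_cm
    if d.shape[0] != od0.shape[0]:
        raise ValueError("distance_cm length does not match channel count")
    # effective pathlength-scaled extinction matrix per channel
    a = constants.epsilon[0] * constants.dpf[0]   # row for 760 nm
    b = constants.epsilon[1] * constants.dpf[1]   # row for 850 nm
    det = a[0] * b[1] - a[1] * b[0]
    y0 = od0 / d[:, None]
    y1 = od1 / d[:, None]
    hbo = (b[1] * y0 - a[1] * y1) / det
    hbr = (-b[0] * y0 + a[0] * y1) / det
    if channel_ids is None:
        channel_ids = list(range(1, od0.shape[0] + 1))
    return HemoTimeSeries(hbo, hbr, sampling_rate, channel_ids,
                          montage=montage)


def design_lowpass_fir(
    cutoff: float,
    sampling_rate: float,
    transition_width: float = 0.1,
    numtaps: int = 121,
) -> np.ndarray:
    """Least-squares linear-phase FIR low-pass, unit DC gain.

    Pass band [0, cutoff - tw/2], stop band [cutoff + tw/2, Nyquist]; taps
    normalized to sum to one so constant signals pass unchanged.
    """
    nyq = sampling_rate / 2.0
    if not 0 < cutoff < nyq:
        raise ValueError(f"cutoff must lie in (0, {nyq}) Hz")
    numtaps += 1 - numtaps % 2   # enforce odd length (type-I, integer delay)
    lo = max(cutoff - transition_width / 2.0, 1e-4)
    hi = min(cutoff + transition_width / 2.0, nyq * 0.999)
    h = firls(numtaps, [0, lo, hi, nyq], [1, 1, 0, 0], fs=sampling_rate)
    return h / h.sum()


def lowpass_filter(
    series: np.ndarray,
    cutoff: float = 0.1,
    sampling_rate: float = 1.955,
    transition_width: float = 0.1,
    numtaps: int = 121,
) -> np.ndarray:
    """Zero-lag low-pass: reflect-pad by half the filter length, convolve,
    so the output is time-aligned with the input (group delay removed)."""
    h = design_lowpass_fir(cutoff, sampling_rate, transition_width, numtaps)
    half = len(h) // 2
    x = np.atleast_2d(np.asarray(series, float))
    if x.shape[-1] <= half:
        raise ValueError("series shorter than half the filter length")
    padded = np.pad(x, [(0, 0), (half, half)], mode="reflect")
    out = np.empty_like(x)
    for i in range(x.shape[0]):
        out[i] = np.convolve(padded[i], h, mode="valid")
    return out if np.ndim(series) > 1 else out[0]


@dataclass
class ChannelQCReport:
    cv_percent: dict[int, np.ndarray]   # wavelength nm -> per channel, %
    threshold: float
    channel_ids: list[int]
    rejected_ids: list[int]

    @property
    def mask(self) -> np.ndarray:
        rej = set(self.rejected_ids)
        return np.array([cid not in rej for cid in self.channel_ids])

    @property
    def worst_cv(self) -> np.ndarray:
        return np.max(np.stack(list(self.cv_percent.values())), axis=0)


def channel_qc(
    raw: dict[int, np.ndarray],
    threshold: float = 20.0,
    channel_ids: list[int] | None = None,
) -> ChannelQCReport:
    """Coefficient-of-variation signal-quality check on unfiltered raw
    intensity: CV = (sigma/mu)*100 per channel and wavelength; a channel is
    rejected when either wavelength exceeds the threshold.  Channels with
    zero mean get infinite CV and are rejected rather than raising."""
    if not raw:
        raise ValueError("raw intensity dict is empty")
    cvs = {}
    n_ch = None
    for wl, x in raw.items():
        x = np.asarray(x, float)
        n_ch = x.shape[0]
        mu = x.mean(axis=-1)
        sd = x.std(axis=-1)
        with np.errstate(divide="ignore", invalid="ignore"):
            cv = np.where(mu != 0, np.abs(sd / mu) * 100.0, np.inf)
        cvs[wl] = cv
    if channel_ids is None:
        channel_ids = list(range(1, n_ch + 1))
    worst = np.max(np.stack(list(cvs.values())), axis=0)
    rejected = [cid for cid, w in zip(channel_ids, worst) if w > threshold]
    return ChannelQCReport(cvs, threshold, list(channel_ids), rejected)


@dataclass
class LabeledSampleSet:
    features: np.ndarray        # sample x channel
    labels: np.ndarray          # induced n-back level per sample
    trial_id: np.ndarray        # per sample
    sample_time: np.ndarray     # s
    channel_ids: list[int]
    participant_id: int | None = None
    excluded: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.labels)

    def subset_channels(self, channel_ids: list[int]) -> "LabeledSampleSet":
        lookup = {c: i for i, c in enumerate(self.channel_ids)}
        missing = [c for c in channel_ids if c not in lookup]
        if missing:
            raise KeyError(f"channels not in sample set: {missing}")
        idx = [lookup[c] for c in channel_ids]
        return LabeledSampleSet(self.features[:, idx], self.labels,
                                self.trial_id, self.sample_time,
                                list(channel_ids), self.participant_id,
                                dict(self.excluded))


def build_sample_set(
    hemo: HemoTimeSeries,
    design: "DesignSchedule",
    transition_exclusion: float = 3.0,
    drop_incorrect: bool = True,
    signal: str = "hbr",
    participant_id: int | None = None,
) -> LabeledSampleSet:
    """Per-sample feature matrix of retained-channel HbR (or HbO) values,
    labeled with the trial's induced n-back level.

    Samples within ``transition_exclusion`` seconds of a sign passage (both
    ends of every trial) are dropped, as are all samples of incorrect
    trials when ``drop_incorrect``; out-of-trial samples (block
    announcements, gaps) never enter.  Every exclusion is tallied.
    """
    onsets = np.array([t.sign_onset for t in design.trials])
    ends = onsets + np.array([t.duration for t in design.trials])
    if np.any(onsets[1:] < ends[:-1] - 1e-9):
        order = np.argsort(onsets)
        if np.any(onsets[order][1:] < ends[order][:-1] - 1e-9):
            raise ValueError("overlapping trials in design")
    retained = hemo.retained()
    data = retained.hbr if signal == "hbr" else retained.hbo
    n = data.shape[1]
    t = np.arange(n) / hemo.sampling_rate
    if design.duration > t[-1] + 1.0 / hemo.sampling_rate:
        raise ValueError("events extend beyond the recording")

    feats, labels, trial_ids, times = [], [], [], []
    excluded = {"transition": 0, "incorrect_trial": 0, "out_of_trial": 0}
    in_any = np.zeros(n, bool)
    for tr in design.trials:
        in_trial = (t >= tr.sign_onset) & (t < tr.sign_onset + tr.duration)
        in_any |= in_trial
        if drop_incorrect and not tr.correct:
            excluded["incorrect_trial"] += int(in_trial.sum())
            continue
        core = (in_trial
                & (t >= tr.sign_onset + transition_exclusion)
                & (t < tr.sign_onset + tr.duration - transition_exclusion))
        excluded["transition"] += int(in_trial.sum() - core.sum())
        if not core.any():
            continue
        feats.append(data[:, core].T)
        labels.append(np.full(int(core.sum()), tr.nback_level))
        trial_ids.append(np.full(int(core.sum()), tr.index))
        times.append(t[core])
    excluded["out_of_trial"] = int((~in_any).sum())
    if not feats:
        raise ValueError("no samples survive the exclusion rules")
    return LabeledSampleSet(
        np.concatenate(feats), np.concatenate(labels),
        np.concatenate(trial_ids), np.concatenate(times),
        list(retained.channel_ids), participant_id, excluded)
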