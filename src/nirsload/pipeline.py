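"""End-to-end orchestration: simulate -> preprocess -> decode -> map ->
behavior -> report, with a YAML-round-trippable config and a run manifest."""

from __future__ import annotations

import dataclasses
import json
import time as _time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .behavior_stats import OutlierPolicy, lmm_trend, remove_outliers
from .decoding import CVScheme, DEFAULT_K_GRID, nested_cv_decode
from .io import (read_events_tsv, read_recording, sha256_of,
                 write_events_tsv, write_recording_csv, write_recording_snirf)
from .mapping import render_topomap, univariate_map
from .montage import Montage, default_montage
from .preprocessing import (BeerLambertConstants, build_sample_set,
                            channel_qc, intensity_to_od, lowpass_filter,
                            mbll_convert)
from .synthetic import (ForwardModelConfig, SubjectParams, generate_behavior,
                        generate_design, generate_fnirs)

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline"]

_TREND_PARAMS = ("time_in_correct_range", "reaction_time", "heart_rate", "rmssd")


@dataclass
class PipelineConfig:
    """Every stage parameter; defaults follow the study protocol."""

    seed: int = 0
    n_participants: int = 2
    # design
    n_levels: int = 5
    trials_per_level: int = 10
    repetitions: int = 2
    trial_interval_s: float = 20.0
    # preprocessing
    cutoff_hz: float = 0.1
    cv_threshold_pct: float = 20.0
    transition_s: float = 3.0
    # decoding
    outer_folds: int = 10
    inner_folds: int = 10
    k_grid: list = field(default_factory=lambda:
                         [k if k is None else int(k) for k in DEFAULT_K_GRID])
    n_lambdas: int = 50
    subset: str = "whole"            # whole | frontal
    # behavior
    outlier_sd: float = 3.0
    # io
    container: str = "snirf"         # snirf | csv
    version: str = __version__

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(dataclasses.asdict(self),
                                       sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


@dataclass
class RunManifest:
    config: dict
    version: str
    stage_timings_s: dict[str, float] = field(default_factory=dict)
    input_digests: dict[str, str] = field(default_factory=dict)
    exclusions: dict = field(default_factory=dict)
    outputs: list[str] = field(default_factory=list)
    failed_stage: str | None = None

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(dataclasses.asdict(self), indent=1))
        return path


def simulate_stage(cfg: PipelineConfig, out: Path) -> dict:
    design = generate_design(cfg.n_levels, cfg.trials_per_level,
                             cfg.repetitions,
                             trial_interval=cfg.trial_interval_s,
                             seed=cfg.seed)
    fwd = ForwardModelConfig(seed=cfg.seed)
    rec = generate_fnirs(design, fwd)
    writer = (write_recording_snirf if cfg.container == "snirf"
              else write_recording_csv)
    ext = "snirf" if cfg.container == "snirf" else "csv"
    files = [writer(rec, out / f"recording.{ext}"),
             write_events_tsv(design, out / "events.tsv")]
    rec.config.montage.to_json(out / "montage.json")
    files.append(out / "montage.json")
    behavior = generate_behavior(design, SubjectParams(),
                                 cfg.n_participants, seed=cfg.seed + 1)
    behavior.to_csv(out / "trials.csv", index=False)
    files.append(out / "trials.csv")
    return {"files": files, "recording": rec, "design": design,
            "behavior": behavior}


def preprocess_stage(cfg: PipelineConfig, out: Path):
    ext = "snirf" if cfg.container == "snirf" else "csv"
    raw = read_recording(out / f"recording.{ext}")
    design = read_events_tsv(out / "events.tsv")
    montage = Montage.from_json(out / "montage.json")
    qc = channel_qc(raw.raw_intensity, cfg.cv_threshold_pct, raw.channel_ids)
    od = intensity_to_od(raw.raw_intensity)
    const = BeerLambertConstants(distance_cm=montage.distances_cm)
    hemo = mbll_convert(od, const, raw.sampling_rate, raw.channel_ids, montage)
    hemo.hbr = lowpass_filter(hemo.hbr, cfg.cutoff_hz, raw.sampling_rate)
    hemo.hbo = lowpass_filter(hemo.hbo, cfg.cutoff_hz, raw.sampling_rate)
    hemo.channel_mask = qc.mask
    samples = build_sample_set(hemo, design, cfg.transition_s)
    pd.DataFrame({"channel_id": qc.channel_ids,
                  "cv_percent_worst": qc.worst_cv,
                  "rejected": ~qc.mask}).to_csv(
        out / "qc_report.tsv", sep="\t", index=False)
    return {"samples": samples, "qc": qc, "montage": montage,
            "design": design}


def run_pipeline(cfg: PipelineConfig, out_dir: str | Path) -> RunManifest:
    """Run every stage in order; deterministic for a fixed config seed."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(dataclasses.asdict(cfg), __version__)
    stage = "simulate"
    try:
        t0 = _time.perf_counter()
        sim = simulate_stage(cfg, out)
        manifest.stage_timings_s["simulate"] = _time.perf_counter() - t0
        for f in sim["files"]:
            manifest.input_digests[Path(f).name] = sha256_of(f)

        stage = "preprocess"
        t0 = _time.perf_counter()
        pre = preprocess_stage(cfg, out)
        samples = pre["samples"]
        manifest.exclusions["samples"] = samples.excluded
        manifest.exclusions["rejected_channels"] = pre["qc"].rejected_ids
        manifest.stage_timings_s["preprocess"] = _time.perf_counter() - t0

        stage = "decode"
        t0 = _time.perf_counter()
        scheme = CVScheme(cfg.outer_folds, cfg.inner_folds, cfg.seed)
        subset = (pre["montage"].frontal_ids if cfg.subset == "frontal"
                  else None)
        label = "frontal" if cfg.subset == "frontal" else "whole-head"
        retained = [c for c in (subset or samples.channel_ids)
                    if c in samples.channel_ids]
        result = nested_cv_decode(samples, scheme,
                                  k_grid=cfg.k_grid,
                                  n_lambdas=cfg.n_lambdas,
                                  channel_subset=retained,
                                  subset_label=label)
        result.trace_frame(samples.sample_time).to_csv(
            out / "decoding_trace.csv", index=False)
        (out / "decoding.json").write_text(json.dumps({
            "r_mvr": result.r_mvr, "per_fold_r": result.per_fold_r,
            "chosen_k": result.chosen_k,
            "chosen_lambda": result.chosen_lambda,
            "subset": result.channel_subset_label}, indent=1))
        manifest.stage_timings_s["decode"] = _time.perf_counter() - t0

        stage = "map"
        t0 = _time.perf_counter()
        umap = univariate_map(samples)
        umap.to_frame().to_csv(out / "channel_map.tsv", sep="\t", index=False)
        render_topomap(umap, pre["montage"], out / "channel_map.png",
                       title="HbR ~ workload (r_uvr)")
        manifest.stage_timings_s["map"] = _time.perf_counter() - t0

        stage = "behavior"
        t0 = _time.perf_counter()
        clean, log = remove_outliers(sim["behavior"],
                                     OutlierPolicy(cfg.outlier_sd))
        log.to_csv(out / "behavior_exclusions.tsv", sep="\t", index=False)
        rows = []
        for param in _TREND_PARAMS:
            res = lmm_trend(clean, param)
            rows.append({"parameter": param, "slope": res.slope,
                         "se": res.slope_se, "chi2": res.chi2,
                         "p": res.p_value, "df": res.df, "t": res.t_value,
                         "r": res.effect_r})
        pd.DataFrame(rows).to_csv(out / "behavior_trends.tsv", sep="\t",
                                  index=False)
        manifest.stage_timings_s["behavior"] = _time.perf_counter() - t0

        stage = "report"
        t0 = _time.perf_counter()
        _trace_figure(result, samples, out / "prediction_trace.png")
        manifest.stage_timings_s["report"] = _time.perf_counter() - t0
        manifest.outputs = sorted(p.name for p in out.iterdir())
    except Exception:
        manifest.failed_stage = stage
        manifest.save(out / "manifest.json")
        raise
    manifest.save(out / "manifest.json")
    return manifest


def _trace_figure(result, samples, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    order = np.argsort(samples.sample_time)
    t = samples.sample_time[order] / 60.0
    fig, ax = plt.subplots(figsize=(10, 3))
    ax.plot(t, result.induced[order], label="induced", lw=1.5)
    ax.plot(t, result.predicted[order], label="predicted", lw=0.8, alpha=0.8)
    ax.set_xlabel("time (min)")
    ax.set_ylabel("n-back level")
    ax.set_title(f"cross-validated workload prediction "
                 f"(r = {result.r_mvr:.2f}, {result.channel_subset_label})")
    ax.legend(loc="upper right")
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
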