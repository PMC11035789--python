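"""End-to-end orchestration: generate -> features -> pretrain ->
evaluate -> compare, driven by one YAML config, with a run manifest
recording seeds, config and artifact hashes for reproducibility.

The config schema is strict — unknown keys abort with the offending
field named, because silent config typos are the main reproducibility
killer in pipelines like this one.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .encoders import EncoderConfig, WindowEncoder, save_checkpoint
from .evaluation import (EvalConfig, EvalReport, LinearProbeEvaluation,
                         compare_methods, random_baseline_crossval)
from .preprocessing import WindowSet, extract_de_features, segment
from .pretext.cpc import CPCConfig, CPCModel
from .pretext.rp_ts import (PretextTrainConfig, RelativePositioningModel,
                            TemporalShufflingModel)
from .pretext.sampling import RPSamplerConfig
from .synthetic import SynthConfig, generate_dataset, load_dataset, save_dataset

__all__ = ["RunManifest", "run_pipeline", "load_config", "DEMO_CONFIG"]


_SCHEMA: dict[str, set[str]] = {
    "": {"seed", "out_dir", "dataset", "features", "pretext", "evaluation"},
    "dataset": {"n_subjects", "n_trials_per_subject", "trial_duration_s",
                "n_channels", "sampling_rate_hz", "n_classes", "noise_sd",
                "noise_color", "envelope_log_sd", "envelope_tau_s", "seed"},
    "features": {"window_length", "hop", "method"},
    "pretext": {"task", "tau_pos", "tau_neg", "n_samples", "epochs",
                "batch_size", "lr", "prediction_steps",
                "negatives_per_positive", "context_length", "weight_decay",
                "max_batches_per_epoch", "embedding_dim", "n_filters",
                "kernel_size", "stride", "val_trials", "seed"},
    "evaluation": {"n_folds", "label_fraction", "probe_c", "seed"},
}

DEMO_CONFIG: dict = {
    "seed": 0,
    "dataset": {"n_subjects": 2, "n_trials_per_subject": 6, "n_classes": 3},
    "features": {"method": "filter"},
    "pretext": {"task": "cpc", "epochs": 4, "val_trials": 2},
    "evaluation": {"n_folds": 6, "label_fraction": 0.1},
}


def _check_schema(cfg: dict) -> None:
    for section, keys in _SCHEMA.items():
        sub = cfg if section == "" else cfg.get(section, {})
        if not isinstance(sub, dict):
            raise ValueError(f"config section {section or 'root'!r} must be a mapping")
        unknown = set(sub) - keys
        if unknown:
            where = section or "top level"
            raise ValueError(
                f"unknown config key(s) {sorted(unknown)} in {where}")
    task = cfg.get("pretext", {}).get("task", "cpc")
    if task not in ("rp", "ts", "cpc"):
        raise ValueError(f"pretext.task must be rp|ts|cpc, got {task!r}")


def load_config(path: str | Path) -> dict:
    cfg = yaml.safe_load(Path(path).read_text()) or {}
    _check_schema(cfg)
    return cfg


@dataclass
class RunManifest:
    """Everything needed to reproduce a pipeline run."""

    config: dict
    seeds: dict[str, int] = field(default_factory=dict)
    version: str = __version__
    artifacts: dict[str, str] = field(default_factory=dict)  # name -> sha256
    timestamps: dict[str, float] = field(default_factory=dict)

    def add_artifact(self, name: str, path: Path) -> None:
        digest = hashlib.sha256(Path(path).read_bytes()).hexdigest()
        self.artifacts[name] = digest
        self.timestamps[name] = time.time()

    def save(self, path: Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2,
                                         default=str))


def _subset(d: dict, keys: set[str]) -> dict:
    return {k: v for k, v in d.items() if k in keys}


def _window_sets(recordings, feat_cfg: dict) -> list[WindowSet]:
    wl = feat_cfg.get("window_length")
    hop = feat_cfg.get("hop")
    return [segment(r, wl, hop) for r in recordings]


def pretrain(window_sets: list[WindowSet], pre_cfg: dict, seed: int):
    """Dispatch to the requested pretext task; returns (results, name)."""
    task = pre_cfg.get("task", "cpc")
    enc_cfg = EncoderConfig(
        seed=seed,
        **_subset(pre_cfg, {"embedding_dim", "n_filters", "kernel_size",
                            "stride"}))
    if task in ("rp", "ts"):
        sampler = RPSamplerConfig(
            seed=seed, **_subset(pre_cfg, {"tau_pos", "tau_neg", "n_samples"}))
        train = PretextTrainConfig(
            seed=seed, **_subset(pre_cfg, {"epochs", "batch_size", "lr"}))
        cls = (RelativePositioningModel if task == "rp"
               else TemporalShufflingModel)
        model = cls(window_sets, sampler, enc_cfg, train)
        return model.fit(), task.upper()
    cpc_cfg = CPCConfig(
        seed=seed,
        **_subset(pre_cfg, {"prediction_steps", "negatives_per_positive",
                            "context_length", "batch_size", "epochs",
                            "max_batches_per_epoch", "lr", "weight_decay"}))
    n_val = pre_cfg.get("val_trials", 0)
    train_ws = window_sets[:-n_val] if n_val else window_sets
    val_ws = window_sets[-n_val:] if n_val else None
    model = CPCModel(train_ws, cpc_cfg, enc_cfg)
    return model.fit(val_window_sets=val_ws), "CPC"


def run_pipeline(config: dict | str | Path, out_dir: str | Path | None = None
                 ) -> RunManifest:
    """Execute the configured stages end to end.

    Stages: synthetic dataset generation, DE feature extraction,
    pretext pretraining of the encoder, downstream cross-validated
    probing (pretrained encoder vs random-init encoder vs DE features
    vs random baseline) and pairwise Wilcoxon comparison. Artifacts
    and a manifest land in ``out_dir``.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    else:
        _check_schema(config)
    out = Path(out_dir or config.get("out_dir", "eegssl_run"))
    out.mkdir(parents=True, exist_ok=True)
    master_seed = int(config.get("seed", 0))
    manifest = RunManifest(config=config)
    stage_seeds = {name: int(s) for name, s in zip(
        ("dataset", "pretext", "evaluation"),
        np.random.SeedSequence(master_seed).generate_state(3) % (2**31))}
    manifest.seeds = stage_seeds

    # stage 1: data
    ds_cfg = dict(config.get("dataset", {}))
    ds_cfg.setdefault("seed", stage_seeds["dataset"])
    synth = SynthConfig(**ds_cfg)
    recordings = generate_dataset(synth)
    save_dataset(recordings, out / "dataset")
    manifest.add_artifact("dataset", out / "dataset" / "manifest.json")

    # stage 2: windows + DE features
    feat_cfg = config.get("features", {})
    wsets = _window_sets(recordings, feat_cfg)
    method = feat_cfg.get("method", "filter")
    de = [extract_de_features(r, window_length=feat_cfg.get("window_length"),
                              hop=feat_cfg.get("hop"), method=method)
          for r in recordings]
    de_flat = np.concatenate([f.flat() for f in de])
    np.save(out / "de_features.npy", de_flat)
    manifest.add_artifact("de_features", out / "de_features.npy")

    labels = np.concatenate([[ws.label] * ws.n_windows for ws in wsets])
    groups = np.concatenate([[i] * ws.n_windows
                             for i, ws in enumerate(wsets)])
    windows = np.concatenate([ws.windows for ws in wsets])

    # stage 3: pretext pretraining
    pre_cfg = config.get("pretext", {})
    results, task_name = pretrain(wsets, pre_cfg, stage_seeds["pretext"])
    ckpt = out / "encoder.npz"
    ctx = getattr(results, "context_model", None)
    save_checkpoint(ckpt, results.encoder, ctx)
    manifest.add_artifact("checkpoint", ckpt)
    np.savetxt(out / "loss_curve.csv",
               np.column_stack([np.arange(len(results.loss_curve)),
                                results.loss_curve]),
               delimiter=",", header="epoch,loss", comments="")
    manifest.add_artifact("loss_curve", out / "loss_curve.csv")

    # stage 4: downstream evaluation
    ev_cfg = config.get("evaluation", {})
    eval_config = EvalConfig(seed=stage_seeds["evaluation"],
                             **_subset(ev_cfg, {"n_folds", "label_fraction",
                                                "probe_c"}))
    reports: dict[str, EvalReport] = {}
    reports[task_name] = LinearProbeEvaluation(
        windows, labels, groups, eval_config, encoder=results.encoder,
        method=task_name).fit()
    rand_enc = WindowEncoder(
        EncoderConfig(seed=stage_seeds["pretext"],
                      **_subset(pre_cfg, {"embedding_dim", "n_filters",
                                          "kernel_size", "stride"})),
        wsets[0].windows.shape[1:])
    reports["random-init"] = LinearProbeEvaluation(
        windows, labels, groups, eval_config, encoder=rand_enc,
        method="random-init").fit()
    reports["DE-features"] = LinearProbeEvaluation(
        de_flat, labels, groups, eval_config, method="DE-features").fit()
    reports["baseline"] = random_baseline_crossval(
        labels, groups, synth.n_classes, eval_config,
        seed=stage_seeds["evaluation"])
    report_path = out / "reports.json"
    report_path.write_text(json.dumps(
        {k: r.to_dict() for k, r in reports.items()}, indent=2))
    manifest.add_artifact("reports", report_path)

    # stage 5: pairwise comparison
    table = compare_methods(reports)
    table.to_csv(out / "comparison.csv", index=False)
    manifest.add_artifact("comparison", out / "comparison.csv")

    manifest.save(out / "run_manifest.json")
    return manifest
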