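"""End-to-end orchestration: simulate -> preprocess -> features -> select -> train -> evaluate.

A single global seed deterministically derives a stream seed for every stage
(SHA-256 of ``"{seed}:{stage}"``), so stages never share random streams and a
re-run with the same config is reproducible artifact-for-artifact.  The
emitted ``report.json`` contains no timestamps and is byte-identical across
same-seed runs.

Two shipped instance layouts:

* ``windowed`` (scientific default): window=128 samples (1 s), step=128 —
  spectral features are defined and instances are non-overlapping.
* ``row``: window=1, step=1 — reproduces the source row-per-sample table; the
  spectral block is absent by construction.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from . import evaluate as ev
from . import features as ft
from . import preprocess as pp
from . import synth
from .autoencoder import AutoencoderSpec, encode, train_autoencoder
from .resnet import ModelConfig, predict, train
from .rsa import RSAConfig, select_features
from .synth import ConfigurationError, SynthConfig

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """Validated parameters of every stage; constructing one validates all stages."""

    seed: int = 0
    mode: str = "windowed"                 # "windowed" or "row"
    out_dir: str = "runs"
    synth: SynthConfig = field(default_factory=SynthConfig)
    filter_lo_hz: float = 4.0
    filter_hi_hz: float = 40.0
    ica_enabled: bool = True
    ica_k: int | None = None
    ica_blink_corr_threshold: float = 0.6
    ica_kurtosis_threshold: float = 10.0
    window: int = 128
    step: int = 128
    autoencoder: AutoencoderSpec = field(default_factory=AutoencoderSpec)
    rsa: RSAConfig = field(default_factory=lambda: RSAConfig(
        n_pop=20, n_iter=40, alpha_fitness=0.99, fitness_subsample=2000))
    model: ModelConfig = field(default_factory=ModelConfig)
    test_fraction: float = 0.2
    run_baseline_models: bool = True
    baseline_n_estimators: int = 100
    save_feature_csv: bool = True

    def __post_init__(self) -> None:
        if self.mode not in ("windowed", "row"):
            raise ConfigurationError(f"mode must be 'windowed' or 'row', got {self.mode!r}")
        nyq = self.synth.sfreq / 2
        if not 0 < self.filter_lo_hz < self.filter_hi_hz:
            raise ConfigurationError("need 0 < filter.lo_hz < filter.hi_hz")
        if self.filter_hi_hz >= nyq:
            raise ConfigurationError(
                f"filter.hi_hz={self.filter_hi_hz} must be below Nyquist ({nyq} Hz)")
        if not 0 < self.test_fraction < 1:
            raise ConfigurationError("test_fraction must lie in (0, 1)")
        if self.mode == "row" and self.window != 1:
            raise ConfigurationError("row mode requires window=1")
        if self.window < 1 or self.step < 1:
            raise ConfigurationError("window and step must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        kwargs = dict(raw)
        for key, sub in (("synth", SynthConfig), ("autoencoder", AutoencoderSpec),
                         ("rsa", RSAConfig), ("model", ModelConfig)):
            if key in kwargs and isinstance(kwargs[key], dict):
                section = dict(kwargs[key])
                for k in ("channel_names", "blocks_per_stage", "stage_kernels",
                          "stage_channels", "encoder_widths", "class_band_power"):
                    if k in section and isinstance(section[k], list):
                        section[k] = tuple(section[k])
                kwargs[key] = sub(**section)
        return cls(**kwargs)

    def to_dict(self) -> dict:
        def convert(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: convert(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, tuple):
                return list(obj)
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            if isinstance(obj, dict):
                return {k: convert(v) for k, v in obj.items()}
            return obj
        return convert(self)


def demo_config(seed: int = 0, out_dir: str = "runs") -> PipelineConfig:
    """Reduced desk-scale configuration: 5,000 one-second instances, a
    4-block (8-convolution) network trained 20 epochs, RSA at N=15/T=40.

    Small enough to finish on one CPU in minutes while exercising every
    stage; the strong default band-power contrast makes the task learnable
    end to end.
    """
    from .resnet import REDUCED_CONFIG

    return PipelineConfig(
        seed=seed,
        out_dir=out_dir,
        synth=SynthConfig(n_samples_per_class=320_000),   # 2,500 epochs per class
        autoencoder=AutoencoderSpec(epochs=30),
        rsa=RSAConfig(n_pop=15, n_iter=40, alpha_fitness=0.99,
                      fitness_subsample=2000),
        model=replace(REDUCED_CONFIG, epochs=20),
        save_feature_csv=False,
    )


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: SHA-256("{seed}:{stage}") mod 2^31."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class RunResult:
    run_dir: Path
    report: dict
    model: object
    mask_names: list[str]


def _simulate(cfg: PipelineConfig) -> tuple[list[synth.Recording], list[synth.Recording]]:
    scfg = replace(cfg.synth, seed=stage_seed(cfg.seed, "simulate"))
    clean, noisy = [], []
    for label in (0, 1):
        rec = synth.generate_recording(scfg, label)
        clean.append(rec)
        noisy.append(synth.inject_artifacts(rec, scfg))
    return clean, noisy


def _preprocess(cfg: PipelineConfig, recs: list[synth.Recording]) -> list[synth.Recording]:
    out = []
    for rec in recs:
        filt = pp.bandpass(rec, cfg.filter_lo_hz, cfg.filter_hi_hz)
        if cfg.ica_enabled:
            dec = pp.run_ica(filt, k=cfg.ica_k, seed=stage_seed(cfg.seed, "ica"))
            flags, _ = pp.score_components(
                dec, filt, cfg.ica_blink_corr_threshold, cfg.ica_kurtosis_threshold)
            if flags.all():
                raise ConfigurationError("ICA criteria flagged every component")
            if flags.any():
                filt = pp.reject_components(dec, filt, flags=flags)
        out.append(filt)
    return out


def _features(cfg: PipelineConfig, recs: list[synth.Recording]
              ) -> tuple[ft.FeatureMatrix, np.ndarray, np.ndarray]:
    """Unified standardized features plus train/test index sets.

    The split happens at the epoch level before any fitting, and the
    autoencoder and standardizer see training instances only.
    """
    window, step = (1, 1) if cfg.mode == "row" else (cfg.window, cfg.step)
    es = ft.concat_epoch_sets([ft.epoch(r, window, step) for r in recs])
    train_idx, test_idx = ev.split(es.epochs, es.labels, cfg.test_fraction,
                                   seed=stage_seed(cfg.seed, "split"))
    flat = es.flattened()
    ae_spec = replace(cfg.autoencoder, seed=stage_seed(cfg.seed, "autoencoder"))
    ae = train_autoencoder(flat[train_idx], ae_spec)
    latent = encode(ae, flat, es.labels)
    tdf = ft.time_domain_features(es)
    fdf = ft.frequency_domain_features(es)
    fm = ft.concat_features(latent, tdf, fdf)
    scaler = ft.Standardizer.fit(fm.subset(train_idx))
    return scaler.transform(fm), train_idx, test_idx


def run_pipeline(cfg: PipelineConfig, run_dir: str | Path | None = None) -> RunResult:
    """Execute all stages in order and write artifacts to the run directory.

    Artifacts: ``config.yaml`` (echo), ``features.csv`` (optional),
    ``selection.json``, ``checkpoint.npz``, ``report.json``, ``roc.csv``,
    ``pipeline.log``.  Same config + seed => byte-identical ``report.json``.
    A stage failure leaves a ``FAILED`` marker naming the stage and re-raises.
    """
    run_dir = Path(run_dir) if run_dir is not None else (
        Path(cfg.out_dir) / f"run_seed{cfg.seed}")
    run_dir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(run_dir / "pipeline.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    stage = "config"
    try:
        (run_dir / "config.yaml").write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))

        stage = "simulate"
        t0 = time.perf_counter()
        _, noisy = _simulate(cfg)
        logger.info("simulate: %d+%d samples in %.1fs", noisy[0].n_samples,
                    noisy[1].n_samples, time.perf_counter() - t0)

        stage = "preprocess"
        t0 = time.perf_counter()
        cleaned = _preprocess(cfg, noisy)
        logger.info("preprocess done in %.1fs", time.perf_counter() - t0)

        stage = "features"
        t0 = time.perf_counter()
        fm, train_idx, test_idx = _features(cfg, cleaned)
        logger.info("features: %d instances x %d features in %.1fs",
                    fm.n_instances, fm.n_features, time.perf_counter() - t0)
        if cfg.save_feature_csv:
            fm.to_csv(run_dir / "features.csv")

        stage = "select"
        t0 = time.perf_counter()
        rsa_cfg = replace(cfg.rsa, seed=stage_seed(cfg.seed, "select"))
        selection = select_features(fm.subset(train_idx), None, rsa_cfg)
        selection.to_json(run_dir / "selection.json")
        sel = fm.select(selection.mask.selected)
        logger.info("select: %d/%d features in %.1fs", selection.mask.n_selected,
                    fm.n_features, time.perf_counter() - t0)

        stage = "train"
        t0 = time.perf_counter()
        model_cfg = replace(cfg.model, seed=stage_seed(cfg.seed, "train"))
        model = train(sel.subset(train_idx), None, model_cfg)
        np.savez(run_dir / "checkpoint.npz",
                 **{k.replace("/", "_"): v for k, v in
                    model.network.all_params().items()},
                 _history=np.array(model.history))
        logger.info("train: %d epochs in %.1fs", model_cfg.epochs,
                    time.perf_counter() - t0)

        stage = "evaluate"
        t0 = time.perf_counter()
        probs, pred = predict(model, sel.subset(test_idx))
        y_test = fm.labels[test_idx]
        roc_points, auc = ev.roc_and_auc(probs[:, 1], y_test)
        cm = ev.confusion(y_test, pred)
        report_model = ev.compute_metrics(cm, roc_auc=auc)
        np.savetxt(run_dir / "roc.csv", roc_points, delimiter=",",
                   header="fpr,tpr", comments="")
        report: dict = {
            "seed": cfg.seed,
            "mode": cfg.mode,
            "n_train": int(len(train_idx)),
            "n_test": int(len(test_idx)),
            "selected_features": selection.selected_names,
            "attention_resnet": {
                "confusion": {"tp": cm.tp, "tn": cm.tn, "fp": cm.fp, "fn": cm.fn},
                "metrics": report_model.as_dict(),
            },
        }
        if cfg.run_baseline_models:
            baselines = ev.run_baselines(
                sel.values[train_idx], fm.labels[train_idx],
                sel.values[test_idx], y_test,
                seed=stage_seed(cfg.seed, "baselines"),
                n_estimators=cfg.baseline_n_estimators)
            report["baselines"] = {name: rep.as_dict()
                                   for name, rep in baselines.items()}
        logger.info("evaluate done in %.1fs", time.perf_counter() - t0)

        def _jsonable(obj):
            if isinstance(obj, dict):
                return {k: _jsonable(v) for k, v in obj.items()}
            if isinstance(obj, float) and not np.isfinite(obj):
                return None
            return obj

        (run_dir / "report.json").write_text(
            json.dumps(_jsonable(report), indent=1, sort_keys=True))
        return RunResult(run_dir, report, model, selection.selected_names)
    except Exception as exc:
        (run_dir / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    finally:
        logger.removeHandler(handler)
        handler.close()


def make_report(run_dir: str | Path) -> str:
    """Render the stored report as text tables (pure function of the artifacts)."""
    run_dir = Path(run_dir)
    report_path = run_dir / "report.json"
    if not report_path.exists():
        missing = [p for p in ("report.json",) if not (run_dir / p).exists()]
        raise FileNotFoundError(f"missing artifacts in {run_dir}: {missing}")
    report = json.loads(report_path.read_text())
    lines = [f"Run (seed {report['seed']}, mode {report['mode']}): "
             f"{report['n_train']} train / {report['n_test']} test instances", ""]
    cm = report["attention_resnet"]["confusion"]
    lines += ["Attention ResNet confusion matrix:",
              "                 predicted 0   predicted 1",
              f"  actual 0 (ctl) {cm['tn']:>11d}   {cm['fp']:>11d}",
              f"  actual 1 (adhd){cm['fn']:>11d}   {cm['tp']:>11d}", ""]
    rows = [("attention_resnet", report["attention_resnet"]["metrics"])]
    rows += sorted(report.get("baselines", {}).items())
    header = f"{'model':<18}{'acc':>8}{'prec':>8}{'rec':>8}{'f1':>8}{'spec':>8}{'bAUC':>8}{'rocAUC':>8}{'miscls':>8}"
    lines.append(header)
    for name, m in rows:
        def fmt(key):
            v = m.get(key)
            return f"{v:>8.4f}" if isinstance(v, (int, float)) and v is not None else f"{'--':>8}"
        lines.append(f"{name:<18}" + "".join(fmt(k) for k in (
            "accuracy", "precision", "recall", "f1", "specificity",
            "balanced_auc", "empirical_roc_auc", "misclassification_rate")))
    lines.append("")
    lines.append(f"Selected features ({len(report['selected_features'])}): "
                 + ", ".join(report["selected_features"][:12])
                 + (" ..." if len(report["selected_features"]) > 12 else ""))
    return "\n".join(lines)
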