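"""End-to-end experiment orchestration.

One invocation runs both study arms on the same generated (or loaded)
dataset: the e-nose block alone and the low-level fusion of e-nose with
the acoustic firmness indices.  Each arm is screened with Wilks' lambda,
explored with PCA, classified with LDA (resubstitution + leave-one-out),
and clustered with the LDA-score-driven competitive network on a
stratified 25/75 train/test split.  The headline output is the contrast
between the arms.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import shutil
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from aromafuse import chemometrics, clnn, io, synthetic
from aromafuse.fusion import fuse
from aromafuse.preprocessing import autoscale

log = logging.getLogger("aromafuse")


@dataclass
class ExperimentConfig:
    seed: int = 0
    n_per_class: int = 80
    enose_sd: float = synthetic.DEFAULT_ENOSE_SD
    acoustic_sd: float = synthetic.DEFAULT_ACOUSTIC_SD
    input_csv: str | None = None  # when set, load instead of generating
    screening_alpha: float = 0.05
    n_score_components: int = 3
    clnn_neurons: int = 6
    clnn_alpha: float = 0.1
    clnn_bias_lr: float = 0.001
    clnn_epochs: int = 200
    clnn_repeats: int = 3
    train_frac: float = 0.25
    run_loo: bool = True
    output_dir: str = "results"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _prepare_arms(df: pd.DataFrame):
    """Autoscale each modality block and build the two analysis arms."""
    chans = io.channel_columns(df)
    enose_scaled, _ = autoscale(df[chans], block="enose")
    arms = {"enose": fuse(enose_scaled, pd.DataFrame(index=df.index))}
    if {"FI", "AFI"} <= set(df.columns):
        acoustic_scaled, _ = autoscale(df[["FI", "AFI"]], block="acoustic")
        arms["fused"] = fuse(enose_scaled, acoustic_scaled)
    return arms


def _run_arm(name: str, fused, y: np.ndarray, cfg: ExperimentConfig, outdir: Path) -> dict:
    X = fused.data
    log.info("arm=%s stage=input rows=%d cols=%d", name, *X.shape)
    screen = chemometrics.wilks_screen(X, y, alpha=cfg.screening_alpha)
    screen.to_frame().to_csv(outdir / f"{name}_wilks.csv", index=False)
    kept = screen.kept_columns()
    log.info("arm=%s stage=screen kept=%d dropped=%d", name,
             len(kept), len(screen.dropped_columns()))
    Xk = X[kept]
    pca = chemometrics.pca_fit(Xk)
    pd.DataFrame(
        {
            "component": np.arange(1, len(pca.explained_variance_ratio) + 1),
            "explained_variance_ratio": pca.explained_variance_ratio,
            "cumulative": np.cumsum(pca.explained_variance_ratio),
        }
    ).to_csv(outdir / f"{name}_pca.csv", index=False)
    result = {
        "arm": name,
        "n_variables": int(X.shape[1]),
        "n_kept": len(kept),
        "pca_n_retained": pca.n_retained,
    }
    if cfg.run_loo:
        report = chemometrics.loo_crossvalidate(Xk, y)
        report.to_frame().to_csv(outdir / f"{name}_lda_report.csv", index=False)
        result["lda_resubstitution_pct"] = report.resubstitution_accuracy
        result["lda_loo_pct"] = report.loo_accuracy
        log.info("arm=%s stage=lda resub=%.1f%% loo=%.1f%%", name,
                 report.resubstitution_accuracy, report.loo_accuracy)
    split = clnn.evaluate_split(
        Xk.to_numpy(),
        y,
        train_frac=cfg.train_frac,
        seed=cfg.seed,
        n_score_components=cfg.n_score_components,
        n_neurons=cfg.clnn_neurons,
        alpha=cfg.clnn_alpha,
        bias_lr=cfg.clnn_bias_lr,
        epochs=cfg.clnn_epochs,
        repeats=cfg.clnn_repeats,
    )
    split.to_frame().to_csv(outdir / f"{name}_clnn_report.csv", index=False)
    result.update(
        clnn_n_train=split.n_train,
        clnn_n_test=split.n_test,
        clnn_clusters_detected=split.n_clusters_detected,
        clnn_classes_detected=split.n_classes_detected,
        clnn_test_accuracy_pct=split.accuracy_pct,
    )
    log.info("arm=%s stage=clnn clusters=%d classes=%d acc=%.1f%%", name,
             split.n_clusters_detected, split.n_classes_detected, split.accuracy_pct)
    return result


def run_experiment(config: ExperimentConfig) -> dict:
    """Run both arms end to end; write all reports under ``config.output_dir``.

    Returns the comparison dictionary also written to ``comparison.json``.
    Any stage failure aborts with a stage-named error and removes the
    partially written output directory.
    """
    outdir = Path(config.output_dir)
    created = not outdir.exists()
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    try:
        stage = "data"
        if config.input_csv:
            df = io.read_feature_csv(config.input_csv)
        else:
            specs = synthetic.paper_default_classes(
                enose_sd=config.enose_sd,
                acoustic_sd=config.acoustic_sd,
                n_per_class=config.n_per_class,
            )
            df = synthetic.generate_dataset(specs, seed=config.seed)
        y = df["class"].to_numpy()
        log.info("stage=data rows=%d classes=%d seed=%d", len(df),
                 len(np.unique(y)), config.seed)
        io.write_feature_csv(df, outdir / "features.csv")
        stage = "arms"
        arms = _prepare_arms(df)
        results = {}
        for name, fused_matrix in arms.items():
            stage = f"arm:{name}"
            results[name] = _run_arm(name, fused_matrix, y, config, outdir)
        comparison = {
            "config": config.to_dict(),
            "config_digest": config.digest(),
            "arms": results,
        }
        (outdir / "comparison.json").write_text(json.dumps(comparison, indent=2))
        return comparison
    except Exception as exc:
        if created:
            shutil.rmtree(outdir, ignore_errors=True)
        raise RuntimeError(f"experiment failed at stage {stage!r}: {exc}") from exc
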