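"""End-to-end orchestration: CLAHE -> features -> tuned DBN -> evaluation.

The pipeline enhances every tile with CLAHE, extracts depthwise-separable
convolutional features, z-scores them on the training rows, optionally
compresses them with the autoencoder, searches DBN hyperparameters with
the Marine Predators Algorithm using validation classifier error as the
fitness, retrains the best configuration on the full training split and
scores the held-out test split.  Index bookkeeping guarantees that no
test-split row ever reaches a fitting stage.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from sklearn.model_selection import train_test_split

from . import dbn as _dbn
from . import mpa as _mpa
from .features import ExtractorConfig, extract_features, standardize
from .metrics import MetricsReport, evaluate
from .preprocess import ClaheConfig, ImageTile, clahe_enhance, load_tiles
from .synthetic import generate_tiles

logger = logging.getLogger(__name__)


@dataclass
class SplitSpec:
    train_fraction: float = 0.8
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie strictly between 0 and 1")


def split_dataset(labels: Sequence, spec: SplitSpec) -> tuple[np.ndarray, np.ndarray]:
    """Disjoint, exhaustive train/test index sets; stratified when asked.

    ``labels`` may be a label sequence or a sequence of tiles.
    """
    labels = np.asarray([t.label if isinstance(t, ImageTile) else t
                         for t in labels])
    idx = np.arange(labels.size)
    strat = None
    if spec.stratified:
        _, counts = np.unique(labels, return_counts=True)
        if counts.min() < 2:
            raise ValueError("stratified split needs at least 2 samples per class")
        strat = labels
    train_idx, test_idx = train_test_split(
        idx, train_size=spec.train_fraction, stratify=strat,
        random_state=spec.seed)
    return np.sort(train_idx), np.sort(test_idx)


@dataclass
class AEConfig:
    enabled: bool = False
    layer_dims: tuple[int, ...] = (64, 32, 16)
    lr: float = 0.05
    epochs: int = 40


@dataclass
class MPASearchConfig:
    n: int = 8
    Imax: int = 8
    P: float = 0.5
    FADs: float = 0.2
    rbm_epochs: int = 10
    val_fraction: float = 0.2


@dataclass
class DBNDefaults:
    """Fallback hyperparameters used when tuning is disabled."""

    hidden: tuple[int, int] = (64, 32)
    rbm_lr: float = 0.05
    rbm_epochs: int = 15
    cd_k: int = 1
    finetune_lr: float = 0.3
    finetune_epochs: int = 30


@dataclass
class PipelineConfig:
    seed: int = 0
    data_dir: Optional[str] = None
    synthetic: bool = False
    synthetic_n_per_class: int = 60
    tile_size: int = 64
    tune: bool = True
    preprocess: ClaheConfig = field(default_factory=ClaheConfig)
    features: ExtractorConfig = field(default_factory=ExtractorConfig)
    ae: AEConfig = field(default_factory=AEConfig)
    mpa: MPASearchConfig = field(default_factory=MPASearchConfig)
    dbn: DBNDefaults = field(default_factory=DBNDefaults)
    split: SplitSpec = field(default_factory=SplitSpec)
    output_dir: Optional[str] = None
    save_preprocessed: bool = False
    features_out: Optional[str] = None
    model_out: Optional[str] = None

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        kwargs = {}
        for key, sub in (("preprocess", ClaheConfig), ("features", ExtractorConfig),
                         ("ae", AEConfig), ("mpa", MPASearchConfig),
                         ("dbn", DBNDefaults), ("split", SplitSpec)):
            if key in raw:
                section = dict(raw.pop(key))
                for fld in ("block_size", "input_size", "layer_dims", "hidden"):
                    if fld in section and isinstance(section[fld], list):
                        section[fld] = tuple(section[fld])
                if "blocks" in section:
                    section["blocks"] = tuple(tuple(b) for b in section["blocks"])
                kwargs[key] = sub(**section)
        kwargs.update(raw)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass
class PipelineResult:
    report: MetricsReport
    best_hyperparams: dict
    convergence: Optional[np.ndarray]
    train_idx: np.ndarray
    test_idx: np.ndarray
    predictions: pd.DataFrame
    fit_row_log: dict
    timings: dict
    model: Optional[_dbn.DBNModel] = None


def _check_no_leakage(fit_row_log: dict, train_idx: np.ndarray,
                      test_idx: np.ndarray) -> None:
    test = set(int(i) for i in test_idx)
    for stage, rows in fit_row_log.items():
        overlap = test.intersection(int(i) for i in rows)
        if overlap:
            raise RuntimeError(f"test rows {sorted(overlap)[:5]} leaked into "
                               f"fitting stage '{stage}'")
    if test.intersection(int(i) for i in train_idx):
        raise RuntimeError("train and test index sets overlap")


def run_pipeline(cfg: PipelineConfig,
                 tiles: Optional[Sequence[ImageTile]] = None) -> PipelineResult:
    """Execute the full pipeline and (optionally) write artifacts.

    Fully deterministic for a fixed config: the master seed drives tile
    generation, the split, extractor weights, the optimizer and all model
    training.
    """
    timings: dict = {}
    t_all = time.perf_counter()

    def stage(name):
        logger.info("stage %s starting (seed=%d)", name, cfg.seed)
        return time.perf_counter()

    def done(name, t0):
        timings[name] = time.perf_counter() - t0
        logger.info("stage %s finished in %.2fs", name, timings[name])

    t0 = stage("load")
    if tiles is None:
        if cfg.synthetic:
            tiles = generate_tiles(cfg.synthetic_n_per_class, size=cfg.tile_size,
                                   seed=cfg.seed)
        elif cfg.data_dir:
            tiles = load_tiles(cfg.data_dir)
        else:
            raise ValueError("config needs data_dir or synthetic=True")
    labels = np.asarray([t.label for t in tiles])
    classes = tuple(sorted(set(labels)))
    y = np.searchsorted(np.asarray(classes, dtype=object), labels)
    done("load", t0)

    t0 = stage("preprocess")
    enhanced = [clahe_enhance(t, cfg.preprocess) for t in tiles]
    if cfg.save_preprocessed and cfg.output_dir:
        from .preprocess import save_tiles
        save_tiles(enhanced, Path(cfg.output_dir) / "preprocessed")
    done("preprocess", t0)

    t0 = stage("split")
    split_spec = SplitSpec(train_fraction=cfg.split.train_fraction,
                           stratified=cfg.split.stratified,
                           seed=cfg.seed + cfg.split.seed)
    train_idx, test_idx = split_dataset(labels, split_spec)
    fit_row_log = {}
    done("split", t0)

    t0 = stage("features")
    fcfg = cfg.features
    if fcfg.weights_seed == 0:
        fcfg = ExtractorConfig(**{**asdict(fcfg), "weights_seed": cfg.seed + 1})
    feats = extract_features(enhanced, fcfg, fit_labels=labels,
                             fit_rows=train_idx)
    if fcfg.weights_mode == "trained":
        fit_row_log["extractor_fit"] = train_idx
    feats = standardize(feats, fit_rows=train_idx)
    fit_row_log["standardize"] = train_idx
    X = feats.values
    if cfg.features_out:
        cols = {f"f{j}": X[:, j] for j in range(X.shape[1])}
        pd.DataFrame({"id": feats.ids, "label": labels, **cols}
                     ).to_csv(cfg.features_out, index=False)
    done("features", t0)

    if cfg.ae.enabled:
        t0 = stage("autoencoder")
        dims = (X.shape[1],) + tuple(cfg.ae.layer_dims[1:]) \
            if cfg.ae.layer_dims[0] != X.shape[1] else tuple(cfg.ae.layer_dims)
        ae = _dbn.train_autoencoder(X[train_idx], dims, lr=cfg.ae.lr,
                                    epochs=cfg.ae.epochs, seed=cfg.seed + 2)
        fit_row_log["autoencoder"] = train_idx
        X = ae.encode(X)
        done("autoencoder", t0)

    convergence = None
    if cfg.tune:
        t0 = stage("mpa_search")
        bundle = _mpa.TrainBundle(X=X[train_idx], y=y[train_idx],
                                  n_classes=len(classes),
                                  val_fraction=cfg.mpa.val_fraction,
                                  seed=cfg.seed + 3,
                                  rbm_epochs=cfg.mpa.rbm_epochs)
        fit_row_log["mpa_fitness"] = train_idx
        space = _mpa.hyperparameter_space()
        mcfg = _mpa.MPAConfig(n=cfg.mpa.n, Imax=cfg.mpa.Imax, P=cfg.mpa.P,
                              FADs=cfg.mpa.FADs, seed=cfg.seed + 4)
        result = _mpa.optimize(
            lambda x: _mpa.classifier_error_fitness(x, space, bundle),
            space, mcfg)
        best_hp = _mpa.decode_candidate(result.best_x)
        convergence = result.history
        logger.info("MPA best validation error %.2f%% with %s",
                    result.best_f, best_hp)
        done("mpa_search", t0)
    else:
        d = cfg.dbn
        best_hp = {"rbm_lr": d.rbm_lr, "finetune_lr": d.finetune_lr,
                   "hidden": tuple(d.hidden), "cd_k": d.cd_k,
                   "finetune_epochs": d.finetune_epochs}

    t0 = stage("final_train")
    model = _dbn.fit_dbn_classifier(
        X[train_idx], y[train_idx], n_classes=len(classes),
        hidden=best_hp["hidden"], rbm_lr=best_hp["rbm_lr"],
        rbm_epochs=cfg.dbn.rbm_epochs, cd_k=best_hp["cd_k"],
        finetune_lr=best_hp["finetune_lr"],
        finetune_epochs=best_hp["finetune_epochs"], seed=cfg.seed + 5)
    fit_row_log["dbn_train"] = train_idx
    if cfg.model_out:
        _dbn.save_model(model, cfg.model_out)
    done("final_train", t0)

    t0 = stage("evaluate")
    _check_no_leakage(fit_row_log, train_idx, test_idx)
    probs, pred = _dbn.predict(model, X[test_idx])
    pred_labels = np.asarray(classes, dtype=object)[pred]
    report = evaluate(labels[test_idx], pred_labels, probs, labels=classes)
    preds = pd.DataFrame({
        "id": [tiles[i].source_id for i in test_idx],
        "true": labels[test_idx],
        "pred": pred_labels,
        **{f"score_{c}": probs[:, k] for k, c in enumerate(classes)},
    })
    done("evaluate", t0)
    timings["total"] = time.perf_counter() - t_all

    out = PipelineResult(report=report, best_hyperparams=best_hp,
                         convergence=convergence, train_idx=train_idx,
                         test_idx=test_idx, predictions=preds,
                         fit_row_log=fit_row_log, timings=timings,
                         model=model)
    if cfg.output_dir:
        write_artifacts(out, cfg, Path(cfg.output_dir))
    return out


def write_artifacts(result: PipelineResult, cfg: PipelineConfig,
                    out_dir: Path) -> None:
    """metrics.json, confusion.csv, convergence.csv, preds.csv, config echo."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report = result.report
    payload = report.percent()
    payload["best_hyperparams"] = {k: (list(v) if isinstance(v, tuple) else v)
                                   for k, v in result.best_hyperparams.items()}
    payload["timings_s"] = {k: round(v, 3) for k, v in result.timings.items()}
    (out_dir / "metrics.json").write_text(json.dumps(payload, indent=2))

    conf = pd.DataFrame(report.confusion, index=list(report.labels),
                        columns=list(report.labels))
    conf.to_csv(out_dir / "confusion.csv")
    if result.convergence is not None:
        pd.DataFrame({"iteration": np.arange(result.convergence.size),
                      "best_error_pct": result.convergence}
                     ).to_csv(out_dir / "convergence.csv", index=False)
    result.predictions.round(6).to_csv(out_dir / "preds.csv", index=False)
    (out_dir / "config.yaml").write_text(yaml.safe_dump(asdict(cfg)))
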