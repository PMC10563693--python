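"""End-to-end experiment orchestration.

``run_experiment`` drives the whole workflow from one configuration:
simulate two-class spectra, Kennard-Stone split, chemometric models over
the nine named preprocessing chains (PLS-DA with permutation diagnostics,
RBF-SVM grid search), per-sample correlation maps, surface-image
rendering with the train/test/external-validation partition, residual-CNN
training per image category, and a machine-readable report of every
number. One global seed fans out deterministically to per-stage seeds, so
any stage can be rerun in isolation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import chemometrics as chem
from . import cnn as cnn_mod
from .cos import per_sample_maps
from .metrics import confusion_metrics, count_confusion
from .preprocess import CHAIN_NAMES, ChainTransformer
from .render import RenderConfig, build_image_dataset, CATEGORIES
from .simulate import SyntheticConfig, default_band_table, generate_spectra
from .spectra import write_labels_csv, write_spectra_csv
from .split import stratified_split, write_split_manifest

__all__ = ["ExperimentConfig", "tiny_config", "paper_scale_config", "run_experiment",
           "stage_seed"]

log = logging.getLogger("mircos")


def stage_seed(seed: int, stage: str) -> int:
    """Derive a per-stage seed below 2^31 from the global seed."""
    return (seed * 1_000_003 + zlib.crc32(stage.encode())) % (2**31 - 1)


@dataclass
class ExperimentConfig:
    """All knobs of one experiment; defaults are desk-scale."""

    seed: int = 0
    out_dir: str = "mircos_run"
    # synthetic data
    n_per_class: dict[str, int] = field(
        default_factory=lambda: {"cultivated": 109, "wild": 63}
    )
    grid: tuple[float, float, float] = (4000.0, 450.0, 2.0)
    class_contrast: float = 1.5
    noise_sd: float = 0.01
    replicates: int = 3
    # split
    split_fraction: float = 0.7
    # chemometrics
    chains: tuple[str, ...] = CHAIN_NAMES
    plsda_components: int = 2
    plsda_folds: int = 7
    n_permutations: int = 200
    run_permutations: bool = True
    svm_grid_c: tuple[float, ...] = tuple(2.0**e for e in range(-2, 16, 2))
    svm_grid_g: tuple[float, ...] = tuple(2.0**e for e in range(-18, 1, 2))
    svm_folds: int = 5
    # correlation maps / images
    cos_mode: str = "replicate"
    cos_downsample: int = 16
    image_size: int = 64
    image_format: str = "PNG"
    image_counts: tuple[int, int, int] = (84, 36, 52)
    # CNN
    cnn_epochs: int = 46
    cnn_arch: cnn_mod.ResNetSpec = field(default_factory=lambda: cnn_mod.TINY)
    cnn_categories: tuple[str, ...] = CATEGORIES

    def synthetic_config(self) -> SyntheticConfig:
        return SyntheticConfig(
            n_per_class=dict(self.n_per_class),
            grid=self.grid,
            peaks=default_band_table(self.class_contrast),
            noise_sd=self.noise_sd,
            replicates=self.replicates,
            seed=stage_seed(self.seed, "simulate"),
        )

    def config_hash(self) -> str:
        """Hash of everything that affects the numbers (output path excluded)."""
        d = dataclasses.asdict(self)
        d.pop("out_dir", None)
        blob = json.dumps(_as_jsonable(d), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name in raw:
                v = raw[f.name]
                if f.name == "cnn_arch" and isinstance(v, dict):
                    v = cnn_mod.ResNetSpec(**{
                        k: tuple(x) if isinstance(x, list) else x for k, x in v.items()
                    })
                elif isinstance(v, list):
                    v = tuple(v)
                kwargs[f.name] = v
        return cls(**kwargs)


def tiny_config(seed: int = 0, out_dir: str = "mircos_tiny") -> ExperimentConfig:
    """A minutes-scale smoke configuration (20 samples, 5 epochs)."""
    return ExperimentConfig(
        seed=seed,
        out_dir=out_dir,
        n_per_class={"cultivated": 18, "wild": 12},
        grid=(4000.0, 450.0, 10.0),
        chains=("RAW", "SNV", "2D"),
        plsda_folds=4,
        svm_folds=3,
        n_permutations=20,
        svm_grid_c=(1.0, 4.0, 16.0),
        svm_grid_g=(2.0**-8, 2.0**-4, 1.0),
        cos_downsample=4,
        image_counts=(16, 6, 8),
        cnn_epochs=25,
        cnn_categories=("synchronous",),
    )


def paper_scale_config(seed: int = 0, out_dir: str = "mircos_full") -> ExperimentConfig:
    """The full-size configuration: 172 samples, 84/36/52 images, 46 epochs."""
    return ExperimentConfig(seed=seed, out_dir=out_dir)


def _as_jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _as_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_as_jsonable(v) for v in obj]
    if isinstance(obj, Path):
        return str(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _as_jsonable(dataclasses.asdict(obj))
    return obj


def run_experiment(config: ExperimentConfig) -> dict:
    """Run every stage and write the report bundle under ``config.out_dir``.

    Returns the report dictionary (also written as ``report.json``).
    Any stage failure is re-raised with the stage name after the partial
    report has been flushed to disk.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    report: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": {},
    }
    stage = "simulate"
    try:
        # ---------------- simulate ---------------- #
        log.info("[%s] generating synthetic spectra", stage)
        spectra = generate_spectra(config.synthetic_config())
        write_spectra_csv(spectra, out / "spectra.csv")
        labels_by_sample = {
            sid: spectra.label_of(sid) for sid in spectra.unique_sample_ids
        }
        write_labels_csv(labels_by_sample, out / "labels.csv")
        report["stages"][stage] = {
            "n_records": spectra.n_records,
            "n_samples": len(spectra.unique_sample_ids),
            "class_counts": {
                c: sum(1 for v in labels_by_sample.values() if v == c)
                for c in spectra.classes
            },
        }

        # ---------------- split ---------------- #
        stage = "split"
        averaged = spectra.mean_by_sample()
        split = stratified_split(averaged, config.split_fraction)
        write_split_manifest(split, out / "split.csv")
        report["stages"][stage] = {
            "per_class_counts": {k: list(v) for k, v in split.per_class_counts.items()},
            "n_train": len(split.train_ids),
            "n_test": len(split.test_ids),
        }
        train_set = averaged.select_samples(split.train_ids)
        test_set = averaged.select_samples(split.test_ids)
        y_train = np.asarray(train_set.labels)
        y_test = np.asarray(test_set.labels)

        # ---------------- chemometric models ---------------- #
        stage = "plsda"
        plsda_rows = []
        perm_rows = []
        for chain in config.chains:
            tf = ChainTransformer.from_name(chain).fit(train_set)
            Xtr = tf.transform(train_set).absorbance
            Xte = tf.transform(test_set).absorbance
            model, m = chem.plsda_fit(
                Xtr, y_train, config.plsda_components, config.plsda_folds,
                seed=stage_seed(config.seed, f"plsda:{chain}"),
            )
            m, counts = chem.plsda_evaluate(model, m, Xte, y_test)
            plsda_rows.append(
                {
                    "Preprocessing": chain,
                    "Acc of train set (%)": round(m.acc_train, 2),
                    "Acc of test set (%)": round(m.acc_test, 2),
                    "RMSEE": round(m.rmsee, 4),
                    "RMSECV": round(m.rmsecv, 4),
                    "RMSEP": round(m.rmsep, 4),
                    "R2": round(m.r2y, 4),
                    "Q2": round(m.q2, 4),
                }
            )
            if config.run_permutations:
                perm = chem.plsda_permutation_test(
                    Xtr, y_train, config.n_permutations, config.plsda_components,
                    config.plsda_folds, seed=stage_seed(config.seed, f"perm:{chain}"),
                )
                perm_rows.append(
                    {
                        "Preprocessing": chain,
                        "R2 intercept": round(perm.r2_intercept, 4),
                        "Q2 intercept": round(perm.q2_intercept, 4),
                        "overfit": perm.overfit_flag,
                    }
                )
            log.info("[plsda] %s: train %.1f%% test %.1f%%", chain, m.acc_train, m.acc_test)
        plsda_table = pd.DataFrame(plsda_rows)
        plsda_table.to_csv(out / "plsda_table.csv", index=False)
        report["stages"]["plsda"] = plsda_rows
        if perm_rows:
            pd.DataFrame(perm_rows).to_csv(out / "plsda_permutations.csv", index=False)
            report["stages"]["plsda_permutations"] = perm_rows

        stage = "svm"
        svm_rows = []
        comparison_rows = []
        for chain in config.chains:
            tf = ChainTransformer.from_name(chain).fit(train_set)
            Xtr = tf.transform(train_set).absorbance
            Xte = tf.transform(test_set).absorbance
            clf, best, _, (mu, sd) = chem.svm_grid_search(
                Xtr, y_train, (list(config.svm_grid_c), list(config.svm_grid_g)),
                config.svm_folds, seed=stage_seed(config.seed, f"svm:{chain}"),
            )
            acc_tr = 100.0 * float(np.mean(clf.predict((Xtr - mu) / sd) == y_train))
            pred_te = clf.predict((Xte - mu) / sd)
            acc_te = 100.0 * float(np.mean(pred_te == y_test))
            svm_rows.append(
                {
                    "Preprocessing": chain,
                    "c": best.c,
                    "g": best.g,
                    f"Acc of train set ({len(y_train)}), %": round(acc_tr, 2),
                    f"Acc of test set ({len(y_test)}), %": round(acc_te, 2),
                }
            )
            cm = confusion_metrics(count_confusion(y_test, pred_te))
            comparison_rows.append(
                {
                    "Model": "SVM",
                    "Preprocessing": chain,
                    "Sen": round(cm.sen, 4),
                    "Spe": round(cm.spe, 4),
                    "Eff": round(cm.eff, 4),
                    "Acc": round(cm.acc, 4),
                }
            )
            log.info("[svm] %s: c=%g g=%g test %.1f%%", chain, best.c, best.g, acc_te)
        pd.DataFrame(svm_rows).to_csv(out / "svm_table.csv", index=False)
        report["stages"]["svm"] = svm_rows
        pd.DataFrame(comparison_rows).to_csv(out / "model_comparison.csv", index=False)
        report["stages"]["model_comparison"] = comparison_rows

        # ---------------- maps + images ---------------- #
        stage = "cosmap"
        maps = per_sample_maps(spectra, config.cos_mode, config.cos_downsample)
        report["stages"][stage] = {
            "n_maps_per_category": len(maps),
            "n_images_total": 3 * len(maps),
            "map_size": int(maps[next(iter(maps))].sync.shape[0]),
        }

        stage = "render"
        render_cfg = RenderConfig(
            image_size=config.image_size, format=config.image_format
        )
        dataset = build_image_dataset(
            maps, labels_by_sample, out / "images", config.image_counts,
            seed=stage_seed(config.seed, "partition"), config=render_cfg,
        )
        report["stages"][stage] = {
            "counts": list(config.image_counts),
            "categories": list(CATEGORIES),
        }

        # ---------------- CNN ---------------- #
        stage = "cnn"
        cnn_rows = []
        for category in config.cnn_categories:
            model, run = cnn_mod.train_classifier(
                dataset, category, config.cnn_epochs,
                seed=stage_seed(config.seed, f"cnn:{category}"),
                arch=config.cnn_arch,
            )
            history = pd.DataFrame(
                {
                    "epoch": np.arange(1, len(run.loss) + 1),
                    "loss": run.loss,
                    "acc_train": run.acc_train,
                    "acc_test": run.acc_test,
                }
            )
            history.to_csv(out / f"cnn_history_{category}.csv", index=False)
            _, m_tr, _ = cnn_mod.evaluate_classifier(model, dataset, category, "train")
            _, m_te, _ = cnn_mod.evaluate_classifier(model, dataset, category, "test")
            counts_ev, m_ev, loss_ev = cnn_mod.evaluate_classifier(
                model, dataset, category, "ev"
            )
            cnn_rows.append(
                {
                    "Classifications": category,
                    "Epochs": config.cnn_epochs,
                    "Acc of train set (%)": round(100 * m_tr.acc, 2),
                    "Acc of test set (%)": round(100 * m_te.acc, 2),
                    "Acc of EV (%)": round(100 * m_ev.acc, 2),
                    "Loss value": round(loss_ev, 4),
                    "Sen": round(m_ev.sen, 4),
                    "Spe": round(m_ev.spe, 4),
                    "Eff": round(m_ev.eff, 4),
                }
            )
            log.info(
                "[cnn] %s: train %.1f%% test %.1f%% ev %.1f%%",
                category, 100 * m_tr.acc, 100 * m_te.acc, 100 * m_ev.acc,
            )
        pd.DataFrame(cnn_rows).to_csv(out / "cnn_table.csv", index=False)
        report["stages"]["cnn"] = cnn_rows

    except Exception as exc:  # persist partial report, name the stage
        report["failed_stage"] = stage
        report["error"] = str(exc)
        (out / "report.json").write_text(json.dumps(_as_jsonable(report), indent=2))
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    # wall time stays out of the file so identical configs write identical reports
    (out / "report.json").write_text(
        json.dumps(_as_jsonable(report), indent=2, sort_keys=True)
    )
    report["elapsed_s"] = round(time.time() - t0, 2)
    return report
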