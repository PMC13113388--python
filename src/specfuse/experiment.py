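"""End-to-end study orchestration: five models, one comparison report.

`FusionExperiment` runs the full workflow on a paired FTIR/Raman dataset
(generated synthetically or loaded from a manifest):

1. condition every spectrum (despike -> baseline offset -> region SNV);
2. split the *pairs* 80/20 into train and test (pairing is atomic — both
   modalities of a sample travel together, and the test pairs are never
   seen by any training, cross-validation or bootstrap stage);
3. for each of the FTIR, Raman and low-level fused spectra: pick the
   latent-variable count by repeated 80/20 cross-validation plus the
   F-ratio parsimony rule, refit on the full training set, and attach
   jackknife+-after-bootstrap 95% prediction intervals to the test set;
4. form the two high-level fusion models from the individual models'
   test-set outputs and intervals (mean, and inverse-variance weighted);
5. score all five models on the identical test set and emit a
   :class:`ComparisonReport`.

Everything derives from one master seed through fixed stage offsets, so a
report is exactly reproducible, and changing e.g. the bootstrap count does
not perturb the data generation or the split.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import synthesis
from .conformal import ConformalConfig, PredictionInterval, jab_intervals
from .exceptions import InvalidDesignError, InvalidInputError
from .fusion import fuse_weighted, mean_fusion_interval
from .metrics import IntervalReport, build_interval_report
from .plsr import PLSR, CVResult, cross_validate, max_components, select_n_components
from .preprocessing import PreprocessingParams, preprocess_dataset
from .spectra import FTIR, RAMAN, PairedDataset, read_dataset

logger = logging.getLogger("specfuse")

#: fixed stage offsets for child-seed derivation from the master seed
STAGE_OFFSETS = {
    "data": 0,
    "split": 1,
    "cv_ftir": 2,
    "cv_raman": 3,
    "cv_low_level": 4,
    "jab_ftir": 5,
    "jab_raman": 6,
    "jab_low_level": 7,
}

MODEL_ORDER = ("ftir", "raman", "high_level_mean", "low_level", "high_level_weighted")
MODEL_LABELS = {
    "ftir": "FTIR",
    "raman": "Raman",
    "high_level_mean": "High-level fusion (mean)",
    "low_level": "Low-level fusion",
    "high_level_weighted": "High-level weighted fusion",
}
PLSR_MODELS = ("ftir", "raman", "low_level")


def stage_seed(master_seed: int, stage: str) -> np.random.SeedSequence:
    return np.random.SeedSequence((int(master_seed), STAGE_OFFSETS[stage]))


@dataclass
class ExperimentConfig:
    """Declarative description of one experiment run."""

    alpha: float = 0.05
    z: float = 1.96
    train_frac: float = 0.8
    n_cv_splits: int = 50
    cv_test_frac: float = 0.2
    lv_max: int = 30
    f_alpha: float = 0.05
    n_bootstrap: int = 100
    seed: int = 0
    # data source: a manifest path, or the synthetic generator settings
    manifest: str | None = None
    ratios: tuple[float, ...] = synthesis.DEFAULT_RATIO_PANEL
    replicates: int = 6
    include_pure: bool = False
    pure_l_value: float | None = None
    pure_s_value: float | None = None
    spike_rate: float = 1.0
    spike_magnitude: float = 8.0
    preprocessing: PreprocessingParams = field(default_factory=PreprocessingParams)
    conformal_point: str = "refit"

    def __post_init__(self) -> None:
        for name in ("train_frac", "cv_test_frac"):
            value = getattr(self, name)
            if not (0.0 < value < 1.0):
                raise InvalidInputError(f"{name} must be in (0, 1), got {value}")
        if not (0.0 < self.alpha < 1.0):
            raise InvalidInputError(f"alpha must be in (0, 1), got {self.alpha}")
        self.ratios = tuple(float(r) for r in self.ratios)

    # -- (de)serialisation -------------------------------------------------
    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["ratios"] = list(self.ratios)
        return out

    @classmethod
    def from_dict(cls, payload: dict) -> "ExperimentConfig":
        payload = dict(payload)
        pre = payload.pop("preprocessing", None)
        if isinstance(pre, dict):
            pre = {
                key: tuple(value) if isinstance(value, list) else value
                for key, value in pre.items()
            }
            payload["preprocessing"] = PreprocessingParams(**pre)
        if "ratios" in payload and payload["ratios"] is not None:
            payload["ratios"] = tuple(payload["ratios"])
        return cls(**payload)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(payload)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
        return path


def split_train_test(
    dataset: PairedDataset, train_frac: float = 0.8, seed=None
) -> tuple[PairedDataset, PairedDataset]:
    """Seeded random split of the *pairs* into disjoint train/test subsets."""
    n = len(dataset)
    if n < 5:
        raise InvalidDesignError(f"need >= 5 pairs to split, got {n}")
    if not (0.0 < train_frac < 1.0):
        raise InvalidInputError(f"train_frac must be in (0, 1), got {train_frac}")
    n_train = int(round(train_frac * n))
    n_train = min(max(n_train, 1), n - 1)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    train_idx = np.sort(perm[:n_train])
    test_idx = np.sort(perm[n_train:])
    return dataset[train_idx], dataset[test_idx]


@dataclass
class ModelOutput:
    """One model's test-set predictions and intervals."""

    name: str
    y_pred: np.ndarray
    intervals: list[PredictionInterval]
    n_lv: int | None = None
    cv: CVResult | None = None

    def frame(self, sample_ids, y_true) -> pd.DataFrame:
        from .conformal import intervals_to_frame

        return intervals_to_frame(self.intervals, sample_ids, y_true).assign(
            point=self.y_pred
        )


@dataclass
class ComparisonReport:
    """Five models' interval reports on one shared test set."""

    reports: dict[str, IntervalReport]
    n_lv: dict[str, int]
    outputs: dict[str, ModelOutput]
    y_test: np.ndarray
    test_ids: list[str]
    config: ExperimentConfig
    seed: int

    def to_frame(self) -> pd.DataFrame:
        """Comparison table: metric rows x model columns (table layout)."""
        rows = {}
        for metric in IntervalReport.FIELD_ORDER + ("r2", "n_test"):
            rows[metric] = {
                MODEL_LABELS[m]: getattr(self.reports[m], metric) for m in MODEL_ORDER
            }
        rows["n_lv"] = {
            MODEL_LABELS[m]: self.n_lv.get(m, np.nan) for m in MODEL_ORDER
        }
        return pd.DataFrame(rows).T[[MODEL_LABELS[m] for m in MODEL_ORDER]]

    def summary(self) -> str:
        frame = self.to_frame()
        header = (
            f"Model comparison on n_test={self.reports['ftir'].n_test} shared "
            f"test pairs (seed={self.seed})"
        )
        return header + "\n" + frame.to_string(float_format=lambda v: f"{v:.4f}")

    def predictions_frame(self, model: str) -> pd.DataFrame:
        return self.outputs[model].frame(self.test_ids, self.y_test)

    def plot_predictions(self, model: str, ax=None):
        """Predicted vs actual L/S with interval whiskers for one model."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        out = self.outputs[model]
        lower = out.y_pred - np.asarray([iv.lower for iv in out.intervals])
        upper = np.asarray([iv.upper for iv in out.intervals]) - out.y_pred
        ax.errorbar(
            self.y_test, out.y_pred, yerr=np.vstack([lower, upper]),
            fmt="o", capsize=3, label=MODEL_LABELS[model],
        )
        span = [self.y_test.min(), self.y_test.max()]
        ax.plot(span, span, "r-", lw=1, label="ideal")
        ax.set_xlabel("actual L/S ratio")
        ax.set_ylabel("predicted L/S ratio")
        ax.legend()
        return ax

    # -- serialisation -----------------------------------------------------
    def to_json_dict(self) -> dict:
        return {
            "seed": int(self.seed),
            "config": self.config.to_dict(),
            "test_ids": list(self.test_ids),
            "y_test": self.y_test.tolist(),
            "n_lv": {k: int(v) for k, v in self.n_lv.items()},
            "reports": {k: v.to_dict() for k, v in self.reports.items()},
            "predictions": {
                name: {
                    "point": out.y_pred.tolist(),
                    "lower": [iv.lower for iv in out.intervals],
                    "upper": [iv.upper for iv in out.intervals],
                    "sigma": [iv.sigma for iv in out.intervals],
                }
                for name, out in self.outputs.items()
            },
        }

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_json_dict(), indent=1))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "ComparisonReport":
        payload = json.loads(Path(path).read_text())
        config = ExperimentConfig.from_dict(payload["config"])
        outputs = {}
        for name, pred in payload["predictions"].items():
            intervals = [
                PredictionInterval(point=p, lower=lo, upper=up, sigma=s)
                for p, lo, up, s in zip(
                    pred["point"], pred["lower"], pred["upper"], pred["sigma"]
                )
            ]
            outputs[name] = ModelOutput(
                name=name,
                y_pred=np.asarray(pred["point"], dtype=float),
                intervals=intervals,
                n_lv=payload["n_lv"].get(name),
            )
        return cls(
            reports={k: IntervalReport(**v) for k, v in payload["reports"].items()},
            n_lv=dict(payload["n_lv"]),
            outputs=outputs,
            y_test=np.asarray(payload["y_test"], dtype=float),
            test_ids=list(payload["test_ids"]),
            config=config,
            seed=int(payload["seed"]),
        )


class FusionExperiment:
    """Model object for the five-way comparison; ``run()`` returns the report."""

    def __init__(self, config: ExperimentConfig | None = None,
                 dataset: PairedDataset | None = None):
        self.config = config or ExperimentConfig()
        self._dataset = dataset

    # -- data --------------------------------------------------------------
    def load_dataset(self) -> PairedDataset:
        cfg = self.config
        if self._dataset is not None:
            dataset = self._dataset
        elif cfg.manifest is not None:
            logger.info("loading dataset from manifest %s", cfg.manifest)
            dataset = read_dataset(cfg.manifest)
        else:
            logger.info(
                "generating synthetic dataset: %d ratios x %d replicates",
                len(cfg.ratios), cfg.replicates,
            )
            dataset = synthesis.generate_paired_dataset(
                ratios=cfg.ratios,
                replicates=cfg.replicates,
                seed=stage_seed(cfg.seed, "data"),
                spike_rate=cfg.spike_rate,
                spike_magnitude=cfg.spike_magnitude,
                include_pure=cfg.include_pure,
            )
        if cfg.include_pure or cfg.manifest is not None:
            dataset = dataset.map_pure(cfg.pure_l_value, cfg.pure_s_value)
        return dataset

    # -- single PLSR pipeline ----------------------------------------------
    def _plsr_pipeline(
        self, name: str, X_train, y_train, X_test
    ) -> ModelOutput:
        cfg = self.config
        cv = cross_validate(
            X_train,
            y_train,
            lv_max=cfg.lv_max,
            n_splits=cfg.n_cv_splits,
            test_frac=cfg.cv_test_frac,
            seed=stage_seed(cfg.seed, f"cv_{name}"),
        )
        n_lv = select_n_components(cv, alpha=cfg.f_alpha)
        logger.info("%s: selected %d latent variables", name, n_lv)

        def learner_factory(Xb, yb):
            k = min(n_lv, max_components(len(yb), Xb.shape[1]))
            return PLSR(yb, Xb, k).fit().predict

        intervals = jab_intervals(
            X_train,
            y_train,
            X_test,
            learner_factory,
            ConformalConfig(
                alpha=cfg.alpha,
                n_bootstrap=cfg.n_bootstrap,
                seed=stage_seed(cfg.seed, f"jab_{name}"),
                z=cfg.z,
                point=cfg.conformal_point,
            ),
        )
        y_pred = np.asarray([iv.point for iv in intervals])
        return ModelOutput(name=name, y_pred=y_pred, intervals=intervals,
                           n_lv=n_lv, cv=cv)

    # -- orchestration -------------------------------------------------------
    def run(self) -> ComparisonReport:
        cfg = self.config
        dataset = self.load_dataset().drop_pure()
        dataset = preprocess_dataset(dataset, cfg.preprocessing)
        train, test = split_train_test(
            dataset, cfg.train_frac, stage_seed(cfg.seed, "split")
        )
        train_ids, test_ids = set(train.sample_ids), set(test.sample_ids)
        assert train_ids.isdisjoint(test_ids), "train/test leakage detected"

        y_train, y_test = train.targets(), test.targets()
        matrices = {
            "ftir": (train.matrix(FTIR), test.matrix(FTIR)),
            "raman": (train.matrix(RAMAN), test.matrix(RAMAN)),
        }
        matrices["low_level"] = (
            np.hstack([matrices["ftir"][0], matrices["raman"][0]]),
            np.hstack([matrices["ftir"][1], matrices["raman"][1]]),
        )

        outputs: dict[str, ModelOutput] = {}
        for name in PLSR_MODELS:
            X_tr, X_te = matrices[name]
            outputs[name] = self._plsr_pipeline(name, X_tr, y_train, X_te)

        ftir_out, raman_out = outputs["ftir"], outputs["raman"]
        mean_ivs = [
            mean_fusion_interval(a, b, z=cfg.z)
            for a, b in zip(ftir_out.intervals, raman_out.intervals)
        ]
        outputs["high_level_mean"] = ModelOutput(
            name="high_level_mean",
            y_pred=0.5 * (ftir_out.y_pred + raman_out.y_pred),
            intervals=mean_ivs,
        )
        weighted_ivs = [
            fuse_weighted(pf, iv_f, pr, iv_r, z=cfg.z)
            for pf, iv_f, pr, iv_r in zip(
                ftir_out.y_pred, ftir_out.intervals,
                raman_out.y_pred, raman_out.intervals,
            )
        ]
        outputs["high_level_weighted"] = ModelOutput(
            name="high_level_weighted",
            y_pred=np.asarray([iv.point for iv in weighted_ivs]),
            intervals=weighted_ivs,
        )

        norm_range = float(y_test.max() - y_test.min())
        reports = {
            name: build_interval_report(
                y_test, out.y_pred, out.intervals,
                alpha=cfg.alpha, norm_range=norm_range,
            )
            for name, out in outputs.items()
        }
        return ComparisonReport(
            reports=reports,
            n_lv={name: outputs[name].n_lv for name in PLSR_MODELS},
            outputs=outputs,
            y_test=y_test,
            test_ids=test.sample_ids,
            config=cfg,
            seed=cfg.seed,
        )


def run_experiment(config: ExperimentConfig | None = None) -> ComparisonReport:
    """Functional entry point: configure, run, return the comparison report."""
    return FusionExperiment(config).run()


def write_report(report: ComparisonReport, directory: str | Path) -> dict[str, Path]:
    """Write the comparison table (CSV), full report (JSON), per-model interval
    CSVs and a config echo into *directory*; returns the paths written."""
    directory = Path(directory)
    tmp = directory.with_name(directory.name + ".partial")
    if tmp.exists():
        import shutil

        shutil.rmtree(tmp)
    tmp.mkdir(parents=True)
    paths: dict[str, Path] = {}
    try:
        frame = report.to_frame()
        frame.to_csv(tmp / "comparison.csv")
        report.to_json(tmp / "report.json")
        report.config.to_yaml(tmp / "config.yaml")
        for model in MODEL_ORDER:
            report.predictions_frame(model).to_csv(
                tmp / f"intervals_{model}.csv", index=False
            )
        (tmp / "summary.txt").write_text(report.summary() + "\n")
    except Exception:
        import shutil

        shutil.rmtree(tmp, ignore_errors=True)
        raise
    if directory.exists():
        import shutil

        shutil.rmtree(directory)
    tmp.rename(directory)
    for name in ("comparison.csv", "report.json", "config.yaml", "summary.txt"):
        paths[name] = directory / name
    for model in MODEL_ORDER:
        paths[f"intervals_{model}.csv"] = directory / f"intervals_{model}.csv"
    return paths
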