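"""End-to-end experiment runner: the 2 single-sensor + 5 fusion models.

Flow (all seeds derived from one experiment seed):

1. simulate or load a withering dataset (spectra + images + MC);
2. SNV-preprocess spectra; extract and min-max normalize the 18 image
   features (scaling fitted on calibration rows only);
3. 3:1 calibration/prediction split stratified by withering hour;
4. train the NIR and MV single-sensor SVR models (always, since the
   high level stacks their predictions);
5. per requested fusion model: variable selection / PCA reduction /
   concatenation, SVR grid search, metrics;
6. one metrics row per model, plus JSON artifacts and a run log.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import fusion as fu
from . import imaging, modeling, selection
from .pls import PLSSettings
from .preprocess import snv_transform
from .synthetic import SyntheticConfig, generate_dataset, spectra_block_from_samples

logger = logging.getLogger(__name__)

ALL_MODELS = ("nir", "mv", "low", "mid-pca", "mid-cars", "mid-vcpa-iriv", "mid-vissa", "high")

_LEVELS = {
    "nir": ("Single", "NIR"),
    "mv": ("Single", "MV"),
    "low": ("Low-level", ""),
    "mid-pca": ("Middle-level", "PCA"),
    "mid-cars": ("Middle-level", "CARS"),
    "mid-vcpa-iriv": ("Middle-level", "VCPA-IRIV"),
    "mid-vissa": ("Middle-level", "VISSA"),
    "high": ("High-level", "MLR"),
}


@dataclass
class ExperimentConfig:
    seed: int = 0
    synthetic: SyntheticConfig | None = None
    models: tuple[str, ...] = ALL_MODELS
    split_ratio: float = 0.75
    split_method: str = "stratified"
    screening_cutoff: float = 0.6
    # sub-model counts sized for a desk-scale run; fully configurable
    cars_runs: int = 50
    cars_folds: int = 5
    vissa_submodels: int = 150
    vissa_best_fraction: float = 0.05
    vissa_max_lv: int = 15
    vissa_folds: int = 5
    vcpa_edf_runs: int = 30
    vcpa_bms_submodels: int = 100
    vcpa_cv_groups: int = 10
    vcpa_max_lv: int = 5
    pca_n_max: int = 18
    svr_grid_step: int = 2
    outdir: str | None = None

    def __post_init__(self) -> None:
        if self.synthetic is None:
            self.synthetic = SyntheticConfig(seed=self.seed)
        unknown = set(self.models) - set(ALL_MODELS)
        if unknown:
            raise ValueError(f"unknown model(s) {sorted(unknown)}")
        if not self.models:
            raise ValueError("at least one model must be requested")


def load_config(path: str | Path) -> ExperimentConfig:
    """Read an ExperimentConfig from YAML (keys match field names)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    syn = raw.pop("synthetic", None)
    cfg = ExperimentConfig(**{k: tuple(v) if k == "models" else v for k, v in raw.items()})
    if syn is not None:
        cfg.synthetic = SyntheticConfig(**syn)
        cfg.synthetic = replace(cfg.synthetic, seed=syn.get("seed", cfg.seed))
    return cfg


def _extract_image_features(samples) -> np.ndarray:
    rows = []
    for s in samples:
        if s.image_features is not None:
            rows.append(np.asarray(s.image_features, dtype=float))
        elif s.image is not None:
            rows.append(imaging.extract_features(s.image, s.mask))
        else:
            raise ValueError(f"sample {s.sample_id} has neither image nor features")
    return np.vstack(rows)


def _fit_model(name, X, y, split, seed, grid_step):
    cal, pred = split.calibration, split.prediction
    params = modeling.grid_search_svr(X[cal], y[cal], cv_folds=5, seed=seed,
                                      grid=modeling.default_svr_grid(step=grid_step))
    yhat_cal = modeling.train_predict_svr(X[cal], y[cal], X[cal], params)
    yhat_pred = modeling.train_predict_svr(X[cal], y[cal], X[pred], params)
    metrics = modeling.evaluate_metrics(y[cal], yhat_cal, y[pred], yhat_pred,
                                        params=params, n_variables=X.shape[1])
    return metrics, yhat_cal, yhat_pred


def run_experiment(config: ExperimentConfig):
    """Execute the requested model grid; returns (metrics DataFrame, artifacts).

    The artifacts dict holds the split, screening report, selection
    results, fused blocks and the stacking model, so every metrics.csv
    number is recomputable from persisted intermediates.
    """
    seeds = np.random.SeedSequence(config.seed).generate_state(8) % (2**31 - 1)
    log_lines = [f"experiment seed {config.seed}", f"models {list(config.models)}"]

    # --- data ---------------------------------------------------------
    syn = replace(config.synthetic, seed=int(config.synthetic.seed))
    samples, truth = generate_dataset(syn)
    y = np.array([s.mc for s in samples])
    strata = np.array([s.time_h for s in samples])
    block = snv_transform(spectra_block_from_samples(samples, syn))
    img_raw = _extract_image_features(samples)

    split = modeling.split_dataset(
        len(samples), strata=strata, ratio=config.split_ratio,
        method=config.split_method, seed=int(seeds[0]),
    )
    cal, pred = split.calibration, split.prediction
    log_lines.append(f"split: {cal.size} calibration / {pred.size} prediction")

    img_norm, *_ = imaging.minmax_normalize(img_raw, cal)
    screening = imaging.pearson_screen(
        img_norm[cal], y[cal], cutoff=config.screening_cutoff,
        feature_names=imaging.FEATURE_NAMES,
    )
    img_screened = img_norm[:, screening.retained]
    log_lines.append(
        f"screening: {screening.n_retained}/18 image features retained at "
        f"|r| >= {config.screening_cutoff}"
    )

    X_nir = block.absorbance
    artifacts: dict = {"split": split, "screening": screening, "ground_truth": truth,
                       "selection": {}, "fused": {}, "predictions": {}}
    rows = []
    results: dict[str, modeling.RegressionMetrics] = {}

    def record(name, metrics):
        results[name] = metrics
        level, method = _LEVELS[name]
        rows.append({"level": level, "method": method, **metrics.as_row()})

    # --- single sensors (always: the high level consumes them) -------
    m_nir, nir_cal, nir_pred = _fit_model("nir", X_nir, y, split, int(seeds[1]),
                                          config.svr_grid_step)
    record("nir", m_nir)
    m_mv, mv_cal, mv_pred = _fit_model("mv", img_norm, y, split, int(seeds[2]),
                                       config.svr_grid_step)
    record("mv", m_mv)
    artifacts["predictions"] = {"nir": (nir_cal, nir_pred), "mv": (mv_cal, mv_pred)}

    if "low" in config.models:
        fused = fu.low_level_fuse([X_nir, img_norm],
                                  sample_ids=[block.sample_ids, block.sample_ids],
                                  sensors=["nir", "mv"])
        artifacts["fused"]["low"] = fused
        m, *_ = _fit_model("low", fused.matrix, y, split, int(seeds[3]),
                           config.svr_grid_step)
        record("low", m)

    if "mid-pca" in config.models:
        n_max = min(config.pca_n_max, cal.size - 1)
        sc_cal, _, _, sc_all = fu.pca_reduce_block(X_nir[cal], n_max, X_nir)
        ic_cal, _, _, ic_all = fu.pca_reduce_block(
            img_norm[cal], min(n_max, img_norm.shape[1]), img_norm)
        k_spec, _ = fu.select_optimal_pcs(sc_cal, y[cal], sc_all[pred], y[pred], n_max)
        k_img, _ = fu.select_optimal_pcs(ic_cal, y[cal], ic_all[pred], y[pred],
                                         min(n_max, img_norm.shape[1]))
        log_lines.append(f"mid-pca: {k_spec} spectral + {k_img} image PCs")
        fused = fu.mid_level_fuse(sc_all[:, :k_spec], ic_all[:, :k_img], "pca")
        artifacts["fused"]["mid-pca"] = fused
        m, *_ = _fit_model("mid-pca", fused.matrix, y, split, int(seeds[4]),
                           config.svr_grid_step)
        record("mid-pca", m)

    sel_requested = [m for m in ("mid-cars", "mid-vcpa-iriv", "mid-vissa")
                     if m in config.models]
    for name in sel_requested:
        if name == "mid-cars":
            sel = selection.cars_select(
                X_nir[cal], y[cal], n_runs=config.cars_runs,
                cv_folds=config.cars_folds, seed=int(seeds[5]))
        elif name == "mid-vissa":
            sel = selection.vissa_select(
                X_nir[cal], y[cal],
                settings=PLSSettings(config.vissa_max_lv, config.vissa_folds),
                seed=int(seeds[6]), n_submodels=config.vissa_submodels,
                best_fraction=config.vissa_best_fraction)
        else:
            sel = selection.vcpa_iriv_select(
                X_nir[cal], y[cal],
                settings=PLSSettings(config.vcpa_max_lv, config.vcpa_cv_groups),
                seed=int(seeds[7]), edf_runs=config.vcpa_edf_runs,
                bms_submodels=config.vcpa_bms_submodels)
        artifacts["selection"][sel.method] = sel
        log_lines.append(
            f"{sel.method}: {sel.n_selected}/{sel.n_original} channels, "
            f"compression rate {sel.compression_rate}%")
        fused = fu.mid_level_fuse(
            X_nir[:, sel.selected_indices], img_screened, name.removeprefix("mid-"),
            spec_provenance=[("nir", "channel", int(j)) for j in sel.selected_indices],
            img_provenance=[("mv", "feature", int(j)) for j in screening.retained_indices])
        artifacts["fused"][name] = fused
        fit_seed = int(np.random.SeedSequence(
            [config.seed, ALL_MODELS.index(name)]).generate_state(1)[0] % (2**31 - 1))
        m, *_ = _fit_model(name, fused.matrix, y, split, fit_seed, config.svr_grid_step)
        record(name, m)

    if "high" in config.models:
        stack = fu.high_level_fit(np.column_stack([nir_cal, mv_cal]), y[cal],
                                  sensor_order=("nir", "mv"))
        yhat_cal = fu.high_level_predict(stack, np.column_stack([nir_cal, mv_cal]))
        yhat_pred = fu.high_level_predict(stack, np.column_stack([nir_pred, mv_pred]))
        metrics = modeling.evaluate_metrics(y[cal], yhat_cal, y[pred], yhat_pred,
                                            n_variables=2)
        artifacts["stacking"] = stack
        log_lines.append(
            "stacking: y = "
            + " + ".join(f"{k:.5f}*x{i + 1}" for i, k in enumerate(stack.coefficients))
            + f" {stack.intercept:+.5f}")
        record("high", metrics)

    table = pd.DataFrame(rows)
    artifacts["log"] = log_lines
    if config.outdir:
        _write_artifacts(Path(config.outdir), config, table, artifacts)
    return table, artifacts


def _write_artifacts(outdir: Path, config, table, artifacts) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    table.to_csv(outdir / "metrics.csv", index=False)
    for sel in artifacts["selection"].values():
        with open(outdir / f"selection_{sel.method}.json", "w") as fh:
            json.dump(
                {
                    "method": sel.method,
                    "selected_indices": sel.selected_indices.tolist(),
                    "n_original": sel.n_original,
                    "n_selected": sel.n_selected,
                    "compression_rate": sel.compression_rate,
                    "rmsecv_trace": [float(v) for v in sel.rmsecv_trace],
                    "seed": sel.seed,
                    "settings": sel.settings,
                },
                fh, indent=2)
    for name, fused in artifacts["fused"].items():
        with open(outdir / f"fusion_{name}.json", "w") as fh:
            json.dump({"level": fused.level, "n_fused": fused.n_fused,
                       "provenance": [list(t) for t in fused.provenance]}, fh)
    if "stacking" in artifacts:
        stack = artifacts["stacking"]
        with open(outdir / "stacking.json", "w") as fh:
            json.dump({"k": stack.coefficients.tolist(), "b": stack.intercept,
                       "sensor_order": list(stack.sensor_order)}, fh, indent=2)
    scr = artifacts["screening"]
    with open(outdir / "screening.json", "w") as fh:
        json.dump(
            {
                "cutoff": scr.cutoff,
                "feature_names": list(scr.feature_names or []),
                "r": [None if np.isnan(v) else float(v) for v in scr.r],
                "p_value": [None if np.isnan(v) else float(v) for v in scr.p_value],
                "retained": scr.retained.astype(bool).tolist(),
            },
            fh, indent=2)
    cfg = asdict(config)  # json renders nested tuples as lists
    with open(outdir / "run.log", "w") as fh:
        fh.write("\n".join(artifacts["log"]) + "\n")
        fh.write(f"config: {json.dumps(cfg)}\n")
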