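"""Single-config, seeded pipeline: simulate -> calibrate -> segment -> patch
-> split -> preprocess -> (select) -> train -> evaluate.

`run_pipeline` chains every stage of the freshness-assessment workflow on a
synthetic study bundle and returns per-target fit reports.  All randomness
flows from the master seed through named substreams; the configuration hash
and seed are stamped into every artifact so a run is exactly reproducible.
Stage products can be persisted to an artifact directory; a rerun that finds
a patch bank with a matching config hash resumes from it instead of
regenerating cubes.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import warnings
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from salmonhsi import synthetic
from salmonhsi.evaluation import (
    DEFAULT_MRE_INTERVALS, FitReport, evaluate_split, mre_in_interval,
)
from salmonhsi.hypercube import radiometric_calibrate
from salmonhsi.models import (
    TrainingProtocol, TransformerConfig, mlr_fit, patches_to_tokens,
    plsr_fit, train, transformer_build, MLPRegressor,
)
from salmonhsi.preprocessing import Preprocessor, SpectraMatrix, screen_protocols
from salmonhsi.segmentation import (
    extract_patches, mean_grayscale, morphological_open, split_by_sample,
    threshold_segment,
)
from salmonhsi.selection import (
    ga_select, lasso_select, random_frog_select, spa_select,
)

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "STAGES"]

log = logging.getLogger("salmonhsi.pipeline")

STAGES = ("simulate", "calibrate", "segment", "patch", "preprocess",
          "select", "train", "evaluate")

_SELECTORS = {"spa": spa_select, "lasso": lasso_select, "ga": ga_select,
              "random_frog": random_frog_select}


@dataclass
class RunConfig:
    """Everything a run needs; YAML-serialisable; hashed into artifacts.

    Defaults are the desk-scale configuration: a reduced 2 temperatures x
    8 days x 3 replicates design, 16x16 token grid and a narrow (d_model 32)
    Transformer — the full-study geometry is reached by overriding the
    design, ``token_grid`` and ``transformer`` fields.
    """

    design: synthetic.StudyDesign = field(
        default_factory=lambda: synthetic.StudyDesign(
            replicates=3, image_shape=(80, 160)))
    threshold: float = 10.0            # percent reflectance
    window: int = 64
    max_bg_fraction: float = 0.05
    preprocess_method: str = "sg"
    preprocess_params: dict = field(default_factory=dict)
    selector: str | None = None
    selector_params: dict = field(default_factory=dict)
    token_grid: tuple[int, int] = (16, 16)
    model: str = "transformer"         # {transformer, mlp, mlr, plsr}
    transformer: dict = field(default_factory=lambda: dict(
        d_model=32, n_layers=3, n_heads=8, dropout=0.1))
    protocol: TrainingProtocol = field(default_factory=lambda: TrainingProtocol(
        lr=1e-3, weight_decay=1e-3, max_epochs=60, batch_size=8,
        scheduler_patience=10))
    targets: tuple[str, ...] = ("tvbn", "tvc")
    split_ratios: tuple[float, float, float] = (0.70, 0.15, 0.15)
    stratify_split: bool = True        # spread design cells over the splits
    mre_intervals: dict = field(default_factory=lambda: dict(DEFAULT_MRE_INTERVALS))
    seed: int = 0
    out_dir: str | None = None

    def to_dict(self) -> dict:
        d = asdict(self)
        d["design"] = asdict(self.design)
        d["protocol"] = asdict(self.protocol)
        return d

    def config_hash(self) -> str:
        payload = yaml.safe_dump(_jsonable(self.to_dict()), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


@dataclass
class PatchBank:
    """Model-facing dataset: token sequences with labels and split tags."""

    tokens: np.ndarray                 # N x T x B float32
    mean_spectra: np.ndarray           # N x B
    labels: pd.DataFrame               # per patch: sample_id, side, origin, tvbn, tvc
    wavelengths_nm: np.ndarray
    split: dict                        # sample_id -> split

    def rows(self, split_name: str) -> np.ndarray:
        tags = self.labels.sample_id.map(self.split)
        return np.flatnonzero((tags == split_name).to_numpy())


@dataclass
class PipelineResult:
    config: RunConfig
    config_hash: str
    reports: dict                      # target -> FitReport
    table: pd.DataFrame
    subsets: dict                      # target -> WavelengthSubset | None
    models: dict                       # target -> trained model
    bank: PatchBank
    timings: dict


# ----------------------------------------------------------------- stages

def _build_patch_bank(config: RunConfig, rng: np.random.Generator) -> PatchBank:
    bundle = synthetic.generate_experiment(config.design, seed=config.seed)
    tokens, spectra, rows = [], [], []
    for i in range(bundle.n_cubes):
        raw, refs, _ = bundle.load_cube(i)
        cube = radiometric_calibrate(raw, refs)
        mask = morphological_open(
            threshold_segment(mean_grayscale(cube), config.threshold))
        lab = bundle.labels_for(cube.sample_id)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            patches = extract_patches(cube, mask, lab, config.window,
                                      config.max_bg_fraction)
        for p in patches:
            tok = patches_to_tokens(p.data[None].astype(np.float32),
                                    config.token_grid)[0]
            tokens.append(tok)
            spectra.append(tok.mean(axis=0))
            rows.append({"sample_id": p.sample_id, "side": p.side,
                         "origin_row": p.origin[0], "origin_col": p.origin[1],
                         "tvbn": lab.tvbn, "tvc": lab.tvc,
                         "temperature_c": lab.temperature_c, "day": lab.day})
    if not tokens:
        raise RuntimeError("patch stage produced no patches")
    labels = pd.DataFrame(rows)
    strata = None
    if config.stratify_split:
        strata = {r.sample_id: (r.temperature_c, r.day)
                  for r in labels.itertuples()}
    split = split_by_sample(labels.sample_id, config.split_ratios,
                            seed=int(rng.integers(2 ** 31)),
                            stratify_by=strata)
    return PatchBank(np.stack(tokens), np.stack(spectra), labels,
                     bundle.wavelengths_nm, dict(split.mapping))


def _preprocess_bank(bank: PatchBank, config: RunConfig) -> PatchBank:
    n, t, b = bank.tokens.shape
    train_rows = bank.rows("train")
    flat_train = bank.tokens[train_rows].reshape(-1, b)
    prep = Preprocessor(config.preprocess_method, **config.preprocess_params)
    prep.fit(SpectraMatrix(flat_train, bank.wavelengths_nm))
    flat_all = SpectraMatrix(bank.tokens.reshape(-1, b), bank.wavelengths_nm)
    tokens = prep.transform(flat_all).values.reshape(n, t, b).astype(np.float32)
    return PatchBank(tokens, tokens.mean(axis=1), bank.labels,
                     bank.wavelengths_nm, bank.split)


def _select_bands(bank: PatchBank, config: RunConfig, target: str,
                  rng: np.random.Generator):
    if config.selector is None:
        return None
    fn = _SELECTORS.get(config.selector)
    if fn is None:
        raise ValueError(f"unknown selector {config.selector!r}")
    tr = bank.rows("train")
    X = bank.mean_spectra[tr]
    y = bank.labels[target].to_numpy()[tr]
    groups = bank.labels.sample_id.to_numpy()[tr]
    params = dict(config.selector_params)
    params.setdefault("wavelengths_nm", bank.wavelengths_nm)
    if config.selector != "spa":
        params.setdefault("groups", groups)
        params.setdefault("seed", int(rng.integers(2 ** 31)))
    return fn(X, y, **params)


def _standardise(X: np.ndarray, train_rows: np.ndarray):
    """Per-band z-scoring with training-split statistics (leakage-free)."""
    flat = X[train_rows].reshape(-1, X.shape[-1])
    mu = flat.mean(axis=0)
    sd = flat.std(axis=0) + 1e-8
    return ((X - mu) / sd).astype(np.float32), mu, sd


def _fit_target(bank: PatchBank, config: RunConfig, target: str, subset,
                seed: int):
    band_sel = slice(None) if subset is None else subset.band_indices
    y = bank.labels[target].to_numpy()
    tr, va = bank.rows("train"), bank.rows("validation")
    if config.model == "transformer":
        X, mu, sd = _standardise(bank.tokens[:, :, band_sel], tr)
        cfg = TransformerConfig(
            n_tokens=X.shape[1], n_bands_in=X.shape[2], **config.transformer)
        model = transformer_build(cfg, seed=seed)
        train(model, (X[tr], y[tr]), (X[va], y[va]),
              replace(config.protocol, seed=seed))
        model.provenance.update({"band_mean": mu, "band_std": sd})
    elif config.model == "mlp":
        X, mu, sd = _standardise(bank.mean_spectra[:, band_sel], tr)
        model = MLPRegressor(X.shape[1], seed=seed)
        train(model, (X[tr], y[tr]), (X[va], y[va]),
              replace(config.protocol, seed=seed))
        model.provenance.update({"band_mean": mu, "band_std": sd})
    elif config.model == "mlr":
        X = bank.mean_spectra[:, band_sel]
        model = mlr_fit(X[tr], y[tr])
    elif config.model == "plsr":
        X = bank.mean_spectra[:, band_sel]
        model = plsr_fit(X[tr], y[tr],
                         cv_groups=bank.labels.sample_id.to_numpy()[tr])
    else:
        raise ValueError(f"unknown model kind {config.model!r}")
    model.provenance = getattr(model, "provenance", {})
    model.provenance.update({
        "preprocessing": (config.preprocess_method, config.preprocess_params),
        "subset": subset, "target": target,
    })
    return model, X


def _evaluate_target(bank: PatchBank, config: RunConfig, target: str,
                     model, X) -> FitReport:
    y = bank.labels[target].to_numpy()
    per_split, per_fillet = {}, {}
    mre_list = []
    for split_name in ("train", "validation", "prediction"):
        idx = bank.rows(split_name)
        yhat = model.predict(X[idx])
        try:
            per_split[split_name] = evaluate_split(y[idx], yhat)
        except ValueError:          # degenerate split (constant labels)
            per_split[split_name] = {"r2": float("nan"),
                                     "rmse": float(np.sqrt(np.mean(
                                         (y[idx] - yhat) ** 2))),
                                     "n": int(len(idx))}
        sid = bank.labels.sample_id.to_numpy()[idx]
        fr = pd.DataFrame({"sid": sid, "y": y[idx], "yhat": yhat}).groupby("sid").mean()
        if len(fr) >= 2 and fr["y"].std() > 0:
            per_fillet[split_name] = evaluate_split(fr["y"], fr["yhat"])
        if split_name == "prediction" and target in config.mre_intervals:
            lo, hi = config.mre_intervals[target]
            try:
                mre_list.append((lo, hi, mre_in_interval(y[idx], yhat, lo, hi)))
            except ValueError:
                pass
    return FitReport(target, per_split, mre_list, None, per_fillet)


# ----------------------------------------------------------------- driver

def run_pipeline(config: RunConfig, until: str = "evaluate") -> PipelineResult:
    """Execute the pipeline through ``until`` (a stage name) and report.

    Identical config + seed give identical results.  When ``config.out_dir``
    is set, stage artifacts (patch bank, subsets, history, report) are
    written there, stamped with the config hash; an existing patch bank with
    a matching hash short-circuits the simulate/segment/patch stages.
    """
    if until not in STAGES:
        raise ValueError(f"unknown stage {until!r}")
    chash = config.config_hash()
    rng = np.random.default_rng([config.seed, 0xC0FFEE])
    split_rng = np.random.default_rng([config.seed, 1])
    select_rng = np.random.default_rng([config.seed, 2])
    timings: dict[str, float] = {}
    out = Path(config.out_dir) if config.out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)
        (out / "config.yaml").write_text(
            yaml.safe_dump(_jsonable(config.to_dict()), sort_keys=True))

    t0 = time.time()
    bank = None
    bank_path = out / "patch_bank.h5" if out else None
    if bank_path and bank_path.exists():
        bank = _load_bank(bank_path, chash)
        if bank is not None:
            log.info("resumed patch bank from %s", bank_path)
    if bank is None:
        bank = _build_patch_bank(config, split_rng)
        if bank_path:
            _save_bank(bank, bank_path, chash)
    timings["simulate+segment+patch"] = time.time() - t0
    log.info("patch bank: %d patches, %d samples [%.1fs]",
             len(bank.labels), len(set(bank.labels.sample_id)),
             timings["simulate+segment+patch"])
    if until in ("simulate", "calibrate", "segment", "patch"):
        return PipelineResult(config, chash, {}, pd.DataFrame(), {}, {}, bank, timings)

    t0 = time.time()
    bank = _preprocess_bank(bank, config)
    timings["preprocess"] = time.time() - t0
    if until == "preprocess":
        return PipelineResult(config, chash, {}, pd.DataFrame(), {}, {}, bank, timings)

    subsets, models, reports = {}, {}, {}
    rows = []
    for target in config.targets:
        t0 = time.time()
        subset = _select_bands(bank, config, target, select_rng)
        timings[f"select:{target}"] = time.time() - t0
        subsets[target] = subset
        if out and subset is not None:
            pd.DataFrame({
                "band_index": subset.band_indices,
                "wavelength_nm": (subset.wavelengths_nm
                                  if subset.wavelengths_nm is not None
                                  else np.full(subset.size, np.nan)),
            }).to_csv(out / f"subset_{target}.csv", index=False)
        if until == "select":
            continue
        t0 = time.time()
        model, X = _fit_target(bank, config, target, subset,
                               seed=int(rng.integers(2 ** 31)))
        timings[f"train:{target}"] = time.time() - t0
        models[target] = model
        if out and getattr(model, "history", None):
            pd.DataFrame(model.history).to_csv(
                out / f"history_{target}.csv", index=False)
        if until == "train":
            continue
        reports[target] = _evaluate_target(bank, config, target, model, X)
        for split_name, m in reports[target].per_split.items():
            rows.append({"target": target, "model": config.model,
                         "preprocessing": config.preprocess_method,
                         "selector": config.selector or "none",
                         "n_bands": (bank.tokens.shape[2] if subset is None
                                     else subset.size),
                         "split": split_name, **m})
    table = pd.DataFrame(rows)
    if out is not None and not table.empty:
        table.assign(config_hash=chash, seed=config.seed).to_csv(
            out / "report.csv", index=False)
        (out / "report.json").write_text(json.dumps(_jsonable({
            "config_hash": chash, "seed": config.seed,
            "reports": {t: {"per_split": r.per_split,
                            "mre_by_interval": r.mre_by_interval,
                            "per_fillet": r.per_fillet}
                        for t, r in reports.items()},
            "timings": timings,
        }), indent=1, default=float))
    return PipelineResult(config, chash, reports, table, subsets, models,
                          bank, timings)


def screen_bank(bank: PatchBank, methods=None) -> pd.DataFrame:
    """Preprocessing screening on the training-split patch mean spectra."""
    from salmonhsi.preprocessing import PREPROCESS_METHODS
    tr = bank.rows("train")
    sm = SpectraMatrix(bank.mean_spectra[tr], bank.wavelengths_nm)
    return screen_protocols(sm, methods or PREPROCESS_METHODS)


# ----------------------------------------------------------------- storage

def _save_bank(bank: PatchBank, path: Path, chash: str) -> None:
    with h5py.File(path, "w") as h:
        h.create_dataset("patches", data=bank.tokens, compression="gzip")
        h.create_dataset("mean_spectra", data=bank.mean_spectra)
        h.create_dataset("wavelengths", data=bank.wavelengths_nm)
        h.create_dataset("origins", data=bank.labels[
            ["origin_row", "origin_col"]].to_numpy())
        h.create_dataset("sample_ids", data=bank.labels.sample_id.to_numpy(
            dtype="S32"))
        h.create_dataset("labels", data=bank.labels[
            ["tvbn", "tvc", "temperature_c", "day"]].to_numpy())
        h.create_dataset("split", data=np.array(
            [bank.split[s] for s in bank.labels.sample_id], dtype="S16"))
        h.attrs["config_hash"] = chash
        h.attrs["sides"] = json.dumps(list(bank.labels.side))


def _load_bank(path: Path, chash: str) -> PatchBank | None:
    with h5py.File(path, "r") as h:
        if h.attrs.get("config_hash") != chash:
            return None
        sids = [s.decode() for s in h["sample_ids"][()]]
        labs = h["labels"][()]
        origins = h["origins"][()]
        labels = pd.DataFrame({
            "sample_id": sids,
            "side": json.loads(h.attrs["sides"]),
            "origin_row": origins[:, 0], "origin_col": origins[:, 1],
            "tvbn": labs[:, 0], "tvc": labs[:, 1],
            "temperature_c": labs[:, 2].astype(int),
            "day": labs[:, 3].astype(int),
        })
        split = {s: sp.decode() for s, sp in zip(sids, h["split"][()])}
        return PatchBank(h["patches"][()], h["mean_spectra"][()], labels,
                         h["wavelengths"][()], split)
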