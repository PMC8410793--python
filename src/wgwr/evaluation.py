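"""Validation protocol: 70/30 split, metrics, AICc comparison, full pipeline.

Models are trained on a seeded random 70% of the samples and evaluated on
the held-out 30%. Metrics (R^2 as 1 - SSE/SST, MAE, RMSE) are computed on
the back-transformed scale whenever the property was transformed before
modelling. Models are further compared by their training-fit AICc through
the relative likelihood eta_j = exp((AICc_min - AICc_j)/2), and by pairwise
percent changes in test R^2 and RMSE.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from . import baselines, gwr, mra, selection, spectra, synthgen

__all__ = [
    "SplitSpec",
    "Metrics",
    "EvaluationReport",
    "split",
    "metrics",
    "relative_likelihood",
    "percent_change",
    "run_pipeline",
    "PipelineConfig",
]


@dataclass(frozen=True)
class SplitSpec:
    """Seeded random partition of samples into training and testing sets."""

    train_idx: np.ndarray
    test_idx: np.ndarray
    fraction: float
    seed: int

    @property
    def n(self) -> int:
        return self.train_idx.size + self.test_idx.size


def split(n: int, fraction: float = 0.7, seed: int = 0) -> SplitSpec:
    """Uniform random train/test partition without stratification."""
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie strictly between 0 and 1")
    if n < 10:
        raise ValueError("need at least 10 samples to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = int(round(fraction * n))
    return SplitSpec(
        train_idx=np.sort(perm[:n_train]),
        test_idx=np.sort(perm[n_train:]),
        fraction=fraction,
        seed=seed,
    )


@dataclass(frozen=True)
class Metrics:
    r2: float
    mae: float
    rmse: float

    def as_dict(self) -> dict:
        return {"r2": self.r2, "mae": self.mae, "rmse": self.rmse}


def metrics(observed, predicted) -> Metrics:
    """R^2 = 1 - SSE/SST (coefficient of determination), MAE and RMSE."""
    o = np.asarray(observed, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if o.shape != p.shape or o.size < 2:
        raise ValueError("observed and predicted must share a length >= 2")
    sst = np.sum((o - o.mean()) ** 2)
    if sst == 0:
        raise ValueError("observed values are constant; R^2 undefined")
    err = o - p
    return Metrics(
        r2=float(1.0 - np.sum(err ** 2) / sst),
        mae=float(np.mean(np.abs(err))),
        rmse=float(np.sqrt(np.mean(err ** 2))),
    )


def relative_likelihood(aicc_values) -> np.ndarray:
    """eta_j = exp((AICc_min - AICc_j) / 2); the best model gets eta = 1."""
    a = np.asarray(aicc_values, dtype=float)
    if not np.all(np.isfinite(a)):
        raise ValueError("AICc values must be finite")
    return np.exp((a.min() - a) / 2.0)


def percent_change(reference: float, comparison: float, mode: str = "increase") -> float:
    """Percent increase of ``comparison`` over ``reference`` (or reduction)."""
    if reference == 0:
        raise ValueError("reference value is zero")
    if mode == "increase":
        return 100.0 * (comparison - reference) / reference
    if mode == "reduction":
        return 100.0 * (reference - comparison) / reference
    raise ValueError(f"unknown mode {mode!r}")


@dataclass
class PipelineConfig:
    """Everything needed to run the full workflow reproducibly.

    Exactly one of ``preset``/``synthetic_spec``/(``spectra_path`` +
    ``property_path``) identifies the data source.
    """

    preset: str | None = None
    synthetic_spec: "synthgen.SyntheticSpec | None" = None
    spectra_path: str | None = None
    property_path: str | None = None
    delimiter: str = ","
    property_name: str | None = None
    depth_average: bool = False
    log_transform: bool = False
    outlier_k: float | None = None
    vanishing_moments: int = 4
    levels: int = 6
    vif_threshold: float = 10.0
    cv_folds: int = 10
    max_features: int | None = 40
    kernel: str = "gaussian"
    q_range: tuple | None = None
    plsr_input: str = "spectra"          # or "wavelets"
    plsr_max_components: int = 20
    split_fraction: float = 0.7
    n_perm: int = 0                      # >0 runs the non-stationarity test
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d)
        if isinstance(cfg.q_range, list):
            cfg.q_range = tuple(cfg.q_range)
        return cfg


@dataclass
class EvaluationReport:
    """Per-model train/test metrics plus AICc, eta and percent changes."""

    models: dict
    aicc: dict
    eta: dict
    percent_changes: dict
    selection: dict
    gwr_summary: dict
    nonstationarity: dict | None
    split_info: dict
    seed: int

    def to_dict(self) -> dict:
        return {
            "models": self.models,
            "aicc": self.aicc,
            "eta": self.eta,
            "percent_changes": self.percent_changes,
            "selection": self.selection,
            "gwr": self.gwr_summary,
            "nonstationarity": self.nonstationarity,
            "split": self.split_info,
            "seed": self.seed,
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent, sort_keys=True)


def _load_data(cfg: PipelineConfig, seed: int):
    if cfg.preset is not None:
        spec = synthgen.benchmark_configs()[cfg.preset]
        ds = synthgen.generate(spec, seed=seed)
        return ds.library, ds.properties, spec.property_name
    if cfg.synthetic_spec is not None:
        ds = synthgen.generate(cfg.synthetic_spec, seed=seed)
        return ds.library, ds.properties, cfg.synthetic_spec.property_name
    if cfg.spectra_path is None or cfg.property_path is None:
        raise ValueError("config must name a preset, a synthetic spec, or data files")
    lib = spectra.read_spectral_library(cfg.spectra_path, delimiter=cfg.delimiter)
    table = spectra.read_property_table(cfg.property_path, delimiter=cfg.delimiter)
    if cfg.depth_average or table.has_depths:
        table = spectra.depth_weighted_average(table)
    prop = cfg.property_name or table.property_names[0]
    # align property rows to library sample order
    df = table.data.set_index("id").loc[[str(s) for s in lib.sample_ids]].reset_index()
    table = spectra.PropertyTable(data=df, property_names=table.property_names)
    return lib, table, prop


def run_pipeline(config, seed: int | None = None) -> EvaluationReport:
    """Preprocess, decompose, select (train only), fit WGWR/WLR/PLSR, evaluate.

    Fully reproducible from (config, seed): rerunning yields byte-identical
    report JSON.
    """
    cfg = config if isinstance(config, PipelineConfig) else PipelineConfig.from_dict(dict(config))
    seed = cfg.seed if seed is None else seed

    lib, table, prop = _load_data(cfg, seed)
    y_raw = table.values(prop)
    locs = table.locations()

    if cfg.outlier_k is not None:
        kept, _ = spectra.remove_outliers(y_raw, k=cfg.outlier_k)
        idx = np.flatnonzero(kept)
        lib = spectra.SpectralLibrary(
            lib.wavelengths, lib.spectra[idx],
            [lib.sample_ids[i] for i in idx], mode=lib.mode,
            x=None if lib.x is None else lib.x[idx],
            y=None if lib.y is None else lib.y[idx],
        )
        y_raw, locs = y_raw[idx], locs[idx]

    y_model = spectra.log_transform(y_raw) if cfg.log_transform else y_raw
    back = spectra.back_transform if cfg.log_transform else (lambda v: np.asarray(v, float))

    ab = spectra.to_absorbance(lib) if lib.mode == "reflectance" else lib
    sp = split(ab.n_samples, fraction=cfg.split_fraction, seed=seed)
    tr, te = sp.train_idx, sp.test_idx

    wspec = mra.WaveletSpec(vanishing_moments=cfg.vanishing_moments, levels=cfg.levels)
    fm = mra.decompose_library(ab, wspec)

    sel = selection.select_features(
        fm.values[tr], y_model[tr], threshold=cfg.vif_threshold,
        folds=cfg.cv_folds, seed=seed, max_features=cfg.max_features,
    )
    # re-attach scale/wavelength labels (selection saw a bare matrix)
    sel_feats = [
        selection.RankedFeature(f.column, *fm.scale_of(f.column), f.abs_corr, f.rank)
        for f in sel.selected
    ]
    cols = [f.column for f in sel_feats]
    Xsel = fm.values[:, cols]

    # --- WGWR ---
    Xg = np.column_stack([np.ones(tr.size), Xsel[tr]])
    q_opt, _ = gwr.optimize_bandwidth(Xg, y_model[tr], locs[tr],
                                      q_range=cfg.q_range, kernel=cfg.kernel)
    gmodel = gwr.fit_gwr(Xg, y_model[tr], locs[tr], q_opt, kernel=cfg.kernel)
    pred_gwr_tr = gmodel.fitted
    pred_gwr_te = gwr.predict(gmodel, np.column_stack([np.ones(te.size), Xsel[te]]),
                              locs[te])

    # --- WLR ---
    wlr = baselines.fit_wlr(Xsel[tr], y_model[tr], columns=cols)
    pred_wlr_tr = wlr.fitted
    pred_wlr_te = wlr.predict(Xsel[te])

    # --- PLSR ---
    Xpls = ab.spectra if cfg.plsr_input == "spectra" else fm.values
    pls = baselines.fit_plsr(Xpls[tr], y_model[tr],
                             max_components=cfg.plsr_max_components,
                             folds=cfg.cv_folds, seed=seed)
    pred_pls_tr = baselines.predict_plsr(pls, Xpls[tr])
    pred_pls_te = baselines.predict_plsr(pls, Xpls[te])
    rss_pls = float(np.sum((y_model[tr] - pred_pls_tr) ** 2))

    obs_tr, obs_te = back(y_model[tr]), back(y_model[te])
    models = {}
    for name, (ptr, pte) in {
        "PLSR": (pred_pls_tr, pred_pls_te),
        "WLR": (pred_wlr_tr, pred_wlr_te),
        "WGWR": (pred_gwr_tr, pred_gwr_te),
    }.items():
        models[name] = {
            "training": metrics(obs_tr, back(ptr)).as_dict(),
            "testing": metrics(obs_te, back(pte)).as_dict(),
        }

    aicc = {
        "PLSR": baselines.linear_aicc(tr.size, rss_pls, pls.n_components),
        "WLR": wlr.aicc,
        "WGWR": gmodel.aicc,
    }
    eta_vals = relative_likelihood(list(aicc.values()))
    eta = {k: float(v) for k, v in zip(aicc, eta_vals)}

    pct = {}
    for ref, comp in (("PLSR", "WLR"), ("WLR", "WGWR"), ("PLSR", "WGWR")):
        pct[f"{ref}_to_{comp}"] = {
            "test_r2_increase": round(percent_change(
                models[ref]["testing"]["r2"], models[comp]["testing"]["r2"],
                "increase"), 1),
            "test_rmse_reduction": round(percent_change(
                models[ref]["testing"]["rmse"], models[comp]["testing"]["rmse"],
                "reduction"), 1),
        }

    nonstat = None
    if cfg.n_perm > 0:
        t = gwr.montecarlo_nonstationarity_test(
            Xg, y_model[tr], locs[tr], q_opt, n_perm=cfg.n_perm,
            seed=seed, kernel=cfg.kernel)
        nonstat = {
            "p_variance": [float(v) for v in t.p_variance],
            "p_cv": [float(v) for v in t.p_cv],
            "n_perm": t.n_perm,
        }

    return EvaluationReport(
        models=models,
        aicc={k: float(v) for k, v in aicc.items()},
        eta=eta,
        percent_changes=pct,
        selection={
            "k_opt": sel.k_opt,
            "n_vif_filtered": len(sel.vif_filtered),
            "selected": [{"scale": f.scale, "wavelength": f.wavelength,
                          "abs_corr": f.abs_corr} for f in sel_feats],
        },
        gwr_summary=gmodel.summary(),
        nonstationarity=nonstat,
        split_info={"n": sp.n, "n_train": tr.size, "n_test": te.size,
                    "fraction": cfg.split_fraction},
        seed=seed,
    )
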