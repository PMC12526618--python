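"""End-to-end orchestration.

simulate -> EMG features -> intermuscular coherence -> 9-feature design
matrix -> grid sweep -> grouped 3-fold cross-validation -> final fit,
pruning, symbolic compression -> repeated-measures ANOVA tables -> report.

Feature order (one row per participant x condition x phase):
x1-x3 alpha/beta/gamma RA-BF coherence, x4-x6 alpha/beta/gamma TA-GL
coherence, x7-x9 iEMG/RMS/MF of the rectus femoris; outcome y is the
phase velocity (m/s).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd
from sklearn.model_selection import GroupKFold, KFold

from . import emg as _emg
from . import imc as _imc
from . import kan as _kan
from . import stats as _stats
from . import synth as _synth

logger = logging.getLogger(__name__)

FEATURE_COLUMNS = [f"x{i}" for i in range(1, 10)]
DEFAULT_GRIDS = (3, 5, 10, 20, 50, 100)


@dataclass
class RunConfig:
    cohort: "_synth.CohortConfig" = field(default_factory=_synth.CohortConfig.default)
    train: "_kan.TrainConfig" = field(default_factory=_kan.TrainConfig)
    folds: int = 3
    grouped: bool = True
    grids: tuple[int, ...] = DEFAULT_GRIDS
    velocity_mode: str = "table"  # "table" | "formula"
    seed: int = 42

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.velocity_mode not in ("table", "formula"):
            raise ValueError("velocity_mode must be 'table' or 'formula'")


def build_feature_matrix(features: pd.DataFrame, imc_table: pd.DataFrame,
                         velocities: pd.DataFrame | None = None) -> pd.DataFrame:
    """Assemble the x1..x9 design matrix from the long feature/IMC tables."""
    keys = ["participant", "condition", "phase"]
    co = imc_table.pivot_table(index=keys, columns=["pair", "band"],
                               values="coherence", observed=True)
    ra = (features[features["channel"] == "RA"]
          .set_index(keys)[["iemg", "rms", "mf"]])
    extra = set(features["channel"]) - set(_emg.CHANNELS)
    if extra:
        logger.warning("ignoring unexpected channels: %s", sorted(extra))
    if set(co.index) != set(ra.index):
        missing = sorted(set(co.index) ^ set(ra.index))
        raise ValueError(f"feature/IMC key mismatch: {missing[:5]}")
    out = pd.DataFrame(index=co.index)
    for col, (pair, band) in zip(FEATURE_COLUMNS[:6],
                                 [("RA-BF", b) for b in ("alpha", "beta", "gamma")]
                                 + [("TA-GL", b) for b in ("alpha", "beta", "gamma")]):
        out[col] = co[(pair, band)]
    out[["x7", "x8", "x9"]] = ra
    if velocities is not None:
        v = velocities.set_index(keys)["velocity"]
        if not set(out.index) <= set(v.index):
            raise ValueError("velocity table does not cover all feature keys")
        out["velocity"] = v
    return out.reset_index()


def apply_formula_velocities(matrix: pd.DataFrame, noise_sd: float,
                             seed: int) -> pd.DataFrame:
    """Replace the outcome with the packaged closed-form equation + noise."""
    rng = np.random.default_rng([seed, 271828])
    out = matrix.copy()
    out["velocity"] = _synth.generate_velocity_from_formula(
        out[FEATURE_COLUMNS].to_numpy(), noise_sd, rng)
    return out


def _splitter(matrix: pd.DataFrame, folds: int, grouped: bool, seed: int):
    X = matrix[FEATURE_COLUMNS].to_numpy()
    groups = matrix["participant"].to_numpy()
    if grouped:
        if len(np.unique(groups)) < folds:
            raise ValueError(f"need at least {folds} distinct participants "
                             f"for grouped {folds}-fold CV")
        return GroupKFold(n_splits=folds).split(X, groups=groups)
    return KFold(n_splits=folds, shuffle=True, random_state=seed).split(X)


def cross_validate(matrix: pd.DataFrame, cfg: "_kan.TrainConfig",
                   folds: int = 3, grouped: bool = True,
                   seed: int = 0, prune_model: bool = True) -> dict:
    """Grouped k-fold CV: scale -> train -> prune -> held-out R^2 per fold."""
    X = matrix[FEATURE_COLUMNS].to_numpy()
    y = matrix["velocity"].to_numpy()
    groups = matrix["participant"].to_numpy()
    fold_r2, fold_participants, fold_sizes = [], [], []
    for f, (tr, te) in enumerate(_splitter(matrix, folds, grouped, seed)):
        fold_cfg = replace(cfg, seed=cfg.seed + f)
        model, _info = _kan.fit_kan(X[tr], y[tr], fold_cfg,
                                    prune_model=prune_model)
        fold_r2.append(_kan.r_squared(model.forward(X[te]), y[te]))
        fold_participants.append(sorted(int(g) for g in np.unique(groups[te])))
        fold_sizes.append(int(len(te)))
    return {"fold_r2": fold_r2, "mean_r2": float(np.mean(fold_r2)),
            "fold_participants": fold_participants, "fold_sizes": fold_sizes}


def grid_sweep(matrix: pd.DataFrame, grids=DEFAULT_GRIDS,
               cfg: "_kan.TrainConfig | None" = None, grouped: bool = True,
               seed: int = 0) -> dict:
    """Train/validation loss per grid value; selection = argmin validation
    MSE with ties broken toward the smaller grid."""
    cfg = cfg or _kan.TrainConfig()
    X = matrix[FEATURE_COLUMNS].to_numpy()
    y = matrix["velocity"].to_numpy()
    tr, te = next(iter(_splitter(matrix, 3, grouped, seed)))
    results = []
    for g in grids:
        model = _kan.KANModel.init(cfg.widths, int(g), seed=cfg.seed)
        model.fit_scaler(X[tr])
        model, _ = _kan.train(model, X[tr], y[tr], cfg)
        results.append({
            "grid": int(g),
            "train_mse": float(np.mean((model.forward(X[tr]) - y[tr]) ** 2)),
            "val_mse": float(np.mean((model.forward(X[te]) - y[te]) ** 2)),
        })
    best = min(results, key=lambda r: (r["val_mse"], r["grid"]))
    return {"results": results, "selected_grid": best["grid"]}


def _anova_to_dict(res: "_stats.AnovaResult") -> dict:
    d = asdict(res)
    d["posthoc"] = [asdict(p) for p in res.posthoc]
    return d


def anova_tables(matrix: pd.DataFrame, imc_table: pd.DataFrame) -> dict:
    """RM-ANOVA per phase for velocity and per (pair, band, phase) for IMC."""
    out = {"velocity": {}, "coherence": {}}
    for phase, grp in matrix.groupby("phase", observed=True):
        tbl = grp.rename(columns={"velocity": "value"})[
            ["participant", "condition", "value"]]
        out["velocity"][str(phase)] = _anova_to_dict(_stats.rm_anova(tbl))
    for (pair, band, phase), grp in imc_table.groupby(
            ["pair", "band", "phase"], observed=True):
        tbl = grp.rename(columns={"coherence": "value"})[
            ["participant", "condition", "value"]]
        out["coherence"][f"{pair}/{band}/{phase}"] = _anova_to_dict(
            _stats.rm_anova(tbl))
    return out


@dataclass
class RunReport:
    provenance: dict
    grid_sweep: dict
    cv: dict
    pruned_summary: dict
    equation: str
    symbolic_terms: list
    anova: dict

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True, indent=1)

    def to_markdown(self) -> str:
        lines = ["# Sprint cohort analysis report", "",
                 f"Provenance: {self.provenance}", "",
                 f"Selected grid: {self.grid_sweep['selected_grid']}",
                 f"CV R^2 per fold: {['%.3f' % r for r in self.cv['fold_r2']]}"
                 f" (mean {self.cv['mean_r2']:.3f})", "",
                 f"Equation: {self.equation}", "",
                 "## Repeated-measures ANOVA (velocity)", "",
                 "| phase | F | p | p_GG | partial eta^2 |",
                 "|---|---|---|---|---|"]
        for phase, a in sorted(self.anova["velocity"].items()):
            lines.append(f"| {phase} | {a['f_value']:.2f} | {a['p_value']:.3f} "
                         f"| {a['p_gg']:.3f} | {a['partial_eta_sq']:.3f} |")
        lines += ["", "## Repeated-measures ANOVA (coherence)", "",
                  "| pair/band/phase | F | p | p_GG | partial eta^2 |",
                  "|---|---|---|---|---|"]
        for key, a in sorted(self.anova["coherence"].items()):
            lines.append(f"| {key} | {a['f_value']:.2f} | {a['p_value']:.3f} "
                         f"| {a['p_gg']:.3f} | {a['partial_eta_sq']:.3f} |")
        return "\n".join(lines)


def run_full(cfg: RunConfig | None = None) -> RunReport:
    """The full reproduction path; deterministic given (config, seed)."""
    cfg = cfg or RunConfig()
    logger.info("simulating cohort (seed=%d)", cfg.cohort.seed)
    cohort = _synth.generate_cohort(cfg.cohort)
    logger.info("extracting features for %d trials", len(cohort))
    features = _emg.feature_table(cohort)
    imc_table = _imc.coherence_table(cohort)
    matrix = build_feature_matrix(features, imc_table, cohort.velocities())
    if cfg.velocity_mode == "formula":
        matrix = apply_formula_velocities(matrix, cfg.cohort.noise_sd_velocity,
                                          cfg.seed)
    logger.info("grid sweep over %s", cfg.grids)
    sweep = grid_sweep(matrix, cfg.grids, cfg.train, cfg.grouped, cfg.seed)
    train_cfg = _kan.TrainConfig(**{**asdict(cfg.train),
                                    "grid": sweep["selected_grid"]})
    train_cfg.widths = tuple(train_cfg.widths)
    logger.info("cross-validating (grid=%d)", train_cfg.grid)
    cv = cross_validate(matrix, train_cfg, cfg.folds, cfg.grouped, cfg.seed)
    X = matrix[FEATURE_COLUMNS].to_numpy()
    y = matrix["velocity"].to_numpy()
    pruned, fit_info = _kan.fit_kan(X, y, train_cfg)
    sym = _kan.symbolize(pruned, X)
    report = RunReport(
        provenance={"config_hash": cfg.cohort.config_hash(),
                    "seed": cfg.seed, "n_rows": len(matrix),
                    "velocity_mode": cfg.velocity_mode},
        grid_sweep=sweep,
        cv=cv,
        pruned_summary={
            "n_active_edges": int(sum(m.sum() for m in pruned.masks)),
            "surviving_inputs": _kan.surviving_inputs(pruned),
            "full_data_r2": _kan.r_squared(pruned.forward(X), y),
        },
        equation=_kan.equation_string(sym),
        symbolic_terms=[asdict(t) for t in sym.terms],
        anova=anova_tables(matrix, imc_table),
    )
    return report
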