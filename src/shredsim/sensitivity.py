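"""Global sensitivity analysis: Latin hypercube design over the ten model
parameters, one simulation per sample, and a boosted-tree emulator of the
binary eradication outcome (relative influence, partial dependence, and
subsample convergence diagnostics).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import qmc
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.metrics import log_loss, roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .demography import max_feasible_r_max
from .engine import run_simulation
from .params import SimConfig

__all__ = [
    "ParameterRange",
    "LHSDesign",
    "EmulatorSettings",
    "EmulatorSummary",
    "DEFAULT_RANGES",
    "PD_CLAMP_DEFAULTS",
    "lhs_sample",
    "config_from_sample",
    "run_design",
    "fit_emulator",
    "partial_dependence",
    "convergence_check",
]


@dataclass(frozen=True)
class ParameterRange:
    """Uniform sampling range for one model parameter; discrete ranges use a
    discrete-uniform over the integer support [lo, hi]."""

    name: str
    lo: float
    hi: float
    discrete: bool = False

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError(f"{self.name}: lo must be < hi")


#: The ten parameters varied in the sensitivity analysis, with their ranges.
DEFAULT_RANGES: tuple[ParameterRange, ...] = (
    ParameterRange("p_c", 0.7, 1.0),
    ParameterRange("p_n", 0.0, 0.5),
    ParameterRange("n_guides", 1, 5, discrete=True),
    ParameterRange("p_nf", 0.66, 1.0),
    ParameterRange("p_y", 0.5, 1.0),
    ParameterRange("xo_fertility", 0.0, 1.0),
    ParameterRange("p_x_xo", 0.5, 1.0),
    ParameterRange("f_max", 1, 10, discrete=True),
    ParameterRange("litter_mean", 2.0, 10.0),
    ParameterRange("r_max", 6.0, 9.0),
)

#: Values at which the less-influential parameters are clamped for the
#: default conditioning-mode partial-dependence curves.
PD_CLAMP_DEFAULTS: dict[str, float] = {
    "litter_mean": 6.0,
    "xo_fertility": 0.6,
    "p_n": 0.1,
    "r_max": 7.76,
    "p_nf": 0.66,
    "n_guides": 3,
    "p_x_xo": 0.66,
    "p_c": 0.95,
}


@dataclass
class LHSDesign:
    """n samples x d parameters, with exactly one sample per equal-probability
    stratum for every continuous parameter."""

    samples: np.ndarray
    ranges: tuple[ParameterRange, ...]
    seed: int

    @property
    def names(self) -> list[str]:
        return [r.name for r in self.ranges]

    @property
    def n(self) -> int:
        return self.samples.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.samples, columns=self.names)

    def row(self, i: int) -> dict[str, float]:
        return dict(zip(self.names, self.samples[i]))

    def subset(self, n: int) -> "LHSDesign":
        return LHSDesign(self.samples[:n], self.ranges, self.seed)


def lhs_sample(ranges: Sequence[ParameterRange], n: int, seed: int) -> LHSDesign:
    """Stratified Latin hypercube sample with within-stratum jitter; discrete
    parameters map the stratified uniforms onto their integer support."""
    if n < 2:
        raise ValueError("n must be >= 2")
    ranges = tuple(ranges)
    unit = qmc.LatinHypercube(d=len(ranges), seed=seed).random(n)
    cols = []
    for j, r in enumerate(ranges):
        u = unit[:, j]
        if r.discrete:
            vals = np.floor(r.lo + u * (r.hi - r.lo + 1)).clip(r.lo, r.hi)
        else:
            vals = r.lo + u * (r.hi - r.lo)
        cols.append(vals)
    return LHSDesign(np.column_stack(cols), ranges, seed)


def config_from_sample(base: SimConfig, values: dict[str, float]) -> SimConfig:
    """Substitute one LHS row into a base configuration.

    r_max is clamped to the feasibility ceiling of the logistic survival
    calibration, cycles_per_year * ln(1 + m/2) (survival cannot exceed 1).
    """
    m = float(values.get("litter_mean", base.demog.litter_mean))
    r_raw = float(values.get("r_max", base.demog.r_max))
    r_cap = max_feasible_r_max(m, base.demog.cycles_per_year)
    drive = replace(
        base.drive,
        cut_prob=float(values.get("p_c", base.drive.cut_prob)),
        nhej_prob=float(values.get("p_n", base.drive.nhej_prob)),
        n_guides=int(values.get("n_guides", base.drive.n_guides)),
        nonfunctional_prob=float(values.get("p_nf", base.drive.nonfunctional_prob)),
        shred_prob=float(values.get("p_y", base.drive.shred_prob)),
        xo_fertility=float(values.get("xo_fertility", base.drive.xo_fertility)),
        x_bias_xo=float(values.get("p_x_xo", base.drive.x_bias_xo)),
    )
    demog = replace(
        base.demog,
        litter_mean=m,
        r_max=min(r_raw, r_cap * (1.0 - 1e-9)),
        max_mates=int(values.get("f_max", base.demog.max_mates)),
    )
    return base.with_(drive=drive, demog=demog)


def run_design(
    design: LHSDesign, base_config: SimConfig, progress: bool = False
) -> np.ndarray:
    """One simulation per design row; returns the binary eradication vector."""
    seeds = np.random.SeedSequence([int(design.seed), 0xD1CE]).spawn(design.n)
    outcomes = np.empty(design.n, dtype=np.int8)
    iterator = range(design.n)
    if progress:  # pragma: no cover - cosmetic
        from tqdm import tqdm

        iterator = tqdm(iterator, desc="design")
    for i in iterator:
        cfg = config_from_sample(base_config, design.row(i))
        outcomes[i] = 1 if run_simulation(cfg, seeds[i]).eradicated else 0
    return outcomes


# ---------------------------------------------------------------------------
# Boosted-tree emulator
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EmulatorSettings:
    """Gradient-boosting settings (tree depth 5, shrinkage 0.01, bag fraction
    0.75, Bernoulli deviance) with staged early stopping on held-out deviance."""

    learning_rate: float = 0.01
    max_depth: int = 5
    bag_fraction: float = 0.75
    max_trees: int = 2500
    chunk: int = 100
    patience: int = 3
    cv_folds: int = 5
    random_state: int = 0


@dataclass
class EmulatorSummary:
    """Fitted emulator plus its sensitivity summaries."""

    names: list[str]
    influence: dict[str, float] | None
    n_trees: int
    cv_deviance: float | None
    cv_auc: float | None
    settings: EmulatorSettings
    model: GradientBoostingClassifier | None = None
    degenerate: bool = False


def _new_model(st: EmulatorSettings, n_estimators: int) -> GradientBoostingClassifier:
    return GradientBoostingClassifier(
        learning_rate=st.learning_rate,
        max_depth=st.max_depth,
        subsample=st.bag_fraction,
        n_estimators=n_estimators,
        random_state=st.random_state,
        warm_start=True,
    )


def _staged_fit(X, y, Xv, yv, st: EmulatorSettings):
    """Warm-start chunked fitting with early stopping on validation deviance.

    Returns (best_n_trees, best_deviance, auc_at_best).
    """
    model = _new_model(st, st.chunk)
    best_dev = math.inf
    best_n = st.chunk
    best_auc = float("nan")
    bad = 0
    for n in range(st.chunk, st.max_trees + 1, st.chunk):
        model.n_estimators = n
        model.fit(X, y)
        proba = model.predict_proba(Xv)[:, 1]
        dev = 2.0 * log_loss(yv, proba, labels=[0, 1])
        if dev < best_dev - 1e-7:
            best_dev, best_n, bad = dev, n, 0
            best_auc = roc_auc_score(yv, proba) if len(np.unique(yv)) > 1 else float("nan")
        else:
            bad += 1
            if bad >= st.patience:
                break
    return best_n, best_dev, best_auc


def fit_emulator(
    design: LHSDesign | np.ndarray,
    outcomes: np.ndarray,
    settings: EmulatorSettings | None = None,
    names: Sequence[str] | None = None,
) -> EmulatorSummary:
    """Fit the boosted-tree emulator of the binary eradication outcome.

    The tree count is chosen by stratified k-fold staged fitting with early
    stopping on held-out Bernoulli deviance; the final model is refit on all
    data with the average selected count.  Relative influence is the
    split-improvement importance of each parameter, normalized to percent.
    """
    st = settings or EmulatorSettings()
    if isinstance(design, LHSDesign):
        X = design.samples
        names = design.names
    else:
        X = np.asarray(design, dtype=float)
        names = list(names) if names is not None else [f"x{j}" for j in range(X.shape[1])]
    y = np.asarray(outcomes, dtype=int)
    if y.shape[0] != X.shape[0]:
        raise ValueError("outcomes must have one entry per design row")
    if len(np.unique(y)) < 2:
        return EmulatorSummary(
            names=list(names),
            influence=None,
            n_trees=0,
            cv_deviance=None,
            cv_auc=None,
            settings=st,
            model=None,
            degenerate=True,
        )
    skf = StratifiedKFold(n_splits=st.cv_folds, shuffle=True, random_state=st.random_state)
    best_ns, devs, aucs = [], [], []
    for train, test in skf.split(X, y):
        bn, dev, auc = _staged_fit(X[train], y[train], X[test], y[test], st)
        best_ns.append(bn)
        devs.append(dev)
        aucs.append(auc)
    n_trees = int(np.mean(best_ns))
    final = _new_model(st, n_trees)
    final.fit(X, y)
    imp = final.feature_importances_
    imp = 100.0 * imp / imp.sum()
    return EmulatorSummary(
        names=list(names),
        influence=dict(zip(names, imp.tolist())),
        n_trees=n_trees,
        cv_deviance=float(np.mean(devs)),
        cv_auc=float(np.nanmean(aucs)),
        settings=st,
        model=final,
    )


def partial_dependence(
    emulator: EmulatorSummary,
    focal_params: str | Sequence[str],
    fixed_values: dict[str, float] | None = None,
    mode: str = "conditioning",
    grid_points: int = 41,
    ranges: Sequence[ParameterRange] = DEFAULT_RANGES,
    design: LHSDesign | None = None,
) -> pd.DataFrame:
    """Predicted eradication probability along a grid of the focal parameter(s).

    ``conditioning`` mode (the default) clamps every non-focal parameter at
    ``fixed_values`` (falling back to :data:`PD_CLAMP_DEFAULTS`); ``marginal``
    mode averages predictions over the design rows with the focal column(s)
    replaced (classical partial dependence; requires ``design``).
    """
    if emulator.model is None:
        raise ValueError("emulator is degenerate or unfitted")
    focal = [focal_params] if isinstance(focal_params, str) else list(focal_params)
    by_name = {r.name: r for r in ranges}
    for name in focal:
        if name not in emulator.names:
            raise ValueError(f"unknown parameter {name!r}")
    grids = []
    for name in focal:
        r = by_name[name]
        if r.discrete:
            grids.append(np.arange(int(r.lo), int(r.hi) + 1, dtype=float))
        else:
            grids.append(np.linspace(r.lo, r.hi, grid_points))
    mesh = np.meshgrid(*grids, indexing="ij")
    flat = [m.ravel() for m in mesh]
    n_grid = flat[0].size
    col = {name: j for j, name in enumerate(emulator.names)}
    if mode == "conditioning":
        fixed = dict(PD_CLAMP_DEFAULTS)
        fixed.update(fixed_values or {})
        base = np.empty(len(emulator.names))
        for name in emulator.names:
            if name in focal:
                continue
            if name not in fixed:
                raise ValueError(f"no clamp value for non-focal parameter {name!r}")
            base[col[name]] = fixed[name]
        Xg = np.tile(base, (n_grid, 1))
        for name, vals in zip(focal, flat):
            Xg[:, col[name]] = vals
        pred = emulator.model.predict_proba(Xg)[:, 1]
    elif mode == "marginal":
        if design is None:
            raise ValueError("marginal mode requires the design")
        Xd = design.samples.copy()
        pred = np.empty(n_grid)
        for g in range(n_grid):
            for name, vals in zip(focal, flat):
                Xd[:, col[name]] = vals[g]
            pred[g] = emulator.model.predict_proba(Xd)[:, 1].mean()
    else:
        raise ValueError("mode must be 'conditioning' or 'marginal'")
    out = {name: vals for name, vals in zip(focal, flat)}
    out["predicted_eradication"] = pred
    return pd.DataFrame(out)


def convergence_check(
    design: LHSDesign,
    outcomes: np.ndarray,
    subsample_sizes: Sequence[int],
    settings: EmulatorSettings | None = None,
    tolerance: float = 10.0,
) -> tuple[pd.DataFrame, bool]:
    """Refit the emulator on nested subsamples of increasing size and report
    influence vectors and CV performance per size.

    Returns (table, converged); ``converged`` is False when the influence
    vectors of the two largest sizes differ by more than ``tolerance`` points
    for any parameter.
    """
    sizes = list(subsample_sizes)
    if len(sizes) < 2:
        raise ValueError("need at least two subsample sizes")
    if any(b < a for a, b in zip(sizes, sizes[1:])):
        raise ValueError("subsample_sizes must be ascending")
    if sizes[-1] > design.n:
        raise ValueError("largest subsample exceeds the design size")
    rows = []
    last_two: list[np.ndarray] = []
    for size in sizes:
        summ = fit_emulator(design.subset(size), np.asarray(outcomes)[:size], settings)
        row: dict[str, float] = {"size": size, "n_trees": summ.n_trees}
        row["cv_deviance"] = summ.cv_deviance if summ.cv_deviance is not None else np.nan
        row["cv_auc"] = summ.cv_auc if summ.cv_auc is not None else np.nan
        infl = summ.influence or {name: np.nan for name in design.names}
        for name in design.names:
            row[f"influence_{name}"] = infl[name]
        rows.append(row)
        last_two = (last_two + [np.array([infl[n] for n in design.names])])[-2:]
    diff = np.abs(last_two[-1] - last_two[-2])
    converged = bool(np.all(np.nan_to_num(diff, nan=np.inf) <= tolerance)) if len(
        last_two
    ) == 2 else False
    return pd.DataFrame(rows), converged
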