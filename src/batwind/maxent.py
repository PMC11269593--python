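"""L1-penalized maximum-entropy presence-background model (LQP features).

The model estimates a Gibbs distribution over background cells,
``raw(x) ∝ exp(λ·f(x))``, whose feature expectations are pulled toward the
presence-sample means, subject to per-feature L1 penalties.  Fitting
maximizes the regularized training gain

    J(λ) = mean_presences[λ·f(x)] − log Σ_b exp(λ·f(z_b)) + log B − Σ_j β_j |λ_j|

by cyclic coordinate descent with a per-coordinate Newton step,
soft-thresholding and backtracking.  The optimizer contract is stated in KKT
form: at convergence, for every zero coefficient |g_j| ≤ β_j + tol and for
every nonzero coefficient |g_j − sign(λ_j) β_j| ≤ tol, where
g_j = (presence mean of f_j) − (expectation of f_j under the fitted
background distribution).

The per-feature penalty is β_j = rm × c_class(kind_j) × max(sd_j, ε) / √m,
with sd_j the feature's standard deviation over the m presences; rm is the
single regularization multiplier tuned by AICc over a 0.5-step grid.

Logistic output rescales the raw density with the fitted distribution's
entropy H: logistic(x) = raw(x)·e^H / (1 + raw(x)·e^H), the usual
prevalence-0.5 transform, so a featureless model scores 0.5 everywhere.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import rankdata

from .grids import RasterLayer

__all__ = [
    "FeatureSpec",
    "RegularizationSchema",
    "MaxentFit",
    "EvalReport",
    "ContributionReport",
    "ResponseCurve",
    "CollinearityReport",
    "build_features",
    "design_from_specs",
    "raster_stack_table",
    "sample_background",
    "fit",
    "raw_at",
    "logistic_at",
    "aicc",
    "select_rm",
    "auc",
    "cross_validate",
    "response_curves",
    "variable_contribution",
    "collinearity_screen",
    "save_fit",
    "load_fit",
]

DEFAULT_RM_GRID = tuple(np.arange(0.5, 5.01, 0.5).round(2))


@dataclass(frozen=True)
class FeatureSpec:
    kind: str                       # linear | quadratic | product | indicator
    variables: tuple[str, ...]
    train_min: tuple[float, ...] = ()
    train_max: tuple[float, ...] = ()
    category: int | None = None

    @property
    def name(self) -> str:
        if self.kind == "linear":
            return self.variables[0]
        if self.kind == "quadratic":
            return f"{self.variables[0]}^2"
        if self.kind == "product":
            return "*".join(self.variables)
        return f"{self.variables[0]}=={self.category}"


@dataclass(frozen=True)
class RegularizationSchema:
    """Penalty configuration: β_j = rm · c_class(kind_j) · max(sd_j, ε)/√m."""

    rm: float = 1.0
    c_class: dict = field(default_factory=lambda: {
        "linear": 1.0, "quadratic": 1.0, "product": 1.0, "indicator": 1.0,
    })
    epsilon_sd: float = 1e-3

    def __post_init__(self) -> None:
        if self.rm < 0:
            raise ValueError("regularization multiplier must be >= 0")

    def betas(self, specs: list[FeatureSpec], presence_design: np.ndarray) -> np.ndarray:
        m = presence_design.shape[0]
        sd = presence_design.std(axis=0)
        c = np.array([self.c_class.get(s.kind, 1.0) for s in specs])
        return self.rm * c * np.maximum(sd, self.epsilon_sd) / np.sqrt(m)

    def with_rm(self, rm: float) -> "RegularizationSchema":
        return RegularizationSchema(rm=rm, c_class=dict(self.c_class),
                                    epsilon_sd=self.epsilon_sd)


@dataclass
class MaxentFit:
    lam: np.ndarray
    feature_specs: list[FeatureSpec]
    schema: RegularizationSchema
    betas: np.ndarray
    log_Z: float
    H: float
    m: int
    B: int
    objective: float
    converged: bool
    kkt_residual: float
    tau: float = 0.5

    @property
    def n_nonzero(self) -> int:
        return int(np.count_nonzero(self.lam))


@dataclass
class EvalReport:
    fold_aucs: list[float]
    mean: float
    sd: float


@dataclass
class ContributionReport:
    percentages: dict[str, float]
    raw_drops: dict[str, float]


@dataclass
class ResponseCurve:
    variable: str
    values: np.ndarray       # variable grid (or category values)
    logistic: np.ndarray
    categorical: bool = False


@dataclass
class CollinearityReport:
    correlations: pd.DataFrame
    flagged: list[tuple[str, str, float]]
    threshold: float


# ---------------------------------------------------------------------------
# Feature construction
# ---------------------------------------------------------------------------

def build_features(values: dict[str, np.ndarray], kinds: dict[str, str],
                   feature_kinds: tuple[str, ...] = ("linear", "quadratic", "product"),
                   ) -> tuple[np.ndarray, list[FeatureSpec]]:
    """Build a training design matrix and the feature specs it defines.

    Continuous variables are min-max scaled to [0,1] using bounds computed
    from the supplied (training) values; categorical variables expand to one
    indicator per observed class.  Zero-variance continuous variables are
    dropped with a warning.
    """
    cont = [v for v in values if kinds[v] == "continuous"]
    cat = [v for v in values if kinds[v] != "continuous"]
    specs: list[FeatureSpec] = []
    usable: list[str] = []
    for v in cont:
        lo, hi = float(np.min(values[v])), float(np.max(values[v]))
        if hi <= lo:
            warnings.warn(f"dropping zero-variance variable {v!r}", stacklevel=2)
            continue
        usable.append(v)
        if "linear" in feature_kinds:
            specs.append(FeatureSpec("linear", (v,), (lo,), (hi,)))
        if "quadratic" in feature_kinds:
            specs.append(FeatureSpec("quadratic", (v,), (lo,), (hi,)))
    if "product" in feature_kinds:
        bounds = {s.variables[0]: (s.train_min[0], s.train_max[0])
                  for s in specs if s.kind == "linear"}
        if not bounds:  # quadratic-only runs still need bounds for products
            bounds = {v: (float(np.min(values[v])), float(np.max(values[v])))
                      for v in usable}
        for a, b in combinations(usable, 2):
            specs.append(FeatureSpec(
                "product", (a, b),
                (bounds[a][0], bounds[b][0]), (bounds[a][1], bounds[b][1]),
            ))
    for v in cat:
        for cls in np.unique(np.asarray(values[v]).astype(int)):
            specs.append(FeatureSpec("indicator", (v,), category=int(cls)))
    X = design_from_specs(values, specs)
    return X, specs


def design_from_specs(values: dict[str, np.ndarray],
                      specs: list[FeatureSpec]) -> np.ndarray:
    """Evaluate existing feature specs on new values (clamped to train bounds)."""
    n = len(next(iter(values.values())))
    X = np.empty((n, len(specs)))
    scaled: dict[tuple[str, float, float], np.ndarray] = {}

    def scale(v: str, lo: float, hi: float) -> np.ndarray:
        key = (v, lo, hi)
        if key not in scaled:
            raw = np.clip(np.asarray(values[v], float), lo, hi)
            scaled[key] = (raw - lo) / (hi - lo)
        return scaled[key]

    for j, s in enumerate(specs):
        if s.kind == "linear":
            X[:, j] = scale(s.variables[0], s.train_min[0], s.train_max[0])
        elif s.kind == "quadratic":
            X[:, j] = scale(s.variables[0], s.train_min[0], s.train_max[0]) ** 2
        elif s.kind == "product":
            X[:, j] = (scale(s.variables[0], s.train_min[0], s.train_max[0])
                       * scale(s.variables[1], s.train_min[1], s.train_max[1]))
        elif s.kind == "indicator":
            X[:, j] = (np.asarray(values[s.variables[0]]).astype(int)
                       == s.category).astype(float)
        else:
            raise ValueError(f"unknown feature kind {s.kind!r}")
    return X


def raster_stack_table(env: dict[str, RasterLayer]) -> pd.DataFrame:
    """Flatten aligned rasters into a table of valid cells (row, col, x, y, vars)."""
    grids = {layer.grid for layer in env.values()}
    if len(grids) != 1:
        raise ValueError("rasters must share one grid")
    grid = next(iter(grids))
    valid = np.ones(grid.shape, dtype=bool)
    for layer in env.values():
        valid &= layer.valid_mask()
    row, col = np.nonzero(valid)
    cx, cy = grid.cell_centers()
    table = pd.DataFrame({"row": row, "col": col,
                          "x": cx[row, col], "y": cy[row, col]})
    for name, layer in env.items():
        table[name] = layer.values[row, col]
    return table


def sample_background(env: dict[str, RasterLayer], B: int = 10000,
                      seed: int = 0) -> pd.DataFrame:
    """B uniform random valid cells, without replacement (all cells if fewer)."""
    table = raster_stack_table(env)
    if len(table) == 0:
        raise ValueError("no valid cells to sample background from")
    if len(table) <= B:
        if len(table) < B:
            warnings.warn(
                f"only {len(table)} valid cells available for {B} background points",
                stacklevel=2)
        return table.reset_index(drop=True)
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(table), size=B, replace=False)
    return table.iloc[np.sort(idx)].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _kkt_residual(lam: np.ndarray, g: np.ndarray, betas: np.ndarray) -> float:
    zero = lam == 0
    r_zero = np.maximum(np.abs(g[zero]) - betas[zero], 0.0)
    r_nz = np.abs(g[~zero] - np.sign(lam[~zero]) * betas[~zero])
    parts = np.concatenate([r_zero, r_nz])
    return float(parts.max()) if parts.size else 0.0


def fit(presence_design: np.ndarray, background_design: np.ndarray,
        specs: list[FeatureSpec], schema: RegularizationSchema | None = None,
        tol: float = 1e-6, max_iter: int = 1000,
        betas: np.ndarray | None = None) -> MaxentFit:
    """Fit the penalized maximum-entropy model by coordinate descent.

    ``betas`` overrides the schema-derived per-feature penalties (useful for
    toy problems with hand-set penalties).  Non-convergence within
    ``max_iter`` sweeps returns a fit flagged ``converged=False`` with a
    warning, never silently.
    """
    schema = schema or RegularizationSchema()
    Xp = np.asarray(presence_design, float)
    Xb = np.asarray(background_design, float)
    if Xp.shape[0] < 2:
        raise ValueError("need at least 2 presences")
    if not (np.all(np.isfinite(Xp)) and np.all(np.isfinite(Xb))):
        raise ValueError("design matrices must be finite")
    m, J = Xp.shape
    B = Xb.shape[0]
    if betas is None:
        betas = schema.betas(specs, Xp)
    betas = np.asarray(betas, float)
    pmean = Xp.mean(axis=0)

    lam = np.zeros(J)
    s = np.zeros(B)              # background scores Xb @ lam, kept incrementally
    log_B = np.log(B)

    def penalized_gain(scores: np.ndarray, lam_: np.ndarray) -> float:
        return float(pmean @ lam_ - logsumexp(scores) + log_B
                     - betas @ np.abs(lam_))

    kkt = np.inf
    converged = False
    for _ in range(max_iter):
        for j in range(J):
            fj = Xb[:, j]
            q = np.exp(s - logsumexp(s))
            Ef = q @ fj
            g = pmean[j] - Ef
            h = max(q @ fj**2 - Ef**2, 1e-12)
            u = lam[j] + g / h
            lam_new = np.sign(u) * max(abs(u) - betas[j] / h, 0.0)
            delta = lam_new - lam[j]
            if delta == 0.0:
                continue
            # backtrack on the 1-D penalized gain so Newton steps never overshoot
            base = (pmean[j] * lam[j] - logsumexp(s) - betas[j] * abs(lam[j]))
            for _bt in range(30):
                cand = lam[j] + delta
                gain = (pmean[j] * cand - logsumexp(s + delta * fj)
                        - betas[j] * abs(cand))
                if gain >= base - 1e-15:
                    break
                delta *= 0.5
            else:
                continue
            lam[j] += delta
            s += delta * fj
        # full gradient for the KKT check
        q = np.exp(s - logsumexp(s))
        g_full = pmean - q @ Xb
        kkt = _kkt_residual(lam, g_full, betas)
        if kkt <= tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"maxent fit did not converge: KKT residual {kkt:.3g} > tol {tol:.3g}",
            stacklevel=2)

    log_Z = float(logsumexp(s))
    raw_b = np.exp(s - log_Z)
    with np.errstate(divide="ignore", invalid="ignore"):
        H = float(-(raw_b * np.where(raw_b > 0, np.log(raw_b), 0.0)).sum())
    return MaxentFit(
        lam=lam, feature_specs=list(specs), schema=schema, betas=betas,
        log_Z=log_Z, H=H, m=m, B=B,
        objective=penalized_gain(s, lam), converged=converged,
        kkt_residual=kkt,
    )


def raw_at(fit_: MaxentFit, design: np.ndarray) -> np.ndarray:
    """Raw (Gibbs) weights; they sum to 1 over the training background."""
    return np.exp(np.asarray(design, float) @ fit_.lam - fit_.log_Z)


def logistic_at(fit_: MaxentFit, design: np.ndarray) -> np.ndarray:
    """Logistic suitability in (0,1) at prevalence tau = 0.5."""
    r = raw_at(fit_, design) * np.exp(fit_.H)
    return r / (1.0 + r)


# ---------------------------------------------------------------------------
# Model selection and evaluation
# ---------------------------------------------------------------------------

def aicc(fit_: MaxentFit, presence_design: np.ndarray,
         extent_design: np.ndarray | None = None) -> float:
    """Small-sample AIC from the extent-normalized raw density at presences.

    k counts nonzero coefficients.  Returns NaN (flagged undefined) when
    k = 0 or k ≥ m − 1.
    """
    m = presence_design.shape[0]
    k = fit_.n_nonzero
    if k == 0 or k >= m - 1:
        return float("nan")
    ext = presence_design if extent_design is None else extent_design
    scores_ext = np.asarray(ext, float) @ fit_.lam
    scores_p = np.asarray(presence_design, float) @ fit_.lam
    lnL = float(scores_p.sum() - m * logsumexp(scores_ext))
    return 2 * k - 2 * lnL + 2 * k * (k + 1) / (m - k - 1)


def select_rm(presence_design: np.ndarray, background_design: np.ndarray,
              specs: list[FeatureSpec],
              candidates: tuple[float, ...] = DEFAULT_RM_GRID,
              base_schema: RegularizationSchema | None = None,
              tol: float = 1e-6, max_iter: int = 1000,
              ) -> tuple[float, pd.DataFrame, MaxentFit]:
    """AICc model selection over a regularization-multiplier grid.

    Returns (best rm, per-candidate table, the winning fit).  Ties go to the
    smallest rm; candidates with undefined AICc are excluded.
    """
    base = base_schema or RegularizationSchema()
    rows = []
    fits: dict[float, MaxentFit] = {}
    for rm in candidates:
        f = fit(presence_design, background_design, specs,
                base.with_rm(rm), tol=tol, max_iter=max_iter)
        fits[rm] = f
        rows.append({
            "rm": rm,
            "aicc": aicc(f, presence_design, background_design),
            "k": f.n_nonzero,
            "converged": f.converged,
        })
    table = pd.DataFrame(rows)
    defined = table[np.isfinite(table["aicc"])]
    if defined.empty:
        raise ValueError("AICc undefined for every regularization multiplier")
    # stable idxmin on ascending candidates implements the smallest-rm tie rule
    best_rm = float(defined.sort_values("rm").set_index("rm")["aicc"].idxmin())
    return best_rm, table, fits[best_rm]


def auc(presence_scores: np.ndarray, background_scores: np.ndarray) -> float:
    """Rank-based (Mann-Whitney) AUC; ties credit 0.5."""
    p = np.asarray(presence_scores, float)
    b = np.asarray(background_scores, float)
    if p.size == 0 or b.size == 0:
        raise ValueError("both score sets must be non-empty")
    ranks = rankdata(np.concatenate([p, b]))
    u = ranks[: p.size].sum() - p.size * (p.size + 1) / 2
    return float(u / (p.size * b.size))


def cross_validate(presence_design: np.ndarray, background_design: np.ndarray,
                   specs: list[FeatureSpec], k: int = 5, seed: int = 0,
                   schema: RegularizationSchema | None = None,
                   tol: float = 1e-6, max_iter: int = 1000) -> EvalReport:
    """k-fold test AUC: fit on k−1 presence folds, score held-out fold vs background."""
    m = presence_design.shape[0]
    if m < k:
        raise ValueError(f"need at least k={k} presences, got {m}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(m)
    folds = np.array_split(order, k)
    if any(len(f) == 0 for f in folds):
        raise ValueError("a fold would be empty")
    aucs = []
    for i in range(k):
        test_idx = folds[i]
        train_idx = np.concatenate([folds[j] for j in range(k) if j != i])
        f = fit(presence_design[train_idx], background_design, specs,
                schema, tol=tol, max_iter=max_iter)
        scores_p = presence_design[test_idx] @ f.lam
        scores_b = background_design @ f.lam
        aucs.append(auc(scores_p, scores_b))
    aucs_arr = np.array(aucs)
    sd = float(aucs_arr.std(ddof=1)) if k > 1 else 0.0
    return EvalReport(fold_aucs=[float(a) for a in aucs],
                      mean=float(aucs_arr.mean()), sd=sd)


def response_curves(presence_values: dict[str, np.ndarray],
                    background_values: dict[str, np.ndarray],
                    kinds: dict[str, str], n_grid: int = 100,
                    rm: float = 1.0, tol: float = 1e-6,
                    max_iter: int = 1000) -> dict[str, ResponseCurve]:
    """Univariate response curves: one L+Q (or indicator) model per variable at rm."""
    curves: dict[str, ResponseCurve] = {}
    schema = RegularizationSchema(rm=rm)
    for var, kind in kinds.items():
        vals_p = {var: presence_values[var]}
        vals_b = {var: background_values[var]}
        train = {var: np.concatenate([vals_p[var], vals_b[var]])}
        if kind == "continuous":
            _, specs = build_features(train, {var: "continuous"},
                                      feature_kinds=("linear", "quadratic"))
        else:
            _, specs = build_features(train, {var: kind}, feature_kinds=())
        Xp = design_from_specs(vals_p, specs)
        Xb = design_from_specs(vals_b, specs)
        f = fit(Xp, Xb, specs, schema, tol=tol, max_iter=max_iter)
        if kind == "continuous":
            lo, hi = float(np.min(train[var])), float(np.max(train[var]))
            grid_vals = np.linspace(lo, hi, n_grid)
            categorical = False
        else:
            grid_vals = np.unique(np.asarray(train[var]).astype(int)).astype(float)
            categorical = True
        Xg = design_from_specs({var: grid_vals}, specs)
        curves[var] = ResponseCurve(var, grid_vals, logistic_at(f, Xg),
                                    categorical=categorical)
    return curves


def variable_contribution(fit_: MaxentFit, presence_design: np.ndarray,
                          background_design: np.ndarray, n_perm: int = 10,
                          seed: int = 0) -> ContributionReport:
    """Permutation importance of each variable, normalized to percentages.

    Each variable's derived feature columns (products count for both parent
    variables) are jointly row-permuted across the pooled evaluation rows;
    the mean drop in training AUC over ``n_perm`` permutations, floored at
    zero, is normalized to sum to 100.
    """
    rng = np.random.default_rng(seed)
    X = np.vstack([presence_design, background_design])
    n_p = presence_design.shape[0]
    var_cols: dict[str, list[int]] = {}
    for j, s in enumerate(fit_.feature_specs):
        for v in s.variables:
            var_cols.setdefault(v, []).append(j)
    scores = X @ fit_.lam
    base = auc(scores[:n_p], scores[n_p:])
    drops: dict[str, float] = {}
    for v, cols in var_cols.items():
        ds = []
        for _ in range(n_perm):
            perm = rng.permutation(X.shape[0])
            Xp_ = X.copy()
            Xp_[:, cols] = X[perm][:, cols]
            s_ = Xp_ @ fit_.lam
            ds.append(base - auc(s_[:n_p], s_[n_p:]))
        drops[v] = max(float(np.mean(ds)), 0.0)
    total = sum(drops.values())
    if total == 0:
        warnings.warn("all permutation drops are zero; reporting uniform "
                      "contributions", stacklevel=2)
        pct = {v: 100.0 / len(drops) for v in drops}
    else:
        pct = {v: 100.0 * d / total for v, d in drops.items()}
    return ContributionReport(percentages=pct, raw_drops=drops)


def collinearity_screen(samples: pd.DataFrame, threshold: float = 0.7,
                        ) -> CollinearityReport:
    """Pairwise Pearson correlations over continuous variables at sample points.

    A screen only: flagged pairs are reported, never dropped automatically.
    Zero-variance variables yield NaN correlations, which are flagged.
    """
    if len(samples) < 3:
        raise ValueError("need at least 3 sample locations")
    corr = samples.corr(method="pearson")
    flagged = []
    cols = list(corr.columns)
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            r = corr.loc[a, b]
            if np.isnan(r) or abs(r) >= threshold:
                flagged.append((a, b, float(r)))
    return CollinearityReport(correlations=corr, flagged=flagged,
                              threshold=threshold)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def save_fit(fit_: MaxentFit, path: str | Path) -> None:
    payload = {
        "lambda": fit_.lam.tolist(),
        "betas": fit_.betas.tolist(),
        "log_Z": fit_.log_Z,
        "H": fit_.H,
        "m": fit_.m,
        "B": fit_.B,
        "objective": fit_.objective,
        "converged": fit_.converged,
        "kkt_residual": fit_.kkt_residual,
        "tau": fit_.tau,
        "schema": {"rm": fit_.schema.rm, "c_class": fit_.schema.c_class,
                   "epsilon_sd": fit_.schema.epsilon_sd},
        "feature_specs": [
            {"kind": s.kind, "variables": list(s.variables),
             "train_min": list(s.train_min), "train_max": list(s.train_max),
             "category": s.category}
            for s in fit_.feature_specs
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_fit(path: str | Path) -> MaxentFit:
    payload = json.loads(Path(path).read_text())
    specs = [
        FeatureSpec(kind=s["kind"], variables=tuple(s["variables"]),
                    train_min=tuple(s["train_min"]),
                    train_max=tuple(s["train_max"]),
                    category=s["category"])
        for s in payload["feature_specs"]
    ]
    schema = RegularizationSchema(rm=payload["schema"]["rm"],
                                  c_class=payload["schema"]["c_class"],
                                  epsilon_sd=payload["schema"]["epsilon_sd"])
    return MaxentFit(
        lam=np.array(payload["lambda"]), feature_specs=specs, schema=schema,
        betas=np.array(payload["betas"]), log_Z=payload["log_Z"],
        H=payload["H"], m=payload["m"], B=payload["B"],
        objective=payload["objective"], converged=payload["converged"],
        kkt_residual=payload["kkt_residual"], tau=payload["tau"],
    )
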