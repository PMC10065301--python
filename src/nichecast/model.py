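"""The presence/background maximum-entropy model.

The model is the Gibbs density q(x) = exp(lambda . f(x)) / Z over a
background sample of landscape cells, fitted by minimising the
L1-regularised negative presence log-likelihood

    J(lambda) = -(1/m) sum_presences lambda.f(x_i) + log Z(lambda)
                + sum_j beta_j |lambda_j|,

with per-feature penalties beta_j = rm * beta_class(m) * s_j / sqrt(m)
(s_j the feature's background standard deviation, m the presence count,
rm the global regularization multiplier, beta_class an interpolated
per-feature-class constant).  The objective is convex; it is minimised
by an accelerated proximal-gradient method with backtracking and
monotone restarts, so the recorded objective trace never increases.

Prediction offers the raw density and the cloglog transform
1 - exp(-e^H q(x)) with H the entropy of the fitted density, which maps
suitability to (0, 1) and equals 1 - 1/e everywhere for the null model.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp
from scipy.stats import rankdata

from .errors import ConvergenceError, NichecastError
from .features import Feature, FeatureExpansion, build_features, sample_background
from .grids import EnvStack, RasterGrid
from .occurrences import OccurrenceSet

logger = logging.getLogger(__name__)

#: |lambda| above this counts as a non-zero parameter (AICc's k)
NONZERO_LAMBDA = 1e-8

#: beta_class interpolation table on presence count, per feature class
_BETA_TABLE = {
    "L": ([10, 30, 100], [1.0, 0.6, 0.5]),
    "Q": ([10, 30, 100], [1.0, 0.6, 0.5]),
    "P": ([10, 30, 100], [1.0, 0.6, 0.5]),
    "T": ([10, 100], [1.0, 1.0]),
    "H": ([10, 100], [0.5, 0.5]),
}


def beta_class(feature_class: str, m: int) -> float:
    """Per-class regularization constant, interpolated on presence count."""
    xs, ys = _BETA_TABLE[feature_class]
    return float(np.interp(m, xs, ys))


def feature_penalties(exp: FeatureExpansion, rm: float) -> np.ndarray:
    """beta_j = rm * beta_class(m) * s_j / sqrt(m) per design column."""
    m = len(exp.X_presence)
    s = exp.X_background.std(axis=0)
    cls = np.array([beta_class(f.feature_class, m) for f in exp.features])
    return rm * cls * s / np.sqrt(max(m, 1))


@dataclass
class MaxentModel:
    """A fitted maximum-entropy model: weights plus everything to score a cell."""

    lambdas: np.ndarray
    feature_meta: FeatureExpansion
    log_Z: float
    entropy_H: float
    rm: float
    fc: frozenset
    beta: np.ndarray
    objective_trace: list = field(default_factory=list)

    @property
    def n_nonzero(self) -> int:
        return int(np.sum(np.abs(self.lambdas) > NONZERO_LAMBDA))

    def background_density(self) -> np.ndarray:
        """q over the training background (sums to 1)."""
        eta = self.feature_meta.X_background @ self.lambdas
        return np.exp(eta - logsumexp(eta))

    def scores(self, raw: dict[str, np.ndarray], output: str = "cloglog") -> np.ndarray:
        """Score arbitrary points given their raw per-variable values."""
        X = self.feature_meta.design(raw)
        q = np.exp(X @ self.lambdas - self.log_Z)
        if output == "raw":
            return q
        if output == "cloglog":
            return 1.0 - np.exp(-np.exp(self.entropy_H) * q)
        raise ValueError(f"unknown output {output!r}")

    # -- portable text serialization -------------------------------------
    def to_json(self) -> str:
        meta = self.feature_meta
        doc = {
            "lambdas": self.lambdas.tolist(),
            "log_Z": self.log_Z,
            "entropy_H": self.entropy_H,
            "rm": self.rm,
            "fc": sorted(self.fc),
            "variables": meta.variables,
            "variable_stats": {k: list(v) for k, v in meta.variable_stats.items()},
            "features": [
                {"kind": f.kind, "variables": list(f.variables), "knot": f.knot}
                for f in meta.features
            ],
        }
        return json.dumps(doc, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "MaxentModel":
        doc = json.loads(text)
        meta = FeatureExpansion(
            variables=list(doc["variables"]),
            variable_stats={k: tuple(v) for k, v in doc["variable_stats"].items()},
            features=[Feature(f["kind"], tuple(f["variables"]), f["knot"])
                      for f in doc["features"]],
            fc=frozenset(doc["fc"]),
        )
        lam = np.array(doc["lambdas"])
        return cls(lam, meta, doc["log_Z"], doc["entropy_H"], doc["rm"],
                   frozenset(doc["fc"]), np.zeros_like(lam))


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def fit(features: FeatureExpansion, rm: float, tol: float = 1e-6,
        max_iter: int = 5000) -> MaxentModel:
    """Minimise the L1-regularised maxent objective (monotone accelerated
    proximal gradient); returns the fitted model with log_Z and entropy
    computed on the training background."""
    Xp, Xb = features.X_presence, features.X_background
    if Xp is None or len(Xp) == 0:
        raise NichecastError("fit requires at least one presence")
    if len(Xb) < len(Xp):
        raise NichecastError("background must be at least as large as presences")
    beta = feature_penalties(features, rm)
    mean_pres = Xp.mean(axis=0)
    J = Xb.shape[1]

    def smooth_val(lam, eta=None):
        eta = Xb @ lam if eta is None else eta
        return -float(mean_pres @ lam) + float(logsumexp(eta))

    def smooth_grad(lam):
        eta = Xb @ lam
        lz = logsumexp(eta)
        q = np.exp(eta - lz)
        return Xb.T @ q - mean_pres, float(lz) - float(mean_pres @ lam)

    def total(lam):
        return smooth_val(lam) + float(beta @ np.abs(lam))

    # step seed from a cheap curvature bound; backtracking guards the rest
    col_norm = np.linalg.norm(Xb, axis=0).max() / np.sqrt(max(len(Xb), 1))
    step = min(max(1.0 / max(col_norm**2, 1e-12), 1e-8), 4.0)

    lam = np.zeros(J)
    y = lam.copy()
    t_mom = 1.0
    F = total(lam)
    trace = [F]
    converged = False
    for _ in range(max_iter):
        g_y, smooth_y = smooth_grad(y)
        # backtracking proximal step from y
        for _bt in range(60):
            z = y - step * g_y
            z = np.sign(z) * np.maximum(np.abs(z) - step * beta, 0.0)
            diff = z - y
            sv = smooth_val(z)
            if sv <= smooth_y + float(g_y @ diff) + float(diff @ diff) / (2 * step) + 1e-12:
                break
            step *= 0.5
        Fz = sv + float(beta @ np.abs(z))
        if Fz > F:  # momentum overshoot: restart from the last accepted point
            y = lam.copy()
            t_mom = 1.0
            g_y, smooth_y = smooth_grad(y)
            for _bt in range(60):
                z = y - step * g_y
                z = np.sign(z) * np.maximum(np.abs(z) - step * beta, 0.0)
                diff = z - y
                sv = smooth_val(z)
                if sv <= smooth_y + float(g_y @ diff) + float(diff @ diff) / (2 * step) + 1e-12:
                    break
                step *= 0.5
            Fz = sv + float(beta @ np.abs(z))
        t_next = (1.0 + np.sqrt(1.0 + 4.0 * t_mom**2)) / 2.0
        y = z + ((t_mom - 1.0) / t_next) * (z - lam)
        rel = abs(F - Fz) / max(1.0, abs(F))
        lam, F, t_mom = z, min(F, Fz), t_next
        trace.append(F)
        step *= 1.2  # allow the step to grow back between backtracks
        if rel < tol:
            converged = True
            break
    if not converged:
        raise ConvergenceError(
            f"maxent fit did not converge in {max_iter} iterations "
            f"(last objective {trace[-1]:.8g})", trace=trace)

    eta = Xb @ lam
    lz = float(logsumexp(eta))
    q = np.exp(eta - lz)
    H = float(-np.sum(q * np.log(np.maximum(q, 1e-300))))
    return MaxentModel(lam, features, lz, H, rm, features.fc, beta, trace)


# ---------------------------------------------------------------------------
# prediction and summaries
# ---------------------------------------------------------------------------

def predict(model: MaxentModel, stack: EnvStack, output: str = "cloglog") -> RasterGrid:
    """Score every valid cell of a stack; nodata is propagated.

    raw: exp(lambda.f - log_Z) (density on the training background scale);
    cloglog: 1 - exp(-e^H q) in (0, 1).  Values outside the training
    range are clamped to the [0, 1] scaled interval.
    """
    missing = set(model.feature_meta.variables) - set(stack.variables)
    if missing:
        raise NichecastError(f"stack lacks model variables: {sorted(missing)}")
    grid = stack.grid
    mask = grid.mask
    cells = np.argwhere(mask)
    raw_vals = stack.values_at_cells(cells)
    scores = model.scores({v: raw_vals[v] for v in model.feature_meta.variables}, output)
    vals = np.full(grid.values.shape, grid.nodata_value)
    vals[mask] = scores
    return RasterGrid(grid.x_ll, grid.y_ll, grid.cell_size, grid.nodata_value, vals)


def training_gain(model: MaxentModel) -> float:
    """Mean presence log density ratio against uniform: mean log(q(x_i) N)."""
    meta = model.feature_meta
    eta_p = meta.X_presence @ model.lambdas
    n_bg = len(meta.X_background)
    return float(np.mean(eta_p) - model.log_Z + np.log(n_bg))


def auc(scores_presence, scores_background) -> float:
    """Rank-based AUC (Mann-Whitney): P(presence outscores background), ties 1/2."""
    sp = np.asarray(scores_presence, dtype=float)
    sb = np.asarray(scores_background, dtype=float)
    if sp.size == 0 or sb.size == 0:
        raise NichecastError("auc requires non-empty score lists")
    ranks = rankdata(np.concatenate([sp, sb]))
    u = ranks[: sp.size].sum() - sp.size * (sp.size + 1) / 2.0
    return float(u / (sp.size * sb.size))


def aicc_formula(k: int, n: int, loglik: float) -> float:
    """AICc = 2k - 2LL + 2k(k+1)/(n-k-1); undefined for n <= k+1."""
    if n <= k + 1:
        return float("nan")
    return 2.0 * k - 2.0 * loglik + 2.0 * k * (k + 1) / (n - k - 1)


@dataclass
class AiccResult:
    aicc: float
    k: int
    loglik: float
    valid: bool


def aicc(model: MaxentModel, stack: EnvStack, occ: OccurrenceSet) -> AiccResult:
    """Small-sample AICc of a fitted model.

    Raw scores are renormalised to sum 1 over *all* valid cells of the
    stack; the log-likelihood sums log normalized scores at the presence
    cells; k counts non-zero weights.  Candidates with n <= k+1 are
    flagged invalid (excluded from selection).
    """
    raw = predict(model, stack, output="raw")
    mask = raw.mask
    total = raw.values[mask].sum()
    cells = occ.cells(stack.grid)
    p_hat = raw.values[cells[:, 0], cells[:, 1]] / total
    ll = float(np.sum(np.log(np.maximum(p_hat, 1e-300))))
    k = model.n_nonzero
    n = len(occ)
    valid = n > k + 1
    return AiccResult(aicc_formula(k, n, ll) if valid else float("nan"), k, ll, valid)


def percent_contribution(model: MaxentModel, features: FeatureExpansion,
                         seed: int, n_permutations: int = 5) -> dict[str, float]:
    """Permutation importance, normalised to sum 100.

    Per variable: its raw values are permuted jointly across presences and
    background, every feature derived from it recomputed, and the drop in
    training gain (fixed weights, re-normalised Z) averaged over seeded
    permutations.  Negative drops truncate to zero.
    """
    rng = np.random.default_rng(seed)
    g0 = training_gain(model)
    n_bg = len(features.X_background)
    drops: dict[str, float] = {}
    for var in features.variables:
        acc = 0.0
        for _ in range(n_permutations):
            raw_b = dict(features.raw_background)
            raw_p = dict(features.raw_presence)
            pooled = np.concatenate([raw_b[var], raw_p[var]])
            pooled = rng.permutation(pooled)
            raw_b[var] = pooled[: len(raw_b[var])]
            raw_p[var] = pooled[len(raw_b[var]):]
            Xb = features.design(raw_b)
            Xp = features.design(raw_p)
            lz = logsumexp(Xb @ model.lambdas)
            gain = float(np.mean(Xp @ model.lambdas) - lz + np.log(n_bg))
            acc += g0 - gain
        drops[var] = max(acc / n_permutations, 0.0)
    total = sum(drops.values())
    if total <= 0:
        warnings.warn("all permutation drops are zero; returning uniform contributions")
        return {v: 100.0 / len(drops) for v in drops}
    return {v: 100.0 * d / total for v, d in drops.items()}


def jackknife_gain(stack: EnvStack, occ: OccurrenceSet, background: np.ndarray,
                   fc, rm: float) -> dict:
    """Training gains with-only and without each variable, plus the full gain."""
    variables = stack.variables
    if len(variables) < 2:
        raise NichecastError("jackknife requires at least 2 variables")

    def _gain(names):
        sub = EnvStack({v: stack.layers[v] for v in names}, stack.scenario_label)
        feats = build_features(sub, occ, background, fc)
        return training_gain(fit(feats, rm))

    full = _gain(variables)
    with_only = {v: _gain([v]) for v in variables}
    without = {v: _gain([u for u in variables if u != v]) for v in variables}
    return {"full": full, "with_only": with_only, "without": without}


def response_curve(model: MaxentModel, variable: str, n_points: int = 101,
                   threshold: float | None = None):
    """Marginal response: sweep one variable, others at background means.

    Returns (curve, suitable_range): curve is an (n_points, 2) array of
    (raw value, cloglog score); suitable_range is the (min, max) of swept
    values whose score is >= threshold, or None.
    """
    meta = model.feature_meta
    if variable not in meta.variables:
        raise NichecastError(f"variable {variable!r} not in model")
    lo, hi = meta.variable_stats[variable]
    sweep = np.linspace(lo, hi, n_points)
    raw = {v: np.full(n_points, float(meta.raw_background[v].mean()))
           for v in meta.variables}
    raw[variable] = sweep
    scores = model.scores(raw, output="cloglog")
    curve = np.column_stack([sweep, scores])
    suitable = None
    if threshold is not None:
        inside = sweep[scores >= threshold]
        if inside.size:
            suitable = (float(inside.min()), float(inside.max()))
    return curve, suitable


# ---------------------------------------------------------------------------
# replicated train/test evaluation
# ---------------------------------------------------------------------------

@dataclass
class EvalResult:
    auc_train: float
    auc_test: float
    replicate_index: int
    seed: int


def replicate_eval(stack: EnvStack, occ: OccurrenceSet, fc, rm: float,
                   n_replicates: int, test_fraction: float, seed: int,
                   background_size: int = 10_000):
    """Seeded replicated subsampling evaluation.

    Per replicate, floor(test_fraction * m) presences are withheld, the
    model refit on the rest, and train/test AUC recorded against the
    common background.  Returns (results, summary) with means and sample
    standard deviations rounded to 3 decimals.
    """
    m = len(occ)
    n_test = int(np.floor(test_fraction * m))
    if n_test < 1:
        raise NichecastError("test split is empty; increase test_fraction or presences")
    if m - n_test < 1:
        raise NichecastError("train split is empty")
    background = sample_background(stack, occ, background_size, seed)
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_replicates)
    results: list[EvalResult] = []
    for r, child in enumerate(children):
        rng = np.random.default_rng(child)
        rep_seed = int(child.generate_state(1)[0] % (2**31))
        test_idx = rng.choice(m, size=n_test, replace=False)
        test_mask = np.zeros(m, dtype=bool)
        test_mask[test_idx] = True
        occ_train = OccurrenceSet(occ.records[~test_mask])
        occ_test = OccurrenceSet(occ.records[test_mask])
        feats = build_features(stack, occ_train, background, fc)
        model = fit(feats, rm)
        bg_scores = feats.X_background @ model.lambdas
        train_scores = feats.X_presence @ model.lambdas
        raw_test = stack.values_at_cells(occ_test.cells(stack.grid))
        X_test = feats.design({v: raw_test[v] for v in feats.variables})
        test_scores = X_test @ model.lambdas
        results.append(EvalResult(auc(train_scores, bg_scores),
                                  auc(test_scores, bg_scores), r, rep_seed))
    a_tr = np.array([e.auc_train for e in results])
    a_te = np.array([e.auc_test for e in results])
    summary = {
        "auc_train_mean": round(float(a_tr.mean()), 3),
        "auc_train_sd": round(float(a_tr.std(ddof=1)), 3) if n_replicates > 1 else 0.0,
        "auc_test_mean": round(float(a_te.mean()), 3),
        "auc_test_sd": round(float(a_te.std(ddof=1)), 3) if n_replicates > 1 else 0.0,
    }
    return results, summary
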