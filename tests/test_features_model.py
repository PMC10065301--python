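"""Feature expansion and the maximum-entropy fit: oracles and closed forms."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.special import logsumexp

import nichecast as nc
from nichecast.features import FeatureExpansion, feature_list
from nichecast.model import aicc_formula, feature_penalties
from nichecast.synthetic import default_geometry


# ---------------------------------------------------------------------------
# feature expansion
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "n_vars,fc,expected",
    [
        (2, "LQ", 4),             # L + Q per variable
        (3, "LQP", 9),            # 3 + 3 + C(3,2)
        (1, "L", 1),
        (2, "T", 2 * 10),         # 10 threshold knots per variable
        (2, "H", 2 * 2 * 10),     # forward + reverse hinges, 10 knots each
        (2, "LQPTH", 2 + 2 + 1 + 20 + 40),
    ],
)
def test_feature_counts(n_vars, fc, expected):
    names = [f"v{k}" for k in range(n_vars)]
    assert len(feature_list(names, fc)) == expected


def test_knots_strictly_interior():
    for f in feature_list(["v"], "TH"):
        assert 0.0 < f.knot < 1.0


def test_scaling_endpoints(small_suite):
    stack, _, _, occ = small_suite
    bg = nc.sample_background(stack, occ, 10_000, 0)
    feats = nc.build_features(stack, occ, bg, "L")
    col = feats.variables.index("env01")
    x = feats.X_background[:, col]
    assert x.min() == 0.0 and x.max() == 1.0
    assert np.all((x >= 0) & (x <= 1))


def test_constant_variable_excluded(small_grid, caplog):
    const = small_grid.copy()
    const.values[const.mask] = 7.0
    stack = nc.EnvStack({"flat": const, "ok": small_grid}, "current")
    occ = nc.OccurrenceSet(np.array([small_grid.cell_center(2, 2),
                                     small_grid.cell_center(3, 3)]))
    bg = nc.sample_background(stack, occ, 10_000, 0)
    feats = nc.build_features(stack, occ, bg, "L")
    assert feats.variables == ["ok"]


def test_projection_clamps_outside_training_range(small_model):
    _, _, _, feats, model = small_model
    lo, hi = feats.variable_stats["env01"]
    raw = {v: np.array([0.0]) for v in feats.variables}
    raw["env01"] = np.array([hi + 100.0])
    X = feats.design(raw)
    col = feats.variables.index("env01")
    assert X[0, col] == 1.0


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _tiny_problem(seed=0, n_bg=10, n_pres=4, n_feats=2):
    """A hand-sized expansion with explicit design matrices."""
    rng = np.random.default_rng(seed)
    Xb = rng.random((n_bg, n_feats))
    Xp = Xb[rng.choice(n_bg, n_pres, replace=True)] * 0.9 + 0.05
    feats = FeatureExpansion(
        variables=[f"v{k}" for k in range(n_feats)],
        variable_stats={f"v{k}": (0.0, 1.0) for k in range(n_feats)},
        features=[nc.features.Feature("linear", (f"v{k}",)) for k in range(n_feats)],
        fc=frozenset("L"),
        X_presence=Xp,
        X_background=Xb,
    )
    return feats


def _oracle_objective(lam, Xp, Xb, beta):
    return (-float(np.mean(Xp @ lam)) + float(logsumexp(Xb @ lam))
            + float(beta @ np.abs(lam)))


def _oracle_fit(feats, rm):
    """Generic convex minimiser on the positive/negative split (L-BFGS-B)."""
    Xp, Xb = feats.X_presence, feats.X_background
    beta = feature_penalties(feats, rm)
    J = Xb.shape[1]

    def obj(z):
        lam = z[:J] - z[J:]
        return _oracle_objective(lam, Xp, Xb, beta)

    res = minimize(obj, np.zeros(2 * J), method="L-BFGS-B",
                   bounds=[(0, None)] * 2 * J,
                   options={"maxiter": 5000, "ftol": 1e-14, "gtol": 1e-12})
    return res.x[:J] - res.x[J:], res.fun


@pytest.mark.parametrize("seed,rm", [(0, 1.0), (1, 0.5), (2, 2.0), (3, 1.0)])
def test_fit_matches_generic_convex_oracle(seed, rm):
    """On <=20-cell instances the objective matches L-BFGS-B to 1e-4."""
    feats = _tiny_problem(seed=seed, n_bg=10 + 5 * (seed % 3), n_feats=2 + seed % 3)
    model = nc.fit(feats, rm)
    beta = feature_penalties(feats, rm)
    ours = _oracle_objective(model.lambdas, feats.X_presence, feats.X_background, beta)
    _, oracle_val = _oracle_fit(feats, rm)
    assert ours == pytest.approx(oracle_val, abs=1e-4)


def test_fit_sign_forced_by_likelihood():
    """Presences concentrated at high feature values force lambda > 0."""
    Xb = np.linspace(0, 1, 20).reshape(-1, 1)
    feats = FeatureExpansion(
        variables=["v"], variable_stats={"v": (0.0, 1.0)},
        features=[nc.features.Feature("linear", ("v",))], fc=frozenset("L"),
        X_presence=np.array([[0.9], [0.95], [1.0], [0.85]]), X_background=Xb,
    )
    model = nc.fit(feats, 0.5)
    assert model.lambdas[0] > 0


def test_huge_rm_shrinks_to_null():
    feats = _tiny_problem(seed=4)
    model = nc.fit(feats, 1e6)
    assert model.n_nonzero == 0
    assert nc.training_gain(model) == pytest.approx(0.0, abs=1e-9)


def test_objective_trace_monotone(small_model):
    _, _, _, _, model = small_model
    t = np.array(model.objective_trace)
    assert np.all(np.diff(t) <= 1e-9)


def test_rm_sweep_monotone_sparsity(small_suite):
    """More regularization never increases the non-zero weight count."""
    stack, _, _, occ = small_suite
    bg = nc.sample_background(stack, occ, 10_000, 0)
    feats = nc.build_features(stack, occ, bg, "LQ")
    ks = [nc.fit(feats, rm).n_nonzero for rm in (0.25, 1.0, 4.0, 16.0, 64.0)]
    assert all(a >= b for a, b in zip(ks, ks[1:]))


def test_density_normalisation(small_model):
    _, _, _, _, model = small_model
    q = model.background_density()
    assert q.sum() == pytest.approx(1.0, abs=1e-9)
    assert 0.0 <= model.entropy_H <= np.log(len(q)) + 1e-9


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------

def test_null_model_closed_forms(small_suite):
    """All-zero weights: q = 1/N, H = log N, cloglog = 1 - 1/e everywhere."""
    stack, _, _, occ = small_suite
    bg = nc.sample_background(stack, occ, 10_000, 0)
    feats = nc.build_features(stack, occ, bg, "L")
    model = nc.fit(feats, 1e9)  # infinite regularization = null model
    n = len(feats.X_background)
    assert model.entropy_H == pytest.approx(np.log(n), abs=1e-9)
    raw = nc.predict(model, stack, output="raw")
    np.testing.assert_allclose(raw.valid_values, 1.0 / n, atol=1e-12)
    clog = nc.predict(model, stack, output="cloglog")
    np.testing.assert_allclose(clog.valid_values, 1.0 - np.exp(-1.0), atol=1e-9)


def test_cloglog_monotone_in_linear_score(small_model):
    stack, _, bg, feats, model = small_model
    clog = nc.predict(model, stack, output="cloglog")
    raw = nc.predict(model, stack, output="raw")
    order = np.argsort(raw.valid_values)
    assert np.all(np.diff(clog.valid_values[order]) >= 0)
    assert np.all((clog.valid_values > 0) & (clog.valid_values < 1))


def test_raw_sums_to_one_over_background(small_model):
    _, _, bg, feats, model = small_model
    raw_bg = model.scores(feats.raw_background, output="raw")
    assert raw_bg.sum() == pytest.approx(1.0, abs=1e-9)


def test_predict_propagates_nodata(small_model):
    stack, _, _, _, model = small_model
    pred = nc.predict(model, stack)
    np.testing.assert_array_equal(pred.mask, stack.mask)


# ---------------------------------------------------------------------------
# gain, AUC, AICc
# ---------------------------------------------------------------------------

def test_gain_hand_computed_on_five_cells():
    """Gain equals the hand-computed mean log(q_i * N) on an enumerated model."""
    Xb = np.array([[0.0], [0.25], [0.5], [0.75], [1.0]])
    Xp = np.array([[0.75], [1.0]])
    feats = FeatureExpansion(
        variables=["v"], variable_stats={"v": (0.0, 1.0)},
        features=[nc.features.Feature("linear", ("v",))], fc=frozenset("L"),
        X_presence=Xp, X_background=Xb,
    )
    lam = np.array([2.0])
    Z = np.exp(Xb @ lam).sum()
    model = nc.MaxentModel(lam, feats, float(np.log(Z)), 0.0, 1.0,
                           frozenset("L"), np.zeros(1))
    by_hand = np.mean([np.log(np.exp(2 * 0.75) / Z * 5), np.log(np.exp(2.0) / Z * 5)])
    assert nc.training_gain(model) == pytest.approx(by_hand, abs=1e-12)


def test_informative_gain_positive(small_model):
    _, _, _, _, model = small_model
    assert nc.training_gain(model) > 0.1


def test_auc_trivial_cases():
    assert nc.auc([3, 4, 5], [0, 1, 2]) == 1.0
    assert nc.auc([1, 2, 3], [1, 2, 3]) == 0.5


def test_auc_matches_pair_counting():
    """Mann-Whitney AUC equals brute-force enumeration of all pairs."""
    rng = np.random.default_rng(5)
    for _ in range(20):
        sp = rng.integers(0, 10, size=rng.integers(1, 50)).astype(float)
        sb = rng.integers(0, 10, size=rng.integers(1, 50)).astype(float)
        brute = np.mean([(1.0 if a > b else 0.5 if a == b else 0.0)
                         for a in sp for b in sb])
        assert nc.auc(sp, sb) == pytest.approx(brute, abs=1e-12)


def test_aicc_formula_cases():
    # k = 0 collapses to -2 LL
    assert aicc_formula(0, 50, -123.4) == pytest.approx(246.8)
    # direct evaluation: n=123, k=10, LL=-800
    assert aicc_formula(10, 123, -800.0) == pytest.approx(1621.9643, abs=1e-4)
    # boundary: undefined when n <= k + 1
    assert np.isnan(aicc_formula(9, 10, -5.0))


def test_aicc_renormalises_over_all_cells(small_model):
    stack, occ, _, _, model = small_model
    res = nc.aicc(model, stack, occ)
    assert res.valid
    raw = nc.predict(model, stack, output="raw")
    cells = occ.cells(stack.grid)
    p_hat = raw.values[cells[:, 0], cells[:, 1]] / raw.valid_values.sum()
    ll = np.sum(np.log(p_hat))
    assert res.loglik == pytest.approx(ll, abs=1e-9)
    assert res.aicc == pytest.approx(aicc_formula(res.k, len(occ), ll), abs=1e-9)


# ---------------------------------------------------------------------------
# importance, response curves, replicated evaluation
# ---------------------------------------------------------------------------

def test_contributions_normalised_and_deterministic(small_model):
    _, _, _, feats, model = small_model
    a = nc.percent_contribution(model, feats, seed=7)
    b = nc.percent_contribution(model, feats, seed=7)
    assert sum(a.values()) == pytest.approx(100.0, abs=1e-9)
    assert a == b
    assert min(a.values()) >= 0.0


def test_contribution_identifies_true_driver(small_model):
    _, _, _, feats, model = small_model
    contrib = nc.percent_contribution(model, feats, seed=7)
    # env01 is the only informative variable (env03 is its 0.9-correlate)
    assert max(contrib, key=contrib.get) in ("env01", "env03")
    assert contrib["env01"] > contrib["env02"]
    assert contrib["env01"] > contrib["env04"]


def test_jackknife_structure_and_ordering(small_suite):
    stack, _, _, occ = small_suite
    bg = nc.sample_background(stack, occ, 10_000, 0)
    jk = nc.jackknife_gain(stack, occ, bg, "L", 1.0)
    V = len(stack.variables)
    assert len(jk["with_only"]) == V and len(jk["without"]) == V  # 2V + 1 gains
    # nested-model ordering, with slack for the L1 penalty (gains are the
    # unpenalised objective part evaluated at penalised optima)
    for v in stack.variables:
        assert jk["without"][v] <= jk["full"] + 1e-3
    # the informative driver dominates an uncorrelated noise layer alone
    assert jk["with_only"]["env01"] > jk["with_only"]["env02"] + 0.1


def test_response_curve_monotone_for_linear_model(small_model):
    _, _, _, _, model = small_model
    curve, _ = nc.response_curve(model, "env01", n_points=50)
    assert curve.shape == (50, 2)
    lam = model.lambdas[model.feature_meta.variables.index("env01")]
    diffs = np.diff(curve[:, 1])
    assert np.all(diffs >= -1e-12) if lam >= 0 else np.all(diffs <= 1e-12)


def test_response_curve_suitable_range_matches_dense_scan(small_model):
    _, _, _, _, model = small_model
    curve, rng_ = nc.response_curve(model, "env01", n_points=500, threshold=0.5)
    scan = curve[curve[:, 1] >= 0.5, 0]
    if scan.size:
        assert rng_ == (pytest.approx(scan.min()), pytest.approx(scan.max()))
    else:
        assert rng_ is None


def test_replicate_eval_counts_and_split(small_suite):
    stack, _, _, occ = small_suite
    results, summary = nc.replicate_eval(stack, occ, "L", 1.0, n_replicates=5,
                                         test_fraction=0.25, seed=3)
    assert len(results) == 5
    assert len({r.seed for r in results}) == 5  # distinct derived seeds
    assert all(0.0 <= r.auc_test <= 1.0 for r in results)
    assert set(summary) == {"auc_train_mean", "auc_train_sd",
                            "auc_test_mean", "auc_test_sd"}


def test_split_sizes_floor_arithmetic():
    """m=123 at 25% test -> 30 test / 93 train."""
    m = 123
    n_test = int(np.floor(0.25 * m))
    assert (n_test, m - n_test) == (30, 93)
    geom = default_geometry(40, 40)
    spec = nc.TruthSpec(true_weights={"env01": 2.0})
    stack = nc.make_env_stack(2, geom, spec, seed=31)
    occ = nc.sample_thinned_occurrences(nc.true_suitability(stack, spec), m, seed=32)
    results, _ = nc.replicate_eval(stack, occ, "L", 1.0, 2, 0.25, seed=33)
    assert len(results) == 2
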