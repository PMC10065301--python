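"""Feature expansion for the presence/background maximum-entropy model.

Variables are min-max scaled to [0, 1] using the *background* range, then
expanded into the classic feature classes:

====  =====================================================================
L     linear: the scaled value itself
Q     quadratic: squared scaled value
P     product: pairwise products of scaled values (all distinct pairs)
T     threshold: step indicators 1{v > knot} at equally spaced interior knots
H     hinge: forward ramps max(0, (v-k)/(1-k)) and reverse ramps
      max(0, (k-v)/k) at equally spaced interior knots
====  =====================================================================

During projection onto a new landscape, scaled values are clamped to
[0, 1] (no extrapolation outside the training range).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .errors import SpecificationError
from .grids import EnvStack
from .occurrences import OccurrenceSet

logger = logging.getLogger(__name__)

FEATURE_CLASSES = ("L", "Q", "P", "T", "H")

#: default interior knot counts per variable
N_THRESHOLD_KNOTS = 10
N_HINGE_KNOTS = 10


@dataclass(frozen=True)
class Feature:
    """One design column: kind, source variable(s), optional knot in (0,1)."""

    kind: str  # linear | quadratic | product | threshold | forward_hinge | reverse_hinge
    variables: tuple[str, ...]
    knot: float | None = None

    @property
    def feature_class(self) -> str:
        return {
            "linear": "L",
            "quadratic": "Q",
            "product": "P",
            "threshold": "T",
            "forward_hinge": "H",
            "reverse_hinge": "H",
        }[self.kind]


@dataclass
class FeatureExpansion:
    """Scaling stats, feature list and design matrices at presences/background."""

    variables: list[str]
    variable_stats: dict[str, tuple[float, float]]
    features: list[Feature]
    fc: frozenset
    raw_presence: dict[str, np.ndarray] = field(default_factory=dict)
    raw_background: dict[str, np.ndarray] = field(default_factory=dict)
    X_presence: np.ndarray | None = None
    X_background: np.ndarray | None = None
    background_cells: np.ndarray | None = None

    @property
    def n_features(self) -> int:
        return len(self.features)

    def scale(self, name: str, values: np.ndarray) -> np.ndarray:
        lo, hi = self.variable_stats[name]
        return np.clip((np.asarray(values, dtype=float) - lo) / (hi - lo), 0.0, 1.0)

    def design(self, raw: dict[str, np.ndarray]) -> np.ndarray:
        """Design matrix for raw per-variable value arrays (clamped scaling)."""
        scaled = {v: self.scale(v, raw[v]) for v in self.variables}
        n = len(next(iter(scaled.values()))) if scaled else 0
        X = np.empty((n, self.n_features))
        for col, f in enumerate(self.features):
            if f.kind == "linear":
                X[:, col] = scaled[f.variables[0]]
            elif f.kind == "quadratic":
                X[:, col] = scaled[f.variables[0]] ** 2
            elif f.kind == "product":
                X[:, col] = scaled[f.variables[0]] * scaled[f.variables[1]]
            elif f.kind == "threshold":
                X[:, col] = (scaled[f.variables[0]] > f.knot).astype(float)
            elif f.kind == "forward_hinge":
                X[:, col] = np.maximum(0.0, (scaled[f.variables[0]] - f.knot) / (1.0 - f.knot))
            elif f.kind == "reverse_hinge":
                X[:, col] = np.maximum(0.0, (f.knot - scaled[f.variables[0]]) / f.knot)
            else:  # pragma: no cover
                raise ValueError(f.kind)
        return X


def _interior_knots(k: int) -> np.ndarray:
    return np.linspace(0.0, 1.0, k + 2)[1:-1]


def feature_list(variables: list[str], fc) -> list[Feature]:
    """Enumerate features for a variable list and feature-class subset."""
    fc = frozenset(fc)
    bad = fc - set(FEATURE_CLASSES)
    if bad or not fc:
        raise SpecificationError(f"feature classes must be a non-empty subset of LQPTH, got {sorted(fc)}")
    feats: list[Feature] = []
    if "L" in fc:
        feats += [Feature("linear", (v,)) for v in variables]
    if "Q" in fc:
        feats += [Feature("quadratic", (v,)) for v in variables]
    if "P" in fc:
        feats += [Feature("product", (a, b)) for a, b in combinations(variables, 2)]
    if "T" in fc:
        feats += [Feature("threshold", (v,), float(k))
                  for v in variables for k in _interior_knots(N_THRESHOLD_KNOTS)]
    if "H" in fc:
        feats += [Feature("forward_hinge", (v,), float(k))
                  for v in variables for k in _interior_knots(N_HINGE_KNOTS)]
        feats += [Feature("reverse_hinge", (v,), float(k))
                  for v in variables for k in _interior_knots(N_HINGE_KNOTS)]
    return feats


def sample_background(stack: EnvStack, occ: OccurrenceSet, background_size: int = 10_000,
                      seed: int = 0) -> np.ndarray:
    """Background cell sample: all valid cells if few enough, else a seeded
    uniform sample; presence cells are always included."""
    grid = stack.grid
    valid = np.argwhere(grid.mask)
    pres_cells = occ.cells(grid)
    if len(valid) <= background_size:
        return valid
    rng = np.random.default_rng(seed)
    pick = rng.choice(len(valid), size=background_size, replace=False)
    chosen = valid[np.sort(pick)]
    both = np.vstack([chosen, pres_cells])
    return np.unique(both, axis=0)


def build_features(stack: EnvStack, occ: OccurrenceSet, background: np.ndarray,
                   fc) -> FeatureExpansion:
    """Expand a stack into design matrices at presences and background cells.

    Constant variables (background min == max) carry no information under
    min-max scaling and are excluded with a warning.
    """
    raw_bg = stack.values_at_cells(background)
    raw_pres = stack.values_at_cells(occ.cells(stack.grid))
    stats: dict[str, tuple[float, float]] = {}
    used: list[str] = []
    for name in stack.variables:
        lo, hi = float(raw_bg[name].min()), float(raw_bg[name].max())
        if hi <= lo:
            logger.warning("build_features: variable %r is constant on background; excluded", name)
            continue
        stats[name] = (lo, hi)
        used.append(name)
    feats = feature_list(used, fc)
    exp = FeatureExpansion(
        variables=used,
        variable_stats=stats,
        features=feats,
        fc=frozenset(fc),
        raw_presence={v: raw_pres[v] for v in used},
        raw_background={v: raw_bg[v] for v in used},
        background_cells=np.asarray(background),
    )
    exp.X_presence = exp.design(exp.raw_presence)
    exp.X_background = exp.design(exp.raw_background)
    return exp
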