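"""Variable and model selection.

Two layers, mirroring standard ENM practice:

1.  **Variable selection** — drop variables with zero percent
    contribution, then resolve collinear pairs: among each pair whose
    Pearson |r| at the occurrence points exceeds a threshold (default
    0.85), the lower-contribution variable is dropped.  Pairs are
    processed in descending |r| so transitive chains resolve
    deterministically.

2.  **Model selection** — a full grid of (regularization multiplier,
    feature-class combination) candidates, each fitted and scored by
    small-sample AICc over the presences; the candidate with minimum
    AICc (delta.AICc = 0) is selected, with deterministic tie-breaks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .errors import NichecastError, SelectionError
from .features import FEATURE_CLASSES, build_features
from .grids import EnvStack
from .model import aicc, fit
from .occurrences import OccurrenceSet

logger = logging.getLogger(__name__)

CORRELATION_THRESHOLD = 0.85


# ---------------------------------------------------------------------------
# variable selection
# ---------------------------------------------------------------------------

def pearson_matrix(stack: EnvStack, occ: OccurrenceSet) -> pd.DataFrame:
    """Pairwise Pearson r between variables at the occurrence cells.

    Zero-variance variables get r = 0 against everything (flagged in the
    log) so they can never trigger the collinearity rule.
    """
    if len(occ) < 3:
        raise NichecastError("pearson_matrix requires at least 3 occurrences")
    cells = occ.cells(stack.grid)
    vals = stack.values_at_cells(cells)
    names = stack.variables
    mat = np.eye(len(names))
    stds = {n: float(np.std(vals[n])) for n in names}
    for n in names:
        if stds[n] == 0:
            logger.warning("pearson_matrix: %r has zero variance at occurrences", n)
    for a_i, b_i in combinations(range(len(names)), 2):
        a, b = names[a_i], names[b_i]
        if stds[a] == 0 or stds[b] == 0:
            r = 0.0
        else:
            r = float(np.corrcoef(vals[a], vals[b])[0, 1])
        mat[a_i, b_i] = mat[b_i, a_i] = r
    return pd.DataFrame(mat, index=names, columns=names)


@dataclass
class VariableSelection:
    contributions: dict[str, float]
    correlation: pd.DataFrame
    retained: list[str]
    dropped: list[tuple[str, str]]  # (variable, reason)


def collinearity_filter(contribs: dict[str, float], corr: pd.DataFrame,
                        threshold: float = CORRELATION_THRESHOLD) -> VariableSelection:
    """Zero-contribution drop, then greedy collinear-pair resolution.

    Pairs with |r| > threshold are scanned in descending |r| (ties by
    variable names); in each pair where both members are still retained,
    the lower-contribution one is dropped (contribution ties keep the
    alphabetically first).  The result never contains a retained pair
    above the threshold.
    """
    names = sorted(contribs)
    if set(names) != set(corr.index):
        raise NichecastError("contributions and correlation matrix cover different variables")
    retained = set()
    dropped: list[tuple[str, str]] = []
    for v in names:
        if contribs[v] > 0:
            retained.add(v)
        else:
            dropped.append((v, "zero-contribution"))
    pairs = [(abs(float(corr.loc[a, b])), a, b)
             for a, b in combinations(names, 2)]
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
    for r_abs, a, b in pairs:
        if r_abs <= threshold:
            break
        if a in retained and b in retained:
            ca, cb = contribs[a], contribs[b]
            # keep the higher contribution; alphabetically first on ties
            if ca == cb:
                loser, winner = max(a, b), min(a, b)
            elif ca > cb:
                loser, winner = b, a
            else:
                loser, winner = a, b
            retained.discard(loser)
            dropped.append((loser, f"collinear-with-{winner}"))
    order = {v: i for i, v in enumerate(corr.index)}
    return VariableSelection(
        contributions=dict(contribs),
        correlation=corr,
        retained=sorted(retained, key=lambda v: order.get(v, 0)),
        dropped=dropped,
    )


# ---------------------------------------------------------------------------
# model selection
# ---------------------------------------------------------------------------

def all_feature_combinations() -> list[str]:
    """All 31 non-empty subsets of {L,Q,P,T,H}, in L-Q-P-T-H canonical order."""
    out = []
    for r in range(1, len(FEATURE_CLASSES) + 1):
        out += ["".join(c) for c in combinations(FEATURE_CLASSES, r)]
    return out


def default_rm_values(n: int = 40, lo: float = 0.1, hi: float = 40.0) -> list[float]:
    """Log-spaced regularization-multiplier grid spanning [lo, hi]."""
    return [float(v) for v in np.geomspace(lo, hi, n)]


def _canon_fc(fc) -> str:
    s = frozenset(fc)
    bad = s - set(FEATURE_CLASSES)
    if bad:
        raise NichecastError(f"unknown feature classes: {sorted(bad)}")
    return "".join(c for c in FEATURE_CLASSES if c in s)


def candidate_grid(rm_values, fc_combos) -> list[tuple[float, str]]:
    """Full cross product (fc-major, rm-minor), deduplicated with a warning."""
    if not rm_values or not fc_combos:
        raise NichecastError("rm_values and fc_combos must be non-empty")
    rms, seen_rm = [], set()
    for rm in rm_values:
        if rm <= 0:
            raise NichecastError(f"regularization multiplier must be > 0, got {rm}")
        if rm not in seen_rm:
            seen_rm.add(rm)
            rms.append(float(rm))
    fcs, seen_fc = [], set()
    for fc in fc_combos:
        c = _canon_fc(fc)
        if c not in seen_fc:
            seen_fc.add(c)
            fcs.append(c)
    if len(rms) < len(rm_values) or len(fcs) < len(fc_combos):
        logger.warning("candidate_grid: duplicate grid entries deduplicated")
    return [(rm, fc) for fc in fcs for rm in rms]


@dataclass
class CandidateResult:
    rm: float
    fc: str
    aicc: float
    delta_aicc: float
    k: int
    loglik: float
    mean_test_auc: float = float("nan")
    valid: bool = True


def run_candidates(grid: list[tuple[float, str]], stack: EnvStack,
                   occ: OccurrenceSet, background: np.ndarray) -> list[CandidateResult]:
    """Fit and AICc-score every (rm, fc) candidate.

    delta.AICc is computed against the minimum over valid candidates
    (those with presence count > k + 1).
    """
    results: list[CandidateResult] = []
    for rm, fc in grid:
        feats = build_features(stack, occ, background, fc)
        model = fit(feats, rm)
        res = aicc(model, stack, occ)
        results.append(CandidateResult(rm, fc, res.aicc, float("nan"),
                                       res.k, res.loglik, valid=res.valid))
    valid = [r for r in results if r.valid]
    if not valid:
        raise SelectionError("no valid candidate (all have n <= k + 1)")
    best = min(r.aicc for r in valid)
    for r in results:
        r.delta_aicc = r.aicc - best if r.valid else float("nan")
    return results


def select_best(results: list[CandidateResult]) -> CandidateResult:
    """Minimum-AICc candidate; ties by smaller k, smaller rm, lexicographic fc."""
    valid = [r for r in results if r.valid and np.isfinite(r.aicc)]
    if not valid:
        raise SelectionError("no valid candidates to select from")
    return min(valid, key=lambda r: (r.aicc, r.k, r.rm, r.fc))


def candidates_table(results: list[CandidateResult]) -> pd.DataFrame:
    """Ranked candidate report (rm, fc, k, loglik, AICc, delta.AICc)."""
    df = pd.DataFrame(
        [
            {"rm": r.rm, "fc": r.fc, "k": r.k, "loglik": r.loglik,
             "AICc": r.aicc, "delta.AICc": r.delta_aicc, "valid": r.valid}
            for r in results
        ]
    )
    return df.sort_values(["delta.AICc", "k", "rm", "fc"],
                          na_position="last").reset_index(drop=True)
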