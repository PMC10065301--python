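"""End-to-end orchestration: fit, select, project, zone, compare.

``run_pipeline`` chains the stages in study order: background sampling,
candidate-model selection over the (rm, feature-combination) grid, final
fit, per-scenario projection and zoning, area reports against the
current scenario, stable/expand/shrink overlays, class transitions and
the centroid trajectory.  Outputs are a pure function of
(config, inputs, seed); a machine-readable manifest records the
configuration and library versions.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .change import CentroidTrack, ChangeMap, centroid_track, change_proportions, overlay, binary_suitable
from .config import RunConfig
from .errors import EmptyInputError
from .features import build_features, sample_background
from .grids import EnvStack, RasterGrid, write_esri_ascii
from .model import MaxentModel, fit, predict, replicate_eval
from .occurrences import OccurrenceSet, thin_per_cell
from .selection import CandidateResult, candidate_grid, candidates_table, run_candidates, select_best
from .suitability import AreaReport, ClassifiedMap, area_report, classify, max_sss_threshold

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    """Everything a run produces, keyed by scenario where applicable."""

    config: RunConfig
    best: CandidateResult
    model: MaxentModel
    threshold_P: dict[str, float]
    continuous: dict[str, RasterGrid]
    classified: dict[str, ClassifiedMap]
    areas: dict[str, AreaReport]
    changes: dict[str, ChangeMap]
    change_props: dict[str, dict]
    track: CentroidTrack | None
    eval_summary: dict
    manifest: dict = field(default_factory=dict)


def _scenario_order(stacks: dict[str, EnvStack]) -> list[str]:
    others = sorted(k for k in stacks if k != "current")
    return ["current"] + others


def run_pipeline(config: RunConfig, stacks: dict[str, EnvStack],
                 occ: OccurrenceSet, outdir: str | Path | None = None) -> PipelineResult:
    """Run the full analysis; optionally write all artifacts under *outdir*."""
    if "current" not in stacks:
        raise EmptyInputError("stacks must include a 'current' scenario")
    if len(occ) == 0:
        raise EmptyInputError("occurrence set is empty")
    current = stacks["current"]
    for label, stack in stacks.items():
        current.check_aligned(stack)

    occ = thin_per_cell(occ, current.grid) if not occ.thinned else occ
    background = sample_background(current, occ, config.background_size, config.seed)

    grid = candidate_grid(config.rm_values, config.feature_combinations)
    results = run_candidates(grid, current, occ, background)
    best = select_best(results)
    logger.info("selected rm=%.3g fc=%s (AICc=%.2f, k=%d)", best.rm, best.fc, best.aicc, best.k)

    feats = build_features(current, occ, background, best.fc)
    model = fit(feats, best.rm)
    _, eval_summary = replicate_eval(current, occ, best.fc, best.rm,
                                     config.n_replicates, config.test_fraction,
                                     config.seed, config.background_size)

    order = _scenario_order(stacks)
    continuous = {lab: predict(model, stacks[lab], output="cloglog") for lab in order}

    pres_cells = occ.cells(current.grid)
    cur_map = continuous["current"]
    pres_scores = cur_map.values[pres_cells[:, 0], pres_cells[:, 1]]
    bg_scores = cur_map.values[background[:, 0], background[:, 1]]
    P_current = max_sss_threshold(pres_scores, bg_scores)

    threshold_P: dict[str, float] = {}
    classified: dict[str, ClassifiedMap] = {}
    areas: dict[str, AreaReport] = {}
    for lab in order:
        if config.reestimate_threshold_per_scenario and lab != "current":
            sc = continuous[lab]
            P = max_sss_threshold(sc.values[pres_cells[:, 0], pres_cells[:, 1]],
                                  sc.values[background[:, 0], background[:, 1]])
        else:
            P = P_current
        threshold_P[lab] = P
        classified[lab] = classify(continuous[lab], P, config.class_breaks)
    base_report = area_report(classified["current"])
    areas["current"] = base_report
    for lab in order[1:]:
        areas[lab] = area_report(classified[lab], baseline=base_report)

    changes: dict[str, ChangeMap] = {}
    change_props: dict[str, dict] = {}
    cur_mask = binary_suitable(classified["current"])
    for lab in order[1:]:
        cm = overlay(cur_mask, binary_suitable(classified[lab]), current.grid,
                     ("current", lab))
        changes[lab] = cm
        change_props[lab] = change_proportions(cm)

    track = centroid_track([(lab, classified[lab]) for lab in order])

    manifest = {
        "config": config.to_dict(),
        "seed": config.seed,
        "scenarios": order,
        "n_presences": len(occ),
        "n_background": int(len(background)),
        "selected": {"rm": best.rm, "fc": best.fc, "aicc": best.aicc, "k": best.k},
        "versions": {
            "nichecast": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
        },
    }

    result = PipelineResult(config, best, model, threshold_P, continuous,
                            classified, areas, changes, change_props, track,
                            eval_summary, manifest)
    if outdir is not None:
        _write_bundle(result, results, Path(outdir))
    return result


def _write_bundle(res: PipelineResult, candidates: list[CandidateResult],
                  outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(res.manifest, fh, indent=1, sort_keys=True)
    candidates_table(candidates).to_csv(outdir / "candidates.csv", index=False)
    with open(outdir / "model.json", "w", encoding="utf-8") as fh:
        fh.write(res.model.to_json())
    for lab in res.continuous:
        safe = lab.replace("/", "_")
        write_esri_ascii(res.continuous[lab], outdir / f"suitability_{safe}.asc")
        write_esri_ascii(res.classified[lab].classes, outdir / f"classes_{safe}.asc")
    for lab, cm in res.changes.items():
        write_esri_ascii(cm.classes, outdir / f"change_{lab.replace('/', '_')}.asc")
    report = {
        "threshold_P": res.threshold_P,
        "areas": {
            lab: {
                "class_areas_1e4km2": r.class_areas,
                "total_suitable_1e4km2": r.total_suitable,
                "shares_pct": r.shares,
                "percent_change": r.percent_change,
            }
            for lab, r in res.areas.items()
        },
        "change_proportions_pct": res.change_props,
        "eval": res.eval_summary,
        "centroid_track": {
            "points": res.track.points,
            "segments": res.track.segments,
            "overall": res.track.overall,
        } if res.track else None,
    }
    with open(outdir / "report.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
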