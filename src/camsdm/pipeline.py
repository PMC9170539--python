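"""End-to-end scenario orchestration.

A *scenario* is one predictor set run through the whole design: surface
range envelope fit on all thinned presences, seeded pseudo-absence
realizations, one supervised dataset per realization, a grid of
(algorithm x realization x repeat) learner runs each with its own
stratified 60/40 split, and a performance-weighted ensemble with
uncertainty map, pooled-held-out scores, permutation importance and a
binary suitable-area total.

Scenario 1 is the bioclim-only predictor set; scenarios 2–5 each add
exactly one derived index (Hellmann–Eberle quotient, aridity index,
cloud cover, R-index).  At the full design — 2 algorithms x 5 PA
realizations x 10 repeats — each scenario fits 100 individual models,
500 across the five scenarios.

All randomness flows from one master seed through
:func:`camsdm.seeds.derive_seed`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import areas as area_mod
from . import ensemble as ens_mod
from . import envelope as env_mod
from . import modeling
from .grid import RasterLayer, RasterStack
from .occurrences import OccurrenceSet, extract_predictors, thin_per_cell
from .seeds import derive_seed

__all__ = [
    "BIOCLIM_PREDICTORS",
    "SCENARIO_EXTRAS",
    "ScenarioConfig",
    "ScenarioReport",
    "scenario_predictors",
    "plan_runs",
    "run_scenario",
    "compare_scenarios",
    "write_report",
]

logger = logging.getLogger("camsdm")

BIOCLIM_PREDICTORS = (
    "mean_diurnal_range",
    "min_temp_coldest_month",
    "annual_precip",
    "precip_seasonality",
)

SCENARIO_EXTRAS = {
    1: None,
    2: "hellmann_eberle_q",
    3: "aridity_index",
    4: "cloud_cover",
    5: "r_index",
}


def scenario_predictors(scenario_id: int) -> list[str]:
    """Predictor names of a numbered scenario (bioclim core + one extra)."""
    if scenario_id not in SCENARIO_EXTRAS:
        raise ValueError(f"scenario_id must be in {sorted(SCENARIO_EXTRAS)}")
    extra = SCENARIO_EXTRAS[scenario_id]
    return list(BIOCLIM_PREDICTORS) + ([extra] if extra else [])


@dataclass(frozen=True)
class ScenarioConfig:
    """Everything one scenario run depends on, besides the input rasters."""

    scenario_id: int
    predictors: tuple[str, ...]
    species: str = ""
    algorithms: tuple[str, ...] = modeling.ALGORITHMS
    n_pa_realizations: int = 5
    n_repeats: int = 10
    sre_quantile: float = 0.025
    train_fraction: float = 0.6
    weighting_metric: str = "tss"
    min_roc: float = 0.5
    n_importance_shuffles: int = 10
    thin_cell_size: float = 1.0
    thin_max_per_cell: int = 5
    master_seed: int = 0

    @classmethod
    def for_scenario(cls, scenario_id: int, **kwargs) -> "ScenarioConfig":
        return cls(scenario_id=scenario_id, predictors=tuple(scenario_predictors(scenario_id)), **kwargs)

    def __post_init__(self) -> None:
        if self.n_pa_realizations < 1 or self.n_repeats < 1:
            raise ValueError("need at least one PA realization and one repeat")
        for a in self.algorithms:
            if a not in modeling.ALGORITHMS:
                raise ValueError(f"unknown algorithm {a!r}")


@dataclass(frozen=True)
class RunKey:
    algorithm: str
    pa_index: int
    repeat_index: int


def plan_runs(config: ScenarioConfig) -> list[RunKey]:
    """The full run grid: every (algorithm, PA realization, repeat) triple."""
    return [
        RunKey(a, p, r)
        for a in config.algorithms
        for p in range(1, config.n_pa_realizations + 1)
        for r in range(1, config.n_repeats + 1)
    ]


@dataclass
class ScenarioReport:
    """Artifacts of one scenario run."""

    config: ScenarioConfig
    ledger: pd.DataFrame  # one row per individual model run
    ensemble: ens_mod.EnsembleModel
    mean_map: RasterLayer
    cv_map: RasterLayer
    binary_map: RasterLayer
    envelope_map: RasterLayer
    importance: pd.DataFrame
    suitable_area_mkm2: float
    n_presences_used: int
    tables: list[pd.DataFrame] = field(default_factory=list)
    member_maps: list[RasterLayer] = field(default_factory=list)

    @property
    def scores(self) -> dict:
        return self.ensemble.ensemble_scores


def run_scenario(
    config: ScenarioConfig,
    stack: RasterStack,
    presences: OccurrenceSet,
    region_mask: RasterLayer | None = None,
    thin: bool = True,
) -> ScenarioReport:
    """Run one scenario end to end; deterministic given (config, inputs)."""
    missing = [p for p in config.predictors if p not in stack]
    if missing:
        raise ValueError(f"input stack is missing predictor layers {missing}")
    sub = stack.subset(config.predictors)
    seed = config.master_seed

    if thin:
        presences = thin_per_cell(
            presences,
            cell_size=config.thin_cell_size,
            max_per_cell=config.thin_max_per_cell,
            seed=derive_seed(seed, "thin"),
        )
    pres_rows, n_dropped = extract_predictors(presences, sub)
    logger.info(
        "scenario %d: %d presences (%d dropped on nodata/extent)",
        config.scenario_id, len(pres_rows), n_dropped,
    )

    sre = env_mod.fit_sre(pres_rows[list(config.predictors)], quantile=config.sre_quantile)
    envelope_map = env_mod.sre_predict(sub, sre)
    realizations = env_mod.sample_pseudoabsences(
        sub,
        envelope_map,
        presences,
        n_per_realization=len(pres_rows),
        n_realizations=config.n_pa_realizations,
        seed=derive_seed(seed, "pa"),
    )
    datasets = {pa.index: modeling.make_dataset(pres_rows, pa, sub) for pa in realizations}

    members: list[modeling.ModelRun] = []
    member_tables: list[pd.DataFrame] = []
    member_maps: list[RasterLayer] = []
    rows = []
    for key in plan_runs(config):
        run = modeling.ModelRun(
            learner=modeling.LearnerSpec(
                algorithm=key.algorithm,
                seed=derive_seed(seed, "learner", key.algorithm, key.pa_index, key.repeat_index),
            ),
            pa_index=key.pa_index,
            repeat_index=key.repeat_index,
        )
        table = datasets[key.pa_index]
        split_seed = derive_seed(seed, "split", key.algorithm, key.pa_index, key.repeat_index)
        modeling.fit_and_score(run, table, config.train_fraction, split_seed)
        members.append(run)
        member_tables.append(table)
        member_maps.append(modeling.project_map(run, sub))
        rows.append(
            {
                "scenario": config.scenario_id,
                "species": config.species,
                "algorithm": key.algorithm,
                "pa_index": key.pa_index,
                "repeat_index": key.repeat_index,
                "learner_seed": run.learner.seed,
                "split_seed": split_seed,
                **run.scores,
            }
        )
    ledger = pd.DataFrame(rows)

    weights = ens_mod.compute_weights(members, metric=config.weighting_metric, min_roc=config.min_roc)
    mean_map = ens_mod.weighted_mean_map(member_maps, weights)
    cv = ens_mod.cv_map(member_maps)
    scores, cutoff = ens_mod.ensemble_evaluate(members, weights, member_tables)
    model = ens_mod.EnsembleModel(
        members=members,
        weights=weights,
        weighting_metric=config.weighting_metric,
        min_roc=config.min_roc,
        ensemble_cutoff=cutoff,
        ensemble_scores=scores,
    )
    # pooled reference table: presences + every PA realization, deduplicated
    pooled = pd.concat(
        [datasets[realizations[0].index]]
        + [datasets[pa.index][datasets[pa.index]["label"] == 0] for pa in realizations[1:]],
        ignore_index=True,
    )
    importance = ens_mod.variable_importance(
        model, pooled, n_shuffles=config.n_importance_shuffles, seed=derive_seed(seed, "importance")
    )
    binary = area_mod.binarize(mean_map, cutoff)
    cell_areas = area_mod.cell_area_layer(stack.grid)
    total_area = area_mod.suitable_area(binary, cell_areas, mask=region_mask)

    return ScenarioReport(
        config=config,
        ledger=ledger,
        ensemble=model,
        mean_map=mean_map,
        cv_map=cv,
        binary_map=binary,
        envelope_map=envelope_map,
        importance=importance,
        suitable_area_mkm2=total_area,
        n_presences_used=len(pres_rows),
        tables=member_tables,
        member_maps=member_maps,
    )


@dataclass
class ComparisonBundle:
    """Scenario 2+ vs scenario-1 baseline: deviations, score deltas, areas."""

    deviation_maps: dict[int, RasterLayer]
    score_deltas: pd.DataFrame
    area_table: pd.DataFrame
    missing_scenarios: list[int] = field(default_factory=list)


def compare_scenarios(reports: dict[int, ScenarioReport]) -> ComparisonBundle:
    """Compare scenarios against the bioclim-only baseline (scenario 1)."""
    if 1 not in reports:
        raise ValueError("scenario 1 (baseline) report is required")
    base = reports[1]
    species = base.config.species
    deviations: dict[int, RasterLayer] = {}
    deltas = []
    area_rows = []
    missing = [sid for sid in (2, 3, 4, 5) if sid not in reports]
    for sid in sorted(reports):
        rep = reports[sid]
        if rep.mean_map.grid != base.mean_map.grid:
            raise ValueError(f"scenario {sid} is on a different grid")
        if rep.config.species != species:
            raise ValueError(f"scenario {sid} is for a different species")
        area_rows.append(
            {"scenario": sid, "species": species, "region": "all", "suitable_area_mkm2": rep.suitable_area_mkm2}
        )
        if sid == 1:
            continue
        deviations[sid] = area_mod.deviation_map(rep.mean_map, base.mean_map)
        deltas.append(
            {
                "scenario": sid,
                "delta_tss": rep.scores["tss"] - base.scores["tss"],
                "delta_roc_auc": rep.scores["roc_auc"] - base.scores["roc_auc"],
            }
        )
    if missing:
        logger.info("compare_scenarios: scenarios %s not provided", missing)
    return ComparisonBundle(
        deviation_maps=deviations,
        score_deltas=pd.DataFrame(deltas),
        area_table=pd.DataFrame(area_rows),
        missing_scenarios=missing,
    )


def write_report(report: ScenarioReport, outdir) -> None:
    """Write one scenario's CSV artifacts (ledger, scores, importance, area)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report.ledger.to_csv(outdir / "run_ledger.csv", index=False)
    scores = {k: round(v, 3) for k, v in report.scores.items()}
    pd.DataFrame(
        [
            {
                "scenario": report.config.scenario_id,
                "species": report.config.species,
                **scores,
                "cutoff": round(report.ensemble.ensemble_cutoff, 3),
            }
        ]
    ).to_csv(outdir / "ensemble_scores.csv", index=False)
    imp = report.importance.copy()
    imp["pct"] = imp["pct"].round(1)
    imp.to_csv(outdir / "variable_importance.csv", index_label="predictor")
    pd.DataFrame(
        [
            {
                "scenario": report.config.scenario_id,
                "species": report.config.species,
                "region": "all",
                "suitable_area_mkm2": round(report.suitable_area_mkm2, 3),
            }
        ]
    ).to_csv(outdir / "suitable_area.csv", index=False)
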