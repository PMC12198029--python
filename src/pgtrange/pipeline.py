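"""End-to-end pipeline: simulate → preprocess → extract → train → evaluate.

The pipeline reproduces the study design: static spots per (energy,
cavity) split into exclude/train/test in delivery order, scanned spots as
a test-only set, and scanned spots accumulated over consecutive layers as
a third evaluation dataset.  Per data subset (one per beam energy plus an
energy-overarching one when several energies are present) the full
configuration grid is trained and the best configuration — lowest
cross-validated RMSE — is evaluated on every test dataset with bootstrap
confidence intervals, plus configuration-level median aggregations.

Everything is reproducible from (configuration, master seed); evaluation
tables are byte-stable across reruns.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import evaluate as ev
from .features import (
    FEATURE_SET_NAMES,
    META_COLUMNS,
    assemble_feature_sets,
    extract_spot_features,
    feature_columns,
    normalize_to_reference,
)
from .modeling import GridResult, LearnerParams, predict, run_grid
from .preprocess import correct_background, correct_phase_shift
from .simulate import (
    SimConfig,
    StudyDesign,
    accumulate_scanned_layers,
    generate_study,
)
from .spectra import (
    TIME_BIN_WIDTH_NS,
    BinningSpec,
    EventList,
    Spectrum2D,
    bin_events,
    project_time,
)

__all__ = [
    "PipelineConfig",
    "PipelineReport",
    "StageError",
    "run_pipeline",
    "simulate_stage",
    "preprocess_stage",
    "extract_stage",
    "train_stage",
    "evaluate_stage",
    "write_feature_table",
    "read_feature_table",
]


class StageError(RuntimeError):
    """A pipeline stage failed; ``stage`` names it."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass(frozen=True)
class PipelineConfig:
    """Pipeline configuration; defaults mirror the full study design.

    :meth:`desk_scale` returns a reduced configuration (one energy, fewer
    spots and events, smaller tree ensembles) that exercises every stage in
    minutes on one CPU.
    """

    sim: SimConfig = field(default_factory=SimConfig)
    design: StudyDesign = field(default_factory=StudyDesign)
    learner_params: LearnerParams = field(default_factory=LearnerParams)
    feature_sets: tuple[str, ...] = ("time", "ert", "energy", "image")
    max_signature: int = 10
    background_quantile: float = 0.10
    background_tol: float = 1e-3
    bootstrap_samples: int = 1000
    confidence_level: float = 0.95

    @classmethod
    def desk_scale(cls) -> "PipelineConfig":
        return cls(
            sim=SimConfig(events_per_1e9_protons=2000.0),
            design=StudyDesign(
                energies=(162.0,),
                static_spots=18,
                static_exclude=4,
                static_train=9,
                static_test=5,
                scanned_layers=8,
                scanned_per_layer=2,
                accum_layers=8,
            ),
            learner_params=LearnerParams(rf_trees=25, xgb_rounds=25),
        )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs: dict = {}
        if "sim" in raw:
            kwargs["sim"] = SimConfig(**raw["sim"])
        if "design" in raw:
            design = dict(raw["design"])
            for key in ("energies", "cavities_mm"):
                if key in design:
                    design[key] = tuple(design[key])
            kwargs["design"] = StudyDesign(**design)
        if "modeling" in raw:
            modeling = dict(raw["modeling"])
            kwargs["max_signature"] = modeling.pop("max_signature", 10)
            kwargs["learner_params"] = LearnerParams(**modeling)
        if "features" in raw:
            kwargs["feature_sets"] = tuple(raw["features"].get("sets", cls.feature_sets))
        if "evaluation" in raw:
            evaluation = raw["evaluation"]
            kwargs["bootstrap_samples"] = evaluation.get("bootstrap_samples", 1000)
            kwargs["confidence_level"] = evaluation.get("confidence_level", 0.95)
        if "background" in raw:
            background = raw["background"]
            kwargs["background_quantile"] = background.get("quantile", 0.10)
            kwargs["background_tol"] = background.get("tol", 1e-3)
        return cls(**kwargs)

    @property
    def binning(self) -> BinningSpec:
        n = int(round(self.sim.t_rf_ns / TIME_BIN_WIDTH_NS))
        return BinningSpec(n_time_bins=n)


@dataclass
class PipelineReport:
    """In-memory artefacts of one pipeline run."""

    manifest: pd.DataFrame
    tables: dict[str, pd.DataFrame]
    grids: dict[str, GridResult]
    eval_tables: dict[str, pd.DataFrame]
    config_results: dict[str, pd.DataFrame]
    aggregations: dict[str, dict[str, pd.DataFrame]]
    outdir: Path | None = None


# ---------------------------------------------------------------------------
# stages


def simulate_stage(config: PipelineConfig, seed: int) -> list[EventList]:
    """Generate the study's event lists plus layer-accumulated scanned spots."""
    sim = replace(config.sim, seed=int(seed) % (2**31))
    spots = generate_study(config.design, sim)
    if config.design.include_scanned:
        spots = spots + accumulate_scanned_layers(spots, config.design.accum_layers)
    return spots


def manifest_frame(spots: list[EventList]) -> pd.DataFrame:
    rows = [
        {
            "spot_id": s.meta.spot_id,
            "beam_energy": s.meta.beam_energy,
            "mode": s.meta.mode,
            "dataset": s.meta.dataset,
            "cavity_mm": s.meta.cavity_mm,
            "split": s.meta.split,
            "layer_index": s.meta.layer_index,
            "n_protons": s.meta.n_protons,
            "n_events": len(s),
            "seed": s.meta.seed,
        }
        for s in spots
    ]
    return pd.DataFrame(rows).set_index("spot_id")


def preprocess_stage(spots: list[EventList], config: PipelineConfig) -> list[Spectrum2D]:
    """Bin, background-correct and phase-align every spot.

    The phase template of each (energy, dataset) group is the summed
    background-corrected time projection of its ΔR = 0 spots (the
    reference measurement); train-labelled reference spots are preferred
    where the group has them.
    """
    binning = config.binning
    corrected: list[Spectrum2D] = []
    for s in spots:
        spec, _ = bin_events(s, binning)
        corrected.append(
            correct_background(
                spec, quantile=config.background_quantile, tol=config.background_tol
            )
        )
    templates: dict[tuple, np.ndarray] = {}
    for key in {(c.meta.beam_energy, c.meta.dataset) for c in corrected}:
        members = [
            c
            for c in corrected
            if (c.meta.beam_energy, c.meta.dataset) == key and c.meta.cavity_mm == 0
        ]
        train_members = [c for c in members if c.meta.split == "train"]
        members = train_members or members
        if not members:
            raise StageError(
                "preprocess", f"no ΔR = 0 reference spots for group {key} (phase template)"
            )
        templates[key] = np.sum([project_time(c) for c in members], axis=0)
    return [
        correct_phase_shift(c, templates[(c.meta.beam_energy, c.meta.dataset)])
        for c in corrected
    ]


def extract_stage(
    spectra: list[Spectrum2D], feature_sets: tuple[str, ...]
) -> dict[str, pd.DataFrame]:
    """Extract, assemble and reference-normalise the feature tables.

    Normalisation runs once on the combined table; per-set tables are
    column slices of it, so shared features are identical across tables.
    """
    rows = [(s.meta, extract_spot_features(s, sets=feature_sets)) for s in spectra]
    tables = assemble_feature_sets(rows)
    combined = normalize_to_reference(tables["combined"])
    out: dict[str, pd.DataFrame] = {}
    for set_name in feature_sets:
        cols = [c for c in combined.columns if c.startswith(f"{set_name}:")]
        out[set_name] = combined[list(META_COLUMNS) + cols]
    if len(feature_sets) > 1:
        out["combined"] = combined
    return out


def _subset_keys(config: PipelineConfig) -> dict[str, tuple[float, ...]]:
    energies = tuple(config.design.energies)
    subsets = {f"{e:g}MeV": (e,) for e in energies}
    if len(energies) > 1:
        subsets["combined_" + "_".join(f"{e:g}" for e in energies)] = energies
    return subsets


def train_stage(
    tables: dict[str, pd.DataFrame], config: PipelineConfig, seed: int
) -> dict[str, GridResult]:
    """Run the configuration grid for every data subset."""
    grids: dict[str, GridResult] = {}
    for idx, (name, energies) in enumerate(sorted(_subset_keys(config).items())):
        subset_tables = {
            set_name: table[table["beam_energy"].isin(energies)]
            for set_name, table in tables.items()
        }
        subset_seed = int((seed * 1000003 + 7919 * idx) % (2**31))
        grids[name] = run_grid(
            subset_tables,
            seed=subset_seed,
            params=config.learner_params,
            max_size=config.max_signature,
        )
    return grids


def _dataset_label(dataset: str, energy: float) -> str:
    return f"{dataset}_{energy:g}"


def evaluate_stage(
    tables: dict[str, pd.DataFrame],
    grids: dict[str, GridResult],
    config: PipelineConfig,
    seed: int,
):
    """Evaluate each subset's best configuration on every test dataset and
    aggregate all configurations by setup parameter."""
    subsets = _subset_keys(config)
    eval_tables: dict[str, pd.DataFrame] = {}
    config_results: dict[str, pd.DataFrame] = {}
    aggregations: dict[str, dict[str, pd.DataFrame]] = {}
    for name, grid in grids.items():
        energies = subsets[name]
        any_table = next(iter(tables.values()))
        test_mask = (any_table["split"] == "test") & any_table["beam_energy"].isin(energies)
        if not test_mask.any():
            raise StageError("evaluate", f"no rows labelled split='test' in subset {name}")
        best = grid.best
        best_table = tables[best.feature_set]
        rows = []
        datasets = sorted(
            {
                (r.dataset, r.beam_energy)
                for r in any_table[test_mask].itertuples()
            }
        )
        for ds_i, (dataset, energy) in enumerate(datasets):
            sel = best_table[
                (best_table["split"] == "test")
                & (best_table["dataset"] == dataset)
                & (best_table["beam_energy"] == energy)
            ]
            y_true = sel["cavity_mm"].to_numpy(dtype=float)
            y_pred = predict(best, sel)
            b = config.bootstrap_samples
            lvl = config.confidence_level
            ci_r = ev.bootstrap_ci(y_true, y_pred, "rmse", B=b, level=lvl, seed=seed + 2 * ds_i)
            ci_m = ev.bootstrap_ci(y_true, y_pred, "mrse", B=b, level=lvl, seed=seed + 2 * ds_i + 1)
            rows.append(
                {
                    "dataset": _dataset_label(dataset, energy),
                    "config": best.config_name,
                    "signature_size": best.chosen_k,
                    "n_spots": len(sel),
                    "rmse_mm": ev.rmse(y_true, y_pred),
                    "rmse_ci_low": ci_r[0],
                    "rmse_ci_high": ci_r[1],
                    "mrse_mm": ev.mrse(y_true, y_pred),
                    "mrse_ci_low": ci_m[0],
                    "mrse_ci_high": ci_m[1],
                }
            )
        eval_tables[name] = pd.DataFrame(rows)

        tidy = []
        for model in grid.models:
            table = tables[model.feature_set]
            for dataset, energy in datasets:
                sel = table[
                    (table["split"] == "test")
                    & (table["dataset"] == dataset)
                    & (table["beam_energy"] == energy)
                ]
                if sel.empty:
                    continue
                y_true = sel["cavity_mm"].to_numpy(dtype=float)
                y_pred = predict(model, sel)
                label = _dataset_label(dataset, energy)
                for metric, fn in (("rmse", ev.rmse), ("mrse", ev.mrse)):
                    tidy.append(
                        {
                            "feature_set": model.feature_set,
                            "ranking": model.ranking_method,
                            "learner": model.learner,
                            "dataset": label,
                            "metric": metric,
                            "value": fn(y_true, y_pred),
                        }
                    )
        config_results[name] = pd.DataFrame(tidy)
        aggregations[name] = {
            key: ev.aggregate_configurations(config_results[name], key)
            for key in ("feature_set", "learner", "ranking")
        }
    return eval_tables, config_results, aggregations


# ---------------------------------------------------------------------------
# feature-table I/O (delimited text with the metadata block as columns)


def write_feature_table(path, table: pd.DataFrame) -> None:
    table.to_csv(path, index_label="spot_id")


def read_feature_table(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="spot_id")


# ---------------------------------------------------------------------------
# orchestration


def run_pipeline(config: PipelineConfig, seed: int, outdir) -> PipelineReport:
    """Execute all stages and write every artefact under ``outdir``.

    Fully reproducible from (config, seed): two runs write byte-identical
    evaluation tables.  A failing stage raises :class:`StageError` naming
    the stage; artefacts of completed stages are retained.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: list[str] = [f"master_seed={seed}", f"config={config!r}"]

    def _run(stage: str, fn, *args):
        try:
            return fn(*args)
        except StageError:
            raise
        except Exception as exc:  # noqa: BLE001 - stage-named abort per contract
            raise StageError(stage, str(exc)) from exc

    spots = _run("simulate", simulate_stage, config, seed)
    manifest = manifest_frame(spots)
    manifest.to_csv(outdir / "manifest.csv")
    log.append(f"simulate: {len(spots)} spots, {int(manifest['n_events'].sum())} events")

    spectra = _run("preprocess", preprocess_stage, spots, config)
    log.append(f"preprocess: {len(spectra)} spectra corrected")

    tables = _run("extract", extract_stage, spectra, config.feature_sets)
    for set_name, table in tables.items():
        write_feature_table(outdir / f"features_{set_name}.csv", table)
    log.append(
        "extract: "
        + ", ".join(f"{k}={len(feature_columns(v))} features" for k, v in tables.items())
    )

    grids = _run("train", train_stage, tables, config, seed)
    summary_rows = []
    bundles: dict[str, dict[str, bytes]] = {}
    for subset, grid in sorted(grids.items()):
        bundles[subset] = {m.config_name: m.to_bytes() for m in grid.models}
        for m in grid.models:
            summary_rows.append(
                {
                    "subset": subset,
                    "config": m.config_name,
                    "chosen_k": m.chosen_k,
                    "cv_rmse_mm": m.best_cv_rmse,
                    "signature": "|".join(m.signature),
                    "is_best": m.config_name == grid.best.config_name,
                }
            )
    pd.DataFrame(summary_rows).to_csv(outdir / "models_summary.csv", index=False)
    with open(outdir / "models.pkl", "wb") as fh:
        pickle.dump(bundles, fh, protocol=5)
    log.append("train: " + ", ".join(f"{k}: {len(g.models)} configs" for k, g in grids.items()))

    eval_tables, config_results, aggregations = _run(
        "evaluate", evaluate_stage, tables, grids, config, seed
    )
    for subset, table in eval_tables.items():
        table.to_csv(outdir / f"evaluation_{subset}.csv", index=False)
        config_results[subset].to_csv(outdir / f"config_results_{subset}.csv", index=False)
        for key, agg in aggregations[subset].items():
            agg.to_csv(outdir / f"aggregation_{subset}_{key}.csv", index=False)
        log.append(f"evaluate: {subset} best={grids[subset].best.config_name}")

    (outdir / "run_log.txt").write_text("\n".join(log) + "\n")
    return PipelineReport(
        manifest=manifest,
        tables=tables,
        grids=grids,
        eval_tables=eval_tables,
        config_results=config_results,
        aggregations=aggregations,
        outdir=outdir,
    )
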