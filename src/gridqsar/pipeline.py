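"""End-to-end pipeline orchestration: align -> fields -> filter -> split ->
select -> fit -> validate -> (optionally) pharmacophore -> screen.

Configuration is a validated :class:`RunConfig`; every run writes a manifest
with the config hash and seeds so numeric outputs are reproducible from the
manifest alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator

from . import chem, fields, pharmacophore, qsar, screening, validation

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name for diagnostics."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


class GridSettings(BaseModel):
    margin: float = fields.DEFAULT_MARGIN
    spacing: float = fields.DEFAULT_SPACING
    dielectric: float = 1.0
    cutoff: float = fields.DEFAULT_CUTOFF
    variance_cutoff: float = 0.1


class ModelSettings(BaseModel):
    max_descriptors: int = 4
    max_components: int | None = None
    n_permutations: int = 100
    run_randomization: bool = True


class PharmacophoreSettings(BaseModel):
    enabled: bool = False
    max_sites: int = 5
    distance_bin: float = 1.0
    site_tolerance: float = 2.0
    active_min_pic50: float | None = None

    @field_validator("max_sites")
    @classmethod
    def _sites_range(cls, v: int) -> int:
        if not 3 <= v <= 7:
            raise ValueError("max_sites must be in 3..7")
        return v


class ScreenSettings(BaseModel):
    enabled: bool = False
    library_path: str | None = None
    external_scores_path: str | None = None
    top_n: int | None = None
    fitness_threshold: float | None = None


class RunConfig(BaseModel):
    """Validated pipeline configuration; defaults match standard practice for
    grid-field QSAR (dielectric 1.0, four descriptors in the final equation,
    variance cutoff 0.1, up to five pharmacophore sites)."""

    structures_path: str
    activities_path: str
    template: str
    reference_id: str | None = None
    rmsd_cutoff: float = 1.0
    test_ids: list[str] = Field(default_factory=list)
    n_test: int = 5
    grid: GridSettings = Field(default_factory=GridSettings)
    model: ModelSettings = Field(default_factory=ModelSettings)
    pharmacophore: PharmacophoreSettings = Field(default_factory=PharmacophoreSettings)
    screen: ScreenSettings = Field(default_factory=ScreenSettings)
    seed: int = 42

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text())
        return cls.model_validate(data)

    def config_hash(self) -> str:
        return hashlib.sha256(
            self.model_dump_json().encode()).hexdigest()[:16]


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, str(exc)) from exc
        return wrapped
    return deco


@_stage("input")
def _load_inputs(config: RunConfig):
    mols = chem.read_molecules(config.structures_path, embed_seed=config.seed)
    activities = chem.read_activities(config.activities_path)
    return mols, activities


@_stage("align")
def _align(config: RunConfig, mols, activities):
    act = {a.compound_id: a.pic50 for a in activities}
    if config.reference_id:
        reference = next((m for m in mols if m.id == config.reference_id), None)
        if reference is None:
            raise ValueError(f"reference {config.reference_id!r} not found")
    else:  # most active molecule is the alignment reference
        scored = [m for m in mols if m.id in act]
        if not scored:
            raise ValueError("no molecule has an activity record")
        reference = max(scored, key=lambda m: act[m.id])
    charged = [chem.assign_peoe_charges(m) for m in mols]
    ref_charged = next(m for m in charged if m.id == reference.id)
    results = chem.select_congeners(charged, config.template, ref_charged,
                                    rmsd_cutoff=config.rmsd_cutoff)
    return [r.molecule for r in results]


@_stage("fields")
def _compute_matrix(config: RunConfig, aligned, activities):
    grid = fields.build_grid(aligned, margin=config.grid.margin,
                             spacing=config.grid.spacing)
    matrix = fields.assemble_descriptor_matrix(
        aligned, activities, grid,
        dielectric=config.grid.dielectric, cutoff=config.grid.cutoff)
    filtered = fields.filter_invariant_columns(matrix,
                                               config.grid.variance_cutoff)
    return grid, filtered


@_stage("split")
def _split(config: RunConfig, matrix):
    if config.test_ids:
        train = [c for c in matrix.compound_ids if c not in set(config.test_ids)]
        split = qsar.SplitSpec.from_lists(train, config.test_ids)
    else:
        split = qsar.split_interpolative(matrix, config.n_test, config.seed)
    uni = {
        "Training": qsar.unicolumn_stats(matrix.subset(split.train_ids).y),
        "Test": qsar.unicolumn_stats(matrix.subset(split.test_ids).y),
    }
    ok, messages = qsar.check_split_interpolative(
        matrix.subset(split.train_ids).y.tolist(),
        matrix.subset(split.test_ids).y.tolist())
    if not ok:
        logger.warning("test set is not interpolative: %s", "; ".join(messages))
    return split, uni, ok


@_stage("model")
def _fit_model(config: RunConfig, matrix, split):
    selected = qsar.stepwise_forward_select(matrix, split,
                                            config.model.max_descriptors)
    model = qsar.fit_pls(matrix, split, selected,
                         max_components=config.model.max_components)
    return selected, model


@_stage("validate")
def _validate(config: RunConfig, matrix, split, model):
    recipe = validation.ModelRecipe(
        max_descriptors=config.model.max_descriptors,
        n_components=model.n_components,
        max_components=config.model.max_components)
    return validation.validate_model(
        matrix, split, model, recipe,
        n_permutations=config.model.n_permutations,
        seed=config.seed,
        run_randomization=config.model.run_randomization)


@_stage("pharmacophore")
def _pharmacophore(config: RunConfig, aligned, activities):
    act = {a.compound_id: a.pic50 for a in activities}
    threshold = config.pharmacophore.active_min_pic50
    actives = [m for m in aligned
               if threshold is None or act.get(m.id, -np.inf) >= threshold]
    if len(actives) < 2:
        raise ValueError("fewer than 2 actives above the activity threshold")
    hypotheses = pharmacophore.enumerate_hypotheses(
        actives, max_sites=config.pharmacophore.max_sites,
        distance_bin=config.pharmacophore.distance_bin)
    inactives = [m for m in aligned if m not in actives] or None
    scored = [(h, pharmacophore.score_hypothesis(
        h, actives, inactives,
        tolerance=config.pharmacophore.site_tolerance,
        distance_bin=config.pharmacophore.distance_bin))
        for h in hypotheses]
    return pharmacophore.rank_hypotheses(scored) if scored else []


@_stage("screen")
def _screen(config: RunConfig, best_hypothesis, model, grid, reference_mol):
    library = chem.read_molecules(config.screen.library_path,
                                  embed_seed=config.seed)
    results = screening.screen_library(
        best_hypothesis, library, model, grid,
        top_n=config.screen.top_n,
        tolerance=config.pharmacophore.site_tolerance,
        reference_mol=reference_mol)
    if config.screen.fitness_threshold is not None:
        results = [r for r in results
                   if r.matched and r.fitness >= config.screen.fitness_threshold]
    if config.screen.external_scores_path:
        results = screening.merge_external_scores(
            results, config.screen.external_scores_path, rerank=True)
    return results


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Execute all configured stages and write artifacts to ``outdir``.

    Returns a summary dict (also written as ``manifest.json``) whose
    ``results_hash`` is a digest of the numeric outputs, so reruns with the
    same config are verifiably identical.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mols, activities = _load_inputs(config)
    aligned = _align(config, mols, activities)
    grid, matrix = _compute_matrix(config, aligned, activities)
    split, uni, interpolative = _split(config, matrix)
    selected, model = _fit_model(config, matrix, split)
    report = _validate(config, matrix, split, model)
    contributions = qsar.contribution_percentages(model, matrix,
                                                  list(split.train_ids))

    (outdir / "model.json").write_text(model.to_json())
    (outdir / "grid.json").write_text(grid.to_json())
    (outdir / "validation.json").write_text(report.to_json())
    uni_df = pd.DataFrame({name: stats.as_row() for name, stats in uni.items()}).T
    uni_df.index.name = "Set"
    uni_df.to_csv(outdir / "unicolumn.csv")
    report.to_table().to_csv(outdir / "randomization.csv", index=False)

    hypotheses_summary = []
    screen_summary = []
    if config.pharmacophore.enabled:
        ranked = _pharmacophore(config, aligned, activities)
        hypotheses_summary = [{
            "ID": h.id, "Survival": s.survival,
            "Survival-inactive": s.survival_inactive,
            "Selectivity": s.selectivity, "Matches": s.matches,
        } for h, s in ranked]
        pd.DataFrame(hypotheses_summary).to_csv(outdir / "hypotheses.csv",
                                                index=False)
        if config.screen.enabled and ranked:
            best_h = ranked[0][0]
            ref = next((m for m in aligned if m.id == best_h.source_id), None)
            results = _screen(config, best_h, model, grid, ref)
            screening.results_table(results).to_csv(outdir / "hits.csv",
                                                    index=False)
            screen_summary = [r.compound_id for r in results]

    numeric = {
        "selected": selected,
        "coefficients": model.coefficients,
        "intercept": model.intercept,
        "r2": report.r2, "q2": report.q2, "pred_r2": report.pred_r2,
        "contributions": contributions,
    }
    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_aligned": len(aligned),
        "split": {"train": list(split.train_ids), "test": list(split.test_ids)},
        "interpolative": interpolative,
        "selected_descriptors": selected,
        "n_hypotheses": len(hypotheses_summary),
        "screen_hits": screen_summary,
        "results_hash": hashlib.sha256(
            json.dumps(numeric, sort_keys=True).encode()).hexdigest(),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
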