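"""End-to-end pipeline: layers + occurrences + tree + clades in, tables out.

Stages: niche models (with variable screening), overlap matrix, PNO
profiles, Brownian-motion niche history, disparity through time. Every
stochastic stage draws its seed deterministically from the master seed (per
species, by a stable hash of the species name), so a rerun with the same
config is byte-identical; the manifest records per-stage output hashes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .enm import (
    ENMSettings,
    binarize_mtp,
    build_background,
    build_features,
    fit_maxent,
    fit_species_model,
    minimum_convex_polygon,
    select_top_variables,
    stack_richness,
    variable_contribution,
)
from .dtt import dtt_pipeline
from .niche_history import reconstruct_history
from .occurrences import MIN_POINTS, read_occurrences
from .overlap import overlap_matrix
from .phylo import CladeMap, read_newick
from .pno import compute_pno, profiles_to_csv
from .rasters import RasterStack, read_ascii_grid, write_ascii_grid

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "validate_inputs"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


@dataclass
class PipelineConfig:
    """All paths and knobs of a pipeline run; defaults follow the study
    protocol (50 PNO bins, 100 reconstruction draws, 1000 null simulations,
    10 variables kept, 10000 background points, 80/20 splits)."""

    layers_dir: str
    occurrences: str
    tree: str
    clades: str
    out_dir: str
    enm: ENMSettings = field(default_factory=ENMSettings)
    n_bins: int = 50
    n_draws: int = 100
    n_sim: int = 1000
    n_keep_variables: int = 10
    n_permutations: int = 10
    density_mass: float = 0.8
    metric: str = "squared"
    strict: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        enm_data = data.pop("enm", {})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**data, enm=ENMSettings(**enm_data))

    def species_seed(self, stage: str, species: str = "") -> np.random.Generator:
        """Stable per-stage, per-species generator derived from the master
        seed by CRC32 hashing of the labels."""
        key = [self.seed, zlib.crc32(stage.encode())]
        if species:
            key.append(zlib.crc32(species.encode()))
        return np.random.default_rng(np.random.SeedSequence(key))


def _load_inputs(config: PipelineConfig):
    layers_dir = Path(config.layers_dir)
    paths = sorted(layers_dir.glob("*.asc"))
    if not paths:
        raise FileNotFoundError(f"no .asc layers in {layers_dir}")
    stack = RasterStack([read_ascii_grid(p) for p in paths])
    tree = read_newick(config.tree)
    occ = read_occurrences(config.occurrences, stack.spec)
    clades = CladeMap.read_csv(config.clades)
    return stack, tree, occ, clades


def validate_inputs(config: PipelineConfig) -> list[str]:
    """Cross-check the inputs; returns a list of problems (empty if clean).

    Problems are reported, not thrown — ``run_pipeline`` aborts on them only
    under ``strict`` (or when they make a stage impossible).
    """
    issues: list[str] = []
    try:
        stack, tree, occ, clades = _load_inputs(config)
    except Exception as exc:  # unreadable inputs are reported, not raised
        return [f"cannot load inputs: {exc}"]
    occ_species = {o.species for o in occ}
    tips = set(tree.tip_labels)
    for missing in sorted(tips - occ_species):
        issues.append(f"tree tip {missing!r} has no occurrence records")
    for extra in sorted(occ_species - tips):
        issues.append(f"occurrence species {extra!r} is not a tree tip")
    for o in occ:
        if len(o) < MIN_POINTS:
            issues.append(
                f"species {o.species!r} has {len(o)} spatially unique points "
                f"(minimum {MIN_POINTS})"
            )
    try:
        clades.validate(tree)
    except ValueError as exc:
        issues.append(str(exc))
    return issues


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage; returns the results directory.

    Outputs: per-species RAW surfaces and binary maps (.asc), a richness
    map, the model-evaluation CSV, the overlap matrix CSV, per-variable PNO
    CSVs, niche-history CSVs, DTT curve and MDI CSVs, and a manifest JSON
    with seeds and per-file hashes.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": config.seed, "stages": []}
    written: list[Path] = []

    def stage(name):
        def wrap(fn):
            t0 = time.perf_counter()
            manifest["stages"].append(name)
            try:
                fn()
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            dt = time.perf_counter() - t0
            logger.info("stage=%s seed=%d elapsed=%.2fs", name, config.seed, dt)

        return wrap

    issues = validate_inputs(config)
    for msg in issues:
        logger.warning("validation: %s", msg)
    if issues and config.strict:
        raise PipelineError(f"stage 'validate' failed: {len(issues)} problems: {issues}")
    stack, tree, occ_sets, clades = _load_inputs(config)
    occ_by_species = {o.species: o for o in occ_sets}
    species_list = [s for s in tree.tip_labels if s in occ_by_species]

    state: dict = {}

    @stage("enm")
    def _enm():
        pooled = [pt for o in occ_sets for pt in o.points]
        polygon = minimum_convex_polygon(pooled)
        background = build_background(
            polygon,
            stack,
            config.enm.background_n,
            config.species_seed("background"),
        )
        # variable screening: one all-points fit per species on every layer
        if config.n_keep_variables < len(stack):
            features_all = build_features(stack, background)
            screen_reports = []
            for sp in species_list:
                res = fit_maxent(
                    occ_by_species[sp],
                    background,
                    features_all,
                    beta=config.enm.beta,
                    max_iter=config.enm.max_iter,
                )
                contrib = variable_contribution(
                    res,
                    occ_by_species[sp],
                    n_permutations=config.n_permutations,
                    seed=config.species_seed("screen", sp),
                )
                screen_reports.append(
                    dataclasses.replace(
                        _report_stub(sp, occ_by_species[sp]), contributions=contrib
                    )
                )
            selected = select_top_variables(screen_reports, config.n_keep_variables)
        else:
            selected = list(stack.names)
        substack = stack.subset(sorted(selected))
        state["stack"] = substack
        features = build_features(substack, background)
        surfaces, reports, binaries = [], [], []
        for sp in species_list:
            occ = occ_by_species[sp]
            surface, report, final = fit_species_model(
                occ,
                background,
                features,
                config.enm,
                config.species_seed("fit", sp),
            )
            contrib = variable_contribution(
                final,
                occ,
                n_permutations=config.n_permutations,
                seed=config.species_seed("contrib", sp),
            )
            report = dataclasses.replace(report, contributions=contrib)
            surfaces.append(surface)
            reports.append(report)
            binaries.append(binarize_mtp(surface, occ))
            p = out / f"surface_{sp}.asc"
            surface.write_asc(p)
            written.append(p)
        rows = []
        for r in reports:
            row = {
                "species": r.species,
                "n_points": r.n_points,
                "auc": round(r.auc, 4),
                "replicates": r.replicates,
            }
            row.update({v: round(p, 2) for v, p in sorted(r.contributions.items())})
            rows.append(row)
        p = out / "enm_report.csv"
        pd.DataFrame(rows).to_csv(p, index=False)
        written.append(p)
        richness = stack_richness(binaries)
        p = out / "richness.asc"
        write_ascii_grid(richness, p)
        written.append(p)
        state["surfaces"] = surfaces

    @stage("overlap")
    def _overlap():
        matrix = overlap_matrix(state["surfaces"], clade_map=clades)
        p = out / "overlap_matrix.csv"
        matrix.write_csv(p)
        written.append(p)

    @stage("pno")
    def _pno():
        profiles: dict[str, dict] = {}
        for layer in state["stack"]:
            per_var = {}
            for surface in state["surfaces"]:
                per_var[surface.species] = compute_pno(
                    surface, layer, n_bins=config.n_bins
                )
            profiles[layer.name] = per_var
            p = out / f"pno_{layer.name}.csv"
            profiles_to_csv(list(per_var.values()), p)
            written.append(p)
        state["profiles"] = profiles

    @stage("reconstruct")
    def _reconstruct():
        for variable, per_var in state["profiles"].items():
            rec = reconstruct_history(
                tree,
                per_var,
                n_draws=config.n_draws,
                seed=config.species_seed("reconstruct", variable),
                mass=config.density_mass,
            )
            p = out / f"history_{variable}.csv"
            rec.summarize().to_csv(p, index=False)
            written.append(p)

    @stage("dtt")
    def _dtt():
        results = dtt_pipeline(
            tree,
            state["profiles"],
            clade_map=clades,
            n_sim=config.n_sim,
            seed=config.species_seed("dtt"),
            metric=config.metric,
        )
        tables = []
        for variable, res in results.items():
            table = res.mdi_table()
            table["seed"] = config.seed
            tables.append(table)
            p = out / f"dtt_curve_{variable}.csv"
            res.curve_table().to_csv(p, index=False)
            written.append(p)
        p = out / "mdi.csv"
        pd.concat(tables, ignore_index=True).to_csv(p, index=False)
        written.append(p)

    @stage("manifest")
    def _manifest():
        manifest["files"] = {p.name: _sha256(p) for p in sorted(written)}
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=1, sort_keys=True) + "\n"
        )

    return out


def _report_stub(species, occ):
    from .enm import EvaluationReport

    return EvaluationReport(
        species=species,
        n_points=len(occ),
        n_train=len(occ),
        n_test=len(occ),
        auc=float("nan"),
    )
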