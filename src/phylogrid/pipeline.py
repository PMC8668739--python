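"""End-to-end runner: occurrences + rasters + tree -> diversity maps.

Stage order (fixed): bias layer -> per-species model tuning and selection
-> suitability -> max-aggregation -> maxSSS threshold -> binarize (or
point fallback) -> crop to region -> presence-absence matrix -> indices
with randomization nulls -> turnover, bioregions and RGB composition.

Species whose models cannot be fit degrade to their raw presence points
with a prominent warning rather than aborting the community analysis; a
configured fallback list forces the same path for named species.

Every run is reproducible from (inputs, seed): all randomness flows from
one ``numpy.random.SeedSequence`` split in a fixed order (bias background,
species background sample, per-species evaluation, null ensemble).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
import yaml

from . import diversity, rasterops, sdm, turnover
from ._rng import as_seedseq
from .grids import RasterStack, write_ascii_grid
from .io import read_occurrences, read_region, read_tree, write_manifest
from .trees import prune_to_taxa

__all__ = ["PipelineConfig", "run_pipeline", "run_analysis"]

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything a full run needs; serializable to/from YAML."""

    occurrences: str
    env_dir: str
    tree: str
    out_dir: str
    region: str | None = None  # WKT, .wkt or GeoJSON path; None = full extent
    feature_classes: tuple = sdm.FEATURE_CLASS_COMBOS
    rms: tuple = sdm.RM_GRID
    n_background: int = 10_000
    auc_filter: float = 0.6
    n_hinge_knots: int = 10
    aggregation_factor: int = 100
    n_null: int = 999
    k_clusters: int = 4
    seed: int = 0
    point_fallback_species: tuple = ()

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("feature_classes", "rms", "point_fallback_species"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def validate_paths(self) -> None:
        for key in ("occurrences", "env_dir", "tree"):
            p = Path(getattr(self, key))
            if not p.exists():
                raise FileNotFoundError(f"{key}: {p} does not exist")


def run_analysis(
    occurrences: pd.DataFrame,
    env: RasterStack,
    tree: dendropy.Tree,
    *,
    region=None,
    feature_classes=sdm.FEATURE_CLASS_COMBOS,
    rms=sdm.RM_GRID,
    n_background: int = 10_000,
    auc_filter: float = 0.6,
    n_hinge_knots: int = 10,
    aggregation_factor: int = 100,
    n_null: int = 999,
    k_clusters: int = 4,
    seed: int = 0,
    point_fallback_species=(),
) -> dict:
    """Run the whole analysis in memory and return all artifacts.

    Returns a dict with keys ``bias, background, suitability, candidates,
    selected, thresholds, fallback, pam, indices, simpson, phylosor,
    clusters, rgb, linkages``.
    """
    root = as_seedseq(seed)
    seed_bias, seed_bg, seed_eval, seed_null = root.spawn(4)

    tips = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    occ = occurrences[occurrences["species"].isin(tips)].copy()
    skipped = sorted(set(occurrences["species"]) - tips)
    if skipped:
        log.warning("species absent from the tree skipped: %s", skipped)
    species = sorted(occ["species"].unique())
    if not species:
        raise ValueError("no occurrence species match the tree tips")

    settings = sdm.settings_grid(feature_classes, rms)
    log.info("tuning grid: %d candidate settings", len(settings))

    bias = sdm.make_bias_layer(occ, env, seed_bias, n_background=n_background)
    background = sdm.sample_background(bias, env, n=n_background, seed=seed_bg)

    suitability: dict[str, np.ndarray] = {}
    fallback: list[str] = []
    selected: dict[str, sdm.ModelSettings] = {}
    candidate_rows = []
    eval_streams = dict(zip(species, seed_eval.spawn(len(species))))
    for sp in species:
        pts = occ[occ["species"] == sp]
        pres_env = env.values_at(pts["lon"].to_numpy(), pts["lat"].to_numpy())
        ok = np.isfinite(pres_env).all(axis=1)
        pres_env, lon, lat = (
            pres_env[ok],
            pts["lon"].to_numpy()[ok],
            pts["lat"].to_numpy()[ok],
        )
        forced = sp in set(point_fallback_species)
        if forced or len(pres_env) < 3:
            if not forced:
                log.warning("%s: fewer than 3 usable points, falling back to points", sp)
            fallback.append(sp)
            continue
        try:
            folds = sdm.partition_occurrences(lon, lat, background.lon, background.lat)
            results = {}
            for st in settings:
                results[st] = sdm.evaluate_settings(
                    pres_env,
                    background.env,
                    st,
                    folds,
                    n_hinge_knots=n_hinge_knots,
                )
            best = sdm.select_model(results, auc_filter=auc_filter)
            for st, m in results.items():
                candidate_rows.append(
                    {
                        "species": sp,
                        "n": len(pres_env),
                        "fc": st.feature_classes,
                        "rm": st.rm,
                        "or_mtp": m.or_mtp,
                        "auc_diff": m.auc_diff,
                        "auc_test": m.auc_test,
                        "n_folds": m.n_folds,
                        "selected": st == best,
                    }
                )
            model = sdm.fit_presence_background(
                pres_env, background.env, best, n_hinge_knots=n_hinge_knots
            )
            suitability[sp] = model.predict_grid(env)
            selected[sp] = best
            log.info(
                "%s: n=%d selected FC=%s RM=%.1f (OR_MTP=%.3f AUC_TEST=%.3f)",
                sp, len(pres_env), best.feature_classes, best.rm,
                results[best].or_mtp, results[best].auc_test,
            )
        except (RuntimeError, ValueError) as exc:
            log.warning("%s: model fitting failed (%s); USING RAW POINTS", sp, exc)
            fallback.append(sp)

    # fine -> coarse -> binary
    factor = aggregation_factor
    coarse_grid = env.grid.coarsen(factor)
    binary: dict[str, np.ndarray] = {}
    thresholds: dict[str, float] = {}
    for sp in species:
        pts = occ[occ["species"] == sp]
        if sp in fallback:
            try:
                binary[sp] = rasterops.points_to_binary(
                    pts["lon"].to_numpy(), pts["lat"].to_numpy(), coarse_grid
                )
            except ValueError:
                log.warning("%s: no points inside the grid; species dropped", sp)
            continue
        coarse = rasterops.aggregate_max(suitability[sp], factor)
        prow, pcol = coarse_grid.point_to_cell(
            pts["lon"].to_numpy(), pts["lat"].to_numpy()
        )
        inside = (
            (prow >= 0) & (prow < coarse_grid.n_rows)
            & (pcol >= 0) & (pcol < coarse_grid.n_cols)
        )
        pres_scores = coarse[prow[inside], pcol[inside]]
        pres_scores = pres_scores[np.isfinite(pres_scores)]
        bg_scores = coarse[np.isfinite(coarse)]
        thresholds[sp] = rasterops.threshold_maxsss(pres_scores, bg_scores.ravel())
        binary[sp] = rasterops.binarize(coarse, thresholds[sp])

    pam = rasterops.build_pam(binary, coarse_grid)
    if region is not None:
        pam = rasterops.crop_to_region(pam, region)
    analysis_tree = prune_to_taxa(tree, pam.species)

    indices = diversity.cell_indices(analysis_tree, pam)
    ensemble = diversity.randomize_pam(pam, n_iter=n_null, seed=seed_null)
    pct = diversity.null_percentiles(analysis_tree, pam, ensemble)
    indices = indices.merge(pct, on="cell_id")

    occupied = pam.richness > 0
    simpson = turnover.simpson_dissimilarity(pam)
    phylosor = turnover.phylosor_turnover(analysis_tree, pam)
    clusters, rgb, linkages = {}, {}, {}
    occ_ids = [cid for cid, k in zip(pam.cell_ids, occupied) if k]
    for name, D in (("simpson", simpson), ("phylosor", phylosor)):
        model = turnover.UPGMABioregions(n_clusters=min(k_clusters, len(occ_ids)))
        clusters[name] = model.fit_predict(D)
        linkages[name] = model
        rgb[name] = turnover.PCoARGB().fit_transform(D) if len(occ_ids) >= 4 else None

    return {
        "bias": bias,
        "background": background,
        "suitability": suitability,
        "candidates": pd.DataFrame(candidate_rows),
        "selected": selected,
        "thresholds": thresholds,
        "fallback": fallback,
        "pam": pam,
        "indices": indices,
        "simpson": simpson,
        "phylosor": phylosor,
        "occupied_cell_ids": occ_ids,
        "clusters": clusters,
        "rgb": rgb,
        "linkages": linkages,
        "coarse_grid": coarse_grid,
        "seed": seed,
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Load inputs per the config, run the analysis, write every output."""
    config.validate_paths()
    env = RasterStack.read_dir(config.env_dir)
    occ = read_occurrences(config.occurrences, extent=env.grid)
    tree = read_tree(config.tree)
    region = read_region(config.region) if config.region else None

    res = run_analysis(
        occ,
        env,
        tree,
        region=region,
        feature_classes=config.feature_classes,
        rms=config.rms,
        n_background=config.n_background,
        auc_filter=config.auc_filter,
        n_hinge_knots=config.n_hinge_knots,
        aggregation_factor=config.aggregation_factor,
        n_null=config.n_null,
        k_clusters=config.k_clusters,
        seed=config.seed,
        point_fallback_species=config.point_fallback_species,
    )

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_ascii_grid(out / "bias.asc", res["bias"], env.grid)
    suit_dir = out / "suitability"
    suit_dir.mkdir(exist_ok=True)
    for sp, grid in res["suitability"].items():
        write_ascii_grid(suit_dir / f"{sp}.asc", grid, env.grid)
    if len(res["candidates"]):
        res["candidates"].to_csv(out / "metrics_candidates.csv", index=False)
        sel = res["candidates"][res["candidates"]["selected"]]
        sel.to_csv(out / "selected_models.csv", index=False)
    (out / "selected_settings.json").write_text(
        json.dumps(
            {
                sp: {"fc": st.feature_classes, "rm": st.rm}
                for sp, st in res["selected"].items()
            },
            indent=2,
            sort_keys=True,
        )
    )
    res["pam"].to_csv(out / "pam.csv")
    res["indices"].to_csv(out / "indices.csv", index=False)
    ids = res["occupied_cell_ids"]
    for name in ("simpson", "phylosor"):
        pd.DataFrame(res[name], index=ids, columns=ids).to_csv(
            out / f"dissimilarity_{name}.csv"
        )
        df = pd.DataFrame({"cell_id": ids, "cluster": res["clusters"][name]})
        if res["rgb"][name] is not None:
            df[["r", "g", "b"]] = res["rgb"][name].round(3)
        df.to_csv(out / f"bioregions_{name}.csv", index=False)
        (out / f"upgma_{name}.nwk").write_text(
            res["linkages"][name].to_newick(leaf_names=ids) + "\n"
        )
    write_manifest(
        out / "manifest.json",
        seed=config.seed,
        settings={
            k: v for k, v in dataclasses.asdict(config).items() if k != "out_dir"
        },
        inputs={
            "occurrences": config.occurrences,
            "tree": config.tree,
            **{
                f"env:{p.name}": p
                for p in sorted(Path(config.env_dir).glob("*.asc"))
            },
        },
    )
    log.info("pipeline complete: outputs in %s", out)
    return res
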