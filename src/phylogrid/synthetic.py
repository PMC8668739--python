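"""Synthetic landscapes, phylogenies, niches and biased occurrence samples.

Every downstream stage of the pipeline can be exercised, with known ground
truth, on worlds built here: an environmental raster stack (standardized
gradients plus a spatially autocorrelated random field), an ultrametric
phylogeny, Gaussian niches whose optima evolve on the tree by Brownian
motion, and occurrence points drawn with a spatial sampling bias.

The generator emulates a community study of ~20 species along a latitudinal
gradient with 3-42 presence points per species and a time tree containing
both an old clade on long branches and a young radiation on short ones.

All randomness descends from one integer seed through a fixed
``numpy.random.SeedSequence`` splitting scheme (one child stream per
component, in a documented order), so identical seeds reproduce every
artifact bit-exactly.

Presets
-------
southern_refuge
    An old, long-branch, narrow-ranged clade plus a young southern subclade
    concentrated at the southern (low-latitude) end of the gradient, and a
    young northern subclade: high diversity, endemism and old lineages in
    the south, with genuine compositional turnover along the gradient.
uniform
    No spatial structure: flat suitability and an exchangeable random
    occupancy (curveball-mixed, i.e. a uniform draw from its fixed-margin
    class), the calibration case for the randomization null.
two_blocks
    Disjoint northern and southern assemblages sharing no species, the
    worst case for turnover and bioregionalization.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from ._rng import as_seedseq
from .grids import GridSpec, RasterStack
from .rasterops import PresenceAbsenceMatrix, aggregate_max, build_pam
from .trees import is_ultrametric, parse_newick

__all__ = [
    "SyntheticWorld",
    "simulate_tree",
    "simulate_landscape",
    "gradient_field",
    "simulate_niches",
    "sample_occurrences",
    "make_fixture",
    "PRESETS",
]

PRESETS = ("southern_refuge", "uniform", "two_blocks")


@dataclass
class SyntheticWorld:
    """A complete synthetic study system with known truth."""

    env: RasterStack
    tree: dendropy.Tree
    true_suitability: dict[str, np.ndarray]
    true_occupancy: PresenceAbsenceMatrix
    occurrences: pd.DataFrame
    bias_truth: np.ndarray
    seed: int
    factor: int
    preset: str | None = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    @property
    def species(self) -> list[str]:
        return sorted({leaf.taxon.label for leaf in self.tree.leaf_node_iter()})

    def validate(self) -> None:
        species = self.species
        occ_species = set(self.occurrences["species"])
        if occ_species != set(species):
            raise ValueError("occurrence species do not match tree tips")
        counts = self.occurrences["species"].value_counts()
        if (counts < 1).any() or len(counts) != len(species):
            raise ValueError("every species needs at least one occurrence")
        if set(self.true_occupancy.species) != set(species):
            raise ValueError("true occupancy does not cover every species")
        if (self.true_occupancy.range_sizes < 1).any():
            raise ValueError("every species needs an occupied coarse cell")
        for name, suit in self.true_suitability.items():
            if suit.min() < 0 or suit.max() > 1:
                raise ValueError(f"suitability for {name} outside [0, 1]")
        for name in self.env.names:
            if not np.isfinite(self.env[name]).all():
                raise ValueError(f"env layer {name} has non-finite values")
        if not is_ultrametric(self.tree):
            raise ValueError("tree is not ultrametric")

    def write(self, directory) -> None:
        """Persist the world: CSV points, .asc rasters, newick, manifest."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.occurrences.to_csv(directory / "occurrences.csv", index=False)
        self.env.write_dir(directory / "env")
        truth = RasterStack(grid=self.env.grid)
        for name, suit in self.true_suitability.items():
            truth.add(f"suit_{name}", suit)
        truth.add("bias_truth", self.bias_truth)
        truth.write_dir(directory / "truth")
        self.tree.write(path=str(directory / "tree.nwk"), schema="newick")
        self.true_occupancy.to_csv(directory / "true_occupancy.csv")
        manifest = {
            "seed": self.seed,
            "preset": self.preset,
            "factor": self.factor,
            "n_taxa": len(self.species),
            "grid": {
                "n_rows": self.env.grid.n_rows,
                "n_cols": self.env.grid.n_cols,
                "cell_size": self.env.grid.cell_size,
                "x_origin": self.env.grid.x_origin,
                "y_origin": self.env.grid.y_origin,
            },
        }
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))


# -- trees ---------------------------------------------------------------


def simulate_tree(
    n_taxa: int,
    birth_rate: float = 0.08,
    death_rate: float = 0.02,
    seed=None,
    max_tries: int = 100,
) -> dendropy.Tree:
    """Constant-rate birth-death tree conditioned on ``n_taxa`` survivors.

    Tips are relabeled sp01..spNN in leaf order and the root edge is
    dropped, so the tree is rooted, binary and ultrametric with depths in
    the same time units as 1/birth_rate.
    """
    from dendropy.model import birthdeath

    if n_taxa < 2:
        raise ValueError("need at least two taxa")
    if not birth_rate > death_rate >= 0:
        raise ValueError("require birth_rate > death_rate >= 0")
    rng = random.Random(int(as_seedseq(seed).generate_state(1)[0]))
    tree = None
    for _ in range(max_tries):
        try:
            tree = birthdeath.birth_death_tree(
                birth_rate,
                death_rate,
                num_extant_tips=n_taxa,
                rng=rng,
                repeat_until_success=False,
            )
            break
        except Exception:
            continue
    if tree is None:
        raise RuntimeError(
            f"birth-death simulation went extinct {max_tries} times "
            f"(birth={birth_rate}, death={death_rate})"
        )
    tree.seed_node.edge.length = None
    width = max(2, len(str(n_taxa)))
    for i, leaf in enumerate(tree.leaf_node_iter(), start=1):
        leaf.taxon.label = f"sp{i:0{width}d}"
    return tree


def ladder_tree_newick(labels: list[str], split_times: list[float]) -> str:
    """Newick for an ultrametric ladder with splits at the given depths.

    ``split_times`` are node ages (time before present), strictly
    decreasing, one fewer than labels; the first label splits off first.
    """
    if sorted(split_times, reverse=True) != list(split_times):
        raise ValueError("split times must be strictly decreasing")
    if len(split_times) != len(labels) - 1:
        raise ValueError("need one split time fewer than labels")

    def build(labs, times):
        if len(labs) == 1:
            return labs[0], 0.0
        inner, age = build(labs[1:], times[1:])
        t = times[0]
        return f"({labs[0]}:{t},{inner}:{t - age})", t

    sub, _ = build(labels, split_times)
    return sub + ";"


# -- landscapes ----------------------------------------------------------


def gradient_field(n_rows: int, n_cols: int, kind: str = "ns") -> np.ndarray:
    """Deterministic gradient component, unit scale.

    ``ns``: linear north-south gradient increasing southward (with row).
    ``ridge``: elevation-like ridge along the central column band.
    """
    rows, cols = np.indices((n_rows, n_cols), dtype=float)
    if kind == "ns":
        g = rows / max(n_rows - 1, 1)
    elif kind == "ridge":
        center = (n_cols - 1) / 2.0
        width = max(n_cols / 4.0, 1.0)
        g = np.exp(-(((cols - center) / width) ** 2))
    else:
        raise ValueError(f"unknown gradient kind {kind!r}")
    g = g - g.mean()
    sd = g.std()
    return g / sd if sd > 0 else g


def simulate_landscape(
    n_rows: int,
    n_cols: int,
    n_env: int = 3,
    autocorr_range: float = 3.0,
    seed=None,
    noise_amplitude: float = 0.4,
    grid: GridSpec | None = None,
) -> RasterStack:
    """Standardized environmental layers: gradient + autocorrelated noise.

    Even-numbered layers carry the north-south gradient and odd-numbered an
    elevation-like ridge; each layer adds a Gaussian random field with the
    given correlation range (in cells; 0 means iid noise) and is
    standardized to mean 0, sd 1.
    """
    if n_rows < 10 or n_cols < 10:
        raise ValueError("landscape needs at least 10 rows and columns")
    if grid is None:
        grid = GridSpec(
            x_origin=70.0,
            y_origin=20.0,
            cell_size=0.0083 * 4,  # desk-scale default; override via grid=
            n_rows=n_rows,
            n_cols=n_cols,
        )
    streams = as_seedseq(seed).spawn(n_env)
    stack = RasterStack(grid=grid)
    for j in range(n_env):
        rng = np.random.default_rng(streams[j])
        g = gradient_field(n_rows, n_cols, "ns" if j % 2 == 0 else "ridge")
        noise = rng.standard_normal((n_rows, n_cols))
        if autocorr_range > 0:
            noise = gaussian_filter(noise, sigma=autocorr_range, mode="reflect")
            sd = noise.std()
            if sd > 0:
                noise = noise / sd
        layer = g + noise_amplitude * noise
        layer = (layer - layer.mean()) / layer.std()
        stack.add(f"env{j}", layer)
    return stack


# -- niches --------------------------------------------------------------


def _brownian_tip_values(tree: dendropy.Tree, rng: np.random.Generator) -> dict[str, float]:
    """One Brownian trait realization, scaled to ~unit tip variance."""
    depth = max(leaf.distance_from_root() for leaf in tree.leaf_node_iter())
    values: dict[int, float] = {}
    out: dict[str, float] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            values[id(node)] = 0.0
        else:
            step = rng.normal(0.0, np.sqrt((node.edge.length or 0.0) / depth))
            values[id(node)] = values[id(node.parent_node)] + step
        if node.is_leaf():
            out[node.taxon.label] = values[id(node)]
    return out


def simulate_niches(
    tree: dendropy.Tree,
    env: RasterStack,
    niche_sd: float = 0.5,
    phylo_signal: float = 1.0,
    seed=None,
    optima: dict[str, np.ndarray] | None = None,
) -> dict[str, np.ndarray]:
    """Gaussian niches with optima evolved on the tree.

    Per environmental layer, each species' niche optimum is a convex mix of
    a Brownian-motion realization on the tree (weight ``phylo_signal``) and
    an iid standard-normal draw, so close relatives share optima when the
    signal is 1 and optima are exchangeable at 0.  Suitability of a cell is
    exp(-sum_j (env_j - opt_j)^2 / (2 niche_sd^2)), in (0, 1], peaking at 1
    where the environment matches the optimum exactly.

    Explicit ``optima`` (species -> vector over layers) override evolution;
    ``niche_sd`` may be a scalar, a per-layer vector, or a species -> vector
    mapping.
    """
    if not 0.0 <= phylo_signal <= 1.0:
        raise ValueError("phylo_signal must lie in [0, 1]")
    species = sorted(leaf.taxon.label for leaf in tree.leaf_node_iter())
    n_env = len(env)
    if optima is None:
        streams = as_seedseq(seed).spawn(2 * n_env)
        optima = {s: np.zeros(n_env) for s in species}
        for j in range(n_env):
            bm_rng = np.random.default_rng(streams[2 * j])
            iid_rng = np.random.default_rng(streams[2 * j + 1])
            bm = _brownian_tip_values(tree, bm_rng)
            for s in species:
                optima[s][j] = phylo_signal * bm[s] + (1 - phylo_signal) * iid_rng.normal()
    table = env.table()  # (cells, layers)
    out = {}
    for s in species:
        sd = niche_sd[s] if isinstance(niche_sd, dict) else niche_sd
        sd = np.broadcast_to(np.asarray(sd, dtype=float), (n_env,))
        d2 = ((table - np.asarray(optima[s])) / sd) ** 2
        out[s] = np.exp(-0.5 * d2.sum(axis=1)).reshape(env.grid.shape)
    return out


# -- occurrences ---------------------------------------------------------


def sample_occurrences(
    true_suitability: dict[str, np.ndarray],
    n_per_species,
    bias_truth: np.ndarray,
    grid: GridSpec,
    seed=None,
    min_weight: float = 1e-12,
) -> pd.DataFrame:
    """Biased presence points: cells ~ suitability x bias, without replacement.

    ``n_per_species`` is an integer, a (low, high) range sampled
    log-uniformly per species (the default study design is (3, 42)), or a
    species -> count mapping.  Points are jittered uniformly within their
    cell so that fine-grid rasterization is exercised.
    """
    species = sorted(true_suitability)
    streams = as_seedseq(seed).spawn(len(species) + 1)
    n_rng = np.random.default_rng(streams[0])
    counts = {}
    for s in species:
        if isinstance(n_per_species, dict):
            counts[s] = int(n_per_species[s])
        elif np.isscalar(n_per_species):
            counts[s] = int(n_per_species)
        else:
            lo, hi = n_per_species
            counts[s] = int(round(np.exp(n_rng.uniform(np.log(lo), np.log(hi)))))
    rows = []
    bias = np.asarray(bias_truth, dtype=float).ravel()
    for k, s in enumerate(species):
        rng = np.random.default_rng(streams[k + 1])
        w = true_suitability[s].ravel() * bias
        w = np.where(np.isfinite(w) & (w > min_weight), w, 0.0)
        available = int((w > 0).sum())
        if available == 0:
            raise ValueError(f"species {s}: bias does not overlap its suitability")
        n = counts[s]
        if n > available:
            raise ValueError(
                f"species {s}: requested {n} points but only {available} "
                "cells have positive sampling weight"
            )
        idx = rng.choice(len(w), size=n, replace=False, p=w / w.sum())
        r, c = np.unravel_index(idx, grid.shape)
        jit_lon = rng.uniform(0, grid.cell_size, size=n)
        jit_lat = rng.uniform(0, grid.cell_size, size=n)
        lon = grid.x_origin + c * grid.cell_size + jit_lon
        lat = grid.y_origin - r * grid.cell_size - jit_lat
        for xx, yy in zip(lon, lat):
            rows.append((s, float(xx), float(yy)))
    return pd.DataFrame(rows, columns=["species", "lon", "lat"])


# -- presets -------------------------------------------------------------


def make_fixture(
    preset: str,
    n_taxa: int = 19,
    n_rows: int = 40,
    n_cols: int = 20,
    factor: int = 4,
    seed: int = 42,
    n_env: int = 3,
    n_range=(3, 42),
) -> SyntheticWorld:
    """Build a preset world (see module docstring for the three designs)."""
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {PRESETS}")
    builder = {
        "southern_refuge": _southern_refuge,
        "uniform": _uniform,
        "two_blocks": _two_blocks,
    }[preset]
    return builder(n_taxa, n_rows, n_cols, factor, seed, n_env, n_range)


def _species_labels(n: int) -> list[str]:
    width = max(2, len(str(n)))
    return [f"sp{i:0{width}d}" for i in range(1, n + 1)]


def _coarse_occupancy(
    suit: dict[str, np.ndarray], grid: GridSpec, factor: int, threshold: float = 0.5
) -> PresenceAbsenceMatrix:
    coarse_grid = grid.coarsen(factor)
    maps = {
        s: (aggregate_max(a, factor) >= threshold).astype(np.uint8)
        for s, a in suit.items()
    }
    return build_pam(maps, coarse_grid)


def _southern_refuge(n_taxa, n_rows, n_cols, factor, seed, n_env, n_range):
    """Old southern endemic clade + young southern and northern subclades.

    The first environmental layer is the dominant latitudinal gradient
    (southward-increasing).  The old clade (about a third of the species)
    splits deep in the tree with long terminal branches and holds narrow
    niches at the far southern end; a young southern subclade sits on the
    southern half and a young northern subclade on the northern half, so
    composition genuinely turns over along the gradient.
    """
    streams = as_seedseq(seed).spawn(4)
    env = simulate_landscape(
        n_rows, n_cols, n_env=n_env, autocorr_range=2.0, seed=streams[0]
    )
    labels = _species_labels(n_taxa)
    n_old = max(2, round(n_taxa * 6 / 19))
    n_ys = max(2, round(n_taxa * 6 / 19))
    n_yn = n_taxa - n_old - n_ys
    old, young_s, young_n = (
        labels[:n_old],
        labels[n_old : n_old + n_ys],
        labels[n_old + n_ys :],
    )
    depth = 100.0
    old_times = list(np.linspace(85.0, 30.0, n_old - 1)) if n_old > 1 else []
    ys_times = list(np.linspace(9.0, 2.0, n_ys - 1)) if n_ys > 1 else []
    yn_times = list(np.linspace(10.0, 2.0, n_yn - 1)) if n_yn > 1 else []
    old_nwk = ladder_tree_newick(old, old_times)[:-1]
    ys_nwk = ladder_tree_newick(young_s, ys_times)[:-1]
    yn_nwk = ladder_tree_newick(young_n, yn_times)[:-1]
    young_crown, old_crown = 12.0, (old_times[0] if old_times else 0.0)
    newick = (
        f"({old_nwk}:{depth - old_crown},"
        f"(({ys_nwk}:{young_crown - (ys_times[0] if ys_times else 0.0)},"
        f"{yn_nwk}:{young_crown - (yn_times[0] if yn_times else 0.0)})"
        f":{depth - young_crown}):0.0);"
    )
    tree = parse_newick(newick)

    rng = np.random.default_rng(streams[1])
    optima = {}
    for i, s in enumerate(old):
        optima[s] = np.zeros(n_env)
        optima[s][0] = np.linspace(1.0, 1.5, len(old))[i]
    for i, s in enumerate(young_s):
        optima[s] = np.zeros(n_env)
        optima[s][0] = np.linspace(0.5, 1.2, len(young_s))[i]
    for i, s in enumerate(young_n):
        optima[s] = np.zeros(n_env)
        optima[s][0] = np.linspace(-1.5, -0.5, len(young_n))[i]
    for s in labels:
        optima[s][1:] = rng.normal(0.0, 0.2, size=n_env - 1)
    niche_sd = {}
    for s in labels:
        sd = np.full(n_env, 3.0)  # weak selectivity off the main gradient
        sd[0] = 0.35 if s in old else 0.45
        niche_sd[s] = sd
    suit = simulate_niches(tree, env, niche_sd=niche_sd, optima=optima)

    bias = _west_bias(n_rows, n_cols, strength=0.5)
    occ = sample_occurrences(suit, n_range, bias, env.grid, seed=streams[2])
    pam = _coarse_occupancy(suit, env.grid, factor)

    southern = set(old) | set(young_s)
    s_count = pam.matrix[:, [pam.species.index(s) for s in pam.species if s in southern]].sum(axis=1)
    n_count = pam.richness - s_count
    # majority fauna per cell; 0 marks cells with no true occupants (no fauna)
    cell_fauna = np.where(pam.richness == 0, 0, np.where(s_count >= n_count, 1, 2))
    n_coarse_rows = env.grid.coarsen(factor).n_rows
    refuge_rows = set(range(n_coarse_rows - 3, n_coarse_rows))
    extras = {
        "fauna": {s: ("southern" if s in southern else "northern") for s in labels},
        "clade": {
            s: ("old" if s in old else "young_south" if s in young_s else "young_north")
            for s in labels
        },
        "cell_fauna": cell_fauna,
        "refuge_rows": sorted(refuge_rows),
        "refuge_cells": np.isin(pam.rows, sorted(refuge_rows)),
    }
    return SyntheticWorld(
        env=env,
        tree=tree,
        true_suitability=suit,
        true_occupancy=pam,
        occurrences=occ,
        bias_truth=bias,
        seed=seed,
        factor=factor,
        preset="southern_refuge",
        extras=extras,
    )


def _west_bias(n_rows: int, n_cols: int, strength: float = 0.5) -> np.ndarray:
    """Sampling effort declining eastward, in (0, 1]."""
    cols = np.indices((n_rows, n_cols))[1].astype(float)
    return 1.0 - strength * cols / max(n_cols - 1, 1)


def _uniform(n_taxa, n_rows, n_cols, factor, seed, n_env, n_range):
    from .diversity import randomize_pam

    streams = as_seedseq(seed).spawn(5)
    env = simulate_landscape(
        n_rows, n_cols, n_env=n_env, autocorr_range=2.0, seed=streams[0]
    )
    tree = simulate_tree(n_taxa, 0.08, 0.02, seed=streams[1])
    labels = sorted(leaf.taxon.label for leaf in tree.leaf_node_iter())
    coarse = env.grid.coarsen(factor)
    n_cells = coarse.n_rows * coarse.n_cols
    rng = np.random.default_rng(streams[2])
    matrix = np.zeros((n_cells, n_taxa), dtype=np.uint8)
    for j in range(n_taxa):
        r = int(rng.integers(max(2, n_cells // 5), max(3, 4 * n_cells // 5)))
        matrix[rng.choice(n_cells, size=r, replace=False), j] = 1
    rows, cols = np.divmod(np.arange(n_cells), coarse.n_cols)
    pam = PresenceAbsenceMatrix(
        matrix=matrix, species=labels, rows=rows, cols=cols, grid=coarse
    )
    # mix so the observed matrix is a uniform draw from its fixed-margin class
    mixed = randomize_pam(pam, n_iter=1, seed=streams[3], burn_in_factor=20)[0]
    pam = PresenceAbsenceMatrix(
        matrix=mixed, species=labels, rows=rows, cols=cols, grid=coarse
    )
    suit = {s: np.full((n_rows, n_cols), 0.8) for s in labels}
    bias = np.ones((n_rows, n_cols))
    occ = sample_occurrences(suit, n_range, bias, env.grid, seed=streams[4])
    return SyntheticWorld(
        env=env,
        tree=tree,
        true_suitability=suit,
        true_occupancy=pam,
        occurrences=occ,
        bias_truth=bias,
        seed=seed,
        factor=factor,
        preset="uniform",
    )


def _two_blocks(n_taxa, n_rows, n_cols, factor, seed, n_env, n_range):
    streams = as_seedseq(seed).spawn(4)
    env = simulate_landscape(
        n_rows, n_cols, n_env=n_env, autocorr_range=2.0, seed=streams[0]
    )
    tree = simulate_tree(n_taxa, 0.08, 0.02, seed=streams[1])
    labels = sorted(leaf.taxon.label for leaf in tree.leaf_node_iter())
    half = n_taxa // 2
    north_sp, south_sp = labels[:half], labels[half:]
    split_row = n_rows // 2
    suit = {}
    for s in labels:
        a = np.full((n_rows, n_cols), 1e-6)
        if s in north_sp:
            a[:split_row, :] = 0.9
        else:
            a[split_row:, :] = 0.9
        suit[s] = a
    coarse = env.grid.coarsen(factor)
    rng = np.random.default_rng(streams[2])
    n_cells = coarse.n_rows * coarse.n_cols
    rows, cols = np.divmod(np.arange(n_cells), coarse.n_cols)
    coarse_split = split_row // factor
    matrix = np.zeros((n_cells, n_taxa), dtype=np.uint8)
    for j, s in enumerate(labels):
        block = rows < coarse_split if s in north_sp else rows >= coarse_split
        cells = np.flatnonzero(block)
        occ_cells = cells[rng.random(len(cells)) < 0.7]
        if len(occ_cells) == 0:
            occ_cells = cells[:1]
        matrix[occ_cells, j] = 1
    # keep every cell occupied by at least one of its block's species
    for c in range(n_cells):
        if matrix[c].sum() == 0:
            block_sp = north_sp if rows[c] < coarse_split else south_sp
            j = labels.index(block_sp[int(rng.integers(len(block_sp)))])
            matrix[c, j] = 1
    pam = PresenceAbsenceMatrix(
        matrix=matrix, species=labels, rows=rows, cols=cols, grid=coarse
    )
    bias = np.ones((n_rows, n_cols))
    occ = sample_occurrences(suit, n_range, bias, env.grid, seed=streams[3])
    extras = {
        "block": {s: ("north" if s in north_sp else "south") for s in labels},
        "cell_block": np.where(rows < coarse_split, 1, 2),
        "coarse_split_row": coarse_split,
    }
    return SyntheticWorld(
        env=env,
        tree=tree,
        true_suitability=suit,
        true_occupancy=pam,
        occurrences=occ,
        bias_truth=bias,
        seed=seed,
        factor=factor,
        preset="two_blocks",
        extras=extras,
    )
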