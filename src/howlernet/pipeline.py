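"""End-to-end orchestration: from feeding records (real or synthetic) to
the full analysis surface — community tables, per-species core/periphery
occurrence, network attributes with null-model significance, and a
bipartite network plot per habitat.

The pipeline is a pure function of (inputs, configuration, seed): every
randomized stage consumes an independent substream of the master seed, so
reruns are bit-identical and disabling one stage never changes another's
draws.
"""
from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
from skbio.stats.distance import DistanceMatrix

from . import __version__
from .io_model import (
    AgeClass,
    Habitat,
    Individual,
    InteractionMatrix,
    ObservationRecord,
    Sex,
    build_interaction_matrix,
    read_observations,
    read_transects,
)
from .network_metrics import network_attributes, class_diet_summary
from .null_models import nestedness_test
from .core_periphery import core_periphery_occurrence
from .community_stats import (
    compute_ivi,
    ivi_table,
    item_time_fractions,
    jaccard,
    mantel_test,
    nested_anova,
)
from .synthetic_data import Scenario, generate_scenario, paper_like_config

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "plot_bipartite", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Settings of one pipeline run.  Defaults follow the analysis design:
    1,000 null-model randomizations, 20 core-periphery runs, alpha 0.05."""

    observations: str | Path | None = None
    transects: str | Path | None = None
    preset: str | None = "paper_like"
    nu: float = 0.8
    weighting: str = "count"
    n_randomizations: int = 1000
    n_cp_runs: int = 20
    alpha: float = 0.05
    seed: int | None = None
    outdir: str | Path = "howlernet_out"


# ---------------------------------------------------------------------------
# Plot

_CLASS_GLYPHS = {
    ("adult", "F"): dict(marker="s", color="0.85", label="adult female"),
    ("adult", "M"): dict(marker="s", color="0.25", label="adult male"),
    ("juvenile", "F"): dict(marker="^", color="0.85", label="juvenile female"),
    ("juvenile", "M"): dict(marker="^", color="0.25", label="juvenile male"),
    ("infant", "F"): dict(marker="D", color="0.85", label="infant female"),
    ("infant", "M"): dict(marker="D", color="0.25", label="infant male"),
}


def plot_bipartite(
    matrix: InteractionMatrix,
    individuals: Sequence[Individual] | None,
    path: str | Path,
) -> Path:
    """Two-column bipartite plot: monkeys left, plant species right, one
    line per link; node glyphs encode the six age/sex classes."""
    if matrix.n_links == 0:
        raise ValueError("cannot plot an empty matrix")
    by_id = {i.individual_id: i for i in individuals or []}
    r, c = matrix.shape
    fig, ax = plt.subplots(figsize=(7, max(4, 0.28 * max(r, c))))
    ys_left = np.linspace(0, 1, r)
    ys_right = np.linspace(0, 1, c)
    for i in range(r):
        for j in np.flatnonzero(matrix.weights[i]):
            ax.plot([0, 1], [ys_left[i], ys_right[j]], color="0.7", lw=0.6, zorder=1)
    seen = set()
    for i, rid in enumerate(matrix.row_labels):
        ind = by_id.get(rid)
        key = (ind.age_class.value, ind.sex.value) if ind else ("adult", "F")
        glyph = _CLASS_GLYPHS[key]
        ax.scatter(
            [0], [ys_left[i]],
            marker=glyph["marker"], c=glyph["color"], edgecolors="black",
            s=60, zorder=2,
            label=glyph["label"] if key not in seen else None,
        )
        seen.add(key)
    ax.scatter([1] * c, ys_right, marker="o", c="forestgreen", s=30, zorder=2)
    for j, sp in enumerate(matrix.col_labels):
        ax.annotate(sp, (1.02, ys_right[j]), fontsize=5, va="center")
    ax.set_xlim(-0.15, 1.45)
    ax.set_xticks([0, 1])
    ax.set_xticklabels(["monkeys", "plants"])
    ax.set_yticks([])
    ax.legend(fontsize=6, loc="upper left", bbox_to_anchor=(-0.15, 1.12), ncol=3)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


# ---------------------------------------------------------------------------
# Helper stages


def _individual_item_fractions(records: Sequence[ObservationRecord]) -> pd.DataFrame:
    """Per-individual fraction of feeding time per item (ANOVA replicates)."""
    rows = [
        {
            "habitat": r.habitat.value,
            "individual_id": r.individual_id,
            "item": r.item.value,
            "duration": r.duration,
        }
        for r in records
        if r.duration > 0
    ]
    frame = pd.DataFrame(rows)
    total = frame.groupby(["habitat", "individual_id"])["duration"].transform("sum")
    frame["fraction"] = frame["duration"] / total
    return (
        frame.groupby(["habitat", "individual_id", "item"])["fraction"]
        .sum()
        .reset_index()
    )


def _transect_distances(transects) -> tuple[DistanceMatrix, DistanceMatrix]:
    """Geographic and floristic (1 - Jaccard) distances between transects."""
    frame = pd.DataFrame(
        {
            "transect_id": [t.transect_id for t in transects],
            "x": [t.x for t in transects],
            "y": [t.y for t in transects],
            "species": [t.species for t in transects],
        }
    )
    grouped = frame.groupby("transect_id")
    ids = sorted(grouped.groups)
    coords = grouped[["x", "y"]].first().loc[ids].to_numpy()
    sets = {tid: set(g["species"]) for tid, g in grouped}
    n = len(ids)
    geo = np.zeros((n, n))
    flo = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            geo[i, j] = geo[j, i] = float(np.hypot(*(coords[i] - coords[j])))
            sim = jaccard(sets[ids[i]], sets[ids[j]])
            flo[i, j] = flo[j, i] = 1.0 - sim
    return DistanceMatrix(geo, ids), DistanceMatrix(flo, ids)


def _community_table(transects, diet_species: dict) -> pd.DataFrame:
    """Per-habitat community attributes (mean per-site species richness and
    tree density, and the summed IVI of diet species)."""
    rows = []
    for hab in Habitat:
        sub = [t for t in transects if t.habitat is hab]
        if not sub:
            continue
        sites = sorted({t.site_id for t in sub})
        rich = [len({t.species for t in sub if t.site_id == s}) for s in sites]
        dens = [sum(1 for t in sub if t.site_id == s) for s in sites]
        ivi = compute_ivi(sub, hab)
        food = diet_species.get(hab.value, set())
        food_ivi = sum(r.ivi for r in ivi if r.species in food)
        rows.append(
            {
                "habitat": hab.value,
                "mean_species_richness": float(np.mean(rich)),
                "sd_species_richness": float(np.std(rich, ddof=1)) if len(rich) > 1 else 0.0,
                "mean_tree_density": float(np.mean(dens)),
                "sd_tree_density": float(np.std(dens, ddof=1)) if len(dens) > 1 else 0.0,
                "ivi_of_food_species": food_ivi,
            }
        )
    return pd.DataFrame(rows)


def _stage(name: str):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - annotate and re-raise
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc

    return wrap


# ---------------------------------------------------------------------------
# Main entry


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis and write the report bundle to ``outdir``.

    Returns a dict with the per-habitat network attributes, null-model
    results, core/periphery tables, community statistics, and the paths of
    every emitted file.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    s_data, s_null, s_cp, s_mantel = ss.spawn(4)

    # -- data ---------------------------------------------------------------
    if config.observations is not None:
        records = _stage("read_observations")(read_observations, config.observations)
        transects = (
            _stage("read_transects")(read_transects, config.transects)
            if config.transects
            else []
        )
        individuals = None
        scenario = None
    else:
        if config.preset != "paper_like":
            raise PipelineError(f"stage 'data' failed: unknown preset {config.preset!r}")
        seed_child = int(s_data.generate_state(1)[0] % (2**31))
        scen_cfg = paper_like_config(seed=seed_child, nu=config.nu)
        scenario = _stage("simulate")(generate_scenario, scen_cfg)
        records, transects = scenario.records, scenario.transects
        individuals = scenario.individuals
    logger.info("pipeline data: %d records, %d transect trees", len(records), len(transects))

    habitats = sorted({r.habitat for r in records}, key=lambda h: h.value)
    bundle: dict = {"habitats": {}, "files": [], "config": vars(config).copy()}
    diet_species: dict[str, set] = {}
    null_seeds = dict(zip([h.value for h in habitats], s_null.spawn(len(habitats))))
    cp_seeds = dict(zip([h.value for h in habitats], s_cp.spawn(len(habitats))))

    for hab in habitats:
        hab_inds = (
            [i for i in individuals if i.habitat is hab] if individuals else None
        )
        matrix = _stage("matrix")(
            build_interaction_matrix, records, hab, config.weighting, hab_inds
        )
        binary = matrix.binary()
        diet_species[hab.value] = {
            sp for sp, d in zip(matrix.col_labels, matrix.col_degrees()) if d > 0
        }
        attrs = _stage("attributes")(network_attributes, matrix)
        null = _stage("nullmodel")(
            nestedness_test, binary, config.n_randomizations, null_seeds[hab.value]
        )
        cp = _stage("coreperiphery")(
            core_periphery_occurrence, binary, config.n_cp_runs, cp_seeds[hab.value]
        )
        class_summary = (
            class_diet_summary(matrix, hab_inds) if hab_inds else None
        )

        tag = hab.value
        matrix.to_csv(outdir / f"matrix_{tag}.csv")
        series = attrs.to_series()
        extra = pd.Series(
            {
                "Null mean NODF": round(null.null_mean, 2),
                "Null SD NODF": round(null.null_sd, 2),
                "P (null >= observed)": round(null.p_value, 4),
                "Significant at alpha": bool(null.p_value <= config.alpha),
            }
        )
        pd.concat([series, extra]).to_csv(
            outdir / f"attributes_{tag}.tsv", sep="\t", header=False
        )
        cp.table.to_csv(outdir / f"core_periphery_{tag}.tsv", sep="\t", index=False)
        plot_path = _stage("plot")(
            plot_bipartite, matrix, hab_inds, outdir / f"network_{tag}.png"
        )
        bundle["files"] += [
            str(outdir / f"matrix_{tag}.csv"),
            str(outdir / f"attributes_{tag}.tsv"),
            str(outdir / f"core_periphery_{tag}.tsv"),
            str(plot_path),
        ]
        bundle["habitats"][tag] = {
            "attributes": attrs,
            "attributes_table": series,
            "null": null,
            "core_periphery": cp,
            "class_summary": class_summary,
        }

    # -- community side -----------------------------------------------------
    community: dict = {}
    if len(diet_species) == 2:
        a, b = (diet_species[h.value] for h in habitats)
        community["diet_jaccard"] = jaccard(a, b)
    if transects:
        comm_table = _stage("community")(_community_table, transects, diet_species)
        comm_table.to_csv(outdir / "community.tsv", sep="\t", index=False)
        bundle["files"].append(str(outdir / "community.tsv"))
        community["table"] = comm_table
        for hab in habitats:
            sub = [t for t in transects if t.habitat is hab]
            if not sub:
                continue
            top = ivi_table(compute_ivi(sub, hab)).head(10)
            top.to_csv(outdir / f"ivi_top10_{hab.value}.tsv", sep="\t", index=False)
            bundle["files"].append(str(outdir / f"ivi_top10_{hab.value}.tsv"))
            community[f"ivi_top10_{hab.value}"] = top
        geo, flo = _transect_distances(transects)
        mantel_seed = int(s_mantel.generate_state(1)[0] % (2**31))
        community["mantel"] = _stage("mantel")(
            mantel_test, geo, flo, 999, mantel_seed
        )
    fractions = _stage("item_fractions")(item_time_fractions, records)
    fractions.to_csv(outdir / "item_time_fractions.tsv", sep="\t")
    bundle["files"].append(str(outdir / "item_time_fractions.tsv"))
    community["item_fractions"] = fractions
    per_ind = _individual_item_fractions(records)
    try:
        community["anova"] = nested_anova(
            per_ind["fraction"], per_ind["habitat"], per_ind["item"]
        )
    except ValueError as exc:
        logger.warning("nested ANOVA skipped: %s", exc)
    bundle["community"] = community

    # -- manifest -----------------------------------------------------------
    manifest = {
        "package_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "seed": config.seed,
        "n_randomizations": config.n_randomizations,
        "n_cp_runs": config.n_cp_runs,
        "alpha": config.alpha,
        "weighting": config.weighting,
        "preset": config.preset if config.observations is None else None,
        "nu": config.nu,
        "n_records": len(records),
        "n_transect_trees": len(transects),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    bundle["files"].append(str(outdir / "manifest.json"))

    summary = {
        hab: {
            "attributes": info["attributes"].to_dict(),
            "null": info["null"].to_dict(),
        }
        for hab, info in bundle["habitats"].items()
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2))
    bundle["files"].append(str(outdir / "summary.json"))
    return bundle
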