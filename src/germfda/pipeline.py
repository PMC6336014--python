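"""End-to-end orchestration of the germination-dormancy analysis.

Stages: penalized-spline AGDF fits and descriptors -> UPGMA dormancy
classification -> PCA / spatial correlograms / spatially corrected
environment correlations -> PCNM + RDA variance partitioning with forward
selection -> niche overlap and equivalency tests -> seed-coat trait
statistics.  Every stage can also be run on its own through the library (or
the ``germfda`` CLI); this module wires them together and writes the result
tables.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .curve_model import SplineConfig, agdf_area, classical_indices, fit_agdf
from .dormancy import LabelThresholds, cut_and_label, pairwise_euclidean, upgma
from .niche import OccurrenceSet, equivalency_test
from .ordination import (axis_env_correlations, collinearity_prune,
                         forward_select, pca_unstandardized, variance_partition)
from .spatial import (haversine_distances, make_distance_classes,
                      morans_i_correlogram, pcnm_eigenvectors)
from .traits import ancova_ratio, kruskal_wallis, ordinal_logistic

__all__ = ["RunConfig", "descriptor_table", "run_full_analysis"]


@dataclass
class RunConfig:
    """Pipeline settings; all stochastic stages derive from ``seed``."""

    spline: SplineConfig = field(default_factory=SplineConfig)
    n_clusters: int = 3
    thresholds: LabelThresholds = field(default_factory=LabelThresholds)
    n_distance_classes: int = 10
    n_permutations: int = 999
    equivalency_reps: int = 100
    forward_alpha: float = 0.05
    seed: int = 0
    output_dir: str | None = None


def descriptor_table(records, spline_config=None, sum_replicates=True):
    """Per-accession x treatment AGDF descriptors.

    Replicates are summed into one series per accession x treatment by
    default (per-replicate mode keeps them separate).  Returns a DataFrame
    indexed by accession with B-spline coefficients ``<treatment>_b1..bK``,
    AUC, final fraction, LT50, MGT, CV per treatment, plus the fitted AGDFs.
    """
    spline_config = spline_config or SplineConfig()
    groups: dict = {}
    for r in records:
        groups.setdefault((r.accession_id, r.treatment), []).append(r)
    rows: dict = {}
    agdfs: dict = {}
    for (acc, tr), reps in sorted(groups.items()):
        rec = reps[0]
        if sum_replicates:
            for other in reps[1:]:
                rec = rec.summed_with(other)
        agdf = fit_agdf(rec, spline_config)
        idx = classical_indices(rec)
        row = rows.setdefault(acc, {})
        for j, b in enumerate(agdf.coefficients, start=1):
            row[f"{tr}_b{j}"] = b
        row[f"{tr}_auc"] = agdf_area(agdf)
        row[f"{tr}_final"] = idx.final_proportion
        row[f"{tr}_lt50"] = idx.lt50
        row[f"{tr}_mgt"] = idx.mgt
        row[f"{tr}_cv"] = idx.cv
        agdfs[(acc, tr)] = agdf
    df = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    df.index.name = "accession_id"
    return df, agdfs


def _coef_matrix(desc: pd.DataFrame) -> pd.DataFrame:
    cols = [c for c in desc.columns if "_b" in c and c.split("_b")[-1].isdigit()]
    return desc[cols]


def run_full_analysis(records, coords, env, traits=None, env_grids=None,
                      config: RunConfig | None = None) -> dict:
    """Run every pipeline stage; returns a dict of result objects.

    ``records``: GerminationRecord list; ``coords``: accession x (lon, lat);
    ``env``: accession x environmental variables; ``traits`` and
    ``env_grids`` optional (trait tests and niche analysis are skipped
    without them).  When ``config.output_dir`` is set, result CSVs and a
    JSON run log (version, seeds, parameters) are written there.
    """
    config = config or RunConfig()
    rng = np.random.default_rng(config.seed)
    results: dict = {}

    # --- AGDF fits and descriptors -------------------------------------
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        desc, agdfs = descriptor_table(records, config.spline)
    ids = desc.index.to_list()
    coords = coords.loc[ids]
    env = env.loc[ids]
    results["descriptors"] = desc

    # --- dormancy classification (combined treatments: AUC pairs) ------
    auc = desc[["T25_15_auc", "T35_15_auc"]].to_numpy()
    dend = upgma(pairwise_euclidean(auc, labels=ids), labels=ids)
    assignments = cut_and_label(
        dend, config.n_clusters,
        desc["T25_15_final"].to_numpy(), desc["T35_15_final"].to_numpy(),
        config.thresholds,
    )
    categories = pd.Series([a.category for a in assignments], index=ids,
                           name="category")
    results["dendrogram"] = dend
    results["assignments"] = assignments
    results["categories"] = categories

    # --- PCA and spatial structure --------------------------------------
    coef = _coef_matrix(desc)
    pca = pca_unstandardized(coef.to_numpy())
    pc_scores = pca.scores_
    # orient PC1 positively with mean final germination (responsivity axis)
    mean_final = desc[["T25_15_final", "T35_15_final"]].mean(axis=1).to_numpy()
    if np.corrcoef(pc_scores[:, 0], mean_final)[0, 1] < 0:
        pc_scores = pc_scores.copy()
        pc_scores[:, 0] = -pc_scores[:, 0]
    results["pca"] = pca
    results["pc_scores"] = pd.DataFrame(
        pc_scores[:, :2], index=ids, columns=["PC1", "PC2"]
    )

    D = haversine_distances(coords[["lon", "lat"]].to_numpy())
    classes = make_distance_classes(D, n_classes=config.n_distance_classes)
    results["distance_classes"] = classes
    results["responsivity_correlogram"] = morans_i_correlogram(
        pc_scores[:, 0], classes, n_permutations=config.n_permutations,
        seed=int(rng.integers(2**31 - 1)),
    )

    env_pruned, prune_log = collinearity_prune(env)
    results["env_pruned"] = env_pruned
    results["prune_log"] = prune_log
    results["env_correlations"] = axis_env_correlations(
        pc_scores[:, :2], env_pruned, coords[["lon", "lat"]].to_numpy(),
        classes=classes,
    )

    # --- PCNM + RDA variance partitioning -------------------------------
    Y = coef.to_numpy() - coef.to_numpy().mean(axis=0)
    V, eigvals, trunc = pcnm_eigenvectors(dist=D)
    pcnm_df = pd.DataFrame(V, index=ids,
                           columns=[f"PCNM{i+1}" for i in range(V.shape[1])])
    sel_pcnm = forward_select(Y, pcnm_df, alpha=config.forward_alpha,
                              n_permutations=config.n_permutations,
                              seed=int(rng.integers(2**31 - 1)))
    sel_env = forward_select(Y, env_pruned, alpha=config.forward_alpha,
                             n_permutations=config.n_permutations,
                             seed=int(rng.integers(2**31 - 1)))
    results["pcnm"] = pcnm_df
    results["pcnm_selected"] = sel_pcnm
    results["env_selected"] = sel_env
    X_space = pcnm_df[sel_pcnm["variable"]].to_numpy() if len(sel_pcnm) else V[:, :1]
    results["partition"] = variance_partition(
        Y, env_pruned.to_numpy(), X_space,
        n_permutations=config.n_permutations,
        seed=int(rng.integers(2**31 - 1)),
    )

    # --- niche overlap ---------------------------------------------------
    if env_grids:
        grids = list(env_grids.values()) if isinstance(env_grids, dict) else list(env_grids)
        overlaps = {}
        xy = coords[["lon", "lat"]].to_numpy()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            for a, b in (("N", "D"), ("N", "R"), ("R", "D")):
                ca, cb = categories == a, categories == b
                if ca.sum() < 3 or cb.sum() < 3:
                    continue
                overlaps[f"{a}-{b}"] = equivalency_test(
                    OccurrenceSet(a, xy[ca.to_numpy()]),
                    OccurrenceSet(b, xy[cb.to_numpy()]),
                    grids, n_reps=config.equivalency_reps,
                    seed=int(rng.integers(2**31 - 1)),
                )
        results["niche_overlap"] = overlaps

    # --- trait statistics ------------------------------------------------
    if traits is not None:
        traits = traits.loc[ids]
        cat = categories.to_numpy()
        results["kruskal_thickness"] = kruskal_wallis(
            traits["testa_um"].to_numpy(), cat
        )
        morpho = [c for c in ("AS", "PL", "L", "W", "LWR", "CS", "HSW")
                  if c in traits.columns]
        if morpho:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                results["ordinal_models"] = ordinal_logistic(cat, traits[morpho])
        if {"soluble_pa", "insoluble_pa", "total_pa"} <= set(traits.columns):
            ratio = traits["soluble_pa"] / traits["insoluble_pa"]
            present = set(cat)
            dormantish = sorted(present & {"D", "R"})
            contrast = None
            if "N" in present and dormantish:
                contrast = {c: 1.0 / len(dormantish) for c in dormantish}
                contrast["N"] = -1.0
            results["pa_ancova"] = ancova_ratio(
                ratio.to_numpy(), cat, traits["total_pa"].to_numpy(),
                contrast=contrast,
            )

    if config.output_dir:
        _write_outputs(results, config)
    return results


def _write_outputs(results: dict, config: RunConfig) -> None:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    results["descriptors"].to_csv(out / "descriptors.csv")
    pd.DataFrame(
        [(a.accession_id, a.category, a.subgroup, a.mean_final_25, a.mean_final_35)
         for a in results["assignments"]],
        columns=["accession_id", "category", "subgroup",
                 "mean_final_25_fraction", "mean_final_35_fraction"],
    ).to_csv(out / "dormancy_assignments.csv", index=False)
    (out / "dendrogram_combined.nwk").write_text(results["dendrogram"].to_newick())
    results["pc_scores"].to_csv(out / "pc_scores.csv")
    results["env_correlations"].to_csv(out / "env_axis_correlations.csv", index=False)
    results["env_selected"].to_csv(out / "forward_selection_env.csv", index=False)
    results["pcnm_selected"].to_csv(out / "forward_selection_pcnm.csv", index=False)
    results["partition"].as_frame().to_csv(out / "variance_partition.csv", index=False)
    cg = results["responsivity_correlogram"]
    pd.DataFrame({
        "class_upper_km": cg.classes.boundaries[1:],
        "morans_i": cg.i_values,
        "p": cg.p_values,
        "n_pairs": cg.pair_counts,
    }).to_csv(out / "responsivity_correlogram.csv", index=False)
    if "niche_overlap" in results:
        pd.DataFrame(
            [(k, v.d, v.i, v.p_d, v.p_i)
             for k, v in results["niche_overlap"].items()],
            columns=["pair", "schoener_d", "hellinger_i", "p_d", "p_i"],
        ).to_csv(out / "niche_overlap.csv", index=False)
    log = {
        "germfda_version": __version__,
        "seed": config.seed,
        "n_permutations": config.n_permutations,
        "equivalency_reps": config.equivalency_reps,
        "n_clusters": config.n_clusters,
        "spline_degree": config.spline.degree,
        "spline_knot_spacing": config.spline.knot_spacing,
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=2))
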