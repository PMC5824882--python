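"""End-to-end orchestration: simulate -> preprocess -> discover ->
sc-cluster -> classify -> cohort.

A single run is driven by one config (YAML file or dict) and a seed. All
randomness derives from that seed, so a rerun with the same config is
byte-identical in every output file; wall-clock timings are the only
non-deterministic quantity and live in their own file (``timings.json``).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import compare_groups
from .datatypes import RunConfig, gate_to_subset
from .discovery import (
    anova_across_gates,
    collapse_gates,
    correlation_cluster,
    pca,
    specificity_scale,
)
from .io import write_expression, write_expression_mtx, write_metadata
from .lda import (
    classification_summary,
    classify_cells,
    fit_lda,
    pairwise_subset_de,
    select_lda_genes,
)
from .preprocess import filter_cells_by_genes_detected, residualize_donor
from .sc_cluster import (
    adjusted_rand_index,
    cluster_cells,
    permutation_concordance,
    select_high_mean_high_variance,
)
from .simulate import (
    GeneratorConfig,
    generate_bulk_cohort,
    generate_donor_proportions,
    generate_single_cells,
)

logger = logging.getLogger(__name__)

__all__ = ["load_config", "run_pipeline"]

#: Study-design sizes of the companion cohorts, distinct from the bulk
#: donors in the generator config: 2 RA + 2 OA single-cell donors and a
#: 16 RA / 26 OA flow-cytometry proportion cohort.
DEFAULT_PIPELINE = {
    "sc_donors_ra": 2,
    "sc_donors_oa": 2,
    "cohort_donors_ra": 16,
    "cohort_donors_oa": 26,
}


def load_config(path_or_dict) -> dict:
    """Load and normalize a pipeline config (YAML path or dict).

    Sections: ``seed`` (int), ``generator`` (GeneratorConfig fields),
    ``run`` (RunConfig fields), ``pipeline`` (companion cohort sizes).
    """
    if isinstance(path_or_dict, (str, Path)):
        with open(path_or_dict) as fh:
            cfg = yaml.safe_load(fh) or {}
    else:
        cfg = dict(path_or_dict or {})
    seed = int(cfg.get("seed", 0))
    gen_kwargs = dict(cfg.get("generator", {}))
    gen_kwargs.setdefault("seed", seed)
    for key in ("proportions_ra", "proportions_oa", "gates"):
        if key in gen_kwargs:
            gen_kwargs[key] = tuple(gen_kwargs[key])
    run_kwargs = dict(cfg.get("run", {}))
    run_kwargs.setdefault("seed", seed)
    pipeline = {**DEFAULT_PIPELINE, **cfg.get("pipeline", {})}
    return {
        "seed": seed,
        "generator": GeneratorConfig(**gen_kwargs),
        "run": RunConfig(**run_kwargs),
        "pipeline": pipeline,
    }


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_jsonify) + "\n")


def _jsonify(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON serializable: {type(x)}")


def run_pipeline(config, outdir: str | Path, seed: int | None = None) -> dict:
    """Execute every stage; return the pipeline report (also written as JSON).

    ``seed`` overrides the config seed. Any stage failure surfaces with
    the stage name attached.
    """
    cfg = load_config(config)
    if seed is not None:
        cfg["seed"] = int(seed)
        cfg["generator"] = dataclasses.replace(cfg["generator"], seed=int(seed))
        cfg["run"] = dataclasses.replace(cfg["run"], seed=int(seed))
    gen: GeneratorConfig = cfg["generator"]
    run: RunConfig = cfg["run"]
    pl = cfg["pipeline"]
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    timings: dict[str, float] = {}
    report: dict = {
        "seed": cfg["seed"],
        "version": __version__,
        "config": {
            "generator": dataclasses.asdict(gen),
            "run": run.to_dict(),
            "pipeline": pl,
        },
        "stages": {},
        "metrics": {},
    }

    def stage(name):
        def wrap(fn):
            t0 = time.perf_counter()
            try:
                fn()
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            timings[name] = time.perf_counter() - t0

        return wrap

    state: dict = {}

    @stage("simulate")
    def _simulate():
        d = outdir / "simulate"
        d.mkdir(exist_ok=True)
        bulk, bulk_meta, bulk_truth = generate_bulk_cohort(gen)
        sc_cfg = dataclasses.replace(
            gen, n_donors_ra=pl["sc_donors_ra"], n_donors_oa=pl["sc_donors_oa"]
        )
        sc, sc_meta, sc_truth = generate_single_cells(sc_cfg)
        coh_cfg = dataclasses.replace(
            gen,
            n_donors_ra=pl["cohort_donors_ra"],
            n_donors_oa=pl["cohort_donors_oa"],
        )
        props, prop_truth = generate_donor_proportions(coh_cfg)
        write_expression(bulk, d / "bulk_expression.tsv")
        write_metadata(bulk_meta, d / "bulk_metadata.tsv")
        write_expression_mtx(sc, d / "sc_expression")
        write_metadata(sc_meta, d / "sc_metadata.tsv")
        props.to_csv(d / "donor_proportions.tsv", sep="\t", index=False)
        _write_json(
            {
                "true_subset_bulk": bulk_truth.true_subset,
                "true_subset_cells": sc_truth.true_subset,
                "signature_genes": {
                    s: sorted(g) for s, g in bulk_truth.signature_genes.items()
                },
                "planted_sc_proportions": {
                    k: v.tolist() for k, v in sc_truth.planted_proportions.items()
                },
                "planted_cohort_proportions": {
                    k: v.tolist() for k, v in prop_truth.planted_proportions.items()
                },
            },
            d / "ground_truth.json",
        )
        state.update(
            bulk=bulk, bulk_meta=bulk_meta, bulk_truth=bulk_truth,
            sc=sc, sc_meta=sc_meta, sc_truth=sc_truth, props=props,
        )
        report["stages"]["simulate"] = {
            "outdir": d.name,
            "n_bulk_samples": len(bulk.sample_ids),
            "n_cells": len(sc.sample_ids),
            "n_cohort_donors": len(props),
        }

    @stage("preprocess")
    def _preprocess():
        d = outdir / "preprocess"
        d.mkdir(exist_ok=True)
        sc_f, sc_meta_f, rep = filter_cells_by_genes_detected(
            state["sc"], state["sc_meta"], run.sc_min_genes
        )
        resid = residualize_donor(state["bulk"], state["bulk_meta"])
        state.update(sc_f=sc_f, sc_meta_f=sc_meta_f, resid=resid)
        write_metadata(sc_meta_f, d / "sc_metadata_filtered.tsv")
        _write_json(rep, d / "cell_filter_report.json")
        report["stages"]["preprocess"] = {"outdir": d.name, **rep}

    @stage("discover")
    def _discover():
        d = outdir / "discover"
        d.mkdir(exist_ok=True)
        de = anova_across_gates(state["resid"], state["bulk_meta"])
        sig = de.loc[de["q_value"] < run.fdr_discovery, "gene_id"].tolist()
        de.to_csv(d / "anova.tsv", sep="\t", index=False)
        resid = state["resid"]
        gene_row = {g: i for i, g in enumerate(resid.gene_ids)}
        sig_rows = [gene_row[g] for g in sig]
        if len(sig_rows) >= 2:
            scaled = specificity_scale(resid.values[sig_rows, :], resid.sample_ids)
            n_pc = min(10, *scaled.T.shape)
            scores, _, var_exp = pca(scaled.T, n_pc)
            pd.DataFrame(
                scores,
                index=resid.sample_ids,
                columns=[f"PC{i + 1}" for i in range(scores.shape[1])],
            ).to_csv(d / "pca_scores.tsv", sep="\t", index_label="sample_id")
            cl = correlation_cluster(
                resid.values[sig_rows, :].T, resid.sample_ids, run.linkage_method
            )
        else:
            var_exp = np.array([])
            cl = None
        marker_map, _ = collapse_gates(state["bulk_meta"], rule="marker")
        dd_map, dd_report = (
            collapse_gates(state["bulk_meta"], cl, rule="data_driven")
            if cl is not None
            else (marker_map, {"rule": "marker", "disagreement_rate": 0.0})
        )
        pd.DataFrame(
            {
                "sample_id": marker_map.index,
                "subset_marker": marker_map.values,
                "subset_data_driven": dd_map.loc[marker_map.index].values,
            }
        ).to_csv(d / "subset_map.tsv", sep="\t", index=False)
        state.update(subset_map=marker_map)
        report["stages"]["discover"] = {
            "outdir": d.name,
            "n_significant": len(sig),
            "variance_explained": var_exp[:3].tolist(),
            "collapse_disagreement_rate": dd_report["disagreement_rate"],
        }
        report["metrics"]["anova_significant_genes"] = len(sig)

    @stage("sc_cluster")
    def _sc_cluster():
        d = outdir / "sc_cluster"
        d.mkdir(exist_ok=True)
        sc_f, sc_meta_f = state["sc_f"], state["sc_meta_f"]
        genes = select_high_mean_high_variance(sc_f, run.topq_mean, run.topq_var)
        _, labels = cluster_cells(sc_f, genes, k=3, linkage_method=run.linkage_method)
        gate_subsets = (
            sc_meta_f.set_index("sample_id")["gate"].map(gate_to_subset)
        )
        labels = labels.loc[gate_subsets.index]
        perm_seed = int(
            np.random.SeedSequence([cfg["seed"], 99]).generate_state(1)[0]
            % (2**31)
        )
        conc = permutation_concordance(
            labels.to_numpy(),
            gate_subsets.to_numpy(),
            B=run.n_permutations,
            seed=perm_seed,
        )
        truth = state["sc_truth"].true_subset
        true_labels = np.array([truth[c] for c in labels.index])
        ari_truth = adjusted_rand_index(labels.to_numpy(), true_labels)
        pd.DataFrame(
            {"cell_id": labels.index, "cluster": labels.values}
        ).to_csv(d / "cell_clusters.tsv", sep="\t", index=False)
        _write_json(
            {"selected_genes": genes, **conc.to_dict(),
             "ari_vs_truth": ari_truth},
            d / "concordance.json",
        )
        state.update(sc_clusters=labels, gate_subsets=gate_subsets)
        report["stages"]["sc_cluster"] = {
            "outdir": d.name,
            "n_selected_genes": len(genes),
        }
        report["metrics"]["sc_selected_genes"] = len(genes)
        report["metrics"]["cluster_gate_ari"] = conc.observed
        report["metrics"]["cluster_truth_ari"] = float(ari_truth)
        report["metrics"]["permutation_p"] = conc.p_value

    @stage("classify")
    def _classify():
        d = outdir / "classify"
        d.mkdir(exist_ok=True)
        resid = state["resid"]
        subset_map = state["subset_map"]
        de = pairwise_subset_de(resid, subset_map)
        de.to_csv(d / "pairwise_de.tsv", sep="\t", index=False)
        genes = select_lda_genes(
            de, state["sc_f"], run.fdr_pairwise, run.sc_expr_floor_log2
        )
        # restore the grand per-gene mean so bulk residuals live on the
        # same scale as single-cell log2 TPM
        train = resid.values + state["bulk"].values.mean(axis=1, keepdims=True)
        model = fit_lda(
            train,
            subset_map,
            genes,
            resid.gene_ids,
            resid.sample_ids,
            run.lda_shrinkage,
        )
        cls = classify_cells(model, state["sc_f"])
        cls.to_csv(d / "classifications.tsv", sep="\t", index=False)
        summary = classification_summary(cls, state["gate_subsets"])
        truth = state["sc_truth"].true_subset
        acc = float(
            (cls["predicted"].to_numpy()
             == np.array([truth[c] for c in cls["cell_id"]])).mean()
        )
        summary["accuracy_vs_truth"] = acc
        _write_json({"n_lda_genes": len(genes), **summary}, d / "summary.json")
        report["stages"]["classify"] = {"outdir": d.name, "n_lda_genes": len(genes)}
        report["metrics"]["lda_gene_count"] = len(genes)
        report["metrics"]["median_max_posterior"] = summary["median_max_posterior"]
        report["metrics"]["proportion_rmse"] = summary["proportion_rmse"]
        report["metrics"]["classification_accuracy_vs_truth"] = acc

    @stage("cohort")
    def _cohort():
        d = outdir / "cohort"
        d.mkdir(exist_ok=True)
        comparisons = compare_groups(state["props"], alpha=0.05, m=run.bonferroni_m)
        rows = [c.to_dict() for c in comparisons]
        pd.DataFrame(rows).to_csv(d / "group_comparisons.tsv", sep="\t", index=False)
        _write_json(rows, d / "group_comparisons.json")
        report["stages"]["cohort"] = {"outdir": d.name}
        report["metrics"]["group_comparisons"] = rows

    report["timings"] = "see timings.json"
    _write_json(report, outdir / "report.json")
    _write_json(timings, outdir / "timings.json")
    return report
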