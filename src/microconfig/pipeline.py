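"""End-to-end pipeline orchestration.

``run_all`` executes every stage on either a simulated cohort or user-supplied
tables, writes one TSV per stage output plus a JSON manifest of every
parameter and seed, and is bit-reproducible under a fixed configuration.

One global seed is expanded into per-stage seeds deterministically:
``stage_seed = SeedSequence(global_seed, spawn_key=(STAGE_INDEX[stage],))``,
so a stage re-run standalone with its manifest seed reproduces its output.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cags import cag_abundance, cag_centroid_correlation, detect_cags
from .classify_covariates import (differential_abundance_standin, rf_classify,
                                  screen_covariates, write_da_results)
from .diet_analysis import diet_ordination, item_centroid_correlation, item_group_tests
from .inflammation_assoc import ccrepe_association, marker_genus_regression
from .ordination import (centroid_group_test, median_centroid, pairwise_permanova,
                         pcoa, permanova)
from .stats_core import alpha_diversity, results_to_frame
from .stratification import label_clusters, replicate_stratification, stratify_group
from .synthetic_data import Cohort, CohortSpec, generate_cohort
from .tables_io import (AbundanceTable, prevalence_filter, read_abundance_table,
                        read_feature_table, read_metadata, to_relative)
from .transforms import bray_curtis

logger = logging.getLogger(__name__)

STAGE_INDEX = {
    "simulate": 0, "ordination": 1, "cags": 2, "stratify": 3,
    "classify": 4, "diff": 5, "covary": 6, "diet": 7, "inflam": 8,
}

DEFAULT_CONFIG = {
    "seed": 0,
    "output_dir": "microconfig_out",
    "simulate": None,          # dict of CohortSpec overrides, or None
    "inputs": None,            # dict with abundance/metadata/diet/markers paths
    "reference_group": "control",
    "confounders": ["study", "patient_id"],
    "min_prevalence": 0.10,
    "n_permutations": 999,
    "cag_k": 4,
    "rf_trees": 500,
    "ccrepe_permutations": 1000,
    "stratify_group": "HS",
    "covariate_exposures": ["antibiotics_last_year", "cardiovascular_drugs",
                            "current_antibiotics", "surgery",
                            "carbonated_soft_drinks"],
}


def stage_seed(global_seed: int, stage: str) -> int:
    ss = np.random.SeedSequence(global_seed, spawn_key=(STAGE_INDEX[stage],))
    return int(ss.generate_state(1)[0] % 2**31)


def load_config(path) -> dict:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    return merge_config(user)


def merge_config(user: dict) -> dict:
    unknown = set(user) - set(DEFAULT_CONFIG)
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    config = dict(DEFAULT_CONFIG)
    config.update(user)
    return config


def _load_inputs(config: dict):
    """Return (AbundanceTable, metadata, diet, markers, truth|None)."""
    if config["inputs"]:
        paths = config["inputs"]
        for key in ("abundance", "metadata"):
            if key not in paths:
                raise FileNotFoundError(f"inputs must name an {key!r} table")
        meta = read_metadata(paths["metadata"])
        abundance = read_abundance_table(paths["abundance"],
                                         known_sample_ids=list(meta.index))
        diet = read_feature_table(paths["diet"]) if paths.get("diet") else None
        markers = read_feature_table(paths["markers"]) if paths.get("markers") else None
        return abundance, meta, diet, markers, None
    overrides = dict(config["simulate"] or {})
    spec = CohortSpec(**overrides)
    cohort = generate_cohort(spec, seed=stage_seed(config["seed"], "simulate"))
    return cohort.abundance, cohort.metadata, cohort.diet, cohort.markers, cohort.truth


def run_all(config, output_dir=None) -> dict:
    """Run every stage; returns the manifest (also written as manifest.json)."""
    if isinstance(config, (str, Path)):
        config = load_config(config)
    else:
        config = merge_config(dict(config))
    out = Path(output_dir or config["output_dir"])
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    artifacts: list[str] = []
    manifest = {"microconfig_version": __version__, "config": _jsonable(config),
                "stage_seeds": {s: stage_seed(seed, s) for s in STAGE_INDEX},
                "library_versions": _library_versions(), "artifacts": artifacts}

    def save(frame, name, **kwargs):
        path = out / name
        if isinstance(frame, (AbundanceTable,)):
            frame.to_tsv(path)
        elif isinstance(frame, pd.Series):
            frame.to_frame().to_csv(path, sep="\t", index_label="sample_id")
        else:
            frame.to_csv(path, sep="\t", **kwargs)
        artifacts.append(name)

    try:
        abundance, metadata, diet, markers, truth = _load_inputs(config)
        save(abundance, "abundance.tsv")
        save(metadata, "metadata.tsv", index_label="sample_id")
        if diet is not None:
            save(diet, "diet.tsv", index_label="sample_id")
        if markers is not None and len(markers):
            save(markers, "markers.tsv", index_label="sample_id")

        # filter + relative ------------------------------------------------
        filtered = prevalence_filter(abundance, config["min_prevalence"])
        save(filtered, "filtered_abundance.tsv")
        rel = to_relative(filtered)
        groups = metadata["group"]
        reference = config["reference_group"]
        n_perm = int(config["n_permutations"])

        # diversity ---------------------------------------------------------
        diversity = pd.DataFrame({
            "shannon": alpha_diversity(filtered, "shannon"),
            "simpson": alpha_diversity(filtered, "simpson"),
        })
        save(diversity, "alpha_diversity.tsv", index_label="sample_id")

        # ordination / centroid / permanova ----------------------------------
        dm = bray_curtis(rel)
        ordination = pcoa(dm, k=2)
        save(ordination.coordinates, "ordination_coords.tsv", index_label="sample_id")
        centroid = median_centroid(ordination, reference, groups)
        save(centroid.distances, "centroid_distances.tsv")
        omnibus, pairwise = centroid_group_test(centroid, groups)
        save(results_to_frame([omnibus] + pairwise), "centroid_tests.tsv", index=False)
        perm = permanova(dm, metadata, "group", confounders=config["confounders"],
                         n_perm=n_perm, seed=stage_seed(seed, "ordination"))
        save(perm.terms, "permanova.tsv", index=False)
        pw = pairwise_permanova(dm, groups, metadata, confounders=None,
                                n_perm=n_perm, seed=stage_seed(seed, "ordination"))
        save(pw, "pairwise_permanova.tsv", index=False)

        # CAGs ---------------------------------------------------------------
        assignment = detect_cags(rel, k=int(config["cag_k"]))
        save(assignment.assignments.rename("cag_id"), "cag_assignment.tsv")
        cag_ab = cag_abundance(rel, assignment)
        save(cag_ab, "cag_abundance.tsv", index_label="sample_id")
        cag_corr = cag_centroid_correlation(rel, assignment, centroid)
        save(cag_corr, "cag_centroid_correlation.tsv", index=False)

        # stratification -----------------------------------------------------
        target_group = config["stratify_group"]
        target_ids = groups.index[groups == target_group]
        strat_frame = None
        if len(target_ids) >= 4:
            sub = rel.restrict_samples(target_ids)
            clusters = stratify_group(sub, k=2)
            strat = label_clusters(clusters, centroid, ordination)
            strat_frame = clusters.rename("cluster").to_frame()
            strat_frame["label"] = strat.sample_labels
            strat_frame["centroid_distance"] = centroid.distances.reindex(strat_frame.index)
            save(strat_frame, "stratification.tsv", index_label="sample_id")

        # classification -----------------------------------------------------
        two_group = groups[groups.isin([reference, "CD"])]
        rf = rf_classify(rel, two_group, predict_on=list(target_ids),
                         n_trees=int(config["rf_trees"]),
                         seed=stage_seed(seed, "classify"))
        rf_summary = pd.DataFrame([{
            "oob_error": rf.oob_error,
            **{f"predicted_fraction_{c}": rf.predicted_fraction.get(c, np.nan)
               for c in rf.classes},
            "n_trees": rf.n_trees, "seed": rf.seed,
        }])
        save(rf_summary, "rf_report.tsv", index=False)
        save(rf.importance, "rf_importance.tsv", index=False)

        # differential abundance ----------------------------------------------
        if strat_frame is not None:
            da_labels = strat_frame["label"]
        else:
            da_labels = two_group
        da = differential_abundance_standin(
            filtered.restrict_samples(da_labels.index), da_labels)
        write_da_results(da, out / "da_results.tsv")
        artifacts.append("da_results.tsv")

        # covariates -----------------------------------------------------------
        if strat_frame is not None:
            meta_cov = metadata.loc[strat_frame.index].copy()
            if diet is not None:
                for item in config["covariate_exposures"]:
                    if item in diet.columns:
                        meta_cov[item] = diet.loc[strat_frame.index, item]
            cov = screen_covariates(strat_frame["label"], meta_cov,
                                    config["covariate_exposures"])
            save(cov, "covariate_models.tsv", index=False)

        # diet -----------------------------------------------------------------
        if diet is not None:
            dd = diet_ordination(diet, groups, reference=reference,
                                 n_perm=n_perm, seed=stage_seed(seed, "diet"))
            save(dd.ordination.coordinates, "diet_ordination.tsv",
                 index_label="sample_id")
            save(dd.permanova.terms, "diet_permanova.tsv", index=False)
            save(item_centroid_correlation(diet, dd.centroid),
                 "diet_item_correlations.tsv", index=False)
            save(item_group_tests(diet, groups), "diet_item_tests.tsv", index=False)

        # inflammation ----------------------------------------------------------
        if markers is not None and len(markers):
            sig = da.loc[da["significant"], "genus_id"].tolist() if len(da) else []
            genus_set = sig or None
            hs_rel = rel.restrict_samples(
                rel.data.index.intersection(markers.index))
            edges, counts = marker_genus_regression(markers, hs_rel,
                                                    genus_set=genus_set)
            save(edges, "inflammation_regression.tsv", index=False)
            save(counts.to_frame(), "inflammation_counts.tsv",
                 index_label="marker_id")
            cc = ccrepe_association(markers, hs_rel,
                                    n_perm=int(config["ccrepe_permutations"]),
                                    seed=stage_seed(seed, "inflam"))
            save(cc, "ccrepe_edges.tsv", index=False)
    except Exception:
        (out / "FAILED").write_text("pipeline stage failed; partial outputs retained\n")
        raise

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def _library_versions() -> dict:
    import scipy
    import sklearn
    import statsmodels

    return {
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "scikit-learn": sklearn.__version__,
        "statsmodels": statsmodels.__version__,
    }
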