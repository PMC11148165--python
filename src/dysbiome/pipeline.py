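"""End-to-end orchestration: simulate/ingest → QC → diversity → DMM →
dysbiosis index → composition → differential abundance → survival.

``run_pipeline`` executes every stage per compartment, writes intermediate
TSVs and a machine-readable JSON report, and is a pure function of
(config, seed): rerunning with the same config produces a byte-identical
report. Stage failures abort with the stage name and leave a FAILED marker
next to the partial outputs.
"""

from __future__ import annotations

import json
import logging
import platform
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .composition import aggregate_class_abundance, filter_low_abundance, gut_origin_enrichment
from .containers import COMPARTMENTS, INTERVALS, CountTable
from .diffab import moderated_t_test
from .dmm import label_clusters, select_k
from .dysbiosis import derive_index
from .ecology import clr_transform, qc_filter, shannon_table
from .io import write_count_table, write_metadata, write_model
from .survival import fisher_association, fit_cox, fit_joint, kaplan_meier
from .synthetic import SimulationConfig, simulate_cohort

log = logging.getLogger("dysbiome.pipeline")

DEFAULT_CONFIG = {
    "seed": 0,
    "n_subjects": 100,
    "compartments": list(COMPARTMENTS),
    "min_reads": 1000,
    "rarefy_depth": 1000,
    "rarefy_reps": 100,
    "kmax": 5,
    "prevalence_min": 0.10,
    "dmm_n_init": 3,
    "n_perm": 999,
    "n_boot": 100,
    "gut_origin_threshold": 0.30,
    "dominance_threshold": 0.50,
    "top_n_taxa": 50,
    "run_joint_model": False,
    "out_dir": "dysbiome_output",
}


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    """Flat key-value JSON config merged over defaults; unknown keys rejected."""
    config = dict(DEFAULT_CONFIG)
    loaded = {}
    if path is not None:
        loaded = json.loads(Path(path).read_text(encoding="utf-8"))
    for source in (loaded, overrides or {}):
        for key, value in source.items():
            if key not in DEFAULT_CONFIG:
                raise KeyError(f"unknown config key {key!r}; allowed: {sorted(DEFAULT_CONFIG)}")
            config[key] = value
    return config


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        return round(float(obj), 10) if np.isfinite(obj) else None
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj]
    return obj


def run_pipeline(config: dict | str | Path, out_dir: str | Path | None = None) -> dict:
    """Run the full analysis on a synthetic cohort and return the report dict."""
    if not isinstance(config, dict):
        config = load_config(config)
    out = Path(out_dir or config["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    failed_marker = out / "FAILED"
    if failed_marker.exists():
        failed_marker.unlink()
    stage = "configure"
    try:
        report: dict = {
            "provenance": {
                "package": "dysbiome",
                "version": __version__,
                "python": platform.python_version(),
                "seed": config["seed"],
                "config": {k: config[k] for k in sorted(config) if k != "out_dir"},
            },
            "compartments": {},
        }

        stage = "simulate"
        log.info("simulating cohort (n_subjects=%d)", config["n_subjects"])
        cohort = simulate_cohort(
            SimulationConfig(
                seed=config["seed"],
                n_subjects=config["n_subjects"],
                compartments=tuple(config["compartments"]),
            )
        )
        write_metadata(cohort.metadata, out / "metadata.tsv")
        cohort.outcomes.to_csv(out / "outcomes.tsv", sep="\t", index=False)

        baseline_labels: dict[str, pd.Series] = {}
        persister_info: dict[str, pd.Series] = {}
        for compartment in config["compartments"]:
            stage = f"{compartment}:qc"
            tables = cohort.count_tables[compartment]
            merged = CountTable(
                counts=np.vstack([tables[iv].counts for iv in INTERVALS if iv in tables]),
                sample_ids=[s for iv in INTERVALS if iv in tables for s in tables[iv].sample_ids],
                taxon_ids=tables["baseline"].taxon_ids,
                compartment=compartment,
            )
            write_count_table(merged, out / f"counts_{compartment}.tsv")
            qc_table, qc_report = qc_filter(merged, cohort.metadata, min_reads=config["min_reads"])
            qc_table = filter_low_abundance(qc_table)
            comp_report = {
                "qc": {
                    "n_input": qc_report.n_input,
                    "n_retained": qc_report.n_retained,
                    "removals": qc_report.removals,
                    "n_taxa_after_filter": qc_table.n_taxa,
                }
            }

            stage = f"{compartment}:diversity"
            shannon = shannon_table(
                qc_table,
                depth=config["rarefy_depth"],
                reps=config["rarefy_reps"],
                seed=config["seed"],
            )
            shannon.rename_axis("sample_id").to_frame().to_csv(
                out / f"shannon_{compartment}.tsv", sep="\t"
            )

            stage = f"{compartment}:dmm"
            model = select_k(
                qc_table,
                K_max=config["kmax"],
                prevalence_min=config["prevalence_min"],
                n_init=config["dmm_n_init"],
                seed=config["seed"],
            )
            labeling = label_clusters(model, shannon.loc[qc_table.sample_ids].to_numpy())
            sample_labels = pd.Series(
                labeling.sample_labels(model), index=qc_table.sample_ids, name="cluster"
            )
            assignments = pd.DataFrame(
                {
                    "component": model.hard_assignments(),
                    "cluster": sample_labels.to_numpy(),
                    "max_responsibility": model.responsibilities.max(axis=1).round(6),
                },
                index=pd.Index(qc_table.sample_ids, name="sample_id"),
            )
            assignments.to_csv(out / f"dmm_{compartment}.tsv", sep="\t")
            comp_report["dmm"] = {
                "selected_K": model.K,
                "laplace_log_evidence": model.laplace_log_evidence,
                "cluster_sizes": sample_labels.value_counts().sort_index().to_dict(),
                "mean_shannon": {labeling.labels[k]: v for k, v in labeling.mean_shannon.items()},
            }

            stage = f"{compartment}:dysbiosis_index"
            derived = derive_index(
                qc_table,
                sample_labels.to_numpy(),
                shannon,
                compartment=compartment,
                top_n=config["top_n_taxa"],
                seed=config["seed"],
            )
            write_model(derived.model, out / f"dysbiosis_index_{compartment}.json")
            comp_report["dysbiosis_index"] = {
                "accuracy": derived.accuracy,
                "ci": list(derived.ci),
                "n_test": derived.n_test,
                "n_features": len(derived.selected_features),
                "features": derived.selected_features,
            }

            stage = f"{compartment}:composition"
            meta = cohort.metadata.set_index("sample_id").loc[qc_table.sample_ids]
            shares_ox, _ = aggregate_class_abundance(qc_table, cohort.annotations, "oxygen")
            shares_pa, _ = aggregate_class_abundance(qc_table, cohort.annotations, "pathogenicity")
            by_interval = {}
            for iv in INTERVALS:
                idx = meta.index[meta["interval"] == iv]
                if len(idx) == 0:
                    continue
                by_interval[iv] = {
                    "obligate_anaerobe": shares_ox.loc[idx, "obligate_anaerobe"].mean(),
                    "respiratory_pathogen": shares_pa.loc[idx, "respiratory_pathogen"].mean(),
                }
            rel = pd.DataFrame(
                qc_table.relative_abundance(), index=qc_table.sample_ids, columns=qc_table.taxon_ids
            )
            enriched = [
                sid
                for sid in qc_table.sample_ids
                if gut_origin_enrichment(
                    rel.loc[sid], cohort.annotations, threshold=config["gut_origin_threshold"]
                )
            ]
            comp_report["composition"] = {
                "class_means_by_interval": by_interval,
                "gut_origin_enriched_fraction": len(enriched) / qc_table.n_samples,
            }

            stage = f"{compartment}:diffab"
            base_idx = meta.index[meta["interval"] == "baseline"]
            base_labels = sample_labels.loc[base_idx]
            lowhigh = base_labels[base_labels.isin(["Low", "High"])]
            if lowhigh.nunique() == 2 and lowhigh.value_counts().min() >= 2:
                clr = clr_transform(qc_table.select_samples(list(lowhigh.index)))
                diff = moderated_t_test(clr, lowhigh.to_numpy())
                diff.to_csv(out / f"diffab_{compartment}.tsv", sep="\t", index=False)
                comp_report["diffab"] = {
                    "n_significant": int(diff["significant"].sum()),
                    "top_taxa": diff.loc[diff["significant"], "taxon"].head(10).tolist(),
                }
            else:
                comp_report["diffab"] = {"n_significant": None, "note": "insufficient Low/High baseline samples"}

            stage = f"{compartment}:survival"
            subj_base = (
                meta.loc[base_idx, ["subject_id"]]
                .assign(cluster=base_labels)
                .drop_duplicates("subject_id")
                .set_index("subject_id")
            )
            records = cohort.outcomes.set_index("subject_id").join(subj_base["cluster"], how="inner")
            curves, logrank_p = kaplan_meier(records.reset_index(), groups="cluster")
            records["low_cluster"] = (records["cluster"] == "Low").astype(int)
            cox_res = None
            if records["low_cluster"].nunique() == 2 and records["event"].sum() > 0:
                cox = fit_cox(
                    records.reset_index(),
                    ["low_cluster", "age", "sex", "copd", "immunosuppression", "sofa"],
                )
                cox_res = {
                    "HR_low_cluster": cox.hr["low_cluster"],
                    "ci": [cox.ci_lower["low_cluster"], cox.ci_upper["low_cluster"]],
                    "p": cox.p["low_cluster"],
                }
            comp_report["survival"] = {"logrank_p": logrank_p, "adjusted_cox": cox_res}
            baseline_labels[compartment] = subj_base["cluster"]

            mid_idx = meta.index[meta["interval"] == "middle"]
            mid = (
                meta.loc[mid_idx, ["subject_id"]]
                .assign(cluster=sample_labels.loc[mid_idx])
                .drop_duplicates("subject_id")
                .set_index("subject_id")["cluster"]
            )
            persister_info[compartment] = mid
            report["compartments"][compartment] = comp_report

        stage = "co-membership"
        if {"oral", "lung"} <= set(baseline_labels):
            both = pd.concat(
                [baseline_labels["oral"].rename("oral"), baseline_labels["lung"].rename("lung")],
                axis=1,
            ).dropna()
            table = [
                [
                    int(((both["oral"] == "Low") & (both["lung"] == "Low")).sum()),
                    int(((both["oral"] == "Low") & (both["lung"] != "Low")).sum()),
                ],
                [
                    int(((both["oral"] != "Low") & (both["lung"] == "Low")).sum()),
                    int(((both["oral"] != "Low") & (both["lung"] != "Low")).sum()),
                ],
            ]
            fisher = fisher_association(table)
            report["oral_lung_low_comembership"] = {
                "odds_ratio": fisher.odds_ratio,
                "ci": list(fisher.ci),
                "p": fisher.p,
                "table": table,
            }

        stage = "persister"
        if "lung" in baseline_labels and "lung" in persister_info:
            base = baseline_labels["lung"]
            mid = persister_info["lung"]
            followed = base.index.intersection(mid.index)
            persister = ((base.loc[followed] == "Low") & (mid.loc[followed] == "Low")).astype(int)
            rec = cohort.outcomes.set_index("subject_id").loc[followed].assign(persister=persister)
            if rec["persister"].nunique() == 2 and rec["event"].sum() > 0:
                cox = fit_cox(rec.reset_index(), ["persister", "age"])
                report["low_diversity_persister"] = {
                    "n_persisters": int(persister.sum()),
                    "HR": cox.hr["persister"],
                    "ci": [cox.ci_lower["persister"], cox.ci_upper["persister"]],
                    "p": cox.p["persister"],
                }
            else:
                report["low_diversity_persister"] = {"n_persisters": int(persister.sum())}

        if config["run_joint_model"]:
            stage = "joint-model"
            meta_all = cohort.metadata.set_index("sample_id")
            lung_tables = cohort.count_tables["lung"]
            frames = []
            for iv, tab in lung_tables.items():
                sh = shannon_table(tab, depth=config["rarefy_depth"], reps=20, seed=config["seed"])
                f = pd.DataFrame({"shannon": sh})
                f["subject_id"] = meta_all.loc[f.index, "subject_id"].to_numpy()
                f["day"] = meta_all.loc[f.index, "day_from_intubation"].to_numpy()
                frames.append(f)
            long_data = pd.concat(frames)
            joint = fit_joint(
                long_data,
                cohort.outcomes,
                value="shannon",
                predictors=["day"],
                surv_covariates=["age"],
                n_boot=config["n_boot"],
                seed=config["seed"],
            )
            report["joint_model_lung_shannon"] = {
                "slope_per_day": joint.beta["day"],
                "nu": joint.nu,
                "nu_ci": list(joint.nu_ci) if joint.nu_ci else None,
                "n_boot_success": joint.n_boot_success,
            }

        stage = "report"
        payload = json.dumps(_jsonable(report), indent=1, sort_keys=True)
        (out / "report.json").write_text(payload, encoding="utf-8")
        return report
    except Exception as exc:
        failed_marker.write_text(f"stage={stage}\nerror={exc}\n", encoding="utf-8")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
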