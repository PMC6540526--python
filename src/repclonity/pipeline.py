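"""End-to-end orchestration: simulate -> diversity -> classify -> associate
-> cluster, with a validated YAML config, per-stage artifacts and a run
report.

Every stage writes a TSV/JSON artifact into the configured output
directory; the run report records per-stage row counts and SHA-256
checksums, so two runs with the same config and seed are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classifiers, diversity, io, simulate, stats
from ._errors import RepclonityError
from .types import GermlineReference, Repertoire

logger = logging.getLogger("repclonity")

__all__ = ["PipelineConfig", "run_pipeline", "summarize_table1",
           "profiles_frame", "measurement_panel", "associate_measurements"]

MEASUREMENTS = ["total_count_norm", "richness", "shannon", "gini_simpson",
                "evenness", "top_clone_prop", "mean_v_identity"]


@dataclass
class PipelineConfig:
    """Validated pipeline configuration; unknown YAML keys are rejected."""

    out_dir: str = "pipeline_out"
    seed: int = 0
    sim: dict = field(default_factory=dict)  # SimConfig overrides
    evenness_mode: str = "shannon_over_richness"
    log_base: str = "e"
    classifier_n_genes: int = 60
    classifier_folds: int = 5
    covariates: list[str] = field(default_factory=lambda: [
        "tissue_site", "sex", "age", "stage"])
    cluster_k: int = 4
    min_prop: float = 0.01
    verbosity: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {f.name for f in dc_fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise RepclonityError(f"unknown config key(s): {sorted(unknown)}")
        cfg = cls(**raw)
        sim_known = {f.name for f in dc_fields(simulate.SimConfig)}
        bad = set(cfg.sim) - sim_known
        if bad:
            raise RepclonityError(f"unknown sim config key(s): {sorted(bad)}")
        if cfg.evenness_mode not in ("shannon_over_richness", "pielou"):
            raise RepclonityError(f"unknown evenness mode {cfg.evenness_mode!r}")
        if cfg.log_base not in ("e", "2"):
            raise RepclonityError(f"unknown log base {cfg.log_base!r}")
        if cfg.cluster_k < 2:
            raise RepclonityError("cluster_k must be at least 2")
        return cfg

    def sim_config(self) -> simulate.SimConfig:
        return simulate.SimConfig(seed=self.seed, **self.sim)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def profiles_frame(repertoires: list[Repertoire],
                   germline: GermlineReference | None = None,
                   evenness_mode: str = "shannon_over_richness",
                   base: str = "e") -> pd.DataFrame:
    """Diversity profiles for a repertoire list as one row per
    (sample, chain); missing metrics are NA, never 0."""
    rows = []
    for rep in repertoires:
        prof = diversity.diversity_profile(rep, ref=germline,
                                           evenness_mode=evenness_mode,
                                           base=base)
        rows.append(vars(prof))
    return pd.DataFrame(rows)


def measurement_panel(profiles: pd.DataFrame,
                      measurements: list[str] = MEASUREMENTS,
                      samples: list[str] | None = None) -> pd.DataFrame:
    """Samples × (chain_measurement) wide panel; samples without an
    assembled chain get NA in that chain's columns."""
    panel = {}
    for chain in sorted(profiles["chain"].unique()):
        sub = profiles[profiles["chain"] == chain].set_index("sample_id")
        for m in measurements:
            panel[f"{chain}_{m}"] = sub[m]
    out = pd.DataFrame(panel)
    if samples is not None:
        out = out.reindex(samples)
    return out


def associate_measurements(profiles: pd.DataFrame, clinical: pd.DataFrame,
                           covariates: list[str], chain: str = "IGHG",
                           measurements: list[str] = MEASUREMENTS
                           ) -> pd.DataFrame:
    """Univariable and covariate-adjusted Cox association of each
    measurement with overall survival (the prognostic-screen table).

    Per measurement: univariable HR with both Wald and LRT-vs-null
    p-values, and the multivariable HR with the LRT p for adding the
    measurement to the clinical covariates. Samples lacking the chain are
    excluded from that chain's rows.
    """
    sub = profiles[profiles["chain"] == chain].set_index("sample_id")
    rows = []
    for m in measurements:
        series = sub[m].dropna()
        if series.nunique() <= 1:
            logger.warning("measurement %s is constant or absent; skipped", m)
            continue
        uni = stats.fit_cox(series.rename(m), clinical, covariates=[])
        uni_lrt = stats.likelihood_ratio_test(
            uni, stats.fit_cox_null(clinical, samples=uni.samples))
        full = stats.fit_cox(series.rename(m), clinical, covariates=covariates)
        reduced = stats.fit_cox(None, clinical.loc[full.samples],
                                covariates=covariates)
        multi_lrt = stats.likelihood_ratio_test(full, reduced)
        rows.append({
            "measurement": m,
            "hr_univariable": float(uni.hazard_ratios[m]),
            "p_univariable_wald": float(uni.wald_p[m]),
            "p_univariable_lrt": uni_lrt.p_value,
            "hr_multivariable": float(full.hazard_ratios[m]),
            "p_multivariable_lrt": multi_lrt.p_value,
            "n": full.n, "n_events": full.n_events,
        })
    return pd.DataFrame(rows).set_index("measurement")


def summarize_table1(assoc: pd.DataFrame) -> pd.DataFrame:
    """The prognostic-screen layout: one row per measurement ordered by
    univariable p ascending (ties by name), univariable HR/p then
    multivariable HR/LRT-p."""
    if assoc.empty:
        raise RepclonityError("association table is empty")
    cols = ["hr_univariable", "p_univariable_lrt",
            "hr_multivariable", "p_multivariable_lrt"]
    out = assoc[cols].copy()
    out = out.loc[sorted(out.index, key=lambda m: (out.loc[m, "p_univariable_lrt"], m))]
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage in dependency order; returns the run report."""
    logging.basicConfig(level=getattr(logging, config.verbosity, logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logfile = out / "run.log"
    handler = logging.FileHandler(logfile, mode="w")
    logger.addHandler(handler)
    report: dict = {"config": {f.name: getattr(config, f.name)
                               for f in dc_fields(config)},
                    "stages": {}}

    def record(stage: str, path: Path, rows: int) -> None:
        report["stages"].setdefault(stage, {})[path.name] = {
            "rows": rows, "sha256": _sha256(path)}
        logger.info("%s: wrote %s (%d rows)", stage, path, rows)

    try:
        # --- simulate -----------------------------------------------------
        sim_cfg = config.sim_config()
        rng = np.random.default_rng(sim_cfg.seed)
        reps, clinical_records, truth = simulate.simulate_cohort(sim_cfg, rng)
        expr, labels = simulate.simulate_expression(sim_cfg, rng)
        germline = simulate.bundled_germline(sim_cfg.n_germline,
                                             sim_cfg.germline_length)
        clones_path = out / "clones.tsv"
        io.write_clone_table(reps, clones_path, dialect="airr")
        libs_path = out / "libs.tsv"
        pd.DataFrame({"sample_id": [c.sample_id for c in clinical_records],
                      "total_reads": sim_cfg.library_size}
                     ).to_csv(libs_path, sep="\t", index=False)
        clin_path = out / "clinical.tsv"
        io.write_clinical_table(clinical_records, clin_path)
        expr_path = out / "expr.tsv"
        io.write_expression_matrix(expr, expr_path)
        truth_path = out / "truth.json"
        with open(truth_path, "w") as fh:
            json.dump({"beta_evenness": truth.beta_evenness,
                       "shm_rate": truth.shm_rate,
                       "dirichlet_alpha": truth.dirichlet_alpha,
                       "evenness": truth.evenness,
                       "response": truth.response,
                       "ighg_absent": truth.ighg_absent,
                       "class_labels": labels.to_dict()}, fh, indent=1,
                      sort_keys=True)
        for p, n in [(clones_path, sum(len(r.clones) for r in reps)),
                     (libs_path, len(clinical_records)),
                     (clin_path, len(clinical_records)),
                     (expr_path, expr.shape[0]), (truth_path, 1)]:
            record("simulate", p, n)

        # --- diversity ----------------------------------------------------
        lib_sizes = io.read_library_sizes(libs_path)
        reps_in = io.read_clone_table(clones_path, dialect="airr",
                                      library_sizes=lib_sizes)
        profiles = profiles_frame(reps_in, germline=germline,
                                  evenness_mode=config.evenness_mode,
                                  base=config.log_base)
        profiles_path = out / "profiles.tsv"
        profiles.to_csv(profiles_path, sep="\t", index=False, na_rep="NA")
        record("diversity", profiles_path, profiles.shape[0])

        # --- classify -----------------------------------------------------
        kept = classifiers.filter_training_samples(expr, labels)
        model = classifiers.train_nearest_centroid(
            expr[kept], labels.loc[kept], n_genes=config.classifier_n_genes,
            cv_folds=config.classifier_folds, seed=config.seed)
        model_path = out / "model.json"
        model.to_json(model_path)
        calls, probs = classifiers.predict_nearest_centroid(model, expr)
        calls_path = out / "calls.tsv"
        pd.concat([calls, probs], axis=1).to_csv(calls_path, sep="\t",
                                                 index_label="sample_id")
        record("classify", model_path, len(model.selected_genes))
        record("classify", calls_path, calls.shape[0])

        # --- associate ----------------------------------------------------
        clinical = io.clinical_to_frame(clinical_records)
        assoc = associate_measurements(profiles, clinical,
                                       covariates=config.covariates)
        assoc_path = out / "assoc.tsv"
        summarize_table1(assoc).join(assoc[["p_univariable_wald",
                                            "n", "n_events"]]) \
            .to_csv(assoc_path, sep="\t", na_rep="NA")
        record("associate", assoc_path, assoc.shape[0])

        # --- cluster ------------------------------------------------------
        panel = measurement_panel(profiles, samples=list(clinical.index))
        clustering = stats.cluster_measurements(panel, k=config.cluster_k)
        clusters_path = out / "clusters.tsv"
        clustering.sample_clusters.to_csv(clusters_path, sep="\t",
                                          index_label="sample_id")
        record("cluster", clusters_path, clustering.sample_clusters.shape[0])
    except Exception as err:
        stage = max(report["stages"], default="simulate")
        logger.error("pipeline failed after stage %s: %s", stage, err)
        raise
    finally:
        logger.removeHandler(handler)
        handler.close()

    report_path = out / "report.json"
    with open(report_path, "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    return report
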