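"""End-to-end orchestration: simulate -> preprocess -> DMS/DMR -> biomarker
-> classifier comparison, with a single JSON run report.

The report echoes the full configuration (defaults plus any overrides), the
named seed registry, and per-stage summaries; identical configuration and
seeds reproduce the report bit-identically.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, biomarker, differential, io, ml_eval, preprocess, synthetic
from .errors import ConfigError

logger = logging.getLogger("crcmeth")

_SEED_STAGES = ("manifest", "baseline", "effects", "intensities", "bootstrap", "ml")


@dataclass
class PipelineConfig:
    """Configuration for the demo pipeline.

    Statistical thresholds default to the standard definitions used
    throughout the package (q < 0.05; |delta beta| > 0.20 for sites, > 0.15
    for regions; detection p <= 0.01). Cohort arm sizes default to a
    20/18/22 normal/LGA/HGA design plus a 20-sample cancer arm.
    """

    # cohort
    n_probes: int = 4000
    n_genes: int = 150
    frac_sex: float = 0.02
    frac_snp: float = 0.02
    n_normal: int = 20
    n_lga: int = 18
    n_hga: int = 22
    n_cancer: int = 20
    marker_genes: tuple = ("GENE_0001",)
    n_hyper_sites: int = 150
    n_hypo_sites: int = 300
    hyper_delta: dict = field(
        default_factory=lambda: {"LGA": 0.25, "HGA": 0.30, "cancer": 0.32}
    )
    hypo_delta: dict = field(
        default_factory=lambda: {"LGA": -0.25, "HGA": -0.28, "cancer": -0.30}
    )
    monotone: bool = True
    # intensity model
    total_intensity: float = 10000.0
    intensity_noise_sd: float = 50.0
    fail_frac: float = 2e-4
    # preprocessing
    detection_p: float = 0.01
    fail_rule: str = "any_sample"
    impute: bool = False
    keep_sex: bool = False
    # differential thresholds
    q_threshold: float = 0.05
    dms_delta: float = 0.20
    dmr_delta: float = 0.15
    region_scheme: str = "gene_category"
    # biomarker / ml
    n_bootstrap: int = 2000
    learner: str = "random_forest"
    ml_scheme: str = "cv_k_fold"
    ml_folds: int = 5
    learner_params: dict = field(default_factory=lambda: {"n_trees": 1000})
    # seeds
    seed: int = 0

    def validate(self) -> None:
        if self.n_normal < 2 or self.n_lga < 2 or self.n_hga < 2:
            raise ConfigError("normal, LGA and HGA arms each need >= 2 samples")
        if self.fail_rule not in ("any_sample", "fraction"):
            raise ConfigError(f"unknown fail_rule {self.fail_rule!r}")
        if not 0 < self.q_threshold < 1:
            raise ConfigError("q_threshold must be in (0, 1)")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["marker_genes"] = list(self.marker_genes)
        return d

    def overrides(self) -> dict:
        default = PipelineConfig().to_dict()
        current = self.to_dict()
        return {k: v for k, v in current.items() if default[k] != v}

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "marker_genes" in data:
            data = {**data, "marker_genes": tuple(data["marker_genes"])}
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"config {path} must be a YAML mapping")
        return cls.from_dict(data)

    def seed_registry(self) -> dict:
        return {
            name: (self.seed + i) % (2**31) for i, name in enumerate(_SEED_STAGES)
        }


def _monotone_fraction(
    betas: pd.DataFrame, groups: pd.Series, truth: pd.DataFrame, tolerance: float = 0.02
) -> float | None:
    """Fraction of injected hyper probes whose group means progress
    monotonically normal <= LGA <= HGA <= cancer within tolerance."""
    hyper_probes = truth.loc[truth["true_delta"] > 0, "probe_id"].unique()
    hyper_probes = [p for p in hyper_probes if p in betas.index]
    if not hyper_probes:
        return None
    stages = [s for s in synthetic.STAGES if (groups == s).any()]
    means = {
        s: betas.loc[hyper_probes, groups.index[groups == s]].mean(axis=1)
        for s in stages
    }
    ok = np.ones(len(hyper_probes), dtype=bool)
    for lo, hi in zip(stages, stages[1:]):
        ok &= (means[hi].to_numpy() - means[lo].to_numpy()) >= -tolerance
    return float(ok.mean())


def run_pipeline(config: PipelineConfig, outdir=None) -> dict:
    """Run the full simulated-cohort analysis and return the run report."""
    config.validate()
    seeds = config.seed_registry()
    t0 = time.monotonic()
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    # --- simulate ------------------------------------------------------
    logger.info("simulating cohort (%d probes, %d genes)", config.n_probes, config.n_genes)
    manifest = synthetic.generate_manifest(
        config.n_probes,
        config.n_genes,
        frac_sex=config.frac_sex,
        frac_snp=config.frac_snp,
        seed=seeds["manifest"],
    )
    n_samples = config.n_normal + config.n_lga + config.n_hga + config.n_cancer
    baseline = synthetic.generate_baseline_betas(
        manifest, n_samples, seed=seeds["baseline"]
    )
    labels = (
        ["normal"] * config.n_normal
        + ["LGA"] * config.n_lga
        + ["HGA"] * config.n_hga
        + ["cancer"] * config.n_cancer
    )
    prefix = {"normal": "N", "LGA": "LGA", "HGA": "HGA", "cancer": "CRC"}
    counters: dict[str, int] = {}
    names = []
    for lab in labels:
        counters[lab] = counters.get(lab, 0) + 1
        names.append(f"{prefix[lab]}{counters[lab]:02d}")
    baseline.columns = names
    groups = pd.Series(labels, index=names, name="group")

    effects = synthetic.EffectSpec(
        n_hyper_sites=config.n_hyper_sites,
        n_hypo_sites=config.n_hypo_sites,
        hyper_delta=config.hyper_delta,
        hypo_delta=config.hypo_delta,
        monotone=config.monotone,
        marker_genes=tuple(config.marker_genes),
        seed=seeds["effects"],
    )
    true_betas, truth = synthetic.inject_effects(baseline, manifest, groups, effects)
    intensities = synthetic.betas_to_intensities(
        true_betas,
        total_intensity=config.total_intensity,
        noise_sd=config.intensity_noise_sd,
        fail_frac=config.fail_frac,
        seed=seeds["intensities"],
    )

    # --- preprocess ----------------------------------------------------
    betas, detection = preprocess.intensities_to_matrices(intensities)
    betas = betas[groups.index]
    detection = detection[groups.index]
    if config.impute:
        failed = detection > config.detection_p
        betas = preprocess.impute_failed(betas, failed, manifest)
        detection = detection.where(~failed, 0.0)
    filtered, report = preprocess.filter_probes(
        betas,
        manifest,
        detection=detection,
        p_threshold=config.detection_p,
        fail_rule=config.fail_rule,
        keep_sex=config.keep_sex,
    )
    summary = preprocess.cohort_beta_summary(filtered, groups)
    logger.info("retained %d / %d probes", report.n_retained, report.n_input_probes)

    # --- differential --------------------------------------------------
    contrasts = [("LGA", "normal"), ("HGA", "normal"), ("HGA", "LGA")]
    dms_tables, dms_tallies, dmr_tables, dmr_tallies = {}, {}, {}, {}
    annot_retained = manifest.loc[filtered.index]
    region_values, regions = differential.aggregate_regions(
        filtered, annot_retained, scheme=config.region_scheme
    )
    for contrast, reference in contrasts:
        cols = groups.index[groups.isin([contrast, reference])]
        key = f"{contrast}_vs_{reference}"
        dms = differential.call_dms(
            filtered[cols],
            groups[cols],
            reference,
            delta_threshold=config.dms_delta,
            q_threshold=config.q_threshold,
        )
        dms_tables[key] = dms
        dms_tallies[key] = differential.direction_tally(dms)
        dmr = differential.call_dmr(
            region_values[cols],
            groups[cols],
            reference,
            delta_threshold=config.dmr_delta,
            q_threshold=config.q_threshold,
        )
        dmr_tables[key] = dmr
        dmr_tallies[key] = differential.direction_tally(dmr)

    # --- biomarker -----------------------------------------------------
    lga_dms = dms_tables["LGA_vs_normal"]
    hyper_ids = tuple(lga_dms.index[lga_dms["is_dms"] & (lga_dms["direction"] == "hyper")])
    hypo_ids = tuple(lga_dms.index[lga_dms["is_dms"] & (lga_dms["direction"] == "hypo")])
    bin_labels = biomarker.as_binary_labels(groups)

    marker_results = {}
    for gene in config.marker_genes:
        site_set = biomarker.promoter_island_set(annot_retained, gene)
        scores = biomarker.mbv(filtered, site_set)
        lab = bin_labels.reindex(scores.index)
        cut = biomarker.optimal_cutoff(scores, lab, polarity="hyper")
        curve = biomarker.roc(scores, lab, polarity="hyper")
        marker_results[gene] = {
            "n_sites": len(site_set.probe_ids),
            "cutoff": cut.to_dict(),
            "auc": round(curve.auc, 3),
            "group_mean_mbv": {
                s: round(float(scores[groups.reindex(scores.index) == s].mean()), 3)
                for s in synthetic.STAGES
                if (groups.reindex(scores.index) == s).any()
            },
        }

    set_comparison = None
    ml_comparison = None
    if hyper_ids and hypo_ids:
        hyper_set = biomarker.SiteSet("hyper_dms", hyper_ids, "hyper")
        hypo_set = biomarker.SiteSet("hypo_dms", hypo_ids, "hypo")
        scores_hyper = biomarker.mbv(filtered, hyper_set)
        scores_hypo = biomarker.mbv(filtered, hypo_set)
        common = scores_hyper.index.intersection(scores_hypo.index)
        boot = biomarker.bootstrap_auc_compare(
            scores_hyper[common],
            scores_hypo[common],
            bin_labels[common],
            polarity_a="hyper",
            polarity_b="hypo",
            n_replicates=config.n_bootstrap,
            seed=seeds["bootstrap"],
        )
        set_comparison = {
            "n_hyper_sites": len(hyper_ids),
            "n_hypo_sites": len(hypo_ids),
            "bootstrap": boot.to_dict(),
        }
        ml = ml_eval.compare_site_set_models(
            filtered,
            bin_labels,
            hyper_set,
            hypo_set,
            learner=config.learner,
            scheme=config.ml_scheme,
            params=config.learner_params,
            seed=seeds["ml"],
            folds=config.ml_folds,
        )
        ml_comparison = {
            "hyper": ml["hyper"].to_dict(),
            "hypo": ml["hypo"].to_dict(),
            "sensitivity_difference": ml["sensitivity_difference"],
            "specificity_difference": ml["specificity_difference"],
        }

    monotone_frac = _monotone_fraction(filtered, groups, truth)
    elapsed = time.monotonic() - t0
    logger.info("pipeline finished in %.1f s", elapsed)

    report_payload = {
        "versions": {"crcmeth": __version__},
        "config": config.to_dict(),
        "config_overrides": config.overrides(),
        "seed_registry": seeds,
        "filter_report": {
            k: v
            for k, v in report.to_dict().items()
            if k.startswith("n_")
        },
        "cohort_summary": summary.to_dict(),
        "dms": {k: dms_tallies[k] for k in dms_tallies},
        "dmr": {k: dmr_tallies[k] for k in dmr_tallies},
        "markers": marker_results,
        "site_set_comparison": set_comparison,
        "ml_comparison": ml_comparison,
        "monotone_hyper_fraction": monotone_frac,
    }

    if out is not None:
        io.write_manifest_csv(manifest, out / "manifest.csv")
        io.write_sample_sheet(groups, out / "samples.csv")
        io.write_truth_tsv(truth, out / "truth.tsv")
        io.write_beta_tsv(filtered, out / "betas_filtered.tsv")
        io.write_json(report.to_dict(), out / "filter_report.json")
        for key, table in dms_tables.items():
            io.write_diff_table(table, out / f"dms_{key}.tsv")
        for key, table in dmr_tables.items():
            io.write_diff_table(table, out / f"dmr_{key}.tsv")
            bed = differential.regions_to_bed(regions, manifest, table)
            io.write_bed(bed, out / f"dmr_{key}.bed")
        io.write_json(report_payload, out / "report.json")

    return report_payload
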