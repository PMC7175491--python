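"""Synthetic 450K-like cohort generation with known ground truth.

Emulates the structure of an Illumina 450K methylation experiment on
colorectal tissue: a probe manifest with gene-model and CpG-island context,
bimodal beta-value baselines, stage-dependent hyper-/hypo-methylation
effects with monotone progression across normal -> LGA -> HGA -> cancer,
and a two-channel intensity model (methylated / unmethylated signal with
detection p-values) that the preprocessing stage inverts.

Every generator is a pure function of its arguments and a seed, and every
injected effect is recorded in a truth table so downstream calls (DMS/DMR
detection, biomarker scoring) can be validated against known answers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError

PROMOTER_CATEGORIES = ("TSS200", "TSS1500", "5'UTR", "1stExon")
REGION_CATEGORIES = PROMOTER_CATEGORIES + ("Body", "3'UTR", "intergenic")
ISLAND_RELATIONS = ("island", "shore", "shelf", "open_sea")
STAGES = ("normal", "LGA", "HGA", "cancer")
AUTOSOMES = tuple(f"chr{i}" for i in range(1, 23))
SEX_CHROMS = ("chrX", "chrY")

# Probability that a probe's baseline is drawn from the unmethylated (low)
# mixture component, by island relation, before global weight adjustment.
# CpG islands are predominantly unmethylated in normal tissue; open-sea CpGs
# are predominantly methylated.
_LOW_MODE_PROPENSITY = {
    "island": 0.85,
    "shore": 0.55,
    "shelf": 0.35,
    "open_sea": 0.20,
}

# Genomic ordering of probe categories within a simulated gene body,
# upstream to downstream.
_GENE_CATEGORY_LAYOUT = (
    "TSS1500",
    "TSS200",
    "5'UTR",
    "1stExon",
    "Body",
    "Body",
    "3'UTR",
)


@dataclass(frozen=True)
class BimodalMixture:
    """Two-component beta mixture for per-probe baseline methylation.

    Parameters
    ----------
    low_mode, high_mode
        Means of the unmethylated and methylated components, in (0, 1).
    weight_low
        Global mixing weight of the low component; per-probe assignment
        combines this weight with the island-relation propensity via odds
        weighting, so ``weight_low=1`` forces every probe to the low mode.
    mode_concentration
        Beta-distribution concentration of per-probe baselines around the
        component mean (larger = tighter).
    sample_concentration
        Concentration of the per-sample, mean-preserving beta noise around
        each probe's baseline.
    sample_intercept_sd
        Standard deviation of a per-sample global methylation offset added
        to every probe's baseline (clamped), modelling the individual-level
        global differences real cohorts show; set to 0 for technically
        identical samples.
    """

    low_mode: float = 0.10
    high_mode: float = 0.85
    weight_low: float = 0.5
    mode_concentration: float = 30.0
    sample_concentration: float = 60.0
    sample_intercept_sd: float = 0.04

    def validate(self) -> None:
        if not (0.0 < self.low_mode < 1.0 and 0.0 < self.high_mode < 1.0):
            raise ConfigError("mixture modes must lie strictly inside (0, 1)")
        if not self.low_mode < self.high_mode:
            raise ConfigError(
                f"degenerate mixture: low mode {self.low_mode} must be below "
                f"high mode {self.high_mode}"
            )
        if not 0.0 <= self.weight_low <= 1.0:
            raise ConfigError("weight_low must be in [0, 1]")
        if self.sample_intercept_sd < 0:
            raise ConfigError("sample_intercept_sd must be nonnegative")


@dataclass(frozen=True)
class EffectSpec:
    """Stage-wise methylation effects to inject into a baseline cohort.

    ``hyper_delta`` / ``hypo_delta`` map each diseased stage to the beta-scale
    shift applied at hyper- / hypo-methylated effect sites. With
    ``monotone=True`` the hyper shifts must be nondecreasing and the hypo
    shifts nonincreasing (increasingly negative) along LGA -> HGA -> cancer,
    so changes appearing in low-grade adenoma are maintained or amplified in
    later stages.
    """

    n_hyper_sites: int = 150
    n_hypo_sites: int = 300
    hyper_delta: dict = field(
        default_factory=lambda: {"LGA": 0.25, "HGA": 0.30, "cancer": 0.32}
    )
    hypo_delta: dict = field(
        default_factory=lambda: {"LGA": -0.25, "HGA": -0.28, "cancer": -0.30}
    )
    monotone: bool = True
    marker_genes: tuple = ()
    seed: int = 0

    def validate(self) -> None:
        for name, mapping, sign in (
            ("hyper_delta", self.hyper_delta, +1),
            ("hypo_delta", self.hypo_delta, -1),
        ):
            bad = [s for s in mapping if s not in ("LGA", "HGA", "cancer")]
            if bad:
                raise ConfigError(f"{name} has unknown stages: {bad}")
            if any(sign * d < 0 for d in mapping.values()):
                raise ConfigError(
                    f"{name} shifts must all be "
                    f"{'nonnegative' if sign > 0 else 'nonpositive'}"
                )
        if self.monotone:
            order = [s for s in ("LGA", "HGA", "cancer") if s in self.hyper_delta]
            deltas = [self.hyper_delta[s] for s in order]
            if any(a > b for a, b in zip(deltas, deltas[1:])):
                raise ConfigError("monotone hyper_delta must be nondecreasing")
            order = [s for s in ("LGA", "HGA", "cancer") if s in self.hypo_delta]
            deltas = [self.hypo_delta[s] for s in order]
            if any(a < b for a, b in zip(deltas, deltas[1:])):
                raise ConfigError("monotone hypo_delta must be nonincreasing")
        if self.n_hyper_sites < 0 or self.n_hypo_sites < 0:
            raise ConfigError("site counts must be nonnegative")


def generate_manifest(
    n_probes: int = 5000,
    n_genes: int = 200,
    frac_sex: float = 0.02,
    frac_snp: float = 0.02,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate a 450K-style probe annotation manifest.

    Each simulated gene receives one probe in every promoter category
    (TSS1500, TSS200, 5'UTR, 1stExon) plus gene-body and 3'UTR probes, so
    promoter site-set extraction is nontrivially exercised downstream.
    Sex-chromosome probes are intergenic (gene structure lives on autosomes,
    so sex-probe filtering never destroys a promoter). TSS200 probes always
    sit in a CpG island, mirroring real promoter architecture.

    Returns a DataFrame indexed by ``probe_id`` with columns
    ``chrom, pos, gene, region_category, island_relation, snp_flagged``;
    positions are 1-based and strictly increasing within each chromosome.
    """
    if not (0.0 <= frac_sex < 1.0 and 0.0 <= frac_snp < 1.0):
        raise ConfigError("frac_sex and frac_snp must lie in [0, 1)")
    per_gene = len(_GENE_CATEGORY_LAYOUT)
    n_sex = int(round(frac_sex * n_probes))
    if n_probes < 8 * n_genes:
        raise ConfigError(
            f"n_probes={n_probes} too small for n_genes={n_genes}: need at "
            f"least {8 * n_genes} probes (8 per gene)"
        )
    if n_genes * per_gene + n_sex > n_probes:
        raise ConfigError("requested sex fraction leaves no room for genes")

    rng = np.random.default_rng(seed)
    genes = [f"GENE_{i + 1:04d}" for i in range(n_genes)]

    chrom_rows: dict[str, list] = {c: [] for c in AUTOSOMES + SEX_CHROMS}

    def _island_relation(category: str) -> str:
        if category == "TSS200":
            return "island"
        if category in ("TSS1500", "5'UTR", "1stExon"):
            return rng.choice(
                ["island", "shore", "shelf"], p=[0.6, 0.3, 0.1]
            )
        if category in ("Body", "3'UTR"):
            return rng.choice(ISLAND_RELATIONS, p=[0.1, 0.2, 0.2, 0.5])
        return rng.choice(ISLAND_RELATIONS, p=[0.05, 0.1, 0.15, 0.7])

    for gi, gene in enumerate(genes):
        chrom = AUTOSOMES[gi % len(AUTOSOMES)]
        for category in _GENE_CATEGORY_LAYOUT:
            chrom_rows[chrom].append((gene, category, _island_relation(category)))

    n_intergenic = n_probes - n_genes * per_gene - n_sex
    for chrom in rng.choice(AUTOSOMES, size=n_intergenic):
        chrom_rows[chrom].append(("", "intergenic", _island_relation("intergenic")))
    for chrom in rng.choice(SEX_CHROMS, size=n_sex):
        chrom_rows[chrom].append(("", "intergenic", _island_relation("intergenic")))

    records = []
    for chrom in AUTOSOMES + SEX_CHROMS:
        rows = chrom_rows[chrom]
        if not rows:
            continue
        gaps = rng.integers(50, 5000, size=len(rows))
        positions = np.cumsum(gaps) + 1
        for (gene, category, island), pos in zip(rows, positions):
            records.append((chrom, int(pos), gene, category, island))

    manifest = pd.DataFrame(
        records, columns=["chrom", "pos", "gene", "region_category", "island_relation"]
    )
    manifest.index = pd.Index(
        [f"cg{i:08d}" for i in range(len(manifest))], name="probe_id"
    )
    n_snp = int(round(frac_snp * n_probes))
    snp = np.zeros(len(manifest), dtype=bool)
    snp[rng.choice(len(manifest), size=n_snp, replace=False)] = True
    manifest["snp_flagged"] = snp
    return manifest


def generate_baseline_betas(
    manifest: pd.DataFrame,
    n_samples: int = 20,
    mixture: BimodalMixture | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw a probes x samples beta matrix with a bimodal marginal density.

    Each probe gets a stable baseline level from a two-component beta
    mixture (unmethylated / methylated modes), with island probes biased
    toward the unmethylated mode; per-sample values are mean-preserving beta
    perturbations around the probe baseline. The resulting pooled density is
    bimodal with one mode below 0.3 and one above 0.7 under the defaults.
    """
    mixture = mixture or BimodalMixture()
    mixture.validate()
    if n_samples < 1:
        raise ConfigError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)

    propensity = manifest["island_relation"].map(_LOW_MODE_PROPENSITY).to_numpy()
    w = mixture.weight_low
    # Odds-weighted combination of global weight and island propensity:
    # w=0.5 recovers the propensity; w in {0,1} forces one component.
    p_low = np.where(
        (w * propensity + (1 - w) * (1 - propensity)) > 0,
        w * propensity / (w * propensity + (1 - w) * (1 - propensity) + 1e-300),
        0.0,
    )
    is_low = rng.random(len(manifest)) < p_low
    modes = np.where(is_low, mixture.low_mode, mixture.high_mode)
    c = mixture.mode_concentration
    baseline = rng.beta(modes * c, (1 - modes) * c)
    baseline = np.clip(baseline, 1e-4, 1 - 1e-4)

    intercepts = (
        rng.normal(0.0, mixture.sample_intercept_sd, size=n_samples)
        if mixture.sample_intercept_sd > 0
        else np.zeros(n_samples)
    )
    per_sample = np.clip(baseline[:, None] + intercepts[None, :], 1e-4, 1 - 1e-4)
    k = mixture.sample_concentration
    values = rng.beta(per_sample * k, (1 - per_sample) * k)
    columns = [f"S{j + 1:03d}" for j in range(n_samples)]
    return pd.DataFrame(values, index=manifest.index.copy(), columns=columns)


def _promoter_island_probes(manifest: pd.DataFrame, gene: str) -> pd.Index:
    mask = (
        (manifest["gene"] == gene)
        & manifest["region_category"].isin(PROMOTER_CATEGORIES)
        & (manifest["island_relation"] == "island")
    )
    return manifest.index[mask]


def inject_effects(
    betas: pd.DataFrame,
    manifest: pd.DataFrame,
    groups: pd.Series,
    spec: EffectSpec,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply stage-dependent effects to a baseline cohort.

    Hyper effect sites are sampled from probes whose baseline mean is below
    0.5 and hypo sites from probes above 0.5 (disease hyper-methylation
    targets normally-unmethylated CpGs and vice versa), which keeps the
    injected shift visible after clamping to [0, 1]. All promoter
    CpG-island probes of each marker gene jointly receive the hyper effect.

    Normal samples are never modified. Returns the shifted matrix and a
    truth table with one row per (affected probe, diseased stage) recording
    the nominal shift and marker membership.
    """
    spec.validate()
    groups = pd.Series(groups)
    unknown = set(groups.unique()) - set(STAGES)
    if unknown:
        raise DataError(f"unknown stage labels: {sorted(unknown)}")
    if not groups.index.equals(betas.columns):
        groups = groups.reindex(betas.columns)
        if groups.isna().any():
            raise DataError("every sample column needs a stage label")

    rng = np.random.default_rng(spec.seed)
    row_means = betas.mean(axis=1)

    marker_probes: list[str] = []
    for gene in spec.marker_genes:
        if not (manifest["gene"] == gene).any():
            raise DataError(f"marker gene {gene!r} absent from manifest")
        probes = _promoter_island_probes(manifest, gene)
        if len(probes) == 0:
            raise DataError(
                f"marker gene {gene!r} has no promoter CpG-island probes"
            )
        marker_probes.extend(probes)
    marker_probes = list(dict.fromkeys(marker_probes))

    eligible_hyper = betas.index[(row_means < 0.5)].difference(marker_probes)
    eligible_hypo = betas.index[(row_means > 0.5)].difference(marker_probes)
    if spec.n_hyper_sites > len(eligible_hyper):
        raise DataError(
            f"n_hyper_sites={spec.n_hyper_sites} exceeds {len(eligible_hyper)} "
            "eligible low-baseline probes"
        )
    if spec.n_hypo_sites > len(eligible_hypo):
        raise DataError(
            f"n_hypo_sites={spec.n_hypo_sites} exceeds {len(eligible_hypo)} "
            "eligible high-baseline probes"
        )
    hyper_sites = list(
        rng.choice(eligible_hyper, size=spec.n_hyper_sites, replace=False)
    )
    hypo_sites = list(rng.choice(eligible_hypo, size=spec.n_hypo_sites, replace=False))

    shifted = betas.copy()
    truth_rows = []
    stage_columns = {
        stage: betas.columns[groups.to_numpy() == stage]
        for stage in ("LGA", "HGA", "cancer")
    }

    def _apply(probes: list, deltas: dict, is_marker: bool) -> None:
        for stage, cols in stage_columns.items():
            if stage not in deltas or len(cols) == 0:
                continue
            delta = deltas[stage]
            block = shifted.loc[probes, cols].to_numpy() + delta
            shifted.loc[probes, cols] = np.clip(block, 0.0, 1.0)
            for probe in probes:
                truth_rows.append((probe, stage, float(delta), is_marker))

    _apply(hyper_sites, spec.hyper_delta, False)
    _apply(hypo_sites, spec.hypo_delta, False)
    if marker_probes:
        _apply(marker_probes, spec.hyper_delta, True)

    truth = pd.DataFrame(
        truth_rows, columns=["probe_id", "stage", "true_delta", "is_marker_promoter"]
    )
    return shifted, truth


def betas_to_intensities(
    betas: pd.DataFrame,
    total_intensity: float = 10_000.0,
    noise_sd: float = 0.0,
    fail_frac: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Invert beta values into a two-channel intensity cohort.

    Splits a total signal T into methylated M = beta * T and unmethylated
    U = (1 - beta) * T, adds optional Gaussian channel noise, and attaches
    detection p-values: passing entries get p ~ U(0, 1e-4) and a
    ``fail_frac`` fraction of entries get p ~ U(0.01, 1], mimicking failed
    detection. Because beta is recomputed downstream with a +100 offset in
    the denominator, the noiseless round trip is accurate to about 100 / T.

    Returns a long-format DataFrame with columns
    ``probe_id, sample_id, M, U, detection_p``.
    """
    if total_intensity <= 0:
        raise ConfigError("total_intensity must be positive")
    if noise_sd < 0:
        raise ConfigError("noise_sd must be nonnegative")
    if not 0.0 <= fail_frac < 1.0:
        raise ConfigError("fail_frac must lie in [0, 1)")
    if total_intensity <= 100:
        warnings.warn(
            "total_intensity is not large relative to the +100 beta offset; "
            "recomputed betas will be strongly biased",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    b = betas.to_numpy()
    M = b * total_intensity
    U = (1.0 - b) * total_intensity
    if noise_sd > 0:
        M = M + rng.normal(0.0, noise_sd, size=M.shape)
        U = U + rng.normal(0.0, noise_sd, size=U.shape)

    fail = rng.random(b.shape) < fail_frac
    detection_p = rng.random(b.shape) * 1e-4
    detection_p[fail] = 0.01 + rng.random(fail.sum()) * 0.99

    long = pd.DataFrame(
        {
            "probe_id": np.repeat(betas.index.to_numpy(), betas.shape[1]),
            "sample_id": np.tile(betas.columns.to_numpy(), betas.shape[0]),
            "M": M.ravel(),
            "U": U.ravel(),
            "detection_p": detection_p.ravel(),
        }
    )
    return long


def simulate_cohort(
    n_probes: int = 5000,
    n_genes: int = 200,
    n_normal: int = 20,
    n_lga: int = 18,
    n_hga: int = 22,
    n_cancer: int = 0,
    frac_sex: float = 0.02,
    frac_snp: float = 0.02,
    mixture: BimodalMixture | None = None,
    effects: EffectSpec | None = None,
    seed: int = 0,
) -> dict:
    """Convenience wrapper: manifest + baseline + effects for a full cohort.

    Default arm sizes mirror a typical adenoma progression study design
    (20 normal, 18 low-grade adenoma, 22 high-grade adenoma) with an
    optional cancer arm. Returns a dict with keys ``manifest``, ``betas``,
    ``groups``, ``truth``.
    """
    manifest = generate_manifest(
        n_probes, n_genes, frac_sex=frac_sex, frac_snp=frac_snp, seed=seed
    )
    n_samples = n_normal + n_lga + n_hga + n_cancer
    betas = generate_baseline_betas(manifest, n_samples, mixture=mixture, seed=seed + 1)
    labels = (
        ["normal"] * n_normal + ["LGA"] * n_lga + ["HGA"] * n_hga + ["cancer"] * n_cancer
    )
    names = []
    counters: dict[str, int] = {}
    prefix = {"normal": "N", "LGA": "LGA", "HGA": "HGA", "cancer": "CRC"}
    for lab in labels:
        counters[lab] = counters.get(lab, 0) + 1
        names.append(f"{prefix[lab]}{counters[lab]:02d}")
    betas.columns = names
    groups = pd.Series(labels, index=names, name="group")

    effects = effects or EffectSpec(seed=seed + 2)
    shifted, truth = inject_effects(betas, manifest, groups, effects)
    return {"manifest": manifest, "betas": shifted, "groups": groups, "truth": truth}
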