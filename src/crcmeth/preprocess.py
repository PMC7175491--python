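"""Beta-value computation, probe QC filtering and imputation for 450K data.

The beta value at a CpG is the fraction of methylated signal,

    beta = max(M, 0) / (max(M, 0) + max(U, 0) + 100)

where M and U are the methylated and unmethylated channel intensities and
the +100 offset regularises low-intensity probes. QC removes probes on sex
chromosomes, probes failing detection, and SNP-flagged probes — in that
order, each probe attributed to the first rule that removes it. Failed
entries can alternatively be imputed from the nearest genomic neighbours.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError, DegenerateInputError

_SEX_LABELS = {"chrX", "chrY", "X", "Y", "chrx", "chry", "x", "y"}


def compute_beta(M, U):
    """Methylation beta value from channel intensities.

    Negative intensities are clamped to zero before the ratio; the +100
    offset keeps the result strictly below 1 and shrinks noisy
    low-intensity probes toward 0. Accepts scalars or arrays.
    """
    M = np.asarray(M, dtype=float)
    U = np.asarray(U, dtype=float)
    if not (np.isfinite(M).all() and np.isfinite(U).all()):
        raise DataError("non-finite intensity passed to compute_beta")
    m = np.maximum(M, 0.0)
    u = np.maximum(U, 0.0)
    beta = m / (m + u + 100.0)
    return beta.item() if beta.ndim == 0 else beta


def intensities_to_matrices(cohort: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pivot a long-format intensity cohort into beta and detection matrices.

    Expects columns ``probe_id, sample_id, M, U, detection_p``; returns
    ``(betas, detection_p)`` both indexed probes x samples.
    """
    required = {"probe_id", "sample_id", "M", "U", "detection_p"}
    missing = required - set(cohort.columns)
    if missing:
        raise DataError(f"intensity table missing columns: {sorted(missing)}")
    dup = cohort.duplicated(["probe_id", "sample_id"])
    if dup.any():
        raise DataError("duplicate (probe_id, sample_id) pairs in intensity table")
    beta_long = cohort.assign(beta=compute_beta(cohort["M"], cohort["U"]))
    betas = beta_long.pivot(index="probe_id", columns="sample_id", values="beta")
    detection = cohort.pivot(index="probe_id", columns="sample_id", values="detection_p")
    betas.columns.name = None
    detection.columns.name = None
    return betas, detection


@dataclass
class FilterReport:
    """Accounting of probe-level QC: every input probe lands in exactly one
    bucket (retained, or removed by the first rule that hit it)."""

    n_input_probes: int
    n_removed_sex: int
    n_removed_detection: int
    n_removed_snp: int
    n_retained: int
    removed_sex: list = field(default_factory=list)
    removed_detection: list = field(default_factory=list)
    removed_snp: list = field(default_factory=list)
    unannotated: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n_input_probes": self.n_input_probes,
            "n_removed_sex": self.n_removed_sex,
            "n_removed_detection": self.n_removed_detection,
            "n_removed_snp": self.n_removed_snp,
            "n_retained": self.n_retained,
            "n_unannotated": len(self.unannotated),
            "removed_sex": list(self.removed_sex),
            "removed_detection": list(self.removed_detection),
            "removed_snp": list(self.removed_snp),
            "unannotated": list(self.unannotated),
        }


def filter_probes(
    betas: pd.DataFrame,
    annot: pd.DataFrame,
    detection: pd.DataFrame | None = None,
    p_threshold: float = 0.01,
    fail_rule: str = "any_sample",
    fail_fraction: float = 0.1,
    keep_sex: bool = False,
) -> tuple[pd.DataFrame, FilterReport]:
    """Remove sex-chromosome, detection-failed and SNP-flagged probes.

    ``fail_rule='any_sample'`` drops a probe if any sample has
    detection p above ``p_threshold`` (the strict in-house rule);
    ``fail_rule='fraction'`` drops it only when the failing fraction of
    samples exceeds ``fail_fraction`` (use together with :func:`impute_failed`
    for the imputation-based processing path). Probes absent from the
    annotation are retained and listed in the report — removal rules
    require positive evidence.
    """
    if fail_rule not in ("any_sample", "fraction"):
        raise ConfigError(f"unknown fail_rule {fail_rule!r}")
    if not 0.0 < p_threshold <= 1.0:
        raise ConfigError("p_threshold must be in (0, 1]")

    probes = betas.index
    annotated = probes.intersection(annot.index)
    unannotated = probes.difference(annot.index)
    if len(unannotated) > 0:
        warnings.warn(
            f"{len(unannotated)} probes missing from annotation; retained",
            stacklevel=2,
        )

    sex_mask = pd.Series(False, index=probes)
    snp_mask = pd.Series(False, index=probes)
    if len(annotated) > 0:
        sex_mask.loc[annotated] = (
            annot.loc[annotated, "chrom"].astype(str).isin(_SEX_LABELS).to_numpy()
        )
        snp_mask.loc[annotated] = annot.loc[annotated, "snp_flagged"].astype(bool).to_numpy()
    if keep_sex:
        sex_mask[:] = False

    det_mask = pd.Series(False, index=probes)
    if detection is not None:
        detection = detection.reindex(index=probes, columns=betas.columns)
        failing = detection > p_threshold
        if fail_rule == "any_sample":
            det_mask = failing.any(axis=1)
        else:
            det_mask = failing.mean(axis=1) > fail_fraction

    removed_sex = probes[sex_mask]
    removed_detection = probes[det_mask & ~sex_mask]
    removed_snp = probes[snp_mask & ~sex_mask & ~det_mask]
    retained = probes[~(sex_mask | det_mask | snp_mask)]

    report = FilterReport(
        n_input_probes=len(probes),
        n_removed_sex=len(removed_sex),
        n_removed_detection=len(removed_detection),
        n_removed_snp=len(removed_snp),
        n_retained=len(retained),
        removed_sex=removed_sex.tolist(),
        removed_detection=removed_detection.tolist(),
        removed_snp=removed_snp.tolist(),
        unannotated=unannotated.tolist(),
    )
    return betas.loc[retained], report


def impute_failed(
    betas: pd.DataFrame,
    failed_mask: pd.DataFrame,
    annot: pd.DataFrame,
) -> pd.DataFrame:
    """Replace failed entries with the nearest-neighbour average.

    For each failed (probe, sample) entry, take the mean of the nearest
    non-failed probes flanking it on the same chromosome in the same
    sample — both flanks where available, the single flank at chromosome
    ends. A chromosome whose entries all failed for a sample is left
    missing with a warning. Non-failed entries are never modified.
    """
    failed_mask = failed_mask.reindex(index=betas.index, columns=betas.columns).fillna(False)
    if not failed_mask.to_numpy().any():
        return betas.copy()

    missing_annot = betas.index.difference(annot.index)
    if len(missing_annot) > 0:
        raise DataError(
            f"{len(missing_annot)} probes lack coordinates needed for imputation"
        )

    out = betas.copy()
    ann = annot.loc[betas.index, ["chrom", "pos"]]
    unfixable = 0
    for chrom, chrom_probes in ann.groupby("chrom", sort=False).groups.items():
        order = ann.loc[chrom_probes].sort_values("pos").index
        vals = out.loc[order].to_numpy(copy=True)
        fail = failed_mask.loc[order].to_numpy()
        for j in range(vals.shape[1]):
            col_fail = fail[:, j]
            if not col_fail.any():
                continue
            good_idx = np.flatnonzero(~col_fail)
            if good_idx.size == 0:
                vals[:, j] = np.nan
                unfixable += int(col_fail.sum())
                continue
            for i in np.flatnonzero(col_fail):
                left = good_idx[good_idx < i]
                right = good_idx[good_idx > i]
                flanks = []
                if left.size:
                    flanks.append(vals[left[-1], j])
                if right.size:
                    flanks.append(vals[right[0], j])
                vals[i, j] = float(np.mean(flanks))
        out.loc[order] = vals
    if unfixable:
        warnings.warn(
            f"{unfixable} failed entries on fully-failed chromosomes left missing",
            stacklevel=2,
        )
    return out


@dataclass
class CohortSummary:
    """Per-group global methylation summaries (group means, pooled density,
    and the count of probes whose group-mean beta lies in [0.7, 0.9] —
    the 'fully methylated peak' of the bimodal density)."""

    group_means: dict
    high_peak_counts: dict
    histograms: dict

    def to_dict(self) -> dict:
        return {
            "group_means": {g: float(v) for g, v in self.group_means.items()},
            "high_peak_counts": {g: int(v) for g, v in self.high_peak_counts.items()},
        }


def cohort_beta_summary(
    betas: pd.DataFrame,
    groups: pd.Series,
    peak_range: tuple[float, float] = (0.7, 0.9),
    n_bins: int = 50,
) -> CohortSummary:
    """Per-group mean beta, value density, and high-methylation peak size."""
    groups = pd.Series(groups).reindex(betas.columns)
    if groups.isna().any():
        raise DataError("every sample needs a group label")
    lo, hi = peak_range
    means, counts, hists = {}, {}, {}
    for group, cols in groups.groupby(groups).groups.items():
        block = betas[list(cols)]
        if block.shape[1] == 0:
            raise DegenerateInputError(f"group {group!r} has no samples")
        means[group] = float(np.nanmean(block.to_numpy()))
        probe_means = block.mean(axis=1)
        counts[group] = int(((probe_means >= lo) & (probe_means <= hi)).sum())
        density, edges = np.histogram(
            block.to_numpy().ravel(), bins=n_bins, range=(0.0, 1.0), density=True
        )
        hists[group] = (edges, density)
    return CohortSummary(group_means=means, high_peak_counts=counts, histograms=hists)
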