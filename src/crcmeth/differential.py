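"""Differential methylation site (DMS) and region (DMR) calling.

Two-group comparisons use the two-sided Wilcoxon rank-sum (Mann-Whitney)
test per unit with Benjamini-Hochberg FDR adjustment across units. A site
is a DMS when q < 0.05 and |delta beta| > 0.20; a region (the unweighted
mean of its member probes per sample, grouped by gene and gene-model
category, or by the pooled promoter definition TSS200 + TSS1500 + 5'UTR +
1stExon) is a DMR at the looser |delta beta| > 0.15 gate. Delta beta is
mean(contrast group) - mean(reference group) on the beta scale, so
direction 'hyper' means methylation gained relative to the reference.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ConfigError, DataError, DegenerateInputError
from .synthetic import PROMOTER_CATEGORIES

DMS_DELTA_THRESHOLD = 0.20
DMR_DELTA_THRESHOLD = 0.15
Q_THRESHOLD = 0.05

_EXACT_MAX_N = 12  # exact Mann-Whitney enumeration limit (no ties)


def rank_sum_test(a, b) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Uses the exact null distribution when the pooled sample size is at most
    12 and no ties are present; otherwise the normal approximation with
    continuity and tie correction. Identical constant samples give p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if a.size == 0 or b.size == 0:
        raise DegenerateInputError("rank_sum_test needs nonempty groups")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        return 1.0
    has_ties = np.unique(pooled).size < pooled.size
    if pooled.size <= _EXACT_MAX_N and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(min(max(res.pvalue, np.nextafter(0, 1)), 1.0))


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-aligned with the input."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise DataError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _split_groups(
    betas: pd.DataFrame, groups: pd.Series, reference: str
) -> tuple[pd.Index, pd.Index, str]:
    groups = pd.Series(groups).reindex(betas.columns)
    if groups.isna().any():
        raise DataError("every sample needs a group label")
    labels = groups.unique().tolist()
    if len(labels) != 2:
        raise DataError(f"need exactly two groups, got {labels}")
    if reference not in labels:
        raise DataError(f"reference {reference!r} not among groups {labels}")
    contrast = next(lab for lab in labels if lab != reference)
    ref_cols = betas.columns[groups.to_numpy() == reference]
    con_cols = betas.columns[groups.to_numpy() == contrast]
    if len(ref_cols) < 2 or len(con_cols) < 2:
        raise DegenerateInputError("each group needs at least 2 samples")
    return ref_cols, con_cols, contrast


def _rank_sum_matrix(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Row-wise two-sided rank-sum p-values for (units x samples) blocks."""
    n = A.shape[1] + B.shape[1]
    pooled = np.concatenate([A, B], axis=1)
    has_nan = np.isnan(pooled).any()
    constant = np.nanmax(pooled, axis=1) - np.nanmin(pooled, axis=1) == 0
    if n <= _EXACT_MAX_N or has_nan:
        p = np.array(
            [
                1.0 if constant[i] else rank_sum_test(A[i], B[i])
                for i in range(A.shape[0])
            ]
        )
        return p
    p = np.ones(A.shape[0])
    todo = ~constant
    if todo.any():
        res = stats.mannwhitneyu(
            A[todo], B[todo], alternative="two-sided", method="asymptotic", axis=1
        )
        p[todo] = np.minimum(np.maximum(res.pvalue, np.nextafter(0, 1)), 1.0)
    return p


def _call_differential(
    values: pd.DataFrame,
    groups: pd.Series,
    reference: str,
    delta_threshold: float,
    q_threshold: float,
    flag_name: str,
) -> pd.DataFrame:
    ref_cols, con_cols, contrast = _split_groups(values, groups, reference)
    A = values[con_cols].to_numpy()
    R = values[ref_cols].to_numpy()
    delta = np.nanmean(A, axis=1) - np.nanmean(R, axis=1)
    p = _rank_sum_matrix(A, R)
    q = bh_fdr(p)
    direction = np.where(delta > 0, "hyper", "hypo")
    flagged = (q < q_threshold) & (np.abs(delta) > delta_threshold)
    table = pd.DataFrame(
        {
            "delta_beta": delta,
            "p_value": p,
            "q_value": q,
            "direction": direction,
            flag_name: flagged,
        },
        index=values.index.copy(),
    )
    table.index.name = "unit_id"
    table.attrs["contrast"] = contrast
    table.attrs["reference"] = reference
    return table


def call_dms(
    betas: pd.DataFrame,
    groups: pd.Series,
    reference: str,
    delta_threshold: float = DMS_DELTA_THRESHOLD,
    q_threshold: float = Q_THRESHOLD,
) -> pd.DataFrame:
    """Site-level differential methylation table (one row per probe)."""
    return _call_differential(
        betas, groups, reference, delta_threshold, q_threshold, "is_dms"
    )


def aggregate_regions(
    betas: pd.DataFrame,
    annot: pd.DataFrame,
    scheme: str = "promoter",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Aggregate probe betas into gene-region mean values.

    ``scheme='gene_category'`` builds one region per (gene, gene-model
    category); ``scheme='promoter'`` pools each gene's TSS200, TSS1500,
    5'UTR and 1stExon probes into a single promoter region. Region values
    are unweighted means of member-probe betas per sample. Returns
    ``(region_values, regions)`` where ``regions`` lists the membership and
    flags single-probe regions.
    """
    if scheme not in ("gene_category", "promoter"):
        raise ConfigError(f"unknown aggregation scheme {scheme!r}")
    ann = annot.reindex(betas.index).dropna(subset=["gene"])
    ann = ann[ann["gene"] != ""]
    if scheme == "promoter":
        ann = ann[ann["region_category"].isin(PROMOTER_CATEGORIES)]
        keys = ann["gene"] + "|promoter"
    else:
        keys = ann["gene"] + "|" + ann["region_category"]

    rows, meta = [], []
    for region_id, probes in keys.groupby(keys).groups.items():
        member = betas.loc[probes]
        rows.append(member.mean(axis=0, skipna=True).rename(region_id))
        gene, category = region_id.rsplit("|", 1)
        meta.append(
            {
                "region_id": region_id,
                "gene": gene,
                "category": category,
                "member_probes": list(probes),
                "n_probes": len(probes),
                "singleton": len(probes) == 1,
            }
        )
    if not rows:
        return (
            pd.DataFrame(columns=betas.columns),
            pd.DataFrame(
                columns=["region_id", "gene", "category", "member_probes", "n_probes", "singleton"]
            ).set_index("region_id"),
        )
    region_values = pd.DataFrame(rows)
    region_values.index.name = "region_id"
    regions = pd.DataFrame(meta).set_index("region_id")
    return region_values.sort_index(), regions.sort_index()


def call_dmr(
    region_values: pd.DataFrame,
    groups: pd.Series,
    reference: str,
    delta_threshold: float = DMR_DELTA_THRESHOLD,
    q_threshold: float = Q_THRESHOLD,
) -> pd.DataFrame:
    """Region-level differential methylation table (one row per region)."""
    return _call_differential(
        region_values, groups, reference, delta_threshold, q_threshold, "is_dmr"
    )


def direction_tally(table: pd.DataFrame) -> dict:
    """Hyper/hypo counts and one-decimal percentages among flagged units."""
    if table.empty:
        raise DegenerateInputError("direction_tally needs a nonempty table")
    flag_col = "is_dms" if "is_dms" in table.columns else "is_dmr"
    flagged = table[table[flag_col]]
    n = len(flagged)
    n_hyper = int((flagged["direction"] == "hyper").sum())
    n_hypo = n - n_hyper
    return {
        "n_flagged": n,
        "n_hyper": n_hyper,
        "n_hypo": n_hypo,
        "pct_hyper": round(100.0 * n_hyper / n, 1) if n else None,
        "pct_hypo": round(100.0 * n_hypo / n, 1) if n else None,
    }


def regions_to_bed(
    regions: pd.DataFrame,
    annot: pd.DataFrame,
    table: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Genomic spans of regions as BED (0-based half-open) records.

    The span is the min/max coordinate of member probes; if a DMR table is
    given, only flagged regions are exported and delta beta is carried in
    the score column (x1000, rounded, clipped to BED's 0-1000 range).
    """
    ids = regions.index
    if table is not None:
        ids = table.index[table["is_dmr"]]
    records = []
    for region_id in ids:
        probes = regions.loc[region_id, "member_probes"]
        sub = annot.loc[probes]
        chroms = sub["chrom"].unique()
        if len(chroms) != 1:
            raise DataError(f"region {region_id!r} spans multiple chromosomes")
        score = 0
        if table is not None:
            score = int(np.clip(round(abs(table.loc[region_id, "delta_beta"]) * 1000), 0, 1000))
        records.append(
            {
                "chrom": chroms[0],
                "start": int(sub["pos"].min()) - 1,
                "end": int(sub["pos"].max()),
                "name": region_id,
                "score": score,
                "strand": ".",
            }
        )
    return pd.DataFrame(records, columns=["chrom", "start", "end", "name", "score", "strand"])
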