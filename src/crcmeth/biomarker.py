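"""Mean-beta-value (mBV) biomarker scoring and evaluation.

A site set (e.g. the CpG-island probes of a gene promoter, or the hyper-/
hypo-DMS sets from a differential analysis) is reduced to one score per
sample: the unweighted mean beta over its member probes. The module then
provides threshold optimisation (minimal misclassification count over all
real thresholds), ROC/AUC built from first principles (trapezoidal area,
equal to the pairwise concordance probability with ties counted one half),
confusion-matrix metrics, and a paired stratified-bootstrap comparison of
two competing score vectors' AUCs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError, DegenerateInputError
from .synthetic import PROMOTER_CATEGORIES

POSITIVE_LABEL = "disease"
NEGATIVE_LABEL = "normal"

# Stages pooled as the positive class: adenoma and cancer together count
# as disease for the two-class biomarker analyses.
DISEASE_STAGES = ("LGA", "HGA", "cancer")


@dataclass(frozen=True)
class SiteSet:
    """Named set of probes scored jointly, with the expected direction of
    the disease shift (hyper: disease scores higher; hypo: lower)."""

    name: str
    probe_ids: tuple
    polarity: str = "hyper"

    def __post_init__(self):
        if len(self.probe_ids) == 0:
            raise DataError(f"site set {self.name!r} is empty")
        if self.polarity not in ("hyper", "hypo"):
            raise ConfigError(f"polarity must be 'hyper' or 'hypo', got {self.polarity!r}")


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 confusion counts with disease as the positive class."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise DataError("confusion counts must be nonnegative")

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    @property
    def n_errors(self) -> int:
        return self.fn + self.fp

    @property
    def sensitivity(self) -> float:
        if self.tp + self.fn == 0:
            raise DegenerateInputError("no positive samples: sensitivity undefined")
        return self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        if self.tn + self.fp == 0:
            raise DegenerateInputError("no negative samples: specificity undefined")
        return self.tn / (self.tn + self.fp)

    def to_dict(self) -> dict:
        return {"TP": self.tp, "FN": self.fn, "FP": self.fp, "TN": self.tn}


def error_rate_percent(n_errors: int, n_samples: int) -> float:
    """Misclassification rate as a percentage, reported to 2 decimals."""
    if n_samples <= 0:
        raise DegenerateInputError("n_samples must be positive")
    return round(100.0 * n_errors / n_samples, 2)


def as_binary_labels(groups: pd.Series, disease_stages=DISEASE_STAGES) -> pd.Series:
    """Collapse stage labels to the two-class disease/normal scheme."""
    groups = pd.Series(groups)
    return groups.isin(disease_stages).map(
        {True: POSITIVE_LABEL, False: NEGATIVE_LABEL}
    ).rename("label")


def mbv(betas: pd.DataFrame, site_set: SiteSet) -> pd.Series:
    """Per-sample mean beta value over the site set, skipping missing entries.

    Samples whose member betas are all missing are dropped with a warning.
    """
    missing = [p for p in site_set.probe_ids if p not in betas.index]
    if missing:
        raise DataError(
            f"site set {site_set.name!r}: {len(missing)} member probes absent "
            f"from the beta matrix (e.g. {missing[:3]})"
        )
    block = betas.loc[list(site_set.probe_ids)]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns handled below
        scores = block.mean(axis=0, skipna=True)
    dead = scores.isna()
    if dead.any():
        warnings.warn(
            f"{int(dead.sum())} samples had no non-missing members of "
            f"{site_set.name!r} and were dropped",
            stacklevel=2,
        )
        scores = scores[~dead]
    return scores.rename(site_set.name)


def promoter_island_set(
    annot: pd.DataFrame,
    gene: str,
    require_island: bool = True,
    polarity: str = "hyper",
) -> SiteSet:
    """Probes of a gene's promoter (TSS200/TSS1500/5'UTR/1stExon),
    optionally restricted to CpG islands."""
    in_gene = annot["gene"] == gene
    if not in_gene.any():
        raise DataError(f"gene {gene!r} not present in annotation")
    mask = in_gene & annot["region_category"].isin(PROMOTER_CATEGORIES)
    if not mask.any():
        raise DataError(f"gene {gene!r} has no promoter-category probes")
    if require_island:
        mask &= annot["island_relation"] == "island"
        if not mask.any():
            raise DataError(
                f"gene {gene!r} has promoter probes but none in a CpG island"
            )
    return SiteSet(
        name=f"{gene}_promoter" + ("_island" if require_island else ""),
        probe_ids=tuple(annot.index[mask]),
        polarity=polarity,
    )


def _check_scores_labels(scores: pd.Series, labels: pd.Series):
    labels = pd.Series(labels).reindex(scores.index)
    if labels.isna().any():
        raise DataError("every scored sample needs a disease/normal label")
    pos = labels == POSITIVE_LABEL
    neg = labels == NEGATIVE_LABEL
    if not (pos | neg).all():
        bad = labels[~(pos | neg)].unique()
        raise DataError(f"labels must be disease/normal, got {bad}")
    if not pos.any() or not neg.any():
        raise DegenerateInputError("both disease and normal samples are required")
    return scores.to_numpy(dtype=float), pos.to_numpy()


def confusion_at(scores, labels, cutoff: float, polarity: str = "hyper") -> ConfusionCounts:
    """Confusion counts when calling disease at score >= cutoff (hyper
    polarity) or score <= cutoff (hypo polarity)."""
    s, pos = _check_scores_labels(pd.Series(scores), pd.Series(labels))
    pred = s >= cutoff if polarity == "hyper" else s <= cutoff
    return ConfusionCounts(
        tp=int((pred & pos).sum()),
        fn=int((~pred & pos).sum()),
        fp=int((pred & ~pos).sum()),
        tn=int((~pred & ~pos).sum()),
    )


@dataclass
class MarkerMetrics:
    """Sensitivity/specificity at a fixed cutoff, rounded to 3 decimals
    for reporting (matching conventional display precision)."""

    confusion: ConfusionCounts
    sensitivity: float
    specificity: float

    def to_dict(self) -> dict:
        return {
            "confusion": self.confusion.to_dict(),
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
        }


def sens_spec(confusion: ConfusionCounts) -> MarkerMetrics:
    """Metrics from confusion counts — the single source of truth used by
    both the biomarker and classifier-evaluation paths."""
    return MarkerMetrics(
        confusion=confusion,
        sensitivity=round(confusion.sensitivity, 3),
        specificity=round(confusion.specificity, 3),
    )


def sens_spec_at(scores, labels, cutoff: float, polarity: str = "hyper") -> MarkerMetrics:
    """Sensitivity and specificity of the cutoff classifier."""
    return sens_spec(confusion_at(scores, labels, cutoff, polarity))


@dataclass
class CutoffResult:
    """Minimal-misclassification threshold over the candidate grid
    (midpoints of adjacent unique scores plus sentinels outside the range;
    this grid attains the optimum over all real thresholds)."""

    cutoff: float
    n_errors: int
    error_rate: float  # percent, 2 decimals
    confusion: ConfusionCounts
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "cutoff": self.cutoff,
            "n_errors": self.n_errors,
            "error_rate": self.error_rate,
            "confusion": self.confusion.to_dict(),
            "degenerate": self.degenerate,
        }


def optimal_cutoff(scores, labels, polarity: str = "hyper") -> CutoffResult:
    """Scan candidate thresholds and return the minimal-error cutoff.

    Ties are broken toward the smallest threshold, which favours
    sensitivity for hyper-methylation markers.
    """
    scores = pd.Series(scores)
    labels = pd.Series(labels)
    _check_scores_labels(scores, labels)
    if polarity not in ("hyper", "hypo"):
        raise ConfigError(f"polarity must be 'hyper' or 'hypo', got {polarity!r}")
    u = np.unique(scores.to_numpy(dtype=float))
    degenerate = u.size == 1
    pad = 0.05 if u.size == 1 else 0.0
    candidates = np.concatenate(
        [[u[0] - max(pad, 0.05)], (u[:-1] + u[1:]) / 2.0, [u[-1] + max(pad, 0.05)]]
    )
    best = None
    for c in candidates:
        conf = confusion_at(scores, labels, float(c), polarity)
        if best is None or conf.n_errors < best[1].n_errors:
            best = (float(c), conf)
    cutoff, conf = best
    return CutoffResult(
        cutoff=cutoff,
        n_errors=conf.n_errors,
        error_rate=error_rate_percent(conf.n_errors, conf.n),
        confusion=conf,
        degenerate=degenerate,
    )


@dataclass
class RocCurve:
    """ROC curve points from (0,0) to (1,1) and the trapezoidal AUC."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float

    def to_dict(self) -> dict:
        return {"auc": self.auc, "n_points": int(len(self.fpr))}


def roc(scores, labels, polarity: str = "hyper") -> RocCurve:
    """ROC curve over all score thresholds.

    For hypo polarity the score ordering is reversed so that larger
    transformed scores always indicate disease. Tied scores enter the curve
    as a single diagonal step, so the trapezoidal area credits ties with
    one half — making the AUC equal to the pairwise concordance statistic.
    """
    s, pos = _check_scores_labels(pd.Series(scores), pd.Series(labels))
    if polarity == "hypo":
        s = -s
    elif polarity != "hyper":
        raise ConfigError(f"polarity must be 'hyper' or 'hypo', got {polarity!r}")
    order = np.argsort(-s, kind="mergesort")
    s_sorted = s[order]
    pos_sorted = pos[order]
    n_pos = int(pos.sum())
    n_neg = len(pos) - n_pos
    # group tied thresholds into single steps
    distinct = np.r_[np.flatnonzero(np.diff(s_sorted) != 0), len(s_sorted) - 1]
    tp = np.cumsum(pos_sorted)[distinct]
    fp = np.cumsum(~pos_sorted)[distinct]
    tpr = np.r_[0.0, tp / n_pos]
    fpr = np.r_[0.0, fp / n_neg]
    thresholds = np.r_[np.inf, s_sorted[distinct]]
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(fpr=fpr, tpr=tpr, thresholds=thresholds, auc=auc)


def _fast_auc(s: np.ndarray, pos: np.ndarray) -> float:
    """Rank-based AUC (ties get half credit); used inside the bootstrap."""
    from scipy.stats import rankdata

    r = rankdata(s)
    n_pos = int(pos.sum())
    n_neg = len(s) - n_pos
    return (r[pos].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


@dataclass
class BootstrapComparison:
    """Paired stratified-bootstrap comparison of two models' AUCs on the
    same samples. The two-sided p-value uses +1 smoothing so it is never
    exactly zero."""

    observed_auc_a: float
    observed_auc_b: float
    n_replicates: int
    differences: np.ndarray
    p_value: float
    seed: int

    def to_dict(self) -> dict:
        return {
            "observed_auc_a": self.observed_auc_a,
            "observed_auc_b": self.observed_auc_b,
            "n_replicates": self.n_replicates,
            "mean_difference": float(np.mean(self.differences)),
            "p_value": self.p_value,
            "seed": self.seed,
        }


def bootstrap_auc_compare(
    scores_a,
    scores_b,
    labels,
    polarity_a: str = "hyper",
    polarity_b: str = "hyper",
    n_replicates: int = 2000,
    seed: int = 0,
) -> BootstrapComparison:
    """Compare two score vectors' AUCs by paired stratified bootstrap.

    Each replicate resamples sample ids with replacement within each class
    and recomputes both AUCs on the same resample; the two-sided p-value is
    2 * min over tails of the smoothed fraction of replicate differences on
    each side of zero, capped at 1.
    """
    scores_a = pd.Series(scores_a)
    scores_b = pd.Series(scores_b)
    if not scores_a.index.sort_values().equals(scores_b.index.sort_values()):
        raise DataError("score vectors must be paired over the same samples")
    scores_b = scores_b.reindex(scores_a.index)
    sa, pos = _check_scores_labels(scores_a, pd.Series(labels))
    sb, _ = _check_scores_labels(scores_b, pd.Series(labels).reindex(scores_a.index))
    if polarity_a == "hypo":
        sa = -sa
    if polarity_b == "hypo":
        sb = -sb

    auc_a = _fast_auc(sa, pos)
    auc_b = _fast_auc(sb, pos)

    rng = np.random.default_rng(seed)
    pos_idx = np.flatnonzero(pos)
    neg_idx = np.flatnonzero(~pos)
    diffs = np.empty(n_replicates)
    for r in range(n_replicates):
        take = np.concatenate(
            [
                rng.choice(pos_idx, size=pos_idx.size, replace=True),
                rng.choice(neg_idx, size=neg_idx.size, replace=True),
            ]
        )
        p = pos[take]
        diffs[r] = _fast_auc(sa[take], p) - _fast_auc(sb[take], p)

    lo = (1 + int((diffs <= 0).sum())) / (n_replicates + 1)
    hi = (1 + int((diffs >= 0).sum())) / (n_replicates + 1)
    p_value = min(1.0, 2.0 * min(lo, hi))
    return BootstrapComparison(
        observed_auc_a=float(auc_a),
        observed_auc_b=float(auc_b),
        n_replicates=n_replicates,
        differences=diffs,
        p_value=float(p_value),
        seed=seed,
    )
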