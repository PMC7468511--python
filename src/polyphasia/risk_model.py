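"""Two-case-scenario association pipeline: allelic odds ratios, risk-class
labelling, a ridge-stabilised logistic risk score, leave-one-out
cross-validation with in-fold feature selection, confusion/ROC metrics, and
average-linkage clustering of the risk outputs.

Per variant, case and control alternate/reference allele counts form a 2×2
table; the allelic odds ratio (with the Haldane–Anscombe +0.5 correction
when any cell is zero) labels variants *high-risk* (OR > 1, more frequent
in polyphasic cases) or *low-risk* (OR < 1). The top-k variants by |log OR|
feed a logistic regression of phenotype on allele counts. A small fixed
ridge penalty (λ = 1e-3 on slopes, never the intercept) keeps the optimum
finite under the quasi-separation that is routine at n ≈ 30. LOOCV repeats
the whole selection + fit inside every fold, so the held-out sample never
influences its own predictors.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import leaves_list, linkage

from .formats_io import GenotypeMatrix, VariantRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class VariantOR:
    """Allelic odds ratio of one variant."""

    variant: VariantRecord
    case_alt: float
    case_ref: float
    control_alt: float
    control_ref: float
    odds_ratio: float
    log_or: float
    risk_class: str  # high | low | neutral

    def __post_init__(self) -> None:
        if not self.odds_ratio > 0:
            raise ValueError("odds ratio must be positive after correction")


@dataclass
class FitResult:
    intercept: float
    coefficients: np.ndarray      # one slope per selected variant
    variant_keys: list[str]
    dropped_constant: list[str] = field(default_factory=list)


@dataclass
class RiskModelResult:
    sample_ids: list[str]
    labels: np.ndarray                     # true phenotype
    predicted_risks: np.ndarray            # out-of-fold logistic probabilities
    weighted_scores: np.ndarray
    unweighted_scores: np.ndarray
    fold_selected: list[list[str]]         # per-fold variant keys
    fold_fits: list[FitResult]
    skipped_folds: list[int] = field(default_factory=list)

    @property
    def pooled_variants(self) -> list[str]:
        """Union of every fold's selected variants, first-seen order."""
        seen: dict[str, None] = {}
        for keys in self.fold_selected:
            for k in keys:
                seen.setdefault(k)
        return list(seen)


@dataclass(frozen=True)
class ConfusionMetrics:
    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float          # percent
    sensitivity: float | None
    specificity: float | None
    mcc: float
    auc: float | None


# ---------------------------------------------------------------------------
# Odds ratios and selection
# ---------------------------------------------------------------------------

def variant_odds_ratios(matrix: GenotypeMatrix) -> list[VariantOR]:
    """Allelic 2×2 odds ratio per variant.

    Missing genotypes drop that sample for that variant only. Any zero cell
    triggers the Haldane–Anscombe +0.5 correction on all four cells.
    Variants missing in every sample are excluded with a warning.
    """
    if matrix.phenotype is None:
        raise ValueError("matrix has no phenotype labels")
    case_mask = matrix.phenotype
    out: list[VariantOR] = []
    for j, variant in enumerate(matrix.variants):
        col = matrix.counts[:, j]
        present = ~np.isnan(col)
        if not present.any():
            logger.warning("variant %s missing in all samples; excluded",
                           variant.key)
            continue
        ca = float(np.nansum(col[case_mask & present]))
        cr = 2.0 * int((case_mask & present).sum()) - ca
        ta = float(np.nansum(col[~case_mask & present]))
        tr = 2.0 * int((~case_mask & present).sum()) - ta
        cells = np.array([ca, cr, ta, tr])
        if (cells == 0).any():
            cells = cells + 0.5
        a, b, c, d = cells
        or_ = (a * d) / (b * c)
        risk = "high" if or_ > 1 else ("low" if or_ < 1 else "neutral")
        out.append(VariantOR(
            variant=variant, case_alt=ca, case_ref=cr, control_alt=ta,
            control_ref=tr, odds_ratio=float(or_), log_or=float(math.log(or_)),
            risk_class=risk))
    return out


def _chrom_sort_key(chrom: str) -> tuple[int, str]:
    c = chrom.removeprefix("chr")
    return (0, f"{int(c):09d}") if c.isdigit() else (1, c)


def select_top_variants(or_list: list[VariantOR], k: int = 16) -> list[str]:
    """The k variants with the largest |log OR|; fully deterministic.

    Ties break by larger total alternate-allele count, then genomic order.
    """
    if len(or_list) < k:
        logger.warning("only %d variants available for top-%d selection",
                       len(or_list), k)

    def sort_key(v: VariantOR):
        return (-abs(v.log_or), -(v.case_alt + v.control_alt),
                _chrom_sort_key(v.variant.chrom), v.variant.pos,
                v.variant.ref, v.variant.alt)

    ranked = sorted(or_list, key=sort_key)
    return [v.variant.key for v in ranked[:k]]


# ---------------------------------------------------------------------------
# Ridge logistic regression (Newton / IRLS)
# ---------------------------------------------------------------------------

def fit_risk_model(counts: np.ndarray, phenotype: np.ndarray,
                   variant_keys: list[str] | None = None,
                   ridge_lambda: float = 1e-3, tol: float = 1e-8,
                   max_iter: int = 200) -> FitResult:
    """Logistic regression of phenotype on allele counts.

    Newton iterations on the penalised log-likelihood with ridge λ on the
    slopes only; the intercept is unpenalised, so an empty design recovers
    the closed form ``logit(n_case / n_control)``. Constant columns carry no
    information and are dropped (their coefficient reported as 0). Missing
    allele counts contribute 0 (documented imputation).
    """
    X = np.nan_to_num(np.asarray(counts, dtype=float), nan=0.0)
    y = np.asarray(phenotype, dtype=float)
    if variant_keys is None:
        variant_keys = [f"v{j}" for j in range(X.shape[1])]
    if y.sum() == 0 or y.sum() == y.size:
        raise ValueError("need at least one sample in each class")

    keep = [j for j in range(X.shape[1]) if np.ptp(X[:, j]) > 0]
    dropped = [variant_keys[j] for j in range(X.shape[1]) if j not in keep]
    Xk = X[:, keep]
    n, p = Xk.shape
    design = np.column_stack([np.ones(n), Xk])
    penalty = np.diag([0.0] + [ridge_lambda] * p)

    beta = np.zeros(p + 1)
    beta[0] = math.log(y.mean() / (1 - y.mean()))
    for _ in range(max_iter):
        eta = design @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        grad = design.T @ (y - mu) - penalty @ beta
        hess = (design * w[:, None]).T @ design + penalty
        step = np.linalg.solve(hess, grad)
        beta = beta + step
        if float(np.max(np.abs(step))) < tol:
            break
    else:
        logger.warning("logistic fit did not reach tol=%g in %d iterations",
                       tol, max_iter)

    coefficients = np.zeros(X.shape[1])
    for idx, j in enumerate(keep):
        coefficients[j] = beta[1 + idx]
    return FitResult(intercept=float(beta[0]), coefficients=coefficients,
                     variant_keys=list(variant_keys),
                     dropped_constant=dropped)


def risk_scores(counts: np.ndarray, fit: FitResult,
                risk_classes: list[str] | None = None
                ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-sample (unweighted, weighted, predicted-risk) triples.

    Unweighted score counts risk alleles: alternate alleles carried at
    high-risk variants. Weighted score is Σ coefficient × allele count;
    predicted risk is ``logistic(intercept + weighted)``. Missing genotypes
    contribute 0.
    """
    X = np.nan_to_num(np.asarray(counts, dtype=float), nan=0.0)
    weighted = X @ fit.coefficients
    if risk_classes is None:
        high = fit.coefficients > 0
    else:
        high = np.array([rc == "high" for rc in risk_classes])
    unweighted = X[:, high].sum(axis=1) if high.any() else np.zeros(X.shape[0])
    risk = 1.0 / (1.0 + np.exp(-(fit.intercept + weighted)))
    return unweighted, weighted, risk


# ---------------------------------------------------------------------------
# LOOCV
# ---------------------------------------------------------------------------

def loocv(matrix: GenotypeMatrix, k: int = 16, ridge_lambda: float = 1e-3
          ) -> RiskModelResult:
    """Leave-one-out cross-validation with in-fold feature selection.

    For each sample: odds ratios and the top-k selection are computed on the
    other n−1 samples only, the logistic model is fitted on those n−1, and
    the held-out sample's risk is predicted. Fully deterministic. Folds
    whose training split loses a whole class are skipped with a warning.
    """
    if matrix.phenotype is None:
        raise ValueError("matrix has no phenotype labels")
    n = matrix.n_samples
    if n < 4:
        raise ValueError("need at least 4 samples for LOOCV")
    key_to_col = {v.key: j for j, v in enumerate(matrix.variants)}

    risks = np.full(n, np.nan)
    weighted = np.full(n, np.nan)
    unweighted = np.full(n, np.nan)
    fold_selected: list[list[str]] = []
    fold_fits: list[FitResult] = []
    skipped: list[int] = []

    for i in range(n):
        train = [s for s in range(n) if s != i]
        sub = matrix.subset_samples(train)
        if sub.phenotype.sum() in (0, sub.n_samples):
            logger.warning("fold %d skipped: empty class in training split", i)
            skipped.append(i)
            fold_selected.append([])
            fold_fits.append(FitResult(0.0, np.zeros(0), []))
            continue
        ors = variant_odds_ratios(sub)
        selected = select_top_variants(ors, k=k)
        cols = [key_to_col[key] for key in selected]
        fit = fit_risk_model(sub.counts[:, cols], sub.phenotype,
                             variant_keys=selected, ridge_lambda=ridge_lambda)
        by_key = {o.variant.key: o.risk_class for o in ors}
        classes = [by_key[key] for key in selected]
        u, w, r = risk_scores(matrix.counts[i:i + 1, cols], fit,
                              risk_classes=classes)
        unweighted[i], weighted[i], risks[i] = u[0], w[0], r[0]
        fold_selected.append(selected)
        fold_fits.append(fit)

    return RiskModelResult(
        sample_ids=list(matrix.sample_ids),
        labels=matrix.phenotype.copy(),
        predicted_risks=risks, weighted_scores=weighted,
        unweighted_scores=unweighted, fold_selected=fold_selected,
        fold_fits=fold_fits, skipped_folds=skipped)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def auc_rank(risks: np.ndarray, labels: np.ndarray) -> float | None:
    """AUC in its Mann–Whitney form (midranks for tied risks)."""
    labels = np.asarray(labels, dtype=bool)
    pos = np.asarray(risks, dtype=float)[labels]
    neg = np.asarray(risks, dtype=float)[~labels]
    if pos.size == 0 or neg.size == 0:
        return None
    greater = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return float((greater + 0.5 * ties) / (pos.size * neg.size))


def confusion_metrics(predicted_risks: np.ndarray, labels: np.ndarray,
                      threshold: float = 0.5) -> ConfusionMetrics:
    """Threshold the risks and compute the confusion-matrix metrics.

    Positive call ⇔ risk > threshold. Accuracy / sensitivity / specificity
    in percent; MCC in [−1, 1] with the 0-when-degenerate convention; AUC
    from the continuous risks by rank statistic. With single-class labels,
    sensitivity or specificity (and AUC) are reported missing.
    """
    risks = np.asarray(predicted_risks, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if np.any((risks < 0) | (risks > 1)):
        raise ValueError("risks must lie in [0, 1]")
    pred = risks > threshold
    tp = int(np.sum(pred & labels))
    fp = int(np.sum(pred & ~labels))
    tn = int(np.sum(~pred & ~labels))
    fn = int(np.sum(~pred & labels))
    n = tp + fp + tn + fn
    accuracy = 100.0 * (tp + tn) / n
    sensitivity = 100.0 * tp / (tp + fn) if (tp + fn) else None
    specificity = 100.0 * tn / (tn + fp) if (tn + fp) else None
    denom = math.sqrt(float((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)))
    mcc = (tp * tn - fp * fn) / denom if denom > 0 else 0.0
    return ConfusionMetrics(tp=tp, fp=fp, tn=tn, fn=fn, accuracy=accuracy,
                            sensitivity=sensitivity, specificity=specificity,
                            mcc=float(mcc), auc=auc_rank(risks, labels))


def confusion_from_counts(tp: int, fp: int, tn: int, fn: int) -> ConfusionMetrics:
    """Metrics directly from confusion-matrix counts (no AUC)."""
    risks = np.concatenate([np.ones(tp + fp), np.zeros(tn + fn)])
    labels = np.concatenate([np.ones(tp, bool), np.zeros(fp, bool),
                             np.zeros(tn, bool), np.ones(fn, bool)])
    m = confusion_metrics(risks, labels)
    return ConfusionMetrics(tp=m.tp, fp=m.fp, tn=m.tn, fn=m.fn,
                            accuracy=m.accuracy, sensitivity=m.sensitivity,
                            specificity=m.specificity, mcc=m.mcc, auc=None)


# ---------------------------------------------------------------------------
# Clustering of risk outputs
# ---------------------------------------------------------------------------

def hclust_average(scores: np.ndarray, sample_ids: list[str]
                   ) -> tuple[np.ndarray, list[str]]:
    """UPGMA (average-linkage, Euclidean) clustering of per-sample scores.

    Returns the SciPy-format merge table (left, right, height, size) and
    the dendrogram leaf order. Merge heights are non-decreasing; SciPy's
    deterministic ordering provides the tie-break.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.ndim == 1:
        scores = scores[:, None]
    if len(sample_ids) != scores.shape[0]:
        raise ValueError("sample id count does not match score rows")
    if len(set(sample_ids)) != len(sample_ids):
        raise ValueError("duplicate sample ids")
    if scores.shape[0] < 2:
        raise ValueError("need at least 2 samples to cluster")
    merges = linkage(scores, method="average", metric="euclidean")
    order = [sample_ids[i] for i in leaves_list(merges)]
    return merges, order
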