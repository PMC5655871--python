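"""Diagnostic scoring of reconstructed NIRST images.

The discriminative statistic is the total-hemoglobin (HbT) contrast: the
mean HbT inside the suspicious region of interest divided by the mean HbT in
the rest of the breast.  Benign-vs-malignant discrimination is quantified by
ROC analysis (trapezoidal AUC, equal by construction to the tie-corrected
Mann-Whitney concordance), the best cutoff is the threshold maximizing
sensitivity + specificity (ties broken toward higher specificity), scores
are combined across modalities by ordinary binary logistic regression, and
group differences are assessed with two-tailed Student's t tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import sparse, stats

from .phantom_synth import InvalidParameterError

__all__ = [
    "MaskError",
    "ClassError",
    "SubjectRecord",
    "ROCResult",
    "hbt_contrast",
    "roi_from_prior",
    "roc_analysis",
    "combine_scores",
    "group_t_test",
    "performance_at_cutoff",
    "simulate_birads",
]

POSITIVE_LABEL = "malignant"


class MaskError(ValueError):
    """The region of interest is empty, all-covering, or degenerate."""


class ClassError(ValueError):
    """Both benign and malignant subjects are required."""


@dataclass(frozen=True)
class SubjectRecord:
    """Per-subject diagnostic scores and pathology ground truth."""

    subject_id: str
    hbt_contrast: float
    pathology_label: str                 # "benign" | "malignant"
    birads_score: int | None = None      # ordinal 1-5
    combined_score: float | None = None

    def __post_init__(self) -> None:
        if self.hbt_contrast <= 0:
            raise InvalidParameterError("hbt_contrast must be > 0")
        if self.pathology_label not in ("benign", "malignant"):
            raise InvalidParameterError("pathology_label must be benign|malignant")


@dataclass(frozen=True)
class ROCResult:
    """ROC sweep summary; the best cutoff attains the maximal sens+spec."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    best_cutoff: float
    best_sensitivity: float
    best_specificity: float
    best_accuracy: float


# --------------------------------------------------------------------------
# contrast statistic and ROI
# --------------------------------------------------------------------------

def hbt_contrast(hbt_map: np.ndarray, roi_mask: np.ndarray) -> float:
    """mean(HbT | ROI) / mean(HbT | rest of the breast)."""
    hbt_map = np.asarray(hbt_map, float)
    roi = np.asarray(roi_mask, bool)
    if roi.shape != hbt_map.shape:
        raise MaskError("roi_mask shape must match the HbT map")
    if not roi.any():
        raise MaskError("ROI is empty")
    if roi.all():
        raise MaskError("ROI covers every node; no background remains")
    background = float(hbt_map[~roi].mean())
    if background == 0.0:
        raise MaskError("background HbT mean is zero; contrast undefined")
    return float(hbt_map[roi].mean()) / background


def roi_from_prior(gamma: np.ndarray, adjacency: sparse.spmatrix | None = None,
                   rule: str = "otsu") -> np.ndarray:
    """Automated ROI surrogate for the radiologist's manual segmentation:
    threshold the nodal grayscale values (Otsu two-class rule by default) and
    keep the largest connected component of the bright class.

    ``adjacency`` is the mesh node-connectivity matrix
    (:meth:`Mesh.node_adjacency`); without it the bright set is returned
    unpruned.
    """
    gamma = np.asarray(gamma, float)
    if rule != "otsu":
        raise InvalidParameterError(f"unknown ROI rule {rule!r}")
    if np.ptp(gamma) == 0:
        raise MaskError("constant grayscale values: no threshold exists")
    from skimage.filters import threshold_otsu

    thr = threshold_otsu(gamma, nbins=256)
    mask = gamma > thr
    if not mask.any():
        raise MaskError("threshold yields an empty region")
    if adjacency is not None:
        from scipy.sparse.csgraph import connected_components

        sub = adjacency[mask][:, mask]
        _n, labels = connected_components(sub, directed=False)
        counts = np.bincount(labels)
        keep = labels == counts.argmax()
        idx = np.flatnonzero(mask)
        mask = np.zeros_like(mask)
        mask[idx[keep]] = True
    return mask


# --------------------------------------------------------------------------
# ROC analysis
# --------------------------------------------------------------------------

def _labels01(records, positive=POSITIVE_LABEL) -> np.ndarray:
    return np.array([1 if r.pathology_label == positive else 0
                     for r in records], int)


def _scores(records, score_field) -> np.ndarray:
    vals = np.array([getattr(r, score_field) for r in records], float)
    if np.isnan(vals).any():
        raise InvalidParameterError(f"missing values in {score_field!r}")
    return vals


def performance_at_cutoff(records, score_field: str, cutoff: float):
    """Sensitivity, specificity and accuracy with score > cutoff positive."""
    y = _labels01(records)
    if y.min() == y.max():
        raise ClassError("need both benign and malignant subjects")
    s = _scores(records, score_field)
    pred = s > cutoff
    tp = int(np.sum(pred & (y == 1)))
    tn = int(np.sum(~pred & (y == 0)))
    sens = tp / int(np.sum(y == 1))
    spec = tn / int(np.sum(y == 0))
    acc = (tp + tn) / len(y)
    return sens, spec, acc


def roc_analysis(records, score_field: str = "hbt_contrast") -> ROCResult:
    """Exhaustive threshold sweep over the observed scores.

    The AUC is computed by the trapezoidal rule over the swept curve, which
    equals the tie-corrected Mann-Whitney concordance between the two
    classes.  The best cutoff maximizes sensitivity + specificity; exact
    ties go to the threshold with higher specificity.
    """
    y = _labels01(records)
    if y.min() == y.max():
        raise ClassError("need both benign and malignant subjects")
    s = _scores(records, score_field)

    # candidate cutoffs: below every score, then each unique observed score
    uniq = np.unique(s)
    cand = np.concatenate([[uniq[0] - 1.0], uniq])
    sens = np.empty(len(cand))
    spec = np.empty(len(cand))
    npos = int(np.sum(y == 1))
    nneg = int(np.sum(y == 0))
    for i, c in enumerate(cand):
        pred = s > c
        sens[i] = np.sum(pred & (y == 1)) / npos
        spec[i] = np.sum(~pred & (y == 0)) / nneg
    # trapezoidal AUC over (FPR, TPR); ascending cutoffs sweep FPR 1 -> 0,
    # so reversing the sweep gives the curve in increasing-FPR order
    fpr = 1.0 - spec
    auc = float(np.trapezoid(sens[::-1], fpr[::-1]))

    total = sens + spec
    best = np.flatnonzero(total == total.max())
    # ties toward higher specificity
    best_i = best[np.argmax(spec[best])]
    cutoff = float(cand[best_i])
    bsens, bspec, bacc = performance_at_cutoff(records, score_field, cutoff)
    return ROCResult(thresholds=cand, sensitivity=sens, specificity=spec,
                     auc=auc, best_cutoff=cutoff, best_sensitivity=bsens,
                     best_specificity=bspec, best_accuracy=bacc)


# --------------------------------------------------------------------------
# score combination and group tests
# --------------------------------------------------------------------------

def combine_scores(records, fields=("hbt_contrast", "birads_score")):
    """Binary logistic regression of pathology on the named score fields;
    the combined score is the fitted linear predictor.

    Returns ``(records_with_combined_score, coefficients, ridge_flag)``.
    Constant predictors are dropped with a warning; on perfect separation
    the fit falls back to a ridge-penalized logistic model (penalty 1e-2)
    and ``ridge_flag`` is True.
    """
    import warnings

    from sklearn.linear_model import LogisticRegression

    y = _labels01(records)
    if np.sum(y == 1) < 2 or np.sum(y == 0) < 2:
        raise ClassError("need >= 2 subjects per class")
    cols = []
    kept = []
    for f in fields:
        v = _scores(records, f)
        if np.ptp(v) == 0:
            warnings.warn(f"field {f!r} is constant; dropped from the "
                          "logistic combination", stacklevel=2)
            continue
        cols.append(v)
        kept.append(f)
    if not cols:
        raise InvalidParameterError("no non-constant fields to combine")
    x = np.column_stack(cols)

    ridge = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = LogisticRegression(C=np.inf, max_iter=5000, tol=1e-10)
        model.fit(x, y)
    lin = x @ model.coef_[0] + model.intercept_[0]
    if lin[y == 1].min() > lin[y == 0].max():
        # perfect separation: the unpenalized MLE does not exist
        ridge = True
        model = LogisticRegression(C=1.0 / 1e-2, max_iter=5000)
        model.fit(x, y)
    coef = {f: float(c) for f, c in zip(kept, model.coef_[0])}
    coef["intercept"] = float(model.intercept_[0])
    lin = x @ model.coef_[0] + model.intercept_[0]
    out = [replace(r, combined_score=float(v)) for r, v in zip(records, lin)]
    return out, coef, ridge


def group_t_test(records, score_field: str = "hbt_contrast",
                 welch: bool = False):
    """Two-sample two-tailed t test between malignant and benign groups.

    Pooled-variance Student form by default; ``welch=True`` drops the
    equal-variance assumption.  Returns (t, p, (mean_malignant, mean_benign)).
    """
    y = _labels01(records)
    s = _scores(records, score_field)
    a, b = s[y == 1], s[y == 0]
    if len(a) < 2 or len(b) < 2:
        raise ClassError("need >= 2 subjects per class")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0, (float(a.mean()), float(b.mean()))
        raise InvalidParameterError("zero variance in both groups")
    t, p = stats.ttest_ind(a, b, equal_var=not welch)
    return float(t), float(p), (float(a.mean()), float(b.mean()))


# --------------------------------------------------------------------------
# simulated radiology scores
# --------------------------------------------------------------------------

def simulate_birads(labels, rng: np.random.Generator,
                    malignant_mean: float = 4.6, benign_mean: float = 2.4,
                    sd: float = 1.0) -> np.ndarray:
    """Noisy ordinal BIRADS surrogate: a Gaussian around a class-conditional
    mean, rounded and clipped to 1-5.  Defaults give roughly 85-90%
    sensitivity/specificity at the conventional BIRADS >= 4 positivity rule,
    emulating radiologist performance on noncontrast MRI."""
    mu = np.where(np.asarray(labels) == POSITIVE_LABEL,
                  malignant_mean, benign_mean)
    raw = rng.normal(mu, sd)
    return np.clip(np.rint(raw), 1, 5).astype(int)
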