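"""PCA-LDA tissue classification and univariate volcano analysis.

The classifier is the one used for spectral tissue recognition in REIMS
workflows: principal-component scores of mean-centered, TIC-normalized binned
spectra are fed to a linear discriminant analysis, and test spectra are
assigned to the nearest class centroid in discriminant space.  Both the PCA
(SVD, with a Gram-matrix shortcut when samples < bins) and the LDA
(within/between scatter with a trace-scaled ridge) are implemented here;
external library implementations serve only as cross-check oracles in the
test suite.

``PCALDA`` is a scikit-learn compatible estimator (``fit`` / ``predict`` /
``get_params``), so it composes with sklearn model selection; the
module-level functions (``fit_pca_lda``, ``cross_validate``, ...) are thin
wrappers and task-specific drivers around it.

Validation follows the leave-20%-out scheme: repeated stratified random
80/20 splits (default 25 repeats) with the model refitted per split, pooled
into a single confusion matrix.  When per-sample group ids are provided
(e.g. specimen of origin), splitting is done by group to avoid leakage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.linalg import eigh
from scipy.stats import mannwhitneyu
from sklearn.base import BaseEstimator, ClassifierMixin
from statsmodels.stats.multitest import multipletests

__all__ = [
    "FeatureMatrix",
    "PCALDA",
    "CvReport",
    "VolcanoResult",
    "fit_pca",
    "fit_pca_lda",
    "cross_validate",
    "cross_modality_eval",
    "confusion_metrics",
    "volcano",
]


@dataclass
class FeatureMatrix:
    """samples x bins matrix of normalized intensities with labels."""

    X: np.ndarray
    labels: np.ndarray
    bin_edges: np.ndarray | None = None
    modality: np.ndarray | None = None
    groups: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.X.ndim != 2 or len(self.labels) != self.X.shape[0]:
            raise ValueError("X must be samples x bins with one label per row")
        if np.any(self.X < 0):
            raise ValueError("feature matrix must be non-negative")
        if self.bin_edges is not None:
            self.bin_edges = np.asarray(self.bin_edges, dtype=float)
            if len(self.bin_edges) != self.X.shape[1]:
                raise ValueError("bin axis length must match feature count")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    def to_csv(self, path) -> None:
        cols = ([f"{e:.4f}" for e in self.bin_edges]
                if self.bin_edges is not None
                else [str(i) for i in range(self.X.shape[1])])
        df = pd.DataFrame(self.X, columns=cols)
        df.insert(0, "label", self.labels)
        if self.modality is not None:
            df.insert(1, "modality", self.modality)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "FeatureMatrix":
        df = pd.read_csv(path)
        labels = df.pop("label").to_numpy()
        modality = df.pop("modality").to_numpy() if "modality" in df else None
        edges = np.array([float(c) for c in df.columns])
        return cls(X=df.to_numpy(float), labels=labels, bin_edges=edges,
                   modality=modality)


def _pca_svd(xc: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Top-k principal axes of centered data; Gram shortcut when n < p.

    Returns (components (k, p), explained variance ratios (k,)).  Component
    sign is fixed so the largest-magnitude loading of each axis is positive.
    """
    n, p = xc.shape
    if n < p:
        gram = xc @ xc.T
        evals, evecs = np.linalg.eigh(gram)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        pos = evals > max(evals[0], 0.0) * 1e-12
        r = min(k, int(pos.sum()))
        comps = (xc.T @ evecs[:, :r]) / np.sqrt(np.maximum(evals[:r], 1e-300))
        comps = comps.T
        var = evals
    else:
        _u, s, vt = np.linalg.svd(xc, full_matrices=False)
        r = min(k, (s > s[0] * 1e-12).sum() if s.size else 0)
        comps = vt[:r]
        var = s**2
    total = var[var > 0].sum()
    ratios = (var[:r] / total) if total > 0 else np.zeros(r)
    # deterministic sign: largest-|loading| entry positive
    for i in range(comps.shape[0]):
        j = np.argmax(np.abs(comps[i]))
        if comps[i, j] < 0:
            comps[i] = -comps[i]
    return comps, ratios


class PCALDA(BaseEstimator, ClassifierMixin):
    """PCA-LDA classifier: LDA on the top-k principal-component scores.

    Parameters
    ----------
    n_components : int
        Number of principal components fed to the LDA (capped at
        samples - classes during fit, floored at the number of classes).
    ridge : float
        Within-class scatter regularization, added as ridge * trace(Sw) * I.

    Attributes (after fit)
    ----------------------
    classes_ : sorted class labels
    mean_ : feature means used for centering
    components_ : (k, p) orthonormal PCA loadings
    explained_variance_ratio_ : per-component explained variance shares
    scalings_ : (k, C-1) LDA discriminant directions in score space
    centroids_ : (C, C-1) class centroids in discriminant space
    """

    def __init__(self, n_components: int = 10, ridge: float = 1e-6) -> None:
        self.n_components = n_components
        self.ridge = ridge

    def fit(self, X, y) -> "PCALDA":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        classes, y_idx = np.unique(y, return_inverse=True)
        if len(classes) < 2:
            raise ValueError("PCA-LDA needs at least two classes")
        counts = np.bincount(y_idx)
        if counts.min() < 2:
            raise ValueError("every class needs at least two samples")
        n = X.shape[0]
        k = int(min(self.n_components, n - len(classes)))
        k = max(k, len(classes))
        self.mean_ = X.mean(axis=0)
        xc = X - self.mean_
        self.components_, self.explained_variance_ratio_ = _pca_svd(xc, k)
        scores = xc @ self.components_.T
        k_eff = scores.shape[1]
        # scatter matrices in score space
        sw = np.zeros((k_eff, k_eff))
        sb = np.zeros((k_eff, k_eff))
        grand = scores.mean(axis=0)
        for ci in range(len(classes)):
            sc = scores[y_idx == ci]
            mu = sc.mean(axis=0)
            d = sc - mu
            sw += d.T @ d
            m = (mu - grand)[:, None]
            sb += len(sc) * (m @ m.T)
        sw_reg = sw + self.ridge * np.trace(sw) * np.eye(k_eff)
        evals, evecs = eigh(sb, sw_reg)
        order = np.argsort(evals)[::-1]
        n_disc = min(len(classes) - 1, k_eff)
        self.scalings_ = evecs[:, order[:n_disc]]
        disc = scores @ self.scalings_
        self.classes_ = classes
        self.centroids_ = np.vstack(
            [disc[y_idx == ci].mean(axis=0) for ci in range(len(classes))])
        self.n_components_ = k_eff
        return self

    def transform(self, X) -> np.ndarray:
        """Project spectra into discriminant space."""
        xc = np.asarray(X, dtype=float) - self.mean_
        return (xc @ self.components_.T) @ self.scalings_

    def predict(self, X) -> np.ndarray:
        disc = self.transform(X)
        d2 = ((disc[:, None, :] - self.centroids_[None]) ** 2).sum(axis=2)
        return self.classes_[np.argmin(d2, axis=1)]

    def to_json(self, path) -> None:
        payload = {
            "classes": self.classes_.tolist(),
            "mean": self.mean_.tolist(),
            "components": self.components_.tolist(),
            "explained_variance_ratio": self.explained_variance_ratio_.tolist(),
            "scalings": self.scalings_.tolist(),
            "centroids": self.centroids_.tolist(),
        }
        Path(path).write_text(json.dumps(payload))


def fit_pca(fm: FeatureMatrix | np.ndarray, k: int):
    """Mean-centered PCA by SVD; returns (components, explained ratios, scores)."""
    X = fm.X if isinstance(fm, FeatureMatrix) else np.asarray(fm, float)
    if k > min(X.shape[0] - 1, X.shape[1]):
        raise ValueError("k exceeds min(samples - 1, bins)")
    mean = X.mean(axis=0)
    comps, ratios = _pca_svd(X - mean, k)
    return comps, ratios, (X - mean) @ comps.T


def fit_pca_lda(fm: FeatureMatrix, k: int = 10, ridge: float = 1e-6) -> PCALDA:
    """Fit the PCA-LDA model on a feature matrix."""
    return PCALDA(n_components=k, ridge=ridge).fit(fm.X, fm.labels)


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

@dataclass
class CvReport:
    """Pooled repeated leave-20%-out cross-validation report (rates in %)."""

    scheme: str
    n_repeats: int
    confusion: pd.DataFrame          # pooled truth x predicted counts
    per_repeat_accuracy: np.ndarray
    sensitivity: float               # %, w.r.t. the positive class
    specificity: float               # %
    per_class_correct: dict          # class -> % correct
    positive_class: str


def confusion_metrics(truth, predicted, positive_class) -> dict:
    """Sensitivity and specificity in percent for a designated positive class.

    A zero denominator (no positives, or no negatives, in truth) yields NaN
    with the corresponding ``*_undefined`` flag set.
    """
    truth = np.asarray(truth)
    predicted = np.asarray(predicted)
    pos = truth == positive_class
    tp = int(np.sum(pos & (predicted == positive_class)))
    fn = int(np.sum(pos & (predicted != positive_class)))
    tn = int(np.sum(~pos & (predicted != positive_class)))
    fp = int(np.sum(~pos & (predicted == positive_class)))
    sens = 100.0 * tp / (tp + fn) if (tp + fn) else float("nan")
    spec = 100.0 * tn / (tn + fp) if (tn + fp) else float("nan")
    return {"sensitivity": sens, "specificity": spec,
            "sensitivity_undefined": (tp + fn) == 0,
            "specificity_undefined": (tn + fp) == 0,
            "tp": tp, "fn": fn, "tn": tn, "fp": fp}


def _stratified_split(y: np.ndarray, test_fraction: float,
                      rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    test_idx = []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        n_test = max(1, int(round(test_fraction * len(idx))))
        if n_test >= len(idx):
            n_test = len(idx) - 1
        test_idx.append(idx[:n_test])
    test_idx = np.concatenate(test_idx)
    mask = np.zeros(len(y), dtype=bool)
    mask[test_idx] = True
    return np.flatnonzero(~mask), np.flatnonzero(mask)


def cross_validate(fm: FeatureMatrix, n_repeats: int = 25, seed: int = 0,
                   test_fraction: float = 0.2, n_components: int = 10,
                   positive_class=None, groups=None) -> CvReport:
    """Repeated stratified random 80/20 splits, model refitted per split.

    With ``groups`` (or ``fm.groups``) the sampling unit is the group, so
    pixels from one specimen never straddle a split.  Reproducible by seed.
    """
    y = fm.labels
    counts = pd.Series(y).value_counts()
    if counts.min() < 2:
        raise ValueError("every class needs at least two samples for CV")
    groups = fm.groups if groups is None else np.asarray(groups)
    rng = np.random.default_rng(seed)
    if positive_class is None:
        positive_class = sorted(np.unique(y))[-1]
    all_truth, all_pred = [], []
    accs = np.zeros(n_repeats)
    for rep in range(n_repeats):
        if groups is not None:
            uniq = np.unique(groups)
            glab = np.array([y[groups == g][0] for g in uniq])
            tr_g, te_g = _stratified_split(glab, test_fraction, rng)
            train = np.isin(groups, uniq[tr_g])
            test = np.isin(groups, uniq[te_g])
            train, test = np.flatnonzero(train), np.flatnonzero(test)
        else:
            train, test = _stratified_split(y, test_fraction, rng)
        model = PCALDA(n_components=n_components).fit(fm.X[train], y[train])
        pred = model.predict(fm.X[test])
        all_truth.append(y[test])
        all_pred.append(pred)
        accs[rep] = np.mean(pred == y[test])
    truth = np.concatenate(all_truth)
    pred = np.concatenate(all_pred)
    confusion = pd.crosstab(pd.Series(truth, name="truth"),
                            pd.Series(pred, name="predicted"), dropna=False)
    metrics = confusion_metrics(truth, pred, positive_class)
    per_class = {cls: 100.0 * np.mean(pred[truth == cls] == cls)
                 for cls in np.unique(y)}
    return CvReport(scheme="repeated 80/20", n_repeats=n_repeats,
                    confusion=confusion, per_repeat_accuracy=accs,
                    sensitivity=metrics["sensitivity"],
                    specificity=metrics["specificity"],
                    per_class_correct=per_class,
                    positive_class=str(positive_class))


def cross_modality_eval(train: FeatureMatrix, test: FeatureMatrix,
                        n_components: int = 10) -> dict:
    """Fit on all of one modality, evaluate on all of another.

    Requires identical bin axes and a shared label vocabulary; returns the
    per-class percent correct on the test modality.
    """
    if train.bin_edges is not None and test.bin_edges is not None:
        if (len(train.bin_edges) != len(test.bin_edges)
                or not np.allclose(train.bin_edges, test.bin_edges)):
            raise ValueError("bin axes of the two modalities do not match")
    elif train.X.shape[1] != test.X.shape[1]:
        raise ValueError("bin axes of the two modalities do not match")
    unseen = set(np.unique(test.labels)) - set(np.unique(train.labels))
    if unseen:
        raise ValueError(f"test labels {sorted(unseen)} absent from training")
    model = PCALDA(n_components=n_components).fit(train.X, train.labels)
    pred = model.predict(test.X)
    return {cls: 100.0 * np.mean(pred[test.labels == cls] == cls)
            for cls in np.unique(test.labels)}


# ---------------------------------------------------------------------------
# univariate volcano analysis
# ---------------------------------------------------------------------------

@dataclass
class VolcanoResult:
    """Per-bin fold change and FDR-corrected Mann-Whitney significance."""

    log2_fold_change: np.ndarray
    p_values: np.ndarray
    q_values: np.ndarray
    significant: np.ndarray           # bool mask at the given thresholds
    q_threshold: float
    fc_threshold: float
    group_a: str
    group_b: str

    @property
    def n_significant(self) -> int:
        return int(self.significant.sum())


def volcano(fm: FeatureMatrix, q_threshold: float = 0.05,
            fc_threshold: float = 1.0, groups: tuple | None = None,
            epsilon: float = 1e-12) -> VolcanoResult:
    """Two-group univariate screen: log2 mean ratio + Mann-Whitney U + BH.

    A bin is significant iff BH-adjusted q < ``q_threshold`` and
    |log2 fold change| > ``fc_threshold``.  Fold change is group A over
    group B, zero-protected by ``epsilon``.
    """
    labels = np.asarray(fm.labels)
    if groups is None:
        uniq = np.unique(labels)
        if len(uniq) != 2:
            raise ValueError("volcano needs exactly two groups; pass groups=")
        groups = tuple(uniq)
    a, b = groups
    xa = fm.X[labels == a]
    xb = fm.X[labels == b]
    if len(xa) < 3 or len(xb) < 3:
        raise ValueError("each group needs at least 3 samples")
    log2fc = np.log2((xa.mean(axis=0) + epsilon) / (xb.mean(axis=0) + epsilon))
    with np.errstate(invalid="ignore", divide="ignore"):
        res = mannwhitneyu(xa, xb, axis=0, alternative="two-sided")
        p = np.asarray(res.pvalue, dtype=float)
    p = np.where(np.isfinite(p), p, 1.0)   # constant bins: no evidence
    _rej, q, _a, _b = multipletests(p, method="fdr_bh")
    significant = (q < q_threshold) & (np.abs(log2fc) > fc_threshold)
    return VolcanoResult(log2_fold_change=log2fc, p_values=p, q_values=q,
                         significant=significant, q_threshold=q_threshold,
                         fc_threshold=fc_threshold, group_a=str(a),
                         group_b=str(b))
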