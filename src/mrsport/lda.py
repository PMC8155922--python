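"""Multiclass Fisher discriminant prediction of lesion class and glioma
molecular subtype.

The discriminant directions w maximize the Fisher criterion

    S(w) = (w^T Sigma_b w) / (w^T Sigma w),

with the between-class scatter Sigma_b the unweighted average of
(mu_i - mu)(mu_i - mu)^T over class means (mu the unweighted mean of the
class means) and Sigma the pooled within-class scatter divided by (n - C).
A small ridge lambda * trace(Sigma)/p is added to Sigma so the generalized
eigenproblem stays well-posed when denoised features are nearly collinear.
Class posteriors come from a shared-covariance Gaussian model in the
projected space (the homoscedasticity assumption under which the denoised
features are treated as normally distributed).

Voxel scores are calibrated against a reference distribution (per-class
Gaussian fit, centered and scaled); the patient-level classifier score
("sport score") is the per-class mean of calibrated scores over predicted
tumor voxels, and the predicted subtype its argmax.  The two-layer model
first masks voxels with high tumor probability (layer 1, region classes)
and only scores the mask with the subtype discriminant (layer 2), which
suppresses the false-positive subtype calls a single-layer model makes on
normal-appearing matter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, stats
from sklearn.base import BaseEstimator, ClassifierMixin

from .core_data import ClassSet, ValidationError

__all__ = [
    "FisherLDA",
    "ScoreCalibrator",
    "VoxelScores",
    "PatientPrediction",
    "TwoLayerSubtypeClassifier",
    "fit_lda",
    "predict_lda",
    "calibrate_scores",
    "sport_score",
    "two_layer_predict",
    "roc_auc",
    "render_score_map",
]


@dataclass
class VoxelScores:
    """Per-voxel per-class scores and posterior-like probabilities."""

    classes: tuple[str, ...]
    scores: np.ndarray  # voxels x classes (discriminant or calibrated)
    probabilities: np.ndarray  # voxels x classes, rows sum to 1
    calibrated: bool = False

    def argmax_classes(self) -> np.ndarray:
        # ties break toward the earlier class in the class set
        return np.array([self.classes[i] for i in
                         np.argmax(self.probabilities, axis=1)])


@dataclass
class PatientPrediction:
    """Patient-level outcome of the two-layer model."""

    tumor_mask: np.ndarray  # boolean over voxels
    sport_scores: dict[str, float] | None  # None when no tumor detected
    predicted: str | None  # subtype, or None for "no tumor detected"
    region_scores: VoxelScores | None = None
    subtype_scores: VoxelScores | None = None  # over masked voxels only
    voxel_ids: list[str] | None = None
    extras: dict = field(default_factory=dict)

    @property
    def no_tumor_detected(self) -> bool:
        return self.predicted is None


class FisherLDA(ClassifierMixin, BaseEstimator):
    """Multiclass Fisher linear discriminant with ridge-stabilized scatter.

    Fitted attributes: ``classes_``, ``means_`` (C x p), ``grand_mean_``,
    ``scatter_between_``, ``scatter_within_`` (covariance-scaled),
    ``scalings_`` (p x C-1 discriminant eigenvectors, unit columns,
    deterministic sign) and the projected-space Gaussian parameters used
    for posteriors.
    """

    def __init__(self, lam: float = 1e-4, class_set: ClassSet | None = None):
        self.lam = lam
        self.class_set = class_set

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or len(y) != X.shape[0]:
            raise ValidationError("X must be 2-D with one label per row")
        present = [c for c in (self.class_set.classes if self.class_set
                               else np.unique(y).tolist()) if np.any(y == c)]
        if self.class_set is not None:
            absent = [c for c in self.class_set.classes if c not in present]
            if absent:
                raise ValidationError(f"classes absent from training data: {absent}")
        if len(present) < 2:
            raise ValidationError("need >= 2 classes present")
        for c in present:
            if np.sum(y == c) < 2:
                raise ValidationError(f"class {c!r} has fewer than 2 samples")
        self.classes_ = tuple(present)
        C, p = len(present), X.shape[1]

        self.means_ = np.stack([X[y == c].mean(axis=0) for c in present])
        mu = self.means_.mean(axis=0)  # unweighted mean of class means
        self.grand_mean_ = mu
        d = self.means_ - mu
        self.scatter_between_ = d.T @ d / C

        Sw = np.zeros((p, p))
        n = X.shape[0]
        for i, c in enumerate(present):
            Xc = X[y == c] - self.means_[i]
            Sw += Xc.T @ Xc
        self.scatter_within_ = Sw / max(n - C, 1)

        ridge = self.lam * np.trace(self.scatter_within_) / p
        if ridge <= 0:
            ridge = self.lam
        Sreg = self.scatter_within_ + ridge * np.eye(p)
        self.ridge_ = ridge

        evals, evecs = linalg.eigh(self.scatter_between_, Sreg)
        order = np.argsort(evals)[::-1][: C - 1]
        W = evecs[:, order]
        W = W / np.linalg.norm(W, axis=0, keepdims=True)
        for j in range(W.shape[1]):  # deterministic sign convention
            i = np.argmax(np.abs(W[:, j]))
            if W[i, j] < 0:
                W[:, j] = -W[:, j]
        self.scalings_ = W
        self.eigenvalues_ = evals[order]

        # shared-covariance Gaussian model in the projected space
        Z = X @ W
        self.proj_means_ = self.means_ @ W
        Sp = np.zeros((W.shape[1], W.shape[1]))
        for i, c in enumerate(present):
            Zc = Z[y == c] - self.proj_means_[i]
            Sp += Zc.T @ Zc
        Sp /= max(n - C, 1)
        Sp += 1e-10 * np.eye(Sp.shape[0]) * max(np.trace(Sp), 1.0)
        self.proj_cov_ = Sp
        self.proj_cov_inv_ = np.linalg.inv(Sp)
        self.n_features_in_ = p
        return self

    def fisher_criterion(self, w: np.ndarray) -> float:
        """S(w) for a single direction w."""
        w = np.asarray(w, dtype=float)
        num = float(w @ self.scatter_between_ @ w)
        den = float(w @ self.scatter_within_ @ w) + 1e-300
        return num / den

    def decision_function(self, X) -> np.ndarray:
        """Per-class Gaussian log-discriminants in the projected space."""
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValidationError(
                f"X has {X.shape[1]} features, model expects {self.n_features_in_}")
        Z = X @ self.scalings_
        D = np.empty((X.shape[0], len(self.classes_)))
        for i in range(len(self.classes_)):
            diff = Z - self.proj_means_[i]
            D[:, i] = -0.5 * np.einsum("ij,jk,ik->i", diff,
                                       self.proj_cov_inv_, diff)
        return D

    def predict_scores(self, X) -> VoxelScores:
        D = self.decision_function(X)
        # softmax with shift for numerical stability
        E = np.exp(D - D.max(axis=1, keepdims=True))
        P = E / E.sum(axis=1, keepdims=True)
        return VoxelScores(classes=self.classes_, scores=D, probabilities=P)

    def predict_proba(self, X) -> np.ndarray:
        return self.predict_scores(X).probabilities

    def predict(self, X) -> np.ndarray:
        return self.predict_scores(X).argmax_classes()

    def to_dict(self) -> dict:
        return {
            "lam": self.lam,
            "classes": list(self.classes_),
            "means": self.means_.tolist(),
            "grand_mean": self.grand_mean_.tolist(),
            "scatter_between": self.scatter_between_.tolist(),
            "scatter_within": self.scatter_within_.tolist(),
            "scalings": self.scalings_.tolist(),
            "eigenvalues": self.eigenvalues_.tolist(),
            "proj_means": self.proj_means_.tolist(),
            "proj_cov": self.proj_cov_.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FisherLDA":
        m = cls(lam=d["lam"])
        m.classes_ = tuple(d["classes"])
        m.means_ = np.asarray(d["means"])
        m.grand_mean_ = np.asarray(d["grand_mean"])
        m.scatter_between_ = np.asarray(d["scatter_between"])
        m.scatter_within_ = np.asarray(d["scatter_within"])
        m.scalings_ = np.asarray(d["scalings"])
        m.eigenvalues_ = np.asarray(d["eigenvalues"])
        m.proj_means_ = np.asarray(d["proj_means"])
        m.proj_cov_ = np.asarray(d["proj_cov"])
        m.proj_cov_inv_ = np.linalg.inv(m.proj_cov_)
        m.n_features_in_ = m.means_.shape[1]
        return m


class ScoreCalibrator(BaseEstimator):
    """Center-and-scale calibration of per-class scores.

    Fits a Gaussian to each class's score distribution over a reference
    voxel set; calibrated score Sc = (score - mean) / sd.  Parameters are
    stored so the same transform applies to new data (monotone per class,
    so within-class rankings are preserved).
    """

    def __init__(self, min_reference: int = 10):
        self.min_reference = min_reference

    def fit(self, scores: VoxelScores):
        S = scores.scores
        if S.shape[0] < self.min_reference:
            raise ValidationError(
                f"reference set must have >= {self.min_reference} voxels")
        self.loc_ = S.mean(axis=0)
        self.scale_ = S.std(axis=0)
        if np.any(self.scale_ == 0):
            raise ValidationError("zero score variance; cannot calibrate")
        self.classes_ = scores.classes
        return self

    def transform(self, scores: VoxelScores) -> VoxelScores:
        if scores.classes != self.classes_:
            raise ValidationError("class set mismatch in calibration")
        Sc = (scores.scores - self.loc_) / self.scale_
        return VoxelScores(classes=scores.classes, scores=Sc,
                           probabilities=scores.probabilities, calibrated=True)

    def to_dict(self) -> dict:
        return {"loc": self.loc_.tolist(), "scale": self.scale_.tolist(),
                "classes": list(self.classes_)}

    @classmethod
    def from_dict(cls, d: dict) -> "ScoreCalibrator":
        c = cls()
        c.loc_ = np.asarray(d["loc"])
        c.scale_ = np.asarray(d["scale"])
        c.classes_ = tuple(d["classes"])
        return c


# ---------------------------------------------------------------------------
# functional wrappers


def fit_lda(X, y, class_set: ClassSet | None = None, lam: float = 1e-4) -> FisherLDA:
    return FisherLDA(lam=lam, class_set=class_set).fit(X, y)


def predict_lda(model: FisherLDA, X) -> VoxelScores:
    return model.predict_scores(X)


def calibrate_scores(scores: VoxelScores,
                     calibrator: ScoreCalibrator | None = None
                     ) -> tuple[VoxelScores, ScoreCalibrator]:
    """Calibrate against the reference distribution (fit here if not given)."""
    if calibrator is None:
        calibrator = ScoreCalibrator().fit(scores)
    return calibrator.transform(scores), calibrator


def sport_score(voxel_scores: VoxelScores) -> dict[str, float]:
    """Patient-level classifier score: per-class mean over the voxel set."""
    if voxel_scores.scores.shape[0] == 0:
        raise ValidationError("empty voxel set: no tumor voxels to score")
    means = voxel_scores.scores.mean(axis=0)
    return {c: float(m) for c, m in zip(voxel_scores.classes, means)}


def two_layer_predict(layer1: FisherLDA, layer2: FisherLDA, X: np.ndarray,
                      calibrator: ScoreCalibrator | None = None,
                      tumor_class: str = "TUMOR",
                      tumor_threshold: float = 0.5,
                      voxel_ids: list[str] | None = None) -> PatientPrediction:
    """Region mask (layer 1) then subtype scoring of masked voxels (layer 2).

    Voxels whose layer-1 tumor-class probability exceeds ``tumor_threshold``
    form the tumor mask; layer 2 scores only the mask; the per-class mean of
    the calibrated layer-2 scores is the patient score and its argmax the
    predicted subtype.  An empty mask yields a "no tumor detected" outcome
    (``predicted is None``).
    """
    X = np.asarray(X, dtype=float)
    region = layer1.predict_scores(X)
    if tumor_class not in region.classes:
        raise ValidationError(f"layer-1 model has no class {tumor_class!r}")
    tcol = region.classes.index(tumor_class)
    mask = region.probabilities[:, tcol] > tumor_threshold
    if not mask.any():
        return PatientPrediction(tumor_mask=mask, sport_scores=None,
                                 predicted=None, region_scores=region,
                                 voxel_ids=voxel_ids)
    sub = layer2.predict_scores(X[mask])
    if calibrator is not None:
        sub = calibrator.transform(sub)
    sc = sport_score(sub)
    # argmax with ties broken by class order
    predicted = max(sub.classes, key=lambda c: (sc[c], -sub.classes.index(c)))
    return PatientPrediction(tumor_mask=mask, sport_scores=sc,
                             predicted=predicted, region_scores=region,
                             subtype_scores=sub, voxel_ids=voxel_ids)


class TwoLayerSubtypeClassifier(BaseEstimator):
    """Trains both layers plus the score calibrator from voxel-level labels.

    ``fit`` takes the feature matrix, per-voxel region labels (voxels with
    labels outside the region class vocabulary are ignored), and per-voxel
    subtype labels (empty string/None for voxels without a subtype).  The
    calibrator is fitted on the layer-2 training scores.
    """

    def __init__(self, tumor_class: str = "TUMOR", tumor_threshold: float = 0.5,
                 lam: float = 1e-4):
        self.tumor_class = tumor_class
        self.tumor_threshold = tumor_threshold
        self.lam = lam

    def fit(self, X, region_labels, subtype_labels):
        X = np.asarray(X, dtype=float)
        region_labels = np.asarray(region_labels, dtype=object)
        subtype_labels = np.asarray(subtype_labels, dtype=object)
        rmask = np.array([bool(l) for l in region_labels])
        self.layer1_ = FisherLDA(lam=self.lam).fit(
            X[rmask], region_labels[rmask].astype(str))
        smask = np.array([bool(s) for s in subtype_labels])
        self.layer2_ = FisherLDA(lam=self.lam).fit(
            X[smask], subtype_labels[smask].astype(str))
        train_scores = self.layer2_.predict_scores(X[smask])
        self.calibrator_ = ScoreCalibrator().fit(train_scores)
        return self

    def predict_patient(self, X, voxel_ids=None) -> PatientPrediction:
        return two_layer_predict(
            self.layer1_, self.layer2_, X, calibrator=self.calibrator_,
            tumor_class=self.tumor_class,
            tumor_threshold=self.tumor_threshold, voxel_ids=voxel_ids)


# ---------------------------------------------------------------------------
# evaluation and rendering


def roc_auc(scores, labels) -> float:
    """Rank-based (Mann-Whitney) AUC with midrank tie handling."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n_pos = int(labels.sum())
    n_neg = int(len(labels) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("both label values must be present")
    ranks = stats.rankdata(scores)  # midranks
    return float((ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0)
                 / (n_pos * n_neg))


def roc_auc_ovr(score_matrix: np.ndarray, labels: np.ndarray,
                classes: tuple[str, ...]) -> dict[str, float]:
    """One-vs-rest AUC per class from a samples x classes score matrix."""
    labels = np.asarray(labels)
    out = {}
    for i, c in enumerate(classes):
        y = labels == c
        if y.all() or not y.any():
            continue
        out[c] = roc_auc(score_matrix[:, i], y)
    return out


def render_score_map(scores_per_voxel: np.ndarray, rows: np.ndarray,
                     cols: np.ndarray, grid_rows: int, grid_cols: int) -> np.ndarray:
    """Scatter per-voxel scores onto the acquisition grid (NaN where absent)."""
    grid = np.full((grid_rows, grid_cols), np.nan)
    grid[np.asarray(rows, dtype=int), np.asarray(cols, dtype=int)] = scores_per_voxel
    return grid


def render_score_image(grid: np.ndarray, path=None, cmap: str = "plasma"):
    """Optional rasterized rendering of a score grid (plasma colormap)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    im = ax.imshow(grid, cmap=cmap, origin="upper")
    fig.colorbar(im, ax=ax, shrink=0.8)
    ax.set_xticks([])
    ax.set_yticks([])
    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
        return None
    return fig
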