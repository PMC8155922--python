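"""Spectrum preprocessing and metabolite-table normalization.

Covers the steps between raw voxel spectra and the matrix fed to the
autoencoder: polynomial baseline correction, linear basis-set quantitation
(non-negative least squares against Lorentzian/Gaussian templates — a
deliberately simple stand-in for full time-domain fitting), residual-based
quality filtering, per-metabolite min-max scaling, and mean/variance
summary spectra.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import nnls
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .core_data import Spectrum, ValidationError
from .synthetic import BasisSet, basis_matrix

__all__ = [
    "NormalizedMatrix",
    "FitResult",
    "MeanSpectrum",
    "MinMaxNormalizer",
    "baseline_correct",
    "fit_basis_amplitudes",
    "quality_filter",
    "minmax_normalize",
    "mean_spectrum",
]


@dataclass
class FitResult:
    """Basis-fit output for one voxel: amplitudes plus residual RMS."""

    amplitudes: np.ndarray
    residual_rms: float

    def __post_init__(self) -> None:
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if not np.isfinite(self.residual_rms):
            raise ValidationError("residual_rms must be finite")


@dataclass
class MeanSpectrum:
    ppm: np.ndarray
    mean: np.ndarray
    variance: np.ndarray


@dataclass
class NormalizedMatrix:
    """Voxels x metabolites matrix scaled to [0, 1] per column.

    ``col_min``/``col_max`` store the transform so it can be inverted or
    reapplied to held-out data; ``constant_cols`` flags columns that carried
    no information (mapped to all-zeros).
    """

    values: np.ndarray
    col_min: np.ndarray
    col_max: np.ndarray
    constant_cols: np.ndarray


class MinMaxNormalizer(TransformerMixin, BaseEstimator):
    """Per-metabolite min-max scaling to [0, 1].

    norm(x) = (x - min(x)) / (max(x) - min(x)) per column; constant columns
    map to zero (an absent metabolite stays at the low end of the sigmoid
    range).  Statistics are learned on the training matrix only, so held-out
    data are scaled with the same parameters (values may then fall slightly
    outside [0, 1] and are clipped).
    """

    def __init__(self, clip: bool = True):
        self.clip = clip

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or not np.all(np.isfinite(X)):
            raise ValidationError("input matrix must be 2-D and finite")
        self.data_min_ = X.min(axis=0)
        self.data_max_ = X.max(axis=0)
        self.constant_cols_ = self.data_max_ == self.data_min_
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self)
        X = np.asarray(X, dtype=float)
        rng = np.where(self.constant_cols_, 1.0, self.data_max_ - self.data_min_)
        out = (X - self.data_min_) / rng
        out[:, self.constant_cols_] = 0.0
        if self.clip:
            out = np.clip(out, 0.0, 1.0)
        return out

    def inverse_transform(self, X):
        check_is_fitted(self)
        X = np.asarray(X, dtype=float)
        rng = np.where(self.constant_cols_, 0.0, self.data_max_ - self.data_min_)
        return X * rng + self.data_min_


def minmax_normalize(matrix: np.ndarray) -> NormalizedMatrix:
    """Fit-and-transform convenience wrapper around :class:`MinMaxNormalizer`."""
    norm = MinMaxNormalizer().fit(matrix)
    return NormalizedMatrix(
        values=norm.transform(matrix),
        col_min=norm.data_min_,
        col_max=norm.data_max_,
        constant_cols=norm.constant_cols_,
    )


def baseline_correct(spectrum: Spectrum, order: int = 2,
                     n_iter: int = 10, asym_weight: float = 0.01) -> Spectrum:
    """Subtract an iteratively-reweighted polynomial baseline.

    An asymmetric weighting scheme (weight 1 below the current fit,
    ``asym_weight`` above) pulls the polynomial under the peaks, so positive
    resonances do not drag the baseline up.  Robust for smooth baselines of
    low order; peaks are assumed positive.
    """
    if order < 0:
        raise ValidationError("order must be >= 0")
    y = spectrum.intensity
    x = spectrum.ppm
    if len(y) < order + 2:
        raise ValidationError("too few points for requested baseline order")
    # scale x to [-1, 1] for numerical conditioning
    xs = (x - x.min()) / max(x.max() - x.min(), 1e-300) * 2.0 - 1.0
    w = np.ones_like(y)
    base = np.zeros_like(y)
    for _ in range(n_iter):
        coeffs = np.polynomial.polynomial.polyfit(xs, y, order, w=np.sqrt(w))
        base = np.polynomial.polynomial.polyval(xs, coeffs)
        w = np.where(y > base, asym_weight, 1.0)
    return Spectrum(ppm=x, intensity=y - base)


def fit_basis_amplitudes(spectrum: Spectrum, basis: BasisSet,
                         metabolite_names: tuple[str, ...] | None = None) -> FitResult:
    """Non-negative linear least-squares quantitation against a basis set.

    Solves min_a ||intensity - B a||^2 s.t. a >= 0, where B's columns are
    unit-amplitude metabolite templates evaluated on the spectrum's ppm axis.
    """
    B = basis_matrix(basis, spectrum.ppm, metabolite_names)
    if np.linalg.matrix_rank(B) < B.shape[1]:
        warnings.warn("basis template matrix is rank-deficient; "
                      "amplitudes are a least-norm solution", stacklevel=2)
    a, rnorm = nnls(B, spectrum.intensity)
    return FitResult(amplitudes=a, residual_rms=float(rnorm / np.sqrt(len(spectrum))))


def quality_filter(fits: list[FitResult], threshold: float = 3.0) -> np.ndarray:
    """Relative residual-based voxel exclusion.

    A voxel passes iff its fit residual RMS is at most ``threshold`` times
    the study median; failing voxels are relabeled EXCLUDED downstream.  The
    rule is scale-invariant by construction.  Raises if nothing passes.
    """
    if threshold <= 0:
        raise ValidationError("threshold must be > 0")
    res = np.array([f.residual_rms for f in fits], dtype=float)
    if len(res) == 0:
        raise ValidationError("no fits supplied")
    mask = res <= threshold * np.median(res)
    if not mask.any():
        raise ValidationError("all voxels fail the quality filter; study unusable")
    return mask


def mean_spectrum(spectra: list[Spectrum]) -> MeanSpectrum:
    """Pointwise mean and population variance over spectra on one ppm axis."""
    if not spectra:
        raise ValidationError("no spectra supplied")
    ppm = spectra[0].ppm
    for sp in spectra[1:]:
        if len(sp.ppm) != len(ppm) or not np.allclose(sp.ppm, ppm, rtol=0, atol=1e-12):
            raise ValidationError("all spectra must share one ppm axis")
    Y = np.stack([sp.intensity for sp in spectra])
    return MeanSpectrum(ppm=ppm, mean=Y.mean(axis=0), variance=Y.var(axis=0))
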