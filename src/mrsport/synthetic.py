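"""Synthetic chemical-shift-imaging phantoms with known ground truth.

Real in-vivo CSI cohorts of this kind are not publicly deposited, so every
downstream stage (denoising, clustering, the two-layer classifier) is
exercised on phantoms: a 16x16 grid (256 voxels, the typical 2D-CSI
acquisition), simple tissue geometry covering the segmentation vocabulary
(normal-appearing matter background, ventricle, tumor core with optional
necrosis, FLAIR rim), and tissue-specific metabolite signatures.

The default signatures encode the qualitative in-vivo picture: high
NAA/creatine in normal matter, lactate/lipid/macromolecule elevation in
IDH-wildtype (glioblastoma-like) tumor and necrosis,
glycerophosphocholine enrichment in IDH-mutant tumor, and myo-inositol in
edema.  Voxel-to-voxel variation is log-normal (intensities are positive
and right-skewed); spectra are sums of Lorentzian/Gaussian basis peaks plus
a polynomial baseline and white noise.  No attempt is made at physical MR
signal modelling (J-coupling, relaxation, shim artifacts).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .core_data import (
    DEFAULT_METABOLITES,
    MetaboliteTable,
    SegmentLabel,
    Spectrum,
    Study,
    ValidationError,
)

__all__ = [
    "BasisSet",
    "PhantomConfig",
    "default_basis",
    "basis_matrix",
    "simulate_spectrum",
    "generate_phantom",
    "generate_cohort",
    "default_tissue_profiles",
]


# ---------------------------------------------------------------------------
# basis set


@dataclass
class BasisSet:
    """Per-metabolite peak triplets (center ppm, linewidth ppm, rel. amplitude)."""

    peaks: dict[str, list[tuple[float, float, float]]]
    lineshape: str = "lorentzian"

    def __post_init__(self) -> None:
        if self.lineshape not in ("lorentzian", "gaussian"):
            raise ValidationError(f"unknown lineshape {self.lineshape!r}")
        for met, triplets in self.peaks.items():
            for c, w, a in triplets:
                if w <= 0:
                    raise ValidationError(f"{met}: linewidth must be > 0")
                if a < 0:
                    raise ValidationError(f"{met}: amplitude must be >= 0")

    @property
    def metabolites(self) -> tuple[str, ...]:
        return tuple(self.peaks)


# Peak positions follow standard short-TE 3T in-vivo assignments.  Nearly
# degenerate species (Cr/PCr, Lac vs. lipid-1.3) are separated through their
# secondary peaks and linewidths so the linear fit is identifiable.
_DEFAULT_PEAKS: dict[str, list[tuple[float, float, float]]] = {
    "NAA": [(2.01, 0.030, 1.0), (2.60, 0.035, 0.25)],
    "NAAG": [(2.04, 0.030, 0.6), (2.72, 0.035, 0.3), (3.78, 0.035, 0.2)],
    "Cr": [(3.03, 0.030, 1.0), (3.91, 0.030, 0.7)],
    "PCr": [(3.03, 0.030, 0.95), (3.93, 0.030, 0.75), (2.50, 0.050, 0.05)],
    "GPC": [(3.21, 0.028, 1.0), (3.66, 0.035, 0.2), (4.31, 0.040, 0.15)],
    "PCh": [(3.22, 0.028, 1.0), (3.59, 0.035, 0.2), (4.16, 0.040, 0.15)],
    "Ins": [(3.56, 0.035, 1.0), (4.06, 0.035, 0.35), (3.27, 0.030, 0.2)],
    "Lac": [(1.31, 0.030, 1.0), (4.10, 0.035, 0.3)],
    "Ala": [(1.47, 0.030, 1.0), (3.77, 0.035, 0.3)],
    "Asp": [(2.65, 0.040, 0.8), (2.80, 0.040, 0.8), (3.89, 0.035, 0.3)],
    "GABA": [(1.89, 0.045, 0.7), (2.28, 0.045, 0.7), (3.01, 0.045, 0.6)],
    "Glc": [(3.43, 0.045, 0.8), (3.80, 0.045, 0.6), (5.22, 0.040, 0.2)],
    "Gln": [(2.12, 0.040, 0.7), (2.44, 0.040, 0.8), (3.75, 0.035, 0.5)],
    "Glu": [(2.08, 0.040, 0.7), (2.34, 0.040, 0.9), (3.74, 0.035, 0.5)],
    "Gly": [(3.55, 0.025, 1.0)],
    "GSH": [(2.15, 0.045, 0.5), (2.95, 0.040, 0.6), (3.77, 0.040, 0.3)],
    "Lip09": [(0.89, 0.090, 1.0)],
    "Lip13a": [(1.26, 0.080, 1.0)],
    "Lip13b": [(1.33, 0.120, 1.0)],
    "Lip20": [(2.02, 0.090, 1.0), (2.24, 0.090, 0.3)],
    "MM09": [(0.93, 0.120, 1.0)],
    "MM12": [(1.21, 0.110, 1.0)],
    "MM14": [(1.43, 0.110, 1.0)],
    "MM17": [(1.67, 0.110, 1.0)],
    "MM20": [(2.06, 0.120, 1.0), (2.26, 0.110, 0.4)],
    "PE": [(3.22, 0.040, 0.5), (3.98, 0.035, 1.0)],
    "Scyllo": [(3.35, 0.022, 1.0)],
    "Tau": [(3.25, 0.035, 0.8), (3.42, 0.035, 0.8)],
    "Cit": [(2.57, 0.035, 1.0), (2.67, 0.035, 0.6)],
    "Cys": [(2.98, 0.040, 0.8), (3.98, 0.045, 0.3)],
    "EtOH": [(1.18, 0.030, 1.0), (3.65, 0.030, 0.4)],
    "Ser": [(3.83, 0.030, 0.8), (3.96, 0.030, 0.8)],
    "Thr": [(1.32, 0.028, 0.6), (3.58, 0.030, 0.7), (4.25, 0.035, 0.4)],
    "Val": [(0.98, 0.028, 0.8), (1.03, 0.028, 0.8), (3.60, 0.035, 0.2)],
}


def default_basis(metabolite_names: tuple[str, ...] = DEFAULT_METABOLITES) -> BasisSet:
    """Lorentzian basis covering the default 34-metabolite list."""
    missing = [m for m in metabolite_names if m not in _DEFAULT_PEAKS]
    if missing:
        raise ValidationError(f"no default peaks for metabolites {missing}")
    return BasisSet(peaks={m: list(_DEFAULT_PEAKS[m]) for m in metabolite_names})


def default_ppm_axis(n_points: int = 512, lo: float = 0.2, hi: float = 4.2) -> np.ndarray:
    return np.linspace(lo, hi, n_points)


def _lineshape(ppm: np.ndarray, center: float, width: float, kind: str) -> np.ndarray:
    # unit-height peaks; width is FWHM in ppm
    if kind == "lorentzian":
        g = width / 2.0
        return g * g / ((ppm - center) ** 2 + g * g)
    s = width / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    return np.exp(-0.5 * ((ppm - center) / s) ** 2)


def basis_matrix(basis: BasisSet, ppm_axis: np.ndarray,
                 metabolite_names: tuple[str, ...] | None = None) -> np.ndarray:
    """Template matrix B (n_points x n_metabolites), unit-amplitude columns."""
    ppm_axis = np.asarray(ppm_axis, dtype=float)
    names = tuple(metabolite_names) if metabolite_names else basis.metabolites
    B = np.zeros((len(ppm_axis), len(names)))
    for j, m in enumerate(names):
        for c, w, a in basis.peaks[m]:
            B[:, j] += a * _lineshape(ppm_axis, c, w, basis.lineshape)
    return B


def simulate_spectrum(profile: np.ndarray, basis: BasisSet, ppm_axis: np.ndarray,
                      noise_sd: float = 0.0,
                      baseline_coeffs: np.ndarray | None = None,
                      seed: int | np.random.Generator = 0) -> Spectrum:
    """Synthesize one voxel spectrum from metabolite amplitudes.

    intensity = B @ profile + polynomial(baseline_coeffs) + N(0, noise_sd^2),
    deterministic given ``seed``.
    """
    if noise_sd < 0:
        raise ValidationError("noise_sd must be >= 0")
    profile = np.asarray(profile, dtype=float)
    if np.any(profile < 0):
        raise ValidationError("profile amplitudes must be non-negative")
    ppm_axis = np.asarray(ppm_axis, dtype=float)
    B = basis_matrix(basis, ppm_axis)
    if B.shape[1] != profile.shape[0]:
        raise ValidationError("profile length does not match basis")
    y = B @ profile
    if baseline_coeffs is not None and len(baseline_coeffs):
        y = y + np.polynomial.polynomial.polyval(ppm_axis, np.asarray(baseline_coeffs))
    if noise_sd > 0:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sd, size=len(ppm_axis))
    return Spectrum(ppm=ppm_axis, intensity=y)


# ---------------------------------------------------------------------------
# tissue profiles


def _profile(names: tuple[str, ...], base: float, **overrides: float) -> np.ndarray:
    p = np.full(len(names), base)
    idx = {m: i for i, m in enumerate(names)}
    for m, v in overrides.items():
        p[idx[m]] = v
    return p


def default_tissue_profiles(
    subtype: str = "none",
    metabolite_names: tuple[str, ...] = DEFAULT_METABOLITES,
) -> dict[SegmentLabel, np.ndarray]:
    """Mean 34-metabolite vectors per tissue class for one phantom.

    Normal matter carries the NAA/Cr-dominated profile; tumor voxels get a
    subtype-specific signature: lactate + lipids + macromolecules up in
    IDH-wildtype, GPC up in both IDH-mutant groups (the 1p/19q-codeleted
    group additionally shifts Gly/Cit/NAAG so the two mutant groups remain
    identifiable in the phantom), myo-inositol up in the FLAIR/edema rim.
    """
    N = metabolite_names
    nam = _profile(N, 0.5, NAA=10.0, NAAG=1.5, Cr=8.0, PCr=4.0, GPC=1.2,
                   PCh=1.0, Ins=4.0, Glu=8.0, Gln=3.0, Lac=0.5, Asp=2.0,
                   GABA=1.5, Tau=1.5, Gly=1.0,
                   Lip09=0.3, Lip13a=0.3, Lip13b=0.3, Lip20=0.3,
                   MM09=0.8, MM12=0.8, MM14=0.8, MM17=0.8, MM20=0.8)
    tumor = _profile(N, 0.5, NAA=3.0, Cr=5.0, PCr=2.5, GPC=3.0, PCh=2.0,
                     Ins=5.0, Glu=4.0, Gln=4.0, Lac=3.0, Gly=1.5,
                     Lip09=1.0, Lip13a=1.0, Lip13b=1.0, Lip20=1.0,
                     MM09=1.5, MM12=1.5, MM14=1.5, MM17=1.5, MM20=1.5)
    idx = {m: i for i, m in enumerate(N)}

    def bump(vec: np.ndarray, **kw: float) -> np.ndarray:
        v = vec.copy()
        for m, x in kw.items():
            v[idx[m]] = x
        return v

    if subtype == "wt":
        tumor = bump(tumor, Lac=8.0, Lip09=4.0, Lip13a=4.0, Lip13b=4.0,
                     Lip20=3.0, MM09=3.0, MM12=3.0, MM14=3.0, MM17=3.0,
                     MM20=3.0, GPC=3.5, NAA=2.0)
    elif subtype == "IDH":
        tumor = bump(tumor, GPC=6.0, PCh=3.0, Lac=2.5, NAA=3.5, Ins=6.0)
    elif subtype == "LOH":
        tumor = bump(tumor, GPC=6.5, PCh=3.0, Lac=2.5, NAA=3.5,
                     Gly=3.5, Cit=2.0, NAAG=3.0, Ins=4.0)
    elif subtype != "none":
        raise ValidationError(f"unknown subtype {subtype!r}")

    contrast = bump(tumor, Lac=min(tumor[idx["Lac"]] * 1.4, 10.0),
                    GPC=tumor[idx["GPC"]] * 1.2)
    necrosis = _profile(N, 0.4, NAA=1.0, Cr=1.0, PCr=0.5, GPC=1.5, Lac=10.0,
                        Lip09=6.0, Lip13a=6.0, Lip13b=6.0, Lip20=4.0,
                        MM09=5.0, MM12=5.0, MM14=5.0, MM17=4.0, MM20=4.0)
    flair = _profile(N, 0.5, NAA=6.0, Cr=6.0, PCr=3.0, GPC=1.8, PCh=1.2,
                     Ins=7.0, Glu=5.0, Gln=3.5, Lac=1.5,
                     MM09=1.0, MM12=1.0, MM14=1.0, MM17=1.0, MM20=1.0)
    lesion = _profile(N, 0.5, NAA=5.0, Cr=6.0, PCr=3.0, GPC=2.2, PCh=1.5,
                      Ins=5.0, Glu=5.0, Gln=3.0, Lac=2.0, Asp=3.0,
                      MM09=1.2, MM12=1.2, MM14=1.2, MM17=1.2, MM20=1.2)
    ventricle = np.full(len(N), 0.2)
    return {
        SegmentLabel.NAM: nam,
        SegmentLabel.TUMOR: tumor,
        SegmentLabel.CONTRAST: contrast,
        SegmentLabel.NECROSIS: necrosis,
        SegmentLabel.FLAIR: flair,
        SegmentLabel.LESION: lesion,
        SegmentLabel.VENTRICLE: ventricle,
    }


# ---------------------------------------------------------------------------
# geometry


@dataclass
class Shape:
    """Painted region in grid coordinates: 'disc' | 'annulus' | 'rect' | 'all'."""

    kind: str
    params: tuple[float, ...] = ()

    def contains(self, r: np.ndarray, c: np.ndarray) -> np.ndarray:
        if self.kind == "all":
            return np.ones_like(r, dtype=bool)
        if self.kind == "rect":
            r0, r1, c0, c1 = self.params
            return (r >= r0) & (r <= r1) & (c >= c0) & (c <= c1)
        if self.kind == "disc":
            cr, cc, rad = self.params
            return (r - cr) ** 2 + (c - cc) ** 2 <= rad**2
        if self.kind == "annulus":
            cr, cc, r_in, r_out = self.params
            d2 = (r - cr) ** 2 + (c - cc) ** 2
            return (d2 > r_in**2) & (d2 <= r_out**2)
        raise ValidationError(f"unknown shape kind {self.kind!r}")


def default_geometry(subtype: str, center: tuple[float, float] = (10.0, 10.0),
                     radius: float = 3.0) -> list[tuple[SegmentLabel, Shape]]:
    """Painter's-order region list: later entries overwrite earlier ones."""
    geom: list[tuple[SegmentLabel, Shape]] = [
        (SegmentLabel.NAM, Shape("all")),
        (SegmentLabel.VENTRICLE, Shape("rect", (0, 2, 6, 9))),
    ]
    cr, cc = center
    if subtype == "none":
        return geom
    geom.append((SegmentLabel.FLAIR, Shape("annulus", (cr, cc, radius, radius + 2.0))))
    geom.append((SegmentLabel.TUMOR, Shape("disc", (cr, cc, radius))))
    if subtype == "wt":
        geom.append((SegmentLabel.NECROSIS, Shape("disc", (cr, cc, 1.0))))
    return geom


@dataclass
class PhantomConfig:
    """Everything needed to synthesize one study deterministically."""

    grid_rows: int = 16
    grid_cols: int = 16
    ppm_points: int = 512
    ppm_range: tuple[float, float] = (0.2, 4.2)
    subtype: str = "none"  # wt | IDH | LOH | none
    tissue_geometry: list[tuple[SegmentLabel, Shape]] | None = None
    tissue_profiles: dict[SegmentLabel, np.ndarray] | None = None
    cv: float = 0.2  # log-normal voxel-to-voxel coefficient of variation
    table_noise_sd: float = 0.3  # additive quantitation noise on the table
    noise_sd: float = 0.05  # spectral white-noise std
    baseline_order: int = 2
    baseline_scale: float = 0.5
    with_spectra: bool = True
    metabolite_names: tuple[str, ...] = DEFAULT_METABOLITES
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0 or self.table_noise_sd < 0 or self.cv < 0:
            raise ValidationError("noise/cv parameters must be >= 0")
        if self.subtype not in ("wt", "IDH", "LOH", "none"):
            raise ValidationError(f"unknown subtype {self.subtype!r}")


def generate_phantom(config: PhantomConfig) -> tuple[Study, dict[str, tuple[SegmentLabel, np.ndarray]]]:
    """Synthesize one study plus per-voxel ground truth.

    Returns ``(study, truth)`` where ``truth[voxel_id] = (label, true
    34-vector)`` is the noise-free per-voxel metabolite profile actually used
    to build the spectrum.  Metabolite values vary log-normally around the
    tissue mean with the configured CV; the stored table additionally carries
    additive quantitation noise (clipped at zero).
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    geometry = cfg.tissue_geometry or default_geometry(cfg.subtype)
    profiles = cfg.tissue_profiles or default_tissue_profiles(
        cfg.subtype, cfg.metabolite_names)

    rr, cc = np.meshgrid(np.arange(cfg.grid_rows), np.arange(cfg.grid_cols),
                         indexing="ij")
    rr, cc = rr.ravel(), cc.ravel()
    labels = np.empty(len(rr), dtype=object)
    for lab, shape in geometry:
        m = shape.contains(rr, cc)
        labels[m] = lab
    if any(l is None for l in labels):
        raise ValidationError("tissue geometry does not cover the grid")

    M = len(cfg.metabolite_names)
    voxel_ids = [f"v{r:02d}_{c:02d}" for r, c in zip(rr, cc)]
    true_vals = np.empty((len(rr), M))
    for i, lab in enumerate(labels):
        mean = profiles[lab]
        if cfg.cv > 0:
            sigma = np.sqrt(np.log(1.0 + cfg.cv**2))
            mu = np.log(np.maximum(mean, 1e-12)) - sigma**2 / 2.0
            true_vals[i] = np.exp(rng.normal(mu, sigma))
        else:
            true_vals[i] = mean

    table_vals = true_vals.copy()
    if cfg.table_noise_sd > 0:
        table_vals = np.clip(
            table_vals + rng.normal(0.0, cfg.table_noise_sd, size=table_vals.shape),
            0.0, None)

    spectra = None
    if cfg.with_spectra:
        ppm = np.linspace(*cfg.ppm_range, cfg.ppm_points)
        basis = default_basis(cfg.metabolite_names)
        spectra = {}
        for i, vid in enumerate(voxel_ids):
            bl = (rng.normal(0.0, cfg.baseline_scale, size=cfg.baseline_order + 1)
                  if cfg.baseline_order >= 0 and cfg.baseline_scale > 0 else None)
            spectra[vid] = simulate_spectrum(
                true_vals[i], basis, ppm, noise_sd=cfg.noise_sd,
                baseline_coeffs=bl, seed=rng)

    table = MetaboliteTable(voxel_ids=voxel_ids, row=rr, col=cc,
                            values=table_vals,
                            metabolite_names=cfg.metabolite_names)
    segmentation = {vid: lab for vid, lab in zip(voxel_ids, labels)}
    study = Study(grid_rows=cfg.grid_rows, grid_cols=cfg.grid_cols,
                  metabolites=table, segmentation=segmentation,
                  spectra=spectra,
                  patient_meta={"subtype": cfg.subtype, "seed": cfg.seed})
    truth = {vid: (lab, true_vals[i]) for i, (vid, lab) in
             enumerate(zip(voxel_ids, labels))}
    return study, truth


def generate_cohort(base_config: PhantomConfig,
                    n_per_subtype: dict[str, int],
                    seed: int = 0) -> list[tuple[Study, str]]:
    """Multi-patient cohort with per-patient jittered lesion geometry.

    Tumor center and radius are varied deterministically from ``seed``;
    each study's ``patient_meta`` carries ``patient_id`` and ``subtype``.
    """
    bad = set(n_per_subtype) - {"wt", "IDH", "LOH", "none"}
    if bad:
        raise ValidationError(f"unknown subtypes {sorted(bad)}")
    if not n_per_subtype or sum(n_per_subtype.values()) == 0:
        raise ValidationError("empty cohort request")
    rng = np.random.default_rng(seed)
    out: list[tuple[Study, str]] = []
    pid = 0
    for subtype in ("wt", "IDH", "LOH", "none"):
        for _ in range(n_per_subtype.get(subtype, 0)):
            center = (float(rng.uniform(8, 12)), float(rng.uniform(8, 12)))
            radius = float(rng.uniform(2.2, 4.0))
            child_seed = int(rng.integers(0, 2**31 - 1))
            cfg = replace(
                base_config, subtype=subtype, seed=child_seed,
                tissue_geometry=default_geometry(subtype, center, radius),
                tissue_profiles=default_tissue_profiles(
                    subtype, base_config.metabolite_names),
            )
            study, _ = generate_phantom(cfg)
            study.patient_meta["patient_id"] = f"p{pid:03d}"
            study.patient_meta["subtype"] = subtype
            out.append((study, subtype))
            pid += 1
    return out
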