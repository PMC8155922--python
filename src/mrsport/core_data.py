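"""Domain types and on-disk formats for chemical-shift-imaging studies.

A *study* is one MRS imaging session: a rectangular voxel grid, per-voxel
metabolite intensity fits (34 metabolites by default), an optional raw
spectrum per voxel, and a per-voxel tissue segmentation label.

On-disk layout (one directory per study, all plain text):

* ``metabolites.tsv``  — ``voxel_id  row  col  <metabolite names...>``
* ``segmentation.tsv`` — ``voxel_id  row  col  label``
* ``spectra.tsv``      — optional long format ``voxel_id  ppm  intensity``
* ``meta.json``        — free-form; ``patient_id`` and ``subtype`` recognized
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_METABOLITES",
    "SegmentLabel",
    "Spectrum",
    "MetaboliteTable",
    "Study",
    "ClassSet",
    "REGION_CLASSES",
    "SUBTYPE_CLASSES",
    "load_study",
    "save_study",
    "validate_study",
]

#: Standard short-TE in-vivo basis; only the length (34) is normative.
DEFAULT_METABOLITES: tuple[str, ...] = (
    "NAA", "NAAG", "Cr", "PCr", "GPC", "PCh", "Ins", "Lac", "Ala", "Asp",
    "GABA", "Glc", "Gln", "Glu", "Gly", "GSH", "Lip09", "Lip13a", "Lip13b",
    "Lip20", "MM09", "MM12", "MM14", "MM17", "MM20", "PE", "Scyllo", "Tau",
    "Cit", "Cys", "EtOH", "Ser", "Thr", "Val",
)

REGION_CLASSES: tuple[str, ...] = ("NAM", "LESION", "TUMOR", "METASTASIS")
SUBTYPE_CLASSES: tuple[str, ...] = ("wt", "IDH", "LOH")


class SegmentLabel(str, enum.Enum):
    """Tissue class assigned to a voxel during semi-automated segmentation.

    ``EXCLUDED`` marks voxels that failed residual-based quality control or
    could not be assigned unambiguously.
    """

    NAM = "NAM"
    LESION = "LESION"
    TUMOR = "TUMOR"
    CONTRAST = "CONTRAST"
    NECROSIS = "NECROSIS"
    FLAIR = "FLAIR"
    VENTRICLE = "VENTRICLE"
    EXCLUDED = "EXCLUDED"


class FormatError(ValueError):
    """Raised when an on-disk file does not match the expected layout."""


class ValidationError(ValueError):
    """Raised when a domain object violates its invariants."""


@dataclass
class Spectrum:
    """One voxel's chemical-shift trace: ppm axis plus intensities."""

    ppm: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.ppm.shape != self.intensity.shape or self.ppm.ndim != 1:
            raise ValidationError("ppm and intensity must be 1-D and equal length")
        d = np.diff(self.ppm)
        if len(d) and not (np.all(d > 0) or np.all(d < 0)):
            raise ValidationError("ppm axis must be strictly monotone")
        if not np.all(np.isfinite(self.intensity)):
            raise ValidationError("intensities must be finite")

    def __len__(self) -> int:
        return len(self.ppm)


@dataclass
class MetaboliteTable:
    """Per-voxel fitted metabolite intensities with grid coordinates."""

    voxel_ids: list[str]
    row: np.ndarray
    col: np.ndarray
    values: np.ndarray
    metabolite_names: tuple[str, ...] = DEFAULT_METABOLITES

    def __post_init__(self) -> None:
        self.row = np.asarray(self.row, dtype=int)
        self.col = np.asarray(self.col, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        self.metabolite_names = tuple(self.metabolite_names)
        n = len(self.voxel_ids)
        if not (len(self.row) == len(self.col) == self.values.shape[0] == n):
            raise ValidationError("voxel_ids, row, col, values row counts differ")
        if self.values.ndim != 2 or self.values.shape[1] != len(self.metabolite_names):
            raise FormatError(
                f"expected {len(self.metabolite_names)} metabolite columns, "
                f"got values of shape {self.values.shape}"
            )

    @property
    def n_voxels(self) -> int:
        return len(self.voxel_ids)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.metabolite_names))
        df.insert(0, "col", self.col)
        df.insert(0, "row", self.row)
        df.insert(0, "voxel_id", self.voxel_ids)
        return df


@dataclass
class Study:
    """Grid geometry, metabolite fits, segmentation and optional spectra."""

    grid_rows: int
    grid_cols: int
    metabolites: MetaboliteTable
    segmentation: dict[str, SegmentLabel]
    spectra: dict[str, Spectrum] | None = None
    patient_meta: dict = field(default_factory=dict)

    @property
    def n_voxels(self) -> int:
        return self.metabolites.n_voxels

    def labels_array(self) -> np.ndarray:
        """Segmentation labels aligned to the metabolite table row order."""
        return np.array(
            [self.segmentation[v].value for v in self.metabolites.voxel_ids]
        )


@dataclass
class ClassSet:
    """Ordered class names for one layer of the prediction model.

    REGION level defaults to (NAM, LESION, TUMOR, METASTASIS); SUBTYPE level
    is exactly (wt, IDH, LOH).
    """

    classes: tuple[str, ...]
    level: str  # "REGION" or "SUBTYPE"

    def __post_init__(self) -> None:
        self.classes = tuple(self.classes)
        if self.level not in ("REGION", "SUBTYPE"):
            raise ValidationError(f"unknown class-set level {self.level!r}")
        if self.level == "SUBTYPE" and self.classes != SUBTYPE_CLASSES:
            raise ValidationError("SUBTYPE class set must be exactly (wt, IDH, LOH)")

    @classmethod
    def region(cls, classes: tuple[str, ...] = REGION_CLASSES) -> "ClassSet":
        return cls(classes=classes, level="REGION")

    @classmethod
    def subtype(cls) -> "ClassSet":
        return cls(classes=SUBTYPE_CLASSES, level="SUBTYPE")


# ---------------------------------------------------------------------------
# validation


def validate_study(study: Study) -> list[str]:
    """Check every invariant; return a list of human-readable violations.

    Never raises: an empty list means the study is valid.  Every downstream
    entry point requires an empty report.
    """
    out: list[str] = []
    mt = study.metabolites
    if len(mt.metabolite_names) != len(set(mt.metabolite_names)):
        out.append("duplicated metabolite names")
    if not np.all(np.isfinite(mt.values)):
        bad = [mt.voxel_ids[i] for i in np.where(~np.isfinite(mt.values).all(axis=1))[0]]
        out.append(f"non-finite metabolite values in voxels {bad[:5]}")
    coords = list(zip(mt.row.tolist(), mt.col.tolist()))
    if len(coords) != len(set(coords)):
        seen: set[tuple[int, int]] = set()
        for vid, rc in zip(mt.voxel_ids, coords):
            if rc in seen:
                out.append(f"duplicated grid coordinate {rc} at voxel {vid}")
            seen.add(rc)
    if len(mt.voxel_ids) != len(set(mt.voxel_ids)):
        out.append("duplicated voxel ids")
    if study.grid_rows * study.grid_cols < mt.n_voxels:
        out.append(
            f"grid {study.grid_rows}x{study.grid_cols} smaller than "
            f"{mt.n_voxels} voxels"
        )
    if len(mt.row) and (mt.row.min() < 0 or mt.col.min() < 0):
        out.append("negative grid coordinates")
    if len(mt.row) and (mt.row.max() >= study.grid_rows or mt.col.max() >= study.grid_cols):
        out.append("grid coordinates outside grid geometry")
    missing = [v for v in mt.voxel_ids if v not in study.segmentation]
    if missing:
        out.append(f"segmentation missing voxels {missing[:10]}")
    if study.spectra is not None:
        for vid, sp in study.spectra.items():
            if not np.all(np.isfinite(sp.intensity)):
                out.append(f"non-finite spectrum for voxel {vid}")
    return out


def require_valid(study: Study) -> None:
    report = validate_study(study)
    if report:
        raise ValidationError("invalid study: " + "; ".join(report))


# ---------------------------------------------------------------------------
# I/O


def save_study(study: Study, path: str | Path) -> None:
    """Write a study directory; ``load_study`` round-trips it losslessly."""
    require_valid(study)
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    mt = study.metabolites
    mt.to_frame().to_csv(path / "metabolites.tsv", sep="\t", index=False,
                         float_format="%.17g")
    seg = pd.DataFrame(
        {
            "voxel_id": mt.voxel_ids,
            "row": mt.row,
            "col": mt.col,
            "label": [study.segmentation[v].value for v in mt.voxel_ids],
        }
    )
    seg.to_csv(path / "segmentation.tsv", sep="\t", index=False)
    meta = dict(study.patient_meta)
    meta["_grid"] = {"rows": study.grid_rows, "cols": study.grid_cols}
    (path / "meta.json").write_text(json.dumps(meta, indent=1, sort_keys=True))
    if study.spectra:
        frames = []
        for vid in mt.voxel_ids:
            sp = study.spectra.get(vid)
            if sp is None:
                continue
            frames.append(pd.DataFrame(
                {"voxel_id": vid, "ppm": sp.ppm, "intensity": sp.intensity}
            ))
        if frames:
            pd.concat(frames, ignore_index=True).to_csv(
                path / "spectra.tsv", sep="\t", index=False, float_format="%.17g"
            )


def load_study(path: str | Path, expect_metabolites: int | None = 34) -> Study:
    """Read a study directory written by :func:`save_study`.

    ``expect_metabolites`` guards against truncated tables (34 columns by
    default); pass ``None`` to accept any width.
    """
    path = Path(path)
    mfile = path / "metabolites.tsv"
    sfile = path / "segmentation.tsv"
    for f in (mfile, sfile):
        if not f.exists():
            raise FileNotFoundError(f"missing required file {f}")
    mdf = pd.read_csv(mfile, sep="\t")
    fixed = ["voxel_id", "row", "col"]
    if mdf.columns[:3].tolist() != fixed:
        raise FormatError("metabolites.tsv must start with voxel_id, row, col")
    names = tuple(mdf.columns[3:])
    if expect_metabolites is not None and len(names) != expect_metabolites:
        raise FormatError(
            f"metabolites.tsv has {len(names)} metabolite columns, "
            f"expected {expect_metabolites}")
    table = MetaboliteTable(
        voxel_ids=[str(v) for v in mdf["voxel_id"]],
        row=mdf["row"].to_numpy(),
        col=mdf["col"].to_numpy(),
        values=mdf[list(names)].to_numpy(dtype=float),
        metabolite_names=names,
    )
    sdf = pd.read_csv(sfile, sep="\t")
    try:
        segmentation = {
            str(v): SegmentLabel(lbl) for v, lbl in zip(sdf["voxel_id"], sdf["label"])
        }
    except ValueError as e:
        raise FormatError(f"unknown segmentation label: {e}") from None

    meta: dict = {}
    grid_rows = grid_cols = None
    mjson = path / "meta.json"
    if mjson.exists():
        meta = json.loads(mjson.read_text())
        grid = meta.pop("_grid", None)
        if grid:
            grid_rows, grid_cols = int(grid["rows"]), int(grid["cols"])
    if grid_rows is None:
        grid_rows = int(table.row.max()) + 1 if table.n_voxels else 0
        grid_cols = int(table.col.max()) + 1 if table.n_voxels else 0

    spectra = None
    spfile = path / "spectra.tsv"
    if spfile.exists():
        spdf = pd.read_csv(spfile, sep="\t")
        spectra = {
            str(vid): Spectrum(g["ppm"].to_numpy(), g["intensity"].to_numpy())
            for vid, g in spdf.groupby("voxel_id", sort=False)
        }

    study = Study(
        grid_rows=grid_rows,
        grid_cols=grid_cols,
        metabolites=table,
        segmentation=segmentation,
        spectra=spectra,
        patient_meta=meta,
    )
    missing = [v for v in table.voxel_ids if v not in segmentation]
    if missing:
        raise ValidationError(f"segmentation missing voxels {missing[:10]}")
    require_valid(study)
    return study


def studies_equal(a: Study, b: Study, tol: float = 1e-12) -> bool:
    """Field-by-field equality with numeric tolerance (round-trip checks)."""
    ma, mb = a.metabolites, b.metabolites
    if ma.voxel_ids != mb.voxel_ids or ma.metabolite_names != mb.metabolite_names:
        return False
    if not (np.array_equal(ma.row, mb.row) and np.array_equal(ma.col, mb.col)):
        return False
    if not np.allclose(ma.values, mb.values, rtol=0, atol=tol):
        return False
    if (a.grid_rows, a.grid_cols) != (b.grid_rows, b.grid_cols):
        return False
    if a.segmentation != b.segmentation:
        return False
    if (a.spectra is None) != (b.spectra is None):
        return False
    if a.spectra is not None:
        if set(a.spectra) != set(b.spectra):
            return False
        for vid in a.spectra:
            sa, sb = a.spectra[vid], b.spectra[vid]
            if not (np.allclose(sa.ppm, sb.ppm, rtol=0, atol=tol)
                    and np.allclose(sa.intensity, sb.intensity, rtol=0, atol=tol)):
                return False
    return True
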