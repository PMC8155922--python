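"""Configuration-driven orchestration of the full workflow.

Two entry points mirror the two arms of the analysis:

* :func:`run_characterize` — simulate/load studies, normalize, denoise,
  select non-trivial principal components, SNN-cluster, embed, and extract
  marker metabolites (the unsupervised characterization arm).
* :func:`run_predict` — patient-level 2/3 train / 1/3 held-out split,
  train the autoencoder and both discriminant layers on training patients'
  voxels only, then evaluate per-patient subtype predictions, voxel-level
  region accuracy and one-vs-rest AUC on held-out patients.

Every run writes a ``manifest.json`` (config hash + seed) and all
artifacts are deterministic functions of (config, seed).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .autoencoder import MetaboliteAutoencoder, bottleneck_search
from .core_data import (
    SegmentLabel,
    Study,
    ValidationError,
    load_study,
    save_study,
)
from .embed_cluster import (
    ParallelAnalysisPCA,
    embed2d,
    marker_metabolites,
    snn_cluster,
)
from .lda import (
    TwoLayerSubtypeClassifier,
    roc_auc,
    render_score_map,
)
from .preprocess import (
    MinMaxNormalizer,
    baseline_correct,
    fit_basis_amplitudes,
    mean_spectrum,
    quality_filter,
)
from .synthetic import (
    PhantomConfig,
    default_basis,
    generate_cohort,
    generate_phantom,
)

logger = logging.getLogger("mrsport")

#: Segmentation label -> layer-1 region class; labels mapping to "" are
#: not used for layer-1 training (but still receive predictions).
SEG_TO_REGION: dict[SegmentLabel, str] = {
    SegmentLabel.NAM: "NAM",
    SegmentLabel.LESION: "LESION",
    SegmentLabel.TUMOR: "TUMOR",
    SegmentLabel.CONTRAST: "TUMOR",
    SegmentLabel.NECROSIS: "TUMOR",
    # ventricle and FLAIR voxels are not a target class of the region model,
    # but layer 1 must see them during training or it will force them into
    # one of the target classes at prediction time (CSF voxels would then
    # contaminate the tumor mask); they train a catch-all OTHER class.
    SegmentLabel.FLAIR: "OTHER",
    SegmentLabel.VENTRICLE: "OTHER",
    SegmentLabel.EXCLUDED: "",
}

TUMOR_LABELS = {SegmentLabel.TUMOR, SegmentLabel.CONTRAST, SegmentLabel.NECROSIS}


@dataclass
class PipelineConfig:
    """Everything a run needs; serializable to/from YAML."""

    seed: int = 0
    input_dirs: list[str] = field(default_factory=list)
    phantom: dict = field(default_factory=dict)  # PhantomConfig overrides
    n_per_subtype: dict = field(default_factory=lambda: {"wt": 10, "IDH": 10, "LOH": 10})
    epochs: int = 500
    encoder_widths: tuple[int, ...] = (32, 16, 8)
    bottleneck: int = 6
    dropout: float = 0.1
    batch_norm: bool = True
    run_bottleneck_search: bool = False
    bottleneck_sizes: tuple[int, ...] = (4, 5, 6, 7, 8, 9, 10)
    k_neighbors: int = 20
    n_randomizations: int = 20
    fixed_n_components: int | None = None  # override the adaptive rule
    quality_threshold: float = 3.0
    train_fraction: float = 2.0 / 3.0
    split_by: str = "patient"  # or "voxel" (for fidelity comparisons)
    tumor_threshold: float = 0.5
    lam: float = 1e-4

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        bad = set(data) - known
        if bad:
            raise ValidationError(f"unknown config keys {sorted(bad)}")
        cfg = cls(**data)
        if cfg.seed is None:
            raise ValidationError("config must set a seed")
        return cfg

    def to_dict(self) -> dict:
        d = asdict(self)
        d["encoder_widths"] = list(self.encoder_widths)
        d["bottleneck_sizes"] = list(self.bottleneck_sizes)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def phantom_config(self, **overrides) -> PhantomConfig:
        kw = dict(self.phantom)
        kw.update(overrides)
        kw.setdefault("seed", self.seed)
        return PhantomConfig(**kw)


def _write_manifest(out: Path, config: PipelineConfig, stage: str) -> None:
    manifest = {
        "stage": stage,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "version": __version__,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))


def _load_or_generate(config: PipelineConfig) -> list[tuple[Study, str]]:
    if config.input_dirs:
        studies = []
        for d in config.input_dirs:
            s = load_study(d)
            studies.append((s, str(s.patient_meta.get("subtype", "none"))))
        return studies
    if not config.n_per_subtype:
        raise ValidationError("no input_dirs and no phantom cohort requested")
    base = config.phantom_config()
    return generate_cohort(base, config.n_per_subtype, seed=config.seed)


def _stack(studies: list[tuple[Study, str]]):
    """Concatenate voxel tables; drop EXCLUDED voxels."""
    frames = []
    for study, subtype in studies:
        mt = study.metabolites
        pid = str(study.patient_meta.get("patient_id", f"p{len(frames)}"))
        labels = [study.segmentation[v] for v in mt.voxel_ids]
        keep = [i for i, l in enumerate(labels) if l != SegmentLabel.EXCLUDED]
        df = pd.DataFrame(mt.values[keep], columns=list(mt.metabolite_names))
        df.insert(0, "segment", [labels[i].value for i in keep])
        df.insert(0, "col", mt.col[keep])
        df.insert(0, "row", mt.row[keep])
        df.insert(0, "voxel_id", [f"{pid}:{mt.voxel_ids[i]}" for i in keep])
        df.insert(0, "subtype", subtype)
        df.insert(0, "patient_id", pid)
        frames.append(df)
    return pd.concat(frames, ignore_index=True), studies[0][0].metabolites.metabolite_names


def apply_quality_filter(studies: list[tuple[Study, str]],
                         threshold: float = 3.0,
                         baseline_order: int = 2) -> pd.DataFrame:
    """Residual-based QC on studies that carry raw spectra.

    Each spectrum is baseline-corrected and re-fitted against the basis;
    voxels whose residual RMS exceeds ``threshold`` x the study median are
    relabeled EXCLUDED in place.  Returns the QC report (one row per
    tested voxel).  Studies without spectra are left untouched.
    """
    rows = []
    for study, _ in studies:
        if not study.spectra:
            continue
        basis = default_basis(study.metabolites.metabolite_names)
        pid = str(study.patient_meta.get("patient_id", ""))
        vids = [v for v in study.metabolites.voxel_ids if v in study.spectra]
        fits = [fit_basis_amplitudes(
            baseline_correct(study.spectra[v], order=baseline_order), basis)
            for v in vids]
        mask = quality_filter(fits, threshold=threshold)
        for v, f, ok in zip(vids, fits, mask):
            rows.append({"patient_id": pid, "voxel_id": v,
                         "residual_rms": f.residual_rms, "pass": bool(ok)})
            if not ok:
                study.segmentation[v] = SegmentLabel.EXCLUDED
    return pd.DataFrame(rows, columns=["patient_id", "voxel_id",
                                       "residual_rms", "pass"])


# ---------------------------------------------------------------------------
# characterization arm


def run_characterize(config: PipelineConfig, out_dir: str | Path) -> dict:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logger.info("characterize: loading/generating studies")
    studies = _load_or_generate(config)
    qc = apply_quality_filter(studies, threshold=config.quality_threshold)
    if len(qc):
        qc.to_csv(out / "qc_report.tsv", sep="\t", index=False,
                  float_format="%.10g")
        logger.info("characterize: %d/%d voxels passed QC",
                    int(qc["pass"].sum()), len(qc))
    table, met_names = _stack(studies)
    X = table[list(met_names)].to_numpy(dtype=float)

    logger.info("characterize: normalizing %d voxels", len(X))
    norm = MinMaxNormalizer().fit(X)
    Xn = norm.transform(X)

    if config.run_bottleneck_search:
        logger.info("characterize: bottleneck search over %s", config.bottleneck_sizes)
        best, bench = bottleneck_search(
            Xn, sizes=config.bottleneck_sizes, seed=config.seed,
            epochs=config.epochs, encoder_widths=tuple(config.encoder_widths),
            dropout=config.dropout, batch_norm=config.batch_norm)
        (out / "bottleneck_search.json").write_text(
            json.dumps({"best": best, "benchmark": bench}, indent=1, sort_keys=True))
        bottleneck = best
    else:
        bottleneck = config.bottleneck

    logger.info("characterize: training autoencoder (bottleneck %d)", bottleneck)
    ae = MetaboliteAutoencoder(
        encoder_widths=tuple(config.encoder_widths), bottleneck=bottleneck,
        dropout=config.dropout, batch_norm=config.batch_norm,
        epochs=config.epochs, random_state=config.seed).fit(Xn)
    Xd = ae.transform(Xn)

    logger.info("characterize: PCA + component selection")
    pa = ParallelAnalysisPCA(n_randomizations=config.n_randomizations,
                             random_state=config.seed).fit(Xd)
    if config.fixed_n_components is not None:
        n_sel = min(config.fixed_n_components, pa.scores_.shape[1])
    else:
        n_sel = max(len(pa.nontrivial_), 2)  # clustering needs >= 2 dims
    scores = pa.scores_[:, :n_sel]

    logger.info("characterize: SNN clustering + UMAP on %d components", n_sel)
    clust = snn_cluster(scores, k_neighbors=config.k_neighbors, seed=config.seed)
    emb = embed2d(scores, seed=config.seed)

    logger.info("characterize: marker metabolites")
    markers = marker_metabolites(X, clust.labels, metabolite_names=met_names)

    # artifacts
    base_cols = table[["patient_id", "voxel_id", "row", "col", "segment"]]
    pd.concat([base_cols, pd.DataFrame(Xn, columns=list(met_names))], axis=1
              ).to_csv(out / "normalized.tsv", sep="\t", index=False, float_format="%.10g")
    pd.concat([base_cols, pd.DataFrame(Xd, columns=list(met_names))], axis=1
              ).to_csv(out / "denoised.tsv", sep="\t", index=False, float_format="%.10g")
    (out / "normalization.json").write_text(json.dumps(
        {m: [float(lo), float(hi)] for m, lo, hi in
         zip(met_names, norm.data_min_, norm.data_max_)},
        indent=1, sort_keys=True))
    pd.DataFrame({"epoch": np.arange(1, len(ae.report_.train_loss) + 1),
                  "train_loss": ae.report_.train_loss,
                  "val_loss": ae.report_.val_loss}).to_csv(
        out / "loss_history.csv", index=False, float_format="%.10g")
    (out / "pca.json").write_text(json.dumps({
        "eigenvalues": pa.eigenvalues_.tolist(),
        "explained_share": pa.explained_share_.tolist(),
        "null_eigenvalues": pa.null_eigenvalues_.tolist(),
        "nontrivial": pa.nontrivial_,
        "n_used": int(n_sel),
    }, indent=1, sort_keys=True))
    cdf = base_cols.copy()
    cdf["cluster"] = clust.labels
    cdf["umap1"] = emb[:, 0]
    cdf["umap2"] = emb[:, 1]
    cdf.to_csv(out / "clusters.tsv", sep="\t", index=False, float_format="%.10g")
    markers.to_csv(out / "markers.tsv", sep="\t", index=False, float_format="%.10g")

    # mean spectrum per cluster where raw spectra exist
    spectra_by_cluster: dict[int, list] = {}
    vox_cluster = dict(zip(table["voxel_id"], clust.labels))
    for study, _ in studies:
        if not study.spectra:
            continue
        pid = str(study.patient_meta.get("patient_id", ""))
        for vid, sp in study.spectra.items():
            c = vox_cluster.get(f"{pid}:{vid}")
            if c is not None:
                spectra_by_cluster.setdefault(int(c), []).append(sp)
    if spectra_by_cluster:
        rows = []
        for c in sorted(spectra_by_cluster):
            ms = mean_spectrum(spectra_by_cluster[c])
            rows.append(pd.DataFrame({"cluster": c, "ppm": ms.ppm,
                                      "mean": ms.mean, "variance": ms.variance}))
        pd.concat(rows, ignore_index=True).to_csv(
            out / "mean_spectra.tsv", sep="\t", index=False, float_format="%.10g")

    _write_manifest(out, config, "characterize")
    return {"out_dir": str(out), "n_voxels": int(len(X)),
            "n_clusters": int(clust.n_clusters), "n_components_used": int(n_sel),
            "nontrivial": pa.nontrivial_}


# ---------------------------------------------------------------------------
# prediction arm


def split_cohort(studies: list[tuple[Study, str]], train_fraction: float,
                 seed: int) -> tuple[list[int], list[int]]:
    """Stratified patient-level split; returns (train_idx, test_idx)."""
    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 17]))
    by_subtype: dict[str, list[int]] = {}
    for i, (_, subtype) in enumerate(studies):
        by_subtype.setdefault(subtype, []).append(i)
    train, test = [], []
    for subtype in sorted(by_subtype):
        idx = np.array(by_subtype[subtype])
        idx = idx[rng.permutation(len(idx))]
        n_train = max(1, int(round(train_fraction * len(idx)))) if len(idx) > 1 else 1
        if n_train == len(idx) and len(idx) > 1:
            n_train -= 1
        train.extend(idx[:n_train].tolist())
        test.extend(idx[n_train:].tolist())
    return sorted(train), sorted(test)


def build_feature_pipeline(train_X: np.ndarray, config: PipelineConfig):
    """Fit normalizer + autoencoder on training voxels only."""
    norm = MinMaxNormalizer().fit(train_X)
    ae = MetaboliteAutoencoder(
        encoder_widths=tuple(config.encoder_widths), bottleneck=config.bottleneck,
        dropout=config.dropout, batch_norm=config.batch_norm,
        epochs=config.epochs, random_state=config.seed)
    ae.fit(norm.transform(train_X))
    return norm, ae


def run_predict(config: PipelineConfig, cohort: list[tuple[Study, str]] | None = None,
                out_dir: str | Path | None = None) -> dict:
    """Train the two-layer model on training patients; evaluate held-out ones."""
    if cohort is None:
        cohort = _load_or_generate(config)
    table, met_names = _stack(cohort)
    if config.split_by == "patient":
        train_idx, test_idx = split_cohort(cohort, config.train_fraction, config.seed)
        pids = [str(s.patient_meta.get("patient_id", i))
                for i, (s, _) in enumerate(cohort)]
        train_pids = {pids[i] for i in train_idx}
        is_train = table["patient_id"].isin(train_pids).to_numpy()
    elif config.split_by == "voxel":
        rng = np.random.default_rng(np.random.SeedSequence([config.seed & 0x7FFFFFFF, 23]))
        is_train = rng.random(len(table)) < config.train_fraction
        train_pids = set(table["patient_id"])  # every patient contributes
        test_idx = list(range(len(cohort)))
    else:
        raise ValidationError(f"unknown split_by {config.split_by!r}")

    X = table[list(met_names)].to_numpy(dtype=float)
    logger.info("predict: fitting features on %d training voxels", int(is_train.sum()))
    norm, ae = build_feature_pipeline(X[is_train], config)
    Xd = ae.transform(norm.transform(X))

    seg = table["segment"].map(lambda s: SEG_TO_REGION[SegmentLabel(s)]).to_numpy()
    subtype_voxel = np.where(
        (table["segment"].map(lambda s: SegmentLabel(s) in TUMOR_LABELS))
        & table["subtype"].isin(["wt", "IDH", "LOH"]),
        table["subtype"], "")

    absent = {s for s in ("wt", "IDH", "LOH")
              if s in set(c for _, c in cohort) and
              not np.any((subtype_voxel == s) & is_train)}
    if absent:
        raise ValidationError(f"subtypes absent from training voxels: {sorted(absent)}")

    logger.info("predict: training two-layer discriminant model")
    model = TwoLayerSubtypeClassifier(
        tumor_threshold=config.tumor_threshold, lam=config.lam)
    model.fit(Xd[is_train], seg[is_train], subtype_voxel[is_train])

    # held-out evaluation, per patient
    patient_rows = []
    per_patient_scores = []
    predictions = {}
    for i in test_idx:
        study, subtype = cohort[i]
        pid = str(study.patient_meta.get("patient_id", i))
        pmask = (table["patient_id"] == pid).to_numpy()
        if config.split_by == "voxel":
            pmask = pmask & ~is_train
            if not pmask.any():
                continue
        pred = model.predict_patient(
            Xd[pmask], voxel_ids=table.loc[pmask, "voxel_id"].tolist())
        predictions[pid] = pred
        patient_rows.append({
            "patient_id": pid, "true_subtype": subtype,
            "predicted": pred.predicted if pred.predicted else "none",
            "n_tumor_voxels": int(pred.tumor_mask.sum()),
        })
        if subtype in ("wt", "IDH", "LOH") and pred.sport_scores is not None:
            per_patient_scores.append((subtype, pred.sport_scores))

    pdf = pd.DataFrame(patient_rows)
    glioma = pdf[pdf["true_subtype"].isin(["wt", "IDH", "LOH"])]
    patient_accuracy = float((glioma["predicted"] == glioma["true_subtype"]).mean()) \
        if len(glioma) else float("nan")

    # voxel-level layer-1 accuracy on held-out voxels with a region label
    test_vox = ~is_train if config.split_by == "voxel" else \
        ~table["patient_id"].isin(train_pids).to_numpy()
    vmask = test_vox & (seg != "")
    layer1_acc = float("nan")
    if vmask.any():
        layer1_acc = float(np.mean(
            model.layer1_.predict(Xd[vmask]) == seg[vmask]))

    # per-class one-vs-rest AUC over patient-level scores
    auc = {}
    if per_patient_scores:
        classes = model.layer2_.classes_
        S = np.array([[sc[c] for c in classes] for _, sc in per_patient_scores])
        y = np.array([s for s, _ in per_patient_scores])
        for j, c in enumerate(classes):
            pos = y == c
            if pos.any() and not pos.all():
                auc[c] = roc_auc(S[:, j], pos)

    confusion = (pd.crosstab(glioma["true_subtype"], glioma["predicted"])
                 if len(glioma) else pd.DataFrame())

    report = {
        "n_patients": len(cohort),
        "n_train_patients": len(train_pids),
        "n_test_patients": len(patient_rows),
        "patient_accuracy": patient_accuracy,
        "layer1_voxel_accuracy": layer1_acc,
        "auc_ovr": {k: float(v) for k, v in auc.items()},
        "confusion": {str(k): {str(kk): int(vv) for kk, vv in v.items()}
                      for k, v in confusion.to_dict().items()},
        "patients": patient_rows,
    }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "evaluation.json").write_text(
            json.dumps(report, indent=1, sort_keys=True))
        by_pid = {str(s.patient_meta.get("patient_id", i)): s
                  for i, (s, _) in enumerate(cohort)}
        for pid, pred in predictions.items():
            d = {
                "tumor_mask": [v for v, m in zip(pred.voxel_ids, pred.tumor_mask)
                               if m] if pred.voxel_ids else [],
                "sport_scores": pred.sport_scores,
                "predicted": pred.predicted,
                "no_tumor_detected": pred.no_tumor_detected,
            }
            (out / f"prediction_{pid}.json").write_text(
                json.dumps(d, indent=1, sort_keys=True))
            # tumor-probability map on the acquisition grid
            study = by_pid.get(pid)
            if study is not None and pred.region_scores is not None:
                pmask = (table["patient_id"] == pid).to_numpy()
                if config.split_by == "voxel":
                    pmask = pmask & ~is_train
                tcol = pred.region_scores.classes.index("TUMOR") \
                    if "TUMOR" in pred.region_scores.classes else None
                if tcol is not None:
                    grid = render_score_map(
                        pred.region_scores.probabilities[:, tcol],
                        table.loc[pmask, "row"].to_numpy(),
                        table.loc[pmask, "col"].to_numpy(),
                        study.grid_rows, study.grid_cols)
                    pd.DataFrame(grid).to_csv(
                        out / f"tumor_probability_{pid}.tsv", sep="\t",
                        index=False, header=False, float_format="%.10g")
        _write_manifest(out, config, "predict")

    report["_predictions"] = predictions
    report["_model"] = model
    report["_norm"] = norm
    report["_ae"] = ae
    return report


def false_positive_comparison(config: PipelineConfig,
                              cohort: list[tuple[Study, str]] | None = None,
                              confidence: float = 0.5) -> dict:
    """Paired comparison of subtype false positives on normal-appearing matter.

    Trains the feature pipeline and both discriminant layers once, then
    scores every held-out true-NAM voxel two ways: the single-layer variant
    applies the subtype discriminant to all voxels, while the two-layer
    model only scores voxels inside the predicted tumor mask.  A false
    positive is a NAM voxel receiving a subtype call with probability above
    ``confidence``.  Returns both rates (two-layer should be lower).
    """
    if cohort is None:
        cohort = _load_or_generate(config)
    rep = run_predict(config, cohort=cohort)
    model = rep["_model"]
    norm, ae = rep["_norm"], rep["_ae"]
    table, met_names = _stack(cohort)
    train_idx, test_idx = split_cohort(cohort, config.train_fraction, config.seed)
    pids = [str(s.patient_meta.get("patient_id", i)) for i, (s, _) in enumerate(cohort)]
    test_pids = {pids[i] for i in test_idx}
    nam = (table["segment"] == SegmentLabel.NAM.value) & \
        table["patient_id"].isin(test_pids)
    X = table.loc[nam, list(met_names)].to_numpy(dtype=float)
    Xd = ae.transform(norm.transform(X))

    sub = model.layer2_.predict_scores(Xd)
    single_fp = np.mean(sub.probabilities.max(axis=1) > confidence)

    region = model.layer1_.predict_scores(Xd)
    tcol = region.classes.index(model.tumor_class)
    in_mask = region.probabilities[:, tcol] > model.tumor_threshold
    two_fp = np.mean(in_mask & (sub.probabilities.max(axis=1) > confidence))
    return {
        "n_nam_voxels": int(nam.sum()),
        "single_layer_fp_rate": float(single_fp),
        "two_layer_fp_rate": float(two_fp),
    }


def audit_patient_leakage(table: pd.DataFrame, is_train: np.ndarray) -> bool:
    """True iff no patient contributes voxels to both splits."""
    tr = set(table.loc[is_train, "patient_id"])
    te = set(table.loc[~is_train, "patient_id"])
    return len(tr & te) == 0


# convenience used by the CLI


def simulate_to_dir(config: PipelineConfig, out_dir: str | Path) -> list[str]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort = _load_or_generate(config)
    paths = []
    truth_rows = []
    for study, subtype in cohort:
        pid = str(study.patient_meta.get("patient_id", "p000"))
        sdir = out / pid
        save_study(study, sdir)
        paths.append(str(sdir))
        for vid in study.metabolites.voxel_ids:
            truth_rows.append({"patient_id": pid, "voxel_id": vid,
                               "label": study.segmentation[vid].value,
                               "subtype": subtype})
    pd.DataFrame(truth_rows).to_csv(out / "truth.tsv", sep="\t", index=False)
    _write_manifest(out, config, "simulate")
    return paths
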