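"""End-to-end orchestration: simulate/load -> preprocess -> PCA -> PLS
calibration -> classification -> evaluation, in one reproducible run.

The run mirrors the study's analysis flow and reports three
classification blocks: LDA on the assayed concentrations (one unit per
sample), LDA on the cross-validated PLS-predicted concentrations (one
unit per spectrum), and PLS-DA on the full spectra (one unit per
spectrum).  The LDA-on-predictions block consumes held-out PLS
predictions, never training fits, and all classifier evaluation is
leave-one-sample-out so replicate spectra of a sample never split
between training and test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    ANALYTES,
    BiomarkerPanel,
    Group,
    SpectraSet,
    read_panels,
    read_spectra,
    write_panels,
    write_spectra,
)
from .preprocess import PreprocessConfig, preprocess_set, qc_filter
from .chemometrics import (
    CVResult,
    CVUnit,
    fit_pca,
    lda_classify,
    lda_fit,
    loocv_pls,
    plsda_classify,
    plsda_fit,
)
from .evaluation import (
    ClassMetrics,
    ConfusionMatrix,
    GroupComparison,
    classification_metrics,
    compare_component_scores,
    confusion_matrix,
    convert_concentration,
    round_percent,
    MOLAR_MASS_G_PER_MOL,
)
from .simulate import CohortConfig, generate_cohort

__all__ = [
    "RunConfig",
    "AnalyteCalibration",
    "ClassificationBlock",
    "RunReport",
    "run_pipeline",
    "render_report",
]


@dataclass
class RunConfig:
    """One pipeline run: exactly one input source (files xor simulate)."""

    simulate: CohortConfig | None = None
    matrix_path: str | None = None
    metadata_path: str | None = None
    concentrations_path: str | None = None
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    n_pca_components: int = 6
    max_lv: int = 10
    plsda_lv: int = 7
    cv_unit: CVUnit = CVUnit.SAMPLE
    seed: int = 0
    outdir: str | None = None

    def __post_init__(self) -> None:
        files = self.matrix_path is not None
        if files == (self.simulate is not None):
            raise ValueError("configure exactly one input source: files or simulate")
        if files and (self.metadata_path is None or self.concentrations_path is None):
            raise ValueError("file input needs matrix, metadata and concentrations")
        if isinstance(self.cv_unit, str):
            self.cv_unit = CVUnit(self.cv_unit)


@dataclass
class AnalyteCalibration:
    analyte: str
    chosen_lv: int
    rmsecv: float  # native units
    rmsecv_mgdL: float | None  # where a molar mass is registered
    r: float
    cv: CVResult


@dataclass
class ClassificationBlock:
    name: str
    cm: ConfusionMatrix
    metrics: ClassMetrics
    n_ct: int
    n_dm: int


@dataclass
class RunReport:
    seed: int
    qc_n_input: int
    qc_n_retained: int
    calibrations: dict[str, AnalyteCalibration]
    blocks: dict[str, ClassificationBlock]
    pca_comparisons: list[GroupComparison]
    pca_variance_6: float
    log: list[dict] = field(default_factory=list)


def _grouped_loo_labels(features, labels, sample_ids) -> list[Group]:
    """Leave-one-sample-out LDA predictions for every row."""
    features = np.atleast_2d(np.asarray(features, dtype=float))
    sample_ids = np.asarray(sample_ids)
    predicted: list[Group | None] = [None] * features.shape[0]
    _, first = np.unique(sample_ids, return_index=True)
    for sid in sample_ids[np.sort(first)]:
        test = np.flatnonzero(sample_ids == sid)
        train = np.flatnonzero(sample_ids != sid)
        model = lda_fit(features[train], [labels[i] for i in train])
        for i, lab in zip(test, lda_classify(model, features[test])):
            predicted[i] = lab
    return predicted  # type: ignore[return-value]


def _plsda_loo_labels(X, labels, sample_ids, n_lv, cv_unit: CVUnit) -> list[Group]:
    """Held-out PLS-DA predictions for every spectrum."""
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    predicted: list[Group | None] = [None] * n
    if cv_unit == CVUnit.SPECTRUM:
        folds = [np.array([i]) for i in range(n)]
    else:
        sample_ids = np.asarray(sample_ids)
        _, first = np.unique(sample_ids, return_index=True)
        folds = [
            np.flatnonzero(sample_ids == sid) for sid in sample_ids[np.sort(first)]
        ]
    for fold in folds:
        train = np.setdiff1d(np.arange(n), fold)
        model = plsda_fit(X[train], [labels[i] for i in train], n_lv)
        for i, lab in zip(fold, plsda_classify(model, X[fold])):
            predicted[i] = lab
    return predicted  # type: ignore[return-value]


def _block(name, truth, predicted) -> ClassificationBlock:
    cm = confusion_matrix(truth, predicted)
    return ClassificationBlock(
        name=name,
        cm=cm,
        metrics=classification_metrics(cm),
        n_ct=cm.tn + cm.fp,
        n_dm=cm.fn + cm.tp,
    )


def run_pipeline(cfg: RunConfig) -> RunReport:
    """Execute every stage and assemble the run report.

    Deterministic given the seed and inputs; with ``cfg.outdir`` set, the
    preprocessed matrix, QC table, selection curves and held-out
    predictions are persisted as delimited text.
    """
    log: list[dict] = []

    # ------------------------------------------------------------- input
    if cfg.simulate is not None:
        sim = cfg.simulate
        if cfg.seed != sim.seed:
            from dataclasses import replace as _replace

            sim = _replace(sim, seed=cfg.seed)
        spectra, panels = generate_cohort(sim)
        log.append(
            {"stage": "simulate", "seed": cfg.seed, "n_out": len(spectra)}
        )
    else:
        spectra = read_spectra(cfg.matrix_path, cfg.metadata_path)
        panels = read_panels(cfg.concentrations_path)
        log.append({"stage": "load", "n_out": len(spectra)})
    panel_by_sample = {p.sample_id: p for p in panels}
    missing = [s.meta.sample_id for s in spectra if s.meta.sample_id not in panel_by_sample]
    if missing:
        raise ValueError(f"no biomarker panel for samples {sorted(set(missing))}")

    # -------------------------------------------------------- preprocess
    n_input = len(spectra)
    processed = preprocess_set(spectra, cfg.preprocess, qc=True)
    log.append(
        {
            "stage": "preprocess",
            "n_in": n_input,
            "n_out": len(processed),
            "n_excluded": n_input - len(processed),
        }
    )

    X = processed.intensity_matrix()
    groups = [s.meta.group for s in processed]
    sample_ids = [s.meta.sample_id for s in processed]

    # --------------------------------------------------------------- PCA
    pca = fit_pca(X, cfg.n_pca_components)
    comparisons = [
        compare_component_scores(pca, groups, k)
        for k in range(cfg.n_pca_components)
    ]
    var6 = float(np.sum(pca.explained_variance_ratio[: cfg.n_pca_components]))
    log.append({"stage": "pca", "n_components": cfg.n_pca_components})

    # ------------------------------------------------------- calibration
    calibrations: dict[str, AnalyteCalibration] = {}
    for analyte in ANALYTES:
        y = np.array([panel_by_sample[sid][analyte] for sid in sample_ids])
        cv = loocv_pls(X, y, cfg.max_lv, cfg.cv_unit, sample_ids)
        rmsecv = float(cv.rmsecv_by_lv[cv.chosen_lv - 1])
        mgdl = (
            convert_concentration(rmsecv, analyte, "mmolL_to_mgdL")
            if analyte in MOLAR_MASS_G_PER_MOL
            else None
        )
        calibrations[analyte] = AnalyteCalibration(
            analyte=analyte,
            chosen_lv=cv.chosen_lv,
            rmsecv=rmsecv,
            rmsecv_mgdL=mgdl,
            r=float(cv.r_by_lv[cv.chosen_lv - 1]),
            cv=cv,
        )
    log.append({"stage": "calibrate", "analytes": list(ANALYTES)})

    # ---------------------------------------------------- classification
    # (a) LDA on assayed concentrations, one unit per sample
    sample_order = sorted(panel_by_sample)
    feats_assayed = np.vstack([panel_by_sample[s].as_vector() for s in sample_order])
    group_by_sample = {}
    for s in processed:
        group_by_sample[s.meta.sample_id] = s.meta.group
    truth_samples = [group_by_sample[s] for s in sample_order]
    pred_a = _grouped_loo_labels(feats_assayed, truth_samples, sample_order)
    block_a = _block("lda_assayed", truth_samples, pred_a)

    # (b) LDA on cross-validated PLS-predicted concentrations, per spectrum
    feats_pls = np.column_stack(
        [calibrations[a].cv.cv_predictions for a in ANALYTES]
    )
    pred_b = _grouped_loo_labels(feats_pls, groups, sample_ids)
    block_b = _block("lda_pls_predicted", groups, pred_b)

    # (c) PLS-DA on full spectra, per spectrum
    pred_c = _plsda_loo_labels(X, groups, sample_ids, cfg.plsda_lv, cfg.cv_unit)
    block_c = _block("plsda", groups, pred_c)
    log.append({"stage": "classify", "blocks": ["lda_assayed", "lda_pls_predicted", "plsda"]})

    report = RunReport(
        seed=cfg.seed,
        qc_n_input=n_input,
        qc_n_retained=len(processed),
        calibrations=calibrations,
        blocks={b.name: b for b in (block_a, block_b, block_c)},
        pca_comparisons=comparisons,
        pca_variance_6=var6,
        log=log,
    )

    if cfg.outdir is not None:
        _persist(cfg, report, processed, panels)
    return report


def _persist(cfg: RunConfig, report: RunReport, processed: SpectraSet, panels) -> None:
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_spectra(processed, out / "preprocessed_matrix.csv", out / "preprocessed_metadata.csv")
    write_panels(panels, out / "panels.csv")
    pd.DataFrame(
        [
            {
                "spectrum_id": s.meta.spectrum_id,
                "snr": s.meta.snr,
                "qc_pass": s.meta.qc_pass,
                "n_spikes_removed": s.meta.n_spikes_removed,
            }
            for s in processed
        ]
    ).to_csv(out / "qc_report.csv", index=False)
    curves = []
    for a, cal in report.calibrations.items():
        for k, (rm, rr) in enumerate(
            zip(cal.cv.rmsecv_by_lv, cal.cv.r_by_lv), start=1
        ):
            curves.append({"analyte": a, "lv": k, "rmsecv": rm, "r": rr})
    pd.DataFrame(curves).to_csv(out / "selection_curves.csv", index=False)
    preds = {"spectrum_id": processed.ids}
    for a, cal in report.calibrations.items():
        preds[f"{a}_cv_prediction"] = cal.cv.cv_predictions
        preds[f"{a}_true"] = cal.cv.y_true
    pd.DataFrame(preds).to_csv(out / "cv_predictions.csv", index=False)
    render_report(report, out / "report.tsv")


_BLOCK_TITLES = {
    "lda_assayed": "LDA on assayed concentrations",
    "lda_pls_predicted": "LDA on PLS-predicted concentrations",
    "plsda": "PLS-DA on Raman spectra",
}


def render_report(report: RunReport, path: str | Path) -> str:
    """Write the report as delimited text plus a human-readable summary.

    The delimited file has three sections (calibration, classification,
    pca), each a tab-separated table introduced by a ``# section`` line;
    a plain-language summary is written next to it with suffix ``.txt``.
    Returns the summary text.
    """
    if not report.blocks:
        raise ValueError("empty report: no classification blocks to render")
    path = Path(path)
    lines = ["# calibration", "analyte\tchosen_lv\trmsecv\trmsecv_mgdL\tr"]
    for a, cal in report.calibrations.items():
        mg = "" if cal.rmsecv_mgdL is None else f"{cal.rmsecv_mgdL:.6g}"
        lines.append(f"{a}\t{cal.chosen_lv}\t{cal.rmsecv:.6g}\t{mg}\t{cal.r:.6g}")
    lines.append("# classification")
    lines.append(
        "model\tn_ct\tn_dm\ttn\tfp\tfn\ttp\tsensitivity_pct\tspecificity_pct\taccuracy_pct"
    )
    for b in report.blocks.values():
        pct = b.metrics.as_percent()
        lines.append(
            f"{b.name}\t{b.n_ct}\t{b.n_dm}\t{b.cm.tn}\t{b.cm.fp}\t{b.cm.fn}\t{b.cm.tp}"
            f"\t{pct['sensitivity']:.1f}\t{pct['specificity']:.1f}\t{pct['accuracy']:.1f}"
        )
    lines.append("# pca")
    lines.append("component\tks_p_ct\tks_p_dm\tt_statistic\tt_p\tsignificant")
    for c in report.pca_comparisons:
        lines.append(
            f"{c.component_index + 1}\t{c.ks_p_ct:.4g}\t{c.ks_p_dm:.4g}"
            f"\t{c.t_statistic:.6g}\t{c.t_p:.4g}\t{c.significant}"
        )
    path.write_text("\n".join(lines) + "\n")

    summary = [
        f"Run seed {report.seed}: {report.qc_n_retained}/{report.qc_n_input} "
        f"spectra retained after SNR quality control.",
        f"First {len(report.pca_comparisons)} principal components capture "
        f"{report.pca_variance_6 * 100:.1f}% of spectral variance.",
        "",
        "Calibration (leave-one-out cross-validation):",
    ]
    for a, cal in report.calibrations.items():
        extra = (
            f" ({cal.rmsecv_mgdL:.1f} mg/dL)" if cal.rmsecv_mgdL is not None else ""
        )
        summary.append(
            f"  {a}: {cal.chosen_lv} LVs, RMSEcv {cal.rmsecv:.3g}{extra}, r {cal.r:.3f}"
        )
    summary.append("")
    summary.append("Classification (held-out):")
    for b in report.blocks.values():
        pct = b.metrics.as_percent()
        summary.append(
            f"  {_BLOCK_TITLES.get(b.name, b.name)}: accuracy {pct['accuracy']:.1f}%, "
            f"sensitivity {pct['sensitivity']:.1f}%, specificity {pct['specificity']:.1f}% "
            f"(tn={b.cm.tn}, fp={b.cm.fp}, fn={b.cm.fn}, tp={b.cm.tp})"
        )
    text = "\n".join(summary) + "\n"
    path.with_suffix(".txt").write_text(text)
    return text
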