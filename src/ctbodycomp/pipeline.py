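"""End-to-end wiring: phantom bundle → composition CSV → statistics report.

Each stage is a plain function over the library modules, so it can be
driven identically from the CLI, the analysis scripts and the tests.
All outputs carry the schema string and config hash in a row-1 comment;
a fixed seed and config make every stage byte-reproducible.
"""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as cio
from .composition import (
    classify_sarcopenia,
    derive_areas,
    mean_muscle_attenuation,
    skeletal_muscle_index,
    stratify_duct,
)
from .cohort import CohortSpec, cohort_to_frame, frame_to_records, generate_cohort
from .config import PipelineConfig
from .phantom import PhantomSpec, generate_phantom
from .segmentation import detect_fov_truncation, quantify_tissue_area, standardize_slice
from .stats import fit_logistic, format_p, roc_auc, summarize_cohort, two_by_two

log = logging.getLogger("ctbodycomp")


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:12]


def cmd_phantom(
    config: PipelineConfig, spec: PhantomSpec, out_dir: str | Path
) -> dict[str, Path]:
    """Write a phantom bundle: DICOM + npz raster, truth JSON, ROI JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ct, truth = generate_phantom(spec)
    paths = {
        "dicom": out / "phantom.dcm",
        "npz": out / "phantom.npz",
        "truth": out / "truth.json",
        "rois": out / "rois.json",
    }
    cio.write_dicom_slice(ct, paths["dicom"])
    cio.write_slice_npz(ct, paths["npz"])
    cio.write_truth(truth, paths["truth"])
    cio.write_rois(truth.roi_set, paths["rois"])
    log.info("phantom bundle written to %s (config %s)", out, config.hash())
    return paths


def quantify_slice(config: PipelineConfig, ct, rois, patient_id=None,
                   height_m=None, sex=None, bmi=None) -> dict:
    """One patient's row: the seven areas, MA, and (when covariates are
    given) SMI and sarcopenia flags.  Standardizes the slice itself."""
    ct = standardize_slice(ct)
    fat = config.adipose()
    mus = config.muscle()
    truncated = detect_fov_truncation(ct, rois.roi_a)
    fat_a = quantify_tissue_area(ct, rois.roi_a, fat)
    fat_b = quantify_tissue_area(ct, rois.roi_b, fat)
    mus_a = quantify_tissue_area(ct, rois.roi_a, mus)
    mus_c = quantify_tissue_area(ct, rois.roi_c, mus)
    mus_d = quantify_tissue_area(ct, rois.roi_d, mus)
    comp = derive_areas(fat_a, fat_b, mus_a, mus_c, mus_d, fov_truncated=truncated)
    ma = mean_muscle_attenuation(ct, rois.roi_c, rois.roi_d, mus)
    row = {
        "patient_id": patient_id or ct.patient_id,
        "a_tat_cm2": comp.a_tat, "a_vat_cm2": comp.a_vat,
        "a_sat_cm2": np.nan if comp.a_sat is None else comp.a_sat,
        "a_mpso_cm2": comp.a_mpso, "a_mspi_cm2": comp.a_mspi,
        "a_mven_cm2": comp.a_mven, "a_mtot_cm2": comp.a_mtot,
        "ma_hu": ma, "fov_truncated": truncated,
    }
    if height_m is not None:
        smi = skeletal_muscle_index(comp.a_mtot, height_m)
        row["smi_cm2_m2"] = smi
        if sex is not None and bmi is not None:
            by_smi, by_ma, both = classify_sarcopenia(
                smi, ma, sex, bmi, config.sarcopenia
            )
            row.update(sarcopenic_by_smi=by_smi, sarcopenic_by_ma=by_ma,
                       sarcopenic=both)
    return row


def cmd_quantify(
    config: PipelineConfig,
    slice_paths: list[str | Path],
    roi_paths: list[str | Path],
    out_csv: str | Path,
) -> pd.DataFrame:
    """Quantify a batch of (slice, ROI) pairs into the composition CSV.

    A missing or unreadable ROI file yields a row of missing markers and
    a logged warning rather than aborting the batch.
    """
    rows = []
    for sp, rp in zip(slice_paths, roi_paths, strict=True):
        sp, rp = Path(sp), Path(rp)
        ct = (
            cio.read_dicom_slice(sp)
            if sp.suffix.lower() in (".dcm", ".dicom")
            else cio.read_slice_npz(sp)
        )
        log.info("input %s checksum %s", sp.name, _checksum(sp))
        try:
            rois = cio.read_rois(rp)
        except (OSError, ValueError, KeyError) as exc:
            log.warning("ROI file %s unusable (%s); emitting missing row", rp, exc)
            rows.append({"patient_id": ct.patient_id or sp.stem})
            continue
        rows.append(quantify_slice(config, ct, rois, patient_id=ct.patient_id or sp.stem))
    df = pd.DataFrame(rows)
    cio.write_csv_with_header(df, out_csv, config.hash())
    return df


def simulate_cohort_csv(
    config: PipelineConfig, spec: CohortSpec, out_csv: str | Path
) -> pd.DataFrame:
    records = generate_cohort(spec)
    df = cohort_to_frame(records)
    cio.write_csv_with_header(df, out_csv, config.hash())
    return df


def cmd_report(
    config: PipelineConfig,
    composition_csv: str | Path,
    out_dir: str | Path,
    clinical_csv: str | Path | None = None,
    make_plot: bool = False,
) -> dict[str, Path]:
    """Statistics layer over a cohort table.

    Writes the univariate comparison table, the multivariable logistic
    fit (sarcopenia + A_VAT + DPD per endpoint), ROC coordinates for MA
    and DPD, and the 3 mm duct 2×2 stratifications, all as CSV.  The
    composition and clinical tables may be one merged file or two files
    sharing ``patient_id``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    df = cio.read_csv_with_header(composition_csv)
    if clinical_csv is not None:
        clin = cio.read_csv_with_header(clinical_csv)
        overlap = (set(df.columns) & set(clin.columns)) - {"patient_id"}
        df = df.merge(clin.drop(columns=list(overlap)), on="patient_id")
    required = {"clavien_dindo", "popf"}
    missing = required - set(df.columns)
    if missing:
        raise KeyError(f"endpoint column(s) absent: {sorted(missing)}")
    records = frame_to_records(df)
    paths = {}
    h = config.hash()

    table = summarize_cohort(records)
    paths["univariate"] = out / "univariate.csv"
    cio.write_csv_with_header(table, paths["univariate"], h)

    # multivariable logistic per endpoint, over measurable-duct patients
    fits = []
    for endpoint, getter in (
        ("major_complication", lambda r: r.major_complication),
        ("severe_popf", lambda r: r.severe_popf),
    ):
        sub = [r for r in records if r.dpd is not None]
        y = [int(getter(r)) for r in sub]
        if len(sub) < 10 or len(set(y)) < 2:
            log.warning("endpoint %s: too few usable records for regression", endpoint)
            continue
        X = pd.DataFrame({
            "sarcopenia": [int(bool(r.composition.sarcopenic)) for r in sub],
            "a_vat": [r.composition.a_vat for r in sub],
            "dpd": [r.dpd for r in sub],
        })
        fit = fit_logistic(y, X)
        fr = fit.summary_frame()
        fr.insert(0, "endpoint", endpoint)
        fr["converged"] = fit.converged
        fr["n"] = fit.n
        fits.append(fr)
    if fits:
        paths["logistic"] = out / "logistic.csv"
        cio.write_csv_with_header(pd.concat(fits, ignore_index=True),
                                  paths["logistic"], h)

    # ROC for the low-is-risk markers against severe POPF and major compl.
    roc_rows = []
    roc_curves = {}
    for endpoint, getter in (
        ("major_complication", lambda r: r.major_complication),
        ("severe_popf", lambda r: r.severe_popf),
    ):
        for marker, value in (("ma", lambda r: r.composition.ma),
                              ("dpd", lambda r: r.dpd)):
            sub = [r for r in records if value(r) is not None]
            labels = [int(getter(r)) for r in sub]
            if len(set(labels)) < 2:
                continue
            roc = roc_auc([value(r) for r in sub], labels, lower_is_positive=True)
            roc_curves[(endpoint, marker)] = roc
            for t, f, s in zip(roc.thresholds, roc.fpr, roc.tpr):
                roc_rows.append({"endpoint": endpoint, "marker": marker,
                                 "threshold": t, "fpr": f, "tpr": s,
                                 "auc": roc.auc})
    if roc_rows:
        paths["roc"] = out / "roc.csv"
        cio.write_csv_with_header(pd.DataFrame(roc_rows), paths["roc"], h)

    # duct stratification at the conventional cutoff
    strat = []
    for endpoint, getter in (
        ("major_complication", lambda r: r.major_complication),
        ("severe_popf", lambda r: r.severe_popf),
    ):
        t = two_by_two(
            records,
            exposure=lambda r: (None if r.dpd is None
                                else stratify_duct(r.dpd, config.duct_cutoff_mm) == "narrow"),
            event=getter,
            percent_mode=config.percent_mode,
        )
        strat.append({
            "endpoint": endpoint, "cutoff_mm": config.duct_cutoff_mm,
            "narrow_event": t.exposed_event, "narrow_total": t.n_exposed,
            "narrow_pct": t.row_percent_exposed(),
            "wide_event": t.unexposed_event, "wide_total": t.n_unexposed,
            "wide_pct": t.row_percent_unexposed(),
            "odds_ratio": t.odds_ratio(),
        })
    paths["duct_2x2"] = out / "duct_stratification.csv"
    cio.write_csv_with_header(pd.DataFrame(strat), paths["duct_2x2"], h)

    if make_plot and roc_curves:
        paths["roc_plot"] = _plot_roc(roc_curves, out / "roc.png")
    return paths


def _plot_roc(curves, path: Path) -> Path:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for (endpoint, marker), roc in curves.items():
        ax.plot(roc.fpr, roc.tpr,
                label=f"{marker.upper()} / {endpoint} (AUC {roc.auc:.3f})")
    ax.plot([0, 1], [0, 1], "k:", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
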