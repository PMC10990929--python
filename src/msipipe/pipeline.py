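"""End-to-end pipeline orchestration with a single validated config.

Stages run in acquisition-processing order: peak picking -> two-step
lock-mass recalibration -> common mass axis + data cube -> semi-
supervised ROI annotation -> off-sample feature filtering ->
colocalization on sample pixels -> first-pass unmixing (whose tissue
abundance map becomes the perceptual reference) -> SSIM/MS-SSIM feature
refinement -> final k-component unmixing -> weighted logistic
classification of labelled regions with group-wise LOOCV, RFE and ROC
comparison.

Every stage writes its artifact into the output directory, and a JSON
manifest records the seed, all applied parameters (no silent defaults)
and per-stage row/feature counts; reruns with the same config and seed
produce an identical manifest hash.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from . import classify as _classify
from .coloc import colocalize
from .io import read_cube_container, write_cube_container
from .massaxis import (LockMassSet, assemble_cube, build_common_axis,
                       recalibrate_table)
from .peaks import pick_peaks_image
from .phantom import DEFAULT_LOCKMASSES, PhantomConfig, Species, make_phantom
from .roi import annotate_roi, auto_seeds_from_tic, offsample_filter
from .ssim import SSIMParams, filter_by_ssim
from .unmix import abundance_image, unmix

log = logging.getLogger("msipipe")


class PipelineConfig(BaseModel):
    """Schema-validated parameters for one pipeline run.

    Unknown keys are rejected before any computation starts.
    """

    model_config = ConfigDict(extra="forbid")

    input_path: str | None = None        # raw-image container; None: simulate
    outdir: str = "msipipe_out"
    seed: int = 0

    # phantom (used only when input_path is None)
    phantom_width: int = 32
    phantom_height: int = 32
    phantom_drift_ppm_sd: float = 5.0
    phantom_noise_sd: float = 2.0
    phantom_baseline: float = 5.0

    # peak picking
    snr_min: float = 3.0
    min_dist: int = 3
    noise_window: int = 51
    intensity_mode: str = "apex"

    # recalibration / axis
    lockmasses: list[float] = Field(default_factory=lambda: list(DEFAULT_LOCKMASSES))
    lock_tol_ppm: float = 30.0
    bin_tol_ppm: float = 10.0

    # ROI + off-sample filter
    roi_seed_frac: float = 0.1
    min_corr: float = 0.2

    # colocalization
    alpha: float = 0.05
    min_rho: float = 0.5

    # SSIM refinement; reference "mean" = mean ion image, "unmix" =
    # two-pass feedback of the first-pass tissue abundance map
    ssim_window: int = 7
    ssim_levels: int = 3
    ssim_w: float = 0.5
    ssim_tau: float = 0.3
    ssim_reference: str = "mean"

    # unmixing
    k: int = 2
    unmix_max_iter: int = 300
    unmix_restarts: int = 5

    # classification
    ridge: float = 1.0
    rfe_step: float = 0.1
    rfe_n_target: int = 5
    n_groups: int = 4

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yml", ".yaml")):
            import yaml
            return cls(**yaml.safe_load(text))
        return cls(**json.loads(text))


def stage_seeds(seed: int, n: int = 8) -> list[int]:
    """Fan one global seed out to independent per-stage seeds (< 2^31)."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2 ** 31) for s in ss.generate_state(n)]


def default_phantom(config: PipelineConfig, seed: int) -> PhantomConfig:
    """Phantom used when the pipeline is run without instrument input:
    tissue-wide metabolites, two lesion-enriched species (present at a
    low level in normal tissue and strongly elevated in the lesion,
    mimicking the inflammatory small-metabolite signal), one
    isotope-bearing lipid, and the three standard calibrants in all
    tissue pixels."""
    species = [
        Species("met_tissue_a", 180.05, {"tissue": 120.0, "lesion": 120.0}),
        Species("met_lesion_a", 200.10, {"tissue": 60.0, "lesion": 150.0}),
        Species("met_lesion_b", 215.20, {"tissue": 50.0, "lesion": 130.0}),
        Species("met_tissue_b", 320.30, {"tissue": 100.0, "lesion": 100.0}),
        Species("lipid_a", 500.40, {"tissue": 90.0, "lesion": 90.0},
                isotope_satellite=True),
        Species("offsample", 600.50, {"background": 80.0}),
    ]
    return PhantomConfig(width=config.phantom_width,
                         height=config.phantom_height,
                         species_table=species,
                         lockmass_list=tuple(config.lockmasses),
                         drift_ppm_sd=config.phantom_drift_ppm_sd,
                         noise_sd=config.phantom_noise_sd,
                         baseline_level=config.phantom_baseline,
                         seed=seed)


def _save_gray_png(image: np.ndarray, path) -> None:
    """Min-max scaled 8-bit grayscale dump of an abundance/ion image."""
    from PIL import Image
    lo, hi = float(image.min()), float(image.max())
    scaled = (image - lo) / (hi - lo) if hi > lo else np.zeros_like(image)
    Image.fromarray((255 * scaled).astype(np.uint8), mode="L").save(path)


def _group_ids(height: int, width: int, n_groups: int) -> np.ndarray:
    """Pseudo-section ids: vertical image strips acting as acquisition
    groups for leave-one-group-out CV."""
    col = np.arange(height * width) % width
    return np.minimum((col * n_groups) // width, n_groups - 1)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and return the manifest (also written to
    ``outdir/manifest.json``)."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(config.seed)
    manifest: dict = {"params": json.loads(config.model_dump_json()),
                      "seed": config.seed, "stages": {}}

    def record(stage: str, **counts) -> None:
        manifest["stages"][stage] = counts
        log.info("stage %-12s %s", stage, counts)

    # --- input ----------------------------------------------------------
    truth = None
    if config.input_path is None:
        image, truth = make_phantom(default_phantom(config, seeds[0]))
        write_cube_container(image, out / "raw_image.h5")
    else:
        image = read_cube_container(config.input_path)
        image.validate()
    record("input", n_pixels=image.n_pixels, axis_points=int(image.mz_axis.size))

    # --- peak picking ----------------------------------------------------
    table = pick_peaks_image(image, snr_min=config.snr_min,
                             min_dist=config.min_dist,
                             noise_window=config.noise_window,
                             intensity_mode=config.intensity_mode)
    table.to_tsv(out / "peaks.tsv")
    record("peaks", n_peaks=len(table.df))

    # --- recalibration ---------------------------------------------------
    lockset = LockMassSet(tuple(config.lockmasses), config.lock_tol_ppm)
    table, calib_report = recalibrate_table(table, lockset)
    calib_report.to_csv(out / "calibration.tsv", sep="\t", index=False)
    record("recalibrate",
           n_calibrated=int(calib_report["calibrated"].sum()),
           n_pixels=len(calib_report))

    # --- cube ------------------------------------------------------------
    axis, _ = build_common_axis(table, tol_ppm=config.bin_tol_ppm)
    cube = assemble_cube(table, axis, tol_ppm=config.bin_tol_ppm)
    axis.to_frame().to_csv(out / "mass_axis.tsv", sep="\t", index=False)
    record("cube", n_features=len(axis))

    # --- ROI -------------------------------------------------------------
    seeds_roi = auto_seeds_from_tic(cube, frac=config.roi_seed_frac)
    roi = annotate_roi(cube, {"background": seeds_roi["background"],
                              "sample": seeds_roi["sample"]})
    cube.roi = (roi.labels == roi.class_names.index("sample")).astype(int)
    roi.to_tsv(out / "roi.tsv")
    record("roi", n_sample=int(cube.roi.sum()),
           n_background=int((cube.roi == 0).sum()))

    # --- off-sample filter ----------------------------------------------
    mean_image = cube.X.mean(axis=1).reshape(cube.height, cube.width)
    kept_off, off_scores = offsample_filter(cube, mean_image,
                                            min_corr=config.min_corr)
    off_scores.to_csv(out / "offsample_scores.tsv", sep="\t", index=False)
    cube = cube.select_features(kept_off)
    record("offsample", n_features=cube.n_features)

    # --- colocalization --------------------------------------------------
    sample_mask = cube.roi.astype(bool)
    pairs = colocalize(cube, sample_mask,
                       alpha=config.alpha, min_rho=config.min_rho)
    pairs.to_csv(out / "coloc_pairs.tsv", sep="\t", index=False)
    record("colocalization", n_pairs=len(pairs))

    # --- SSIM refinement -------------------------------------------------
    if config.ssim_reference == "unmix":
        # two-pass: first-pass tissue abundance map as the reference
        pre = unmix(cube, k=config.k, seed=seeds[1],
                    max_iter=config.unmix_max_iter,
                    n_restarts=config.unmix_restarts)
        reference = abundance_image(pre, pre.tissue_index)
    elif config.ssim_reference == "mean":
        reference = cube.X.mean(axis=1).reshape(cube.height, cube.width)
    else:
        raise ValueError("ssim_reference must be 'mean' or 'unmix'")
    sparams = SSIMParams(window=config.ssim_window, levels=config.ssim_levels,
                         w=config.ssim_w, tau=config.ssim_tau)
    kept_ssim, ssim_scores = filter_by_ssim(cube, reference, sparams)
    ssim_scores.to_csv(out / "ssim_scores.tsv", sep="\t", index=False)
    cube = cube.select_features(kept_ssim)
    write_cube_container(cube, out / "cube.h5")
    record("ssim_filter", n_features=cube.n_features,
           tau=config.ssim_tau, w=config.ssim_w)

    # --- final unmixing --------------------------------------------------
    result = unmix(cube, k=config.k, seed=seeds[2],
                   max_iter=config.unmix_max_iter,
                   n_restarts=config.unmix_restarts)
    np.savetxt(out / "endmembers.tsv",
               np.column_stack([cube.axis.centers, result.endmembers.T]),
               delimiter="\t",
               header="mz\t" + "\t".join(f"component_{i}"
                                         for i in range(config.k)))
    for comp in range(config.k):
        img = abundance_image(result, comp)
        _save_gray_png(img, out / f"abundance_{comp}.png")
    roi.to_png(out / "roi.png")
    record("unmixing", k=config.k, final_error=float(result.errors[-1]),
           n_iter=int(result.errors.size),
           tissue_component=result.tissue_index)

    # --- classification --------------------------------------------------
    if truth is not None and "lesion" in truth.region_names:
        labels = truth.labels_flat()
        lesion = truth.region_index("lesion")
        tissue = truth.region_index("tissue")
        use = np.isin(labels, [lesion, tissue])
        y = np.where(labels[use] == lesion, "lesion", "tissue")
        groups = _group_ids(cube.height, cube.width, config.n_groups)[use]
        data = _classify.LabelledSpectra(cube.X[use], y, groups)
        spec = {"ridge": config.ridge}
        full_report = _classify.loocv_groups(data, spec)
        n_target = min(config.rfe_n_target, cube.n_features)
        ranking, selected = _classify.rfe(data, spec, step=config.rfe_step,
                                          n_target=n_target)
        comparison = _classify.compare_models(
            data, np.arange(cube.n_features), selected, spec)
        record("classification",
               n_samples=int(use.sum()),
               auc_full=round(full_report.auc, 6),
               auc_selected=round(comparison.selected.auc, 6),
               n_selected=int(selected.size))
        np.savetxt(out / "selected_features.tsv",
                   np.column_stack([selected, cube.axis.centers[selected]]),
                   delimiter="\t", header="feature\tmz")
        report = {
            "auc_full": full_report.auc,
            "auc_selected": comparison.selected.auc,
            "delta_auc": comparison.delta_auc,
            "positive_class": str(full_report.positive_class),
            "rfe_ranking": ranking.tolist(),
            "selected_features": selected.tolist(),
            "selected_mz": cube.axis.centers[selected].tolist(),
            "skipped_folds": [str(g) for g in full_report.skipped_groups],
        }
        (out / "classifier_report.json").write_text(
            json.dumps(report, indent=2))
        pd.DataFrame({"group": groups, "label": y,
                      "heldout_proba": full_report.proba}
                     ).to_csv(out / "heldout_probabilities.tsv",
                              sep="\t", index=False)
        pd.DataFrame({"fpr": full_report.fpr, "tpr": full_report.tpr}
                     ).to_csv(out / "roc_full.tsv", sep="\t", index=False)
        pd.DataFrame({"fpr": comparison.selected.fpr,
                      "tpr": comparison.selected.tpr}
                     ).to_csv(out / "roc_selected.tsv", sep="\t", index=False)
    else:
        record("classification", skipped="no labelled regions available")

    manifest["manifest_hash"] = manifest_hash(manifest)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True))
    return manifest


def manifest_hash(manifest: dict) -> str:
    """SHA-256 over the canonical JSON of everything except the hash
    itself and the output location (which does not affect the science)."""
    body = {k: v for k, v in manifest.items() if k != "manifest_hash"}
    body["params"] = {k: v for k, v in body.get("params", {}).items()
                      if k != "outdir"}
    return hashlib.sha256(
        json.dumps(body, sort_keys=True).encode()).hexdigest()
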