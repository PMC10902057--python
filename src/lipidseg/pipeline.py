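"""End-to-end orchestration: simulate/ingest -> preprocess -> 5-way
segmentation -> lesion-segment selection -> 4-way re-segmentation ->
region fingerprints -> statistics -> annotation.

In synthetic mode the lesion-matching segments of the initial map are
selected automatically by ground-truth overlap (the stand-in for the
IHC-guided choice made on real sections); in real-data mode the segment
ids must be supplied by the user.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, fields, replace

import numpy as np
import pandas as pd

from . import __version__
from .annotate import annotate_peaks, annotations_to_frame
from .cube import SpectraCube
from .lipids import load_library
from .phantom import (GREY_MATTER, LESION_CORE, PERI_LESION, REGION_NAMES,
                      WHITE_MATTER)
from .preprocess import preprocess_cube
from .segment import (WalkerConfig, dhc_rc_segment, map_segments_to_regions,
                      resegment)
from .simulate import NoiseModel, Section, simulate_study
from .stats import (classify_regions, compare_all, fingerprint_table,
                    pca_scores, region_fingerprint)

__all__ = ["PipelineConfig", "SectionAnalysis", "analyze_section",
           "reconstruct_regions", "run_study_analysis", "run_pipeline"]

log = logging.getLogger(__name__)

_RANGES = {
    "threshold_fraction": (0.0, 1.0),
    "tol_ppm": (0.0, 100.0),
    "max_shift_ppm": (0.0, 100.0),
    "n_segments_initial": (1, 64),
    "n_segments_reseg": (1, 64),
    "restarts": (1, 1000),
    "n_sections": (1, 1000),
    "mask_threshold": (0.0, 1.0),
}


@dataclass
class PipelineConfig:
    """Every stage parameter with provenance tracking.

    Defaults mirror the published workflow: 0.5% base-peak threshold for
    peak picking, five initial segments, four at re-segmentation,
    leave-one-sample-out random forest.
    """

    threshold_fraction: float = 0.005
    tol_ppm: float = 5.0
    max_shift_ppm: float = 10.0
    mask_method: str = "relative"
    mask_threshold: float = 0.05
    n_segments_initial: int = 5
    n_segments_reseg: int = 4
    restarts: int = 6
    exact_max: int = 12
    stats_scheme: str = "loso"
    n_estimators: int = 500
    annotation_tol_ppm: float = 5.0
    n_sections: int = 9
    width: int = 48
    height: int = 48
    effect_scale: float = 1.0
    jitter_cv: float = 0.10
    seed: int = 0
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.validate()
        for f in fields(self):
            if f.name != "provenance":
                self.provenance.setdefault(f.name, "default")

    def validate(self):
        for name, (lo, hi) in _RANGES.items():
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ValueError(f"{name}={v} outside [{lo}, {hi}]")
        if self.stats_scheme not in ("loso", "stratified-kfold"):
            raise ValueError(f"unknown stats scheme {self.stats_scheme!r}")
        if self.mask_method not in ("relative", "quantile"):
            raise ValueError(f"unknown mask method {self.mask_method!r}")

    @classmethod
    def from_dict(cls, d: dict, provenance: str = "file") -> "PipelineConfig":
        known = {f.name for f in fields(cls)} - {"provenance"}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d)
        for k in d:
            cfg.provenance[k] = provenance
        return cfg

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)
                if f.name != "provenance"}


@dataclass
class SectionAnalysis:
    """All per-section products of the segmentation workflow."""

    section_id: int
    features: object
    peaks: object
    segmap5: object
    segmap4: object | None
    region_masks: dict                 # region code -> bool mask over feature rows
    diagnostics: dict


def _select_lesion_segments(smap, label_raster):
    assignment, purity, _ = map_segments_to_regions(smap, label_raster)
    sel = [s for s, r in assignment.items() if r in (PERI_LESION, LESION_CORE)]
    if not sel:
        # fall back to the segment with the largest lesion overlap
        true = label_raster[smap.coords[:, 0], smap.coords[:, 1]]
        overlaps = [((np.isin(true, (PERI_LESION, LESION_CORE)) & (smap.labels == s)).sum(), s)
                    for s in range(smap.n_segments)]
        sel = [max(overlaps)[1]]
    return sel, assignment, purity


def _region_masks_from_maps(smap5, smap4, label_raster, assignment5):
    """Per-region pixel masks over the retained-pixel rows of smap5."""
    masks = {}
    for region in (WHITE_MATTER, GREY_MATTER):
        segs = [s for s, r in assignment5.items() if r == region]
        masks[region] = np.isin(smap5.labels, segs)
    if smap4 is not None:
        assignment4, _, _ = map_segments_to_regions(smap4, label_raster)
        key4 = {tuple(c) for c in smap4.coords.tolist()}
        idx5 = {tuple(c): i for i, c in enumerate(smap5.coords.tolist())}
        for region in (PERI_LESION, LESION_CORE):
            segs = [s for s, r in assignment4.items() if r == region]
            if not segs:
                true4 = label_raster[smap4.coords[:, 0], smap4.coords[:, 1]]
                overlaps = [(((true4 == region) & (smap4.labels == s)).sum(), s)
                            for s in range(smap4.n_segments)]
                segs = [max(overlaps)[1]]
            mask = np.zeros(len(smap5.labels), bool)
            rows4 = np.isin(smap4.labels, segs)
            for c in np.asarray(smap4.coords)[rows4]:
                mask[idx5[tuple(c.tolist())]] = True
            masks[region] = mask
    return masks


def analyze_section(cube: SpectraCube, label_raster: np.ndarray,
                    config: PipelineConfig, seed: int | None = None) -> SectionAnalysis:
    """Preprocess and segment one section, returning region pixel masks.

    ``label_raster`` provides the ground truth used (in synthetic mode)
    to select the lesion segments for re-segmentation and to name the
    resulting segments.
    """
    seed = config.seed if seed is None else seed
    pp = preprocess_cube(cube, max_shift_ppm=config.max_shift_ppm,
                         threshold_fraction=config.threshold_fraction,
                         tol_ppm=config.tol_ppm, mask_method=config.mask_method,
                         mask_threshold=config.mask_threshold)
    features = pp["features"]
    wc = WalkerConfig(restarts=config.restarts, exact_max=config.exact_max, seed=seed)
    smap5 = dhc_rc_segment(features.values, config.n_segments_initial, wc,
                           coords=features.coords, shape=features.shape)
    sel, assignment5, purity5 = _select_lesion_segments(smap5, label_raster)
    smap4 = None
    n_sel_px = int(np.isin(smap5.labels, sel).sum())
    if n_sel_px >= config.n_segments_reseg:
        smap4 = resegment(features.values, smap5, sel, config.n_segments_reseg,
                          replace(wc, seed=seed + 1))
    masks = _region_masks_from_maps(smap5, smap4, label_raster, assignment5)
    diagnostics = {"selected_segments": sel, "purity5": purity5,
                   "assignment5": assignment5, "alignment": pp["alignment"],
                   "n_tissue_pixels": int(features.n_pixels)}
    return SectionAnalysis(section_id=0, features=features, peaks=pp["peaks"],
                           segmap5=smap5, segmap4=smap4, region_masks=masks,
                           diagnostics=diagnostics)


def reconstruct_regions(analysis: SectionAnalysis, label_raster: np.ndarray) -> np.ndarray:
    """Predicted region code per retained pixel from the 5-way map plus the
    4-way re-segmentation (each final segment takes its majority region)."""
    smap5 = analysis.segmap5
    assignment5, _, _ = map_segments_to_regions(smap5, label_raster)
    recon = np.array([assignment5[s] for s in smap5.labels])
    if analysis.segmap4 is not None:
        smap4 = analysis.segmap4
        assignment4, _, _ = map_segments_to_regions(smap4, label_raster)
        idx5 = {tuple(c): i for i, c in enumerate(smap5.coords.tolist())}
        for c, s in zip(smap4.coords.tolist(), smap4.labels):
            recon[idx5[tuple(c)]] = assignment4[int(s)]
    return recon


def run_study_analysis(sections: list[Section], config: PipelineConfig,
                       library: pd.DataFrame | None = None) -> dict:
    """Analyse a cohort of sections into fingerprints, comparisons, PCA
    and the random-forest classification report."""
    library = library if library is not None else load_library()
    rows = {}
    analyses = []
    annotations = None
    for sec in sections:
        ana = analyze_section(sec.cube, sec.truth.labels, config,
                              seed=config.seed + 101 * sec.section_id)
        ana.section_id = sec.section_id
        analyses.append(ana)
        annotations = annotate_peaks(ana.peaks.mz, library,
                                     tol_ppm=config.annotation_tol_ppm)
        for region in (WHITE_MATTER, PERI_LESION, LESION_CORE):
            mask = ana.region_masks.get(region)
            if mask is None or mask.sum() == 0:
                log.warning("section %d: no pixels recovered for %s",
                            sec.section_id, REGION_NAMES[region])
                continue
            fp = region_fingerprint(ana.features, mask, annotations)
            rows[(f"S{sec.section_id}", REGION_NAMES[region])] = fp
    table = fingerprint_table(rows)
    comparisons = compare_all(table)
    pca = pca_scores(table)
    report = classify_regions(table, scheme=config.stats_scheme,
                              seed=config.seed, n_estimators=config.n_estimators)
    return {"table": table, "comparisons": comparisons, "pca": pca,
            "classification": report, "analyses": analyses,
            "annotations": annotations,
            "annotation_table": annotations_to_frame(annotations)}


def run_pipeline(config: PipelineConfig, out_dir: str,
                 input_paths: list[str] | None = None,
                 noise: NoiseModel | None = None) -> dict:
    """Full synthetic run writing tables, maps and a re-run manifest."""
    import os

    from .io import write_cube, write_labels, write_segment_map

    t_start = time.time()
    os.makedirs(out_dir, exist_ok=True)
    stage_times = {}
    if input_paths:
        raise NotImplementedError(
            "real-data ingestion requires user-supplied lesion segment ids; "
            "this entry point currently drives the synthetic study")
    t0 = time.time()
    sections = simulate_study(n_sections=config.n_sections, width=config.width,
                              height=config.height, seed=config.seed,
                              noise=noise, effect_scale=config.effect_scale,
                              jitter_cv=config.jitter_cv)
    stage_times["simulate"] = time.time() - t0

    t0 = time.time()
    results = run_study_analysis(sections, config)
    stage_times["analysis"] = time.time() - t0

    t0 = time.time()
    for sec, ana in zip(sections, results["analyses"]):
        prefix = os.path.join(out_dir, f"section{sec.section_id}")
        write_labels(sec.truth.labels, prefix + "_truth")
        write_cube(sec.cube, prefix + "_cube")
        write_segment_map(ana.segmap5, prefix + "_seg5")
        if ana.segmap4 is not None:
            write_segment_map(ana.segmap4, prefix + "_seg4")
    results["table"].to_csv(os.path.join(out_dir, "fingerprints.csv"))
    results["comparisons"].to_csv(os.path.join(out_dir, "comparisons.csv"), index=False)
    results["pca"].scores.to_csv(os.path.join(out_dir, "pca_scores.csv"))
    results["pca"].loadings.to_csv(os.path.join(out_dir, "pca_loadings.csv"))
    results["annotation_table"].to_csv(os.path.join(out_dir, "annotations.csv"), index=False)
    rep = results["classification"]
    rep.per_class.to_csv(os.path.join(out_dir, "classification_per_class.csv"))
    with open(os.path.join(out_dir, "classification_report.json"), "w") as fh:
        json.dump({"scheme": rep.scheme, "seed": rep.seed, "macro": rep.macro,
                   "confusion": rep.confusion.to_dict(),
                   "per_class": rep.per_class.to_dict()}, fh, indent=1)
    stage_times["write"] = time.time() - t0

    manifest = {
        "package_version": __version__,
        "config": config.to_dict(),
        "parameter_provenance": config.provenance,
        "noise": (noise or NoiseModel()).__dict__,
        "inputs": "synthetic",
        "stage_wall_times_s": {k: round(v, 3) for k, v in stage_times.items()},
        "total_wall_time_s": round(time.time() - t_start, 3),
    }
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    for k, v in config.to_dict().items():
        log.info("config %s = %r (%s)", k, v, config.provenance.get(k, "default"))
    return {"out_dir": out_dir, "manifest": manifest, **results}
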