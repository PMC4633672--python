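"""Configured, logged, reproducible orchestration of the four stages.

simulate -> segment -> quantify -> analyze. Segmentation runs before
quantification because the leakage correction excludes the segmented tumor
from its reference tissue; the FLAIR volume it needs is available as soon as
the cohort is simulated.

A single global seed deterministically derives every stage's randomness, and
a JSON manifest records the effective configuration hash plus a checksum of
every file each stage wrote.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import nibabel as nib
import pandas as pd
import yaml

from . import __version__
from .simulate import (AcquisitionSpec, CohortSpec, synthesize_cohort,
                       write_cohort)
from .perfusion import DeconvolutionConfig, DscSeries, quantify_subject
from .segmentation import (RegionGrowConfig, RoiMask, SeedPoint, region_grow,
                           extract_roi_values)
from .stats import (DEFAULT_PERCENTILE_LEVELS, HistogramSpec, build_profiles,
                    compare_groups, evaluate_percentiles, export_heatmap)

__all__ = ["PipelineConfig", "RunManifest", "validate_config", "run_pipeline",
           "STAGES"]

STAGES = ("simulate", "segment", "quantify", "analyze")

logger = logging.getLogger("rcbvpipe")


@dataclass
class PipelineConfig:
    out_dir: Path = Path("rcbvpipe_out")
    acquisition: AcquisitionSpec = field(default_factory=AcquisitionSpec)
    cohort: CohortSpec = field(default_factory=CohortSpec)
    deconvolution: DeconvolutionConfig = field(
        default_factory=DeconvolutionConfig)
    region_grow: RegionGrowConfig = field(default_factory=RegionGrowConfig)
    histogram: HistogramSpec = field(default_factory=HistogramSpec)
    percentile_levels: tuple = DEFAULT_PERCENTILE_LEVELS
    seed: int = 0
    log_level: str = "INFO"

    def config_hash(self) -> str:
        payload = json.dumps(_serialize(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    config_hash: str
    version: str
    stages: dict
    timestamps: dict


def _serialize(cfg: PipelineConfig) -> dict:
    d = asdict(cfg)
    d["out_dir"] = str(cfg.out_dir)
    return d


_SECTION_TYPES = {
    "acquisition": AcquisitionSpec,
    "cohort": CohortSpec,
    "deconvolution": DeconvolutionConfig,
    "region_grow": RegionGrowConfig,
    "histogram": HistogramSpec,
}


def validate_config(raw: str | Path | dict) -> PipelineConfig:
    """Build a validated PipelineConfig from a YAML file/string or a dict.

    Missing fields fall back to defaults (a missing seed defaults to 0, with
    a log line); invariant violations raise a ValueError naming the field.
    """
    if isinstance(raw, dict):
        data = dict(raw)
    else:
        path = Path(raw)
        text = path.read_text() if path.exists() else str(raw)
        data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise ValueError("config must parse to a mapping")

    kwargs: dict = {}
    for key, cls in _SECTION_TYPES.items():
        section = data.pop(key, {})
        if not isinstance(section, dict):
            raise ValueError(f"config section '{key}' must be a mapping")
        if key == "cohort":
            for tup_key in ("class_rcbv_iqr",):
                if tup_key in section:
                    section[tup_key] = {g: tuple(v)
                                        for g, v in section[tup_key].items()}
            if "tumor_radii" in section:
                section["tumor_radii"] = tuple(section["tumor_radii"])
        if key == "acquisition" and "grid_shape" in section:
            section["grid_shape"] = tuple(section["grid_shape"])
        try:
            kwargs[key] = cls(**section)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"invalid config section '{key}': {exc}") from exc

    if "out_dir" in data:
        kwargs["out_dir"] = Path(data.pop("out_dir"))
    if "percentile_levels" in data:
        kwargs["percentile_levels"] = tuple(data.pop("percentile_levels"))
    if "seed" in data:
        kwargs["seed"] = int(data.pop("seed"))
    else:
        logger.info("no seed in config; using default seed 0")
    if "log_level" in data:
        kwargs["log_level"] = str(data.pop("log_level"))
    if data:
        raise ValueError(f"unknown config keys: {sorted(data)}")

    cfg = PipelineConfig(**kwargs)
    # the cohort seed is derived from the global pipeline seed
    cfg.cohort.seed = int(
        np.random.SeedSequence(cfg.seed).spawn(1)[0].generate_state(1)[0]
        % (2 ** 31))
    logger.info("effective config: %s", json.dumps(_serialize(cfg),
                                                   sort_keys=True))
    return cfg


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_nifti(path: Path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj, dtype=float)


def _subject_dirs(cfg: PipelineConfig) -> list[Path]:
    cohort_csv = cfg.out_dir / "subjects" / "cohort.csv"
    if not cohort_csv.exists():
        raise FileNotFoundError(
            "stage requires simulate output: missing " + str(cohort_csv))
    table = pd.read_csv(cohort_csv)
    return [cfg.out_dir / "subjects" / sid for sid in table.subject_id]


def stage_simulate(cfg: PipelineConfig) -> list[Path]:
    out = cfg.out_dir / "subjects"
    subjects, table = synthesize_cohort(cfg.acquisition, cfg.cohort)
    write_cohort(subjects, table, out)
    logger.info("simulate: wrote %d subjects under %s", len(subjects), out)
    files = [out / "cohort.csv"]
    files += sorted(out.glob("sub-*/*.json"))
    return files


def stage_segment(cfg: PipelineConfig) -> list[Path]:
    """Region-grow each subject's FLAIR. The operator's seed click is
    emulated by the brightest-neighborhood voxel of the FLAIR volume."""
    files = []
    for sdir in _subject_dirs(cfg):
        flair_path = sdir / "flair.nii.gz"
        if not flair_path.exists():
            raise FileNotFoundError(
                f"segment stage: missing {flair_path} (run simulate first)")
        flair = _load_nifti(flair_path)
        # seed at the maximum of a lightly smoothed FLAIR (stands in for the
        # operator clicking inside the hyperintensity)
        from scipy.ndimage import uniform_filter
        smoothed = uniform_filter(flair, size=3)
        seed = SeedPoint(*np.unravel_index(int(np.argmax(smoothed)),
                                           flair.shape))
        roi = region_grow(flair, seed, cfg.region_grow)
        mask_path = sdir / "mask.nii.gz"
        nib.save(nib.Nifti1Image(roi.mask.astype(np.float32), np.eye(4)),
                 str(mask_path))
        files.append(mask_path)
    logger.info("segment: wrote %d masks", len(files))
    return files


def stage_quantify(cfg: PipelineConfig) -> list[Path]:
    files = []
    ss = np.random.SeedSequence(cfg.seed).spawn(2)[1]
    kmeans_seed = int(ss.generate_state(1)[0] % (2 ** 31))
    for sdir in _subject_dirs(cfg):
        dsc_path = sdir / "dsc.nii.gz"
        mask_path = sdir / "mask.nii.gz"
        for p in (dsc_path, mask_path):
            if not p.exists():
                raise FileNotFoundError(
                    f"quantify stage: missing {p} (run earlier stages first)")
        data = _load_nifti(dsc_path)
        signal = np.moveaxis(data, -1, 0)
        dsc = DscSeries(signal=signal, acquisition=cfg.acquisition,
                        brain_mask=np.ones(cfg.acquisition.grid_shape,
                                           dtype=bool))
        tumor = _load_nifti(mask_path) > 0.5
        maps, aif = quantify_subject(dsc, tumor_mask=tumor,
                                     config=cfg.deconvolution,
                                     random_state=kmeans_seed)
        for name, vol in (("rcbv", maps.rcbv), ("cbf", maps.cbf),
                          ("mtt", maps.mtt), ("k1", maps.k1), ("k2", maps.k2)):
            path = sdir / f"{name}.nii.gz"
            nib.save(nib.Nifti1Image(vol.astype(np.float32), np.eye(4)),
                     str(path))
            files.append(path)
        aif_path = sdir / "aif.json"
        aif_path.write_text(json.dumps({
            "curve": aif.curve.tolist(),
            "member_voxels": [list(v) for v in aif.member_voxels],
            "first_moment": aif.first_moment}, indent=2))
        files.append(aif_path)
    logger.info("quantify: wrote maps for %d subjects", len(files) // 6)
    return files


def stage_analyze(cfg: PipelineConfig) -> list[Path]:
    table_path = cfg.out_dir / "subjects" / "cohort.csv"
    if not table_path.exists():
        raise FileNotFoundError(
            "analyze stage: missing " + str(table_path))
    table = pd.read_csv(table_path)
    subjects = []
    for _, row in table.iterrows():
        sdir = cfg.out_dir / "subjects" / row.subject_id
        rcbv_path, mask_path = sdir / "rcbv.nii.gz", sdir / "mask.nii.gz"
        for p in (rcbv_path, mask_path):
            if not p.exists():
                raise FileNotFoundError(
                    f"analyze stage: missing {p} (run earlier stages first)")
        roi = RoiMask(mask=_load_nifti(mask_path) > 0.5)
        values = extract_roi_values(_load_nifti(rcbv_path), roi)
        pd.DataFrame({"rcbv": values}).to_csv(sdir / "roi_values.csv",
                                              index=False)
        subjects.append({"subject_id": row.subject_id,
                         "genotype": row.genotype, "values": values})

    profiles = build_profiles(subjects, cfg.histogram, cfg.percentile_levels)
    out = cfg.out_dir / "analysis"
    out.mkdir(parents=True, exist_ok=True)

    pct_rows = []
    for p in profiles:
        row = {"subject_id": p.subject_id, "genotype": p.genotype}
        row.update({f"p{lev:g}": v for lev, v in p.percentiles.items()})
        pct_rows.append(row)
    files = []
    pct_path = out / "percentiles.csv"
    pd.DataFrame(pct_rows).to_csv(pct_path, index=False)
    files.append(pct_path)

    tests_path = out / "group_tests.csv"
    compare_groups(profiles, cfg.percentile_levels).to_csv(tests_path,
                                                           index=False)
    files.append(tests_path)

    loocv_path = out / "loocv_results.csv"
    evaluate_percentiles(profiles, cfg.percentile_levels).to_csv(loocv_path,
                                                                 index=False)
    files.append(loocv_path)

    heat_csv, heat_png = out / "heatmap.csv", out / "heatmap.png"
    export_heatmap(profiles, heat_csv, heat_png, cfg.histogram)
    files += [heat_csv, heat_png]
    logger.info("analyze: wrote %s", [str(f) for f in files])
    return files


_STAGE_FUNCS = {"simulate": stage_simulate, "segment": stage_segment,
                "quantify": stage_quantify, "analyze": stage_analyze}


def run_pipeline(config: PipelineConfig,
                 stages: tuple[str, ...] = STAGES) -> RunManifest:
    """Run the requested stages in canonical order and write a manifest."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(),
                                      logging.INFO))
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    config.out_dir.mkdir(parents=True, exist_ok=True)
    (config.out_dir / "effective_config.json").write_text(
        json.dumps(_serialize(config), indent=2, sort_keys=True))

    stage_files: dict[str, dict[str, str]] = {}
    timestamps: dict[str, float] = {}
    for stage in STAGES:
        if stage not in stages:
            continue
        t0 = time.monotonic()
        files = _STAGE_FUNCS[stage](config)
        timestamps[stage] = time.monotonic() - t0
        stage_files[stage] = {str(f.relative_to(config.out_dir)): _sha256(f)
                              for f in files}
        logger.info("stage %s finished in %.1f s", stage, timestamps[stage])

    manifest = RunManifest(config_hash=config.config_hash(),
                           version=__version__, stages=stage_files,
                           timestamps=timestamps)
    (config.out_dir / "manifest.json").write_text(
        json.dumps(asdict(manifest), indent=2, sort_keys=True))
    return manifest
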