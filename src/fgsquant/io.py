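"""Readers and writers for sections, masks, and tabular data.

Conventions: nuclear and NIR channels travel together as a two-page
float32 TIFF; the RGB blue-light image is an 8-bit PNG (rescaled to [0,1]
floats on load); masks are single-page 8-bit TIFFs with 0/255 values;
identifiers, geometry and labels live in YAML sidecar files next to the
images; tables are UTF-8 comma-separated CSV with fixed headers.
"""

from __future__ import annotations

import os
from typing import Optional

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml

from .errors import PipelineIOError
from .phantom import ExVivoFragment, HomogenateRecord, MultiChannelSection
from .quantify import TNRResult
from .segmentation import RegionMask

__all__ = [
    "write_section", "load_section",
    "write_mask", "load_mask",
    "write_homogenates", "load_homogenates",
    "write_exvivo", "load_exvivo",
    "write_tnr_results", "write_exvivo_results",
]

HOMOGENATE_COLUMNS = ["animal_id", "tissue", "fluorescence_au", "weight_mg"]
EXVIVO_COLUMNS = ["sample_id", "group", "timepoint_min", "fluorescence_au",
                  "experiment_id"]
TNR_COLUMNS = ["section_id", "animal_id", "agent", "tumor_mean",
               "normal_mean", "tnr", "tumor_px", "normal_px"]


# ------------------------------------------------------------------ sections

def write_section(section: MultiChannelSection, out_dir: str,
                  stem: Optional[str] = None) -> dict[str, str]:
    """Write one section (TIFF + PNG + YAML sidecar, mask TIFF if present)."""
    os.makedirs(out_dir, exist_ok=True)
    stem = stem or section.section_id
    paths = {
        "channels": os.path.join(out_dir, f"{stem}_channels.tif"),
        "rgb": os.path.join(out_dir, f"{stem}_rgb.png"),
        "meta": os.path.join(out_dir, f"{stem}.yaml"),
    }
    stack = np.stack([section.nuclear, section.nir]).astype(np.float32)
    tifffile.imwrite(paths["channels"], stack)
    iio.imwrite(paths["rgb"],
                np.round(section.rgb * 255).astype(np.uint8))
    meta = {
        "section_id": section.section_id,
        "animal_id": section.animal_id,
        "midline_col": int(section.midline_col),
        "pages": ["nuclear", "nir"],
        "true_nir_contrast": section.true_nir_contrast,
    }
    if section.ground_truth_mask is not None:
        paths["ground_truth"] = os.path.join(out_dir, f"{stem}_gt.tif")
        tifffile.imwrite(
            paths["ground_truth"],
            (section.ground_truth_mask.astype(np.uint8) * 255))
        meta["ground_truth"] = os.path.basename(paths["ground_truth"])
    with open(paths["meta"], "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)
    return paths


def load_section(channels_path: str, rgb_path: str,
                 meta_path: str) -> MultiChannelSection:
    """Load a section written by :func:`write_section`."""
    for p in (channels_path, rgb_path, meta_path):
        if not os.path.exists(p):
            raise PipelineIOError(f"missing input file: {p}")
    try:
        stack = tifffile.imread(channels_path).astype(float)
        rgb8 = iio.imread(rgb_path)
        with open(meta_path) as fh:
            meta = yaml.safe_load(fh)
    except (OSError, ValueError) as exc:
        raise PipelineIOError(f"unreadable input: {exc}") from exc
    if stack.ndim != 3 or stack.shape[0] != 2:
        raise PipelineIOError(
            f"{channels_path}: expected 2 float pages (nuclear, nir)")
    if "midline_col" not in meta:
        raise PipelineIOError(f"{meta_path}: missing midline_col")
    nuclear, nir = stack[0], stack[1]
    if rgb8.shape[:2] != nuclear.shape:
        raise PipelineIOError(
            f"{rgb_path}: RGB shape {rgb8.shape[:2]} does not match "
            f"channel shape {nuclear.shape}")
    gt = None
    if meta.get("ground_truth"):
        gt_path = os.path.join(os.path.dirname(meta_path),
                               meta["ground_truth"])
        gt = tifffile.imread(gt_path) > 0
    return MultiChannelSection(
        nuclear=nuclear, nir=nir,
        rgb=rgb8[..., :3].astype(float) / 255.0,
        midline_col=int(meta["midline_col"]),
        section_id=str(meta.get("section_id", "S0")),
        animal_id=str(meta.get("animal_id", "A0")),
        ground_truth_mask=gt,
        true_nir_contrast=meta.get("true_nir_contrast"),
    )


# --------------------------------------------------------------------- masks

def write_mask(mask: RegionMask, path: str) -> None:
    tifffile.imwrite(path, mask.pixels.astype(np.uint8) * 255)
    with open(os.path.splitext(path)[0] + ".yaml", "w") as fh:
        yaml.safe_dump({"label": mask.label,
                        "source_channel": mask.source_channel}, fh)


def load_mask(path: str) -> RegionMask:
    if not os.path.exists(path):
        raise PipelineIOError(f"missing mask file: {path}")
    pixels = tifffile.imread(path) > 0
    sidecar = os.path.splitext(path)[0] + ".yaml"
    label, source = "tissue", "nuclear"
    if os.path.exists(sidecar):
        with open(sidecar) as fh:
            meta = yaml.safe_load(fh) or {}
        label = meta.get("label", label)
        source = meta.get("source_channel", source)
    return RegionMask(pixels, label, source)


# -------------------------------------------------------------------- tables

def write_homogenates(records: list[HomogenateRecord], path: str) -> None:
    pd.DataFrame(
        [(r.animal_id, r.tissue, r.fluorescence, r.weight) for r in records],
        columns=HOMOGENATE_COLUMNS).to_csv(path, index=False, float_format="%.17g")


def load_homogenates(path: str) -> list[HomogenateRecord]:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(HOMOGENATE_COLUMNS) - set(df.columns)
    if missing:
        raise PipelineIOError(f"{path}: missing columns {sorted(missing)}")
    return [HomogenateRecord(str(r.animal_id), str(r.tissue),
                             float(r.fluorescence_au), float(r.weight_mg))
            for r in df.itertuples(index=False)]


def write_exvivo(fragments: list[ExVivoFragment], path: str) -> None:
    pd.DataFrame(
        [(f.sample_id, f.group, f.timepoint, f.fluorescence, f.experiment_id)
         for f in fragments],
        columns=EXVIVO_COLUMNS).to_csv(path, index=False, float_format="%.17g")


def load_exvivo(path: str) -> list[ExVivoFragment]:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(EXVIVO_COLUMNS) - set(df.columns)
    if missing:
        raise PipelineIOError(f"{path}: missing columns {sorted(missing)}")
    return [ExVivoFragment(str(r.sample_id), str(r.group),
                           float(r.timepoint_min), float(r.fluorescence_au),
                           str(r.experiment_id))
            for r in df.itertuples(index=False)]


def write_tnr_results(results: list[TNRResult], path: str) -> None:
    pd.DataFrame(
        [(r.section_id, r.animal_id, r.agent, r.tumor_mean, r.normal_mean,
          r.tnr, r.tumor_pixels, r.normal_pixels) for r in results],
        columns=TNR_COLUMNS).to_csv(path, index=False, float_format="%.17g")


def write_exvivo_results(rows: list[tuple[ExVivoFragment, float]],
                         path: str) -> None:
    pd.DataFrame(
        [(f.sample_id, f.group, f.timepoint, v) for f, v in rows],
        columns=["sample_id", "group", "timepoint_min",
                 "normalized_fluorescence"]).to_csv(path, index=False, float_format="%.17g")
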