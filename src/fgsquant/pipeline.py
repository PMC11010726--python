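"""End-to-end orchestration: simulate/load -> segment -> quantify ->
project -> compare, with a single resolved configuration and seed.

Every run writes, next to its result tables, the fully resolved
configuration (including defaults and the package version) so outputs are
reproducible from their sidecars alone.  All randomness flows from the
single config seed; identical config + seed produce byte-identical output
files.  Outputs are computed fully before anything is written, so a failed
stage leaves no partial CSV behind.
"""

from __future__ import annotations

import dataclasses
import glob
import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import yaml

from . import __version__
from .colorproj import (ProjectionVector, mean_projection, median_color,
                        optimal_projection, ppix_tnr)
from .errors import FgsQuantError, ParameterError, PipelineIOError
from .io import load_section, write_tnr_results
from .phantom import MultiChannelSection, PhantomSpec, generate_cohort
from .quantify import TNRResult, cohort_table, paired_values
from .segmentation import hemisphere_roi, mirror_roi, segment_tumor
from .stats import TestResult, mann_whitney, paired_t, wilcoxon_signed_rank

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass(frozen=True)
class PipelineConfig:
    """Resolved parameterization of one end-to-end run."""

    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    input_dir: Optional[str] = None  # load sections instead of simulating
    n_animals: int = 10
    sections_per_animal: int = 3
    between_animal_cv: float = 0.55
    min_area: int = 25
    smoothing_radius: int = 1
    normal_roi: str = "mirror"  # "mirror" | "hemisphere"
    projection_mode: str = "clamp"  # "clamp" | "offset"
    projection_nonnegative: bool = False
    stat_test: str = "wilcoxon"  # "wilcoxon" | "paired_t" | "mann_whitney"
    agent_nir: str = "6QC-ICG"
    agent_ppix: str = "5-ALA"
    aggregation: str = "mean_sections"  # | "pooled"
    out_dir: str = "fgsquant_run"
    seed: int = 0
    force: bool = False

    def validate(self) -> None:
        if self.normal_roi not in ("mirror", "hemisphere"):
            raise ParameterError(f"unknown normal_roi: {self.normal_roi!r}")
        if self.projection_mode not in ("clamp", "offset"):
            raise ParameterError(
                f"unknown projection_mode: {self.projection_mode!r}")
        if self.stat_test not in ("wilcoxon", "paired_t", "mann_whitney"):
            raise ParameterError(f"unknown stat_test: {self.stat_test!r}")
        if self.input_dir is None:
            self.phantom.validate()

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        ph = raw.pop("phantom", {})
        if isinstance(ph, dict):
            for key in ("tumor_center", "tumor_axes", "ppix_tumor_color",
                        "ppix_background_color"):
                if key in ph:
                    ph[key] = tuple(ph[key])
            ph = PhantomSpec(**ph)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        return cls(phantom=ph, **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("tumor_center", "tumor_axes", "ppix_tumor_color",
                    "ppix_background_color"):
            d["phantom"][key] = list(d["phantom"][key])
        return d


@dataclass
class PipelineResult:
    section_results: list[TNRResult]
    animal_table: "object"  # pandas DataFrame: animal_id, agent, tnr
    mean_vector: ProjectionVector
    per_sample_vectors: list[ProjectionVector]
    test_result: TestResult
    out_dir: str


_STAGE_TESTS = {"wilcoxon": wilcoxon_signed_rank, "paired_t": paired_t,
                "mann_whitney": mann_whitney}


def _load_sections(input_dir: str) -> list[MultiChannelSection]:
    metas = sorted(glob.glob(os.path.join(input_dir, "*.yaml")))
    metas = [m for m in metas if not m.endswith(("_gt.yaml",))]
    sections = []
    for meta in metas:
        stem = os.path.splitext(meta)[0]
        chan, rgb = stem + "_channels.tif", stem + "_rgb.png"
        if os.path.exists(chan) and os.path.exists(rgb):
            sections.append(load_section(chan, rgb, meta))
    if not sections:
        raise PipelineIOError(f"no loadable sections under {input_dir!r}")
    return sections


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the full comparison workflow and write the result bundle."""
    config.validate()
    out = config.out_dir
    existing = [f for f in ("sections.csv", "animals.csv", "stats.yaml")
                if os.path.exists(os.path.join(out, f))]
    if existing and not config.force:
        raise PipelineIOError(
            f"outputs already exist in {out!r} ({existing}); use force")

    log: list[str] = [f"fgsquant {__version__}"]
    if config.input_dir is not None:
        sections = _load_sections(config.input_dir)
        log.append(f"loaded {len(sections)} sections from {config.input_dir}")
    else:
        sections = generate_cohort(
            config.phantom, config.n_animals, config.sections_per_animal,
            config.between_animal_cv, config.seed)
        log.append(f"simulated {len(sections)} sections "
                   f"({config.n_animals} animals)")

    section_results: list[TNRResult] = []
    vectors: list[ProjectionVector] = []
    tumor_masks, normal_masks = [], []
    for sec in sections:
        try:
            tumor = segment_tumor(sec.nuclear, config.min_area,
                                  config.smoothing_radius)
            if config.normal_roi == "mirror":
                normal = mirror_roi(tumor, sec.midline_col)
            else:
                normal = hemisphere_roi(sec.nuclear, sec.midline_col, tumor)
        except FgsQuantError as exc:
            raise type(exc)(
                f"[segmentation, section {sec.section_id}] {exc}") from exc
        tumor_masks.append(tumor)
        normal_masks.append(normal)
        try:
            from .quantify import compute_tnr
            section_results.append(compute_tnr(
                sec.nir, tumor, normal, section_id=sec.section_id,
                animal_id=sec.animal_id, agent=config.agent_nir))
            vectors.append(optimal_projection(
                median_color(sec.rgb, tumor), median_color(sec.rgb, normal),
                nonnegative=config.projection_nonnegative))
        except FgsQuantError as exc:
            raise type(exc)(
                f"[quantification, section {sec.section_id}] {exc}") from exc

    mean_vec = mean_projection(vectors)
    log.append(f"mean projection vector: {mean_vec.v.round(4).tolist()}")
    for sec, tumor, normal in zip(sections, tumor_masks, normal_masks):
        try:
            section_results.append(ppix_tnr(
                sec.rgb, tumor, normal, mean_vec, mode=config.projection_mode,
                section_id=sec.section_id, animal_id=sec.animal_id,
                agent=config.agent_ppix))
        except FgsQuantError as exc:
            raise type(exc)(
                f"[projection, section {sec.section_id}] {exc}") from exc

    animals = cohort_table(section_results, method=config.aggregation)
    a, b = paired_values(animals, config.agent_nir, config.agent_ppix)
    test = _STAGE_TESTS[config.stat_test](a, b)
    log.append(f"{config.stat_test}: statistic={test.statistic:.4g} "
               f"p={test.p_value:.4g} n={test.n} ({test.method})")

    os.makedirs(out, exist_ok=True)
    write_tnr_results(section_results, os.path.join(out, "sections.csv"))
    animals.to_csv(os.path.join(out, "animals.csv"), index=False)
    with open(os.path.join(out, "vectors.yaml"), "w") as fh:
        yaml.safe_dump({
            "mean_projection_vector": mean_vec.v.tolist(),
            "per_sample_vectors": [p.v.tolist() for p in vectors],
            "projection_mode": config.projection_mode,
        }, fh, sort_keys=True)
    with open(os.path.join(out, "stats.yaml"), "w") as fh:
        yaml.safe_dump({
            "test": config.stat_test,
            "statistic": float(test.statistic),
            "p_value": float(test.p_value),
            "n": int(test.n),
            "method": test.method,
            "agents": [config.agent_nir, config.agent_ppix],
        }, fh, sort_keys=True)
    with open(os.path.join(out, "config.yaml"), "w") as fh:
        yaml.safe_dump({"fgsquant_version": __version__,
                        "config": config.to_dict()}, fh, sort_keys=True)
    with open(os.path.join(out, "run.log"), "w") as fh:
        fh.write("\n".join(log) + "\n")

    return PipelineResult(section_results, animals, mean_vec, vectors,
                          test, out)
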