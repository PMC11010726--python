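"""Scalar readouts: TNR, normalization, section CV, homogenate TNR, MFI
ratio, ex-vivo normalization and fold differences.

All readouts are ratios of arithmetic means and therefore invariant to a
common positive gain on the intensities — the property that makes them
comparable across instruments with different (linear) sensitivities.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import InputError, MaskError, QuantificationError
from .phantom import ExVivoFragment, HomogenateRecord
from .segmentation import RegionMask

__all__ = [
    "TNRResult",
    "compute_tnr",
    "normalize_to_normal",
    "section_cv",
    "animal_tnr",
    "cohort_table",
    "paired_values",
    "homogenate_tnr",
    "mfi_ratio",
    "normalize_exvivo",
    "fold_difference",
]


@dataclass(frozen=True)
class TNRResult:
    """Tumor-to-normal ratio of one section/channel, with provenance."""

    tumor_mean: float
    normal_mean: float
    tnr: float
    tumor_pixels: int
    normal_pixels: int
    section_id: str = "S0"
    animal_id: str = "A0"
    agent: str = ""


def compute_tnr(channel: np.ndarray, tumor_mask: RegionMask,
                normal_mask: RegionMask, section_id: str = "S0",
                animal_id: str = "A0", agent: str = "") -> TNRResult:
    """Mean tumor intensity over mean normal intensity.

    Masks must be non-empty, disjoint, and match the channel shape; the
    normal mean must be positive for the ratio to exist.
    """
    channel = np.asarray(channel, dtype=float)
    for m in (tumor_mask, normal_mask):
        if m.pixels.shape != channel.shape:
            raise MaskError("mask shape does not match channel")
        if not m.pixels.any():
            raise MaskError("empty mask")
    if (tumor_mask.pixels & normal_mask.pixels).any():
        raise MaskError("tumor and normal masks overlap")
    tumor_mean = float(channel[tumor_mask.pixels].mean())
    normal_mean = float(channel[normal_mask.pixels].mean())
    if normal_mean <= 0:
        raise QuantificationError(
            "normal-region mean is non-positive; TNR undefined")
    return TNRResult(tumor_mean, normal_mean, tumor_mean / normal_mean,
                     tumor_mask.area, normal_mask.area,
                     section_id, animal_id, agent)


def normalize_to_normal(channel: np.ndarray,
                        normal_mask: RegionMask) -> np.ndarray:
    """Divide every pixel by the mean over the normal-brain ROI.

    The output is dimensionless with mean exactly 1 over the normal mask;
    applying the operation twice is a no-op.
    """
    channel = np.asarray(channel, dtype=float)
    if normal_mask.pixels.shape != channel.shape:
        raise MaskError("mask shape does not match channel")
    ref = channel[normal_mask.pixels].mean()
    if ref <= 0:
        raise QuantificationError("normal-region mean is non-positive")
    return channel / ref


def section_cv(per_section_tnrs: Sequence[float]) -> float:
    """Coefficient of variation (sample sd / mean) of per-section TNRs."""
    values = np.asarray(per_section_tnrs, dtype=float)
    if values.size < 2:
        raise InputError("CV needs at least two sections")
    if (values <= 0).any():
        raise InputError("TNRs must be positive")
    return float(values.std(ddof=1) / values.mean())


def animal_tnr(results: Sequence[TNRResult],
               method: str = "mean_sections") -> float:
    """Aggregate per-section TNRs of one animal into a single value.

    ``mean_sections`` (default) treats each section as one observation;
    ``pooled`` pools pixels, i.e. ratio of pixel-count-weighted means.
    """
    if not results:
        raise InputError("no section results to aggregate")
    if method == "mean_sections":
        return float(np.mean([r.tnr for r in results]))
    if method == "pooled":
        t = sum(r.tumor_mean * r.tumor_pixels for r in results) / \
            sum(r.tumor_pixels for r in results)
        n = sum(r.normal_mean * r.normal_pixels for r in results) / \
            sum(r.normal_pixels for r in results)
        if n <= 0:
            raise QuantificationError("pooled normal mean is non-positive")
        return float(t / n)
    raise InputError(f"unknown aggregation method: {method!r}")


def cohort_table(results: Iterable[TNRResult],
                 method: str = "mean_sections") -> pd.DataFrame:
    """Per-animal, per-agent TNR table (one row per animal per agent)."""
    rows = [(r.animal_id, r.agent, r) for r in results]
    if not rows:
        raise InputError("no results")
    df = pd.DataFrame(rows, columns=["animal_id", "agent", "result"])
    out = (df.groupby(["animal_id", "agent"], sort=True)["result"]
             .apply(lambda rs: animal_tnr(list(rs), method=method))
             .rename("tnr").reset_index())
    return out


def paired_values(table: pd.DataFrame, agent_a: str, agent_b: str,
                  pair_on: str = "animal_id",
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Align two agents' TNRs by animal for a paired comparison."""
    a = table[table["agent"] == agent_a].set_index(pair_on)["tnr"]
    b = table[table["agent"] == agent_b].set_index(pair_on)["tnr"]
    common = a.index.intersection(b.index)
    if len(common) < len(a) or len(common) < len(b):
        raise InputError("paired analysis requires every animal under "
                         "both agents")
    common = common.sort_values()
    return a.loc[common].to_numpy(), b.loc[common].to_numpy()


def homogenate_tnr(records: Sequence[HomogenateRecord], animal_id: str,
                   denominator: str = "weight") -> float:
    """Weight- (or protein-) normalized homogenate TNR for one animal.

    (tumor fluorescence / tumor denominator) over the same quantity in
    normal tissue; requires exactly one tumor and one normal record.
    """
    if denominator not in ("weight", "protein"):
        raise InputError(f"unknown denominator: {denominator!r}")
    mine = [r for r in records if r.animal_id == animal_id]
    tum = [r for r in mine if r.tissue == "tumor"]
    nor = [r for r in mine if r.tissue == "normal"]
    if len(tum) != 1 or len(nor) != 1:
        raise InputError(
            f"animal {animal_id!r} needs exactly one tumor and one normal "
            f"record (got {len(tum)}/{len(nor)})")

    def per_unit(r: HomogenateRecord) -> float:
        d = getattr(r, denominator)
        if d is None or d <= 0:
            raise InputError(
                f"non-positive {denominator} for {r.animal_id}/{r.tissue}")
        return r.fluorescence / d

    denom = per_unit(nor[0])
    if denom <= 0:
        raise InputError("normal per-unit fluorescence must be positive")
    return per_unit(tum[0]) / denom


def mfi_ratio(stained_mfi: float, unstained_mfi: float) -> float:
    """Stained/unstained mean-fluorescence-intensity ratio."""
    if unstained_mfi <= 0:
        raise InputError("unstained MFI must be positive")
    return stained_mfi / unstained_mfi


def normalize_exvivo(fragments: Sequence[ExVivoFragment], experiment_id: str,
                     ) -> list[tuple[ExVivoFragment, float]]:
    """Normalize fragment fluorescence to the reference group.

    Within one experiment, every fragment reading is divided by the mean
    fluorescence of the reference-tissue fragments at the same timepoint,
    removing between-experiment instrument/batch factors.  The reference
    group's normalized mean is 1 at every timepoint by construction.
    """
    mine = [f for f in fragments if f.experiment_id == experiment_id]
    if not mine:
        raise InputError(f"no fragments for experiment {experiment_id!r}")
    refs = [f for f in mine if f.group == "reference"]
    if not refs:
        raise InputError(
            f"experiment {experiment_id!r} has no reference fragment")
    ref_mean: dict[float, float] = {}
    for t in sorted({f.timepoint for f in mine}):
        at_t = [f.fluorescence for f in refs if f.timepoint == t]
        if not at_t:
            raise InputError(
                f"no reference reading at timepoint {t} in {experiment_id!r}")
        m = float(np.mean(at_t))
        if m <= 0:
            raise InputError("reference mean must be positive")
        ref_mean[t] = m
    return [(f, f.fluorescence / ref_mean[f.timepoint]) for f in mine]


def fold_difference(group_a_values: Sequence[float],
                    group_b_values: Sequence[float]) -> float:
    """Ratio of group means, mean(a) / mean(b)."""
    a = np.asarray(group_a_values, dtype=float)
    b = np.asarray(group_b_values, dtype=float)
    if a.size == 0 or b.size == 0:
        raise InputError("both groups must be non-empty")
    if (a <= 0).any() or (b <= 0).any():
        raise InputError("values must be positive")
    return float(a.mean() / b.mean())
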