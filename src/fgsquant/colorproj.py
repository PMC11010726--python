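"""Discriminative RGB-to-grayscale conversion for PPIX blue-light images.

Under blue light, PPIX-accumulating tumor tissue appears red-pink over a
blue background; a fixed luminance conversion largely discards that hue
contrast.  Instead, each RGB pixel is mapped to its scalar product with a
unit *projection vector* chosen to maximize the separation between the
median tumor color and the median healthy-tissue color.  With the unit-norm
constraint the maximizer has a closed form: the normalized difference of
the two median colors, signed so tumor projects higher than normal.  The
per-sample vectors of a cohort are averaged (and re-normalized) to give a
single conversion applied to all images, whose projected grayscale then
feeds the ordinary TNR computation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import (AggregationError, NoSeparationError, ParameterError,
                     QuantificationError)
from .quantify import TNRResult, compute_tnr
from .segmentation import RegionMask

__all__ = [
    "ProjectionVector",
    "median_color",
    "optimal_projection",
    "mean_projection",
    "project_to_gray",
    "ppix_tnr",
]


@dataclass(frozen=True)
class ProjectionVector:
    """A unit-norm RGB weight vector; projection = v . (R, G, B)."""

    v: np.ndarray  # shape (3,), unit Euclidean norm

    def __post_init__(self) -> None:
        v = np.asarray(self.v, dtype=float)
        if v.shape != (3,):
            raise ParameterError("projection vector must have 3 components")
        if not np.isclose(np.linalg.norm(v), 1.0, atol=1e-8):
            raise ParameterError("projection vector must have unit norm")
        object.__setattr__(self, "v", v)

    @classmethod
    def from_direction(cls, d: np.ndarray) -> "ProjectionVector":
        d = np.asarray(d, dtype=float)
        n = np.linalg.norm(d)
        if n == 0:
            raise ParameterError("zero direction has no unit vector")
        return cls(d / n)


def median_color(rgb: np.ndarray, mask: RegionMask) -> np.ndarray:
    """Channel-wise (marginal) median color over the mask pixels."""
    rgb = np.asarray(rgb, dtype=float)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ParameterError("rgb must be H x W x 3")
    if rgb.shape[:2] != mask.pixels.shape:
        raise ParameterError("mask shape does not match image")
    if not mask.pixels.any():
        raise ParameterError("empty mask")
    return np.median(rgb[mask.pixels], axis=0)


def optimal_projection(median_tumor: np.ndarray, median_normal: np.ndarray,
                       nonnegative: bool = False) -> ProjectionVector:
    """Unit vector maximizing the projected distance of two median colors.

    argmax over unit v of |v.m_T - v.m_N| is the normalized difference
    m_T - m_N, with the sign fixed so the tumor projects higher.  With
    ``nonnegative=True`` the search is restricted to the non-negative
    orthant (clip the difference at zero; if no component is positive,
    the best feasible vector is the axis of the largest component).
    """
    d = np.asarray(median_tumor, dtype=float) - \
        np.asarray(median_normal, dtype=float)
    if np.linalg.norm(d) < 1e-12:
        raise NoSeparationError(
            "tumor and normal median colors coincide; no projection "
            "direction separates them")
    if nonnegative:
        dpos = np.clip(d, 0.0, None)
        if dpos.max() <= 0:
            axis = np.zeros(3)
            axis[int(np.argmax(d))] = 1.0
            return ProjectionVector(axis)
        return ProjectionVector.from_direction(dpos)
    return ProjectionVector.from_direction(d)


def mean_projection(vectors: list[ProjectionVector]) -> ProjectionVector:
    """Arithmetic mean of unit vectors, re-normalized to unit norm."""
    if not vectors:
        raise AggregationError("no projection vectors to average")
    m = np.mean([p.v for p in vectors], axis=0)
    if np.linalg.norm(m) < 1e-9:
        raise AggregationError(
            "projection vectors cancel (antipodal); mean has no direction")
    return ProjectionVector.from_direction(m)


def project_to_gray(rgb: np.ndarray, v: ProjectionVector,
                    mode: str = "clamp") -> np.ndarray:
    """Scalar-product grayscale conversion of an RGB image.

    ``clamp`` (default) sets negative projections to zero — projected
    values proportional to PPIX-specific signal cannot meaningfully be
    negative.  ``offset`` instead shifts the whole image up by its global
    minimum when that minimum is negative, preserving linear structure.
    """
    rgb = np.asarray(rgb, dtype=float)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ParameterError("rgb must be H x W x 3")
    gray = rgb @ v.v
    if mode == "clamp":
        return np.maximum(gray, 0.0)
    if mode == "offset":
        lo = gray.min()
        return gray - lo if lo < 0 else gray
    raise ParameterError(f"unknown projection mode: {mode!r}")


def ppix_tnr(rgb: np.ndarray, tumor_mask: RegionMask,
             normal_mask: RegionMask, v: ProjectionVector,
             mode: str = "clamp", section_id: str = "S0",
             animal_id: str = "A0", agent: str = "5-ALA") -> TNRResult:
    """TNR of the projected grayscale PPIX image."""
    gray = project_to_gray(rgb, v, mode=mode)
    try:
        return compute_tnr(gray, tumor_mask, normal_mask,
                           section_id=section_id, animal_id=animal_id,
                           agent=agent)
    except QuantificationError as exc:
        raise QuantificationError(
            f"{exc}; with mode='clamp' a fully clamped normal region can "
            "cause this — consider mode='offset'") from exc
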