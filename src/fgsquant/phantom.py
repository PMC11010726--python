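"""Synthetic fluorescence phantoms with known ground truth.

Emulates the data a coronal-section imaging workflow produces when a
contrast agent is compared against 5-ALA/PPIX in an orthotopic glioma
model: co-registered nuclear-dye / NIR / RGB blue-light section images,
paired tumor-normal homogenate fluorescence tables, and ex-vivo fragment
time courses.  Every generator is a pure function of its parameters and
an explicit seed, and records the ground truth it used, so downstream
estimators can be tested for parameter recovery without any external data.

Geometry convention: 0-based (row, col), origin top-left.  The tumor is a
single ellipse placed in one hemisphere; the hemispheric midline is a pixel
column.  Intensities are in arbitrary units (AU) and must be non-negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import distance_transform_edt

from .errors import GeometryError, ParameterError

__all__ = [
    "PhantomSpec",
    "MultiChannelSection",
    "HomogenateRecord",
    "ExVivoFragment",
    "ellipse_mask",
    "generate_section",
    "draw_contrasts",
    "draw_paired_contrasts",
    "generate_cohort",
    "generate_paired_cohort",
    "generate_homogenates",
    "generate_exvivo",
]

#: timepoints (minutes) used in the ex-vivo activation experiment
EXVIVO_TIMEPOINTS = (2, 5, 10, 120)


@dataclass(frozen=True)
class PhantomSpec:
    """Full parameterization of one synthetic coronal section.

    The defaults describe the study conditions the pipeline is meant to
    recover: a high-cell-density elliptical tumor in the right hemisphere,
    an NIR probe channel with true tumor:normal contrast ``nir_contrast``
    (default 30, the order of magnitude reported for a cathepsin-activated
    ICG probe), and an RGB blue-light channel in which tumor pixels are a
    red-pink PPIX-like mixture over a blue background.
    """

    image_height: int = 192
    image_width: int = 192
    midline_col: int = 96
    tumor_center: tuple[int, int] = (96, 144)
    tumor_axes: tuple[int, int] = (26, 20)  # (semi-axis rows, semi-axis cols)
    nuclear_tumor_level: float = 1.0
    nuclear_background_level: float = 0.1
    nir_contrast: float = 30.0  # true tumor:normal ratio rho >= 1
    nir_normal_level: float = 1.0
    gaussian_noise_sd: float = 0.05  # AU, additive, shared by nuclear and NIR
    infiltration_width: int = 0  # px; linear signal decay band around tumor
    ppix_tumor_color: tuple[float, float, float] = (0.80, 0.20, 0.24)
    ppix_background_color: tuple[float, float, float] = (0.20, 0.20, 0.45)
    ppix_color_jitter_sd: float = 0.02
    seed: int = 0

    def validate(self) -> None:
        if self.image_height < 4 or self.image_width < 4:
            raise ParameterError("image dimensions must be at least 4 px")
        if not 0 < self.midline_col < self.image_width - 1:
            raise ParameterError("midline_col must be an interior column")
        for name in ("nuclear_tumor_level", "nuclear_background_level",
                     "nir_normal_level"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be strictly positive")
        if self.nir_contrast < 1:
            raise ParameterError("nir_contrast must be >= 1")
        if self.gaussian_noise_sd < 0 or self.ppix_color_jitter_sd < 0:
            raise ParameterError("noise/jitter sd must be >= 0")
        if self.infiltration_width < 0:
            raise ParameterError("infiltration_width must be >= 0")
        ar, ac = self.tumor_axes
        if ar <= 0 or ac <= 0:
            raise ParameterError("tumor semi-axes must be positive")
        for c in (*self.ppix_tumor_color, *self.ppix_background_color):
            if not 0.0 <= c <= 1.0:
                raise ParameterError("RGB components must lie in [0, 1]")
        r0, c0 = self.tumor_center
        if not (0 <= r0 < self.image_height and 0 <= c0 < self.image_width):
            raise ParameterError("tumor_center must lie inside the image")
        # the ellipse (including the infiltration band) must stay on one
        # side of the midline so a mirrored contralateral ROI exists
        reach = ac + self.infiltration_width
        if c0 > self.midline_col:
            if c0 - reach <= self.midline_col:
                raise GeometryError("tumor ellipse crosses the midline")
        elif c0 < self.midline_col:
            if c0 + reach >= self.midline_col:
                raise GeometryError("tumor ellipse crosses the midline")
        else:
            raise GeometryError("tumor centered on the midline")


@dataclass
class MultiChannelSection:
    """One co-registered coronal section (nuclear, NIR, RGB channels)."""

    nuclear: np.ndarray  # H x W, AU >= 0
    nir: np.ndarray      # H x W, AU >= 0
    rgb: np.ndarray      # H x W x 3 in [0, 1]
    midline_col: int
    section_id: str = "S0"
    animal_id: str = "A0"
    ground_truth_mask: Optional[np.ndarray] = None  # H x W bool (synthetic only)
    true_nir_contrast: Optional[float] = None

    def validate(self) -> None:
        if self.nuclear.shape != self.nir.shape or \
                self.rgb.shape[:2] != self.nuclear.shape:
            raise ParameterError("channel dimensions disagree")
        if self.nuclear.min() < 0 or self.nir.min() < 0:
            raise ParameterError("negative intensities are not allowed")
        if self.rgb.min() < 0 or self.rgb.max() > 1:
            raise ParameterError("RGB values must lie in [0, 1]")
        if self.ground_truth_mask is not None and \
                self.ground_truth_mask.shape != self.nuclear.shape:
            raise ParameterError("ground-truth mask shape mismatch")


@dataclass(frozen=True)
class HomogenateRecord:
    """One spectrofluorimetric reading of a homogenized tissue sample."""

    animal_id: str
    tissue: str  # "tumor" | "normal"
    fluorescence: float  # AU > 0
    weight: float  # mg > 0
    protein: Optional[float] = None  # mg, optional alternative denominator


@dataclass(frozen=True)
class ExVivoFragment:
    """One fragment x timepoint fluorescence reading in the ex-vivo assay."""

    sample_id: str
    group: str  # "GBM" | "PRE" | "reference"
    timepoint: float  # minutes
    fluorescence: float  # AU > 0
    experiment_id: str


def ellipse_mask(shape: tuple[int, int], center: tuple[int, int],
                 axes: tuple[int, int]) -> np.ndarray:
    """Rasterize a filled ellipse by testing pixel centers."""
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    r0, c0 = center
    ar, ac = axes
    return ((rr - r0) / ar) ** 2 + ((cc - c0) / ac) ** 2 <= 1.0


def _tumor_profile(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Return (core ellipse mask, [0,1] signal profile with margin ramp)."""
    core = ellipse_mask((spec.image_height, spec.image_width),
                        spec.tumor_center, spec.tumor_axes)
    if spec.infiltration_width == 0:
        return core, core.astype(float)
    # linear decay over `infiltration_width` pixels of Euclidean distance
    # from the tumor edge, standing in for an infiltrating-cell margin
    dist = distance_transform_edt(~core)
    profile = np.clip(1.0 - dist / spec.infiltration_width, 0.0, 1.0)
    profile[core] = 1.0
    return core, profile


def generate_section(spec: PhantomSpec, seed: Optional[int] = None,
                     section_id: str = "S0", animal_id: str = "A0",
                     ) -> MultiChannelSection:
    """Render one synthetic multi-channel section.

    Noiseless construction guarantees: mean NIR inside the tumor ellipse
    divided by mean NIR anywhere outside the margin equals ``nir_contrast``
    exactly, and the nuclear channel is exactly two-level.  Identical
    (spec, seed) pairs yield bit-identical arrays.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    core, profile = _tumor_profile(spec)

    nuclear = spec.nuclear_background_level + \
        (spec.nuclear_tumor_level - spec.nuclear_background_level) * profile
    nir = spec.nir_normal_level * (1.0 + (spec.nir_contrast - 1.0) * profile)
    rgb = np.asarray(spec.ppix_background_color) + \
        (np.asarray(spec.ppix_tumor_color) -
         np.asarray(spec.ppix_background_color)) * profile[..., None]

    if spec.gaussian_noise_sd > 0:
        nuclear = nuclear + rng.normal(0.0, spec.gaussian_noise_sd,
                                       nuclear.shape)
        nir = nir + rng.normal(0.0, spec.gaussian_noise_sd, nir.shape)
    if spec.ppix_color_jitter_sd > 0:
        rgb = rgb + rng.normal(0.0, spec.ppix_color_jitter_sd, rgb.shape)

    section = MultiChannelSection(
        nuclear=np.maximum(nuclear, 0.0),
        nir=np.maximum(nir, 0.0),
        rgb=np.clip(rgb, 0.0, 1.0),
        midline_col=spec.midline_col,
        section_id=section_id,
        animal_id=animal_id,
        ground_truth_mask=core,
        true_nir_contrast=spec.nir_contrast,
    )
    section.validate()
    return section


def _lognormal_sigma(cv: float) -> float:
    # CV of a lognormal depends only on sigma: cv^2 = exp(sigma^2) - 1
    return float(np.sqrt(np.log1p(cv * cv)))


def draw_contrasts(median: float, cv: float, n: int,
                   rng: np.random.Generator) -> np.ndarray:
    """Draw per-animal true contrasts, lognormal with the given median/CV."""
    if n < 1:
        raise ParameterError("need at least one animal")
    if cv < 0:
        raise ParameterError("between-animal CV must be >= 0")
    if cv == 0:
        return np.full(n, float(median))
    sigma = _lognormal_sigma(cv)
    # floor at 1: an activatable probe is never dimmer in tumor than in
    # normal brain, and downstream generators require rho >= 1
    return np.maximum(median * np.exp(sigma * rng.standard_normal(n)), 1.0)


def draw_paired_contrasts(median_a: float, median_b: float, cv_a: float,
                          cv_b: float, shared_cv: float, n: int,
                          rng: np.random.Generator,
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Draw correlated per-animal contrasts for two coadministered agents.

    Both agents are given to the same animal, so per-animal TNRs share a
    common biological factor (tumor size, cellularity, vascular leak).  The
    shared factor is lognormal with CV ``shared_cv``; agent-specific factors
    absorb the remaining log-variance so the marginal CVs equal cv_a / cv_b.
    ``shared_cv`` is capped so neither specific variance goes negative.
    """
    if n < 1:
        raise ParameterError("need at least one animal")
    sa, sb = _lognormal_sigma(cv_a), _lognormal_sigma(cv_b)
    ss = min(_lognormal_sigma(shared_cv), sa, sb)
    shared = np.exp(ss * rng.standard_normal(n))
    spec_a = np.exp(np.sqrt(sa * sa - ss * ss) * rng.standard_normal(n))
    spec_b = np.exp(np.sqrt(sb * sb - ss * ss) * rng.standard_normal(n))
    return (np.maximum(median_a * shared * spec_a, 1.0),
            np.maximum(median_b * shared * spec_b, 1.0))


def generate_cohort(spec: PhantomSpec, n_animals: int,
                    sections_per_animal: int, between_animal_cv: float,
                    seed: int) -> list[MultiChannelSection]:
    """Render a cohort; each animal draws its own true contrast.

    Per-animal contrast is lognormal with median ``spec.nir_contrast`` and
    the requested coefficient of variation; it is recorded on every section
    as ``true_nir_contrast``.
    """
    if n_animals < 1 or sections_per_animal < 1:
        raise ParameterError("animal and section counts must be positive")
    rng = np.random.default_rng(seed)
    rhos = draw_contrasts(spec.nir_contrast, between_animal_cv, n_animals, rng)
    sections = []
    for i, rho in enumerate(rhos):
        animal_spec = replace(spec, nir_contrast=float(rho))
        for j in range(sections_per_animal):
            sections.append(generate_section(
                animal_spec, seed=int(rng.integers(0, 2**31)),
                section_id=f"A{i:03d}_S{j}", animal_id=f"A{i:03d}"))
    return sections


def generate_paired_cohort(spec_a: PhantomSpec, spec_b: PhantomSpec,
                           n_animals: int, sections_per_animal: int,
                           cv_a: float, cv_b: float, shared_cv: float,
                           seed: int,
                           ) -> tuple[list[MultiChannelSection],
                                      list[MultiChannelSection]]:
    """Render a paired two-agent cohort (same animals, correlated contrasts)."""
    if n_animals < 1 or sections_per_animal < 1:
        raise ParameterError("animal and section counts must be positive")
    rng = np.random.default_rng(seed)
    rho_a, rho_b = draw_paired_contrasts(
        spec_a.nir_contrast, spec_b.nir_contrast, cv_a, cv_b, shared_cv,
        n_animals, rng)
    out_a, out_b = [], []
    for i in range(n_animals):
        for j in range(sections_per_animal):
            out_a.append(generate_section(
                replace(spec_a, nir_contrast=float(rho_a[i])),
                seed=int(rng.integers(0, 2**31)),
                section_id=f"A{i:03d}_S{j}", animal_id=f"A{i:03d}"))
            out_b.append(generate_section(
                replace(spec_b, nir_contrast=float(rho_b[i])),
                seed=int(rng.integers(0, 2**31)),
                section_id=f"A{i:03d}_S{j}", animal_id=f"A{i:03d}"))
    return out_a, out_b


def generate_homogenates(n_animals: int, true_tnr: float, noise_cv: float,
                         seed: int, baseline_per_mg: float = 100.0,
                         weight_range: tuple[float, float] = (10.0, 30.0),
                         ) -> list[HomogenateRecord]:
    """Paired tumor/normal homogenate readings, weight-normalized ground truth.

    Per-animal tumor per-mg fluorescence equals ``true_tnr`` times the
    normal per-mg fluorescence up to multiplicative lognormal noise with
    mean 1 and CV ``noise_cv``, so the expected recovered TNR equals
    ``true_tnr``.  Weights are uniform on ``weight_range`` (mg).
    """
    if n_animals < 1:
        raise ParameterError("n_animals must be >= 1")
    if true_tnr < 1:
        raise ParameterError("true_tnr must be >= 1")
    if noise_cv < 0:
        raise ParameterError("noise_cv must be >= 0")
    rng = np.random.default_rng(seed)
    records = []
    sigma = _lognormal_sigma(noise_cv)
    for i in range(n_animals):
        aid = f"A{i:03d}"
        # modest between-animal spread of the normal-tissue baseline
        per_mg_normal = baseline_per_mg * np.exp(
            0.2 * rng.standard_normal())
        eps = np.exp(sigma * rng.standard_normal() - sigma * sigma / 2) \
            if noise_cv > 0 else 1.0
        per_mg_tumor = true_tnr * per_mg_normal * eps
        w_t, w_n = rng.uniform(*weight_range, size=2)
        records.append(HomogenateRecord(aid, "tumor",
                                        float(per_mg_tumor * w_t), float(w_t)))
        records.append(HomogenateRecord(aid, "normal",
                                        float(per_mg_normal * w_n), float(w_n)))
    return records


def _activation_curve(t: np.ndarray, t_half: float = 10.0) -> np.ndarray:
    # saturating uptake/cleavage kinetics; strictly increasing in t
    t = np.asarray(t, dtype=float)
    return t / (t + t_half)


def generate_exvivo(n_gbm: int, n_pre: int, fold_gbm_vs_pre: float,
                    timepoints: Sequence[float] = EXVIVO_TIMEPOINTS,
                    noise_cv: float = 0.0, n_reference: int = 3,
                    experiment_id: str = "E1", seed: int = 0,
                    ) -> list[ExVivoFragment]:
    """Ex-vivo fragment activation time course with a reference-tissue group.

    Fluorescence follows a saturating activation curve; the expected GBM
    group mean is ``fold_gbm_vs_pre`` times the PRE mean at every timepoint
    (hence also at the final one).  A reference group (healthy mouse brain
    processed alongside the human material) is always emitted so per-
    experiment normalization is possible.
    """
    if n_gbm < 1 or n_pre < 1 or n_reference < 1:
        raise ParameterError("all group sizes must be >= 1")
    if fold_gbm_vs_pre < 1:
        raise ParameterError("fold_gbm_vs_pre must be >= 1")
    if len(timepoints) == 0:
        raise ParameterError("timepoints must be non-empty")
    rng = np.random.default_rng(seed)
    sigma = _lognormal_sigma(noise_cv)
    amp = {"PRE": 100.0, "GBM": 100.0 * fold_gbm_vs_pre, "reference": 40.0}
    counts = {"GBM": n_gbm, "PRE": n_pre, "reference": n_reference}
    curve = _activation_curve(np.asarray(timepoints, dtype=float))
    fragments = []
    for group, n in counts.items():
        for k in range(n):
            sid = f"{experiment_id}_{group}{k:02d}"
            for t, c in zip(timepoints, curve):
                eps = np.exp(sigma * rng.standard_normal()
                             - sigma * sigma / 2) if noise_cv > 0 else 1.0
                fragments.append(ExVivoFragment(
                    sid, group, float(t), float(amp[group] * c * eps),
                    experiment_id))
    return fragments
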