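"""Phantom generator: ground-truth conservation, determinism, samplers."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import fgsquant as fq
from conftest import gt_masks


class TestGenerateSection:
    @pytest.mark.parametrize("rho", [1.0, 5.0, 30.0])
    def test_noiseless_contrast_is_exact(self, noiseless_spec, rho):
        spec = dataclasses.replace(noiseless_spec, nir_contrast=rho)
        sec = fq.generate_section(spec, seed=0)
        tumor, normal = gt_masks(sec)
        ratio = sec.nir[tumor.pixels].mean() / sec.nir[normal.pixels].mean()
        assert ratio == pytest.approx(rho, rel=1e-12)

    def test_unit_contrast_gives_constant_nir(self, noiseless_spec):
        spec = dataclasses.replace(noiseless_spec, nir_contrast=1.0)
        sec = fq.generate_section(spec, seed=0)
        assert np.ptp(sec.nir) == 0

    def test_same_seed_bit_identical_different_seed_differs(self,
                                                            default_spec):
        a = fq.generate_section(default_spec, seed=7)
        b = fq.generate_section(default_spec, seed=7)
        c = fq.generate_section(default_spec, seed=8)
        for ch in ("nuclear", "nir", "rgb"):
            assert np.array_equal(getattr(a, ch), getattr(b, ch))
        assert (a.nir != c.nir).any()

    def test_nuclear_channel_is_two_level_without_infiltration(
            self, noiseless_spec):
        sec = fq.generate_section(noiseless_spec, seed=0)
        levels = np.unique(sec.nuclear)
        assert set(levels) == {noiseless_spec.nuclear_background_level,
                               noiseless_spec.nuclear_tumor_level}

    def test_infiltration_band_ramps_between_levels(self, noiseless_spec):
        spec = dataclasses.replace(noiseless_spec, infiltration_width=6,
                                   tumor_axes=(20, 14))
        sec = fq.generate_section(spec, seed=0)
        core = sec.ground_truth_mask
        outside = sec.nuclear[~core]
        bg, tu = spec.nuclear_background_level, spec.nuclear_tumor_level
        assert ((outside > bg) & (outside < tu)).any()  # ramp pixels exist
        assert outside.max() < tu  # strictly below tumor level off-core

    def test_midline_crossing_ellipse_rejected(self, noiseless_spec):
        bad = dataclasses.replace(noiseless_spec, tumor_center=(96, 100))
        with pytest.raises(fq.GeometryError):
            fq.generate_section(bad, seed=0)

    @pytest.mark.parametrize("field", ["nuclear_tumor_level",
                                       "nir_normal_level"])
    def test_nonpositive_levels_rejected(self, noiseless_spec, field):
        bad = dataclasses.replace(noiseless_spec, **{field: 0.0})
        with pytest.raises(fq.ParameterError):
            fq.generate_section(bad, seed=0)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(rho=st.floats(1.0, 50.0), sd=st.floats(0.0, 0.3),
           jitter=st.floats(0.0, 0.3), width=st.integers(0, 4),
           seed=st.integers(0, 2**31 - 1))
    def test_section_invariants_hold(self, rho, sd, jitter, width, seed):
        spec = fq.PhantomSpec(image_height=64, image_width=64,
                              midline_col=32, tumor_center=(32, 48),
                              tumor_axes=(9, 7), nir_contrast=rho,
                              gaussian_noise_sd=sd, ppix_color_jitter_sd=jitter,
                              infiltration_width=width)
        sec = fq.generate_section(spec, seed=seed)
        sec.validate()  # shapes agree, intensities >= 0, rgb in [0, 1]
        assert sec.ground_truth_mask.any()


class TestCohort:
    def test_zero_cv_fixes_all_contrasts(self, small_spec):
        sections = fq.generate_cohort(small_spec, 4, 2, 0.0, seed=0)
        assert {s.true_nir_contrast for s in sections} == \
            {small_spec.nir_contrast}

    def test_counts_and_distinct_contrasts(self, small_spec):
        sections = fq.generate_cohort(small_spec, 10, 3, 0.4, seed=0)
        assert len(sections) == 30
        assert len({s.true_nir_contrast for s in sections}) == 10
        assert len({s.animal_id for s in sections}) == 10

    def test_contrast_sampler_matches_requested_cv(self):
        rng = np.random.default_rng(0)
        rhos = fq.draw_contrasts(30.0, 0.5, 10_000, rng)
        cv = rhos.std(ddof=1) / rhos.mean()
        assert cv == pytest.approx(0.5, rel=0.05)
        assert np.median(rhos) == pytest.approx(30.0, rel=0.05)

    def test_paired_sampler_marginals_and_correlation(self):
        rng = np.random.default_rng(1)
        a, b = fq.draw_paired_contrasts(30.1, 8.2, 0.55, 0.70, 0.35,
                                        20_000, rng)
        assert np.median(a) == pytest.approx(30.1, rel=0.05)
        assert np.median(b) == pytest.approx(8.2, rel=0.05)
        assert a.std(ddof=1) / a.mean() == pytest.approx(0.55, rel=0.1)
        r = np.corrcoef(np.log(a), np.log(b))[0, 1]
        assert r > 0.2  # coadministration induces positive correlation

    def test_bad_counts_rejected(self, small_spec):
        with pytest.raises(fq.ParameterError):
            fq.generate_cohort(small_spec, 0, 3, 0.1, seed=0)


class TestHomogenates:
    def test_noiseless_recovery_is_exact(self):
        records = fq.generate_homogenates(5, 12.0, 0.0, seed=0)
        assert len(records) == 10
        for i in range(5):
            tnr = fq.homogenate_tnr(records, f"A{i:03d}")
            assert tnr == pytest.approx(12.0, rel=1e-12)

    def test_each_animal_paired(self):
        records = fq.generate_homogenates(5, 2.0, 0.1, seed=0)
        by_animal = {}
        for r in records:
            by_animal.setdefault(r.animal_id, []).append(r.tissue)
        assert all(sorted(v) == ["normal", "tumor"]
                   for v in by_animal.values())

    def test_mean_recovered_tnr_unbiased(self):
        records = fq.generate_homogenates(1000, 30.0, 0.2, seed=3)
        tnrs = [fq.homogenate_tnr(records, f"A{i:03d}") for i in range(1000)]
        assert np.mean(tnrs) == pytest.approx(30.0, rel=0.05)


class TestExVivo:
    def test_four_records_per_fragment_at_study_timepoints(self):
        frags = fq.generate_exvivo(3, 2, 1.91, seed=0)
        per_fragment = {}
        for f in frags:
            per_fragment.setdefault(f.sample_id, []).append(f.timepoint)
        assert all(sorted(ts) == [2, 5, 10, 120]
                   for ts in per_fragment.values())

    def test_reference_group_always_present(self):
        frags = fq.generate_exvivo(2, 2, 1.5, seed=0)
        assert any(f.group == "reference" for f in frags)

    def test_unit_fold_noiseless_means_identical(self):
        frags = fq.generate_exvivo(3, 3, 1.0, noise_cv=0.0, seed=0)
        for t in (2, 5, 10, 120):
            g = [f.fluorescence for f in frags
                 if f.group == "GBM" and f.timepoint == t]
            p = [f.fluorescence for f in frags
                 if f.group == "PRE" and f.timepoint == t]
            assert np.mean(g) == pytest.approx(np.mean(p), rel=1e-12)

    def test_fold_two_noiseless_exact_at_final_timepoint(self):
        frags = fq.generate_exvivo(3, 2, 2.0, noise_cv=0.0, seed=0)
        rows = fq.normalize_exvivo(frags, "E1")
        g = [v for f, v in rows if f.group == "GBM" and f.timepoint == 120]
        p = [v for f, v in rows if f.group == "PRE" and f.timepoint == 120]
        assert fq.fold_difference(g, p) == pytest.approx(2.0, rel=1e-12)

    def test_fluorescence_monotone_in_time_noiseless(self):
        frags = fq.generate_exvivo(2, 2, 1.5, noise_cv=0.0, seed=0)
        for sid in {f.sample_id for f in frags}:
            mine = sorted((f.timepoint, f.fluorescence)
                          for f in frags if f.sample_id == sid)
            vals = [v for _, v in mine]
            assert all(a < b for a, b in zip(vals, vals[1:]))

    def test_empty_group_rejected(self):
        with pytest.raises(fq.ParameterError):
            fq.generate_exvivo(0, 2, 1.5, seed=0)
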