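"""Scalar readouts: TNR, normalization, CV, homogenates, MFI, ex vivo."""

import numpy as np
import pytest

import fgsquant as fq
from fgsquant.phantom import HomogenateRecord


def _uniform_masks(shape=(20, 40)):
    tumor = np.zeros(shape, dtype=bool)
    normal = np.zeros(shape, dtype=bool)
    tumor[5:15, 25:35] = True
    normal[5:15, 5:15] = True
    return fq.RegionMask(tumor, "tumor"), fq.RegionMask(normal, "normal")


class TestComputeTnr:
    def test_uniform_regions(self):
        tumor, normal = _uniform_masks()
        img = np.ones((20, 40))
        img[tumor.pixels] = 30.0
        r = fq.compute_tnr(img, tumor, normal)
        assert r.tnr == 30.0
        assert r.tumor_pixels == 100 and r.normal_pixels == 100
        assert r.tnr == pytest.approx(r.tumor_mean / r.normal_mean)

    def test_gain_invariance(self):
        tumor, normal = _uniform_masks()
        rng = np.random.default_rng(0)
        img = rng.random((20, 40)) + 0.5
        base = fq.compute_tnr(img, tumor, normal).tnr
        assert fq.compute_tnr(2.0 * img, tumor, normal).tnr == base
        assert fq.compute_tnr(7.0 * img, tumor, normal).tnr == \
            pytest.approx(base, rel=1e-12)

    def test_zero_normal_region_rejected(self):
        tumor, normal = _uniform_masks()
        img = np.zeros((20, 40))
        img[tumor.pixels] = 1.0
        with pytest.raises(fq.QuantificationError):
            fq.compute_tnr(img, tumor, normal)

    def test_overlapping_masks_rejected(self):
        tumor, _ = _uniform_masks()
        with pytest.raises(fq.MaskError):
            fq.compute_tnr(np.ones((20, 40)), tumor, tumor)


class TestNormalizeToNormal:
    def test_normal_mean_becomes_one_and_idempotent(self):
        tumor, normal = _uniform_masks()
        rng = np.random.default_rng(1)
        img = rng.random((20, 40)) + 0.2
        out = fq.normalize_to_normal(img, normal)
        assert out[normal.pixels].mean() == pytest.approx(1.0, rel=1e-12)
        again = fq.normalize_to_normal(out, normal)
        assert np.allclose(again, out, rtol=1e-12)

    def test_tumor_value_becomes_ratio(self):
        tumor, normal = _uniform_masks()
        img = np.ones((20, 40))
        img[tumor.pixels] = 30.0
        out = fq.normalize_to_normal(img, normal)
        assert out[tumor.pixels].max() == pytest.approx(30.0)


class TestSectionCv:
    def test_constant_input_zero(self):
        assert fq.section_cv([10, 10, 10]) == 0.0

    def test_two_values(self):
        assert fq.section_cv([8, 12]) == pytest.approx(2 * np.sqrt(2) / 10)

    def test_scale_invariance(self):
        vals = [8.0, 11.0, 9.5, 12.5]
        assert fq.section_cv([v * 3.7 for v in vals]) == \
            pytest.approx(fq.section_cv(vals), rel=1e-12)

    def test_too_few_values_rejected(self):
        with pytest.raises(fq.InputError):
            fq.section_cv([5.0])


class TestAnimalAggregation:
    def _results(self):
        return [
            fq.TNRResult(30.0, 1.0, 30.0, 100, 100, "S0", "A0", "x"),
            fq.TNRResult(20.0, 1.0, 20.0, 300, 300, "S1", "A0", "x"),
        ]

    def test_mean_of_sections_default(self):
        assert fq.animal_tnr(self._results()) == 25.0

    def test_pooled_pixels_weighting(self):
        # pooled tumor mean = (30*100 + 20*300)/400 = 22.5 over normal 1.0
        assert fq.animal_tnr(self._results(), method="pooled") == \
            pytest.approx(22.5)

    def test_cohort_table_and_pairing(self):
        results = [
            fq.TNRResult(30, 1, 30.0, 10, 10, "S0", "A0", "nir"),
            fq.TNRResult(10, 1, 10.0, 10, 10, "S0", "A0", "ppix"),
            fq.TNRResult(28, 1, 28.0, 10, 10, "S0", "A1", "nir"),
        ]
        table = fq.cohort_table(results)
        assert len(table) == 3
        with pytest.raises(fq.InputError):  # A1 lacks the ppix arm
            fq.paired_values(table, "nir", "ppix")


class TestHomogenateTnr:
    def _records(self):
        return [HomogenateRecord("A0", "tumor", 3000.0, 10.0),
                HomogenateRecord("A0", "normal", 200.0, 20.0)]

    def test_direct_formula(self):
        assert fq.homogenate_tnr(self._records(), "A0") == 30.0

    def test_equal_per_mg_gives_unity(self):
        recs = [HomogenateRecord("A0", "tumor", 100.0, 10.0),
                HomogenateRecord("A0", "normal", 200.0, 20.0)]
        assert fq.homogenate_tnr(recs, "A0") == 1.0

    def test_zero_weight_rejected(self):
        recs = [HomogenateRecord("A0", "tumor", 100.0, 0.0),
                HomogenateRecord("A0", "normal", 200.0, 20.0)]
        with pytest.raises(fq.InputError):
            fq.homogenate_tnr(recs, "A0")

    def test_missing_pair_rejected(self):
        with pytest.raises(fq.InputError):
            fq.homogenate_tnr(self._records()[:1], "A0")

    def test_protein_denominator_option(self):
        recs = [HomogenateRecord("A0", "tumor", 3000.0, 10.0, protein=5.0),
                HomogenateRecord("A0", "normal", 200.0, 20.0, protein=10.0)]
        assert fq.homogenate_tnr(recs, "A0", denominator="protein") == 30.0


class TestMfiRatio:
    def test_examples(self):
        assert fq.mfi_ratio(500.0, 50.0) == 10.0
        assert fq.mfi_ratio(3.0, 3.0) == 1.0

    def test_zero_unstained_rejected(self):
        with pytest.raises(fq.InputError):
            fq.mfi_ratio(500.0, 0.0)


class TestExVivoNormalization:
    def test_ratio_definition_and_reference_identity(self):
        frags = [
            fq.ExVivoFragment("r0", "reference", 120.0, 100.0, "E1"),
            fq.ExVivoFragment("g0", "GBM", 120.0, 150.0, "E1"),
        ]
        rows = dict((f.sample_id, v)
                    for f, v in fq.normalize_exvivo(frags, "E1"))
        assert rows["g0"] == pytest.approx(1.5)
        assert rows["r0"] == pytest.approx(1.0)

    def test_batch_effect_removed_across_experiments(self):
        def experiment(eid, scale):
            return [
                fq.ExVivoFragment(f"{eid}r", "reference", 120.0,
                                  100.0 * scale, eid),
                fq.ExVivoFragment(f"{eid}g", "GBM", 120.0,
                                  180.0 * scale, eid),
            ]
        frags = experiment("E1", 1.0) + experiment("E2", 7.3)
        v1 = dict((f.sample_id, v)
                  for f, v in fq.normalize_exvivo(frags, "E1"))["E1g"]
        v2 = dict((f.sample_id, v)
                  for f, v in fq.normalize_exvivo(frags, "E2"))["E2g"]
        assert v1 == pytest.approx(v2, rel=1e-12)

    def test_missing_reference_rejected(self):
        frags = [fq.ExVivoFragment("g0", "GBM", 120.0, 150.0, "E1")]
        with pytest.raises(fq.InputError):
            fq.normalize_exvivo(frags, "E1")


class TestFoldDifference:
    def test_examples(self):
        assert fq.fold_difference([2, 2], [1, 1]) == 2.0
        assert fq.fold_difference([3, 4], [3, 4]) == 1.0

    def test_noiseless_generator_round_trip(self):
        frags = fq.generate_exvivo(4, 3, 1.91, noise_cv=0.0, seed=0)
        rows = fq.normalize_exvivo(frags, "E1")
        g = [v for f, v in rows if f.group == "GBM" and f.timepoint == 120]
        p = [v for f, v in rows if f.group == "PRE" and f.timepoint == 120]
        assert fq.fold_difference(g, p) == pytest.approx(1.91, rel=1e-12)

    def test_gain_invariance(self):
        a, b = [2.0, 3.5, 4.1], [1.1, 0.8]
        base = fq.fold_difference(a, b)
        scaled = fq.fold_difference([x * 2.0 for x in a],
                                    [x * 2.0 for x in b])
        assert scaled == base
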