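"""Score-aware augmentation: exact score accounting under both operators."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import vitreg as v
from vitreg.augment import CutMixSpec, cutmix_image


def _scored(image, left, right, score_type="GE", image_id=""):
    return v.ScoredImage(
        image=image,
        left_score=left,
        right_score=right,
        global_score=left + right,
        score_type=score_type,
        image_id=image_id,
    )


class TestMixScores:
    @pytest.mark.parametrize(
        "lam, ya, yb, expected",
        [(1.0, 3.5, 7.0, 3.5), (0.5, 2, 6, 4), (0.25, 8, 0, 2), (0.0, 1, 5, 5)],
    )
    def test_weighted_average(self, lam, ya, yb, expected):
        assert v.mix_scores(lam, ya, yb) == expected

    @pytest.mark.parametrize("lam", [-0.1, 1.1])
    def test_lambda_outside_unit_interval_rejected(self, lam):
        with pytest.raises(ValueError):
            v.mix_scores(lam, 1, 2)

    @given(
        st.floats(0, 1, allow_nan=False),
        st.floats(0, 8, allow_nan=False),
        st.floats(0, 8, allow_nan=False),
    )
    @settings(max_examples=200, deadline=None)
    def test_convexity(self, lam, ya, yb):
        mixed = v.mix_scores(lam, ya, yb)
        assert min(ya, yb) - 1e-12 <= mixed <= max(ya, yb) + 1e-12


class TestLungReplace:
    def test_self_composition_is_identity(self):
        rng = np.random.default_rng(0)
        a = _scored(rng.uniform(size=(16, 16)), 2.0, 3.0)
        out = v.lung_replace(a, a)
        assert np.array_equal(out.image, a.image)
        assert (out.left_score, out.right_score) == (2.0, 3.0)

    def test_halves_and_scores_come_from_matching_parents(self):
        a = _scored(np.zeros((8, 8)), 1.0, 3.0, image_id="a")
        b = _scored(np.ones((8, 8)), 4.0, 0.0, image_id="b")
        out = v.lung_replace(a, b)
        assert (out.left_score, out.right_score, out.global_score) == (1.0, 0.0, 1.0)
        assert np.array_equal(out.image[:, :4], a.image[:, :4])
        assert np.array_equal(out.image[:, 4:], b.image[:, 4:])

    def test_odd_width_gives_extra_column_to_the_right(self):
        a = _scored(np.zeros((8, 9)), 1.0, 1.0)
        b = _scored(np.ones((8, 9)), 1.0, 1.0)
        out = v.lung_replace(a, b)
        assert (out.image[0] == 1.0).sum() == 5

    def test_reciprocal_replacements_conserve_total_score(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            la, ra, lb, rb = rng.integers(0, 5, size=4).astype(float)
            a = _scored(np.zeros((8, 8)), la, ra)
            b = _scored(np.zeros((8, 8)), lb, rb)
            total = (
                v.lung_replace(a, b).global_score + v.lung_replace(b, a).global_score
            )
            assert total == a.global_score + b.global_score

    def test_requires_per_lung_scores(self):
        a = v.ScoredImage(np.zeros((8, 8)), global_score=3.0, score_type="GE")
        b = _scored(np.zeros((8, 8)), 1.0, 1.0)
        with pytest.raises(ValueError, match="per-lung"):
            v.lung_replace(a, b)

    def test_mismatched_inputs_rejected(self):
        a = _scored(np.zeros((8, 8)), 1.0, 1.0, score_type="GE")
        with pytest.raises(ValueError):
            v.lung_replace(a, _scored(np.zeros((8, 10)), 1.0, 1.0))
        with pytest.raises(ValueError):
            v.lung_replace(a, _scored(np.zeros((8, 8)), 1.0, 1.0, score_type="LO"))


class TestOfflineAugment:
    @pytest.mark.parametrize(
        "n, score_types, expected",
        [(10, ("GE",), 20), (9, ("GE", "LO"), 27), (2, ("GE",), 4)],
    )
    def test_count_law(self, n, score_types, expected):
        samples = v.generate_dataset(n, seed=4, score_types=score_types)
        out, records = v.offline_augment(samples, score_types, seed=0)
        assert len(out) == expected == n * (1 + len(score_types))
        assert len(records) == n * len(score_types)

    def test_partners_never_self(self, small_samples):
        _, records = v.offline_augment(small_samples, ("GE",), seed=2)
        assert all(r.parent_a != r.parent_b for r in records)

    def test_reciprocal_pairing_swaps_pairs(self, small_samples):
        _, records = v.offline_augment(
            small_samples, ("GE",), seed=2, pairing="reciprocal"
        )
        mates = {r.parent_a: r.parent_b for r in records}
        assert all(mates[b] == a for a, b in mates.items())

    def test_deterministic_given_seed(self, small_samples):
        out1, rec1 = v.offline_augment(small_samples, ("GE", "LO"), seed=8)
        out2, rec2 = v.offline_augment(small_samples, ("GE", "LO"), seed=8)
        assert rec1 == rec2
        assert all(
            np.array_equal(x.image, y.image) for x, y in zip(out1, out2)
        )

    def test_synthetic_scores_obey_replacement_rule(self, small_samples):
        out, records = v.offline_augment(small_samples, ("GE",), seed=1)
        by_id = {s.image_id: s for s in small_samples}
        for rec in records:
            assert rec.left_score == by_id[rec.parent_a].scores["GE"][0]
            assert rec.right_score == by_id[rec.parent_b].scores["GE"][1]
            assert rec.global_score == rec.left_score + rec.right_score

    def test_too_small_dataset_rejected(self, small_samples):
        with pytest.raises(ValueError):
            v.offline_augment(small_samples[:1], ("GE",), seed=0)


class TestCutMixBox:
    def test_area_fraction_within_range_over_many_draws(self):
        rng = np.random.default_rng(0)
        total = 100 * 100
        for _ in range(2000):
            spec = v.sample_cutmix_box(100, 100, (0.1, 0.3), rng)
            frac = spec.box_area / total
            assert 0.1 - 0.01 <= frac <= 0.3 + 0.01
            assert spec.lam == (total - spec.box_area) / total

    def test_degenerate_range_pins_box_area(self):
        rng = np.random.default_rng(1)
        spec = v.sample_cutmix_box(100, 100, (0.1, 0.1), rng)
        assert abs(spec.box_area - 1000) <= 100  # one row/column tolerance
        assert abs(spec.lam - 0.9) <= 0.01

    def test_infeasible_or_invalid_ranges_rejected(self):
        with pytest.raises(ValueError):
            v.sample_cutmix_box(64, 64, (0.0, 0.4), np.random.default_rng(0))
        with pytest.raises(ValueError):
            v.sample_cutmix_box(64, 64, (0.5, 0.4), np.random.default_rng(0))

    def test_spec_validates_lambda_against_box(self):
        with pytest.raises(ValueError):
            CutMixSpec(box=(0, 0, 10, 10), lam=0.5, height=10, width=10)


class TestCutMix:
    def _two_tone(self):
        a = _scored(np.zeros((20, 30)), 4.0, 4.0, image_id="a")
        b = _scored(np.ones((20, 30)), 0.0, 0.0, image_id="b")
        return a, b

    def test_zero_area_box_returns_base_image(self):
        a, b = self._two_tone()
        spec = CutMixSpec(box=(0, 0, 0, 0), lam=1.0, height=20, width=30)
        out = v.cutmix(a, b, spec)
        assert np.array_equal(out.image, a.image)
        assert out.global_score == a.global_score

    def test_full_frame_box_returns_donor_image(self):
        a, b = self._two_tone()
        spec = CutMixSpec(box=(0, 0, 20, 30), lam=0.0, height=20, width=30)
        out = v.cutmix(a, b, spec)
        assert np.array_equal(out.image, b.image)
        assert out.global_score == b.global_score

    def test_pixel_provenance_count_equals_lambda_exactly(self):
        a, b = self._two_tone()
        rng = np.random.default_rng(3)
        for _ in range(50):
            spec = v.sample_cutmix_box(20, 30, (0.05, 0.5), rng)
            out = v.cutmix(a, b, spec)
            from_a = (out.image == 0.0).sum()
            assert from_a / (20 * 30) == spec.lam
            assert out.global_score == v.mix_scores(spec.lam, 8.0, 0.0)

    def test_donor_weighted_lambda_flag(self):
        a, b = self._two_tone()
        spec = CutMixSpec(box=(0, 0, 5, 30), lam=0.75, height=20, width=30)
        assert v.cutmix(a, b, spec).global_score == 6.0
        assert v.cutmix(a, b, spec, lambda_from_donor=True).global_score == 2.0

    def test_per_lung_scores_dropped_on_output(self):
        a, b = self._two_tone()
        spec = CutMixSpec(box=(0, 0, 10, 10), lam=500 / 600, height=20, width=30)
        assert not v.cutmix(a, b, spec).has_per_lung_scores

    def test_out_of_bounds_box_rejected(self):
        with pytest.raises(ValueError):
            cutmix_image(
                np.zeros((8, 8)),
                np.ones((8, 8)),
                CutMixSpec(box=(0, 0, 4, 4), lam=84 / 100, height=10, width=10),
            )
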