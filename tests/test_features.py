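"""Region statistics, sub-volume proportions, CSA and standardization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ligload import features as feat
from ligload import synthgen
from ligload.relaxometry import T2StarMap, ValidationError


def _map_from_values(values, voxel_size=(1.0, 1.0, 1.0)):
    v = np.asarray(values, dtype=float)
    t2 = v.reshape(-1, 1, 1)
    mask = np.ones_like(t2, dtype=bool)
    return T2StarMap(t2, np.zeros_like(t2), np.ones_like(t2), mask, voxel_size)


class TestT2Statistics:
    def test_constant_sample(self):
        s = feat.t2star_statistics([10.0, 10.0, 10.0, 10.0])
        assert (s.median, s.mean, s.sd, s.skew) == (10.0, 10.0, 0.0, 0.0)
        assert (s.q1, s.q3) == (10.0, 10.0)

    def test_symmetric_sample(self):
        s = feat.t2star_statistics([1.0, 2.0, 3.0, 4.0, 5.0])
        assert (s.median, s.mean, s.q1, s.q3) == (3.0, 3.0, 2.0, 4.0)
        assert s.skew == pytest.approx(0.0, abs=1e-12)

    def test_single_voxel_rejected(self):
        with pytest.raises(ValidationError):
            feat.t2star_statistics([5.0])

    def test_lognormal_skew_matches_closed_form(self):
        # adjusted Fisher–Pearson skew of LogNormal(mu, s): (e^{s^2}+2)sqrt(e^{s^2}-1)
        sigma = 0.4
        analytic = (np.exp(sigma**2) + 2) * np.sqrt(np.exp(sigma**2) - 1)
        v = np.random.default_rng(7).lognormal(2.5, sigma, 20_000)
        s = feat.t2star_statistics(v)
        assert s.skew == pytest.approx(analytic, rel=0.10)

    def test_accepts_map_input(self, surgical_map):
        s = feat.t2star_statistics(surgical_map)
        assert s.q1 <= s.median <= s.q3


def brute_force_proportions(values, edges=(0.0, 12.5, 25.0, 37.5, 50.0)):
    """Independent per-voxel classifier used as the binning oracle."""
    counts = [0, 0, 0, 0]
    for v in values:
        for i in range(4):
            lo, hi = edges[i], edges[i + 1]
            if (lo <= v < hi) or (i == 3 and v == hi):
                counts[i] += 1
                break
    return tuple(c / len(values) for c in counts)


class TestSubvolumeProportions:
    def test_all_in_first_bin(self):
        assert feat.subvolume_proportions([10.0] * 7) == (1.0, 0, 0, 0)

    def test_one_per_bin_plus_overflow(self):
        props = feat.subvolume_proportions([5.0, 15.0, 30.0, 45.0, 60.0])
        assert props == (0.2, 0.2, 0.2, 0.2)
        assert sum(props) == pytest.approx(0.8)

    def test_bin_edges_half_open_top_closed(self):
        # 12.5 belongs to bin 2; 50 belongs to bin 4; 50.0001 to no bin
        assert feat.subvolume_proportions([12.5]) == (0, 1.0, 0, 0)
        assert feat.subvolume_proportions([50.0]) == (0, 0, 0, 1.0)
        assert sum(feat.subvolume_proportions([50.01])) == 0.0

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(50):
            n = rng.integers(5, 200)
            values = rng.uniform(0.0, 60.0, n)
            assert feat.subvolume_proportions(values) == pytest.approx(
                brute_force_proportions(values), abs=1e-12)

    def test_sums_to_one_when_all_below_top_edge(self, rng):
        values = rng.uniform(0.0, 49.99, 500)
        assert sum(feat.subvolume_proportions(values)) == pytest.approx(1.0)

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            feat.subvolume_proportions([])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0.1, 79.0), min_size=2, max_size=40),
           st.randoms(use_true_random=False))
    def test_permutation_invariance(self, values, rnd):
        shuffled = list(values)
        rnd.shuffle(shuffled)
        assert feat.subvolume_proportions(values) == pytest.approx(
            feat.subvolume_proportions(shuffled))


class TestCSA:
    def test_simple_volume_over_length(self):
        mask = np.ones((10, 10, 10), dtype=bool)
        assert feat.average_csa(mask, (1, 1, 1), 20.0) == pytest.approx(50.0)

    def test_single_porcine_voxel(self):
        mask = np.ones((1, 1, 1), dtype=bool)
        csa = feat.average_csa(mask, (0.3125, 0.3125, 0.8), 0.8)
        assert csa == pytest.approx(0.09766, abs=5e-5)

    def test_non_positive_length_rejected(self):
        with pytest.raises(ValidationError):
            feat.average_csa(np.ones((2, 2, 2), bool), (1, 1, 1), 0.0)

    def test_ellipsoid_geometry_oracle(self):
        # mean CSA of an ellipsoid = V / (2c) = (2/3)*pi*a*b
        from ligload.synthgen import _ellipsoid_mask

        a = b = 5.0
        c = 12.0
        voxel = (0.4, 0.4, 0.5)
        mask = _ellipsoid_mask((40, 40, 60), voxel, (a, b, c))
        length = feat.mask_principal_length(mask, voxel)
        assert length == pytest.approx(2 * c, rel=0.05)
        csa = feat.average_csa(mask, voxel, length)
        assert csa == pytest.approx(2.0 / 3.0 * np.pi * a * b, rel=0.05)


class TestStandardization:
    def _table(self, rng, n=30):
        cols = {f: rng.normal(10, 3, n) for f in feat.CONTINUOUS_FEATURES}
        cols["limb_type"] = rng.integers(0, 2, n)
        cols["subject_id"] = [f"s{i}" for i in range(n)]
        return pd.DataFrame(cols)

    def test_reference_record_is_zero(self, rng):
        table = self._table(rng)
        ref = feat.StandardizationReference.from_table(table)
        means = pd.DataFrame([{f: ref.means[f] for f in ref.means} | {"limb_type": 1}])
        z = feat.standardize(means, ref)
        assert np.allclose(z[list(ref.means)].to_numpy(), 0.0)
        assert z["limb_type"].iloc[0] == 1  # passthrough

    def test_self_standardization_unit_moments(self, rng):
        table = self._table(rng)
        ref = feat.StandardizationReference.from_table(table)
        z = feat.standardize(table, ref)
        for f in ref.means:
            assert z[f].mean() == pytest.approx(0.0, abs=1e-12)
            assert z[f].std(ddof=1) == pytest.approx(1.0, rel=1e-12)

    def test_invertibility(self, rng):
        table = self._table(rng)
        ref = feat.StandardizationReference.from_table(table, source="porcine-train")
        other = self._table(np.random.default_rng(99))
        back = feat.destandardize(feat.standardize(other, ref), ref)
        np.testing.assert_allclose(
            back[list(ref.means)].to_numpy(),
            other[list(ref.means)].to_numpy(), rtol=1e-12, atol=1e-12)

    def test_zero_sd_reference_names_feature(self, rng):
        table = self._table(rng)
        table["csa"] = 42.0
        with pytest.raises(ValidationError, match="csa"):
            feat.StandardizationReference.from_table(table)

    def test_yaml_round_trip(self, rng, tmp_path):
        ref = feat.StandardizationReference.from_table(self._table(rng), source="x")
        path = ref.to_yaml(tmp_path / "ref.yaml")
        back = feat.StandardizationReference.from_yaml(path)
        assert back.means == ref.means and back.sds == ref.sds


class TestHarmonization:
    def _two_scanner_table(self, rng, offset=0.0):
        n = 20
        cols = {f: rng.normal(10, 2, n) for f in feat.CONTINUOUS_FEATURES}
        table = pd.DataFrame(cols)
        table["scanner_id"] = ["A"] * 10 + ["B"] * 10
        table.loc[table.scanner_id == "B", list(feat.CONTINUOUS_FEATURES)] += offset
        return table

    def test_single_scanner_equals_global_zscore(self, rng):
        table = self._two_scanner_table(rng)
        table["scanner_id"] = "A"
        out = feat.harmonize_by_scanner(table, rescale=False)
        ref = feat.StandardizationReference.from_table(table)
        z = feat.standardize(table, ref)
        np.testing.assert_allclose(
            out[list(feat.CONTINUOUS_FEATURES)].to_numpy(),
            z[list(feat.CONTINUOUS_FEATURES)].to_numpy(), atol=1e-12)

    def test_single_scanner_rescaled_is_identity(self, rng):
        table = self._two_scanner_table(rng)
        table["scanner_id"] = "A"
        out = feat.harmonize_by_scanner(table)
        np.testing.assert_allclose(
            out[list(feat.CONTINUOUS_FEATURES)].to_numpy(),
            table[list(feat.CONTINUOUS_FEATURES)].to_numpy(), atol=1e-10)

    def test_rescaled_harmonization_preserves_pooled_scale(self, rng):
        table = self._two_scanner_table(rng, offset=5.0)
        out = feat.harmonize_by_scanner(table)
        for f in feat.CONTINUOUS_FEATURES:
            assert out[f].mean() == pytest.approx(table[f].mean(), abs=1e-9)

    def test_constant_offset_removed(self, rng):
        table = self._two_scanner_table(rng, offset=5.0)
        out = feat.harmonize_by_scanner(table)
        for f in feat.CONTINUOUS_FEATURES:
            ga = out.loc[out.scanner_id == "A", f].mean()
            gb = out.loc[out.scanner_id == "B", f].mean()
            assert ga == pytest.approx(gb, abs=1e-10)

    def test_small_scanner_rejected(self, rng):
        table = self._two_scanner_table(rng)
        table.loc[0, "scanner_id"] = "C"
        with pytest.raises(ValidationError):
            feat.harmonize_by_scanner(table)


class TestExtractFeatures:
    def test_record_invariants(self, surgical_map):
        rec = feat.extract_features(surgical_map, "pig0", "surgical")
        assert rec["limb_type"] == 1
        assert rec["q1_t2"] <= rec["median_t2"] <= rec["q3_t2"]
        props = [rec[f"prop{i}"] for i in (1, 2, 3, 4)]
        assert all(0 <= p <= 1 for p in props) and sum(props) <= 1.0 + 1e-12
        assert rec["csa"] > 0

    def test_unknown_limb_type_rejected(self, surgical_map):
        with pytest.raises(ValidationError):
            feat.extract_features(surgical_map, "pig0", "left")
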