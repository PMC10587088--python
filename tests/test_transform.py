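import numpy as np
import pytest

from harpipe.records import RawRecordSet
from harpipe.transform import (
    DiscretizationModel,
    channel_entropy,
    discretize,
    fit_discretizer,
    integrate,
    quantize_channel,
)


def _stream(values, sid="a"):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if values.shape[0] == 1:
        values = values.T
    n = len(values)
    return RawRecordSet(
        timestamps=np.arange(n),
        values=values,
        labels=np.zeros(n, dtype=int),
        source_ids=np.full(n, sid),
        stage="cleaned",
    )


class TestIntegrate:
    def test_single_source_is_identity_merge(self):
        s = _stream(np.arange(5.0))
        out = integrate([s])
        np.testing.assert_array_equal(out.values, s.values)
        assert out.stage == "integrated"

    def test_disjoint_time_sources_concatenate_in_order(self):
        a = _stream(np.arange(3.0), sid="a")
        b = _stream(np.arange(3.0) + 10, sid="b")
        out = integrate([b, a])
        assert list(out.source_ids[:3]) == ["a"] * 3

    def test_record_count_is_conserved(self):
        sources = [_stream(np.arange(n), sid=f"s{n}") for n in (5, 7, 9)]
        assert integrate(sources).n_records == 21

    def test_schema_mismatch_lists_channels(self):
        a = _stream(np.arange(3.0))
        b = _stream(np.arange(3.0))
        b.channel_names = ["other"]
        with pytest.raises(ValueError, match="other"):
            integrate([a, b])

    def test_affine_unit_harmonization(self):
        a = _stream(np.arange(3.0), sid="a")
        out = integrate([a], affine_maps={"a": (2.0, 1.0)})
        np.testing.assert_allclose(out.values.ravel(), [1.0, 3.0, 5.0])


class TestChannelEntropy:
    def test_single_bin_has_zero_entropy(self):
        assert channel_entropy(np.full(50, 3.3), 10) == 0.0

    def test_uniform_over_four_bins_is_ln4(self):
        values = np.repeat([0.1, 1.1, 2.1, 3.1], 25)
        assert channel_entropy(values, 4) == pytest.approx(np.log(4), abs=1e-9)

    def test_two_bin_25_75_split(self):
        values = np.concatenate([np.zeros(25), np.ones(75)])
        expected = -(0.25 * np.log(0.25) + 0.75 * np.log(0.75))
        assert channel_entropy(values, 2) == pytest.approx(expected, abs=1e-7)
        assert expected == pytest.approx(0.5623351, abs=1e-7)

    def test_boltzmann_constant_scales_linearly(self):
        values = np.concatenate([np.zeros(25), np.ones(75)])
        assert channel_entropy(values, 2, C_boltz=2.0) == pytest.approx(
            2 * channel_entropy(values, 2), abs=1e-12
        )


class TestFitDiscretizer:
    def test_perfectly_separated_pair(self):
        model = fit_discretizer(_stream([0, 0, 10, 10.0]), candidate_ks=[2], seed=0)
        np.testing.assert_allclose(model.centroids[0], [0, 10])
        assert model.inertia[2] == pytest.approx(0.0, abs=1e-12)

    def test_constant_channel_raises(self):
        with pytest.raises(ValueError, match="skipped"):
            fit_discretizer(_stream(np.ones(20)), candidate_ks=[2, 3], seed=0)

    def test_three_gaussians_select_k3(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            x = np.concatenate(
                [rng.normal(m, 0.1, 100) for m in (0.0, 5.0, 10.0)]
            )
            model = fit_discretizer(
                _stream(x), candidate_ks=[2, 3, 4, 5], n_init=5, seed=seed
            )
            hits += model.k == 3
        assert hits >= 9

    def test_inertia_nonincreasing_in_k(self):
        rng = np.random.default_rng(0)
        model = fit_discretizer(
            _stream(rng.normal(size=400)), candidate_ks=[2, 3, 4, 6, 8], seed=1
        )
        ks = sorted(model.inertia)
        inert = [model.inertia[k] for k in ks]
        assert all(b <= a + 1e-9 for a, b in zip(inert, inert[1:]))

    def test_json_round_trip(self, tmp_path):
        model = fit_discretizer(_stream([0, 0, 10, 10.0]), candidate_ks=[2], seed=0)
        p = tmp_path / "disc.json"
        model.to_json(p)
        back = DiscretizationModel.from_json(p)
        assert back.k == model.k
        np.testing.assert_allclose(back.centroids[0], model.centroids[0])


class TestDiscretize:
    def test_value_at_centroid_is_unchanged(self):
        assert quantize_channel(np.array([2.0]), np.array([2.0, 4.0]))[0] == 2.0

    def test_equidistant_value_maps_to_smaller_centroid(self):
        assert quantize_channel(np.array([3.0]), np.array([2.0, 4.0]))[0] == 2.0

    def test_quantization_error_equals_fitted_inertia(self):
        rng = np.random.default_rng(4)
        stream = _stream(rng.normal(size=300))
        model = fit_discretizer(stream, candidate_ks=[4], seed=2)
        q = discretize(stream, model)
        err = float(((stream.values - q.values) ** 2).sum())
        assert err == pytest.approx(model.inertia[4], rel=1e-9)

    def test_projection_idempotence_and_codomain(self):
        rng = np.random.default_rng(5)
        stream = _stream(rng.normal(size=200))
        model = fit_discretizer(stream, candidate_ks=[3], seed=3)
        once = discretize(stream, model)
        twice = discretize(once, model)
        np.testing.assert_array_equal(once.values, twice.values)
        assert np.isin(once.values.ravel(), model.centroids[0]).all()
        assert once.stage == "digital"
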