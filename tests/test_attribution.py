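"""SE lead-weight extraction and Grad-CAM attribution."""

import numpy as np
import pytest

from ecgnet import CANONICAL_LEADS, EcgNetConfig, build_ecgnet, grad_cam, \
    extract_se_weights, lead_ranking_report
from ecgnet import nn
from ecgnet.attribution import AttributionMap, _rank_leads


@pytest.fixture(scope="module")
def model():
    return build_ecgnet(EcgNetConfig(n_classes=4, base_filters=4,
                                     block2_repeats=1), rng=0)


@pytest.fixture(scope="module")
def beat():
    rng = np.random.default_rng(1)
    return rng.normal(0, 0.3, (651, 12)).astype(np.float32)


class _ToyConvModel:
    """Single time convolution, single channel, identity head.

    The class score is the plain sum of the feature map, so the Grad-CAM
    channel weight is exactly 1 and the map is the rectified feature map —
    computable by hand.
    """

    class _Cfg:
        branch_kernels = (3,)
        input_length = 651
        n_classes = 2
        np_dtype = np.float64

    cfg = _Cfg()

    def __init__(self):
        rng = np.random.default_rng(5)
        self.conv = nn.ConvTime(1, 1, 3, rng, np.float64)

    def forward(self, X, train=False):
        x = nn.Tensor(np.asarray(X, dtype=np.float64))
        feat = self.conv(x)
        score = nn.mean(feat, axes=(1, 2, 3))
        n = X.shape[0]
        zero = nn.mul(score, nn.Tensor(np.zeros(n)))
        logits = nn.concat([nn.reshape(score, (n, 1)),
                            nn.reshape(zero, (n, 1))], axis=1)
        return logits, {"lastconv_scale3": feat}


class TestSeWeights:
    def test_four_stages_with_twelve_gates_each(self, model, beat):
        stages = extract_se_weights(model, beat)
        assert [w.stage for w in stages] == ["input", "scale3", "scale5", "scale7"]
        for w in stages:
            assert w.weights.shape == (12,)
            assert np.all((w.weights > 0) & (w.weights < 1))

    def test_zeroed_excitation_gives_flat_half_profile(self, beat):
        m = build_ecgnet(EcgNetConfig(n_classes=4, base_filters=4,
                                      block2_repeats=1), rng=2)
        for layer in (m.lead_se, *[b.se for b in m.branches]):
            layer.fc1.w.data[:] = 0.0
            layer.fc1.b.data[:] = 0.0
            layer.fc2.w.data[:] = 0.0
            layer.fc2.b.data[:] = 0.0
        stages = extract_se_weights(m, beat)
        np.testing.assert_allclose(stages[0].weights, 0.5, atol=1e-7)
        # per-scale weights are composed with channel gates, also 0.5 each
        for w in stages[1:]:
            np.testing.assert_allclose(w.weights, 0.25, atol=1e-6)

    def test_untrained_input_gates_cluster_mid_range(self, model, beat):
        """Before training, lead gates show little variation (mid-range)."""
        gates = extract_se_weights(model, beat)[0].weights
        assert np.all((gates > 0.3) & (gates < 0.7))


class TestGradCam:
    def test_matches_manual_chain_rule_on_toy_model(self):
        toy = _ToyConvModel()
        rng = np.random.default_rng(6)
        beat = rng.standard_normal((651, 12))
        am = grad_cam(toy, beat, class_index=0)
        # manual: score = mean(feat); d score/d feat = 1/size, averaged -> w;
        # map = relu(w * feat); lead scores are time-means
        logits, handles = toy.forward(beat[None, ..., None])
        feat = handles["lastconv_scale3"].data[0, :, :, 0]
        w = 1.0 / feat.size
        expect = np.maximum(w * feat, 0.0)
        np.testing.assert_allclose(am.relevance, expect, atol=1e-6)
        np.testing.assert_allclose(am.lead_scores, expect.mean(axis=0), atol=1e-6)

    def test_constant_score_gives_all_zero_map(self, beat):
        m = build_ecgnet(EcgNetConfig(n_classes=4, base_filters=4,
                                      block2_repeats=1), rng=3)
        m.head.w.data[:] = 0.0
        m.head.b.data[:] = 0.0
        am = grad_cam(m, beat, class_index=1)
        np.testing.assert_allclose(am.relevance, 0.0, atol=1e-12)
        np.testing.assert_allclose(am.lead_scores, 0.0, atol=1e-12)

    def test_invariant_to_constant_logit_offset(self, model, beat):
        """Adding a constant to every pre-softmax score leaves the map
        unchanged (gradient of one logit is unaffected)."""
        before = grad_cam(model, beat, class_index=2)
        model.head.b.data += 3.5
        try:
            after = grad_cam(model, beat, class_index=2)
        finally:
            model.head.b.data -= 3.5
        np.testing.assert_allclose(before.relevance, after.relevance, atol=1e-5)

    def test_amplitude_scaling_preserves_toy_ranking(self):
        toy = _ToyConvModel()
        rng = np.random.default_rng(7)
        beat = rng.standard_normal((651, 12))
        r1 = grad_cam(toy, beat, class_index=0).ranking
        r2 = grad_cam(toy, 3.0 * beat, class_index=0).ranking
        assert r1 == r2

    def test_relevance_non_negative_and_some_leads_may_be_zero(self):
        toy = _ToyConvModel()
        toy.conv.w.data[:] = 1.0  # positive kernel: sign of input is preserved
        toy.conv.b.data[:] = 0.0
        beat = np.zeros((651, 12))
        beat[:, 3] = -5.0  # drives its feature negative -> rectified to 0
        beat[:, 7] = 2.0
        am = grad_cam(toy, beat, class_index=0)
        assert np.all(am.relevance >= 0)
        assert am.lead_scores[3] == 0.0
        assert am.lead_scores[7] > 0.0

    def test_out_of_range_class_rejected(self, model, beat):
        with pytest.raises(ValueError, match="out of range"):
            grad_cam(model, beat, class_index=99)

    def test_fusion_modes(self, model, beat):
        mean_map = grad_cam(model, beat, 0, fusion="mean")
        max_map = grad_cam(model, beat, 0, fusion="max")
        assert np.all(max_map.relevance >= mean_map.relevance - 1e-9)
        with pytest.raises(ValueError, match="fusion"):
            grad_cam(model, beat, 0, fusion="median")


class TestRanking:
    def test_tie_break_follows_canonical_order(self):
        assert _rank_leads(np.zeros(12)) == CANONICAL_LEADS
        scores = np.zeros(12)
        scores[5] = 1.0
        assert _rank_leads(scores)[0] == CANONICAL_LEADS[5]
        assert _rank_leads(scores)[1:] == tuple(
            l for i, l in enumerate(CANONICAL_LEADS) if i != 5)

    def test_single_map_report_equals_map_ranking(self, model, beat):
        am = grad_cam(model, beat, 0)
        report = lead_ranking_report({"A": [am]})
        assert tuple(report["A"]["ranking"]) == am.ranking

    def test_report_averages_scores_across_beats(self):
        a = AttributionMap(np.zeros((651, 12)), np.arange(12.0),
                           _rank_leads(np.arange(12.0)))
        b = AttributionMap(np.zeros((651, 12)), np.arange(12.0)[::-1].copy(),
                           _rank_leads(np.arange(12.0)[::-1].copy()))
        report = lead_ranking_report({"X": [a, b]})
        # symmetric scores average to a constant: canonical tie-break
        assert tuple(report["X"]["ranking"]) == CANONICAL_LEADS

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError, match="no attribution maps"):
            lead_ranking_report({"A": []})
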