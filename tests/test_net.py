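"""Multi-head network: forward invariants, combined loss, decisions, training."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from tiradscope import net
from conftest import random_labels


def _batch(rng, n=4, side=16):
    x = rng.random((n, 3, side, side))
    x[:, 2] = x[:, 2] > 0.5
    return x


class TestForward:
    def test_simplex_heads_sum_to_one(self, micro_model, rng):
        out = net.forward(_batch(rng), micro_model)
        np.testing.assert_allclose(out.composition.sum(axis=1), 1.0, atol=1e-6)
        np.testing.assert_allclose(out.echogenicity.sum(axis=1), 1.0, atol=1e-6)
        np.testing.assert_allclose(out.margin.sum(axis=1), 1.0, atol=1e-6)
        assert np.all((out.p_malignant >= 0) & (out.p_malignant <= 1))
        assert np.all((out.foci >= 0) & (out.foci <= 1))

    def test_deterministic_on_duplicate_input(self, micro_model, small_stack):
        a = net.forward(small_stack, micro_model)
        b = net.forward(small_stack, micro_model)
        np.testing.assert_array_equal(a.composition, b.composition)
        np.testing.assert_array_equal(a.p_malignant, b.p_malignant)

    def test_batch_permutation_equivariance(self, micro_model, rng):
        x = _batch(rng, n=5)
        perm = np.array([3, 0, 4, 1, 2])
        out = net.forward(x, micro_model)
        out_p = net.forward(x[perm], micro_model)
        np.testing.assert_allclose(out.composition[perm], out_p.composition,
                                   atol=1e-12)
        np.testing.assert_allclose(out.foci[perm], out_p.foci, atol=1e-12)

    def test_wrong_plane_count_rejected(self, micro_model):
        with pytest.raises(ValueError):
            micro_model.forward_features(np.zeros((1, 2, 16, 16)))

    def test_v2_head_arities(self, micro_model_v2, rng):
        out = net.forward(_batch(rng), micro_model_v2)
        assert out.composition.shape[1] == 3
        assert out.margin.shape[1] == 3
        assert out.echogenicity.ndim == 1

    def test_version_switch_keeps_backbone_family(self):
        m1 = net.build_model(net.HeadConfig(version="v1"), seed=0)
        m2 = net.build_model(net.HeadConfig(version="v2"), seed=0)
        assert m1.heads["margin"].W.shape[0] == 4
        assert m2.heads["margin"].W.shape[0] == 3
        assert m1.n_features == m2.n_features

    def test_pretrained_weights_unavailable(self):
        with pytest.raises(ValueError):
            net.HeadConfig(pretrained=True)


def oracle_breakdown(out, labels, version):
    """Independent per-head loss recomputation (plain-python formulas)."""
    eps = 1e-7

    def bce(p, y):
        vals = [
            -(yi * math.log(min(max(pi, eps), 1 - eps))
              + (1 - yi) * math.log(1 - min(max(pi, eps), 1 - eps)))
            for pi, yi in zip(p, y)
        ]
        return sum(vals) / len(vals)

    def ce(rows, idx):
        return sum(-math.log(max(row[i], eps)) for row, i in zip(rows, idx)) / len(idx)

    y_mal = [float(l.malignant) for l in labels]
    terms = {"L_m": bce(out.p_malignant, y_mal)}
    for j, (key, focus) in enumerate(zip(
            ("L_a", "L_b", "L_c", "L_d"), net.FOCI_ORDER)):
        terms[key] = bce(out.foci[:, j], [float(focus in l.foci) for l in labels])
    if version == "v1":
        terms["L_p"] = ce(out.composition,
                          [net.V1_COMPOSITION_CLASSES.index(l.composition)
                           for l in labels])
        terms["L_e"] = ce(out.echogenicity, [l.echogenicity_code for l in labels])
        terms["L_f"] = ce(out.margin,
                          [net.V1_MARGIN_CLASSES.index(l.margin) for l in labels])
    else:
        comp_targets = [l.composition_components() for l in labels]
        terms["L_p"] = sum(
            bce(out.composition[:, j], [t[j] for t in comp_targets])
            for j in range(3))
        terms["L_e"] = sum((v - l.echogenicity_code) ** 2
                           for v, l in zip(out.echogenicity, labels)) / len(labels)
        terms["L_f"] = ce(out.margin,
                          [net.V2_MARGIN_CLASSES.index(l.margin_v2)
                           for l in labels])
    return terms


class TestTotalLoss:
    def test_perfect_one_hot_predictions_give_near_zero_loss(self):
        labels = [net.LabelSet(True, "solid", "hypoechoic",
                               "lobulated_irregular", frozenset({"punctate_micro"}))]
        comp = np.zeros((1, 4)); comp[0, 1] = 1.0
        echo = np.zeros((1, 4)); echo[0, 1] = 1.0
        margin = np.zeros((1, 4)); margin[0, 2] = 1.0
        out = net.HeadOutputs("v1", np.array([1.0]), comp, echo, margin,
                              np.array([[0.0, 1.0, 0.0, 0.0]]))
        lb = net.total_loss(out, labels, net.HeadConfig())
        assert lb.L_all == pytest.approx(0.0, abs=1e-5)

    def test_uniform_four_class_head_contributes_ln4(self):
        labels = [net.LabelSet(False, "cystic", "anechoic", "smooth")]
        out = net.HeadOutputs(
            "v1", np.array([0.5]), np.full((1, 4), 0.25), np.full((1, 4), 0.25),
            np.full((1, 4), 0.25), np.full((1, 4), 0.5))
        lb = net.total_loss(out, labels, net.HeadConfig())
        assert lb.L_p == pytest.approx(math.log(4))
        assert lb.L_e == pytest.approx(math.log(4))
        assert lb.L_f == pytest.approx(math.log(4))

    @pytest.mark.parametrize("version", ["v1", "v2"])
    def test_random_batch_matches_per_head_oracle(self, version, rng,
                                                  micro_model, micro_model_v2):
        model = micro_model if version == "v1" else micro_model_v2
        labels = random_labels(6, rng)
        out = net.forward(_batch(rng, n=6), model)
        lb = net.total_loss(out, labels, model.cfg)
        oracle = oracle_breakdown(out, labels, version)
        for key, val in oracle.items():
            assert getattr(lb, key) == pytest.approx(val, rel=1e-9)
        assert lb.L_all == (lb.L_m + lb.L_p + lb.L_a + lb.L_b
                            + lb.L_c + lb.L_d + lb.L_e + lb.L_f)

    def test_version_mismatch_rejected(self, micro_model, rng):
        out = net.forward(_batch(rng), micro_model)
        with pytest.raises(ValueError):
            net.total_loss(out, random_labels(4, rng),
                           net.HeadConfig(version="v2", backbone="micro"))


class TestDecisions:
    @pytest.mark.parametrize("probs,expected", [
        ((0.6, 0.7, 0.1), "mixed"),
        ((0.6, 0.2, 0.1), "cystic"),
        ((0.4, 0.4, 0.9), "spongiform"),
        ((0.5, 0.5, 0.1), "cystic"),  # threshold not strictly exceeded; argmax
                                      # tie breaks to the first component
        ((0.2, 0.8, 0.3), "solid"),
    ])
    def test_mixed_rule(self, probs, expected):
        out = net.HeadOutputs("v2", np.array([0.5]), np.array([probs]),
                              np.array([1.0]), np.full((1, 3), 1 / 3),
                              np.full((1, 4), 0.5))
        cfg = net.HeadConfig(version="v2", backbone="micro")
        assert net.decide_composition(out, cfg) == [expected]

    @pytest.mark.parametrize("value,expected", [
        (1.4, "hypoechoic"),
        (3.7, "anechoic"),
        (-0.2, "hyperechoic"),
        (1.5, "very_hypoechoic"),   # half away from zero
        (0.49, "hyperechoic"),
        (2.51, "anechoic"),
    ])
    def test_echogenicity_rounding(self, value, expected):
        assert net.decide_echogenicity(value) == expected

    def test_echogenicity_identity_on_codes(self):
        for code, name in enumerate(net.ECHOGENICITY_CODE_ORDER):
            assert net.decide_echogenicity(float(code)) == name

    def test_echogenicity_rejects_non_finite(self):
        with pytest.raises(ValueError):
            net.decide_echogenicity(float("nan"))

    @given(st.floats(-5, 5, allow_nan=False))
    def test_echogenicity_always_a_valid_class(self, value):
        assert net.decide_echogenicity(value) in net.ECHOGENICITY_CODE_ORDER


class TestGradients:
    def test_every_head_reaches_the_backbone(self, rng):
        """Each head's loss alone must produce nonzero backbone gradients."""
        model = net.build_model(net.HeadConfig(backbone="micro"), seed=3)
        x = _batch(rng, n=2)
        for head in model.heads:
            feats = model.forward_features(x)
            logits = model.logits_from_features(feats)
            grads = {h: np.zeros_like(v) for h, v in logits.items()}
            grads[head][:, 0] = 1.0
            model.zero_grad()
            model.backward_from_logit_grads(feats, grads)
            backbone_norm = sum(
                float(np.abs(g).sum()) for _, g in model.backbone.params())
            assert backbone_norm > 0, f"head {head} detached from backbone"


@pytest.fixture(scope="module")
def tiny_run():
    from tiradscope import synthgen

    (tr_s, tr_l), _ = synthgen.composition_recovery_sets(
        n_train=32, n_test=0, seed=9, image_side=64)
    cfg = net.HeadConfig()
    model, hist = net.train((tr_s, tr_l), cfg, epochs=3, seed=9)
    return tr_s, tr_l, cfg, model, hist


class TestTraining:
    def test_loss_descends(self, tiny_run):
        _, _, _, _, hist = tiny_run
        assert hist[-1].L_all < hist[0].L_all

    def test_seeded_reruns_are_identical(self, tiny_run):
        tr_s, tr_l, cfg, _, hist = tiny_run
        _, hist2 = net.train((tr_s, tr_l), cfg, epochs=3, seed=9)
        assert hist2[-1].L_all == hist[-1].L_all

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            net.train((np.zeros((0, 3, 8, 8)), []), net.HeadConfig(backbone="micro"))

    def test_evaluate_matches_confusion_oracle(self, tiny_run):
        tr_s, tr_l, cfg, model, _ = tiny_run
        table = net.evaluate(model, (tr_s, tr_l), cfg)
        out = net.forward(tr_s, model)
        comp_pred = net.decide_composition(out, cfg)
        acc = 100.0 * sum(p == l.composition
                          for p, l in zip(comp_pred, tr_l)) / len(tr_l)
        assert table["composition"] == pytest.approx(acc)
        mal_pred = net.decide_malignant(out)
        acc_m = 100.0 * sum(bool(p) == bool(l.malignant)
                            for p, l in zip(mal_pred, tr_l)) / len(tr_l)
        assert table["malignancy"] == pytest.approx(acc_m)
        assert set(table) == set(net.EVAL_ROWS)

    def test_perfect_predictor_scores_100(self, tiny_run):
        """Evaluation of outputs equal to the labels yields 100% rows."""
        tr_s, tr_l, cfg, _, _ = tiny_run

        class Oracle:
            cfg = net.HeadConfig()

            def forward_logits(self, stacks):
                idx = [int(round(float(s[0, 0, 0]) * 1e6)) for s in stacks]
                logits = {"malignancy": [], "composition": [],
                          "echogenicity": [], "margin": [], "foci": []}
                for i in idx:
                    l = tr_l[i]
                    logits["malignancy"].append([20.0 if l.malignant else -20.0])
                    logits["composition"].append(
                        [20.0 if c == l.composition else -20.0
                         for c in net.V1_COMPOSITION_CLASSES])
                    logits["echogenicity"].append(
                        [20.0 if e == l.echogenicity else -20.0
                         for e in net.ECHOGENICITY_CODE_ORDER])
                    logits["margin"].append(
                        [20.0 if m == l.margin else -20.0
                         for m in net.V1_MARGIN_CLASSES])
                    logits["foci"].append(
                        [20.0 if f in l.foci else -20.0 for f in net.FOCI_ORDER])
                return {k: np.array(v) for k, v in logits.items()}

        tagged = tr_s.copy()
        for i in range(len(tagged)):
            tagged[i, 0, 0, 0] = i * 1e-6
        table = net.evaluate(Oracle(), (tagged, tr_l), cfg)
        assert all(v == 100.0 for v in table.values())

    def test_model_save_load_roundtrip(self, tiny_run, tmp_path, rng):
        _, _, _, model, _ = tiny_run
        path = str(tmp_path / "m.npz")
        model.save(path)
        clone = net.MultiHeadModel.load(path)
        x = _batch(rng, n=2, side=64)
        np.testing.assert_array_equal(
            net.forward(x, model).composition, net.forward(x, clone).composition)
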