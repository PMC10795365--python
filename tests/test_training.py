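import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import roc_curve

from lncpred.data_io import SyntheticSpec, generate_synthetic
from lncpred.fusion import EncoderConfig
from lncpred.nafs import NafsConfig
from lncpred.sdne import SdneConfig
from lncpred.similarity import build_similarity_bundle, semantic_similarity
from lncpred.training import (
    TrainConfig,
    _assert_no_leakage,
    bilinear_scores,
    evaluate,
    link_loss,
    link_loss_logits,
    make_folds,
    model_forward,
    run_cv,
    sample_negatives,
    train_fold,
)


def small_cfg(**kw):
    """Cheap configuration for unit-level end-to-end runs."""
    defaults = dict(
        epochs=3,
        n_ensembles=1,
        nafs=NafsConfig(k=3, r_list=(0.0, 0.5)),
        sdne=SdneConfig(nhid1=8, n_p=4),
        enc=EncoderConfig(l1=1, l2=1, h1=4, h2=4, width=16, ffn_width=32,
                          out_dim=8),
    )
    defaults.update(kw)
    return TrainConfig(**defaults)


@pytest.fixture(scope="module")
def small_data():
    ds, onto = generate_synthetic(
        SyntheticSpec(n_lnc=30, n_dis=24, n_blocks=3, p_in=0.35, p_out=0.03,
                      seed=11)
    )
    sem = semantic_similarity(onto, ds.disease_ids)
    return ds, onto, sem


class TestBilinearDecoder:
    def test_zero_weights_give_half(self):
        X_L = np.random.default_rng(0).normal(size=(4, 3))
        X_D = np.random.default_rng(1).normal(size=(5, 3))
        assert np.allclose(bilinear_scores(X_L, X_D, np.zeros((3, 3))), 0.5)

    def test_basis_vector_closed_form(self):
        e = np.zeros((1, 3))
        e[0, 0] = 1.0
        s = bilinear_scores(e, e, np.eye(3))
        assert np.isclose(s[0, 0], 1.0 / (1.0 + np.exp(-1.0)))

    def test_scores_increase_with_logit(self):
        X_L = np.array([[1.0], [2.0], [3.0]])
        X_D = np.array([[1.0]])
        s = np.asarray(bilinear_scores(X_L, X_D, np.eye(1)))
        assert (np.diff(s[:, 0]) > 0).all()

    def test_width_mismatch_rejected(self):
        with pytest.raises(ValueError):
            bilinear_scores(np.zeros((2, 3)), np.zeros((2, 4)), np.eye(3))


class TestLinkLoss:
    def test_uninformative_scores_give_n_ln2(self):
        A = np.array([[1, 1], [0, 0]])
        A_hat = np.full((2, 2), 0.5)
        pos = [(0, 0), (0, 1)]
        neg = [(1, 0), (1, 1)]
        assert np.isclose(link_loss(A, A_hat, pos, neg), 4 * np.log(2))

    def test_perfect_scores_drive_loss_to_zero(self):
        A = np.array([[1, 0]])
        A_hat = np.array([[1 - 1e-9, 1e-9]])
        assert link_loss(A, A_hat, [(0, 0)], [(0, 1)]) < 1e-6

    def test_empty_union_rejected(self):
        with pytest.raises(ValueError):
            link_loss(np.eye(2), np.eye(2), [], [])

    def test_matches_per_pair_loop_oracle(self):
        rng = np.random.default_rng(2)
        A = (rng.random((6, 5)) < 0.4).astype(int)
        A_hat = rng.uniform(0.01, 0.99, (6, 5))
        pos = np.argwhere(A == 1)[:4]
        neg = np.argwhere(A == 0)[:5]
        oracle = 0.0
        for i, j in pos:
            oracle -= np.log(A_hat[i, j])
        for i, j in neg:
            oracle -= np.log(1.0 - A_hat[i, j])
        assert abs(link_loss(A, A_hat, pos, neg) - oracle) < 1e-10

    def test_logit_form_agrees_with_probability_form(self):
        rng = np.random.default_rng(3)
        logits = rng.normal(scale=3.0, size=(5, 4))
        probs = 1.0 / (1.0 + np.exp(-logits))
        A = (rng.random((5, 4)) < 0.5).astype(int)
        pos = np.argwhere(A == 1)
        neg = np.argwhere(A == 0)
        assert np.isclose(
            link_loss_logits(logits, pos, neg),
            link_loss(A, probs, pos, neg),
        )


class TestSampling:
    def test_negatives_are_zeros_and_reproducible(self):
        rng = np.random.default_rng(4)
        A = (np.random.default_rng(0).random((8, 6)) < 0.4).astype(int)
        neg = sample_negatives(A, 10, np.random.default_rng(4))
        assert (A[neg[:, 0], neg[:, 1]] == 0).all()
        neg2 = sample_negatives(A, 10, np.random.default_rng(4))
        assert np.array_equal(neg, neg2)

    def test_exhaustion_returns_all_zeros(self):
        A = np.array([[1, 0], [0, 1]])
        neg = sample_negatives(A, 2, np.random.default_rng(0))
        assert sorted(map(tuple, neg)) == [(0, 1), (1, 0)]

    def test_oversampling_rejected(self):
        A = np.ones((2, 2), dtype=int)
        with pytest.raises(ValueError):
            sample_negatives(A, 1, np.random.default_rng(0))

    def test_excluded_pairs_never_sampled(self):
        A = np.zeros((4, 4), dtype=int)
        excl = np.array([[0, 0], [1, 1]])
        for seed in range(5):
            neg = sample_negatives(A, 14, np.random.default_rng(seed), excl)
            assert not ({(0, 0), (1, 1)} & set(map(tuple, neg)))


class TestFolds:
    def test_five_fold_partition_of_ten(self):
        pos = np.array([(i, i) for i in range(10)])
        folds = make_folds(pos, 5, np.random.default_rng(0))
        assert len(folds) == 5
        assert all(len(test) == 2 for _, test in folds)
        seen = sorted(tuple(p) for _, test in folds for p in test)
        assert seen == sorted(map(tuple, pos))

    def test_same_seed_same_partition(self):
        pos = np.array([(i, j) for i in range(4) for j in range(3)])
        f1 = make_folds(pos, 4, np.random.default_rng(9))
        f2 = make_folds(pos, 4, np.random.default_rng(9))
        for (tr1, te1), (tr2, te2) in zip(f1, f2):
            assert np.array_equal(te1, te2)

    def test_too_few_folds_rejected(self):
        with pytest.raises(ValueError):
            make_folds(np.array([(0, 0), (1, 1)]), 1, np.random.default_rng(0))


class TestEvaluate:
    def test_perfect_separation(self):
        m = evaluate([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0])
        assert m["auc"] == 1.0
        assert m["aupr"] == 1.0
        assert m["f1"] == 1.0

    def test_three_score_worked_example(self):
        # one concordant and one discordant positive-negative pair
        m = evaluate([0.9, 0.8, 0.3], [1, 0, 1])
        assert np.isclose(m["auc"], 0.5)

    def test_thresholded_confusion_example(self):
        m = evaluate([0.9, 0.2], [1, 0], threshold=0.5)
        assert m["acc"] == 1.0
        assert m["f1"] == 1.0
        assert m["specificity"] == 1.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            evaluate([0.4, 0.6], [1, 1])

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_auc_equals_trapezoidal_roc_integral(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.random(60)
        labels = (rng.random(60) < 0.4).astype(int)
        m = evaluate(scores, labels)
        fpr, tpr, _ = roc_curve(labels, scores)
        assert abs(m["auc"] - np.trapezoid(tpr, fpr)) < 1e-9

    @pytest.mark.parametrize(
        "transform", [np.exp, lambda s: 3.0 * s + 1.0, lambda s: s**3]
    )
    def test_rank_metrics_invariant_to_monotone_transforms(self, transform):
        rng = np.random.default_rng(5)
        scores = rng.uniform(0.05, 0.95, 40)
        labels = (rng.random(40) < 0.5).astype(int)
        base = evaluate(scores, labels)
        moved = evaluate(transform(scores), labels)
        assert np.isclose(base["auc"], moved["auc"])
        assert np.isclose(base["aupr"], moved["aupr"])

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(
        data=st.lists(
            st.tuples(
                st.floats(0.01, 0.99, allow_nan=False), st.booleans()
            ),
            min_size=4,
            max_size=30,
        ),
        scale=st.floats(0.1, 5.0),
        shift=st.floats(-2.0, 2.0),
    )
    def test_auc_invariance_property(self, data, scale, shift):
        scores = np.array([s for s, _ in data])
        labels = np.array([int(l) for _, l in data])
        if len(np.unique(labels)) < 2:
            return
        base = evaluate(scores, labels)["auc"]
        moved = evaluate(scale * scores + shift, labels)["auc"]
        assert np.isclose(base, moved)


class TestLeakageGuard:
    def test_masked_bundle_passes_and_leaky_bundle_fails(self, small_data):
        ds, onto, sem = small_data
        test_pos = ds.positives()[:5]
        masked = ds.masked(test_pos)
        bundle = build_similarity_bundle(masked, sem)
        _assert_no_leakage(masked, bundle, test_pos)  # must not raise
        leaky = build_similarity_bundle(ds, sem)
        with pytest.raises(AssertionError):
            _assert_no_leakage(ds, leaky, test_pos)


class TestEndToEnd:
    def test_report_structure_and_mean(self, small_data):
        ds, onto, _ = small_data
        cfg = small_cfg(k_folds=3)
        report = run_cv(ds, onto, cfg)
        assert len(report.folds) == 3
        for key, value in report.mean.items():
            assert np.isclose(
                value, np.mean([f[key] for f in report.folds]), atol=1e-12
            )
            assert 0.0 <= value <= 1.0

    def test_identical_seed_identical_report(self, small_data):
        ds, onto, _ = small_data
        cfg = small_cfg(k_folds=3)
        r1 = run_cv(ds, onto, cfg)
        r2 = run_cv(ds, onto, cfg)
        assert r1.to_dict() == r2.to_dict()

    def test_ratio_changes_only_negative_counts(self, small_data):
        """The fold partition of the positives is ratio-independent."""
        ds, _, _ = small_data
        pos = ds.positives()
        f1 = make_folds(pos, 3, np.random.default_rng(50))
        f5 = make_folds(pos, 3, np.random.default_rng(50))
        for (_, te1), (_, te5) in zip(f1, f5):
            assert np.array_equal(te1, te5)
        cfg1 = small_cfg(ratio=1.0)
        cfg5 = small_cfg(ratio=5.0)
        assert cfg1.to_dict()["ratio"] != cfg5.to_dict()["ratio"]

    def test_remove_t1_ablation_runs_end_to_end(self, small_data):
        ds, onto, sem = small_data
        cfg = small_cfg(ablations=("remove_T1",))
        folds = make_folds(ds.positives(), cfg.k_folds, np.random.default_rng(1))
        _, metrics, _ = train_fold(ds, sem, folds[0], cfg,
                                   np.random.default_rng(2))
        assert 0.0 <= metrics["auc"] <= 1.0

    def test_untrained_model_scores_are_uninformative(self, small_data):
        ds, onto, sem = small_data
        cfg = small_cfg(epochs=0)
        folds = make_folds(ds.positives(), cfg.k_folds, np.random.default_rng(3))
        _, metrics, _ = train_fold(ds, sem, folds[0], cfg,
                                   np.random.default_rng(4))
        assert 0.2 < metrics["auc"] < 0.8

    def test_loss_trace_decreases(self, small_data):
        ds, onto, sem = small_data
        cfg = small_cfg(epochs=40)
        folds = make_folds(ds.positives(), cfg.k_folds, np.random.default_rng(5))
        _, _, trace = train_fold(ds, sem, folds[0], cfg,
                                 np.random.default_rng(6))
        l_m = [t["l_m"] for t in trace]
        smooth = np.convolve(l_m, np.ones(10) / 10, mode="valid")
        assert smooth[-1] < smooth[0]
        assert (np.diff(smooth) < 0).mean() > 0.8

    def test_zero_structure_bias_equals_remove_sdne_path(self, small_data):
        """Ablating both SDNE encoders is exactly the SF = 0 fusion path."""
        ds, onto, sem = small_data
        bundle = build_similarity_bundle(ds, sem)
        cfg_abl = small_cfg(ablations=("remove_lnc_sdne", "remove_dis_sdne"))
        cfg_full = small_cfg()
        from lncpred.training import _build_inputs, init_model_params

        inputs = _build_inputs(bundle, cfg_full)
        dims = {
            "n_l": ds.n_lnc,
            "n_d": ds.n_dis,
            "d_ZG": inputs["Z_G"].shape[1],
            "d_ZL": inputs["Z_L"].shape[1],
            "d_ZD": inputs["Z_D"].shape[1],
        }
        params = init_model_params(dims, cfg_full, np.random.default_rng(7))
        logits_abl, l_l, l_d = model_forward(params, inputs, cfg_abl)
        assert l_l == 0.0 and l_d == 0.0

        from lncpred.fusion import fuse, global_encode
        from lncpred.nafs import project_and_stack
        from lncpred.training import bilinear_logits

        Z_LD = project_and_stack(inputs["Z_L"], inputs["Z_D"],
                                 params["W_LD"], params["b_LD"])
        X = global_encode(inputs["Z_G"], params["global"], cfg_full.enc)
        SF0 = np.zeros((ds.n_lnc + ds.n_dis, cfg_full.sdne.n_p))
        X_S = fuse(X, Z_LD, SF0, params["fusion"], cfg_full.enc)
        manual = bilinear_logits(X_S[: ds.n_lnc], X_S[ds.n_lnc :],
                                 params["W_B"])
        assert np.allclose(np.asarray(logits_abl), np.asarray(manual))
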