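import numpy as np
import pytest

from splicebalance.model import (
    ModelParams,
    TunerFull,
    TunerPrime,
    encode_dataset,
    model_forward_batch,
    softplus,
)
from splicebalance.training import (
    TrainConfig,
    _batch_forward_backward,
    activity_penalty,
    bernoulli_kl,
    grid_search,
    smoothness_penalty,
    sparsity_metric,
    train_stage1,
    train_stage2,
    train_stage3,
)

from conftest import assay_to_dataset
from splicebalance.preprocess import train_test_split
from splicebalance.synthetic import build_synthetic_assay


class TestBernoulliKL:
    @pytest.mark.parametrize(
        "p,q,expect",
        [
            (0.5, 0.5, 0.0),
            (1.0, 0.5, np.log(2)),
            (0.0, 0.5, np.log(2)),
            # direct evaluation: 0.3 ln(0.3/0.7) + 0.7 ln(0.7/0.3)
            (0.3, 0.7, 0.3 * np.log(3 / 7) + 0.7 * np.log(7 / 3)),
        ],
    )
    def test_closed_form(self, p, q, expect):
        assert bernoulli_kl(p, q) == pytest.approx(expect, abs=1e-9)

    def test_nonnegative_zero_iff_equal(self):
        grid = np.linspace(0.01, 0.99, 25)
        P, Q = np.meshgrid(grid, grid)
        kl = bernoulli_kl(P, Q)
        assert np.all(kl >= 0)
        diag = bernoulli_kl(grid, grid)
        assert np.allclose(diag, 0.0, atol=1e-12)
        off = kl[~np.eye(25, dtype=bool)]
        assert np.all(off > 0)


class TestPenalties:
    def test_activity_is_plain_sum_of_strengths(self, rng):
        maps = [softplus(rng.normal(size=(10, 4))), softplus(rng.normal(size=(5, 2)))]
        assert activity_penalty(maps) == pytest.approx(sum(m.sum() for m in maps))

    def test_activity_zero_preactivation_value(self):
        # softplus(0) = ln 2 at every one of 85 x 20 entries
        maps = [np.full((85, 20), np.log(2.0))]
        assert activity_penalty(maps) == pytest.approx(1700 * np.log(2.0))

    def test_smoothness_constant_column_is_zero(self):
        assert smoothness_penalty([np.full((40, 3), 2.5)]) == 0.0

    def test_smoothness_hand_value(self):
        beta = np.array([[0.0], [1.0], [3.0]])  # diffs 1, 2 -> 1 + 4 = 5
        assert smoothness_penalty([beta]) == pytest.approx(5.0)

    def test_smoothness_shift_invariant(self, rng):
        beta = rng.normal(size=(20, 4))
        assert smoothness_penalty([beta]) == pytest.approx(
            smoothness_penalty([beta + 7.3])
        )


class TestGradients:
    """Analytic gradients vs central finite differences."""

    def _loss(self, params, Xs, Xt, p, cfg):
        from numpy.lib.stride_tricks import sliding_window_view
        from splicebalance.model import SCM_SIGNS, sigmoid

        n = Xs.shape[0]
        inputs = {"seq": Xs, "struct": Xt}
        delta = np.full(n, params.B)
        act = 0.0
        smooth = 0.0
        for key, scm in params.scms.items():
            win = sliding_window_view(inputs[scm.channels], scm.w, axis=1)
            z = np.einsum("npcw,wcf->npf", win, scm.alpha)
            s = softplus(z + scm.beta)
            delta += SCM_SIGNS[key] * s.sum(axis=(1, 2))
            act += s.sum()
            smooth += (np.diff(scm.beta, axis=0) ** 2).sum()
        q = np.asarray(params.tuner(delta), dtype=float)
        kl = np.mean(bernoulli_kl(p, q, eps=cfg.eps_clip))
        return kl + cfg.lambda_activity * act / n + cfg.lambda_smooth * smooth

    @pytest.mark.parametrize("tuner_kind", ["prime", "full"])
    def test_gradients_match_finite_differences(self, rng, tuner_kind):
        d, n = 12, 6
        params = ModelParams.default(d=d, k_seq=3, k_struct=2, w_seq=3, w_struct=5, seed=1)
        params.B = 0.2
        if tuner_kind == "full":
            params.tuner = TunerFull.from_prime(TunerPrime(1.1, -0.2), hidden=(4, 3), seed=2)
            params.tuner.w3 = rng.normal(0, 0.3, params.tuner.w3.shape)
        Xs = (rng.random((n, d, 4)) < 0.25).astype(float)
        Xt = rng.random((n, d, 8))
        p = rng.random(n)
        cfg = TrainConfig(lambda_activity=1e-3, lambda_smooth=1e-2)
        _, grads = _batch_forward_backward(params, Xs, Xt, p, cfg)

        def check(key, setter, getter):
            eps = 1e-6
            p_hi, p_lo = params.copy(), params.copy()
            setter(p_hi, +eps)
            setter(p_lo, -eps)
            num = (self._loss(p_hi, Xs, Xt, p, cfg) - self._loss(p_lo, Xs, Xt, p, cfg)) / (2 * eps)
            assert getter(grads) == pytest.approx(num, rel=1e-4, abs=1e-7), key

        check("B", lambda pp, e: setattr(pp, "B", pp.B + e), lambda g: g["B"])
        check(
            "alpha",
            lambda pp, e: pp.scms["skip_struct"].alpha.__setitem__((2, 5, 1), pp.scms["skip_struct"].alpha[2, 5, 1] + e),
            lambda g: g["scm.skip_struct.alpha"][2, 5, 1],
        )
        check(
            "beta",
            lambda pp, e: pp.scms["incl_seq"].beta.__setitem__((4, 0), pp.scms["incl_seq"].beta[4, 0] + e),
            lambda g: g["scm.incl_seq.beta"][4, 0],
        )
        if tuner_kind == "prime":
            check("nu", lambda pp, e: setattr(pp.tuner, "nu", pp.tuner.nu + e), lambda g: g["tuner.nu"])
        else:
            check("r", lambda pp, e: setattr(pp.tuner, "r", pp.tuner.r + e), lambda g: g["tuner.r"])
            check(
                "W2",
                lambda pp, e: pp.tuner.W2.__setitem__((1, 2), pp.tuner.W2[1, 2] + e),
                lambda g: g["tuner.W2"][1, 2],
            )


@pytest.fixture(scope="module")
def tiny_training_setup():
    """A small planted-motif assay split and encoded once for stage tests."""
    assay = build_synthetic_assay(n_exons=1200, depth=300, seed=21)
    df = assay_to_dataset(assay)
    train, test = train_test_split(df, 0.8, seed=0)
    return encode_dataset(train), encode_dataset(test), test


@pytest.fixture(scope="module")
def tiny_config():
    return TrainConfig(seed=0, epochs_stage1=120, epochs_stage2=40, epochs_stage3=8)


@pytest.fixture(scope="module")
def staged_params(tiny_training_setup, tiny_config):
    train_enc, test_enc, _ = tiny_training_setup
    p1, h1 = train_stage1(train_enc, tiny_config, heldout=test_enc, k_seq=4)
    p2, h2 = train_stage2(p1, train_enc, tiny_config, heldout=test_enc, k_struct=2)
    p3, h3 = train_stage3(p2, train_enc, tiny_config, heldout=test_enc)
    return {"1": (p1, h1), "2": (p2, h2), "3": (p3, h3)}


class TestStagedTraining:
    def test_stage1_beats_constant_predictor_on_separable_data(self):
        """One strong planted motif, no structure features: stage 1 must beat
        the best constant predictor on held-out KL."""
        from splicebalance.synthetic import (
            GroundTruthRule, MotifFeature, PlantingScheme, build_synthetic_assay,
        )

        rule = GroundTruthRule(
            motifs=(MotifFeature("GAAGAA", "inclusion", 3.0),),
            stem_feature=None, gpoor_feature=None,
        )
        assay = build_synthetic_assay(
            rule=rule, n_exons=1200, depth=300, seed=23,
            planting=PlantingScheme(p_motif=0.4, p_stem=0.0, p_gpoor=0.0),
        )
        df = assay_to_dataset(assay)
        train, test = train_test_split(df, 0.8, seed=0)
        train_enc, test_enc = encode_dataset(train), encode_dataset(test)
        cfg = TrainConfig(seed=0, epochs_stage1=60)
        _, h1 = train_stage1(train_enc, cfg, heldout=test_enc, k_seq=2)
        baseline_q = np.full(len(test_enc), float(test_enc.psi.mean()))
        baseline = float(np.mean(bernoulli_kl(test_enc.psi, baseline_q)))
        assert h1[-1]["heldout_kl"] < baseline

    def test_stage1_deterministic(self, tiny_training_setup, tiny_config):
        train_enc, _, _ = tiny_training_setup
        a, ha = train_stage1(train_enc, tiny_config, k_seq=2)
        b, hb = train_stage1(train_enc, tiny_config, k_seq=2)
        assert ha[-1]["loss"] == hb[-1]["loss"]
        assert np.array_equal(a.scms["incl_seq"].alpha, b.scms["incl_seq"].alpha)

    def test_stage1_has_no_structure_scms(self, staged_params):
        p1, _ = staged_params["1"]
        assert set(p1.scms) == {"incl_seq", "skip_seq"}

    def test_stage2_warm_start_and_improvement(self, staged_params):
        p2, h2 = staged_params["2"]
        _, h1 = staged_params["1"]
        assert set(p2.scms) == {"incl_seq", "incl_struct", "skip_seq", "skip_struct"}
        # planted stem/G-poor features are invisible to stage 1, so adding
        # structure SCMs must improve held-out KL on this assay
        assert h2[-1]["heldout_kl"] < h1[-1]["heldout_kl"]

    def test_stage3_initially_reproduces_stage2(self, tiny_training_setup, staged_params, tiny_config):
        train_enc, test_enc, _ = tiny_training_setup
        p2, _ = staged_params["2"]
        p3_init = p2.copy()
        p3_init.tuner = TunerFull.from_prime(p2.tuner, seed=tiny_config.seed + 3)
        q2, _ = model_forward_batch(test_enc.X_seq, test_enc.X_struct, p2)
        q3, _ = model_forward_batch(test_enc.X_seq, test_enc.X_struct, p3_init)
        assert np.abs(q2 - q3).max() < 1e-4

    def test_stage3_does_not_regress(self, staged_params):
        (_, h2), (_, h3) = staged_params["2"], staged_params["3"]
        assert h3[-1]["heldout_kl"] <= h2[-1]["heldout_kl"] + 0.01

    def test_loss_decomposition_logged(self, staged_params):
        _, h1 = staged_params["1"]
        for entry in h1:
            assert set(entry) >= {"loss", "kl", "activity", "smoothness", "heldout_kl"}
            assert np.isfinite(entry["loss"])


class TestSparsityMetric:
    def test_infinite_threshold_gives_zero(self, staged_params, tiny_training_setup):
        _, test_enc, _ = tiny_training_setup
        p3, _ = staged_params["3"]
        assert sparsity_metric(p3, test_enc, kl_threshold=np.inf, max_records=50) == 0.0

    def test_non_increasing_in_threshold(self, staged_params, tiny_training_setup):
        _, test_enc, _ = tiny_training_setup
        p3, _ = staged_params["3"]
        vals = [
            sparsity_metric(p3, test_enc, kl_threshold=t, max_records=50)
            for t in (0.01, 0.05, 0.2, 1.0)
        ]
        assert all(a >= b for a, b in zip(vals, vals[1:]))

    def test_dominant_single_filter_counts_one(self):
        """A model whose prediction is driven by one huge activation per exon."""
        d = 12
        params = ModelParams.default(d=d, k_seq=1, w_seq=3, include_structure=False, seed=0)
        scm = params.scms["incl_seq"]
        scm.alpha[:] = 0.0
        scm.alpha[0, 0, 0] = 30.0  # 'A' at window start -> huge strength
        scm.beta[:] = -15.0
        params.scms["skip_seq"].alpha[:] = 0.0
        params.scms["skip_seq"].beta[:] = -15.0
        params.tuner = TunerPrime(1.0, 0.0)
        import pandas as pd

        df = pd.DataFrame(
            {"sequence": ["AGGGGGGGGGGG", "AGGGGGGGGGGG"],
             "structure": ["." * d] * 2, "psi": [1.0, 1.0]}
        )
        enc = encode_dataset(df)
        val = sparsity_metric(params, enc, kl_threshold=0.05)
        assert val == pytest.approx(1.0)


class TestGridSearch:
    def _fake_train(self, results):
        def fn(cfg):
            key = (cfg.lambda_activity, cfg.lambda_smooth)
            return results[key]
        return fn

    def test_single_point_returned(self, tiny_training_setup, tiny_config):
        train_enc, test_enc, _ = tiny_training_setup
        params = ModelParams.default(d=90, k_seq=2, k_struct=2, seed=0)
        chosen, report = grid_search(
            train_enc, test_enc, tiny_config,
            grid_activity=(1e-4,), grid_smooth=(1e-3,),
            kl_cutoff=np.inf, sparsity_cutoff=np.inf,
            train_fn=lambda cfg: (params, 0.01),
        )
        assert chosen.lambda_activity == 1e-4
        assert chosen.lambda_smooth == 1e-3
        assert len(report) == 1

    def test_highest_smoothness_among_passing(self, tiny_training_setup, tiny_config):
        train_enc, test_enc, _ = tiny_training_setup
        params = ModelParams.default(d=90, k_seq=2, k_struct=2, seed=0)
        chosen, _ = grid_search(
            train_enc, test_enc, tiny_config,
            grid_activity=(1e-4,), grid_smooth=(0.1, 1.0),
            kl_cutoff=np.inf, sparsity_cutoff=np.inf,
            train_fn=lambda cfg: (params, 0.01),
        )
        assert chosen.lambda_smooth == 1.0

    def test_fallback_warns_when_unmeetable(self, tiny_training_setup, tiny_config):
        train_enc, test_enc, _ = tiny_training_setup
        params = ModelParams.default(d=90, k_seq=2, k_struct=2, seed=0)
        with pytest.warns(RuntimeWarning):
            chosen, report = grid_search(
                train_enc, test_enc, tiny_config,
                grid_activity=(1e-4,), grid_smooth=(0.1, 1.0),
                kl_cutoff=-1.0, sparsity_cutoff=-1.0,  # impossible
                train_fn=lambda cfg: (params, 0.01),
            )
        assert chosen is not None


class TestMonotonicityAudit:
    def test_prime_always_monotone(self):
        from splicebalance.training import audit_tuner_monotonicity

        assert audit_tuner_monotonicity(TunerPrime(2.0, -1.0), (-5, 5))

    def test_rigged_full_tuner_flagged(self):
        from splicebalance.training import audit_tuner_monotonicity

        tuner = TunerFull.from_prime(TunerPrime(0.01, 0.0), hidden=(4, 4), seed=0)
        tuner.w3 = np.full(4, 5.0)  # large MLP term dominates the tiny residual
        with pytest.warns(RuntimeWarning):
            assert not audit_tuner_monotonicity(tuner, (-5, 5))


def test_staged_no_worse_than_joint_training(tiny_training_setup, tiny_config):
    """Regression guard: the staged schedule should not lose to training all
    four SCMs jointly from scratch with the same total budget."""
    from dataclasses import replace

    from splicebalance.model import ModelParams
    from splicebalance.training import _heldout_kl, _run_epochs, train_staged

    train_enc, test_enc, _ = tiny_training_setup
    cfg = replace(tiny_config, epochs_stage1=60, epochs_stage2=30)
    staged, _ = train_staged(
        train_enc, cfg, heldout=None, stages=(1, 2), k_seq=4, k_struct=2
    )
    joint = ModelParams.default(
        d=train_enc.d, k_seq=4, k_struct=2, include_structure=True,
        init_scale=cfg.init_scale, beta_init=cfg.beta_init, seed=cfg.seed,
    )
    rng = np.random.default_rng(cfg.seed)
    _run_epochs(joint, train_enc, cfg, 90, 1, None, rng, False)
    staged_kl = _heldout_kl(staged, test_enc, cfg.eps_clip)
    joint_kl = _heldout_kl(joint, test_enc, cfg.eps_clip)
    assert staged_kl <= joint_kl + 0.05
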