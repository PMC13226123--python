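"""Tests of the attention-MIL survival model and late fusion."""

import numpy as np
import pandas as pd
import pytest

from multirisk import mil, survival as sv, synth
from multirisk.synth import PatchBag


def make_bag(n, d, seed, pid="P0"):
    rng = np.random.default_rng(seed)
    side = max(2, int(np.ceil(np.sqrt(n))) * 2)
    cells = rng.choice(side * side, n, replace=False)
    coords = np.stack([cells % side, cells // side], axis=1) * 224
    return PatchBag(pid, rng.normal(0, 1, (n, d)).astype(np.float32), coords)


def make_model(d=4, a=3, h=5, t=2, uses_mol=False, seed=0):
    rng = np.random.default_rng(seed)
    F = d + int(uses_mol) + t
    params = mil._init_params(d, F, mil.MILHyperparams(attention_dim=a, mlp_hidden=h), rng)
    return mil.TrainedMILModel(
        params=params,
        embed_dim=d,
        treatment_levels=["Pembro", "PembroChemo"][:t],
        uses_molecular=uses_mol,
        chosen_hyperparams=mil.MILHyperparams(attention_dim=a, mlp_hidden=h),
        train_median_risk=0.0,
    )


class TestAttentionPool:
    def test_single_patch_simplex(self):
        bag = make_bag(1, 4, 0)
        model = make_model()
        z, a = mil.attention_pool(bag, model)
        np.testing.assert_allclose(a, [1.0])
        np.testing.assert_allclose(z, bag.embeddings[0], rtol=1e-6)

    def test_identical_patches_uniform(self):
        emb = np.tile(np.random.default_rng(1).normal(0, 1, 4), (6, 1)).astype(np.float32)
        coords = np.stack([np.arange(6), np.zeros(6, int)], axis=1) * 224
        bag = PatchBag("P0", emb, coords)
        _, a = mil.attention_pool(bag, make_model())
        np.testing.assert_allclose(a, np.full(6, 1 / 6), atol=1e-12)

    def test_permutation_equivariance(self):
        bag = make_bag(9, 4, 2)
        model = make_model()
        z1, a1 = mil.attention_pool(bag, model)
        perm = np.random.default_rng(3).permutation(9)
        bag2 = PatchBag("P0", bag.embeddings[perm], bag.coords[perm])
        z2, a2 = mil.attention_pool(bag2, model)
        np.testing.assert_allclose(z1, z2, atol=1e-12)
        np.testing.assert_allclose(a1[perm], a2, atol=1e-12)

    def test_dimension_mismatch_rejected(self):
        bag = make_bag(5, 7, 4)
        with pytest.raises(ValueError, match="dimension"):
            mil.attention_pool(bag, make_model(d=4))


class TestForwardRisk:
    def test_zero_mlp_outputs_bias(self):
        model = make_model()
        model.params["W1"][:] = 0
        model.params["W2"][:] = 0
        model.params["b2"][:] = 1.75
        for seed in range(3):
            bag = make_bag(6, 4, seed + 10)
            assert mil.forward_risk(bag, model, "Pembro") == pytest.approx(1.75)

    def test_finite_output_contract(self):
        model = make_model(uses_mol=True)
        for seed in range(5):
            bag = make_bag(8, 4, seed + 20)
            r = mil.forward_risk(bag, model, "PembroChemo", molecular_score=0.3)
            assert np.isfinite(r)

    def test_molecular_flag_mismatch_rejected(self):
        bag = make_bag(4, 4, 30)
        with pytest.raises(ValueError, match="uses_molecular"):
            mil.forward_risk(bag, make_model(uses_mol=True), "Pembro")
        with pytest.raises(ValueError, match="uses_molecular"):
            mil.forward_risk(bag, make_model(), "Pembro", molecular_score=0.5)

    def test_risk_gradient_matches_finite_differences(self):
        # d(risk)/d(parameter) on a small model, inference path (no dropout)
        rng = np.random.default_rng(5)
        B, N, D, T = 3, 6, 4, 2
        H = rng.normal(0, 1, (B, N, D))
        mask = np.ones((B, N), bool)
        mol = rng.random(B)
        treat = np.eye(T)[rng.integers(0, T, B)]
        hp = mil.MILHyperparams(attention_dim=3, mlp_hidden=5)
        params = mil._init_params(D, D + 1 + T, hp, rng)
        target = 1  # gradient of patient 1's risk
        r, cache = mil._forward(params, H, mask, mol, treat)
        dr = np.zeros(B)
        dr[target] = 1.0
        grads = mil._backward(params, cache, dr)
        eps = 1e-6
        for k, v in params.items():
            num = np.zeros_like(v)
            it = np.nditer(v, flags=["multi_index"])
            for _ in it:
                idx = it.multi_index
                v[idx] += eps
                rp, _ = mil._forward(params, H, mask, mol, treat)
                v[idx] -= 2 * eps
                rm, _ = mil._forward(params, H, mask, mol, treat)
                v[idx] += eps
                num[idx] = (rp[target] - rm[target]) / (2 * eps)
            scale = max(np.abs(num).max(), 1e-3)
            assert np.abs(num - grads[k]).max() / scale < 1e-4, k


class TestCoxNll:
    def test_shift_invariance(self):
        rng = np.random.default_rng(6)
        r = rng.normal(0, 1, 20)
        t = rng.exponential(5, 20)
        e = rng.integers(0, 2, 20)
        e[0] = 1
        assert mil.cox_nll(r, t, e) == pytest.approx(mil.cox_nll(r + 17.3, t, e))

    def test_two_patient_closed_form(self):
        for r1, r2 in [(0.0, 0.0), (1.0, -1.0), (2.5, 0.3)]:
            loss = mil.cox_nll([r1, r2], [1.0, 2.0], [1, 0])
            assert loss == pytest.approx(np.log(1 + np.exp(r2 - r1)))

    def test_agrees_with_survival_core(self):
        rng = np.random.default_rng(7)
        r = rng.normal(0, 1, 40)
        t = np.round(rng.exponential(5, 40), 0) + 0.5  # forces ties
        e = rng.integers(0, 2, 40)
        e[:4] = 1
        data = sv.SurvivalData(t, e, r[:, None])
        expected = -sv.cox_partial_loglik(np.ones(1), data, "breslow") / e.sum()
        assert mil.cox_nll(r, t, e) == pytest.approx(expected, abs=1e-10)

    def test_gradient_matches_finite_differences_with_ties(self):
        rng = np.random.default_rng(8)
        r = rng.normal(0, 1, 15)
        t = np.round(rng.exponential(5, 15), 0) + 0.5
        e = rng.integers(0, 2, 15)
        e[:3] = 1
        g = mil._cox_nll_grad(r, t, e)
        eps = 1e-6
        for i in range(15):
            d = np.zeros(15)
            d[i] = eps
            num = (mil.cox_nll(r + d, t, e) - mil.cox_nll(r - d, t, e)) / (2 * eps)
            assert g[i] == pytest.approx(num, abs=1e-7)

    def test_no_events_rejected(self):
        with pytest.raises(ValueError):
            mil.cox_nll([0.1, 0.2], [1.0, 2.0], [0, 0])


def strong_cohort_and_bags(n=100, seed=0):
    cfg = synth.CohortConfig(
        seed=seed, n_pembro=n // 2, n_chemo=n - n // 2,
        covariate_effect_logHR=0.0, mol_risk_sd=0.2, img_risk_sd=1.6,
        tls_effect_logHR=0.0,
    )
    coh = synth.generate_cohort(cfg)
    bcfg = synth.BagConfig(
        seed=seed + 1, embed_dim=8, patches_min=15, patches_max=30,
        informative_fraction=0.5, informative_shift=4.0, marker_shift=3.0,
        risk_slope=3.0,
    )
    bags = synth.generate_patch_bags(coh, bcfg)
    return coh, bags


QUICK_HP = mil.MILHyperparams(
    attention_dim=4, mlp_hidden=8, epochs=120, n_final_refits=2
)


class TestTraining:
    def test_strong_signal_learnability(self):
        coh, bags = strong_cohort_and_bags(seed=100)
        tr = coh.index[: int(0.7 * len(coh))]
        te = coh.index[int(0.7 * len(coh)):]
        model = mil.train_mil(
            bags.bags, coh.loc[tr, "pfs_months"], coh.loc[tr, "event"],
            coh.loc[tr, "arm"], grid=[QUICK_HP], seed=5,
        )
        assert model.training_loss[-1] < model.training_loss[0]
        pred = mil.predict_and_stratify(model, bags.bags, coh.loc[te, "arm"])
        ci = sv.concordance_index(
            pred["risk"], coh.loc[te, "pfs_months"], coh.loc[te, "event"]
        )
        assert ci >= 0.7

    def test_null_bags_chance_level(self):
        cfg = synth.CohortConfig(seed=101, n_pembro=50, n_chemo=50)
        coh = synth.generate_cohort(cfg)
        bags = synth.generate_patch_bags(
            coh,
            synth.BagConfig(
                seed=102, embed_dim=8, patches_min=15, patches_max=30,
                informative_fraction=0.0,
            ),
        )
        tr = coh.index[:70]
        te = coh.index[70:]
        model = mil.train_mil(
            bags.bags, coh.loc[tr, "pfs_months"], coh.loc[tr, "event"],
            coh.loc[tr, "arm"], grid=[QUICK_HP], seed=6,
        )
        pred = mil.predict_and_stratify(model, bags.bags, coh.loc[te, "arm"])
        ci = sv.concordance_index(
            pred["risk"], coh.loc[te, "pfs_months"], coh.loc[te, "event"]
        )
        assert 0.4 <= ci <= 0.6

    def test_bit_reproducible_given_seed(self):
        coh, bags = strong_cohort_and_bags(n=40, seed=103)
        kw = dict(
            time=coh["pfs_months"], event=coh["event"], treatments=coh["arm"],
            grid=[mil.MILHyperparams(attention_dim=3, mlp_hidden=4, epochs=15)],
        )
        m1 = mil.train_mil(bags.bags, seed=7, **kw)
        m2 = mil.train_mil(bags.bags, seed=7, **kw)
        assert m1.chosen_hyperparams == m2.chosen_hyperparams
        for p1, p2 in zip(m1.members, m2.members):
            for k in p1:
                np.testing.assert_array_equal(p1[k], p2[k])

    def test_cv_folds_disjoint_and_exhaustive(self):
        coh, bags = strong_cohort_and_bags(n=40, seed=104)
        model = mil.train_mil(
            bags.bags, coh["pfs_months"], coh["event"], coh["arm"],
            grid=[mil.MILHyperparams(attention_dim=3, mlp_hidden=4, epochs=10)],
            seed=8,
        )
        folds = pd.Series(model.fold_assignments)
        assert set(folds.index) == set(coh.index)
        assert set(folds.unique()) == set(range(5))

    def test_empty_grid_rejected(self):
        coh, bags = strong_cohort_and_bags(n=40, seed=105)
        with pytest.raises(ValueError, match="grid"):
            mil.train_mil(
                bags.bags, coh["pfs_months"], coh["event"], coh["arm"],
                grid=[], seed=9,
            )

    def test_missing_bag_rejected(self):
        coh, bags = strong_cohort_and_bags(n=40, seed=106)
        del bags.bags[coh.index[0]]
        with pytest.raises(ValueError, match="bag"):
            mil.train_mil(
                bags.bags, coh["pfs_months"], coh["event"], coh["arm"],
                grid=[QUICK_HP], seed=10,
            )


class TestPredictStratify:
    @staticmethod
    def trained(seed=107):
        coh, bags = strong_cohort_and_bags(n=60, seed=seed)
        model = mil.train_mil(
            bags.bags, coh["pfs_months"], coh["event"], coh["arm"],
            grid=[mil.MILHyperparams(attention_dim=3, mlp_hidden=4, epochs=40)],
            seed=11,
        )
        return coh, bags, model

    def test_training_set_splits_near_half(self):
        coh, bags, model = self.trained()
        pred = mil.predict_and_stratify(model, bags.bags, coh["arm"])
        n_high = (pred["group"] == "high").sum()
        assert abs(n_high - len(coh) / 2) <= 1

    def test_threshold_tie_goes_low(self):
        coh, bags, model = self.trained(seed=108)
        risks = mil.predict_risks(model, bags.bags, coh["arm"])
        # place the threshold exactly at one patient's risk: that patient
        # must fall in the low group (documented tie rule)
        model.train_median_risk = float(risks.iloc[4])
        pred = mil.predict_and_stratify(model, bags.bags, coh["arm"])
        assert pred["group"].iloc[4] == "low"

    def test_untrained_model_rejected(self):
        coh, bags, model = self.trained(seed=109)
        model.train_median_risk = None
        with pytest.raises(ValueError, match="untrained"):
            mil.predict_and_stratify(model, bags.bags, coh["arm"])

    def test_inference_permutation_invariance(self):
        coh, bags, model = self.trained(seed=110)
        pred1 = mil.predict_and_stratify(model, bags.bags, coh["arm"])
        rng = np.random.default_rng(0)
        shuffled = {}
        for pid, bag in bags.bags.items():
            perm = rng.permutation(bag.n_patches)
            shuffled[pid] = PatchBag(pid, bag.embeddings[perm], bag.coords[perm])
        pred2 = mil.predict_and_stratify(model, shuffled, coh["arm"])
        np.testing.assert_array_equal(pred1["risk"].to_numpy(), pred2["risk"].to_numpy())


class TestExportAttention:
    def test_simplex_export(self):
        model = make_model()
        bag = make_bag(12, 4, 40)
        tab = mil.export_attention(model, bag)
        assert len(tab) == 12
        assert tab["attention_weight"].sum() == pytest.approx(1.0, abs=1e-8)
        np.testing.assert_array_equal(tab["x"].to_numpy(), bag.coords[:, 0])
        np.testing.assert_array_equal(tab["y"].to_numpy(), bag.coords[:, 1])

    def test_random_init_near_uniform_on_exchangeable_patches(self):
        ratios = []
        for seed in range(5):
            model = make_model(seed=seed)
            bag = make_bag(30, 4, seed + 50)
            a = mil.export_attention(model, bag)["attention_weight"].to_numpy()
            ratios.append(a.max() / a.min())
        assert max(ratios) < 10.0

    def test_trained_model_localizes_informative_patches(self):
        coh, bags = strong_cohort_and_bags(seed=111)
        tr = coh.index[:70]
        te = coh.index[70:]
        hp = mil.MILHyperparams(
            attention_dim=8, mlp_hidden=8, epochs=250, n_final_refits=2
        )
        model = mil.train_mil(
            bags.bags, coh.loc[tr, "pfs_months"], coh.loc[tr, "event"],
            coh.loc[tr, "arm"], grid=[hp], seed=12,
        )
        ratios = []
        for pid in te:
            info = bags.informative_idx[pid]
            bag = bags[pid]
            if 0 < len(info) < bag.n_patches:
                a = mil.export_attention(model, bag)["attention_weight"].to_numpy()
                m = np.zeros(bag.n_patches, bool)
                m[info] = True
                ratios.append(a[m].mean() / a[~m].mean())
        assert np.mean(ratios) >= 2.0


def test_model_save_load_roundtrip(tmp_path):
    coh, bags = strong_cohort_and_bags(n=40, seed=112)
    model = mil.train_mil(
        bags.bags, coh["pfs_months"], coh["event"], coh["arm"],
        grid=[mil.MILHyperparams(attention_dim=3, mlp_hidden=4, epochs=10)],
        seed=13,
    )
    model.save(str(tmp_path / "model"))
    back = mil.TrainedMILModel.load(str(tmp_path / "model"))
    p1 = mil.predict_and_stratify(model, bags.bags, coh["arm"])
    p2 = mil.predict_and_stratify(back, bags.bags, coh["arm"])
    np.testing.assert_allclose(p1["risk"], p2["risk"], atol=1e-12)
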