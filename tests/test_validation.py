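"""Independent-validation contracts: PA/ACC arithmetic, cohort
disjointness, and the cambial-age sweep's consistency properties."""
import numpy as np
import pandas as pd
import pytest

from crossgen_gs import blup, phenotypes, validation
from crossgen_gs.relationships import blend, build_G
from crossgen_gs.synthetic_data import SimConfig, simulate_population


class TestPredictiveAbility:
    def test_perfect_and_anti_correlation(self, rng):
        y = rng.normal(size=10)
        assert np.isclose(validation.predictive_ability(y, y), 1.0)
        assert np.isclose(validation.predictive_ability(y, -y), -1.0)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match="3 paired"):
            validation.predictive_ability([1.0, 2.0], [1.0, 2.0])
        with pytest.raises(ValueError, match="unequal"):
            validation.predictive_ability([1.0, 2.0, 3.0], [1.0, 2.0])

    def test_zero_variance_warns_and_returns_nan(self, rng):
        y = rng.normal(size=5)
        with pytest.warns(UserWarning, match="zero variance"):
            out = validation.predictive_ability(y, np.ones(5))
        assert np.isnan(out)

    def test_pa_increases_with_training_size(self):
        """More phenotyped relatives -> better predictions of their kin.

        Paired design: within each replicate the same population is fitted
        with nested training sets, so the training-size effect is compared
        on identical data.
        """
        from crossgen_gs.relationships import GenotypeMatrix

        n_pool, n_valid, n_markers = 260, 120, 400
        sizes = (50, 120, 200)
        pas = {n: [] for n in sizes}
        for rep in range(8):
            r = np.random.default_rng([20260920, rep])
            p = r.uniform(0.2, 0.5, n_markers)
            codes = r.binomial(2, p, size=(n_pool + n_valid, n_markers)).astype(float)
            ids = [f"i{k}" for k in range(n_pool + n_valid)]
            # validation ids are offspring of pool members: dams are the
            # first 120 pool ids, sires drawn from pool ids 120..260
            dam = codes[:n_valid]
            gam = np.where(dam == 1.0, r.integers(0, 2, dam.shape), dam / 2)
            sire = codes[r.integers(n_valid, n_pool, n_valid)]
            gs = np.where(sire == 1.0, r.integers(0, 2, sire.shape), sire / 2)
            codes[n_pool:] = gam + gs
            gm = GenotypeMatrix(ids, [f"m{j}" for j in range(n_markers)], codes)
            G = blend(build_G(gm), 0.98)
            beta = np.zeros(n_markers)
            beta[r.choice(n_markers, 60, replace=False)] = r.normal(size=60)
            tbv = codes @ beta
            tbv = (tbv - tbv[:n_pool].mean()) / tbv[:n_pool].std() * np.sqrt(0.5)
            y = tbv + r.normal(0, np.sqrt(0.5), len(ids))
            for n_train in sizes:
                train = ids[:n_train]
                vc = blup.reml_fit(y[:n_train], G.submatrix(train), algorithm="ai")
                fit = blup.solve_mme(y[:n_train], G, train, vc)
                pas[n_train].append(validation.predictive_ability(
                    y[n_pool:], fit.ebv.iloc[n_pool:].to_numpy()))
        means = [np.nanmean(pas[n]) for n in sizes]
        assert means[0] < means[1] < means[2]


class TestPredictionAccuracy:
    def test_arithmetic(self):
        assert np.isclose(validation.prediction_accuracy(0.3, 0.36), 0.5)
        assert round(validation.prediction_accuracy(0.25, 0.384), 3) == 0.403

    def test_inestimable_below_threshold(self):
        assert np.isnan(validation.prediction_accuracy(0.3, 0.0))
        assert np.isnan(validation.prediction_accuracy(0.3, 5e-4))
        with pytest.raises(ValueError):
            validation.prediction_accuracy(0.3, 1.2)


class TestRunApproach:
    def test_cohort_splits_and_schema(self, small_sim, small_kernel,
                                      small_adjusted, small_cohorts):
        rows = []
        for approach, (train, valids) in validation.APPROACHES.items():
            res = validation.run_approach(
                approach, "GBLUP", small_adjusted, small_cohorts, small_kernel,
                algorithm="ai",
            )
            assert [r.validation_cohort for r in res] == valids
            for r in res:
                assert r.train_cohort == train
                assert abs(r.pa) <= 1.0
                assert r.n_train >= 3 and r.n_valid >= 3
                rows.append(r)
        frame = validation.results_to_frame(rows)
        assert len(frame) == 6
        assert frame["pa"].notna().all()

    def test_acc_times_sqrt_h2_reproduces_pa(self, small_sim, small_kernel,
                                             small_adjusted, small_cohorts):
        for approach in ("A", "B", "C"):
            for r in validation.run_approach(
                approach, "GBLUP", small_adjusted, small_cohorts, small_kernel,
                algorithm="ai",
            ):
                if not np.isnan(r.acc):
                    assert abs(r.acc * np.sqrt(r.h2) - r.pa) < 1e-12

    def test_ablup_and_gblup_both_complete(self, small_sim, small_adjusted,
                                           small_cohorts):
        from crossgen_gs.relationships import build_A

        A = build_A(small_sim.pedigree)
        res = validation.run_approach("B", "ABLUP", small_adjusted,
                                      small_cohorts, A, algorithm="ai")
        assert all(np.isfinite(r.pa) for r in res)

    def test_unknown_approach_rejected(self, small_adjusted, small_cohorts,
                                       small_kernel):
        with pytest.raises(ValueError, match="unknown approach"):
            validation.run_approach("D", "GBLUP", small_adjusted,
                                    small_cohorts, small_kernel)


@pytest.fixture(scope="module")
def sweep_inputs():
    cfg = SimConfig(
        n_founders=90, n_families_phenotyped=30, progeny_per_family_per_trial=3,
        n_blocks_per_trial=4, n_markers=400, n_qtl=80, target_h2=0.6,
        n_rings_g0=12, n_rings_g1=10, seed=99,
    )
    sim = simulate_population(cfg)
    G = blend(build_G(sim.genotypes), 0.98)
    g0_ids = sim.design.loc[sim.design["cohort"] == "G0", "id"]
    g0_rings = sim.ring_table[sim.ring_table["id"].isin(g0_ids)]
    from crossgen_gs.experiments import adjusted_whole_core

    adj = adjusted_whole_core(sim)
    targets = {}
    for trial in ("H", "E"):
        ids = sim.design.loc[sim.design["cohort"] == f"G1{trial}", "id"]
        targets[(trial, "whole-core")] = adj.loc[adj.index.isin(ids)]
    return sim, G, g0_rings, targets


def _same_result(a, b, atol):
    # identical training data must give identical output, including a
    # shared undefined (NaN) correlation when variance collapses
    if np.isnan(a) or np.isnan(b):
        return np.isnan(a) and np.isnan(b)
    return np.isclose(a, b, atol=atol)


class TestEarlyTrainingSweep:
    def test_awe_and_sad_coincide_at_first_ring(self, sweep_inputs):
        sim, G, g0_rings, targets = sweep_inputs
        awe = validation.early_training_sweep(g0_rings, targets, G, "AWE",
                                              rings=[1], algorithm="ai")
        sad = validation.early_training_sweep(g0_rings, targets, G, "SAD",
                                              rings=[1], algorithm="ai")
        for a, s in zip(awe, sad):
            assert _same_result(a.pa, s.pa, atol=1e-10)

    def test_awe_at_max_ring_equals_whole_core_training(self, sweep_inputs):
        sim, G, g0_rings, targets = sweep_inputs
        k_max = int(g0_rings.groupby("id")["ring"].max().min())
        res = validation.early_training_sweep(g0_rings, targets, G, "AWE",
                                              rings=[k_max], algorithm="ai")
        train_awe = phenotypes.awe_table(g0_rings, upto_ring=k_max)
        whole = phenotypes.awe_table(g0_rings)
        np.testing.assert_allclose(train_awe.to_numpy(), whole.to_numpy())
        assert res[0].n_train == len(train_awe)

    def test_constant_profile_makes_modes_identical(self):
        cfg = SimConfig(
            n_founders=40, n_families_phenotyped=12,
            progeny_per_family_per_trial=2, n_markers=200, n_qtl=40,
            target_h2=0.5, ring_age_correlation=1.0, ring_noise_sd=0.0,
            trend_amplitude=0.0, n_rings_g0=8, n_rings_g1=6, seed=100,
        )
        sim = simulate_population(cfg)
        G = blend(build_G(sim.genotypes), 0.98)
        g0_ids = sim.design.loc[sim.design["cohort"] == "G0", "id"]
        g0_rings = sim.ring_table[sim.ring_table["id"].isin(g0_ids)]
        from crossgen_gs.experiments import adjusted_whole_core

        adj = adjusted_whole_core(sim)
        ids_h = sim.design.loc[sim.design["cohort"] == "G1H", "id"]
        targets = {("H", "whole-core"): adj.loc[adj.index.isin(ids_h)]}
        awe = validation.early_training_sweep(g0_rings, targets, G, "AWE",
                                              rings=range(1, 9), algorithm="ai")
        sad = validation.early_training_sweep(g0_rings, targets, G, "SAD",
                                              rings=range(1, 9), algorithm="ai")
        for a, s in zip(awe, sad):
            assert _same_result(a.pa, s.pa, atol=1e-8)

    def test_unreachable_rings_skipped_with_warning(self, sweep_inputs):
        sim, G, g0_rings, targets = sweep_inputs
        with pytest.warns(UserWarning, match="skipped"):
            res = validation.early_training_sweep(g0_rings, targets, G, "AWE",
                                                  rings=[1, 40], algorithm="ai")
        assert {r.ring for r in res} == {1}

    def test_acc_flag_beyond_reliability_cutoff(self, sweep_inputs):
        sim, G, g0_rings, targets = sweep_inputs
        res = validation.early_training_sweep(
            g0_rings, targets, G, "SAD", rings=[5], acc_display_max_ring=4,
            algorithm="ai",
        )
        assert all(r.acc_flagged for r in res)
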