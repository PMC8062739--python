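"""Spectral evidence, random-effects BMS, group comparison, modulation tests."""

import numpy as np
import pandas as pd
import pytest

from sifinet.model_selection import (
    compare_modulations, evidence_matrix, fit_couplings,
    group_model_comparison, model_evidence, rfx_bms,
)
from sifinet.model_space import ModelSpec
from sifinet.synthetic import GroundTruthNetwork, simulate_coupled_network

BAND = (12.0, 25.0)
WINDOW = (-0.25, 0.075)


def chain_net():
    return GroundTruthNetwork(n_nodes=3, links=[(0, 1, 0.5, 3), (1, 2, 0.5, 2)],
                              self_coefficients=0.5, node_names=["A", "B", "C"])


def model_from(links, nodes=("A", "B", "C"), family="excitatory"):
    n = len(nodes)
    A = np.zeros((n, n), bool)
    delays = np.ones((n, n), int)
    for (i, j, d) in links:
        A[i, j] = True
        delays[i, j] = d
    return ModelSpec(nodes=list(nodes), A=A, family=family, delays=delays)


TRUE_MODEL = model_from([(0, 1, 3), (1, 2, 2)])
MISSING_LINK = model_from([(0, 1, 3)])
EXTRA_LINK = model_from([(0, 1, 3), (1, 2, 2), (0, 2, 5)])


class TestModelEvidence:
    def test_identical_models_identical_evidence(self):
        ens = simulate_coupled_network(chain_net(), 20, 487, seed=0)
        m2 = model_from([(0, 1, 3), (1, 2, 2)])
        assert model_evidence(ens, TRUE_MODEL, BAND, WINDOW) == \
            model_evidence(ens, m2, BAND, WINDOW)

    def test_generating_model_beats_missing_strong_link(self):
        wins = 0
        for seed in range(10):
            ens = simulate_coupled_network(chain_net(), 30, 487, seed=seed)
            e_true = model_evidence(ens, TRUE_MODEL, BAND, WINDOW)
            e_miss = model_evidence(ens, MISSING_LINK, BAND, WINDOW)
            wins += e_true > e_miss
        assert wins >= 9

    def test_penalty_removes_spurious_link_as_data_grow(self):
        wins = 0
        for seed in range(10):
            ens = simulate_coupled_network(chain_net(), 60, 487, seed=30 + seed)
            e_true = model_evidence(ens, TRUE_MODEL, BAND, WINDOW)
            e_extra = model_evidence(ens, EXTRA_LINK, BAND, WINDOW)
            wins += e_true > e_extra
        assert wins >= 8

    def test_invariant_to_consistent_channel_relabeling(self):
        ens = simulate_coupled_network(chain_net(), 15, 487, seed=2)
        perm = [2, 0, 1]
        ens_p = simulate_coupled_network(chain_net(), 15, 487, seed=2)
        ens_p.data = ens_p.data[:, perm, :]
        ens_p.channel_names = [ens.channel_names[i] for i in perm]
        inv = np.argsort(perm)
        A = TRUE_MODEL.A[np.ix_(perm, perm)]
        delays = TRUE_MODEL.delays[np.ix_(perm, perm)]
        model_p = ModelSpec(nodes=[TRUE_MODEL.nodes[i] for i in perm],
                            A=A, delays=delays)
        assert model_evidence(ens, TRUE_MODEL, BAND, WINDOW) == pytest.approx(
            model_evidence(ens_p, model_p, BAND, WINDOW), rel=1e-9)

    def test_node_mismatch_rejected(self):
        ens = simulate_coupled_network(chain_net(), 5, 487, seed=3)
        bad = model_from([(0, 1, 3)], nodes=("X", "Y", "Z"))
        with pytest.raises(ValueError, match="match"):
            model_evidence(ens, bad, BAND, WINDOW)

    def test_window_too_short_for_band_rejected(self):
        ens = simulate_coupled_network(chain_net(), 5, 487, seed=4)
        with pytest.raises(ValueError, match="window"):
            model_evidence(ens, TRUE_MODEL, band=(12.0, 13.0),
                           window=(0.0, 0.05))

    def test_fitted_couplings_near_truth_on_full_band(self):
        # the band-limited fit estimates a filtered projection of the
        # couplings; on the full frequency grid the Whittle fit is the
        # time-domain regression and recovers the generative values
        ens = simulate_coupled_network(chain_net(), 60, 487, seed=5)
        coefs = fit_couplings(ens, TRUE_MODEL, band=(2.0, 149.0),
                              window=(-1.0, 0.62))
        assert coefs[("A", "B")] == pytest.approx(0.5, abs=0.05)
        assert coefs[("B", "C")] == pytest.approx(0.5, abs=0.05)


class TestRfxBms:
    def test_equal_evidence_gives_uniform_probabilities(self):
        ev = np.full((6, 4), -100.0)
        res = rfx_bms(ev)
        assert np.allclose(res.expected_p, 0.25, atol=1e-6)
        assert np.allclose(res.exceedance_p, 0.25, atol=0.02)

    def test_probabilities_sum_to_one(self, rng):
        res = rfx_bms(rng.normal(size=(8, 5)))
        assert res.expected_p.sum() == pytest.approx(1.0, abs=1e-6)
        assert res.exceedance_p.sum() == pytest.approx(1.0, abs=1e-6)

    def test_dominant_model_has_high_exceedance(self, rng):
        ev = rng.normal(size=(10, 3))
        ev[:, 1] += 10.0
        res = rfx_bms(ev)
        assert res.winner == 1
        assert res.exceedance_p[1] > 0.99
        # Monte-Carlo oracle on the fitted Dirichlet posterior
        samples = np.random.default_rng(7).dirichlet(res.alpha, 200_000)
        oracle = (samples.argmax(axis=1) == 1).mean()
        assert res.exceedance_p[1] == pytest.approx(oracle, abs=0.005)

    def test_model_permutation_equivariance(self, rng):
        ev = rng.normal(size=(7, 4))
        perm = [2, 0, 3, 1]
        r1 = rfx_bms(ev)
        r2 = rfx_bms(ev[:, perm])
        assert np.allclose(r2.expected_p, r1.expected_p[perm], atol=1e-8)

    def test_nonfinite_evidence_rejected(self):
        ev = np.zeros((3, 2))
        ev[0, 0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            rfx_bms(ev)

    def test_single_subject_or_model_rejected(self):
        with pytest.raises(ValueError):
            rfx_bms(np.zeros((1, 3)))
        with pytest.raises(ValueError):
            rfx_bms(np.zeros((4, 1)))


class TestGroupModelComparison:
    def test_copied_group_favors_same_distribution(self, rng):
        for seed in range(10):
            ev = np.random.default_rng(seed).normal(size=(8, 3))
            ev[:, 0] += 3.0
            out = group_model_comparison(ev, ev.copy())
            assert out["log_bf_same_vs_diff"] > 0

    def test_well_separated_groups_favor_different(self, rng):
        ev1 = rng.normal(size=(10, 2))
        ev2 = rng.normal(size=(10, 2))
        ev1[:, 0] += 8.0
        ev2[:, 1] += 8.0
        out = group_model_comparison(ev1, ev2)
        assert out["log_bf_same_vs_diff"] < 0
        assert out["favors"] == "different"

    def test_random_split_of_one_cohort_favors_same_on_average(self, rng):
        ev = rng.normal(size=(16, 3))
        ev[:, 2] += 4.0
        bfs = []
        for seed in range(10):
            perm = np.random.default_rng(seed).permutation(16)
            out = group_model_comparison(ev[perm[:8]], ev[perm[8:]])
            bfs.append(out["log_bf_same_vs_diff"])
        assert np.mean(bfs) > 0

    def test_mismatched_model_sets_rejected(self, rng):
        with pytest.raises(ValueError, match="model set"):
            group_model_comparison(rng.normal(size=(4, 3)),
                                   rng.normal(size=(4, 2)))


class TestCompareModulations:
    def _table(self, g1, g2, link="A->B"):
        rows = [{"subject": f"y{i}", "group": "young", "link": link,
                 "modulation": v} for i, v in enumerate(g1)]
        rows += [{"subject": f"o{i}", "group": "older", "link": link,
                  "modulation": v} for i, v in enumerate(g2)]
        return pd.DataFrame(rows)

    def test_identical_groups_t_zero(self):
        t = self._table([0.1, 0.2, 0.3], [0.1, 0.2, 0.3])
        out = compare_modulations(t)
        assert out["t"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_five_pooled_sd_separation_highly_significant(self, rng):
        g1 = rng.normal(0.0, 1.0, 10)
        g2 = rng.normal(5.0, 1.0, 10)
        out = compare_modulations(self._table(g1, g2))
        assert out["p"].iloc[0] < 0.001

    def test_matches_hand_computed_welch_t(self):
        g1 = [1.0, 2.0, 3.0, 4.0]
        g2 = [2.0, 4.0, 6.0, 8.0]
        out = compare_modulations(self._table(g1, g2))
        # groups enter in sorted order: older first, then young
        m1, m2 = np.mean(g2), np.mean(g1)
        v1, v2 = np.var(g2, ddof=1) / 4, np.var(g1, ddof=1) / 4
        t_hand = (m1 - m2) / np.sqrt(v1 + v2)
        assert out["t"].iloc[0] == pytest.approx(t_hand)
        assert out["df"].iloc[0] == pytest.approx(
            (v1 + v2) ** 2 / (v1**2 / 3 + v2**2 / 3))

    def test_zero_variance_flagged(self):
        t = self._table([1.0, 1.0], [1.0, 1.0])
        with pytest.warns(UserWarning, match="zero variance"):
            out = compare_modulations(t)
        assert np.isnan(out["t"].iloc[0])

    def test_modulated_generator_detected_via_fits(self):
        # older group has x2 coupling modulation on the illusion trials
        net = chain_net()
        rows = []
        for group, factor in (("young", 1.0), ("older", 2.0)):
            for i in range(4):
                conds = ["illusion"] * 30 + ["no-illusion"] * 30
                ens = simulate_coupled_network(
                    net, 60, 487, seed=hash((group, i)) % 2**31,
                    conditions=conds,
                    modulation={(0, 1): factor})
                for cond in ("illusion", "no-illusion"):
                    c = fit_couplings(ens.select_conditions(cond), TRUE_MODEL,
                                      BAND, WINDOW)
                    rows.append({"subject": f"{group}{i}", "group": group,
                                 "cond": cond, "c": c[("A", "B")]})
        df = pd.DataFrame(rows).pivot_table(index=["subject", "group"],
                                            columns="cond", values="c")
        df = df.reset_index()
        mods = pd.DataFrame({
            "subject": df["subject"], "group": df["group"], "link": "A->B",
            "modulation": df["illusion"] - df["no-illusion"]})
        out = compare_modulations(mods)
        assert out["p"].iloc[0] < 0.05
        assert out["mean_older"].iloc[0] > out["mean_young"].iloc[0]


class TestSelectFamily:
    def test_positive_couplings_select_excitatory(self):
        from sifinet.model_selection import select_family
        ens = [simulate_coupled_network(chain_net(), 20, 487, seed=s)
               for s in (0, 1, 2)]
        fam, scores, ev = select_family(ens, [TRUE_MODEL, MISSING_LINK],
                                        BAND, WINDOW)
        assert fam == "excitatory"
        assert scores["excitatory"] > scores["inhibitory"]
        assert ev.values.shape == (3, 2)

    def test_negative_couplings_select_inhibitory(self):
        from sifinet.model_selection import select_family
        net = GroundTruthNetwork(
            n_nodes=3, links=[(0, 1, -0.5, 3), (1, 2, -0.5, 2)],
            self_coefficients=0.5, node_names=["A", "B", "C"])
        ens = [simulate_coupled_network(net, 20, 487, seed=s)
               for s in (3, 4, 5)]
        fam, scores, _ = select_family(ens, [TRUE_MODEL, MISSING_LINK],
                                       BAND, WINDOW)
        assert fam == "inhibitory"
        assert scores["inhibitory"] > scores["excitatory"]


def test_evidence_matrix_shape_and_labels():
    ens = [simulate_coupled_network(chain_net(), 10, 487, seed=s)
           for s in (0, 1)]
    ev = evidence_matrix(ens, [TRUE_MODEL, MISSING_LINK], BAND, WINDOW)
    assert ev.values.shape == (2, 2)
    assert len(ev.model_labels) == 2
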