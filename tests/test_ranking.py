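"""Monte-Carlo null, empirical p, FDR cut and shortlist rules."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest

import poolgwas as pg
from poolgwas.ranking import NullDistribution, dominance_counts


def _manual_null(mean, cv, **kw):
    mean = np.asarray(mean, dtype=float)
    args = dict(chromosome="1", n_snps=len(mean), n_reps=1, seed=0,
                mode="uniform", mean=mean, cv=np.asarray(cv, dtype=float))
    args.update(kw)
    return NullDistribution(**args)


class TestSimulateNull:
    def test_single_pair(self):
        null = pg.simulate_null("1", 1, 1, seed=0)
        assert null.n_pairs == 1

    def test_deterministic(self):
        a = pg.simulate_null("1", 100, 5, seed=9)
        b = pg.simulate_null("1", 100, 5, seed=9)
        assert np.array_equal(a.mean, b.mean)
        assert np.array_equal(a.cv, b.cv)
        c = pg.simulate_null("1", 100, 5, seed=10)
        assert not np.array_equal(a.mean, c.mean)

    def test_null_location_matches_simulation_oracle(self):
        """Null location checked against an independent simulation oracle.

        For iid uniform pool frequencies a single ratio F1/F2 has
        median 1 by symmetry, but the *mean of the four cross ratios*
        is biased upward (E[1/X] > 1/E[X]): its median is ~1.2567
        (frozen from a 4M-draw direct simulation).
        """
        nulls = [pg.simulate_null("1", 20000, 1, seed=s,
                                  compute_scores=False) for s in range(10)]
        med_mean = np.median([np.median(n.mean) for n in nulls])
        assert med_mean == pytest.approx(1.2567, abs=0.02)
        rng = np.random.default_rng(0)
        f = pg.clamp_frequencies(rng.random((40000, 2)))
        assert np.median(f[:, 0] / f[:, 1]) == pytest.approx(1.0, abs=0.02)

    def test_empirical_mode_resamples_observed(self):
        obs = np.array([[0.5, 0.5, 0.5, 0.5]])
        null = pg.simulate_null("1", 50, 2, seed=1, mode="empirical",
                                observed_freqs=obs)
        assert np.allclose(null.mean, 1.0)
        with pytest.raises(ValueError, match="observed_freqs"):
            pg.simulate_null("1", 10, 1, seed=1, mode="empirical")

    def test_save_load_roundtrip(self, small_null, tmp_path):
        path = tmp_path / "null.npz"
        small_null.save(path)
        back = NullDistribution.load(path)
        assert np.array_equal(back.mean, small_null.mean)
        assert np.array_equal(back.scores, small_null.scores)
        assert back.chromosome == small_null.chromosome


class TestDominanceCounts:
    def test_matches_brute_force(self, small_null):
        """The Fenwick-sweep counter agrees with direct O(NQ) counting."""
        rng = np.random.default_rng(3)
        idx = rng.integers(0, small_null.n_pairs, 150)
        obs_m = small_null.mean[idx] * rng.choice([1.0, 1.0001], 150)
        obs_c = small_null.cv[idx]
        fast = dominance_counts(small_null.mean, small_null.cv, obs_m, obs_c)
        for j in rng.choice(len(obs_m), 40, replace=False):
            if obs_m[j] >= 1:
                brute = np.sum((small_null.mean >= obs_m[j])
                               & (small_null.cv <= obs_c[j]))
            else:
                brute = np.sum((small_null.mean <= obs_m[j])
                               & (small_null.cv <= obs_c[j]))
            assert fast[j] == brute

    def test_self_scores_match_brute_force(self):
        null = pg.simulate_null("1", 300, 1, seed=5)
        scores = []
        for m, c in zip(null.mean, null.cv):
            if m >= 1:
                cnt = np.sum((null.mean >= m) & (null.cv <= c))
            else:
                cnt = np.sum((null.mean <= m) & (null.cv <= c))
            scores.append((1.0 + cnt) / (1.0 + null.n_pairs))
        assert np.allclose(np.sort(scores), null.scores)


class TestEmpiricalP:
    def test_add_one_floor(self):
        null = pg.simulate_null("1", 100, 100, seed=13)
        for mode in ("dominance", "calibrated"):
            p = pg.empirical_p(null.mean.max() * 10, -1.0, null, mode=mode)
            assert p == pytest.approx(1.0 / (null.n_pairs + 1))

    def test_least_extreme_observation_has_p_one(self):
        mean = np.linspace(1.0, 30.0, 50)
        cv = np.linspace(0.01, 2.0, 50)
        null = _manual_null(mean, cv)
        for mode in ("dominance", "calibrated"):
            p = pg.empirical_p(mean.min(), np.inf, null, mode=mode)
            assert p == pytest.approx(1.0)

    def test_calibration_uniform_under_null(self, small_null):
        """p of a fresh null draw is uniform on (0, 1] (KS, alpha=0.01)."""
        rng = np.random.default_rng(6)
        f = pg.clamp_frequencies(rng.random((500, 4)))
        r = pg.four_ratios(f[:, 0], f[:, 1], f[:, 2], f[:, 3])
        m, c = pg.mean_cv(*r)
        p = pg.empirical_p(m, c, small_null)
        assert kstest(p, "uniform").pvalue > 0.01

    def test_p_within_unit_interval_floor(self, small_null):
        rng = np.random.default_rng(8)
        f = pg.clamp_frequencies(rng.random((100, 4)))
        r = pg.four_ratios(f[:, 0], f[:, 1], f[:, 2], f[:, 3])
        m, c = pg.mean_cv(*r)
        for mode in ("dominance", "calibrated"):
            p = pg.empirical_p(m, c, small_null, mode=mode)
            assert (p >= 1.0 / (small_null.n_pairs + 1)).all()
            assert (p <= 1.0).all()


class TestFdrSelect:
    def test_paper_mode_threshold(self):
        mask = pg.fdr_select([0.001, 0.04, 0.2], alpha=0.05, mode="paper")
        assert mask.tolist() == [True, True, False]

    def test_all_ones_kept_out(self):
        assert not pg.fdr_select([1.0, 1.0], mode="paper").any()
        assert not pg.fdr_select([1.0, 1.0], mode="bh").any()

    def test_bh_hand_computation(self):
        """BH at alpha=0.05, m=3: only 0.001 survives (0.04 > 2*0.05/3)."""
        mask = pg.fdr_select([0.001, 0.04, 0.2], alpha=0.05, mode="bh")
        assert mask.tolist() == [True, False, False]

    def test_empty_input(self):
        assert pg.fdr_select([], mode="paper").size == 0


class TestReplicationShortlist:
    def _selected(self, rows):
        return pd.DataFrame(rows, columns=["snp_id", "subtype", "p_mc",
                                           "F_ctrl"])

    def _annotation(self, mapping):
        return pd.DataFrame(
            [(s, "1", i + 1, g) for i, (s, g) in enumerate(mapping.items())],
            columns=["snp_id", "chrom", "pos", "gene_label"],
        )

    def test_gene_sharing_rule(self):
        sel = self._selected([("s1", "OMA", 0.02, 0.5),
                              ("s2", "OMA", 0.03, 0.5)])
        ann = self._annotation({"s1": "G", "s2": "G"})
        out = pg.replication_shortlist(sel, ann)
        assert set(out["snp_id"]) == {"s1", "s2"}
        assert (out["shortlist_rule"] == "A").all()

    def test_subtype_sharing_rule(self):
        sel = self._selected([("s1", "SUP", 0.02, 0.5),
                              ("s1", "OMA", 0.03, 0.5),
                              ("s2", "OMA", 0.04, 0.5)])
        ann = self._annotation({"s1": "G1", "s2": "G2"})
        out = pg.replication_shortlist(sel, ann)
        assert set(out["snp_id"]) == {"s1"}

    def test_stringent_rule_reference_tolerance(self):
        """p <= 0.001 but control frequency 0.25 away from the reference."""
        sel = self._selected([("s1", "OMA", 0.0005, 0.30)])
        ann = self._annotation({"s1": "G1"})
        ref = pd.DataFrame({"snp_id": ["s1"], "F_ref": [0.55]})
        out = pg.replication_shortlist(sel, ann, ref)
        assert len(out) == 0
        ref_ok = pd.DataFrame({"snp_id": ["s1"], "F_ref": [0.35]})
        out = pg.replication_shortlist(sel, ann, ref_ok)
        assert out["shortlist_rule"].tolist() == ["B"]

    def test_missing_annotation_warns_and_limits_to_subtype_rule(self):
        sel = self._selected([("s1", "SUP", 0.02, 0.5),
                              ("s1", "OMA", 0.03, 0.5),
                              ("s2", "OMA", 0.04, 0.5)])
        ann = self._annotation({})
        with pytest.warns(UserWarning, match="lack annotation"):
            out = pg.replication_shortlist(sel, ann)
        assert set(out["snp_id"]) == {"s1"}
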