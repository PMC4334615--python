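"""Replication association statistics and their independent oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from statsmodels.stats.contingency_tables import StratifiedTable, Table2x2

import poolgwas as pg
from poolgwas.assoc import GenotypeCounts
from poolgwas.datasets import PUBLISHED_RESULTS, REPLICATION_COUNTS


def brute_chi2(table: np.ndarray) -> tuple[float, int]:
    """Direct expected-count Pearson chi-square (independent oracle)."""
    table = np.asarray(table, dtype=float)
    keep = table.sum(axis=1) > 0
    table = table[keep]
    total = table.sum()
    stat = 0.0
    for i in range(table.shape[0]):
        for j in range(table.shape[1]):
            e = table[i].sum() * table[:, j].sum() / total
            stat += (table[i, j] - e) ** 2 / e
    return stat, (table.shape[0] - 1) * (table.shape[1] - 1)


def counts_from(case, control):
    return GenotypeCounts(snp_id="s", case_label="case",
                          control_label="CTR", case=tuple(case),
                          control=tuple(control))


class TestTabulate:
    def _frame(self, values, groups):
        geno = pd.DataFrame({"s1": values},
                            index=[f"i{k}" for k in range(len(values))])
        pheno = pd.Series(groups, index=geno.index)
        return geno, pheno

    def test_direct_counting(self):
        geno, pheno = self._frame([0, 1, 2, 2], ["OMA", "OMA", "CTR", "CTR"])
        c = pg.tabulate(geno, pheno, "s1", "OMA")
        assert c.case == (1, 1, 0)
        assert c.control == (0, 0, 2)
        assert c.call_rate == 1.0

    def test_missing_excluded_and_call_rate(self):
        values = [1.0] * 39 + [np.nan]
        c = pg.tabulate(*self._frame(values, ["OMA"] * 20 + ["CTR"] * 20),
                        "s1", "OMA")
        assert c.call_rate == pytest.approx(0.975)
        assert sum(c.case) + sum(c.control) == 39

    def test_all_missing_rejected(self):
        geno, pheno = self._frame([np.nan, np.nan], ["OMA", "CTR"])
        with pytest.raises(ValueError, match="missing"):
            pg.tabulate(geno, pheno, "s1", "OMA")

    def test_empty_subtype_rejected(self):
        geno, pheno = self._frame([0, 1], ["CTR", "CTR"])
        with pytest.raises(ValueError, match="DIE"):
            pg.tabulate(geno, pheno, "s1", "DIE")

    def test_allele_margins_conserved(self):
        geno, pheno = self._frame([0, 1, 2, 1, 1, 2],
                                  ["OMA"] * 3 + ["CTR"] * 3)
        c = pg.tabulate(geno, pheno, "s1", "OMA")
        assert (c.allele_table.sum(axis=0) == [6, 6]).all()


class TestGenotypicChi2:
    def test_published_contrast(self):
        """CTR (39,39,17) vs OMA (7,27,16): chi2 ~ 11.63, df 2."""
        chi2, df, p = pg.genotypic_chi2(counts_from((7, 27, 16),
                                                    (39, 39, 17)))
        oracle_stat, oracle_df = brute_chi2(
            np.array([[7, 39], [27, 39], [16, 17]]))
        assert chi2 == pytest.approx(oracle_stat, abs=1e-10)
        assert chi2 == pytest.approx(11.63, abs=0.01)
        assert df == oracle_df == 2
        assert round(p, 3) == 0.003

    def test_identical_proportions(self):
        chi2, df, p = pg.genotypic_chi2(counts_from((10, 20, 10),
                                                    (20, 40, 20)))
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_degenerate_single_row(self):
        chi2, df, p = pg.genotypic_chi2(counts_from((0, 0, 10), (0, 0, 20)))
        assert np.isnan(chi2) and df == 0 and np.isnan(p)

    def test_oracle_equivalence_random_tables(self):
        """Agreement with the expected-count oracle on random tables."""
        rng = np.random.default_rng(17)
        for _ in range(300):
            case = tuple(rng.integers(1, 60, 3))
            control = tuple(rng.integers(1, 60, 3))
            chi2, df, p = pg.genotypic_chi2(counts_from(case, control))
            stat, odf = brute_chi2(np.array([case, control]).T)
            assert chi2 == pytest.approx(stat, abs=1e-10)
            assert df == odf


class TestAllelicOr:
    @pytest.mark.parametrize("key", sorted(REPLICATION_COUNTS))
    def test_published_or_and_ci(self, key):
        """Each published contrast reproduces its OR and Woolf CI."""
        orv, lo, hi, risk, haldane = pg.allelic_or(REPLICATION_COUNTS[key])
        pub = PUBLISHED_RESULTS[key]
        assert round(orv, 2) == pub["or"]
        assert round(lo, 2) == pub["ci"][0]
        assert round(hi, 2) == pub["ci"][1]
        assert not haldane

    def test_equal_frequencies_give_unit_or(self):
        orv, lo, hi, _, _ = pg.allelic_or(counts_from((10, 20, 10),
                                                      (10, 20, 10)))
        assert orv == pytest.approx(1.0)
        assert lo < 1.0 < hi

    def test_orientation_invariance(self):
        """Relabeling alleles A<->B leaves OR, CI and chi2 unchanged."""
        c = counts_from((7, 27, 16), (39, 39, 17))
        flipped = counts_from((16, 27, 7), (17, 39, 39))
        assert pg.allelic_or(c)[:3] == pytest.approx(
            pg.allelic_or(flipped)[:3])
        assert pg.genotypic_chi2(c)[0] == pytest.approx(
            pg.genotypic_chi2(flipped)[0])

    def test_haldane_correction_on_zero_cell(self):
        orv, lo, hi, _, haldane = pg.allelic_or(counts_from((0, 0, 10),
                                                            (5, 5, 5)))
        assert haldane
        assert np.isfinite([orv, lo, hi]).all()
        assert lo <= orv <= hi

    def test_woolf_matches_statsmodels(self):
        rng = np.random.default_rng(29)
        for _ in range(100):
            c = counts_from(rng.integers(1, 50, 3), rng.integers(1, 50, 3))
            orv, lo, hi, risk, _ = pg.allelic_or(c)
            at = c.allele_table
            if risk == "B":
                at = at[::-1]
            t22 = Table2x2(np.array([[at[0, 0], at[1, 0]],
                                     [at[0, 1], at[1, 1]]]))
            assert orv == pytest.approx(t22.oddsratio, rel=1e-10)
            sm_lo, sm_hi = t22.oddsratio_confint(0.05)
            # statsmodels uses the exact normal quantile, Woolf uses 1.96
            assert lo == pytest.approx(sm_lo, rel=1e-3)
            assert hi == pytest.approx(sm_hi, rel=1e-3)


class TestHwe:
    def test_exact_hwe_proportions(self):
        p, mono = pg.hwe_test((25, 50, 25))
        assert p == pytest.approx(1.0) and not mono

    def test_no_heterozygotes_departure(self):
        p, _ = pg.hwe_test((50, 0, 50))
        assert p < 1e-10

    def test_published_control_group_in_equilibrium(self):
        p, _ = pg.hwe_test((64, 30, 1))
        expected = 1 - stats.chi2.cdf(brute_hwe_chi2(64, 30, 1), 1)
        assert p == pytest.approx(expected, abs=1e-12)
        assert p > 0.05

    def test_monomorphic_flagged(self):
        p, mono = pg.hwe_test((30, 0, 0))
        assert p == 1.0 and mono

    def test_exact_matches_enumeration(self):
        rng = np.random.default_rng(31)
        for _ in range(200):
            counts = tuple(int(x) for x in rng.integers(0, 40, 3))
            if sum(counts) == 0:
                continue
            p_fast, mono = pg.hwe_test(counts, method="exact")
            if mono:
                continue
            assert p_fast == pytest.approx(
                brute_hwe_exact(*counts), abs=1e-10)


def brute_hwe_chi2(n_aa, n_ab, n_bb):
    n = n_aa + n_ab + n_bb
    p = (2 * n_aa + n_ab) / (2 * n)
    exp = [n * p * p, 2 * n * p * (1 - p), n * (1 - p) * (1 - p)]
    return sum((o - e) ** 2 / e for o, e in zip((n_aa, n_ab, n_bb), exp))


def brute_hwe_exact(n_aa, n_ab, n_bb):
    """Enumerate all genotype configurations given the allele counts."""
    import math

    n = n_aa + n_ab + n_bb
    n_a = 2 * n_aa + n_ab
    rare = min(n_a, 2 * n - n_a)
    probs = {}
    for h in range(rare % 2, rare + 1, 2):
        logp = (h * math.log(2) + math.lgamma(n + 1)
                - math.lgamma(h + 1) - math.lgamma((rare - h) // 2 + 1)
                - math.lgamma(n - (rare + h) // 2 + 1))
        probs[h] = logp
    mx = max(probs.values())
    weights = {h: np.exp(v - mx) for h, v in probs.items()}
    total = sum(weights.values())
    obs = weights[n_ab]
    return sum(w for w in weights.values() if w <= obs + 1e-12) / total


class TestBreslowDay:
    def test_identical_strata_homogeneous(self):
        t = np.array([[30, 20], [15, 35]])
        stat, p = pg.breslow_day([t, t])
        assert stat == pytest.approx(0.0, abs=1e-10)
        assert p == pytest.approx(1.0)

    def test_detects_heterogeneity(self):
        """Strata with true ORs 1 and 5 at n=100 each are heterogeneous."""
        homo = np.array([[25, 25], [25, 25]])       # OR 1
        hetero = np.array([[40, 10], [14, 36]])     # OR ~10
        stat, p = pg.breslow_day([homo, hetero])
        assert p < 0.05

    def test_single_stratum_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            pg.breslow_day([np.array([[1, 2], [3, 4]])])

    def test_zero_margin_stratum_dropped_with_warning(self):
        good = np.array([[10, 10], [10, 10]])
        bad = np.array([[0, 0], [10, 10]])
        with pytest.warns(UserWarning, match="zero margin"):
            stat, p = pg.breslow_day([good, good, bad])
        assert p == pytest.approx(1.0)

    def test_oracle_equivalence_statsmodels(self):
        """Tarone and plain variants match the reference implementation."""
        rng = np.random.default_rng(37)
        for _ in range(150):
            k = int(rng.integers(2, 5))
            strata = [rng.integers(1, 40, (2, 2)) for _ in range(k)]
            st_obj = StratifiedTable([np.asarray(t) for t in strata])
            for tarone in (False, True):
                stat, p = pg.breslow_day(strata, tarone=tarone)
                ref = st_obj.test_equal_odds(adjust=tarone)
                assert stat == pytest.approx(ref.statistic, abs=1e-8)
                assert p == pytest.approx(ref.pvalue, abs=1e-8)


class TestAssociate:
    def test_full_summary_fields(self):
        rng = np.random.default_rng(41)
        geno = pd.DataFrame(
            {"s1": rng.integers(0, 3, 80)},
            index=[f"i{k}" for k in range(80)],
        )
        pheno = pd.Series(["OMA"] * 40 + ["CTR"] * 40, index=geno.index)
        res = pg.associate(geno, pheno, "s1", "OMA",
                           discovery_stratum=np.array([[30, 10], [25, 15]]))
        assert res.ci_low <= res.or_value <= res.ci_high
        assert res.or_value >= 1.0
        assert 0 <= res.p_geno <= 1
        assert 0 <= res.phet <= 1
        assert res.call_rate == 1.0
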