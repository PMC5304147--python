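"""Correlation screening against WIS and Duncan's multiple range test."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import shadescreen as ss
from shadescreen.analytes import ALL_VARIABLES, DERIVED
from shadescreen.corrstats import _least_significant_range


@pytest.fixture(scope="module")
def genotype_profiles(seed_profiles):
    return seed_profiles.groupby("genotype", observed=True)[list(ALL_VARIABLES)].mean()


@pytest.fixture(scope="module")
def panel_wis():
    return ss.load_reference_germplasms().set_index("code")["wis"]


class TestCorrelateWithWis:
    def test_variable_identical_to_wis(self, genotype_profiles, panel_wis):
        prof = genotype_profiles.copy()
        prof["probe"] = panel_wis
        out = ss.correlate_with_wis(prof, panel_wis, variables=["probe"])
        assert out.loc[0, "r"] == pytest.approx(1.0)
        assert out.loc[0, "p"] < 1e-9
        assert out.loc[0, "flag"] == "**"

    def test_affine_anticorrelation(self, genotype_profiles, panel_wis):
        prof = genotype_profiles.copy()
        prof["probe"] = -panel_wis + 3.0
        out = ss.correlate_with_wis(prof, panel_wis, variables=["probe"])
        assert out.loc[0, "r"] == pytest.approx(-1.0)

    def test_zero_variance_variable_reported_missing(self, genotype_profiles, panel_wis):
        prof = genotype_profiles.copy()
        prof["flat"] = 1.0
        out = ss.correlate_with_wis(prof, panel_wis, variables=["flat"])
        assert np.isnan(out.loc[0, "r"])
        assert out.loc[0, "flag"] == "ns"

    def test_aglycones_anticorrelate_with_wis_on_synthetic_profiles(
        self, genotype_profiles, panel_wis
    ):
        """Aglycone variables must be significantly negative at 0.01, with the
        total aglycone content the most negative among the derived totals."""
        out = ss.correlate_with_wis(genotype_profiles, panel_wis).set_index("variable")
        for var in ("GE", "DE", "GLE", "T-e"):
            assert out.loc[var, "r"] < 0
            assert out.loc[var, "flag"] == "**"
        derived = out.loc[list(DERIVED), "r"]
        assert derived.idxmin() == "T-e"

    def test_pvalue_matches_permutation_oracle(self):
        rng = np.random.default_rng(4)
        n = 8
        x = rng.normal(size=n)
        w = 0.6 * x + rng.normal(scale=0.8, size=n)
        prof = pd.DataFrame({"v": x}, index=[f"g{i}" for i in range(n)])
        wis = pd.Series(w, index=prof.index)
        p_t = ss.correlate_with_wis(prof, wis, variables=["v"]).loc[0, "p"]
        r_obs = abs(np.corrcoef(x, w)[0, 1])
        n_perm = 20000
        hits = 0
        for _ in range(n_perm):
            hits += abs(np.corrcoef(x, rng.permutation(w))[0, 1]) >= r_obs
        p_perm = hits / n_perm
        assert p_t == pytest.approx(p_perm, abs=0.02)

    def test_too_few_genotypes_rejected(self, genotype_profiles, panel_wis):
        with pytest.raises(ValueError, match="3 matching"):
            ss.correlate_with_wis(genotype_profiles.iloc[:2], panel_wis)


class TestDuncan:
    def test_identical_groups_share_one_letter(self):
        values = [5.0] * 12
        groups = ["a"] * 4 + ["b"] * 4 + ["c"] * 4
        out = ss.duncan_mrt(values, groups)
        assert set(out["letters"]) == {"a"}

    def test_clearly_separated_pair_gets_distinct_letters(self):
        rng = np.random.default_rng(0)
        values = np.concatenate([rng.normal(0, 0.1, 5), rng.normal(10, 0.1, 5)])
        groups = ["low"] * 5 + ["high"] * 5
        out = ss.duncan_mrt(values, groups).set_index("group")
        assert out.loc["low", "letters"] != out.loc["high", "letters"]
        # two-group Duncan reduces to an LSD test: q_{2,df} = sqrt(2) t_{df}
        lsr = _least_significant_range(2, 8, 0.05, mse=0.01, n_h=5)
        lsd = stats.t.ppf(0.975, 8) * np.sqrt(2 * 0.01 / 5)
        assert lsr == pytest.approx(lsd, rel=1e-9)

    def test_near_equal_pair_shares_letter_and_outlier_does_not(self):
        rng = np.random.default_rng(1)
        values = np.concatenate(
            [rng.normal(0, 0.1, 5), rng.normal(0.05, 0.1, 5), rng.normal(10, 0.1, 5)]
        )
        groups = ["g1"] * 5 + ["g2"] * 5 + ["g3"] * 5
        out = ss.duncan_mrt(values, groups).set_index("group")
        assert set(out.loc["g1", "letters"]) & set(out.loc["g2", "letters"])
        assert not set(out.loc["g3", "letters"]) & set(out.loc["g1", "letters"])

    @pytest.mark.parametrize("seed", range(8))
    def test_letter_display_consistent_with_least_significant_ranges(self, seed):
        """Adjacent groups sharing a letter must differ by less than their
        least significant range; groups with disjoint letters must exceed it."""
        rng = np.random.default_rng(seed)
        k, n = 4, 6
        shifts = rng.uniform(0, 3, size=k)
        values = np.concatenate([rng.normal(s, 1.0, n) for s in shifts])
        groups = np.repeat([f"g{i}" for i in range(k)], n)
        out = ss.duncan_mrt(values, groups)
        frame = pd.DataFrame({"value": values, "group": groups})
        mse = (
            frame.groupby("group")["value"].apply(lambda v: ((v - v.mean()) ** 2).sum()).sum()
            / (k * n - k)
        )
        if out.attrs["anova_p"] >= 0.05:
            assert set(out["letters"]) == {"a"}
            return
        means = out.set_index("group")["mean"]
        letters = out.set_index("group")["letters"]
        ordered = means.sort_values(ascending=False).index.tolist()
        # every letter marks a run of adjacent means whose full range is
        # within the least significant range for that run size
        for ch in sorted(set("".join(letters))):
            members = [g for g in ordered if ch in letters[g]]
            p = len(members)
            if p < 2:
                continue
            span = means[members[0]] - means[members[-1]]
            assert span <= _least_significant_range(p, k * n - k, 0.05, mse, n)
        # disjoint letters mean the direct range exceeded its own threshold
        for i, gi in enumerate(ordered):
            for j in range(i + 1, len(ordered)):
                gj = ordered[j]
                if not (set(letters[gi]) & set(letters[gj])):
                    lsr = _least_significant_range(j - i + 1, k * n - k, 0.05, mse, n)
                    assert means[gi] - means[gj] > lsr

    def test_group_of_one_rejected(self):
        with pytest.raises(ValueError, match="at least 2 samples"):
            ss.duncan_mrt([1.0, 2.0, 3.0], ["a", "a", "b"])

    def test_type_i_error_of_anova_gate_near_nominal(self):
        """Under a global null the 0.05 ANOVA gate should reject ~5% of runs."""
        rng = np.random.default_rng(42)
        n_sim, k, n = 2000, 3, 5
        rejections = 0
        for _ in range(n_sim):
            values = rng.normal(size=k * n)
            groups = np.repeat(list("abc"), n)
            out = ss.duncan_mrt(values, groups)
            rejections += out.attrs["anova_p"] < 0.05
        rate = rejections / n_sim
        assert 0.035 <= rate <= 0.065
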