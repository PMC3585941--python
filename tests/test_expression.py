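"""TPM normalization, the exact two-library test, DE calls, stage
preference and profile clustering."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import gammaln

from oryzamir import expression
from oryzamir.expression import (call_de, cluster_profiles, de_test,
                                 normalize, prepare_pair, stage_preference)


def ac_posterior_pvalue(x, n1, y, n2):
    """Independent oracle: direct summation of the Audic-Claverie
    posterior predictive p(k | x) = (n2/n1)^k (x+k)! /
    (x! k! (1 + n2/n1)^(x+k+1)), two-sided, both directions averaged."""
    def direction(x, n1, y, n2):
        r = n2 / n1
        def logp(k):
            return (k * np.log(r) + gammaln(x + k + 1) - gammaln(x + 1)
                    - gammaln(k + 1) - (x + k + 1) * np.log1p(r))
        lower = sum(np.exp(logp(k)) for k in range(0, y + 1))
        upper = 1.0 - sum(np.exp(logp(k)) for k in range(0, y))
        return min(1.0, 2.0 * min(lower, upper))
    return min(1.0, (direction(x, n1, y, n2) + direction(y, n2, x, n1)) / 2)


class TestNormalize:
    def test_formula_on_published_scale(self):
        counts = pd.DataFrame({"5DAF": [651290]}, index=["m"])
        tpm = normalize(counts, {"5DAF": 17029030})
        assert round(float(tpm.at["m", "5DAF"]), 2) == 38245.87

    def test_zero_and_full(self):
        counts = pd.DataFrame({"A": [0, 1000]}, index=["m0", "m1"])
        tpm = normalize(counts, {"A": 1000})
        assert float(tpm.at["m0", "A"]) == 0.0
        assert float(tpm.at["m1", "A"]) == 1e6

    def test_negative_count_rejected(self):
        counts = pd.DataFrame({"A": [-1]}, index=["m"])
        with pytest.raises(ValueError):
            normalize(counts, {"A": 10})

    def test_tpm_sums_to_one_million(self, default_run):
        """Over the full tag table of each library TPM sums to 1e6."""
        table = default_run.table
        totals = table.totals
        counts = table.to_frame().drop(columns="length")
        tpm = normalize(counts, totals)
        for lib in table.libraries:
            assert float(tpm[lib].sum()) == pytest.approx(1e6, rel=1e-9)


class TestPreparePair:
    @pytest.mark.parametrize("a,b,expected", [
        (0, 50, (0.01, 50, True)),
        (0.5, 0.8, (0.5, 0.8, False)),
        (10, 10, (10, 10, True)),
        (50, 0, (50, 0.01, True)),
    ])
    def test_substitution_and_filter(self, a, b, expected):
        assert prepare_pair(a, b) == expected


class TestDeTest:
    def test_symmetry_under_swap(self):
        p1 = de_test(10, 1.5e6, 25, 1.0e6)
        p2 = de_test(25, 1.0e6, 10, 1.5e6)
        assert p1 == p2

    def test_extreme_difference(self):
        assert de_test(0, 1e6, 1000, 1e6) < 1e-10

    @pytest.mark.parametrize("x,y", [(10, 12), (10, 40), (0, 3), (100, 70)])
    def test_matches_posterior_summation_oracle(self, x, y):
        ours = de_test(x, 1e6, y, 1e6)
        oracle = ac_posterior_pvalue(x, 1e6, y, 1e6)
        assert ours == pytest.approx(oracle, abs=1e-10)

    def test_matches_oracle_unequal_depths(self):
        ours = de_test(10, 2e6, 30, 1e6)
        oracle = ac_posterior_pvalue(10, 2e6, 30, 1e6)
        assert ours == pytest.approx(oracle, abs=1e-10)

    def test_invalid_totals(self):
        with pytest.raises(ValueError):
            de_test(1, 0, 1, 10)


class TestCallDe:
    def _counts(self):
        return pd.DataFrame(
            {"5DAF": [100, 800, 500], "7DAF": [800, 100, 500]},
            index=["up8", "down8", "flat"])

    def test_planted_eightfold_direction(self):
        totals = {"5DAF": 1_000_000, "7DAF": 1_000_000}
        frame, tallies = call_de(self._counts(), totals)
        by_id = frame.set_index("mirna")
        assert by_id.at["up8", "direction"] == "up"
        assert by_id.at["down8", "direction"] == "down"
        assert by_id.at["flat", "direction"] == "ns"
        assert tallies["5DAF->7DAF"] == (2, 1, 1)

    def test_antisymmetry(self):
        totals = {"5DAF": 1_000_000, "7DAF": 1_000_000}
        fwd, _ = call_de(self._counts(), totals)
        rev_counts = self._counts()[["7DAF", "5DAF"]]
        rev, _ = call_de(rev_counts, totals)
        flip = {"up": "down", "down": "up", "ns": "ns"}
        for mirna in fwd.mirna:
            a = fwd.set_index("mirna").loc[mirna]
            b = rev.set_index("mirna").loc[mirna]
            assert b.direction == flip[a.direction]
            assert b.p_value == pytest.approx(a.p_value, abs=1e-12)

    def test_alpha_zero_calls_nothing(self):
        totals = {"5DAF": 1_000_000, "7DAF": 1_000_000}
        frame, tallies = call_de(self._counts(), totals, alpha=0.0)
        assert (frame.direction == "ns").all()

    def test_planted_fold_changes_recovered(self, default_run):
        """Every planted |log2FC| >= 2 change with >= 100 expected reads
        on the low side is called with the right direction."""
        sig = default_run.de_results[
            default_run.de_results.direction != "ns"]
        for row in default_run.truth.de_truth.itertuples(index=False):
            match = sig[(sig.mirna == row.miRNA)
                        & (sig.transition == row.transition)
                        & (sig.direction == row.direction)]
            assert len(match) == 1, (row.miRNA, row.transition)


class TestStagePreference:
    def test_flat_profile_not_called(self):
        tpm = pd.DataFrame([[10, 10, 10, 10]], index=["m"],
                           columns=list("abcd"))
        assert len(stage_preference(tpm)) == 0

    def test_degenerate_sd_rule(self):
        tpm = pd.DataFrame([[100, 1, 1, 1]], index=["m"],
                           columns=list("abcd"))
        calls = stage_preference(tpm)
        assert len(calls) == 1
        assert calls.iloc[0].stage == "a"
        assert calls.iloc[0].ratio == pytest.approx(100.0)

    def test_high_ratio_low_z_not_called(self):
        tpm = pd.DataFrame([[100, 90, 1, 1]], index=["m"],
                           columns=list("abcd"))
        calls = stage_preference(tpm)
        assert not ((calls.mirna == "m") & (calls.stage == "a")).any()
        # hand arithmetic: ratio 3.26, z ~ 1.35
        others = np.array([90, 1, 1.0])
        assert 100 / others.mean() == pytest.approx(3.26, abs=0.01)
        z = (100 - others.mean()) / others.std(ddof=1)
        assert z == pytest.approx(1.35, abs=0.01)

    def test_planted_spikes_called(self, default_run):
        counts = default_run.known_counts
        tpm = normalize(counts, default_run.table.totals)
        calls = stage_preference(tpm)
        called = set(zip(calls.mirna, calls.stage))
        assert ("osa-miR9027", "7DAF") in called
        assert ("osa-miR9028", "17DAF") in called


class TestClusterProfiles:
    def _profiles(self, rng, n_per=20):
        up = np.array([1, 2, 4, 8.0])
        peaked = np.array([1, 8, 1, 1.0])
        rows = []
        for arch in (up, peaked):
            for _ in range(n_per):
                rows.append(arch * rng.lognormal(0, 0.05, 4) * 100)
        idx = [f"m{i}" for i in range(2 * n_per)]
        return pd.DataFrame(rows, index=idx, columns=list("abcd"))

    def test_single_cluster(self, rng):
        tpm = self._profiles(rng)
        assign, _ = cluster_profiles(tpm, k=1, seed=0)
        assert assign.nunique() == 1

    def test_two_archetypes_separate(self, rng):
        tpm = self._profiles(rng)
        assign, _ = cluster_profiles(tpm, k=2, seed=0)
        first = assign.iloc[:20]
        second = assign.iloc[20:]
        assert first.nunique() == 1 and second.nunique() == 1
        assert first.iloc[0] != second.iloc[0]

    def test_deterministic_for_seed(self, rng):
        tpm = self._profiles(rng)
        a1, _ = cluster_profiles(tpm, k=4, seed=3)
        a2, _ = cluster_profiles(tpm, k=4, seed=3)
        assert (a1 == a2).all()

    def test_too_few_rows_rejected(self, rng):
        tpm = self._profiles(rng).iloc[:5]
        with pytest.raises(ValueError):
            cluster_profiles(tpm, k=10, seed=0)
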