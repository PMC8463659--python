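import itertools
import math
from collections import Counter

import numpy as np
import pandas as pd
import pytest

from csfmir.errors import InsufficientDataError, InvalidInputError
from csfmir.info_dependence import (
    BinnedVariable,
    bin_secondary,
    bin_tertile,
    build_primaries,
    composite_scores,
    entropy,
    mutual_information,
    run_search,
    stringent_filter,
    symmetric_delta,
)
from csfmir.qpcr_io import PhenotypeTable


# --------------------------------------------------------------------------
# independent oracles, written straight from the definitions


def entropy_oracle(codes) -> float:
    n = len(codes)
    return -sum(
        (c / n) * math.log2(c / n) for c in Counter(codes).values()
    )


def mi_oracle(x, y) -> float:
    n = len(x)
    pxy = Counter(zip(x, y))
    px, py = Counter(x), Counter(y)
    return sum(
        (c / n) * math.log2((c / n) / ((px[a] / n) * (py[b] / n)))
        for (a, b), c in pxy.items()
    )


def delta_oracle(m, p, s):
    def H(*cols):
        return entropy_oracle(list(zip(*cols))) if len(cols) > 1 else entropy_oracle(cols[0])

    i_mp = H(m) + H(p) - H(m, p)
    i_ms = H(m) + H(s) - H(m, s)
    i_ps = H(p) + H(s) - H(p, s)
    i_mp_given_s = H(m, s) + H(p, s) - H(s) - H(m, p, s)
    i3 = i_mp - i_mp_given_s
    dm, dp, ds = i3 - i_ps, i3 - i_ms, i3 - i_mp
    return dm, dp, ds, dm * dp * ds


def _xor_triple():
    m = np.array([0, 0, 1, 1])
    p = np.array([0, 1, 0, 1])
    return m, p, m ^ p


# --------------------------------------------------------------------------


class TestEntropy:
    def test_fair_binary(self):
        assert entropy([5, 5]) == pytest.approx(1.0)

    def test_deterministic(self):
        assert entropy([7]) == pytest.approx(0.0)
        assert entropy([7, 0, 0]) == pytest.approx(0.0)

    def test_hand_arithmetic(self):
        assert entropy([2, 1, 1]) == pytest.approx(1.5)

    def test_empty_rejected(self):
        with pytest.raises(InvalidInputError):
            entropy([])
        with pytest.raises(InvalidInputError):
            entropy([0, 0])


class TestMutualInformation:
    def test_identical_fair_bits(self):
        x = np.array([0, 1, 0, 1])
        assert mutual_information(x, x) == pytest.approx(1.0)

    def test_independent_product_table(self):
        # exact product distribution: each (x, y) combo equally often
        x, y = zip(*itertools.product([0, 1, 2], [0, 1]))
        assert mutual_information(np.array(x), np.array(y)) == pytest.approx(
            0.0, abs=1e-15
        )

    def test_brute_force_oracle_random(self, rng):
        for _ in range(50):
            x = rng.integers(0, 3, 40)
            y = rng.integers(0, 2, 40)
            assert mutual_information(x, y) == pytest.approx(
                mi_oracle(list(x), list(y)), abs=1e-12
            )

    def test_properties(self, rng):
        for _ in range(20):
            x = rng.integers(0, 3, 30)
            y = rng.integers(0, 3, 30)
            mi = mutual_information(x, y)
            assert mi >= -1e-12
            assert mi == pytest.approx(mutual_information(y, x), abs=1e-12)
            assert mi <= min(entropy_oracle(list(x)), entropy_oracle(list(y))) + 1e-12

    def test_mi_of_self_is_entropy(self, rng):
        x = rng.integers(0, 4, 50)
        assert mutual_information(x, x) == pytest.approx(
            entropy_oracle(list(x)), abs=1e-12
        )

    def test_complete_case(self):
        x = np.array([0, 1, np.nan, 0, 1])
        y = np.array([0, 1, 1, np.nan, 1])
        # only 3 complete pairs: (0,0), (1,1), (1,1)
        assert mutual_information(x, y) == pytest.approx(
            mi_oracle([0, 1, 1], [0, 1, 1]), abs=1e-12
        )


class TestSymmetricDelta:
    def test_xor_closed_form(self):
        m, p, s = _xor_triple()
        dm, dp, ds, dbar = symmetric_delta(m, p, s)
        assert mutual_information(m, p) == pytest.approx(0.0, abs=1e-15)
        assert mutual_information(m, s) == pytest.approx(0.0, abs=1e-15)
        assert (dm, dp, ds) == pytest.approx((-1.0, -1.0, -1.0), abs=1e-12)
        assert dbar == pytest.approx(-1.0, abs=1e-12)

    def test_independent_third_variable(self):
        # S independent of (M, P): delta_bar is exactly 0 on the joint table
        m, p = zip(*itertools.product([0, 1], [0, 1]))
        m, p = np.array(m * 2), np.array(p * 2)
        s = np.array([0] * 4 + [1] * 4)
        *_, dbar = symmetric_delta(m, p, s)
        assert dbar == pytest.approx(0.0, abs=1e-12)

    def test_brute_force_oracle_random(self, rng):
        for _ in range(200):
            m = rng.integers(0, 2, 30)
            p = rng.integers(0, 2, 30)
            s = rng.integers(0, 2, 30)
            got = symmetric_delta(m, p, s)
            want = delta_oracle(list(m), list(p), list(s))
            assert got == pytest.approx(want, abs=1e-12)

    def test_permutation_invariance(self, rng):
        m = rng.integers(0, 3, 40)
        p = rng.integers(0, 2, 40)
        s = rng.integers(0, 2, 40)
        base = symmetric_delta(m, p, s)[3]
        for perm in itertools.permutations([m, p, s]):
            assert symmetric_delta(*perm)[3] == pytest.approx(base, abs=1e-12)


class TestBinTertile:
    def test_normal_sample_f_matches_quantile_oracle(self, rng):
        # tertile boundaries of the standard normal are at +/- 0.4307 sigma
        v = rng.normal(0, 1, 20_000)
        bv = bin_tertile(v)
        assert bv.factor_f == pytest.approx(0.4307, abs=0.03)
        counts = pd.Series(bv.values).value_counts()
        assert (abs(counts - len(v) / 3) / (len(v) / 3) < 0.05).all()

    def test_uniform_sample_f_matches_closed_form(self, rng):
        # uniform(0,1): tertiles at 1/3, 2/3 -> f = (1/6)/(1/sqrt(12)) ... the
        # thresholds mu +/- f*s must land at 1/3 and 2/3, so f = (1/6)/sigma
        v = rng.uniform(0, 1, 20_000)
        bv = bin_tertile(v)
        f_expected = (1 / 6) / (1 / np.sqrt(12))
        assert bv.factor_f == pytest.approx(f_expected, abs=0.05)

    def test_codes_follow_documented_tie_rule(self, rng):
        v = pd.Series(rng.normal(0, 1, 50))
        bv = bin_tertile(v)
        lo, hi = bv.bin_edges
        # boundary values belong to the lower bin: <= lo -> 0, <= hi -> 1
        expect = np.where(v <= lo, 0.0, np.where(v <= hi, 1.0, 2.0))
        assert np.array_equal(bv.values.to_numpy(), expect)

    def test_ties_at_mean_go_to_middle(self):
        v = np.array([1.0, 2.0, 5.0, 5.0, 5.0, 5.0, 8.0, 9.0])
        bv = bin_tertile(v)
        assert (bv.values[v == 5.0] == 1.0).all()

    def test_smallest_f_wins_ties(self):
        # symmetric data: many f give identical bin counts; smallest returned
        v = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        bv = bin_tertile(v)
        fs = np.arange(0.01, 2.005, 0.01)
        mu, sd = v.mean(), v.std(ddof=1)
        best = None
        for f in fs:
            lo, hi = mu - f * sd, mu + f * sd
            c = [(v <= lo).sum(), ((v > lo) & (v <= hi)).sum(), (v > hi).sum()]
            cost = max(abs(ci - len(v) / 3) for ci in c)
            if best is None or cost < best[0] - 1e-12:
                best = (cost, f)
        assert bv.factor_f == pytest.approx(best[1], abs=1e-9)

    def test_too_few_values(self):
        with pytest.raises(InsufficientDataError):
            bin_tertile(np.array([1.0, 2.0, 3.0]))

    def test_zero_variance(self):
        with pytest.raises(InvalidInputError):
            bin_tertile(np.full(10, 5.0))


def _pheno_table():
    idx = [f"s{i}" for i in range(12)]
    return PhenotypeTable(
        pd.DataFrame(
            {
                "group": ["ComC"] * 5 + ["DepC"] * 3 + ["DepTBI"] * 4,
                "age": [30, 35, 40, 28, 33, 36, 29, 41, 38, 27, 45, 31],
                "bmi": [24.0, 25.5, 23.0, 27.0, 26.0, 29.0, 28.0, 30.0, 22.0, 26.5, 31.0, 24.5],
                "mmse": [30, 29, 30, 29, 30, 28, 29, 28, 30, 27, 29, 30],
                "abeta42": [320.0, 310.0, 330.0, 300.0, 315.0, 305.0, 325.0, 318.0, 312.0, 308.0, 322.0, 316.0],
                "ttau": [30.0, 40.0, 50.0, 36.0, 35.0, 37.0, 39.0, 41.0, 38.0, 42.0, 33.0, 44.0],
                "ptau181": [27.0, 28.0, 26.0, 29.0, 30.0, 28.5, 27.5, 28.0, 26.5, 29.5, 28.0, 27.0],
                "apoe": ["e3/e3", "e3/e4", "e3/e3", "e3/e3", "e3/e4", "e4/e4",
                         "e3/e3", "e3/e4", "e2/e3", "e3/e3", None, "e3/e3"],
                "smoke": ["no", "no", "yes", "no", "no", "yes",
                          "no", "no", "unknown", "yes", "no", "no"],
                "race": ["white", "white", "asian", "white", "other", "white",
                         "black", "white", "native", "white", "asian", "white"],
            },
            index=pd.Index(idx, name="sample_id"),
        )
    )


class TestBinSecondary:
    def test_mean_split_boundary_to_upper(self):
        phenos = _pheno_table()
        out = bin_secondary(phenos)
        ttau = out["ttau"]
        # first three ttau values are {30, 40, 50}; overall mean decides codes
        mu = phenos.data["ttau"].mean()
        vals = phenos.data["ttau"]
        assert (ttau.values[vals >= mu] == 1.0).all()
        assert (ttau.values[vals < mu] == 0.0).all()

    def test_mean_split_hand_example(self):
        from csfmir.info_dependence import _mean_split

        bv = _mean_split(pd.Series([30.0, 40.0, 50.0]), "ttau")
        assert bv.values.tolist() == [0.0, 1.0, 1.0]

    def test_apoe4_from_genotype(self):
        out = bin_secondary(_pheno_table())
        apoe4 = out["apoe4"].values
        assert apoe4["s1"] == 1.0  # e3/e4
        assert apoe4["s0"] == 0.0  # e3/e3
        assert apoe4["s5"] == 1.0  # e4/e4
        assert np.isnan(apoe4["s10"])  # missing genotype

    def test_smoke_unknown_missing(self):
        out = bin_secondary(_pheno_table())
        smoke = out["smoke"].values
        assert np.isnan(smoke["s8"])
        assert smoke["s2"] == 1.0
        assert smoke["s0"] == 0.0

    def test_race_merged_to_three(self):
        out = bin_secondary(_pheno_table())
        race = out["race"]
        assert race.n_bins <= 3
        codes = race.values.dropna()
        assert set(codes.unique()) <= {0.0, 1.0, 2.0}
        # most frequent category gets code 0
        assert race.values["s0"] == 0.0  # white is the majority

    def test_all_thirteen_present(self):
        out = bin_secondary(_pheno_table())
        assert len(out) == 13

    def test_tertile_for_age_bmi(self):
        out = bin_secondary(_pheno_table())
        assert out["age"].scheme == "tertile-musigma"
        assert out["bmi"].scheme == "tertile-musigma"
        assert out["mmse"].scheme == "mean-split"


class TestBuildPrimaries:
    def test_recodings(self):
        phenos = _pheno_table()
        out = build_primaries(phenos)
        assert out["deployment"].values["s0"] == 0.0  # ComC
        assert out["tbi"].values["s0"] == 0.0
        assert out["exp_grp"].values["s0"] == 0.0
        assert out["deployment"].values["s5"] == 1.0  # DepC
        assert out["tbi"].values["s5"] == 0.0
        assert out["exp_grp"].values["s5"] == 1.0
        assert out["deployment"].values["s8"] == 1.0  # DepTBI
        assert out["tbi"].values["s8"] == 1.0
        assert out["exp_grp"].values["s8"] == 2.0


def _search_inputs(rng, n=60, n_mirnas=15):
    groups = (
        ["ComC"] * (n // 2) + ["DepC"] * (n // 6) + ["DepTBI"] * (n - n // 2 - n // 6)
    )
    idx = [f"s{i}" for i in range(n)]
    df = pd.DataFrame(
        {
            "group": groups,
            "age": rng.normal(33, 8, n).round(1),
            "bmi": rng.normal(26, 4, n).round(1),
            "mmse": rng.integers(26, 31, n),
            "abeta42": rng.normal(315, 50, n).round(1),
            "ttau": rng.normal(40, 12, n).round(1),
            "ptau181": rng.normal(28, 6, n).round(1),
            "apoe": rng.choice(["e3/e3", "e3/e4", "e4/e4"], n, p=[0.6, 0.3, 0.1]),
            "smoke": rng.choice(["no", "yes"], n, p=[0.8, 0.2]),
            "race": rng.choice(["white", "black", "asian", "other"], n),
        },
        index=pd.Index(idx, name="sample_id"),
    )
    phenos = PhenotypeTable(df)
    primaries = build_primaries(phenos)
    secondaries = bin_secondary(phenos)
    codes = pd.DataFrame(
        rng.integers(0, 3, size=(n, n_mirnas)).astype(float),
        index=idx,
        columns=[f"m{j:02d}" for j in range(n_mirnas)],
    )
    return phenos, primaries, secondaries, codes


class TestRunSearch:
    def test_43_lists(self, rng):
        _, primaries, secondaries, codes = _search_inputs(rng)
        res = run_search(codes, primaries, secondaries)
        assert res["list_id"].nunique() == 43
        # 3 MI lists + 40 delta lists
        assert res[res["measure"] == "MI"]["list_id"].nunique() == 3
        assert res[res["measure"] == "delta"]["list_id"].nunique() == 40

    def test_every_list_scores_all_mirnas(self, rng):
        _, primaries, secondaries, codes = _search_inputs(rng)
        res = run_search(codes, primaries, secondaries)
        sizes = res.groupby("list_id").size()
        assert (sizes == codes.shape[1]).all()

    def test_z_standardized_within_list(self, rng):
        _, primaries, secondaries, codes = _search_inputs(rng)
        res = run_search(codes, primaries, secondaries)
        for _, sub in res.groupby("list_id"):
            z = sub["z"].dropna()
            assert z.mean() == pytest.approx(0.0, abs=1e-10)
            assert z.std(ddof=1) == pytest.approx(1.0, abs=1e-10)

    def test_top_sets_bounded_and_above_one_sd(self, rng):
        _, primaries, secondaries, codes = _search_inputs(rng)
        res = run_search(codes, primaries, secondaries)
        ranked = res[res["rank"].notna()]
        assert (ranked["z"] > 1.0).all()
        assert ranked.groupby("list_id").size().max() <= 20

    def test_planted_synergy_ranks_first_only_in_3way(self, rng):
        phenos, primaries, secondaries, codes = _search_inputs(rng, n=90)
        dep = primaries["deployment"].values
        tbi = primaries["tbi"].values
        parity = (dep.astype(int) ^ tbi.astype(int)).astype(float)
        # miRNA tertile is a noisy parity function of (deployment, tbi)
        noise = rng.random(len(parity)) < 0.1
        codes["synergy"] = np.where(noise, 2.0, parity * 2.0)
        res = run_search(codes, primaries, secondaries)
        three_way = res[res["list_id"] == "delta:deployment:tbi"]
        top = three_way.sort_values("rank").iloc[0]
        assert top["mirna_id"] == "synergy"
        assert top["rank"] == 1.0

    def test_short_list_emitted_empty(self, rng):
        _, primaries, secondaries, codes = _search_inputs(rng)
        # a secondary with almost no data empties its lists
        sparse = secondaries["age"].values.copy()
        sparse[:] = np.nan
        sparse.iloc[:5] = 1.0
        secondaries["age"] = BinnedVariable("age", sparse, 3, "tertile-musigma")
        res = run_search(codes, primaries, secondaries, min_samples=10)
        assert res[res["list_id"] == "delta:tbi:age"].empty


def _records_for_composite(mirnas, z_by_list):
    rows = []
    for list_id, zmap in z_by_list.items():
        measure = "MI" if list_id.startswith("MI") else "delta"
        for m in mirnas:
            rows.append(
                {
                    "list_id": list_id, "measure": measure, "mirna_id": m,
                    "raw": 0.0, "score": 0.0, "z": zmap.get(m, 0.0),
                    "rank": np.nan, "n_samples": 50,
                }
            )
    return pd.DataFrame(rows)


class TestCompositeScores:
    LISTS = [
        "MI:tbi", "delta:tbi:ptau-ttau", "delta:tbi:abeta-ttau",
        "delta:tbi:abeta-ptau", "delta:tbi:apoe4", "delta:tbi:age",
        "delta:tbi:bmi", "delta:tbi:smoke",
    ]

    def test_all_zero_components(self):
        records = _records_for_composite(["m1"], {l: {} for l in self.LISTS})
        cs = composite_scores(records, "tbi")
        assert cs.loc[cs["mirna_id"] == "m1", "value"].iloc[0] == pytest.approx(0.0)

    def test_direct_substitution(self):
        z = {l: {} for l in self.LISTS}
        z["MI:tbi"] = {"m1": 2.0}
        z["delta:tbi:ptau-ttau"] = {"m1": 1.0}
        z["delta:tbi:apoe4"] = {"m1": 1.0}
        records = _records_for_composite(["m1"], z)
        cs = composite_scores(records, "tbi")
        assert cs["value"].iloc[0] == pytest.approx(2.0 + 0.5 * (1.0 + 1.0))

    def test_ratio_term_is_max_not_sum(self):
        z = {l: {} for l in self.LISTS}
        z["delta:tbi:ptau-ttau"] = {"m1": 3.0}
        z["delta:tbi:abeta-ttau"] = {"m1": 1.0}
        z["delta:tbi:abeta-ptau"] = {"m1": 2.0}
        records = _records_for_composite(["m1"], z)
        cs = composite_scores(records, "tbi")
        assert cs["value"].iloc[0] == pytest.approx(0.5 * 3.0)

    def test_demographic_weight_one_third(self):
        z = {l: {} for l in self.LISTS}
        z["delta:tbi:age"] = {"m1": 1.5}
        z["delta:tbi:bmi"] = {"m1": 1.5}
        z["delta:tbi:smoke"] = {"m1": 1.5}
        records = _records_for_composite(["m1"], z)
        cs = composite_scores(records, "tbi")
        assert cs["value"].iloc[0] == pytest.approx(1.5)

    def test_linearity_in_components(self, rng):
        z = {l: {"m1": float(rng.normal())} for l in self.LISTS}
        records = _records_for_composite(["m1"], z)
        cs = composite_scores(records, "tbi")
        expected = (
            z["MI:tbi"]["m1"]
            + 0.5 * (
                max(
                    z["delta:tbi:ptau-ttau"]["m1"],
                    z["delta:tbi:abeta-ttau"]["m1"],
                    z["delta:tbi:abeta-ptau"]["m1"],
                )
                + z["delta:tbi:apoe4"]["m1"]
            )
            + (z["delta:tbi:age"]["m1"] + z["delta:tbi:bmi"]["m1"]
               + z["delta:tbi:smoke"]["m1"]) / 3.0
        )
        assert cs["value"].iloc[0] == pytest.approx(expected, abs=1e-12)


class TestStringentFilter:
    def _scores(self, values):
        return pd.DataFrame(
            {"mirna_id": [f"m{i}" for i in range(len(values))], "value": values}
        )

    def test_all_equal_empty(self):
        scores = {"tbi": self._scores([1.0] * 20)}
        assert stringent_filter(scores) == []

    def test_single_outlier_selected(self, rng):
        vals = list(rng.normal(0, 1, 50)) + [10.0]
        scores = {"tbi": self._scores(vals)}
        assert stringent_filter(scores) == ["m50"]

    def test_qc_intersection(self, rng):
        vals = list(rng.normal(0, 1, 50)) + [10.0]
        scores = {"tbi": self._scores(vals)}
        assert stringent_filter(scores, qc_passing={"m1"}) == []

    def test_union_over_primaries(self, rng):
        base = list(rng.normal(0, 1, 50))
        scores = {
            "tbi": self._scores(base + [10.0, 0.0]),
            "deployment": self._scores(base + [0.0, 10.0]),
        }
        assert stringent_filter(scores) == ["m50", "m51"]
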