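import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from coaldiscord.fstats import (
    FrequencyTable,
    block_jackknife_ratio,
    d_statistic,
    f3,
    f4,
    f4_ratio,
    outgroup_f3,
    rank_outgroup_f3,
    read_frequency_table,
)


def make_table(freqs: dict[str, np.ndarray], sites_per_chrom=None, spacing=100_000):
    pops = list(freqs)
    n = len(freqs[pops[0]])
    if sites_per_chrom is None:
        sites_per_chrom = n
    chrom = np.array([str(1 + i // sites_per_chrom) for i in range(n)])
    pos = np.array([1 + (i % sites_per_chrom) * spacing for i in range(n)])
    df = pd.DataFrame({"CHROM": chrom, "POS": pos, **{p: freqs[p] for p in pops}})
    return FrequencyTable(df, tuple(pops))


def drift(rng, p, fst):
    """One generation-of-drift step: Beta around p with variance fst*p*(1-p)."""
    k = (1 - fst) / fst
    return rng.beta(np.clip(p, 1e-3, 1 - 1e-3) * k, np.clip(1 - p, 1e-3, 1 - 1e-3) * k)


def drifted_pair(rng, n, fst=0.2):
    """Two populations drifted independently from a Beta-distributed ancestor."""
    anc = rng.beta(0.8, 0.8, size=n)
    return anc, drift(rng, anc, fst), drift(rng, anc, fst)


class TestFrequencyTable:
    def test_validation(self):
        df = pd.DataFrame({"CHROM": ["1", "1"], "POS": [5, 3], "A": [0.1, 0.2]})
        with pytest.raises(ValueError, match="increasing"):
            FrequencyTable(df, ("A",))
        df2 = pd.DataFrame({"CHROM": ["1"], "POS": [1], "A": [1.2]})
        with pytest.raises(ValueError, match="frequencies"):
            FrequencyTable(df2, ("A",))

    def test_block_ids_per_chromosome(self):
        ft = make_table({"A": np.zeros(40)}, sites_per_chrom=20, spacing=400_000)
        ids = ft.block_ids(block_size=5_000_000)
        # 20 sites x 400 kb span 7.6 Mb -> 2 blocks per chromosome
        assert len(np.unique(ids)) == 4
        # blocks are contiguous runs
        assert (np.diff(ids) >= 0).all()

    def test_tsv_round_trip(self, tmp_path):
        rng = np.random.default_rng(1)
        ft = make_table({"A": rng.random(10), "B": rng.random(10)})
        path = tmp_path / "f.tsv"
        ft.to_tsv(path)
        back = read_frequency_table(path)
        assert back.populations == ("A", "B")
        pd.testing.assert_frame_equal(back.data, ft.data)


class TestDStatistic:
    def test_count_form(self):
        # 30 ABBA sites and 10 BABA sites with fixed frequencies
        a = np.array([0.0] * 30 + [1.0] * 10)
        b = np.array([1.0] * 30 + [0.0] * 10)
        c = np.ones(40)
        d = np.zeros(40)
        res = d_statistic(make_table({"A": a, "B": b, "C": c, "D": d}), "A", "B", "C", "D")
        assert res.estimate == pytest.approx((30 - 10) / (30 + 10))

    def test_identical_sisters_give_zero(self):
        rng = np.random.default_rng(3)
        x = rng.random(500)
        c = rng.random(500)
        ft = make_table({"A": x, "B": x.copy(), "C": c, "D": np.zeros(500)})
        assert d_statistic(ft, "A", "B", "C", "D").estimate == pytest.approx(0.0)

    def test_antisymmetry_in_first_pair(self):
        rng = np.random.default_rng(4)
        ft = make_table({p: rng.random(2000) for p in "ABCD"})
        d1 = d_statistic(ft, "A", "B", "C", "D").estimate
        d2 = d_statistic(ft, "B", "A", "C", "D").estimate
        assert d1 == pytest.approx(-d2)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_bounded_in_unit_interval(self, seed):
        rng = np.random.default_rng(seed)
        ft = make_table({p: rng.random(200) for p in "ABCD"})
        try:
            res = d_statistic(ft, "A", "B", "C", "D")
        except ValueError:
            return  # no informative sites is a legal outcome
        assert -1.0 <= res.estimate <= 1.0

    def test_no_informative_sites(self):
        z = np.zeros(10)
        ft = make_table({"A": z, "B": z, "C": z, "D": z})
        with pytest.raises(ValueError, match="informative"):
            d_statistic(ft, "A", "B", "C", "D")

    def test_distinct_populations_required(self):
        ft = make_table({p: np.linspace(0, 1, 10) for p in "ABCD"})
        with pytest.raises(ValueError):
            d_statistic(ft, "A", "A", "C", "D")


class TestF3:
    def test_single_site_arithmetic(self):
        ft = make_table({"T": np.array([0.5]), "R1": np.array([0.2]), "R2": np.array([0.8])})
        res = f3(ft, "T", "R1", "R2")
        assert res.estimate == pytest.approx((0.5 - 0.2) * (0.5 - 0.8))

    def test_test_equal_to_reference(self):
        rng = np.random.default_rng(5)
        t = rng.random(300)
        ft = make_table({"T": t, "R1": t.copy(), "R2": rng.random(300)})
        assert f3(ft, "T", "R1", "R2").estimate == pytest.approx(0.0)

    def test_fifty_fifty_mixture_is_negative(self):
        rng = np.random.default_rng(6)
        n = 100_000
        _, r1, r2 = drifted_pair(rng, n, fst=0.25)
        t = 0.5 * r1 + 0.5 * r2
        ft = make_table({"T": t, "R1": r1, "R2": r2}, sites_per_chrom=5000)
        res = f3(ft, "T", "R1", "R2")
        assert res.estimate < 0
        assert res.z < -3
        assert res.significant

    def test_empty_table_rejected(self):
        ft = make_table({"T": np.array([0.5]), "R1": np.array([0.1]), "R2": np.array([0.9])})
        ft.data = ft.data.iloc[:0]
        with pytest.raises(ValueError):
            f3(ft, "T", "R1", "R2")


class TestOutgroupF3:
    def test_shared_drift_ranking(self):
        rng = np.random.default_rng(7)
        n = 20_000
        anc = rng.beta(0.8, 0.8, size=n)
        stem = drift(rng, anc, 0.15)  # shared drift of A and Xn
        a = drift(rng, stem, 0.05)
        x_close = drift(rng, stem, 0.05)  # shares the stem drift with A
        x_far = drift(rng, anc, 0.3)  # only shares the root
        o = anc
        ft = make_table(
            {"O": o, "A": a, "Xc": a.copy(), "Xn": x_close, "Xf": x_far},
            sites_per_chrom=2000,
        )
        ranking = rank_outgroup_f3(ft, "O", "A", ["Xc", "Xn", "Xf"])
        assert [r.populations[2] for r in ranking] == ["Xc", "Xn", "Xf"]

    def test_constant_frequencies_give_zero(self):
        c = np.full(50, 0.4)
        ft = make_table({"O": c, "A": c.copy(), "X": c.copy()})
        assert outgroup_f3(ft, "O", "A", "X").estimate == pytest.approx(0.0)


class TestF4:
    def test_antisymmetries(self):
        rng = np.random.default_rng(8)
        ft = make_table({p: rng.random(1000) for p in "ABCD"})
        base = f4(ft, "A", "B", "C", "D").estimate
        assert f4(ft, "B", "A", "C", "D").estimate == pytest.approx(-base)
        assert f4(ft, "A", "B", "D", "C").estimate == pytest.approx(-base)

    def test_duplicated_population_zero(self):
        rng = np.random.default_rng(9)
        a = rng.random(500)
        ft = make_table({"A1": a, "A2": a.copy(), "C": rng.random(500), "D": rng.random(500)})
        assert f4(ft, "A1", "A2", "C", "D").estimate == pytest.approx(0.0)


class TestF4Ratio:
    def _mixture_table(self, alpha, n=50_000, seed=10):
        rng = np.random.default_rng(seed)
        anc = rng.beta(0.8, 0.8, size=n)
        fst = 0.2
        o = drift(rng, anc, fst)
        abc = drift(rng, anc, fst)
        c = drift(rng, abc, fst)
        ab = drift(rng, abc, fst)
        a = drift(rng, ab, fst)
        b = drift(rng, ab, fst)
        x = alpha * b + (1 - alpha) * c
        return make_table(
            {"A": a, "B": b, "C": c, "X": x, "O": o}, sites_per_chrom=2500
        )

    def test_pure_endpoints(self):
        ft1 = self._mixture_table(1.0)
        assert f4_ratio(ft1, "A", "O", "X", "B", "C").estimate == pytest.approx(1.0)
        ft0 = self._mixture_table(0.0)
        assert f4_ratio(ft0, "A", "O", "X", "B", "C").estimate == pytest.approx(0.0)

    def test_alpha_recovery(self):
        ft = self._mixture_table(0.04)
        res = f4_ratio(ft, "A", "O", "X", "B", "C")
        assert res.estimate == pytest.approx(0.04, abs=3 * res.se)
        assert res.extra["denominator_z"] > 1

    def test_uninformative_denominator_warns(self):
        rng = np.random.default_rng(1)
        # C is B plus pure noise, so the denominator f4 carries no signal
        b = rng.random(2000)
        ft = make_table(
            {"A": rng.random(2000), "O": rng.random(2000), "X": rng.random(2000),
             "B": b, "C": (b + rng.normal(0, 1e-3, 2000)).clip(0, 1)},
        )
        with pytest.warns(UserWarning, match="denominator"):
            f4_ratio(ft, "A", "O", "X", "B", "C")

    def test_zero_denominator_rejected(self):
        rng = np.random.default_rng(2)
        b = rng.random(500)
        ft = make_table(
            {"A": rng.random(500), "O": rng.random(500), "X": rng.random(500),
             "B": b, "C": b.copy()},
        )
        with pytest.raises(ValueError, match="denominator"):
            f4_ratio(ft, "A", "O", "X", "B", "C")


class TestBlockJackknife:
    def test_linear_statistic_equals_plain_mean(self):
        rng = np.random.default_rng(12)
        x = rng.normal(0.1, 1.0, size=1000)
        blocks = np.repeat(np.arange(10), 100)
        est, se, n_blocks, n_sites = block_jackknife_ratio(x, np.ones_like(x), blocks)
        assert est == pytest.approx(x.mean())
        assert n_blocks == 10 and n_sites == 1000
        assert se > 0

    def test_matches_explicit_leave_one_out_oracle(self):
        # independent re-implementation of the weighted jackknife on a
        # 10-block toy table with unequal block sizes
        rng = np.random.default_rng(13)
        sizes = rng.integers(20, 120, size=10)
        blocks = np.repeat(np.arange(10), sizes)
        num = rng.normal(0.05, 0.3, size=blocks.size)
        den = np.ones_like(num)
        est, se, G, _ = block_jackknife_ratio(num, den, blocks)

        n = blocks.size
        theta = num.sum() / n
        theta_minus = np.array(
            [num[blocks != j].sum() / (n - sizes[j]) for j in range(10)]
        )
        h = n / sizes
        theta_jack = 10 * theta - ((1 - sizes / n) * theta_minus).sum()
        pseudo = h * theta - (h - 1) * theta_minus
        var = ((pseudo - theta_jack) ** 2 / (h - 1)).sum() / 10
        assert est == pytest.approx(theta)
        assert se == pytest.approx(np.sqrt(var))

    def test_constant_blocks_give_zero_se(self):
        x = np.full(100, 0.25)
        blocks = np.repeat(np.arange(10), 10)
        est, se, _, _ = block_jackknife_ratio(x, np.ones_like(x), blocks)
        assert est == pytest.approx(0.25)
        assert se == pytest.approx(0.0, abs=1e-12)

    def test_null_z_calibration(self):
        # iid zero-mean sites: |Z| > 3 should be rare across replicates
        rng = np.random.default_rng(14)
        exceed = 0
        for _ in range(100):
            x = rng.normal(0.0, 1.0, size=2000)
            blocks = np.repeat(np.arange(20), 100)
            est, se, _, _ = block_jackknife_ratio(x, np.ones_like(x), blocks)
            exceed += abs(est / se) > 3
        assert exceed <= 2
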