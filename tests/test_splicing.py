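"""Intron x PAC cross-tables, control resampling and the rank-sum test."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import apakit as ak
from apakit.splicing import _rank_sum_u


def intron_frame(rows):
    return pd.DataFrame(
        rows,
        columns=["intron_id", "gene_id", "chrom", "strand", "start", "end",
                 "splice_class", "gene_class"],
    )


def pac_frame(rows):
    return pd.DataFrame(rows, columns=["chrom", "strand",
                                       "representative_position",
                                       "start", "end"])


class TestTableFromCounts:
    def test_published_style_cells_and_means(self):
        # printed intron totals and with-PAC counts reproduce the quoted
        # percentages: 12,031 of 134,708 constitutive coding introns = 8.93 %
        totals = pd.DataFrame(
            {"constitutive": [134708, 2550], "retained": [5151, 116]},
            index=["coding", "noncoding"],
        )
        withp = pd.DataFrame(
            {"constitutive": [12031, 153], "retained": [120, 5]},
            index=["coding", "noncoding"],
        )
        out = ak.table_from_counts(totals, withp)
        pct = out["pct"]
        assert pct.loc["coding", "constitutive"] == pytest.approx(8.93, abs=0.005)
        assert pct.loc["noncoding", "constitutive"] == pytest.approx(6.00, abs=0.005)
        assert pct.loc["coding", "retained"] == pytest.approx(2.33, abs=0.005)
        assert pct.loc["noncoding", "retained"] == pytest.approx(4.31, abs=0.005)
        means = out["means"]
        assert means["constitutive"] == pytest.approx(7.47, abs=0.005)
        assert means["retained"] == pytest.approx(3.32, abs=0.005)
        assert means["coding"] == pytest.approx(5.63, abs=0.005)
        assert means["noncoding"] == pytest.approx(5.16, abs=0.005)


class TestIntronPacTable:
    @pytest.fixture()
    def introns(self):
        rows = []
        for i in range(10):
            cls = "constitutive" if i < 8 else "retained"
            rows.append([f"i{i}", f"g{i}", "c", "+", 1000 * i + 100,
                         1000 * i + 400, cls, "coding"])
        return intron_frame(rows)

    def test_zero_pacs_all_zero(self, introns):
        out = ak.intron_pac_table(introns, pac_frame([]))
        assert (out["pct"].to_numpy() == 0).all()

    def test_counts_and_conservation(self, introns):
        # one PAC inside intron i0, one outside any intron
        pacs = pac_frame([["c", "+", 250, 245, 255], ["c", "+", 600, 595, 605]])
        out = ak.intron_pac_table(introns, pacs)
        assert out["with_pac"].loc["coding", "constitutive"] == 1
        flags = out["introns"]["contains_pac"]
        assert flags.sum() == 1
        # containing + non-containing = total per cell
        assert (out["totals"] - out["with_pac"] >= 0).all().all()

    def test_strictly_inside_and_strand_matched(self, introns):
        boundary = pac_frame([["c", "+", 100, 95, 105]])  # at the 5' edge
        out = ak.intron_pac_table(introns, boundary)
        assert out["introns"]["contains_pac"].sum() == 0
        antisense = pac_frame([["c", "-", 250, 245, 255]])
        out = ak.intron_pac_table(introns, antisense)
        assert out["introns"]["contains_pac"].sum() == 0

    def test_order_invariance(self, introns):
        pacs = pac_frame([["c", "+", 250, 245, 255], ["c", "+", 1200, 1195, 1205]])
        a = ak.intron_pac_table(introns, pacs)
        b = ak.intron_pac_table(
            introns.iloc[::-1].reset_index(drop=True), pacs.iloc[::-1]
        )
        assert a["with_pac"].equals(b["with_pac"])

    def test_multi_pac_intron_counts_once(self, introns):
        pacs = pac_frame([["c", "+", 200, 195, 205], ["c", "+", 300, 295, 305]])
        out = ak.intron_pac_table(introns, pacs)
        assert out["introns"]["contains_pac"].sum() == 1

    def test_pacs_only_in_constitutive_introns(self, introns):
        cons = introns.query("splice_class == 'constitutive'")
        pacs = pac_frame(
            [["c", "+", int((r.start + r.end) / 2), 0, 0]
             for r in cons.itertuples(index=False)]
        )
        out = ak.intron_pac_table(introns, pacs)
        assert (out["pct"]["retained"] == 0).all()
        assert out["means"]["constitutive"] > out["means"]["retained"]


class TestSampleControls:
    def test_pool_equals_n(self):
        pool = list(range(8))
        groups = ak.sample_controls(pool, 8, n_groups=2, seed=1)
        for g in groups:
            assert sorted(g) == pool

    def test_seeded_reproducibility(self):
        pool = list(range(1000))
        a = ak.sample_controls(pool, 100, seed=17)
        b = ak.sample_controls(pool, 100, seed=17)
        for x, y in zip(a, b):
            assert np.array_equal(x, y)

    def test_different_seeds_differ(self):
        pool = list(range(1000))
        a = ak.sample_controls(pool, 100, seed=1)
        b = ak.sample_controls(pool, 100, seed=2)
        assert not all(np.array_equal(x, y) for x, y in zip(a, b))

    def test_pool_too_small_errors(self):
        with pytest.raises(ValueError):
            ak.sample_controls(list(range(5)), 6)


def permutation_oracle(x, y):
    """Independent exhaustive two-sided rank-sum p-value."""
    pooled = list(x) + list(y)
    n1 = len(x)
    mu = n1 * len(y) / 2.0
    obs = abs(_rank_sum_u(x, y) - mu)
    hits = total = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        chosen = set(combo)
        xs = [pooled[i] for i in combo]
        ys = [pooled[i] for i in range(len(pooled)) if i not in chosen]
        total += 1
        if abs(_rank_sum_u(xs, ys) - mu) >= obs - 1e-12:
            hits += 1
    return hits / total


class TestRankSum:
    def test_identical_multisets_p_one(self):
        assert ak.rank_sum_test([1, 2, 3, 4], [1, 2, 3, 4]) == pytest.approx(1.0)

    def test_strong_shift_significant_at_n50(self):
        rng = np.random.default_rng(0)
        y = rng.uniform(10, 20, size=50)
        x = 10 * y
        assert ak.rank_sum_test(list(x), list(y)) < 0.01

    def test_matches_permutation_oracle_small_n(self):
        rng = np.random.default_rng(4)
        for _ in range(25):
            n1 = int(rng.integers(2, 7))
            n2 = int(rng.integers(2, 7))
            x = rng.integers(0, 6, size=n1).tolist()  # ties likely
            y = rng.integers(0, 6, size=n2).tolist()
            assert ak.rank_sum_test(x, y) == pytest.approx(
                permutation_oracle(x, y), abs=1e-12
            )

    def test_agrees_with_scipy_exact_no_ties(self):
        rng = np.random.default_rng(5)
        for _ in range(15):
            n1 = int(rng.integers(3, 8))
            n2 = int(rng.integers(3, 8))
            vals = rng.permutation(100)[: n1 + n2]
            x, y = vals[:n1].tolist(), vals[n1:].tolist()
            expected = stats.mannwhitneyu(x, y, alternative="two-sided",
                                          method="exact").pvalue
            assert ak.rank_sum_test(x, y) == pytest.approx(expected, abs=1e-9)


class TestLengthComparison:
    def test_toy_statistics_exact(self):
        cmp = ak.length_comparison([10, 20, 30], [[10, 20, 30], [5, 15, 25]])
        assert cmp.with_mean == 20 and cmp.with_median == 20
        assert cmp.control_means == [20, 15]
        assert cmp.pvalues[0] == pytest.approx(1.0)

    def test_control_sizes_must_match_use(self):
        with pytest.raises(ValueError):
            ak.length_comparison([], [[1.0]])

    def test_synthetic_intron_lengths(self, sim_ngs, pipeline_ngs):
        _, _, _, truth, _, _ = sim_ngs
        introns = truth.introns
        pacs = pipeline_ngs.pac_table.rename(
            columns={"representative_position": "representative_position"}
        )
        out = ak.intron_pac_table(introns, pacs)
        flagged = out["introns"]
        with_pac = flagged.query("contains_pac")
        without = flagged.query("~contains_pac")
        if len(with_pac) >= 2 and len(without) >= len(with_pac):
            controls = ak.sample_controls(without, len(with_pac), seed=7)
            cmp = ak.length_comparison(
                (with_pac["end"] - with_pac["start"] + 1).tolist(),
                [(g["end"] - g["start"] + 1).tolist() for g in controls],
            )
            assert cmp.n == len(with_pac)
            assert all(0.0 <= p <= 1.0 for p in cmp.pvalues)
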