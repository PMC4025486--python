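"""K-mer scanning modes, profiles, Markov backgrounds and Z-scores."""

import math

import numpy as np
import pytest

import apakit as ak
from apakit.signals import _greedy_count


def naive_counts(sequences, spec):
    """Independent quadratic scanner used as the oracle for all modes."""
    counts = {}
    for seq in sequences:
        seq = seq.upper()
        lo, hi = spec.window_indices(len(seq))
        occ = {}
        for s in range(lo, hi - spec.k + 1):
            kmer = seq[s : s + spec.k]
            if "N" not in kmer:
                occ.setdefault(kmer, []).append(s)
        for kmer, starts in occ.items():
            if spec.mode == "overlapping":
                n = len(starts)
            elif spec.mode == "distribution":
                n, prev = 0, None
                for s in starts:
                    if prev is None or s >= prev + spec.k + spec.gap:
                        n += 1
                        prev = s
            else:  # frequency
                n = 1
            counts[kmer] = counts.get(kmer, 0) + n
    return counts


def random_flanks(n, rng, length=150):
    bases = np.array(list("ACGT"))
    return ["".join(bases[rng.integers(0, 4, size=length)]) for _ in range(n)]


class TestScanModes:
    def test_distribution_mode_worked_example(self):
        # in ATATATAT with gap=2, ATATAT and TATATA each count once
        spec = ak.ScanSpec(k=6, window=None, mode="distribution", gap=2)
        table = ak.scan_kmers(["ATATATAT"], spec)
        assert table.loc["AUAUAU", "count"] == 1
        assert table.loc["UAUAUA", "count"] == 1

    def test_overlapping_mode_counts_both_starts(self):
        spec = ak.ScanSpec(k=6, window=None, mode="overlapping")
        table = ak.scan_kmers(["ATATATAT"], spec)
        assert table.loc["AUAUAU", "count"] == 2

    def test_gap_zero_is_adjacent_nonoverlapping(self):
        spec = ak.ScanSpec(k=2, window=None, mode="distribution", gap=0)
        table = ak.scan_kmers(["AAAAAA"], spec)
        assert table.loc["AA", "count"] == 3

    def test_frequency_mode_counts_once_closest_to_site(self):
        # UGUAA at labels -25..-21 and -10..-6; one count, at the 3' one
        seq = list("G" * 150)
        for offset, base in zip(range(-25, -20), "TGTAA"):
            seq[100 + offset] = base
        for offset, base in zip(range(-10, -5), "TGTAA"):
            seq[100 + offset] = base
        flank = "".join(seq)
        spec = ak.ScanSpec(k=5, window=(-28, -5), mode="frequency")
        table = ak.scan_kmers([flank], spec)
        assert table.loc["UGUAA", "count"] == 1
        pssm = ak.motif_pssm([flank], "UGUAA", spec)
        assert pssm.loc[-10, "count"] == 1
        assert pssm.loc[-25, "count"] == 0

    def test_mode_monotonicity(self):
        rng = np.random.default_rng(3)
        seqs = random_flanks(40, rng)
        counts = {}
        for mode in ("overlapping", "distribution", "frequency"):
            spec = ak.ScanSpec(k=3, window=(-60, -5), mode=mode, gap=1)
            counts[mode] = ak.scan_kmers(seqs, spec, all_kmers=True)["count"]
        assert (counts["overlapping"] >= counts["distribution"]).all()
        assert (counts["distribution"] >= counts["frequency"]).all()

    def test_overlapping_total_is_conserved(self):
        rng = np.random.default_rng(4)
        seqs = random_flanks(25, rng)
        spec = ak.ScanSpec(k=5, window=(-28, -5), mode="overlapping")
        table = ak.scan_kmers(seqs, spec)
        assert table["count"].sum() == table.attrs["n_positions"]
        assert table.attrs["n_positions"] == 25 * (24 - 5 + 1)

    @pytest.mark.parametrize("mode, gap", [("overlapping", 0),
                                           ("distribution", 2),
                                           ("frequency", 0)])
    def test_matches_naive_scanner(self, mode, gap):
        rng = np.random.default_rng(9)
        # biased composition creates repeats that stress the greedy rule
        bases = np.array(list("AATC"))
        seqs = ["".join(bases[rng.integers(0, 4, size=150)]) for _ in range(60)]
        spec = ak.ScanSpec(k=4, window=(-80, 20), mode=mode, gap=gap)
        table = ak.scan_kmers(seqs, spec)
        expected = naive_counts(seqs, spec)
        for kmer, n in expected.items():
            assert table.loc[kmer.replace("T", "U"), "count"] == n
        assert int(table["count"].sum()) == sum(expected.values())

    def test_n_windows_skipped(self):
        spec = ak.ScanSpec(k=3, window=None, mode="overlapping")
        table = ak.scan_kmers(["AANAA"], spec)
        assert table["count"].sum() == 0 or "N" not in "".join(table.index)
        assert table.attrs["n_positions"] == 0

    def test_k_larger_than_window_errors(self):
        with pytest.raises(ValueError):
            ak.ScanSpec(k=30, window=(-28, -5))


class TestGreedy:
    def test_respects_gap_spacing(self):
        # matches at 0, 3, 6, 9 with k=3, gap=1: picks 0, 6
        assert _greedy_count([0, 3, 6, 9], k=3, gap=1) == [0, 6]


class TestNucleotideProfile:
    def test_uniform_a(self):
        prof = ak.nucleotide_profile(["A" * 150] * 3)
        assert (prof["A"] == 1.0).all()
        assert (prof[["C", "G", "U"]] == 0.0).all().all()

    def test_rows_normalized(self):
        rng = np.random.default_rng(6)
        prof = ak.nucleotide_profile(random_flanks(30, rng))
        assert np.allclose(prof.sum(axis=1), 1.0, atol=1e-9)

    def test_planted_motif_peak(self, sim_ngs, pipeline_ngs):
        utr3 = set(
            pipeline_ngs.assignments.query("region == 'UTR3'")["pac_id"]
        )
        flanks = [f.sequence for f in pipeline_ngs.flanks if f.pac_id in utr3]
        prof = ak.nucleotide_profile(flanks)
        # UGUAA planted at -22..-18 of the true site; representatives sit
        # within 1 nt of it, so the U-peak spreads over -23..-21
        peak = prof.loc[-23:-21, "U"].max()
        background = prof.loc[-100:-40, "U"].mean()
        assert peak > 0.45
        assert peak > 2 * background

    def test_unequal_lengths_error(self):
        with pytest.raises(ValueError):
            ak.nucleotide_profile(["AAA", "AAAA"])


class TestMotifPssm:
    def test_absent_motif_all_zero(self):
        spec = ak.ScanSpec(k=5, window=(-28, -5), mode="overlapping")
        pssm = ak.motif_pssm(["G" * 150] * 4, "UGUAA", spec)
        assert (pssm["count"] == 0).all() and (pssm["frequency"] == 0).all()

    def test_planted_motif_unit_mass(self):
        seq = list("G" * 150)
        for offset, base in zip(range(-22, -17), "TGTAA"):
            seq[100 + offset] = base
        flanks = ["".join(seq)] * 5
        spec = ak.ScanSpec(k=5, window=(-28, -5), mode="overlapping")
        pssm = ak.motif_pssm(flanks, "UGUAA", spec)
        assert pssm.loc[-22, "frequency"] == 1.0
        assert pssm["count"].sum() == 5


class TestMarkov:
    def test_order0_equal_composition_closed_form(self):
        # equal base counts survive add-one smoothing exactly
        bg = ak.train_markov(["ACGT" * 100], order=0)
        assert bg.motif_probability("UGUAA") == pytest.approx(0.25**5)

    def test_order1_periodic_sequence(self):
        bg = ak.train_markov(["AC" * 3000], order=1)
        # A->C and C->A transitions dominate; smoothing keeps them < 1
        assert bg.transition("A", "C") > 0.99
        assert bg.transition("C", "A") > 0.99
        assert bg.motif_probability("UGUAA") < 1e-6
        assert bg.motif_probability("UGUAA") > 0.0

    def test_smoothing_never_zero(self):
        bg = ak.train_markov(["ACGT" * 50], order=2)
        assert bg.motif_probability("GGGGG") > 0.0

    def test_order_not_below_motif_length(self):
        with pytest.warns(UserWarning):  # 200 nt is sparse for order 3
            bg = ak.train_markov(["ACGT" * 50], order=3)
        with pytest.raises(ValueError):
            bg.motif_probability("ACG")


class TestZScore:
    def test_observed_equals_expected_is_zero(self):
        bg = ak.train_markov(["ACGT" * 100], order=0)
        expected = 1000 * 0.25**5
        z, e = ak.motif_zscore(expected, "AAAAA", bg, 1000)
        assert z == pytest.approx(0.0)
        assert e == pytest.approx(expected)

    def test_monotone_in_observed(self):
        bg = ak.train_markov(["ACGT" * 100], order=0)
        zs = [ak.motif_zscore(obs, "AAAAA", bg, 1000)[0] for obs in (1, 5, 20)]
        assert zs[0] < zs[1] < zs[2]

    def test_score_motifs_adds_columns(self):
        rng = np.random.default_rng(2)
        seqs = random_flanks(30, rng)
        spec = ak.ScanSpec(k=5, window=(-28, -5), mode="overlapping")
        table = ak.scan_kmers(seqs, spec)
        bg = ak.train_markov(seqs, order=0)
        scored = ak.score_motifs(table, bg)
        assert {"expected", "zscore"} <= set(scored.columns)
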