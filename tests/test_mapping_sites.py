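"""Read placement, site calling, internal-priming filter, aggregation."""

import numpy as np
import pytest

from apakit import (
    Alignment,
    GenomeIndex,
    SiteCandidate,
    TailParams,
    aggregate_unique_sites,
    call_site,
    internal_priming_filter,
    map_read,
    revcomp,
)

NGS = TailParams.for_mode("NGS")


@pytest.fixture(scope="module")
def genome():
    rng = np.random.default_rng(7)
    bases = np.array(list("ACGT"))
    seq = "".join(bases[rng.integers(0, 4, size=600)])
    return {"chrX": seq}


@pytest.fixture(scope="module")
def index(genome):
    return GenomeIndex(genome)


class TestMapRead:
    def test_plus_strand_identity(self, genome, index):
        body = genome["chrX"][100:140]
        aln = map_read(body, index)
        assert aln is not None
        assert (aln.chrom, aln.strand, aln.start, aln.end) == ("chrX", "+", 101, 140)
        assert aln.three_prime_end == 140

    def test_minus_strand_identity(self, genome, index):
        body = revcomp(genome["chrX"][200:240])
        aln = map_read(body, index)
        assert aln is not None
        assert (aln.chrom, aln.strand, aln.start, aln.end) == ("chrX", "-", 201, 240)
        assert aln.three_prime_end == 201

    def test_ambiguous_body_unmapped(self, genome):
        dup = genome["chrX"][:80] + genome["chrX"]
        idx = GenomeIndex({"chrX": dup})
        body = dup[10:40]  # present twice
        assert map_read(body, idx) is None

    def test_nontemplated_offset_recovered(self, genome, index):
        body = genome["chrX"][100:140] + "GC"  # 2 nontemplated bases
        aln = map_read(body, index)
        assert aln is not None
        assert aln.nontemplated_count == 2
        assert aln.end == 140

    def test_too_short_body_unmapped(self, genome, index):
        assert map_read(genome["chrX"][100:115], index) is None


class TestCallSite:
    def test_non_a_end_keeps_position(self):
        genome = {"c": "G" * 50 + "CG" + "G" * 50}
        aln = Alignment("c", "+", 21, 52)
        cand, reason = call_site(aln, genome, NGS)
        assert reason is None and cand.position == 52

    def test_trailing_genomic_a_reassigned(self):
        # aligned end ...C,A,A,A -> site moves 3 nt upstream to the C
        genome = {"c": "G" * 48 + "CAAA" + "G" * 50}
        aln = Alignment("c", "+", 21, 52)
        cand, reason = call_site(aln, genome, NGS)
        assert reason is None and cand.position == 49

    def test_five_trailing_a_rejected(self):
        genome = {"c": "G" * 47 + "CAAAAA" + "G" * 50}
        aln = Alignment("c", "+", 21, 53)
        cand, reason = call_site(aln, genome, NGS)
        assert cand is None and reason == "genomic_a_run"

    def test_minus_strand_reassignment(self):
        # sense-strand trailing A == plus-strand leading T at the start
        genome = {"c": "G" * 20 + "TTG" + "G" * 50}
        aln = Alignment("c", "-", 21, 52)
        cand, reason = call_site(aln, genome, NGS)
        assert reason is None and cand.position == 23
        assert cand.strand == "-"

    def test_contig_edge_rejected(self):
        genome = {"c": "G" * 52}
        aln = Alignment("c", "+", 21, 52)
        cand, reason = call_site(aln, genome, NGS)
        assert cand is None and reason == "contig_edge"


def oracle_filter(window, run_threshold=6, count_threshold=7, size=10):
    """Independent check: explicit run scan + all 10-nt subwindows."""
    run = 0
    for b in window:
        run = run + 1 if b == "A" else 0
        if run >= run_threshold:
            return False
    for i in range(len(window) - size + 1):
        if window[i : i + size].count("A") >= count_threshold:
            return False
    return True


class TestInternalPrimingFilter:
    def test_saturated_a_window_dropped(self):
        genome = {"c": "G" * 30 + "A" * 21 + "G" * 30}
        keep, reason = internal_priming_filter(genome, "c", "+", 41)
        assert not keep and reason == "ip_a_run"

    def test_a_free_window_kept(self):
        genome = {"c": "G" * 100}
        keep, reason = internal_priming_filter(genome, "c", "+", 50)
        assert keep and reason is None

    def test_exact_run_downstream_dropped(self):
        # AAAAAA at +1..+6, no other A in the -10..+10 window
        genome = {"c": "G" * 50 + "AAAAAA" + "G" * 50}
        keep, reason = internal_priming_filter(genome, "c", "+", 50)
        assert not keep and reason == "ip_a_run"

    def test_dispersed_a_rich_window_dropped(self):
        # 7 A in one 10-nt stretch without any 6-run
        genome = {"c": "G" * 50 + "AAAGAAAGAA" + "G" * 50}
        keep, reason = internal_priming_filter(genome, "c", "+", 55)
        assert not keep and reason == "ip_a_rich_window"

    def test_minus_strand_uses_sense_bases(self):
        # plus-strand T-run = sense-strand A-run for a minus-strand site
        genome = {"c": "G" * 50 + "TTTTTT" + "G" * 50}
        keep, _ = internal_priming_filter(genome, "c", "-", 50)
        assert not keep
        keep, _ = internal_priming_filter(genome, "c", "+", 50)
        assert keep

    def test_matches_sliding_window_oracle(self):
        rng = np.random.default_rng(12)
        bases = np.array(list("ACGT"))
        for _ in range(300):
            seq = "".join(bases[rng.integers(0, 4, size=60)])
            genome = {"c": seq}
            pos = int(rng.integers(12, 49))
            keep, _ = internal_priming_filter(genome, "c", "+", pos)
            window = seq[pos - 11 : pos + 10]
            assert keep == oracle_filter(window)

    def test_every_survivor_is_a_run_free(self, pipeline_ngs, sim_ngs):
        _, genome, *_ = sim_ngs
        seq = genome["chr1"]
        for r in pipeline_ngs.sites.itertuples(index=False):
            lo = max(0, r.position - 11)
            window = seq[lo : r.position + 10]
            if r.strand == "-":
                window = revcomp(window)
            assert "A" * 6 not in window


class TestAggregate:
    def test_identical_coordinates_merge(self):
        cands = [SiteCandidate("c", "+", 100, "est"),
                 SiteCandidate("c", "+", 100, "ngs")]
        out = aggregate_unique_sites(cands)
        assert len(out) == 1
        assert out.loc[0, "support"] == 2
        assert out.loc[0, "n_est"] == 1 and out.loc[0, "n_ngs"] == 1

    def test_opposite_strands_stay_separate(self):
        cands = [SiteCandidate("c", "+", 100), SiteCandidate("c", "-", 100)]
        assert len(aggregate_unique_sites(cands)) == 2

    def test_empty_input(self):
        out = aggregate_unique_sites([])
        assert out.empty and "support" in out.columns

    def test_sorted_by_coordinate(self):
        cands = [SiteCandidate("c", "+", p) for p in (300, 100, 200)]
        out = aggregate_unique_sites(cands)
        assert out["position"].tolist() == [100, 200, 300]
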