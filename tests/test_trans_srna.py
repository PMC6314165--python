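"""Exact-match search, artsRNA decomposition, AGO scoring, library
matching, TE proximity, screen criteria and report ordering."""

import numpy as np
import pandas as pd
import pytest

from epirilqtl import mapping, synthetic_data as sd, trans_srna as ts
from epirilqtl.io_core import (
    ArtsRNACandidate,
    GeneModel,
    SRNALibrary,
    revcomp,
)
from conftest import planted_trait


# ---------------------------------------------------------------------------
# brute-force oracle for maximal exact matches
# ---------------------------------------------------------------------------

def oracle_matches(a: str, b: str, k: int):
    """All maximal exact matches >= k by per-diagonal run scanning."""
    out = set()
    na, nb = len(a), len(b)
    av = np.frombuffer(a.encode(), np.uint8)
    bv = np.frombuffer(b.encode(), np.uint8)
    for d in range(-(na - 1), nb):
        i0 = max(0, -d)
        j0 = i0 + d
        L = min(na - i0, nb - j0)
        if L < k:
            continue
        eq = (av[i0:i0 + L] == bv[j0:j0 + L]) & (av[i0:i0 + L] != ord("N"))
        run = 0
        for t in range(L + 1):
            if t < L and eq[t]:
                run += 1
            else:
                if run >= k:
                    out.add((i0 + t - run, j0 + t - run, run))
                run = 0
    return out


def segs_to_set(segs, strand):
    return {(s.promoter_start, s.qtl_start, s.length)
            for s in segs if s.strand == strand}


class TestFindMatchSegments:
    def test_identical_sequences(self):
        rng = np.random.default_rng(1)
        seq = "".join(rng.choice(list("ACGT"), 40))
        segs = ts.find_match_segments(seq, seq, min_match=21)
        plus = [s for s in segs if s.strand == "+"]
        full = [s for s in plus if s.length == 40]
        assert len(full) == 1
        assert full[0].promoter_start == 0 and full[0].qtl_start == 0

    def test_no_shared_21mer_empty(self):
        a = "AC" * 50  # ACAC...
        b = "AG" * 50  # AGAG...; revcomp is CTCT...
        assert ts.find_match_segments(a, b) == []
        # brute-force 21-mer intersection confirms, both orientations
        ka = {a[i:i + 21] for i in range(len(a) - 20)}
        for s in (b, revcomp(b)):
            kb = {s[i:i + 21] for i in range(len(s) - 20)}
            assert not (ka & kb)

    def test_reverse_complement_insert(self):
        rng = np.random.default_rng(2)
        insert = "".join(rng.choice(list("ACGT"), 30))
        prom = "".join(rng.choice(list("ACGT"), 80)) + insert \
            + "".join(rng.choice(list("ACGT"), 80))
        qtl = "".join(rng.choice(list("ACGT"), 60)) + revcomp(insert) \
            + "".join(rng.choice(list("ACGT"), 60))
        segs = ts.find_match_segments(prom, qtl, min_match=21)
        minus = [s for s in segs if s.strand == "-" and s.length >= 30]
        assert len(minus) == 1
        s = minus[0]
        assert insert in s.sequence
        assert revcomp(s.sequence) == qtl[s.qtl_start:s.qtl_end]

    def test_agrees_with_bruteforce_oracle(self):
        rng = np.random.default_rng(3)
        for trial in range(60):
            na, nb = rng.integers(21, 200, 2)
            # small alphabet pressure so matches actually occur
            a = "".join(rng.choice(list("ACGT"), na))
            b_parts = [a[i:i + int(rng.integers(21, 40))]
                       for i in rng.integers(0, max(1, na - 40), 2)]
            b = "".join(rng.choice(list("ACGT"), nb)) + "".join(b_parts)
            segs = ts.find_match_segments(a, b, min_match=21)
            assert segs_to_set(segs, "+") == oracle_matches(a, b, 21)
            rc = oracle_matches(a, revcomp(b), 21)
            rc_mapped = {(s, len(b) - t - L, L) for s, t, L in rc}
            assert segs_to_set(segs, "-") == rc_mapped

    def test_revcomp_both_inputs_invariance(self):
        rng = np.random.default_rng(4)
        a = "".join(rng.choice(list("ACGT"), 80))
        b = a[10:45] + "".join(rng.choice(list("ACGT"), 60))
        fwd = ts.find_match_segments(a, b)
        rev = ts.find_match_segments(revcomp(a), revcomp(b))
        assert {(s.length, s.strand) for s in fwd} == \
            {(s.length, s.strand) for s in rev}

    def test_min_match_floor(self):
        with pytest.raises(ValueError):
            ts.find_match_segments("A" * 30, "A" * 30, min_match=20)


def make_segment(seq, segment_id="seg1", gene_id="g"):
    return ts.MatchSegment(segment_id=segment_id, gene_id=gene_id,
                           promoter_start=0, promoter_end=len(seq),
                           qtl_start=0, qtl_end=len(seq), strand="+",
                           sequence=seq)


class TestDecompose:
    @pytest.mark.parametrize("L,expected", [(20, 0), (21, 2), (24, 20),
                                            (30, 68)])
    def test_counts(self, L, expected):
        rng = np.random.default_rng(5)
        seg = make_segment("".join(rng.choice(list("ACGT"), L)))
        cands = ts.decompose_artsrnas(seg)
        assert len(cands) == expected

    def test_counts_match_closed_form_all_lengths(self):
        rng = np.random.default_rng(6)
        for L in range(20, 61):
            seg = make_segment("".join(rng.choice(list("ACGT"), L)))
            expected = sum(2 * (L - k + 1) for k in (21, 22, 23, 24) if k <= L)
            assert len(ts.decompose_artsrnas(seg)) == expected

    def test_both_strands_present(self):
        seg = make_segment("A" * 21 + "C" * 3)
        strands = {c.strand for c in ts.decompose_artsrnas(seg)}
        assert strands == {"+", "-"}


class TestAgoScoring:
    def test_default_rules(self):
        scorer = ts.DefaultAgoScorer()
        assert scorer.score("A" + "C" * 23)["AGO4"] == 0.9  # 24 nt, 5' A
        s21 = scorer.score("T" + "G" * 20)
        assert s21["AGO4"] == 0.1 and s21["AGO6"] == 0.4
        assert scorer.score("G" * 23)["AGO4"] == 0.2

    def test_filter_at_default_cutoff(self):
        cands = [ArtsRNACandidate("A" + "C" * 23, "+", "s", 0),
                 ArtsRNACandidate("T" + "G" * 20, "+", "s", 0)]
        kept = ts.score_ago_loading(cands)
        assert [c.sequence[0] for c in kept] == ["A"]
        # scores retained on the filtered-out candidate object too
        assert cands[1].ago_scores["AGO6"] == 0.4

    def test_constant_scorer_keeps_all(self):
        class One:
            def score(self, seq):
                return {"AGO4": 1.0, "AGO6": 1.0, "AGO9": 1.0}
        cands = [ArtsRNACandidate("G" * 21, "+", "s", 0)]
        assert len(ts.score_ago_loading(cands, scorer=One())) == 1

    def test_out_of_range_scores_rejected(self):
        class Bad:
            def score(self, seq):
                return {"AGO4": 1.5, "AGO6": 0.0, "AGO9": 0.0}
        with pytest.raises(ValueError, match="outside"):
            ts.score_ago_loading([ArtsRNACandidate("G" * 21, "+", "s", 0)],
                                 scorer=Bad())


class TestLibraryMatching:
    def lib(self, source, rows):
        return SRNALibrary(source, pd.DataFrame(rows, columns=["sequence", "count"]))

    def test_counts_summed(self):
        seq = "A" * 24
        wt = self.lib("WT", [(seq, 100), (seq, 42)])
        cands = [ArtsRNACandidate(seq, "+", "s", 0)]
        out = ts.match_srna_library(cands, [wt])
        assert out[0].library_hits["WT"] == 142

    def test_antisense_counts(self):
        seq = "AAGT" * 6
        wt = self.lib("WT", [(revcomp(seq), 7)])
        out = ts.match_srna_library([ArtsRNACandidate(seq, "+", "s", 0)], [wt])
        assert out[0].library_hits["WT"] == 7

    def test_palindromic_candidate_not_double_counted(self):
        seq = "ACGT" * 6  # its own reverse complement
        wt = self.lib("WT", [(seq, 7)])
        out = ts.match_srna_library([ArtsRNACandidate(seq, "+", "s", 0)], [wt])
        assert out[0].library_hits["WT"] == 7

    def test_absent_zero(self):
        wt = self.lib("WT", [("G" * 24, 5)])
        out = ts.match_srna_library([ArtsRNACandidate("A" * 24, "+", "s", 0)], [wt])
        assert out[0].library_hits["WT"] == 0

    def test_depletion_fixture_ratio(self):
        seq = "AT" * 12
        wt = self.lib("WT", [(seq, 100)])
        dd = self.lib("ddm1", [(seq, 10)])
        out = ts.match_srna_library([ArtsRNACandidate(seq, "+", "s", 0)], [wt, dd])
        assert out[0].library_hits["WT"] / out[0].library_hits["ddm1"] == 10

    def test_mismatch_limits(self):
        seq = "A" * 24
        near = "A" * 23 + "C"
        wt = self.lib("WT", [(near, 3)])
        c = [ArtsRNACandidate(seq, "+", "s", 0)]
        assert ts.match_srna_library(c, [wt], max_mismatch=0)[0].library_hits["WT"] == 0
        assert ts.match_srna_library(c, [wt], max_mismatch=1)[0].library_hits["WT"] == 3
        with pytest.raises(ValueError):
            ts.match_srna_library(c, [wt], max_mismatch=3)


class TestTeProximity:
    def setup_gene(self, te_start, te_end):
        return GeneModel(gene_id="g", chrom="chr1", strand="+", tss=10_000,
                         promoter=(9000, 10_000), gene_body=(10_000, 11_000),
                         downstream_1kb=(11_000, 12_000),
                         te_features=[((te_start, te_end), "LTR")])

    def candidate_at(self, offset=0):
        seg = ts.MatchSegment("s1", "g", promoter_start=100, promoter_end=130,
                              qtl_start=0, qtl_end=30, strand="+", sequence="A" * 30)
        c = ArtsRNACandidate("A" * 24, "+", "s1", offset)
        return c, {"s1": seg}

    def test_inside_te(self):
        # candidate genomic interval: 9000+100 .. +24
        c, segs = self.candidate_at()
        g = self.setup_gene(9000, 9200)
        assert ts.annotate_te_proximity([c], segs, {"g": g})[0].te_within_1kb

    def test_strict_1000_boundary(self):
        c, segs = self.candidate_at()
        # candidate ends at 9124; TE starting at 10123 -> gap 999 -> true
        g999 = self.setup_gene(10_123, 10_200)
        assert ts.annotate_te_proximity([c], segs, {"g": g999})[0].te_within_1kb
        # gap exactly 1000 -> false
        g1000 = self.setup_gene(10_124, 10_200)
        assert not ts.annotate_te_proximity([c], segs, {"g": g1000})[0].te_within_1kb

    def test_no_tes_false(self):
        c, segs = self.candidate_at()
        g = GeneModel(gene_id="g", chrom="chr1", strand="+", tss=10_000,
                      promoter=(9000, 10_000), gene_body=(10_000, 11_000),
                      downstream_1kb=(11_000, 12_000))
        assert not ts.annotate_te_proximity([c], segs, {"g": g})[0].te_within_1kb


@pytest.fixture(scope="module")
def screen_setup():
    cfg = sd.SimulationConfig(
        n_lines=200, seed=31,
        trans_targets=[sd.TransTarget("MM010", "T001", 30)],
        n_decoy_genes=5)
    epi = sd.simulate_epigenotypes(cfg, seed=31)
    scanpos = mapping.genotype_probabilities(epi, step_cM=2.0)
    trait = planted_trait(epi, "MM010", 0.4, seed=32, trait_id="t")
    scan = mapping.call_peaks(mapping.hk_scan(trait, scanpos, epi),
                              threshold=3.0)
    sim = sd.simulate_sequences(cfg, seed=33)
    regions = sd.probe_regions_from_gene_table(sim.gene_table)
    probes, parents = sd.simulate_gene_probes(epi, regions, seed=34)
    genes = []
    for _, r in sim.gene_table.iterrows():
        start = int(r["promoter_start"])
        genes.append(GeneModel(
            gene_id=r["gene_id"], chrom=r["chrom"], strand="+",
            tss=start + 1000, promoter=(start, start + 1000),
            gene_body=(start + 1000, start + 2000),
            downstream_1kb=(start + 2000, start + 3000)))
    return epi, genes, probes, parents, [scan]


class TestScreen:
    def test_planted_target_passes(self, screen_setup):
        epi, genes, probes, parents, scans = screen_setup
        hits = ts.screen_trans_genes(probes, genes, epi, scans, parents)
        assert {h.gene_id for h in hits} == {"T001"}
        assert len(hits[0].probe_run) == 2

    def test_gene_inside_interval_fails_criterion5(self, screen_setup):
        epi, genes, probes, parents, scans = screen_setup
        peak = scans[0].peaks[0]
        from epirilqtl.cis_candidates import cm_to_bp
        lo = cm_to_bp(epi.markers, peak.chrom, peak.ci_lo)
        inside = GeneModel(
            gene_id="T001", chrom=peak.chrom, strand="+", tss=int(lo) + 1000,
            promoter=(int(lo), int(lo) + 1000),
            gene_body=(int(lo) + 1000, int(lo) + 2000),
            downstream_1kb=(int(lo) + 2000, int(lo) + 3000))
        # same probes would pass, but location inside the interval kills it
        moved = probes.probes.copy()
        t_mask = moved["probe_id"].str.startswith("T001")
        moved.loc[t_mask, "start"] = [int(lo) + 100, int(lo) + 400, int(lo) + 700]
        moved.loc[t_mask, "end"] = moved.loc[t_mask, "start"] + 60
        moved.loc[t_mask, "chrom"] = peak.chrom
        from epirilqtl.io_core import ProbeMethylation
        probes_moved = ProbeMethylation(probes=moved, post_m=probes.post_m)
        hits = ts.screen_trans_genes(probes_moved, [inside], epi, scans, parents)
        assert hits == []

    def test_zero_variance_fails_criterion2(self, screen_setup):
        epi, genes, probes, parents, scans = screen_setup
        regions = pd.DataFrame({
            "region_id": ["T001"], "chrom": [genes[0].chrom],
            "start": [genes[0].promoter[0]], "end": [genes[0].promoter[1]],
            "driver_marker": [""]})
        flat, flat_parents = sd.simulate_gene_probes(epi, regions, noise_sd=0.0,
                                                     seed=35)
        # force parents polymorphic so only criterion 2 can fail
        flat_parents["ddm1"] = 0.0
        hits = ts.screen_trans_genes(flat, genes[:1], epi, scans, flat_parents)
        assert hits == []


def test_trans_report_ordering():
    hits = [ts.ScreenHit("gA", "t", "chr1", 0, 10, "MM001"),
            ts.ScreenHit("gB", "t", "chr1", 0, 10, "MM001")]
    seg = make_segment("A" * 30, "s1", "gA")
    cand = ArtsRNACandidate("A" * 24, "+", "s1", 0,
                            ago_scores={"AGO4": 0.9, "AGO6": 0.2, "AGO9": 0.2},
                            library_hits={"WT": 50, "ddm1": 5},
                            te_within_1kb=True)
    report = ts.trans_report(hits, {"gA": [seg]}, {"gA": [cand], "gB": []},
                             {"gA": True})
    assert report["gene_id"].tolist() == ["gA", "gB"]
    assert report.loc[0, "wt_ddm1_ratio"] == pytest.approx(10.0)
    empty = ts.trans_report([], {}, {}, {})
    assert len(empty) == 0
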