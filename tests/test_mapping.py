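"""Interval-mapping engine: genotype probabilities, Haley-Knott LOD,
permutation thresholds, cofactor selection, peaks, pleiotropy."""

import numpy as np
import pandas as pd
import pytest

from epirilqtl import mapping
from epirilqtl.io_core import (
    CALL_COL,
    CALL_DDM1,
    EpigenotypeMap,
    MarkerMap,
    QtlPeak,
    QtlScanResult,
    TraitVector,
)
from conftest import planted_trait


def tiny_epi(calls: dict[str, list[str]], pos=(0.0, 10.0)) -> EpigenotypeMap:
    markers = MarkerMap(pd.DataFrame({
        "marker_id": list(calls), "chrom": ["chr1"] * len(calls),
        "pos_cM": list(pos),
        "phys_start": [i * 10000 for i in range(len(calls))],
        "phys_end": [i * 10000 + 100 for i in range(len(calls))]}))
    n = len(next(iter(calls.values())))
    df = pd.DataFrame(calls, index=[f"L{i}" for i in range(n)])
    return EpigenotypeMap(markers=markers, calls=df)


class TestGenotypeProbabilities:
    def test_observed_marker_exact(self, epi, scanpos):
        j = scanpos.marker_column("MM001")
        coded = epi.coded()["MM001"]
        probs = scanpos.p_ddm1.iloc[:, j]
        assert np.allclose(probs[coded == 1.0], 1.0)
        assert np.allclose(probs[coded == 0.0], 0.0)

    def test_midpoint_discordant_flanks_matches_enumeration(self):
        epi = tiny_epi({"A": [CALL_COL] * 12, "B": [CALL_DDM1] * 12})
        sp = mapping.genotype_probabilities(epi, step_cM=5.0)
        mid = sp.positions.index[(sp.positions["cM"] == 5.0)][0]
        p = sp.p_ddm1.iloc[0, mid]
        # brute-force enumeration of the symmetric two-state chain
        r = mapping.haldane_r(5.0)
        num1 = r * (1 - r)        # COL ->(switch) DDM1 ->(stay) DDM1
        num0 = (1 - r) * r        # COL ->(stay) COL ->(switch) DDM1
        expected = num1 / (num0 + num1)
        assert p == pytest.approx(expected, abs=1e-12)
        assert p == pytest.approx(0.5, abs=1e-12)

    def test_concordant_flanks_small_gap(self):
        epi = tiny_epi({"A": [CALL_DDM1] * 12, "B": [CALL_DDM1] * 12},
                       pos=(0.0, 0.5))
        sp = mapping.genotype_probabilities(epi, step_cM=0.25)
        assert np.all(sp.p_ddm1.to_numpy() > 0.99)

    def test_missing_call_uses_flanks(self):
        calls = {"A": [CALL_DDM1] * 12, "B": [CALL_DDM1] * 12}
        epi = tiny_epi(calls, pos=(0.0, 1.0))
        epi.calls.iloc[0, 1] = np.nan
        sp = mapping.genotype_probabilities(epi, step_cM=1.0)
        j = sp.marker_column("B")
        assert sp.p_ddm1.iloc[0, j] > 0.9  # pulled toward the observed flank


class TestHkScan:
    def test_worked_example_closed_form(self):
        """Genotype [0,0,1,1], trait [1,2,3,4]: r2=0.8 ->
        LOD = (4/2) log10(1/0.2) = 1.39794."""
        epi = tiny_epi({"A": [CALL_COL, CALL_COL, CALL_DDM1, CALL_DDM1]},
                       pos=(0.0,))
        sp = mapping.genotype_probabilities(epi, step_cM=1.0)
        trait = TraitVector("t", pd.Series([1.0, 2.0, 3.0, 4.0],
                                           index=epi.calls.index))
        scan = mapping.hk_scan(trait, sp, epi, min_lines=4)
        assert scan.lod[0] == pytest.approx(1.39794, abs=1e-5)

    def test_constant_trait_zero_lod(self, epi, scanpos):
        trait = TraitVector("t", pd.Series(5.0, index=epi.calls.index))
        scan = mapping.hk_scan(trait, scanpos, epi)
        assert np.allclose(scan.lod, 0.0)

    def test_matches_regression_oracle_at_markers(self, epi, scanpos):
        """No-cofactor LOD at observed markers vs an independent OLS oracle."""
        trait = planted_trait(epi, "MM050", 0.2, seed=11)
        scan = mapping.hk_scan(trait, scanpos, epi)
        y = trait.values.to_numpy()
        n = len(y)
        for marker in ("MM001", "MM050", "MM100"):
            j = scanpos.marker_column(marker)
            x = scanpos.p_ddm1.iloc[:, j].to_numpy()
            X = np.column_stack([np.ones(n), x])
            beta, rss1, *_ = np.linalg.lstsq(X, y, rcond=None)
            rss0 = ((y - y.mean()) ** 2).sum()
            lod_oracle = (n / 2) * np.log10(rss0 / rss1[0])
            assert scan.lod[j] == pytest.approx(lod_oracle, abs=1e-10)

    def test_cofactor_route_matches_statsmodels(self, epi, scanpos):
        import statsmodels.api as sm

        trait = planted_trait(epi, "MM050", 0.2, seed=12)
        cof = mapping.CofactorSet(marker_ids=["MM010", "MM100"], window_cM=10.0)
        scan = mapping.hk_scan(trait, scanpos, epi, cofactors=cof)
        j = scanpos.marker_column("MM050")
        y = trait.values.to_numpy()
        n = len(y)
        coded = epi.coded()
        C = coded[["MM010", "MM100"]].to_numpy()
        x = scanpos.p_ddm1.iloc[:, j].to_numpy()
        X1 = sm.add_constant(np.column_stack([C, x]))
        X0 = sm.add_constant(C)
        rss1 = sm.OLS(y, X1).fit().ssr
        rss0 = sm.OLS(y, X0).fit().ssr
        assert scan.lod[j] == pytest.approx((n / 2) * np.log10(rss0 / rss1),
                                            abs=1e-8)

    def test_lod_affine_invariant(self, epi, scanpos):
        trait = planted_trait(epi, "MM020", 0.15, seed=13)
        shifted = TraitVector("t2", 7.0 - 3.0 * trait.values)
        a = mapping.hk_scan(trait, scanpos, epi)
        b = mapping.hk_scan(shifted, scanpos, epi)
        assert np.allclose(a.lod, b.lod, atol=1e-9)


class TestPermutationThreshold:
    def test_deterministic(self, epi, scanpos):
        trait = planted_trait(epi, "MM020", 0.0, seed=14)
        t1 = mapping.permutation_threshold(trait, scanpos, n_perm=200, seed=5)
        t2 = mapping.permutation_threshold(trait, scanpos, n_perm=200, seed=5)
        assert t1 == t2

    def test_alpha_zero_gives_max(self, epi, scanpos):
        trait = planted_trait(epi, "MM020", 0.0, seed=15)
        maxima = mapping.permutation_max_lods(trait, scanpos, 150, seed=6)
        thr = mapping.permutation_threshold(trait, scanpos, n_perm=150,
                                            alpha=0.0, seed=6)
        assert thr == pytest.approx(maxima.max())

    def test_small_n_perm_rejected(self, epi, scanpos):
        trait = planted_trait(epi, "MM020", 0.0, seed=16)
        with pytest.raises(ValueError):
            mapping.permutation_threshold(trait, scanpos, n_perm=50)


class TestCofactors:
    def test_true_qtl_retained(self, epi):
        trait = planted_trait(epi, "MM050", 0.4, seed=17)
        candidates = ["MM010", "MM030", "MM050", "MM070", "MM090", "MM110"]
        cof = mapping.select_cofactors(trait, epi, candidates, drop_alpha=0.02)
        assert "MM050" in cof.marker_ids

    def test_null_trait_retention_rate(self, epi):
        # expected retained count ~ drop_alpha * n_candidates under the null
        candidates = mapping.evenly_spaced_candidates(epi, spacing_cM=20.0)
        kept = 0
        reps = 30
        for s in range(reps):
            trait = planted_trait(epi, "MM001", 0.0, seed=100 + s)
            cof = mapping.select_cofactors(trait, epi, candidates, drop_alpha=0.02)
            kept += len(cof)
        rate = kept / (reps * len(candidates))
        assert rate < 0.1  # loose null bound; expectation ~= 0.02

    def test_empty_candidates_reduce_to_interval_mapping(self, epi, scanpos):
        trait = planted_trait(epi, "MM020", 0.2, seed=18)
        cof = mapping.CofactorSet(marker_ids=[])
        a = mapping.hk_scan(trait, scanpos, epi, cofactors=cof)
        b = mapping.hk_scan(trait, scanpos, epi, cofactors=None)
        assert np.allclose(a.lod, b.lod, atol=1e-9)


class TestCallPeaks:
    def test_single_planted_peak_at_marker(self, epi, scanpos):
        trait = planted_trait(epi, "MM050", 0.5, seed=19)
        scan = mapping.hk_scan(trait, scanpos, epi)
        res = mapping.call_peaks(scan, threshold=3.0)
        assert len(res.peaks) >= 1
        top = max(res.peaks, key=lambda p: p.lod)
        mrow = epi.markers.table.set_index("marker_id").loc["MM050"]
        assert top.chrom == mrow["chrom"]
        assert abs(top.pos_cM - mrow["pos_cM"]) <= 4.0
        assert top.ci_lo <= mrow["pos_cM"] <= top.ci_hi

    def test_flat_profile_below_threshold(self, scanpos):
        scan = QtlScanResult("t", scanpos.positions.assign(effect=0.0),
                             np.full(len(scanpos.positions), 2.9))
        res = mapping.call_peaks(scan, threshold=3.0)
        assert res.peaks == []

    def test_effect_sign_convention(self, epi, scanpos):
        # DDM1 group mean above COL -> negative sign
        g = epi.coded()["MM050"]
        trait = TraitVector("t", pd.Series(10.0 + 5.0 * g, index=g.index)
                            + np.random.default_rng(1).normal(0, 0.1, len(g)))
        scan = mapping.hk_scan(trait, scanpos, epi)
        res = mapping.call_peaks(scan, threshold=3.0)
        top = max(res.peaks, key=lambda p: p.lod)
        assert top.effect_sign == -1


class TestQpcrAndColocalize:
    def test_qpcr_normalize(self):
        ct = pd.DataFrame({"SAND": [24.0], "TIP41": [26.0], "G": [24.0]},
                          index=["L1"])
        expr = mapping.qpcr_normalize(ct, ["SAND", "TIP41"], "G")
        assert expr.values["L1"] == pytest.approx(2.0)  # 2^(25-24)
        ct2 = pd.DataFrame({"R": [25.0], "G": [25.0]}, index=["L1"])
        assert mapping.qpcr_normalize(ct2, ["R"], "G").values["L1"] == 1.0

    def test_colocalize(self, scanpos):
        peak = QtlPeak("chr4", 37.0, 5.0, 30.0, 45.0, 0.1, 1)
        scan = QtlScanResult("e", scanpos.positions, np.zeros(len(scanpos.positions)),
                             peaks=[peak])
        assert mapping.colocalize(scan, ("chr4", 30.0, 45.0))
        assert mapping.colocalize(scan, ("chr4", 20.0, 37.0))  # boundary closed
        assert not mapping.colocalize(scan, ("chr1", 30.0, 45.0))
        with pytest.raises(ValueError):
            mapping.colocalize(scan, ("chrX", 0.0, 1.0))


class TestPleiotropyRegions:
    def scan_with_peak(self, trait, chrom, lo, hi, pos):
        peak = QtlPeak(chrom, (lo + hi) / 2, 5.0, lo, hi, 0.1, 1)
        return QtlScanResult(trait, pos, np.zeros(len(pos)), peaks=[peak])

    def test_single_linkage_merge(self, scanpos):
        pos = scanpos.positions
        scans = [self.scan_with_peak("t1", "chr1", 10.0, 20.0, pos),
                 self.scan_with_peak("t2", "chr1", 18.0, 30.0, pos)]
        regions, _ = mapping.pleiotropy_regions(scans)
        assert len(regions) == 1
        assert regions.iloc[0]["cM_lo"] == 10.0
        assert regions.iloc[0]["cM_hi"] == 30.0

    def test_disjoint_intervals(self, scanpos):
        pos = scanpos.positions
        scans = [self.scan_with_peak("t1", "chr1", 0.0, 5.0, pos),
                 self.scan_with_peak("t2", "chr1", 50.0, 60.0, pos)]
        regions, _ = mapping.pleiotropy_regions(scans)
        assert len(regions) == 2

    def test_five_traits_one_region(self, epi, scanpos):
        scans = []
        for i in range(5):
            trait = planted_trait(epi, "MM050", 0.5, seed=200 + i,
                                  trait_id=f"t{i}")
            scan = mapping.hk_scan(trait, scanpos, epi)
            scans.append(mapping.call_peaks(scan, threshold=3.0))
        regions, pairs = mapping.pleiotropy_regions(
            scans, traits={s.trait_id: planted_trait(epi, "MM050", 0.5,
                                                     seed=200 + i, trait_id=s.trait_id)
                           for i, s in enumerate(scans)})
        big = regions.sort_values("n_traits", ascending=False).iloc[0]
        assert big["n_traits"] == 5
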