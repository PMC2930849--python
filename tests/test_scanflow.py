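"""Pipeline orchestration, PED/MAP I/O, peaks, split-panel stability."""

import numpy as np
import pandas as pd
import pytest

from sibscan.panel import simulate_panel
from sibscan.pedio import read_ped_map, write_ped_map
from sibscan.peaks import find_peaks
from sibscan.phenotype import subgroup_rows
from sibscan.scanflow import ScanConfig, run_scan, split_panel_check
from sibscan.simulate import LongevityModel, simulate_cohort


class TestPedMapIO:
    def test_round_trip_byte_stable(self, null_cohort, tmp_path):
        p1, m1 = tmp_path / "a.ped", tmp_path / "a.map"
        p2, m2 = tmp_path / "b.ped", tmp_path / "b.map"
        write_ped_map(null_cohort, p1, m1)
        back = read_ped_map(p1, m1, panel=null_cohort.panel)
        assert np.array_equal(back.genotypes, null_cohort.genotypes)
        write_ped_map(back, p2, m2)
        assert p1.read_bytes() == p2.read_bytes()
        assert m1.read_bytes() == m2.read_bytes()

    def test_founders_written_untyped(self, null_cohort, tmp_path):
        ped, mp = tmp_path / "c.ped", tmp_path / "c.map"
        write_ped_map(null_cohort, ped, mp)
        sibs = null_cohort.sibships()
        n_founders = sum(len(s.founders) for s in sibs)
        founder_lines = 0
        for line in ped.read_text().splitlines():
            fields = line.split("\t")
            if fields[2] == "0" and fields[3] == "0":
                founder_lines += 1
                assert set(fields[6:]) == {"0"}
        assert founder_lines == n_founders

    def test_minimal_sibpair_fixture(self, tmp_path):
        ped = tmp_path / "mini.ped"
        mp = tmp_path / "mini.map"
        mp.write_text("1\trs1\t0.0\t100\n1\trs2\t10.0\t200\n")
        ped.write_text(
            "f1\tdad\t0\t0\t0\t0\t0\t0\t0\t0\n"
            "f1\tmum\t0\t0\t0\t0\t0\t0\t0\t0\n"
            "f1\tkid1\tdad\tmum\t2\t2\t1\t2\t1\t1\n"
            "f1\tkid2\tdad\tmum\t1\t2\t1\t1\t2\t2\n")
        coh = read_ped_map(ped, mp)
        sibs = coh.sibships()
        assert len(sibs) == 1 and sibs[0].size == 2
        assert sibs[0].founders == ["dad", "mum"]
        assert coh.genotypes.shape == (2, 2)
        assert coh.genotypes[0, 0] == 1 and coh.genotypes[1, 1] == 0

    def test_malformed_line_names_line_number(self, tmp_path):
        ped = tmp_path / "bad.ped"
        mp = tmp_path / "bad.map"
        mp.write_text("1\trs1\t0.0\t100\n")
        ped.write_text("f1\ta\t0\t0\t1\t2\t1\t1\n"
                       "f1\tb\t0\t0\t1\t2\t1\n")        # 7 fields, needs 8
        with pytest.raises(ValueError, match="line 2"):
            read_ped_map(ped, mp)

    def test_bad_sex_code_rejected(self, tmp_path):
        ped = tmp_path / "bad2.ped"
        mp = tmp_path / "bad2.map"
        mp.write_text("1\trs1\t0.0\t100\n")
        ped.write_text("f1\ta\t0\t0\t5\t2\t1\t1\n")
        with pytest.raises(ValueError, match="sex"):
            read_ped_map(ped, mp)


class TestRunScan:
    @pytest.fixture(scope="class")
    def result(self, small_panel, life_table):
        coh = simulate_cohort(small_panel, 40, seed=19)
        config = ScanConfig(categories=tuple(range(1, 11)), parametric=False)
        return coh, run_scan(coh, life_table, config, skip_qc=True)

    def test_ten_curves_with_nonincreasing_families(self, result):
        coh, res = result
        curves = [res.curves[("Total", k)] for k in range(1, 11)
                  if ("Total", k) in res.curves]
        assert len(curves) >= 8       # very strict categories may empty out
        nfam = [c["n_families"].iloc[0] for c in curves]
        assert all(a >= b for a, b in zip(nfam, nfam[1:]))

    def test_overall_max_covers_category_maxima(self, result):
        coh, res = result
        best = res.overall_max("Total")
        per_cat = res.category_maxima("Total")
        assert best["lod"] == pytest.approx(per_cat["lod"].max())

    def test_mc_fo_partition_category1(self, small_panel, life_table):
        coh = simulate_cohort(small_panel, 30, seed=20)
        from sibscan.phenotype import add_expected_age, assign_categories
        coh2 = add_expected_age(coh, life_table)
        membership = assign_categories(coh2.subjects)
        mc = subgroup_rows(coh2, "MC", membership)
        fo = subgroup_rows(coh2, "FO", membership)
        assert set(mc) & set(fo) == set()
        assert sorted(set(mc) | set(fo)) == list(range(coh2.n_subjects))

    def test_previous_new_partition(self, null_cohort):
        prev = subgroup_rows(null_cohort, "Previous")
        new = subgroup_rows(null_cohort, "New")
        assert sorted(set(prev) | set(new)) == list(range(null_cohort.n_subjects))
        assert set(prev) & set(new) == set()

    def test_scan_tsv_complete(self, result, tmp_path):
        from sibscan.scanflow import write_scan_tsv
        coh, res = result
        out = tmp_path / "scan.tsv"
        write_scan_tsv(res, out)
        df = pd.read_csv(out, sep="\t")
        assert not df[["chrom", "cm", "marker", "lod", "delta", "zmean"]].isna().any().any()

    def test_end_to_end_deterministic(self, small_panel, life_table, tmp_path):
        from sibscan.scanflow import write_scan_tsv
        files = []
        for tag in ("x", "y"):
            coh = simulate_cohort(small_panel, 40, seed=33)
            res = run_scan(coh, life_table,
                           ScanConfig(categories=(1, 3), parametric=False),
                           skip_qc=True)
            path = tmp_path / f"{tag}.tsv"
            write_scan_tsv(res, path)
            files.append(path.read_bytes())
        assert files[0] == files[1]


class TestPeaks:
    def _curve(self, lods, cms=None):
        lods = np.asarray(lods, dtype=float)
        if cms is None:
            cms = np.arange(len(lods), dtype=float)
        return pd.DataFrame({"chrom": 1, "cm": cms,
                             "marker": [f"m{i}" for i in range(len(lods))],
                             "lod": lods})

    def test_flat_zero_curve_has_no_peaks(self):
        assert find_peaks(self._curve(np.zeros(10))) == []

    def test_triangular_peak_boundaries(self):
        lods = np.array([0, 0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0,
                         3.5, 3.0, 2.5, 2.0, 1.5, 1.0, 0.5, 0])
        peaks = find_peaks(self._curve(lods), min_lod=3.0)
        assert len(peaks) == 1
        p = peaks[0]
        assert p.lod == 4.0 and p.cm == 8.0
        # -2 LOD interval: first positions with LOD <= 2.0 on each side
        assert p.support_2lod[0] == 4.0 and p.support_2lod[1] == 12.0
        # -1 LOD interval nested inside
        assert p.support_1lod[0] >= p.support_2lod[0]
        assert p.support_1lod[1] <= p.support_2lod[1]

    def test_chromosome_end_truncates_support(self):
        lods = np.array([4.0, 3.0, 2.0, 1.0])
        p = find_peaks(self._curve(lods), min_lod=3.0)[0]
        assert p.support_2lod[0] == 0.0      # clipped at chromosome start


class TestSplitPanel:
    def test_odd_even_subsets_partition(self, null_cohort):
        n = null_cohort.panel.n_markers
        even = null_cohort.subset_markers(np.arange(0, n, 2))
        odd = null_cohort.subset_markers(np.arange(1, n, 2))
        ids_even = set(even.panel.markers["marker"])
        ids_odd = set(odd.panel.markers["marker"])
        assert ids_even | ids_odd == set(null_cohort.panel.markers["marker"])
        assert ids_even & ids_odd == set()

    def test_informative_peak_retained_in_halves(self):
        """On a dense informative panel with a planted locus, both
        half-panel LOD maxima stay within 25% of the full-panel peak."""
        from sibscan.linkage import linkage_scan
        panel = simulate_panel(80, [80.0], maf_mean=0.45, seed=61)
        marker = panel.markers["marker"].iloc[40]
        model = LongevityModel(trait_locus=marker, mode="recessive",
                               effect_years=18.0)
        coh = simulate_cohort(panel, 120, seed=62, model=model,
                              size_dist={2: 0.6, 3: 0.4},
                              half_sib_fraction=0.0)
        curve = linkage_scan(coh)
        peaks = find_peaks(curve, min_lod=1.0)
        assert peaks, "planted locus should produce a peak"
        halves = split_panel_check(coh, peaks[0], margin_cm=5.0)
        for lod in halves.values():
            assert lod >= 0.75 * peaks[0].lod or lod >= peaks[0].lod - 0.5

    def test_null_cohort_halves_stay_small(self, null_cohort):
        from sibscan.linkage import linkage_scan
        curve = linkage_scan(null_cohort)
        peaks = find_peaks(curve, min_lod=0.0)
        halves = split_panel_check(null_cohort, peaks[0], margin_cm=5.0)
        for lod in halves.values():
            assert lod < max(1.0, peaks[0].lod + 0.5)
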