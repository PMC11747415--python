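"""Backcross simulation and per-locus frequency mapping."""

import numpy as np
import pytest

from synchrom.segmap import (
    LocusFrequencyTable,
    Marker,
    SegregantPanel,
    call_defect_intervals,
    locus_frequency,
    simulate_cross,
)


@pytest.fixture(scope="module")
def markers16():
    return [Marker(f"M{i + 1}", (i + 1) * 56_000) for i in range(16)]


class TestSimulateCross:
    def test_zero_crossover_rate_gives_parental_strains(self, markers16):
        panel = simulate_cross(markers16, 50, 0.0, [], 0.5, seed=1)
        for row in panel.genotypes:
            assert row.all() or not row.any()

    def test_unselected_syn_fraction_near_half(self, markers16):
        n = 2000
        panel = simulate_cross(markers16, n, 3.5e-6, [], 0.0, seed=2,
                               baseline_unfit_rate=0.0)
        frac = panel.genotypes.mean(axis=0)
        se = 3 * np.sqrt(0.25 / n)
        assert np.all(np.abs(frac - 0.5) <= se)

    def test_full_penetrance_fit_strains_are_wt_at_defects(self, markers16):
        panel = simulate_cross(markers16, 200, 3.5e-6, ["M5", "M12"], 1.0,
                               seed=3, baseline_unfit_rate=0.0)
        fit = panel.genotypes[~panel.phenotype]
        assert not fit[:, [4, 11]].any()

    def test_zero_markers_is_an_error(self):
        with pytest.raises(ValueError):
            simulate_cross([], 10, 1e-6, [], 0.5, seed=0)

    def test_unknown_defect_locus_rejected(self, markers16):
        with pytest.raises(ValueError, match="unknown defect"):
            simulate_cross(markers16, 10, 1e-6, ["nope"], 0.5, seed=0)

    def test_deterministic_under_seed(self, markers16):
        a = simulate_cross(markers16, 30, 3.5e-6, ["M5"], 0.9, seed=7)
        b = simulate_cross(markers16, 30, 3.5e-6, ["M5"], 0.9, seed=7)
        assert (a.genotypes == b.genotypes).all()
        assert (a.phenotype == b.phenotype).all()

    def test_forced_crossover_breaks_every_strain_at_cut(self, markers16):
        panel = simulate_cross(markers16, 40, 0.0, [], 0.0, seed=4,
                               baseline_unfit_rate=0.5,
                               forced_crossover_at="M8")
        for row in panel.genotypes:
            assert (row[:8] == row[0]).all()
            assert (row[8:] == (not row[0])).all()


class TestLocusFrequency:
    def test_hand_counted_ratio(self, markers16):
        geno = np.zeros((20, 16), dtype=bool)
        geno[:2, 4] = True  # 2 of 15 fit strains SYN at M5
        geno[15:, :] = True  # 5 unfit strains all-SYN
        pheno = np.array([False] * 15 + [True] * 5)
        panel = SegregantPanel(markers=markers16, genotypes=geno, phenotype=pheno)
        table = locus_frequency(panel)
        assert table.n_fit == 15 and table.n_unfit == 5
        assert table.f_syn_fit[4] == pytest.approx(2 / 15)
        assert table.f_syn_unfit[4] == 1.0

    def test_all_wt_panel_gives_zero_frequencies(self, markers16):
        geno = np.zeros((10, 16), dtype=bool)
        pheno = np.array([False] * 5 + [True] * 5)
        table = locus_frequency(
            SegregantPanel(markers=markers16, genotypes=geno, phenotype=pheno)
        )
        assert (table.f_syn_fit == 0).all() and (table.f_syn_unfit == 0).all()

    def test_empty_class_is_an_error(self, markers16):
        geno = np.zeros((5, 16), dtype=bool)
        pheno = np.zeros(5, dtype=bool)
        with pytest.raises(ValueError, match="per class"):
            locus_frequency(SegregantPanel(markers=markers16, genotypes=geno,
                                           phenotype=pheno))

    def test_frequencies_equal_brute_force_recount(self, markers16):
        rng = np.random.default_rng(5)
        for _ in range(10):
            panel = simulate_cross(markers16, 40, 3.5e-6, ["M3"], 0.8,
                                   seed=rng)
            try:
                table = locus_frequency(panel)
            except ValueError:
                continue
            df = panel.to_frame()
            for j, m in enumerate(markers16):
                fit_rows = df[df.phenotype == "fit"]
                unfit_rows = df[df.phenotype == "unfit"]
                assert table.f_syn_fit[j] == pytest.approx(
                    (fit_rows[m.id] == "SYN").mean())
                assert table.f_syn_unfit[j] == pytest.approx(
                    (unfit_rows[m.id] == "SYN").mean())

    def test_delta_peaks_at_fully_penetrant_defect(self, markers16):
        panel = simulate_cross(markers16, 400, 3.5e-6, ["M9"], 1.0, seed=6,
                               baseline_unfit_rate=0.0)
        table = locus_frequency(panel)
        assert abs(int(np.argmax(table.delta)) - 8) <= 1


def _table(f_fit, f_unfit, markers):
    return LocusFrequencyTable(
        markers=markers,
        f_syn_fit=np.array(f_fit),
        f_syn_unfit=np.array(f_unfit),
        n_fit=15,
        n_unfit=15,
    )


class TestCallDefectIntervals:
    def test_single_qualifying_marker(self, markers16):
        f_fit = [0.5] * 16
        f_unfit = [0.5] * 16
        f_fit[6], f_unfit[6] = 0.1, 0.8
        calls = call_defect_intervals(_table(f_fit, f_unfit, markers16), 0.3, 0.6)
        assert calls == [("M7", "M7")]

    def test_two_separated_regions_like_the_backcross_map(self, markers16):
        """Two depleted/enriched blocks, as in an F-I plus X3-X4 situation."""
        f_fit = [0.5] * 16
        f_unfit = [0.5] * 16
        for i in (4, 5, 6):  # one multi-marker region
            f_fit[i], f_unfit[i] = 0.14, 0.73
        for i in (12, 13):  # a second, separated region
            f_fit[i], f_unfit[i] = 0.0, 0.63
        calls = call_defect_intervals(_table(f_fit, f_unfit, markers16), 0.3, 0.6)
        assert calls == [("M5", "M7"), ("M13", "M14")]

    def test_no_qualifying_markers(self, markers16):
        calls = call_defect_intervals(
            _table([0.5] * 16, [0.5] * 16, markers16), 0.3, 0.6)
        assert calls == []

    def test_bad_thresholds_rejected(self, markers16):
        with pytest.raises(ValueError):
            call_defect_intervals(_table([0.5] * 16, [0.5] * 16, markers16),
                                  0.7, 0.3)
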