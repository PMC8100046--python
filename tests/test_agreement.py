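import math

import numpy as np
import pytest

from hrfcount import (PairedCounts, agree_report, bland_altman,
                      cloud_diagnostics, icc)
from oracles import icc_absolute_bruteforce


class TestPairedCounts:
    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            PairedCounts(np.array([1.0, 2.0]), np.array([1.0]))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            PairedCounts(np.array([1.0, -2.0]), np.array([1.0, 2.0]))


class TestICC:
    def test_perfect_agreement(self):
        pc = PairedCounts(np.array([1.0, 2, 3, 4]), np.array([1.0, 2, 3, 4]))
        assert icc(pc) == pytest.approx(1.0)

    def test_reversed_pairing_negative_and_matches_oracle(self):
        pc = PairedCounts(np.array([1.0, 2, 3, 4]), np.array([4.0, 3, 2, 1]))
        val = icc(pc)
        assert val < 0
        assert val == pytest.approx(icc_absolute_bruteforce(pc.manual,
                                                            pc.semi),
                                    abs=1e-12)

    def test_offset_lowers_absolute_vs_consistency(self, rng):
        man = rng.uniform(0, 50, 30)
        semi = man + 40.0
        pc = PairedCounts(man, semi)
        assert icc(pc) < icc(pc, model="consistency") - 0.1
        # a pure offset leaves consistency-ICC at 1
        assert icc(pc, model="consistency") == pytest.approx(1.0)

    def test_matches_bruteforce_random_tables(self, rng):
        for _ in range(50):
            n = int(rng.integers(2, 51))
            man = np.floor(rng.uniform(0, 200, n))
            semi = np.floor(rng.uniform(0, 200, n))
            if np.ptp(np.concatenate([man, semi])) == 0:
                continue
            pc = PairedCounts(man, semi)
            assert icc(pc) == pytest.approx(
                icc_absolute_bruteforce(man, semi), abs=1e-10)

    def test_matches_pingouin_icc2(self, rng):
        pg = pytest.importorskip("pingouin")
        import pandas as pd
        man = np.floor(rng.uniform(0, 100, 25))
        semi = np.floor(np.abs(man + rng.normal(0, 5, 25)))
        df = pd.DataFrame({
            "t": np.repeat(np.arange(25), 2),
            "r": ["m", "s"] * 25,
            "y": np.column_stack([man, semi]).ravel()})
        ref = pg.intraclass_corr(df, targets="t", raters="r", ratings="y")
        ref_val = float(ref.loc[ref["Type"] == "ICC(A,1)", "ICC"].iloc[0])
        assert icc(PairedCounts(man, semi)) == pytest.approx(ref_val,
                                                             abs=1e-10)

    def test_constant_data_is_one_with_warning(self):
        pc = PairedCounts(np.array([5.0, 5, 5]), np.array([5.0, 5, 5]))
        with pytest.warns(UserWarning):
            assert icc(pc) == 1.0

    def test_shift_invariance_both_raters(self, rng):
        man = np.floor(rng.uniform(0, 80, 20))
        semi = np.floor(rng.uniform(0, 80, 20))
        a = icc(PairedCounts(man, semi))
        b = icc(PairedCounts(man + 10, semi + 10))
        assert a == pytest.approx(b, abs=1e-12)


class TestBlandAltman:
    def test_identical_vectors(self):
        pc = PairedCounts(np.array([3.0, 7, 9]), np.array([3.0, 7, 9]))
        ba = bland_altman(pc)
        assert ba["bias"] == 0.0 and ba["loa_halfwidth"] == 0.0

    def test_plus_minus_one_differences(self):
        pc = PairedCounts(np.array([1.0, 2.0]), np.array([2.0, 1.0]))
        ba = bland_altman(pc)
        assert ba["bias"] == 0.0
        assert ba["loa_halfwidth"] == pytest.approx(1.96 * math.sqrt(2))

    def test_constant_offset(self):
        man = np.array([10.0, 20, 30])
        pc = PairedCounts(man, man - 5)
        ba = bland_altman(pc)
        assert ba["bias"] == pytest.approx(5.0)
        assert ba["loa_halfwidth"] == 0.0

    def test_bias_antisymmetric_loa_invariant(self, rng):
        man = np.floor(rng.uniform(0, 100, 30))
        semi = np.floor(rng.uniform(0, 100, 30))
        a = bland_altman(PairedCounts(man, semi))
        b = bland_altman(PairedCounts(semi, man))
        assert a["bias"] == pytest.approx(-b["bias"])
        assert a["loa_halfwidth"] == pytest.approx(b["loa_halfwidth"])


class TestCloudDiagnostics:
    def test_perfect_trend(self):
        man = np.array([10.0, 20, 30, 40, 50])
        semi = np.zeros(5)
        # d = manual, m = manual/2 -> slope of d on m is exactly 2
        diag = cloud_diagnostics(PairedCounts(man, semi))
        assert diag["trend_slope"] == pytest.approx(2.0)
        assert diag["trend_p"] < 1e-6

    def test_no_trend_by_construction(self, rng):
        man = np.floor(rng.uniform(20, 100, 200))
        d = rng.normal(0, 3, 200)
        semi = np.maximum(man - d, 0)
        diag = cloud_diagnostics(PairedCounts(man, semi))
        assert abs(diag["trend_slope"]) < 0.15
        assert diag["trend_p"] > 0.05

    def test_heteroscedastic_detected(self, rng):
        m_base = np.floor(rng.uniform(10, 100, 200))
        scale = np.where(m_base > np.median(m_base), 8.0, 2.0)
        d = rng.normal(0, scale)
        semi = np.maximum(m_base - d, 0)
        diag = cloud_diagnostics(PairedCounts(m_base, semi))
        assert diag["levene_p"] < 0.01

    def test_degenerate_means_reported(self):
        pc = PairedCounts(np.array([5.0, 5, 5, 5]), np.array([5.0, 5, 5, 5]))
        diag = cloud_diagnostics(pc)
        assert math.isnan(diag["trend_slope"])
        assert "undefined" in diag["notes"]

    def test_too_few_pairs_refused(self):
        with pytest.raises(ValueError, match="4"):
            cloud_diagnostics(PairedCounts(np.array([1.0, 2]),
                                           np.array([1.0, 2])))


class TestAgreeReport:
    def test_identical_vectors_summary(self):
        v = np.array([3.0, 8, 15, 22])
        rep = agree_report(PairedCounts(v, v.copy()))
        assert rep.icc == pytest.approx(1.0)
        assert rep.bias == 0.0 and rep.loa_halfwidth == 0.0

    def test_n2_diagnostics_refused_with_message(self):
        rep = agree_report(PairedCounts(np.array([1.0, 5]),
                                        np.array([2.0, 4])))
        assert math.isnan(rep.trend_slope)
        assert "refused" in rep.notes

    def test_plots_written(self, tmp_path, rng):
        man = np.floor(rng.uniform(0, 100, 30))
        semi = np.floor(np.abs(man + rng.normal(0, 5, 30)))
        agree_report(PairedCounts(man, semi), plots_dir=tmp_path)
        assert (tmp_path / "agreement_scatter.png").exists()
        assert (tmp_path / "agreement_bland_altman.png").exists()
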