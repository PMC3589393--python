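"""Formula masses, deuteron counting, back-exchange, significance tests."""

import numpy as np
import pytest
from pyteomics.mass import calculate_mass
from scipy import stats

from liganddyn import (DELTA_MASS_D_H, HdxRecord, back_exchange_fraction,
                       correct_deuterons, deuteron_count, monoisotopic_mass,
                       parse_formula, summarize_conditions, ttest_unpaired)
from liganddyn.hdx import amide_count
from liganddyn.masses import ELECTRON_MASS

#: published calcd (M-H)- values for the 15N-labeled ligand series
CALCD = {
    "C9H9N[15N]O5S": 258.0208,
    "C11H12N2[15N]O6S": 315.0423,
    "C13H15N3[15N]O7S": 372.0637,
    "C15H18N4[15N]O8S": 429.0852,
    "C17H21N5[15N]O9S": 486.1067,
}


class TestMonoisotopicMass:
    def test_single_hydrogen(self):
        assert monoisotopic_mass("H") == pytest.approx(1.0078, abs=5e-5)

    @pytest.mark.parametrize("formula,expected", sorted(CALCD.items()))
    def test_all_published_anion_masses(self, formula, expected):
        assert round(monoisotopic_mass(formula, charge=-1), 4) == expected

    @pytest.mark.parametrize("formula", sorted(CALCD))
    def test_against_independent_summation(self, formula):
        # oracle: pyteomics' own parser/summation on a translated formula
        translated = formula.replace("[15N]", "N[15]")
        oracle = calculate_mass(formula=translated) + ELECTRON_MASS
        assert monoisotopic_mass(formula, charge=-1) == pytest.approx(
            oracle, abs=1e-9)

    def test_isotope_label_shifts_mass_by_one_neutron(self):
        plain = monoisotopic_mass("C9H9N2O5S")
        labeled = monoisotopic_mass("C9H9N[15N]O5S")
        assert labeled - plain == pytest.approx(0.9970, abs=1e-3)

    def test_unknown_symbol_named_in_error(self):
        with pytest.raises(ValueError, match="Xx"):
            parse_formula("C2Xx3")
        with pytest.raises(ValueError):
            parse_formula("")

    def test_counts_and_brackets_parse(self):
        comp = parse_formula("C2H5[15N]2O")
        assert comp[("C", 0)] == 2 and comp[("N", 15)] == 2
        assert comp[("H", 0)] == 5 and comp[("O", 0)] == 1


class TestDeuteronCount:
    def test_no_shift_counts_zero(self):
        assert deuteron_count(29089.0, 29089.0) == 0.0

    def test_seventy_five_deuterons(self):
        obs = 29089.0 + 75 * DELTA_MASS_D_H
        assert deuteron_count(obs, 29089.0) == pytest.approx(75.0, rel=1e-12)

    def test_linearity_with_unit_slope_in_delta_mass(self):
        ref = 29089.0
        counts = [deuteron_count(ref + x, ref) for x in (1.0, 2.0, 10.0)]
        assert counts[1] - counts[0] == pytest.approx(1 / DELTA_MASS_D_H)
        assert counts[2] == pytest.approx(10 / DELTA_MASS_D_H)

    def test_negative_shift_clips_with_warning(self):
        with pytest.warns(UserWarning):
            assert deuteron_count(29088.5, 29089.0) == 0.0


class TestBackExchange:
    REF = 29089.0
    N = 240

    def theory(self):
        return self.REF + 0.9 * self.N * DELTA_MASS_D_H

    def test_no_loss_when_control_hits_theory(self):
        assert back_exchange_fraction(self.theory(), self.REF, self.N) == 0.0

    def test_constructed_thirty_five_percent(self):
        obs = self.theory() - 0.35 * (self.theory() - self.REF)
        frac = back_exchange_fraction(obs, self.REF, self.N)
        assert frac == pytest.approx(0.35, rel=1e-12)

    def test_correction_inverts_the_loss(self):
        assert correct_deuterons(48.75, 0.35) == pytest.approx(48.75 / 0.65)

    def test_correction_monotone_in_back_exchange(self):
        fracs = np.linspace(0.0, 0.9, 10)
        corrected = [correct_deuterons(50.0, f) for f in fracs]
        assert np.all(np.diff(corrected) > 0)

    def test_control_above_theory_warns_to_zero(self):
        with pytest.warns(UserWarning):
            assert back_exchange_fraction(self.theory() + 5.0, self.REF,
                                          self.N) == 0.0


class TestTTest:
    def test_identical_groups(self):
        t, df, p = ttest_unpaired([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_critical_value_at_df8(self):
        # |t| at p = 0.05, df = 8 must be the tabulated 2.306
        assert stats.t.ppf(0.975, 8) == pytest.approx(2.306, abs=1e-3)
        rng = np.random.default_rng(1)
        a, b = rng.normal(0, 1, 5), rng.normal(0, 1, 5)
        t, df, p = ttest_unpaired(a, b)
        assert df == 8
        # p crosses 0.05 exactly where |t| crosses 2.306
        assert (p < 0.05) == (abs(t) > 2.306)

    def test_type_i_error_calibration(self):
        # 10^4 null trials at n = 5 per group: rejection rate ~ alpha
        rng = np.random.default_rng(20130305)
        a = rng.normal(0, 1, (10000, 5))
        b = rng.normal(0, 1, (10000, 5))
        _, p = stats.ttest_ind(a, b, axis=1, equal_var=True)
        rate = np.mean(p < 0.05)
        assert 0.04 <= rate <= 0.06
        # spot-check our wrapper against the vectorized oracle
        t0, _, p0 = ttest_unpaired(a[0], b[0])
        assert p0 == pytest.approx(p[0], rel=1e-12)

    def test_degenerate_zero_variance_groups(self):
        with pytest.warns(UserWarning):
            t, _, p = ttest_unpaired([1.0, 1.0], [2.0, 2.0])
        assert p == 0.0


class TestSummarize:
    REF = 29089.0

    def record(self, condition, mean_count, n=5, sd=0.0, seed=0, time=3.0):
        rng = np.random.default_rng(seed)
        masses = (self.REF + mean_count * DELTA_MASS_D_H
                  + rng.normal(0, sd, n))
        return HdxRecord(condition=condition, time_in_D2O=time,
                         replicate_masses=masses, reference_mass_H=self.REF)

    def test_identical_replicates_have_zero_sem(self):
        out = summarize_conditions([self.record("apo", 75.0)],
                                   back_exchange=0.0)
        assert out.loc[0, "sem_deuterons"] == 0.0
        assert out.loc[0, "mean_deuterons"] == pytest.approx(75.0)

    def test_monotone_trend_preserved(self):
        means = {f"SA-Gly{n}": 60.0 + 2.0 * n for n in range(1, 6)}
        recs = [self.record(c, m, sd=0.1, seed=j)
                for j, (c, m) in enumerate(means.items())]
        with pytest.warns(UserWarning):  # no apo condition
            out = summarize_conditions(recs, back_exchange=0.35)
        ordered = out.sort_values("condition")["mean_deuterons"].to_numpy()
        assert np.all(np.diff(ordered) > 0)

    def test_separated_conditions_flagged_significant(self):
        # 2.5 SEM-unit separation at n = 5 should reach p < 0.05
        sd = 1.0
        sem = sd / np.sqrt(5) / DELTA_MASS_D_H
        recs = [self.record("apo", 75.0, sd=sd, seed=1),
                self.record("SA-Gly1", 75.0 - 5 * sem, sd=sd, seed=2),
                self.record("SA-Gly5", 75.0 + 2 * sem, sd=sd, seed=3)]
        out = summarize_conditions(recs, back_exchange=0.35)
        row = out[out["condition"] == "SA-Gly1"].iloc[0]
        assert row["p_vs_apo"] < 0.05
        assert "*" in row["significance"]
        p51 = ttest_unpaired(
            [deuteron_count(m, self.REF)
             for m in recs[2].replicate_masses],
            [deuteron_count(m, self.REF)
             for m in recs[1].replicate_masses])[2]
        assert p51 < 0.05

    def test_corrected_counts_scale_raw_by_back_exchange(self):
        out = summarize_conditions([self.record("apo", 48.75)],
                                   back_exchange=0.35)
        assert out.loc[0, "corrected_deuterons"] == pytest.approx(
            48.75 / 0.65)


def test_amide_count_excludes_nterm_and_prolines(tmp_path):
    assert amide_count("ACDEFG") == 5
    assert amide_count("ACPDEPFG") == 5
    fasta = tmp_path / "seq.fasta"
    fasta.write_text(">toy protein\nACPDEPFG\n")
    from liganddyn.hdx import amide_count_from_fasta
    assert amide_count_from_fasta(fasta) == 5
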