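"""Haplotype-sharing scan, dosage calling, population frequencies, grouping."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import kinpipe as kp
from kinpipe import synthetic_pedigree as sim
from kinpipe.haplotype_sharing import (SHARES_NONE, SHARES_ONE_OR_TWO,
                                       SHARES_TWO, UNINFORMATIVE,
                                       SharingParams, _dosage_from_counts,
                                       assign_ancestry_groups,
                                       call_dosage, population_frequencies,
                                       sharing_scan,
                                       verify_reference_homozygosity)

from conftest import make_matrix

TARGET = (3_000_000, 6_000_000)


@pytest.fixture(scope="module")
def recovery():
    """Frequency-recovery panel (f=0.4, n=25) with its sharing profiles."""
    cfg = sim.frequency_recovery_config(0.4, seed=20)
    res = sim.simulate(cfg)
    profs = sharing_scan(res.genotypes, "REF", "chr2", n_windows=40,
                         target=TARGET, chrom_length=8_000_000)
    return cfg, res, profs


class TestReferenceVerification:
    def test_all_homozygous_passes(self):
        gm = make_matrix([[0], [2], [0], [2]] * 25)
        frac, ok = verify_reference_homozygosity(gm, "S0", "chr1", (0, 100_000))
        assert frac == 1.0 and ok

    def test_five_percent_hets_fails_default(self):
        codes = [[0]] * 95 + [[1]] * 5
        gm = make_matrix(codes)
        frac, ok = verify_reference_homozygosity(gm, "S0", "chr1", (0, 100_000))
        assert frac == pytest.approx(0.95)
        assert not ok

    def test_no_sites_in_region_fails_with_nan(self, caplog):
        gm = make_matrix([[0]])
        frac, ok = verify_reference_homozygosity(gm, "S0", "chr1",
                                                 (900_000, 950_000))
        assert np.isnan(frac) and not ok

    def test_planted_homozygote_passes(self, recovery):
        _, res, _ = recovery
        frac, ok = verify_reference_homozygosity(res.genotypes, "REF",
                                                 "chr2", TARGET)
        assert ok

    def test_unverified_reference_refused_for_scan(self, recovery):
        _, res, _ = recovery
        het_wild = next(a for a, d in res.truth.dosages.items()
                        if d == 1)  # heterozygous carrier cannot anchor a scan
        with pytest.raises(ValueError, match="not homozygous"):
            sharing_scan(res.genotypes, het_wild, "chr2", n_windows=40,
                         target=TARGET, chrom_length=8_000_000)


class TestSharingScan:
    def test_reference_shares_two_everywhere_and_dosage_two(self, recovery):
        _, _, profs = recovery
        ref = profs["REF"]
        informative = ref.states[ref.states != UNINFORMATIVE]
        assert (informative == SHARES_TWO).all()
        assert ref.dosage_at_target == 2

    def test_het_carrier_target_windows_not_opposite(self, recovery):
        cfg, res, profs = recovery
        bounds = profs["REF"].window_bounds
        target_w = np.flatnonzero((bounds[:-1] < TARGET[1])
                                  & (bounds[1:] > TARGET[0]))
        carriers1 = [a for a, d in res.truth.dosages.items() if d == 1]
        for acc in carriers1:
            states = profs[acc].states[target_w]
            states = states[states != UNINFORMATIVE]
            # single-window miscall noise is tolerated; the bulk of the
            # target must read as one-or-two copies and the pooled call is 1
            assert (states == SHARES_ONE_OR_TWO).mean() > 0.6
            assert (states == SHARES_NONE).sum() <= 2
            assert profs[acc].dosage_at_target == 1

    def test_shared_segment_contains_target_for_carriers(self, recovery):
        _, res, profs = recovery
        for acc, d in res.truth.dosages.items():
            if d >= 1:
                seg = profs[acc].shared_segment
                assert seg is not None
                assert seg[0] < TARGET[1] and seg[1] > TARGET[0]  # overlaps target

    def test_dosage_recovery_against_planted_truth(self, recovery):
        _, res, profs = recovery
        wrong = [a for a, p in profs.items()
                 if p.dosage_at_target is not None
                 and p.dosage_at_target != res.truth.dosages.get(a, 0)]
        assert wrong == []

    def test_call_dosage_on_profile_matches_scan(self, recovery):
        _, _, profs = recovery
        for p in profs.values():
            assert call_dosage(p, TARGET) == p.dosage_at_target

    def test_unknown_chromosome_raises(self, recovery):
        _, res, _ = recovery
        with pytest.raises(ValueError, match="no sites"):
            sharing_scan(res.genotypes, "REF", "chrX")


class TestDosageRule:
    def test_pooled_rule_values(self):
        params = SharingParams()
        n = np.array([100, 100])
        # no opposite homozygotes, everything matching -> two copies
        assert _dosage_from_counts(n, np.array([0, 0]), np.array([100, 99]),
                                   params) == 2
        # opposite homozygotes above tolerance -> zero copies
        assert _dosage_from_counts(n, np.array([4, 3]), np.array([50, 50]),
                                   params) == 0
        # in between -> one copy
        assert _dosage_from_counts(n, np.array([1, 0]), np.array([60, 70]),
                                   params) == 1
        # nothing informative -> undetermined
        assert _dosage_from_counts(np.array([0]), np.array([0]),
                                   np.array([0]), params) is None

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(st.integers(0, 50), st.integers(0, 50))
    def test_monotone_in_opposite_homozygotes(self, opp1, opp2):
        # adding opposite-homozygote evidence can only decrease dosage
        lo, hi = sorted((opp1, opp2))
        params = SharingParams()
        n = np.array([200])
        match = np.array([120])
        d_hi = _dosage_from_counts(n, np.array([lo]), match, params)
        d_lo = _dosage_from_counts(n, np.array([hi]), match, params)
        assert d_lo <= d_hi


class TestPopulationFrequencies:
    def test_arithmetic(self):
        dosages = {f"a{i}": 2 for i in range(10)}
        pops = {f"a{i}": "P" for i in range(10)}
        out = population_frequencies(dosages, pops)
        assert out.loc[0, "frequency"] == 1.0

    def test_quarter_frequency(self):
        dosages = {f"x{i}": (1 if i < 10 else 0) for i in range(20)}
        pops = {f"x{i}": "P" for i in range(20)}
        out = population_frequencies(dosages, pops)
        assert out.loc[0, "frequency"] == pytest.approx(0.25)

    def test_undetermined_excluded_from_denominator(self):
        dosages = {"a": 2, "b": None, "c": 0}
        pops = {"a": "P", "b": "P", "c": "P"}
        out = population_frequencies(dosages, pops)
        assert out.loc[0, "n_called"] == 2
        assert out.loc[0, "n_undetermined"] == 1
        assert out.loc[0, "frequency"] == pytest.approx(0.5)

    def test_empty_population_is_na(self):
        out = population_frequencies({"a": None}, {"a": "P"})
        assert np.isnan(out.loc[0, "frequency"])

    def test_estimator_unbiased_over_replicates(self):
        diffs = []
        for seed in range(30, 40):
            cfg = sim.frequency_recovery_config(0.25, seed=seed)
            res = sim.simulate(cfg)
            profs = sharing_scan(res.genotypes, "REF", "chr2", n_windows=40,
                                 target=TARGET, chrom_length=8_000_000)
            dosages = {a: p.dosage_at_target for a, p in profs.items()}
            out = population_frequencies(dosages, cfg.populations)
            est = out.set_index("population").loc["wild", "frequency"]
            truth = sum(res.truth.dosages[a] for a, p in cfg.populations.items()
                        if p == "wild") / (2 * 25)
            diffs.append(est - truth)
        assert abs(np.mean(diffs)) < 0.02


class TestAncestryGroups:
    def test_pure_component_assigned(self):
        q = pd.DataFrame([[1.0, 0.0, 0.0]], index=["x"],
                         columns=["c1", "c2", "c3"])
        assert assign_ancestry_groups(q)["x"] == "c1"

    def test_admixed_below_threshold(self):
        q = pd.DataFrame([[0.5, 0.3, 0.2]], index=["x"],
                         columns=["c1", "c2", "c3"])
        assert assign_ancestry_groups(q)["x"] == "admixed"

    def test_threshold_is_strict(self):
        # exactly 0.85 is NOT "higher than 0.85"
        q = pd.DataFrame([[0.85, 0.15, 0.0]], index=["x"],
                         columns=["c1", "c2", "c3"])
        assert assign_ancestry_groups(q)["x"] == "admixed"

    def test_malformed_row_names_accession(self):
        q = pd.DataFrame([[0.9, 0.3, 0.0]], index=["broken"],
                         columns=["c1", "c2", "c3"])
        with pytest.raises(ValueError, match="broken"):
            assign_ancestry_groups(q)

    def test_simulated_truth_q_matrix(self, sim7):
        groups = assign_ancestry_groups(sim7.truth.ancestry)
        assert groups["A1"] == "cult1"
        assert groups["B4"] == "cult2"
        assert groups["GEN2"] == "admixed"   # 0.25 / 0.75 split at best
        assert groups["W_Paklenica_1"] == "wild"
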