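"""Mendelian compatibility table, trio verdicts, and trio search."""

import itertools

import numpy as np
import pytest

import kinpipe as kp
from kinpipe import synthetic_pedigree as sim
from kinpipe.trio_validation import test_trio as validate_trio
from kinpipe.trio_validation import (TrioParams, build_compatibility_table,
                                     compatibility_lists, incompatible_regions,
                                     infer_full_sibs, search_trios,
                                     trios_table, window_error_track)

from conftest import make_matrix

# The two published lists of genotypic combinations for P1×P2→F1
# (a = reference allele, b = alternative allele).
PRINTED_COMPATIBLE = {
    "aa×aa→aa", "aa×ab→aa", "aa×ab→ab", "aa×bb→ab",
    "ab×aa→aa", "ab×aa→ab", "ab×ab→aa", "ab×ab→ab", "ab×ab→bb",
    "ab×bb→ab", "ab×bb→bb", "bb×aa→ab", "bb×ab→ab", "bb×ab→bb", "bb×bb→bb",
}
PRINTED_INCOMPATIBLE = {
    "aa×aa→ab", "aa×aa→bb", "aa×ab→bb", "aa×bb→aa", "aa×bb→bb",
    "ab×aa→bb", "ab×bb→aa", "bb×aa→aa", "bb×aa→bb", "bb×ab→aa",
    "bb×bb→aa", "bb×bb→ab",
}


class TestCompatibilityTable:
    def test_matches_published_lists_exactly(self):
        compat, incompat = compatibility_lists()
        assert set(compat) == PRINTED_COMPATIBLE
        assert set(incompat) == PRINTED_INCOMPATIBLE
        assert len(compat) == 15 and len(incompat) == 12

    def test_equals_exhaustive_mendelian_enumeration(self):
        # independent oracle: enumerate every transmission explicitly
        table = build_compatibility_table()
        alleles = {0: (0, 0), 1: (0, 1), 2: (1, 1)}
        for g1, g2, gf in itertools.product(range(3), repeat=3):
            expected = any(
                sorted((a1, a2)) == sorted(alleles[gf])
                for a1 in alleles[g1] for a2 in alleles[g2])
            assert table[g1, g2, gf] == expected

    def test_symmetric_under_parent_swap(self):
        table = build_compatibility_table()
        np.testing.assert_array_equal(table, table.transpose(1, 0, 2))


class TestSingleTrio:
    def test_error_free_genuine_trio_accepted_with_zero_errors(self, errorfree1):
        res, ws = errorfree1
        for f, p1, p2 in res.truth.trios:
            r = validate_trio(res.genotypes, ws, p1, p2, f)
            assert r.n_mendelian_errors == 0
            assert r.verdict == "accepted"

    def test_noisy_genuine_trios_accepted_with_background_errors(self, recovery_sweep):
        for rep in recovery_sweep:
            res, ws = rep["res"], rep["ws"]
            for f, p1, p2 in res.truth.trios:
                r = validate_trio(res.genotypes, ws, p1, p2, f)
                assert r.verdict == "accepted"
                assert 0 < r.error_rate <= 0.013
                assert not r.flagged_runs

    def test_sibling_substitution_rejected_as_clustered(self, sim7, ws7):
        # the true parent SIB1 replaced by its full sibling SIB2
        r = validate_trio(sim7.genotypes, ws7, "SIB2", "B3", "XCHILD")
        assert r.verdict == "rejected_clustered"
        chroms = ws7.table["chrom"].to_numpy()
        for run in r.flagged_runs:
            assert run == list(range(run[0], run[-1] + 1))  # contiguous
            assert len(set(chroms[run])) == 1               # one chromosome

    def test_parent_swap_changes_nothing(self, sim7, ws7):
        a = validate_trio(sim7.genotypes, ws7, "A1", "A2", "QUAD1")
        b = validate_trio(sim7.genotypes, ws7, "A2", "A1", "QUAD1")
        assert a.n_informative == b.n_informative
        assert a.n_mendelian_errors == b.n_mendelian_errors
        assert a.verdict == b.verdict

    def test_overlapping_ids_rejected(self, sim7, ws7):
        with pytest.raises(ValueError, match="distinct"):
            validate_trio(sim7.genotypes, ws7, "A1", "A1", "QUAD1")

    def test_zero_informative_sites_undetermined(self):
        gm = make_matrix([[-1, 0, 1], [0, -1, 1], [1, 0, -1]] * 5)
        gmap = kp.GenomeMap.fully_nonrepetitive([("chr1", 200_000)])
        ws = kp.build_windows(gmap, 200_000)
        r = validate_trio(gm, ws, "S0", "S1", "S2")
        assert r.verdict == "undetermined"
        assert r.n_informative == 0

    def test_uniform_excess_rate_rejected_by_rate_not_clustering(self):
        # a genuine trio under exaggerated undercalling noise: errors stay
        # uniformly scattered, so rejection is by rate, never by clustering
        cfg = sim.default_config(seed=4, with_wild=False, het_to_hom_rate=0.04)
        res = sim.simulate(cfg)
        ws = kp.build_windows(res.genome)
        r = validate_trio(res.genotypes, ws, "A1", "A2", "QUAD1")
        assert r.error_rate > 0.013
        assert r.verdict == "rejected_rate"
        assert not r.flagged_runs


class TestIncompatibleRegions:
    def test_accepted_trio_has_no_regions(self, sim7, ws7):
        r = validate_trio(sim7.genotypes, ws7, "A1", "A2", "QUAD1")
        regions, fraction = incompatible_regions(r, ws7, sim7.genome)
        assert len(regions) == 0 and fraction == 0.0

    def test_regions_match_runs_and_fractions_add(self, sim7, ws7):
        r = validate_trio(sim7.genotypes, ws7, "SIB2", "B3", "XCHILD")
        regions, fraction = incompatible_regions(r, ws7, sim7.genome)
        assert len(regions) == len(r.flagged_runs) > 0
        total = sim7.genome.nonrepetitive_total()
        assert fraction == pytest.approx(regions["nonrep_bp"].sum() / total)
        spans = ws7.table["nonrep_span"].to_numpy()
        for run, row in zip(r.flagged_runs, regions.itertuples(index=False)):
            assert row.nonrep_bp == spans[run].sum()
            assert row.n_windows == len(run)


class TestSearchTrios:
    def test_recovers_exactly_the_planted_trios(self, recovery_sweep):
        for rep in recovery_sweep:
            accepted = {(r.f, r.p1, r.p2) for r in rep["accepted"]}
            assert accepted == rep["res"].truth.trio_set()

    def test_full_sibs_from_shared_parent_pairs(self, recovery_sweep):
        for rep in recovery_sweep:
            assert set(rep["sibs"]) == set(rep["res"].truth.full_sib_pairs)

    def test_single_partner_accession_not_tested_as_offspring(self, sim7, ws7):
        from kinpipe.ibd_relatedness import PairIBDProfile

        def po(a, b):
            return PairIBDProfile(a=a, b=b, states=np.empty(0, dtype=np.int8),
                                  f_ibd0=0.0, f_ibd1=1.0, f_ibd2=0.0,
                                  longest_ibd0_bp=0, n_informative_windows=200,
                                  call="parent_offspring")

        _, _, reports = search_trios(sim7.genotypes, ws7, [po("B1", "DUO1")])
        assert reports == []

    def test_exhaustive_mode_tests_arbitrary_candidates(self, sim7, ws7):
        # false-pedigree triangle: B1 and QUAD1 are both PO with GEN2, but
        # combinations replacing one with a non-parent must all fail
        cands = [("B2", "QUAD1", "GEN2"), ("B1", "QUAD2", "GEN2"),
                 ("DUO1", "QUAD1", "GEN2")]
        accepted, _, reports = search_trios(sim7.genotypes, ws7, [],
                                            extra_candidates=cands)
        assert len(reports) == 3
        assert accepted == []

    def test_quartet_yields_six_sib_pairs(self, sim7, ws7, profiles7):
        accepted, sibs, _ = search_trios(sim7.genotypes, ws7, profiles7)
        quartet_sibs = [p for p in sibs if set(p) <= {"QUAD1", "QUAD2",
                                                      "QUAD3", "QUAD4"}]
        assert len(quartet_sibs) == 6

    def test_infer_full_sibs_combinatorics(self):
        from kinpipe.trio_validation import TrioReport

        def rep(f, p1, p2):
            return TrioReport(p1=p1, p2=p2, f=f, n_informative=1,
                              n_mendelian_errors=0, error_rate=0.0,
                              window_errors=np.empty(0, dtype=int),
                              window_informative=np.empty(0, dtype=int),
                              flagged_windows=np.empty(0, dtype=int),
                              flagged_runs=[], verdict="accepted")

        trios = [rep(f, "P", "Q") for f in "ABCD"] + [rep("E", "P", "R")]
        sibs = infer_full_sibs(trios)
        assert len(sibs) == 6
        assert ("A", "E") not in sibs


def test_trios_table_columns(sim7, ws7):
    r = validate_trio(sim7.genotypes, ws7, "A1", "A2", "QUAD1")
    df = trios_table([r])
    assert df.loc[0, "verdict"] == "accepted"
    assert df.loc[0, "n_informative"] == r.n_informative
    track = window_error_track(r, ws7)
    assert track["n_errors"].sum() == r.n_mendelian_errors
    assert len(track) == ws7.n_windows
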