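"""Parent-offspring trio validation via Mendelian-inconsistency modelling.

A candidate trio P1 × P2 → F is tested at every biallelic site informative
(non-missing) in all three individuals.  A site is compatible when the two
alleles of F can be split so that one is attributable to P1 and the other
to P2; the 27 ordered genotype triples partition into 15 compatible and 12
incompatible combinations.

Because reduced-coverage genotyping undercalls heterozygotes, genuine
trios show a background of unmatching sites (on the order of 1% of
informative sites) scattered uniformly along the genome.  A false pedigree
instead concentrates unmatching sites in the contiguous chromosomal
segments where the offspring's true haplotype is absent from the putative
parent.  The verdict therefore combines two tests:

* rate — reject when the genome-wide inconsistency rate exceeds
  ``max_rate`` (default 1.3%),
* clustering — flag windows whose error count exceeds the Bonferroni-
  corrected upper binomial tail under the genome-wide rate, and reject when
  ``run_min`` (default 3) consecutive windows are flagged.

A trio passing both is accepted.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genotype_io import GenomeMap, GenotypeMatrix, WindowSet, assign_sites_to_windows
from .ibd_relatedness import PairIBDProfile

GENO_SYMBOL = {0: "aa", 1: "ab", 2: "bb"}


@dataclass
class TrioParams:
    max_rate: float = 0.013   # genome-wide Mendelian-inconsistency ceiling
    alpha_w: float = 0.05     # family-wise one-sided level for window flagging
    run_min: int = 3          # consecutive flagged windows forcing rejection


@dataclass
class TrioReport:
    p1: str
    p2: str
    f: str
    n_informative: int
    n_mendelian_errors: int
    error_rate: float
    window_errors: np.ndarray      # per-window inconsistency counts
    window_informative: np.ndarray  # per-window informative-site counts
    flagged_windows: np.ndarray    # indices of windows with excess errors
    flagged_runs: list[list[int]]  # maximal runs of >= run_min consecutive flagged windows
    verdict: str                   # accepted | rejected_rate | rejected_clustered | undetermined


# ---------------------------------------------------------------------------
# Compatibility table
# ---------------------------------------------------------------------------

def build_compatibility_table() -> np.ndarray:
    """Boolean table over ordered triples (gP1, gP2, gF) in {0,1,2}^3.

    Derived from first principles: F's two alleles must be attributable to
    distinct parents — some ordering (u, v) of F's alleles has u among P1's
    alleles and v among P2's.
    """
    alleles = {0: (0, 0), 1: (0, 1), 2: (1, 1)}
    table = np.zeros((3, 3, 3), dtype=bool)
    for g1, g2, gf in itertools.product(range(3), repeat=3):
        fa, fb = alleles[gf]
        ok = ((fa in alleles[g1] and fb in alleles[g2])
              or (fb in alleles[g1] and fa in alleles[g2]))
        table[g1, g2, gf] = ok
    return table


_COMPAT = build_compatibility_table()


def compatibility_lists() -> tuple[list[str], list[str]]:
    """The table as 'aa×ab→ab'-style strings (compatible, incompatible)."""
    compat, incompat = [], []
    for g1, g2, gf in itertools.product(range(3), repeat=3):
        s = f"{GENO_SYMBOL[g1]}×{GENO_SYMBOL[g2]}→{GENO_SYMBOL[gf]}"
        (compat if _COMPAT[g1, g2, gf] else incompat).append(s)
    return compat, incompat


# ---------------------------------------------------------------------------
# Single-trio test
# ---------------------------------------------------------------------------

def test_trio(gm: GenotypeMatrix, ws: WindowSet, p1: str, p2: str, f: str,
              params: TrioParams = TrioParams(),
              widx: np.ndarray | None = None) -> TrioReport:
    """Validate one candidate trio; see the module docstring for the tests."""
    if len({p1, p2, f}) != 3:
        raise ValueError(f"trio members must be distinct: {p1}, {p2}, {f}")
    if widx is None:
        widx = assign_sites_to_windows(gm, ws)
    g1, g2, gf = gm.column(p1), gm.column(p2), gm.column(f)
    informative = (g1 >= 0) & (g2 >= 0) & (gf >= 0) & (widx >= 0)
    n_inf = int(informative.sum())
    nw = ws.n_windows
    if n_inf == 0:
        return TrioReport(p1, p2, f, 0, 0, float("nan"),
                          np.zeros(nw, dtype=int), np.zeros(nw, dtype=int),
                          np.array([], dtype=int), [], "undetermined")
    err = ~_COMPAT[g1[informative], g2[informative], gf[informative]]
    w = widx[informative]
    window_err = np.bincount(w[err], minlength=nw)
    window_n = np.bincount(w, minlength=nw)
    n_err = int(err.sum())
    rate = n_err / n_inf
    # Background baseline for the clustering test: the genuine-trio noise
    # process cannot exceed max_rate, so a contaminated trio's own inflated
    # genome-wide rate is capped — otherwise the contamination it is meant
    # to localise would mask its own clusters.
    baseline = min(rate, params.max_rate)
    flagged = _flag_windows(window_err, window_n, baseline, params.alpha_w)
    runs = _flagged_runs(flagged, ws, params.run_min)
    if runs:
        verdict = "rejected_clustered"
    elif rate > params.max_rate:
        verdict = "rejected_rate"
    else:
        verdict = "accepted"
    return TrioReport(p1, p2, f, n_inf, n_err, rate, window_err, window_n,
                      flagged, runs, verdict)


def _flag_windows(window_err: np.ndarray, window_n: np.ndarray,
                  genome_rate: float, alpha_w: float) -> np.ndarray:
    """Windows whose error count exceeds the Bonferroni-corrected one-sided
    binomial upper tail under the genome-wide rate."""
    informative = window_n > 0
    n_tests = int(informative.sum())
    if n_tests == 0 or genome_rate == 0:
        return np.array([], dtype=int)
    # P(X >= k) under Binomial(n_w, rate); sf(k-1) == P(X >= k)
    pvals = stats.binom.sf(window_err - 1, window_n, genome_rate)
    hit = informative & (window_err > 0) & (pvals < alpha_w / n_tests)
    return np.flatnonzero(hit)


def _flagged_runs(flagged: np.ndarray, ws: WindowSet, run_min: int) -> list[list[int]]:
    """Maximal runs of >= run_min consecutive flagged windows, same chromosome."""
    if len(flagged) == 0:
        return []
    chroms = ws.table["chrom"].to_numpy()
    runs, current = [], [int(flagged[0])]
    for i in flagged[1:]:
        i = int(i)
        if i == current[-1] + 1 and chroms[i] == chroms[current[-1]]:
            current.append(i)
        else:
            runs.append(current)
            current = [i]
    runs.append(current)
    return [r for r in runs if len(r) >= run_min]


def incompatible_regions(report: TrioReport, ws: WindowSet,
                         genome: GenomeMap) -> tuple[pd.DataFrame, float]:
    """Merge flagged runs into genomic intervals.

    Returns a table (chrom, start, end, n_windows, nonrep_bp) and the
    cumulative non-repetitive bp of the intervals as a fraction of the
    genome's non-repetitive total.
    """
    rows = []
    spans = ws.table["nonrep_span"].to_numpy()
    for run in report.flagged_runs:
        start, end, chrom = ws.physical_span(run)
        rows.append({"chrom": chrom, "start": start, "end": end,
                     "n_windows": len(run), "nonrep_bp": int(spans[run].sum())})
    regions = pd.DataFrame(rows, columns=["chrom", "start", "end", "n_windows", "nonrep_bp"])
    total = genome.nonrepetitive_total()
    fraction = float(regions["nonrep_bp"].sum() / total) if total else 0.0
    return regions, fraction


# ---------------------------------------------------------------------------
# Trio search and full-sib inference
# ---------------------------------------------------------------------------

def search_trios(gm: GenotypeMatrix, ws: WindowSet,
                 pair_calls: list[PairIBDProfile],
                 params: TrioParams = TrioParams(),
                 extra_candidates: list[tuple[str, str, str]] | None = None,
                 ) -> tuple[list[TrioReport], list[tuple[str, str]], list[TrioReport]]:
    """Test every candidate trio implied by the pairwise PO calls.

    For each accession F, every unordered pair of F's parent_offspring
    partners is tested as (P1, P2) -> F.  `extra_candidates` lists (p1, p2, f)
    triples to test exhaustively regardless of the pair pre-filtering — the
    procedure used to re-examine a contested pedigree against arbitrary
    parent combinations.

    Returns (accepted trios, full-sib pairs, all tested reports).
    Two accessions are full siblings iff they appear as offspring of the
    same unordered parent pair among the accepted trios.
    """
    widx = assign_sites_to_windows(gm, ws)
    partners: dict[str, set[str]] = {}
    for prof in pair_calls:
        if prof.call == "parent_offspring":
            partners.setdefault(prof.a, set()).add(prof.b)
            partners.setdefault(prof.b, set()).add(prof.a)
    reports: list[TrioReport] = []
    tested: set[tuple[str, str, str]] = set()
    for f in gm.accession_ids:
        cands = sorted(partners.get(f, ()))
        for p1, p2 in itertools.combinations(cands, 2):
            key = (min(p1, p2), max(p1, p2), f)
            if key in tested:
                continue
            tested.add(key)
            reports.append(test_trio(gm, ws, key[0], key[1], f, params, widx=widx))
    for p1, p2, f in extra_candidates or []:
        key = (min(p1, p2), max(p1, p2), f)
        if key not in tested:
            tested.add(key)
            reports.append(test_trio(gm, ws, key[0], key[1], f, params, widx=widx))
    accepted = [r for r in reports if r.verdict == "accepted"]
    full_sibs = infer_full_sibs(accepted)
    return accepted, full_sibs, reports


def infer_full_sibs(accepted: list[TrioReport]) -> list[tuple[str, str]]:
    """Full-sib pairs: offspring sharing the same unordered parent pair."""
    by_parents: dict[frozenset[str], list[str]] = {}
    for r in accepted:
        by_parents.setdefault(frozenset((r.p1, r.p2)), []).append(r.f)
    sibs = set()
    for kids in by_parents.values():
        for a, b in itertools.combinations(sorted(set(kids)), 2):
            sibs.add((a, b))
    return sorted(sibs)


def trios_table(reports: list[TrioReport]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"offspring": r.f, "parent1": r.p1, "parent2": r.p2,
          "n_informative": r.n_informative,
          "n_mendelian_errors": r.n_mendelian_errors,
          "error_rate": round(r.error_rate, 6) if r.n_informative else float("nan"),
          "n_flagged_windows": len(r.flagged_windows),
          "n_flagged_runs": len(r.flagged_runs), "verdict": r.verdict}
         for r in reports])


def window_error_track(report: TrioReport, ws: WindowSet) -> pd.DataFrame:
    """Per-window error-count track (the chromosomal-distribution plot input)."""
    flagged = np.zeros(ws.n_windows, dtype=bool)
    flagged[report.flagged_windows] = True
    return pd.DataFrame({
        "chrom": ws.table["chrom"], "start": ws.table["start"],
        "end": ws.table["end"], "n_informative": report.window_informative,
        "n_errors": report.window_errors, "flagged": flagged,
    })
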