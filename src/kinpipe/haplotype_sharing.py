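"""Reference-anchored haplotype sharing, dosage calling and population
frequencies — the crop-to-wild introgression scan.

The analysis exploits a reference accession that is homozygous for the
haplotype of interest across a chromosome arm (the white-berry haplotype
around the MybA array in the motivating system).  Because the reference is
homozygous, opposite homozygotes are fully informative without phasing: an
accession homozygous for the other allele cannot carry the reference
haplotype at that site.

The scan divides the target chromosome into ``n_windows`` equal physical
windows (coarser than, and independent of, the 200-kb IBD windows) and
labels each window per accession:

* ``shares_two``        — genotypes match the reference's homozygous
  genotype at >= t2 of sites (two copies),
* ``shares_none``       — opposite homozygotes exceed the error tolerance
  t_err (no copy),
* ``shares_one_or_two`` — otherwise (at least one copy),
* ``uninformative``     — fewer than min_sites usable sites.

Dosage at a target interval applies the same two tolerances to the sites
pooled across the target windows (pooling keeps the false-zero and
false-two probabilities independent of how many windows the target spans):
0 if the pooled opposite-homozygote fraction exceeds t_err, 2 if the
pooled genotype-match fraction reaches t2, else 1.  Population haplotype
frequency is Σdosage / (2 × called accessions).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import GenotypeMatrix

logger = logging.getLogger("kinpipe")

SHARES_NONE = 0
SHARES_ONE_OR_TWO = 1
SHARES_TWO = 2
UNINFORMATIVE = -1
SHARE_NAMES = {SHARES_NONE: "shares_none", SHARES_ONE_OR_TWO: "shares_one_or_two",
               SHARES_TWO: "shares_two", UNINFORMATIVE: "uninformative"}


@dataclass
class SharingParams:
    t_err: float = 0.02       # opposite-homozygote fraction tolerated before shares_none
    t2: float = 0.98          # genotype-match fraction required for shares_two
    min_sites: int = 10       # usable sites per scan window
    ref_hom_min: float = 0.99  # homozygosity required of the reference in the region


@dataclass
class SharingProfile:
    accession: str
    chrom: str
    window_bounds: np.ndarray   # (n_windows+1,) bp edges along the chromosome
    states: np.ndarray          # per-window share state
    n_sites: np.ndarray         # per-window informative-site counts
    n_opposite: np.ndarray      # per-window opposite-homozygote counts
    n_match: np.ndarray         # per-window genotype-match counts
    dosage_at_target: int | None   # 0/1/2 or None (undetermined)
    shared_segment: tuple[int, int] | None  # maximal sharing interval over the target

    def state_names(self) -> list[str]:
        return [SHARE_NAMES[int(s)] for s in self.states]


# ---------------------------------------------------------------------------

def verify_reference_homozygosity(gm: GenotypeMatrix, ref_id: str,
                                  chrom: str, region: tuple[int, int],
                                  params: SharingParams = SharingParams(),
                                  ) -> tuple[float, bool]:
    """Fraction of non-missing reference calls in `region` that are homozygous.

    `region` is 0-based half-open bp.  Passes iff the fraction reaches
    ``ref_hom_min`` (default 0.99).
    """
    g = gm.column(ref_id)
    s, e = region
    in_region = ((gm.sites["chrom"] == chrom)
                 & (gm.sites["pos"] - 1 >= s) & (gm.sites["pos"] - 1 < e)).to_numpy()
    calls = g[in_region]
    calls = calls[calls >= 0]
    if len(calls) == 0:
        logger.warning("no genotyped sites for %s in %s:%d-%d", ref_id, chrom, s, e)
        return float("nan"), False
    frac = float((calls != 1).mean())
    return frac, frac >= params.ref_hom_min


def sharing_scan(gm: GenotypeMatrix, ref_id: str, chrom: str,
                 n_windows: int = 50,
                 target: tuple[int, int] | None = None,
                 chrom_length: int | None = None,
                 params: SharingParams = SharingParams(),
                 skip_verification: bool = False) -> dict[str, SharingProfile]:
    """Haplotype-sharing profile of every accession against the reference.

    The scan chromosome is cut into `n_windows` equal physical windows.
    Sites where the reference is heterozygous or missing are unusable (the
    reference haplotype allele is then ambiguous) and do not count toward
    `min_sites`.  If `target` is given the reference must verify as
    homozygous across it (unless `skip_verification`), and dosage plus the
    shared segment containing the target are computed per accession.
    """
    sites_mask = (gm.sites["chrom"] == chrom).to_numpy()
    if not sites_mask.any():
        raise ValueError(f"no sites on chromosome {chrom!r}")
    pos0 = gm.sites.loc[sites_mask, "pos"].to_numpy() - 1
    length = chrom_length if chrom_length is not None else int(pos0.max()) + 1
    if target is not None and not skip_verification:
        frac, ok = verify_reference_homozygosity(gm, ref_id, chrom, target, params)
        if not ok:
            raise ValueError(
                f"reference {ref_id!r} is not homozygous across the target "
                f"(fraction {frac:.3f} < {params.ref_hom_min})")
    bounds = np.linspace(0, length, n_windows + 1)
    widx = np.clip(np.searchsorted(bounds, pos0, side="right") - 1, 0, n_windows - 1)

    ref = gm.column(ref_id)[sites_mask]
    usable = (ref == 0) | (ref == 2)   # reference homozygous and called
    profiles: dict[str, SharingProfile] = {}
    target_w = None
    if target is not None:
        ts, te = target
        target_w = np.flatnonzero((bounds[:-1] < te) & (bounds[1:] > ts))
    for acc in gm.accession_ids:
        g = gm.column(acc)[sites_mask]
        informative = usable & (g >= 0)
        w = widx[informative]
        gi, ri = g[informative], ref[informative]
        opp = ((ri == 0) & (gi == 2)) | ((ri == 2) & (gi == 0))
        match = gi == ri
        n = np.bincount(w, minlength=n_windows)
        n_opp = np.bincount(w[opp], minlength=n_windows)
        n_match = np.bincount(w[match], minlength=n_windows)
        states = np.full(n_windows, UNINFORMATIVE, dtype=np.int8)
        ok = n >= params.min_sites
        with np.errstate(invalid="ignore", divide="ignore"):
            f_opp = np.where(ok, n_opp / np.maximum(n, 1), 0)
            f_match = np.where(ok, n_match / np.maximum(n, 1), 0)
        states[ok & (f_opp > params.t_err)] = SHARES_NONE
        remaining = ok & (f_opp <= params.t_err)
        states[remaining & (f_match >= params.t2)] = SHARES_TWO
        states[remaining & (f_match < params.t2)] = SHARES_ONE_OR_TWO
        profile = SharingProfile(accession=acc, chrom=chrom,
                                 window_bounds=bounds, states=states,
                                 n_sites=n, n_opposite=n_opp, n_match=n_match,
                                 dosage_at_target=None, shared_segment=None)
        if target_w is not None:
            profile.dosage_at_target = _dosage_from_counts(
                n[target_w], n_opp[target_w], n_match[target_w], params)
            profile.shared_segment = _shared_segment(states, bounds, target_w)
        profiles[acc] = profile
    return profiles


def _dosage_from_counts(n: np.ndarray, n_opp: np.ndarray, n_match: np.ndarray,
                        params: SharingParams) -> int | None:
    """Pooled dosage rule over the target windows.

    The same tolerances that classify a window are applied to the pooled
    target sites: opposite homozygotes above t_err exclude any copy (0);
    genotype matches at t2 or more imply two copies; anything between is one
    copy.  None when no sites are informative.
    """
    total = int(n.sum())
    if total == 0:
        return None
    if n_opp.sum() / total > params.t_err:
        return 0
    if n_match.sum() / total >= params.t2:
        return 2
    return 1


def call_dosage(profile: SharingProfile, target: tuple[int, int],
                params: SharingParams = SharingParams()) -> int | None:
    """Dosage of the reference haplotype at `target` (0-based bp interval)."""
    bounds = profile.window_bounds
    ts, te = target
    target_w = np.flatnonzero((bounds[:-1] < te) & (bounds[1:] > ts))
    if len(target_w) == 0:
        raise ValueError("target interval overlaps no scan window")
    return _dosage_from_counts(profile.n_sites[target_w],
                               profile.n_opposite[target_w],
                               profile.n_match[target_w], params)


def _shared_segment(states: np.ndarray, bounds: np.ndarray,
                    target_w: np.ndarray) -> tuple[int, int] | None:
    """Maximal run of sharing (non-shares_none, informative) windows
    containing the target, as a bp interval."""
    sharing = (states == SHARES_TWO) | (states == SHARES_ONE_OR_TWO)
    anchor = [w for w in target_w if sharing[w]]
    if not anchor:
        return None
    lo = hi = anchor[0]
    while lo > 0 and sharing[lo - 1]:
        lo -= 1
    while hi < len(states) - 1 and sharing[hi + 1]:
        hi += 1
    return int(bounds[lo]), int(bounds[hi + 1])


# ---------------------------------------------------------------------------
# Population frequencies and ancestry grouping
# ---------------------------------------------------------------------------

def population_frequencies(dosages: dict[str, int | None],
                           populations: dict[str, str]) -> pd.DataFrame:
    """Per-population haplotype frequency Σdosage / (2 × called accessions).

    Accessions with undetermined (None) dosage are excluded from the
    denominator; the exclusion count is reported per population.  Empty or
    fully undetermined populations get frequency NA.
    """
    pops = sorted(set(populations.values()))
    rows = []
    for pop in pops:
        members = [a for a, p in populations.items() if p == pop and a in dosages]
        called = [dosages[a] for a in members if dosages[a] is not None]
        n_undet = len(members) - len(called)
        if n_undet:
            logger.info("population %s: %d accessions with undetermined dosage "
                        "excluded", pop, n_undet)
        freq = sum(called) / (2 * len(called)) if called else float("nan")
        rows.append({"population": pop, "n_accessions": len(members),
                     "n_called": len(called), "n_undetermined": n_undet,
                     "sum_dosage": sum(called), "frequency": freq})
    return pd.DataFrame(rows)


def assign_ancestry_groups(q_matrix: pd.DataFrame, threshold: float = 0.85) -> pd.Series:
    """Assign each accession to its majority ancestry component or 'admixed'.

    `q_matrix` rows are accessions, columns ancestry components, each row
    summing to 1 (±1e-6).  The label is the argmax component name iff its
    proportion is strictly greater than `threshold`, else 'admixed'.
    """
    labels = {}
    for acc, row in q_matrix.iterrows():
        vals = row.to_numpy(dtype=float)
        if np.any(vals < -1e-9) or abs(vals.sum() - 1.0) > 1e-6:
            raise ValueError(f"malformed Q row for accession {acc!r}: "
                             f"values {vals.tolist()} (must be >=0 and sum to 1)")
        best = int(np.argmax(vals))
        labels[acc] = q_matrix.columns[best] if vals[best] > threshold else "admixed"
    return pd.Series(labels, name="group")


def sharing_track(profiles: dict[str, SharingProfile]) -> pd.DataFrame:
    """Long-format per-window sharing states for plotting/TSV export."""
    rows = []
    for acc, prof in profiles.items():
        for i, name in enumerate(prof.state_names()):
            rows.append({"accession": acc, "chrom": prof.chrom,
                         "start": int(prof.window_bounds[i]),
                         "end": int(prof.window_bounds[i + 1]), "state": name})
    return pd.DataFrame(rows)
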