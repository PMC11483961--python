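"""Forward pedigree simulator with genotyping-error and introgression structure.

Generates diploid SNP datasets that emulate a germplasm-collection panel
genotyped on a reduced-representation (gene-targeted) platform:

* three ancestry components (two cultivated, one wild) with
  Balding–Nichols-style divergent allele frequencies,
* SNP sites clustered around simulated gene anchors rather than uniform,
* a scripted pedigree (crosses, selfs, clones) over named accessions,
* a dominant het→hom undercalling error mode (plus a minor hom→het mode at
  one tenth the rate) and missing genotypes,
* an optional "white haplotype": one fixed haplotype planted at known
  dosage per accession across a target interval, the marker used for
  crop-to-wild gene-flow detection.

Everything is driven by one seeded numpy Generator; with a fixed seed the
full output (genotypes, mask, truth files) is reproducible bit for bit.
Event order: mask → site positions → component frequencies → founders →
pedigree events in script order → haplotype planting → error model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genotype_io import (
    HET,
    HOM_ALT,
    HOM_REF,
    MISSING,
    GenomeMap,
    GenotypeMatrix,
    _write_vcf,
    write_genome_table,
    write_mask_bed,
)

# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

DEFAULT_CHROMOSOMES: list[tuple[str, int]] = [(f"chr{i}", 10_000_000) for i in range(1, 6)]


@dataclass
class PedigreeEvent:
    """One step of the pedigree script: 'cross', 'self' or 'clone'."""

    kind: str                 # cross | self | clone
    child: str
    parent1: str
    parent2: str | None = None  # None for self/clone

    def parents(self) -> list[str]:
        if self.kind == "cross":
            return [self.parent1, self.parent2]
        if self.kind == "self":
            return [self.parent1, self.parent1]
        return [self.parent1]


@dataclass
class PlantedHaplotype:
    """A fixed haplotype planted across `interval` at known per-accession dosage.

    `reference` always carries two copies; `dosages` maps further accession
    ids to 1 or 2 copies.  The haplotype itself is drawn once from the first
    cultivated component's allele frequencies.
    """

    chrom: str
    interval: tuple[int, int]     # 0-based half-open, bp
    reference: str
    dosages: dict[str, int] = field(default_factory=dict)


@dataclass
class SimConfig:
    seed: int = 7
    chromosomes: list[tuple[str, int]] = field(default_factory=lambda: list(DEFAULT_CHROMOSOMES))
    n_sites: int = 20_000
    founders: dict[str, list[str]] = field(default_factory=dict)   # component -> founder ids
    fst: dict[str, float] = field(default_factory=lambda: {"cult1": 0.05, "cult2": 0.05, "wild": 0.20})
    pedigree: list[PedigreeEvent] = field(default_factory=list)
    # Crossovers per Mb per meiosis. Chosen to preserve the genome-wide
    # genetic length of a grapevine-like organism (~1300-1500 cM ≈ 26-30
    # crossovers per meiosis) on the scaled-down 50-Mb desk genome: with
    # fewer chromosomes, per-chromosome realism would leave too few
    # independent segments and inflate the variance of genome-wide IBD
    # fractions relative to the system being emulated.
    recomb_rate: float = 0.6
    het_to_hom_rate: float = 0.01     # dominant undercalling error mode
    genotype_missing_rate: float = 0.02
    repeat_fraction: float = 0.1      # fraction of each chromosome masked as repetitive
    genes_per_mb: float = 40.0        # density of gene anchors attracting SNP sites
    site_jitter_bp: int = 2_000       # sd of site offsets around their gene anchor
    planted: PlantedHaplotype | None = None
    populations: dict[str, str] = field(default_factory=dict)      # accession -> population

    def __post_init__(self) -> None:
        for name, r in (("het_to_hom_rate", self.het_to_hom_rate),
                        ("genotype_missing_rate", self.genotype_missing_rate),
                        ("repeat_fraction", self.repeat_fraction)):
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {r}")
        if self.recomb_rate < 0:
            raise ValueError("recomb_rate must be >= 0")
        _check_script(self.founders, self.pedigree)


def _check_script(founders: dict[str, list[str]], events: list[PedigreeEvent]) -> None:
    known = {a for ids in founders.values() for a in ids}
    if len(known) != sum(len(v) for v in founders.values()):
        raise ValueError("founder ids are not unique")
    for ev in events:
        for p in ev.parents():
            if p not in known:
                raise ValueError(f"event for {ev.child!r} names unknown parent {p!r}")
        if ev.child in known:
            raise ValueError(f"accession id {ev.child!r} defined twice")
        known.add(ev.child)


@dataclass
class TruthSet:
    """Ground truth emitted alongside the simulated genotypes.

    Parent-offspring and full-sib relations are closed over clone
    equivalence: a clone inherits every genotypic relationship of its
    source, because the two are indistinguishable at the genotype level.
    """

    po_pairs: list[tuple[str, str]]            # oriented (parent, offspring)
    trios: list[tuple[str, str, str]]          # (offspring, parent1, parent2), parents sorted
    full_sib_pairs: list[tuple[str, str]]      # unordered, stored sorted
    clone_pairs: list[tuple[str, str]]         # unordered, stored sorted
    dosages: dict[str, int]                    # planted-haplotype copies per accession
    ancestry: pd.DataFrame                     # accession × component proportions

    def po_set(self) -> set[tuple[str, str]]:
        return set(self.po_pairs)

    def po_unordered(self) -> set[frozenset[str]]:
        return {frozenset(p) for p in self.po_pairs}

    def trio_set(self) -> set[tuple[str, str, str]]:
        return set(self.trios)


@dataclass
class SimResult:
    config: SimConfig
    genome: GenomeMap
    genotypes: GenotypeMatrix          # with error model applied
    truth_genotypes: GenotypeMatrix    # error-free
    haplotypes: dict[str, np.ndarray]  # accession -> (2, M) uint8 phased truth
    truth: TruthSet


# ---------------------------------------------------------------------------
# Default pedigree script (the study-like panel)
# ---------------------------------------------------------------------------

def default_config(seed: int = 7, with_wild: bool = True, **overrides) -> SimConfig:
    """The default desk-scale panel used throughout the test battery.

    Cultivated founders A1–A4 (component cult1) and B1–B4 (cult2); a
    four-offspring quartet from one recurrent founder pair (A1×A2), a
    two-offspring pair (B1×B2), a second-generation cross, a full-sib pair
    whose sibling seeds the false-pedigree scenario, and a clone of a
    childless wild founder.  With `with_wild`, four wild populations of six
    accessions each carry a planted white haplotype on chr2 at frequencies
    echoing a crop-to-wild introgression gradient.
    """
    founders = {
        "cult1": ["A1", "A2", "A3", "A4"],
        "cult2": ["B1", "B2", "B3", "B4"],
    }
    pedigree = [
        PedigreeEvent("cross", "QUAD1", "A1", "A2"),
        PedigreeEvent("cross", "QUAD2", "A1", "A2"),
        PedigreeEvent("cross", "QUAD3", "A1", "A2"),
        PedigreeEvent("cross", "QUAD4", "A1", "A2"),
        PedigreeEvent("cross", "DUO1", "B1", "B2"),
        PedigreeEvent("cross", "DUO2", "B1", "B2"),
        PedigreeEvent("cross", "GEN2", "B1", "QUAD1"),
        PedigreeEvent("cross", "SIB1", "A3", "A4"),
        PedigreeEvent("cross", "SIB2", "A3", "A4"),
        PedigreeEvent("cross", "XCHILD", "SIB1", "B3"),
    ]
    populations = {a: "cultivated" for a in
                   ["A1", "A2", "A3", "A4", "B1", "B2", "B3", "B4",
                    "QUAD1", "QUAD2", "QUAD3", "QUAD4", "DUO1", "DUO2",
                    "GEN2", "SIB1", "SIB2", "XCHILD"]}
    planted = None
    if with_wild:
        wild_ids = []
        pop_sizes = {"Cerovica": 6, "ModroJezero": 6, "Psunj": 6, "Paklenica": 6}
        for pop, n in pop_sizes.items():
            for k in range(1, n + 1):
                wid = f"W_{pop}_{k}"
                wild_ids.append(wid)
                populations[wid] = pop
        founders["wild"] = wild_ids
        pedigree.append(PedigreeEvent("clone", "W_Cerovica_1_CLONE", "W_Cerovica_1"))
        populations["W_Cerovica_1_CLONE"] = "Cerovica"
        # introgression gradient: Σdosage / (2 n) = 1/12, 2/12, 2/12, 5/12
        dosages = {"W_Cerovica_2": 1,
                   "W_ModroJezero_1": 1, "W_ModroJezero_2": 1,
                   "W_Psunj_1": 1, "W_Psunj_2": 1,
                   "W_Paklenica_1": 2, "W_Paklenica_2": 1,
                   "W_Paklenica_3": 1, "W_Paklenica_4": 1}
        planted = PlantedHaplotype(chrom="chr2", interval=(6_000_000, 9_000_000),
                                   reference="B4", dosages=dosages)
    cfg = SimConfig(seed=seed, founders=founders, pedigree=pedigree,
                    planted=planted, populations=populations)
    for key, val in overrides.items():
        setattr(cfg, key, val)
    return cfg


def frequency_recovery_config(freq: float, seed: int, n_accessions: int = 25,
                              ) -> SimConfig:
    """Config for the haplotype-frequency recovery experiment.

    One wild population of `n_accessions` carries the planted haplotype at
    (as near as integer copies allow) frequency `freq`; copies are planted
    mostly in heterozygous condition, as introgressed haplotypes appear in
    wild populations.  A homozygous cultivated reference anchors the scan.
    The genome is two 8-Mb chromosomes with the target interval on chr2.
    """
    if not 0 <= freq <= 1:
        raise ValueError("freq must be in [0,1]")
    wild_ids = [f"W{i}" for i in range(1, n_accessions + 1)]
    total = round(2 * n_accessions * freq)
    dosages: dict[str, int] = {}
    for i, wid in enumerate(wild_ids):
        if total <= 0:
            break
        d = 2 if total > n_accessions - i else 1
        dosages[wid] = d
        total -= d
    populations = {w: "wild" for w in wild_ids}
    populations.update({"REF": "cultivated", "C1": "cultivated", "C2": "cultivated"})
    return SimConfig(
        seed=seed,
        chromosomes=[("chr1", 8_000_000), ("chr2", 8_000_000)],
        n_sites=6_400,
        founders={"cult1": ["REF", "C1", "C2"], "wild": wild_ids},
        planted=PlantedHaplotype(chrom="chr2", interval=(3_000_000, 6_000_000),
                                 reference="REF", dosages=dosages),
        populations=populations,
    )


# ---------------------------------------------------------------------------
# Simulation primitives
# ---------------------------------------------------------------------------

def _simulate_mask(cfg: SimConfig, rng: np.random.Generator) -> GenomeMap:
    """Mask a `repeat_fraction` of each chromosome as repetitive blocks."""
    nonrep: dict[str, list[tuple[int, int]]] = {}
    for chrom, length in cfg.chromosomes:
        if cfg.repeat_fraction <= 0:
            nonrep[chrom] = [(0, length)]
            continue
        n_blocks = 8
        block = int(length * cfg.repeat_fraction / n_blocks)
        starts = np.sort(rng.integers(0, length - block, size=n_blocks))
        repeats = [(int(s), int(s) + block) for s in starts]
        # complement of (possibly overlapping) repeat blocks
        merged: list[tuple[int, int]] = []
        for s, e in repeats:
            if merged and s <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], e))
            else:
                merged.append((s, e))
        ivs, cursor = [], 0
        for s, e in merged:
            if s > cursor:
                ivs.append((cursor, s))
            cursor = max(cursor, e)
        if cursor < length:
            ivs.append((cursor, length))
        nonrep[chrom] = ivs
    return GenomeMap(list(cfg.chromosomes), nonrep)


def _simulate_sites(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Gene-anchored site placement: SNPs cluster near gene positions."""
    total_len = sum(l for _, l in cfg.chromosomes)
    per_chrom = [max(1, round(cfg.n_sites * l / total_len)) for _, l in cfg.chromosomes]
    # adjust rounding so counts sum exactly to n_sites
    while sum(per_chrom) > cfg.n_sites:
        per_chrom[int(np.argmax(per_chrom))] -= 1
    while sum(per_chrom) < cfg.n_sites:
        per_chrom[int(np.argmin(per_chrom))] += 1
    frames = []
    for (chrom, length), n in zip(cfg.chromosomes, per_chrom):
        n_genes = max(1, int(cfg.genes_per_mb * length / 1e6))
        anchors = rng.uniform(0, length, size=n_genes)
        chosen = rng.integers(0, n_genes, size=n * 3)
        pos = anchors[chosen] + rng.normal(0, cfg.site_jitter_bp, size=n * 3)
        pos = np.unique(np.clip(pos, 1, length).astype(np.int64))
        if len(pos) > n:
            pos = np.sort(rng.choice(pos, size=n, replace=False))
        frames.append(pd.DataFrame({"chrom": chrom, "pos": pos}))
    sites = pd.concat(frames, ignore_index=True)
    m = len(sites)
    ref = rng.choice(list("ACGT"), size=m)
    shift = rng.integers(1, 4, size=m)
    bases = np.array(list("ACGT"))
    base_idx = {b: i for i, b in enumerate(bases)}
    alt = bases[(np.vectorize(base_idx.get)(ref) + shift) % 4]
    sites["ref"] = ref
    sites["alt"] = alt
    return sites


def simulate_founders(cfg: SimConfig, sites: pd.DataFrame,
                      rng: np.random.Generator) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Draw per-component allele frequencies and phased founder haplotypes.

    Component frequencies follow the Balding–Nichols model: an ancestral
    frequency p ~ U(0.05, 0.95) per site, and each component draws its own
    frequency from Beta(p(1-F)/F, (1-p)(1-F)/F) with F the component's
    divergence parameter.  Each founder haplotype samples alleles
    independently per site from its component's frequencies.

    Returns (haplotypes, component_freqs); haplotypes maps accession id to a
    (2, M) uint8 array of alt-allele indicators.
    """
    m = len(sites)
    p_anc = rng.uniform(0.05, 0.95, size=m)
    freqs: dict[str, np.ndarray] = {}
    for comp in cfg.founders:
        f = cfg.fst.get(comp, 0.1)
        if f <= 0:
            freqs[comp] = p_anc.copy()
        else:
            a = p_anc * (1 - f) / f
            b = (1 - p_anc) * (1 - f) / f
            freqs[comp] = rng.beta(a, b)
    haplotypes: dict[str, np.ndarray] = {}
    for comp, ids in cfg.founders.items():
        for acc in ids:
            haplotypes[acc] = (rng.random((2, m)) < freqs[comp]).astype(np.uint8)
    return haplotypes, freqs


def simulate_meiosis(parent_haps: np.ndarray, sites: pd.DataFrame,
                     chromosomes: list[tuple[str, int]], recomb_rate: float,
                     rng: np.random.Generator) -> np.ndarray:
    """One gamete from a (2, M) phased parent.

    Per chromosome the crossover count is Poisson(recomb_rate × length-Mb),
    breakpoints are uniform, and the gamete alternates between the two
    parental haplotypes at each breakpoint, starting from a random one.
    """
    m = parent_haps.shape[1]
    gamete = np.empty(m, dtype=np.uint8)
    chrom_arr = sites["chrom"].to_numpy()
    pos_arr = sites["pos"].to_numpy()
    for chrom, length in chromosomes:
        mask = chrom_arr == chrom
        if not mask.any():
            continue
        n_co = rng.poisson(recomb_rate * length / 1e6)
        breaks = np.sort(rng.uniform(0, length, size=n_co))
        start = rng.integers(0, 2)
        seg = np.searchsorted(breaks, pos_arr[mask])
        use = (start + seg) % 2
        gamete[mask] = parent_haps[:, mask][use, np.arange(mask.sum())]
    return gamete


def _run_pedigree(cfg: SimConfig, sites: pd.DataFrame,
                  haplotypes: dict[str, np.ndarray], rng: np.random.Generator) -> None:
    for ev in cfg.pedigree:
        if ev.kind == "clone":
            haplotypes[ev.child] = haplotypes[ev.parent1].copy()
        elif ev.kind in ("cross", "self"):
            p2 = ev.parent1 if ev.kind == "self" else ev.parent2
            g1 = simulate_meiosis(haplotypes[ev.parent1], sites, cfg.chromosomes,
                                  cfg.recomb_rate, rng)
            g2 = simulate_meiosis(haplotypes[p2], sites, cfg.chromosomes,
                                  cfg.recomb_rate, rng)
            haplotypes[ev.child] = np.stack([g1, g2])
        else:
            raise ValueError(f"unknown pedigree event kind: {ev.kind!r}")


def plant_haplotype(cfg: SimConfig, sites: pd.DataFrame,
                    haplotypes: dict[str, np.ndarray], freqs: dict[str, np.ndarray],
                    rng: np.random.Generator) -> dict[str, int]:
    """Overwrite carrier haplotypes with the fixed planted haplotype.

    Returns the dosage truth (0 for accessions not named as carriers).
    """
    planted = cfg.planted
    if planted is None:
        return {acc: 0 for acc in haplotypes}
    lengths = dict(cfg.chromosomes)
    if planted.chrom not in lengths:
        raise ValueError(f"planted haplotype chromosome {planted.chrom!r} not in genome")
    s, e = planted.interval
    if not (0 <= s < e <= lengths[planted.chrom]):
        raise ValueError(f"planted interval {planted.interval} outside chromosome bounds")
    in_iv = ((sites["chrom"] == planted.chrom)
             & (sites["pos"] - 1 >= s) & (sites["pos"] - 1 < e)).to_numpy()
    comp0 = next(iter(cfg.founders))
    hap = (rng.random(int(in_iv.sum())) < freqs[comp0][in_iv]).astype(np.uint8)
    dosages = {acc: 0 for acc in haplotypes}
    all_carriers = dict(planted.dosages)
    all_carriers[planted.reference] = 2
    for acc, d in all_carriers.items():
        if acc not in haplotypes:
            raise ValueError(f"planted carrier {acc!r} is not a simulated accession")
        if d not in (1, 2):
            raise ValueError(f"dosage for {acc!r} must be 1 or 2, got {d}")
        for copy_i in range(d):
            haplotypes[acc][copy_i, in_iv] = hap
        dosages[acc] = d
    return dosages


def apply_error_model(truth: GenotypeMatrix, cfg: SimConfig,
                      rng: np.random.Generator) -> GenotypeMatrix:
    """Apply het→hom undercalling, minor hom→het noise, and missingness.

    Each HET flips to a random matching HOM with probability
    `het_to_hom_rate`; each HOM becomes HET at one tenth of that rate; each
    call is independently set MISSING with `genotype_missing_rate`.
    """
    calls = truth.calls.copy()
    if cfg.het_to_hom_rate > 0:
        het = calls == HET
        flip = het & (rng.random(calls.shape) < cfg.het_to_hom_rate)
        target = rng.integers(0, 2, size=calls.shape).astype(np.int8) * 2  # 0 or 2
        calls[flip] = target[flip]
        hom = (calls == HOM_REF) | (calls == HOM_ALT)
        hom &= ~flip  # do not re-touch the calls just flipped
        flip2 = hom & (rng.random(calls.shape) < cfg.het_to_hom_rate / 10.0)
        calls[flip2] = HET
    if cfg.genotype_missing_rate > 0:
        miss = rng.random(calls.shape) < cfg.genotype_missing_rate
        calls[miss] = MISSING
    return GenotypeMatrix(list(truth.accession_ids), truth.sites.copy(), calls)


# ---------------------------------------------------------------------------
# Truth bookkeeping
# ---------------------------------------------------------------------------

def _build_truth(cfg: SimConfig, dosages: dict[str, int],
                 accession_ids: list[str]) -> TruthSet:
    clone_of: dict[str, str] = {}
    for ev in cfg.pedigree:
        if ev.kind == "clone":
            # resolve chains: clone of a clone points at the original
            clone_of[ev.child] = clone_of.get(ev.parent1, ev.parent1)

    def variants(acc: str) -> list[str]:
        """The accession plus every clone genotypically identical to it."""
        root = clone_of.get(acc, acc)
        return [a for a in accession_ids if clone_of.get(a, a) == root]

    po: set[tuple[str, str]] = set()
    trios: set[tuple[str, str, str]] = set()
    parents_of: dict[str, tuple[str, str]] = {}
    for ev in cfg.pedigree:
        if ev.kind == "clone":
            continue
        p1, p2 = ev.parents()
        parents_of[ev.child] = tuple(sorted((p1, p2)))
        for parent in {p1, p2}:
            for pv in variants(parent):
                for cv in variants(ev.child):
                    po.add((pv, cv))
        for a in variants(p1):
            for b in variants(p2):
                for cv in variants(ev.child):
                    pa, pb = sorted((a, b))
                    trios.add((cv, pa, pb))
    sibs: set[tuple[str, str]] = set()
    kids = list(parents_of)
    for i, c1 in enumerate(kids):
        for c2 in kids[i + 1:]:
            if parents_of[c1] == parents_of[c2]:
                for a in variants(c1):
                    for b in variants(c2):
                        sibs.add(tuple(sorted((a, b))))
    clones = {tuple(sorted((c, o))) for c, o in clone_of.items()}
    # expected ancestry proportions: founders one-hot, offspring = parent mean
    comps = list(cfg.founders)
    anc: dict[str, np.ndarray] = {}
    for ci, comp in enumerate(comps):
        for acc in cfg.founders[comp]:
            v = np.zeros(len(comps))
            v[ci] = 1.0
            anc[acc] = v
    for ev in cfg.pedigree:
        if ev.kind == "clone":
            anc[ev.child] = anc[ev.parent1].copy()
        else:
            p1, p2 = ev.parents()
            anc[ev.child] = (anc[p1] + anc[p2]) / 2
    ancestry = pd.DataFrame({acc: anc[acc] for acc in accession_ids},
                            index=comps).T
    return TruthSet(po_pairs=sorted(po), trios=sorted(trios),
                    full_sib_pairs=sorted(sibs), clone_pairs=sorted(clones),
                    dosages=dosages, ancestry=ancestry)


# ---------------------------------------------------------------------------
# Top-level driver
# ---------------------------------------------------------------------------

def simulate(cfg: SimConfig) -> SimResult:
    """Run the full simulation pipeline for one config."""
    rng = np.random.default_rng(cfg.seed)
    genome = _simulate_mask(cfg, rng)
    sites = _simulate_sites(cfg, rng)
    haplotypes, freqs = simulate_founders(cfg, sites, rng)
    _run_pedigree(cfg, sites, haplotypes, rng)
    dosages = plant_haplotype(cfg, sites, haplotypes, freqs, rng)
    accession_ids = list(haplotypes)
    calls = np.column_stack([haplotypes[a].sum(axis=0) for a in accession_ids]).astype(np.int8)
    truth_gm = GenotypeMatrix(accession_ids, sites.copy(), calls)
    observed = apply_error_model(truth_gm, cfg, rng)
    truth = _build_truth(cfg, dosages, accession_ids)
    return SimResult(config=cfg, genome=genome, genotypes=observed,
                     truth_genotypes=truth_gm, haplotypes=haplotypes, truth=truth)


def write_outputs(result: SimResult, outdir: str | Path) -> dict[str, Path]:
    """Write genotypes.vcf, mask.bed, genome.tsv, truth and population tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = result.config
    paths = {
        "genotypes": outdir / "genotypes.vcf",
        "genome": outdir / "genome.tsv",
        "mask": outdir / "mask.bed",
        "truth_pairs": outdir / "truth_pairs.tsv",
        "truth_trios": outdir / "truth_trios.tsv",
        "truth_sibs": outdir / "truth_sibs.tsv",
        "truth_clones": outdir / "truth_clones.tsv",
        "truth_dosage": outdir / "truth_dosage.tsv",
        "q_matrix": outdir / "q_truth.tsv",
        "pops": outdir / "pops.tsv",
    }
    _write_vcf(result.genotypes, paths["genotypes"], contigs=cfg.chromosomes)
    write_genome_table(cfg.chromosomes, paths["genome"])
    write_mask_bed(result.genome.nonrepetitive, paths["mask"])
    t = result.truth
    pd.DataFrame(t.po_pairs, columns=["parent", "offspring"]).to_csv(
        paths["truth_pairs"], sep="\t", index=False)
    pd.DataFrame(t.trios, columns=["offspring", "parent1", "parent2"]).to_csv(
        paths["truth_trios"], sep="\t", index=False)
    pd.DataFrame(t.full_sib_pairs, columns=["a", "b"]).to_csv(
        paths["truth_sibs"], sep="\t", index=False)
    pd.DataFrame(t.clone_pairs, columns=["a", "b"]).to_csv(
        paths["truth_clones"], sep="\t", index=False)
    pd.DataFrame(sorted(t.dosages.items()), columns=["accession", "dosage"]).to_csv(
        paths["truth_dosage"], sep="\t", index=False)
    t.ancestry.rename_axis("accession").to_csv(paths["q_matrix"], sep="\t")
    pd.DataFrame(sorted(cfg.populations.items()), columns=["accession", "population"]).to_csv(
        paths["pops"], sep="\t", index=False)
    return paths
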