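"""Genotype and genome-annotation I/O, plus the masked window system.

This module defines the three containers every downstream analysis shares:

* :class:`GenotypeMatrix` — accessions × biallelic SNP sites with unphased
  genotype codes,
* :class:`GenomeMap` — chromosome lengths plus the non-repetitive
  (repeat-masked complement) intervals,
* :class:`WindowSet` — the tiling of each chromosome into windows that each
  contain a fixed span (default 200 kb) of non-repetitive sequence.

Coordinate conventions: VCF positions are 1-based; internal intervals,
windows and the BED mask are 0-based half-open.  Phase information present
in input VCFs is discarded — all downstream statistics are genotype-based.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("kinpipe")

# Genotype codes (int8). MISSING sorts below the valid codes on purpose so
# that `calls >= 0` selects non-missing entries.
HOM_REF = 0
HET = 1
HOM_ALT = 2
MISSING = -1

_TSV_CODE = {0: "0", 1: "1", 2: "2", -1: "."}
_TSV_DECODE = {"0": 0, "1": 1, "2": 2, ".": -1}


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """Unphased biallelic genotypes for N accessions at M sites.

    Parameters
    ----------
    accession_ids
        Unique accession names, order fixes the column order of `calls`.
    sites
        DataFrame with columns ``chrom``, ``pos`` (1-based), ``ref``, ``alt``,
        sorted by (chrom, pos) with positions strictly increasing within a
        chromosome.
    calls
        int8 array of shape (M, N) over {HOM_REF, HET, HOM_ALT, MISSING}.
    """

    accession_ids: list[str]
    sites: pd.DataFrame
    calls: np.ndarray

    def __post_init__(self) -> None:
        if len(set(self.accession_ids)) != len(self.accession_ids):
            dupes = sorted({a for a in self.accession_ids if self.accession_ids.count(a) > 1})
            raise ValueError(f"duplicate accession ids: {dupes}")
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.sites), len(self.accession_ids)):
            raise ValueError(
                f"calls shape {self.calls.shape} != (n_sites={len(self.sites)}, "
                f"n_accessions={len(self.accession_ids)})"
            )
        valid = np.isin(self.calls, (HOM_REF, HET, HOM_ALT, MISSING))
        if not valid.all():
            raise ValueError("calls contain codes outside {0,1,2,-1}")
        self._index = {a: i for i, a in enumerate(self.accession_ids)}

    @property
    def n_accessions(self) -> int:
        return len(self.accession_ids)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def column(self, accession: str) -> np.ndarray:
        """Genotype vector for one accession (length M)."""
        try:
            return self.calls[:, self._index[accession]]
        except KeyError:
            raise KeyError(f"unknown accession: {accession!r}") from None

    def index_of(self, accession: str) -> int:
        try:
            return self._index[accession]
        except KeyError:
            raise KeyError(f"unknown accession: {accession!r}") from None


@dataclass
class GenomeMap:
    """Chromosome lengths and the non-repetitive intervals per chromosome.

    ``chromosomes`` is an ordered list of (id, length-bp); ``nonrepetitive``
    maps chromosome id -> list of 0-based half-open (start, end) intervals,
    normalised to be sorted, non-overlapping and clipped to [0, length).
    """

    chromosomes: list[tuple[str, int]]
    nonrepetitive: dict[str, list[tuple[int, int]]]

    def __post_init__(self) -> None:
        lengths = dict(self.chromosomes)
        norm: dict[str, list[tuple[int, int]]] = {}
        for chrom, length in self.chromosomes:
            ivs = sorted((max(0, s), min(length, e)) for s, e in self.nonrepetitive.get(chrom, []))
            merged: list[tuple[int, int]] = []
            for s, e in ivs:
                if e <= s:
                    continue
                if merged and s <= merged[-1][1]:
                    merged[-1] = (merged[-1][0], max(merged[-1][1], e))
                else:
                    merged.append((s, e))
            norm[chrom] = merged
        unknown = set(self.nonrepetitive) - set(lengths)
        if unknown:
            raise ValueError(f"mask refers to chromosomes absent from genome: {sorted(unknown)}")
        self.nonrepetitive = norm

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    def nonrepetitive_total(self, chrom: str | None = None) -> int:
        """Total non-repetitive bp on one chromosome or genome-wide."""
        if chrom is not None:
            return sum(e - s for s, e in self.nonrepetitive.get(chrom, []))
        return sum(self.nonrepetitive_total(c) for c, _ in self.chromosomes)

    @classmethod
    def fully_nonrepetitive(cls, chromosomes: Sequence[tuple[str, int]]) -> "GenomeMap":
        return cls(list(chromosomes), {c: [(0, l)] for c, l in chromosomes})


@dataclass
class WindowSet:
    """Windows each covering `target_span` bp of non-repetitive DNA.

    ``table`` has one row per window with columns ``chrom``, ``start``,
    ``end`` (0-based half-open physical coordinates), ``nonrep_span`` (bp of
    non-repetitive sequence inside the window) and ``cum_nonrep`` (running
    genome-wide total including this window).  Windows tile each chromosome
    left to right without overlap; only the last window of a chromosome may
    hold less than `target_span` non-repetitive bp.
    """

    table: pd.DataFrame
    target_span: int

    @property
    def n_windows(self) -> int:
        return len(self.table)

    def physical_span(self, idx: Iterable[int]) -> tuple[int, int, str]:
        """(start, end, chrom) covering a run of window indices on one chromosome."""
        idx = sorted(idx)
        rows = self.table.iloc[idx]
        chroms = rows["chrom"].unique()
        if len(chroms) != 1:
            raise ValueError("window run spans multiple chromosomes")
        return int(rows["start"].iloc[0]), int(rows["end"].iloc[-1]), str(chroms[0])


# ---------------------------------------------------------------------------
# Window construction
# ---------------------------------------------------------------------------

def build_windows(genome: GenomeMap, target_span: int = 200_000) -> WindowSet:
    """Tile each chromosome into windows of `target_span` non-repetitive bp.

    A window accumulates non-repetitive sequence left to right and closes at
    the exact base where the running total reaches `target_span`; repetitive
    gaps contribute nothing, so a window spanning a masked gap is physically
    wider than `target_span`.  The final window of each chromosome keeps
    whatever non-repetitive remainder is left (it is dropped if that
    remainder is zero).  Chromosomes with no non-repetitive sequence yield no
    windows and a warning.
    """
    if target_span <= 0:
        raise ValueError("target_span must be positive")
    rows = []
    cum_total = 0
    for chrom, length in genome.chromosomes:
        intervals = genome.nonrepetitive.get(chrom, [])
        if not intervals:
            logger.warning("chromosome %s has zero non-repetitive bp: no windows built", chrom)
            continue
        win_start = 0
        acc = 0  # non-repetitive bp accumulated since win_start
        for s, e in intervals:
            pos = s
            while e - pos >= target_span - acc:
                close_at = pos + (target_span - acc)
                cum_total += target_span
                rows.append((chrom, win_start, close_at, target_span, cum_total))
                win_start = close_at
                pos = close_at
                acc = 0
            acc += e - pos
        if acc > 0:  # trailing partial window runs to the chromosome end
            cum_total += acc
            rows.append((chrom, win_start, length, acc, cum_total))
    table = pd.DataFrame(rows, columns=["chrom", "start", "end", "nonrep_span", "cum_nonrep"])
    return WindowSet(table=table, target_span=target_span)


def assign_sites_to_windows(gm: GenotypeMatrix, ws: WindowSet) -> np.ndarray:
    """Map each site to its window index, or -1 if outside every window.

    Windows are half-open [start, end) in 0-based coordinates; a 1-based VCF
    position `pos` falls in a window iff start <= pos-1 < end.
    """
    widx = np.full(gm.n_sites, -1, dtype=np.int64)
    tbl = ws.table
    for chrom, sub in tbl.groupby("chrom", sort=False):
        site_mask = (gm.sites["chrom"] == chrom).to_numpy()
        if not site_mask.any():
            continue
        pos0 = gm.sites.loc[site_mask, "pos"].to_numpy() - 1  # to 0-based
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        j = np.searchsorted(starts, pos0, side="right") - 1
        ok = (j >= 0) & (pos0 < ends[np.clip(j, 0, len(ends) - 1)])
        out = np.where(ok, sub.index.to_numpy()[np.clip(j, 0, len(ends) - 1)], -1)
        widx[site_mask] = out
    return widx


# ---------------------------------------------------------------------------
# Genotype readers / writers
# ---------------------------------------------------------------------------

def read_genotypes(path: str | Path, min_maf: float = 0.0) -> GenotypeMatrix:
    """Read genotypes from VCF (.vcf) or the TSV dialect (anything else).

    Multi-allelic records are skipped with a logged count.  If `min_maf` > 0,
    sites whose minor-allele frequency among non-missing calls is <= min_maf
    are dropped.  Input sites are sorted by (chrom, pos) with a warning if
    they were unsorted.
    """
    path = Path(path)
    if path.suffix in {".vcf"} or path.name.endswith(".vcf.gz"):
        gm = _read_vcf(path)
    else:
        gm = _read_tsv(path)
    if min_maf > 0:
        keep = _maf(gm.calls) > min_maf
        n_drop = int((~keep).sum())
        if n_drop:
            logger.info("MAF filter: dropped %d sites with MAF <= %g", n_drop, min_maf)
        gm = GenotypeMatrix(gm.accession_ids, gm.sites.loc[keep].reset_index(drop=True),
                            gm.calls[keep])
    return gm


def _maf(calls: np.ndarray) -> np.ndarray:
    nonmiss = (calls >= 0).sum(axis=1)
    alt = np.where(calls >= 0, calls, 0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(nonmiss > 0, alt / (2 * nonmiss), 0.0)
    return np.minimum(p, 1 - p)


def _finalise(accessions: list[str], recs: list[tuple], calls_rows: list[np.ndarray]) -> GenotypeMatrix:
    sites = pd.DataFrame(recs, columns=["chrom", "pos", "ref", "alt"])
    calls = (np.vstack(calls_rows) if calls_rows
             else np.empty((0, len(accessions)), dtype=np.int8))
    # stable sort by (chrom in order of first appearance, pos)
    chrom_order = {c: i for i, c in enumerate(pd.unique(sites["chrom"]))}
    order = np.lexsort((sites["pos"].to_numpy(),
                        sites["chrom"].map(chrom_order).to_numpy()))
    if len(sites) and not np.array_equal(order, np.arange(len(sites))):
        logger.warning("input sites were not coordinate-sorted; sorting")
        sites = sites.iloc[order].reset_index(drop=True)
        calls = calls[order]
    return GenotypeMatrix(accessions, sites, calls)


def _read_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)  # gt_types: 0=hom_ref,1=het,2=hom_alt,3=missing
    accessions = list(vcf.samples)
    recs, rows, n_multi = [], [], 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_multi += 1
            continue
        g = var.gt_types.astype(np.int8)
        g[g == 3] = MISSING
        recs.append((var.CHROM, var.POS, var.REF, var.ALT[0]))
        rows.append(g)
    vcf.close()
    if n_multi:
        logger.warning("skipped %d multi-allelic records in %s", n_multi, path)
    return _finalise(accessions, recs, rows)


def _read_tsv(path: Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    fixed = ["chrom", "pos", "ref", "alt"]
    accessions = [c for c in df.columns if c not in fixed]
    multi = df["alt"].str.contains(",")
    if multi.any():
        logger.warning("skipped %d multi-allelic records in %s", int(multi.sum()), path)
        df = df.loc[~multi]
    recs = [(r.chrom, int(r.pos), r.ref, r.alt)
            for r in df[fixed].itertuples(index=False)]
    rows = [np.array([_TSV_DECODE[v] for v in row], dtype=np.int8)
            for row in df[accessions].to_numpy()]
    return _finalise(accessions, recs, rows)


def write_genotypes(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write VCF (.vcf suffix) or the TSV dialect (anything else)."""
    path = Path(path)
    if path.suffix == ".vcf":
        _write_vcf(gm, path)
    else:
        _write_tsv(gm, path)


_VCF_GT = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}


def _write_vcf(gm: GenotypeMatrix, path: Path, contigs: Sequence[tuple[str, int]] | None = None) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=kinpipe\n")
        if contigs:
            for chrom, length in contigs:
                fh.write(f"##contig=<ID={chrom},length={length}>\n")
        else:
            for chrom in pd.unique(gm.sites["chrom"]):
                fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(gm.accession_ids) + "\n")
        for i, rec in enumerate(gm.sites.itertuples(index=False)):
            gts = "\t".join(_VCF_GT[int(c)] for c in gm.calls[i])
            fh.write(f"{rec.chrom}\t{rec.pos}\t.\t{rec.ref}\t{rec.alt}\t.\tPASS\t.\tGT\t{gts}\n")


def _write_tsv(gm: GenotypeMatrix, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tref\talt\t" + "\t".join(gm.accession_ids) + "\n")
        for i, rec in enumerate(gm.sites.itertuples(index=False)):
            codes = "\t".join(_TSV_CODE[int(c)] for c in gm.calls[i])
            fh.write(f"{rec.chrom}\t{rec.pos}\t{rec.ref}\t{rec.alt}\t{codes}\n")


# ---------------------------------------------------------------------------
# Genome annotation readers / writers
# ---------------------------------------------------------------------------

def read_genome_table(path: str | Path) -> list[tuple[str, int]]:
    """Two-column TSV (chrom id, length bp) -> ordered chromosome list."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            chrom, length = line.split("\t")[:2]
            out.append((chrom, int(length)))
    return out


def write_genome_table(chromosomes: Sequence[tuple[str, int]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, length in chromosomes:
            fh.write(f"{chrom}\t{length}\n")


def read_mask_bed(path: str | Path) -> dict[str, list[tuple[int, int]]]:
    """BED of non-repetitive intervals -> chrom -> [(start, end), ...]."""
    out: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end = line.split("\t")[:3]
            out.setdefault(chrom, []).append((int(start), int(end)))
    return out


def write_mask_bed(nonrepetitive: dict[str, list[tuple[int, int]]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, intervals in nonrepetitive.items():
            for s, e in intervals:
                fh.write(f"{chrom}\t{s}\t{e}\n")


def read_genome_map(genome_path: str | Path, mask_path: str | Path | None = None) -> GenomeMap:
    """Assemble a GenomeMap from the chromosome-length TSV and optional BED mask.

    Without a mask every chromosome is treated as fully non-repetitive.
    """
    chromosomes = read_genome_table(genome_path)
    if mask_path is None:
        return GenomeMap.fully_nonrepetitive(chromosomes)
    return GenomeMap(chromosomes, read_mask_bed(mask_path))


def write_window_table(ws: WindowSet, widx: np.ndarray, path: str | Path) -> None:
    """Window table TSV with the per-window mapped-site counts."""
    counts = np.bincount(widx[widx >= 0], minlength=ws.n_windows)
    tbl = ws.table.assign(n_sites=counts)
    tbl.to_csv(path, sep="\t", index=False)
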