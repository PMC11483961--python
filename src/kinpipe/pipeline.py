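"""End-to-end orchestration: simulate → ibd → trios → network → haploshare.

One flat, documented config drives every stage; effective parameter values
and input/output checksums are recorded in a JSON run manifest so a run is
reproducible from its manifest alone.  All randomness flows from the single
config seed, so reruns with an identical config are byte-identical for the
deterministic stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .genotype_io import read_genome_map, read_genotypes, build_windows, \
    assign_sites_to_windows, write_window_table
from .ibd_relatedness import IBDParams, all_pairs, pairs_table
from .trio_validation import TrioParams, search_trios, trios_table
from .kinship_network import build_graph, export_graph
from .haplotype_sharing import SharingParams, population_frequencies, sharing_scan, \
    sharing_track, assign_ancestry_groups
from . import synthetic_pedigree as sim

logger = logging.getLogger("kinpipe")

TSV_HEADER_COMMENT = f"# kinpipe v{__version__}\n"


@dataclass
class RunConfig:
    """Flat configuration namespace for a full pipeline run."""

    outdir: str = "kinpipe_run"
    seed: int = 7
    simulate: bool = True          # generate inputs with the synthetic module
    # externally supplied inputs (used when simulate=False)
    vcf: str | None = None
    genome: str | None = None
    mask: str | None = None
    pops: str | None = None
    q_matrix: str | None = None
    # genotype filtering
    min_maf: float = 0.0
    # window system
    window_span: int = 200_000
    # IBD thresholds
    ibd_t2: float = 0.95
    ibd_t0: float = 0.02
    ibd_min_sites: int = 10
    ibd_min_windows: int = 50
    po_max_ibd0: float = 0.15
    po_min_ibd1: float = 0.60
    po_max_seg_bp: int = 3_800_000
    clone_min_ibd2: float = 0.90
    # trio validation
    trio_max_rate: float = 0.013
    trio_alpha_w: float = 0.05
    trio_run_min: int = 3
    # haplotype-sharing scan
    share_ref: str | None = "B4"
    share_chrom: str = "chr2"
    share_target_start: int = 6_000_000
    share_target_end: int = 9_000_000
    share_n_windows: int = 50
    share_t_err: float = 0.02
    share_t2: float = 0.98
    share_min_sites: int = 10
    ancestry_threshold: float = 0.85

    def ibd_params(self) -> IBDParams:
        return IBDParams(t2=self.ibd_t2, t0=self.ibd_t0,
                         min_sites=self.ibd_min_sites,
                         min_windows=self.ibd_min_windows,
                         po_max_ibd0=self.po_max_ibd0,
                         po_min_ibd1=self.po_min_ibd1,
                         po_max_seg_bp=self.po_max_seg_bp,
                         clone_min_ibd2=self.clone_min_ibd2)

    def trio_params(self) -> TrioParams:
        return TrioParams(max_rate=self.trio_max_rate, alpha_w=self.trio_alpha_w,
                          run_min=self.trio_run_min)

    def sharing_params(self) -> SharingParams:
        return SharingParams(t_err=self.share_t_err, t2=self.share_t2,
                             min_sites=self.share_min_sites)


def load_config(path: str | Path, **overrides) -> RunConfig:
    """Load a YAML config; keyword overrides (e.g. CLI flags) win."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    known = {f.name for f in fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    data.update({k: v for k, v in overrides.items() if v is not None})
    return RunConfig(**data)


_UNIT_FIELDS = ["min_maf", "ibd_t2", "ibd_t0", "po_max_ibd0", "po_min_ibd1",
                "clone_min_ibd2", "trio_max_rate", "trio_alpha_w",
                "share_t_err", "share_t2", "ancestry_threshold"]
_POSITIVE_FIELDS = ["window_span", "po_max_seg_bp", "trio_run_min",
                    "ibd_min_sites", "ibd_min_windows", "share_n_windows",
                    "share_min_sites"]


def validate_config(cfg: RunConfig) -> list[str]:
    """Constraint violations (empty list iff the config is runnable)."""
    violations = []
    for name in _UNIT_FIELDS:
        v = getattr(cfg, name)
        if not 0.0 <= v <= 1.0:
            violations.append(f"{name}={v}: must be in [0,1]")
    for name in _POSITIVE_FIELDS:
        v = getattr(cfg, name)
        if v <= 0:
            violations.append(f"{name}={v}: must be positive")
    if cfg.seed < 0:
        violations.append(f"seed={cfg.seed}: must be non-negative")
    if cfg.share_target_end <= cfg.share_target_start:
        violations.append("share_target_end must exceed share_target_start")
    if not cfg.simulate:
        for name in ("vcf", "genome"):
            p = getattr(cfg, name)
            if p is None:
                violations.append(f"{name}: required when simulate=false")
            elif not Path(p).exists():
                violations.append(f"{name}={p}: file not found")
        for name in ("mask", "pops", "q_matrix"):
            p = getattr(cfg, name)
            if p is not None and not Path(p).exists():
                violations.append(f"{name}={p}: file not found")
    return violations


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write(TSV_HEADER_COMMENT)
        df.to_csv(fh, sep="\t", index=False)


def run_pipeline(cfg: RunConfig) -> dict:
    """Run all stages in dependency order; return (and write) the manifest."""
    violations = validate_config(cfg)
    if violations:
        raise ValueError("invalid config:\n  " + "\n  ".join(violations))
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"tool": "kinpipe", "version": __version__,
                      "parameters": asdict(cfg), "stages": []}

    def stage(name):
        logger.info("stage %s: start", name)
        return {"name": name, "t0": time.time(), "outputs": {}}

    def done(st):
        st["seconds"] = round(time.time() - st.pop("t0"), 3)
        st["outputs"] = {k: {"path": str(p), "sha256": _sha256(Path(p))}
                         for k, p in st["outputs"].items()}
        manifest["stages"].append(st)
        logger.info("stage %s: done in %.1fs", st["name"], st["seconds"])

    # ---- stage 1: simulate (or load) ------------------------------------
    st = stage("simulate")
    populations: dict[str, str] = {}
    q_matrix = None
    if cfg.simulate:
        sim_cfg = sim.default_config(seed=cfg.seed)
        result = sim.simulate(sim_cfg)
        paths = sim.write_outputs(result, outdir / "simulated")
        gm = result.genotypes
        genome = result.genome
        populations = dict(sim_cfg.populations)
        q_matrix = result.truth.ancestry
        st["outputs"].update(paths)
    else:
        gm = read_genotypes(cfg.vcf, min_maf=cfg.min_maf)
        genome = read_genome_map(cfg.genome, cfg.mask)
        if cfg.pops:
            pops_df = pd.read_csv(cfg.pops, sep="\t", comment="#")
            populations = dict(zip(pops_df["accession"], pops_df["population"]))
        if cfg.q_matrix:
            q_matrix = pd.read_csv(cfg.q_matrix, sep="\t", index_col=0, comment="#")
        st["inputs"] = {k: {"path": str(getattr(cfg, k)),
                            "sha256": _sha256(Path(getattr(cfg, k)))}
                        for k in ("vcf", "genome", "mask", "pops", "q_matrix")
                        if getattr(cfg, k)}
    done(st)

    # ---- stage 2: windowed IBD over all pairs ---------------------------
    st = stage("ibd")
    ws = build_windows(genome, cfg.window_span)
    widx = assign_sites_to_windows(gm, ws)
    write_window_table(ws, widx, outdir / "windows.tsv")
    profiles = all_pairs(gm, ws, cfg.ibd_params())
    _write_tsv(pairs_table(profiles), outdir / "pairs.tsv")
    st["outputs"].update(windows=outdir / "windows.tsv", pairs=outdir / "pairs.tsv")
    done(st)

    # ---- stage 3: trio search and validation ----------------------------
    st = stage("trios")
    accepted, full_sibs, reports = search_trios(gm, ws, profiles, cfg.trio_params())
    _write_tsv(trios_table(reports), outdir / "trios_all.tsv")
    _write_tsv(trios_table(accepted), outdir / "trios.tsv")
    _write_tsv(pd.DataFrame(full_sibs, columns=["a", "b"]), outdir / "full_sibs.tsv")
    st["outputs"].update(trios=outdir / "trios.tsv",
                         trios_all=outdir / "trios_all.tsv",
                         full_sibs=outdir / "full_sibs.tsv")
    done(st)

    # ---- stage 4: kinship network ---------------------------------------
    st = stage("network")
    graph = build_graph(profiles, accepted, full_sibs, ancestry=q_matrix)
    export_graph(graph, outdir / "network.graphml")
    export_graph(graph, outdir / "network.tsv")
    st["outputs"].update(graphml=outdir / "network.graphml",
                         edges=outdir / "network.tsv")
    done(st)

    # ---- stage 5: haplotype sharing -------------------------------------
    if cfg.share_ref and cfg.share_ref in gm.accession_ids:
        st = stage("haploshare")
        target = (cfg.share_target_start, cfg.share_target_end)
        length = dict(genome.chromosomes).get(cfg.share_chrom)
        share_profiles = sharing_scan(gm, cfg.share_ref, cfg.share_chrom,
                                      n_windows=cfg.share_n_windows, target=target,
                                      chrom_length=length,
                                      params=cfg.sharing_params())
        dosages = {a: p.dosage_at_target for a, p in share_profiles.items()}
        _write_tsv(sharing_track(share_profiles), outdir / "share_track.tsv")
        dose_df = pd.DataFrame(
            [{"accession": a,
              "population": populations.get(a, "unassigned"),
              "dosage": "NA" if d is None else d}
             for a, d in sorted(dosages.items())])
        _write_tsv(dose_df, outdir / "dosages.tsv")
        if populations:
            _write_tsv(population_frequencies(dosages, populations),
                       outdir / "haplotype_frequencies.tsv")
            st["outputs"]["frequencies"] = outdir / "haplotype_frequencies.tsv"
        if q_matrix is not None:
            groups = assign_ancestry_groups(q_matrix, cfg.ancestry_threshold)
            _write_tsv(groups.rename_axis("accession").reset_index(),
                       outdir / "ancestry_groups.tsv")
            st["outputs"]["ancestry_groups"] = outdir / "ancestry_groups.tsv"
        st["outputs"].update(share_track=outdir / "share_track.tsv",
                             dosages=outdir / "dosages.tsv")
        done(st)

    manifest_path = outdir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def setup_logging(level: int = logging.INFO) -> None:
    """Stage-timed logging to stderr (idempotent)."""
    root = logging.getLogger("kinpipe")
    if not root.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(logging.Formatter("[%(asctime)s] %(levelname)s %(message)s",
                                               "%H:%M:%S"))
        root.addHandler(handler)
    root.setLevel(level)
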