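"""Shared fixtures: simulated panels reused across the test battery."""

import numpy as np
import pytest

import kinpipe as kp
from kinpipe import synthetic_pedigree as sim


@pytest.fixture(scope="session")
def sim7():
    """The default simulated panel (seed 7): pedigree, wild populations,
    planted haplotype, default error rates."""
    return sim.simulate(sim.default_config(seed=7))


@pytest.fixture(scope="session")
def ws7(sim7):
    return kp.build_windows(sim7.genome)


@pytest.fixture(scope="session")
def profiles7(sim7, ws7):
    return kp.all_pairs(sim7.genotypes, ws7)


@pytest.fixture(scope="session")
def errorfree1():
    """Cultivated panel without genotyping error or missingness (seed 1)."""
    cfg = sim.default_config(seed=1, with_wild=False,
                             het_to_hom_rate=0.0, genotype_missing_rate=0.0)
    res = sim.simulate(cfg)
    ws = kp.build_windows(res.genome)
    return res, ws


@pytest.fixture(scope="session")
def recovery_sweep():
    """Ten replicate panels at default conditions with pairwise and trio
    results — the parameter-recovery study conditions."""
    out = []
    for seed in range(1, 11):
        res = sim.simulate(sim.default_config(seed=seed))
        ws = kp.build_windows(res.genome)
        profiles = kp.all_pairs(res.genotypes, ws)
        accepted, sibs, reports = kp.search_trios(res.genotypes, ws, profiles)
        out.append({"res": res, "ws": ws, "profiles": profiles,
                    "accepted": accepted, "sibs": sibs, "reports": reports})
    return out


@pytest.fixture(scope="session")
def errorfree_sweep():
    """Ten replicate error-free cultivated panels with pairwise profiles."""
    out = []
    for seed in range(1, 11):
        cfg = sim.default_config(seed=seed, with_wild=False,
                                 het_to_hom_rate=0.0, genotype_missing_rate=0.0)
        res = sim.simulate(cfg)
        ws = kp.build_windows(res.genome)
        profiles = kp.all_pairs(res.genotypes, ws)
        out.append({"res": res, "ws": ws, "profiles": profiles, "cfg": cfg})
    return out


@pytest.fixture
def toy_genome():
    """1-Mb single chromosome with a repeat block masking [400k, 600k)."""
    return kp.GenomeMap([("chr1", 1_000_000)],
                        {"chr1": [(0, 400_000), (600_000, 1_000_000)]})


def make_matrix(codes, chrom="chr1", start_pos=100, spacing=100,
                accessions=None):
    """GenotypeMatrix from a per-site list of genotype-code tuples."""
    import pandas as pd

    codes = np.asarray(codes, dtype=np.int8)
    n_sites, n_acc = codes.shape
    if accessions is None:
        accessions = [f"S{i}" for i in range(n_acc)]
    sites = pd.DataFrame({
        "chrom": chrom,
        "pos": start_pos + spacing * np.arange(n_sites),
        "ref": "A", "alt": "G",
    })
    return kp.GenotypeMatrix(list(accessions), sites, codes)
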