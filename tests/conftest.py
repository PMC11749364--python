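import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

from editome.simulate import SimulationConfig, simulate_dataset
from editome.types import GeneModel


def make_obs_frame(rows, sample_id="s1", chrom="chr1"):
    """Build an observation frame from (pos0, ref, base, baq, mapq, read_pos)."""
    recs = []
    for i, (pos0, ref, base, baq, mapq, read_pos) in enumerate(rows):
        recs.append({"sample_id": sample_id, "chrom": chrom, "pos0": pos0,
                     "ref": ref, "base": base, "baq": baq, "mapq": mapq,
                     "read_pos": read_pos, "read_id": f"r{i}"})
    cols = ["sample_id", "chrom", "pos0", "ref", "base", "baq", "mapq",
            "read_pos", "read_id"]
    df = pd.DataFrame(recs, columns=cols)
    return df.sort_values(["chrom", "pos0"], kind="stable").reset_index(drop=True)


def column(pos0, ref, bases, baq=30, mapq=40, read_pos=50, **kw):
    """One pileup column: bases is a string like 'AAAGG'."""
    return [(pos0, ref, b, baq, mapq, read_pos) for b in bases]


@pytest.fixture(scope="session")
def two_genes():
    """A plus-strand and a minus-strand coding gene on chr1."""
    plus = GeneModel("gplus", "chr1", "+",
                     exons=[(100, 300), (500, 700), (900, 1200)],
                     cds=[(150, 300), (500, 700), (900, 1000)],
                     utr5=[(100, 150)], utr3=[(1000, 1200)])
    minus = GeneModel("gminus", "chr1", "-",
                      exons=[(2000, 2300), (2500, 2800)],
                      cds=[(2150, 2300), (2500, 2700)],
                      utr3=[(2000, 2150)], utr5=[(2700, 2800)])
    return [plus, minus]


@pytest.fixture(scope="session")
def small_dataset():
    """A small planted dataset shared by discovery/differential tests."""
    cfg = SimulationConfig(seed=42)
    cfg.genome.chrom_length = 20_000
    cfg.genome.n_genes = 6
    cfg.sites.n_editing_sites = 60
    cfg.sites.n_snps = 12
    cfg.sites.n_hexamer_artifact_sites = 6
    cfg.sites.n_homopolymer_sites = 5
    ds = simulate_dataset(cfg)
    ds["config"] = cfg
    return ds


@pytest.fixture
def resources(small_dataset):
    ref = small_dataset["reference"]
    return {
        "ref": ref.sequences,
        "genes": ref.genes,
        "alu": ref.alu,
        "similarity": ref.similarity,
        "snp_sets": [{(c, p, a)
                      for c, p, _r, a, _z in small_dataset["truth"].snps}],
        "dna_obs": small_dataset["dna"],
    }


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
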