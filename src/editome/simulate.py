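"""Synthetic data generator with planted ground truth.

Every input the pipeline consumes can be generated here with the
statistical structure the analysis assumes: a random genome with Alu-like
intervals, stranded gene models, planted A-to-G editing sites whose levels
follow a right-skewed Beta distribution and concentrate in Alu regions,
germline SNPs (variant in both DNA and RNA), random-hexamer priming
artifacts (variant reads only within the first six read bases), homopolymer
contexts, uniform sequencing errors, multi-sample editing-level matrices
with correlated one-factor modules and group-shifted differential sites,
and 3'UTR sites where the single A>G change creates or destroys a miRNA
target. Planted site classes are disjoint (and sequencing errors avoid
planted positions) so that per-filter attribution is unambiguous.

All randomness flows from one integer seed through ``numpy``'s
``default_rng``; identical config + seed reproduces identical outputs.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as eio
from .discovery import splice_junction_distance, homopolymer_run_length
from .mirna import AlleleQueryPair, ScanParams, build_allele_queries, scan_targets
from .types import (
    BASES,
    COMPLEMENT,
    EditingSite,
    GeneModel,
    IntervalSet,
    SampleRecord,
    SampleSheet,
)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class GenomeConfig:
    n_chroms: int = 1
    chrom_length: int = 100_000
    alu_fraction: float = 0.3
    alu_element_len: int = 300
    n_genes: int = 30
    exons_per_gene: int = 3
    exon_len: int = 400
    intron_len: int = 400
    utr5_len: int = 100
    utr3_len: int = 300
    ncrna_fraction: float = 0.1
    similarity_fraction: float = 0.02


@dataclass
class SitesConfig:
    n_editing_sites: int = 300
    alu_site_fraction: float = 0.97
    level_beta_a: float = 2.0
    level_beta_b: float = 5.0
    min_level: float = 0.1
    n_snps: int = 50
    n_hexamer_artifact_sites: int = 30
    n_homopolymer_sites: int = 20


@dataclass
class ReadsConfig:
    mean_coverage: float = 30.0
    dna_mean_coverage: float = 30.0
    read_length: int = 101
    base_error_rate: float = 0.001
    baq_pass_fraction: float = 0.92
    baq_pass: int = 35
    baq_fail: int = 15
    mapq_pass_fraction: float = 0.95
    mapq_pass: int = 50
    mapq_fail: int = 10
    n_rna_replicates: int = 2


@dataclass
class MatrixConfig:
    n_samples_a: int = 5
    n_samples_b: int = 4
    module_sizes: tuple[int, ...] = (60, 40, 30)
    within_cor: float = 0.8
    n_hubs_per_module: int = 3
    hub_weight: float = 0.98
    n_background: int = 200
    level_sd: float = 0.1
    n_des: int = 0
    des_fold: float = 2.5
    #: per-sample deviation around the group mean for DES sites; 0 means
    #: replicates share the exact true level (pure count noise)
    des_level_sd: float = 0.0
    #: the lower of the two group rates, uniform over the editing-level
    #: range typical of qualified sites (median levels sit near 0.2-0.3);
    #: the higher rate is fold times larger, assigned to a random group
    des_base_level_low: float = 0.2
    des_base_level_high: float = 0.35
    depth: float = 50.0


@dataclass
class MirnaConfig:
    n_mirnas: int = 10
    n_gain_events: int = 10
    n_loss_events: int = 10
    n_neutral_sites: int = 10
    mirna_len: int = 21
    max_tries: int = 60


@dataclass
class SimulationConfig:
    seed: int
    genome: GenomeConfig = field(default_factory=GenomeConfig)
    sites: SitesConfig = field(default_factory=SitesConfig)
    reads: ReadsConfig = field(default_factory=ReadsConfig)
    matrix: MatrixConfig = field(default_factory=MatrixConfig)
    mirna: MirnaConfig = field(default_factory=MirnaConfig)


# ---------------------------------------------------------------------------
# truth records
# ---------------------------------------------------------------------------

@dataclass
class PlantedSite:
    chrom: str
    pos0: int
    ref_base: str
    var_base: str
    level: float
    in_alu: bool
    gene_id: str | None = None
    strand: str = "."


@dataclass
class TruthTables:
    editing_sites: list[PlantedSite] = field(default_factory=list)
    snps: list[tuple[str, int, str, str, float]] = field(default_factory=list)
    hexamer_sites: list[tuple[str, int, str]] = field(default_factory=list)
    homopolymer_sites: list[tuple[str, int, str]] = field(default_factory=list)


@dataclass
class Reference:
    sequences: dict[str, str]
    genes: list[GeneModel]
    alu: IntervalSet
    similarity: IntervalSet
    homopolymer_runs: list[tuple[str, int, int]]


# ---------------------------------------------------------------------------
# reference genome
# ---------------------------------------------------------------------------

def _place_nonoverlapping(rng: np.random.Generator, length: int,
                          element_len: int, target_total: int,
                          max_tries: int = 200_000) -> list[tuple[int, int]]:
    """Greedy random packing of fixed-length intervals without overlap."""
    starts: list[int] = []
    total = 0
    tries = 0
    while total < target_total:
        tries += 1
        if tries > max_tries:
            raise RuntimeError("infeasible interval packing")
        s = int(rng.integers(0, length - element_len))
        i = bisect.bisect_left(starts, s)
        if i > 0 and starts[i - 1] + element_len > s:
            continue
        if i < len(starts) and s + element_len > starts[i]:
            continue
        starts.insert(i, s)
        total += element_len
    return [(s, s + element_len) for s in starts]


def simulate_reference(config: SimulationConfig,
                       rng: np.random.Generator | None = None) -> Reference:
    """Random genome with Alu-like intervals, genes and homopolymer runs."""
    rng = rng or np.random.default_rng(config.seed)
    g = config.genome
    sequences: dict[str, str] = {}
    genes: list[GeneModel] = []
    alu_ivs: dict[str, list[tuple[int, int]]] = {}
    sim_ivs: dict[str, list[tuple[int, int]]] = {}
    homopolymers: list[tuple[str, int, int]] = []
    gene_span = (g.exons_per_gene * g.exon_len
                 + (g.exons_per_gene - 1) * g.intron_len)
    if g.n_genes * (gene_span + 200) > g.chrom_length * g.n_chroms:
        raise RuntimeError("infeasible packing: too many genes for length")
    for ci in range(g.n_chroms):
        chrom = f"chr{ci + 1}"
        seq = rng.integers(0, 4, g.chrom_length)
        # Alu-like intervals (a leading inverted-repeat pair is cosmetic)
        alu = _place_nonoverlapping(rng, g.chrom_length, g.alu_element_len,
                                    int(g.alu_fraction * g.chrom_length))
        alu_ivs[chrom] = alu
        # genes: evenly spread slots with random jitter
        n_here = g.n_genes // g.n_chroms + (1 if ci < g.n_genes % g.n_chroms
                                            else 0)
        slot = g.chrom_length // max(n_here, 1)
        for gi in range(n_here):
            lo = gi * slot
            start = lo + int(rng.integers(0, max(slot - gene_span - 10, 1)))
            exons = []
            pos = start
            for _ in range(g.exons_per_gene):
                exons.append((pos, pos + g.exon_len))
                pos += g.exon_len + g.intron_len
            strand = "+" if rng.random() < 0.5 else "-"
            gid = f"gene{ci + 1}_{gi + 1}"
            if rng.random() < g.ncrna_fraction:
                genes.append(GeneModel(gid, chrom, strand, exons,
                                       biotype="ncRNA"))
                continue
            if strand == "+":
                thick = (exons[0][0] + g.utr5_len, exons[-1][1] - g.utr3_len)
            else:
                thick = (exons[0][0] + g.utr3_len, exons[-1][1] - g.utr5_len)
            cds, utr5, utr3 = eio._derive_utrs(exons, thick, strand)
            genes.append(GeneModel(gid, chrom, strand, exons, cds=cds,
                                   utr5=utr5, utr3=utr3, biotype="coding"))
        # similarity mask: a few intervals
        n_sim = max(1, int(g.similarity_fraction * g.chrom_length) // 200)
        sim = _place_nonoverlapping(rng, g.chrom_length, 200, n_sim * 200)
        sim_ivs[chrom] = sim
        # homopolymer runs stamped into the sequence
        base_codes = {b: i for i, b in enumerate(BASES)}
        # extra runs beyond the planted artifact sites: some land in Alu or
        # near splice junctions and are unusable as artifact positions
        n_runs = config.sites.n_homopolymer_sites * 4
        for _ in range(n_runs):
            run_len = int(rng.integers(5, 8))
            s = int(rng.integers(10, g.chrom_length - run_len - 10))
            b = int(rng.integers(0, 4))
            seq[s:s + run_len] = b
            homopolymers.append((chrom, s, s + run_len))
        sequences[chrom] = "".join(BASES[i] for i in seq)
        del base_codes
    return Reference(sequences, genes, IntervalSet(alu_ivs, label="Alu"),
                     IntervalSet(sim_ivs, label="similarity_mask"),
                     homopolymers)


# ---------------------------------------------------------------------------
# planting site classes
# ---------------------------------------------------------------------------

def _truncated_beta(rng, a, b, min_level, size) -> np.ndarray:
    out = rng.beta(a, b, size)
    for i in range(size):
        tries = 0
        while out[i] < min_level:
            out[i] = rng.beta(a, b)
            tries += 1
            if tries > 10_000:
                raise RuntimeError("min_level incompatible with Beta params")
    return out


def plant_truth(reference: Reference, config: SimulationConfig,
                rng: np.random.Generator) -> TruthTables:
    """Choose disjoint planted positions for every site class."""
    s = config.sites
    truth = TruthTables()
    taken: set[tuple[str, int]] = set()
    by_chrom_genes: dict[str, list[GeneModel]] = {}
    for g in reference.genes:
        by_chrom_genes.setdefault(g.chrom, []).append(g)

    def usable(chrom: str, pos0: int, need_non_alu: bool) -> bool:
        if (chrom, pos0) in taken:
            return False
        if (chrom, pos0) in reference.similarity:
            return False
        in_alu = (chrom, pos0) in reference.alu
        if need_non_alu and in_alu:
            return False
        seq = reference.sequences[chrom]
        if homopolymer_run_length(seq, pos0) >= 5:
            return False
        dist = splice_junction_distance(pos0, by_chrom_genes.get(chrom, []))
        if dist is not None and dist <= 4:
            return False
        return True

    chroms = sorted(reference.sequences)
    seqs = {c: reference.sequences[c] for c in chroms}
    a_positions = {c: np.flatnonzero(np.frombuffer(
        seqs[c].encode(), dtype=np.uint8) == ord("A")) for c in chroms}
    t_positions = {c: np.flatnonzero(np.frombuffer(
        seqs[c].encode(), dtype=np.uint8) == ord("T")) for c in chroms}

    # --- editing sites
    n_alu_sites = int(round(s.alu_site_fraction * s.n_editing_sites))
    n_nonalu = s.n_editing_sites - n_alu_sites
    levels = _truncated_beta(rng, s.level_beta_a, s.level_beta_b,
                             max(s.min_level, 0.0), s.n_editing_sites)
    # non-Alu sites must clear the frequency filter to be discoverable
    nonalu_min = max(s.min_level, 0.1)
    for i in range(n_nonalu):
        while levels[i] < nonalu_min:
            levels[i] = rng.beta(s.level_beta_a, s.level_beta_b)
    idx = 0
    placed = 0
    while placed < n_alu_sites:
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        pos_arr = a_positions[chrom]
        pos0 = int(pos_arr[int(rng.integers(0, len(pos_arr)))])
        if (chrom, pos0) not in reference.alu:
            continue
        if not usable(chrom, pos0, need_non_alu=False):
            continue
        truth.editing_sites.append(PlantedSite(
            chrom, pos0, "A", "G", float(levels[n_nonalu + placed]),
            in_alu=True))
        taken.add((chrom, pos0))
        placed += 1
    placed = 0
    tries = 0
    while placed < n_nonalu:
        tries += 1
        if tries > 500_000:
            raise RuntimeError("could not place non-Alu editing sites")
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        genes = by_chrom_genes.get(chrom, [])
        if not genes:
            continue
        gene = genes[int(rng.integers(0, len(genes)))]
        pool = a_positions[chrom] if gene.strand == "+" else t_positions[chrom]
        lo = np.searchsorted(pool, gene.start)
        hi = np.searchsorted(pool, gene.end)
        if hi <= lo:
            continue
        pos0 = int(pool[int(rng.integers(lo, hi))])
        if not usable(chrom, pos0, need_non_alu=True):
            continue
        ref_b = seqs[chrom][pos0]
        var_b = "G" if ref_b == "A" else "C"
        truth.editing_sites.append(PlantedSite(
            chrom, pos0, ref_b, var_b, float(levels[idx]), in_alu=False,
            gene_id=gene.gene_id, strand=gene.strand))
        taken.add((chrom, pos0))
        idx += 1
        placed += 1

    # --- SNPs
    placed = 0
    while placed < s.n_snps:
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        pos0 = int(rng.integers(0, len(seqs[chrom])))
        if not usable(chrom, pos0, need_non_alu=False):
            continue
        ref_b = seqs[chrom][pos0]
        alts = [b for b in BASES if b != ref_b]
        alt = alts[int(rng.integers(0, 3))]
        zygosity = 0.5 if rng.random() < 0.7 else 1.0
        truth.snps.append((chrom, pos0, ref_b, alt, zygosity))
        taken.add((chrom, pos0))
        placed += 1

    # --- hexamer artifacts
    placed = 0
    while placed < s.n_hexamer_artifact_sites:
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        pos0 = int(rng.integers(0, len(seqs[chrom])))
        if not usable(chrom, pos0, need_non_alu=False):
            continue
        ref_b = seqs[chrom][pos0]
        alts = [b for b in BASES if b != ref_b]
        truth.hexamer_sites.append((chrom, pos0, alts[int(rng.integers(0, 3))]))
        taken.add((chrom, pos0))
        placed += 1

    # --- homopolymer artifact sites (non-Alu, level >= 0.1 so only the
    #     homopolymer filter removes them)
    runs = [r for r in reference.homopolymer_runs]
    rng.shuffle(runs)
    placed = 0
    for chrom, rs, re_ in runs:
        if placed >= s.n_homopolymer_sites:
            break
        pos0 = (rs + re_) // 2
        if (chrom, pos0) in taken or (chrom, pos0) in reference.alu:
            continue
        if (chrom, pos0) in reference.similarity:
            continue
        dist = splice_junction_distance(pos0, by_chrom_genes.get(chrom, []))
        if dist is not None and dist <= 4:
            continue
        ref_b = seqs[chrom][pos0]
        alts = [b for b in BASES if b != ref_b]
        truth.homopolymer_sites.append(
            (chrom, pos0, alts[int(rng.integers(0, 3))]))
        taken.add((chrom, pos0))
        placed += 1
    if placed < s.n_homopolymer_sites:
        raise RuntimeError("not enough usable homopolymer runs")
    return truth


# ---------------------------------------------------------------------------
# read-level observations
# ---------------------------------------------------------------------------

def _observation_frame(rng, chrom: str, seq: str, coverage: float,
                       rc: ReadsConfig, sample_id: str,
                       variant_plan: dict[int, tuple[str, float]],
                       hexamer_plan: dict[int, str] | None = None,
                       planted: set[int] | None = None) -> pd.DataFrame:
    """Vectorised pileup for one chromosome of one sample.

    ``variant_plan`` maps pos0 -> (var_base, level); ``hexamer_plan`` maps
    pos0 -> var_base for artifact sites whose variant reads are forced to
    read positions 1-6. Errors avoid ``planted`` positions.
    """
    L = len(seq)
    depths = rng.poisson(coverage, L)
    n_obs = int(depths.sum())
    pos0 = np.repeat(np.arange(L), depths)
    offsets = np.concatenate([[0], np.cumsum(depths)])
    ref_arr = np.frombuffer(seq.encode(), dtype="S1").astype("U1")
    ref_col = ref_arr[pos0]
    base_col = ref_col.copy()
    read_pos = rng.integers(1, rc.read_length + 1, n_obs)
    baq = np.where(rng.random(n_obs) < rc.baq_pass_fraction, rc.baq_pass,
                   rc.baq_fail)
    mapq = np.where(rng.random(n_obs) < rc.mapq_pass_fraction, rc.mapq_pass,
                    rc.mapq_fail)
    planted = planted or set()
    for p, (var, level) in variant_plan.items():
        d = int(depths[p])
        if d == 0:
            continue
        k = int(rng.binomial(d, level))
        base_col[offsets[p]:offsets[p] + k] = var
    if hexamer_plan:
        for p, var in hexamer_plan.items():
            d = int(depths[p])
            if d == 0:
                continue
            k = min(d, max(3, int(round(0.4 * d))))
            sl = slice(offsets[p], offsets[p] + k)
            base_col[sl] = var
            read_pos[sl] = rng.integers(1, 7, k)
            baq[sl] = rc.baq_pass
            mapq[sl] = rc.mapq_pass
            # remaining reads stay reference but must sit past the prefix
            rest = slice(offsets[p] + k, offsets[p] + d)
            read_pos[rest] = rng.integers(7, rc.read_length + 1, d - k)
    # uniform errors at unplanted positions
    n_err = int(rng.binomial(n_obs, rc.base_error_rate))
    if n_err:
        err_idx = rng.choice(n_obs, size=n_err, replace=False)
        err_idx = np.array([i for i in err_idx
                            if int(pos0[i]) not in planted], dtype=int)
        shift = rng.integers(1, 4, len(err_idx))
        base_codes = np.array(BASES)
        code_of = {b: i for i, b in enumerate(BASES)}
        for i, sh in zip(err_idx, shift):
            base_col[i] = base_codes[(code_of[str(base_col[i])] + sh) % 4]
    return pd.DataFrame({
        "sample_id": sample_id,
        "chrom": chrom,
        "pos0": pos0,
        "ref": ref_col,
        "base": base_col,
        "baq": baq,
        "mapq": mapq,
        "read_pos": read_pos,
        "read_id": [f"{sample_id}_r{i}" for i in range(n_obs)],
    })


def simulate_observations(reference: Reference, truth: TruthTables,
                          config: SimulationConfig,
                          rng: np.random.Generator | None = None
                          ) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Generate RNA replicate observation frames and the DNA frame."""
    rng = rng or np.random.default_rng(config.seed + 1)
    rc = config.reads
    rna_plan: dict[str, dict[int, tuple[str, float]]] = {}
    dna_plan: dict[str, dict[int, tuple[str, float]]] = {}
    hex_plan: dict[str, dict[int, str]] = {}
    planted: dict[str, set[int]] = {c: set() for c in reference.sequences}
    for site in truth.editing_sites:
        rna_plan.setdefault(site.chrom, {})[site.pos0] = (site.var_base,
                                                          site.level)
        planted[site.chrom].add(site.pos0)
    for chrom, pos0, ref_b, alt, zyg in truth.snps:
        rna_plan.setdefault(chrom, {})[pos0] = (alt, zyg)
        dna_plan.setdefault(chrom, {})[pos0] = (alt, zyg)
        planted[chrom].add(pos0)
    for chrom, pos0, var in truth.hexamer_sites:
        hex_plan.setdefault(chrom, {})[pos0] = var
        planted[chrom].add(pos0)
    for chrom, pos0, var in truth.homopolymer_sites:
        rna_plan.setdefault(chrom, {})[pos0] = (var, 0.3)
        planted[chrom].add(pos0)

    rna: dict[str, pd.DataFrame] = {}
    for r in range(rc.n_rna_replicates):
        sid = f"rna_rep{r + 1}"
        frames = [
            _observation_frame(rng, chrom, seq, rc.mean_coverage, rc, sid,
                               rna_plan.get(chrom, {}),
                               hex_plan.get(chrom, {}), planted[chrom])
            for chrom, seq in sorted(reference.sequences.items())]
        rna[sid] = pd.concat(frames, ignore_index=True)
    dna_frames = [
        _observation_frame(rng, chrom, seq, rc.dna_mean_coverage, rc, "dna",
                           dna_plan.get(chrom, {}), None, planted[chrom])
        for chrom, seq in sorted(reference.sequences.items())]
    return rna, pd.concat(dna_frames, ignore_index=True)


# ---------------------------------------------------------------------------
# editing-level matrix with modules and DESs
# ---------------------------------------------------------------------------

def simulate_editing_matrix(config: SimulationConfig,
                            rng: np.random.Generator | None = None) -> dict:
    """Sites x samples level matrix with planted modules and DES shifts.

    Module sites follow a one-factor model x_i = w_i f_m + sqrt(1-w_i^2) e
    on a standardized scale mapped to levels by mu_i + level_sd * x; DES
    sites get a group mean ratio of ``des_fold`` (direction random),
    clipped to [0.01, 0.99] with the realised fold recorded. Counts are
    drawn as total ~ Poisson(depth) (min 5) and edited ~ Binomial(total,
    level).
    """
    rng = rng or np.random.default_rng(config.seed + 2)
    m = config.matrix
    samples = ([f"A{i + 1}" for i in range(m.n_samples_a)]
               + [f"B{i + 1}" for i in range(m.n_samples_b)])
    n_samples = len(samples)
    group = {s: ("A" if s.startswith("A") else "B") for s in samples}
    site_ids: list[str] = []
    rows: list[np.ndarray] = []
    labels: list[int] = []
    weights: list[float] = []
    base_w = float(np.sqrt(m.within_cor))
    for mi, size in enumerate(m.module_sizes, start=1):
        f = rng.standard_normal(n_samples)
        for si in range(size):
            w = m.hub_weight if si < m.n_hubs_per_module else base_w
            eps = rng.standard_normal(n_samples)
            x = w * f + np.sqrt(1.0 - w * w) * eps
            mu = rng.uniform(0.25, 0.6)
            rows.append(np.clip(mu + m.level_sd * x, 0.01, 0.99))
            site_ids.append(f"mod{mi}_{si + 1:03d}")
            labels.append(mi)
            weights.append(w)
    for bi in range(m.n_background):
        x = rng.standard_normal(n_samples)
        mu = rng.uniform(0.25, 0.6)
        rows.append(np.clip(mu + m.level_sd * x, 0.01, 0.99))
        site_ids.append(f"bg_{bi + 1:04d}")
        labels.append(0)
        weights.append(0.0)
    des_truth: list[dict] = []
    for di in range(m.n_des):
        mu_low = rng.uniform(m.des_base_level_low, m.des_base_level_high)
        up = rng.random() < 0.5  # True: group B carries the higher rate
        mu_high = min(mu_low * m.des_fold, 0.99)
        mu_a, mu_b = (mu_low, mu_high) if up else (mu_high, mu_low)
        level = np.where([group[s] == "A" for s in samples], mu_a, mu_b)
        level = np.clip(level + m.des_level_sd * rng.standard_normal(n_samples),
                        0.01, 0.99)
        rows.append(level)
        sid = f"des_{di + 1:04d}"
        site_ids.append(sid)
        labels.append(0)
        weights.append(0.0)
        la = float(level[[group[s] == "A" for s in samples]].mean())
        lb = float(level[[group[s] == "B" for s in samples]].mean())
        des_truth.append({"site": sid, "mu_a": mu_a, "mu_b": mu_b,
                          "realized_fold": max(la, lb) / min(la, lb),
                          "direction": "up" if up else "down"})
    levels = pd.DataFrame(rows, index=site_ids, columns=samples)
    total = pd.DataFrame(
        np.maximum(rng.poisson(m.depth, levels.shape), 5),
        index=site_ids, columns=samples)
    edited = pd.DataFrame(
        rng.binomial(total.to_numpy(), levels.to_numpy()),
        index=site_ids, columns=samples)
    return {
        "levels": levels, "edited": edited, "total": total,
        "samples": samples, "groups": group,
        "module_labels": pd.Series(labels, index=site_ids),
        "weights": pd.Series(weights, index=site_ids),
        "des_truth": pd.DataFrame(des_truth),
    }


def simulate_factor_module(n_sites: int = 50, n_samples: int = 9,
                           noise_sd: float = 0.1,
                           rng: np.random.Generator | None = None) -> dict:
    """One-factor module fixture: x_i = w_i * f + noise, small noise.

    Weights are drawn uniform on [0.5, 1.0]; sites with w_i >= 0.95 are the
    planted hubs. Returns the levels-scale matrix (0.4 + 0.1 * x clipped),
    the latent factor and the weights.
    """
    rng = rng or np.random.default_rng(0)
    f = rng.standard_normal(n_samples)
    w = rng.uniform(0.5, 1.0, n_sites)
    X = w[:, None] * f[None, :] + noise_sd * rng.standard_normal(
        (n_sites, n_samples))
    levels = np.clip(0.4 + 0.1 * X, 0.01, 0.99)
    mat = pd.DataFrame(levels, index=[f"s{i + 1:03d}" for i in range(n_sites)],
                       columns=[f"c{j + 1}" for j in range(n_samples)])
    return {"levels": mat, "factor": f,
            "weights": pd.Series(w, index=mat.index)}


def matrix_to_interrogation(sim: dict) -> pd.DataFrame:
    """Reshape a simulated matrix into the long interrogation frame."""
    rows = []
    edited, total = sim["edited"], sim["total"]
    for site in edited.index:
        for sample in edited.columns:
            e, t = int(edited.at[site, sample]), int(total.at[site, sample])
            rows.append({"site": site, "sample_id": sample, "edited": e,
                         "total": t, "level": e / t if t >= 5 else np.nan,
                         "qualified": t >= 5})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# miRNA retargeting fixture
# ---------------------------------------------------------------------------

_RNA_COMP = {"A": "U", "C": "G", "G": "C", "T": "A", "U": "A"}


def _perfect_mirna(query: str, site_offset: int, seed_pos: int,
                   length: int) -> str | None:
    """miRNA (5'->3') perfectly complementary to the query window placing
    the site at miRNA seed position ``seed_pos``."""
    a = site_offset - length + seed_pos  # query index paired with miRNA 3' end
    if a < 0 or a + length > len(query):
        return None
    window = query[a:a + length]
    return "".join(_RNA_COMP[b] for b in reversed(window))


def simulate_mirna_fixture(reference: Reference, config: SimulationConfig,
                           rng: np.random.Generator | None = None,
                           scan_params: ScanParams | None = None) -> dict:
    """3'UTR editing sites plus miRNAs planted as gain/loss/neutral events.

    For a gain event the miRNA matches the edited (G) allele and misses the
    reference allele at default thresholds; loss events are symmetric;
    neutral sites match no miRNA. Every event is verified through the
    actual scanner, with bounded retries, so the truth is correct by
    construction.
    """
    rng = rng or np.random.default_rng(config.seed + 3)
    mc = config.mirna
    sp = scan_params or ScanParams()
    utr3_sites: list[EditingSite] = []
    for g in reference.genes:
        if g.biotype != "coding":
            continue
        seq = reference.sequences[g.chrom]
        for (s, e) in g.utr3:
            for pos0 in range(s + 35, e - 35):
                base = seq[pos0]
                want = "A" if g.strand == "+" else "T"
                if base != want:
                    continue
                var = "G" if base == "A" else "C"
                utr3_sites.append(EditingSite(
                    chrom=g.chrom, pos0=pos0, ref_base=base, var_base=var,
                    strand=g.strand, region_class="UTR3",
                    gene_ids=[g.gene_id], edited_reads=1, total_reads=2))
    rng.shuffle(utr3_sites)
    need = mc.n_gain_events + mc.n_loss_events + mc.n_neutral_sites
    if len(utr3_sites) < need:
        raise RuntimeError("not enough 3'UTR adenosines for the fixture")

    mirnas: dict[str, str] = {}
    for i in range(mc.n_mirnas):
        mirnas[f"mir_bg_{i + 1}"] = "".join(
            "ACGU"[int(rng.integers(0, 4))] for _ in range(mc.mirna_len))

    events: list[dict] = []
    site_iter = iter(utr3_sites)

    def plant(kind: str, index: int) -> tuple[EditingSite, str, str]:
        for site in site_iter:
            pair = build_allele_queries(site, reference.sequences,
                                        reference.genes)
            if pair.truncated:
                continue
            target = pair.edit_query if kind == "gain" else pair.ref_query
            for _ in range(mc.max_tries):
                seed_pos = int(rng.integers(3, 8))
                core = _perfect_mirna(target, pair.site_offset, seed_pos,
                                      mc.mirna_len)
                if core is None:
                    break
                seq = list(core)
                n_mm = int(rng.integers(2, 4))
                # mutate non-seed positions away from the site pairing
                cand = [p for p in range(9, mc.mirna_len - 2)]
                rng.shuffle(cand)
                for p in cand[:n_mm]:
                    cur = seq[p]
                    seq[p] = {"A": "C", "C": "A", "G": "A", "U": "C"}[cur]
                mir = "".join(seq)
                if _verify_event(pair, mir, kind, sp):
                    return site, f"mir_{kind}_{index}", mir
        raise RuntimeError(f"could not plant {kind} event after retries")

    chosen_sites: list[EditingSite] = []
    for i in range(mc.n_gain_events):
        site, mid, mir = plant("gain", i + 1)
        mirnas[mid] = mir
        chosen_sites.append(site)
        events.append({"site": f"{site.chrom}:{site.pos0 + 1}:{site.var_base}",
                       "mirna": mid, "kind": "gain"})
    for i in range(mc.n_loss_events):
        site, mid, mir = plant("loss", i + 1)
        mirnas[mid] = mir
        chosen_sites.append(site)
        events.append({"site": f"{site.chrom}:{site.pos0 + 1}:{site.var_base}",
                       "mirna": mid, "kind": "loss"})
    neutral: list[EditingSite] = []
    for site in site_iter:
        if len(neutral) >= mc.n_neutral_sites:
            break
        pair = build_allele_queries(site, reference.sequences, reference.genes)
        hits = scan_targets(pair, mirnas, sp)
        if any(h.covers_site for h in hits):
            continue
        neutral.append(site)
        events.append({"site": f"{site.chrom}:{site.pos0 + 1}:{site.var_base}",
                       "mirna": None, "kind": "neutral"})
    return {"sites": chosen_sites + neutral, "mirnas": mirnas,
            "events": pd.DataFrame(events)}


def _verify_event(pair: AlleleQueryPair, mirna: str, kind: str,
                  sp: ScanParams) -> bool:
    hits = scan_targets(pair, {"x": mirna}, sp)
    ref_cov = any(h.covers_site for h in hits if h.allele == "ref")
    edit_cov = any(h.covers_site for h in hits if h.allele == "edit")
    if kind == "gain":
        return edit_cov and not ref_cov
    return ref_cov and not edit_cov


# ---------------------------------------------------------------------------
# orchestration / file emission
# ---------------------------------------------------------------------------

def simulate_dataset(config: SimulationConfig) -> dict:
    """Reference + truth + observations, all in memory."""
    root = np.random.default_rng(config.seed)
    seeds = root.integers(0, 2 ** 31 - 1, size=4)
    reference = simulate_reference(config, np.random.default_rng(seeds[0]))
    truth = plant_truth(reference, config, np.random.default_rng(seeds[1]))
    rna, dna = simulate_observations(reference, truth, config,
                                     np.random.default_rng(seeds[2]))
    return {"reference": reference, "truth": truth, "rna": rna, "dna": dna}


def write_dataset(dataset: dict, out_dir: str | Path,
                  config: SimulationConfig) -> SampleSheet:
    """Emit every standard-format file plus the truth tables."""
    out = Path(out_dir)
    (out / "truth").mkdir(parents=True, exist_ok=True)
    ref: Reference = dataset["reference"]
    truth: TruthTables = dataset["truth"]
    eio.write_fasta(ref.sequences, out / "ref.fa")
    eio.write_gene_models_bed12(ref.genes, out / "genes.bed")
    eio.write_interval_mask(ref.alu, out / "alu.bed")
    eio.write_interval_mask(ref.similarity, out / "similarity.bed")
    eio.write_variant_positions(
        [(c, p, r, a) for c, p, r, a, _ in truth.snps], out / "snps.vcf")
    records = []
    for sid, frame in dataset["rna"].items():
        path = out / f"obs_{sid}.tsv"
        eio.write_observations(frame, path)
        records.append(SampleRecord(sid, "cellA", sid, str(path)))
    eio.write_observations(dataset["dna"], out / "obs_dna.tsv")
    sheet = SampleSheet(records)
    eio.write_sample_sheet(sheet, out / "samples.tsv")
    pd.DataFrame([s.__dict__ for s in truth.editing_sites]).to_csv(
        out / "truth" / "editing_sites.tsv", sep="\t", index=False)
    pd.DataFrame(truth.snps, columns=["chrom", "pos0", "ref", "alt",
                                      "zygosity"]).to_csv(
        out / "truth" / "snps.tsv", sep="\t", index=False)
    pd.DataFrame(truth.hexamer_sites,
                 columns=["chrom", "pos0", "var"]).to_csv(
        out / "truth" / "hexamer_sites.tsv", sep="\t", index=False)
    pd.DataFrame(truth.homopolymer_sites,
                 columns=["chrom", "pos0", "var"]).to_csv(
        out / "truth" / "homopolymer_sites.tsv", sep="\t", index=False)
    return sheet
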