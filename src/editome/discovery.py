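"""Candidate variant calling and the editing-site filter cascade.

A candidate requires at least ``min_depth`` qualified RNA reads (BAQ >=
``min_baq``, MAPQ >= ``min_mapq``) of which at least ``min_variant_reads``
carry the most frequent non-reference base. Bases within the first
``hexamer_prefix_len`` positions of a read are excluded before counting
(random-hexamer priming artifacts). Candidates are then filtered against
genomic (DNA) read evidence and known SNP positions; candidates outside the
Alu mask must additionally pass a frequency floor, a splice-junction
distance rule, a homopolymer rule, and a genome-similarity mask. Each filter
is subtractive and idempotent: it only marks its own audit flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io as eio
from .types import (
    CallerParams,
    COMPLEMENT,
    EditingSite,
    GeneModel,
    IntervalSet,
    SampleSheet,
)

logger = logging.getLogger(__name__)

#: Site-level filters, in cascade order. Audit flags are True when passed.
FILTER_NAMES = ("genomic_evidence", "known_snp", "frequency", "splice",
                "homopolymer", "similarity")


@dataclass
class CandidateSite:
    """A candidate RNA variant with per-filter audit flags."""

    chrom: str
    pos0: int
    ref_base: str
    var_base: str
    edited_reads: int
    total_reads: int
    variant_read_pos: list[int] = field(default_factory=list)
    in_alu: bool = False
    filters: dict[str, bool] = field(default_factory=dict)

    @property
    def level(self) -> float:
        return self.edited_reads / self.total_reads if self.total_reads else 0.0

    @property
    def retained(self) -> bool:
        return all(self.filters.get(name, True) for name in FILTER_NAMES)


def _as_frame(obs) -> pd.DataFrame:
    if isinstance(obs, pd.DataFrame):
        return obs
    rows = [(o.sample_id, o.chrom, o.pos0, o.ref_base, o.obs_base,
             o.base_quality, o.map_quality, o.read_pos, o.read_id)
            for o in obs]
    return pd.DataFrame(rows, columns=["sample_id", "chrom", "pos0", "ref",
                                       "base", "baq", "mapq", "read_pos",
                                       "read_id"])


def filter_hexamer_prefix(obs: pd.DataFrame,
                          prefix_len: int = 6) -> pd.DataFrame:
    """Drop observations within the first ``prefix_len`` bases of a read."""
    obs = _as_frame(obs)
    return obs[obs["read_pos"] > prefix_len]


def qualified_observations(obs: pd.DataFrame, params: CallerParams,
                           exclude_read_prefix: bool = True) -> pd.DataFrame:
    """Observations meeting the BAQ/MAPQ thresholds, excluding N calls.

    ``exclude_read_prefix`` additionally applies the hexamer rule; DNA
    observations are qualified without it (the artifact is specific to
    randomly-primed RNA-seq reads).
    """
    obs = _as_frame(obs)
    mask = ((obs["baq"] >= params.min_baq)
            & (obs["mapq"] >= params.min_mapq)
            & (obs["base"] != "N"))
    out = obs[mask]
    if exclude_read_prefix:
        out = filter_hexamer_prefix(out, params.hexamer_prefix_len)
    return out


def call_candidates(obs, params: CallerParams | None = None
                    ) -> list[CandidateSite]:
    """Call candidate variants from one sample's observations.

    Returns candidates sorted by (chrom, pos0). Columns whose two most
    frequent non-reference bases tie in both count and summed base quality
    are dropped (logged) — a deterministic, conservative resolution.
    """
    params = params or CallerParams()
    q = qualified_observations(obs, params)
    if q.empty:
        return []
    if q["sample_id"].nunique() > 1:
        raise ValueError("call_candidates expects observations of one sample")

    grp = q.groupby(["chrom", "pos0", "ref", "base"], sort=True)
    counts = grp.size().rename("n")
    baqsum = grp["baq"].sum().rename("baq_sum")
    tab = pd.concat([counts, baqsum], axis=1).reset_index()
    depth = tab.groupby(["chrom", "pos0", "ref"])["n"].sum().rename("depth")

    nonref = tab[tab["base"] != tab["ref"]]
    pending: list[tuple[str, int, str, str, int, int]] = []
    for (chrom, pos0, ref), sub in nonref.groupby(["chrom", "pos0", "ref"],
                                                  sort=True):
        d = int(depth.loc[(chrom, pos0, ref)])
        if d < params.min_depth:
            continue
        best = sub.sort_values(["n", "baq_sum", "base"],
                               ascending=[False, False, True])
        top = best.iloc[0]
        if int(top["n"]) < params.min_variant_reads:
            continue
        if len(best) > 1:
            second = best.iloc[1]
            if (second["n"] == top["n"]
                    and second["baq_sum"] == top["baq_sum"]):
                logger.info("dropping tied variant column %s:%d", chrom,
                            pos0 + 1)
                continue
        pending.append((str(chrom), int(pos0), str(ref), str(top["base"]),
                        int(top["n"]), d))
    keys = {(c, p, v) for c, p, _r, v, _n, _d in pending}
    sup = q[pd.MultiIndex.from_frame(q[["chrom", "pos0", "base"]]).isin(keys)]
    support = sup.groupby(["chrom", "pos0", "base"])["read_pos"].agg(list)
    return [CandidateSite(chrom=c, pos0=p, ref_base=r, var_base=v,
                          edited_reads=n, total_reads=d,
                          variant_read_pos=sorted(support.get((c, p, v), [])))
            for c, p, r, v, n, d in pending]


# ---------------------------------------------------------------------------
# site-level filters
# ---------------------------------------------------------------------------

def filter_genomic_evidence(cands: list[CandidateSite], dna_obs,
                            params: CallerParams | None = None
                            ) -> list[CandidateSite]:
    """Fail candidates with DNA variant evidence or insufficient DNA depth.

    A candidate passes only when qualified DNA depth >= ``min_dna_depth``
    and at most ``max_dna_variant_reads`` DNA reads carry the variant base:
    absence from the genome must be positively demonstrated.
    """
    params = params or CallerParams()
    q = qualified_observations(dna_obs, params, exclude_read_prefix=False)
    keys = {(c.chrom, c.pos0) for c in cands}
    if not q.empty:
        q = q[pd.MultiIndex.from_frame(q[["chrom", "pos0"]]).isin(keys)]
    depth = q.groupby(["chrom", "pos0"]).size() if not q.empty else pd.Series(dtype=int)
    for c in cands:
        d = int(depth.get((c.chrom, c.pos0), 0))
        if d < params.min_dna_depth:
            ok = False
        else:
            nvar = int(((q["chrom"] == c.chrom) & (q["pos0"] == c.pos0)
                        & (q["base"] == c.var_base)).sum())
            ok = nvar <= params.max_dna_variant_reads
        c.filters["genomic_evidence"] = ok
    return cands


def filter_known_variants(cands: list[CandidateSite],
                          variant_sets) -> list[CandidateSite]:
    """Fail candidates whose position appears in any known-variant set.

    Exclusion is position-level: any catalogued allele at the position
    disqualifies the candidate.
    """
    positions: set[tuple[str, int]] = set()
    for vs in variant_sets:
        positions.update((chrom, pos0) for chrom, pos0, _alt in vs)
    for c in cands:
        c.filters["known_snp"] = (c.chrom, c.pos0) not in positions
    return cands


def homopolymer_run_length(ref_seq: str, pos0: int) -> int:
    """Length of the run of identical reference bases covering ``pos0``."""
    base = ref_seq[pos0]
    i = pos0
    while i > 0 and ref_seq[i - 1] == base:
        i -= 1
    j = pos0
    while j + 1 < len(ref_seq) and ref_seq[j + 1] == base:
        j += 1
    return j - i + 1


def splice_junction_distance(pos0: int, genes: list[GeneModel]) -> int | None:
    """Distance (bp) from an intronic position to the nearest exon boundary.

    Returns None when the position is not intronic in any overlapping gene
    (exonic or intergenic). Distance 1 means immediately adjacent to the
    junction.
    """
    best: int | None = None
    for g in genes:
        if not g.contains(pos0) or g.in_intervals(pos0, "exons"):
            continue
        for (s1, e1), (s2, e2) in zip(g.exons, g.exons[1:]):
            if e1 <= pos0 < s2:
                d = min(pos0 - e1 + 1, s2 - pos0)
                best = d if best is None else min(best, d)
                break
    return best


def apply_non_alu_filters(cands: list[CandidateSite], alu: IntervalSet,
                          genes: list[GeneModel], ref: dict[str, str],
                          similarity: IntervalSet | None = None,
                          params: CallerParams | None = None
                          ) -> list[CandidateSite]:
    """Apply the four non-Alu filters; candidates inside Alu are exempt.

    Non-Alu candidates fail on: level below ``non_alu_min_freq``; intronic
    position within ``splice_flank_bp`` of an annotated exon boundary; a
    homopolymer run >= ``homopolymer_min_run`` covering the site; or
    membership in the genome-similarity mask.
    """
    params = params or CallerParams()
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for c in cands:
        c.in_alu = (c.chrom, c.pos0) in alu
        if c.in_alu:
            for name in ("frequency", "splice", "homopolymer", "similarity"):
                c.filters[name] = True
            continue
        c.filters["frequency"] = c.level >= params.non_alu_min_freq
        dist = splice_junction_distance(c.pos0, by_chrom.get(c.chrom, []))
        c.filters["splice"] = dist is None or dist > params.splice_flank_bp
        if c.chrom not in ref:
            raise KeyError(f"reference sequence missing for {c.chrom}")
        run = homopolymer_run_length(ref[c.chrom], c.pos0)
        c.filters["homopolymer"] = run < params.homopolymer_min_run
        in_sim = similarity is not None and (c.chrom, c.pos0) in similarity
        c.filters["similarity"] = not in_sim
    return cands


# ---------------------------------------------------------------------------
# strand assignment and replicate intersection
# ---------------------------------------------------------------------------

def assign_strand(sites: list[EditingSite],
                  genes: list[GeneModel]) -> list[EditingSite]:
    """Assign strand from overlapping gene models; re-express subst_type.

    A strand is assigned only when every overlapping gene model is on the
    same strand; otherwise the strand stays unknown and the substitution
    stays genomic. On '-' the substitution is complemented (genomic T>C
    becomes A>G).
    """
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for s in sites:
        overlapping = [g for g in by_chrom.get(s.chrom, [])
                       if g.contains(s.pos0)]
        strands = {g.strand for g in overlapping}
        if len(strands) == 1:
            s.strand = strands.pop()
        else:
            s.strand = "."
        if s.strand == "-":
            s.subst_type = (f"{COMPLEMENT[s.ref_base]}>"
                            f"{COMPLEMENT[s.var_base]}")
        else:
            s.subst_type = f"{s.ref_base}>{s.var_base}"
    return sites


def candidate_to_site(c: CandidateSite) -> EditingSite:
    return EditingSite(chrom=c.chrom, pos0=c.pos0, ref_base=c.ref_base,
                       var_base=c.var_base, in_alu=c.in_alu,
                       edited_reads=c.edited_reads, total_reads=c.total_reads)


def intersect_replicates(sites_a: list[EditingSite],
                         sites_b: list[EditingSite]
                         ) -> dict[str, list]:
    """Split two replicates' sites into shared and replicate-specific sets.

    Sites are matched on (chrom, pos0, var_base). ``shared`` holds
    (site_a, site_b) pairs so per-replicate read support is retained.
    """
    index_b = {s.key: s for s in sites_b}
    shared, only_a = [], []
    for s in sites_a:
        other = index_b.pop(s.key, None)
        if other is not None:
            shared.append((s, other))
        else:
            only_a.append(s)
    return {"shared": shared, "specific_a": only_a,
            "specific_b": list(index_b.values())}


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def run_sample_cascade(obs, resources: dict, params: CallerParams | None = None
                       ) -> tuple[list[CandidateSite], dict[str, int]]:
    """Run the full cascade on one sample; returns candidates + attrition.

    ``resources`` keys: ``dna_obs`` (frame), ``snp_sets`` (list of variant
    sets), ``alu`` and ``similarity`` (IntervalSet), ``genes`` (GeneModel
    list), ``ref`` (chrom -> sequence).
    """
    params = params or CallerParams()
    cands = call_candidates(obs, params)
    attrition = {"candidates": len(cands)}
    cands = filter_genomic_evidence(cands, resources["dna_obs"], params)
    cands = filter_known_variants(cands, resources.get("snp_sets", []))
    cands = apply_non_alu_filters(cands, resources["alu"], resources["genes"],
                                  resources["ref"],
                                  resources.get("similarity"), params)
    for name in FILTER_NAMES:
        attrition[f"failed_{name}"] = sum(
            1 for c in cands if not c.filters.get(name, True))
    attrition["retained"] = sum(1 for c in cands if c.retained)
    return cands, attrition


def audit_frame(cands: list[CandidateSite]) -> pd.DataFrame:
    rows = []
    for c in cands:
        row = {"chrom": c.chrom, "pos": c.pos0 + 1, "ref": c.ref_base,
               "var": c.var_base, "edited_reads": c.edited_reads,
               "total_reads": c.total_reads, "level": round(c.level, 6),
               "in_alu": int(c.in_alu)}
        for name in FILTER_NAMES:
            row[f"pass_{name}"] = int(c.filters.get(name, True))
        row["retained"] = int(c.retained)
        rows.append(row)
    return pd.DataFrame(rows)


def run_site_discovery(sample_sheet: SampleSheet, resources: dict,
                       params: CallerParams | None = None,
                       out_dir: str | Path | None = None) -> dict:
    """Run discovery for every sample in the sheet and intersect replicates.

    Returns per-sample retained EditingSite lists (strand-assigned), audit
    frames, attrition counts, and per-cell-type shared sites (present in
    every replicate of the cell type). Deterministic given inputs; when
    ``out_dir`` is given, site/audit TSVs are written there.
    """
    params = params or CallerParams()
    per_sample: dict[str, list[EditingSite]] = {}
    audits: dict[str, pd.DataFrame] = {}
    attritions: dict[str, dict[str, int]] = {}
    for rec in sample_sheet:
        obs = eio.read_observations_frame(rec.path, sample_id=rec.sample_id)
        try:
            cands, attrition = run_sample_cascade(obs, resources, params)
        except Exception as exc:
            raise RuntimeError(
                f"site discovery failed for sample {rec.sample_id}") from exc
        sites = [candidate_to_site(c) for c in cands if c.retained]
        assign_strand(sites, resources["genes"])
        from .annotate import annotate_region  # deferred: avoids cycle
        annotate_region(sites, resources["genes"])
        per_sample[rec.sample_id] = sites
        audits[rec.sample_id] = audit_frame(cands)
        attritions[rec.sample_id] = attrition
        logger.info("sample %s attrition: %s", rec.sample_id, attrition)

    shared: dict[str, list[EditingSite]] = {}
    by_type: dict[str, list[str]] = {}
    for rec in sample_sheet:
        by_type.setdefault(rec.cell_type, []).append(rec.sample_id)
    for cell_type, sample_ids in by_type.items():
        if len(sample_ids) < 2:
            continue
        current = per_sample[sample_ids[0]]
        for other_id in sample_ids[1:]:
            pairs = intersect_replicates(current, per_sample[other_id])
            current = [a for a, _ in pairs["shared"]]
        shared[cell_type] = current

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for sid, sites in per_sample.items():
            eio.write_site_table(sites, out / f"sites_{sid}.tsv")
            audits[sid].to_csv(out / f"audit_{sid}.tsv", sep="\t", index=False)
        for cell_type, sites in shared.items():
            eio.write_site_table(sites, out / f"shared_{cell_type}.tsv")
        pd.DataFrame(attritions).to_csv(out / "attrition.tsv", sep="\t")
    return {"per_sample": per_sample, "audits": audits,
            "attrition": attritions, "shared": shared}
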