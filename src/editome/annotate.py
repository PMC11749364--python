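"""Editome annotation, substitution spectrum, and enrichment analyses."""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import EditingSite, GeneModel, SUBSTITUTION_TYPES

logger = logging.getLogger(__name__)

#: Region classes in precedence order when several gene models overlap.
REGION_PRECEDENCE = ("CDS", "UTR3", "UTR5", "ncRNA_exonic", "intronic",
                     "ncRNA_intronic", "intergenic")


def substitution_spectrum(sites: list[EditingSite],
                          reclassified: bool = True) -> pd.DataFrame:
    """Counts and fractions of the 12 substitution types.

    With ``reclassified`` the strand-aware ``subst_type`` is tallied (a
    genomic T>C inside a minus-strand gene counts as A>G); otherwise the
    genomic-strand substitution is used. Fractions sum to 1 over non-empty
    input.
    """
    counts = dict.fromkeys(SUBSTITUTION_TYPES, 0)
    for s in sites:
        st = s.subst_type if reclassified else f"{s.ref_base}>{s.var_base}"
        counts[st] += 1
    total = sum(counts.values())
    return pd.DataFrame({
        "count": pd.Series(counts),
        "fraction": pd.Series({k: (v / total if total else 0.0)
                               for k, v in counts.items()}),
    })


def classify_position(pos0: int, chrom: str, genes: list[GeneModel]
                      ) -> tuple[str, list[str]]:
    """Region class and gene ids for one genomic position.

    When several gene models overlap, the highest-precedence class wins
    (CDS > UTR3 > UTR5 > ncRNA_exonic > intronic > ncRNA_intronic);
    positions overlapping no model are intergenic with no genes.
    """
    classes: list[str] = []
    gene_ids: list[str] = []
    for g in genes:
        if g.chrom != chrom or not g.contains(pos0):
            continue
        gene_ids.append(g.gene_id)
        if g.biotype == "ncRNA":
            cls = ("ncRNA_exonic" if g.in_intervals(pos0, "exons")
                   else "ncRNA_intronic")
        elif g.in_intervals(pos0, "cds"):
            cls = "CDS"
        elif g.in_intervals(pos0, "utr3"):
            cls = "UTR3"
        elif g.in_intervals(pos0, "utr5"):
            cls = "UTR5"
        elif g.in_intervals(pos0, "exons"):
            # exonic but outside annotated CDS/UTR (e.g. block not split);
            # treat by gene biotype as coding-exonic fallback
            cls = "CDS"
        else:
            cls = "intronic"
        classes.append(cls)
    if not classes:
        return "intergenic", []
    best = min(classes, key=REGION_PRECEDENCE.index)
    if len(set(classes)) > 1:
        logger.debug("position %s:%d multi-class %s -> %s", chrom, pos0 + 1,
                     classes, best)
    return best, sorted(set(gene_ids))


def annotate_region(sites: list[EditingSite],
                    genes: list[GeneModel]) -> list[EditingSite]:
    """Set ``region_class`` and ``gene_ids`` on every site (in place)."""
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for s in sites:
        cls, gids = classify_position(s.pos0, s.chrom,
                                      by_chrom.get(s.chrom, []))
        s.region_class = cls
        s.gene_ids = gids
    return sites


def category_enrichment(sites: list[EditingSite],
                        covered_background: dict[str, int],
                        alpha: float = 0.05) -> pd.DataFrame:
    """Coverage-normalised per-category enrichment of edited sites.

    ``covered_background`` maps region class to the number of adenosines
    with qualified coverage in that class. Per category a two-sided Fisher
    exact test compares {edited, covered-not-edited} x {in category,
    elsewhere}; p-values are BH-adjusted across categories.
    """
    edited = pd.Series([s.region_class for s in sites]).value_counts()
    cats = [c for c, n in covered_background.items() if n > 0]
    skipped = [c for c, n in covered_background.items() if n <= 0]
    if skipped:
        warnings.warn(f"categories with zero background excluded: {skipped}")
    edited_total = int(edited.reindex(cats).fillna(0).sum())
    bg_total = sum(covered_background[c] for c in cats)
    rows = []
    for cat in cats:
        a = int(edited.get(cat, 0))
        b = edited_total - a
        c = covered_background[cat] - a
        d = (bg_total - covered_background[cat]) - b
        odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        rows.append({"category": cat, "edited_in": a, "edited_out": b,
                     "background_in": covered_background[cat],
                     "background_out": bg_total - covered_background[cat],
                     "odds_ratio": odds, "p": p})
    res = pd.DataFrame(rows)
    if not res.empty:
        res["p_adjusted"] = multipletests(res["p"], method="fdr_bh")[1]
        res["significant"] = res["p_adjusted"] < alpha
    return res


def compare_proportions(k1: int, n1: int, k2: int, n2: int
                        ) -> tuple[float, float]:
    """Two-sided Fisher exact comparison of two site-class proportions.

    The generic operation behind questions like "are 3'UTR sites more
    frequent among confirmed DESs (k1 of n1) than among the original DES
    set (k2 of n2)?". Returns (odds_ratio, p).
    """
    odds, p = stats.fisher_exact([[k1, n1 - k1], [k2, n2 - k2]],
                                 alternative="two-sided")
    return float(odds), float(p)


def per_gene_counts(sites: list[EditingSite]) -> tuple[pd.Series, float]:
    """Editing-site count per gene (genes with >= 1 site) and the mean."""
    counts: dict[str, int] = {}
    for s in sites:
        for gid in s.gene_ids:
            counts[gid] = counts.get(gid, 0) + 1
    series = pd.Series(counts, dtype=int).sort_values(ascending=False)
    mean = float(series.mean()) if len(series) else float("nan")
    return series, mean


def level_histogram(sites: list[EditingSite],
                    bin_edges: np.ndarray | None = None) -> np.ndarray:
    """Binned counts of editing levels (default: ten equal bins on [0,1])."""
    if bin_edges is None:
        bin_edges = np.linspace(0.0, 1.0, 11)
    levels = [s.level for s in sites]
    counts, _ = np.histogram(levels, bins=bin_edges)
    return counts


def compare_level_distributions(counts_a: np.ndarray, counts_b: np.ndarray
                                ) -> tuple[float, float]:
    """Chi-square homogeneity test between two binned level distributions.

    Bins whose expected count under homogeneity falls below 5 are merged
    rightward (standard validity rule); all-zero bins disappear in the
    merge. Returns (statistic, p).
    """
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("histograms must share bin edges")
    total = a + b
    grand = total.sum()
    if grand == 0:
        raise ValueError("both histograms empty")
    # expected count in a bin (either row) is proportional to bin total
    merged_a, merged_b = [], []
    acc_a = acc_b = acc_t = 0.0
    min_row = min(a.sum(), b.sum())
    for i in range(len(a)):
        acc_a += a[i]
        acc_b += b[i]
        acc_t += total[i]
        expected_min = acc_t * min_row / grand
        if expected_min >= 5 or i == len(a) - 1:
            merged_a.append(acc_a)
            merged_b.append(acc_b)
            acc_a = acc_b = acc_t = 0.0
    if acc_t > 0:  # trailing remainder folded into last kept bin
        merged_a[-1] += acc_a
        merged_b[-1] += acc_b
    table = np.array([merged_a, merged_b])
    table = table[:, table.sum(axis=0) > 0]
    if table.shape[1] < 2:
        return 0.0, 1.0
    stat, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(stat), float(p)


def geneset_overrepresentation(gene_list: list[str],
                               gene_sets: dict[str, set[str]],
                               universe: set[str]) -> pd.DataFrame:
    """One-sided hypergeometric over-representation with BH correction.

    Genes outside the universe are dropped with a warning. For a set with
    K universe members, a query of n genes with k hits has
    p = P[X >= k], X ~ Hypergeom(N, K, n).
    """
    query = set(gene_list)
    outside = query - universe
    if outside:
        warnings.warn(f"{len(outside)} query genes outside universe dropped")
        query &= universe
    n_universe = len(universe)
    rows = []
    for name, members in gene_sets.items():
        members_in = members & universe
        k = len(query & members_in)
        K = len(members_in)
        n = len(query)
        p = float(stats.hypergeom.sf(k - 1, n_universe, K, n))
        rows.append({"gene_set": name, "hits": k, "set_size": K,
                     "query_size": n, "universe_size": n_universe, "p": p})
    res = pd.DataFrame(rows)
    if not res.empty:
        res["p_adjusted"] = multipletests(res["p"], method="fdr_bh")[1]
        res = res.sort_values("p", kind="stable").reset_index(drop=True)
    return res


def depth_comparison(shared_sites: list[EditingSite],
                     specific_sites: list[EditingSite]
                     ) -> dict[str, float]:
    """Median read depth of shared vs replicate-specific sites + ranksum p."""
    if not shared_sites or not specific_sites:
        raise ValueError("both site groups must be non-empty")
    depths_a = [s.total_reads for s in shared_sites]
    depths_b = [s.total_reads for s in specific_sites]
    res = stats.mannwhitneyu(depths_a, depths_b, alternative="two-sided",
                             method="auto")
    return {"median_shared": float(np.median(depths_a)),
            "median_specific": float(np.median(depths_b)),
            "p": float(res.pvalue)}
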