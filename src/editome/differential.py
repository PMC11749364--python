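"""Cross-sample interrogation and differentially edited site (DES) calling.

A site is *qualified* in a sample when covered by at least five qualified
reads. DES calling is two-stage: replicate concordance within each group
must pass (two-sided Fisher exact test, p >= alpha for every replicate
pair), then replicates are pooled per group and an exact conditional rate
test is applied — conditioned on the total edited count K = k1 + k2, k1 is
Binomial(K, n1/(n1+n2)) under equal editing rates, the standard exact
construction for comparing two Poisson rates with unequal exposure. A DES
additionally requires a fold change >= ``min_fold`` between the pooled
group levels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .discovery import qualified_observations
from .types import CallerParams, EditingSite

logger = logging.getLogger(__name__)

MIN_QUALIFIED_READS = 5


def interrogate_sites(query_sites: list[EditingSite], obs_by_sample: dict,
                      params: CallerParams | None = None) -> pd.DataFrame:
    """Re-count edited/total qualified reads at query sites in each sample.

    ``obs_by_sample`` maps sample_id to an observation frame. Returns a
    long frame with columns site, sample_id, edited, total, level,
    qualified. The hexamer prefix exclusion applies, matching discovery.
    A site absent from a sample's observations is unqualified there.
    """
    params = params or CallerParams()
    keys = [f"{s.chrom}:{s.pos0 + 1}:{s.var_base}" for s in query_sites]
    rows = []
    for sample_id, obs in obs_by_sample.items():
        q = qualified_observations(obs, params)
        grouped = q.groupby(["chrom", "pos0"])
        depth = grouped.size()
        var_counts = q.groupby(["chrom", "pos0", "base"]).size()
        for site, key in zip(query_sites, keys):
            total = int(depth.get((site.chrom, site.pos0), 0))
            edited = int(var_counts.get((site.chrom, site.pos0,
                                         site.var_base), 0))
            qualified = total >= MIN_QUALIFIED_READS
            rows.append({
                "site": key, "sample_id": sample_id, "edited": edited,
                "total": total,
                "level": edited / total if qualified else np.nan,
                "qualified": qualified})
    return pd.DataFrame(rows)


def replicate_concordance(k1: int, n1: int, k2: int, n2: int,
                          alpha: float = 0.05) -> tuple[float, bool]:
    """Two-sided Fisher exact test of equal editing level in two replicates.

    Passes when p >= alpha (no significant replicate disagreement).
    Either replicate with zero qualified reads makes the site ineligible.
    """
    if n1 == 0 or n2 == 0:
        raise ValueError("replicate with zero qualified reads is ineligible")
    _, p = stats.fisher_exact([[k1, n1 - k1], [k2, n2 - k2]],
                              alternative="two-sided")
    return float(p), p >= alpha


def poisson_rate_test(k1: int, n1: int, k2: int, n2: int) -> float:
    """Exact conditional test of equal editing rates with unequal exposure.

    Under the null, conditional on K = k1 + k2, k1 ~ Binomial(K,
    n1/(n1+n2)). Two-sided p sums all outcomes with point probability not
    exceeding the observed one. K = 0 gives p = 1.
    """
    K = k1 + k2
    if K == 0:
        return 1.0
    if n1 <= 0 or n2 <= 0:
        raise ValueError("exposures must be positive")
    return float(stats.binomtest(k1, K, n1 / (n1 + n2),
                                 alternative="two-sided").pvalue)


@dataclass
class DESRecord:
    site: str
    k_a: int
    n_a: int
    k_b: int
    n_b: int
    level_a: float
    level_b: float
    concordance_p_a: float
    concordance_p_b: float
    p: float
    p_adjusted: float
    fold_change: float
    direction: str  # 'up'/'down' in B vs A, or 'none'
    status: str  # 'DES' | 'not-DES' | 'ineligible'


def _pooled(rows: pd.DataFrame) -> tuple[int, int]:
    return int(rows["edited"].sum()), int(rows["total"].sum())


def _concordance_all_pairs(rows: pd.DataFrame, alpha: float
                           ) -> tuple[float, bool]:
    """Minimum pairwise Fisher p across replicates; pass iff all pass."""
    reps = list(rows.itertuples())
    if len(reps) == 1:
        logger.debug("single replicate: concordance skipped")
        return float("nan"), True
    min_p, ok = np.inf, True
    for i in range(len(reps)):
        for j in range(i + 1, len(reps)):
            p, passed = replicate_concordance(
                reps[i].edited, reps[i].total, reps[j].edited, reps[j].total,
                alpha)
            min_p = min(min_p, p)
            ok = ok and passed
    return float(min_p), ok


def call_des(levels: pd.DataFrame, groups: dict[str, str], group_a: str,
             group_b: str, alpha: float = 0.05, min_fold: float = 2.0,
             adjust: bool = True) -> pd.DataFrame:
    """Call DESs between two groups from an interrogation frame.

    ``levels`` is the long frame from :func:`interrogate_sites`; ``groups``
    maps sample_id to group name. Per site: replicate concordance must pass
    within each group over qualified replicates; replicates are pooled;
    the exact rate test is BH-adjusted across eligible sites (``adjust``);
    fold change is the ratio of pooled levels (larger over smaller). Sites
    unqualified in any replicate are 'ineligible', never 'not-DES'.
    """
    samples_a = [s for s, g in groups.items() if g == group_a]
    samples_b = [s for s, g in groups.items() if g == group_b]
    if not samples_a or not samples_b:
        raise ValueError("both groups need at least one sample")
    recs: list[DESRecord] = []
    for site, sub in levels.groupby("site", sort=True):
        rows_a = sub[sub["sample_id"].isin(samples_a)]
        rows_b = sub[sub["sample_id"].isin(samples_b)]
        if (len(rows_a) < len(samples_a) or len(rows_b) < len(samples_b)
                or not bool(rows_a["qualified"].all())
                or not bool(rows_b["qualified"].all())):
            recs.append(DESRecord(site, 0, 0, 0, 0, np.nan, np.nan, np.nan,
                                  np.nan, np.nan, np.nan, np.nan, "none",
                                  "ineligible"))
            continue
        p_conc_a, ok_a = _concordance_all_pairs(rows_a, alpha)
        p_conc_b, ok_b = _concordance_all_pairs(rows_b, alpha)
        k_a, n_a = _pooled(rows_a)
        k_b, n_b = _pooled(rows_b)
        level_a, level_b = k_a / n_a, k_b / n_b
        if not (ok_a and ok_b):
            recs.append(DESRecord(site, k_a, n_a, k_b, n_b, level_a, level_b,
                                  p_conc_a, p_conc_b, np.nan, np.nan, np.nan,
                                  "none", "ineligible"))
            continue
        p = poisson_rate_test(k_a, n_a, k_b, n_b)
        lo, hi = sorted([level_a, level_b])
        if hi == 0:
            fold = 1.0
        elif lo == 0:
            fold = np.inf
        else:
            fold = hi / lo
        recs.append(DESRecord(site, k_a, n_a, k_b, n_b, level_a, level_b,
                              p_conc_a, p_conc_b, p, np.nan, fold, "none",
                              "pending"))
    df = pd.DataFrame([r.__dict__ for r in recs])
    eligible = df["status"] == "pending"
    if eligible.any():
        if adjust:
            df.loc[eligible, "p_adjusted"] = multipletests(
                df.loc[eligible, "p"], method="fdr_bh")[1]
        else:
            df.loc[eligible, "p_adjusted"] = df.loc[eligible, "p"]
        is_des = (eligible & (df["p_adjusted"] < alpha)
                  & (df["fold_change"] >= min_fold))
        df.loc[eligible, "status"] = np.where(is_des[eligible], "DES",
                                              "not-DES")
        df.loc[eligible, "direction"] = np.where(
            df.loc[eligible, "level_b"] > df.loc[eligible, "level_a"], "up",
            np.where(df.loc[eligible, "level_b"]
                     < df.loc[eligible, "level_a"], "down", "none"))
    return df


def confirm_des_large_set(matrix: pd.DataFrame, group_labels: dict[str, str],
                          group_a: str, group_b: str, alpha: float = 0.05
                          ) -> pd.DataFrame:
    """Per-site two-sided rank-sum test across samples with BH correction.

    ``matrix`` is sites x samples of editing levels with no missingness
    (sites qualified in every sample). Groups need >= 2 samples each.
    """
    cols_a = [c for c in matrix.columns if group_labels.get(c) == group_a]
    cols_b = [c for c in matrix.columns if group_labels.get(c) == group_b]
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError("each group needs at least two samples")
    pvals = []
    for _, row in matrix.iterrows():
        a, b = row[cols_a].to_numpy(float), row[cols_b].to_numpy(float)
        if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
            pvals.append(1.0)
            continue
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
        pvals.append(float(res.pvalue))
    out = pd.DataFrame({"site": matrix.index, "p": pvals})
    out["p_adjusted"] = multipletests(out["p"], method="fdr_bh")[1]
    out["significant"] = out["p_adjusted"] < alpha
    return out.set_index("site")


def median_level_comparison(levels_a, levels_b) -> dict[str, float]:
    """Median editing level per group over a common site universe + p.

    ``levels_a``/``levels_b`` are per-site level vectors over the same
    qualified sites; p is the two-sided Wilcoxon rank-sum p.
    """
    a = np.asarray(levels_a, float)
    b = np.asarray(levels_b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty site overlap")
    if np.array_equal(a, b):
        p = 1.0
    else:
        p = float(stats.mannwhitneyu(a, b, alternative="two-sided",
                                     method="auto").pvalue)
    return {"median_a": float(np.median(a)), "median_b": float(np.median(b)),
            "p": p}
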