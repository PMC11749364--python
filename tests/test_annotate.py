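import numpy as np
import pytest
from scipy import stats

from editome import annotate as anno
from editome.discovery import assign_strand
from editome.types import EditingSite, GeneModel


def _site(pos, ref="A", var="G", total=10, edited=2, genes=(), cls=None):
    s = EditingSite("chr1", pos, ref, var, edited_reads=edited,
                    total_reads=total, gene_ids=list(genes))
    if cls:
        s.region_class = cls
    return s


class TestSpectrum:
    def test_pure_ag_input_has_fraction_one(self):
        spec = anno.substitution_spectrum([_site(i) for i in range(10)])
        assert spec.loc["A>G", "fraction"] == 1.0
        assert spec["fraction"].sum() == pytest.approx(1.0)

    def test_reclassification_folds_tc_into_ag(self, two_genes):
        sites = [_site(i) for i in range(8)]
        tc = [_site(2100 + i, ref="T", var="C") for i in range(2)]
        assign_strand(sites + tc, two_genes)  # T>C sites sit in gminus
        spec = anno.substitution_spectrum(sites + tc, reclassified=True)
        assert spec.loc["A>G", "fraction"] == 1.0
        genomic = anno.substitution_spectrum(sites + tc, reclassified=False)
        assert genomic.loc["T>C", "count"] == 2

    def test_fractions_match_hand_tally(self, rng):
        from editome.types import BASES, SUBSTITUTION_TYPES
        sites = []
        for _ in range(200):
            ref = str(rng.choice(BASES))
            var = str(rng.choice([b for b in BASES if b != ref]))
            sites.append(_site(int(rng.integers(0, 1000)), ref=ref, var=var))
        spec = anno.substitution_spectrum(sites, reclassified=False)
        for st in SUBSTITUTION_TYPES:
            expected = sum(1 for s in sites
                           if f"{s.ref_base}>{s.var_base}" == st)
            assert spec.loc[st, "count"] == expected

    def test_empty_input_gives_zero_spectrum(self):
        spec = anno.substitution_spectrum([])
        assert spec["count"].sum() == 0
        assert (spec["fraction"] == 0).all()


class TestRegionAnnotation:
    def test_utr3_site_classified(self, two_genes):
        (s,) = anno.annotate_region([_site(1100)], two_genes)
        assert s.region_class == "UTR3"
        assert s.gene_ids == ["gplus"]

    def test_intergenic_site_has_no_genes(self, two_genes):
        (s,) = anno.annotate_region([_site(5000)], two_genes)
        assert s.region_class == "intergenic"
        assert s.gene_ids == []

    def test_every_site_gets_exactly_one_class(self, rng, two_genes):
        sites = [_site(int(p)) for p in rng.integers(0, 3000, 300)]
        anno.annotate_region(sites, two_genes)
        from editome.types import REGION_CLASSES
        assert all(s.region_class in REGION_CLASSES for s in sites)

    def test_matches_per_base_bruteforce(self, rng):
        genes = [
            GeneModel("a", "chr1", "+", exons=[(0, 200), (400, 600)],
                      cds=[(100, 200), (400, 500)], utr5=[(0, 100)],
                      utr3=[(500, 600)]),
            GeneModel("b", "chr1", "-", exons=[(150, 450)],
                      biotype="ncRNA"),
            GeneModel("c", "chr1", "+", exons=[(800, 1000)],
                      biotype="ncRNA"),
            GeneModel("d", "chr1", "+", exons=[(950, 1200)],
                      cds=[(1000, 1100)], utr5=[(950, 1000)],
                      utr3=[(1100, 1200)]),
            GeneModel("e", "chr1", "-", exons=[(1300, 1400), (1500, 1600)],
                      cds=[(1350, 1400), (1500, 1550)], utr3=[(1300, 1350)],
                      utr5=[(1550, 1600)]),
        ]
        order = anno.REGION_PRECEDENCE
        for pos in rng.integers(0, 1700, 300):
            pos = int(pos)
            cls, gids = anno.classify_position(pos, "chr1", genes)
            classes = []
            expected_gids = set()
            for g in genes:
                if not (g.start <= pos < g.end):
                    continue
                expected_gids.add(g.gene_id)
                exonic = any(s <= pos < e for s, e in g.exons)
                if g.biotype == "ncRNA":
                    classes.append("ncRNA_exonic" if exonic
                                   else "ncRNA_intronic")
                elif any(s <= pos < e for s, e in g.cds):
                    classes.append("CDS")
                elif any(s <= pos < e for s, e in g.utr3):
                    classes.append("UTR3")
                elif any(s <= pos < e for s, e in g.utr5):
                    classes.append("UTR5")
                elif exonic:
                    classes.append("CDS")
                else:
                    classes.append("intronic")
            expected = (min(classes, key=order.index) if classes
                        else "intergenic")
            assert cls == expected, pos
            assert set(gids) == expected_gids


class TestCategoryEnrichment:
    BACKGROUND = {"UTR3": 500, "intronic": 3000, "intergenic": 2500,
                  "CDS": 400}

    def test_uniform_draw_is_rarely_significant(self, rng):
        cats = list(self.BACKGROUND)
        weights = np.array([self.BACKGROUND[c] for c in cats], float)
        weights /= weights.sum()
        hits = 0
        for _ in range(100):
            draw = rng.choice(cats, size=120, p=weights)
            sites = [_site(i, cls=str(c)) for i, c in enumerate(draw)]
            res = anno.category_enrichment(sites, self.BACKGROUND)
            if bool(res["significant"].any()):
                hits += 1
        assert hits <= 5  # null draws: <=5% of 100 repeats flag anything

    def test_forced_utr3_concentration_is_top_hit(self):
        sites = [_site(i, cls="UTR3") for i in range(80)]
        sites += [_site(1000 + i, cls="intronic") for i in range(20)]
        res = anno.category_enrichment(sites, self.BACKGROUND)
        row = res.set_index("category").loc["UTR3"]
        assert row["odds_ratio"] > 1
        assert row["p"] == res["p"].min()
        assert row["p_adjusted"] < 0.05

    def test_fisher_p_matches_hypergeometric_enumeration(self, rng):
        for _ in range(20):
            a = int(rng.integers(0, 20))
            b = int(rng.integers(0, 20))
            c = int(rng.integers(0, 20))
            d = int(rng.integers(0, 20))
            if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
                continue
            _, p = stats.fisher_exact([[a, b], [c, d]])
            # enumeration over the fixed-margin family
            n = a + b + c + d
            row, col = a + b, a + c
            pmf_obs = stats.hypergeom.pmf(a, n, row, col)
            total = 0.0
            for x in range(max(0, row + col - n), min(row, col) + 1):
                px = stats.hypergeom.pmf(x, n, row, col)
                if px <= pmf_obs * (1 + 1e-9):
                    total += px
            assert p == pytest.approx(total, abs=1e-12)

    def test_zero_background_category_excluded_with_warning(self):
        sites = [_site(0, cls="UTR3")]
        with pytest.warns(UserWarning, match="zero background"):
            res = anno.category_enrichment(sites, {"UTR3": 100, "CDS": 0})
        assert "CDS" not in set(res["category"])


class TestPerGeneCounts:
    def test_single_gene_count(self):
        sites = [_site(i, genes=["CYP20A"], cls="UTR3") for i in range(33)]
        counts, mean = anno.per_gene_counts(sites)
        assert counts["CYP20A"] == 33
        assert mean == 33.0

    def test_empty_input(self):
        counts, mean = anno.per_gene_counts([])
        assert counts.empty and np.isnan(mean)

    def test_matches_groupby_oracle(self, rng):
        genes = [f"g{i}" for i in range(20)]
        sites = []
        tally = {}
        for i in range(300):
            g = str(rng.choice(genes))
            sites.append(_site(i, genes=[g]))
            tally[g] = tally.get(g, 0) + 1
        counts, mean = anno.per_gene_counts(sites)
        assert counts.to_dict() == tally
        assert mean == pytest.approx(np.mean(list(tally.values())))


class TestLevelDistributions:
    def _sites(self, levels):
        return [_site(i, edited=int(round(l * 1000)), total=1000)
                for i, l in enumerate(levels)]

    def test_identical_distributions_not_significant(self, rng):
        levels = rng.uniform(0, 1, 400)
        h = anno.level_histogram(self._sites(levels))
        stat, p = anno.compare_level_distributions(h, h)
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_separated_distributions_are_significant(self, rng):
        high = anno.level_histogram(self._sites(rng.uniform(0.9, 1.0, 300)))
        flat = anno.level_histogram(self._sites(rng.uniform(0, 1, 300)))
        stat, p = anno.compare_level_distributions(high, flat)
        assert p < 1e-10

    def test_statistic_matches_textbook_formula(self, rng):
        a = rng.integers(10, 60, 6).astype(float)
        b = rng.integers(10, 60, 6).astype(float)
        stat, _ = anno.compare_level_distributions(a, b)
        table = np.array([a, b])
        expected = 0.0
        rowsums = table.sum(axis=1, keepdims=True)
        colsums = table.sum(axis=0, keepdims=True)
        exp = rowsums @ colsums / table.sum()
        expected = ((table - exp) ** 2 / exp).sum()
        assert stat == pytest.approx(expected, rel=1e-12)


class TestGenesetOverrepresentation:
    def test_whole_set_query_is_top_ranked(self):
        universe = {f"g{i}" for i in range(100)}
        sets = {"target": {f"g{i}" for i in range(10)},
                "other": {f"g{i}" for i in range(40, 90)}}
        res = anno.geneset_overrepresentation(
            [f"g{i}" for i in range(10)], sets, universe)
        assert res.iloc[0]["gene_set"] == "target"
        assert res.iloc[0]["p"] < 1e-10

    def test_gene_outside_universe_dropped_with_warning(self):
        universe = {"a", "b"}
        with pytest.warns(UserWarning, match="outside universe"):
            res = anno.geneset_overrepresentation(
                ["a", "zzz"], {"s": {"a"}}, universe)
        assert res.iloc[0]["query_size"] == 1

    def test_p_matches_enumeration_on_small_universes(self, rng):
        from itertools import combinations
        for _ in range(10):
            n_u = int(rng.integers(6, 12))
            universe = {f"g{i}" for i in range(n_u)}
            members = set(rng.choice(sorted(universe),
                                     int(rng.integers(1, n_u)),
                                     replace=False))
            query = set(rng.choice(sorted(universe),
                                   int(rng.integers(1, n_u)), replace=False))
            res = anno.geneset_overrepresentation(
                sorted(query), {"s": members}, universe)
            k = len(query & members)
            # exact enumeration of draws of |query| genes from the universe
            hits = total = 0
            for combo in combinations(sorted(universe), len(query)):
                total += 1
                if len(set(combo) & members) >= k:
                    hits += 1
            assert res.iloc[0]["p"] == pytest.approx(hits / total, abs=1e-12)


class TestDepthComparison:
    def test_identical_groups_boundary(self):
        a = [_site(i, total=10) for i in range(6)]
        res = anno.depth_comparison(a, list(a))
        assert res["median_shared"] == res["median_specific"]
        assert res["p"] == pytest.approx(1.0, abs=0.05)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            anno.depth_comparison([], [_site(0)])

    def test_p_matches_exact_enumeration_small_n(self, rng):
        from itertools import combinations
        for _ in range(10):
            n1, n2 = int(rng.integers(3, 5)), int(rng.integers(3, 5))
            depths = rng.choice(np.arange(5, 200), n1 + n2,
                                replace=False)
            a = [_site(i, total=int(d)) for i, d in enumerate(depths[:n1])]
            b = [_site(100 + i, total=int(d))
                 for i, d in enumerate(depths[n1:])]
            res = anno.depth_comparison(a, b)
            # enumerate the exact distribution of the rank-sum statistic
            pooled = list(depths)
            obs_u = sum(1 for x in depths[:n1] for y in depths[n1:] if x > y)
            us = []
            idx = range(len(pooled))
            for combo in combinations(idx, n1):
                grp = set(combo)
                u = sum(1 for i in combo for j in idx if j not in grp
                        and pooled[i] > pooled[j])
                us.append(u)
            us = np.array(us)
            cdf = np.mean(us <= obs_u)
            sf = np.mean(us >= obs_u)
            expected = min(1.0, 2 * min(cdf, sf))
            assert res["p"] == pytest.approx(expected, abs=1e-12)
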