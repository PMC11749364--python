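import numpy as np
import pandas as pd
import pytest

from conftest import column, make_obs_frame
from editome import discovery as disc
from editome.types import CallerParams, EditingSite, IntervalSet


def brute_force_candidates(frame, params):
    """Independent re-count over raw rows (per-position dict tally)."""
    q = frame[(frame["baq"] >= params.min_baq)
              & (frame["mapq"] >= params.min_mapq)
              & (frame["base"] != "N")
              & (frame["read_pos"] > params.hexamer_prefix_len)]
    out = {}
    for _, row in q.iterrows():
        key = (row["chrom"], row["pos0"])
        out.setdefault(key, {"ref": row["ref"], "counts": {}})
        out[key]["counts"][row["base"]] = \
            out[key]["counts"].get(row["base"], 0) + 1
    cands = {}
    for (chrom, pos0), col in sorted(out.items()):
        depth = sum(col["counts"].values())
        if depth < params.min_depth:
            continue
        nonref = {b: n for b, n in col["counts"].items() if b != col["ref"]}
        if not nonref:
            continue
        best = max(nonref.values())
        top = sorted(b for b, n in nonref.items() if n == best)
        if best < params.min_variant_reads:
            continue
        cands[(chrom, pos0)] = (col["ref"], top, best, depth)
    return cands


class TestCallCandidates:
    def test_all_reference_column_yields_no_candidate(self):
        frame = make_obs_frame(column(10, "A", "AAAAA"))
        assert disc.call_candidates(frame, CallerParams()) == []

    def test_five_reads_two_variant_is_a_candidate_at_level_04(self):
        frame = make_obs_frame(column(10, "A", "AAAGG"))
        (c,) = disc.call_candidates(frame, CallerParams())
        assert (c.var_base, c.edited_reads, c.total_reads) == ("G", 2, 5)
        assert c.level == pytest.approx(0.4)

    def test_depth_four_is_below_threshold(self):
        frame = make_obs_frame(column(10, "A", "AAGG"))
        assert disc.call_candidates(frame, CallerParams()) == []

    def test_matches_bruteforce_recount_on_random_columns(self, rng):
        rows = []
        for pos in range(200):
            depth = int(rng.integers(1, 15))
            for _ in range(depth):
                rows.append((pos, "A", str(rng.choice(list("AACGT"))),
                             int(rng.choice([30, 10])),
                             int(rng.choice([40, 5])),
                             int(rng.integers(1, 101))))
        frame = make_obs_frame(rows)
        params = CallerParams()
        got = {(c.chrom, c.pos0): c for c in disc.call_candidates(frame,
                                                                  params)}
        expected = brute_force_candidates(frame, params)
        # tie-dropped columns are the only allowed difference
        for key, (ref, top, best, depth) in expected.items():
            if key in got:
                c = got[key]
                assert c.var_base in top
                assert c.edited_reads == best and c.total_reads == depth
            else:
                assert len(top) > 1  # dropped only on an exact tie
        assert set(got) <= set(expected)


class TestHexamerFilter:
    def test_prefix_only_support_removes_candidate(self):
        frame = make_obs_frame(
            column(10, "A", "AAA", read_pos=50)
            + column(10, "A", "GG", read_pos=3)
            + column(10, "A", "AA", read_pos=50))
        assert disc.call_candidates(frame, CallerParams()) == []

    def test_read_pos_seven_is_retained(self):
        frame = make_obs_frame(column(10, "A", "AAA", read_pos=7)
                               + column(10, "A", "GG", read_pos=7))
        (c,) = disc.call_candidates(frame, CallerParams())
        assert c.edited_reads == 2

    def test_output_is_input_minus_prefix_rows(self, rng):
        rows = [(int(p), "A", "G", 30, 40, int(rp))
                for p, rp in zip(sorted(rng.integers(0, 100, 300)),
                                 rng.integers(1, 101, 300))]
        frame = make_obs_frame(rows)
        out = disc.filter_hexamer_prefix(frame, 6)
        assert set(out.index) == set(frame.index[frame["read_pos"] > 6])


class TestGenomicEvidence:
    def _cand(self):
        return disc.CandidateSite("chr1", 10, "A", "G", 3, 10)

    @pytest.mark.parametrize("dna_bases,expected_pass", [
        ("AAAAAGGGGG", False),   # clear genomic variant
        ("AAAAAAAAAA", True),    # homozygous reference
        ("AAAA", False),         # insufficient DNA depth
        ("AAAAAAAAG", False),    # one variant DNA read > max allowed
        ("AAAAAAAAT", True),     # non-variant alt base does not count
    ])
    def test_decision_table(self, dna_bases, expected_pass):
        cand = self._cand()
        dna = make_obs_frame(column(10, "A", dna_bases), sample_id="dna")
        disc.filter_genomic_evidence([cand], dna, CallerParams())
        assert cand.filters["genomic_evidence"] is expected_pass

    def test_exhaustive_small_grid_oracle(self):
        params = CallerParams()
        for depth in range(0, 12):
            for nvar in range(0, depth + 1):
                cand = self._cand()
                bases = "G" * nvar + "A" * (depth - nvar)
                dna = make_obs_frame(column(10, "A", bases) if depth else [],
                                     sample_id="dna")
                if dna.empty:
                    dna = make_obs_frame(column(99, "A", "A"),
                                         sample_id="dna")
                disc.filter_genomic_evidence([cand], dna, params)
                expected = (depth >= params.min_dna_depth
                            and nvar <= params.max_dna_variant_reads)
                assert cand.filters["genomic_evidence"] is expected


class TestKnownVariants:
    def test_candidate_at_catalogued_position_removed(self):
        cand = disc.CandidateSite("chr1", 99, "A", "G", 3, 10)
        disc.filter_known_variants([cand], [{("chr1", 99, "T")}])
        assert cand.filters["known_snp"] is False  # position-level exclusion

    def test_empty_variant_set_is_identity(self):
        cand = disc.CandidateSite("chr1", 99, "A", "G", 3, 10)
        disc.filter_known_variants([cand], [])
        assert cand.retained

    def test_survivors_equal_set_difference(self, rng):
        cands = [disc.CandidateSite("chr1", int(p), "A", "G", 3, 10)
                 for p in rng.choice(5000, 1000, replace=False)]
        snps = {("chr1", int(p), "G") for p in rng.integers(0, 5000, 300)}
        disc.filter_known_variants(cands, [snps])
        snp_pos = {(c, p) for c, p, _ in snps}
        for c in cands:
            assert c.filters["known_snp"] == (("chr1", c.pos0) not in snp_pos)


class TestNonAluFilters:
    REF = {"chr1": "ACGT" * 3000}

    def _apply(self, cand, alu=None, genes=(), ref=None, similarity=None):
        disc.apply_non_alu_filters(
            [cand], alu or IntervalSet({}, label="Alu"), list(genes),
            ref or self.REF, similarity, CallerParams())
        return cand

    def test_low_frequency_fails_outside_alu_only(self):
        low = disc.CandidateSite("chr1", 100, "A", "G", 1, 13)
        assert self._apply(low).filters["frequency"] is False
        in_alu = disc.CandidateSite("chr1", 100, "A", "G", 1, 13)
        alu = IntervalSet({"chr1": [(50, 150)]}, label="Alu")
        assert self._apply(in_alu, alu=alu).retained
        assert in_alu.in_alu

    def test_splice_distance_boundary(self, two_genes):
        # gplus introns: [300,500) and [700,900)
        for pos, expected in [(302, False), (304, True), (497, False),
                              (495, True)]:
            cand = disc.CandidateSite("chr1", pos, "A", "G", 5, 10)
            got = self._apply(cand, genes=two_genes).filters["splice"]
            assert got is expected, pos

    def test_homopolymer_run_boundary(self):
        ref = {"chr1": "CG" + "AAAAA" + "CG" + "AAAA" + "CGCGCGCG"}
        in_run = disc.CandidateSite("chr1", 4, "A", "G", 5, 10)
        assert self._apply(in_run, ref=ref).filters["homopolymer"] is False
        in_four = disc.CandidateSite("chr1", 10, "A", "G", 5, 10)
        assert self._apply(in_four, ref=ref).filters["homopolymer"] is True

    def test_similarity_mask_membership(self):
        sim = IntervalSet({"chr1": [(90, 110)]}, label="sim")
        cand = disc.CandidateSite("chr1", 100, "A", "G", 5, 10)
        assert self._apply(cand, similarity=sim).filters["similarity"] is False

    def test_missing_reference_chrom_raises(self):
        cand = disc.CandidateSite("chr9", 100, "A", "G", 5, 10)
        with pytest.raises(KeyError, match="chr9"):
            self._apply(cand)

    def test_random_candidates_match_per_rule_oracle(self, rng, two_genes):
        ref = {"chr1": "".join(rng.choice(list("ACGT"), 12_000))}
        alu = IntervalSet({"chr1": [(4000, 4800)]}, label="Alu")
        sim = IntervalSet({"chr1": [(6000, 6100)]}, label="sim")
        params = CallerParams()
        cands = []
        for _ in range(500):
            total = int(rng.integers(5, 40))
            edited = int(rng.integers(1, total + 1))
            pos = int(rng.integers(0, 12_000))
            cands.append(disc.CandidateSite("chr1", pos, ref["chr1"][pos]
                                            if ref["chr1"][pos] != "G" else "A",
                                            "G", edited, total))
        disc.apply_non_alu_filters(cands, alu, two_genes, ref, sim, params)
        for c in cands:
            if ("chr1", c.pos0) in alu:
                assert all(c.filters[f] for f in
                           ("frequency", "splice", "homopolymer",
                            "similarity"))
                continue
            assert c.filters["frequency"] == (c.level >= 0.1)
            d = disc.splice_junction_distance(c.pos0, two_genes)
            assert c.filters["splice"] == (d is None or d > 4)
            assert c.filters["homopolymer"] == \
                   (disc.homopolymer_run_length(ref["chr1"], c.pos0) < 5)
            assert c.filters["similarity"] == (("chr1", c.pos0) not in sim)


class TestStrandAssignment:
    def test_tc_in_minus_gene_reported_as_ag(self, two_genes):
        site = EditingSite("chr1", 2100, "T", "C", edited_reads=3,
                           total_reads=10)
        disc.assign_strand([site], two_genes)
        assert site.strand == "-"
        assert site.subst_type == "A>G"

    def test_conflicting_strands_stay_unknown(self, two_genes):
        from editome.types import GeneModel
        overlap = GeneModel("gx", "chr1", "+", exons=[(2000, 2800)],
                            biotype="ncRNA")
        site = EditingSite("chr1", 2100, "T", "C", edited_reads=3,
                           total_reads=10)
        disc.assign_strand([site], two_genes + [overlap])
        assert site.strand == "."
        assert site.subst_type == "T>C"

    def test_complementary_pair_totals_conserved(self, rng, two_genes):
        sites = []
        for _ in range(100):
            ref, var = rng.choice([("A", "G"), ("T", "C")])
            sites.append(EditingSite("chr1", int(rng.integers(0, 4000)),
                                     ref, var, edited_reads=2, total_reads=8))
        before = sum(1 for s in sites if s.subst_type in ("A>G", "T>C"))
        disc.assign_strand(sites, two_genes)
        after = sum(1 for s in sites if s.subst_type in ("A>G", "T>C"))
        assert before == after == 100


class TestReplicateIntersection:
    def _site(self, pos, var="G"):
        return EditingSite("chr1", pos, "A", var, edited_reads=2,
                           total_reads=10)

    def test_disjoint_inputs_share_nothing(self):
        out = disc.intersect_replicates([self._site(1)], [self._site(2)])
        assert out["shared"] == []
        assert len(out["specific_a"]) == len(out["specific_b"]) == 1

    def test_identical_inputs_all_shared(self):
        a = [self._site(p) for p in range(10)]
        b = [self._site(p) for p in range(10)]
        out = disc.intersect_replicates(a, b)
        assert len(out["shared"]) == 10
        assert out["specific_a"] == [] and out["specific_b"] == []

    def test_matches_hash_join_oracle(self, rng):
        pos_a = rng.choice(1000, 200, replace=False)
        pos_b = rng.choice(1000, 200, replace=False)
        a = [self._site(int(p)) for p in sorted(pos_a)]
        b = [self._site(int(p)) for p in sorted(pos_b)]
        out = disc.intersect_replicates(a, b)
        expected = set(pos_a) & set(pos_b)
        assert {s.pos0 for s, _ in out["shared"]} == expected


class TestCascade:
    def test_cascade_is_idempotent(self, small_dataset, resources):
        cands, _ = disc.run_sample_cascade(small_dataset["rna"]["rna_rep1"],
                                           resources)
        flags_once = [dict(c.filters) for c in cands]
        params = CallerParams()
        disc.filter_genomic_evidence(cands, resources["dna_obs"], params)
        disc.filter_known_variants(cands, resources["snp_sets"])
        disc.apply_non_alu_filters(cands, resources["alu"],
                                   resources["genes"], resources["ref"],
                                   resources["similarity"], params)
        assert [dict(c.filters) for c in cands] == flags_once

    def test_retained_sites_respect_frequency_or_alu_invariant(
            self, small_dataset, resources):
        cands, _ = disc.run_sample_cascade(small_dataset["rna"]["rna_rep1"],
                                           resources)
        for c in cands:
            if c.retained:
                assert c.in_alu or c.level >= 0.1

    def test_run_site_discovery_is_deterministic(self, small_dataset,
                                                 resources, tmp_path):
        from editome.simulate import write_dataset
        sheet = write_dataset(small_dataset, tmp_path,
                              small_dataset["config"])
        r1 = disc.run_site_discovery(sheet, resources,
                                     out_dir=tmp_path / "o1")
        r2 = disc.run_site_discovery(sheet, resources,
                                     out_dir=tmp_path / "o2")
        assert (tmp_path / "o1" / "sites_rna_rep1.tsv").read_bytes() == \
               (tmp_path / "o2" / "sites_rna_rep1.tsv").read_bytes()
        assert r1["attrition"] == r2["attrition"]
        shared = r1["shared"]["cellA"]
        per1 = {s.key for s in r1["per_sample"]["rna_rep1"]}
        per2 = {s.key for s in r1["per_sample"]["rna_rep2"]}
        assert {s.key for s in shared} == per1 & per2

    def test_removing_snp_resource_zeroes_snp_attrition(
            self, small_dataset, resources):
        res = dict(resources)
        res["snp_sets"] = []
        _, attr = disc.run_sample_cascade(small_dataset["rna"]["rna_rep1"],
                                          res)
        assert attr["failed_known_snp"] == 0
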