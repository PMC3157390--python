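"""Catalog curation: filters, deduplication, LD pruning, proxies, strand."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from replix.catalog import (
    LDTable,
    PlatformManifest,
    check_strand,
    curate,
    deduplicate,
    filter_entries,
    prune_ld,
    select_proxy,
)
from .conftest import make_entry


class TestFilterEntries:
    @pytest.mark.parametrize(
        "over, kept",
        [
            ({}, True),
            ({"p_value": 1e-6}, False),  # weaker than genome-wide significance
            ({"p_value": 1e-8}, True),
            ({"effect": None}, False),
            ({"ancestry": "East Asian"}, False),
            ({"single_snp": False}, False),  # haplotype association
            ({"includes_this_cohort": True}, False),
        ],
    )
    def test_stated_filters(self, over, kept):
        out = filter_entries([make_entry(**over)])
        assert bool(out) == kept

    def test_threshold_is_inclusive(self):
        assert filter_entries([make_entry(p_value=1e-7)])


class TestDeduplicate:
    def test_largest_case_count_survives(self):
        a = make_entry(study_id="PMID1", n_cases=500)
        b = make_entry(study_id="PMID2", n_cases=2000)
        assert deduplicate([a, b]) == [b]

    def test_no_duplicates_is_identity(self):
        a = make_entry(snp_id="rs1")
        b = make_entry(snp_id="rs2", phenotype="other")
        assert deduplicate([a, b]) == [a, b]

    def test_tie_breaks_to_smaller_p_then_study(self):
        a = make_entry(study_id="PMID9", n_cases=1000, p_value=1e-9)
        b = make_entry(study_id="PMID1", n_cases=1000, p_value=1e-12)
        assert deduplicate([a, b]) == [b]
        c = make_entry(study_id="PMID2", n_cases=1000, p_value=1e-12)
        assert deduplicate([b, c]) == [b]

    def test_same_snp_different_phenotypes_both_kept(self):
        a = make_entry(phenotype="p1")
        b = make_entry(phenotype="p2")
        assert len(deduplicate([a, b])) == 2


class TestPruneLD:
    def test_within_study_smallest_p_wins(self):
        a = make_entry(snp_id="rs1", p_value=1e-9)
        b = make_entry(snp_id="rs2", p_value=1e-8)
        ld = LDTable({("rs1", "rs2"): 0.2})
        assert prune_ld([a, b], ld) == [a]

    def test_below_threshold_both_kept(self):
        a = make_entry(snp_id="rs1")
        b = make_entry(snp_id="rs2")
        ld = LDTable({("rs1", "rs2"): 0.05})
        assert len(prune_ld([a, b], ld)) == 2

    def test_transitive_component_collapses_to_one(self):
        # chain rs1-rs2-rs3 where rs1/rs3 are themselves nearly independent
        entries = [make_entry(snp_id=f"rs{i}", p_value=10.0 ** -(8 + i)) for i in (1, 2, 3)]
        ld = LDTable({("rs1", "rs2"): 0.15, ("rs2", "rs3"): 0.15, ("rs1", "rs3"): 0.02})
        out = prune_ld(entries, ld)
        assert [e.snp_id for e in out] == ["rs3"]

    def test_across_studies_largest_case_count_wins(self):
        a = make_entry(snp_id="rs1", study_id="PMID1", n_cases=500, p_value=1e-20)
        b = make_entry(snp_id="rs2", study_id="PMID2", n_cases=5000, p_value=1e-8)
        ld = LDTable({("rs1", "rs2"): 0.5})
        assert prune_ld([a, b], ld) == [b]

    def test_pruning_is_per_phenotype(self):
        a = make_entry(snp_id="rs1", phenotype="p1")
        b = make_entry(snp_id="rs2", phenotype="p2")
        ld = LDTable({("rs1", "rs2"): 0.9})
        assert len(prune_ld([a, b], ld)) == 2

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 2**24 - 1))
    def test_one_survivor_per_component_against_graph_oracle(self, edge_bits):
        """Brute-force oracle: survivors are exactly one per connected
        component of the r2>=0.1 graph on up to 8 SNPs."""
        n = 8
        snps = [f"rs{i}" for i in range(n)]
        entries = [make_entry(snp_id=s, p_value=10.0 ** -(9 + i)) for i, s in enumerate(snps)]
        pairs = list(itertools.combinations(range(n), 2))
        ld = LDTable()
        adj = {i: {i} for i in range(n)}
        for bit, (i, j) in enumerate(pairs):
            if (edge_bits >> bit) & 1:
                ld.set(snps[i], snps[j], 0.2)
                adj[i].add(j)
                adj[j].add(i)
        # oracle components by BFS
        seen, comps = set(), []
        for i in range(n):
            if i in seen:
                continue
            comp, frontier = set(), {i}
            while frontier:
                k = frontier.pop()
                if k in comp:
                    continue
                comp.add(k)
                frontier |= adj[k] - comp
            seen |= comp
            comps.append(comp)
        out = {e.snp_id for e in prune_ld(entries, ld)}
        assert len(out) == len(comps)
        for comp in comps:
            assert len(out & {snps[i] for i in comp}) == 1


class TestSelectProxy:
    platform = PlatformManifest({"rs1": 0.995, "rsP": 0.999, "rsQ": 0.999, "rsLow": 0.95})

    def test_on_platform_snp_is_its_own_test_snp(self):
        cur = select_proxy(make_entry(snp_id="rs1"), self.platform, LDTable())
        assert cur.test_snp == "rs1" and cur.proxy_r2 == 1.0

    def test_off_platform_uses_best_proxy(self):
        ld = LDTable({("rsX", "rsP"): 0.6, ("rsX", "rsQ"): 0.55})
        cur = select_proxy(make_entry(snp_id="rsX"), self.platform, ld)
        assert cur.test_snp == "rsP" and cur.proxy_r2 == 0.6

    def test_weak_proxy_drops_association(self):
        ld = LDTable({("rsX", "rsP"): 0.4})
        assert select_proxy(make_entry(snp_id="rsX"), self.platform, ld) is None

    def test_poor_call_rate_triggers_proxy(self):
        ld = LDTable({("rsLow", "rsP"): 0.8})
        cur = select_proxy(make_entry(snp_id="rsLow"), self.platform, ld)
        assert cur.test_snp == "rsP" and cur.proxy_r2 == 0.8

    def test_proxy_must_itself_be_callable(self):
        ld = LDTable({("rsX", "rsLow"): 0.9})
        assert select_proxy(make_entry(snp_id="rsX"), self.platform, ld) is None


class TestCheckStrand:
    @pytest.mark.parametrize(
        "raf, ref, alleles, expected",
        [
            (0.2, 0.3, ("A", "G"), "confirmed"),
            (0.2, 0.3, ("A", "T"), "manual_review"),  # ambiguous pair
            (0.8, 0.9, ("C", "G"), "manual_review"),
            (0.5, 0.5, ("A", "G"), "manual_review"),  # neither side of band
            (0.7, 0.7, ("A", "G"), "confirmed"),
            (0.2, 0.7, ("A", "G"), "manual_review"),  # frequency mismatch
            (0.35, 0.2, ("A", "G"), "manual_review"),  # band is strict
            (0.2, None, ("A", "G"), "manual_review"),  # no reference data
        ],
    )
    def test_band_and_ambiguity(self, raf, ref, alleles, expected):
        e = make_entry(raf_controls=raf, risk_allele=alleles[0], other_allele=alleles[1])
        assert check_strand(e, ref) == expected

    def test_unresolvable_is_undetermined(self):
        assert check_strand(make_entry(), 0.3, unresolvable=True) == "undetermined"

    def test_invalid_allele_rejected(self):
        with pytest.raises(ValueError, match="invalid allele"):
            check_strand(make_entry(risk_allele="N"), 0.3)


class TestCuratePipeline:
    def _inputs(self):
        entries = [
            make_entry(snp_id="rs1", phenotype="p1"),
            make_entry(snp_id="rs1", phenotype="p1", study_id="PMID2", n_cases=100),
            make_entry(snp_id="rs2", phenotype="p1", p_value=1e-8),
            make_entry(snp_id="rs3", phenotype="p1", p_value=1e-5),
        ]
        ld = LDTable({("rs1", "rs2"): 0.4})
        platform = PlatformManifest({"rs1": 0.999, "rs2": 0.999, "rs3": 0.999})
        refs = {"rs1": 0.25, "rs2": 0.25, "rs3": 0.25}
        return entries, ld, platform, refs

    def test_reasons_recorded_per_stage(self):
        entries, ld, platform, refs = self._inputs()
        report = curate(entries, ld, platform, refs)
        assert [c.source.snp_id for c in report.curated] == ["rs1"]
        reasons = {(e.snp_id, e.study_id): r for e, r in report.dropped}
        assert reasons[("rs3", "PMID1")] == "filtered"
        assert reasons[("rs1", "PMID2")] == "duplicate"
        assert reasons[("rs2", "PMID1")] == "ld_pruned"

    def test_curation_is_idempotent(self):
        entries, ld, platform, refs = self._inputs()
        first = curate(entries, ld, platform, refs)
        again = curate([c.source for c in first.curated], ld, platform, refs)
        assert [c.source.snp_id for c in again.curated] == [c.source.snp_id for c in first.curated]
        assert not again.dropped

    def test_filter_dedup_order_insensitive(self):
        entries, *_ = self._inputs()
        a = deduplicate(filter_entries(entries))
        b = filter_entries(deduplicate(entries))
        assert {(e.snp_id, e.study_id) for e in a} == {(e.snp_id, e.study_id) for e in b}

    def test_every_curated_association_is_traceable_and_proxied(self):
        entries, ld, platform, refs = self._inputs()
        report = curate(entries, ld, platform, refs)
        for c in report.curated:
            assert c.proxy_r2 >= 0.5
            assert c.source in entries
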