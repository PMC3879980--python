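"""Informative patterns, tabulation, flow signatures, ranking concordance."""

import itertools
from fractions import Fraction
from math import comb

import pytest
from hypothesis import given, settings, strategies as st

from ringroot import datasets
from ringroot.pattern_flows import (
    flow_signatures,
    informative_patterns,
    pattern_string,
    rank_concordance_p,
    tabulate_patterns,
    top_k_concordance,
)


class TestInformativePatterns:
    @pytest.mark.parametrize("n,expected", [(3, 3), (4, 10), (5, 25)])
    def test_counts(self, n, expected):
        pats = informative_patterns(n)
        assert len(pats) == expected == 2**n - n - 2

    def test_two_taxa_yield_nothing(self):
        assert informative_patterns(2) == []

    def test_below_two_rejected(self):
        with pytest.raises(ValueError):
            informative_patterns(1)

    @given(st.integers(2, 10))
    @settings(derandomize=True, deadline=None)
    def test_closed_form_matches_enumeration(self, n):
        brute = [
            p
            for p in itertools.product([0, 1], repeat=n)
            if sum(p) >= 2 and sum(p) < n
        ]
        assert len(informative_patterns(n)) == len(brute)
        assert set(informative_patterns(n)) == set(brute)

    def test_pattern_string(self):
        assert pattern_string((1, 1, 0, 0, 1), "ADFHE") == "AD--E"


class TestTabulatePatterns:
    def test_single_pattern_table(self):
        table = tabulate_patterns({f"fam{i}": {"A", "D"} for i in range(10)}, "ADFHE")
        assert table.counts[(1, 1, 0, 0, 0)] == 10
        assert sum(table.counts.values()) == 10
        assert table.ranked()[0] == ((1, 1, 0, 0, 0), 10)

    def test_noninformative_families_counted_separately(self):
        table = tabulate_patterns(
            {"ubiq": set("ADFHE"), "single": {"A"}, "none": set(), "inf": {"A", "D"}},
            "ADFHE",
        )
        assert table.noninformative == {"singleton": 1, "ubiquitous": 1, "absent": 1}
        assert table.n_families == 4

    def test_unknown_taxon_rejected(self):
        with pytest.raises(KeyError, match="unknown"):
            tabulate_patterns({"f": {"Z"}}, "ADFHE")

    def test_member_taxa_collapse_to_supergroups(self):
        sg = {"Bacilli": "F", "Clostridia": "F", "Actino": "A", "Cyano": "D"}
        table = tabulate_patterns(
            {"f1": {"Bacilli", "Clostridia"}, "f2": {"Actino", "Cyano"}},
            "ADFHE",
            supergroup_of=sg,
        )
        # f1 collapses to the singleton F — non-informative
        assert table.noninformative["singleton"] == 1
        assert table.counts[(1, 1, 0, 0, 0)] == 1

    def test_generator_tally_oracle(self):
        """Tabulation matches the simulator's own bookkeeping exactly."""
        from ringroot.synthetic_data import default_config, simulate_flows

        cfg = default_config(seed=11, loss_prob=0.05)
        table, truth = simulate_flows(cfg)
        pt = tabulate_patterns(table, datasets.FIVE_TAXA)
        # every informative tally in truth appears with the same count
        for pattern, count in truth.tallies.items():
            bits = tuple(int(t in pattern) for t in datasets.FIVE_TAXA)
            if sum(bits) >= 2 and sum(bits) < 5:
                assert pt.counts[bits] == count
        assert pt.n_families == cfg.n_families


class TestFlowSignatures:
    def test_six_distinct_signatures_on_five_taxon_ring(self, ring_five):
        sites = datasets.inner_ring_five_gain_sites()
        sigs = flow_signatures(ring_five, sites, datasets.FIVE_TAXA)
        assert len(sigs.signatures) == 6
        assert not sigs.duplicates
        rendered = {
            pattern_string(p, datasets.FIVE_TAXA) for p in sigs.signatures.values()
        }
        assert rendered == {"AD---", "---HE", "-DFH-", "-DF--", "ADF--", "-DFHE"}

    def test_six_taxon_ring_root_sites_flagged_noninformative(self, ring_six):
        sites = list(datasets.inner_ring_six_gain_sites().values())
        sigs = flow_signatures(ring_six, sites, datasets.SIX_TAXA)
        # HisF and GyrA both flood everything from the root: flagged twice
        assert sigs.noninformative == ["ROOT", "ROOT"]
        assert set(sigs.signatures) == {"root->L", "root->R"}

    def test_single_edge_graph_signature_flagged(self):
        from ringroot.ring_model import build_flow_graph

        g = build_flow_graph([("root", "leafA")], {"leafA": "A"})
        sigs = flow_signatures(g, [("root", "leafA")], ("A", "B", "C"))
        assert sigs.signatures == {}
        assert sigs.noninformative == ["root->leafA"]


class TestRankConcordance:
    def test_headline_exact_value(self):
        p = rank_concordance_p(25, 6, exact=True)
        assert p == Fraction(1, 177100)
        assert float(p) <= 5.7e-6

    @pytest.mark.parametrize("n,k,expected", [(4, 2, Fraction(1, 6)), (5, 0, 1), (5, 5, 1)])
    def test_small_cases(self, n, k, expected):
        assert rank_concordance_p(n, k, exact=True) == expected

    def test_symmetry_in_k(self):
        for n in range(2, 10):
            for k in range(n + 1):
                assert rank_concordance_p(n, k) == rank_concordance_p(n, n - k)

    def test_k_exceeding_n_rejected(self):
        with pytest.raises(ValueError):
            rank_concordance_p(5, 6)

    @pytest.mark.parametrize("n,k", [(4, 2), (5, 2), (6, 3), (7, 3)])
    def test_permutation_oracle_full_enumeration(self, n, k):
        """Fraction of orderings whose top-k equals a fixed set is 1/C(n,k)."""
        target = frozenset(range(k))
        favorable = sum(
            1
            for perm in itertools.permutations(range(n))
            if frozenset(perm[:k]) == target
        )
        import math

        assert Fraction(favorable, math.factorial(n)) == rank_concordance_p(
            n, k, exact=True
        )


class TestTopKConcordance:
    def _table_and_sigs(self, counts_by_pattern):
        sites = datasets.inner_ring_five_gain_sites()
        ring = datasets.inner_ring_five()
        sigs = flow_signatures(ring, sites, datasets.FIVE_TAXA)
        pats = informative_patterns(5)
        counts = {p: counts_by_pattern.get(p, 0) for p in pats}
        from ringroot.pattern_flows import PatternTable

        return PatternTable(taxa=datasets.FIVE_TAXA, counts=counts), sigs

    def test_exact_match(self):
        sigs_patterns = list(
            flow_signatures(
                datasets.inner_ring_five(),
                datasets.inner_ring_five_gain_sites(),
                datasets.FIVE_TAXA,
            ).signatures.values()
        )
        counts = {p: 100 - 10 * i for i, p in enumerate(sigs_patterns)}
        table, sigs = self._table_and_sigs(counts)
        report = top_k_concordance(table, sigs)
        assert report["match"] is True
        assert report["overlap"] == 6
        assert report["p"] == pytest.approx(1 / comb(25, 6))

    def test_one_signature_ranked_seventh(self):
        sigs_patterns = list(
            flow_signatures(
                datasets.inner_ring_five(),
                datasets.inner_ring_five_gain_sites(),
                datasets.FIVE_TAXA,
            ).signatures.values()
        )
        counts = {p: 100 - 10 * i for i, p in enumerate(sigs_patterns[:5])}
        counts[sigs_patterns[5]] = 1  # will fall below an interloper
        interloper = (1, 0, 1, 1, 0)
        assert interloper not in sigs_patterns
        counts[interloper] = 40
        table, sigs = self._table_and_sigs(counts)
        report = top_k_concordance(table, sigs)
        assert report["match"] is False
        assert report["overlap"] == 5
        assert report["p"] is None

    def test_tie_across_boundary_is_indeterminate(self):
        sigs_patterns = list(
            flow_signatures(
                datasets.inner_ring_five(),
                datasets.inner_ring_five_gain_sites(),
                datasets.FIVE_TAXA,
            ).signatures.values()
        )
        counts = {p: 100 for p in sigs_patterns[:5]}
        counts[sigs_patterns[5]] = 7
        other = (1, 0, 1, 1, 0)
        counts[other] = 7  # exact tie at the 6th place
        table, sigs = self._table_and_sigs(counts)
        report = top_k_concordance(table, sigs)
        assert report["match"] is None

    def test_k_exceeding_nonzero_patterns_rejected(self):
        table, sigs = self._table_and_sigs({(1, 1, 0, 0, 0): 5})
        with pytest.raises(ValueError, match="nonzero"):
            top_k_concordance(table, sigs)
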