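"""Phyletic presence/absence patterns and ranking concordance.

A *pattern* is a bit vector over an ordered set of super-taxa saying which
of them carry a gene family.  A pattern is *phylogenetically informative*
when at least two taxa share the gene and at least one lacks it —
singletons carry no grouping signal and ubiquitous or absent families
carry none either.  For n taxa there are 2**n - n - 2 informative
patterns (25 for the five prokaryotic super-taxa).

A ring topology predicts which patterns should dominate: each gain site
floods exactly the leaves reachable from it, so the ring's *flow
signatures* are a small set of patterns.  If the k signatures predicted by
one line of evidence (indels) are exactly the k most gene-rich patterns in
an independent whole-genome ortholog tabulation, the probability of that
agreement under a uniformly random ordering of the n patterns is
k!(n-k)!/n! = 1/C(n,k).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from math import comb
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .ring_model import FlowGraph, reachable_leaves

__all__ = [
    "Pattern",
    "PatternTable",
    "FlowSignatureSet",
    "MIN_PRESENT",
    "MIN_ABSENT",
    "informative_patterns",
    "pattern_string",
    "tabulate_patterns",
    "flow_signatures",
    "rank_concordance_p",
    "top_k_concordance",
]

Pattern = tuple[int, ...]

#: Informative-pattern definition: at least MIN_PRESENT taxa carry the gene
#: and at least MIN_ABSENT lack it.  With 5 taxa this gives
#: C(5,2)+C(5,3)+C(5,4) = 25 patterns — the denominator behind the exact
#: 1/C(25,6) concordance probability.
MIN_PRESENT = 2
MIN_ABSENT = 1


def informative_patterns(n_taxa: int) -> list[Pattern]:
    """All informative patterns over ``n_taxa``, in canonical order.

    Canonical order: by decreasing number of present taxa, then
    lexicographically by the bit vector (1 before 0).  There are
    2**n - n - 2 such patterns; for n = 2 the list is empty, and n < 2 is
    an error (the definition needs at least MIN_PRESENT + MIN_ABSENT taxa
    to ever be satisfiable... n=2 yields the empty list by convention).
    """
    if n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    pats = []
    for bits in range(2**n_taxa):
        pat = tuple((bits >> (n_taxa - 1 - i)) & 1 for i in range(n_taxa))
        ones = sum(pat)
        if ones >= MIN_PRESENT and n_taxa - ones >= MIN_ABSENT:
            pats.append(pat)
    pats.sort(key=lambda p: (-sum(p), tuple(-b for b in p)))
    return pats


def pattern_string(pattern: Pattern, taxa: Sequence[str]) -> str:
    """Render a pattern like ``AD--E``: taxon letter if present, ``-`` if not."""
    return "".join(t if b else "-" for t, b in zip(taxa, pattern))


@dataclass
class PatternTable:
    """Gene-family counts per informative pattern, with ranking.

    ``counts`` maps every informative pattern over ``taxa`` to a count
    (zero included); non-informative families are tallied separately in
    ``noninformative`` under the keys ``singleton``, ``ubiquitous`` and
    ``absent``.
    """

    taxa: tuple[str, ...]
    counts: dict[Pattern, int]
    noninformative: dict[str, int] = field(
        default_factory=lambda: {"singleton": 0, "ubiquitous": 0, "absent": 0}
    )

    @property
    def n_families(self) -> int:
        return sum(self.counts.values()) + sum(self.noninformative.values())

    def ranked(self) -> list[tuple[Pattern, int]]:
        """Patterns by descending count; ties broken by canonical order."""
        order = {p: i for i, p in enumerate(informative_patterns(len(self.taxa)))}
        return sorted(self.counts.items(), key=lambda kv: (-kv[1], order[kv[0]]))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "pattern": pattern_string(p, self.taxa),
                "count": c,
                "rank": i + 1,
            }
            for i, (p, c) in enumerate(self.ranked())
        ]
        return pd.DataFrame(rows).set_index("pattern")

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")


@dataclass
class FlowSignatureSet:
    """The supergroup patterns flooded by each gain site of a flow graph.

    ``signatures`` maps a printable site id to its pattern;
    ``noninformative`` lists site ids whose pattern fails the informative
    definition (e.g. the root, which floods everything); ``duplicates``
    groups sites sharing one pattern.
    """

    taxa: tuple[str, ...]
    signatures: dict[str, Pattern]
    noninformative: list[str] = field(default_factory=list)
    duplicates: dict[Pattern, list[str]] = field(default_factory=dict)

    def informative_pattern_set(self) -> set[Pattern]:
        return set(self.signatures.values())


# ---------------------------------------------------------------------------

def _classify(pattern: Pattern) -> str:
    ones = sum(pattern)
    if ones == 0:
        return "absent"
    if ones == 1:
        return "singleton"
    if ones == len(pattern):
        return "ubiquitous"
    return "informative"


def tabulate_patterns(
    ortholog_table: Mapping[str, Iterable[str]],
    taxa: Sequence[str],
    supergroup_of: Mapping[str, str] | None = None,
) -> PatternTable:
    """Tally informative presence/absence patterns from an ortholog table.

    Parameters
    ----------
    ortholog_table:
        family id -> iterable of taxon (or member-taxon) ids where the
        family is present.
    taxa:
        Ordered super-taxon labels defining the pattern space.
    supergroup_of:
        Optional map from member taxon id to super-taxon label; a family
        counts as present in a super-taxon if present in at least one
        member.  Without it, the table's ids must already be super-taxon
        labels.

    Raises
    ------
    KeyError
        If a family names a taxon outside the declared set.
    """
    taxa = tuple(taxa)
    index = {t: i for i, t in enumerate(taxa)}
    counts = {p: 0 for p in informative_patterns(len(taxa))}
    noninf = {"singleton": 0, "ubiquitous": 0, "absent": 0}
    for family, members in ortholog_table.items():
        bits = [0] * len(taxa)
        for m in members:
            group = supergroup_of[m] if supergroup_of is not None else m
            if group not in index:
                raise KeyError(f"family {family!r} maps to unknown taxon {group!r}")
            bits[index[group]] = 1
        pattern = tuple(bits)
        kind = _classify(pattern)
        if kind == "informative":
            counts[pattern] += 1
        else:
            noninf[kind] += 1
    return PatternTable(taxa=taxa, counts=counts, noninformative=noninf)


def flow_signatures(
    ring: FlowGraph,
    gain_sites: Sequence[object],
    taxa: Sequence[str],
    supergroup_of: Mapping[str, str] | None = None,
) -> FlowSignatureSet:
    """Pattern flooded by each gain site, collapsed to super-taxa.

    A leaf taxon contributes presence to its super-group (any member
    suffices).  Sites whose pattern is non-informative are flagged and
    excluded from ``signatures``; sites sharing a pattern are reported in
    ``duplicates``.
    """
    taxa = tuple(taxa)
    index = {t: i for i, t in enumerate(taxa)}
    signatures: dict[str, Pattern] = {}
    noninformative: list[str] = []
    by_pattern: dict[Pattern, list[str]] = {}
    for site in gain_sites:
        leaves = reachable_leaves(ring, site)
        bits = [0] * len(taxa)
        for leaf in leaves:
            group = supergroup_of[leaf] if supergroup_of is not None else leaf
            if group not in index:
                raise KeyError(f"leaf {leaf!r} maps to unknown super-taxon {group!r}")
            bits[index[group]] = 1
        pattern = tuple(bits)
        sid = FlowGraph.site_id(site)
        if _classify(pattern) == "informative":
            signatures[sid] = pattern
            by_pattern.setdefault(pattern, []).append(sid)
        else:
            noninformative.append(sid)
    duplicates = {p: sids for p, sids in by_pattern.items() if len(sids) > 1}
    return FlowSignatureSet(
        taxa=taxa,
        signatures=signatures,
        noninformative=noninformative,
        duplicates=duplicates,
    )


def rank_concordance_p(n_patterns: int, k_predicted: int, *, exact: bool = False):
    """P that a fixed k-set tops a uniformly random ordering of n items.

    p = k!(n-k)!/n! = 1/C(n,k): of the n! equally likely orderings, the
    favorable ones are those whose first k places are the predicted set in
    any order.  Returns a float by default, an exact
    :class:`fractions.Fraction` with ``exact=True``.
    """
    if k_predicted < 0 or n_patterns < 0:
        raise ValueError("counts must be non-negative")
    if k_predicted > n_patterns:
        raise ValueError(f"k={k_predicted} exceeds n={n_patterns}")
    frac = Fraction(1, comb(n_patterns, k_predicted))
    return frac if exact else float(frac)


def top_k_concordance(table: PatternTable, signatures: FlowSignatureSet) -> dict:
    """Do the flow signatures occupy the top-k counts of the table?

    Returns a report dict with keys ``match`` (True/False/None — None when
    a tie spans the k-th boundary and the ranking is indeterminate),
    ``overlap`` (|signatures ∩ observed top-k| / k), ``k``, ``n_patterns``
    and ``p`` (1/C(n,k) if the match is exact, else None).
    """
    sig_set = signatures.informative_pattern_set()
    k = len(sig_set)
    space = set(informative_patterns(len(table.taxa)))
    if not sig_set <= space:
        raise ValueError("signatures outside the table's informative pattern space")
    if k == 0:
        # an empty prediction trivially tops any ordering
        return {"match": True, "overlap": 0, "k": 0, "n_patterns": len(space), "p": 1.0}
    ranked = table.ranked()
    nonzero = sum(1 for _, c in ranked if c > 0)
    if k > nonzero:
        raise ValueError(f"k={k} exceeds the {nonzero} patterns with nonzero counts")
    top = ranked[:k]
    top_set = {p for p, _ in top}
    kth = top[-1][1]
    boundary_tied = k < len(ranked) and ranked[k][1] == kth
    overlap = len(sig_set & top_set)
    n = len(space)
    if boundary_tied:
        # the k-th place is shared; whether the signatures occupy it is not
        # decidable from counts alone
        tied = {p for p, c in ranked if c == kth}
        definite = {p for p, c in ranked if c > kth}
        match = None if sig_set >= definite and sig_set - definite <= tied else False
    else:
        match = top_set == sig_set
    return {
        "match": match,
        "overlap": overlap,
        "k": k,
        "n_patterns": n,
        "p": rank_concordance_p(n, k) if match else None,
    }
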