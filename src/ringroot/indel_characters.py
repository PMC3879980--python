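"""Indel characters and paralog presence/absence from aligned blocks.

Indels — shared insertion/deletion blocks at fixed alignment columns — are
rare genomic changes: a multi-residue block is unlikely to be gained or
lost twice independently, so the split of taxa into a gap-bearing side and
a residue-bearing side is a strong binary character.  This module reads
aligned paralog-pair blocks (aligned FASTA plus a sidecar label table),
calls maximal uniform gap blocks, and assembles the binary character
matrix (paralog presence rows + indel rows) that feeds the parsimony
stage.

Gene absence is metadata: a taxon marked "gene absent" in the label table
simply has no sequence row.  An all-gap row is never interpreted as
absence.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd
from Bio import SeqIO

from .flow_parsimony import CharacterMatrix

__all__ = [
    "SeqLabel",
    "AlignmentBlock",
    "IndelCharacter",
    "read_alignment",
    "read_label_table",
    "call_indels",
    "build_character_matrix",
    "indel_calls_to_tsv",
]

GAP = "-"
# standard amino acids + X (unknown) + gap
_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX" + GAP)


@dataclass(frozen=True)
class SeqLabel:
    """Label for one alignment row (or one recorded absence).

    ``present`` is False for "gene absent" annotations, which carry no
    sequence; ``supergroup`` places the taxon in the study's label set.
    """

    seq_id: str
    taxon: str
    supergroup: str
    gene: str
    present: bool = True


@dataclass
class AlignmentBlock:
    """Equal-length aligned rows plus their labels and recorded absences."""

    sequences: dict[str, str]
    labels: dict[str, SeqLabel]
    absences: list[SeqLabel] = field(default_factory=list)

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) > 1:
            raise ValueError(f"ragged alignment: row lengths {sorted(lengths)}")
        for sid, seq in self.sequences.items():
            bad = set(seq.upper()) - _ALPHABET
            if bad:
                raise ValueError(f"unknown symbols {sorted(bad)} in {sid!r}")
            if sid not in self.labels:
                raise ValueError(f"sequence {sid!r} has no label")

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.sequences.values()))) if self.sequences else 0

    @property
    def row_ids(self) -> list[str]:
        return sorted(self.sequences)

    def genes(self) -> list[str]:
        names = {l.gene for l in self.labels.values()}
        names |= {l.gene for l in self.absences}
        return sorted(names)


@dataclass(frozen=True)
class IndelCharacter:
    """A maximal shared gap block.

    Coordinates are 0-based, half-open, in alignment-column space.  The
    rows split into a gap-bearing and a residue-bearing side; sides are
    reported as sequence-id sets and as supergroup sets.
    """

    start: int
    end: int
    gap_rows: frozenset[str]
    residue_rows: frozenset[str]
    gap_groups: frozenset[str]
    residue_groups: frozenset[str]

    @property
    def width(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def read_label_table(path) -> list[SeqLabel]:
    """Read a label TSV: seq_id, taxon, supergroup, gene, present(0/1).

    Rows with ``present = 0`` are gene-absence annotations and need no
    matching sequence.
    """
    labels: list[SeqLabel] = []
    seen = set()
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            sid = row["seq_id"]
            if sid in seen:
                raise ValueError(f"duplicate label for {sid!r}")
            seen.add(sid)
            labels.append(
                SeqLabel(
                    seq_id=sid,
                    taxon=row["taxon"],
                    supergroup=row["supergroup"],
                    gene=row["gene"],
                    present=row.get("present", "1").strip() not in ("0", "false", "no"),
                )
            )
    return labels


def read_alignment(path, labels: Sequence[SeqLabel]) -> AlignmentBlock:
    """Read an aligned FASTA and attach labels.

    Every FASTA record must have a label with ``present = True``; labels
    with ``present = False`` are recorded as absences.  Raises on an empty
    file, ragged rows, unknown residue symbols or duplicate ids.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no sequences in {path}")
    sequences: dict[str, str] = {}
    for rec in records:
        if rec.id in sequences:
            raise ValueError(f"duplicate sequence id {rec.id!r}")
        sequences[rec.id] = str(rec.seq).upper()
    by_id = {l.seq_id: l for l in labels}
    label_map: dict[str, SeqLabel] = {}
    for sid in sequences:
        if sid not in by_id:
            raise ValueError(f"sequence {sid!r} missing from the label table")
        if not by_id[sid].present:
            raise ValueError(f"sequence {sid!r} is labelled absent but has a row")
        label_map[sid] = by_id[sid]
    absences = [l for l in labels if not l.present]
    return AlignmentBlock(sequences=sequences, labels=label_map, absences=absences)


def indel_calls_to_tsv(calls: Sequence[IndelCharacter], path) -> None:
    """Write calls as BED-like TSV (alignment-space, 0-based half-open)."""
    with open(path, "w") as fh:
        fh.write("start\tend\twidth\tgap_groups\tresidue_groups\tresidue_rows\n")
        for c in calls:
            fh.write(
                f"{c.start}\t{c.end}\t{c.width}\t"
                f"{','.join(sorted(c.gap_groups))}\t"
                f"{','.join(sorted(c.residue_groups))}\t"
                f"{','.join(sorted(c.residue_rows))}\n"
            )


# ---------------------------------------------------------------------------
# calling
# ---------------------------------------------------------------------------

def call_indels(
    block: AlignmentBlock,
    min_width: int = 2,
    purity: float = 1.0,
) -> list[IndelCharacter]:
    """Call maximal shared gap blocks.

    A column is *mixed* when some rows carry a gap and some a residue.  At
    ``purity = 1.0`` a call is a maximal run of mixed columns with an
    identical gap-row set throughout — every row is uniformly gap or
    uniformly residue across the range, and extending the range by one
    column in either direction breaks that uniformity.  With
    ``purity < 1`` a run of mixed columns is accepted if every row is
    gap (or residue) in at least ``purity`` of the run's columns; rows are
    assigned to the majority side.  Calls never overlap.  Default
    ``min_width = 2`` suppresses single-column alignment noise.
    """
    if min_width < 1:
        raise ValueError("min_width must be >= 1")
    if not 0.5 < purity <= 1.0:
        raise ValueError("purity must be in (0.5, 1]")
    rows = block.row_ids
    if not rows:
        return []
    ncol = block.n_columns
    gap_sets = []
    for col in range(ncol):
        gaps = frozenset(r for r in rows if block.sequences[r][col] == GAP)
        gap_sets.append(gaps)

    def mixed(col: int) -> bool:
        return 0 < len(gap_sets[col]) < len(rows)

    calls: list[IndelCharacter] = []
    col = 0
    while col < ncol:
        if not mixed(col):
            col += 1
            continue
        # maximal run of mixed columns
        run_start = col
        while col < ncol and mixed(col):
            col += 1
        run_end = col
        calls.extend(
            _calls_in_run(block, rows, gap_sets, run_start, run_end, min_width, purity)
        )
    return calls


def _calls_in_run(block, rows, gap_sets, start, end, min_width, purity):
    """Split a run of mixed columns into calls."""
    if purity >= 1.0:
        # sub-runs of identical gap sets
        out = []
        i = start
        while i < end:
            j = i
            while j < end and gap_sets[j] == gap_sets[i]:
                j += 1
            if j - i >= min_width:
                out.append(_make_call(block, rows, gap_sets[i], i, j))
            i = j
        return out
    # purity < 1: classify each row over the whole run by majority,
    # accept if every row meets the purity threshold on its side
    width = end - start
    if width < min_width:
        return []
    gap_frac = {
        r: sum(1 for c in range(start, end) if r in gap_sets[c]) / width for r in rows
    }
    gap_rows = frozenset(r for r, f in gap_frac.items() if f >= purity)
    res_rows = frozenset(r for r, f in gap_frac.items() if 1 - f >= purity)
    if gap_rows and res_rows and len(gap_rows) + len(res_rows) == len(rows):
        return [_make_call(block, rows, gap_rows, start, end)]
    return []


def _make_call(block, rows, gap_rows, start, end) -> IndelCharacter:
    residue_rows = frozenset(rows) - gap_rows
    return IndelCharacter(
        start=start,
        end=end,
        gap_rows=frozenset(gap_rows),
        residue_rows=residue_rows,
        gap_groups=frozenset(block.labels[r].supergroup for r in gap_rows),
        residue_groups=frozenset(block.labels[r].supergroup for r in residue_rows),
    )


# ---------------------------------------------------------------------------
# matrix assembly
# ---------------------------------------------------------------------------

def build_character_matrix(
    blocks: Sequence[AlignmentBlock],
    indel_calls: Mapping[str, Sequence[IndelCharacter]] | None,
    taxa: Sequence[str],
    expand: Mapping[str, Sequence[str]] | None = None,
    include_indels: bool = True,
) -> CharacterMatrix:
    """Assemble the binary matrix feeding the parsimony stage.

    One row per paralog family (presence from the label tables: a taxon
    column is 1 if any member sequence is present, 0 if the gene is
    recorded absent) plus, optionally, one row per indel call (state 1 =
    residue-bearing, 0 = gap-bearing; taxa with no evidence in the block
    stay 0).  Characters are stored unpolarized — deciding whether the
    residue state is the insertion or the gap state the deletion needs the
    rooted graph and is out of scope here.

    Parameters
    ----------
    expand:
        Optional map from a composite supergroup label to the matrix
        columns it stands for (e.g. a single "Firmicutes" row standing for
        both the Bacilli and the Clostridia).  Labels absent from the map
        pass through unchanged.
    indel_calls:
        Map from a block name to that block's calls; keys also prefix the
        indel row ids.  Pass None to skip indel rows.

    Raises
    ------
    ValueError
        When a supergroup (after expansion) is not a declared taxon, or a
        gene has conflicting evidence leaving no presence at all.
    """
    taxa = list(taxa)

    def columns(group: str) -> list[str]:
        cols = list(expand[group]) if expand and group in expand else [group]
        for c in cols:
            if c not in taxa:
                raise ValueError(f"supergroup {c!r} not in the declared taxon set")
        return cols

    rows: dict[str, dict[str, int]] = {}
    for block in blocks:
        for gene in block.genes():
            row = rows.setdefault(gene, {t: 0 for t in taxa})
            for label in block.labels.values():
                if label.gene == gene:
                    for c in columns(label.supergroup):
                        row[c] = 1
            for label in block.absences:
                if label.gene == gene:
                    for c in columns(label.supergroup):
                        row.setdefault(c, 0)  # absence: leave at 0; presence wins
    if include_indels and indel_calls:
        for name, calls in indel_calls.items():
            for i, call in enumerate(calls):
                row = {t: 0 for t in taxa}
                for group in call.residue_groups:
                    for c in columns(group):
                        row[c] = 1
                rows[f"{name}_indel{i}_{call.start}_{call.end}"] = row
    return CharacterMatrix(pd.DataFrame.from_dict(rows, orient="index")[taxa])
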