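"""Packaged example data: curated paralog-pair blocks and ring topologies.

The alignment excerpts are the published ParC/GyrA and HisF/GGGPS
paralog-pair blocks across the prokaryotic super-taxa — the classic
demonstration that some gene distributions contradict every rooted tree
while fitting a rooted ring with no losses.  Group letters follow the
field's convention: Actinobacteria (A), double-membrane prokaryotes (D),
Bacilli (B), Clostridia (C), Eocyta (E), Halobacteria/Euryarchaeota (H);
the five-way scheme merges B and C into the Firmicutes (F).

Composite rows are expanded explicitly: a single "Firmicutes" row stands
for both B and C, and an "Archaebacteria" row for both H and E (see
:data:`TABLE12_EXPAND`).  The Thermoprotei HisF row is assigned to the
eocytes (E): Thermoprotei are the Crenarchaeota, i.e. the eocyte lineage.

The five-taxon ring with six gain sites is a reconstruction from
published descriptions of the major prokaryotic gene flows (the A- and
Firmicute-flows merging into the DM prokaryotes; the phototrophic flow
from the archaeal arc into the Halobacteria and the Firmicutes; the E/H
sister arc), arranged so its six sites yield six distinct informative
flow signatures.
"""

from __future__ import annotations

from .flow_parsimony import CharacterMatrix
from .indel_characters import AlignmentBlock, SeqLabel, build_character_matrix, call_indels
from .ring_model import ROOT_SITE, FlowGraph, Taxon, UnrootedTree, build_flow_graph

import networkx as nx

__all__ = [
    "SIX_TAXA",
    "FIVE_TAXA",
    "TABLE12_EXPAND",
    "parc_gyra_block",
    "gggps_hisf_block",
    "paralog_character_matrix",
    "inner_ring_six",
    "inner_ring_six_gain_sites",
    "three_cherry_tree",
    "inner_ring_five",
    "inner_ring_five_gain_sites",
    "gggps_census",
    "parc_census",
]

#: Six-group scheme used for the paralog-pair parsimony demonstration.
SIX_TAXA = ("A", "D", "B", "C", "E", "H")
#: Five prokaryotic super-taxa used for whole-genome pattern tabulation.
FIVE_TAXA = ("A", "D", "F", "H", "E")

#: Composite label expansion: one Firmicutes row stands for Bacilli and
#: Clostridia; one Archaebacteria row for Halobacteria and Eocyta.
TABLE12_EXPAND = {"F": ("B", "C"), "Rarch": ("H", "E")}

_PARC_GYRA = [
    # (seq_id, taxon, supergroup, gene, sequence or None for recorded absence)
    ("ParC_Proteo1", "Proteobacteria-1", "D", "ParC",
     "NGAGGIAVGMATNIPPHNLGEVIDACLLLIDQPDVT----TDQLLDLVPGPDFPT"),
    ("ParC_Proteo2", "Proteobacteria-2", "D", "ParC",
     "NGTTGIAVGMATDIPPHNLREVAQAAIALIDQPKTT----LDQLLDIVQGPDYPT"),
    ("ParC_Cyano", "Cyanobacteria", "D", "ParC",
     "NGCSGIAVGMATNVPPHNLGEVVDGLIALIDNPDLP----DEKLFQLIPGPDFPT"),
    ("ParC_Actino", "Actinobacteria", "A", "ParC",
     "NGASGIAVGMATNMAPHNLVEVVGAARHLLDNPDAT----LDDLMAYIPGPDLPS"),
    ("ParC_Firmi", "Firmicutes", "F", "ParC",
     "NGANGIAVGMTTNIPPHNLSEVISGLHMLMRNPDAT----TKDLMKEIPGPDFPT"),
    ("ParC_Eury", "Euryarchaeota", "H", "ParC", None),
    ("ParC_Eocyta", "Eocyta", "E", "ParC", None),
    ("GyrA_Proteo1", "Proteobacteria-1", "D", "GyrA",
     "NGSGGIAVGMATNIPPHNLGEVIDGCVALIDNPAIE----LSELMELIPGPDFPT"),
    ("GyrA_Proteo2", "Proteobacteria-2", "D", "GyrA",
     "NGSSGIAVGMATNIPPHNLTEVINGCLAYIDDEDIS----IEGLMEHIPGPDFPT"),
    ("GyrA_Cyano", "Cyanobacteria", "D", "GyrA",
     "NGSSGIAVGMATNIPPHNLGELIDALVAVIHNPEIT----DLELMQYVHGPDFPT"),
    ("GyrA_Actino", "Actinobacteria", "A", "GyrA",
     "NGSSGIAVGMATNIPTHNLREVNEAVQWSLAHPNASHEELLEACMERIKGPDFPG"),
    ("GyrA_Firmi", "Firmicutes", "F", "GyrA",
     "NGSTGISSGYATEIPPHNLGEVIDATIYLLKHPNAS----LEDLMNYVKGPDFPT"),
    ("GyrA_Arch", "Archaebacteria", "Rarch", "GyrA",
     "NGSSGIAVGMSTNIPPHNLGELVDATVHLLGNPDCT----VEDLMEHIKGPDFPT"),
]

_HISF_GGGPS = [
    ("HisF_Proteo1", "Proteobacteria-1", "D", "HisF", "KNGFDLGVTRAISDALGIPVIASGGVGNLQH"),
    ("HisF_Proteo2", "Proteobacteria-2", "D", "HisF", "KSGFDLELTRAVSDAVPVPVIASGGVGNLQH"),
    ("HisF_Cyano", "Cyanobacteria", "D", "HisF", "QAGYDLELTRAVAQAVPVPVIASGGAGCLDH"),
    ("HisF_Deino", "Deino-Thermus", "D", "HisF", "RAGFDLEATRAVAREVDLPVIASGGAGKVQD"),
    ("HisF_OtherDM", "Other-DM-Proks", "D", "HisF", "KDGYDIELNRAISEAVNIPVIASGGAGKKEH"),
    ("HisF_Actino", "Actinobacteria", "A", "HisF", "KAGFDLALLRAVRAAVTVPVIASGGAGAVEH"),
    ("HisF_Bacilli", "Bacilli", "B", "HisF", "KNGYDLRLTEEISKSVSVPVIASGGCGHADH"),
    ("HisF_Clostridia", "Clostridia", "C", "HisF", "KDGYDIELTRTVSENVKIPVIASGGAGKMEH"),
    ("HisF_Halo", "Halobacteria", "H", "HisF", "KDGYDIPLMKAVCDTVSTPVIASSGCGSPED"),
    ("HisF_Thermoplasma", "Thermoplasmata", "H", "HisF", "KKGFDTDLIRKITGSVNIPVIASGGAGSPED"),
    # Thermoprotei = Crenarchaeota = the eocyte lineage
    ("HisF_Thermoprotei", "Thermoprotei", "E", "HisF", "RLGYDLELTRKIVDSVNIPVIASGGAGKMEH"),
    ("GGGPS_Proteo1", "Proteobacteria-1", "D", "GGGPS", None),
    ("GGGPS_Proteo2", "Proteobacteria-2", "D", "GGGPS", None),
    ("GGGPS_Cyano", "Cyanobacteria", "D", "GGGPS", None),
    ("GGGPS_Deino", "Deino-Thermus", "D", "GGGPS", None),
    ("GGGPS_OtherDM", "Other-DM-Proks", "D", "GGGPS", None),
    ("GGGPS_Actino", "Actinobacteria", "A", "GGGPS", None),
    ("GGGPS_Bacilli1", "Bacilli-1", "B", "GGGPS", "MLGDIEAVKKTKAVLETSTLFYGGGIKDAET"),
    ("GGGPS_Clostridia", "Clostridia", "C", "GGGPS", "RFGDPAWVGAAAGAMRGARLFYGGGIGTAEQ"),
    ("GGGPS_Bacilli2", "Bacilli-2", "B", "GGGPS", "IYGDVSKVQAVSEHLTETQLFYGGGISSEQQ"),
    ("GGGPS_Halo", "Halobacteria", "H", "GGGPS", "MFGDTEKVQAAHDALDDATLFYGGGIRDYDA"),
    ("GGGPS_Archaeoglobus", "Archaeoglobus", "H", "GGGPS", "IYGNPELVAEVKKVLDKARLFYGGGIDSREK"),
    ("GGGPS_Methanobacter", "Methanobacter", "H", "GGGPS", "PEHVPEEMIALVKRCTDQILIVGGGIRSGED"),
    ("GGGPS_Methanocaldo", "Methanocaldococcus", "E", "GGGPS", "SYPVNNETIALSKKLSGINIIVGGGIRKPEI"),
    ("GGGPS_Pyrococcus", "Pyrococcus", "E", "GGGPS", "PEPVPEEMVRVVKSVIDVPLIVGGGIKSGEQ"),
]


def _block(rows) -> AlignmentBlock:
    sequences, labels, absences = {}, {}, []
    for sid, taxon, group, gene, seq in rows:
        label = SeqLabel(seq_id=sid, taxon=taxon, supergroup=group, gene=gene,
                         present=seq is not None)
        if seq is None:
            absences.append(label)
        else:
            sequences[sid] = seq
            labels[sid] = label
    return AlignmentBlock(sequences=sequences, labels=labels, absences=absences)


def parc_gyra_block() -> AlignmentBlock:
    """The ParC/GyrA paralog-pair block (11 sequences, 55 columns).

    ParC is absent from the archaebacterial groups (recorded absences for
    the Euryarchaeota and the Eocyta); the block contains one width-4
    shared gap whose only residue-bearing row is the Actinobacteria GyrA
    sequence.
    """
    return _block(_PARC_GYRA)


def gggps_hisf_block() -> AlignmentBlock:
    """The HisF/GGGPS paralog-pair block (19 sequences, 31 columns).

    GGGPS is absent from the Actinobacteria and all DM groups (recorded
    absences); HisF is present everywhere.
    """
    return _block(_HISF_GGGPS)


def paralog_character_matrix(include_indels: bool = False) -> CharacterMatrix:
    """The six-taxon binary matrix of the four paralog families.

    ParC: present A, D, B, C; GyrA/HisF: all present; GGGPS: present
    B, C, E, H.  Built by running the full alignment pipeline on the two
    packaged blocks.
    """
    blocks = [parc_gyra_block(), gggps_hisf_block()]
    calls = None
    if include_indels:
        calls = {
            "parc_gyra": call_indels(blocks[0]),
            "hisf_gggps": call_indels(blocks[1]),
        }
    return build_character_matrix(
        blocks, calls, SIX_TAXA, expand=TABLE12_EXPAND, include_indels=include_indels
    )


# ---------------------------------------------------------------------------
# topologies
# ---------------------------------------------------------------------------

def _six_leaf_map() -> dict[str, Taxon]:
    names = {
        "A": "Actinobacteria", "D": "DM prokaryotes", "B": "Bacilli",
        "C": "Clostridia", "E": "Eocyta", "H": "Halobacteria",
    }
    return {t: Taxon(id=t, name=names[t], supergroup=t) for t in SIX_TAXA}


def inner_ring_six() -> FlowGraph:
    """The rooted six-taxon inner ring.

    The root splits into a left arc (toward A and D) and a right arc
    (toward H and E); the two arcs merge before flowing into the
    Firmicutes (B and C).  On this ring the four paralog families need
    four gains and no losses.
    """
    edges = [
        ("root", "L"), ("root", "R"),
        ("L", "AD"), ("AD", "A"), ("AD", "D"), ("L", "M"),
        ("R", "HE"), ("HE", "H"), ("HE", "E"), ("R", "M"),
        ("M", "B"), ("M", "C"),
    ]
    return build_flow_graph(edges, _six_leaf_map())


def inner_ring_six_gain_sites() -> dict[str, object]:
    """Gain site of each paralog family on the six-taxon ring."""
    return {
        "HisF": ROOT_SITE,
        "GyrA": ROOT_SITE,
        "ParC": ("root", "L"),
        "GGGPS": ("root", "R"),
    }


def three_cherry_tree() -> UnrootedTree:
    """The canonical 6-leaf unrooted tree with cherries (A,D)(B,C)(E,H).

    Its nine rootings are the tree hypotheses the ring is compared
    against.
    """
    g = nx.Graph()
    g.add_edges_from([
        ("x", "A"), ("x", "D"), ("y", "B"), ("y", "C"), ("z", "E"), ("z", "H"),
        ("c", "x"), ("c", "y"), ("c", "z"),
    ])
    return UnrootedTree(g, _six_leaf_map())


def inner_ring_five() -> FlowGraph:
    """Five-super-taxon rooted ring with three merge nodes (reconstruction).

    Left arc: A, with the A-lineage flow joining the Firmicute flow to
    form the DM prokaryotes (merge D1).  Right arc: the archaeal side,
    splitting into the E/H sister pair and a phototrophic flow that joins
    H and continues into the Firmicutes (merges H1 and M).
    """
    edges = [
        ("root", "L"), ("root", "R"),
        ("L", "A1"), ("A1", "A"), ("A1", "D1"), ("L", "M"),
        ("R", "S"), ("S", "S2"), ("S2", "E"), ("S2", "H1"),
        ("S", "P"), ("P", "H1"), ("H1", "H"), ("P", "M"),
        ("M", "F1"), ("F1", "F"), ("F1", "D1"), ("D1", "D"),
    ]
    names = {
        "A": "Actinobacteria", "D": "DM prokaryotes", "F": "Firmicutes",
        "H": "Halobacteria/Euryarchaeota", "E": "Eocyta",
    }
    leaf_map = {t: Taxon(id=t, name=names[t], supergroup=t) for t in FIVE_TAXA}
    return build_flow_graph(edges, leaf_map)


def inner_ring_five_gain_sites() -> list[tuple[str, str]]:
    """The six gain sites of the five-taxon ring.

    Their flow signatures are six distinct informative patterns:
    {A,D}, {E,H}, {H,F,D} (phototrophic), {F,D}, {A,D,F}, {D,E,F,H}.
    """
    return [
        ("L", "A1"),
        ("S", "S2"),
        ("S", "P"),
        ("L", "M"),
        ("root", "L"),
        ("root", "R"),
    ]


# ---------------------------------------------------------------------------
# sequence census counts for the two-urn tests
# ---------------------------------------------------------------------------

def gggps_census() -> dict[str, int]:
    """GGGPS sequence census: 111 archaeal-side vs 21 AD-side of 420.

    The 420 aligned family members split into 111 unique Euryarchaeota +
    eocyte species against 21 Actinobacteria + DM species.
    """
    return {"side_archaeal": 111, "side_AD": 21, "population": 420}


def parc_census() -> dict[str, int]:
    """ParC sequence census: 2,249 AD-side vs 39 euryarchaeal of 8,014.

    2,249 = 1,505 DM-side + 744 Firmicute unique species; 376
    uncharacterized and 256 probable-DM species are conservatively
    excluded from the marked count (``excluded`` records them).
    """
    return {
        "side_AD": 2249,
        "side_archaeal": 39,
        "population": 8014,
        "excluded": 376 + 256,
    }
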