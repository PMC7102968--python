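"""Fixed chemical reference tables.

Everything geometric in this package (contacts, hydrogen bonds, ring
interactions, base-pair edges, surface areas) is driven by the small,
versioned lookup tables in this module rather than by per-call heuristics,
so that every threshold and atom-class assignment is inspectable and
overridable.
"""

from __future__ import annotations

# ---------------------------------------------------------------------------
# Residue classification
# ---------------------------------------------------------------------------

AMINO_ACIDS = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

RIBONUCLEOTIDES = {"A", "C", "G", "U"}
DEOXYNUCLEOTIDES = {"DA", "DC", "DG", "DT"}
NUCLEOTIDES = RIBONUCLEOTIDES | DEOXYNUCLEOTIDES

WATER_NAMES = {"HOH", "WAT", "DOD"}


def residue_kind(name: str) -> str:
    """Classify a residue name as ``amino_acid``, ``nucleotide`` or ``other``."""
    name = name.strip().upper()
    if name in AMINO_ACIDS:
        return "amino_acid"
    if name in NUCLEOTIDES:
        return "nucleotide"
    return "other"


# Base letter of a nucleotide residue name ("DG" -> "G").
def base_letter(resname: str) -> str:
    resname = resname.strip().upper()
    if resname in DEOXYNUCLEOTIDES:
        return resname[1]
    if resname in RIBONUCLEOTIDES:
        return resname
    raise ValueError(f"not a standard nucleotide residue: {resname!r}")


PURINES = {"A", "G"}
PYRIMIDINES = {"C", "U", "T"}

# Watson-Crick complements; G:U is a wobble, flagged separately downstream.
WC_COMPLEMENT = {"A": {"U", "T"}, "U": {"A"}, "T": {"A"}, "G": {"C"}, "C": {"G"}}

# ---------------------------------------------------------------------------
# van der Waals radii (Bondi 1964, single-source set; Å)
# ---------------------------------------------------------------------------

VDW_RADII = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "P": 1.80,
    "S": 1.80,
    "F": 1.47,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
    "SE": 1.90,
    "MG": 1.73,
    "K": 2.75,
    "NA": 2.27,
    "ZN": 1.39,
}


def vdw_radius(element: str) -> float:
    try:
        return VDW_RADII[element.strip().upper()]
    except KeyError:
        raise KeyError(f"no van der Waals radius for element {element!r}") from None


# ---------------------------------------------------------------------------
# Hydrogen-bond chemistry (heavy-atom criteria; deposited models lack H)
#
# donors: atom -> antecedent heavy atom used for the antecedent-donor-acceptor
# angle gate.  acceptors: plain atom sets.
# ---------------------------------------------------------------------------

_BACKBONE_DONOR = {"N": "CA"}
_BACKBONE_ACCEPTOR = {"O", "OXT"}

PROTEIN_SIDECHAIN_DONORS = {
    "ARG": {"NE": "CZ", "NH1": "CZ", "NH2": "CZ"},
    "ASN": {"ND2": "CG"},
    "GLN": {"NE2": "CD"},
    "HIS": {"ND1": "CG", "NE2": "CE1"},
    "LYS": {"NZ": "CE"},
    "SER": {"OG": "CB"},
    "THR": {"OG1": "CB"},
    "TRP": {"NE1": "CD1"},
    "TYR": {"OH": "CZ"},
    "CYS": {"SG": "CB"},
}

PROTEIN_SIDECHAIN_ACCEPTORS = {
    "ASN": {"OD1"},
    "ASP": {"OD1", "OD2"},
    "GLN": {"OE1"},
    "GLU": {"OE1", "OE2"},
    "HIS": {"ND1", "NE2"},
    "SER": {"OG"},
    "THR": {"OG1"},
    "TYR": {"OH"},
    "MET": {"SD"},
}

# Nucleotide donors/acceptors per base letter (sugar/phosphate shared).
_SUGAR_DONORS = {"O2'": "C2'"}
_SUGAR_PHOSPHATE_ACCEPTORS = {"OP1", "OP2", "OP3", "O5'", "O3'", "O4'", "O2'"}

BASE_DONORS = {
    "A": {"N6": "C6"},
    "G": {"N1": "C2", "N2": "C2"},
    "C": {"N4": "C4"},
    "U": {"N3": "C2"},
    "T": {"N3": "C2"},
}

BASE_ACCEPTORS = {
    "A": {"N1", "N3", "N7"},
    "G": {"N3", "N7", "O6"},
    "C": {"N3", "O2"},
    "U": {"O2", "O4"},
    "T": {"O2", "O4"},
}


def donor_map(resname: str) -> dict[str, str]:
    """atom -> antecedent for every H-bond donor atom of a residue type."""
    kind = residue_kind(resname)
    if kind == "amino_acid":
        d = dict(_BACKBONE_DONOR)
        d.update(PROTEIN_SIDECHAIN_DONORS.get(resname.upper(), {}))
        return d
    if kind == "nucleotide":
        d = dict(_SUGAR_DONORS) if resname.upper() in RIBONUCLEOTIDES else {}
        d.update(BASE_DONORS[base_letter(resname)])
        return d
    return {}


def acceptor_set(resname: str) -> set[str]:
    kind = residue_kind(resname)
    if kind == "amino_acid":
        return _BACKBONE_ACCEPTOR | PROTEIN_SIDECHAIN_ACCEPTORS.get(resname.upper(), set())
    if kind == "nucleotide":
        acc = set(_SUGAR_PHOSPHATE_ACCEPTORS)
        if resname.upper() not in RIBONUCLEOTIDES:
            acc.discard("O2'")
        return acc | BASE_ACCEPTORS[base_letter(resname)]
    return set()


# ---------------------------------------------------------------------------
# Aromatic rings and cationic groups
# ---------------------------------------------------------------------------

PROTEIN_RINGS = {
    "PHE": [("CG", "CD1", "CD2", "CE1", "CE2", "CZ")],
    "TYR": [("CG", "CD1", "CD2", "CE1", "CE2", "CZ")],
    "TRP": [("CG", "CD1", "CD2", "NE1", "CE2"),
            ("CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2")],
    "HIS": [("CG", "ND1", "CD2", "CE1", "NE2")],
}

# Purines: the six-membered and five-membered rings; pyrimidines: one ring.
BASE_RINGS = {
    "A": [("N1", "C2", "N3", "C4", "C5", "C6"), ("C4", "C5", "N7", "C8", "N9")],
    "G": [("N1", "C2", "N3", "C4", "C5", "C6"), ("C4", "C5", "N7", "C8", "N9")],
    "C": [("N1", "C2", "N3", "C4", "C5", "C6")],
    "U": [("N1", "C2", "N3", "C4", "C5", "C6")],
    "T": [("N1", "C2", "N3", "C4", "C5", "C6")],
}

# All heavy base atoms (ring + exocyclic), used for base planes and centroids.
BASE_ATOMS = {
    "A": ("N1", "C2", "N3", "C4", "C5", "C6", "N6", "N7", "C8", "N9"),
    "G": ("N1", "C2", "N2", "N3", "C4", "C5", "C6", "O6", "N7", "C8", "N9"),
    "C": ("N1", "C2", "O2", "N3", "C4", "N4", "C5", "C6"),
    "U": ("N1", "C2", "O2", "N3", "C4", "O4", "C5", "C6"),
    "T": ("N1", "C2", "O2", "N3", "C4", "O4", "C5", "C7", "C6"),
}

CATION_GROUPS = {
    "ARG": ("NE", "CZ", "NH1", "NH2"),   # guanidinium
    "LYS": ("NZ",),                      # ammonium
}

# ---------------------------------------------------------------------------
# Leontis-Westhof edge assignment
#
# Each polar base atom is assigned to the edge families it can serve
# (Watson-Crick, Hoogsteen, Sugar).  Atoms on an edge boundary carry several
# memberships and contribute fractional weight to each during the majority
# vote in base-pair classification.  The ribose O2' belongs to the sugar edge.
# ---------------------------------------------------------------------------

WC, HOOGSTEEN, SUGAR = "WatsonCrick", "Hoogsteen", "SugarEdge"

EDGE_MEMBERSHIP = {
    "A": {
        "N1": (WC,), "N6": (WC, HOOGSTEEN), "C2": (WC, SUGAR),
        "N7": (HOOGSTEEN,), "N3": (SUGAR,), "O2'": (SUGAR,),
    },
    "G": {
        "N1": (WC,), "O6": (WC, HOOGSTEEN), "N2": (WC, SUGAR),
        "N7": (HOOGSTEEN,), "N3": (SUGAR,), "O2'": (SUGAR,),
    },
    "C": {
        "N3": (WC,), "N4": (WC, HOOGSTEEN), "O2": (WC, SUGAR),
        "O2'": (SUGAR,),
    },
    "U": {
        "N3": (WC,), "O4": (WC, HOOGSTEEN), "O2": (WC, SUGAR),
        "O2'": (SUGAR,),
    },
    "T": {
        "N3": (WC,), "O4": (WC, HOOGSTEEN), "O2": (WC, SUGAR),
        "O2'": (SUGAR,),
    },
}

# Glycosidic nitrogen and the chi-defining base atom per base letter.
GLYCOSIDIC_N = {"A": "N9", "G": "N9", "C": "N1", "U": "N1", "T": "N1"}
CHI_BASE_ATOM = {"A": "C4", "G": "C4", "C": "C2", "U": "C2", "T": "C2"}
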