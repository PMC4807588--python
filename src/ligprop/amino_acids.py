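"""Amino-acid alphabets and physicochemical class definitions.

All 20-vectors in this package (counts, compositions, propensities) are
aligned to :data:`AA_ORDER`, the alphabetical one-letter order of the
twenty standard amino acids.  The eight physicochemical classes follow the
classical size/charge/polarity/hydrophobicity grouping; classes overlap
(e.g. glycine is both small and non-polar), except that acidic and basic
partition the charged class exactly.
"""

from __future__ import annotations

from Bio.Data.IUPACData import protein_letters_1to3

#: One-letter codes of the 20 standard amino acids, alphabetical.
AA_ORDER: str = "ACDEFGHIKLMNPQRSTVWY"

#: Map one-letter code -> index into any 20-vector.
AA_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(AA_ORDER)}

#: Map one-letter -> upper-case three-letter code (ALA, CYS, ...).
ONE_TO_THREE: dict[str, str] = {
    aa: protein_letters_1to3[aa].upper() for aa in AA_ORDER
}

#: Map three-letter -> one-letter code.
THREE_TO_ONE: dict[str, str] = {v: k for k, v in ONE_TO_THREE.items()}

#: Three-letter codes of the standard amino acids.
STANDARD_AA3 = frozenset(THREE_TO_ONE)

#: Het codes treated as water and never as ligands.
WATER_CODES = frozenset({"HOH", "WAT", "DOD"})

#: Placeholder symbol for unknown residues / terminal window padding.
UNKNOWN = "X"

#: Physicochemical classes.  Acidic and basic are disjoint and their union
#: is exactly the charged class; the other classes overlap freely.
PROPERTY_CLASSES: dict[str, frozenset[str]] = {
    "charged": frozenset("DEKHR"),
    "acidic": frozenset("DE"),
    "basic": frozenset("KRH"),
    "small": frozenset("PACGSNDTV"),
    "polar": frozenset("STYNQ"),
    "non_polar": frozenset("AVLIPFWMCG"),
    "aromatic": frozenset("FYW"),
    "aliphatic": frozenset("LIVAG"),
}

#: Canonical ordering of the 8 property classes for PC vectors.
PROPERTY_ORDER: tuple[str, ...] = (
    "charged",
    "acidic",
    "basic",
    "small",
    "polar",
    "non_polar",
    "aromatic",
    "aliphatic",
)
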