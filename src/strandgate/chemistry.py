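"""Minimal sidechain chemistry table for reduced (pseudo-atom) residues.

Each residue carries at most one sidechain interaction-site atom (named
``SC``) besides CB.  The table below assigns that site its hydrogen-bonding
polarity, formal charge and aromaticity, which is all the interaction
detector needs.  Histidine is treated as neutral and non-aromatic here so
that planted salt bridges and stackings in fixtures are unambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass

#: atom name of the single sidechain interaction site
SIDECHAIN_SITE = "SC"

#: residue name used for the chromophore pseudo-residue
CHROMOPHORE_RESNAME = "CRO"


@dataclass(frozen=True)
class SidechainProps:
    polar: bool
    charge: int
    aromatic: bool
    has_sidechain: bool = True


_APOLAR = SidechainProps(polar=False, charge=0, aromatic=False)
_POLAR = SidechainProps(polar=True, charge=0, aromatic=False)

SIDECHAIN_PROPS: dict[str, SidechainProps] = {
    "GLY": SidechainProps(polar=False, charge=0, aromatic=False, has_sidechain=False),
    "ALA": _APOLAR,
    "VAL": _APOLAR,
    "LEU": _APOLAR,
    "ILE": _APOLAR,
    "PRO": _APOLAR,
    "MET": _APOLAR,
    "CYS": _POLAR,
    "SER": _POLAR,
    "THR": _POLAR,
    "ASN": _POLAR,
    "GLN": _POLAR,
    "HIS": _POLAR,
    "TYR": SidechainProps(polar=True, charge=0, aromatic=True),
    "TRP": SidechainProps(polar=False, charge=0, aromatic=True),
    "PHE": SidechainProps(polar=False, charge=0, aromatic=True),
    "LYS": SidechainProps(polar=True, charge=+1, aromatic=False),
    "ARG": SidechainProps(polar=True, charge=+1, aromatic=False),
    "ASP": SidechainProps(polar=True, charge=-1, aromatic=False),
    "GLU": SidechainProps(polar=True, charge=-1, aromatic=False),
    # chromophore pseudo-residue: polar contacts handled atom-wise (N/O atoms),
    # neutral and non-stacking in this reduced representation
    CHROMOPHORE_RESNAME: SidechainProps(polar=True, charge=0, aromatic=False),
}


def sidechain_props(residue_name: str) -> SidechainProps:
    """Look up sidechain properties; unknown residues are treated apolar."""
    return SIDECHAIN_PROPS.get(residue_name.upper(), _APOLAR)


#: van der Waals radii per element for SASA (single-atom set, Angstrom)
VDW_RADII: dict[str, float] = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "H": 1.20,
}
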