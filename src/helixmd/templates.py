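"""Residue template table: rings, H-bond donors/acceptors, anionic atoms.

The geometric interaction analyses need to know, per residue type, which
atoms form aromatic rings, which (heavy atom, hydrogen) pairs can donate a
hydrogen bond, which atoms accept one, and which carry a formal negative
charge.  Trajectory formats do not carry this chemistry, so it ships here
as a template table keyed by 3-letter residue name, user-overridable via
:func:`load_templates` (YAML with the same structure).

Ring atom lists follow the standard PDB atom nomenclature.  Tryptophan
contributes two rings (the 5-membered pyrrole and the 6-membered benzene
moiety of the indole), handled separately downstream.
"""

from __future__ import annotations

import copy
from typing import Any

import yaml

#: aromatic ring atoms per residue type; list of rings, each an ordered
#: atom-name list.  HIS inclusion in π tallies is a downstream config flag;
#: the ring itself is always annotated.
RING_ATOMS: dict[str, list[list[str]]] = {
    "PHE": [["CG", "CD1", "CE1", "CZ", "CE2", "CD2"]],
    "TYR": [["CG", "CD1", "CE1", "CZ", "CE2", "CD2"]],
    "HIS": [["CG", "ND1", "CE1", "NE2", "CD2"]],
    "HSD": [["CG", "ND1", "CE1", "NE2", "CD2"]],
    "HSE": [["CG", "ND1", "CE1", "NE2", "CD2"]],
    "TRP": [
        ["CG", "CD1", "NE1", "CE2", "CD2"],          # pyrrole ring
        ["CD2", "CE2", "CZ2", "CH2", "CZ3", "CE3"],  # benzene ring
    ],
}

#: side-chain donor heavy atoms -> names of bonded hydrogens
SIDECHAIN_DONORS: dict[str, dict[str, list[str]]] = {
    "SER": {"OG": ["HG", "HG1"]},
    "THR": {"OG1": ["HG1"]},
    "TYR": {"OH": ["HH"]},
    "CYS": {"SG": ["HG", "HG1"]},
    "LYS": {"NZ": ["HZ1", "HZ2", "HZ3"]},
    "ARG": {"NE": ["HE"], "NH1": ["HH11", "HH12"], "NH2": ["HH21", "HH22"]},
    "ASN": {"ND2": ["HD21", "HD22"]},
    "GLN": {"NE2": ["HE21", "HE22"]},
    "TRP": {"NE1": ["HE1"]},
    "HIS": {"ND1": ["HD1"], "NE2": ["HE2"]},
    "HSD": {"ND1": ["HD1"]},
    "HSE": {"NE2": ["HE2"]},
}

#: side-chain acceptor atoms
SIDECHAIN_ACCEPTORS: dict[str, list[str]] = {
    "SER": ["OG"],
    "THR": ["OG1"],
    "TYR": ["OH"],
    "ASP": ["OD1", "OD2"],
    "GLU": ["OE1", "OE2"],
    "ASN": ["OD1"],
    "GLN": ["OE1"],
    "HIS": ["ND1", "NE2"],
    "HSD": ["NE2"],
    "HSE": ["ND1"],
    "MET": ["SD"],
}

#: charged carboxylate oxygens used by the anion-π detector
ANION_ATOMS: dict[str, list[str]] = {
    "ASP": ["OD1", "OD2"],
    "GLU": ["OE1", "OE2"],
}

#: backbone donor (N-H) and acceptor (O) apply to every amino-acid residue
BACKBONE_DONOR: tuple[str, list[str]] = ("N", ["H", "HN", "H1", "H2", "H3"])
BACKBONE_ACCEPTOR = "O"

PROTEIN_RESIDUES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "HSD",
    "HSE", "HSP", "ILE", "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR",
    "TRP", "TYR", "VAL",
}

#: residue-name -> molecule class used to partition the system
MOLECULE_CLASSES: dict[str, str] = {
    **{r: "protein" for r in PROTEIN_RESIDUES},
    "POPC": "POPC",
    "POPE": "POPE",
    "CHL1": "cholesterol",
    "CHOL": "cholesterol",
    "CLR": "cholesterol",
    "TIP3": "water",
    "HOH": "water",
    "WAT": "water",
    "SOL": "water",
    "SOD": "ion", "NA": "ion", "CLA": "ion", "CL": "ion",
    "POT": "ion", "K": "ion", "MG": "ion", "CAL": "ion",
    "SRO": "ligand", "5HT": "ligand",
}

#: head-group atom used for leaflet assignment, per lipid residue name
LIPID_HEAD_ATOMS: dict[str, list[str]] = {
    "POPC": ["P", "P1"],
    "POPE": ["P", "P1"],
    "CHL1": ["O3", "O1", "OH"],
    "CHOL": ["O3", "O1", "OH"],
    "CLR": ["O3", "O1", "OH"],
}

_ELEMENT_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999,
    "P": 30.974, "S": 32.06, "NA": 22.990, "CL": 35.45,
    "K": 39.098, "MG": 24.305, "CA": 40.078,
}


def guess_element(atom_name: str) -> str:
    """Infer the element from a PDB-style atom name."""
    stripped = atom_name.strip().lstrip("0123456789")
    if not stripped:
        return "X"
    if stripped[:2].upper() in ("CL", "NA", "MG") and len(atom_name.strip()) <= 2:
        return stripped[:2].capitalize()
    return stripped[0].upper()


def element_mass(element: str) -> float:
    return _ELEMENT_MASSES.get(element.upper(), 12.011)


def default_templates() -> dict[str, Any]:
    """Return a deep copy of the built-in template table."""
    return copy.deepcopy(
        {
            "rings": RING_ATOMS,
            "sidechain_donors": SIDECHAIN_DONORS,
            "sidechain_acceptors": SIDECHAIN_ACCEPTORS,
            "anions": ANION_ATOMS,
            "molecule_classes": MOLECULE_CLASSES,
            "lipid_heads": LIPID_HEAD_ATOMS,
        }
    )


def load_templates(path: str | None = None) -> dict[str, Any]:
    """Built-in templates, optionally overlaid with a user YAML file.

    The YAML file may redefine any subset of the top-level keys; entries
    merge per residue name (user entries win).
    """
    table = default_templates()
    if path is None:
        return table
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    for key, overlay in user.items():
        if key not in table:
            raise KeyError(f"unknown template section {key!r}")
        table[key].update(overlay)
    return table
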