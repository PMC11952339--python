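"""Residue-level chemical reference data for the 20 standard amino acids.

Provides: one/three-letter code maps, side-chain chi torsion definitions
(standard IUPAC atom quadruples, capped at chi4), per-residue heavy-atom
templates with idealized geometry and intra-residue bond graphs (taken from
the chemical component dictionary bundled with ``biotite``), van der Waals
radii (Bondi set), and helpers used by the chain builder and the relaxation
energy terms.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}
STANDARD_RESIDUES = tuple(sorted(THREE_TO_ONE))

# Standard IUPAC chi torsion atom quadruples, capped at chi4 (ARG chi5 ignored).
CHI_ATOMS: dict[str, tuple[tuple[str, str, str, str], ...]] = {
    "ALA": (),
    "GLY": (),
    "SER": (("N", "CA", "CB", "OG"),),
    "THR": (("N", "CA", "CB", "OG1"),),
    "VAL": (("N", "CA", "CB", "CG1"),),
    "CYS": (("N", "CA", "CB", "SG"),),
    "ASP": (("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")),
    "ASN": (("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")),
    "HIS": (("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "ND1")),
    "ILE": (("N", "CA", "CB", "CG1"), ("CA", "CB", "CG1", "CD1")),
    "LEU": (("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")),
    "PHE": (("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")),
    "PRO": (("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD")),
    "TRP": (("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")),
    "TYR": (("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")),
    "MET": (
        ("N", "CA", "CB", "CG"),
        ("CA", "CB", "CG", "SD"),
        ("CB", "CG", "SD", "CE"),
    ),
    "GLU": (
        ("N", "CA", "CB", "CG"),
        ("CA", "CB", "CG", "CD"),
        ("CB", "CG", "CD", "OE1"),
    ),
    "GLN": (
        ("N", "CA", "CB", "CG"),
        ("CA", "CB", "CG", "CD"),
        ("CB", "CG", "CD", "OE1"),
    ),
    "LYS": (
        ("N", "CA", "CB", "CG"),
        ("CA", "CB", "CG", "CD"),
        ("CB", "CG", "CD", "CE"),
        ("CG", "CD", "CE", "NZ"),
    ),
    "ARG": (
        ("N", "CA", "CB", "CG"),
        ("CA", "CB", "CG", "CD"),
        ("CB", "CG", "CD", "NE"),
        ("CG", "CD", "NE", "CZ"),
    ),
}

def n_chi(res_name: str) -> int:
    """Number of chi torsions defined for a residue type (0..4)."""
    return len(CHI_ATOMS[res_name])


# Bondi van der Waals radii, Angstrom.
BONDI_RADII: dict[str, float] = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.20}

# Idealized backbone geometry used by the chain builder and relaxation terms.
BACKBONE_GEOMETRY = {
    "bond_N_CA": 1.458,
    "bond_CA_C": 1.525,
    "bond_C_O": 1.231,
    # Peptide C(i)-N(i+1): one value throughout, the reference mean of the
    # bond-length violation counter, so ideal chains score zero violations
    # and are fixed points of the relaxation's bond terms.
    "bond_C_N_build": 1.348,
    "bond_C_N_eq": 1.348,
    "angle_N_CA_C": 111.2,
    "angle_CA_C_N": 116.6,
    "angle_C_N_CA": 121.7,
    "angle_CA_C_O": 120.5,
    "angle_O_C_N": 122.7,
}


@dataclass(frozen=True)
class ResidueTemplate:
    """Idealized heavy-atom geometry of one amino-acid type.

    ``coords`` carry the component-dictionary ideal coordinates; ``bonds`` is
    the intra-residue heavy-atom bond list as index pairs into ``atom_names``.
    """

    name: str
    atom_names: tuple[str, ...]
    elements: tuple[str, ...]
    coords: np.ndarray
    bonds: tuple[tuple[int, int], ...]

    def index(self, atom_name: str) -> int:
        return self.atom_names.index(atom_name)

    @property
    def side_chain_names(self) -> tuple[str, ...]:
        return tuple(n for n in self.atom_names if n not in ("N", "CA", "C", "O"))


@lru_cache(maxsize=None)
def residue_template(res_name: str) -> ResidueTemplate:
    """Heavy-atom ideal-geometry template for a standard residue.

    Hydrogens and the C-terminal OXT are stripped; atom order follows the
    component dictionary (N, CA, C, O, then side chain).
    """
    if res_name not in THREE_TO_ONE:
        raise ValueError(
            f"unknown residue name {res_name!r}; supported codes: "
            + ", ".join(STANDARD_RESIDUES)
        )
    import biotite.structure.info as info

    arr = info.residue(res_name)
    keep = (arr.element != "H") & (arr.atom_name != "OXT")
    idx_map = {}
    names, elements, coords = [], [], []
    for i in np.flatnonzero(keep):
        idx_map[i] = len(names)
        names.append(str(arr.atom_name[i]))
        elements.append(str(arr.element[i]))
        coords.append(arr.coord[i])
    bonds = []
    for i, j, _order in arr.bonds.as_array():
        if i in idx_map and j in idx_map:
            a, b = idx_map[i], idx_map[j]
            bonds.append((min(a, b), max(a, b)))
    return ResidueTemplate(
        name=res_name,
        atom_names=tuple(names),
        elements=tuple(elements),
        coords=np.asarray(coords, dtype=float),
        bonds=tuple(sorted(set(bonds))),
    )


@lru_cache(maxsize=None)
def chi_rotating_atoms(res_name: str, chi_index: int) -> tuple[str, ...]:
    """Atom names moved when rotating chi_{chi_index+1} about its central bond.

    These are the atoms on the far side of the B-C bond of the chi quadruple
    (A, B, C, D) in the residue's bond graph, D included.
    """
    tmpl = residue_template(res_name)
    quad = CHI_ATOMS[res_name][chi_index]
    b, c = tmpl.index(quad[1]), tmpl.index(quad[2])
    adjacency: dict[int, set[int]] = {i: set() for i in range(len(tmpl.atom_names))}
    for i, j in tmpl.bonds:
        adjacency[i].add(j)
        adjacency[j].add(i)
    adjacency[b].discard(c)
    adjacency[c].discard(b)
    seen = {c}
    stack = [c]
    while stack:
        u = stack.pop()
        for v in adjacency[u]:
            if v not in seen:
                seen.add(v)
                stack.append(v)
    seen.discard(c)
    return tuple(tmpl.atom_names[i] for i in sorted(seen))
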