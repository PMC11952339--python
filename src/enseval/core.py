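"""Core domain types and geometry operations for protein conformational ensembles.

The heavy-atom model: a :class:`Topology` (chain, residues, atoms, implied
backbone connectivity), per-frame :class:`Conformation` coordinates in
Angstrom, and the :class:`Ensemble` that ties a topology to a stack of frames
with an optional simulation temperature in Kelvin.  Torsion angles are in
degrees wrapped to (-180, 180].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from . import chemdata
from .geometry import apply_rigid, dihedral, kabsch

__all__ = [
    "Topology",
    "Conformation",
    "Ensemble",
    "TorsionTable",
    "VdwTable",
    "TORSION_NAMES",
    "compute_torsions",
    "superpose",
    "side_chain_centroid",
]

#: Column layout of :class:`TorsionTable`; the last slot is reserved.
TORSION_NAMES = ("phi", "psi", "omega", "chi1", "chi2", "chi3", "chi4", "reserved")

BACKBONE_ATOMS = ("N", "CA", "C", "O")


class MissingAtomError(KeyError):
    """A required atom is absent from a residue."""


@dataclass(frozen=True)
class Topology:
    """Single-chain heavy-atom protein topology.

    Residues are indexed contiguously from 0 internally (1-based only in
    user-facing reports).  Backbone N-CA-C-O connectivity plus inter-residue
    C(i)-N(i+1) peptide bonds are implied.
    """

    chain_id: str
    residue_names: tuple[str, ...]
    atom_names: tuple[str, ...]
    atom_elements: tuple[str, ...]
    atom_residue: np.ndarray  # (n_atoms,) int, residue index of each atom

    def __post_init__(self):
        for name in self.residue_names:
            if name not in chemdata.THREE_TO_ONE:
                raise ValueError(
                    f"unknown residue name {name!r}; supported codes: "
                    + ", ".join(chemdata.STANDARD_RESIDUES)
                )
        res = np.asarray(self.atom_residue, dtype=int)
        object.__setattr__(self, "atom_residue", res)
        if res.shape != (len(self.atom_names),):
            raise ValueError("atom_residue must map every atom to a residue")
        if len(self.residue_names) == 0:
            raise ValueError("topology must contain at least one residue")
        if not np.array_equal(np.unique(res), np.arange(self.n_residues)):
            raise ValueError("residue indices must be contiguous from 0")
        lut = {}
        for i, (name, r) in enumerate(zip(self.atom_names, res)):
            lut[(int(r), name)] = i
        object.__setattr__(self, "_atom_lut", lut)
        for r, name in enumerate(self.residue_names):
            for required in ("N", "CA", "C"):
                if (r, required) not in lut:
                    raise MissingAtomError(
                        f"residue {name} {r + 1} is missing backbone atom {required}"
                    )

    @property
    def n_residues(self) -> int:
        return len(self.residue_names)

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    @property
    def sequence(self) -> str:
        """One-letter amino-acid sequence."""
        return "".join(chemdata.THREE_TO_ONE[n] for n in self.residue_names)

    def atom_index(self, residue: int, atom_name: str) -> int:
        """Flat index of ``atom_name`` in residue ``residue`` (0-based)."""
        try:
            return self._atom_lut[(residue, atom_name)]
        except KeyError:
            raise MissingAtomError(
                f"residue {self.residue_names[residue]} {residue + 1} has no "
                f"atom {atom_name}"
            ) from None

    def has_atom(self, residue: int, atom_name: str) -> bool:
        return (residue, atom_name) in self._atom_lut

    def residue_atom_indices(self, residue: int) -> np.ndarray:
        return np.flatnonzero(self.atom_residue == residue)

    def backbone_indices(self, atom_name: str = "CA") -> np.ndarray:
        """Per-residue flat indices of one backbone atom type."""
        return np.array(
            [self.atom_index(r, atom_name) for r in range(self.n_residues)], dtype=int
        )

    def bonds(self) -> np.ndarray:
        """All heavy-atom bonds as an (n_bonds, 2) index array.

        Intra-residue bonds follow the residue templates; inter-residue
        peptide C(i)-N(i+1) bonds are appended.
        """
        pairs: list[tuple[int, int]] = []
        for r, name in enumerate(self.residue_names):
            tmpl = chemdata.residue_template(name)
            for i, j in tmpl.bonds:
                a = tmpl.atom_names[i]
                b = tmpl.atom_names[j]
                if self.has_atom(r, a) and self.has_atom(r, b):
                    pairs.append((self.atom_index(r, a), self.atom_index(r, b)))
        for r in range(self.n_residues - 1):
            pairs.append((self.atom_index(r, "C"), self.atom_index(r + 1, "N")))
        return np.asarray(pairs, dtype=int)


@dataclass(frozen=True)
class Conformation:
    """One heavy-atom conformation: an (n_atoms, 3) coordinate array in Angstrom."""

    coords: np.ndarray

    def __post_init__(self):
        c = np.asarray(self.coords, dtype=float)
        if c.ndim != 2 or c.shape[1] != 3:
            raise ValueError("coords must have shape (n_atoms, 3)")
        if not np.all(np.isfinite(c)):
            raise ValueError("coords must be finite")
        object.__setattr__(self, "coords", c)

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]


@dataclass
class Ensemble:
    """A topology plus >= 1 conformations, optionally tagged with a temperature (K)."""

    topology: Topology
    frames: list[Conformation]
    temperature: Optional[float] = None
    label: str = ""

    def __post_init__(self):
        if len(self.frames) == 0:
            raise ValueError("ensemble must contain at least one frame")
        for f in self.frames:
            if f.n_atoms != self.topology.n_atoms:
                raise ValueError(
                    f"frame has {f.n_atoms} atoms, topology has "
                    f"{self.topology.n_atoms}"
                )
        if self.temperature is not None and not self.temperature > 0:
            raise ValueError("temperature must be positive (Kelvin)")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def coordinates(self) -> np.ndarray:
        """All frames stacked as (n_frames, n_atoms, 3)."""
        return np.stack([f.coords for f in self.frames])

    def subset(self, frame_indices: Sequence[int], label: str | None = None) -> "Ensemble":
        return Ensemble(
            topology=self.topology,
            frames=[self.frames[i] for i in frame_indices],
            temperature=self.temperature,
            label=self.label if label is None else label,
        )


@dataclass(frozen=True)
class TorsionTable:
    """Per-frame, per-residue torsions (phi, psi, omega, chi1..chi4, reserved).

    ``values`` has shape (n_frames, n_residues, 8) in degrees within
    (-180, 180]; ``valid`` masks chain termini and undefined chi slots.
    """

    values: np.ndarray
    valid: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, float)
        m = np.asarray(self.valid, bool)
        if v.shape != m.shape or v.ndim != 3 or v.shape[2] != 8:
            raise ValueError("values/valid must share shape (frames, residues, 8)")
        if np.any((v[m] <= -180.0) | (v[m] > 180.0)):
            raise ValueError("valid torsions must lie in (-180, 180]")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "valid", m)

    def angle(self, name: str) -> np.ndarray:
        """(frames, residues) view of one torsion type by name."""
        k = TORSION_NAMES.index(name)
        return self.values[:, :, k]

    def mask(self, name: str) -> np.ndarray:
        k = TORSION_NAMES.index(name)
        return self.valid[:, :, k]


@dataclass(frozen=True)
class VdwTable:
    """Element -> van der Waals radius (Angstrom). Default: Bondi radii."""

    radii: dict = field(default_factory=lambda: dict(chemdata.BONDI_RADII))

    def __post_init__(self):
        if any(r <= 0 for r in self.radii.values()):
            raise ValueError("van der Waals radii must be strictly positive")
        for el in ("C", "N", "O", "S"):
            if el not in self.radii:
                raise ValueError(f"radius table must cover element {el}")

    def radius(self, element: str) -> float:
        try:
            return self.radii[element]
        except KeyError:
            raise KeyError(
                f"element {element!r} missing from van der Waals radius table"
            ) from None


def _torsion_index_table(topology: Topology):
    """(L, 8, 4) atom-index table plus (L, 8) validity for all torsions."""
    L = topology.n_residues
    idx = np.zeros((L, 8, 4), dtype=int)
    valid = np.zeros((L, 8), dtype=bool)
    for r in range(L):
        if r > 0:  # phi: C(i-1), N, CA, C
            idx[r, 0] = [
                topology.atom_index(r - 1, "C"),
                topology.atom_index(r, "N"),
                topology.atom_index(r, "CA"),
                topology.atom_index(r, "C"),
            ]
            valid[r, 0] = True
        if r < L - 1:  # psi: N, CA, C, N(i+1); omega: CA, C, N(i+1), CA(i+1)
            idx[r, 1] = [
                topology.atom_index(r, "N"),
                topology.atom_index(r, "CA"),
                topology.atom_index(r, "C"),
                topology.atom_index(r + 1, "N"),
            ]
            valid[r, 1] = True
            idx[r, 2] = [
                topology.atom_index(r, "CA"),
                topology.atom_index(r, "C"),
                topology.atom_index(r + 1, "N"),
                topology.atom_index(r + 1, "CA"),
            ]
            valid[r, 2] = True
        quads = chemdata.CHI_ATOMS[topology.residue_names[r]]
        for k, quad in enumerate(quads):
            if all(topology.has_atom(r, a) for a in quad):
                idx[r, 3 + k] = [topology.atom_index(r, a) for a in quad]
                valid[r, 3 + k] = True
    return idx, valid


def compute_torsions(ensemble: Ensemble) -> TorsionTable:
    """Measure phi/psi/omega/chi1-4 for every frame and residue.

    Returns a :class:`TorsionTable` with the validity mask set per the chain
    termini (phi undefined at residue 1, psi/omega at the last residue) and
    per the chi count of each residue type.
    """
    topo = ensemble.topology
    idx, valid = _torsion_index_table(topo)
    X = ensemble.coordinates()  # (F, A, 3)
    F, L = X.shape[0], topo.n_residues
    values = np.zeros((F, L, 8), dtype=float)
    flat_valid = np.flatnonzero(valid.ravel())
    if flat_valid.size:
        quads = idx.reshape(-1, 4)[flat_valid]  # (T, 4)
        p = X[:, quads, :]  # (F, T, 4, 3)
        ang = dihedral(p[:, :, 0], p[:, :, 1], p[:, :, 2], p[:, :, 3])
        out = values.reshape(F, -1)
        out[:, flat_valid] = ang
    mask = np.broadcast_to(valid[None, :, :], (F, L, 8)).copy()
    return TorsionTable(values=values, valid=mask)


def superpose(
    mobile: Conformation,
    reference: Conformation,
    selection: Iterable[int],
) -> tuple[Conformation, float]:
    """Rigidly superpose ``mobile`` onto ``reference`` over ``selection``.

    Least-squares (Kabsch, proper rotation only).  Returns the transformed
    conformation (all atoms moved) and the minimized RMSD over the selection.
    """
    sel = np.asarray(sorted(set(int(i) for i in selection)), dtype=int)
    if sel.size < 3:
        raise ValueError("superposition needs at least 3 selected atoms")
    if sel.max() >= mobile.n_atoms or sel.max() >= reference.n_atoms:
        raise IndexError("selection exceeds atom count")
    R, t, rmsd = kabsch(mobile.coords[sel], reference.coords[sel])
    return Conformation(apply_rigid(mobile.coords, R, t)), rmsd


def side_chain_centroid(conformation: Conformation, topology: Topology) -> np.ndarray:
    """Per-residue unweighted centroid of side-chain heavy atoms, (L, 3).

    Glycine (no side chain) falls back to the CA position.
    """
    out = np.zeros((topology.n_residues, 3), dtype=float)
    for r in range(topology.n_residues):
        atoms = [
            i
            for i in topology.residue_atom_indices(r)
            if topology.atom_names[i] not in BACKBONE_ATOMS
        ]
        if atoms:
            out[r] = conformation.coords[atoms].mean(axis=0)
        else:
            out[r] = conformation.coords[topology.atom_index(r, "CA")]
    return out
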