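"""Seeded synthetic protein ensembles with known ground truth.

Everything here is built from idealized geometry: backbones are grown by
sequential torsion placement (NeRF) with literature bond lengths/angles, and
side chains are grafted from ideal residue templates and rotated to target
chi values.  Peptide bonds are built at 1.348 A, the reference mean of the
bond-length violation counter, so freshly built chains score zero violations
and zero clashes by construction (clash-free presets).

Generators:

* :func:`build_ideal_chain` -- single-frame ensembles with preset or explicit
  phi/psi (named presets: ``helix`` -57/-47, ``extended`` 180/180).
* :func:`two_state_ensemble` -- folded/unfolded mixtures whose folded
  probability follows a known logistic in temperature; the realized folded
  count is recorded as ground truth.
* :func:`rotamer_ensemble` -- side-chain chi angles drawn from prescribed
  9-bin torus tables, the oracle source for the chi-divergence score.
* :func:`inject_defects` -- deliberate clashes and peptide-bond stretches
  with a manifest of the expected counter increments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import chemdata
from .chemdata import BACKBONE_GEOMETRY as BB
from .core import Conformation, Ensemble, Topology, compute_torsions
from .geometry import dihedral, kabsch, place_atom, rotate_about_axis, wrap_angle

__all__ = [
    "FixtureSpec",
    "make_topology",
    "build_conformation",
    "build_ideal_chain",
    "torsion_jitter_ensemble",
    "two_state_ensemble",
    "rotamer_ensemble",
    "inject_defects",
    "PRESETS",
]

#: Named backbone presets: (phi, psi) in degrees.
PRESETS = {"helix": (-57.0, -47.0), "extended": (180.0, 180.0)}

DEFAULT_CHI = (-60.0, 180.0, 180.0, 180.0)


def make_topology(sequence: str, chain_id: str = "A") -> Topology:
    """Heavy-atom topology for a one-letter sequence, template atom order."""
    names, elements, res_idx, res_names = [], [], [], []
    for r, one in enumerate(sequence):
        if one not in chemdata.ONE_TO_THREE:
            raise ValueError(f"invalid one-letter residue code {one!r}")
        res_name = chemdata.ONE_TO_THREE[one]
        res_names.append(res_name)
        tmpl = chemdata.residue_template(res_name)
        for a, el in zip(tmpl.atom_names, tmpl.elements):
            names.append(a)
            elements.append(el)
            res_idx.append(r)
    return Topology(
        chain_id=chain_id,
        residue_names=tuple(res_names),
        atom_names=tuple(names),
        atom_elements=tuple(elements),
        atom_residue=np.asarray(res_idx, dtype=int),
    )


def _as_per_residue(value, L: int, default: float) -> np.ndarray:
    if value is None:
        return np.full(L, default, dtype=float)
    arr = np.asarray(value, dtype=float)
    if arr.ndim == 0:
        return np.full(L, float(arr))
    if arr.shape != (L,):
        raise ValueError(f"per-residue torsion spec must have length {L}")
    return arr


def build_conformation(
    topology: Topology,
    phi=None,
    psi=None,
    omega=None,
    chi: Optional[Sequence[Optional[Sequence[float]]]] = None,
) -> Conformation:
    """Build heavy-atom coordinates from a torsion specification.

    ``phi``/``psi``/``omega`` are scalars or length-L arrays (degrees);
    ``chi`` is an optional per-residue sequence of chi values (each up to the
    residue's chi count; missing entries fall back to a default rotamer).
    Proline side chains keep their template ring geometry (chi ignored).
    """
    L = topology.n_residues
    phi = _as_per_residue(phi, L, -120.0)
    psi = _as_per_residue(psi, L, 140.0)
    omega = _as_per_residue(omega, L, 180.0)

    coords = np.zeros((topology.n_atoms, 3), dtype=float)
    n_xyz = np.array([0.0, 0.0, 0.0])
    ca_xyz = np.array([BB["bond_N_CA"], 0.0, 0.0])
    th = np.radians(BB["angle_N_CA_C"])
    c_xyz = ca_xyz + BB["bond_CA_C"] * np.array([-np.cos(th), np.sin(th), 0.0])

    bb = np.zeros((L, 3, 3))  # N, CA, C per residue
    bb[0] = [n_xyz, ca_xyz, c_xyz]
    for r in range(1, L):
        n_prev, ca_prev, c_prev = bb[r - 1]
        n_new = place_atom(
            n_prev, ca_prev, c_prev, BB["bond_C_N_build"], BB["angle_CA_C_N"], psi[r - 1]
        )
        ca_new = place_atom(
            ca_prev, c_prev, n_new, BB["bond_N_CA"], BB["angle_C_N_CA"], omega[r - 1]
        )
        c_new = place_atom(
            c_prev, n_new, ca_new, BB["bond_CA_C"], BB["angle_N_CA_C"], phi[r]
        )
        bb[r] = [n_new, ca_new, c_new]

    for r, res_name in enumerate(topology.residue_names):
        n_i = topology.atom_index(r, "N")
        ca_i = topology.atom_index(r, "CA")
        c_i = topology.atom_index(r, "C")
        coords[n_i], coords[ca_i], coords[c_i] = bb[r]
        # Carbonyl O anti to the next amide nitrogen (torsion psi + 180).
        coords[topology.atom_index(r, "O")] = place_atom(
            bb[r, 0], bb[r, 1], bb[r, 2], BB["bond_C_O"], BB["angle_CA_C_O"],
            psi[r] + 180.0,
        )
        _graft_side_chain(topology, coords, r, chi[r] if chi is not None else None)
    return Conformation(coords)


def _graft_side_chain(topology, coords, r, chi_values):
    """Place side-chain atoms of residue r from its ideal template, then set chi."""
    res_name = topology.residue_names[r]
    tmpl = chemdata.residue_template(res_name)
    side = tmpl.side_chain_names
    if not side:
        return
    anchor = ["N", "CA", "C"]
    src = np.array([tmpl.coords[tmpl.index(a)] for a in anchor])
    dst = np.array([coords[topology.atom_index(r, a)] for a in anchor])
    R, t, _ = kabsch(src, dst)
    for a in side:
        coords[topology.atom_index(r, a)] = tmpl.coords[tmpl.index(a)] @ R.T + t
    if res_name == "PRO":
        return  # ring geometry fixed by the template
    quads = chemdata.CHI_ATOMS[res_name]
    targets = list(DEFAULT_CHI[: len(quads)])
    if chi_values is not None:
        for k, v in enumerate(chi_values[: len(quads)]):
            if v is not None:
                targets[k] = float(v)
    for k, quad in enumerate(quads):
        pts = [coords[topology.atom_index(r, a)] for a in quad]
        current = dihedral(*pts)
        # rotating about b->c by +delta decreases the measured torsion by delta
        delta = wrap_angle(current - targets[k])
        moving = chemdata.chi_rotating_atoms(res_name, k)
        idx = [topology.atom_index(r, a) for a in moving]
        b = coords[topology.atom_index(r, quad[1])]
        c = coords[topology.atom_index(r, quad[2])]
        coords[idx] = rotate_about_axis(coords[idx], b, c - b, delta)


def build_ideal_chain(sequence: str, phi_psi_spec="helix", label: str = "") -> Ensemble:
    """One-frame ideal-geometry ensemble with preset or explicit backbone torsions.

    ``phi_psi_spec`` is a preset name (``helix``, ``extended``), a
    ``(phi, psi)`` pair of scalars, or a pair of length-L arrays.
    """
    topo = make_topology(sequence)
    if isinstance(phi_psi_spec, str):
        try:
            phi, psi = PRESETS[phi_psi_spec]
        except KeyError:
            raise ValueError(
                f"unknown preset {phi_psi_spec!r}; choose from {sorted(PRESETS)}"
            ) from None
    else:
        phi, psi = phi_psi_spec
    conf = build_conformation(topo, phi=phi, psi=psi)
    return Ensemble(topology=topo, frames=[conf], label=label or str(phi_psi_spec))


def _native_torsion_spec(topology: Topology, native: Conformation):
    """Extract per-residue phi/psi/omega/chi arrays from a native conformation."""
    ens = Ensemble(topology=topology, frames=[native])
    table = compute_torsions(ens)
    v, m = table.values[0], table.valid[0]
    L = topology.n_residues
    phi = np.where(m[:, 0], v[:, 0], -120.0)
    psi = np.where(m[:, 1], v[:, 1], 140.0)
    omega = np.where(m[:, 2], v[:, 2], 180.0)
    chi = []
    for r in range(L):
        k = chemdata.n_chi(topology.residue_names[r])
        chi.append([v[r, 3 + j] if m[r, 3 + j] else None for j in range(k)])
    return phi, psi, omega, chi


def torsion_jitter_ensemble(
    topology: Topology,
    native: Conformation,
    n_frames: int,
    sigma_deg: float = 5.0,
    seed: int = 0,
) -> Ensemble:
    """Rebuild the native chain with i.i.d. Gaussian torsion noise (degrees)."""
    rng = np.random.default_rng(seed)
    phi, psi, omega, chi = _native_torsion_spec(topology, native)
    frames = []
    for _ in range(n_frames):
        frames.append(
            _jittered_frame(topology, phi, psi, omega, chi, sigma_deg, rng)
        )
    return Ensemble(topology=topology, frames=frames, label="torsion_jitter")


def _jittered_frame(topology, phi, psi, omega, chi, sigma, rng):
    L = topology.n_residues
    jphi = wrap_angle(phi + rng.normal(0.0, sigma, L))
    jpsi = wrap_angle(psi + rng.normal(0.0, sigma, L))
    jchi = [
        [None if c is None else wrap_angle(c + rng.normal(0.0, sigma)) for c in row]
        for row in chi
    ]
    return build_conformation(topology, phi=jphi, psi=jpsi, omega=omega, chi=jchi)


def _random_coil_frame(topology, rng, max_retries: int = 100, clash_budget: int = 5):
    """Self-avoiding (best-effort) random-torsion rebuild."""
    from .integrity import count_heavy_clashes  # deferred: avoids import cycle

    L = topology.n_residues
    best = None
    best_clashes = None
    for _ in range(max_retries):
        phi = rng.uniform(-180.0, 180.0, L)
        psi = rng.uniform(-180.0, 180.0, L)
        chi = [
            list(rng.uniform(-180.0, 180.0, chemdata.n_chi(name)))
            for name in topology.residue_names
        ]
        conf = build_conformation(topology, phi=phi, psi=psi, chi=chi)
        c = count_heavy_clashes(conf, topology)
        if best is None or c < best_clashes:
            best, best_clashes = conf, c
        if c <= clash_budget:
            return best
    return best


def two_state_ensemble(
    topology: Topology,
    native: Conformation,
    temperature: float,
    true_tm: float,
    true_k: float,
    n_frames: int,
    seed: int = 0,
    jitter_sigma: float = 5.0,
) -> tuple[Ensemble, dict]:
    """Two-state folded/unfolded mixture at a given temperature.

    Each frame is independently folded with probability
    ``p(T) = 1 / (1 + exp((T - true_tm) / true_k))`` -- a logistic melting
    curve decreasing in T.  Folded frames are the native rebuilt with
    ``jitter_sigma`` torsion noise; unfolded frames are randomized-torsion
    self-avoiding rebuilds.  Returns the ensemble and a ground-truth manifest
    with the realized folded count.
    """
    if not true_k > 0:
        raise ValueError("true_k must be positive")
    rng = np.random.default_rng(seed)
    p_folded = 1.0 / (1.0 + np.exp((temperature - true_tm) / true_k))
    folded_flags = rng.random(n_frames) < p_folded
    phi, psi, omega, chi = _native_torsion_spec(topology, native)
    frames = []
    for folded in folded_flags:
        if folded:
            frames.append(
                _jittered_frame(topology, phi, psi, omega, chi, jitter_sigma, rng)
            )
        else:
            frames.append(_random_coil_frame(topology, rng))
    ens = Ensemble(
        topology=topology,
        frames=frames,
        temperature=float(temperature),
        label=f"two_state_T{temperature:g}",
    )
    manifest = {
        "temperature": float(temperature),
        "p_folded": float(p_folded),
        "n_folded": int(folded_flags.sum()),
        "n_frames": int(n_frames),
        "folded_fraction": float(folded_flags.mean()),
        "true_tm": float(true_tm),
        "true_k": float(true_k),
    }
    return ens, manifest


_BIN_LOW = np.array([-120.0, 0.0, 120.0])  # lower edges of the 3 torus bins


def _sample_angle_in_bin(bin_index: int, rng) -> float:
    lo = _BIN_LOW[bin_index]
    return float(wrap_angle(rng.uniform(lo, lo + 120.0)))


def rotamer_ensemble(
    sequence: str,
    bin_tables: dict,
    n_frames: int,
    seed: int = 0,
    backbone: str = "extended",
) -> Ensemble:
    """Ensemble whose chi-pair distributions follow prescribed 9-bin tables.

    ``bin_tables`` maps ``(residue_index, pair)`` -- pair one of ``(1, 2)``,
    ``(2, 3)``, ``(3, 4)`` -- to a 3x3 probability table over the torus bins
    with edges at -120/0/120 degrees (rows: first chi of the pair).  Pairs
    without a table default to uniform.  Consecutive pairs share a chi angle,
    so the second pair of a triple is sampled conditionally on the bin already
    drawn for the shared angle; tables should therefore have consistent shared
    marginals for the empirical frequencies to converge to them.
    """
    topo = make_topology(sequence)
    rng = np.random.default_rng(seed)
    phi, psi = PRESETS[backbone]
    for table in bin_tables.values():
        t = np.asarray(table, float)
        if t.shape != (3, 3) or not np.isclose(t.sum(), 1.0, atol=1e-9):
            raise ValueError("each bin table must be 3x3 and sum to 1")
    frames = []
    for _ in range(n_frames):
        chi_all = []
        for r, res_name in enumerate(topo.residue_names):
            k = chemdata.n_chi(res_name)
            chis = [None] * k
            prev_bin = None
            for p in range(k - 1):
                pair = (p + 1, p + 2)
                table = np.asarray(
                    bin_tables.get((r, pair), np.full((3, 3), 1.0 / 9.0)), float
                )
                if prev_bin is None:
                    cell = rng.choice(9, p=(table / table.sum()).ravel())
                    b1, b2 = divmod(int(cell), 3)
                    chis[p] = _sample_angle_in_bin(b1, rng)
                else:
                    row = table[prev_bin]
                    if row.sum() <= 0:
                        row = table.sum(axis=0)
                    if row.sum() <= 0:
                        row = np.full(3, 1.0 / 3.0)
                    b2 = int(rng.choice(3, p=row / row.sum()))
                chis[p + 1] = _sample_angle_in_bin(b2, rng)
                prev_bin = b2
            if k == 1:
                chis[0] = _sample_angle_in_bin(int(rng.choice(3)), rng)
            chi_all.append(chis)
        frames.append(build_conformation(topo, phi=phi, psi=psi, chi=chi_all))
    return Ensemble(topology=topo, frames=frames, label="rotamer")


def _sphere_directions(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit vectors (Fibonacci sphere)."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * k
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


def inject_defects(
    ensemble: Ensemble,
    clash_specs: Sequence[tuple] = (),
    stretch_specs: Sequence[tuple] = (),
) -> tuple[Ensemble, dict]:
    """Inject steric clashes and peptide-bond stretches into every frame.

    ``clash_specs``: tuples ``(res_i, atom_i, res_j, atom_j, distance)``;
    atom_j is translated along the i->j line to the target distance.  The
    pair must span non-adjacent residues (|res_i - res_j| >= 2), otherwise
    the clash counter would ignore it and an error is raised.
    ``stretch_specs``: tuples ``(res_index, length)``; the C(res)-N(res+1)
    peptide bond is set to ``length`` by rigidly translating all downstream
    residues along the bond axis.

    Returns the modified ensemble and a manifest of expected per-frame
    counter increments.
    """
    from .core import VdwTable
    from .chemdata import BONDI_RADII

    topo = ensemble.topology
    vdw = VdwTable()
    expected_clashes = 0
    for res_i, atom_i, res_j, atom_j, distance in clash_specs:
        if abs(res_i - res_j) < 2:
            raise ValueError(
                "clash spec targets adjacent residues; such pairs are not counted"
            )
        r_sum = vdw.radius(topo.atom_elements[topo.atom_index(res_i, atom_i)]) + \
            vdw.radius(topo.atom_elements[topo.atom_index(res_j, atom_j)])
        if distance < 0.5 * r_sum:
            expected_clashes += 1
    expected_violations = sum(
        1 for _res, length in stretch_specs if abs(length - 1.348) / 0.029 >= 3.0
    )

    new_frames = []
    for frame in ensemble.frames:
        c = frame.coords.copy()
        for res_i, atom_i, res_j, atom_j, distance in clash_specs:
            ia = topo.atom_index(res_i, atom_i)
            ja = topo.atom_index(res_j, atom_j)
            # place atom_j on the sphere of radius `distance` around atom_i in
            # the direction with maximal clearance from every other atom, so
            # the injection creates exactly the intended clash pair
            others = np.delete(np.arange(topo.n_atoms), [ia, ja])
            best_pos, best_clearance = None, -np.inf
            for u in _sphere_directions(64):
                pos = c[ia] + u * distance
                clearance = np.min(np.linalg.norm(c[others] - pos, axis=1))
                if clearance > best_clearance:
                    best_clearance = clearance
                    best_pos = pos
            c[ja] = best_pos
        for res, length in stretch_specs:
            if res >= topo.n_residues - 1:
                raise ValueError("stretch spec beyond last peptide bond")
            ci = topo.atom_index(res, "C")
            ni = topo.atom_index(res + 1, "N")
            u = c[ni] - c[ci]
            u = u / np.linalg.norm(u)
            shift = u * (length - np.linalg.norm(c[ni] - c[ci]))
            downstream = np.flatnonzero(topo.atom_residue > res)
            c[downstream] += shift
        new_frames.append(Conformation(c))
    out = Ensemble(
        topology=topo,
        frames=new_frames,
        temperature=ensemble.temperature,
        label=ensemble.label + "+defects",
    )
    manifest = {
        "expected_clash_increment": expected_clashes,
        "expected_violation_increment": expected_violations,
    }
    return out, manifest


@dataclass
class FixtureSpec:
    """Declarative fixture request (used by the ``synth`` CLI subcommand)."""

    sequence: str
    n_frames: int = 1
    seed: int = 0
    mode: str = "helix"  # rigid | torsion_jitter | two_state | rotamer_categorical | extended | helix
    parameters: dict = field(default_factory=dict)

    def build(self) -> tuple[Ensemble, dict]:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        p = dict(self.parameters)
        if self.mode in ("helix", "extended"):
            ens = build_ideal_chain(self.sequence, self.mode)
            if self.n_frames > 1:
                ens = Ensemble(
                    topology=ens.topology,
                    frames=[ens.frames[0]] * self.n_frames,
                    label=self.mode,
                )
            return ens, {"mode": self.mode}
        if self.mode == "rigid":
            base = build_ideal_chain(self.sequence, p.get("preset", "helix"))
            return (
                Ensemble(
                    topology=base.topology,
                    frames=[base.frames[0]] * self.n_frames,
                    label="rigid",
                ),
                {"mode": "rigid"},
            )
        if self.mode == "torsion_jitter":
            base = build_ideal_chain(self.sequence, p.get("preset", "helix"))
            ens = torsion_jitter_ensemble(
                base.topology,
                base.frames[0],
                self.n_frames,
                sigma_deg=p.get("sigma", 5.0),
                seed=self.seed,
            )
            return ens, {"mode": "torsion_jitter", "sigma": p.get("sigma", 5.0)}
        if self.mode == "two_state":
            base = build_ideal_chain(self.sequence, p.get("preset", "helix"))
            ens, manifest = two_state_ensemble(
                base.topology,
                base.frames[0],
                temperature=p.get("temperature", 400.0),
                true_tm=p.get("true_tm", 400.0),
                true_k=p.get("true_k", 20.0),
                n_frames=self.n_frames,
                seed=self.seed,
            )
            manifest["mode"] = "two_state"
            return ens, manifest
        if self.mode == "rotamer_categorical":
            tables = {
                (int(r), tuple(pair)): np.asarray(t, float)
                for (r, pair), t in p.get("bin_tables", {}).items()
            }
            ens = rotamer_ensemble(
                self.sequence, tables, self.n_frames, seed=self.seed,
                backbone=p.get("backbone", "extended"),
            )
            return ens, {"mode": "rotamer_categorical"}
        raise ValueError(f"unknown fixture mode {self.mode!r}")
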