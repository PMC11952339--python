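"""Stereochemical integrity counters and restrained clash relaxation.

Two counters mirror common ensemble-quality checks on generated structures:

* heavy-atom clashes: pairs of heavy atoms from non-adjacent residues
  (|i - j| >= 2) closer than half the sum of their van der Waals radii
  (strict ``<``);
* peptide-bond violations: inter-residue C(i)-N(i+1) bonds whose length
  deviates from the reference mean b_m = 1.348 A by at least 3 reference
  standard deviations b_s = 0.029 A (two-sided, inclusive ``>=``).

:func:`relax` removes clashes with minimal perturbation: an idealized bonded
energy (harmonic bonds and angles, peptide-omega planarity, carbonyl
planarity impropers) plus harmonic restraints tethering phi/psi/chi1-4
(circular difference) and adjacent CA-CA distances to their input values,
plus a soft half-quadratic repulsion between non-adjacent heavy atoms,
minimized per frame with an L-BFGS-class optimizer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import minimize
from scipy.spatial import cKDTree

from . import chemdata
from .chemdata import BACKBONE_GEOMETRY as BB
from .core import Conformation, Ensemble, Topology, VdwTable
from .geometry import bond_angle, dihedral

__all__ = [
    "PEPTIDE_BOND_MEAN",
    "PEPTIDE_BOND_SD",
    "IntegrityReport",
    "RelaxConfig",
    "count_heavy_clashes",
    "count_peptide_violations",
    "find_heavy_clashes",
    "integrity_report",
    "relax",
]

PEPTIDE_BOND_MEAN = 1.348  # Angstrom, reference mean for C-N peptide bonds
PEPTIDE_BOND_SD = 0.029  # Angstrom, reference standard deviation
VIOLATION_Z = 3.0


def _pair_candidates(coords: np.ndarray, cutoff: float) -> np.ndarray:
    """Unique index pairs within ``cutoff`` (KD-tree; includes bonded pairs)."""
    tree = cKDTree(coords)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    return pairs.reshape(-1, 2)


def find_heavy_clashes(
    conformation: Conformation,
    topology: Topology,
    radii: Optional[VdwTable] = None,
) -> list[tuple[int, int, float]]:
    """All clashing heavy-atom pairs as (atom_i, atom_j, distance)."""
    radii = radii or VdwTable()
    r = np.array([radii.radius(el) for el in topology.atom_elements])
    coords = conformation.coords
    max_thresh = 0.5 * (2 * r.max())
    pairs = _pair_candidates(coords, max_thresh)
    if pairs.size == 0:
        return []
    res = topology.atom_residue
    sep = np.abs(res[pairs[:, 0]] - res[pairs[:, 1]])
    pairs = pairs[sep >= 2]
    if pairs.size == 0:
        return []
    d = np.linalg.norm(coords[pairs[:, 0]] - coords[pairs[:, 1]], axis=1)
    thresh = 0.5 * (r[pairs[:, 0]] + r[pairs[:, 1]])
    hit = d < thresh
    return [
        (int(i), int(j), float(dist))
        for (i, j), dist in zip(pairs[hit], d[hit])
    ]


def count_heavy_clashes(
    conformation: Conformation,
    topology: Topology,
    radii: Optional[VdwTable] = None,
) -> int:
    """Number of heavy-atom clash pairs (non-adjacent residues, d < half vdW sum)."""
    return len(find_heavy_clashes(conformation, topology, radii))


def count_peptide_violations(conformation: Conformation, topology: Topology) -> int:
    """Number of peptide C(i)-N(i+1) bonds with |b - b_m| / b_s >= 3."""
    L = topology.n_residues
    if L < 2:
        return 0
    c_idx = np.array([topology.atom_index(r, "C") for r in range(L - 1)])
    n_idx = np.array([topology.atom_index(r + 1, "N") for r in range(L - 1)])
    b = np.linalg.norm(
        conformation.coords[c_idx] - conformation.coords[n_idx], axis=1
    )
    z = np.abs(b - PEPTIDE_BOND_MEAN) / PEPTIDE_BOND_SD
    return int(np.sum(z >= VIOLATION_Z))


@dataclass(frozen=True)
class IntegrityReport:
    """Per-frame and mean clash / bond-violation counts for an ensemble."""

    clashes_per_frame: np.ndarray
    violations_per_frame: np.ndarray
    worst_offenders: list  # (frame, atom_i, atom_j, distance)

    @property
    def mean_clashes(self) -> float:
        return float(np.mean(self.clashes_per_frame))

    @property
    def mean_violations(self) -> float:
        return float(np.mean(self.violations_per_frame))


def integrity_report(
    ensemble: Ensemble, radii: Optional[VdwTable] = None, n_offenders: int = 10
) -> IntegrityReport:
    """Clash and peptide-bond violation statistics over all frames."""
    clashes, violations, offenders = [], [], []
    for f, frame in enumerate(ensemble.frames):
        hits = find_heavy_clashes(frame, ensemble.topology, radii)
        clashes.append(len(hits))
        violations.append(count_peptide_violations(frame, ensemble.topology))
        offenders.extend((f, i, j, d) for i, j, d in hits)
    offenders.sort(key=lambda t: t[3])
    return IntegrityReport(
        clashes_per_frame=np.asarray(clashes, float),
        violations_per_frame=np.asarray(violations, float),
        worst_offenders=offenders[:n_offenders],
    )


@dataclass
class RelaxConfig:
    """Tunable parameters of the restrained relaxation.

    Force constants are in arbitrary energy units per squared deviation
    (Angstrom or degree); only their ratios matter for the minimizer.
    """

    max_iterations: int = 200
    force_tolerance: float = 1e-3
    restraint_k_torsion: float = 0.02  # energy / deg^2
    restraint_k_ca: float = 20.0  # energy / A^2
    repulsion_enabled: bool = True
    repulsion_scale: float = 0.8  # fraction of the vdW-sum used as soft floor
    repulsion_k: float = 60.0  # energy / A^2
    bond_k: float = 400.0  # energy / A^2
    angle_k: float = 60.0  # energy / rad^2
    planarity_k: float = 30.0  # energy / rad^2

    def __post_init__(self):
        for name in (
            "restraint_k_torsion", "restraint_k_ca", "repulsion_k",
            "bond_k", "angle_k", "planarity_k",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 < self.repulsion_scale < 1.0:
            raise ValueError("repulsion_scale must be in (0, 1)")


# ---------------------------------------------------------------------------
# Energy terms with analytic gradients (vectorized over term lists).
# ---------------------------------------------------------------------------


def _bond_energy(x, idx, r0, k):
    d = x[idx[:, 0]] - x[idx[:, 1]]
    dist = np.linalg.norm(d, axis=1)
    dev = dist - r0
    e = np.sum(k * dev**2)
    g = np.zeros_like(x)
    coef = (2.0 * k * dev / np.where(dist == 0, 1.0, dist))[:, None] * d
    np.add.at(g, idx[:, 0], coef)
    np.add.at(g, idx[:, 1], -coef)
    return e, g


def _angle_energy(x, idx, theta0, k):
    p0, p1, p2 = x[idx[:, 0]], x[idx[:, 1]], x[idx[:, 2]]
    u = p0 - p1
    v = p2 - p1
    nu = np.linalg.norm(u, axis=1)
    nv = np.linalg.norm(v, axis=1)
    uh = u / nu[:, None]
    vh = v / nv[:, None]
    c = np.clip(np.sum(uh * vh, axis=1), -1.0, 1.0)
    theta = np.arccos(c)
    s = np.sqrt(np.maximum(1.0 - c**2, 1e-12))
    dev = theta - theta0
    e = np.sum(k * dev**2)
    dtheta_dp0 = (c[:, None] * uh - vh) / (nu * s)[:, None]
    dtheta_dp2 = (c[:, None] * vh - uh) / (nv * s)[:, None]
    dtheta_dp1 = -(dtheta_dp0 + dtheta_dp2)
    coef = (2.0 * k * dev)[:, None]
    g = np.zeros_like(x)
    np.add.at(g, idx[:, 0], coef * dtheta_dp0)
    np.add.at(g, idx[:, 1], coef * dtheta_dp1)
    np.add.at(g, idx[:, 2], coef * dtheta_dp2)
    return e, g


def _dihedral_and_grad(x, idx):
    """Torsion angles (radians) and gradients w.r.t. the four points."""
    p0, p1, p2, p3 = (x[idx[:, i]] for i in range(4))
    b1 = p1 - p0
    b2 = p2 - p1
    b3 = p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2, axis=1)
    m1 = np.cross(n1, b2 / nb2[:, None])
    xx = np.sum(n1 * n2, axis=1)
    yy = np.sum(m1 * n2, axis=1)
    phi = np.arctan2(yy, xx)
    n1sq = np.sum(n1 * n1, axis=1)
    n2sq = np.sum(n2 * n2, axis=1)
    # near-collinear quadruples have an ill-defined torsion whose harmonic
    # force diverges; drop their force instead of letting it explode
    b1sq = np.sum(b1 * b1, axis=1)
    b3sq = np.sum(b3 * b3, axis=1)
    degenerate = (n1sq < 1e-6 * b1sq * nb2**2) | (n2sq < 1e-6 * b3sq * nb2**2)
    dphi_dp0 = (nb2 / np.maximum(n1sq, 1e-12))[:, None] * n1
    dphi_dp3 = -(nb2 / np.maximum(n2sq, 1e-12))[:, None] * n2
    dphi_dp0[degenerate] = 0.0
    dphi_dp3[degenerate] = 0.0
    a = np.sum(b1 * b2, axis=1) / nb2**2
    b = np.sum(b3 * b2, axis=1) / nb2**2
    dphi_dp1 = -(1.0 + a)[:, None] * dphi_dp0 + b[:, None] * dphi_dp3
    dphi_dp2 = a[:, None] * dphi_dp0 - (1.0 + b)[:, None] * dphi_dp3
    return phi, (dphi_dp0, dphi_dp1, dphi_dp2, dphi_dp3)


def _torsion_restraint_energy(x, idx, phi0, k):
    """Harmonic on the circular difference to phi0 (radians)."""
    phi, grads = _dihedral_and_grad(x, idx)
    dev = np.arctan2(np.sin(phi - phi0), np.cos(phi - phi0))
    e = np.sum(k * dev**2)
    coef = (2.0 * k * dev)[:, None]
    g = np.zeros_like(x)
    for col, dg in enumerate(grads):
        np.add.at(g, idx[:, col], coef * dg)
    return e, g


def _repulsion_energy(x, pairs, floor, k):
    if len(pairs) == 0:
        return 0.0, np.zeros_like(x)
    d = x[pairs[:, 0]] - x[pairs[:, 1]]
    dist = np.linalg.norm(d, axis=1)
    gap = floor - dist
    act = gap > 0
    e = np.sum(k * gap[act] ** 2)
    g = np.zeros_like(x)
    if np.any(act):
        coef = (-2.0 * k * gap[act] / dist[act])[:, None] * d[act]
        np.add.at(g, pairs[act, 0], coef)
        np.add.at(g, pairs[act, 1], -coef)
    return e, g


class _RelaxProblem:
    """Precomputed term lists for one topology + one input frame."""

    def __init__(self, topology: Topology, x0: np.ndarray, config: RelaxConfig,
                 radii: VdwTable):
        self.cfg = config
        self.topology = topology
        bonds = topology.bonds()
        # Equilibrium bond lengths: template geometry for intra-residue bonds,
        # literature C-N for peptide bonds.
        r0 = []
        ref = _template_coords(topology)
        std_bb = {
            frozenset(("N", "CA")): BB["bond_N_CA"],
            frozenset(("CA", "C")): BB["bond_CA_C"],
            frozenset(("C", "O")): BB["bond_C_O"],
        }
        for i, j in bonds:
            if topology.atom_residue[i] != topology.atom_residue[j]:
                r0.append(BB["bond_C_N_eq"])
                continue
            key = frozenset((topology.atom_names[i], topology.atom_names[j]))
            r0.append(
                std_bb.get(key) or float(np.linalg.norm(ref[i] - ref[j]))
            )
        self.bonds = bonds
        self.bond_r0 = np.asarray(r0)

        self.angles, self.angle_theta0 = _angle_terms(topology, ref)
        self.planar_idx, self.planar_phi0 = _planarity_terms(topology, x0)
        self.restraint_idx, self.restraint_phi0 = _torsion_restraints(topology, x0)

        L = topology.n_residues
        ca = topology.backbone_indices("CA")
        self.ca_pairs = np.column_stack([ca[:-1], ca[1:]]) if L > 1 else np.zeros((0, 2), int)
        self.ca_r0 = np.linalg.norm(
            x0[self.ca_pairs[:, 0]] - x0[self.ca_pairs[:, 1]], axis=1
        ) if L > 1 else np.zeros(0)

        r = np.array([radii.radius(el) for el in topology.atom_elements])
        if config.repulsion_enabled:
            cutoff = config.repulsion_scale * 2 * r.max() + 2.0
            pairs = _pair_candidates(x0, cutoff)
            if pairs.size:
                sep = np.abs(
                    topology.atom_residue[pairs[:, 0]]
                    - topology.atom_residue[pairs[:, 1]]
                )
                pairs = pairs[sep >= 2]
            self.rep_pairs = pairs
            self.rep_floor = config.repulsion_scale * (
                r[pairs[:, 0]] + r[pairs[:, 1]]
            ) if pairs.size else np.zeros(0)
        else:
            self.rep_pairs = np.zeros((0, 2), int)
            self.rep_floor = np.zeros(0)

    def energy_grad(self, flat: np.ndarray):
        x = flat.reshape(-1, 3)
        cfg = self.cfg
        e, g = _bond_energy(x, self.bonds, self.bond_r0, cfg.bond_k)
        e2, g2 = _angle_energy(x, self.angles, self.angle_theta0, cfg.angle_k)
        e += e2
        g += g2
        if len(self.planar_idx):
            e3, g3 = _torsion_restraint_energy(
                x, self.planar_idx, self.planar_phi0, cfg.planarity_k
            )
            e += e3
            g += g3
        if len(self.restraint_idx):
            k_rad = cfg.restraint_k_torsion * (180.0 / np.pi) ** 2
            e4, g4 = _torsion_restraint_energy(
                x, self.restraint_idx, self.restraint_phi0, k_rad
            )
            e += e4
            g += g4
        if len(self.ca_pairs):
            e5, g5 = _bond_energy(x, self.ca_pairs, self.ca_r0, cfg.restraint_k_ca)
            e += e5
            g += g5
        e6, g6 = _repulsion_energy(x, self.rep_pairs, self.rep_floor, cfg.repulsion_k)
        e += e6
        g += g6
        return e, g.ravel()


def _template_coords(topology: Topology) -> np.ndarray:
    """Ideal-geometry reference coordinates, residue templates side by side."""
    out = np.zeros((topology.n_atoms, 3))
    for r, name in enumerate(topology.residue_names):
        tmpl = chemdata.residue_template(name)
        for i in topology.residue_atom_indices(r):
            a = topology.atom_names[i]
            if a in tmpl.atom_names:
                out[i] = tmpl.coords[tmpl.index(a)]
    return out


def _angle_terms(topology: Topology, ref: np.ndarray):
    """All bonded triples with template equilibrium angles (radians)."""
    bonds = topology.bonds()
    adjacency: dict[int, list[int]] = {}
    for i, j in bonds:
        adjacency.setdefault(int(i), []).append(int(j))
        adjacency.setdefault(int(j), []).append(int(i))
    triples = []
    for center, nbrs in adjacency.items():
        nbrs = sorted(nbrs)
        for a in range(len(nbrs)):
            for b in range(a + 1, len(nbrs)):
                triples.append((nbrs[a], center, nbrs[b]))
    idx = np.asarray(triples, int).reshape(-1, 3)
    theta0 = []
    res = topology.atom_residue
    names = topology.atom_names
    std = {
        ("CA", "C", "N"): BB["angle_CA_C_N"],
        ("C", "N", "CA"): BB["angle_C_N_CA"],
        ("O", "C", "N"): BB["angle_O_C_N"],
    }
    # backbone equilibria use the same literature values as the rest of the
    # package's idealized geometry (template side chains, standard backbone)
    intra_std = {
        ("N", "CA", "C"): BB["angle_N_CA_C"],
        ("CA", "C", "O"): BB["angle_CA_C_O"],
    }
    for i, c, j in idx:
        same_res = res[i] == res[c] == res[j]
        if same_res:
            key = (names[i], names[c], names[j])
            deg = intra_std.get(key) or intra_std.get(key[::-1])
            if deg is not None:
                theta0.append(np.radians(deg))
            else:
                theta0.append(np.radians(bond_angle(ref[i], ref[c], ref[j])))
        else:
            key = (names[i], names[c], names[j])
            deg = std.get(key) or std.get(key[::-1]) or 120.0
            theta0.append(np.radians(deg))
    return idx, np.asarray(theta0)


def _planarity_terms(topology: Topology, x0: np.ndarray):
    """Peptide omega (kept at nearest of 0/180) and carbonyl impropers."""
    idx, phi0 = [], []
    L = topology.n_residues
    for r in range(L - 1):
        quad = [
            topology.atom_index(r, "CA"),
            topology.atom_index(r, "C"),
            topology.atom_index(r + 1, "N"),
            topology.atom_index(r + 1, "CA"),
        ]
        omega = dihedral(*(x0[q] for q in quad))
        idx.append(quad)
        phi0.append(0.0 if abs(omega) < 90.0 else np.pi)
        # improper keeping O in the CA-C-N(+1) plane
        quad_o = [
            topology.atom_index(r, "CA"),
            topology.atom_index(r + 1, "N"),
            topology.atom_index(r, "C"),
            topology.atom_index(r, "O"),
        ]
        idx.append(quad_o)
        phi0.append(np.pi)
    return np.asarray(idx, int).reshape(-1, 4), np.asarray(phi0)


def _torsion_restraints(topology: Topology, x0: np.ndarray):
    """phi/psi/chi quadruples with their input-frame values (radians)."""
    from .core import _torsion_index_table

    idx_tab, valid = _torsion_index_table(topology)
    quads = []
    slots = [0, 1] + [3 + k for k in range(4)]  # phi, psi, chi1..chi4
    for r in range(topology.n_residues):
        for s in slots:
            if valid[r, s]:
                quads.append(idx_tab[r, s])
    idx = np.asarray(quads, int).reshape(-1, 4)
    if len(idx) == 0:
        return idx, np.zeros(0)
    phi0 = np.radians(
        dihedral(x0[idx[:, 0]], x0[idx[:, 1]], x0[idx[:, 2]], x0[idx[:, 3]])
    )
    return idx, phi0


def relax(
    ensemble: Ensemble,
    config: Optional[RelaxConfig] = None,
    radii: Optional[VdwTable] = None,
) -> tuple[Ensemble, list[dict]]:
    """Restrained per-frame energy minimization removing heavy clashes.

    Returns the relaxed ensemble and per-frame diagnostics (clashes before and
    after, CA RMSD shift, iterations, final energy, converged flag).  Frames
    whose energy or gradient turns non-finite are returned unmodified with a
    diagnostic.
    """
    config = config or RelaxConfig()
    radii = radii or VdwTable()
    topo = ensemble.topology
    ca = topo.backbone_indices("CA")
    out_frames, diagnostics = [], []
    for frame in ensemble.frames:
        x0 = frame.coords
        before = count_heavy_clashes(frame, topo, radii)
        problem = _RelaxProblem(topo, x0, config, radii)
        opts = {
            "maxiter": config.max_iterations,
            "gtol": config.force_tolerance,
            "ftol": 1e-12,
        }
        try:
            start = x0.ravel()
            # stage 1: heal grossly stretched bonds (> 20% deviation) by
            # moving only the atoms of those bonds, with the nonbonded push
            # off -- otherwise the huge bond force drags whole groups out of
            # their restrained torsions before the geometry is sane again
            d = np.linalg.norm(
                x0[problem.bonds[:, 0]] - x0[problem.bonds[:, 1]], axis=1
            )
            bad = np.abs(d - problem.bond_r0) / problem.bond_r0 > 0.2
            if np.any(bad):
                # move only the distal (lower-connectivity) end of each bad
                # bond: healing then proceeds radially and leaves the
                # restrained torsions of the rest of the group untouched
                degree = np.bincount(
                    problem.bonds.ravel(), minlength=topo.n_atoms
                )
                moving = np.zeros(topo.n_atoms, dtype=bool)
                for i, j in problem.bonds[bad]:
                    moving[j if degree[j] <= degree[i] else i] = True
                rep_pairs, rep_floor = problem.rep_pairs, problem.rep_floor
                problem.rep_pairs = np.zeros((0, 2), int)
                problem.rep_floor = np.zeros(0)
                mask = np.repeat(moving, 3).astype(float)

                def masked(flat):
                    e, g = problem.energy_grad(flat)
                    return e, g * mask

                pre = minimize(
                    masked, start, jac=True, method="L-BFGS-B", options=opts
                )
                if np.all(np.isfinite(pre.x)):
                    start = pre.x
                problem.rep_pairs, problem.rep_floor = rep_pairs, rep_floor
            res = minimize(
                problem.energy_grad, start, jac=True, method="L-BFGS-B",
                options=opts,
            )
            ok = np.all(np.isfinite(res.x)) and np.isfinite(res.fun)
        except (FloatingPointError, ValueError):
            ok = False
        if not ok:
            out_frames.append(frame)
            diagnostics.append(
                {
                    "clashes_before": before,
                    "clashes_after": before,
                    "ca_rmsd_shift": 0.0,
                    "iterations": 0,
                    "energy": float("nan"),
                    "converged": False,
                    "skipped": True,
                }
            )
            continue
        new = Conformation(res.x.reshape(-1, 3))
        after = count_heavy_clashes(new, topo, radii)
        shift = float(
            np.sqrt(np.mean(np.sum((new.coords[ca] - x0[ca]) ** 2, axis=1)))
        )
        out_frames.append(new)
        diagnostics.append(
            {
                "clashes_before": before,
                "clashes_after": after,
                "ca_rmsd_shift": shift,
                "iterations": int(res.nit),
                "energy": float(res.fun),
                "converged": bool(res.success or res.nit >= 1),
                "skipped": False,
            }
        )
    relaxed = Ensemble(
        topology=topo,
        frames=out_frames,
        temperature=ensemble.temperature,
        label=ensemble.label + "+relaxed",
    )
    return relaxed, diagnostics
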