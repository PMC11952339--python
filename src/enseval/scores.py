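"""Ensemble-comparison scores: side-chain torsion divergence, native-contact
foldedness (Q / folded-state fraction) and secondary-structure preservation.

The side-chain score is the mean Jensen-Shannon divergence (natural log)
between 9-bin joint histograms of consecutive chi-angle pairs -- (1,2), (2,3),
(3,4) per the residue's chi count -- discretized on the torus with bin edges
at -120/0/120 degrees per axis.  It ranges from 0 (identical rotamer
statistics) to ln 2 (disjoint).

Foldedness follows the soft native-contact count

    Q(x) = (1/N_contacts) * sum_ij 1 / (1 + exp(beta * (d_ij - lambda * d0_ij)))

with beta = 5.0 1/A and lambda = 1.2, over all residue pairs at least 3 apart
in sequence whose shortest native heavy-atom distance d0 is <= 10 A.  The
folded-state fraction (FSF) of an ensemble is the fraction of frames with
Q > 0.6.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from . import chemdata
from .core import Conformation, Ensemble, Topology, compute_torsions
from .dssp import assign_sse

__all__ = [
    "Q_BETA",
    "Q_LAMBDA",
    "Q_THRESHOLD",
    "CONTACT_D0_MAX",
    "CONTACT_MIN_SEPARATION",
    "ChiPairHistogram",
    "NativeContactSet",
    "NativeSSE",
    "jsd",
    "chi_bin_index",
    "chi_pair_histograms",
    "chijsd",
    "native_sse",
    "ssep",
    "native_contacts",
    "contact_distances",
    "q_fraction",
    "q_series",
    "folded_state_fraction",
]

Q_BETA = 5.0  # 1/Angstrom, steepness of the contact switch
Q_LAMBDA = 1.2  # tolerance factor on the native distance
Q_THRESHOLD = 0.6  # frames with Q above this count as folded
CONTACT_D0_MAX = 10.0  # Angstrom, inclusive cap on native contact distances
CONTACT_MIN_SEPARATION = 3  # |i - j| >= 3 in sequence

CHI_PAIRS = ((1, 2), (2, 3), (3, 4))


# ---------------------------------------------------------------------------
# Jensen-Shannon divergence and chi-pair histograms
# ---------------------------------------------------------------------------


def jsd(p, q) -> float:
    """Jensen-Shannon divergence (natural log) between two probability vectors.

    Symmetric, bounded in [0, ln 2]; the convention 0 * ln 0 = 0 applies, so
    zero bins are handled without pseudocounts.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("p and q must have the same shape")
    for name, v in (("p", p), ("q", q)):
        if np.any(v < 0):
            raise ValueError(f"{name} has negative entries")
        if abs(v.sum() - 1.0) > 1e-9:
            raise ValueError(f"{name} does not sum to 1 (got {v.sum()!r})")
    m = 0.5 * (p + q)

    def _kl(a, b):
        mask = a > 0
        return float(np.sum(a[mask] * np.log(a[mask] / b[mask])))

    return 0.5 * _kl(p.ravel(), m.ravel()) + 0.5 * _kl(q.ravel(), m.ravel())


def chi_bin_index(angle_deg) -> np.ndarray:
    """Map chi angles (degrees) to torus bin 0/1/2 with edges at -120/0/120.

    Values outside [-120, 240) wrap around the circle, so -180..-120 lands in
    the [120, 240) bin.
    """
    a = np.mod(np.asarray(angle_deg, dtype=float) + 120.0, 360.0)
    return np.clip((a // 120.0).astype(int), 0, 2)


@dataclass(frozen=True)
class ChiPairHistogram:
    """3x3 count table of one residue's (chi_j, chi_k) pair over an ensemble."""

    residue_index: int
    pair: tuple[int, int]
    counts: np.ndarray  # (3, 3) ints; rows: first chi of the pair

    @property
    def n_observations(self) -> int:
        return int(self.counts.sum())

    def probabilities(self) -> np.ndarray:
        n = self.counts.sum()
        if n == 0:
            raise ValueError("histogram has no valid observations")
        return self.counts / n


def chi_pair_histograms(ensemble: Ensemble) -> list[ChiPairHistogram]:
    """Per-residue 9-bin joint histograms of consecutive chi pairs.

    A residue with k chi angles contributes the pairs (1,2) .. (k-1,k);
    residues with fewer than two chi angles contribute nothing.
    """
    table = compute_torsions(ensemble)
    out: list[ChiPairHistogram] = []
    for r, res_name in enumerate(ensemble.topology.residue_names):
        k = chemdata.n_chi(res_name)
        for pair in CHI_PAIRS[: max(0, k - 1)]:
            j, kk = pair
            aj = table.values[:, r, 2 + j]
            ak = table.values[:, r, 2 + kk]
            ok = table.valid[:, r, 2 + j] & table.valid[:, r, 2 + kk]
            bj = chi_bin_index(aj[ok])
            bk = chi_bin_index(ak[ok])
            counts = np.zeros((3, 3), dtype=int)
            np.add.at(counts, (bj, bk), 1)
            out.append(ChiPairHistogram(residue_index=r, pair=pair, counts=counts))
    return out


def chijsd(
    reference: Ensemble, proposed: Ensemble, return_details: bool = False
):
    """Mean chi-pair Jensen-Shannon divergence between two ensembles.

    Both ensembles must share the topology.  Pairs lacking valid observations
    in either ensemble are excluded from the mean (and reported when
    ``return_details``).  Raises if no pair is evaluable at all.
    """
    if reference.topology.residue_names != proposed.topology.residue_names:
        raise ValueError("ensembles must share residue composition")
    h_ref = chi_pair_histograms(reference)
    h_prop = chi_pair_histograms(proposed)
    values, skipped = [], []
    for a, b in zip(h_ref, h_prop):
        if a.n_observations == 0 or b.n_observations == 0:
            skipped.append((a.residue_index, a.pair))
            continue
        values.append(jsd(a.probabilities(), b.probabilities()))
    if not values:
        raise ValueError(
            "chi-pair divergence undefined: no residue contributes an "
            "evaluable chi pair (e.g. poly-GLY/ALA/SER chains)"
        )
    score = float(np.mean(values))
    if return_details:
        return score, {"n_pairs": len(values), "skipped_pairs": skipped}
    return score


# ---------------------------------------------------------------------------
# Secondary structure preservation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NativeSSE:
    """Native 3-state secondary structure and its helix/strand residue set."""

    states0: tuple[str, ...]
    hot_indices: tuple[int, ...]

    @property
    def count(self) -> int:
        return len(self.hot_indices)


def native_sse(native: Conformation, topology: Topology) -> NativeSSE:
    """DSSP-derived native states with the H/E residue set used by SSEP."""
    states = assign_sse(native, topology)
    hot = tuple(i for i, s in enumerate(states) if s in ("H", "E"))
    return NativeSSE(states0=tuple(states), hot_indices=hot)


def ssep(
    ensemble: Ensemble,
    native: Conformation,
    native_states: Optional[NativeSSE] = None,
    return_per_frame: bool = False,
):
    """Secondary structure element preservation in [0, 1].

    Per frame: the fraction of natively helical/strand residues whose 3-state
    assignment matches the native state; SSEP is the mean over frames.
    """
    if native_states is None:
        native_states = native_sse(native, ensemble.topology)
    if native_states.count == 0:
        raise ValueError(
            "SSEP undefined: native structure has no residue in H or E state"
        )
    hot = np.asarray(native_states.hot_indices, int)
    target = np.array([native_states.states0[i] for i in hot])
    per_frame = np.empty(ensemble.n_frames)
    for f, frame in enumerate(ensemble.frames):
        states = np.asarray(assign_sse(frame, ensemble.topology))
        per_frame[f] = float(np.mean(states[hot] == target))
    value = float(per_frame.mean())
    if return_per_frame:
        return value, per_frame
    return value


# ---------------------------------------------------------------------------
# Native contacts, Q and FSF
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NativeContactSet:
    """Native residue-pair contacts (i, j, d0) parameterizing Q."""

    contacts: tuple[tuple[int, int, float], ...]

    @property
    def count(self) -> int:
        return len(self.contacts)

    def __post_init__(self):
        for i, j, d0 in self.contacts:
            if abs(i - j) < CONTACT_MIN_SEPARATION:
                raise ValueError("contact pairs must be >= 3 residues apart")
            if not 0.0 < d0 <= CONTACT_D0_MAX:
                raise ValueError("native contact distances must be in (0, 10] A")


def _residue_atom_groups(topology: Topology) -> list[np.ndarray]:
    return [topology.residue_atom_indices(r) for r in range(topology.n_residues)]


def _min_distance(coords: np.ndarray, gi: np.ndarray, gj: np.ndarray) -> float:
    d = coords[gi][:, None, :] - coords[gj][None, :, :]
    return float(np.sqrt(np.min(np.sum(d * d, axis=-1))))


def native_contacts(native: Conformation, topology: Topology) -> NativeContactSet:
    """All residue pairs >= 3 apart whose shortest heavy-atom distance <= 10 A."""
    groups = _residue_atom_groups(topology)
    L = topology.n_residues
    contacts = []
    for i in range(L):
        for j in range(i + CONTACT_MIN_SEPARATION, L):
            d0 = _min_distance(native.coords, groups[i], groups[j])
            if d0 <= CONTACT_D0_MAX:
                contacts.append((i, j, d0))
    return NativeContactSet(contacts=tuple(contacts))


def contact_distances(
    conformation: Conformation, topology: Topology, contacts: NativeContactSet
) -> np.ndarray:
    """Shortest heavy-atom distance of each native contact pair in a frame."""
    groups = _residue_atom_groups(topology)
    return np.array(
        [_min_distance(conformation.coords, groups[i], groups[j])
         for i, j, _ in contacts.contacts]
    )


def q_fraction(
    conformation: Conformation, topology: Topology, contacts: NativeContactSet
) -> float:
    """Soft fraction of native contacts of one conformation, in (0, 1)."""
    if contacts.count == 0:
        raise ValueError("Q undefined for an empty native contact set")
    d = contact_distances(conformation, topology, contacts)
    d0 = np.array([c[2] for c in contacts.contacts])
    terms = 1.0 / (1.0 + np.exp(Q_BETA * (d - Q_LAMBDA * d0)))
    return float(terms.mean())


def q_series(ensemble: Ensemble, contacts: NativeContactSet) -> np.ndarray:
    """Per-frame Q values of an ensemble."""
    return np.array(
        [q_fraction(f, ensemble.topology, contacts) for f in ensemble.frames]
    )


def folded_state_fraction(
    ensemble: Ensemble,
    contacts: NativeContactSet,
    q_thresh: float = Q_THRESHOLD,
    return_q: bool = False,
):
    """Fraction of frames with Q strictly above ``q_thresh``."""
    q = q_series(ensemble, contacts)
    fsf = float(np.mean(q > q_thresh))
    if return_q:
        return fsf, q
    return fsf
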