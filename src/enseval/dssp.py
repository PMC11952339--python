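"""Kabsch-Sander secondary-structure assignment, simplified to 3 states.

Backbone hydrogen bonds are detected with the classic electrostatic energy

    E = 0.084 * 332 * (1/d_ON + 1/d_CH - 1/d_OH - 1/d_CN)   [kcal/mol]

using an ideal amide hydrogen placed 1.0 A from N along the reversed carbonyl
direction of the preceding residue (the model is hydrogen-free).  A bond
exists when E < -0.5 kcal/mol.  From the bond pattern, 4-turn helices (H),
3-turns (G), 5-turns (I) and parallel/antiparallel bridges (E/B) are derived
per Kabsch & Sander; the 8-state alphabet is reduced to 3 states with
{H, G, I} -> H, {E, B} -> E, everything else C.  Chains shorter than 4
residues are assigned all-coil.
"""

from __future__ import annotations

import numpy as np

from .core import Conformation, Topology

__all__ = ["assign_sse", "hbond_matrix"]

_HB_COUPLING = 0.084 * 332.0  # kcal/mol * Angstrom
_HB_CUTOFF = -0.5  # kcal/mol
_CA_PRESCREEN = 9.0  # Angstrom, donor/acceptor CA distance prescreen


def _backbone(conformation: Conformation, topology: Topology):
    L = topology.n_residues
    take = lambda name: np.array(
        [conformation.coords[topology.atom_index(r, name)] for r in range(L)]
    )
    return take("N"), take("CA"), take("C"), take("O")


def hbond_matrix(conformation: Conformation, topology: Topology) -> np.ndarray:
    """Boolean (L, L) matrix: entry [i, j] True if CO of i accepts the NH of j.

    Proline and the first residue cannot donate (no amide hydrogen).
    """
    N, CA, C, O = _backbone(conformation, topology)
    L = topology.n_residues
    hb = np.zeros((L, L), dtype=bool)
    if L < 2:
        return hb
    # ideal amide H on residue j >= 1: 1.0 A from N, anti to C(j-1)=O(j-1)
    co = C[:-1] - O[:-1]
    co /= np.linalg.norm(co, axis=1, keepdims=True)
    H = N[1:] + co  # donors are residues 1..L-1
    donors = np.arange(1, L)
    is_pro = np.array(
        [topology.residue_names[j] == "PRO" for j in donors]
    )
    donors = donors[~is_pro]
    if donors.size == 0:
        return hb
    Hd = H[donors - 1]
    Nd = N[donors]
    # acceptors: all residues with C=O (every residue here)
    d_ca = np.linalg.norm(CA[:, None, :] - CA[None, donors, :], axis=-1)
    for ai in range(L):
        for k, dj in enumerate(donors):
            if dj == ai or d_ca[ai, k] > _CA_PRESCREEN:
                continue
            d_on = np.linalg.norm(O[ai] - Nd[k])
            d_ch = np.linalg.norm(C[ai] - Hd[k])
            d_oh = np.linalg.norm(O[ai] - Hd[k])
            d_cn = np.linalg.norm(C[ai] - Nd[k])
            if min(d_on, d_ch, d_oh, d_cn) < 0.5:
                e = -1e3  # overlapping atoms: treat as bonded per DSSP
            else:
                e = _HB_COUPLING * (1 / d_on + 1 / d_ch - 1 / d_oh - 1 / d_cn)
            if e < _HB_CUTOFF:
                hb[ai, dj] = True
    return hb


def assign_sse(conformation: Conformation, topology: Topology) -> list[str]:
    """Per-residue 3-state secondary structure: H (helix), E (strand), C (coil)."""
    L = topology.n_residues
    if L < 4:
        return ["C"] * L
    hb = hbond_matrix(conformation, topology)

    def turn(n):
        t = np.zeros(L, dtype=bool)
        idx = np.arange(0, L - n)
        t[idx] = hb[idx, idx + n]
        return t

    t3, t4, t5 = turn(3), turn(4), turn(5)

    helix4 = np.zeros(L, dtype=bool)
    for i in range(1, L - 4):
        if t4[i - 1] and t4[i]:
            helix4[i : i + 4] = True
    helix3 = np.zeros(L, dtype=bool)
    for i in range(1, L - 3):
        if t3[i - 1] and t3[i]:
            helix3[i : i + 3] = True
    helix5 = np.zeros(L, dtype=bool)
    for i in range(1, L - 5):
        if t5[i - 1] and t5[i]:
            helix5[i : i + 5] = True

    bridge = np.zeros(L, dtype=bool)
    for i in range(1, L - 1):
        for j in range(i + 3, L - 1):
            parallel = (hb[i - 1, j] and hb[j, i + 1]) or (
                hb[j - 1, i] and hb[i, j + 1]
            )
            antiparallel = (hb[i, j] and hb[j, i]) or (
                hb[i - 1, j + 1] and hb[j - 1, i + 1]
            )
            if parallel or antiparallel:
                bridge[i] = True
                bridge[j] = True

    out = []
    for i in range(L):
        if helix4[i]:
            out.append("H")
        elif bridge[i]:
            out.append("E")
        elif helix3[i] or helix5[i]:
            out.append("H")
        else:
            out.append("C")
    return out
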