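"""Positional and fluctuation metrics comparing ensembles.

CA-based profiles (RMSF, RMSD to the initial structure), compactness (radius
of gyration), contact-frequency maps, a PCA landscape over non-adjacent CA-CA
distances, and free-energy surfaces G = -RT ln P over 2D projections binned
on a uniform 50 x 50 grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Conformation, Ensemble
from .geometry import apply_rigid, kabsch

__all__ = [
    "GAS_CONSTANT_KJ",
    "LandscapeModel",
    "FreeEnergyGrid",
    "rmsf_profile",
    "rmsf_pcc",
    "init_rmsd",
    "radius_of_gyration",
    "contact_map",
    "fit_landscape",
    "project_landscape",
    "free_energy_grid",
]

GAS_CONSTANT_KJ = 8.314462618e-3  # kJ / (mol K)


def _ca_coords(ensemble: Ensemble) -> np.ndarray:
    ca = ensemble.topology.backbone_indices("CA")
    return ensemble.coordinates()[:, ca, :]


def _superpose_frames_onto(ensemble: Ensemble, initial: Conformation) -> np.ndarray:
    """All-frame CA coordinates after CA superposition onto ``initial``."""
    ca = ensemble.topology.backbone_indices("CA")
    ref = initial.coords[ca]
    out = np.empty((ensemble.n_frames, len(ca), 3))
    for f, frame in enumerate(ensemble.frames):
        R, t, _ = kabsch(frame.coords[ca], ref)
        out[f] = apply_rigid(frame.coords[ca], R, t)
    return out


def rmsf_profile(ensemble: Ensemble, initial: Conformation) -> np.ndarray:
    """Per-residue CA root-mean-square fluctuation (Angstrom).

    Every frame is CA-superposed onto ``initial``; fluctuations are measured
    about the ensemble-mean CA positions after that alignment.
    """
    if ensemble.n_frames < 2:
        raise ValueError("RMSF undefined for a single-frame ensemble")
    aligned = _superpose_frames_onto(ensemble, initial)
    mean = aligned.mean(axis=0)
    return np.sqrt(np.mean(np.sum((aligned - mean) ** 2, axis=-1), axis=0))


def rmsf_pcc(profile_a: np.ndarray, profile_b: np.ndarray) -> float:
    """Pearson correlation between two per-residue profiles."""
    a = np.asarray(profile_a, float)
    b = np.asarray(profile_b, float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 3:
        raise ValueError("profiles must be equal-length 1D arrays with >= 3 entries")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("correlation undefined for a constant profile")
    return float(np.corrcoef(a, b)[0, 1])


def init_rmsd(ensemble: Ensemble, initial: Conformation) -> np.ndarray:
    """Per-frame CA RMSD to the initial structure after optimal superposition."""
    ca = ensemble.topology.backbone_indices("CA")
    ref = initial.coords[ca]
    out = np.empty(ensemble.n_frames)
    for f, frame in enumerate(ensemble.frames):
        _, _, rmsd = kabsch(frame.coords[ca], ref)
        out[f] = rmsd
    return out


def radius_of_gyration(ensemble: Ensemble) -> np.ndarray:
    """Per-frame mass-unweighted heavy-atom radius of gyration (Angstrom)."""
    X = ensemble.coordinates()
    centered = X - X.mean(axis=1, keepdims=True)
    return np.sqrt(np.mean(np.sum(centered**2, axis=-1), axis=1))


def contact_map(ensemble: Ensemble, cutoff: float = 9.0) -> np.ndarray:
    """(L, L) frequency of CA-CA distance <= cutoff over frames.

    Only non-adjacent pairs (|i - j| >= 2) are scored; the diagonal and
    adjacent entries are 0.  The comparison is inclusive (<=).
    """
    if not cutoff > 0:
        raise ValueError("cutoff must be positive")
    ca = _ca_coords(ensemble)
    d = np.linalg.norm(ca[:, :, None, :] - ca[:, None, :, :], axis=-1)
    freq = np.mean(d <= cutoff, axis=0)
    L = freq.shape[0]
    ij = np.abs(np.subtract.outer(np.arange(L), np.arange(L)))
    freq[ij < 2] = 0.0
    return freq


def _nonadjacent_pairs(L: int) -> np.ndarray:
    i, j = np.triu_indices(L, k=2)
    return np.column_stack([i, j])


def _distance_features(ensemble: Ensemble, pairs: np.ndarray) -> np.ndarray:
    ca = _ca_coords(ensemble)
    return np.linalg.norm(ca[:, pairs[:, 0], :] - ca[:, pairs[:, 1], :], axis=-1)


@dataclass(frozen=True)
class LandscapeModel:
    """Top-2 PCA of non-adjacent CA-CA distance features of a reference ensemble."""

    feature_pairs: np.ndarray  # (n_features, 2) residue index pairs
    mean: np.ndarray  # (n_features,)
    axes: np.ndarray  # (2, n_features), orthonormal rows
    explained_variance: np.ndarray  # (2,), non-increasing

    @property
    def n_residues(self) -> int:
        return int(self.feature_pairs.max()) + 1


def fit_landscape(reference: Ensemble) -> LandscapeModel:
    """PCA (centered, unscaled) on the non-adjacent CA-CA distance matrix."""
    L = reference.topology.n_residues
    if reference.n_frames < 3 or L < 4:
        raise ValueError("landscape fit needs >= 3 frames and >= 4 residues")
    pairs = _nonadjacent_pairs(L)
    X = _distance_features(reference, pairs)
    mean = X.mean(axis=0)
    Xc = X - mean
    if np.allclose(Xc, 0.0):
        raise ValueError("all features have zero variance")
    # economy SVD: principal axes = right singular vectors
    _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    var = s**2 / (X.shape[0] - 1)
    return LandscapeModel(
        feature_pairs=pairs,
        mean=mean,
        axes=Vt[:2],
        explained_variance=var[:2],
    )


def project_landscape(model: LandscapeModel, query: Ensemble) -> np.ndarray:
    """Per-frame (pc1, pc2) scores of ``query`` on the model's axes."""
    if query.topology.n_residues != model.n_residues:
        raise ValueError(
            f"query has {query.topology.n_residues} residues, "
            f"model expects {model.n_residues}"
        )
    X = _distance_features(query, model.feature_pairs)
    return (X - model.mean) @ model.axes.T


@dataclass(frozen=True)
class FreeEnergyGrid:
    """Binned free-energy surface G = -RT ln P relative to its minimum."""

    x_edges: np.ndarray  # (bins + 1,)
    y_edges: np.ndarray
    G: np.ndarray  # (bins, bins); masked entries hold +inf
    mask: np.ndarray  # True where the bin is empty
    temperature: float  # K
    P: np.ndarray  # raw frequencies, for round-trip checks

    @property
    def rt(self) -> float:
        return GAS_CONSTANT_KJ * self.temperature


def free_energy_grid(
    points: np.ndarray, temperature: float, bins: int = 50
) -> FreeEnergyGrid:
    """Free-energy surface over 2D projection points.

    Uniform ``bins x bins`` grid spanning the data range per axis;
    P is the raw frequency (count / total), G = -RT ln P in kJ/mol shifted so
    the occupied minimum is 0; empty bins are masked (+inf).
    """
    pts = np.asarray(points, float).reshape(-1, 2)
    if pts.shape[0] < 1:
        raise ValueError("need at least one projection point")
    if not temperature > 0:
        raise ValueError("temperature must be positive (Kelvin)")
    counts, x_edges, y_edges = np.histogram2d(pts[:, 0], pts[:, 1], bins=bins)
    P = counts / counts.sum()
    mask = P == 0
    rt = GAS_CONSTANT_KJ * temperature
    with np.errstate(divide="ignore"):
        G = -rt * np.log(np.where(mask, 1.0, P))
    G[mask] = np.inf
    G -= G[~mask].min()
    return FreeEnergyGrid(
        x_edges=x_edges, y_edges=y_edges, G=G, mask=mask,
        temperature=float(temperature), P=P,
    )
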