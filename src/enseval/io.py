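"""Reading and writing ensembles (PDB, optionally DCD/XTC) and metric reports.

Reading keeps the first chain, drops hydrogens, waters and hetero records,
and turns each MODEL of a multi-model PDB into one frame.  Writing always
emits MODEL/ENDMDL records, even for single frames, so round trips are
uniform.  Coordinates are Angstrom internally; trajectory formats in nm are
converted on read.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from . import chemdata
from .core import Conformation, Ensemble, Topology

__all__ = ["EnsembleSource", "read_ensemble", "write_ensemble", "write_report"]


@dataclass
class EnsembleSource:
    """Where and how to load one ensemble."""

    structure_path: Path
    trajectory_path: Optional[Path] = None
    temperature: Optional[float] = None
    frame_stride: int = 1
    max_frames: Optional[int] = None
    chain: Optional[str] = None
    label: str = ""

    def __post_init__(self):
        self.structure_path = Path(self.structure_path)
        if not self.structure_path.exists():
            raise FileNotFoundError(self.structure_path)
        if self.frame_stride < 1:
            raise ValueError("frame_stride must be >= 1")


def _load_pdb_stack(path: Path, chain: Optional[str]):
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    pdb = PDBFile.read(str(path))
    stack = pdb.get_structure(model=None, altloc="first")
    arr0 = stack[0]
    keep = struc.filter_amino_acids(arr0) & ~arr0.hetero & (arr0.element != "H")
    chains = arr0.chain_id[keep]
    wanted = chain if chain is not None else (chains[0] if len(chains) else None)
    keep &= arr0.chain_id == wanted
    return stack[:, keep]


def _topology_from_atomarray(arr) -> Topology:
    res_ids = arr.res_id
    _, first_idx = np.unique(res_ids, return_index=True)
    first_idx.sort()
    id_to_index = {int(res_ids[i]): k for k, i in enumerate(first_idx)}
    residue_names = tuple(str(arr.res_name[i]) for i in first_idx)
    return Topology(
        chain_id=str(arr.chain_id[0]),
        residue_names=residue_names,
        atom_names=tuple(str(a) for a in arr.atom_name),
        atom_elements=tuple(str(e) for e in arr.element),
        atom_residue=np.array([id_to_index[int(r)] for r in res_ids], dtype=int),
    )


def read_ensemble(source: EnsembleSource) -> Ensemble:
    """Load an ensemble from a (multi-model) PDB plus an optional trajectory.

    Without a trajectory, each MODEL becomes one frame.  With a DCD/XTC
    trajectory, the PDB provides the topology and the trajectory the frames
    (coordinates converted from nm where applicable).  Frames are subsampled
    by ``frame_stride`` and then truncated to ``max_frames``.
    """
    stack = _load_pdb_stack(source.structure_path, source.chain)
    topo = _topology_from_atomarray(stack[0])
    if source.trajectory_path is not None:
        coords = _load_trajectory(source.trajectory_path, source.structure_path)
        if coords.shape[1] != topo.n_atoms:
            raise ValueError(
                f"trajectory has {coords.shape[1]} atoms but the topology has "
                f"{topo.n_atoms}"
            )
        all_frames = coords
    else:
        all_frames = stack.coord
    frames = all_frames[:: source.frame_stride]
    if source.max_frames is not None:
        frames = frames[: source.max_frames]
    if len(frames) == 0:
        raise ValueError("no frames left after stride/max_frames filtering")
    return Ensemble(
        topology=topo,
        frames=[Conformation(f) for f in frames],
        temperature=source.temperature,
        label=source.label or source.structure_path.stem,
    )


def _load_trajectory(traj_path: Path, top_path: Path) -> np.ndarray:
    try:
        import mdtraj
    except ImportError:  # pragma: no cover - optional runtime dependency
        raise ImportError(
            "reading DCD/XTC trajectories requires the optional mdtraj dependency"
        ) from None
    t = mdtraj.load(str(traj_path), top=str(top_path))
    heavy = t.topology.select("protein and element != H")
    return np.asarray(t.xyz[:, heavy, :], dtype=float) * 10.0  # nm -> Angstrom


_PDB_LINE = (
    "ATOM  {serial:>5d} {name:<4s}{altloc:1s}{res:<3s} {chain:1s}{resseq:>4d}"
    "{icode:1s}   {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}          {el:>2s}\n"
)


def _format_atom_name(name: str, element: str) -> str:
    # columns 13-16: element right-aligned into cols 13-14 for 1-2 char names
    if len(name) >= 4:
        return name[:4]
    if len(element) == 1 and len(name) <= 3:
        return f" {name:<3s}"
    return f"{name:<4s}"


def write_ensemble(ensemble: Ensemble, path) -> None:
    """Write a multi-model PDB (MODEL/ENDMDL emitted even for one frame)."""
    topo = ensemble.topology
    path = Path(path)
    with open(path, "w") as fh:
        for m, frame in enumerate(ensemble.frames, start=1):
            fh.write(f"MODEL     {m:>4d}\n")
            serial = 1
            for i in range(topo.n_atoms):
                r = int(topo.atom_residue[i])
                fh.write(
                    _PDB_LINE.format(
                        serial=min(serial, 99999),
                        name=_format_atom_name(
                            topo.atom_names[i], topo.atom_elements[i]
                        ),
                        altloc=" ",
                        res=topo.residue_names[r],
                        chain=topo.chain_id[:1] or "A",
                        resseq=r + 1,
                        icode=" ",
                        x=frame.coords[i, 0],
                        y=frame.coords[i, 1],
                        z=frame.coords[i, 2],
                        occ=1.00,
                        b=0.00,
                        el=topo.atom_elements[i],
                    )
                )
                serial += 1
            fh.write("ENDMDL\n")
        fh.write("END\n")


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return None if not math.isfinite(f) else f
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def write_report(report, path, format: str = "json") -> None:
    """Serialize a :class:`~enseval.report.MetricReport` to JSON or TSV.

    JSON keeps the full nested schema; TSV flattens scalar scores into a
    key-value section followed by one block per per-residue/per-frame profile.
    """
    data = report.to_dict() if hasattr(report, "to_dict") else dict(report)
    path = Path(path)
    if format == "json":
        with open(path, "w") as fh:
            json.dump(_jsonable(data), fh, indent=2, sort_keys=True)
            fh.write("\n")
    elif format == "tsv":
        with open(path, "w") as fh:
            fh.write("# section\tkey\tvalue\n")
            for k, v in sorted(data.get("scalar", {}).items()):
                fh.write(f"scalar\t{k}\t{_jsonable(v)}\n")
            for name, prof in sorted(data.get("profiles", {}).items()):
                arr = np.asarray(prof, dtype=float)
                if arr.ndim != 1:
                    continue
                fh.write(f"# profile\t{name}\tindex\tvalue\n")
                for i, v in enumerate(arr):
                    fh.write(f"{name}\t{i + 1}\t{v:.6g}\n")
    else:
        raise ValueError(f"unknown report format {format!r}; use 'json' or 'tsv'")
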