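"""The MetricReport aggregator: one nested, serializable record per comparison.

`compare_ensembles` runs the requested subset of the evaluation battery on a
(reference, generated, native) triple and collects scalar scores, per-residue
and per-frame profiles, histograms (chi-pair tables, contact maps) and
warnings under a schema-versioned dict.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import __version__
from .core import Conformation, Ensemble
from .integrity import integrity_report
from .metrics import (
    contact_map,
    fit_landscape,
    init_rmsd,
    project_landscape,
    radius_of_gyration,
    rmsf_pcc,
    rmsf_profile,
)
from .scores import (
    chi_pair_histograms,
    chijsd,
    folded_state_fraction,
    native_contacts,
    native_sse,
    ssep,
)

SCHEMA_VERSION = 1

ALL_METRICS = (
    "rmsf", "init_rmsd", "rg", "contact_map", "chijsd", "ssep", "fsf",
    "integrity", "landscape",
)


@dataclass
class MetricReport:
    """Nested record of every score comparing two ensembles."""

    meta: dict = field(default_factory=dict)
    scalar: dict = field(default_factory=dict)
    profiles: dict = field(default_factory=dict)
    histograms: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "meta": {"schema_version": SCHEMA_VERSION, **self.meta},
            "scalar": self.scalar,
            "profiles": self.profiles,
            "histograms": self.histograms,
            "warnings": self.warnings,
        }


def _check_topologies(ref: Ensemble, gen: Ensemble):
    a, b = ref.topology.residue_names, gen.topology.residue_names
    if a != b:
        for i, (x, y) in enumerate(zip(a, b)):
            if x != y:
                raise ValueError(
                    f"topology mismatch at residue {i + 1}: {x} vs {y}"
                )
        raise ValueError(f"topology mismatch: {len(a)} vs {len(b)} residues")


def compare_ensembles(
    reference: Ensemble,
    generated: Ensemble,
    native: Optional[Conformation] = None,
    metrics: Sequence[str] = ALL_METRICS,
    contact_cutoff: float = 9.0,
) -> MetricReport:
    """Run the evaluation battery; ``native`` defaults to the first reference frame."""
    _check_topologies(reference, generated)
    unknown = set(metrics) - set(ALL_METRICS)
    if unknown:
        raise ValueError(f"unknown metrics: {sorted(unknown)}")
    if native is None:
        native = reference.frames[0]
    rep = MetricReport(
        meta={
            "enseval_version": __version__,
            "n_frames_reference": reference.n_frames,
            "n_frames_generated": generated.n_frames,
            "n_residues": reference.topology.n_residues,
            "metrics": list(metrics),
        }
    )

    if "rmsf" in metrics:
        try:
            prof_ref = rmsf_profile(reference, native)
            prof_gen = rmsf_profile(generated, native)
            rep.profiles["rmsf_reference"] = prof_ref
            rep.profiles["rmsf_generated"] = prof_gen
            rep.scalar["rmsf_pcc"] = rmsf_pcc(prof_ref, prof_gen)
        except ValueError as exc:
            rep.scalar["rmsf_pcc"] = None
            rep.warnings.append(f"rmsf: {exc}")
    if "init_rmsd" in metrics:
        series = init_rmsd(generated, native)
        rep.profiles["init_rmsd"] = series
        rep.scalar["mean_init_rmsd"] = float(series.mean())
    if "rg" in metrics:
        rg = radius_of_gyration(generated)
        rep.profiles["rg"] = rg
        rep.scalar["mean_rg"] = float(rg.mean())
    if "contact_map" in metrics:
        rep.histograms["contact_map_reference"] = contact_map(
            reference, contact_cutoff
        )
        rep.histograms["contact_map_generated"] = contact_map(
            generated, contact_cutoff
        )
    if "chijsd" in metrics:
        try:
            score, details = chijsd(reference, generated, return_details=True)
            rep.scalar["chijsd"] = score
            rep.meta["chijsd_n_pairs"] = details["n_pairs"]
            if details["skipped_pairs"]:
                rep.warnings.append(
                    f"chijsd: {len(details['skipped_pairs'])} pairs lacked "
                    "observations and were excluded"
                )
            rep.histograms["chi_pairs_reference"] = [
                {"residue": h.residue_index + 1, "pair": list(h.pair),
                 "counts": h.counts}
                for h in chi_pair_histograms(reference)
            ]
        except ValueError as exc:
            rep.scalar["chijsd"] = None
            rep.warnings.append(f"chijsd: {exc}")
    if "ssep" in metrics:
        try:
            states = native_sse(native, reference.topology)
            value, per_frame = ssep(
                generated, native, native_states=states, return_per_frame=True
            )
            rep.scalar["ssep"] = value
            rep.profiles["ssep_per_frame"] = per_frame
            rep.meta["n_native_he"] = states.count
        except ValueError as exc:
            rep.scalar["ssep"] = None
            rep.warnings.append(f"ssep: {exc}")
    if "fsf" in metrics:
        try:
            contacts = native_contacts(native, reference.topology)
            fsf, q = folded_state_fraction(generated, contacts, return_q=True)
            rep.scalar["fsf"] = fsf
            rep.profiles["q_per_frame"] = q
            rep.meta["n_native_contacts"] = contacts.count
        except ValueError as exc:
            rep.scalar["fsf"] = None
            rep.warnings.append(f"fsf: {exc}")
    if "integrity" in metrics:
        ir = integrity_report(generated)
        rep.scalar["mean_clashes"] = ir.mean_clashes
        rep.scalar["mean_violations"] = ir.mean_violations
        rep.profiles["clashes_per_frame"] = ir.clashes_per_frame
        rep.profiles["violations_per_frame"] = ir.violations_per_frame
    if "landscape" in metrics:
        try:
            model = fit_landscape(reference)
            rep.histograms["pca_reference"] = project_landscape(model, reference)
            rep.histograms["pca_generated"] = project_landscape(model, generated)
            rep.meta["pca_explained_variance"] = [
                float(v) for v in model.explained_variance
            ]
        except ValueError as exc:
            rep.warnings.append(f"landscape: {exc}")
    return rep
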