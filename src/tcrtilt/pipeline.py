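"""Config-driven orchestration of the full ensemble analysis.

Stages, in order: read -> equilibration gate -> orientations -> contacts
(probability map, element counts, clusters, cluster correlations) ->
tilt-binned profiles -> 2D tilt-rotation density -> convergence series ->
RMSD series (if a reference is given) -> membrane annulus thickness (if
lipids are present) -> force-tilt model from the gated tilt samples.  Every
written CSV is listed in a manifest with a config hash; the pipeline itself
is deterministic.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import contacts as _contacts
from . import force_model as _force
from . import geometry as _geometry
from . import membrane as _membrane
from . import tilt_stats as _stats
from .structure_io import (
    Conformation,
    DomainMap,
    Ensemble,
    load_domain_map,
    read_multimodel_pdb,
    write_table,
)

log = logging.getLogger("tcrtilt.pipeline")


class PipelineError(RuntimeError):
    """A stage failure; the message names the stage."""


@dataclass
class AnalysisConfig:
    ensemble: "str | Path | Ensemble"
    domain_map: "str | Path | DomainMap | None" = None
    reference: "str | Path | Conformation | None" = None
    outdir: "str | Path" = "results"
    contact_cutoff: float = _contacts.DEFAULT_CONTACT_CUTOFF
    lipid_cutoff: float = _membrane.DEFAULT_LIPID_CUTOFF
    prob_threshold: float = _contacts.DEFAULT_PROB_THRESHOLD
    gate_us: float = _stats.EQUILIBRATION_GATE_US
    gate_override: bool = False
    tilt_bin_width: float = _stats.DEFAULT_BIN_WIDTH
    density_bin_width: tuple = (2.5, 2.5)
    cluster_radius: int = _contacts.DEFAULT_CLUSTER_RADIUS
    n_subsets: int = _stats.DEFAULT_N_SUBSETS
    h_nm: float = _force.DEFAULT_EC_EXTENSION
    temperature_K: float = _force.DEFAULT_TEMPERATURE
    forces_pN: tuple = (2.0, 5.0)
    seed: int = 0

    def __post_init__(self):
        for name in ("contact_cutoff", "lipid_cutoff", "prob_threshold",
                     "tilt_bin_width"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.gate_us < 0:
            raise ValueError("gate_us must be non-negative")

    def hash(self) -> str:
        payload = {}
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            payload[f.name] = v if isinstance(v, (int, float, str, bool, tuple, list)) \
                else repr(type(v).__name__)
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return wrapped
    return deco


def run_analysis(config: AnalysisConfig) -> dict:
    """Run the full analysis; returns the manifest (also written as JSON)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[str] = []

    def emit(df, name):
        path = outdir / name
        write_table(df, path)
        written.append(name)
        return path

    # -- read ---------------------------------------------------------------
    @_stage("read")
    def _read():
        ens = config.ensemble
        if not isinstance(ens, Ensemble):
            ens = read_multimodel_pdb(ens)
        dm = config.domain_map
        if not isinstance(dm, DomainMap):
            dm = load_domain_map(dm)
        return ens, dm

    ensemble, dm = _read()
    log.info("read: %d conformations, %d atoms each",
             len(ensemble), ensemble[0].n_atoms)

    # -- equilibration gate --------------------------------------------------
    @_stage("gate")
    def _gate():
        if ensemble[0].source is None:
            log.info("gate: no provenance, gate skipped")
            return ensemble
        return _stats.filter_equilibrated_ensemble(
            ensemble, config.gate_us, override=config.gate_override
        )

    gated = _gate()
    log.info("gate: %d of %d frames beyond %.2f us",
             len(gated), len(ensemble), config.gate_us)

    # -- orientations ---------------------------------------------------------
    @_stage("orientations")
    def _orient(frames):
        return _stats.orientation_table(
            [_geometry.orientation(c, dm) for c in frames]
        )

    ori_all = _orient(ensemble)
    ori = ori_all if len(gated) == len(ensemble) else _orient(gated)
    emit(ori, "orientations.csv")

    # -- contacts -------------------------------------------------------------
    @_stage("contacts")
    def _contact_block():
        frame_sets = [
            _contacts.frame_contacts(c, dm, config.contact_cutoff) for c in gated
        ]
        pmap = _contacts.probability_map(
            gated, dm, config.contact_cutoff, config.prob_threshold,
            frame_sets=frame_sets,
        )
        counts = _contacts.element_contact_counts(frame_sets, dm)
        clusters = _contacts.cluster_contacts(pmap, config.cluster_radius)
        corr = _contacts.cluster_correlation(clusters) if len(clusters) > 1 else None
        return pmap, counts, clusters, corr

    pmap, el_counts, clusters, corr = _contact_block()
    el_table = el_counts.copy()
    el_table.insert(0, "trajectory", ori["trajectory"].to_numpy())
    el_table.insert(1, "time_us", ori["time_us"].to_numpy())
    el_table.insert(2, "tilt", ori["tilt"].to_numpy())
    emit(el_table, "element_contact_counts.csv")
    emit(pmap.to_frame(reported_only=False), "contact_counts_raw.csv")
    emit(pmap.to_frame(reported_only=True), "contact_map_reported.csv")
    cluster_rows = [
        {"cluster_id": c.cluster_id, "dimer_a": c.dimer_pair[0],
         "dimer_b": c.dimer_pair[1], "n_members": len(c.members),
         "members": ";".join(
             f"{a[0]}{a[1]}-{b[0]}{b[1]}" for _, a, b in c.members)}
        for c in clusters
    ]
    emit(cluster_rows, "contact_clusters.csv")
    if corr is not None:
        emit(corr.reset_index(names="cluster_id"), "cluster_correlation.csv")
    log.info("contacts: %d reported pairs in %d clusters",
             len(pmap.reported), len(clusters))

    # -- tilt-binned profiles --------------------------------------------------
    @_stage("tilt_profiles")
    def _profiles():
        rows = []
        tilt = ori["tilt"].to_numpy()
        traj = ori["trajectory"].to_numpy()
        if np.isnan(traj.astype(float)).all():
            # no provenance: fall back to per-frame pseudo-trajectories so
            # subset errors reflect arbitrary contiguous blocks of frames
            traj = np.arange(len(ori))
        n_subsets = min(config.n_subsets, len(np.unique(traj)))
        quantities = {f"contacts {el}": el_counts[el].to_numpy()
                      for el in el_counts.columns}
        quantities.update(
            {c.replace("incl_", "inclination "): ori[c].to_numpy()
             for c in ori.columns if c.startswith("incl_")}
        )
        for qname, values in quantities.items():
            prof = _stats.bin_by_tilt(
                tilt, values, traj,
                bin_width=config.tilt_bin_width, n_subsets=n_subsets,
            )
            d = prof.to_frame()
            d.insert(0, "quantity", qname)
            rows.append(d)
        return pd.concat(rows, ignore_index=True)

    emit(_profiles(), "tilt_binned_profiles.csv")

    # -- 2D density --------------------------------------------------------------
    @_stage("density_2d")
    def _density():
        dens = _stats.density_2d(
            ori["tilt"].to_numpy(), ori["rotation"].to_numpy(),
            bin_width=tuple(config.density_bin_width),
        )
        tl, rl = np.meshgrid(dens.tilt_edges[:-1], dens.rotation_edges[:-1],
                             indexing="ij")
        return pd.DataFrame({
            "tilt_bin_left": tl.ravel(),
            "rotation_bin_left": rl.ravel(),
            "density": dens.density.ravel(),
        })

    emit(_density(), "tilt_rotation_density.csv")

    # -- convergence (full, ungated series) ---------------------------------------
    @_stage("convergence")
    def _convergence():
        if ori_all["trajectory"].isna().any():
            return None
        counts_all = _contacts.element_contact_counts(
            [_contacts.frame_contacts(c, dm, config.contact_cutoff)
             for c in ensemble], dm,
        ) if len(gated) != len(ensemble) else el_counts
        df = pd.concat([ori_all.reset_index(drop=True),
                        counts_all.reset_index(drop=True)], axis=1)
        quantities = (["tilt", "rotation"]
                      + [c for c in ori_all.columns if c.startswith("incl_")]
                      + list(el_counts.columns))
        return _stats.time_convergence(df, quantities)

    conv = _convergence()
    if conv is not None:
        emit(conv, "time_convergence.csv")

    # -- RMSD ---------------------------------------------------------------------
    if config.reference is not None:
        @_stage("rmsd")
        def _rmsd():
            ref = config.reference
            if not isinstance(ref, Conformation):
                ref = read_multimodel_pdb(ref)[0]
            series = _geometry.ca_rmsd(gated, ref, ["Calpha", "Cbeta",
                                                    "Valpha", "Vbeta"], dm)
            return pd.DataFrame({
                "trajectory": [c.source.trajectory_id if c.source else np.nan
                               for c in gated],
                "time_us": [c.source.time_us if c.source else np.nan
                            for c in gated],
                "rmsd_A": series,
            })

        emit(_rmsd(), "ca_rmsd.csv")

    # -- membrane -----------------------------------------------------------------
    has_lipids = bool(
        np.isin(gated[0].residue_names, list(_membrane.DEFAULT_LIPID_RESNAMES)).any()
    )
    if has_lipids:
        @_stage("membrane")
        def _thickness():
            return _membrane.thickness_series(gated, dm, config.lipid_cutoff)

        emit(_thickness(), "annulus_thickness.csv")

    # -- force model --------------------------------------------------------------
    @_stage("force_model")
    def _force_block():
        tilts = ori["tilt"].to_numpy()
        if len(tilts) >= 100:
            model = _force.empirical_p0(tilts, h=config.h_nm,
                                        T=config.temperature_K)
        else:  # too few samples for a KDE; use the moment-matched surrogate
            log.info("force_model: %d tilt samples, using Gaussian surrogate",
                     len(tilts))
            model = _force.gaussian_surrogate(
                float(tilts.mean()), float(tilts.std(ddof=1)),
                h=config.h_nm, T=config.temperature_K,
            )
        summary = _force.force_response_table(model, list(config.forces_pN))
        grid = pd.DataFrame({
            "tau_deg": np.degrees(model.tau), "P0": model.p0,
            "E0_pNnm": model.energy(0.0),
        })
        for f in config.forces_pN:
            grid[f"Pf_{f}pN"] = _force.reweight(model, f)
            grid[f"Ef_{f}pN_pNnm"] = model.energy(f)
        return summary, grid

    force_summary, force_grid = _force_block()
    emit(force_summary, "force_tilt_summary.csv")
    emit(force_grid, "force_tilt_grid.csv")

    manifest = {
        "config_hash": AnalysisConfig.hash(config),
        "n_frames_total": len(ensemble),
        "n_frames_gated": len(gated),
        "outputs": written,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    manifest["outputs"] = list(written)
    return manifest
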