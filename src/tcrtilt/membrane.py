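"""Lipid annulus around the TM domain and local bilayer thickness.

A POPC lipid belongs to the annulus of a frame when the minimum distance
between its non-hydrogen atoms and the non-hydrogen atoms of any TM-helix
residue is smaller than 0.5 nm.  Leaflets are assigned by the lipid
headgroup COM z relative to the bilayer midplane (mean headgroup z over all
lipids of the frame).  The annulus thickness is the z-distance between the
headgroup COMs of the two leaflets' annulus lipids.  Cholesterol (or any
non-POPC residue) is excluded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .constants import atomic_mass
from .structure_io import Conformation, DomainMap, Ensemble

DEFAULT_LIPID_CUTOFF = 0.5  # nm, strict
DEFAULT_LIPID_RESNAMES = ("POPC",)
# Phosphate + choline heavy atoms, Lipid14 naming; configurable because
# different force fields name headgroup atoms differently.
DEFAULT_HEADGROUP_ATOMS = (
    "P", "O11", "O12", "O13", "O14", "N", "C11", "C12", "C13", "C14", "C15",
)


class MembraneError(ValueError):
    pass


@dataclass
class AnnulusRecord:
    upper: list[tuple[str, int]]  # (chain, residue) lipid ids
    lower: list[tuple[str, int]]
    thickness: float | None = None  # nm
    source: object = None


def _lipid_ids(conf: Conformation, resnames) -> list[tuple[str, int]]:
    mask = np.isin(conf.residue_names, list(resnames))
    if not mask.any():
        raise MembraneError("no lipid residues present")
    ids = sorted(
        {(c, int(r)) for c, r in
         zip(conf.chain_ids[mask], conf.residue_indices[mask])}
    )
    return ids


def _headgroup_z(conf: Conformation, lipid: tuple[str, int], headgroup_atoms) -> float:
    mask = conf.select(chain_id=lipid[0], residue_index=lipid[1],
                       atom_names=headgroup_atoms, heavy_only=True)
    if not mask.any():
        raise MembraneError(f"lipid {lipid} has no headgroup atoms")
    m = np.array([atomic_mass(e) for e in conf.elements[mask]])
    return float(np.average(conf.positions[mask, 2], weights=m))


def annulus_lipids(
    conf: Conformation,
    domains: DomainMap,
    cutoff: float = DEFAULT_LIPID_CUTOFF,
    lipid_resnames=DEFAULT_LIPID_RESNAMES,
    headgroup_atoms=DEFAULT_HEADGROUP_ATOMS,
) -> AnnulusRecord:
    """Lipids in heavy-atom contact (< cutoff) with the TM domain, per leaflet."""
    lipids = _lipid_ids(conf, lipid_resnames)

    tm_mask = np.zeros(conf.n_atoms, bool)
    for span in domains.tm_helices.values():
        tm_mask |= conf.select(chain_id=span.chain_id,
                               residue_span=(span.start, span.end))
    tm_mask &= conf.heavy_mask
    if not tm_mask.any():
        raise MembraneError("no TM heavy atoms found")
    tree = cKDTree(conf.positions[tm_mask])

    head_z = {lip: _headgroup_z(conf, lip, headgroup_atoms) for lip in lipids}
    midplane = float(np.mean(list(head_z.values())))

    upper, lower = [], []
    for lip in lipids:
        mask = conf.select(chain_id=lip[0], residue_index=lip[1], heavy_only=True)
        d, _ = tree.query(conf.positions[mask], k=1)
        if d.min() < cutoff:  # strict
            (upper if head_z[lip] >= midplane else lower).append(lip)
    return AnnulusRecord(upper=upper, lower=lower, source=conf.source)


def annulus_thickness(
    conf: Conformation,
    annulus: AnnulusRecord,
    headgroup_atoms=DEFAULT_HEADGROUP_ATOMS,
) -> float:
    """|z(upper-leaflet headgroup COM) - z(lower)| of the annulus lipids, nm."""
    if not annulus.upper or not annulus.lower:
        raise MembraneError("annulus is one-sided; cannot measure a thickness")

    def _leaflet_z(lipids) -> float:
        zs, ws = [], []
        for lip in lipids:
            mask = conf.select(chain_id=lip[0], residue_index=lip[1],
                               atom_names=headgroup_atoms, heavy_only=True)
            if not mask.any():
                raise MembraneError(f"lipid {lip} has no headgroup atoms")
            zs.append(conf.positions[mask, 2])
            ws.append([atomic_mass(e) for e in conf.elements[mask]])
        z = np.concatenate(zs)
        w = np.concatenate([np.asarray(x) for x in ws])
        return float(np.average(z, weights=w))

    return abs(_leaflet_z(annulus.upper) - _leaflet_z(annulus.lower))


def thickness_series(
    ensemble: Ensemble,
    domains: DomainMap,
    cutoff: float = DEFAULT_LIPID_CUTOFF,
    lipid_resnames=DEFAULT_LIPID_RESNAMES,
    headgroup_atoms=DEFAULT_HEADGROUP_ATOMS,
) -> pd.DataFrame:
    """Per-frame annulus sizes and thickness for a lipid-containing ensemble."""
    rows = []
    for conf in ensemble:
        ann = annulus_lipids(conf, domains, cutoff, lipid_resnames, headgroup_atoms)
        ann.thickness = annulus_thickness(conf, ann, headgroup_atoms)
        rows.append(
            {
                "trajectory": conf.source.trajectory_id if conf.source else np.nan,
                "time_us": conf.source.time_us if conf.source else np.nan,
                "n_upper": len(ann.upper),
                "n_lower": len(ann.lower),
                "thickness_nm": ann.thickness,
            }
        )
    return pd.DataFrame(rows)
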