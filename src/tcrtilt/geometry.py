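"""Orientation geometry of the TCRab EC domain and the TM helices.

The orientation of the TCRab extracellular (EC) domain relative to the
membrane is described by two angles derived from two axes:

* axis A runs from the centre of mass (COM) of the constant-domain dimer
  Cab = Calpha u Cbeta to the COM of the variable-domain dimer
  Vab = Valpha u Vbeta;
* axis B runs from the COM of Valpha to the COM of Vbeta.

The tilt angle is the angle between axis A and the membrane normal (+z).
The rotation angle is the angle between axis B and the normal of the plane
spanned by axis A and the membrane normal, folded to [0, 90] degrees and
signed: positive when Valpha's COM is closer to the membrane midplane than
Vbeta's.  A TM helix's inclination is the angle between the membrane normal
and the line connecting the COMs of the two halves of its residue span.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .constants import ANGSTROM_PER_NM, atomic_mass
from .structure_io import Conformation, DomainMap, Ensemble, Span


class GeometryError(ValueError):
    pass


def _angle_deg(u: np.ndarray, v: np.ndarray) -> float:
    """Angle between two vectors in degrees, via a clamped dot product."""
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise GeometryError("angle of zero-length vector")
    c = float(np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0))
    return float(np.degrees(np.arccos(c)))


def _masses(conf: Conformation, mask: np.ndarray) -> np.ndarray:
    return np.array([atomic_mass(e) for e in conf.elements[mask]])


def _resolve_selection(
    conf: Conformation,
    selection,
    domains: DomainMap | None,
) -> np.ndarray:
    """Selection -> boolean atom mask.

    ``selection`` may be a domain/element/TM-helix name (needs ``domains``),
    a :class:`Span`, a (chain_id, (start, end)) tuple, or a list of several
    such items (union).
    """
    if isinstance(selection, (list, tuple)) and selection and not (
        isinstance(selection, tuple) and len(selection) == 2
        and isinstance(selection[0], str) and isinstance(selection[1], tuple)
    ):
        mask = np.zeros(conf.n_atoms, bool)
        for item in selection:
            mask |= _resolve_selection(conf, item, domains)
        return mask
    if isinstance(selection, str):
        if domains is None:
            raise GeometryError("named selection requires a DomainMap")
        selection = domains.span_of(selection)
    if isinstance(selection, Span):
        return conf.select(chain_id=selection.chain_id,
                           residue_span=(selection.start, selection.end))
    if isinstance(selection, tuple) and len(selection) == 2:
        chain, span = selection
        return conf.select(chain_id=chain, residue_span=tuple(span))
    raise GeometryError(f"cannot interpret selection {selection!r}")


def center_of_mass(
    conf: Conformation,
    selection,
    domains: DomainMap | None = None,
    include_hydrogens: bool = True,
) -> np.ndarray:
    """Mass-weighted mean position (nm) of a selection.

    All atoms of the selection are weighted by their standard atomic masses;
    hydrogens are included by default (documented switch).
    """
    mask = _resolve_selection(conf, selection, domains)
    if not include_hydrogens:
        mask = mask & conf.heavy_mask
    if not mask.any():
        raise GeometryError(f"selection {selection!r} resolves to no atoms")
    m = _masses(conf, mask)
    return np.average(conf.positions[mask], axis=0, weights=m)


MIN_AXIS_LENGTH = 0.1  # nm; shorter pre-normalization axes are degenerate


def tcr_axes(conf: Conformation, domains: DomainMap) -> tuple[np.ndarray, np.ndarray]:
    """Unit axes (A, B) of the TCRab EC domain.

    A points from COM(Cab) to COM(Vab); B from COM(Valpha) to COM(Vbeta).
    """
    com_c = center_of_mass(conf, ["Calpha", "Cbeta"], domains)
    com_v = center_of_mass(conf, ["Valpha", "Vbeta"], domains)
    com_va = center_of_mass(conf, "Valpha", domains)
    com_vb = center_of_mass(conf, "Vbeta", domains)
    a = com_v - com_c
    b = com_vb - com_va
    for name, vec in (("A", a), ("B", b)):
        if np.linalg.norm(vec) < MIN_AXIS_LENGTH:
            raise GeometryError(f"degenerate axis {name}: length < {MIN_AXIS_LENGTH} nm")
    return a / np.linalg.norm(a), b / np.linalg.norm(b)


@dataclass
class OrientationRecord:
    tilt: float  # degrees
    rotation: float  # signed degrees; NaN when axis A || membrane normal
    inter_axis_angle: float  # degrees
    helix_inclinations: dict[str, float] = field(default_factory=dict)
    source: object = None


def helix_inclination(conf: Conformation, helix_span: Span | tuple) -> float:
    """Inclination (degrees in [0, 90]) of a TM helix span.

    The span is split into two halves (first half gets floor(n/2) residues);
    the inclination is the angle between the membrane normal and the line
    connecting the COMs of the halves, folded to [0, 90].
    """
    if isinstance(helix_span, tuple):
        helix_span = Span(helix_span[0], *helix_span[1])
    residues = np.unique(
        conf.residue_indices[conf.select(chain_id=helix_span.chain_id,
                                         residue_span=(helix_span.start, helix_span.end))]
    )
    if len(residues) < 2:
        raise GeometryError("helix span must contain at least two residues")
    half = len(residues) // 2
    first, second = residues[:half], residues[half:]

    def _com(res: np.ndarray) -> np.ndarray:
        mask = conf.select(chain_id=helix_span.chain_id) & np.isin(
            conf.residue_indices, res
        )
        m = _masses(conf, mask)
        return np.average(conf.positions[mask], axis=0, weights=m)

    line = _com(second) - _com(first)
    ang = _angle_deg(line, conf.membrane_normal)
    return min(ang, 180.0 - ang)


PARALLEL_TOL_RAD = 1e-6


def orientation(conf: Conformation, domains: DomainMap) -> OrientationRecord:
    """Tilt, signed rotation, inter-axis angle and TM inclinations of a frame.

    When axis A is parallel to the membrane normal (within 1e-6 rad), the
    rotation is undefined and reported as NaN while the tilt stays valid.
    """
    a, b = tcr_axes(conf, domains)
    n = conf.membrane_normal
    tilt = _angle_deg(a, n)
    inter = _angle_deg(a, b)

    n_plane = np.cross(a, n)
    if np.linalg.norm(n_plane) < PARALLEL_TOL_RAD:
        rotation = float("nan")
    else:
        n_plane = n_plane / np.linalg.norm(n_plane)
        ang = _angle_deg(b, n_plane)
        mag = min(ang, 180.0 - ang)  # fold to [0, 90]
        midz = conf.membrane_midplane_z if conf.membrane_midplane_z is not None else 0.0
        z_va = center_of_mass(conf, "Valpha", domains)[2]
        z_vb = center_of_mass(conf, "Vbeta", domains)[2]
        d_va, d_vb = abs(z_va - midz), abs(z_vb - midz)
        sign = 1.0 if d_va < d_vb else (-1.0 if d_vb < d_va else 1.0)
        rotation = sign * mag

    inclinations = {
        chain: helix_inclination(conf, span)
        for chain, span in domains.tm_helices.items()
    }
    return OrientationRecord(
        tilt=tilt,
        rotation=rotation,
        inter_axis_angle=inter,
        helix_inclinations=inclinations,
        source=conf.source,
    )


# ---------------------------------------------------------------------------
# superposition / RMSD
# ---------------------------------------------------------------------------


def _paired_coordinates(
    mobile: Conformation,
    reference: Conformation,
    selection,
    domains: DomainMap | None,
    ca_only: bool,
) -> tuple[np.ndarray, np.ndarray]:
    mm = _resolve_selection(mobile, selection, domains)
    rm = _resolve_selection(reference, selection, domains)
    if ca_only:
        mm &= mobile.atom_names == "CA"
        rm &= reference.atom_names == "CA"

    def _keys(conf: Conformation, mask: np.ndarray):
        idx = np.flatnonzero(mask)
        return {
            (conf.chain_ids[i], int(conf.residue_indices[i]), conf.atom_names[i]): i
            for i in idx
        }

    kmob, kref = _keys(mobile, mm), _keys(reference, rm)
    common = sorted(set(kmob) & set(kref))
    mismatched = sorted(set(kmob) ^ set(kref))
    if mismatched:
        raise GeometryError(
            f"atom correspondence mismatch for {len(mismatched)} atoms, "
            f"e.g. {mismatched[:5]}"
        )
    if len(common) < 3:
        raise GeometryError("superposition needs at least 3 paired atoms")
    x = np.array([mobile.positions[kmob[k]] for k in common])
    y = np.array([reference.positions[kref[k]] for k in common])
    return x, y


def superpose(
    mobile: Conformation,
    reference: Conformation,
    selection,
    domains: DomainMap | None = None,
    ca_only: bool = True,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Atoms are paired by (chain, residue, atom name) within ``selection``.
    Returns (rotation matrix, translation, RMSD in Angstrom); the transform
    maps mobile coordinates as x -> R x + t.  Kabsch with a determinant
    correction, so no reflections.
    """
    x, y = _paired_coordinates(mobile, reference, selection, domains, ca_only)
    xc, yc = x.mean(axis=0), y.mean(axis=0)
    h = (x - xc).T @ (y - yc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    t = yc - rot @ xc
    fitted = (x @ rot.T) + t
    rmsd_nm = float(np.sqrt(np.mean(np.sum((fitted - y) ** 2, axis=1))))
    return rot, t, rmsd_nm * ANGSTROM_PER_NM


def ca_rmsd(
    ensemble: Ensemble,
    reference: Conformation,
    domain,
    domains: DomainMap | None = None,
) -> np.ndarray:
    """Per-frame C-alpha RMSD (Angstrom) to a reference after domain fit."""
    out = np.empty(len(ensemble))
    for k, conf in enumerate(ensemble):
        _, _, rmsd = superpose(conf, reference, domain, domains, ca_only=True)
        out[k] = rmsd
    return out


def orient_reference_by_tm(
    reference: Conformation,
    frames: Ensemble,
    domains: DomainMap,
) -> list[OrientationRecord]:
    """Orientation of a reference structure embedded by TM-domain alignment.

    The reference (e.g. a detergent-solubilized cryo-EM structure without a
    membrane frame) is rigidly superposed, via the C-alpha atoms of all eight
    annotated TM spans jointly, onto each frame of a membrane-embedded
    ensemble; its tilt/rotation are then measured in that frame's membrane
    frame.  The spread over frames gives the error of the mean.
    """
    tm_selection = list(domains.tm_helices.values())
    records = []
    for conf in frames:
        rot, t, _ = superpose(reference, conf, tm_selection, domains, ca_only=True)
        placed = reference.transformed(rot, t)
        placed.membrane_midplane_z = conf.membrane_midplane_z
        rec = orientation(placed, domains)
        rec.source = conf.source
        records.append(rec)
    return records
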