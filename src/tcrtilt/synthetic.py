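"""Synthetic structure ensembles with known ground truth.

The generator emulates the statistical structure of an equilibrated
membrane-embedded TCR-CD3 simulation ensemble -- not its physics.  Per frame
it samples

* a tilt angle from a truncated Gaussian (default mean 33.4 deg, SD 8.9 deg,
  the equilibrated simulation moments), optionally with an initial-mean
  relaxation to emulate equilibration time series;
* a rotation angle linearly coupled to tilt plus Gaussian noise (the
  tilt-rotation coupling of the 2D density);
* per-chain TM-helix inclinations linearly coupled to tilt plus noise;
* per-element contact occupancy flags with tilt-dependent (logistic,
  optionally hard-gated) probabilities;

and then *constructs coordinates* realizing those values exactly: rigid
pseudo-atom clusters for the Calpha/Cbeta/Valpha/Vbeta and CD3 EC domains
placed so the geometry module recovers the sampled tilt/rotation, straight
poly-alanine-like TM helices at the sampled inclinations, contact-bead
residues at 0.40 nm (occupied) or 0.60 nm (unoccupied) from their CD3
partner residues, and a toy annular bilayer with headgroup beads at
prescribed z-offsets.  Contacts are planted geometrically so the contact
detector itself is exercised.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .structure_io import Conformation, DomainMap, Ensemble, SourceLabel, load_domain_map


class SyntheticError(ValueError):
    pass


# ---------------------------------------------------------------------------
# statistical laws
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TiltLaw:
    mean: float = 33.4  # deg
    sd: float = 8.9
    lo: float = 1.0
    hi: float = 89.0
    # optional equilibration drift: the mean relaxes from mean0 to mean
    mean0: float | None = None
    relax_time_us: float = 0.15

    def mean_at(self, t_us: float) -> float:
        if self.mean0 is None:
            return self.mean
        return self.mean + (self.mean0 - self.mean) * np.exp(-t_us / self.relax_time_us)


@dataclass(frozen=True)
class LinearLaw:
    intercept: float
    slope: float
    noise_sd: float = 0.0

    def mean_at(self, tilt: np.ndarray) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(tilt, float)


@dataclass(frozen=True)
class ContactLaw:
    """Occupancy probability as a function of tilt (degrees).

    ``width`` > 0 gives an increasing logistic, < 0 decreasing, ``None`` a
    tilt-independent probability ``p_max``.  ``gated`` forces zero occupancy
    at tilts at or below the midpoint (hard gate), on top of the logistic.
    """

    p_max: float = 1.0
    midpoint: float | None = 30.0
    width: float | None = 3.0
    gated: bool = False

    def probability(self, tilt: np.ndarray) -> np.ndarray:
        tilt = np.asarray(tilt, float)
        if not 0.0 <= self.p_max <= 1.0:
            raise SyntheticError("p_max must lie in [0, 1]")
        if self.width is None or self.midpoint is None:
            p = np.full_like(tilt, self.p_max)
        else:
            p = self.p_max / (1.0 + np.exp(-(tilt - self.midpoint) / self.width))
        if self.gated and self.midpoint is not None:
            p = np.where(tilt <= self.midpoint, 0.0, p)
        return p


def _default_inclination_laws() -> dict[str, LinearLaw]:
    # anchored to the reported tilt-coupled TM profiles: TCRalpha decreases
    # ~11.5 -> 8.5 deg, CD3gamma increases ~15.5 -> 24 deg, the epsilon chain
    # of the gamma dimer ~19 -> 22 deg over tilt 15 -> 50 deg; the other
    # helices are tilt-independent.
    return {
        "TCRalpha": LinearLaw(12.79, -0.0857, 2.0),
        "TCRbeta": LinearLaw(13.0, 0.0, 2.0),
        "CD3epsilon_g": LinearLaw(17.71, 0.0857, 2.0),
        "CD3gamma": LinearLaw(11.86, 0.2429, 2.0),
        "CD3epsilon_d": LinearLaw(15.0, 0.0, 2.0),
        "CD3delta": LinearLaw(18.0, 0.0, 2.0),
        "CD3zeta": LinearLaw(10.0, 0.0, 2.0),
        "CD3zeta_prime": LinearLaw(10.0, 0.0, 2.0),
    }


def _default_contact_laws() -> dict[str, ContactLaw]:
    # Valpha loop contacts exist only above ~30 deg tilt (hard gate); the
    # Cbeta FG loop (and several constant-domain elements) lose contacts
    # with increasing tilt; DE/EF are tilt-independent.
    return {
        "Valpha A'B loop": ContactLaw(0.8, 30.0, 3.0, gated=True),
        "Valpha C''D loop": ContactLaw(0.8, 30.0, 3.0, gated=True),
        "Valpha EF loop": ContactLaw(0.8, 30.0, 3.0, gated=True),
        "Calpha AB loop": ContactLaw(0.6, 32.0, -5.0),
        "Calpha DE loop": ContactLaw(0.7, None, None),
        "Cbeta A strand": ContactLaw(0.5, 32.0, -5.0),
        "Cbeta B strand": ContactLaw(0.4, None, None),
        "Cbeta CC' loop": ContactLaw(0.6, 32.0, -5.0),
        "Cbeta EF loop": ContactLaw(0.7, None, None),
        "Cbeta FG loop": ContactLaw(1.0, 30.0, -4.0),
        "Cbeta G strand": ContactLaw(0.5, 32.0, -5.0),
    }


@dataclass(frozen=True)
class BilayerSpec:
    leaflet_z: float = 1.9  # headgroup |z| offset, nm (POPC-like ~3.8 nm bilayer)
    scatter: float = 0.1  # per-lipid headgroup z noise SD, nm
    n_inner: int = 4  # annulus lipids per leaflet
    n_outer: int = 4  # bulk lipids per leaflet (outside the 0.5 nm cutoff)


@dataclass(frozen=True)
class SyntheticSpec:
    """Stated world of the fixture ensemble; the seed fully determines output."""

    n_trajectories: int = 120
    n_frames: int = 50
    seed: int = 0
    t_start_us: float = 0.51
    dt_us: float = 0.01
    tilt: TiltLaw = TiltLaw()
    rotation: LinearLaw = LinearLaw(0.0, 0.8, 8.0)
    inclinations: dict[str, LinearLaw] = field(default_factory=_default_inclination_laws)
    contact_laws: dict[str, ContactLaw] = field(default_factory=_default_contact_laws)
    bilayer: BilayerSpec = BilayerSpec()
    include_lipids: bool = True

    def __post_init__(self):
        if self.tilt.sd < 0 or self.rotation.noise_sd < 0:
            raise SyntheticError("noise SDs must be non-negative")
        for law in self.inclinations.values():
            if law.noise_sd < 0:
                raise SyntheticError("noise SDs must be non-negative")


def sample_frames(spec: SyntheticSpec) -> pd.DataFrame:
    """Sample the per-frame ground-truth table (no coordinates).

    Columns: trajectory, time_us, tilt, rotation, incl_<chain>, occ_<element>.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_trajectories * spec.n_frames
    traj = np.repeat(np.arange(1, spec.n_trajectories + 1), spec.n_frames)
    times = np.tile(
        spec.t_start_us + spec.dt_us * np.arange(spec.n_frames), spec.n_trajectories
    )

    tl = spec.tilt
    a = (tl.lo - tl.mean) / tl.sd
    b = (tl.hi - tl.mean) / tl.sd
    tilt = stats.truncnorm.rvs(a, b, loc=tl.mean, scale=tl.sd, size=n, random_state=rng)
    if tl.mean0 is not None:
        tilt = tilt - tl.mean + np.array([tl.mean_at(t) for t in times])
        tilt = np.clip(tilt, tl.lo, tl.hi)

    rot = spec.rotation.mean_at(tilt) + rng.normal(0, spec.rotation.noise_sd, n)
    rot = np.clip(rot, -89.0, 89.0)

    data = {"trajectory": traj, "time_us": times, "tilt": tilt, "rotation": rot}
    for chain, law in spec.inclinations.items():
        inc = law.mean_at(tilt) + rng.normal(0, law.noise_sd, n)
        data[f"incl_{chain}"] = np.clip(inc, 0.5, 89.0)
    for element, law in spec.contact_laws.items():
        p = law.probability(tilt)
        data[f"occ_{element}"] = (rng.random(n) < p).astype(int)
    return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# coordinate construction
# ---------------------------------------------------------------------------

# EC-domain placement geometry (nm): the constant dimer COM sits Z_BASE above
# the bilayer midplane, axis A has length L_A, the variable and constant
# domains are D_V and D_C apart within their dimers.
Z_BASE = 3.5
L_A = 4.0
D_V = 3.0
D_C = 2.5
SPIKE_LEN = 1.2  # contact-bead residues sit on spikes off the domain body
CONTACT_NM = 0.40
NO_CONTACT_NM = 0.60
BODY_RADIUS = 0.35
TM_CIRCLE_R = 1.0
TM_HALF_LEN = 1.6
TM_N_RES = 24

# which CD3 residue each element's planted contact partner is
PARTNER_RESIDUES = {
    "Valpha A'B loop": ("D", 10),
    "Valpha C''D loop": ("D", 30),
    "Valpha EF loop": ("D", 50),
    "Calpha AB loop": ("E", 20),
    "Calpha DE loop": ("F", 20),
    "Cbeta A strand": ("E", 40),
    "Cbeta B strand": ("E", 60),
    "Cbeta CC' loop": ("F", 40),
    "Cbeta EF loop": ("E", 80),
    "Cbeta FG loop": ("G", 6),
    "Cbeta G strand": ("G", 30),
}

# fixed far-away anchors for the CD3 EC bodies and the zeta stubs
_BODY_ANCHORS = {
    "CD3epsilon_g": np.array([6.0, 6.0, 2.0]),
    "CD3gamma": np.array([7.5, 6.0, 2.0]),
    "CD3epsilon_d": np.array([-6.0, 6.0, 2.0]),
    "CD3delta": np.array([-7.5, 6.0, 2.0]),
    "CD3zeta": np.array([0.0, -6.0, 2.5]),
    "CD3zeta_prime": np.array([0.0, -7.5, 2.5]),
}

_TM_CHAIN_ORDER = [
    "TCRalpha", "TCRbeta", "CD3epsilon_g", "CD3gamma",
    "CD3epsilon_d", "CD3delta", "CD3zeta", "CD3zeta_prime",
]


def _sphere_points(n: int, radius: float) -> np.ndarray:
    """n deterministic points roughly uniform in a ball (golden spiral shells)."""
    k = np.arange(n)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * k
    z = 1.0 - 2.0 * (k + 0.5) / n
    r_xy = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    shell = radius * ((k % 3 + 1) / 3.0)
    return np.column_stack([shell * r_xy * np.cos(phi),
                            shell * r_xy * np.sin(phi),
                            shell * z])


class _Template:
    """Frame-independent atom metadata and body offsets for one DomainMap."""

    def __init__(self, dm: DomainMap, include_lipids: bool, bilayer: BilayerSpec):
        self.dm = dm
        chain_ids: list[str] = []
        res_idx: list[int] = []
        res_names: list[str] = []
        atom_names: list[str] = []
        elements: list[str] = []
        self.body_offset = []  # per-atom offset within its domain body (or 0)
        self.domain_of = []  # per-atom domain name or None
        self.atom_index: dict[tuple[str, int], int] = {}  # (chain,res)->CA index

        element_residues = {}  # (chain, res) -> element name, pulled onto spikes
        for el, span in dm.elements.items():
            mid = (span.start + span.end) // 2
            element_residues[(span.chain_id, mid)] = el
        self.spike_residue = {el: key for key, el in element_residues.items()}
        partner_set = set(PARTNER_RESIDUES.values())

        def add_atom(chain, resi, resname, name, elem, domain, offset):
            self.atom_index.setdefault((chain, resi), len(chain_ids))
            chain_ids.append(chain)
            res_idx.append(resi)
            res_names.append(resname)
            atom_names.append(name)
            elements.append(elem)
            self.domain_of.append(domain)
            self.body_offset.append(offset)

        for dom, span in dm.domains.items():
            residues = list(range(span.start, span.end + 1))
            pts = _sphere_points(len(residues), BODY_RADIUS)
            for resi, off in zip(residues, pts):
                key = (span.chain_id, resi)
                if key in element_residues or key in partner_set:
                    off = np.zeros(3)  # positioned per frame (spike / partner)
                add_atom(span.chain_id, resi, "ALA", "CA", "C", dom, off)
            # one hydrogen per domain exercises the heavy-atom filters
            add_atom(span.chain_id, residues[0], "ALA", "HA", "H", dom,
                     pts[0] + np.array([0.05, 0.0, 0.0]))
        for chain_name, span in dm.tm_helices.items():
            for resi in range(span.start, span.end + 1):
                add_atom(span.chain_id, resi, "ALA", "CA", "C",
                         f"TM {chain_name}", np.zeros(3))

        self.n_lipids = 0
        self.lipid_meta = []  # (leaflet +-1, azimuth, radius, inner flag)
        if include_lipids:
            azim = np.arange(8) * (2 * np.pi / 8)
            lip = 0
            for leaflet in (+1, -1):
                inner_az = azim[0::2] if leaflet > 0 else azim[1::2]
                for k in range(bilayer.n_inner):
                    lip += 1
                    self._add_lipid(add_atom, lip)
                    self.lipid_meta.append((leaflet, inner_az[k % len(inner_az)], 1.3, True))
                for k in range(bilayer.n_outer):
                    lip += 1
                    self._add_lipid(add_atom, lip)
                    self.lipid_meta.append(
                        (leaflet, azim[k % 8] + np.pi / 8, 3.5, False)
                    )
            self.n_lipids = lip

        self.chain_ids = np.array(chain_ids, dtype=object)
        self.res_idx = np.array(res_idx, dtype=np.int64)
        self.res_names = np.array(res_names, dtype=object)
        self.atom_names = np.array(atom_names, dtype=object)
        self.elements = np.array(elements, dtype=object)
        self.body_offset = np.array(self.body_offset, dtype=float)
        self.n_atoms = len(chain_ids)

        # masses for exact COM placement (CA carbons + one H per domain)
        from .constants import atomic_mass

        self.masses = np.array([atomic_mass(e) for e in self.elements])
        self.domain_atoms = {}
        for dom in dm.domains:
            self.domain_atoms[dom] = np.array(
                [i for i, d in enumerate(self.domain_of) if d == dom]
            )

    LIPID_ATOMS = (
        ("P", "P"), ("O11", "O"), ("N", "N"), ("C13", "C"),  # headgroup
        ("C22", "C"), ("C32", "C"),  # tail beads
    )

    def _add_lipid(self, add_atom, resi: int):
        for name, elem in self.LIPID_ATOMS:
            add_atom("L", resi, "POPC", name, elem, None, np.zeros(3))


# spike directions per element, expressed in the local frame (e1, q, e3)
# of the TCRab EC domain; all are perpendicular to the within-dimer
# separation axes so planted beads never collide with other domains.
def _spike_directions(e1, q, e3) -> dict[str, np.ndarray]:
    dirs = {
        "Valpha A'B loop": e1,
        "Valpha C''D loop": e3,
        "Valpha EF loop": -e3,
        "Calpha AB loop": q,
        "Calpha DE loop": -q,
    }
    cbeta = ["Cbeta A strand", "Cbeta B strand", "Cbeta CC' loop",
             "Cbeta EF loop", "Cbeta FG loop", "Cbeta G strand"]
    for k, el in enumerate(cbeta):
        th = np.deg2rad(60.0 * k)
        dirs[el] = np.cos(th) * e1 + np.sin(th) * q
    return dirs


def build_frame(
    dm: DomainMap,
    tilt_deg: float,
    rotation_deg: float,
    inclinations_deg: dict[str, float],
    occupancy: dict[str, int] | None = None,
    template: _Template | None = None,
    bilayer: BilayerSpec | None = None,
    lipid_head_noise: np.ndarray | None = None,
    source: SourceLabel | None = None,
) -> Conformation:
    """Construct one conformation realizing the given angles exactly.

    Raises for tilt or inclinations outside [0, 90] degrees.
    """
    if not 0.0 <= tilt_deg <= 90.0:
        raise SyntheticError(f"tilt {tilt_deg} outside [0, 90] degrees")
    for ch, inc in inclinations_deg.items():
        if not 0.0 <= inc <= 90.0:
            raise SyntheticError(f"inclination {inc} ({ch}) outside [0, 90] degrees")
    if template is None:
        template = _Template(dm, include_lipids=bilayer is not None,
                             bilayer=bilayer or BilayerSpec())
    occupancy = occupancy or {}
    tau = np.deg2rad(tilt_deg)
    rho = np.deg2rad(rotation_deg)

    # local frame of the TCRab EC domain (all unit, mutually orthogonal)
    a = np.array([np.sin(tau), 0.0, np.cos(tau)])  # axis A direction
    u = np.array([0.0, -1.0, 0.0])  # normalize(a x z)
    v = np.cross(u, a)
    b = np.cos(rho) * u + np.sin(rho) * v  # axis B direction
    e3 = np.cross(a, b)
    q = -np.sin(rho) * b + np.cos(rho) * e3  # in-plane direction, perp. to u

    p_c = np.array([0.0, 0.0, Z_BASE])  # COM of Calpha u Cbeta
    p_v = p_c + L_A * a  # COM of Valpha u Vbeta

    # domain clusters have unequal total masses (span lengths differ), so the
    # paired offsets are mass-weighted to keep the *union* COM on axis A
    def _pair_offsets(dom_a: str, dom_b: str, sep: float):
        m_a = template.masses[template.domain_atoms[dom_a]].sum()
        m_b = template.masses[template.domain_atoms[dom_b]].sum()
        return -sep * m_b / (m_a + m_b), sep * m_a / (m_a + m_b)

    off_va, off_vb = _pair_offsets("Valpha", "Vbeta", D_V)
    off_ca, off_cb = _pair_offsets("Calpha", "Cbeta", D_C)
    com_targets = {
        "Valpha": p_v + off_va * b,
        "Vbeta": p_v + off_vb * b,
        "Calpha": p_c + off_ca * u,
        "Cbeta": p_c + off_cb * u,
    }
    for dom, anchor in _BODY_ANCHORS.items():
        com_targets[dom] = anchor

    pos = np.zeros((template.n_atoms, 3))
    spike_dirs = _spike_directions(a, q, e3)

    # spike offsets relative to the parent-domain COM target
    spike_offsets: dict[str, tuple[int, np.ndarray, str]] = {}
    for el, (chain, resi) in template.spike_residue.items():
        idx = template.atom_index[(chain, resi)]
        parent = template.domain_of[idx]
        spike_offsets[el] = (idx, SPIKE_LEN * spike_dirs[el], parent)

    # exact COM placement: shift each domain so its mass-weighted COM
    # (body + spike atoms) lands on the target
    for dom, atoms in template.domain_atoms.items():
        target = com_targets[dom]
        offs = template.body_offset[atoms].copy()
        local = {i: k for k, i in enumerate(atoms)}
        for el, (idx, off, parent) in spike_offsets.items():
            if parent == dom:
                offs[local[idx]] = off
        m = template.masses[atoms]
        centroid = np.average(offs, axis=0, weights=m)
        pos[atoms] = target + (offs - centroid)

    # CD3 partner beads sit on the spikes at the planted distance
    for el, (idx, off, parent) in spike_offsets.items():
        chain_p, res_p = PARTNER_RESIDUES[el]
        pidx = template.atom_index[(chain_p, res_p)]
        dist = CONTACT_NM if occupancy.get(el, 0) else NO_CONTACT_NM
        direction = spike_dirs[el]
        pos[pidx] = pos[idx] + dist * direction

    # TM helices: straight CA traces through fixed membrane anchors
    for k, chain_name in enumerate(_TM_CHAIN_ORDER):
        span = dm.tm_helices[chain_name]
        inc = np.deg2rad(inclinations_deg.get(chain_name, 10.0))
        phi = 2 * np.pi * k / 8
        center = np.array([TM_CIRCLE_R * np.cos(phi), TM_CIRCLE_R * np.sin(phi), 0.0])
        axis = np.array(
            [np.sin(inc) * np.cos(phi), np.sin(inc) * np.sin(phi), np.cos(inc)]
        )
        s = np.linspace(-TM_HALF_LEN, TM_HALF_LEN, TM_N_RES)
        coords = center[None, :] + s[:, None] * axis[None, :]
        for j, resi in enumerate(range(span.start, span.end + 1)):
            pos[template.atom_index[(span.chain_id, resi)]] = coords[min(j, TM_N_RES - 1)]

    # toy bilayer
    if template.n_lipids:
        bl = bilayer or BilayerSpec()
        noise = (
            lipid_head_noise
            if lipid_head_noise is not None
            else np.zeros(template.n_lipids)
        )
        for lip, (leaflet, az, radius, inner) in enumerate(template.lipid_meta, start=1):
            xy = np.array([radius * np.cos(az), radius * np.sin(az)])
            zh = leaflet * bl.leaflet_z + noise[lip - 1]
            base = template.atom_index[("L", lip)]
            head = np.array([
                [xy[0], xy[1], zh],
                [xy[0] + 0.05, xy[1], zh],
                [xy[0], xy[1] + 0.05, zh],
                [xy[0], xy[1], zh + 0.05 * leaflet],
            ])
            tail_z = 0.0 if inner else 0.5 * leaflet
            tails = np.array([
                [xy[0], xy[1], leaflet * 0.9],
                [xy[0], xy[1], tail_z],
            ])
            pos[base:base + 4] = head
            pos[base + 4:base + 6] = tails

    return Conformation(
        template.chain_ids, template.res_idx, template.res_names,
        template.atom_names, template.elements, pos,
        membrane_midplane_z=0.0, source=source,
    )


def build_ensemble(
    spec: SyntheticSpec,
    dm: DomainMap | None = None,
    truth: pd.DataFrame | None = None,
) -> tuple[Ensemble, pd.DataFrame]:
    """Sample a ground-truth table and realize it as a structure ensemble."""
    if dm is None:
        dm = load_domain_map()
    if truth is None:
        truth = sample_frames(spec)
    template = _Template(dm, spec.include_lipids, spec.bilayer)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 7]))
    incl_cols = {c: c[len("incl_"):] for c in truth.columns if c.startswith("incl_")}
    occ_cols = {c: c[len("occ_"):] for c in truth.columns if c.startswith("occ_")}
    conformations = []
    for _, row in truth.iterrows():
        noise = (
            rng.normal(0.0, spec.bilayer.scatter, template.n_lipids)
            if template.n_lipids
            else None
        )
        conf = build_frame(
            dm,
            float(row["tilt"]),
            float(row["rotation"]),
            {name: float(row[c]) for c, name in incl_cols.items()},
            {name: int(row[c]) for c, name in occ_cols.items()},
            template=template,
            bilayer=spec.bilayer if spec.include_lipids else None,
            lipid_head_noise=noise,
            source=SourceLabel(int(row["trajectory"]), float(row["time_us"])),
        )
        conformations.append(conf)
    meta = {
        "n_trajectories": spec.n_trajectories,
        "n_frames_per_trajectory": spec.n_frames,
        "sampling_interval_us": spec.dt_us,
        "seed": spec.seed,
    }
    return Ensemble(conformations, metadata=meta), truth
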