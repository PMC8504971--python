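"""Inter-dimer residue contacts, probability maps, clusters and correlations.

Two residues from different EC dimers (TCRab, CD3ed, CD3eg) are in contact in
a frame when the minimum distance between their non-hydrogen atoms is smaller
than 0.45 nm (strict inequality).  Ensemble contact probabilities are
occurrence fractions; the reported map keeps pairs with probability strictly
above a threshold (default 0.5%), while raw counts are always retained so
other thresholds can be re-derived.  Contacts group into clusters: connected
components of reported pairs under a Chebyshev adjacency in residue-index
space, a heuristic stand-in for the visually grouped loop/strand interactions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .structure_io import Conformation, DomainMap, Ensemble, DIMER_ORDER

DEFAULT_CONTACT_CUTOFF = 0.45  # nm, strict
DEFAULT_PROB_THRESHOLD = 0.005  # report only probabilities strictly above

# a contact pair: ((dimerA, dimerB), (chainA, resA), (chainB, resB))
PairKey = tuple[tuple[str, str], tuple[str, int], tuple[str, int]]


class ContactError(ValueError):
    pass


def residue_min_distance(
    conf: Conformation,
    res_a: tuple[str, int],
    res_b: tuple[str, int],
    heavy_only: bool = True,
) -> float:
    """Minimum inter-atomic distance (nm) between two residues."""
    masks = []
    for chain, resi in (res_a, res_b):
        m = conf.select(chain_id=chain, residue_index=resi, heavy_only=heavy_only)
        if not m.any():
            kind = "heavy atoms" if heavy_only else "atoms"
            raise ContactError(f"residue {chain}:{resi} has no {kind}")
        masks.append(m)
    pa, pb = conf.positions[masks[0]], conf.positions[masks[1]]
    d = np.linalg.norm(pa[:, None, :] - pb[None, :, :], axis=-1)
    return float(d.min())


@dataclass
class ContactSet:
    """Contacts of one frame, deterministically ordered."""

    pairs: list[PairKey]
    source: object = None

    def __post_init__(self):
        order = {name: i for i, name in enumerate(DIMER_ORDER)}
        self.pairs = sorted(
            set(self.pairs),
            key=lambda p: (order[p[0][0]], order[p[0][1]], p[1], p[2]),
        )

    def __len__(self):
        return len(self.pairs)


def _dimer_atoms(conf: Conformation, domains: DomainMap, dimer: str):
    """Heavy-atom coordinates and residue labels of a dimer's EC domains."""
    mask = np.zeros(conf.n_atoms, bool)
    for span in domains.ec_spans_of_dimer(dimer):
        mask |= conf.select(chain_id=span.chain_id,
                            residue_span=(span.start, span.end))
    mask &= conf.heavy_mask
    idx = np.flatnonzero(mask)
    return conf.positions[idx], conf.chain_ids[idx], conf.residue_indices[idx]


def frame_contacts(
    conf: Conformation,
    domains: DomainMap,
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
) -> ContactSet:
    """All inter-dimer residue contacts of one frame (strict < cutoff)."""
    cached = {d: _dimer_atoms(conf, domains, d) for d in DIMER_ORDER}
    pairs: list[PairKey] = []
    for i, da in enumerate(DIMER_ORDER):
        for db in DIMER_ORDER[i + 1:]:
            pa, ca, ra = cached[da]
            pb, cb, rb = cached[db]
            if len(pa) == 0 or len(pb) == 0:
                continue
            tree_b = cKDTree(pb)
            hits = cKDTree(pa).query_ball_tree(tree_b, r=cutoff)
            seen = set()
            for ia, lst in enumerate(hits):
                for ib in lst:
                    if np.linalg.norm(pa[ia] - pb[ib]) < cutoff:  # strict
                        seen.add(((ca[ia], int(ra[ia])), (cb[ib], int(rb[ib]))))
            pairs.extend(((da, db), a, b) for a, b in seen)
    return ContactSet(pairs, source=conf.source)


@dataclass
class ContactProbabilityMap:
    counts: dict[PairKey, int]
    n_frames: int
    threshold: float = DEFAULT_PROB_THRESHOLD
    per_frame: list[frozenset] = field(default_factory=list)

    @property
    def probabilities(self) -> dict[PairKey, float]:
        """All pair probabilities (occurrence count / n_frames)."""
        return {k: v / self.n_frames for k, v in self.counts.items()}

    @property
    def reported(self) -> dict[PairKey, float]:
        """Pairs with probability strictly above the reporting threshold."""
        return {k: p for k, p in self.probabilities.items() if p > self.threshold}

    def to_frame(self, reported_only: bool = False) -> pd.DataFrame:
        src = self.reported if reported_only else self.probabilities
        rows = [
            {
                "dimer_a": k[0][0], "dimer_b": k[0][1],
                "chain_a": k[1][0], "res_a": k[1][1],
                "chain_b": k[2][0], "res_b": k[2][1],
                "count": self.counts[k], "probability": p,
            }
            for k, p in sorted(src.items())
        ]
        return pd.DataFrame(
            rows,
            columns=["dimer_a", "dimer_b", "chain_a", "res_a",
                     "chain_b", "res_b", "count", "probability"],
        )


def probability_map(
    ensemble: Ensemble,
    domains: DomainMap,
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
    threshold: float = DEFAULT_PROB_THRESHOLD,
    frame_sets: list[ContactSet] | None = None,
) -> ContactProbabilityMap:
    """Ensemble contact probability map; per-frame sets retained.

    ``frame_sets`` may pass precomputed :func:`frame_contacts` results to
    avoid recomputation (their order must match the ensemble).
    """
    if frame_sets is None:
        frame_sets = [frame_contacts(c, domains, cutoff) for c in ensemble]
    counts: dict[PairKey, int] = {}
    per_frame = []
    for cs in frame_sets:
        keys = frozenset(cs.pairs)
        per_frame.append(keys)
        for k in keys:
            counts[k] = counts.get(k, 0) + 1
    return ContactProbabilityMap(
        counts=counts,
        n_frames=len(frame_sets),
        threshold=threshold,
        per_frame=per_frame,
    )


# ---------------------------------------------------------------------------
# per-element counts
# ---------------------------------------------------------------------------


def _element_residues(domains: DomainMap) -> dict[str, set[tuple[str, int]]]:
    return {
        name: {(span.chain_id, r) for r in range(span.start, span.end + 1)}
        for name, span in domains.elements.items()
    }


def element_contact_counts(
    frame_sets: list[ContactSet] | ContactSet,
    domains: DomainMap,
) -> pd.DataFrame:
    """Per-frame counts of element contacts with the CD3 EC domains.

    For each annotated Ig loop/strand element, counts the contacts of that
    element's residues with any CD3 EC residue in each frame.  Returns one
    row per frame, one column per element.
    """
    single = isinstance(frame_sets, ContactSet)
    if single:
        frame_sets = [frame_sets]
    el_res = _element_residues(domains)
    cd3_dimers = {"CD3ed", "CD3eg"}
    rows = []
    for cs in frame_sets:
        counts = dict.fromkeys(el_res, 0)
        for (da, db), a, b in cs.pairs:
            for el, residues in el_res.items():
                if a in residues and db in cd3_dimers:
                    counts[el] += 1
                elif b in residues and da in cd3_dimers:
                    counts[el] += 1
        rows.append(counts)
    return pd.DataFrame(rows, columns=sorted(el_res))


# ---------------------------------------------------------------------------
# clusters
# ---------------------------------------------------------------------------


@dataclass
class ContactCluster:
    cluster_id: int
    dimer_pair: tuple[str, str]
    members: list[PairKey]
    occupancy: np.ndarray | None = None  # per-frame count of members present


DEFAULT_CLUSTER_RADIUS = 2


def cluster_contacts(
    pmap: ContactProbabilityMap,
    radius: int = DEFAULT_CLUSTER_RADIUS,
) -> list[ContactCluster]:
    """Group reported contact pairs into clusters.

    Two pairs of the same dimer-dimer map (and same chain combination) are
    adjacent when both residue-index offsets are <= ``radius`` (Chebyshev).
    Connected components are numbered by ascending minimum residue index
    within each map, maps ordered TCRab < CD3ed < CD3eg.  Occupancy series
    are filled from the map's retained per-frame contact sets.
    """
    if not pmap.counts:
        raise ContactError("cannot cluster an empty contact map")
    reported = sorted(pmap.reported)
    order = {name: i for i, name in enumerate(DIMER_ORDER)}

    parent = list(range(len(reported)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    for i, (dpi, ai, bi) in enumerate(reported):
        for j in range(i + 1, len(reported)):
            dpj, aj, bj = reported[j]
            if dpi != dpj or ai[0] != aj[0] or bi[0] != bj[0]:
                continue
            if abs(ai[1] - aj[1]) <= radius and abs(bi[1] - bj[1]) <= radius:
                union(i, j)

    groups: dict[int, list[PairKey]] = {}
    for i, key in enumerate(reported):
        groups.setdefault(find(i), []).append(key)

    def sort_key(members: list[PairKey]):
        dp = members[0][0]
        return (order[dp[0]], order[dp[1]],
                min(min(a[1], b[1]) for _, a, b in members))

    clusters = []
    for cid, members in enumerate(sorted(groups.values(), key=sort_key), start=1):
        occ = None
        if pmap.per_frame:
            mset = set(members)
            occ = np.array([len(mset & fs) for fs in pmap.per_frame])
        clusters.append(
            ContactCluster(cid, members[0][0], sorted(members), occupancy=occ)
        )
    return clusters


def cluster_correlation(clusters: list[ContactCluster]) -> pd.DataFrame:
    """Pearson correlation matrix of cluster occupancy series.

    Diagonal entries are 1; correlations with a constant series are undefined
    and reported as NaN.
    """
    if len(clusters) < 2:
        raise ContactError("need at least two clusters for a correlation matrix")
    lengths = {len(c.occupancy) for c in clusters}
    if len(lengths) != 1:
        raise ContactError(f"occupancy series length mismatch: {sorted(lengths)}")
    series = np.array([c.occupancy for c in clusters], dtype=float)
    ids = [c.cluster_id for c in clusters]
    n = len(clusters)
    mat = np.full((n, n), np.nan)
    sd = series.std(axis=1)
    centered = series - series.mean(axis=1, keepdims=True)
    for i in range(n):
        mat[i, i] = 1.0
        for j in range(i + 1, n):
            if sd[i] == 0.0 or sd[j] == 0.0:
                continue  # undefined, stays NaN
            r = float(centered[i] @ centered[j] / (len(centered[i]) * sd[i] * sd[j]))
            mat[i, j] = mat[j, i] = r
    return pd.DataFrame(mat, index=ids, columns=ids)
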