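"""Contact detection vs brute-force oracle, probability maps, clusters."""

import numpy as np
import pandas as pd
import pytest

from tcrtilt.contacts import (
    ContactCluster,
    ContactError,
    ContactProbabilityMap,
    cluster_contacts,
    cluster_correlation,
    element_contact_counts,
    frame_contacts,
    probability_map,
    residue_min_distance,
)
from tcrtilt.structure_io import Ensemble
from tcrtilt.synthetic import PARTNER_RESIDUES, SyntheticSpec, build_ensemble, build_frame

from conftest import make_conformation


def brute_force_contacts(conf, domains, cutoff):
    """Exhaustive all-pairs oracle: loops over every inter-dimer residue pair."""
    residues = {}  # dimer -> [(chain, res)]
    for dimer in ("TCRab", "CD3ed", "CD3eg"):
        out = []
        for span in domains.ec_spans_of_dimer(dimer):
            present = np.unique(conf.residue_indices[
                (conf.chain_ids == span.chain_id)
                & (conf.residue_indices >= span.start)
                & (conf.residue_indices <= span.end)
            ])
            out.extend((span.chain_id, int(r)) for r in present)
        residues[dimer] = out
    pairs = set()
    dimers = ("TCRab", "CD3ed", "CD3eg")
    for i, da in enumerate(dimers):
        for db in dimers[i + 1:]:
            for ra in residues[da]:
                for rb in residues[db]:
                    if residue_min_distance(conf, ra, rb) < cutoff:
                        pairs.add(((da, db), ra, rb))
    return pairs


class TestResidueMinDistance:
    def test_known_separation(self):
        conf = make_conformation([
            ("A", 1, "ALA", "CA", "C", (0, 0, 0)),
            ("A", 1, "ALA", "CB", "C", (0, 0, 0.1)),
            ("B", 1, "ALA", "CA", "C", (0, 0, 0.4)),
        ])
        assert residue_min_distance(conf, ("A", 1), ("B", 1)) == pytest.approx(0.30)

    def test_identical_residue_zero(self):
        conf = make_conformation([("A", 1, "ALA", "CA", "C", (1, 1, 1))])
        assert residue_min_distance(conf, ("A", 1), ("A", 1)) == 0.0

    def test_hydrogens_excluded_by_default(self):
        conf = make_conformation([
            ("A", 1, "ALA", "CA", "C", (0, 0, 0)),
            ("A", 1, "ALA", "HA", "H", (0, 0, 0.35)),
            ("B", 1, "ALA", "CA", "C", (0, 0, 0.4)),
        ])
        assert residue_min_distance(conf, ("A", 1), ("B", 1)) == pytest.approx(0.4)
        assert residue_min_distance(
            conf, ("A", 1), ("B", 1), heavy_only=False
        ) == pytest.approx(0.05)

    def test_hydrogen_only_residue_raises(self):
        conf = make_conformation([
            ("A", 1, "ALA", "HA", "H", (0, 0, 0)),
            ("B", 1, "ALA", "CA", "C", (0, 0, 1)),
        ])
        with pytest.raises(ContactError, match="heavy"):
            residue_min_distance(conf, ("A", 1), ("B", 1))

    def test_random_residues_match_double_loop_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            atoms = []
            for chain in ("A", "B"):
                for i in range(5):
                    atoms.append(
                        (chain, 1, "ALA", f"C{i}", "C", rng.uniform(0, 1.2, 3))
                    )
            conf = make_conformation(atoms)
            pa = conf.positions[:5]
            pb = conf.positions[5:]
            oracle = min(
                float(np.linalg.norm(x - y)) for x in pa for y in pb
            )
            # equality up to 1 ulp: vectorized vs scalar norm evaluation
            assert residue_min_distance(conf, ("A", 1), ("B", 1)) == pytest.approx(
                oracle, rel=1e-14
            )


class TestFrameContacts:
    def test_exact_boundary_is_not_contact(self, toy_domain_map):
        conf = make_conformation([
            ("A", 1, "ALA", "CA", "C", (0, 0, 0)),
            ("D", 1, "ALA", "CA", "C", (0.45, 0, 0)),
            ("D", 2, "ALA", "CA", "C", (0.449999, 0, 1e-9)),
        ])
        cs = frame_contacts(conf, toy_domain_map)
        assert [(p[1], p[2]) for p in cs.pairs] == [(("A", 1), ("D", 2))]

    def test_planted_contacts_recovered_exactly(self, dm):
        occ = {el: (1 if i % 3 == 0 else 0) for i, el in enumerate(PARTNER_RESIDUES)}
        conf = build_frame(dm, 40.0, 20.0, {k: 15.0 for k in dm.tm_helices}, occ)
        cs = frame_contacts(conf, dm)
        assert len(cs) == sum(occ.values())
        counts = element_contact_counts(cs, dm)
        for el, o in occ.items():
            assert counts[el].iloc[0] == o

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_oracle_on_random_instances(
        self, toy_domain_map, seed
    ):
        """KD-tree detection must equal the exhaustive all-pairs oracle."""
        rng = np.random.default_rng(seed)
        atoms = []
        for chain in ("A", "B", "E", "G", "F", "D"):
            for res in range(1, 5):
                for k in range(3):
                    atoms.append(
                        (chain, res, "ALA", f"C{k}", "C", rng.uniform(0, 1.5, 3))
                    )
        conf = make_conformation(atoms)
        got = set(frame_contacts(conf, toy_domain_map).pairs)
        assert got == brute_force_contacts(conf, toy_domain_map, 0.45)

    def test_deterministic_ordering(self, toy_domain_map):
        rng = np.random.default_rng(0)
        atoms = []
        for chain in ("A", "B", "E", "G", "F", "D"):
            for res in range(1, 5):
                atoms.append((chain, res, "ALA", "CA", "C", rng.uniform(0, 1.0, 3)))
        conf = make_conformation(atoms)
        p1 = frame_contacts(conf, toy_domain_map).pairs
        p2 = frame_contacts(conf, toy_domain_map).pairs
        assert p1 == p2 == sorted(
            p1, key=lambda p: (("TCRab", "CD3ed", "CD3eg").index(p[0][0]),
                               ("TCRab", "CD3ed", "CD3eg").index(p[0][1]),
                               p[1], p[2])
        )


class TestProbabilityMap:
    def test_boundary_probability_dropped(self):
        pair = (("TCRab", "CD3eg"), ("A", 1), ("E", 1))
        pmap = ContactProbabilityMap(counts={pair: 30}, n_frames=6000)
        assert pmap.probabilities[pair] == pytest.approx(0.005)
        assert pair not in pmap.reported  # strictly larger than 0.5% required

    def test_always_present_pair(self, dm):
        occ = {"Cbeta FG loop": 1}
        frames = [
            build_frame(dm, t, 10.0, {k: 15.0 for k in dm.tm_helices}, occ)
            for t in (20.0, 30.0, 40.0)
        ]
        pmap = probability_map(Ensemble(frames), dm)
        span = dm.elements["Cbeta FG loop"]
        mid = (span.start + span.end) // 2
        key = (("TCRab", "CD3eg"), ("B", mid), PARTNER_RESIDUES["Cbeta FG loop"])
        assert pmap.probabilities[key] == 1.0
        assert key in pmap.reported

    def test_planted_occupancy_within_binomial_error(self, dm):
        """Occupancy 0.25 planted over n frames recovers within 3 binomial SE."""
        from tcrtilt.synthetic import ContactLaw, sample_frames

        spec = SyntheticSpec(
            n_trajectories=20, n_frames=25, seed=9,
            contact_laws={"Cbeta FG loop": ContactLaw(0.25, None, None)},
        )
        truth = sample_frames(spec)
        n = len(truth)
        p_hat = truth["occ_Cbeta FG loop"].mean()
        se = np.sqrt(0.25 * 0.75 / n)
        assert abs(p_hat - 0.25) < 3 * se

    def test_invariant_to_frame_order(self, dm):
        occ = {"Cbeta FG loop": 1}
        frames = [
            build_frame(dm, t, 10.0, {k: 15.0 for k in dm.tm_helices},
                        occ if t > 25 else {})
            for t in (20.0, 30.0, 40.0)
        ]
        p1 = probability_map(Ensemble(frames), dm).probabilities
        p2 = probability_map(Ensemble(frames[::-1]), dm).probabilities
        assert p1 == p2


def _pmap_from_pairs(pairs, per_frame=None, n_frames=10):
    counts = {p: n_frames for p in pairs}
    return ContactProbabilityMap(
        counts=counts, n_frames=n_frames, per_frame=per_frame or []
    )


class TestClusters:
    KEY = ("TCRab", "CD3eg")

    def test_adjacent_pairs_merge(self):
        pairs = [
            (self.KEY, ("B", 10), ("E", 20)),
            (self.KEY, ("B", 10), ("E", 21)),
        ]
        clusters = cluster_contacts(_pmap_from_pairs(pairs))
        assert len(clusters) == 1
        assert clusters[0].cluster_id == 1

    def test_distant_pairs_separate(self):
        pairs = [
            (self.KEY, ("B", 10), ("E", 20)),
            (self.KEY, ("B", 20), ("E", 30)),
        ]
        clusters = cluster_contacts(_pmap_from_pairs(pairs))
        assert len(clusters) == 2

    def test_block_structure_recovered(self):
        """Four well-separated blocks of pairs give exactly four clusters."""
        rng = np.random.default_rng(2)
        pairs = []
        blocks = [(10, 20), (40, 50), (10, 80), (70, 20)]
        for bi, bj in blocks:
            for _ in range(4):
                pairs.append(
                    (self.KEY,
                     ("B", bi + int(rng.integers(0, 3))),
                     ("E", bj + int(rng.integers(0, 3))))
                )
        clusters = cluster_contacts(_pmap_from_pairs(sorted(set(pairs))))
        assert len(clusters) == 4
        # partition property: union of members = input, pairwise disjoint
        all_members = [p for c in clusters for p in c.members]
        assert sorted(all_members) == sorted(set(pairs))

    def test_clusters_partition_reported_pairs_of_ensemble(self, small_ensemble, dm):
        ens, _ = small_ensemble
        pmap = probability_map(ens, dm)
        clusters = cluster_contacts(pmap)
        members = [p for c in clusters for p in c.members]
        assert sorted(members) == sorted(pmap.reported)

    def test_empty_map_raises(self):
        with pytest.raises(ContactError, match="empty"):
            cluster_contacts(ContactProbabilityMap(counts={}, n_frames=1))


class TestClusterCorrelation:
    def _cluster(self, cid, occupancy):
        return ContactCluster(cid, ("TCRab", "CD3eg"),
                              members=[], occupancy=np.asarray(occupancy, float))

    def test_self_correlation_one_and_anticorrelation(self):
        x = np.array([0, 1, 2, 3, 2, 1, 0], float)
        c = [self._cluster(1, x), self._cluster(2, x.max() - x)]
        mat = cluster_correlation(c)
        assert mat.loc[1, 1] == 1.0
        assert mat.loc[1, 2] == pytest.approx(-1.0)

    def test_constant_series_gives_nan(self):
        c = [self._cluster(1, [1, 1, 1]), self._cluster(2, [0, 1, 2])]
        mat = cluster_correlation(c)
        assert np.isnan(mat.loc[1, 2])
        assert mat.loc[1, 1] == 1.0

    def test_length_mismatch_raises(self):
        c = [self._cluster(1, [1, 2]), self._cluster(2, [1, 2, 3])]
        with pytest.raises(ContactError, match="length"):
            cluster_correlation(c)

    def test_latent_tilt_coupling_induces_positive_correlation(self, dm):
        """Two clusters driven by the same tilt gate correlate positively,
        matching a closed-form estimate from the shared Bernoulli gating."""
        from tcrtilt.synthetic import ContactLaw, sample_frames

        laws = {
            "Valpha A'B loop": ContactLaw(0.9, 30.0, 2.0),
            "Valpha C''D loop": ContactLaw(0.9, 30.0, 2.0),
        }
        spec = SyntheticSpec(n_trajectories=40, n_frames=25, seed=21,
                             contact_laws=laws)
        truth = sample_frames(spec)
        occ1 = truth["occ_Valpha A'B loop"].to_numpy(float)
        occ2 = truth["occ_Valpha C''D loop"].to_numpy(float)
        c = [self._cluster(1, occ1), self._cluster(2, occ2)]
        r = cluster_correlation(c).loc[1, 2]
        # oracle: corr = var(p(tilt)) / (var(p) + E[p(1-p)]) for shared p(tilt)
        p = laws["Valpha A'B loop"].probability(truth["tilt"].to_numpy())
        expected = p.var() / (p.var() + (p * (1 - p)).mean())
        se = 3 / np.sqrt(len(occ1))
        assert r == pytest.approx(expected, abs=3 * se)
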