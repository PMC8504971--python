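"""Shared fixtures: domain maps, toy PDB text, small synthetic ensembles."""

import numpy as np
import pytest

from tcrtilt.structure_io import (
    Conformation,
    DomainMap,
    Span,
    load_domain_map,
)
from tcrtilt.synthetic import SyntheticSpec, build_ensemble


@pytest.fixture(scope="session")
def dm() -> DomainMap:
    return load_domain_map()


@pytest.fixture(scope="session")
def small_ensemble(dm):
    """5 trajectories x 10 frames with lipids; deterministic (seed 42)."""
    spec = SyntheticSpec(n_trajectories=5, n_frames=10, seed=42)
    return build_ensemble(spec, dm)


def make_conformation(atoms, **kwargs):
    """Build a Conformation from (chain, resi, resname, name, element, xyz)."""
    return Conformation(
        [a[0] for a in atoms],
        [a[1] for a in atoms],
        [a[2] for a in atoms],
        [a[3] for a in atoms],
        [a[4] for a in atoms],
        np.array([a[5] for a in atoms], dtype=float),
        **kwargs,
    )


TOY_PDB_2MODEL = """\
MODEL        1
ATOM      1  N   ALA A   1      10.000  10.000  10.000  1.00  0.00           N
ATOM      2  CA  ALA A   1      11.000  10.000  10.000  1.00  0.00           C
ATOM      3  O   ALA A   2      12.000  10.000  10.000  1.00  0.00           O
ENDMDL
MODEL        2
ATOM      1  N   ALA A   1      10.000  10.000  11.000  1.00  0.00           N
ATOM      2  CA  ALA A   1      11.000  10.000  11.000  1.00  0.00           C
ATOM      3  O   ALA A   2      12.000  10.000  11.000  1.00  0.00           O
ENDMDL
END
"""


@pytest.fixture
def toy_pdb_path(tmp_path):
    p = tmp_path / "toy.pdb"
    p.write_text(TOY_PDB_2MODEL)
    return p


@pytest.fixture(scope="session")
def toy_domain_map() -> DomainMap:
    """Minimal two-dimer map for hand-built conformations."""
    return DomainMap(
        domains={
            "Valpha": Span("A", 1, 4),
            "Calpha": Span("A", 10, 13),
            "Vbeta": Span("B", 1, 4),
            "Cbeta": Span("B", 10, 13),
            "CD3epsilon_g": Span("E", 1, 4),
            "CD3gamma": Span("G", 1, 4),
            "CD3epsilon_d": Span("F", 1, 4),
            "CD3delta": Span("D", 1, 4),
        },
        tm_helices={"TCRalpha": Span("A", 20, 27)},
        elements={"Cbeta FG loop": Span("B", 11, 12)},
        dimers={"TCRab": ("A", "B"), "CD3ed": ("F", "D"), "CD3eg": ("E", "G")},
    )
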