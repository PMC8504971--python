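"""Multi-model PDB I/O, domain annotations, and tabular output.

The structure container is deliberately simple: a :class:`Conformation` holds
parallel numpy arrays for one model of an eight-chain membrane-protein complex
(optionally with lipids), with coordinates in nm and the membrane normal fixed
to the +z axis of the frame, matching the simulation-box convention in which
the complex was aligned along z.  An :class:`Ensemble` is an ordered list of
conformations with provenance (trajectory id, time in microseconds).

Parsing is strict where downstream analyses need it to be: malformed ATOM
lines fail with their line number, MODEL records must be closed by ENDMDL,
blank chain identifiers and insertion codes are rejected.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .constants import ANGSTROM_PER_NM, HYDROGEN_ELEMENTS


class PDBParseError(ValueError):
    """Raised for malformed multi-model PDB input, with a line number."""


class DomainMapError(ValueError):
    """Raised when a domain annotation fails validation."""


# ---------------------------------------------------------------------------
# atom / conformation containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AtomRecord:
    chain_id: str
    residue_index: int
    residue_name: str
    atom_name: str
    element: str
    position: np.ndarray  # (3,) nm
    model_index: int = 1


@dataclass(frozen=True)
class SourceLabel:
    """Provenance of one conformation: trajectory id and time in us."""

    trajectory_id: int
    time_us: float


class Conformation:
    """One model's atoms as parallel arrays, coordinates in nm."""

    def __init__(
        self,
        chain_ids: Sequence[str],
        residue_indices: Sequence[int],
        residue_names: Sequence[str],
        atom_names: Sequence[str],
        elements: Sequence[str],
        positions: np.ndarray,
        model_index: int = 1,
        membrane_normal: Sequence[float] = (0.0, 0.0, 1.0),
        membrane_midplane_z: float | None = None,
        source: SourceLabel | None = None,
    ):
        self.chain_ids = np.asarray(chain_ids, dtype=object)
        self.residue_indices = np.asarray(residue_indices, dtype=np.int64)
        self.residue_names = np.asarray(residue_names, dtype=object)
        self.atom_names = np.asarray(atom_names, dtype=object)
        self.elements = np.asarray([e.upper() for e in elements], dtype=object)
        self.positions = np.asarray(positions, dtype=float).reshape(-1, 3)
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("non-finite atom coordinates")
        if (self.elements == "").any():
            raise ValueError("empty element symbol after parsing")
        n = len(self.chain_ids)
        for arr in (self.residue_indices, self.residue_names, self.atom_names,
                    self.elements):
            if len(arr) != n:
                raise ValueError("inconsistent per-atom array lengths")
        if self.positions.shape[0] != n:
            raise ValueError("inconsistent position array length")
        self.model_index = int(model_index)
        normal = np.asarray(membrane_normal, dtype=float)
        if abs(np.linalg.norm(normal) - 1.0) > 1e-9:
            raise ValueError("membrane_normal must be a unit vector")
        self.membrane_normal = normal
        self.membrane_midplane_z = membrane_midplane_z
        self.source = source

    # -- basic introspection ------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.chain_ids)

    @property
    def heavy_mask(self) -> np.ndarray:
        return ~np.isin(self.elements, list(HYDROGEN_ELEMENTS))

    def atoms(self) -> Iterator[AtomRecord]:
        for i in range(self.n_atoms):
            yield AtomRecord(
                chain_id=self.chain_ids[i],
                residue_index=int(self.residue_indices[i]),
                residue_name=self.residue_names[i],
                atom_name=self.atom_names[i],
                element=self.elements[i],
                position=self.positions[i].copy(),
                model_index=self.model_index,
            )

    @classmethod
    def from_atom_records(
        cls, records: Sequence[AtomRecord], **kwargs
    ) -> "Conformation":
        if not records:
            raise ValueError("empty atom record list")
        models = {r.model_index for r in records}
        if len(models) != 1:
            raise ValueError("atoms of one conformation must share a model index")
        return cls(
            [r.chain_id for r in records],
            [r.residue_index for r in records],
            [r.residue_name for r in records],
            [r.atom_name for r in records],
            [r.element for r in records],
            np.array([r.position for r in records]),
            model_index=records[0].model_index,
            **kwargs,
        )

    # -- selection ----------------------------------------------------------

    def select(
        self,
        chain_id: str | None = None,
        residue_span: tuple[int, int] | None = None,
        residue_index: int | None = None,
        atom_names: Iterable[str] | None = None,
        heavy_only: bool = False,
    ) -> np.ndarray:
        """Boolean mask of atoms matching all given criteria."""
        mask = np.ones(self.n_atoms, dtype=bool)
        if chain_id is not None:
            mask &= self.chain_ids == chain_id
        if residue_span is not None:
            lo, hi = residue_span
            mask &= (self.residue_indices >= lo) & (self.residue_indices <= hi)
        if residue_index is not None:
            mask &= self.residue_indices == residue_index
        if atom_names is not None:
            mask &= np.isin(self.atom_names, list(atom_names))
        if heavy_only:
            mask &= self.heavy_mask
        return mask

    def subset(self, mask: np.ndarray) -> "Conformation":
        return Conformation(
            self.chain_ids[mask],
            self.residue_indices[mask],
            self.residue_names[mask],
            self.atom_names[mask],
            self.elements[mask],
            self.positions[mask],
            model_index=self.model_index,
            membrane_normal=self.membrane_normal,
            membrane_midplane_z=self.membrane_midplane_z,
            source=self.source,
        )

    def transformed(
        self, rotation: np.ndarray | None = None, translation: Sequence[float] | None = None
    ) -> "Conformation":
        """Rigidly moved copy: x -> R x + t (membrane frame left unchanged)."""
        pos = self.positions
        if rotation is not None:
            pos = pos @ np.asarray(rotation, float).T
        if translation is not None:
            pos = pos + np.asarray(translation, float)
        out = self.subset(np.ones(self.n_atoms, bool))
        out.positions = pos
        return out


@dataclass
class Ensemble:
    conformations: list[Conformation]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.conformations:
            raise ValueError("an Ensemble must contain at least one conformation")

    def __len__(self) -> int:
        return len(self.conformations)

    def __iter__(self) -> Iterator[Conformation]:
        return iter(self.conformations)

    def __getitem__(self, i):
        return self.conformations[i]

    def validate_against(self, domain_map: "DomainMap") -> None:
        """Every annotated residue must exist in every conformation."""
        spans = {**domain_map.domains, **domain_map.tm_helices_by_name(),
                 **domain_map.elements}
        for k, conf in enumerate(self.conformations):
            for name, span in spans.items():
                present = np.unique(
                    conf.residue_indices[conf.chain_ids == span.chain_id]
                )
                wanted = np.arange(span.start, span.end + 1)
                missing = np.setdiff1d(wanted, present)
                if missing.size:
                    raise DomainMapError(
                        f"conformation {k}: residues {missing.tolist()} of "
                        f"{name!r} (chain {span.chain_id}) absent"
                    )


# ---------------------------------------------------------------------------
# domain annotation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Span:
    chain_id: str
    start: int
    end: int

    def __post_init__(self):
        if self.end < self.start:
            raise DomainMapError(f"span end {self.end} < start {self.start}")

    def contains(self, other: "Span") -> bool:
        return (
            self.chain_id == other.chain_id
            and self.start <= other.start
            and other.end <= self.end
        )

    def overlaps(self, other: "Span") -> bool:
        return (
            self.chain_id == other.chain_id
            and self.start <= other.end
            and other.start <= self.end
        )


# Deterministic analysis order of the three EC dimers.
DIMER_ORDER = ("TCRab", "CD3ed", "CD3eg")


@dataclass
class DomainMap:
    """Named residue-span annotations: EC domains, TM helices, Ig elements.

    ``dimers`` maps dimer name -> chain ids; contact analyses run over the
    three EC dimers in the fixed order TCRab < CD3ed < CD3eg.
    """

    domains: dict[str, Span]
    tm_helices: dict[str, Span]  # keyed by chain name (e.g. "TCRalpha")
    elements: dict[str, Span]
    dimers: dict[str, tuple[str, ...]]
    chain_names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        self.validate()

    # -- derived views ------------------------------------------------------

    def tm_helices_by_name(self) -> dict[str, Span]:
        return {f"TM {k}": v for k, v in self.tm_helices.items()}

    @property
    def known_chains(self) -> set[str]:
        chains = {s.chain_id for s in self.domains.values()}
        chains |= {s.chain_id for s in self.tm_helices.values()}
        return chains

    def span_of(self, name: str) -> Span:
        for table in (self.domains, self.elements):
            if name in table:
                return table[name]
        if name in self.tm_helices:
            return self.tm_helices[name]
        raise DomainMapError(f"unknown domain/element name {name!r}")

    def parent_domain(self, element_name: str) -> str:
        span = self.elements[element_name]
        for dom, dspan in self.domains.items():
            if dspan.contains(span):
                return dom
        raise DomainMapError(f"element {element_name!r} has no parent domain")

    def dimer_of_chain(self, chain_id: str) -> str | None:
        for dimer, chains in self.dimers.items():
            if chain_id in chains:
                return dimer
        return None

    def ec_spans_of_dimer(self, dimer: str) -> list[Span]:
        chains = set(self.dimers[dimer])
        return [s for s in self.domains.values() if s.chain_id in chains]

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        known = self.known_chains
        for dimer, chains in self.dimers.items():
            for c in chains:
                if c not in known:
                    raise DomainMapError(
                        f"dimer {dimer!r} references unknown chain {c!r}"
                    )
        # the domain partition plus TM spans must be non-overlapping per chain
        spans = list(self.domains.items()) + list(self.tm_helices_by_name().items())
        for i, (ni, si) in enumerate(spans):
            for nj, sj in spans[i + 1:]:
                if si.overlaps(sj):
                    raise DomainMapError(
                        f"spans of {ni!r} and {nj!r} overlap on chain {si.chain_id}"
                    )
        for name, span in self.elements.items():
            if span.chain_id not in known:
                raise DomainMapError(
                    f"element {name!r} references unknown chain {span.chain_id!r}"
                )
            parents = [d for d, ds in self.domains.items() if ds.contains(span)]
            if not parents:
                raise DomainMapError(
                    f"element {name!r} span lies outside every parent domain"
                )
            # "Cbeta FG loop" must live inside Cbeta, not merely inside
            # some domain on whatever chain it was (mis)assigned to
            prefix = name.split()[0]
            if prefix in self.domains and prefix not in parents:
                raise DomainMapError(
                    f"element {name!r} lies in {parents[0]!r}, not in {prefix!r}"
                )


def _span_from_entry(name: str, entry: Mapping) -> Span:
    try:
        return Span(str(entry["chain"]), int(entry["start"]), int(entry["end"]))
    except (KeyError, TypeError) as exc:
        raise DomainMapError(f"entry {name!r} must define chain/start/end") from exc


def load_domain_map(path: str | Path | None = None) -> DomainMap:
    """Load a domain annotation; ``None`` loads the packaged default.

    The packaged default is a synthetic stand-in that follows the eight-chain
    layout and Ig-element naming convention of the cryo-EM deposition; edit a
    copy to match your own residue numbering.
    """
    if path is None:
        text = (
            resources.files("tcrtilt").joinpath("data/domain_map_synthetic.yaml")
            .read_text()
        )
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    dm = DomainMap(
        domains={k: _span_from_entry(k, v) for k, v in raw["domains"].items()},
        tm_helices={k: _span_from_entry(k, v) for k, v in raw["tm_helices"].items()},
        elements={k: _span_from_entry(k, v) for k, v in raw.get("elements", {}).items()},
        dimers={k: tuple(v) for k, v in raw["dimers"].items()},
        chain_names=dict(raw.get("chains", {})),
    )
    return dm


# ---------------------------------------------------------------------------
# PDB parsing / writing
# ---------------------------------------------------------------------------


def element_from_atom_name(name: str) -> str:
    """Fallback element inference from a PDB atom name.

    Strips digits and spaces; a leading 'H' (after stripping) means hydrogen,
    otherwise the first remaining letter is taken as a one-letter element.
    """
    stripped = "".join(c for c in name if c.isalpha())
    if not stripped:
        raise ValueError(f"cannot infer element from atom name {name!r}")
    if stripped[0].upper() == "H":
        return "H"
    return stripped[0].upper()


def _parse_atom_line(line: str, lineno: int) -> tuple:
    if len(line.rstrip("\n")) < 54:
        raise PDBParseError(f"line {lineno}: ATOM record shorter than 54 columns")
    try:
        atom_name = line[12:16].strip()
        res_name = line[17:21].strip()
        chain_id = line[21].strip()
        res_seq = int(line[22:26])
        icode = line[26].strip()
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except ValueError as exc:
        raise PDBParseError(f"line {lineno}: malformed ATOM record ({exc})") from None
    if not chain_id:
        raise PDBParseError(f"line {lineno}: missing chain identifier")
    if icode:
        raise PDBParseError(f"line {lineno}: insertion codes are not supported")
    element = line[76:78].strip() if len(line) >= 78 else ""
    if not element:
        element = element_from_atom_name(atom_name)
    pos = np.array([x, y, z]) / ANGSTROM_PER_NM
    return chain_id, res_seq, res_name, atom_name, element.upper(), pos


def read_multimodel_pdb(
    path: str | Path,
    source_labels: Sequence[SourceLabel] | None = None,
    membrane_midplane_z: float | None = None,
) -> Ensemble:
    """Read a (multi-)model PDB file into an :class:`Ensemble`.

    A file without MODEL records yields a single conformation.  Coordinates
    are converted from Angstrom to nm.  ``source_labels``, if given, must
    provide one (trajectory, time) label per model.
    """
    path = Path(path)
    conformations: list[Conformation] = []
    current: list[tuple] | None = None  # atoms of the open MODEL
    preamble: list[tuple] = []  # atoms before any MODEL record
    in_model = False
    model_count = 0

    def _finish(atom_rows: list[tuple], model_index: int) -> None:
        if not atom_rows:
            raise PDBParseError(f"model {model_index} contains no atoms")
        cols = list(zip(*atom_rows))
        conformations.append(
            Conformation(
                cols[0], cols[1], cols[2], cols[3], cols[4],
                np.array(cols[5]),
                model_index=model_index,
                membrane_midplane_z=membrane_midplane_z,
            )
        )

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec == "MODEL ":
                if in_model:
                    raise PDBParseError(
                        f"line {lineno}: MODEL opened before previous ENDMDL"
                    )
                in_model = True
                model_count += 1
                current = []
            elif rec == "ENDMDL":
                if not in_model:
                    raise PDBParseError(f"line {lineno}: ENDMDL without MODEL")
                _finish(current, model_count)
                in_model = False
                current = None
            elif rec in ("ATOM  ", "HETATM"):
                row = _parse_atom_line(line, lineno)
                if in_model:
                    current.append(row)
                else:
                    preamble.append(row)
    if in_model:
        raise PDBParseError("file ends inside a MODEL record (missing ENDMDL)")
    if preamble and conformations:
        raise PDBParseError("ATOM records found outside MODEL blocks")
    if preamble:
        _finish(preamble, 1)
    if not conformations:
        raise PDBParseError(f"{path}: no atoms found")
    if source_labels is not None:
        if len(source_labels) != len(conformations):
            raise ValueError(
                f"{len(source_labels)} source labels for "
                f"{len(conformations)} models"
            )
        for conf, label in zip(conformations, source_labels):
            conf.source = label
    return Ensemble(conformations, metadata={"path": str(path)})


def _format_atom_line(serial: int, a: AtomRecord) -> str:
    name = a.atom_name if len(a.atom_name) >= 4 else f" {a.atom_name}"
    x, y, z = a.position * ANGSTROM_PER_NM
    return (
        f"ATOM  {serial:>5d} {name:<4s} {a.residue_name:<4s}"[:21] + f"{a.chain_id:1s}"
        f"{a.residue_index:>4d}    {x:8.3f}{y:8.3f}{z:8.3f}"
        f"{1.00:6.2f}{0.00:6.2f}          {a.element:>2s}\n"
    )


def write_multimodel_pdb(ensemble: Ensemble | Conformation, path: str | Path) -> None:
    """Write an ensemble (or single conformation) as a multi-model PDB."""
    confs = ensemble.conformations if isinstance(ensemble, Ensemble) else [ensemble]
    buf = _io.StringIO()
    multi = len(confs) > 1
    for k, conf in enumerate(confs, start=1):
        if multi:
            buf.write(f"MODEL {k:>8d}\n")
        for serial, atom in enumerate(conf.atoms(), start=1):
            buf.write(_format_atom_line(serial, atom))
        if multi:
            buf.write("ENDMDL\n")
    buf.write("END\n")
    Path(path).write_text(buf.getvalue())


# ---------------------------------------------------------------------------
# tabular output
# ---------------------------------------------------------------------------


def write_table(rows, path: str | Path, columns: Sequence[str] | None = None) -> None:
    """Write records as CSV with header, deterministic column order, '.' decimals.

    ``rows`` may be a DataFrame, a list of dicts (column order from the first
    record), or an empty list with explicit ``columns`` for a header-only file.
    """
    if isinstance(rows, pd.DataFrame):
        df = rows
    else:
        rows = list(rows)
        if rows:
            cols = columns or list(rows[0].keys())
            df = pd.DataFrame(rows, columns=cols)
        else:
            df = pd.DataFrame(columns=columns or [])
    df.to_csv(path, index=False, float_format="%.12g")
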