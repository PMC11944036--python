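"""Readers and writers for the external formats the pipeline touches.

Molecule structures come in as MDL molfiles (V2000 connection tables, the
dialect ChEBI distributes), pathway membership as two-column annotation
tables (plain ``pathway<TAB>compound`` pairs or the Reactome ChEBI-to-pathway
mapping file), and the pathway hierarchy as parent/child ID pairs.  Feature
matrices round-trip through TSV (default) or HDF5.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from typing import Iterable, TextIO

import networkx as nx

from .errors import (
    CapacityError,
    EmptyInputError,
    HierarchyError,
    MolfileFormatError,
    MolfileIndexError,
    SchemaError,
    UnsupportedDialectError,
)

logger = logging.getLogger(__name__)

#: IUPAC element symbols (periodic table through Og) used to validate atom blocks.
ELEMENT_SYMBOLS = frozenset(
    """H He Li Be B C N O F Ne Na Mg Al Si P S Cl Ar K Ca Sc Ti V Cr Mn Fe Co Ni
    Cu Zn Ga Ge As Se Br Kr Rb Sr Y Zr Nb Mo Tc Ru Rh Pd Ag Cd In Sn Sb Te I Xe
    Cs Ba La Ce Pr Nd Pm Sm Eu Gd Tb Dy Ho Er Tm Yb Lu Hf Ta W Re Os Ir Pt Au Hg
    Tl Pb Bi Po At Rn Fr Ra Ac Th Pa U Np Pu Am Cm Bk Cf Es Fm Md No Lr Rf Db Sg
    Bh Hs Mt Ds Rg Cn Nh Fl Mc Lv Ts Og""".split()
)

# Atom-block charge column codes (ccc field): code -> formal charge.
_CHARGE_CODES = {0: 0, 1: 3, 2: 2, 3: 1, 4: 0, 5: -1, 6: -2, 7: -3}
_CHARGE_TO_CODE = {3: 1, 2: 2, 1: 3, 0: 0, -1: 5, -2: 6, -3: 7}


@dataclass(frozen=True)
class Atom:
    element: str
    charge: int = 0


@dataclass
class MoleculeGraph:
    """A compound's heavy/light atoms and bonds as parsed from a molfile.

    Bonds are ``(a, b, order)`` with 0-based atom indices and order in
    {1, 2, 3, 4} where 4 encodes an aromatic bond.
    """

    compound_id: str
    atoms: list[Atom] = field(default_factory=list)
    bonds: list[tuple[int, int, int]] = field(default_factory=list)

    def validate(self) -> None:
        n = len(self.atoms)
        seen: set[tuple[int, int]] = set()
        for a, b, order in self.bonds:
            if not (0 <= a < n and 0 <= b < n):
                raise MolfileIndexError(
                    f"{self.compound_id}: bond ({a},{b}) references atom outside 0..{n - 1}"
                )
            if a == b:
                raise MolfileFormatError(f"{self.compound_id}: self-bond on atom {a}")
            key = (min(a, b), max(a, b))
            if key in seen:
                raise MolfileFormatError(f"{self.compound_id}: duplicate bond {key}")
            seen.add(key)
            if order not in (1, 2, 3, 4):
                raise MolfileFormatError(f"{self.compound_id}: bond order {order}")
        for atom in self.atoms:
            if atom.element not in ELEMENT_SYMBOLS:
                raise MolfileFormatError(
                    f"{self.compound_id}: unknown element symbol {atom.element!r}"
                )

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)


@dataclass
class AnnotationTable:
    """Deduplicated set of (compound_id, pathway_id) membership pairs."""

    pairs: set[tuple[str, str]] = field(default_factory=set)

    @property
    def compounds(self) -> set[str]:
        return {c for c, _ in self.pairs}

    @property
    def pathways(self) -> set[str]:
        return {p for _, p in self.pairs}

    def pathway_members(self) -> dict[str, set[str]]:
        members: dict[str, set[str]] = {}
        for c, p in self.pairs:
            members.setdefault(p, set()).add(c)
        return members


@dataclass
class PathwayHierarchy:
    """Parent -> child pathway edges; must form a DAG."""

    edges: set[tuple[str, str]] = field(default_factory=set)

    def to_digraph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for parent, child in self.edges:
            g.add_edge(parent, child)
        return g

    def validate(self) -> None:
        for parent, child in self.edges:
            if parent == child:
                raise HierarchyError(f"self-edge on pathway {parent!r}")
        g = self.to_digraph()
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise HierarchyError(f"hierarchy contains a cycle through edge {cycle[0][:2]}")


# ---------------------------------------------------------------------------
# Molfile V2000
# ---------------------------------------------------------------------------


def _int_field(line: str, start: int, width: int, what: str) -> int:
    raw = line[start : start + width].strip()
    if not raw:
        return 0
    try:
        return int(raw)
    except ValueError as exc:
        raise MolfileFormatError(f"cannot parse {what} from {raw!r}") from exc


def parse_molfile(text: str, compound_id: str | None = None) -> MoleculeGraph:
    """Parse a V2000 molfile into a :class:`MoleculeGraph`.

    Formal charges are taken from the atom-block charge column; if any
    ``M  CHG`` property line is present it supersedes *all* atom-block
    charges (per the CTAB convention).  V3000 input is rejected.
    """
    lines = text.splitlines()
    if len(lines) < 4:
        raise MolfileFormatError("molfile has fewer than 4 lines (no counts line)")
    title = lines[0].strip()
    counts = lines[3]
    if "V3000" in counts:
        raise UnsupportedDialectError(
            "V3000 connection tables are not supported; supply a V2000 molfile"
        )
    try:
        n_atoms = _int_field(counts, 0, 3, "atom count")
        n_bonds = _int_field(counts, 3, 3, "bond count")
    except MolfileFormatError:
        # lenient fallback: whitespace-separated counts line
        parts = counts.split()
        if len(parts) >= 2 and parts[0].isdigit() and parts[1].isdigit():
            n_atoms, n_bonds = int(parts[0]), int(parts[1])
        else:
            raise
    if len(lines) < 4 + n_atoms + n_bonds:
        raise MolfileFormatError(
            f"molfile truncated: counts line promises {n_atoms} atoms / "
            f"{n_bonds} bonds but only {len(lines) - 4} block lines follow"
        )

    atoms: list[Atom] = []
    for i in range(n_atoms):
        line = lines[4 + i]
        if len(line) < 34:
            raise MolfileFormatError(f"atom line {i + 1} too short: {line!r}")
        symbol = line[31:34].strip()
        if symbol not in ELEMENT_SYMBOLS:
            raise MolfileFormatError(f"atom line {i + 1}: unknown element {symbol!r}")
        code = _int_field(line, 36, 3, "charge code") if len(line) >= 39 else 0
        atoms.append(Atom(symbol, _CHARGE_CODES.get(code, 0)))

    bonds: list[tuple[int, int, int]] = []
    for i in range(n_bonds):
        line = lines[4 + n_atoms + i]
        a = _int_field(line, 0, 3, "bond atom 1")
        b = _int_field(line, 3, 3, "bond atom 2")
        order = _int_field(line, 6, 3, "bond order")
        if not (1 <= a <= n_atoms and 1 <= b <= n_atoms):
            raise MolfileIndexError(
                f"bond line {i + 1} references atom {max(a, b)} but molecule has {n_atoms}"
            )
        bonds.append((a - 1, b - 1, order))

    # M  CHG property lines override the atom-block charge column wholesale.
    chg_pairs: list[tuple[int, int]] = []
    for line in lines[4 + n_atoms + n_bonds :]:
        if line.startswith("M  END"):
            break
        if line.startswith("M  CHG"):
            fields = line.split()
            n_pairs = int(fields[2])
            vals = fields[3 : 3 + 2 * n_pairs]
            for j in range(n_pairs):
                chg_pairs.append((int(vals[2 * j]) - 1, int(vals[2 * j + 1])))
    if chg_pairs:
        atoms = [Atom(a.element, 0) for a in atoms]
        for idx, charge in chg_pairs:
            if not 0 <= idx < n_atoms:
                raise MolfileIndexError(f"M  CHG references atom {idx + 1} of {n_atoms}")
            atoms[idx] = Atom(atoms[idx].element, charge)

    graph = MoleculeGraph(compound_id or title or "unnamed", atoms, bonds)
    graph.validate()
    return graph


def write_molfile(graph: MoleculeGraph) -> str:
    """Serialize a :class:`MoleculeGraph` as a V2000 molfile string.

    Coordinates are written as zeros (the pipeline is 2D/3D-agnostic) and
    nonzero formal charges go into ``M  CHG`` property lines.
    """
    n = len(graph.atoms)
    if n > 999 or len(graph.bonds) > 999:
        raise CapacityError(
            f"{graph.compound_id}: {n} atoms / {len(graph.bonds)} bonds exceed "
            "the V2000 3-digit field width"
        )
    graph.validate()
    out = [graph.compound_id, "  pathcolor", ""]
    out.append(f"{n:3d}{len(graph.bonds):3d}  0  0  0  0  0  0  0  0999 V2000")
    for atom in graph.atoms:
        out.append(
            f"{0.0:10.4f}{0.0:10.4f}{0.0:10.4f} {atom.element:<3s} 0  0  0  0  0  0"
            "  0  0  0  0  0  0"
        )
    for a, b, order in graph.bonds:
        out.append(f"{a + 1:3d}{b + 1:3d}{order:3d}  0")
    charged = [(i + 1, atom.charge) for i, atom in enumerate(graph.atoms) if atom.charge]
    for start in range(0, len(charged), 8):
        chunk = charged[start : start + 8]
        body = "".join(f"{idx:4d}{chg:4d}" for idx, chg in chunk)
        out.append(f"M  CHG{len(chunk):3d}{body}")
    out.append("M  END")
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# Annotation tables and hierarchy relations
# ---------------------------------------------------------------------------


def _as_lines(stream: TextIO | str | Iterable[str]) -> Iterable[str]:
    if isinstance(stream, str):
        return io.StringIO(stream)
    return stream


def normalize_chebi_id(raw: str) -> str:
    raw = raw.strip()
    return raw if raw.upper().startswith("CHEBI:") else f"CHEBI:{raw}"


def read_annotations(
    stream: TextIO | str,
    dialect: str = "two_column",
    species: str | None = None,
) -> AnnotationTable:
    """Read compound<->pathway membership pairs.

    ``two_column``: ``pathway_id<TAB>compound_id`` (comma also accepted).
    ``reactome_chebi``: the Reactome ChEBI2Reactome mapping layout —
    tab-separated (compound, pathway stable ID, URL, event name, evidence,
    species); compound IDs are normalized to the ``CHEBI:`` prefix and an
    optional ``species`` filter restricts rows (default keeps all species).
    """
    if dialect not in ("two_column", "reactome_chebi"):
        raise UnsupportedDialectError(f"unknown annotation dialect {dialect!r}")
    pairs: set[tuple[str, str]] = set()
    skipped = 0
    for line in _as_lines(stream):
        line = line.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t") if "\t" in line else line.split(",")
        if dialect == "two_column":
            if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
                skipped += 1
                continue
            pathway, compound = fields[0].strip(), fields[1].strip()
        else:
            if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
                skipped += 1
                continue
            if species is not None and len(fields) >= 6 and fields[5].strip() != species:
                continue
            compound = normalize_chebi_id(fields[0])
            pathway = fields[1].strip()
        pairs.add((compound, pathway))
    if skipped:
        logger.warning("read_annotations: skipped %d rows with missing ID fields", skipped)
    if not pairs:
        raise EmptyInputError("annotation input contained no usable rows")
    return AnnotationTable(pairs)


def read_hierarchy(stream: TextIO | str) -> PathwayHierarchy:
    """Read parent/child pathway relations (TSV or CSV) and verify acyclicity."""
    edges: set[tuple[str, str]] = set()
    for line in _as_lines(stream):
        line = line.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t") if "\t" in line else line.split(",")
        if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
            continue
        edges.add((fields[0].strip(), fields[1].strip()))
    hierarchy = PathwayHierarchy(edges)
    hierarchy.validate()
    return hierarchy


def write_annotations(table: AnnotationTable, path: str) -> None:
    with open(path, "w") as fh:
        for compound, pathway in sorted(table.pairs, key=lambda cp: (cp[1], cp[0])):
            fh.write(f"{pathway}\t{compound}\n")


def write_hierarchy(hierarchy: PathwayHierarchy, path: str) -> None:
    with open(path, "w") as fh:
        for parent, child in sorted(hierarchy.edges):
            fh.write(f"{parent}\t{child}\n")


# ---------------------------------------------------------------------------
# Feature-matrix persistence
# ---------------------------------------------------------------------------


def save_matrix(matrix, path: str) -> None:
    """Persist a FeatureMatrix losslessly.

    ``.h5``/``.hdf5`` extensions select an HDF5 container; anything else is
    written as TSV with entity IDs in the first column and one column per
    atom color.
    """
    if str(path).endswith((".h5", ".hdf5")):
        import h5py

        with h5py.File(path, "w") as fh:
            fh.create_dataset("values", data=matrix.values)
            fh.create_dataset(
                "entity_ids", data=[s.encode() for s in matrix.entity_ids]
            )
            fh.create_dataset("colors", data=[s.encode() for s in matrix.colors])
    else:
        frame = matrix.to_frame()
        frame.to_csv(path, sep="\t", index_label="entity_id")


def load_matrix(path: str):
    """Load a FeatureMatrix written by :func:`save_matrix`."""
    import numpy as np
    import pandas as pd

    from .coloring import FeatureMatrix

    if str(path).endswith((".h5", ".hdf5")):
        import h5py

        with h5py.File(path, "r") as fh:
            try:
                values = fh["values"][...]
                ids = [b.decode() for b in fh["entity_ids"][...]]
                colors = [b.decode() for b in fh["colors"][...]]
            except KeyError as exc:
                raise SchemaError(f"{path}: missing dataset {exc}") from exc
        if values.shape != (len(ids), len(colors)):
            raise SchemaError(f"{path}: values shape {values.shape} != ids x colors")
        return FeatureMatrix(list(ids), list(colors), np.asarray(values))
    frame = pd.read_csv(path, sep="\t", index_col="entity_id", dtype={"entity_id": str})
    return FeatureMatrix(
        [str(i) for i in frame.index],
        [str(c) for c in frame.columns],
        frame.to_numpy(),
    )
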