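"""Substructure-count featurization of molecular graphs via iterative atom coloring.

Each atom receives a canonical string "color" describing its bonded
neighborhood out to some radius: at radius 0 the color is the element symbol
(plus formal charge when nonzero); at radius r+1 it is the radius-r color
extended with the lexicographically sorted multiset of ``(bond order,
neighbor radius-r color)`` terms.  Two atoms — in the same or different
molecules — get equal colors exactly when their rooted neighborhoods are
isomorphic under this encoding, so counting color occurrences per molecule
yields substructure-count feature vectors.  This is the Weisfeiler–Lehman
style refinement underlying Morgan-type canonical labeling.

Colors from different radii coexist in one vocabulary: a feature vector is
the union, over radii 0..R, of per-radius color counts.

Grammar version: ``pc-color-v1`` — ``elem[{+q|-q}]`` at radius 0, then
``prev|(order:neighbor_prev),...`` sorted.  Hydrogens are stripped before
coloring; aromatic bonds keep order code 4; isotopes/stereo are ignored.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .chem_io import Atom, MoleculeGraph
from .errors import EmptyInputError

COLOR_GRAMMAR_VERSION = "pc-color-v1"


@dataclass
class FeatureMatrix:
    """Entity-by-color count (or normalized) matrix.

    ``entity_ids`` index the rows, ``colors`` (the ordered ColorVocabulary)
    the columns.  Raw matrices hold non-negative integer counts; normalized
    matrices hold values in [0, 1].
    """

    entity_ids: list[str]
    colors: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != (len(self.entity_ids), len(self.colors)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.entity_ids)} ids x {len(self.colors)} colors"
            )

    @property
    def index(self) -> dict[str, int]:
        return {e: i for i, e in enumerate(self.entity_ids)}

    def row(self, entity_id: str) -> np.ndarray:
        return self.values[self.index[entity_id]]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.entity_ids, columns=self.colors)

    def equals(self, other: "FeatureMatrix") -> bool:
        return (
            self.entity_ids == other.entity_ids
            and self.colors == other.colors
            and self.values.shape == other.values.shape
            and np.array_equal(self.values, other.values)
        )


def strip_hydrogens(graph: MoleculeGraph) -> MoleculeGraph:
    """Remove H atoms and incident bonds, re-indexing remaining atoms in order."""
    keep = [i for i, atom in enumerate(graph.atoms) if atom.element != "H"]
    remap = {old: new for new, old in enumerate(keep)}
    atoms = [graph.atoms[i] for i in keep]
    bonds = [
        (remap[a], remap[b], order)
        for a, b, order in graph.bonds
        if a in remap and b in remap
    ]
    return MoleculeGraph(graph.compound_id, atoms, bonds)


def compound_size(graph: MoleculeGraph) -> int:
    """Number of non-hydrogen atoms."""
    return sum(1 for atom in graph.atoms if atom.element != "H")


def _adjacency(graph: MoleculeGraph) -> list[list[tuple[int, int]]]:
    adj: list[list[tuple[int, int]]] = [[] for _ in graph.atoms]
    for a, b, order in graph.bonds:
        adj[a].append((order, b))
        adj[b].append((order, a))
    return adj


def _diameter(adj: list[list[tuple[int, int]]]) -> int:
    """Max BFS eccentricity over connected components (0 for <=1 atom)."""
    n = len(adj)
    best = 0
    for source in range(n):
        dist = [-1] * n
        dist[source] = 0
        queue = [source]
        while queue:
            nxt = []
            for u in queue:
                for _, v in adj[u]:
                    if dist[v] < 0:
                        dist[v] = dist[u] + 1
                        nxt.append(v)
            queue = nxt
        best = max(best, max(d for d in dist if d >= 0))
    return best


def _radius0(atom: Atom) -> str:
    if atom.charge:
        return f"{atom.element}{atom.charge:+d}"
    return atom.element


def color_atoms(
    graph: MoleculeGraph, max_radius: int | str = "auto"
) -> list[list[str]]:
    """Per-radius atom colors: result[r][i] is atom i's color at radius r.

    An atom with no neighbors keeps its color unchanged at every radius.
    ``max_radius="auto"`` refines until the number of distinct colors in the
    graph stops increasing (that final radius is included), capped at the
    graph diameter.  An empty graph yields ``[[]]``.
    """
    n = len(graph.atoms)
    if n == 0:
        return [[]]
    adj = _adjacency(graph)
    auto = max_radius == "auto"
    if auto:
        cap = _diameter(adj)
    else:
        cap = int(max_radius)
        if cap < 0:
            raise ValueError("max_radius must be >= 0")

    rounds: list[list[str]] = [[_radius0(atom) for atom in graph.atoms]]
    while len(rounds) - 1 < cap:
        prev = rounds[-1]
        nxt = []
        for i in range(n):
            if not adj[i]:
                nxt.append(prev[i])
                continue
            terms = sorted(f"({order}:{prev[j]})" for order, j in adj[i])
            nxt.append(prev[i] + "|" + ",".join(terms))
        rounds.append(nxt)
        if auto and len(set(nxt)) <= len(set(prev)):
            break
    return rounds


def color_counts(
    graph: MoleculeGraph, max_radius: int | str = "auto"
) -> dict[str, int]:
    """Union over radii of per-radius color counts.

    A color that persists across radii (neighbor-less atom) is counted once,
    at its first radius of appearance; equal color strings always label the
    same atom set, so counts are unambiguous.
    """
    counts: dict[str, int] = {}
    for round_colors in color_atoms(graph, max_radius):
        per_radius: dict[str, int] = {}
        for color in round_colors:
            per_radius[color] = per_radius.get(color, 0) + 1
        for color, count in per_radius.items():
            counts.setdefault(color, count)
    return counts


def featurize_compounds(
    graphs: list[MoleculeGraph], max_radius: int | str = "auto"
) -> FeatureMatrix:
    """Raw count FeatureMatrix over the corpus-wide color vocabulary.

    Hydrogens are stripped before coloring.  The vocabulary is the
    lexicographically sorted union of all colors observed across the corpus,
    so the result is independent of compound input order up to row keying.
    """
    if not graphs:
        raise EmptyInputError("featurize_compounds: empty corpus")
    ids = [g.compound_id for g in graphs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate compound IDs in corpus")
    per_compound = [color_counts(strip_hydrogens(g), max_radius) for g in graphs]
    vocabulary = sorted(set().union(*[set(c) for c in per_compound]))
    col = {c: j for j, c in enumerate(vocabulary)}
    values = np.zeros((len(graphs), len(vocabulary)), dtype=np.int64)
    for i, counts in enumerate(per_compound):
        for color, count in counts.items():
            values[i, col[color]] = count
    return FeatureMatrix(ids, vocabulary, values)
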