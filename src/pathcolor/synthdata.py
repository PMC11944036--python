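"""Synthetic molecules, pathway hierarchies, and annotations with planted signal.

The generator emulates the three real-world inputs (one molfile per
compound, a multi-level pathway hierarchy, a pathway->compound annotation
table) at benchmark scale, with a *learnable* planted relationship: every
pathway owns a small structural motif, compounds embed one or more motifs,
and a compound is annotated to a pathway (with probability
``signal_strength``) exactly when it carries that pathway's motif.  A small
amount of spurious annotation noise is added on top.

Motifs are 3-atom chains containing an order-3 bond.  Background molecules
are random trees/rings over C/N/O/S/P with bond orders 1-2 only, so any
atom color involving a triple bond is motif-specific already at radius 1;
the motif's middle atom never gains extra bonds, making its radius-1 color a
clean per-motif signature that survives embedding.  Chemistry here is
deliberately schematic (degree caps instead of valence rules): the point is
a controllable, fully deterministic benchmark, not realistic molecules.

Pathways are grouped into *families* that share one motif (default: 10
families over the pathway set), mirroring how related knowledgebase pathways
share substrate chemistry.  Sharing matters statistically: each motif
pattern is then supported by members of several pathways, giving a
classifier enough positive examples per pattern to recover the planted
signal at benchmark scale.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .chem_io import (
    AnnotationTable,
    Atom,
    MoleculeGraph,
    PathwayHierarchy,
    parse_molfile,
    write_molfile,
)
from .coloring import color_counts, strip_hydrogens
from .dataset import LevelMap, assign_levels
from .errors import ConfigError

# max number of bonds per element in generated molecules
_DEGREE_CAP = {"C": 4, "N": 4, "O": 2, "S": 2, "P": 3}
_BACKGROUND_ELEMENTS = ["C", "N", "O", "S", "P"]
_BACKGROUND_WEIGHTS = [0.55, 0.15, 0.15, 0.08, 0.07]


@dataclass(frozen=True)
class Motif:
    """A 3-atom chain a#b-c (or a#b=c): one triple bond plus a second bond."""

    elements: tuple[str, str, str]
    second_order: int  # order of the b-c bond

    def as_graph(self, compound_id: str = "motif") -> MoleculeGraph:
        atoms = [Atom(e) for e in self.elements]
        bonds = [(0, 1, 3), (1, 2, self.second_order)]
        return MoleculeGraph(compound_id, atoms, bonds)

    @property
    def center_color(self) -> str:
        """Radius-1 color of the middle atom — unique corpus-wide signature."""
        a, b, c = self.elements
        terms = sorted([f"(3:{a})", f"({self.second_order}:{c})"])
        return f"{b}|" + ",".join(terms)


def default_motifs(n: int) -> list[Motif]:
    """First ``n`` motifs with pairwise-distinct center-color signatures."""
    motifs: list[Motif] = []
    seen: set[str] = set()
    for second_order in (1, 2):
        for elems in itertools.product(("C", "N", "P"), repeat=3):
            motif = Motif(elems, second_order)
            if motif.center_color not in seen:
                seen.add(motif.center_color)
                motifs.append(motif)
    if n > len(motifs):
        raise ConfigError(f"only {len(motifs)} distinct motifs available, {n} requested")
    return motifs[:n]


@dataclass
class SynthConfig:
    """Benchmark generator settings.

    Defaults define the package's reference study: 200 compounds x 50
    pathways, a 6-deep hierarchy (so the L6+ display group is exercised),
    near-deterministic signal (0.95) with 1% spurious-annotation noise.
    """

    n_compounds: int = 200
    n_pathways: int = 50
    hierarchy_depth: int = 6
    motif_set: list[Motif] | None = None
    n_motif_families: int = 10
    signal_strength: float = 0.95
    noise_rate: float = 0.01
    min_atoms: int = 3
    max_atoms: int = 30
    max_extra_motifs: int = 2
    ring_probability: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_compounds < 1 or self.n_pathways < 1:
            raise ConfigError("n_compounds and n_pathways must be >= 1")
        if not 1 <= self.hierarchy_depth <= 9:
            raise ConfigError("hierarchy_depth must be in 1..9")
        for name in ("signal_strength", "noise_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1]")
        if self.min_atoms < 1 or self.max_atoms < self.min_atoms:
            raise ConfigError("invalid atom-count range")

    def motifs(self) -> list[Motif]:
        """The distinct motif families (one motif per family)."""
        motifs = self.motif_set or default_motifs(
            min(self.n_motif_families, self.n_pathways)
        )
        if not motifs:
            raise ConfigError("motif set is empty")
        for m in motifs:
            if len(m.elements) > self.max_atoms:
                raise ConfigError("motif larger than the molecule atom budget")
        return motifs

    def pathway_motif(self, pathway_index: int) -> int:
        """Family motif owned by a pathway: families tile the pathway list."""
        return pathway_index % len(self.motifs())

    def pathway_ids(self) -> list[str]:
        return [f"PWY{j:04d}" for j in range(self.n_pathways)]

    def compound_ids(self) -> list[str]:
        return [f"SYN{i:04d}" for i in range(self.n_compounds)]


def _gen_background(rng: np.random.Generator, n_atoms: int, ring_p: float) -> MoleculeGraph:
    """Random connected tree over C/N/O/S/P, optionally with one ring closure."""
    atoms = [
        Atom(str(rng.choice(_BACKGROUND_ELEMENTS, p=_BACKGROUND_WEIGHTS)))
        for _ in range(n_atoms)
    ]
    degree = [0] * n_atoms
    bonds: list[tuple[int, int, int]] = []
    for i in range(1, n_atoms):
        open_atoms = [
            j for j in range(i) if degree[j] < _DEGREE_CAP[atoms[j].element]
        ]
        if not open_atoms:  # everything saturated; start a new component
            continue
        j = int(rng.choice(open_atoms))
        order = 2 if (
            rng.random() < 0.2
            and degree[j] + 2 <= _DEGREE_CAP[atoms[j].element]
            and 2 <= _DEGREE_CAP[atoms[i].element]
        ) else 1
        bonds.append((j, i, order))
        degree[i] += order if order == 1 else 2
        degree[j] += order if order == 1 else 2
    if n_atoms >= 4 and rng.random() < ring_p:
        bonded = {(min(a, b), max(a, b)) for a, b, _ in bonds}
        open_atoms = [j for j in range(n_atoms) if degree[j] < _DEGREE_CAP[atoms[j].element]]
        if len(open_atoms) >= 2:
            a, b = rng.choice(open_atoms, size=2, replace=False)
            a, b = int(min(a, b)), int(max(a, b))
            if a != b and (a, b) not in bonded:
                bonds.append((a, b, 1))
    return MoleculeGraph("bg", atoms, bonds)


def _embed_motif(
    graph: MoleculeGraph,
    motif: Motif,
    rng: np.random.Generator,
    n_background: int,
) -> None:
    """Append motif atoms and attach the chain end to a *background* atom.

    Only the end atom ``c`` may bond outward, and only to one of the first
    ``n_background`` atoms — never to another motif's atoms — so every
    embedded motif's middle-atom radius-1 color (its signature) survives
    embedding intact.  If all background atoms are saturated the motif is
    left as a disconnected fragment (still a valid connection table).
    """
    base = len(graph.atoms)
    graph.atoms.extend(Atom(e) for e in motif.elements)
    graph.bonds.append((base, base + 1, 3))
    graph.bonds.append((base + 1, base + 2, motif.second_order))
    degree = {i: 0 for i in range(n_background)}
    for a, b, _ in graph.bonds:
        for x in (a, b):
            if x < n_background:
                degree[x] = degree.get(x, 0) + 1
    open_atoms = [
        i
        for i in range(n_background)
        if degree[i] < _DEGREE_CAP[graph.atoms[i].element]
    ]
    if open_atoms:
        anchor = int(rng.choice(open_atoms))
        graph.bonds.append((anchor, base + 2, 1))


def gen_molecules(config: SynthConfig) -> list[str]:
    """Seed-deterministic corpus of V2000 molfile strings.

    Compound ``i`` always carries family motif ``i mod n_families`` (so every
    motif, hence every pathway, has carriers) plus 0..max_extra_motifs random
    extra motifs.
    """
    rng = np.random.default_rng(config.seed)
    motifs = config.motifs()
    n_families = len(motifs)
    texts = []
    for i, cid in enumerate(config.compound_ids()):
        n_bg = int(rng.integers(config.min_atoms, config.max_atoms + 1))
        graph = _gen_background(rng, n_bg, config.ring_probability)
        graph.compound_id = cid
        carried = {i % n_families}
        n_extra = int(rng.integers(0, config.max_extra_motifs + 1))
        if n_extra:
            carried.update(
                int(k) for k in rng.choice(n_families, size=min(n_extra, n_families), replace=False)
            )
        for k in sorted(carried):
            _embed_motif(graph, motifs[k], rng, n_bg)
        graph.validate()
        texts.append(write_molfile(graph))
    return texts


def gen_hierarchy(config: SynthConfig) -> tuple[PathwayHierarchy, LevelMap]:
    """Random pathway forest of the requested depth.

    Levels are assigned round-robin so every depth up to ``hierarchy_depth``
    is populated (given enough pathways); each non-root picks a random parent
    one level up, and some gain a second parent at the same parent level
    (multi-parent pathways keep their min-depth level).
    """
    rng = np.random.default_rng(config.seed + 1)
    ids = config.pathway_ids()
    depth = min(config.hierarchy_depth, config.n_pathways)
    target_level = {pid: 1 + (j % depth) for j, pid in enumerate(ids)}
    by_level: dict[int, list[str]] = {}
    for pid, lvl in target_level.items():
        by_level.setdefault(lvl, []).append(pid)
    edges: set[tuple[str, str]] = set()
    for lvl in range(2, depth + 1):
        for pid in by_level.get(lvl, []):
            parent = str(rng.choice(by_level[lvl - 1]))
            edges.add((parent, pid))
            if rng.random() < 0.1 and len(by_level[lvl - 1]) > 1:
                others = [p for p in by_level[lvl - 1] if p != parent]
                edges.add((str(rng.choice(others)), pid))
    hierarchy = PathwayHierarchy(edges)
    levels = assign_levels(hierarchy, extra_pathways=set(ids))
    return hierarchy, levels


def motif_carriers(config: SynthConfig, molfiles: list[str]) -> dict[str, set[int]]:
    """Which family motifs each compound carries, read back from structure.

    Carriage is detected through the coloring module itself — a compound
    carries motif ``k`` iff its radius-1 color counts contain motif k's
    center-color signature — so the planted signal is exactly what the
    featurization sees.
    """
    motifs = config.motifs()
    out: dict[str, set[int]] = {}
    for text in molfiles:
        graph = strip_hydrogens(parse_molfile(text))
        colors = set(color_counts(graph, max_radius=1))
        out[graph.compound_id] = {
            k for k, m in enumerate(motifs) if m.center_color in colors
        }
    return out


def gen_annotations(
    config: SynthConfig,
    molfiles: list[str],
    hierarchy: PathwayHierarchy | None = None,
) -> AnnotationTable:
    """Plant compound->pathway annotations from motif carriage.

    Each carrier pair — compound carries the family motif owned by the
    pathway — is annotated independently with probability
    ``signal_strength``.  Noise: each compound independently gains, with
    probability ``noise_rate``, one spurious annotation to a uniformly
    chosen pathway whose motif it does not carry.
    """
    rng = np.random.default_rng(config.seed + 2)
    pathway_ids = config.pathway_ids()
    carriers = motif_carriers(config, molfiles)
    pairs: set[tuple[str, str]] = set()
    for cid in sorted(carriers):
        carried = carriers[cid]
        for j, pid in enumerate(pathway_ids):
            if config.pathway_motif(j) in carried:
                if rng.random() < config.signal_strength:
                    pairs.add((cid, pid))
        if config.noise_rate > 0 and rng.random() < config.noise_rate:
            others = [
                j
                for j in range(config.n_pathways)
                if config.pathway_motif(j) not in carried
            ]
            if others:
                pairs.add((cid, pathway_ids[int(rng.choice(others))]))
    return AnnotationTable(pairs)


@dataclass
class SynthStudy:
    config: SynthConfig
    molfiles: list[str]
    graphs: list[MoleculeGraph]
    hierarchy: PathwayHierarchy
    levels: LevelMap
    annotations: AnnotationTable
    carriers: dict[str, set[int]] = field(default_factory=dict)


def generate_study(config: SynthConfig | None = None) -> SynthStudy:
    """Generate the full benchmark: molfiles, hierarchy, annotations."""
    config = config or SynthConfig()
    molfiles = gen_molecules(config)
    graphs = [parse_molfile(t) for t in molfiles]
    hierarchy, levels = gen_hierarchy(config)
    annotations = gen_annotations(config, molfiles, hierarchy)
    return SynthStudy(
        config=config,
        molfiles=molfiles,
        graphs=graphs,
        hierarchy=hierarchy,
        levels=levels,
        annotations=annotations,
        carriers=motif_carriers(config, molfiles),
    )
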