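"""Labeled cross-join dataset construction.

The pipeline order is: featurize compounds -> aggregate pathway features ->
deduplicate identical feature vectors -> normalize -> cross-join into one
entry per (compound, pathway) pair, labeled by annotation membership.
Hierarchy levels are assigned by minimum depth from a root and drive the
L1+/L2+/L3+ dataset subsets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .chem_io import AnnotationTable, PathwayHierarchy
from .coloring import FeatureMatrix
from .errors import EmptyInputError

logger = logging.getLogger(__name__)


@dataclass
class LevelMap:
    """Pathway hierarchy depth: roots are level 1; children take 1 + min parent level."""

    level: dict[str, int] = field(default_factory=dict)

    def display_level(self, pathway_id: str) -> str:
        lvl = self.level[pathway_id]
        return "L6+" if lvl >= 6 else f"L{lvl}"

    def display_levels(self) -> dict[str, str]:
        return {p: self.display_level(p) for p in self.level}

    def get(self, pathway_id: str, default: int | None = None) -> int | None:
        return self.level.get(pathway_id, default)


@dataclass
class CrossJoinDataset:
    """All |C| x |P| compound-pathway pairs with boolean association labels.

    Entries are ordered row-major: entry ``k`` pairs compound ``k // |P|``
    with pathway ``k % |P|``; its feature vector is the concatenation of the
    two normalized rows.  Feature vectors are materialized on demand
    (:meth:`entry_features`) because the full matrix can be large.
    """

    compound_matrix: FeatureMatrix
    pathway_matrix: FeatureMatrix
    labels: np.ndarray  # bool, length |C| * |P|

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=bool)
        if self.labels.shape != (self.n_entries,):
            raise ValueError(
                f"labels length {self.labels.shape} != |C| x |P| = {self.n_entries}"
            )

    @property
    def n_compounds(self) -> int:
        return len(self.compound_matrix.entity_ids)

    @property
    def n_pathways(self) -> int:
        return len(self.pathway_matrix.entity_ids)

    @property
    def n_entries(self) -> int:
        return self.n_compounds * self.n_pathways

    @property
    def n_positive(self) -> int:
        return int(self.labels.sum())

    @property
    def feature_width(self) -> int:
        return len(self.compound_matrix.colors) + len(self.pathway_matrix.colors)

    def entry_pair(self, k: int | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Compound and pathway indices of entry/entries ``k``."""
        k = np.asarray(k)
        return k // self.n_pathways, k % self.n_pathways

    def entry_features(self, indices: np.ndarray, dtype=np.float32) -> np.ndarray:
        ci, pi = self.entry_pair(np.asarray(indices))
        return np.hstack(
            [
                self.compound_matrix.values[ci].astype(dtype),
                self.pathway_matrix.values[pi].astype(dtype),
            ]
        )


def aggregate_pathway_features(
    compound_matrix: FeatureMatrix, annotations: AnnotationTable
) -> FeatureMatrix:
    """Pathway row = element-wise sum of raw count rows of its member compounds.

    Annotated compounds missing from the matrix are dropped (logged);
    pathways left with no members are excluded entirely.
    """
    idx = compound_matrix.index
    members = annotations.pathway_members()
    dropped = sum(1 for comps in members.values() for c in comps if c not in idx)
    if dropped:
        logger.warning(
            "aggregate_pathway_features: dropped %d member references without "
            "a feature row",
            dropped,
        )
    pathway_ids = sorted(
        p for p, comps in members.items() if any(c in idx for c in comps)
    )
    if not pathway_ids:
        raise EmptyInputError("no pathway retains any member with features")
    values = np.zeros(
        (len(pathway_ids), len(compound_matrix.colors)),
        dtype=compound_matrix.values.dtype,
    )
    for i, p in enumerate(pathway_ids):
        rows = [idx[c] for c in members[p] if c in idx]
        values[i] = compound_matrix.values[rows].sum(axis=0)
    return FeatureMatrix(pathway_ids, list(compound_matrix.colors), values)


def pathway_size(
    annotations: AnnotationTable, sizes: dict[str, int]
) -> dict[str, int]:
    """Pathway size = sum of member compound sizes (non-hydrogen atom counts).

    Pathways whose members all lack a size entry are excluded, mirroring the
    member-drop rule of feature aggregation.
    """
    out: dict[str, int] = {}
    for p, comps in annotations.pathway_members().items():
        known = [sizes[c] for c in comps if c in sizes]
        if known:
            out[p] = int(sum(known))
    return out


def deduplicate(
    matrix: FeatureMatrix,
    annotations: AnnotationTable,
    entity: str = "compound",
) -> tuple[FeatureMatrix, AnnotationTable, dict[str, str]]:
    """Collapse rows with identical feature vectors.

    The lexicographically smallest ID in each duplicate group is kept;
    annotations of removed IDs are re-pointed to the representative (union).
    ``entity`` says which side of the annotation pairs the matrix indexes.
    Returns (matrix, annotations, representative_map) where the map records
    removed_id -> representative_id merges only.
    """
    if entity not in ("compound", "pathway"):
        raise ValueError(f"entity must be compound|pathway, got {entity!r}")
    groups: dict[bytes, list[str]] = {}
    for eid in matrix.entity_ids:
        groups.setdefault(np.ascontiguousarray(matrix.row(eid)).tobytes(), []).append(eid)
    rep_map: dict[str, str] = {}
    keep: set[str] = set()
    for ids in groups.values():
        rep = min(ids)
        keep.add(rep)
        for other in ids:
            if other != rep:
                rep_map[other] = rep
    kept_ids = [e for e in matrix.entity_ids if e in keep]
    idx = matrix.index
    new_matrix = FeatureMatrix(
        kept_ids, list(matrix.colors), matrix.values[[idx[e] for e in kept_ids]]
    )
    pairs = set()
    for compound, pathway in annotations.pairs:
        if entity == "compound":
            compound = rep_map.get(compound, compound)
        else:
            pathway = rep_map.get(pathway, pathway)
        pairs.add((compound, pathway))
    if rep_map:
        logger.info(
            "deduplicate(%s): merged %d duplicate rows into representatives",
            entity,
            len(rep_map),
        )
    return new_matrix, AnnotationTable(pairs), rep_map


def normalize(matrix: FeatureMatrix, method: str = "column_max") -> FeatureMatrix:
    """Scale a raw count matrix into [0, 1].

    ``column_max`` (default): each column divided by its corpus maximum
    (all-zero columns stay 0).  ``row_sum``: each row divided by its sum.
    """
    values = matrix.values.astype(np.float64)
    if method == "column_max":
        colmax = values.max(axis=0)
        scale = np.where(colmax > 0, colmax, 1.0)
        values = values / scale
    elif method == "row_sum":
        rowsum = values.sum(axis=1, keepdims=True)
        values = values / np.where(rowsum > 0, rowsum, 1.0)
    else:
        raise ValueError(f"unknown normalization method {method!r}")
    return FeatureMatrix(list(matrix.entity_ids), list(matrix.colors), values)


def cross_join(
    compound_matrix: FeatureMatrix,
    pathway_matrix: FeatureMatrix,
    annotations: AnnotationTable,
) -> CrossJoinDataset:
    """Cartesian product of compounds and pathways with membership labels."""
    n_c, n_p = len(compound_matrix.entity_ids), len(pathway_matrix.entity_ids)
    if n_c == 0 or n_p == 0:
        raise EmptyInputError("cross_join: empty compound or pathway matrix")
    c_idx = compound_matrix.index
    p_idx = pathway_matrix.index
    labels = np.zeros(n_c * n_p, dtype=bool)
    for compound, pathway in annotations.pairs:
        if compound in c_idx and pathway in p_idx:
            labels[c_idx[compound] * n_p + p_idx[pathway]] = True
    return CrossJoinDataset(compound_matrix, pathway_matrix, labels)


def assign_levels(
    hierarchy: PathwayHierarchy, extra_pathways: set[str] | None = None
) -> LevelMap:
    """Depth of each pathway: 1 for roots, else 1 + minimum over parents.

    Pathways in ``extra_pathways`` but absent from the hierarchy are treated
    as roots (level 1) with a log message.
    """
    import networkx as nx

    hierarchy.validate()
    g = hierarchy.to_digraph()
    level: dict[str, int] = {}
    for node in nx.topological_sort(g):
        parents = list(g.predecessors(node))
        if not parents:
            level[node] = 1
        else:
            level[node] = 1 + min(level[p] for p in parents)
    if extra_pathways:
        missing = sorted(set(extra_pathways) - set(level))
        if missing:
            logger.info(
                "assign_levels: %d annotated pathways absent from hierarchy; "
                "assigned level 1",
                len(missing),
            )
            for p in missing:
                level[p] = 1
    return LevelMap(level)


def subset_by_level(
    dataset: CrossJoinDataset, levels: LevelMap, min_level: int
) -> CrossJoinDataset:
    """Restrict the dataset to pathways with hierarchy level >= ``min_level``.

    ``min_level=1`` returns the full (L1+) dataset unchanged; compounds are
    never removed, so entry count becomes |C| x |P'|.
    """
    if min_level not in (1, 2, 3):
        raise ValueError(f"min_level must be 1, 2 or 3, got {min_level}")
    if min_level == 1:
        return dataset
    keep = [
        i
        for i, p in enumerate(dataset.pathway_matrix.entity_ids)
        if (levels.get(p, 1) or 1) >= min_level
    ]
    if not keep:
        raise EmptyInputError(f"no pathway has level >= {min_level}")
    n_p = dataset.n_pathways
    pm = dataset.pathway_matrix
    new_pm = FeatureMatrix(
        [pm.entity_ids[i] for i in keep], list(pm.colors), pm.values[keep]
    )
    label_grid = dataset.labels.reshape(dataset.n_compounds, n_p)[:, keep]
    return CrossJoinDataset(dataset.compound_matrix, new_pm, label_grid.ravel())


def build_dataset(
    graphs,
    annotations: AnnotationTable,
    hierarchy: PathwayHierarchy | None = None,
    min_level: int = 1,
    max_radius: int | str = "auto",
    normalization: str = "column_max",
) -> tuple[CrossJoinDataset, LevelMap]:
    """End-to-end dataset construction from molecular graphs and annotations.

    Runs featurize -> aggregate -> dedup (compounds then pathways) ->
    normalize -> cross-join -> level subset.  Annotation pairs whose compound
    has no structure are dropped with a logged count.
    """
    from .coloring import featurize_compounds

    compound_raw = featurize_compounds(list(graphs), max_radius)
    have = set(compound_raw.entity_ids)
    usable = {(c, p) for c, p in annotations.pairs if c in have}
    dropped = len(annotations.pairs) - len(usable)
    if dropped:
        logger.warning(
            "build_dataset: dropped %d annotation pairs without a parseable structure",
            dropped,
        )
    if not usable:
        raise EmptyInputError("no annotation pair has a compound with a structure")
    annotations = AnnotationTable(usable)

    pathway_raw = aggregate_pathway_features(compound_raw, annotations)
    compound_raw, annotations, _ = deduplicate(compound_raw, annotations, "compound")
    pathway_raw, annotations, _ = deduplicate(pathway_raw, annotations, "pathway")
    compound_norm = normalize(compound_raw, normalization)
    pathway_norm = normalize(pathway_raw, normalization)
    dataset = cross_join(compound_norm, pathway_norm, annotations)

    if hierarchy is not None:
        levels = assign_levels(hierarchy, extra_pathways=annotations.pathways)
    else:
        levels = LevelMap({p: 1 for p in dataset.pathway_matrix.entity_ids})
    if min_level > 1:
        dataset = subset_by_level(dataset, levels, min_level)
    return dataset, levels
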