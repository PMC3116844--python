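"""Template selection within a predicted fold.

Candidate template domains and the modeling target are each represented as
a feature vector over the fold library's PSSMs: per PSSM, the (identity
fraction x coverage) of the best surviving local alignment, or 0 when no
alignment passes the thresholds. Entities are then clustered hierarchically
with 1 - Pearson as the distance, and the templates most correlated with
the target are selected (downstream modeling conventionally uses at most
3 templates, hence the default k). Identity here is over aligned pairs of the *local* alignment —
distinct from the global identity used by the redundancy filters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.cluster import hierarchy

from .fold_library import FoldLibrary
from .fold_scoring import ScanThresholds, pearson, scan
from .pairwise_align import KarlinAltschulParams
from .seq_formats import SequenceRecord


@dataclass(frozen=True)
class TemplateFeatureVector:
    """Per-PSSM (identity x coverage) features for one domain or target."""

    entity_id: str
    pssm_ids: tuple[str, ...]
    values: np.ndarray  # in [0, 1]

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        if values.shape != (len(self.pssm_ids),):
            raise ValueError("feature length must equal the number of PSSMs")
        if np.any((values < 0) | (values > 1)):
            raise ValueError("features are products of fractions, in [0, 1]")
        values.setflags(write=False)
        object.__setattr__(self, "values", values)


@dataclass(frozen=True)
class Dendrogram:
    """Agglomerative clustering result: scipy linkage matrix plus leaf ids."""

    linkage: np.ndarray  # (n-1, 4) scipy format
    leaf_ids: tuple[str, ...]

    @property
    def merge_heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def to_newick(self) -> str:
        """Serialize as a Newick tree with merge heights as branch lengths."""
        tree = hierarchy.to_tree(self.linkage)

        def render(node) -> str:
            if node.is_leaf():
                return self.leaf_ids[node.id]
            left, right = node.get_left(), node.get_right()
            ln = node.dist - left.dist
            rn = node.dist - right.dist
            return f"({render(left)}:{ln:.6g},{render(right)}:{rn:.6g})"

        return render(tree) + ";"


def template_features(
    entities: Sequence[SequenceRecord],
    library: FoldLibrary,
    thresholds: ScanThresholds | None = None,
    ka_params: KarlinAltschulParams | None = None,
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> list[TemplateFeatureVector]:
    """Best-alignment (identity x coverage) per entity per library PSSM."""
    if len(library) == 0:
        raise ValueError("library is empty")
    pssm_ids = tuple(p.id for p in library.pssms)
    references = {p.id: p.reference.residues for p in library.pssms}
    out = []
    for entity in entities:
        hits = {
            aln.pssm_id: aln
            for aln in scan(
                entity, library, thresholds, ka_params,
                gap_open=gap_open, gap_extend=gap_extend,
            )
        }
        values = np.zeros(len(pssm_ids))
        for i, pid in enumerate(pssm_ids):
            aln = hits.get(pid)
            if aln is None:
                continue
            reference = references[pid]
            identical = sum(
                entity.residues[qi - 1] == reference[pj - 1] for qi, pj in aln.pairs
            )
            identity = identical / len(aln.pairs)
            values[i] = identity * aln.coverage
        out.append(
            TemplateFeatureVector(entity_id=entity.id, pssm_ids=pssm_ids, values=values)
        )
    return out


def _similarity_to(target: TemplateFeatureVector, other: TemplateFeatureVector) -> float:
    return pearson(target.values, other.values)


def cluster(
    vectors: Sequence[TemplateFeatureVector], linkage: str = "average"
) -> Dendrogram:
    """Agglomerative clustering with distance = 1 - Pearson correlation.

    Zero-variance vectors follow the package-wide convention (similarity 0,
    hence distance 1). Average linkage (UPGMA) by default.
    """
    if len(vectors) < 2:
        raise ValueError("clustering requires >= 2 vectors")
    ids = tuple(v.entity_id for v in vectors)
    axes = vectors[0].pssm_ids
    for v in vectors[1:]:
        if v.pssm_ids != axes:
            raise ValueError("feature vectors have mismatched PSSM axes")
    n = len(vectors)
    condensed = []
    for i in range(n):
        for j in range(i + 1, n):
            condensed.append(1.0 - pearson(vectors[i].values, vectors[j].values))
    Z = hierarchy.linkage(np.asarray(condensed), method=linkage)
    return Dendrogram(linkage=Z, leaf_ids=ids)


def select_templates(
    dendrogram: Dendrogram,
    vectors: Sequence[TemplateFeatureVector],
    target_id: str,
    k: int = 3,
) -> list[str]:
    """Rank non-target entities by Pearson similarity to the target; top k.

    The dendrogram is retained for reporting/visual grouping; selection
    itself is the deterministic correlation ranking (ties by entity id).
    """
    by_id = {v.entity_id: v for v in vectors}
    if target_id not in by_id or target_id not in dendrogram.leaf_ids:
        raise ValueError(f"target {target_id!r} not among clustered entities")
    target = by_id[target_id]
    # similarities rounded to 12 decimals so mathematically tied entities
    # fall through to the id tie-break regardless of float noise
    ranked = sorted(
        (v for v in vectors if v.entity_id != target_id),
        key=lambda v: (-round(_similarity_to(target, v), 12), v.entity_id),
    )
    return [v.entity_id for v in ranked[:k]]
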