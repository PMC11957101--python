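"""Metapath-based label and feature generation.

Two fixed metapaths over the typed graph drive everything downstream:

* ``Disease - Compound - Gene`` — a gene reachable from a query disease
  through a compound intermediary is a *labeled positive* (class 1).
* ``Gene - term - Gene`` — genes that share an ontology term (EFO role)
  with a positive gene, and are not themselves positive, form the
  *unlabeled* pool (class 0).

The feature space is the set of ontology-term nodes bridging at least
one positive gene to at least one unlabeled gene; each gene's feature
vector is the binary indicator of adjacency to each term, stored as a
CSR sparse matrix.  All orderings are lexicographic so the dataset is
reproducible byte-for-byte regardless of input row order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .graph import KnowledgeGraph

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TypeRoles:
    """Which node type plays each metapath role."""

    disease: str = "Disease"
    compound: str = "Compound"
    gene: str = "Gene"
    term: str = "EFO"


DEFAULT_ROLES = TypeRoles()


@dataclass
class LabeledGeneSets:
    disease_cuis: list[str]
    positive_genes: list[str]
    unlabeled_genes: list[str]
    feature_terms: list[str]

    def validate(self) -> None:
        if set(self.positive_genes) & set(self.unlabeled_genes):
            raise ValueError("positive and unlabeled gene sets overlap")


@dataclass
class PUDataset:
    """Sparse binary gene x term matrix with PU labels (1 labeled, 0 unlabeled)."""

    X: sp.csr_matrix
    y: np.ndarray
    row_ids: list[str]
    col_ids: list[str]

    @property
    def n_pos(self) -> int:
        return int(self.y.sum())

    @property
    def n_unl(self) -> int:
        return int((self.y == 0).sum())

    def unlabeled_ids(self) -> list[str]:
        return [g for g, yi in zip(self.row_ids, self.y) if yi == 0]

    def save(self, prefix: str | Path) -> None:
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        scipy.io.mmwrite(str(prefix) + ".X.mtx", self.X.tocoo(), field="integer")
        pd.DataFrame({"gene_id": self.row_ids, "label": self.y}).to_csv(
            str(prefix) + ".rows.tsv", sep="\t", index=False
        )
        pd.DataFrame({"term_id": self.col_ids}).to_csv(
            str(prefix) + ".cols.tsv", sep="\t", index=False
        )

    @classmethod
    def load(cls, prefix: str | Path) -> "PUDataset":
        prefix = str(prefix)
        X = sp.csr_matrix(scipy.io.mmread(prefix + ".X.mtx"))
        rows = pd.read_csv(prefix + ".rows.tsv", sep="\t", dtype={"gene_id": str})
        cols = pd.read_csv(prefix + ".cols.tsv", sep="\t", dtype=str)
        return cls(
            X=X,
            y=rows["label"].to_numpy(dtype=np.int64),
            row_ids=rows["gene_id"].tolist(),
            col_ids=cols["term_id"].tolist(),
        )


def select_positive_genes(
    kg: KnowledgeGraph,
    disease_cuis: Iterable[str],
    roles: TypeRoles = DEFAULT_ROLES,
) -> list[str]:
    """Genes on a Disease-Compound-Gene path from any query disease.

    The union over the given disease CUIs is returned in lexicographic
    order.  A direct disease-gene edge does not qualify: the compound
    intermediary is part of the path template.
    """
    cuis = list(disease_cuis)
    if not cuis:
        raise ValueError("at least one disease CUI is required")
    positives: set[str] = set()
    for cui in cuis:
        if not kg.has_node(cui):
            raise KeyError(f"disease CUI {cui!r} not found in graph")
        if kg.node_type(cui) != roles.disease:
            raise TypeError(
                f"node {cui!r} has type {kg.node_type(cui)!r}, "
                f"expected {roles.disease!r}"
            )
        for compound in kg.neighbors(cui, roles.compound):
            positives.update(kg.neighbors(compound, roles.gene))
    return sorted(positives)


def select_unlabeled_genes(
    kg: KnowledgeGraph,
    positives: Sequence[str],
    roles: TypeRoles = DEFAULT_ROLES,
) -> list[str]:
    """Genes sharing an ontology term with a positive, minus the positives."""
    if not positives:
        raise ValueError("positives must be non-empty")
    pos = set(positives)
    bridge_terms: set[str] = set()
    for g in pos:
        bridge_terms.update(kg.neighbors(g, roles.term))
    unlabeled: set[str] = set()
    for term in bridge_terms:
        unlabeled.update(kg.neighbors(term, roles.gene))
    return sorted(unlabeled - pos)


def collect_feature_terms(
    kg: KnowledgeGraph,
    positives: Sequence[str],
    unlabeled: Sequence[str],
    roles: TypeRoles = DEFAULT_ROLES,
) -> list[str]:
    """Ontology terms bridging >=1 positive gene to >=1 unlabeled gene."""
    pos, unl = set(positives), set(unlabeled)
    if pos & unl:
        raise ValueError("positives and unlabeled overlap")
    terms: set[str] = set()
    candidate_terms: set[str] = set()
    for g in pos:
        candidate_terms.update(kg.neighbors(g, roles.term))
    for term in candidate_terms:
        genes = set(kg.neighbors(term, roles.gene))
        if genes & unl:
            terms.add(term)
    return sorted(terms)


def label_genes(
    kg: KnowledgeGraph,
    disease_cuis: Iterable[str],
    roles: TypeRoles = DEFAULT_ROLES,
) -> LabeledGeneSets:
    """Run both metapath selections and the feature-term collection."""
    cuis = sorted(set(disease_cuis))
    positives = select_positive_genes(kg, cuis, roles)
    unlabeled = select_unlabeled_genes(kg, positives, roles)
    terms = collect_feature_terms(kg, positives, unlabeled, roles)
    logger.info(
        "labeled %d positive, %d unlabeled genes; %d feature terms",
        len(positives), len(unlabeled), len(terms),
    )
    sets = LabeledGeneSets(cuis, positives, unlabeled, terms)
    sets.validate()
    return sets


def build_pu_dataset(
    kg: KnowledgeGraph,
    sets: LabeledGeneSets,
    roles: TypeRoles = DEFAULT_ROLES,
) -> PUDataset:
    """Assemble the n x m binary indicator matrix and PU label vector.

    Rows are positives first, then unlabeled, each block lexicographic;
    ``X[i, j] = 1`` iff gene ``row_ids[i]`` is adjacent to term
    ``col_ids[j]``.  All-zero rows (genes touching none of the selected
    feature terms) are retained and logged, not dropped.
    """
    sets.validate()
    if not sets.feature_terms:
        raise ValueError(
            "no feature terms: the graph has no Gene-term-Gene bridge between "
            "positive and unlabeled genes"
        )
    row_ids = sorted(sets.positive_genes) + sorted(sets.unlabeled_genes)
    col_ids = sorted(sets.feature_terms)
    col_index = {t: j for j, t in enumerate(col_ids)}
    indptr = [0]
    indices: list[int] = []
    for g in row_ids:
        js = sorted(
            col_index[t] for t in kg.neighbors(g, roles.term) if t in col_index
        )
        indices.extend(js)
        indptr.append(len(indices))
    X = sp.csr_matrix(
        (np.ones(len(indices), dtype=np.int8), indices, indptr),
        shape=(len(row_ids), len(col_ids)),
    )
    y = np.r_[
        np.ones(len(sets.positive_genes), dtype=np.int64),
        np.zeros(len(sets.unlabeled_genes), dtype=np.int64),
    ]
    zero_rows = [g for g, c in zip(row_ids, np.diff(X.indptr)) if c == 0]
    if zero_rows:
        logger.warning(
            "%d gene(s) have all-zero feature rows (kept): %s",
            len(zero_rows), zero_rows[:10],
        )
    return PUDataset(X=X, y=y, row_ids=row_ids, col_ids=col_ids)
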