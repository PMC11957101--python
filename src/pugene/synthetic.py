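"""Synthetic heterogeneous knowledge graphs with a planted class prior.

The generator emulates the data regime the pipeline targets: a disease
connected through compound nodes to its *labeled* positive genes
(Disease-Compound-Gene metapath), genes co-annotated to ontology terms
(Gene-term-Gene metapath) which provide both the unlabeled candidate
pool and the binary feature space, and — crucially — a planted fraction
``alpha_true`` of *hidden* positives among the unlabeled genes.

SCAR holds by construction: the labeled positives are a uniform random
subsample of the true positives, and every true positive (labeled or
hidden) draws its term edges from the same Bernoulli law
(``p_feature_pos`` per term, vs. ``p_feature_neg`` for negatives), so
labeling is independent of the features.

Default sizes follow the study conditions used throughout the test
suite: 1,000 labeled positives, 2,000 unlabeled genes, 200 terms,
edge probabilities 0.3 (positive) vs 0.05 (negative).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .graph import KnowledgeGraph, load_graph, save_graph
from .labels import DEFAULT_ROLES, PUDataset, TypeRoles, build_pu_dataset, label_genes

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SyntheticSpec:
    n_genes: int = 3000
    n_terms: int = 200
    alpha_true: float = 0.3
    label_fraction: float = 0.625
    p_feature_pos: float = 0.3
    p_feature_neg: float = 0.05
    n_diseases: int = 1
    compounds_per_positive: int = 1
    seed: int = 0
    # optional explicit labeled-pool size; resolves the degeneracy at
    # alpha_true = 0 (where label_fraction must be 1 and any number of
    # true positives would be consistent)
    n_labeled: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha_true <= 1.0:
            raise ValueError("alpha_true must lie in [0, 1]")
        if not 0.0 < self.label_fraction <= 1.0:
            raise ValueError("label_fraction must lie in (0, 1]")
        if not 0.0 <= self.p_feature_neg < self.p_feature_pos <= 1.0:
            raise ValueError("need 0 <= p_feature_neg < p_feature_pos <= 1")
        if self.n_genes < 2 or self.n_terms < 1:
            raise ValueError("graph too small")
        if self.n_diseases < 1 or self.compounds_per_positive < 1:
            raise ValueError("need >= 1 disease and >= 1 compound per positive")

    @classmethod
    def from_pool_sizes(
        cls,
        n_labeled: int = 1000,
        n_unlabeled: int = 2000,
        alpha: float = 0.3,
        **kwargs,
    ) -> "SyntheticSpec":
        """Spec whose labeled/unlabeled pools hit the requested sizes.

        ``alpha`` is the target fraction of hidden positives among the
        ``n_unlabeled`` genes.
        """
        n_hidden = round(alpha * n_unlabeled)
        n_true = n_labeled + n_hidden
        return cls(
            n_genes=n_labeled + n_unlabeled,
            alpha_true=alpha,
            label_fraction=n_labeled / n_true,
            n_labeled=n_labeled,
            **kwargs,
        )


@dataclass
class SyntheticTruth:
    true_positive_genes: set[str]
    labeled_positive_genes: set[str]
    hidden_positive_genes: set[str]
    realized_alpha: float


def _solve_counts(spec: SyntheticSpec) -> tuple[int, int]:
    """Integer (n_true, n_labeled) best realizing alpha_true and label_fraction."""
    if spec.n_labeled is not None:
        n_labeled = spec.n_labeled
        n_unl = spec.n_genes - n_labeled
        if n_labeled < 1 or n_unl < 1:
            raise ValueError("infeasible spec: n_labeled leaves no unlabeled pool")
        n_hidden = round(spec.alpha_true * n_unl)
        if spec.alpha_true > 0 and n_hidden == 0:
            raise ValueError(
                "infeasible spec: alpha_true > 0 but no hidden positive can be "
                "realized at this graph size"
            )
        return n_labeled + n_hidden, n_labeled
    best = None
    for n_true in range(1, spec.n_genes + 1):
        n_labeled = round(spec.label_fraction * n_true)
        if n_labeled < 1 or n_labeled > n_true:
            continue
        n_unl = spec.n_genes - n_labeled
        if n_unl < 1:
            continue
        n_hidden = n_true - n_labeled
        realized = n_hidden / n_unl
        cost = abs(realized - spec.alpha_true) + abs(
            n_labeled / n_true - spec.label_fraction
        )
        if best is None or cost < best[0]:
            best = (cost, n_true, n_labeled)
    if best is None:
        raise ValueError("infeasible spec: no valid (n_true, n_labeled) split")
    _, n_true, n_labeled = best
    n_hidden = n_true - n_labeled
    realized = n_hidden / (spec.n_genes - n_labeled)
    if spec.alpha_true > 0 and n_hidden == 0:
        raise ValueError(
            "infeasible spec: alpha_true > 0 but no hidden positive can be "
            "realized at this graph size"
        )
    if abs(realized - spec.alpha_true) > 0.05:
        raise ValueError(
            f"infeasible spec: closest realizable alpha is {realized:.3f}, "
            f"target {spec.alpha_true:.3f}"
        )
    return n_true, n_labeled


def generate(spec: SyntheticSpec) -> tuple[KnowledgeGraph, SyntheticTruth]:
    """Build the typed graph and its planted ground truth.

    Deterministic given ``spec.seed``.  Guarantees: (a) exactly the
    labeled positives are wired Disease-Compound-Gene, so the metapath
    labeler recovers them as class 1; (b) every unlabeled gene shares at
    least one term with at least one labeled positive (isolated genes
    are re-wired, with a logged count), so the unlabeled pool is exactly
    the remaining genes.
    """
    rng = np.random.default_rng(spec.seed)
    n_true, n_labeled = _solve_counts(spec)

    gw = max(4, len(str(spec.n_genes)))
    genes = [f"G{i:0{gw}d}" for i in range(spec.n_genes)]
    terms = [f"T{i:04d}" for i in range(spec.n_terms)]
    diseases = [f"C00D{i:03d}" for i in range(spec.n_diseases)]

    true_idx = rng.choice(spec.n_genes, size=n_true, replace=False)
    labeled_idx = rng.choice(true_idx, size=n_labeled, replace=False)  # SCAR
    is_true = np.zeros(spec.n_genes, dtype=bool)
    is_true[true_idx] = True
    is_labeled = np.zeros(spec.n_genes, dtype=bool)
    is_labeled[labeled_idx] = True

    # per-gene Bernoulli term edges; identical law for labeled and hidden
    # positives is what makes the SCAR assumption hold exactly
    p_vec = np.where(is_true, spec.p_feature_pos, spec.p_feature_neg)
    M = rng.random((spec.n_genes, spec.n_terms)) < p_vec[:, None]

    # each labeled positive needs >= 1 term edge so it can bridge
    empty_pos = np.flatnonzero(is_labeled & ~M.any(axis=1))
    for i in empty_pos:
        M[i, rng.integers(spec.n_terms)] = True
    pos_terms = np.flatnonzero(M[is_labeled].any(axis=0))
    # every unlabeled gene must share a term with some labeled positive
    rewired = 0
    for i in np.flatnonzero(~is_labeled):
        if not M[i, pos_terms].any():
            M[i, rng.choice(pos_terms)] = True
            rewired += 1
    if empty_pos.size or rewired:
        logger.info(
            "re-wired %d empty positive row(s) and %d isolated unlabeled gene(s)",
            empty_pos.size, rewired,
        )

    kg = KnowledgeGraph()
    for d in diseases:
        kg.add_node(d, DEFAULT_ROLES.disease)
    for t in terms:
        kg.add_node(t, DEFAULT_ROLES.term)
    for g in genes:
        kg.add_node(g, DEFAULT_ROLES.gene)
    cid = 0
    for j, i in enumerate(sorted(labeled_idx)):
        for _ in range(spec.compounds_per_positive):
            c = f"CMP{cid:05d}"
            cid += 1
            kg.add_node(c, DEFAULT_ROLES.compound)
            kg.add_edge(diseases[j % spec.n_diseases], c, "indication")
            kg.add_edge(c, genes[i], "targets")
    gi, ti = np.nonzero(M)
    for i, j in zip(gi, ti):
        kg.add_edge(genes[i], terms[j], "associated_with")

    labeled_set = {genes[i] for i in labeled_idx}
    true_set = {genes[i] for i in true_idx}
    hidden_set = true_set - labeled_set
    truth = SyntheticTruth(
        true_positive_genes=true_set,
        labeled_positive_genes=labeled_set,
        hidden_positive_genes=hidden_set,
        realized_alpha=len(hidden_set) / (spec.n_genes - n_labeled),
    )
    logger.info(
        "synthetic graph: %d genes (%d labeled, %d hidden positives), "
        "%d terms, realized alpha %.4f",
        spec.n_genes, n_labeled, len(hidden_set), spec.n_terms,
        truth.realized_alpha,
    )
    return kg, truth


def emit_fixture(spec: SyntheticSpec, out_dir: str | Path) -> dict[str, Path]:
    """Write the graph (edge/node TSV) plus a planted-truth table."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    kg, truth = generate(spec)
    paths = {
        "edges": out_dir / "edges.tsv",
        "nodes": out_dir / "nodes.tsv",
        "truth": out_dir / "truth.tsv",
    }
    save_graph(kg, paths["edges"], paths["nodes"])
    genes = sorted(
        g for g in kg.node_ids() if kg.node_type(g) == DEFAULT_ROLES.gene
    )
    pd.DataFrame(
        {
            "gene_id": genes,
            "true_class": [int(g in truth.true_positive_genes) for g in genes],
            "labeled_flag": [int(g in truth.labeled_positive_genes) for g in genes],
        }
    ).to_csv(paths["truth"], sep="\t", index=False)
    return paths


def disease_cuis(kg: KnowledgeGraph, roles: TypeRoles = DEFAULT_ROLES) -> list[str]:
    """All disease-typed node ids in a (synthetic) graph."""
    return kg.nodes_of_type(roles.disease)


def make_pu_dataset(
    spec: SyntheticSpec,
) -> tuple[PUDataset, SyntheticTruth]:
    """End-to-end: generate the graph, then run the metapath labeler on it."""
    kg, truth = generate(spec)
    sets = label_genes(kg, disease_cuis(kg))
    return build_pu_dataset(kg, sets), truth
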