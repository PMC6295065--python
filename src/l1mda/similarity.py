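"""Disease semantic similarity and miRNA functional similarity.

A disease ``d`` is placed in a hierarchical ontology (MeSH Category C in the
human data) and is described by its DAG: the set ``T(d)`` of ``d`` plus all of
its ancestors, together with the parent->child edges ``E(d)`` among them.
Each ancestor ``t`` contributes to the semantics of ``d`` with a weight that
decays by a factor (0.5 by default) per hierarchy level::

    D_d(d) = 1
    D_d(t) = max{ decay * D_d(t') : t' a child of t inside the DAG }

The semantic value ``DV(d)`` is the sum of all contributions, and the
similarity of two diseases is the ratio of their shared contributions to the
sum of their semantic values.  MiRNA functional similarity (MISIM) follows by
a best-match average over the two miRNAs' associated-disease sets.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "DiseaseDAG",
    "SemanticProfile",
    "semantic_profile",
    "disease_similarity",
    "disease_group_similarity",
    "build_disease_similarity",
    "mirna_functional_similarity",
    "check_similarity",
]

DEFAULT_DECAY = 0.5


@dataclass(frozen=True)
class DiseaseDAG:
    """A disease plus its ancestor closure.

    Parameters
    ----------
    disease_id
        Identifier of the disease itself; must be a member of ``nodes``.
    nodes
        ``T(d)``: the disease and every ontology ancestor of it.
    edges
        ``E(d)``: directed parent->child pairs among ``nodes``.
    """

    disease_id: str
    nodes: frozenset[str]
    edges: frozenset[tuple[str, str]] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        object.__setattr__(self, "nodes", frozenset(self.nodes))
        object.__setattr__(self, "edges", frozenset(tuple(e) for e in self.edges))
        if self.disease_id not in self.nodes:
            raise ValueError(
                f"disease {self.disease_id!r} missing from its own node set"
            )
        for p, c in self.edges:
            if p not in self.nodes or c not in self.nodes:
                raise ValueError(f"edge ({p!r}, {c!r}) leaves the node set")

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g

    def validate(self) -> None:
        """Check acyclicity and that every node is an ancestor of the disease."""
        g = self.graph()
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError(f"cycle detected in DAG of {self.disease_id!r}")
        closure = nx.ancestors(g, self.disease_id) | {self.disease_id}
        stranded = self.nodes - closure
        if stranded:
            raise ValueError(
                f"nodes with no path down to {self.disease_id!r}: {sorted(stranded)}"
            )


@dataclass(frozen=True)
class SemanticProfile:
    """Per-ancestor contributions ``D_d(t)`` and their sum ``DV(d)``."""

    disease_id: str
    contribution: dict[str, float]
    semantic_value: float


def semantic_profile(dag: DiseaseDAG, decay: float = DEFAULT_DECAY) -> SemanticProfile:
    """Evaluate the decaying-contribution recursion over a disease DAG.

    Nodes are processed children-before-parents (reverse topological order),
    so each contribution is a single max over already-computed children.
    """
    if not 0.0 < decay < 1.0:
        raise ValueError(f"decay must lie in (0, 1), got {decay}")
    dag.validate()
    g = dag.graph()
    contribution: dict[str, float] = {}
    for node in reversed(list(nx.topological_sort(g))):
        if node == dag.disease_id:
            contribution[node] = 1.0
        else:
            # every non-disease node has >=1 child on a path to the disease
            contribution[node] = decay * max(
                contribution[c] for c in g.successors(node)
            )
    return SemanticProfile(
        disease_id=dag.disease_id,
        contribution=contribution,
        semantic_value=float(sum(contribution.values())),
    )


def disease_similarity(p_i: SemanticProfile, p_j: SemanticProfile) -> float:
    """Semantic similarity of two diseases from their profiles.

    Shared ancestors contribute the sum of both profiles' contributions,
    normalised by the two semantic values; the result lies in [0, 1] and an
    empty intersection gives 0.
    """
    shared = p_i.contribution.keys() & p_j.contribution.keys()
    if not shared:
        return 0.0
    num = sum(p_i.contribution[t] + p_j.contribution[t] for t in shared)
    return num / (p_i.semantic_value + p_j.semantic_value)


def disease_group_similarity(
    d: str, group: set[str] | list[str], w_d: pd.DataFrame
) -> float:
    """Best-match similarity of disease ``d`` against a nonempty disease group."""
    members = list(group)
    if not members:
        raise ValueError("disease group must be nonempty")
    missing = [t for t in [d, *members] if t not in w_d.index]
    if missing:
        raise KeyError(f"diseases absent from similarity matrix: {missing}")
    return float(w_d.loc[d, members].max())


def build_disease_similarity(
    dags: list[DiseaseDAG], decay: float = DEFAULT_DECAY
) -> pd.DataFrame:
    """Pairwise semantic similarity matrix over a collection of disease DAGs.

    The upper triangle is computed and mirrored; the diagonal is exactly 1.
    """
    if not dags:
        raise ValueError("need at least one disease DAG")
    ids = [dag.disease_id for dag in dags]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate disease ids: {dupes}")
    profiles = [semantic_profile(dag, decay=decay) for dag in dags]
    n = len(ids)
    values = np.eye(n)
    for a, b in itertools.combinations(range(n), 2):
        s = disease_similarity(profiles[a], profiles[b])
        values[a, b] = values[b, a] = s
    return pd.DataFrame(values, index=ids, columns=ids)


def mirna_functional_similarity(a: pd.DataFrame, w_d: pd.DataFrame) -> pd.DataFrame:
    """MISIM: best-match-average functional similarity between miRNAs.

    For miRNAs with associated-disease sets DT1 and DT2, the score is::

        ( sum_{d in DT1} S(d, DT2) + sum_{d in DT2} S(d, DT1) ) / (|DT1| + |DT2|)

    where ``S(d, DT)`` is the best-match group similarity.  A miRNA with no
    associated disease has similarity 0 to every other miRNA (no functional
    evidence) and 1 to itself.
    """
    missing = [d for d in a.columns if d not in w_d.index]
    if missing:
        raise KeyError(f"association diseases absent from W_d: {missing}")
    wd = w_d.loc[a.columns, a.columns].to_numpy()
    amat = a.to_numpy()
    disease_sets = [np.flatnonzero(amat[i] == 1) for i in range(amat.shape[0])]
    n = amat.shape[0]
    values = np.eye(n)
    for i, j in itertools.combinations(range(n), 2):
        dt1, dt2 = disease_sets[i], disease_sets[j]
        if dt1.size == 0 or dt2.size == 0:
            continue
        block = wd[np.ix_(dt1, dt2)]
        num = block.max(axis=1).sum() + block.max(axis=0).sum()
        values[i, j] = values[j, i] = num / (dt1.size + dt2.size)
    return pd.DataFrame(values, index=a.index, columns=a.index)


def check_similarity(m: pd.DataFrame, atol: float = 1e-8) -> None:
    """Validate similarity-matrix invariants: square, symmetric, unit diagonal,
    entries in [0, 1] (within ``atol``)."""
    v = m.to_numpy(dtype=float)
    if v.ndim != 2 or v.shape[0] != v.shape[1]:
        raise ValueError(f"similarity matrix must be square, got shape {v.shape}")
    if list(m.index) != list(m.columns):
        raise ValueError("similarity matrix row and column labels differ")
    if not np.allclose(v, v.T, atol=atol):
        raise ValueError("similarity matrix is not symmetric")
    if not np.allclose(np.diag(v), 1.0, atol=atol):
        raise ValueError("similarity matrix diagonal is not 1")
    if v.min() < -atol or v.max() > 1 + atol:
        raise ValueError("similarity values outside [0, 1]")
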