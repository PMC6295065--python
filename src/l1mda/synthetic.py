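"""Seeded synthetic fixtures: ontology forests and block-structured associations.

The generator emulates the shape of the real inputs without any downloads:

* a disease ontology as balanced trees under one shared root — one subtree
  per planted block, so diseases of the same block share a deep ancestor and
  their semantic similarity exceeds the between-block similarity;
* a binary association matrix with miRNAs and diseases partitioned into the
  same number of blocks, matched-block pairs drawn Bernoulli(p_within) and
  mismatched pairs Bernoulli(p_between);
* the miRNA functional similarity derived from the generated associations
  (mirroring the real data flow, where MISIM is association-derived).

Defaults are the planted-block study conditions used throughout the test
surface: 20 miRNAs x 12 diseases in 3 blocks, p_within 0.8, p_between 0.05.
All randomness flows from one seed, split into independent per-component
streams so adding a component never perturbs earlier draws.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .similarity import (
    DiseaseDAG,
    build_disease_similarity,
    mirna_functional_similarity,
)

__all__ = ["FixtureSpec", "Fixture", "make_dag_forest", "make_associations", "make_fixture"]

ROOT = "C"  # shared ontology root, after the MeSH disease category


@dataclass(frozen=True)
class FixtureSpec:
    n_mirnas: int = 20
    n_diseases: int = 12
    n_blocks: int = 3
    p_within: float = 0.8
    p_between: float = 0.05
    dag_depth: int = 3
    dag_branching: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_mirnas", "n_diseases", "n_blocks", "dag_depth", "dag_branching"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0.0 <= self.p_between <= self.p_within <= 1.0:
            raise ValueError("need 0 <= p_between <= p_within <= 1")

    def _streams(self) -> list[np.random.Generator]:
        # one child stream per component, in a fixed documented order:
        # 0 = dag forest (currently deterministic), 1 = associations
        return [np.random.default_rng(s) for s in np.random.SeedSequence(self.seed).spawn(2)]


@dataclass
class Fixture:
    spec: FixtureSpec
    dags: list[DiseaseDAG]
    A: pd.DataFrame
    W_m: pd.DataFrame
    W_d: pd.DataFrame
    planted_pairs: set[tuple[str, str]]
    mirna_blocks: dict[str, int]
    disease_blocks: dict[str, int]


def _block_split(n: int, n_blocks: int) -> list[int]:
    """Block index per entity, contiguous near-equal groups."""
    return [b for b, chunk in enumerate(np.array_split(np.arange(n), n_blocks)) for _ in chunk]


def disease_ids(spec: FixtureSpec) -> list[str]:
    return [f"D{i:03d}" for i in range(spec.n_diseases)]


def mirna_ids(spec: FixtureSpec) -> list[str]:
    return [f"M{i:03d}" for i in range(spec.n_mirnas)]


def make_dag_forest(spec: FixtureSpec) -> list[DiseaseDAG]:
    """One balanced subtree per block under a shared root; leaves are diseases.

    Disease ``j`` of block ``b`` occupies leaf ``j`` of subtree ``b``; its DAG
    is the root-to-leaf ancestor chain.  Rejects specs whose trees have fewer
    leaves than the largest block needs.
    """
    blocks = _block_split(spec.n_diseases, spec.n_blocks)
    per_block = [blocks.count(b) for b in range(spec.n_blocks)]
    capacity = spec.dag_branching**spec.dag_depth
    if max(per_block) > capacity:
        raise ValueError(
            f"dag_depth={spec.dag_depth}, dag_branching={spec.dag_branching} "
            f"give only {capacity} leaves per block; largest block needs {max(per_block)}"
        )
    ids = disease_ids(spec)
    slot_in_block = [0] * spec.n_blocks
    dags = []
    for disease, b in zip(ids, blocks):
        leaf = slot_in_block[b]
        slot_in_block[b] += 1
        # path digits of the leaf in the balanced dag_branching-ary tree
        digits = []
        x = leaf
        for _ in range(spec.dag_depth):
            digits.append(x % spec.dag_branching)
            x //= spec.dag_branching
        digits.reverse()
        chain = [ROOT, f"{ROOT}.B{b}"]
        for level in range(spec.dag_depth - 1):
            chain.append(chain[-1] + f".{digits[level]}")
        chain.append(disease)  # the leaf itself is the disease node
        edges = set(zip(chain[:-1], chain[1:]))
        dags.append(DiseaseDAG(disease_id=disease, nodes=frozenset(chain), edges=edges))
    return dags


def make_associations(spec: FixtureSpec) -> tuple[pd.DataFrame, set[tuple[str, str]]]:
    """Planted-block Bernoulli association matrix plus the matched-block pairs."""
    rng = spec._streams()[1]
    m_blocks = _block_split(spec.n_mirnas, spec.n_blocks)
    d_blocks = _block_split(spec.n_diseases, spec.n_blocks)
    match = np.equal.outer(np.asarray(m_blocks), np.asarray(d_blocks))
    p = np.where(match, spec.p_within, spec.p_between)
    values = (rng.random(p.shape) < p).astype(int)
    a = pd.DataFrame(values, index=mirna_ids(spec), columns=disease_ids(spec))
    planted = {
        (a.index[i], a.columns[j]) for i, j in np.argwhere(match)
    }
    return a, planted


def make_fixture(spec: FixtureSpec | None = None) -> Fixture:
    """Full bundle: DAG forest -> W_d -> associations -> W_m."""
    spec = spec or FixtureSpec()
    dags = make_dag_forest(spec)
    w_d = build_disease_similarity(dags)
    a, planted = make_associations(spec)
    w_m = mirna_functional_similarity(a, w_d)
    return Fixture(
        spec=spec,
        dags=dags,
        A=a,
        W_m=w_m,
        W_d=w_d,
        planted_pairs=planted,
        mirna_blocks=dict(zip(mirna_ids(spec), _block_split(spec.n_mirnas, spec.n_blocks))),
        disease_blocks=dict(zip(disease_ids(spec), _block_split(spec.n_diseases, spec.n_blocks))),
    )
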