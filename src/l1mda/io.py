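"""Readers and writers for the tabular interchange formats.

TSV is the canonical dialect; a comma-delimited fallback is auto-detected
from the header line.  Entity ids are opaque case-sensitive strings.  Every
reader rejects malformed input rather than silently coercing it.  Label
order is stable: matrix inputs keep their file order, pair-list inputs are
sorted.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .core import check_association
from .similarity import DiseaseDAG

__all__ = [
    "read_similarity",
    "write_similarity",
    "read_association",
    "write_association",
    "write_pairs",
    "write_predictions",
    "read_dag_edgelist",
    "dags_from_edges",
    "read_mesh_records",
    "dags_from_tree_numbers",
]

_FLOAT_FMT = "%.17g"  # round-trips IEEE doubles exactly


def _sep(path: Path) -> str:
    header = Path(path).open().readline()
    return "\t" if "\t" in header or "," not in header else ","


def read_similarity(path: str | Path) -> pd.DataFrame:
    """Read a labeled square similarity matrix.

    Asymmetries up to 1e-6 are averaged away; a diagonal off 1 by more than
    1e-6 triggers a warning before being snapped to exactly 1.  Non-square
    layouts, mismatched labels and values outside [-1e-6, 1 + 1e-6] are
    rejected.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep(path), index_col=0, float_precision="round_trip")
    if df.shape[0] != df.shape[1]:
        raise ValueError(f"{path}: similarity matrix is {df.shape[0]}x{df.shape[1]}, not square")
    if list(df.index.astype(str)) != list(df.columns.astype(str)):
        raise ValueError(f"{path}: row labels differ from column labels")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    v = df.to_numpy(dtype=float)
    if not np.isfinite(v).all():
        raise ValueError(f"{path}: non-finite similarity values")
    if v.min() < -1e-6 or v.max() > 1 + 1e-6:
        raise ValueError(f"{path}: similarity values outside [0, 1]")
    if np.abs(v - v.T).max() > 1e-6:
        raise ValueError(f"{path}: asymmetry exceeds 1e-6")
    v = (v + v.T) / 2.0
    if np.abs(np.diag(v) - 1.0).max() > 1e-6:
        warnings.warn(f"{path}: diagonal entries off 1; snapping to 1", stacklevel=2)
    np.fill_diagonal(v, 1.0)
    np.clip(v, 0.0, 1.0, out=v)
    return pd.DataFrame(v, index=df.index, columns=df.columns)


def write_similarity(m: pd.DataFrame, path: str | Path) -> None:
    m.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def read_association(path: str | Path, format: str = "matrix") -> pd.DataFrame:
    """Read known associations as a labeled binary matrix.

    ``format="matrix"``: labeled 0/1 matrix, rejected with coordinates on any
    non-binary value.  ``format="pairs"``: two-column (miRNA, disease) list
    with a header line and optional extra provenance columns; the matrix is
    built over the sorted union of observed ids, duplicates collapse to a
    single 1 with a warning.
    """
    path = Path(path)
    if format == "matrix":
        df = pd.read_csv(path, sep=_sep(path), index_col=0)
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        check_association(df)
        return df.astype(int)
    if format == "pairs":
        df = pd.read_csv(path, sep=_sep(path), header=0, dtype=str)
        if df.shape[1] < 2:
            raise ValueError(f"{path}: pair list needs >= 2 columns")
        pairs = df.iloc[:, :2].dropna()
        if (pairs == "").any().any():
            raise ValueError(f"{path}: empty entity id in pair list")
        if pairs.duplicated().any():
            n_dup = int(pairs.duplicated().sum())
            warnings.warn(f"{path}: {n_dup} duplicate pair(s) collapsed", stacklevel=2)
            pairs = pairs.drop_duplicates()
        mirnas = sorted(pairs.iloc[:, 0].unique())
        diseases = sorted(pairs.iloc[:, 1].unique())
        a = pd.DataFrame(0, index=mirnas, columns=diseases)
        for m, d in pairs.itertuples(index=False):
            a.loc[m, d] = 1
        return a
    raise ValueError(f"unknown association format {format!r}")


def write_association(a: pd.DataFrame, path: str | Path) -> None:
    a.to_csv(path, sep="\t")


def write_pairs(a: pd.DataFrame, path: str | Path) -> None:
    """Write the 1-entries of an association matrix as a 2-column pair list."""
    rows = [(a.index[i], a.columns[j]) for i, j in np.argwhere(a.to_numpy() == 1)]
    pd.DataFrame(rows, columns=["mirna_id", "disease_id"]).to_csv(
        path, sep="\t", index=False
    )


def write_predictions(q: pd.DataFrame, a: pd.DataFrame, path: str | Path) -> None:
    """Long-format scores: (miRNA, disease, score, known), descending score."""
    long = q.stack().rename("score").reset_index()
    long.columns = ["mirna_id", "disease_id", "score"]
    known = a.stack().rename("known").reset_index()
    known.columns = ["mirna_id", "disease_id", "known"]
    long = long.merge(known, on=["mirna_id", "disease_id"], how="left")
    long["known"] = long["known"].fillna(0).astype(int)
    long = long.sort_values(
        ["score", "mirna_id", "disease_id"], ascending=[False, True, True]
    )
    long.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_dag_edgelist(path: str | Path) -> list[tuple[str, str]]:
    """Read parent->child ontology edges: 2-column TSV with one header line."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep(path), header=0, dtype=str)
    if df.shape[1] != 2:
        raise ValueError(f"{path}: edge list needs exactly 2 columns")
    if df.isna().any().any() or (df == "").any().any():
        raise ValueError(f"{path}: empty node id in edge list")
    return [tuple(r) for r in df.itertuples(index=False)]


def dags_from_edges(
    edges: list[tuple[str, str]], diseases: list[str] | None = None
) -> list[DiseaseDAG]:
    """Build each disease's ancestor-closure DAG from a global edge list.

    ``diseases`` defaults to every node that appears in the edge list.
    """
    parents: dict[str, set[str]] = {}
    nodes: set[str] = set()
    for p, c in edges:
        parents.setdefault(c, set()).add(p)
        nodes.update((p, c))
    if diseases is None:
        diseases = sorted(nodes)
    out = []
    for d in diseases:
        if d not in nodes:
            raise KeyError(f"disease {d!r} not present in the ontology edges")
        closure = {d}
        frontier = [d]
        dag_edges = set()
        while frontier:
            x = frontier.pop()
            for p in parents.get(x, ()):
                dag_edges.add((p, x))
                if p not in closure:
                    closure.add(p)
                    frontier.append(p)
        out.append(DiseaseDAG(disease_id=d, nodes=frozenset(closure), edges=dag_edges))
    return out


def read_mesh_records(path: str | Path) -> dict[str, list[str]]:
    """Read (disease name, tree number) records; keeps Category C only.

    One row per tree number; names may repeat across rows (a disease can sit
    at several ontology positions).
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep(path), header=0, dtype=str)
    if df.shape[1] != 2:
        raise ValueError(f"{path}: MeSH records need exactly 2 columns")
    records: dict[str, list[str]] = {}
    for name, tn in df.itertuples(index=False):
        if not name or not tn or pd.isna(name) or pd.isna(tn):
            raise ValueError(f"{path}: empty name or tree number")
        if not tn.startswith("C"):
            continue  # diseases live in Category C; other categories dropped
        records.setdefault(name, [])
        if tn not in records[name]:
            records[name].append(tn)
    return records


def dags_from_tree_numbers(records: dict[str, list[str]]) -> list[DiseaseDAG]:
    """Disease DAGs from dot-delimited tree numbers.

    Ancestry is prefix truncation at each dot (``C04.557.337`` has parents
    ``C04.557`` and so on).  A prefix that is itself a recorded disease
    position is identified with that disease name, so shared ancestors unify
    across diseases; unrecorded prefixes keep their raw tree-number id.  A
    disease at several positions gets ONE DAG over the union of ancestors.
    """
    position_to_name = {
        tn: name for name, tns in records.items() for tn in tns
    }

    def node_id(tn: str) -> str:
        return position_to_name.get(tn, tn)

    dags = []
    for name, tns in sorted(records.items()):
        nodes = {name}
        edges: set[tuple[str, str]] = set()
        for tn in tns:
            parts = tn.split(".")
            chain = [".".join(parts[: k + 1]) for k in range(len(parts))]
            for parent, child in zip(chain[:-1], chain[1:]):
                pid, cid = node_id(parent), node_id(child)
                if pid != cid:
                    edges.add((pid, cid))
                    nodes.update((pid, cid))
        dags.append(DiseaseDAG(disease_id=name, nodes=frozenset(nodes), edges=edges))
    return dags
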