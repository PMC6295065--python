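"""Leave-one-out cross validation, AUC, and candidate ranking.

Each known miRNA-disease association is held out in turn: it is zeroed in
the association matrix, the predictor is re-run, and the held-out pair's
score is ranked against the unconfirmed pairs.  Global LOOCV ranks against
every unconfirmed pair; local LOOCV ranks only against the unconfirmed
miRNAs of the held-out pair's disease.  Folds are summarised by the pooled
Mann-Whitney statistic: each fold contributes its wins (and half-ties)
against its own candidate set, and the sums are normalised by the total
number of comparisons — the standard LOOCV ROC construction in this
literature.

Similarity matrices are held fixed across folds by default, matching an
evaluation against precomputed similarity files; pass
``refit_mirna_similarity=True`` to rebuild the miRNA functional similarity
from each fold's reduced association matrix instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .core import SolverConfig, check_association, predict
from .similarity import mirna_functional_similarity

__all__ = [
    "RankedCandidates",
    "CVResult",
    "roc_auc",
    "global_loocv",
    "local_loocv",
    "rank_candidates",
    "ablate_disease",
]

logger = logging.getLogger(__name__)


@dataclass
class RankedCandidates:
    """Top candidate miRNAs for one disease, scores non-increasing."""

    disease_id: str
    entries: list[tuple[str, float, int]]
    known_excluded: bool


@dataclass
class CVResult:
    """LOOCV summary: pooled AUC, per-fold ranks, per-disease AUCs."""

    mode: str
    auc: float
    per_fold_ranks: pd.DataFrame
    per_disease_auc: dict[str, float] = field(default_factory=dict)


def roc_auc(scores, labels) -> float:
    """Mann-Whitney AUC: probability a random positive outscores a random
    negative, with ties counting one half.  Equals the trapezoidal area
    under the threshold-swept ROC curve."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-d sequences")
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos + n_neg != labels.size:
        raise ValueError("labels must be 0 or 1")
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need at least one positive and one negative label")
    ranks = rankdata(scores)  # average ranks on ties
    pos_rank_sum = ranks[labels == 1].sum()
    return float((pos_rank_sum - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def _pooled_auc(wins: np.ndarray, ties: np.ndarray, n_cand: np.ndarray) -> float:
    return float((wins + 0.5 * ties).sum() / n_cand.sum())


def _loocv(
    w_m: pd.DataFrame,
    w_d: pd.DataFrame,
    a: pd.DataFrame,
    config: SolverConfig | None,
    mode: str,
    refit_mirna_similarity: bool,
) -> CVResult:
    check_association(a)
    amat = a.to_numpy()
    known = np.argwhere(amat == 1)
    if len(known) < 2:
        raise ValueError(f"LOOCV needs >= 2 known associations, got {len(known)}")
    zero_mask = amat == 0  # the unconfirmed pairs, identical for every fold

    records: list[tuple[str, str, float, int]] = []
    wins, ties, cands = [], [], []
    for i, j in known:
        a_fold = a.copy()
        a_fold.iat[i, j] = 0
        w_m_fold = (
            mirna_functional_similarity(a_fold, w_d)
            if refit_mirna_similarity
            else w_m
        )
        try:
            q = predict(w_m_fold, w_d, a_fold, config)
        except Exception as exc:
            raise RuntimeError(
                f"solver failed on fold ({a.index[i]!r}, {a.columns[j]!r}): {exc}"
            ) from exc
        qv = q.to_numpy()
        s = qv[i, j]
        if mode == "global":
            neg = qv[zero_mask]
        else:
            neg = qv[zero_mask[:, j], j]
        if neg.size == 0:
            logger.warning(
                "fold (%s, %s) has no negative candidates; skipped",
                a.index[i], a.columns[j],
            )
            continue
        w = int((s > neg).sum())
        t = int((s == neg).sum())
        # average rank among the candidate set (held-out pair included)
        rank = neg.size + 1 - (w + 0.5 * t)
        records.append((a.index[i], a.columns[j], rank, neg.size + 1))
        wins.append(w)
        ties.append(t)
        cands.append(neg.size)

    if not records:
        raise ValueError("every fold was skipped; no candidates to rank")
    wins_a, ties_a, cands_a = map(np.asarray, (wins, ties, cands))
    folds = pd.DataFrame(
        records, columns=["mirna_id", "disease_id", "rank", "candidate_count"]
    )
    per_disease: dict[str, float] = {}
    for disease, grp in folds.groupby("disease_id", sort=False):
        idx = grp.index.to_numpy()
        per_disease[disease] = _pooled_auc(wins_a[idx], ties_a[idx], cands_a[idx])
    return CVResult(
        mode=mode,
        auc=_pooled_auc(wins_a, ties_a, cands_a),
        per_fold_ranks=folds,
        per_disease_auc=per_disease,
    )


def global_loocv(
    w_m: pd.DataFrame,
    w_d: pd.DataFrame,
    a: pd.DataFrame,
    config: SolverConfig | None = None,
    refit_mirna_similarity: bool = False,
) -> CVResult:
    """Hold out each known association and rank it against all unconfirmed
    pairs of the whole matrix."""
    return _loocv(w_m, w_d, a, config, "global", refit_mirna_similarity)


def local_loocv(
    w_m: pd.DataFrame,
    w_d: pd.DataFrame,
    a: pd.DataFrame,
    config: SolverConfig | None = None,
    refit_mirna_similarity: bool = False,
) -> CVResult:
    """Hold out each known association and rank it against the unconfirmed
    miRNAs of its own disease; also reports per-disease AUCs."""
    return _loocv(w_m, w_d, a, config, "local", refit_mirna_similarity)


def rank_candidates(
    q_final: pd.DataFrame,
    a: pd.DataFrame,
    disease_id: str,
    k: int = 50,
    exclude_known: bool = False,
) -> RankedCandidates:
    """Top-k miRNA candidates for one disease, by descending score.

    With ``exclude_known``, miRNAs already associated with the disease are
    dropped from the candidate list first.  Score ties break
    lexicographically by miRNA id so output is deterministic.
    """
    if disease_id not in q_final.columns:
        raise KeyError(f"unknown disease {disease_id!r}")
    scores = q_final[disease_id]
    if exclude_known:
        known = a.index[a[disease_id] == 1]
        scores = scores.drop(index=[m for m in known if m in scores.index])
    order = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    entries = [(m, float(s), r) for r, (m, s) in enumerate(order[:k], start=1)]
    return RankedCandidates(
        disease_id=disease_id, entries=entries, known_excluded=exclude_known
    )


def ablate_disease(a: pd.DataFrame, disease_id: str) -> pd.DataFrame:
    """Copy of the association matrix with one disease's column zeroed,
    emulating a disease with no known miRNA associations."""
    if disease_id not in a.columns:
        raise KeyError(f"unknown disease {disease_id!r}")
    out = a.copy()
    out[disease_id] = 0
    return out
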