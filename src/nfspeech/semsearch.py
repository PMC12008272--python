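"""Approach 1 — semantic search against the NFS items.

Each transcript is a query; the 20 NFS items are the corpus.  The query
is classified ON or OFF by a majority vote over the polarities of its
top-k most cosine-similar items (k odd, default 5, to avoid ties).  The
neuropsychiatric state score is predicted by a similarity-weighted
average of the scores of the top-k most similar transcripts from *other*
patients (kNN regression in embedding space, k default 5), clipped to
[0, 60].
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .corpus_io import MedState, NFSItem, SCORE_MAX, SCORE_MIN
from .embed import EmbeddingMatrix, cosine_similarity
from .errors import PoolError


@dataclass(frozen=True)
class RankedMatches:
    """All corpus entries ranked by similarity to one query.

    Similarities are non-increasing; exact ties are broken by ascending
    target id so rankings are deterministic.
    """

    query_id: str
    matches: tuple[tuple[str, object, float], ...]  # (target_id, payload, similarity)

    def top(self, k: int) -> tuple[tuple[str, object, float], ...]:
        return self.matches[:k]


@dataclass(frozen=True)
class VoteResult:
    """Outcome of the odd-k majority vote over NFS item polarities."""

    label: MedState
    votes_on: int
    votes_off: int
    k: int
    voters: tuple[tuple[int, MedState, float], ...]  # (item_id, polarity, similarity)

    @property
    def vote_share(self) -> float:
        return max(self.votes_on, self.votes_off) / self.k

    @property
    def p_on(self) -> float:
        """ROC-usable confidence: fraction of ON voters."""
        return self.votes_on / self.k


def rank_items(
    query_vec: np.ndarray, item_matrix: EmbeddingMatrix, items: Sequence[NFSItem]
) -> RankedMatches:
    """Rank all NFS items by cosine similarity to the query, descending."""
    if item_matrix.n_docs != len(items):
        raise ValueError("item_matrix rows do not align with items")
    sims = [cosine_similarity(query_vec, item_matrix.row(i)) for i in range(len(items))]
    order = sorted(range(len(items)), key=lambda i: (-sims[i], items[i].item_id))
    matches = tuple((str(items[i].item_id), items[i].polarity, sims[i]) for i in order)
    return RankedMatches(query_id="query", matches=matches)


def classify_by_vote(ranked: RankedMatches, k: int = 5) -> VoteResult:
    """Majority vote over the polarities of the top-k ranked items.

    k must be odd (a tie is impossible for an odd voter count over two
    polarities) and at most the corpus size.
    """
    if k % 2 == 0:
        raise ValueError(f"voter count must be odd to avoid ties, got k={k}")
    if not 1 <= k <= len(ranked.matches):
        raise ValueError(f"k={k} outside 1..{len(ranked.matches)}")
    voters = tuple(
        (int(tid), pol, sim) for tid, pol, sim in ranked.top(k)
    )
    votes_on = sum(1 for _, pol, _ in voters if pol is MedState.ON)
    votes_off = k - votes_on
    label = MedState.ON if votes_on > votes_off else MedState.OFF
    return VoteResult(label=label, votes_on=votes_on, votes_off=votes_off, k=k, voters=voters)


def item_frequency_profile(
    vote_results: Sequence[VoteResult],
    true_states: Sequence[MedState],
    item_ids: Sequence[int] = tuple(range(1, 21)),
) -> dict[str, dict[int, float]]:
    """Per-state normalized frequency of each item among the voters.

    For each true medication state, counts how often each NFS item
    appeared among the top-k voters, normalized to sum to 1 within the
    state group.  Mirrors the item-frequency profile used to audit which
    scale items the search retrieves for ON vs OFF speech.
    """
    if len(vote_results) != len(true_states):
        raise ValueError("vote_results and true_states must align")
    profile: dict[str, dict[int, float]] = {}
    for state in (MedState.ON, MedState.OFF):
        counts = {iid: 0 for iid in item_ids}
        total = 0
        for vr, st in zip(vote_results, true_states):
            if st is not state:
                continue
            for iid, _, _ in vr.voters:
                counts[iid] += 1
                total += 1
        if total > 0:
            profile[state.value] = {iid: c / total for iid, c in counts.items()}
        elif any(st is state for st in true_states):
            profile[state.value] = {iid: 0.0 for iid in item_ids}
    return profile


def predict_score_knn(
    query_vec: np.ndarray,
    pool: EmbeddingMatrix,
    pool_scores: Sequence[float],
    pool_patient_ids: Sequence[str],
    k: int = 5,
    exclude_patient: str | None = None,
) -> tuple[float, tuple[tuple[str, float, float], ...]]:
    """Similarity-weighted kNN prediction of the state score.

    Weights are the cosine similarities clamped at zero (negative
    similarity carries no evidence and could push the weighted mean out
    of the convex hull of neighbour scores); if every weight is zero the
    unweighted mean of the top-k is used.  Returns the clipped score and
    the (doc_id, score, similarity) neighbour triples.

    The pool must not contain the query patient's recordings; passing
    ``exclude_patient`` asserts this.
    """
    if pool.n_docs == 0:
        raise PoolError("empty transcript pool")
    if len(pool_scores) != pool.n_docs or len(pool_patient_ids) != pool.n_docs:
        raise ValueError("pool scores/patient ids do not align with matrix rows")
    if exclude_patient is not None and exclude_patient in set(pool_patient_ids):
        raise PoolError(f"pool contains recordings of excluded patient {exclude_patient!r}")
    if not 1 <= k <= pool.n_docs:
        raise ValueError(f"k={k} outside 1..{pool.n_docs}")
    sims = [cosine_similarity(query_vec, pool.row(i)) for i in range(pool.n_docs)]
    order = sorted(range(pool.n_docs), key=lambda i: (-sims[i], pool.doc_ids[i]))[:k]
    neighbours = tuple((pool.doc_ids[i], float(pool_scores[i]), sims[i]) for i in order)
    weights = np.maximum([s for _, _, s in neighbours], 0.0)
    scores = np.array([s for _, s, _ in neighbours])
    if weights.sum() > 0:
        score = float(np.dot(weights, scores) / weights.sum())
    else:
        score = float(scores.mean())
    return float(np.clip(score, SCORE_MIN, SCORE_MAX)), neighbours
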