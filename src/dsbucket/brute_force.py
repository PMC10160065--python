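"""Naive all-pairs database search.

Scores every (reference, query) pair with the model log-likelihood ratio
and ranks references per query.  Quadratic in the database/query sizes by
construction — it exists as the correctness oracle and complexity baseline
for the bucketed search, and must stay free of any indexing or pruning.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .models import (
    HMMParams,
    SAParams,
    encode,
    hmm_forward_joint_batch,
    sa_llr,
)

__all__ = ["RankedMatch", "brute_force_search", "quadratic_cost_probe", "write_matches"]


@dataclass(frozen=True)
class RankedMatch:
    ref_id: str
    query_id: str
    score: float
    rank: int


def _hmm_llr_row(params: HMMParams, xs_enc: np.ndarray, y: str) -> np.ndarray:
    """LLR of one query against all encoded database rows (vectorized)."""
    yi = encode(y, params.obs_alphabet_y)
    joint = hmm_forward_joint_batch(params, xs_enc, yi)
    bg_x = np.log(params.px_background)[xs_enc].sum(axis=1)
    bg_y = float(np.log(params.py_background)[yi].sum())
    return joint - bg_x - bg_y


def brute_force_search(
    database: list[str],
    queries: list[str],
    model: HMMParams | SAParams,
    top_k: int = 1,
    db_ids: list[str] | None = None,
    query_ids: list[str] | None = None,
) -> list[RankedMatch]:
    """Score every database sequence against every query; return the
    ``top_k`` per query, ties broken by database order (stable)."""
    if not database:
        raise ValueError("empty database")
    if not queries:
        raise ValueError("empty query set")
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    db_ids = db_ids or [f"ref{i}" for i in range(len(database))]
    query_ids = query_ids or [f"query{i}" for i in range(len(queries))]

    out: list[RankedMatch] = []
    if isinstance(model, HMMParams):
        xs_enc = np.array(
            [encode(s, model.obs_alphabet_x) for s in database], dtype=np.int64
        )
        for qid, y in zip(query_ids, queries):
            scores = _hmm_llr_row(model, xs_enc, y)
            order = np.argsort(-scores, kind="stable")[:top_k]
            for rank, i in enumerate(order, start=1):
                out.append(RankedMatch(db_ids[i], qid, float(scores[i]), rank))
    else:
        for qid, y in zip(query_ids, queries):
            scores = np.array([sa_llr(model, x, y) for x in database])
            order = np.argsort(-scores, kind="stable")[:top_k]
            for rank, i in enumerate(order, start=1):
                out.append(RankedMatch(db_ids[i], qid, float(scores[i]), rank))
    return out


def quadratic_cost_probe(Ns: list[int]) -> list[tuple[int, int]]:
    """Pair-evaluation counts of the naive search: exactly N^2 scored pairs
    for N queries against N references."""
    if any(b <= a for a, b in zip(Ns, Ns[1:])):
        raise ValueError("Ns must be ascending")
    return [(n, n * n) for n in Ns]


def write_matches(path, matches: list[RankedMatch]) -> None:
    """Ranked matches as TSV: query_id, ref_id, rank, score."""
    with open(path, "w") as fh:
        fh.write("query_id\tref_id\trank\tscore\n")
        for m in matches:
            fh.write(f"{m.query_id}\t{m.ref_id}\t{m.rank}\t{m.score:.6f}\n")
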