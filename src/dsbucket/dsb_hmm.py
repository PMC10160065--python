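"""Distribution-sensitive bucketing for the joint HMM.

A decision tree over *pairs* of prefixes is grown breadth-first from the
empty pair.  Each node holds an x-string and a y-string of equal length
(its depth) together with the exact joint prefix probability (a forward
state vector), the background prefix probabilities, and one of three
statuses:

* **pruned** — joint mass below ``prune_threshold``: the subtree cannot
  contribute enough true-positive mass and is discarded;
* **accepted** — the enrichment ratio ``p_joint / (p_x p_y)`` clears
  ``accept_ratio`` (or depth hit the cap with ratio >= 1): the node becomes
  a bucket;
* **branched** — expanded into all |A| x |B| children.

A sequence falls into a bucket at band ``j`` when the bucket's string on
that axis is a prefix of the sequence's j-th suffix.  Jointly generated
pairs land in the same bucket of a band with probability ``alpha`` (the sum
of accepted joint masses — exact, because buckets are disjoint leaves);
independent pairs collide with probability ``beta``.  Running ``J`` bands
lifts the true-positive rate to ``1 - (1 - alpha)**J``, which fixes
``J >= -ln(eps_miss) / alpha`` for a target miss tolerance.

Search maps every database and query sequence into buckets across bands,
collects co-occurring pairs, and verifies each candidate once with the
exact log-likelihood ratio.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from itertools import product

import numpy as np

from .brute_force import RankedMatch
from .models import HMMParams, encode, hmm_forward_joint_batch

__all__ = [
    "BuildConfig",
    "TreeNode",
    "BucketIndex",
    "root_node",
    "extend_node",
    "build_tree",
    "tree_stats",
    "choose_bands",
    "predicted_tpr",
    "predicted_tpr_bound",
    "map_sequence",
    "dsb_search",
    "SearchResult",
    "empirical_tpr",
]

STATUS_BRANCHED = 0
STATUS_PRUNED = 1
STATUS_ACCEPTED = 2

_STATUS_NAMES = {0: "branched", 1: "pruned", 2: "accepted"}


@dataclass
class BuildConfig:
    """Knobs of the accept/prune/branch construction.

    ``prune_threshold`` is an absolute joint-prefix-probability floor;
    ``accept_ratio`` the enrichment needed to become a bucket.  ``eps_miss``
    is the tolerated overall miss probability that sets the band count.
    ``band_stride`` spaces bands apart (default: ``max_depth``) so that
    per-band collision events are effectively independent.
    """

    max_depth: int = 12
    prune_threshold: float = 3e-6
    accept_ratio: float = 300.0
    eps_miss: float = 0.05
    db_size_m: int = 1000
    query_size_n: int = 1000
    band_stride: int | None = None

    def __post_init__(self):
        if not 0 < self.eps_miss < 1:
            raise ValueError("eps_miss must be in (0, 1)")
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")

    def to_dict(self) -> dict:
        import dataclasses

        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# Single-node operations (reference semantics; the builder vectorizes these)
# ---------------------------------------------------------------------------


@dataclass
class TreeNode:
    s_x: str
    s_y: str
    forward_state: np.ndarray  # joint prefix probability per hidden state
    p_joint: float
    p_x: float
    p_y: float
    status: str = "branched"
    children: dict = field(default_factory=dict)

    @property
    def depth(self) -> int:
        return len(self.s_x)


def root_node(params: HMMParams) -> TreeNode:
    """Empty-prefix root; its forward state is the hidden-state prior."""
    return TreeNode(
        s_x="",
        s_y="",
        forward_state=params.p_init.copy(),
        p_joint=1.0,
        p_x=1.0,
        p_y=1.0,
    )


def extend_node(parent: TreeNode, a: str, b: str, params: HMMParams) -> TreeNode:
    """Child of ``parent`` along the (a, b) edge.

    The forward state is advanced one column: transition (skipped at the
    root, where the prior applies directly) then emission of (a, b).
    """
    if parent.status == "pruned":
        raise ValueError("cannot extend a pruned node")
    ai = int(encode(a, params.obs_alphabet_x)[0])
    bi = int(encode(b, params.obs_alphabet_y)[0])
    if parent.depth == 0:
        f = parent.forward_state * params.p_emit[ai, bi, :]
    else:
        f = (parent.forward_state @ params.p_trans) * params.p_emit[ai, bi, :]
    child = TreeNode(
        s_x=parent.s_x + a,
        s_y=parent.s_y + b,
        forward_state=f,
        p_joint=float(f.sum()),
        p_x=parent.p_x * float(params.px_background[ai]),
        p_y=parent.p_y * float(params.py_background[bi]),
    )
    parent.children[(a, b)] = child
    return child


# ---------------------------------------------------------------------------
# Index container
# ---------------------------------------------------------------------------


@dataclass
class BucketIndex:
    """Finished decision structure plus its band plan."""

    kind: str
    s_x: list[str]
    s_y: list[str]
    p_joint: np.ndarray
    p_x: np.ndarray
    p_y: np.ndarray
    alpha: float
    beta: float
    gamma_x: float
    gamma_y: float
    eps_miss: float
    j_bands: int
    band_stride: int
    max_depth: int
    obs_alphabet_x: str
    obs_alphabet_y: str
    model_hash: str
    config: dict
    node_record: list | None = None

    @property
    def d(self) -> int:
        return len(self.s_x)

    @property
    def band_set(self) -> list[int]:
        return list(range(1, self.j_bands + 1))

    def bands_for_length(self, seq_len: int) -> list[int]:
        """1-based band start positions, spaced by ``band_stride`` and kept
        long enough for the deepest bucket; capped at ``j_bands``."""
        last_start = seq_len - self.max_depth + 1
        positions = list(range(1, last_start + 1, self.band_stride))
        return positions[: self.j_bands]

    # mapping tables, built lazily ---------------------------------------
    def _axis_map(self, axis: str) -> dict[int, dict[str, list[int]]]:
        attr = f"_map_{axis}"
        cached = getattr(self, attr, None)
        if cached is None:
            strings = self.s_x if axis == "x" else self.s_y
            cached = {}
            for i, s in enumerate(strings):
                cached.setdefault(len(s), {}).setdefault(s, []).append(i)
            object.__setattr__(self, attr, cached)
        return cached

    def _pair_map(self) -> dict[int, set[tuple[str, str]]]:
        cached = getattr(self, "_pairs", None)
        if cached is None:
            cached = {}
            for sx, sy in zip(self.s_x, self.s_y):
                cached.setdefault(len(sx), set()).add((sx, sy))
            object.__setattr__(self, "_pairs", cached)
        return cached

    # serialization -------------------------------------------------------
    def save(self, path) -> None:
        header = {
            "format": "dsbucket-index",
            "version": 1,
            "kind": self.kind,
            "model_hash": self.model_hash,
            "config": self.config,
            "alpha": self.alpha,
            "beta": self.beta,
            "gamma_x": self.gamma_x,
            "gamma_y": self.gamma_y,
            "eps_miss": self.eps_miss,
            "j_bands": self.j_bands,
            "band_stride": self.band_stride,
            "max_depth": self.max_depth,
            "obs_alphabet_x": self.obs_alphabet_x,
            "obs_alphabet_y": self.obs_alphabet_y,
        }
        with open(path, "w") as fh:
            fh.write(json.dumps(header) + "\n")
            for sx, sy, pj, px, py in zip(
                self.s_x, self.s_y, self.p_joint, self.p_x, self.p_y
            ):
                fh.write(f"{sx}\t{sy}\t{float(pj)!r}\t{float(px)!r}\t{float(py)!r}\n")

    @classmethod
    def load(cls, path) -> "BucketIndex":
        with open(path) as fh:
            header = json.loads(fh.readline())
            if header.get("format") != "dsbucket-index":
                raise ValueError(f"{path}: not a dsbucket index file")
            s_x, s_y, pj, px, py = [], [], [], [], []
            for line in fh:
                fields = line.rstrip("\n").split("\t")
                s_x.append(fields[0])
                s_y.append(fields[1])
                pj.append(float(fields[2]))
                px.append(float(fields[3]))
                py.append(float(fields[4]))
        return cls(
            kind=header["kind"],
            s_x=s_x,
            s_y=s_y,
            p_joint=np.array(pj),
            p_x=np.array(px),
            p_y=np.array(py),
            alpha=header["alpha"],
            beta=header["beta"],
            gamma_x=header["gamma_x"],
            gamma_y=header["gamma_y"],
            eps_miss=header["eps_miss"],
            j_bands=header["j_bands"],
            band_stride=header["band_stride"],
            max_depth=header["max_depth"],
            obs_alphabet_x=header["obs_alphabet_x"],
            obs_alphabet_y=header["obs_alphabet_y"],
            model_hash=header["model_hash"],
            config=header["config"],
        )


def model_hash(params) -> str:
    blob = json.dumps(params.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Tree construction (vectorized breadth-first)
# ---------------------------------------------------------------------------


def _decode(code: int, depth: int, alphabet: str) -> str:
    n = len(alphabet)
    out = []
    for _ in range(depth):
        code, r = divmod(code, n)
        out.append(alphabet[r])
    return "".join(reversed(out))


def build_tree(
    params: HMMParams, cfg: BuildConfig, record_nodes: bool = False
) -> BucketIndex:
    """Grow the pair-prefix decision tree and return the bucket index.

    Deterministic.  With ``record_nodes=True`` the per-layer node tables
    (parent pointer, joint mass, status) are kept on the index so that the
    mass-conservation invariant can be audited.
    """
    na, nb = len(params.obs_alphabet_x), len(params.obs_alphabet_y)
    nh = params.n_hidden
    bgx, bgy = params.px_background, params.py_background

    # frontier state (branched nodes of the current layer)
    F = params.p_init.reshape(1, nh)
    px = np.ones(1)
    py = np.ones(1)
    sx_code = np.zeros(1, dtype=np.int64)
    sy_code = np.zeros(1, dtype=np.int64)

    buckets_sx: list[str] = []
    buckets_sy: list[str] = []
    buckets_pj: list[float] = []
    buckets_px: list[float] = []
    buckets_py: list[float] = []
    record: list[dict] = []
    prev_keep: np.ndarray | None = None

    for depth in range(1, cfg.max_depth + 1):
        n_par = F.shape[0]
        if n_par == 0:
            break
        Ft = F if depth == 1 else F @ params.p_trans
        blocks_F, blocks_px, blocks_py = [], [], []
        blocks_sx, blocks_sy, blocks_parent = [], [], []
        for a, b in product(range(na), range(nb)):
            Fab = Ft * params.p_emit[a, b, :]
            blocks_F.append(Fab)
            blocks_px.append(px * bgx[a])
            blocks_py.append(py * bgy[b])
            blocks_sx.append(sx_code * na + a)
            blocks_sy.append(sy_code * nb + b)
            blocks_parent.append(np.arange(n_par, dtype=np.int64))
        F_new = np.concatenate(blocks_F, axis=0)
        px_new = np.concatenate(blocks_px)
        py_new = np.concatenate(blocks_py)
        sx_new = np.concatenate(blocks_sx)
        sy_new = np.concatenate(blocks_sy)
        parent = np.concatenate(blocks_parent)

        pj = F_new.sum(axis=1)
        ratio = pj / (px_new * py_new)
        prune = pj < cfg.prune_threshold
        if depth == cfg.max_depth:
            accept = ~prune & ((ratio >= cfg.accept_ratio) | (ratio >= 1.0))
            branch = np.zeros_like(prune)
        else:
            accept = ~prune & (ratio >= cfg.accept_ratio)
            branch = ~prune & ~accept

        status = np.full(pj.shape, STATUS_PRUNED, dtype=np.int8)
        status[accept] = STATUS_ACCEPTED
        status[branch] = STATUS_BRANCHED

        if record_nodes:
            # parent indices refer to the previous layer's branched subset;
            # translate to positions within the full previous layer table
            record.append(
                {
                    "depth": depth,
                    "parent": prev_keep[parent] if prev_keep is not None else parent,
                    "p_joint": pj,
                    "status": status,
                }
            )

        idx = np.nonzero(accept)[0]
        for i in idx:
            buckets_sx.append(_decode(int(sx_new[i]), depth, params.obs_alphabet_x))
            buckets_sy.append(_decode(int(sy_new[i]), depth, params.obs_alphabet_y))
            buckets_pj.append(float(pj[i]))
            buckets_px.append(float(px_new[i]))
            buckets_py.append(float(py_new[i]))

        keep = np.nonzero(branch)[0]
        F, px, py = F_new[keep], px_new[keep], py_new[keep]
        sx_code, sy_code = sx_new[keep], sy_new[keep]
        prev_keep = keep

    if not buckets_sx:
        raise ValueError("index empty: relax thresholds")

    p_joint = np.array(buckets_pj)
    p_x = np.array(buckets_px)
    p_y = np.array(buckets_py)
    alpha = float(p_joint.sum())
    beta = float((p_x * p_y).sum())
    gamma_x = float(p_x.sum())
    gamma_y = float(p_y.sum())
    j_bands = choose_bands(min(alpha, 1.0), cfg.eps_miss)
    stride = cfg.band_stride if cfg.band_stride is not None else cfg.max_depth

    return BucketIndex(
        kind="hmm",
        s_x=buckets_sx,
        s_y=buckets_sy,
        p_joint=p_joint,
        p_x=p_x,
        p_y=p_y,
        alpha=alpha,
        beta=beta,
        gamma_x=gamma_x,
        gamma_y=gamma_y,
        eps_miss=cfg.eps_miss,
        j_bands=j_bands,
        band_stride=stride,
        max_depth=cfg.max_depth,
        obs_alphabet_x=params.obs_alphabet_x,
        obs_alphabet_y=params.obs_alphabet_y,
        model_hash=model_hash(params),
        config=cfg.to_dict(),
        node_record=record if record_nodes else None,
    )


def conservation_error(index: BucketIndex) -> float:
    """Max |sum of child joint masses - parent joint mass| over all
    fully expanded (branched) nodes.  Requires ``record_nodes=True``."""
    if not index.node_record:
        raise ValueError("index was built without record_nodes=True")
    worst = 0.0
    prev_pj = None
    prev_status = None
    for layer in index.node_record:
        if prev_pj is not None:
            child_sum = np.zeros_like(prev_pj)
            np.add.at(child_sum, layer["parent"], layer["p_joint"])
            branched = prev_status == STATUS_BRANCHED
            if branched.any():
                worst = max(worst, float(np.abs(child_sum - prev_pj)[branched].max()))
        prev_pj = layer["p_joint"]
        prev_status = layer["status"]
    return worst


def tree_stats(index: BucketIndex) -> tuple[float, float, float, float]:
    """(alpha, beta, gamma_x, gamma_y) recomputed from bucket probabilities."""
    if index.d == 0:
        raise ValueError("empty bucket set")
    alpha = float(index.p_joint.sum())
    beta = float((index.p_x * index.p_y).sum())
    return alpha, beta, float(index.p_x.sum()), float(index.p_y.sum())


# ---------------------------------------------------------------------------
# Band planning
# ---------------------------------------------------------------------------


def choose_bands(alpha: float, eps_miss: float) -> int:
    """Smallest J with (1 - alpha)^J <= eps_miss, via J >= -ln(eps)/alpha."""
    if alpha <= 0:
        raise ValueError("no true-positive mass (alpha = 0)")
    if not 0 < eps_miss < 1:
        raise ValueError("eps_miss must be in (0, 1)")
    if alpha > 1:
        raise ValueError("alpha must be <= 1")
    return max(1, math.ceil(-math.log(eps_miss) / alpha))


def predicted_tpr(alpha: float, J: int) -> float:
    """Overall true-positive rate of J independent bands."""
    if J < 1:
        raise ValueError("J must be >= 1")
    return 1.0 - (1.0 - alpha) ** J


def predicted_tpr_bound(alpha: float, J: int) -> float:
    """Lower bound 1 - exp(-alpha J) on the J-band true-positive rate."""
    if J < 1:
        raise ValueError("J must be >= 1")
    return 1.0 - math.exp(-alpha * J)


# ---------------------------------------------------------------------------
# Mapping and search
# ---------------------------------------------------------------------------


def map_sequence(index: BucketIndex, s: str, axis: str, band_j: int) -> set[int]:
    """Bucket ids whose axis-string prefixes the ``band_j``-th suffix of ``s``
    (1-based band, matching the prefix-of-suffix bucketing rule).

    A band beyond the end of the sequence yields the empty set.
    """
    if axis not in ("x", "y"):
        raise ValueError("axis must be 'x' or 'y'")
    if band_j < 1:
        raise ValueError("band_j must be >= 1")
    table = index._axis_map(axis)
    out: set[int] = set()
    start = band_j - 1
    if start >= len(s):
        return out
    for length, strings in table.items():
        if start + length <= len(s):
            hit = strings.get(s[start : start + length])
            if hit:
                out.update(hit)
    return out


@dataclass
class SearchResult:
    matches: list[RankedMatch]
    n_candidates: int
    n_verified: int
    j_bands_used: int


def dsb_search(
    index: BucketIndex,
    database: list[str],
    queries: list[str],
    params: HMMParams,
    llr_threshold: float = 0.0,
    top_k: int = 1,
    db_ids: list[str] | None = None,
    query_ids: list[str] | None = None,
) -> SearchResult:
    """Bucket -> verify search.

    Database sequences are mapped on the x axis, queries on the y axis, for
    every band; pairs co-occurring in at least one bucket are deduplicated
    and verified once with the exact log-likelihood ratio (the same
    computation the naive search uses, so reported scores agree exactly).
    """
    if (
        params.obs_alphabet_x != index.obs_alphabet_x
        or params.obs_alphabet_y != index.obs_alphabet_y
    ):
        raise ValueError("params/index mismatch: different alphabets")
    if not database:
        raise ValueError("empty database")
    db_ids = db_ids or [f"ref{i}" for i in range(len(database))]
    query_ids = query_ids or [f"query{i}" for i in range(len(queries))]

    t_db = min(len(s) for s in database)
    t_q = min(len(s) for s in queries)
    bands = index.bands_for_length(min(t_db, t_q))

    candidates: set[tuple[int, int]] = set()
    for j in bands:
        per_bucket_db: dict[int, list[int]] = {}
        for i, s in enumerate(database):
            for b in map_sequence(index, s, "x", j):
                per_bucket_db.setdefault(b, []).append(i)
        for qi, s in enumerate(queries):
            for b in map_sequence(index, s, "y", j):
                hits = per_bucket_db.get(b)
                if hits:
                    for i in hits:
                        candidates.add((i, qi))

    # verify once per candidate pair, batched per query
    by_query: dict[int, list[int]] = {}
    for i, qi in candidates:
        by_query.setdefault(qi, []).append(i)

    lbg_x = np.log(params.px_background)
    lbg_y = np.log(params.py_background)
    matches: list[RankedMatch] = []
    n_verified = 0
    for qi, db_idx in by_query.items():
        db_idx = sorted(db_idx)
        xs_enc = np.array(
            [encode(database[i], params.obs_alphabet_x) for i in db_idx],
            dtype=np.int64,
        )
        yi = encode(queries[qi], params.obs_alphabet_y)
        joint = hmm_forward_joint_batch(params, xs_enc, yi)
        scores = joint - lbg_x[xs_enc].sum(axis=1) - float(lbg_y[yi].sum())
        n_verified += len(db_idx)
        ok = np.nonzero(scores >= llr_threshold)[0]
        order = ok[np.argsort(-scores[ok], kind="stable")][:top_k]
        for rank, k in enumerate(order, start=1):
            matches.append(
                RankedMatch(db_ids[db_idx[k]], query_ids[qi], float(scores[k]), rank)
            )
    return SearchResult(
        matches=matches,
        n_candidates=len(candidates),
        n_verified=n_verified,
        j_bands_used=len(bands),
    )


def empirical_tpr(
    index: BucketIndex,
    params: HMMParams,
    T: int,
    n_pairs: int,
    J: int | None = None,
    rng_seed=0,
) -> float:
    """Fraction of jointly simulated pairs that share a bucket in at least
    one of the first J bands (Monte-Carlo check of the band formula)."""
    from .models import sample_hmm_pair

    rng = np.random.default_rng(rng_seed)
    pairs_by_len = index._pair_map()
    bands = index.bands_for_length(T)
    if J is not None:
        bands = bands[:J]
    hits = 0
    for _ in range(n_pairs):
        pair = sample_hmm_pair(params, T, rng)
        found = False
        for j in bands:
            start = j - 1
            for length, pairset in pairs_by_len.items():
                if start + length <= T and (
                    pair.x[start : start + length],
                    pair.y[start : start + length],
                ) in pairset:
                    found = True
                    break
            if found:
                break
        if found:
            hits += 1
    return hits / n_pairs
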