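"""Distribution-sensitive bucketing for the sequence alignment model.

With insertions and deletions, a bucket pair (S_x, S_y) may have unequal
lengths, and a node of the decision structure has three predecessor types
(match edge from the pair one column shorter on both sides, deletion edge
from one x-column shorter, insertion edge from one y-column shorter), so
the structure is a *graph* whose duplicate (S_x, S_y) nodes are merged.

Two builders are provided:

* :func:`build_graph` — the concrete decision graph.  Nodes are keyed by
  their literal string pair, probabilities of merging event paths are
  accumulated, and every node's joint mass equals the pair-prefix DP value
  (restricted to paths through branched ancestors).  Exponential in the
  bucket length, so it serves small alphabets / short buckets and acts as
  the reference implementation.

* :func:`build_structure_index` — for base-exchangeable DNA models
  (uniform backgrounds, one substitution rate) the accept/prune decision
  depends only on the *event-column pattern* of a node: how many clean
  matches (M), substitutions (S), deletions (D) and insertions (I) it
  contains and in what order.  The builder therefore grows pattern classes
  instead of concrete pairs; one accepted class stands for all its
  concrete instantiations.  Bucket keys are (class, concrete x-string):
  the genome side contributes one key per class per position, the read
  side enumerates the x-strings compatible with its suffix (3 per
  substitution column, 4 per deletion column) — the asymmetric-enumeration
  side of the hash.  The whole genome/read join is a vectorized
  integer-key match.

Search converts bucket co-occurrences into (reference position - read
position) diagonal votes, clusters votes per read and diagonal band, and
verifies each cluster's window with the exact log-likelihood ratio DP.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from ._dp import sa_forward_scaled, sa_semiglobal_llr
from .dsb_hmm import choose_bands, model_hash
from .models import SAParams, sample_sa_pair

__all__ = [
    "SABuildConfig",
    "GraphNode",
    "SAIndex",
    "Hit",
    "SASearchStats",
    "extend_graph_node",
    "build_graph",
    "build_structure_index",
    "estimate_alpha",
    "map_sequence_sa",
    "dsb_sa_search",
    "exhaustive_window_search",
    "reverse_complement",
]

_RC = str.maketrans("ACGT", "TGCA")


def reverse_complement(s: str) -> str:
    return s.translate(_RC)[::-1]


_DNA_LUT = np.full(256, -1, dtype=np.int64)
for _i, _c in enumerate("ACGT"):
    _DNA_LUT[ord(_c)] = _i


def encode_dna(s: str) -> np.ndarray:
    arr = _DNA_LUT[np.frombuffer(s.encode("ascii"), dtype=np.uint8)]
    if (arr < 0).any():
        pos = int(np.nonzero(arr < 0)[0][0])
        raise ValueError(f"unknown symbol {s[pos]!r} at position {pos}")
    return arr


# ---------------------------------------------------------------------------
# Build configuration
# ---------------------------------------------------------------------------


@dataclass
class SABuildConfig:
    """Construction knobs for the SA decision structures.

    ``max_total_len`` caps |S_x| + |S_y|; when ``None`` the structure
    builder derives it from the model so that a bucket can afford
    ``max_error_cols`` of the costliest error columns and still clear the
    enrichment bar with clean match columns.  ``accept_ratio`` is the
    per-concrete-pair enrichment needed to become a bucket — for DNA it
    must be large (default 1e4) so that buckets are long enough to make
    background collisions rare; error columns cost enrichment, which is
    exactly what forces buckets containing them to be longer.
    ``max_error_cols`` caps the number of non-clean-match columns per
    bucket: each substitution/deletion column multiplies the read-side
    enumeration cost (the gamma term of the complexity), so tolerance
    beyond a couple of errors per bucket is paid for with bands instead.
    """

    max_total_len: int | None = None
    prune_threshold: float = 1e-6
    accept_ratio: float = 1e4
    eps_miss: float = 0.05
    max_error_cols: int = 2
    exact_match: bool = False

    def __post_init__(self):
        if not 0 < self.eps_miss < 1:
            raise ValueError("eps_miss must be in (0, 1)")
        if self.max_total_len is not None and self.max_total_len < 2:
            raise ValueError("max_total_len must be >= 2")
        if self.exact_match:
            self.max_error_cols = 0

    def to_dict(self) -> dict:
        import dataclasses

        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# Concrete decision graph
# ---------------------------------------------------------------------------


@dataclass
class GraphNode:
    s_x: str
    s_y: str
    p_joint: float
    p_x: float
    p_y: float
    status: str = "branched"

    @property
    def total_len(self) -> int:
        return len(self.s_x) + len(self.s_y)


def extend_graph_node(
    parent: GraphNode,
    event: tuple,
    params: SAParams,
    graph: dict | None = None,
) -> GraphNode:
    """Child of ``parent`` along one event edge.

    ``event`` is ``("m", a, b)``, ``("d", a)`` or ``("i", b)``.  When a
    ``graph`` dict (keyed by (s_x, s_y)) is supplied and the child pair
    already exists, the new path's probability is accumulated onto the
    existing node (merge) instead of creating a duplicate.
    """
    if parent.status == "pruned":
        raise ValueError("cannot extend a pruned node")
    lut = {c: i for i, c in enumerate(params.alphabet)}
    kind = event[0]
    if kind == "m":
        _, a, b = event
        factor = params.q_match * params.p_m[lut[a], lut[b]]
        sx, sy = parent.s_x + a, parent.s_y + b
        px = parent.p_x * params.px_background[lut[a]]
        py = parent.p_y * params.py_background[lut[b]]
    elif kind == "d":
        _, a = event
        factor = params.q_deletion * params.p_d[lut[a]]
        sx, sy = parent.s_x + a, parent.s_y
        px = parent.p_x * params.px_background[lut[a]]
        py = parent.p_y
    elif kind == "i":
        _, b = event
        factor = params.q_insertion * params.p_i[lut[b]]
        sx, sy = parent.s_x, parent.s_y + b
        px = parent.p_x
        py = parent.p_y * params.py_background[lut[b]]
    else:
        raise ValueError(f"unknown event kind {kind!r}")
    contrib = parent.p_joint * factor
    if graph is not None and (sx, sy) in graph:
        node = graph[(sx, sy)]
        node.p_joint += contrib
        return node
    node = GraphNode(s_x=sx, s_y=sy, p_joint=contrib, p_x=float(px), p_y=float(py))
    if graph is not None:
        graph[(sx, sy)] = node
    return node


def build_graph(params: SAParams, cfg: SABuildConfig) -> "SAIndex":
    """Grow the concrete decision graph layer by layer (total emitted
    length), merging duplicate (S_x, S_y) nodes, and collect buckets.

    Layer L receives match-edge mass from branched layer-(L-2) nodes and
    indel-edge mass from branched layer-(L-1) nodes; only once a layer is
    complete is its accept/prune/branch status decided, so merged joint
    masses are exact over all paths through branched ancestors.
    """
    if cfg.max_total_len is None:
        raise ValueError(
            "the concrete graph builder enumerates strings and needs an "
            "explicit max_total_len"
        )
    n = len(params.alphabet)
    root = GraphNode(s_x="", s_y="", p_joint=1.0, p_x=1.0, p_y=1.0)
    layers: dict[int, dict[tuple[str, str], GraphNode]] = {0: {("", ""): root}}
    buckets: list[GraphNode] = []

    for L in range(0, cfg.max_total_len + 1):
        layer = layers.get(L, {})
        if not layer:
            continue
        # decide statuses
        for node in layer.values():
            if L == 0:
                node.status = "branched"
                continue
            ratio = node.p_joint / (node.p_x * node.p_y)
            if node.p_joint < cfg.prune_threshold:
                node.status = "pruned"
            elif ratio >= cfg.accept_ratio or (
                L >= cfg.max_total_len - 1 and ratio >= 1.0
            ):
                node.status = "accepted"
                buckets.append(node)
            else:
                node.status = "branched"
        # expand branched nodes
        if L >= cfg.max_total_len - 1:
            continue
        for node in layer.values():
            if node.status != "branched":
                continue
            if cfg.exact_match:
                events = [("m", a, a) for a in params.alphabet]
            else:
                events = (
                    [("m", a, b) for a in params.alphabet for b in params.alphabet]
                    + [("d", a) for a in params.alphabet]
                    + [("i", b) for b in params.alphabet]
                )
            for ev in events:
                dest_len = L + (2 if ev[0] == "m" else 1)
                if dest_len > cfg.max_total_len:
                    continue
                dest = layers.setdefault(dest_len, {})
                extend_graph_node(node, ev, params, graph=dest)

    if not buckets:
        raise ValueError("index empty: relax thresholds")

    s_x = [b.s_x for b in buckets]
    s_y = [b.s_y for b in buckets]
    p_joint = np.array([b.p_joint for b in buckets])
    p_x = np.array([b.p_x for b in buckets])
    p_y = np.array([b.p_y for b in buckets])
    beta = float((p_x * p_y).sum())
    alpha_sum = float(p_joint.sum())
    return SAIndex(
        kind="sa-concrete",
        s_x=s_x,
        s_y=s_y,
        p_joint=p_joint,
        p_x=p_x,
        p_y=p_y,
        classes=None,
        beta=beta,
        gamma_x=float(p_x.sum()),
        gamma_y=float(p_y.sum()),
        alpha_sum=alpha_sum,
        alpha_estimate=None,
        eps_miss=cfg.eps_miss,
        j_bands=None,
        max_x_len=max((len(s) for s in s_x), default=0),
        model_hash=model_hash(params),
        config=cfg.to_dict(),
    )


# ---------------------------------------------------------------------------
# Structure (event-pattern) builder for exchangeable DNA models
# ---------------------------------------------------------------------------


@dataclass
class _ColumnStats:
    """Per-column per-concrete factors of an exchangeable model."""

    factor: dict  # event -> per-concrete emission probability
    count: dict  # event -> number of concrete instantiations
    ratio: dict  # event -> enrichment factor per concrete pair


def _column_stats(params: SAParams) -> _ColumnStats:
    n = len(params.alphabet)
    diag = np.diag(params.p_m)
    off = params.p_m[~np.eye(n, dtype=bool)]
    uni = np.full(n, 1 / n)
    exch = (
        np.allclose(diag, diag[0])
        and (off.size == 0 or np.allclose(off, off[0]))
        and np.allclose(params.p_i, params.p_i[0])
        and np.allclose(params.p_d, params.p_d[0])
        and np.allclose(params.px_background, uni)
        and np.allclose(params.py_background, uni)
    )
    if not exch:
        raise ValueError(
            "structure index requires a base-exchangeable model "
            "(constant p_m diagonal/off-diagonal, uniform p_i/p_d/backgrounds)"
        )
    f = {
        "M": params.q_match * float(diag[0]),
        "S": params.q_match * (float(off[0]) if off.size else 0.0),
        "D": params.q_deletion * float(params.p_d[0]),
        "I": params.q_insertion * float(params.p_i[0]),
    }
    count = {"M": n, "S": n * (n - 1), "D": n, "I": n}
    bg = {"M": n**-2, "S": n**-2, "D": 1 / n, "I": 1 / n}
    ratio = {k: (f[k] / bg[k] if f[k] > 0 else 0.0) for k in f}
    return _ColumnStats(factor=f, count=count, ratio=ratio)


@dataclass
class _ClassNode:
    cols: str
    ratio: float  # per-concrete enrichment, incl. indel-run multiplicity
    mass: float  # total probability of the event class
    k: int  # x-length
    l: int  # y-length
    run_d: int
    run_i: int
    mult: int


def build_structure_index(params: SAParams, cfg: SABuildConfig) -> "SAIndex":
    """Grow event-pattern classes for a base-exchangeable model.

    A class is a column string over {M, S, D, I}; indel runs are kept in
    canonical order (deletions before insertions) with a multiplicity
    factor counting the merged orderings, mirroring node merging in the
    concrete graph.  A class is accepted when its per-concrete enrichment
    ratio clears ``accept_ratio``; branches that can no longer reach the
    ratio within the length budget are cut.
    """
    st = _column_stats(params)
    r_m = st.ratio["M"]
    if r_m <= 1.0:
        raise ValueError("model has no diagonal enrichment; no buckets exist")

    allowed = ["M"] if cfg.exact_match else ["M", "S", "D", "I"]
    if cfg.max_total_len is None:
        # Budget so a bucket can pay for max_error_cols of the costliest
        # error column with clean match columns and still clear the bar.
        err_cost = max(
            (-math.log(st.ratio[e]) for e in allowed if 0 < st.ratio[e] < 1),
            default=0.0,
        )
        needed = math.ceil(
            (math.log(cfg.accept_ratio) + cfg.max_error_cols * err_cost)
            / math.log(r_m)
        )
        max_total_len = 2 * needed + 2 * cfg.max_error_cols
    else:
        max_total_len = cfg.max_total_len

    root = _ClassNode("", 1.0, 1.0, 0, 0, 0, 0, 1)
    frontier = [root]
    accepted: list[_ClassNode] = []

    while frontier:
        nxt: list[_ClassNode] = []
        for node in frontier:
            for ev in allowed:
                emit = 2 if ev in ("M", "S") else 1
                total = node.k + node.l + emit
                if total > max_total_len:
                    continue
                if ev != "M" and _n_errors(node.cols) + 1 > cfg.max_error_cols:
                    continue
                if ev == "D" and node.run_i > 0:
                    continue  # canonical order: D before I within a run
                mult = node.mult
                run_d, run_i = node.run_d, node.run_i
                if ev == "I":
                    mult = mult * (run_d + run_i + 1) // (run_i + 1)
                    run_i += 1
                elif ev == "D":
                    run_d += 1
                else:
                    run_d = run_i = 0
                base_ratio = node.ratio / node.mult
                ratio = base_ratio * st.ratio[ev] * mult
                mass = node.mass / node.mult * st.factor[ev] * st.count[ev] * mult
                child = _ClassNode(
                    node.cols + ev,
                    ratio,
                    mass,
                    node.k + (1 if ev != "I" else 0),
                    node.l + (1 if ev != "D" else 0),
                    run_d,
                    run_i,
                    mult,
                )
                if child.mass < cfg.prune_threshold:
                    continue
                if child.ratio >= cfg.accept_ratio:
                    accepted.append(child)
                    continue
                # bound: best case appends clean matches only
                budget = (max_total_len - child.k - child.l) // 2
                if child.ratio * r_m**budget < cfg.accept_ratio:
                    if child.k + child.l >= max_total_len - 1 and child.ratio >= 1:
                        accepted.append(child)
                    continue
                nxt.append(child)
        frontier = nxt

    if not accepted:
        raise ValueError("index empty: relax thresholds")

    n = len(params.alphabet)
    class_cols = [c.cols for c in accepted]
    class_mass = np.array([c.mass for c in accepted])
    class_ratio = np.array([c.ratio for c in accepted])
    ks = np.array([c.k for c in accepted])
    ls = np.array([c.l for c in accepted])
    counts = np.array(
        [
            np.prod([st.count[e] for e in c.cols]) if c.cols else 1.0
            for c in accepted
        ],
        dtype=float,
    )
    beta = float((counts * n**-(ks + ls).astype(float)).sum())
    gamma_x = float((counts * n**-ks.astype(float)).sum())
    gamma_y = float((counts * n**-ls.astype(float)).sum())
    return SAIndex(
        kind="sa-structure",
        s_x=None,
        s_y=None,
        p_joint=class_mass,
        p_x=None,
        p_y=None,
        classes=class_cols,
        beta=beta,
        gamma_x=gamma_x,
        gamma_y=gamma_y,
        alpha_sum=float(class_mass.sum()),
        alpha_estimate=None,
        eps_miss=cfg.eps_miss,
        j_bands=None,
        max_x_len=int(ks.max()),
        model_hash=model_hash(params),
        config={**cfg.to_dict(), "max_total_len": max_total_len},
        class_ratio=class_ratio,
    )


def _n_errors(cols: str) -> int:
    return sum(1 for c in cols if c != "M")


# ---------------------------------------------------------------------------
# Index container
# ---------------------------------------------------------------------------


@dataclass
class SAIndex:
    """Bucket structure for the SA model, concrete or pattern-class form.

    ``alpha_sum`` (the summed bucket joint mass) is only an upper bound on
    the per-band true-positive rate because graph buckets overlap as
    events; ``alpha_estimate`` is the Monte-Carlo value filled in by
    :func:`estimate_alpha` and used for band planning.
    """

    kind: str
    s_x: list[str] | None
    s_y: list[str] | None
    p_joint: np.ndarray
    p_x: np.ndarray | None
    p_y: np.ndarray | None
    classes: list[str] | None
    beta: float
    gamma_x: float
    gamma_y: float
    alpha_sum: float
    alpha_estimate: float | None
    eps_miss: float
    j_bands: int | None
    max_x_len: int
    model_hash: str
    config: dict
    class_ratio: np.ndarray | None = None
    alpha_seed: int | None = None

    @property
    def d(self) -> int:
        return len(self.classes) if self.classes is not None else len(self.s_x)

    @property
    def alpha(self) -> float:
        return self.alpha_estimate if self.alpha_estimate is not None else self.alpha_sum

    # ---- mapping (concrete form) ---------------------------------------
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

    # ---- mapping (structure form) --------------------------------------
    def _class_tables(self):
        cached = getattr(self, "_ctab", None)
        if cached is None:
            ks = [sum(1 for e in c if e != "I") for c in self.classes]
            ls = [sum(1 for e in c if e != "D") for c in self.classes]
            cached = (ks, ls, sorted(set(ks)))
            object.__setattr__(self, "_ctab", cached)
        return cached

    def read_keys(
        self, enc: np.ndarray, offsets: np.ndarray
    ) -> dict[int, tuple[np.ndarray, np.ndarray]]:
        """Candidate x k-mer codes per x-length, for read suffixes.

        This is the enumeration side of the asymmetric hash: for every
        class and read offset, the compatible x-strings are enumerated
        (the read base fixes M columns, S columns take the three other
        bases, D columns take all four, I columns consume a read base
        without contributing to x).  Classes of equal x-length k share
        one key space of raw k-mer codes, so the reference side needs
        only one key per position per distinct k; duplicate
        (code, offset) pairs produced by different classes are merged.
        Returns ``{k: (codes, offsets)}``.
        """
        ks, ls, _ = self._class_tables()
        m = enc.shape[0]
        acc: dict[int, list[tuple[np.ndarray, np.ndarray]]] = {}
        for ci, cols in enumerate(self.classes):
            valid = offsets[offsets + ls[ci] <= m]
            if valid.size == 0:
                continue
            codes = [np.zeros(valid.size, dtype=np.int64)]
            masks = [np.ones(valid.size, dtype=bool)]
            ypos = 0
            for ev in cols:
                if ev == "M":
                    b = enc[valid + ypos]
                    codes = [c * 4 + b for c in codes]
                    ypos += 1
                elif ev == "S":
                    b = enc[valid + ypos]
                    codes, masks = (
                        [c * 4 + a for c in codes for a in range(4)],
                        [mk & (b != a) for mk in masks for a in range(4)],
                    )
                    ypos += 1
                elif ev == "D":
                    codes = [c * 4 + a for c in codes for a in range(4)]
                    masks = [mk for mk in masks for _ in range(4)]
                else:  # I: read base consumed, absent from the x string
                    ypos += 1
            store = acc.setdefault(ks[ci], [])
            for c, mk in zip(codes, masks):
                store.append((c[mk], valid[mk]) if not mk.all() else (c, valid))
        out: dict[int, tuple[np.ndarray, np.ndarray]] = {}
        for k, parts in acc.items():
            codes = np.concatenate([p[0] for p in parts])
            offs = np.concatenate([p[1] for p in parts])
            pair_key = codes * np.int64(m + 1) + offs
            _, keep = np.unique(pair_key, return_index=True)
            out[k] = (codes[keep], offs[keep])
        return out

    def read_key_set(self, enc: np.ndarray, offset: int) -> set:
        """Candidate (x-length, x k-mer code) keys for one read offset.

        Scalar counterpart of :meth:`read_keys`, avoiding per-class array
        overhead; used by the Monte-Carlo band-rate estimator where a
        single offset is mapped for many short simulated pairs.
        """
        ks, ls, _ = self._class_tables()
        chars = enc[offset:].tolist()
        m = len(chars)
        out: set = set()
        for ci, cols in enumerate(self.classes):
            if ls[ci] > m:
                continue
            codes = [0]
            ypos = 0
            for ev in cols:
                if ev == "M":
                    b = chars[ypos]
                    codes = [c * 4 + b for c in codes]
                    ypos += 1
                elif ev == "S":
                    b = chars[ypos]
                    codes = [c * 4 + a for c in codes for a in range(4) if a != b]
                    ypos += 1
                elif ev == "D":
                    codes = [c * 4 + a for c in codes for a in range(4)]
                else:  # I
                    ypos += 1
            k = ks[ci]
            out.update((k, c) for c in codes)
        return out

    # ---- serialization --------------------------------------------------
    def save(self, path) -> None:
        header = {
            "format": "dsbucket-index",
            "version": 1,
            "kind": self.kind,
            "model_hash": self.model_hash,
            "config": self.config,
            "beta": self.beta,
            "gamma_x": self.gamma_x,
            "gamma_y": self.gamma_y,
            "alpha_sum": self.alpha_sum,
            "alpha_estimate": self.alpha_estimate,
            "alpha_seed": self.alpha_seed,
            "eps_miss": self.eps_miss,
            "j_bands": self.j_bands,
            "max_x_len": self.max_x_len,
        }
        with open(path, "w") as fh:
            fh.write(json.dumps(header) + "\n")
            if self.kind == "sa-concrete":
                for sx, sy, pj, px, py in zip(
                    self.s_x, self.s_y, self.p_joint, self.p_x, self.p_y
                ):
                    fh.write(
                        f"{sx}\t{sy}\t{float(pj)!r}\t{float(px)!r}\t{float(py)!r}\n"
                    )
            else:
                for cols, pj, r in zip(self.classes, self.p_joint, self.class_ratio):
                    fh.write(f"{cols}\t{float(pj)!r}\t{float(r)!r}\n")

    @classmethod
    def load(cls, path) -> "SAIndex":
        with open(path) as fh:
            header = json.loads(fh.readline())
            if header.get("format") != "dsbucket-index":
                raise ValueError(f"{path}: not a dsbucket index file")
            kind = header["kind"]
            if kind == "sa-concrete":
                s_x, s_y, pj, px, py = [], [], [], [], []
                for line in fh:
                    f = line.rstrip("\n").split("\t")
                    s_x.append(f[0])
                    s_y.append(f[1])
                    pj.append(float(f[2]))
                    px.append(float(f[3]))
                    py.append(float(f[4]))
                return cls(
                    kind=kind,
                    s_x=s_x,
                    s_y=s_y,
                    p_joint=np.array(pj),
                    p_x=np.array(px),
                    p_y=np.array(py),
                    classes=None,
                    beta=header["beta"],
                    gamma_x=header["gamma_x"],
                    gamma_y=header["gamma_y"],
                    alpha_sum=header["alpha_sum"],
                    alpha_estimate=header["alpha_estimate"],
                    alpha_seed=header.get("alpha_seed"),
                    eps_miss=header["eps_miss"],
                    j_bands=header["j_bands"],
                    max_x_len=header["max_x_len"],
                    model_hash=header["model_hash"],
                    config=header["config"],
                )
            classes, pj, ratio = [], [], []
            for line in fh:
                f = line.rstrip("\n").split("\t")
                classes.append(f[0])
                pj.append(float(f[1]))
                ratio.append(float(f[2]))
            return cls(
                kind=kind,
                s_x=None,
                s_y=None,
                p_joint=np.array(pj),
                p_x=None,
                p_y=None,
                classes=classes,
                beta=header["beta"],
                gamma_x=header["gamma_x"],
                gamma_y=header["gamma_y"],
                alpha_sum=header["alpha_sum"],
                alpha_estimate=header["alpha_estimate"],
                alpha_seed=header.get("alpha_seed"),
                eps_miss=header["eps_miss"],
                j_bands=header["j_bands"],
                max_x_len=header["max_x_len"],
                model_hash=header["model_hash"],
                config=header["config"],
                class_ratio=np.array(ratio),
            )


# ---------------------------------------------------------------------------
# Mapping and alpha estimation
# ---------------------------------------------------------------------------


def map_sequence_sa(index: SAIndex, s: str, axis: str, band_j: int) -> set:
    """Buckets whose axis-string prefixes the ``band_j``-th suffix of ``s``.

    For the concrete form the returned set holds bucket ids; for the
    structure form it holds (x-length, x k-mer code) keys — forced on the
    x axis, enumerated on the y axis — and co-occurrence is set
    intersection in either case.
    """
    if axis not in ("x", "y"):
        raise ValueError("axis must be 'x' or 'y'")
    if band_j < 1:
        raise ValueError("band_j must be >= 1")
    start = band_j - 1
    if start >= len(s) + 1:
        return set()
    if index.kind == "sa-concrete":
        table = index._axis_map(axis)
        out: set[int] = set()
        for length, strings in table.items():
            if start + length <= len(s):
                hit = strings.get(s[start : start + length])
                if hit:
                    out.update(hit)
        return out
    enc = encode_dna(s)
    if axis == "y":
        return index.read_key_set(enc, start)
    _, _, distinct = index._class_tables()
    out = set()
    for k in distinct:
        if start + k <= len(s):
            code = 0
            for t in range(start, start + k):
                code = code * 4 + int(enc[t])
            out.add((k, code))
    return out


def estimate_alpha(
    index: SAIndex, params: SAParams, n_sim: int = 1000, rng_seed=0, S: int = 60
) -> tuple[float, float]:
    """Monte-Carlo per-band true-positive rate: fraction of jointly
    simulated pairs whose two sides share at least one bucket at band 1.
    Returns (estimate, binomial standard error)."""
    if n_sim < 100:
        raise ValueError("n_sim must be >= 100")
    rng = np.random.default_rng(rng_seed)
    hits = 0
    for _ in range(n_sim):
        pair = sample_sa_pair(params, S, rng)
        if map_sequence_sa(index, pair.x, "x", 1) & map_sequence_sa(
            index, pair.y, "y", 1
        ):
            hits += 1
    a = hits / n_sim
    se = math.sqrt(max(a * (1 - a), 1.0 / n_sim) / n_sim)
    return a, se


def plan_bands(index: SAIndex, params: SAParams, n_sim: int = 2000, rng_seed=0) -> None:
    """Fill in alpha_estimate and the band count J on the index.

    When no simulated pair shares a bucket, the rate is below the
    resolution of the simulation; 1/n_sim is then used as a conservative
    stand-in (the resulting J over-provisions bands, which the search
    caps at the number of available offsets anyway).
    """
    a, _ = estimate_alpha(index, params, n_sim=n_sim, rng_seed=rng_seed)
    if a <= 0:
        a = 1.0 / n_sim
    index.alpha_estimate = a
    index.alpha_seed = int(rng_seed) if not isinstance(rng_seed, np.random.Generator) else None
    index.j_bands = choose_bands(min(a, 1.0), index.eps_miss)


# ---------------------------------------------------------------------------
# Read-versus-genome search
# ---------------------------------------------------------------------------


@dataclass
class Hit:
    query_id: str
    ref_id: str
    ref_start: int
    ref_end: int
    query_start: int
    query_end: int
    strand: str
    score: float
    n_bucket_votes: int


@dataclass
class SASearchStats:
    n_votes: int
    n_clusters: int
    n_verified: int
    n_hits: int
    j_bands: int


def _kmer_codes(enc: np.ndarray, ks: list[int]) -> dict[int, np.ndarray]:
    """Integer codes of every k-mer of the encoded sequence, for each k."""
    out: dict[int, np.ndarray] = {}
    L = enc.shape[0]
    kmax = max(ks)
    code = None
    for k in range(1, kmax + 1):
        if code is None:
            code = enc.astype(np.int64).copy()
        else:
            code = code[:-1] * 4 + enc[k - 1 :]
        if k in ks:
            out[k] = code
    return out


def _sa_llr_enc(params: SAParams, x_enc: np.ndarray, y_enc: np.ndarray) -> float:
    em = params.q_match * params.p_m
    ei = params.q_insertion * params.p_i
    ed = params.q_deletion * params.p_d
    joint = sa_forward_scaled(x_enc, y_enc, em, ei, ed)
    bg = float(np.log(params.px_background)[x_enc].sum()) + float(
        np.log(params.py_background)[y_enc].sum()
    )
    return float(joint - bg)


def _ratio_tables(params: SAParams) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Background-normalized column factors for the semi-global DP."""
    bx = params.px_background
    by = params.py_background
    rm = params.q_match * params.p_m / np.outer(bx, by)
    ri = params.q_insertion * params.p_i / by
    rd = params.q_deletion * params.p_d / bx
    return rm, ri, rd


def sa_llr_window(params: SAParams, x_enc: np.ndarray, y_enc: np.ndarray) -> float:
    """Log-likelihood ratio of y against a longer x window, with the
    unaligned x flanks explained by the background model.

    This is the verification score for read-to-reference windows: the
    global joint probability would charge every flank position as a
    deletion, so a window longer than the read's true span would always
    score below background even for a perfect read.
    """
    rm, ri, rd = _ratio_tables(params)
    return float(sa_semiglobal_llr(x_enc, y_enc, rm, ri, rd))


def dsb_sa_search(
    index: SAIndex,
    reference: list[tuple[str, str]],
    reads: list[tuple[str, str]],
    params: SAParams,
    llr_threshold: float = 0.0,
    window_pad: float = 0.25,
    min_votes: int = 1,
    search_rc: bool = True,
    diag_frac: float = 0.35,
) -> tuple[list[Hit], SASearchStats]:
    """Map reads against reference sequences through the bucket index.

    Every reference position is a band on the x side; each read (and,
    optionally, its reverse complement) is mapped from J evenly spaced
    suffix positions.  A bucket co-occurrence at reference position p and
    read offset r votes for the diagonal p - r; votes are clustered per
    read within a tolerance of ``diag_frac`` times the read length (the
    indel drift bound), and each cluster's reference window (read length
    plus ``2 * window_pad`` times the read length) is verified with the
    exact log-likelihood ratio.
    """
    if index.model_hash != model_hash(params):
        raise ValueError("params/index mismatch: model hash differs")
    if index.j_bands is None:
        plan_bands(index, params)
    J = index.j_bands

    hits: list[Hit] = []
    n_votes = n_clusters = n_verified = 0
    rm, ri, rd = _ratio_tables(params)

    # read instances (forward and reverse complement)
    instances = []
    for rid, seq in reads:
        instances.append((rid, "+", seq))
        if search_rc:
            instances.append((rid, "-", reverse_complement(seq)))

    for ref_id, ref_seq in reference:
        if len(ref_seq) < index.max_x_len:
            raise ValueError(
                f"reference {ref_id!r} shorter than the longest bucket x-string"
            )
        ref_enc = encode_dna(ref_seq)

        gtab: dict[int, tuple[np.ndarray, np.ndarray]] = {}
        if index.kind == "sa-structure":
            # one key per reference position per distinct x-length
            _, _, distinct = index._class_tables()
            codes = _kmer_codes(ref_enc, distinct)
            for k in distinct:
                c = codes[k]
                order = np.argsort(c, kind="stable")
                gtab[k] = (c[order], order.astype(np.int64))
            gkeys = np.empty(0, dtype=np.int64)
            gpos = np.empty(0, dtype=np.int64)
        else:
            # concrete form: one key per (bucket x-length, position)
            table = index._axis_map("x")
            gkeys_l, gpos_l = [], []
            codes = _kmer_codes(ref_enc, sorted(table.keys())) if table else {}
            lut = {}
            for length, strings in table.items():
                for s, ids in strings.items():
                    code = 0
                    for ch in s:
                        code = code * 4 + int(_DNA_LUT[ord(ch)])
                    for b in ids:
                        lut.setdefault((length, code), []).append(b)
            # build genome keys as (bucket id) occurrences
            for (length, code), bids in lut.items():
                pos = np.nonzero(codes[length] == code)[0]
                for b in bids:
                    gkeys_l.append(np.full(pos.shape[0], b, dtype=np.int64))
                    gpos_l.append(pos)
            gkeys = (
                np.concatenate(gkeys_l) if gkeys_l else np.empty(0, dtype=np.int64)
            )
            gpos = np.concatenate(gpos_l) if gpos_l else np.empty(0, dtype=np.int64)

        order = np.argsort(gkeys, kind="stable")
        gkeys_s = gkeys[order]
        gpos_s = gpos[order]

        for rid, strand, seq in instances:
            L = len(seq)
            enc = encode_dna(seq)
            max_off = L - index.max_x_len
            if max_off < 0:
                continue
            offsets = np.unique(
                np.linspace(0, max_off, num=min(J, max_off + 1)).astype(int)
            )
            diag_list: list[np.ndarray] = []
            if index.kind == "sa-structure":
                rk = index.read_keys(enc, offsets.astype(np.int64))
                for k, (rc, ro) in rk.items():
                    gs, gp = gtab[k]
                    lo = np.searchsorted(gs, rc, side="left")
                    hi = np.searchsorted(gs, rc, side="right")
                    for i in np.nonzero(hi - lo)[0]:
                        diag_list.append(gp[lo[i] : hi[i]] - ro[i])
            else:
                rkeys, roffs = [], []
                table_y = index._axis_map("y")
                for off in offsets:
                    for length, strings in table_y.items():
                        if off + length <= L:
                            for b in strings.get(seq[off : off + length], ()):
                                rkeys.append(b)
                                roffs.append(int(off))
                if rkeys:
                    rkeys = np.array(rkeys, dtype=np.int64)
                    roffs = np.array(roffs, dtype=np.int64)
                    lo = np.searchsorted(gkeys_s, rkeys, side="left")
                    hi = np.searchsorted(gkeys_s, rkeys, side="right")
                    for i in np.nonzero(hi - lo)[0]:
                        diag_list.append(gpos_s[lo[i] : hi[i]] - roffs[i])
            if not diag_list:
                continue
            diags = np.concatenate(diag_list)
            n_votes += diags.shape[0]

            # cluster votes by diagonal
            tol = max(1, int(diag_frac * L))
            ds = np.sort(diags)
            breaks = np.nonzero(np.diff(ds) > tol)[0]
            groups = np.split(ds, breaks + 1)
            pad = int(window_pad * L)
            for g in groups:
                if g.shape[0] < min_votes:
                    continue
                n_clusters += 1
                d = int(np.median(g))
                w_start = max(0, d - pad)
                w_end = min(len(ref_seq), d + L + pad)
                if w_end <= w_start:
                    continue
                n_verified += 1
                window = ref_enc[w_start:w_end]
                score = float(sa_semiglobal_llr(window, enc, rm, ri, rd))
                if score >= llr_threshold:
                    hits.append(
                        Hit(
                            query_id=rid,
                            ref_id=ref_id,
                            ref_start=w_start,
                            ref_end=w_end,
                            query_start=0,
                            query_end=L,
                            strand=strand,
                            score=score,
                            n_bucket_votes=int(g.shape[0]),
                        )
                    )
    return hits, SASearchStats(
        n_votes=n_votes,
        n_clusters=n_clusters,
        n_verified=n_verified,
        n_hits=len(hits),
        j_bands=J,
    )


def exhaustive_window_search(
    reference: list[tuple[str, str]],
    reads: list[tuple[str, str]],
    params: SAParams,
    llr_threshold: float = 0.0,
    window_frac: float = 1.5,
    stride_frac: float = 0.5,
    search_rc: bool = True,
) -> list[Hit]:
    """Brute-force oracle: verify every read against every sliding window
    of every reference with the semi-global log-likelihood-ratio DP.
    Quadratic; intended for small inputs and as the sensitivity
    reference."""
    rm, ri, rd = _ratio_tables(params)
    hits: list[Hit] = []
    instances = []
    for rid, seq in reads:
        instances.append((rid, "+", seq))
        if search_rc:
            instances.append((rid, "-", reverse_complement(seq)))
    for ref_id, ref_seq in reference:
        ref_enc = encode_dna(ref_seq)
        for rid, strand, seq in instances:
            enc = encode_dna(seq)
            L = len(seq)
            w = min(len(ref_seq), max(1, int(window_frac * L)))
            stride = max(1, int(stride_frac * L))
            starts = list(range(0, max(1, len(ref_seq) - w + 1), stride))
            if starts[-1] != len(ref_seq) - w:
                starts.append(max(0, len(ref_seq) - w))
            for s0 in starts:
                window = ref_enc[s0 : s0 + w]
                score = float(sa_semiglobal_llr(window, enc, rm, ri, rd))
                if score >= llr_threshold:
                    hits.append(
                        Hit(
                            query_id=rid,
                            ref_id=ref_id,
                            ref_start=s0,
                            ref_end=s0 + w,
                            query_start=0,
                            query_end=L,
                            strand=strand,
                            score=score,
                            n_bucket_votes=0,
                        )
                    )
    return hits
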