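"""Generative models for pairwise sequence similarity.

Two latent-variable models of jointly generated sequence pairs:

* a joint HMM emitting one symbol pair ``(x_t, y_t)`` per step, suitable for
  gapless (substitution-only) similarity, and
* a *sequence alignment* (SA) model, a pair-HMM-like process whose latent
  string over ``{m, i, d}`` interleaves match/mismatch columns with
  insertions and deletions, so the two emitted sequences may differ in
  length.

Under either model, a pair's alignment score is the log-likelihood ratio

    log P(X, Y) - log Px(X) - log Py(Y)

of being generated jointly versus independently from background models.
All probabilities are handled in natural-log space (scaled forward
recursions), so sequences of length in the thousands are safe.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import yaml

from ._dp import sa_forward_scaled

__all__ = [
    "HMMParams",
    "SAParams",
    "SequencePair",
    "hmm_forward_joint",
    "hmm_forward_joint_batch",
    "hmm_marginal",
    "hmm_llr",
    "sa_path_probability",
    "sa_joint_probability",
    "sa_llr",
    "sample_hmm_pair",
    "sample_sa_pair",
]

DNA = "ACGT"

_ATOL = 1e-9


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def encode(seq: str | Sequence[str], alphabet: str) -> np.ndarray:
    """Map a sequence to integer codes, reporting the first bad position."""
    lut = {c: i for i, c in enumerate(alphabet)}
    out = np.empty(len(seq), dtype=np.int64)
    for i, c in enumerate(seq):
        try:
            out[i] = lut[c]
        except KeyError:
            raise ValueError(
                f"unknown symbol {c!r} at position {i} (alphabet {alphabet!r})"
            ) from None
    return out


def _check_prob_vector(v: np.ndarray, name: str) -> None:
    if np.any(v < -_ATOL) or np.any(v > 1 + _ATOL):
        raise ValueError(f"{name}: entries must lie in [0, 1]")
    if not np.isclose(v.sum(), 1.0, atol=1e-6):
        raise ValueError(f"{name}: must sum to 1 (got {v.sum():.8f})")


# ---------------------------------------------------------------------------
# Joint HMM over paired observations
# ---------------------------------------------------------------------------


@dataclass
class HMMParams:
    """Joint HMM over aligned symbol pairs.

    The hidden chain has initial distribution ``p_init`` and transition
    matrix ``p_trans``; state ``h`` emits the pair ``(a, b)`` with
    probability ``p_emit[a, b, h]``.  ``px_background`` / ``py_background``
    are the independent (background) per-symbol models used for the
    likelihood-ratio denominator.
    """

    hidden_alphabet: tuple
    obs_alphabet_x: str
    obs_alphabet_y: str
    p_init: np.ndarray
    p_trans: np.ndarray
    p_emit: np.ndarray  # shape (|A|, |B|, |H|)
    px_background: np.ndarray
    py_background: np.ndarray

    def __post_init__(self):
        self.p_init = np.asarray(self.p_init, dtype=float)
        self.p_trans = np.asarray(self.p_trans, dtype=float)
        self.p_emit = np.asarray(self.p_emit, dtype=float)
        self.px_background = np.asarray(self.px_background, dtype=float)
        self.py_background = np.asarray(self.py_background, dtype=float)
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        nh = len(self.hidden_alphabet)
        na, nb = len(self.obs_alphabet_x), len(self.obs_alphabet_y)
        if self.p_init.shape != (nh,):
            raise ValueError("p_init: wrong shape")
        _check_prob_vector(self.p_init, "p_init")
        if self.p_trans.shape != (nh, nh):
            raise ValueError("p_trans: wrong shape")
        for i in range(nh):
            _check_prob_vector(self.p_trans[i], f"p_trans row {i}")
        if self.p_emit.shape != (na, nb, nh):
            raise ValueError("p_emit: wrong shape")
        for h in range(nh):
            _check_prob_vector(self.p_emit[:, :, h].ravel(), f"p_emit state {h}")
        if self.px_background.shape != (na,):
            raise ValueError("px_background: wrong shape")
        _check_prob_vector(self.px_background, "px_background")
        if self.py_background.shape != (nb,):
            raise ValueError("py_background: wrong shape")
        _check_prob_vector(self.py_background, "py_background")

    @property
    def n_hidden(self) -> int:
        return len(self.hidden_alphabet)

    # -- canonical instance ----------------------------------------------
    @classmethod
    def symmetric_binary(
        cls,
        error_rate: float,
        switch_prob: float,
        p_init: Iterable[float] | None = None,
    ) -> "HMMParams":
        """Two-state binary model: state 0 emits mostly matching bits,
        state 1 mostly mismatching bits.

        ``error_rate`` is the off-pattern emission mass per cell and
        ``switch_prob`` the probability of flipping hidden state between
        consecutive columns.  The hidden-state prior defaults to uniform.
        """
        e, d = float(error_rate), float(switch_prob)
        if not 0 <= e <= 0.5:
            raise ValueError("error_rate must be in [0, 0.5]")
        if not 0 <= d <= 1:
            raise ValueError("switch_prob must be in [0, 1]")
        emit0 = np.array([[0.5 - e, e], [e, 0.5 - e]])
        emit1 = np.array([[e, 0.5 - e], [0.5 - e, e]])
        p_emit = np.stack([emit0, emit1], axis=-1)
        init = np.array([0.5, 0.5]) if p_init is None else np.asarray(p_init, float)
        return cls(
            hidden_alphabet=(0, 1),
            obs_alphabet_x="01",
            obs_alphabet_y="01",
            p_init=init,
            p_trans=np.array([[1 - d, d], [d, 1 - d]]),
            p_emit=p_emit,
            px_background=np.array([0.5, 0.5]),
            py_background=np.array([0.5, 0.5]),
        )

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "kind": "hmm",
            "hidden_alphabet": list(self.hidden_alphabet),
            "obs_alphabet_x": self.obs_alphabet_x,
            "obs_alphabet_y": self.obs_alphabet_y,
            "p_init": self.p_init.tolist(),
            "p_trans": self.p_trans.tolist(),
            "p_emit": self.p_emit.tolist(),
            "px_background": self.px_background.tolist(),
            "py_background": self.py_background.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "HMMParams":
        d = dict(d)
        d.pop("kind", None)
        d["hidden_alphabet"] = tuple(d["hidden_alphabet"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh)

    @classmethod
    def from_yaml(cls, path) -> "HMMParams":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class SAParams:
    """Sequence alignment model (pair-HMM-like, independent indels).

    A latent string over ``{m, i, d}`` is drawn i.i.d. from
    ``(q_match, q_insertion, q_deletion)``; an ``m`` column emits a pair
    from ``p_m`` (its off-diagonal mass is the substitution rate), a ``d``
    column emits into X only (from ``p_d``) and an ``i`` column into Y only
    (from ``p_i``).
    """

    p_m: np.ndarray  # (4, 4) joint match/mismatch emission
    p_i: np.ndarray  # (4,)
    p_d: np.ndarray  # (4,)
    q_match: float
    q_insertion: float
    q_deletion: float
    px_background: np.ndarray
    py_background: np.ndarray
    alphabet: str = DNA

    def __post_init__(self):
        self.p_m = np.asarray(self.p_m, dtype=float)
        self.p_i = np.asarray(self.p_i, dtype=float)
        self.p_d = np.asarray(self.p_d, dtype=float)
        self.px_background = np.asarray(self.px_background, dtype=float)
        self.py_background = np.asarray(self.py_background, dtype=float)
        self.validate()

    def validate(self) -> None:
        n = len(self.alphabet)
        qs = np.array([self.q_match, self.q_insertion, self.q_deletion])
        if np.any(qs < 0):
            raise ValueError("q probabilities must be non-negative")
        if not np.isclose(qs.sum(), 1.0, atol=1e-6):
            raise ValueError(
                "q_match + q_insertion + q_deletion must equal 1 "
                f"(got {qs.sum():.8f})"
            )
        if self.p_m.shape != (n, n):
            raise ValueError("p_m: wrong shape")
        _check_prob_vector(self.p_m.ravel(), "p_m")
        for name in ("p_i", "p_d", "px_background", "py_background"):
            v = getattr(self, name)
            if v.shape != (n,):
                raise ValueError(f"{name}: wrong shape")
            _check_prob_vector(v, name)

    @classmethod
    def uniform(cls, q=(1 / 3, 1 / 3, 1 / 3), alphabet: str = DNA) -> "SAParams":
        """Fully uniform tables; joint equals independent."""
        n = len(alphabet)
        return cls(
            p_m=np.full((n, n), 1 / n**2),
            p_i=np.full(n, 1 / n),
            p_d=np.full(n, 1 / n),
            q_match=q[0],
            q_insertion=q[1],
            q_deletion=q[2],
            px_background=np.full(n, 1 / n),
            py_background=np.full(n, 1 / n),
            alphabet=alphabet,
        )

    @classmethod
    def from_error_profile(
        cls,
        total_error: float,
        indel_frac: float = 2 / 3,
        base_freqs: Iterable[float] | None = None,
        alphabet: str = DNA,
    ) -> "SAParams":
        """Model matched to a read error profile.

        ``total_error`` is the per-base error rate on reads; a fraction
        ``indel_frac`` of it is indels (split evenly between insertions and
        deletions) and the rest substitutions.  The diagonal of ``p_m``
        carries the non-substituted mass.
        """
        if not 0 <= total_error < 1:
            raise ValueError("total_error must be in [0, 1)")
        if not 0 <= indel_frac <= 1:
            raise ValueError("indel_frac must be in [0, 1]")
        n = len(alphabet)
        pi = (
            np.full(n, 1 / n)
            if base_freqs is None
            else np.asarray(base_freqs, dtype=float)
        )
        q_ins = q_del = total_error * indel_frac / 2
        q_match = 1.0 - q_ins - q_del
        sub = total_error * (1 - indel_frac) / q_match  # P(substitution | m column)
        p_m = np.outer(pi, np.full(n, sub / (n - 1)))
        np.fill_diagonal(p_m, 0.0)
        p_m += np.diag(pi * (1 - sub))
        return cls(
            p_m=p_m,
            p_i=pi.copy(),
            p_d=pi.copy(),
            q_match=q_match,
            q_insertion=q_ins,
            q_deletion=q_del,
            px_background=pi.copy(),
            py_background=pi.copy(),
            alphabet=alphabet,
        )

    def to_dict(self) -> dict:
        return {
            "kind": "sa",
            "alphabet": self.alphabet,
            "p_m": self.p_m.tolist(),
            "p_i": self.p_i.tolist(),
            "p_d": self.p_d.tolist(),
            "q_match": float(self.q_match),
            "q_insertion": float(self.q_insertion),
            "q_deletion": float(self.q_deletion),
            "px_background": self.px_background.tolist(),
            "py_background": self.py_background.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SAParams":
        d = dict(d)
        d.pop("kind", None)
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh)

    @classmethod
    def from_yaml(cls, path) -> "SAParams":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class SequencePair:
    """A simulated pair with its ground-truth latent string.

    For HMM pairs ``latent`` is the hidden-state sequence (same length as
    ``x`` and ``y``); for SA pairs it is the event string over ``mid`` and
    ``xbar`` / ``ybar`` hold the gapped pre-sequences.
    """

    x: str
    y: str
    latent: tuple | str | None = None
    xbar: str | None = None
    ybar: str | None = None


# ---------------------------------------------------------------------------
# HMM probability computations
# ---------------------------------------------------------------------------


def hmm_forward_joint(params: HMMParams, x: str, y: str) -> float:
    """log P(X, Y) under the joint HMM (scaled forward recursion)."""
    if len(x) != len(y):
        raise ValueError(f"unequal lengths: |x|={len(x)}, |y|={len(y)}")
    if len(x) == 0:
        raise ValueError("empty sequences")
    xi = encode(x, params.obs_alphabet_x)
    yi = encode(y, params.obs_alphabet_y)
    f = params.p_init * params.p_emit[xi[0], yi[0], :]
    log_p = 0.0
    for t in range(1, len(xi)):
        c = f.sum()
        if c == 0.0:
            return -np.inf
        log_p += np.log(c)
        f = (f / c) @ params.p_trans * params.p_emit[xi[t], yi[t], :]
    total = f.sum()
    return log_p + (np.log(total) if total > 0 else -np.inf)


def hmm_forward_joint_batch(params: HMMParams, xs: np.ndarray, y: np.ndarray) -> np.ndarray:
    """log P(X_i, Y) for many integer-encoded database rows against one query.

    ``xs`` is (N, T) int, ``y`` (T,) int.  Vectorizes the scaled forward
    recursion across the database dimension.
    """
    n, t_len = xs.shape
    f = params.p_init[None, :] * params.p_emit[xs[:, 0], y[0], :]
    log_p = np.zeros(n)
    for t in range(1, t_len):
        c = f.sum(axis=1)
        np.clip(c, 1e-300, None, out=c)
        log_p += np.log(c)
        f = (f / c[:, None]) @ params.p_trans * params.p_emit[xs[:, t], y[t], :]
    c = f.sum(axis=1)
    np.clip(c, 1e-300, None, out=c)
    return log_p + np.log(c)


def hmm_marginal(params: HMMParams, s: str, axis: str = "x", exact: bool = False) -> float:
    """log of the marginal model probability of one side.

    Default scores against the background table; ``exact=True`` runs the
    forward recursion on the emission table summed over the other side,
    i.e. the true marginal of the joint HMM.
    """
    if axis not in ("x", "y"):
        raise ValueError("axis must be 'x' or 'y'")
    if len(s) == 0:
        raise ValueError("empty sequence")
    alphabet = params.obs_alphabet_x if axis == "x" else params.obs_alphabet_y
    si = encode(s, alphabet)
    if not exact:
        bg = params.px_background if axis == "x" else params.py_background
        return float(np.log(bg[si]).sum())
    emit = params.p_emit.sum(axis=1) if axis == "x" else params.p_emit.sum(axis=0)
    f = params.p_init * emit[si[0], :]
    log_p = 0.0
    for t in range(1, len(si)):
        c = f.sum()
        if c == 0.0:
            return -np.inf
        log_p += np.log(c)
        f = (f / c) @ params.p_trans * emit[si[t], :]
    total = f.sum()
    return log_p + (np.log(total) if total > 0 else -np.inf)


def hmm_llr(params: HMMParams, x: str, y: str, exact_marginal: bool = False) -> float:
    """Log-likelihood ratio of joint versus independent generation."""
    return (
        hmm_forward_joint(params, x, y)
        - hmm_marginal(params, x, "x", exact=exact_marginal)
        - hmm_marginal(params, y, "y", exact=exact_marginal)
    )


# ---------------------------------------------------------------------------
# SA model probability computations
# ---------------------------------------------------------------------------


def sa_path_probability(params: SAParams, latent: str, xbar: str, ybar: str) -> float:
    """log P(X, Y | H) + log P(H) for one explicit gapped alignment.

    ``latent`` is the event string over ``mid``; ``xbar`` carries '-'
    exactly at insertion columns and ``ybar`` '-' exactly at deletion
    columns.
    """
    if not (len(latent) == len(xbar) == len(ybar)):
        raise ValueError("latent, xbar, ybar must have equal lengths")
    lut = {c: i for i, c in enumerate(params.alphabet)}
    log_p = 0.0
    lq_m, lq_i, lq_d = (
        np.log(params.q_match) if params.q_match > 0 else -np.inf,
        np.log(params.q_insertion) if params.q_insertion > 0 else -np.inf,
        np.log(params.q_deletion) if params.q_deletion > 0 else -np.inf,
    )
    for t, ev in enumerate(latent):
        a, b = xbar[t], ybar[t]
        if ev == "m":
            if a == "-" or b == "-":
                raise ValueError(f"position {t}: match column cannot carry a gap")
            log_p += lq_m + np.log(params.p_m[lut[a], lut[b]])
        elif ev == "i":
            if a != "-" or b == "-":
                raise ValueError(f"position {t}: insertion column must gap xbar only")
            log_p += lq_i + np.log(params.p_i[lut[b]])
        elif ev == "d":
            if b != "-" or a == "-":
                raise ValueError(f"position {t}: deletion column must gap ybar only")
            log_p += lq_d + np.log(params.p_d[lut[a]])
        else:
            raise ValueError(f"position {t}: unknown event {ev!r}")
    return float(log_p)


def sa_joint_probability(params: SAParams, x: str, y: str) -> float:
    """log P(X, Y) summed over all latent event strings consistent with the
    observed lengths (standard O(|x| |y|) pair-HMM forward DP)."""
    xi = encode(x, params.alphabet)
    yi = encode(y, params.alphabet)
    return float(
        sa_forward_scaled(
            xi,
            yi,
            params.q_match * params.p_m,
            params.q_insertion * params.p_i,
            params.q_deletion * params.p_d,
        )
    )


def sa_llr(params: SAParams, x: str, y: str) -> float:
    """Log-likelihood ratio of joint versus background generation."""
    xi = encode(x, params.alphabet)
    yi = encode(y, params.alphabet)
    bg = float(np.log(params.px_background[xi]).sum()) + float(
        np.log(params.py_background[yi]).sum()
    )
    return sa_joint_probability(params, x, y) - bg


# ---------------------------------------------------------------------------
# Samplers
# ---------------------------------------------------------------------------


def sample_hmm_pair(params: HMMParams, T: int, rng_seed) -> SequencePair:
    """Draw (x, y, hidden states): first the hidden chain, then emissions."""
    if T < 1:
        raise ValueError("T must be >= 1")
    rng = _as_rng(rng_seed)
    nh = params.n_hidden
    states = np.empty(T, dtype=np.int64)
    cum_trans = np.cumsum(params.p_trans, axis=1)
    states[0] = min(
        int(np.searchsorted(np.cumsum(params.p_init), rng.random(), side="right")),
        nh - 1,
    )
    for t in range(1, T):
        states[t] = min(
            int(np.searchsorted(cum_trans[states[t - 1]], rng.random(), side="right")),
            nh - 1,
        )
    na, nb = len(params.obs_alphabet_x), len(params.obs_alphabet_y)
    cum_emit = np.cumsum(params.p_emit.reshape(na * nb, nh), axis=0)
    u = rng.random(T)
    flat = np.empty(T, dtype=np.int64)
    for h in range(nh):
        mask = states == h
        flat[mask] = np.searchsorted(cum_emit[:, h], u[mask], side="right")
    np.clip(flat, 0, na * nb - 1, out=flat)
    xs, ys = np.divmod(flat, nb)
    x = "".join(params.obs_alphabet_x[i] for i in xs)
    y = "".join(params.obs_alphabet_y[i] for i in ys)
    return SequencePair(x=x, y=y, latent=tuple(params.hidden_alphabet[h] for h in states))


def sample_sa_pair(params: SAParams, S: int, rng_seed) -> SequencePair:
    """Draw a pair from the SA model: latent events i.i.d., then emissions,
    then strip gaps from the pre-sequences."""
    if S < 0:
        raise ValueError("S must be >= 0")
    rng = _as_rng(rng_seed)
    q = np.array([params.q_match, params.q_insertion, params.q_deletion])
    events = rng.choice(3, size=S, p=q)  # 0=m, 1=i, 2=d
    n = len(params.alphabet)
    u = rng.random(S)
    emit = np.empty(S, dtype=np.int64)
    for ev, cum, top in (
        (0, np.cumsum(params.p_m.ravel()), n * n),
        (1, np.cumsum(params.p_i), n),
        (2, np.cumsum(params.p_d), n),
    ):
        mask = events == ev
        emit[mask] = np.minimum(
            np.searchsorted(cum, u[mask], side="right"), top - 1
        )
    xbar, ybar, lat = [], [], []
    for ev, e in zip(events, emit):
        if ev == 0:
            a, b = divmod(int(e), n)
            xbar.append(params.alphabet[a])
            ybar.append(params.alphabet[b])
            lat.append("m")
        elif ev == 1:
            xbar.append("-")
            ybar.append(params.alphabet[int(e)])
            lat.append("i")
        else:
            xbar.append(params.alphabet[int(e)])
            ybar.append("-")
            lat.append("d")
    xbar_s, ybar_s = "".join(xbar), "".join(ybar)
    return SequencePair(
        x=xbar_s.replace("-", ""),
        y=ybar_s.replace("-", ""),
        latent="".join(lat),
        xbar=xbar_s,
        ybar=ybar_s,
    )
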