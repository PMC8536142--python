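"""Zero- and first-order Markov reference models.

Reference spectra are built from simulated random sequences; replicate
ensembles provide the spread used for significance referencing. First-order
models are parameterized by a target G+C content with a strand-symmetric
stationary distribution (p(A)=p(T), p(C)=p(G)) and an optional homopolymer
persistence that adds genuine dinucleotide structure on top of the base
composition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .kmers import BASES, Spectrum, compute_spectrum

try:  # pragma: no cover - exercised implicitly wherever available
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

_PROB_TOL = 1e-12


@dataclass(frozen=True)
class MarkovModel:
    """order 0: i.i.d. base draws; order 1: stationary chain over ACGT."""

    order: int
    base_probs: np.ndarray | None = None  # order 0
    transition: np.ndarray | None = None  # order 1, rows = current base
    initial: np.ndarray | None = None  # order 1 start distribution

    def __post_init__(self) -> None:
        if self.order not in (0, 1):
            raise ValueError("order must be 0 or 1")
        if self.order == 0:
            p = np.asarray(self.base_probs, dtype=float)
            if p.shape != (4,) or np.any(p < 0) or abs(p.sum() - 1) > _PROB_TOL:
                raise ValueError("base_probs must be a length-4 distribution")
            object.__setattr__(self, "base_probs", p)
        else:
            t = np.asarray(self.transition, dtype=float)
            if t.shape != (4, 4) or np.any(t < 0):
                raise ValueError("transition must be a nonnegative 4x4 matrix")
            if np.any(np.abs(t.sum(axis=1) - 1) > _PROB_TOL):
                raise ValueError("transition rows must sum to 1")
            init = self.initial
            if init is None:
                init = stationary_distribution(t)
            init = np.asarray(init, dtype=float)
            if init.shape != (4,) or np.any(init < 0) or abs(init.sum() - 1) > _PROB_TOL:
                raise ValueError("initial must be a length-4 distribution")
            object.__setattr__(self, "transition", t)
            object.__setattr__(self, "initial", init)

    @property
    def stationary(self) -> np.ndarray:
        if self.order == 0:
            return self.base_probs
        return stationary_distribution(self.transition)

    @property
    def gc_content(self) -> float:
        """G+C fraction of the stationary distribution."""
        pi = self.stationary
        return float(pi[1] + pi[2])

    @classmethod
    def order0(cls, gc: float) -> "MarkovModel":
        """Zero-order model with strand-symmetric base probabilities."""
        if not 0 < gc < 1:
            raise ValueError("gc must be in (0, 1)")
        at = (1 - gc) / 2
        s = gc / 2
        return cls(order=0, base_probs=np.array([at, s, s, at]))

    @classmethod
    def order1_gc(cls, gc: float, persistence: float = 0.02) -> "MarkovModel":
        """First-order model with target G+C and homopolymer persistence.

        Rows are ``(1 - rho) * pi + rho * I`` so the stationary distribution
        is exactly ``pi``; ``persistence`` (rho) > 0 yields mild same-base
        runs, giving the spectra non-trivial structure at every G+C level.
        """
        if not 0 <= persistence < 1:
            raise ValueError("persistence must be in [0, 1)")
        pi = cls.order0(gc).base_probs
        t = (1 - persistence) * np.tile(pi, (4, 1)) + persistence * np.eye(4)
        return cls(order=1, transition=t, initial=pi)


def stationary_distribution(transition: np.ndarray) -> np.ndarray:
    """Left eigenvector of the transition matrix for eigenvalue 1."""
    w, v = np.linalg.eig(transition.T)
    i = int(np.argmin(np.abs(w - 1)))
    pi = np.real(v[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()


if _HAVE_NUMBA:

    @njit(cache=True)
    def _chain_kernel(cum: np.ndarray, start: int, u: np.ndarray) -> np.ndarray:
        out = np.empty(u.size, dtype=np.int8)
        state = start
        for i in range(u.size):
            row = cum[state]
            ui = u[i]
            nxt = 0
            while row[nxt] <= ui:
                nxt += 1
            out[i] = nxt
            state = nxt
        return out


def _chain_fallback(cum: np.ndarray, start: int, u: np.ndarray) -> np.ndarray:
    # candidate next state per position for each possible current state,
    # then a cheap sequential pick
    cand = np.empty((4, u.size), dtype=np.int8)
    for s in range(4):
        cand[s] = np.searchsorted(cum[s], u, side="right").astype(np.int8)
    out = np.empty(u.size, dtype=np.int8)
    state = start
    rows = [cand[s].tolist() for s in range(4)]
    for i in range(u.size):
        state = rows[state][i]
        out[i] = state
    return out


def simulate_sequence(
    model: MarkovModel, length: int, seed: int | np.random.Generator
) -> str:
    """Simulate ``length`` bases; identical seed+model+length is reproducible."""
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lut = np.frombuffer("ACGT".encode(), dtype=np.uint8)
    if model.order == 0:
        states = rng.choice(4, size=length, p=model.base_probs).astype(np.int8)
    else:
        u = rng.random(length)
        init_cum = np.cumsum(model.initial)
        start = int(np.searchsorted(init_cum, u[0], side="right"))
        start = min(start, 3)
        cum = np.cumsum(model.transition, axis=1)
        cum[:, 3] = 1.0 + 1e-12  # guard against u == row sum
        if length == 1:
            states = np.array([start], dtype=np.int8)
        else:
            kernel = _chain_kernel if _HAVE_NUMBA else _chain_fallback
            rest = kernel(cum, start, u[1:])
            states = np.concatenate(([np.int8(start)], rest))
    return lut[states].tobytes().decode("ascii")


def word_probabilities(model: MarkovModel, k: int) -> np.ndarray:
    """P(w) for all 4^k words under the model (stationary start for order 1)."""
    n = 4**k
    idx = np.arange(n, dtype=np.int64)
    probs = np.ones(n, dtype=float)
    prev = None
    for j in range(k):
        digit = (idx >> (2 * (k - 1 - j))) & 3
        if j == 0:
            probs *= (model.base_probs if model.order == 0 else model.initial)[digit]
        elif model.order == 0:
            probs *= model.base_probs[digit]
        else:
            probs *= model.transition[prev, digit]
        prev = digit
    return probs


def expected_spectrum(model: MarkovModel, k: int, length: int) -> Spectrum:
    """Expected (fractional) counts: (length - k + 1) * P(w)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    windows = max(length - k + 1, 0)
    probs = word_probabilities(model, k)
    return Spectrum(
        k=k,
        counts=windows * probs,
        total_windows=float(windows),
        label=f"expected(order={model.order},gc={model.gc_content:.3f})",
    )


@dataclass
class ReferenceEnsemble:
    """Replicate spectra from one model, for mean +/- sd referencing."""

    model: MarkovModel
    k: int
    length: int
    spectra: list[Spectrum] = field(default_factory=list)

    def __post_init__(self) -> None:
        for s in self.spectra:
            if s.k != self.k:
                raise ValueError("all replicates must share k")

    @property
    def n_replicates(self) -> int:
        return len(self.spectra)

    def replicate_pairs(self) -> list[tuple[Spectrum, Spectrum]]:
        out = []
        for i in range(len(self.spectra)):
            for j in range(i + 1, len(self.spectra)):
                out.append((self.spectra[i], self.spectra[j]))
        return out

    def pairwise_statistic(
        self, func: Callable[[Spectrum, Spectrum], float]
    ) -> tuple[float, float, list[float]]:
        """Evaluate ``func`` on every replicate pair; return mean, sd, values."""
        values = [float(func(x, y)) for x, y in self.replicate_pairs()]
        if not values:
            raise ValueError("ensemble needs >= 2 replicates")
        arr = np.asarray(values)
        sd = float(arr.std(ddof=1)) if len(values) > 1 else 0.0
        return float(arr.mean()), sd, values


def build_reference_ensemble(
    model: MarkovModel,
    k: int,
    length: int,
    n_replicates: int = 5,
    seed: int = 0,
) -> ReferenceEnsemble:
    """Simulate replicate sequences and store their spectra.

    A master seed spawns one child stream per replicate, so replicate i is
    reproducible independently of n_replicates.
    """
    if n_replicates < 2:
        raise ValueError("n_replicates must be >= 2")
    children = np.random.SeedSequence(seed).spawn(n_replicates)
    spectra = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        seq = simulate_sequence(model, length, rng)
        spectra.append(compute_spectrum([seq], k, label=f"ref{i}"))
    return ReferenceEnsemble(model=model, k=k, length=length, spectra=spectra)
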