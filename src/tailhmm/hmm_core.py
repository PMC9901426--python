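"""The two-state tail/non-tail hidden Markov model.

The model is trained purely by frequency counting on a labeled corpus:
the initial vector is the global state frequency, the transition matrix
counts adjacent within-genome state pairs, and each state's emission
distribution counts the Pfam symbols observed in that state (``NOHIT``
is a first-class symbol, so unannotated proteins still get a posterior).
Decoding is exact forward-backward with per-position scaling, giving
each protein P(tail | whole genome).  Viterbi is available as a second
decoder but posteriors are the primary output because they feed the ROC.

Unseen symbols: each state reserves a smoothing mass ``epsilon``
(default 1e-4) emitted by any symbol outside the training alphabet, and
observed-symbol probabilities are rescaled by (1 - epsilon).  This keeps
decoding finite on novel phages whose domains never occurred in
training.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

TAIL = "TAIL"
NONTAIL = "NONTAIL"
STATES = (TAIL, NONTAIL)
_IDX = {TAIL: 0, NONTAIL: 1}

DEFAULT_EPSILON = 1e-4
DEFAULT_TAU = 0.5


@dataclass
class TailHmm:
    """Two-state HMM with per-state categorical emissions over symbols.

    ``pi`` and rows of ``A`` are ordered (TAIL, NONTAIL).  ``B[state]``
    maps symbol -> probability; probabilities sum to (1 - epsilon) per
    state, the remaining epsilon being the mass of any unseen symbol.
    """

    pi: np.ndarray
    A: np.ndarray
    B: dict[str, dict[str, float]]
    alphabet: frozenset[str]
    epsilon: float = DEFAULT_EPSILON
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        self.A = np.asarray(self.A, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.pi.shape != (2,):
            raise ValueError("pi must be a length-2 vector")
        if self.A.shape != (2, 2):
            raise ValueError("A must be 2x2")
        if not 0 <= self.epsilon < 1:
            raise ValueError(f"epsilon must be in [0,1), got {self.epsilon}")
        if np.any(self.pi < 0) or np.any(self.A < 0):
            raise ValueError("probabilities must be >= 0")
        if abs(self.pi.sum() - 1.0) > 1e-12:
            raise ValueError(f"pi sums to {self.pi.sum()!r}, not 1")
        for i, s in enumerate(STATES):
            if abs(self.A[i].sum() - 1.0) > 1e-12:
                raise ValueError(f"A row {s} sums to {self.A[i].sum()!r}, not 1")
        for s in STATES:
            if s not in self.B:
                raise ValueError(f"missing emission distribution for state {s}")
            probs = self.B[s]
            if any(p < 0 for p in probs.values()):
                raise ValueError(f"negative emission probability in state {s}")
            total = sum(probs.values()) + self.epsilon
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"B[{s}] + epsilon sums to {total!r}, not 1"
                )

    def emission(self, state: str, symbol: str) -> float:
        """P(symbol | state); any symbol outside the alphabet emits epsilon."""
        if symbol in self.alphabet:
            return self.B[state].get(symbol, 0.0)
        return self.epsilon

    def emission_row(self, symbol: str) -> np.ndarray:
        return np.array([self.emission(s, symbol) for s in STATES])


@dataclass
class PosteriorTrack:
    """Per-protein posterior tail probabilities along one genome."""

    genome_id: str
    posteriors: np.ndarray  # P(TAIL | all observations), per ordinal
    calls: list[str] | None = None
    log_likelihood: float | None = None
    tau: float | None = None

    def __post_init__(self) -> None:
        self.posteriors = np.asarray(self.posteriors, dtype=float)
        if np.any(self.posteriors < -1e-12) or np.any(self.posteriors > 1 + 1e-12):
            raise ValueError("posteriors outside [0,1]")


def fit(
    corpus: Iterable[Sequence[tuple[str, str]]],
    epsilon: float = DEFAULT_EPSILON,
    alpha: float = 0.0,
    pi_mode: str = "start",
    metadata: dict | None = None,
) -> TailHmm:
    """Train by frequency counting on per-genome (symbol, state) sequences.

    A counts adjacent within-genome state pairs (never across genome
    boundaries); B counts symbols per state.  pi counts genome-start
    states by default (``pi_mode="start"``), which is the distribution a
    Markov-chain generator restarts from at every genome, so fitting
    data simulated from a known model recovers that model's pi;
    ``pi_mode="global"`` instead counts every position, i.e. the overall
    tail fraction of the corpus.  ``alpha`` adds optional Laplace
    pseudocounts to emissions (default 0 = pure maximum likelihood).
    ``epsilon=0`` disables unseen-symbol smoothing, leaving pure count
    ratios; decoding then fails on symbols outside the training
    alphabet.

    Raises if either state has zero positions or if no genome has >= 2
    proteins (no transitions to count).
    """
    if pi_mode not in ("start", "global"):
        raise ValueError(f"pi_mode must be 'start' or 'global', got {pi_mode!r}")
    state_counts = np.zeros(2)
    start_counts = np.zeros(2)
    trans_counts = np.zeros((2, 2))
    emit_counts: dict[str, dict[str, float]] = {TAIL: {}, NONTAIL: {}}
    alphabet: set[str] = set()
    n_genomes = 0

    for genome in corpus:
        genome = list(genome)
        if not genome:
            continue
        n_genomes += 1
        prev = None
        for symbol, state in genome:
            if state not in _IDX:
                raise ValueError(f"unknown state {state!r}")
            i = _IDX[state]
            state_counts[i] += 1
            emit_counts[state][symbol] = emit_counts[state].get(symbol, 0.0) + 1.0
            alphabet.add(symbol)
            if prev is None:
                start_counts[i] += 1
            else:
                trans_counts[_IDX[prev], i] += 1
            prev = state

    if n_genomes == 0:
        raise ValueError("empty corpus")
    if np.any(state_counts == 0):
        missing = STATES[int(np.argmin(state_counts))]
        raise ValueError(f"state {missing} has zero positions; cannot normalize")
    if np.any(trans_counts.sum(axis=1) == 0):
        raise ValueError(
            "no transitions observed from one state (corpus of "
            "single-protein genomes?); cannot normalize A"
        )

    if pi_mode == "start":
        pi = start_counts / start_counts.sum()
    else:
        pi = state_counts / state_counts.sum()
    A = trans_counts / trans_counts.sum(axis=1, keepdims=True)

    B: dict[str, dict[str, float]] = {}
    for s in STATES:
        counts = dict(emit_counts[s])
        if alpha > 0:
            for sym in alphabet:
                counts[sym] = counts.get(sym, 0.0) + alpha
        total = sum(counts.values())
        B[s] = {sym: (c / total) * (1.0 - epsilon) for sym, c in counts.items()}

    meta = dict(metadata or {})
    meta.setdefault("n_genomes", n_genomes)
    meta.setdefault("n_positions", int(state_counts.sum()))
    return TailHmm(pi=pi, A=A, B=B, alphabet=frozenset(alphabet),
                   epsilon=epsilon, metadata=meta)


def _forward_backward(model: TailHmm, observations: Sequence[str]):
    """Scaled forward-backward; returns (posteriors[n,2], log-likelihood)."""
    n = len(observations)
    E = np.array([model.emission_row(o) for o in observations])  # (n, 2)
    alpha = np.zeros((n, 2))
    scale = np.zeros(n)

    alpha[0] = model.pi * E[0]
    scale[0] = alpha[0].sum()
    if scale[0] == 0:
        raise ValueError("zero-probability observation at position 0")
    alpha[0] /= scale[0]
    for t in range(1, n):
        alpha[t] = (alpha[t - 1] @ model.A) * E[t]
        scale[t] = alpha[t].sum()
        if scale[t] == 0:
            raise ValueError(f"zero-probability observation at position {t}")
        alpha[t] /= scale[t]

    beta = np.zeros((n, 2))
    beta[-1] = 1.0
    for t in range(n - 2, -1, -1):
        beta[t] = model.A @ (E[t + 1] * beta[t + 1])
        beta[t] /= scale[t + 1]

    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)
    return gamma, float(np.log(scale).sum())


def posterior_decode(model: TailHmm, observations: Sequence[str],
                     genome_id: str = "") -> PosteriorTrack:
    """Exact per-position posteriors P(state_i = TAIL | o_1..o_n).

    Per-position scaling keeps the recursion stable for genomes of any
    length.  Symbols outside the model alphabet emit the epsilon mass.
    """
    if len(observations) == 0:
        raise ValueError("observation sequence is empty")
    gamma, loglik = _forward_backward(model, observations)
    return PosteriorTrack(genome_id=genome_id, posteriors=gamma[:, 0],
                          log_likelihood=loglik)


def backward_log_likelihood(model: TailHmm, observations: Sequence[str]) -> float:
    """Sequence log-likelihood from an independent backward-only pass.

    Used to cross-check the forward pass; computed in plain probability
    space with its own scaling.
    """
    n = len(observations)
    E = np.array([model.emission_row(o) for o in observations])
    beta = np.ones(2)
    loglik = 0.0
    for t in range(n - 1, 0, -1):
        beta = model.A @ (E[t] * beta)
        s = beta.sum()
        beta /= s
        loglik += math.log(s)
    final = float((model.pi * E[0] * beta).sum())
    return loglik + math.log(final)


def call_tails(track: PosteriorTrack, tau: float = DEFAULT_TAU) -> PosteriorTrack:
    """Fill threshold calls: TAIL iff posterior >= tau."""
    if not 0.0 <= tau <= 1.0:
        raise ValueError(f"tau must be in [0,1], got {tau}")
    track.calls = [TAIL if p >= tau else NONTAIL for p in track.posteriors]
    track.tau = tau
    return track


def viterbi_decode(model: TailHmm, observations: Sequence[str]) -> list[str]:
    """Most-probable joint state path (optional second decoder)."""
    if len(observations) == 0:
        raise ValueError("observation sequence is empty")
    n = len(observations)
    with np.errstate(divide="ignore"):
        logA = np.log(model.A)
        logpi = np.log(model.pi)
        logE = np.log(np.array([model.emission_row(o) for o in observations]))
    delta = np.zeros((n, 2))
    back = np.zeros((n, 2), dtype=int)
    delta[0] = logpi + logE[0]
    for t in range(1, n):
        cand = delta[t - 1][:, None] + logA
        back[t] = np.argmax(cand, axis=0)
        delta[t] = cand[back[t], [0, 1]] + logE[t]
    path = [int(np.argmax(delta[-1]))]
    for t in range(n - 1, 0, -1):
        path.append(int(back[t, path[-1]]))
    return [STATES[i] for i in reversed(path)]


def save_model(model: TailHmm, path: str | Path) -> None:
    """Write the model as JSON, preserving full float precision."""
    doc = {
        "pi": {s: model.pi[i] for i, s in enumerate(STATES)},
        "A": {s: {t: model.A[i, j] for j, t in enumerate(STATES)}
              for i, s in enumerate(STATES)},
        "B": {s: dict(sorted(model.B[s].items())) for s in STATES},
        "alphabet": sorted(model.alphabet),
        "epsilon": model.epsilon,
        "metadata": model.metadata,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
        fh.write("\n")


def load_model(path: str | Path) -> TailHmm:
    """Read and re-validate a model JSON; invariant violations raise."""
    with open(path) as fh:
        doc = json.load(fh)
    try:
        pi = np.array([doc["pi"][s] for s in STATES])
        A = np.array([[doc["A"][s][t] for t in STATES] for s in STATES])
        B = {s: {k: float(v) for k, v in doc["B"][s].items()} for s in STATES}
        model = TailHmm(
            pi=pi, A=A, B=B,
            alphabet=frozenset(doc["alphabet"]),
            epsilon=float(doc["epsilon"]),
            metadata=doc.get("metadata", {}),
        )
    except KeyError as exc:
        raise ValueError(f"model file missing field: {exc}") from exc
    return model
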