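"""Synthetic phage corpora from a known two-state Markov process.

Hidden tail/non-tail states are drawn from a Markov chain (the default
parameters are the frequencies a large curated phage corpus yields:
initial vector (0.2039, 0.7961) and transition rows (0.1712, 0.8288) /
(0.0203, 0.9797)); each state emits a Pfam-style symbol from its own
alphabet, with a per-state no-hit rate replacing the symbol by ``NOHIT``.
Tail-state proteins receive product strings built from tail keywords so
the keyword labeler recovers the true states, which closes the loop for
end-to-end testing: training, decoding, clustering and evaluation can
all be exercised without any download.

The generator also writes the same GenBank and hmmscan-tabular dialects
the readers consume, plus a truth TSV (genome_id, ordinal, state).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord
from Bio import SeqIO

from tailhmm.io_formats import NOHIT
from tailhmm.hmm_core import NONTAIL, TAIL

#: Default hidden-chain parameters (tail-state frequency and persistence
#: as estimated from a large curated phage training corpus).
DEFAULT_PI = (0.2039, 0.7961)
DEFAULT_A = ((0.1712, 0.8288), (0.0203, 0.9797))

TAIL_PRODUCTS = (
    "tail fibre protein",
    "tail fiber protein",
    "tail tube protein",
    "tail sheath protein",
    "tape measure protein",
    "baseplate wedge protein",
    "tail spike protein",
    "baseplate hub subunit",
    "tail needle protein",
)

NONTAIL_PRODUCTS = (
    "major capsid protein",
    "portal protein",
    "DNA polymerase",
    "holin",
    "endolysin",
    "integrase",
    "single-stranded DNA binding protein",
    "hypothetical protein",
    "HNH endonuclease",
)


def _default_tail_alphabet() -> tuple[str, ...]:
    return tuple(f"PF9{i:04d}" for i in range(30))


def _default_nontail_alphabet() -> tuple[str, ...]:
    return tuple(f"PF1{i:04d}" for i in range(90))


@dataclass
class GeneratorSpec:
    """Study conditions for one synthetic corpus.

    Genome lengths are drawn uniformly from ``length_range`` (inclusive).
    ``nohit_rate`` gives, per state, the probability that a protein has
    no retained domain hit; roughly a third of real phage proteins lack
    a Pfam hit, hence the defaults.  Emission weights default to uniform
    over each state's alphabet.
    """

    n_genomes: int = 100
    length_range: tuple[int, int] = (30, 80)
    pi: tuple[float, float] = DEFAULT_PI
    A: tuple[tuple[float, float], tuple[float, float]] = DEFAULT_A
    tail_alphabet: tuple[str, ...] = field(default_factory=_default_tail_alphabet)
    nontail_alphabet: tuple[str, ...] = field(default_factory=_default_nontail_alphabet)
    tail_weights: tuple[float, ...] | None = None
    nontail_weights: tuple[float, ...] | None = None
    nohit_rate: tuple[float, float] = (0.3, 0.3)  # (tail, nontail)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genomes < 1:
            raise ValueError("n_genomes must be >= 1")
        lo, hi = self.length_range
        if not 1 <= lo <= hi:
            raise ValueError(f"bad length_range {self.length_range}")
        pi = np.asarray(self.pi, dtype=float)
        A = np.asarray(self.A, dtype=float)
        if pi.shape != (2,) or abs(pi.sum() - 1) > 1e-12 or np.any(pi < 0):
            raise ValueError("pi must be a length-2 probability vector")
        if A.shape != (2, 2) or np.any(np.abs(A.sum(axis=1) - 1) > 1e-12) or np.any(A < 0):
            raise ValueError("A must be 2x2 row-stochastic")
        for name, alphabet, weights in (
            ("tail", self.tail_alphabet, self.tail_weights),
            ("nontail", self.nontail_alphabet, self.nontail_weights),
        ):
            if not alphabet:
                raise ValueError(f"{name} alphabet is empty")
            if weights is not None:
                w = np.asarray(weights, dtype=float)
                if w.shape != (len(alphabet),) or abs(w.sum() - 1) > 1e-12 or np.any(w < 0):
                    raise ValueError(f"{name} weights must sum to 1 over the alphabet")
        for r in self.nohit_rate:
            if not 0 <= r <= 1:
                raise ValueError(f"nohit_rate entries must be in [0,1], got {r}")


@dataclass
class SyntheticCorpus:
    """Per-genome (symbol, state) sequences plus product strings."""

    spec: GeneratorSpec
    sequences: dict[str, list[tuple[str, str]]]  # genome_id -> [(symbol, state)]
    products: dict[str, list[str]]  # genome_id -> product per ordinal

    @property
    def genome_ids(self) -> list[str]:
        return sorted(self.sequences)

    def observations(self) -> dict[str, list[str]]:
        return {g: [s for s, _ in seq] for g, seq in self.sequences.items()}

    def states(self) -> dict[str, list[str]]:
        return {g: [st for _, st in seq] for g, seq in self.sequences.items()}


def generate(spec: GeneratorSpec) -> SyntheticCorpus:
    """Draw a corpus from the spec's Markov chain; reproducible from seed."""
    rng = np.random.default_rng(spec.seed)
    pi = np.asarray(spec.pi, dtype=float)
    A = np.asarray(spec.A, dtype=float)
    alphabets = {TAIL: list(spec.tail_alphabet), NONTAIL: list(spec.nontail_alphabet)}
    weights = {
        TAIL: spec.tail_weights,
        NONTAIL: spec.nontail_weights,
    }
    nohit = {TAIL: spec.nohit_rate[0], NONTAIL: spec.nohit_rate[1]}

    sequences: dict[str, list[tuple[str, str]]] = {}
    products: dict[str, list[str]] = {}
    width = len(str(spec.n_genomes))
    for g in range(spec.n_genomes):
        gid = f"SYNPHG{g + 1:0{width}d}"
        n = int(rng.integers(spec.length_range[0], spec.length_range[1] + 1))
        seq: list[tuple[str, str]] = []
        prods: list[str] = []
        state_idx = int(rng.choice(2, p=pi))
        for i in range(n):
            if i > 0:
                state_idx = int(rng.choice(2, p=A[state_idx]))
            state = TAIL if state_idx == 0 else NONTAIL
            if rng.random() < nohit[state]:
                symbol = NOHIT
            else:
                symbol = str(rng.choice(alphabets[state], p=weights[state]))
            templates = TAIL_PRODUCTS if state == TAIL else NONTAIL_PRODUCTS
            prods.append(str(templates[int(rng.integers(len(templates)))]))
            seq.append((symbol, state))
        sequences[gid] = seq
        products[gid] = prods
    return SyntheticCorpus(spec=spec, sequences=sequences, products=products)


def true_model(spec: GeneratorSpec, epsilon: float = 1e-4):
    """The exact TailHmm the generator draws from.

    Emissions fold in the per-state no-hit rate: P(NOHIT|state) is the
    state's nohit_rate and each alphabet symbol gets (1 - nohit_rate)
    times its weight, rescaled by (1 - epsilon) like a fitted model.
    """
    from tailhmm.hmm_core import TailHmm

    B: dict[str, dict[str, float]] = {}
    for state, alphabet, weights, rate in (
        (TAIL, spec.tail_alphabet, spec.tail_weights, spec.nohit_rate[0]),
        (NONTAIL, spec.nontail_alphabet, spec.nontail_weights, spec.nohit_rate[1]),
    ):
        w = np.full(len(alphabet), 1.0 / len(alphabet)) if weights is None \
            else np.asarray(weights, dtype=float)
        probs = {sym: float((1.0 - rate) * wi) * (1.0 - epsilon)
                 for sym, wi in zip(alphabet, w)}
        probs[NOHIT] = rate * (1.0 - epsilon)
        B[state] = probs
    alphabet = frozenset(spec.tail_alphabet) | frozenset(spec.nontail_alphabet) | {NOHIT}
    return TailHmm(pi=np.asarray(spec.pi, float), A=np.asarray(spec.A, float),
                   B=B, alphabet=alphabet, epsilon=epsilon,
                   metadata={"source": "generator"})


# --- fixture writers: the same dialects io_formats reads -----------------

_GENE_NT = 900  # nominal CDS length; only coordinates matter downstream
_GAP_NT = 100


def write_genbank(corpus: SyntheticCorpus, path: str | Path) -> None:
    """Write the corpus as a multi-record GenBank flat file."""
    rng = np.random.default_rng(corpus.spec.seed + 1)
    records = []
    for gid in corpus.genome_ids:
        n = len(corpus.sequences[gid])
        length = n * (_GENE_NT + _GAP_NT) + _GAP_NT
        seq = Seq("".join(rng.choice(list("ACGT"), size=length)))
        rec = SeqRecord(seq, id=gid, name=gid, description="synthetic phage genome")
        rec.annotations["molecule_type"] = "DNA"
        for i, product in enumerate(corpus.products[gid]):
            start = _GAP_NT + i * (_GENE_NT + _GAP_NT)
            feat = SeqFeature(
                FeatureLocation(start, start + _GENE_NT, strand=1),
                type="CDS",
                qualifiers={
                    "protein_id": [f"{gid}_p{i:03d}"],
                    "product": [product],
                },
            )
            rec.features.append(feat)
        records.append(rec)
    SeqIO.write(records, str(path), "genbank")


_DOMTBL_HEADER = (
    "#                                                               "
    "--- full sequence --- -------------- this domain -------------\n"
    "# target name        accession   tlen query name           accession"
    "   qlen   E-value  score  bias   #  of  c-Evalue  i-Evalue  score  bias\n"
)


def write_domtbl(corpus: SyntheticCorpus, path: str | Path) -> None:
    """Write hmmscan-style per-domain rows for every non-NOHIT protein.

    Primary hits get e-values well inside the default threshold; with
    probability 0.2 a second, weaker same-state hit is added so the
    smallest-e-value assignment rule is exercised on realistic input.
    """
    rng = np.random.default_rng(corpus.spec.seed + 2)
    alphabets = {
        TAIL: list(corpus.spec.tail_alphabet),
        NONTAIL: list(corpus.spec.nontail_alphabet),
    }
    with open(path, "w") as fh:
        fh.write(_DOMTBL_HEADER)
        for gid in corpus.genome_ids:
            for i, (symbol, state) in enumerate(corpus.sequences[gid]):
                if symbol == NOHIT:
                    continue
                pid = f"{gid}_p{i:03d}"
                e1 = 10.0 ** rng.uniform(-30, -6)
                score1 = rng.uniform(40, 300)
                fh.write(_domtbl_row(symbol, pid, e1, score1))
                if rng.random() < 0.2:
                    other = str(rng.choice(alphabets[state]))
                    e2 = 10.0 ** rng.uniform(-5.9, -4.1)  # weaker but retained
                    fh.write(_domtbl_row(other, pid, e2, rng.uniform(10, 39)))


def _domtbl_row(accession: str, protein_id: str, e_value: float, score: float) -> str:
    name = f"{accession}_dom"
    return (
        f"{name:<20} {accession:<11} 200 {protein_id:<20} -            300 "
        f"{e_value:9.2g} {score:6.1f}   0.0   1   1 {e_value:9.2g} {e_value:9.2g} "
        f"{score:6.1f}   0.0 1 200 1 200 1 200 0.95 synthetic domain\n"
    )


def write_truth(corpus: SyntheticCorpus, path: str | Path) -> None:
    """Truth TSV: genome_id, ordinal, state."""
    with open(path, "w") as fh:
        fh.write("genome_id\tordinal\tstate\n")
        for gid in corpus.genome_ids:
            for i, (_, state) in enumerate(corpus.sequences[gid]):
                fh.write(f"{gid}\t{i}\t{state}\n")


def read_truth(path: str | Path) -> dict[str, list[str]]:
    truth: dict[str, list[str]] = {}
    with open(path) as fh:
        fh.readline()
        for line in fh:
            gid, ordinal, state = line.rstrip("\n").split("\t")
            truth.setdefault(gid, []).append(state)
    return truth
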