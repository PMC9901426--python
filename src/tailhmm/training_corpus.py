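"""Labeled-corpus construction: keyword tagging and domain vocabularies.

Ground-truth tail/non-tail states come from the NCBI product annotation:
a protein is tail-state iff its product string contains one of ten
tail keywords (case-insensitive substring match).  Keyword labels are
then supplemented by domain evidence: a keyword-negative protein whose
assigned Pfam symbol belongs to the tail vocabulary is promoted to the
tail state.  Vocabularies are kept disjoint -- a symbol ever seen on a
tail-state protein is a tail domain and excluded from the non-tail set.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from tailhmm.io_formats import NOHIT, DomainObservation, ProteinRecord

#: The ten tail keywords.  "fiber" is accepted alongside "fibre" because
#: both spellings occur in NCBI product strings.
DEFAULT_KEYWORDS = (
    "tail",
    "tube",
    "sheath",
    "fibre",
    "fiber",
    "spike",
    "baseplate",
    "needle",
    "tape",
    "Terms",
    "TermL",
)

#: Opt-in aliases for the terminase keywords (off by default).
TERMINASE_ALIASES = ("terminase small", "terminase large")

STATE_TAIL = "TAIL"
STATE_NONTAIL = "NONTAIL"

EVIDENCE_KEYWORD = "KEYWORD"
EVIDENCE_DOMAIN = "DOMAIN"
EVIDENCE_NONE = "NONE"


@dataclass(frozen=True)
class TailLabel:
    protein_id: str
    state: str  # TAIL | NONTAIL
    evidence: str  # KEYWORD | DOMAIN | NONE

    def __post_init__(self) -> None:
        if self.state not in (STATE_TAIL, STATE_NONTAIL):
            raise ValueError(f"bad state {self.state!r}")
        if self.evidence not in (EVIDENCE_KEYWORD, EVIDENCE_DOMAIN, EVIDENCE_NONE):
            raise ValueError(f"bad evidence {self.evidence!r}")
        if self.evidence == EVIDENCE_NONE and self.state == STATE_TAIL:
            raise ValueError("TAIL label requires KEYWORD or DOMAIN evidence")


@dataclass(frozen=True)
class DomainVocabulary:
    tail_domains: frozenset[str]
    nontail_domains: frozenset[str]

    def __post_init__(self) -> None:
        shared = self.tail_domains & self.nontail_domains
        if shared:
            raise ValueError(f"vocabularies overlap: {sorted(shared)[:5]}")


def label_by_keyword(
    product: str, keywords: Sequence[str] = DEFAULT_KEYWORDS
) -> str:
    """TAIL iff any keyword occurs case-insensitively in the product string."""
    if not keywords:
        raise ValueError("keyword list must be non-empty")
    low = product.lower()
    return STATE_TAIL if any(k.lower() in low for k in keywords) else STATE_NONTAIL


def label_proteins(
    proteins: Iterable[ProteinRecord], keywords: Sequence[str] = DEFAULT_KEYWORDS
) -> dict[str, TailLabel]:
    """Keyword-label every protein; returns a map protein_id -> TailLabel."""
    labels: dict[str, TailLabel] = {}
    for p in proteins:
        state = label_by_keyword(p.product, keywords)
        evidence = EVIDENCE_KEYWORD if state == STATE_TAIL else EVIDENCE_NONE
        labels[p.protein_id] = TailLabel(p.protein_id, state, evidence)
    return labels


def build_vocabulary(
    labels: Mapping[str, TailLabel], observations: Iterable[DomainObservation]
) -> DomainVocabulary:
    """Partition observed symbols into tail and non-tail vocabularies.

    Tail domains are all non-NOHIT symbols seen on TAIL-labeled proteins.
    Non-tail domains are symbols seen on NONTAIL proteins that never occur
    on a TAIL protein; the exclusion enforces disjointness (the symbol-space
    analogue of screening candidate non-tail domains for sequence
    similarity to tail profiles).
    """
    obs = list(observations)
    if not obs or not labels:
        raise ValueError("empty corpus")
    tail: set[str] = set()
    seen_nontail: set[str] = set()
    for o in obs:
        if o.symbol == NOHIT:
            continue
        label = labels.get(o.protein_id)
        if label is None:
            raise ValueError(f"no label for protein {o.protein_id!r}")
        if label.state == STATE_TAIL:
            tail.add(o.symbol)
        else:
            seen_nontail.add(o.symbol)
    return DomainVocabulary(frozenset(tail), frozenset(seen_nontail - tail))


def propagate_domain_labels(
    labels: Mapping[str, TailLabel],
    observations: Iterable[DomainObservation],
    vocab: DomainVocabulary,
) -> dict[str, TailLabel]:
    """Promote keyword-negative proteins carrying a tail-vocabulary symbol.

    A NONTAIL-labeled protein whose symbol is in ``tail_domains`` becomes
    TAIL with DOMAIN evidence.  Keyword-positive proteins are never
    demoted, whatever their symbol.
    """
    out = dict(labels)
    for o in observations:
        label = out.get(o.protein_id)
        if label is None:
            continue
        if label.state == STATE_NONTAIL and o.symbol in vocab.tail_domains:
            out[o.protein_id] = TailLabel(o.protein_id, STATE_TAIL, EVIDENCE_DOMAIN)
    return out


def save_vocabulary(vocab: DomainVocabulary, path: str | Path) -> None:
    """Persist as two-column TSV (accession, state)."""
    with open(path, "w") as fh:
        for acc in sorted(vocab.tail_domains):
            fh.write(f"{acc}\t{STATE_TAIL}\n")
        for acc in sorted(vocab.nontail_domains):
            fh.write(f"{acc}\t{STATE_NONTAIL}\n")


def load_vocabulary(path: str | Path) -> DomainVocabulary:
    tail: set[str] = set()
    nontail: set[str] = set()
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            acc, state = line.rstrip("\n").split("\t")
            (tail if state == STATE_TAIL else nontail).add(acc)
    return DomainVocabulary(frozenset(tail), frozenset(nontail))


def load_keywords(path: str | Path) -> tuple[str, ...]:
    """Read a keyword list, one keyword per line, '#' comments allowed."""
    words = []
    with open(path) as fh:
        for line in fh:
            word = line.strip()
            if word and not word.startswith("#"):
                words.append(word)
    if not words:
        raise ValueError(f"no keywords in {path}")
    return tuple(words)
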