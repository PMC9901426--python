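"""Reading genomes and domain annotations; writing predictions.

Genomes come in as GenBank flat files (one ``ProteinRecord`` per CDS, in
genome order) or as protein FASTA.  Domain annotations come from hmmscan's
per-domain tabular output (``--domtblout``); each protein is then reduced
to exactly one observation symbol: the Pfam accession of its
smallest-e-value hit, or the reserved sentinel ``NOHIT`` when no hit
survives the e-value threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

logger = logging.getLogger(__name__)

#: Reserved observation symbol for proteins with no retained domain hit.
NOHIT = "NOHIT"

#: Default hmmscan e-value inclusion threshold.
DEFAULT_E_THRESHOLD = 1e-4

#: Conservative threshold for large uncurated catalogs.
CONSERVATIVE_E_THRESHOLD = 1e-10


@dataclass(frozen=True)
class ProteinRecord:
    """One CDS of one genome.

    ``ordinal`` is the 0-based position of the CDS along the genome and is
    the coordinate on which protein-spacing distances are measured.
    ``start``/``end`` are 1-based inclusive nucleotide coordinates when
    known.
    """

    protein_id: str
    genome_id: str
    ordinal: int
    product: str = ""
    start: int | None = None
    end: int | None = None
    strand: str | None = None
    aa_sequence: str | None = None

    def __post_init__(self) -> None:
        if self.ordinal < 0:
            raise ValueError(f"ordinal must be >= 0, got {self.ordinal}")
        if self.start is not None and self.end is not None and self.start > self.end:
            raise ValueError(
                f"start {self.start} > end {self.end} for {self.protein_id}"
            )


@dataclass(frozen=True)
class DomainHit:
    """A retained hmmscan hit of one profile against one protein."""

    protein_id: str
    domain_accession: str
    e_value: float
    bit_score: float

    def __post_init__(self) -> None:
        if self.e_value <= 0:
            raise ValueError(f"e_value must be > 0, got {self.e_value}")


@dataclass(frozen=True)
class DomainObservation:
    """The single symbol assigned to a protein (a Pfam accession or NOHIT)."""

    protein_id: str
    symbol: str


def read_genbank(path: str | Path) -> dict[str, list[ProteinRecord]]:
    """Read a GenBank flat file into per-genome protein lists.

    Each record in the file is one genome; each CDS feature becomes one
    ``ProteinRecord`` with ordinals following feature order.  Records with
    no CDS features are skipped with a warning.

    Parameters
    ----------
    path:
        GenBank flat file (may contain multiple records).

    Returns
    -------
    dict mapping genome_id -> list of ProteinRecord in ordinal order.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"GenBank file not found: {path}")
    if path.stat().st_size == 0:
        raise ValueError(f"GenBank file is empty: {path}")

    genomes: dict[str, list[ProteinRecord]] = {}
    for record in SeqIO.parse(str(path), "genbank"):
        genome_id = record.id if record.id and record.id != "<unknown id>" else record.name
        proteins: list[ProteinRecord] = []
        ordinal = 0
        for feat in record.features:
            if feat.type != "CDS":
                continue
            quals = feat.qualifiers
            protein_id = (
                quals.get("protein_id", [None])[0]
                or quals.get("locus_tag", [None])[0]
                or f"{genome_id}_{ordinal}"
            )
            product = quals.get("product", [""])[0] or ""
            translation = quals.get("translation", [None])[0]
            strand = None
            if feat.location is not None and feat.location.strand is not None:
                strand = "+" if feat.location.strand >= 0 else "-"
            start = end = None
            if feat.location is not None:
                start = int(feat.location.start) + 1  # GenBank 1-based inclusive
                end = int(feat.location.end)
            proteins.append(
                ProteinRecord(
                    protein_id=protein_id,
                    genome_id=genome_id,
                    ordinal=ordinal,
                    product=product,
                    start=start,
                    end=end,
                    strand=strand,
                    aa_sequence=translation,
                )
            )
            ordinal += 1
        if not proteins:
            logger.warning("genome %s has no CDS features; skipped", genome_id)
            continue
        genomes[genome_id] = proteins
    if not genomes:
        raise ValueError(f"no genomes with CDS features in {path}")
    return genomes


def read_fasta_proteins(path: str | Path, genome_id: str | None = None) -> dict[str, list[ProteinRecord]]:
    """Read a protein FASTA as one genome, ordinals in file order.

    The FASTA header token is the protein_id; the rest of the description
    line is kept as the product annotation.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"FASTA file not found: {path}")
    gid = genome_id or path.stem
    proteins = []
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta")):
        desc = rec.description
        product = desc[len(rec.id):].strip() if desc.startswith(rec.id) else desc
        proteins.append(
            ProteinRecord(
                protein_id=rec.id,
                genome_id=gid,
                ordinal=i,
                product=product,
                aa_sequence=str(rec.seq),
            )
        )
    if not proteins:
        raise ValueError(f"no sequences in {path}")
    return {gid: proteins}


def read_domtbl(path: str | Path, e_threshold: float = DEFAULT_E_THRESHOLD) -> list[DomainHit]:
    """Parse hmmscan per-domain tabular output, keeping hits with e-value
    strictly below ``e_threshold``.

    Column layout follows hmmscan ``--domtblout``: target (profile) name,
    target accession, tlen, query (protein) name, ...; the full-sequence
    e-value and bit score (columns 7-8) are used.  Malformed rows are
    skipped with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"domtbl file not found: {path}")
    hits: list[DomainHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 9:
                logger.warning("%s:%d: malformed row skipped", path, lineno)
                continue
            try:
                target_name, target_acc = fields[0], fields[1]
                protein_id = fields[3]
                e_value = float(fields[6])
                bit_score = float(fields[7])
            except ValueError:
                logger.warning("%s:%d: malformed row skipped", path, lineno)
                continue
            if e_value >= e_threshold:
                continue
            accession = target_acc if target_acc not in ("-", "") else target_name
            # drop Pfam accession version suffix (PF00001.21 -> PF00001)
            accession = accession.split(".")[0]
            hits.append(DomainHit(protein_id, accession, e_value, bit_score))
    return hits


def assign_observations(
    proteins: Sequence[ProteinRecord], hits: Iterable[DomainHit]
) -> list[DomainObservation]:
    """Assign exactly one symbol per protein.

    The hit with the smallest e-value wins; ties break by higher bit
    score, then lexicographically smallest accession.  Proteins with no
    retained hit get the ``NOHIT`` sentinel.  Output follows protein
    ordinal order.
    """
    known = {p.protein_id for p in proteins}
    best: dict[str, DomainHit] = {}
    for hit in hits:
        if hit.protein_id not in known:
            raise ValueError(
                f"domain hit references unknown protein_id: {hit.protein_id!r}"
            )
        cur = best.get(hit.protein_id)
        if cur is None or _hit_key(hit) < _hit_key(cur):
            best[hit.protein_id] = hit
    ordered = sorted(proteins, key=lambda p: (p.genome_id, p.ordinal))
    return [
        DomainObservation(
            p.protein_id,
            best[p.protein_id].domain_accession if p.protein_id in best else NOHIT,
        )
        for p in ordered
    ]


def _hit_key(hit: DomainHit) -> tuple:
    # smaller is better: e-value asc, bit score desc, accession asc
    return (hit.e_value, -hit.bit_score, hit.domain_accession)


PREDICTION_COLUMNS = (
    "genome_id",
    "ordinal",
    "protein_id",
    "symbol",
    "posterior_tail",
    "call",
    "cluster_id",
)


def write_predictions(rows: Iterable[Mapping], path: str | Path) -> None:
    """Write prediction rows as TSV.

    Each row maps the columns genome_id, ordinal, protein_id, symbol,
    posterior_tail (float), call (``tail``/``non-tail``), cluster_id
    (integer, ``outlier``, or ``.`` for non-tail proteins).  Posteriors
    are printed with 10 significant digits so a re-read reproduces them
    to printed precision.
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("\t".join(PREDICTION_COLUMNS) + "\n")
        for row in rows:
            fh.write(
                "\t".join(
                    [
                        str(row["genome_id"]),
                        str(row["ordinal"]),
                        str(row["protein_id"]),
                        str(row["symbol"]),
                        format(float(row["posterior_tail"]), ".10g"),
                        str(row["call"]),
                        str(row["cluster_id"]),
                    ]
                )
                + "\n"
            )


def read_predictions(path: str | Path) -> list[dict]:
    """Read a prediction TSV back into a list of row dicts."""
    path = Path(path)
    rows: list[dict] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != list(PREDICTION_COLUMNS):
            raise ValueError(f"unexpected prediction header in {path}: {header}")
        for line in fh:
            vals = line.rstrip("\n").split("\t")
            row = dict(zip(header, vals))
            row["ordinal"] = int(row["ordinal"])
            row["posterior_tail"] = float(row["posterior_tail"])
            rows.append(row)
    return rows
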