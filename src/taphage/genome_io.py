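"""Reading, validation and filtering of viral genome sequences and metadata.

Genomes are held internally as RNA: sequences are uppercased and ``T`` is
mapped to ``U`` on read, so motifs written in RNA form (``ACA``, ``GCU``,
``ACG``, ``ACU``) match NCBI downloads regardless of the T/U convention of
the source file.  IUPAC ambiguity letters are accepted and preserved; they
count toward genome length but never match a motif position.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: Concrete RNA bases.
RNA_BASES = "ACGU"

#: Full IUPAC nucleotide alphabet after T->U normalization.
IUPAC_RNA = frozenset("ACGURYSWKMBDHVN")

#: Ambiguity codes (everything that is not a concrete base).
AMBIGUITY_CODES = IUPAC_RNA - frozenset(RNA_BASES)

#: Recognized molecule-type labels for viral genomes.
MOLTYPES = ("ssRNA+", "ssRNA-", "dsRNA", "ssDNA", "dsDNA", "unknown")

METADATA_COLUMNS = ("id", "moltype", "host", "complete", "evolved")


@dataclass
class GenomeRecord:
    """One genome sequence with its host/genome-class metadata.

    Attributes
    ----------
    id : str
        Accession or free-form identifier; unique within a collection.
    description : str
        Free-text description from the FASTA header.
    sequence : str
        Normalized sequence over ``{A, C, G, U}`` plus IUPAC ambiguity codes.
    moltype : str
        One of :data:`MOLTYPES`.
    host : str
        Host genus (free text), ``"non-bacterial"``, or ``"unknown"``.
    complete : bool
        Whether the genome is complete (user-supplied; not inferred).
    evolved : bool
        Whether the sequence comes from an experimentally evolved isolate.
    """

    id: str
    description: str = ""
    sequence: str = ""
    moltype: str = "unknown"
    host: str = "unknown"
    complete: bool = False
    evolved: bool = False

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("GenomeRecord id must be non-empty")

    @property
    def length(self) -> int:
        """Genome length in nucleotides (ambiguity codes included)."""
        return len(self.sequence)


def normalize_sequence(sequence: str, *, name: str = "sequence") -> str:
    """Uppercase, map T (and t) to U, and validate against the IUPAC alphabet.

    Idempotent: normalizing twice equals normalizing once.  Raises
    ``ValueError`` naming the 1-based position of the first invalid character.
    """
    normalized = sequence.upper().replace("T", "U")
    for pos, char in enumerate(normalized, start=1):
        if char not in IUPAC_RNA:
            raise ValueError(
                f"invalid character {char!r} at position {pos} in {name}: "
                "not an IUPAC nucleotide code"
            )
    return normalized


def read_fasta(path: str | Path) -> list[GenomeRecord]:
    """Read a (multi-record) FASTA file into normalized :class:`GenomeRecord` s.

    Record ids are the header token before the first whitespace.  Metadata
    fields are left at their defaults until :func:`join_metadata` is applied.

    Raises
    ------
    ValueError
        If the file holds no records, contains duplicate ids, or a sequence
        contains characters outside the IUPAC nucleotide codes.
    """
    path = Path(path)
    records: list[GenomeRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(
            GenomeRecord(
                id=rec.id,
                description=rec.description,
                sequence=normalize_sequence(str(rec.seq), name=rec.id),
            )
        )
    if not records:
        raise ValueError(f"no records in {path}")
    return records


def write_fasta(records: Iterable[GenomeRecord], path: str | Path) -> None:
    """Write records to FASTA, preserving ids and normalized sequences."""
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.description)
        for r in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


def read_genbank(path: str | Path) -> list[GenomeRecord]:
    """Read GenBank records, keeping the sequence and the host/organism note.

    The ``host`` qualifier of the source feature is used when present,
    otherwise the organism annotation; everything else defaults.
    """
    records: list[GenomeRecord] = []
    for rec in SeqIO.parse(str(path), "genbank"):
        host = "unknown"
        for feat in rec.features:
            if feat.type == "source":
                quals = feat.qualifiers
                host = (quals.get("host") or quals.get("lab_host") or ["unknown"])[0]
                break
        records.append(
            GenomeRecord(
                id=rec.id,
                description=rec.description,
                sequence=normalize_sequence(str(rec.seq), name=rec.id),
                host=host,
            )
        )
    if not records:
        raise ValueError(f"no records in {path}")
    return records


def _parse_bool(value: object) -> bool:
    text = str(value).strip().lower()
    if text in {"true", "1", "yes", "y"}:
        return True
    if text in {"false", "0", "no", "n", "", "nan"}:
        return False
    raise ValueError(f"cannot interpret {value!r} as a boolean")


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read a metadata TSV with columns id, moltype, host, complete, evolved."""
    table = pd.read_csv(path, sep="\t", dtype=str, comment="#").fillna("")
    missing = [c for c in METADATA_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"metadata table {path} is missing columns: {missing}")
    return table


def join_metadata(
    records: Sequence[GenomeRecord], table: str | Path | pd.DataFrame
) -> list[GenomeRecord]:
    """Enrich records with metadata rows matched by id.

    Records without a metadata row keep their defaults (logged); metadata rows
    whose id matches no record produce a warning, not an error.
    """
    if not isinstance(table, pd.DataFrame):
        table = read_metadata(table)
    by_id = {str(row["id"]): row for _, row in table.iterrows()}
    known = set(by_id)
    record_ids = {r.id for r in records}
    for orphan in sorted(known - record_ids):
        logger.warning("metadata row %r matches no genome record", orphan)

    enriched: list[GenomeRecord] = []
    for rec in records:
        row = by_id.get(rec.id)
        if row is None:
            logger.warning("no metadata for genome %r; keeping defaults", rec.id)
            enriched.append(rec)
            continue
        moltype = str(row["moltype"]).strip() or "unknown"
        if moltype not in MOLTYPES:
            logger.warning(
                "unrecognized moltype %r for %r; treating as unknown", moltype, rec.id
            )
            moltype = "unknown"
        enriched.append(
            replace(
                rec,
                moltype=moltype,
                host=str(row["host"]).strip() or "unknown",
                complete=_parse_bool(row["complete"]),
                evolved=_parse_bool(row["evolved"]),
            )
        )
    return enriched


def filter_genomes(
    records: Sequence[GenomeRecord],
    min_length: int = 1000,
    exclude_evolved: bool = True,
) -> list[GenomeRecord]:
    """Keep genomes strictly longer than ``min_length`` nucleotides.

    With ``exclude_evolved`` (default) genomes flagged as coming from
    experimentally evolved isolates are dropped.  Order is preserved; an
    empty result is legal.
    """
    if min_length < 1:
        raise ValueError("min_length must be >= 1")
    kept = [r for r in records if r.length > min_length]
    if exclude_evolved:
        kept = [r for r in kept if not r.evolved]
    return kept
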