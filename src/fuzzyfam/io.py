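"""Input parsing and validation for sequences, domain hits and EST hits.

All downstream analysis consumes the three record types defined here:
:class:`SequenceRecord` (the proteins being clustered), :class:`DomainHit`
(Pfam-style domain annotations, typically from ``hmmscan``) and
:class:`EstHit` (EST-to-gene alignments, typically BLAST tabular output).
Parsers accept either a simple headered TSV dialect or the native tool
format, auto-detected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

logger = logging.getLogger(__name__)

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")
AMBIGUITY_AA = set("BZXUO")
GAP_CHARS = set("-.")
VALID_AA = STANDARD_AA | AMBIGUITY_AA


class InputError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True)
class SequenceRecord:
    """One protein sequence with a unique identifier."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise InputError("sequence record has an empty id")
        if len(self.sequence) < 1:
            raise InputError(f"sequence {self.id!r} is empty")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class DomainHit:
    """A domain-model match on one sequence (e.g. one hmmscan domain row)."""

    sequence_id: str
    domain_model: str
    e_value: float
    start: int | None = None
    end: int | None = None

    def __post_init__(self) -> None:
        if self.e_value < 0:
            raise InputError(
                f"negative E-value {self.e_value} for hit "
                f"{self.sequence_id}/{self.domain_model}"
            )
        if self.start is not None and self.end is not None and self.start > self.end:
            raise InputError(
                f"start > end ({self.start} > {self.end}) for hit "
                f"{self.sequence_id}/{self.domain_model}"
            )


@dataclass(frozen=True)
class EstHit:
    """One EST-to-gene alignment record with the gene's group label attached."""

    est_id: str
    gene_id: str
    group_label: str
    e_value: float
    identity: float | None = None
    start: int | None = None
    end: int | None = None

    def __post_init__(self) -> None:
        if not self.est_id or not self.gene_id:
            raise InputError("EST hit with empty est_id or gene_id")
        if self.e_value < 0:
            raise InputError(f"negative E-value for EST hit {self.est_id}")


def _clean_sequence(raw: str, record_id: str) -> str:
    seq = raw.upper()
    if any(c in GAP_CHARS for c in seq):
        logger.warning("gap characters stripped from sequence %s", record_id)
        seq = "".join(c for c in seq if c not in GAP_CHARS)
    for pos, c in enumerate(seq, start=1):
        if c not in VALID_AA:
            raise InputError(
                f"invalid residue character {c!r} at position {pos} "
                f"in sequence {record_id!r}"
            )
    return seq


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a multi-record FASTA file into :class:`SequenceRecord` objects.

    Sequences are upper-cased, gap characters stripped with a warning.
    Raises :class:`InputError` on an empty file, duplicate ids or residue
    characters outside the 20 standard letters plus B/Z/X/U/O.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise InputError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = _clean_sequence(str(rec.seq), rec.id)
        if not seq:
            raise InputError(f"sequence {rec.id!r} is empty after cleaning")
        records.append(SequenceRecord(rec.id, seq, rec.description))
    if not records:
        raise InputError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    """Write records as unwrapped FASTA (round-trips with :func:`read_fasta`)."""
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id if not rec.description or rec.description == rec.id \
                else rec.description
            fh.write(f">{header}\n{rec.sequence}\n")


def _parse_float(token: str, what: str, lineno: int) -> float:
    try:
        return float(token)
    except ValueError:
        raise InputError(f"unparseable {what} {token!r} on line {lineno}") from None


def read_domain_hits(
    path: str | Path,
    e_value_cutoff: float = 1.0,
    known_ids: set[str] | None = None,
) -> tuple[list[DomainHit], list[str]]:
    """Read domain hits from a TSV or hmmscan ``--domtblout`` file.

    Hits with ``e_value <= e_value_cutoff`` are retained (the boundary is
    kept: a cutoff of 1 retains E-value 1.0 hits). The default cutoff of 1
    is the conventional permissive threshold for Pfam architecture scans.

    Returns ``(hits, unknown_ids)`` where ``unknown_ids`` lists sequence ids
    present in the table but absent from ``known_ids`` (empty when
    ``known_ids`` is None); such hits are retained but flagged.
    """
    path = Path(path)
    hits: list[DomainHit] = []
    unknown: list[str] = []
    n_rows = 0
    with open(path) as fh:
        lines = fh.readlines()
    domtblout = any(ln.startswith("#") and "domtblout" in ln.lower() for ln in lines) \
        or (bool(lines) and lines[0].startswith("#"))
    for lineno, line in enumerate(lines, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        if domtblout:
            # domtblout: target name [0], query name [3], domain i-Evalue [12]
            parts = line.split()
            if len(parts) < 13:
                raise InputError(f"unparseable domtblout row on line {lineno}")
            model, seq_id = parts[0], parts[3]
            e_value = _parse_float(parts[12], "E-value", lineno)
            start = int(parts[17]) if len(parts) > 18 else None
            end = int(parts[18]) if len(parts) > 18 else None
        else:
            parts = line.split("\t")
            if lineno == 1 and parts and parts[0].lower() in {"seq_id", "sequence_id"}:
                continue
            if len(parts) < 3:
                raise InputError(f"unparseable domain-hit row on line {lineno}")
            seq_id, model = parts[0], parts[1]
            e_value = _parse_float(parts[2], "E-value", lineno)
            start = int(parts[3]) if len(parts) > 4 and parts[3] else None
            end = int(parts[4]) if len(parts) > 4 and parts[4] else None
        if e_value < 0:
            raise InputError(f"negative E-value on line {lineno}")
        n_rows += 1
        if e_value <= e_value_cutoff:
            if known_ids is not None and seq_id not in known_ids:
                unknown.append(seq_id)
            hits.append(DomainHit(seq_id, model, e_value, start, end))
    if n_rows == 0:
        logger.warning("domain-hit table %s is empty", path)
    return hits, sorted(set(unknown))


def read_gene_groups(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV mapping gene id to group label."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise InputError(f"unparseable gene-group row on line {lineno}")
            if lineno == 1 and parts[0].lower() in {"gene_id", "gene"}:
                continue
            mapping[parts[0]] = parts[1]
    return mapping


def read_est_hits(
    path: str | Path,
    gene_groups: Mapping[str, str],
    e_value_cutoff: float = 1e-5,
) -> list[EstHit]:
    """Read EST alignment hits from BLAST outfmt-6 TSV or a simple TSV.

    Only hits with ``e_value < e_value_cutoff`` (strict) are retained, and
    each retained hit gets its gene's group label from ``gene_groups``.
    Identical (est_id, gene_id, start, end) rows are deduplicated with the
    count logged. Raises :class:`InputError` listing any retained gene id
    missing from the mapping.
    """
    path = Path(path)
    raw: list[EstHit] = []
    missing: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if lineno == 1 and parts[0].lower() in {"est_id", "qseqid"}:
                continue
            if len(parts) >= 12:
                # BLAST outfmt 6: qseqid sseqid pident ... evalue [10] bitscore
                est_id, gene_id = parts[0], parts[1]
                identity = _parse_float(parts[2], "identity", lineno)
                e_value = _parse_float(parts[10], "E-value", lineno)
                start, end = int(parts[8]), int(parts[9])
            elif len(parts) >= 3:
                est_id, gene_id = parts[0], parts[1]
                e_value = _parse_float(parts[2], "E-value", lineno)
                identity, start, end = None, None, None
            else:
                raise InputError(f"unparseable EST-hit row on line {lineno}")
            if e_value >= e_value_cutoff:
                continue
            group = gene_groups.get(gene_id)
            if group is None:
                missing.add(gene_id)
                continue
            raw.append(EstHit(est_id, gene_id, group, e_value, identity, start, end))
    if missing:
        raise InputError(
            "gene ids missing from the group mapping: " + ", ".join(sorted(missing))
        )
    seen: set[tuple] = set()
    hits: list[EstHit] = []
    for h in raw:
        key = (h.est_id, h.gene_id, h.start, h.end)
        if key in seen:
            continue
        seen.add(key)
        hits.append(h)
    if len(hits) < len(raw):
        logger.info("deduplicated %d identical EST-hit rows", len(raw) - len(hits))
    return hits
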