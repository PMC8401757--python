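"""Plain-text readers and writers for the pipeline's external formats.

Sequences are normalized to an RNA alphabet on ingest (``T`` -> ``U``,
upper-cased); IUPAC ambiguity codes and ``-`` alignment gaps are permitted.
Structures travel as Vienna dot-bracket triplets (header, sequence,
structure), strain metadata as tab-separated tables, and networks as
edge-list TSV or GraphML.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord


class FormatError(ValueError):
    """Raised when an input file violates a format contract."""


#: IUPAC RNA nucleotides, ambiguity codes and the alignment gap character.
RNA_ALPHABET = frozenset("ACGURYSWKMBDHVN-")

#: Unambiguous RNA bases.
UNAMBIGUOUS = frozenset("ACGU")

#: Closed habitat vocabulary; anything else maps to "unknown".
HABITATS = ("marine", "terrestrial", "saline-soil", "unknown")

METADATA_COLUMNS = ("strain", "species_label", "origin", "habitat",
                    "geography", "accession")


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide sequence (RNA alphabet, gaps allowed)."""

    id: str
    sequence: str
    description: str = ""

    def ungapped(self) -> str:
        return self.sequence.replace("-", "")


@dataclass(frozen=True)
class MetadataRecord:
    """One strain/sample row of the metadata table."""

    strain: str
    species_label: str = ""
    origin: str = ""
    habitat: str = "unknown"
    geography: str = ""
    accession: str = ""

    def __post_init__(self):
        if not self.strain:
            raise FormatError("metadata record with empty strain ID")
        if self.habitat not in HABITATS:
            object.__setattr__(self, "habitat", "unknown")


def normalize_sequence(seq: str) -> str:
    """Upper-case and convert DNA ``T`` to RNA ``U``. Idempotent."""
    return seq.upper().replace("T", "U")


def _validate_alphabet(seq: str, rec_id: str) -> None:
    for pos, ch in enumerate(seq):
        if ch not in RNA_ALPHABET:
            raise FormatError(
                f"record {rec_id!r}: invalid character {ch!r} at position "
                f"{pos + 1}")


def make_record(rec_id: str, sequence: str, description: str = "") -> SequenceRecord:
    """Build a validated, normalized :class:`SequenceRecord`."""
    if not rec_id:
        raise FormatError("sequence record with empty ID")
    seq = normalize_sequence(sequence)
    if not seq:
        raise FormatError(f"record {rec_id!r}: empty sequence")
    _validate_alphabet(seq, rec_id)
    return SequenceRecord(rec_id, seq, description)


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path) -> list[SequenceRecord]:
    """Read a multi-record FASTA file.

    Sequences are normalized (T->U, upper case) and validated against the
    IUPAC RNA alphabet. Duplicate IDs and empty files are errors.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for bio in SeqIO.parse(str(path), "fasta"):
        if bio.id in seen:
            raise FormatError(f"duplicate sequence ID {bio.id!r} in {path}")
        seen.add(bio.id)
        desc = bio.description
        if desc.startswith(bio.id):
            desc = desc[len(bio.id):].strip()
        records.append(make_record(bio.id, str(bio.seq), desc))
    if not records:
        raise FormatError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path) -> None:
    bio_records = [
        _BioSeqRecord(Seq(r.sequence), id=r.id, description=r.description)
        for r in records
    ]
    SeqIO.write(bio_records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Vienna dot-bracket triplets

_OPEN = "("
_CLOSE = ")"
_UNPAIRED = "."
_PSEUDOKNOT_CHARS = set("[]{}<>") | set("abcdefghijklmnopqrstuvwxyz") \
    | set("ABCDEFGHIJKLMNOPQRSTUVWXYZ")


def validate_dotbracket(structure: str, rec_id: str = "?") -> None:
    """Check a dot-bracket string: nested round brackets only, balanced.

    Extra bracket tiers (pseudoknot notation) are rejected: the ITS-2 and V4
    models handled here are nested.
    """
    depth = 0
    open_stack: list[int] = []
    for pos, ch in enumerate(structure):
        if ch == _OPEN:
            open_stack.append(pos)
            depth += 1
        elif ch == _CLOSE:
            if depth == 0:
                raise FormatError(
                    f"record {rec_id!r}: unbalanced ')' at index {pos}")
            open_stack.pop()
            depth -= 1
        elif ch == _UNPAIRED:
            continue
        elif ch in _PSEUDOKNOT_CHARS:
            raise FormatError(
                f"record {rec_id!r}: pseudoknot bracket {ch!r} at index "
                f"{pos}; only nested round brackets are supported")
        else:
            raise FormatError(
                f"record {rec_id!r}: invalid structure character {ch!r} "
                f"at index {pos}")
    if open_stack:
        raise FormatError(
            f"record {rec_id!r}: unbalanced '(' at index {open_stack[0]}")


def read_vienna(path) -> list[tuple[SequenceRecord, str]]:
    """Read Vienna triplets (``>header`` / sequence / dot-bracket).

    Returns ``(record, structure)`` pairs; structure length must equal
    sequence length and brackets must balance.
    """
    lines = [ln.rstrip("\n") for ln in Path(path).read_text().splitlines()]
    lines = [ln for ln in lines if ln.strip()]
    if not lines:
        raise FormatError(f"empty Vienna file {path}")
    out: list[tuple[SequenceRecord, str]] = []
    seen: set[str] = set()
    i = 0
    while i < len(lines):
        header = lines[i]
        if not header.startswith(">"):
            raise FormatError(
                f"{path}: expected '>' header at line {i + 1}, got "
                f"{header[:30]!r}")
        if i + 2 >= len(lines):
            raise FormatError(
                f"{path}: truncated record {header[1:]!r} (triplet format "
                "requires header, sequence and structure lines)")
        name = header[1:].split()[0]
        desc = header[1:][len(name):].strip()
        if name in seen:
            raise FormatError(f"duplicate sequence ID {name!r} in {path}")
        seen.add(name)
        rec = make_record(name, lines[i + 1], desc)
        structure = lines[i + 2].strip()
        if len(structure) != len(rec.sequence):
            raise FormatError(
                f"record {name!r}: structure length {len(structure)} != "
                f"sequence length {len(rec.sequence)}")
        validate_dotbracket(structure, name)
        out.append((rec, structure))
        i += 3
    return out


def write_vienna(pairs: Iterable[tuple[SequenceRecord, str]], path) -> None:
    with open(path, "w") as fh:
        for rec, structure in pairs:
            if len(structure) != len(rec.sequence):
                raise FormatError(
                    f"record {rec.id!r}: structure/sequence length mismatch")
            header = f">{rec.id}"
            if rec.description:
                header += f" {rec.description}"
            fh.write(f"{header}\n{rec.sequence}\n{structure}\n")


# ---------------------------------------------------------------------------
# Metadata TSV

def read_metadata(path) -> list[MetadataRecord]:
    """Read the tab-separated strain metadata table.

    A ``strain`` column is required; missing optional columns are filled
    with empty strings, and habitats outside the closed vocabulary map to
    ``unknown``. Strain IDs (which may contain spaces) are kept verbatim.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "strain" not in df.columns:
        raise FormatError(f"{path}: metadata table lacks a 'strain' column")
    for col in METADATA_COLUMNS:
        if col not in df.columns:
            df[col] = ""
    out = []
    for row in df.itertuples(index=False):
        out.append(MetadataRecord(
            strain=row.strain,
            species_label=row.species_label,
            origin=row.origin,
            habitat=row.habitat if row.habitat in HABITATS else "unknown",
            geography=row.geography,
            accession=row.accession,
        ))
    return out


def write_metadata(records: Iterable[MetadataRecord], path) -> None:
    df = pd.DataFrame(
        [{c: getattr(r, c) for c in METADATA_COLUMNS} for r in records],
        columns=list(METADATA_COLUMNS),
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Network exports

def write_edgelist(graph: nx.Graph, path) -> None:
    """Write a two-column (node1, node2) tab-separated edge list."""
    with open(path, "w") as fh:
        fh.write("node1\tnode2\n")
        for u, v in sorted(graph.edges()):
            fh.write(f"{u}\t{v}\n")


def write_graphml(graph: nx.Graph, path) -> None:
    nx.write_graphml(graph, str(path))
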