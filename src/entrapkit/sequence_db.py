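"""FASTA I/O and in-silico tryptic digestion.

These are the primitives that feed entrapment-database construction:
reading a protein database, cleaving each protein into tryptic peptides,
and filtering peptides by length.  The default digestion rule is trypsin
*without* proline suppression, i.e. the protein is cleaved C-terminal to
every K or R, including when the following residue is proline.  A
proline-suppressed variant is available behind a flag but is never the
default.  The N-terminal methionine is never clipped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "ProteinRecord",
    "DigestParams",
    "FastaParseError",
    "read_fasta",
    "write_fasta",
    "digest",
    "digest_proteins",
]

# residues accepted on input: the 20 canonical letters plus ambiguity
# codes and selenocysteine, which pass through digestion and shuffling
# as ordinary symbols
VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWYXBZU")


class FastaParseError(ValueError):
    """Raised when a FASTA file is malformed."""


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with its database origin.

    origin is one of ``original`` (the real, sample-relevant database),
    ``entrapment`` (sequences known to be absent from the sample) or
    ``foreign`` (a foreign-species pool used to build entrapments).
    """

    accession: str
    sequence: str
    origin: str = "original"

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"protein {self.accession!r} has an empty sequence")
        if self.origin not in ("original", "entrapment", "foreign"):
            raise ValueError(f"unknown origin {self.origin!r}")


@dataclass(frozen=True)
class DigestParams:
    """Parameters of the in-silico tryptic digest.

    Defaults follow the common peptide-database convention: one missed
    cleavage allowed, peptide lengths between 7 and 35 residues.
    ``min_length``/``max_length`` of ``None`` disable length filtering.
    """

    enzyme: str = "trypsin_no_proline_suppression"
    missed_cleavages: int = 1
    min_length: int | None = 7
    max_length: int | None = 35

    def __post_init__(self) -> None:
        if self.enzyme not in ("trypsin_no_proline_suppression", "trypsin"):
            raise ValueError(f"unsupported enzyme {self.enzyme!r}")
        if self.missed_cleavages < 0:
            raise ValueError("missed_cleavages must be non-negative")
        if (
            self.min_length is not None
            and self.max_length is not None
            and self.min_length > self.max_length
        ):
            raise ValueError("min_length must be <= max_length")

    @property
    def proline_suppression(self) -> bool:
        return self.enzyme == "trypsin"

    @classmethod
    def unfiltered(cls, missed_cleavages: int = 0) -> "DigestParams":
        """Digest with no length constraints (used for protein-level
        entrapment construction, where every fragment is retained)."""
        return cls(
            missed_cleavages=missed_cleavages, min_length=None, max_length=None
        )


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a FASTA file into :class:`ProteinRecord` objects.

    The accession is the header token before the first whitespace;
    sequences are uppercased and line breaks removed.  Sequence data
    appearing before the first header raises :class:`FastaParseError`
    naming the offending line.
    """
    records: list[ProteinRecord] = []
    accession: str | None = None
    chunks: list[str] = []

    def flush() -> None:
        if accession is not None:
            seq = "".join(chunks)
            if not seq:
                raise FastaParseError(f"entry {accession!r} has no sequence")
            records.append(ProteinRecord(accession, seq))

    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                accession = line[1:].split()[0] if line[1:].split() else ""
                if not accession:
                    raise FastaParseError(f"line {lineno}: empty FASTA header")
                chunks = []
            else:
                if accession is None:
                    raise FastaParseError(
                        f"line {lineno}: sequence data before any '>' header"
                    )
                chunks.append(line.upper())
    flush()
    seen: set[str] = set()
    for rec in records:
        if rec.accession in seen:
            raise FastaParseError(f"duplicate accession {rec.accession!r}")
        seen.add(rec.accession)
    return records


def write_fasta(
    records: Iterable[ProteinRecord], path: str | Path, width: int = 60
) -> None:
    """Write records to FASTA, wrapping sequences at ``width`` columns."""
    with open(path, "w") as handle:
        for rec in records:
            handle.write(f">{rec.accession}\n")
            for i in range(0, len(rec.sequence), width):
                handle.write(rec.sequence[i : i + width] + "\n")


def _cleavage_fragments(sequence: str, proline_suppression: bool) -> list[str]:
    """Split a sequence after every K/R (0 missed cleavages), in order.

    Under proline suppression a K/R followed by P is not cleaved.  The
    C-terminal fragment is kept even if it does not end in K/R, so the
    fragments always concatenate back to the input.
    """
    fragments: list[str] = []
    start = 0
    n = len(sequence)
    for i, residue in enumerate(sequence):
        if residue in "KR":
            if proline_suppression and i + 1 < n and sequence[i + 1] == "P":
                continue
            fragments.append(sequence[start : i + 1])
            start = i + 1
    if start < n:
        fragments.append(sequence[start:])
    return fragments


def digest(
    protein: ProteinRecord | str,
    params: DigestParams = DigestParams(),
    unique: bool = False,
) -> list[str]:
    """Digest one protein into tryptic peptides.

    Returns peptides ordered by start position (and, within a position,
    by increasing number of missed cleavages).  Positional duplicates
    are retained unless ``unique`` is set, in which case the first
    occurrence of each sequence is kept — the form used when building a
    peptide database.  An empty sequence yields an empty list.
    """
    sequence = protein.sequence if isinstance(protein, ProteinRecord) else protein
    if not sequence:
        return []
    fragments = _cleavage_fragments(sequence, params.proline_suppression)
    peptides: list[str] = []
    for i in range(len(fragments)):
        peptide = ""
        for m in range(params.missed_cleavages + 1):
            if i + m >= len(fragments):
                break
            peptide += fragments[i + m]
            if params.min_length is not None and len(peptide) < params.min_length:
                continue
            if params.max_length is not None and len(peptide) > params.max_length:
                continue
            peptides.append(peptide)
    if unique:
        peptides = list(dict.fromkeys(peptides))
    return peptides


def digest_proteins(
    proteins: Sequence[ProteinRecord], params: DigestParams = DigestParams()
) -> list[str]:
    """Digest many proteins into one deduplicated peptide list.

    Deduplication is by exact string equality (I and L are distinct);
    first-occurrence order is preserved so downstream generation is
    deterministic.
    """
    seen: dict[str, None] = {}
    for protein in proteins:
        for peptide in digest(protein, params):
            seen.setdefault(peptide, None)
    return list(seen)
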