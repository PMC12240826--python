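"""Parsing search-result tables and assigning origin labels.

Search engines report delimited tables with one row per peptide,
precursor or protein group, carrying a score and/or a q-value column
(e.g. ``Q.Value``, ``PG.Q.Value``, ``PepQValue``, ``peptide_q``,
``EG.Qvalue`` depending on the engine).  This module parses such tables
into neutral records, strips modification annotations, and labels each
record as original or entrapment by lookup against an entrapment
database — the step that "reveals" the labels hidden from the engine.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .entrapment_gen import EntrapmentDatabase
from .estimators import DiscoveryList, DiscoveryRecord

__all__ = [
    "ResultsSchema",
    "ParsedRecord",
    "parse_results",
    "label_origins",
    "classify_protein_group",
]

#: default modification-stripping rule: bracketed or parenthesized mass
#: or name annotations (e.g. ``[+57.02]``, ``(UniMod:4)``) and lowercase
#: flag characters are removed
DEFAULT_MOD_PATTERN = r"\[[^\]]*\]|\([^)]*\)"


@dataclass(frozen=True)
class ResultsSchema:
    """Column mapping and conventions of one engine's report."""

    id_column: str
    level: str = "peptide"  # peptide | precursor | protein
    score_column: str | None = None
    q_column: str | None = None
    charge_column: str | None = None
    run_column: str | None = None
    delimiter: str = "\t"
    mod_pattern: str = DEFAULT_MOD_PATTERN
    group_separator: str = ";"

    def __post_init__(self) -> None:
        if self.level not in ("peptide", "precursor", "protein"):
            raise ValueError(f"unknown level {self.level!r}")
        if self.score_column is None and self.q_column is None:
            raise ValueError("schema needs a score column or a q-value column")
        if self.level == "precursor" and self.charge_column is None:
            raise ValueError("precursor-level schema needs a charge column")

    def strip_mods(self, sequence: str) -> str:
        stripped = re.sub(self.mod_pattern, "", sequence)
        return re.sub(r"[a-z]", "", stripped)


@dataclass(frozen=True)
class ParsedRecord:
    identifier: str
    score: float | None
    q_value: float | None
    run: str | None = None


def parse_results(
    path: str | Path, schema: ResultsSchema
) -> list[ParsedRecord]:
    """Parse a delimited results table into neutral records.

    Precursor identifiers are normalized to ``strippedSequence/charge``;
    modification annotations are removed by the schema rule before any
    matching.  Duplicate identifiers are kept — deduplication (best
    score wins) is the caller's explicit choice downstream.
    """
    table = pd.read_csv(path, sep=schema.delimiter)
    needed = [
        col
        for col in (
            schema.id_column,
            schema.score_column,
            schema.q_column,
            schema.charge_column,
            schema.run_column,
        )
        if col is not None
    ]
    missing = [col for col in needed if col not in table.columns]
    if missing:
        raise ValueError(
            f"missing column(s) {missing}; available: {list(table.columns)}"
        )
    records: list[ParsedRecord] = []
    for row in table.itertuples(index=False):
        data = row._asdict() if hasattr(row, "_asdict") else dict(zip(table.columns, row))
        raw_id = str(data[schema.id_column])
        if schema.level == "protein":
            identifier = raw_id
        else:
            identifier = schema.strip_mods(raw_id)
            if schema.level == "precursor":
                identifier = f"{identifier}/{int(data[schema.charge_column])}"
        score = (
            float(data[schema.score_column])
            if schema.score_column is not None
            else None
        )
        q_value = (
            float(data[schema.q_column]) if schema.q_column is not None else None
        )
        run = str(data[schema.run_column]) if schema.run_column else None
        records.append(ParsedRecord(identifier, score, q_value, run))
    return records


def classify_protein_group(
    member_accessions: Sequence[str], db: EntrapmentDatabase
) -> str:
    """Origin of a protein group: original if any member protein comes
    from the original target database, else entrapment.  Single-member
    groups take their member's origin."""
    if not member_accessions:
        raise ValueError("empty protein group")
    origins = []
    for accession in member_accessions:
        try:
            origin, _ = db.origin_of(accession)
        except KeyError:
            raise ValueError(f"unresolvable accession {accession!r}") from None
        origins.append(origin)
    return "original" if "original" in origins else "entrapment"


def label_origins(
    records: Sequence[ParsedRecord],
    db: EntrapmentDatabase,
    max_unmatched_frac: float = 0.01,
) -> tuple[DiscoveryList, list[ParsedRecord]]:
    """Label parsed records against an entrapment database.

    Peptide/precursor records are matched by stripped sequence; protein
    records are protein groups whose members (split on the schema's
    group separator, here ";") are classified by the any-original rule.
    Returns the labeled :class:`DiscoveryList` and the remainder of
    unmatched records.  More than ``max_unmatched_frac`` unmatched
    records raises, since that usually signals a schema/database
    mismatch.
    """
    pair_index: dict[str, int] = {}
    if db.level == "protein" and db.pairing:
        for group, (orig_acc, ent_accs) in enumerate(db.pairing.items()):
            pair_index[orig_acc] = group
            for acc in ent_accs:
                pair_index[acc] = group

    labeled: list[DiscoveryRecord] = []
    remainder: list[ParsedRecord] = []
    for record in records:
        if db.level == "protein":
            members = [
                m for m in record.identifier.split(";") if m
            ]
            try:
                origin = classify_protein_group(members, db)
                pair_group = next(
                    (pair_index[m] for m in members if m in pair_index), None
                )
            except ValueError:
                remainder.append(record)
                continue
        else:
            sequence = record.identifier.split("/")[0]
            try:
                origin, pair_group = db.origin_of(sequence)
            except KeyError:
                remainder.append(record)
                continue
            if origin == "decoy":
                remainder.append(record)
                continue
        labeled.append(
            DiscoveryRecord(
                identifier=record.identifier,
                origin=origin,
                score=record.score,
                q_value=record.q_value,
                pair_group=pair_group,
            )
        )
    if records and len(remainder) / len(records) > max_unmatched_frac:
        raise ValueError(
            f"{len(remainder)} of {len(records)} records "
            f"({100 * len(remainder) / len(records):.1f}%) did not match "
            "the database; check the schema level and the database files"
        )
    if remainder:
        warnings.warn(
            f"{len(remainder)} records did not match the database and "
            "were set aside",
            stacklevel=2,
        )
    r = db.r if db.r > 0 else 1.0
    return DiscoveryList(labeled, r=r, k=db.k), remainder
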