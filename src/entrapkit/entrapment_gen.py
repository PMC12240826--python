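"""Construction of shuffled and foreign entrapment databases.

An entrapment database augments an original target database with
sequences known to be absent from the sample.  Two construction modes
are supported, at both peptide and protein level:

* **shuffled** — each original peptide is paired with ``k`` random
  shuffles of itself that keep the C-terminal residue fixed (so tryptic
  character is preserved).  Pairing enables the paired/k-matched FDP
  estimators, and the entrapment-to-original ratio is exactly ``r = k``.
* **foreign** — entrapment sequences are sampled from the proteome of a
  species not expected in the sample.  No pairing exists, so only the
  lower-bound, combined and sample estimators apply.

Generation is deterministic given a seed: each original peptide draws
its shuffles from a sub-stream derived from ``(seed, peptide index)``,
so inserting or removing one peptide does not perturb the shuffles of
the others.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .sequence_db import DigestParams, ProteinRecord, digest, read_fasta, write_fasta

__all__ = [
    "PeptideRecord",
    "EntrapmentDatabase",
    "shuffle_peptide",
    "build_peptide_entrapment",
    "build_protein_entrapment",
    "build_foreign_entrapment",
    "write_database",
    "read_database",
]


@dataclass(frozen=True)
class PeptideRecord:
    """A peptide with its origin label and pairing information.

    ``pair_group`` links an original peptide to its entrapment
    partner(s); every entrapment record carries the pair_group of
    exactly one original record.
    """

    sequence: str
    origin: str  # original | entrapment | decoy
    pair_group: int | None = None
    source_accessions: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.origin not in ("original", "entrapment", "decoy"):
            raise ValueError(f"unknown origin {self.origin!r}")
        if not self.sequence:
            raise ValueError("empty peptide sequence")


@dataclass
class EntrapmentDatabase:
    """A paired original/entrapment database.

    Attributes
    ----------
    level:
        ``"peptide"`` or ``"protein"``.
    records:
        :class:`PeptideRecord` list (peptide level) or
        :class:`~entrapkit.sequence_db.ProteinRecord` list (protein
        level), originals and entrapments interleaved by pair group.
    r:
        Effective entrapment-to-original database-size ratio.
    pairing:
        Original identifier (pair_group at peptide level, accession at
        protein level) mapped to the list of its entrapment sequences /
        accessions.  Empty for foreign databases.
    dropped:
        Original peptides removed because no distinct shuffle could be
        found within the retry budget (peptide level only).
    peptide_swaps:
        Protein level only: digested original peptide mapped to its k
        entrapment replacements, applied consistently across proteins.
    """

    level: str
    records: list
    r: float
    pairing: dict = field(default_factory=dict)
    dropped: list[str] = field(default_factory=list)
    seed: int | None = None
    peptide_swaps: dict[str, list[str]] = field(default_factory=dict)

    # -- lookups -------------------------------------------------------
    def originals(self) -> list:
        return [rec for rec in self.records if rec.origin == "original"]

    def entrapments(self) -> list:
        return [rec for rec in self.records if rec.origin == "entrapment"]

    @property
    def k(self) -> int | None:
        """Entrapments per original for paired databases, else None."""
        if not self.pairing:
            return None
        sizes = {len(v) for v in self.pairing.values()}
        return sizes.pop() if len(sizes) == 1 else None

    def origin_of(self, key: str) -> tuple[str, int | None]:
        """Look up (origin, pair_group) of a peptide sequence or a
        protein accession.  Raises KeyError for unknown keys."""
        if not hasattr(self, "_index"):
            if self.level == "peptide":
                self._index = {
                    rec.sequence: (rec.origin, rec.pair_group)
                    for rec in self.records
                }
            else:
                self._index = {
                    rec.accession: (rec.origin, None) for rec in self.records
                }
        return self._index[key]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EntrapmentDatabase):
            return NotImplemented
        return (
            self.level == other.level
            and self.records == other.records
            and math.isclose(self.r, other.r)
            and self.pairing == other.pairing
            and self.dropped == other.dropped
            and self.peptide_swaps == other.peptide_swaps
        )


def shuffle_peptide(
    peptide: str, rng: np.random.Generator, fix_nterm: bool = False
) -> str:
    """Uniformly shuffle a peptide, keeping the C-terminal residue fixed.

    With ``fix_nterm`` the first residue is also held in place (the
    variant used for controlled-mixture analyses).  The residue multiset
    is conserved exactly.
    """
    if len(peptide) <= 1:
        return peptide
    head = 1 if fix_nterm else 0
    core = np.array(list(peptide[head : len(peptide) - 1]))
    rng.shuffle(core)
    return peptide[:head] + "".join(core) + peptide[-1]


def _substream(seed: int | None, index: int) -> np.random.Generator:
    """Deterministic per-peptide RNG derived from (seed, index)."""
    return np.random.default_rng([0 if seed is None else seed, index])


def build_peptide_entrapment(
    targets: Sequence[str],
    k: int = 1,
    seed: int = 0,
    max_extra_tries: int = 20,
    fix_nterm: bool = False,
) -> EntrapmentDatabase:
    """Build a k-fold paired shuffled entrapment database at peptide level.

    For each original peptide, up to ``max_extra_tries + k`` shuffles
    are drawn to find ``k`` entrapment peptides distinct from all
    original peptides and all previously generated entrapments.
    Originals for which this fails are removed from the database and
    listed in ``dropped``; the resulting ratio is exactly ``r = k``.
    """
    if k < 1:
        raise ValueError("k must be a positive integer")
    if len(set(targets)) != len(targets):
        raise ValueError("targets must be deduplicated")
    taken = set(targets)
    records: list[PeptideRecord] = []
    pairing: dict[int, list[str]] = {}
    dropped: list[str] = []
    budget = max_extra_tries + k
    group = 0
    for index, peptide in enumerate(targets):
        rng = _substream(seed, index)
        entrapments: list[str] = []
        for _ in range(budget):
            if len(entrapments) == k:
                break
            candidate = shuffle_peptide(peptide, rng, fix_nterm=fix_nterm)
            if candidate not in taken:
                entrapments.append(candidate)
                taken.add(candidate)
        if len(entrapments) < k:
            taken.difference_update(entrapments)
            dropped.append(peptide)
            continue
        records.append(PeptideRecord(peptide, "original", group))
        records.extend(
            PeptideRecord(ent, "entrapment", group) for ent in entrapments
        )
        pairing[group] = list(entrapments)
        group += 1
    return EntrapmentDatabase(
        level="peptide",
        records=records,
        r=float(k),
        pairing=pairing,
        dropped=dropped,
        seed=seed,
    )


def build_protein_entrapment(
    proteins: Sequence[ProteinRecord], k: int = 1, seed: int = 0
) -> EntrapmentDatabase:
    """Build a k-fold paired shuffled entrapment database at protein level.

    Each protein is digested with 0 missed cleavages and no length
    filter; every distinct digested peptide is assigned ``k`` shuffled
    replacements (C-terminal fixed, distinct from the original and from
    each other when possible).  If only ``n < k`` distinct shuffles
    exist within the retry budget the remainder is sampled with
    replacement from those ``n``; if none exist the replacement equals
    the original, so — unlike the peptide level — no protein is ever
    dropped.  A peptide shared between proteins or positions is swapped
    consistently everywhere.  Entrapment protein ``j`` is the
    concatenation, in original order, of the ``j``-th replacement of
    each digested peptide; it therefore has the same length and the same
    K/R cleavage-site positions as its original.
    """
    if k < 1:
        raise ValueError("k must be a positive integer")
    accessions = [p.accession for p in proteins]
    if len(set(accessions)) != len(accessions):
        raise ValueError("proteins must be deduplicated by accession")
    params = DigestParams.unfiltered(missed_cleavages=0)
    fragments = {p.accession: digest(p, params) for p in proteins}
    distinct: dict[str, None] = {}
    for p in proteins:
        for pep in fragments[p.accession]:
            distinct.setdefault(pep, None)

    swaps: dict[str, list[str]] = {}
    budget_extra = 20
    for index, peptide in enumerate(distinct):
        rng = _substream(seed, index)
        found: list[str] = []
        for _ in range(budget_extra + k):
            if len(found) == k:
                break
            candidate = shuffle_peptide(peptide, rng)
            if candidate != peptide and candidate not in found:
                found.append(candidate)
        if not found:
            swaps[peptide] = [peptide] * k
        elif len(found) < k:
            extra = rng.choice(np.array(found), size=k - len(found), replace=True)
            swaps[peptide] = found + [str(e) for e in extra]
        else:
            swaps[peptide] = found

    records: list[ProteinRecord] = []
    pairing: dict[str, list[str]] = {}
    for p in proteins:
        records.append(p)
        partners = []
        for j in range(k):
            ent_seq = "".join(swaps[pep][j] for pep in fragments[p.accession])
            acc = f"{p.accession}_entrapment_{j + 1}"
            records.append(ProteinRecord(acc, ent_seq, origin="entrapment"))
            partners.append(acc)
        pairing[p.accession] = partners
    return EntrapmentDatabase(
        level="protein",
        records=records,
        r=float(k),
        pairing=pairing,
        seed=seed,
        peptide_swaps=swaps,
    )


def build_foreign_entrapment(
    targets: Sequence[str] | Sequence[ProteinRecord],
    foreign: Sequence[ProteinRecord],
    r: float,
    level: str = "peptide",
    seed: int = 0,
    digest_params: DigestParams = DigestParams(),
) -> EntrapmentDatabase:
    """Build a foreign-species entrapment database.

    Protein level: ``floor(r * n_targets)`` foreign proteins are sampled
    uniformly without replacement.  Peptide level: both sets are
    digested with ``digest_params`` (default: one missed cleavage,
    lengths 7-35), foreign peptides matching any original peptide are
    removed, and ``floor(r * n_originals)`` of the remainder are
    sampled.  The pairing map is empty — foreign entrapment supports the
    lower/combined/sample estimators but not the paired one.
    """
    if r <= 0:
        raise ValueError("r must be positive")
    rng = np.random.default_rng(seed)
    if level == "protein":
        if not all(isinstance(t, ProteinRecord) for t in targets):
            raise TypeError("protein-level targets must be ProteinRecord")
        n_needed = math.floor(r * len(targets))
        if n_needed > len(foreign):
            raise ValueError(
                "foreign pool too small: requested r=%g but at most r=%g "
                "is achievable with %d foreign proteins"
                % (r, len(foreign) / len(targets), len(foreign))
            )
        idx = rng.choice(len(foreign), size=n_needed, replace=False)
        records = list(targets) + [
            ProteinRecord(foreign[i].accession, foreign[i].sequence, "entrapment")
            for i in sorted(idx)
        ]
        achieved = n_needed / len(targets) if targets else 0.0
        return EntrapmentDatabase(
            level="protein", records=records, r=achieved, seed=seed
        )
    if level != "peptide":
        raise ValueError(f"unknown level {level!r}")
    if targets and isinstance(targets[0], ProteinRecord):
        originals = []
        seen: dict[str, None] = {}
        for t in targets:
            for pep in digest(t, digest_params):
                seen.setdefault(pep, None)
        originals = list(seen)
    else:
        originals = list(dict.fromkeys(targets))
    foreign_peps: dict[str, None] = {}
    for p in foreign:
        for pep in digest(p, digest_params):
            foreign_peps.setdefault(pep, None)
    original_set = set(originals)
    pool = [pep for pep in foreign_peps if pep not in original_set]
    n_needed = math.floor(r * len(originals))
    if n_needed > len(pool):
        raise ValueError(
            "foreign pool too small: requested r=%g but at most r=%g is "
            "achievable with %d usable foreign peptides"
            % (r, len(pool) / max(len(originals), 1), len(pool))
        )
    idx = rng.choice(len(pool), size=n_needed, replace=False)
    records = [PeptideRecord(pep, "original") for pep in originals]
    records += [PeptideRecord(pool[i], "entrapment") for i in sorted(idx)]
    achieved = n_needed / len(originals) if originals else 0.0
    return EntrapmentDatabase(
        level="peptide", records=records, r=achieved, seed=seed
    )


# ---------------------------------------------------------------------------
# persistence: FASTA + sidecar TSV + JSON metadata, lossless round trip
# ---------------------------------------------------------------------------


def _record_rows(db: EntrapmentDatabase) -> pd.DataFrame:
    if db.level == "peptide":
        return pd.DataFrame(
            {
                "sequence": [rec.sequence for rec in db.records],
                "origin": [rec.origin for rec in db.records],
                "pair_group": [
                    -1 if rec.pair_group is None else rec.pair_group
                    for rec in db.records
                ],
                "source_accessions": [
                    ";".join(rec.source_accessions) for rec in db.records
                ],
            }
        )
    return pd.DataFrame(
        {
            "sequence": [rec.sequence for rec in db.records],
            "origin": [rec.origin for rec in db.records],
            "accession": [rec.accession for rec in db.records],
        }
    )


def write_database(db: EntrapmentDatabase, prefix: str | Path) -> list[Path]:
    """Write a database as ``PREFIX.fasta`` + ``PREFIX.tsv`` +
    ``PREFIX.meta.json`` (round-trips losslessly via
    :func:`read_database`).  Origins are encoded in FASTA accession
    suffixes such as ``_entrapment_1``."""
    prefix = Path(prefix)
    fasta_path = prefix.with_suffix(".fasta")
    tsv_path = prefix.with_suffix(".tsv")
    meta_path = prefix.with_suffix(".meta.json")

    if db.level == "peptide":
        counters: dict[int, int] = {}
        fasta_records = []
        for rec in db.records:
            group = -1 if rec.pair_group is None else rec.pair_group
            if rec.origin == "original":
                acc = f"pep_{group}" if group >= 0 else f"pep_x{len(fasta_records)}"
            else:
                counters[group] = counters.get(group, 0) + 1
                base = f"pep_{group}" if group >= 0 else f"pep_x{len(fasta_records)}"
                acc = f"{base}_{rec.origin}_{counters[group]}"
            fasta_records.append(ProteinRecord(acc, rec.sequence))
        write_fasta(fasta_records, fasta_path)
    else:
        write_fasta(
            [ProteinRecord(r.accession, r.sequence) for r in db.records], fasta_path
        )

    _record_rows(db).to_csv(tsv_path, sep="\t", index=False)
    meta = {
        "level": db.level,
        "r": db.r,
        "seed": db.seed,
        "dropped": db.dropped,
        "pairing": {str(key): val for key, val in db.pairing.items()},
        "peptide_swaps": db.peptide_swaps,
    }
    meta_path.write_text(json.dumps(meta, indent=1, sort_keys=True))
    return [fasta_path, tsv_path, meta_path]


def read_database(prefix: str | Path) -> EntrapmentDatabase:
    """Load a database written by :func:`write_database`."""
    prefix = Path(prefix)
    meta = json.loads(prefix.with_suffix(".meta.json").read_text())
    table = pd.read_csv(
        prefix.with_suffix(".tsv"), sep="\t", keep_default_na=False
    )
    level = meta["level"]
    if level == "peptide":
        records: list = [
            PeptideRecord(
                row.sequence,
                row.origin,
                None if row.pair_group < 0 else int(row.pair_group),
                tuple(row.source_accessions.split(";"))
                if row.source_accessions
                else (),
            )
            for row in table.itertuples()
        ]
        pairing = {int(key): val for key, val in meta["pairing"].items()}
    else:
        records = [
            ProteinRecord(row.accession, row.sequence, row.origin)
            for row in table.itertuples()
        ]
        pairing = dict(meta["pairing"])
    return EntrapmentDatabase(
        level=level,
        records=records,
        r=float(meta["r"]),
        pairing=pairing,
        dropped=list(meta["dropped"]),
        seed=meta["seed"],
        peptide_swaps={k: list(v) for k, v in meta["peptide_swaps"].items()},
    )
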