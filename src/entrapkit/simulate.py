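"""Ground-truthed simulation of entrapment experiments.

This module stands in for a search engine: it draws scores for a
target+entrapment peptide database, runs honest target-decoy competition
(TDC) to produce reported q-values, and returns discovery lists whose
per-record truth (present in the sample or not) is known.  Because the
truth is known, every upper/lower-bound property of the FDP estimators
can be verified empirically, with no mass-spectrometry data.

Model: ``n_native`` original peptides are truly present and draw scores
from a right-shifted Gumbel distribution; absent originals, entrapment
peptides and the tool's decoys draw i.i.d. from a standard Gaussian
null.  The equal-chance assumption underlying both TDC and the
combined/paired estimators therefore holds by construction.  A tool that
misreports its error rates is emulated by multiplying the honest
q-values by a bias factor (anticonservative < 1, conservative > 1).

``double_entrapment`` augments the original-target pool with a large
foreign pool that is absent by construction, so the estimators can be
compared against a "direct" truth-based FDP estimate — the in-silico
analogue of spiking a known protein mixture into a foreign database.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .entrapment_gen import EntrapmentDatabase
from .estimators import (
    DiscoveryList,
    DiscoveryRecord,
    FdpCurve,
    MissingPairWarning,
    coverage_band,
    direct_fdp,
    fdp_curve,
)
from .fdr_control import ScoredCompetition, tdc_qvalues

__all__ = [
    "SimConfig",
    "ReplicateResult",
    "SimResult",
    "simulate_experiment",
    "double_entrapment",
    "write_replicate_tsv",
]

TOOL_MODES = ("honest_tdc", "anticonservative", "conservative")


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated entrapment experiment.

    Defaults give a mid-sized experiment with clear but imperfect score
    separation: 300 present peptides among 1000 originals, one
    entrapment per original, Gumbel(loc=3) present scores against
    standard-normal nulls.
    """

    n_native: int = 300
    n_absent_originals: int = 700
    k: int = 1
    n_reps: int = 200
    seed: int = 0
    present_loc: float = 3.0
    present_scale: float = 1.0
    null_loc: float = 0.0
    null_scale: float = 1.0
    tool_mode: str = "honest_tdc"
    bias: float = 1.0
    foreign_fraction: float | None = None
    thresholds: tuple[float, ...] = (0.005, 0.01, 0.02, 0.05, 0.10)
    methods: tuple[str, ...] = ("lower", "combined", "sample", "paired")
    database: EntrapmentDatabase | None = None

    def __post_init__(self) -> None:
        if self.n_native < 0 or self.n_absent_originals < 0:
            raise ValueError("counts must be non-negative")
        if self.k < 1:
            raise ValueError("k must be a positive integer")
        if self.n_reps < 1:
            raise ValueError("n_reps must be positive")
        if self.tool_mode not in TOOL_MODES:
            raise ValueError(f"unknown tool_mode {self.tool_mode!r}")
        if self.bias <= 0:
            raise ValueError("bias factor must be positive")
        if self.null_scale < 0:
            raise ValueError("null_scale must be non-negative")
        if self.tool_mode == "anticonservative" and self.bias >= 1:
            raise ValueError("anticonservative mode needs bias < 1")
        if self.tool_mode == "conservative" and self.bias <= 1:
            raise ValueError("conservative mode needs bias > 1")
        if self.foreign_fraction is not None and not 0 <= self.foreign_fraction < 1:
            raise ValueError("foreign_fraction must lie in [0, 1)")
        if self.database is not None and self.database.level != "peptide":
            raise ValueError("simulation requires a peptide-level database")


@dataclass
class ReplicateResult:
    """One replicate: the tool-reported discovery list plus hidden truth."""

    dlist: DiscoveryList
    truth_false: np.ndarray  # per record: not present in the sample
    is_foreign: np.ndarray  # per record: from the foreign-absent pool

    def true_fdp(self, threshold: float) -> float:
        selected = self.dlist.q_values <= threshold
        total = int(selected.sum())
        if total == 0:
            return 0.0
        return float(np.sum(selected & self.truth_false)) / total

    def direct_fdp(self, threshold: float) -> float:
        selected = self.dlist.q_values <= threshold
        n_entrap = int(np.sum(selected & self.dlist.is_entrapment))
        foreign = int(np.sum(selected & self.is_foreign))
        native = int(selected.sum()) - n_entrap - foreign
        return direct_fdp(native, foreign, n_entrap)


@dataclass
class SimResult:
    """All replicates of a simulated experiment plus summaries."""

    config: SimConfig
    thresholds: np.ndarray
    replicates: list[ReplicateResult]
    curves: list[FdpCurve]
    true_fdp: np.ndarray  # (n_reps, n_thresholds)
    direct: np.ndarray | None = None  # double entrapment only
    summary: FdpCurve | None = None  # mean curve with coverage bands


def _identifiers(cfg: SimConfig, n_orig: int) -> tuple[list[str], list[list[str]]]:
    """Original and per-original entrapment identifiers, taken from an
    attached entrapment database when one is provided."""
    if cfg.database is not None:
        originals = cfg.database.originals()
        if len(originals) != n_orig:
            raise ValueError(
                f"database has {len(originals)} originals; config needs {n_orig}"
            )
        if cfg.database.k != cfg.k:
            raise ValueError("database k does not match config k")
        orig_ids = [rec.sequence for rec in originals]
        ent_ids = [
            list(cfg.database.pairing[rec.pair_group]) for rec in originals
        ]
        return orig_ids, ent_ids
    orig_ids = [f"orig{g}" for g in range(n_orig)]
    ent_ids = [
        [f"ent{g}_{j}" for j in range(cfg.k)] for g in range(n_orig)
    ]
    return orig_ids, ent_ids


def _run_replicate(
    cfg: SimConfig, n_foreign: int, rng: np.random.Generator
) -> ReplicateResult:
    n_orig = cfg.n_native + cfg.n_absent_originals + n_foreign
    k = cfg.k
    orig_ids, ent_ids = _identifiers(cfg, n_orig)

    def null(size):
        return rng.normal(cfg.null_loc, cfg.null_scale, size=size)

    orig_scores = np.empty(n_orig)
    orig_scores[: cfg.n_native] = rng.gumbel(
        loc=cfg.present_loc, scale=cfg.present_scale, size=cfg.n_native
    )
    orig_scores[cfg.n_native :] = null(n_orig - cfg.n_native)
    ent_scores = null((n_orig, k))
    decoy_scores = null(n_orig * (1 + k))

    # honest TDC over the full target+entrapment database: each database
    # peptide competes against its own decoy, the winners are ranked and
    # the +1-corrected sweep yields a q-value per surviving peptide
    identifiers = list(orig_ids)
    for g in range(n_orig):
        identifiers.extend(ent_ids[g])
    # row-major ravel matches ent_ids flattened per original
    peptide_scores = np.concatenate([orig_scores, ent_scores.reshape(n_orig * k)])
    ties = peptide_scores == decoy_scores
    wins = (peptide_scores > decoy_scores) | (
        ties & (rng.random(peptide_scores.size) < 0.5)
    )
    winner_scores = np.maximum(peptide_scores, decoy_scores)
    entries = [
        (float(w), 1 if win else -1, ident)
        for w, win, ident in zip(winner_scores, wins, identifiers)
    ]
    qmap = tdc_qvalues(ScoredCompetition(entries), rng)

    factor = 1.0 if cfg.tool_mode == "honest_tdc" else cfg.bias
    records: list[DiscoveryRecord] = []
    truth_false: list[bool] = []
    is_foreign: list[bool] = []
    for g in range(n_orig):
        native = g < cfg.n_native
        foreign = g >= cfg.n_native + cfg.n_absent_originals
        if orig_ids[g] in qmap:
            records.append(
                DiscoveryRecord(
                    identifier=orig_ids[g],
                    origin="original",
                    score=float(orig_scores[g]),
                    q_value=min(qmap[orig_ids[g]] * factor, 1.0),
                    pair_group=g,
                )
            )
            truth_false.append(not native)
            is_foreign.append(foreign)
        for j in range(k):
            ident = ent_ids[g][j]
            if ident in qmap:
                records.append(
                    DiscoveryRecord(
                        identifier=ident,
                        origin="entrapment",
                        score=float(ent_scores[g, j]),
                        q_value=min(qmap[ident] * factor, 1.0),
                        pair_group=g,
                    )
                )
                truth_false.append(True)
                is_foreign.append(False)
    dlist = DiscoveryList(records, r=float(k), k=k)
    return ReplicateResult(
        dlist=dlist,
        truth_false=np.array(truth_false, dtype=bool),
        is_foreign=np.array(is_foreign, dtype=bool),
    )


def _simulate(cfg: SimConfig, n_foreign: int) -> SimResult:
    thresholds = np.asarray(cfg.thresholds, dtype=float)
    methods = list(cfg.methods)
    if cfg.k > 1:
        methods = [m if m != "paired" else "k_matched" for m in methods]
    replicates: list[ReplicateResult] = []
    curves: list[FdpCurve] = []
    true_fdp = np.zeros((cfg.n_reps, thresholds.size))
    direct = np.zeros_like(true_fdp) if n_foreign > 0 else None
    root = np.random.default_rng(cfg.seed)
    seeds = root.integers(0, 2**31 - 1, size=cfg.n_reps)
    for rep in range(cfg.n_reps):
        rng = np.random.default_rng(seeds[rep])
        replicate = _run_replicate(cfg, n_foreign, rng)
        replicates.append(replicate)
        with warnings.catch_warnings():
            # an original losing its decoy competition is simply not
            # reported; its entrapment partner then has no paired record
            warnings.simplefilter("ignore", MissingPairWarning)
            curves.append(fdp_curve(replicate.dlist, methods, thresholds))
        for i, t in enumerate(thresholds):
            true_fdp[rep, i] = replicate.true_fdp(t)
            if direct is not None:
                direct[rep, i] = replicate.direct_fdp(t)
    summary = coverage_band(curves) if cfg.n_reps >= 2 else None
    return SimResult(
        config=cfg,
        thresholds=thresholds,
        replicates=replicates,
        curves=curves,
        true_fdp=true_fdp,
        direct=direct,
        summary=summary,
    )


def simulate_experiment(cfg: SimConfig) -> SimResult:
    """Run ``cfg.n_reps`` independent replicates of the simulated
    entrapment experiment and summarize the estimator curves."""
    return _simulate(cfg, n_foreign=0)


def double_entrapment(cfg: SimConfig) -> SimResult:
    """Double-entrapment experiment: the original-target pool combines
    the native peptides with a foreign-absent pool whose size is set by
    ``cfg.foreign_fraction`` (the foreign share of the original pool).
    Foreign and entrapment discoveries are known false, so ``direct``
    holds the truth-anchored FDP estimate per replicate and threshold.
    """
    if cfg.foreign_fraction is None:
        raise ValueError("double_entrapment requires foreign_fraction")
    f = cfg.foreign_fraction
    n_foreign = int(round(cfg.n_native * f / (1.0 - f))) if f > 0 else 0
    return _simulate(cfg, n_foreign=n_foreign)


def write_replicate_tsv(
    result: SimResult, rep: int, path: str | Path
) -> None:
    """Write one replicate's reported discoveries as a results table
    parseable by :mod:`entrapkit.results_io` (columns: peptide, score,
    q_value)."""
    replicate = result.replicates[rep]
    frame = pd.DataFrame(
        {
            "peptide": [r.identifier for r in replicate.dlist.records],
            "score": replicate.dlist.scores,
            "q_value": replicate.dlist.q_values,
        }
    )
    frame.to_csv(path, sep="\t", index=False)
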