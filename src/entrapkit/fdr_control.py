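"""Reference FDR-control procedures for target-decoy searches.

Implements the procedures whose error reporting an entrapment experiment
evaluates: target-decoy competition (TDC) with the +1-corrected
rejection rule, the PSM-and-peptide double-competition protocol for
peptide-level analysis, and the non-competition route of empirical
p-values followed by Benjamini-Hochberg or Storey q-value adjustment.

TDC consumes a list of pairs ``(W_i, L_i)`` — a winning score and a
label, +1 for a target and -1 for a decoy.  Sorted by decreasing score,
with ``D_k``/``T_k`` the decoy/target counts among the top ``k``, the
rejection index is ``K = max{k : (D_k + 1) / max(T_k, 1) <= alpha}`` and
the targets among the top ``K`` are reported.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from statsmodels.stats.multitest import multipletests

from .estimators import SENTINEL_LOWEST

__all__ = [
    "ScoredCompetition",
    "PsmTable",
    "tdc_threshold",
    "tdc_qvalues",
    "psm_and_peptide",
    "empirical_pvalues",
    "bh_adjust",
    "storey_qvalues",
]


@dataclass
class ScoredCompetition:
    """Winner-score/label pairs consumed by TDC.

    ``entries`` holds ``(W, L, identifier)`` with ``L`` +1 (target) or
    -1 (decoy).  ``W`` may be the sentinel-lowest score.
    """

    entries: list[tuple[float, int, str]]

    def __post_init__(self) -> None:
        for w, label, _ in self.entries:
            if label not in (1, -1):
                raise ValueError(f"label must be +1 or -1, got {label}")


@dataclass
class PsmTable:
    """Rows of (spectrum_id, peptide, score); the best peptide per
    spectrum is selected during the PSM-level competition."""

    rows: list[tuple[str, str, float]]


def _competition_order(
    comp: ScoredCompetition, rng: np.random.Generator
) -> np.ndarray:
    """Indices sorting entries by decreasing score, ties broken
    uniformly at random from the module RNG."""
    scores = np.array([w for w, _, _ in comp.entries], dtype=float)
    jitter = rng.random(len(scores))
    return np.lexsort((jitter, -scores))


def _fdr_levels(labels_sorted: np.ndarray) -> np.ndarray:
    decoys = np.cumsum(labels_sorted == -1)
    targets = np.cumsum(labels_sorted == 1)
    return (decoys + 1) / np.maximum(targets, 1)


def tdc_threshold(
    comp: ScoredCompetition,
    alpha: float,
    rng: np.random.Generator | int | None = None,
) -> tuple[int, list[str]]:
    """TDC rejection index and reported target identifiers at level
    ``alpha``.  Returns ``(0, [])`` when no index satisfies the rule."""
    if not 0 < alpha <= 1:
        raise ValueError("alpha must lie in (0, 1]")
    if not comp.entries:
        raise ValueError("competition has no entries")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    order = _competition_order(comp, rng)
    labels = np.array([comp.entries[i][1] for i in order])
    fdr = _fdr_levels(labels)
    passing = np.flatnonzero(fdr <= alpha)
    if passing.size == 0:
        return 0, []
    K = int(passing[-1]) + 1
    discoveries = [
        comp.entries[i][2] for i in order[:K] if comp.entries[i][1] == 1
    ]
    return K, discoveries


def tdc_qvalues(
    comp: ScoredCompetition,
    rng: np.random.Generator | int | None = None,
) -> dict[str, float]:
    """q-value of every target entry under the TDC sweep.

    The q-value of the target at sorted position ``k`` is the minimum of
    ``(D_j + 1) / max(T_j, 1)`` over ``j >= k``, so the targets with
    ``q <= alpha`` are exactly those reported by :func:`tdc_threshold`
    at ``alpha`` under the same tie-broken order.  Values above 1 mark
    entries that no level ``alpha <= 1`` can report; cap them at the
    caller if a proper q-value scale is needed.
    """
    if not comp.entries:
        return {}
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    order = _competition_order(comp, rng)
    labels = np.array([comp.entries[i][1] for i in order])
    fdr = _fdr_levels(labels)
    q = np.minimum.accumulate(fdr[::-1])[::-1]
    return {
        comp.entries[i][2]: float(q[pos])
        for pos, i in enumerate(order)
        if comp.entries[i][1] == 1
    }


def psm_and_peptide(
    psms: PsmTable,
    pairing: Mapping[str, str],
    alpha: float,
    rng: np.random.Generator | int | None = None,
) -> list[str]:
    """Peptide-level TDC via the PSM-and-peptide double competition.

    First each spectrum keeps its best-scoring PSM (ties broken
    randomly); each target or decoy peptide is then scored by the
    maximum over its surviving PSMs, with the sentinel-lowest score when
    it has none.  Within each target-decoy pair only the higher scorer
    survives (ties random), producing the ``(W, L)`` list fed to
    :func:`tdc_threshold`.  Pairs in which neither peptide was observed
    are dropped.  Returns the discovered target peptides.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    decoy_of = dict(pairing)
    target_of = {d: t for t, d in decoy_of.items()}
    if len(target_of) != len(decoy_of):
        raise ValueError("pairing must be one-to-one")

    best_per_spectrum: dict[str, tuple[float, float, str]] = {}
    for spectrum, peptide, score in psms.rows:
        if peptide not in decoy_of and peptide not in target_of:
            raise ValueError(f"peptide {peptide!r} has no target-decoy pair")
        key = (score, rng.random(), peptide)
        if spectrum not in best_per_spectrum or key > best_per_spectrum[spectrum]:
            best_per_spectrum[spectrum] = key

    peptide_score: dict[str, float] = {}
    for score, _, peptide in best_per_spectrum.values():
        peptide_score[peptide] = max(
            peptide_score.get(peptide, SENTINEL_LOWEST), score
        )

    entries: list[tuple[float, int, str]] = []
    for target, decoy in decoy_of.items():
        t_score = peptide_score.get(target, SENTINEL_LOWEST)
        d_score = peptide_score.get(decoy, SENTINEL_LOWEST)
        if t_score == SENTINEL_LOWEST and d_score == SENTINEL_LOWEST:
            continue
        if t_score > d_score:
            winner, label = (t_score, 1)
        elif d_score > t_score:
            winner, label = (d_score, -1)
        else:
            label = 1 if rng.random() < 0.5 else -1
            winner = t_score
        entries.append((winner, label, target))
    if not entries:
        return []
    _, discoveries = tdc_threshold(ScoredCompetition(entries), alpha, rng)
    return discoveries


def empirical_pvalues(
    target_scores: Sequence[float],
    decoy_scores: Sequence[float],
    add_one: bool = False,
) -> np.ndarray:
    """Empirical p-value of each target score against the decoy score
    distribution: the proportion of decoys scoring at least as high.

    ``add_one`` applies the (count+1)/(n+1) correction that keeps
    p-values strictly positive; it is off by default.
    """
    decoys = np.sort(np.asarray(decoy_scores, dtype=float))
    if decoys.size == 0:
        raise ValueError("decoy score list must be non-empty")
    targets = np.asarray(target_scores, dtype=float)
    at_least = decoys.size - np.searchsorted(decoys, targets, side="left")
    if add_one:
        return (at_least + 1) / (decoys.size + 1)
    return at_least / decoys.size


def _validate_pvalues(pvalues: Sequence[float]) -> np.ndarray:
    p = np.asarray(pvalues, dtype=float)
    if p.size and (np.any(p < 0) or np.any(p > 1) or np.any(np.isnan(p))):
        raise ValueError("p-values must lie in [0, 1]")
    return p


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = _validate_pvalues(pvalues)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def _pi0_smoother(p: np.ndarray, lambdas: np.ndarray) -> float:
    pi0_lambda = np.array(
        [np.mean(p > lam) / (1.0 - lam) for lam in lambdas]
    )
    coeffs = np.polyfit(lambdas, pi0_lambda, deg=3)
    return float(np.polyval(coeffs, lambdas.max()))


def _pi0_bootstrap(
    p: np.ndarray, lambdas: np.ndarray, n_boot: int = 100, seed: int = 0
) -> float:
    """Storey's bootstrap pi0: pick the lambda minimizing the estimated
    mean squared error around the smallest candidate pi0."""
    rng = np.random.default_rng(seed)
    pi0_lambda = np.array([np.mean(p > lam) / (1.0 - lam) for lam in lambdas])
    target = min(pi0_lambda.min(), 1.0)
    mse = np.zeros_like(lambdas)
    for _ in range(n_boot):
        sample = rng.choice(p, size=p.size, replace=True)
        boot = np.array([np.mean(sample > lam) / (1.0 - lam) for lam in lambdas])
        mse += (boot - target) ** 2
    return float(pi0_lambda[int(np.argmin(mse))])


def storey_qvalues(
    pvalues: Sequence[float],
    pi0_method: str = "smoother",
    pi0: float | None = None,
) -> np.ndarray:
    """Storey q-values: ``pi0`` times the BH step-up adjustment.

    ``pi0`` (the null proportion) is estimated over the lambda grid
    0.05, 0.10, ..., 0.95 with a cubic smoother evaluated at the largest
    lambda (default) or Storey's bootstrap (``pi0_method="bootstrap"``).
    A fixed ``pi0`` can be supplied instead; ``pi0 = 1`` reproduces BH
    exactly.  Degenerate inputs clamp pi0 to 1 with a warning.
    """
    p = _validate_pvalues(pvalues)
    if p.size == 0:
        return p
    if pi0 is None:
        lambdas = np.arange(0.05, 0.951, 0.05)
        if np.all(p >= lambdas.max()):
            warnings.warn(
                "degenerate p-values (all above the lambda grid); "
                "clamping pi0 to 1",
                stacklevel=2,
            )
            pi0 = 1.0
        elif pi0_method == "smoother":
            pi0 = _pi0_smoother(p, lambdas)
        elif pi0_method == "bootstrap":
            pi0 = _pi0_bootstrap(p, lambdas)
        else:
            raise ValueError(f"unknown pi0 method {pi0_method!r}")
        if pi0 > 1.0:
            pi0 = 1.0
        if pi0 <= 0.0:
            warnings.warn(
                "estimated pi0 <= 0; clamping to the smallest usable "
                "value 1/m",
                stacklevel=2,
            )
            pi0 = 1.0 / p.size
    elif not 0 < pi0 <= 1:
        raise ValueError("pi0 must lie in (0, 1]")
    return pi0 * bh_adjust(p)
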