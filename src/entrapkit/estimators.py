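"""False discovery proportion (FDP) estimation from entrapment experiments.

Given a ranked list of discoveries whose target/entrapment origin is
known (but was hidden from the search tool), these estimators gauge the
FDP of the tool's reported list.  With ``N_T`` original-target and
``N_E`` entrapment discoveries at a cutoff, and ``r`` the effective
entrapment-to-original database-size ratio:

* **lower bound**:  ``N_E / (N_T + N_E)`` — a lower bound on the FDP of
  the combined target+entrapment list (any entrapment discovery is
  false).  Can only expose *broken* FDR control.
* **combined**:  ``N_E (1 + 1/r) / (N_T + N_E)`` — on average an upper
  bound under an equal-chance assumption; with ``r = 1`` it is the
  classic concatenated target-decoy estimate.
* **sample**:  ``(N_E / r) / N_T`` — estimates the FDP among original
  target discoveries only; typically underestimates but can also
  overestimate, so it supports neither validation nor refutation.
* **paired**:  using one-to-one original/entrapment pairing (``r = 1``),
  ``(N_E + N_{E>=s>T} + 2 N_{E>T>=s}) / (N_T + N_E)`` — a tighter
  average upper bound than the combined method.
* **k-matched**: the generalization of the paired estimator to ``k``
  entrapment partners per original (``r = k``); reduces exactly to the
  paired estimator at ``k = 1``.

All estimators are reported both raw and clipped to [0, 1].
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SENTINEL_LOWEST",
    "MissingPairWarning",
    "DiscoveryRecord",
    "DiscoveryList",
    "FdpCurve",
    "estimate_lower",
    "estimate_combined",
    "estimate_sample",
    "estimate_paired",
    "estimate_k_matched",
    "fdp_curve",
    "coverage_band",
    "inflation_rate",
    "direct_fdp",
]

#: Score assigned to a peptide with no matching observation.  Any real
#: score beats it and two sentinels tie.
SENTINEL_LOWEST = float("-inf")


class MissingPairWarning(UserWarning):
    """An entrapment discovery's paired original has no record at all
    (e.g. the tool never reported it); it is scored sentinel-lowest."""

METHODS = ("lower", "combined", "sample", "paired", "k_matched")


@dataclass(frozen=True)
class DiscoveryRecord:
    """One reported discovery (peptide, precursor or protein group)."""

    identifier: str
    origin: str  # original | entrapment
    score: float | None = None
    q_value: float | None = None
    pair_group: int | None = None

    def __post_init__(self) -> None:
        if self.origin not in ("original", "entrapment"):
            raise ValueError(f"unknown origin {self.origin!r}")
        if self.score is None and self.q_value is None:
            raise ValueError(
                f"record {self.identifier!r} needs a score or a q-value"
            )
        if self.q_value is not None and not 0 <= self.q_value <= 1:
            raise ValueError("q_value must lie in [0, 1]")


class DiscoveryList:
    """A labeled discovery list with cached array views.

    ``r`` is the entrapment-to-original database ratio and ``k`` the
    number of entrapment partners per original for paired designs.
    When a record has no score, ``-q_value`` is used as a monotone score
    surrogate (with a warning).
    """

    def __init__(
        self,
        records: Sequence[DiscoveryRecord],
        r: float = 1.0,
        k: int | None = None,
    ) -> None:
        if r <= 0:
            raise ValueError("r must be positive")
        self.records = list(records)
        self.r = float(r)
        self.k = k
        if any(rec.score is None for rec in self.records):
            warnings.warn(
                "some records lack a score; using -q_value as a monotone "
                "score surrogate",
                stacklevel=2,
            )
        self.scores = np.array(
            [
                rec.score if rec.score is not None else -rec.q_value
                for rec in self.records
            ],
            dtype=float,
        )
        self.q_values = np.array(
            [math.nan if rec.q_value is None else rec.q_value for rec in self.records],
            dtype=float,
        )
        self.is_entrapment = np.array(
            [rec.origin == "entrapment" for rec in self.records], dtype=bool
        )
        self.pair_groups = np.array(
            [-1 if rec.pair_group is None else rec.pair_group for rec in self.records],
            dtype=int,
        )

    def __len__(self) -> int:
        return len(self.records)

    @property
    def has_pairing(self) -> bool:
        return bool(np.any(self.pair_groups[self.is_entrapment] >= 0))

    def require_pairing(self) -> None:
        # a list without entrapment discoveries is trivially fine
        unpaired = self.is_entrapment & (self.pair_groups < 0)
        if np.any(unpaired):
            raise ValueError(
                "paired/k-matched estimation needs pair_group on every "
                "entrapment record; use the combined or lower-bound "
                "methods for unpaired (e.g. foreign) entrapment databases"
            )

    @property
    def paired_scores(self) -> dict[int, tuple[float, list[float]]]:
        """pair_group -> (original score, entrapment scores); peptides
        absent from the list carry the sentinel-lowest score."""
        out: dict[int, tuple[float, list[float]]] = {}
        for rec, score in zip(self.records, self.scores):
            if rec.pair_group is None:
                continue
            orig, ents = out.get(rec.pair_group, (SENTINEL_LOWEST, []))
            if rec.origin == "original":
                orig = float(score)
            else:
                ents = ents + [float(score)]
            out[rec.pair_group] = (orig, ents)
        return out


# ---------------------------------------------------------------------------
# count-based estimators
# ---------------------------------------------------------------------------


def _check_counts(n_T: int, n_E: int) -> None:
    if n_T < 0 or n_E < 0:
        raise ValueError("discovery counts must be non-negative")


def estimate_lower(n_T: int, n_E: int) -> float:
    """Lower bound on the FDP of the target+entrapment list:
    ``N_E / (N_T + N_E)`` (0 on an empty list)."""
    _check_counts(n_T, n_E)
    if n_T + n_E == 0:
        return 0.0
    return n_E / (n_T + n_E)


def estimate_combined(n_T: int, n_E: int, r: float) -> float:
    """Combined (average upper-bound) estimate:
    ``N_E (1 + 1/r) / (N_T + N_E)`` (0 on an empty list)."""
    _check_counts(n_T, n_E)
    if r <= 0:
        raise ValueError("r must be positive")
    if n_T + n_E == 0:
        return 0.0
    return n_E * (1.0 + 1.0 / r) / (n_T + n_E)


def estimate_sample(n_T: int, n_E: int, r: float) -> float:
    """Sample estimate of the FDP among original-target discoveries
    only: ``(N_E / r) / N_T``.

    With ``N_T = 0`` and ``N_E > 0`` the ratio is undefined; it is
    reported as 1.0 with a warning.
    """
    _check_counts(n_T, n_E)
    if r <= 0:
        raise ValueError("r must be positive")
    if n_T == 0:
        if n_E == 0:
            return 0.0
        warnings.warn(
            "sample estimate undefined with no original-target "
            "discoveries; reporting clipped value 1.0",
            stacklevel=2,
        )
        return 1.0
    return (n_E / r) / n_T


# ---------------------------------------------------------------------------
# paired / k-matched estimators
# ---------------------------------------------------------------------------


def _group_arrays(dlist: DiscoveryList, selected: np.ndarray):
    """Per-pair-group quantities over a boolean discovery mask.

    Returns (t_in, t_score, e_max) dictionaries keyed by pair group:
    whether the original is discovered, its score, and the best score
    among *discovered* entrapment partners (sentinel if none).
    """
    t_in: dict[int, bool] = {}
    t_score: dict[int, float] = {}
    e_max: dict[int, float] = {}
    e_count: dict[int, int] = {}
    for idx in np.flatnonzero(dlist.pair_groups >= 0):
        group = int(dlist.pair_groups[idx])
        score = float(dlist.scores[idx])
        if dlist.is_entrapment[idx]:
            e_count[group] = e_count.get(group, 0) + 1
            if selected[idx]:
                e_max[group] = max(e_max.get(group, SENTINEL_LOWEST), score)
        else:
            t_score[group] = score
            if selected[idx]:
                t_in[group] = True
    return t_in, t_score, e_max, e_count


def _paired_numerator_terms(
    dlist: DiscoveryList, selected: np.ndarray, k: int
) -> tuple[int, float, int, int, int]:
    """The k-matched numerator pieces over a discovery mask.

    ``beats`` counts pair groups whose best discovered entrapment
    strictly beats the (discovered or sentinel-scored) original;
    ``beaten`` counts discovered originals strictly beaten by one of
    their discovered entrapment partners.  At ``k = 1`` these are
    ``N_{E>=s>T} + N_{E>T>=s}`` and ``N_{E>T>=s}``.
    """
    t_in, t_score, e_max, e_count = _group_arrays(dlist, selected)
    bad = {g: c for g, c in e_count.items() if c > k}
    if bad:
        raise ValueError(
            f"pairing cardinality exceeds k={k} for pair groups "
            f"{sorted(bad)[:5]}"
        )
    missing_orig = [g for g in e_max if g not in t_score]
    if missing_orig:
        warnings.warn(
            "entrapment discoveries whose paired original has no record "
            "at all; treating the original as sentinel-lowest "
            f"(pair groups {sorted(missing_orig)[:5]})",
            MissingPairWarning,
            stacklevel=3,
        )
    n_T = int(np.sum(selected & ~dlist.is_entrapment))
    n_E = int(np.sum(selected & dlist.is_entrapment))
    beats = 0
    beaten = 0
    for group, emax in e_max.items():
        t_eff = t_score.get(group, SENTINEL_LOWEST)
        if not t_in.get(group, False):
            t_eff = SENTINEL_LOWEST
        if emax > t_eff:
            beats += 1
        if t_in.get(group, False) and emax > t_score[group]:
            beaten += 1
    return n_T, n_E, beats, beaten, len(e_max)


def estimate_paired(dlist: DiscoveryList, cutoff: float) -> float:
    """Paired estimate at score cutoff ``s``:
    ``(N_E + N_{E>=s>T} + 2 N_{E>T>=s}) / (N_T + N_E)``.

    ``N_{E>=s>T}`` counts discovered entrapments whose paired original
    scored below the cutoff; ``N_{E>T>=s}`` counts discovered
    entrapments whose paired original was also discovered but scored
    strictly lower.  Requires a one-to-one pairing (``r = 1``).
    """
    if not math.isclose(dlist.r, 1.0):
        raise ValueError("the paired estimator requires r = 1; use "
                         "estimate_k_matched for k-fold designs")
    return estimate_k_matched(dlist, cutoff, k=1)


def estimate_k_matched(dlist: DiscoveryList, cutoff: float, k: int) -> float:
    """k-matched generalization of the paired estimate (``r = k``).

    Each original has ``k`` entrapment partners.  The numerator adds to
    ``N_E`` (every discovered entrapment is false) an estimate of the
    number of false original-target discoveries: ``1/k`` times the
    number of pair groups whose best discovered entrapment beats the
    original (by score exchangeability each of the k partners of a false
    original is as likely as the original itself to top its group), plus
    the number of discovered originals beaten by one of their discovered
    partners.  Reduces exactly to the paired estimate at ``k = 1``.
    """
    if k < 1:
        raise ValueError("k must be a positive integer")
    if dlist.k is not None and dlist.k != k:
        raise ValueError(f"discovery list declares k={dlist.k}, got k={k}")
    dlist.require_pairing()
    selected = dlist.scores >= cutoff
    return _k_matched_on_mask(dlist, selected, k)


def _k_matched_on_mask(dlist: DiscoveryList, selected: np.ndarray, k: int) -> float:
    n_T, n_E, beats, beaten, _ = _paired_numerator_terms(dlist, selected, k)
    if n_T + n_E == 0:
        return 0.0
    return (n_E + beats / k + beaten) / (n_T + n_E)


# ---------------------------------------------------------------------------
# curves, bands and summary metrics
# ---------------------------------------------------------------------------


@dataclass
class FdpCurve:
    """Per-threshold FDP estimates for one or more methods.

    ``estimates`` holds values clipped to [0, 1]; ``raw_estimates`` the
    unclipped diagnostics.  ``band_half_width`` (when present) is the
    95% coverage half-width ``1.96 * sigma_n / sqrt(n)`` per method.
    """

    thresholds: np.ndarray
    estimates: dict[str, np.ndarray]
    raw_estimates: dict[str, np.ndarray]
    n_T: np.ndarray
    n_E: np.ndarray
    band_half_width: dict[str, np.ndarray] | None = None

    def __post_init__(self) -> None:
        n = len(self.thresholds)
        for name, values in {**self.estimates, **self.raw_estimates}.items():
            if len(values) != n:
                raise ValueError(f"length mismatch for method {name!r}")

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: threshold, method, raw, clipped, band."""
        rows = []
        for method, clipped in self.estimates.items():
            raw = self.raw_estimates[method]
            half = (
                self.band_half_width.get(method)
                if self.band_half_width is not None
                else None
            )
            for i, threshold in enumerate(self.thresholds):
                rows.append(
                    {
                        "threshold": float(threshold),
                        "method": method,
                        "raw": float(raw[i]),
                        "clipped": float(clipped[i]),
                        "band_lo": float(clipped[i] - half[i]) if half is not None else math.nan,
                        "band_hi": float(clipped[i] + half[i]) if half is not None else math.nan,
                        "n_T": int(self.n_T[i]),
                        "n_E": int(self.n_E[i]),
                    }
                )
        return pd.DataFrame(rows)


def fdp_curve(
    dlist: DiscoveryList,
    methods: Iterable[str] = ("lower", "combined", "paired"),
    thresholds: Sequence[float] | str = "reported",
) -> FdpCurve:
    """Evaluate estimators across FDR thresholds.

    At threshold ``t`` the discovery set is every record with reported
    ``q_value <= t``.  For the paired/k-matched methods a record counts
    as discovered by the same rule, and score comparisons use the score
    column (or its surrogate).  ``thresholds="reported"`` uses all
    distinct reported q-values.
    """
    methods = list(methods)
    unknown = set(methods) - set(METHODS)
    if unknown:
        raise ValueError(f"unknown methods: {sorted(unknown)}")
    if np.any(np.isnan(dlist.q_values)):
        raise ValueError("thresholding by reported FDR requires a q-value "
                         "on every record")
    if isinstance(thresholds, str):
        if thresholds != "reported":
            raise ValueError(f"unknown threshold rule {thresholds!r}")
        grid = np.unique(dlist.q_values)
    else:
        grid = np.asarray(thresholds, dtype=float)
        if np.any(np.diff(grid) < 0):
            raise ValueError("thresholds must be ascending")
    if any(m in ("paired", "k_matched") for m in methods):
        dlist.require_pairing()
    k = dlist.k if dlist.k is not None else max(int(round(dlist.r)), 1)

    raw: dict[str, list[float]] = {m: [] for m in methods}
    n_T_list, n_E_list = [], []
    for t in grid:
        selected = dlist.q_values <= t
        n_T = int(np.sum(selected & ~dlist.is_entrapment))
        n_E = int(np.sum(selected & dlist.is_entrapment))
        n_T_list.append(n_T)
        n_E_list.append(n_E)
        for method in methods:
            if method == "lower":
                value = estimate_lower(n_T, n_E)
            elif method == "combined":
                value = estimate_combined(n_T, n_E, dlist.r)
            elif method == "sample":
                if n_T == 0 and n_E > 0:
                    value = math.inf
                else:
                    value = estimate_sample(n_T, n_E, dlist.r) if n_T else 0.0
            elif method == "paired":
                value = _k_matched_on_mask(dlist, selected, 1)
            else:  # k_matched
                value = _k_matched_on_mask(dlist, selected, k)
            raw[method].append(value)

    raw_arrays = {m: np.array(v, dtype=float) for m, v in raw.items()}
    clipped = {m: np.clip(v, 0.0, 1.0) for m, v in raw_arrays.items()}
    return FdpCurve(
        thresholds=grid,
        estimates=clipped,
        raw_estimates=raw_arrays,
        n_T=np.array(n_T_list),
        n_E=np.array(n_E_list),
    )


def coverage_band(curves: Sequence[FdpCurve]) -> FdpCurve:
    """Average replicate curves and attach 95% coverage bands.

    The half-width at each threshold is ``1.96 * sigma_n / sqrt(n)``
    with ``sigma_n`` the sample standard deviation over the ``n``
    replicate estimates.
    """
    if len(curves) < 2:
        raise ValueError("coverage bands require at least two replicates")
    base = curves[0].thresholds
    for curve in curves[1:]:
        if len(curve.thresholds) != len(base) or not np.allclose(
            curve.thresholds, base
        ):
            raise ValueError("replicate curves have misaligned thresholds")
    methods = set(curves[0].estimates)
    for curve in curves[1:]:
        methods &= set(curve.estimates)
    n = len(curves)
    mean_clipped, mean_raw, half_widths = {}, {}, {}
    for method in sorted(methods):
        stack = np.vstack([c.estimates[method] for c in curves])
        raw_stack = np.vstack([c.raw_estimates[method] for c in curves])
        mean_clipped[method] = stack.mean(axis=0)
        mean_raw[method] = raw_stack.mean(axis=0)
        half_widths[method] = 1.96 * stack.std(axis=0, ddof=1) / math.sqrt(n)
    return FdpCurve(
        thresholds=base.copy(),
        estimates=mean_clipped,
        raw_estimates=mean_raw,
        n_T=np.vstack([c.n_T for c in curves]).mean(axis=0),
        n_E=np.vstack([c.n_E for c in curves]).mean(axis=0),
        band_half_width=half_widths,
    )


def inflation_rate(n_reported: int, n_at_estimated: int) -> float:
    """Percent inflation of a tool's discovery count relative to the
    count at which the entrapment-estimated FDP reaches the nominal
    level: ``100 * (n1 - n2) / n2``."""
    if n_at_estimated <= 0:
        raise ValueError("reference discovery count must be positive")
    return 100.0 * (n_reported - n_at_estimated) / n_at_estimated


def direct_fdp(n_native: int, n_foreign: int, n_entrapment: int) -> float:
    """Direct FDP estimate for a double-entrapment experiment: foreign
    and shuffled-entrapment discoveries are known false, so the FDP is
    their share of all discoveries (0 on an empty list)."""
    for n in (n_native, n_foreign, n_entrapment):
        if n < 0:
            raise ValueError("counts must be non-negative")
    total = n_native + n_foreign + n_entrapment
    if total == 0:
        return 0.0
    return (n_foreign + n_entrapment) / total
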