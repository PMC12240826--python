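"""FDP estimator contracts, algebraic identities and brute-force oracles."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from entrapkit.estimators import (
    SENTINEL_LOWEST,
    DiscoveryList,
    DiscoveryRecord,
    MissingPairWarning,
    coverage_band,
    direct_fdp,
    estimate_combined,
    estimate_k_matched,
    estimate_lower,
    estimate_paired,
    estimate_sample,
    fdp_curve,
    inflation_rate,
)


def brute_force_paired(dlist: DiscoveryList, cutoff: float) -> float:
    """Independent O(n^2) recount of the paired estimate's three terms.

    Walks the raw records: discovered = score >= cutoff; for each
    discovered entrapment, finds its paired original by scanning the
    whole list (sentinel-lowest if absent).
    """
    records = dlist.records
    discovered = [r for r in records if r.score >= cutoff]
    n_T = sum(1 for r in discovered if r.origin == "original")
    n_E = sum(1 for r in discovered if r.origin == "entrapment")
    n_e_above_t_below = 0  # N_{E>=s>T}
    n_e_beats_t_discovered = 0  # N_{E>T>=s}
    for entrap in discovered:
        if entrap.origin != "entrapment":
            continue
        partner_score = SENTINEL_LOWEST
        for other in records:
            if other.origin == "original" and other.pair_group == entrap.pair_group:
                partner_score = other.score
        if partner_score < cutoff:
            n_e_above_t_below += 1
        elif entrap.score > partner_score:
            n_e_beats_t_discovered += 1
    if n_T + n_E == 0:
        return 0.0
    return (n_E + n_e_above_t_below + 2 * n_e_beats_t_discovered) / (n_T + n_E)


def random_paired_list(rng: np.random.Generator, max_records: int = 20):
    """A random discovery list with one-to-one pairing: each pair group
    has one original and at most one entrapment record, and either side
    may be missing (unreported)."""
    n_groups = int(rng.integers(1, max_records // 2 + 1))
    records = []
    for group in range(n_groups):
        t_score = float(rng.integers(0, 8))  # integer scores force ties
        e_score = float(rng.integers(0, 8))
        has_t, has_e = rng.random() < 0.85, rng.random() < 0.85
        if has_t:
            records.append(
                DiscoveryRecord(f"t{group}", "original", t_score, pair_group=group)
            )
        if has_e:
            records.append(
                DiscoveryRecord(f"e{group}", "entrapment", e_score, pair_group=group)
            )
    return DiscoveryList(records, r=1.0, k=1)


class TestCountEstimators:
    def test_lower_bound_examples(self):
        assert estimate_lower(9, 1) == pytest.approx(0.1)
        assert estimate_lower(5, 0) == 0.0
        assert estimate_lower(0, 0) == 0.0

    def test_lower_bound_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            estimate_lower(-1, 0)

    def test_combined_examples(self):
        assert estimate_combined(9, 1, r=1) == pytest.approx(0.2)
        assert estimate_combined(8, 2, r=5) == pytest.approx(0.24)
        assert estimate_combined(5, 0, r=3) == 0.0

    def test_combined_requires_positive_r(self):
        with pytest.raises(ValueError):
            estimate_combined(1, 1, r=0)

    def test_sample_examples(self):
        assert estimate_sample(10, 2, r=2) == pytest.approx(0.1)
        assert estimate_sample(10, 0, r=1) == 0.0

    def test_sample_degenerate_no_targets_warns_and_clips(self):
        with pytest.warns(UserWarning, match="undefined"):
            assert estimate_sample(0, 3, r=1) == 1.0

    @given(
        n_T=st.integers(0, 500),
        n_E=st.integers(0, 500),
        r=st.sampled_from([0.5, 1.0, 2.0, 5.0]),
    )
    def test_combined_is_lower_times_one_plus_inv_r(self, n_T, n_E, r):
        if n_T + n_E == 0:
            return
        combined = estimate_combined(n_T, n_E, r)
        lower = estimate_lower(n_T, n_E)
        assert combined == pytest.approx(lower * (1 + 1 / r))
        assert lower <= combined


class TestPairedEstimator:
    def test_entrapment_beating_undiscovered_partner(self):
        records = [
            DiscoveryRecord("t1", "original", 10, pair_group=1),
            DiscoveryRecord("t2", "original", 8, pair_group=2),
            DiscoveryRecord("e1", "entrapment", 9, pair_group=3),
            DiscoveryRecord("t3", "original", 2, pair_group=3),
        ]
        dlist = DiscoveryList(records, r=1.0, k=1)
        assert estimate_paired(dlist, 5) == pytest.approx(2 / 3)

    def test_entrapment_below_its_discovered_partner_counts_once(self):
        records = [
            DiscoveryRecord("t1", "original", 10, pair_group=1),
            DiscoveryRecord("e2", "entrapment", 7, pair_group=1),
        ]
        dlist = DiscoveryList(records, r=1.0, k=1)
        assert estimate_paired(dlist, 5) == pytest.approx(0.5)

    def test_no_entrapment_discoveries_gives_zero(self):
        records = [
            DiscoveryRecord("t1", "original", 10, pair_group=1),
            DiscoveryRecord("e1", "entrapment", 1, pair_group=1),
        ]
        assert estimate_paired(DiscoveryList(records, r=1.0, k=1), 5) == 0.0

    def test_missing_pairing_directs_to_other_methods(self):
        records = [DiscoveryRecord("e1", "entrapment", 9)]
        with pytest.raises(ValueError, match="combined or lower"):
            estimate_paired(DiscoveryList(records, r=1.0), 5)

    def test_partner_with_no_record_at_all_warns(self):
        records = [DiscoveryRecord("e1", "entrapment", 9, pair_group=4)]
        with pytest.warns(MissingPairWarning):
            value = estimate_paired(DiscoveryList(records, r=1.0, k=1), 5)
        assert value == pytest.approx(2.0)  # raw value may exceed 1

    def test_all_partners_below_cutoff_degenerates_to_combined_r1(self):
        records = [
            DiscoveryRecord("t1", "original", 10, pair_group=1),
            DiscoveryRecord("e1", "entrapment", 9, pair_group=2),
            DiscoveryRecord("t2", "original", 1, pair_group=2),
            DiscoveryRecord("e2", "entrapment", 8, pair_group=3),
            DiscoveryRecord("t3", "original", 2, pair_group=3),
        ]
        dlist = DiscoveryList(records, r=1.0, k=1)
        n_T, n_E = 1, 2
        assert estimate_paired(dlist, 5) == pytest.approx(2 * n_E / (n_T + n_E))
        assert estimate_paired(dlist, 5) == pytest.approx(
            estimate_combined(n_T, n_E, r=1)
        )

    def test_matches_brute_force_on_random_lists(self):
        rng = np.random.default_rng(42)
        for _ in range(300):
            dlist = random_paired_list(rng)
            cutoff = float(rng.integers(0, 9))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", MissingPairWarning)
                assert estimate_paired(dlist, cutoff) == pytest.approx(
                    brute_force_paired(dlist, cutoff)
                )

    def test_requires_r_equal_one(self):
        records = [DiscoveryRecord("t1", "original", 1, pair_group=0)]
        with pytest.raises(ValueError, match="r = 1"):
            estimate_paired(DiscoveryList(records, r=2.0), 0)


class TestKMatchedEstimator:
    def test_reduces_to_paired_at_k_one(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            dlist = random_paired_list(rng)
            cutoff = float(rng.integers(0, 9))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", MissingPairWarning)
                assert estimate_k_matched(dlist, cutoff, k=1) == pytest.approx(
                    estimate_paired(dlist, cutoff)
                )

    def test_k2_toy_list_hand_computed(self):
        # three pair groups, k=2, cutoff 5; worked by hand:
        # g0: T=10 disc, E={9,3}: contributes N_E=1, no beats/beaten
        # g1: T=4 not disc, E={8,6}: N_E=2, best E beats sentinel -> beats
        # g2: T=7 disc, E={7.5,1}: N_E=1, 7.5 > 7 -> beats and beaten
        # value = (4 + 2/2 + 1) / (2 + 4) = 1.0
        records = [
            DiscoveryRecord("t0", "original", 10, pair_group=0),
            DiscoveryRecord("e0a", "entrapment", 9, pair_group=0),
            DiscoveryRecord("e0b", "entrapment", 3, pair_group=0),
            DiscoveryRecord("t1", "original", 4, pair_group=1),
            DiscoveryRecord("e1a", "entrapment", 8, pair_group=1),
            DiscoveryRecord("e1b", "entrapment", 6, pair_group=1),
            DiscoveryRecord("t2", "original", 7, pair_group=2),
            DiscoveryRecord("e2a", "entrapment", 7.5, pair_group=2),
            DiscoveryRecord("e2b", "entrapment", 1, pair_group=2),
        ]
        dlist = DiscoveryList(records, r=2.0, k=2)
        assert estimate_k_matched(dlist, 5, k=2) == pytest.approx(1.0)

    def test_no_entrapment_discoveries_gives_zero(self):
        records = [
            DiscoveryRecord("t0", "original", 10, pair_group=0),
            DiscoveryRecord("e0a", "entrapment", 1, pair_group=0),
            DiscoveryRecord("e0b", "entrapment", 2, pair_group=0),
        ]
        assert estimate_k_matched(DiscoveryList(records, r=2.0, k=2), 5, k=2) == 0.0

    def test_dominates_lower_bound(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            n_groups = int(rng.integers(1, 8))
            records = []
            for g in range(n_groups):
                records.append(
                    DiscoveryRecord(
                        f"t{g}", "original", float(rng.integers(0, 8)), pair_group=g
                    )
                )
                for j in range(2):
                    records.append(
                        DiscoveryRecord(
                            f"e{g}_{j}",
                            "entrapment",
                            float(rng.integers(0, 8)),
                            pair_group=g,
                        )
                    )
            dlist = DiscoveryList(records, r=2.0, k=2)
            cutoff = float(rng.integers(0, 9))
            selected = dlist.scores >= cutoff
            n_T = int(np.sum(selected & ~dlist.is_entrapment))
            n_E = int(np.sum(selected & dlist.is_entrapment))
            assert estimate_k_matched(dlist, cutoff, k=2) >= estimate_lower(n_T, n_E)

    def test_cardinality_mismatch_rejected(self):
        records = [
            DiscoveryRecord("t0", "original", 10, pair_group=0),
            DiscoveryRecord("e0a", "entrapment", 9, pair_group=0),
            DiscoveryRecord("e0b", "entrapment", 8, pair_group=0),
        ]
        with pytest.raises(ValueError, match="cardinality"):
            estimate_k_matched(DiscoveryList(records, r=1.0), 5, k=1)


def _qlist():
    records = [
        DiscoveryRecord("t1", "original", 10, 0.001, pair_group=0),
        DiscoveryRecord("e1", "entrapment", 9, 0.005, pair_group=1),
        DiscoveryRecord("t0", "original", 2, 0.02, pair_group=1),
        DiscoveryRecord("t2", "original", 8, 0.008, pair_group=2),
        DiscoveryRecord("e2", "entrapment", 1, 0.9, pair_group=2),
    ]
    return DiscoveryList(records, r=1.0, k=1)


class TestFdpCurve:
    def test_single_threshold_reproduces_point_estimators(self):
        dlist = _qlist()
        curve = fdp_curve(dlist, ("lower", "combined", "sample", "paired"), [0.01])
        # at q <= 0.01: t1, e1, t2 discovered
        assert curve.n_T[0] == 2 and curve.n_E[0] == 1
        assert curve.estimates["lower"][0] == pytest.approx(estimate_lower(2, 1))
        assert curve.estimates["combined"][0] == pytest.approx(
            estimate_combined(2, 1, 1)
        )
        assert curve.estimates["sample"][0] == pytest.approx(estimate_sample(2, 1, 1))
        # paired: e1 discovered, partner t0 not discovered -> beats term
        assert curve.estimates["paired"][0] == pytest.approx((1 + 1) / 3)

    def test_empty_threshold_gives_zero_everywhere(self):
        curve = fdp_curve(_qlist(), ("lower", "combined", "paired"), [0.0, 0.0005])
        for method in ("lower", "combined", "paired"):
            assert np.all(curve.estimates[method] == 0.0)

    def test_discovery_counts_monotone_in_threshold(self):
        curve = fdp_curve(_qlist(), ("lower",), [0.001, 0.005, 0.01, 0.5, 1.0])
        totals = curve.n_T + curve.n_E
        assert np.all(np.diff(totals) >= 0)

    def test_reported_thresholds_are_all_q_values(self):
        curve = fdp_curve(_qlist(), ("lower",), "reported")
        assert list(curve.thresholds) == [0.001, 0.005, 0.008, 0.02, 0.9]

    def test_paired_without_pairing_rejected(self):
        records = [
            DiscoveryRecord("t", "original", 2, 0.01),
            DiscoveryRecord("e", "entrapment", 1, 0.01),  # no pair_group
        ]
        with pytest.raises(ValueError, match="pair"):
            fdp_curve(DiscoveryList(records, r=1.0), ("paired",), [0.01])

    def test_missing_q_values_rejected(self):
        records = [DiscoveryRecord("t", "original", 1.0)]
        with pytest.raises(ValueError, match="q-value"):
            fdp_curve(DiscoveryList(records, r=1.0), ("lower",), [0.01])

    def test_clipping_keeps_raw_values(self):
        records = [DiscoveryRecord("e1", "entrapment", 9, 0.01, pair_group=4)]
        with pytest.warns(MissingPairWarning):
            curve = fdp_curve(DiscoveryList(records, r=1.0, k=1), ("paired",), [0.01])
        assert curve.raw_estimates["paired"][0] == pytest.approx(2.0)
        assert curve.estimates["paired"][0] == 1.0


class TestCoverageBand:
    def test_identical_replicates_zero_width(self):
        curves = [fdp_curve(_qlist(), ("lower",), [0.01, 0.5]) for _ in range(3)]
        band = coverage_band(curves)
        assert np.allclose(band.band_half_width["lower"], 0.0)
        assert np.allclose(band.estimates["lower"], curves[0].estimates["lower"])

    def test_two_replicate_hand_computation(self):
        base = fdp_curve(_qlist(), ("lower",), [0.01])
        a = base
        b = fdp_curve(_qlist(), ("lower",), [0.01])
        a.estimates["lower"] = np.array([0.0])
        b.estimates["lower"] = np.array([0.02])
        band = coverage_band([a, b])
        assert band.estimates["lower"][0] == pytest.approx(0.01)
        sigma = np.std([0.0, 0.02], ddof=1)
        assert band.band_half_width["lower"][0] == pytest.approx(
            1.96 * sigma / math.sqrt(2)
        )

    def test_single_replicate_rejected(self):
        with pytest.raises(ValueError, match="two replicates"):
            coverage_band([fdp_curve(_qlist(), ("lower",), [0.01])])

    def test_misaligned_thresholds_rejected(self):
        a = fdp_curve(_qlist(), ("lower",), [0.01])
        b = fdp_curve(_qlist(), ("lower",), [0.02])
        with pytest.raises(ValueError, match="misaligned"):
            coverage_band([a, b])


class TestSummaryMetrics:
    def test_inflation_rate(self):
        assert inflation_rate(103, 100) == pytest.approx(3.0)
        assert inflation_rate(100, 100) == 0.0
        assert inflation_rate(90, 100) == pytest.approx(-10.0)
        with pytest.raises(ValueError):
            inflation_rate(10, 0)

    def test_direct_fdp(self):
        assert direct_fdp(90, 5, 5) == pytest.approx(0.1)
        assert direct_fdp(10, 0, 0) == 0.0
        assert direct_fdp(0, 0, 0) == 0.0

    def test_score_surrogate_warns(self):
        with pytest.warns(UserWarning, match="surrogate"):
            DiscoveryList([DiscoveryRecord("t", "original", None, 0.01)], r=1.0)
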