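import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fuzzynmr.core_io import PeakList, ValidationError
from fuzzynmr.csp import (
    FitError,
    classify_perturbed,
    contiguous_regions,
    cumulative_delta,
    detect_peak_doubling,
    linewidth_fwhm,
    track_titration,
)
from conftest import make_shift_table


def amide_table(entries, state="free"):
    """entries: residue -> (aa, H, N); None skips the residue."""
    records = []
    for res, value in entries.items():
        if value is None:
            continue
        aa, h, n = value
        records.append((res, aa, "H", h))
        records.append((res, aa, "N", n))
    return make_shift_table(records, state=state)


class TestCumulativeDelta:
    def test_identical_states_give_zero(self):
        free = amide_table({10: ("A", 8.2, 123.0)})
        bound = amide_table({10: ("A", 8.2, 123.0)}, state="bound")
        prof = cumulative_delta(free, bound)
        assert prof.per_residue.delta_cum.iloc[0] == 0.0

    def test_hand_value(self):
        # sqrt(0.09^2 + (0.14*0.857)^2) = sqrt(0.0081 + 0.0144) = 0.15
        free = amide_table({10: ("A", 8.20, 123.000)})
        bound = amide_table({10: ("A", 8.29, 123.857)}, state="bound")
        prof = cumulative_delta(free, bound, alpha=0.14)
        assert prof.per_residue.delta_cum.iloc[0] == pytest.approx(0.15, abs=1e-3)

    def test_missing_bound_residue_is_broadened(self):
        free = amide_table({10: ("A", 8.2, 123.0), 11: ("D", 8.3, 120.0)})
        bound = amide_table({10: ("A", 8.2, 123.0)}, state="bound")
        prof = cumulative_delta(free, bound)
        row = prof.per_residue.set_index("residue_index").loc[11]
        assert bool(row.broadened)
        assert np.isnan(row.delta_cum)

    def test_swap_invariance(self):
        free = amide_table({10: ("A", 8.2, 123.0)})
        bound = amide_table({10: ("A", 8.4, 121.5)}, state="bound")
        fwd = cumulative_delta(free, bound).per_residue.delta_cum.iloc[0]
        rev = cumulative_delta(bound, free).per_residue.delta_cum.iloc[0]
        assert fwd == pytest.approx(rev)

    @given(
        dh=st.floats(-0.5, 0.5), dn=st.floats(-3, 3),
        k=st.floats(0.1, 5.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_homogeneity(self, dh, dn, k):
        free = amide_table({10: ("A", 8.0, 120.0)})
        b1 = amide_table({10: ("A", 8.0 + dh, 120.0 + dn)}, state="bound")
        bk = amide_table({10: ("A", 8.0 + k * dh, 120.0 + k * dn)}, state="bound")
        d1 = cumulative_delta(free, b1).per_residue.delta_cum.iloc[0]
        dk = cumulative_delta(free, bk).per_residue.delta_cum.iloc[0]
        assert dk == pytest.approx(k * d1, rel=1e-9, abs=1e-12)

    def test_no_overlap_is_error(self):
        free = amide_table({10: ("A", 8.2, 123.0)})
        bound = amide_table({50: ("I", 8.0, 119.9)}, state="bound")
        with pytest.raises(ValidationError):
            cumulative_delta(free, bound)


class TestClassification:
    def build(self, delta_cum, broadened=False):
        free = amide_table({10: ("A", 8.2, 123.0)})
        if broadened:
            bound = amide_table({}, state="bound")
            bound = amide_table({11: ("D", 8.0, 120.0)}, state="bound")
            free = amide_table({10: ("A", 8.2, 123.0), 11: ("D", 8.0, 120.0)})
        else:
            bound = amide_table({10: ("A", 8.2 + delta_cum, 123.0)}, state="bound")
        return cumulative_delta(free, bound)

    @pytest.mark.parametrize(
        "delta,expected", [(0.16, True), (0.15, True), (0.14, False)]
    )
    def test_threshold_boundary(self, delta, expected):
        prof = classify_perturbed(self.build(delta), threshold=0.15)
        assert bool(prof.per_residue.perturbed.iloc[0]) is expected

    def test_broadened_always_perturbed(self):
        prof = classify_perturbed(self.build(0.0, broadened=True))
        row = prof.per_residue.set_index("residue_index").loc[10]
        assert bool(row.perturbed)


class TestContiguousRegions:
    def profile_from_flags(self, flags, nodata=()):
        """flags: residue -> perturbed bool; nodata residues absent entirely."""
        entries_free, entries_bound = {}, {}
        for res, hit in flags.items():
            if res in nodata:
                continue
            entries_free[res] = ("A", 8.2, 123.0)
            entries_bound[res] = ("A", 8.2 + (0.3 if hit else 0.0), 123.0)
        prof = cumulative_delta(
            amide_table(entries_free), amide_table(entries_bound, state="bound")
        )
        return classify_perturbed(prof)

    def test_single_run(self):
        flags = {r: 20 <= r <= 29 for r in range(15, 35)}
        prof = self.profile_from_flags(flags)
        assert contiguous_regions(prof, min_len=3) == [(20, 29)]

    def test_gap_bridged_only_without_data(self):
        flags = {r: r in set(range(20, 25)) | set(range(26, 30))
                 for r in range(15, 35)}
        prof = self.profile_from_flags(flags, nodata={25})
        assert contiguous_regions(prof, min_len=3) == [(20, 29)]

    def test_gap_with_data_splits(self):
        flags = {r: r in set(range(20, 25)) | set(range(26, 30))
                 for r in range(15, 35)}
        prof = self.profile_from_flags(flags)  # residue 25 measured, unperturbed
        assert contiguous_regions(prof, min_len=3) == [(20, 24), (26, 29)]

    def test_empty(self):
        prof = self.profile_from_flags({r: False for r in range(15, 35)})
        assert contiguous_regions(prof, min_len=3) == []

    def test_min_len_filters(self):
        flags = {r: r in (20, 21) for r in range(15, 30)}
        prof = self.profile_from_flags(flags)
        assert contiguous_regions(prof, min_len=3) == []


class TestLinewidth:
    def lorentzian(self, f, fwhm, f0=0.0):
        return (fwhm / 2) ** 2 / ((f - f0) ** 2 + (fwhm / 2) ** 2)

    def test_exact_recovery(self):
        f = np.linspace(-100, 100, 81)
        assert linewidth_fwhm(f, self.lorentzian(f, 20.0)) == pytest.approx(
            20.0, abs=0.1
        )

    def test_noisy_recovery_mean(self):
        rng = np.random.default_rng(42)
        f = np.linspace(-400, 400, 161)
        values = []
        for _ in range(50):
            y = self.lorentzian(f, 120.0) + rng.normal(0, 0.05, f.size)
            values.append(linewidth_fwhm(f, y))
        assert np.mean(values) == pytest.approx(120.0, abs=10.0)

    def test_flat_profile_rejected(self):
        f = np.linspace(0, 100, 20)
        with pytest.raises(FitError):
            linewidth_fwhm(f, np.ones_like(f))

    def test_monotone_profile_rejected(self):
        f = np.linspace(0, 100, 20)
        with pytest.raises(FitError):
            linewidth_fwhm(f, f / 100.0)

    def test_too_few_samples(self):
        with pytest.raises(ValidationError):
            linewidth_fwhm(np.arange(5.0), np.arange(5.0))


def peaklist(fraction, peaks):
    """peaks: list of (assignment, w1, w2)."""
    return PeakList(
        spectrum_id=f"t{fraction}",
        condition={"titration_fraction": fraction},
        peaks=pd.DataFrame(
            [(a, w1, w2, 1.0) for a, w1, w2 in peaks],
            columns=["assignment", "w1", "w2", "height"],
        ),
    )


class TestTrackTitration:
    def test_slow_drift_full_trajectory(self):
        series = [
            peaklist(0.2 * i, [("L26N-H", 121.4, 8.05 + 0.01 * i)])
            for i in range(5)
        ]
        trajs = track_titration(series)
        assert trajs[26].status == "complete"
        assert len(trajs[26]) == 5

    def test_vanishing_peak_flagged_broadened(self):
        series = [
            peaklist(0.0, [("L26N-H", 121.4, 8.05), ("K24N-H", 118.0, 8.30)]),
            peaklist(0.3, [("?-?", 121.4, 8.06), ("?-?", 118.0, 8.30)]),
            peaklist(0.6, [("?-?", 118.0, 8.30)]),  # L26 gone
            peaklist(0.9, [("?-?", 118.0, 8.30)]),
        ]
        trajs = track_titration(series)
        assert trajs[26].status == "broadened"
        assert len(trajs[26]) == 2
        assert trajs[24].status == "complete"

    def test_collision_flags_both_ambiguous(self):
        series = [
            peaklist(0.0, [("L26N-H", 121.40, 8.050), ("K24N-H", 121.45, 8.055)]),
            peaklist(0.5, [("?-?", 121.42, 8.052)]),
        ]
        trajs = track_titration(series)
        assert trajs[26].status == "ambiguous"
        assert trajs[24].status == "ambiguous"

    def test_unordered_series_rejected(self):
        series = [peaklist(0.5, [("L26N-H", 121.4, 8.05)]),
                  peaklist(0.2, [("?-?", 121.4, 8.05)])]
        with pytest.raises(ValidationError):
            track_titration(series)


class TestPeakDoubling:
    def reference(self):
        return amide_table({26: ("L", 8.05, 121.4)})

    def test_single_peak(self):
        pl = peaklist(1.0, [("?-?", 121.40, 8.05)])
        out = detect_peak_doubling(pl, self.reference())
        assert out.n_peaks.iloc[0] == 1
        assert not out.asymmetric.iloc[0]

    def test_doublet_marks_asymmetry(self):
        pl = peaklist(1.0, [("?-?", 121.4, 8.025), ("?-?", 121.4, 8.075)])
        out = detect_peak_doubling(pl, self.reference())
        assert out.n_peaks.iloc[0] == 2
        assert bool(out.asymmetric.iloc[0])

    def test_vanished_peak_counts_zero(self):
        pl = peaklist(1.0, [("?-?", 110.0, 7.5)])
        out = detect_peak_doubling(pl, self.reference())
        assert out.n_peaks.iloc[0] == 0


class TestResponsiveRecovery:
    def test_recovers_responsive_residues(self):
        """Ground-truth responsive residues (endpoint >= limit, noise sigma
        <= limit/5) are recovered at >= 95% over 100 replicates."""
        rng = np.random.default_rng(7)
        threshold, sigma = 0.15, 0.15 / 5
        hits = total = 0
        for _ in range(100):
            residues = range(1, 21)
            responsive = set(rng.choice(list(residues), size=5, replace=False))
            free_entries, bound_entries = {}, {}
            for res in residues:
                h, n = 8.2, 120.0
                dh = 0.25 if res in responsive else 0.0
                free_entries[res] = ("A", h + rng.normal(0, sigma), n)
                bound_entries[res] = ("A", h + dh + rng.normal(0, sigma), n)
            prof = classify_perturbed(
                cumulative_delta(
                    amide_table(free_entries),
                    amide_table(bound_entries, state="bound"),
                ),
                threshold=threshold,
            )
            flagged = set(
                prof.per_residue.residue_index[
                    prof.per_residue.perturbed.fillna(False)
                ]
            )
            hits += len(flagged & responsive)
            total += len(responsive)
        assert hits / total >= 0.95
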