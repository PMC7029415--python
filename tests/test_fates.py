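"""Fate analysis: mitosis detection against ground truth, window summaries."""

import numpy as np
import pandas as pd
import pytest

import erktrace as ek


def record(cell_id, entry_h, dur_min=45.0, cond="c", window=24.0, excl=""):
    censored = not np.isfinite(entry_h)
    return dict(
        cell_id=cell_id,
        condition=cond,
        entry_hours=entry_h,
        mitosis_duration_min=dur_min if not censored else np.nan,
        censored=censored,
        window_hours=window,
        excluded_reason=excl,
    )


class TestSummarize:
    def test_fraction_arithmetic(self):
        recs = pd.DataFrame(
            [record(i, 5.0) for i in range(4)] + [record(i, np.nan) for i in range(4, 10)]
        )
        out = ek.summarize_fates(recs, window_hours=24.0)
        assert out.iloc[0]["fraction_mitotic"] == pytest.approx(0.40)
        assert out.iloc[0]["n_eligible"] == 10

    def test_default_windows_available(self):
        cfg = ek.FateConfig()
        assert cfg.allowed_windows == (24.0, 12.0)
        assert cfg.window_hours == 24.0

    def test_window_monotonicity(self):
        rng = np.random.default_rng(2)
        recs = pd.DataFrame(
            [record(i, rng.uniform(0, 30)) for i in range(200)]
            + [record(i, np.nan) for i in range(200, 300)]
        )
        fracs = [
            ek.summarize_fates(recs, window_hours=w).iloc[0]["fraction_mitotic"]
            for w in (30.0, 24.0, 12.0, 6.0)
        ]
        assert fracs == sorted(fracs, reverse=True)

    def test_excluded_cells_out_of_denominator(self):
        recs = pd.DataFrame(
            [record(1, 5.0), record(2, np.nan), record(3, 5.0, excl="border_touch")]
        )
        out = ek.summarize_fates(recs, window_hours=24.0)
        assert out.iloc[0]["n_eligible"] == 2
        assert out.iloc[0]["n_excluded"] == 1
        assert out.iloc[0]["fraction_mitotic"] == pytest.approx(0.5)

    def test_zero_eligible_raises(self):
        recs = pd.DataFrame([record(1, 5.0, excl="border_touch")])
        with pytest.raises(ValueError):
            ek.summarize_fates(recs, window_hours=24.0)

    def test_durations_over_observed_exits_only(self):
        recs = pd.DataFrame(
            [record(1, 5.0, dur_min=30.0), record(2, 6.0, dur_min=np.nan), record(3, np.nan)]
        )
        out = ek.summarize_fates(recs, window_hours=24.0)
        assert out.iloc[0]["mean_mitosis_min"] == pytest.approx(30.0)

    def test_preset_fraction_recovered_from_truth(self):
        """1000 simulated damage-preset cells: estimated fraction within
        3*sqrt(p(1-p)/n) of the preset probability."""
        acq = ek.AcquisitionConfig(n_frames=41, image_size=(256, 256), seed=0)
        preset = ek.FATE_PRESETS["ncs"]
        truth = ek.simulate_cohort(1000, preset, ek.damage_stochastic(), acq, seed=21)
        recs = ek.records_from_truth(truth)
        out = ek.summarize_fates(recs, window_hours=24.0)
        p = preset.p_mitosis
        tol = 3 * np.sqrt(p * (1 - p) / 1000)
        assert abs(out.iloc[0]["fraction_mitotic"] - p) < tol


class TestDetection:
    def test_entries_within_two_frames_of_truth(self, mitosis_movie):
        truth, result, acq = mitosis_movie
        from conftest import match_tracks_to_truth

        mapping = match_tracks_to_truth(truth, result.tracks)
        recs = ek.records_from_tracker(result.tracker, "mito", acq.frame_interval_min, 24.0)
        gt = truth.cells.set_index("cell_id")
        checked = 0
        for row in recs.itertuples(index=False):
            if row.excluded_reason:
                continue
            true_cell = gt.loc[mapping[row.cell_id]]
            true_entry = true_cell["entry_hours"]
            # skip cells whose mitosis outlasts the split horizon by design
            if not np.isfinite(true_entry):
                continue
            tol_h = 2 * acq.frame_interval_min / 60.0
            assert abs(row.entry_hours - true_entry) <= tol_h + 1e-9
            if np.isfinite(row.mitosis_duration_min):
                assert abs(
                    row.mitosis_duration_min - true_cell["mitosis_duration_min"]
                ) <= 2 * acq.frame_interval_min + 1e-9
            checked += 1
        assert checked >= 4  # most of the 8 programmed mitoses are scored

    def test_no_mitosis_means_censored(self, quiet_result):
        truth, result = quiet_result
        recs = ek.records_from_tracker(result.tracker, "quiet", 3.0, 24.0)
        assert recs["censored"].all()

    def test_static_movie_zero_detections(self):
        frames = np.zeros((30, 30), dtype=np.int32)
        frames[10:20, 10:20] = 1
        from erktrace.segmentation import LabelMap, _territories_from_labels

        lm = LabelMap(labels=frames, territories=_territories_from_labels(frames))
        tracker = ek.track_movie([lm] * 30)
        recs = ek.records_from_tracker(tracker, "static", 3.0, 24.0)
        assert recs["censored"].all()
        assert len(tracker.divisions) == 0

    def test_censored_record_cannot_have_entry(self):
        with pytest.raises(ValueError):
            ek.FateRecord(
                cell_id=1, condition="c", entry_hours=5.0,
                mitosis_duration_min=np.nan, censored=True, window_hours=24.0,
            )


def test_fate_trace_plot_smoke(tmp_path):
    recs = pd.DataFrame([record(1, 5.0), record(2, 8.0), record(3, np.nan)])
    ax = ek.plot_fate_traces(recs)
    fig = ax.get_figure()
    fig.savefig(tmp_path / "fates.svg")
    import matplotlib.pyplot as plt

    plt.close(fig)
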