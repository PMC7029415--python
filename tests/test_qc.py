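"""Trace QC: pruning rules (strict inequalities) and gap healing."""

import numpy as np
import pandas as pd
import pytest

import erktrace as ek
from erktrace.config import QCConfig

DT = 3.0  # minutes per frame


def make_trace(cell_id, frames, values=1.0):
    frames = np.asarray(frames)
    vals = np.broadcast_to(np.asarray(values, dtype=float), frames.shape)
    return pd.DataFrame(
        dict(
            cell_id=cell_id,
            frame=frames,
            t_min=frames * DT,
            donor_mean=500.0,
            acceptor_mean=500.0,
            ratio=vals,
            ring_px=100,
        )
    )


class TestPruningRules:
    def test_short_trace_removed(self):
        # 9.5 h span at 3-min sampling: frames 0..190
        tr = make_trace(1, np.arange(191))
        kept, log = ek.qc_filter(tr, DT)
        assert kept.empty
        assert log.iloc[0]["rule"] == "too_short"

    def test_exactly_ten_hours_kept(self):
        # 10 h span = 200 frame intervals -> frames 0..200; "< 10hrs" is strict
        tr = make_trace(1, np.arange(201))
        kept, log = ek.qc_filter(tr, DT)
        assert not kept.empty and log.empty

    def test_four_frame_contiguous_gap_removed(self):
        frames = np.concatenate([np.arange(100), np.arange(104, 241)])  # 4-frame gap
        kept, log = ek.qc_filter(make_trace(1, frames), DT)
        assert kept.empty
        assert log.iloc[0]["rule"] == "contiguous_gap"

    def test_three_frame_contiguous_gap_survives_gap_rule(self):
        frames = np.concatenate([np.arange(100), np.arange(103, 241)])  # 3-frame gap
        kept, log = ek.qc_filter(make_trace(1, frames), DT)
        assert not kept.empty

    def test_gap_fraction_boundary(self):
        # 12-h trace: frames 0..240 (241 frames). 12 scattered missing = 4.98% kept;
        # 13 missing = 5.39% removed (strict > 5%).
        all_frames = np.arange(241)
        missing12 = np.arange(20, 240, 19)[:12]  # scattered, no contiguous run
        assert len(missing12) == 12
        frames = np.setdiff1d(all_frames, missing12)
        kept, _ = ek.qc_filter(make_trace(1, frames), DT)
        assert not kept.empty

        missing13 = np.concatenate([missing12, [5]])
        frames = np.setdiff1d(all_frames, missing13)
        kept, log = ek.qc_filter(make_trace(1, frames), DT)
        assert kept.empty
        assert log.iloc[0]["rule"] == "gap_fraction"

    def test_each_rejection_logged_with_rule(self):
        t1 = make_trace(1, np.arange(50))  # too short
        frames = np.concatenate([np.arange(100), np.arange(110, 241)])
        t2 = make_trace(2, frames)  # 10-frame gap
        t3 = make_trace(3, np.arange(241))  # fine
        kept, log = ek.qc_filter(pd.concat([t1, t2, t3]), DT)
        assert set(kept["cell_id"]) == {3}
        assert dict(zip(log["cell_id"], log["rule"])) == {
            1: "too_short",
            2: "contiguous_gap",
        }

    def test_monotone_adding_gaps_never_rescues(self):
        """Removing observations from a kept trace can only keep it kept or
        reject it; a rejected trace never becomes kept."""
        rng = np.random.default_rng(4)
        base = np.arange(241)
        frames = base.copy()
        previous_removed = False
        for n_drop in (0, 6, 12, 18, 30):
            dropped = rng.choice(base[1:-1], size=n_drop, replace=False)
            tr = make_trace(1, np.setdiff1d(base, dropped))
            kept, _ = ek.qc_filter(tr, DT)
            removed = kept.empty
            if previous_removed:
                assert removed
            previous_removed = removed or previous_removed


class TestHealing:
    def test_constant_trace_filled_with_constant(self):
        v = np.ones(20)
        v[7] = np.nan
        healed, mask = ek.heal_series(v)
        assert healed[7] == 1.0
        assert mask[7] and mask.sum() == 1

    def test_median_of_six_neighbors(self):
        # observed neighbours around the gap: 1, 2, 3, 4 | gap | 100, 6
        v = np.array([1.0, 2.0, 3.0, 4.0, np.nan, 100.0, 6.0])
        healed, _ = ek.heal_series(v)
        assert healed[4] == 3.5  # median of {1,2,3,4,100,6}

    def test_gap_free_trace_bit_identical(self):
        v = np.linspace(0.5, 2.0, 30)
        healed, mask = ek.heal_series(v.copy())
        np.testing.assert_array_equal(healed, v)
        assert not mask.any()

    def test_only_missing_samples_modified(self):
        rng = np.random.default_rng(1)
        v = rng.uniform(0.5, 2.0, 50)
        v[[10, 11, 30]] = np.nan
        healed, mask = ek.heal_series(v)
        obs = np.isfinite(v)
        np.testing.assert_array_equal(healed[obs], v[obs])
        assert set(np.nonzero(mask)[0]) == {10, 11, 30}
        assert np.isfinite(healed).all()

    def test_end_gap_borrows_from_one_side(self):
        v = np.array([np.nan, 2.0, 4.0, 6.0, 8.0, 10.0, 12.0, 14.0])
        healed, _ = ek.heal_series(v)
        # nearest 6 observed are 2,4,6,8,10,12 -> median 7
        assert healed[0] == 7.0

    def test_all_missing_raises(self):
        with pytest.raises(ValueError):
            ek.heal_series(np.full(5, np.nan))

    def test_heal_gaps_dataframe_roundtrip(self):
        frames = np.setdiff1d(np.arange(221), [50, 51, 120])
        tr = make_trace(1, frames, values=np.linspace(1, 2, len(frames)))
        healed = ek.heal_gaps(tr, DT)
        assert len(healed) == 221
        assert healed["healed"].sum() == 3
        assert np.isfinite(healed["ratio"]).all()
        # observed samples pass through unchanged
        merged = healed[~healed["healed"]].set_index("frame")["ratio"]
        orig = tr.set_index("frame")["ratio"]
        np.testing.assert_array_equal(merged.loc[orig.index].to_numpy(), orig.to_numpy())
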