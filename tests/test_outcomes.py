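import datetime as dt
import math

import numpy as np
import pandas as pd
import pytest

from nightscratch.intervals import Interval
from nightscratch.outcomes import (
    DEFAULT_ITCH_BANDS,
    ProResponse,
    filter_pro_responses,
    geometric_mean,
    group_summary,
    night_summary,
    participant_summary,
    stratify_by_itch,
)
from nightscratch.tso import TsoRecord

H = 3600.0


def _tso(hours=8.0, pid="P1", nid="2024-01-01", source="Reference", start=0.0):
    return TsoRecord(pid, nid, source, Interval(start, start + hours * H))


class TestNightSummary:
    def test_five_bouts_in_8h(self, track):
        t = track([(i * 100.0, i * 100.0 + 12.0) for i in range(5)])
        s = night_summary(t, _tso(8.0))
        assert s.scratch_seconds == 60.0
        assert s.bout_count == 5
        assert s.norm_duration == pytest.approx(7.5)
        assert s.norm_frequency == pytest.approx(0.625)

    def test_empty_track_is_zero(self, track):
        s = night_summary(track([]), _tso(8.0))
        assert s.norm_duration == 0.0 and s.norm_frequency == 0.0

    def test_doubling_tso_halves_outcomes(self, track):
        t = track([(0, 30), (100, 130)])
        s1 = night_summary(t, _tso(4.0))
        s2 = night_summary(t, _tso(8.0))
        assert s2.norm_duration == pytest.approx(s1.norm_duration / 2)
        assert s2.norm_frequency == pytest.approx(s1.norm_frequency / 2)

    def test_origin_shift_invariance(self, track):
        """Shifting all times by a constant leaves normalized outcomes unchanged."""
        t0 = track([(0, 30), (100, 130)])
        t1 = track([(500, 530), (600, 630)])
        s0 = night_summary(t0, _tso(8.0, start=0.0))
        s1 = night_summary(t1, _tso(8.0, start=500.0))
        assert s0.norm_duration == s1.norm_duration
        assert s0.norm_frequency == s1.norm_frequency

    def test_excluded_tso_rejected(self, track):
        rec = _tso(8.0)
        rec.excluded = True
        with pytest.raises(ValueError):
            night_summary(track([]), rec)


class TestGeometricMean:
    def test_plain(self):
        assert geometric_mean([4, 9], offset=0.0) == pytest.approx(6.0)

    def test_single_value(self):
        assert geometric_mean([7.3], offset=0.0) == pytest.approx(7.3)

    def test_offset_keeps_zero_nights(self):
        want = math.exp((math.log(1) + math.log(11)) / 2) - 1
        assert geometric_mean([0, 10], offset=1.0) == pytest.approx(want, abs=1e-4)
        assert want == pytest.approx(2.3166, abs=1e-4)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            geometric_mean([])

    def test_am_gm_inequality(self, rng):
        for _ in range(50):
            x = rng.uniform(0, 30, size=6)
            assert geometric_mean(x, offset=0.5) <= np.mean(x) + 1e-9


class TestParticipantAndGroupSummary:
    def _nights(self):
        rows = []
        for pid, vals in (("P1", [4, 9]), ("P2", [16, 25])):
            for i, v in enumerate(vals):
                rows.append(
                    dict(
                        participant_id=pid, night_id=f"n{i}", source="Reference",
                        tso_hours=8.0, scratch_seconds=v * 8.0, bout_count=int(v),
                        norm_duration=float(v), norm_frequency=float(v),
                    )
                )
        return pd.DataFrame(rows)

    def test_geometric_means_per_participant(self):
        out = participant_summary(self._nights(), offset=0.0)
        assert out.set_index("participant_id").loc["P1", "norm_duration"] == pytest.approx(6.0)
        assert out.set_index("participant_id").loc["P2", "norm_duration"] == pytest.approx(20.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            participant_summary(pd.DataFrame())

    def test_single_participant_group_median(self):
        part = participant_summary(self._nights(), offset=0.0)
        part["cohort"] = ["A", "B"]
        g = group_summary(part, "cohort")
        assert g.set_index("cohort").loc["A", "norm_duration_median"] == pytest.approx(6.0)
        assert g.set_index("cohort").loc["A", "n"] == 1

    def test_permutation_invariance(self):
        part = participant_summary(self._nights(), offset=0.0)
        part["cohort"] = "A"
        g1 = group_summary(part, "cohort")
        g2 = group_summary(part.iloc[::-1], "cohort")
        pd.testing.assert_frame_equal(g1, g2)


class TestProFilter:
    def _resp(self, time_str, date="2024-01-02", pid="P1", admin="morning", itch=3):
        return ProResponse(pid, dt.date.fromisoformat(date), admin,
                           dt.time.fromisoformat(time_str), itch)

    def test_window_boundaries(self):
        kept = filter_pro_responses(
            [self._resp("03:59"), self._resp("04:00", date="2024-01-03"),
             self._resp("12:00", date="2024-01-04"), self._resp("12:01", date="2024-01-05")]
        )
        assert [r.timestamp.isoformat(timespec="minutes") for r in kept] == ["04:00", "12:00"]

    def test_evening_responses_ignored(self):
        kept = filter_pro_responses([self._resp("08:00", admin="evening")])
        assert kept == []

    def test_duplicate_day_drops_all(self):
        kept = filter_pro_responses([self._resp("08:00"), self._resp("09:00")])
        assert kept == []

    def test_duplicates_scoped_to_participant_day(self):
        kept = filter_pro_responses(
            [self._resp("08:00"), self._resp("09:00"),
             self._resp("08:30", pid="P2")]
        )
        assert [r.participant_id for r in kept] == ["P2"]


class TestStratifyByItch:
    def _nights(self):
        return pd.DataFrame(
            [
                dict(participant_id="P1", night_id="2024-01-01", source="Reference",
                     norm_duration=5.0, norm_frequency=2.0),
                dict(participant_id="P1", night_id="2024-01-04", source="Reference",
                     norm_duration=25.0, norm_frequency=5.0),
            ]
        )

    def test_joins_following_morning(self):
        pros = [
            ProResponse("P1", dt.date(2024, 1, 2), "morning", dt.time(8, 0), 0),
            ProResponse("P1", dt.date(2024, 1, 5), "morning", dt.time(8, 0), 5),
        ]
        out = stratify_by_itch(self._nights(), pros)
        bands = dict(zip(out["night_id"], out["itch_band"]))
        assert bands == {"2024-01-01": "no itch", "2024-01-04": "moderate"}

    def test_missing_pro_leaves_night_out(self):
        pros = [ProResponse("P1", dt.date(2024, 1, 2), "morning", dt.time(8, 0), 2)]
        out = stratify_by_itch(self._nights(), pros)
        assert out["night_id"].tolist() == ["2024-01-01"]

    def test_default_bands_partition_all_nrs_values(self):
        covered = set()
        for _, lo, hi in DEFAULT_ITCH_BANDS:
            covered |= set(range(lo, hi + 1))
        assert covered == set(range(11))

    def test_overlapping_bands_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            stratify_by_itch(self._nights(), [], bands=[("a", 0, 5), ("b", 5, 10)])
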