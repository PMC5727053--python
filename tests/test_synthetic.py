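"""Generator honesty: determinism, monotone workload signatures, artifacts."""

import numpy as np
import pytest

from dfhm.errors import ValidationError
from dfhm.maps import LabelRule, auto_label
from dfhm.montage import FRONTAL
from dfhm.preprocess import segment
from dfhm.spectral import band_power
from dfhm.synthetic import (
    BatteryBlock,
    CohortSpec,
    WorkloadProfile,
    default_battery,
    generate_cohort,
    generate_labeled_dfhm_set,
    generate_recording,
    scale_battery,
    with_held_out_task,
)


def _mean_band_power(rec, region_channels, band_attr):
    segs = segment(rec)
    idx = [rec.channels.index(c) for c in region_channels]
    vals = [getattr(band_power(s), band_attr)[idx].mean() for s in segs]
    return float(np.mean(vals)), len(segs)


def _one_block_spec(condition="moderate", duration=180.0, seed=9, **kw):
    return CohortSpec(n_subjects=1, seed=seed,
                      battery=(BatteryBlock("t", duration, condition),), **kw)


class TestGenerateRecording:
    def test_shape_and_metadata(self, montage):
        sub = generate_recording(_one_block_spec(duration=60.0), 0)
        rec = sub.recording
        assert rec.n_channels == 25
        assert rec.rate == 500.0
        assert rec.channels == list(montage.labels)
        assert rec.reference == "Cz"
        assert sub.truth == {"t": "moderate"}

    def test_seed_determinism(self):
        a = generate_recording(_one_block_spec(duration=60.0), 0).recording
        b = generate_recording(_one_block_spec(duration=60.0), 0).recording
        assert np.array_equal(a.samples, b.samples)
        c = generate_recording(_one_block_spec(duration=60.0, seed=10), 0).recording
        assert not np.array_equal(a.samples, c.samples)

    def test_theta_power_monotone_in_gain(self, montage):
        """Frontal theta band power rises with the theta gain, all else fixed."""
        powers = []
        for gain in (0.6, 1.0, 1.7):
            profiles = {"moderate": WorkloadProfile(gain, 1.0, "moderate")}
            spec = _one_block_spec(duration=180.0, profiles=profiles)
            rec = generate_recording(spec, 0).recording
            p, n = _mean_band_power(rec, montage.frontal, "theta")
            assert n >= 30
            powers.append(p)
        assert powers[0] < powers[1] < powers[2]

    def test_alpha_power_monotone_in_gain(self, montage):
        powers = []
        for gain in (0.5, 1.0, 1.5):
            profiles = {"moderate": WorkloadProfile(1.0, gain, "moderate")}
            spec = _one_block_spec(duration=180.0, profiles=profiles)
            rec = generate_recording(spec, 0).recording
            p, _ = _mean_band_power(rec, montage.parietal, "alpha")
            powers.append(p)
        assert powers[0] < powers[1] < powers[2]

    def test_artifact_rate_zero_means_no_blinks(self):
        quiet = generate_recording(_one_block_spec(duration=60.0), 0).recording
        blinky = generate_recording(
            _one_block_spec(duration=60.0, artifact_rate_hz=0.3), 0).recording
        fp = quiet.channels.index("Fp1")
        pz = quiet.channels.index("Pz")
        # blinks add large positive deflections on fronto-polar channels only
        assert blinky.samples[fp].max() > 1.5 * quiet.samples[fp].max()
        assert blinky.samples[pz].max() < 1.5 * quiet.samples[pz].max()

    def test_spec_validation(self):
        with pytest.raises(ValidationError):
            CohortSpec(n_subjects=0, seed=1)
        with pytest.raises(ValidationError):
            CohortSpec(n_subjects=1, seed=1,
                       battery=(BatteryBlock("x", 30.0, "low"),))  # < 60 s
        with pytest.raises(ValidationError):
            CohortSpec(n_subjects=1, seed=1,
                       battery=(BatteryBlock("x", 60.0, "nope"),))
        with pytest.raises(ValidationError):
            WorkloadProfile(-1.0, 1.0, "low")


class TestCohort:
    def test_cohort_size_and_independence(self):
        spec = _one_block_spec(duration=60.0)
        spec.n_subjects = 3
        subs = list(generate_cohort(spec))
        assert len(subs) == 3
        assert len({s.subject_id for s in subs}) == 3
        assert not np.array_equal(subs[0].recording.samples, subs[1].recording.samples)

    def test_held_out_task_appended(self):
        battery = with_held_out_task(scale_battery(default_battery(), 0.2))
        assert battery[-1].task_id == "stop_signal"
        assert len(battery) == 12
        spec = CohortSpec(n_subjects=1, seed=4, battery=battery)
        sub = generate_recording(spec, 0)
        assert sub.truth["stop_signal"] == "high"  # moderate-to-high demand

    def test_battery_scaling_floors_at_baseline_minute(self):
        scaled = scale_battery(default_battery(), 0.2)
        assert all(b.duration_s >= 60.0 for b in scaled)
        assert scaled[0].duration_s == 60.0  # 180 s rest floored
        assert scaled[-2].duration_s == 240.0  # 1200 s span task / 5


class TestLabeledMapSet:
    def test_labels_are_rule_consistent(self, labeled_set):
        rule = LabelRule()
        assert all(m.label == auto_label(m, rule) for m in labeled_set)

    def test_all_three_classes_present(self, labeled_set):
        labels = {m.label for m in labeled_set}
        assert labels == {"low", "moderate", "high"}

    def test_margin_controls_archetype_separation(self, montage):
        wide = generate_labeled_dfhm_set(90, margin=2.0, montage=montage, seed=0)
        highs = [m.frontal_mean for m in wide if m.label == "high"]
        lows = [m.frontal_mean for m in wide if m.label == "low"]
        assert min(highs) - max(lows) > 2.0

    def test_determinism(self, montage):
        a = generate_labeled_dfhm_set(30, montage=montage, seed=7)
        b = generate_labeled_dfhm_set(30, montage=montage, seed=7)
        assert all(np.array_equal(x.values, y.values) for x, y in zip(a, b))

    def test_frontal_carries_theta_side(self, labeled_set, montage):
        m = next(m for m in labeled_set if m.label == "high")
        frontal = m.values[[r == FRONTAL for r in m.region]]
        parietal = m.values[[r != FRONTAL for r in m.region]]
        assert frontal.mean() > parietal.mean()
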