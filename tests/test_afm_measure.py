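"""Recovery of the generator ground truth by the measurement pipeline."""

import math

import numpy as np
import pytest

from vippgeom.afm_synth import (
    AFMImage,
    synth_filament_field,
    synth_growth_series,
    synth_ring_field,
    synth_sheet,
    synth_spiral_field,
)
from vippgeom.afm_measure import (
    background_mode,
    detect_objects,
    growth_rate,
    object_morphometrics,
    ridge_period,
    ring_protrusion,
)
from vippgeom.errors import InvalidArgumentError

from conftest import match_objects


def _sheet_mask(img):
    return img.heights > background_mode(img) + 2.0


class TestRidgePeriod:
    def test_default_sheet_recovers_54A(self):
        img, _ = synth_sheet(seed=42)
        period = ridge_period(img, region_mask=_sheet_mask(img))
        assert period == pytest.approx(54.0, rel=0.02)

    def test_pure_sinusoid_exact(self):
        n, px, period_nm = 512, 0.7, 6.0
        x = (np.arange(n) + 0.5) * px
        img = AFMImage(
            heights=np.tile(np.sin(2 * math.pi * x / period_nm), (n, 1)).astype(np.float32),
            pixel_nm=px,
        )
        assert ridge_period(img) == pytest.approx(period_nm * 10.0, rel=0.005)

    def test_white_noise_has_no_periodicity(self):
        rng = np.random.default_rng(0)
        img = AFMImage(heights=rng.normal(0, 0.1, (256, 256)).astype(np.float32),
                       pixel_nm=0.7)
        assert ridge_period(img) is None

    def test_small_region_rejected(self):
        img = AFMImage(heights=np.zeros((32, 32), dtype=np.float32), pixel_nm=0.7)
        with pytest.raises(InvalidArgumentError):
            ridge_period(img)


class TestDetection:
    def test_blank_membrane_yields_nothing(self):
        rng = np.random.default_rng(1)
        img = AFMImage(heights=rng.normal(0, 0.1, (300, 300)).astype(np.float32),
                       pixel_nm=1.0)
        assert detect_objects(img) == []

    def test_single_ring_classified(self):
        img, _ = synth_ring_field(n_rings=1, seed=5)
        objs = detect_objects(img)
        assert len(objs) == 1 and objs[0].kind == "ring"

    def test_sheet_classified(self):
        img, _ = synth_sheet(field_nm=400, seed=2)
        objs = detect_objects(img)
        assert len(objs) == 1 and objs[0].kind == "sheet"

    def test_spiral_field_classification_rate(self):
        """>= 95% of generated spirals are detected with the correct class."""
        img, truth = synth_spiral_field(n_spirals=50, seed=1)
        objs = detect_objects(img)
        pairs = match_objects(objs, truth)
        correct = sum(1 for _, o in pairs if o is not None and o.kind == "spiral")
        assert correct >= 0.95 * len(truth)

    def test_rotation_and_translation_invariance(self):
        img, _ = synth_spiral_field(n_spirals=1, seed=3, diameter_mean_nm=90.0,
                                    diameter_sd_nm=0.0, ring_fraction=0.0)
        base = detect_objects(img)[0]
        rot = AFMImage(heights=np.ascontiguousarray(np.rot90(img.heights)),
                       pixel_nm=img.pixel_nm)
        shifted = AFMImage(heights=np.roll(img.heights, (31, -17), axis=(0, 1)),
                           pixel_nm=img.pixel_nm)
        for other in (rot, shifted):
            objs = detect_objects(other)
            assert len(objs) == 1 and objs[0].kind == base.kind
            assert objs[0].width_nm == pytest.approx(base.width_nm, rel=0.02)
            assert objs[0].area_nm2 == pytest.approx(base.area_nm2, rel=1e-6)


class TestMorphometrics:
    def test_spiral_diameters_recover_truth(self):
        img, truth = synth_spiral_field(n_spirals=40, seed=2)
        objs = detect_objects(img)
        report = object_morphometrics(objs, img)
        sem = truth.diameter_nm.std() / math.sqrt(len(truth))
        spirals = report.per_object[report.per_object.kind == "spiral"]
        assert abs(spirals.diameter_nm.mean() - truth.diameter_nm.mean()) < 2 * sem
        # per-object agreement is far tighter than the distribution width
        pairs = match_objects(objs, truth)
        for t, o in pairs:
            assert o is not None
            row = report.per_object[report.per_object.label == o.label].iloc[0]
            assert row.diameter_nm == pytest.approx(t.diameter_nm, abs=1.5)

    def test_filament_width_within_five_percent(self):
        img, truth = synth_filament_field(n_filaments=13, seed=2)
        report = object_morphometrics(detect_objects(img), img)
        fil = report.per_object[report.per_object.kind == "filament"]
        assert len(fil) == 13
        assert fil.width_nm.mean() == pytest.approx(truth.width_nm.mean(), rel=0.05)

    def test_sheet_height_offset(self):
        img, _ = synth_sheet(field_nm=400, seed=11)
        report = object_morphometrics(detect_objects(img), img)
        sheet = report.per_object[report.per_object.kind == "sheet"].iloc[0]
        assert sheet.height_offset_nm == pytest.approx(5.5, abs=0.1)

    def test_summary_counts(self):
        img, truth = synth_ring_field(n_rings=8, seed=9)
        report = object_morphometrics(detect_objects(img), img)
        n = report.summary.query("kind == 'ring'")["n"].iloc[0]
        assert n == 8


class TestRingProtrusion:
    def _field_with_rings(self, protrusion, seed=11):
        return synth_spiral_field(
            n_spirals=6, seed=seed, diameter_mean_nm=160.0, diameter_sd_nm=0.0,
            ring_fraction=1.0, ring_protrusion_nm=protrusion,
        )

    def test_one_nm_protrusion_recovered(self):
        img, truth = self._field_with_rings(1.0)
        objs = detect_objects(img)
        spirals = [o for o in objs if o.kind == "spiral"]
        vals = [ring_protrusion(img, s, objs) for s in spirals]
        vals = [v for v in vals if v is not None]
        assert len(vals) == len(truth)
        assert np.mean(vals) == pytest.approx(1.0, abs=0.1)

    def test_zero_protrusion(self):
        img, _ = self._field_with_rings(0.0, seed=13)
        objs = detect_objects(img)
        spirals = [o for o in objs if o.kind == "spiral"]
        vals = [ring_protrusion(img, s, objs) for s in spirals if
                ring_protrusion(img, s, objs) is not None]
        assert vals and abs(np.mean(vals)) <= 0.1

    def test_spiral_without_ring_is_not_applicable(self):
        img, _ = synth_spiral_field(n_spirals=3, seed=4, ring_fraction=0.0)
        objs = detect_objects(img)
        spiral = next(o for o in objs if o.kind == "spiral")
        assert ring_protrusion(img, spiral, objs) is None


class TestGrowthRate:
    def test_mean_velocity_recovered(self):
        frames, truth = synth_growth_series(n_frames=8, seed=7)
        df = growth_rate(frames)
        ok = df[~df.flagged]
        assert abs(ok.velocity_nm_s.mean() - truth.velocity_nm_s.mean()) \
            < 0.15 * max(truth.velocity_nm_s.mean(), 1.0)

    def test_zero_velocity_series(self):
        frames, _ = synth_growth_series(
            n_frames=4, n_filaments=3, seed=1,
            velocity_mean_nm_s=0.0, velocity_sd_nm_s=0.0,
        )
        df = growth_rate(frames)
        assert np.allclose(df[~df.flagged].velocity_nm_s, 0.0, atol=1.0)

    def test_two_frames_rejected(self):
        frames, _ = synth_growth_series(n_frames=3, n_filaments=2, seed=2)
        with pytest.raises(InvalidArgumentError):
            growth_rate(frames[:2])
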