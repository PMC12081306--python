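"""Image quantification: calibration, backgrounds, objects, regions."""

import math

import numpy as np
import pandas as pd
import pytest

from pulsechase import errors, imagequant, synthetic
from pulsechase.imagequant import (CalibrationCurve, ChannelCalibration,
                                   QuantImage)


def flat_image(shape=(32, 32), pulse=5.0, chase=5.0):
    return QuantImage(channels={"pulse": np.full(shape, pulse),
                                "chase": np.full(shape, chase)})


CAL = CalibrationCurve({"pulse": (40.0, 100.0), "chase": (40.0, 100.0),
                        "chase2": (40.0, 100.0)})


class TestQuantImage:
    def test_requires_pulse_and_chase(self):
        with pytest.raises(errors.DomainError):
            QuantImage(channels={"pulse": np.zeros((4, 4))})

    def test_rejects_shape_mismatch_and_unknown_roles(self):
        with pytest.raises(errors.DomainError):
            QuantImage(channels={"pulse": np.zeros((4, 4)),
                                 "chase": np.zeros((5, 5))})
        with pytest.raises(errors.DomainError):
            QuantImage(channels={"pulse": np.zeros((4, 4)),
                                 "chase": np.zeros((4, 4)),
                                 "oops": np.zeros((4, 4))})


class TestNormalize:
    def test_percentile_anchors_map_to_unit_interval(self):
        data = np.arange(1000.0).reshape(25, 40)
        img = QuantImage(channels={"pulse": data, "chase": data.copy()})
        norm = imagequant.normalize_channels(img)
        lo, hi = np.percentile(data, (0.3, 99.7))
        expected = np.clip((data - lo) / (hi - lo), 0, 1)
        np.testing.assert_allclose(norm["pulse"], expected)
        assert norm["pulse"].min() == 0.0 and norm["pulse"].max() == 1.0

    def test_constant_channel_is_degenerate(self):
        with pytest.raises(errors.DomainError):
            imagequant.normalize_channels(flat_image())

    def test_spanning_channel_changes_only_by_clipping(self):
        rng = np.random.default_rng(0)
        data = rng.uniform(0.0, 1.0, (50, 50))
        img = QuantImage(channels={"pulse": data, "chase": data.copy()})
        norm = imagequant.normalize_channels(img)
        inner = (data > np.percentile(data, 0.3)) & \
                (data < np.percentile(data, 99.7))
        np.testing.assert_allclose(norm["pulse"][inner], data[inner],
                                   atol=0.01)


class TestDownsample:
    def test_factor_one_is_identity(self):
        img = flat_image()
        assert imagequant.downsample(img, 1) is img

    def test_block_mean(self):
        data = np.array([[1.0, 1.0], [3.0, 3.0]])
        img = QuantImage(channels={"pulse": data, "chase": data.copy()})
        out = imagequant.downsample(img, 2)
        assert out["pulse"].shape == (1, 1)
        assert out["pulse"][0, 0] == 2.0
        assert out.pixel_size_um == 2.0

    def test_mean_preserved(self):
        rng = np.random.default_rng(1)
        data = rng.uniform(0, 10, (64, 64))
        img = QuantImage(channels={"pulse": data, "chase": data.copy()})
        out = imagequant.downsample(img, 4)
        assert out["pulse"].mean() == pytest.approx(data.mean(), abs=1e-12)

    def test_partial_trailing_blocks_average_actual_pixels(self):
        data = np.ones((5, 5))
        data[4, :] = 3.0  # last (partial) row block
        img = QuantImage(channels={"pulse": data, "chase": data.copy()})
        out = imagequant.downsample(img, 2)
        assert out["pulse"].shape == (3, 3)
        assert out["pulse"][2, 0] == 3.0  # 1x2 block of the value-3 row

    def test_non_integer_factor_rejected(self):
        with pytest.raises(errors.DomainError):
            imagequant.downsample(flat_image(), 1.5)


class TestSegmentation:
    @staticmethod
    def disk_image(centers, radius=6.0, shape=(64, 64), amp=100.0):
        rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
        stain = np.zeros(shape)
        for r, c in centers:
            stain[(rr - r) ** 2 + (cc - c) ** 2 <= radius ** 2] = amp
        return QuantImage(channels={"nuclear_stain": stain,
                                    "pulse": stain * 0.5 + 1.0,
                                    "chase": stain * 0.5 + 1.0})

    def test_single_disk_found_with_centroid(self):
        img = self.disk_image([(32, 20)])
        labels = imagequant.segment_objects(img, "nuclei", threshold=10.0)
        assert labels.max() == 1
        import skimage.measure as msr
        centroid = msr.regionprops(labels)[0].centroid
        assert centroid[0] == pytest.approx(32, abs=0.5)
        assert centroid[1] == pytest.approx(20, abs=0.5)

    def test_two_separated_disks(self):
        img = self.disk_image([(16, 16), (48, 48)])
        labels = imagequant.segment_objects(img, "nuclei", threshold=10.0)
        assert labels.max() == 2

    def test_puncta_field_recall_and_precision(self):
        image, truth = synthetic.make_image(
            n_objects=200, mode="puncta", tau_days=14.0, delta_t=14.0,
            snr=10.0, shape=(512, 512), seed=21)
        norm = imagequant.normalize_channels(image)
        labels = imagequant.segment_objects(norm, "puncta")
        import skimage.measure as msr
        found = np.array([p.centroid for p in msr.regionprops(labels)])
        true_pos = truth.objects[["row", "col"]].to_numpy()
        d2 = ((found[:, None, :] - true_pos[None, :, :]) ** 2).sum(-1)
        matched_truth = (d2.min(axis=0) < 4.0 ** 2)
        matched_found = (d2.min(axis=1) < 4.0 ** 2)
        recall = matched_truth.mean()
        precision = matched_found.mean()
        assert recall >= 0.95
        assert precision >= 0.95

    def test_invalid_mode_rejected(self):
        with pytest.raises(errors.DomainError):
            imagequant.segment_objects(flat_image(), "cells")


class TestLocalBackground:
    @staticmethod
    def one_object(bg=10.0, obj=50.0, shape=(40, 40)):
        channel = np.full(shape, bg)
        labels = np.zeros(shape, dtype=int)
        labels[18:23, 18:23] = 1
        channel[labels == 1] = obj
        return channel, labels

    def test_uniform_background_recovered(self):
        channel, labels = self.one_object()
        est = imagequant.local_background(channel, labels, 1)
        assert est.value == 10.0
        assert not est.global_fallback

    def test_neighbor_pixels_excluded(self):
        channel, labels = self.one_object()
        labels[18:23, 25:28] = 2  # neighbor inside the annulus
        channel[labels == 2] = 500.0
        est = imagequant.local_background(channel, labels, 1)
        assert est.value == 10.0

    def test_gradient_background_tracked_locally(self):
        shape = (60, 60)
        rr = np.mgrid[0:shape[0], 0:shape[1]][0]
        channel = 0.5 * rr.astype(float)
        labels = np.zeros(shape, dtype=int)
        labels[28:33, 28:33] = 1
        est = imagequant.local_background(channel, labels, 1)
        assert abs(est.value - 0.5 * 30) <= 1.0

    def test_fallback_when_annulus_fully_excluded(self):
        channel, labels = self.one_object()
        artifact = np.ones_like(labels, bool)
        artifact[:5, :5] = False  # only a far corner is clean
        artifact[labels == 1] = False
        est = imagequant.local_background(channel, labels, 1,
                                          artifact_mask=artifact)
        assert est.global_fallback
        assert est.value == 10.0

    def test_missing_object_rejected(self):
        channel, labels = self.one_object()
        with pytest.raises(errors.DomainError):
            imagequant.local_background(channel, labels, 99)


class TestToMicromolar:
    def test_linear_inversion(self):
        cal = ChannelCalibration(40.0, 100.0)
        assert imagequant.to_micromolar(100.0 + 40.0 * 2.5, 100.0, cal) == \
            pytest.approx(2.5)

    def test_below_background_clamps_with_flag(self):
        cal = ChannelCalibration(40.0, 100.0)
        um, flags = imagequant.to_micromolar(90.0, 100.0, cal,
                                             return_flags=True)
        assert um == 0.0 and flags["clamped"]

    def test_round_trip_over_many_values(self):
        cal = ChannelCalibration(40.0, 100.0)
        truth = np.linspace(0.01, 20.0, 100)
        intensity = cal.intercept + cal.slope * truth
        um = imagequant.to_micromolar(intensity, cal.intercept, cal)
        np.testing.assert_allclose(um, truth, rtol=1e-12)

    def test_out_of_range_flagged(self):
        cal = ChannelCalibration(40.0, 100.0, (0.0, 5.0))
        _, flags = imagequant.to_micromolar(100.0 + 40.0 * 8.0, 100.0, cal,
                                            return_flags=True)
        assert flags["extrapolated"]


class TestQuantify:
    @staticmethod
    def simple_scene(um_pulse, um_chase, cal=CAL, bg=7.0):
        shape = (40, 40)
        labels = np.zeros(shape, dtype=int)
        labels[15:25, 15:25] = 1
        pulse = np.full(shape, cal["pulse"].intercept + bg)
        chase = np.full(shape, cal["chase"].intercept + bg)
        pulse[labels == 1] += cal["pulse"].slope * um_pulse
        chase[labels == 1] += cal["chase"].slope * um_chase
        img = QuantImage(channels={"pulse": pulse, "chase": chase})
        return img, labels

    def test_equal_amounts_give_half_life_identity(self):
        img, labels = self.simple_scene(3.0, 3.0)
        table = imagequant.quantify(img, labels, CAL, delta_t=14.0)
        assert table.loc[0, "fraction_pulse"] == pytest.approx(0.5)
        assert table.loc[0, "lifetime_days"] == pytest.approx(
            14.0 / math.log(2), rel=1e-9)

    def test_pure_pulse_flagged_infinite(self):
        img, labels = self.simple_scene(3.0, 0.0)
        table = imagequant.quantify(img, labels, CAL, delta_t=14.0)
        assert table.loc[0, "flag"] == "infinite_lifetime"
        assert np.isnan(table.loc[0, "lifetime_days"])

    def test_total_protein_invariant_to_interval(self):
        img, labels = self.simple_scene(2.0, 4.0)
        t1 = imagequant.quantify(img, labels, CAL, delta_t=7.0)
        t2 = imagequant.quantify(img, labels, CAL, delta_t=21.0)
        assert t1.loc[0, "total_protein_um"] == t2.loc[0, "total_protein_um"]

    def test_noiseless_recovery_is_exact(self, noiseless_image):
        image, truth = noiseless_image
        table = imagequant.quantify(image, truth.label_map,
                                    truth.calibration, truth.delta_t)
        merged = table.merge(truth.objects, left_on="label", right_on="label")
        np.testing.assert_allclose(merged["lifetime_days"],
                                   merged["tau_days"], rtol=1e-9)

    def test_label_shape_mismatch_rejected(self):
        img, _ = self.simple_scene(1.0, 1.0)
        with pytest.raises(errors.DomainError):
            imagequant.quantify(img, np.zeros((3, 3), int), CAL, 14.0)


class TestTripleLabel:
    def test_observation_windows(self):
        obs = imagequant.triple_label_observations(
            2.0, 1.0, 1.0, t_pulse=0.0, t_chase1=7.0, t_chase2=21.0)
        fractions = [o[0] for o in obs]
        intervals = [o[1] for o in obs]
        assert fractions == pytest.approx([2 / 3, 3 / 4, 1 / 2])
        assert intervals == [7.0, 21.0, 14.0]

    def test_headline_fraction_uses_both_in_vivo_dyes(self):
        shape = (40, 40)
        labels = np.zeros(shape, dtype=int)
        labels[15:25, 15:25] = 1
        chans = {}
        for role, um in [("pulse", 2.0), ("chase", 1.0), ("chase2", 1.0)]:
            arr = np.full(shape, CAL[role].intercept)
            arr[labels == 1] += CAL[role].slope * um
            chans[role] = arr
        img = QuantImage(channels=chans)
        table = imagequant.quantify(img, labels, CAL, delta_t=21.0)
        assert table.loc[0, "fraction_pulse"] == pytest.approx(3 / 4)


class TestPixelPipeline:
    def test_per_pixel_lifetimes_with_floor(self):
        cal = CalibrationCurve({"pulse": (10.0, 50.0), "chase": (10.0, 50.0)})
        pulse = np.full((8, 8), 50.0 + 10.0 * 3.0)
        chase = np.full((8, 8), 50.0 + 10.0 * 3.0)
        pulse[0, 0] = chase[0, 0] = 50.0  # empty pixel
        img = QuantImage(channels={"pulse": pulse, "chase": chase})
        maps = imagequant.quantify_pixels(img, cal, delta_t=14.0,
                                          protein_floor_um=0.5)
        assert not maps["valid"][0, 0]
        assert maps["lifetime_days"][3, 3] == pytest.approx(
            14.0 / math.log(2))

    def test_median_filter_smooths_impulse(self):
        lt = np.full((9, 9), 10.0)
        lt[4, 4] = 1000.0
        filtered = imagequant.median_filter_lifetime(lt)
        assert filtered[4, 4] == 10.0


class TestAggregateRegions:
    @staticmethod
    def region_maps():
        lifetime = np.zeros((10, 10))
        lifetime[:, :5] = 5.0
        lifetime[:, 5:] = 10.0
        region = np.zeros((10, 10), int)
        region[:, :5] = 1
        region[:, 5:] = 2
        maps = {"lifetime_days": lifetime,
                "total_protein_um": np.ones((10, 10)),
                "um_pulse": np.ones((10, 10)) * 0.5,
                "um_chase": np.ones((10, 10)) * 0.5,
                "valid": np.ones((10, 10), bool)}
        return maps, region

    def test_constant_regions_recovered(self):
        maps, region = self.region_maps()
        table = imagequant.aggregate_regions(maps, region, exclude_ids=())
        means = dict(zip(table["region_id"], table["mean_lifetime_days"]))
        assert means == {1: 5.0, 2: 10.0}

    def test_excluded_regions_never_counted(self):
        maps, region = self.region_maps()
        table = imagequant.aggregate_regions(maps, region, exclude_ids=(2,))
        row = table[table["region_id"] == 2].iloc[0]
        assert row["excluded"] and row["reason"] == \
            imagequant.ATLAS_EXCLUSION_REASON
        assert "mean_lifetime_days" not in row.dropna()
        included = table[~table["excluded"]]
        assert set(included["region_id"]) == {1}

    def test_pixel_counts_conserved(self):
        maps, region = self.region_maps()
        table = imagequant.aggregate_regions(maps, region, exclude_ids=(1,))
        assert table["n_pixels"].sum() == maps["valid"].sum()

    def test_four_region_exact_means(self):
        rng = np.random.default_rng(4)
        region = np.repeat(np.arange(1, 5), 25).reshape(10, 10)
        lifetime = np.take([0.0, 6.0, 9.0, 12.0, 15.0], region)
        maps = {"lifetime_days": lifetime.astype(float),
                "total_protein_um": rng.uniform(1, 2, (10, 10)),
                "um_pulse": np.ones((10, 10)),
                "um_chase": np.ones((10, 10)),
                "valid": np.ones((10, 10), bool)}
        table = imagequant.aggregate_regions(maps, region, exclude_ids=())
        means = dict(zip(table["region_id"], table["mean_lifetime_days"]))
        assert means == {1: 6.0, 2: 9.0, 3: 12.0, 4: 15.0}


class TestNegativeControlFilter:
    @staticmethod
    def make_tables(signal_level, region_ids=range(1, 21)):
        rng = np.random.default_rng(0)
        controls = []
        for _ in range(3):
            controls.append(pd.DataFrame({
                "region_id": list(region_ids),
                "mean_pulse": 10.0 + rng.normal(0, 0.5, len(region_ids)),
                "mean_chase": 10.0 + rng.normal(0, 0.5, len(region_ids))}))
        signal = pd.DataFrame({
            "region_id": list(region_ids),
            "mean_pulse": signal_level, "mean_chase": signal_level})
        return controls, signal

    def test_signal_equal_to_control_all_excluded(self):
        controls, signal = self.make_tables(10.0)
        out = imagequant.negative_control_filter(controls, signal)
        assert out["excluded"].all()
        assert (out["reason"] == "negative_control_threshold").all()

    def test_strong_signal_none_excluded(self):
        controls, signal = self.make_tables(100.0)
        out = imagequant.negative_control_filter(controls, signal)
        assert not out["excluded"].any()

    def test_exactly_constructed_failures_excluded(self):
        controls, signal = self.make_tables(100.0)
        bad = [3, 7, 11, 15, 19]
        signal.loc[signal["region_id"].isin(bad), "mean_chase"] = 10.0
        out = imagequant.negative_control_filter(controls, signal)
        assert sorted(out.loc[out["excluded"], "region_id"]) == bad

    def test_region_without_controls_flagged(self):
        controls, signal = self.make_tables(100.0)
        extra = pd.DataFrame({"region_id": [99], "mean_pulse": [100.0],
                              "mean_chase": [100.0]})
        signal = pd.concat([signal, extra], ignore_index=True)
        out = imagequant.negative_control_filter(controls, signal)
        row = out[out["region_id"] == 99].iloc[0]
        assert row["excluded"] and row["reason"] == "no_control"
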