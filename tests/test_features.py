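"""Central-window physicochemical features, insertion estimation,
abundance weighting, Z-scoring and aggregation."""

from __future__ import annotations

import math
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from repfeat.features import (
    CentralRegionTooShort,
    DEFAULT_SCALES,
    FEATURE_COLUMNS,
    added_nucleotides,
    aggregate_sample_features,
    central_region,
    clonotype_charge,
    clonotype_strength,
    clonotype_volume,
    slice_features,
    weighted_feature,
    zscore_within_stratum,
)
from repfeat.simulate import SyntheticCohortConfig, recombine_clonotype

from conftest import make_clonotype
from test_metrics import make_slice


class TestCentralRegion:
    @pytest.mark.parametrize(
        "cdr3,expected",
        [
            ("CASSLGQAYEQYF", "LGQAY"),  # L=13, offset (13-5)//2 = 4
            ("CASSLGYEQYF", "SLGYE"),    # L=11, offset 3
            ("LGQAY", "LGQAY"),          # L=5: identity window
        ],
    )
    def test_window_extraction(self, cdr3, expected):
        assert central_region(cdr3) == expected

    def test_even_parity_tie_toward_n_terminus(self):
        # L=8: offset floor(3/2)=1, not 2
        assert central_region("ABCDEFGH".replace("B", "C")) == "CCDEF"[0:5]

    def test_too_short_is_exclusion_signal(self):
        with pytest.raises(CentralRegionTooShort):
            central_region("CASF")

    def test_nonfunctional_rejected(self):
        with pytest.raises(ValueError):
            central_region("CAS*LGYF")


class TestPhysicochemical:
    def test_strength_hand_value(self):
        # central of CASSLGQAYEQYF is LGQAY: L and Y strong -> 2/5
        assert clonotype_strength("CASSLGQAYEQYF") == 0.4

    def test_strength_extremes(self):
        assert clonotype_strength("WWWWW") == 1.0
        assert clonotype_strength("GGSGG") == 0.0

    def test_volume_constant_window(self):
        assert clonotype_volume("AAAAA") == DEFAULT_SCALES.volume_scale["A"]

    def test_volume_monotone_in_substitution(self):
        small, big = "GGGGG", "GGWGG"
        assert clonotype_volume(big) > clonotype_volume(small)

    def test_charge_hand_value(self):
        assert clonotype_charge("DEKRG") == 0.8

    def test_bounds(self):
        rng = np.random.default_rng(1)
        residues = list(DEFAULT_SCALES.volume_scale)
        vmin, vmax = min(DEFAULT_SCALES.volume_scale.values()), max(
            DEFAULT_SCALES.volume_scale.values())
        for _ in range(50):
            aa = "".join(rng.choice(residues, size=9))
            assert 0.0 <= clonotype_strength(aa) <= 1.0
            assert 0.0 <= clonotype_charge(aa) <= 1.0
            assert vmin <= clonotype_volume(aa) <= vmax


class TestAddedNucleotides:
    def test_annotated_path_exact(self, germline):
        cfg = SyntheticCohortConfig(seed=1)
        rng = np.random.default_rng(2)
        for _ in range(100):
            c = recombine_clonotype(germline, cfg, rng)
            assert added_nucleotides(c) == c.true_insertions

    def test_pure_germline_junction_is_zero(self, germline):
        cfg = SyntheticCohortConfig(
            insertion_mean_vd=0, insertion_mean_dj=0,
            v_trim_max=0, d_trim_max=0, j_trim_max=0, seed=1,
        )
        rng = np.random.default_rng(3)
        c = recombine_clonotype(germline, cfg, rng)
        blind = replace(c, v_end=None, d_span=None, j_start=None)
        assert added_nucleotides(blind, germline) == 0

    def test_estimator_recovery_mae(self, germline):
        """Blind germline-alignment estimate vs simulator ground truth:
        mean absolute error <= 1.5 nt at insertion means 4+4 (10,000 draws)."""
        cfg = SyntheticCohortConfig(insertion_mean_vd=4, insertion_mean_dj=4, seed=1)
        rng = np.random.default_rng(4)
        errs = []
        for _ in range(10_000):
            c = recombine_clonotype(germline, cfg, rng)
            blind = replace(c, v_end=None, d_span=None, j_start=None)
            errs.append(abs(added_nucleotides(blind, germline) - c.true_insertions))
        assert np.mean(errs) <= 1.5

    def test_needs_annotations_or_germline(self):
        c = make_clonotype("CASSLGYF", 1)
        with pytest.raises(ValueError):
            added_nucleotides(c)


class TestWeightedFeature:
    def test_weighted_mean_hand_value(self):
        sl = make_slice([
            make_clonotype("GGSGGGSGG", 1),   # strength 0
            make_clonotype("WWWWWWWWW", 3),   # strength 1
        ])
        val = weighted_feature(sl, lambda c: clonotype_strength(c.cdr3_aa))
        assert val == 0.75

    def test_uniform_counts_reduce_to_plain_mean(self):
        sl = make_slice([make_clonotype(f"CASS{a}GYF", 2) for a in "ADEK"])
        w = weighted_feature(sl, lambda c: clonotype_volume(c.cdr3_aa), "umi")
        u = weighted_feature(sl, lambda c: clonotype_volume(c.cdr3_aa), "unweighted")
        assert math.isclose(w, u)

    def test_equals_per_umi_expansion(self, synthetic_repertoire):
        """UMI weighting is identical to expanding each clonotype into
        per-molecule rows and taking a plain mean (brute-force oracle)."""
        from repfeat.io import slice_by_v
        v = synthetic_repertoire.v_segments()[0]
        sl = slice_by_v(synthetic_repertoire, v)
        feature = lambda c: float(len(c.cdr3_aa))
        got = weighted_feature(sl, feature)
        expanded = [feature(c) for c in sl.clonotypes for _ in range(c.umi_count)]
        assert math.isclose(got, np.mean(expanded))

    def test_invariant_to_count_rescaling(self):
        clons = [make_clonotype(f"CASS{a}GYF", n) for a, n in zip("ADEK", (1, 2, 3, 4))]
        scaled = [replace(c, umi_count=c.umi_count * 5) for c in clons]
        f = lambda c: clonotype_strength(c.cdr3_aa)
        assert math.isclose(
            weighted_feature(make_slice(clons), f),
            weighted_feature(make_slice(scaled), f),
        )

    def test_all_excluded_gives_missing(self):
        sl = make_slice([make_clonotype("CASGLGYF", 1)])
        short = replace(sl.clonotypes[0], cdr3_nt="CASTTT"[:0] + "TGTGCATTT",
                        cdr3_aa="CAF")
        sl = make_slice([short])
        assert weighted_feature(sl, lambda c: clonotype_strength(c.cdr3_aa)) is None


class TestZScore:
    def _frame(self, values, feature="strength", subset="nTreg", v="TRBV9"):
        return pd.DataFrame([
            {
                "sample_id": f"s{i}", "donor_id": f"d{i}", "cohort": "young",
                "subset": subset, "v_segment": v, "feature": feature,
                "raw_value": x, "z_value": np.nan,
                "n_umi_used": 100, "n_clonotypes_used": 10,
            }
            for i, x in enumerate(values)
        ])

    def test_hand_values(self):
        out = zscore_within_stratum(self._frame([1.0, 2.0, 3.0]))
        np.testing.assert_allclose(
            out["z_value"].to_numpy(), [-1.2247448, 0.0, 1.2247448], atol=1e-6
        )

    def test_degenerate_stratum_maps_to_zero(self):
        out = zscore_within_stratum(self._frame([5.0, 5.0, 5.0]))
        assert (out["z_value"] == 0).all()

    def test_normalization_identity(self):
        rng = np.random.default_rng(8)
        out = zscore_within_stratum(self._frame(rng.normal(size=12)))
        z = out["z_value"].to_numpy()
        assert abs(z.mean()) < 1e-9
        assert abs(z.std(ddof=0) - 1) < 1e-9

    def test_idempotent_on_zscored_strata(self):
        rng = np.random.default_rng(9)
        once = zscore_within_stratum(self._frame(rng.normal(size=10)))
        once = once.assign(raw_value=once["z_value"])
        twice = zscore_within_stratum(once)
        np.testing.assert_allclose(
            twice["z_value"].to_numpy(), once["z_value"].to_numpy(), atol=1e-9
        )

    def test_singleton_stratum_dropped(self):
        out = zscore_within_stratum(self._frame([1.0]))
        assert out.empty


class TestAggregate:
    def _two_segment_frame(self):
        rows = []
        for v, z in (("TRBV1", 1.0), ("TRBV2", 1.0)):
            for i in range(3):
                rows.append({
                    "sample_id": f"s{i}", "donor_id": f"d{i}", "cohort": "young",
                    "subset": "nTreg", "v_segment": v, "feature": "strength",
                    "raw_value": 0.5, "z_value": z,
                    "n_umi_used": 100, "n_clonotypes_used": 10,
                })
        return pd.DataFrame(rows)

    def test_single_segment_modes_coincide(self):
        df = self._two_segment_frame().query("v_segment == 'TRBV1'")
        pooled = aggregate_sample_features(df, "pooled_segments")
        mean = aggregate_sample_features(df, "mean_over_segments")
        assert len(pooled) == len(mean) == 3
        np.testing.assert_allclose(
            sorted(pooled["z_value"]), sorted(mean["z_value"])
        )

    def test_constant_z_preserved_by_mean(self):
        out = aggregate_sample_features(self._two_segment_frame(), "mean_over_segments")
        assert (out["z_value"] == 1.0).all()
        assert len(out) == 3  # one row per sample

    def test_pooled_row_count_bookkeeping(self):
        df = self._two_segment_frame()
        pooled = aggregate_sample_features(df, "pooled_segments")
        assert len(pooled) == len(df)


class TestSliceFeatures:
    def test_tidy_records_complete(self, synthetic_repertoire):
        from repfeat.io import slice_by_v
        v = synthetic_repertoire.v_segments()[0]
        recs = slice_features(slice_by_v(synthetic_repertoire, v))
        df = pd.DataFrame(recs)
        assert set(df.columns) == set(FEATURE_COLUMNS)
        assert set(df["feature"]) == {"strength", "volume", "charge", "cdr3_len", "added_nt"}
        assert (df["n_umi_used"] > 0).all()
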