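"""Centromere calling, composition, classification, regression, metaplots."""
import numpy as np
import pandas as pd
import pytest

from caninakit.centromere import (CentromereInterval, SignalTrack,
                                  call_centromere, canr4_cenh3_regression,
                                  classify_centromere, classify_composition,
                                  enrichment_track, metaplot, metaplot_frame,
                                  methylation_summary, profiles_frame,
                                  repeat_composition)
from caninakit.errors import CaninakitError
from caninakit.genome_map import ChromRecord, GenomeMap
from caninakit.simulate import generate_chip_tracks


def _track(values, chrom="c1", window=10_000, kind="log2_ratio"):
    n = len(values)
    starts = np.arange(n) * window
    return SignalTrack(pd.DataFrame({"chrom": chrom, "start0": starts,
                                     "end": starts + window,
                                     "value": np.asarray(values, float)}),
                       kind, window)


class TestEnrichmentTrack:
    def test_equal_tracks_give_zero(self):
        a = _track([2.0, 5.0, 1.0], kind="cenh3")
        b = _track([2.0, 5.0, 1.0], kind="h3")
        out = enrichment_track(a, b, pseudocount=1e-9)
        assert np.allclose(out.df["value"], 0.0)

    def test_eightfold_region_gives_three(self):
        a = _track([1.0, 8.0, 1.0], kind="cenh3")
        b = _track([1.0, 1.0, 1.0], kind="h3")
        out = enrichment_track(a, b, pseudocount=1e-9)
        assert out.df["value"].iloc[1] == pytest.approx(3.0, abs=1e-6)

    def test_window_mismatch_raises(self):
        a = _track([1.0, 2.0], kind="cenh3")
        b = _track([1.0, 2.0, 3.0], kind="h3")
        with pytest.raises(CaninakitError, match="window"):
            enrichment_track(a, b)

    def test_mass_normalization_equalizes_totals(self):
        a = _track([4.0, 4.0, 4.0], kind="cenh3")
        b = _track([1.0, 1.0, 1.0], kind="h3")
        out = enrichment_track(a, b, pseudocount=1e-9, normalize="mass")
        assert np.allclose(out.df["value"], 0.0)  # constant factor cancels


class TestCallCentromere:
    def test_noiseless_block_called_exactly(self):
        values = [0.0] * 20 + [3.0] * 10 + [0.0] * 20
        calls = call_centromere(_track(values), threshold_k=2.0, merge_gap=100_000)
        assert len(calls) == 1
        c = calls[0]
        assert (c.start0, c.end) == (20 * 10_000, 30 * 10_000)
        assert c.cenh3_abundance == pytest.approx(30.0)
        assert c.start0 <= c.max_position < c.end

    def test_two_peaks_within_gap_span_one_interval(self):
        # enrichment peaks at windows 10 and 12-13; gap below merge_gap
        values = [0.0] * 10 + [3.0] + [0.0] + [3.0, 3.2] + [0.0] * 10
        calls = call_centromere(_track(values), threshold_k=1.0, merge_gap=30_000)
        assert len(calls) == 1
        c = calls[0]
        assert (c.start0, c.end) == (10 * 10_000, 14 * 10_000)

    def test_distant_cluster_not_merged(self):
        values = [0.0] * 5 + [3.0] + [0.0] * 40 + [4.0, 4.0] + [0.0] * 5
        calls = call_centromere(_track(values), threshold_k=1.5, merge_gap=30_000)
        c = calls[0]
        # the cluster containing the global maximum wins
        assert c.start0 == 46 * 10_000 and c.end == 48 * 10_000

    def test_flat_track_gives_no_centromere(self):
        calls = call_centromere(_track([0.0] * 30))
        assert calls == []

    def test_call_contains_chromosomewide_argmax(self, bundle_default,
                                                 chip_default):
        cenh3, h3, _ = chip_default
        track = enrichment_track(cenh3, h3)
        for c in call_centromere(track):
            sub = track.chrom_values(c.chrom)
            arg = sub.loc[sub["value"].idxmax()]
            assert c.start0 <= arg["start0"] < c.end


class TestRepeatComposition:
    def _interval(self, start, end, chrom="c1"):
        return CentromereInterval(chrom, start, end, 0.0, start)

    def test_feature_fully_inside(self):
        ann = pd.DataFrame([{"chrom": "c1", "start0": 100_000, "end": 600_000,
                             "family": "CANR4"}])
        p = repeat_composition(self._interval(0, 1_000_000), ann)
        assert p.canr4_bp == 500_000

    def test_half_overlapping_feature_clipped(self):
        ann = pd.DataFrame([{"chrom": "c1", "start0": 900_000, "end": 1_100_000,
                             "family": "ATHILA"}])
        p = repeat_composition(self._interval(0, 1_000_000), ann)
        assert p.athila_bp == 100_000

    def test_invariant_to_feature_splitting(self):
        whole = pd.DataFrame([{"chrom": "c1", "start0": 10_000, "end": 40_000,
                               "family": "CANR4"}])
        split = pd.DataFrame([
            {"chrom": "c1", "start0": 10_000, "end": 25_000, "family": "CANR4"},
            {"chrom": "c1", "start0": 20_000, "end": 40_000, "family": "CANR4"}])
        iv = self._interval(0, 100_000)
        assert repeat_composition(iv, whole).canr4_bp == \
            repeat_composition(iv, split).canr4_bp == 30_000

    def test_nested_ltr_features_not_double_counted(self):
        ann = pd.DataFrame([
            {"chrom": "c1", "start0": 0, "end": 1_600, "family": "ATHILA"},
            {"chrom": "c1", "start0": 0, "end": 400, "family": "ATHILA_LTR"},
            {"chrom": "c1", "start0": 1_200, "end": 1_600, "family": "ATHILA_LTR"}])
        p = repeat_composition(self._interval(0, 10_000), ann)
        assert p.athila_bp == 1_600

    def test_generator_composition_matches_truth(self, bundle_default):
        truth = bundle_default.truth.centromeres
        for r in truth.head(10).itertuples():
            iv = CentromereInterval(r.chrom, r.start0, r.end, 0.0, r.start0)
            p = repeat_composition(iv, bundle_default.features)
            assert p.canr4_bp == r.canr4_bp
            assert p.athila_bp == r.athila_bp
            assert p.cenltr_bp == r.cenltr_bp


class TestClassification:
    def test_satellite_dominated(self):
        assert classify_composition(80_000, 0, 0, 100_000) == "CANR4-based"

    def test_cenltr_array_without_satellite(self):
        # a 235 kb LTR-derived tandem array, no satellite
        assert classify_composition(0, 40_000, 235_000, 300_000) == "cenLTR-based"

    def test_retroelement_based(self):
        assert classify_composition(0, 60_000, 0, 100_000) == "ATHILA-based"

    def test_mixed_fallback(self):
        assert classify_composition(10_000, 10_000, 0, 100_000) == "mixed"

    def test_zero_length_raises(self):
        with pytest.raises(CaninakitError):
            classify_composition(0, 0, 0, 0)

    def test_truth_class_recovery_all_35(self, bundle_default, chip_default):
        cenh3, h3, _ = chip_default
        track = enrichment_track(cenh3, h3)
        calls = call_centromere(track)
        truth = bundle_default.truth.centromeres.set_index("chrom")
        assert len(calls) == 35
        for c in calls:
            p = classify_centromere(repeat_composition(c, bundle_default.features))
            assert p.cls == truth.loc[c.chrom, "class"]


class TestRegression:
    def _profiles(self, xs, ys):
        out = []
        for i, (x, y) in enumerate(zip(xs, ys)):
            iv = CentromereInterval(f"c{i}", 0, 100_000, float(y), 0)
            p = classify_centromere(repeat_composition(iv, pd.DataFrame(
                columns=["chrom", "start0", "end", "family"])))
            p.canr4_bp = int(x)
            out.append(p)
        return out

    def test_collinear_points(self):
        xs = [0, 10_000, 20_000, 30_000]
        ys = [1.0, 2.0, 3.0, 4.0]
        r = canr4_cenh3_regression(self._profiles(xs, ys))
        assert r.r_squared == pytest.approx(1.0)
        assert r.spearman_rho == pytest.approx(1.0)
        assert r.slope == pytest.approx(1.0 / 10_000)

    def test_strictly_decreasing_rho_minus_one(self):
        r = canr4_cenh3_regression(self._profiles([0, 1000, 2000], [5, 3, 1]))
        assert r.spearman_rho == pytest.approx(-1.0)

    def test_constant_predictor_reported_missing(self):
        r = canr4_cenh3_regression(self._profiles([500] * 4, [1, 2, 3, 4]))
        assert r.r_squared is None and "constant" in r.diagnostic

    def test_matches_normal_equations_oracle(self, bundle_default, chip_default):
        cenh3, h3, _ = chip_default
        track = enrichment_track(cenh3, h3)
        calls = call_centromere(track)
        profiles = [classify_centromere(
            repeat_composition(c, bundle_default.features)) for c in calls]
        r = canr4_cenh3_regression(profiles)
        df = profiles_frame(profiles)
        x = df["canr4_bp"].to_numpy(float)
        y = df["cenh3_abundance"].to_numpy(float)
        # normal equations, solved directly
        X = np.column_stack([x, np.ones_like(x)])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ beta
        r2 = 1 - resid @ resid / ((y - y.mean()) @ (y - y.mean()))
        assert r.slope == pytest.approx(beta[0], rel=1e-9)
        assert r.intercept == pytest.approx(beta[1], rel=1e-9)
        assert r.r_squared == pytest.approx(r2, rel=1e-9)
        assert r.spearman_rho > 0.8

    def test_too_few_points_raises(self):
        with pytest.raises(CaninakitError):
            canr4_cenh3_regression(self._profiles([1, 2], [1, 2]))


class TestMetaplot:
    def _gm(self, n=1, length=500_000):
        return GenomeMap([ChromRecord(f"c{i + 1}", i + 1, "S1", None, length)
                          for i in range(n)])

    def test_constant_signal_scales_to_one(self):
        track = _track([2.0] * 50, window=10_000)
        calls = [CentromereInterval("c1", 240_000, 260_000, 1.0, 250_000)]
        mp = metaplot({"sig": track}, calls, self._gm(), n_bins=10)
        assert np.allclose(mp.profiles[("S1", "sig")], 1.0)

    def test_symmetric_signal_arms_agree(self):
        vals = np.concatenate([np.linspace(0, 3, 25), np.linspace(3, 0, 25)])
        track = _track(vals, window=10_000)
        calls = [CentromereInterval("c1", 240_000, 260_000, 1.0, 250_000)]
        mp = metaplot({"sig": track}, calls, self._gm(), n_bins=10)
        prof = mp.profiles[("S1", "sig")]
        # telomere (0) low, centromere (1) high, monotone overall
        assert prof[0] == min(prof) and prof[-1] == max(prof)
        assert (np.diff(prof) >= -1e-9).all()

    def test_scaled_values_within_unit_interval(self, bundle_default,
                                                chip_default):
        cenh3, h3, _ = chip_default
        track = enrichment_track(cenh3, h3)
        calls = call_centromere(track)
        mp = metaplot({"cenh3_log2": track}, calls, bundle_default.genome_map)
        for (sub, kind), prof in mp.profiles.items():
            assert prof.min() >= -1e-9 and prof.max() <= 1 + 1e-9
        # identical bin grid across subgenomes
        subs = {sub for sub, _ in mp.profiles}
        assert len(subs) == 4 and len(mp.coords) == 100

    def test_proximity_profile_rises_toward_centromere(self, bundle_default,
                                                       chip_default):
        from scipy.stats import spearmanr

        cenh3, h3, _ = chip_default
        track = enrichment_track(cenh3, h3)
        calls = call_centromere(track)
        mp = metaplot({"cenh3_log2": track}, calls, bundle_default.genome_map,
                      proximity_fraction=0.20)
        for sub in ("S1", "S2", "R3", "R4"):
            coords, vals = mp.proximity_view(sub, "cenh3_log2")
            assert vals[-1] > vals[0]
            assert spearmanr(coords, vals).statistic > 0.8

    def test_missing_call_warns_and_skips(self):
        track = _track([1.0] * 50, window=10_000)
        with pytest.warns(UserWarning, match="no centromere"):
            mp = metaplot({"sig": track}, [], self._gm(), n_bins=5)
        assert mp.profiles == {}

    def test_bad_bins_raise(self):
        with pytest.raises(ValueError):
            metaplot({}, [], self._gm(), n_bins=1)

    def test_frame_export(self):
        track = _track([2.0] * 50, window=10_000)
        calls = [CentromereInterval("c1", 240_000, 260_000, 1.0, 250_000)]
        mp = metaplot({"sig": track}, calls, self._gm(), n_bins=10)
        df = metaplot_frame(mp)
        assert set(df.columns) == {"subgenome", "kind", "scaled_coord", "value"}
        assert len(df) == 10


class TestMethylationSummary:
    def test_all_methylated_is_hundred(self):
        calls = pd.DataFrame({"chrom": ["c1"] * 4, "pos0": [10, 20, 30, 40],
                              "context": ["CpG"] * 4,
                              "methylated": [3, 2, 5, 1],
                              "unmethylated": [0, 0, 0, 0]})
        tracks = methylation_summary(calls, 1_000, {"c1": 2_000})
        assert tracks["methylation_CpG"].df["value"].iloc[0] == 100.0

    def test_one_of_four_is_25(self):
        calls = pd.DataFrame({"chrom": ["c1"], "pos0": [10],
                              "context": ["CHG"], "methylated": [1],
                              "unmethylated": [3]})
        tracks = methylation_summary(calls, 1_000, {"c1": 1_000})
        assert tracks["methylation_CHG"].df["value"].iloc[0] == 25.0

    def test_window_without_cytosines_is_nan(self):
        calls = pd.DataFrame({"chrom": ["c1"], "pos0": [10],
                              "context": ["CpG"], "methylated": [1],
                              "unmethylated": [0]})
        tracks = methylation_summary(calls, 1_000, {"c1": 3_000})
        vals = tracks["methylation_CpG"].df["value"]
        assert np.isnan(vals.iloc[1]) and np.isnan(vals.iloc[2])

    def test_unknown_context_raises(self):
        calls = pd.DataFrame({"chrom": ["c1"], "pos0": [1], "context": ["CWW"],
                              "methylated": [1], "unmethylated": [1]})
        with pytest.raises(CaninakitError):
            methylation_summary(calls, 1_000, {"c1": 1_000})


class TestTruthIntervalRecovery:
    def test_reciprocal_overlap_all_chromosomes(self, bundle_default,
                                                chip_default):
        cenh3, h3, _ = chip_default
        track = enrichment_track(cenh3, h3)
        calls = call_centromere(track)
        truth = bundle_default.truth.centromeres.set_index("chrom")
        assert len(calls) == 35
        for c in calls:
            t = truth.loc[c.chrom]
            inter = max(0, min(c.end, t.end) - max(c.start0, t.start0))
            ro = inter / max(c.end - c.start0, t.end - t.start0)
            assert ro >= 0.8, c.chrom
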