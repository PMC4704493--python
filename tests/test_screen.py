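import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mimictox import screen as mscreen
from mimictox.datatypes import MimicAnnotations, ScreenPlate, ZScoreMatrix
from mimictox.errors import (AnnotationGapError, ConfigError,
                             DegenerateDataError)


def _one_row_plate(values, row="A"):
    wells = pd.DataFrame({"row": row, "column": range(1, len(values) + 1),
                          "mimic_id": [f"m{i}" for i in range(len(values))],
                          "value": values})
    return ScreenPlate("P", "L", 1, wells)


class TestNormalizeRowMedian:
    @pytest.mark.parametrize("values,expected", [
        ([4.0, 4.0, 4.0], [1.0, 1.0, 1.0]),
        ([2.0, 4.0, 6.0], [0.5, 1.0, 1.5]),
    ])
    def test_known_rows(self, values, expected):
        out = mscreen.normalize_row_median(_one_row_plate(values))
        assert out.wells["value"].tolist() == expected

    def test_planted_gains_removed(self, grid_plate):
        plate, gains = grid_plate
        out = mscreen.normalize_row_median(plate)
        # spreadsheet-style recomputation: value / row median, per well
        raw = plate.wells.set_index(["row", "column"])["value"]
        expected = raw / raw.groupby("row").median()
        got = out.wells.set_index(["row", "column"])["value"]
        assert np.allclose(got, expected.loc[got.index])
        medians = out.wells.groupby("row")["value"].median()
        assert np.allclose(medians, 1.0)

    def test_zero_median_row_rejected(self):
        with pytest.raises(DegenerateDataError, match="row"):
            mscreen.normalize_row_median(_one_row_plate([0.0, 0.0, 1.0]))

    @settings(derandomize=True, max_examples=25)
    @given(scale=st.floats(min_value=1e-3, max_value=1e3))
    def test_scale_invariance(self, scale):
        base = [80.0, 100.0, 120.0, 95.0]
        a = mscreen.normalize_row_median(_one_row_plate(base))
        b = mscreen.normalize_row_median(
            _one_row_plate([v * scale for v in base]))
        assert np.allclose(a.wells["value"], b.wells["value"])


class TestAggregateReplicates:
    def _replicate_plates(self, triples):
        plates = []
        for rep in range(1, 4):
            wells = pd.DataFrame({
                "row": "A", "column": range(1, len(triples) + 1),
                "mimic_id": list(triples),
                "value": [triples[m][rep - 1] for m in triples]})
            wells = wells.dropna(subset=["value"])
            plates.append(ScreenPlate(f"P-r{rep}", "L", rep, wells,
                                      normalized=True))
        return plates

    def test_mean_and_sample_sd(self):
        plates = self._replicate_plates({"a": (1.0, 1.0, 1.0),
                                         "b": (0.8, 1.0, 1.2)})
        mean, sd, n = mscreen.aggregate_replicates(plates)
        assert mean.loc["a", "L"] == 1.0 and sd.loc["a", "L"] == 0.0
        assert mean.loc["b", "L"] == pytest.approx(1.0)
        assert sd.loc["b", "L"] == pytest.approx(0.2)
        assert (n == 3).all().all()

    def test_missing_replicate_counted_not_fabricated(self):
        plates = self._replicate_plates({"a": (1.0, 1.0, 1.0),
                                         "b": (0.9, 1.1, np.nan)})
        mean, sd, n = mscreen.aggregate_replicates(plates)
        assert n.loc["b", "L"] == 2
        assert mean.loc["b", "L"] == pytest.approx(1.0)
        assert sd.loc["b", "L"] == pytest.approx(np.std([0.9, 1.1], ddof=1))

    def test_single_replicate_sd_flagged_missing(self):
        plates = self._replicate_plates({"a": (1.0, np.nan, np.nan)})
        mean, sd, n = mscreen.aggregate_replicates(plates)
        assert n.loc["a", "L"] == 1 and np.isnan(sd.loc["a", "L"])


class TestComputeZscores:
    def test_three_values(self):
        mv = pd.DataFrame({"L": [1.0, 2.0, 3.0]}, index=["a", "b", "c"])
        z = mscreen.compute_zscores(mv)
        assert z.z["L"].tolist() == [-1.0, 0.0, 1.0]

    def test_constant_column_rejected(self):
        mv = pd.DataFrame({"L": [1.0, 1.0, 1.0]}, index=list("abc"))
        with pytest.raises(DegenerateDataError):
            mscreen.compute_zscores(mv)

    def test_matches_two_pass_oracle(self, screen_run):
        mean = screen_run["mean"]
        z = screen_run["zm"].z.to_numpy()
        x = mean.to_numpy()
        mu = x.mean(axis=0)
        sd = np.sqrt(((x - mu) ** 2).sum(axis=0) / (x.shape[0] - 1))
        assert np.abs(z - (x - mu) / sd).max() <= 1e-10

    def test_column_standardization_invariant(self, screen_run):
        z = screen_run["zm"].z
        assert np.abs(z.mean(axis=0)).max() <= 1e-9
        assert np.abs(z.std(axis=0, ddof=1) - 1).max() <= 1e-9

    def test_affine_invariance(self):
        rng = np.random.default_rng(0)
        mv = pd.DataFrame({"L": rng.normal(1, 0.1, 20)},
                          index=[f"m{i}" for i in range(20)])
        z1 = mscreen.compute_zscores(mv).z
        z2 = mscreen.compute_zscores(3.7 * mv + 11.0).z
        assert np.allclose(z1, z2)


class TestCallHits:
    def test_inclusive_boundary(self):
        z = ZScoreMatrix(pd.DataFrame({"L": [-2.0, -1.99, 0.4]},
                                      index=list("abc")))
        hits = mscreen.call_hits(z)
        assert hits["mimic_id"].tolist() == ["a"]

    def test_planted_count(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.uniform(-1.5, 1.5, (50, 4)),
                          index=[f"m{i}" for i in range(50)],
                          columns=list("wxyz"))
        planted = [("m3", "w"), ("m10", "y"), ("m10", "z")]
        for m, l in planted:
            df.loc[m, l] = -2.5
        hits = mscreen.call_hits(ZScoreMatrix(df))
        assert set(map(tuple, hits[["mimic_id", "cell_line"]].values)) \
            == set(planted)

    @settings(derandomize=True, max_examples=20)
    @given(t1=st.floats(min_value=-4, max_value=-0.5),
           t2=st.floats(min_value=-4, max_value=-0.5))
    def test_monotone_in_threshold(self, t1, t2):
        rng = np.random.default_rng(11)
        z = ZScoreMatrix(pd.DataFrame(rng.normal(0, 2, (30, 3)),
                                      index=[f"m{i}" for i in range(30)],
                                      columns=list("abc")))
        lo, hi = sorted([t1, t2])
        s_lo = set(map(tuple, mscreen.call_hits(z, lo)[["mimic_id", "cell_line"]].values))
        s_hi = set(map(tuple, mscreen.call_hits(z, hi)[["mimic_id", "cell_line"]].values))
        assert s_lo <= s_hi

    def test_deterministic(self, screen_run):
        again = mscreen.call_hits(screen_run["zm"])
        pd.testing.assert_frame_equal(again, screen_run["hits"])

    def test_positive_threshold_rejected(self, screen_run):
        with pytest.raises(ConfigError):
            mscreen.call_hits(screen_run["zm"], threshold=2.0)


class TestResponsivenessSummary:
    def test_single_private_hit(self):
        hits = pd.DataFrame({"mimic_id": ["a"], "cell_line": ["L1"],
                             "z": [-3.0]})
        s = mscreen.responsiveness_summary(hits, 16)
        assert s.histogram[0] == 1 and s.histogram[1:].sum() == 0
        assert s.fraction_private == 1.0 and s.max_lines == 1

    def test_empty_table_signals_undefined_fraction(self):
        s = mscreen.responsiveness_summary(
            pd.DataFrame(columns=["mimic_id", "cell_line", "z"]), 16)
        assert s.histogram.sum() == 0 and s.fraction_private is None
        assert s.max_lines == 0

    def test_planted_design(self):
        # 60 mimics hitting 1 line, 26 hitting 2, 22 spread over 3..9
        rows = []
        mid = 0
        for count, n_mimics in [(1, 60), (2, 26)] + [(c, 3) for c in range(3, 9)] + [(9, 4)]:
            for _ in range(n_mimics):
                mid += 1
                for l in range(count):
                    rows.append({"mimic_id": f"m{mid:03d}",
                                 "cell_line": f"L{l}", "z": -2.5})
        hits = pd.DataFrame(rows)
        s = mscreen.responsiveness_summary(hits, 16)
        assert s.n_hit_mimics == 108
        assert s.histogram.sum() == 108
        assert s.fraction_private == pytest.approx(86 / 108)
        assert s.max_lines == 9


class TestCollapseUniqueMature:
    def _ann(self, seqs):
        return MimicAnnotations.from_sequences(pd.Series(seqs))

    def test_shared_sequence_collapses(self):
        seq = "ACGUACGUACGUACGUACGUAC"
        ann = self._ann({"a": seq, "b": seq})
        hits = pd.DataFrame({"mimic_id": ["a", "b"], "cell_line": "L",
                             "z": -3.0})
        assert mscreen.collapse_unique_mature(hits, ann) == 1

    def test_distinct_sequences(self):
        ann = self._ann({"a": "ACGUACGUACGUACGUACGUAC",
                         "b": "UGCAUGCAUGCAUGCAUGCAUG",
                         "c": "AAAACCCCGGGGUUUUAACCGG"})
        hits = pd.DataFrame({"mimic_id": list("abc"), "cell_line": "L",
                             "z": -3.0})
        assert mscreen.collapse_unique_mature(hits, ann) == 3

    def test_unannotated_mimic_raises(self):
        ann = self._ann({"a": "ACGUACGUACGUACGUACGUAC"})
        hits = pd.DataFrame({"mimic_id": ["a", "ghost"], "cell_line": "L",
                             "z": -3.0})
        with pytest.raises(AnnotationGapError, match="ghost"):
            mscreen.collapse_unique_mature(hits, ann)

    def test_duplication_map_on_synthetic_library(self, screen_run):
        hits, ann = screen_run["hits"], screen_run["ann"]
        n = mscreen.collapse_unique_mature(hits, ann)
        hit_ids = hits["mimic_id"].unique()
        assert n == len({ann.table.loc[m, "mature_sequence"] for m in hit_ids})
        assert n <= len(hit_ids)


class TestVarianceProfile:
    def _ann_for(self, index, family_seed=None):
        rng = np.random.default_rng(0)
        seqs = {}
        for m in index:
            if family_seed:
                seqs[m] = "A" + family_seed + "".join(
                    rng.choice(list("ACGU"), 14))
            else:
                seqs[m] = "".join(rng.choice(list("ACGU"), 22))
        return MimicAnnotations.from_sequences(pd.Series(seqs))

    def test_identical_phenotypes_give_zero_sds(self):
        mv = pd.DataFrame(1.0, index=[f"m{i}" for i in range(10)],
                          columns=list("abcd"))
        sd = pd.DataFrame(0.01, index=mv.index, columns=mv.columns)
        ann = self._ann_for(mv.index, family_seed="ACGUACG")
        prof = mscreen.variance_profile(mv, sd, ann)
        assert (prof.across_panel_sd == 0).all()
        assert (prof.family_sd == 0).all()
        # KDE mass concentrates at 0
        grid, dens = prof.kde["across_panel"]
        assert abs(grid[np.argmax(dens)]) < 1e-3

    def test_all_singleton_families_signaled(self):
        rng = np.random.default_rng(1)
        mv = pd.DataFrame(rng.normal(1, 0.1, (8, 4)),
                          index=[f"m{i}" for i in range(8)],
                          columns=list("abcd"))
        sd = pd.DataFrame(0.02, index=mv.index, columns=mv.columns)
        prof = mscreen.variance_profile(mv, sd, self._ann_for(mv.index))
        assert not prof.family_defined and prof.family_sd.empty

    def test_kde_integrates_to_one(self, screen_run):
        prof = mscreen.variance_profile(screen_run["mean"], screen_run["sd"],
                                        screen_run["ann"])
        for grid, dens in prof.kde.values():
            assert np.trapezoid(dens, grid) == pytest.approx(1.0, abs=1e-3)

    def test_family_correlation_orders_medians(self, screen_run):
        # planted intra-family correlation 0.8: family SDs sit below the
        # across-panel phenotypic SDs
        prof = mscreen.variance_profile(screen_run["mean"], screen_run["sd"],
                                        screen_run["ann"])
        assert prof.family_defined
        assert prof.family_sd.median() < prof.across_panel_sd.median()
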