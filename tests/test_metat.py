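"""mRNA:rRNA pipeline: ratios, QC, relative abundance, half-life estimation."""

import numpy as np
import pandas as pd
import pytest

from rifdecay import (
    AnnotatedCounts,
    CommunityConfig,
    FitSettings,
    QcAbortError,
    ValidationError,
    estimate_class_cog_halflives,
    estimate_family_halflives,
    family_relative_abundance,
    mrna_rrna_ratio,
    qc_filter_samples,
    simulate_metatranscriptome,
)
from rifdecay.metat import _disagreement


class TestRatio:
    def test_basic_ratio(self, paired_tables):
        m, r = paired_tables({"f": [100, 80, 20, 10]}, {"f": [1000] * 4})
        s = mrna_rrna_ratio(m, r, "f")
        assert s.values == pytest.approx([0.1, 0.08, 0.02, 0.01])
        assert s.detected.all()

    def test_depth_invariance_of_one_sample(self, paired_tables):
        m1, r1 = paired_tables({"f": [100, 80, 20, 10]}, {"f": [1000] * 4})
        m2, r2 = paired_tables({"f": [100, 160, 20, 10]},
                               {"f": [1000, 2000, 1000, 1000]})
        s1 = mrna_rrna_ratio(m1, r1, "f")
        s2 = mrna_rrna_ratio(m2, r2, "f")
        assert s1.values == pytest.approx(s2.values)

    def test_zero_counts_flag_undetected(self, paired_tables):
        m, r = paired_tables({"f": [5, 0, 1, 0]}, {"f": [10, 10, 0, 10]})
        s = mrna_rrna_ratio(m, r, "f")
        assert list(s.detected) == [True, False, False, False]

    def test_missing_feature_raises_keyerror(self, paired_tables):
        m, r = paired_tables({"f": [1, 1, 1, 1]}, {"g": [1, 1, 1, 1]})
        with pytest.raises(KeyError):
            mrna_rrna_ratio(m, r, "f")

    def test_mismatched_columns_rejected(self, paired_tables):
        m, _ = paired_tables({"f": [1, 1, 1, 1]}, {"f": [1, 1, 1, 1]})
        r = AnnotatedCounts(
            pd.DataFrame({"0": [1], "5": [1], "20": [1], "60": [1]}, index=["f"]),
            "rRNA",
        )
        with pytest.raises(ValidationError, match="columns"):
            mrna_rrna_ratio(m, r, "f")


class TestRelativeAbundance:
    def test_single_family(self, paired_tables):
        _, r = paired_tables({}, {"f": [10, 20, 30, 40]})
        out = family_relative_abundance(r)
        assert out.loc["f", "mean"] == 1.0
        assert out.loc["f", "sd"] == 0.0

    def test_two_families_constant_split(self, paired_tables):
        _, r = paired_tables({}, {"a": [300] * 4, "b": [700] * 4})
        out = family_relative_abundance(r)
        assert out["mean"].to_dict() == pytest.approx({"a": 0.3, "b": 0.7})
        assert out["sd"].to_dict() == pytest.approx({"a": 0.0, "b": 0.0})

    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(7)
        counts = pd.DataFrame(rng.integers(1, 500, size=(20, 4)),
                              index=[f"f{i}" for i in range(20)],
                              columns=["0", "5", "40", "60"])
        r = AnnotatedCounts(counts, "rRNA")
        fractions = r.counts / r.counts.sum(axis=0)
        assert fractions.sum(axis=0).to_numpy() == pytest.approx(np.ones(4))


def _profiled_tables(n_samples=7, n_features=40, seed=0, scrambled=()):
    """Replicated family profiles; in scrambled samples, half the features
    get their mRNA counts re-assigned in reversed rank order (a 50%
    compositional scramble)."""
    rng = np.random.default_rng(seed)
    cols = [f"{5 * i}" for i in range(n_samples)]
    base_m = rng.integers(50, 5000, size=n_features)
    base_r = rng.integers(500, 20000, size=n_features)
    m = pd.DataFrame({c: base_m for c in cols},
                     index=[f"f{i}" for i in range(n_features)])
    r = pd.DataFrame({c: base_r for c in cols}, index=m.index)
    for c in scrambled:
        half = rng.choice(n_features, size=n_features // 2, replace=False)
        vals = m.iloc[half][c].to_numpy()
        order = np.argsort(vals)
        anti = np.empty_like(vals)
        anti[order] = np.sort(vals)[::-1]
        m.loc[m.index[half], c] = anti
    return AnnotatedCounts(m, "mRNA", None), AnnotatedCounts(r, "rRNA", None)


class TestQcFilter:
    def test_identical_profiles_have_zero_disagreement(self):
        m, r = _profiled_tables()
        qc = qc_filter_samples(m, r)
        assert qc.per_sample["disagreement"].to_numpy() == pytest.approx(0.0)
        assert not qc.per_sample["dropped"].any()

    def test_scrambled_samples_flagged_as_outliers(self):
        # emulates the study losing its 2.5/10/20-min samples to disagreement
        scrambled = {"5", "15", "20"}
        m, r = _profiled_tables(scrambled=sorted(scrambled, key=float))
        qc = qc_filter_samples(m, r)
        flagged = set(qc.per_sample.index[qc.per_sample["outlier"]])
        assert flagged == scrambled
        assert set(qc.retained_cols) == {"0", "10", "25", "30"}

    def test_low_retention_dropped(self):
        m, r = _profiled_tables()
        qc = qc_filter_samples(
            m, r, original_mrna_reads={"10": float(m.counts["10"].sum()) / 0.4}
        )
        assert qc.per_sample.loc["10", "retained_fraction"] == pytest.approx(0.4)
        assert qc.per_sample.loc["10", "dropped"]
        assert "10" not in qc.retained_cols

    def test_abort_when_too_few_samples_survive(self):
        m, r = _profiled_tables(n_samples=4)
        raw = {c: float(m.counts[c].sum()) / 0.4 for c in ("5", "10")}
        with pytest.raises(QcAbortError, match="5"):
            qc_filter_samples(m, r, original_mrna_reads=raw)

    def test_disagreement_statistic_direct_computation(self):
        # median profile is (2, 3, 4): same ranks as a and b, reversed for c
        ratios = pd.DataFrame(
            {"a": [1.0, 2.0, 4.0], "b": [2.0, 4.0, 8.0], "c": [5.0, 3.0, 1.0]},
            index=["f1", "f2", "f3"],
        )
        d = _disagreement(ratios)
        assert d["a"] == pytest.approx(0.0)  # same ranks as the median profile
        assert d["b"] == pytest.approx(0.0)  # rank-based: scaling is free
        assert d["c"] == pytest.approx(2.0)  # perfectly anti-correlated


def _tally_fixture():
    """100 families: 60 clean exponentials, 24 with a zero timepoint, 16 flat."""
    cols = ["0", "5", "40", "60"]
    t = np.array([0.0, 5.0, 40.0, 60.0])
    m_rows, r_rows = {}, {}
    for i in range(60):
        h = 10.0 + i
        m_rows[f"exp{i}"] = np.round(1e6 * 2 ** (-t / h)).astype(int)
    for i in range(24):
        row = np.array([500, 400, 0, 100])
        m_rows[f"gap{i}"] = row
    for i in range(16):
        m_rows[f"flat{i}"] = np.array([700] * 4)
    for k in m_rows:
        r_rows[k] = np.array([10**6] * 4)
    m = AnnotatedCounts(pd.DataFrame(m_rows, index=cols).T, "mRNA", None)
    r = AnnotatedCounts(pd.DataFrame(r_rows, index=cols).T, "rRNA", None)
    return m, r


class TestFamilyHalflives:
    def test_exclusion_tally(self):
        m, r = _tally_fixture()
        results, tally = estimate_family_halflives(m, r)
        assert tally == {
            "jointly_assigned": 100,
            "excluded_detection": 24,
            "excluded_non_exponential": 16,
            "retained_exponential": 60,
        }

    def test_tally_conservation_on_simulated_data(self):
        m, r, _ = simulate_metatranscriptome(CommunityConfig(seed=3))
        _, tally = estimate_family_halflives(m, r)
        assert tally["jointly_assigned"] == (
            tally["excluded_detection"]
            + tally["excluded_non_exponential"]
            + tally["retained_exponential"]
        )

    def test_noiseless_ratio_recovery(self, paired_tables):
        t = np.array([0.0, 5.0, 40.0, 60.0])
        m, r = paired_tables(
            {"f": np.round(1e7 * 0.1 * 2 ** (-t / 28.0)).astype(int)},
            {"f": [10**7] * 4},
        )
        results, _ = estimate_family_halflives(m, r)
        assert results[0].fit.half_life_min == pytest.approx(28.0, rel=1e-4)

    def test_family_missing_from_rrna_not_jointly_assigned(self, paired_tables):
        m, r = paired_tables(
            {"f": [10, 5, 2, 1], "only_m": [9, 9, 9, 9]},
            {"f": [100, 100, 100, 100]},
        )
        _, tally = estimate_family_halflives(m, r)
        assert tally["jointly_assigned"] == 1

    def test_depth_invariance_of_fits(self):
        m, r, _ = simulate_metatranscriptome(
            CommunityConfig(seed=5, n_families=30, depth_range=(2e5, 2e5))
        )
        res1, _ = estimate_family_halflives(m, r)
        m2 = AnnotatedCounts(m.counts.assign(**{"40": m.counts["40"] * 7}), "mRNA", m.pre_col)
        r2 = AnnotatedCounts(r.counts.assign(**{"40": r.counts["40"] * 7}), "rRNA", r.pre_col)
        res2, _ = estimate_family_halflives(m2, r2)
        for a, b in zip(res1, res2):
            assert a.fit.decay_class == b.fit.decay_class
            if a.fit.half_life_min is not None:
                assert b.fit.half_life_min == pytest.approx(a.fit.half_life_min)


class TestClassCog:
    def _tables(self, halflives, rrna_level=10**6, mrna_scale=10**5):
        cols = ["0", "5", "40", "60"]
        t = np.array([0.0, 5.0, 40.0, 60.0])
        m_rows = {
            feat: np.round(mrna_scale * 2 ** (-t / h)).astype(int)
            for feat, h in halflives.items()
        }
        classes = sorted({f.split("|")[0] for f in halflives})
        r_rows = {c: [rrna_level] * 4 for c in classes}
        m = AnnotatedCounts(pd.DataFrame(m_rows, index=cols).T, "mRNA", None)
        r = AnnotatedCounts(pd.DataFrame(r_rows, index=cols).T, "rRNA", None)
        return m, r

    def test_noiseless_recovery_across_classes_and_subcats(self):
        from rifdecay.metat import COG_SUBCATEGORIES

        halflives = {
            f"Class{c}|{s}": 9.0 + 7 * c + 2 * i
            for c in range(5)
            for i, s in enumerate(COG_SUBCATEGORIES)
        }
        m, r = self._tables(halflives)
        results = estimate_class_cog_halflives(m, r)
        assert len(results) == 90
        for res in results:
            assert res.fit.half_life_min == pytest.approx(
                halflives[res.feature], rel=1e-3
            )

    def test_sparse_class_excluded_by_rrna_threshold(self):
        m, r = self._tables({"Big|V": 28.0, "Small|V": 28.0})
        r.counts.loc["Small"] = 999
        results = estimate_class_cog_halflives(m, r)
        assert [x.feature for x in results] == ["Big|V"]

    def test_sparse_class_excluded_by_mrna_threshold(self):
        m, r = self._tables({"Big|V": 28.0, "Tiny|V": 28.0})
        m.counts.loc["Tiny|V"] //= 1000  # mean mRNA falls below 200
        results = estimate_class_cog_halflives(m, r)
        assert [x.feature for x in results] == ["Big|V"]

    def test_unknown_subcategory_letter_rejected(self):
        m, r = self._tables({"Class|V": 28.0})
        bad = AnnotatedCounts(
            m.counts.rename(index={"Class|V": "Class|Z"}), "mRNA", None
        )
        with pytest.raises(ValidationError, match="Z"):
            estimate_class_cog_halflives(bad, r)

    def test_rrna_keyed_by_class_cog_is_aggregated(self):
        halflives = {"ClassA|V": 20.0, "ClassA|N": 40.0}
        m, r = self._tables(halflives)
        split = pd.DataFrame(
            {c: r.counts.loc["ClassA"] // 2 for c in r.counts.columns}
        ).T
        r_split = AnnotatedCounts(
            pd.DataFrame(
                {"ClassA|V": split.iloc[:, 0], "ClassA|N": split.iloc[:, 0]},
            ).T.set_axis(r.counts.columns, axis=1),
            "rRNA",
            None,
        )
        out_class = estimate_class_cog_halflives(m, r)
        out_split = estimate_class_cog_halflives(m, r_split)
        for a, b in zip(out_class, out_split):
            assert b.fit.half_life_min == pytest.approx(a.fit.half_life_min, rel=1e-6)
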