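"""QC, rarefied Shannon, CLR, Bray-Curtis, PCoA, and PERMANOVA."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from dysbiome.containers import CountTable
from dysbiome.ecology import (
    DistanceMatrix,
    bonferroni,
    bray_curtis,
    clr_transform,
    pcoa,
    permanova,
    qc_filter,
    rarefied_shannon,
    shannon_table,
)


def _meta(sample_ids, compartment="lung", soiled=True):
    n = len(sample_ids)
    return pd.DataFrame(
        {
            "sample_id": sample_ids,
            "subject_id": [f"p{i}" for i in range(n)],
            "compartment": [compartment] * n,
            "interval": ["baseline"] * n,
            "day_from_intubation": [2] * n,
            "specimen_type": ["ETA" if compartment == "lung" else "rectal_swab"] * n,
            "soiled_flag": soiled if isinstance(soiled, list) else [soiled] * n,
            "qpcr_copies": [1e5] * n,
        }
    )


class TestQCFilter:
    def test_depth_threshold_is_inclusive(self):
        table = CountTable(
            np.array([[999, 0], [1000, 0], [500, 600]]),
            ["below", "at", "above"],
            ["T1", "T2"],
            compartment="lung",
        )
        kept, report = qc_filter(table, _meta(table.sample_ids), min_reads=1000)
        assert kept.sample_ids == ["at", "above"]
        assert ("below", "low_depth<1000") in report.removals

    def test_unsoiled_gut_sample_removed_despite_depth(self):
        table = CountTable(
            np.array([[5000, 0], [4000, 100]]), ["s1", "s2"], ["T1", "T2"], "gut"
        )
        meta = _meta(table.sample_ids, compartment="gut", soiled=[False, True])
        kept, report = qc_filter(table, meta, min_reads=1000)
        assert kept.sample_ids == ["s2"]
        assert ("s1", "unsoiled") in report.removals

    def test_all_removed_is_error(self):
        table = CountTable(np.array([[10, 0]]), ["s1"], ["T1", "T2"], "lung")
        with pytest.raises(ValueError, match="no samples passed"):
            qc_filter(table, _meta(["s1"]), min_reads=1000)


class TestRarefiedShannon:
    def test_uniform_community_at_exact_depth(self):
        # total = depth so subsampling is the identity: Shannon = ln 4 exactly
        res = rarefied_shannon(np.array([250, 250, 250, 250]), depth=1000, reps=10, seed=0)
        assert res.mean_shannon == pytest.approx(np.log(4), abs=1e-12)

    def test_single_taxon_zero(self):
        res = rarefied_shannon(np.array([1000, 0, 0]), depth=1000, reps=5, seed=0)
        assert res.mean_shannon == 0.0

    def test_two_even_taxa_near_ln2(self):
        res = rarefied_shannon(np.array([5000, 5000]), depth=1000, reps=100, seed=1)
        assert res.mean_shannon == pytest.approx(np.log(2), abs=0.01)

    def test_depth_shortfall_is_error(self):
        with pytest.raises(ValueError, match="QC filter"):
            rarefied_shannon(np.array([400, 400]), depth=1000)

    def test_taxon_order_invariance(self):
        counts = np.array([700, 200, 80, 20, 0, 1000])
        a = rarefied_shannon(counts, depth=1000, reps=200, seed=3).mean_shannon
        b = rarefied_shannon(counts[::-1].copy(), depth=1000, reps=200, seed=3).mean_shannon
        assert a == pytest.approx(b, abs=0.02)  # Monte-Carlo error only

    def test_table_helper_reproducible(self):
        table = CountTable(
            np.array([[600, 500, 100], [1500, 0, 30]]), ["a", "b"], ["x", "y", "z"]
        )
        s1 = shannon_table(table, depth=1000, reps=20, seed=5)
        s2 = shannon_table(table, depth=1000, reps=20, seed=5)
        pd.testing.assert_series_equal(s1, s2)


class TestCLR:
    def test_equal_counts_map_to_zero(self):
        out = clr_transform(np.array([[7, 7, 7, 7]]))
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_hand_computed_row(self):
        x = np.array([10.0, 1.0, 1.0, 1.0]) + 0.5
        expected = np.log(x) - np.log(x).mean()
        out = clr_transform(np.array([[10, 1, 1, 1]]), pseudocount=0.5)
        np.testing.assert_allclose(out[0], expected, atol=1e-12)

    def test_permutation_equivariance(self):
        counts = np.array([[5, 9, 0, 2, 31]])
        perm = [4, 2, 0, 1, 3]
        np.testing.assert_allclose(
            clr_transform(counts[:, perm]), clr_transform(counts)[:, perm]
        )

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        st.lists(
            st.lists(st.integers(min_value=0, max_value=10_000), min_size=3, max_size=8),
            min_size=1,
            max_size=6,
        ).filter(lambda rows: len({len(r) for r in rows}) == 1)
    )
    def test_rows_always_sum_to_zero(self, rows):
        out = clr_transform(np.array(rows))
        np.testing.assert_allclose(out.sum(axis=1), 0.0, atol=1e-9)

    def test_scaling_invariance_in_large_count_limit(self):
        counts = np.array([[100_000, 300_000, 600_000]])
        scaled = clr_transform(counts * 10)
        np.testing.assert_allclose(scaled, clr_transform(counts), atol=1e-3)

    def test_nonpositive_pseudocount_rejected(self):
        with pytest.raises(ValueError):
            clr_transform(np.array([[1, 2]]), pseudocount=0.0)


class TestBrayCurtis:
    def test_identical_samples_zero(self):
        d = bray_curtis(np.array([[0.2, 0.8], [0.2, 0.8]]))
        assert d.matrix[0, 1] == 0.0

    def test_disjoint_supports_one(self):
        d = bray_curtis(np.array([[1.0, 0.0], [0.0, 1.0]]))
        assert d.matrix[0, 1] == pytest.approx(1.0)

    def test_direct_formula(self):
        d = bray_curtis(np.array([[0.5, 0.5], [1.0, 0.0]]))
        assert d.matrix[0, 1] == pytest.approx(0.5)

    def test_negative_entries_rejected_in_relative_mode(self):
        with pytest.raises(ValueError, match="non-negative"):
            bray_curtis(np.array([[0.5, -0.5], [1.0, 0.0]]))

    def test_clr_shifted_mode_accepts_clr_values(self):
        clr = clr_transform(np.array([[10, 1, 1], [1, 10, 1]]))
        d = bray_curtis(clr, mode="clr_shifted")
        assert 0 < d.matrix[0, 1] <= 1


class TestPCoA:
    def test_duplicate_samples_identical_coordinates(self):
        m = np.array(
            [[0.0, 0.0, 0.7], [0.0, 0.0, 0.7], [0.7, 0.7, 0.0]]
        )
        coords, _ = pcoa(DistanceMatrix(["a", "b", "c"], m))
        np.testing.assert_allclose(coords[0], coords[1], atol=1e-10)

    def test_metric_distances_reconstructed(self):
        points = np.array([[0.0, 0.0], [3.0, 0.0], [0.0, 4.0]])
        d = np.sqrt(((points[:, None, :] - points[None, :, :]) ** 2).sum(-1))
        coords, eigvals = pcoa(DistanceMatrix(["a", "b", "c"], d))
        embedded = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
        np.testing.assert_allclose(embedded, d, atol=1e-8)
        assert np.all(np.diff(eigvals) <= 1e-9)  # non-increasing spectrum

    def test_agrees_with_skbio(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(0)
        x = rng.random((6, 4))
        d = bray_curtis(x / x.sum(axis=1, keepdims=True))
        coords, eigvals = pcoa(d)
        ref = skbio.stats.ordination.pcoa(
            skbio.DistanceMatrix(d.matrix, ids=d.sample_ids)
        )
        n_pos = coords.shape[1]
        np.testing.assert_allclose(
            eigvals[:n_pos], ref.eigvals.to_numpy()[:n_pos], atol=1e-8
        )
        np.testing.assert_allclose(
            np.abs(coords), np.abs(ref.samples.to_numpy()[:, :n_pos]), atol=1e-6
        )


class TestPermanova:
    def test_separated_clouds_saturate_p(self):
        rng = np.random.default_rng(1)
        x = np.vstack([rng.normal(0, 0.1, (10, 3)), rng.normal(5, 0.1, (10, 3))])
        d = DistanceMatrix(
            [f"s{i}" for i in range(20)],
            np.sqrt(((x[:, None] - x[None, :]) ** 2).sum(-1)),
        )
        res = permanova(d, ["a"] * 10 + ["b"] * 10, n_perm=199, seed=0)
        # a random permutation can tie F by re-creating the same bipartition,
        # so saturation means at most one tied permutation above F_obs
        assert res.p <= 2 / 200
        assert 0 <= res.R2 <= 1

    def test_matches_skbio_pseudo_f(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(2)
        x = rng.random((14, 5))
        d = bray_curtis(x / x.sum(axis=1, keepdims=True))
        labels = ["a"] * 7 + ["b"] * 7
        ours = permanova(d, labels, n_perm=99, seed=0)
        ref = skbio.stats.distance.permanova(
            skbio.DistanceMatrix(d.matrix, ids=d.sample_ids), labels, permutations=99
        )
        assert ours.pseudo_F == pytest.approx(ref["test statistic"], rel=1e-10)

    def test_single_group_rejected(self):
        d = DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [1.0, 0.0]]))
        with pytest.raises(ValueError, match="two groups"):
            permanova(d, ["x", "x"])

    def test_bonferroni_arithmetic(self):
        assert bonferroni([0.01, 0.04], m=2) == [0.02, 0.08]
        assert bonferroni([0.7, 0.9]) == [1.0, 1.0]
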