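import numpy as np
import pytest

from ecognet.functional import (
    ConnectivityMatrix,
    SpectralParams,
    adjacency_matrix,
    coherence_pair,
    mutual_information_pair,
    region_summary,
)
from ecognet.recording import Recording


class TestCoherence:
    def test_identical_signals(self, rng):
        x = rng.standard_normal(4096)
        assert coherence_pair(x, x, fs=256.0) == pytest.approx(1.0, abs=1e-10)

    def test_scale_invariance(self, rng):
        x = rng.standard_normal(4096)
        assert coherence_pair(x, 3.0 * x, fs=256.0) == pytest.approx(1.0, abs=1e-10)

    def test_independent_noise_near_bias_level(self):
        # 64 Welch segments: coherence bias ~ 1/segments; band mean < 0.1
        vals = []
        for seed in range(10):
            r = np.random.default_rng(seed)
            n = 65 * 128 + 128  # 64+ overlapping 256-sample segments
            vals.append(coherence_pair(r.standard_normal(n), r.standard_normal(n), fs=256.0))
        assert np.mean(vals) < 0.1

    def test_too_short_rejected(self, rng):
        with pytest.raises(ValueError):
            coherence_pair(rng.standard_normal(300), rng.standard_normal(300), fs=256.0)


class TestMutualInformation:
    def test_identical_two_bins_one_bit(self):
        x = np.arange(1000.0)  # exactly equiprobable halves
        assert mutual_information_pair(x, x, n_bins=2) == pytest.approx(1.0, abs=1e-12)

    def test_independent_uniforms_near_zero(self):
        vals = []
        for seed in range(10):
            r = np.random.default_rng(seed)
            vals.append(
                mutual_information_pair(r.uniform(size=10_000), r.uniform(size=10_000), 16)
            )
        assert np.mean(vals) < 0.05

    def test_symmetry(self, rng):
        x, y = rng.standard_normal((2, 2000))
        assert mutual_information_pair(x, y) == pytest.approx(
            mutual_information_pair(y, x), abs=1e-12
        )

    def test_bounded_by_marginal_entropy(self, rng):
        x = rng.standard_normal(5000)
        y = x + 0.1 * rng.standard_normal(5000)
        n_bins = 16
        counts, _ = np.histogram(x, bins=n_bins)
        p = counts[counts > 0] / counts.sum()
        hx = -(p * np.log2(p)).sum()
        assert mutual_information_pair(x, y, n_bins) <= hx + 1e-9

    def test_constant_series_zero(self, rng):
        assert mutual_information_pair(np.ones(100), rng.standard_normal(100)) == 0.0

    def test_bad_bins_rejected(self, rng):
        with pytest.raises(ValueError):
            mutual_information_pair(rng.uniform(size=10), rng.uniform(size=10), 1)


class TestAdjacency:
    def test_coherence_matrix_properties(self, processed_epochs):
        mat = adjacency_matrix(processed_epochs[0], "coherence")
        v = mat.values
        assert v.shape == (10, 10)
        np.testing.assert_allclose(v, v.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(v), 1.0)
        off = v[~np.eye(10, dtype=bool)]
        assert ((off >= 0) & (off <= 1)).all()

    def test_matches_pairwise_route(self, processed_epochs):
        # vectorized all-pairs Welch agrees with the scalar pair estimator
        rec = processed_epochs[0]
        mat = adjacency_matrix(rec, "coherence")
        for i, j in [(0, 5), (2, 9), (4, 7)]:
            direct = coherence_pair(rec.samples[i], rec.samples[j], fs=rec.fs)
            assert mat.values[i, j] == pytest.approx(direct, rel=1e-10)

    def test_mi_matrix_symmetric_nonnegative(self, processed_epochs):
        mat = adjacency_matrix(processed_epochs[0], "mi")
        assert np.allclose(mat.values, mat.values.T)
        assert (mat.values >= 0).all()

    def test_channel_permutation_equivariance(self, processed_epochs):
        rec = processed_epochs[0]
        perm = [3, 1, 4, 0, 2, 9, 8, 7, 6, 5]
        shuffled = Recording(
            samples=rec.samples[perm], fs=rec.fs,
            channel_labels=[rec.channel_labels[i] for i in perm],
        )
        a = adjacency_matrix(rec, "coherence").values
        b = adjacency_matrix(shuffled, "coherence").values
        np.testing.assert_allclose(b, a[np.ix_(perm, perm)], atol=1e-12)

    def test_unknown_metric_rejected(self, processed_epochs):
        with pytest.raises(ValueError):
            adjacency_matrix(processed_epochs[0], "plv")


class TestRegionSummary:
    @staticmethod
    def make_matrix(values, labels):
        return ConnectivityMatrix(values=values, metric="coherence",
                                  channel_labels=labels)

    def test_all_ones(self, layout):
        mat = self.make_matrix(np.ones((10, 10)), layout.labels)
        rs = region_summary(mat, layout)
        assert all(v == 1.0 for v in rs.within.values())
        assert all(v == 1.0 for v in rs.between.values())

    def test_hand_computed_means(self, layout, rng):
        v = rng.uniform(size=(10, 10))
        v = (v + v.T) / 2
        mat = self.make_matrix(v, layout.labels)
        rs = region_summary(mat, layout)
        # brute force: F channels are indices 0..3
        f_pairs = [(a, b) for a in range(4) for b in range(4) if a < b]
        assert rs.within["F"] == pytest.approx(np.mean([v[a, b] for a, b in f_pairs]))
        fp_pairs = [(a, b) for a in range(4) for b in range(4, 8)]
        assert len(fp_pairs) == 16
        assert rs.between["F-P"] == pytest.approx(np.mean([v[a, b] for a, b in fp_pairs]))
        po_pairs = [(a, b) for a in range(4, 8) for b in (8, 9)]
        assert len(po_pairs) == 8
        assert rs.between["P-O"] == pytest.approx(np.mean([v[a, b] for a, b in po_pairs]))

    def test_single_channel_region_flagged(self, rng):
        from ecognet.layout import ElectrodeLayout

        labels = ["FL1", "FR1", "PL1", "PR1", "OL"]
        layout = ElectrodeLayout(tuple(
            (lab, 0.0, 0.0, lab[0]) for lab in labels
        ))
        v = rng.uniform(size=(5, 5))
        mat = self.make_matrix((v + v.T) / 2, labels)
        rs = region_summary(mat, layout)
        assert np.isnan(rs.within["O"])


def test_group_contrast_connectivity_lower_in_scz(tiny_cohort_processed, layout):
    """Within- and between-region coherence and MI all drop in the SCZ-like cohort."""
    import pandas as pd

    means = {}
    for cond in ("normal", "scz"):
        rows = []
        for (s, c), recs in tiny_cohort_processed.items():
            if c != cond:
                continue
            for rec in recs:
                for metric in ("coherence", "mi"):
                    rs = region_summary(adjacency_matrix(rec, metric), layout)
                    rows.append({
                        "metric": metric,
                        "within": np.nanmean(list(rs.within.values())),
                        "between": np.nanmean(list(rs.between.values())),
                    })
        means[cond] = pd.DataFrame(rows).groupby("metric").mean()
    for metric in ("coherence", "mi"):
        for scope in ("within", "between"):
            assert means["scz"].loc[metric, scope] < means["normal"].loc[metric, scope]
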