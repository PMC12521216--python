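import numpy as np
import pytest

from emgselect import (SelectionConfig, cr_select, enn_select, qa_select,
                       reject_test)


def enn_brute_force(features, labels, cfg):
    """O(n^2) sorted-distance oracle for the edited-nearest-neighbour vote."""
    X = np.asarray(features, float)
    if cfg.enn_standardise:
        mu, sd = X.mean(axis=0), X.std(axis=0)
        sd = np.where(sd == 0, 1.0, sd)
        X = (X - mu) / sd
    labels = np.asarray(labels)
    n = len(X)
    keep = np.zeros(n, dtype=bool)
    for i in range(n):
        d = np.sqrt(((X - X[i]) ** 2).sum(axis=1))
        order = [j for j in np.argsort(d, kind="stable") if j != i]
        voters = order[cfg.enn_skip:cfg.enn_skip + cfg.enn_vote_k]
        votes = np.zeros(8)
        for j in voters:
            votes[labels[j]] += 1.0 / max(d[j], 1e-12)
        keep[i] = np.argmax(votes) == labels[i]
    return keep


class TestQualityAcceptance:
    @pytest.mark.parametrize("snrs,kept", [
        ([5.0, 3.0, 2.0, -1.0], True),    # all top-3 above 1.8
        ([5.0, 3.0, 1.0, -1.0], False),   # third-largest below threshold
        ([1.8, 1.8, 1.8, 1.8], False),    # strict inequality at the threshold
    ])
    def test_top3_all_rule(self, snrs, kept):
        mask = qa_select(np.array([snrs]))
        assert mask.keep[0] == kept

    def test_any_aggregation_option(self):
        cfg = SelectionConfig(snr_aggregate="any")
        assert qa_select(np.array([[5.0, 1.0, 0.0]]), cfg).keep[0]
        assert not qa_select(np.array([[1.0, 0.5, 0.0]]), cfg).keep[0]

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(0)
        snr = rng.normal(2.0, 2.0, size=(300, 6))
        kept = [qa_select(snr, SelectionConfig(snr_threshold_db=t)).n_kept
                for t in np.linspace(-2, 6, 9)]
        assert all(a >= b for a, b in zip(kept, kept[1:]))

    def test_too_few_channels_errors(self):
        with pytest.raises(ValueError):
            qa_select(np.array([[2.0, 2.0]]))

    def test_retention_per_class(self):
        snr = np.array([[5, 5, 5], [0, 0, 0], [5, 5, 5], [0, 0, 0.0]])
        mask = qa_select(snr, labels=np.array([1, 1, 0, 0]))
        assert mask.retention_per_class[1] == pytest.approx(50.0)
        assert mask.retention_per_class[0] == pytest.approx(50.0)


class TestConfidenceRetraining:
    def _rows(self, maxima):
        rows = []
        for m in maxima:
            row = np.full(8, (1.0 - m) / 7.0)
            row[0] = m
            rows.append(row)
        return np.array(rows)

    def test_threshold_inclusive(self):
        mask = cr_select(self._rows([0.75, 0.7499, 0.125, 0.9]))
        np.testing.assert_array_equal(mask.keep, [True, False, False, True])

    def test_malformed_rows_error(self):
        with pytest.raises(ValueError):
            cr_select(np.array([[0.5, 0.6] + [0.0] * 6]))
        with pytest.raises(ValueError):
            cr_select(np.array([[-0.1, 1.1] + [0.0] * 6]))

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(1)
        P = rng.dirichlet(np.ones(8) * 0.5, size=400)
        kept = [cr_select(P, cfg=SelectionConfig(cr_threshold=t)).n_kept
                for t in np.linspace(0.1, 0.95, 10)]
        assert all(a >= b for a, b in zip(kept, kept[1:]))


class TestEditedNearestNeighbour:
    def test_unanimous_labels_all_kept_with_no_skip(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((60, 4))
        y = np.zeros(60, dtype=int)
        cfg = SelectionConfig(enn_skip=0)
        assert enn_select(X, y, cfg).keep.all()

    def test_separated_clusters_kept_mixed_point_rejected(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0, 0.1, (30, 2))
        b = rng.normal(10, 0.1, (30, 2))
        X = np.vstack([a, b])
        y = np.r_[np.zeros(30, int), np.ones(30, int)]
        # mislabel one point deep inside cluster b
        y[35] = 0
        cfg = SelectionConfig(enn_skip=0, enn_standardise=False)
        mask = enn_select(X, y, cfg)
        assert not mask.keep[35]           # voters unanimously disagree
        assert mask.keep[:30].all()        # clean cluster untouched
        assert mask.keep.sum() >= 58       # at most the mislabelled point's
        #                                    nearest neighbour is dragged along

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(4)
        for trial in range(50):
            n = int(rng.integers(40, 160))
            d = int(rng.integers(2, 9))
            skip = int(rng.integers(0, 8))
            vote = int(rng.integers(1, 9))
            X = rng.standard_normal((n, d)) * rng.uniform(0.5, 3.0, d)
            y = rng.integers(0, 4, n)
            cfg = SelectionConfig(enn_skip=skip, enn_vote_k=vote,
                                  enn_standardise=bool(trial % 2))
            got = enn_select(X, y, cfg).keep
            want = enn_brute_force(X, y, cfg)
            np.testing.assert_array_equal(got, want)

    def test_default_skip20_vote7_against_oracle(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((200, 6))
        y = rng.integers(0, 8, 200)
        cfg = SelectionConfig()
        np.testing.assert_array_equal(enn_select(X, y, cfg).keep,
                                      enn_brute_force(X, y, cfg))

    def test_too_few_windows_errors(self):
        with pytest.raises(ValueError):
            enn_select(np.zeros((20, 3)), np.zeros(20, dtype=int), SelectionConfig())


class TestRejection:
    def test_same_rules_as_selection(self):
        snr = np.array([[5.0, 3.0, 2.0], [1.0, 1.0, 1.0]])
        mask = reject_test("qa", snr_db=snr)
        np.testing.assert_array_equal(mask.keep, [True, False])

        P = np.zeros((2, 8))
        P[0, 2], P[0, 3] = 0.9, 0.1
        P[1] = 0.125
        mask = reject_test("cr", probabilities=P)
        np.testing.assert_array_equal(mask.keep, [True, False])

    def test_enn_rejection_requires_labels(self):
        with pytest.raises(ValueError, match="label"):
            reject_test("enn", features=np.zeros((50, 3)))

    def test_unknown_paradigm_errors(self):
        with pytest.raises(ValueError):
            reject_test("foo", snr_db=np.zeros((3, 3)))


def test_paradigms_are_deterministic():
    rng = np.random.default_rng(6)
    X = rng.standard_normal((120, 8))
    y = rng.integers(0, 8, 120)
    snr = rng.normal(2, 2, (120, 5))
    P = rng.dirichlet(np.ones(8), 120)
    for _ in range(2):
        assert np.array_equal(qa_select(snr).keep, qa_select(snr).keep)
        assert np.array_equal(enn_select(X, y).keep, enn_select(X, y).keep)
        assert np.array_equal(cr_select(P).keep, cr_select(P).keep)
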