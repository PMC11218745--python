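import numpy as np
import pytest

import gridtap as gt
from conftest import random_epochs
from gridtap.classify import SWLDAModel


def stepwise_oracle(X, y, p_enter=0.10, p_remove=0.15, max_features=60):
    """Textbook stepwise regression via statsmodels, fitted from scratch
    at every step; independent of the incremental-QR implementation."""
    import statsmodels.api as sm

    sel: list[int] = []
    n, p = X.shape
    while len(sel) < max_features:
        candidates = [j for j in range(p) if j not in sel]
        if not candidates:
            break
        best, best_p = None, np.inf
        for j in candidates:
            cols = sm.add_constant(X[:, sel + [j]])
            fit = sm.OLS(y, cols).fit()
            pval = fit.pvalues[-1]
            if pval < best_p:
                best, best_p = j, pval
        if best is None or not best_p < p_enter:
            break
        sel.append(best)
        while len(sel) > 1:
            fit = sm.OLS(y, sm.add_constant(X[:, sel])).fit()
            pv = np.asarray(fit.pvalues[1:])
            pv[-1] = 0.0  # just-added feature exempt
            worst = int(np.argmax(pv))
            if pv[worst] > p_remove:
                sel.pop(worst)
            else:
                break
    return sel


def labelled_problem(seed, n=40, p=5, informative=(0,), snr=2.0):
    rng = np.random.default_rng(seed)
    y = np.where(rng.random(n) < 0.25, 1.0, -1.0)
    X = rng.standard_normal((n, p))
    for j in informative:
        X[:, j] += snr * y * rng.uniform(0.5, 1.0)
    return X, y


class TestBuildFeatures:
    def test_cap_feature_count(self, small_session, montage):
        X, y, names = gt.build_features(
            small_session, gt.ClassifierConfig(),
            gt.channels_for_system(montage, "cap"))
        assert X.shape == (small_session.n_epochs, 192)
        assert y.shape == (small_session.n_epochs,)

    def test_ceegrid_feature_count(self, small_session, montage):
        channels = gt.channels_for_system(montage, "ceegrid")
        assert len(channels) == 26
        X, _, names = gt.build_features(small_session,
                                        gt.ClassifierConfig(), channels)
        assert X.shape[1] == 416
        assert names[0] == (channels[0], 0)

    def test_constant_epoch_gives_constant_features(self):
        eps = random_epochs(0, scale=0.0, n=4)
        eps.data[:, :, eps.n_pre:] = 1.0
        eps = gt.EpochSet(data=eps.data, channel_labels=eps.channel_labels,
                          sample_rate=eps.sample_rate,
                          epoch_pre_ms=eps.epoch_pre_ms,
                          epoch_post_ms=eps.epoch_post_ms,
                          events=eps.events, baseline_corrected=True)
        X, _, _ = gt.build_features(eps, gt.ClassifierConfig(), ["ch0"])
        assert np.allclose(X, 1.0)

    def test_partial_bin_dropped_with_warning(self, small_session):
        cfg = gt.ClassifierConfig(feature_bin_ms=70.0)
        with pytest.warns(UserWarning, match="partial bin"):
            X, _, _ = gt.build_features(small_session, cfg, ["Cz"])
        assert X.shape[1] == 11  # floor(800 / 70)


class TestSWLDAFit:
    def test_perfect_separator_selected_first(self):
        X, y = labelled_problem(1, p=10, informative=(4,), snr=50.0)
        model = gt.swlda_fit(X, y)
        assert model.selected[0] == 4

    def test_zero_p_enter_yields_degenerate_model(self):
        X, y = labelled_problem(2)
        model = gt.swlda_fit(X, y, gt.ClassifierConfig(p_enter=0.0))
        assert model.degenerate
        assert np.allclose(gt.score(model, X), model.intercept)

    @pytest.mark.parametrize("seed", range(10))
    def test_selection_path_matches_independent_oracle(self, seed):
        X, y = labelled_problem(seed, n=40, p=5, informative=(0, 2), snr=1.0)
        model = gt.swlda_fit(X, y)
        assert model.selected == stepwise_oracle(X, y)

    def test_disabled_selection_equals_ols(self):
        X, y = labelled_problem(3, n=60, p=8, informative=(0, 1), snr=1.0)
        cfg = gt.ClassifierConfig(p_enter=1.0, p_remove=1.0, max_features=None)
        model = gt.swlda_fit(X, y, cfg)
        assert sorted(model.selected) == list(range(8))
        A = np.column_stack([np.ones(len(y)), X])
        beta = np.linalg.lstsq(A, y, rcond=None)[0]
        reordered = np.empty(8)
        for pos, j in enumerate(model.selected):
            reordered[j] = model.weights[pos]
        assert np.allclose(reordered, beta[1:], atol=1e-8)
        assert model.intercept == pytest.approx(beta[0], abs=1e-8)

    def test_max_features_is_respected(self):
        X, y = labelled_problem(4, n=200, p=30, informative=tuple(range(10)),
                                snr=0.8)
        model = gt.swlda_fit(X, y, gt.ClassifierConfig(max_features=5))
        assert len(model.selected) <= 5

    def test_single_class_rejected(self):
        X = np.random.default_rng(0).standard_normal((10, 3))
        with pytest.raises(ValueError, match="classes"):
            gt.swlda_fit(X, np.ones(10))


class TestScore:
    def test_zero_weights_give_intercept(self):
        model = SWLDAModel(selected=[0], weights=np.array([0.0]),
                           intercept=0.7)
        X = np.random.default_rng(1).standard_normal((5, 2))
        assert np.allclose(gt.score(model, X), 0.7)

    def test_duplicate_epochs_score_identically(self):
        X, y = labelled_problem(5)
        model = gt.swlda_fit(X, y)
        doubled = np.vstack([X, X])
        s = gt.score(model, doubled)
        assert np.array_equal(s[:len(X)], s[len(X):])

    def test_matches_manual_dot_product(self):
        model = SWLDAModel(selected=[0, 1], weights=np.array([2.0, -0.5]),
                           intercept=1.0)
        X = np.array([[1.0, 4.0], [3.0, -2.0]])
        assert np.allclose(gt.score(model, X),
                           [1 + 2 * 1 - 0.5 * 4, 1 + 2 * 3 - 0.5 * (-2)])

    def test_dimension_mismatch_rejected(self):
        model = SWLDAModel(selected=[3], weights=np.array([1.0]), intercept=0.0)
        with pytest.raises(ValueError, match="narrower"):
            gt.score(model, np.zeros((2, 2)))


def block_events(run=1, block=1, reps=2):
    events = []
    for rep in range(reps):
        for pos in gt.POSITIONS:
            events.append(gt.StimulusEvent(
                sample=1000 + 155 * len(events), run=run, block=block,
                position=pos, is_target=(pos == "front")))
    return events


class TestSelectTarget:
    def test_clear_winner(self):
        events = block_events(reps=1)
        scores = np.array([1.0, 0.2, 0.1, 0.0])
        res = gt.select_target(scores, events)
        assert res.chosen_position == "front" and res.correct

    def test_all_equal_scores_fall_back_to_canonical_order(self):
        events = block_events(reps=1)
        res = gt.select_target(np.zeros(4), events)
        assert res.chosen_position == "front"  # first in canonical order

    def test_matches_bruteforce_mean_argmax(self):
        rng = np.random.default_rng(6)
        events = block_events(reps=10)
        scores = rng.standard_normal(len(events))
        res = gt.select_target(scores, events)
        means = {pos: np.mean([s for s, ev in zip(scores, events)
                               if ev.position == pos])
                 for pos in gt.POSITIONS}
        assert res.chosen_position == max(means, key=means.get)
        assert res.position_scores == pytest.approx(means)


class TestChanceThreshold:
    def test_full_session_bound_is_18_of_48(self):
        k, pct = gt.chance_threshold(48, 0.25, 0.05)
        assert k == 18
        assert pct == pytest.approx(37.5)

    def test_four_selections_by_hand_enumeration(self):
        # P(X>=3) = 4 * .25^3 * .75 + .25^4 = 0.05078 >= .05 -> k = 4
        k, pct = gt.chance_threshold(4, 0.25, 0.05)
        assert k == 4 and pct == 100.0

    def test_lax_alpha_boundary(self):
        # P(X>=1) = 1 - 0.75^4 = 0.684 < 0.999, P(X>=0) = 1 is not
        k, _ = gt.chance_threshold(4, 0.25, 0.999)
        assert k == 1

    def test_invalid_alpha_rejected(self):
        with pytest.raises(ValueError):
            gt.chance_threshold(48, 0.25, 1.5)


class TestLOOCV:
    def _separable_session(self, n_blocks=2, reps=2, seed=0):
        rng = np.random.default_rng(seed)
        events = []
        for b in range(1, n_blocks + 1):
            events.extend(block_events(block=b, reps=reps))
        n = len(events)
        data = 0.01 * rng.standard_normal((n, 1, 225))
        for i, ev in enumerate(events):
            if ev.is_target:
                data[i, 0, 25:] += 1.0
        return gt.EpochSet(data=data, channel_labels=["Cz"],
                           sample_rate=250.0, epoch_pre_ms=100.0,
                           epoch_post_ms=800.0, events=events,
                           baseline_corrected=True)

    def test_separable_session_is_perfect(self):
        eps = self._separable_session(n_blocks=4, reps=3)
        res = gt.loocv_accuracy(eps, gt.ClassifierConfig(), ["Cz"])
        assert res.accuracy_pct == 100.0
        assert res.n_blocks == 4

    def test_two_block_folds_traced_by_hand(self):
        eps = self._separable_session(n_blocks=2)
        res = gt.loocv_accuracy(eps, gt.ClassifierConfig(), ["Cz"])
        # fold 1 trains on block 2 and selects on block 1, and vice versa;
        # the target channel mean is ~1 for 'front' and ~0 elsewhere
        assert [s.block for s in res.selections] == [1, 2]
        assert all(s.chosen_position == "front" for s in res.selections)
        assert res.n_correct == 2 and res.accuracy_pct == 100.0
        # with two selections the exact binomial tail cannot drop below
        # alpha (min is 0.25^2 = 0.0625), so significance is unattainable
        assert not res.significant
        assert res.significance_threshold_pct > 100.0

    def test_invariant_to_epoch_order_within_blocks(self):
        eps = self._separable_session(n_blocks=3, reps=3, seed=5)
        rng = np.random.default_rng(1)
        perm = rng.permutation(eps.n_epochs)
        shuffled = gt.EpochSet(
            data=eps.data[perm], channel_labels=eps.channel_labels,
            sample_rate=eps.sample_rate, epoch_pre_ms=eps.epoch_pre_ms,
            epoch_post_ms=eps.epoch_post_ms,
            events=[eps.events[i] for i in perm], baseline_corrected=True)
        a = gt.loocv_accuracy(eps, gt.ClassifierConfig(), ["Cz"])
        b = gt.loocv_accuracy(shuffled, gt.ClassifierConfig(), ["Cz"])
        assert a.accuracy_pct == b.accuracy_pct

    def test_single_block_rejected(self):
        eps = self._separable_session(n_blocks=1)
        with pytest.raises(ValueError, match="two blocks"):
            gt.loocv_accuracy(eps, gt.ClassifierConfig(), ["Cz"])
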