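"""Offline target classification with SWLDA.

Stepwise linear discriminant analysis in the P300-BCI tradition:
forward–backward stepwise least-squares regression of the class labels
(+1 target / −1 non-target) on time-binned channel features, followed by
linear scoring.  Per target block, the position with the highest mean
epoch score over its (up to ten) repetitions is selected; session
accuracy is estimated by leave-one-block-out cross-validation.  The
exact binomial tail under the 25% four-choice chance level gives the
minimum accuracy that counts as significantly above chance (18 of 48
selections, i.e. 37.5%).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.linalg import solve_triangular

from .events import POSITIONS, StimulusEvent
from .montage import Montage
from .preprocess import EpochSet

logger = logging.getLogger(__name__)

#: Practically useful BCI control requires at least this accuracy.
USABILITY_THRESHOLD_PCT = 70.0


@dataclass(frozen=True)
class ClassifierConfig:
    """SWLDA and cross-validation settings.

    Feature construction averages each channel over consecutive
    ``feature_bin_ms`` segments of the 0–800 ms post-stimulus window (50
    ms bins → 16 bins per channel).  The stepwise thresholds (enter at
    p < 0.10, remove at p > 0.15, at most 60 features) follow the
    P300-classifier convention; they are conventions, not fitted values.
    """

    feature_bin_ms: float = 50.0
    p_enter: float = 0.10
    p_remove: float = 0.15
    max_features: int | None = 60
    reject_for_classification: bool = False

    def __post_init__(self) -> None:
        if self.p_enter > self.p_remove:
            raise ValueError("p_enter must not exceed p_remove")
        if self.max_features is not None and self.max_features < 1:
            raise ValueError("max_features must be >= 1")


def channels_for_system(montage: Montage, system: str) -> list[str]:
    """Channel set entering classification for one EEG system.

    ``"cap"``: the 12 scalp electrodes.  ``"ceegrid"``: all 18
    recordable ear electrodes plus the eight bipolar channels.
    """
    if system == "cap":
        return list(montage.scalp_channels)
    if system == "ceegrid":
        return list(montage.ceegrid_channels) + list(montage.bipolar_labels)
    raise ValueError(f"unknown system {system!r}; expected 'cap' or 'ceegrid'")


def build_features(eps: EpochSet, cfg: ClassifierConfig,
                   channels: list[str]) -> tuple[np.ndarray, np.ndarray, list[tuple[str, int]]]:
    """Time-binned mean-amplitude features.

    Returns ``(X, y, names)`` where ``X`` is (n_epochs, n_channels ×
    n_bins), ``y`` is +1 for target epochs and −1 otherwise, and
    ``names`` holds ``(channel, bin)`` per column.  Samples with latency
    in ``[b·bin, (b+1)·bin)`` feed bin ``b``; a trailing partial bin is
    dropped with a warning.
    """
    if not eps.baseline_corrected:
        raise ValueError("features require baseline-corrected epochs")
    lat = eps.latencies_ms
    n_bins = int(eps.epoch_post_ms // cfg.feature_bin_ms)
    if n_bins < 1:
        raise ValueError("feature bin wider than the post-stimulus window")
    if n_bins * cfg.feature_bin_ms < eps.epoch_post_ms - 1e-9:
        warnings.warn("feature bin width does not divide the post-stimulus "
                      "window; trailing partial bin dropped", stacklevel=2)
    ch_idx = eps.channel_index(channels)
    data = eps.data[:, ch_idx, :]
    cols = []
    names: list[tuple[str, int]] = []
    bin_masks = []
    for b in range(n_bins):
        lo, hi = b * cfg.feature_bin_ms, (b + 1) * cfg.feature_bin_ms
        bin_masks.append((lat >= lo) & (lat < hi))
    for ci, ch in enumerate(channels):
        for b, mask in enumerate(bin_masks):
            cols.append(data[:, ci, mask].mean(axis=1))
            names.append((ch, b))
    X = np.column_stack(cols) if cols else np.empty((eps.n_epochs, 0))
    y = np.where(eps.is_target, 1.0, -1.0)
    return X, y, names


@dataclass
class SWLDAModel:
    """Selected features and discriminant weights of a stepwise fit."""

    selected: list[int]
    weights: np.ndarray
    intercept: float
    feature_names: list[tuple[str, int]] = field(default_factory=list)
    n_target: int = 0
    n_nontarget: int = 0

    @property
    def degenerate(self) -> bool:
        return len(self.selected) == 0


def _ols_stats(R: np.ndarray, qty: np.ndarray, rss: float, n: int
               ) -> tuple[np.ndarray, np.ndarray]:
    """Coefficients and two-sided p-values of the current regression."""
    k = R.shape[0]
    beta = solve_triangular(R, qty)
    df = n - k - 1
    if df <= 0 or rss <= 0:
        return beta, np.zeros(k)
    inv_r = solve_triangular(R, np.eye(k))
    se = np.sqrt(rss / df * (inv_r ** 2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, np.inf)
    return beta, 2.0 * stats.t.sf(np.abs(t), df)


def swlda_fit(X: np.ndarray, y: np.ndarray,
              cfg: ClassifierConfig = ClassifierConfig(),
              feature_names: list[tuple[str, int]] | None = None) -> SWLDAModel:
    """Forward–backward stepwise least-squares regression of labels on features.

    Repeatedly adds the candidate with the smallest partial-F p-value
    while it is below ``p_enter``, then removes any included feature
    whose p-value exceeds ``p_remove`` (the feature just added is
    exempt, which prevents enter/remove cycling).  Stops when no change
    occurs, ``max_features`` is reached, or the fit is numerically
    exact.  If nothing can enter, the model is degenerate and scores are
    constant.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n <= 2:
        raise ValueError("need more than two epochs to fit")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    max_feat = cfg.max_features if cfg.max_features is not None else p

    x_mean = X.mean(axis=0)
    y_mean = y.mean()
    Xc = np.asfortranarray(X - x_mean)
    yc = y - y_mean

    col_norms2 = (Xc ** 2).sum(axis=0)
    tss = float(yc @ yc)
    dead_tol = 1e-12 * max(1.0, col_norms2.max(initial=0.0))

    # Residualized candidate geometry is tracked without forming the
    # residualized matrix: with Q the orthonormal basis of the selected
    # columns, the projection of a new basis vector q onto the
    # residualized candidates equals q @ Xc (q is orthogonal to Q), so
    # cross-products c = Z'r and squared norms update in O(n p) per step.
    norms2 = col_norms2.copy()
    c = Xc.T @ yc
    rss = tss
    alive = norms2 > dead_tol

    sel: list[int] = []
    Q = np.empty((n, 0))
    R = np.empty((0, 0))
    qty = np.empty(0)

    def rebuild(indices: list[int]) -> None:
        nonlocal Q, R, qty, rss, c, norms2, alive
        if indices:
            Q, R = np.linalg.qr(Xc[:, indices])
            qty = Q.T @ yc
        else:
            Q, R, qty = np.empty((n, 0)), np.empty((0, 0)), np.empty(0)
        rss = float(tss - qty @ qty)
        QtX = Q.T @ Xc
        norms2 = np.maximum(col_norms2 - (QtX ** 2).sum(axis=0), 0.0)
        c = Xc.T @ yc - QtX.T @ qty
        alive = norms2 > dead_tol
        alive[indices] = False

    for _ in range(4 * max_feat + 4):
        if len(sel) >= max_feat or rss <= 1e-12 * tss:
            break
        k = len(sel)
        df2 = n - k - 2
        if df2 <= 0:
            break
        # the partial-F p-value is monotone in the RSS gain (same dfs for
        # all candidates), so the argmax gain is the argmin p
        with np.errstate(divide="ignore", invalid="ignore"):
            gains = np.where(alive & (norms2 > 0),
                             c ** 2 / np.where(norms2 > 0, norms2, 1.0), -1.0)
        gains = np.minimum(gains, rss)
        best = int(np.argmax(gains))
        if gains[best] <= 0:
            break
        denom = (rss - gains[best]) / df2
        f_best = np.inf if denom <= 0 else gains[best] / denom
        p_best = float(stats.f.sf(f_best, 1, df2))
        if not p_best < cfg.p_enter:
            break

        x = Xc[:, best]
        u = Q.T @ x
        z = x - Q @ u
        znorm = float(np.sqrt(norms2[best]))
        q = z / znorm
        qy = float(c[best]) / znorm
        R = np.block([[R, u[:, None]],
                      [np.zeros((1, k)), np.array([[znorm]])]])
        Q = np.column_stack([Q, q])
        qty = np.append(qty, qy)
        rss = max(rss - qy * qy, 0.0)
        proj = q @ Xc
        c -= qy * proj
        norms2 = np.maximum(norms2 - proj ** 2, 0.0)
        sel.append(best)
        alive[best] = False

        # backward pass: drop features that no longer earn their place
        while len(sel) > 1:
            _, pv = _ols_stats(R, qty, rss, n)
            pv = pv.copy()
            pv[len(sel) - 1] = 0.0  # just-added feature is exempt
            worst = int(np.argmax(pv))
            if pv[worst] > cfg.p_remove:
                removed = sel.pop(worst)
                logger.debug("stepwise removal of feature %d", removed)
                rebuild(sel)
            else:
                break

    if not sel:
        logger.info("degenerate SWLDA model: no feature passed p_enter=%g",
                    cfg.p_enter)
        return SWLDAModel(selected=[], weights=np.empty(0), intercept=y_mean,
                          feature_names=[],
                          n_target=int((y > 0).sum()),
                          n_nontarget=int((y < 0).sum()))

    beta, _ = _ols_stats(R, qty, rss, n)
    intercept = float(y_mean - x_mean[sel] @ beta)
    names = [feature_names[j] for j in sel] if feature_names else []
    return SWLDAModel(selected=list(sel), weights=np.asarray(beta),
                      intercept=intercept, feature_names=names,
                      n_target=int((y > 0).sum()),
                      n_nontarget=int((y < 0).sum()))


def score(model: SWLDAModel, X: np.ndarray) -> np.ndarray:
    """Linear discriminant score per epoch; higher is more target-like."""
    X = np.asarray(X, dtype=float)
    if model.degenerate:
        return np.full(X.shape[0], model.intercept)
    if X.shape[1] <= max(model.selected):
        raise ValueError("feature matrix narrower than the model's selection")
    return model.intercept + X[:, model.selected] @ model.weights


@dataclass
class SelectionResult:
    run: int
    block: int
    true_target: str
    position_scores: dict[str, float]
    chosen_position: str
    correct: bool


@dataclass
class AccuracyResult:
    """Cross-validated selection accuracy with chance/usability context."""

    n_blocks: int
    n_correct: int
    accuracy_pct: float
    chance_pct: float
    significance_threshold_pct: float
    significant: bool
    meets_usability: bool
    selections: list[SelectionResult] = field(default_factory=list)


def select_target(scores: np.ndarray, events: list[StimulusEvent],
                  positions: tuple[str, ...] = POSITIONS) -> SelectionResult:
    """Aggregate one block's epoch scores into a 4-way position choice.

    Per position, the mean score over its repetitions; the chosen
    position is the argmax, ties resolving to the earliest position in
    canonical order.
    """
    if len(scores) != len(events):
        raise ValueError("one score per event required")
    runs = {ev.run for ev in events}
    blocks = {ev.block for ev in events}
    if len(runs) != 1 or len(blocks) != 1:
        raise ValueError("select_target expects events of exactly one block")
    true_targets = {ev.position for ev in events if ev.is_target}
    if len(true_targets) != 1:
        raise ValueError("block must have exactly one target position")
    true_target = true_targets.pop()
    pos_scores: dict[str, float] = {}
    for pos in positions:
        mask = np.array([ev.position == pos for ev in events])
        if not mask.any():
            raise ValueError(f"no scorable epochs for position {pos!r}")
        pos_scores[pos] = float(np.asarray(scores)[mask].mean())
    best = max(pos_scores.values())
    chosen = next(pp for pp in positions if pos_scores[pp] == best)
    return SelectionResult(
        run=runs.pop(), block=blocks.pop(), true_target=true_target,
        position_scores=pos_scores, chosen_position=chosen,
        correct=(chosen == true_target))


def chance_threshold(n_selections: int, chance_p: float = 0.25,
                     alpha: float = 0.05) -> tuple[int, float]:
    """Smallest correct count significantly above chance (exact binomial).

    Returns ``(min_correct, threshold_pct)``: the smallest ``k`` with
    ``P(X >= k | n, chance_p) < alpha`` and the matching accuracy in
    percent.  For 48 four-choice selections at α = 0.05 this is 18
    correct, 37.5%.
    """
    if not 0 < chance_p < 1:
        raise ValueError("chance_p must lie in (0, 1)")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if n_selections < 1:
        raise ValueError("need at least one selection")
    tails = stats.binom.sf(np.arange(n_selections + 1) - 1, n_selections, chance_p)
    below = np.nonzero(tails < alpha)[0]
    k = int(below[0]) if below.size else n_selections + 1
    return k, 100.0 * k / n_selections


def loocv_accuracy(eps: EpochSet, cfg: ClassifierConfig,
                   channels: list[str],
                   chance_p: float = 0.25, alpha: float = 0.05) -> AccuracyResult:
    """Leave-one-block-out cross-validated selection accuracy.

    For every target block, an SWLDA model is fitted on all other
    blocks' epochs and the held-out block's target position is selected
    from the aggregated scores.  A degenerate fold (no feature selected)
    is counted incorrect and logged.  With
    ``cfg.reject_for_classification`` set, epochs flagged by artifact
    rejection are excluded from training and scoring.
    """
    X, y, names = build_features(eps, cfg, channels)
    keys = [(ev.run, ev.block) for ev in eps.events]
    block_ids = sorted(set(keys))
    if len(block_ids) < 2:
        raise ValueError("need at least two blocks for cross-validation")
    keys_arr = np.array(keys)
    usable = eps.kept if cfg.reject_for_classification else \
        np.ones(eps.n_epochs, dtype=bool)

    selections: list[SelectionResult] = []
    for run, block in block_ids:
        test_mask = (keys_arr[:, 0] == run) & (keys_arr[:, 1] == block)
        train_mask = ~test_mask & usable
        score_mask = test_mask & usable
        test_events = [ev for ev, m in zip(eps.events, score_mask) if m]
        true_target = next(ev.position for ev, m in zip(eps.events, test_mask)
                           if m and ev.is_target)
        try:
            model = swlda_fit(X[train_mask], y[train_mask], cfg, names)
        except ValueError as exc:
            logger.warning("fold (%d,%d) could not be fit: %s", run, block, exc)
            model = SWLDAModel([], np.empty(0), 0.0)
        if model.degenerate:
            logger.warning("fold (%d,%d): degenerate model counted incorrect",
                           run, block)
            selections.append(SelectionResult(
                run=run, block=block, true_target=true_target,
                position_scores={}, chosen_position="", correct=False))
            continue
        fold_scores = score(model, X[score_mask])
        selections.append(select_target(fold_scores, test_events))

    n_blocks = len(selections)
    n_correct = sum(s.correct for s in selections)
    acc = 100.0 * n_correct / n_blocks
    k_min, thr = chance_threshold(n_blocks, chance_p, alpha)
    return AccuracyResult(
        n_blocks=n_blocks, n_correct=n_correct, accuracy_pct=acc,
        chance_pct=100.0 * chance_p, significance_threshold_pct=thr,
        significant=n_correct >= k_min,
        meets_usability=acc >= USABILITY_THRESHOLD_PCT,
        selections=selections)
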