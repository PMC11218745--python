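"""Result tables and grand-average figures.

The amplitude table lists per-channel group means and SDs of the
window-mean target amplitudes; the accuracy table lists per-subject
cross-validated accuracies for both EEG systems alongside the
somatosensory sensitivity threshold, with a ``+`` marking accuracies
not significantly above chance (below 18/48 = 37.5%), a ``*`` marking
significant accuracies below the 70% usability criterion, and missing
values rendered as ``–``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .classify import USABILITY_THRESHOLD_PCT, AccuracyResult
from .erp import summarize_features
from .preprocess import ERPAverage

MISSING = "–"


def _mark(acc: AccuracyResult | None) -> str:
    if acc is None:
        return MISSING
    val = f"{acc.accuracy_pct:.0f}"
    if not acc.significant:
        return val + "+"
    if acc.accuracy_pct < USABILITY_THRESHOLD_PCT:
        return val + "*"
    return val


def amplitude_table(features: pd.DataFrame) -> pd.DataFrame:
    """Group amplitude summary in the two-system layout."""
    summary = summarize_features(features)
    summary["system"] = np.where(
        summary["channel"].str.contains("-"), "cEEGrid", "EEG cap")
    cols = ["system", "channel", "window", "mean_amplitude_uv",
            "sd_amplitude_uv", "mean_latency_ms", "n_subjects"]
    return summary[cols]


def accuracy_table(cap: dict[str, AccuracyResult | None],
                   grid: dict[str, AccuracyResult | None],
                   thresholds: dict[str, float | None]) -> pd.DataFrame:
    """Per-subject accuracy/sensitivity overview (one row per subject).

    Numeric columns carry plain values (NaN when missing); the
    ``*_display`` columns carry the annotated strings.
    """
    subjects = sorted(set(cap) | set(grid) | set(thresholds))
    rows = []
    for s in subjects:
        c, g, th = cap.get(s), grid.get(s), thresholds.get(s)
        rows.append({
            "subject": s,
            "cap_pct": c.accuracy_pct if c else np.nan,
            "ceegrid_pct": g.accuracy_pct if g else np.nan,
            "sensitivity_pct": th if th is not None else np.nan,
            "cap_display": _mark(c),
            "ceegrid_display": _mark(g),
            "sensitivity_display":
                f"{th:.1f}" if th is not None else MISSING,
        })
    table = pd.DataFrame(rows)
    mean_row = {
        "subject": "M",
        "cap_pct": table["cap_pct"].mean(),
        "ceegrid_pct": table["ceegrid_pct"].mean(),
        "sensitivity_pct": table["sensitivity_pct"].mean(),
        "cap_display": f"{table['cap_pct'].mean():.0f} "
                       f"(SD = {table['cap_pct'].std():.0f})"
                       if table["cap_pct"].notna().any() else MISSING,
        "ceegrid_display": f"{table['ceegrid_pct'].mean():.0f} "
                           f"(SD = {table['ceegrid_pct'].std():.0f})"
                           if table["ceegrid_pct"].notna().any() else MISSING,
        "sensitivity_display": f"{table['sensitivity_pct'].mean():.1f} "
                               f"(SD = {table['sensitivity_pct'].std():.1f})"
                               if table["sensitivity_pct"].notna().any() else MISSING,
    }
    return pd.concat([table, pd.DataFrame([mean_row])], ignore_index=True)


def grand_average_figure(averages: dict[str, ERPAverage],
                         channels: list[str], path: str | Path) -> None:
    """Grand-average target/non-target waveforms with between-subject SE bands."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = len(channels)
    ncols = min(4, n)
    nrows = -(-n // ncols)
    fig, axes = plt.subplots(nrows, ncols, figsize=(3.2 * ncols, 2.6 * nrows),
                             squeeze=False, sharex=True, sharey=True)
    some = next(iter(averages.values()))
    lat = some.latencies_ms
    for ax, ch in zip(axes.ravel(), channels):
        for which, color in (("target", "tab:red"), ("nontarget", "tab:blue")):
            waves = np.array([
                avg.waveform(ch, "target" if which == "target" else "non")
                for avg in averages.values() if ch in avg.channel_labels])
            if waves.size == 0:
                continue
            mean = waves.mean(axis=0)
            se = waves.std(axis=0, ddof=1) / np.sqrt(len(waves)) \
                if len(waves) > 1 else np.zeros_like(mean)
            ax.plot(lat, mean, color=color, label=which)
            ax.fill_between(lat, mean - se, mean + se, color=color, alpha=0.25)
        ax.axvline(0, color="k", lw=0.5)
        ax.axhline(0, color="k", lw=0.5)
        ax.set_title(ch)
    for ax in axes.ravel()[n:]:
        ax.set_visible(False)
    axes[0, 0].legend(fontsize=8)
    fig.supxlabel("latency [ms]")
    fig.supylabel("amplitude [μV]")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def report_tables(features: pd.DataFrame,
                  cap: dict[str, AccuracyResult | None],
                  grid: dict[str, AccuracyResult | None],
                  thresholds: dict[str, float | None],
                  out_dir: str | Path,
                  averages: dict[str, ERPAverage] | None = None) -> dict[str, Path]:
    """Write the report bundle (CSVs and, if averages given, figures)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    amp = amplitude_table(features)
    paths["amplitudes"] = out / "amplitudes.csv"
    amp.to_csv(paths["amplitudes"], index=False)

    acc = accuracy_table(cap, grid, thresholds)
    paths["accuracies"] = out / "accuracies.csv"
    acc.to_csv(paths["accuracies"], index=False)

    paths["features"] = out / "features.csv"
    features.to_csv(paths["features"], index=False)

    if averages:
        chans = [c for c in amp["channel"] if
                 all(c in a.channel_labels for a in averages.values())]
        paths["grand_average"] = out / "grand_average.png"
        grand_average_figure(averages, chans, paths["grand_average"])
    return paths
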