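"""Result tables and figures for a cohort analysis.

Emits the analysis surface as files: grand-average ERP with standard
error, magnitude-versus-lag curves, the name-locked score time course,
before/after boxplots with per-subject lines, condition comparisons, and
one TSV of all statistics.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

STATS_COLUMNS = ["test", "statistic", "p", "n", "direction"]


def stats_table(rows: list[dict]) -> pd.DataFrame:
    table = pd.DataFrame(rows)
    missing = set(STATS_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"stats rows missing fields: {sorted(missing)}")
    return table[STATS_COLUMNS]


def build_report(results: dict, outdir: str | Path) -> list[Path]:
    """Write all tables and figures; returns the created paths.

    ``results`` must contain: ``stats_rows`` (list of dicts),
    ``erp`` (dict with times, name/control per-subject Pz waveforms),
    ``magnitude`` (dict role -> per-subject magnitude arrays + lags),
    ``event_locked`` (dict stream -> per-subject {slot: score}),
    ``before_after`` (dict stream -> list of (before, after)).
    """
    required = {"stats_rows", "erp", "magnitude", "event_locked", "before_after"}
    missing = required - set(results)
    if missing:
        raise ValueError(f"missing report inputs: {sorted(missing)}")
    if not results["stats_rows"]:
        raise ValueError("empty cohort: no statistics to report")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    created: list[Path] = []

    table = stats_table(results["stats_rows"])
    path = outdir / "statistics.tsv"
    table.to_csv(path, sep="\t", index=False)
    created.append(path)

    # grand-average ERP with SE band
    e = results["erp"]
    fig, ax = plt.subplots(figsize=(6, 4))
    for label, color in (("name", "tab:blue"), ("control", "0.5")):
        wave = np.asarray(e[label])  # (n_subjects, n_times)
        m = wave.mean(axis=0)
        se = wave.std(axis=0, ddof=1) / np.sqrt(wave.shape[0]) if wave.shape[0] > 1 else 0 * m
        ax.plot(e["times"], m, color=color, label=label)
        ax.fill_between(e["times"], m - se, m + se, color=color, alpha=0.3, lw=0)
    ax.axvspan(0.5, 1.2, color="tab:cyan", alpha=0.15)
    ax.set(xlabel="time re name onset (s)", ylabel="amplitude (uV)", title="ERP at Pz")
    ax.legend()
    p = outdir / "erp_waveforms.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    created.append(p)

    # magnitude vs lag
    mag = results["magnitude"]
    fig, ax = plt.subplots(figsize=(6, 4))
    colors = {"attended": "tab:red", "ignored": "tab:blue", "control": "0.5"}
    for role, entry in mag.items():
        arr = np.asarray(entry["per_subject"])
        m = arr.mean(axis=0)
        se = arr.std(axis=0, ddof=1) / np.sqrt(arr.shape[0]) if arr.shape[0] > 1 else 0 * m
        ax.plot(entry["lags"], m, color=colors.get(role, None), label=role)
        ax.fill_between(entry["lags"], m - se, m + se, alpha=0.3, lw=0,
                        color=colors.get(role, None))
    ax.set(xlabel="time lag (s)", ylabel="cross-correlation magnitude (GFP)",
           title="envelope tracking by lag")
    ax.legend()
    p = outdir / "magnitude_by_lag.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    created.append(p)

    # name-locked score time course
    fig, ax = plt.subplots(figsize=(6, 4))
    for stream, label, color in (("att", "attended", "tab:red"), ("ign", "ignored", "tab:blue")):
        per_subj = results["event_locked"][stream]  # list of {slot: score}
        slots = sorted(set.intersection(*(set(d) for d in per_subj)))
        centers = [(-0.5 + s) * 5 if s > 0 else (s + 0.5) * 5 for s in slots]
        arr = np.array([[d[s] for s in slots] for d in per_subj])
        m, se = arr.mean(axis=0), arr.std(axis=0, ddof=1) / np.sqrt(arr.shape[0])
        ax.errorbar(centers, m, yerr=se, fmt="o-", color=color, label=label, ms=4)
    ax.axvline(0, color="k", lw=0.8, ls="--")
    ax.set(xlabel="segment center re name onset (s)", ylabel="summary score",
           title="tracking around the name")
    ax.legend()
    p = outdir / "event_locked_timecourse.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    created.append(p)

    # before/after boxplots with per-subject lines
    fig, axes = plt.subplots(1, 2, figsize=(8, 4), sharey=True)
    for ax, stream, label in ((axes[0], "att", "attended"), (axes[1], "ign", "ignored")):
        pairs = np.asarray(results["before_after"][stream])
        ax.boxplot([pairs[:, 0], pairs[:, 1]], tick_labels=["before", "after"])
        for b, a in pairs:
            ax.plot([1, 2], [b, a], color="0.6", lw=0.6, ls="--")
        ax.set_title(label)
    axes[0].set_ylabel("summary score")
    p = outdir / "before_after.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    created.append(p)

    if "condition" in results:
        cond = results["condition"]
        fig, axes = plt.subplots(1, len(cond), figsize=(4 * len(cond), 4))
        axes = np.atleast_1d(axes)
        for ax, (name, entry) in zip(axes, cond.items()):
            ax.boxplot([entry["higher"], entry["lower"]], tick_labels=["higher", "lower"])
            ax.set_title(name)
        p = outdir / "condition_comparison.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        created.append(p)
    return created
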