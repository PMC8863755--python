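"""The three standard figures for a day of usage data.

* **App totals** — horizontal bars of total time per app in one 24-h
  period.
* **Day barcode** — a single 24-h strip where dark bars mark sessions of
  consistent use and white gaps mark the device lying idle; insomnia is
  visible at a glance.
* **App timeline** — the same strip colored by app, top-k apps by
  duration named in the legend and the rest pooled as "other".

Every plot writes a machine-readable *sidecar* CSV of the geometry it
drew (one row per bar/segment). The sidecar is the contract tests assert
against; pixels are not. Given identical data and spec, vector (SVG)
output is byte-identical.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from os import PathLike
from pathlib import Path

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt

from .metrics import Session
from .simulate import AppInterval

__all__ = [
    "PlotSpec",
    "plot_app_totals",
    "plot_day_barcode",
    "plot_app_timeline",
    "DEFAULT_TIMELINE_COLORS",
]

MS_PER_HOUR = 3_600_000
MS_PER_DAY = 86_400_000

#: Five named colors for the five most used apps, plus grey for "other".
DEFAULT_TIMELINE_COLORS = ("black", "red", "green", "gold", "blue")


@dataclass
class PlotSpec:
    out_path: str | PathLike
    image_format: str = "svg"  # "svg" (deterministic bytes) or "png"
    day_start_ms: int = 0
    colors: tuple[str, ...] = DEFAULT_TIMELINE_COLORS
    top_k: int = 5
    figsize: tuple[float, float] = (10.0, 2.5)
    title: str | None = None

    def __post_init__(self) -> None:
        if self.image_format not in ("svg", "png"):
            raise ValueError("image_format must be 'svg' or 'png'")

    @property
    def sidecar_path(self) -> Path:
        p = Path(self.out_path)
        return p.with_suffix(p.suffix + ".geometry.csv")


def _save(fig, spec: PlotSpec) -> None:
    plt.rcParams["svg.hashsalt"] = "phonelog"
    kwargs = {"format": spec.image_format}
    if spec.image_format == "svg":
        kwargs["metadata"] = {"Date": None}  # strip wall-clock for determinism
    fig.savefig(spec.out_path, **kwargs)
    plt.close(fig)


def _write_sidecar(spec: PlotSpec, header: list[str], rows: list[list]) -> None:
    with open(spec.sidecar_path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(header)
        w.writerows(rows)


def plot_app_totals(durations: dict[str, int], spec: PlotSpec) -> Path:
    """Horizontal bar chart: total time per app in a 24-h period.

    Bar lengths are proportional to duration; apps are sorted longest
    first. An empty map yields a labeled empty chart, still with its
    sidecar.
    """
    items = sorted(durations.items(), key=lambda kv: kv[1], reverse=True)
    fig, ax = plt.subplots(figsize=(spec.figsize[0], max(2.0, 0.4 * len(items) + 1)))
    labels = [a for a, _ in items]
    hours = [ms / MS_PER_HOUR for _, ms in items]
    ax.barh(range(len(items)), hours, color="steelblue")
    ax.set_yticks(range(len(items)), labels)
    ax.invert_yaxis()
    ax.set_xlabel("hours of use")
    ax.set_title(spec.title or "Time per app, 24-h period")
    if not items:
        ax.text(0.5, 0.5, "no app usage", ha="center", va="center", transform=ax.transAxes)
    fig.tight_layout()
    _save(fig, spec)
    _write_sidecar(
        spec,
        ["app", "duration_ms"],
        [[a, ms] for a, ms in items],
    )
    return Path(spec.out_path)


def plot_day_barcode(sessions: list[Session], spec: PlotSpec) -> Path:
    """24-h barcode strip: one dark bar per session, gaps blank.

    Sessions are clipped to the day ``[day_start_ms, day_start_ms + 24 h)``;
    sessions outside it are ignored. Micro-gaps are drawn as-is, without
    bridging.
    """
    day_end = spec.day_start_ms + MS_PER_DAY
    clipped = [
        (max(s.start_ms, spec.day_start_ms), min(s.end_ms, day_end))
        for s in sessions
        if s.end_ms > spec.day_start_ms and s.start_ms < day_end
    ]
    fig, ax = plt.subplots(figsize=spec.figsize)
    for a, b in clipped:
        x0 = (a - spec.day_start_ms) / MS_PER_HOUR
        ax.axvspan(x0, x0 + (b - a) / MS_PER_HOUR, color="black")
    ax.set_xlim(0, 24)
    ax.set_yticks([])
    ax.set_xticks(range(0, 25, 2))
    ax.set_xlabel("hour of day")
    ax.set_title(spec.title or "Device use across the day")
    fig.tight_layout()
    _save(fig, spec)
    _write_sidecar(
        spec,
        ["start_ms", "end_ms"],
        [[a, b] for a, b in clipped],
    )
    return Path(spec.out_path)


def plot_app_timeline(intervals: list[AppInterval], spec: PlotSpec) -> Path:
    """24-h strip colored by app; top-k apps by total duration get named
    colors, everything else is pooled as grey "other"."""
    day_end = spec.day_start_ms + MS_PER_DAY
    clipped = [
        AppInterval(
            iv.app_id, max(iv.start_ms, spec.day_start_ms), min(iv.end_ms, day_end)
        )
        for iv in intervals
        if iv.end_ms > spec.day_start_ms and iv.start_ms < day_end
    ]
    totals: dict[str, int] = {}
    for iv in clipped:
        totals[iv.app_id] = totals.get(iv.app_id, 0) + (iv.end_ms - iv.start_ms)
    ranked = sorted(totals.items(), key=lambda kv: kv[1], reverse=True)
    top = [a for a, _ in ranked[: spec.top_k]]
    color_of = {a: spec.colors[i % len(spec.colors)] for i, a in enumerate(top)}

    fig, ax = plt.subplots(figsize=spec.figsize)
    rows: list[list] = []
    for iv in clipped:
        color = color_of.get(iv.app_id, "lightgrey")
        label = iv.app_id if iv.app_id in color_of else "other"
        x0 = (iv.start_ms - spec.day_start_ms) / MS_PER_HOUR
        x1 = (iv.end_ms - spec.day_start_ms) / MS_PER_HOUR
        ax.axvspan(x0, x1, color=color)
        rows.append([label, color, iv.app_id, iv.start_ms, iv.end_ms])
    handles = [plt.Rectangle((0, 0), 1, 1, color=color_of[a]) for a in top]
    labels = list(top)
    if len(totals) > len(top):
        handles.append(plt.Rectangle((0, 0), 1, 1, color="lightgrey"))
        labels.append("other")
    if handles:
        ax.legend(handles, labels, loc="upper left", bbox_to_anchor=(1.01, 1.0), fontsize=7)
    ax.set_xlim(0, 24)
    ax.set_yticks([])
    ax.set_xticks(range(0, 25, 2))
    ax.set_xlabel("hour of day")
    ax.set_title(spec.title or "App use across the day")
    fig.tight_layout()
    _save(fig, spec)
    _write_sidecar(spec, ["legend_label", "color", "app", "start_ms", "end_ms"], rows)
    return Path(spec.out_path)
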