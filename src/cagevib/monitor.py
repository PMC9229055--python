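"""Continuous activity monitoring: window-by-window classification of an IMU
stream, 30-min occurrence summaries and per-class duration totals.

Every consecutive 15-s window of the stream is classified independently and
stamped with its start time, giving an activity timeline with 15-s
resolution. Gaps (e.g., the sensor detaching from the cage) are represented
as missing records — labels are never imputed — so summary bins overlapping a
gap simply report fewer windows, and an empty bin reports a count of 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime, timezone

import numpy as np
import pandas as pd

from .classify import ModelBundle
from .errors import ContractError
from .features import FEATURE_NAMES, extract_features
from .imu import WINDOW_S, ImuStream, segment_windows
from .sim import CLASS_ORDER, ActivityClass

__all__ = [
    "ActivityTimeline", "SummaryBin", "ClassTotals", "classify_stream",
    "summarize", "totals", "write_timeline_csv", "read_timeline_csv",
    "plot_timeline",
]


@dataclass
class ActivityTimeline:
    """Time-stamped 15-s activity records; gaps between records are allowed."""

    times: np.ndarray   # window start times, seconds since epoch
    labels: np.ndarray  # class value strings
    window_s: float = WINDOW_S

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        if len(self.times) != len(self.labels):
            raise ContractError("times and labels must have equal length")
        if len(self.times) > 1 and (np.diff(self.times) < self.window_s - 1e-9).any():
            raise ContractError("records must be increasing by at least one window")

    def __len__(self) -> int:
        return len(self.times)

    @staticmethod
    def concat(parts: list["ActivityTimeline"]) -> "ActivityTimeline":
        """Join segments (e.g., around a sensor-detachment gap)."""
        return ActivityTimeline(
            np.concatenate([p.times for p in parts]),
            np.concatenate([p.labels for p in parts]),
            parts[0].window_s,
        )


@dataclass(frozen=True)
class SummaryBin:
    start: float
    width: float
    count: int
    percent: dict[str, float]  # per class, sums to 100 when count > 0


@dataclass(frozen=True)
class ClassTotals:
    hours: dict[str, float]

    @property
    def total_hours(self) -> float:
        return sum(self.hours.values())


def classify_stream(stream: ImuStream, bundle: ModelBundle,
                    window_s: float = WINDOW_S) -> ActivityTimeline:
    """Classify every consecutive window of the stream with the bundle.

    The bundle may have been trained on a feature subset (axis ablation);
    the matching columns are selected by name. Unknown feature names raise.
    """
    try:
        cols = [FEATURE_NAMES.index(n) for n in bundle.feature_names]
    except ValueError as exc:
        raise ContractError("model bundle names unknown features") from exc
    windows = segment_windows(stream, window_s)
    if not windows:
        raise ContractError("stream shorter than one window")
    X = np.array([extract_features(w) for w in windows])[:, cols]
    labels = bundle.predict(X)
    times = np.array([w.start_time for w in windows])
    return ActivityTimeline(times, labels, window_s)


def summarize(timeline: ActivityTimeline, bin_s: float = 1800.0,
              align: str = "absolute") -> list[SummaryBin]:
    """Per-class occurrence (percent of windows) in consecutive bins.

    ``align="absolute"`` anchors bins at wall-clock multiples of ``bin_s``
    (half-hours); ``align="relative"`` anchors at the first record. Bins in
    the span with no windows (a data gap) are reported with count 0 and 0 %
    everywhere, never with fabricated labels.
    """
    if len(timeline) == 0:
        raise ContractError("cannot summarize an empty timeline")
    t0 = timeline.times[0]
    origin = np.floor(t0 / bin_s) * bin_s if align == "absolute" else t0
    idx = np.floor((timeline.times - origin) / bin_s).astype(int)
    out = []
    for i in range(0, idx.max() + 1):
        in_bin = timeline.labels[idx == i]
        count = len(in_bin)
        percent = {
            c.value: (100.0 * float((in_bin == c.value).sum()) / count if count else 0.0)
            for c in CLASS_ORDER
        }
        out.append(SummaryBin(origin + i * bin_s, bin_s, count, percent))
    return out


def totals(timeline: ActivityTimeline) -> ClassTotals:
    """Per-class monitored hours: window count × window length.

    Conservation is exact: the class hours sum to ``len(timeline) ×
    window_s / 3600`` with no internal rounding.
    """
    per_hour = timeline.window_s / 3600.0
    return ClassTotals({
        c.value: float((timeline.labels == c.value).sum()) * per_hour
        for c in CLASS_ORDER
    })


def _iso(t: float) -> str:
    return datetime.fromtimestamp(t, tz=timezone.utc).isoformat()


def write_timeline_csv(timeline: ActivityTimeline, path) -> None:
    pd.DataFrame({
        "start_time": timeline.times,
        "timestamp": [_iso(t) for t in timeline.times],
        "label": timeline.labels,
    }).to_csv(path, index=False)


def read_timeline_csv(path) -> ActivityTimeline:
    table = pd.read_csv(path)
    return ActivityTimeline(table["start_time"].to_numpy(dtype=float),
                            table["label"].to_numpy(dtype=object))


def write_summary_csv(bins: list[SummaryBin], path) -> None:
    rows = []
    for b in bins:
        row = {"bin_start": b.start, "timestamp": _iso(b.start),
               "width_s": b.width, "count": b.count}
        row.update({f"pct_{c}": p for c, p in b.percent.items()})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def format_totals(t: ClassTotals) -> str:
    lines = [f"{c.value:>12s}: {t.hours[c.value]:6.2f} h" for c in CLASS_ORDER]
    lines.append(f"{'total':>12s}: {t.total_hours:6.2f} h")
    return "\n".join(lines)


def plot_timeline(timeline: ActivityTimeline, bins: list[SummaryBin] | None = None,
                  path=None):
    """Actogram-style view: the 15-s label raster and, optionally, the
    stacked 30-min occurrence percentages underneath."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = {ActivityClass.RESTING.value: "black",
              ActivityClass.STATIONARY.value: "gray",
              ActivityClass.LOCOMOTION.value: "red"}
    n_rows = 2 if bins else 1
    fig, axes = plt.subplots(n_rows, 1, figsize=(10, 2.2 * n_rows), sharex=True,
                             squeeze=False)
    ax = axes[0][0]
    hours = (timeline.times - timeline.times[0]) / 3600
    levels = {c.value: i for i, c in enumerate(CLASS_ORDER)}
    ax.scatter(hours, [levels[l] for l in timeline.labels], s=2,
               c=[colors[l] for l in timeline.labels])
    ax.set_yticks(range(3), [c.value for c in CLASS_ORDER])
    ax.set_ylabel("class")
    if bins:
        ax2 = axes[1][0]
        bh = (np.array([b.start for b in bins]) - timeline.times[0]) / 3600
        bottom = np.zeros(len(bins))
        for c in CLASS_ORDER:
            pct = np.array([b.percent[c.value] for b in bins])
            ax2.bar(bh, pct, width=bins[0].width / 3600, bottom=bottom,
                    align="edge", color=colors[c.value], label=c.value)
            bottom += pct
        ax2.set_ylabel("occurrence [%]")
        ax2.legend(fontsize="small")
    axes[-1][0].set_xlabel("time since start [h]")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
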