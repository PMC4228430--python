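"""On-line population-segregation statistics for cytometry samples.

Two gating-free / gating-based indicators of microbial population
segregation, computed per sample and assembled into time series:

* **MMR**, the mean-to-median ratio of a cytometric variable on the linear
  scale. A unimodal, near-symmetric population has MMR ≈ 1; a right-skewed
  mixture (a minority subpopulation at higher intensity) pulls the mean
  above the median, so MMR > 1. Because it needs no gates it can be
  computed on the raw list-mode stream, which is what makes it usable for
  on-line monitoring and feedback control.

* **Degree of segregation** = 1 − |f_R1 − f_R2| on the *fractions* of cells
  in the PI-negative (R1) and PI-intermediate (R2) gates: 0 when one gate
  holds all cells, 1 at equal partition. Inputs are fractions in [0, 1];
  percent-scale arguments (which would push the statistic outside its range)
  are rejected loudly.

All statistics operate on linear raw channel values after the FSC
acquisition threshold; a log-scale MMR variant is available under a
separate name (:func:`log_mmr`) and is never the default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .fcs_io import EventTable
from .gating import (
    GateSet,
    UNGATED,
    apply_fsc_threshold,
    assign_gates,
    gate_fractions,
    EmptySampleError,
)

__all__ = [
    "SampleSummary",
    "SegregationSeries",
    "SegmetricsError",
    "UndefinedMMRError",
    "InvalidFractionError",
    "DuplicateTimeError",
    "LOW_COUNT_THRESHOLD",
    "mmr",
    "log_mmr",
    "degree_of_segregation",
    "summarize_sample",
    "build_series",
]

#: Gates holding fewer events than this get their MMR flagged low-count:
#: with only a handful of cells in a gate the mean and median lose meaning
#: (the sparse early R2 gate is the motivating case).
LOW_COUNT_THRESHOLD = 100


class SegmetricsError(ValueError):
    pass


class UndefinedMMRError(SegmetricsError):
    """Median is zero — the sample is degenerate or off-scale."""


class InvalidFractionError(SegmetricsError):
    """Fractions outside [0,1] or summing above 1 (percent-scale misuse)."""


class DuplicateTimeError(SegmetricsError):
    pass


def mmr(values: Sequence[float] | np.ndarray) -> float:
    """Mean-to-median ratio of linear channel values.

    The median of an even-sized sample is the mid-average of the two
    central order statistics. Raises on empty input and when the median is
    zero (MMR undefined).
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise EmptySampleError("cannot compute MMR of an empty sample")
    med = float(np.median(arr))
    if med == 0.0:
        raise UndefinedMMRError("median is zero; MMR undefined for this sample")
    return float(np.mean(arr)) / med


def log_mmr(values: Sequence[float] | np.ndarray) -> float:
    """MMR computed on log10-transformed values (optional variant).

    Requires strictly positive inputs. Not the default statistic: the
    skew-sensitivity that makes the MMR useful lives on the linear scale.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise EmptySampleError("cannot compute MMR of an empty sample")
    if np.any(arr <= 0):
        raise SegmetricsError("log-MMR requires strictly positive values")
    return mmr(np.log10(arr))


def degree_of_segregation(f_r1: float, f_r2: float) -> float:
    """1 − |f_R1 − f_R2| on gate fractions.

    0 = minimal segregation (all cells in a single gate), 1 = maximal
    (cells equally partitioned between the two subpopulations). Symmetric
    in its arguments. Inputs must be fractions in [0, 1] summing to at most
    1; anything else (e.g. percentages) raises
    :class:`InvalidFractionError`.
    """
    for name, f in (("f_r1", f_r1), ("f_r2", f_r2)):
        if not (0.0 <= f <= 1.0):
            raise InvalidFractionError(
                f"{name}={f} outside [0,1]; pass fractions, not percentages"
            )
    if f_r1 + f_r2 > 1.0 + 1e-12:
        raise InvalidFractionError(f"fractions sum to {f_r1 + f_r2} > 1")
    return 1.0 - abs(f_r1 - f_r2)


@dataclass(frozen=True)
class ChannelStats:
    """Mean/median/MMR of one channel for one (sub)population."""

    mean: float
    median: float
    mmr: float | None  # None when the median is zero
    n: int
    low_count: bool = False


@dataclass(frozen=True)
class SampleSummary:
    """Per-sample segregation summary.

    Holds, for every channel, the overall statistics and the per-gate
    statistics of the FSC-thresholded events, the gate fractions, and the
    degree of segregation computed from the R1/R2 fractions.
    """

    time_h: float
    overall: Mapping[str, ChannelStats]
    per_gate: Mapping[str, Mapping[str, ChannelStats]]  # gate -> channel -> stats
    fractions: Mapping[str, float]
    degree_of_segregation: float
    n_events: int
    sample_id: str = ""

    def to_row(self) -> dict[str, float]:
        """Flatten to one tidy CSV row (columns ``statistic_channel_gate``)."""
        row: dict[str, float] = {
            "time_h": self.time_h,
            "n_events": self.n_events,
            "degree_of_segregation": self.degree_of_segregation,
        }
        for gate, frac in sorted(self.fractions.items()):
            row[f"fraction_{gate}"] = frac
        for ch, st in sorted(self.overall.items()):
            row[f"mean_{ch}_all"] = st.mean
            row[f"median_{ch}_all"] = st.median
            row[f"mmr_{ch}_all"] = st.mmr if st.mmr is not None else math.nan
        for gate, chans in sorted(self.per_gate.items()):
            for ch, st in sorted(chans.items()):
                row[f"mean_{ch}_{gate}"] = st.mean
                row[f"median_{ch}_{gate}"] = st.median
                row[f"mmr_{ch}_{gate}"] = st.mmr if st.mmr is not None else math.nan
                row[f"lowcount_{ch}_{gate}"] = float(st.low_count)
        return row


def _channel_stats(values: np.ndarray) -> ChannelStats:
    n = values.size
    mean = float(np.mean(values))
    median = float(np.median(values))
    ratio = mean / median if median != 0.0 else None
    return ChannelStats(mean=mean, median=median, mmr=ratio, n=n, low_count=n < LOW_COUNT_THRESHOLD)


def summarize_sample(
    table: EventTable,
    gateset: GateSet,
    time_h: float,
    sample_id: str = "",
) -> SampleSummary:
    """Threshold, gate, and summarize one sample.

    Statistics are computed on the FSC-thresholded events only. Per-gate
    MMRs for gates with fewer than :data:`LOW_COUNT_THRESHOLD` events carry
    a low-count flag. The degree of segregation uses the R1 and R2
    fractions (0 for a missing gate).
    """
    if "FSC" in table.events.columns:
        kept = apply_fsc_threshold(table, gateset.fsc_threshold)
    elif gateset.fsc_threshold <= 0:
        kept = table  # scatter-free table; a zero threshold keeps everything
    else:
        kept = apply_fsc_threshold(table, gateset.fsc_threshold)  # raises
    if kept.n_events == 0:
        raise EmptySampleError("no events above the FSC threshold")
    labels = assign_gates(kept, gateset, sample_id=sample_id)
    fractions = gate_fractions(labels)

    channels = kept.channels
    overall = {ch: _channel_stats(kept.events[ch].to_numpy(dtype=float)) for ch in channels}

    per_gate: dict[str, dict[str, ChannelStats]] = {}
    for gate in gateset.gate_names():
        mask = labels.labels == gate
        if not mask.any():
            continue
        sub = kept.events.loc[mask]
        per_gate[gate] = {ch: _channel_stats(sub[ch].to_numpy(dtype=float)) for ch in channels}

    seg = degree_of_segregation(fractions.get("R1", 0.0), fractions.get("R2", 0.0))
    return SampleSummary(
        time_h=time_h,
        overall=overall,
        per_gate=per_gate,
        fractions=fractions,
        degree_of_segregation=seg,
        n_events=kept.n_events,
        sample_id=sample_id,
    )


@dataclass(frozen=True)
class SegregationSeries:
    """Time-ordered collection of sample summaries for one reactor."""

    summaries: tuple[SampleSummary, ...]
    reactor_id: str = ""

    def __post_init__(self) -> None:
        times = [s.time_h for s in self.summaries]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise DuplicateTimeError(f"timestamps must be strictly increasing, got {times}")

    def __len__(self) -> int:
        return len(self.summaries)

    def __iter__(self):
        return iter(self.summaries)

    @property
    def times(self) -> np.ndarray:
        return np.array([s.time_h for s in self.summaries])

    def statistic(self, name: str) -> np.ndarray:
        """Extract one flattened statistic over time (column of to_frame)."""
        return self.to_frame()[name].to_numpy()

    def degree(self) -> np.ndarray:
        return np.array([s.degree_of_segregation for s in self.summaries])

    def mmr(self, channel: str, gate: str = "all") -> np.ndarray:
        return self.statistic(f"mmr_{channel}_{gate}")

    def to_frame(self) -> pd.DataFrame:
        rows = [s.to_row() for s in self.summaries]
        frame = pd.DataFrame(rows)
        if self.reactor_id:
            frame.insert(0, "reactor", self.reactor_id)
        return frame

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def build_series(
    summaries: Iterable[SampleSummary], reactor_id: str = ""
) -> SegregationSeries:
    """Assemble summaries into a time-sorted series (unique timestamps)."""
    ordered = sorted(summaries, key=lambda s: s.time_h)
    times = [s.time_h for s in ordered]
    if len(set(times)) != len(times):
        raise DuplicateTimeError(f"duplicate timestamps in {times}")
    return SegregationSeries(summaries=tuple(ordered), reactor_id=reactor_id)
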