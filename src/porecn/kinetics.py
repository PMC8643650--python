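"""Run-kinetics statistics from sequencing-summary tables.

A nanopore run's molecule throughput is governed by three quantities: how
many channels are alive, how long each molecule resides in a pore
(length / translocation speed), and the vacancy time between consecutive
molecules in the same pore.  The functions here compute those statistics,
plus cumulative yield, channel activity rasters, per-device relative read
counts, and the MAPQ/length stratification used to pick a library length.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "cumulative_reads",
    "channel_lifetimes",
    "vacancy_times",
    "residence_time",
    "channel_activity",
    "relative_reads_per_channel",
    "mapq_from_error_prob",
    "length_stratified_mapq_fractions",
    "read_sequencing_summary",
]

MAX_MAPQ = 60

_SUMMARY_ALIASES = {
    "read_id": "read_id",
    "channel": "channel",
    "mux": "mux",
    "start_time": "start_time",
    "duration": "duration",
    "sequence_length_template": "length",
    "mean_qscore_template": "mean_q",
    "passes_filtering": "passed",
    "barcode_arrangement": "barcode",
    # already-canonical names pass through
    "length": "length",
    "mean_q": "mean_q",
    "passed": "passed",
    "barcode": "barcode",
}


def read_sequencing_summary(path) -> pd.DataFrame:
    """Read an ONT-dialect sequencing-summary TSV into canonical columns.

    Header matching is case-insensitive and extra columns are ignored.
    """
    df = pd.read_csv(path, sep="\t")
    rename = {}
    for col in df.columns:
        canon = _SUMMARY_ALIASES.get(col.strip().lower())
        if canon and canon not in rename.values():
            rename[col] = canon
    df = df.rename(columns=rename)
    keep = [c for c in ("read_id", "channel", "mux", "start_time", "duration",
                        "length", "mean_q", "passed", "barcode") if c in df.columns]
    missing = {"channel", "start_time", "duration"} - set(keep)
    if missing:
        raise ValueError(f"summary file lacks required columns: {sorted(missing)}")
    out = df[keep].copy()
    if "passed" in out.columns and out["passed"].dtype == object:
        out["passed"] = out["passed"].astype(str).str.lower().isin(("true", "1", "pass", "t"))
    return out


def cumulative_reads(summary: pd.DataFrame, grid: np.ndarray) -> np.ndarray:
    """Number of reads finished by each time point of ``grid``.

    A read counts toward the yield once it finishes sequencing, i.e. at
    ``start_time + duration``.  The curve is non-decreasing and reaches the
    total read count at any grid point past the last read end.
    """
    grid = np.asarray(grid, dtype=float)
    if np.any(np.diff(grid) < 0):
        raise ValueError("grid must be sorted ascending")
    if len(summary) == 0:
        return np.zeros(len(grid), dtype=int)
    ends = np.sort((summary["start_time"] + summary["duration"]).to_numpy())
    return np.searchsorted(ends, grid, side="right")


def channel_lifetimes(summary: pd.DataFrame) -> dict[int, float]:
    """Per-channel lifetime: when each channel finished its final read.

    Channels that produced no reads are absent from the result.
    """
    if len(summary) == 0:
        return {}
    ends = summary["start_time"] + summary["duration"]
    return ends.groupby(summary["channel"]).max().to_dict()


def vacancy_times(summary: pd.DataFrame) -> np.ndarray:
    """Gaps between consecutive reads of the same pore within a channel.

    Only same-(channel, mux) consecutive read pairs contribute; the gap is
    ``next.start - prev.(start + duration)``.  Overlapping reads within one
    pore are invalid input and raise.
    """
    if len(summary) == 0:
        return np.array([], dtype=float)
    mux = summary["mux"] if "mux" in summary.columns else pd.Series(1, index=summary.index)
    df = summary.assign(_mux=mux).sort_values(["channel", "_mux", "start_time"])
    same = (df["channel"].to_numpy()[1:] == df["channel"].to_numpy()[:-1]) & (
        df["_mux"].to_numpy()[1:] == df["_mux"].to_numpy()[:-1]
    )
    prev_end = (df["start_time"] + df["duration"]).to_numpy()[:-1]
    gaps = df["start_time"].to_numpy()[1:] - prev_end
    gaps = gaps[same]
    if np.any(gaps < -1e-9):
        raise ValueError("overlapping reads within a (channel, pore)")
    return np.clip(gaps, 0.0, None)


def residence_time(length: float, speed: float = 450.0) -> float:
    """Time a molecule of ``length`` bases spends translocating at ``speed`` b/s.

    At the default 450 b/s a 10 kb molecule resides ~22 s in the pore while a
    400 bp molecule takes under a second — the kinetic basis for the higher
    molecule throughput of short libraries.
    """
    if speed <= 0:
        raise ValueError(f"speed must be > 0, got {speed}")
    if length < 0:
        raise ValueError("length must be >= 0")
    return length / speed


def channel_activity(
    summary: pd.DataFrame,
    window: float = 300.0,
    run_duration: float | None = None,
    n_channels: int | None = None,
) -> pd.DataFrame:
    """Boolean channel x time-window activity raster.

    A cell is True iff the channel sequenced any part of a read during that
    window (default five-minute windows); a read spanning several windows
    marks all of them.  Rows are channels, columns window start times.
    """
    if window <= 0:
        raise ValueError("window must be > 0")
    ends = summary["start_time"] + summary["duration"] if len(summary) else pd.Series(dtype=float)
    if run_duration is None:
        run_duration = float(ends.max()) if len(summary) else window
    n_win = max(1, int(np.ceil(run_duration / window)))
    channels = sorted(summary["channel"].unique()) if len(summary) else []
    if n_channels is not None:
        channels = sorted(set(channels) | set(range(1, n_channels + 1)))
    mat = np.zeros((len(channels), n_win), dtype=bool)
    index = {c: i for i, c in enumerate(channels)}
    if len(summary):
        first = np.floor(summary["start_time"].to_numpy() / window).astype(int)
        last = np.ceil(ends.to_numpy() / window).astype(int) - 1
        last = np.clip(last, 0, n_win - 1)
        first = np.clip(first, 0, n_win - 1)
        for ch, a, b in zip(summary["channel"].to_numpy(), first, last):
            mat[index[ch], a : b + 1] = True
    return pd.DataFrame(mat, index=pd.Index(channels, name="channel"),
                        columns=np.arange(n_win) * window)


def relative_reads_per_channel(total_reads: int, n_channels: int) -> float:
    """Total reads normalized by the device's channel count.

    Lets runs from devices with different channel counts (512-channel MinION
    vs 126-channel Flongle) be compared on one scale.
    """
    if n_channels < 1:
        raise ValueError("n_channels must be >= 1")
    if total_reads < 0:
        raise ValueError("total_reads must be >= 0")
    return total_reads / n_channels


def mapq_from_error_prob(p: float) -> int:
    """Mapping quality from the probability the alignment is wrong.

    MAPQ = round(-10*log10(p)), capped at 60 (the aligner's reported maximum,
    reached at p <= 1e-6).
    """
    if not 0.0 < p <= 1.0:
        raise ValueError(f"error probability must be in (0, 1], got {p}")
    return min(MAX_MAPQ, int(round(-10.0 * np.log10(p))))


def length_stratified_mapq_fractions(
    records: pd.DataFrame,
    length_bins: np.ndarray | None = None,
) -> pd.DataFrame:
    """Fraction of unaligned / perfect-MAPQ / suboptimal reads per length stratum.

    ``records`` needs columns ``read_length, mapq, is_unmapped``.  Default
    strata step by 100 bp from 100 bp to 1 kb, the read-length classes used
    when truncating long reads to choose a library length.  Per stratum the
    three fractions sum to 1: perfect = MAPQ 60, unaligned = unmapped flag,
    suboptimal = everything else.
    """
    if length_bins is None:
        length_bins = np.arange(100, 1001, 100)
    length_bins = np.asarray(length_bins)
    if np.any(np.diff(length_bins) <= 0):
        raise ValueError("length_bins must be strictly increasing")
    labels = pd.cut(records["read_length"], bins=length_bins, include_lowest=True)
    rows = []
    for stratum, grp in records.groupby(labels, observed=True):
        n = len(grp)
        unaligned = grp["is_unmapped"].sum() / n
        perfect = ((~grp["is_unmapped"]) & (grp["mapq"] == MAX_MAPQ)).sum() / n
        rows.append((stratum, n, unaligned, perfect, 1.0 - unaligned - perfect))
    return pd.DataFrame(rows, columns=["stratum", "n", "unaligned", "perfect", "suboptimal"])
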