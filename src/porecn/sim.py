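"""Synthetic data generation for the short-molecule nanopore CN pipeline.

Everything downstream (kinetics QC, binning, segmentation, integer copy
number, demultiplexing) can be exercised against data with known truth:

* :func:`simulate_run` emulates pore kinetics over a flow-cell run —
  length-proportional residence time at a fixed translocation speed,
  exponential (or fixed) vacancy gaps between molecules, and per-channel
  exponential lifetimes whose hazard scales with loading concentration.
* :func:`simulate_cn_profile` / :func:`simulate_bin_counts` produce bin-level
  read counts from a known integer copy-number profile, with optional GC bias
  and tumor-purity dilution.
* :func:`simulate_barcoded_reads` emits barcode sequences with iid
  substitution errors plus their true labels.

All randomness is driven by a single integer seed per call.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RunSimParams",
    "SimTruth",
    "BarcodeSet",
    "ONT_BARCODES",
    "simulate_run",
    "simulate_cn_profile",
    "simulate_bin_counts",
    "simulate_barcoded_reads",
    "standard_complex_truth",
    "write_sequencing_summary",
    "write_truth_json",
    "write_bin_counts_tsv",
]

_HOUR = 3600.0


@dataclass
class RunSimParams:
    """Parameters of a simulated sequencing run.

    Defaults describe a MinION-like device (512 channels) running for 48 h at
    450 bases/s.  ``loading_factor`` is the library amount as a multiple of
    the manufacturer-suggested molar equivalent (ME); loading more molecules
    shortens vacancy gaps but accelerates channel death.
    """

    n_channels: int = 512
    run_duration: float = 48 * _HOUR
    speed: float = 450.0
    median_bp: float = 500.0
    length_log_sd: float = 0.35
    min_length_bp: float = 50.0
    mean_vacancy: float = 2.0
    vacancy_model: str = "exponential"  # or "fixed"
    channel_death_hazard: float = 0.03  # per hour, at 1 ME
    loading_factor: float = 1.0
    pores_per_channel: int = 1
    mean_q: float = 10.0
    q_sd: float = 1.5
    pass_q: float = 7.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")
        if self.run_duration < 0:
            raise ValueError("run_duration must be >= 0")
        if self.speed <= 0:
            raise ValueError(f"speed must be > 0, got {self.speed}")
        if self.median_bp <= 0:
            raise ValueError(f"median_bp must be > 0, got {self.median_bp}")
        if self.mean_vacancy <= 0:
            raise ValueError("mean_vacancy must be > 0")
        if self.loading_factor <= 0:
            raise ValueError("loading_factor must be > 0")
        if self.channel_death_hazard < 0:
            raise ValueError("channel_death_hazard must be >= 0")
        if self.vacancy_model not in ("exponential", "fixed"):
            raise ValueError(f"unknown vacancy_model {self.vacancy_model!r}")
        if self.pores_per_channel < 1:
            raise ValueError("pores_per_channel must be >= 1")


@dataclass
class SimTruth:
    """Known integer copy-number truth over a binned genome.

    ``cn`` holds the tumor copy number per bin; ``events`` records the
    (start, end, cn) intervals that were painted over the ``baseline_cn``
    background; ``purity`` is the tumor cell fraction (observed signal is
    ``purity*cn + (1-purity)*baseline_cn``).  ``chrom`` optionally labels each
    bin with a chromosome so segmentation can respect chromosome breaks.
    """

    n_bins: int
    cn: np.ndarray
    events: list[tuple[int, int, int]] = field(default_factory=list)
    purity: float = 1.0
    baseline_cn: int = 2
    chrom: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.cn = np.asarray(self.cn, dtype=int)
        if len(self.cn) != self.n_bins:
            raise ValueError("cn length must equal n_bins")
        if np.any(self.cn < 0):
            raise ValueError("copy numbers must be >= 0")
        if not 0.0 <= self.purity <= 1.0:
            raise ValueError("purity must be in [0, 1]")
        if self.chrom is not None:
            self.chrom = np.asarray(self.chrom)
            if len(self.chrom) != self.n_bins:
                raise ValueError("chrom length must equal n_bins")

    @property
    def effective_cn(self) -> np.ndarray:
        """Purity-diluted copy number actually seen by sequencing."""
        return self.purity * self.cn + (1.0 - self.purity) * self.baseline_cn

    def true_boundaries(self) -> np.ndarray:
        """Bin indices where the copy number changes, excluding chromosome starts."""
        change = np.flatnonzero(np.diff(self.cn)) + 1
        if self.chrom is not None:
            starts = np.flatnonzero(self.chrom[1:] != self.chrom[:-1]) + 1
            change = np.setdiff1d(change, starts)
        return change


@dataclass(frozen=True)
class BarcodeSet:
    """A named set of equal-length DNA barcodes."""

    names: tuple[str, ...]
    sequences: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.names) != len(self.sequences):
            raise ValueError("names and sequences must have equal length")
        if len(set(self.names)) != len(self.names):
            raise ValueError("barcode names must be unique")
        if self.sequences:
            L = len(self.sequences[0])
            for s in self.sequences:
                if len(s) != L:
                    raise ValueError("all barcode sequences must have equal length")
                if set(s) - set("ACGT"):
                    raise ValueError(f"barcode {s!r} contains non-ACGT characters")

    def __len__(self) -> int:
        return len(self.names)

    @property
    def length(self) -> int:
        if not self.sequences:
            raise ValueError("empty barcode set has no length")
        return len(self.sequences[0])

    def items(self):
        return zip(self.names, self.sequences)


#: The five 24-nt native barcodes used for multiplexed runs (ONT BC01-BC05).
ONT_BARCODES = BarcodeSet(
    names=("BC01", "BC02", "BC03", "BC04", "BC05"),
    sequences=(
        "AAGAAAGTTGTCGGTGTCTTTGTG",
        "TCGATTCCGTTTGTAGTCGTCTGT",
        "GAGTCTTGTGTCCCAGTTACCAGG",
        "TTCGGATTCTATCGTGTTTCCCTA",
        "CTTGTCCAGGGTTTGTGTAACCTT",
    ),
)


def _sample_lengths(rng: np.random.Generator, n: int, params: RunSimParams) -> np.ndarray:
    """Log-normal read lengths parameterized by median, truncated from below."""
    if params.length_log_sd == 0:
        return np.full(n, params.median_bp)
    mu = math.log(params.median_bp)
    lengths = rng.lognormal(mean=mu, sigma=params.length_log_sd, size=n)
    return np.maximum(lengths, params.min_length_bp)


def simulate_run(params: RunSimParams) -> pd.DataFrame:
    """Simulate a sequencing run; returns a per-read run-summary table.

    Each (channel, pore) alternates vacancy gaps and reads until the run ends
    or the channel dies.  A read's duration is its length divided by the
    translocation speed, so shorter libraries turn over molecules faster and
    yield more reads in the same wall time.

    Returns a DataFrame with columns ``read_id, channel, mux, start_time,
    duration, length, mean_q, passed``; within one (channel, mux) reads never
    overlap in time and ``start_time + duration <= run_duration`` always.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)

    T = params.run_duration
    rows_channel: list[np.ndarray] = []
    rows_mux: list[np.ndarray] = []
    rows_start: list[np.ndarray] = []
    rows_len: list[np.ndarray] = []

    hazard_per_s = params.channel_death_hazard * params.loading_factor / _HOUR
    eff_vacancy = params.mean_vacancy / params.loading_factor

    for ch in range(1, params.n_channels + 1):
        if hazard_per_s > 0:
            death = rng.exponential(1.0 / hazard_per_s)
        else:
            death = math.inf
        horizon = min(T, death)
        for mux in range(1, params.pores_per_channel + 1):
            t = 0.0
            starts: list[float] = []
            lens: list[float] = []
            # draw in blocks to limit Python-level looping
            while t < horizon:
                block = max(16, int(horizon / max(eff_vacancy + params.median_bp / params.speed, 1e-9) * 1.2) + 8)
                block = min(block, 65536)
                if params.vacancy_model == "fixed":
                    gaps = np.full(block, eff_vacancy)
                else:
                    gaps = rng.exponential(eff_vacancy, size=block)
                lengths = _sample_lengths(rng, block, params)
                durs = lengths / params.speed
                ends = t + np.cumsum(gaps + durs)
                begins = ends - durs
                ok = ends <= horizon
                n_ok = int(np.count_nonzero(ok))
                starts.extend(begins[:n_ok])
                lens.extend(lengths[:n_ok])
                if n_ok < block:
                    t = horizon  # first read crossing the horizon ends the pore
                else:
                    t = ends[-1]
            if starts:
                n = len(starts)
                rows_channel.append(np.full(n, ch))
                rows_mux.append(np.full(n, mux))
                rows_start.append(np.asarray(starts))
                rows_len.append(np.asarray(lens))

    if not rows_start:
        return _empty_run_summary()

    channel = np.concatenate(rows_channel)
    mux = np.concatenate(rows_mux)
    start = np.concatenate(rows_start)
    length = np.concatenate(rows_len)
    n = len(start)
    q = rng.normal(params.mean_q, params.q_sd, size=n)
    df = pd.DataFrame(
        {
            "read_id": [f"read-{i:07d}" for i in range(n)],
            "channel": channel.astype(int),
            "mux": mux.astype(int),
            "start_time": start,
            "duration": length / params.speed,
            "length": np.round(length).astype(int).clip(min=1),
            "mean_q": q,
            "passed": q >= params.pass_q,
        }
    )
    return df.sort_values(["channel", "mux", "start_time"], ignore_index=True)


def _empty_run_summary() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "read_id": pd.Series(dtype=str),
            "channel": pd.Series(dtype=int),
            "mux": pd.Series(dtype=int),
            "start_time": pd.Series(dtype=float),
            "duration": pd.Series(dtype=float),
            "length": pd.Series(dtype=int),
            "mean_q": pd.Series(dtype=float),
            "passed": pd.Series(dtype=bool),
        }
    )


def simulate_cn_profile(
    n_bins: int,
    events: list[tuple[int, int, int]] | None = None,
    baseline_cn: int = 2,
    seed: int | None = None,
    n_random_events: int = 0,
    cn_choices: tuple[int, ...] = (0, 1, 3, 4),
    chrom: np.ndarray | None = None,
) -> SimTruth:
    """Build an integer copy-number truth vector.

    ``events`` are half-open ``(start_bin, end_bin, cn)`` intervals painted
    over a flat ``baseline_cn`` background; overlapping events are rejected.
    Alternatively ``n_random_events`` non-overlapping events are drawn from a
    seeded generator.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if events is not None and n_random_events:
        raise ValueError("give either explicit events or n_random_events, not both")

    if events is None and n_random_events:
        rng = np.random.default_rng(seed)
        events = []
        occupied = np.zeros(n_bins, dtype=bool)
        attempts = 0
        while len(events) < n_random_events and attempts < 1000:
            attempts += 1
            width = int(rng.integers(max(5, n_bins // 50), max(6, n_bins // 10)))
            start = int(rng.integers(0, max(1, n_bins - width)))
            end = start + width
            if occupied[start:end].any():
                continue
            occupied[start:end] = True
            events.append((start, end, int(rng.choice(cn_choices))))
        events.sort()
    events = list(events or [])

    cn = np.full(n_bins, baseline_cn, dtype=int)
    painted = np.zeros(n_bins, dtype=bool)
    for start, end, value in events:
        if not (0 <= start < end <= n_bins):
            raise ValueError(f"event ({start}, {end}) outside [0, {n_bins})")
        if value < 0:
            raise ValueError("event copy number must be >= 0")
        if painted[start:end].any():
            raise ValueError(f"event ({start}, {end}) overlaps a previous event")
        painted[start:end] = True
        cn[start:end] = value
    return SimTruth(n_bins=n_bins, cn=cn, events=events, baseline_cn=baseline_cn, chrom=chrom)


def standard_complex_truth(n_bins: int = 5000, n_chroms: int = 20) -> SimTruth:
    """The package's standard complex-karyotype truth.

    A 5000-bin genome split into 20 equal chromosomes, with deterministic
    deletion and gain events: 30% of bins at CN 1, 10% at CN 4, the remainder
    at the diploid baseline — the bin-fraction structure of a complex
    karyotype with whole-chromosome, arm-level and focal events.
    """
    if n_bins % n_chroms:
        raise ValueError("n_bins must be divisible by n_chroms")
    size = n_bins // n_chroms
    chrom = np.repeat([f"chr{i + 1}" for i in range(n_chroms)], size)

    def ev(c, lo, hi, cn):  # chromosome-relative, fractions of chromosome size
        return (c * size + int(lo * size), c * size + int(hi * size), cn)

    events = [
        # deletions, CN 1 — 30% of bins
        ev(0, 0.20, 0.80, 1),
        ev(2, 0.00, 1.00, 1),
        ev(4, 0.00, 0.40, 1),
        ev(6, 0.24, 1.00, 1),
        ev(8, 0.00, 1.00, 1),
        ev(10, 0.40, 1.00, 1),
        ev(12, 0.00, 0.64, 1),
        ev(14, 0.20, 1.00, 1),
        ev(16, 0.20, 0.40, 1),
        # gains, CN 4 — 10% of bins
        ev(1, 0.20, 0.60, 4),
        ev(5, 0.20, 0.32, 4),
        ev(9, 0.20, 0.68, 4),
        ev(13, 0.20, 0.60, 4),
        ev(17, 0.20, 0.80, 4),
    ]
    truth = simulate_cn_profile(n_bins, events=events, baseline_cn=2, chrom=chrom)
    assert int((truth.cn == 1).sum()) == int(0.30 * n_bins)
    assert int((truth.cn == 4).sum()) == int(0.10 * n_bins)
    return truth


def _gc_bias(gc: np.ndarray, strength: float) -> np.ndarray:
    """Unimodal quadratic bias peaking at 45% GC, as in amplified libraries."""
    bias = 1.0 - strength * (gc - 0.45) ** 2 / 0.25**2
    return np.clip(bias, 0.05, None)


def simulate_bin_counts(
    truth: SimTruth,
    total_reads: int,
    gc: np.ndarray | None = None,
    gc_bias_strength: float = 0.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Draw per-bin read counts from a copy-number truth.

    Counts are multinomial with bin probability proportional to
    ``effective_cn * bias(gc)``, so the total is conserved exactly.  Returns a
    DataFrame with columns ``chrom, bin, gc, count``.
    """
    if total_reads < 0:
        raise ValueError("total_reads must be >= 0")
    n = truth.n_bins
    if gc is not None:
        gc = np.asarray(gc, dtype=float)
        if len(gc) != n:
            raise ValueError("gc must be aligned to n_bins")
    weights = truth.effective_cn.astype(float)
    if gc is not None and gc_bias_strength:
        weights = weights * _gc_bias(gc, gc_bias_strength)
    if weights.sum() <= 0:
        # all-zero copy number: no reads can map anywhere
        counts = np.zeros(n, dtype=int)
        if total_reads:
            raise ValueError("cannot place reads on an all-zero copy profile")
    else:
        rng = np.random.default_rng(seed)
        counts = rng.multinomial(total_reads, weights / weights.sum())
    return pd.DataFrame(
        {
            "chrom": truth.chrom if truth.chrom is not None else np.repeat("chr1", n),
            "bin": np.arange(n),
            "gc": gc if gc is not None else np.full(n, np.nan),
            "count": counts,
        }
    )


_OTHER = {
    "A": np.array(list("CGT")),
    "C": np.array(list("AGT")),
    "G": np.array(list("ACT")),
    "T": np.array(list("ACG")),
}


def simulate_barcoded_reads(
    barcodes: BarcodeSet,
    n_per_sample: int,
    sub_error_rate: float = 0.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Emit barcode reads with iid per-base substitutions and true labels.

    Returns a balanced DataFrame (``n_per_sample`` rows per barcode) with
    columns ``read_id, true_barcode, sequence``.
    """
    if len(barcodes) == 0:
        raise ValueError("empty barcode set")
    if not 0.0 <= sub_error_rate < 1.0:
        raise ValueError("sub_error_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    L = barcodes.length
    rows = []
    for name, seq in barcodes.items():
        base = np.array(list(seq))
        for i in range(n_per_sample):
            read = base.copy()
            if sub_error_rate:
                hits = np.flatnonzero(rng.random(L) < sub_error_rate)
                for pos in hits:
                    read[pos] = rng.choice(_OTHER[base[pos]])
            rows.append((f"{name}-{i:05d}", name, "".join(read)))
    return pd.DataFrame(rows, columns=["read_id", "true_barcode", "sequence"])


# ---------------------------------------------------------------------------
# text-format writers (ONT sequencing-summary dialect, truth JSON, counts TSV)

_SUMMARY_COLS = {
    "read_id": "read_id",
    "channel": "channel",
    "mux": "mux",
    "start_time": "start_time",
    "duration": "duration",
    "length": "sequence_length_template",
    "mean_q": "mean_qscore_template",
    "passed": "passes_filtering",
    "barcode": "barcode_arrangement",
}


def write_sequencing_summary(summary: pd.DataFrame, path) -> None:
    """Write a run summary as an ONT-dialect sequencing_summary TSV."""
    out = summary.rename(columns=_SUMMARY_COLS)
    cols = [c for c in _SUMMARY_COLS.values() if c in out.columns]
    out[cols].to_csv(path, sep="\t", index=False)


def write_truth_json(truth: SimTruth, path) -> None:
    import json

    payload = {
        "n_bins": truth.n_bins,
        "baseline_cn": truth.baseline_cn,
        "purity": truth.purity,
        "events": [list(e) for e in truth.events],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def write_bin_counts_tsv(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index=False)
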