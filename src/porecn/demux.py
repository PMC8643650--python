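"""Barcode distance computation and demultiplexing for pooled runs.

Multiplexed libraries carry one of a set of sample barcodes at the read 5'
end.  The barcode sets used for pooled nanopore runs are designed with a
minimum pairwise Hamming distance of at least 10 between 24-nt sequences, so
a nearest-barcode rule with a maximum accepted distance of
floor((d_min - 1) / 2) = 4 can never mis-assign a read whose barcode carries
at most 4 substitution errors — a perfect-code argument.  Reads with no
barcode within the accepted distance, or tied between two barcodes, stay
unclassified.  Substitutions only; indel-tolerant matching is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .sim import BarcodeSet

__all__ = [
    "hamming",
    "min_pairwise_distance",
    "BarcodeDemultiplexer",
    "DemuxResult",
    "demultiplex",
    "read_barcodes",
]

UNCLASSIFIED = "unclassified"


def hamming(a: str, b: str) -> int:
    """Number of mismatching positions between two equal-length sequences."""
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    return sum(x != y for x, y in zip(a, b))


def min_pairwise_distance(barcodes: BarcodeSet) -> int:
    """Minimum Hamming distance over all unordered barcode pairs."""
    seqs = list(barcodes.sequences)
    if len(seqs) < 2:
        raise ValueError("need at least two barcodes")
    best = len(seqs[0])
    for i in range(len(seqs)):
        for j in range(i + 1, len(seqs)):
            best = min(best, hamming(seqs[i], seqs[j]))
    return best


def _encode(seqs, length: int, offset: int = 0) -> np.ndarray:
    """Byte-encode the [offset, offset+length) window of each sequence."""
    arr = np.zeros((len(seqs), length), dtype=np.uint8)
    for k, s in enumerate(seqs):
        window = s[offset : offset + length]
        arr[k, : len(window)] = np.frombuffer(window.encode("ascii"), dtype=np.uint8)
    return arr


@dataclass
class DemuxResult:
    """Per-read assignments plus per-sample accounting.

    ``assignments`` has columns ``read_id, assignment, distance``; ``counts``
    maps each barcode name (plus ``unclassified``) to its read count, and
    ``fractions`` to its share of all input reads (fractions sum to 1).
    """

    assignments: pd.DataFrame
    counts: dict[str, int]
    fractions: dict[str, float]

    @property
    def n_reads(self) -> int:
        return len(self.assignments)

    @property
    def assigned_fraction(self) -> float:
        return 1.0 - self.fractions.get(UNCLASSIFIED, 0.0)


class BarcodeDemultiplexer(BaseEstimator):
    """Nearest-barcode-by-Hamming classifier over read prefixes.

    Fit stores the byte-encoded barcode matrix; ``predict`` assigns each read
    to the unique barcode within ``max_dist`` mismatches of the window at
    ``offset`` from the read 5' end, or ``"unclassified"`` on ties, distant
    matches, or too-short reads.

    Parameters
    ----------
    barcodes : BarcodeSet
        The sample barcodes; must be non-empty and of equal length.
    max_dist : int, default 4
        Maximum accepted Hamming distance.  The default equals
        floor((10 - 1)/2), the largest radius at which a >=10-separated set
        guarantees unambiguous assignment.
    offset : int, default 0
        Where the barcode window starts in each read (0 = untrimmed 5' end).
    """

    def __init__(self, barcodes: BarcodeSet | None = None, max_dist: int = 4,
                 offset: int = 0):
        self.barcodes = barcodes
        self.max_dist = max_dist
        self.offset = offset

    def fit(self, X=None, y=None):
        if self.barcodes is None or len(self.barcodes) == 0:
            raise ValueError("a non-empty BarcodeSet is required")
        if self.max_dist < 0:
            raise ValueError("max_dist must be >= 0")
        self.length_ = self.barcodes.length
        self.names_ = np.asarray(self.barcodes.names)
        self.matrix_ = _encode(self.barcodes.sequences, self.length_)
        return self

    def _distances(self, reads) -> np.ndarray:
        enc = _encode(reads, self.length_, self.offset)
        # (n_reads, n_barcodes): mismatches within the barcode window
        return (enc[:, None, :] != self.matrix_[None, :, :]).sum(axis=2)

    def predict(self, reads) -> np.ndarray:
        """Barcode name per read, or ``"unclassified"``."""
        if not hasattr(self, "matrix_"):
            self.fit()
        reads = list(reads)
        if not reads:
            return np.array([], dtype=object)
        dist = self._distances(reads)
        best = dist.min(axis=1)
        ties = (dist == best[:, None]).sum(axis=1) > 1
        too_short = np.array(
            [len(r) < self.offset + self.length_ for r in reads], dtype=bool
        )
        labels = self.names_[dist.argmin(axis=1)].astype(object)
        labels[(best > self.max_dist) | ties | too_short] = UNCLASSIFIED
        return labels

    def predict_distance(self, reads) -> tuple[np.ndarray, np.ndarray]:
        """(labels, best distances) per read."""
        if not hasattr(self, "matrix_"):
            self.fit()
        reads = list(reads)
        labels = self.predict(reads)
        dist = self._distances(reads).min(axis=1) if reads else np.array([], dtype=int)
        return labels, dist


def demultiplex(
    reads,
    barcodes: BarcodeSet,
    max_dist: int = 4,
    offset: int = 0,
    read_ids=None,
) -> DemuxResult:
    """Assign pooled reads to sample barcodes; thin wrapper over the estimator.

    ``reads`` is a sequence of strings or a DataFrame with ``sequence`` (and
    optionally ``read_id``) columns.  Conservation holds by construction:
    per-sample counts plus unclassified equal the number of input reads.
    """
    if isinstance(reads, pd.DataFrame):
        if read_ids is None and "read_id" in reads.columns:
            read_ids = reads["read_id"].to_numpy()
        reads = reads["sequence"].tolist()
    else:
        reads = list(reads)
    if read_ids is None:
        read_ids = [f"read-{i}" for i in range(len(reads))]

    est = BarcodeDemultiplexer(barcodes, max_dist=max_dist, offset=offset).fit()
    labels, dist = est.predict_distance(reads)
    assignments = pd.DataFrame(
        {"read_id": read_ids, "assignment": labels, "distance": dist}
    )
    names = list(barcodes.names) + [UNCLASSIFIED]
    counts = {name: int((labels == name).sum()) for name in names}
    total = max(1, len(reads))
    fractions = {name: counts[name] / total for name in names}
    return DemuxResult(assignments=assignments, counts=counts, fractions=fractions)


def read_barcodes(path) -> BarcodeSet:
    """Load barcodes from FASTA or a 2-column (name, sequence) TSV."""
    path = str(path)
    names: list[str] = []
    seqs: list[str] = []
    with open(path) as fh:
        first = fh.read(1)
    if first == ">":
        from Bio import SeqIO

        for rec in SeqIO.parse(path, "fasta"):
            names.append(rec.id)
            seqs.append(str(rec.seq).upper())
    else:
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
        names = df.iloc[:, 0].astype(str).tolist()
        seqs = df.iloc[:, 1].astype(str).str.upper().tolist()
    return BarcodeSet(names=tuple(names), sequences=tuple(seqs))
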