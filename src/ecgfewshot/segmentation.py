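"""Beat segmentation and QRS extraction.

Records are cut at the midpoints between consecutive R-peaks; the first
and last (edge) segments are removed, and each retained segment is
resampled per lead to exactly 100 samples by linear interpolation. Each
beat carries BPM and resampling-ratio metadata derived from its own
pre-resampling segment length: ``bpm = 60 * fs / L`` and
``ratio = L / 100``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .consensus import ConsensusRPeaks
from .records import N_LEADS, MultiLeadRecord

QRS_SAMPLES = 100

__all__ = [
    "QRS_SAMPLES",
    "QRSComplex",
    "QRSSet",
    "segment_boundaries",
    "extract_qrs",
    "write_qrs_archive",
    "read_qrs_archive",
]


@dataclass
class QRSComplex:
    """One beat: a 12 x 100 resampled segment plus per-beat metadata."""

    samples: np.ndarray
    bpm: float
    resample_ratio: float
    source_record: str
    beat_index: int

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.shape != (N_LEADS, QRS_SAMPLES):
            raise ValueError(
                f"QRS complex must be {N_LEADS} x {QRS_SAMPLES}, got {self.samples.shape}"
            )
        if not self.bpm > 0 or not self.resample_ratio > 0:
            raise ValueError("bpm and resample_ratio must be > 0")


@dataclass
class QRSSet:
    """The ordered beats of one record, with labels carried over."""

    complexes: list[QRSComplex]
    record_id: str
    superclass: str | None = None
    subclass: str | None = None

    def __post_init__(self) -> None:
        if not self.complexes:
            raise ValueError("QRSSet must contain at least one beat")
        if any(q.source_record != self.record_id for q in self.complexes):
            raise ValueError("all beats must come from the same record")

    def __len__(self) -> int:
        return len(self.complexes)

    def stacked(self) -> np.ndarray:
        """All beats as an (n, 12, 100) array."""
        return np.stack([q.samples for q in self.complexes])


def segment_boundaries(
    rpeaks: np.ndarray, record_length: int
) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    """Cut a record at midpoints between consecutive R-peaks.

    Returns ``(all_intervals, retained)``: half-open intervals partitioning
    ``[0, record_length)``, and the interior intervals that survive removal
    of the first and last (edge) segments. Cut points are
    ``floor((r_i + r_{i+1}) / 2)``.
    """
    rpeaks = np.asarray(rpeaks, dtype=int)
    if rpeaks.size < 3:
        raise ValueError("need at least 3 R-peaks for one interior segment")
    cuts = (rpeaks[:-1] + rpeaks[1:]) // 2
    edges = np.concatenate([[0], cuts, [record_length]])
    intervals = [(int(a), int(b)) for a, b in zip(edges[:-1], edges[1:])]
    return intervals, intervals[1:-1]


def _resample_linear(segment: np.ndarray, n_out: int = QRS_SAMPLES) -> np.ndarray:
    """Linearly resample each lead of an (12, L) segment to ``n_out`` points.

    When ``L == n_out`` the grid points are exactly the original samples,
    so resampling is the identity map.
    """
    L = segment.shape[1]
    x_new = np.linspace(0.0, L - 1, n_out)
    x_old = np.arange(L)
    return np.stack([np.interp(x_new, x_old, lead) for lead in segment])


def extract_qrs(
    record: MultiLeadRecord, rpeaks: ConsensusRPeaks | np.ndarray
) -> QRSSet:
    """Extract the record's interior beats as resampled QRS complexes.

    The number of extracted beats equals ``len(peaks) - 2``.
    """
    peaks = rpeaks.peaks if isinstance(rpeaks, ConsensusRPeaks) else np.asarray(rpeaks)
    _, retained = segment_boundaries(peaks, record.n_samples)
    complexes = []
    for i, (a, b) in enumerate(retained):
        L = b - a
        complexes.append(
            QRSComplex(
                samples=_resample_linear(record.signal[:, a:b]),
                bpm=60.0 * record.fs / L,
                resample_ratio=L / QRS_SAMPLES,
                source_record=record.record_id,
                beat_index=i,
            )
        )
    return QRSSet(
        complexes=complexes,
        record_id=record.record_id,
        superclass=record.superclass,
        subclass=record.subclass,
    )


def write_qrs_archive(path, qrs_set: QRSSet) -> None:
    """One-record QRS archive: the stacked beats plus per-beat metadata."""
    np.savez(
        path,
        samples=qrs_set.stacked(),
        bpm=np.array([q.bpm for q in qrs_set.complexes]),
        resample_ratio=np.array([q.resample_ratio for q in qrs_set.complexes]),
        record_id=np.array(qrs_set.record_id),
        superclass=np.array(qrs_set.superclass or ""),
        subclass=np.array(qrs_set.subclass or ""),
    )


def read_qrs_archive(path) -> QRSSet:
    with np.load(path, allow_pickle=False) as data:
        rid = str(data["record_id"])
        complexes = [
            QRSComplex(
                samples=s, bpm=float(b), resample_ratio=float(r),
                source_record=rid, beat_index=i,
            )
            for i, (s, b, r) in enumerate(
                zip(data["samples"], data["bpm"], data["resample_ratio"])
            )
        ]
        return QRSSet(
            complexes=complexes,
            record_id=rid,
            superclass=str(data["superclass"]) or None,
            subclass=str(data["subclass"]) or None,
        )
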