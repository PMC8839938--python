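"""Consensus R-peak labeling across detectors and leads.

No single-lead detector is reliable on every record, so candidates from
each (detector, lead) stream are pooled and reconciled by one-dimensional
k-means clustering over sample positions:

* k is the rounded median of candidate counts over non-empty streams,
* centers are initialized at the k evenly spaced quantiles of the sorted
  pool (deterministic; no random restarts),
* cluster members farther than half the refractory period from their
  cluster's median are spurious (a stream's isolated extra detection that
  merged into a neighboring beat's cluster) and are dropped,
* clusters supported by fewer than ``support_frac`` of the non-empty
  streams are discarded,
* surviving centers are rounded to integer samples and centers closer than
  the refractory period are merged, keeping the higher-support one.

The result is deterministic and invariant to detector/lead ordering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .detectors import DETECTOR_NAMES, detect
from .records import N_LEADS, MultiLeadRecord

__all__ = ["CandidateSet", "ConsensusRPeaks", "detect_candidates", "consensus_rpeaks"]


@dataclass
class CandidateSet:
    """Per-(detector, lead) candidate R-peak sample indices."""

    candidates: dict[tuple[str, int], np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for (name, lead), idx in self.candidates.items():
            idx = np.asarray(idx, dtype=int)
            if not 0 <= lead < N_LEADS:
                raise ValueError(f"lead index {lead} outside [0, {N_LEADS})")
            if idx.size > 1 and np.any(np.diff(idx) <= 0):
                raise ValueError(f"candidates for ({name}, {lead}) not strictly increasing")
            self.candidates[(name, lead)] = idx

    def streams(self) -> list[np.ndarray]:
        """Non-empty candidate lists, in a canonical (sorted-key) order."""
        return [
            self.candidates[k]
            for k in sorted(self.candidates)
            if self.candidates[k].size > 0
        ]


@dataclass
class ConsensusRPeaks:
    """Consensus peak positions and their per-peak stream support."""

    peaks: np.ndarray
    support: np.ndarray

    def __post_init__(self) -> None:
        self.peaks = np.asarray(self.peaks, dtype=int)
        self.support = np.asarray(self.support, dtype=int)
        if self.peaks.size > 1 and np.any(np.diff(self.peaks) <= 0):
            raise ValueError("consensus peaks must be strictly increasing")


def detect_candidates(
    record: MultiLeadRecord,
    detectors: tuple[str, ...] = DETECTOR_NAMES,
) -> CandidateSet:
    """Run each named detector on each of the 12 leads."""
    if not detectors:
        raise ValueError("need at least one detector")
    if record.duration < 2.0:
        raise ValueError("record shorter than 2 s")
    out = {}
    for name in detectors:
        for lead in range(N_LEADS):
            out[(name, lead)] = detect(name, record.signal[lead], record.fs)
    return CandidateSet(out)


def _kmeans_1d(pool: np.ndarray, k: int, max_iter: int = 100) -> np.ndarray:
    """Lloyd's algorithm on sorted 1-D data with quantile initialization.

    Returns cluster labels aligned with the (sorted) pool.
    """
    qs = (np.arange(k) + 0.5) / k
    centers = np.quantile(pool, qs)
    labels = np.zeros(len(pool), dtype=int)
    for it in range(max_iter):
        # nearest center assignment; centers stay sorted in 1-D Lloyd steps
        d = np.abs(pool[:, None] - centers[None, :])
        new_labels = np.argmin(d, axis=1)
        if it > 0 and np.array_equal(new_labels, labels):
            break
        labels = new_labels
        for c in range(k):
            members = pool[labels == c]
            if members.size:
                centers[c] = members.mean()
    return labels


def consensus_rpeaks(
    candidates: CandidateSet,
    fs: float,
    refractory: float = 0.2,
    support_frac: float = 0.5,
) -> ConsensusRPeaks:
    """Reconcile pooled candidates into consensus peaks via 1-D k-means."""
    streams = candidates.streams()
    if not streams:
        raise ValueError("all candidate lists are empty")
    n_streams = len(streams)
    k = int(round(float(np.median([len(s) for s in streams]))))
    k = max(1, k)

    pool = np.concatenate(streams).astype(float)
    stream_of = np.concatenate([np.full(len(s), i) for i, s in enumerate(streams)])
    order = np.argsort(pool, kind="stable")
    pool, stream_of = pool[order], stream_of[order]
    k = min(k, len(pool))

    labels = _kmeans_1d(pool, k)

    trim = 0.5 * refractory * fs
    centers, supports = [], []
    for c in range(k):
        mask = labels == c
        if not mask.any():
            continue
        members = pool[mask]
        inlier = np.abs(members - np.median(members)) <= trim
        members, who = members[inlier], stream_of[mask][inlier]
        support = len(np.unique(who))
        if support < support_frac * n_streams:
            continue
        centers.append(int(round(members.mean())))
        supports.append(support)

    if not centers:
        return ConsensusRPeaks(np.asarray([], dtype=int), np.asarray([], dtype=int))

    order = np.argsort(centers)
    centers = np.asarray(centers)[order]
    supports = np.asarray(supports)[order]

    # merge centers within the refractory period, keeping the higher support
    min_gap = refractory * fs
    keep_c, keep_s = [centers[0]], [supports[0]]
    for c, s in zip(centers[1:], supports[1:]):
        if c - keep_c[-1] <= min_gap:
            if s > keep_s[-1]:
                keep_c[-1], keep_s[-1] = c, s
        else:
            keep_c.append(c)
            keep_s.append(s)
    return ConsensusRPeaks(np.asarray(keep_c), np.asarray(keep_s))
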