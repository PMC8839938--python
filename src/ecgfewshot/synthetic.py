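"""Synthetic 12-lead ECG generation with known R-peak ground truth.

Each beat is a sum of five Gaussian bumps (P, Q, R, S, T) placed relative
to the R peak, scaled per lead, on top of optional white noise. This is a
fixture model of the PQRST cycle — closed-form ground truth for exercising
detectors, segmentation and classifiers — not a physiological simulator.

Reproducibility: per-record RNG streams are spawned from a root seed by
record index, so datasets are reproducible element-wise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .records import N_LEADS, MultiLeadRecord

__all__ = [
    "MorphologyParams",
    "SyntheticClassSpec",
    "generate_record",
    "generate_dataset",
    "default_class_specs",
]

WAVES = ("P", "Q", "R", "S", "T")


def _default_lead_scale() -> np.ndarray:
    # Rough relative projection of the cardiac vector onto the 12 leads;
    # lead II (index 1) carries the largest R deflection.
    return np.array(
        [0.7, 1.0, 0.4, -0.5, 0.25, 0.8, -0.3, 0.5, 0.7, 0.9, 0.85, 0.75]
    )


@dataclass
class MorphologyParams:
    """Per-wave Gaussian bump parameters and per-lead scaling.

    ``amplitudes`` are in millivolts, ``offsets`` are wave-center offsets in
    seconds relative to the R peak, ``widths`` are Gaussian sigmas in
    seconds. ``lead_scale`` multiplies the whole beat per lead.
    """

    amplitudes: dict[str, float] = field(
        default_factory=lambda: {"P": 0.15, "Q": -0.1, "R": 1.2, "S": -0.25, "T": 0.35}
    )
    offsets: dict[str, float] = field(
        default_factory=lambda: {"P": -0.18, "Q": -0.035, "R": 0.0, "S": 0.035, "T": 0.30}
    )
    widths: dict[str, float] = field(
        default_factory=lambda: {"P": 0.025, "Q": 0.010, "R": 0.012, "S": 0.012, "T": 0.06}
    )
    lead_scale: np.ndarray = field(default_factory=_default_lead_scale)

    def __post_init__(self) -> None:
        self.lead_scale = np.asarray(self.lead_scale, dtype=float)
        if self.lead_scale.shape != (N_LEADS,):
            raise ValueError(f"lead_scale must have length {N_LEADS}")
        for w in WAVES:
            if not self.widths[w] > 0:
                raise ValueError(f"width of wave {w} must be > 0")
        # R must dominate on at least one lead so the R peak is the beat's extremum
        r = max(abs(self.amplitudes["R"] * self.lead_scale))
        others = max(
            abs(self.amplitudes[w] * s)
            for w in WAVES if w != "R"
            for s in self.lead_scale
        )
        if r <= others:
            raise ValueError("R amplitude must dominate on at least one lead")


@dataclass
class SyntheticClassSpec:
    """One synthetic class: morphology, heart-rate range and noise level."""

    label: str
    morphology: MorphologyParams = field(default_factory=MorphologyParams)
    bpm_range: tuple[float, float] = (55.0, 65.0)
    noise_sd: float = 0.02  # millivolts

    def __post_init__(self) -> None:
        lo, hi = self.bpm_range
        if not (20.0 < lo <= hi < 250.0):
            raise ValueError(f"bpm_range {self.bpm_range} outside (20, 250)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def generate_record(
    spec: SyntheticClassSpec,
    duration: float = 10.0,
    fs: float = 500.0,
    seed: int | np.random.SeedSequence = 0,
    record_id: str | None = None,
) -> MultiLeadRecord:
    """Generate one 12-lead record with ground-truth R-peak positions.

    Beat-to-beat RR intervals are drawn uniformly from the BPM range (a
    degenerate range gives an exactly constant rate). The first beat is
    placed half an RR interval into the record and beats are laid down
    until one refractory period (0.2 s) before the record ends, so no
    ground-truth beat is half-truncated at the boundary. The same seed
    gives bit-identical output.
    """
    rng = np.random.default_rng(seed)
    lo, hi = spec.bpm_range
    if duration < 3 * 60.0 / lo:
        raise ValueError(
            f"duration {duration}s holds fewer than 3 beats at {lo} BPM"
        )
    n_samples = int(round(duration * fs))

    beat_times = []
    t = 0.5 * 60.0 / rng.uniform(lo, hi) if lo != hi else 0.5 * 60.0 / lo
    while t < duration - 0.2:
        beat_times.append(t)
        bpm = rng.uniform(lo, hi) if lo != hi else lo
        t += 60.0 / bpm
    beat_times = np.asarray(beat_times)

    time = np.arange(n_samples) / fs
    template = np.zeros(n_samples)
    m = spec.morphology
    for tb in beat_times:
        for w in WAVES:
            c, sd, a = tb + m.offsets[w], m.widths[w], m.amplitudes[w]
            # evaluate only within ±5 sigma of the bump center
            i0 = max(0, int((c - 5 * sd) * fs))
            i1 = min(n_samples, int((c + 5 * sd) * fs) + 1)
            template[i0:i1] += a * np.exp(-0.5 * ((time[i0:i1] - c) / sd) ** 2)

    signal = m.lead_scale[:, None] * template[None, :]
    if spec.noise_sd > 0:
        signal = signal + rng.normal(0.0, spec.noise_sd, size=signal.shape)

    rpeaks = np.round(beat_times * fs).astype(int)
    rpeaks = rpeaks[rpeaks < n_samples]
    return MultiLeadRecord(
        record_id=record_id or f"synthetic-{spec.label}",
        signal=signal,
        fs=fs,
        superclass=spec.label,
        truth_rpeaks=rpeaks,
    )


def generate_dataset(
    specs: list[SyntheticClassSpec],
    n_per_class: int,
    duration: float = 10.0,
    fs: float = 500.0,
    seed: int = 0,
) -> list[MultiLeadRecord]:
    """Generate ``n_per_class`` labeled records per class spec.

    Per-record seeds are spawned deterministically from the root seed, so
    record ``i`` is identical regardless of how many records follow it.
    """
    if not specs:
        raise ValueError("need at least one class spec")
    children = np.random.SeedSequence(seed).spawn(len(specs) * n_per_class)
    out = []
    for i, spec in enumerate(specs):
        for j in range(n_per_class):
            idx = i * n_per_class + j
            out.append(
                generate_record(
                    spec, duration, fs, seed=children[idx],
                    record_id=f"syn-{spec.label}-{j:04d}",
                )
            )
    return out


def default_class_specs(
    n_classes: int = 2,
    noise_sd: float = 0.02,
    bpm_range: tuple[float, float] = (55.0, 75.0),
) -> list[SyntheticClassSpec]:
    """Class specs separated by waveform morphology, not heart rate.

    All classes share one BPM range so their per-record beat counts
    overlap — a requirement of homogeneous-cardinality triplet batching,
    where every triplet mixes classes at a fixed QRS count. Classes differ
    in R/T/P amplitudes, T width and S depth (disjoint morphologies).
    """
    if not 1 <= n_classes <= 5:
        raise ValueError("supports 1-5 synthetic classes")
    bases = [
        ("classA", {"R": 1.2, "T": 0.35, "P": 0.15, "S": -0.25}, {}),
        ("classB", {"R": 0.6, "T": 0.70, "P": 0.05, "S": -0.60}, {"T": 0.09}),
        ("classC", {"R": 1.7, "T": 0.15, "P": 0.28, "S": -0.10}, {"T": 0.04}),
        ("classD", {"R": 0.9, "T": -0.30, "P": 0.15, "S": -0.40}, {}),
        ("classE", {"R": 1.4, "T": 0.50, "P": 0.02, "S": -0.05}, {"P": 0.04}),
    ]
    specs = []
    for label, amps, widths in bases[:n_classes]:
        morph = MorphologyParams()
        morph.amplitudes.update(amps)
        morph.widths.update(widths)
        specs.append(
            SyntheticClassSpec(
                label=label, morphology=morph, bpm_range=bpm_range, noise_sd=noise_sd
            )
        )
    return specs
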