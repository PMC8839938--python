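"""Multi-lead ECG record containers, CSV I/O and the PTB-XL filtering rules.

A record is a 12-lead, uniformly sampled signal in millivolts with an
optional diagnostic superclass/subclass pair and, for synthetic records,
ground-truth R-peak sample positions.

On-disk format: one CSV per record (one row per sample, 12 comma-separated
millivolt columns) plus a JSON sidecar carrying the sampling rate, labels
and truth peaks. Sample indices are 0-based throughout; segments elsewhere
in the package are half-open intervals ``[start, end)``.
"""

from __future__ import annotations

import ast
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

N_LEADS = 12

__all__ = [
    "N_LEADS",
    "MultiLeadRecord",
    "LabelCatalog",
    "read_record",
    "write_record",
    "filter_ptbxl",
]


@dataclass
class MultiLeadRecord:
    """A 12-lead ECG signal with metadata.

    Parameters
    ----------
    record_id : str
        Unique identifier of the record.
    signal : ndarray of shape (12, n_samples)
        Lead-by-sample signal in millivolts.
    fs : float
        Sampling rate in Hz, strictly positive.
    superclass, subclass : str, optional
        Diagnostic labels (5-way superclass, 20-way subclass).
    truth_rpeaks : ndarray, optional
        Strictly increasing 0-based R-peak sample indices; populated only
        for synthetic records where the ground truth is known.
    """

    record_id: str
    signal: np.ndarray
    fs: float
    superclass: str | None = None
    subclass: str | None = None
    truth_rpeaks: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2 or self.signal.shape[0] != N_LEADS:
            raise ValueError(
                f"record {self.record_id!r}: expected {N_LEADS} leads, "
                f"got signal shape {self.signal.shape}"
            )
        if self.signal.shape[1] < 1:
            raise ValueError(f"record {self.record_id!r}: empty signal")
        if not self.fs > 0:
            raise ValueError(f"record {self.record_id!r}: fs must be > 0, got {self.fs}")
        if self.truth_rpeaks is not None:
            self.truth_rpeaks = np.asarray(self.truth_rpeaks, dtype=int)
            r = self.truth_rpeaks
            if r.size and (np.any(np.diff(r) <= 0) or r[0] < 0 or r[-1] >= self.n_samples):
                raise ValueError(
                    f"record {self.record_id!r}: truth_rpeaks must be strictly "
                    "increasing and within [0, n_samples)"
                )

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration(self) -> float:
        """Record duration in seconds."""
        return self.n_samples / self.fs


@dataclass
class LabelCatalog:
    """Ordered label sets and the subclass → superclass mapping.

    Tie-breaking and one-hot encodings downstream follow catalog order.
    """

    superclasses: list[str]
    subclasses: list[str] = field(default_factory=list)
    subclass_to_superclass: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sub, sup in self.subclass_to_superclass.items():
            if sub not in self.subclasses:
                raise ValueError(f"unknown subclass {sub!r} in mapping")
            if sup not in self.superclasses:
                raise ValueError(f"subclass {sub!r} maps to unknown superclass {sup!r}")
        missing = set(self.subclasses) - set(self.subclass_to_superclass)
        if missing:
            raise ValueError(f"subclasses without a superclass mapping: {sorted(missing)}")

    def superclass_index(self, label: str) -> int:
        return self.superclasses.index(label)


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_record(path: str | Path, record: MultiLeadRecord) -> Path:
    """Write a record as a 12-column CSV plus a JSON metadata sidecar."""
    path = Path(path)
    np.savetxt(path, record.signal.T, delimiter=",", fmt="%.9g")
    meta: dict = {"record_id": record.record_id, "fs": record.fs, "n_leads": N_LEADS}
    if record.superclass is not None:
        meta["superclass"] = record.superclass
    if record.subclass is not None:
        meta["subclass"] = record.subclass
    if record.truth_rpeaks is not None:
        meta["truth_rpeaks"] = [int(i) for i in record.truth_rpeaks]
    _sidecar_path(path).write_text(json.dumps(meta))
    return path


def read_record(path: str | Path, format: str = "csv") -> MultiLeadRecord:
    """Read a record from disk.

    Only the CSV dialect (12-column CSV + JSON sidecar) is supported;
    ``format="wfdb"`` is declared but not implemented in this build.
    """
    if format == "wfdb":
        raise NotImplementedError(
            "WFDB input is not supported in this build; convert to the "
            "12-column CSV + JSON sidecar dialect"
        )
    if format != "csv":
        raise ValueError(f"unknown record format {format!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(f"missing sidecar header {sidecar}")
    meta = json.loads(sidecar.read_text())
    if int(meta.get("n_leads", -1)) != N_LEADS:
        raise ValueError(
            f"{path}: header declares {meta.get('n_leads')} leads, expected {N_LEADS}"
        )
    signal = np.loadtxt(path, delimiter=",", ndmin=2)
    if signal.shape[1] != N_LEADS:
        raise ValueError(f"{path}: expected {N_LEADS} columns, got {signal.shape[1]}")
    return MultiLeadRecord(
        record_id=meta["record_id"],
        signal=signal.T,
        fs=float(meta["fs"]),
        superclass=meta.get("superclass"),
        subclass=meta.get("subclass"),
        truth_rpeaks=meta.get("truth_rpeaks"),
    )


def _parse_codes(value) -> dict[str, float]:
    """Parse a diagnostic-code → confidence mapping.

    Accepts a dict directly or its Python-literal string form, as stored in
    the PTB-XL ``scp_codes`` column.
    """
    if isinstance(value, dict):
        return {str(k): float(v) for k, v in value.items()}
    return {str(k): float(v) for k, v in ast.literal_eval(value).items()}


def filter_ptbxl(
    metadata: pd.DataFrame,
    statements: pd.DataFrame,
    *,
    confidence: float = 100.0,
    min_subclass_size: int = 20,
) -> pd.DataFrame:
    """Apply the PTB-XL record-filtering rules.

    A record survives when it (a) has at least one diagnostic label,
    (b) carries it at full (100%) confidence, (c) resolves to exactly one
    superclass and one subclass, and (d) belongs to a subclass with at
    least ``min_subclass_size`` surviving records. The subclass-size rule
    is applied once, after (a)-(c).

    Parameters
    ----------
    metadata : DataFrame
        Indexed by record id, with an ``scp_codes`` column holding the
        per-record code → confidence mapping (dict or its string form).
    statements : DataFrame
        Indexed by code, with columns ``diagnostic`` (1 for diagnostic
        codes), ``diagnostic_class`` and ``diagnostic_subclass``.

    Returns
    -------
    DataFrame with columns ``record_id``, ``superclass``, ``subclass``.
    """
    for col in ("diagnostic", "diagnostic_class", "diagnostic_subclass"):
        if col not in statements.columns:
            raise ValueError(f"statements table missing required column {col!r}")
    if "scp_codes" not in metadata.columns:
        raise ValueError("metadata table missing required column 'scp_codes'")

    diag = statements[statements["diagnostic"] == 1]
    code_to_sup = diag["diagnostic_class"].to_dict()
    code_to_sub = diag["diagnostic_subclass"].to_dict()

    rows: list[tuple] = []
    for rid, codes in metadata["scp_codes"].items():
        confident = [
            c for c, lik in _parse_codes(codes).items()
            if c in code_to_sup and lik == confidence
        ]
        sups = {code_to_sup[c] for c in confident if pd.notna(code_to_sup[c])}
        subs = {code_to_sub[c] for c in confident if pd.notna(code_to_sub[c])}
        if len(sups) == 1 and len(subs) == 1:
            rows.append((rid, sups.pop(), subs.pop()))

    out = pd.DataFrame(rows, columns=["record_id", "superclass", "subclass"])
    keep = out["subclass"].map(out["subclass"].value_counts()) >= min_subclass_size
    return out[keep].reset_index(drop=True)
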