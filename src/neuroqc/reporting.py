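"""QC report model and JSON/CSV writers.

JSON is the canonical schema; CSV export emits one scalar table plus one tidy
table per named vector.  Reports are pure functions of (inputs, config, seed)
— no timestamps enter the serialised form, so fixed-seed reruns are
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import ValidationError

SCHEMA_VERSION = "1"
REQUIRED_BLOCKS = ("scan_id", "profile", "metrics", "vectors", "verdict", "provenance")


def _jsonable(value):
    if isinstance(value, (np.floating, np.integer)):
        return value.item()
    if isinstance(value, np.ndarray):
        return [None if (isinstance(v, float) and not np.isfinite(v)) else v
                for v in value.astype(float).tolist()]
    if isinstance(value, float) and not np.isfinite(value):
        return None
    return value


@dataclass
class QCReport:
    scan_id: str
    profile: str
    metrics: dict = field(default_factory=dict)   # name -> {value, flag, directionality}
    vectors: dict = field(default_factory=dict)   # name -> list/array
    verdict: dict = field(default_factory=dict)   # CaseDecision-shaped block (may be empty)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.provenance.setdefault("tool_version", __version__)
        self.provenance.setdefault("schema_version", SCHEMA_VERSION)

    def add_metric(self, name: str, value, flag: str = "available",
                   directionality: str | None = None):
        if name in self.metrics:
            raise ValidationError(f"metric {name!r} already present in the report")
        self.metrics[name] = {
            "value": _jsonable(value),
            "flag": flag if value is not None else "unavailable",
            "directionality": directionality,
        }

    def add_vector(self, name: str, values):
        self.vectors[name] = _jsonable(np.asarray(values, dtype=float))

    def to_dict(self) -> dict:
        return {
            "scan_id": self.scan_id,
            "profile": self.profile,
            "metrics": self.metrics,
            "vectors": self.vectors,
            "verdict": self.verdict,
            "provenance": self.provenance,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "QCReport":
        missing = [k for k in REQUIRED_BLOCKS if k not in data]
        if missing:
            raise ValidationError(f"report missing required block(s): {missing}")
        return cls(scan_id=data["scan_id"], profile=data["profile"],
                   metrics=data["metrics"], vectors=data["vectors"],
                   verdict=data["verdict"], provenance=data["provenance"])

    def content_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()


def write_report(report: QCReport, path, format: str = "json") -> list[Path]:
    """Write a report; JSON gives one file, CSV a scalar table + vector tables."""
    path = Path(path)
    written = []
    if format == "json":
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")
        written.append(path)
    elif format == "csv":
        path.parent.mkdir(parents=True, exist_ok=True)
        rows = [{"name": name, **entry} for name, entry in report.metrics.items()]
        pd.DataFrame(rows).to_csv(path, index=False)
        written.append(path)
        for name, values in report.vectors.items():
            vpath = path.with_name(f"{path.stem}_{name}.csv")
            pd.DataFrame({"index": range(len(values)), "metric": name,
                          "value": values}).to_csv(vpath, index=False)
            written.append(vpath)
    else:
        raise ValidationError(f"unknown report format {format!r}")
    return written


def read_report(path) -> QCReport:
    with open(path) as fh:
        return QCReport.from_dict(json.load(fh))
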