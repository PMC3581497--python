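"""Delimited-text I/O for records, labels, measures and session manifests.

Records are stored as tab-separated text (one row per sample, header naming
the channel roles) with a JSON sidecar holding the stimulus spec and, for
synthetic records, the generating truth. Segment labels serialize as a
BED-like interval table. Session manifests are YAML.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .segmentation import SegmentLabels
from .session import SessionData
from .simulate import RawRecord, SimTruth
from .stimuli import StimulusSpec

__all__ = [
    "write_record", "read_record", "write_labels",
    "write_measures", "load_manifest",
]

_CHANNELS = ("t", "pupil_h", "pupil_v", "cr_h", "cr_v", "pupil_diameter",
             "table_position", "planetarium_velocity")


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_record(rec: RawRecord, path) -> Path:
    """Write a record as TSV plus a JSON sidecar with spec and truth."""
    path = Path(path)
    rec.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")
    meta = {"sample_rate": rec.sample_rate,
            "stimulus": rec.stimulus.to_dict(),
            "truth": None if rec.truth is None else rec.truth.to_dict()}
    _sidecar(path).write_text(json.dumps(meta, indent=1))
    return path


def read_record(path) -> RawRecord:
    """Read a record written by :func:`write_record`."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    meta = json.loads(_sidecar(path).read_text())
    spec = StimulusSpec.from_dict(meta["stimulus"])
    truth = None if meta.get("truth") is None else SimTruth.from_dict(meta["truth"])
    fs = float(meta["sample_rate"])
    n = len(df)
    # reading back %.6g-rounded t would fail the uniformity check; rebuild it
    t = np.arange(n) / fs
    kwargs = {c: df[c].to_numpy(dtype=float) for c in _CHANNELS if c != "t"}
    return RawRecord(sample_rate=fs, t=t, stimulus=spec, truth=truth, **kwargs)


def write_labels(labels: SegmentLabels, path, record_id: str = "") -> Path:
    """Write labels as a BED-like interval table (record id, start, end, class)."""
    path = Path(path)
    df = labels.to_frame()
    df.insert(0, "record", record_id)
    df.to_csv(path, sep="\t", index=False, float_format="%.4f")
    return path


def write_measures(frame: pd.DataFrame, path) -> Path:
    """Write a tidy measures table as TSV."""
    path = Path(path)
    frame.to_csv(path, sep="\t", index=False, float_format="%.6g")
    return path


def load_manifest(path) -> list[SessionData]:
    """Load a YAML session manifest into SessionData objects.

    Expected structure::

        sessions:
          - animal: tg01
            cohort: young_mutant
            treatment: saline
            injection_volume: null     # pL/injection, optional
            excluded: false
            exclusion_reason: ""
            records:
              pre:  [rec_pre_vvor_1.tsv, ...]
              post: [rec_post_vvor_1.tsv, ...]

    Record paths are resolved relative to the manifest file.
    """
    path = Path(path)
    doc = yaml.safe_load(path.read_text())
    out = []
    for entry in doc.get("sessions", []):
        records = {}
        for phase, files in (entry.get("records") or {}).items():
            records[phase] = [read_record(path.parent / f) for f in files or []]
        out.append(SessionData(
            animal=str(entry["animal"]), cohort=entry["cohort"],
            treatment=entry["treatment"], records=records,
            injection_volume=entry.get("injection_volume"),
            excluded=bool(entry.get("excluded", False)),
            exclusion_reason=str(entry.get("exclusion_reason", ""))))
    return out
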