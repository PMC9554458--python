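"""Readers and writers for the package's plain-text interchange formats.

Everything is CSV/JSON: concentration profiles as tidy long tables, PTA
curves and summaries, virtual cohorts, and the NONMEM-flavoured TDM
dialect (columns ID, TIME, DV, AMT, RATE, WT, GROUP plus the dataset
extras GA, PNA, BLQ) that round-trips through these functions.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .estimation import TDMDataset, LLOQ_DEFAULT
from .model import ConcentrationProfile
from .pkpd import PTAResult

__all__ = [
    "write_profiles_csv",
    "write_pta_csv",
    "write_pta_summary",
    "read_tdm_csv",
    "write_tdm_csv",
    "write_json",
]


def write_profiles_csv(
    profiles: Sequence[ConcentrationProfile],
    path,
    subject_ids: Sequence[str] | None = None,
    tissues: bool = False,
) -> None:
    """Tidy CSV: subject_id, time_h, conc_mg_L, compartment."""
    if subject_ids is None:
        subject_ids = [f"subj-{i + 1:04d}" for i in range(len(profiles))]
    frames = [p.to_frame(sid, tissues=tissues) for sid, p in zip(subject_ids, profiles)]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def write_pta_csv(result: PTAResult, path) -> None:
    """PTA curves: MIC, criterion, PTA_percent."""
    result.to_frame().to_csv(path, index=False)


def write_pta_summary(results: dict[str, PTAResult], mic: float, path) -> None:
    """Summary keyed by (subpopulation x regimen) label at a reference MIC."""
    rows = []
    for label, result in results.items():
        values = result.at_mic(mic)
        for criterion, value in values.items():
            if value is not None:
                rows.append(
                    {"label": label, "MIC": mic, "criterion": criterion, "PTA_percent": value, "n": result.n}
                )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_tdm_csv(path, lloq: float = LLOQ_DEFAULT) -> TDMDataset:
    """Read the TDM CSV dialect; schema violations raise ValueError."""
    try:
        frame = pd.read_csv(path)
    except Exception as exc:  # malformed file -> data error
        raise ValueError(f"could not parse TDM CSV {path}: {exc}") from exc
    return TDMDataset(data=frame, lloq=lloq)


def write_tdm_csv(dataset: TDMDataset, path) -> None:
    """Write the TDM CSV dialect with stable column order and formatting."""
    cols = [c for c in ("ID", "TIME", "DV", "AMT", "RATE", "WT", "GROUP", "GA", "PNA", "BLQ")
            if c in dataset.data.columns]
    dataset.data.loc[:, cols].to_csv(path, index=False, float_format="%.6g")


def write_json(payload: dict, path) -> None:
    """JSON with deterministic key order and numpy-safe encoding."""

    def default(obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        raise TypeError(f"not JSON serialisable: {type(obj)}")

    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True, default=default) + "\n")
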