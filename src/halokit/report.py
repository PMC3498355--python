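"""Assembly of machine-readable survey/QSAR reports.

JSON is the canonical output; every block is optional so partial
pipelines (survey without QSAR, QSAR without structures) assemble
without error.  Keys are sorted and no timestamps are embedded, so
identical configurations produce byte-identical reports.
"""

from __future__ import annotations

import json
from dataclasses import asdict, is_dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ParameterError

__all__ = ["assemble_report", "report_to_json"]


def _plain(obj):
    """Recursively convert package objects to JSON-serializable forms."""
    if obj is None or isinstance(obj, (bool, int, str)):
        return obj
    if isinstance(obj, float):
        return float(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if is_dataclass(obj) and not isinstance(obj, type):
        return {k: _plain(v) for k, v in asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return [_plain(v) for v in obj.tolist()]
    if isinstance(obj, pd.Series):
        return {str(k): _plain(v) for k, v in obj.items()}
    if isinstance(obj, pd.DataFrame):
        return json.loads(obj.to_json(orient="index"))
    if isinstance(obj, dict):
        return {str(k): _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set)):
        return [_plain(v) for v in obj]
    if hasattr(obj, "value"):  # enums
        return obj.value
    return str(obj)


def assemble_report(
    contacts: Optional[pd.DataFrame] = None,
    distance_fits: Optional[dict] = None,
    ad_result=None,
    acceptor_stats: Optional[Sequence] = None,
    qsar: Optional[dict] = None,
    ic50: Optional[dict] = None,
    config: Optional[dict] = None,
) -> dict:
    """Merge available stage outputs into one report dictionary.

    At least one block must be provided; absent blocks are simply
    omitted from the report.
    """
    blocks = {
        "contacts": None if contacts is None else _plain(contacts),
        "distance_fits": _plain(distance_fits) if distance_fits else None,
        "anderson_darling": _plain(ad_result) if ad_result is not None else None,
        "acceptor_stats": _plain(list(acceptor_stats)) if acceptor_stats else None,
        "qsar": _plain(qsar) if qsar else None,
        "ic50": _plain(ic50) if ic50 else None,
    }
    report = {k: v for k, v in blocks.items() if v is not None}
    if not report:
        raise ParameterError("assemble_report needs at least one stage output")
    if config:
        report["config"] = _plain(config)
    return report


def report_to_json(report: dict) -> str:
    """Serialize a report deterministically (sorted keys, fixed format)."""
    return json.dumps(report, indent=2, sort_keys=True)
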