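"""Result serialization: wide delimited tables and run manifests."""

from __future__ import annotations

import json
from pathlib import Path

from .config import RunConfig, config_to_dict
from .engine import SimulationResult
from .errors import GlucoflowError

__all__ = ["write_timeseries", "write_manifest"]


def write_timeseries(result: SimulationResult, path: str | Path, sep: str = "\t") -> Path:
    """Write the result as one wide delimited table, time first.

    Column order is fixed (the assembly order of the result frame), floats
    are written with full repr precision, so re-running an identical scenario
    re-writes a byte-identical file.
    """
    path = Path(path)
    frame = result.frame
    cols = ["time_min"] + [c for c in frame.columns if c != "time_min"]
    try:
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write(sep.join(cols) + "\n")
            for row in frame[cols].itertuples(index=False):
                fh.write(sep.join(repr(float(v)) for v in row) + "\n")
    except OSError as exc:
        raise GlucoflowError(f"cannot write time series to {path}: {exc}") from exc
    return path


def write_manifest(cfg: RunConfig, path: str | Path) -> Path:
    """Record every effective parameter of a run as JSON, for reproducibility."""
    from . import __version__

    path = Path(path)
    payload = {"glucoflow_version": __version__, "config": config_to_dict(cfg)}
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path
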