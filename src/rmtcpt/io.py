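"""Reading and writing: delimited time-series matrices, result records,
benchmark tables, and the validated run configuration."""

from __future__ import annotations

import csv
import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .benchmark import BenchmarkMetrics, metrics_frame
from .detector import DetectionResult, TimeSeriesMatrix

Orientation = Literal["rows_time", "rows_roi"]


@dataclass(frozen=True)
class RunConfig:
    """Validated settings for a detection run; echoed into every output."""

    method: Literal["rmt", "aue"] = "rmt"
    t_min: int | None = None
    alpha: float = 0.05
    block_size: int = 5
    n_perm: int = 1000
    seed: int | None = None
    tw_form: Literal["squared", "literal"] = "squared"
    df_correction: Literal["plain", "mean_corrected"] = "plain"
    orientation: Orientation = "rows_time"

    def __post_init__(self):
        if self.method not in ("rmt", "aue"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.tw_form not in ("squared", "literal"):
            raise ValueError(f"unknown tw_form {self.tw_form!r}")
        if self.df_correction not in ("plain", "mean_corrected"):
            raise ValueError(f"unknown df_correction {self.df_correction!r}")
        if self.orientation not in ("rows_time", "rows_roi"):
            raise ValueError(f"unknown orientation {self.orientation!r}")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")
        if self.block_size < 1 or self.n_perm < 1:
            raise ValueError("block_size and n_perm must be positive")
        if self.t_min is not None and self.t_min < 1:
            raise ValueError("t_min must be positive")


def read_matrix(path: str | Path, orientation: Orientation = "rows_time") -> TimeSeriesMatrix:
    """Read a delimited numeric matrix as a ``d x T`` series.

    The delimiter is sniffed among comma, tab and whitespace and a header row
    is auto-detected.  With ``rows_time`` (default) file rows are time points
    and columns variables; ``rows_roi`` reads the transpose.  NaN or
    non-numeric payload is rejected with the offending coordinates.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0 or not path.read_text().strip():
        raise ValueError(f"{path}: empty file")
    try:
        frame = pd.read_csv(path, sep=None, engine="python", header=None, comment="#")
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty file") from None
    except (pd.errors.ParserError, csv.Error) as e:
        raise ValueError(f"{path}: parse error: {e}") from e
    # header auto-detection: drop a first row that fails numeric conversion
    first = pd.to_numeric(frame.iloc[0], errors="coerce")
    if first.isna().any():
        frame = frame.iloc[1:]
    try:
        values = frame.astype(float).to_numpy()
    except (TypeError, ValueError):
        coerced = frame.apply(pd.to_numeric, errors="coerce")
        bad = np.argwhere(coerced.isna().to_numpy() & frame.notna().to_numpy())
        r, c = (bad[0] + [1, 1]) if len(bad) else (0, 0)
        raise ValueError(f"{path}: non-numeric cell at row {r}, column {c}") from None
    if np.isnan(values).any():
        r, c = np.argwhere(np.isnan(values))[0] + 1
        raise ValueError(f"{path}: NaN at row {r}, column {c}")
    if orientation == "rows_time":
        values = values.T
    elif orientation != "rows_roi":
        raise ValueError(f"unknown orientation {orientation!r}")
    return TimeSeriesMatrix(values)


def write_matrix(y: TimeSeriesMatrix, path: str | Path, orientation: Orientation = "rows_time") -> None:
    """Write a series as TSV (rows = time points unless ``rows_roi``)."""
    values = y.values.T if orientation == "rows_time" else y.values
    np.savetxt(path, values, delimiter="\t", fmt="%.10g")


def result_to_dict(result: DetectionResult, config: RunConfig | None = None) -> dict:
    """JSON-ready record for a detection result, with config echo."""
    rec = {
        "tau_hat": result.tau_hat,
        "theta_hat": result.theta_hat,
        "lambda_T": result.lambda_T,
        "threshold": result.threshold,
        "p_value": result.p_value,
        "rejected": result.rejected,
    }
    if config is not None:
        rec["config"] = dataclasses.asdict(config)
    return rec


def write_result(
    result: DetectionResult | Sequence[BenchmarkMetrics],
    path: str | Path,
    config: RunConfig | None = None,
) -> None:
    """Persist a detection result (JSON) or benchmark metrics (TSV table)."""
    path = Path(path)
    if isinstance(result, DetectionResult):
        path.write_text(json.dumps(result_to_dict(result, config), indent=2) + "\n")
        return
    metrics = list(result)
    if not metrics:
        path.write_text("statistic\n")
        return
    frame = metrics_frame(metrics)
    frame.round(6).to_csv(path, sep="\t", index_label="statistic")


def read_result(path: str | Path) -> dict:
    """Read back a JSON detection record."""
    return json.loads(Path(path).read_text())


def write_process_table(t_values, g, path: str | Path) -> None:
    """Per-split table of the change process: columns t, G_t, G_t^2 (TSV)."""
    pd.DataFrame({"t": t_values, "G_t": g, "G_t_sq": np.asarray(g) ** 2}).to_csv(
        path, sep="\t", index=False
    )
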