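"""Plain-text series I/O and reproducibility plumbing for the CLI.

Series files are one value per line (or one CSV column); ``#`` lines are
comments.  Every CLI run writes a JSON config echo alongside its outputs
so any result can be regenerated from the echoed file alone.  Numbers
are serialised with 17 significant digits, enough to round-trip float64
bit-for-bit, which makes end-to-end determinism testable byte-wise.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .series import TimeSeries

__all__ = ["read_series", "write_series", "write_config_echo", "fmt17"]


def fmt17(x: float) -> str:
    """Shortest-faithful decimal form of a float (17 significant digits)."""
    return f"{float(x):.17g}"


def _split(line: str) -> list[str]:
    if "," in line:
        return [tok.strip() for tok in line.split(",")]
    return line.split()


def read_series(path, column=None) -> TimeSeries:
    """Read a scalar series from a plain-text/CSV file.

    ``column`` selects a CSV column by 0-based index or by header name;
    default is the first column.  Comment lines starting with ``#`` and
    blank lines are skipped.  A non-numeric or non-finite token raises an
    error naming the offending line.
    """
    path = Path(path)
    values: list[float] = []
    col_idx = column if isinstance(column, int) else 0
    first = True
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            tokens = _split(line)
            if first:
                first = False
                if _is_header(tokens):
                    if isinstance(column, str):
                        try:
                            col_idx = tokens.index(column)
                        except ValueError:
                            raise ValueError(
                                f"{path}:{lineno}: no column named {column!r} in header {tokens}"
                            ) from None
                    continue  # skip the header row
                if isinstance(column, str):
                    raise ValueError(
                        f"{path}:{lineno}: column selected by name {column!r} but file has no header row"
                    )
            if col_idx >= len(tokens):
                raise ValueError(f"{path}:{lineno}: line has only {len(tokens)} column(s)")
            tok = tokens[col_idx]
            try:
                v = float(tok)
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-numeric token {tok!r}") from None
            if not np.isfinite(v):
                raise ValueError(f"{path}:{lineno}: non-finite value {tok!r}")
            values.append(v)
    if not values:
        raise ValueError(f"{path}: no numeric data found")
    return TimeSeries(np.array(values), meta={"source": str(path), "column": column})


def _is_header(tokens: list[str]) -> bool:
    try:
        float(tokens[0])
        return False
    except ValueError:
        return True


def write_series(series, path, columns=None) -> None:
    """Write a series (1-D) or trajectory matrix (2-D) as CSV."""
    arr = np.asarray(series, dtype=float)
    path = Path(path)
    with path.open("w") as fh:
        if arr.ndim == 1:
            fh.write((columns[0] if columns else "value") + "\n")
            for v in arr:
                fh.write(fmt17(v) + "\n")
        else:
            fh.write(",".join(columns or [f"c{i}" for i in range(arr.shape[1])]) + "\n")
            for row in arr:
                fh.write(",".join(fmt17(v) for v in row) + "\n")


def write_config_echo(out_path, config: dict) -> Path:
    """Write ``<out>.config.json`` echoing the fully resolved run config."""
    echo_path = Path(str(out_path) + ".config.json")
    echo_path.write_text(json.dumps(config, indent=2, sort_keys=True, default=str) + "\n")
    return echo_path
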