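"""CSV/JSON input-output for trajectories and run configuration.

Trajectory CSV dialect: comma-separated, ``.`` decimal, mandatory
header, ``#``-prefixed comment lines carrying metadata as ``key=value``
pairs.  Floats are written with ``repr`` round-trip precision so that a
write/read cycle is bitwise exact.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .parameters import ReactionParameters
from .timecourse import TimeCourse

__all__ = ["read_timecourse", "write_timecourse", "load_config", "read_series"]


def write_timecourse(tc: TimeCourse, path: str | Path,
                     include_derived: bool = False) -> None:
    """Write a trajectory as commented CSV with full float precision."""
    path = Path(path)
    lines = [f"# model_label={tc.model_label}"]
    for key, value in sorted(tc.meta.items()):
        if key == "residuals":
            continue
        lines.append(f"# {key}={value!r}" if isinstance(value, str)
                     else f"# {key}={value}")
    cols = ["t", "s", "c"]
    data = [tc.t, tc.s, tc.c]
    if include_derived:
        cols += ["total", "product"]
        data += [tc.total(), tc.product()]
    lines.append(",".join(cols))
    for row in zip(*data):
        lines.append(",".join(repr(float(v)) for v in row))
    path.write_text("\n".join(lines) + "\n")


def _parse_meta(comment_lines: list[str]) -> dict:
    meta = {}
    for line in comment_lines:
        body = line.lstrip("#").strip()
        if "=" not in body:
            continue
        key, _, raw = body.partition("=")
        raw = raw.strip()
        try:
            meta[key.strip()] = json.loads(raw)
        except json.JSONDecodeError:
            meta[key.strip()] = raw.strip("'\"")
    return meta


def _read_table(path: Path) -> tuple[dict[str, np.ndarray], dict]:
    comments, header, rows = [], None, []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            comments.append(line)
            continue
        if header is None:
            header = [h.strip() for h in line.split(",")]
            continue
        values = line.split(",")
        if len(values) != len(header):
            raise ValueError(f"{path}: row at line {lineno} has "
                             f"{len(values)} fields, expected {len(header)}")
        try:
            rows.append([float(v) for v in values])
        except ValueError as exc:
            raise ValueError(f"{path}: unparsable value at line {lineno}: {exc}")
    if header is None or not rows:
        raise ValueError(f"{path}: no data rows")
    arr = np.asarray(rows, dtype=float)
    return {name: arr[:, i] for i, name in enumerate(header)}, _parse_meta(comments)


def read_series(path: str | Path, columns: tuple[str, ...] = ("t",)
                ) -> tuple[dict[str, np.ndarray], dict]:
    """Read a conforming CSV requiring only the named columns.

    Used by consumers that need fewer channels than a full trajectory
    (e.g. fitting a single observable).  The time column must be
    strictly increasing.
    """
    path = Path(path)
    table, meta = _read_table(path)
    for col in columns:
        if col not in table:
            raise ValueError(f"{path}: missing required column {col!r}; "
                             f"found {sorted(table)}")
    t = table["t"]
    bad = np.flatnonzero(np.diff(t) <= 0)
    if bad.size:
        raise ValueError(f"{path}: time not strictly increasing at data row "
                         f"{int(bad[0]) + 1}")
    return table, meta


def read_timecourse(path: str | Path) -> TimeCourse:
    """Read a full (t, s, c) trajectory CSV; rejects missing columns or
    non-monotone time, naming the offending row."""
    table, meta = read_series(path, columns=("t", "s", "c"))
    label = meta.pop("model_label", "full")
    return TimeCourse(table["t"], table["s"], table["c"],
                      model_label=label, meta=meta)


def load_config(config_path: str | Path | None,
                overrides: dict[str, float | None]) -> ReactionParameters:
    """Build ReactionParameters from an optional JSON config plus CLI
    flag overrides (flags win)."""
    merged: dict[str, float] = {}
    if config_path is not None:
        with open(config_path) as fh:
            merged.update(json.load(fh))
    merged.update({k: v for k, v in overrides.items() if v is not None})
    try:
        return ReactionParameters.from_dict(merged)
    except TypeError as exc:
        raise ValueError(f"incomplete parameters: {exc}") from exc
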