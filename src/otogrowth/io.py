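"""Delimited-text readers/writers and run manifests.

All tabular formats are plain delimited text with a header row; comma or
tab delimiters are auto-detected (and logged on the CLI).  Dates are
ISO-8601.  Ages are stored in days in ageing outputs and years in growth
outputs, with a 365 day/year convention.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .ageing import FishRecord, ReadingSet
from .mcmc import PosteriorDraws

__all__ = [
    "read_table",
    "read_fish_table",
    "write_fish_table",
    "read_readings_table",
    "write_readings_table",
    "read_maxima_table",
    "read_catch_table",
    "write_draws",
    "read_draws",
    "write_manifest",
]

_FISH_COLS = ["fish_id", "program", "otc_tagged", "length_rec", "length_tag",
              "date_tag", "tal_min", "tal_max"]


def sniff_delimiter(path) -> str:
    """Detect the delimiter (comma/tab/semicolon) from the header line."""
    with open(path) as fh:
        header = fh.readline()
    counts = {d: header.count(d) for d in (",", "\t", ";")}
    return max(counts, key=counts.get) if max(counts.values()) else ","


def read_table(path) -> pd.DataFrame:
    """Read a delimited text table, auto-detecting comma/tab/semicolon.

    Floats are parsed with round-trip precision so write -> read is exact.
    """
    return pd.read_csv(path, sep=sniff_delimiter(path), float_precision="round_trip")


def _opt(v, cast=float):
    if v is None or (isinstance(v, float) and np.isnan(v)) or v == "":
        return None
    return cast(v)


def read_fish_table(path) -> list[FishRecord]:
    """Parse a fish table into validated records.

    Required columns: fish_id, program, otc_tagged, length_rec.  Optional:
    length_tag, date_tag (ISO-8601), tal_min, tal_max (days).  Malformed
    rows raise with their line numbers.
    """
    df = read_table(path)
    missing = [c for c in ("fish_id", "program", "otc_tagged", "length_rec")
               if c not in df.columns]
    if missing:
        raise ValueError(f"fish table {path} missing columns {missing}")
    records, errors = [], []
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        try:
            date_tag = _opt(row.get("date_tag"), str)
            if date_tag is not None:
                _dt.date.fromisoformat(date_tag)
            records.append(FishRecord(
                fish_id=str(row["fish_id"]),
                program=str(row["program"]),
                otc_tagged=bool(row["otc_tagged"]) if not isinstance(row["otc_tagged"], str)
                else row["otc_tagged"].strip().lower() in ("1", "true", "yes"),
                length_rec=float(row["length_rec"]),
                length_tag=_opt(row.get("length_tag")),
                date_tag=date_tag,
                tal_min=_opt(row.get("tal_min")),
                tal_max=_opt(row.get("tal_max")),
            ))
        except (ValueError, TypeError) as e:
            errors.append(f"line {line}: {e}")
    if errors:
        raise ValueError("malformed fish rows:\n" + "\n".join(errors))
    return records


def write_fish_table(records, path) -> None:
    rows = []
    for r in records:
        rows.append({"fish_id": r.fish_id, "program": r.program,
                     "otc_tagged": int(r.otc_tagged), "length_rec": r.length_rec,
                     "length_tag": r.length_tag, "date_tag": r.date_tag,
                     "tal_min": r.tal_min, "tal_max": r.tal_max})
    pd.DataFrame(rows, columns=_FISH_COLS).to_csv(path, index=False, float_format="%.17g")


def read_readings_table(path) -> list[ReadingSet]:
    """Parse a readings table (fish_id, section, reading_index, count)."""
    df = read_table(path)
    missing = [c for c in ("fish_id", "section", "count") if c not in df.columns]
    if missing:
        raise ValueError(f"readings table {path} missing columns {missing}")
    if "reading_index" in df.columns:
        df = df.sort_values(["fish_id", "section", "reading_index"], kind="stable")
    out = []
    for (fid, sec), grp in df.groupby(["fish_id", "section"], sort=False):
        out.append(ReadingSet(fish_id=str(fid), section=str(sec),
                              counts=tuple(float(c) for c in grp["count"])))
    return out


def write_readings_table(readings, path) -> None:
    rows = []
    for rs in readings:
        for j, c in enumerate(rs.counts):
            rows.append({"fish_id": rs.fish_id, "section": rs.section,
                         "reading_index": j, "count": c})
    pd.DataFrame(rows, columns=["fish_id", "section", "reading_index", "count"]
                 ).to_csv(path, index=False, float_format="%.17g")


def read_maxima_table(path) -> np.ndarray:
    """Per-stratum maximum fork lengths (cm) from a maxima table."""
    df = read_table(path)
    if "max_fork_length_cm" not in df.columns:
        raise ValueError(f"maxima table {path} needs a max_fork_length_cm column")
    return df["max_fork_length_cm"].to_numpy(dtype=float)


def read_catch_table(path) -> pd.Series:
    """Catch-at-size: columns length_bin_lower_cm, catch."""
    df = read_table(path)
    missing = [c for c in ("length_bin_lower_cm", "catch") if c not in df.columns]
    if missing:
        raise ValueError(f"catch table {path} missing columns {missing}")
    s = pd.Series(df["catch"].to_numpy(dtype=float),
                  index=df["length_bin_lower_cm"].to_numpy(dtype=float), name="catch")
    if (s < 0).any():
        raise ValueError("catch quantities must be non-negative")
    return s


def write_draws(draws: PosteriorDraws, path, sidecar=None) -> None:
    """Persist parameter draws as long-format CSV plus a JSON metadata sidecar."""
    path = Path(path)
    rows = []
    for name, arr in draws.params.items():
        for c in range(arr.shape[0]):
            for i in range(arr.shape[1]):
                rows.append((name, c, i, arr[c, i]))
    pd.DataFrame(rows, columns=["parameter", "chain", "iteration", "value"]
                 ).to_csv(path, index=False, float_format="%.17g")
    side = Path(sidecar) if sidecar else path.with_suffix(".meta.json")
    side.write_text(json.dumps(draws.meta, indent=2, default=float))


def read_draws(path, sidecar=None) -> PosteriorDraws:
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    params = {}
    for name, grp in df.groupby("parameter", sort=False):
        piv = grp.pivot(index="chain", columns="iteration", values="value")
        params[name] = piv.to_numpy()
    side = Path(sidecar) if sidecar else path.with_suffix(".meta.json")
    meta = json.loads(side.read_text()) if side.exists() else {}
    return PosteriorDraws(params=params, meta=meta)


def write_manifest(outdir, stage: str, inputs: dict, config: dict, seed: int) -> Path:
    """Machine-readable record of a pipeline stage sufficient to re-run it."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_json = json.dumps(config, sort_keys=True, default=str)
    manifest = {
        "stage": stage,
        "inputs": {k: str(v) for k, v in inputs.items()},
        "config": config,
        "config_hash": hashlib.sha256(cfg_json.encode()).hexdigest()[:16],
        "seed": int(seed),
        "versions": _versions(),
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path


def _versions() -> dict:
    import numpy, pandas, scipy

    from . import __version__

    return {"otogrowth": __version__, "numpy": numpy.__version__,
            "scipy": scipy.__version__, "pandas": pandas.__version__}
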