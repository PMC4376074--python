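"""Plain-text I/O: probe tables, BED regions and calls, TSV tables, YAML
configs, and JSON reports.

All genomic coordinates are 0-based half-open (BED convention) both in
memory and on disk. Floats are written at full precision so a write/read
round trip is exact to well below 1e-9.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

from .diffmeth_level1 import DifferentialCall
from .mira_peaks import ArrayDesign
from .region_summary import RegionSet
from .synthetic_data import SimulationConfig

__all__ = [
    "write_probe_table",
    "read_probe_table",
    "write_bed",
    "read_bed",
    "write_calls_bed",
    "read_calls_bed",
    "write_table",
    "read_table",
    "save_config",
    "load_config",
    "write_report_json",
]


class FormatError(ValueError):
    """Malformed input file; message carries the offending line number."""


def write_probe_table(design: ArrayDesign, values: pd.DataFrame, path) -> None:
    """Write probe intervals plus one column per sample, tab-delimited.

    ``values`` is a probes x samples frame aligned to the design's probe
    order.
    """
    if len(values) != design.n_probes:
        raise ValueError("values rows must match design probes")
    out = design.to_frame()
    for col in values.columns:
        out[col] = np.asarray(values[col], dtype=float)
    out.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_probe_table(path) -> tuple[ArrayDesign, pd.DataFrame]:
    """Read a probe table back into (ArrayDesign, probes x samples frame)."""
    df = pd.read_csv(path, sep="\t")
    required = ["probe_id", "chrom", "start", "end"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"probe table missing columns {missing}")
    design = ArrayDesign.from_frame(df[required])
    samples = df.drop(columns=required).astype(float)
    return design, samples


def _validate_bed_fields(chrom: str, start: int, end: int, lineno: int) -> None:
    if start < 0:
        raise FormatError(f"line {lineno}: negative start {start}")
    if end <= start:
        raise FormatError(f"line {lineno}: end {end} <= start {start}")
    if not chrom:
        raise FormatError(f"line {lineno}: empty chromosome")


def write_bed(regions: RegionSet, path, comment: str | None = None) -> None:
    """Write a RegionSet as BED (chrom start end name score=0 strand=. class)."""
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        for row in regions.frame.itertuples(index=False):
            fh.write(
                f"{row.chrom}\t{row.start}\t{row.end}\t{row.name}\t0\t.\t{row.region_class}\n"
            )


def read_bed(path) -> RegionSet:
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise FormatError(f"line {lineno}: expected >= 4 BED fields, got {len(fields)}")
            chrom, start_s, end_s, name = fields[:4]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise FormatError(f"line {lineno}: non-integer coordinates") from exc
            _validate_bed_fields(chrom, start, end, lineno)
            region_class = fields[6] if len(fields) >= 7 else "control"
            records.append((name, chrom, start, end, region_class))
    return RegionSet.from_records(records)


def write_calls_bed(calls: Iterable[DifferentialCall], path, comment: str | None = None) -> None:
    """Differential calls as BED: name = test_id, score column = delta_log2.

    An empty call list yields a valid BED containing only the header
    comment. Extra columns carry direction, p-value, and the passed flag so
    the persistence stage can consume exactly what level 1 emits.
    """
    calls = list(calls)
    with open(path, "w") as fh:
        fh.write("# chrom\tstart\tend\ttest_id\tdelta_log2\tdirection\tp_value\tpassed\n")
        if comment:
            fh.write(f"# {comment}\n")
        for c in calls:
            fh.write(
                f"{c.chrom}\t{c.start}\t{c.end}\t{c.test_id}\t{c.delta_log2:.17g}"
                f"\t{c.direction}\t{c.p_value:.17g}\t{int(c.passed)}\n"
            )


def read_calls_bed(path) -> list[DifferentialCall]:
    calls: list[DifferentialCall] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 8:
                raise FormatError(f"line {lineno}: expected 8 fields, got {len(fields)}")
            chrom, start_s, end_s, test_id, delta_s, direction, p_s, passed_s = fields
            try:
                start, end = int(start_s), int(end_s)
                delta, p = float(delta_s), float(p_s)
                passed = bool(int(passed_s))
            except ValueError as exc:
                raise FormatError(f"line {lineno}: malformed numeric field") from exc
            _validate_bed_fields(chrom, start, end, lineno)
            calls.append(
                DifferentialCall(
                    chrom=chrom, start=start, end=end, test_id=test_id,
                    mean_a=float("nan"), mean_b=float("nan"), delta_log2=delta,
                    direction=direction, p_value=p, passed=passed, n_probes=0,
                )
            )
    return calls


def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    """Generic tab-delimited table with full-precision floats."""
    df.to_csv(path, sep="\t", index=index, float_format="%.17g")


def read_table(path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def save_config(cfg: SimulationConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)


def load_config(path) -> SimulationConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return SimulationConfig.from_dict(data)


def write_report_json(report: dict, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")
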