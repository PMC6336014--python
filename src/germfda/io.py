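"""CSV readers/writers for the pipeline's tabular interchange formats.

Germination counts travel in long format (accession_id, treatment,
replicate, day, cumulative_count, seeds_total); descriptors, coordinates,
environment and trait tables are plain indexed CSVs.  All files are
comma-separated UTF-8 with "." decimals.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .curve_model import GerminationRecord

__all__ = [
    "read_germination_csv",
    "write_germination_csv",
    "read_coordinates_csv",
    "read_table_csv",
    "write_descriptors_csv",
]

GERMINATION_COLUMNS = ["accession_id", "treatment", "replicate", "day",
                       "cumulative_count", "seeds_total"]


def read_germination_csv(path) -> list[GerminationRecord]:
    """Read and validate long-format daily cumulative counts.

    Rejects duplicate (accession, treatment, replicate, day) rows, counts
    exceeding seeds_total and non-monotone cumulative series (the error
    names the offending accession and day).
    """
    df = pd.read_csv(path)
    missing = [c for c in GERMINATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    key = ["accession_id", "treatment", "replicate"]
    dup = df.duplicated(subset=key + ["day"])
    if dup.any():
        row = df[dup].iloc[0]
        raise ValueError(
            f"duplicate row for {row.accession_id}/{row.treatment}"
            f"/rep{row.replicate} day {row.day}"
        )
    records = []
    for (acc, tr, rep), grp in df.groupby(key, sort=True):
        grp = grp.sort_values("day")
        counts = grp["cumulative_count"].to_numpy(dtype=float)
        days = grp["day"].to_numpy(dtype=float)
        decr = np.where(np.diff(counts) < 0)[0]
        if decr.size:
            raise ValueError(
                f"cumulative count decreases for {acc}/{tr}/rep{rep} at day "
                f"{days[decr[0] + 1]:g}"
            )
        total = int(grp["seeds_total"].iloc[0])
        if (counts > total).any():
            raise ValueError(f"count exceeds seeds_total for {acc}/{tr}/rep{rep}")
        records.append(GerminationRecord(str(acc), str(tr), int(rep), total,
                                         days, counts))
    return records


def write_germination_csv(records, path) -> None:
    rows = []
    for r in records:
        for d, c in zip(r.days, r.counts):
            rows.append((r.accession_id, r.treatment, r.replicate, d, c,
                         r.seeds_total))
    pd.DataFrame(rows, columns=GERMINATION_COLUMNS).to_csv(path, index=False)


def read_coordinates_csv(path) -> pd.DataFrame:
    """accession_id, lon, lat (WGS-84 decimal degrees)."""
    df = pd.read_csv(path)
    for c in ("accession_id", "lon", "lat"):
        if c not in df.columns:
            raise ValueError(f"{path}: missing column {c!r}")
    return df.set_index("accession_id")[["lon", "lat"]]


def read_table_csv(path, index_col="accession_id") -> pd.DataFrame:
    return pd.read_csv(path).set_index(index_col)


def write_descriptors_csv(desc: pd.DataFrame, path) -> None:
    desc.to_csv(path)
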