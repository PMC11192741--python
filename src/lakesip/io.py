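"""CSV schemas for pipeline inputs and outputs.

All formats are plain CSV handled by pandas.

incubation series : time_d, observable, value, units, event
    one bottle per file; ``event`` is ``subsample`` where a headspace
    subsample was taken (blank otherwise); bottle-level metadata (DIC,
    labeling fraction, volumes) travels in the run configuration, not the
    CSV.
depth profile     : depth_m, concentration_uM
roi table         : roi_id, fov_id, morphotype, counts_12C, counts_13C,
                    counts_12C14N, counts_12C15N, is_background
count table       : morphotype, cells_counted, fields_screened,
                    filter_area_fraction, volume_filtered_ml
                    [, depth_m, time_d, cluster_sizes]
                    ``cluster_sizes`` is a semicolon-separated integer list.
"""
from __future__ import annotations

from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .types import CountRecord, DepthProfile, IncubationSeries, RoiMeasurement

__all__ = [
    "read_incubation_csv",
    "write_incubation_csv",
    "read_profile_csv",
    "write_profile_csv",
    "read_roi_csv",
    "write_roi_csv",
    "read_counts_csv",
]

PathLike = Union[str, Path]

_UNITS = {
    "co2_ratio": "atom fraction",
    "n30_headspace": "umol/L water",
    "biomass_atpct": "excess atom fraction",
}


def write_incubation_csv(series: IncubationSeries, path: PathLike) -> None:
    sub = set(np.atleast_1d(series.subsample_times).tolist()) if series.subsample_times is not None else set()
    df = pd.DataFrame(
        {
            "time_d": series.times,
            "observable": series.observable,
            "value": series.values,
            "units": _UNITS.get(series.observable, ""),
            "event": ["subsample" if t in sub else "" for t in series.times],
        }
    )
    df.to_csv(path, index=False)


def read_incubation_csv(path: PathLike, **metadata) -> IncubationSeries:
    """Load one bottle's series; bottle metadata (dic_uM, label_fraction,
    volumes, condition, depth) is supplied as keyword arguments."""
    df = pd.read_csv(path)
    observable = str(df["observable"].iloc[0])
    events = df["event"].fillna("") if "event" in df else pd.Series([""] * len(df))
    sub_times = df.loc[events == "subsample", "time_d"].to_numpy(dtype=float)
    return IncubationSeries(
        times=df["time_d"].to_numpy(dtype=float),
        values=df["value"].to_numpy(dtype=float),
        observable=observable,
        subsample_times=sub_times if sub_times.size else None,
        **metadata,
    )


def write_profile_csv(profile: DepthProfile, path: PathLike) -> None:
    pd.DataFrame(
        {"depth_m": profile.depths, "concentration_uM": profile.concentrations}
    ).to_csv(path, index=False)


def read_profile_csv(path: PathLike, species: str = "CH4") -> DepthProfile:
    df = pd.read_csv(path).sort_values("depth_m")
    return DepthProfile(
        depths=df["depth_m"].to_numpy(dtype=float),
        concentrations=df["concentration_uM"].to_numpy(dtype=float),
        species=species,
    )


_ROI_COLUMNS = [
    "roi_id",
    "fov_id",
    "morphotype",
    "counts_12C",
    "counts_13C",
    "counts_12C14N",
    "counts_12C15N",
    "is_background",
]


def write_roi_csv(rois: list[RoiMeasurement], path: PathLike) -> None:
    pd.DataFrame([{c: getattr(r, c) for c in _ROI_COLUMNS} for r in rois]).to_csv(
        path, index=False
    )


def read_roi_csv(path: PathLike) -> list[RoiMeasurement]:
    df = pd.read_csv(path)
    return [
        RoiMeasurement(
            roi_id=str(row.roi_id),
            fov_id=str(row.fov_id),
            morphotype=str(row.morphotype),
            counts_12C=int(row.counts_12C),
            counts_13C=int(row.counts_13C),
            counts_12C14N=int(getattr(row, "counts_12C14N", 0) or 0),
            counts_12C15N=int(getattr(row, "counts_12C15N", 0) or 0),
            is_background=bool(row.is_background),
        )
        for row in df.itertuples(index=False)
    ]


def _parse_clusters(raw) -> Optional[list[int]]:
    if raw is None or (isinstance(raw, float) and np.isnan(raw)) or raw == "":
        return None
    return [int(x) for x in str(raw).split(";") if x.strip()]


def read_counts_csv(path: PathLike) -> list[CountRecord]:
    df = pd.read_csv(path)
    records = []
    for row in df.to_dict("records"):
        records.append(
            CountRecord(
                morphotype=str(row["morphotype"]),
                cells_counted=int(row["cells_counted"]),
                fields_screened=int(row["fields_screened"]),
                filter_area_fraction=float(row["filter_area_fraction"]),
                volume_filtered_ml=float(row["volume_filtered_ml"]),
                depth_m=row.get("depth_m"),
                time_d=row.get("time_d"),
                cluster_sizes=_parse_clusters(row.get("cluster_sizes")),
            )
        )
    return records
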