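"""Cohort I/O and time-series conditioning.

The package's file contract is deliberately plain: one TSV per subject
(rows = time, columns = regions, header = region ids), a cohort manifest CSV,
and a region-to-network TSV.  The two conditioning steps the pipeline owns are
polynomial detrending and zero-phase Butterworth band-pass filtering; all
image-space preprocessing (realignment, normalisation, smoothing, nuisance
regression) is assumed to have happened upstream.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

logger = logging.getLogger("gradstates.signal_prep")

#: the seven Yeo cortical networks; regions may additionally carry "subcortical"
YEO7 = (
    "visual",
    "somatomotor",
    "dorsal_attention",
    "ventral_attention",
    "limbic",
    "frontoparietal",
    "default_mode",
)
SUBCORTICAL = "subcortical"

MANIFEST_COLUMNS = (
    "subject_id",
    "group",
    "age",
    "sex",
    "duration_years",
    "verbal_comprehension",
    "perceptual_processing",
    "working_memory",
    "processing_speed",
    "full_scale",
)


@dataclass(frozen=True)
class SubjectTimeSeries:
    """One subject's T x P region-by-time matrix with sampling metadata."""

    subject_id: str
    group: str
    data: np.ndarray  # shape (T, P), rows = time
    tr: float  # sampling interval, seconds
    region_ids: tuple[str, ...] = field(default=())

    def __post_init__(self):
        data = np.asarray(self.data, dtype=float)
        object.__setattr__(self, "data", data)
        if data.ndim != 2:
            raise ValueError("data must be a 2-D (T x P) array")
        T, P = data.shape
        if T < 2 or P < 2:
            raise ValueError(f"need T >= 2 and P >= 2, got T={T}, P={P}")
        if not np.all(np.isfinite(data)):
            raise ValueError(f"subject {self.subject_id}: non-finite values in time series")
        if self.tr <= 0:
            raise ValueError("TR must be positive")
        ids = tuple(self.region_ids) or tuple(f"r{i:03d}" for i in range(P))
        if len(ids) != P or len(set(ids)) != P:
            raise ValueError("region_ids must be unique and match the number of columns")
        object.__setattr__(self, "region_ids", ids)

    @property
    def n_volumes(self) -> int:
        return self.data.shape[0]

    @property
    def n_regions(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class NetworkMap:
    """region id -> resting-state network label (7 Yeo names or subcortical)."""

    labels: Mapping[str, str]

    def __post_init__(self):
        allowed = set(YEO7) | {SUBCORTICAL}
        bad = {v for v in self.labels.values() if v not in allowed}
        if bad:
            raise ValueError(f"unknown network labels: {sorted(bad)}")

    def __getitem__(self, region_id: str) -> str:
        return self.labels[region_id]

    def regions_of(self, network: str) -> list[str]:
        return [r for r, n in self.labels.items() if n == network]

    def check_covers(self, region_ids: Sequence[str]) -> None:
        missing = [r for r in region_ids if r not in self.labels]
        if missing:
            raise ValueError(f"regions without a network label: {missing[:5]}")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_timeseries(path: str | Path, ts: SubjectTimeSeries) -> None:
    df = pd.DataFrame(ts.data, columns=list(ts.region_ids))
    df.to_csv(path, sep="\t", index=False, float_format="%.8g")


def read_timeseries(path: str | Path, subject_id: str, group: str, tr: float,
                    region_order: Sequence[str] | None = None) -> SubjectTimeSeries:
    df = pd.read_csv(path, sep="\t")
    for j, col in enumerate(df.columns):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            row = int(vals.isna().idxmax())
            raise ValueError(
                f"subject {subject_id}: non-numeric cell at row {row}, column {col!r}"
            )
        df[col] = vals
    if region_order is not None:
        missing = set(region_order) - set(df.columns)
        extra = set(df.columns) - set(region_order)
        if missing or extra:
            raise ValueError(
                f"subject {subject_id}: region ids do not match the cohort "
                f"(missing {sorted(missing)[:3]}, unexpected {sorted(extra)[:3]})"
            )
        df = df[list(region_order)]
    return SubjectTimeSeries(subject_id, group, df.to_numpy(float), tr,
                             tuple(df.columns))


def write_manifest(path: str | Path, clinical: pd.DataFrame) -> None:
    clinical.to_csv(path, index=False)


def write_network_map(path: str | Path, nmap: NetworkMap) -> None:
    pd.DataFrame(
        {"region_id": list(nmap.labels), "network": list(nmap.labels.values())}
    ).to_csv(path, sep="\t", index=False)


def read_network_map(path: str | Path) -> NetworkMap:
    df = pd.read_csv(path, sep="\t")
    return NetworkMap(dict(zip(df["region_id"].astype(str), df["network"])))


def load_cohort(manifest_path: str | Path, timeseries_dir: str | Path,
                tr: float = 2.0) -> tuple[list[SubjectTimeSeries], pd.DataFrame]:
    """Load every subject listed in the manifest, in manifest order.

    The first subject's region ids define the canonical column order; later
    subjects with permuted columns are re-ordered, mismatching id sets are an
    error naming the offending subject.
    """
    manifest_path = Path(manifest_path)
    timeseries_dir = Path(timeseries_dir)
    clinical = pd.read_csv(manifest_path)
    missing_cols = [c for c in ("subject_id", "group") if c not in clinical.columns]
    if missing_cols:
        raise ValueError(f"manifest is missing required columns: {missing_cols}")
    subjects: list[SubjectTimeSeries] = []
    region_order: tuple[str, ...] | None = None
    for _, row in clinical.iterrows():
        sid = str(row["subject_id"])
        path = timeseries_dir / f"{sid}.tsv"
        if not path.exists():
            raise FileNotFoundError(f"time-series file missing for subject {sid}: {path}")
        ts = read_timeseries(path, sid, str(row["group"]), tr, region_order)
        if region_order is None:
            region_order = ts.region_ids
        subjects.append(ts)
    return subjects, clinical


# ---------------------------------------------------------------------------
# Conditioning
# ---------------------------------------------------------------------------

def detrend(ts: SubjectTimeSeries, order: int = 1) -> SubjectTimeSeries:
    """Remove a per-column least-squares polynomial trend of degree 0 or 1.

    Column means are zero afterwards; applying it twice is a no-op.
    """
    if order not in (0, 1):
        raise ValueError("order must be 0 or 1")
    T = ts.n_volumes
    if T <= order + 1:
        raise ValueError(f"need T > order+1, got T={T}")
    t = np.arange(T, dtype=float)
    X = np.vander(t, order + 1, increasing=True)  # [1] or [1, t]
    beta, *_ = np.linalg.lstsq(X, ts.data, rcond=None)
    return replace(ts, data=ts.data - X @ beta)


def bandpass(ts: SubjectTimeSeries, low: float = 0.01, high: float = 0.08,
             order: int = 4) -> SubjectTimeSeries:
    """Zero-phase Butterworth band-pass (default 0.01-0.08 Hz).

    Applied forward-backward (sosfiltfilt) so no phase is introduced; the
    effective attenuation order is 2x the design order.
    """
    fs = 1.0 / ts.tr
    nyq = fs / 2.0
    if not (0.0 < low < high):
        raise ValueError("need 0 < low < high")
    if high >= nyq:
        raise ValueError(f"high cutoff {high} Hz is at or above Nyquist {nyq} Hz")
    sos = sps.butter(order, [low, high], btype="band", fs=fs, output="sos")
    # sosfiltfilt needs T > padlen (its edge-transient pad)
    padlen = 3 * (2 * sos.shape[0] + 1 - min((sos[:, 2] == 0).sum(),
                                             (sos[:, 5] == 0).sum()))
    if ts.n_volumes <= padlen:
        raise ValueError(
            f"series too short for the filter transient: T={ts.n_volumes} <= {padlen}"
        )
    return replace(ts, data=sps.sosfiltfilt(sos, ts.data, axis=0))
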