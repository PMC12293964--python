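"""Seed-based network connectivity features from ROI time series.

The pipeline: average BOLD time series per atlas region, optional 0.01-0.1 Hz
zero-phase band-pass, Pearson correlation between every region pair, Fisher
z-transform (z = arctanh r), then unweighted averaging of z over region pairs
within one network configuration (intra) or across two configurations
(inter).  Feature names are ``intra|<net>:<scope>`` and
``inter|<netA>:<scopeA>|<netB>:<scopeB>`` with configurations in canonical
registry order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .registry import NetworkConfiguration, NetworkRegistry

logger = logging.getLogger(__name__)

#: Correlations are clipped to this magnitude before arctanh so degenerate
#: inputs (|r| = 1) map to a large but finite z.
R_CLIP = 1.0 - 1e-7


@dataclass
class RoiTimeSeriesSet:
    """A T x R matrix of region-averaged signals with its sampling interval.

    ``data[t, j]`` is the signal of region ``region_names[j]`` at timepoint
    ``t``; ``sampling_interval`` is the repetition time in seconds.
    """

    data: np.ndarray
    region_names: list[str]
    sampling_interval: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.region_names = list(self.region_names)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D (timepoints x regions) array")
        if self.data.shape[0] < 3:
            raise ValueError("need at least 3 timepoints")
        if self.data.shape[1] != len(self.region_names):
            raise ValueError(
                f"{self.data.shape[1]} columns but "
                f"{len(self.region_names)} region names"
            )
        if len(set(self.region_names)) != len(self.region_names):
            raise ValueError("region names must be unique")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("time series contain missing/non-finite values")
        if self.sampling_interval <= 0:
            raise ValueError("sampling_interval must be positive")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_regions(self) -> int:
        return self.data.shape[1]

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.data, columns=self.region_names).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def from_tsv(cls, path, sampling_interval: float) -> "RoiTimeSeriesSet":
        df = pd.read_csv(path, sep="\t")
        return cls(
            data=df.to_numpy(dtype=float),
            region_names=list(df.columns),
            sampling_interval=sampling_interval,
        )


# ---------------------------------------------------------------------------
# temporal filtering


def bandpass_filter(
    ts: RoiTimeSeriesSet,
    low: float = 0.01,
    high: float = 0.1,
    order: int = 4,
) -> RoiTimeSeriesSet:
    """Zero-phase Butterworth band-pass of every region's series.

    The default 0.01-0.1 Hz band isolates the low-frequency BOLD
    fluctuations used for resting-state connectivity.  Applied forward and
    backward (``sosfiltfilt``) so no phase shift is introduced.
    """
    nyquist = 1.0 / (2.0 * ts.sampling_interval)
    if not (0 < low < high):
        raise ValueError("need 0 < low < high")
    if high >= nyquist:
        raise ValueError(
            f"band edge {high} Hz is not below the Nyquist frequency "
            f"{nyquist:.4g} Hz; admissible band is (0, {nyquist:.4g}) Hz"
        )
    sos = signal.butter(
        order, [low, high], btype="bandpass", fs=1.0 / ts.sampling_interval,
        output="sos",
    )
    filtered = signal.sosfiltfilt(sos, ts.data, axis=0)
    return RoiTimeSeriesSet(
        data=filtered,
        region_names=list(ts.region_names),
        sampling_interval=ts.sampling_interval,
    )


# ---------------------------------------------------------------------------
# ROI extraction


def extract_roi_timeseries(
    image4d: np.ndarray,
    labels: np.ndarray,
    region_map: dict[int, str],
    sampling_interval: float,
) -> RoiTimeSeriesSet:
    """Average the 4-D image over each labelled ROI.

    ``image4d`` is (X, Y, Z, T); ``labels`` an integer (X, Y, Z) volume;
    ``region_map`` maps label values to region names.  Nonzero labels absent
    from the map are ignored (with a logged count); a mapped label missing
    from the volume is an error.
    """
    image4d = np.asarray(image4d, dtype=float)
    labels = np.asarray(labels)
    if image4d.ndim != 4:
        raise ValueError("image must be 4-D (x, y, z, t)")
    if labels.shape != image4d.shape[:3]:
        raise ValueError(
            f"label grid {labels.shape} does not match image grid "
            f"{image4d.shape[:3]}"
        )
    present = set(np.unique(labels).tolist()) - {0}
    mapped = set(region_map)
    missing = sorted(mapped - present)
    if missing:
        raise ValueError(f"mapped labels absent from label volume: {missing}")
    unmapped = present - mapped
    if unmapped:
        logger.info("ignoring %d unmapped nonzero labels", len(unmapped))
    names, series = [], []
    for label, name in region_map.items():
        voxels = image4d[labels == label]  # (n_voxels, T)
        names.append(name)
        series.append(voxels.mean(axis=0))
    return RoiTimeSeriesSet(
        data=np.column_stack(series),
        region_names=names,
        sampling_interval=sampling_interval,
    )


# ---------------------------------------------------------------------------
# correlation and Fisher z


def correlation_matrix(ts: RoiTimeSeriesSet) -> pd.DataFrame:
    """Pearson correlation between every pair of region series."""
    sd = ts.data.std(axis=0)
    dead = [n for n, s in zip(ts.region_names, sd) if s == 0]
    if dead:
        raise ValueError(f"zero-variance region(s): {dead}")
    r = np.corrcoef(ts.data, rowvar=False)
    np.fill_diagonal(r, 1.0)
    return pd.DataFrame(r, index=ts.region_names, columns=ts.region_names)


def fisher_z(r):
    """Variance-stabilizing Fisher transform z = arctanh(r).

    ``|r|`` is clipped to ``1 - 1e-7`` so perfectly correlated pairs stay
    finite; magnitudes beyond 1 (allowing 1e-12 rounding slack) are rejected.
    """
    arr = np.asarray(r, dtype=float)
    if np.any(np.abs(arr) > 1.0 + 1e-12):
        raise ValueError("correlation magnitude exceeds 1")
    z = np.arctanh(np.clip(arr, -R_CLIP, R_CLIP))
    return z if arr.ndim else float(z)


def fisher_z_matrix(corr: pd.DataFrame) -> pd.DataFrame:
    return pd.DataFrame(
        fisher_z(corr.to_numpy()), index=corr.index, columns=corr.columns
    )


# ---------------------------------------------------------------------------
# network aggregation


def _indices(names: list[str]) -> dict[str, int]:
    return {n: i for i, n in enumerate(names)}


def intra_network_connectivity(
    zmatrix: pd.DataFrame, config: NetworkConfiguration
) -> float:
    """Mean z over all unordered pairs of the configuration's members."""
    members = config.member_regions
    if len(members) < 2:
        raise ValueError(
            f"configuration {config.name} has a single member: no pairs"
        )
    missing = [m for m in members if m not in zmatrix.index]
    if missing:
        raise ValueError(f"regions missing from z-matrix: {missing}")
    idx = [zmatrix.index.get_loc(m) for m in members]
    z = zmatrix.to_numpy()
    rows, cols = zip(
        *[(idx[i], idx[j]) for i in range(len(idx)) for j in range(i + 1, len(idx))]
    )
    return float(z[list(rows), list(cols)].mean())


def inter_network_connectivity(
    zmatrix: pd.DataFrame,
    config_a: NetworkConfiguration,
    config_b: NetworkConfiguration,
) -> float:
    """Mean z over all cross pairs (a in A, b in B), excluding self-pairs.

    Configurations may share regions (networks overlap, and the ``both``
    scope contains each single-hemisphere scope); a pair of one region with
    itself has r = 1 and infinite z, so identical-region pairs are dropped.
    Overlapping-but-distinct pairs are kept.
    """
    if config_a.name == config_b.name:
        raise ValueError("inter-network connectivity needs two distinct configurations")
    for cfg in (config_a, config_b):
        missing = [m for m in cfg.member_regions if m not in zmatrix.index]
        if missing:
            raise ValueError(f"regions missing from z-matrix: {missing}")
    loc = {n: zmatrix.index.get_loc(n) for n in zmatrix.index}
    pairs = [
        (loc[a], loc[b])
        for a in config_a.member_regions
        for b in config_b.member_regions
        if a != b
    ]
    if not pairs:
        raise ValueError(
            f"no cross pairs remain between {config_a.name} and "
            f"{config_b.name} after excluding shared-region self-pairs"
        )
    z = zmatrix.to_numpy()
    rows, cols = zip(*pairs)
    return float(z[list(rows), list(cols)].mean())


# ---------------------------------------------------------------------------
# full feature vector


def feature_names(registry: NetworkRegistry) -> list[str]:
    """Canonical feature ordering: all intra, then all inter pairs (i < j)."""
    configs = registry.configurations()
    names = [f"intra|{c.name}" for c in configs]
    for i in range(len(configs)):
        for j in range(i + 1, len(configs)):
            names.append(f"inter|{configs[i].name}|{configs[j].name}")
    return names


@dataclass
class _FeaturePlan:
    names: list[str]
    rows: list[np.ndarray]
    cols: list[np.ndarray]


_PLAN_CACHE: dict[tuple, _FeaturePlan] = {}


def _feature_plan(
    registry: NetworkRegistry, region_names: tuple[str, ...]
) -> _FeaturePlan:
    key = (registry.cache_key(), region_names)
    plan = _PLAN_CACHE.get(key)
    if plan is not None:
        return plan
    loc = _indices(list(region_names))
    configs = registry.configurations()
    missing = sorted(
        {m for c in configs for m in c.member_regions} - set(region_names)
    )
    if missing:
        raise ValueError(f"registry regions missing from time series: {missing}")
    names: list[str] = []
    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    for c in configs:
        if len(c.member_regions) < 2:
            raise ValueError(f"configuration {c.name} has fewer than 2 members")
        idx = [loc[m] for m in c.member_regions]
        pr, pc = zip(
            *[
                (idx[i], idx[j])
                for i in range(len(idx))
                for j in range(i + 1, len(idx))
            ]
        )
        names.append(f"intra|{c.name}")
        rows.append(np.asarray(pr))
        cols.append(np.asarray(pc))
    for i in range(len(configs)):
        for j in range(i + 1, len(configs)):
            a, b = configs[i], configs[j]
            pairs = [
                (loc[x], loc[y])
                for x in a.member_regions
                for y in b.member_regions
                if x != y
            ]
            if not pairs:
                raise ValueError(
                    f"no cross pairs between {a.name} and {b.name}"
                )
            pr, pc = zip(*pairs)
            names.append(f"inter|{a.name}|{b.name}")
            rows.append(np.asarray(pr))
            cols.append(np.asarray(pc))
    plan = _FeaturePlan(names=names, rows=rows, cols=cols)
    _PLAN_CACHE[key] = plan
    return plan


def build_feature_vector(
    ts: RoiTimeSeriesSet, registry: NetworkRegistry
) -> pd.Series:
    """All intra- and inter-network z-features of one subject.

    Returns an ordered Series of length C + C(C-1)/2 where C is the number
    of network configurations (171 under the default registry).
    """
    plan = _feature_plan(registry, tuple(ts.region_names))
    corr = correlation_matrix(ts).to_numpy()
    z = np.arctanh(np.clip(corr, -R_CLIP, R_CLIP))
    values = [float(z[r, c].mean()) for r, c in zip(plan.rows, plan.cols)]
    return pd.Series(values, index=plan.names, name="connectivity")
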