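"""Synthetic stroke cohorts with the statistical structure the analysis
assumes.

Each subject's ROI signals are drawn from a stationary zero-mean multivariate
normal whose correlation matrix places ``within_network_r`` on every pair of
regions belonging to a common network and ``between_network_r`` elsewhere.
Lesions degrade connectivity in the *affected networks* only (default: the
primary-motor and basal-ganglia motor networks, matching a subcortical
motor stroke).  Each affected network's within-network correlations are
attenuated linearly by a lesion impact score — a weighted mix of lesion
volume and an independent per-network severity (``damping_lesion_weight``)
— so degradation is coupled to, but not a deterministic function of,
lesion size.  Damage is lateralized: each subject has a stroke side, and
attenuation falls mostly on within-hemisphere region pairs of that side,
with a weaker effect on interhemispheric pairs
(``interhemispheric_damping``).  NIHSS is generated by a
linear model on named pipeline predictors (lesion volume and connectivity
features) with Gaussian noise.

Randomness is fully reproducible: one master seed, with per-subject streams
derived through ``numpy.random.SeedSequence`` spawn keys so that growing the
cohort never reshuffles earlier subjects.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from .connectivity import RoiTimeSeriesSet, build_feature_vector, feature_names
from .lesion import LesionMask
from .registry import NetworkRegistry, default_registry

#: Default NIHSS model: severity rises with lesion volume and with loss of
#: motor-network coherence (negative slopes on connectivity z-features);
#: left-hemisphere coherence weighs more, reflecting the dominance of the
#: left hemisphere in skilled movement.
DEFAULT_OUTCOME_COEFFICIENTS: dict[str, float] = {
    "intercept": 11.0,
    "lesion_volume": 2.5e-4,
    "intra|MotorI:left": -10.0,
    "intra|MotorI:right": -5.0,
    "intra|MotorIV:left": -7.0,
}


@dataclass
class SimulationConfig:
    """Study conditions for a synthetic cohort.

    Defaults emulate an acute subcortical stroke cohort: 44 subjects, 260
    EPI volumes at TR 1.78 s, moderate within-network coupling (r = 0.4)
    over a weaker global background (r = 0.2; the networks overlap, so a
    large within/between gap would violate positive definiteness),
    subcortical lesion volumes of 0.1-20 cm^3, and NIHSS on the
    mild-to-moderate 0-14 range.
    """

    n_subjects: int = 44
    n_timepoints: int = 260
    sampling_interval: float = 1.78  # seconds (TR)
    within_network_r: float | Mapping[str, float] = 0.4
    between_network_r: float = 0.2
    lesion_volume_range: tuple[float, float] = (100.0, 20000.0)  # mm^3
    connectivity_damping_slope: float = 1.5e-5  # fraction of within-r per mm^3
    damping_lesion_weight: float = 0.4  # volume share of the impact score
    affected_networks: tuple[str, ...] = ("MotorI", "MotorIV")
    interhemispheric_damping: float = 0.25  # damping share on cross-hemisphere pairs
    p_left_lesion: float = 0.57  # probability of a left-hemispheric stroke
    ar1_phi: float = 0.0  # optional temporal autocorrelation
    outcome_coefficients: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_OUTCOME_COEFFICIENTS)
    )
    noise_sd: float = 2.0  # NIHSS points
    target_design_r2: float | None = None  # calibrate noise_sd to this R2
    integer_outcome: bool = False  # round and clip NIHSS to [0, 14]
    registry: NetworkRegistry = field(default_factory=default_registry)
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ----------------------------------------------------------

    def _within_r(self, network: str) -> float:
        if isinstance(self.within_network_r, Mapping):
            return float(self.within_network_r[network])
        return float(self.within_network_r)

    def max_attenuation(self) -> float:
        # impact score is a convex combination of two draws from the volume
        # range, so attenuation is bounded by slope * v_max
        return self.connectivity_damping_slope * self.lesion_volume_range[1]

    def validate(self) -> None:
        if self.n_subjects < 5:
            raise ValueError("n_subjects must be at least the number of CV folds (5)")
        if self.n_timepoints < 3:
            raise ValueError("need at least 3 timepoints")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.target_design_r2 is not None and not (
            0 < self.target_design_r2 < 1
        ):
            raise ValueError("target_design_r2 must lie in (0, 1)")
        if not -1 < self.between_network_r < 1:
            raise ValueError("between_network_r must lie in (-1, 1)")
        for net in self.registry.networks:
            r = self._within_r(net)
            if not -1 < r < 1:
                raise ValueError(
                    f"within_network_r for network {net!r} must lie in (-1, 1)"
                )
        if not 0 <= self.damping_lesion_weight <= 1:
            raise ValueError("damping_lesion_weight must lie in [0, 1]")
        if not 0 <= abs(self.ar1_phi) < 1:
            raise ValueError("ar1_phi must lie in (-1, 1)")
        lo, hi = self.lesion_volume_range
        if not 0 <= lo <= hi:
            raise ValueError("lesion_volume_range must be a non-negative interval")
        unknown = sorted(set(self.affected_networks) - set(self.registry.networks))
        if unknown:
            raise ValueError(f"affected networks not in registry: {unknown}")
        if not 0 <= self.interhemispheric_damping <= 1:
            raise ValueError("interhemispheric_damping must lie in [0, 1]")
        if not 0 <= self.p_left_lesion <= 1:
            raise ValueError("p_left_lesion must lie in [0, 1]")
        if self.max_attenuation() >= 1.0:
            raise ValueError(
                "connectivity damping exceeds 100% attenuation at the largest "
                "lesion; reduce connectivity_damping_slope or the volume range"
            )
        # per-block necessary condition, naming the offending network
        worst = 1.0 - self.max_attenuation()
        for net in self.registry.networks:
            m = len(self.registry.lateralized_members(net, "both"))
            r = self._within_r(net)
            r_min = min(r, r * worst)
            if m > 1 and r_min <= -1.0 / (m - 1):
                raise ValueError(
                    f"within-network correlation {r_min:.3f} makes the "
                    f"{net!r} block non-positive-definite (size {m})"
                )
        # PD check of the implied correlation matrix at damping extremes
        a_max = self.max_attenuation()
        extremes = [({n: 0.0 for n in self.affected_networks}, 0.5)] + [
            ({n: a_max for n in self.affected_networks}, lam)
            for lam in (0.0, 0.5, 1.0)
        ]
        for atten, lam in extremes:
            self._check_positive_definite(atten, lam)

    def _check_positive_definite(
        self, atten_by_network: Mapping[str, float], laterality: float
    ) -> None:
        corr = _target_correlation(self, atten_by_network, laterality)
        try:
            np.linalg.cholesky(corr)
        except np.linalg.LinAlgError:
            eigmin = float(np.linalg.eigvalsh(corr).min())
            raise ValueError(
                "implied whole-brain correlation matrix is not positive "
                f"definite (min eigenvalue {eigmin:.3g}) at attenuation "
                f"{atten_by_network} with laterality {laterality:.2f}; "
                "adjust within/between correlations or the damping"
            ) from None


def _target_correlation(
    config: SimulationConfig,
    atten_by_network: Mapping[str, float],
    laterality: float,
) -> np.ndarray:
    """Implied R x R correlation matrix under per-network attenuation.

    ``laterality`` is the share of damage on the left hemisphere: left-left
    pairs of an affected network are attenuated by ``atten * laterality``,
    right-right pairs by ``atten * (1 - laterality)`` and cross-hemisphere
    pairs by ``atten * interhemispheric_damping``.
    """
    regions = config.registry.all_regions()
    loc = {r: i for i, r in enumerate(regions)}
    n = len(regions)
    corr = np.full((n, n), config.between_network_r, dtype=float)
    for net in config.registry.networks:
        bases = config.registry.networks[net]
        left = np.array([loc[config.registry.lateralization[b][0]] for b in bases])
        right = np.array([loc[config.registry.lateralization[b][1]] for b in bases])
        r = config._within_r(net)
        atten = float(atten_by_network.get(net, 0.0))
        r_ll = r * (1.0 - atten * laterality)
        r_rr = r * (1.0 - atten * (1.0 - laterality))
        r_lr = r * (1.0 - atten * config.interhemispheric_damping)
        # overlapping networks: a pair keeps the strongest claim on it
        for idx_a, idx_b, val in (
            (left, left, r_ll),
            (right, right, r_rr),
            (left, right, r_lr),
            (right, left, r_lr),
        ):
            block = corr[np.ix_(idx_a, idx_b)]
            corr[np.ix_(idx_a, idx_b)] = np.maximum(block, val)
    np.fill_diagonal(corr, 1.0)
    return corr


# ---------------------------------------------------------------------------
# per-subject random streams


def _subject_rng(seed: int, subject_index: int, stream: int) -> np.random.Generator:
    """Stable per-subject stream: independent of cohort size and of draws
    made for other subjects."""
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(subject_index, stream))
    )


_STREAM_VOLUME = 0
_STREAM_TIMESERIES = 1
_STREAM_SUSCEPTIBILITY = 2
_STREAM_OUTCOME = 3
_STREAM_MASK = 4


def subject_lesion_volume(config: SimulationConfig, subject_index: int) -> float:
    """Lesion volume in mm^3, uniform over the configured range and rounded
    to whole cubic millimeters (achievable on a 1 mm isotropic grid)."""
    rng = _subject_rng(config.seed, subject_index, _STREAM_VOLUME)
    lo, hi = config.lesion_volume_range
    return float(np.round(rng.uniform(lo, hi)))


def _subject_damage(
    config: SimulationConfig, subject_index: int
) -> tuple[float, dict[str, float]]:
    """(laterality, attenuation per affected network) for one subject.

    Strokes are unilateral: a left-hemispheric stroke (probability
    ``p_left_lesion``) puts 75-100% of the damage on the left hemisphere, a
    right stroke 0-25%.  Each affected network's attenuation is the damping
    slope times an impact score ``weight * volume + (1 - weight) *
    severity``, with an independent per-network severity draw: equally
    sized lesions can hit networks unequally depending on location.
    """
    rng = _subject_rng(config.seed, subject_index, _STREAM_SUSCEPTIBILITY)
    left_side = rng.random() < config.p_left_lesion
    spread = rng.uniform(0.0, 0.25)
    laterality = float(1.0 - spread if left_side else spread)
    lo, hi = config.lesion_volume_range
    w = config.damping_lesion_weight
    volume = subject_lesion_volume(config, subject_index)
    atten = {}
    for net in config.affected_networks:
        severity = rng.uniform(lo, hi)
        impact = w * volume + (1.0 - w) * severity
        atten[net] = config.connectivity_damping_slope * impact
    return laterality, atten


def subject_laterality(config: SimulationConfig, subject_index: int) -> float:
    """Share of network damage on the left hemisphere."""
    return _subject_damage(config, subject_index)[0]


def subject_network_attenuations(
    config: SimulationConfig, subject_index: int
) -> dict[str, float]:
    """Attenuation of each affected network's within-correlation."""
    return _subject_damage(config, subject_index)[1]


def simulate_roi_timeseries(
    config: SimulationConfig, subject_index: int
) -> RoiTimeSeriesSet:
    """Draw one subject's T x R matrix from the implied block covariance.

    Deterministic given ``(config.seed, subject_index)``.  With
    ``ar1_phi != 0`` the series follow a first-order autoregression whose
    innovations carry the block covariance; the marginal correlation
    structure is unchanged.
    """
    if not 0 <= subject_index < config.n_subjects:
        raise ValueError(
            f"subject_index {subject_index} outside cohort of "
            f"{config.n_subjects}"
        )
    laterality, atten = _subject_damage(config, subject_index)
    corr = _target_correlation(config, atten, laterality)
    try:
        chol = np.linalg.cholesky(corr)
    except np.linalg.LinAlgError:
        raise ValueError(
            "subject-level damped correlation matrix is not positive "
            "definite; the configuration should have been rejected"
        ) from None
    rng = _subject_rng(config.seed, subject_index, _STREAM_TIMESERIES)
    T, R = config.n_timepoints, corr.shape[0]
    innov = rng.standard_normal((T, R)) @ chol.T
    phi = config.ar1_phi
    if phi != 0.0:
        data = np.empty_like(innov)
        scale = np.sqrt(1.0 - phi**2)
        data[0] = innov[0]
        for t in range(1, T):
            data[t] = phi * data[t - 1] + scale * innov[t]
    else:
        data = innov
    return RoiTimeSeriesSet(
        data=data,
        region_names=config.registry.all_regions(),
        sampling_interval=config.sampling_interval,
    )


# ---------------------------------------------------------------------------
# cohort assembly


@dataclass
class SimulationTruth:
    """Generating coefficients and the design-level (population) R-squared."""

    coefficients: dict[str, float]  # includes "intercept"
    noise_sd: float
    design_r2: float
    linear_predictor: np.ndarray

    def to_json(self, path) -> None:
        payload = {
            "coefficients": self.coefficients,
            "noise_sd": self.noise_sd,
            "design_r2": self.design_r2,
            "linear_predictor": self.linear_predictor.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


@dataclass
class SyntheticCohort:
    table: pd.DataFrame  # subject_id, lesion_volume, features..., nihss
    timeseries: list[RoiTimeSeriesSet]
    lesion_masks: list[LesionMask] | None
    truth: SimulationTruth


def simulate_cohort(
    config: SimulationConfig, include_masks: bool = False
) -> SyntheticCohort:
    """Generate the full cohort table: lesion volume, the complete
    connectivity feature vector per subject, and the NIHSS outcome.

    With ``target_design_r2`` set, the noise standard deviation is
    calibrated so that var(linear predictor) / var(outcome) equals the
    target on this design.  With ``noise_sd = 0`` the truth coefficients
    reproduce every outcome exactly.
    """
    names = feature_names(config.registry)
    coefs = dict(config.outcome_coefficients)
    intercept = float(coefs.pop("intercept", 0.0))
    available = {"lesion_volume", *names}
    unknown = sorted(set(coefs) - available)
    if unknown:
        raise ValueError(
            f"outcome_coefficients reference unknown predictors {unknown}; "
            f"available: lesion_volume plus {len(names)} connectivity "
            "features such as " + ", ".join(names[:3])
        )

    rows, ts_list, masks = [], [], []
    for i in range(config.n_subjects):
        volume = subject_lesion_volume(config, i)
        ts = simulate_roi_timeseries(config, i)
        features = build_feature_vector(ts, config.registry)
        rows.append({"lesion_volume": volume, **features.to_dict()})
        ts_list.append(ts)
        if include_masks:
            masks.append(
                make_lesion_mask(
                    target_volume=volume,
                    grid_shape=(64, 64, 64),
                    voxel_dims=(1.0, 1.0, 1.0),
                    seed=int(
                        _subject_rng(config.seed, i, _STREAM_MASK).integers(
                            2**31
                        )
                    ),
                )
            )
    table = pd.DataFrame(rows)
    table.insert(
        0,
        "subject_id",
        [f"sub-{i + 1:03d}" for i in range(config.n_subjects)],
    )

    eta = np.full(config.n_subjects, intercept)
    for name, beta in coefs.items():
        eta += beta * table[name].to_numpy(dtype=float)

    var_eta = float(np.var(eta))
    if config.target_design_r2 is not None:
        rho = config.target_design_r2
        if var_eta == 0:
            raise ValueError(
                "cannot calibrate noise to a design R2 target: the linear "
                "predictor has zero variance"
            )
        noise_sd = float(np.sqrt(var_eta * (1.0 - rho) / rho))
    else:
        noise_sd = config.noise_sd
    design_r2 = (
        1.0 if noise_sd == 0 and var_eta > 0
        else var_eta / (var_eta + noise_sd**2) if var_eta + noise_sd**2 > 0
        else 0.0
    )

    eps = np.array(
        [
            _subject_rng(config.seed, i, _STREAM_OUTCOME).normal(0.0, noise_sd)
            if noise_sd > 0
            else 0.0
            for i in range(config.n_subjects)
        ]
    )
    nihss = eta + eps
    if config.integer_outcome:
        nihss = np.clip(np.round(nihss), 0, 14)
    table["nihss"] = nihss

    truth = SimulationTruth(
        coefficients={"intercept": intercept, **coefs},
        noise_sd=noise_sd,
        design_r2=float(design_r2),
        linear_predictor=eta,
    )
    return SyntheticCohort(
        table=table,
        timeseries=ts_list,
        lesion_masks=masks if include_masks else None,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# lesion masks and toy volumetric images


_NEIGHBORS = np.array(
    [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]]
)


def make_lesion_mask(
    target_volume: float,
    grid_shape: tuple[int, int, int],
    voxel_dims: tuple[float, float, float] = (1.0, 1.0, 1.0),
    seed: int = 0,
) -> LesionMask:
    """Grow a single 6-connected blob of exactly
    ``target_volume / voxel_volume`` voxels from the grid center."""
    voxel_volume = float(np.prod(voxel_dims))
    n_voxels_f = target_volume / voxel_volume
    n_voxels = int(round(n_voxels_f))
    if abs(n_voxels_f - n_voxels) > 1e-9:
        raise ValueError(
            f"target volume {target_volume} mm^3 is not a multiple of the "
            f"voxel volume {voxel_volume} mm^3; nearest achievable volume is "
            f"{n_voxels * voxel_volume} mm^3"
        )
    capacity = int(np.prod(grid_shape))
    if n_voxels > capacity:
        raise ValueError(
            f"target volume needs {n_voxels} voxels but the grid holds only "
            f"{capacity}; nearest achievable volume is "
            f"{capacity * voxel_volume} mm^3"
        )
    grid = np.zeros(grid_shape, dtype=np.uint8)
    if n_voxels == 0:
        return LesionMask(grid=grid, voxel_dims=voxel_dims, space_label="synthetic")
    rng = np.random.default_rng(seed)
    start = tuple(s // 2 for s in grid_shape)
    grid[start] = 1
    frontier = [start]
    placed = 1
    shape = np.array(grid_shape)
    while placed < n_voxels:
        # random frontier voxel; extend into a random free neighbor
        j = rng.integers(len(frontier))
        vox = np.array(frontier[j])
        nbrs = vox + _NEIGHBORS
        ok = np.all((nbrs >= 0) & (nbrs < shape), axis=1)
        free = [tuple(p) for p in nbrs[ok] if grid[tuple(p)] == 0]
        if not free:
            frontier.pop(j)
            if not frontier:  # cannot happen while placed < capacity
                raise RuntimeError("lesion growth stalled")
            continue
        new = free[rng.integers(len(free))]
        grid[new] = 1
        frontier.append(new)
        placed += 1
    return LesionMask(grid=grid, voxel_dims=voxel_dims, space_label="synthetic")


@dataclass
class ToyImageSet:
    """In-memory volumetric rendering of a synthetic cohort."""

    images: list[nib.Nifti1Image]  # one 4-D image per subject
    label_volume: nib.Nifti1Image
    region_labels: dict[str, int]  # region name -> integer label

    def write(self, out_dir) -> None:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        nib.save(self.label_volume, str(out / "labels.nii.gz"))
        for i, img in enumerate(self.images):
            nib.save(img, str(out / f"sub-{i + 1:03d}_bold.nii.gz"))
        with open(out / "region_labels.json", "w") as fh:
            json.dump(self.region_labels, fh, indent=2)


def default_atlas_layout(
    region_names: Sequence[str], block_shape: tuple[int, int, int] = (2, 2, 2)
) -> dict[str, tuple[slice, slice, slice]]:
    """Disjoint cubic voxel blocks for each region on a compact grid."""
    n = len(region_names)
    per_axis = int(np.ceil(n ** (1.0 / 3.0)))
    layout = {}
    for i, name in enumerate(region_names):
        x, rem = divmod(i, per_axis * per_axis)
        y, z = divmod(rem, per_axis)
        layout[name] = (
            slice(x * block_shape[0], (x + 1) * block_shape[0]),
            slice(y * block_shape[1], (y + 1) * block_shape[1]),
            slice(z * block_shape[2], (z + 1) * block_shape[2]),
        )
    return layout


def render_toy_dataset(
    cohort: SyntheticCohort,
    atlas_layout: Mapping[str, tuple[slice, slice, slice]] | None = None,
    voxel_noise_sd: float = 0.0,
    seed: int = 0,
    out_dir=None,
) -> ToyImageSet:
    """Render each subject as a 4-D image where every voxel of a region's
    block carries that region's time series (plus optional i.i.d. voxel
    noise), with one shared integer label volume.

    Averaging the voxels of each region recovers the input series, so the
    rendering is a round-trip fixture for ROI extraction.
    """
    region_names = cohort.timeseries[0].region_names
    if atlas_layout is None:
        atlas_layout = default_atlas_layout(region_names)
    missing = [r for r in region_names if r not in atlas_layout]
    if missing:
        raise ValueError(f"atlas layout missing regions: {missing}")

    # grid size from the layout; verify blocks are disjoint
    stops = np.array(
        [[sl.stop for sl in atlas_layout[r]] for r in region_names]
    )
    grid_shape = tuple(int(s) for s in stops.max(axis=0))
    occupancy = np.zeros(grid_shape, dtype=np.int32)
    labels = np.zeros(grid_shape, dtype=np.int16)
    region_labels = {}
    for i, name in enumerate(region_names, start=1):
        occupancy[atlas_layout[name]] += 1
        labels[atlas_layout[name]] = i
        region_labels[name] = i
    if occupancy.max() > 1:
        raise ValueError("atlas layout blocks overlap")

    rng = np.random.default_rng(seed)
    affine = np.eye(4)
    images = []
    T = cohort.timeseries[0].n_timepoints
    for ts in cohort.timeseries:
        vol = np.zeros((*grid_shape, T), dtype=np.float32)
        for name in region_names:
            series = ts.data[:, ts.region_names.index(name)]
            block = atlas_layout[name]
            vol[block] = series.astype(np.float32)
            if voxel_noise_sd > 0:
                vol[block] += rng.normal(
                    0.0, voxel_noise_sd, size=vol[block].shape
                ).astype(np.float32)
        images.append(nib.Nifti1Image(vol, affine))
    toy = ToyImageSet(
        images=images,
        label_volume=nib.Nifti1Image(labels, affine),
        region_labels=region_labels,
    )
    if out_dir is not None:
        toy.write(out_dir)
    return toy
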