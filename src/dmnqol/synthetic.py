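"""Synthetic cohorts of DMN-like ROI time series and QoL scores.

Real resting-state recordings for this population are not redistributable,
so the package ships a generator with the statistical structure the
analysis assumes: band-limited, block-correlated multivariate series over
the three DMN subnetworks (6 + 6 + 12 ROIs), two groups that differ in the
level and the *spread* of their connectivity parameters (the clinical group
is modelled as hyper-connected and more heterogeneous), and QoL scores with
a configurable planted dependence on the complexity indicators (negative
slopes for complexity, positive for stability).

The signal model is deliberately minimal: zero-mean Gaussian innovations
with a block covariance, colored by a first-order autoregression, plus
white measurement noise.  A single cohort seed expands into independent
per-subject streams through ``SeedSequence`` spawn keys, so adding or
removing subjects never perturbs the draws of the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ParameterError, SchemaError
from .io_formats import QOL_DIMENSIONS, ROITimeSeriesSet, load_dmn_roi_scheme
from .metrics import INDICATORS, ComplexityProfile, profiles_to_frame

__all__ = [
    "CohortConfig",
    "GroupSpec",
    "QoLGenSpec",
    "SubnetworkSpec",
    "gen_cohort",
    "gen_qol_table",
    "gen_subject_timeseries",
    "make_block_covariance",
]


@dataclass
class SubnetworkSpec:
    """Block-correlation structure over the three DMN subnetworks.

    ``r_within`` is the correlation between ROIs of the same subnetwork,
    ``r_between`` across subnetworks.  Validity (positive semi-definite
    block covariance) is checked at construction.
    """

    sizes: tuple[int, int, int] = (6, 6, 12)
    r_within: float = 0.5
    r_between: float = 0.1

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.sizes):
            raise ParameterError("subnetwork sizes must be positive")
        for name in ("r_within", "r_between"):
            if not -1.0 < getattr(self, name) < 1.0:
                raise ParameterError(f"{name} must lie in (-1, 1)")
        cov = _block_covariance(self.sizes, self.r_within, self.r_between)
        smallest = float(np.linalg.eigvalsh(cov)[0])
        if smallest < -1e-10:
            raise ParameterError(
                f"block covariance is not PSD (smallest eigenvalue "
                f"{smallest:.4g})"
            )


def _block_covariance(
    sizes: Sequence[int], r_within: float, r_between: float
) -> np.ndarray:
    n = int(sum(sizes))
    cov = np.full((n, n), r_between)
    start = 0
    for s in sizes:
        cov[start : start + s, start : start + s] = r_within
        start += s
    np.fill_diagonal(cov, 1.0)
    return cov


def make_block_covariance(spec: SubnetworkSpec) -> np.ndarray:
    """Unit-diagonal block covariance matrix implied by ``spec``."""
    return _block_covariance(spec.sizes, spec.r_within, spec.r_between)


def _safe_cholesky(cov: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        w, v = np.linalg.eigh(cov)
        if w[0] < -1e-8:
            raise ParameterError(
                f"covariance is not PSD (smallest eigenvalue {w[0]:.4g})"
            )
        return v @ np.diag(np.sqrt(np.clip(w, 0.0, None)))


def gen_subject_timeseries(
    cov: np.ndarray,
    time_points: int = 220,
    ar_coefficient: float = 0.3,
    seed: int | np.random.SeedSequence = 0,
    noise_sd: float = 0.0,
    subject_id: str = "subject",
    tr_seconds: float = 2.0,
    roi_labels: Sequence[str] | None = None,
) -> ROITimeSeriesSet:
    """Draw one subject's ROI x time matrix.

    x_t = phi x_{t-1} + e_t with e_t ~ N(0, cov) and a stationary start, so
    the cross-ROI *correlation* matrix of the process equals the
    correlation matrix of ``cov`` for any |phi| < 1.  Optional white noise
    of standard deviation ``noise_sd`` is added on top (attenuating the
    observed correlations, as measurement noise does).  Identical seeds
    give bit-identical output.
    """
    cov = np.asarray(cov, dtype=float)
    if time_points < 2:
        raise ParameterError("time_points must be >= 2")
    if not 0.0 <= ar_coefficient < 1.0:
        raise ParameterError("ar_coefficient must lie in [0, 1)")
    chol = _safe_cholesky(cov)
    rng = np.random.default_rng(seed)
    n = cov.shape[0]
    innovations = chol @ rng.standard_normal((n, time_points))
    x = np.empty((n, time_points))
    x[:, 0] = innovations[:, 0] / np.sqrt(1.0 - ar_coefficient**2)
    for t in range(1, time_points):
        x[:, t] = ar_coefficient * x[:, t - 1] + innovations[:, t]
    if noise_sd > 0:
        x = x + noise_sd * rng.standard_normal((n, time_points))
    if roi_labels is None:
        scheme = load_dmn_roi_scheme()
        roi_labels = (
            list(scheme["region_name"]) if n == len(scheme) else None
        )
    return ROITimeSeriesSet(
        subject_id=subject_id,
        values=x,
        tr_seconds=tr_seconds,
        roi_labels=roi_labels or [f"ROI{i}" for i in range(n)],
    )


@dataclass
class GroupSpec:
    """Distribution of per-subject connectivity parameters for one group."""

    mean_r_within: float = 0.45
    sd_r_within: float = 0.04
    mean_r_between: float = 0.10
    sd_r_between: float = 0.03

    def __post_init__(self) -> None:
        if self.sd_r_within < 0 or self.sd_r_between < 0:
            raise ParameterError("spreads must be nonnegative")


@dataclass
class CohortConfig:
    """Two-group cohort settings.

    Defaults emulate the study conditions: 22 + 22 subjects, 24 ROIs in
    three subnetworks, 220 retained volumes at TR = 2 s.  Group B stands
    in for the clinical (Down syndrome) group: higher mean connectivity
    (hyper-connectivity) and a 3x larger spread of the connectivity
    parameters (greater inter-individual variability).
    """

    n_group_a: int = 22
    n_group_b: int = 22
    group_a: GroupSpec = field(default_factory=GroupSpec)
    group_b: GroupSpec = field(
        default_factory=lambda: GroupSpec(
            mean_r_within=0.55,
            sd_r_within=0.12,
            mean_r_between=0.20,
            sd_r_between=0.09,
        )
    )
    sizes: tuple[int, int, int] = (6, 6, 12)
    time_points: int = 220
    ar_coefficient: float = 0.3
    noise_sd: float = 0.5
    tr_seconds: float = 2.0
    label_a: str = "control"
    label_b: str = "ds"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_group_a <= 0 or self.n_group_b <= 0:
            raise ParameterError("group sizes must be positive")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be nonnegative")


def _draw_subject_spec(
    group: GroupSpec, sizes: tuple[int, int, int], rng: np.random.Generator
) -> SubnetworkSpec:
    """Truncated-normal draw of (r_within, r_between), kept PSD-valid."""
    for _ in range(200):
        r_w = rng.normal(group.mean_r_within, group.sd_r_within)
        r_b = rng.normal(group.mean_r_between, group.sd_r_between)
        if not (-0.99 < r_w < 0.99 and -0.99 < r_b < 0.99):
            continue
        try:
            return SubnetworkSpec(sizes=sizes, r_within=r_w, r_between=r_b)
        except ParameterError:
            continue
    return SubnetworkSpec(
        sizes=sizes,
        r_within=group.mean_r_within,
        r_between=group.mean_r_between,
    )


def gen_cohort(
    config: CohortConfig | None = None,
) -> list[tuple[ROITimeSeriesSet, str]]:
    """Generate the full two-group cohort, reproducibly by seed.

    Subject i's randomness comes from ``SeedSequence(config.seed,
    spawn_key=(i,))``, so per-subject draws are independent of cohort
    composition.
    """
    config = config or CohortConfig()
    cohort: list[tuple[ROITimeSeriesSet, str]] = []
    labels = [config.label_a] * config.n_group_a + (
        [config.label_b] * config.n_group_b
    )
    groups = [config.group_a] * config.n_group_a + (
        [config.group_b] * config.n_group_b
    )
    for i, (label, group) in enumerate(zip(labels, groups)):
        ss = np.random.SeedSequence(config.seed, spawn_key=(i,))
        rng = np.random.default_rng(ss)
        spec = _draw_subject_spec(group, config.sizes, rng)
        ts = gen_subject_timeseries(
            make_block_covariance(spec),
            time_points=config.time_points,
            ar_coefficient=config.ar_coefficient,
            seed=np.random.SeedSequence(config.seed, spawn_key=(i, 1)),
            noise_sd=config.noise_sd,
            subject_id=f"{label}_{i:03d}",
            tr_seconds=config.tr_seconds,
        )
        cohort.append((ts, label))
    return cohort


@dataclass
class QoLGenSpec:
    """Planted linear model for the QoL scores.

    Each dimension is ``intercept + sum_j slope_j * indicator_j + noise``.
    Keys of ``slopes`` are ``(dimension, indicator)`` pairs; by the study's
    hypothesis, slopes on complexity indicators are negative and slopes on
    stability indicators positive, but any sign is accepted.
    """

    intercepts: dict[str, float] = field(default_factory=dict)
    slopes: dict[tuple[str, str], float] = field(default_factory=dict)
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be nonnegative")
        for dim in self.intercepts:
            if dim not in QOL_DIMENSIONS:
                raise SchemaError(f"unknown QoL dimension {dim!r}")
        for dim, indicator in self.slopes:
            if dim not in QOL_DIMENSIONS:
                raise SchemaError(f"unknown QoL dimension {dim!r}")
            if indicator not in INDICATORS:
                raise SchemaError(f"unknown indicator {indicator!r}")


def gen_qol_table(
    profiles: Sequence[ComplexityProfile], spec: QoLGenSpec | None = None
) -> pd.DataFrame:
    """Generate the eight-dimension QoL table from subject profiles."""
    if not profiles:
        raise ParameterError("profiles must be nonempty")
    spec = spec or QoLGenSpec()
    frame = profiles_to_frame(profiles)
    rng = np.random.default_rng(spec.seed)
    out = pd.DataFrame(index=frame.index, columns=list(QOL_DIMENSIONS),
                       dtype=float)
    for dim in QOL_DIMENSIONS:
        score = np.full(len(frame), spec.intercepts.get(dim, 0.0))
        for (d, indicator), slope in spec.slopes.items():
            if d == dim:
                score = score + slope * frame[indicator].to_numpy()
        if spec.noise_sd > 0:
            score = score + spec.noise_sd * rng.standard_normal(len(frame))
        out[dim] = score
    return out
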