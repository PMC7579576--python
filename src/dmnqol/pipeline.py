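"""Orchestration: simulate -> connect -> profile -> compare / relate.

`run_compare` produces the group-comparison table (one row per indicator
and group with mean, mean rank, SD, one-sided Mann–Whitney significance in
the direction of the larger mean rank, and the two-group variance-test p);
`run_relate` produces the flagged correlation matrix over QoL dimensions and
indicators plus one AIC-stepwise model per dimension.  A single top-level
seed determines every stochastic step.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .connectivity import (
    ConnectivityConfig,
    bandpass_filter,
    binarize_graph,
    pearson_connectivity,
)
from .errors import JoinError, SchemaError
from .io_formats import QOL_DIMENSIONS, ReportBundle, ROITimeSeriesSet
from .metrics import (
    INDICATORS,
    ComplexityProfile,
    compute_profile,
    profiles_to_frame,
)
from .stats import (
    brown_forsythe_two_groups,
    pearson_flagged_matrix,
    rank_with_ties,
    mann_whitney_from_ranks,
    stepwise_aic,
)
from .synthetic import CohortConfig, QoLGenSpec, gen_cohort, gen_qol_table

logger = logging.getLogger("dmnqol")

__all__ = [
    "PipelineConfig",
    "profile_subject",
    "profile_cohort",
    "run_all",
    "run_compare",
    "run_relate",
]


@dataclass
class PipelineConfig:
    """Everything one end-to-end run needs; one seed rules them all."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    connectivity: ConnectivityConfig = field(
        default_factory=ConnectivityConfig
    )
    qol: QoLGenSpec = field(default_factory=QoLGenSpec)
    n_null: int = 100
    k_clusters: int = 3
    apply_bandpass: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        # the top-level seed overrides the sub-config seeds
        self.cohort = dataclasses.replace(self.cohort, seed=self.seed)
        self.qol = dataclasses.replace(self.qol, seed=self.seed + 1)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        cohort = CohortConfig(**raw.get("cohort", {}))
        conn = ConnectivityConfig(**raw.get("connectivity", {}))
        qol_raw = dict(raw.get("qol", {}))
        if "slopes" in qol_raw:
            qol_raw["slopes"] = {
                tuple(k.split(":")): v for k, v in qol_raw["slopes"].items()
            }
        qol = QoLGenSpec(**qol_raw)
        return cls(
            cohort=cohort,
            connectivity=conn,
            qol=qol,
            n_null=raw.get("n_null", 100),
            k_clusters=raw.get("k_clusters", 3),
            apply_bandpass=raw.get("apply_bandpass", True),
            seed=raw.get("seed", 0),
        )


def profile_subject(
    ts: ROITimeSeriesSet,
    config: PipelineConfig | None = None,
    seed: int | None = None,
) -> ComplexityProfile:
    """Time series -> (band-pass) -> correlation -> graph -> profile."""
    config = config or PipelineConfig()
    if config.apply_bandpass:
        ts = bandpass_filter(ts, config.connectivity)
    conn = pearson_connectivity(ts)
    graph = binarize_graph(conn, config.connectivity)
    return compute_profile(
        graph,
        conn,
        n_null=config.n_null,
        k=config.k_clusters,
        seed=config.seed if seed is None else seed,
        subject_id=ts.subject_id,
    )


def profile_cohort(
    cohort: Sequence[tuple[ROITimeSeriesSet, str]],
    config: PipelineConfig | None = None,
) -> list[tuple[ComplexityProfile, str]]:
    """Profile every subject; per-subject seeds derive from the run seed."""
    config = config or PipelineConfig()
    out = []
    for i, (ts, label) in enumerate(cohort):
        seed = int(
            np.random.SeedSequence(
                config.seed, spawn_key=(7, i)
            ).generate_state(1)[0] % (2**31 - 1)
        )
        out.append((profile_subject(ts, config, seed=seed), label))
    return out


def run_compare(
    subjects: Sequence[tuple[ComplexityProfile, str]]
) -> pd.DataFrame:
    """Two-group comparison of every indicator.

    Output has two rows per indicator (one per group) with n, mean, mean
    rank and SD; the first row of each pair carries the one-sided
    Mann–Whitney p (direction = group with the larger mean rank, which is
    also named in the ``direction`` column) and the median-centered
    two-group variance-test p.
    """
    profiles = [p for p, _ in subjects]
    labels = [lab for _, lab in subjects]
    unique_labels = list(dict.fromkeys(labels))
    if len(unique_labels) != 2:
        raise SchemaError(f"need exactly 2 groups, got {unique_labels}")
    frame = profiles_to_frame(profiles)
    missing = [ind for ind in INDICATORS if ind not in frame.columns]
    if missing:
        raise SchemaError(f"profiles missing indicators: {missing}")
    if frame.isna().any().any():
        bad = frame.columns[frame.isna().any()].tolist()
        raise SchemaError(f"indicator missing for some subject: {bad}")
    lab_arr = np.asarray(labels)
    rows = []
    for indicator in INDICATORS:
        values = frame[indicator].to_numpy()
        x = values[lab_arr == unique_labels[0]]
        y = values[lab_arr == unique_labels[1]]
        summary = rank_with_ties(values, lab_arr)
        mw = mann_whitney_from_ranks(
            summary.mean_rank_1, summary.n1,
            summary.mean_rank_2, summary.n2,
        )
        lev = brown_forsythe_two_groups(x, y)
        direction = unique_labels[mw.direction - 1]
        for gi, (lab, vals, mean_rank) in enumerate(
            [
                (unique_labels[0], x, summary.mean_rank_1),
                (unique_labels[1], y, summary.mean_rank_2),
            ]
        ):
            rows.append(
                {
                    "indicator": indicator,
                    "group": lab,
                    "n": len(vals),
                    "mean": float(np.mean(vals)),
                    "mean_rank": mean_rank,
                    "sd": float(np.std(vals, ddof=1)),
                    "p_mw_one_sided": mw.p_one_sided if gi == 0 else np.nan,
                    "direction": direction if gi == 0 else "",
                    "p_levene": lev.p if gi == 0 else np.nan,
                }
            )
    return pd.DataFrame(rows)


def run_relate(
    profiles: Sequence[ComplexityProfile], qol: pd.DataFrame
) -> tuple:
    """Correlations and stepwise models linking indicators to QoL.

    Returns ``(flagged_correlations, models_table, models)``: the flagged
    Pearson matrix over the 8 QoL dimensions + 11 indicators, a models
    table with one indicator row per dimension column (NaN = predictor not
    selected; extra rows report each model's R² and AIC), and the list of
    fitted :class:`~dmnqol.stats.StepwiseModel` objects.
    """
    frame = profiles_to_frame(profiles)
    orphans = frame.index.symmetric_difference(qol.index)
    if len(orphans):
        raise JoinError(f"subject ids not shared: {list(orphans)[:10]}")
    qol = qol.loc[frame.index]
    joint = pd.concat([qol, frame], axis=1)
    # fixed-density binarization makes mean degree (and hence the density
    # complexity) constant across subjects: such columns carry no
    # correlation information and are excluded from the matrix
    constant = [c for c in joint.columns if joint[c].std(ddof=0) == 0.0]
    if constant:
        logger.info("run_relate constant_columns=%s", ",".join(constant))
    corr = pearson_flagged_matrix(joint.drop(columns=constant))
    models = []
    models_table = pd.DataFrame(
        index=list(INDICATORS) + ["r_squared", "aic"],
        columns=list(QOL_DIMENSIONS),
        dtype=float,
    )
    for dim in QOL_DIMENSIONS:
        model = stepwise_aic(
            qol[dim].to_numpy(), frame, response_name=dim
        )
        models.append(model)
        for name, beta in model.coefficients.items():
            if name != "intercept":
                models_table.loc[name, dim] = beta
        models_table.loc["r_squared", dim] = model.r_squared
        models_table.loc["aic", dim] = model.aic
    return corr, models_table, models


def run_all(config: PipelineConfig | None = None) -> ReportBundle:
    """Full pipeline on a synthetic cohort; returns a report bundle.

    The QoL table is generated (with the configured planted slopes) for the
    second group only, mirroring a study where QoL is assessed in the
    clinical group alone.
    """
    config = config or PipelineConfig()
    logger.info(
        "run_all seed=%d n_a=%d n_b=%d density=%s n_null=%d k=%d",
        config.seed, config.cohort.n_group_a, config.cohort.n_group_b,
        config.connectivity.threshold_value, config.n_null, config.k_clusters,
    )
    cohort = gen_cohort(config.cohort)
    profiled = profile_cohort(cohort, config)
    comparison = run_compare(profiled)
    group_b = [p for p, lab in profiled if lab == config.cohort.label_b]
    qol = gen_qol_table(group_b, config.qol)
    corr, models_table, _ = run_relate(group_b, qol)
    flagged = corr.r.round(3).astype(str) + corr.flags
    return ReportBundle(
        comparison_table=comparison,
        correlation_table=flagged,
        models_table=models_table,
        metadata={
            "seed": config.seed,
            "n_null": config.n_null,
            "k_clusters": config.k_clusters,
            "threshold_method": config.connectivity.threshold_method,
            "threshold_value": config.connectivity.threshold_value,
            "band_hz": list(config.connectivity.band),
            "version": "0.1.0",
        },
    )
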