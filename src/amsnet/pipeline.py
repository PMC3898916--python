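"""End-to-end analysis orchestration and sensitivity subsets.

A run executes: read -> orient (optional) -> QC filter -> subset rule ->
correlation network -> MCL -> cluster median profiles -> symptom
correlation matrix -> severity-score diagnostics, and emits a
machine-readable report plus the standard artifacts (GraphML network,
clusters.csv, stats.json, ledger.json).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import records as rec
from .mcl import MCLParams, mcl_cluster, write_clusters_csv
from .network import NetworkParams, build_network, node_table, write_edge_list, write_graphml
from .stats import (
    SymptomCorrMatrix,
    chi_squared_independence,
    cluster_treatment_table,
    ks_normality,
    skewness,
    sqrt_transform,
    summary_stats,
    symptom_matrix,
)

logger = logging.getLogger(__name__)

SUBSET_RULES = (
    "all",
    "longitudinal_only",
    "cross_sectional_only",
    "placebo_only",
    "single_timepoint",
    "sleep_substituted",
)

#: Study day used by the ``single_timepoint`` rule for the longitudinal arm.
SINGLE_TIMEPOINT_DAY = 3


@dataclass
class RunConfig:
    input_path: str | Path | None = None
    qc_threshold_mm: float = rec.QC_THRESHOLD_MM
    network: NetworkParams = field(default_factory=NetworkParams)
    mcl: MCLParams = field(default_factory=MCLParams)
    subset: str = "all"
    output_dir: str | Path | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.subset not in SUBSET_RULES:
            raise ValueError(f"unknown subset rule {self.subset!r}")


def substitute_next_night_sleep(df: pd.DataFrame) -> pd.DataFrame:
    """Replace each sleep score by the one reported the following day.

    Questionnaires ask about the *preceding* night; physiologically the
    following night is equally relevant, so this sensitivity edit shifts
    each longitudinal subject's sleep item back by one study day.  Records
    without a following-day sleep value are dropped; all other items are
    untouched.
    """
    if (df["expedition"] != "longitudinal").any():
        raise ValueError("sleep substitution applies to longitudinal records only")
    out = df.copy()
    key = pd.MultiIndex.from_arrays([out["subject_id"], out["day"].astype("Int64")])
    next_key = pd.MultiIndex.from_arrays(
        [out["subject_id"], (out["day"] + 1).astype("Int64")]
    )
    sleep_by_key = pd.Series(out["vas_sleep"].to_numpy(), index=key)
    if not sleep_by_key.index.is_unique:
        raise ValueError("duplicate (subject, day) records")
    nxt = sleep_by_key.reindex(next_key)
    out["vas_sleep"] = nxt.to_numpy()
    return out[~out["vas_sleep"].isna()].copy()


def apply_subset(df: pd.DataFrame, rule: str) -> pd.DataFrame:
    """Questionnaire inclusion rules for the sensitivity reruns."""
    if rule == "all":
        return df
    if rule == "longitudinal_only":
        return df[df["expedition"] == "longitudinal"]
    if rule == "cross_sectional_only":
        return df[df["expedition"] == "cross_sectional"]
    if rule == "placebo_only":
        return df[df["treatment"].isin(["placebo", "unknown"])]
    if rule == "single_timepoint":
        keep = (df["expedition"] == "cross_sectional") | (
            (df["expedition"] == "longitudinal") & (df["day"] == SINGLE_TIMEPOINT_DAY)
        )
        return df[keep]
    if rule == "sleep_substituted":
        return substitute_next_night_sleep(
            df[df["expedition"] == "longitudinal"]
        )
    raise ValueError(f"unknown subset rule {rule!r}")


def filtering_ledger(
    df: pd.DataFrame, qc_threshold_mm: float = rec.QC_THRESHOLD_MM
) -> dict:
    """Counts at each filtering stage, by expedition, with conservation.

    Stages: raw -> complete (all VAS and LLS items present) -> qc_passed.
    At every stage excluded + retained equals the stage input.
    """
    item_cols = list(rec.VAS_COLUMNS) + list(rec.LLS_COLUMNS)
    complete_mask = df[item_cols].notna().all(axis=1)
    complete = df[complete_mask]
    qc_mask = rec.qc_filter(complete, qc_threshold_mm)
    passed = complete[qc_mask]

    def by_exp(frame: pd.DataFrame) -> dict:
        return {
            exp: int((frame["expedition"] == exp).sum()) for exp in rec.EXPEDITIONS
        }

    ledger = {
        "raw": {"n": int(len(df)), "by_expedition": by_exp(df)},
        "complete": {
            "n": int(len(complete)),
            "excluded": int(len(df) - len(complete)),
            "by_expedition": by_exp(complete),
        },
        "qc_passed": {
            "n": int(len(passed)),
            "excluded": int(len(complete) - len(passed)),
            "excluded_pct": round(
                100.0 * (len(complete) - len(passed)) / len(complete), 1
            )
            if len(complete)
            else 0.0,
            "by_expedition": by_exp(passed),
        },
    }
    assert ledger["complete"]["n"] + ledger["complete"]["excluded"] == ledger["raw"]["n"]
    assert ledger["qc_passed"]["n"] + ledger["qc_passed"]["excluded"] == ledger["complete"]["n"]
    return ledger


def select_one_per_subject(
    df: pd.DataFrame, day: int = SINGLE_TIMEPOINT_DAY
) -> pd.DataFrame:
    """One questionnaire per subject for the correlation analysis.

    Longitudinal subjects contribute their day-``day`` questionnaire;
    cross-sectional subjects their single record (the first, should
    duplicates exist).
    """
    keep = apply_subset(df, "single_timepoint") if day == SINGLE_TIMEPOINT_DAY else df[
        (df["expedition"] == "cross_sectional") | (df["day"] == day)
    ]
    return keep.drop_duplicates(subset="subject_id", keep="first")


def run_pipeline(
    config: RunConfig, records_frame: pd.DataFrame | None = None
) -> dict:
    """Execute the full analysis; returns the machine-readable run report.

    ``records_frame`` short-circuits file reading (records already oriented
    and in the dialect); otherwise ``config.input_path`` is read.
    """
    if records_frame is None:
        if config.input_path is None:
            raise ValueError("read stage: no input path and no in-memory records")
        records_frame = rec.read_records(config.input_path)
    if records_frame.empty:
        raise ValueError("read stage: no records to analyse")

    ledger = filtering_ledger(records_frame, config.qc_threshold_mm)
    qc_passed = records_frame[
        rec.qc_filter(records_frame, config.qc_threshold_mm)
    ].copy()
    subset = apply_subset(qc_passed, config.subset)
    logger.info("subset %s: %d of %d QC-passed records", config.subset,
                len(subset), len(qc_passed))
    if len(subset) < 2:
        raise ValueError(f"subset stage: rule {config.subset!r} left <2 records")

    graph = build_network(subset, config.network)
    result = mcl_cluster(graph, config.mcl, records=subset)

    one_per_subject = select_one_per_subject(subset)
    profiles = rec.symptom_profile_frame(one_per_subject)
    corr = (
        symptom_matrix(profiles) if len(one_per_subject) >= 4 else None
    )

    totals = rec.total_vas(subset)
    stats_block = {
        "total_vas": asdict(summary_stats(totals)),
        "total_vas_skewness": skewness(totals),
        "sqrt_total_vas_skewness": skewness(sqrt_transform(totals)),
        "lls_total_median": float(np.median(rec.lls_total(subset))),
        "ams_cases": int(rec.ams_case(subset).sum()),
    }
    if len(totals) >= 5:
        d, p = ks_normality(sqrt_transform(totals))
        stats_block["sqrt_total_vas_ks"] = {"distance": d, "p": p}

    report = {
        "config": {
            "subset": config.subset,
            "qc_threshold_mm": config.qc_threshold_mm,
            "r_threshold": config.network.r_threshold,
            "profile_mode": config.network.profile_mode,
            "inflation": config.mcl.inflation,
            "min_cluster_size": config.mcl.min_cluster_size,
            "seed": config.seed,
        },
        "ledger": ledger,
        "subset_n": int(len(subset)),
        "network": {
            "n_nodes": graph.number_of_nodes(),
            "n_edges": graph.number_of_edges(),
            "n_isolated_removed": int(len(subset) - graph.number_of_nodes()),
        },
        "clusters": {
            "n_clusters": result.n_clusters,
            "sizes": result.sizes,
            "n_unclustered": result.n_unclustered,
            "converged": result.converged,
            "median_profiles": (
                result.median_profiles.round(1).to_dict(orient="index")
                if result.median_profiles is not None
                else None
            ),
        },
        "symptom_correlation": (
            {
                "n": corr.n,
                "rho": corr.rho.round(3).to_dict(orient="index"),
                "per_symptom_mean": corr.per_symptom_mean.round(3).to_dict(),
            }
            if corr is not None
            else None
        ),
        "severity": stats_block,
    }

    treatment_counts = cluster_treatment_table(subset, result.assignment)
    if result.n_clusters >= 2 and (treatment_counts.to_numpy().sum(axis=0) > 0).all() \
            and (treatment_counts.to_numpy().sum(axis=1) > 0).all():
        stat, dof, p = chi_squared_independence(treatment_counts)
        report["treatment_balance"] = {
            "counts": treatment_counts.to_dict(orient="index"),
            "chi2": stat, "dof": dof, "p": p,
        }

    if config.output_dir is not None:
        _write_artifacts(Path(config.output_dir), graph, result, report)
    return report


def _write_artifacts(outdir: Path, graph, result, report) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    write_graphml(graph, outdir / "network.graphml")
    write_edge_list(graph, outdir / "edges.csv")
    write_clusters_csv(result, outdir / "clusters.csv")
    node_table(graph, result.assignment).to_csv(outdir / "nodes.csv", index=False)
    (outdir / "ledger.json").write_text(json.dumps(report["ledger"], indent=2))
    (outdir / "run_report.json").write_text(json.dumps(report, indent=2, default=str))
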