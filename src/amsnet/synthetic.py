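"""Synthetic questionnaire generator.

Emulates the statistical structure the downstream analysis assumes: a
mixture of a few clustered symptom *archetypes* (subject-days whose
seven-item VAS profiles are tightly correlated within the archetype) on top
of a large diffuse background whose item responses are mutually independent
and right-skewed toward low severity, plus a known fraction of records with
an injected quality-control discordance.

The defaults mirror the shape of the source cohort: 292 subjects, a
longitudinal arm (103 subjects followed over 9 study days, 3650 m then
5200 m) and a cross-sectional arm (189 one-off questionnaires at 4730 m),
about 5.9% QC-discordant records, 45% unclustered background and three
archetypes in roughly 0.39/0.12/0.04 proportion.

Within-archetype noise matters: two records drawn from the same archetype
with per-item sd sigma correlate across the seven items at roughly
s^2 / (s^2 + sigma^2), where s^2 is the variance of the archetype's item
means.  The shipped means have s^2 ~= 600-740 mm^2, so sigma = 5 mm keeps
same-archetype correlations around 0.95-0.97, above the 0.95 network
threshold, while between-archetype correlations stay below ~0.8.

The two duplicate-fatigue items are coupled (the second tracks the first
to within a few mm), as an attentive respondent answers them: natural QC
failures are then vanishingly rare and the injected discordance (always
displaced by more than the 40 mm threshold) is exactly recoverable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .records import CSV_COLUMNS, LLS_COLUMNS, VAS_COLUMNS, VAS_ITEMS, write_records

#: Truth columns appended by the generator (not part of the CSV dialect).
TRUTH_COLUMNS = ("sim_component", "sim_qc_fail")

BACKGROUND = "background"


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class ArchetypeSpec:
    """A clustered symptom archetype.

    Parameters
    ----------
    name:
        Label carried through to the truth column.
    item_means:
        Seven oriented VAS item means in mm (:data:`~amsnet.records.VAS_ITEMS`
        order).
    item_sd:
        Within-archetype per-item noise scale in mm.
    weight:
        Expected fraction of all records drawn from this archetype.
    """

    name: str
    item_means: tuple[float, ...]
    item_sd: float
    weight: float

    def __post_init__(self) -> None:
        if len(self.item_means) != len(VAS_ITEMS):
            raise ConfigurationError(f"{self.name}: need seven item means")
        if not all(0.0 <= m <= 100.0 for m in self.item_means):
            raise ConfigurationError(f"{self.name}: item means must lie in [0, 100]")
        if self.item_sd <= 0:
            raise ConfigurationError(f"{self.name}: item_sd must be positive")
        if not 0.0 <= self.weight <= 1.0:
            raise ConfigurationError(f"{self.name}: weight must lie in [0, 1]")


def default_archetypes() -> tuple[ArchetypeSpec, ...]:
    """Three archetypes shaped on the canonical cluster phenotypes.

    Item order: headache, nausea_sick, nausea_guts, fatigue_exhausted,
    fatigue_best, dizziness, sleep.
    """
    return (
        # poor sleep + fatigue, little headache (the commonest pattern)
        ArchetypeSpec("sleepy_fatigued", (5, 5, 5, 55, 55, 5, 65), 5.0, 0.388),
        # poor sleep + headache + fatigue
        ArchetypeSpec("sleepy_headache", (65, 10, 10, 65, 65, 20, 75), 5.0, 0.121),
        # headache + fatigue but little sleep disturbance
        ArchetypeSpec("headache_no_sleep", (70, 10, 10, 55, 55, 25, 5), 5.0, 0.041),
    )


@dataclass(frozen=True)
class SimConfig:
    """Generator configuration; defaults are the shipped study conditions."""

    n_subjects: int = 292
    days_per_subject: int = 9
    archetypes: tuple[ArchetypeSpec, ...] = field(default_factory=default_archetypes)
    background_fraction: float = 0.45
    qc_fail_rate: float = 0.059
    seed: int = 0
    expedition_split: float = 103 / 292  # fraction of subjects followed longitudinally
    treatment_probs: tuple[float, float, float] = (42 / 103, 41 / 103, 20 / 103)
    subject_offset_sd: float = 4.0  # per-subject severity shift, mm

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ConfigurationError("n_subjects must be >= 1")
        if self.days_per_subject < 1:
            raise ConfigurationError("days_per_subject must be >= 1")
        if not self.archetypes:
            raise ConfigurationError("at least one archetype is required")
        for p, name in (
            (self.background_fraction, "background_fraction"),
            (self.qc_fail_rate, "qc_fail_rate"),
            (self.expedition_split, "expedition_split"),
        ):
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        total = self.background_fraction + sum(a.weight for a in self.archetypes)
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(
                f"archetype weights + background_fraction must sum to 1 (got {total})"
            )
        if abs(sum(self.treatment_probs) - 1.0) > 1e-9:
            raise ConfigurationError("treatment_probs must sum to 1")


def simulate_dataset(config: SimConfig) -> pd.DataFrame:
    """Generate a questionnaire table in the canonical dialect plus truth.

    Returns a DataFrame with the CSV dialect columns and two extra truth
    columns: ``sim_component`` (archetype name or ``"background"``) and
    ``sim_qc_fail`` (whether a QC discordance was injected).  Item values
    are truncated to [0, 100] and rounded to 0.1 mm; the LLS items are
    derived from the oriented VAS items by monotone binning
    (0-25 -> 0, 26-50 -> 1, 51-75 -> 2, 76-100 -> 3) with a +-1 jitter of
    probability 0.1, clamped to [0, 3].
    """
    rng = np.random.default_rng(config.seed)
    meta = _subject_table(config, rng)

    rows: list[dict] = []
    for _, subj in meta.iterrows():
        days = (
            range(1, config.days_per_subject + 1)
            if subj["expedition"] == "longitudinal"
            else [None]
        )
        for day in days:
            rows.append(
                {
                    "subject_id": subj["subject_id"],
                    "expedition": subj["expedition"],
                    "day": day,
                    "altitude_m": _altitude(subj["expedition"], day),
                    "treatment": subj["treatment"],
                    "sex": subj["sex"],
                    "age_band": subj["age_band"],
                    "_offset": subj["_offset"],
                }
            )
    df = pd.DataFrame(rows)
    n = len(df)

    weights = [a.weight for a in config.archetypes] + [config.background_fraction]
    names = [a.name for a in config.archetypes] + [BACKGROUND]
    component = rng.choice(len(names), size=n, p=np.asarray(weights) / sum(weights))
    df["sim_component"] = [names[k] for k in component]

    fb_col = VAS_ITEMS.index("fatigue_best")
    fe_col = VAS_ITEMS.index("fatigue_exhausted")
    items = np.empty((n, len(VAS_ITEMS)))
    for k, arch in enumerate(config.archetypes):
        mask = component == k
        m = int(mask.sum())
        items[mask] = np.asarray(arch.item_means) + rng.normal(
            0.0, arch.item_sd, size=(m, len(VAS_ITEMS))
        )
    bg = component == len(config.archetypes)
    items[bg] = 100.0 * rng.beta(0.55, 2.4, size=(int(bg.sum()), len(VAS_ITEMS)))
    # background duplicate-fatigue pair: an independent same-marginal draw,
    # rejection-constrained to agree within 35 mm.  A consistent respondent
    # never trips the 40 mm QC bound naturally, yet the pair stays far less
    # correlated than additive coupling would make it, keeping background
    # profile-profile correlations rarely above the network threshold.
    bg_idx = np.flatnonzero(bg)
    fe_bg = items[bg_idx, fe_col]
    fb_bg = 100.0 * rng.beta(0.55, 2.4, size=len(bg_idx))
    disagree = np.abs(fb_bg - fe_bg) > 35.0
    while disagree.any():
        fb_bg[disagree] = 100.0 * rng.beta(0.55, 2.4, size=int(disagree.sum()))
        disagree = np.abs(fb_bg - fe_bg) > 35.0
    items[bg_idx, fb_col] = fb_bg
    # subject-level severity shift; cancels in profile-profile Pearson r
    items += df["_offset"].to_numpy()[:, None]
    items = np.clip(items, 0.0, 100.0)

    qc_fail = rng.random(n) < config.qc_fail_rate
    fe = items[:, fe_col]
    for i in np.flatnonzero(qc_fail):
        items[i, fb_col] = _displace(fe[i], rng)
    df["sim_qc_fail"] = qc_fail

    items = np.round(items, 1)
    for j, col in enumerate(VAS_COLUMNS):
        df[col] = items[:, j]

    lls = _derive_lls(items, rng)
    for j, col in enumerate(LLS_COLUMNS):
        df[col] = lls[:, j]

    df = df.drop(columns="_offset")
    df["day"] = pd.array(
        [None if pd.isna(d) else int(d) for d in df["day"]], dtype="Int64"
    )
    return df[list(CSV_COLUMNS) + list(TRUTH_COLUMNS)]


def _subject_table(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    n_long = int(round(config.n_subjects * config.expedition_split))
    rows = []
    for i in range(config.n_subjects):
        longitudinal = i < n_long
        if longitudinal:
            treatment = ("placebo", "antioxidant", "sildenafil")[
                rng.choice(3, p=config.treatment_probs)
            ]
        else:
            treatment = "unknown"
        rows.append(
            {
                "subject_id": f"S{i + 1:04d}",
                "expedition": "longitudinal" if longitudinal else "cross_sectional",
                "treatment": treatment,
                "sex": rng.choice(["male", "female", "missing"], p=[0.475, 0.475, 0.05]),
                "age_band": rng.choice(
                    ["<=21", "22-25", ">=26", "missing"], p=[0.30, 0.35, 0.30, 0.05]
                ),
                "_offset": rng.normal(0.0, config.subject_offset_sd),
            }
        )
    return pd.DataFrame(rows)


def _altitude(expedition: str, day: int | None) -> float:
    if expedition == "cross_sectional":
        return 4730.0
    return 3650.0 if day is not None and day <= 4 else 5200.0


def _displace(anchor: float, rng: np.random.Generator) -> float:
    """A duplicate-fatigue value >40 mm away from ``anchor``, inside [0, 100].

    The displacement is at least 41 mm so the discordance survives 0.1 mm
    rounding and stays exactly recoverable by the QC filter.
    """
    up = 100.0 - anchor
    room = max(up, anchor)
    disp = 41.0 + rng.random() * (room - 41.0)
    return anchor + disp if up >= anchor else anchor - disp


def _derive_lls(items: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Monotone VAS->LLS binning with small integer jitter."""
    idx = {name: VAS_ITEMS.index(name) for name in VAS_ITEMS}
    composites = np.column_stack(
        [
            items[:, idx["headache"]],
            (items[:, idx["nausea_sick"]] + items[:, idx["nausea_guts"]]) / 2.0,
            (items[:, idx["fatigue_exhausted"]] + items[:, idx["fatigue_best"]]) / 2.0,
            items[:, idx["dizziness"]],
            items[:, idx["sleep"]],
        ]
    )
    binned = np.digitize(composites, [25.0, 50.0, 75.0], right=True)
    jitter_mask = rng.random(binned.shape) < 0.1
    jitter = rng.choice([-1, 1], size=binned.shape)
    binned = binned + jitter_mask * jitter
    return np.clip(binned, 0, 3).astype(int)


def write_fixture(records: pd.DataFrame, path, include_truth: bool = False) -> None:
    """Write a generated dataset as a dialect CSV.

    Truth columns are dropped unless ``include_truth``; with them included
    the file is no longer readable by the strict dialect reader.
    """
    if records.empty:
        raise ConfigurationError("refusing to write an empty fixture")
    if include_truth:
        cols = list(CSV_COLUMNS) + [c for c in TRUTH_COLUMNS if c in records.columns]
        records[cols].to_csv(path, index=False, float_format="%.1f")
    else:
        write_records(records, path)
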