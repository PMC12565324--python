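"""Specimen exclusions, patient-level cluster pairing and demographics tables."""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .geometry_io import CohortTable, SpecimenRecord
from .shape_stats import chi_square_test, kruskal_wallis_test

__all__ = [
    "ExclusionRule",
    "PairSummary",
    "round_half_away",
    "exclude_specimens",
    "pair_clusters_by_patient",
    "at_least_one_membership",
    "demographics_table",
]


def round_half_away(x: float, decimals: int = 1) -> float:
    """Round with halves away from zero (matches hand-rounded percentages)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class ExclusionRule:
    reason: str
    predicate: Callable[[SpecimenRecord], bool]


@dataclass
class PairSummary:
    """Unordered per-patient cluster pairs (side-agnostic)."""

    pair_counts: dict[tuple[int, int], int]
    total_patients: int
    excluded_patients: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if sum(self.pair_counts.values()) != self.total_patients:
            raise ValueError("pair counts must sum to the total patient count")

    def percentages(self) -> dict[tuple[int, int], float]:
        return {
            pair: round_half_away(100.0 * n / self.total_patients)
            for pair, n in self.pair_counts.items()
        }

    def to_frame(self) -> pd.DataFrame:
        pct = self.percentages()
        rows = [
            {"pair": f"{a}-{b}", "n_patients": n, "pct": pct[(a, b)]}
            for (a, b), n in sorted(self.pair_counts.items())
        ]
        return pd.DataFrame(rows)


def exclude_specimens(
    records: Sequence[SpecimenRecord], rules: Sequence[ExclusionRule]
) -> tuple[list[SpecimenRecord], pd.DataFrame]:
    """Apply exclusion rules; returns surviving records and an audit table."""
    kept: list[SpecimenRecord] = []
    audit_rows = []
    for rec in records:
        hit = next((r for r in rules if r.predicate(rec)), None)
        if hit is None:
            kept.append(rec)
        else:
            audit_rows.append(
                {
                    "specimen_id": rec.specimen_id,
                    "patient_id": rec.patient_id,
                    "side": rec.side,
                    "reason": hit.reason,
                }
            )
    audit = pd.DataFrame(audit_rows, columns=["specimen_id", "patient_id", "side", "reason"])
    return kept, audit


def pair_clusters_by_patient(
    labels: Mapping[str, int], records: Sequence[SpecimenRecord]
) -> PairSummary:
    """Form unordered cluster pairs for patients with exactly two labelled cavities.

    Patients contributing fewer (or more) than two labelled cavities are
    excluded from the pairing and listed in ``excluded_patients``.
    """
    by_patient: dict[str, list[int]] = {}
    for rec in records:
        if rec.specimen_id in labels:
            by_patient.setdefault(rec.patient_id, []).append(int(labels[rec.specimen_id]))
    counts: dict[tuple[int, int], int] = {}
    excluded: list[str] = []
    for patient, labs in by_patient.items():
        if len(labs) != 2:
            excluded.append(patient)
            continue
        pair = tuple(sorted(labs))
        counts[pair] = counts.get(pair, 0) + 1
    total = sum(counts.values())
    return PairSummary(counts, total, sorted(excluded))


def at_least_one_membership(summary: PairSummary, cluster: int) -> float:
    """Percent of paired patients whose pair contains ``cluster`` (1 decimal)."""
    n = sum(
        count
        for pair, count in summary.pair_counts.items()
        if cluster in pair
    )
    return round_half_away(100.0 * n / summary.total_patients)


def _safe_chi2_p(table: np.ndarray):
    """Chi-square p, or None when a zero marginal makes the test undefined."""
    table = np.asarray(table, float)
    if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
        return None
    return chi_square_test(table)[2]


def demographics_table(
    labels: Mapping[str, int],
    records: Sequence[SpecimenRecord],
    cohort: CohortTable,
) -> tuple[pd.DataFrame, dict]:
    """Per-cluster demographics with association tests.

    One row per variable (cavity counts, side ratio, sex ratio, age); side
    and sex use a Pearson chi-square, age a Kruskal-Wallis test.  Cavities
    whose patient lacks a demographic value are dropped from that statistic
    only; the count of such drops is reported in the summary dict.
    """
    demo = cohort.table.set_index("patient_id")
    rows = []
    for rec in records:
        if rec.specimen_id not in labels:
            continue
        entry = {
            "specimen_id": rec.specimen_id,
            "cluster": int(labels[rec.specimen_id]),
            "side": rec.side,
            "sex": "unknown",
            "age": np.nan,
        }
        if rec.patient_id in demo.index:
            info = demo.loc[rec.patient_id]
            entry["sex"] = info["sex"] if pd.notna(info["sex"]) else "unknown"
            entry["age"] = info["age"]
        rows.append(entry)
    df = pd.DataFrame(rows)
    if df.empty:
        raise ValueError("no labelled specimens to summarize")
    clusters = sorted(df["cluster"].unique())
    total = len(df)

    out_rows: list[dict] = []
    n_row: dict = {"variable": "n_cavities"}
    side_row: dict = {"variable": "side_right_left"}
    sex_row: dict = {"variable": "sex_female_male"}
    age_row: dict = {"variable": "age_mean_sd"}
    for c in clusters:
        sub = df[df["cluster"] == c]
        n_row[f"cluster_{c}"] = f"{len(sub)} ({round_half_away(100 * len(sub) / total)})"
        nr = int((sub["side"] == "right").sum())
        nl = int((sub["side"] == "left").sum())
        side_row[f"cluster_{c}"] = f"{nr}:{nl}"
        nf = int((sub["sex"] == "female").sum())
        nm = int((sub["sex"] == "male").sum())
        sex_row[f"cluster_{c}"] = f"{nf}:{nm}"
        ages = sub["age"].dropna()
        if len(ages):
            age_row[f"cluster_{c}"] = f"{ages.mean():.1f} +/- {ages.std(ddof=1):.1f}"
        else:
            age_row[f"cluster_{c}"] = "NA"

    summary: dict = {"n_clusters": len(clusters), "n_cavities": total}
    if len(clusters) < 2:
        for row in (n_row, side_row, sex_row, age_row):
            row["p"] = None
        summary["note"] = "single cluster: association tests not applicable"
    else:
        n_row["p"] = None
        side_tab = np.array(
            [
                [
                    int(((df["cluster"] == c) & (df["side"] == s)).sum())
                    for s in ("right", "left")
                ]
                for c in clusters
            ]
        )
        side_row["p"] = _safe_chi2_p(side_tab)
        known_sex = df[df["sex"].isin(["female", "male"])]
        summary["sex_missing"] = total - len(known_sex)
        sex_tab = np.array(
            [
                [
                    int(((known_sex["cluster"] == c) & (known_sex["sex"] == s)).sum())
                    for s in ("female", "male")
                ]
                for c in clusters
            ]
        )
        sex_row["p"] = _safe_chi2_p(sex_tab)
        known_age = df.dropna(subset=["age"])
        summary["age_missing"] = total - len(known_age)
        age_groups = [
            known_age.loc[known_age["cluster"] == c, "age"].to_numpy()
            for c in clusters
        ]
        if all(len(g) > 0 for g in age_groups):
            _, _, age_row["p"] = kruskal_wallis_test(age_groups)
        else:
            age_row["p"] = None
    out_rows.extend([n_row, side_row, sex_row, age_row])
    return pd.DataFrame(out_rows), summary
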