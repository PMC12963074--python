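"""Cohort scoring and contrast-phase comparison.

The pipeline scores every trabecular measurement against a reference
model, then quantifies what intravenous contrast does to the scores:

* paired absolute / relative changes of HU, T and Z between the
  non-contrast baseline and each enhanced phase (arterial, venous), with
  a Wilcoxon signed-rank p-value;
* diagnostic transition tables (4×4 contingency over normal / osteopenia
  / osteoporosis / unknown) per phase pair and subgroup;
* misclassification rates per directed transition and per phase pair,
  with the overall change rate counted as change *events* (arterial +
  venous) over the subgroup size, plus a clearly labelled unique-patient
  rate;
* the standard nonparametric group tests (Mann–Whitney U,
  Kruskal–Wallis, chi-squared without continuity correction, Wilcoxon
  signed-rank).

Patients lacking a phase are dropped pairwise per comparison, never
imputed.  Undefined scores travel as category ``"unknown"``: they occupy
the unknown row/column of transition tables, are excluded from
misclassification numerators, and stay in subgroup denominators.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .reference import CATEGORIES, ReferenceModel, classify, t_score, z_score

PHASES = ("noncontrast", "arterial", "venous")
BASELINE_PHASE = "noncontrast"

#: patients with |baseline| below this are excluded from relative changes
REL_CHANGE_EPS = 1e-9

_QUANTITY_COL = {"HU": None, "T": "t", "Z": "z"}  # HU column depends on statistic


@dataclass(frozen=True)
class ChangeSummary:
    """Paired change of one quantity between two phases at one level."""

    phase_pair: tuple[str, str]
    level: str
    quantity: str  # "HU" | "T" | "Z"
    median_abs_change: float
    iqr_abs_change: tuple[float, float]
    median_rel_change_pct: float
    iqr_rel_change_pct: tuple[float, float]
    n_pairs: int
    n_rel_excluded: int
    p_value: float
    p_degenerate: bool = False


@dataclass(frozen=True)
class TransitionTable:
    """Diagnostic category counts between a phase pair for one subgroup.

    ``counts`` is a 4×4 DataFrame, baseline categories on rows and
    comparison categories on columns, ordered normal / osteopenia /
    osteoporosis / unknown.  The diagonal holds unchanged diagnoses.
    """

    phase_pair: tuple[str, str]
    level: str
    subgroup: str
    counts: pd.DataFrame
    n_eligible: int


class CohortError(ValueError):
    pass


def validate_patients(patients: pd.DataFrame) -> pd.DataFrame:
    """Check the cohort table invariants (adults only, unique ids)."""
    problems = []
    if patients["patient_id"].duplicated().any():
        dup = patients.loc[patients["patient_id"].duplicated(), "patient_id"].tolist()
        problems.append(f"duplicate patient ids: {dup}")
    under = patients.loc[patients["age"] < 18, "patient_id"].tolist()
    if under:
        problems.append(f"patients under 18: {under}")
    bad_sex = patients.loc[~patients["sex"].isin(["female", "male"]), "patient_id"].tolist()
    if bad_sex:
        problems.append(f"unrecognized sex for: {bad_sex}")
    if problems:
        raise CohortError("; ".join(problems))
    return patients


def score_cohort(
    measurements: pd.DataFrame,
    patients: pd.DataFrame,
    ref: ReferenceModel,
    statistic: str = "median",
) -> pd.DataFrame:
    """Attach T, Z and diagnostic category to every measurement row.

    ``statistic`` selects which HU statistic drives the scores
    (``"median"``, the default, or ``"mean"``).  Undefined scores are kept
    as NaN with category ``"unknown"``; orphan measurements (patient_id
    absent from the cohort table) raise, listing the offending ids.
    """
    if statistic not in ("median", "mean"):
        raise ValueError(f"statistic must be 'median' or 'mean', got {statistic!r}")
    validate_patients(patients)
    hu_col = f"{statistic}_hu"
    orphans = sorted(set(measurements["patient_id"]) - set(patients["patient_id"]))
    if orphans:
        raise CohortError(f"measurements reference unknown patients: {orphans}")

    scored = measurements.merge(patients[["patient_id", "age", "sex"]], on="patient_id")
    hu = scored[hu_col].to_numpy(dtype=float)
    t = np.array(
        [t_score(h, s, ref) for h, s in zip(hu, scored["sex"])], dtype=float
    )
    z = np.array(
        [z_score(h, a, s, ref) for h, a, s in zip(hu, scored["age"], scored["sex"])],
        dtype=float,
    )
    scored = scored.assign(
        hu=hu, t=t, z=z, category=[classify(v) for v in t]
    )
    return scored


def _paired_frame(
    scored: pd.DataFrame, baseline_phase: str, comparison_phase: str, level: str, col: str
) -> pd.DataFrame:
    """Wide per-patient frame with baseline/comparison values, complete pairs only."""
    sub = scored[scored["level"] == level]
    base = sub[sub["phase"] == baseline_phase].set_index("patient_id")[col]
    comp = sub[sub["phase"] == comparison_phase].set_index("patient_id")[col]
    pairs = pd.DataFrame({"baseline": base, "comparison": comp}).dropna()
    return pairs


def paired_changes(
    scored: pd.DataFrame,
    baseline_phase: str,
    comparison_phase: str,
    level: str,
    quantity: str,
) -> ChangeSummary:
    """Median (IQR) absolute and relative paired change plus Wilcoxon p.

    Relative change per patient is ``100 * (comparison - baseline) /
    |baseline|``; patients with near-zero baseline are excluded from the
    relative (never the absolute) summary and their count reported.
    All-tied differences yield the degenerate convention p = 1, flagged.
    """
    if quantity not in _QUANTITY_COL:
        raise ValueError(f"quantity must be one of {sorted(_QUANTITY_COL)}")
    col = _QUANTITY_COL[quantity] or "hu"
    pairs = _paired_frame(scored, baseline_phase, comparison_phase, level, col)
    if pairs.empty:
        raise CohortError(
            f"no complete {baseline_phase}/{comparison_phase} pairs at {level}"
        )
    diff = (pairs["comparison"] - pairs["baseline"]).to_numpy()
    ok = np.abs(pairs["baseline"].to_numpy()) > REL_CHANGE_EPS
    rel = 100.0 * diff[ok] / np.abs(pairs["baseline"].to_numpy()[ok])

    degenerate = bool(np.all(diff == 0))
    if degenerate:
        p = 1.0
    else:
        p = float(stats.wilcoxon(diff, zero_method="wilcox").pvalue)

    q25a, q75a = np.percentile(diff, [25, 75])
    if rel.size:
        q25r, q75r = np.percentile(rel, [25, 75])
        med_rel = float(np.median(rel))
    else:
        q25r = q75r = med_rel = float("nan")
    return ChangeSummary(
        phase_pair=(baseline_phase, comparison_phase),
        level=level,
        quantity=quantity,
        median_abs_change=float(np.median(diff)),
        iqr_abs_change=(float(q25a), float(q75a)),
        median_rel_change_pct=med_rel,
        iqr_rel_change_pct=(float(q25r), float(q75r)),
        n_pairs=int(len(pairs)),
        n_rel_excluded=int((~ok).sum()),
        p_value=p,
        p_degenerate=degenerate,
    )


def transition_table(
    scored: pd.DataFrame,
    baseline_phase: str,
    comparison_phase: str,
    level: str,
    subgroup_ids=None,
    subgroup_name: str = "all",
) -> TransitionTable:
    """4×4 diagnostic transition counts between two phases.

    ``subgroup_ids`` restricts to those patient ids (None = everyone).
    Every patient with a measurement in both phases is counted exactly
    once, so the matrix total equals the eligible subgroup size.
    """
    pairs = _paired_frame(scored, baseline_phase, comparison_phase, level, "category")
    if subgroup_ids is not None:
        pairs = pairs[pairs.index.isin(set(subgroup_ids))]
    counts = pd.DataFrame(0, index=list(CATEGORIES), columns=list(CATEGORIES), dtype=int)
    tab = pairs.groupby(["baseline", "comparison"]).size()
    for (b, c), n in tab.items():
        counts.loc[b, c] = int(n)
    return TransitionTable(
        phase_pair=(baseline_phase, comparison_phase),
        level=level,
        subgroup=subgroup_name,
        counts=counts,
        n_eligible=int(len(pairs)),
    )


def _changed_events(table: TransitionTable) -> int:
    """Off-diagonal count over the three defined categories (unknown excluded)."""
    real = [c for c in CATEGORIES if c != "unknown"]
    c = table.counts.loc[real, real]
    return int(c.to_numpy().sum() - np.trace(c.to_numpy()))


def misclassification_report(
    tables: dict[str, TransitionTable], subgroup_n: int
) -> pd.DataFrame:
    """Long-format reclassification report across phase pairs.

    One row per phase pair (kind ``"pair_total"``), per directed
    off-diagonal transition (kind ``"transition"``), and a final
    ``"overall"`` row whose rate is the *sum of change events across
    phase pairs* over the subgroup size — so with both an arterial and a
    venous comparison the overall rate is the sum of the two pair rates.
    Percentages are carried at full precision; rounding is display-only.
    """
    if not tables:
        raise CohortError("no transition tables supplied")
    levels = {t.level for t in tables.values()}
    subgroups = {t.subgroup for t in tables.values()}
    if len(levels) > 1 or len(subgroups) > 1:
        raise CohortError("tables must share level and subgroup")
    real = [c for c in CATEGORIES if c != "unknown"]

    rows = []
    total_events = 0
    for pair_name, table in tables.items():
        n_changed = _changed_events(table)
        total_events += n_changed
        rows.append(
            dict(
                phase_pair=pair_name,
                kind="pair_total",
                baseline_cat="",
                comparison_cat="",
                count=n_changed,
                pct=100.0 * n_changed / subgroup_n if subgroup_n else float("nan"),
            )
        )
        for b in real:
            for c in real:
                if b == c:
                    continue
                k = int(table.counts.loc[b, c])
                rows.append(
                    dict(
                        phase_pair=pair_name,
                        kind="transition",
                        baseline_cat=b,
                        comparison_cat=c,
                        count=k,
                        pct=100.0 * k / subgroup_n if subgroup_n else float("nan"),
                    )
                )
    rows.append(
        dict(
            phase_pair="+".join(tables),
            kind="overall",
            baseline_cat="",
            comparison_cat="",
            count=total_events,
            pct=100.0 * total_events / subgroup_n if subgroup_n else float("nan"),
        )
    )
    return pd.DataFrame(rows)


def unique_patient_change_rate(
    tables: dict[str, TransitionTable], scored: pd.DataFrame, subgroup_ids, subgroup_n: int
) -> float:
    """Fraction of distinct patients reclassified in at least one phase pair.

    Companion to the event-sum overall rate of
    :func:`misclassification_report` (the two differ when the same
    patient changes in both the arterial and the venous comparison).
    """
    changed: set = set()
    for table in tables.values():
        b_phase, c_phase = table.phase_pair
        pairs = _paired_frame(scored, b_phase, c_phase, table.level, "category")
        if subgroup_ids is not None:
            pairs = pairs[pairs.index.isin(set(subgroup_ids))]
        mask = (
            (pairs["baseline"] != pairs["comparison"])
            & (pairs["baseline"] != "unknown")
            & (pairs["comparison"] != "unknown")
        )
        changed |= set(pairs.index[mask])
    return 100.0 * len(changed) / subgroup_n if subgroup_n else float("nan")


def subgroup_split(patients: pd.DataFrame, age_threshold: float = 50.0) -> dict[str, pd.DataFrame]:
    """Standard subgroups: all / by sex / by age threshold / sex × over-threshold."""
    if not 18 < age_threshold < 100:
        raise ValueError(f"age threshold must be in (18, 100), got {age_threshold}")
    f = patients["sex"] == "female"
    m = patients["sex"] == "male"
    under = patients["age"] < age_threshold
    over = ~under
    return {
        "all": patients,
        "female": patients[f],
        "male": patients[m],
        "under": patients[under],
        "over": patients[over],
        "female-over": patients[f & over],
        "male-over": patients[m & over],
    }


# ---------------------------------------------------------------------------
# group tests
# ---------------------------------------------------------------------------

def mann_whitney(x, y) -> float:
    """Two-sided Mann–Whitney U p-value for two independent samples."""
    return float(stats.mannwhitneyu(x, y, alternative="two-sided").pvalue)


def kruskal_wallis(*groups) -> float:
    """Kruskal–Wallis p-value across >= 3 independent groups."""
    if len(groups) < 3:
        raise ValueError("Kruskal–Wallis needs at least 3 groups")
    return float(stats.kruskal(*groups).pvalue)


def chi_squared(table) -> tuple[float, float]:
    """Pearson chi-squared (statistic, p) on a contingency table.

    No continuity correction, so 2×2 tables reproduce the textbook
    statistic.
    """
    res = stats.chi2_contingency(np.asarray(table), correction=False)
    return float(res.statistic), float(res.pvalue)


def wilcoxon_signed_rank(diff) -> tuple[float, bool]:
    """Paired Wilcoxon p-value; all-tied differences give (1.0, True)."""
    diff = np.asarray(diff, dtype=float)
    if np.all(diff == 0):
        return 1.0, True
    return float(stats.wilcoxon(diff, zero_method="wilcox").pvalue), False
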