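"""Result tables: cohort summaries, change tables, reclassification reports.

Everything here is a display layer over :mod:`ctbmd.cohort` — full
precision is kept internally and rounding (half-up, to the granularity a
radiology journal would print: integers for transition percentages, two
decimals for change rates, one decimal for relative HU changes) happens
only when a table is materialised.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from . import cohort as ch
from .reference import CATEGORIES

ENHANCED_PHASES = ("arterial", "venous")
REPORT_SUBGROUPS = ("all", "female-over", "male-over", "under")


def round_half_up(x: float, decimals: int = 0) -> float:
    """Deterministic half-up rounding for display (0.5 always rounds up)."""
    if x is None or (isinstance(x, float) and np.isnan(x)):
        return float("nan")
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def relative_change_display(abs_change: float, baseline: float, decimals: int = 1) -> float:
    """Relative change (%) implied by a summary absolute change and baseline.

    This is the display companion of the per-patient relative change: the
    percentage implied by the *printed* median absolute change over the
    *printed* baseline median, e.g. +23.6 HU on a 127.7 HU baseline is
    +18.5 %.
    """
    if abs(baseline) < ch.REL_CHANGE_EPS:
        return float("nan")
    return round_half_up(100.0 * abs_change / abs(baseline), decimals)


def cohort_summary(patients: pd.DataFrame, scored: pd.DataFrame,
                   age_threshold: float = 50.0, level: str = "L1") -> pd.DataFrame:
    """Baseline-characteristics table by subgroup.

    Rows: n, median age with IQR, sex counts, non-contrast diagnosis
    counts at ``level``; columns: the standard subgroups.
    """
    subgroups = ch.subgroup_split(patients, age_threshold)
    base = scored[(scored["phase"] == ch.BASELINE_PHASE) & (scored["level"] == level)]
    cols = {}
    for name, grp in subgroups.items():
        ids = set(grp["patient_id"])
        sub = base[base["patient_id"].isin(ids)]
        ages = grp["age"]
        entry = {
            "n": len(grp),
            "age_median": round_half_up(float(ages.median())) if len(grp) else float("nan"),
            "age_q25": round_half_up(float(ages.quantile(0.25))) if len(grp) else float("nan"),
            "age_q75": round_half_up(float(ages.quantile(0.75))) if len(grp) else float("nan"),
            "female": int((grp["sex"] == "female").sum()),
            "male": int((grp["sex"] == "male").sum()),
        }
        counts = sub["category"].value_counts()
        for cat in CATEGORIES:
            entry[cat] = int(counts.get(cat, 0))
            entry[f"{cat}_pct"] = (
                round_half_up(100.0 * counts.get(cat, 0) / len(grp)) if len(grp) else float("nan")
            )
        cols[name] = entry
    return pd.DataFrame(cols)


def change_table(scored: pd.DataFrame, levels=("L1", "L1L4"),
                 quantities=("HU", "T", "Z")) -> pd.DataFrame:
    """Paired-change summaries for every phase pair × level × quantity."""
    rows = []
    for comparison in ENHANCED_PHASES:
        for level in levels:
            for q in quantities:
                s = ch.paired_changes(scored, ch.BASELINE_PHASE, comparison, level, q)
                dec = 1 if q == "HU" else 2
                rows.append(dict(
                    comparison=comparison, level=level, quantity=q,
                    n_pairs=s.n_pairs,
                    median_abs_change=round_half_up(s.median_abs_change, dec),
                    iqr_abs_low=round_half_up(s.iqr_abs_change[0], dec),
                    iqr_abs_high=round_half_up(s.iqr_abs_change[1], dec),
                    median_rel_change_pct=round_half_up(s.median_rel_change_pct, 1),
                    n_rel_excluded=s.n_rel_excluded,
                    p_value=s.p_value,
                ))
    return pd.DataFrame(rows)


def transition_long(table: ch.TransitionTable, subgroup_n: int) -> pd.DataFrame:
    """Long-format transition table with percentages of the subgroup size."""
    rows = []
    for b in CATEGORIES:
        for c in CATEGORIES:
            k = int(table.counts.loc[b, c])
            rows.append(dict(
                phase_pair="->".join(table.phase_pair), level=table.level,
                subgroup=table.subgroup, baseline_cat=b, comparison_cat=c,
                count=k,
                pct=round_half_up(100.0 * k / subgroup_n, 2) if subgroup_n else float("nan"),
            ))
    return pd.DataFrame(rows)


def reclassification_report(scored: pd.DataFrame, patients: pd.DataFrame,
                            level: str = "L1", age_threshold: float = 50.0,
                            subgroups=REPORT_SUBGROUPS) -> dict[str, pd.DataFrame]:
    """Misclassification report per subgroup.

    For each subgroup: transition tables against each enhanced phase,
    directed-transition counts/percentages, per-pair change rates, the
    event-sum overall rate and the unique-patient rate.
    """
    split = ch.subgroup_split(patients, age_threshold)
    out = {}
    for name in subgroups:
        grp = split[name]
        ids = set(grp["patient_id"])
        tables = {
            phase: ch.transition_table(scored, ch.BASELINE_PHASE, phase, level,
                                       subgroup_ids=ids, subgroup_name=name)
            for phase in ENHANCED_PHASES
        }
        n = len(grp)
        rep = ch.misclassification_report(tables, subgroup_n=n)
        unique = ch.unique_patient_change_rate(tables, scored, ids, n)
        extra = pd.DataFrame([dict(
            phase_pair="+".join(ENHANCED_PHASES), kind="overall_unique_patients",
            baseline_cat="", comparison_cat="",
            count=int(round(unique * n / 100.0)) if n else 0, pct=unique,
        )])
        out[name] = pd.concat([rep, extra], ignore_index=True)
    return out


def statistical_tests(scored: pd.DataFrame, level: str = "L1") -> pd.DataFrame:
    """Standard group tests on the scored cohort.

    * Mann–Whitney U: arterial HU change, female vs male;
    * Kruskal–Wallis: HU across the three phases;
    * chi-squared: baseline diagnostic category × sex;
    * Wilcoxon signed-rank: per phase pair, HU change vs zero.
    """
    rows = []
    base = scored[(scored["level"] == level)]

    pairs_art = ch._paired_frame(scored, ch.BASELINE_PHASE, "arterial", level, "hu")
    if not pairs_art.empty:
        diff = pairs_art["comparison"] - pairs_art["baseline"]
        sex = scored.drop_duplicates("patient_id").set_index("patient_id")["sex"]
        d_f = diff[sex.reindex(diff.index) == "female"]
        d_m = diff[sex.reindex(diff.index) == "male"]
        if len(d_f) and len(d_m):
            rows.append(dict(test="mann_whitney", description="arterial HU change, female vs male",
                             p_value=ch.mann_whitney(d_f, d_m)))

    groups = [base.loc[base["phase"] == p, "hu"].dropna() for p in ch.PHASES]
    if all(len(g) for g in groups):
        rows.append(dict(test="kruskal_wallis", description="HU across phases",
                         p_value=ch.kruskal_wallis(*groups)))

    nc = base[base["phase"] == ch.BASELINE_PHASE]
    tab = pd.crosstab(nc["category"], nc["sex"])
    tab = tab.loc[[c for c in tab.index if c != "unknown"]]
    if tab.shape[0] >= 2 and tab.shape[1] == 2 and (tab.to_numpy().sum(axis=0) > 0).all():
        stat, p = ch.chi_squared(tab.to_numpy())
        rows.append(dict(test="chi_squared", description="baseline category x sex", p_value=p))

    for phase in ENHANCED_PHASES:
        pairs = ch._paired_frame(scored, ch.BASELINE_PHASE, phase, level, "hu")
        if not pairs.empty:
            p, degen = ch.wilcoxon_signed_rank(pairs["comparison"] - pairs["baseline"])
            rows.append(dict(test="wilcoxon", description=f"HU change, {phase} vs baseline",
                             p_value=p))
    return pd.DataFrame(rows)
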