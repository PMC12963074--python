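"""Reference population model and HU -> T/Z-score conversion.

A T-score expresses a patient's trabecular attenuation as the number of
standard deviations below (negative) or above (positive) the mean of a
young-normal (age ~30) population of the same sex:

    T = (HU - mu_young[sex]) / sigma_young[sex]

The Z-score is the analogous quantity against the age- and sex-matched
stratum of the reference population:

    Z = (HU - mu[sex, bin(age)]) / sigma[sex, bin(age)]

Diagnostic categories follow the WHO densitometry convention transplanted
to CT attenuation: T > -1.0 is normal bone mass, T < -2.5 is osteoporosis,
and the band between is osteopenia.  Both boundary values (-1.0 and -2.5)
are assigned to osteopenia so that the three bands partition the real line;
the thresholds are configurable.

Scores that cannot be computed (missing reference stratum, missing
measurement, age outside the covered bins) are carried as NaN and classify
to the explicit category ``"unknown"`` — they are never silently dropped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SEXES = ("female", "male")
CATEGORIES = ("normal", "osteopenia", "osteoporosis", "unknown")

#: default WHO-style thresholds on the T-score
NORMAL_ABOVE = -1.0
OSTEOPOROSIS_BELOW = -2.5


class ReferenceValidationError(ValueError):
    """Raised when a reference table violates the model invariants.

    The message enumerates every offending row rather than stopping at
    the first one.
    """


@dataclass(frozen=True)
class ReferenceModel:
    """Sex- and age-stratified trabecular-HU reference statistics.

    Parameters
    ----------
    young_mean_by_sex, young_sd_by_sex
        Mean / SD of young-normal (age ~30) trabecular HU per sex; the
        anchor of the T-score.
    agematched_mean, agematched_sd
        Maps ``(sex, bin_index) -> HU`` for the Z-score strata.
    age_bin_edges
        Strictly increasing bin edges in years; bin *i* covers
        ``[edges[i], edges[i+1])``, the last bin is open-ended.
    """

    young_mean_by_sex: dict[str, float]
    young_sd_by_sex: dict[str, float]
    agematched_mean: dict[tuple[str, int], float]
    agematched_sd: dict[tuple[str, int], float]
    age_bin_edges: tuple[float, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        problems = []
        for s in SEXES:
            if s not in self.young_mean_by_sex or s not in self.young_sd_by_sex:
                problems.append(f"sex {s!r} missing from young-normal maps")
            elif not self.young_sd_by_sex[s] > 0:
                problems.append(f"young SD for {s!r} not > 0")
        for key, sd in self.agematched_sd.items():
            if not sd > 0:
                problems.append(f"SD for stratum {key} not > 0")
        edges = self.age_bin_edges
        if len(edges) >= 2 and any(b <= a for a, b in zip(edges, edges[1:])):
            problems.append("age_bin_edges not strictly increasing")
        if problems:
            raise ReferenceValidationError("; ".join(problems))

    def age_bin(self, age: float) -> int | None:
        """Index of the bin covering ``age``, or None below the first edge.

        The last bin is open-ended on the right.
        """
        edges = self.age_bin_edges
        if not edges or age < edges[0] or not math.isfinite(age):
            return None
        # open-ended last bin
        idx = int(np.searchsorted(np.asarray(edges), age, side="right")) - 1
        return min(idx, len(edges) - 2) if len(edges) >= 2 else 0

    @property
    def n_strata(self) -> int:
        return len(self.agematched_mean)


def t_score(hu: float, sex: str, ref: ReferenceModel) -> float:
    """T-score of a trabecular HU statistic against the young-normal mean.

    Returns NaN (the undefined-score signal) when the sex has no reference
    entry or the measurement is not finite; never raises.
    """
    if sex not in ref.young_mean_by_sex or sex not in ref.young_sd_by_sex:
        return math.nan
    if hu is None or not math.isfinite(hu):
        return math.nan
    return (hu - ref.young_mean_by_sex[sex]) / ref.young_sd_by_sex[sex]


def z_score(hu: float, age: float, sex: str, ref: ReferenceModel) -> float:
    """Z-score against the age- and sex-matched reference stratum.

    NaN when the age falls outside the covered bins, the stratum is
    missing, or the measurement is not finite.
    """
    if hu is None or not math.isfinite(hu):
        return math.nan
    b = ref.age_bin(age)
    if b is None or (sex, b) not in ref.agematched_mean:
        return math.nan
    sd = ref.agematched_sd[(sex, b)]
    return (hu - ref.agematched_mean[(sex, b)]) / sd


def classify(
    t: float,
    normal_above: float = NORMAL_ABOVE,
    osteoporosis_below: float = OSTEOPOROSIS_BELOW,
) -> str:
    """Map a T-score to a diagnostic category.

    ``t > normal_above`` is normal, ``t < osteoporosis_below`` is
    osteoporosis, everything between — including both boundary values —
    is osteopenia.  NaN / None maps to ``"unknown"``.
    """
    if t is None or (isinstance(t, float) and math.isnan(t)):
        return "unknown"
    if t > normal_above:
        return "normal"
    if t < osteoporosis_below:
        return "osteoporosis"
    return "osteopenia"


# ---------------------------------------------------------------------------
# reference table I/O
# ---------------------------------------------------------------------------

_REF_COLUMNS = ["sex", "age_bin_low", "age_bin_high", "mean_hu", "sd_hu", "young_normal"]


def load_reference(path) -> ReferenceModel:
    """Load a CSV reference table into a validated :class:`ReferenceModel`.

    Expected columns: ``sex, age_bin_low, age_bin_high, mean_hu, sd_hu,
    young_normal`` (the last a 0/1 flag marking the young-normal row per
    sex).  Validation failures list every offending row by its 0-based
    position in the file.
    """
    df = pd.read_csv(path)
    missing = [c for c in _REF_COLUMNS if c not in df.columns]
    if missing:
        raise ReferenceValidationError(f"missing columns: {missing}")

    problems = []
    for i, row in df.iterrows():
        if not row["sd_hu"] > 0:
            problems.append(f"row {i}: sd_hu must be > 0 (got {row['sd_hu']})")
        if row["sex"] not in SEXES:
            problems.append(f"row {i}: unknown sex {row['sex']!r}")
        if not row["age_bin_low"] < row["age_bin_high"]:
            problems.append(f"row {i}: empty age bin [{row['age_bin_low']}, {row['age_bin_high']})")

    strata = df[df["young_normal"] == 0].sort_values(["sex", "age_bin_low"])
    for sex, grp in strata.groupby("sex"):
        lows = grp["age_bin_low"].to_numpy()
        highs = grp["age_bin_high"].to_numpy()
        for j in range(len(lows) - 1):
            if highs[j] > lows[j + 1]:
                problems.append(
                    f"sex {sex!r}: overlapping bins [{lows[j]}, {highs[j]}) and [{lows[j+1]}, {highs[j+1]})"
                )
    for s in SEXES:
        if s not in set(df["sex"]):
            problems.append(f"sex {s!r} absent from table")
        elif not ((df["sex"] == s) & (df["young_normal"] == 1)).any():
            problems.append(f"sex {s!r} has no young_normal row")
    if problems:
        raise ReferenceValidationError("; ".join(problems))

    young = df[df["young_normal"] == 1]
    young_mean = {r["sex"]: float(r["mean_hu"]) for _, r in young.iterrows()}
    young_sd = {r["sex"]: float(r["sd_hu"]) for _, r in young.iterrows()}

    edges = sorted(set(strata["age_bin_low"]).union(strata["age_bin_high"]))
    agematched_mean: dict[tuple[str, int], float] = {}
    agematched_sd: dict[tuple[str, int], float] = {}
    lows = edges[:-1]
    for _, r in strata.iterrows():
        b = lows.index(r["age_bin_low"])
        agematched_mean[(r["sex"], b)] = float(r["mean_hu"])
        agematched_sd[(r["sex"], b)] = float(r["sd_hu"])

    return ReferenceModel(
        young_mean_by_sex=young_mean,
        young_sd_by_sex=young_sd,
        agematched_mean=agematched_mean,
        agematched_sd=agematched_sd,
        age_bin_edges=tuple(float(e) for e in edges),
    )


def write_reference(model: ReferenceModel, path, young_age: float = 30.0) -> None:
    """Serialize a :class:`ReferenceModel` to the CSV layout of load_reference."""
    rows = []
    for s in SEXES:
        rows.append(
            dict(
                sex=s,
                age_bin_low=young_age,
                age_bin_high=young_age + 1,
                mean_hu=model.young_mean_by_sex[s],
                sd_hu=model.young_sd_by_sex[s],
                young_normal=1,
            )
        )
    edges = model.age_bin_edges
    for (s, b), m in sorted(model.agematched_mean.items(), key=lambda kv: (kv[0][0], kv[0][1])):
        rows.append(
            dict(
                sex=s,
                age_bin_low=edges[b],
                age_bin_high=edges[b + 1] if b + 1 < len(edges) else edges[-1] + 10,
                mean_hu=m,
                sd_hu=model.agematched_sd[(s, b)],
                young_normal=0,
            )
        )
    pd.DataFrame(rows).to_csv(path, index=False)
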