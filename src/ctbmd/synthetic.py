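"""Synthetic reference populations, cohorts and CT phantoms.

No imaging or reference data are distributed with the package, so this
module generates everything the pipeline needs:

* a young-normal + age-stratified reference population, from a linear
  age-decline model of trabecular HU with a sex difference;
* per-patient, per-phase trabecular HU values under a parameterised
  contrast-enhancement model — an additive HU offset per enhanced phase,
  amplified in females and in younger patients (vertebral marrow in the
  young takes up more contrast), plus patient, vertebra and measurement
  noise;
* labelled 3-D vertebral phantoms: four elliptic-cylinder vertebral
  bodies stacked along the superior-inferior axis, each with a bright
  cortical shell and a trabecular interior at the patient's phase HU;
* a deterministic cohort builder from explicit category / transition
  counts, used to reproduce published marginal tables exactly.

Every generator output is a pure function of (parameters, seed); random
substreams are spawned per patient so regenerating one patient never
perturbs another.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .reference import ReferenceModel, SEXES
from .roi import LabeledVolume
from .cohort import PHASES

HU_LO, HU_HI = 0.0, 500.0  # physiologic truncation bounds for trabecular HU
LEVELS = ("L1", "L2", "L3", "L4")


@dataclass(frozen=True)
class GenerativeParams:
    """Parameters of the synthetic cohort generator.

    Defaults are the "paper-like" preset: a vascular-referral cohort of
    597 adults, mostly male, arterial enhancement ~+24 HU and venous
    ~+16 HU, with stronger enhancement in women (×1.4) and in patients
    under 50.  These are illustrative settings chosen to make the
    synthetic result tables qualitatively resemble a real triphasic CT
    cohort; they are not fitted estimates.
    """

    n_patients: int = 597
    female_fraction: float = 157 / 597
    age_min: float = 18.0
    age_max: float = 95.0
    #: target cohort median age (two-piece uniform sampling); None = uniform
    age_median: float | None = 66.0
    young_mean_by_sex: dict = field(
        default_factory=lambda: {"female": 175.0, "male": 180.0}
    )
    young_sd_by_sex: dict = field(
        default_factory=lambda: {"female": 35.0, "male": 35.0}
    )
    #: HU lost per year after age 30
    age_decline_rate: float = 2.0
    #: inter-patient spread of baseline HU around the age trend
    patient_sd: float = 25.0
    arterial_offset_mean: float = 24.0
    arterial_offset_sd: float = 8.0
    venous_offset_mean: float = 16.0
    venous_offset_sd: float = 6.0
    #: multiplies the enhancement offset for female patients
    sex_enhancement_multiplier: float = 1.4
    #: per-year enhancement gain below the modifier pivot age (50)
    age_enhancement_slope: float = 0.03
    age_enhancement_pivot: float = 50.0
    age_enhancement_cap: float = 2.0
    #: per-vertebra anatomical deviation from the patient value
    vertebra_sd: float = 5.0
    #: per-measurement (per phase × level) noise
    measurement_sd: float = 4.0
    #: voxel-level noise inside phantom interiors
    voxel_noise_sd: float = 10.0
    roi_voxel_count: int = 2000
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.female_fraction <= 1:
            raise ValueError("female_fraction must be in [0, 1]")
        for name in ("arterial_offset_sd", "venous_offset_sd", "patient_sd",
                     "vertebra_sd", "measurement_sd", "voxel_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for m in (self.arterial_offset_mean, self.venous_offset_mean):
            if not np.isfinite(m):
                raise ValueError("enhancement offsets must be finite")

    def enhancement_modifier(self, age: float, sex: str) -> float:
        """Multiplier applied to the contrast offset for one patient."""
        age_mod = 1.0 + self.age_enhancement_slope * max(
            0.0, self.age_enhancement_pivot - age
        )
        age_mod = min(age_mod, self.age_enhancement_cap)
        sex_mod = self.sex_enhancement_multiplier if sex == "female" else 1.0
        return age_mod * sex_mod


def neutral_enhancement(params: GenerativeParams) -> GenerativeParams:
    """Copy of ``params`` with sex/age enhancement modifiers switched off.

    Useful when a study design needs the injected phase offsets to act
    uniformly across the cohort (e.g. offset-recovery checks).
    """
    return replace(params, sex_enhancement_multiplier=1.0, age_enhancement_slope=0.0)


def _expected_hu(params: GenerativeParams, age: float, sex: str) -> float:
    return params.young_mean_by_sex[sex] - params.age_decline_rate * max(0.0, age - 30.0)


# ---------------------------------------------------------------------------
# reference population
# ---------------------------------------------------------------------------

def generate_reference_population(
    params: GenerativeParams,
    seed: int | None = None,
    n_young_per_sex: int = 5000,
    n_per_stratum: int = 500,
    age_bin_edges: tuple[float, ...] = tuple(float(a) for a in range(20, 95, 5)),
) -> tuple[ReferenceModel, dict[str, np.ndarray]]:
    """Sample a reference population and summarise it into a ReferenceModel.

    Young-normal samples are drawn per sex from N(young_mean, young_sd);
    each age stratum is sampled around the age-decline trend evaluated at
    the bin midpoint (last bin open-ended, midpoint of a nominal 5-year
    width).  Returns the model plus the raw young-normal samples.
    """
    rng = np.random.default_rng(params.seed if seed is None else seed)
    young_samples: dict[str, np.ndarray] = {}
    young_mean: dict[str, float] = {}
    young_sd: dict[str, float] = {}
    for s in SEXES:
        x = rng.normal(params.young_mean_by_sex[s], params.young_sd_by_sex[s],
                       size=n_young_per_sex)
        x = np.clip(x, HU_LO, HU_HI)
        young_samples[s] = x
        young_mean[s] = float(x.mean())
        young_sd[s] = float(x.std(ddof=1))

    agematched_mean: dict[tuple[str, int], float] = {}
    agematched_sd: dict[tuple[str, int], float] = {}
    edges = list(age_bin_edges)
    for s in SEXES:
        for b in range(len(edges) - 1):
            mid = 0.5 * (edges[b] + edges[b + 1])
            mu = _expected_hu(params, mid, s)
            x = rng.normal(mu, params.young_sd_by_sex[s], size=n_per_stratum)
            x = np.clip(x, HU_LO, HU_HI)
            agematched_mean[(s, b)] = float(x.mean())
            agematched_sd[(s, b)] = float(x.std(ddof=1))
    model = ReferenceModel(
        young_mean_by_sex=young_mean,
        young_sd_by_sex=young_sd,
        agematched_mean=agematched_mean,
        agematched_sd=agematched_sd,
        age_bin_edges=tuple(edges),
    )
    return model, young_samples


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

def generate_cohort(
    params: GenerativeParams, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Draw a full triphasic cohort.

    Returns ``(patients, measurements, truth)``:

    * ``patients`` — patient_id, age, sex (sex counts by quota:
      ``round(n × female_fraction)`` females exactly);
    * ``measurements`` — one row per patient × phase × level (L1..L4 and
      the L1–L4 aggregate) with mean/median HU, voxel count, ROI volume;
    * ``truth`` — per patient: the noiseless baseline HU and the actual
      enhancement applied in each phase (offset × sex × age modifier).

    The patient's phase value is baseline + applied enhancement; each
    vertebra deviates from it by a fixed anatomical offset plus
    per-measurement noise.
    """
    root = np.random.SeedSequence(params.seed if seed is None else seed)
    cohort_ss, *patient_ss = root.spawn(params.n_patients + 1)
    rng = np.random.default_rng(cohort_ss)

    n_f = int(round(params.n_patients * params.female_fraction))
    sexes = np.array(["female"] * n_f + ["male"] * (params.n_patients - n_f))
    rng.shuffle(sexes)
    n = params.n_patients
    if params.age_median is None:
        ages = rng.uniform(params.age_min, params.age_max, size=n)
    else:
        # two-piece uniform: half below the target median, half above
        n_low = n // 2
        ages = np.concatenate([
            rng.uniform(params.age_min, params.age_median, size=n_low),
            rng.uniform(params.age_median, params.age_max, size=n - n_low),
        ])
        rng.shuffle(ages)

    patients, truth_rows, meas_rows = [], [], []
    for i in range(params.n_patients):
        prng = np.random.default_rng(patient_ss[i])
        pid = f"P{i:04d}"
        age, sex = float(ages[i]), str(sexes[i])
        baseline = _expected_hu(params, age, sex) + prng.normal(0, params.patient_sd)
        baseline = float(np.clip(baseline, HU_LO, HU_HI))
        mod = params.enhancement_modifier(age, sex)
        art = float(prng.normal(params.arterial_offset_mean, params.arterial_offset_sd) * mod)
        ven = float(prng.normal(params.venous_offset_mean, params.venous_offset_sd) * mod)
        patients.append(dict(patient_id=pid, age=age, sex=sex))
        truth_rows.append(
            dict(patient_id=pid, age=age, sex=sex, baseline_hu=baseline,
                 arterial_offset=art, venous_offset=ven)
        )
        level_dev = prng.normal(0, params.vertebra_sd, size=len(LEVELS))
        for phase, offset in zip(PHASES, (0.0, art, ven)):
            level_values = []
            for li, level in enumerate(LEVELS):
                v = baseline + offset + level_dev[li] + prng.normal(0, params.measurement_sd)
                v = float(np.clip(v, HU_LO, HU_HI))
                level_values.append(v)
                meas_rows.append(_measurement_row(params, pid, phase, level, v))
            meas_rows.append(
                _measurement_row(params, pid, phase, "L1L4",
                                 float(np.mean(level_values)), n_levels=len(LEVELS))
            )
    return (
        pd.DataFrame(patients),
        pd.DataFrame(meas_rows),
        pd.DataFrame(truth_rows),
    )


def _measurement_row(params, pid, phase, level, value, n_levels=1):
    count = params.roi_voxel_count * n_levels
    return dict(
        patient_id=pid, phase=phase, level=level,
        mean_hu=value, median_hu=value,
        voxel_count=count, roi_volume_ml=count / 1000.0,  # 1 mm isotropic
    )


# ---------------------------------------------------------------------------
# phantoms
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and tissue values of the 4-vertebra phantom."""

    shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    background_hu: float = 40.0
    shell_hu: float = 400.0
    shell_voxels: int = 2
    #: ellipse semi-axes as fractions of the in-plane grid half-extent
    semi_axis_frac: tuple[float, float] = (0.55, 0.45)
    #: gap between stacked vertebral bodies, voxels
    gap: int = 2


def generate_phantom(
    interior_hu: float,
    spec: PhantomSpec = PhantomSpec(),
    voxel_noise_sd: float = 0.0,
    seed: int = 0,
) -> LabeledVolume:
    """Labelled 4-vertebra phantom with interiors at ``interior_hu``.

    Vertebral bodies are elliptic cylinders stacked along the third
    (superior-inferior) grid axis, labelled 1..4 (L1..L4).  Each has a
    cortical shell of ``shell_hu`` and a trabecular interior of
    ``interior_hu`` plus optional Gaussian voxel noise; background is
    soft tissue.
    """
    nx, ny, nz = spec.shape
    slab = nz // 4
    height = slab - spec.gap
    if height < 3 + 2 * spec.shell_voxels:
        raise ValueError(f"grid {spec.shape} too small for four vertebral bodies")
    a = spec.semi_axis_frac[0] * nx / 2.0
    b = spec.semi_axis_frac[1] * ny / 2.0
    if min(a, b) <= spec.shell_voxels + 1:
        raise ValueError("ellipse too small for the requested shell thickness")

    rng = np.random.default_rng(seed)
    image = np.full(spec.shape, spec.background_hu, dtype=float)
    mask = np.zeros(spec.shape, dtype=int)

    x = np.arange(nx) - (nx - 1) / 2.0
    y = np.arange(ny) - (ny - 1) / 2.0
    xx, yy = np.meshgrid(x, y, indexing="ij")
    outer = (xx / a) ** 2 + (yy / b) ** 2 <= 1.0
    inner = (xx / (a - spec.shell_voxels)) ** 2 + (yy / (b - spec.shell_voxels)) ** 2 <= 1.0

    for label in range(1, 5):
        z0 = (label - 1) * slab + spec.gap // 2
        z1 = z0 + height
        core_z0, core_z1 = z0 + spec.shell_voxels, z1 - spec.shell_voxels
        for z in range(z0, z1):
            mask[:, :, z][outer] = label
            image[:, :, z][outer] = spec.shell_hu
        for z in range(core_z0, core_z1):
            core = image[:, :, z]
            vals = np.full(int(inner.sum()), interior_hu)
            if voxel_noise_sd > 0:
                vals = vals + rng.normal(0, voxel_noise_sd, size=vals.size)
            core[inner] = vals
    return LabeledVolume(image=image, mask=mask, voxel_spacing=spec.spacing)


def write_phantom(vol: LabeledVolume, image_path, mask_path) -> None:
    """Write a phantom as a NIfTI image/mask pair (1 mm-scaled affine)."""
    import nibabel as nib

    affine = np.diag(list(vol.voxel_spacing) + [1.0])
    nib.save(nib.Nifti1Image(vol.image.astype(np.float32), affine), str(image_path))
    nib.save(nib.Nifti1Image(vol.mask.astype(np.int16), affine), str(mask_path))


# ---------------------------------------------------------------------------
# deterministic cohorts from explicit category counts
# ---------------------------------------------------------------------------

#: Worked-example stratum specification: a 597-patient triphasic
#: vascular-referral cohort (157 women, 440 men, 78 under 50) with the
#: diagnostic transition counts reported by a published opportunistic-CT
#: reclassification analysis.  Keys of the arterial/venous maps are
#: (baseline category -> enhanced-phase category) moves.
EXAMPLE_RECLASSIFICATION_GROUPS: tuple = (
    dict(name="female-under", sex="female", age=41.0, n=17,
         baseline={"normal": 8, "osteopenia": 9},
         arterial={}, venous={}),
    dict(name="male-under", sex="male", age=41.0, n=61,
         baseline={"normal": 33, "osteopenia": 28},
         arterial={("osteopenia", "normal"): 11},
         venous={("osteopenia", "normal"): 5}),
    dict(name="female-over", sex="female", age=72.0, n=140,
         baseline={"normal": 8, "osteopenia": 27, "osteoporosis": 104, "unknown": 1},
         arterial={("osteopenia", "normal"): 16,
                   ("osteoporosis", "osteopenia"): 29,
                   ("osteoporosis", "normal"): 2},
         venous={("osteopenia", "normal"): 8,
                 ("osteoporosis", "osteopenia"): 25,
                 ("osteoporosis", "normal"): 2}),
    dict(name="male-over", sex="male", age=68.0, n=379,
         baseline={"normal": 59, "osteopenia": 212, "osteoporosis": 106, "unknown": 2},
         arterial={("osteopenia", "normal"): 70,
                   ("osteoporosis", "osteopenia"): 43,
                   ("osteoporosis", "normal"): 4},
         venous={("osteopenia", "normal"): 35,
                 ("osteoporosis", "osteopenia"): 55,
                 ("osteoporosis", "normal"): 4}),
)


def example_reclassification_cohort(level: str = "L1") -> tuple[pd.DataFrame, pd.DataFrame]:
    """(patients, scored) realising :data:`EXAMPLE_RECLASSIFICATION_GROUPS`."""
    return cohort_from_category_counts(list(EXAMPLE_RECLASSIFICATION_GROUPS), level=level)


def cohort_from_category_counts(
    groups: list[dict], level: str = "L1"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Build a scored cohort realising explicit marginal/transition counts.

    Each entry of ``groups`` describes a stratum::

        dict(name="female-over", sex="female", age=72, n=140,
             baseline={"normal": 8, "osteopenia": 27, "osteoporosis": 104,
                       "unknown": 1},
             arterial={("osteopenia", "normal"): 16,
                       ("osteoporosis", "osteopenia"): 29},
             venous={...})

    ``baseline`` allocates diagnostic categories in the non-contrast
    phase (must sum to ``n``); ``arterial`` / ``venous`` map directed
    transitions to the number of patients making them — unlisted patients
    keep their baseline category.  Transition counts per source category
    must not exceed its baseline count.  Returns ``(patients, scored)``
    where ``scored`` has one row per patient × phase with a ``category``
    column, directly consumable by the transition-table machinery.
    """
    patients, scored = [], []
    pid_counter = 0
    for g in groups:
        n = g["n"]
        baseline = dict(g["baseline"])
        if sum(baseline.values()) != n:
            raise ValueError(
                f"group {g.get('name')}: baseline counts sum to "
                f"{sum(baseline.values())}, expected n={n}"
            )
        # stable expansion: patients of one baseline category are contiguous
        base_cats = [c for c, k in baseline.items() for _ in range(k)]
        ids = [f"C{pid_counter + i:04d}" for i in range(n)]
        pid_counter += n
        for pid in ids:
            patients.append(dict(patient_id=pid, age=g["age"], sex=g["sex"]))

        phase_cats = {"noncontrast": dict(zip(ids, base_cats))}
        for phase in ("arterial", "venous"):
            moves = dict(g.get(phase, {}))
            assigned = dict(zip(ids, base_cats))
            used: dict[str, int] = {}
            for (src, dst), k in moves.items():
                candidates = [p for p in ids if phase_cats["noncontrast"][p] == src]
                start = used.get(src, 0)
                if start + k > len(candidates):
                    raise ValueError(
                        f"group {g.get('name')}: {phase} moves {src}->{dst} "
                        f"exceed the {len(candidates)} baseline {src} patients"
                    )
                for p in candidates[start:start + k]:
                    assigned[p] = dst
                used[src] = start + k
            phase_cats[phase] = assigned

        for phase, assigned in phase_cats.items():
            for pid in ids:
                scored.append(
                    dict(patient_id=pid, age=g["age"], sex=g["sex"], phase=phase,
                         level=level, category=assigned[pid])
                )
    return pd.DataFrame(patients), pd.DataFrame(scored)
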