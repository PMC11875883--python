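"""Seeded generator of ADNI-like longitudinal cohorts.

Emulates the structure of a merged longitudinal Alzheimer's cohort: up to
six annual visits (M0..M60), monotone non-reversing CN -> MCI -> AD
diagnosis paths, six regional brain volumes trending down over time except
the ventricles trending up, demographics and APOE4 genotype, plus two toy
3-D imaging modalities rendered from a shared scalar atrophy state so
cross-modal reconstruction is learnable.  Per-element missingness defaults
match the observed rates of a real merged cohort (MRI 45.8%, PET 77.8%,
diagnosis 31.0%, biomarkers 47.5-54.4%).

Everything is deterministic given ``CohortConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import (
    BIOMARKERS,
    DIAGNOSES,
    PatientSequence,
    VisitRecord,
)

__all__ = [
    "CohortConfig",
    "LatentAtrophyState",
    "generate_cohort",
    "render_volumes",
    "apply_missingness",
    "write_cohort",
    "read_cohort",
]

# disease paths as (start stage, end stage); stages index CN < MCI < AD
PATHS = ("CN-CN", "MCI-MCI", "AD-AD", "CN-MCI", "MCI-AD", "CN-AD")
_PATH_STAGES = {
    "CN-CN": (0, 0), "MCI-MCI": (1, 1), "AD-AD": (2, 2),
    "CN-MCI": (0, 1), "MCI-AD": (1, 2), "CN-AD": (0, 2),
}
# path frequencies of the real cohort: 426 / 361 / 184 / 101 / 289 / 8
_PATH_COUNTS = np.array([426.0, 361.0, 184.0, 101.0, 289.0, 8.0])

_BASE_MEAN = np.array([39.0, 6.9, 1050.0, 3.5, 17.5, 19.5])  # ml
_BASE_STD = np.array([11.0, 0.9, 100.0, 0.7, 2.5, 3.0])
# per-month biomarker slopes by current stage; ventricles grow, the rest shrink
_SLOPES = {
    0: np.array([0.04, -0.002, -0.15, -0.001, -0.004, -0.004]),
    1: np.array([0.10, -0.008, -0.40, -0.004, -0.012, -0.012]),
    2: np.array([0.18, -0.015, -0.80, -0.008, -0.025, -0.025]),
}
_BIO_NOISE = np.array([0.8, 0.06, 6.0, 0.05, 0.18, 0.20])  # ml

# cross-sectional stage effect at baseline (ml at full atrophy): AD patients
# start with enlarged ventricles and smaller regional volumes
_BIO_STAGE_EFFECT = np.array([12.0, -1.2, -60.0, -0.6, -1.8, -1.8])

_STAGE_ATROPHY = np.array([0.15, 0.50, 0.85])


@dataclass
class CohortConfig:
    """Generator settings; defaults are the study conditions of the package."""

    n_patients: int = 200
    n_visits: int = 6
    visit_interval_months: float = 12.0
    path_probs: np.ndarray = field(
        default_factory=lambda: _PATH_COUNTS / _PATH_COUNTS.sum()
    )
    biomarker_baseline_mean: np.ndarray = field(default_factory=lambda: _BASE_MEAN.copy())
    biomarker_baseline_std: np.ndarray = field(default_factory=lambda: _BASE_STD.copy())
    stage_slopes: dict = field(default_factory=lambda: {k: v.copy() for k, v in _SLOPES.items()})
    biomarker_noise_std: np.ndarray = field(default_factory=lambda: _BIO_NOISE.copy())
    volume_shape: tuple = (16, 20, 16)
    volume_noise_std: float = 0.02
    missing_rates: dict = field(
        default_factory=lambda: {
            "mri": 0.458, "pet": 0.778, "diagnosis": 0.310,
            "ventricles": 0.475, "hippocampus": 0.511, "wholebrain": 0.458,
            "entorhinal": 0.544, "fusiform": 0.544, "midtemp": 0.544,
            "age": 0.0, "gender": 0.0, "education": 0.0, "apoe4": 0.0,
        }
    )
    visit_missing_rate: float = 0.0  # completely-missing-visit mechanism
    render_images: bool = True
    seed: int = 0

    def __post_init__(self):
        self.path_probs = np.asarray(self.path_probs, dtype=float)
        if not np.isclose(self.path_probs.sum(), 1.0):
            raise ValueError("path probabilities must sum to 1")
        for name, r in self.missing_rates.items():
            if not 0.0 <= r < 1.0:
                raise ValueError(f"missing rate for {name!r} must lie in [0, 1)")
        if not 0.0 <= self.visit_missing_rate < 1.0:
            raise ValueError("visit_missing_rate must lie in [0, 1)")
        if any(s <= 0 for s in self.volume_shape):
            raise ValueError("volume shape must be positive")


@dataclass
class LatentAtrophyState:
    """Shared scalar atrophy trajectory driving biomarkers and both images."""

    atrophy: np.ndarray  # (T,), nondecreasing in [0, 1]
    stages: np.ndarray  # (T,), int stage indices, nondecreasing
    transition_months: tuple = ()

    def __post_init__(self):
        if np.any(np.diff(self.atrophy) < 0):
            raise ValueError("atrophy trajectory must be nondecreasing")


def _stage_sequence(path: str, n_visits: int, rng: np.random.Generator) -> np.ndarray:
    start, end = _PATH_STAGES[path]
    stages = np.full(n_visits, start, dtype=int)
    if end == start:
        return stages
    if end - start == 1:
        t = rng.integers(1, n_visits)
        stages[t:] = end
    else:  # CN -> AD: two ordered transitions
        t1, t2 = sorted(rng.choice(np.arange(1, n_visits), size=2, replace=False))
        stages[t1:] = 1
        stages[t2:] = 2
    return stages


def _atrophy_from_stages(stages: np.ndarray, offset: float, months: np.ndarray) -> np.ndarray:
    a = _STAGE_ATROPHY[stages] + offset + 0.002 * (months / 12.0)
    return np.clip(np.maximum.accumulate(a), 0.0, 1.0)


def generate_cohort(config: CohortConfig) -> list:
    """Generate a fully observed cohort (all masks one)."""
    rng = np.random.default_rng(config.seed)
    months = np.arange(config.n_visits) * config.visit_interval_months
    cohort = []
    for i in range(config.n_patients):
        path = PATHS[rng.choice(len(PATHS), p=config.path_probs)]
        stages = _stage_sequence(path, config.n_visits, rng)
        offset = rng.uniform(-0.05, 0.05)
        atrophy = _atrophy_from_stages(stages, offset, months)
        trans = tuple(months[t] for t in range(1, len(stages)) if stages[t] != stages[t - 1])
        state = LatentAtrophyState(atrophy=atrophy, stages=stages, transition_months=trans)

        icv = float(rng.normal(1500.0, 120.0))
        base_age = float(np.clip(rng.normal(73.0, 6.0), 55.0, 92.0))
        gender = "M" if rng.random() < 0.46 else "F"
        education = float(np.clip(rng.normal(16.0, 2.5), 6.0, 22.0))
        apoe4 = int(rng.choice(3, p=[0.55, 0.35, 0.10]))

        stage_frac = (atrophy[0] - _STAGE_ATROPHY[0]) / (_STAGE_ATROPHY[2] - _STAGE_ATROPHY[0])
        # regional volumes scale with head size; ICV division removes this
        bio0 = (config.biomarker_baseline_mean
                + _BIO_STAGE_EFFECT * stage_frac
                + rng.standard_normal(6) * config.biomarker_baseline_std) * (icv / 1500.0)
        bio = np.zeros((config.n_visits, 6))
        bio[0] = bio0
        for t in range(1, config.n_visits):
            gap = months[t] - months[t - 1]
            bio[t] = bio[t - 1] + config.stage_slopes[int(stages[t])] * gap
        bio = bio + rng.standard_normal(bio.shape) * config.biomarker_noise_std
        bio = np.maximum(bio, 0.05)

        if config.render_images:
            vol_seed = int(rng.integers(0, 2**31 - 1))
            vols = render_volumes(state, config.volume_shape, vol_seed,
                                  noise_std=config.volume_noise_std)
        else:
            vols = [{"mri": None, "pet": None} for _ in range(config.n_visits)]

        visits = [
            VisitRecord(
                timestamp_months=float(months[t]),
                diagnosis=DIAGNOSES[stages[t]],
                biomarkers=bio[t],
                age=base_age + months[t] / 12.0,
                gender=gender,
                education=education,
                apoe4=apoe4,
                volumes=vols[t],
            )
            for t in range(config.n_visits)
        ]
        seq = PatientSequence(patient_id=f"SYN{i:05d}", icv=icv, visits=visits)
        seq.atrophy_state = state  # generator ground truth, kept for probes
        cohort.append(seq)
    return cohort


def _grids(shape):
    axes = [np.linspace(-1.0, 1.0, s) for s in shape]
    return np.meshgrid(*axes, indexing="ij")


def render_volumes(state: LatentAtrophyState, shape, seed: int, noise_std: float = 0.02):
    """Render the two toy modalities from the atrophy trajectory.

    Modality "mri": a bright central (hippocampus-like) blob that fades and
    shrinks with atrophy inside an enlarging dark ventricular core.
    Modality "pet": two lateral uptake blobs whose intensity fades with
    atrophy.  Distinct smooth layouts of the same scalar, plus independent
    Gaussian noise, clipped to [0, 1], so cross-modal reconstruction is
    learnable by design: the blob supports are wide enough that the
    atrophy-explained voxel variance dominates the noise floor at the
    default resolution.  Deterministic given (state, seed).
    """
    rng = np.random.default_rng(seed)
    X, Y, Z = _grids(shape)
    r2 = X**2 + Y**2 + Z**2
    brain = np.exp(-1.2 * r2)
    out = []
    for a in state.atrophy:
        # MRI-like: central blob amplitude falls with atrophy, ventricle grows
        central = (0.75 - 0.55 * a) * np.exp(-(r2 / (0.12 + 0.03 * a)))
        ventricle = (0.25 + 0.45 * a) * np.exp(-((X**2 + (Y - 0.25) ** 2 + Z**2) / 0.05))
        mri = 0.15 + 0.45 * brain + central - ventricle
        # PET-like: lateral uptake blobs fade with atrophy
        lat = np.exp(-(((np.abs(X) - 0.5) ** 2 + Y**2 + Z**2) / 0.10))
        pet = 0.10 + 0.25 * brain + (0.70 - 0.55 * a) * lat
        vols = {}
        for name, v in (("mri", mri), ("pet", pet)):
            v = v + rng.standard_normal(shape) * noise_std
            vols[name] = np.clip(v, 0.0, 1.0)
        out.append(vols)
    return out


def apply_missingness(cohort, config: CohortConfig, seed: int | None = None):
    """Drop elements with independent Bernoulli draws at the configured rates.

    The baseline diagnosis is never dropped.  With ``visit_missing_rate`` > 0,
    whole non-baseline visits are additionally blanked.  Returns a new cohort;
    masks and intervals are rebuilt.
    """
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    rates = config.missing_rates
    out = []
    for seq in cohort:
        visits = []
        for t, v in enumerate(seq.visits):
            drop_all = t > 0 and rng.random() < config.visit_missing_rate
            bio = v.biomarkers.copy()
            for j, name in enumerate(BIOMARKERS):
                if drop_all or rng.random() < rates.get(name, 0.0):
                    bio[j] = np.nan
            vols = {}
            for name in ("mri", "pet"):
                keep = v.volumes.get(name) is not None and not drop_all \
                    and rng.random() >= rates.get(name, 0.0)
                vols[name] = v.volumes.get(name) if keep else None
            diag = v.diagnosis
            if t > 0 and (drop_all or rng.random() < rates.get("diagnosis", 0.0)):
                diag = None
            keep_demo = not drop_all
            visits.append(VisitRecord(
                timestamp_months=v.timestamp_months,
                diagnosis=diag,
                biomarkers=bio,
                age=v.age if keep_demo and rng.random() >= rates.get("age", 0.0) else None,
                gender=v.gender if keep_demo and rng.random() >= rates.get("gender", 0.0) else None,
                education=v.education if keep_demo and rng.random() >= rates.get("education", 0.0) else None,
                apoe4=v.apoe4 if keep_demo and rng.random() >= rates.get("apoe4", 0.0) else None,
                volumes=vols,
            ))
        new = PatientSequence(patient_id=seq.patient_id, icv=seq.icv, visits=visits)
        if hasattr(seq, "atrophy_state"):
            new.atrophy_state = seq.atrophy_state
        out.append(new)
    return out


# ----------------------------------------------------------------------
# cohort IO: CSV table + one NIfTI file per (patient, visit, modality)


def write_cohort(cohort, outdir) -> None:
    import os

    import nibabel as nib

    os.makedirs(outdir, exist_ok=True)
    imgdir = os.path.join(outdir, "volumes")
    rows = []
    for seq in cohort:
        for v in seq.visits:
            paths = {}
            for name in ("mri", "pet"):
                vol = v.volumes.get(name)
                if vol is None:
                    paths[name] = ""
                    continue
                os.makedirs(imgdir, exist_ok=True)
                fn = f"{seq.patient_id}_M{int(v.timestamp_months):03d}_{name}.nii.gz"
                nib.save(nib.Nifti1Image(vol.astype(np.float32), np.eye(4)),
                         os.path.join(imgdir, fn))
                paths[name] = os.path.join("volumes", fn)
            row = {
                "patient_id": seq.patient_id,
                "visit_month": v.timestamp_months,
                "diagnosis": v.diagnosis or "",
                "icv": seq.icv,
                "age_baseline": "" if v.age is None else v.age - v.timestamp_months / 12.0,
                "gender": v.gender or "",
                "education": "" if v.education is None else v.education,
                "apoe4": "" if v.apoe4 is None else v.apoe4,
                "mri_path": paths["mri"],
                "pet_path": paths["pet"],
            }
            for j, name in enumerate(BIOMARKERS):
                row[name] = v.biomarkers[j]
            rows.append(row)
    pd.DataFrame(rows).to_csv(os.path.join(outdir, "cohort.csv"), index=False)


def read_cohort(outdir) -> list:
    import os

    import nibabel as nib

    df = pd.read_csv(os.path.join(outdir, "cohort.csv"))
    cohort = []
    for pid, grp in df.groupby("patient_id", sort=True):
        grp = grp.sort_values("visit_month")
        if grp["icv"].isna().any():
            raise ValueError(f"patient {pid} lacks an ICV value")
        visits = []
        for _, r in grp.iterrows():
            vols = {}
            for name in ("mri", "pet"):
                p = r[f"{name}_path"]
                if isinstance(p, str) and p:
                    vols[name] = np.asarray(
                        nib.load(os.path.join(outdir, p)).get_fdata(), dtype=float
                    )
                else:
                    vols[name] = None
            diag = r["diagnosis"] if isinstance(r["diagnosis"], str) and r["diagnosis"] else None
            visits.append(VisitRecord(
                timestamp_months=float(r["visit_month"]),
                diagnosis=diag,
                biomarkers=np.array([r[n] for n in BIOMARKERS], dtype=float),
                age=None if pd.isna(r["age_baseline"]) else float(r["age_baseline"]) + float(r["visit_month"]) / 12.0,
                gender=r["gender"] if isinstance(r["gender"], str) and r["gender"] else None,
                education=None if pd.isna(r["education"]) else float(r["education"]),
                apoe4=None if pd.isna(r["apoe4"]) else int(r["apoe4"]),
                volumes=vols,
            ))
        cohort.append(PatientSequence(patient_id=str(pid), icv=float(grp["icv"].iloc[0]),
                                      visits=visits))
    return cohort
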