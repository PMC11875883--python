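"""Canonical longitudinal data structures and tabular preprocessing.

A cohort is a list of :class:`PatientSequence`; each sequence holds ordered
:class:`VisitRecord` objects plus per-visit element-level masks ``m_t`` and
time-since-last-observation intervals ``delta_t``.

Element indexing (fixed; data level, 13 elements)::

    0 mri, 1 pet, 2..7 biomarkers (ventricles, hippocampus, wholebrain,
    entorhinal, fusiform, midtemp), 8 age, 9 gender, 10 education,
    11 apoe4, 12 diagnosis

Tabular model slots (13 columns after encoding)::

    0..5 biomarkers (ICV-normalized, z-scored), 6 age (z), 7..8 gender
    one-hot, 9 education (z), 10..12 APOE4 one-hot

Timestamps and intervals are in months; age is propagated from the
baseline age in years (months / 12).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

BIOMARKERS = ("ventricles", "hippocampus", "wholebrain", "entorhinal", "fusiform", "midtemp")
MODALITIES = ("mri", "pet")
ELEMENTS = MODALITIES + BIOMARKERS + ("age", "gender", "education", "apoe4", "diagnosis")
N_ELEMENTS = len(ELEMENTS)  # 13

DIAGNOSES = ("CN", "MCI", "AD")
DIAGNOSIS_INDEX = {d: i for i, d in enumerate(DIAGNOSES)}

E_MRI, E_PET = 0, 1
E_BIO = slice(2, 8)
E_AGE, E_GENDER, E_EDU, E_APOE, E_DIAG = 8, 9, 10, 11, 12

# tabular slot layout (after one-hot encoding)
N_TAB_SLOTS = 13
S_BIO = slice(0, 6)
S_AGE = 6
S_GENDER = slice(7, 9)
S_EDU = 9
S_APOE = slice(10, 13)
# data-level element index backing each tabular slot
TAB_SLOT_ELEMENT = np.array([2, 3, 4, 5, 6, 7, E_AGE, E_GENDER, E_GENDER, E_EDU,
                             E_APOE, E_APOE, E_APOE])


@dataclass
class VisitRecord:
    """One clinical visit: timestamp, diagnosis, biomarkers, covariates, scans.

    ``biomarkers`` is a length-6 array in ml with NaN marking unobserved
    entries; ``volumes`` maps modality name to a 3-D array in [0, 1] or None.
    """

    timestamp_months: float
    diagnosis: str | None = None
    biomarkers: np.ndarray = field(default_factory=lambda: np.full(6, np.nan))
    age: float | None = None
    gender: str | None = None  # "M" / "F"
    education: float | None = None
    apoe4: int | None = None  # 0, 1 or 2 copies
    volumes: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.timestamp_months < 0:
            raise ValueError("visit timestamp must be nonnegative")
        self.biomarkers = np.asarray(self.biomarkers, dtype=float)
        if self.biomarkers.shape != (6,):
            raise ValueError("expected 6 biomarker values")
        if self.diagnosis is not None and self.diagnosis not in DIAGNOSES:
            raise ValueError(f"unknown diagnosis level {self.diagnosis!r}")
        if self.apoe4 is not None and self.apoe4 not in (0, 1, 2):
            raise ValueError(f"APOE4 copy number must be 0, 1 or 2, got {self.apoe4}")
        if self.gender is not None and self.gender not in ("M", "F"):
            raise ValueError(f"unknown gender level {self.gender!r}")
        for name, vol in self.volumes.items():
            if vol is not None:
                vol = np.asarray(vol)
                if vol.min() < 0.0 or vol.max() > 1.0:
                    raise ValueError(f"{name} volume values must lie in [0, 1]")
                self.volumes[name] = vol


@dataclass
class PatientSequence:
    """Ordered visits for one patient plus masks and intervals."""

    patient_id: str
    icv: float
    visits: list
    masks: np.ndarray | None = None  # (T, 13) in {0, 1}
    intervals: np.ndarray | None = None  # (T, 13), months
    n_history: int | None = None  # T - 1
    n_followup: int | None = None  # K

    def __post_init__(self):
        ts = self.timestamps
        if np.any(np.diff(ts) <= 0):
            raise ValueError("visit timestamps must be strictly increasing")
        if self.masks is None:
            self.masks = build_masks(self.visits)
        if self.intervals is None:
            self.intervals = build_intervals(ts, self.masks)

    @property
    def timestamps(self) -> np.ndarray:
        return np.array([v.timestamp_months for v in self.visits], dtype=float)

    @property
    def n_visits(self) -> int:
        return len(self.visits)

    def refresh(self) -> None:
        """Recompute masks and intervals after visit edits (e.g. missingness)."""
        self.masks = build_masks(self.visits)
        self.intervals = build_intervals(self.timestamps, self.masks)


def build_masks(visits) -> np.ndarray:
    """Binary observation mask per visit over the 13 data-level elements.

    An entry is 1 iff that element is recorded at that visit; imaging flags
    cover each modality, the diagnosis flag is ``m_t^(y)``.
    """
    ts = np.array([v.timestamp_months for v in visits], dtype=float)
    if len(set(ts.tolist())) != len(ts):
        raise ValueError("duplicate visit timestamps in one patient sequence")
    m = np.zeros((len(visits), N_ELEMENTS))
    for t, v in enumerate(visits):
        m[t, E_MRI] = 1.0 if v.volumes.get("mri") is not None else 0.0
        m[t, E_PET] = 1.0 if v.volumes.get("pet") is not None else 0.0
        m[t, E_BIO] = ~np.isnan(v.biomarkers)
        m[t, E_AGE] = v.age is not None
        m[t, E_GENDER] = v.gender is not None
        m[t, E_EDU] = v.education is not None
        m[t, E_APOE] = v.apoe4 is not None
        m[t, E_DIAG] = v.diagnosis is not None
    return m


def build_intervals(timestamps: np.ndarray, masks: np.ndarray) -> np.ndarray:
    """Per-element latency since the last observed visit.

    ``delta[0] = 0``; for t > 1 the gap to the previous visit is added, and
    if the element was unobserved there the previous latency accumulates.
    """
    timestamps = np.asarray(timestamps, dtype=float)
    if np.any(np.diff(timestamps) <= 0):
        raise ValueError("timestamps must be strictly increasing")
    masks = np.asarray(masks, dtype=float)
    delta = np.zeros_like(masks)
    for t in range(1, len(timestamps)):
        gap = timestamps[t] - timestamps[t - 1]
        delta[t] = gap + (1.0 - masks[t - 1]) * delta[t - 1]
    return delta


@dataclass
class GlobalStats:
    """Per-slot normalization statistics computed on a training split.

    ``mean``/``std`` apply to continuous tabular slots (one-hot slots keep
    mean 0 / std 1 so they pass through untouched); ``slot_global_mean`` is
    the post-normalization training mean of every slot, used to impute
    unobserved entries at the first visit.
    """

    mean: np.ndarray
    std: np.ndarray
    slot_global_mean: np.ndarray

    def __post_init__(self):
        if np.any(self.std <= 0):
            raise ValueError("standard deviations must be positive")


_CONTINUOUS_SLOTS = np.zeros(N_TAB_SLOTS, dtype=bool)
_CONTINUOUS_SLOTS[S_BIO] = True
_CONTINUOUS_SLOTS[S_AGE] = True
_CONTINUOUS_SLOTS[S_EDU] = True


def raw_tabular(seq: PatientSequence) -> np.ndarray:
    """Encode a sequence into the 13 tabular slots, pre-normalization.

    Biomarkers are divided by the patient's ICV; age is propagated from the
    baseline age by elapsed months; gender and APOE4 are one-hot encoded.
    Unobserved entries are NaN.
    """
    T = seq.n_visits
    X = np.full((T, N_TAB_SLOTS), np.nan)
    base_age = None
    for v in seq.visits:
        if v.age is not None:
            base_age = v.age - v.timestamp_months / 12.0
            break
    for t, v in enumerate(seq.visits):
        X[t, S_BIO] = v.biomarkers / seq.icv
        if base_age is not None:
            X[t, S_AGE] = base_age + v.timestamp_months / 12.0
        if v.gender is not None:
            X[t, S_GENDER] = 0.0
            X[t, 7 + (0 if v.gender == "M" else 1)] = 1.0
        if v.education is not None:
            X[t, S_EDU] = v.education
        if v.apoe4 is not None:
            X[t, S_APOE] = 0.0
            X[t, 10 + v.apoe4] = 1.0
    return X


def tabular_masks(seq: PatientSequence) -> np.ndarray:
    """Broadcast the element-level mask onto the 13 tabular slots."""
    return seq.masks[:, TAB_SLOT_ELEMENT]


def tabular_intervals(seq: PatientSequence) -> np.ndarray:
    return seq.intervals[:, TAB_SLOT_ELEMENT]


def compute_global_stats(training_split) -> GlobalStats:
    """Fit per-slot mean/std over observed entries of a training split.

    Deterministic given the split.  A slot observed fewer than twice (or with
    zero variance) falls back to std 1; a never-observed slot falls back to
    mean 0 / std 1 with a warning.
    """
    if not training_split:
        raise ValueError("training split must be nonempty")
    rows = np.concatenate([raw_tabular(s) for s in training_split], axis=0)
    obs = np.concatenate([tabular_masks(s) for s in training_split], axis=0) > 0
    mean = np.zeros(N_TAB_SLOTS)
    std = np.ones(N_TAB_SLOTS)
    raw_mean = np.zeros(N_TAB_SLOTS)
    for j in range(N_TAB_SLOTS):
        vals = rows[obs[:, j], j]
        vals = vals[~np.isnan(vals)]
        if vals.size == 0:
            warnings.warn(
                f"tabular slot {j} never observed in training split; "
                "falling back to mean 0, std 1"
            )
            continue
        raw_mean[j] = vals.mean()
        if _CONTINUOUS_SLOTS[j]:
            mean[j] = vals.mean()
            s = vals.std()
            std[j] = s if (vals.size > 1 and s > 0) else 1.0
    slot_global_mean = (raw_mean - mean) / std
    return GlobalStats(mean=mean, std=std, slot_global_mean=slot_global_mean)


def preprocess_tabular(seq: PatientSequence, stats: GlobalStats) -> np.ndarray:
    """Normalized (T, 13) feature table; unobserved entries are set to 0.

    Continuous slots are z-scored with training statistics; one-hot slots
    pass through.  The transform is invertible for biomarkers via
    :func:`inverse_biomarkers`.
    """
    X = (raw_tabular(seq) - stats.mean) / stats.std
    X[np.isnan(X)] = 0.0
    return X


def inverse_biomarkers(z: np.ndarray, icv: float, stats: GlobalStats) -> np.ndarray:
    """Map z-scored, ICV-normalized biomarker slots back to ml."""
    return (np.asarray(z) * stats.std[S_BIO] + stats.mean[S_BIO]) * icv
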