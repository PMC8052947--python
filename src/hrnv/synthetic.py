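"""Synthetic ED chest-pain cohorts for exercising the full pipeline.

Real 30-day-MACE cohorts with RR tachograms are not publicly deposited, so
this module generates cohorts with the statistical structure the analysis
assumes: a binary outcome at a configurable prevalence, a registry of 174
candidate variables (32 clinical + 142 RR-derived stream features), a small
set of genuinely discriminative variables with configurable effect sizes, RR
tachograms with LF/HF oscillatory structure whose vagally mediated
variability is reduced in the MACE group, and bounded integer HEART/TIMI/
GRACE scores correlated with the outcome.

Simulation is outcome-conditional: the outcome is drawn first and covariates
are drawn given the group, which gives direct control over prevalence and
per-variable effect sizes for recovery tests.  Everything is a deterministic
function of the spec seed.

``reference_cohort_counts`` carries a small set of printed contingency counts from a
published 795-patient cohort, used to check the descriptive-statistics code
against exact arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .features import FEATURE_NAMES, feature_table
from .model import derive_seed
from .rr import RRSeries, write_rr_file

__all__ = [
    "RRModel",
    "CohortSpec",
    "simulate_rr",
    "simulate_cohort",
    "reference_cohort_counts",
    "cohort_summary",
    "CLINICAL_NAMES",
    "CANDIDATE_NAMES",
    "SCORE_NAMES",
    "OUTCOME",
    "DEFAULT_EFFECTS",
    "write_cohort_artifacts",
]

OUTCOME = "mace"
SCORE_NAMES = ("heart", "timi", "grace")

# Continuous clinical variables: name -> (non-MACE mean, SD). Troponin is
# simulated on the log scale (heavily right-skewed in practice).
CONTINUOUS_BASE: dict[str, tuple[float, float]] = {
    "age": (59.0, 12.0),
    "temperature": (36.4, 0.5),
    "heart_rate": (76.0, 15.0),
    "resp_rate": (18.0, 1.5),
    "sbp": (139.0, 25.0),
    "dbp": (76.0, 12.0),
    "spo2": (98.5, 1.5),
    "pain_score": (2.5, 2.5),
    "troponin": (2.3, 1.4),   # log ng/L
    "ck_mb": (0.9, 0.5),      # log ng/mL
}
_LOG_SCALE = ("troponin", "ck_mb")

# Binary clinical variables: name -> non-MACE prevalence.
BINARY_BASE: dict[str, float] = {
    "male": 0.646,
    "race_chinese": 0.61, "race_indian": 0.17, "race_malay": 0.19,
    "ihd": 0.416, "diabetes": 0.314, "hypertension": 0.635,
    "hypercholesterolaemia": 0.593, "stroke": 0.078, "cancer": 0.040,
    "respiratory_disease": 0.047, "ckd": 0.111, "chf": 0.053,
    "prior_pci": 0.239, "prior_cabg": 0.082, "prior_ami": 0.155,
    "smoker": 0.226,
    "st_elevation": 0.031, "st_depression": 0.042,
    "t_wave_inversion": 0.224, "q_wave": 0.064, "qtc_prolongation": 0.184,
}

CLINICAL_NAMES: tuple[str, ...] = tuple(CONTINUOUS_BASE) + tuple(BINARY_BASE)
CANDIDATE_NAMES: tuple[str, ...] = CLINICAL_NAMES + FEATURE_NAMES  # D = 174

# Default discriminative variables: standardized mean differences for
# continuous variables (applied on the latent normal scale), log-odds shifts
# for binary ones. Directions follow the clinical picture (older, male,
# diabetic smokers with ischaemic ECG changes and raised troponin are at
# higher MACE risk).
DEFAULT_EFFECTS: dict[str, float] = {
    "troponin": 1.1,
    "age": 0.35,
    "dbp": 0.40,
    "pain_score": 0.35,
    "heart_rate": 0.35,
    "male": 0.60,
    "diabetes": 0.55,
    "smoker": 0.60,
    "st_elevation": 2.0,
    "st_depression": 2.1,
    "q_wave": 1.3,
    "qtc_prolongation": 0.70,
}


@dataclass(frozen=True)
class RRModel:
    """Tachogram generator parameters (milliseconds / Hz).

    RR(t) = mean_i − shift·1[MACE] + a_LF·sin(2π·0.1t) + a_HF·sin(2π·0.25t+φ)
    + white noise, with the MACE group given a lower mean RR (higher heart
    rate) and reduced HF amplitude and noise (lower vagal variability).

    Patients are heterogeneous: the resting mean RR varies between patients
    (``between_sd_ms``) and the oscillation amplitudes / noise level carry a
    log-normal between-patient dispersion (``amp_cv``), so no single feature
    separates the groups deterministically.
    """

    mean_rr_ms: float = 800.0
    mace_shift_ms: float = 20.0
    between_sd_ms: float = 100.0
    lf_amp_ms: float = 25.0
    hf_amp_ms: float = 18.0
    hf_amp_mace_ms: float = 15.5
    noise_sd_ms: float = 24.0
    noise_sd_mace_ms: float = 21.5
    amp_cv: float = 0.4
    lf_freq_hz: float = 0.10
    hf_freq_hz: float = 0.25
    duration_min_s: float = 300.0
    duration_max_s: float = 360.0
    floor_ms: float = 300.0


@dataclass(frozen=True)
class CohortSpec:
    n_patients: int = 800
    prevalence: float = 0.31
    effects: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_EFFECTS))
    rr: RRModel = field(default_factory=RRModel)
    score_noise: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.rr, dict):
            object.__setattr__(self, "rr", RRModel(**self.rr))
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError(f"prevalence must be in (0,1), got {self.prevalence}")
        unknown = set(self.effects) - set(CLINICAL_NAMES)
        if unknown:
            raise ValueError(f"effects refer to unknown variables: {sorted(unknown)}")

    @property
    def n_informative(self) -> int:
        return sum(1 for v in self.effects.values() if v != 0)

    @property
    def informative(self) -> tuple[str, ...]:
        return tuple(k for k, v in self.effects.items() if v != 0)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CohortSpec":
        d = dict(d)
        if "rr" in d and isinstance(d["rr"], dict):
            d["rr"] = RRModel(**d["rr"])
        return cls(**d)


def simulate_rr(group: str, spec: CohortSpec, patient_seed: int) -> RRSeries:
    """One 5-6 minute tachogram for a patient of the given outcome group."""
    if group not in ("mace", "non_mace"):
        raise ValueError(f"group must be 'mace' or 'non_mace', got {group!r}")
    rng = np.random.default_rng(int(patient_seed))
    p = spec.rr
    is_mace = group == "mace"
    base = (p.mean_rr_ms - (p.mace_shift_ms if is_mace else 0.0)
            + (rng.normal(0.0, p.between_sd_ms) if p.between_sd_ms > 0 else 0.0))
    base = max(base, 2.0 * p.floor_ms)
    # log-normal between-patient dispersion of oscillation amplitudes / noise
    sigma = np.sqrt(np.log1p(p.amp_cv**2))
    scale = np.exp(rng.normal(-sigma**2 / 2, sigma, size=3)) if sigma > 0 else np.ones(3)
    lf_amp = p.lf_amp_ms * scale[0]
    hf_amp = (p.hf_amp_mace_ms if is_mace else p.hf_amp_ms) * scale[1]
    noise_sd = (p.noise_sd_mace_ms if is_mace else p.noise_sd_ms) * scale[2]
    duration = rng.uniform(p.duration_min_s, p.duration_max_s)
    phi = rng.uniform(0, 2 * np.pi)
    t, beats = 0.0, []
    while t < duration:
        rr = (base
              + lf_amp * np.sin(2 * np.pi * p.lf_freq_hz * t)
              + hf_amp * np.sin(2 * np.pi * p.hf_freq_hz * t + phi)
              + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0))
        rr = max(rr, p.floor_ms)
        beats.append(rr)
        t += rr / 1000.0
    return RRSeries(patient_id=f"seed{patient_seed}", intervals=np.array(beats))


def _simulate_clinical(y: np.ndarray, spec: CohortSpec,
                       rng: np.random.Generator) -> pd.DataFrame:
    n = len(y)
    cols: dict[str, np.ndarray] = {}
    for name, (mu, sd) in CONTINUOUS_BASE.items():
        shift = spec.effects.get(name, 0.0) * sd
        x = rng.normal(mu + shift * y, sd)
        if name in _LOG_SCALE:
            x = np.exp(x)
        cols[name] = x
    # race drawn once as a mutually exclusive category, independent of outcome
    race_names = ["race_chinese", "race_indian", "race_malay"]
    race_p = np.array([BINARY_BASE[r] for r in race_names])
    cat = rng.choice(4, size=n, p=np.append(race_p, 1 - race_p.sum()))
    for i, r in enumerate(race_names):
        cols[r] = (cat == i).astype(float)
    for name, p0 in BINARY_BASE.items():
        if name in race_names:
            continue
        beta = spec.effects.get(name, 0.0)
        logit = np.log(p0 / (1 - p0)) + beta * y
        prob = 1.0 / (1.0 + np.exp(-logit))
        cols[name] = (rng.random(n) < prob).astype(float)
    return pd.DataFrame(cols)[list(CLINICAL_NAMES)]


def _simulate_scores(y: np.ndarray, spec: CohortSpec,
                     rng: np.random.Generator) -> pd.DataFrame:
    """Bounded integer risk scores from an outcome-linked latent mean + noise."""
    n = len(y)
    s = spec.score_noise
    heart = np.clip(np.round(rng.normal(4.5 + 2.5 * y, 1.6 * s)), 0, 10)
    timi = np.clip(np.round(rng.normal(2.0 + 1.2 * y, 1.3 * s)), 0, 7)
    grace = np.clip(np.round(rng.normal(100.0 + 20.0 * y, 30.0 * s)), 0, 300)
    return pd.DataFrame({"heart": heart, "timi": timi, "grace": grace})


def simulate_base(spec: CohortSpec) -> tuple[pd.DataFrame, list[RRSeries]]:
    """Outcome, clinical variables, scores, and raw tachograms (no features)."""
    root = spec.seed
    rng_y = np.random.default_rng(derive_seed(root, 0))
    y = (rng_y.random(spec.n_patients) < spec.prevalence).astype(int)
    clin = _simulate_clinical(y, spec, np.random.default_rng(derive_seed(root, 1)))
    scores = _simulate_scores(y, spec, np.random.default_rng(derive_seed(root, 2)))
    series = []
    for i in range(spec.n_patients):
        rr = simulate_rr("mace" if y[i] else "non_mace", spec,
                         derive_seed(root, 3, i))
        series.append(RRSeries(patient_id=f"p{i:04d}", intervals=rr.intervals))
    df = pd.concat([clin, scores], axis=1)
    df[OUTCOME] = y
    df.index = pd.Index([s.patient_id for s in series], name="patient_id")
    return df, series


def assemble_cohort(base: pd.DataFrame, feats: pd.DataFrame) -> pd.DataFrame:
    """Merge clinical table and feature table into the canonical column order."""
    feats = feats.reindex(base.index)
    df = pd.concat([base[list(CLINICAL_NAMES)], feats[list(FEATURE_NAMES)],
                    base[list(SCORE_NAMES)], base[[OUTCOME]]], axis=1)
    return df


def simulate_cohort(spec: CohortSpec,
                    return_rr: bool = False) -> pd.DataFrame | tuple:
    """Full cohort table: 174 candidates + HEART/TIMI/GRACE + outcome.

    Signal features are computed by the feature-extraction pipeline on
    per-patient simulated tachograms; they carry outcome information only
    through the group-dependent tachogram parameters.  With
    ``return_rr=True`` the per-patient RRSeries list is returned as well.
    """
    base, series = simulate_base(spec)
    df = assemble_cohort(base, feature_table(series))
    if return_rr:
        return df, series
    return df


# ---------------------------------------------------------------------------
# Printed reference counts and descriptive summary
# ---------------------------------------------------------------------------

def reference_cohort_counts() -> pd.DataFrame:
    """Published contingency counts of a 795-patient chest-pain cohort.

    Columns are group totals (total / MACE / non-MACE) for the overall
    cohort and a handful of n (%) rows; used to validate the descriptive-
    statistics arithmetic against printed values.
    """
    rows = {
        "patients": (795, 247, 548),
        "male": (542, 188, 354),
        "diabetes": (278, 106, 172),
        "smoker": (197, 73, 124),
        "st_elevation": (65, 48, 17),
        "st_depression": (92, 69, 23),
        "t_wave_inversion": (209, 86, 123),
        "q_wave": (86, 51, 35),
        "qtc_prolongation": (174, 73, 101),
    }
    return pd.DataFrame(rows, index=["total", "mace", "non_mace"]).T


def cohort_summary(counts: pd.DataFrame) -> pd.DataFrame:
    """Percentages of each count row within its group denominator.

    The prevalence row reports MACE/total; every other row reports the row
    count as a percentage of the group's patient total, rounded to one
    decimal as conventionally printed.
    """
    total, mace, non_mace = counts.loc["patients"]
    out = {"prevalence_pct": {
        "total": round(100.0 * mace / total, 1),
        "mace": 100.0, "non_mace": 0.0,
    }}
    for name, row in counts.iterrows():
        if name == "patients":
            continue
        out[f"{name}_pct"] = {
            "total": round(100.0 * row["total"] / total, 1),
            "mace": round(100.0 * row["mace"] / mace, 1),
            "non_mace": round(100.0 * row["non_mace"] / non_mace, 1),
        }
    return pd.DataFrame(out).T


# ---------------------------------------------------------------------------
# Artifact writing (cohort CSV + RR files + manifest)
# ---------------------------------------------------------------------------

def write_cohort_artifacts(spec: CohortSpec, outdir: str | Path) -> dict[str, Path]:
    """Write the clinical table, per-patient RR files, and the RR manifest.

    Signal features are intentionally not written here; the feature-extraction
    stage derives them from the RR files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    base, series = simulate_base(spec)
    clinical_path = outdir / "cohort_clinical.csv"
    base.to_csv(clinical_path)
    rr_dir = outdir / "rr"
    manifest_rows = []
    for s in series:
        p = rr_dir / f"{s.patient_id}.txt"
        write_rr_file(s, p)
        manifest_rows.append({"patient_id": s.patient_id,
                              "path": str(p.relative_to(outdir))})
    manifest_path = outdir / "rr_manifest.csv"
    pd.DataFrame(manifest_rows).to_csv(manifest_path, index=False)
    return {"clinical": clinical_path, "manifest": manifest_path}
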