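"""Synthetic two-arm trial generator.

Emulates the statistical structure the enrichment analysis assumes: a
randomized two-arm cohort (control arm ``DOX``, experimental arm
``DOX_EVO``) with clinical covariates, a block-correlated standardized
radiomic feature matrix, and right-censored overall-survival times whose
hazard is log-linear in planted features with *arm-specific* coefficients
(the generator's way of planting treatment-differential prognostic
structure).  Optionally emits voxel-level lesion images so the texture
pipeline can be exercised end to end.

Survival sampling uses a Weibull baseline hazard via inverse-CDF:
``T = scale * (-log U * exp(-eta))**(1/shape)``; censoring is
administrative at a follow-up horizon with uniform accrual entry, i.e.
censor time ~ Uniform(horizon - accrual, horizon).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import integrate
from scipy import ndimage

from .volumes import LabeledVolume

ARMS = ("DOX", "DOX_EVO")

#: multinomial histology mix (reference level first); the common
#: leiomyosarcoma subtype dominates at ~40% as in metastatic STS cohorts
HISTOLOGY_LEVELS = ("Leiomyosarcoma", "Pleomorphic", "Liposarcoma", "Other")
HISTOLOGY_PROBS = (0.40, 0.15, 0.10, 0.35)
GRADE_LEVELS = ("Intermediate", "High")
GRADE_PROBS = (0.30, 0.70)


@dataclass
class PlantedEffect:
    """Arm-specific log hazard ratio attached to one variable.

    ``variable`` is a radiomic feature index (int) or a clinical column
    name (str).  Betas are log-HR per SD for (standardized) features and
    per unit for clinical indicators.
    """

    variable: int | str
    beta_dox: float = 0.0
    beta_doxevo: float = 0.0


@dataclass
class SimConfig:
    """Study conditions for one simulated trial."""

    n_patients: int = 296
    arm_ratio: tuple[int, int] = (1, 1)  # DOX_EVO : DOX
    n_features: int = 164
    #: list of (block size, within-block correlation); remaining features iid
    block_structure: list[tuple[int, float]] = field(
        default_factory=lambda: [(6, 0.7)] * 10
    )
    planted: list[PlantedEffect] = field(default_factory=list)
    weibull_shape: float = 1.2
    weibull_scale_months: float = 24.5  # median OS ~ 18 months
    horizon_months: float = 36.0
    accrual_months: float = 18.0
    smoking_ever_prob: float = 0.45
    prior_rt_prob: float = 0.45
    train_fraction: float = 0.7
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 2:
            raise ValueError("need at least 2 patients")
        if min(self.arm_ratio) <= 0:
            raise ValueError("arm ratio parts must be positive")
        if self.weibull_shape <= 0 or self.weibull_scale_months <= 0:
            raise ValueError("Weibull parameters must be positive")
        if not 0 < self.accrual_months <= self.horizon_months:
            raise ValueError("accrual must be positive and <= horizon")
        for size, r in self.block_structure:
            if not -1.0 <= r <= 1.0:
                raise ValueError(f"block correlation {r} outside [-1, 1]")
            if size < 1:
                raise ValueError("block size must be >= 1")
        if sum(s for s, _ in self.block_structure) > self.n_features:
            raise ValueError("block sizes exceed n_features")
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")

    def nominal_censoring(self) -> float:
        """Expected censored fraction under no planted effects,
        P(T > C) with C ~ U(horizon - accrual, horizon)."""
        k, lam = self.weibull_shape, self.weibull_scale_months
        lo, hi = self.horizon_months - self.accrual_months, self.horizon_months
        surv = lambda t: np.exp(-((t / lam) ** k))
        val, _ = integrate.quad(surv, lo, hi)
        return val / (hi - lo)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["planted"] = [asdict(p) for p in self.planted]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        # only coerce keys that are present; omitted keys keep class defaults
        d = dict(d)
        if "planted" in d:
            d["planted"] = [PlantedEffect(**p) for p in d["planted"]]
        if "arm_ratio" in d:
            d["arm_ratio"] = tuple(d["arm_ratio"])
        if "block_structure" in d:
            d["block_structure"] = [tuple(b) for b in d["block_structure"]]
        return cls(**d)


@dataclass
class TrialDataset:
    """Simulated (or ingested) trial: clinical table with outcome, a
    feature matrix aligned on patient_id, and a frozen train/test split."""

    clinical: pd.DataFrame  # index patient_id; arm, covariates, time, event, split
    features: pd.DataFrame  # index patient_id x feature columns

    def subset(self, split: str | None = None, arm: str | None = None) -> "TrialDataset":
        m = pd.Series(True, index=self.clinical.index)
        if split is not None:
            m &= self.clinical["split"] == split
        if arm is not None:
            m &= self.clinical["arm"] == arm
        idx = self.clinical.index[m]
        return TrialDataset(self.clinical.loc[idx], self.features.loc[idx])

    @property
    def train(self) -> "TrialDataset":
        return self.subset(split="train")

    @property
    def test(self) -> "TrialDataset":
        return self.subset(split="test")

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.clinical.to_csv(out / "clinical.csv")
        self.features.to_csv(out / "features.csv")

    @classmethod
    def read(cls, out_dir: str | Path) -> "TrialDataset":
        out = Path(out_dir)
        clinical = pd.read_csv(out / "clinical.csv", index_col="patient_id")
        features = pd.read_csv(out / "features.csv", index_col="patient_id")
        return cls(clinical, features.loc[clinical.index])


def _categorical(rng, n, levels, probs):
    """Multinomial draw guaranteeing every level appears for large n."""
    counts = rng.multinomial(n, probs)
    if n >= len(levels):
        while (counts == 0).any():
            counts[np.argmax(counts)] -= 1
            counts[np.argmin(counts)] += 1
    labels = np.repeat(levels, counts)
    return rng.permutation(labels)


def generate_clinical(config: SimConfig) -> pd.DataFrame:
    """Clinical covariate table: arm, age, histology, smoking, grade,
    prior radiotherapy.  Arm assignment is independent of covariates."""
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    a, b = config.arm_ratio
    n_evo = int(round(n * a / (a + b)))
    n_evo = min(max(n_evo, 1), n - 1)
    arm = np.array(["DOX_EVO"] * n_evo + ["DOX"] * (n - n_evo))
    arm = rng.permutation(arm)
    df = pd.DataFrame(
        {
            "patient_id": [f"P{i:04d}" for i in range(n)],
            "arm": arm,
            "age": np.clip(rng.normal(57, 15, n).round(0), 18, 90),
            "histology": _categorical(rng, n, HISTOLOGY_LEVELS, HISTOLOGY_PROBS),
            "smoking": np.where(
                rng.uniform(size=n) < config.smoking_ever_prob, "ever", "never"
            ),
            "grade": _categorical(rng, n, GRADE_LEVELS, GRADE_PROBS),
            "prior_radiotherapy": np.where(
                rng.uniform(size=n) < config.prior_rt_prob, "yes", "no"
            ),
        }
    ).set_index("patient_id")
    return df


def generate_features(config: SimConfig, clinical: pd.DataFrame) -> pd.DataFrame:
    """Standardized block-correlated Gaussian feature matrix.

    Each block shares a latent factor: x = sqrt(r) f + sqrt(1-r) eps, so
    the within-block correlation is r in expectation; features outside
    blocks are iid.  Columns are standardized to zero mean, unit (1/n) SD.
    """
    rng = np.random.default_rng(config.seed + 1)
    n = len(clinical)
    X = rng.normal(size=(n, config.n_features))
    col = 0
    for size, r in config.block_structure:
        if abs(r) > 0:
            f = rng.normal(size=(n, 1))
            sgn = np.sign(r)
            X[:, col : col + size] = (
                np.sqrt(abs(r)) * f * (sgn ** np.arange(size))
                + np.sqrt(1 - abs(r)) * X[:, col : col + size]
            )
        col += size
    X = (X - X.mean(axis=0)) / X.std(axis=0)
    cols = [f"feat_{i:03d}" for i in range(config.n_features)]
    return pd.DataFrame(X, index=clinical.index, columns=cols)


def _planted_eta(config, clinical, features):
    """Per-patient, per-arm linear predictors from the planted effects."""
    n = len(clinical)
    eta_dox = np.zeros(n)
    eta_evo = np.zeros(n)
    for eff in config.planted:
        if isinstance(eff.variable, int):
            if not 0 <= eff.variable < features.shape[1]:
                raise ValueError(f"planted feature index {eff.variable} out of range")
            x = features.iloc[:, eff.variable].to_numpy()
        else:
            if eff.variable not in clinical.columns:
                raise ValueError(f"planted covariate {eff.variable!r} not found")
            col = clinical[eff.variable]
            if col.dtype == object:
                x = (col != col.iloc[0]).astype(float).to_numpy()
                # indicator vs. first-row level; for binary covariates this
                # is the usual 0/1 coding up to sign
                ref = {"smoking": "never", "prior_radiotherapy": "no"}.get(
                    eff.variable
                )
                if ref is not None:
                    x = (col != ref).astype(float).to_numpy()
            else:
                x = col.to_numpy(dtype=float)
                x = (x - x.mean()) / x.std()
        eta_dox += eff.beta_dox * x
        eta_evo += eff.beta_doxevo * x
    return eta_dox, eta_evo


def generate_survival(
    clinical: pd.DataFrame, features: pd.DataFrame, config: SimConfig
) -> pd.DataFrame:
    """Right-censored survival outcome with arm-specific planted hazards.

    h(t|x) = h0(t) exp(sum_k beta_arm(k) x_k) with Weibull h0; event
    times by inverse-transform sampling, administrative censoring at the
    follow-up horizon minus a uniform accrual offset.
    """
    rng = np.random.default_rng(config.seed + 2)
    n = len(clinical)
    eta_dox, eta_evo = _planted_eta(config, clinical, features)
    eta = np.where(clinical["arm"].to_numpy() == "DOX", eta_dox, eta_evo)
    u = rng.uniform(size=n)
    T = config.weibull_scale_months * (
        -np.log(u) * np.exp(-eta)
    ) ** (1.0 / config.weibull_shape)
    C = config.horizon_months - rng.uniform(0, config.accrual_months, n)
    time = np.maximum(np.minimum(T, C), 1e-3)
    event = (T <= C).astype(int)
    return pd.DataFrame({"time": time, "event": event}, index=clinical.index)


def generate_lesion_image(
    texture_scale_mm: float,
    size: int | tuple[int, int, int] = 24,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    seed: int = 0,
    mean_hu: float = 40.0,
    sd_hu: float = 20.0,
    radius_frac: float = 0.38,
) -> LabeledVolume:
    """Ellipsoidal lesion filled with a smoothed Gaussian random field.

    ``texture_scale_mm`` is the Gaussian smoothing length of the field:
    small scales give rapidly varying, heterogeneous texture (short grey
    level runs, high Short Run Emphasis), large scales give smooth,
    homogeneous texture.  Background is milder noise so the peritumoral
    shell is well defined.
    """
    if texture_scale_mm <= 0:
        raise ValueError("texture scale must be positive")
    if isinstance(size, int):
        size = (size, size, size)
    if min(size) < 8:
        raise ValueError("lesion grid must be at least 8 voxels per axis")
    rng = np.random.default_rng(seed)
    noise = rng.normal(size=size)
    sigma = [texture_scale_mm / s for s in spacing]
    fieldv = ndimage.gaussian_filter(noise, sigma=sigma, mode="reflect")
    fieldv = (fieldv - fieldv.mean()) / max(fieldv.std(), 1e-12)
    intensities = mean_hu + sd_hu * fieldv

    if not 0 < radius_frac <= 0.5:
        raise ValueError("radius_frac must be in (0, 0.5]")
    centre = [(s - 1) / 2 for s in size]
    semi = [radius_frac * s * sp for s, sp in zip(size, spacing)]
    grid = np.indices(size).astype(float)
    q = sum(
        ((grid[k] - centre[k]) * spacing[k] / semi[k]) ** 2 for k in range(3)
    )
    mask = q <= 1.0
    return LabeledVolume(intensities, mask, spacing)


def split_cohort(clinical: pd.DataFrame, config: SimConfig) -> pd.Series:
    """Simple random 70:30 split (no stratification);
    n_train = round(train_fraction * n)."""
    rng = np.random.default_rng(config.seed + 3)
    n = len(clinical)
    n_train = int(round(config.train_fraction * n))
    perm = rng.permutation(n)
    split = np.array(["test"] * n, dtype=object)
    split[perm[:n_train]] = "train"
    return pd.Series(split, index=clinical.index, name="split")


def generate_trial(config: SimConfig, features: pd.DataFrame | None = None) -> TrialDataset:
    """Assemble a full synthetic trial: clinical + features + survival +
    split.  ``features`` may be supplied externally (e.g. extracted from
    synthetic lesion images); otherwise the numeric generator is used."""
    clinical = generate_clinical(config)
    if features is None:
        features = generate_features(config, clinical)
    else:
        features = features.loc[clinical.index]
    outcome = generate_survival(clinical, features, config)
    clinical = clinical.join(outcome)
    clinical["split"] = split_cohort(clinical, config)
    return TrialDataset(clinical, features)
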