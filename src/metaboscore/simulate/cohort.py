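"""Synthetic TMA cohorts with known ground truth.

Per-marker latent standard normals are drawn from a Gaussian copula (a
single Spearman target couples PCK2 and GLUT1 within the LUAD stratum)
with an additive monotone T-stage trend.  Tumor-level positivity is a
threshold on the latent scale calibrated so the marginal positivity
rate per marker and histology is hit exactly in expectation; positive
tumors receive cores with intensity in {1,2,3} and density in {1..100}
via a logistic link, negative tumors score 0.  Survival is exponential
with a phenotype-dependent hazard and uniform administrative censoring.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import NamedTuple, Optional

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import expit

from ..scoring import MARKERS, Phenotype, classify_phenotype

HISTOLOGIES = ("LUAD", "LUSC")

#: positivity rates calibrated to the reference TMA cohort
DEFAULT_POSITIVITY = {
    "PCK1": {"LUAD": 0.42, "LUSC": 0.51},
    "PCK2": {"LUAD": 0.69, "LUSC": 0.40},
    "LDHB": {"LUAD": 0.91, "LUSC": 0.91},
    "GLUT1": {"LUAD": 0.41, "LUSC": 0.94},
}
DEFAULT_STAGE_EFFECTS = {"PCK1": 0.0, "PCK2": -0.3, "LDHB": 0.0, "GLUT1": 0.5}
DEFAULT_HAZARD_RATIOS = {
    "glycolytic": 2.0, "mixed": 1.8, "gluconeogenic": 1.0, "unspecified": 1.3,
}
STAGE_PROBS = (0.35, 0.35, 0.20, 0.10)  # T1..T4
STAGE_LABELS = {1: "I", 2: "II", 3: "III", 4: "IV"}


class ParameterError(ValueError):
    pass


@dataclass
class CohortParams:
    n_patients: int = 300
    histology_mix: float = 0.7  # fraction LUAD
    positivity_rates: dict = field(default_factory=lambda: {m: dict(v) for m, v in DEFAULT_POSITIVITY.items()})
    rho_pck2_glut1: float = -0.2  # Spearman target, LUAD stratum
    stage_effects: dict = field(default_factory=lambda: dict(DEFAULT_STAGE_EFFECTS))
    hazard_ratios: dict = field(default_factory=lambda: dict(DEFAULT_HAZARD_RATIOS))
    baseline_hazard: float = 0.015  # events per month
    censor_rate: float = 0.3
    cores_per_tumor: int = 3
    missing_core_rate: float = 0.03
    metastasis_fraction: float = 0.0
    max_followup_months: float = 120.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ParameterError("n_patients must be >= 1")
        if not (0.0 <= self.histology_mix <= 1.0):
            raise ParameterError("histology_mix must be in [0,1]")
        if not (-1.0 <= self.rho_pck2_glut1 <= 1.0):
            raise ParameterError("rho_pck2_glut1 must be in [-1,1]")
        for m in MARKERS:
            for h in HISTOLOGIES:
                p = self.positivity_rates[m][h]
                if not (0.0 <= p <= 1.0):
                    raise ParameterError(f"positivity rate {m}/{h} out of [0,1]: {p}")
        for ph, hr in self.hazard_ratios.items():
            if hr <= 0:
                raise ParameterError(f"hazard ratio for {ph} must be > 0")
        if not (0.0 <= self.censor_rate <= 1.0):
            raise ParameterError("censor_rate must be in [0,1]")
        if self.cores_per_tumor < 1:
            raise ParameterError("cores_per_tumor must be >= 1")
        if self.baseline_hazard <= 0:
            raise ParameterError("baseline_hazard must be > 0")
        # Gaussian-copula feasibility of the Spearman target, accounting
        # for the correlation already induced by the shared stage trend
        _noise_correlation(self)


@dataclass
class CohortTruth:
    params: dict
    latent_thresholds: dict
    realized_positivity: dict  # marker -> histology -> realized tumor-level rate
    realized_spearman_latent_luad: float
    realized_spearman_scores_luad: float
    phenotype_counts: dict
    hazard_ratios: dict


class CohortResult(NamedTuple):
    cores: pd.DataFrame
    patients: pd.DataFrame
    truth: CohortTruth


def spearman_to_pearson(rho_s: float) -> float:
    """Pearson correlation of a bivariate normal with the given Spearman rho."""
    return 2.0 * math.sin(math.pi * rho_s / 6.0)


def _stage_moments() -> tuple[float, float]:
    mean = sum(s * p for s, p in zip((1, 2, 3, 4), STAGE_PROBS))
    var = sum((s - mean) ** 2 * p for s, p in zip((1, 2, 3, 4), STAGE_PROBS))
    return mean, var


def _noise_correlation(params: "CohortParams") -> float:
    """Copula noise correlation between the PCK2 and GLUT1 latents.

    The shared T-stage trend already correlates the two latents by
    se2*seg*var(stage); the Gaussian noise picks up the remainder so the
    TOTAL latent Pearson correlation equals the bivariate-normal
    equivalent of the Spearman target.
    """
    _, stage_var = _stage_moments()
    se2 = params.stage_effects.get("PCK2", 0.0)
    seg = params.stage_effects.get("GLUT1", 0.0)
    sd2 = math.sqrt(1.0 + se2 * se2 * stage_var)
    sdg = math.sqrt(1.0 + seg * seg * stage_var)
    r_target = spearman_to_pearson(params.rho_pck2_glut1)
    r_noise = r_target * sd2 * sdg - se2 * seg * stage_var
    if not (-1.0 + 1e-9 < r_noise < 1.0 - 1e-9):
        raise ParameterError(
            f"Spearman target {params.rho_pck2_glut1} not attainable with the "
            f"given stage effects (required noise correlation {r_noise:.3f})"
        )
    return r_noise


def _copula_cholesky(params: "CohortParams") -> np.ndarray:
    corr = np.eye(len(MARKERS))
    i2, ig = MARKERS.index("PCK2"), MARKERS.index("GLUT1")
    corr[i2, ig] = corr[ig, i2] = _noise_correlation(params)
    try:
        return np.linalg.cholesky(corr)
    except np.linalg.LinAlgError as e:
        raise ParameterError(f"copula correlation not positive definite: {e}") from e


def generate_cohort(params: CohortParams) -> CohortResult:
    """Draw a full synthetic cohort; see the module docstring for the model."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    n = params.n_patients

    histology = np.where(rng.random(n) < params.histology_mix, "LUAD", "LUSC")
    t_stage = rng.choice([1, 2, 3, 4], size=n, p=STAGE_PROBS)
    gender = rng.choice(["f", "m"], size=n)
    grade = rng.choice([1, 2, 3], size=n, p=[0.2, 0.5, 0.3])
    age = np.round(rng.normal(66, 9, size=n)).clip(35, 90)
    site = np.where(rng.random(n) < params.metastasis_fraction, "metastasis", "primary")

    stage_mean, stage_var = _stage_moments()

    chol = _copula_cholesky(params)
    z = rng.standard_normal((n, len(MARKERS)))
    z_luad = z @ chol.T  # correlated copula applies in the LUAD stratum only
    is_luad = histology == "LUAD"
    z = np.where(is_luad[:, None], z_luad, z)

    latent = np.empty((n, len(MARKERS)))
    positive = np.empty((n, len(MARKERS)), dtype=bool)
    thresholds: dict = {}
    for k, m in enumerate(MARKERS):
        se = params.stage_effects.get(m, 0.0)
        lat = se * (t_stage - stage_mean) + z[:, k]
        sd_total = math.sqrt(1.0 + se * se * stage_var)
        latent[:, k] = lat / sd_total  # standardized latent, N(0,1) marginally
        thresholds[m] = {}
        for h in HISTOLOGIES:
            p = params.positivity_rates[m][h]
            thr = math.inf if p == 0 else (-math.inf if p == 1 else sps.norm.ppf(1.0 - p))
            thresholds[m][h] = thr
            sel = histology == h
            positive[sel, k] = latent[sel, k] > thr

    # --- per-core readings -------------------------------------------------
    core_rows = []
    cpt = params.cores_per_tumor
    for k, m in enumerate(MARKERS):
        # relative quantile of the latent within the positive tail drives
        # the tumor's typical intensity/density
        u = sps.norm.cdf(latent[:, k])
        base_int = np.clip(1 + np.floor(3 * np.clip((u - 0.5) * 2, 0, 0.999)), 1, 3).astype(int)
        for c in range(cpt):
            jitter = rng.choice([-1, 0, 1], size=n, p=[0.15, 0.7, 0.15])
            intensity = np.where(positive[:, k], np.clip(base_int + jitter, 1, 3), 0)
            dens_noise = rng.normal(0.0, 0.6, size=n)
            density = np.round(100.0 * expit(1.8 * latent[:, k] + dens_noise))
            density = np.where(positive[:, k], np.clip(density, 1, 100), 0.0)
            missing = rng.random(n) < params.missing_core_rate
            core_rows.append(pd.DataFrame({
                "patient_id": np.arange(n),
                "marker": m,
                "core_index": c,
                "intensity": np.where(missing, np.nan, intensity.astype(float)),
                "density": np.where(missing, np.nan, density),
            }))
    cores = pd.concat(core_rows, ignore_index=True)
    clinical = pd.DataFrame({
        "patient_id": np.arange(n), "histology": histology, "site": site,
        "t_stage": t_stage, "grade": grade, "gender": gender, "age": age,
    })
    cores = clinical.merge(cores, on="patient_id")
    cores = cores.sort_values(["patient_id", "marker", "core_index"], ignore_index=True)

    # --- phenotype & survival ---------------------------------------------
    flags = {m: positive[:, MARKERS.index(m)] for m in MARKERS}
    phenotype = np.array([
        classify_phenotype(bool(g), bool(p1), bool(p2)).value
        for g, p1, p2 in zip(flags["GLUT1"], flags["PCK1"], flags["PCK2"])
    ])
    hr = np.array([params.hazard_ratios[ph] for ph in phenotype])
    t_event = rng.exponential(1.0 / (params.baseline_hazard * hr))
    censor_sel = rng.random(n) < params.censor_rate
    c_admin = np.where(censor_sel, rng.uniform(0.0, params.max_followup_months, size=n),
                       params.max_followup_months)
    time = np.minimum(t_event, c_admin)
    event = t_event <= c_admin
    time = np.maximum(time, 1e-6)

    patients = clinical.copy()
    patients["stage"] = [STAGE_LABELS[s] for s in t_stage]
    for m in MARKERS:
        patients[f"true_positive_{m}"] = flags[m]
    patients["true_phenotype"] = phenotype
    patients["time"] = time
    patients["event"] = event

    # --- truth -------------------------------------------------------------
    realized = {
        m: {h: float(positive[histology == h, MARKERS.index(m)].mean())
            if (histology == h).any() else math.nan
            for h in HISTOLOGIES}
        for m in MARKERS
    }
    i2, ig = MARKERS.index("PCK2"), MARKERS.index("GLUT1")
    if is_luad.sum() >= 3:
        rho_lat = float(sps.spearmanr(latent[is_luad, i2], latent[is_luad, ig]).statistic)
        score2 = latent[is_luad, i2] * positive[is_luad, i2]
        scoreg = latent[is_luad, ig] * positive[is_luad, ig]
        rho_score = float(sps.spearmanr(score2, scoreg).statistic)
    else:
        rho_lat = rho_score = math.nan
    pheno_counts = {ph.value: int((phenotype == ph.value).sum()) for ph in Phenotype}
    truth = CohortTruth(
        params=asdict(params),
        latent_thresholds=thresholds,
        realized_positivity=realized,
        realized_spearman_latent_luad=rho_lat,
        realized_spearman_scores_luad=rho_score,
        phenotype_counts=pheno_counts,
        hazard_ratios=dict(params.hazard_ratios),
    )
    return CohortResult(cores=cores, patients=patients, truth=truth)
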