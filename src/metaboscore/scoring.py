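"""IHC combined scoring, positivity calling and metabolic phenotyping.

A core is read as a staining intensity category (0 = negative, 1 = weak,
2 = moderate, 3 = strong) and a density, the percentage of positively
stained tumor cells (0-100).  The combined score is their product
(range 0-300); a tumor with several cores gets the arithmetic mean of
its evaluable core scores, and staining is called positive when the
mean combined score reaches the cutoff (default 1).

Tumors are classified into one of four metabolic phenotypes from the
GLUT1 / PCK1 / PCK2 positivity flags; LDHB is scored and summarized but
never classifies.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

MARKERS = ("PCK1", "PCK2", "LDHB", "GLUT1")
#: markers that enter the phenotype call, in flag order
CLASSIFYING_MARKERS = ("GLUT1", "PCK1", "PCK2")

DEFAULT_CUTOFF = 1.0


class Phenotype(str, enum.Enum):
    GLYCOLYTIC = "glycolytic"
    GLUCONEOGENIC = "gluconeogenic"
    MIXED = "mixed"
    UNSPECIFIED = "unspecified"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class NonEvaluableError(ValueError):
    """Raised when a quantity is requested from non-evaluable readings."""


@dataclass(frozen=True)
class CoreReading:
    """One TMA core's reading for a single marker."""

    marker: str
    intensity: int
    density: float

    def __post_init__(self) -> None:
        if self.intensity not in (0, 1, 2, 3):
            raise ValueError(f"intensity must be in {{0,1,2,3}}, got {self.intensity!r}")
        if not (0.0 <= float(self.density) <= 100.0):
            raise ValueError(f"density must be in [0, 100], got {self.density!r}")


def core_score(reading: CoreReading) -> float:
    """Combined score of a single core: intensity x density, in [0, 300]."""
    return float(reading.intensity) * float(reading.density)


def tumor_score(cores: Sequence[Optional[CoreReading]]) -> float:
    """Mean combined score over the evaluable cores of one tumor/marker.

    Missing cores (``None``) are dropped, never zero-imputed.  Returns
    ``nan`` when no core is evaluable ("non-evaluable" is distinct from
    a true score of 0).
    """
    scores = [core_score(c) for c in cores if c is not None]
    if not scores:
        return math.nan
    return float(np.mean(scores))


def is_positive(mean_score: float, cutoff: float = DEFAULT_CUTOFF) -> bool:
    """Positivity call: mean combined score >= cutoff."""
    if math.isnan(mean_score):
        raise NonEvaluableError("cannot call positivity on a non-evaluable score")
    if not (0.0 <= mean_score <= 300.0):
        raise ValueError(f"mean score must be in [0, 300], got {mean_score!r}")
    return mean_score >= cutoff


def classify_phenotype(glut1_pos: bool, pck1_pos: bool, pck2_pos: bool) -> Phenotype:
    """Map the three positivity flags onto the four-way metabolic phenotype.

    glycolytic     GLUT1+ and both PCK1/PCK2 negative
    gluconeogenic  GLUT1- and PCK1 or PCK2 positive
    mixed          GLUT1+ and PCK1 or PCK2 positive
    unspecified    all three negative
    """
    for name, flag in (("glut1_pos", glut1_pos), ("pck1_pos", pck1_pos), ("pck2_pos", pck2_pos)):
        if flag is None or not isinstance(flag, (bool, np.bool_)):
            raise NonEvaluableError(f"{name} must be an evaluable boolean, got {flag!r}")
    pck_any = bool(pck1_pos) or bool(pck2_pos)
    if glut1_pos:
        return Phenotype.MIXED if pck_any else Phenotype.GLYCOLYTIC
    return Phenotype.GLUCONEOGENIC if pck_any else Phenotype.UNSPECIFIED


def combined_pck_score(pck1_mean: float, pck2_mean: float) -> float:
    """Sum of the PCK1 and PCK2 mean scores, in [0, 600].

    Non-evaluable (nan) in either marker propagates to the sum.
    """
    if math.isnan(pck1_mean) or math.isnan(pck2_mean):
        return math.nan
    return float(pck1_mean) + float(pck2_mean)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


# ---------------------------------------------------------------------------
# table-level pipeline

CORE_COLUMNS = (
    "patient_id", "histology", "site", "t_stage", "grade", "gender",
    "age", "marker", "core_index", "intensity", "density",
)


def score_cohort(cores: pd.DataFrame, cutoff: float = DEFAULT_CUTOFF) -> pd.DataFrame:
    """Aggregate a long per-core table to one row per patient.

    ``cores`` needs at least patient_id / marker / intensity / density;
    clinical columns present in the input are carried through.  Cores
    with missing intensity or density are dropped.  Output columns per
    marker M: ``score_M`` (nan if non-evaluable), ``positive_M``
    (nullable boolean), plus ``score_pck_combined`` and ``phenotype``
    (missing when any classifying marker is non-evaluable).
    """
    df = cores.copy()
    for col in ("patient_id", "marker", "intensity", "density"):
        if col not in df.columns:
            raise ValueError(f"cores table is missing required column {col!r}")
    bad_int = df["intensity"].dropna()
    if not bad_int.isin([0, 1, 2, 3]).all():
        raise ValueError("intensity values outside {0,1,2,3}")
    bad_den = df["density"].dropna()
    if ((bad_den < 0) | (bad_den > 100)).any():
        raise ValueError("density values outside [0, 100]")

    evaluable = df.dropna(subset=["intensity", "density"]).copy()
    evaluable["core_score"] = evaluable["intensity"].astype(float) * evaluable["density"].astype(float)
    means = (
        evaluable.groupby(["patient_id", "marker"])["core_score"]
        .mean()
        .unstack("marker")
    )

    clinical_cols = [c for c in ("histology", "site", "t_stage", "grade", "gender", "age") if c in df.columns]
    clinical = df.drop_duplicates("patient_id").set_index("patient_id")[clinical_cols]
    out = clinical.join(means, how="left")

    for m in MARKERS:
        score_col = out[m] if m in out.columns else pd.Series(math.nan, index=out.index)
        out[f"score_{m}"] = score_col
        out[f"positive_{m}"] = pd.array(
            [None if math.isnan(s) else bool(s >= cutoff) for s in score_col],
            dtype="boolean",
        )
        if m in out.columns:
            out = out.drop(columns=[m])

    out["score_pck_combined"] = [
        combined_pck_score(a, b) for a, b in zip(out["score_PCK1"], out["score_PCK2"])
    ]

    phenos = []
    for g, p1, p2 in zip(out["positive_GLUT1"], out["positive_PCK1"], out["positive_PCK2"]):
        if pd.isna(g) or pd.isna(p1) or pd.isna(p2):
            phenos.append(None)
        else:
            phenos.append(classify_phenotype(bool(g), bool(p1), bool(p2)).value)
    out["phenotype"] = phenos
    return out.reset_index().rename(columns={"index": "patient_id"})


def cohort_summary(
    samples: pd.DataFrame,
    strata: Iterable[str] = ("histology",),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Positivity table and phenotype frequency table per stratum.

    Returns ``(positivity, phenotypes)``.  Positivity rows carry the
    evaluable n, positive n, the raw fraction, and the percentage
    rounded half-up to the nearest integer; empty strata are emitted
    with n = 0 and missing percentages.  Phenotype fractions are taken
    over samples evaluable for all three classifying markers.
    """
    if len(samples) == 0:
        raise ValueError("cohort_summary needs at least one sample")
    strata = list(strata)
    grouped = samples.groupby(strata, dropna=False, observed=False) if strata else [((), samples)]

    pos_rows, pheno_rows = [], []
    for key, grp in grouped:
        if not isinstance(key, tuple):
            key = (key,)
        stratum = dict(zip(strata, key))
        for m in MARKERS:
            flags = grp[f"positive_{m}"]
            ev = flags.notna()
            n_eval = int(ev.sum())
            n_pos = int(flags[ev].sum()) if n_eval else 0
            row = dict(stratum, marker=m, n_evaluable=n_eval, n_positive=n_pos)
            if n_eval:
                frac = n_pos / n_eval
                row["fraction_positive"] = frac
                row["percent_positive"] = _round_half_up(100.0 * frac)
            else:
                row["fraction_positive"] = math.nan
                row["percent_positive"] = pd.NA
            pos_rows.append(row)

        classified = grp["phenotype"].dropna()
        n_cls = len(classified)
        for ph in Phenotype:
            k = int((classified == ph.value).sum())
            pheno_rows.append(
                dict(
                    stratum,
                    phenotype=ph.value,
                    n=k,
                    n_classified=n_cls,
                    fraction=(k / n_cls) if n_cls else math.nan,
                )
            )
    return pd.DataFrame(pos_rows), pd.DataFrame(pheno_rows)
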