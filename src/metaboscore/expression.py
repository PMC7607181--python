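"""Relative expression from qPCR crossing points and blot densitometry.

dCp = Cp(reference gene) - Cp(gene of interest), so a higher dCp means
higher expression.  ddCp = dCp(treated) - dCp(control) and the fold
change is 2**ddCp (amplification efficiency fixed at 2).  Densitometry
folds are band/loading normalized to a flagged reference sample.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd


def delta_cp(cp_gene: float, cp_reference: float) -> float:
    """dCp = Cp(reference) - Cp(gene)."""
    for name, v in (("cp_gene", cp_gene), ("cp_reference", cp_reference)):
        if v is None or not math.isfinite(v) or v <= 0:
            raise ValueError(f"{name} must be finite and > 0, got {v!r}")
    return float(cp_reference) - float(cp_gene)


def fold_change(dcp_treated, dcp_control) -> float:
    """2**ddCp where ddCp = dCp(treated) - mean dCp(control).

    Scalars or sequences are accepted; multiple replicates are combined
    by the arithmetic mean of dCp (i.e. geometric mean on the fold
    scale).
    """
    treated = np.atleast_1d(np.asarray(dcp_treated, dtype=float))
    control = np.atleast_1d(np.asarray(dcp_control, dtype=float))
    if control.size == 0:
        raise ValueError("empty control group")
    if treated.size == 0:
        raise ValueError("empty treated group")
    ddcp = float(treated.mean()) - float(control.mean())
    return float(2.0 ** ddcp)


def qpcr_fold_changes(table: pd.DataFrame, gene: str, reference_gene: str,
                      control_group: str, group_col: str = "group") -> pd.DataFrame:
    """Per-sample and per-group fold changes from a long Cp table.

    ``table`` columns: sample_id, ``group_col``, gene, cp.  Each sample
    must carry a Cp for both ``gene`` and ``reference_gene``.  Folds are
    2**ddCp against the control-group mean dCp; the group summary uses
    the geometric mean (arithmetic mean of ddCp).
    """
    wide = table.pivot_table(index=["sample_id", group_col], columns="gene",
                             values="cp", aggfunc="mean").reset_index()
    for g in (gene, reference_gene):
        if g not in wide.columns or wide[g].isna().any():
            raise ValueError(f"every sample needs a Cp for {g!r}")
    wide["dcp"] = [delta_cp(a, b) for a, b in zip(wide[gene], wide[reference_gene])]
    ctrl = wide.loc[wide[group_col] == control_group, "dcp"]
    if len(ctrl) == 0:
        raise ValueError(f"no samples in control group {control_group!r}")
    ctrl_mean = float(ctrl.mean())
    wide["ddcp"] = wide["dcp"] - ctrl_mean
    wide["fold"] = 2.0 ** wide["ddcp"]
    wide["gene"] = gene
    return wide[["sample_id", group_col, "gene", "dcp", "ddcp", "fold"]]


def summarize_folds(per_sample: pd.DataFrame, group_col: str = "group") -> pd.DataFrame:
    """Geometric-mean fold per group (mean of ddCp, exponentiated)."""
    out = (
        per_sample.groupby(group_col)
        .agg(n=("fold", "size"), mean_ddcp=("ddcp", "mean"))
        .reset_index()
    )
    out["fold_geomean"] = 2.0 ** out["mean_ddcp"]
    return out


def normalize_density(records: pd.DataFrame,
                      band_col: str = "band_density",
                      loading_col: str = "loading_density",
                      reference_col: str = "is_reference") -> pd.DataFrame:
    """Normalize blot band densities to the loading control and the
    flagged reference sample; the reference sample maps to exactly 1.
    """
    df = records.copy()
    if (df[band_col] <= 0).any() or (df[loading_col] <= 0).any():
        raise ValueError("densities must be > 0")
    ref = df[df[reference_col].astype(bool)]
    if len(ref) != 1:
        raise ValueError(f"exactly one reference sample required, found {len(ref)}")
    ref_ratio = float(ref[band_col].iloc[0]) / float(ref[loading_col].iloc[0])
    df["normalized_fold"] = (df[band_col] / df[loading_col]) / ref_ratio
    return df
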