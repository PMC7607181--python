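"""Synthetic qPCR plates with known fold changes.

The reference gene (18S-like) has a constant low Cp per sample plus
measurement noise; each gene of interest is offset so that the expected
2**ddCp against the control group equals the requested true fold.
"""

from __future__ import annotations

import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

REFERENCE_CP = 10.0
BASE_GENE_CP = 25.0  # control-group Cp of a gene of interest


def generate_qpcr(
    genes: Sequence[str],
    groups: Sequence[str],
    true_fold_changes: Mapping[str, Mapping[str, float]],
    cp_noise_sd: float = 0.0,
    n_replicates: int = 3,
    reference_gene: str = "18S",
    control_group: str | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Long Cp table: sample_id, group, gene, cp (reference gene included).

    ``true_fold_changes[gene][group]`` is the fold vs the control group
    (the first group by default), which is forced to fold 1.
    """
    if cp_noise_sd < 0:
        raise ValueError("cp_noise_sd must be >= 0")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    groups = list(groups)
    control_group = control_group or groups[0]
    if control_group not in groups:
        raise ValueError(f"control group {control_group!r} not among groups")
    for g in genes:
        for grp in groups:
            f = true_fold_changes.get(g, {}).get(grp, 1.0)
            if f <= 0:
                raise ValueError(f"fold change for {g}/{grp} must be > 0, got {f}")

    rng = np.random.default_rng(seed)
    rows = []
    for grp in groups:
        for rep in range(n_replicates):
            sid = f"{grp}_{rep + 1}"
            cp_ref = REFERENCE_CP + rng.normal(0.0, cp_noise_sd)
            rows.append(dict(sample_id=sid, group=grp, gene=reference_gene, cp=cp_ref))
            for g in genes:
                fold = true_fold_changes.get(g, {}).get(grp, 1.0)
                if grp == control_group:
                    fold = 1.0
                # dCp = cp_ref - cp_gene rises by log2(fold) vs control
                cp_gene = BASE_GENE_CP - math.log2(fold) + rng.normal(0.0, cp_noise_sd)
                rows.append(dict(sample_id=sid, group=grp, gene=g, cp=cp_gene))
    return pd.DataFrame(rows)
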