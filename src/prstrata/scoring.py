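"""Additive polygenic risk scoring.

``PRS_i = sum_j weight_j * dosage_ij`` over the variants shared by the
dosage matrix and the weight table (the sum convention, not the per-allele
average some scoring tools default to; the two differ by a positive scale
factor, to which every downstream partial R-squared is invariant).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DegenerateDataError, ValidationError

logger = logging.getLogger(__name__)


def score_individuals(dosages: pd.DataFrame, weights: pd.DataFrame) -> pd.Series:
    """Per-individual weighted dosage sum.

    ``dosages`` is individuals x variants (variant IDs as columns);
    ``weights`` has columns ``variant_id`` and ``weight`` (the standard
    3-column scoring layout also carries ``effect_allele``, which is assumed
    already aligned to the dosage coding — see ``sumstats.align_alleles``).
    Missing dosage entries are mean-imputed per variant; the imputation
    count is logged.
    """
    if weights["variant_id"].duplicated().any():
        dup = weights.loc[weights["variant_id"].duplicated(), "variant_id"].tolist()
        raise ValidationError(f"duplicate variant_ids in weight table: {dup[:5]}")
    if not np.isfinite(weights["weight"].to_numpy(dtype=float)).all():
        raise ValidationError("weights must be finite")

    shared = dosages.columns.intersection(weights["variant_id"])
    if len(shared) == 0:
        raise ValidationError(
            "no overlapping variants between dosage matrix "
            f"({len(dosages.columns)} variants) and weight table "
            f"({len(weights)} variants); check variant ID conventions"
        )
    X = dosages[shared].to_numpy(dtype=float)
    finite = np.isfinite(X)
    if ((X < 0) & finite).any() or ((X > 2) & finite).any():
        raise ValidationError("dosage values must lie in [0, 2]")
    n_missing = int((~finite).sum())
    if n_missing:
        col_means = np.nanmean(np.where(finite, X, np.nan), axis=0)
        col_means = np.where(np.isfinite(col_means), col_means, 0.0)
        X = np.where(finite, X, col_means[None, :])
        logger.info("mean-imputed %d missing dosage entries", n_missing)

    w = (
        weights.set_index("variant_id")["weight"]
        .reindex(shared)
        .to_numpy(dtype=float)
    )
    return pd.Series(X @ w, index=dosages.index, name="PRS")


def standardize_scores(prs: pd.Series | np.ndarray) -> pd.Series | np.ndarray:
    """Zero-mean, unit-SD transform (population SD); rank-preserving."""
    values = np.asarray(prs, dtype=float)
    if values.size < 2:
        raise ValidationError("need at least 2 individuals to standardize")
    sd = values.std()
    if sd == 0:
        raise DegenerateDataError("PRS has zero variance; cannot standardize")
    z = (values - values.mean()) / sd
    if isinstance(prs, pd.Series):
        return pd.Series(z, index=prs.index, name=prs.name)
    return z


def write_scores(prs: pd.Series, path: str | Path) -> None:
    """Two-column text: individual ID, PRS."""
    prs.rename("PRS").to_csv(path, sep="\t", index_label="individual_id")
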