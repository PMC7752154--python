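"""Attach per-patient signature scores to a clinical table and stratify.

The clinical table is a pandas DataFrame keyed by ``patient_id`` with the
response label (1 = clinical improvement), covariates (TMB, CTL,
*PD-1*/*PD-L1*/*CTLA-4* expression), survival time and event flag. Scores come
from projecting the cohort's bulk expression through the trained signature
model; stratification defaults to a median split (ties go low), the
conventional cut when no model-derived activation threshold is specified.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, DegenerateStratificationError, DimensionError

logger = logging.getLogger(__name__)

SCORE_COLUMN = "signature_score"
GROUP_COLUMN = "group"


def attach_scores(
    cohort: pd.DataFrame,
    scores: pd.DataFrame,
    signature_id: str,
    min_overlap: float = 0.8,
) -> pd.DataFrame:
    """Merge one signature's per-patient scores into the clinical table.

    Joins on ``patient_id`` (order-invariant); patients missing from either
    side are dropped and logged. Fails hard if fewer than ``min_overlap`` of
    cohort patients have a score, or if ``signature_id`` is unknown.
    """
    if signature_id not in scores.columns:
        raise ConfigurationError(
            f"signature {signature_id!r} not found; available: "
            f"{', '.join(map(str, scores.columns))}")
    if "patient_id" not in cohort.columns:
        raise ConfigurationError("cohort table must have a 'patient_id' column")
    if cohort["patient_id"].duplicated().any():
        raise ConfigurationError("cohort patient_id values must be unique")

    shared = cohort["patient_id"].isin(scores.index)
    frac = shared.mean() if len(cohort) else 0.0
    if frac < min_overlap:
        raise DimensionError(
            f"only {int(shared.sum())}/{len(cohort)} cohort patients have scores "
            f"({frac:.0%} < required {min_overlap:.0%})")
    dropped = int((~shared).sum())
    if dropped:
        logger.info("attach_scores: dropped %d patients without scores", dropped)

    merged = cohort.loc[shared].copy()
    merged[SCORE_COLUMN] = scores.loc[merged["patient_id"], signature_id].values
    return merged.sort_values("patient_id").reset_index(drop=True)


@dataclass
class StratifiedCohort:
    """Clinical table augmented with a high/low signature group."""

    table: pd.DataFrame   # includes SCORE_COLUMN and GROUP_COLUMN
    threshold: float
    method: str

    @property
    def n_high(self) -> int:
        return int((self.table[GROUP_COLUMN] == "high").sum())

    @property
    def n_low(self) -> int:
        return int((self.table[GROUP_COLUMN] == "low").sum())


def dichotomize(
    cohort: pd.DataFrame,
    method: str = "median",
    threshold: float | None = None,
) -> StratifiedCohort:
    """Split patients into high/low signature groups.

    ``method='median'`` cuts at the cohort median with ties going low;
    ``method='threshold'`` uses the supplied cut. A split that leaves either
    group empty (e.g. a constant score vector) raises
    :class:`DegenerateStratificationError` — group-based tests are undefined
    there and silent fallback would bias them.
    """
    if SCORE_COLUMN not in cohort.columns:
        raise ConfigurationError(f"cohort lacks the {SCORE_COLUMN!r} column; "
                                 "call attach_scores first")
    scores = cohort[SCORE_COLUMN].astype(float)
    if len(scores) < 4:
        raise ConfigurationError("need at least 4 scored patients to stratify")
    if method == "median":
        cut = float(np.median(scores))
    elif method == "threshold":
        if threshold is None:
            raise ConfigurationError("method='threshold' requires a threshold value")
        cut = float(threshold)
    else:
        raise ConfigurationError(f"unknown stratification method {method!r}")

    high = scores > cut  # ties go low
    if high.all() or not high.any():
        raise DegenerateStratificationError(
            f"stratification at {cut:.4g} leaves an empty group "
            f"({int(high.sum())} high / {int((~high).sum())} low)")
    out = cohort.copy()
    out[GROUP_COLUMN] = np.where(high, "high", "low")
    return StratifiedCohort(table=out, threshold=cut, method=method)
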