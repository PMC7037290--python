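"""Expression-matrix preprocessing: duplicate-symbol collapse and the
per-gene Z-score transform.

The Z transform standardizes each gene row across all samples of a study,
Z_ij = (g_ij - mean_i) / sd_i, making expression magnitudes comparable
across samples and diseases.  It is applied after duplicate collapse
(normalizing first would distort the largest-mean collapse criterion).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .types import ExpressionStudy

log = logging.getLogger(__name__)

COLLAPSE_RULES = ("max_mean", "max_variance")
SD_MODES = ("sample", "population")


@dataclass
class NormalizedStudy:
    """Z-scored study: per-gene standardized values plus the audit trail.

    ``degenerate`` flags constant rows (sd == 0), which are kept in place
    but excluded from downstream testing rather than silently zeroed.
    """

    study: ExpressionStudy  # values hold Z_ij
    row_means: np.ndarray
    row_sds: np.ndarray
    degenerate: np.ndarray  # boolean per gene

    @property
    def n_degenerate(self) -> int:
        return int(self.degenerate.sum())


def collapse_duplicate_symbols(
    study: ExpressionStudy, rule: str = "max_mean"
) -> ExpressionStudy:
    """Keep exactly one row per symbol: the duplicate with the largest mean
    (default) or largest variance.  Ties keep the first row in file order."""
    if rule not in COLLAPSE_RULES:
        raise ValueError(f"unknown collapse rule '{rule}'")
    criterion = (
        study.values.mean(axis=1) if rule == "max_mean"
        else study.values.var(axis=1, ddof=1)
    )
    best: dict[str, int] = {}
    for i, sym in enumerate(study.gene_ids):
        if sym not in best or criterion[i] > criterion[best[sym]]:
            best[sym] = i
    keep = sorted(best.values())
    n_collapsed = len(study.gene_ids) - len(keep)
    if n_collapsed:
        log.info("collapsed %d duplicate rows by %s in '%s'",
                 n_collapsed, rule, study.disease_id)
    return ExpressionStudy(
        disease_id=study.disease_id,
        gene_ids=[study.gene_ids[i] for i in keep],
        sample_ids=list(study.sample_ids),
        values=study.values[keep],
        group_labels=list(study.group_labels),
    )


def zscore_normalize(
    study: ExpressionStudy, sd_mode: str = "sample"
) -> NormalizedStudy:
    """Standardize every gene row across all samples of the study.

    Uses the sample (n-1) standard deviation by default; ``sd_mode=
    "population"`` switches to the n denominator.  Constant rows (sd == 0)
    are flagged degenerate and left unchanged; their count is logged.
    """
    if sd_mode not in SD_MODES:
        raise ValueError(f"unknown sd mode '{sd_mode}'")
    if study.n_samples < 2:
        raise ValueError("Z-scoring needs at least 2 samples")
    ddof = 1 if sd_mode == "sample" else 0
    means = study.values.mean(axis=1)
    sds = study.values.std(axis=1, ddof=ddof)
    degenerate = sds == 0.0
    if degenerate.any():
        log.info("%d constant rows flagged degenerate in '%s'",
                 int(degenerate.sum()), study.disease_id)
    safe_sds = np.where(degenerate, 1.0, sds)
    z = (study.values - means[:, None]) / safe_sds[:, None]
    z[degenerate] = study.values[degenerate]  # flagged, not zeroed
    normalized = ExpressionStudy(
        disease_id=study.disease_id,
        gene_ids=list(study.gene_ids),
        sample_ids=list(study.sample_ids),
        values=z,
        group_labels=list(study.group_labels),
    )
    return NormalizedStudy(
        study=normalized, row_means=means, row_sds=sds, degenerate=degenerate
    )
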