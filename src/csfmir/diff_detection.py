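"""Differential detection per miRNA per contrast via Fisher's exact test.

The 2x2 table counts detected (good flag) vs not-detected (censored)
cells in the test and reference groups, excluded cells dropped from both
margins.  The odds ratio is the conditional maximum-likelihood estimate
with an exact (test-inversion) 95% interval, so zero-cell tables produce
the 0-or-Inf estimate with one finite bound.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from csfmir.diff_expression import CONTRASTS
from csfmir.errors import InsufficientDataError, InvalidInputError
from csfmir.normalization import ExpressionMatrix
from csfmir.qpcr_io import PhenotypeTable

logger = logging.getLogger(__name__)


def detection_table(
    matrix: ExpressionMatrix,
    mirna: str,
    phenos: PhenotypeTable,
    contrast: tuple[str, str],
) -> np.ndarray:
    """2x2 counts [[det_test, notdet_test], [det_ref, notdet_ref]]."""
    test_g, ref_g = contrast
    rows = []
    for g in (test_g, ref_g):
        idx = [s for s in phenos.samples_in(g) if s in matrix.dcq.index]
        if not idx:
            raise InsufficientDataError(
                f"empty group {g!r} in contrast {test_g} vs {ref_g}"
            )
        usable = ~matrix.excluded.loc[idx, mirna]
        cens = matrix.censored.loc[idx, mirna]
        detected = int((usable & ~cens).sum())
        notdet = int((usable & cens).sum())
        rows.append([detected, notdet])
    return np.array(rows, dtype=int)


def fisher_exact(table: np.ndarray) -> tuple[float, float, float, float]:
    """Two-sided Fisher exact test with conditional-MLE odds ratio.

    Returns ``(or_est, or_lo, or_hi, p)``.  The two-sided p sums
    hypergeometric probabilities no larger than the observed table's;
    the interval inverts one-sided exact tests at 95%.  Zero cells give
    0 or Inf estimates with one finite bound; an all-zero table is an
    error.
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise InvalidInputError("need a nonnegative 2x2 table")
    if t.sum() == 0:
        raise InvalidInputError("all-zero 2x2 table: odds ratio undefined")
    _, p = stats.fisher_exact(t, alternative="two-sided")
    res = stats.contingency.odds_ratio(t, kind="conditional")
    ci = res.confidence_interval(confidence_level=0.95)
    return float(res.statistic), float(ci.low), float(ci.high), float(p)


def run_detection_contrasts(
    matrix: ExpressionMatrix,
    phenos: PhenotypeTable,
    alpha: float = 0.025,
    contrasts: tuple[tuple[str, str], ...] = CONTRASTS,
) -> pd.DataFrame:
    """Fisher exact detection tests for every (miRNA, contrast)."""
    rows = []
    for contrast in contrasts:
        test_g, ref_g = contrast
        for mirna in matrix.mirnas:
            t = detection_table(matrix, mirna, phenos, contrast)
            if t.sum() == 0:
                logger.warning(
                    "%s %s vs %s: no usable cells", mirna, test_g, ref_g
                )
                continue
            or_est, or_lo, or_hi, p = fisher_exact(t)
            rows.append(
                {
                    "mirna_id": mirna,
                    "test": test_g,
                    "ref": ref_g,
                    "det_test": t[0, 0],
                    "notdet_test": t[0, 1],
                    "det_ref": t[1, 0],
                    "notdet_ref": t[1, 1],
                    "or_est": or_est,
                    "or_lo": or_lo,
                    "or_hi": or_hi,
                    "p": p,
                }
            )
    df = pd.DataFrame(
        rows,
        columns=[
            "mirna_id", "test", "ref",
            "det_test", "notdet_test", "det_ref", "notdet_ref",
            "or_est", "or_lo", "or_hi", "p",
        ],
    )
    df["significant"] = df["p"] < alpha if not df.empty else pd.Series(dtype=bool)
    return df
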