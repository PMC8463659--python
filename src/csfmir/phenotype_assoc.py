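"""Per-group covariate regressions and between-run correlation summaries."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from csfmir.errors import InsufficientDataError
from csfmir.normalization import ExpressionMatrix
from csfmir.qpcr_io import PhenotypeTable

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AssocResult:
    mirna_id: str
    group: str
    covariate: str
    slope: float
    p_uncorrected: float
    r2: float
    n: int


def regress_mirna_on_covariate(
    dcq: np.ndarray, covariate: np.ndarray, *,
    mirna_id: str = "", group: str = "", covariate_name: str = "",
) -> AssocResult:
    """Simple OLS of uncensored ΔCq on one covariate.

    Reports the slope, its t-test p-value (uncorrected), and R².
    Requires at least 3 complete pairs and a non-constant covariate.
    """
    x = np.asarray(covariate, float)
    y = np.asarray(dcq, float)
    ok = ~np.isnan(x) & ~np.isnan(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise InsufficientDataError(f"need >=3 complete pairs, got {x.size}")
    if np.ptp(x) == 0:
        raise InsufficientDataError("constant covariate")
    res = stats.linregress(x, y)
    return AssocResult(
        mirna_id=mirna_id,
        group=group,
        covariate=covariate_name,
        slope=float(res.slope),
        p_uncorrected=float(res.pvalue),
        r2=float(res.rvalue**2),
        n=int(x.size),
    )


#: Covariates regressed against expression, per group.
DEFAULT_COVARIATES = (
    "age", "mmse", "bmi", "n_tbi", "years_since_tbi",
    "abeta42", "ttau", "ptau181", "abeta_ttau", "ptau_ttau",
)


def run_regressions(
    matrix: ExpressionMatrix,
    phenos: PhenotypeTable,
    mirnas: list[str] | None = None,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
) -> pd.DataFrame:
    """Per-group regressions of each miRNA on each available covariate.

    Censored and excluded cells are dropped (substituting at the
    detection bound would fabricate linear signal there).
    """
    mirnas = list(matrix.mirnas) if mirnas is None else mirnas
    rows = []
    for group in sorted(phenos.group.unique()):
        idx = [s for s in phenos.samples_in(group) if s in matrix.dcq.index]
        for cov in covariates:
            if cov not in phenos.data.columns:
                continue
            x_all = phenos.data.loc[idx, cov].astype(float)
            for mirna in mirnas:
                detected = matrix.detected_mask().loc[idx, mirna]
                y = matrix.dcq.loc[idx, mirna].where(detected)
                try:
                    res = regress_mirna_on_covariate(
                        y.to_numpy(float), x_all.to_numpy(float),
                        mirna_id=mirna, group=group, covariate_name=cov,
                    )
                except InsufficientDataError as exc:
                    logger.warning("%s/%s/%s: %s", mirna, group, cov, exc)
                    continue
                rows.append(res.__dict__)
    return pd.DataFrame(
        rows,
        columns=["mirna_id", "group", "covariate", "slope", "p_uncorrected", "r2", "n"],
    )


def paired_run_correlation(
    run_a: pd.DataFrame, run_b: pd.DataFrame, min_shared: int = 3
) -> dict[str, pd.Series | float]:
    """Correlate two ΔCq runs over their shared (sample, miRNA) cells.

    ``run_a``/``run_b`` are samples x miRNAs ΔCq frames (NaN = unusable).
    Returns Pearson correlations per sample (across shared miRNAs) and
    per miRNA (across shared samples), with their medians and ranges.
    Entities with fewer than ``min_shared`` shared cells are omitted.
    """
    samples = run_a.index.intersection(run_b.index)
    mirnas = run_a.columns.intersection(run_b.columns)
    a = run_a.loc[samples, mirnas]
    b = run_b.loc[samples, mirnas]

    def _corr_along(axis: int) -> pd.Series:
        out = {}
        labels = samples if axis == 0 else mirnas
        for lab in labels:
            va = a.loc[lab] if axis == 0 else a[lab]
            vb = b.loc[lab] if axis == 0 else b[lab]
            ok = va.notna() & vb.notna()
            if ok.sum() < min_shared or va[ok].std() == 0 or vb[ok].std() == 0:
                continue
            out[lab] = float(np.corrcoef(va[ok], vb[ok])[0, 1])
        return pd.Series(out, dtype=float)

    per_sample = _corr_along(0)
    per_mirna = _corr_along(1)
    return {
        "per_sample": per_sample,
        "per_mirna": per_mirna,
        "median_per_sample": float(per_sample.median()) if len(per_sample) else np.nan,
        "range_per_sample": (
            (float(per_sample.min()), float(per_sample.max()))
            if len(per_sample)
            else (np.nan, np.nan)
        ),
        "median_per_mirna": float(per_mirna.median()) if len(per_mirna) else np.nan,
    }
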