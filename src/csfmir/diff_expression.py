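"""Two-group differential expression of censored ΔCq.

ΔCq is treated as a time-like axis: a detected reaction is an "event" at
its ΔCq, an undetected one is right-censored at its sample's censoring
threshold (larger ΔCq = lower abundance).  Group comparison uses the
standard two-group log-rank statistic with hypergeometric variance and
pooled ties; fold changes follow the 2^-ΔΔCq relative-quantitation
convention with censored cells substituted at their threshold.
"""

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

#: (test, reference) group pairs analyzed throughout the pipeline.
CONTRASTS = (("DepTBI", "ComC"), ("DepC", "ComC"), ("DepTBI", "DepC"))


@dataclass(frozen=True)
class DEResult:
    mirna_id: str
    contrast: tuple[str, str]
    n_test: int
    n_ref: int
    chisq: float
    p: float
    fc: float
    fc_lo: float
    fc_hi: float
    fdr: float = np.nan
    significant: bool = False


def logrank_censored(
    dcq_test: np.ndarray,
    censored_test: np.ndarray,
    dcq_ref: np.ndarray,
    censored_ref: np.ndarray,
) -> tuple[float, float]:
    """Two-group log-rank test on right-censored ΔCq values.

    Censored observations enter the risk set at their threshold value;
    at a tied value, events are counted before censorings leave the risk
    set.  Returns (chi-square statistic, p from chi-square with 1 df).
    Raises if either group has no usable cell or there are no events.
    """
    t = np.concatenate([np.asarray(dcq_test, float), np.asarray(dcq_ref, float)])
    c = np.concatenate(
        [np.asarray(censored_test, bool), np.asarray(censored_ref, bool)]
    )
    grp = np.concatenate(
        [np.zeros(len(dcq_test), bool), np.ones(len(dcq_ref), bool)]
    )
    if len(dcq_test) == 0 or len(dcq_ref) == 0:
        raise InsufficientDataError("a contrast group has zero usable cells")
    events = ~c
    if not events.any():
        raise InsufficientDataError("all observations censored")

    obs_minus_exp = 0.0
    var = 0.0
    for v in np.unique(t[events]):
        at_risk = t >= v
        n = at_risk.sum()
        n1 = (at_risk & ~grp).sum()
        d = (events & (t == v)).sum()
        d1 = (events & (t == v) & ~grp).sum()
        e1 = d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
        obs_minus_exp += d1 - e1
    if var == 0.0:
        return 0.0, 1.0
    chisq = obs_minus_exp**2 / var
    return float(chisq), float(stats.chi2.sf(chisq, df=1))


def fold_change(
    dcq_test: np.ndarray,
    dcq_ref: np.ndarray,
) -> tuple[float, float, float]:
    """2^-ΔΔCq fold change with a combined-SD interval.

    Inputs are ΔCq values with censored cells already substituted at
    their thresholds.  ΔΔCq is the difference of group means; the
    interval is ``2^-(ΔΔCq ± s)`` with ``s = sqrt(sd_test^2 + sd_ref^2)``
    (combined SD), bounds ordered low-to-high.  With a single-observation
    group the interval is returned as NaN.
    """
    a = np.asarray(dcq_test, float)
    b = np.asarray(dcq_ref, float)
    if a.size == 0 or b.size == 0:
        raise InsufficientDataError("empty group in fold change")
    ddcq = a.mean() - b.mean()
    fc = 2.0 ** (-ddcq)
    if a.size < 2 or b.size < 2:
        return float(fc), np.nan, np.nan
    s = np.sqrt(a.std(ddof=1) ** 2 + b.std(ddof=1) ** 2)
    lo, hi = sorted((2.0 ** (-(ddcq + s)), 2.0 ** (-(ddcq - s))))
    return float(fc), float(lo), float(hi)


def bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (NaNs passed through)."""
    p = np.asarray(p, float)
    out = np.full_like(p, np.nan)
    mask = ~np.isnan(p)
    if mask.any():
        out[mask] = stats.false_discovery_control(p[mask], method="bh")
    return out


def _group_cells(matrix: ExpressionMatrix, mirna: str, samples: list[str]):
    idx = [s for s in samples if s in matrix.dcq.index]
    usable = ~matrix.excluded.loc[idx, mirna]
    vals = matrix.dcq.loc[idx, mirna][usable].to_numpy(float)
    cens = matrix.censored.loc[idx, mirna][usable].to_numpy(bool)
    return vals, cens


def run_contrasts(
    matrix: ExpressionMatrix,
    phenos: PhenotypeTable,
    alpha: float = 0.025,
    contrasts: tuple[tuple[str, str], ...] = CONTRASTS,
) -> pd.DataFrame:
    """Run all (miRNA, contrast) log-rank tests and fold changes.

    FDR is adjusted within each contrast across all tested miRNAs; the
    significance flag uses the raw p-value against ``alpha`` (FDR is
    reported alongside, not used for flagging).
    """
    rows = []
    for test_g, ref_g in contrasts:
        test_samples = phenos.samples_in(test_g)
        ref_samples = phenos.samples_in(ref_g)
        for mirna in matrix.mirnas:
            vt, ct = _group_cells(matrix, mirna, test_samples)
            vr, cr = _group_cells(matrix, mirna, ref_samples)
            try:
                chisq, p = logrank_censored(vt, ct, vr, cr)
            except InsufficientDataError as exc:
                logger.warning("%s %s vs %s: %s", mirna, test_g, ref_g, exc)
                continue
            fc, lo, hi = fold_change(vt, vr)
            rows.append(
                {
                    "mirna_id": mirna,
                    "test": test_g,
                    "ref": ref_g,
                    "n_test": len(vt),
                    "n_ref": len(vr),
                    "chisq": chisq,
                    "p": p,
                    "fc": fc,
                    "fc_lo": lo,
                    "fc_hi": hi,
                }
            )
    df = pd.DataFrame(
        rows,
        columns=[
            "mirna_id", "test", "ref", "n_test", "n_ref",
            "chisq", "p", "fc", "fc_lo", "fc_hi",
        ],
    )
    if not df.empty:
        df["fdr"] = np.nan
        for (t, r), idx in df.groupby(["test", "ref"]).groups.items():
            df.loc[idx, "fdr"] = bh_fdr(df.loc[idx, "p"].to_numpy())
        df["significant"] = df["p"] < alpha
    else:
        df["fdr"] = pd.Series(dtype=float)
        df["significant"] = pd.Series(dtype=bool)
    return df
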