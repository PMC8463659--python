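"""Endogenous-control selection and ΔCq normalization.

Candidate reference miRNAs are screened by per-sample quality criteria,
ranked by expression stability (mean pairwise SD of Cq differences, with
iterative removal of the least stable candidate), and the final control
set is chosen by the pairwise-variation stopping rule.  Expression is
then normalized per sample as Cq minus the geometric mean of the control
Cq values, carrying censoring through as a per-sample ΔCq threshold.

Stability is computed on Cq directly: Cq is already a log-scale quantity,
so the SD of a Cq difference equals the SD of the corresponding log-ratio
up to a constant factor and the ranking is unchanged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gmean

from csfmir.errors import InsufficientDataError, InvalidInputError
from csfmir.qpcr_io import (
    FLAG_CENSORED,
    FLAG_EXCLUDED,
    FLAG_GOOD,
    AmplificationRecord,
    ProbePanel,
    QCParams,
    records_to_frame,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ECCriteria:
    """Endogenous-control candidacy thresholds.

    A miRNA is a candidate only if, in every sample, it has an
    amplification score at or above ``amp_score_min``, a Cq strictly
    below ``cq_max`` and a Cq confidence strictly above ``cq_conf_min``.
    """

    detection_fraction: float = 1.0
    amp_score_min: float = 1.0
    cq_max: float = 30.0
    cq_conf_min: float = 0.8
    v_threshold: float = 0.1527


@dataclass
class StabilityRanking:
    """Outcome of the stability ranking of EC candidates.

    ``candidates`` are ordered most-stable first (ascending M);
    ``pairwise_variation`` maps k -> V_k for k = 2 .. n-1; ``selected_ecs``
    is the chosen control set.
    """

    candidates: list[str]
    m_values: dict[str, float]
    pairwise_variation: dict[int, float] = field(default_factory=dict)
    selected_ecs: list[str] = field(default_factory=list)


@dataclass
class ExpressionMatrix:
    """Samples x miRNAs ΔCq with per-cell censoring state.

    ``dcq`` holds the normalized value for good cells, the sample's
    censoring threshold for censored cells, and NaN for excluded cells.
    ``censor_threshold`` is ``cq_ceiling - (geometric-mean EC Cq)`` per
    sample.
    """

    dcq: pd.DataFrame
    censored: pd.DataFrame
    excluded: pd.DataFrame
    censor_threshold: pd.Series
    ecs: list[str] = field(default_factory=list)

    @property
    def samples(self) -> list[str]:
        return list(self.dcq.index)

    @property
    def mirnas(self) -> list[str]:
        return list(self.dcq.columns)

    def usable_mask(self) -> pd.DataFrame:
        """Cells that enter analysis (good or censored, not excluded)."""
        return ~self.excluded

    def detected_mask(self) -> pd.DataFrame:
        return ~self.excluded & ~self.censored


def select_ec_candidates(
    records: list[AmplificationRecord],
    panel: ProbePanel,
    crit: ECCriteria = ECCriteria(),
) -> list[str]:
    """Screen panel miRNAs for endogenous-control candidacy.

    Returns the miRNAs (never control probes) meeting every criterion in
    at least ``detection_fraction`` of the samples (default: all of them).
    Raises if fewer than 3 qualify, since stability ranking then cannot
    produce a defensible control set.
    """
    df = records_to_frame(records)
    n_samples = df["sample_id"].nunique()
    if n_samples == 0:
        raise InsufficientDataError("no amplification records")
    eligible = set(panel.candidate_ec_ids)
    ok = (
        (df["amp_score"] >= crit.amp_score_min)
        & df["cq"].notna()
        & (df["cq"] < crit.cq_max)
        & (df["cq_conf"] > crit.cq_conf_min)
    )
    per_mirna = ok.groupby(df["mirna_id"]).sum()
    # a miRNA absent from some sample's rows cannot satisfy 100% presence
    n_rows = df.groupby("mirna_id").size()
    frac = per_mirna / n_samples
    candidates = sorted(
        m
        for m in per_mirna.index
        if m in eligible
        and n_rows[m] == n_samples
        and frac[m] >= crit.detection_fraction
    )
    if len(candidates) < 3:
        raise InsufficientDataError(
            f"insufficient EC candidates: {len(candidates)} found, need >= 3"
        )
    return candidates


def _stability_values(cq: pd.DataFrame) -> pd.Series:
    """M(j) = mean over k != j of SD across samples of (Cq_j - Cq_k)."""
    arr = cq.to_numpy(dtype=float)
    n = arr.shape[1]
    diffs = arr[:, :, None] - arr[:, None, :]           # samples x j x k
    sds = diffs.std(axis=0, ddof=1)                     # j x k pairwise SDs
    m = sds.sum(axis=1) / (n - 1)                       # diagonal SD is 0
    return pd.Series(m, index=cq.columns)


def stability_rank(
    candidates: list[str],
    cq_table: pd.DataFrame,
    v_threshold: float = 0.1527,
) -> StabilityRanking:
    """Rank EC candidates by stability and select the final control set.

    Iteratively removes the least stable candidate (highest M, ties broken
    lexicographically) to build a most-stable-first ranking.  V_k is the
    SD across samples of the difference between the log-scale
    normalization factors of the top-k and top-(k+1) sets; the selected
    set is the smallest k >= 2 with V_k below ``v_threshold`` (all
    candidates if the threshold is never met).
    """
    cq = cq_table[candidates].astype(float)
    if cq.isna().any().any():
        raise InvalidInputError("missing Cq among EC candidates")
    if len(candidates) < 2:
        raise InsufficientDataError("stability ranking needs >= 2 candidates")

    remaining = list(candidates)
    removed: list[str] = []
    m_values: dict[str, float] = {}
    while len(remaining) > 2:
        m = _stability_values(cq[remaining])
        # worst = highest M; lexicographic tie-break for determinism
        worst = sorted(m.index, key=lambda g: (-m[g], g))[0]
        m_values[worst] = float(m[worst])
        remaining.remove(worst)
        removed.append(worst)
    m_final = _stability_values(cq[remaining])
    for g in sorted(remaining):
        m_values[g] = float(m_final[g])
    ranking = sorted(remaining) + removed[::-1]

    pairwise_variation: dict[int, float] = {}
    n = len(candidates)
    for k in range(2, n):
        nf_k = gmean(cq[ranking[:k]], axis=1)
        nf_k1 = gmean(cq[ranking[: k + 1]], axis=1)
        pairwise_variation[k] = float(np.std(nf_k - nf_k1, ddof=1))

    selected = list(ranking)
    for k in range(2, n):
        if pairwise_variation[k] < v_threshold:
            selected = ranking[:k]
            break
    return StabilityRanking(
        candidates=ranking,
        m_values=m_values,
        pairwise_variation=pairwise_variation,
        selected_ecs=selected,
    )


def normalize_dcq(
    records: list[AmplificationRecord],
    ecs: list[str],
    qc: QCParams = QCParams(),
) -> ExpressionMatrix:
    """Normalize Cq to ΔCq against the geometric mean of the EC Cq values.

    Per sample s with EC geometric mean g_s: good cells get
    ``dcq = cq - g_s``; censored cells get the sample's censoring
    threshold ``cq_ceiling - g_s``; excluded cells get NaN.  Samples
    missing a good EC measurement are dropped with a warning.
    """
    df = records_to_frame(records)
    cq = df.pivot(index="sample_id", columns="mirna_id", values="cq")
    flag = df.pivot(index="sample_id", columns="mirna_id", values="flag")

    missing_ec = [m for m in ecs if m not in cq.columns]
    if missing_ec:
        raise InvalidInputError(f"EC probes absent from data: {missing_ec}")
    ec_good = (flag[ecs] == FLAG_GOOD).all(axis=1) & cq[ecs].notna().all(axis=1)
    dropped = sorted(cq.index[~ec_good])
    if dropped:
        logger.warning(
            "dropping %d samples missing a good EC measurement: %s",
            len(dropped),
            dropped[:10],
        )
    cq = cq.loc[ec_good]
    flag = flag.loc[ec_good]

    g = pd.Series(gmean(cq[ecs], axis=1), index=cq.index)
    threshold = qc.cq_ceiling - g

    targets = [m for m in cq.columns if m not in ecs]
    censored = flag[targets] == FLAG_CENSORED
    excluded = flag[targets] == FLAG_EXCLUDED
    dcq = cq[targets].sub(g, axis=0)
    # censored cells carry the sample threshold; excluded cells carry nothing
    thr = np.broadcast_to(threshold.to_numpy()[:, None], dcq.shape)
    dcq = dcq.where(~censored, other=pd.DataFrame(thr, index=dcq.index, columns=dcq.columns))
    dcq = dcq.mask(excluded)
    return ExpressionMatrix(
        dcq=dcq,
        censored=censored,
        excluded=excluded,
        censor_threshold=threshold,
        ecs=list(ecs),
    )


def filter_mirnas(
    matrix: ExpressionMatrix,
    fail_frac_max: float = 0.20,
    detect_frac_min: float = 0.10,
) -> ExpressionMatrix:
    """Apply the miRNA-level inclusion filters.

    Drops miRNAs whose excluded-cell (technical failure) fraction is
    strictly above ``fail_frac_max``; of the remainder keeps miRNAs whose
    good-cell (detected) fraction is at least ``detect_frac_min``.
    Censored cells count toward neither fraction's numerator.
    """
    n = len(matrix.samples)
    fail_frac = matrix.excluded.sum(axis=0) / n
    detect_frac = matrix.detected_mask().sum(axis=0) / n
    keep = [
        m
        for m in matrix.mirnas
        if fail_frac[m] <= fail_frac_max and detect_frac[m] >= detect_frac_min
    ]
    return ExpressionMatrix(
        dcq=matrix.dcq[keep],
        censored=matrix.censored[keep],
        excluded=matrix.excluded[keep],
        censor_threshold=matrix.censor_threshold,
        ecs=matrix.ecs,
    )
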