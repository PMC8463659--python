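"""Multivariable dependency search on binned variables.

All continuous variables are discretized (near-equal-count tertiles via a
``mu ± f*s`` threshold grid search, or mean splits), then scanned for
pairwise dependence (mutual information with a primary grouping
variable) and three-way dependence (symmetric delta with a primary and a
secondary phenotype).  Every search scores the full miRNA background,
standardizes within-list to z-scores, and keeps up to 20 top miRNAs more
than one SD beyond the mean in the stronger-dependence direction.
Composite scores then aggregate a miRNA's evidence across searches for
one primary variable.

Entropies are plug-in (maximum likelihood) in bits.  Interaction
information is I(M,P) - I(M,P|S); the asymmetric delta for a target
variable subtracts the pairwise mutual information of the other two, and
the symmetric delta is the product of the three asymmetric deltas — zero
whenever any variable is independent of the others, and negative on
purely synergistic triples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from csfmir.errors import InsufficientDataError, InvalidInputError, SchemaError
from csfmir.normalization import ExpressionMatrix
from csfmir.qpcr_io import PhenotypeTable

logger = logging.getLogger(__name__)

PRIMARY_NAMES = ("deployment", "tbi", "exp_grp")
SECONDARY_NAMES = (
    "age", "bmi", "mmse", "abeta", "ttau", "ptau",
    "abeta-ttau", "abeta-ptau", "ptau-ttau",
    "apoe", "apoe4", "smoke", "race",
)
#: phenotype-table column backing each binned secondary variable
_SECONDARY_COLUMNS = {
    "age": "age", "bmi": "bmi", "mmse": "mmse",
    "abeta": "abeta42", "ttau": "ttau", "ptau": "ptau181",
    "abeta-ttau": "abeta_ttau", "abeta-ptau": "abeta_ptau",
    "ptau-ttau": "ptau_ttau",
    "apoe": "apoe", "apoe4": "apoe", "smoke": "smoke", "race": "race",
}
_RATIO_SECONDARIES = ("ptau-ttau", "abeta-ttau", "abeta-ptau")
_TERTILE_SECONDARIES = ("age", "bmi")
_MEANSPLIT_SECONDARIES = (
    "mmse", "abeta", "ttau", "ptau", "abeta-ttau", "abeta-ptau", "ptau-ttau"
)


@dataclass
class BinnedVariable:
    """A discretized variable: integer codes per sample, NaN = missing."""

    name: str
    values: pd.Series
    n_bins: int
    scheme: str
    factor_f: float | None = None
    bin_edges: tuple[float, ...] = ()

    def codes(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# binning


def bin_tertile(
    values, name: str = "", f_step: float = 0.01, f_max: float = 2.0
) -> BinnedVariable:
    """Discretize into three near-equal bins with ``mu ± f*s`` thresholds.

    ``f`` is grid-searched over (0, f_max] in steps of ``f_step``; the
    chosen ``f`` minimizes the maximum absolute deviation of the three
    bin counts from n/3 (ties -> smallest f).  Values at a threshold go
    to the lower bin; codes are 0/1/2 by ascending value.
    """
    s = pd.Series(values, dtype=float) if not isinstance(values, pd.Series) else values.astype(float)
    v = s.dropna().to_numpy()
    if v.size < 6:
        raise InsufficientDataError(f"tertile binning needs >=6 values, got {v.size}")
    mu, sd = v.mean(), v.std(ddof=1)
    if sd == 0:
        raise InvalidInputError(f"zero variance: cannot tertile-bin {name!r}")
    fs = np.arange(f_step, f_max + f_step / 2, f_step)
    lo = mu - fs[:, None] * sd
    hi = mu + fs[:, None] * sd
    c0 = (v[None, :] <= lo).sum(axis=1)
    c2 = (v[None, :] > hi).sum(axis=1)
    c1 = v.size - c0 - c2
    target = v.size / 3.0
    cost = np.max(
        np.abs(np.stack([c0, c1, c2], axis=1) - target), axis=1
    )
    best = int(np.argmin(cost))  # argmin takes the first (smallest f) tie
    f = float(fs[best])
    edge_lo, edge_hi = mu - f * sd, mu + f * sd
    codes = pd.Series(np.nan, index=s.index)
    codes[s <= edge_lo] = 0.0
    codes[(s > edge_lo) & (s <= edge_hi)] = 1.0
    codes[s > edge_hi] = 2.0
    return BinnedVariable(
        name=name, values=codes, n_bins=3, scheme="tertile-musigma",
        factor_f=f, bin_edges=(float(edge_lo), float(edge_hi)),
    )


def _mean_split(values: pd.Series, name: str) -> BinnedVariable:
    v = values.astype(float)
    mu = v.mean()
    codes = pd.Series(np.nan, index=v.index)
    codes[v < mu] = 0.0
    codes[v >= mu] = 1.0  # boundary goes to the upper bin
    return BinnedVariable(
        name=name, values=codes, n_bins=2, scheme="mean-split",
        bin_edges=(float(mu),),
    )


def _category_map(values: pd.Series, name: str, max_bins: int = 3) -> BinnedVariable:
    """Integer-code a categorical, merging rare levels into 'other' when >3."""
    v = values.astype("object").where(values.notna())
    freq = v.value_counts()
    levels = list(freq.index)
    if len(levels) > max_bins:
        keep = sorted(levels[: max_bins - 1], key=lambda c: (-freq[c], str(c)))
        v = v.where(v.isin(keep) | v.isna(), other="other")
        freq = v.value_counts()
        levels = list(freq.index)
    order = sorted(levels, key=lambda c: (-freq[c], str(c)))
    mapping = {c: float(i) for i, c in enumerate(order)}
    codes = v.map(mapping).astype(float)
    return BinnedVariable(
        name=name, values=codes, n_bins=len(order), scheme="categorical-map"
    )


def _apoe4_codes(apoe: pd.Series) -> pd.Series:
    def has_e4(g):
        if not isinstance(g, str):
            return np.nan
        return 1.0 if "e4" in g.lower() else 0.0

    return apoe.map(has_e4).astype(float)


def bin_secondary(phenos: PhenotypeTable) -> dict[str, BinnedVariable]:
    """Bin the 13 secondary phenotypes.

    Age and BMI get near-equal tertiles; the remaining continuous
    variables are mean-split into two bins; categorical variables are
    integer-coded with rare levels merged; ``apoe4`` is 1 iff the APOE
    genotype contains the e4 allele.  'unknown' smoking status is
    treated as missing.
    """
    df = phenos.data
    out: dict[str, BinnedVariable] = {}
    for name in SECONDARY_NAMES:
        col = _SECONDARY_COLUMNS[name]
        if col not in df.columns:
            logger.warning("phenotype column %r absent; skipping %r", col, name)
            continue
        series = df[col]
        if name in _TERTILE_SECONDARIES:
            out[name] = bin_tertile(series, name=name)
        elif name in _MEANSPLIT_SECONDARIES:
            out[name] = _mean_split(series, name)
        elif name == "apoe4":
            out[name] = BinnedVariable(
                name=name, values=_apoe4_codes(series), n_bins=2,
                scheme="categorical-map",
            )
        elif name == "smoke":
            cleaned = series.where(
                series.astype(str).str.lower() != "unknown"
            )
            bad = set(cleaned.dropna().astype(str).str.lower()) - {"no", "yes"}
            if bad:
                raise SchemaError(f"unknown smoking labels {sorted(bad)}")
            codes = cleaned.astype(str).str.lower().map({"no": 0.0, "yes": 1.0})
            out[name] = BinnedVariable(
                name=name, values=codes.astype(float), n_bins=2,
                scheme="categorical-map",
            )
        else:  # apoe, race
            out[name] = _category_map(series, name)
    return out


def build_primaries(phenos: PhenotypeTable) -> dict[str, BinnedVariable]:
    """Recode the participant group into the three primary variables.

    ``deployment``: ComC=0 vs deployed (DepC, DepTBI)=1; ``tbi``:
    no-TBI (ComC, DepC)=0 vs DepTBI=1; ``exp_grp``: the three groups
    coded 0/1/2.
    """
    g = phenos.group
    deployment = g.map({"ComC": 0.0, "DepC": 1.0, "DepTBI": 1.0})
    tbi = g.map({"ComC": 0.0, "DepC": 0.0, "DepTBI": 1.0})
    exp_grp = g.map({"ComC": 0.0, "DepC": 1.0, "DepTBI": 2.0})
    return {
        "deployment": BinnedVariable("deployment", deployment, 2, "categorical-map"),
        "tbi": BinnedVariable("tbi", tbi, 2, "categorical-map"),
        "exp_grp": BinnedVariable("exp_grp", exp_grp, 3, "categorical-map"),
    }


# ---------------------------------------------------------------------------
# information measures


def entropy(counts) -> float:
    """Plug-in Shannon entropy in bits of a joint count table."""
    c = np.asarray(counts, dtype=float).ravel()
    if c.size == 0 or c.sum() <= 0:
        raise InvalidInputError("entropy needs a nonempty count table")
    if (c < 0).any():
        raise InvalidInputError("negative counts")
    p = c[c > 0] / c.sum()
    return float(-(p * np.log2(p)).sum())


def _complete(*arrays: np.ndarray) -> list[np.ndarray]:
    cols = [np.asarray(a, dtype=float) for a in arrays]
    ok = ~np.any([np.isnan(c) for c in cols], axis=0)
    if not ok.any():
        raise InsufficientDataError("no complete cases")
    return [c[ok].astype(np.int64) for c in cols]


def _joint_entropy(*codes: np.ndarray) -> float:
    """Entropy of the joint distribution of integer code arrays."""
    idx = codes[0].copy()
    for c in codes[1:]:
        idx = idx * (c.max() + 1) + c
    return entropy(np.bincount(idx))


def mutual_information(x, y) -> float:
    """Plug-in mutual information I(X,Y) in bits, complete-case."""
    cx, cy = _complete(x, y)
    return _joint_entropy(cx) + _joint_entropy(cy) - _joint_entropy(cx, cy)


def symmetric_delta(m, p, s) -> tuple[float, float, float, float]:
    """Asymmetric deltas and their product for a variable triple.

    Returns ``(delta_m, delta_p, delta_s, delta_bar)`` where each
    asymmetric delta is the interaction information minus the pairwise
    mutual information of the two other variables, and ``delta_bar`` is
    the product of the three.
    """
    cm, cp, cs_ = _complete(m, p, s)
    h_m, h_p, h_s = _joint_entropy(cm), _joint_entropy(cp), _joint_entropy(cs_)
    h_mp = _joint_entropy(cm, cp)
    h_ms = _joint_entropy(cm, cs_)
    h_ps = _joint_entropy(cp, cs_)
    h_mps = _joint_entropy(cm, cp, cs_)
    i_mp = h_m + h_p - h_mp
    i_ms = h_m + h_s - h_ms
    i_ps = h_p + h_s - h_ps
    i_mp_given_s = h_ms + h_ps - h_s - h_mps
    i3 = i_mp - i_mp_given_s
    delta_m = i3 - i_ps
    delta_p = i3 - i_ms
    delta_s = i3 - i_mp
    return delta_m, delta_p, delta_s, delta_m * delta_p * delta_s


# ---------------------------------------------------------------------------
# search


def bin_mirna_matrix(
    matrix: ExpressionMatrix, censored_policy: str = "lowest_bin"
) -> tuple[pd.DataFrame, pd.Series]:
    """Tertile-bin every miRNA's ΔCq column.

    Binning thresholds are fitted on detected (uncensored) cells.  With
    the default policy, censored cells are coded into the highest-ΔCq
    (lowest expression) bin — detection failure is informative; with
    ``censored_policy='drop'`` they are left missing.  miRNAs with too
    few detected cells for a tertile fit fall back to a two-level
    detected(0)/censored(2) coding.

    Returns (samples x miRNAs code frame, per-miRNA chosen f factors).
    """
    if censored_policy not in ("lowest_bin", "drop"):
        raise InvalidInputError(f"unknown censored_policy {censored_policy!r}")
    codes = {}
    factors = {}
    detected = matrix.detected_mask()
    for mirna in matrix.mirnas:
        col = matrix.dcq[mirna].where(detected[mirna])
        try:
            bv = bin_tertile(col, name=mirna)
            c = bv.values.copy()
            factors[mirna] = bv.factor_f
        except (InsufficientDataError, InvalidInputError):
            c = pd.Series(np.nan, index=col.index)
            c[detected[mirna]] = 0.0
            factors[mirna] = np.nan
        if censored_policy == "lowest_bin":
            c[matrix.censored[mirna]] = 2.0
        codes[mirna] = c
    return pd.DataFrame(codes, columns=matrix.mirnas), pd.Series(factors)


def _list_records(
    list_id: str,
    measure: str,
    mirna_codes: pd.DataFrame,
    pheno_codes: list[pd.Series],
    max_top: int,
    z_min: float,
    min_samples: int,
) -> pd.DataFrame:
    pheno = pd.concat(pheno_codes, axis=1).reindex(mirna_codes.index)
    pheno_ok = pheno.notna().all(axis=1)
    rows = []
    if pheno_ok.sum() < min_samples:
        logger.warning(
            "list %s: only %d phenotype-complete samples (<%d); emitting empty",
            list_id, int(pheno_ok.sum()), min_samples,
        )
        return pd.DataFrame(
            columns=["list_id", "measure", "mirna_id", "raw", "score", "z",
                     "rank", "n_samples"]
        )
    for mirna in mirna_codes.columns:
        mask = pheno_ok & mirna_codes[mirna].notna()
        n = int(mask.sum())
        if n < 2:
            raw = np.nan
        else:
            m = mirna_codes.loc[mask, mirna].to_numpy()
            ph = [p[mask].to_numpy() for _, p in pheno.items()]
            if measure == "MI":
                raw = mutual_information(m, ph[0])
            else:
                raw = symmetric_delta(m, ph[0], ph[1])[3]
        rows.append({"mirna_id": mirna, "raw": raw, "n_samples": n})
    df = pd.DataFrame(rows)
    # deltas are z-scored on magnitude so "top" means stronger dependence
    df["score"] = df["raw"].abs() if measure == "delta" else df["raw"]
    mu, sd = df["score"].mean(), df["score"].std(ddof=1)
    df["z"] = (df["score"] - mu) / sd if sd > 0 else 0.0
    df["list_id"] = list_id
    df["measure"] = measure
    df["rank"] = np.nan
    top = df[df["z"] > z_min].sort_values(
        ["z", "mirna_id"], ascending=[False, True]
    ).head(max_top)
    df.loc[top.index, "rank"] = np.arange(1, len(top) + 1, dtype=float)
    return df[["list_id", "measure", "mirna_id", "raw", "score", "z",
               "rank", "n_samples"]]


def run_search(
    mirna_codes: pd.DataFrame,
    primaries: dict[str, BinnedVariable],
    secondaries: dict[str, BinnedVariable],
    max_top: int = 20,
    z_min: float = 1.0,
    min_samples: int = 10,
) -> pd.DataFrame:
    """Run the full dependency search.

    Produces one list per primary (pairwise mutual information), one per
    (primary, secondary) pair (three-way symmetric delta), and one
    three-way list of miRNA with the deployment and tbi primaries — 43
    lists for 3 primaries and 13 secondaries.  Each list scores the full
    miRNA background, standardizes within-list, and ranks up to
    ``max_top`` miRNAs with z above ``z_min``.
    """
    frames = []
    for pname, p in primaries.items():
        frames.append(
            _list_records(
                f"MI:{pname}", "MI", mirna_codes, [p.values.rename(pname)],
                max_top, z_min, min_samples,
            )
        )
    for pname, p in primaries.items():
        for sname, s in secondaries.items():
            frames.append(
                _list_records(
                    f"delta:{pname}:{sname}", "delta", mirna_codes,
                    [p.values.rename(pname), s.values.rename(sname)],
                    max_top, z_min, min_samples,
                )
            )
    if "deployment" in primaries and "tbi" in primaries:
        frames.append(
            _list_records(
                "delta:deployment:tbi", "delta", mirna_codes,
                [
                    primaries["deployment"].values.rename("deployment"),
                    primaries["tbi"].values.rename("tbi"),
                ],
                max_top, z_min, min_samples,
            )
        )
    nonempty = [f for f in frames if not f.empty]
    if not nonempty:
        return frames[0]
    return pd.concat(nonempty, ignore_index=True)


# ---------------------------------------------------------------------------
# composite scores and filtering

#: weights of the composite-score terms
CS_WEIGHT_MI = 1.0
CS_WEIGHT_RATIO_APOE = 0.5
CS_WEIGHT_DEMOGRAPHIC = 1.0 / 3.0


def composite_scores(records: pd.DataFrame, primary: str) -> pd.DataFrame:
    """Aggregate one primary variable's dependency evidence per miRNA.

    cs = z(MI) + 1/2 * (max of the three tau/abeta-ratio delta z-scores
    + apoe4 delta z-score) + 1/3 * (age + bmi + smoke delta z-scores).
    Absent or NaN list entries contribute 0.
    """
    def zcol(list_id: str) -> pd.Series:
        sub = records[records["list_id"] == list_id]
        return sub.set_index("mirna_id")["z"]

    mirnas = sorted(records["mirna_id"].unique())
    z_mi = zcol(f"MI:{primary}").reindex(mirnas).fillna(0.0)
    ratio_z = pd.concat(
        [zcol(f"delta:{primary}:{r}").reindex(mirnas) for r in _RATIO_SECONDARIES],
        axis=1,
    ).fillna(0.0)
    z_ratio_max = ratio_z.max(axis=1)
    z_apoe4 = zcol(f"delta:{primary}:apoe4").reindex(mirnas).fillna(0.0)
    z_age = zcol(f"delta:{primary}:age").reindex(mirnas).fillna(0.0)
    z_bmi = zcol(f"delta:{primary}:bmi").reindex(mirnas).fillna(0.0)
    z_smoke = zcol(f"delta:{primary}:smoke").reindex(mirnas).fillna(0.0)
    value = (
        CS_WEIGHT_MI * z_mi
        + CS_WEIGHT_RATIO_APOE * (z_ratio_max + z_apoe4)
        + CS_WEIGHT_DEMOGRAPHIC * (z_age + z_bmi + z_smoke)
    )
    return pd.DataFrame(
        {
            "mirna_id": mirnas,
            "primary": primary,
            "value": value.to_numpy(),
            "z_mi": z_mi.to_numpy(),
            "z_ratio_max": z_ratio_max.to_numpy(),
            "z_apoe4": z_apoe4.to_numpy(),
            "z_age": z_age.to_numpy(),
            "z_bmi": z_bmi.to_numpy(),
            "z_smoke": z_smoke.to_numpy(),
        }
    )


def stringent_filter(
    scores_by_primary: dict[str, pd.DataFrame],
    qc_passing: set[str] | None = None,
    n_sd: float = 2.0,
) -> list[str]:
    """Keep miRNAs with composite score beyond mean + ``n_sd``*SD.

    The cutoff is computed per primary over that primary's all-miRNA
    composite distribution; selections are unioned over primaries and
    intersected with the QC-passing miRNA set when given.
    """
    selected: set[str] = set()
    for primary, df in scores_by_primary.items():
        mu, sd = df["value"].mean(), df["value"].std(ddof=1)
        if sd == 0 or np.isnan(sd):
            continue
        cutoff = mu + n_sd * sd
        selected |= set(df.loc[df["value"] > cutoff, "mirna_id"])
    if qc_passing is not None:
        selected &= set(qc_passing)
    return sorted(selected)
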