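"""Seeded generator of qPCR amplification records and phenotype tables.

The generator emulates the statistical structure the analysis assumes:
three participant groups, ~377 panel miRNAs with per-miRNA baseline Cq
and dispersion, a shared per-sample (card) offset that endogenous-control
normalization must remove, mechanistic detection censoring at the Cq
ceiling (a latent Cq beyond the ceiling is emitted as an undetected
reaction, so level and detection effects are coupled), stable low-noise
control miRNAs, and optional planted group effects on level, detection
and three-way synergy.  Everything is reproducible from the seed, and a
ground-truth manifest records every planted effect.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from csfmir.errors import ConfigError
from csfmir.qpcr_io import (
    GROUPS,
    AmplificationRecord,
    PhenotypeTable,
    ProbePanel,
    QCParams,
    flag_amplification,
)


@dataclass(frozen=True)
class LevelEffect:
    """Planted ΔCq shift for one miRNA in one group (vs baseline)."""

    mirna: str
    group: str
    dcq_shift: float  # negative = higher expression


@dataclass(frozen=True)
class DetectionEffect:
    """Planted detection probabilities: baseline groups vs target group."""

    mirna: str
    group: str
    p_detect_group: float
    p_detect_other: float


@dataclass(frozen=True)
class SynergyEffect:
    """Planted parity-style 3-way dependence with (deployment, tbi)."""

    mirna: str
    strength: float  # Cq shift applied when deployment XOR tbi is 1


@dataclass
class SimConfig:
    group_sizes: tuple[int, int, int] = (52, 18, 45)
    n_mirnas: int = 377
    n_ecs: int = 3
    baseline_cq_range: tuple[float, float] = (24.0, 33.0)
    sd_range: tuple[float, float] = (0.4, 1.5)
    ec_baseline_max: float = 28.0
    ec_sd: float = 0.12
    cq_ceiling: float = 34.0
    sample_effect_sd: float = 0.3
    failure_rate: float = 0.01
    level_effects: Sequence[LevelEffect] = field(default_factory=tuple)
    detection_effects: Sequence[DetectionEffect] = field(default_factory=tuple)
    synergy_effects: Sequence[SynergyEffect] = field(default_factory=tuple)
    seed: int = 0

    def validate(self) -> None:
        if any(n < 2 for n in self.group_sizes):
            raise ConfigError("each group needs >= 2 samples")
        if self.n_mirnas < self.n_ecs + 1:
            raise ConfigError("n_mirnas must exceed n_ecs")
        touched: dict[str, str] = {}
        for eff in (*self.level_effects, *self.detection_effects, *self.synergy_effects):
            kind = type(eff).__name__
            if eff.mirna in touched and touched[eff.mirna] != kind:
                raise ConfigError(
                    f"contradictory plantings on {eff.mirna}: "
                    f"{touched[eff.mirna]} and {kind}"
                )
            touched[eff.mirna] = kind
        for eff in (*self.level_effects, *self.detection_effects):
            if eff.group not in GROUPS:
                raise ConfigError(f"unknown group {eff.group!r}")


def mirna_names(config: SimConfig) -> tuple[list[str], list[str]]:
    """Deterministic panel names; ECs first for readability."""
    ecs = [f"sim-ec-{i + 1:02d}" for i in range(config.n_ecs)]
    targets = [
        f"sim-mir-{i + 1:04d}" for i in range(config.n_mirnas - config.n_ecs)
    ]
    return ecs, targets


def make_panel(config: SimConfig) -> ProbePanel:
    ecs, targets = mirna_names(config)
    return ProbePanel(mirna_ids=tuple(ecs + targets))


def simulate(
    config: SimConfig,
) -> tuple[list[AmplificationRecord], PhenotypeTable, dict]:
    """Generate amplification records, phenotypes and a truth manifest."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    ecs, targets = mirna_names(config)
    all_mirnas = ecs + targets

    n_total = sum(config.group_sizes)
    groups = np.repeat(list(GROUPS), config.group_sizes)
    sample_ids = [f"S{i + 1:03d}" for i in range(n_total)]
    deployment = (groups != "ComC").astype(int)
    tbi = (groups == "DepTBI").astype(int)

    lo, hi = config.baseline_cq_range
    baseline = dict(zip(targets, rng.uniform(lo, hi, size=len(targets))))
    sd = dict(zip(targets, rng.uniform(*config.sd_range, size=len(targets))))
    for ec in ecs:
        baseline[ec] = rng.uniform(24.0, config.ec_baseline_max)
        sd[ec] = config.ec_sd

    # detection-effect miRNAs: per-group baselines hit target P(latent < ceiling)
    det_baseline: dict[str, dict[str, float]] = {}
    for eff in config.detection_effects:
        sigma_tot = np.hypot(sd[eff.mirna], config.sample_effect_sd)
        det_baseline[eff.mirna] = {
            g: config.cq_ceiling
            - sigma_tot * stats.norm.ppf(
                eff.p_detect_group if g == eff.group else eff.p_detect_other
            )
            for g in GROUPS
        }

    level_by_mirna: dict[str, dict[str, float]] = {}
    for eff in config.level_effects:
        level_by_mirna.setdefault(eff.mirna, {})[eff.group] = eff.dcq_shift
    synergy_by_mirna = {eff.mirna: eff.strength for eff in config.synergy_effects}

    sample_effect = rng.normal(0.0, config.sample_effect_sd, size=n_total)
    parity = deployment ^ tbi

    records: list[AmplificationRecord] = []
    qc = QCParams(cq_ceiling=config.cq_ceiling)
    for m in all_mirnas:
        shift = np.zeros(n_total)
        if m in level_by_mirna:
            for g, delta in level_by_mirna[m].items():
                shift[groups == g] += delta
        if m in synergy_by_mirna:
            shift -= synergy_by_mirna[m] * parity
        if m in det_baseline:
            base = np.array([det_baseline[m][g] for g in groups])
        else:
            base = np.full(n_total, baseline[m])
        latent = base + shift + sample_effect + rng.normal(0.0, sd[m], n_total)
        failed = rng.random(n_total) < config.failure_rate
        if m in ecs:
            failed[:] = False  # ECs must be measurable in every sample
        for i, s in enumerate(sample_ids):
            detected = latent[i] < config.cq_ceiling
            cq = float(latent[i]) if detected else None
            amp_score = (
                float(rng.uniform(0.3, 0.9))
                if failed[i]
                else float(rng.uniform(1.1, 1.6))
            )
            cq_conf = (
                float(rng.uniform(0.85, 0.99))
                if detected
                else float(rng.uniform(0.3, 0.8))
            )
            records.append(
                AmplificationRecord(
                    sample_id=s,
                    mirna_id=m,
                    cq=cq,
                    amp_score=amp_score,
                    cq_conf=cq_conf,
                    flag=flag_amplification(cq, amp_score, qc),
                )
            )

    phenos = _simulate_phenotypes(rng, sample_ids, groups)
    manifest = {
        "seed": config.seed,
        "group_sizes": list(config.group_sizes),
        "n_mirnas": config.n_mirnas,
        "ecs": ecs,
        "cq_ceiling": config.cq_ceiling,
        "baseline_cq": {m: float(baseline[m]) for m in all_mirnas},
        "sd": {m: float(sd[m]) for m in all_mirnas},
        "level_effects": [e.__dict__ for e in config.level_effects],
        "detection_effects": [e.__dict__ for e in config.detection_effects],
        "synergy_effects": [e.__dict__ for e in config.synergy_effects],
    }
    return records, phenos, manifest


#: Group phenotype parameters (mean, sd) shaped like the study population.
_PHENO_PARAMS = {
    "age": {"ComC": (33.4, 9.3), "DepC": (31.8, 7.1), "DepTBI": (34.0, 10.0)},
    "bmi": {"ComC": (25.1, 3.4), "DepC": (26.9, 4.3), "DepTBI": (28.5, 4.4)},
    "mmse": {"ComC": (29.5, 0.6), "DepC": (29.1, 1.1), "DepTBI": (28.5, 1.6)},
    "abeta42": {"ComC": (321.4, 54.2), "DepC": (309.5, 70.3), "DepTBI": (316.0, 55.8)},
    "ttau": {"ComC": (42.9, 17.3), "DepC": (35.2, 14.1), "DepTBI": (37.5, 13.7)},
    "ptau181": {"ComC": (27.8, 9.3), "DepC": (28.7, 8.9), "DepTBI": (28.2, 6.4)},
}
_APOE4_FRACTION = {"ComC": 0.27, "DepC": 0.53, "DepTBI": 0.22}
_SMOKE_YES = {"ComC": 0.04, "DepC": 0.06, "DepTBI": 0.31}


def _lognormal(rng, mean, sd, size):
    var = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - var / 2
    return rng.lognormal(mu, np.sqrt(var), size)


def _simulate_phenotypes(rng, sample_ids, groups) -> PhenotypeTable:
    n = len(sample_ids)
    df = pd.DataFrame(index=pd.Index(sample_ids, name="sample_id"))
    df["group"] = groups
    for col in ("age", "bmi"):
        vals = np.empty(n)
        for g in GROUPS:
            mask = groups == g
            mean, sd = _PHENO_PARAMS[col][g]
            vals[mask] = rng.normal(mean, sd, mask.sum())
        df[col] = np.round(np.clip(vals, 18, None), 1)
    mmse = np.empty(n)
    for g in GROUPS:
        mask = groups == g
        mean, sd = _PHENO_PARAMS["mmse"][g]
        mmse[mask] = np.clip(np.round(rng.normal(mean, sd, mask.sum())), 0, 30)
    df["mmse"] = mmse
    for col in ("abeta42", "ttau", "ptau181"):
        vals = np.empty(n)
        for g in GROUPS:
            mask = groups == g
            mean, sd = _PHENO_PARAMS[col][g]
            vals[mask] = _lognormal(rng, mean, sd, mask.sum())
        df[col] = np.round(vals, 1)

    genotypes = np.empty(n, dtype=object)
    for i, g in enumerate(groups):
        has_e4 = rng.random() < _APOE4_FRACTION[g]
        if has_e4:
            genotypes[i] = "e4/e4" if rng.random() < 0.1 else "e3/e4"
        else:
            genotypes[i] = "e2/e3" if rng.random() < 0.1 else "e3/e3"
    missing = rng.random(n) < 0.04
    genotypes[missing] = None
    df["apoe"] = genotypes

    smoke = np.where(
        rng.random(n) < np.vectorize(_SMOKE_YES.get)(groups), "yes", "no"
    ).astype(object)
    smoke[rng.random(n) < 0.01] = "unknown"
    df["smoke"] = smoke
    df["race"] = rng.choice(
        ["white", "black", "asian", "native", "other"],
        size=n,
        p=[0.7, 0.05, 0.1, 0.03, 0.12],
    )
    df["n_tbi"] = np.where(
        groups == "DepTBI", np.maximum(1, rng.poisson(8, n)), 0
    )
    df["years_since_tbi"] = np.where(
        groups == "DepTBI", np.round(rng.uniform(1.5, 11.5, n), 1), np.nan
    )
    df.loc[groups != "DepTBI", "n_tbi"] = 0
    return PhenotypeTable(df)


def worked_example_fixture() -> tuple[list[AmplificationRecord], PhenotypeTable, dict]:
    """Tiny deterministic dataset with hand-computable expectations.

    8 samples x 12 probes: 3 noiseless ECs at Cq 20 (+ per-sample card
    offset), a target at ΔCq exactly 5 in sample S001, one miRNA
    censored in half the samples, one miRNA with an exact within-group
    2-fold shift (ΔCq lower by 1 in DepTBI vs ComC), and one technically
    failed reaction.
    """
    samples = [f"S{i + 1:03d}" for i in range(8)]
    groups = ["ComC"] * 3 + ["DepC"] * 2 + ["DepTBI"] * 3
    card_offset = [0.0, 0.5, -0.5, 0.25, -0.25, 1.0, -1.0, 0.0]

    records: list[AmplificationRecord] = []

    def add(sample_i, mirna, cq, amp_score=1.5, cq_conf=0.95):
        flag = flag_amplification(cq, amp_score)
        records.append(
            AmplificationRecord(
                sample_id=samples[sample_i], mirna_id=mirna, cq=cq,
                amp_score=amp_score, cq_conf=cq_conf, flag=flag,
            )
        )

    for i in range(8):
        for ec in ("fx-ec-1", "fx-ec-2", "fx-ec-3"):
            add(i, ec, 20.0 + card_offset[i])
        # target A: ΔCq = 5 everywhere by construction
        add(i, "fx-mir-a", 25.0 + card_offset[i])
        # target B: censored in even samples, detected at ΔCq 8 otherwise
        if i % 2 == 0:
            add(i, "fx-mir-b", None, cq_conf=0.5)
        else:
            add(i, "fx-mir-b", 28.0 + card_offset[i])
        # target C: planted exact 2-fold shift in DepTBI vs ComC
        base = 27.0 if groups[i] != "DepTBI" else 26.0
        add(i, "fx-mir-c", base + card_offset[i])
        # target D: constant mid-range expression
        add(i, "fx-mir-d", 24.0 + card_offset[i])
        # targets E-H: varied but deterministic levels
        add(i, "fx-mir-e", 22.0 + 0.5 * i + card_offset[i])
        add(i, "fx-mir-f", 30.0 + (i % 3) + card_offset[i])
        add(i, "fx-mir-g", 26.5 - 0.25 * i + card_offset[i])
        add(i, "fx-mir-h", 23.0 + ((-1) ** i) * 0.5 + card_offset[i])
    # target I: one technical failure in S002, detected elsewhere
    for i in range(8):
        if i == 1:
            add(i, "fx-mir-i", 25.0 + card_offset[i], amp_score=0.5)
        else:
            add(i, "fx-mir-i", 25.5 + card_offset[i])

    df = pd.DataFrame(
        {
            "group": groups,
            "age": [30, 35, 40, 28, 33, 36, 29, 41],
            "bmi": [24.0, 25.5, 23.0, 27.0, 26.0, 29.0, 28.0, 30.0],
            "mmse": [30, 29, 30, 29, 30, 28, 29, 28],
            "abeta42": [320.0, 310.0, 330.0, 300.0, 315.0, 305.0, 325.0, 318.0],
            "ttau": [40.0, 42.0, 38.0, 36.0, 35.0, 37.0, 39.0, 41.0],
            "ptau181": [27.0, 28.0, 26.0, 29.0, 30.0, 28.5, 27.5, 28.0],
            "apoe": ["e3/e3", "e3/e4", "e3/e3", "e3/e3", "e3/e4", "e4/e4", "e3/e3", "e3/e4"],
            "smoke": ["no", "no", "yes", "no", "no", "yes", "no", "no"],
            "race": ["white", "white", "asian", "white", "other", "white", "black", "white"],
            "n_tbi": [0, 0, 0, 0, 0, 3, 5, 2],
            "years_since_tbi": [np.nan] * 5 + [4.0, 6.5, 2.0],
        },
        index=pd.Index(samples, name="sample_id"),
    )
    expectations = {
        "ecs": ["fx-ec-1", "fx-ec-2", "fx-ec-3"],
        "dcq_s001_fx_mir_a": 5.0,
        "planted_fc_mirna": "fx-mir-c",
        "planted_fc": 2.0,
        "censored_mirna": "fx-mir-b",
        "failed_cell": ["S002", "fx-mir-i"],
    }
    return records, PhenotypeTable(df), expectations
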