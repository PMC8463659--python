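"""End-to-end orchestration: configuration and the staged run.

Every stage writes plain CSV plus a JSON run manifest, so any stage can
be re-run in isolation and every number in the final report traces back
to a stage file.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from csfmir import __version__
from csfmir.diff_detection import run_detection_contrasts
from csfmir.diff_expression import run_contrasts
from csfmir.errors import ConfigError
from csfmir.info_dependence import (
    bin_mirna_matrix,
    bin_secondary,
    build_primaries,
    composite_scores,
    run_search,
    stringent_filter,
)
from csfmir.normalization import (
    ECCriteria,
    filter_mirnas,
    normalize_dcq,
    select_ec_candidates,
    stability_rank,
)
from csfmir.phenotype_assoc import run_regressions
from csfmir.qpcr_io import (
    ProbePanel,
    QCParams,
    qc_summary,
    read_amplifications,
    read_phenotypes,
    records_to_frame,
    write_amplifications,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All tunable thresholds of the pipeline, YAML round-trip safe."""

    cq_ceiling: float = 34.0
    amp_score_min: float = 1.0
    ec_detection_fraction: float = 1.0
    ec_amp_score_min: float = 1.0
    ec_cq_max: float = 30.0
    ec_cq_conf_min: float = 0.8
    v_threshold: float = 0.1527
    fail_frac_max: float = 0.20
    detect_frac_min: float = 0.10
    alpha: float = 0.025
    bin_f_step: float = 0.01
    bin_f_max: float = 2.0
    censored_policy: str = "lowest_bin"
    search_max_top: int = 20
    search_z_min: float = 1.0
    search_min_samples: int = 10
    stringent_n_sd: float = 2.0
    seed: int = 0
    amplifications: str = ""
    phenotypes: str = ""
    out_dir: str = "results"

    def __post_init__(self) -> None:
        for name in (
            "cq_ceiling", "amp_score_min", "v_threshold", "fail_frac_max",
            "detect_frac_min", "alpha", "bin_f_step", "bin_f_max",
            "stringent_n_sd",
        ):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")

    @property
    def qc_params(self) -> QCParams:
        return QCParams(cq_ceiling=self.cq_ceiling, amp_score_min=self.amp_score_min)

    @property
    def ec_criteria(self) -> ECCriteria:
        return ECCriteria(
            detection_fraction=self.ec_detection_fraction,
            amp_score_min=self.ec_amp_score_min,
            cq_max=self.ec_cq_max,
            cq_conf_min=self.ec_cq_conf_min,
            v_threshold=self.v_threshold,
        )

    def to_yaml(self, path) -> None:
        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def digest(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def write_matrix(matrix, out_dir, suffix: str = "") -> None:
    """Persist an expression matrix as four plain CSVs."""
    out = Path(out_dir)
    matrix.dcq.to_csv(out / f"dcq_matrix{suffix}.csv")
    matrix.censored.to_csv(out / f"censor_mask{suffix}.csv")
    matrix.excluded.to_csv(out / f"excluded_mask{suffix}.csv")
    matrix.censor_threshold.rename("censor_threshold").to_csv(
        out / f"censor_threshold{suffix}.csv"
    )


def load_matrix(out_dir, suffix: str = ""):
    """Rebuild an ExpressionMatrix written by :func:`write_matrix`."""
    from csfmir.normalization import ExpressionMatrix

    out = Path(out_dir)
    dcq = pd.read_csv(out / f"dcq_matrix{suffix}.csv", index_col=0)
    censored = pd.read_csv(out / f"censor_mask{suffix}.csv", index_col=0).astype(bool)
    excluded = pd.read_csv(out / f"excluded_mask{suffix}.csv", index_col=0).astype(bool)
    threshold = pd.read_csv(out / f"censor_threshold{suffix}.csv", index_col=0)[
        "censor_threshold"
    ]
    for df in (dcq, censored, excluded):
        df.index = df.index.astype(str)
    threshold.index = threshold.index.astype(str)
    return ExpressionMatrix(
        dcq=dcq, censored=censored, excluded=excluded,
        censor_threshold=threshold,
    )


def run_all(config: RunConfig, panel: ProbePanel | None = None) -> dict:
    """Execute every pipeline stage, writing stage CSVs and a manifest.

    Returns the manifest (config hash, per-stage counts) as a dict.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}

    # qc
    records = read_amplifications(
        config.amplifications, panel=panel, qc=config.qc_params
    )
    if panel is None:
        mirnas = tuple(sorted({r.mirna_id for r in records}))
        panel = ProbePanel(mirna_ids=mirnas)
    counts["records"] = len(records)
    counts["assayed_mirnas"] = len(panel.analyzable_ids)
    phenos = read_phenotypes(
        config.phenotypes, known_samples={r.sample_id for r in records}
    )
    write_amplifications(records, out / "amplifications_flagged.csv")
    qc_summary(records, phenos).to_csv(out / "qc_summary.csv", index=False)
    logger.info("stage qc: %d records, %d miRNAs", len(records), counts["assayed_mirnas"])

    # normalize
    candidates = select_ec_candidates(records, panel, config.ec_criteria)
    counts["ec_candidates"] = len(candidates)
    cq_table = records_to_frame(records).pivot(
        index="sample_id", columns="mirna_id", values="cq"
    )
    ranking = stability_rank(candidates, cq_table, config.v_threshold)
    counts["ecs_selected"] = len(ranking.selected_ecs)
    ec_report = pd.DataFrame(
        {
            "mirna_id": ranking.candidates,
            "stability_m": [ranking.m_values[m] for m in ranking.candidates],
            "selected": [m in ranking.selected_ecs for m in ranking.candidates],
        }
    )
    ec_report.to_csv(out / "ec_report.csv", index=False)
    pd.DataFrame(
        {
            "k": list(ranking.pairwise_variation),
            "v": list(ranking.pairwise_variation.values()),
        }
    ).to_csv(out / "ec_pairwise_variation.csv", index=False)

    matrix_full = normalize_dcq(records, ranking.selected_ecs, config.qc_params)
    matrix = filter_mirnas(
        matrix_full, config.fail_frac_max, config.detect_frac_min
    )
    counts["samples_normalized"] = len(matrix.samples)
    counts["qc_passed_mirnas"] = len(matrix.mirnas)
    write_matrix(matrix, out)
    write_matrix(matrix_full, out, suffix="_full")
    logger.info(
        "stage normalize: %d EC candidates -> %d ECs, %d/%d miRNAs retained",
        len(candidates), len(ranking.selected_ecs),
        len(matrix.mirnas), len(matrix_full.mirnas),
    )

    # de
    de = run_contrasts(matrix, phenos, alpha=config.alpha)
    de.to_csv(out / "de_results.csv", index=False)
    counts["de_significant"] = int(de["significant"].sum())
    counts["de_significant_unique"] = de.loc[de["significant"], "mirna_id"].nunique()

    # detect
    det = run_detection_contrasts(matrix, phenos, alpha=config.alpha)
    det.to_csv(out / "detection_results.csv", index=False)
    counts["detection_significant"] = int(det["significant"].sum())
    counts["detection_significant_unique"] = det.loc[
        det["significant"], "mirna_id"
    ].nunique()

    # assoc
    assoc = run_regressions(matrix, phenos)
    assoc.to_csv(out / "assoc_results.csv", index=False)
    counts["assoc_fits"] = len(assoc)

    # deps: score the full assayed background, not just QC-passing miRNAs
    mirna_codes, factors = bin_mirna_matrix(matrix_full, config.censored_policy)
    factors.rename("factor_f").to_csv(out / "binning_factors.csv")
    primaries = build_primaries(phenos)
    secondaries = bin_secondary(phenos)
    records_df = run_search(
        mirna_codes.reindex(phenos.sample_ids),
        primaries,
        secondaries,
        max_top=config.search_max_top,
        z_min=config.search_z_min,
        min_samples=config.search_min_samples,
    )
    records_df.to_csv(out / "dependency_records.csv", index=False)
    counts["dependency_lists"] = records_df["list_id"].nunique()
    listed = records_df.loc[records_df["rank"].notna(), "mirna_id"].nunique()
    counts["listed_mirnas"] = int(listed)

    # composite + filter
    scores_by_primary = {}
    for primary in primaries:
        cs = composite_scores(records_df, primary)
        cs.to_csv(out / f"composite_{primary}.csv", index=False)
        scores_by_primary[primary] = cs
    selected = stringent_filter(
        scores_by_primary,
        qc_passing=set(matrix.mirnas),
        n_sd=config.stringent_n_sd,
    )
    pd.Series(selected, name="mirna_id").to_csv(
        out / "stringent_candidates.csv", index=False
    )
    counts["stringent_mirnas"] = len(selected)

    manifest = {
        "version": __version__,
        "config": dataclasses.asdict(config),
        "config_digest": config.digest(),
        "counts": counts,
    }
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2))
    logger.info("run complete: %s", counts)
    return manifest
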