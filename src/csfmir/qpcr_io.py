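"""Data model and I/O for qPCR array exports and phenotype tables.

The canonical on-disk format is a long CSV with one row per amplification
(sample x probe reaction).  A wide samples-x-probes Cq matrix is accepted
on input and converted; long format is canonical because it carries the
per-reaction quality metrics (amplification score, Cq confidence).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from csfmir.errors import DuplicateRecordError, InvalidInputError, SchemaError

logger = logging.getLogger(__name__)

FLAG_GOOD = "good"
FLAG_CENSORED = "censored"
FLAG_EXCLUDED = "excluded"
FLAGS = (FLAG_GOOD, FLAG_CENSORED, FLAG_EXCLUDED)

GROUPS = ("ComC", "DepC", "DepTBI")

#: Cell values meaning "no Cq was called" in instrument exports.
_ABSENT_CQ = {"", "undetermined", "undetected", "na", "nan", "none"}

# Accepted header aliases, lowercased, for the long format.
_COLUMN_ALIASES = {
    "sample_id": {"sample_id", "sample", "sample.id", "samplename"},
    "mirna_id": {"mirna_id", "mirna", "probe", "probe_id", "detector", "target"},
    "cq": {"cq", "ct", "cq_value"},
    "amp_score": {"amp_score", "ampscore", "amplification_score"},
    "cq_conf": {"cq_conf", "cqconf", "cq_confidence"},
}


@dataclass(frozen=True)
class QCParams:
    """Per-amplification flagging thresholds.

    ``cq_ceiling`` is the detection limit: reactions with no Cq call or a
    Cq at or beyond the ceiling are censored.  ``amp_score_min`` is the
    signal-quality floor below which a reaction is a technical failure.
    """

    cq_ceiling: float = 34.0
    amp_score_min: float = 1.0


@dataclass(frozen=True)
class AmplificationRecord:
    """One probe reaction on one sample."""

    sample_id: str
    mirna_id: str
    cq: float | None
    amp_score: float
    cq_conf: float
    flag: str

    def __post_init__(self) -> None:
        if self.flag not in FLAGS:
            raise InvalidInputError(f"unknown flag {self.flag!r}")


@dataclass(frozen=True)
class ProbePanel:
    """The probe content of one array card.

    ``withdrawn_ids`` are probes excluded a priori (targets no longer
    annotated as miRNAs); ``control_ids`` are non-miRNA control probes
    (U6-class) that are never candidates for endogenous controls.
    """

    mirna_ids: tuple[str, ...]
    withdrawn_ids: frozenset[str] = field(default_factory=frozenset)
    control_ids: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        unknown = self.withdrawn_ids - set(self.mirna_ids)
        if unknown:
            raise InvalidInputError(
                f"withdrawn probes not on the panel: {sorted(unknown)[:5]}"
            )

    @property
    def analyzable_ids(self) -> tuple[str, ...]:
        """Panel probes kept for analysis (withdrawn probes dropped)."""
        return tuple(m for m in self.mirna_ids if m not in self.withdrawn_ids)

    @property
    def candidate_ec_ids(self) -> tuple[str, ...]:
        """Analyzable probes that are annotated miRNAs (not controls)."""
        return tuple(m for m in self.analyzable_ids if m not in self.control_ids)


@dataclass
class PhenotypeTable:
    """Per-sample phenotypes, indexed by sample id.

    Ratio columns (``abeta_ttau``, ``abeta_ptau``, ``ptau_ttau``) are
    derived from their components on construction; any cell except
    ``group`` may be missing.
    """

    data: pd.DataFrame

    RATIOS = {
        "abeta_ttau": ("abeta42", "ttau"),
        "abeta_ptau": ("abeta42", "ptau181"),
        "ptau_ttau": ("ptau181", "ttau"),
    }

    def __post_init__(self) -> None:
        df = self.data
        if "group" not in df.columns:
            raise SchemaError("phenotype table must have a 'group' column")
        bad = set(df["group"].dropna().unique()) - set(GROUPS)
        if bad:
            raise SchemaError(f"unknown group labels {sorted(bad)}; expected {GROUPS}")
        if df["group"].isna().any():
            raise SchemaError("group may not be missing")
        for ratio, (num, den) in self.RATIOS.items():
            if num in df.columns and den in df.columns:
                df[ratio] = df[num] / df[den].replace(0, np.nan)
        self.data = df

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def group(self) -> pd.Series:
        return self.data["group"]

    def samples_in(self, group: str) -> list[str]:
        if group not in GROUPS:
            raise InvalidInputError(f"unknown group {group!r}")
        return list(self.data.index[self.data["group"] == group])


def flag_amplification(
    cq: float | None, amp_score: float, qc: QCParams = QCParams()
) -> str:
    """Assign the QC flag for one reaction.

    Exclusion (technical failure) takes precedence: ``amp_score`` below
    the floor excludes the reaction regardless of Cq.  Otherwise an
    absent Cq or a Cq at/beyond the ceiling censors it; remaining
    reactions are good.
    """
    if cq is not None:
        if math.isnan(cq):
            cq = None
        elif cq < 0:
            raise InvalidInputError(f"negative Cq: {cq}")
    if amp_score < qc.amp_score_min:
        return FLAG_EXCLUDED
    if cq is None or cq >= qc.cq_ceiling:
        return FLAG_CENSORED
    return FLAG_GOOD


def _parse_cq(raw) -> float | None:
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return None
    if isinstance(raw, str):
        if raw.strip().lower() in _ABSENT_CQ:
            return None
        return float(raw)
    return float(raw)


def _resolve_columns(columns: Sequence[str]) -> dict[str, str] | None:
    """Map canonical names to actual header names; None if not long format."""
    lowered = {c.lower().strip(): c for c in columns}
    resolved = {}
    for canon, aliases in _COLUMN_ALIASES.items():
        hit = next((lowered[a] for a in aliases if a in lowered), None)
        if hit is None:
            return None
        resolved[canon] = hit
    return resolved


def read_amplifications(
    path,
    panel: ProbePanel | None = None,
    qc: QCParams = QCParams(),
) -> list[AmplificationRecord]:
    """Read an amplification export (long or wide; dialect auto-detected).

    Long format needs sample, probe, Cq, amplification-score and Cq-confidence
    columns (header aliases accepted).  A wide file is interpreted as a
    samples-x-probes Cq matrix; quality metrics are then unavailable and
    default to passing values.  Probes withdrawn from the panel are dropped;
    every record gets exactly one QC flag.
    """
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    if df.empty and df.columns.size == 0:
        return []
    resolved = _resolve_columns(df.columns)
    if resolved is None:
        lowered = {c.lower().strip() for c in df.columns}
        partial = {
            canon
            for canon, aliases in _COLUMN_ALIASES.items()
            if lowered & aliases
        }
        # headers that partially match the long schema are a malformed long
        # file, not a wide Cq matrix
        if partial - {"sample_id", "mirna_id"}:
            missing = sorted(set(_COLUMN_ALIASES) - partial)
            raise SchemaError(
                f"missing required columns: {missing} (got {list(df.columns)})"
            )
        if df.columns.size >= 2:
            return _read_wide(df, panel, qc)
        raise SchemaError(
            f"cannot interpret columns {list(df.columns)} as long or wide format"
        )

    withdrawn = panel.withdrawn_ids if panel is not None else frozenset()
    records: list[AmplificationRecord] = []
    seen: set[tuple[str, str]] = set()
    for row in df.itertuples(index=False):
        r = dict(zip(df.columns, row))
        sample = str(r[resolved["sample_id"]]).strip()
        mirna = str(r[resolved["mirna_id"]]).strip()
        if mirna in withdrawn:
            continue
        key = (sample, mirna)
        if key in seen:
            raise DuplicateRecordError(f"duplicate reaction for {key}")
        seen.add(key)
        cq = _parse_cq(r[resolved["cq"]])
        amp_score = float(r[resolved["amp_score"]])
        cq_conf = float(r[resolved["cq_conf"]])
        records.append(
            AmplificationRecord(
                sample_id=sample,
                mirna_id=mirna,
                cq=cq,
                amp_score=amp_score,
                cq_conf=cq_conf,
                flag=flag_amplification(cq, amp_score, qc),
            )
        )
    return records


def _read_wide(
    df: pd.DataFrame, panel: ProbePanel | None, qc: QCParams
) -> list[AmplificationRecord]:
    # Wide exports carry only Cq; amp score / Cq confidence default to passing.
    withdrawn = panel.withdrawn_ids if panel is not None else frozenset()
    sample_col = df.columns[0]
    records = []
    seen: set[tuple[str, str]] = set()
    for row in df.itertuples(index=False):
        r = dict(zip(df.columns, row))
        sample = str(r[sample_col]).strip()
        for mirna in df.columns[1:]:
            if mirna in withdrawn:
                continue
            key = (sample, mirna)
            if key in seen:
                raise DuplicateRecordError(f"duplicate reaction for {key}")
            seen.add(key)
            cq = _parse_cq(r[mirna])
            records.append(
                AmplificationRecord(
                    sample_id=sample,
                    mirna_id=str(mirna),
                    cq=cq,
                    amp_score=qc.amp_score_min,
                    cq_conf=1.0,
                    flag=flag_amplification(cq, qc.amp_score_min, qc),
                )
            )
    return records


def write_amplifications(records: Iterable[AmplificationRecord], path) -> None:
    """Write the canonical long CSV (with flag column); round-trip safe."""
    df = records_to_frame(records)
    df.to_csv(path, index=False, float_format="%.17g")


def records_to_frame(records: Iterable[AmplificationRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample_id": r.sample_id,
                "mirna_id": r.mirna_id,
                "cq": r.cq,
                "amp_score": r.amp_score,
                "cq_conf": r.cq_conf,
                "flag": r.flag,
            }
            for r in records
        ],
        columns=["sample_id", "mirna_id", "cq", "amp_score", "cq_conf", "flag"],
    )


def qc_summary(
    records: Iterable[AmplificationRecord], phenos: PhenotypeTable | None = None
) -> pd.DataFrame:
    """Per-miRNA flag counts, optionally split by participant group."""
    df = records_to_frame(records)
    if phenos is not None:
        df = df.join(phenos.group, on="sample_id")
        counts = df.groupby(["mirna_id", "group", "flag"], observed=True).size()
        out = counts.unstack("flag", fill_value=0).reset_index()
    else:
        counts = df.groupby(["mirna_id", "flag"]).size()
        out = counts.unstack("flag", fill_value=0).reset_index()
    for f in FLAGS:
        if f not in out.columns:
            out[f] = 0
    return out


def read_phenotypes(
    path, known_samples: Iterable[str] | None = None
) -> PhenotypeTable:
    """Read a per-sample phenotype CSV/TSV.

    ``known_samples``, when given, is the set of sample ids present in the
    amplification data; phenotype rows not matching it are reported as a
    warning (not fatal).
    """
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    if "sample_id" not in df.columns:
        raise SchemaError("phenotype table must have a 'sample_id' column")
    df["sample_id"] = df["sample_id"].astype(str)
    df = df.set_index("sample_id")
    if known_samples is not None:
        unmatched = sorted(set(df.index) - set(known_samples))
        if unmatched:
            logger.warning(
                "%d phenotype sample ids not found in amplification data: %s",
                len(unmatched),
                unmatched[:10],
            )
    return PhenotypeTable(df)
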