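"""Cohort stratification filters for a repair-proficient analysis set.

Hypermutators (more than 100,000 substitutions or more than 7,000 indels),
samples with fewer than 1,000 substitutions, and samples whose normalized
SBS-96 profile resembles a flagged repair-deficiency signature (cosine
similarity above 0.80) are removed, in that precedence.  All inequalities
are strict, so boundary samples are retained.  An explicit manual exclusion
list covers ad-hoc removals that no automatic rule captures.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd

from .analysis import cosine_similarity
from .catalogs import MutationalMatrix, collapse_matrix
from .signatures import SignatureSet

logger = logging.getLogger(__name__)

RETAINED = "retained"
REMOVED_HYPERMUTATOR = "removed_hypermutator"
REMOVED_LOW_COUNT = "removed_low_count"
REMOVED_FLAG_SIGNATURE = "removed_flag_signature"
REMOVED_MANUAL = "removed_manual"


@dataclass
class QCThresholds:
    """Burden and flag-signature thresholds (strict inequalities throughout)."""

    max_sbs: int = 100_000
    max_indels: int = 7_000
    min_sbs: int = 1_000
    flag_cosine: float = 0.80
    flag_signatures: SignatureSet | None = None

    def __post_init__(self) -> None:
        if self.min_sbs >= self.max_sbs:
            raise ValueError("min_sbs must be below max_sbs")
        if not (0.0 < self.flag_cosine < 1.0):
            raise ValueError("flag_cosine must lie in (0, 1)")


@dataclass
class QCReport:
    """Per-sample QC decisions with the retained sample list."""

    table: pd.DataFrame  # sample-indexed: sbs_count, indel_count,
    # max_flag_cosine, flag_hit_name, decision
    retained_samples: list[str] = field(default_factory=list)

    def decision_counts(self) -> pd.Series:
        return self.table["decision"].value_counts()

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index_label="sample")


def qc_filter(
    matrix: MutationalMatrix,
    indel_counts: pd.Series | dict | None = None,
    thresholds: QCThresholds = None,
    manual_exclusions: Iterable[str] = (),
) -> QCReport:
    """Apply the stratification filters to a cohort catalog.

    Decision precedence per sample: manual exclusion, hypermutator
    (sbs > max_sbs or indels > max_indels), low count (sbs < min_sbs),
    flag-signature hit (profile cosine > flag_cosine to any flag signature),
    else retained.  Missing indel counts are treated as 0 with a warning.
    """
    if thresholds is None:
        thresholds = QCThresholds()
    sbs = collapse_matrix(matrix)
    totals = sbs.column_sums()
    if indel_counts is None:
        logger.warning("qc_filter: no indel counts supplied; treating all as 0")
        indels = pd.Series(0, index=totals.index)
    else:
        indels = pd.Series(indel_counts).reindex(totals.index)
        if indels.isna().any():
            logger.warning(
                "qc_filter: missing indel counts for %d sample(s); treated as 0",
                int(indels.isna().sum()),
            )
            indels = indels.fillna(0)
    manual = set(manual_exclusions)
    flags = thresholds.flag_signatures
    flag_profiles = (
        {n: flags.collapse()[n] for n in flags.names} if flags is not None else {}
    )
    rows = []
    retained = []
    V = sbs.counts
    for s in totals.index:
        n_sbs = int(totals[s])
        n_ind = int(indels[s])
        max_cos, hit = 0.0, ""
        if flag_profiles and n_sbs > 0:
            profile = V[s].to_numpy(dtype=float)
            for name, fp in flag_profiles.items():
                cos = cosine_similarity(profile, fp)
                if cos > max_cos:
                    max_cos, hit = cos, name
        if s in manual:
            decision = REMOVED_MANUAL
        elif n_sbs > thresholds.max_sbs or n_ind > thresholds.max_indels:
            decision = REMOVED_HYPERMUTATOR
        elif n_sbs < thresholds.min_sbs:
            decision = REMOVED_LOW_COUNT
        elif max_cos > thresholds.flag_cosine:
            decision = REMOVED_FLAG_SIGNATURE
        else:
            decision = RETAINED
            retained.append(s)
        rows.append(
            {
                "sample": s,
                "sbs_count": n_sbs,
                "indel_count": n_ind,
                "max_flag_cosine": max_cos,
                "flag_hit_name": hit if decision == REMOVED_FLAG_SIGNATURE else "",
                "decision": decision,
            }
        )
    table = pd.DataFrame(rows).set_index("sample")
    return QCReport(table=table, retained_samples=retained)


def apply_qc(matrix: MutationalMatrix, report: QCReport) -> MutationalMatrix:
    """Subset a catalog to the retained samples of a QC report."""
    return MutationalMatrix(
        matrix.schema, matrix.counts[report.retained_samples]
    )


def read_exclusion_list(path: str | Path) -> list[str]:
    """Read a manual exclusion list (one sample id per line, '#' comments)."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out
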