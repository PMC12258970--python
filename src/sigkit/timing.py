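"""Clonal timing of mutations relative to copy-number gains.

In a segment where the major allele has gained (major copy number >= 2), a
clonal mutation present on more than one chromosome copy must have occurred
before the gain (early clonal); a clonal mutation on at most one copy arose
after it (likely late clonal).  Only clonal mutations (cancer cell fraction
strictly above 0.95) are timed; everything else is unclassified.  Samples
with at least 256 mutations in each phase are eligible for phase-specific
attribution, and per-signature timing asymmetry is tested with McNemar's
test on paired early/late positivity calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
import pandas as pd
from scipy import stats

from .attribution import DEFAULT_PRUNE_DELTA, ExposureMatrix, attribute_cohort
from .catalogs import MutationalMatrix, MutationRecord, build_matrix
from .schemas import SBS96, Schema, get_schema
from .signatures import SignatureSet

EARLY = "early_clonal"
LATE = "late_clonal"
UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class TimingConfig:
    """Thresholds for the timing rules.

    ``ccf_clonal_threshold`` is strict (CCF must exceed it); ``gain_rule``
    fixes how "a gain on the major allele" is operationalized (currently
    major copy number >= 2); ``min_per_phase`` is the per-phase mutation
    floor for sample eligibility.
    """

    ccf_clonal_threshold: float = 0.95
    min_per_phase: int = 256
    gain_rule: str = "major_cn_ge_2"

    def __post_init__(self) -> None:
        if not (0.0 < self.ccf_clonal_threshold <= 1.0):
            raise ValueError("ccf_clonal_threshold must lie in (0, 1]")
        if self.min_per_phase < 0:
            raise ValueError("min_per_phase must be >= 0")
        if self.gain_rule != "major_cn_ge_2":
            raise ValueError(f"unknown gain rule {self.gain_rule!r}")


def classify_timing(record: MutationRecord, config: TimingConfig = TimingConfig()) -> str:
    """Label one mutation early_clonal / late_clonal / unclassified.

    Requires ccf, multiplicity and major_cn; missing annotations, subclonal
    CCF, or the absence of a major-allele gain all yield ``unclassified``.
    """
    if record.ccf is None or record.multiplicity is None or record.major_cn is None:
        return UNCLASSIFIED
    if record.ccf <= config.ccf_clonal_threshold:
        return UNCLASSIFIED
    if record.major_cn < 2:
        return UNCLASSIFIED
    return EARLY if record.multiplicity >= 2 else LATE


def classify_timing_frame(
    records: pd.DataFrame, config: TimingConfig = TimingConfig()
) -> pd.Series:
    """Vectorized `classify_timing` over a records table."""
    ccf = pd.to_numeric(records.get("ccf"), errors="coerce")
    mult = pd.to_numeric(records.get("multiplicity"), errors="coerce")
    major = pd.to_numeric(records.get("major_cn"), errors="coerce")
    ok = ccf.notna() & mult.notna() & major.notna()
    clonal = ok & (ccf > config.ccf_clonal_threshold) & (major >= 2)
    out = pd.Series(UNCLASSIFIED, index=records.index)
    out[clonal & (mult >= 2)] = EARLY
    out[clonal & (mult <= 1)] = LATE
    return out


@dataclass
class TimedCatalogs:
    """Early- and late-clonal catalogs with per-sample eligibility."""

    early: MutationalMatrix
    late: MutationalMatrix
    eligible_samples: list[str]
    min_per_phase: int
    n_unclassified: pd.Series = field(default=None)

    def report(self) -> pd.DataFrame:
        early = self.early.column_sums()
        late = self.late.column_sums()
        df = pd.DataFrame(
            {
                "n_early": early,
                "n_late": late,
                "n_unclassified": (
                    self.n_unclassified
                    if self.n_unclassified is not None
                    else np.nan
                ),
            }
        )
        df["eligible"] = df.index.isin(self.eligible_samples)
        return df


def split_catalogs(
    records,
    config: TimingConfig = TimingConfig(),
    schema: str | Schema = SBS96,
) -> TimedCatalogs:
    """Build early/late catalogs and compute per-sample eligibility.

    ``records`` may be a list of `MutationRecord` or a records table with the
    interchange columns.  Ineligible samples (fewer than ``min_per_phase``
    mutations in either phase) remain as columns but are excluded from
    ``eligible_samples``.
    """
    schema = get_schema(schema)
    if isinstance(records, pd.DataFrame):
        from .catalogs import build_matrix_from_frame

        labels = classify_timing_frame(records, config)
        samples = sorted(records["sample"].astype(str).unique())
        early_m = build_matrix_from_frame(
            records[labels == EARLY], schema, sample_ids=samples
        )
        late_m = build_matrix_from_frame(
            records[labels == LATE], schema, sample_ids=samples
        )
        unclassified = (
            records.loc[labels == UNCLASSIFIED, "sample"]
            .astype(str)
            .value_counts()
            .reindex(samples, fill_value=0)
            .astype(int)
        )
    else:
        recs = list(records)
        labels = pd.Series([classify_timing(r, config) for r in recs])
        samples = sorted({r.sample_id for r in recs})
        early = [r for r, lab in zip(recs, labels) if lab == EARLY]
        late = [r for r, lab in zip(recs, labels) if lab == LATE]
        early_m = build_matrix(early, schema, sample_ids=samples)
        late_m = build_matrix(late, schema, sample_ids=samples)
        unclassified = pd.Series(0, index=samples, dtype=int)
        counts = (
            pd.Series(
                [r.sample_id for r, lab in zip(recs, labels) if lab == UNCLASSIFIED]
            ).value_counts()
        )
        unclassified.update(counts)
    e, l = early_m.column_sums(), late_m.column_sums()
    eligible = [
        s
        for s in samples
        if e[s] >= config.min_per_phase and l[s] >= config.min_per_phase
    ]
    return TimedCatalogs(
        early=early_m,
        late=late_m,
        eligible_samples=eligible,
        min_per_phase=config.min_per_phase,
        n_unclassified=unclassified,
    )


def _frame_to_records(df: pd.DataFrame) -> list[MutationRecord]:
    recs = []
    has = df.columns
    for row in df.itertuples(index=False):
        recs.append(
            MutationRecord(
                sample_id=str(row.sample),
                chrom=str(getattr(row, "chrom", "chr1")),
                pos=int(getattr(row, "pos", 3)),
                ref=str(row.ref),
                alt=str(row.alt),
                pentacontext=str(row.pentacontext),
                strand_status=str(getattr(row, "strand_status", "non_transcribed")),
                ccf=float(row.ccf) if "ccf" in has and pd.notna(row.ccf) else None,
                multiplicity=(
                    int(row.multiplicity)
                    if "multiplicity" in has and pd.notna(row.multiplicity)
                    else None
                ),
                major_cn=(
                    int(row.major_cn)
                    if "major_cn" in has and pd.notna(row.major_cn)
                    else None
                ),
                minor_cn=(
                    int(row.minor_cn)
                    if "minor_cn" in has and pd.notna(row.minor_cn)
                    else None
                ),
            )
        )
    return recs


@dataclass
class ContrastResult:
    """McNemar contrast of paired early/late positivity over eligible samples."""

    n_early_only: int
    n_late_only: int
    n_both: int
    n_neither: int
    statistic: float
    p_value: float
    method: str

    @property
    def n(self) -> int:
        return self.n_early_only + self.n_late_only + self.n_both + self.n_neither


def timing_contrast(pos_early, pos_late) -> ContrastResult:
    """McNemar test on paired early/late positivity calls.

    Exact two-sided binomial on the discordant pairs when there are fewer
    than 25 of them, chi-square with continuity correction otherwise;
    p = 1 with no discordance.
    """
    e = np.asarray(pos_early, dtype=bool)
    l = np.asarray(pos_late, dtype=bool)
    if e.shape != l.shape:
        raise ValueError("positivity vectors must have equal length")
    b = int(np.sum(e & ~l))  # early only
    c = int(np.sum(~e & l))  # late only
    both = int(np.sum(e & l))
    neither = int(np.sum(~e & ~l))
    n_disc = b + c
    if n_disc == 0:
        return ContrastResult(b, c, both, neither, 0.0, 1.0, "exact_binomial")
    if n_disc < 25:
        p = float(stats.binomtest(b, n_disc, 0.5).pvalue)
        return ContrastResult(b, c, both, neither, float(min(b, c)), p, "exact_binomial")
    stat = (abs(b - c) - 1.0) ** 2 / n_disc
    p = float(stats.chi2.sf(stat, df=1))
    return ContrastResult(b, c, both, neither, float(stat), p, "chi_square_cc")


def phase_attribution(
    timed: TimedCatalogs,
    signatures: SignatureSet,
    prune_delta: float = DEFAULT_PRUNE_DELTA,
) -> tuple[ExposureMatrix, ExposureMatrix]:
    """Pruned attribution run independently on the early and late catalogs.

    Restricted to eligible samples.
    """
    samples = timed.eligible_samples
    if not samples:
        raise ValueError("no eligible samples")
    early = MutationalMatrix(timed.early.schema, timed.early.counts[samples])
    late = MutationalMatrix(timed.late.schema, timed.late.counts[samples])
    return (
        attribute_cohort(early, signatures, prune_delta),
        attribute_cohort(late, signatures, prune_delta),
    )
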