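"""Mutation records, channel classification and mutational matrices.

A cohort's somatic single-base substitutions are classified into the channels
of a `Schema` and aggregated into a channels × samples count matrix (the
mutational catalog).  Classification is pyrimidine-centric: records whose
reference base is a purine are reverse-complemented (context and alternate
allele) before the channel is read off, so every mutation lands on one of the
six canonical substitution types.

Coordinates are 1-based and fully closed (VCF convention); the pentanucleotide
context is always stored on the reference strand and the purine flip happens
at classification time.  Soft-masked (lowercase) reference bases are
uppercased; an ambiguous base (N) in a context position the schema needs
rejects the record with a counted reason.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .schemas import (
    PYRIMIDINES,
    COMPLEMENT,
    Schema,
    SBS96,
    collapse_label,
    get_schema,
    revcomp,
)

logger = logging.getLogger(__name__)

STRAND_STATUSES = ("non_transcribed", "gene_forward", "gene_reverse", "gene_both")

TSV_COLUMNS = (
    "sample",
    "chrom",
    "pos",
    "ref",
    "alt",
    "pentacontext",
    "strand_status",
    "ccf",
    "multiplicity",
    "major_cn",
    "minor_cn",
)
_OPTIONAL_COLUMNS = TSV_COLUMNS[7:]


class RecordError(ValueError):
    """A mutation record violated an invariant; carries a short reason tag."""

    def __init__(self, reason: str, detail: str = ""):
        self.reason = reason
        super().__init__(f"{reason}: {detail}" if detail else reason)


@dataclass
class MutationRecord:
    """One somatic single-base substitution with optional clonality annotations.

    ``pentacontext`` is the 5-base reference-strand slice centred on the
    mutated base; it may be ``None`` before `annotate_context` fills it in.
    ``ccf`` (cancer cell fraction), ``multiplicity`` and the allele-specific
    copy numbers are upstream subclonal-deconvolution outputs consumed as-is.
    """

    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    pentacontext: str | None = None
    strand_status: str = "non_transcribed"
    ccf: float | None = None
    multiplicity: int | None = None
    major_cn: int | None = None
    minor_cn: int | None = None

    def validate(self) -> None:
        """Raise `RecordError` if any structural invariant is violated."""
        if self.ref not in "ACGT" or len(self.ref) != 1:
            raise RecordError("bad_ref", repr(self.ref))
        if self.alt not in "ACGT" or len(self.alt) != 1:
            raise RecordError("bad_alt", repr(self.alt))
        if self.ref == self.alt:
            raise RecordError("ref_equals_alt", f"{self.ref}>{self.alt}")
        if self.strand_status not in STRAND_STATUSES:
            raise RecordError("bad_strand_status", self.strand_status)
        if self.pentacontext is not None:
            ctx = self.pentacontext.upper()
            if len(ctx) != 5:
                raise RecordError("bad_context_length", ctx)
            if ctx[2] != self.ref:
                raise RecordError(
                    "context_ref_mismatch", f"center {ctx[2]} vs ref {self.ref}"
                )
        if self.ccf is not None and not (0.0 <= self.ccf <= 1.0):
            raise RecordError("ccf_out_of_range", str(self.ccf))
        if (
            self.major_cn is not None
            and self.minor_cn is not None
            and self.minor_cn > self.major_cn
        ):
            raise RecordError(
                "minor_gt_major_cn", f"{self.minor_cn} > {self.major_cn}"
            )


class RecordList(list):
    """A list of `MutationRecord` that also carries per-reason rejection counts."""

    def __init__(self, records: Iterable[MutationRecord] = (), rejections=None):
        super().__init__(records)
        self.rejections: Counter = Counter(rejections or {})


def classify_sbs(record: MutationRecord, schema: str | Schema = SBS96) -> str:
    """Classify a substitution into a channel label of ``schema``.

    Purine-reference records are mapped by reverse-complementing the context
    and complementing the alternate allele.  For SBS-288 the strand prefix is
    ``T:`` when the mutated pyrimidine lies on the gene's template strand,
    ``U:`` when on the coding strand, and ``N:`` for non-transcribed loci
    (including loci covered by genes on both strands).

    Raises `RecordError` (reason ``ambiguous_context``) when a context
    position the schema requires is not an unambiguous A/C/G/T.
    """
    schema = get_schema(schema)
    record.validate()
    if record.pentacontext is None:
        raise RecordError("missing_context", f"{record.chrom}:{record.pos}")
    ctx = record.pentacontext.upper()
    alt = record.alt
    on_reference_pyrimidine = record.ref in PYRIMIDINES
    if not on_reference_pyrimidine:
        ctx = revcomp(ctx)
        alt = COMPLEMENT[alt]
    needed = slice(0, 5) if schema.name == "SBS1536" else slice(1, 4)
    if any(b not in "ACGT" for b in ctx[needed]):
        raise RecordError("ambiguous_context", record.pentacontext)
    sub = f"{ctx[2]}>{alt}"
    if schema.name == "SBS1536":
        return f"{ctx[0]}{ctx[1]}[{sub}]{ctx[3]}{ctx[4]}"
    core = f"{ctx[1]}[{sub}]{ctx[3]}"
    if schema.name == "SBS96":
        return core
    # SBS288: orient the pyrimidine relative to the transcribed gene.
    status = record.strand_status
    if status in ("non_transcribed", "gene_both"):
        prefix = "N"
    elif status == "gene_forward":
        # coding strand is '+': a reference-strand pyrimidine sits on the
        # coding strand (U), a flipped purine record on the template (T)
        prefix = "U" if on_reference_pyrimidine else "T"
    else:  # gene_reverse: template strand is '+'
        prefix = "T" if on_reference_pyrimidine else "U"
    return f"{prefix}:{core}"


_COMP_TABLE = str.maketrans("ACGTN", "TGCAN")


def classify_frame(records: pd.DataFrame, schema: str | Schema = SBS96) -> pd.Series:
    """Vectorized `classify_sbs` over a records table.

    Returns a Series of channel labels aligned with ``records``; rows that
    fail classification (ambiguous context, context/ref mismatch) get NaN.
    Requires columns ref, alt, pentacontext (and strand_status for SBS-288).
    """
    schema = get_schema(schema)
    penta = records["pentacontext"].astype(str).str.upper()
    ref = records["ref"].astype(str).str.upper()
    alt = records["alt"].astype(str).str.upper()
    ok = (penta.str.len() == 5) & (penta.str[2] == ref) & (ref != alt)
    flip = ref.isin(["A", "G"])
    rc = penta.str.translate(_COMP_TABLE).str[::-1]
    ctx = penta.where(~flip, rc)
    alt_p = alt.where(~flip, alt.str.translate(_COMP_TABLE))
    needed = ctx.str[:5] if schema.name == "SBS1536" else ctx.str[1:4]
    ok &= ~needed.str.contains("[^ACGT]", regex=True, na=False)
    sub = ctx.str[2] + ">" + alt_p
    if schema.name == "SBS1536":
        labels = ctx.str[:2] + "[" + sub + "]" + ctx.str[3:]
    else:
        labels = ctx.str[1] + "[" + sub + "]" + ctx.str[3]
        if schema.name == "SBS288":
            status = records["strand_status"].astype(str)
            prefix = pd.Series("N", index=records.index)
            fwd = status == "gene_forward"
            rev = status == "gene_reverse"
            prefix[fwd & ~flip] = "U"
            prefix[fwd & flip] = "T"
            prefix[rev & ~flip] = "T"
            prefix[rev & flip] = "U"
            labels = prefix + ":" + labels
    return labels.where(ok)


def build_matrix_from_frame(
    records: pd.DataFrame,
    schema: str | Schema = SBS96,
    sample_ids: Sequence[str] | None = None,
) -> MutationalMatrix:
    """`build_matrix` for a records table, using vectorized classification."""
    schema = get_schema(schema)
    labels = classify_frame(records, schema)
    good = labels.notna()
    tab = pd.crosstab(labels[good], records.loc[good, "sample"].astype(str))
    columns = (
        list(sample_ids)
        if sample_ids is not None
        else sorted(records["sample"].astype(str).unique())
    )
    counts = tab.reindex(
        index=list(schema.channel_labels), columns=columns, fill_value=0
    )
    counts.index.name = None
    counts.columns.name = None
    rejections = Counter()
    if (~good).any():
        rejections["unclassifiable"] = int((~good).sum())
    return MutationalMatrix(schema, counts, rejections)


@dataclass
class MutationalMatrix:
    """A channels × samples nonnegative integer catalog under a named schema."""

    schema: Schema
    counts: pd.DataFrame
    rejections: Counter = field(default_factory=Counter, compare=False)

    def __post_init__(self) -> None:
        self.schema = get_schema(self.schema)
        if list(self.counts.index) != list(self.schema.channel_labels):
            self.counts = self.counts.reindex(
                list(self.schema.channel_labels), fill_value=0
            )
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("mutational matrix must be nonnegative")
        self.counts = self.counts.astype(np.int64)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_channels(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def column_sums(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def to_tsv(self, path: str | Path) -> None:
        out = self.counts.copy()
        out.insert(0, "MutationType", out.index)
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, schema: str | Schema | None = None):
        df = pd.read_csv(path, sep="\t")
        if "MutationType" not in df.columns:
            raise ValueError(f"{path}: missing MutationType column")
        df = df.set_index("MutationType")
        df.index.name = None
        if schema is None:
            schema = {96: "SBS96", 288: "SBS288", 1536: "SBS1536"}.get(len(df))
            if schema is None:
                raise ValueError(f"{path}: {len(df)} rows match no known schema")
        return cls(get_schema(schema), df)


def build_matrix(
    records: Iterable[MutationRecord],
    schema: str | Schema = SBS96,
    sample_ids: Sequence[str] | None = None,
) -> MutationalMatrix:
    """Aggregate records into a channels × samples count matrix.

    Samples with zero classifiable records (declared via ``sample_ids``)
    appear as all-zero columns.  Records that fail classification are
    dropped and counted in the returned matrix's ``rejections``.
    """
    schema = get_schema(schema)
    rejections: Counter = Counter()
    cells: Counter = Counter()
    seen: dict[str, None] = {}
    for rec in records:
        seen.setdefault(rec.sample_id)
        try:
            label = classify_sbs(rec, schema)
        except RecordError as err:
            rejections[err.reason] += 1
            continue
        cells[(label, rec.sample_id)] += 1
    columns = list(sample_ids) if sample_ids is not None else list(seen)
    if not columns:
        raise ValueError("no records and no declared sample list")
    counts = pd.DataFrame(
        0, index=list(schema.channel_labels), columns=columns, dtype=np.int64
    )
    for (label, sample), n in cells.items():
        if sample in counts.columns:
            counts.at[label, sample] = n
    if rejections:
        logger.warning("build_matrix rejected %d records: %s",
                       sum(rejections.values()), dict(rejections))
    return MutationalMatrix(schema, counts, rejections)


def collapse_matrix(matrix: MutationalMatrix) -> MutationalMatrix:
    """Collapse an SBS-288 or SBS-1536 matrix to SBS-96.

    Strand categories (288) or outer flanks (1536) are summed; column totals
    are preserved exactly.  An SBS-96 input is returned unchanged.
    """
    if matrix.schema.name == "SBS96":
        return matrix
    mapped = matrix.counts.groupby(
        [collapse_label(lab) for lab in matrix.counts.index]
    ).sum()
    mapped = mapped.reindex(list(SBS96.channel_labels), fill_value=0)
    return MutationalMatrix(SBS96, mapped, Counter(matrix.rejections))


def _parse_optional(value, caster):
    if value is None or (isinstance(value, float) and np.isnan(value)) or value == "":
        return None
    return caster(value)


def read_mutation_table(path: str | Path, format: str = "tsv") -> RecordList:
    """Read mutation records from the tab-separated interchange format.

    Required columns: sample, chrom, pos, ref, alt, pentacontext,
    strand_status; optional: ccf, multiplicity, major_cn, minor_cn (empty
    cell = absent).  Malformed rows are skipped and counted in the returned
    list's ``rejections``; a missing required column is fatal.
    """
    if format != "tsv":
        raise ValueError(f"unsupported format {format!r}")
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "sample": str})
    missing = [c for c in TSV_COLUMNS[:7] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    for col in _OPTIONAL_COLUMNS:
        if col not in df.columns:
            df[col] = None
    out = RecordList()
    for row in df.itertuples(index=False):
        try:
            rec = MutationRecord(
                sample_id=str(row.sample),
                chrom=str(row.chrom),
                pos=int(row.pos),
                ref=str(row.ref).upper(),
                alt=str(row.alt).upper(),
                pentacontext=(
                    None
                    if pd.isna(row.pentacontext) or row.pentacontext == ""
                    else str(row.pentacontext).upper()
                ),
                strand_status=str(row.strand_status),
                ccf=_parse_optional(row.ccf, float),
                multiplicity=_parse_optional(row.multiplicity, int),
                major_cn=_parse_optional(row.major_cn, int),
                minor_cn=_parse_optional(row.minor_cn, int),
            )
            rec.validate()
        except (RecordError, ValueError, TypeError) as err:
            reason = err.reason if isinstance(err, RecordError) else "malformed_row"
            out.rejections[reason] += 1
            continue
        out.append(rec)
    if out.rejections:
        logger.warning("read_mutation_table skipped %d row(s): %s",
                       sum(out.rejections.values()), dict(out.rejections))
    return out


def read_vcf(path: str | Path, sample_id: str | None = None) -> RecordList:
    """Read PASS single-base substitutions from a (minimal) VCF.

    Multi-allelic rows are split into one record per alternate allele;
    indels and multi-nucleotide variants are skipped with a counted reason.
    ``sample_id`` overrides the VCF's sample name (required for sample-less
    VCFs).  Contexts are left unset; run `annotate_context` afterwards.
    """
    from cyvcf2 import VCF  # optional dependency, only needed for VCF input

    vcf = VCF(str(path))
    if sample_id is None:
        if len(vcf.samples) != 1:
            raise ValueError(
                f"{path}: sample_id required (VCF has {len(vcf.samples)} samples)"
            )
        sample_id = vcf.samples[0]
    out = RecordList()
    for variant in vcf:
        if variant.FILTER is not None:  # cyvcf2: None means PASS/'.'
            out.rejections["non_pass"] += 1
            continue
        for alt in variant.ALT:
            if len(variant.REF) != 1 or len(alt) != 1:
                out.rejections["not_sbs"] += 1
                continue
            if variant.REF not in "ACGT" or alt not in "ACGT":
                out.rejections["ambiguous_allele"] += 1
                continue
            out.append(
                MutationRecord(
                    sample_id=sample_id,
                    chrom=str(variant.CHROM),
                    pos=int(variant.POS),
                    ref=variant.REF,
                    alt=alt,
                )
            )
    return out


def annotate_context(
    records: Iterable[MutationRecord], genome_fasta: str | Path
) -> RecordList:
    """Fill in pentanucleotide contexts from a reference FASTA.

    The context is the uppercase reference slice [pos-2, pos+2] (1-based,
    closed).  A record whose existing context disagrees with the genome, whose
    reference allele mismatches, or whose position lies within two bases of a
    contig edge is rejected with a counted reason.
    """
    from pyfaidx import Fasta

    genome = Fasta(str(genome_fasta), rebuild=False)
    out = RecordList()
    for rec in records:
        if rec.chrom not in genome:
            out.rejections["unknown_contig"] += 1
            continue
        contig = genome[rec.chrom]
        if rec.pos < 3 or rec.pos > len(contig) - 2:
            out.rejections["contig_edge"] += 1
            continue
        ctx = str(contig[rec.pos - 3 : rec.pos + 2]).upper()
        if ctx[2] != rec.ref:
            out.rejections["context_ref_mismatch"] += 1
            continue
        if rec.pentacontext is not None and rec.pentacontext.upper() != ctx:
            out.rejections["context_disagreement"] += 1
            continue
        out.append(replace(rec, pentacontext=ctx))
    if out.rejections:
        logger.warning("annotate_context rejected %d record(s): %s",
                       sum(out.rejections.values()), dict(out.rejections))
    return out
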