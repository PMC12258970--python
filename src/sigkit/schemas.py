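"""Substitution classification schemas (SBS-96, SBS-288, SBS-1536).

Somatic single-base substitutions are conventionally reported relative to the
pyrimidine of the mutated Watson–Crick base pair, giving six substitution
types (C>A, C>G, C>T, T>A, T>C, T>G).  The SBS-96 schema refines each type by
the immediate 5' and 3' flanking bases; SBS-1536 extends the flanks to two
bases on each side; SBS-288 instead annotates each SBS-96 channel with the
transcriptional status of the locus (T: pyrimidine on the template strand,
U: pyrimidine on the coding strand, N: outside annotated genes).

Channel ordering is fixed so that matrix files are byte-reproducible:
substitution-type blocks in the order C>A, C>G, C>T, T>A, T>C, T>G, flanks
lexicographic within each block.  SBS-288 labels are grouped by strand prefix
(T:, U:, N:) outermost, each holding the 96 channels in standard order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

BASES = ("A", "C", "G", "T")
PYRIMIDINES = frozenset("CT")
PURINES = frozenset("AG")
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

SUBSTITUTION_TYPES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
STRAND_PREFIXES = ("T", "U", "N")

SCHEMA_NAMES = ("SBS96", "SBS288", "SBS1536")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (supports N)."""
    return "".join(COMPLEMENT[b] for b in reversed(seq.upper()))


def _sbs96_labels() -> list[str]:
    return [
        f"{five}[{sub}]{three}"
        for sub in SUBSTITUTION_TYPES
        for five in BASES
        for three in BASES
    ]


def _sbs288_labels() -> list[str]:
    base = _sbs96_labels()
    return [f"{p}:{lab}" for p in STRAND_PREFIXES for lab in base]


def _sbs1536_labels() -> list[str]:
    return [
        f"{f2}{f1}[{sub}]{t1}{t2}"
        for sub in SUBSTITUTION_TYPES
        for f2 in BASES
        for f1 in BASES
        for t1 in BASES
        for t2 in BASES
    ]


@dataclass(frozen=True)
class Schema:
    """A named channel schema with its fixed, ordered channel labels."""

    name: str
    channel_labels: tuple[str, ...] = field(repr=False)

    def __post_init__(self) -> None:
        expected = {"SBS96": 96, "SBS288": 288, "SBS1536": 1536}
        if self.name not in expected:
            raise ValueError(f"unknown schema name {self.name!r}")
        if len(self.channel_labels) != expected[self.name]:
            raise ValueError(
                f"{self.name} requires {expected[self.name]} labels, "
                f"got {len(self.channel_labels)}"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")

    @property
    def n_channels(self) -> int:
        return len(self.channel_labels)

    def __len__(self) -> int:  # pragma: no cover - convenience
        return self.n_channels


SBS96 = Schema("SBS96", tuple(_sbs96_labels()))
SBS288 = Schema("SBS288", tuple(_sbs288_labels()))
SBS1536 = Schema("SBS1536", tuple(_sbs1536_labels()))

_BY_NAME = {s.name: s for s in (SBS96, SBS288, SBS1536)}


def get_schema(name: str | Schema) -> Schema:
    """Look a schema up by name; passes `Schema` instances through."""
    if isinstance(name, Schema):
        return name
    try:
        return _BY_NAME[name.upper().replace("-", "")]
    except KeyError:
        raise ValueError(f"unknown schema {name!r}; expected one of {SCHEMA_NAMES}")


def collapse_label(label: str) -> str:
    """Map an SBS-288 or SBS-1536 channel label to its SBS-96 label.

    SBS-96 labels are returned unchanged.
    """
    if ":" in label:  # SBS-288 -> strip strand prefix
        return label.split(":", 1)[1]
    lo = label.index("[")
    if lo == 2:  # SBS-1536 -> keep inner flanks only
        return label[1:-1]
    return label
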