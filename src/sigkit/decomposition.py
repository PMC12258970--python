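"""Decomposition of de novo signatures into reference catalogs.

A de novo signature is expressed as a nonnegative mixture of known reference
signatures by forward selection: start from the single best-cosine reference,
repeatedly add the candidate that most improves the nonnegative-least-squares
reconstruction cosine, stop when the improvement falls below a threshold, and
finish with one removal pass dropping references whose removal barely hurts.
In the *optimized* mode, references carrying excluded subgroup tags (e.g.
ultraviolet or mismatch-repair-deficiency signatures in a cohort where those
aetiologies are implausible) are removed from the candidate set before
selection.  A signature whose best reconstruction stays below the novelty
threshold (cosine 0.90) is flagged novel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment, nnls

from .analysis import cosine_similarity
from .signatures import SignatureSet

NOVELTY_THRESHOLD = 0.90
RESEMBLANCE_THRESHOLD = 0.85  # cross-cohort "same signature" floor
DEFAULT_ADD_THRESHOLD = 0.01

SUBGROUP_TAGS = frozenset(
    {
        "artifact",
        "ultraviolet",
        "lymphoid",
        "mismatch_repair_deficiency",
        "polymerase_deficiency",
        "base_excision_repair_deficiency",
        "treatment",
        "clock_like",
        "none",
    }
)

#: the repair/treatment subgroups excluded when decomposing signatures from a
#: treatment-naive, repair-proficient cohort
REPAIR_PROFICIENT_EXCLUSIONS = frozenset(
    {
        "artifact",
        "ultraviolet",
        "lymphoid",
        "mismatch_repair_deficiency",
        "polymerase_deficiency",
        "base_excision_repair_deficiency",
        "treatment",
    }
)


@dataclass
class ReferenceCatalog:
    """An SBS-96 reference signature set with per-signature subgroup tags."""

    signatures: SignatureSet
    subgroup_tags: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        tagged = {}
        for name in self.signatures.names:
            tags = frozenset(self.subgroup_tags.get(name, {"none"}) or {"none"})
            unknown = tags - SUBGROUP_TAGS
            if unknown:
                raise ValueError(f"{name}: unknown subgroup tags {sorted(unknown)}")
            tagged[name] = tags
        self.subgroup_tags = tagged

    @property
    def names(self) -> list[str]:
        return self.signatures.names

    def excluding(self, excluded_subgroups: Iterable[str]) -> list[str]:
        """Names of references carrying none of the excluded tags."""
        excluded = set(excluded_subgroups)
        return [
            n for n in self.names if not (self.subgroup_tags[n] & excluded)
        ]

    def to_tsv(self, signatures_path: str | Path, tags_path: str | Path) -> None:
        self.signatures.to_tsv(signatures_path)
        pd.DataFrame(
            {
                "signature": self.names,
                "tags": [",".join(sorted(self.subgroup_tags[n])) for n in self.names],
            }
        ).to_csv(tags_path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, signatures_path: str | Path, tags_path: str | Path | None = None):
        sigs = SignatureSet.from_tsv(signatures_path)
        tags: dict[str, frozenset[str]] = {}
        if tags_path is not None:
            df = pd.read_csv(tags_path, sep="\t")
            for row in df.itertuples(index=False):
                tags[str(row.signature)] = frozenset(
                    t.strip() for t in str(row.tags).split(",") if t.strip()
                )
        return cls(sigs, tags)


def fit_weights(target, refs: SignatureSet | np.ndarray) -> np.ndarray:
    """Nonnegative least-squares weights of ``target`` on reference columns.

    Weights are renormalized to sum 1 (reported as mixture proportions).
    """
    t = np.asarray(target, dtype=float).ravel()
    if t.sum() <= 0:
        raise ValueError("target must have positive mass")
    R = refs.values() if isinstance(refs, SignatureSet) else np.asarray(refs, float)
    if R.ndim != 2 or R.shape[0] != t.size:
        raise ValueError("reference matrix shape mismatch")
    w, _ = nnls(R, t)
    s = w.sum()
    if s == 0:
        return w
    return w / s


def _recon_cosine(target: np.ndarray, R: np.ndarray) -> tuple[float, np.ndarray]:
    w, _ = nnls(R, target)
    recon = R @ w
    if recon.sum() == 0 or np.linalg.norm(recon) == 0:
        return 0.0, w
    return cosine_similarity(target, recon), w


@dataclass
class DecompositionResult:
    """Mixture of references explaining one target signature."""

    target_name: str
    weights: pd.Series  # over all catalog references; unselected = 0
    reconstruction_cosine: float
    novel: bool
    mode: str
    excluded_subgroups: frozenset[str] = frozenset()
    selection_trace: list = field(default_factory=list, repr=False)

    @property
    def selected(self) -> pd.Series:
        sel = self.weights[self.weights > 0].sort_values(ascending=False)
        return sel

    def summary(self) -> str:
        parts = ", ".join(
            f"{name} ({100 * w:.1f}%)" for name, w in self.selected.items()
        )
        flag = "NOVEL" if self.novel else "known"
        return (
            f"{self.target_name} [{self.mode}]: {parts or '(none)'}; "
            f"reconstruction cosine {self.reconstruction_cosine:.3f} ({flag})"
        )

    def to_frame(self) -> pd.DataFrame:
        sel = self.selected
        return pd.DataFrame(
            {
                "target": self.target_name,
                "mode": self.mode,
                "reference": sel.index,
                "weight_percent": 100 * sel.to_numpy(),
                "reconstruction_cosine": self.reconstruction_cosine,
                "novel": self.novel,
            }
        )


def decompose_signature(
    target,
    catalog: ReferenceCatalog,
    mode: str = "naive",
    excluded_subgroups: Iterable[str] = (),
    add_threshold: float = DEFAULT_ADD_THRESHOLD,
    novelty_threshold: float = NOVELTY_THRESHOLD,
    target_name: str = "target",
) -> DecompositionResult:
    """Decompose a 96-channel signature into the reference catalog.

    ``mode='naive'`` uses the full catalog; ``mode='optimized'`` first drops
    every reference carrying any tag in ``excluded_subgroups`` (which must be
    non-empty in that mode).  Forward selection adds the reference giving the
    largest reconstruction-cosine increase while the increase is at least
    ``add_threshold``; a final backward pass removes references whose removal
    costs less than ``add_threshold``.  The reconstruction cosine never
    decreases during forward selection (asserted).
    """
    if mode not in ("naive", "optimized"):
        raise ValueError(f"unknown mode {mode!r}")
    excluded = frozenset(excluded_subgroups)
    if mode == "optimized" and not excluded:
        raise ValueError("optimized mode requires a non-empty exclusion list")
    candidates = catalog.excluding(excluded) if mode == "optimized" else list(
        catalog.names
    )
    if not candidates:
        raise ValueError(
            f"no candidate references remain after excluding {sorted(excluded)}"
        )
    t = np.asarray(
        target if not isinstance(target, pd.Series) else target.to_numpy(),
        dtype=float,
    ).ravel()
    if t.sum() <= 0:
        raise ValueError("target must have positive mass")
    profiles = catalog.signatures.profiles
    cols = {n: profiles[n].to_numpy() for n in candidates}

    selected: list[str] = []
    trace: list[tuple[str, str, float]] = []
    # start from the single best-cosine reference
    best0 = max(candidates, key=lambda n: cosine_similarity(t, cols[n]))
    selected.append(best0)
    current, _ = _recon_cosine(t, np.column_stack([cols[n] for n in selected]))
    trace.append(("add", best0, current))
    while True:
        remaining = [n for n in candidates if n not in selected]
        if not remaining:
            break
        gains = []
        for n in remaining:
            cos, _ = _recon_cosine(
                t, np.column_stack([cols[m] for m in selected + [n]])
            )
            gains.append((cos, n))
        best_cos, best_name = max(gains)
        if best_cos - current < add_threshold:
            break
        assert best_cos >= current - 1e-12, "forward selection decreased cosine"
        selected.append(best_name)
        current = best_cos
        trace.append(("add", best_name, current))
    # one removal pass: drop anything whose removal barely hurts
    for n in list(selected):
        if len(selected) == 1:
            break
        rest = [m for m in selected if m != n]
        cos, _ = _recon_cosine(t, np.column_stack([cols[m] for m in rest]))
        if current - cos < add_threshold:
            selected = rest
            current = cos
            trace.append(("remove", n, current))
    final_cos, w = _recon_cosine(t, np.column_stack([cols[m] for m in selected]))
    weights = pd.Series(0.0, index=catalog.names)
    if w.sum() > 0:
        weights[selected] = w / w.sum()
    return DecompositionResult(
        target_name=target_name,
        weights=weights,
        reconstruction_cosine=final_cos,
        novel=final_cos < novelty_threshold,
        mode=mode,
        excluded_subgroups=excluded,
        selection_trace=trace,
    )


@dataclass
class SignatureMatch:
    """Optimal one-to-one pairing between two signature sets."""

    pairs: list[tuple[str, str]]
    cosines: list[float]

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "a": [p[0] for p in self.pairs],
                "b": [p[1] for p in self.pairs],
                "cosine": self.cosines,
            }
        )


def match_signatures(set_a: SignatureSet, set_b: SignatureSet) -> SignatureMatch:
    """Maximum-total-cosine one-to-one assignment between two signature sets.

    Sets on different schemas are collapsed to SBS-96 first.  When the sets
    have unequal sizes, the smaller side is fully matched.
    """
    a = set_a.collapse() if set_a.schema.name != set_b.schema.name else set_a
    b = set_b.collapse() if set_a.schema.name != set_b.schema.name else set_b
    A, B = a.values(), b.values()
    cos = np.zeros((A.shape[1], B.shape[1]))
    for i in range(A.shape[1]):
        for j in range(B.shape[1]):
            cos[i, j] = cosine_similarity(A[:, i], B[:, j])
    rows, cols = linear_sum_assignment(-cos)
    pairs = [(a.names[i], b.names[j]) for i, j in zip(rows, cols)]
    return SignatureMatch(
        pairs=pairs, cosines=[float(cos[i, j]) for i, j in zip(rows, cols)]
    )
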