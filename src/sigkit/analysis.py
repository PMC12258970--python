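"""Comparison and association statistics.

Cosine similarity is the field's pervasive profile-comparison metric;
Spearman rank correlation complements it for sub-context comparisons, where
two profiles can share support (high cosine) yet rank their channels quite
differently.  Burden associations are fitted as log-linear normal models of
burden on a positivity indicator plus arbitrary covariates; the indicator
coefficient is exponentiated to a fold change, and batches of p-values are
adjusted by Benjamini–Hochberg.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .schemas import SUBSTITUTION_TYPES
from .signatures import SignatureSet


def cosine_similarity(a, b) -> float:
    """Cosine similarity dot(a,b)/(|a||b|); raises on a zero vector."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError(f"length mismatch {a.shape} vs {b.shape}")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(np.dot(a, b) / (na * nb))


def rank_correlation(a, b) -> float:
    """Spearman rho with average ranks for ties; NaN if either input is constant."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size < 3 or a.size != b.size:
        raise ValueError("rank correlation needs two equal-length vectors, n >= 3")
    if np.ptp(a) == 0.0 or np.ptp(b) == 0.0:
        return float("nan")
    return float(stats.spearmanr(a, b).statistic)


@dataclass
class SubcontextComparison:
    """Comparison of two signatures within one substitution-type block."""

    substitution_type: str
    cosine: float
    spearman_rho: float
    slice_a: np.ndarray
    slice_b: np.ndarray


def compare_subcontext(
    sig_a, sig_b, substitution_type: str, schema=None
) -> SubcontextComparison:
    """Compare two SBS-96 profiles on one substitution type's 16 channels.

    Each 16-channel slice is renormalized to sum 1 before computing cosine
    and Spearman rho, so the comparison reflects only the within-type shape.
    """
    if substitution_type not in SUBSTITUTION_TYPES:
        raise ValueError(f"unknown substitution type {substitution_type!r}")
    from .schemas import SBS96

    mask = np.array(
        [f"[{substitution_type}]" in lab for lab in SBS96.channel_labels]
    )
    a = np.asarray(sig_a, dtype=float).ravel()[mask]
    b = np.asarray(sig_b, dtype=float).ravel()[mask]
    if a.sum() <= 0 or b.sum() <= 0:
        raise ValueError(f"zero mass in the {substitution_type} block")
    a, b = a / a.sum(), b / b.sum()
    return SubcontextComparison(
        substitution_type=substitution_type,
        cosine=cosine_similarity(a, b),
        spearman_rho=rank_correlation(a, b),
        slice_a=a,
        slice_b=b,
    )


@dataclass
class AssociationResult:
    """Covariate-adjusted association of a binary status with a positive burden."""

    response_name: str
    fold_change: float
    coefficient: float
    std_err: float
    p_value: float
    n: int
    covariate_names: list[str] = field(default_factory=list)
    q_value: float = float("nan")

    def summary(self) -> str:
        lines = [
            f"burden association: {self.response_name} (n={self.n})",
            f"  status coefficient (log scale): {self.coefficient:+.4f} "
            f"(se {self.std_err:.4f})",
            f"  fold change: {self.fold_change:.3f}",
            f"  p-value: {self.p_value:.3g}",
        ]
        if not math.isnan(self.q_value):
            lines.append(f"  q-value: {self.q_value:.3g}")
        if self.covariate_names:
            lines.append(f"  covariates: {', '.join(self.covariate_names)}")
        return "\n".join(lines)


def _design_matrix(status, covariates: pd.DataFrame | None):
    cols = {"status": np.asarray(status, dtype=float)}
    names: list[str] = []
    if covariates is not None:
        enc = pd.get_dummies(covariates, drop_first=True, dtype=float)
        for c in enc.columns:
            cols[str(c)] = enc[c].to_numpy(dtype=float)
            names.append(str(c))
    X = pd.DataFrame(cols)
    return sm.add_constant(X, has_constant="add"), names


def burden_association(
    status,
    burden,
    covariates: pd.DataFrame | None = None,
    response_name: str = "burden",
) -> AssociationResult:
    """Fit log(burden) ~ status + covariates and report the status fold change.

    ``status`` is a boolean/0-1 indicator (e.g. signature positivity);
    ``burden`` must be strictly positive counts or rates.  Categorical
    covariates are one-hot encoded against a reference level; collinear
    columns are dropped by the pseudoinverse fit with a warning from
    statsmodels.  The returned fold change is exp(status coefficient).
    """
    status = np.asarray(status).astype(float)
    burden = np.asarray(burden, dtype=float)
    if np.any(burden <= 0):
        raise ValueError("burdens must be strictly positive for the log model")
    n = burden.size
    X, names = _design_matrix(status, covariates)
    if n <= X.shape[1] + 1:
        raise ValueError(f"n={n} too small for {X.shape[1]} model columns")
    fit = sm.OLS(np.log(burden), X).fit()
    coef = float(fit.params["status"])
    return AssociationResult(
        response_name=response_name,
        fold_change=float(np.exp(coef)),
        coefficient=coef,
        std_err=float(fit.bse["status"]),
        p_value=float(fit.pvalues["status"]),
        n=int(n),
        covariate_names=names,
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def attach_q_values(results: list[AssociationResult]) -> list[AssociationResult]:
    """Assign BH q-values across a batch of association results (in place)."""
    q = bh_adjust([r.p_value for r in results])
    for r, qv in zip(results, q):
        r.q_value = float(qv)
    return results


def plot_signature(signature, name: str = "", ax=None):
    """Bar plot of an SBS-96 profile, colour-coded by substitution type."""
    import matplotlib.pyplot as plt

    from .schemas import SBS96

    sig = np.asarray(signature, dtype=float).ravel()
    if ax is None:
        _, ax = plt.subplots(figsize=(12, 2.5))
    colors = {"C>A": "#03BCEE", "C>G": "#010101", "C>T": "#E32926",
              "T>A": "#CAC9C9", "T>C": "#A1CE63", "T>G": "#EBC6C4"}
    bar_colors = [
        colors[lab[2:5]] for lab in SBS96.channel_labels
    ]
    ax.bar(range(96), sig, color=bar_colors, width=0.8)
    ax.set_xlim(-1, 96)
    ax.set_xticks([])
    ax.set_ylabel("probability")
    if name:
        ax.set_title(name)
    return ax


def signature_cosine_table(set_a: SignatureSet, set_b: SignatureSet) -> pd.DataFrame:
    """All-pairs cosine similarities between two signature sets (rows = A)."""
    a, b = set_a.collapse(), set_b.collapse()
    table = pd.DataFrame(index=a.names, columns=b.names, dtype=float)
    for na in a.names:
        for nb in b.names:
            table.at[na, nb] = cosine_similarity(a[na], b[nb])
    return table
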