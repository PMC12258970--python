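"""De novo signature extraction by bootstrapped NMF with consensus clustering.

The extraction model follows the field's standard recipe: for each candidate
rank k, the catalog's columns are resampled multinomially (preserving each
sample's burden), every bootstrap replicate is factorized by
generalized-Kullback–Leibler NMF with multiplicative updates, the pooled
replicate signatures are partitioned into k clusters by iterated one-to-one
cosine matching, and each cluster's stability is summarized by its mean
silhouette under cosine distance.  The suggested rank is the largest k whose
solution is simultaneously stable (minimum per-signature stability above a
floor) and accurate (mean per-sample reconstruction cosine above a floor).

The generalized KL objective D(V || WH) = sum(V log(V/WH) - V + WH) is the
Poisson-consistent divergence for count catalogs; multiplicative updates
guarantee a monotonically non-increasing objective, which is asserted on the
tracked trace.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numba
import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .catalogs import MutationalMatrix
from .signatures import SignatureSet

logger = logging.getLogger(__name__)

_EPS = np.finfo(float).tiny

DEFAULT_N_REPLICATES = 30
DEFAULT_MAX_ITER = 10_000
DEFAULT_TOL = 1e-9
DEFAULT_STABILITY_FLOOR = 0.8
DEFAULT_RECON_FLOOR = 0.95


# --------------------------------------------------------------------------
# bootstrap


def bootstrap_catalog(
    matrix: MutationalMatrix, seed: int | np.random.Generator | None = None
) -> MutationalMatrix:
    """Resample each column multinomially, preserving its total exactly.

    Each sample's channel counts are redrawn with n = the column sum and
    p = the column's normalized profile.  All-zero columns are copied
    unchanged with a warning.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    counts = matrix.counts.to_numpy()
    out = np.empty_like(counts)
    for j in range(counts.shape[1]):
        total = counts[:, j].sum()
        if total == 0:
            logger.warning(
                "bootstrap_catalog: zero column %s copied unchanged",
                matrix.sample_ids[j],
            )
            out[:, j] = 0
            continue
        out[:, j] = rng.multinomial(total, counts[:, j] / total)
    return MutationalMatrix(
        matrix.schema,
        pd.DataFrame(out, index=matrix.counts.index, columns=matrix.counts.columns),
    )


# --------------------------------------------------------------------------
# NMF


@dataclass
class FactorPair:
    """One NMF solution: column-normalized signatures, scaled exposures."""

    signatures: np.ndarray  # channels x k, columns sum to 1
    exposures: np.ndarray  # k x samples
    objective_value: float
    objective_trace: np.ndarray = field(default=None, repr=False, compare=False)
    n_iter: int = 0

    @property
    def k(self) -> int:
        return self.signatures.shape[1]


def _gkl(V: np.ndarray, WH: np.ndarray) -> float:
    mask = V > 0
    div = np.sum(V[mask] * np.log(V[mask] / np.maximum(WH[mask], _EPS)))
    return float(div - V.sum() + WH.sum())


@numba.njit(cache=False, fastmath=True)
def _gkl_nb(V, W, H):  # pragma: no cover - exercised through nmf_factorize
    m, n = V.shape
    total = 0.0
    WH = W @ H
    for i in range(m):
        for j in range(n):
            wh = WH[i, j]
            if wh < 1e-300:
                wh = 1e-300
            v = V[i, j]
            if v > 0.0:
                total += v * np.log(v / wh) - v + wh
            else:
                total += wh
    return total


@numba.njit(cache=False, fastmath=True)
def _mu_updates(V, W, H, n_iter, tol, check_every):
    """Multiplicative KL updates in place; returns (trace, iterations run).

    The objective is evaluated every ``check_every`` iterations; the loop
    stops early when its relative decrease falls below ``tol`` (tol < 0
    disables the check, used for fixed-length burn-in).
    """
    m, n = V.shape
    k = W.shape[1]
    trace = np.empty(n_iter // check_every + 2)
    n_trace = 0
    prev = 0.0
    have_prev = False
    it = 0
    Q = np.empty((m, n))
    for it in range(1, n_iter + 1):
        WH = W @ H
        for i in range(m):
            for j in range(n):
                wh = WH[i, j]
                Q[i, j] = V[i, j] / (wh if wh > 1e-300 else 1e-300)
        # W update: W *= (Q @ H.T) / row-broadcast(H @ 1)
        hsum = np.sum(H, axis=1)
        QHt = Q @ H.T
        for i in range(m):
            for c in range(k):
                d = hsum[c]
                W[i, c] *= QHt[i, c] / (d if d > 1e-300 else 1e-300)
        WH = W @ H
        for i in range(m):
            for j in range(n):
                wh = WH[i, j]
                Q[i, j] = V[i, j] / (wh if wh > 1e-300 else 1e-300)
        wsum = np.sum(W, axis=0)
        WtQ = W.T @ Q
        for c in range(k):
            d = wsum[c]
            if d < 1e-300:
                d = 1e-300
            for j in range(n):
                H[c, j] *= WtQ[c, j] / d
        if it % check_every == 0 or it == 1:
            obj = _gkl_nb(V, W, H)
            trace[n_trace] = obj
            n_trace += 1
            if tol >= 0.0 and have_prev:
                ref = abs(prev)
                if ref < 1.0:
                    ref = 1.0
                if prev - obj <= tol * ref:
                    prev = obj
                    break
            prev = obj
            have_prev = True
    return trace[:n_trace], it


DEFAULT_N_INITS = 5
_BURN_IN = 200


def nmf_factorize(
    matrix,
    k: int,
    seed: int | np.random.Generator | None = None,
    max_iter: int = DEFAULT_MAX_ITER,
    tol: float = DEFAULT_TOL,
    n_inits: int = DEFAULT_N_INITS,
) -> FactorPair:
    """Factorize a nonnegative matrix as W·H by generalized-KL NMF.

    Multiplicative updates from random uniform(0, 1] initializations scaled
    to the matrix mass.  ``n_inits`` starts are burned in for a short fixed
    number of iterations and the best-objective one is run to convergence
    (multi-start guards against the poor local optima that a single random
    start of KL-NMF is prone to).  Stops when the relative objective change
    over ten iterations drops below ``tol`` or at ``max_iter``.  The
    returned signatures are column-normalized (scale moved into exposures).
    """
    V = (
        matrix.counts.to_numpy(dtype=float)
        if isinstance(matrix, MutationalMatrix)
        else np.asarray(matrix, dtype=float)
    )
    if (V < 0).any():
        raise ValueError("NMF input must be nonnegative")
    m, n = V.shape
    if k < 1 or k > min(m, n):
        raise ValueError(f"k={k} outside [1, min(channels, samples)={min(m, n)}]")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    V = np.ascontiguousarray(V)
    scale = np.sqrt(V.mean() / k)
    best = None
    burn_total = 0
    for _ in range(max(1, n_inits)):
        W = scale * (1.0 - rng.random((m, k)))  # uniform (0, 1]
        H = scale * (1.0 - rng.random((k, n)))
        burn = min(_BURN_IN, max_iter)
        _, it = _mu_updates(V, W, H, burn, -1.0, burn)
        burn_total += it
        obj = _gkl(V, np.maximum(W @ H, _EPS))
        if best is None or obj < best[0]:
            best = (obj, W, H)
    _, W, H = best
    trace, it = _mu_updates(V, W, H, max(0, max_iter - _BURN_IN), tol, 10)
    col = W.sum(axis=0)
    col[col == 0] = 1.0
    W = W / col
    H = H * col[:, None]
    return FactorPair(
        signatures=W,
        exposures=H,
        objective_value=float(trace[-1]) if len(trace) else _gkl(
            V, np.maximum(W @ H, _EPS)
        ),
        objective_trace=np.asarray(trace),
        n_iter=it + _BURN_IN,
    )


# --------------------------------------------------------------------------
# consensus clustering of replicate solutions


def _cosine_matrix(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    An = A / np.maximum(np.linalg.norm(A, axis=0, keepdims=True), _EPS)
    Bn = B / np.maximum(np.linalg.norm(B, axis=0, keepdims=True), _EPS)
    return An.T @ Bn


def _greedy_match(cos: np.ndarray) -> np.ndarray:
    """Greedy one-to-one assignment, highest-cosine pair first.

    Returns ``assign`` with ``assign[row] = column``.  Exact ties break on
    (row, column) order, keeping the procedure deterministic.
    """
    k = cos.shape[0]
    assign = np.full(k, -1)
    used_r = np.zeros(k, dtype=bool)
    used_c = np.zeros(k, dtype=bool)
    flat = [(-cos[r, c], r, c) for r in range(k) for c in range(k)]
    flat.sort()
    for _, r, c in flat:
        if not used_r[r] and not used_c[c]:
            assign[r] = c
            used_r[r] = True
            used_c[c] = True
    return assign


@dataclass
class ConsensusSolution:
    """Consensus signatures at one rank with per-cluster stability."""

    k: int
    consensus_signatures: SignatureSet
    per_signature_stability: np.ndarray
    mean_reconstruction_cosine: float
    replicate_count: int
    exposures: pd.DataFrame | None = None

    @property
    def min_stability(self) -> float:
        return float(np.min(self.per_signature_stability))


def cluster_solutions(
    replicate_factors: list[FactorPair],
    k: int,
    schema="SBS96",
    max_rounds: int = 100,
) -> ConsensusSolution:
    """Partition pooled replicate signatures into k clusters by iterated matching.

    Each replicate's k signatures are greedily matched one-to-one to the
    current centroids under cosine similarity; centroids are recomputed as
    normalized cluster means until assignments stabilize.  Per-cluster
    stability is the mean silhouette of its members under cosine distance
    (defined as the mean member-to-centroid cosine when k = 1, where the
    silhouette has no "other cluster").  Fewer than two replicates leave the
    stability undefined (NaN).
    """
    if not replicate_factors:
        raise ValueError("no replicate factorizations supplied")
    if any(f.k != k for f in replicate_factors):
        raise ValueError("all replicates must have the same rank k")
    R = len(replicate_factors)
    centroids = replicate_factors[0].signatures.copy()
    assignments = np.zeros((R, k), dtype=int)
    for _ in range(max_rounds):
        changed = False
        for r, fac in enumerate(replicate_factors):
            cos = _cosine_matrix(fac.signatures, centroids)
            assign = _greedy_match(cos)
            if not np.array_equal(assign, assignments[r]):
                changed = True
                assignments[r] = assign
        new_centroids = np.zeros_like(centroids)
        for c in range(k):
            members = [
                replicate_factors[r].signatures[:, s]
                for r in range(R)
                for s in range(k)
                if assignments[r, s] == c
            ]
            mean = np.mean(members, axis=0)
            total = mean.sum()
            new_centroids[:, c] = mean / total if total > 0 else mean
        centroids = new_centroids
        if not changed:
            break
    # silhouette under cosine distance
    members_of = {c: [] for c in range(k)}
    for r in range(R):
        for s in range(k):
            members_of[assignments[r, s]].append(replicate_factors[r].signatures[:, s])
    stability = np.empty(k)
    if R < 2:
        stability[:] = np.nan
        logger.warning("cluster_solutions: <2 replicates, stability undefined")
    elif k == 1:
        mem = np.column_stack(members_of[0])
        stability[0] = float(np.mean(_cosine_matrix(mem, centroids[:, :1])))
    else:
        pooled = [
            (c, v) for c in range(k) for v in members_of[c]
        ]
        X = np.column_stack([v for _, v in pooled])
        labels = np.array([c for c, _ in pooled])
        D = 1.0 - _cosine_matrix(X, X)
        sil = np.empty(len(pooled))
        for i in range(len(pooled)):
            own = labels == labels[i]
            own[i] = False
            a = D[i, own].mean() if own.any() else 0.0
            b = min(
                D[i, labels == c].mean() for c in range(k) if c != labels[i]
            )
            denom = max(a, b)
            sil[i] = 0.0 if denom == 0 else (b - a) / denom
        for c in range(k):
            stability[c] = float(sil[labels == c].mean())
    consensus = SignatureSet.from_array(
        centroids / centroids.sum(axis=0, keepdims=True),
        names=[f"DENOVO_{chr(ord('A') + c)}" for c in range(k)],
        schema=schema,
    )
    return ConsensusSolution(
        k=k,
        consensus_signatures=consensus,
        per_signature_stability=stability,
        mean_reconstruction_cosine=float("nan"),
        replicate_count=R,
    )


def _nnls_refit(V: np.ndarray, S: np.ndarray) -> np.ndarray:
    """Column-wise nonnegative least-squares refit of V on signatures S."""
    H = np.zeros((S.shape[1], V.shape[1]))
    for j in range(V.shape[1]):
        H[:, j], _ = nnls(S, V[:, j])
    return H


def reconstruction_cosine(matrix, signatures: SignatureSet) -> tuple[float, np.ndarray]:
    """Mean (and per-sample) cosine between columns and their NNLS reconstruction."""
    V = (
        matrix.counts.to_numpy(dtype=float)
        if isinstance(matrix, MutationalMatrix)
        else np.asarray(matrix, dtype=float)
    )
    S = signatures.values()
    H = _nnls_refit(V, S)
    recon = S @ H
    per = np.empty(V.shape[1])
    for j in range(V.shape[1]):
        nv, nr = np.linalg.norm(V[:, j]), np.linalg.norm(recon[:, j])
        per[j] = 0.0 if nv == 0 or nr == 0 else float(V[:, j] @ recon[:, j] / (nv * nr))
    return float(per.mean()), per


# --------------------------------------------------------------------------
# the extraction model


@dataclass
class ExtractionResult:
    """Extraction results across ranks, with the suggested solution."""

    solutions: dict[int, ConsensusSolution]
    suggested_k: int
    seed: int | None
    stability_floor: float
    recon_floor: float

    @property
    def suggested(self) -> ConsensusSolution:
        return self.solutions[self.suggested_k]

    def metrics(self) -> pd.DataFrame:
        rows = []
        for k in sorted(self.solutions):
            sol = self.solutions[k]
            rows.append(
                {
                    "k": k,
                    "min_stability": sol.min_stability,
                    "mean_stability": float(np.mean(sol.per_signature_stability)),
                    "mean_reconstruction_cosine": sol.mean_reconstruction_cosine,
                    "suggested": k == self.suggested_k,
                }
            )
        return pd.DataFrame(rows).set_index("k")

    def summary(self) -> str:
        lines = [
            "De novo signature extraction",
            f"  replicates per rank: {next(iter(self.solutions.values())).replicate_count}",
            f"  rank selection: largest k with min stability >= "
            f"{self.stability_floor} and mean reconstruction cosine >= "
            f"{self.recon_floor}",
            "",
            self.metrics().to_string(float_format=lambda x: f"{x:.4f}"),
            "",
            f"  suggested k = {self.suggested_k}",
        ]
        return "\n".join(lines)


class SignatureExtraction:
    """De novo extraction model over a mutational catalog.

    Parameters
    ----------
    matrix : MutationalMatrix
        Channels x samples count catalog (any schema; extraction is native
        to the input schema).
    k_range : iterable of int
        Candidate ranks.
    n_replicates : int
        Bootstrap replicates per rank.
    stability_floor, recon_floor : float
        Admissibility floors for the suggested rank.
    """

    def __init__(
        self,
        matrix: MutationalMatrix,
        k_range=(2, 3, 4, 5, 6),
        n_replicates: int = DEFAULT_N_REPLICATES,
        max_iter: int = DEFAULT_MAX_ITER,
        tol: float = DEFAULT_TOL,
        stability_floor: float = DEFAULT_STABILITY_FLOOR,
        recon_floor: float = DEFAULT_RECON_FLOOR,
    ):
        self.matrix = matrix
        self.k_range = sorted(set(int(k) for k in k_range))
        if not self.k_range:
            raise ValueError("k_range must be non-empty")
        if n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")
        self.n_replicates = n_replicates
        self.max_iter = max_iter
        self.tol = tol
        self.stability_floor = stability_floor
        self.recon_floor = recon_floor

    def fit(self, seed: int | None = None) -> ExtractionResult:
        rng = np.random.default_rng(seed)
        V = self.matrix.counts.to_numpy(dtype=float)
        solutions: dict[int, ConsensusSolution] = {}
        for k in self.k_range:
            replicates = []
            for _ in range(self.n_replicates):
                boot = bootstrap_catalog(self.matrix, rng)
                replicates.append(
                    nmf_factorize(boot, k, rng, self.max_iter, self.tol)
                )
            sol = cluster_solutions(replicates, k, schema=self.matrix.schema)
            mean_cos, _ = reconstruction_cosine(V, sol.consensus_signatures)
            sol.mean_reconstruction_cosine = mean_cos
            H = _nnls_refit(V, sol.consensus_signatures.values())
            sol.exposures = pd.DataFrame(
                H, index=sol.consensus_signatures.names,
                columns=self.matrix.sample_ids,
            )
            solutions[k] = sol
            logger.info(
                "k=%d: min stability %.3f, mean reconstruction cosine %.4f",
                k, sol.min_stability, mean_cos,
            )
        admissible = [
            k
            for k, sol in solutions.items()
            if sol.min_stability >= self.stability_floor
            and sol.mean_reconstruction_cosine >= self.recon_floor
        ]
        if admissible:
            suggested = max(admissible)
        else:
            warnings.warn(
                "no rank met the stability/reconstruction floors; falling back "
                "to argmax(min stability + mean reconstruction cosine)"
            )
            suggested = max(
                solutions,
                key=lambda k: solutions[k].min_stability
                + solutions[k].mean_reconstruction_cosine,
            )
        return ExtractionResult(
            solutions=solutions,
            suggested_k=suggested,
            seed=seed,
            stability_floor=self.stability_floor,
            recon_floor=self.recon_floor,
        )


def extract(
    matrix: MutationalMatrix,
    k_range=(2, 3, 4, 5, 6),
    n_replicates: int = DEFAULT_N_REPLICATES,
    seed: int | None = None,
    **kwargs,
) -> ExtractionResult:
    """Functional wrapper: build a `SignatureExtraction` model and fit it."""
    return SignatureExtraction(
        matrix, k_range=k_range, n_replicates=n_replicates, **kwargs
    ).fit(seed=seed)
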