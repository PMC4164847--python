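"""The improved-FAHP calculus on complementary three-scale matrices.

Pipeline for one node of the hierarchy, given a panel of expert scores over
its n children:

1. :func:`aggregate_scores` — plurality vote per pair gives the fuzzy
   judgment matrix F, with f_ii = 0.5 and f_ij + f_ji = 1.
2. :func:`to_consistent` — row sums r_i = sum_j f_ij and the transform
   r_ij = (r_i - r_j)/(2n) + 0.5 yield a fuzzy *consistent* matrix R, which
   satisfies the additive identity r_ij = r_ik - r_jk + 0.5 for every
   triple by construction, so no separate consistency check is needed.
3. :func:`weights_normalizing` / :func:`weights_sqrt` — a first priority
   vector from row sums or row geometric means of R.
4. :func:`to_reciprocal` — e_ij = r_ij / r_ji gives a positive reciprocal
   matrix E whose principal eigenvector refines the priorities.
5. :func:`power_iterate` — power iteration on E, seeded with the
   normalizing-method vector so that only a handful of iterations are
   needed; returns the sum-normalized ranking vector and the dominant
   eigenvalue estimate lambda_max (the infinity norm of the final
   unnormalized iterate).

All arithmetic is carried out in full double precision; nothing is rounded
internally.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Literal

import numpy as np
import numpy.typing as npt

from .errors import ConvergenceError, DegenerateMatrixError, ValidationError
from .hierarchy import SCALE, ExpertPanel

Method = Literal["normalizing", "sqrt", "iterative"]


def _as_square(a: npt.ArrayLike, name: str) -> np.ndarray:
    arr = np.asarray(a, dtype=float)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ValidationError(f"{name} must be square, got shape {arr.shape}")
    return arr


@dataclass(frozen=True)
class FuzzyJudgmentMatrix:
    """Complementary judgment matrix F with entries on {0, 0.5, 1}."""

    f: np.ndarray

    def __post_init__(self) -> None:
        arr = _as_square(self.f, "F")
        object.__setattr__(self, "f", arr)
        if not np.isin(arr, SCALE).all():
            raise ValidationError("F entries must lie on the scale {0, 0.5, 1}")
        if not np.allclose(np.diag(arr), 0.5):
            raise ValidationError("F must have 0.5 on the diagonal")
        if not np.allclose(arr + arr.T, 1.0):
            raise ValidationError("F must be complementary: f_ij + f_ji = 1")

    @property
    def n(self) -> int:
        return self.f.shape[0]

    def row_sums(self) -> np.ndarray:
        return self.f.sum(axis=1)


@dataclass(frozen=True)
class FuzzyConsistentMatrix:
    """Additively consistent complementary matrix R derived from F.

    ``row_sums`` carries the r_i of the source judgment matrix so that the
    provenance of each entry r_ij = (r_i - r_j)/(2n) + 0.5 stays inspectable.
    """

    r: np.ndarray
    row_sums: np.ndarray

    def __post_init__(self) -> None:
        arr = _as_square(self.r, "R")
        object.__setattr__(self, "r", arr)
        object.__setattr__(self, "row_sums", np.asarray(self.row_sums, float))
        if not np.allclose(np.diag(arr), 0.5, atol=1e-12):
            raise ValidationError("R must have 0.5 on the diagonal")
        if not np.allclose(arr + arr.T, 1.0, atol=1e-12):
            raise ValidationError("R must be complementary")

    @property
    def n(self) -> int:
        return self.r.shape[0]


@dataclass(frozen=True)
class ReciprocalMatrix:
    """Positive matrix E with e_ij * e_ji = 1 and unit diagonal."""

    e: np.ndarray

    def __post_init__(self) -> None:
        arr = _as_square(self.e, "E")
        object.__setattr__(self, "e", arr)
        if (arr <= 0).any():
            raise ValidationError("E entries must be strictly positive")
        if not np.allclose(arr * arr.T, 1.0, atol=1e-9):
            raise ValidationError("E must be reciprocal: e_ij * e_ji = 1")

    @property
    def n(self) -> int:
        return self.e.shape[0]


@dataclass(frozen=True)
class WeightVector:
    """A priority vector over a node's children (positive, sums to one).

    ``lambda_max`` and ``iterations`` are filled only by the iterative
    method.
    """

    w: np.ndarray
    method: Method
    lambda_max: float | None = None
    iterations: int | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.w, dtype=float)
        object.__setattr__(self, "w", arr)
        if (arr <= 0).any():
            raise ValidationError("weights must be strictly positive")
        if abs(arr.sum() - 1.0) > 1e-9:
            raise ValidationError(f"weights sum to {arr.sum()!r}, not 1")

    def __len__(self) -> int:
        return len(self.w)


def aggregate_scores(panel: ExpertPanel) -> FuzzyJudgmentMatrix:
    """Aggregate a panel's pairwise scores into a judgment matrix F.

    For each pair, the score chosen by the most experts wins (plurality).
    When no single score has a strict plurality the pair is recorded as
    equal importance (0.5) — the only tie-break that treats the two
    children symmetrically.  The lower triangle is filled by
    complementarity, f_ji = 1 - f_ij.
    """
    n = panel.n
    f = np.full((n, n), 0.5)
    index = {cid: k for k, cid in enumerate(panel.children)}
    for (ci, cj), votes in panel.scores.items():
        if not votes:
            raise ValidationError(f"pair ({ci}, {cj}): empty score list")
        counts = Counter(votes)
        top = counts.most_common()
        if len(top) > 1 and top[0][1] == top[1][1]:
            winner = 0.5
        else:
            winner = top[0][0]
        i, j = index[ci], index[cj]
        f[i, j] = winner
        f[j, i] = 1.0 - winner
    return FuzzyJudgmentMatrix(f)


def to_consistent(judgment: FuzzyJudgmentMatrix) -> FuzzyConsistentMatrix:
    """Transform F into the fuzzy consistent matrix R.

    With row sums r_i = sum_j f_ij, the entry is
    r_ij = (r_i - r_j) / (2n) + 0.5.  The result is complementary and
    additively consistent for every triple (i, j, k) by construction.
    """
    r_i = judgment.row_sums()
    n = judgment.n
    r = (r_i[:, None] - r_i[None, :]) / (2 * n) + 0.5
    return FuzzyConsistentMatrix(r=r, row_sums=r_i)


def weights_normalizing(consistent: FuzzyConsistentMatrix) -> WeightVector:
    """Row-normalizing priority vector: w_i = (row sum of R) / (grand sum)."""
    sums = consistent.r.sum(axis=1)
    return WeightVector(w=sums / sums.sum(), method="normalizing")


def weights_sqrt(consistent: FuzzyConsistentMatrix) -> WeightVector:
    """Square-root (row geometric mean) priority vector.

    w_i is proportional to the n-th root of the product of row i's entries.
    Undefined when any entry is zero, which happens when one child's
    judgment-matrix row sum exceeds another's by n or more (unanimous
    extremes on a small matrix).
    """
    r = consistent.r
    if (r <= 0).any():
        bad = tuple(zip(*np.nonzero(r <= 0)))
        raise DegenerateMatrixError(
            f"geometric mean undefined: zero entries at positions {bad}"
        )
    gm = np.prod(r, axis=1) ** (1.0 / consistent.n)
    return WeightVector(w=gm / gm.sum(), method="sqrt")


def to_reciprocal(consistent: FuzzyConsistentMatrix) -> ReciprocalMatrix:
    """Convert R to the positive reciprocal matrix E via e_ij = r_ij / r_ji."""
    r = consistent.r
    off = ~np.eye(consistent.n, dtype=bool)
    extreme = off & ((r <= 0.0) | (r >= 1.0))
    if extreme.any():
        pairs = tuple(zip(*np.nonzero(extreme)))
        raise DegenerateMatrixError(
            f"reciprocal transform undefined: r_ij in {{0, 1}} at {pairs}"
        )
    return ReciprocalMatrix(e=r / r.T)


def power_iterate(
    reciprocal: ReciprocalMatrix,
    seed: WeightVector | npt.ArrayLike,
    tol: float = 1e-4,
    max_iter: int = 100,
) -> WeightVector:
    """Refine a priority vector by power iteration on E.

    Iterates V <- E @ Y with Y = V / ||V||_inf, starting from ``seed``, and
    stops when successive normalized iterates Y differ by less than ``tol``
    in the infinity norm.  Returns the final V normalized to sum one, with
    ``lambda_max = ||V||_inf`` (>= n for any reciprocal matrix, by the
    Perron bound) and the iteration count.
    """
    v0 = seed.w if isinstance(seed, WeightVector) else np.asarray(seed, float)
    if v0.shape != (reciprocal.n,):
        raise ValidationError(
            f"seed length {v0.shape} does not match matrix order {reciprocal.n}"
        )
    if (v0 <= 0).any():
        raise ValidationError("seed vector must be strictly positive")

    e = reciprocal.e
    y = v0 / np.abs(v0).max()
    residual = float("inf")
    for iteration in range(1, max_iter + 1):
        v = e @ y
        y_next = v / np.abs(v).max()
        residual = np.abs(y_next - y).max()
        if residual < tol:
            return WeightVector(
                w=v / v.sum(),
                method="iterative",
                lambda_max=float(np.abs(v).max()),
                iterations=iteration,
            )
        y = y_next
    raise ConvergenceError(
        f"no convergence in {max_iter} iterations (last residual {residual:.3e})"
    )


def node_weights(
    panel: ExpertPanel,
    method: Method = "iterative",
    tol: float = 1e-4,
    max_iter: int = 100,
) -> WeightVector:
    """Full per-node pipeline from raw expert scores to a priority vector.

    ``iterative`` runs aggregate -> consistent -> reciprocal -> power
    iteration seeded with the normalizing-method vector; ``normalizing``
    and ``sqrt`` stop after the corresponding direct method.
    """
    consistent = to_consistent(aggregate_scores(panel))
    if method == "normalizing":
        return weights_normalizing(consistent)
    if method == "sqrt":
        return weights_sqrt(consistent)
    if method == "iterative":
        seed = weights_normalizing(consistent)
        return power_iterate(to_reciprocal(consistent), seed, tol=tol,
                             max_iter=max_iter)
    raise ValidationError(f"unknown method {method!r}")
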