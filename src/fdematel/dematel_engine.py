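"""The fuzzy DEMATEL computation: from linguistic ratings to cause/effect.

The method proceeds in stages:

1. Each expert's pairwise linguistic ratings become an initial
   direct-relation fuzzy matrix Z (zero diagonal, TFN cells).
2. Z is normalized by r = max row sum of the upper-bound component, so the
   geometric series of the normalized matrix converges.
3. Normalized matrices are averaged componentwise across the panel.
4. The total-relation fuzzy matrix is T_C = C (I - C)^{-1} for each
   component C in {L, M, U}, i.e. the limit of C + C^2 + ... capturing
   direct plus all indirect influence paths.
5. T is defuzzified cellwise by BNP to a crisp matrix T'.
6. Row sums D (influence dispatched) and column sums R (influence
   received) give prominence D+R and relation D-R; positive relation marks
   a net driver ("cause"), non-positive a net receiver ("effect").
   Criteria are ranked by prominence, descending.

All intermediate arithmetic is double precision; rounding happens only at
display time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np

from .fuzzy_core import LinguisticScale, TriangularFuzzyNumber, bnp

__all__ = [
    "FuzzyMatrix",
    "DematelResult",
    "initial_matrix",
    "normalization_factor",
    "normalize",
    "average_panel",
    "total_relation",
    "defuzzify_matrix",
    "prominence_relation",
    "classify_and_rank",
    "ranking_by_prominence",
    "run_pipeline",
]

Stage = Literal["initial", "normalized", "averaged", "total"]

#: Condition-number ceiling for the (I - C) solves; beyond this the
#: inversion is treated as numerically singular.
CONDITION_LIMIT = 1e12

_HOLLOW_STAGES = ("initial", "normalized", "averaged")


@dataclass(frozen=True)
class FuzzyMatrix:
    """Three aligned real matrices holding the L/M/U components of a fuzzy matrix."""

    L: np.ndarray
    M: np.ndarray
    U: np.ndarray
    stage: Stage = "initial"

    def __post_init__(self) -> None:
        L = np.asarray(self.L, dtype=float)
        M = np.asarray(self.M, dtype=float)
        U = np.asarray(self.U, dtype=float)
        object.__setattr__(self, "L", L)
        object.__setattr__(self, "M", M)
        object.__setattr__(self, "U", U)
        if not (L.shape == M.shape == U.shape):
            raise ValueError("L, M, U components must share one shape")
        if L.ndim != 2 or L.shape[0] != L.shape[1]:
            raise ValueError(f"fuzzy matrix must be square, got shape {L.shape}")
        if not (np.isfinite(L).all() and np.isfinite(M).all() and np.isfinite(U).all()):
            raise ValueError("fuzzy matrix components must be finite")
        if (L < 0).any():
            raise ValueError("fuzzy matrix entries must be non-negative")
        if not ((L <= M + 1e-12).all() and (M <= U + 1e-12).all()):
            raise ValueError("components must satisfy L <= M <= U elementwise")
        if self.stage in _HOLLOW_STAGES:
            for name, C in (("L", L), ("M", M), ("U", U)):
                if np.diag(C).any():
                    raise ValueError(f"{self.stage} matrix must have a zero diagonal ({name})")

    @property
    def n(self) -> int:
        return self.L.shape[0]

    def components(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return self.L, self.M, self.U

    def cell(self, i: int, j: int) -> TriangularFuzzyNumber:
        return TriangularFuzzyNumber(self.L[i, j], self.M[i, j], self.U[i, j])

    def with_stage(self, stage: Stage) -> "FuzzyMatrix":
        return FuzzyMatrix(self.L, self.M, self.U, stage)


@dataclass(frozen=True)
class DematelResult:
    """Defuzzified total-relation matrix and the per-criterion cause/effect indices."""

    criteria: tuple[str, ...]
    tprime: np.ndarray                    # defuzzified total-relation matrix
    D: np.ndarray                         # row sums: influence dispatched
    R: np.ndarray                         # column sums: influence received
    prominence: np.ndarray                # D + R
    relation: np.ndarray                  # D - R
    group: tuple[str, ...]                # "cause" | "effect" per criterion
    ranking: tuple[str, ...]              # criteria by prominence, descending
    boundary_flags: tuple[str, ...] = ()  # criteria with D-R exactly 0
    tie_flags: tuple[str, ...] = ()       # criteria involved in prominence ties
    audit: dict = field(default_factory=dict, compare=False)

    @property
    def n(self) -> int:
        return len(self.criteria)

    @property
    def cause_group(self) -> tuple[str, ...]:
        return tuple(c for c, g in zip(self.criteria, self.group) if g == "cause")

    @property
    def effect_group(self) -> tuple[str, ...]:
        return tuple(c for c, g in zip(self.criteria, self.group) if g == "effect")

    def index_table(self):
        """Per-criterion indices as a pandas DataFrame (columns D, R, D+R, D-R, group)."""
        import pandas as pd

        return pd.DataFrame(
            {"D": self.D, "R": self.R, "D+R": self.prominence,
             "D-R": self.relation, "group": list(self.group)},
            index=list(self.criteria),
        )


def initial_matrix(responses: Sequence[Sequence[str]], scale: LinguisticScale) -> FuzzyMatrix:
    """Map one expert's n x n linguistic matrix to an initial fuzzy matrix.

    Off-diagonal cells go through the scale lookup; diagonal cells are
    forced to the crisp zero (0, 0, 0) regardless of what was recorded.
    Empty off-diagonal cells are not allowed.
    """
    n = len(responses)
    if n < 2:
        raise ValueError("need at least 2 criteria")
    L = np.zeros((n, n))
    M = np.zeros((n, n))
    U = np.zeros((n, n))
    for i, row in enumerate(responses):
        if len(row) != n:
            raise ValueError(f"row {i} has {len(row)} cells, expected {n}")
        for j, term in enumerate(row):
            if i == j:
                continue
            v = scale[term]
            L[i, j], M[i, j], U[i, j] = v.l, v.m, v.u
    return FuzzyMatrix(L, M, U, "initial")


def normalization_factor(Z: FuzzyMatrix) -> float:
    """Normalization constant r: the maximum row sum of the upper-bound component."""
    r = float(Z.U.sum(axis=1).max())
    if r <= 0.0:
        raise ValueError("degenerate panel: all upper bounds are zero, cannot normalize")
    return r


def normalize(Z: FuzzyMatrix, r: float) -> FuzzyMatrix:
    """Divide every component of Z by r, producing the normalized matrix X."""
    if r <= 0:
        raise ValueError(f"normalization factor must be positive, got {r}")
    return FuzzyMatrix(Z.L / r, Z.M / r, Z.U / r, "normalized")


def average_panel(X_list: Sequence[FuzzyMatrix]) -> FuzzyMatrix:
    """Componentwise mean of the experts' normalized matrices."""
    if not X_list:
        raise ValueError("cannot average an empty list of matrices")
    n = X_list[0].n
    if any(X.n != n for X in X_list):
        raise ValueError("all matrices must share one shape")
    p = len(X_list)
    L = sum(X.L for X in X_list) / p
    M = sum(X.M for X in X_list) / p
    U = sum(X.U for X in X_list) / p
    return FuzzyMatrix(L, M, U, "averaged")


def _series_limit(C: np.ndarray, name: str) -> np.ndarray:
    """The limit C + C^2 + ... = C (I - C)^{-1}, with convergence guards."""
    n = C.shape[0]
    rho = float(np.abs(np.linalg.eigvals(C)).max())
    if rho >= 1.0:
        raise ValueError(
            f"component {name}: spectral radius {rho:.4f} >= 1, "
            "the influence series does not converge"
        )
    A = np.eye(n) - C
    cond = float(np.linalg.cond(A, 1))
    if not np.isfinite(cond) or cond > CONDITION_LIMIT:
        raise ValueError(
            f"component {name}: (I - C) is numerically singular (condition {cond:.3e})"
        )
    # T = C (I - C)^{-1} solved as A^T T^T = C^T to avoid forming the inverse
    return np.linalg.solve(A.T, C.T).T


def total_relation(A: FuzzyMatrix) -> FuzzyMatrix:
    """Total-relation fuzzy matrix: T_C = C (I - C)^{-1} per component."""
    TL = _series_limit(A.L, "L")
    TM = _series_limit(A.M, "M")
    TU = _series_limit(A.U, "U")
    return FuzzyMatrix(TL, TM, TU, "total")


def defuzzify_matrix(T: FuzzyMatrix) -> np.ndarray:
    """Cellwise BNP defuzzification: T' = T_L + ((T_U - T_L) + (T_M - T_L)) / 3.

    Algebraically (T_L + T_M + T_U) / 3; the anchored form is exact for
    crisp cells (l = m = u) in floating point.
    """
    return T.L + ((T.U - T.L) + (T.M - T.L)) / 3.0


def prominence_relation(tprime: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Row sums D, column sums R, prominence D+R, relation D-R."""
    tprime = np.asarray(tprime, dtype=float)
    if tprime.ndim != 2 or tprime.shape[0] != tprime.shape[1]:
        raise ValueError(f"total-relation matrix must be square, got shape {tprime.shape}")
    D = tprime.sum(axis=1)
    R = tprime.sum(axis=0)
    return D, R, D + R, D - R


def ranking_by_prominence(
    criteria: Sequence[str],
    prominence: np.ndarray,
    decimals: int | None = None,
) -> tuple[tuple[str, ...], tuple[str, ...]]:
    """Criteria ordered by prominence descending, with deterministic ties.

    Ties (after optional rounding to ``decimals``, round-half-even) are
    broken by criterion label order and the criteria involved are returned
    as tie flags.  Rounding to the display precision mirrors a report in
    which the ranking is read off the printed prominence column.
    """
    values = np.asarray(prominence, dtype=float)
    if decimals is not None:
        values = np.round(values, decimals)
    order = sorted(range(len(criteria)), key=lambda i: (-values[i], i))
    ties = []
    by_value: dict[float, list[str]] = {}
    for i, c in enumerate(criteria):
        by_value.setdefault(float(values[i]), []).append(c)
    for group in by_value.values():
        if len(group) > 1:
            ties.extend(group)
    return tuple(criteria[i] for i in order), tuple(ties)


def classify_and_rank(
    criteria: Sequence[str],
    tprime: np.ndarray,
    *,
    zero_tol: float = 1e-12,
    audit: dict | None = None,
) -> DematelResult:
    """Assemble the full result: indices, cause/effect groups, ranking.

    A criterion is a cause iff its relation D-R is strictly positive; a
    relation at zero (within ``zero_tol``, absorbing float round-off of the
    row/column sums) is classified as effect and flagged as a boundary case.
    """
    criteria = tuple(criteria)
    D, R, prom, rel = prominence_relation(tprime)
    if len(criteria) != len(D):
        raise ValueError("criteria labels do not match matrix dimension")
    group = tuple("cause" if r > zero_tol else "effect" for r in rel)
    boundary = tuple(c for c, r in zip(criteria, rel) if abs(r) <= zero_tol)
    ranking, ties = ranking_by_prominence(criteria, prom)
    return DematelResult(
        criteria=criteria,
        tprime=np.asarray(tprime, dtype=float),
        D=D, R=R, prominence=prom, relation=rel,
        group=group, ranking=ranking,
        boundary_flags=boundary, tie_flags=ties,
        audit=audit or {},
    )


def run_pipeline(
    panel_or_matrix,
    scale: LinguisticScale | None = None,
    criteria: Sequence[str] | None = None,
) -> DematelResult:
    """Run the full analysis from an expert panel or an averaged fuzzy matrix.

    Given an ``ExpertPanel`` the linguistic responses are mapped, normalized
    per expert, and averaged first; given an averaged ``FuzzyMatrix`` the
    computation starts at the total-relation stage (``criteria`` may then
    supply labels; the default is C1..Cn).  The result's ``audit`` dict
    records every intermediate matrix.
    """
    audit: dict = {}
    if isinstance(panel_or_matrix, FuzzyMatrix):
        averaged = panel_or_matrix
        if averaged.stage != "averaged":
            averaged = averaged.with_stage("averaged")
        if criteria is None:
            criteria = tuple(f"C{i + 1}" for i in range(averaged.n))
        criteria = tuple(criteria)
        if len(criteria) != averaged.n:
            raise ValueError("criteria labels do not match matrix dimension")
    else:
        panel = panel_or_matrix
        if scale is None:
            raise ValueError("a linguistic scale is required to analyze a panel")
        Z_list = [initial_matrix(resp, scale) for resp in panel.responses]
        X_list = [normalize(Z, normalization_factor(Z)) for Z in Z_list]
        averaged = average_panel(X_list)
        criteria = tuple(panel.criteria)
        audit["initial"] = Z_list
        audit["normalized"] = X_list
    audit["averaged"] = averaged
    T = total_relation(averaged)
    audit["total"] = T
    tprime = defuzzify_matrix(T)
    return classify_and_rank(criteria, tprime, audit=audit)
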