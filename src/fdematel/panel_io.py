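"""Reading expert panels, the embedded study fixture, and writing results.

Panel file dialect: one delimiter-separated text file per expert (comma or
tab, auto-detected), first row and first column holding the criterion
labels, every off-diagonal cell a linguistic term of the active scale.
Diagonal cells may be empty, the weakest term, or a "-" placeholder; they
are forced to crisp zero downstream in any case.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import _fixture
from .dematel_engine import DematelResult, FuzzyMatrix
from .fuzzy_core import LinguisticScale

__all__ = [
    "ExpertPanel",
    "FixtureBundle",
    "RetestReport",
    "read_panel",
    "load_liao_fixture",
    "retest_agreement",
    "write_results",
]

_DIAGONAL_PLACEHOLDERS = {"", "-", "0", "nan"}


@dataclass(frozen=True)
class ExpertPanel:
    """A panel of p experts, each rating n x n criterion-pair influences."""

    criteria: tuple[str, ...]
    responses: tuple[tuple[tuple[str, ...], ...], ...]  # [expert][row][col] terms
    sources: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        n = len(self.criteria)
        if n < 2:
            raise ValueError("a panel needs at least 2 criteria")
        if len(self.responses) < 1:
            raise ValueError("a panel needs at least 1 expert")
        for k, mat in enumerate(self.responses):
            if len(mat) != n or any(len(row) != n for row in mat):
                raise ValueError(f"expert {k}: response matrix is not {n}x{n}")

    @property
    def n(self) -> int:
        return len(self.criteria)

    @property
    def p(self) -> int:
        return len(self.responses)


@dataclass(frozen=True)
class FixtureBundle:
    """The embedded published case study: input matrix plus expected outputs."""

    criteria: tuple[str, ...]
    criterion_names: dict[str, str]
    aggregated: FuzzyMatrix            # averaged normalized fuzzy matrix
    expected_tprime: np.ndarray        # published defuzzified total-relation matrix
    expected_indices: pd.DataFrame     # published D, R, D+R, D-R per criterion
    expected_ranking: tuple[str, ...]
    expected_cause_group: frozenset[str]
    repair_log: tuple[dict, ...]       # documented transcription repairs


@dataclass(frozen=True)
class RetestReport:
    """Test-retest stability of a panel: per-expert agreement proportions."""

    proportions: tuple[float, ...]
    threshold: float
    stable: bool


def _read_matrix_file(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=None, engine="python", index_col=0, dtype=str,
                     keep_default_na=False, skipinitialspace=True)
    df.index = [str(x).strip() for x in df.index]
    df.columns = [str(x).strip() for x in df.columns]
    return df


def read_panel(paths: Sequence[str | Path], scale: LinguisticScale) -> ExpertPanel:
    """Read one file per expert into a validated panel.

    All files must share the same square header labels in the same order;
    every off-diagonal cell must be a term of ``scale``.  Errors name the
    offending file and cell.
    """
    paths = [Path(p) for p in paths]
    if not paths:
        raise ValueError("no panel files given")
    criteria: tuple[str, ...] | None = None
    responses = []
    for path in paths:
        df = _read_matrix_file(path)
        labels = tuple(df.index)
        if labels != tuple(df.columns):
            raise ValueError(
                f"{path}: matrix is not square with matching labels "
                f"(rows {list(df.index)}, columns {list(df.columns)})"
            )
        if criteria is None:
            criteria = labels
        elif labels != criteria:
            raise ValueError(
                f"{path}: criterion labels {list(labels)} do not match "
                f"the first expert's labels {list(criteria)}"
            )
        matrix = []
        for i, ri in enumerate(criteria):
            row = []
            for j, cj in enumerate(criteria):
                cell = str(df.iat[i, j]).strip()
                if i == j:
                    row.append(scale.weakest)
                    if cell.lower() not in _DIAGONAL_PLACEHOLDERS and cell not in scale:
                        raise ValueError(
                            f"{path}: diagonal cell ({ri},{cj}) holds {cell!r}; "
                            "expected empty or a scale term"
                        )
                    continue
                if cell not in scale:
                    raise ValueError(
                        f"{path}: cell ({ri},{cj}) holds unknown term {cell!r}; "
                        f"valid terms: {', '.join(scale.terms)}"
                    )
                row.append(cell)
            matrix.append(tuple(row))
        responses.append(tuple(matrix))
    return ExpertPanel(criteria=criteria, responses=tuple(responses),
                       sources=tuple(str(p) for p in paths))


def _parse_triples(text: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    rows = [[tuple(float(x) for x in cell.split(","))
             for cell in line.split("|")]
            for line in text.strip().splitlines()]
    arr = np.array(rows, dtype=float)
    return arr[:, :, 0], arr[:, :, 1], arr[:, :, 2]


def load_liao_fixture() -> FixtureBundle:
    """The embedded 14-criterion health-promotion social-marketing case.

    Returns the aggregated normalized fuzzy direct-relation matrix exactly
    as published (with the three documented typesetting repairs applied and
    logged) together with the published total-relation matrix, per-criterion
    indices, ranking and cause group for comparison.
    """
    L, M, U = _parse_triples(_fixture.AGGREGATED_TRIPLES)
    aggregated = FuzzyMatrix(L, M, U, "averaged")
    tprime = np.array([[float(x) for x in row.split()]
                       for row in _fixture.EXPECTED_TPRIME.strip().splitlines()])
    indices = pd.DataFrame.from_dict(
        _fixture.EXPECTED_INDICES, orient="index", columns=["D", "R", "D+R", "D-R"]
    )
    return FixtureBundle(
        criteria=tuple(_fixture.CRITERIA),
        criterion_names=dict(_fixture.CRITERION_NAMES),
        aggregated=aggregated,
        expected_tprime=tprime,
        expected_indices=indices,
        expected_ranking=tuple(_fixture.EXPECTED_RANKING),
        expected_cause_group=frozenset(_fixture.EXPECTED_CAUSE_GROUP),
        repair_log=tuple(dict(r) for r in _fixture.REPAIRS),
    )


def retest_agreement(
    panel_a: ExpertPanel, panel_b: ExpertPanel, threshold: float = 0.8
) -> RetestReport:
    """Test-retest stability: per-expert fraction of identical off-diagonal cells.

    The panels must hold the same criteria and experts in the same order.
    The panel is flagged stable when every expert's agreement proportion
    reaches ``threshold``.
    """
    if panel_a.criteria != panel_b.criteria:
        raise ValueError("panels rate different criteria")
    if panel_a.p != panel_b.p:
        raise ValueError(f"expert counts differ ({panel_a.p} vs {panel_b.p})")
    n = panel_a.n
    off_diag = n * (n - 1)
    proportions = []
    for ma, mb in zip(panel_a.responses, panel_b.responses):
        agree = sum(
            1
            for i in range(n)
            for j in range(n)
            if i != j and ma[i][j] == mb[i][j]
        )
        proportions.append(agree / off_diag)
    stable = all(p >= threshold for p in proportions)
    return RetestReport(tuple(proportions), threshold, stable)


def write_results(
    result: DematelResult,
    destination: str | Path,
    *,
    precision: int | None = None,
    provenance: dict | None = None,
) -> dict[str, Path]:
    """Write a completed analysis to ``destination``.

    Produces four files: the defuzzified total-relation matrix
    (``total_relation.csv``), the per-criterion index table mirroring the
    D / R / D+R / D-R columns (``indices.csv``), the cause-effect diagram
    coordinates (``coordinates.csv``: prominence on x, relation on y), and
    a machine-readable run summary (``summary.json``).  Values are written
    at full precision unless ``precision`` asks for a fixed number of
    decimals (round-half-even, mirroring a printed report).
    """
    if result is None or result.n == 0:
        raise ValueError("cannot write an empty result")
    if precision is not None and precision < 1:
        raise ValueError("display precision must be at least 1 decimal")
    dest = Path(destination)
    dest.mkdir(parents=True, exist_ok=True)
    labels = list(result.criteria)

    tprime = pd.DataFrame(result.tprime, index=labels, columns=labels)
    indices = result.index_table()
    coords = pd.DataFrame(
        {"D+R": result.prominence, "D-R": result.relation}, index=labels
    )
    if precision is not None:
        tprime = tprime.round(precision)
        for df in (indices, coords):
            for col in df.columns:
                if df[col].dtype.kind == "f":
                    df[col] = df[col].round(precision)

    paths = {
        "tprime": dest / "total_relation.csv",
        "indices": dest / "indices.csv",
        "coordinates": dest / "coordinates.csv",
        "summary": dest / "summary.json",
    }
    float_format = f"%.{precision}f" if precision is not None else None
    tprime.to_csv(paths["tprime"], float_format=float_format)
    indices.to_csv(paths["indices"], float_format=float_format)
    coords.to_csv(paths["coordinates"], float_format=float_format)

    summary = {
        "criteria": labels,
        "cause_group": list(result.cause_group),
        "effect_group": list(result.effect_group),
        "ranking": list(result.ranking),
        "boundary_flags": list(result.boundary_flags),
        "tie_flags": list(result.tie_flags),
        "D": result.D.tolist(),
        "R": result.R.tolist(),
        "prominence": result.prominence.tolist(),
        "relation": result.relation.tolist(),
        "relation_sum": float(result.relation.sum()),
    }
    if provenance:
        summary["provenance"] = provenance
    paths["summary"].write_text(json.dumps(summary, indent=2) + "\n", encoding="utf-8")
    return paths
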