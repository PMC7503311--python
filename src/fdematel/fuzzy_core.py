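"""Triangular fuzzy numbers, linguistic rating scales, and defuzzification.

Expert influence judgments are elicited as linguistic terms ("High
influence", "No influence", ...) and carried through the computation as
triangular fuzzy numbers (TFNs): triples ``(l, m, u)`` with membership
rising linearly from ``l`` to a peak at the modal value ``m`` and falling
back to zero at ``u``.  The scale used throughout is a five-level mapping
from term to TFN on [0, 1]; a custom scale may be supplied as long as it
satisfies the same ordering invariants.

Defuzzification uses the best non-fuzzy performance (BNP) value,
``l + ((u - l) + (m - l)) / 3``, which simplifies to the centroid
``(l + m + u) / 3`` of a triangular number.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "TriangularFuzzyNumber",
    "LinguisticScale",
    "DEFAULT_SCALE",
    "term_to_tfn",
    "tfn_mean",
    "bnp",
]


@dataclass(frozen=True)
class TriangularFuzzyNumber:
    """A triangular fuzzy number (l, m, u) with l <= m <= u, all finite."""

    l: float
    m: float
    u: float

    def __post_init__(self) -> None:
        for name in ("l", "m", "u"):
            v = getattr(self, name)
            if not isinstance(v, (int, float)) or isinstance(v, bool):
                raise TypeError(f"TFN component {name!r} must be a real number, got {v!r}")
            if not math.isfinite(v):
                raise ValueError(f"TFN component {name!r} must be finite, got {v!r}")
        if not (self.l <= self.m <= self.u):
            raise ValueError(
                f"TFN components must satisfy l <= m <= u, got ({self.l}, {self.m}, {self.u})"
            )

    def __iter__(self):
        return iter((self.l, self.m, self.u))

    @property
    def is_crisp(self) -> bool:
        return self.l == self.m == self.u

    def defuzzify(self) -> float:
        return bnp(self)


def _normalize_term(term: str) -> str:
    # case-insensitive, whitespace-collapsed comparison key
    return " ".join(term.split()).casefold()


class LinguisticScale:
    """Ordered mapping from linguistic terms to triangular fuzzy numbers.

    Terms are listed from weakest to strongest influence.  Lookup is
    case-insensitive and tolerant of surrounding/duplicated whitespace.
    All fuzzy values must lie in [0, 1] with l <= m <= u.
    """

    def __init__(self, entries: Sequence[tuple[str, TriangularFuzzyNumber]]):
        entries = [(str(t), v if isinstance(v, TriangularFuzzyNumber) else TriangularFuzzyNumber(*v))
                   for t, v in entries]
        if len(entries) < 2:
            raise ValueError("a linguistic scale needs at least two terms")
        keys = [_normalize_term(t) for t, _ in entries]
        if len(set(keys)) != len(keys):
            raise ValueError("linguistic terms must be unique (case-insensitive)")
        for term, v in entries:
            if not (0.0 <= v.l <= v.m <= v.u <= 1.0):
                raise ValueError(
                    f"scale value for {term!r} must satisfy 0 <= l <= m <= u <= 1, got {tuple(v)}"
                )
        self._entries = entries
        self._lookup = dict(zip(keys, (v for _, v in entries)))
        self._inverse = {tuple(v): t for t, v in entries}

    @property
    def terms(self) -> list[str]:
        return [t for t, _ in self._entries]

    @property
    def values(self) -> list[TriangularFuzzyNumber]:
        return [v for _, v in self._entries]

    @property
    def weakest(self) -> str:
        return self._entries[0][0]

    @property
    def strongest(self) -> str:
        return self._entries[-1][0]

    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, term: str) -> bool:
        return _normalize_term(term) in self._lookup

    def __getitem__(self, term: str) -> TriangularFuzzyNumber:
        key = _normalize_term(term)
        try:
            return self._lookup[key]
        except KeyError:
            raise KeyError(
                f"unknown linguistic term {term!r}; valid terms are: "
                + ", ".join(repr(t) for t in self.terms)
            ) from None

    def term_for(self, value: TriangularFuzzyNumber) -> str:
        """Inverse lookup: the term whose tabulated triple equals ``value``."""
        try:
            return self._inverse[tuple(value)]
        except KeyError:
            raise KeyError(f"no term maps to {tuple(value)}") from None

    def index_of(self, term: str) -> int:
        key = _normalize_term(term)
        for i, (t, _) in enumerate(self._entries):
            if _normalize_term(t) == key:
                return i
        raise KeyError(f"unknown linguistic term {term!r}")

    @classmethod
    def from_file(cls, path: str | Path) -> "LinguisticScale":
        """Load a scale from a delimited text file with rows ``term, l, m, u``.

        Comma or tab delimited; a header row is skipped if its numeric
        columns do not parse.  Rows are kept in file order (weakest first).
        """
        path = Path(path)
        entries: list[tuple[str, TriangularFuzzyNumber]] = []
        with open(path, newline="", encoding="utf-8") as fh:
            sample = fh.read(4096)
            fh.seek(0)
            delim = "\t" if sample.count("\t") >= sample.count(",") else ","
            for row in csv.reader(fh, delimiter=delim):
                if not row or not any(cell.strip() for cell in row):
                    continue
                if len(row) != 4:
                    raise ValueError(
                        f"{path}: each scale row needs 4 fields (term, l, m, u), got {row!r}"
                    )
                term = row[0].strip()
                try:
                    l, m, u = (float(x) for x in row[1:])
                except ValueError:
                    if not entries:  # header row
                        continue
                    raise ValueError(f"{path}: non-numeric fuzzy components in row {row!r}")
                entries.append((term, TriangularFuzzyNumber(l, m, u)))
        return cls(entries)


#: Five-level influence scale used by default (terms weakest to strongest).
DEFAULT_SCALE = LinguisticScale(
    [
        ("No influence", TriangularFuzzyNumber(0.00, 0.00, 0.25)),
        ("Very low influence", TriangularFuzzyNumber(0.00, 0.25, 0.50)),
        ("Low influence", TriangularFuzzyNumber(0.25, 0.50, 0.75)),
        ("High influence", TriangularFuzzyNumber(0.50, 0.75, 1.00)),
        ("Very high influence", TriangularFuzzyNumber(0.75, 1.00, 1.00)),
    ]
)


def term_to_tfn(scale: LinguisticScale, term: str) -> TriangularFuzzyNumber:
    """Map a linguistic term to its tabulated triangular fuzzy number."""
    return scale[term]


def tfn_mean(values: Iterable[TriangularFuzzyNumber]) -> TriangularFuzzyNumber:
    """Componentwise arithmetic mean of a non-empty collection of TFNs."""
    values = list(values)
    if not values:
        raise ValueError("cannot average an empty list of fuzzy numbers")
    n = len(values)
    return TriangularFuzzyNumber(
        sum(v.l for v in values) / n,
        sum(v.m for v in values) / n,
        sum(v.u for v in values) / n,
    )


def bnp(value: TriangularFuzzyNumber) -> float:
    """Best non-fuzzy performance of a TFN: l + ((u-l) + (m-l))/3 = (l+m+u)/3."""
    return value.l + ((value.u - value.l) + (value.m - value.l)) / 3.0
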