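"""Positional residue propensity statistics over PTS2 nonapeptide sets.

For a set of n nonapeptides, the *propensity* of residue r at position p is

    propensity(p, r) = 100 * count(p, r) / n       (percent)

where count(p, r) is the number of sequences carrying r at p.  A residue
present in every sequence at a position therefore has propensity 100.

Two renditions of the value are kept: the full-precision percentage, and a
*printed* value obtained by truncating the decimal expansion toward zero at
three significant figures (so 11/14 -> 78.571... prints as 78.5, and
1/14 -> 7.1428... prints as 7.14).  Truncation, not rounding, is what
reproduces the published table cells for the 14-sequence set.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from fractions import Fraction

import pandas as pd

from .errors import InputError

POSITIONS = tuple(range(1, 10))


def truncate_significant(value: Fraction | float, sig: int = 3) -> float:
    """Truncate *value* toward zero to *sig* significant figures."""
    frac = Fraction(value).limit_denominator(10**9) if not isinstance(value, Fraction) else value
    if frac == 0:
        return 0.0
    mag = abs(frac)
    # exponent e with 10**e <= |value| < 10**(e+1), computed exactly
    e = 0
    while mag >= 10:
        mag /= 10
        e += 1
    while mag < 1:
        mag *= 10
        e -= 1
    scale = Fraction(10) ** (e - sig + 1)
    truncated = (abs(frac) // scale) * scale
    return float(truncated if frac > 0 else -truncated)


@dataclass(frozen=True)
class PropensityTable:
    """Per-position residue counts and propensities over n nonapeptides."""

    n: int
    counts: tuple[tuple[tuple[str, int], ...], ...]  # index 0..8 -> ((residue, count), ...)

    def count(self, position: int, residue: str) -> int:
        self._check_position(position)
        return dict(self.counts[position - 1]).get(residue.upper(), 0)

    def propensity_exact(self, position: int, residue: str) -> Fraction:
        return Fraction(100 * self.count(position, residue), self.n)

    def propensity(self, position: int, residue: str) -> float:
        """Full-precision percentage 100*count/n."""
        return float(self.propensity_exact(position, residue))

    def printed(self, position: int, residue: str) -> float:
        """The 3-significant-figure truncated percentage."""
        return truncate_significant(self.propensity_exact(position, residue))

    def residues(self, position: int) -> tuple[str, ...]:
        self._check_position(position)
        return tuple(res for res, _ in self.counts[position - 1])

    @staticmethod
    def _check_position(position: int) -> None:
        if position not in POSITIONS:
            raise InputError(f"PTS2 position must be in 1..9, got {position}")


def compute_propensity(nonapeptides: list[str]) -> PropensityTable:
    """Exact per-(position, residue) occurrence counts and percentages."""
    if not nonapeptides:
        raise InputError("need at least one nonapeptide")
    seqs = [s.upper() for s in nonapeptides]
    for s in seqs:
        if len(s) != 9:
            raise InputError(f"nonapeptide must have 9 residues, got {s!r}")
    n = len(seqs)
    per_pos = []
    for i in range(9):
        counter = Counter(s[i] for s in seqs)
        per_pos.append(tuple(sorted(counter.items())))
    return PropensityTable(n=n, counts=tuple(per_pos))


def most_prevalent(table: PropensityTable, position: int) -> list[str]:
    """Residues observed at *position*, by descending count; ties alphabetical."""
    table._check_position(position)
    items = [(res, cnt) for res, cnt in table.counts[position - 1] if cnt > 0]
    items.sort(key=lambda rc: (-rc[1], rc[0]))
    return [res for res, _ in items]


def format_table(
    table: PropensityTable,
    comparison: PropensityTable | None = None,
    labels: tuple[str, str] = ("A", "B"),
) -> pd.DataFrame:
    """Tabular report: one row per (position, prevalence rank).

    With a *comparison* table, the two species are laid out side by side,
    rank-paired within each position (the k-th most prevalent residue of each
    species shares a row); absent cells are NA.
    """
    la, lb = labels
    rows = []
    for pos in POSITIONS:
        ranked_a = most_prevalent(table, pos)
        ranked_b = most_prevalent(comparison, pos) if comparison is not None else []
        for rank in range(max(len(ranked_a), len(ranked_b)) or 0):
            row: dict = {"position": pos, "rank": rank + 1}
            if rank < len(ranked_a):
                res = ranked_a[rank]
                row[f"residue_{la}"] = res
                row[f"count_{la}"] = table.count(pos, res)
                row[f"propensity_{la}"] = table.printed(pos, res)
            if comparison is not None and rank < len(ranked_b):
                res = ranked_b[rank]
                row[f"residue_{lb}"] = res
                row[f"count_{lb}"] = comparison.count(pos, res)
                row[f"propensity_{lb}"] = comparison.printed(pos, res)
            rows.append(row)
    df = pd.DataFrame(rows)
    if comparison is None:
        df = df.rename(
            columns={
                f"residue_{la}": "residue",
                f"count_{la}": "count",
                f"propensity_{la}": "propensity",
            }
        )
    return df
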