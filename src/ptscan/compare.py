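"""Two-species comparative catalogue of peroxisomal targeting signals.

Builds, from two annotated proteomes (a reference species and a target
species), the comparative summaries a proteome survey reports: per-category
tallies, integer percentage of canonical PTS1 proteins, shared and unique
non-canonical tripeptide inventories, no-obvious sub-category listings, and
ortholog-map orphans.

Conventions:

* Integer percentages are truncated (floor), not rounded — the convention
  under which 55/97 reports as 56, not 57.
* Proteins whose only signal is a catalase-type internal PTS are counted
  inside "no obvious PTS" for the headline tally and additionally broken out,
  so both renditions of the no-obvious count (with and without the catalase
  family) are available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .annotate import (
    CAT_INTERNAL,
    CAT_NONE,
    CAT_PTS1_CANONICAL,
    CAT_PTS1_NONCANONICAL,
    CAT_PTS2,
    NO_OBVIOUS_LABELS,
    NON_CANONICAL,
    ProteinAnnotation,
)
from .errors import InputError


@dataclass(frozen=True)
class OrthologMap:
    """Pairs of (reference_id, target_id); reference IDs may be unmatched."""

    pairs: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        seen = set()
        for ref, tgt in self.pairs:
            if not ref or not tgt:
                raise InputError("ortholog map IDs must be non-empty")
            if (ref, tgt) in seen:
                raise InputError(f"duplicate ortholog pair ({ref}, {tgt})")
            seen.add((ref, tgt))

    @property
    def reference_ids(self) -> frozenset[str]:
        return frozenset(ref for ref, _ in self.pairs)

    def orphans(self, reference_ids: Iterable[str]) -> list[str]:
        """Reference IDs with no target-species counterpart, input order kept."""
        mapped = self.reference_ids
        return [rid for rid in reference_ids if rid not in mapped]

    @classmethod
    def from_tsv(cls, path: str | Path) -> "OrthologMap":
        """Two-column TSV (reference_id, target_id); '#' comment lines allowed."""
        pairs = []
        for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            fields = stripped.split("\t")
            if len(fields) != 2:
                raise InputError(f"{path}:{lineno}: expected 2 tab-separated columns")
            pairs.append((fields[0], fields[1]))
        return cls(pairs=tuple(pairs))


@dataclass(frozen=True)
class SpeciesTally:
    """Category counts for one species."""

    n_total: int
    n_pts2: int
    n_pts1_canonical: int
    n_pts1_noncanonical: int
    n_no_obvious: int  # includes catalase-type internal-PTS proteins
    n_catalase_internal: int

    @property
    def n_no_pts_strict(self) -> int:
        """No-obvious count excluding the catalase-type internal-PTS proteins."""
        return self.n_no_obvious - self.n_catalase_internal

    @property
    def total_pts1(self) -> int:
        """Size of the PTS1 catalogue: canonical + non-canonical + no-obvious."""
        return self.n_pts1_canonical + self.n_pts1_noncanonical + self.n_no_obvious

    @property
    def pct_canonical(self) -> int | None:
        if self.total_pts1 == 0:
            return None
        return percent_canonical(self.n_pts1_canonical, self.total_pts1)


def tally_categories(annotations: Sequence[ProteinAnnotation]) -> SpeciesTally:
    """Count annotations per summary category."""
    n_pts2 = sum(a.summary_category == CAT_PTS2 for a in annotations)
    n_can = sum(a.summary_category == CAT_PTS1_CANONICAL for a in annotations)
    n_non = sum(a.summary_category == CAT_PTS1_NONCANONICAL for a in annotations)
    n_internal = sum(a.summary_category == CAT_INTERNAL for a in annotations)
    n_none = sum(a.summary_category == CAT_NONE for a in annotations)
    return SpeciesTally(
        n_total=len(annotations),
        n_pts2=n_pts2,
        n_pts1_canonical=n_can,
        n_pts1_noncanonical=n_non,
        n_no_obvious=n_internal + n_none,
        n_catalase_internal=n_internal,
    )


def percent_canonical(canonical: int, total: int) -> int:
    """floor(100 * canonical / total) — integer truncation, not rounding."""
    if total <= 0:
        raise InputError("total must be positive")
    return math.floor(100 * canonical / total)


def _noncanonical_tripeptides(annotations: Sequence[ProteinAnnotation]) -> frozenset[str]:
    return frozenset(
        a.terminal.tripeptide
        for a in annotations
        if a.terminal is not None and a.terminal.label == NON_CANONICAL
    )


def noncanonical_sets(
    annotations_a: Sequence[ProteinAnnotation],
    annotations_b: Sequence[ProteinAnnotation],
) -> tuple[frozenset[str], frozenset[str], frozenset[str]]:
    """(shared, unique_a, unique_b) over distinct non-canonical terminal tripeptides."""
    set_a = _noncanonical_tripeptides(annotations_a)
    set_b = _noncanonical_tripeptides(annotations_b)
    return set_a & set_b, set_a - set_b, set_b - set_a


def no_obvious_listing(annotations: Sequence[ProteinAnnotation]) -> list[tuple[str, str]]:
    """(tripeptide, sub-category) pairs for no-obvious terminal calls.

    Ordered by sub-category (i, ii, iii) then alphabetically; distinct
    tripeptides only.
    """
    order = {label: k for k, label in enumerate(NO_OBVIOUS_LABELS)}
    pairs = {
        (a.terminal.tripeptide, a.terminal.label)
        for a in annotations
        if a.terminal is not None and a.terminal.label in order
    }
    return sorted(pairs, key=lambda tl: (order[tl[1]], tl[0]))


@dataclass(frozen=True)
class ComparativeSummary:
    species: tuple[str, str]
    tallies: tuple[SpeciesTally, SpeciesTally]
    shared_noncanonical: frozenset[str]
    unique_noncanonical: tuple[frozenset[str], frozenset[str]]
    no_obvious: tuple[tuple[tuple[str, str], ...], tuple[tuple[str, str], ...]]
    orphans: tuple[str, ...] = ()


def compare_proteomes(
    annotations_a: Sequence[ProteinAnnotation],
    annotations_b: Sequence[ProteinAnnotation],
    species: tuple[str, str] = ("reference", "target"),
    ortholog_map: OrthologMap | None = None,
) -> ComparativeSummary:
    """Assemble the full comparative summary for two annotated proteomes."""
    shared, uniq_a, uniq_b = noncanonical_sets(annotations_a, annotations_b)
    orphans: tuple[str, ...] = ()
    if ortholog_map is not None:
        orphans = tuple(ortholog_map.orphans(a.protein_id for a in annotations_a))
    return ComparativeSummary(
        species=species,
        tallies=(tally_categories(annotations_a), tally_categories(annotations_b)),
        shared_noncanonical=shared,
        unique_noncanonical=(uniq_a, uniq_b),
        no_obvious=(
            tuple(no_obvious_listing(annotations_a)),
            tuple(no_obvious_listing(annotations_b)),
        ),
        orphans=orphans,
    )


def build_report(summary: ComparativeSummary) -> dict:
    """Machine-readable (JSON-serializable) rendition of a ComparativeSummary."""
    per_species = {}
    for name, tally, uniq, no_obv in zip(
        summary.species, summary.tallies, summary.unique_noncanonical, summary.no_obvious
    ):
        per_species[name] = {
            "n_total": tally.n_total,
            "n_pts2": tally.n_pts2,
            "n_pts1_canonical": tally.n_pts1_canonical,
            "n_pts1_noncanonical": tally.n_pts1_noncanonical,
            "n_no_obvious": tally.n_no_obvious,
            "n_catalase_internal": tally.n_catalase_internal,
            "n_no_pts_strict": tally.n_no_pts_strict,
            "total_pts1": tally.total_pts1,
            "pct_canonical": tally.pct_canonical,
            "unique_noncanonical": sorted(uniq),
            "no_obvious_tripeptides": [list(pair) for pair in no_obv],
        }
    return {
        "species": list(summary.species),
        "per_species": per_species,
        "shared_noncanonical": sorted(summary.shared_noncanonical),
        "orphans": list(summary.orphans),
    }
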