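"""Protein and proteome annotation: PTS1 classification and PTS2 scanning.

A protein is summarised into one of five categories by a fixed precedence:

1. ``PTS2`` — an N-terminal nonapeptide match (internal PTS2 matches never
   set the summary on their own unless internal scanning is enabled and no
   other signal is present; they are always retained as evidence);
2. ``PTS1_canonical`` / ``PTS1_noncanonical`` — from the terminal tripeptide;
3. ``internal_PTS`` — a canonical or non-canonical PTS1-like tripeptide
   upstream of the C terminus (the catalase QKL-10> convention);
4. ``none`` — no obvious PTS.

Proteins carrying more than one kind of evidence (e.g. a PTS2 domain plus a
terminal SKL>) keep all of it and are flagged ``dual_signal``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

from .errors import InputError
from .signal_tables import (
    LOW,
    UNPROVEN,
    RELAXED,
    STRICT,
    Pts2ConsensusSpec,
    ResidueClassTable,
    default_pts2_spec,
    default_tables,
)

# PTS1 labels
CANONICAL = "canonical"
NON_CANONICAL = "non_canonical"
NO_OBVIOUS_I = "no_obvious_i"
NO_OBVIOUS_II = "no_obvious_ii"
NO_OBVIOUS_III = "no_obvious_iii"

PTS1_LABELS = (CANONICAL, NON_CANONICAL, NO_OBVIOUS_I, NO_OBVIOUS_II, NO_OBVIOUS_III)
NO_OBVIOUS_LABELS = (NO_OBVIOUS_I, NO_OBVIOUS_II, NO_OBVIOUS_III)

# summary categories
CAT_PTS2 = "PTS2"
CAT_PTS1_CANONICAL = "PTS1_canonical"
CAT_PTS1_NONCANONICAL = "PTS1_noncanonical"
CAT_INTERNAL = "internal_PTS"
CAT_NONE = "none"

SUMMARY_CATEGORIES = (
    CAT_PTS2,
    CAT_PTS1_CANONICAL,
    CAT_PTS1_NONCANONICAL,
    CAT_INTERNAL,
    CAT_NONE,
)


@dataclass(frozen=True)
class AnnotatorOptions:
    """Tunable scan parameters.

    pts2_window
        Number of N-terminal start positions scanned for the nonapeptide
        (the "N-terminal portion"); default 40 residues.
    allow_internal_pts2
        Also scan the rest of the sequence, flagging matches internal=True.
    pts2_mode
        ``relaxed`` (anchors 1/8/9 must conform, default) or ``strict``.
    internal_min_offset, internal_max_offset
        end_offset range for the internal-PTS1 scan; observed plant offsets
        are 3, 10 and 13, default range 1..50.
    offset_convention
        ``exclusive`` (default): end_offset counts residues strictly after
        the motif, so the catalase motif written "QKL-10>" has ten residues
        following the L.  ``inclusive``: the motif's last residue is itself
        counted, shifting every reported offset up by one.
    """

    pts2_window: int = 40
    allow_internal_pts2: bool = False
    pts2_mode: str = RELAXED
    internal_min_offset: int = 1
    internal_max_offset: int = 50
    offset_convention: str = "exclusive"


DEFAULT_OPTIONS = AnnotatorOptions()


@dataclass(frozen=True)
class Pts1Call:
    """A classified C-terminal (or internal) tripeptide."""

    tripeptide: str
    classes: tuple[str, str, str]  # classes at -3, -2, -1
    label: str
    low_position: frozenset[int] = frozenset()  # populated for non_canonical only


@dataclass(frozen=True)
class InternalPtsHit:
    """A PTS1-like tripeptide upstream of the C terminus."""

    tripeptide: str
    end_offset: int
    label: str

    def token(self) -> str:
        return f"{self.tripeptide}-{self.end_offset}"


@dataclass(frozen=True)
class Pts2Match:
    """A nonapeptide scored against the consensus."""

    start: int  # 1-based offset of nonapeptide position 1
    nonapeptide: str
    conforms: tuple[bool, ...]  # per position 1..9 against the strict consensus
    deviations: tuple[tuple[int, str], ...]
    matched: bool
    internal: bool = False


@dataclass(frozen=True)
class ProteinAnnotation:
    protein_id: str
    length: int
    terminal: Pts1Call | None
    internal_hits: tuple[InternalPtsHit, ...]
    pts2_matches: tuple[Pts2Match, ...]
    summary_category: str
    dual_signal: bool = False


def _clean(sequence: str) -> str:
    return sequence.upper().rstrip("*")


def extract_tripeptide(sequence: str) -> str:
    """Last three residues of *sequence* (N->C order), stop symbol stripped."""
    seq = _clean(sequence)
    if len(seq) < 3:
        raise InputError(f"sequence too short for a C-terminal tripeptide (length {len(seq)})")
    return seq[-3:]


def classify_pts1(tripeptide: str, table: ResidueClassTable | None = None) -> Pts1Call:
    """Classify a tripeptide into canonical / non-canonical / no-obvious classes.

    The label is a total function of the per-position residue classes:

    * all three high                      -> canonical
    * exactly one low, two high           -> non_canonical
    * no unproven and >= 2 low            -> no_obvious_i
    * exactly one unproven                -> no_obvious_ii
    * >= 2 unproven                       -> no_obvious_iii
    """
    if table is None:
        table = default_tables()
    tri = tripeptide.upper().rstrip("*")
    if len(tri) != 3:
        raise InputError(f"tripeptide must have exactly 3 residues, got {tripeptide!r}")
    positions = (-3, -2, -1)
    classes = tuple(table.residue_class(pos, res) for pos, res in zip(positions, tri))
    n_low = classes.count(LOW)
    n_unproven = classes.count(UNPROVEN)
    low_position: frozenset[int] = frozenset()
    if n_unproven >= 2:
        label = NO_OBVIOUS_III
    elif n_unproven == 1:
        label = NO_OBVIOUS_II
    elif n_low >= 2:
        label = NO_OBVIOUS_I
    elif n_low == 1:
        label = NON_CANONICAL
        low_position = frozenset(p for p, c in zip(positions, classes) if c == LOW)
    else:
        label = CANONICAL
    return Pts1Call(tripeptide=tri, classes=classes, label=label, low_position=low_position)


def scan_internal_pts1(
    sequence: str,
    table: ResidueClassTable | None = None,
    min_offset: int = 1,
    max_offset: int = 50,
    offset_convention: str = "exclusive",
) -> list[InternalPtsHit]:
    """Find canonical / non-canonical tripeptides ending upstream of the C terminus.

    Returns hits whose end_offset lies in ``[min_offset, max_offset]``,
    ordered by increasing end_offset (C terminus inward).
    """
    if min_offset < 1:
        raise InputError("min_offset must be >= 1")
    if max_offset < min_offset:
        raise InputError("max_offset must be >= min_offset")
    if offset_convention not in ("exclusive", "inclusive"):
        raise InputError(f"unknown offset convention {offset_convention!r}")
    seq = _clean(sequence)
    shift = 0 if offset_convention == "exclusive" else 1
    hits: list[InternalPtsHit] = []
    for offset in range(min_offset, max_offset + 1):
        n_after = offset - shift  # residues after the motif
        if n_after < 1:  # end_offset 0 / terminal tripeptide never counts as internal
            continue
        start = len(seq) - 3 - n_after
        if start < 0:
            break
        call = classify_pts1(seq[start : start + 3], table)
        if call.label in (CANONICAL, NON_CANONICAL):
            hits.append(InternalPtsHit(tripeptide=call.tripeptide, end_offset=offset, label=call.label))
    return hits


def match_pts2_site(nonapeptide: str, spec: Pts2ConsensusSpec | None = None) -> Pts2Match:
    """Score a 9-mer against the PTS2 consensus.

    Conformity and deviations are always reported against the strict
    consensus; ``matched`` reflects the spec's mode (strict: all constrained
    positions conform; relaxed: all anchor positions conform).
    """
    if spec is None:
        spec = default_pts2_spec()
    nona = nonapeptide.upper()
    if len(nona) != 9:
        raise InputError(f"PTS2 site must have exactly 9 residues, got {len(nona)}")
    conforms = []
    deviations = []
    for pos in range(1, 10):
        allowed = spec.allowed[pos]
        ok = allowed is None or nona[pos - 1] in allowed
        conforms.append(ok)
        if not ok:
            deviations.append((pos, nona[pos - 1]))
    if spec.mode == STRICT:
        matched = not deviations
    else:
        matched = all(conforms[p - 1] for p in spec.anchors)
    return Pts2Match(
        start=1,
        nonapeptide=nona,
        conforms=tuple(conforms),
        deviations=tuple(deviations),
        matched=matched,
    )


def scan_pts2(
    sequence: str,
    spec: Pts2ConsensusSpec | None = None,
    window: int = 40,
    allow_internal: bool = False,
) -> list[Pts2Match]:
    """Slide the nonapeptide matcher over the sequence; return matches in start order.

    Starts 1..window are scanned always; with ``allow_internal`` the whole
    sequence is scanned and matches starting beyond the window are flagged
    ``internal=True``.
    """
    if window < 1:
        raise InputError("window must be >= 1")
    if spec is None:
        spec = default_pts2_spec()
    seq = _clean(sequence)
    last_start = len(seq) - 8  # 1-based start of the final full 9-mer
    limit = last_start if allow_internal else min(window, last_start)
    matches = []
    for start in range(1, limit + 1):
        m = match_pts2_site(seq[start - 1 : start + 8], spec)
        if m.matched:
            matches.append(replace(m, start=start, internal=start > window))
    return matches


def annotate_protein(
    sequence: str,
    table: ResidueClassTable | None = None,
    spec: Pts2ConsensusSpec | None = None,
    options: AnnotatorOptions = DEFAULT_OPTIONS,
    protein_id: str = "",
) -> ProteinAnnotation:
    """Annotate one protein; see module docstring for the precedence rule."""
    if table is None:
        table = default_tables()
    if spec is None:
        spec = default_pts2_spec(mode=options.pts2_mode)
    seq = _clean(sequence)
    pts2 = tuple(
        scan_pts2(seq, spec, window=options.pts2_window, allow_internal=options.allow_internal_pts2)
    )
    terminal = classify_pts1(extract_tripeptide(seq), table) if len(seq) >= 3 else None
    internal_hits = tuple(
        scan_internal_pts1(
            seq,
            table,
            min_offset=options.internal_min_offset,
            max_offset=options.internal_max_offset,
            offset_convention=options.offset_convention,
        )
    )
    has_nterm_pts2 = any(not m.internal for m in pts2)
    has_terminal_pts1 = terminal is not None and terminal.label in (CANONICAL, NON_CANONICAL)
    if has_nterm_pts2:
        category = CAT_PTS2
    elif has_terminal_pts1:
        category = CAT_PTS1_CANONICAL if terminal.label == CANONICAL else CAT_PTS1_NONCANONICAL
    elif internal_hits:
        category = CAT_INTERNAL
    elif any(m.internal for m in pts2):
        category = CAT_PTS2
    else:
        category = CAT_NONE
    n_evidence = sum((bool(pts2), has_terminal_pts1, bool(internal_hits)))
    return ProteinAnnotation(
        protein_id=protein_id,
        length=len(seq),
        terminal=terminal,
        internal_hits=internal_hits,
        pts2_matches=pts2,
        summary_category=category,
        dual_signal=n_evidence >= 2,
    )


def annotate_proteome(
    records: Iterable[tuple[str, str]] | Sequence,
    table: ResidueClassTable | None = None,
    spec: Pts2ConsensusSpec | None = None,
    options: AnnotatorOptions = DEFAULT_OPTIONS,
) -> list[ProteinAnnotation]:
    """Annotate every record of a proteome, preserving input order.

    *records* yields ``(id, sequence)`` pairs (objects with ``.id`` and
    ``.seq`` attributes, e.g. Bio.SeqRecord, are accepted too).
    Duplicate IDs are rejected.
    """
    seen: set[str] = set()
    out: list[ProteinAnnotation] = []
    for rec in records:
        if hasattr(rec, "id") and hasattr(rec, "seq"):
            rid, seq = rec.id, str(rec.seq)
        else:
            rid, seq = rec
        if rid in seen:
            raise InputError(f"duplicate record ID {rid!r}")
        seen.add(rid)
        out.append(annotate_protein(seq, table, spec, options, protein_id=rid))
    return out
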