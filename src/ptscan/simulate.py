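"""Synthetic proteomes with embedded targeting signals and ground truth.

The generator emulates the composition of a curated plant peroxisomal matrix
catalogue: a configurable fraction of proteins carry a terminal canonical
PTS1, a terminal non-canonical PTS1, an N-terminal PTS2 nonapeptide, or an
internal catalase-type tripeptide (QKL ten residues before the terminus by
default); the remainder are signal-free background.  Default fractions
(0.58 / 0.19 / 0.15 / 0.02 / 0.06) follow the reference-species catalogue
proportions (74 canonical, 24 non-canonical, 19 PTS2, 3 catalase-type
internal, 7 with no PTS).

Signals are embedded by overwriting residues in place, so lengths are fixed
and coordinates need no bookkeeping.  Because the i.i.d. background can
produce signals by chance, every record carries an *incidental-signal audit*:
an exhaustive scan of the final sequence whose extra hits (anything beyond
the deliberately embedded signal) are listed in the truth record.  The
generator is thus unbiased and both recall and precision of an annotator are
measurable against the truth table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .annotate import (
    CANONICAL,
    CAT_INTERNAL,
    CAT_NONE,
    CAT_PTS1_CANONICAL,
    CAT_PTS1_NONCANONICAL,
    CAT_PTS2,
    NON_CANONICAL,
    AnnotatorOptions,
    DEFAULT_OPTIONS,
    classify_pts1,
    match_pts2_site,
)
from .errors import InputError
from .signal_tables import (
    STRICT_PTS2_ALLOWED,
    Pts2ConsensusSpec,
    ResidueClassTable,
    default_pts2_spec,
    default_tables,
)

AA_ORDER = tuple("ACDEFGHIKLMNPQRSTVWY")

KIND_CANONICAL = "canonical_pts1"
KIND_NONCANONICAL = "noncanonical_pts1"
KIND_PTS2 = "pts2"
KIND_INTERNAL = "internal_pts"
KIND_NONE = "none"
SIGNAL_KINDS = (KIND_CANONICAL, KIND_NONCANONICAL, KIND_PTS2, KIND_INTERNAL, KIND_NONE)

#: Canonical terminal tripeptides: {S,A} x {K,R} x {L,M,I}.
CANONICAL_TRIPEPTIDES = tuple(
    a + b + c for a in "SA" for b in "KR" for c in "LMI"
)

#: Non-canonical tripeptides observed across the two-species inventory.
NONCANONICAL_TRIPEPTIDES = (
    "AHL", "AKV", "ANL", "ASL", "PKL", "PRL", "SLM", "SML", "SNI",
    "SNL", "SRF", "SRY", "SSI", "SSL", "SSM", "SYM", "TKL",
)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for a synthetic proteome."""

    n_proteins: int = 100
    length_range: tuple[int, int] = (60, 300)
    fractions: tuple[float, float, float, float, float] = (0.58, 0.19, 0.15, 0.02, 0.06)
    pts2_start_range: tuple[int, int] = (1, 30)
    internal_offset_range: tuple[int, int] = (10, 10)
    internal_motifs: tuple[str, ...] = ("QKL",)
    background_frequencies: tuple[float, ...] = tuple([1 / 20] * 20)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 0:
            raise InputError("n_proteins must be >= 0")
        lo, hi = self.length_range
        if lo < 20 or hi < lo:
            raise InputError("length_range minimum must be >= 20 and max >= min")
        if len(self.fractions) != len(SIGNAL_KINDS):
            raise InputError(f"need {len(SIGNAL_KINDS)} signal-mix fractions")
        if any(f < 0 or f > 1 for f in self.fractions):
            raise InputError("fractions must lie in [0, 1]")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise InputError("signal-mix fractions must sum to 1")
        _check_frequencies(self.background_frequencies)


def _check_frequencies(frequencies: Sequence[float]) -> None:
    if len(frequencies) != 20:
        raise InputError("background frequencies must cover the 20 standard residues")
    if any(f < 0 for f in frequencies):
        raise InputError("background frequencies must be non-negative")
    if abs(sum(frequencies) - 1.0) > 1e-9:
        raise InputError("background frequencies must sum to 1")


@dataclass(frozen=True)
class SignalEvidence:
    """One targeting-signal occurrence found in (or embedded into) a sequence."""

    signal: str  # terminal_pts1 | pts2 | internal_pts1
    motif: str
    position: int  # 1-based start (pts2) or end_offset (internal); 0 for terminal
    label: str  # tripeptide label or "match"

    def token(self) -> str:
        return f"{self.signal}:{self.motif}@{self.position}:{self.label}"


@dataclass(frozen=True)
class TruthRecord:
    protein_id: str
    kind: str
    motif: str  # embedded motif string ("" for kind none)
    position: int  # pts2: 1-based start; internal: end_offset; terminal PTS1: 0
    incidental_signals: tuple[SignalEvidence, ...]


def sample_background(
    length: int,
    frequencies: Sequence[float] | None = None,
    rng: np.random.Generator | None = None,
) -> str:
    """An i.i.d. amino-acid sequence of the given length."""
    if frequencies is None:
        frequencies = [1 / 20] * 20
    _check_frequencies(frequencies)
    if rng is None:
        rng = np.random.default_rng()
    idx = rng.choice(len(AA_ORDER), size=length, p=np.asarray(frequencies, dtype=float))
    return "".join(AA_ORDER[i] for i in idx)


def _sample_pts2_nonapeptide(rng: np.random.Generator, frequencies: Sequence[float]) -> str:
    """A strict-consensus PTS2 instantiation (wildcards drawn from background)."""
    residues = []
    for pos in range(1, 10):
        allowed = STRICT_PTS2_ALLOWED[pos]
        if allowed is None:
            residues.append(sample_background(1, frequencies, rng))
        else:
            choices = sorted(allowed)
            residues.append(choices[rng.integers(len(choices))])
    return "".join(residues)


def embed_signal(
    sequence: str,
    kind: str,
    rng: np.random.Generator,
    config: SimulationConfig | None = None,
) -> tuple[str, str, int]:
    """Overwrite residues of *sequence* in place with a signal of *kind*.

    Returns ``(new_sequence, motif, position)`` where position is the PTS2
    1-based start, the internal-motif end_offset, or 0 for terminal/none.
    """
    if config is None:
        config = SimulationConfig()
    if kind not in SIGNAL_KINDS:
        raise InputError(f"unknown signal kind {kind!r}")
    seq = sequence
    if kind == KIND_NONE:
        return seq, "", 0
    if kind == KIND_CANONICAL:
        motif = CANONICAL_TRIPEPTIDES[rng.integers(len(CANONICAL_TRIPEPTIDES))]
        if len(seq) < 3:
            raise InputError("sequence too short for a terminal tripeptide")
        return seq[:-3] + motif, motif, 0
    if kind == KIND_NONCANONICAL:
        motif = NONCANONICAL_TRIPEPTIDES[rng.integers(len(NONCANONICAL_TRIPEPTIDES))]
        if len(seq) < 3:
            raise InputError("sequence too short for a terminal tripeptide")
        return seq[:-3] + motif, motif, 0
    if kind == KIND_PTS2:
        lo, hi = config.pts2_start_range
        start = int(rng.integers(lo, hi + 1))
        if start < 1 or start + 8 > len(seq):
            raise InputError(f"PTS2 placement at start {start} impossible for length {len(seq)}")
        motif = _sample_pts2_nonapeptide(rng, config.background_frequencies)
        return seq[: start - 1] + motif + seq[start + 8 :], motif, start
    # internal catalase-type PTS
    lo, hi = config.internal_offset_range
    end_offset = int(rng.integers(lo, hi + 1))
    motif = config.internal_motifs[rng.integers(len(config.internal_motifs))]
    start_idx = len(seq) - len(motif) - end_offset
    if end_offset < 1 or start_idx < 0:
        raise InputError(
            f"internal-PTS placement at end_offset {end_offset} impossible for length {len(seq)}"
        )
    return seq[:start_idx] + motif + seq[start_idx + len(motif) :], motif, end_offset


def scan_all_signals(
    sequence: str,
    table: ResidueClassTable | None = None,
    spec: Pts2ConsensusSpec | None = None,
    options: AnnotatorOptions = DEFAULT_OPTIONS,
) -> list[SignalEvidence]:
    """Exhaustive audit scan: every signal an annotator with *options* can see.

    Lists the terminal tripeptide (if canonical/non-canonical), every PTS2
    match with start within the N-terminal window, and every internal PTS1
    hit within the configured offset range.
    """
    if table is None:
        table = default_tables()
    if spec is None:
        spec = default_pts2_spec(mode=options.pts2_mode)
    seq = sequence.upper().rstrip("*")
    found: list[SignalEvidence] = []
    for start in range(1, min(options.pts2_window, len(seq) - 8) + 1):
        m = match_pts2_site(seq[start - 1 : start + 8], spec)
        if m.matched:
            found.append(SignalEvidence("pts2", m.nonapeptide, start, "match"))
    if len(seq) >= 3:
        call = classify_pts1(seq[-3:], table)
        if call.label in (CANONICAL, NON_CANONICAL):
            found.append(SignalEvidence("terminal_pts1", call.tripeptide, 0, call.label))
    for offset in range(options.internal_min_offset, options.internal_max_offset + 1):
        start_idx = len(seq) - 3 - offset
        if start_idx < 0:
            break
        call = classify_pts1(seq[start_idx : start_idx + 3], table)
        if call.label in (CANONICAL, NON_CANONICAL):
            found.append(SignalEvidence("internal_pts1", call.tripeptide, offset, call.label))
    return found


def _embedded_evidence(kind: str, motif: str, position: int, table: ResidueClassTable) -> SignalEvidence | None:
    if kind == KIND_NONE:
        return None
    if kind in (KIND_CANONICAL, KIND_NONCANONICAL):
        return SignalEvidence("terminal_pts1", motif, 0, classify_pts1(motif, table).label)
    if kind == KIND_PTS2:
        return SignalEvidence("pts2", motif, position, "match")
    return SignalEvidence("internal_pts1", motif, position, classify_pts1(motif, table).label)


def gen_proteome(
    config: SimulationConfig,
) -> tuple[list[tuple[str, str]], list[TruthRecord]]:
    """Generate ``(records, truth)``: FASTA-ready (id, sequence) pairs + truth table.

    Signal kinds are assigned multinomially per the configured fractions;
    output is byte-identical under a fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    table = default_tables()
    records: list[tuple[str, str]] = []
    truths: list[TruthRecord] = []
    probs = np.asarray(config.fractions, dtype=float)
    for i in range(config.n_proteins):
        length = int(rng.integers(config.length_range[0], config.length_range[1] + 1))
        seq = sample_background(length, config.background_frequencies, rng)
        kind = SIGNAL_KINDS[int(rng.choice(len(SIGNAL_KINDS), p=probs))]
        seq, motif, position = embed_signal(seq, kind, rng, config)
        embedded = _embedded_evidence(kind, motif, position, table)
        audit = scan_all_signals(seq, table)
        incidental = tuple(s for s in audit if s != embedded)
        pid = f"SYN{i + 1:05d}"
        records.append((pid, seq))
        truths.append(
            TruthRecord(
                protein_id=pid,
                kind=kind,
                motif=motif,
                position=position,
                incidental_signals=incidental,
            )
        )
    return records, truths


def expected_category(truth: TruthRecord, table: ResidueClassTable | None = None) -> str:
    """Summary category an annotator should report for this protein.

    Applies the annotator's precedence rule to the embedded signal plus the
    audited incidental signals.
    """
    if table is None:
        table = default_tables()
    signals = list(truth.incidental_signals)
    embedded = _embedded_evidence(truth.kind, truth.motif, truth.position, table)
    if embedded is not None:
        signals.append(embedded)
    if any(s.signal == "pts2" for s in signals):
        return CAT_PTS2
    terminal = [s for s in signals if s.signal == "terminal_pts1"]
    if terminal:
        return CAT_PTS1_CANONICAL if terminal[0].label == CANONICAL else CAT_PTS1_NONCANONICAL
    if any(s.signal == "internal_pts1" for s in signals):
        return CAT_INTERNAL
    return CAT_NONE


def truth_frame(truths: Sequence[TruthRecord]) -> pd.DataFrame:
    """Truth records as a DataFrame (TSV-ready)."""
    return pd.DataFrame(
        {
            "protein_id": [t.protein_id for t in truths],
            "kind": [t.kind for t in truths],
            "motif": [t.motif or "." for t in truths],
            "position": [t.position for t in truths],
            "incidental_signals": [
                ";".join(s.token() for s in t.incidental_signals) or "." for t in truths
            ],
        }
    )
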