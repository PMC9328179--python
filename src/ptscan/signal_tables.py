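"""Residue-class tables and the PTS2 consensus specification.

The PTS1 classifier is driven by a per-position partition of the 20 standard
amino acids into three classes:

* ``high`` — high-abundance (canonical) residues, i.e. the classical
  C-terminal tripeptide consensus [SA] at -3, [KR] at -2, [LMI] at -1;
* ``low`` — low-abundance (non-canonical) residues, rare but experimentally
  demonstrated to support peroxisomal import at that position;
* ``unproven`` — everything else: residues never shown to occur in a
  functional PTS1 at that position (implied, never stored).

The PTS2 scanner is driven by a degenerate nonapeptide consensus,
``[RK][LVIQ]xx[LVIHQ][LSGAK]x[HQ][LAF]``, with positions numbered 1 (N-side)
to 9.  Because experimentally observed PTS2 domains deviate from the strict
consensus at the weakly constrained middle positions, the matcher also has a
*relaxed* mode in which only a set of anchor positions (default {1, 8, 9}:
the invariant arginine/lysine, histidine/glutamine and terminal hydrophobic
residue) must conform, with remaining deviations reported rather than
disqualifying.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

from .errors import ConfigurationError, InputError, TableValidationError

#: The 20 standard one-letter amino-acid codes.
STANDARD_AA: frozenset[str] = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: PTS1 tripeptide positions, N->C order, numbered from the C terminus.
PTS1_POSITIONS: tuple[int, int, int] = (-3, -2, -1)

HIGH = "high"
LOW = "low"
UNPROVEN = "unproven"


@dataclass(frozen=True)
class ResidueClassTable:
    """Per-position partition of residues into high / low / unproven classes.

    Parameters
    ----------
    high, low
        Maps from PTS1 position (-3, -2, -1) to the set of one-letter codes
        in that class.  The unproven class is implied: the 20 standard
        residues minus (high ∪ low).
    """

    high: Mapping[int, frozenset[str]]
    low: Mapping[int, frozenset[str]]

    def __post_init__(self) -> None:
        for pos in PTS1_POSITIONS:
            if pos not in self.high or pos not in self.low:
                raise TableValidationError(f"missing position {pos} in residue-class table")
            hi, lo = self.high[pos], self.low[pos]
            if not hi:
                raise TableValidationError(f"high-abundance set at position {pos} is empty")
            for res in hi | lo:
                if res not in STANDARD_AA:
                    raise TableValidationError(
                        f"position {pos}: {res!r} is not a standard one-letter amino-acid code"
                    )
            overlap = hi & lo
            if overlap:
                raise TableValidationError(
                    f"position {pos}: residue(s) {sorted(overlap)} listed as both "
                    "high- and low-abundance"
                )

    def unproven(self, position: int) -> frozenset[str]:
        """Residues with no demonstrated PTS1 function at *position*."""
        self._check_position(position)
        return STANDARD_AA - self.high[position] - self.low[position]

    def residue_class(self, position: int, residue: str) -> str:
        """Class of *residue* at *position*: ``high``, ``low`` or ``unproven``.

        Lookup is case-insensitive.  Non-standard letters (X, B, Z, U, ``*``)
        fall to ``unproven`` with a warning.
        """
        self._check_position(position)
        res = residue.upper()
        if res not in STANDARD_AA:
            warnings.warn(
                f"non-standard residue {residue!r} treated as unproven at position {position}",
                stacklevel=2,
            )
            return UNPROVEN
        if res in self.high[position]:
            return HIGH
        if res in self.low[position]:
            return LOW
        return UNPROVEN

    @staticmethod
    def _check_position(position: int) -> None:
        if position not in PTS1_POSITIONS:
            raise InputError(f"PTS1 position must be one of {PTS1_POSITIONS}, got {position}")

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            str(pos): {
                "high": sorted(self.high[pos]),
                "low": sorted(self.low[pos]),
            }
            for pos in PTS1_POSITIONS
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "ResidueClassTable":
        try:
            high = {int(pos): frozenset(spec["high"]) for pos, spec in data.items()}
            low = {int(pos): frozenset(spec.get("low", ())) for pos, spec in data.items()}
        except (TypeError, KeyError, ValueError, AttributeError) as exc:
            raise ConfigurationError(f"malformed residue-class table: {exc}") from exc
        return cls(high=high, low=low)


# Default table.  The canonical (high-abundance) sets are the classical
# tripeptide consensus; the low-abundance sets collect every residue with a
# demonstrated functional non-canonical PTS1 at that position in the plant
# literature inventory this package ships (e.g. P/T at -3 from PKL>/TKL>,
# N/S/Y/H/M/L/A at -2 from SNL>/SSL>/SYM>/AHL>/SML>/SLM>/SAK>, F/V/Y at -1
# from SRF>/AKV>/SRY>).
_DEFAULT = ResidueClassTable(
    high={
        -3: frozenset("SA"),
        -2: frozenset("KR"),
        -1: frozenset("LMI"),
    },
    low={
        -3: frozenset("PTQIV"),
        -2: frozenset("NSTYHMLQFA"),
        -1: frozenset("FVY"),
    },
)


def default_tables() -> ResidueClassTable:
    """The built-in residue-class table (see module docstring)."""
    return _DEFAULT


def load_tables(path: str | Path) -> ResidueClassTable:
    """Load and validate a residue-class table from a JSON config file.

    Schema: ``{"-3": {"high": [...], "low": [...]}, "-2": ..., "-1": ...}``.
    """
    path = Path(path)
    try:
        text = path.read_text()
        data = json.loads(text)
    except OSError as exc:
        raise ConfigurationError(f"cannot read residue-class table {path}: {exc}") from exc
    except json.JSONDecodeError as exc:
        raise ConfigurationError(f"residue-class table {path} is not valid JSON: {exc}") from exc
    if not isinstance(data, dict) or not data:
        raise ConfigurationError(f"residue-class table {path} must be a non-empty JSON object")
    return ResidueClassTable.from_dict(data)


def dump_tables(table: ResidueClassTable, path: str | Path) -> None:
    """Serialize *table* to JSON (round-trips through :func:`load_tables`)."""
    Path(path).write_text(json.dumps(table.to_dict(), indent=2, sort_keys=True) + "\n")


# -- PTS2 consensus --------------------------------------------------------

#: Strict published consensus: position -> allowed residues (None = wildcard).
STRICT_PTS2_ALLOWED: dict[int, frozenset[str] | None] = {
    1: frozenset("RK"),
    2: frozenset("LVIQ"),
    3: None,
    4: None,
    5: frozenset("LVIHQ"),
    6: frozenset("LSGAK"),
    7: None,
    8: frozenset("HQ"),
    9: frozenset("LAF"),
}

STRICT = "strict"
RELAXED = "relaxed"


@dataclass(frozen=True)
class Pts2ConsensusSpec:
    """The nonapeptide consensus plus matching mode.

    ``mode="strict"`` requires every constrained position to conform;
    ``mode="relaxed"`` requires only ``anchors`` to conform and reports the
    remaining non-conforming positions as deviations.
    """

    allowed: Mapping[int, frozenset[str] | None] = field(
        default_factory=lambda: dict(STRICT_PTS2_ALLOWED)
    )
    mode: str = RELAXED
    anchors: frozenset[int] = frozenset({1, 8, 9})

    def __post_init__(self) -> None:
        if self.mode not in (STRICT, RELAXED):
            raise ConfigurationError(f"PTS2 mode must be 'strict' or 'relaxed', got {self.mode!r}")
        if set(self.allowed) != set(range(1, 10)):
            raise ConfigurationError("PTS2 consensus must specify positions 1..9")
        if not self.anchors <= set(range(1, 10)):
            raise ConfigurationError("anchor positions must lie within 1..9")

    def constrained_positions(self) -> tuple[int, ...]:
        return tuple(p for p in range(1, 10) if self.allowed[p] is not None)


def default_pts2_spec(mode: str = RELAXED) -> Pts2ConsensusSpec:
    """The published PTS2 consensus with the given matching mode."""
    return Pts2ConsensusSpec(mode=mode)
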