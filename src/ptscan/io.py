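"""FASTA / TSV / JSON readers and writers, and the end-to-end pipeline.

TSV dialect: tab-separated, UTF-8, header row, no quoting, '.' for missing
values.  All outputs are deterministic for identical inputs and
configuration.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
from Bio import SeqIO

from .annotate import (
    AnnotatorOptions,
    DEFAULT_OPTIONS,
    ProteinAnnotation,
    Pts1Call,
    annotate_proteome,
)
from .compare import OrthologMap, build_report, compare_proteomes
from .errors import ConfigurationError, FastaParseError
from .propensity import compute_propensity, format_table
from .signal_tables import default_pts2_spec, default_tables, load_tables

logger = logging.getLogger("ptscan")

MISSING = "."


@dataclass(frozen=True)
class FastaRecord:
    id: str
    description: str
    seq: str


def _header_line_numbers(path: Path) -> list[int]:
    return [i for i, line in enumerate(path.read_text().splitlines(), 1) if line.startswith(">")]


def read_fasta(path: str | Path) -> list[FastaRecord]:
    """Ordered records with wrapped lines joined and sequences upper-cased.

    The description after the first whitespace of the header is preserved
    separately.  A trailing stop symbol '*' is stripped with a warning.
    Records with empty sequences (and non-FASTA content) raise
    :class:`FastaParseError` with a line number.
    """
    path = Path(path)
    if not path.exists():
        raise FastaParseError(f"no such file: {path}")
    try:
        records = list(SeqIO.parse(str(path), "fasta"))
    except ValueError as exc:
        raise FastaParseError(f"{path}:1: {exc}") from exc
    headers = _header_line_numbers(path)
    if not records:
        if path.read_text().strip():
            raise FastaParseError(f"{path}:1: not a FASTA file (no '>' records found)")
        return []
    out = []
    for k, rec in enumerate(records):
        line = headers[k] if k < len(headers) else 0
        seq = str(rec.seq).upper()
        if seq.endswith("*"):
            warnings.warn(f"{path}:{line}: stripped trailing stop symbol from {rec.id}")
            seq = seq.rstrip("*")
        if not seq:
            raise FastaParseError(f"{path}:{line}: record {rec.id!r} has an empty sequence")
        out.append(FastaRecord(id=rec.id, description=rec.description, seq=seq))
    return out


def write_fasta(records: Sequence[tuple[str, str]], path: str | Path, width: int = 60) -> None:
    """Write (id, sequence) pairs as wrapped FASTA."""
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# -- annotation TSV --------------------------------------------------------

ANNOTATION_COLUMNS = (
    "id",
    "length",
    "terminal_tripeptide",
    "pts1_label",
    "low_position",
    "pts2_best_start",
    "pts2_deviations",
    "internal_hits",
    "summary_category",
    "dual_signal",
)


def annotations_to_frame(annotations: Sequence[ProteinAnnotation]) -> pd.DataFrame:
    """One TSV-ready row per protein annotation."""
    rows = []
    for a in annotations:
        best = next((m for m in a.pts2_matches if not m.internal), None) or (
            a.pts2_matches[0] if a.pts2_matches else None
        )
        rows.append(
            {
                "id": a.protein_id,
                "length": a.length,
                "terminal_tripeptide": a.terminal.tripeptide if a.terminal else MISSING,
                "pts1_label": a.terminal.label if a.terminal else MISSING,
                "low_position": (
                    ";".join(str(p) for p in sorted(a.terminal.low_position))
                    if a.terminal and a.terminal.low_position
                    else MISSING
                ),
                "pts2_best_start": best.start if best else MISSING,
                "pts2_deviations": (
                    ";".join(f"{pos}{res}" for pos, res in best.deviations)
                    if best and best.deviations
                    else MISSING
                ),
                "internal_hits": (
                    ";".join(h.token() for h in a.internal_hits) if a.internal_hits else MISSING
                ),
                "summary_category": a.summary_category,
                "dual_signal": int(a.dual_signal),
            }
        )
    return pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)


def write_annotations(annotations: Sequence[ProteinAnnotation], path: str | Path) -> None:
    annotations_to_frame(annotations).to_csv(path, sep="\t", index=False)


def read_annotations(path: str | Path) -> pd.DataFrame:
    """Read an annotation TSV back; missing cells stay as the '.' sentinel."""
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)


def _minimal_annotations(frame: pd.DataFrame) -> list[ProteinAnnotation]:
    """Rebuild just enough annotation structure from a TSV for tallying/set ops."""
    anns = []
    for row in frame.itertuples(index=False):
        terminal = None
        if row.pts1_label != MISSING:
            low = (
                frozenset(int(p) for p in row.low_position.split(";"))
                if row.low_position != MISSING
                else frozenset()
            )
            terminal = Pts1Call(
                tripeptide=row.terminal_tripeptide,
                classes=("", "", ""),
                label=row.pts1_label,
                low_position=low,
            )
        anns.append(
            ProteinAnnotation(
                protein_id=row.id,
                length=int(row.length),
                terminal=terminal,
                internal_hits=(),
                pts2_matches=(),
                summary_category=row.summary_category,
                dual_signal=bool(int(row.dual_signal)),
            )
        )
    return anns


def pts2_nonapeptides(annotations: Sequence[ProteinAnnotation]) -> list[str]:
    """Best (first non-internal) PTS2 nonapeptide of each PTS2-matching protein."""
    out = []
    for a in annotations:
        best = next((m for m in a.pts2_matches if not m.internal), None)
        if best is not None:
            out.append(best.nonapeptide)
    return out


# -- pipeline --------------------------------------------------------------


@dataclass
class PipelineConfig:
    """Paths and options for the end-to-end run."""

    fasta: dict[str, str | Path] = field(default_factory=dict)  # species name -> FASTA path
    ortholog_map: str | Path | None = None
    tables: str | Path | None = None  # residue-class table JSON; None = built-in
    out_dir: str | Path = "ptscan_out"
    options: AnnotatorOptions = DEFAULT_OPTIONS
    compare: bool = True

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        try:
            data = json.loads(Path(path).read_text())
        except (OSError, json.JSONDecodeError) as exc:
            raise ConfigurationError(f"cannot read pipeline config {path}: {exc}") from exc
        opt_kwargs = data.get("options", {})
        try:
            options = AnnotatorOptions(**opt_kwargs)
        except TypeError as exc:
            raise ConfigurationError(f"bad annotator options: {exc}") from exc
        return cls(
            fasta=data.get("fasta", {}),
            ortholog_map=data.get("ortholog_map"),
            tables=data.get("tables"),
            out_dir=data.get("out_dir", "ptscan_out"),
            options=options,
            compare=data.get("compare", True),
        )


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Annotate each species, write annotation + propensity TSVs, and (for two
    species) the comparative report.  Returns the paths written."""
    if not config.fasta:
        raise ConfigurationError("pipeline config lists no FASTA inputs")
    if config.compare and len(config.fasta) == 2 and config.ortholog_map is None:
        logger.info("no ortholog map given; comparative report will list no orphans")
    table = load_tables(config.tables) if config.tables else default_tables()
    spec = default_pts2_spec(mode=config.options.pts2_mode)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    per_species: dict[str, list[ProteinAnnotation]] = {}
    for species, fasta_path in config.fasta.items():
        records = read_fasta(fasta_path)
        anns = annotate_proteome([(r.id, r.seq) for r in records], table, spec, config.options)
        per_species[species] = anns
        ann_path = out_dir / f"{species}.annotations.tsv"
        write_annotations(anns, ann_path)
        artifacts[f"annotations:{species}"] = ann_path
        logger.info("%s: %d proteins annotated", species, len(anns))
        nonas = pts2_nonapeptides(anns)
        if nonas:
            prop_path = out_dir / f"{species}.propensity.tsv"
            format_table(compute_propensity(nonas)).to_csv(prop_path, sep="\t", index=False)
            artifacts[f"propensity:{species}"] = prop_path
            logger.info("%s: propensity table over %d PTS2 nonapeptides", species, len(nonas))
    if config.compare and len(per_species) == 2:
        (name_a, anns_a), (name_b, anns_b) = per_species.items()
        omap = OrthologMap.from_tsv(config.ortholog_map) if config.ortholog_map else None
        summary = compare_proteomes(anns_a, anns_b, species=(name_a, name_b), ortholog_map=omap)
        report = build_report(summary)
        json_path = out_dir / "comparative_report.json"
        json_path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
        artifacts["report:json"] = json_path
        tsv_path = out_dir / "comparative_report.tsv"
        _report_tsv(report).to_csv(tsv_path, sep="\t", index=False)
        artifacts["report:tsv"] = tsv_path
        logger.info("comparative report written for (%s, %s)", name_a, name_b)
    return artifacts


def _report_tsv(report: dict) -> pd.DataFrame:
    rows = []
    for species, stats in report["per_species"].items():
        for key in (
            "n_total",
            "n_pts2",
            "n_pts1_canonical",
            "n_pts1_noncanonical",
            "n_no_obvious",
            "n_catalase_internal",
            "n_no_pts_strict",
            "total_pts1",
            "pct_canonical",
        ):
            value = stats[key]
            rows.append({"species": species, "metric": key, "value": MISSING if value is None else value})
        rows.append(
            {
                "species": species,
                "metric": "unique_noncanonical",
                "value": ";".join(stats["unique_noncanonical"]) or MISSING,
            }
        )
    rows.append(
        {
            "species": "both",
            "metric": "shared_noncanonical",
            "value": ";".join(report["shared_noncanonical"]) or MISSING,
        }
    )
    rows.append(
        {"species": "both", "metric": "orphans", "value": ";".join(report["orphans"]) or MISSING}
    )
    return pd.DataFrame(rows, columns=["species", "metric", "value"])
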