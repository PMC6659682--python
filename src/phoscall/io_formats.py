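"""Tabular and sequence I/O for the effector-calling pipeline.

All tables are plain TSV with a header row. Phosphosite and protein tables
follow the MaxQuant convention that an intensity of 0 means "not quantified";
both 0 and empty cells are mapped to missing (NaN) on read. Column names are
configurable through :class:`ColumnMap` so MaxQuant "Phospho (STY)Sites"
exports can be ingested without renaming.

Coordinates are 1-based inclusive (MaxQuant convention). Flanking sequence
windows are 15-mers centered on the phospho-acceptor (positions -7..+7) with
``_`` padding where the window crosses a protein terminus.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import pandas as pd
import yaml
from Bio import SeqIO

CHANNELS = ("H", "M", "L")
FLANK_WIDTH = 7
FLANK_LEN = 2 * FLANK_WIDTH + 1
PAD = "_"


class SchemaError(ValueError):
    """A required column is absent from an input table."""


class ParseError(ValueError):
    """A cell could not be parsed; message carries the 1-based line number."""


class FlankError(LookupError):
    """Flank extraction failed (unknown protein or out-of-range position)."""


# ---------------------------------------------------------------------------
# records


@dataclass
class PhosphoSiteRecord:
    """One quantified phosphosite with localization evidence.

    ``intensities`` maps condition -> replicate -> channel ("H"/"M"/"L") ->
    intensity, with NaN for non-quantified channels. The medium (super-SILAC)
    channel is carried through but never used by downstream statistics.
    """

    site_id: str
    protein_id: str
    position: int
    residue: str
    localization_prob: float
    score_diff: float
    flank: str
    intensities: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.flank) != FLANK_LEN:
            raise ValueError(
                f"flank must be {FLANK_LEN} characters, got {len(self.flank)!r}"
            )
        if self.flank[FLANK_WIDTH] != self.residue:
            raise ValueError(
                f"flank center {self.flank[FLANK_WIDTH]!r} does not match "
                f"residue {self.residue!r}"
            )
        if not 0.0 <= self.localization_prob <= 1.0:
            raise ValueError("localization_prob must lie in [0, 1]")


@dataclass
class ProteinRecord:
    """Per-protein SILAC channel intensities, same nesting as phosphosites."""

    protein_id: str
    intensities: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# column mapping


@dataclass(frozen=True)
class ColumnMap:
    """Maps record fields to table columns.

    ``intensity_pattern`` is a format string with ``{channel}``,
    ``{condition}`` and ``{replicate}`` placeholders; replicate numbers are
    1-based integers.
    """

    site_id: str = "site_id"
    protein_id: str = "protein_id"
    position: str = "position"
    residue: str = "residue"
    localization_prob: str = "localization_prob"
    score_diff: str = "score_diff"
    flank: str = "flank"
    intensity_pattern: str = "intensity_{channel}_{condition}_{replicate}"

    def intensity_column(self, channel: str, condition: str, replicate: int) -> str:
        return self.intensity_pattern.format(
            channel=channel, condition=condition, replicate=replicate
        )

    def intensity_regex(self) -> re.Pattern:
        pat = re.escape(self.intensity_pattern)
        pat = pat.replace(re.escape("{channel}"), r"(?P<channel>[HML])")
        pat = pat.replace(re.escape("{condition}"), r"(?P<condition>.+?)")
        pat = pat.replace(re.escape("{replicate}"), r"(?P<replicate>\d+)")
        return re.compile("^" + pat + "$")


#: Preset for MaxQuant "Phospho (STY)Sites.txt" exports where experiments are
#: named ``<condition>_<replicate>``.
MAXQUANT_COLUMNS = ColumnMap(
    site_id="id",
    protein_id="Protein",
    position="Position",
    residue="Amino acid",
    localization_prob="Localization prob",
    score_diff="Score diff",
    flank="Sequence window",
    intensity_pattern="Intensity {channel} {condition}_{replicate}",
)


def _parse_intensity(cell, line_no: int, column: str) -> float:
    if cell is None or (isinstance(cell, float) and math.isnan(cell)):
        return math.nan
    text = str(cell).strip()
    if text == "" or text.lower() in {"nan", "na"}:
        return math.nan
    try:
        value = float(text)
    except ValueError:
        raise ParseError(
            f"line {line_no}: cannot parse {text!r} in column {column!r}"
        ) from None
    if value < 0:
        raise ParseError(f"line {line_no}: negative intensity in column {column!r}")
    # MaxQuant writes 0 for channels that were not quantified
    return math.nan if value == 0 else value


def _parse_number(cell, line_no: int, column: str, caster=float):
    try:
        return caster(cell)
    except (TypeError, ValueError):
        raise ParseError(
            f"line {line_no}: cannot parse {cell!r} in column {column!r}"
        ) from None


def _intensity_layout(columns, cmap: ColumnMap):
    """Infer (conditions, replicates, column lookup) from table headers."""
    rx = cmap.intensity_regex()
    layout: dict[tuple[str, str, int], str] = {}
    conditions: list[str] = []
    replicates: set[int] = set()
    for col in columns:
        m = rx.match(col)
        if not m:
            continue
        cond = m.group("condition")
        rep = int(m.group("replicate"))
        layout[(m.group("channel"), cond, rep)] = col
        if cond not in conditions:
            conditions.append(cond)
        replicates.add(rep)
    return conditions, sorted(replicates), layout


def read_phosphosite_table(path, column_map: ColumnMap | None = None):
    """Read a phosphosite TSV into a list of :class:`PhosphoSiteRecord`.

    Raises :class:`SchemaError` naming any absent required column and
    :class:`ParseError` (with 1-based line number) on malformed numbers.
    """
    cmap = column_map or ColumnMap()
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = [
        cmap.site_id, cmap.protein_id, cmap.position, cmap.residue,
        cmap.localization_prob, cmap.score_diff, cmap.flank,
    ]
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"required column {col!r} missing from {path}")
    conditions, replicates, layout = _intensity_layout(df.columns, cmap)
    if not layout:
        raise SchemaError(
            f"no intensity columns matching pattern {cmap.intensity_pattern!r}"
        )

    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        line_no = i + 2  # header is line 1
        row = dict(zip(df.columns, row))
        intensities = {
            cond: {
                rep: {
                    ch: _parse_intensity(row.get(layout.get((ch, cond, rep))),
                                         line_no, str(layout.get((ch, cond, rep))))
                    if (ch, cond, rep) in layout else math.nan
                    for ch in CHANNELS
                }
                for rep in replicates
            }
            for cond in conditions
        }
        records.append(PhosphoSiteRecord(
            site_id=str(row[cmap.site_id]),
            protein_id=str(row[cmap.protein_id]),
            position=_parse_number(row[cmap.position], line_no, cmap.position, int),
            residue=str(row[cmap.residue]),
            localization_prob=_parse_number(
                row[cmap.localization_prob], line_no, cmap.localization_prob),
            score_diff=_parse_number(row[cmap.score_diff], line_no, cmap.score_diff),
            flank=str(row[cmap.flank]),
            intensities=intensities,
        ))
    return records


def read_protein_table(path, column_map: ColumnMap | None = None):
    """Read a protein-group TSV into a list of :class:`ProteinRecord`."""
    cmap = column_map or ColumnMap()
    df = pd.read_csv(path, sep="\t", dtype=str)
    if cmap.protein_id not in df.columns:
        raise SchemaError(f"required column {cmap.protein_id!r} missing from {path}")
    conditions, replicates, layout = _intensity_layout(df.columns, cmap)
    if not layout:
        raise SchemaError(
            f"no intensity columns matching pattern {cmap.intensity_pattern!r}"
        )
    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        line_no = i + 2
        row = dict(zip(df.columns, row))
        intensities = {
            cond: {
                rep: {
                    ch: _parse_intensity(row.get(layout.get((ch, cond, rep))),
                                         line_no, str(layout.get((ch, cond, rep))))
                    if (ch, cond, rep) in layout else math.nan
                    for ch in CHANNELS
                }
                for rep in replicates
            }
            for cond in conditions
        }
        records.append(ProteinRecord(protein_id=str(row[cmap.protein_id]),
                                     intensities=intensities))
    return records


def write_phosphosite_table(records, path, column_map: ColumnMap | None = None):
    cmap = column_map or ColumnMap()
    rows = []
    for rec in records:
        row = {
            cmap.site_id: rec.site_id,
            cmap.protein_id: rec.protein_id,
            cmap.position: rec.position,
            cmap.residue: rec.residue,
            cmap.localization_prob: rec.localization_prob,
            cmap.score_diff: rec.score_diff,
            cmap.flank: rec.flank,
        }
        for cond, reps in rec.intensities.items():
            for rep, channels in reps.items():
                for ch, value in channels.items():
                    row[cmap.intensity_column(ch, cond, rep)] = (
                        "" if value is None or math.isnan(value) else repr(value)
                    )
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_protein_table(records, path, column_map: ColumnMap | None = None):
    cmap = column_map or ColumnMap()
    rows = []
    for rec in records:
        row = {cmap.protein_id: rec.protein_id}
        for cond, reps in rec.intensities.items():
            for rep, channels in reps.items():
                for ch, value in channels.items():
                    row[cmap.intensity_column(ch, cond, rep)] = (
                        "" if value is None or math.isnan(value) else repr(value)
                    )
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# FASTA flank extraction


def extract_flank(sequence: str, position: int) -> str:
    """15-mer window around a 1-based position, ``_``-padded at termini."""
    if not 1 <= position <= len(sequence):
        raise FlankError(
            f"position {position} outside sequence of length {len(sequence)}"
        )
    idx = position - 1
    left = sequence[max(0, idx - FLANK_WIDTH):idx]
    right = sequence[idx + 1:idx + 1 + FLANK_WIDTH]
    return PAD * (FLANK_WIDTH - len(left)) + left + sequence[idx] + right \
        + PAD * (FLANK_WIDTH - len(right))


def extract_flanks(fasta_path, sites):
    """Map ``(protein_id, position)`` pairs to 15-mer flanks from a FASTA file."""
    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")}
    flanks = {}
    for protein_id, position in sites:
        if protein_id not in seqs:
            raise FlankError(f"protein {protein_id!r} not found in {fasta_path}")
        flanks[(protein_id, position)] = extract_flank(seqs[protein_id], position)
    return flanks


# ---------------------------------------------------------------------------
# derived tables, PSSM matrices, config


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"])


PSSM_POSITIONS = ["-5", "-4", "-3", "-2", "-1", "+1", "+2", "+3", "+4"]


def write_pssm(values: pd.DataFrame, path) -> None:
    """Write a residues x positions matrix as TSV (first column ``residue``)."""
    out = values.copy()
    out.columns = [str(c) for c in out.columns]
    out.index.name = "residue"
    out.reset_index().to_csv(path, sep="\t", index=False)


def read_pssm(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "residue" not in df.columns:
        raise SchemaError(f"required column 'residue' missing from {path}")
    df = df.set_index("residue")
    missing = [p for p in PSSM_POSITIONS if p not in df.columns]
    if missing:
        raise SchemaError(f"PSSM {path} missing position columns {missing}")
    return df[PSSM_POSITIONS].astype(float)


def read_site_list(path) -> list[str]:
    """One site_id per line; blank lines and ``#`` comments ignored."""
    with open(path) as fh:
        return [ln.strip() for ln in fh
                if ln.strip() and not ln.lstrip().startswith("#")]


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}
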