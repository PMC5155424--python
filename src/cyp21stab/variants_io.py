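"""Protein-level variant labels and the tab-separated tables the pipeline consumes.

Variants are described at the protein level only ("p.L107Q" style), 1-based on
the CYP21A2 reference protein sequence. Both one-letter and three-letter amino
acid codes are accepted on input; the canonical form is one-letter. Activities
are percentages of wild-type enzyme activity, per substrate.
"""

from __future__ import annotations

import enum
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, TextIO, Union

import pandas as pd

# --------------------------------------------------------------------------
# Amino-acid code tables
# --------------------------------------------------------------------------

AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA1 = set(AA3_TO_1.values())
AA1_TO_3 = {v: k.capitalize() for k, v in AA3_TO_1.items()}

#: Symbolic mutant tokens: premature stop and frameshift.
STOP_TOKEN = "X"
FRAMESHIFT_TOKEN = "fs"

#: Default protein length bound; the reference protein is 494-495 residues
#: depending on the isoform convention, so the bound is configurable.
DEFAULT_MAX_POSITION = 495


class VariantKind(enum.Enum):
    MISSENSE = "missense"
    NONSENSE = "nonsense"
    FRAMESHIFT = "frameshift"
    SYNONYMOUS = "synonymous"
    INDEL_OR_OTHER = "indel_or_other"


class Substrate(enum.Enum):
    """Substrates of the 21-hydroxylation reaction used in activity assays."""

    OHP17 = "17-OHP"
    PROGESTERONE = "progesterone"


class VariantParseError(ValueError):
    """Raised when a protein-variant label does not match the grammar."""


@dataclass(frozen=True)
class ProteinVariant:
    """One protein-level sequence change.

    ``mut_residue`` is a one-letter code, ``"X"`` for a premature stop, or
    ``"fs"`` for a frameshift.
    """

    wt_residue: str
    position: int
    mut_residue: str
    kind: VariantKind = field(compare=False)
    raw_label: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if self.position < 1:
            raise VariantParseError(f"position must be >= 1, got {self.position}")
        if self.wt_residue not in AA1:
            raise VariantParseError(f"unknown wild-type residue {self.wt_residue!r}")
        if self.mut_residue not in AA1 | {STOP_TOKEN, FRAMESHIFT_TOKEN}:
            raise VariantParseError(f"unknown mutant token {self.mut_residue!r}")

    @property
    def label(self) -> str:
        """Canonical one-letter label, e.g. ``p.L107Q``."""
        return f"p.{self.wt_residue}{self.position}{self.mut_residue}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.label


@dataclass(frozen=True)
class ActivityMeasurement:
    """In vitro residual activity (% of wild type) for one variant/substrate."""

    variant: ProteinVariant
    substrate: Substrate
    activity_pct: float
    sd_pct: Optional[float] = None
    source: str = ""

    def __post_init__(self) -> None:
        if not math.isfinite(self.activity_pct):
            raise ValueError("activity_pct must be finite")
        if self.activity_pct < 0:
            raise ValueError(f"activity_pct must be >= 0, got {self.activity_pct}")
        if self.sd_pct is not None and self.sd_pct < 0:
            raise ValueError("sd_pct must be non-negative")


# --------------------------------------------------------------------------
# Label grammar
# --------------------------------------------------------------------------

_LABEL_RE = re.compile(
    r"""^p\.
        (?P<wt>[A-Z][a-z]{2}|[A-Z])          # wild-type residue, 1- or 3-letter
        (?P<pos>\d+)
        (?P<mut>[A-Z][a-z]{2}|fs|Ter|\*|[A-Z])  # mutant residue / stop / fs
        $""",
    re.VERBOSE,
)


def _normalize_residue(token: str, *, what: str) -> str:
    if len(token) == 3:
        try:
            return AA3_TO_1[token.upper()]
        except KeyError:
            raise VariantParseError(f"unknown {what} residue code {token!r}") from None
    if token in AA1:
        return token
    raise VariantParseError(f"unknown {what} residue code {token!r}")


def _kind_for(wt: str, mut: str) -> VariantKind:
    if mut == FRAMESHIFT_TOKEN:
        return VariantKind.FRAMESHIFT
    if mut == STOP_TOKEN:
        return VariantKind.NONSENSE
    if wt == mut:
        return VariantKind.SYNONYMOUS
    return VariantKind.MISSENSE


def parse_protein_variant(
    label: str, *, max_position: int = DEFAULT_MAX_POSITION
) -> ProteinVariant:
    """Parse a protein-level variant label such as ``p.L107Q`` or ``p.H466fs``.

    Three-letter codes (``p.Leu107Gln``), ``Ter``/``*`` stop spellings and the
    ``fs`` frameshift suffix are accepted and normalised. The kind is derived
    deterministically: wt == mut -> synonymous, stop -> nonsense, ``fs`` ->
    frameshift, otherwise missense.
    """
    raw = label
    stripped = label.strip()
    m = _LABEL_RE.match(stripped)
    if m is None:
        raise VariantParseError(f"malformed variant label {label!r}")
    wt = _normalize_residue(m.group("wt"), what="wild-type")
    pos = int(m.group("pos"))
    if pos < 1:
        raise VariantParseError(f"position must be >= 1 in {label!r}")
    if pos > max_position:
        raise VariantParseError(
            f"position {pos} exceeds protein length bound {max_position} in {label!r}"
        )
    mut_token = m.group("mut")
    if mut_token == FRAMESHIFT_TOKEN:
        mut = FRAMESHIFT_TOKEN
    elif mut_token in {"Ter", "*", STOP_TOKEN}:
        mut = STOP_TOKEN
    else:
        mut = _normalize_residue(mut_token, what="mutant")
    return ProteinVariant(wt, pos, mut, _kind_for(wt, mut), raw_label=raw)


def format_protein_variant(variant: ProteinVariant, *, three_letter: bool = False) -> str:
    """Inverse of :func:`parse_protein_variant` (canonical one-letter by default)."""
    if not three_letter:
        return variant.label
    wt3 = AA1_TO_3[variant.wt_residue]
    if variant.mut_residue in (STOP_TOKEN, FRAMESHIFT_TOKEN):
        mut3 = "Ter" if variant.mut_residue == STOP_TOKEN else "fs"
    else:
        mut3 = AA1_TO_3[variant.mut_residue]
    return f"p.{wt3}{variant.position}{mut3}"


# --------------------------------------------------------------------------
# Display convention for activities
# --------------------------------------------------------------------------

def format_activity(value: float, *, capped: bool = False) -> str:
    """Format a percent activity with the survey tables' mixed precision.

    One decimal for values >= 0.1, two decimals below 0.1; exact integers are
    printed without a decimal part; cap-saturated predictions render ``>=100``.
    """
    if capped:
        return "≥100"
    if float(value).is_integer():
        return str(int(value))
    if value < 0.1:
        return f"{value:.2f}"
    return f"{value:.1f}"


def parse_activity_cell(cell: str) -> tuple[Optional[float], bool]:
    """Parse an activity cell; returns (value, capped_flag), (None, False) if empty."""
    text = str(cell).strip()
    if text == "" or text.lower() in {"nan", "nd", "na"}:
        return None, False
    if text.startswith(("≥", ">=")):
        return float(text.lstrip("≥>=")), True
    return float(text), False


# --------------------------------------------------------------------------
# Tables
# --------------------------------------------------------------------------

#: Default column names; overridable through ``column_map``.
DEFAULT_COLUMNS = {
    "variant": "variant",
    "substrate": "substrate",
    "activity": "activity_pct",
    "sd": "sd_pct",
    "source": "source",
}

_SUBSTRATE_ALIASES = {
    "17-ohp": Substrate.OHP17,
    "17ohp": Substrate.OHP17,
    "ohp17": Substrate.OHP17,
    "17-hydroxyprogesterone": Substrate.OHP17,
    "progesterone": Substrate.PROGESTERONE,
    "p": Substrate.PROGESTERONE,
}


def parse_substrate(token: str) -> Substrate:
    key = str(token).strip().lower()
    try:
        return _SUBSTRATE_ALIASES[key]
    except KeyError:
        raise ValueError(f"unknown substrate {token!r}") from None


@dataclass
class VariantRecord:
    """One parsed table row: variant plus optional measurement and annotations."""

    variant: ProteinVariant
    measurement: Optional[ActivityMeasurement] = None
    annotations: dict = field(default_factory=dict)


class TableFormatError(ValueError):
    pass


def read_variant_table(
    path: Union[str, Path, TextIO],
    *,
    dialect: str = "tsv",
    column_map: Optional[dict] = None,
    max_position: int = DEFAULT_MAX_POSITION,
) -> list[VariantRecord]:
    """Read a variant/activity table (TSV default, CSV via ``dialect="csv"``).

    Empty activity cells yield absent measurements, never zeros. Rows failing
    validation raise with their line number. Duplicate variant+substrate rows
    keep the last occurrence.
    """
    sep = {"tsv": "\t", "csv": ","}[dialect]
    cols = {**DEFAULT_COLUMNS, **(column_map or {})}
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if cols["variant"] not in df.columns:
        raise TableFormatError(
            f"missing mandatory variant column {cols['variant']!r}; "
            f"found {list(df.columns)}"
        )
    records: dict[tuple, VariantRecord] = {}
    for i, row in df.iterrows():
        line_no = i + 2  # header is line 1
        try:
            variant = parse_protein_variant(row[cols["variant"]], max_position=max_position)
            measurement = None
            substrate = None
            if cols["substrate"] in df.columns and str(row[cols["substrate"]]).strip():
                substrate = parse_substrate(row[cols["substrate"]])
            if cols["activity"] in df.columns:
                value, _capped = parse_activity_cell(row[cols["activity"]])
                if value is not None:
                    if substrate is None:
                        raise ValueError(
                            "activity given without an explicit substrate"
                        )
                    sd = None
                    if cols["sd"] in df.columns and str(row[cols["sd"]]).strip():
                        sd = float(row[cols["sd"]])
                    source = str(row.get(cols["source"], "") or "")
                    measurement = ActivityMeasurement(
                        variant, substrate, value, sd, source
                    )
            annotations = {
                c: row[c]
                for c in df.columns
                if c not in set(cols.values()) and str(row[c]).strip() != ""
            }
        except (VariantParseError, ValueError) as exc:
            raise TableFormatError(f"line {line_no}: {exc}") from exc
        key = (variant.label, substrate)
        records[key] = VariantRecord(variant, measurement, annotations)
    return list(records.values())


def write_report_table(
    records: Sequence, path: Union[str, Path], *, dialect: str = "tsv"
) -> None:
    """Write prediction records to a table re-readable by :func:`read_variant_table`.

    Accepts any objects exposing ``variant`` plus optional prediction fields
    (``ddg_mean``, ``activity_pred_pct``, ``capped_flag``, ``pathogenicity_call``,
    ``severity_band``) or measurement fields. Deterministic column order.
    """
    sep = {"tsv": "\t", "csv": ","}[dialect]
    columns = [
        "variant", "substrate", "activity_pct", "sd_pct",
        "ddg_mean", "predicted_activity", "pathogenicity", "severity_band",
        "source",
    ]
    rows = []
    for rec in records:
        variant = rec.variant
        row = {c: "" for c in columns}
        row["variant"] = variant.label
        meas = getattr(rec, "measurement", None)
        if meas is not None:
            row["substrate"] = meas.substrate.value
            row["activity_pct"] = format_activity(meas.activity_pct)
            if meas.sd_pct is not None:
                row["sd_pct"] = format_activity(meas.sd_pct)
            row["source"] = meas.source
        ddg = getattr(rec, "ddg_mean", None)
        if ddg is not None:
            row["ddg_mean"] = f"{ddg:.2f}"
        pred = getattr(rec, "activity_pred_pct", None)
        if pred is not None:
            row["predicted_activity"] = format_activity(
                pred, capped=bool(getattr(rec, "capped_flag", False))
            )
        call = getattr(rec, "pathogenicity_call", None)
        if call is not None:
            row["pathogenicity"] = getattr(call, "value", str(call))
        band = getattr(rec, "severity_band", None)
        if band is not None:
            row["severity_band"] = getattr(band, "value", str(band))
        rows.append(row)
    pd.DataFrame(rows, columns=columns).to_csv(path, sep=sep, index=False)
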