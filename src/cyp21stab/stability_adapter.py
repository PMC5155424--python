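"""Ingest stability-predictor output and aggregate replica ∆∆G values.

∆∆G is the folding free-energy change of the mutant relative to wild type in
kcal/mol; positive values destabilize. The canonical protocol runs the
predictor five times per mutation and averages; a mutation is called
significantly destabilizing when its mean ∆∆G exceeds 1.6 kcal/mol (twice
the predictor's estimated standard deviation of 0.8 kcal/mol).

Two FoldX-style table layouts are understood ("Dif" per-replica differences
and "Average" pre-aggregated) plus a generic TSV. The predictor itself is
never executed here; for users who have FoldX, the expected upstream
commands are RepairPDB on the template followed by BuildModel with
numberOfRuns=5, whose Dif_*.fxout output this module reads.
"""

from __future__ import annotations

import enum
import logging
import math
import re
import statistics
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

from .variants_io import (
    AA1,
    ProteinVariant,
    VariantParseError,
    parse_protein_variant,
    _kind_for,
)

logger = logging.getLogger(__name__)

CANONICAL_REPLICA_COUNT = 5


class Template(enum.Enum):
    """Structural template the ∆∆G was computed on."""

    HUMAN_4Y8W = "human_4Y8W"
    BOVINE_3QZ1_MODEL = "bovine_3QZ1_model"


_TEMPLATE_ALIASES = {
    "human": Template.HUMAN_4Y8W,
    "4y8w": Template.HUMAN_4Y8W,
    "human_4y8w": Template.HUMAN_4Y8W,
    "crystal": Template.HUMAN_4Y8W,
    "bovine": Template.BOVINE_3QZ1_MODEL,
    "3qz1": Template.BOVINE_3QZ1_MODEL,
    "bovine_3qz1_model": Template.BOVINE_3QZ1_MODEL,
    "model": Template.BOVINE_3QZ1_MODEL,
}


def parse_template(token: str) -> Template:
    try:
        return _TEMPLATE_ALIASES[str(token).strip().lower()]
    except KeyError:
        raise ValueError(f"unknown template {token!r}") from None


@dataclass(frozen=True)
class AnalysisConfig:
    """Thresholds of the stability→activity analysis.

    destabilization_threshold: kcal/mol; strictly greater means significant
        destabilization (1.6 = twice the predictor SD).
    ddg_fit_cap: kcal/mol; ∆∆G values are clamped here before calibration
        fitting because activities near 0% saturate the log-linear relation.
    nonpathogenic_activity_threshold: percent; predictions above it are
        called non-pathogenic.
    activity_cap: percent; predictions clamp here (reported as ">=100").
    """

    destabilization_threshold: float = 1.6
    ddg_fit_cap: float = 5.5
    nonpathogenic_activity_threshold: float = 75.0
    activity_cap: float = 100.0

    def __post_init__(self) -> None:
        for name in ("destabilization_threshold", "ddg_fit_cap",
                     "nonpathogenic_activity_threshold", "activity_cap"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class StabilityEstimate:
    variant: ProteinVariant
    template: Template
    replicas: list
    ddg_mean: float = field(init=False)
    ddg_sd: float = field(init=False)
    provenance: str = ""

    def __post_init__(self) -> None:
        mean, sd = aggregate_replicas(self.replicas)
        self.ddg_mean = mean
        self.ddg_sd = sd

    @classmethod
    def from_summary(
        cls,
        variant: ProteinVariant,
        template: Template,
        ddg_mean: float,
        ddg_sd: float = 0.0,
        provenance: str = "",
    ) -> "StabilityEstimate":
        """Build from a pre-aggregated mean ± SD (replica detail unavailable)."""
        est = cls(variant, template, [ddg_mean], provenance=provenance)
        est.ddg_sd = float(ddg_sd)
        return est


def aggregate_replicas(values: Sequence[float]) -> tuple[float, float]:
    """Arithmetic mean and sample (n−1) standard deviation of replica ∆∆G values.

    A single replica has SD 0 by convention.
    """
    vals = [float(v) for v in values]
    if not vals:
        raise ValueError("at least one replica value is required")
    if any(not math.isfinite(v) for v in vals):
        raise ValueError("replica values must be finite")
    mean = sum(vals) / len(vals)
    sd = statistics.stdev(vals) if len(vals) > 1 else 0.0
    return mean, sd


def is_destabilizing(
    estimate: StabilityEstimate, cfg: AnalysisConfig = AnalysisConfig()
) -> bool:
    """True iff mean ∆∆G is strictly above the destabilization threshold."""
    return estimate.ddg_mean > cfg.destabilization_threshold


# --------------------------------------------------------------------------
# FoldX mutant codes
# --------------------------------------------------------------------------

_FOLDX_CODE_RE = re.compile(r"^(?P<wt>[A-Z])(?P<chain>[A-Za-z])(?P<pos>\d+)(?P<mut>[A-Za-z])$")


def parse_foldx_code(code: str) -> ProteinVariant:
    """Translate a chain-qualified FoldX mutation code (``LA107Q``) to a variant."""
    m = _FOLDX_CODE_RE.match(code.strip().rstrip(";"))
    if m is None:
        raise VariantParseError(f"malformed FoldX mutation code {code!r}")
    wt, mut = m.group("wt"), m.group("mut").upper()
    if wt not in AA1 or mut not in AA1:
        raise VariantParseError(f"unknown residue code in {code!r}")
    pos = int(m.group("pos"))
    return ProteinVariant(wt, pos, mut, _kind_for(wt, mut), raw_label=code)


# --------------------------------------------------------------------------
# Table readers
# --------------------------------------------------------------------------

class DDGTableError(ValueError):
    pass


def _parse_float(token: str, line_no: int) -> float:
    try:
        return float(str(token).replace(",", "."))
    except ValueError:
        raise DDGTableError(f"line {line_no}: unparseable number {token!r}") from None


def _warn_replica_count(label: str, count: int) -> None:
    if count != CANONICAL_REPLICA_COUNT:
        logger.warning(
            "%s has %d replicas (canonical protocol uses %d)",
            label, count, CANONICAL_REPLICA_COUNT,
        )


def _mutation_code_from_pdb_field(token: str) -> str:
    """Strip run suffix / extension from a Dif first column (``LA107Q_3.pdb``)."""
    stem = token.strip().split("/")[-1]
    if stem.lower().endswith(".pdb"):
        stem = stem[:-4]
    return re.sub(r"_\d+$", "", stem)


def _read_foldx(
    path: Union[str, Path], template: Template, averaged: bool
) -> list[StabilityEstimate]:
    lines = Path(path).read_text().splitlines()
    start = 0
    for i, line in enumerate(lines):
        if line.startswith("Pdb\t"):
            start = i + 1
            break
    groups: dict[str, list] = {}
    order: list[str] = []
    for offset, line in enumerate(lines[start:]):
        if not line.strip():
            continue
        fields = line.split("\t")
        code = _mutation_code_from_pdb_field(fields[0])
        value = _parse_float(fields[1], start + offset + 1)
        groups.setdefault(code, []).append(value)
        if code not in order:
            order.append(code)
    estimates = []
    for code in order:
        variant = parse_foldx_code(code)
        values = groups[code]
        if averaged:
            est = StabilityEstimate.from_summary(
                variant, template, values[0], provenance=str(path)
            )
        else:
            _warn_replica_count(code, len(values))
            est = StabilityEstimate(variant, template, values, provenance=str(path))
        estimates.append(est)
    return estimates


def _read_generic_tsv(path: Union[str, Path]) -> list[StabilityEstimate]:
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise DDGTableError(f"{path}: empty file")
    header = [h.strip().lower() for h in lines[0].split("\t")]
    try:
        vcol = header.index("variant")
    except ValueError:
        raise DDGTableError(f"{path}: missing 'variant' column") from None
    tcol = header.index("template") if "template" in header else None
    mean_col = header.index("ddg_mean") if "ddg_mean" in header else None
    sd_col = header.index("ddg_sd") if "ddg_sd" in header else None
    replica_cols = [i for i, h in enumerate(header) if h.startswith("replica")]
    ddg_col = header.index("ddg") if "ddg" in header else None

    estimates = []
    for line_no, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        variant = parse_protein_variant(fields[vcol])
        template = (
            parse_template(fields[tcol]) if tcol is not None and tcol < len(fields)
            and fields[tcol].strip() else Template.BOVINE_3QZ1_MODEL
        )
        if replica_cols:
            values = [
                _parse_float(fields[i], line_no)
                for i in replica_cols
                if i < len(fields) and fields[i].strip()
            ]
            _warn_replica_count(variant.label, len(values))
            est = StabilityEstimate(variant, template, values, provenance=str(path))
        elif mean_col is not None:
            mean = _parse_float(fields[mean_col], line_no)
            sd = (
                _parse_float(fields[sd_col], line_no)
                if sd_col is not None and sd_col < len(fields) and fields[sd_col].strip()
                else 0.0
            )
            est = StabilityEstimate.from_summary(
                variant, template, mean, sd, provenance=str(path)
            )
        elif ddg_col is not None:
            value = _parse_float(fields[ddg_col], line_no)
            est = StabilityEstimate.from_summary(
                variant, template, value, provenance=str(path)
            )
        else:
            raise DDGTableError(
                f"{path}: need 'replica*' columns, a 'ddg_mean' or a 'ddg' column"
            )
        estimates.append(est)
    return estimates


def read_ddg_table(
    path: Union[str, Path],
    dialect: str = "generic_tsv",
    template: Template = Template.BOVINE_3QZ1_MODEL,
) -> list[StabilityEstimate]:
    """Read a ∆∆G table.

    ``dialect`` is one of ``foldx_dif`` (per-replica rows, grouped and
    aggregated), ``foldx_average`` (pre-averaged rows) or ``generic_tsv``
    (columns ``variant``, optional ``template``, and either ``replica*``
    columns, ``ddg_mean``/``ddg_sd``, or a single ``ddg``). For the FoldX
    dialects the template must be supplied by the caller — the .fxout files
    do not record it.
    """
    if dialect == "foldx_dif":
        return _read_foldx(path, template, averaged=False)
    if dialect == "foldx_average":
        return _read_foldx(path, template, averaged=True)
    if dialect == "generic_tsv":
        return _read_generic_tsv(path)
    raise ValueError(f"unknown dialect {dialect!r}")
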