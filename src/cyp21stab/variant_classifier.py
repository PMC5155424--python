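"""Assign each variant to exactly one functional/structural category.

The categories follow the survey taxonomy for CYP21A2 variants: truncating
lesions, heme/ligand contacts, POR-interface residues, degradation and
meander/ERR-triad motif positions, low-resolution exclusions — and, as the
default, "stability": variants whose only plausible effect is a change in
folding free energy. Only the stability class feeds the ∆∆G → activity
calibration; the other classes impair the enzyme through mechanisms a pure
stability model cannot capture.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

from .structure_context import (
    Evidence,
    GeometryConfig,
    IncompleteResidueError,
    StructureContext,
    is_heme_or_ligand_contact,
    is_por_interface,
)
from .variants_io import ProteinVariant, VariantKind


class VariantClass(enum.Enum):
    NONSENSE_INDEL_DEL_DUP = "nonsense_indel_del_dup"
    HEME_OR_LIGAND_INTERACTION = "heme_or_ligand_interaction"
    POR_INTERACTION = "por_interaction"
    PROTEIN_DEGRADATION = "protein_degradation"
    MEANDER_ERR_TRIAD = "meander_err_triad"
    STABILITY = "stability"
    EXCLUDED_LOW_RESOLUTION = "excluded_low_resolution"


@dataclass(frozen=True)
class MotifAnnotation:
    """Residue sets for motif-based classes, supplied via configuration.

    The degradation and meander/ERR-triad positions are curation products,
    not derivable from the structure, so they ship empty by default.
    """

    degradation_positions: frozenset = frozenset()
    meander_err_triad_positions: frozenset = frozenset()
    excluded_positions: frozenset = frozenset()

    def __post_init__(self) -> None:
        pairs = [
            (self.degradation_positions, self.meander_err_triad_positions),
            (self.degradation_positions, self.excluded_positions),
            (self.meander_err_triad_positions, self.excluded_positions),
        ]
        for a, b in pairs:
            if set(a) & set(b):
                raise ValueError("motif residue sets must be disjoint")

    @classmethod
    def from_dict(cls, mapping: dict) -> "MotifAnnotation":
        return cls(
            degradation_positions=frozenset(mapping.get("degradation", ())),
            meander_err_triad_positions=frozenset(
                mapping.get("meander_err_triad", ())
            ),
            excluded_positions=frozenset(mapping.get("excluded", ())),
        )


@dataclass
class Classification:
    variant: ProteinVariant
    variant_class: VariantClass
    evidence: Evidence


def classify_variant(
    variant: ProteinVariant,
    ctx: Optional[StructureContext],
    motifs: MotifAnnotation = MotifAnnotation(),
    cfg: GeometryConfig = GeometryConfig(),
) -> Classification:
    """Classify one variant; functional categories take precedence over stability.

    Precedence: truncating kind, low-resolution exclusion, heme/ligand
    contact, POR interface, degradation motif, meander/ERR triad, then
    stability. A missense variant at a position absent from the structure is
    excluded (not resolved). With ``ctx=None`` the geometric rules are
    skipped and every missense variant not in a motif set is "stability".
    """
    if variant.kind is not VariantKind.MISSENSE:
        return Classification(
            variant,
            VariantClass.NONSENSE_INDEL_DEL_DUP,
            Evidence(rule="kind", detail=variant.kind.value),
        )
    pos = variant.position
    if pos in motifs.excluded_positions:
        return Classification(
            variant,
            VariantClass.EXCLUDED_LOW_RESOLUTION,
            Evidence(rule="excluded_position"),
        )
    if ctx is not None:
        if pos not in ctx.residues:
            return Classification(
                variant,
                VariantClass.EXCLUDED_LOW_RESOLUTION,
                Evidence(rule="not_resolved", detail="position absent from structure"),
            )
        heme_hit, heme_ev = is_heme_or_ligand_contact(ctx, pos, cfg)
        if heme_hit:
            return Classification(
                variant, VariantClass.HEME_OR_LIGAND_INTERACTION, heme_ev
            )
        por_hit, por_ev = is_por_interface(ctx, pos, None, cfg)
        if por_hit:
            return Classification(variant, VariantClass.POR_INTERACTION, por_ev)
    if pos in motifs.degradation_positions:
        return Classification(
            variant, VariantClass.PROTEIN_DEGRADATION, Evidence(rule="degradation_motif")
        )
    if pos in motifs.meander_err_triad_positions:
        return Classification(
            variant, VariantClass.MEANDER_ERR_TRIAD, Evidence(rule="meander_err_motif")
        )
    return Classification(variant, VariantClass.STABILITY, Evidence(rule="default"))


def classify_table(
    variants: Iterable[ProteinVariant],
    ctx: Optional[StructureContext],
    motifs: MotifAnnotation = MotifAnnotation(),
    cfg: GeometryConfig = GeometryConfig(),
) -> tuple[pd.DataFrame, dict]:
    """Classify a batch; per-row errors are recorded, never abort the batch.

    Returns (table, class counts). The table has one row per variant with the
    class and the evidence fields; ordering follows the input.
    """
    rows = []
    counts: dict[str, int] = {}
    for variant in variants:
        try:
            result = classify_variant(variant, ctx, motifs, cfg)
            cls_name = result.variant_class.value
            ev = result.evidence
            rows.append(
                {
                    "variant": variant.label,
                    "class": cls_name,
                    "rule": ev.rule,
                    "distance_A": ev.distance,
                    "angle_deg": ev.angle_deg,
                    "nearest_atom": ev.nearest_atom,
                    "exposure": ev.exposure,
                    "error": "",
                }
            )
        except (IncompleteResidueError, KeyError, ValueError) as exc:
            cls_name = "error"
            rows.append(
                {
                    "variant": variant.label,
                    "class": "error",
                    "rule": "",
                    "distance_A": None,
                    "angle_deg": None,
                    "nearest_atom": None,
                    "exposure": None,
                    "error": str(exc),
                }
            )
        counts[cls_name] = counts.get(cls_name, 0) + 1
    columns = [
        "variant", "class", "rule", "distance_A", "angle_deg",
        "nearest_atom", "exposure", "error",
    ]
    return pd.DataFrame(rows, columns=columns), counts
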