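"""Geometric predicates against constructed fixtures and brute-force oracles."""

import numpy as np
import pytest

import cyp21stab as cs
from cyp21stab.structure_context import (
    POR_CORE_SET,
    GeometryConfig,
    IncompleteResidueError,
)


def brute_force_min_distance(coords_a, coords_b):
    return min(
        float(np.linalg.norm(a - b)) for a in np.asarray(coords_a)
        for b in np.asarray(coords_b)
    )


def test_load_structure_populates_context(toy_context):
    assert sorted(toy_context.residues) == [1, 2, 3, 4]
    assert len(toy_context.heme_atoms) > 0
    assert all(0.0 <= e <= 1.0 for e in toy_context.exposure.values())
    assert toy_context.por_core_set == POR_CORE_SET


def test_load_structure_without_heme_warns_and_disables_predicate(tmp_path, caplog):
    pdb = cs.generate_toy_structure([("LEU", 4.0, True)])
    stripped = "\n".join(
        line for line in pdb.splitlines() if not line.startswith("HETATM")
    )
    path = tmp_path / "noheme.pdb"
    path.write_text(stripped + "\n")
    with caplog.at_level("WARNING"):
        ctx = cs.load_structure(path)
    assert len(ctx.heme_atoms) == 0
    assert any("heme" in rec.message.lower() for rec in caplog.records)
    hit, evidence = cs.is_heme_or_ligand_contact(ctx, 1)
    assert hit is False


def test_min_sidechain_distance_matches_brute_force(toy_context):
    atoms = toy_context.heme_atoms
    for pos in toy_context.residues:
        expected = brute_force_min_distance(
            toy_context.residues[pos].sidechain_coords(), atoms
        )
        assert cs.min_sidechain_distance(toy_context, pos, atoms) == pytest.approx(
            expected, abs=1e-12
        )


def test_min_sidechain_distance_known_values(toy_context):
    assert cs.min_sidechain_distance(
        toy_context, 1, toy_context.heme_atoms
    ) == pytest.approx(4.31, abs=0.01)
    with pytest.raises(ValueError):
        cs.min_sidechain_distance(toy_context, 1, np.empty((0, 3)))


def test_min_distance_zero_when_coincident(toy_context):
    tip = toy_context.residues[1].sidechain_coords()[0]
    assert cs.min_sidechain_distance(toy_context, 1, tip[None, :]) == 0.0


@pytest.mark.parametrize(
    "position, expected",
    [(1, True), (2, False), (3, True), (4, False)],
)
def test_heme_contact_fixture_truth(toy_context, position, expected):
    """4.31 Å towards → hit; 20 Å → miss; 5.0 Å boundary → hit (≤ cutoff);
    4.0 Å pointing away → miss (orientation)."""
    hit, evidence = cs.is_heme_or_ligand_contact(toy_context, position)
    assert hit is expected
    assert evidence.distance is not None and evidence.nearest_atom is not None


def test_heme_contact_monotone_in_cutoff(toy_context):
    """Enlarging the distance cutoff never turns a contact off."""
    cutoffs = [3.0, 4.31, 5.0, 8.0, 25.0]
    for pos in toy_context.residues:
        previous = False
        for cutoff in cutoffs:
            hit, _ = cs.is_heme_or_ligand_contact(
                toy_context, pos, GeometryConfig(heme_contact_cutoff=cutoff)
            )
            assert not (previous and not hit)
            previous = hit


def test_predicates_independent_of_atom_order(tmp_path):
    pdb = cs.generate_toy_structure([("LEU", 4.31, True), ("VAL", 6.5, True)])
    lines = pdb.splitlines()
    body = [l for l in lines if l.startswith(("ATOM", "HETATM"))]
    reordered = (
        [lines[0]] + body[::-1] + ["END"]
    )
    p1, p2 = tmp_path / "fwd.pdb", tmp_path / "rev.pdb"
    p1.write_text(pdb)
    p2.write_text("\n".join(reordered) + "\n")
    for pos in (1, 2):
        h1, e1 = cs.is_heme_or_ligand_contact(cs.load_structure(p1), pos)
        h2, e2 = cs.is_heme_or_ligand_contact(cs.load_structure(p2), pos)
        assert h1 == h2
        assert e1.distance == pytest.approx(e2.distance, abs=1e-9)


def test_por_interface_core_positions(toy_context):
    """Core interface positions answer True regardless of the residue present."""
    for pos in sorted(POR_CORE_SET):
        hit, evidence = cs.is_por_interface(toy_context, pos)
        assert hit is True
        assert evidence.rule == "por_core"


def test_por_interface_charged_proximal_exposed(tmp_path):
    """An exposed Arg near the core set on the same face joins the interface;
    a hydrophobic residue in the same spot does not."""
    # Two residues on nearby directions; renumber one onto core position 124.
    pdb = cs.generate_toy_structure(
        [
            cs.Placement("ARG", 10.0, True, residue_number=124),
            cs.Placement("ARG", 12.0, True, residue_number=200),
            cs.Placement("LEU", 12.5, True, residue_number=201),
        ]
    )
    path = tmp_path / "por.pdb"
    path.write_text(pdb)
    ctx = cs.load_structure(path)
    d = cs.min_sidechain_distance(
        ctx, 200, ctx.residues[124].sidechain_coords()
    )
    hit_arg, ev = cs.is_por_interface(ctx, 200)
    assert hit_arg is (d <= 8.0 and ev.exposure >= 0.25)
    hit_leu, ev_leu = cs.is_por_interface(ctx, 201)
    assert hit_leu is False
    assert ev_leu.rule == "not_charged"


def test_glycine_uses_calpha_proxy(tmp_path):
    pdb = cs.generate_toy_structure([("LEU", 4.0, True)])
    # Keep only backbone atoms of a relabelled glycine residue.
    kept = []
    for line in pdb.splitlines():
        if line.startswith("ATOM"):
            name = line[12:16].strip()
            if name in {"CB", "CG", "CD"}:
                continue
            line = line[:17] + "GLY" + line[20:]
        kept.append(line)
    path = tmp_path / "gly.pdb"
    path.write_text("\n".join(kept) + "\n")
    ctx = cs.load_structure(path)
    expected = float(
        np.sqrt(((ctx.residues[1].atoms["CA"] - ctx.heme_atoms) ** 2).sum(axis=1)).min()
    )
    assert cs.min_sidechain_distance(ctx, 1, ctx.heme_atoms) == pytest.approx(expected)


def test_incomplete_residue_raises(tmp_path):
    pdb = cs.generate_toy_structure([("LEU", 4.0, True)])
    backbone_only = "\n".join(
        line
        for line in pdb.splitlines()
        if not (line.startswith("ATOM") and line[12:16].strip() in {"CB", "CG", "CD"})
    )
    path = tmp_path / "incomplete.pdb"
    path.write_text(backbone_only + "\n")
    ctx = cs.load_structure(path)
    with pytest.raises(IncompleteResidueError):
        cs.min_sidechain_distance(ctx, 1, ctx.heme_atoms)
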