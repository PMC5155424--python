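"""Synthetic inputs for every pipeline stage.

Emulates the statistical structure of the study conditions without any
downloads: calibration pairs drawn from the log-linear activity model,
replica ∆∆G estimates with predictor-like scatter, in-cis double-variant
sets constructed region-by-region for each scenario, and tiny PDB fixtures
whose residues sit at controlled distances and orientations from a heme
group so every geometric predicate's truth value is known by construction.

All generators are pure functions of their arguments and seed: repeated
calls produce byte-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from .calibration import CalibrationPair
from .stability_adapter import AnalysisConfig
from .structure_context import GeometryConfig
from .synergy import DoubleVariantRecord, Scenario

# Defaults mirror the study conditions: the fitted line sits near
# ln(activity%) = 5.35 - 1.53·∆∆G, predictor replicate SD is 0.8 kcal/mol
# (half the 1.6 kcal/mol significance cutoff), five replicas per mutation,
# and observed ∆∆G values span roughly -2 to 10 kcal/mol. The ln-scale noise
# of 0.35 reproduces the visual scatter of experimental activity assays.
DEFAULT_A_TRUE = 5.35
DEFAULT_B_TRUE = -1.53
DEFAULT_NOISE_SD = 0.35
DEFAULT_DDG_RANGE = (-2.0, 10.0)
DEFAULT_REPLICA_SD = 0.8
DEFAULT_REPLICA_COUNT = 5


@dataclass(frozen=True)
class SyntheticSpec:
    a_true: float = DEFAULT_A_TRUE
    b_true: float = DEFAULT_B_TRUE
    noise_sd: float = DEFAULT_NOISE_SD
    n_pairs: int = 30
    ddg_range: tuple = DEFAULT_DDG_RANGE
    replica_sd: float = DEFAULT_REPLICA_SD
    replica_count: int = DEFAULT_REPLICA_COUNT
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.ddg_range[0] >= self.ddg_range[1]:
            raise ValueError("ddg_range must satisfy low < high")
        if self.replica_count < 1:
            raise ValueError("replica_count must be >= 1")


def generate_calibration_pairs(
    spec: SyntheticSpec, activity_cap: float = 100.0
) -> list[CalibrationPair]:
    """Draw (∆∆G, activity) pairs from the log-linear model with saturation.

    ∆∆G is uniform on ``spec.ddg_range``; activity = exp(a + b·∆∆G + ε) with
    ε ~ N(0, noise_sd²). Activities above the cap are clamped to it and
    flagged ``capped`` — those points are censored, exactly as a wild-type-
    level assay readout would be.
    """
    rng = np.random.default_rng(spec.seed)
    low, high = spec.ddg_range
    ddgs = rng.uniform(low, high, size=spec.n_pairs)
    noise = rng.normal(0.0, spec.noise_sd, size=spec.n_pairs) if spec.noise_sd > 0 \
        else np.zeros(spec.n_pairs)
    pairs = []
    for ddg, eps in zip(ddgs, noise):
        activity = math.exp(spec.a_true + spec.b_true * ddg + eps)
        capped = activity > activity_cap
        pairs.append(
            CalibrationPair(
                ddg=float(ddg),
                activity_pct=min(activity, activity_cap),
                capped=capped,
            )
        )
    return pairs


def generate_replicas(
    true_ddg: float,
    replica_sd: float = DEFAULT_REPLICA_SD,
    replica_count: int = DEFAULT_REPLICA_COUNT,
    seed: int = 0,
) -> list[float]:
    """Replica ∆∆G values: N(true_ddg, replica_sd²) draws."""
    if replica_count < 1:
        raise ValueError("replica_count must be >= 1")
    if replica_sd < 0:
        raise ValueError("replica_sd must be >= 0")
    rng = np.random.default_rng(seed)
    return [float(v) for v in rng.normal(true_ddg, replica_sd, size=replica_count)]


# --------------------------------------------------------------------------
# Toy structures
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Placement:
    """One residue of a toy structure: distance and orientation to the heme."""

    residue_name: str
    target_distance: float
    toward_heme: bool = True
    residue_number: Optional[int] = None

    def __post_init__(self) -> None:
        if self.target_distance <= 0:
            raise ValueError("target_distance must be positive")


class PlacementError(ValueError):
    pass


#: Heme proxy group: iron at the origin, four pyrrole-like nitrogens, and two
#: propionate-like oxygens. Coordinates in Å.
_HEME_ATOMS = [
    ("FE", np.array([0.0, 0.0, 0.0])),
    ("NA", np.array([2.0, 0.0, 0.0])),
    ("NB", np.array([0.0, 2.0, 0.0])),
    ("NC", np.array([-2.0, 0.0, 0.0])),
    ("ND", np.array([0.0, -2.0, 0.0])),
    ("O1A", np.array([2.2, 2.2, 0.0])),
    ("O2A", np.array([2.2, -2.2, 0.0])),
]


def _pdb_atom_line(
    serial: int, name: str, resname: str, chain: str, resnum: int,
    xyz: np.ndarray, hetatm: bool = False,
) -> str:
    record = "HETATM" if hetatm else "ATOM  "
    element = name.strip()[0] if not name.strip().startswith("FE") else "FE"
    atom_field = f"{name:^4s}" if len(name) < 4 else name
    return (
        f"{record}{serial:5d} {atom_field}{'':1s}{resname:>3s} {chain}"
        f"{resnum:4d}    {xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
        f"{1.00:6.2f}{0.00:6.2f}          {element:>2s}"
    )


def _fibonacci_directions(n: int) -> np.ndarray:
    """n well-separated unit vectors (spherical Fibonacci lattice)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5 ** 0.5) * i
    return np.stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)],
        axis=1,
    )


def generate_toy_structure(
    placements: Sequence[Union[Placement, tuple]],
    seed: int = 0,
    heme_resname: str = "HEM",
) -> str:
    """Emit a minimal PDB with one heme group and controlled residue geometry.

    Each placement produces a residue whose side-chain proxy (three atoms,
    nearest one exactly at the target distance from the heme atom set) either
    points towards the heme (Cα behind the side chain) or away from it (Cα
    between heme and side chain). The construction is verified numerically;
    an overlapping or infeasible placement raises :class:`PlacementError`.
    """
    placements = [
        p if isinstance(p, Placement) else Placement(*p) for p in placements
    ]
    heme_names = [n for n, _ in _HEME_ATOMS]
    heme_xyz = np.array([c for _, c in _HEME_ATOMS])
    directions = _fibonacci_directions(max(len(placements), 1))

    lines = ["HEADER    SYNTHETIC TOY FIXTURE"]
    serial = 1
    atom_lines: list[str] = []
    for idx, placement in enumerate(placements):
        u = directions[idx]
        # Heme atom most extreme along u is the guaranteed nearest one.
        proj = heme_xyz @ u
        anchor = heme_xyz[int(np.argmax(proj))]
        d = placement.target_distance
        tip = anchor + d * u  # side-chain atom realising the target distance
        # Perpendicular helper direction.
        helper = np.array([1.0, 0.0, 0.0])
        if abs(np.dot(helper, u)) > 0.9:
            helper = np.array([0.0, 1.0, 0.0])
        v = np.cross(u, helper)
        v /= np.linalg.norm(v)
        cb = tip + 0.7 * u
        cd = tip + 0.7 * u + 0.7 * v
        if placement.toward_heme:
            ca = tip + 1.8 * u
        else:
            ca = tip - 1.8 * u
            if np.min(np.linalg.norm(heme_xyz - ca, axis=1)) < 1.0:
                raise PlacementError(
                    f"placement {idx}: Cα would overlap the heme group "
                    f"(distance {d} too small for an away-facing residue)"
                )
        n_atom = ca + 1.45 * v
        c_atom = ca - 1.52 * v
        o_atom = c_atom + 1.23 * u

        sidechain = np.array([tip, cb, cd])
        realized = np.sqrt(
            ((sidechain[:, None, :] - heme_xyz[None, :, :]) ** 2).sum(axis=2)
        ).min()
        if abs(realized - d) > 0.01:
            raise PlacementError(
                f"placement {idx}: realised distance {realized:.3f} deviates "
                f"from target {d:.3f}"
            )
        resnum = placement.residue_number or (idx + 1)
        resname = placement.residue_name.upper()
        for name, xyz in [
            ("N", n_atom), ("CA", ca), ("C", c_atom), ("O", o_atom),
            ("CB", cb), ("CG", tip), ("CD", cd),
        ]:
            atom_lines.append(
                _pdb_atom_line(serial, name, resname, "A", resnum, xyz)
            )
            serial += 1
    lines.extend(atom_lines)
    for name, xyz in _HEME_ATOMS:
        lines.append(
            _pdb_atom_line(serial, name, heme_resname, "A", 900, xyz, hetatm=True)
        )
        serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


# --------------------------------------------------------------------------
# Double-variant scenario sets
# --------------------------------------------------------------------------

def _sample_scenario(
    scenario: Scenario, rng: np.random.Generator, threshold: float, tol: float
) -> DoubleVariantRecord:
    """One (ddg_1, ddg_2, ddg_double) triple from the region mapping to
    ``scenario`` under :func:`cyp21stab.synergy.classify_double`."""
    T = threshold
    if scenario is Scenario.BOTH_ABOVE:
        d1 = rng.uniform(T + 0.2, T + 2.0)
        d2 = rng.uniform(T + 0.2, T + 2.0)
        comb = d1 + d2
    elif scenario is Scenario.ADDITIVE_PATHOGENIC:
        d1 = rng.uniform(0.6 * T, 0.95 * T)
        d2 = rng.uniform(0.6 * T, 0.95 * T)
        comb = d1 + d2
    elif scenario is Scenario.COMBINED_RESCUE:
        d1 = rng.uniform(T + 0.2, T + 1.0)
        d2 = rng.uniform(-2.5, T - d1 - 0.2)
        comb = d1 + d2
    elif scenario is Scenario.NEGATIVE_SYNERGY:
        excess = rng.uniform(0.05, 0.5)
        total = T + excess
        d1 = d2 = total / 2.0
        comb = total - (tol + excess + 0.1)  # == T - tol - 0.1 < T
    elif scenario is Scenario.POSITIVE_SYNERGY:
        d1 = T + rng.uniform(0.2, 1.0)
        total = T - 0.2 - rng.uniform(0.0, 0.8)
        d2 = total - d1
        comb = max(total + tol, T) + 0.2 + rng.uniform(0.0, 0.3)
    elif scenario is Scenario.SYNERGY_SUBTHRESHOLD_PATHOGENIC:
        d1 = rng.uniform(0.1, 0.45 * T)
        d2 = rng.uniform(0.1, 0.45 * T)
        comb = T + rng.uniform(0.2, 1.0)
    elif scenario is Scenario.ADDITIVE_NONPATHOGENIC:
        d1 = rng.uniform(-0.5, 0.4 * T)
        d2 = rng.uniform(-0.5, 0.4 * T)
        comb = d1 + d2
    else:  # pragma: no cover - exhaustive over the enum
        raise ValueError(f"unknown scenario {scenario}")
    return DoubleVariantRecord(
        variant_1=None, variant_2=None,
        ddg_1=float(d1), ddg_2=float(d2), ddg_double=float(comb),
    )


def generate_double_variant_set(
    scenario_mix: dict,
    cfg: AnalysisConfig = AnalysisConfig(),
    seed: int = 0,
    synergy_tolerance: float = 0.8,
) -> list[DoubleVariantRecord]:
    """Records whose classification is known by construction.

    ``scenario_mix`` maps :class:`Scenario` (or its value string) to a count.
    Sampling is rejection-free: each scenario's region of the ∆∆G triple
    space is parameterised directly.
    """
    rng = np.random.default_rng(seed)
    records = []
    for scenario, count in scenario_mix.items():
        if not isinstance(scenario, Scenario):
            scenario = Scenario(scenario)
        if count < 0:
            raise ValueError("scenario counts must be >= 0")
        for _ in range(count):
            records.append(
                _sample_scenario(
                    scenario, rng, cfg.destabilization_threshold, synergy_tolerance
                )
            )
    return records
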