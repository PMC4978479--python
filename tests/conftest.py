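"""Shared fixtures: fast configurations and hand-built synthetic models."""

from __future__ import annotations

import numpy as np
import pytest

from ctsim import NucleusModel, Sphere, SpeciesConfig, brachypodium_preset
from ctsim.model import Bead


@pytest.fixture(scope="session")
def bd_cfg() -> SpeciesConfig:
    """The B. distachyon preset (5 pairs, 540 beads total)."""
    return brachypodium_preset()


@pytest.fixture()
def tiny_cfg() -> SpeciesConfig:
    """A 2-pair toy karyotype in a roomy nucleus; simulates in milliseconds."""
    return SpeciesConfig(
        chr_pair=2,
        l_arm_c=[(1, 1), (1, 2)],
        l_arm_d=[(3, 3), (2, 4)],
        min_rad_nu=4000.0,
        max_rad_nu=4500.0,
        min_vol_no=0.02,
        max_vol_no=0.05,
    )


def synthetic_model(
    arm_positions: dict[tuple[int, str], list],
    nucleus_radius: float = 100_000.0,
    rad_bead: float = 250.0,
) -> NucleusModel:
    """Build a NucleusModel directly from per-(chromosome, arm) bead centres.

    Geometry is whatever the caller supplies (no growth, no invariant
    enforcement) — intended for exercising the analysis layer on known
    configurations.  A centromere bead is placed at each chromosome's first
    top-arm position shifted far along +z so it never participates in
    arm-distance measurements being tested.
    """
    chroms = sorted({c for c, _ in arm_positions})
    n_pairs = max((c + 1) // 2 for c in chroms)
    arm_counts: dict[tuple[int, str], int] = {}
    beads: list[Bead] = []
    offset = np.array([0.0, 0.0, nucleus_radius / 2.0])
    for c in range(1, 2 * n_pairs + 1):
        beads.append(Bead(c, "cen", 0, offset + [c * 10 * rad_bead, 0, 0], rad_bead))
        for arm in ("top", "bottom"):
            for i, p in enumerate(arm_positions.get((c, arm), []), start=1):
                beads.append(Bead(c, arm, i, np.asarray(p, float), rad_bead))
                arm_counts[(c, arm)] = i
    l_arm = [
        (
            arm_counts.get((2 * p - 1, "top"), arm_counts.get((2 * p, "top"), 1)),
            arm_counts.get((2 * p - 1, "bottom"), arm_counts.get((2 * p, "bottom"), 1)),
        )
        for p in range(1, n_pairs + 1)
    ]
    cfg = SpeciesConfig(
        chr_pair=n_pairs,
        l_arm_c=l_arm,
        l_arm_d=l_arm,
        min_rad_nu=nucleus_radius,
        max_rad_nu=nucleus_radius,
        min_vol_no=0.01,
        max_vol_no=0.01,
        rad_bead=rad_bead,
    )
    nucleolus = Sphere(np.array([0.0, 0.0, -nucleus_radius * 0.8]), 10.0)
    return NucleusModel(
        nucleus=Sphere(np.zeros(3), nucleus_radius),
        nucleolus=nucleolus,
        beads=beads,
        config=cfg,
    )
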