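"""Vector geometry and candidate-acceptance predicates.

Everything works in a nucleus-centred Cartesian frame (the nucleus centre is
the origin), in nanometres.  Points are plain ``numpy`` arrays of shape
``(3,)``; bead collections are ``(n, 3)`` arrays.

The rejection sampler accepts or rejects each candidate bead position with
the predicates here.  Two clearance regimes apply:

* *own* chromosome: beads of the same chromosome may approach down to
  ``2*r_b - 2*eps_1`` centre distance (slight intermingling allowed);
* *foreign* chromosomes, nucleolus and nuclear envelope: clearance is padded
  by ``eps_2`` (> ``eps_1``), keeping territories mutually exclusive.

Rejections are verdicts, not errors: each predicate returns a
:class:`Verdict` carrying the code of the first failed condition
(``C1``/``C2``/``C3`` for centromeres, ``C1'``/``C2'``/``C3'``/``C4``/``C5``
for domains).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence

import numpy as np

from .config import SpeciesConfig

__all__ = [
    "Sphere",
    "Verdict",
    "DistanceWindows",
    "random_offset",
    "random_offsets",
    "centromere_candidate_ok",
    "domain_candidate_ok",
    "nucleolus_radius_bounds",
]


@dataclass(frozen=True)
class Sphere:
    """A sphere given by centre (nm, nucleus-centred frame) and radius (nm)."""

    centre: np.ndarray
    radius: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "centre", np.asarray(self.centre, dtype=float))
        if self.centre.shape != (3,) or not np.all(np.isfinite(self.centre)):
            raise ValueError("sphere centre must be a finite 3-vector")
        if not (self.radius > 0):
            raise ValueError("sphere radius must be > 0")


class Verdict(NamedTuple):
    """Outcome of a candidate check: accepted or the first failing condition."""

    ok: bool
    code: Optional[str] = None

    def __bool__(self) -> bool:  # allows `if verdict:`
        return self.ok


ACCEPT = Verdict(True, None)


@dataclass(frozen=True)
class DistanceWindows:
    """The two admissible distance windows of the collision rules.

    ``d1`` bounds distances to beads of the *own* chromosome,
    ``d2`` distances to *foreign* beads (centre-to-centre, nm).
    """

    d1_min: float
    d1_max: float
    d2_min: float
    d2_max: float

    @classmethod
    def from_config(cls, R: float, cfg: SpeciesConfig) -> "DistanceWindows":
        return cls(
            d1_min=2.0 * cfg.rad_bead,
            d1_max=R - 2.0 * cfg.rad_bead - cfg.eps_1,
            d2_min=foreign_threshold(cfg),
            d2_max=R - cfg.rad_bead - 5.0 * cfg.eps_2,
        )


def foreign_threshold(cfg: SpeciesConfig) -> float:
    """Minimum centre distance tolerated between beads of different chromosomes.

    Default ``2*r_b + eps_2`` (surfaces at least ``eps_2`` apart); the
    ``paper_literal`` toggle restores ``2*r_b - 2*eps_2`` for comparison runs.
    """
    if cfg.paper_literal:
        return 2.0 * cfg.rad_bead - 2.0 * cfg.eps_2
    return 2.0 * cfg.rad_bead + cfg.eps_2


def own_threshold(cfg: SpeciesConfig) -> float:
    """Minimum centre distance tolerated between beads of the same chromosome."""
    return 2.0 * cfg.rad_bead - 2.0 * cfg.eps_1


def random_offset(origin: np.ndarray, step: float, rng: np.random.Generator) -> np.ndarray:
    """A point at Euclidean distance exactly ``step`` from ``origin``.

    The direction is drawn by the simulator's spherical-angle convention,
    theta in (0, pi), phi in (0, 2 pi) with::

        dx = step * cos(theta) * sin(phi)
        dy = step * sin(theta) * sin(phi)
        dz = step * cos(phi)

    Note the roles of the angles are swapped relative to the physics
    convention (z depends on phi); the step length is still exactly
    ``step`` and the azimuthal distribution about the z-axis is uniform,
    which is all the growth process relies on.
    """
    if not (step > 0):
        raise ValueError("step must be > 0")
    theta = rng.uniform(0.0, math.pi)
    phi = rng.uniform(0.0, 2.0 * math.pi)
    return np.asarray(origin, dtype=float) + step * np.array(
        [math.cos(theta) * math.sin(phi), math.sin(theta) * math.sin(phi), math.cos(phi)]
    )


def random_offsets(origins: np.ndarray, step: float, rng: np.random.Generator) -> np.ndarray:
    """Vectorised :func:`random_offset`: one offset per row of ``origins``."""
    if not (step > 0):
        raise ValueError("step must be > 0")
    origins = np.atleast_2d(np.asarray(origins, dtype=float))
    k = origins.shape[0]
    theta = rng.uniform(0.0, math.pi, size=k)
    phi = rng.uniform(0.0, 2.0 * math.pi, size=k)
    d = np.empty((k, 3))
    d[:, 0] = np.cos(theta) * np.sin(phi)
    d[:, 1] = np.sin(theta) * np.sin(phi)
    d[:, 2] = np.cos(phi)
    return origins + step * d


def centromere_candidate_ok(
    p: np.ndarray,
    nucleus: Sphere,
    nucleolus: Sphere,
    existing_centromeres: Sequence[np.ndarray] | np.ndarray,
    cfg: SpeciesConfig,
) -> Verdict:
    """Check a candidate centromere position against conditions C1-C3.

    C1: strictly inside the nucleus with margin ``r_b + 5*eps_2``;
    C2: centre strictly farther than ``r + r_b + eps_2`` from the nucleolus;
    C3: centre strictly farther than ``2*r_b + eps_2`` from every existing
    centromere.
    """
    p = np.asarray(p, dtype=float)
    r_b, eps2 = cfg.rad_bead, cfg.eps_2
    if np.linalg.norm(p - nucleus.centre) >= nucleus.radius - (r_b + 5.0 * eps2):
        return Verdict(False, "C1")
    if np.linalg.norm(p - nucleolus.centre) <= nucleolus.radius + r_b + eps2:
        return Verdict(False, "C2")
    existing = np.asarray(existing_centromeres, dtype=float).reshape(-1, 3)
    if len(existing):
        d = np.linalg.norm(existing - p, axis=1)
        if np.any(d <= 2.0 * r_b + eps2):
            return Verdict(False, "C3")
    return ACCEPT


def domain_candidate_ok(
    p: np.ndarray,
    nucleus: Sphere,
    nucleolus: Sphere,
    own_beads: np.ndarray,
    foreign_beads: np.ndarray,
    cfg: SpeciesConfig,
    precursor_index: Optional[int] = None,
) -> Verdict:
    """Check a candidate domain position against conditions C1'-C3', C4, C5.

    C1': strictly inside the nucleus (``|p| < R - r_b``);
    C2': centre strictly farther than ``r + r_b + eps_2`` from the nucleolus;
    C3': centre distance to every own bead except the precursory one at
    least ``2*r_b - 2*eps_1``;
    C4: close enough to the own chromosome — nearest own bead within
    ``R - 2*r_b - eps_1``;
    C5: centre distance to every foreign bead at least the foreign
    threshold (default ``2*r_b + eps_2``).

    ``own_beads``/``foreign_beads`` are ``(n, 3)`` arrays;
    ``precursor_index`` is the row of the precursory bead in ``own_beads``.
    """
    p = np.asarray(p, dtype=float)
    if np.linalg.norm(p - nucleus.centre) >= nucleus.radius - cfg.rad_bead:
        return Verdict(False, "C1'")
    if np.linalg.norm(p - nucleolus.centre) <= nucleolus.radius + cfg.rad_bead + cfg.eps_2:
        return Verdict(False, "C2'")
    own = np.asarray(own_beads, dtype=float).reshape(-1, 3)
    if len(own):
        d_own = np.linalg.norm(own - p, axis=1)
        others = np.ones(len(own), dtype=bool)
        if precursor_index is not None:
            others[precursor_index] = False
        if np.any(d_own[others] < own_threshold(cfg)):
            return Verdict(False, "C3'")
        if d_own.min() > nucleus.radius - 2.0 * cfg.rad_bead - cfg.eps_1:
            return Verdict(False, "C4")
    foreign = np.asarray(foreign_beads, dtype=float).reshape(-1, 3)
    if len(foreign):
        d_for = np.linalg.norm(foreign - p, axis=1)
        if np.any(d_for < foreign_threshold(cfg)):
            return Verdict(False, "C5")
    return ACCEPT


def nucleolus_radius_bounds(R: float, vol_min: float, vol_max: float) -> tuple[float, float]:
    """Nucleolus radius interval realising volume fractions [vol_min, vol_max].

    A nucleolus occupying fraction ``v`` of a nucleus of radius ``R`` has
    radius ``(v * R**3) ** (1/3)``.
    """
    if not (0 < vol_min <= vol_max < 1):
        raise ValueError("need 0 < vol_min <= vol_max < 1")
    if not (R > 0):
        raise ValueError("R must be > 0")
    return ((vol_min * R**3) ** (1.0 / 3.0), (vol_max * R**3) ** (1.0 / 3.0))
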