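"""In-memory representation of one simulated nucleus and its invariant suite.

A :class:`NucleusModel` bundles the nucleus sphere, the nucleolus sphere and
the complete, ordered bead set of one simulated interphase nucleus, together
with the configuration snapshot and the seed that produced it.

Chromosome numbering: homologous pair ``p`` (1-based) contributes
chromosomes ``2p - 1`` (copy 1) and ``2p`` (copy 2).  Within a chromosome
the centromere bead carries arm tag ``"cen"`` and index 0; arm beads are
indexed 1.. outward from the centromere, so a bead is addressed by the
triple ``(chromosome, arm, index)``.

:func:`validate_model` re-asserts, post hoc, everything the rejection
sampler guaranteed during growth: containment, nucleolus exclusion, the
inter- and intra-chromosome clearance thresholds, chain connectivity and
the per-arm bead counts demanded by the configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional

import numpy as np

from .config import SpeciesConfig
from .geometry import Sphere, foreign_threshold, own_threshold

__all__ = ["Bead", "NucleusModel", "IntegrityError", "validate_model", "ARM_ORDER"]

ARM_ORDER = {"cen": 0, "top": 1, "bottom": 2}

# slack for exact-arithmetic comparisons on deserialised coordinates
_TOL = 1e-6


class IntegrityError(ValueError):
    """A model violates one of the structural or geometric invariants."""


@dataclass
class Bead:
    """One chromatin domain: a sphere belonging to a specific chromosome arm."""

    chromosome: int
    arm: str  # "cen" | "top" | "bottom"
    index: int  # 0 for the centromere, 1.. within each arm
    position: np.ndarray
    radius: float
    phase: str = "condensed"  # "condensed" | "decondensed"
    precursor: Optional[tuple[int, str, int]] = None

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ValueError("bead position must be a 3-vector")
        if self.arm not in ARM_ORDER:
            raise ValueError(f"unknown arm tag {self.arm!r}")

    @property
    def pair(self) -> int:
        """Homologous pair number (1-based)."""
        return (self.chromosome + 1) // 2

    @property
    def copy(self) -> int:
        """Homologue copy within the pair: 1 or 2."""
        return 1 if self.chromosome % 2 == 1 else 2

    @property
    def is_centromere(self) -> bool:
        return self.arm == "cen"

    @property
    def key(self) -> tuple[int, str, int]:
        return (self.chromosome, self.arm, self.index)

    def same_geometry(self, other: "Bead") -> bool:
        return (
            self.key == other.key
            and self.phase == other.phase
            and self.precursor == other.precursor
            and self.radius == other.radius
            and bool(np.all(self.position == other.position))
        )


@dataclass
class NucleusModel:
    """One completed simulated nucleus."""

    nucleus: Sphere
    nucleolus: Sphere
    beads: list[Bead]
    config: SpeciesConfig
    seed: Optional[int] = None
    restarts: int = 0
    _index: dict[tuple[int, str, int], Bead] = field(
        default=None, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        self.sort_beads()

    def sort_beads(self) -> None:
        """Deterministic order: (chromosome, arm [cen, top, bottom], index)."""
        self.beads.sort(key=lambda b: (b.chromosome, ARM_ORDER[b.arm], b.index))
        self._index = {b.key: b for b in self.beads}

    # -- access helpers -------------------------------------------------

    def __len__(self) -> int:
        return len(self.beads)

    def bead(self, chromosome: int, arm: str, index: int) -> Bead:
        return self._index[(chromosome, arm, index)]

    def positions(self) -> np.ndarray:
        """All bead centres as an (n, 3) array in model order."""
        return np.array([b.position for b in self.beads])

    def chromosome_ids(self) -> np.ndarray:
        return np.array([b.chromosome for b in self.beads])

    def chromosomes(self) -> Iterator[int]:
        return iter(range(1, self.config.n_chromosomes + 1))

    def beads_of(self, chromosome: int, arm: Optional[str] = None) -> list[Bead]:
        """Beads of one chromosome, optionally restricted to one arm tag."""
        return [
            b
            for b in self.beads
            if b.chromosome == chromosome and (arm is None or b.arm == arm)
        ]

    def arm_positions(self, chromosome: int, arm: Optional[str] = None) -> np.ndarray:
        sel = self.beads_of(chromosome, arm)
        return np.array([b.position for b in sel]).reshape(-1, 3)

    def equals(self, other: "NucleusModel") -> bool:
        """Exact equality: same geometry, beads, seed and configuration."""
        return (
            len(self.beads) == len(other.beads)
            and self.seed == other.seed
            and self.restarts == other.restarts
            and self.config.to_dict() == other.config.to_dict()
            and bool(np.all(self.nucleus.centre == other.nucleus.centre))
            and self.nucleus.radius == other.nucleus.radius
            and bool(np.all(self.nucleolus.centre == other.nucleolus.centre))
            and self.nucleolus.radius == other.nucleolus.radius
            and all(a.same_geometry(b) for a, b in zip(self.beads, other.beads))
        )


def validate_model(model: NucleusModel, complete: bool = True) -> None:
    """Re-assert every structural and geometric invariant of a model.

    Raises :class:`IntegrityError` on the first violation.  With
    ``complete=True`` (the default) the per-arm bead counts must equal the
    decondensed arm-length table of the configuration.
    """
    cfg = model.config
    nucleus, nucleolus = model.nucleus, model.nucleolus

    if np.linalg.norm(nucleolus.centre) + nucleolus.radius >= nucleus.radius:
        raise IntegrityError("nucleolus is not strictly inside the nucleus")
    if not (cfg.min_rad_nu - _TOL <= nucleus.radius <= cfg.max_rad_nu + _TOL):
        raise IntegrityError("nucleus radius outside the configured range")

    # structural bookkeeping
    counts: dict[tuple[int, str], int] = {}
    centromeres: dict[int, int] = {}
    for b in model.beads:
        if b.is_centromere:
            centromeres[b.chromosome] = centromeres.get(b.chromosome, 0) + 1
        else:
            counts[(b.chromosome, b.arm)] = counts.get((b.chromosome, b.arm), 0) + 1
    for c in range(1, cfg.n_chromosomes + 1):
        if centromeres.get(c, 0) != 1:
            raise IntegrityError(f"chromosome {c}: expected exactly one centromere bead")
        if complete:
            top_d, bottom_d = cfg.l_arm_d[(c + 1) // 2 - 1]
            if counts.get((c, "top"), 0) != top_d:
                raise IntegrityError(
                    f"chromosome {c}: top arm has {counts.get((c, 'top'), 0)} beads, expected {top_d}"
                )
            if counts.get((c, "bottom"), 0) != bottom_d:
                raise IntegrityError(
                    f"chromosome {c}: bottom arm has {counts.get((c, 'bottom'), 0)} beads, expected {bottom_d}"
                )
    if set(centromeres) - set(range(1, cfg.n_chromosomes + 1)):
        raise IntegrityError("bead with chromosome id outside 1..2*chr_pair")

    pos = model.positions()
    chrom = model.chromosome_ids()

    # containment and nucleolus exclusion
    radial = np.linalg.norm(pos, axis=1)
    if np.any(radial >= nucleus.radius - cfg.rad_bead + _TOL):
        raise IntegrityError("bead outside the nucleus (containment violated)")
    d_no = np.linalg.norm(pos - nucleolus.centre, axis=1)
    if np.any(d_no <= nucleolus.radius + cfg.rad_bead + cfg.eps_2 - _TOL):
        raise IntegrityError("bead intrudes into the nucleolus clearance zone")

    # pairwise clearances (brute force; fine at these problem sizes)
    n = len(pos)
    if n > 1:
        diff = pos[:, None, :] - pos[None, :, :]
        dist = np.sqrt((diff**2).sum(-1))
        iu, ju = np.triu_indices(n, k=1)
        same = chrom[iu] == chrom[ju]
        f_thr = foreign_threshold(cfg)
        if np.any(dist[iu[~same], ju[~same]] < f_thr - _TOL):
            raise IntegrityError("foreign-bead clearance violated")
        # own-chromosome pairs, excluding bead/precursor contacts
        adj = set()
        for b in model.beads:
            if b.precursor is not None:
                adj.add((b.key, b.precursor))
                adj.add((b.precursor, b.key))
        keys = [b.key for b in model.beads]
        o_thr = own_threshold(cfg)
        for i, j in zip(iu[same], ju[same]):
            if (keys[i], keys[j]) in adj:
                continue
            if dist[i, j] < o_thr - _TOL:
                raise IntegrityError("own-chromosome clearance violated")

    # chain connectivity: each bead sits exactly one step from its precursor
    step = cfg.step
    for b in model.beads:
        if b.precursor is None:
            if not b.is_centromere:
                raise IntegrityError(f"non-centromere bead {b.key} lacks a precursor")
            continue
        if b.precursor not in model._index:
            raise IntegrityError(f"bead {b.key} references missing precursor {b.precursor}")
        d = np.linalg.norm(b.position - model.bead(*b.precursor).position)
        if abs(d - step) > _TOL * max(1.0, step):
            raise IntegrityError(f"bead {b.key} is not at step distance from its precursor")
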