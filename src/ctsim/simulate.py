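"""The six-block growth algorithm producing :class:`NucleusModel` instances.

One simulation proceeds through six blocks:

I    set up parameters (the :class:`~ctsim.config.SpeciesConfig`);
II   create the nucleus — a sphere centred at the origin with radius drawn
     uniformly from ``[min_rad_nu, max_rad_nu]``;
III  create the nucleolus — radius drawn so its volume fraction is uniform
     between ``min_vol_no`` and ``max_vol_no``, centre redrawn until the
     nucleolus lies strictly inside the nucleus;
IV   place one centromere bead per chromosome by rejection sampling
     (conditions C1-C3);
V    grow the condensed chromosomes bead-by-bead, bidirectionally from each
     centromere, until every arm reaches its condensed length (conditions
     C1'-C3', C4, C5);
VI   decondense: keep adding beads anywhere along each chromosome — each new
     bead buds off a randomly chosen *precursory* bead of the arm being
     extended — until every arm reaches its decondensed length.

Every candidate position is screened by the predicates in
:mod:`ctsim.geometry`.  A shared counter tracks consecutive rejected
candidates; when it reaches ``restart_after`` the whole attempt is
discarded (nothing of it is kept) and the simulation restarts from block II
with fresh randomness.  The restart count is reported alongside the model;
a batch's success rate is ``n_models / (n_models + total_restarts)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .config import SpeciesConfig
from .geometry import (
    Sphere,
    centromere_candidate_ok,
    domain_candidate_ok,
    nucleolus_radius_bounds,
    random_offset,
)
from .model import Bead, NucleusModel, validate_model

__all__ = [
    "PlacementFailure",
    "AbortError",
    "BatchReport",
    "create_nucleus",
    "create_nucleolus",
    "place_centromeres",
    "grow_condensed",
    "decondense",
    "simulate_model",
    "simulate_batch",
]


class PlacementFailure(RuntimeError):
    """Raised when ``restart_after`` consecutive candidate placements failed."""


class AbortError(RuntimeError):
    """Raised when the configured hard cap on restarts is exhausted."""


def create_nucleus(cfg: SpeciesConfig, rng: np.random.Generator) -> Sphere:
    """Block II: the nucleus sphere, centred at the origin."""
    R = rng.uniform(cfg.min_rad_nu, cfg.max_rad_nu)
    return Sphere(np.zeros(3), R)


def create_nucleolus(nucleus: Sphere, cfg: SpeciesConfig, rng: np.random.Generator) -> Sphere:
    """Block III: a nucleolus strictly inside the nucleus.

    The radius realises a volume fraction uniform in
    ``[min_vol_no, max_vol_no]``; the centre is drawn uniformly in the
    bounding box of admissible centres and redrawn until the whole
    nucleolus fits inside the nucleus.
    """
    R = nucleus.radius
    r_min, r_max = nucleolus_radius_bounds(R, cfg.min_vol_no, cfg.max_vol_no)
    r = rng.uniform(r_min, r_max)
    half = R - r
    while True:
        centre = rng.uniform(-half, half, size=3)
        if np.linalg.norm(centre) + r < R:
            return Sphere(centre, r)


@dataclass
class _Attempt:
    """Mutable state of one model-building attempt (blocks II-VI)."""

    cfg: SpeciesConfig
    nucleus: Sphere
    nucleolus: Sphere
    rng: np.random.Generator
    beads: list[Bead] = field(default_factory=list)
    failures: int = 0  # consecutive rejected candidates

    def __post_init__(self) -> None:
        cap = max(self.cfg.total_beads, 1)
        self._pos = np.empty((cap, 3))
        self._chrom = np.empty(cap, dtype=np.int64)
        self._n = 0

    # -- bead table ----------------------------------------------------

    def add(self, bead: Bead) -> int:
        i = self._n
        self._pos[i] = bead.position
        self._chrom[i] = bead.chromosome
        self._n += 1
        self.beads.append(bead)
        self.failures = 0
        return i

    def positions(self) -> np.ndarray:
        return self._pos[: self._n]

    def own_foreign(self, chromosome: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        mask = self._chrom[: self._n] == chromosome
        pos = self.positions()
        return mask, pos[mask], pos[~mask]

    def reject(self) -> None:
        self.failures += 1
        if self.failures >= self.cfg.restart_after:
            raise PlacementFailure(
                f"{self.failures} consecutive failed placements (restart_after reached)"
            )


def place_centromeres(
    nucleus: Sphere, nucleolus: Sphere, cfg: SpeciesConfig, rng: np.random.Generator,
    attempt: Optional[_Attempt] = None,
) -> list[Bead]:
    """Block IV: one centromere bead per chromosome, rejection-sampled.

    Candidates are drawn uniformly in the cube circumscribing the
    admissible region and screened by conditions C1-C3.  Raises
    :class:`PlacementFailure` after ``restart_after`` consecutive
    rejections.
    """
    if attempt is None:
        attempt = _Attempt(cfg, nucleus, nucleolus, rng)
    half = nucleus.radius - (cfg.rad_bead + 5.0 * cfg.eps_2)
    if half <= 0:
        raise PlacementFailure("nucleus too small to admit any centromere")
    placed: list[np.ndarray] = []
    for chromosome in range(1, cfg.n_chromosomes + 1):
        while True:
            p = rng.uniform(-half, half, size=3)
            if centromere_candidate_ok(p, nucleus, nucleolus, placed, cfg):
                placed.append(p)
                attempt.add(
                    Bead(chromosome, "cen", 0, p, cfg.rad_bead, phase="condensed")
                )
                break
            attempt.reject()
    return attempt.beads


def _extend_arm(
    attempt: _Attempt,
    chromosome: int,
    arm: str,
    precursor: Bead,
    precursor_row: int,
    phase: str,
    index: int,
) -> Bead:
    """Propose positions budding off ``precursor`` until one is accepted."""
    cfg = attempt.cfg
    mask, own, foreign = attempt.own_foreign(chromosome)
    own_rows = np.flatnonzero(mask)
    prec_local = int(np.searchsorted(own_rows, precursor_row))
    while True:
        p = random_offset(precursor.position, cfg.step, attempt.rng)
        if domain_candidate_ok(
            p, attempt.nucleus, attempt.nucleolus, own, foreign, cfg,
            precursor_index=prec_local,
        ):
            bead = Bead(
                chromosome, arm, index, p, cfg.rad_bead,
                phase=phase, precursor=precursor.key,
            )
            attempt.add(bead)
            return bead
        attempt.reject()


def grow_condensed(attempt: _Attempt) -> None:
    """Block V: grow every chromosome to its condensed arm lengths.

    Chromosomes advance round-robin, one bead per turn, alternating arms
    within each chromosome; each new bead buds off the current terminal
    bead of its arm (the centromere for the first arm bead).
    """
    cfg = attempt.cfg
    cen_row = {b.chromosome: i for i, b in enumerate(attempt.beads) if b.is_centromere}
    tip: dict[tuple[int, str], tuple[Bead, int]] = {}
    done: dict[tuple[int, str], int] = {}
    targets: dict[tuple[int, str], int] = {}
    for c in range(1, cfg.n_chromosomes + 1):
        top_c, bottom_c = cfg.l_arm_c[(c + 1) // 2 - 1]
        targets[(c, "top")], targets[(c, "bottom")] = top_c, bottom_c
        for arm in ("top", "bottom"):
            done[(c, arm)] = 0
            tip[(c, arm)] = (attempt.beads[cen_row[c]], cen_row[c])

    pending = True
    while pending:
        pending = False
        for c in range(1, cfg.n_chromosomes + 1):
            for arm in ("top", "bottom"):
                if done[(c, arm)] >= targets[(c, arm)]:
                    continue
                prec, prec_row = tip[(c, arm)]
                idx = done[(c, arm)] + 1
                bead = _extend_arm(attempt, c, arm, prec, prec_row, "condensed", idx)
                tip[(c, arm)] = (bead, attempt._n - 1)
                done[(c, arm)] = idx
                if idx < targets[(c, arm)]:
                    pending = True


def decondense(attempt: _Attempt) -> None:
    """Block VI: add beads along each chromosome until decondensed lengths.

    Each new bead buds off a *precursory* bead drawn uniformly from the
    beads of the arm being extended plus the centromere (widened to the
    whole chromosome with ``precursor_pool: chromosome``); rejected
    candidates are discarded and a new precursor/direction pair is drawn.
    """
    cfg = attempt.cfg
    rng = attempt.rng
    # rows of each (chromosome, arm) group and the centromere rows
    rows: dict[tuple[int, str], list[int]] = {}
    cen_row: dict[int, int] = {}
    done: dict[tuple[int, str], int] = {}
    targets: dict[tuple[int, str], int] = {}
    for i, b in enumerate(attempt.beads):
        if b.is_centromere:
            cen_row[b.chromosome] = i
        else:
            rows.setdefault((b.chromosome, b.arm), []).append(i)
    for c in range(1, cfg.n_chromosomes + 1):
        top_d, bottom_d = cfg.l_arm_d[(c + 1) // 2 - 1]
        for arm, tgt in (("top", top_d), ("bottom", bottom_d)):
            rows.setdefault((c, arm), [])
            done[(c, arm)] = len(rows[(c, arm)])
            targets[(c, arm)] = tgt

    pending = True
    while pending:
        pending = False
        for c in range(1, cfg.n_chromosomes + 1):
            for arm in ("top", "bottom"):
                if done[(c, arm)] >= targets[(c, arm)]:
                    continue
                if cfg.precursor_pool == "chromosome":
                    pool = [cen_row[c]] + rows[(c, "top")] + rows[(c, "bottom")]
                else:
                    pool = [cen_row[c]] + rows[(c, arm)]
                idx = done[(c, arm)] + 1
                _place_decondensed(attempt, c, arm, pool, idx)
                rows[(c, arm)].append(attempt._n - 1)
                done[(c, arm)] = idx
                if idx < targets[(c, arm)]:
                    pending = True


def _place_decondensed(
    attempt: _Attempt, chromosome: int, arm: str, pool: Sequence[int], index: int
) -> Bead:
    """One decondensation bead: redraw (precursor, direction) until accepted."""
    cfg = attempt.cfg
    mask, own, foreign = attempt.own_foreign(chromosome)
    own_rows = np.flatnonzero(mask)
    while True:
        prec_row = pool[int(attempt.rng.integers(len(pool)))]
        prec = attempt.beads[prec_row]
        p = random_offset(prec.position, cfg.step, attempt.rng)
        prec_local = int(np.searchsorted(own_rows, prec_row))
        if domain_candidate_ok(
            p, attempt.nucleus, attempt.nucleolus, own, foreign, cfg,
            precursor_index=prec_local,
        ):
            bead = Bead(
                chromosome, arm, index, p, cfg.rad_bead,
                phase="decondensed", precursor=prec.key,
            )
            attempt.add(bead)
            return bead
        attempt.reject()


def _build_once(cfg: SpeciesConfig, rng: np.random.Generator) -> tuple[Sphere, Sphere, list[Bead]]:
    nucleus = create_nucleus(cfg, rng)
    nucleolus = create_nucleolus(nucleus, cfg, rng)
    attempt = _Attempt(cfg, nucleus, nucleolus, rng)
    place_centromeres(nucleus, nucleolus, cfg, rng, attempt=attempt)
    grow_condensed(attempt)
    decondense(attempt)
    return nucleus, nucleolus, attempt.beads


def simulate_model(
    cfg: SpeciesConfig,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> NucleusModel:
    """Run blocks I-VI to completion; restart on placement failure.

    On a :class:`PlacementFailure` the whole partial model is discarded and
    building restarts from block II on the same random stream (so a fixed
    ``(cfg, seed)`` reproduces the identical model, restarts included).
    With ``cfg.max_restarts`` set, exceeding the cap raises
    :class:`AbortError`.
    """
    if rng is None:
        if seed is None:
            seed = cfg.seed
        rng = np.random.default_rng(seed)
    restarts = 0
    while True:
        try:
            nucleus, nucleolus, beads = _build_once(cfg, rng)
            break
        except PlacementFailure:
            restarts += 1
            if cfg.max_restarts is not None and restarts > cfg.max_restarts:
                raise AbortError(
                    f"gave up after {restarts - 1} restarts (max_restarts={cfg.max_restarts})"
                ) from None
    model = NucleusModel(nucleus, nucleolus, beads, cfg, seed=seed, restarts=restarts)
    validate_model(model)
    return model


@dataclass
class BatchReport:
    """Bookkeeping of a batch run: restarts per model and the success rate."""

    n_models: int
    restarts_per_model: list[int]

    @property
    def total_restarts(self) -> int:
        return sum(self.restarts_per_model)

    @property
    def success_rate(self) -> float:
        """Completed models over total attempts, ``n / (n + restarts)``."""
        return self.n_models / (self.n_models + self.total_restarts)


def simulate_batch(
    cfg: SpeciesConfig, n_models: int, seed: Optional[int] = None
) -> tuple[list[NucleusModel], BatchReport]:
    """Simulate exactly ``n_models`` completed nuclei.

    Restarts do not reduce the number of delivered models.  Each model runs
    on its own child seed derived from ``seed`` so batches are reproducible
    and models are independently re-simulatable from their recorded seeds.
    """
    if n_models < 1:
        raise ValueError("n_models must be >= 1")
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s) & 0x7FFFFFFF for s in ss.generate_state(n_models)]
    models = []
    for child in child_seeds:
        models.append(simulate_model(cfg, seed=child))
    report = BatchReport(n_models, [m.restarts for m in models])
    return models, report
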