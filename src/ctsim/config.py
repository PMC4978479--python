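"""Model parameters and species presets.

A :class:`SpeciesConfig` collects every tunable of the territory simulator:
karyotype tables (condensed and decondensed arm lengths per chromosome),
nuclear geometry ranges, bead radius, and the collision tolerances used by
the rejection sampler.  All geometry is handled internally in nanometres;
chromosome lengths given in micrometres are converted with
:func:`beads_per_condensed_length`.

Presets ship as YAML data files under ``ctsim/presets``:

``set1``
    the *Brachypodium distachyon* karyotype (5 pairs, 28-75 Mbp,
    condensed chains of 7-14 beads) — also returned by
    :func:`brachypodium_preset`;
``set2``
    a human-like karyotype (23 pairs, 57-249 Mbp);
``set3``
    a *Miscanthus*-like karyotype (19 pairs, 87-244 Mbp).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional

import yaml

__all__ = [
    "SpeciesConfig",
    "ConfigError",
    "load_config",
    "load_preset",
    "brachypodium_preset",
    "beads_per_condensed_length",
    "split_arm_lengths",
    "PRESET_NAMES",
]

PRESET_NAMES = ("set1", "set2", "set3")


class ConfigError(ValueError):
    """Raised when a configuration file fails parsing or validation."""


@dataclass
class SpeciesConfig:
    """All tunable model variables for one species.

    Parameters
    ----------
    chr_pair
        Number of chromosome pairs; the nucleus holds ``2 * chr_pair``
        chromosomes.
    l_arm_c, l_arm_d
        Per-chromosome ``(top, bottom)`` arm lengths, in beads, for the
        condensed and the decondensed state.  Arm lengths exclude the
        centromere bead, so a condensed chain of *n* beads total has arm
        lengths summing to ``n - 1``.
    min_rad_nu, max_rad_nu
        Nucleus radius bounds, nm.
    min_vol_no, max_vol_no
        Nucleolus volume as a fraction of nuclear volume.
    rad_bead
        Radius of one 1 Mbp chromatin domain (bead), nm.
    eps_1, eps_2
        Collision tolerances, nm.  ``eps_1`` softens the own-chromosome
        contact distance; ``eps_2`` pads the clearance from foreign
        chromosomes, the nucleolus and the nuclear envelope and must be
        the larger of the two.
    multi
        Beads per domain; only ``1`` is supported.
    restart_after
        Consecutive failed placements tolerated before the whole model
        attempt is discarded and restarted.
    seed
        Default RNG seed recorded in the config (optional).
    step_mode
        ``"tangent"`` places each new bead at centre distance
        ``2 * rad_bead`` from its precursor (consecutive beads touch);
        ``"literal"`` uses ``rad_bead``.
    paper_literal
        If True, the foreign-bead clearance threshold becomes
        ``2*rad_bead - 2*eps_2`` instead of ``2*rad_bead + eps_2``
        (comparison mode; allows foreign overlap).
    precursor_pool
        ``"arm"`` draws decondensation precursors from the arm being
        extended (plus the centromere); ``"chromosome"`` from the whole
        chromosome.
    max_restarts
        Optional hard cap on restarts per model (None = unlimited).
    """

    chr_pair: int
    l_arm_c: list[tuple[int, int]]
    l_arm_d: list[tuple[int, int]]
    min_rad_nu: float
    max_rad_nu: float
    min_vol_no: float
    max_vol_no: float
    rad_bead: float = 250.0
    eps_1: Optional[float] = None
    eps_2: Optional[float] = None
    multi: int = 1
    restart_after: int = 500_000
    seed: Optional[int] = None
    step_mode: str = "tangent"
    paper_literal: bool = False
    precursor_pool: str = "arm"
    max_restarts: Optional[int] = None
    name: str = field(default="custom", compare=False)

    def __post_init__(self) -> None:
        if self.eps_1 is None:
            self.eps_1 = 0.1 * self.rad_bead
        if self.eps_2 is None:
            self.eps_2 = 0.2 * self.rad_bead
        self.l_arm_c = [tuple(int(v) for v in pair) for pair in self.l_arm_c]
        self.l_arm_d = [tuple(int(v) for v in pair) for pair in self.l_arm_d]
        self.validate()

    # -- validation ----------------------------------------------------

    def validate(self) -> None:
        """Check every invariant; raise :class:`ConfigError` naming the field."""
        if self.chr_pair < 1:
            raise ConfigError("chr_pair must be a positive integer")
        if not (0 < self.min_rad_nu <= self.max_rad_nu):
            raise ConfigError("min_rad_nu/max_rad_nu: need 0 < min_rad_nu <= max_rad_nu")
        if not (0 < self.min_vol_no <= self.max_vol_no < 1):
            raise ConfigError("min_vol_no/max_vol_no: need 0 < min_vol_no <= max_vol_no < 1")
        if self.rad_bead <= 0:
            raise ConfigError("rad_bead must be > 0")
        if not (self.eps_2 > self.eps_1 > 0):
            raise ConfigError("eps_1/eps_2: need eps_2 > eps_1 > 0")
        if self.multi != 1:
            raise ConfigError("multi: only multi = 1 is supported")
        if self.restart_after < 1:
            raise ConfigError("restart_after must be >= 1")
        if self.step_mode not in ("tangent", "literal"):
            raise ConfigError("step_mode must be 'tangent' or 'literal'")
        if self.precursor_pool not in ("arm", "chromosome"):
            raise ConfigError("precursor_pool must be 'arm' or 'chromosome'")
        if len(self.l_arm_c) != self.chr_pair or len(self.l_arm_d) != self.chr_pair:
            raise ConfigError("l_arm_c/l_arm_d must have one (top, bottom) entry per chromosome pair")
        for i, ((tc, bc), (td, bd)) in enumerate(zip(self.l_arm_c, self.l_arm_d), start=1):
            if tc < 0 or bc < 0 or tc + bc < 0:
                raise ConfigError(f"l_arm_c[{i}]: arm lengths must be non-negative")
            if td < tc or bd < bc:
                raise ConfigError(
                    f"l_arm_d[{i}]: decondensed arm lengths must be >= condensed arm lengths"
                )

    # -- derived quantities --------------------------------------------

    @property
    def n_chromosomes(self) -> int:
        return 2 * self.chr_pair

    @property
    def step(self) -> float:
        """Centre-to-centre distance between a new bead and its precursor."""
        return 2.0 * self.rad_bead if self.step_mode == "tangent" else self.rad_bead

    def condensed_total(self, pair: int) -> int:
        """Condensed chain length of one chromosome of `pair` (1-based), centromere included."""
        t, b = self.l_arm_c[pair - 1]
        return t + b + 1

    def decondensed_total(self, pair: int) -> int:
        """Final domain count of one chromosome of `pair`, centromere included."""
        t, b = self.l_arm_d[pair - 1]
        return t + b + 1

    @property
    def total_beads(self) -> int:
        """Bead count of a completed model (all chromosomes, both copies)."""
        return 2 * sum(self.decondensed_total(p) for p in range(1, self.chr_pair + 1))

    # -- (de)serialisation ---------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["l_arm_c"] = [list(p) for p in self.l_arm_c]
        d["l_arm_d"] = [list(p) for p in self.l_arm_d]
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "SpeciesConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config field(s): {', '.join(sorted(unknown))}")
        try:
            return cls(**data)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc


def beads_per_condensed_length(length_um: float, bead_diameter_um: float) -> int:
    """Number of beads representing a condensed chromosome of given length.

    A mitotic chromosome of ``length_um`` micrometres is rendered as a chain
    of tangent beads of ``bead_diameter_um`` micrometres, so the chain length
    is the rounded ratio, never less than one bead.  With the default 500 nm
    domain diameter, the 3.5-7.0 um *B. distachyon* chromosomes map to chains
    of 7-14 beads.
    """
    if length_um <= 0 or bead_diameter_um <= 0:
        raise ValueError("length_um and bead_diameter_um must be > 0")
    return max(1, round(length_um / bead_diameter_um))


def split_arm_lengths(total_beads: int, frac_top: float) -> tuple[int, int]:
    """Split a chain of ``total_beads`` (centromere included) into (top, bottom) arms.

    The centromere takes one bead; the top arm gets ``floor(frac_top * rest)``
    beads but at least one, the bottom arm the remainder.  Metacentric
    chromosomes use ``frac_top = 0.5`` (odd remainders favour the bottom
    arm), acrocentric ones ``0.25``.
    """
    if total_beads < 3:
        raise ValueError("need at least 3 beads (centromere + one per arm)")
    if not (0 < frac_top < 1):
        raise ValueError("frac_top must lie in (0, 1)")
    arms = total_beads - 1
    top = max(1, int(frac_top * arms))
    return top, arms - top


def load_config(path: str | Path) -> SpeciesConfig:
    """Load and validate a species configuration from a YAML file."""
    path = Path(path)
    try:
        text = path.read_text()
    except OSError as exc:
        raise ConfigError(f"cannot read config file {path}: {exc}") from exc
    return _parse_config(text, name=path.stem)


def _parse_config(text: str, name: str) -> SpeciesConfig:
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"config parse failure: {exc}") from exc
    if not isinstance(data, dict):
        raise ConfigError("config file must contain a mapping of parameters")
    data.setdefault("name", name)
    return SpeciesConfig.from_dict(data)


def load_preset(name: str) -> SpeciesConfig:
    """Load one of the packaged presets (``set1``, ``set2``, ``set3``)."""
    if name not in PRESET_NAMES:
        raise ConfigError(f"unknown preset {name!r}; available: {', '.join(PRESET_NAMES)}")
    text = resources.files("ctsim.presets").joinpath(f"{name}.yaml").read_text()
    return _parse_config(text, name=name)


def brachypodium_preset() -> SpeciesConfig:
    """The detailed *B. distachyon* karyotype (identical to preset ``set1``).

    Five chromosome pairs; decondensed totals per chromosome equal the Mbp
    contents 75, 59, 60, 48 and 28 (one bead per 1 Mbp domain), condensed
    chains span 7-14 beads; Bd1-Bd3 are metacentric, Bd4-Bd5 acrocentric.
    """
    return load_preset("set1")
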