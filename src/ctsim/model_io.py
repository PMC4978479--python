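"""Plain-text persistence of simulated nuclei.

The model file is a tab-separated dialect with ``#``-prefixed header lines::

    # ctsim-model	1
    # seed	42
    # restarts	0
    # nucleus_radius	4017.33980...
    # nucleolus	-301.2...	55.0...	812.9...	1193.4...
    # config	{"chr_pair": 5, ...}
    # n_beads	540
    # columns	chromosome	copy	arm	index	x	y	z	radius	centromere	phase	precursor

followed by one record per bead, ordered by (chromosome, arm, index) with
arms in centromere/top/bottom order.  Coordinates are serialised with
``repr``, i.e. the shortest decimal that round-trips the IEEE-754 double,
so ``read_model(write_model(m))`` reproduces the model exactly and output
for a fixed model is byte-stable.  The precursor column holds
``chromosome:arm:index`` or ``-`` for centromeres.

Reloaded models are revalidated against the full invariant suite; a
malformed record raises :class:`ParseError` with its line number, a
geometrically inconsistent one :class:`~ctsim.model.IntegrityError`.

:func:`write_xyz` additionally emits a flat XYZ-style export (element
column carrying a chromosome/arm label) for generic 3-D viewers.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np

from .config import SpeciesConfig
from .geometry import Sphere
from .model import ARM_ORDER, Bead, NucleusModel, validate_model

__all__ = ["write_model", "read_model", "write_xyz", "ParseError", "FORMAT_VERSION"]

FORMAT_VERSION = 1

_COLUMNS = (
    "chromosome", "copy", "arm", "index",
    "x", "y", "z", "radius", "centromere", "phase", "precursor",
)


class ParseError(ValueError):
    """A model file does not conform to the documented dialect."""


def _fmt(x: float) -> str:
    return repr(float(x))


def write_model(model: NucleusModel, path: str | Path) -> None:
    """Serialise a validated model to ``path`` in the documented text dialect."""
    validate_model(model)
    path = Path(path)
    lines = [
        f"# ctsim-model\t{FORMAT_VERSION}",
        f"# seed\t{'-' if model.seed is None else model.seed}",
        f"# restarts\t{model.restarts}",
        f"# nucleus_radius\t{_fmt(model.nucleus.radius)}",
        "# nucleolus\t"
        + "\t".join(_fmt(v) for v in (*model.nucleolus.centre, model.nucleolus.radius)),
        f"# config\t{json.dumps(model.config.to_dict(), sort_keys=True)}",
        f"# n_beads\t{len(model)}",
        "# columns\t" + "\t".join(_COLUMNS),
    ]
    for b in model.beads:
        prec = "-" if b.precursor is None else f"{b.precursor[0]}:{b.precursor[1]}:{b.precursor[2]}"
        lines.append(
            "\t".join(
                (
                    str(b.chromosome), str(b.copy), b.arm, str(b.index),
                    _fmt(b.position[0]), _fmt(b.position[1]), _fmt(b.position[2]),
                    _fmt(b.radius), "1" if b.is_centromere else "0", b.phase, prec,
                )
            )
        )
    try:
        path.write_text("\n".join(lines) + "\n")
    except OSError as exc:
        raise OSError(f"cannot write model file {path}: {exc}") from exc


def read_model(path: str | Path) -> NucleusModel:
    """Reload a model file, revalidating every structural/geometric invariant."""
    path = Path(path)
    try:
        text = path.read_text()
    except OSError as exc:
        raise OSError(f"cannot read model file {path}: {exc}") from exc

    header: dict[str, str] = {}
    beads: list[Bead] = []
    n_declared: Optional[int] = None
    for lineno, raw in enumerate(text.splitlines(), start=1):
        if not raw.strip():
            continue
        if raw.startswith("#"):
            parts = raw[1:].strip().split("\t")
            key, values = parts[0], parts[1:]
            header[key] = "\t".join(values)
            continue
        fields = raw.split("\t")
        if len(fields) != len(_COLUMNS):
            raise ParseError(
                f"{path}:{lineno}: expected {len(_COLUMNS)} fields, got {len(fields)}"
            )
        try:
            chromosome = int(fields[0])
            arm = fields[2]
            index = int(fields[3])
            pos = np.array([float(fields[4]), float(fields[5]), float(fields[6])])
            radius = float(fields[7])
            is_cen = fields[8] == "1"
            phase = fields[9]
            prec_s = fields[10]
            if prec_s == "-":
                precursor = None
            else:
                pc, pa, pi = prec_s.split(":")
                precursor = (int(pc), pa, int(pi))
            if arm not in ARM_ORDER or phase not in ("condensed", "decondensed"):
                raise ValueError(f"bad arm/phase tags {arm!r}/{phase!r}")
            if is_cen != (arm == "cen"):
                raise ValueError("centromere flag inconsistent with arm tag")
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: malformed record: {exc}") from exc
        beads.append(Bead(chromosome, arm, index, pos, radius, phase=phase, precursor=precursor))

    for required in ("ctsim-model", "nucleus_radius", "nucleolus", "config", "n_beads"):
        if required not in header:
            raise ParseError(f"{path}: missing header line '# {required}'")
    if int(header["ctsim-model"]) != FORMAT_VERSION:
        raise ParseError(f"{path}: unsupported format version {header['ctsim-model']}")
    n_declared = int(header["n_beads"])
    if n_declared != len(beads):
        raise ParseError(
            f"{path}: header declares {n_declared} beads but body has {len(beads)}"
        )

    cfg = SpeciesConfig.from_dict(json.loads(header["config"]))
    no_vals = [float(v) for v in header["nucleolus"].split("\t")]
    if len(no_vals) != 4:
        raise ParseError(f"{path}: nucleolus header needs x, y, z, r")
    seed_s = header.get("seed", "-")
    model = NucleusModel(
        nucleus=Sphere(np.zeros(3), float(header["nucleus_radius"])),
        nucleolus=Sphere(np.array(no_vals[:3]), no_vals[3]),
        beads=beads,
        config=cfg,
        seed=None if seed_s == "-" else int(seed_s),
        restarts=int(header.get("restarts", "0")),
    )
    validate_model(model)
    return model


def write_xyz(model: NucleusModel, path: str | Path, labels: Optional[dict] = None) -> None:
    """XYZ-style flat export: one row per bead plus one for the nucleolus.

    The element column is repurposed as a ``C<chromosome><arm-initial>``
    label (``NO`` for the nucleolus) so generic molecular viewers colour
    chromosomes apart.  Coordinates are in nm.
    """
    path = Path(path)
    rows = [f"{len(model) + 1}", f"ctsim model, nucleus R={_fmt(model.nucleus.radius)} nm"]
    no = model.nucleolus
    rows.append(f"NO\t{_fmt(no.centre[0])}\t{_fmt(no.centre[1])}\t{_fmt(no.centre[2])}")
    for b in model.beads:
        label = (labels or {}).get((b.chromosome, b.arm), f"C{b.chromosome}{b.arm[0]}")
        rows.append(
            f"{label}\t{_fmt(b.position[0])}\t{_fmt(b.position[1])}\t{_fmt(b.position[2])}"
        )
    path.write_text("\n".join(rows) + "\n")
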