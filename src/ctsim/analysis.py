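"""Classification of chromosome-territory arrangements and their statistics.

Two territories (or two arms) are *associated* when the minimum gap between
their bead surfaces — centre distance minus two bead radii, floored at
zero — is strictly below a threshold, 500 nm by default (one bead
diameter).

For a homologous pair the four arm pairings (top:top, bottom:bottom and the
two cross pairings) are each tested, and the pattern maps onto exactly five
arrangement classes:

``complete_separation``
    no arm pairing associated;
``both_arms``
    top:top and bottom:bottom both associated;
``top_top`` / ``bottom_bottom``
    only that same-arm pairing associated;
``top_bottom``
    only cross pairings (top of one homologue with bottom of the other)
    associated — the class that simulation produces but microscopy of real
    nuclei does not.

Same-arm evidence dominates cross-arm evidence in composite cases
(precedence ``both_arms`` > ``top_top``/``bottom_bottom`` >
``top_bottom``); :func:`arm_association_profile` exposes the raw per-pairing
booleans for auditing.  Heterologous pairs are classified associated or
separated on the whole-territory border distance.

Frequencies over replicate models are tabulated per chromosome pair and
compared with expected distributions by Pearson's chi-squared goodness of
fit.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import SpeciesConfig
from .model import NucleusModel

__all__ = [
    "ArrangementClass",
    "HOMOLOGUE_CLASSES",
    "ASSOCIATION_THRESHOLD_NM",
    "border_distance",
    "arm_association_profile",
    "classify_homologue_pair",
    "classify_heterologue_pair",
    "FrequencyTable",
    "tabulate",
    "chisq_goodness_of_fit",
]

ASSOCIATION_THRESHOLD_NM = 500.0


class ArrangementClass(str, Enum):
    """The five homologous arrangement patterns, plus the heterologue verdicts."""

    COMPLETE_SEPARATION = "complete_separation"
    TOP_TOP = "top_top"
    BOTTOM_BOTTOM = "bottom_bottom"
    BOTH_ARMS = "both_arms"
    TOP_BOTTOM = "top_bottom"
    # heterologue verdicts
    ASSOCIATED = "associated"
    SEPARATED = "separated"


HOMOLOGUE_CLASSES: tuple[ArrangementClass, ...] = (
    ArrangementClass.COMPLETE_SEPARATION,
    ArrangementClass.TOP_TOP,
    ArrangementClass.BOTTOM_BOTTOM,
    ArrangementClass.BOTH_ARMS,
    ArrangementClass.TOP_BOTTOM,
)


def border_distance(beads_a: np.ndarray, beads_b: np.ndarray, r_b: float) -> float:
    """Minimum surface-to-surface gap between two bead sets, nm (floored at 0).

    ``beads_a``/``beads_b`` are ``(n, 3)`` centre arrays; the gap is the
    smallest cross-pair centre distance minus ``2 * r_b``.
    """
    a = np.asarray(beads_a, dtype=float).reshape(-1, 3)
    b = np.asarray(beads_b, dtype=float).reshape(-1, 3)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("border_distance needs two non-empty bead sets")
    d2 = ((a[:, None, :] - b[None, :, :]) ** 2).sum(-1)
    return max(0.0, float(np.sqrt(d2.min())) - 2.0 * r_b)


def _arm_beads(model: NucleusModel, chromosome: int, arm: str) -> np.ndarray:
    pos = model.arm_positions(chromosome, arm)
    if len(pos) == 0:
        raise ValueError(f"chromosome {chromosome} has no beads tagged {arm!r}")
    return pos


def arm_association_profile(
    model: NucleusModel, pair: int, threshold: float = ASSOCIATION_THRESHOLD_NM
) -> dict[str, bool]:
    """Raw per-pairing association booleans for one homologous pair.

    Keys: ``"top:top"``, ``"bottom:bottom"``, ``"top:bottom"`` (copy-1 top
    vs copy-2 bottom) and ``"bottom:top"``.  Association is strict:
    border distance < threshold.
    """
    c1, c2 = 2 * pair - 1, 2 * pair
    r_b = model.config.rad_bead
    arms = {
        (c, a): _arm_beads(model, c, a) for c in (c1, c2) for a in ("top", "bottom")
    }
    return {
        "top:top": border_distance(arms[(c1, "top")], arms[(c2, "top")], r_b) < threshold,
        "bottom:bottom": border_distance(arms[(c1, "bottom")], arms[(c2, "bottom")], r_b) < threshold,
        "top:bottom": border_distance(arms[(c1, "top")], arms[(c2, "bottom")], r_b) < threshold,
        "bottom:top": border_distance(arms[(c1, "bottom")], arms[(c2, "top")], r_b) < threshold,
    }


def classify_homologue_pair(
    model: NucleusModel, pair: int, threshold: float = ASSOCIATION_THRESHOLD_NM
) -> ArrangementClass:
    """Assign one of the five arrangement classes to a homologous pair."""
    prof = arm_association_profile(model, pair, threshold)
    tt, bb = prof["top:top"], prof["bottom:bottom"]
    cross = prof["top:bottom"] or prof["bottom:top"]
    if tt and bb:
        return ArrangementClass.BOTH_ARMS
    if tt:
        return ArrangementClass.TOP_TOP
    if bb:
        return ArrangementClass.BOTTOM_BOTTOM
    if cross:
        return ArrangementClass.TOP_BOTTOM
    return ArrangementClass.COMPLETE_SEPARATION


def classify_heterologue_pair(
    model: NucleusModel,
    chromosomes: tuple[int, int],
    threshold: float = ASSOCIATION_THRESHOLD_NM,
) -> ArrangementClass:
    """Associated/separated verdict for two whole (heterologous) territories."""
    ca, cb = chromosomes
    gap = border_distance(
        model.arm_positions(ca), model.arm_positions(cb), model.config.rad_bead
    )
    return ArrangementClass.ASSOCIATED if gap < threshold else ArrangementClass.SEPARATED


@dataclass
class FrequencyTable:
    """Arrangement-class counts per chromosome pair over replicate models."""

    counts: pd.DataFrame  # index: pair (1-based), columns: the five classes
    n_models: int

    @property
    def percentages(self) -> pd.DataFrame:
        return 100.0 * self.counts / self.n_models

    def to_tsv(self, path) -> None:
        out = self.counts.copy()
        out.index.name = "pair"
        out.to_csv(path, sep="\t")


def tabulate(
    models: Sequence[NucleusModel],
    cfg: Optional[SpeciesConfig] = None,
    threshold: float = ASSOCIATION_THRESHOLD_NM,
) -> FrequencyTable:
    """Tabulate homologous arrangement classes across replicate models.

    All models must share one configuration (karyotypes must agree for the
    per-pair counts to be comparable).
    """
    if not models:
        raise ValueError("tabulate needs at least one model")
    if cfg is None:
        cfg = models[0].config
    ref = cfg.to_dict()
    for m in models:
        if m.config.to_dict() != ref:
            raise ValueError("tabulate: models were generated under different configs")
    cols = [c.value for c in HOMOLOGUE_CLASSES]
    counts = pd.DataFrame(
        0, index=pd.RangeIndex(1, cfg.chr_pair + 1, name="pair"), columns=cols
    )
    for m in models:
        for pair in range(1, cfg.chr_pair + 1):
            cls = classify_homologue_pair(m, pair, threshold)
            counts.loc[pair, cls.value] += 1
    return FrequencyTable(counts=counts, n_models=len(models))


def chisq_goodness_of_fit(
    observed: Iterable[float], expected: Iterable[float]
) -> tuple[float, int, float]:
    """Pearson chi-squared goodness of fit.

    ``expected`` may be counts (rescaled to the observed total if the
    totals differ) or proportions (summing to 1).  Returns
    ``(statistic, dof, p_value)`` with ``dof = k - 1`` and an upper-tail
    p-value; the statistic is ``sum((O - E)^2 / E)``.
    """
    obs = np.asarray(list(observed), dtype=float)
    exp = np.asarray(list(expected), dtype=float)
    if obs.shape != exp.shape or obs.ndim != 1 or len(obs) < 2:
        raise ValueError("observed and expected must be matching 1-D arrays (k >= 2)")
    if np.any(exp <= 0):
        raise ValueError("expected frequencies must all be > 0")
    total = obs.sum()
    if not np.isclose(exp.sum(), total):
        exp = exp * (total / exp.sum())
    stat = float(((obs - exp) ** 2 / exp).sum())
    dof = len(obs) - 1
    p = float(stats.chi2.sf(stat, dof))
    return stat, dof, p
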