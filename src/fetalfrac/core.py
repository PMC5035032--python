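"""Targeted-zone geometry and the median fetal-fraction estimator.

A maternal-plasma SNP locus is a point (x, y) of major/minor allele counts.
With maternal/fetal genotype combinations AAaa, AAab, ABaa and ABab
(upper case maternal, lower case fetal), only AAab loci — mother homozygous,
fetus heterozygous — carry the fetal fraction f in their minor-allele count:
E[y] = (f/2)·(x+y).  The *targeted zone* selects those loci without any
genotype information, by three inequalities in the (x, y) plane:

1. ``y <= x/3`` — excludes maternally heterozygous loci (ABaa/ABab), whose
   minor fraction is at least (1-f)/2 >= 1/4 for f <= 1/2;
2. ``y > (x+y)·e + k_error·sqrt(e·(x+y))`` — excludes AAaa loci, whose minor
   count is sequencing error: Poisson with mean e·(x+y), so the threshold is
   the mean plus ``k_error`` standard deviations (3 at depth >= 100-fold,
   relaxed to 2 below 100-fold);
3. ``|x + y - D| <= 3·sqrt(D)`` — keeps loci whose total depth is within
   three standard deviations of the sample depth D (Poisson depth model).

Each zone locus yields a per-locus estimate f_i = 2y/(x+y); the sample
estimate is their median.  Condition 1 caps every accepted f_i at 0.5.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Sequence

import numpy as np

from .counts import SnpAlleleCount

if TYPE_CHECKING:  # pragma: no cover
    from .correction import CorrectionModel

__all__ = [
    "ZoneBoundaries",
    "FetalFractionEstimate",
    "NoEffectiveSnpsError",
    "estimate_sample_depth",
    "build_boundaries",
    "in_targeted_zone",
    "targeted_zone_mask",
    "locus_fetal_fraction",
    "estimate_fetal_fraction",
    "estimate_from_arrays",
    "estimate_fraction_chrY",
]

DEFAULT_ERROR_RATE = 0.01  # Q20 filtering => 1% residual base-call error
DEFAULT_MIN_EFFECTIVE = 30
DEPTH_RELAXATION_THRESHOLD = 100.0  # fold coverage below which the error line relaxes
MAX_FETAL_FRACTION = 0.5


class NoEffectiveSnpsError(ValueError):
    """No locus fell inside the targeted zone."""


@dataclass(frozen=True)
class ZoneBoundaries:
    """The four boundary lines delimiting the targeted zone.

    Parameters
    ----------
    D : float
        Sample sequencing depth in fold coverage (median of per-locus totals).
    e : float
        Sequencing-error rate after quality filtering (default 0.01).
    k_error : int
        Multiplier on the error-line standard deviation: 3 when ``D >= 100``,
        2 below (low-depth relaxation).
    k_depth : int
        Multiplier on the depth-window standard deviation (fixed 3).
    max_f : float
        Maximum admissible fetal fraction (fixed 0.5; gives the y = x/3 line).
    """

    D: float
    e: float = DEFAULT_ERROR_RATE
    k_error: int = 3
    k_depth: int = 3
    max_f: float = MAX_FETAL_FRACTION

    def __post_init__(self) -> None:
        if self.D <= 0:
            raise ValueError(f"depth must be positive, got {self.D}")
        if not 0 < self.e < 1:
            raise ValueError(f"error rate must be in (0, 1), got {self.e}")
        if self.k_error not in (2, 3):
            raise ValueError(f"k_error must be 2 or 3, got {self.k_error}")

    @property
    def depth_window(self) -> tuple[float, float]:
        """Inclusive (low, high) bounds on x+y from the depth lines."""
        half = self.k_depth * math.sqrt(self.D)
        return self.D - half, self.D + half

    def error_threshold(self, total: float | np.ndarray) -> float | np.ndarray:
        """Maximum minor count attributable to sequencing error at depth ``total``."""
        return total * self.e + self.k_error * np.sqrt(self.e * total)


def estimate_sample_depth(loci: Sequence[SnpAlleleCount]) -> float:
    """Median of per-locus total counts x+y, the sample depth D (fold)."""
    if len(loci) == 0:
        raise ValueError("no loci: cannot estimate sample depth")
    return float(np.median([r.total for r in loci]))


def build_boundaries(D: float, e: float = DEFAULT_ERROR_RATE) -> ZoneBoundaries:
    """Boundaries for sample depth ``D``: the error line uses 3 standard
    deviations at ``D >= 100`` and 2 below (strictly less than 100-fold)."""
    if D <= 0:
        raise ValueError(f"depth must be positive, got {D}")
    k_error = 3 if D >= DEPTH_RELAXATION_THRESHOLD else 2
    return ZoneBoundaries(D=D, e=e, k_error=k_error)


def targeted_zone_mask(
    x: np.ndarray, y: np.ndarray, boundaries: ZoneBoundaries
) -> np.ndarray:
    """Vectorised zone membership for count arrays ``x`` and ``y``."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    total = x + y
    lo, hi = boundaries.depth_window
    with np.errstate(invalid="ignore"):
        mask = (
            (y <= x / 3.0)
            & (y > boundaries.error_threshold(total))
            & (total >= lo)
            & (total <= hi)
        )
    return mask


def in_targeted_zone(locus: SnpAlleleCount, boundaries: ZoneBoundaries) -> bool:
    """Whether a locus lies in the targeted zone (effective-SNP region)."""
    return bool(
        targeted_zone_mask(np.array([locus.x]), np.array([locus.y]), boundaries)[0]
    )


def locus_fetal_fraction(x: int, y: int) -> float:
    """Per-locus fetal fraction f = 2y/(x+y)."""
    if x + y == 0:
        raise ValueError("zero depth locus: x + y must be positive")
    return 2.0 * y / (x + y)


@dataclass
class FetalFractionEstimate:
    """Result of the zone-median estimator for one sample."""

    D: float
    f_raw: float
    n_effective: int
    per_locus_f: np.ndarray = field(repr=False)
    f_corrected: float | None = None
    corrected: bool = False
    low_confidence: bool = False

    @property
    def f(self) -> float:
        """The final estimate: corrected value when available, else raw."""
        return self.f_corrected if self.corrected else self.f_raw

    def to_dict(self) -> dict:
        return {
            "depth": self.D,
            "f_raw": self.f_raw,
            "f_raw_percent": 100.0 * self.f_raw,
            "f_corrected": self.f_corrected,
            "f_corrected_percent": (
                None if self.f_corrected is None else 100.0 * self.f_corrected
            ),
            "n_effective": self.n_effective,
            "corrected": self.corrected,
            "low_confidence": self.low_confidence,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def estimate_from_arrays(
    x: np.ndarray,
    y: np.ndarray,
    model: "CorrectionModel | None" = None,
    e: float = DEFAULT_ERROR_RATE,
    min_effective: int = DEFAULT_MIN_EFFECTIVE,
) -> FetalFractionEstimate:
    """Array fast path of :func:`estimate_fetal_fraction`.

    ``x`` and ``y`` are parallel arrays of major/minor counts; see
    :func:`estimate_fetal_fraction` for semantics.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0:
        raise ValueError("no loci")
    D = float(np.median(x + y))
    boundaries = build_boundaries(D, e=e)
    mask = targeted_zone_mask(x, y, boundaries)
    n_eff = int(mask.sum())
    if n_eff == 0:
        raise NoEffectiveSnpsError(
            f"no effective SNPs: zero loci in the targeted zone at depth {D:g}"
        )
    xz, yz = x[mask], y[mask]
    per_locus = 2.0 * yz / (xz + yz)
    f_raw = float(np.median(per_locus))
    est = FetalFractionEstimate(
        D=D,
        f_raw=f_raw,
        n_effective=n_eff,
        per_locus_f=per_locus,
        low_confidence=n_eff < min_effective,
    )
    needs_correction = D < DEPTH_RELAXATION_THRESHOLD or f_raw < 0.10
    if needs_correction:
        if model is not None:
            from .correction import apply_correction

            est.f_corrected = apply_correction(f_raw, D, model)
            est.corrected = True
        else:
            warnings.warn(
                f"correction indicated (depth {D:g}-fold, f_raw {f_raw:.3f}) "
                "but no correction model supplied; returning raw estimate",
                stacklevel=2,
            )
    return est


def estimate_fetal_fraction(
    loci: Sequence[SnpAlleleCount],
    model: "CorrectionModel | None" = None,
    e: float = DEFAULT_ERROR_RATE,
    min_effective: int = DEFAULT_MIN_EFFECTIVE,
) -> FetalFractionEstimate:
    """Estimate the fetal fraction of a sample from its SNP allele counts.

    Computes the sample depth D (median total count), filters loci through
    the targeted zone, takes the median of per-locus fractions 2y/(x+y) as
    the raw estimate, and — when D < 100-fold or the raw estimate is below
    10% — applies the depth-bias correction model if one is supplied.
    Estimates resting on fewer than ``min_effective`` zone loci are flagged
    ``low_confidence`` but still returned.

    Raises
    ------
    NoEffectiveSnpsError
        When no locus falls in the targeted zone.
    """
    if len(loci) == 0:
        raise ValueError("no loci")
    x = np.array([r.x for r in loci], dtype=float)
    y = np.array([r.y for r in loci], dtype=float)
    return estimate_from_arrays(x, y, model=model, e=e, min_effective=min_effective)


def estimate_fraction_chrY(
    chrY_site_depths: Sequence[float], autosomal_site_depths: Sequence[float]
) -> float:
    """Orthogonal fetal-fraction estimate from chrY coverage (male fetus).

    In a mixture where the fetus contributes fraction f, a male fetus
    supplies f/2 haploid chrY copies per diploid autosomal genome, so
    f = 2 · median(chrY depth) / median(autosomal depth), clamped to [0, 1].
    """
    if len(chrY_site_depths) == 0 or len(autosomal_site_depths) == 0:
        raise ValueError("empty depth list")
    auto = float(np.median(autosomal_site_depths))
    if auto <= 0:
        raise ValueError("autosomal median depth must be positive")
    f = 2.0 * float(np.median(chrY_site_depths)) / auto
    return min(max(f, 0.0), 1.0)
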