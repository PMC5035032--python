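"""Deviation metrics, zone diagnostics, design sweeps and the clinical summary.

Two deviation measures score a deduced fetal fraction against the standard
(reference) value: the absolute deviation e1 in percentage points, and the
relative deviation e2 as a fraction of the standard value.  The sweeps ask
two study-design questions on synthetic data — the minimum sequencing depth
at a fixed low fetal fraction, and the minimum number of predefined SNP
loci at a fixed depth — and the clinical summary reproduces the cohort
statistics of an 18-sample targeted-sequencing study shipped as a fixture.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np

from .core import (
    NoEffectiveSnpsError,
    ZoneBoundaries,
    estimate_from_arrays,
    targeted_zone_mask,
)
from .correction import CorrectionModel, build_correction_model
from .simulate import SimulatedDataset, SimulationParams, simulate_dataset, standard_f_of_dataset

__all__ = [
    "deviation_e1",
    "deviation_e2",
    "zone_sensitivity_specificity",
    "SweepPoint",
    "SweepResult",
    "DepthSweepOutcome",
    "SnpSweepOutcome",
    "min_depth_sweep",
    "min_snps_sweep",
    "ClinicalTableRow",
    "ClinicalSummary",
    "load_clinical_table",
    "summarize_clinical_table",
]

DEFAULT_DEPTH_GRID: tuple[int, ...] = tuple(range(40, 201, 5))
DEFAULT_LOCI_GRID: tuple[int, ...] = (100, 250, 500, 1000, 2000, 4000, 8000, 11000)
DEFAULT_SWEEP_REPS = 20
MIN_ZONE_LOCI = 30  # zone census below which an estimate is low-confidence


def deviation_e1(standard_f: float, deduced_f: float) -> float:
    """Absolute deviation |standard - deduced| in percentage points."""
    return abs(standard_f - deduced_f) * 100.0


def deviation_e2(standard_f: float, deduced_f: float) -> float:
    """Relative deviation |standard - deduced| / standard (a fraction)."""
    if standard_f == 0:
        raise ValueError("relative deviation undefined for standard_f = 0")
    return abs(standard_f - deduced_f) / standard_f


def zone_sensitivity_specificity(
    ds: SimulatedDataset, boundaries: ZoneBoundaries
) -> tuple[float, float]:
    """Confusion-matrix view of the targeted zone with AAab as positive class.

    Sensitivity: percent of true AAab loci captured by the zone.
    Specificity: percent of non-AAab loci excluded by it.
    """
    inside = targeted_zone_mask(ds.x, ds.y, boundaries)
    is_pos = ds.categories == 1
    n_pos = int(is_pos.sum())
    if n_pos == 0:
        raise ValueError("no AAab loci: sensitivity undefined")
    sens = 100.0 * float((inside & is_pos).sum()) / n_pos
    n_neg = int((~is_pos).sum())
    spec = float("nan") if n_neg == 0 else 100.0 * float((~inside & ~is_pos).sum()) / n_neg
    return sens, spec


@dataclass(frozen=True)
class SweepPoint:
    value: float  # swept axis value (depth in fold, or locus count)
    mean_deviation: float  # mean e1 (pct points) or e2 (relative fraction)
    n_reps: int  # replicates contributing (zone non-empty)
    mean_zone_loci: float  # mean targeted-zone census across those replicates


@dataclass
class SweepResult:
    axis: str  # "depth" or "n_loci"
    points: list[SweepPoint]
    threshold: float

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{self.axis}\tmean_deviation\tn_reps\tmean_zone_loci\n")
            for p in self.points:
                fh.write(
                    f"{p.value:g}\t{p.mean_deviation:.6g}\t{p.n_reps}"
                    f"\t{p.mean_zone_loci:.6g}\n"
                )


@dataclass
class DepthSweepOutcome:
    sweep: SweepResult
    min_depth: float | None  # smallest swept depth with mean e1 below threshold


@dataclass
class SnpSweepOutcome:
    sweep: SweepResult
    min_loci_e2: int | None  # smallest count with mean e2 below threshold
    min_loci_zone: int | None  # smallest count with mean zone census > 30


def _replicate_scores(
    depth: float,
    f: float,
    n_loci: int,
    n_reps: int,
    seed_seq: np.random.SeedSequence,
    model: CorrectionModel | None,
    relative: bool,
) -> tuple[list[float], list[int]]:
    """Deviations and zone censuses for seeded replicates of one condition."""
    devs: list[float] = []
    zones: list[int] = []
    for rep_ss in seed_seq.spawn(n_reps):
        params = SimulationParams(
            D=depth, f=f, n_loci=n_loci, seed=int(rep_ss.generate_state(1)[0] % (2**31))
        )
        ds = simulate_dataset(params)
        try:
            std = standard_f_of_dataset(ds)
            est = estimate_from_arrays(ds.x, ds.y, model=model)
        except (NoEffectiveSnpsError, ValueError):
            continue
        dev = deviation_e2(std, est.f) if relative else deviation_e1(std, est.f)
        devs.append(dev)
        zones.append(est.n_effective)
    return devs, zones


def min_depth_sweep(
    f: float = 0.035,
    n_loci: int = 11_000,
    depths: Sequence[float] = DEFAULT_DEPTH_GRID,
    n_reps: int = DEFAULT_SWEEP_REPS,
    seed: int = 0,
    criterion: float = 1.0,
    model: CorrectionModel | None = None,
) -> DepthSweepOutcome:
    """Mean absolute deviation e1 of the corrected estimator across depths.

    At each swept depth, ``n_reps`` datasets of ``n_loci`` loci are simulated
    at true fraction ``f`` and scored (corrected estimate vs standard f).
    When no model is passed, one is calibrated at the swept depths on an
    independent seed stream.  The minimal depth is the smallest swept depth
    whose mean e1 falls below ``criterion`` percentage points (None if none
    does).
    """
    depths = sorted(depths)
    if model is None:
        model = build_correction_model(depths=depths, seed=seed + 1)
    ss = np.random.SeedSequence(seed)
    points: list[SweepPoint] = []
    for depth, depth_ss in zip(depths, ss.spawn(len(depths))):
        devs, zones = _replicate_scores(
            depth, f, n_loci, n_reps, depth_ss, model, relative=False
        )
        points.append(
            SweepPoint(
                value=float(depth),
                mean_deviation=float(np.mean(devs)) if devs else float("nan"),
                n_reps=len(devs),
                mean_zone_loci=float(np.mean(zones)) if zones else float("nan"),
            )
        )
    min_depth = next(
        (p.value for p in points if p.n_reps > 0 and p.mean_deviation < criterion),
        None,
    )
    return DepthSweepOutcome(
        sweep=SweepResult(axis="depth", points=points, threshold=criterion),
        min_depth=min_depth,
    )


def min_snps_sweep(
    f: float,
    D: float = 65.0,
    loci_counts: Sequence[int] = DEFAULT_LOCI_GRID,
    n_reps: int = DEFAULT_SWEEP_REPS,
    seed: int = 0,
    criterion: float = 0.01,
    model: CorrectionModel | None = None,
) -> SnpSweepOutcome:
    """Mean relative deviation e2 of the corrected estimator vs locus count.

    At fixed depth ``D`` and fraction ``f``, sweeps the number of predefined
    SNP loci.  Reports the smallest count whose mean e2 falls below
    ``criterion`` and, separately, the smallest count at which the targeted
    zone holds more than 30 loci on average — the census the accuracy claim
    rests on (both None when never met on the grid).
    """
    counts = sorted(loci_counts)
    if model is None:
        model = build_correction_model(depths=[D], seed=seed + 1)
    ss = np.random.SeedSequence(seed)
    points: list[SweepPoint] = []
    for count, count_ss in zip(counts, ss.spawn(len(counts))):
        devs, zones = _replicate_scores(
            D, f, count, n_reps, count_ss, model, relative=True
        )
        points.append(
            SweepPoint(
                value=float(count),
                mean_deviation=float(np.mean(devs)) if devs else float("nan"),
                n_reps=len(devs),
                mean_zone_loci=float(np.mean(zones)) if zones else float("nan"),
            )
        )
    min_e2 = next(
        (
            int(p.value)
            for p in points
            if p.n_reps > 0 and p.mean_deviation < criterion
        ),
        None,
    )
    min_zone = next(
        (
            int(p.value)
            for p in points
            if p.n_reps > 0 and p.mean_zone_loci > MIN_ZONE_LOCI
        ),
        None,
    )
    return SnpSweepOutcome(
        sweep=SweepResult(axis="n_loci", points=points, threshold=criterion),
        min_loci_e2=min_e2,
        min_loci_zone=min_zone,
    )


@dataclass(frozen=True)
class ClinicalTableRow:
    """One sample of the 18-pregnancy targeted-sequencing cohort."""

    sample: str
    depth: float
    sensitivity: float
    specificity: float
    standard_cff: float  # chrY / AAab reference fraction, percent
    estimated_cff: float  # zone-median estimate, percent
    corrected_cff: float | None  # after depth-bias correction; None above 100-fold

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise ValueError("depth must be positive")


def load_clinical_table() -> list[ClinicalTableRow]:
    """The packaged 18-sample cohort table (percent units, as published)."""
    text = (
        resources.files("fetalfrac").joinpath("data/clinical_table.tsv").read_text()
    )
    rows = []
    lines = text.strip().split("\n")
    for line in lines[1:]:
        s, d, sens, spec, std, est, corr = line.split("\t")
        rows.append(
            ClinicalTableRow(
                sample=s,
                depth=float(d),
                sensitivity=float(sens),
                specificity=float(spec),
                standard_cff=float(std),
                estimated_cff=float(est),
                corrected_cff=None if corr == "-" else float(corr),
            )
        )
    return rows


@dataclass
class ClinicalSummary:
    n_samples: int
    n_low_depth: int
    median_depth: float
    pre_correction_median: float  # median |standard - estimated|, low-depth rows
    pre_correction_range: tuple[float, float]
    post_correction_median: float  # median |standard - corrected|, low-depth rows
    post_correction_range: tuple[float, float]
    final_abs_median: float  # median |standard - final| over all rows
    final_abs_median_1dp: float  # same, rounded half-up to one decimal
    final_rel_median_percent: float  # median 100·|standard - final|/standard


def _median(values: Sequence[float]) -> float:
    """Median with the mean-of-central-pair convention for even lengths."""
    return round(float(np.median(np.asarray(values, dtype=float))), 6)


def _round_half_up(value: float, digits: int) -> float:
    q = Decimal(1).scaleb(-digits)
    return float(Decimal(str(value)).quantize(q, rounding=ROUND_HALF_UP))


def summarize_clinical_table(rows: Sequence[ClinicalTableRow]) -> ClinicalSummary:
    """Cohort summary statistics (all deviations in percentage points).

    Low-depth rows (depth < 100-fold) contribute the pre- and post-correction
    deviation medians and ranges; all rows contribute the median depth and the
    median final deviation, where "final" uses the corrected value when
    present and the raw estimate otherwise.  Per-row deviations are rounded
    to 4 decimals (beyond the table's print precision) before aggregating.
    The final median is also reported as 100·|dev|/standard — the relative
    reading of the same quantity.
    """
    if not rows:
        raise ValueError("empty clinical table")
    low = [r for r in rows if r.depth < 100]
    pre = [round(abs(r.standard_cff - r.estimated_cff), 4) for r in low]
    post = []
    for r in low:
        if r.corrected_cff is None:
            warnings.warn(
                f"low-depth sample {r.sample} has no corrected value; "
                "excluded from post-correction median",
                stacklevel=2,
            )
            continue
        post.append(round(abs(r.standard_cff - r.corrected_cff), 4))
    final = [
        round(
            abs(
                r.standard_cff
                - (r.corrected_cff if r.corrected_cff is not None else r.estimated_cff)
            ),
            4,
        )
        for r in rows
    ]
    rel = [
        round(
            100.0
            * abs(
                r.standard_cff
                - (r.corrected_cff if r.corrected_cff is not None else r.estimated_cff)
            )
            / r.standard_cff,
            4,
        )
        for r in rows
    ]
    final_median = _median(final)
    return ClinicalSummary(
        n_samples=len(rows),
        n_low_depth=len(low),
        median_depth=_median([r.depth for r in rows]),
        pre_correction_median=_median(pre) if pre else float("nan"),
        pre_correction_range=(min(pre), max(pre)) if pre else (float("nan"),) * 2,
        post_correction_median=_median(post) if post else float("nan"),
        post_correction_range=(min(post), max(post)) if post else (float("nan"),) * 2,
        final_abs_median=final_median,
        final_abs_median_1dp=_round_half_up(final_median, 1),
        final_rel_median_percent=_median(rel),
    )
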