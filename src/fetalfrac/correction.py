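"""Depth-bias correction calibrated on synthetic datasets.

The zone-median estimator is positively biased at low depth or low fetal
fraction: the error line then truncates the AAab minor-count distribution
from below, so only the upper tail of effective loci survives and the
median of their per-locus fractions overshoots.  The bias is systematic at
a given depth, so it can be removed by a calibration curve: for each
calibration depth, simulate datasets over a grid of true fractions, run the
estimator without correction, and fit the standard (truth-level) fraction
on the raw estimate by ordinary least squares.

The fitted relationship is strongly nonlinear — the raw estimate saturates
toward a depth-dependent floor as f decreases (local slope of standard on
raw reaches ~2-3 near the floor, 1 above ~10%) — so each depth's curve is a
low-order polynomial (default cubic) rather than a straight line; a single
line leaves several percentage points of residual bias at low fractions.
Predictions are evaluated with the raw value clipped to the calibrated raw
range (no polynomial extrapolation) and clamped to [0, 0.5].
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .core import NoEffectiveSnpsError, estimate_from_arrays
from .simulate import SimulationParams, simulate_dataset, standard_f_of_dataset

__all__ = [
    "CorrectionEntry",
    "CorrectionModel",
    "build_correction_model",
    "apply_correction",
    "save_model",
    "load_model",
    "DEFAULT_CALIBRATION_DEPTHS",
    "DEFAULT_F_GRID",
    "DEFAULT_DEGREE",
]

# calibration grid of true fractions: 0.5% to 25% in 0.5% steps
DEFAULT_F_GRID: tuple[float, ...] = tuple(np.round(np.arange(0.005, 0.2501, 0.005), 4))
# low-depth regime where correction is routinely needed
DEFAULT_CALIBRATION_DEPTHS: tuple[float, ...] = tuple(range(40, 100, 5))
DEFAULT_N_REPS = 25
DEFAULT_DEGREE = 3
MIN_USABLE_CELLS = 5


@dataclass(frozen=True)
class CorrectionEntry:
    """One depth's calibration curve.

    ``coef`` are polynomial coefficients in ascending order, so
    ``f_corrected = coef[0] + coef[1]·f_raw + coef[2]·f_raw² + ...``;
    a degree-1 entry is the familiar (intercept, slope) pair.
    ``raw_range`` is the span of raw estimates seen during calibration;
    queries outside it are clipped to its ends before evaluation.
    """

    coef: tuple[float, ...]
    raw_range: tuple[float, float]

    def __call__(self, f_raw: float) -> float:
        r = float(np.clip(f_raw, *self.raw_range))
        val = float(np.polynomial.polynomial.polyval(r, np.asarray(self.coef)))
        return float(np.clip(val, 0.0, 0.5))


@dataclass
class CorrectionModel:
    """Per-depth calibration curves mapping raw to corrected fetal fraction.

    Lookup is nearest-depth, ties resolved to the lower depth.
    """

    entries: dict[float, CorrectionEntry]
    f_grid: tuple[float, ...] = DEFAULT_F_GRID
    n_reps: int = DEFAULT_N_REPS
    degree: int = DEFAULT_DEGREE
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("correction model must have at least one depth entry")
        for d, entry in self.entries.items():
            if not all(np.isfinite(c) for c in entry.coef):
                raise ValueError(f"non-finite coefficients at depth {d}")

    def nearest_depth(self, D: float) -> float:
        depths = sorted(self.entries)
        return min(depths, key=lambda d: (abs(d - D), d))

    def to_dict(self) -> dict:
        return {
            "entries": {
                str(d): {"coef": list(e.coef), "raw_range": list(e.raw_range)}
                for d, e in sorted(self.entries.items())
            },
            "f_grid": list(self.f_grid),
            "n_reps": self.n_reps,
            "degree": self.degree,
            "seed": self.seed,
        }


def build_correction_model(
    depths: Sequence[float] = DEFAULT_CALIBRATION_DEPTHS,
    f_grid: Sequence[float] = DEFAULT_F_GRID,
    n_reps: int = DEFAULT_N_REPS,
    seed: int = 0,
    degree: int = DEFAULT_DEGREE,
    n_loci: int | None = None,
) -> CorrectionModel:
    """Calibrate per-depth correction curves on synthetic data.

    For every depth and every true fraction on ``f_grid``, ``n_reps``
    datasets are simulated (generator defaults unless ``n_loci`` is given)
    and scored with the uncorrected estimator; an OLS polynomial of standard
    f on raw f over all usable replicates yields that depth's curve.

    Cells (depth, f) where every replicate leaves the targeted zone empty
    are dropped with a warning — typical at very low f·D where no minor
    allele clears the error line; a depth retaining fewer than 5 usable
    cells raises, as its fit would be unsupported.
    """
    depths = list(depths)
    if not depths:
        raise ValueError("depths list must be non-empty")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if degree < 1:
        raise ValueError("degree must be >= 1")
    ss = np.random.SeedSequence(seed)
    entries: dict[float, CorrectionEntry] = {}
    for depth, depth_ss in zip(depths, ss.spawn(len(depths))):
        raw_vals: list[float] = []
        std_vals: list[float] = []
        usable_cells = 0
        cell_seeds = depth_ss.spawn(len(f_grid))
        for f, cell_ss in zip(f_grid, cell_seeds):
            cell_raw: list[float] = []
            cell_std: list[float] = []
            for rep_ss in cell_ss.spawn(n_reps):
                params = SimulationParams(
                    D=depth,
                    f=float(f),
                    seed=int(rep_ss.generate_state(1)[0] % (2**31)),
                    **({"n_loci": n_loci} if n_loci is not None else {}),
                )
                ds = simulate_dataset(params)
                try:
                    with warnings.catch_warnings():
                        # the raw (uncorrected) estimate is exactly what is
                        # being calibrated here
                        warnings.simplefilter("ignore", UserWarning)
                        est = estimate_from_arrays(ds.x, ds.y, model=None)
                except NoEffectiveSnpsError:
                    continue  # empty zone: missing, never zero
                cell_raw.append(est.f_raw)
                cell_std.append(standard_f_of_dataset(ds))
            if not cell_raw:
                warnings.warn(
                    f"calibration cell (depth={depth}, f={f}) had an empty "
                    "targeted zone in all replicates; cell dropped",
                    stacklevel=2,
                )
                continue
            usable_cells += 1
            raw_vals.extend(cell_raw)
            std_vals.extend(cell_std)
        if usable_cells < MIN_USABLE_CELLS:
            raise ValueError(
                f"depth {depth}: only {usable_cells} usable calibration cells "
                f"(need >= {MIN_USABLE_CELLS})"
            )
        raw_arr = np.asarray(raw_vals)
        coef = np.polynomial.polynomial.polyfit(raw_arr, np.asarray(std_vals), degree)
        entries[float(depth)] = CorrectionEntry(
            coef=tuple(float(c) for c in coef),
            raw_range=(float(raw_arr.min()), float(raw_arr.max())),
        )
    return CorrectionModel(
        entries=entries,
        f_grid=tuple(f_grid),
        n_reps=n_reps,
        degree=degree,
        seed=seed,
    )


def apply_correction(f_raw: float, D: float, model: CorrectionModel) -> float:
    """Map a raw estimate through the calibration entry nearest to depth D."""
    return model.entries[model.nearest_depth(D)](f_raw)


def save_model(model: CorrectionModel, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(model.to_dict(), fh, indent=1, sort_keys=True)
        fh.write("\n")


def load_model(path: str | Path) -> CorrectionModel:
    with open(path) as fh:
        payload = json.load(fh)
    for key in ("entries", "f_grid", "n_reps", "degree", "seed"):
        if key not in payload:
            raise ValueError(f"correction model file missing key {key!r}")
    entries = {}
    for d, e in payload["entries"].items():
        if "coef" not in e or "raw_range" not in e:
            raise ValueError("correction model entry missing 'coef' or 'raw_range'")
        entries[float(d)] = CorrectionEntry(
            coef=tuple(float(c) for c in e["coef"]),
            raw_range=(float(e["raw_range"][0]), float(e["raw_range"][1])),
        )
    return CorrectionModel(
        entries=entries,
        f_grid=tuple(payload["f_grid"]),
        n_reps=int(payload["n_reps"]),
        degree=int(payload["degree"]),
        seed=int(payload["seed"]),
    )
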