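"""Parametric generator of labeled maternal-plasma SNP allele-count data.

Each simulated locus is assigned one of the four maternal/fetal genotype
combinations and its major/minor counts are drawn from normal distributions
with variance equal to the mean (the normal limit of Poisson-dispersed
depth), rounded to integers and truncated at zero.  At predefined median
depth D and true fetal fraction f the minor-allele means are

    AAaa : e_sim · D        (sequencing error only)
    AAab : (f/2) · D        (fetal heterozygote — the signal carriers)
    ABaa : ((1-f)/2) · D    (maternal heterozygote, fetal allele a)
    ABab : D/2              (both heterozygous)

with the major-allele mean D minus the minor mean.  ``e_sim`` is the
platform base-call error rate used for AAaa minor counts (default 0.26%,
a HiSeq-class rate); it is distinct from the e = 1% post-Q20 rate used in
the zone boundaries and the two are never conflated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .counts import COUNTS_HEADER, SnpAlleleCount

__all__ = [
    "CATEGORIES",
    "SimulationParams",
    "SimulatedDataset",
    "simulate_dataset",
    "standard_f_of_dataset",
]

CATEGORIES = ("AAaa", "AAab", "ABaa", "ABab")

DEFAULT_PROPORTIONS = (0.7, 0.1, 0.1, 0.1)
DEFAULT_N_LOCI = 10_000
DEFAULT_PLATFORM_ERROR = 0.0026


@dataclass(frozen=True)
class SimulationParams:
    """Study conditions for one synthetic dataset.

    Parameters
    ----------
    D : float
        Predefined median sequencing depth (fold).
    f : float
        True cell-free fetal DNA fraction, in [0, 0.5].
    n_loci : int
        Number of SNP loci (default 10,000).
    proportions : tuple of 4 floats
        Category mix over (AAaa, AAab, ABaa, ABab); default (0.7, 0.1, 0.1, 0.1).
    e_sim : float
        Platform error rate driving AAaa minor counts (default 0.0026).
    seed : int
        Random seed; identical params + seed give an identical dataset.
    """

    D: float
    f: float
    n_loci: int = DEFAULT_N_LOCI
    proportions: tuple[float, float, float, float] = DEFAULT_PROPORTIONS
    e_sim: float = DEFAULT_PLATFORM_ERROR
    seed: int = 0

    def __post_init__(self) -> None:
        if self.D <= 0:
            raise ValueError(f"depth must be positive, got {self.D}")
        if not 0 <= self.f <= 0.5:
            raise ValueError(f"fetal fraction must be in [0, 0.5], got {self.f}")
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")
        if len(self.proportions) != 4 or any(p < 0 for p in self.proportions):
            raise ValueError("proportions must be 4 non-negative numbers")
        if abs(sum(self.proportions) - 1.0) > 1e-9:
            raise ValueError(f"proportions must sum to 1, got {sum(self.proportions)}")
        if not 0 <= self.e_sim < 1:
            raise ValueError("e_sim must be in [0, 1)")


@dataclass
class SimulatedDataset:
    """Synthetic dataset: count arrays plus the true category labels."""

    x: np.ndarray
    y: np.ndarray
    categories: np.ndarray  # integer codes into CATEGORIES
    params: SimulationParams
    _loci: list[SnpAlleleCount] | None = field(default=None, repr=False)

    @property
    def n_loci(self) -> int:
        return int(self.x.size)

    @property
    def labels(self) -> list[str]:
        """Per-locus genotype-category labels, parallel to ``loci``."""
        return [CATEGORIES[c] for c in self.categories]

    @property
    def loci(self) -> list[SnpAlleleCount]:
        """The dataset as allele-count records (materialised on demand).

        Synthetic loci are placed on a synthetic chromosome at consecutive
        positions; major base is always A, minor G (or "." when y = 0).
        """
        if self._loci is None:
            self._loci = [
                SnpAlleleCount(
                    "chrS", i + 1, "A", "G" if yi > 0 else ".", int(xi), int(yi)
                )
                for i, (xi, yi) in enumerate(zip(self.x, self.y))
            ]
        return self._loci

    def to_tsv(self, path: str | Path) -> None:
        """Write counts + a trailing ``category`` column (extended dialect)."""
        with open(path, "w") as fh:
            fh.write("\t".join(COUNTS_HEADER + ("category",)) + "\n")
            for rec, cat in zip(self.loci, self.labels):
                fh.write(
                    f"{rec.chrom}\t{rec.pos}\t{rec.major_base}\t{rec.minor_base}"
                    f"\t{rec.x}\t{rec.y}\t{cat}\n"
                )

    @classmethod
    def from_tsv(cls, path: str | Path, params: SimulationParams) -> "SimulatedDataset":
        xs, ys, cats = [], [], []
        code = {c: i for i, c in enumerate(CATEGORIES)}
        with open(path) as fh:
            fh.readline()
            for line in fh:
                fields = line.rstrip("\n").split("\t")
                if len(fields) != 7:
                    raise ValueError("expected 7 columns in labeled counts TSV")
                xs.append(int(fields[4]))
                ys.append(int(fields[5]))
                cats.append(code[fields[6]])
        return cls(
            x=np.array(xs), y=np.array(ys), categories=np.array(cats), params=params
        )


def _minor_means(params: SimulationParams) -> np.ndarray:
    D, f = params.D, params.f
    return np.array([params.e_sim * D, (f / 2.0) * D, ((1.0 - f) / 2.0) * D, D / 2.0])


def simulate_dataset(params: SimulationParams) -> SimulatedDataset:
    """Draw one labeled dataset under the stated generative model."""
    rng = np.random.default_rng(params.seed)
    n = params.n_loci
    cats = rng.choice(4, size=n, p=np.asarray(params.proportions, dtype=float))
    minor_mean = _minor_means(params)[cats]
    major_mean = params.D - minor_mean
    # variance equals the mean for both allele counts; mean-zero draws are
    # degenerate at 0
    minor = rng.normal(minor_mean, np.sqrt(minor_mean))
    major = rng.normal(major_mean, np.sqrt(np.maximum(major_mean, 0.0)))
    minor = np.maximum(np.rint(minor), 0.0).astype(np.int64)
    major = np.maximum(np.rint(major), 0.0).astype(np.int64)
    x = np.maximum(major, minor)
    y = np.minimum(major, minor)
    return SimulatedDataset(x=x, y=y, categories=cats, params=params)


def standard_f_of_dataset(ds: SimulatedDataset) -> float:
    """The dataset's standard (ground-truth-level) fetal fraction.

    Median of 2y/(x+y) over the loci whose *true* label is AAab — i.e. what
    a perfect genotype oracle would report; used as the reference value when
    scoring the blind zone-based estimator.
    """
    mask = (ds.categories == 1) & (ds.x + ds.y > 0)
    if not mask.any():
        raise ValueError("no AAab loci with positive depth in dataset")
    x, y = ds.x[mask].astype(float), ds.y[mask].astype(float)
    return float(np.median(2.0 * y / (x + y)))
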