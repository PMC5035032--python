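"""Per-SNP allele-count records and their file formats.

The estimator consumes one record per biallelic SNP locus: the counts of the
most frequent (major, ``x``) and second most frequent (minor, ``y``) base
observed in plasma sequencing after base-quality filtering.  Records come
either from a pre-tabulated TSV or directly from a samtools text pileup
restricted to a SNP panel (BED3).
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "SnpAlleleCount",
    "SnpPanel",
    "PileupParseError",
    "CountsParseError",
    "read_counts_table",
    "write_counts_table",
    "counts_from_pileup",
]

_NUCLEOTIDES = ("A", "C", "G", "T")

COUNTS_HEADER = ("chrom", "pos", "major", "minor", "x", "y")


class CountsParseError(ValueError):
    """Malformed row in an allele-counts table."""


class PileupParseError(ValueError):
    """Malformed samtools text-pileup line."""


@dataclass(frozen=True)
class SnpAlleleCount:
    """Allele counts at one biallelic SNP locus.

    Attributes
    ----------
    chrom : str
        Chromosome name.
    pos : int
        1-based genomic position.
    major_base, minor_base : str
        The most / second most frequent nucleotide.  When no second allele
        was observed (``y == 0``) the minor base is recorded as ``"."``.
    x, y : int
        Major and minor allele counts; ``x >= y >= 0`` always holds.
    """

    chrom: str
    pos: int
    major_base: str
    minor_base: str
    x: int
    y: int

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.y < 0 or self.x < self.y:
            raise ValueError(f"require x >= y >= 0, got x={self.x}, y={self.y}")
        if self.y > 0 and self.major_base == self.minor_base:
            raise ValueError("major and minor base must differ when y > 0")

    @property
    def total(self) -> int:
        """Locus depth ``x + y``."""
        return self.x + self.y


class SnpPanel:
    """Set of panel SNP sites given as genomic intervals.

    Intervals are stored 0-based half-open (BED convention) and merged so
    that overlapping or book-ended intervals collapse to one.
    """

    def __init__(self, intervals: Iterable[tuple[str, int, int]]):
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in intervals:
            if end <= start:
                raise ValueError(f"interval end must exceed start: {chrom}:{start}-{end}")
            by_chrom.setdefault(chrom, []).append((start, end))
        self._starts: dict[str, list[int]] = {}
        self._ends: dict[str, list[int]] = {}
        for chrom, ivs in by_chrom.items():
            ivs.sort()
            merged: list[list[int]] = []
            for s, e in ivs:
                if merged and s <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            self._starts[chrom] = [s for s, _ in merged]
            self._ends[chrom] = [e for _, e in merged]

    @classmethod
    def from_bed(cls, path: str | Path) -> "SnpPanel":
        """Load a panel from a BED3 file (extra columns ignored)."""
        intervals = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split("\t")
                if len(fields) < 3:
                    raise CountsParseError(f"BED line {lineno}: expected >= 3 columns")
                try:
                    intervals.append((fields[0], int(fields[1]), int(fields[2])))
                except ValueError as exc:
                    raise CountsParseError(f"BED line {lineno}: {exc}") from None
        return cls(intervals)

    def contains(self, chrom: str, pos: int) -> bool:
        """Whether the 1-based position ``pos`` falls inside the panel."""
        starts = self._starts.get(chrom)
        if not starts:
            return False
        zero = pos - 1
        i = bisect.bisect_right(starts, zero) - 1
        return i >= 0 and zero < self._ends[chrom][i]

    @property
    def intervals(self) -> list[tuple[str, int, int]]:
        return [
            (chrom, s, e)
            for chrom in sorted(self._starts)
            for s, e in zip(self._starts[chrom], self._ends[chrom])
        ]


def read_counts_table(path: str | Path) -> list[SnpAlleleCount]:
    """Read a tab-separated allele-counts table.

    The file has a header row ``chrom pos major minor x y``.  Rows where the
    stated minor count exceeds the major count are normalised by swapping
    the two alleles, so the returned records always satisfy ``x >= y``.

    Raises
    ------
    CountsParseError
        On a wrong column count, non-integer or negative counts; the message
        names the offending line number.
    """
    records: list[SnpAlleleCount] = []
    with open(path) as fh:
        header = fh.readline()
        if header and tuple(header.rstrip("\n").split("\t")) != COUNTS_HEADER:
            raise CountsParseError(
                f"unexpected header {header.strip()!r}; expected {' '.join(COUNTS_HEADER)}"
            )
        for lineno, line in enumerate(fh, 2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 6:
                raise CountsParseError(f"line {lineno}: expected 6 columns, got {len(fields)}")
            chrom, pos_s, major, minor, x_s, y_s = fields
            try:
                pos, x, y = int(pos_s), int(x_s), int(y_s)
            except ValueError:
                raise CountsParseError(f"line {lineno}: non-integer pos or counts") from None
            if x < 0 or y < 0:
                raise CountsParseError(f"line {lineno}: negative count")
            if x < y:
                x, y = y, x
                major, minor = minor, major
            try:
                records.append(SnpAlleleCount(chrom, pos, major, minor, x, y))
            except ValueError as exc:
                raise CountsParseError(f"line {lineno}: {exc}") from None
    return records


def write_counts_table(records: Sequence[SnpAlleleCount], path: str | Path) -> None:
    """Write records as the TSV dialect read by :func:`read_counts_table`."""
    with open(path, "w") as fh:
        fh.write("\t".join(COUNTS_HEADER) + "\n")
        for r in records:
            fh.write(f"{r.chrom}\t{r.pos}\t{r.major_base}\t{r.minor_base}\t{r.x}\t{r.y}\n")


def decode_pileup_bases(bases: str, ref_base: str) -> list[str]:
    """Decode a samtools read-bases string into one nucleotide per base call.

    Handles ``^`` (read start; the following char is a mapping quality),
    ``$`` (read end), ``+N``/``-N`` indel runs, ``*``/``#`` deletion
    placeholders and ``>``/``<`` reference skips.  Placeholders and skips
    consume a quality slot and are returned as ``"*"`` so the caller can pair
    them with the quality string before discarding them; ambiguous bases are
    returned as ``"N"``.
    """
    ref = ref_base.upper()
    out: list[str] = []
    i, n = 0, len(bases)
    while i < n:
        c = bases[i]
        if c == "^":
            i += 2  # skip mapping-quality char
            continue
        if c == "$":
            i += 1
            continue
        if c in "+-":
            j = i + 1
            while j < n and bases[j].isdigit():
                j += 1
            if j == i + 1:
                raise PileupParseError(f"indel marker {c!r} without length at column {i}")
            run = int(bases[i + 1 : j])
            i = j + run
            continue
        if c in ".,":
            out.append(ref)
        elif c.upper() in _NUCLEOTIDES:
            out.append(c.upper())
        elif c.upper() == "N":
            out.append("N")
        elif c in "*#><":
            out.append("*")
        else:
            raise PileupParseError(f"unknown symbol {c!r} in read-bases string")
        i += 1
    return out


def _tally_to_record(
    chrom: str, pos: int, counts: dict[str, int]
) -> SnpAlleleCount | None:
    if sum(counts.values()) == 0:
        return None
    # sort by count desc, then lexicographic base for deterministic ties
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    major, x = ranked[0]
    minor, y = ranked[1]
    if y == 0:
        minor = "."
    return SnpAlleleCount(chrom, pos, major, minor, x, y)


def counts_from_pileup(
    path: str | Path, panel: SnpPanel, min_base_quality: int = 20
) -> list[SnpAlleleCount]:
    """Tally allele counts at panel positions from a samtools text pileup.

    For each pileup line whose position lies in ``panel``, the read-bases
    string is decoded, bases with Phred quality below ``min_base_quality``
    are discarded, and the two most frequent remaining nucleotides become
    the (major, minor) pair.  Positions with no surviving base are omitted.
    Only A/C/G/T are tallied; Ns and deletion placeholders are dropped after
    quality pairing.
    """
    records: list[SnpAlleleCount] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise PileupParseError(f"line {lineno}: expected 6 pileup columns")
            chrom, pos_s, ref, _depth, bases, quals = fields[:6]
            pos = int(pos_s)
            if not panel.contains(chrom, pos):
                continue
            try:
                decoded = decode_pileup_bases(bases, ref)
            except PileupParseError as exc:
                raise PileupParseError(f"line {lineno}: {exc}") from None
            if len(decoded) != len(quals):
                raise PileupParseError(
                    f"line {lineno}: {len(decoded)} decoded bases but "
                    f"{len(quals)} quality characters"
                )
            counts = dict.fromkeys(_NUCLEOTIDES, 0)
            for base, qc in zip(decoded, quals):
                if base not in _NUCLEOTIDES:
                    continue
                if ord(qc) - 33 < min_base_quality:
                    continue
                counts[base] += 1
            rec = _tally_to_record(chrom, pos, counts)
            if rec is not None:
                records.append(rec)
    return records
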