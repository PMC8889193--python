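"""Domain types and coordinate conventions.

Every positional quantity in the package is expressed in 0-based half-open
coordinates (BED convention).  GFF3 input/output is converted at the I/O
boundary (:mod:`oximap.io`); nothing past that boundary ever sees 1-based
closed coordinates.

CG dinucleotides are strand-collapsed: a site is identified by the position
of its plus-strand C, and a modification observed on either strand of the
dinucleotide maps to that single site.  Fraction statistics count CGs, not
strand-specific cytosines.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

STRANDS = ("+", "-", ".")

MODS = ("5mC", "5hmC", "5fC")


class OximapError(Exception):
    """Base class for package errors."""


class ValidationError(OximapError):
    """A record violates an invariant (coordinates, counts, strands)."""


class ParseError(OximapError):
    """A file could not be parsed; the message names the offending line."""


class ConfigError(OximapError):
    """An operation was configured inconsistently."""


@dataclass(frozen=True)
class Scaffold:
    """A scaffold/chromosome: an id and its length in bp."""

    id: str
    length: int

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValidationError(f"scaffold {self.id!r}: length must be positive")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """0-based half-open interval ``[start, end)`` on a scaffold."""

    scaffold: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval {self.scaffold}:[{self.start},{self.end})"
            )
        if self.strand not in STRANDS:
            raise ValidationError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.scaffold == other.scaffold
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class GeneModel:
    """A gene body with exons and (possibly empty) UTR annotations.

    ``upstream_bp`` is the promoter-proxy length used when deriving the
    upstream interval (strand-aware, default 1 kb).
    """

    gene_id: str
    body: GenomicInterval
    exons: tuple[GenomicInterval, ...] = ()
    utr5: tuple[GenomicInterval, ...] = ()
    utr3: tuple[GenomicInterval, ...] = ()
    upstream_bp: int = 1000

    def __post_init__(self) -> None:
        if self.body.strand not in ("+", "-"):
            raise ValidationError(f"gene {self.gene_id!r}: body must be stranded")
        for name, ivs in (("exon", self.exons), ("utr5", self.utr5), ("utr3", self.utr3)):
            for iv in ivs:
                if iv.scaffold != self.body.scaffold or iv.start < self.body.start or iv.end > self.body.end:
                    raise ValidationError(
                        f"gene {self.gene_id!r}: {name} {iv} outside body {self.body}"
                    )
        ex = sorted(self.exons, key=lambda i: i.start)
        for a, b in zip(ex, ex[1:]):
            if a.end > b.start:
                raise ValidationError(f"gene {self.gene_id!r}: overlapping exons")
        object.__setattr__(self, "exons", tuple(ex))

    @property
    def strand(self) -> str:
        return self.body.strand

    def upstream_interval(self, scaffold_length: int | None = None) -> GenomicInterval | None:
        """Strand-aware upstream (promoter-proxy) interval of ``upstream_bp``.

        Clipped to scaffold bounds; ``None`` when the gene starts at the
        scaffold edge and no upstream base exists.
        """
        if self.strand == "+":
            s = max(0, self.body.start - self.upstream_bp)
            e = self.body.start
        else:
            s = self.body.end
            e = self.body.end + self.upstream_bp
            if scaffold_length is not None:
                e = min(e, scaffold_length)
        if s >= e:
            return None
        return GenomicInterval(self.body.scaffold, s, e, self.strand)

    def introns(self) -> tuple[GenomicInterval, ...]:
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            if a.end < b.start:
                out.append(GenomicInterval(self.body.scaffold, a.end, b.start, self.strand))
        return tuple(out)


@dataclass(frozen=True)
class TEFeature:
    """A transposable element with (possibly unknown) classification labels."""

    te_id: str
    location: GenomicInterval
    te_class: str = "unknown"  # "I" (retro), "II" (DNA), "other", "unknown"
    order: str = "unknown"  # e.g. LTR, TIR, DIRS, LINE, helitron
    family: str = "unknown"  # e.g. Gypsy, Copia


@dataclass(frozen=True, order=True)
class CGSite:
    """Plus-strand C position of a CG dinucleotide (strand-collapsed)."""

    scaffold: str
    pos: int

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValidationError(f"negative CG position {self.pos}")


@dataclass(frozen=True)
class ModCall:
    """A single-CG modification call (TOP-seq style) with read coverage."""

    site: CGSite
    mod: str
    coverage: int
    sample_id: str = ""
    multimap: bool = False

    def __post_init__(self) -> None:
        if self.mod not in MODS:
            raise ValidationError(f"unknown modification {self.mod!r}")
        if not isinstance(self.coverage, (int, np.integer)) or self.coverage < 0:
            raise ValidationError(f"coverage must be a non-negative integer, got {self.coverage!r}")


@dataclass(frozen=True)
class WGBSCall:
    """Bisulfite counts at one CG: methylated reads out of total reads."""

    site: CGSite
    methylated: int
    total: int

    def __post_init__(self) -> None:
        if not (0 <= self.methylated <= self.total):
            raise ValidationError(
                f"WGBS counts {self.methylated}/{self.total} at {self.site} invalid"
            )

    @property
    def level(self) -> float:
        return self.methylated / self.total if self.total else float("nan")


@dataclass(frozen=True, order=True)
class FragmentAlignment:
    """A mapped sequencing fragment: leftmost/rightmost positions, half-open."""

    scaffold: str
    left: int
    right: int
    sample_id: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.left < self.right):
            raise ValidationError(
                f"invalid fragment {self.scaffold}:[{self.left},{self.right})"
            )


@dataclass(frozen=True)
class ExpressionRecord:
    gene_id: str
    tpm: float

    def __post_init__(self) -> None:
        if self.tpm < 0:
            raise ValidationError(f"gene {self.gene_id!r}: negative TPM {self.tpm}")


class IntervalSet:
    """Union of intervals per scaffold with fast positional queries.

    Intervals are merged on construction; queries work on sorted,
    disjoint per-scaffold arrays.
    """

    def __init__(self, intervals: Iterable[GenomicInterval] = ()) -> None:
        by_scaf: dict[str, list[tuple[int, int]]] = {}
        for iv in intervals:
            by_scaf.setdefault(iv.scaffold, []).append((iv.start, iv.end))
        self._merged: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for scaf, pairs in by_scaf.items():
            pairs.sort()
            starts: list[int] = []
            ends: list[int] = []
            for s, e in pairs:
                if starts and s <= ends[-1]:
                    ends[-1] = max(ends[-1], e)
                else:
                    starts.append(s)
                    ends.append(e)
            self._merged[scaf] = (
                np.asarray(starts, dtype=np.int64),
                np.asarray(ends, dtype=np.int64),
            )

    @classmethod
    def from_arrays(cls, by_scaffold: Mapping[str, tuple[np.ndarray, np.ndarray]]) -> "IntervalSet":
        obj = cls()
        for scaf, (s, e) in by_scaffold.items():
            order = np.argsort(s, kind="stable")
            s, e = np.asarray(s)[order], np.asarray(e)[order]
            starts: list[int] = []
            ends: list[int] = []
            for a, b in zip(s.tolist(), e.tolist()):
                if starts and a <= ends[-1]:
                    ends[-1] = max(ends[-1], b)
                else:
                    starts.append(a)
                    ends.append(b)
            obj._merged[scaf] = (
                np.asarray(starts, dtype=np.int64),
                np.asarray(ends, dtype=np.int64),
            )
        return obj

    def scaffolds(self) -> list[str]:
        return sorted(self._merged)

    def intervals(self) -> list[GenomicInterval]:
        out = []
        for scaf in self.scaffolds():
            s, e = self._merged[scaf]
            out.extend(GenomicInterval(scaf, int(a), int(b)) for a, b in zip(s, e))
        return out

    def total_bases(self) -> int:
        return int(
            sum((e - s).sum() for s, e in self._merged.values())
        )

    def _f(self, scaf: str, x: np.ndarray) -> np.ndarray:
        """Covered bases in [0, x) for a vector of positions x."""
        if scaf not in self._merged:
            return np.zeros(len(x), dtype=np.int64)
        s, e = self._merged[scaf]
        if len(s) == 0:
            return np.zeros(len(x), dtype=np.int64)
        cum = np.concatenate([[0], np.cumsum(e - s)])
        j = np.searchsorted(s, x, side="right")  # intervals 0..j-1 start before x
        res = cum[j].copy()
        nz = j > 0
        overshoot = np.zeros_like(res)
        overshoot[nz] = np.clip(e[j[nz] - 1] - x[nz], 0, (e - s)[j[nz] - 1])
        return res - overshoot

    def covered_bases(self, scaffold: str, starts, ends) -> np.ndarray:
        """Bases of each query interval covered by the union."""
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        return self._f(scaffold, ends) - self._f(scaffold, starts)

    def contains(self, scaffold: str, pos) -> np.ndarray:
        """Boolean per position: inside the union?"""
        pos = np.atleast_1d(np.asarray(pos, dtype=np.int64))
        if scaffold not in self._merged:
            return np.zeros(len(pos), dtype=bool)
        s, e = self._merged[scaffold]
        j = np.searchsorted(s, pos, side="right")
        ok = j > 0
        ok[ok] = pos[ok] < e[j[ok] - 1]
        return ok

    def overlaps(self, scaffold: str, starts, ends) -> np.ndarray:
        """Boolean per query interval: >=1 bp overlap with the union?"""
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        if scaffold not in self._merged:
            return np.zeros(len(starts), dtype=bool)
        s, e = self._merged[scaffold]
        if len(s) == 0:
            return np.zeros(len(starts), dtype=bool)
        j = np.searchsorted(s, ends, side="left")  # last interval with s < end is j-1
        ok = j > 0
        ok[ok] = e[j[ok] - 1] > starts[ok]
        return ok

    def overlaps_intervals(self, intervals: Sequence[GenomicInterval]) -> np.ndarray:
        out = np.zeros(len(intervals), dtype=bool)
        by_scaf: dict[str, list[int]] = {}
        for i, iv in enumerate(intervals):
            by_scaf.setdefault(iv.scaffold, []).append(i)
        for scaf, idx in by_scaf.items():
            s = np.array([intervals[i].start for i in idx])
            e = np.array([intervals[i].end for i in idx])
            out[np.asarray(idx)] = self.overlaps(scaf, s, e)
        return out


def validate_against_scaffolds(
    intervals: Iterable[GenomicInterval],
    scaffolds: Sequence[Scaffold],
    lenient: bool = False,
) -> list[GenomicInterval]:
    """Check records against a scaffold table.

    Unknown scaffold or out-of-bounds coordinates raise by default; under
    ``lenient`` the offending records are dropped with a warning.
    """
    import warnings

    lengths = {s.id: s.length for s in scaffolds}
    kept = []
    for iv in intervals:
        if iv.scaffold not in lengths:
            if lenient:
                warnings.warn(f"unknown scaffold {iv.scaffold!r}; record skipped")
                continue
            raise ValidationError(f"unknown scaffold {iv.scaffold!r}")
        if iv.end > lengths[iv.scaffold]:
            if lenient:
                warnings.warn(f"interval {iv} beyond scaffold end; record skipped")
                continue
            raise ValidationError(
                f"interval {iv} extends beyond scaffold length {lengths[iv.scaffold]}"
            )
        kept.append(iv)
    return kept
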