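"""De-novo detection of transposable-element clusters.

A TE cluster is a genomic region of at least 5 kb whose TE base content is
at least 50%.  Detection works on a fixed 100-bp window grid anchored at
scaffold position 0:

1. compute each window's TE content as union-TE bases / window length and
   select windows with content >= 25%;
2. merge selected windows whose gap is <= 100 bp into core clusters;
3. merge core clusters separated by < 10 kb;
4. keep merged cores spanning >= 5 kb with union-TE content >= 50% of the
   span;
5. extend each survivor by 5 kb on both sides, clipped to scaffold bounds;
6. merge any final intervals that overlap after extension.

TE content is always computed over the union of TE intervals, so the
detector is invariant to TE ordering and to splitting a TE into adjacent
pieces.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from oximap.core import GenomicInterval, IntervalSet, Scaffold, TEFeature, ValidationError

DEFAULT_PARAMS = dict(
    window_bp=100,
    content_min=0.25,
    core_gap=100,
    merge_gap=10_000,
    min_len=5_000,
    final_content_min=0.5,
    extend=5_000,
)


@dataclass(frozen=True)
class TECluster:
    """A detected TE cluster: extended interval plus its pre-extension core."""

    final: GenomicInterval
    core: GenomicInterval
    n_te: int
    te_bp: int

    def __post_init__(self) -> None:
        if self.core.scaffold != self.final.scaffold or not (
            self.final.start <= self.core.start and self.core.end <= self.final.end
        ):
            raise ValidationError("cluster core must lie within its final interval")

    @property
    def te_fraction(self) -> float:
        return self.te_bp / len(self.core)


def window_te_content(
    tes: Sequence[TEFeature],
    scaffolds: Sequence[Scaffold],
    window_bp: int = 100,
) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Per-scaffold window grid and TE content fractions.

    Returns ``{scaffold: (starts, ends, fraction)}``.  The trailing partial
    window uses its actual length as the denominator.  Overlapping TEs
    count once (union rule).
    """
    union = IntervalSet(t.location for t in tes)
    out: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for s in sorted(scaffolds, key=lambda x: x.id):
        starts = np.arange(0, s.length, window_bp, dtype=np.int64)
        ends = np.minimum(starts + window_bp, s.length)
        covered = union.covered_bases(s.id, starts, ends)
        out[s.id] = (starts, ends, covered / (ends - starts))
    return out


def _merge_runs(starts: np.ndarray, ends: np.ndarray, max_gap: int, strict: bool) -> list[tuple[int, int]]:
    """Merge sorted intervals whose gap is <= max_gap (or < max_gap if strict)."""
    merged: list[tuple[int, int]] = []
    for a, b in zip(starts.tolist(), ends.tolist()):
        if merged:
            gap = a - merged[-1][1]
            close = gap < max_gap if strict else gap <= max_gap
            if close:
                merged[-1] = (merged[-1][0], max(merged[-1][1], b))
                continue
        merged.append((a, b))
    return merged


def detect_te_clusters(
    tes: Sequence[TEFeature],
    scaffolds: Sequence[Scaffold],
    window_bp: int = 100,
    content_min: float = 0.25,
    core_gap: int = 100,
    merge_gap: int = 10_000,
    min_len: int = 5_000,
    final_content_min: float = 0.5,
    extend: int = 5_000,
) -> list[TECluster]:
    """Run the six detection steps; see the module docstring.

    Gap semantics follow the definitions exactly: windows merge when their
    gap is <= ``core_gap``; cores merge when their gap is strictly below
    ``merge_gap``.  Step-4 content is recomputed over the merged span from
    the union of TE bases, not from window fractions.
    """
    union = IntervalSet(t.location for t in tes)
    lengths = {s.id: s.length for s in scaffolds}
    content = window_te_content(tes, scaffolds, window_bp)

    clusters: list[TECluster] = []
    for s in sorted(scaffolds, key=lambda x: x.id):
        starts, ends, frac = content[s.id]
        sel = frac >= content_min
        if not sel.any():
            continue
        # step 2: selected windows -> core clusters (gap <= core_gap)
        cores = _merge_runs(starts[sel], ends[sel], core_gap, strict=False)
        # step 3: cores within < merge_gap merged
        cs = np.array([c[0] for c in cores])
        ce = np.array([c[1] for c in cores])
        merged = _merge_runs(cs, ce, merge_gap, strict=True)
        # step 4: length and content thresholds over the merged span
        survivors: list[tuple[int, int, int]] = []
        for a, b in merged:
            span = b - a
            te_bp = int(union.covered_bases(s.id, [a], [b])[0])
            if span >= min_len and te_bp / span >= final_content_min:
                survivors.append((a, b, te_bp))
        # step 5: extend, clipped to scaffold bounds
        finals = [
            (max(0, a - extend), min(lengths[s.id], b + extend), a, b, te_bp)
            for a, b, te_bp in survivors
        ]
        # step 6: merge overlapping extended intervals (core becomes the
        # hull of member cores; TE stats recomputed over the hull)
        finals.sort()
        out: list[list[int]] = []
        for fa, fb, ca, cb, te_bp in finals:
            if out and fa < out[-1][1]:
                out[-1][1] = max(out[-1][1], fb)
                out[-1][3] = max(out[-1][3], cb)
            else:
                out.append([fa, fb, ca, cb])
        for fa, fb, ca, cb in out:
            te_bp = int(union.covered_bases(s.id, [ca], [cb])[0])
            core = GenomicInterval(s.id, ca, cb)
            n_te = sum(
                1
                for t in tes
                if t.location.scaffold == s.id
                and t.location.start < cb
                and t.location.end > ca
            )
            clusters.append(TECluster(GenomicInterval(s.id, fa, fb), core, n_te, te_bp))
    clusters.sort(key=lambda c: (c.final.scaffold, c.final.start))
    return clusters


def cluster_summary(clusters: Sequence[TECluster], scaffolds: Sequence[Scaffold]) -> dict:
    """Genome-level cluster statistics over the final (extended) intervals."""
    total_bp = sum(len(c.final) for c in clusters)
    genome_bp = sum(s.length for s in scaffolds)
    return {
        "n_clusters": len(clusters),
        "total_bp": int(total_bp),
        "genome_fraction": total_bp / genome_bp if genome_bp else 0.0,
        "mean_te_per_cluster": (
            float(np.mean([c.n_te for c in clusters])) if clusters else 0.0
        ),
    }


def assign_cluster_membership(
    items: Sequence[GenomicInterval], clusters: Sequence[TECluster]
) -> np.ndarray:
    """True per item iff it overlaps any final cluster interval by >= 1 bp."""
    finals = IntervalSet(c.final for c in clusters)
    return finals.overlaps_intervals(items)
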