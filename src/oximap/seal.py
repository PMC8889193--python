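"""Affinity-enrichment (Seal-style) window signal workflow.

From deduplicated fragment alignments onward: PCR-duplicate removal by
fragment endpoints, equal-size downsampling, non-overlapping 200-bp window
coverage, and background subtraction against a no-labelling control using
the 1.2x enrichment rule.  A window's modification level is the coverage
difference sample - control wherever sample >= 1.2 x control, else 0.

"Coverage" of a window is the number of fragments overlapping it by at
least 1 bp: after endpoint deduplication the fragment is the natural unit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from oximap.core import (
    ConfigError,
    FragmentAlignment,
    GenomicInterval,
    Scaffold,
    ValidationError,
)

DEFAULT_WINDOW = 200
DEFAULT_RATIO = 1.2


@dataclass(frozen=True)
class WindowSignal:
    """Per-window enrichment signal after background subtraction."""

    window: GenomicInterval
    sample_cov: int
    control_cov: int
    signal: float

    def __post_init__(self) -> None:
        if not (0 <= self.signal <= self.sample_cov):
            raise ValidationError(
                f"signal {self.signal} outside [0, sample_cov={self.sample_cov}]"
            )


def deduplicate_fragments(frags: Sequence[FragmentAlignment]) -> list[FragmentAlignment]:
    """Remove PCR duplicates by identical (scaffold, left, right).

    The first occurrence is kept; output is sorted.  Idempotent.
    """
    seen: dict[tuple[str, int, int], FragmentAlignment] = {}
    for f in frags:
        key = (f.scaffold, f.left, f.right)
        if key not in seen:
            seen[key] = f
    return sorted(seen.values())


def downsample_fragments(
    frags: Sequence[FragmentAlignment], n: int, seed: int
) -> list[FragmentAlignment]:
    """Uniform sample of ``n`` fragments without replacement, seeded.

    Used to equalise library sizes per modification and organism before
    window comparison.
    """
    if n > len(frags):
        raise ConfigError(f"cannot downsample {len(frags)} fragments to {n}")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(frags), size=n, replace=False)
    return sorted(frags[i] for i in sorted(idx))


def tile_windows(scaffolds: Sequence[Scaffold], window_bp: int = DEFAULT_WINDOW) -> list[GenomicInterval]:
    """Non-overlapping windows tiling each scaffold from position 0.

    The trailing partial window is kept.
    """
    out: list[GenomicInterval] = []
    for s in sorted(scaffolds, key=lambda x: x.id):
        starts = range(0, s.length, window_bp)
        out.extend(GenomicInterval(s.id, a, min(a + window_bp, s.length)) for a in starts)
    return out


def window_coverage(
    frags: Sequence[FragmentAlignment],
    scaffolds: Sequence[Scaffold],
    window_bp: int = DEFAULT_WINDOW,
) -> tuple[list[GenomicInterval], np.ndarray]:
    """Fragment counts per non-overlapping window.

    A fragment counts for every window it overlaps by >= 1 bp.  Fragments
    beyond a scaffold end (or on unknown scaffolds) are an error.
    """
    lengths = {s.id: s.length for s in scaffolds}
    windows = tile_windows(scaffolds, window_bp)
    counts = np.zeros(len(windows), dtype=np.int64)
    # index of first window of each scaffold in the flat window list
    offset: dict[str, int] = {}
    nwin: dict[str, int] = {}
    for i, w in enumerate(windows):
        if w.scaffold not in offset:
            offset[w.scaffold] = i
        nwin[w.scaffold] = nwin.get(w.scaffold, 0) + 1
    for f in frags:
        if f.scaffold not in lengths:
            raise ValidationError(f"fragment on unknown scaffold {f.scaffold!r}")
        if f.right > lengths[f.scaffold]:
            raise ValidationError(
                f"fragment {f.scaffold}:[{f.left},{f.right}) beyond scaffold end"
            )
        first = f.left // window_bp
        last = (f.right - 1) // window_bp  # inclusive window index
        base = offset[f.scaffold]
        counts[base + first : base + last + 1] += 1
    return windows, counts


def subtract_background(
    sample_windows: Sequence[GenomicInterval],
    sample_cov: np.ndarray,
    control_windows: Sequence[GenomicInterval],
    control_cov: np.ndarray,
    ratio: float = DEFAULT_RATIO,
) -> list[WindowSignal]:
    """Background subtraction with the enrichment-ratio rule.

    signal = sample - control where sample >= ratio * control (inclusive),
    else 0.  A window with control 0 and sample > 0 passes trivially.
    Both inputs must share an identical window tiling.
    """
    if list(sample_windows) != list(control_windows):
        raise ConfigError("sample and control window tilings differ")
    sample_cov = np.asarray(sample_cov)
    control_cov = np.asarray(control_cov)
    if len(sample_cov) != len(sample_windows) or len(control_cov) != len(control_windows):
        raise ConfigError("coverage vectors do not match window tiling")
    passes = sample_cov >= ratio * control_cov
    signal = np.where(passes, sample_cov - control_cov, 0)
    return [
        WindowSignal(w, int(s), int(c), float(x))
        for w, s, c, x in zip(sample_windows, sample_cov, control_cov, signal)
    ]


def positive_windows(signals: Sequence[WindowSignal]) -> set[GenomicInterval]:
    """Windows carrying signal (> 0); the membership unit for bin overlap."""
    return {w.window for w in signals if w.signal > 0}


def jaccard_bins(set_a: set, set_b: set) -> float:
    """Jaccard coefficient |A & B| / |A | B| of two signal-positive bin sets.

    Defined as 0 when both sets are empty.
    """
    union = set_a | set_b
    if not union:
        return 0.0
    return len(set_a & set_b) / len(union)
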