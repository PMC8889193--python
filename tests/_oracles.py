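"""Independent brute-force oracles used to validate the implementation.

Everything here is deliberately literal and slow: base-level boolean masks
for interval arithmetic, exact integer hypergeometric enumeration for
Fisher's test, linear scans for overlap queries.  None of it shares code
with the package.
"""

from __future__ import annotations

import math

import numpy as np


def brute_window_te_content(te_spans, scaffold_len, window_bp=100):
    """Per-window TE content via a base-level mask."""
    mask = np.zeros(scaffold_len, dtype=bool)
    for s, e in te_spans:
        mask[s:e] = True
    out = []
    for a in range(0, scaffold_len, window_bp):
        b = min(a + window_bp, scaffold_len)
        out.append((a, b, mask[a:b].mean()))
    return out


def brute_detect_clusters(
    te_spans,
    scaffold_len,
    window_bp=100,
    content_min=0.25,
    core_gap=100,
    merge_gap=10_000,
    min_len=5_000,
    final_content_min=0.5,
    extend=5_000,
):
    """Literal implementation of the detection steps on one scaffold.

    Returns a list of (final_start, final_end, core_start, core_end).
    """
    mask = np.zeros(scaffold_len, dtype=bool)
    for s, e in te_spans:
        mask[s:e] = True
    # step 1: windows with content >= content_min
    selected = [
        (a, b)
        for a, b, f in brute_window_te_content(te_spans, scaffold_len, window_bp)
        if f >= content_min
    ]
    # step 2: merge windows with gap <= core_gap
    cores = []
    for a, b in selected:
        if cores and a - cores[-1][1] <= core_gap:
            cores[-1][1] = max(cores[-1][1], b)
        else:
            cores.append([a, b])
    # step 3: merge cores with gap < merge_gap
    merged = []
    for a, b in cores:
        if merged and a - merged[-1][1] < merge_gap:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    # step 4: length and union-content thresholds
    survivors = [
        (a, b)
        for a, b in merged
        if b - a >= min_len and mask[a:b].sum() / (b - a) >= final_content_min
    ]
    # step 5: extend, clipped
    finals = [
        [max(0, a - extend), min(scaffold_len, b + extend), a, b] for a, b in survivors
    ]
    # step 6: merge overlapping finals
    out = []
    for fa, fb, ca, cb in finals:
        if out and fa < out[-1][1]:
            out[-1][1] = max(out[-1][1], fb)
            out[-1][3] = max(out[-1][3], cb)
        else:
            out.append([fa, fb, ca, cb])
    return [tuple(x) for x in out]


def fisher_twosided_exact(a, b, c, d):
    """Two-sided Fisher p by exact integer hypergeometric enumeration.

    All tables with the observed margins whose (integer) probability
    weight does not exceed the observed table's weight contribute.
    """
    n1, n2, m1 = a + b, c + d, a + c
    w_obs = math.comb(n1, a) * math.comb(n2, c)
    total = math.comb(n1 + n2, m1)
    num = 0
    for k in range(max(0, m1 - n2), min(n1, m1) + 1):
        w = math.comb(n1, k) * math.comb(n2, m1 - k)
        if w <= w_obs:
            num += w
    return num / total


def brute_fragment_window_counts(frags, scaffold_len, window_bp=200):
    """Per-window fragment counts by pairwise overlap checks."""
    windows = [
        (a, min(a + window_bp, scaffold_len)) for a in range(0, scaffold_len, window_bp)
    ]
    counts = []
    for ws, we in windows:
        counts.append(sum(1 for l, r in frags if l < we and ws < r))
    return windows, counts


def brute_te_context(gene_start, gene_end, strand, te_spans, distance=1000):
    """Nearest-TE scan classification for a single-scaffold gene."""
    overlap = any(s < gene_end and gene_start < e for s, e in te_spans)
    if overlap:
        return "overlap"
    left = any(e <= gene_start and gene_start - e < distance for s, e in te_spans)
    right = any(s >= gene_end and s - gene_end < distance for s, e in te_spans)
    up, down = (left, right) if strand == "+" else (right, left)
    if up and down:
        return "up/downstream"
    if up:
        return "upstream"
    if down:
        return "downstream"
    return "clean"


def brute_cg_scan(sequence):
    """Positions of plus-strand CG dinucleotides by a character loop."""
    seq = sequence.upper()
    return [i for i in range(len(seq) - 1) if seq[i] == "C" and seq[i + 1] == "G"]


def random_te_spans(rng, scaffold_len, max_tes=30, max_len=8000):
    """Random TE layout for oracle-equivalence checks (overlaps allowed)."""
    n = int(rng.integers(0, max_tes + 1))
    spans = []
    for _ in range(n):
        length = int(rng.integers(100, max_len + 1))
        start = int(rng.integers(0, max(1, scaffold_len - length)))
        spans.append((start, start + length))
    return spans
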