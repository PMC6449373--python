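"""Independent brute-force oracles used by the test suite.

Each oracle recomputes a quantity by the most literal method available
(explicit enumeration, union-find, exact rational arithmetic) and stays
independent of the implementation path it checks.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np


def percentile_scores_oracle(values, genes):
    """Per-sample mean percentile by explicit sort and tie-group enumeration.

    ``values`` is a probesets x samples DataFrame.  Ranks are ascending
    1..N; every member of a tie group receives the arithmetic mean of the
    ranks the group spans; percentile = rank / N.
    """

    n = values.shape[0]
    out = {}
    for sample in values.columns:
        col = values[sample]
        ordered = col.sort_values(kind="mergesort")
        ranks: dict[str, float] = {}
        i = 0
        vals = ordered.to_numpy()
        ids = ordered.index.to_list()
        while i < n:
            j = i
            while j + 1 < n and vals[j + 1] == vals[i]:
                j += 1
            avg_rank = (i + 1 + j + 1) / 2.0
            for k in range(i, j + 1):
                ranks[ids[k]] = avg_rank
            i = j + 1
        percs = np.array([ranks[g] / n for g in genes])
        out[sample] = np.mean(percs)
    return out


def run_length_peaks_oracle(counts, threshold, bin_width, min_width, start_offset=0):
    """Peak intervals by walking bins one at a time."""
    peaks = []
    run_start = None
    for i, v in enumerate(list(counts) + [-1.0]):  # sentinel terminates last run
        if v >= threshold and run_start is None:
            run_start = i
        elif v < threshold and run_start is not None:
            a = start_offset + run_start * bin_width
            b = start_offset + i * bin_width
            if b - a >= min_width:
                peaks.append((a, b))
            run_start = None
    return peaks


def stitch_oracle(peaks, distance):
    """Transitive merge by union-find over all peak pairs."""
    n = len(peaks)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x, y):
        parent[find(x)] = find(y)

    for i in range(n):
        for j in range(i + 1, n):
            gap = max(peaks[j][0] - peaks[i][1], peaks[i][0] - peaks[j][1])
            if gap <= distance:
                union(i, j)
    groups: dict[int, list[tuple[int, int]]] = {}
    for i, p in enumerate(peaks):
        groups.setdefault(find(i), []).append(p)
    merged = sorted(
        (min(a for a, _ in g), max(b for _, b in g), len(g)) for g in groups.values()
    )
    return merged


def elbow_cutoff_oracle(signals):
    """Cutoff index by scanning every rank's discrete slope explicitly.

    Signals must be sorted ascending.  Axes are min-max rescaled; the
    cutoff is one above the largest rank whose slope is <= 1 (i.e. the
    first non-steep rank met when descending from the top).
    """

    signals = np.asarray(signals, dtype=float)
    n = signals.size
    lo, hi = signals.min(), signals.max()
    if hi == lo:
        return n - 1
    y = (signals - lo) / (hi - lo)
    x = np.arange(n) / (n - 1)
    best = 0
    for i in range(n - 1):
        slope = (y[i + 1] - y[i]) / (x[i + 1] - x[i])
        if slope <= 1.0:
            best = i + 1
    return best


def fisher_greater_oracle(a, b, c, d):
    """One-sided (enrichment) Fisher p by exact hypergeometric enumeration."""
    row1 = a + b
    row2 = c + d
    col1 = a + c
    n = row1 + row2
    denom = comb(n, col1)
    p = Fraction(0)
    for k in range(a, min(row1, col1) + 1):
        if col1 - k <= row2:
            p += Fraction(comb(row1, k) * comb(row2, col1 - k), denom)
    return float(p)


_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(seq):
    return "".join(_COMP[b] for b in reversed(seq))


def scan_oracle(sequence, counts, pseudocount, score_fraction):
    """All motif hits by rescoring every window in pure Python.

    ``counts`` is the 4 x L count grid in A, C, G, T order.  Returns a set
    of (start, end, strand) triples.
    """

    counts = np.asarray(counts, dtype=float)
    L = counts.shape[1]
    totals = counts.sum(axis=0)
    lods = np.log2((counts + pseudocount * 0.25) / (totals + pseudocount) / 0.25)
    max_score = sum(max(lods[r][j] for r in range(4)) for j in range(L))
    threshold = score_fraction * max_score
    order = "ACGT"
    hits = set()
    for start in range(len(sequence) - L + 1):
        window = sequence[start : start + L]
        if "N" in window:
            continue
        fwd = sum(lods[order.index(base)][j] for j, base in enumerate(window))
        if fwd >= threshold:
            hits.add((start, start + L, "+"))
        rev = sum(
            lods[order.index(base)][j] for j, base in enumerate(revcomp(window))
        )
        if rev >= threshold:
            hits.add((start, start + L, "-"))
    return hits


def assign_genes_oracle(regions, genes):
    """Region-to-gene assignment by exhaustive distance computation."""
    out = {}
    for start, end in regions:
        overlapping = sorted(
            g.gene_id for g in genes if g.start < end and start < g.end
        )
        if overlapping:
            out[(start, end)] = overlapping
            continue
        best_gene, best_dist = None, None
        for g in sorted(genes, key=lambda g: g.gene_id):
            if start <= g.tss < end:
                dist = 0
            elif g.tss < start:
                dist = start - g.tss
            else:
                dist = g.tss - (end - 1)
            if best_dist is None or dist < best_dist:
                best_gene, best_dist = g.gene_id, dist
        out[(start, end)] = [best_gene]
    return out
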