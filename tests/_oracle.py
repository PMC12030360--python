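"""Naive O(n*w) reference detector used as an independent oracle in tests.

Everything here is deliberately written the slow, direct way: per-base run
scores by walking the string, every window mean recomputed from scratch by
slicing, merging and refinement by explicit scanning. It shares no code
with g4scape.g4scan.
"""

from __future__ import annotations

import numpy as np

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def naive_revcomp(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq.upper()))


def naive_base_scores(seq: str, run_cap: int = 4) -> list[int]:
    seq = seq.upper()
    scores = [0] * len(seq)
    i = 0
    while i < len(seq):
        b = seq[i]
        if b in "GC":
            j = i
            while j < len(seq) and seq[j] == b:
                j += 1
            val = min(j - i, run_cap)
            for k in range(i, j):
                scores[k] = val if b == "G" else -val
            i = j
        else:
            i += 1
    return scores


def naive_detect(
    seq: str,
    window: int = 25,
    threshold: float = 1.2,
    run_cap: int = 4,
    drop_n: bool = True,
    dedupe: bool = True,
) -> list[tuple[int, int, str, float]]:
    """(start, end, strand, refined mean score) tuples, sorted."""
    seq = seq.upper()
    scores = naive_base_scores(seq, run_cap)
    n = len(seq)
    if n < window:
        return []
    arr = np.asarray(scores)
    means = [float(arr[i : i + window].mean()) for i in range(n - window + 1)]

    hits: list[tuple[int, int, str, float]] = []
    for sign, strand, base in ((+1, "+", "G"), (-1, "-", "C")):
        selected = [
            i for i, m in enumerate(means) if (m >= threshold if sign > 0 else m <= -threshold)
        ]
        # merge overlapping/adjacent selected windows
        candidates: list[list[int]] = []
        for i in selected:
            if candidates and i <= candidates[-1][1]:
                candidates[-1][1] = max(candidates[-1][1], i + window)
            else:
                candidates.append([i, i + window])
        for s, e in candidates:
            # extend to complete runs of the signed base crossing the ends
            while s > 0 and seq[s] == base and seq[s - 1] == base:
                s -= 1
            while e < n and seq[e - 1] == base and seq[e] == base:
                e += 1
            # trim terminal zero-scoring bases
            while s < e and scores[s] == 0:
                s += 1
            while e > s and scores[e - 1] == 0:
                e -= 1
            if s >= e:
                continue
            score = float(np.mean(scores[s:e]))
            if score == 0 or (score > 0) != (sign > 0):
                continue
            hits.append((s, e, strand, score))

    if drop_n:
        hits = [h for h in hits if "N" not in seq[h[0] : h[1]]]
    if dedupe:
        hits = sorted(set(hits))
    return sorted(hits)
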