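"""G4Hunter-style detection of G-quadruplex-forming sequences.

The score of a base is the length of the maximal run of guanines it belongs
to, capped at 4 (positive), or minus the capped length of its cytosine run
(negative); A, T and N score 0 and break runs.  A sliding window of fixed
size (default 25 nt) is averaged over these per-base scores; windows whose
mean reaches +threshold mark G-rich (``+`` strand) candidates and windows
reaching -threshold mark C-rich (``-`` strand) candidates, i.e. a G-tract on
the reverse strand.  Overlapping/adjacent same-sign windows are merged,
merged intervals are refined to complete G/C runs and stripped of
zero-scoring terminal bases, and the reported score is the mean base score
over the refined interval.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger("g4scape")

_CODE_A, _CODE_C, _CODE_G, _CODE_T, _CODE_N = 65, 67, 71, 84, 78
_VALID_CODES = frozenset((_CODE_A, _CODE_C, _CODE_G, _CODE_T, _CODE_N))

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(sequence: str) -> str:
    """Reverse complement of a nucleotide string (case preserved)."""
    return sequence.translate(COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ScanParams:
    """Parameters of a detection run.

    window
        Sliding-window size in bp (default 25).
    threshold
        Minimum |window mean| for a candidate window (default 1.2,
        inclusive comparison).
    run_cap
        Per-base run-length score cap (default 4).
    drop_n
        Cleaning step: discard refined hits whose sequence contains N.
    dedupe
        Cleaning step: collapse identical refined intervals.
    skip_masked
        Treat soft-masked (lowercase) bases as N, i.e. skip masked regions.
    """

    window: int = 25
    threshold: float = 1.2
    run_cap: int = 4
    drop_n: bool = True
    dedupe: bool = True
    skip_masked: bool = False

    def __post_init__(self) -> None:
        if self.window < 1:
            raise ValueError(f"window must be >= 1, got {self.window}")
        if not self.threshold > 0:
            raise ValueError(f"threshold must be > 0, got {self.threshold}")
        if self.run_cap < 1:
            raise ValueError(f"run_cap must be >= 1, got {self.run_cap}")


@dataclass(frozen=True)
class G4Hit:
    """One detected quadruplex-forming interval (0-based half-open).

    ``strand`` is the strand carrying the G-rich tract; ``score`` is the
    signed mean per-base score over the refined interval on the forward
    strand, so positive scores always pair with strand ``+``.
    ``max_window_mean`` retains the most extreme window mean among the
    windows that seeded the hit.
    """

    seq_id: str
    start: int
    end: int
    strand: str
    score: float
    max_window_mean: float
    sequence: str

    @property
    def length(self) -> int:
        return self.end - self.start

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("hit interval must be non-empty")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")
        if self.score == 0:
            raise ValueError("hit score must be nonzero")
        if (self.score > 0) != (self.strand == "+"):
            raise ValueError("sign of score must match strand")


def _encode(sequence: str, skip_masked: bool) -> np.ndarray:
    """Uppercase byte codes; masked bases become N when skip_masked."""
    try:
        arr = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8).copy()
    except UnicodeEncodeError as exc:
        raise ValueError(f"non-ASCII character in sequence: {exc}") from None
    lower = (arr >= 97) & (arr <= 122)
    if skip_masked:
        arr[lower] = _CODE_N
    else:
        arr[lower] -= 32
    bad = ~np.isin(arr, list(_VALID_CODES))
    if bad.any():
        pos = int(np.flatnonzero(bad)[0])
        raise ValueError(
            f"non-nucleotide character {sequence[pos]!r} at position {pos}"
        )
    return arr


def _run_lengths(mask: np.ndarray) -> np.ndarray:
    """For each True base, the length of its maximal run; 0 elsewhere."""
    n = mask.size
    out = np.zeros(n, dtype=np.int64)
    if n == 0 or not mask.any():
        return out
    m = mask.astype(np.int8)
    diff = np.diff(m)
    starts = np.flatnonzero(diff == 1) + 1
    ends = np.flatnonzero(diff == -1) + 1
    if mask[0]:
        starts = np.concatenate(([0], starts))
    if mask[-1]:
        ends = np.concatenate((ends, [n]))
    for s, e in zip(starts, ends):
        out[s:e] = e - s
    return out


def base_scores(sequence: str, run_cap: int = 4, *, skip_masked: bool = False) -> np.ndarray:
    """Signed per-base run scores: +min(k, cap) in G runs, -min(k, cap) in C runs."""
    arr = _encode(sequence, skip_masked)
    scores = np.zeros(arr.size, dtype=np.int64)
    g_len = _run_lengths(arr == _CODE_G)
    c_len = _run_lengths(arr == _CODE_C)
    np.minimum(g_len, run_cap, out=g_len)
    np.minimum(c_len, run_cap, out=c_len)
    return scores + g_len - c_len


def window_means(scores: np.ndarray, window: int) -> np.ndarray:
    """Arithmetic mean of every length-`window` slice; empty if too short."""
    scores = np.asarray(scores)
    if scores.size < window:
        logger.debug("sequence shorter than window (%d < %d)", scores.size, window)
        return np.zeros(0, dtype=float)
    cs = np.concatenate(([0], np.cumsum(scores, dtype=np.int64)))
    return (cs[window:] - cs[:-window]) / window


def _merge_window_starts(starts: np.ndarray, window: int) -> list[tuple[int, int]]:
    """Union intervals of overlapping/adjacent selected windows."""
    if starts.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(starts) > window)
    groups = np.split(starts, breaks + 1)
    return [(int(g[0]), int(g[-1]) + window) for g in groups]


def _refine(
    cand: tuple[int, int],
    arr: np.ndarray,
    scores: np.ndarray,
    sign: int,
) -> tuple[int, int] | None:
    """Extend to complete G (sign +) / C (sign -) runs, then trim zero ends."""
    s, e = cand
    code = _CODE_G if sign > 0 else _CODE_C
    if arr[s] == code:
        while s > 0 and arr[s - 1] == code:
            s -= 1
    if arr[e - 1] == code:
        while e < arr.size and arr[e] == code:
            e += 1
    while s < e and scores[s] == 0:
        s += 1
    while e > s and scores[e - 1] == 0:
        e -= 1
    if s >= e:
        return None
    return s, e


def detect(sequence: str, params: ScanParams | None = None, seq_id: str = "seq") -> list[G4Hit]:
    """Run the full detection pass on one sequence.

    Returns hits sorted by start; ``+`` hits are G-rich on the forward
    strand, ``-`` hits are C-rich on the forward strand (G-rich on the
    reverse strand). Scores are means over the refined interval and may
    fall below the window threshold.
    """
    params = params or ScanParams()
    arr = _encode(sequence, params.skip_masked)
    scores = np.zeros(arr.size, dtype=np.int64)
    g_len = np.minimum(_run_lengths(arr == _CODE_G), params.run_cap)
    c_len = np.minimum(_run_lengths(arr == _CODE_C), params.run_cap)
    scores += g_len - c_len

    means = window_means(scores, params.window)
    if means.size == 0:
        return []

    hits: list[G4Hit] = []
    for sign in (+1, -1):
        if sign > 0:
            sel = np.flatnonzero(means >= params.threshold)
        else:
            sel = np.flatnonzero(means <= -params.threshold)
        for cand in _merge_window_starts(sel, params.window):
            refined = _refine(cand, arr, scores, sign)
            if refined is None:
                continue
            s, e = refined
            seed_lo = max(0, cand[0])
            seed_hi = min(means.size, cand[1] - params.window + 1)
            seed = means[seed_lo:seed_hi]
            extreme = float(seed.max() if sign > 0 else seed.min())
            score = float(scores[s:e].mean())
            # degenerate refinements whose mean lost the candidate's sign
            if score == 0 or (score > 0) != (sign > 0):
                continue
            hits.append(
                G4Hit(
                    seq_id=seq_id,
                    start=s,
                    end=e,
                    strand="+" if sign > 0 else "-",
                    score=score,
                    max_window_mean=extreme,
                    sequence=sequence[s:e].upper(),
                )
            )

    if params.drop_n:
        kept = [h for h in hits if "N" not in h.sequence]
        if len(kept) != len(hits):
            logger.info("dropped %d hit(s) containing N", len(hits) - len(kept))
        hits = kept
    if params.dedupe:
        seen: set[tuple[int, int, str]] = set()
        unique = []
        for h in sorted(hits, key=lambda h: (h.start, h.end, h.strand)):
            key = (h.start, h.end, h.strand)
            if key not in seen:
                seen.add(key)
                unique.append(h)
        hits = unique
    hits.sort(key=lambda h: (h.start, h.end, h.strand))
    return hits


HIT_COLUMNS = ["seq_id", "start", "end", "strand", "score", "max_window_mean", "length", "sequence"]


def hits_to_frame(hits: Iterable[G4Hit]) -> pd.DataFrame:
    rows = [
        (h.seq_id, h.start, h.end, h.strand, h.score, h.max_window_mean, h.length, h.sequence)
        for h in hits
    ]
    return pd.DataFrame(rows, columns=HIT_COLUMNS)


def _iter_fasta(path: str | Path) -> Iterator:
    path = Path(path)
    if path.suffix == ".gz":
        with gzip.open(path, "rt") as fh:
            yield from SeqIO.parse(fh, "fasta")
    else:
        yield from SeqIO.parse(str(path), "fasta")


def fasta_lengths(path: str | Path) -> dict[str, int]:
    """Sequence lengths keyed by record ID (duplicate IDs are an error)."""
    lengths: dict[str, int] = {}
    for record in _iter_fasta(path):
        if record.id in lengths:
            raise ValueError(f"duplicate sequence ID {record.id!r} in {path}")
        lengths[record.id] = len(record.seq)
    if not lengths:
        raise ValueError(f"no sequences found in FASTA {path}")
    return lengths


def gc_percent(sequence: str) -> float:
    up = sequence.upper()
    n = len(sequence)
    if n == 0:
        return 0.0
    return 100.0 * (up.count("G") + up.count("C")) / n


def scan_fasta(
    path: str | Path, params: ScanParams | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Scan every record of a FASTA file.

    Returns ``(hits, summary)``: the hit table and a per-sequence summary
    with length, GC%, hit count and density per kbp (full precision; round
    for reports).
    """
    params = params or ScanParams()
    all_hits: list[G4Hit] = []
    summary_rows = []
    seen_ids: set[str] = set()
    for record in _iter_fasta(path):
        if record.id in seen_ids:
            raise ValueError(f"duplicate sequence ID {record.id!r} in {path}")
        seen_ids.add(record.id)
        seq = str(record.seq)
        hits = detect(seq, params, seq_id=record.id)
        all_hits.extend(hits)
        summary_rows.append(
            (
                record.id,
                len(seq),
                gc_percent(seq),
                len(hits),
                len(hits) / (len(seq) / 1000.0) if len(seq) else 0.0,
            )
        )
    if not summary_rows:
        raise ValueError(f"no sequences found in FASTA {path}")
    hits_df = hits_to_frame(all_hits)
    summary = pd.DataFrame(
        summary_rows, columns=["seq_id", "length", "gc_percent", "n_hits", "density_per_kbp"]
    )
    return hits_df, summary


def write_bed(hits: pd.DataFrame, path: str | Path) -> None:
    """BED6: name = sequential hit ID, score = round(|score| * 100)."""
    with open(path, "w") as fh:
        for i, row in enumerate(hits.itertuples(index=False), start=1):
            fh.write(
                f"{row.seq_id}\t{row.start}\t{row.end}\tg4_{i:06d}"
                f"\t{round(abs(row.score) * 100)}\t{row.strand}\n"
            )


def write_hits_tsv(hits: pd.DataFrame, path: str | Path) -> None:
    hits.to_csv(path, sep="\t", index=False)


def write_summary_tsv(summary: pd.DataFrame, path: str | Path) -> None:
    out = summary.copy()
    out["gc_percent"] = out["gc_percent"].round(1)
    out["density_per_kbp"] = out["density_per_kbp"].round(2)
    out.to_csv(path, sep="\t", index=False)
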