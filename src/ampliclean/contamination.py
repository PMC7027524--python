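"""Positional peak detection and amplicon read removal.

Under random fragmentation, read start (and end) coordinates on an
rRNA model of length L are uniform: each of N reads hits position p
with probability ~1/L, so the per-position count is Binomial(N, 1/L).
Amplicon carryover breaks this — contaminating reads share the
primer-anchored coordinates, producing sharp peaks in the start/end
histograms.  "A clear peak" is formalized here as a per-position
one-sided binomial test against Binomial(N, 1/L), Benjamini-Hochberg
adjusted across the L positions, combined with a fold-enrichment floor
and an absolute count floor so low-depth noise cannot trigger calls.
Flagged positions are merged into windows; any read whose start falls
in a start-window or whose end falls in an end-window is removed.

A cheap per-sample screen precedes all of this: a wildly inflated
SSU:LSU read-count ratio (tens instead of order one) is itself a
symptom of 16S amplicon carryover and marks the sample for coordinate
profiling.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .rrna_mapping import CoordRecord

logger = logging.getLogger(__name__)


@dataclass
class CoordProfile:
    """Per-position start/end count histograms for one marker.

    ``start_counts[p-1]`` is the number of records with model_start = p
    (1-based positions); likewise ``end_counts``.  Both arrays have
    length ``length`` and each sums to ``total``.
    """

    marker: str
    length: int
    start_counts: np.ndarray
    end_counts: np.ndarray

    @property
    def total(self) -> int:
        return int(self.start_counts.sum())


@dataclass(frozen=True)
class PeakWindow:
    """A contiguous run of significantly enriched positions.

    ``kind`` says which histogram it was called on; ``lo``..``hi`` are
    1-based inclusive model positions; ``fold`` is the window's maximum
    per-position count over the uniform expectation N/L; ``p_adj`` the
    smallest BH-adjusted p-value inside the window.
    """

    kind: str  # "start" | "end"
    lo: int
    hi: int
    read_count: int
    fold: float
    p_adj: float

    @property
    def width(self) -> int:
        return self.hi - self.lo + 1

    def __contains__(self, position: int) -> bool:
        return self.lo <= position <= self.hi


@dataclass
class DecontamReport:
    """Outcome of one removal pass (conservation: removed + retained = input)."""

    windows: list[PeakWindow]
    n_input: int
    n_removed: int
    n_retained: int
    removed_ids: list[str] = field(default_factory=list)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)
            fh.write("\n")


@dataclass
class ScreenResult:
    """SSU:LSU count-ratio screen for one sample."""

    n_ssu: int
    n_lsu: int
    ratio: float | None
    flagged: bool
    threshold: float


def build_profile(records, marker: str, length: int) -> CoordProfile:
    """Histogram record start/end coordinates over a model of ``length``.

    Every record must carry ``marker`` and coordinates within
    [1, length]; violations raise, naming the offending read.
    """
    records = list(records)
    for rec in records:
        if rec.marker != marker:
            raise ValueError(
                f"read {rec.read_id} has marker {rec.marker}, expected {marker}"
            )
        if not (1 <= rec.model_start <= length and 1 <= rec.model_end <= length):
            raise ValueError(
                f"read {rec.read_id} coordinates ({rec.model_start}, "
                f"{rec.model_end}) outside [1, {length}]"
            )
    starts = np.fromiter((r.model_start for r in records), dtype=np.int64,
                         count=len(records))
    ends = np.fromiter((r.model_end for r in records), dtype=np.int64,
                       count=len(records))
    return profile_from_coords(starts, ends, marker, length)


def profile_from_coords(starts, ends, marker: str, length: int) -> CoordProfile:
    """Vectorized profile construction from coordinate arrays (1-based)."""
    starts = np.asarray(starts, dtype=np.int64)
    ends = np.asarray(ends, dtype=np.int64)
    if starts.shape != ends.shape:
        raise ValueError("starts and ends must have equal length")
    if starts.size and not (
        (starts >= 1).all() and (ends <= length).all() and (starts <= ends).all()
    ):
        raise ValueError(f"coordinates outside [1, {length}] or start > end")
    return CoordProfile(
        marker=marker,
        length=length,
        start_counts=np.bincount(starts - 1, minlength=length),
        end_counts=np.bincount(ends - 1, minlength=length),
    )


def _merge_positions(positions: np.ndarray, merge_gap: int) -> list[tuple[int, int]]:
    """Group sorted flagged positions; gaps <= merge_gap stay in one window."""
    windows = []
    lo = prev = int(positions[0])
    for p in positions[1:]:
        p = int(p)
        if p - prev <= merge_gap:
            prev = p
        else:
            windows.append((lo, prev))
            lo = prev = p
    windows.append((lo, prev))
    return windows


def detect_peaks(
    profile: CoordProfile,
    alpha: float = 0.01,
    min_fold: float = 5.0,
    min_count: int = 10,
    merge_gap: int = 3,
) -> list[PeakWindow]:
    """Call enriched start/end windows against the uniform null.

    For each of the start and end histograms independently: test each
    position's count c_p one-sided against Binomial(N, 1/L), adjust the
    L p-values with Benjamini-Hochberg, and flag positions with
    p_adj <= ``alpha`` AND c_p >= ``min_fold``*N/L AND c_p >=
    ``min_count``.  Flagged positions within ``merge_gap`` of each other
    merge into one window.  Windows are returned start-kind first, each
    kind sorted by position.
    """
    N = profile.total
    L = profile.length
    if L == 0:
        raise ValueError("profile has zero length")
    if N == 0:
        raise ValueError("profile has zero reads")
    expected = N / L
    out: list[PeakWindow] = []
    for kind, counts in (("start", profile.start_counts), ("end", profile.end_counts)):
        pvals = stats.binom.sf(counts - 1, N, 1.0 / L)  # P(X >= c)
        p_adj = multipletests(pvals, alpha=alpha, method="fdr_bh")[1]
        flagged = (p_adj <= alpha) & (counts >= min_fold * expected) & (counts >= min_count)
        pos = np.flatnonzero(flagged) + 1
        if pos.size == 0:
            continue
        for lo, hi in _merge_positions(pos, merge_gap):
            window_counts = counts[lo - 1 : hi]
            out.append(
                PeakWindow(
                    kind=kind,
                    lo=lo,
                    hi=hi,
                    read_count=int(window_counts.sum()),
                    fold=float(window_counts.max() / expected),
                    p_adj=float(p_adj[lo - 1 : hi].min()),
                )
            )
    return out


def decontaminate(records, windows) -> tuple[list[CoordRecord], DecontamReport]:
    """Remove reads anchored in any peak window.

    A record is removed iff its model_start lies in a start-kind window
    OR its model_end lies in an end-kind window.  With no windows this
    is the identity.  Returns (retained records, report).
    """
    start_wins = [w for w in windows if w.kind == "start"]
    end_wins = [w for w in windows if w.kind == "end"]
    retained: list[CoordRecord] = []
    removed_ids: list[str] = []
    n_input = 0
    for rec in records:
        n_input += 1
        hit = any(rec.model_start in w for w in start_wins) or any(
            rec.model_end in w for w in end_wins
        )
        if hit:
            removed_ids.append(rec.read_id)
        else:
            retained.append(rec)
    report = DecontamReport(
        windows=list(windows),
        n_input=n_input,
        n_removed=len(removed_ids),
        n_retained=len(retained),
        removed_ids=removed_ids,
    )
    return retained, report


def screen_ssu_lsu(n_ssu: int, n_lsu: int, threshold: float = 10.0) -> ScreenResult:
    """Flag a sample whose SSU:LSU read-count ratio is implausibly high.

    Both rRNA subunits are single-copy per operon, so counts of the same
    order are expected; a ratio above ``threshold`` (default 10) marks
    likely 16S amplicon carryover.  ``n_lsu = 0`` with ``n_ssu > 0``
    flags with an undefined ratio; both zero yields an unflagged result
    with a warning.
    """
    if n_ssu < 0 or n_lsu < 0:
        raise ValueError("counts must be >= 0")
    if n_lsu == 0:
        if n_ssu == 0:
            warnings.warn("no SSU or LSU reads; screen is uninformative")
            return ScreenResult(n_ssu, n_lsu, None, False, threshold)
        return ScreenResult(n_ssu, n_lsu, None, True, threshold)
    ratio = n_ssu / n_lsu
    return ScreenResult(n_ssu, n_lsu, ratio, ratio > threshold, threshold)


def _normalized(profile: CoordProfile) -> np.ndarray:
    total = profile.start_counts.sum() + profile.end_counts.sum()
    if total == 0:
        raise ValueError("profile has zero total; cannot normalize")
    return np.concatenate([profile.start_counts, profile.end_counts]) / total


def profile_tv_distance(a: CoordProfile, b: CoordProfile) -> float:
    """Total-variation distance between two coordinate profiles.

    Half the L1 distance of the jointly normalized (start ‖ end)
    histograms; 0 for identical shapes, 1 for disjoint support.
    """
    if a.length != b.length:
        raise ValueError(f"profile lengths differ: {a.length} != {b.length}")
    return float(0.5 * np.abs(_normalized(a) - _normalized(b)).sum())


def compare_decontaminated(
    profile_before: CoordProfile,
    profile_after: CoordProfile,
    profile_reference: CoordProfile,
) -> tuple[float, float]:
    """(after-vs-reference, before-vs-reference) TV distances.

    When the removal windows captured a genuine amplicon spike the
    cleaned profile moves toward the uncontaminated reference, so the
    first distance should not exceed the second.
    """
    d_after = profile_tv_distance(profile_after, profile_reference)
    d_before = profile_tv_distance(profile_before, profile_reference)
    return d_after, d_before


def write_windows_bed(windows, path, chrom: str = "model") -> None:
    """Write windows as BED-like TSV (0-based half-open, noted in header)."""
    with open(path, "w") as fh:
        fh.write("# coordinates are 0-based half-open (BED); internal "
                 "representation is 1-based inclusive\n")
        fh.write("#chrom\tstart\tend\tkind\tread_count\tfold\tp_adj\n")
        for w in windows:
            fh.write(f"{chrom}\t{w.lo - 1}\t{w.hi}\t{w.kind}\t"
                     f"{w.read_count}\t{w.fold:.3f}\t{w.p_adj:.3e}\n")


def filter_reads(in_path, out_path, drop_ids) -> dict:
    """Copy a FASTA/FASTQ file, dropping reads whose id is in ``drop_ids``.

    Applies a removed-id list (one id per line, or any iterable) to the
    raw read file.  Returns counts of kept and dropped records.
    """
    from Bio import SeqIO

    drop = set(drop_ids)
    in_path = str(in_path)
    fmt = "fasta" if in_path.endswith((".fa", ".fasta", ".fna")) else "fastq"
    n_kept = n_dropped = 0
    with open(out_path, "w") as out_fh:
        for rec in SeqIO.parse(in_path, fmt):
            if rec.id in drop:
                n_dropped += 1
            else:
                SeqIO.write(rec, out_fh, fmt)
                n_kept += 1
    return {"n_kept": n_kept, "n_dropped": n_dropped}
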