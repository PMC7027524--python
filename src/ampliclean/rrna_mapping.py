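"""rRNA read coordinates: the per-read coordinate table.

Contamination detection works entirely in *model coordinates* — each
rRNA-matching read's start/end positions on the SSU or LSU gene model
(E. coli numbering for 16S).  Two routes produce the coordinate table:

* :func:`parse_tblout` reads Infernal ``cmsearch --tblout`` output, the
  supported path for real data (Infernal run in HMM-only mode against
  the Rfam SSU/LSU models), taking the model-coordinate column pair as
  (model_start, model_end);
* :func:`align_reads` is a built-in seed-and-extend nucleotide matcher
  (exact k-mer seeds, ungapped diagonal extension) so that synthetic
  data can be processed without any external binary.  It is
  substitution-aware only; the simulator emits no indels.

The table is exchanged between modules as a TSV with header
``read_id, marker, model_start, model_end, strand, score, evalue``.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass

from .simdata import MARKERS, ReferenceModel

logger = logging.getLogger(__name__)

#: default model-name -> marker inference: any query whose name contains
#: one of these substrings (case-insensitive) maps to that marker.
DEFAULT_MARKER_MAP = {"SSU": "SSU", "16S": "SSU", "18S": "SSU",
                      "LSU": "LSU", "23S": "LSU", "28S": "LSU"}

_COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class CoordRecord:
    """One read's best match to an rRNA model.

    Coordinates are 1-based inclusive model positions; for minus-strand
    matches they are still reported on the forward model.
    """

    read_id: str
    marker: str
    model_start: int
    model_end: int
    strand: str = "+"
    score: float | None = None
    evalue: float | None = None

    def __post_init__(self) -> None:
        if self.marker not in MARKERS:
            raise ValueError(f"marker must be one of {MARKERS}, got {self.marker!r}")
        if not (1 <= self.model_start <= self.model_end):
            raise ValueError(
                f"require 1 <= model_start <= model_end, got "
                f"({self.model_start}, {self.model_end}) for read {self.read_id}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")


def _infer_marker(model_name: str, marker_map: dict[str, str]) -> str | None:
    upper = model_name.upper()
    for key, marker in marker_map.items():
        if key.upper() in upper:
            return marker
    return None


def _better(a: CoordRecord, b: CoordRecord) -> CoordRecord:
    """Best-hit resolution: min E-value, then max score, then marker name."""
    ka = (a.evalue if a.evalue is not None else float("inf"),
          -(a.score if a.score is not None else float("-inf")), a.marker)
    kb = (b.evalue if b.evalue is not None else float("inf"),
          -(b.score if b.score is not None else float("-inf")), b.marker)
    return a if ka <= kb else b


def parse_tblout(
    path,
    marker_map: dict[str, str] | None = None,
    evalue_max: float = 1e-5,
) -> list[CoordRecord]:
    """Parse Infernal ``cmsearch --tblout`` into coordinate records.

    Expects cmsearch orientation (target = read, query = model); the
    model-coordinate columns ``mdl from``/``mdl to`` become
    (model_start, model_end).  The marker is inferred from the query
    name through ``marker_map`` (substring match, default
    :data:`DEFAULT_MARKER_MAP`).  Rows with E-value above ``evalue_max``
    are dropped; when one read hits several models only the best hit
    (lowest E-value, ties by score) is kept.  Malformed rows are skipped
    with a logged warning.
    """
    marker_map = marker_map if marker_map is not None else DEFAULT_MARKER_MAP
    best: dict[str, CoordRecord] = {}
    order: list[str] = []
    n_rows = n_malformed = 0
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            n_rows += 1
            fields = line.split(None, 17)
            try:
                read_id, query = fields[0], fields[2]
                mdl_from, mdl_to = int(fields[5]), int(fields[6])
                strand = fields[9]
                score, evalue = float(fields[14]), float(fields[15])
                if strand not in ("+", "-"):
                    raise ValueError(f"bad strand {strand!r}")
                marker = _infer_marker(query, marker_map)
                if marker is None:
                    raise ValueError(f"cannot infer marker from model name {query!r}")
                lo, hi = min(mdl_from, mdl_to), max(mdl_from, mdl_to)
                rec = CoordRecord(read_id, marker, lo, hi, strand, score, evalue)
            except (IndexError, ValueError) as exc:
                n_malformed += 1
                logger.warning("skipping malformed tblout row %d: %s", n_rows, exc)
                continue
            if evalue > evalue_max:
                continue
            if read_id in best:
                best[read_id] = _better(best[read_id], rec)
            else:
                best[read_id] = rec
                order.append(read_id)
    if n_malformed:
        logger.warning("%d of %d tblout rows were malformed and skipped",
                       n_malformed, n_rows)
    if not best:
        logger.warning("no parseable hits in %s (rows seen: %d)", path, n_rows)
    return [best[rid] for rid in order]


def _kmer_index(seq: str, k: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = defaultdict(list)
    for i in range(len(seq) - k + 1):
        index[seq[i : i + k]].append(i)
    return index


def _best_diagonal(read: str, ref_seq: str, index, k: int):
    """Best ungapped placement of ``read`` on ``ref_seq`` via k-mer seeds.

    Returns (identity, matched_len, ref_offset0) or None.  Seeds are
    sampled every k bases (plus the final window) so a single
    substitution cannot kill every seed of a 2k-long read.
    """
    m = len(read)
    L = len(ref_seq)
    seed_pos = list(range(0, m - k + 1, k))
    if seed_pos and seed_pos[-1] != m - k:
        seed_pos.append(m - k)
    diagonals = set()
    for rp in seed_pos:
        for refp in index.get(read[rp : rp + k], ()):
            diagonals.add(refp - rp)
    best = None
    for diag in diagonals:
        # overlap of read [0, m) placed at ref offset diag
        r_lo = max(0, -diag)
        r_hi = min(m, L - diag)
        if r_hi <= r_lo:
            continue
        sub_read = read[r_lo:r_hi]
        sub_ref = ref_seq[r_lo + diag : r_hi + diag]
        matches = sum(a == b for a, b in zip(sub_read, sub_ref))
        length = r_hi - r_lo
        ident = matches / length
        cand = (ident, length, r_lo + diag)
        if best is None or (cand[0], cand[1]) > (best[0], best[1]):
            best = cand
    return best


def align_reads(
    reads,
    ref: ReferenceModel,
    min_identity: float = 0.90,
    min_len: int = 50,
    k: int = 15,
) -> list[CoordRecord]:
    """Map reads onto ``ref`` with an exact-k-mer seed-and-extend matcher.

    ``reads`` is an iterable of ``(read_id, sequence)`` pairs or a
    mapping id -> sequence.  Both the read and its reverse complement
    are placed on the forward model; the better-identity placement wins
    and minus-strand matches are reported with strand ``'-'`` but
    forward-model coordinates.  Reads whose best placement falls below
    ``min_identity`` or spans fewer than ``min_len`` model positions are
    omitted; reads shorter than ``k`` are skipped with a warning.
    """
    if ref.sequence is None:
        raise ValueError("align_reads requires a reference with a sequence")
    if hasattr(reads, "items"):
        reads = reads.items()
    index = _kmer_index(ref.sequence, k)
    out: list[CoordRecord] = []
    for read_id, seq in reads:
        if seq is None or len(seq) < k:
            logger.warning("read %s shorter than k=%d; skipped", read_id, k)
            continue
        placements = []
        fwd = _best_diagonal(seq, ref.sequence, index, k)
        if fwd is not None:
            placements.append((*fwd, "+"))
        rev = _best_diagonal(reverse_complement(seq), ref.sequence, index, k)
        if rev is not None:
            placements.append((*rev, "-"))
        if not placements:
            continue
        ident, length, offset0, strand = max(placements, key=lambda p: (p[0], p[1]))
        if ident < min_identity or length < min_len:
            continue
        out.append(
            CoordRecord(
                read_id=read_id,
                marker=ref.marker,
                model_start=offset0 + 1,
                model_end=offset0 + length,
                strand=strand,
                score=ident * length,
            )
        )
    return out


def records_from_truth(readset, marker: str = "SSU") -> list[CoordRecord]:
    """Coordinate records straight from a simulator truth table.

    Bypasses sequence alignment for count-only simulations: each read's
    true (model_start, model_end) becomes its record, as if mapped
    perfectly.
    """
    return [
        CoordRecord(read_id=rid, marker=marker, model_start=s, model_end=e)
        for rid, (s, e) in readset.truth_coords.items()
    ]


def marker_counts(records) -> dict[str, int]:
    """Exact per-marker record counts, always reporting both markers."""
    counts = {m: 0 for m in MARKERS}
    for rec in records:
        counts[rec.marker] += 1
    return counts


def write_coord_table(records, path) -> None:
    """Write the coordinate table TSV (the inter-module contract)."""
    with open(path, "w") as fh:
        fh.write("read_id\tmarker\tmodel_start\tmodel_end\tstrand\tscore\tevalue\n")
        for r in records:
            score = "" if r.score is None else repr(r.score)
            evalue = "" if r.evalue is None else repr(r.evalue)
            fh.write(
                f"{r.read_id}\t{r.marker}\t{r.model_start}\t{r.model_end}\t"
                f"{r.strand}\t{score}\t{evalue}\n"
            )


def read_coord_table(path) -> list[CoordRecord]:
    """Read a coordinate table TSV back into records (round-trip exact)."""
    out: list[CoordRecord] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:5] != ["read_id", "marker", "model_start", "model_end", "strand"]:
            raise ValueError(f"{path} is not a coordinate table (bad header)")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            out.append(
                CoordRecord(
                    read_id=f[0],
                    marker=f[1],
                    model_start=int(f[2]),
                    model_end=int(f[3]),
                    strand=f[4],
                    score=float(f[5]) if len(f) > 5 and f[5] else None,
                    evalue=float(f[6]) if len(f) > 6 and f[6] else None,
                )
            )
    return out
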