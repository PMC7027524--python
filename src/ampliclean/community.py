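"""Community-summary arithmetic: domain abundances and ratios.

Whole-metagenome shotgun data yields both bacterial (SSU ~ 16S) and
fungal (SSU ~ 18S) rRNA fragments on a single axis, so per-sample
relative abundances of the two domains — and their ratio — can be
computed per marker (SSU, LSU) and compared across markers.  The
bacteria/fungi ratio is computed from the reported percentages (to two
half-up-rounded decimals), and SSU-vs-LSU agreement is quantified as
the total-variation distance between the two percentage compositions.

Also here: the plasmid-contig hit filter (percent identity and minimum
alignment length thresholds on BLAST-tabular hits) and the matched
fraction it feeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP

import pandas as pd

DOMAINS = ("Bacteria", "Fungi", "Other", "Unassigned")

#: BLAST tabular (outfmt 6) default columns
BLAST6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


class UndefinedRatioError(ZeroDivisionError):
    """Raised when a ratio's denominator is zero."""


def round_half_up(x: float, ndigits: int) -> float:
    """Round with ties away from zero, as printed tables conventionally do."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class DomainCounts:
    """Per-sample, per-marker read counts by domain."""

    sample_id: str
    marker: str
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def domain_percentages(dc: DomainCounts) -> dict[str, float]:
    """Relative abundance (%) of each domain category.

    All four categories (Bacteria, Fungi, Other, Unassigned)
    participate in normalization; percentages sum to 100 exactly
    (before any reporting rounding).
    """
    total = dc.total
    if total <= 0:
        raise ValueError(f"sample {dc.sample_id}: zero total count")
    return {d: 100.0 * dc.counts.get(d, 0) / total for d in DOMAINS}


def bf_ratio(bacteria_pct: float, fungi_pct: float) -> float:
    """Bacteria/fungi ratio from printed percentages, half-up to 2 decimals."""
    if fungi_pct == 0:
        raise UndefinedRatioError("fungi percentage is zero; ratio undefined")
    return round_half_up(bacteria_pct / fungi_pct, 2)


def concordance(p1: dict[str, float], p2: dict[str, float]) -> float:
    """Total-variation distance between two percentage compositions.

    ``0.5 * sum |p1_d - p2_d| / 100`` over the shared category set,
    in [0, 1]; mismatched category sets raise.
    """
    if set(p1) != set(p2):
        raise ValueError(f"category sets differ: {sorted(p1)} vs {sorted(p2)}")
    return 0.5 * sum(abs(p1[d] - p2[d]) for d in p1) / 100.0


def in_agreement(p1, p2, tolerance: float = 0.05) -> bool:
    """Whether two marker-based compositions agree within ``tolerance`` TV."""
    return concordance(p1, p2) <= tolerance


@dataclass(frozen=True)
class HitRecord:
    """One BLAST-tabular alignment hit; unlisted columns ride along."""

    query_id: str
    subject_id: str
    pct_identity: float
    align_len: int
    bitscore: float | None = None
    extra: tuple = ()

    def __post_init__(self) -> None:
        if self.align_len < 1:
            raise ValueError("align_len must be >= 1")


def read_blast_tab(path) -> list[HitRecord]:
    """Load a BLAST outfmt-6 TSV into hit records."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = BLAST6_COLUMNS[: df.shape[1]] + list(df.columns[len(BLAST6_COLUMNS):])
    out = []
    for row in df.itertuples(index=False):
        out.append(
            HitRecord(
                query_id=str(row.qseqid),
                subject_id=str(row.sseqid),
                pct_identity=float(row.pident),
                align_len=int(row.length),
                bitscore=float(row.bitscore) if hasattr(row, "bitscore") else None,
                extra=tuple(row[4:]),
            )
        )
    return out


def hit_filter(
    hits,
    min_identity: float = 95.0,
    min_len: int = 90,
    best_per_query: bool = False,
) -> list[HitRecord]:
    """Keep significant hits: identity >= ``min_identity`` (percent) and
    alignment length >= ``min_len`` bp, both inclusive.

    With ``best_per_query`` the surviving hits are collapsed to one per
    query (highest bitscore, ties by identity).
    """
    kept = [h for h in hits if h.pct_identity >= min_identity and h.align_len >= min_len]
    if not best_per_query:
        return kept
    best: dict[str, HitRecord] = {}
    for h in kept:
        cur = best.get(h.query_id)
        key = (h.bitscore if h.bitscore is not None else float("-inf"), h.pct_identity)
        if cur is None:
            best[h.query_id] = h
        else:
            cur_key = (cur.bitscore if cur.bitscore is not None else float("-inf"),
                       cur.pct_identity)
            if key > cur_key:
                best[h.query_id] = h
    return list(best.values())


def match_fraction(n_matched: int, n_total: int) -> float:
    """Percentage of queries with a significant match, half-up to 1 decimal."""
    if n_total <= 0:
        raise ValueError("n_total must be > 0")
    if n_matched > n_total:
        raise ValueError("n_matched cannot exceed n_total")
    return round_half_up(100.0 * n_matched / n_total, 1)


def read_domain_counts(path) -> list[DomainCounts]:
    """Load a (sample, marker, domain, count) TSV into DomainCounts."""
    df = pd.read_csv(path, sep="\t")
    required = {"sample", "marker", "domain", "count"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path} must have columns {sorted(required)}")
    out = []
    for (sample, marker), grp in df.groupby(["sample", "marker"], sort=False):
        out.append(
            DomainCounts(
                sample_id=str(sample),
                marker=str(marker),
                counts={str(r.domain): int(r.count) for r in grp.itertuples()},
            )
        )
    return out


def summarize(domain_counts: list[DomainCounts]) -> pd.DataFrame:
    """Per-sample, per-marker summary table.

    Columns: sample, marker, bacteria_pct, fungi_pct, bf_ratio, with
    percentages half-up rounded to 2 decimals and the ratio computed
    from the rounded (as-reported) percentages.
    """
    rows = []
    for dc in domain_counts:
        pct = domain_percentages(dc)
        b = round_half_up(pct["Bacteria"], 2)
        f = round_half_up(pct["Fungi"], 2)
        try:
            ratio = bf_ratio(b, f)
        except UndefinedRatioError:
            ratio = float("nan")
        rows.append(
            {"sample": dc.sample_id, "marker": dc.marker,
             "bacteria_pct": b, "fungi_pct": f, "bf_ratio": ratio}
        )
    return pd.DataFrame(rows, columns=["sample", "marker", "bacteria_pct",
                                       "fungi_pct", "bf_ratio"])
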