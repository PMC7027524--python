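"""Synthetic rRNA read mixtures with per-read truth labels.

Random fragmentation of input DNA for shotgun sequencing places read
start coordinates uniformly over an rRNA gene model, whereas PCR
amplicons leaking into a shotgun library share primer-defined anchor
coordinates.  For the V3-V4 16S design the forward primer sits at
E. coli positions 341-357 and the reverse primer at 785-805, so
contaminating reads pile up at a fixed (start, end) pair instead of
spreading uniformly.  The generators in this module emit both read
populations on a shared model coordinate system (1-based, inclusive),
together with a truth table mapping every read id to its origin and
its true model coordinates, so that downstream detection and removal
can be scored exactly.

Sequences are optional: a :class:`ReferenceModel` without a sequence
supports count-only simulation (coordinates and truth only), which is
all the peak-calling statistics need.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

MARKERS = ("SSU", "LSU")
_BASES = np.frombuffer(b"ACGT", dtype="S1")


class SimConfigError(ValueError):
    """A simulation configuration violates its invariants."""


@dataclass(frozen=True)
class ReferenceModel:
    """An rRNA gene model (SSU or LSU) defining the coordinate system.

    Parameters
    ----------
    model_id : str
        Name of the model, e.g. ``"SSU_rRNA_bacteria"``.
    marker : str
        ``"SSU"`` or ``"LSU"``.
    length : int
        Model length in positions (1-based coordinates run 1..length).
    sequence : str, optional
        Nucleotide sequence of exactly ``length`` bases.  Required only
        when simulated reads must carry sequences.
    """

    model_id: str
    marker: str
    length: int
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.marker not in MARKERS:
            raise SimConfigError(f"marker must be one of {MARKERS}, got {self.marker!r}")
        if self.length < 1:
            raise SimConfigError("model length must be >= 1")
        if self.sequence is not None and len(self.sequence) != self.length:
            raise SimConfigError(
                f"sequence length {len(self.sequence)} != declared length {self.length}"
            )


@dataclass(frozen=True)
class AmpliconDesign:
    """Primer footprints of an amplicon assay, in model coordinates.

    Defaults are the V3-V4 16S design (E. coli numbering): forward
    primer 341-357, reverse primer 785-805.  ``jitter_sd`` adds
    Gaussian position noise (rounded to integers) to each read's
    anchors, emulating ragged amplicon ends; 0 gives exact anchoring.
    """

    fwd_start: int = 341
    fwd_end: int = 357
    rev_start: int = 785
    rev_end: int = 805
    jitter_sd: float = 0.0

    def __post_init__(self) -> None:
        if not (1 <= self.fwd_start <= self.fwd_end < self.rev_start <= self.rev_end):
            raise SimConfigError(
                "primer coordinates must satisfy "
                "1 <= fwd_start <= fwd_end < rev_start <= rev_end"
            )
        if self.jitter_sd < 0:
            raise SimConfigError("jitter_sd must be non-negative")

    def validate_against(self, ref: ReferenceModel) -> None:
        if self.rev_end > ref.length:
            raise SimConfigError(
                f"design end {self.rev_end} exceeds model length {ref.length}"
            )


@dataclass(frozen=True)
class FragmentLength:
    """Truncated-normal fragment length spec (bp).

    Defaults (mean 150, sd 30, min 50, max 300) match merged reads from
    a 2x150 run; all four are free parameters.
    """

    mean: float = 150.0
    sd: float = 30.0
    min: int = 50
    max: int = 300

    def __post_init__(self) -> None:
        if not (self.min <= self.mean <= self.max):
            raise SimConfigError("fragment lengths must satisfy min <= mean <= max")
        if self.min < 1:
            raise SimConfigError("fragment min must be >= 1")
        if self.sd < 0:
            raise SimConfigError("fragment sd must be non-negative")

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw ``n`` integer lengths in [min, max] (rejection sampling)."""
        if n == 0:
            return np.zeros(0, dtype=np.int64)
        if self.sd == 0:
            return np.full(n, int(round(self.mean)), dtype=np.int64)
        out = np.empty(n, dtype=np.int64)
        filled = 0
        while filled < n:
            draw = np.rint(rng.normal(self.mean, self.sd, size=2 * (n - filled)))
            ok = draw[(draw >= self.min) & (draw <= self.max)]
            take = min(len(ok), n - filled)
            out[filled : filled + take] = ok[:take]
            filled += take
        return out


@dataclass(frozen=True)
class SimConfig:
    """Knobs for one simulation run (counts, fragments, errors, seed)."""

    n_shotgun: int = 0
    n_amplicon: int = 0
    fragment_length: FragmentLength = field(default_factory=FragmentLength)
    error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_shotgun < 0 or self.n_amplicon < 0:
            raise SimConfigError("read counts must be >= 0")
        if not (0.0 <= self.error_rate <= 1.0):
            raise SimConfigError("error_rate must lie in [0, 1]")


@dataclass
class LabeledReadSet:
    """Simulated reads plus ground truth.

    ``reads`` maps read id -> sequence (or ``None`` for count-only
    runs); ``truth`` maps read id -> ``"shotgun"`` or ``"amplicon"``;
    ``truth_coords`` maps read id -> true (model_start, model_end).
    """

    reads: dict[str, str | None] = field(default_factory=dict)
    truth: dict[str, str] = field(default_factory=dict)
    truth_coords: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.reads)


def random_reference(
    length: int = 1542,
    marker: str = "SSU",
    seed: int = 0,
    model_id: str | None = None,
) -> ReferenceModel:
    """A synthetic reference model with an i.i.d. random sequence.

    Stands in for a real 16S/23S template in tests and simulations; the
    positional statistics under study do not depend on base composition.
    """
    rng = np.random.default_rng(seed)
    seq = rng.choice(_BASES, size=length).tobytes().decode("ascii")
    return ReferenceModel(
        model_id=model_id or f"synthetic_{marker}_{length}",
        marker=marker,
        length=length,
        sequence=seq,
    )


def _apply_errors(seq: str, error_rate: float, rng: np.random.Generator) -> str:
    """Substitute bases independently at ``error_rate`` (no indels)."""
    if error_rate == 0.0 or not seq:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype="S1").copy()
    hit = rng.random(len(arr)) < error_rate
    idx = np.flatnonzero(hit)
    if idx.size:
        # replace with one of the three *other* bases
        cur = arr[idx]
        repl = _BASES[rng.integers(0, 4, size=idx.size)]
        clash = repl == cur
        while clash.any():
            repl[clash] = _BASES[rng.integers(0, 4, size=int(clash.sum()))]
            clash = repl == cur
        arr[idx] = repl
    return arr.tobytes().decode("ascii")


def simulate_shotgun_rrna(
    ref: ReferenceModel, config: SimConfig, id_prefix: str = "shotgun"
) -> LabeledReadSet:
    """Simulate rRNA-derived shotgun fragments under the uniform null.

    Each read's fragment length is drawn from ``config.fragment_length``
    and its model start uniformly from the positions that admit that
    length, i.e. 1..(L - len + 1).  All truth labels are ``"shotgun"``.
    Deterministic for a fixed ``config.seed``.
    """
    if config.fragment_length.max > ref.length:
        raise SimConfigError(
            f"fragment length up to {config.fragment_length.max} exceeds "
            f"model length {ref.length}"
        )
    rng = np.random.default_rng(config.seed)
    n = config.n_shotgun
    lengths = config.fragment_length.sample(n, rng)
    out = LabeledReadSet()
    if n == 0:
        return out
    starts = rng.integers(1, ref.length - lengths + 2)
    ends = starts + lengths - 1
    for i in range(n):
        rid = f"{id_prefix}_{i}"
        s, e = int(starts[i]), int(ends[i])
        seq = None
        if ref.sequence is not None:
            seq = _apply_errors(ref.sequence[s - 1 : e], config.error_rate, rng)
        out.reads[rid] = seq
        out.truth[rid] = "shotgun"
        out.truth_coords[rid] = (s, e)
    return out


def simulate_amplicon(
    ref: ReferenceModel,
    design: AmpliconDesign,
    config: SimConfig,
    id_prefix: str = "amplicon",
) -> LabeledReadSet:
    """Simulate merged amplicon reads anchored at the primer coordinates.

    Read start = ``design.fwd_start`` and end = ``design.rev_end``, each
    offset by independent N(0, jitter_sd) noise rounded to integer
    positions and truncated to the model bounds.  With ``jitter_sd=0``
    every read spans exactly (fwd_start, rev_end).  All labels are
    ``"amplicon"``.
    """
    design.validate_against(ref)
    rng = np.random.default_rng(config.seed)
    n = config.n_amplicon
    out = LabeledReadSet()
    if n == 0:
        return out
    if design.jitter_sd > 0:
        starts = design.fwd_start + np.rint(rng.normal(0, design.jitter_sd, n)).astype(int)
        ends = design.rev_end + np.rint(rng.normal(0, design.jitter_sd, n)).astype(int)
    else:
        starts = np.full(n, design.fwd_start, dtype=int)
        ends = np.full(n, design.rev_end, dtype=int)
    starts = np.clip(starts, 1, ref.length)
    ends = np.clip(ends, starts, ref.length)
    for i in range(n):
        rid = f"{id_prefix}_{i}"
        s, e = int(starts[i]), int(ends[i])
        seq = None
        if ref.sequence is not None:
            seq = _apply_errors(ref.sequence[s - 1 : e], config.error_rate, rng)
        out.reads[rid] = seq
        out.truth[rid] = "amplicon"
        out.truth_coords[rid] = (s, e)
    return out


def merge_sets(sets: list[LabeledReadSet]) -> LabeledReadSet:
    """Concatenate read sets, renaming ids on collision (``<id>_dupN``)."""
    merged = LabeledReadSet()
    for rs in sets:
        for rid in rs.reads:
            new_id = rid
            n_dup = 1
            while new_id in merged.reads:
                new_id = f"{rid}_dup{n_dup}"
                n_dup += 1
            merged.reads[new_id] = rs.reads[rid]
            merged.truth[new_id] = rs.truth[rid]
            merged.truth_coords[new_id] = rs.truth_coords[rid]
    return merged


def mix_and_write(
    sets: list[LabeledReadSet],
    out_reads,
    out_truth,
    seed: int = 0,
) -> dict:
    """Mix read sets, shuffle, and write reads + truth table to disk.

    Reads go to ``out_reads`` as FASTA if its suffix is ``.fa``/``.fasta``,
    else FASTQ (Phred+33, constant quality ``I``).  The truth table is a
    4-column TSV (read_id, label, start, end) with a header, in the same
    shuffled order.  Returns ``{"n_total": ..., "n_per_set": [...]}``.
    """
    merged = merge_sets(sets)
    order = list(merged.reads)
    np.random.default_rng(seed).shuffle(order)

    out_reads = str(out_reads)
    fasta = out_reads.endswith((".fa", ".fasta", ".fna"))
    with open(out_reads, "w") as fh:
        for rid in order:
            seq = merged.reads[rid]
            if seq is None:
                raise SimConfigError(
                    f"read {rid} has no sequence; simulate with a sequenced "
                    "reference to write read files"
                )
            if fasta:
                fh.write(f">{rid}\n{seq}\n")
            else:
                fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")
    with open(out_truth, "w") as fh:
        fh.write("read_id\tlabel\tstart\tend\n")
        for rid in order:
            s, e = merged.truth_coords[rid]
            fh.write(f"{rid}\t{merged.truth[rid]}\t{s}\t{e}\n")
    return {"n_total": len(merged), "n_per_set": [len(rs) for rs in sets]}


def read_truth_table(path) -> LabeledReadSet:
    """Load a truth TSV written by :func:`mix_and_write` (no sequences)."""
    out = LabeledReadSet()
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("read_id"):
            raise ValueError(f"{path} is not a truth table (bad header)")
        for line in fh:
            rid, label, s, e = line.rstrip("\n").split("\t")
            out.reads[rid] = None
            out.truth[rid] = label
            out.truth_coords[rid] = (int(s), int(e))
    return out
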