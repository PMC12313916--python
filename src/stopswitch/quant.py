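"""Quantification of base-editing outcomes from single-end amplicon reads.

Pipeline: mean-Phred quality filter (strictly greater than the threshold)
-> orientation-aware semi-global alignment to the amplicon reference ->
exclusion of reads with an indel overlapping the quantification window
(default policy) -> per-position substitution tally -> editing frequency at
the guide's target position, reported as the percentage of quantified reads
carrying the converted base.

Alignment scoring is fixed at match +2 / mismatch -3 / gap open -5 / gap
extend -2 with free end gaps on the amplicon overhangs, the orientation
being whichever strand scores higher (plus strand on ties). Reads scoring
below 0.4 x 2 x read-length are dropped as unalignable. For speed,
substitution-only reads are placed by exact k-mer seeding and a vectorized
mismatch count; the full affine dynamic program (Bio.Align.PairwiseAligner)
is the fallback whenever seeding fails or the mismatch load is high, and is
what :func:`align_to_amplicon` always computes.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
from Bio import Align
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .errors import InconsistentInputError, StopSwitchError
from .seqcore import GuideDesign, NucleotideSequence, complement_base

MATCH_SCORE = 2
MISMATCH_SCORE = -3
GAP_OPEN = -5
GAP_EXTEND = -2
#: Fraction of the maximum attainable score below which a read is unalignable.
MIN_SCORE_FRACTION = 0.4
#: Fast-path mismatch ceiling; noisier reads go through the full DP.
_FASTPATH_MAX_MISMATCH_FRACTION = 0.1
_SEED_K = 16


@dataclass(frozen=True)
class ReadRecord:
    """One sequencing read with Sanger-encoded qualities (decoded)."""

    id: str
    bases: NucleotideSequence
    quals: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "bases", NucleotideSequence(self.bases))
        if len(self.bases) != len(self.quals):
            raise ValueError(
                f"read {self.id}: {len(self.bases)} bases vs "
                f"{len(self.quals)} quality scores"
            )

    @property
    def mean_quality(self) -> float:
        return float(np.mean(self.quals))


@dataclass(frozen=True)
class QuantConfig:
    """Quantification parameters.

    The quantification window spans protospacer positions
    ``window_center - window_halfwidth .. window_center + window_halfwidth``
    mapped to amplicon coordinates and clipped to the amplicon; the defaults
    always cover a full 20-mer protospacer.
    """

    min_mean_phred: float = 30.0
    window_center: int = 10
    window_halfwidth: int = 20
    indel_policy: str = "exclude_window_indels"  # or "count_all"

    def __post_init__(self) -> None:
        if self.min_mean_phred <= 0 or self.window_halfwidth < 0:
            raise ValueError("thresholds must be positive")
        if self.indel_policy not in ("exclude_window_indels", "count_all"):
            raise ValueError(f"unknown indel policy {self.indel_policy!r}")


@dataclass
class QuantResult:
    """Per-position substitution counts and editing frequency for one sample.

    ``editing_percent`` is the percentage of quantified reads carrying the
    converted base at the target position (None when no read was
    quantified, which is reported as missing rather than zero).
    """

    n_total: int
    n_pass_quality: int
    n_quantified: int
    n_unalignable: int
    n_window_excluded: int
    editing_percent: float | None
    per_position_conversion: pd.Series
    substitution_table: pd.DataFrame
    target_amplicon_position: int  # 1-based
    config: QuantConfig
    metadata: dict = field(default_factory=dict)

    def summary(self) -> str:
        lines = [
            f"reads total            {self.n_total}",
            f"pass mean-Q filter     {self.n_pass_quality}",
            f"quantified             {self.n_quantified}",
            f"unalignable            {self.n_unalignable}",
            f"window-excluded        {self.n_window_excluded}",
            f"target position (1-based amplicon) {self.target_amplicon_position}",
        ]
        if self.editing_percent is None:
            lines.append("editing percent        NA (no quantified reads)")
        else:
            lines.append(f"editing percent        {self.editing_percent:.1f}")
        return "\n".join(lines)


def read_fastq(path: str | Path) -> Iterator[ReadRecord]:
    """Stream Sanger FASTQ records (gzip transparently handled)."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        for rid, seq, qual in FastqGeneralIterator(fh):
            quals = tuple(
                int(q) for q in np.frombuffer(qual.encode("ascii"), np.uint8) - 33
            )
            if any(q < 0 for q in quals):
                raise StopSwitchError(f"read {rid}: invalid quality encoding")
            yield ReadRecord(rid.split()[0], NucleotideSequence(seq), quals)


def filter_by_mean_quality(
    reads: Iterable[ReadRecord], min_mean_phred: float = 30.0
) -> list[ReadRecord]:
    """Keep reads whose arithmetic mean Phred is strictly above the threshold."""
    return [r for r in reads if r.mean_quality > min_mean_phred]


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = MATCH_SCORE
    aligner.mismatch_score = MISMATCH_SCORE
    aligner.open_gap_score = GAP_OPEN
    aligner.extend_gap_score = GAP_EXTEND
    # Amplicon overhangs beyond the read are free (semi-global on the read).
    try:
        aligner.end_deletion_score = 0
    except AttributeError:  # older attribute name
        aligner.query_end_gap_score = 0
    return aligner


@dataclass(frozen=True)
class ReadAlignment:
    """A read placed on the amplicon plus strand.

    ``blocks`` pairs half-open amplicon and read intervals of gap-free
    aligned segments, in amplicon order; ``read_bases`` is the read as
    aligned (reverse-complemented when the minus orientation won).
    """

    score: float
    strand: str
    blocks: tuple[tuple[tuple[int, int], tuple[int, int]], ...]
    read_bases: NucleotideSequence

    @property
    def amplicon_span(self) -> tuple[int, int]:
        return self.blocks[0][0][0], self.blocks[-1][0][1]

    def has_indel_in(self, lo: int, hi: int) -> bool:
        """True if a gap column falls inside amplicon interval [lo, hi)."""
        for i in range(1, len(self.blocks)):
            (a0, a1), (r0, r1) = self.blocks[i - 1]
            (b0, b1), (s0, s1) = self.blocks[i]
            if a1 != b0:  # deletion in the read spanning amplicon [a1, b0)
                if a1 < hi and b0 > lo:
                    return True
            if r1 != s0:  # insertion in the read at amplicon position a1
                if lo <= a1 < hi or lo < a1 <= hi:
                    return True
        return False

    def base_at(self, amplicon_pos: int) -> str | None:
        """Read base aligned to a 0-based amplicon position, None if gapped
        or uncovered."""
        for (a0, a1), (r0, r1) in self.blocks:
            if a0 <= amplicon_pos < a1:
                return self.read_bases[r0 + (amplicon_pos - a0)]
        return None


def align_to_amplicon(
    read: ReadRecord | str, amplicon: str | NucleotideSequence
) -> ReadAlignment | None:
    """Full affine semi-global alignment of one read against both amplicon
    strands; None when the best score falls below the alignability floor."""
    bases = read.bases if isinstance(read, ReadRecord) else NucleotideSequence(read)
    amplicon = NucleotideSequence(amplicon)
    aligner = _make_aligner()
    best = None
    for strand, oriented in (
        ("+", bases),
        ("-", bases.reverse_complement()),
    ):
        alignments = aligner.align(str(amplicon), str(oriented))
        aln = alignments[0]
        if best is None or aln.score > best[0]:
            best = (aln.score, strand, aln, oriented)
    score, strand, aln, oriented = best
    if score < MIN_SCORE_FRACTION * MATCH_SCORE * len(bases):
        return None
    target_blocks, query_blocks = aln.aligned
    blocks = tuple(
        ((int(t0), int(t1)), (int(q0), int(q1)))
        for (t0, t1), (q0, q1) in zip(target_blocks, query_blocks)
    )
    return ReadAlignment(
        score=float(score), strand=strand, blocks=blocks, read_bases=oriented
    )


def locate_guide(
    amplicon: str | NucleotideSequence,
    spacer: str | NucleotideSequence,
    target_position: int,
) -> GuideDesign:
    """Place a spacer on an amplicon (either strand, exactly one hit) and
    return the corresponding guide with amplicon coordinates."""
    amplicon = NucleotideSequence(amplicon)
    spacer = NucleotideSequence(spacer)
    fwd = [i for i in _find_all(amplicon, spacer)]
    rev = [i for i in _find_all(amplicon, spacer.reverse_complement())]
    if len(fwd) + len(rev) != 1:
        raise InconsistentInputError(
            f"spacer must occur exactly once on the amplicon "
            f"(found {len(fwd)} forward, {len(rev)} reverse)"
        )
    if fwd:
        return GuideDesign(
            spacer=spacer,
            strand="+",
            protospacer_start=fwd[0],
            pam_seq=NucleotideSequence(""),
            target_position=target_position,
        )
    return GuideDesign(
        spacer=spacer,
        strand="-",
        protospacer_start=rev[0],
        pam_seq=NucleotideSequence(""),
        target_position=target_position,
    )


def _find_all(haystack: str, needle: str) -> Iterator[int]:
    i = haystack.find(needle)
    while i != -1:
        yield i
        i = haystack.find(needle, i + 1)


def _window_interval(
    guide: GuideDesign, config: QuantConfig, amplicon_length: int
) -> tuple[int, int]:
    """Half-open 0-based amplicon interval of the quantification window."""
    L = len(guide.spacer)

    def coord(p: int) -> int:
        if guide.strand == "+":
            return guide.protospacer_start + p - 1
        return guide.protospacer_start + L - p

    a = coord(config.window_center - config.window_halfwidth)
    b = coord(config.window_center + config.window_halfwidth)
    lo, hi = min(a, b), max(a, b) + 1
    lo, hi = max(lo, 0), min(hi, amplicon_length)
    if lo >= hi:
        raise ValueError("quantification window empty after clipping")
    return lo, hi


def _build_seed_index(amp: str, k: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = {}
    for i in range(len(amp) - k + 1):
        index.setdefault(amp[i : i + k], []).append(i)
    return index


def _fastpath_place(
    oriented: str,
    amp_arr: np.ndarray,
    seed_index: dict[str, list[int]],
    k: int,
) -> tuple[int, int] | None:
    """Gap-free placement by exact seeding: (offset, n_mismatches) of the
    best candidate, or None when no seed anchors the read."""
    n = len(oriented)
    best: tuple[int, int] | None = None
    seen: set[int] = set()
    for read_off in (0, n // 2, n - k):
        if read_off < 0:
            continue
        seed = oriented[read_off : read_off + k]
        for pos in seed_index.get(seed, ()):
            off = pos - read_off
            if off < 0 or off + n > len(amp_arr) or off in seen:
                continue
            seen.add(off)
            mism = int(
                np.count_nonzero(
                    amp_arr[off : off + n]
                    != np.frombuffer(oriented.encode("ascii"), np.uint8)
                )
            )
            if best is None or mism < best[1]:
                best = (off, mism)
    return best


def quantify_sample(
    fastq: str | Path | Sequence[ReadRecord],
    amplicon: str | NucleotideSequence,
    guide: GuideDesign,
    config: QuantConfig | None = None,
    conversion: tuple[str, str] = ("A", "G"),
) -> QuantResult:
    """Run the full quantification pipeline for one amplicon sample.

    ``conversion`` is (base_from, base_to) read on the guide strand;
    ``guide.protospacer_start`` must place the spacer on the amplicon.
    """
    config = config or QuantConfig()
    amplicon = NucleotideSequence(amplicon)
    amp = str(amplicon)

    # Guide/amplicon consistency.
    L = len(guide.spacer)
    s = guide.protospacer_start
    if s < 0 or s + L > len(amp):
        raise InconsistentInputError("guide placement outside amplicon")
    observed = amp[s : s + L]
    if guide.strand == "-":
        observed = str(NucleotideSequence(observed).reverse_complement())
    if observed != str(guide.spacer):
        raise InconsistentInputError("guide spacer not found on amplicon")

    base_from, base_to = conversion[0].upper(), conversion[1].upper()
    target0 = guide.plus_strand_coord(guide.target_position)
    if guide.strand == "+":
        ref_target, edited_target = base_from, base_to
    else:
        ref_target = complement_base(base_from)
        edited_target = complement_base(base_to)
    if amp[target0] != ref_target:
        raise InconsistentInputError(
            f"amplicon base at target position is {amp[target0]}, "
            f"expected {ref_target}"
        )

    if isinstance(fastq, (str, Path)):
        reads: list[ReadRecord] = list(read_fastq(fastq))
    else:
        reads = list(fastq)

    n_total = len(reads)
    passing = filter_by_mean_quality(reads, config.min_mean_phred)
    n_pass = len(passing)

    win_lo, win_hi = _window_interval(guide, config, len(amp))
    win_len = win_hi - win_lo
    amp_arr = np.frombuffer(amp.encode("ascii"), np.uint8).copy()
    seed_index = _build_seed_index(amp, _SEED_K)
    exclude_indels = config.indel_policy == "exclude_window_indels"

    window_rows: list[np.ndarray] = []  # read bases over the window, uint8; 0 = gap/uncovered
    n_unalignable = 0
    n_window_excluded = 0

    for read in passing:
        row = _quantify_one(
            read, amp_arr, amp, seed_index, win_lo, win_hi, exclude_indels
        )
        if row is None:
            n_unalignable += 1
        elif row is False:
            n_window_excluded += 1
        else:
            window_rows.append(row)

    n_quantified = len(window_rows)

    positions = np.arange(win_lo, win_hi)
    ref_bases = [amp[p] for p in positions]
    if n_quantified:
        M = np.vstack(window_rows)
        base_counts = {
            b: (M == ord(b)).sum(axis=0).astype(int) for b in "ACGTN"
        }
    else:
        base_counts = {b: np.zeros(win_len, dtype=int) for b in "ACGTN"}

    table = pd.DataFrame(base_counts, index=positions + 1)
    table.insert(0, "ref", ref_bases)
    table.index.name = "amplicon_position"

    # Editing percent at the target.
    editing_percent: float | None = None
    if n_quantified:
        ti = target0 - win_lo
        if not 0 <= ti < win_len:
            raise InconsistentInputError(
                "target position falls outside the quantification window"
            )
        edited = int(base_counts[edited_target][ti])
        editing_percent = 100.0 * edited / n_quantified

    # Per-position conversion (positions whose reference carries base_from
    # on the guide strand).
    ref_from = base_from if guide.strand == "+" else complement_base(base_from)
    ed_base = base_to if guide.strand == "+" else complement_base(base_to)
    conv = np.full(win_len, np.nan)
    if n_quantified:
        for i, rb in enumerate(ref_bases):
            if rb == ref_from:
                conv[i] = 100.0 * base_counts[ed_base][i] / n_quantified
    per_position = pd.Series(conv, index=positions + 1, name="conversion_percent")
    per_position.index.name = "amplicon_position"

    return QuantResult(
        n_total=n_total,
        n_pass_quality=n_pass,
        n_quantified=n_quantified,
        n_unalignable=n_unalignable,
        n_window_excluded=n_window_excluded,
        editing_percent=editing_percent,
        per_position_conversion=per_position,
        substitution_table=table,
        target_amplicon_position=target0 + 1,
        config=config,
        metadata={
            "match": MATCH_SCORE,
            "mismatch": MISMATCH_SCORE,
            "gap_open": GAP_OPEN,
            "gap_extend": GAP_EXTEND,
            "min_score_fraction": MIN_SCORE_FRACTION,
            "conversion": f"{base_from}>{base_to}",
            "guide_strand": guide.strand,
            "window_amplicon_interval": (win_lo + 1, win_hi),
        },
    )


def _quantify_one(
    read: ReadRecord,
    amp_arr: np.ndarray,
    amp: str,
    seed_index: dict[str, list[int]],
    win_lo: int,
    win_hi: int,
    exclude_indels: bool,
):
    """Place one read; return the window base row (uint8 array), False when
    window-excluded, or None when unalignable."""
    n = len(read.bases)
    floor = MIN_SCORE_FRACTION * MATCH_SCORE * n
    fwd = str(read.bases)
    rev = str(read.bases.reverse_complement())

    cand = []
    for oriented in (fwd, rev):
        hit = _fastpath_place(oriented, amp_arr, seed_index, _SEED_K)
        if hit is not None:
            off, mism = hit
            score = MATCH_SCORE * (n - mism) + MISMATCH_SCORE * mism
            cand.append((score, oriented, off, mism))

    if cand:
        best = max(cand, key=lambda c: c[0])
        if best[3] / n <= _FASTPATH_MAX_MISMATCH_FRACTION:
            cand = [best]
        else:
            cand = []
    if cand:
        score, oriented, off, mism = cand[0]
        if score < floor:
            return None
        if off > win_lo or off + n < win_hi:
            # Read does not cover the full quantification window.
            return False
        row = np.frombuffer(oriented.encode("ascii"), np.uint8)[
            win_lo - off : win_hi - off
        ]
        return row.copy()

    aln = align_to_amplicon(read, amp)
    if aln is None:
        return None
    span_lo, span_hi = aln.amplicon_span
    if span_lo > win_lo or span_hi < win_hi:
        return False
    if exclude_indels and aln.has_indel_in(win_lo, win_hi):
        return False
    row = np.zeros(win_hi - win_lo, dtype=np.uint8)
    for p in range(win_lo, win_hi):
        b = aln.base_at(p)
        if b is not None:
            row[p - win_lo] = ord(b)
    return row
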