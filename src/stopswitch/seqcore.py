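"""Nucleotide-sequence primitives shared by every pipeline stage.

Conventions used throughout the package:

* Genomic / CDS coordinates are 0-based half-open on the plus strand, except
  where a field is explicitly documented as 1-based (codon indices, CDS
  nucleotide coordinates in reports, protospacer positions).
* Protospacer positions are 1-based from the PAM-distal (5') end of the
  spacer, so "A7" means an adenine at spacer position 7.
* The PAM lies immediately 3' of the protospacer on the protospacer strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Data.IUPACData import ambiguous_dna_values
from Bio.Seq import Seq

from .errors import AlphabetError, FrameError

_ALPHABET = set("ACGTN")


class NucleotideSequence(str):
    """An uppercase DNA string over {A,C,G,T,N}.

    RNA input (containing U) is normalized to DNA on construction, so the
    printed guide spacers, which the vendor writes as RNA, can be pasted in
    directly.
    """

    def __new__(cls, bases: str) -> "NucleotideSequence":
        normalized = str(bases).upper().replace("U", "T")
        bad = set(normalized) - _ALPHABET
        if bad:
            raise AlphabetError(
                f"non-nucleotide characters {sorted(bad)!r} in sequence"
            )
        return super().__new__(cls, normalized)

    @property
    def bases(self) -> str:
        return str(self)

    def reverse_complement(self) -> "NucleotideSequence":
        return NucleotideSequence(str(Seq(str(self)).reverse_complement()))


def reverse_complement(seq: str | NucleotideSequence) -> NucleotideSequence:
    """Watson-Crick complement, reversed; N maps to N."""
    return NucleotideSequence(seq).reverse_complement()


_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def complement_base(base: str) -> str:
    return _COMPLEMENT[base]


@dataclass(frozen=True)
class CodingSequence:
    """An ORF with the 1-based codon convention: codon ``k`` occupies CDS
    nucleotides ``3k-2 .. 3k``."""

    seq: NucleotideSequence
    name: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", NucleotideSequence(self.seq))
        if len(self.seq) % 3 != 0:
            raise FrameError(
                f"CDS length {len(self.seq)} is not divisible by 3"
            )

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def n_codons(self) -> int:
        return len(self.seq) // 3

    def codon(self, index: int) -> NucleotideSequence:
        """The codon at 1-based ``index``."""
        if not 1 <= index <= self.n_codons:
            raise IndexError(f"codon index {index} out of range")
        return NucleotideSequence(self.seq[3 * index - 3 : 3 * index])

    def translate(self) -> str:
        return translate(self)


def translate(cds: CodingSequence | str) -> str:
    """Standard-genetic-code translation, one letter per codon, stop as '*'.

    Codons containing N translate to 'X'.
    """
    seq = cds.seq if isinstance(cds, CodingSequence) else NucleotideSequence(cds)
    if len(seq) % 3 != 0:
        raise FrameError(f"length {len(seq)} not divisible by 3")
    out = []
    for i in range(0, len(seq), 3):
        codon = seq[i : i + 3]
        if "N" in codon:
            out.append("X")
        else:
            out.append(str(Seq(str(codon)).translate()))
    return "".join(out)


STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


class IupacPattern:
    """A fixed-length degenerate nucleotide pattern (IUPAC codes).

    Matching is position-wise set membership. An N in the *candidate* window
    never matches (conservative: an unknown base is not assumed to satisfy
    the PAM).
    """

    def __init__(self, pattern: str):
        pattern = str(pattern).upper()
        for ch in pattern:
            if ch not in ambiguous_dna_values:
                raise AlphabetError(f"invalid IUPAC code {ch!r} in pattern")
        self.pattern = pattern
        self._sets = [frozenset(ambiguous_dna_values[ch]) for ch in pattern]

    def __len__(self) -> int:
        return len(self.pattern)

    def __repr__(self) -> str:
        return f"IupacPattern({self.pattern!r})"

    def __eq__(self, other) -> bool:
        return isinstance(other, IupacPattern) and self.pattern == other.pattern

    def __hash__(self) -> int:
        return hash(self.pattern)

    def matches(self, window: str) -> bool:
        if len(window) != len(self.pattern):
            raise ValueError(
                f"window length {len(window)} != pattern length {len(self.pattern)}"
            )
        return all(b in s for b, s in zip(str(window).upper(), self._sets))


def iupac_match(pattern: IupacPattern | str, window: str) -> bool:
    """True iff ``window`` satisfies the degenerate ``pattern`` position-wise."""
    if not isinstance(pattern, IupacPattern):
        pattern = IupacPattern(pattern)
    return pattern.matches(window)


@dataclass(frozen=True)
class EditorProfile:
    """Parameters of one base-editor / Cas orthologue combination.

    ``window_start``/``window_end`` are 1-based protospacer positions
    (inclusive) of the efficient deamination window; ``pam`` sits immediately
    3' of the protospacer on the protospacer strand.
    """

    name: str
    base_from: str
    base_to: str
    window_start: int
    window_end: int
    pam: IupacPattern
    spacer_length: int
    window_assumed: bool = False  # True when the window is a package default,
    #                               not an experimentally reported range

    def __post_init__(self) -> None:
        if isinstance(self.pam, str):
            object.__setattr__(self, "pam", IupacPattern(self.pam))
        if self.base_from not in "ACGT" or self.base_to not in "ACGT":
            raise AlphabetError("base_from/base_to must be single ACGT bases")
        if not (1 <= self.window_start <= self.window_end <= self.spacer_length):
            raise ValueError(
                f"invalid window {self.window_start}-{self.window_end} "
                f"for spacer length {self.spacer_length}"
            )

    @property
    def is_cbe(self) -> bool:
        return (self.base_from, self.base_to) == ("C", "T")

    @property
    def is_abe(self) -> bool:
        return (self.base_from, self.base_to) == ("A", "G")


@dataclass(frozen=True)
class GuideDesign:
    """One concrete protospacer placement on an input sequence.

    ``protospacer_start`` is 0-based half-open on the plus strand of the
    input sequence regardless of guide strand; ``spacer`` is the
    protospacer-strand sequence; ``target_position`` and
    ``bystander_positions`` are 1-based protospacer positions.
    """

    spacer: NucleotideSequence
    strand: str  # "+" or "-"
    protospacer_start: int
    pam_seq: NucleotideSequence
    target_position: int
    bystander_positions: tuple[int, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        object.__setattr__(self, "spacer", NucleotideSequence(self.spacer))
        object.__setattr__(self, "pam_seq", NucleotideSequence(self.pam_seq))
        object.__setattr__(
            self, "bystander_positions", tuple(self.bystander_positions)
        )
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.target_position in self.bystander_positions:
            raise ValueError("target_position listed among bystanders")

    def plus_strand_coord(self, protospacer_position: int) -> int:
        """Map a 1-based protospacer position to the 0-based plus-strand
        coordinate it covers on the input sequence."""
        if not 1 <= protospacer_position <= len(self.spacer):
            raise IndexError(
                f"protospacer position {protospacer_position} out of range"
            )
        if self.strand == "+":
            return self.protospacer_start + protospacer_position - 1
        return self.protospacer_start + len(self.spacer) - protospacer_position


def find_protospacers(
    seq: str | NucleotideSequence,
    site: int,
    profile: EditorProfile,
) -> list[GuideDesign]:
    """Enumerate every protospacer placement putting ``site`` in the window.

    Both strands are searched. A placement is reported when the base at
    ``site`` *on the protospacer strand* equals ``profile.base_from``, the
    site falls at a protospacer position within the editing window, the
    protospacer and PAM lie entirely within the sequence, and the observed
    PAM matches ``profile.pam``. Results are sorted by (strand, start), plus
    strand first.
    """
    seq = NucleotideSequence(seq)
    if not 0 <= site < len(seq):
        raise IndexError(f"site {site} out of bounds for length {len(seq)}")

    L = profile.spacer_length
    plen = len(profile.pam)
    designs: list[GuideDesign] = []

    # Plus strand: protospacer occupies [start, start+L), PAM [start+L, start+L+plen)
    if seq[site] == profile.base_from:
        for tp in range(profile.window_start, profile.window_end + 1):
            start = site - (tp - 1)
            if start < 0 or start + L + plen > len(seq):
                continue
            pam_seq = seq[start + L : start + L + plen]
            if not profile.pam.matches(pam_seq):
                continue
            spacer = NucleotideSequence(seq[start : start + L])
            designs.append(
                GuideDesign(
                    spacer=spacer,
                    strand="+",
                    protospacer_start=start,
                    pam_seq=NucleotideSequence(pam_seq),
                    target_position=tp,
                    bystander_positions=_window_bystanders(spacer, profile, tp),
                )
            )

    # Minus strand: protospacer is RC of [start, start+L); its PAM (3' on the
    # minus strand) is the RC of the plus-strand interval [start-plen, start).
    if complement_base(seq[site]) == profile.base_from:
        for tp in range(profile.window_start, profile.window_end + 1):
            start = site + tp - L  # from tp = start + L - site
            if start < 0 or start - plen < 0 or start + L > len(seq):
                continue
            pam_seq = reverse_complement(seq[start - plen : start])
            if not profile.pam.matches(pam_seq):
                continue
            spacer = reverse_complement(seq[start : start + L])
            designs.append(
                GuideDesign(
                    spacer=spacer,
                    strand="-",
                    protospacer_start=start,
                    pam_seq=pam_seq,
                    target_position=tp,
                    bystander_positions=_window_bystanders(spacer, profile, tp),
                )
            )

    designs.sort(key=lambda d: (0 if d.strand == "+" else 1, d.protospacer_start))
    return designs


def _window_bystanders(
    spacer: str, profile: EditorProfile, target_position: int
) -> tuple[int, ...]:
    """In-window positions carrying ``base_from`` other than the target."""
    return tuple(
        p
        for p in range(profile.window_start, profile.window_end + 1)
        if p != target_position and spacer[p - 1] == profile.base_from
    )
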