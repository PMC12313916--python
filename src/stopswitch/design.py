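"""The stop-switch design screen.

Enumerates codons of an ORF that a cytosine base editor (CBE) can convert
into a premature termination codon with a single C>T edit (on either
strand), designs the adenine-base-editor (ABE) guides that revert the
installed stop, annotates bystander bases inside each editing window, tests
compatibility with smaller Cas orthologues, and ranks candidates by
reversion cleanliness.

Only four sense codons are one C>T (or antisense G>A) edit away from a
stop: CGA (R), TGG (W), and CAA/CAG (Q).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

from .errors import (
    EditPreconditionError,
    InconsistentInputError,
    ProfileKindError,
)
from .profiles import ORTHOLOGUE_PROFILE_KEYS, get_profile
from .seqcore import (
    STOP_CODONS,
    CodingSequence,
    EditorProfile,
    GuideDesign,
    NucleotideSequence,
    complement_base,
    find_protospacers,
    translate,
)

#: Sense codons convertible to a stop by a single C>T edit on either strand.
SWITCHABLE_CODONS = ("CGA", "TGG", "CAA", "CAG")


def apply_edit(
    seq: str | NucleotideSequence,
    position: int,
    from_base: str,
    to_base: str,
    strand: str = "+",
) -> NucleotideSequence:
    """Substitute one base at 1-based ``position``; ``from_base``/``to_base``
    are read on ``strand``.

    Raises :class:`EditPreconditionError` when the base actually present on
    that strand is not ``from_base``.
    """
    seq = NucleotideSequence(seq)
    if not 1 <= position <= len(seq):
        raise IndexError(f"position {position} out of range 1..{len(seq)}")
    if strand not in "+-":
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    plus_base = seq[position - 1]
    observed = plus_base if strand == "+" else complement_base(plus_base)
    if observed != from_base.upper():
        raise EditPreconditionError(
            f"expected {from_base} at position {position} on strand {strand}, "
            f"found {observed}"
        )
    new_plus = to_base.upper() if strand == "+" else complement_base(to_base.upper())
    return NucleotideSequence(seq[: position - 1] + new_plus + seq[position:])


@dataclass(frozen=True)
class BystanderAnnotation:
    """One editable in-window base other than the target, with the coding
    consequence of editing it alone."""

    protospacer_position: int
    cds_position: int  # 1-based
    codon_index: int  # 1-based
    consequence: str | None  # synonymous | missense | nonsense | stop_loss
    residue_change: str | None  # e.g. "Q81H"


@dataclass(frozen=True)
class StopSwitchCandidate:
    """One codon convertible to a premature stop, with its guides."""

    codon_index: int
    wt_codon: NucleotideSequence
    installed_codon: NucleotideSequence
    edit_cds_position: int  # 1-based CDS coordinate of the edited base
    edit_strand: str  # strand carrying the installing C>T change
    install_guides: tuple[GuideDesign, ...] = ()
    reversion_guides: Mapping[str, tuple[GuideDesign, ...]] = field(
        default_factory=dict
    )
    min_reversion_bystanders: int | None = None

    @property
    def has_reversion_guide(self) -> bool:
        return any(len(g) > 0 for g in self.reversion_guides.values())

    @property
    def n_compatible_profiles(self) -> int:
        return sum(1 for g in self.reversion_guides.values() if len(g) > 0)


def _stop_creating_edits(codon: str) -> list[tuple[int, str, str]]:
    """All (codon_offset 0-2, edit_strand, installed_codon) single C>T edits
    turning ``codon`` into a stop."""
    edits = []
    for offset in range(3):
        base = codon[offset]
        if base == "C":  # C>T on the sense strand
            new = codon[:offset] + "T" + codon[offset + 1 :]
            if new in STOP_CODONS:
                edits.append((offset, "+", new))
        if base == "G":  # C>T on the antisense strand = G>A on sense
            new = codon[:offset] + "A" + codon[offset + 1 :]
            if new in STOP_CODONS:
                edits.append((offset, "-", new))
    return edits


def enumerate_stop_switch_sites(
    cds: CodingSequence,
    install_profile: EditorProfile,
    revert_profiles: Iterable[EditorProfile] | None = None,
    max_codon: int | None = None,
) -> list[StopSwitchCandidate]:
    """Screen an ORF for CBE-installable premature stop codons.

    Every single C>T edit (either strand) converting a switchable codon into
    an in-frame stop is considered; a candidate is retained iff at least one
    install guide exists under ``install_profile``. When ``revert_profiles``
    is given (default: SpCas9 ABE8e plus the Sa/Sauri orthologues), reversion
    guides are designed against the corresponding mutant and
    ``min_reversion_bystanders`` is the minimum bystander count over valid
    guides of the *first* revert profile.
    """
    if not install_profile.is_cbe:
        raise ProfileKindError(
            f"install profile must be a CBE (C>T); got "
            f"{install_profile.base_from}>{install_profile.base_to}"
        )
    if revert_profiles is None:
        revert_profiles = [get_profile("abe8e-sp")] + [
            get_profile(k) for k in ORTHOLOGUE_PROFILE_KEYS
        ]
    revert_profiles = list(revert_profiles)

    candidates = []
    for codon_index in range(1, cds.n_codons + 1):
        codon = str(cds.codon(codon_index))
        if codon not in SWITCHABLE_CODONS:
            continue
        if max_codon is not None and codon_index > max_codon:
            continue
        for offset, strand, installed in _stop_creating_edits(codon):
            site = 3 * (codon_index - 1) + offset  # 0-based CDS coordinate
            install_guides = find_protospacers(cds.seq, site, install_profile)
            if not install_guides:
                continue
            candidate = StopSwitchCandidate(
                codon_index=codon_index,
                wt_codon=NucleotideSequence(codon),
                installed_codon=NucleotideSequence(installed),
                edit_cds_position=site + 1,
                edit_strand=strand,
                install_guides=tuple(install_guides),
            )
            candidate = _attach_reversion_guides(cds, candidate, revert_profiles)
            candidates.append(candidate)
    candidates.sort(key=lambda c: (c.codon_index, c.edit_cds_position))
    return candidates


def _attach_reversion_guides(
    cds: CodingSequence,
    candidate: StopSwitchCandidate,
    revert_profiles: list[EditorProfile],
) -> StopSwitchCandidate:
    mutant = CodingSequence(
        apply_edit(
            cds.seq,
            candidate.edit_cds_position,
            from_base="C",
            to_base="T",
            strand=candidate.edit_strand,
        ),
        name=cds.name,
    )
    guide_map: dict[str, tuple[GuideDesign, ...]] = {}
    for profile in revert_profiles:
        guide_map[profile.name] = tuple(
            design_reversion_guides(mutant, candidate, profile)
        )
    min_bystanders = None
    if revert_profiles:
        default_guides = guide_map[revert_profiles[0].name]
        if default_guides:
            min_bystanders = min(
                len(g.bystander_positions) for g in default_guides
            )
    return replace(
        candidate,
        reversion_guides=guide_map,
        min_reversion_bystanders=min_bystanders,
    )


def design_reversion_guides(
    mutant: CodingSequence,
    candidate: StopSwitchCandidate,
    revert_profile: EditorProfile,
) -> list[GuideDesign]:
    """ABE guides reverting an installed premature stop.

    The installing edit left a T on ``candidate.edit_strand``; the editable
    adenine therefore sits on the opposite strand at the same coordinate,
    and all protospacers placing that adenine inside the ABE window with a
    matching PAM are returned (bystander adenines annotated).
    """
    if not revert_profile.is_abe:
        raise ProfileKindError(
            f"revert profile must be an ABE (A>G); got "
            f"{revert_profile.base_from}>{revert_profile.base_to}"
        )
    if str(mutant.codon(candidate.codon_index)) != str(candidate.installed_codon):
        raise InconsistentInputError(
            f"mutant codon {candidate.codon_index} is "
            f"{mutant.codon(candidate.codon_index)}, expected "
            f"{candidate.installed_codon}"
        )
    site = candidate.edit_cds_position - 1
    return find_protospacers(mutant.seq, site, revert_profile)


def count_bystanders(
    guide: GuideDesign,
    profile: EditorProfile,
    context: str | NucleotideSequence,
) -> tuple[int, list[BystanderAnnotation]]:
    """Count in-window editable bases other than the target, annotating each
    with the coding consequence of editing it alone.

    ``context`` is read in frame from its first base (i.e. a CDS); the guide
    must match its recorded placement on the context.
    """
    context = NucleotideSequence(context)
    L = len(guide.spacer)
    start = guide.protospacer_start
    if start < 0 or start + L > len(context):
        raise InconsistentInputError("guide placement outside context")
    observed = context[start : start + L]
    if guide.strand == "-":
        observed = NucleotideSequence(observed).reverse_complement()
    if str(observed) != str(guide.spacer):
        raise InconsistentInputError(
            "guide spacer does not match context at its recorded placement"
        )

    annotations = []
    for p in range(profile.window_start, profile.window_end + 1):
        if p == guide.target_position or guide.spacer[p - 1] != profile.base_from:
            continue
        coord = guide.plus_strand_coord(p)  # 0-based on context
        consequence, change = _edit_consequence(
            context, coord, profile, guide.strand
        )
        annotations.append(
            BystanderAnnotation(
                protospacer_position=p,
                cds_position=coord + 1,
                codon_index=coord // 3 + 1,
                consequence=consequence,
                residue_change=change,
            )
        )
    return len(annotations), annotations


def _edit_consequence(
    context: NucleotideSequence,
    coord: int,
    profile: EditorProfile,
    strand: str,
) -> tuple[str | None, str | None]:
    codon_start = (coord // 3) * 3
    if codon_start + 3 > len(context):
        return None, None
    old_codon = context[codon_start : codon_start + 3]
    new_plus = (
        profile.base_to
        if strand == "+"
        else complement_base(profile.base_to)
    )
    pos_in_codon = coord - codon_start
    new_codon = old_codon[:pos_in_codon] + new_plus + old_codon[pos_in_codon + 1 :]
    old_aa = translate(old_codon + "")  # single codon
    new_aa = translate(new_codon + "")
    index = coord // 3 + 1
    change = f"{old_aa}{index}{new_aa}"
    if old_aa == new_aa:
        return "synonymous", change
    if new_aa == "*":
        return "nonsense", change
    if old_aa == "*":
        return "stop_loss", change
    return "missense", change


def rank_candidates(
    candidates: Iterable[StopSwitchCandidate],
) -> list[StopSwitchCandidate]:
    """Order candidates for reversion cleanliness.

    Ascending by ``min_reversion_bystanders``; ties broken by more
    orthologue profiles with at least one valid reversion guide, then by
    smaller (5'-most) codon index. Candidates with no reversion guide under
    any profile rank last.
    """
    return sorted(
        candidates,
        key=lambda c: (
            0 if c.has_reversion_guide else 1,
            c.min_reversion_bystanders
            if c.min_reversion_bystanders is not None
            else float("inf"),
            -c.n_compatible_profiles,
            c.codon_index,
        ),
    )
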