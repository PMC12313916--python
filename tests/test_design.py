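"""The stop-switch screen: enumeration, reversion design, bystander
annotation, ranking, and editing round trips, checked against independent
brute force on random ORFs."""

import numpy as np
import pytest

from conftest import random_orf
from stopswitch import (
    CodingSequence,
    EditorProfile,
    IupacPattern,
    NucleotideSequence,
    apply_edit,
    count_bystanders,
    design_reversion_guides,
    enumerate_stop_switch_sites,
    get_profile,
    rank_candidates,
    translate,
)
from stopswitch.design import StopSwitchCandidate, _stop_creating_edits
from stopswitch.errors import (
    EditPreconditionError,
    InconsistentInputError,
    ProfileKindError,
)

STOPS = {"TAA", "TAG", "TGA"}


# ---------------------------------------------------------------------------
# apply_edit


def test_install_edit_creates_stop_at_codon_81(wt_cds):
    edited = apply_edit(wt_cds.seq, 241, "C", "T", "+")
    assert edited[240:243] == "TAG"
    assert translate(CodingSequence(edited))[80] == "*"


def test_install_then_revert_round_trip(wt_cds):
    edited = apply_edit(wt_cds.seq, 241, "C", "T", "+")
    # reversion is an A>G edit on the antisense strand at the same coordinate
    restored = apply_edit(edited, 241, "A", "G", "-")
    assert str(restored) == str(wt_cds.seq)


def test_apply_edit_precondition():
    with pytest.raises(EditPreconditionError):
        apply_edit("ACGT", 1, "G", "A", "+")


# ---------------------------------------------------------------------------
# enumeration


def test_screen_recovers_q81x_with_printed_guide(wt_cds):
    candidates = enumerate_stop_switch_sites(wt_cds, get_profile("be4max-ng"))
    q81 = [c for c in candidates if c.codon_index == 81]
    assert len(q81) == 1
    c = q81[0]
    assert str(c.wt_codon) == "CAG" and str(c.installed_codon) == "TAG"
    assert c.edit_cds_position == 241
    assert any(
        str(g.spacer) == "GAAGCAGCACGACTTCTTCA" for g in c.install_guides
    )


def test_screen_output_sorted_and_contains_q81(wt_cds):
    candidates = enumerate_stop_switch_sites(wt_cds, get_profile("be4max-ng"))
    indices = [c.codon_index for c in candidates]
    assert indices == sorted(indices)
    assert 81 in indices
    # every candidate codon is one of the four switchable codons
    assert {str(c.wt_codon) for c in candidates} <= {"CGA", "TGG", "CAA", "CAG"}


def test_cds_without_switchable_codons_yields_nothing():
    cds = CodingSequence("ATGTTTTTTTTTTTTTTTTTTTTTTTTTTT")
    assert enumerate_stop_switch_sites(cds, get_profile("be4max-ng")) == []


def test_toy_cds_single_candidate():
    # ATG CGA + A-free, TGG-free padding; permissive profile sees every edit
    permissive = EditorProfile(
        name="permissive", base_from="C", base_to="T",
        window_start=1, window_end=20, pam=IupacPattern("N"), spacer_length=20,
    )
    cds = CodingSequence("ATGCGA" + "TGC" * 8)
    candidates = enumerate_stop_switch_sites(cds, permissive)
    assert len(candidates) == 1
    assert candidates[0].codon_index == 2
    assert str(candidates[0].installed_codon) == "TGA"


def test_abe_profile_rejected_for_install(wt_cds):
    with pytest.raises(ProfileKindError):
        enumerate_stop_switch_sites(wt_cds, get_profile("abe8e-sp"))


def test_tgg_yields_two_stop_edits():
    assert {(o, s, c) for o, s, c in _stop_creating_edits("TGG")} == {
        (1, "-", "TAG"),
        (2, "-", "TGA"),
    }
    assert _stop_creating_edits("CAG") == [(0, "+", "TAG")]


# ---------------------------------------------------------------------------
# reversion guides


def test_reversion_guides_include_printed_sgrnas(wt_cds, mutant_cds):
    candidates = enumerate_stop_switch_sites(wt_cds, get_profile("be4max-ng"))
    (c,) = [x for x in candidates if x.codon_index == 81]
    guides = design_reversion_guides(mutant_cds, c, get_profile("abe8e-sp"))
    by_spacer = {str(g.spacer): g for g in guides}
    g1 = by_spacer["CGTGCTACTTCATGTGGTCG"]
    assert g1.target_position == 7 and str(g1.pam_seq) == "GGG"
    assert by_spacer["GTCGTGCTACTTCATGTGGT"].target_position == 9
    assert by_spacer["TCGTGCTACTTCATGTGGTC"].target_position == 8


def test_sa_orthologue_reversion_guide(wt_cds, mutant_cds):
    candidates = enumerate_stop_switch_sites(wt_cds, get_profile("be4max-ng"))
    (c,) = [x for x in candidates if x.codon_index == 81]
    guides = design_reversion_guides(mutant_cds, c, get_profile("saabe8e"))
    assert "AGTCGTGCTACTTCATGTGGT" in {str(g.spacer) for g in guides}


def test_narrowed_window_filters_targets(wt_cds, mutant_cds):
    candidates = enumerate_stop_switch_sites(wt_cds, get_profile("be4max-ng"))
    (c,) = [x for x in candidates if x.codon_index == 81]
    narrow = get_profile("abe8e-sp", window_start=7, window_end=7)
    guides = design_reversion_guides(mutant_cds, c, narrow)
    assert guides and all(g.target_position == 7 for g in guides)


def test_reversion_requires_consistent_mutant(wt_cds):
    candidates = enumerate_stop_switch_sites(wt_cds, get_profile("be4max-ng"))
    (c,) = [x for x in candidates if x.codon_index == 81]
    with pytest.raises(InconsistentInputError):
        design_reversion_guides(wt_cds, c, get_profile("abe8e-sp"))


# ---------------------------------------------------------------------------
# bystanders


def test_sgrna1_has_no_bystanders_in_abe_window(mutant_cds):
    from stopswitch import find_protospacers

    guides = find_protospacers(mutant_cds.seq, 240, get_profile("abe8e-sp"))
    g1 = [g for g in guides if str(g.spacer) == "CGTGCTACTTCATGTGGTCG"][0]
    n, anns = count_bystanders(g1, get_profile("abe8e-sp"), mutant_cds.seq)
    assert n == 0 and anns == []
    # the spacer's only other adenine sits at position 12, outside 3-10
    assert [i + 1 for i, b in enumerate(str(g1.spacer)) if b == "A"] == [7, 12]


def test_install_guide_has_one_bystander_cytosine(wt_cds):
    from stopswitch import find_protospacers

    profile = get_profile("be4max-ng")
    (g,) = find_protospacers(wt_cds.seq, 240, profile)
    n, anns = count_bystanders(g, profile, wt_cds.seq)
    assert n == 1
    assert anns[0].protospacer_position == 8
    assert anns[0].consequence in {"synonymous", "missense", "nonsense", "stop_loss"}


def test_bystander_annotation_consequence_recomputable(wt_cds):
    from stopswitch import find_protospacers

    profile = get_profile("be4max-ng")
    (g,) = find_protospacers(wt_cds.seq, 240, profile)
    _, anns = count_bystanders(g, profile, wt_cds.seq)
    for a in anns:
        edited = apply_edit(
            wt_cds.seq, a.cds_position, profile.base_from, profile.base_to, g.strand
        )
        old_aa = translate(wt_cds)[a.codon_index - 1]
        new_aa = translate(CodingSequence(edited))[a.codon_index - 1]
        assert a.residue_change == f"{old_aa}{a.codon_index}{new_aa}"


def test_count_bystanders_rejects_mismatched_context(mutant_cds):
    from stopswitch import find_protospacers

    guides = find_protospacers(mutant_cds.seq, 240, get_profile("abe8e-sp"))
    with pytest.raises(InconsistentInputError):
        count_bystanders(guides[0], get_profile("abe8e-sp"), "A" * 720)


# ---------------------------------------------------------------------------
# ranking


def _candidate(codon_index, bystanders, n_profiles=1):
    guides = {f"p{i}": ("g",) for i in range(n_profiles)}
    return StopSwitchCandidate(
        codon_index=codon_index,
        wt_codon=NucleotideSequence("CAG"),
        installed_codon=NucleotideSequence("TAG"),
        edit_cds_position=3 * codon_index - 2,
        edit_strand="+",
        reversion_guides=guides if bystanders is not None else {},
        min_reversion_bystanders=bystanders,
    )


def test_rank_ascending_by_bystanders():
    ranked = rank_candidates(
        [_candidate(10, 2), _candidate(20, 0), _candidate(30, 1)]
    )
    assert [c.min_reversion_bystanders for c in ranked] == [0, 1, 2]


def test_rank_tie_broken_by_compatibility_then_position():
    ranked = rank_candidates(
        [_candidate(10, 0, n_profiles=1), _candidate(20, 0, n_profiles=3)]
    )
    assert ranked[0].codon_index == 20
    ranked = rank_candidates([_candidate(50, 0), _candidate(5, 0)])
    assert ranked[0].codon_index == 5


def test_unrevertible_candidates_rank_last():
    ranked = rank_candidates([_candidate(5, None), _candidate(99, 3)])
    assert ranked[-1].codon_index == 5
    assert not ranked[-1].has_reversion_guide


def test_q81_ranked_first_on_egfp(wt_cds):
    candidates = enumerate_stop_switch_sites(wt_cds, get_profile("be4max-ng"))
    ranked = rank_candidates(candidates)
    assert ranked[0].codon_index == 81
    assert ranked[0].min_reversion_bystanders == 0


# ---------------------------------------------------------------------------
# screen vs brute force, round trips, monotonicity


def _oracle_screen(cds: CodingSequence, profile, bf_designs):
    """Independent screen: try every single C>T (either strand) edit at every
    CDS position; keep edits creating a new in-frame stop with >= 1 guide."""
    seq = str(cds.seq)
    found = set()
    for pos in range(len(seq)):
        for plus_new, strand in (("T", "+"), ("A", "-")):
            base_needed = "C" if strand == "+" else "G"
            if seq[pos] != base_needed:
                continue
            codon_i = pos // 3
            old = seq[3 * codon_i : 3 * codon_i + 3]
            new = list(old)
            new[pos % 3] = plus_new
            new = "".join(new)
            if old in STOPS or new not in STOPS:
                continue
            if bf_designs.get(pos):
                found.add((codon_i + 1, new, pos + 1, strand))
    return found


def test_screen_matches_bruteforce_on_random_orfs():
    from test_seqcore import brute_force_designs

    profile = get_profile("be4max-sp-ng")
    rng = np.random.default_rng(11)
    for _ in range(10):
        cds = CodingSequence(random_orf(rng, 100))
        bf = brute_force_designs(str(cds.seq), profile)
        oracle = _oracle_screen(cds, profile, bf)
        got = {
            (c.codon_index, str(c.installed_codon), c.edit_cds_position, c.edit_strand)
            for c in enumerate_stop_switch_sites(cds, profile, revert_profiles=[])
        }
        assert got == oracle


def test_round_trip_restores_cds_on_random_orfs():
    rng = np.random.default_rng(13)
    abe = get_profile("abe8e-sp")
    for _ in range(10):
        cds = CodingSequence(random_orf(rng, 100))
        for c in enumerate_stop_switch_sites(cds, get_profile("be4max-ng")):
            mutant = apply_edit(cds.seq, c.edit_cds_position, "C", "T", c.edit_strand)
            mut_prot = translate(CodingSequence(mutant))
            assert mut_prot[c.codon_index - 1] == "*"
            # the stop is the only protein change
            wt_prot = translate(cds)
            diffs = [i for i, (a, b) in enumerate(zip(wt_prot, mut_prot)) if a != b]
            assert diffs == [c.codon_index - 1]
            for g in c.reversion_guides.get(abe.name, ()):
                reverted = apply_edit(
                    mutant, c.edit_cds_position, "A", "G",
                    "-" if c.edit_strand == "+" else "+",
                )
                assert str(reverted) == str(cds.seq)


def test_relaxing_constraints_never_removes_candidates(wt_cds):
    def key(cands):
        return {
            (c.codon_index, str(c.installed_codon), c.edit_cds_position)
            for c in cands
        }

    ngg = key(enumerate_stop_switch_sites(wt_cds, get_profile("be4max-ngg")))
    ng = key(enumerate_stop_switch_sites(wt_cds, get_profile("be4max-ng")))
    permissive = EditorProfile(
        name="perm", base_from="C", base_to="T",
        window_start=4, window_end=8, pam=IupacPattern("N"), spacer_length=20,
    )
    n_any = key(enumerate_stop_switch_sites(wt_cds, permissive))
    assert ngg <= ng <= n_any

    wide = EditorProfile(
        name="wide", base_from="C", base_to="T",
        window_start=1, window_end=20, pam=IupacPattern("NG"), spacer_length=20,
    )
    assert ng <= key(enumerate_stop_switch_sites(wt_cds, wide))
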