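"""Shipped base-editor profiles and YAML profile loading.

The SpCas9 profiles carry experimentally characterized editing windows
(ABE8e positions 3-10; BE4max positions 4-8, which under the
"d bases upstream of the PAM" distance convention d = spacer_length -
target_position corresponds to targets 12-16 nt upstream of the PAM on a
20-mer). The SaCas9 and S. auricularis Cas9 ABE windows are package
defaults (positions 4-12 of a 21-mer), flagged ``window_assumed`` and
overridable per call or via a YAML profile file.
"""

from __future__ import annotations

from dataclasses import replace
from pathlib import Path

import yaml

from .seqcore import EditorProfile, IupacPattern

BUILTIN_PROFILES: dict[str, EditorProfile] = {
    "abe8e-sp": EditorProfile(
        name="ABE8e-Sp",
        base_from="A",
        base_to="G",
        window_start=3,
        window_end=10,
        pam=IupacPattern("NGG"),
        spacer_length=20,
    ),
    "be4max-sp-ng": EditorProfile(
        name="BE4max-Sp-NG",
        base_from="C",
        base_to="T",
        window_start=4,
        window_end=8,
        pam=IupacPattern("NG"),
        spacer_length=20,
    ),
    "be4max-sp-ngg": EditorProfile(
        name="BE4max-Sp-NGG",
        base_from="C",
        base_to="T",
        window_start=4,
        window_end=8,
        pam=IupacPattern("NGG"),
        spacer_length=20,
    ),
    "saabe8e": EditorProfile(
        name="SaABE8e",
        base_from="A",
        base_to="G",
        window_start=4,
        window_end=12,
        pam=IupacPattern("NNGRRT"),
        spacer_length=21,
        window_assumed=True,
    ),
    "sauriabe": EditorProfile(
        name="SauriABE",
        base_from="A",
        base_to="G",
        window_start=4,
        window_end=12,
        pam=IupacPattern("NNGG"),
        spacer_length=21,
        window_assumed=True,
    ),
}

_ALIASES = {
    "abe8e": "abe8e-sp",
    "abe8e-ngg": "abe8e-sp",
    "be4max-ng": "be4max-sp-ng",
    "be4max-ngg": "be4max-sp-ngg",
    "sa": "saabe8e",
    "sa-abe8e": "saabe8e",
    "sauri": "sauriabe",
    "sauri-abe": "sauriabe",
}

#: Orthologue profiles consulted for multi-editor reversion compatibility.
ORTHOLOGUE_PROFILE_KEYS = ("saabe8e", "sauriabe")


def get_profile(
    name: str,
    *,
    window_start: int | None = None,
    window_end: int | None = None,
) -> EditorProfile:
    """Look up a shipped profile by (case-insensitive) name or alias,
    optionally overriding the editing window."""
    key = name.strip().lower()
    key = _ALIASES.get(key, key)
    if key not in BUILTIN_PROFILES:
        known = sorted(set(BUILTIN_PROFILES) | set(_ALIASES))
        raise KeyError(f"unknown editor profile {name!r}; known: {known}")
    profile = BUILTIN_PROFILES[key]
    if window_start is not None or window_end is not None:
        profile = replace(
            profile,
            window_start=window_start or profile.window_start,
            window_end=window_end or profile.window_end,
            window_assumed=False,
        )
    return profile


def load_profiles(path: str | Path) -> dict[str, EditorProfile]:
    """Load editor profiles from a YAML mapping of name -> fields.

    Expected fields per entry: base_from, base_to, window_start, window_end,
    pam, spacer_length. Entries merge over (and may shadow) the shipped set.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    profiles = dict(BUILTIN_PROFILES)
    for name, fields in raw.items():
        profiles[name.strip().lower()] = EditorProfile(
            name=name,
            base_from=fields["base_from"].upper(),
            base_to=fields["base_to"].upper(),
            window_start=int(fields["window_start"]),
            window_end=int(fields["window_end"]),
            pam=IupacPattern(fields["pam"]),
            spacer_length=int(fields["spacer_length"]),
        )
    return profiles
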