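"""Packaged reference sequences and oligo table for the EGFP reporter locus.

The wild-type fixture is the canonical EGFP coding sequence; the mutant
fixture is derived at load time by applying the single premature-stop
installation edit (C>T at CDS position 241, converting codon 81 CAG to TAG,
i.e. Q81X). The oligo table lists every guide spacer and ddPCR oligo used
by the reporter workflow, each of which occurs exactly once in one of the
two fixtures (on either strand).
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

import pandas as pd
from Bio import SeqIO

from .design import apply_edit
from .seqcore import CodingSequence, NucleotideSequence

#: 1-based CDS coordinate of the installation edit (C>T on the coding strand).
Q81X_CDS_POSITION = 241
#: 1-based codon index of the installed premature stop.
Q81X_CODON_INDEX = 81

INSTALL_SPACER = NucleotideSequence("GAAGCAGCACGACTTCTTCA")
#: Protospacer position of the target cytosine within the install spacer.
INSTALL_TARGET_POSITION = 5

SGRNA_SPACERS = {
    "sgRNA1": NucleotideSequence("CGTGCTACTTCATGTGGTCG"),
    "sgRNA2": NucleotideSequence("GTCGTGCTACTTCATGTGGT"),
    "sgRNA3": NucleotideSequence("TCGTGCTACTTCATGTGGTC"),
}
SA_SPACER = NucleotideSequence("AGTCGTGCTACTTCATGTGGT")


def _data_path(name: str):
    return resources.files("stopswitch.data").joinpath(name)


@lru_cache(maxsize=1)
def wt_egfp_cds() -> CodingSequence:
    """The canonical wild-type EGFP coding sequence (720 nt)."""
    with resources.as_file(_data_path("egfp_wt_cds.fasta")) as path:
        record = next(SeqIO.parse(str(path), "fasta"))
    return CodingSequence(NucleotideSequence(str(record.seq)), name=record.id)


@lru_cache(maxsize=1)
def q81x_mutant_cds() -> CodingSequence:
    """The GFP-on allele: EGFP with the Q81X premature stop installed."""
    wt = wt_egfp_cds()
    mutant_seq = apply_edit(
        wt.seq, Q81X_CDS_POSITION, from_base="C", to_base="T", strand="+"
    )
    return CodingSequence(mutant_seq, name=wt.name + "_Q81X")


@lru_cache(maxsize=1)
def printed_oligos() -> pd.DataFrame:
    """Guide spacers and ddPCR oligos, with roles and orientations."""
    with resources.as_file(_data_path("printed_oligos.tsv")) as path:
        return pd.read_csv(path, sep="\t")


def builtin_fixtures() -> dict:
    """All packaged fixtures in one mapping."""
    return {
        "wt_egfp_cds": wt_egfp_cds(),
        "q81x_mutant_cds": q81x_mutant_cds(),
        "printed_oligos": printed_oligos(),
    }
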