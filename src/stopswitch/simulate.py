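"""Ground-truthed simulators for every readout stage.

``simulate_amplicon_reads`` emulates the single-end amplicon sequencing
readout (220-280 cycle reads covering the protospacer, a target A>G
conversion at a known per-read fraction, optional bystander co-edits,
uniform per-base substitution error, and truncated-normal Phred strings,
with a configurable share of low-quality reads exercising the mean-Q
filter). ``simulate_ddpcr`` draws per-partition Poisson occupancies for the
two ddPCR channels, and ``simulate_cell_population`` draws per-cell
independent copy-editing outcomes for the multi-copy activation model.

All generators are deterministic under a fixed seed and echo their
configuration and seed in the returned truth manifest.
"""

from __future__ import annotations

import dataclasses
import gzip
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .copynumber import PartitionCounts
from .errors import InconsistentInputError
from .quant import ReadRecord
from .seqcore import GuideDesign, NucleotideSequence, complement_base

_BASES = np.frombuffer(b"ACGT", np.uint8)
_PHRED_MIN, _PHRED_MAX = 2, 41


@dataclass(frozen=True)
class AmpliconSimConfig:
    """Parameters of one simulated amplicon sequencing run.

    ``read_length=None`` draws each read's length uniformly from 220-280
    cycles (clipped to the amplicon). Bystander co-edits are independent of
    the target edit unless ``bystanders_linked_to_edit`` is set, in which
    case they occur only on edited reads (processive deamination on the
    same molecule).
    """

    amplicon: NucleotideSequence
    guide: GuideDesign
    edit_fraction: float
    n_reads: int
    bystander_fractions: dict[int, float] = field(default_factory=dict)
    bystanders_linked_to_edit: bool = False
    per_base_error: float = 0.001
    read_length: int | None = None
    phred_mean: float = 37.0
    phred_sd: float = 3.0
    low_quality_mean: float = 25.0
    fraction_low_quality: float = 0.05
    window_center: int = 10
    window_halfwidth: int = 20
    base_from: str = "A"
    base_to: str = "G"
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "amplicon", NucleotideSequence(self.amplicon)
        )
        for p in (
            self.edit_fraction,
            self.per_base_error,
            self.fraction_low_quality,
            *self.bystander_fractions.values(),
        ):
            if not 0 <= p <= 1:
                raise ValueError(f"probability {p} outside [0, 1]")
        if self.read_length is not None and self.read_length > len(self.amplicon):
            raise ValueError("read_length exceeds amplicon length")


@dataclass(frozen=True)
class TruthManifest:
    """Per-read ground truth for one simulated run."""

    edited: tuple[bool, ...]
    bystanders: tuple[tuple[int, ...], ...]  # protospacer positions per read
    intended_pass_quality: tuple[bool, ...]
    realized_edit_fraction: float
    seed: int
    config: dict

    def __post_init__(self) -> None:
        assert self.realized_edit_fraction == sum(self.edited) / len(self.edited)


def _config_echo(config) -> dict:
    d = dataclasses.asdict(config)
    for k, v in d.items():
        if isinstance(v, NucleotideSequence):
            d[k] = str(v)
    if "guide" in d:
        d["guide"] = {k: str(v) if isinstance(v, str) else v for k, v in d["guide"].items()}
    return d


def simulate_amplicon_reads(
    config: AmpliconSimConfig,
) -> tuple[list[ReadRecord], TruthManifest]:
    """Draw single-end reads from the amplicon with known editing truth."""
    amp = str(config.amplicon)
    guide = config.guide
    L = len(guide.spacer)
    s = guide.protospacer_start
    if s < 0 or s + L > len(amp):
        raise InconsistentInputError("guide placement outside amplicon")
    observed = amp[s : s + L]
    if guide.strand == "-":
        observed = str(NucleotideSequence(observed).reverse_complement())
    if observed != str(guide.spacer):
        raise InconsistentInputError("guide spacer not found on amplicon")

    def plus_coord(p: int) -> int:
        return s + p - 1 if guide.strand == "+" else s + L - p

    def plus_base(b: str) -> str:
        return b if guide.strand == "+" else complement_base(b)

    target0 = plus_coord(guide.target_position)
    edited_base = ord(plus_base(config.base_to))

    # Quantification window the reads must cover.
    a = plus_coord(config.window_center - config.window_halfwidth)
    b = plus_coord(config.window_center + config.window_halfwidth)
    win_lo, win_hi = max(min(a, b), 0), min(max(a, b) + 1, len(amp))

    rng = np.random.default_rng(config.seed)
    n = config.n_reads
    amp_arr = np.frombuffer(amp.encode("ascii"), np.uint8)

    edited = rng.random(n) < config.edit_fraction
    low_quality = rng.random(n) < config.fraction_low_quality
    if config.read_length is None:
        lengths = rng.integers(220, 281, size=n)
        lengths = np.minimum(lengths, len(amp))
    else:
        lengths = np.full(n, config.read_length)

    by_positions = sorted(config.bystander_fractions)
    reads: list[ReadRecord] = []
    bystanders_truth: list[tuple[int, ...]] = []

    for i in range(n):
        rl = int(lengths[i])
        lo_start = max(0, win_hi - rl)
        hi_start = min(win_lo, len(amp) - rl)
        if hi_start < lo_start:
            raise ValueError("read length cannot cover the quantification window")
        start = int(rng.integers(lo_start, hi_start + 1))
        read = amp_arr[start : start + rl].copy()

        if edited[i]:
            read[target0 - start] = edited_base

        hit_bystanders = []
        for p in by_positions:
            if config.bystanders_linked_to_edit and not edited[i]:
                continue
            if rng.random() < config.bystander_fractions[p]:
                c = plus_coord(p)
                if start <= c < start + rl:
                    read[c - start] = ord(plus_base(config.base_to))
                    hit_bystanders.append(p)
        bystanders_truth.append(tuple(hit_bystanders))

        if config.per_base_error > 0:
            err = rng.random(rl) < config.per_base_error
            idx = np.nonzero(err)[0]
            if idx.size:
                # substitute with one of the three other bases, uniformly
                shift = rng.integers(1, 4, size=idx.size)
                cur = np.searchsorted(_BASES, read[idx])
                read[idx] = _BASES[(cur + shift) % 4]

        mean_q = config.low_quality_mean if low_quality[i] else config.phred_mean
        quals = np.clip(
            np.rint(rng.normal(mean_q, config.phred_sd, size=rl)),
            _PHRED_MIN,
            _PHRED_MAX,
        ).astype(int)

        reads.append(
            ReadRecord(
                id=f"sim_{i:06d}",
                bases=NucleotideSequence(read.tobytes().decode("ascii")),
                quals=tuple(int(q) for q in quals),
            )
        )

    manifest = TruthManifest(
        edited=tuple(bool(e) for e in edited),
        bystanders=tuple(bystanders_truth),
        intended_pass_quality=tuple(bool(not l) for l in low_quality),
        realized_edit_fraction=float(np.count_nonzero(edited)) / n,
        seed=config.seed,
        config=_config_echo(config),
    )
    return reads, manifest


def write_fastq(reads: list[ReadRecord], path: str | Path) -> None:
    """Write Sanger FASTQ (gzip when the path ends in .gz)."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        for r in reads:
            qual = "".join(chr(q + 33) for q in r.quals)
            fh.write(f"@{r.id}\n{r.bases}\n+\n{qual}\n")


def simulate_ddpcr(
    lambda_target: float,
    lambda_reference: float,
    n_partitions: int,
    seed: int = 0,
) -> tuple[PartitionCounts, dict]:
    """Per-partition Poisson occupancies, positive iff occupancy >= 1."""
    if lambda_target < 0 or lambda_reference < 0:
        raise ValueError("lambda must be non-negative")
    rng = np.random.default_rng(seed)
    occ_t = rng.poisson(lambda_target, n_partitions)
    occ_r = rng.poisson(lambda_reference, n_partitions)
    counts = PartitionCounts(
        n_partitions=n_partitions,
        n_positive_target=int(np.count_nonzero(occ_t)),
        n_positive_reference=int(np.count_nonzero(occ_r)),
    )
    truth = {
        "lambda_target": lambda_target,
        "lambda_reference": lambda_reference,
        "ratio": (lambda_target / lambda_reference)
        if lambda_reference > 0
        else None,
        "seed": seed,
    }
    return counts, truth


@dataclass(frozen=True)
class PopulationSimConfig:
    """A population of cells each carrying ``n_copies`` reporter copies,
    each copy edited independently with probability ``q``."""

    n_copies: int = 6
    q: float = 0.1
    n_cells: int = 100_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.q <= 1:
            raise ValueError("q outside [0, 1]")
        if self.n_copies < 1 or self.n_cells < 1:
            raise ValueError("n_copies and n_cells must be >= 1")


def simulate_cell_population(config: PopulationSimConfig) -> dict:
    """Empirical per-copy edited fraction and positive-cell fraction."""
    rng = np.random.default_rng(config.seed)
    edited = rng.random((config.n_cells, config.n_copies)) < config.q
    return {
        "allele_fraction": float(edited.mean()),
        "cell_positive_fraction": float(edited.any(axis=1).mean()),
        "n_cells": config.n_cells,
        "n_copies": config.n_copies,
        "q": config.q,
        "seed": config.seed,
    }
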