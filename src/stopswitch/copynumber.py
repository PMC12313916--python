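"""ddPCR Poisson copy-number estimation and the multi-copy reporter
activation model.

Digital PCR partitions a reaction into thousands of droplets/wells; with a
positive-partition fraction p per channel, the mean template occupancy is
lambda = -ln(1 - p). The target:reference concentration ratio cancels the
partition volume, and multiplying by the reference gene's copies per
diploid genome (2 for a standard single-locus autosomal reference) yields
target copies per diploid genome.

The activation model links the per-copy edited fraction q of a reporter
present in n independent copies per cell to the fraction of
reporter-positive cells f = 1 - (1-q)^n; since correction of any single
copy lights the cell up, f >= q, so the percentage of edited alleles is
generally lower than the percentage of positive cells. Independence of
copies within a cell is an assumption (co-delivery of editor correlates
copies in reality); see the methods note.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from statsmodels.stats.proportion import proportion_confint

from .errors import SaturationError

_Z95 = 1.959963984540054


@dataclass(frozen=True)
class PartitionCounts:
    """Accepted-partition totals and per-channel positive counts."""

    n_partitions: int
    n_positive_target: int
    n_positive_reference: int

    def __post_init__(self) -> None:
        if self.n_partitions <= 0:
            raise ValueError("n_partitions must be positive")
        for n in (self.n_positive_target, self.n_positive_reference):
            if not 0 <= n <= self.n_partitions:
                raise ValueError(
                    f"positive count {n} outside 0..{self.n_partitions}"
                )


@dataclass(frozen=True)
class CopyNumberResult:
    """Poisson-corrected target:reference ratio and copies per diploid."""

    lambda_target: float
    lambda_reference: float
    ratio: float
    copies_per_diploid: float
    ci95: tuple[float, float]  # on the ratio
    reference_copies_per_diploid: int = 2

    def summary(self) -> str:
        lo, hi = self.ci95
        return (
            f"lambda(target)    {self.lambda_target:.4f}\n"
            f"lambda(reference) {self.lambda_reference:.4f}\n"
            f"ratio             {self.ratio:.3f} (95% CI {lo:.3f}-{hi:.3f})\n"
            f"copies/diploid    {self.copies_per_diploid:.2f} "
            f"(x{self.reference_copies_per_diploid} reference copies)"
        )


def poisson_lambda(n_positive: int, n_partitions: int) -> float:
    """Mean copies per partition from the positive fraction:
    lambda = -ln(1 - p)."""
    if n_partitions <= 0:
        raise ValueError("n_partitions must be positive")
    if not 0 <= n_positive <= n_partitions:
        raise ValueError("n_positive outside 0..n_partitions")
    if n_positive == n_partitions:
        raise SaturationError(
            "all partitions positive: occupancy unbounded; dilute the sample"
        )
    p = n_positive / n_partitions
    return -math.log1p(-p)


def _lambda_ci(n_positive: int, n_partitions: int) -> tuple[float, float]:
    """Wilson 95% interval on p mapped through the (monotone) Poisson
    correction."""
    lo, hi = proportion_confint(n_positive, n_partitions, method="wilson")
    hi = min(hi, 1.0 - 1.0 / (2 * n_partitions))  # guard against saturation
    return -math.log1p(-lo), -math.log1p(-hi)


def copies_per_genome(
    counts: PartitionCounts, reference_copies_per_diploid: int = 2
) -> CopyNumberResult:
    """Target copies per diploid genome from dual-channel partition counts.

    The ratio of the two Poisson-corrected concentrations is volume-free;
    its 95% CI combines per-channel Wilson intervals on p propagated
    through lambda, delta-method on the log ratio.
    """
    lam_t = poisson_lambda(counts.n_positive_target, counts.n_partitions)
    lam_r = poisson_lambda(counts.n_positive_reference, counts.n_partitions)
    if lam_r == 0:
        raise ValueError("reference channel has no positive partitions")
    ratio = lam_t / lam_r

    lo_t, hi_t = _lambda_ci(counts.n_positive_target, counts.n_partitions)
    lo_r, hi_r = _lambda_ci(counts.n_positive_reference, counts.n_partitions)
    se_t = (hi_t - lo_t) / (2 * _Z95)
    se_r = (hi_r - lo_r) / (2 * _Z95)
    if lam_t > 0:
        se_log = math.sqrt((se_t / lam_t) ** 2 + (se_r / lam_r) ** 2)
        ci = (ratio * math.exp(-_Z95 * se_log), ratio * math.exp(_Z95 * se_log))
    else:
        ci = (0.0, hi_t / lo_r if lo_r > 0 else math.inf)

    return CopyNumberResult(
        lambda_target=lam_t,
        lambda_reference=lam_r,
        ratio=ratio,
        copies_per_diploid=ratio * reference_copies_per_diploid,
        ci95=ci,
        reference_copies_per_diploid=reference_copies_per_diploid,
    )


@dataclass(frozen=True)
class ReporterActivationModel:
    """Reporter with ``n_copies`` independently edited copies per cell."""

    n_copies: int = 6

    def __post_init__(self) -> None:
        if self.n_copies < 1:
            raise ValueError("n_copies must be >= 1")

    def cell_positive_fraction(self, q: float) -> float:
        return cell_positive_fraction(q, self.n_copies)

    def allele_fraction_from_cells(self, f: float) -> float:
        return allele_fraction_from_cells(f, self.n_copies)


def cell_positive_fraction(q: float, n_copies: int) -> float:
    """Fraction of cells with at least one edited copy:
    f = 1 - (1-q)^n."""
    if not 0 <= q <= 1:
        raise ValueError(f"q = {q} outside [0, 1]")
    if n_copies < 1:
        raise ValueError("n_copies must be >= 1")
    if n_copies == 1:  # identity, kept exact in floats
        return float(q)
    if q == 1:
        return 1.0
    return -math.expm1(n_copies * math.log1p(-q))


def allele_fraction_from_cells(f: float, n_copies: int) -> float:
    """Per-copy edited fraction from the positive-cell fraction:
    q = 1 - (1-f)^(1/n); inverse of :func:`cell_positive_fraction`."""
    if not 0 <= f <= 1:
        raise ValueError(f"f = {f} outside [0, 1]")
    if n_copies < 1:
        raise ValueError("n_copies must be >= 1")
    if n_copies == 1:
        return float(f)
    if f == 1:
        return 1.0
    return -math.expm1(math.log1p(-f) / n_copies)


def dose_fold_difference(dose_a: float, dose_b: float) -> tuple[float, int]:
    """Fold difference between two vector-genome doses, with the rounded
    integer fold alongside."""
    if dose_a <= 0 or dose_b <= 0:
        raise ValueError("doses must be positive")
    fold = dose_a / dose_b
    return fold, round(fold)
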