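"""Single-variant genotype sanity statistics: MAF and Hardy-Weinberg tests."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln
from scipy.stats import chi2

logger = logging.getLogger(__name__)

__all__ = [
    "GenotypeCounts",
    "counts_from_dosage",
    "minor_allele_frequency",
    "hwe_test",
]


@dataclass(frozen=True)
class GenotypeCounts:
    """Genotype class counts at a biallelic site; ``a`` is the minor allele."""

    n_AA: int
    n_Aa: int
    n_aa: int

    def __post_init__(self) -> None:
        if min(self.n_AA, self.n_Aa, self.n_aa) < 0:
            raise ValueError("genotype counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.n_AA + self.n_Aa + self.n_aa

    def normalized(self) -> "GenotypeCounts":
        """Swap homozygote labels if the 'minor' allele is actually major."""
        n_minor = self.n_Aa + 2 * self.n_aa
        if self.total and n_minor > self.total:  # frequency > 0.5
            logger.warning("allele labels swapped: minor allele frequency > 0.5")
            return GenotypeCounts(self.n_aa, self.n_Aa, self.n_AA)
        return self


def counts_from_dosage(dosage: np.ndarray) -> GenotypeCounts:
    """Tabulate hard-call genotype classes from a dosage vector by rounding."""
    hard = np.round(np.asarray(dosage, float)).astype(int)
    if np.any((hard < 0) | (hard > 2)):
        raise ValueError("dosage values must round to 0, 1 or 2")
    counts = np.bincount(hard, minlength=3)
    return GenotypeCounts(int(counts[0]), int(counts[1]), int(counts[2]))


def minor_allele_frequency(counts: GenotypeCounts) -> float:
    """Empirical minor allele frequency, in [0, 0.5]."""
    if counts.total < 1:
        raise ValueError("cannot compute MAF of empty counts")
    counts = counts.normalized()
    return (counts.n_Aa + 2 * counts.n_aa) / (2 * counts.total)


def _hwe_chi_square(counts: GenotypeCounts) -> float:
    n = counts.total
    p = 1.0 - minor_allele_frequency(counts)  # major allele
    q = 1.0 - p
    expected = np.array([p * p, 2 * p * q, q * q]) * n
    observed = np.array(
        [counts.n_AA, counts.n_Aa, counts.n_aa], dtype=float
    )
    # guard expected-zero cells (monomorphic handled by caller)
    nz = expected > 0
    stat = float(((observed[nz] - expected[nz]) ** 2 / expected[nz]).sum())
    return float(chi2.sf(stat, df=1))

def _hwe_exact(counts: GenotypeCounts) -> float:
    """Exact Hardy-Weinberg test conditional on the allele counts.

    Sums, over all heterozygote counts compatible with the observed allele
    counts, the probabilities no larger than that of the observed
    heterozygote count (no mid-p adjustment).
    """
    n = counts.total
    n_minor = counts.n_Aa + 2 * counts.n_aa
    n_major = 2 * n - n_minor
    het_obs = counts.n_Aa
    parity = n_minor % 2
    hets = np.arange(parity, min(n_minor, n_major) + 1, 2)
    # log P(het) under the conditional distribution, up to a shared constant
    n_aa = (n_minor - hets) // 2
    n_AA = (n_major - hets) // 2
    logp = (
        hets * np.log(2.0)
        - gammaln(n_aa + 1)
        - gammaln(n_AA + 1)
        - gammaln(hets + 1)
    )
    logp -= logp.max()
    prob = np.exp(logp)
    prob /= prob.sum()
    p_obs = prob[hets == het_obs][0]
    # tolerance for ties under floating point, as in standard implementations
    return float(min(1.0, prob[prob <= p_obs * (1 + 1e-12)].sum()))


def hwe_test(counts: GenotypeCounts, method: str = "exact") -> float:
    """Hardy-Weinberg equilibrium p-value.

    ``method="chi_square"`` runs the 1-df goodness-of-fit test against the
    expected (p^2, 2pq, q^2) class counts; ``method="exact"`` (default, the
    usual QC choice) runs the exact test conditional on allele counts.
    Monomorphic variants return p = 1 by convention.
    """
    if counts.total < 1:
        raise ValueError("cannot test empty counts")
    counts = counts.normalized()
    n_minor = counts.n_Aa + 2 * counts.n_aa
    if n_minor == 0 or n_minor == 2 * counts.total:
        logger.warning("monomorphic variant: HWE p set to 1")
        return 1.0
    if method == "chi_square":
        return _hwe_chi_square(counts)
    if method == "exact":
        return _hwe_exact(counts)
    raise ValueError(f"unknown method {method!r}")
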