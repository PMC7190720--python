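"""Method-of-moments pairwise IBD estimation (Z0, Z1, Z2, PI-HAT).

For each pair of samples the observed identity-by-state (IBS) counts over
shared non-missing loci are combined with the expected IBS distribution given
0, 1 or 2 alleles shared identical by descent (IBD) at cohort allele
frequencies, solving for the IBD mixture by the classic plug-in moments
scheme:

    Z0 = N0 / sum E[IBS0 | IBD0]
    Z1 = (N1 - Z0 * sum E[IBS1 | IBD0]) / sum E[IBS1 | IBD1]
    Z2 = (N2 - Z0 * sum E[IBS2 | IBD0] - Z1 * sum E[IBS2 | IBD1]) / n_loci

Each component is clamped to [0, 1] in Z0 -> Z1 -> Z2 order and the vector
renormalised to sum 1; PI-HAT = Z2 + Z1/2 holds exactly on the final values.
No finite-sample bias correction is applied, and allele frequencies are taken
from the full cohort including the tested pair; at chip-scale locus counts
the sampling error this leaves is well inside the decision tolerances used
downstream.

Reference points: parent-offspring (0, 1, 0), full sibs (0.25, 0.5, 0.25),
half sibs (0.5, 0.5, 0), unrelated (1, 0, 0); PI-HAT ~ 0.5 for first-degree
pairs and ~1 for clones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.exceptions import NotFittedError

from .errors import DataError, TooFewLociError
from .genotype_io import MISSING, SNPGenotypeMatrix

DEFAULT_MIN_LOCI = 100


@dataclass
class IBDResult:
    """Pairwise IBD estimate; Z components sum to 1, PI_HAT = Z2 + Z1/2."""

    pair: tuple[str, str]
    Z0: float
    Z1: float
    Z2: float
    PI_HAT: float
    n_loci: int

    def z(self) -> tuple[float, float, float]:
        return (self.Z0, self.Z1, self.Z2)


def ibs_state(code1: int, code2: int) -> int:
    """IBS state of two genotype codes: 2 equal, 0 opposite homozygotes, else 1."""
    if code1 == MISSING or code2 == MISSING:
        raise DataError("ibs_state requires non-missing genotypes")
    return 2 - abs(int(code1) - int(code2))


def expected_ibs_given_ibd(p: float) -> np.ndarray:
    """3x3 table E[IBS=j | IBD=i] at alt-allele frequency p (rows sum to 1)."""
    if not 0.0 < p < 1.0:
        raise DataError(f"allele frequency must be in (0, 1), got {p}")
    q = 1.0 - p
    return np.array(
        [
            [2 * p**2 * q**2, 4 * p**3 * q + 4 * p * q**3, p**4 + q**4 + 4 * p**2 * q**2],
            [0.0, 2 * p**2 * q + 2 * p * q**2, p**3 + q**3 + p * q],
            [0.0, 0.0, 1.0],
        ]
    )


def _moments(g1: np.ndarray, g2: np.ndarray, p: np.ndarray, min_loci: int):
    """Core estimator on raw code vectors with per-locus alt frequencies."""
    informative = (g1 != MISSING) & (g2 != MISSING) & (p > 0.0) & (p < 1.0)
    L = int(informative.sum())
    if L < min_loci:
        raise TooFewLociError(
            f"only {L} shared informative loci (< {min_loci} required)"
        )
    a = g1[informative].astype(np.int64)
    b = g2[informative].astype(np.int64)
    pp = p[informative]
    qq = 1.0 - pp

    ibs = 2 - np.abs(a - b)
    N = np.bincount(ibs, minlength=3).astype(float)

    s00 = float(np.sum(2 * pp**2 * qq**2))
    s01 = float(np.sum(4 * pp**3 * qq + 4 * pp * qq**3))
    s02 = float(np.sum(pp**4 + qq**4 + 4 * pp**2 * qq**2))
    s11 = float(np.sum(2 * pp**2 * qq + 2 * pp * qq**2))
    s12 = float(np.sum(pp**3 + qq**3 + pp * qq))

    z0 = N[0] / s00
    z0 = min(max(z0, 0.0), 1.0)
    z1 = (N[1] - z0 * s01) / s11
    z1 = min(max(z1, 0.0), 1.0)
    z2 = (N[2] - z0 * s02 - z1 * s12) / L
    z2 = min(max(z2, 0.0), 1.0)
    total = z0 + z1 + z2
    if total == 0.0:  # cannot occur for non-degenerate input; guard anyway
        z0 = 1.0
        total = 1.0
    z0, z1, z2 = z0 / total, z1 / total, z2 / total
    return z0, z1, z2, L


class IBDMomentsEstimator(BaseEstimator):
    """Cohort-frequency moments IBD estimator.

    fit(X) stores per-locus alt-allele frequencies from the cohort (loci that
    are monomorphic in the cohort carry no IBS information and are excluded).
    estimate() / pairwise() then produce :class:`IBDResult` objects.
    """

    def __init__(self, min_loci: int = DEFAULT_MIN_LOCI):
        self.min_loci = min_loci

    def fit(self, X: SNPGenotypeMatrix, y=None):
        freqs = X.alt_freq()
        self.allele_freqs_ = np.where(np.isnan(freqs), 0.0, freqs)
        self.matrix_ = X
        return self

    def _check_fitted(self):
        if not hasattr(self, "allele_freqs_"):
            raise NotFittedError("IBDMomentsEstimator is not fitted")

    def estimate(self, id1: str, id2: str) -> IBDResult:
        self._check_fitted()
        g1 = self.matrix_.row(id1)
        g2 = self.matrix_.row(id2)
        z0, z1, z2, L = _moments(g1, g2, self.allele_freqs_, self.min_loci)
        return IBDResult((id1, id2), z0, z1, z2, z2 + 0.5 * z1, L)

    def pairwise(self) -> list[IBDResult]:
        """All unordered pairs, in lexicographic sample-id order."""
        self._check_fitted()
        ids = sorted(self.matrix_.sample_ids)
        return [
            self.estimate(a, b)
            for i, a in enumerate(ids)
            for b in ids[i + 1:]
        ]


def estimate_ibd(
    matrix: SNPGenotypeMatrix,
    pair: tuple[str, str],
    freqs: np.ndarray | None = None,
    min_loci: int = DEFAULT_MIN_LOCI,
) -> IBDResult:
    """Moments IBD estimate for one pair.

    ``freqs`` defaults to the per-locus alt frequency of the whole cohort in
    ``matrix`` (the tested pair included).
    """
    est = IBDMomentsEstimator(min_loci=min_loci).fit(matrix)
    if freqs is not None:
        est.allele_freqs_ = np.asarray(freqs, dtype=float)
    return est.estimate(*pair)


def pairwise_ibd(
    matrix: SNPGenotypeMatrix, min_loci: int = DEFAULT_MIN_LOCI
) -> list[IBDResult]:
    """IBD estimates for all unordered sample pairs (deterministic order)."""
    return IBDMomentsEstimator(min_loci=min_loci).fit(matrix).pairwise()


def ibd_table(results: list[IBDResult]) -> pd.DataFrame:
    """Results as a table with the canonical column layout."""
    return pd.DataFrame(
        [
            {
                "sample_1": r.pair[0],
                "sample_2": r.pair[1],
                "Z0": r.Z0,
                "Z1": r.Z1,
                "Z2": r.Z2,
                "PI_HAT": r.PI_HAT,
                "n_loci": r.n_loci,
            }
            for r in results
        ]
    )
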