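"""SNP panel curation: quality filtering and a four-class reliability map.

The quality filter applies the array-QC thresholds used for germplasm SNP
panels: minor-allele frequency strictly above 0.05, missing-call fraction
strictly below 0.05 and, where a per-locus call-quality score exists,
quality strictly above 0.54. Strict inequalities are deliberate: a locus
sitting exactly on a boundary is rejected.

The reliability classifier re-derives, from genotype counts alone, the four
marker classes used to stratify Mendelian inconsistencies:

* ``ROBUST`` — both homozygote classes common, Hardy-Weinberg compatible;
* ``ONE_HOM_RARE_HWE`` / ``ONE_HOM_RARE_NOT_HWE`` — one homozygote class
  nearly absent, split by the HWE exact test;
* ``DISTORTED`` — segregation distortion, typically a heterozygote deficit
  as produced by a null (non-amplifying) allele inflating apparent
  homozygosity;
* ``DISCARDED`` — call rate too low on the classification cohort.

This is a deliberate approximation of cluster-level SNP scoring tools, which
operate on raw intensity data unavailable downstream of genotype calling;
class assignment here is a pure function of (n_AA, n_AB, n_BB).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.exceptions import NotFittedError

from .errors import DataError
from .genotype_io import SNPGenotypeMatrix


class SNPClass(str, Enum):
    ROBUST = "ROBUST"
    ONE_HOM_RARE_HWE = "ONE_HOM_RARE_HWE"
    ONE_HOM_RARE_NOT_HWE = "ONE_HOM_RARE_NOT_HWE"
    DISTORTED = "DISTORTED"
    DISCARDED = "DISCARDED"


#: Classes whose Mendelian inconsistencies are trusted (merged reporting class).
MERGED_CLASSES = (SNPClass.ROBUST, SNPClass.ONE_HOM_RARE_HWE, SNPClass.ONE_HOM_RARE_NOT_HWE)


@dataclass
class QCThresholds:
    """Panel QC thresholds (all strict inequalities)."""

    maf_min: float = 0.05
    missing_max: float = 0.05
    quality_min: float = 0.54

    def __post_init__(self):
        for f in ("maf_min", "missing_max", "quality_min"):
            v = getattr(self, f)
            if not 0.0 <= v <= 1.0:
                raise DataError(f"{f} must be in [0, 1], got {v}")


class SNPQualityFilter(BaseEstimator):
    """Per-locus QC transformer.

    fit() computes per-locus MAF, missing fraction and quality; transform()
    drops loci failing any criterion. Criteria are checked in the order MAF,
    missing, quality and the rejection log records the first that failed.

    Attributes (after fit): ``support_`` (bool mask of retained loci),
    ``rejection_log_`` (DataFrame: locus, maf, missing, quality, reason).
    """

    def __init__(self, maf_min: float = 0.05, missing_max: float = 0.05,
                 quality_min: float = 0.54):
        self.maf_min = maf_min
        self.missing_max = missing_max
        self.quality_min = quality_min

    def fit(self, X: SNPGenotypeMatrix, y=None):
        if X.n_loci == 0 or X.n_samples == 0:
            raise DataError("cannot fit SNPQualityFilter on an empty matrix")
        maf = X.maf()
        miss = X.missing_fraction()
        qual = X.quality
        reasons = np.array([""] * X.n_loci, dtype=object)
        # monomorphic / all-missing loci have MAF NaN -> fails the MAF rule
        fail_maf = ~(maf > self.maf_min)
        fail_miss = ~(miss < self.missing_max)
        reasons[fail_miss] = "missing"
        reasons[fail_maf] = "maf"  # MAF checked first, so it wins the log
        keep = ~fail_maf & ~fail_miss
        if qual is not None:
            fail_q = ~(qual > self.quality_min)
            reasons[keep & fail_q] = "quality"
            keep &= ~fail_q
        self.maf_ = maf
        self.missing_ = miss
        self.support_ = keep
        self.rejection_log_ = pd.DataFrame(
            {
                "locus": X.locus_ids,
                "maf": maf,
                "missing": miss,
                "quality": qual if qual is not None else np.nan,
                "retained": keep,
                "reason": reasons,
            }
        )
        return self

    def get_support(self) -> np.ndarray:
        self._check_fitted()
        return self.support_

    def transform(self, X: SNPGenotypeMatrix) -> SNPGenotypeMatrix:
        self._check_fitted()
        if X.n_loci != len(self.support_):
            raise DataError("matrix locus count differs from the fitted panel")
        if not self.support_.any():
            import warnings

            warnings.warn("all loci rejected by QC; returning an empty matrix")
        return X.subset_loci(self.support_)

    def fit_transform(self, X: SNPGenotypeMatrix, y=None) -> SNPGenotypeMatrix:
        return self.fit(X).transform(X)

    def _check_fitted(self):
        if not hasattr(self, "support_"):
            raise NotFittedError("SNPQualityFilter is not fitted")


def filter_snps(
    matrix: SNPGenotypeMatrix, thresholds: QCThresholds | None = None
) -> tuple[SNPGenotypeMatrix, pd.DataFrame]:
    """Apply panel QC; returns (filtered matrix, per-locus rejection log)."""
    t = thresholds or QCThresholds()
    f = SNPQualityFilter(t.maf_min, t.missing_max, t.quality_min).fit(matrix)
    return f.transform(matrix), f.rejection_log_


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def hwe_exact_test(n_AA: int, n_AB: int, n_BB: int) -> float:
    """Exact conditional Hardy-Weinberg test, two-sided on the het count.

    Probability of each heterozygote count compatible with the observed
    allele counts is computed by the standard recurrence; the p-value sums
    the probabilities of all configurations no more likely than the observed
    one. Returns a value in (0, 1].
    """
    if min(n_AA, n_AB, n_BB) < 0:
        raise DataError("negative genotype count")
    n = n_AA + n_AB + n_BB
    if n == 0:
        raise DataError("all-zero genotype counts")
    n_a = 2 * n_AA + n_AB
    rare = min(n_a, 2 * n - n_a)
    # het counts share the parity of the rare allele count
    het_counts = np.arange(rare % 2, rare + 1, 2)
    probs = np.zeros(len(het_counts))
    # start at the mode-ish midpoint and fill outward by recurrence
    mid = int(rare * (2 * n - rare) / (2 * n))
    if mid % 2 != rare % 2:
        mid += 1
    i_mid = (mid - rare % 2) // 2
    probs[i_mid] = 1.0
    # going down in het count: P(h-2)/P(h) = h(h-1) / (4 * nAA(h-2)+... )
    for i in range(i_mid, 0, -1):
        h = het_counts[i]
        hom_r = (rare - h) // 2       # rare homozygotes at het count h
        hom_c = n - h - hom_r
        probs[i - 1] = probs[i] * h * (h - 1) / (4.0 * (hom_r + 1) * (hom_c + 1))
    for i in range(i_mid, len(het_counts) - 1):
        h = het_counts[i]
        hom_r = (rare - h) // 2
        hom_c = n - h - hom_r
        probs[i + 1] = probs[i] * 4.0 * hom_r * hom_c / ((h + 1.0) * (h + 2.0))
    probs /= probs.sum()
    p_obs = probs[(n_AB - rare % 2) // 2]
    p = probs[probs <= p_obs * (1 + 1e-12)].sum()
    return float(min(p, 1.0))


# ---------------------------------------------------------------------------
# four-class reliability map
# ---------------------------------------------------------------------------

def classify_snp(
    n_AA: int, n_AB: int, n_BB: int,
    rare_hom_max: float = 0.01, hwe_alpha: float = 0.01,
) -> SNPClass:
    """Assign a reliability class from genotype counts.

    A homozygote class with frequency strictly below ``rare_hom_max`` marks a
    one-homozygote-rare marker, split into HWE / not-HWE by the exact test at
    ``hwe_alpha``. Otherwise HWE failure marks the locus DISTORTED (the
    het-deficit direction is the classic null-allele AB x AO signature; both
    directions are treated as unreliable). Everything else is ROBUST.
    """
    n = n_AA + n_AB + n_BB
    if n == 0:
        raise DataError("all-zero genotype counts")
    p = hwe_exact_test(n_AA, n_AB, n_BB)
    f_hom_min = min(n_AA, n_BB) / n
    if f_hom_min < rare_hom_max:
        return SNPClass.ONE_HOM_RARE_HWE if p >= hwe_alpha else SNPClass.ONE_HOM_RARE_NOT_HWE
    if p < hwe_alpha:
        return SNPClass.DISTORTED
    return SNPClass.ROBUST


class SNPReliabilityClassifier(BaseEstimator):
    """Panel-level reliability classifier.

    fit(X, cohort=...) classifies every locus of X from genotype counts taken
    on the classification cohort (defaults to X itself; a larger cohort gives
    more stable counts than the analysis panel alone). Loci whose cohort
    missing fraction is >= ``missing_max`` are DISCARDED. Per-locus call
    quality plays no role here; it belongs to :class:`SNPQualityFilter`.

    Attributes: ``class_map_`` — dict locus name -> SNPClass.
    """

    def __init__(self, rare_hom_max: float = 0.01, hwe_alpha: float = 0.01,
                 missing_max: float = 0.05):
        self.rare_hom_max = rare_hom_max
        self.hwe_alpha = hwe_alpha
        self.missing_max = missing_max

    def fit(self, X: SNPGenotypeMatrix, cohort: SNPGenotypeMatrix | None = None):
        cohort = X if cohort is None else cohort
        if cohort.locus_ids != X.locus_ids:
            cohort = cohort.subset_loci(X.locus_ids)
        n_aa, n_ab, n_bb = cohort.genotype_counts()
        miss = cohort.missing_fraction()
        class_map = {}
        for j, name in enumerate(X.locus_ids):
            if miss[j] >= self.missing_max or (n_aa[j] + n_ab[j] + n_bb[j]) == 0:
                class_map[name] = SNPClass.DISCARDED
            else:
                class_map[name] = classify_snp(
                    int(n_aa[j]), int(n_ab[j]), int(n_bb[j]),
                    self.rare_hom_max, self.hwe_alpha,
                )
        self.class_map_ = class_map
        return self

    def to_frame(self) -> pd.DataFrame:
        if not hasattr(self, "class_map_"):
            raise NotFittedError("SNPReliabilityClassifier is not fitted")
        return pd.DataFrame(
            {"locus": list(self.class_map_), "snp_class": [c.value for c in self.class_map_.values()]}
        )


def classify_panel(
    matrix: SNPGenotypeMatrix,
    cohort: SNPGenotypeMatrix | None = None,
    rare_hom_max: float = 0.01,
    hwe_alpha: float = 0.01,
    missing_max: float = 0.05,
) -> dict[str, SNPClass]:
    """Classify every locus of ``matrix``; see SNPReliabilityClassifier."""
    clf = SNPReliabilityClassifier(rare_hom_max, hwe_alpha, missing_max)
    return clf.fit(matrix, cohort=cohort).class_map_
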