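"""Mendelian-inconsistency (MI) engines for duos and trios.

SNP duos: the only observable conflict between a putative parent-offspring
pair at a biallelic locus is opposite homozygosity (codes 0 vs 2);
heterozygotes can never be inconsistent in a duo. SNP trios: a child
genotype is inconsistent when it cannot arise from one allele of each
proposed parent. SSR duos/trios use allele sharing / bipartite allele-origin
assignment on the multiallelic fragment-size pairs.

MI rates are reported with the retained-panel locus count as the default
denominator: published reference rates back-compute that way (25 conflicts
over an 11,929-locus panel gives the 0.0021 reference rate), while the
per-compared-loci rate is kept alongside as ``error_rate`` (the
parent-parent-child error-rate analogue).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError
from .genotype_io import MISSING, SNPGenotypeMatrix, SSRProfile
from .snp_curation import MERGED_CLASSES, SNPClass


@dataclass
class MendelResult:
    """MI accounting for one duo or trio."""

    unit: tuple[str, ...]
    kind: str                      # "duo" | "trio"
    mi_total: int
    n_compared: int                # loci non-missing in every member
    n_panel: int                   # retained loci in the panel (rate denominator)
    mi_loci: list[str] = field(default_factory=list)
    per_class: dict[SNPClass, int] | None = None
    mi_merged: int | None = None
    mi_pruned_total: int | None = None
    reduction_pct: float | None = None

    @property
    def mi_rate(self) -> float:
        """MI per retained panel locus (the published-rate convention)."""
        return self.mi_total / self.n_panel

    @property
    def error_rate(self) -> float:
        """MI per compared locus (trio P-P-C error-rate analogue)."""
        return self.mi_total / self.n_compared


def duo_mi_snp(matrix: SNPGenotypeMatrix, id1: str, id2: str) -> MendelResult:
    """Opposite-homozygote conflicts between two samples over shared loci."""
    g1, g2 = matrix.row(id1), matrix.row(id2)
    both = (g1 != MISSING) & (g2 != MISSING)
    if not both.any():
        raise DataError(f"zero comparable loci for duo ({id1}, {id2})")
    conflict = both & (np.abs(g1 - g2) == 2)
    names = [matrix.locus_ids[j] for j in np.flatnonzero(conflict)]
    return MendelResult(
        unit=(id1, id2), kind="duo",
        mi_total=int(conflict.sum()), n_compared=int(both.sum()),
        n_panel=matrix.n_loci, mi_loci=names,
    )


def _trio_conflict(child: np.ndarray, p1: np.ndarray, p2: np.ndarray) -> np.ndarray:
    """Vectorised impossibility of child given both parents (biallelic)."""
    return (
        ((child == 0) & ((p1 == 2) | (p2 == 2)))
        | ((child == 2) & ((p1 == 0) | (p2 == 0)))
        | ((child == 1) & (((p1 == 0) & (p2 == 0)) | ((p1 == 2) & (p2 == 2))))
    )


def trio_mi_snp(
    matrix: SNPGenotypeMatrix, child: str, parent1: str, parent2: str
) -> MendelResult:
    """Mendelian-transmission conflicts for a parent-parent-child triple."""
    gc = matrix.row(child)
    g1 = matrix.row(parent1)
    g2 = matrix.row(parent2)
    all3 = (gc != MISSING) & (g1 != MISSING) & (g2 != MISSING)
    if not all3.any():
        raise DataError(f"zero comparable loci for trio ({child}, {parent1}, {parent2})")
    conflict = all3 & _trio_conflict(gc, g1, g2)
    names = [matrix.locus_ids[j] for j in np.flatnonzero(conflict)]
    return MendelResult(
        unit=(child, parent1, parent2), kind="trio",
        mi_total=int(conflict.sum()), n_compared=int(all3.sum()),
        n_panel=matrix.n_loci, mi_loci=names,
    )


# ---------------------------------------------------------------------------
# SSR exclusion checks
# ---------------------------------------------------------------------------

def duo_compatible_ssr(
    profile1: SSRProfile, profile2: SSRProfile, max_mismatch: int = 1
) -> tuple[bool, list[str]]:
    """Parent-offspring compatibility on multiallelic SSRs.

    A locus mismatches when the two genotypes share no allele; loci missing
    in either profile are skipped. Compatible iff mismatches <= max_mismatch.
    """
    mismatches = []
    for locus, pair1 in profile1.genotypes.items():
        pair2 = profile2.genotypes.get(locus)
        if pair1 is None or pair2 is None:
            continue
        if not set(pair1) & set(pair2):
            mismatches.append(locus)
    return len(mismatches) <= max_mismatch, mismatches


def trio_compatible_ssr(
    child: SSRProfile, parent1: SSRProfile, parent2: SSRProfile,
    max_mismatch: int = 1,
) -> tuple[bool, list[str]]:
    """Trio compatibility: child's pair must take one allele from each parent.

    The bipartite assignment check covers homozygote double-counting: a
    homozygous child needs its allele present in *both* parents.
    """
    mismatches = []
    for locus, cg in child.genotypes.items():
        g1 = parent1.genotypes.get(locus)
        g2 = parent2.genotypes.get(locus)
        if cg is None or g1 is None or g2 is None:
            continue
        a, b = cg
        ok = (a in g1 and b in g2) or (b in g1 and a in g2)
        if not ok:
            mismatches.append(locus)
    return len(mismatches) <= max_mismatch, mismatches


# ---------------------------------------------------------------------------
# per-class MI stratification
# ---------------------------------------------------------------------------

def mi_reduction_pct(mi_full: int, mi_pruned: int) -> float:
    """Percentage of total MI removed by panel pruning, one decimal."""
    if mi_full == 0:
        return 0.0
    return round((mi_full - mi_pruned) / mi_full * 100.0, 1)


def stratify_mi(result: MendelResult, class_map: dict[str, SNPClass]) -> MendelResult:
    """Split a unit's MI by SNP reliability class.

    Per-class counts run over the class-map loci only (DISCARDED excluded);
    ``mi_merged`` merges the trusted classes (ROBUST plus both
    one-homozygote-rare classes); ``reduction_pct`` is the share of the
    full-panel MI removed by restriction to the pruned panel.
    """
    pruned = {l for l, c in class_map.items() if c != SNPClass.DISCARDED}
    per_class: dict[SNPClass, int] = {c: 0 for c in SNPClass if c != SNPClass.DISCARDED}
    mi_pruned = 0
    for locus in result.mi_loci:
        c = class_map.get(locus)
        if c is None or c == SNPClass.DISCARDED or locus not in pruned:
            continue
        per_class[c] += 1
        mi_pruned += 1
    merged = sum(per_class[c] for c in MERGED_CLASSES)
    out = MendelResult(
        unit=result.unit, kind=result.kind,
        mi_total=result.mi_total, n_compared=result.n_compared,
        n_panel=result.n_panel, mi_loci=list(result.mi_loci),
        per_class=per_class, mi_merged=merged,
        mi_pruned_total=mi_pruned,
        reduction_pct=mi_reduction_pct(result.mi_total, mi_pruned),
    )
    return out


def mendel_table(results: list[MendelResult]) -> pd.DataFrame:
    """MI results as a table mirroring the published duo/trio layouts."""
    rows = []
    for r in results:
        row = {
            "unit": "|".join(r.unit),
            "kind": r.kind,
            "mi_total": r.mi_total,
            "n_compared": r.n_compared,
            "n_panel": r.n_panel,
            "mi_rate": r.mi_rate,
            "error_rate": r.error_rate,
        }
        if r.per_class is not None:
            row.update(
                mi_pruned_total=r.mi_pruned_total,
                mi_robust=r.per_class[SNPClass.ROBUST],
                mi_distorted=r.per_class[SNPClass.DISTORTED],
                mi_one_hom_rare=(
                    r.per_class[SNPClass.ONE_HOM_RARE_HWE]
                    + r.per_class[SNPClass.ONE_HOM_RARE_NOT_HWE]
                ),
                mi_merged=r.mi_merged,
                reduction_pct=r.reduction_pct,
            )
        rows.append(row)
    return pd.DataFrame(rows)
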