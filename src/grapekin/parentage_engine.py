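"""Candidate parentage search and reference-calibrated verdicts.

The two-step scheme mirrors standard germplasm practice: a cheap multiallelic
SSR exclusion search proposes candidate duos and trios, then chip-scale SNP
metrics (moments IBD and Mendelian-inconsistency rates) confirm or reject
them against thresholds *calibrated on reference relationships* — known trios
and duos present in the panel. Calibration takes the lowest reference Z1 and
the highest reference MI rate; a candidate is

* SUPPORTED when its Z1 is at least the reference minimum, its PI-HAT sits in
  the first-degree window and its MI rate is at most ``accept_factor`` times
  the reference maximum;
* REJECTED when its MI rate reaches ``reject_factor`` times the reference
  maximum or its Z1 falls more than 0.1 below the reference minimum;
* POSSIBLE otherwise (the conflicted middle tier).

Pairs with PI-HAT above the clone threshold are routed to clone/synonym
reporting and never judged as parentage. Chlorotype (maternal) consistency
annotates trios — a conflict is flagged, never auto-rejected, because cpSSR
homoplasy and sampling slips are plausible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence

from sklearn.base import BaseEstimator
from sklearn.exceptions import NotFittedError

from .errors import CalibrationError, DataError
from .genotype_io import ChlorotypeTable, SNPGenotypeMatrix, SSRProfile
from .ibd_moments import IBDResult
from .mendel_check import (
    MendelResult,
    duo_compatible_ssr,
    trio_compatible_ssr,
    trio_mi_snp,
)

DEFAULT_PI_HAT_WINDOW = (0.45, 0.56)
DEFAULT_CLONE_PI = 0.9
Z1_REJECT_MARGIN = 0.1


class Verdict(str, Enum):
    SUPPORTED = "SUPPORTED"
    POSSIBLE = "POSSIBLE"
    REJECTED = "REJECTED"


@dataclass
class ThresholdSet:
    """Decision thresholds, calibrated from reference relationships."""

    z1_min: float
    mi_rate_ref_max: float
    trio_rate_ref_max: float | None = None
    pi_hat_window: tuple[float, float] = DEFAULT_PI_HAT_WINDOW
    accept_factor: float = 1.1
    reject_factor: float = 2.0
    trio_possible_factor: float = 1.3

    def __post_init__(self):
        if not self.accept_factor < self.reject_factor:
            raise DataError("accept_factor must be < reject_factor")
        lo, hi = self.pi_hat_window
        if not lo <= 0.5 <= hi:
            raise DataError("pi_hat_window must contain 0.5")


@dataclass
class RelationshipVerdict:
    """Classified duo or trio with its evidence attached."""

    unit: tuple[str, ...]
    status: Verdict
    ibd: IBDResult | tuple[IBDResult, IBDResult] | None
    mendel: MendelResult
    maternal_candidate: str | None = None
    reasons: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

def _pair_key(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


def calibrate(
    reference_units: Sequence[tuple[str, ...]],
    ibd_results: Mapping[tuple[str, str], IBDResult],
    mendel_results: Mapping[tuple[str, ...], MendelResult],
    pi_hat_window: tuple[float, float] = DEFAULT_PI_HAT_WINDOW,
    accept_factor: float = 1.1,
    reject_factor: float = 2.0,
    trio_possible_factor: float = 1.3,
) -> ThresholdSet:
    """Derive decision thresholds from reference trios/duos.

    ``reference_units`` are 2-tuples (parent, offspring) and/or 3-tuples
    (child, parent1, parent2). ``ibd_results`` is keyed by sorted pair;
    ``mendel_results`` by the unit tuple (duos as sorted pairs). Trio units
    contribute both child-parent IBD legs to the Z1 floor, their duo legs to
    the MI-rate ceiling (when present) and their trio error rate to the trio
    ceiling.
    """
    if not reference_units:
        raise CalibrationError(
            "no reference relationships: provide reference units or explicit "
            "manual thresholds"
        )
    z1s: list[float] = []
    duo_rates: list[float] = []
    trio_rates: list[float] = []
    for unit in reference_units:
        if len(unit) == 2:
            key = _pair_key(*unit)
            z1s.append(ibd_results[key].Z1)
            duo_rates.append(mendel_results[key].mi_rate)
        elif len(unit) == 3:
            child, p1, p2 = unit
            for parent in (p1, p2):
                key = _pair_key(child, parent)
                z1s.append(ibd_results[key].Z1)
                if key in mendel_results:
                    duo_rates.append(mendel_results[key].mi_rate)
            if unit in mendel_results:
                trio_rates.append(mendel_results[unit].error_rate)
        else:
            raise DataError(f"reference unit must be a duo or trio, got {unit}")
    return ThresholdSet(
        z1_min=min(z1s),
        mi_rate_ref_max=max(duo_rates) if duo_rates else 0.0,
        trio_rate_ref_max=max(trio_rates) if trio_rates else None,
        pi_hat_window=pi_hat_window,
        accept_factor=accept_factor,
        reject_factor=reject_factor,
        trio_possible_factor=trio_possible_factor,
    )


# ---------------------------------------------------------------------------
# verdicts
# ---------------------------------------------------------------------------

def classify_duo(
    ibd: IBDResult, mendel: MendelResult, thresholds: ThresholdSet
) -> RelationshipVerdict:
    """Accept/reject a candidate parent-offspring pair."""
    t = thresholds
    lo, hi = t.pi_hat_window
    reasons = []
    supported = (
        ibd.Z1 >= t.z1_min
        and lo <= ibd.PI_HAT <= hi
        and mendel.mi_rate <= t.accept_factor * t.mi_rate_ref_max
    )
    if supported:
        status = Verdict.SUPPORTED
    else:
        # rejection rules; the MI rule only fires on a nonzero rate so that a
        # zero-MI reference set does not reject clean candidates outright
        if mendel.mi_rate >= t.reject_factor * t.mi_rate_ref_max and mendel.mi_rate > 0:
            reasons.append(
                f"mi_rate {mendel.mi_rate:.4f} >= {t.reject_factor} x reference max "
                f"{t.mi_rate_ref_max:.4f}"
            )
        if ibd.Z1 < t.z1_min - Z1_REJECT_MARGIN:
            reasons.append(f"Z1 {ibd.Z1:.4f} below reference minimum {t.z1_min:.4f} by > {Z1_REJECT_MARGIN}")
        status = Verdict.REJECTED if reasons else Verdict.POSSIBLE
    verdict = RelationshipVerdict((ibd.pair[0], ibd.pair[1]), status, ibd, mendel, reasons=reasons)
    assert not (
        verdict.status == Verdict.SUPPORTED and not lo <= ibd.PI_HAT <= hi
    ), "SUPPORTED verdict with PI_HAT outside the window"
    return verdict


def classify_trio(
    trio_mendel: MendelResult,
    duo_verdicts: tuple[RelationshipVerdict, RelationshipVerdict],
    ibd_legs: tuple[IBDResult, IBDResult],
    thresholds: ThresholdSet,
) -> RelationshipVerdict:
    """Accept/reject a candidate parent-parent-child triple.

    The trio metric is the per-compared-locus error rate, measured against the
    reference trio ceiling; both child-parent legs must not be REJECTED for a
    SUPPORTED call.
    """
    t = thresholds
    ref = t.trio_rate_ref_max if t.trio_rate_ref_max is not None else 0.0
    rate = trio_mendel.error_rate
    legs_ok = all(v.status != Verdict.REJECTED for v in duo_verdicts)
    reasons = []
    if rate <= t.accept_factor * ref and legs_ok:
        status = Verdict.SUPPORTED
    elif rate <= t.trio_possible_factor * ref and legs_ok:
        status = Verdict.POSSIBLE
        reasons.append(
            f"trio error rate {rate:.5f} above reference max {ref:.5f} "
            f"but within {t.trio_possible_factor}x"
        )
    else:
        status = Verdict.REJECTED
        if not legs_ok:
            reasons.append("a child-parent leg was rejected")
        if rate > t.trio_possible_factor * ref:
            reasons.append(f"trio error rate {rate:.5f} > {t.trio_possible_factor} x reference {ref:.5f}")
    return RelationshipVerdict(trio_mendel.unit, status, ibd_legs, trio_mendel, reasons=reasons)


# ---------------------------------------------------------------------------
# candidate search
# ---------------------------------------------------------------------------

@dataclass
class DuoCandidate:
    candidate_id: str
    n_mismatch: int
    mismatch_loci: list[str]
    mi_rate: float | None = None
    is_clone: bool = False


@dataclass
class TrioCandidate:
    parent1: str
    parent2: str
    ssr_mismatches: list[str]
    trio_mendel: MendelResult | None = None
    ibd_legs: tuple[IBDResult, IBDResult] | None = None


def search_duos(
    target: str,
    ssr_profiles: Mapping[str, SSRProfile],
    ssr_max_mismatch: int = 1,
    ibd_lookup: Mapping[tuple[str, str], IBDResult] | None = None,
    mendel_lookup: Mapping[tuple[str, str], MendelResult] | None = None,
    clone_pi: float = DEFAULT_CLONE_PI,
) -> list[DuoCandidate]:
    """SSR exclusion search for parent-offspring candidates of ``target``.

    Every database sample duo-compatible with the target within
    ``ssr_max_mismatch`` mismatching loci is returned, ranked by mismatch
    count then SNP MI rate (when available) then id. Samples whose PI-HAT
    with the target exceeds ``clone_pi`` are flagged as clones, not duos.
    """
    if target not in ssr_profiles:
        raise DataError(f"unknown target sample {target!r}")
    query = ssr_profiles[target]
    out = []
    for sid, prof in ssr_profiles.items():
        if sid == target:
            continue
        ok, mismatches = duo_compatible_ssr(query, prof, ssr_max_mismatch)
        if not ok:
            continue
        cand = DuoCandidate(sid, len(mismatches), mismatches)
        key = _pair_key(target, sid)
        if ibd_lookup is not None and key in ibd_lookup:
            if ibd_lookup[key].PI_HAT > clone_pi:
                cand.is_clone = True
        if mendel_lookup is not None and key in mendel_lookup:
            cand.mi_rate = mendel_lookup[key].mi_rate
        out.append(cand)
    out.sort(
        key=lambda c: (c.n_mismatch, c.mi_rate if c.mi_rate is not None else 0.0, c.candidate_id)
    )
    return out


def search_trios(
    target: str,
    ssr_profiles: Mapping[str, SSRProfile],
    matrix: SNPGenotypeMatrix | None = None,
    ibd_lookup: Mapping[tuple[str, str], IBDResult] | None = None,
    ssr_max_mismatch: int = 1,
    clone_pi: float = DEFAULT_CLONE_PI,
) -> list[TrioCandidate]:
    """All unordered pairs of duo-compatible candidates passing the joint trio
    SSR check, each scored with trio MI (when a SNP matrix is given) and both
    child-parent IBD legs."""
    duos = [
        c for c in search_duos(
            target, ssr_profiles, ssr_max_mismatch, ibd_lookup, clone_pi=clone_pi
        )
        if not c.is_clone
    ]
    child = ssr_profiles[target]
    trios = []
    for i, c1 in enumerate(duos):
        for c2 in duos[i + 1:]:
            ok, mismatches = trio_compatible_ssr(
                child, ssr_profiles[c1.candidate_id], ssr_profiles[c2.candidate_id],
                ssr_max_mismatch,
            )
            if not ok:
                continue
            cand = TrioCandidate(c1.candidate_id, c2.candidate_id, mismatches)
            if matrix is not None:
                cand.trio_mendel = trio_mi_snp(matrix, target, c1.candidate_id, c2.candidate_id)
            if ibd_lookup is not None:
                cand.ibd_legs = (
                    ibd_lookup[_pair_key(target, c1.candidate_id)],
                    ibd_lookup[_pair_key(target, c2.candidate_id)],
                )
            trios.append(cand)
    return trios


# ---------------------------------------------------------------------------
# chlorotype (maternal) consistency
# ---------------------------------------------------------------------------

def maternal_consistency(
    trio: tuple[str, str, str], chlorotypes: ChlorotypeTable
) -> str:
    """Identify the maternal parent of a trio from chlorotype labels.

    Returns the maternal candidate's sample id, "undetermined" (child matches
    both parents, or labels missing) or "conflict" (child matches neither).
    A conflict is an annotation only — never an automatic rejection.
    """
    child, p1, p2 = trio
    lc = chlorotypes.label(child)
    l1 = chlorotypes.label(p1)
    l2 = chlorotypes.label(p2)
    if lc is None or (l1 is None and l2 is None):
        return "undetermined"
    m1 = l1 == lc
    m2 = l2 == lc
    if m1 and m2:
        return "undetermined"
    if m1:
        return p1
    if m2:
        return p2
    return "conflict"


# ---------------------------------------------------------------------------
# sklearn-style front end
# ---------------------------------------------------------------------------

class ParentageClassifier(BaseEstimator):
    """Reference-calibrated duo/trio classifier.

    fit() consumes reference units with their IBD and MI evidence and learns
    the :class:`ThresholdSet` (``thresholds_``); predict_duo()/predict_trio()
    classify candidates. Verdicts are deterministic given data + thresholds.
    """

    def __init__(self, accept_factor: float = 1.1, reject_factor: float = 2.0,
                 trio_possible_factor: float = 1.3,
                 pi_hat_window: tuple[float, float] = DEFAULT_PI_HAT_WINDOW,
                 clone_pi: float = DEFAULT_CLONE_PI):
        self.accept_factor = accept_factor
        self.reject_factor = reject_factor
        self.trio_possible_factor = trio_possible_factor
        self.pi_hat_window = pi_hat_window
        self.clone_pi = clone_pi

    def fit(self, reference_units, ibd_results, mendel_results):
        self.thresholds_ = calibrate(
            reference_units, ibd_results, mendel_results,
            pi_hat_window=self.pi_hat_window,
            accept_factor=self.accept_factor,
            reject_factor=self.reject_factor,
            trio_possible_factor=self.trio_possible_factor,
        )
        return self

    def _check_fitted(self):
        if not hasattr(self, "thresholds_"):
            raise NotFittedError("ParentageClassifier is not fitted")

    def predict_duo(self, ibd: IBDResult, mendel: MendelResult) -> RelationshipVerdict:
        self._check_fitted()
        return classify_duo(ibd, mendel, self.thresholds_)

    def predict_trio(self, trio_mendel, duo_verdicts, ibd_legs) -> RelationshipVerdict:
        self._check_fitted()
        return classify_trio(trio_mendel, duo_verdicts, ibd_legs, self.thresholds_)
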