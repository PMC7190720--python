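"""Pairwise relationship calls, full-sib grouping and reconstruction of a
missing parent's SSR genotype.

Relationship calls snap the moments IBD vector (Z0, Z1, Z2) to the nearest
canonical point: unrelated (1,0,0), half-sib-like (0.5,0.5,0), full sibs
(0.25,0.5,0.25), parent-offspring (0,1,0); a PI-HAT above the clone threshold
overrides everything. Half sibs, avuncular and grandparent-grandchild pairs
share the same expected vector and are deliberately not distinguished
(HS_LIKE).

Full-sib groups are connected components of the FS-labelled pair graph; a
component in which some member is not FS with every other is reported as a
"soft" group rather than silently split.

When a set of sibs shares one known parent, the absent parent's SSR genotype
is reconstructed by deterministic constraint propagation: at each locus every
offspring contributes the allele(s) the known parent cannot explain; the
union of obligate alleles across offspring determines the missing genotype
(two alleles: fully determined; one or zero: wildcard; more than two: the
sib set is inconsistent at that locus). A homozygous offspring whose allele
is shared with the known parent contributes nothing — the allele's origin is
ambiguous under this conservative rule, which keeps the constraint set sound.
The reconstructed profile can then be matched against a genotype database
and every hit re-validated as a full trio.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np

from .errors import DataError
from .genotype_io import SSRProfile
from .ibd_moments import IBDResult
from .mendel_check import trio_compatible_ssr
from .pedigree_sim import CLONE, FS, HS, PO, UNRELATED

HS_LIKE = "HS_LIKE"
DEFAULT_CLONE_PI = 0.9

CANONICAL_Z = {
    UNRELATED: np.array([1.0, 0.0, 0.0]),
    HS_LIKE: np.array([0.5, 0.5, 0.0]),
    FS: np.array([0.25, 0.5, 0.25]),
    PO: np.array([0.0, 1.0, 0.0]),
}


@dataclass
class RelationshipCall:
    pair: tuple[str, str]
    label: str
    distance: float          # Euclidean distance to the canonical Z point
    pi_hat: float


def classify_relationship(
    ibd: IBDResult, clone_pi: float = DEFAULT_CLONE_PI
) -> RelationshipCall:
    """Label a pair by its nearest canonical IBD vector (CLONE overrides)."""
    z = np.array(ibd.z())
    if ibd.PI_HAT > clone_pi:
        return RelationshipCall(ibd.pair, CLONE, float(np.linalg.norm(z - [0, 0, 1])), ibd.PI_HAT)
    best, dist = None, np.inf
    for label, ref in CANONICAL_Z.items():
        d = float(np.linalg.norm(z - ref))
        if d < dist:
            best, dist = label, d
    return RelationshipCall(ibd.pair, best, dist, ibd.PI_HAT)


@dataclass
class SibGroup:
    members: list[str]
    soft: bool   # True when some member pair is not FS-labelled


def find_fullsib_groups(calls: Sequence[RelationshipCall]) -> list[SibGroup]:
    """Connected components of the FS pair graph, flagged when not a clique."""
    g = nx.Graph()
    for c in calls:
        if c.label == FS:
            g.add_edge(*c.pair)
    groups = []
    for comp in nx.connected_components(g):
        members = sorted(comp)
        n = len(members)
        soft = g.subgraph(comp).number_of_edges() < n * (n - 1) // 2
        groups.append(SibGroup(members, soft))
    groups.sort(key=lambda s: s.members)
    return groups


# ---------------------------------------------------------------------------
# missing-parent reconstruction
# ---------------------------------------------------------------------------

@dataclass
class LocusConstraint:
    required: frozenset[int]
    wildcard: bool           # genotype under-determined (fewer than 2 obligate alleles)
    consistent: bool         # False when > 2 obligate alleles were deduced


@dataclass
class ReconstructedParent:
    known_parent: str
    offspring: list[str]
    loci: dict[str, LocusConstraint] = field(default_factory=dict)

    @property
    def consistent(self) -> bool:
        return all(c.consistent for c in self.loci.values())

    def to_rows(self) -> dict[str, tuple[str, str]]:
        """Per-locus allele pair in the SSR CSV dialect, '*' for wildcards."""
        out = {}
        for locus, c in self.loci.items():
            req = sorted(c.required)
            if not c.consistent:
                out[locus] = ("!", "!")
            elif len(req) == 2:
                out[locus] = (str(req[0]), str(req[1]))
            elif len(req) == 1:
                out[locus] = (str(req[0]), "*")
            else:
                out[locus] = ("*", "*")
        return out


def reconstruct_missing_parent(
    known_parent: SSRProfile, offspring_profiles: Sequence[SSRProfile]
) -> ReconstructedParent:
    """Constraint-propagate the absent parent's SSR genotype from its sibs.

    Every offspring must be duo-compatible with the known parent at every
    jointly called locus; an incompatible locus raises a DataError naming the
    offspring and locus.
    """
    if not offspring_profiles:
        raise DataError("no offspring profiles supplied")
    rec = ReconstructedParent(known_parent.sample_id, [o.sample_id for o in offspring_profiles])
    for locus, kp in known_parent.genotypes.items():
        if kp is None:
            continue
        kset = set(kp)
        required: set[int] = set()
        any_seen = False
        for off in offspring_profiles:
            og = off.genotypes.get(locus)
            if og is None:
                continue
            any_seen = True
            a, b = og
            if a not in kset and b not in kset:
                raise DataError(
                    f"offspring {off.sample_id!r} incompatible with known parent "
                    f"{known_parent.sample_id!r} at locus {locus}: "
                    f"{og} shares no allele with {kp}"
                )
            if a == b:
                continue  # homozygote shared with known parent: origin ambiguous
            if a in kset and b not in kset:
                required.add(b)
            elif b in kset and a not in kset:
                required.add(a)
            # both alleles in the known parent: no obligate contribution
        if not any_seen:
            continue
        rec.loci[locus] = LocusConstraint(
            required=frozenset(required),
            wildcard=len(required) < 2,
            consistent=len(required) <= 2,
        )
    return rec


@dataclass
class CandidateMatch:
    sample_id: str
    n_loci_checked: int
    trio_mismatches: dict[str, int]    # offspring id -> mismatching loci in re-check
    flagged: bool                      # True when any trio re-check mismatched


def scan_candidates(
    reconstructed: ReconstructedParent,
    database: Mapping[str, SSRProfile],
    known_parent: SSRProfile,
    offspring_profiles: Sequence[SSRProfile],
) -> list[CandidateMatch]:
    """Find database samples compatible with the reconstructed parent.

    A candidate must carry every required allele at every constrained locus
    (loci missing in the candidate are skipped — absence of evidence); each
    hit is then re-validated as a full trio with the known parent and each
    offspring, and flagged when any re-check mismatches.
    """
    exclude = {known_parent.sample_id, *(o.sample_id for o in offspring_profiles)}
    hits = []
    for sid, prof in database.items():
        if sid in exclude:
            continue
        ok = True
        checked = 0
        for locus, constraint in reconstructed.loci.items():
            if not constraint.consistent or not constraint.required:
                continue
            g = prof.genotypes.get(locus)
            if g is None:
                continue
            checked += 1
            if not constraint.required <= set(g):
                ok = False
                break
        if not ok or checked == 0:
            continue
        mismatches = {}
        for off in offspring_profiles:
            _, mm = trio_compatible_ssr(off, known_parent, prof, max_mismatch=10**9)
            mismatches[off.sample_id] = len(mm)
        hits.append(
            CandidateMatch(sid, checked, mismatches, any(v > 0 for v in mismatches.values()))
        )
    hits.sort(key=lambda h: (sum(h.trio_mismatches.values()), h.sample_id))
    return hits
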