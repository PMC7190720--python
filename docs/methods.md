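# Methods

## The inference problem

A germplasm collection of clonally propagated cultivars is genotyped with
three marker systems: ~12 multiallelic nuclear SSRs (fragment sizes in bp),
a SNP array yielding ~12–18k biallelic genotypes coded 0/1/2, and 8
chloroplast SSRs whose joint haplotype (the *chlorotype*) is maternally
inherited. The goal is to recover first-degree structure — parent–offspring
(PO) duos and parent–parent–offspring trios — plus full-sib groups, clones
and synonyms, and to reconstruct parents absent from the panel.

Parentage inference here is deliberately *exclusion plus calibration*, not
likelihood maximisation: SSRs exclude impossible parents cheaply, SNP-scale
metrics (IBD moments and Mendelian-inconsistency rates) confirm survivors
against thresholds measured on pedigrees already known to be true.

## Moments IBD estimator

For samples *i, j*, each shared non-missing locus contributes an
identity-by-state (IBS) observation: 2 if the genotype codes are equal, 0
for opposite homozygotes, 1 otherwise. With cohort alt-allele frequency *p*
(q = 1 − p), the conditional IBS distribution given the number of alleles
shared identical by descent (IBD) is

| IBD \ IBS | 0 | 1 | 2 |
|---|---|---|---|
| 0 | 2p²q² | 4p³q + 4pq³ | p⁴ + q⁴ + 4p²q² |
| 1 | 0 | 2p²q + 2pq² | p³ + q³ + pq |
| 2 | 0 | 0 | 1 |

Summing the expectations over the shared loci and equating them with the
observed IBS counts N₀, N₁, N₂ gives the plug-in solution

    Z0 = N0 / ΣE[IBS0|IBD0]
    Z1 = (N1 − Z0·ΣE[IBS1|IBD0]) / ΣE[IBS1|IBD1]
    Z2 = (N2 − Z0·ΣE[IBS2|IBD0] − Z1·ΣE[IBS2|IBD1]) / L

Numerical conventions (fixed so results are bit-reproducible): components
are clamped to [0, 1] in Z0 → Z1 → Z2 order, then renormalised to sum 1;
PI-HAT = Z2 + Z1/2 is computed from the final values, so the identity holds
exactly on every reported result. Loci monomorphic in the cohort are
excluded (no IBS information, division hazard), and a pair needs ≥ 100
shared informative loci (configurable) or the estimate is refused.

Two deliberate simplifications: no finite-sample bias correction, and allele
frequencies taken from the full cohort *including* the tested pair. At
chip-scale locus counts the residual error is far inside the ±0.05 band the
verdict thresholds operate on, and both choices keep the estimator a pure
function of (genotypes, cohort). The estimator's accuracy claims therefore
assume a reasonably panmictic frequency cohort; strong population structure
biases Z upward for within-group pairs and is listed as a limitation.

## SNP curation

Quality filtering uses strict inequalities throughout — MAF > 0.05, missing
fraction < 0.05, call quality > 0.54 where a per-locus quality column
exists — so a locus exactly on a boundary is rejected; the rejection log
records the first criterion that failed (checked in MAF, missing, quality
order).

The reliability classifier re-derives four marker classes from genotype
counts alone (the original intensity-cluster scoring operates on raw array
data that no longer exists downstream of genotype calling):

* a homozygote class with frequency < `rare_hom_max` (default 0.01) marks a
  one-homozygote-rare marker, split into HWE / not-HWE by an exact
  Hardy–Weinberg test at `hwe_alpha` (default 0.01);
* otherwise an HWE failure marks the locus *distorted* — the heterozygote
  deficit direction is the classic null-allele (AB × AO) signature that
  manufactures spurious Mendelian conflicts;
* the rest are *robust*; loci with ≥ 5% missing calls on the classification
  cohort are *discarded*.

The HWE test is the exact conditional test, two-sided on the heterozygote
count (p = sum of probabilities of all configurations no more likely than
the observed one), computed by the standard recurrence; the test suite pins
it to an exact-rational enumeration oracle at 1e-12 for n ≤ 200. The
classification cohort may be larger than the analysis panel — the API takes
an optional separate cohort matrix, matching the practice of classifying on
every genotyped accession while analysing a subset.

Because this is a re-derivation from counts, per-class SNP totals are not
expected to match any particular external tool count-for-count; what is
asserted (and tested) is behaviour: HWE panels classify ≥ 95% robust,
planted null-allele loci land in the distorted class, and the classes
partition the retained panel.

## Mendelian-inconsistency accounting

Duo conflicts are opposite homozygotes only (a heterozygote can never
contradict a single parent). Trio conflicts are genotypes impossible under
one-allele-from-each-parent transmission; both engines are pinned to
exhaustive enumeration oracles (9 ordered duo cells, 27 trio cells).

Rates are reported two ways. `mi_rate` divides by the retained panel size —
the convention under which published reference rates back-compute (25
conflicts / 11,929 loci = 0.0021) — and `error_rate` divides by the loci
actually compared for the unit (the parent-parent-child error-rate
analogue). Duo calibration and verdicts use `mi_rate`; trio verdicts use
`error_rate`. Stratification restricts a unit's conflict loci to the
classified panel, counts per class, and merges robust + one-homozygote-rare
as the trusted reporting class; the reduction percentage is
(MI_full − MI_pruned)/MI_full × 100 rounded to one decimal.

## Verdict calibration

From reference units (known trios/duos in the panel) the engine takes
`z1_min` = lowest reference Z1 and `mi_rate_ref_max` = highest reference MI
rate. A candidate duo is

* SUPPORTED when Z1 ≥ z1_min, PI-HAT ∈ [0.45, 0.56] and
  mi_rate ≤ 1.1 × mi_rate_ref_max;
* REJECTED when mi_rate ≥ 2.0 × mi_rate_ref_max (the rule only fires on a
  nonzero rate, so a zero-MI reference set cannot reject clean candidates)
  or Z1 < z1_min − 0.1;
* POSSIBLE otherwise.

Trios: SUPPORTED when the trio error rate is ≤ 1.1 × the reference trio
ceiling and neither child–parent leg is rejected; POSSIBLE up to 1.3 ×; else
REJECTED. The 1.1 / 2.0 / 1.3 factors reproduce the qualitative decision
pattern of real germplasm studies — supported pairs sit at or just above the
reference ceiling, excluded pairs show conflict rates several-fold higher,
and a borderline trio at ~1.2 × reference is kept as "possible" — and are
all configurable. Pairs with PI-HAT > 0.9 are routed to clone/synonym
reporting and never judged as parentage; chlorotype conflicts annotate a
trio (cpSSR homoplasy and sampling slips are plausible) but never reject it.

One statistical caveat, relevant to simulation studies more than to real
panels: `z1_min` is a sample minimum. Among exchangeable clean PO pairs, a
non-reference pair falls below the minimum of k reference legs with
probability ≈ 1/(k+1), so strict SUPPORTED-duo recall has expectation
≈ k/(k+1) rather than 1; such pairs land in POSSIBLE (never REJECTED, since
the margin rule needs a 0.1 drop), and trio recovery — which only requires
legs not be rejected — is unaffected. On real data the reference spread is
wide and the effect is invisible.

## Sibship and missing-parent reconstruction

Pairwise relationship calls snap (Z0, Z1, Z2) to the nearest canonical point
by Euclidean distance (clone override at PI-HAT > 0.9). Half-sib, avuncular
and grandparent–grandchild pairs share the expected (0.5, 0.5, 0) and are
deliberately labelled HS_LIKE rather than distinguished. Full-sib groups are
connected components of the FS pair graph, flagged "soft" when not a clique.

The full-likelihood sibship machinery of dedicated software is replaced by
this moment classifier plus deterministic constraint propagation: at
chip-scale marker counts only unambiguous full-sib dyads are retained
anyway, so the deterministic surrogate loses little. For a sib set with one
known parent, each offspring contributes the allele(s) at each SSR locus the
known parent cannot explain; the union across offspring is the required
allele set of the missing parent (2 alleles: determined; ≤ 1: wildcard; > 2:
inconsistent sib set). A homozygous offspring sharing its allele with the
known parent contributes nothing — the allele's origin is ambiguous under
the conservative rule, which keeps the constraint set sound (the true hidden
parent always satisfies it; tested at 100% over error-free replicates).
Candidate database hits must cover every required allele and are re-validated
as full trios.

## Distances and clustering

Diploid genotypes become two nucleotide characters per locus (heterozygotes
in alphabetical order, missing as NN) rather than IUPAC codes, so transition
/transversion counting is well-defined and pairwise deletion acts per
character; this is an explicit approximation of feeding SNP genotypes to a
nucleotide-distance program, whose own convention is unspecified, and only
topology-level conclusions should be drawn. K2P distance over
pairwise-complete sites: d = −½·ln((1 − 2P − Q)·√(1 − 2Q)). Saturated pairs
(log argument ≤ 0) are flagged and replaced at matrix level by 1.1 × the
largest finite distance, with a warning, so UPGMA stays total. K2P may
violate the triangle inequality; nothing assumes it.

UPGMA merges the closest pair with size-weighted arithmetic-mean updates;
ties break to the lowest (row, column) index, making every tree
reproducible; node height is half the merge distance, so trees are
ultrametric by construction (asserted to 1e-9). The bootstrap resamples SNP
loci with replacement — both characters of a locus move together, preserving
within-genotype dependence — and supports are the percentage of 500
replicates (default) containing each original clade; renderers are told to
mark only supports above 75.

## The simulator

The generator emulates the statistical structure the analysis assumes: a
panmictic founder pool (SNP alt frequencies uniform on [0.05, 0.5]; SSR
allele frequencies Dirichlet(1,…,1) over 4–12 distinct sizes per locus; 4
chlorotype classes), Mendelian transmission with unlinked loci, strict
maternal chlorotype inheritance, per-allele miscall errors (SNP: allele
flip; SSR: one motif step) and per-call missingness. The default noise
rates, 0.1% per allele and 1% missing, are typical of array-scale genotyping
in germplasm panels; validation runs that require error-free data set both
to zero explicitly. The built-in "founder-star" scenario plants two
recurrent founders with six offspring each, three full-sib pairs, three
reference trios, one clone pair and unrelated accessions — the topology the
calibration logic expects. All draws flow through one seeded generator in a
fixed documented order, so identical (seed, config) pairs give byte-identical
datasets.

What the simulator does *not* model — linkage, population structure,
coalescent founder history, SSR size-calling artefacts, locus-specific error
rates — bounds what passing tests show: they validate the estimators and the
decision logic under the stated assumptions, not robustness to structured
real-world noise.

## Problem sizes used in validation

Unit tests run the founder-star study at 1,500–3,000 loci; the acceptance
checks run the estimator benchmark at its stated scale (50 error-free pairs
per relationship class, 12,000 loci — mean PO PI-HAT within 0.5 ± 0.02,
class means within ±0.05 of canonical) and the end-to-end pedigree recovery
at 12,000 loci, where SUPPORTED-trio precision and recall against the
planted pedigree are 1.0. Replication of the original study's real-data
counts (11,929 retained SNPs, twenty-three duos, …) requires its
supplementary genotype tables and is therefore optional: given those tables
in any supported dialect, the same pipeline configuration reproduces the
published table layouts.

## Known limitations

* Allele frequencies from small, related cohorts bias IBD estimates; no
  bias correction is applied.
* SSR inputs are assumed pre-binned; no inter-lab fragment-size alignment.
* The four-class SNP map approximates intensity-based scoring from counts;
  class totals are not comparable across tools.
* The quadratic SNP-only search mode is intended for ≤ a few hundred
  samples.
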