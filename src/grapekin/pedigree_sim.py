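"""Synthetic germplasm panels with known pedigree structure.

The generator emulates the statistical setting of a varietal collection
genotyped at ~12 nuclear SSRs, ~12k unlinked biallelic SNPs and 8 chloroplast
SSRs: a panmictic founder pool, a handful of recurrent founders each with
several direct offspring, full-sib and half-sib pairs, reference trios for
threshold calibration, a clone pair and unrelated accessions. Loci segregate
independently (the downstream analysis uses unmapped markers), founders are
drawn from one allele-frequency pool, and chlorotypes are strictly maternal.

All randomness flows through one seeded generator with a documented draw
order, so a (seed, config) pair yields a byte-identical dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from .errors import ConfigError, DataError
from .genotype_io import (
    MISSING,
    ChlorotypeTable,
    Locus,
    MarkerPanel,
    SNPGenotypeMatrix,
    SSRProfile,
    write_chlorotype_table,
    write_snp_csv,
    write_ssr_table,
)

# Pairwise relationship labels.
PO = "PO"
FS = "FS"
HS = "HS"
UNRELATED = "UNRELATED"
CLONE = "CLONE"
SELF = "SELF"

_SSR_MOTIF = 2  # dinucleotide repeat step for simulated SSR alleles


@dataclass
class SimulationConfig:
    """Study-design knobs for the synthetic panel.

    Defaults emulate a germplasm SNP-array study: 12 nuclear SSRs with 4-12
    alleles each, 12,000 SNPs with minor-allele frequencies uniform on
    [0.05, 0.5], 4 chlorotype classes, a 0.1% per-allele miscall rate and 1%
    missing calls (typical array-scale noise).
    """

    n_founders: int = 10
    ssr_loci: int = 12
    ssr_alleles_per_locus: tuple[int, int] = (4, 12)
    snp_loci: int = 12000
    snp_maf_range: tuple[float, float] = (0.05, 0.5)
    cp_haplotypes: int = 4
    error_rate: float = 0.001
    missing_rate: float = 0.01
    clone_divergence: int = 0
    seed: int = 0

    def __post_init__(self):
        for name in ("error_rate", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        for name in ("n_founders", "ssr_loci", "snp_loci", "cp_haplotypes"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        lo, hi = self.snp_maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigError(f"snp_maf_range must satisfy 0 < lo <= hi <= 0.5, got {self.snp_maf_range}")
        lo, hi = self.ssr_alleles_per_locus
        if not (2 <= lo <= hi):
            raise ConfigError("ssr_alleles_per_locus must satisfy 2 <= lo <= hi")
        if self.clone_divergence < 0:
            raise ConfigError("clone_divergence must be >= 0")


@dataclass
class PedigreeTruth:
    """Simulator ground truth: parent links, clone links, chlorotype lineage."""

    parents: dict[str, tuple[str, str] | None] = field(default_factory=dict)
    clones: dict[str, str] = field(default_factory=dict)  # clone id -> source id
    chlorotype_of: dict[str, int] = field(default_factory=dict)
    reference_trios: list[tuple[str, str, str]] = field(default_factory=list)

    def genet(self, sample: str) -> str:
        """Representative genotype id: clones collapse onto their source."""
        return self.clones.get(sample, sample)

    def relationship(self, a: str, b: str) -> str:
        """Deterministic pairwise label derived from the parent/clone maps."""
        if a == b:
            return SELF
        ga, gb = self.genet(a), self.genet(b)
        if ga == gb:
            return CLONE
        pa = set(self.parents.get(ga) or ())
        pb = set(self.parents.get(gb) or ())
        if gb in pa or ga in pb:
            return PO
        shared = len(pa & pb)
        if pa and pb:
            if shared == 2 and len(pa) == 2:
                return FS
            if shared == 1:
                return HS
        elif shared == 1:  # one founder, one offspring of it handled above; cannot happen
            return HS
        return UNRELATED

    def all_pair_labels(self) -> dict[tuple[str, str], str]:
        ids = sorted(self.parents)
        return {
            (a, b): self.relationship(a, b)
            for i, a in enumerate(ids)
            for b in ids[i + 1:]
        }

    def true_mother(self, child: str) -> str | None:
        p = self.parents.get(child)
        return p[0] if p else None


@dataclass
class SimulatedStudy:
    """A complete simulated dataset plus its ground truth."""

    snp: SNPGenotypeMatrix
    ssr: dict[str, SSRProfile]
    chlorotypes: ChlorotypeTable
    truth: PedigreeTruth
    snp_freqs: np.ndarray                      # founder-pool alt frequencies
    ssr_freqs: list[dict[int, float]]          # per-locus allele -> frequency
    config: SimulationConfig

    @property
    def sample_ids(self) -> list[str]:
        return self.snp.sample_ids


# ---------------------------------------------------------------------------
# founders
# ---------------------------------------------------------------------------

def simulate_founders(config: SimulationConfig, rng: np.random.Generator | None = None) -> SimulatedStudy:
    """Draw an unrelated founder panel from a single panmictic pool.

    Draw order (fixed for cross-version stability): SNP alt frequencies, SNP
    genotypes, SSR allele counts, SSR frequencies, SSR genotypes, chloroplast
    haplotype assignments.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    ids = [f"F{i + 1:03d}" for i in range(config.n_founders)]

    lo, hi = config.snp_maf_range
    snp_freqs = rng.uniform(lo, hi, size=config.snp_loci)
    snp_calls = rng.binomial(2, snp_freqs, size=(config.n_founders, config.snp_loci)).astype(np.int16)
    nt = np.array(["A", "C", "G", "T"])
    refs = nt[rng.integers(0, 4, size=config.snp_loci)]
    alts = np.array([nt[(np.flatnonzero(nt == r)[0] + rng.integers(1, 4)) % 4] for r in refs])
    panel = MarkerPanel(
        [Locus(f"snp{j + 1:05d}", "SNP", refs[j], alts[j]) for j in range(config.snp_loci)]
    )

    klo, khi = config.ssr_alleles_per_locus
    ssr_freqs: list[dict[int, float]] = []
    ssr_names = [f"ssr{j + 1:02d}" for j in range(config.ssr_loci)]
    ssr_calls = {}
    for j in range(config.ssr_loci):
        k = int(rng.integers(klo, khi + 1))
        sizes = 100 + 20 * j + _SSR_MOTIF * np.arange(k)
        freqs = rng.dirichlet(np.ones(k))
        ssr_freqs.append({int(s): float(f) for s, f in zip(sizes, freqs)})
        draws = rng.choice(sizes, size=(config.n_founders, 2), p=freqs)
        ssr_calls[j] = draws
    ssr = {
        sid: SSRProfile(
            sid, {ssr_names[j]: tuple(ssr_calls[j][i]) for j in range(config.ssr_loci)}
        )
        for i, sid in enumerate(ids)
    }

    cp_assign = rng.integers(0, config.cp_haplotypes, size=config.n_founders)
    truth = PedigreeTruth(parents={sid: None for sid in ids})
    truth.chlorotype_of = {sid: int(h) for sid, h in zip(ids, cp_assign)}
    chloro = ChlorotypeTable({sid: _cp_haplotype(h) for sid, h in truth.chlorotype_of.items()})

    return SimulatedStudy(
        snp=SNPGenotypeMatrix(ids, snp_calls, panel),
        ssr=ssr,
        chlorotypes=chloro,
        truth=truth,
        snp_freqs=snp_freqs,
        ssr_freqs=ssr_freqs,
        config=config,
    )


def _cp_haplotype(h: int) -> tuple[int, ...]:
    # distinct deterministic 8-locus haplotype per chlorotype class
    return tuple(100 + 10 * j + h for j in range(ChlorotypeTable.N_LOCI))


# ---------------------------------------------------------------------------
# crosses and clones
# ---------------------------------------------------------------------------

def simulate_cross(
    study: SimulatedStudy, mother: str, father: str, child_id: str,
    rng: np.random.Generator,
) -> None:
    """Add one offspring of ``mother`` x ``father`` (selfing when equal).

    One allele is sampled uniformly from each parent at every SNP and SSR
    locus; the chlorotype is the mother's (strict maternal inheritance).
    """
    for p in (mother, father):
        if p not in study.snp._row_index:
            raise DataError(f"unknown parent id {p!r}")
    gm = study.snp.row(mother)
    gf = study.snp.row(father)
    am = (rng.random(study.snp.n_loci) < gm / 2.0).astype(np.int16)
    af = (rng.random(study.snp.n_loci) < gf / 2.0).astype(np.int16)
    child_row = am + af

    genotypes = {}
    for locus in study.ssr[mother].genotypes:
        pm = study.ssr[mother].genotypes[locus]
        pf = study.ssr[father].genotypes[locus]
        genotypes[locus] = (pm[int(rng.integers(2))], pf[int(rng.integers(2))])
    _append_sample(study, child_id, child_row, SSRProfile(child_id, genotypes),
                   study.truth.chlorotype_of[mother])
    study.truth.parents[child_id] = (mother, father)


def make_clone(
    study: SimulatedStudy, source: str, clone_id: str, rng: np.random.Generator,
    snp_divergence: int = 0, ssr_divergence: int = 0,
) -> None:
    """Add a vegetatively propagated copy of ``source``.

    Somatic divergence is modelled as genotype changes at ``snp_divergence``
    random SNP loci and single-step motif shifts at ``ssr_divergence`` random
    SSR alleles, mimicking mutations accumulated during clonal propagation.
    """
    row = study.snp.row(source).copy()
    if snp_divergence:
        idx = rng.choice(study.snp.n_loci, size=snp_divergence, replace=False)
        row[idx] = (row[idx] + rng.integers(1, 3, size=snp_divergence)) % 3
    prof = SSRProfile(clone_id, dict(study.ssr[source].genotypes))
    if ssr_divergence:
        loci = list(prof.genotypes)
        for locus in rng.choice(len(loci), size=ssr_divergence, replace=False):
            name = loci[int(locus)]
            a, b = prof.genotypes[name]
            shift = _SSR_MOTIF * (1 if rng.random() < 0.5 else -1)
            prof.genotypes[name] = tuple(sorted((a + shift, b)))
    _append_sample(study, clone_id, row, prof, study.truth.chlorotype_of[source])
    study.truth.parents[clone_id] = study.truth.parents[source]
    study.truth.clones[clone_id] = source


def _append_sample(study, sid, snp_row, ssr_profile, cp_hap):
    m = study.snp
    study.snp = SNPGenotypeMatrix(
        m.sample_ids + [sid], np.vstack([m.calls, snp_row[None, :]]), m.panel, m.quality
    )
    study.ssr[sid] = ssr_profile
    study.truth.chlorotype_of[sid] = cp_hap
    study.truth.parents.setdefault(sid, None)
    study.chlorotypes = ChlorotypeTable(
        {s: _cp_haplotype(study.truth.chlorotype_of[s]) for s in study.snp.sample_ids}
    )


# ---------------------------------------------------------------------------
# observation noise
# ---------------------------------------------------------------------------

def apply_errors(
    study: SimulatedStudy, error_rate: float, missing_rate: float,
    seed: int | np.random.Generator,
) -> SimulatedStudy:
    """Overlay genotyping noise; truth is untouched.

    Each SNP allele is independently miscalled (flipped to the other allele)
    with probability ``error_rate``; each SSR allele is shifted by one motif
    step (random direction) with the same probability. Each call is then set
    missing with probability ``missing_rate``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    calls = study.snp.calls.copy()
    if error_rate > 0:
        # per-call allele flips: ref->alt among (2-g) ref alleles, alt->ref among g
        flips_ref = rng.binomial(2 - np.clip(calls, 0, 2), error_rate)
        flips_alt = rng.binomial(np.clip(calls, 0, 2), error_rate)
        noisy = calls + flips_ref - flips_alt
        calls = np.where(calls == MISSING, MISSING, noisy).astype(np.int16)
    if missing_rate > 0:
        drop = rng.random(calls.shape) < missing_rate
        calls[drop] = MISSING

    ssr = {}
    for sid, prof in study.ssr.items():
        genotypes = {}
        for locus, pair in prof.genotypes.items():
            if pair is None:
                genotypes[locus] = None
                continue
            a, b = pair
            if error_rate > 0:
                if rng.random() < error_rate:
                    a += _SSR_MOTIF * (1 if rng.random() < 0.5 else -1)
                if rng.random() < error_rate:
                    b += _SSR_MOTIF * (1 if rng.random() < 0.5 else -1)
            genotypes[locus] = None if (missing_rate > 0 and rng.random() < missing_rate) else (a, b)
        ssr[sid] = SSRProfile(sid, genotypes)

    return replace(
        study,
        snp=SNPGenotypeMatrix(study.snp.sample_ids, calls, study.snp.panel, study.snp.quality),
        ssr=ssr,
    )


# ---------------------------------------------------------------------------
# study scenarios
# ---------------------------------------------------------------------------

def _build_founder_star(study: SimulatedStudy, rng: np.random.Generator) -> None:
    """Default topology: two recurrent founders with 6 offspring each, FS and
    HS pairs, three reference trios, one clone pair, unrelated accessions."""
    cfg = study.config
    if cfg.n_founders < 8:
        raise ConfigError("founder-star scenario needs n_founders >= 8")
    F = [f"F{i + 1:03d}" for i in range(cfg.n_founders)]
    crosses = [
        # recurrent founder F1 (6 offspring, one FS pair among them)
        ("C01", F[0], F[2]), ("C02", F[0], F[2]),          # FS pair
        ("C03", F[0], F[3]), ("C04", F[0], F[3]),          # FS pair
        ("C05", F[0], F[4]), ("C06", F[0], F[5]),
        # recurrent founder F2 (6 offspring, one FS pair)
        ("C07", F[1], F[3]), ("C08", F[1], F[4]),
        ("C09", F[1], F[4]), ("C10", F[1], F[5]),          # C08/C09 FS pair
        ("C11", F[1], F[6]), ("C12", F[1], F[7]),
        # an outside cross, unrelated to both big families
        ("C13", F[2], F[6]),
    ]
    for child, mother, father in crosses:
        simulate_cross(study, mother, father, child, rng)
    study.truth.reference_trios = [
        ("C01", F[0], F[2]), ("C07", F[1], F[3]), ("C13", F[2], F[6]),
    ]
    make_clone(study, F[0], F[0] + "cl", rng, snp_divergence=cfg.clone_divergence)


SCENARIOS = {"founder-star": _build_founder_star}


def simulate_study(
    config: SimulationConfig, scenario: str = "founder-star"
) -> tuple[SimulatedStudy, PedigreeTruth]:
    """Simulate a complete study: founders, pedigree topology, noise overlay.

    Returns the *observed* dataset (with the config's error and missing rates
    applied) together with its ground truth.
    """
    if scenario not in SCENARIOS:
        raise ConfigError(
            f"unknown scenario {scenario!r}; built-ins: {sorted(SCENARIOS)}"
        )
    rng = np.random.default_rng(config.seed)
    study = simulate_founders(config, rng)
    SCENARIOS[scenario](study, rng)
    observed = apply_errors(study, config.error_rate, config.missing_rate, rng)
    return observed, observed.truth


def simulate_relationship_pairs(
    n_pairs_per_class: int = 50,
    snp_loci: int = 12000,
    maf_range: tuple[float, float] = (0.05, 0.5),
    seed: int = 0,
) -> tuple[SNPGenotypeMatrix, dict[str, list[tuple[str, str]]]]:
    """Cohort of independent pair replicates for estimator validation.

    For each relationship class (PO, FS, HS, UNRELATED) ``n_pairs_per_class``
    error-free pairs are drawn from fresh unrelated parents at ``snp_loci``
    unlinked biallelic loci with alt frequency uniform on ``maf_range``.
    Returns the pooled genotype matrix (the frequency cohort) and the pair
    ids per class. Vectorised: all founders and all transmissions are drawn
    in bulk, in a fixed order (founders, then PO/FS/HS children).
    """
    rng = np.random.default_rng(seed)
    k = n_pairs_per_class
    p = rng.uniform(maf_range[0], maf_range[1], size=snp_loci)

    def cross(gm, gf):
        am = (rng.random(gm.shape) < gm / 2.0).astype(np.int16)
        af = (rng.random(gf.shape) < gf / 2.0).astype(np.int16)
        return am + af

    # founders: PO needs 2/pair, FS 2, HS 3, UNRELATED 2
    F = rng.binomial(2, p, size=(9 * k, snp_loci)).astype(np.int16)
    po_m, po_f = F[0:k], F[k:2 * k]
    fs_m, fs_f = F[2 * k:3 * k], F[3 * k:4 * k]
    hs_shared, hs_o1, hs_o2 = F[4 * k:5 * k], F[5 * k:6 * k], F[6 * k:7 * k]
    un_a, un_b = F[7 * k:8 * k], F[8 * k:9 * k]

    po_c = cross(po_m, po_f)
    fs_c1, fs_c2 = cross(fs_m, fs_f), cross(fs_m, fs_f)
    hs_c1, hs_c2 = cross(hs_shared, hs_o1), cross(hs_shared, hs_o2)

    blocks = [
        ("POp", po_m), ("POc", po_c),
        ("FSa", fs_c1), ("FSb", fs_c2),
        ("HSa", hs_c1), ("HSb", hs_c2),
        ("UNa", un_a), ("UNb", un_b),
    ]
    ids, rows = [], []
    for tag, block in blocks:
        ids.extend(f"{tag}{i:03d}" for i in range(k))
        rows.append(block)
    panel = MarkerPanel(
        [Locus(f"snp{j + 1:05d}", "SNP", "A", "G") for j in range(snp_loci)]
    )
    matrix = SNPGenotypeMatrix(ids, np.vstack(rows), panel)
    pairs = {
        PO: [(f"POp{i:03d}", f"POc{i:03d}") for i in range(k)],
        FS: [(f"FSa{i:03d}", f"FSb{i:03d}") for i in range(k)],
        HS: [(f"HSa{i:03d}", f"HSb{i:03d}") for i in range(k)],
        UNRELATED: [(f"UNa{i:03d}", f"UNb{i:03d}") for i in range(k)],
    }
    return matrix, pairs


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def write_study(study: SimulatedStudy, outdir) -> dict[str, Path]:
    """Write the dataset in the same dialects genotype_io reads, plus truth
    tables and a YAML echo of the configuration."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "snp_csv": outdir / "snp_genotypes.csv",
        "ssr_csv": outdir / "ssr_profiles.csv",
        "chlorotypes": outdir / "chlorotypes.csv",
        "truth": outdir / "truth_pedigree.csv",
        "config": outdir / "sim_config.yaml",
    }
    write_snp_csv(study.snp, paths["snp_csv"])
    ssr_panel = MarkerPanel([Locus(n, "SSR") for n in next(iter(study.ssr.values())).genotypes])
    write_ssr_table(study.ssr.values(), ssr_panel, paths["ssr_csv"])
    write_chlorotype_table(study.chlorotypes, paths["chlorotypes"])

    import pandas as pd

    rows = []
    for sid in study.sample_ids:
        p = study.truth.parents.get(sid)
        rows.append(
            {"sample_id": sid,
             "mother": p[0] if p else "",
             "father": p[1] if p else "",
             "clone_of": study.truth.clones.get(sid, ""),
             "chlorotype": study.truth.chlorotype_of[sid],
             "reference_trio": int(any(sid == t[0] for t in study.truth.reference_trios))}
        )
    pd.DataFrame(rows).to_csv(paths["truth"], index=False)
    cfg = study.config
    paths["config"].write_text(yaml.safe_dump({
        "n_founders": cfg.n_founders, "ssr_loci": cfg.ssr_loci,
        "ssr_alleles_per_locus": list(cfg.ssr_alleles_per_locus),
        "snp_loci": cfg.snp_loci, "snp_maf_range": list(cfg.snp_maf_range),
        "cp_haplotypes": cfg.cp_haplotypes, "error_rate": cfg.error_rate,
        "missing_rate": cfg.missing_rate, "clone_divergence": cfg.clone_divergence,
        "seed": cfg.seed,
    }))
    return paths
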