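"""End-to-end orchestration: QC -> IBD -> Mendel -> parentage -> sibship ->
chlorotypes -> tree, from a single YAML configuration.

The flow enforces the two-step strategy used in germplasm parentage work:
the SSR exclusion search proposes candidate duos/trios, SNP metrics confirm
them against reference-calibrated thresholds. With no SSR input the pipeline
falls back to scoring all pairs directly on SNPs (quadratic; fine up to a
few hundred samples). Every stage logs the thresholds it actually applied,
and a fixed seed makes reruns byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .errors import CalibrationError, ConfigError
from .genotype_io import (
    read_chlorotype_table,
    read_snp_matrix,
    read_ssr_table,
)
from .mendel_check import duo_mi_snp, stratify_mi, trio_mi_snp
from .distance_tree import UPGMADendrogram
from .ibd_moments import IBDMomentsEstimator, ibd_table
from .parentage_engine import (
    ParentageClassifier,
    Verdict,
    classify_duo,
    maternal_consistency,
    search_trios,
    _pair_key,
)
from .pedigree_sim import SimulationConfig, simulate_study
from .sibship_reconstruct import (
    PO,
    classify_relationship,
    find_fullsib_groups,
    reconstruct_missing_parent,
    scan_candidates,
)
from .snp_curation import SNPQualityFilter, SNPReliabilityClassifier

log = logging.getLogger("grapekin")

_KNOWN_KEYS = {
    "inputs", "simulate", "snp_qc", "classify", "ibd", "parentage",
    "sibship", "tree", "output_dir", "seed",
}

REPORT_SCHEMA_VERSION = 1


@dataclass
class PipelineConfig:
    inputs: dict = field(default_factory=dict)
    simulate: dict | None = None
    snp_qc: dict = field(default_factory=dict)
    classify: dict = field(default_factory=dict)
    ibd: dict = field(default_factory=dict)
    parentage: dict = field(default_factory=dict)
    sibship: dict = field(default_factory=dict)
    tree: dict = field(default_factory=dict)
    output_dir: str = "grapekin_out"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        path = Path(path)
        if not path.exists():
            raise ConfigError(f"config file not found: {path}")
        raw = yaml.safe_load(path.read_text()) or {}
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        for key in ("ssr", "snp", "cpssr"):
            p = cfg.inputs.get(key)
            if p and not Path(p).exists():
                raise ConfigError(f"input file does not exist: {p}")
        if cfg.simulate is None and not (cfg.inputs.get("snp") or cfg.inputs.get("ssr")):
            raise ConfigError("need at least a SNP or SSR input (or a simulate block)")
        return cfg


@dataclass
class ReportBundle:
    """All pipeline outputs; every verdict row is traceable to evidence rows
    through the sample ids shared across tables."""

    trio_table: pd.DataFrame
    duo_table: pd.DataFrame
    clone_table: pd.DataFrame
    fs_groups: pd.DataFrame
    reconstructed_parents: pd.DataFrame
    ibd: pd.DataFrame
    qc_log: pd.DataFrame
    newick: str | None
    run_log: list[str]

    def write(self, outdir) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, df in [
            ("trios", self.trio_table), ("duos", self.duo_table),
            ("clones", self.clone_table), ("fs_groups", self.fs_groups),
            ("reconstructed_parents", self.reconstructed_parents),
            ("ibd", self.ibd), ("qc_log", self.qc_log),
        ]:
            p = outdir / f"{name}.csv"
            df.to_csv(p, index=False)
            paths[name] = p
        if self.newick is not None:
            p = outdir / "tree.nwk"
            p.write_text(self.newick + "\n")
            paths["tree"] = p
        p = outdir / "run_log.txt"
        p.write_text("\n".join(self.run_log) + "\n")
        paths["log"] = p
        (outdir / "manifest.json").write_text(json.dumps(
            {"schema_version": REPORT_SCHEMA_VERSION, "grapekin": __version__,
             "tables": sorted(paths)}, indent=1))
        return paths


def _load_inputs(cfg: PipelineConfig):
    """Returns (snp matrix | None, ssr profiles | None, chlorotypes | None,
    reference units, truth | None)."""
    if cfg.simulate is not None:
        sim_kwargs = dict(cfg.simulate)
        scenario = sim_kwargs.pop("scenario", "founder-star")
        sim_kwargs.setdefault("seed", cfg.seed)
        study, truth = simulate_study(SimulationConfig(**sim_kwargs), scenario)
        refs = [tuple(t) for t in truth.reference_trios]
        return study.snp, study.ssr, study.chlorotypes, refs, truth
    snp = ssr = cpssr = None
    if cfg.inputs.get("snp"):
        snp = read_snp_matrix(cfg.inputs["snp"], cfg.inputs.get("snp_format", "csv"))
    if cfg.inputs.get("ssr"):
        profiles, _ = read_ssr_table(cfg.inputs["ssr"])
        ssr = {p.sample_id: p for p in profiles}
    if cfg.inputs.get("cpssr"):
        cpssr = read_chlorotype_table(cfg.inputs["cpssr"])
    refs = [tuple(u) for u in cfg.inputs.get("references", [])]
    return snp, ssr, cpssr, refs, None


def run_pipeline(cfg: PipelineConfig) -> ReportBundle:
    run_log: list[str] = [f"grapekin {__version__}, seed {cfg.seed}"]

    def say(msg):
        log.info(msg)
        run_log.append(msg)

    snp, ssr, cpssr, references, truth = _load_inputs(cfg)
    say(f"inputs: snp={'yes' if snp is not None else 'no'} "
        f"ssr={'yes' if ssr is not None else 'no'} "
        f"cpssr={'yes' if cpssr is not None else 'no'} "
        f"references={len(references)}")

    empty = pd.DataFrame()
    qc_log = empty
    class_map = None
    ibd_lookup = {}
    ibd_df = empty
    calls = []

    if snp is not None:
        qc = SNPQualityFilter(**cfg.snp_qc)
        retained = qc.fit(snp).transform(snp)
        qc_log = qc.rejection_log_
        say(f"snp qc: {retained.n_loci}/{snp.n_loci} loci retained "
            f"(maf>{qc.maf_min}, missing<{qc.missing_max}, quality>{qc.quality_min})")
        snp = retained
        clf = SNPReliabilityClassifier(**cfg.classify)
        class_map = clf.fit(snp).class_map_
        say("snp classes: " + ", ".join(
            f"{c.value}={sum(1 for v in class_map.values() if v is c)}"
            for c in set(class_map.values())))

        est = IBDMomentsEstimator(**cfg.ibd).fit(snp)
        results = est.pairwise()
        ibd_lookup = {_pair_key(*r.pair): r for r in results}
        ibd_df = ibd_table(results)
        clone_pi = cfg.parentage.get("clone_pi", 0.9)
        calls = [classify_relationship(r, clone_pi) for r in results]
        say(f"ibd: {len(results)} pairs estimated over {snp.n_loci} loci")
    elif ssr is None:
        raise ConfigError("no usable inputs")

    clone_rows = [
        {"sample_1": c.pair[0], "sample_2": c.pair[1], "pi_hat": c.pi_hat}
        for c in calls if c.label == "CLONE"
    ]
    clone_table = pd.DataFrame(clone_rows)

    # ---- parentage -------------------------------------------------------
    trio_rows, duo_rows = [], []
    verdict_trios = []
    if snp is not None:
        if not references:
            raise CalibrationError(
                "no calibration references configured and no manual thresholds; "
                "add inputs.references (duos/trios of known relationships)"
            )
        mendel_lookup = {}
        for unit in references:
            if len(unit) == 3:
                child, p1, p2 = unit
                mendel_lookup[unit] = trio_mi_snp(snp, child, p1, p2)
                for parent in (p1, p2):
                    key = _pair_key(child, parent)
                    mendel_lookup[key] = duo_mi_snp(snp, *key)
            else:
                key = _pair_key(*unit)
                mendel_lookup[key] = duo_mi_snp(snp, *key)
        engine = ParentageClassifier(
            **{k: v for k, v in cfg.parentage.items() if k != "ssr_max_mismatch"}
        ).fit(references, ibd_lookup, mendel_lookup)
        t = engine.thresholds_
        say(f"calibration: z1_min={t.z1_min:.4f} mi_rate_ref_max={t.mi_rate_ref_max:.5f} "
            f"trio_rate_ref_max={t.trio_rate_ref_max}")

        ssr_max_mismatch = cfg.parentage.get("ssr_max_mismatch", 1)
        samples = snp.sample_ids
        for target in samples:
            if ssr is not None and target in ssr:
                trio_cands = search_trios(
                    target, ssr, snp, ibd_lookup, ssr_max_mismatch,
                    clone_pi=engine.clone_pi,
                )
            else:  # SNP-only mode: every non-clone pair is a candidate parent pair
                others = [
                    s for s in samples
                    if s != target and ibd_lookup[_pair_key(target, s)].PI_HAT <= engine.clone_pi
                ]
                from .parentage_engine import TrioCandidate

                trio_cands = []
                for i, a in enumerate(others):
                    for b in others[i + 1:]:
                        trio_cands.append(TrioCandidate(
                            a, b, [], trio_mi_snp(snp, target, a, b),
                            (ibd_lookup[_pair_key(target, a)], ibd_lookup[_pair_key(target, b)]),
                        ))
            for cand in trio_cands:
                legs = cand.ibd_legs
                duo_vs = tuple(
                    classify_duo(leg, duo_mi_snp(snp, *leg.pair), t) for leg in legs
                )
                v = engine.predict_trio(cand.trio_mendel, duo_vs, legs)
                if v.status == Verdict.REJECTED:
                    continue
                maternal = (
                    maternal_consistency((target, cand.parent1, cand.parent2), cpssr)
                    if cpssr is not None else "undetermined"
                )
                verdict_trios.append((v, maternal))
                strat = stratify_mi(cand.trio_mendel, class_map) if class_map else cand.trio_mendel
                trio_rows.append({
                    "offspring": target, "parent_1": cand.parent1, "parent_2": cand.parent2,
                    "status": v.status.value,
                    "Z1_leg1": legs[0].Z1, "Z1_leg2": legs[1].Z1,
                    "PI_HAT_leg1": legs[0].PI_HAT, "PI_HAT_leg2": legs[1].PI_HAT,
                    "trio_mi": cand.trio_mendel.mi_total,
                    "ppc_error_rate": cand.trio_mendel.error_rate,
                    "mi_merged": strat.mi_merged,
                    "maternal_candidate": maternal,
                })

        # duo verdicts on PO-like pairs (direct, symmetric)
        for r in ibd_lookup.values():
            if r.PI_HAT > engine.clone_pi:
                continue
            lo, hi = t.pi_hat_window
            if not (lo - 0.15 <= r.PI_HAT <= hi + 0.15):  # skip clearly unrelated pairs
                continue
            mendel = duo_mi_snp(snp, *r.pair)
            strat = stratify_mi(mendel, class_map) if class_map else mendel
            v = classify_duo(r, mendel, t)
            duo_rows.append({
                "sample_1": r.pair[0], "sample_2": r.pair[1],
                "status": v.status.value,
                "Z0": r.Z0, "Z1": r.Z1, "Z2": r.Z2, "PI_HAT": r.PI_HAT,
                "mi_total": mendel.mi_total, "mi_rate": mendel.mi_rate,
                "mi_merged": strat.mi_merged if class_map else None,
                "reduction_pct": strat.reduction_pct if class_map else None,
            })
        say(f"parentage: {len(trio_rows)} candidate trios kept, "
            f"{len(duo_rows)} first-degree duo rows")

    # ---- sibship ---------------------------------------------------------
    fs_rows, recon_rows = [], []
    if calls:
        groups = find_fullsib_groups(calls)
        po_pairs = {c.pair for c in calls if c.label == PO}
        for gi, grp in enumerate(groups):
            fs_rows.append({
                "group": gi + 1, "members": "|".join(grp.members), "soft": grp.soft,
            })
            if ssr is None:
                continue
            # a shared parent known in the panel: PO with every member
            shared = [
                s for s in snp.sample_ids
                if s not in grp.members
                and all(tuple(sorted((s, m))) in {tuple(sorted(p)) for p in po_pairs}
                        for m in grp.members)
            ]
            for parent in shared:
                try:
                    rec = reconstruct_missing_parent(
                        ssr[parent], [ssr[m] for m in grp.members]
                    )
                except Exception as e:  # incompatible sib set: report, don't abort
                    say(f"reconstruction skipped for group {gi + 1} via {parent}: {e}")
                    continue
                hits = scan_candidates(rec, ssr, ssr[parent], [ssr[m] for m in grp.members])
                recon_rows.append({
                    "group": gi + 1, "known_parent": parent,
                    "consistent": rec.consistent,
                    "profile": ";".join(
                        f"{l}:{a}/{b}" for l, (a, b) in rec.to_rows().items()
                    ),
                    "candidates": "|".join(
                        f"{h.sample_id}({sum(h.trio_mismatches.values())})" for h in hits
                    ),
                })
        say(f"sibship: {len(fs_rows)} full-sib groups")

    # ---- tree ------------------------------------------------------------
    newick = None
    if snp is not None and cfg.tree.get("enabled", True):
        dendro = UPGMADendrogram(
            n_bootstrap=cfg.tree.get("n_reps", 500),
            seed=cfg.tree.get("seed", cfg.seed),
            support_display_min=cfg.tree.get("support_display_min", 75),
        ).fit(snp)
        newick = dendro.tree_.to_newick()
        say(f"tree: {len(dendro.labels_)} leaves, "
            f"{cfg.tree.get('n_reps', 500)} bootstrap replicates")

    return ReportBundle(
        trio_table=pd.DataFrame(trio_rows),
        duo_table=pd.DataFrame(duo_rows),
        clone_table=clone_table,
        fs_groups=pd.DataFrame(fs_rows),
        reconstructed_parents=pd.DataFrame(recon_rows),
        ibd=ibd_df,
        qc_log=qc_log,
        newick=newick,
        run_log=run_log,
    )
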