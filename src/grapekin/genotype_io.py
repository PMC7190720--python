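"""Genotype containers and readers/writers for the formats the pipeline touches.

Three marker systems coexist in a germplasm panel:

* nuclear SSRs — multiallelic, genotypes are unordered pairs of integer
  fragment sizes (base pairs);
* biallelic SNPs — coded 0 (hom-ref) / 1 (het) / 2 (hom-alt) / missing;
* chloroplast SSRs — 8-locus haplotypes, maternally inherited, collapsed
  into letter-coded chlorotypes.

SSR allele sizes are assumed pre-binned: no size standardisation is applied
here because binning is instrument- and lab-specific.

Every writer emits a sidecar JSON manifest (``<path>.manifest.json``) with a
panel hash and the sample/locus counts, so downstream runs can verify they
are looking at the dataset they think they are.
"""

from __future__ import annotations

import hashlib
import json
import string
from dataclasses import dataclass, field
from pathlib import Path
from typing import Hashable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DataFormatError, IncomparableProfilesError

#: Sentinel code for a missing SNP call.
MISSING = -1

_NUCLEOTIDES = {"A", "C", "G", "T"}


@dataclass(frozen=True)
class Locus:
    """One marker descriptor: an SSR, a biallelic SNP or a chloroplast SSR."""

    name: str
    kind: str  # "SSR" | "SNP" | "cpSSR"
    ref: str | None = None
    alt: str | None = None
    motif: int | None = None

    def __post_init__(self):
        if self.kind not in ("SSR", "SNP", "cpSSR"):
            raise DataFormatError(f"unknown locus kind {self.kind!r} for {self.name!r}")
        if self.kind == "SNP":
            if self.ref not in _NUCLEOTIDES or self.alt not in _NUCLEOTIDES:
                raise DataFormatError(
                    f"SNP {self.name!r} needs ref/alt nucleotides, got {self.ref!r}/{self.alt!r}"
                )
            if self.ref == self.alt:
                raise DataFormatError(f"SNP {self.name!r} has ref == alt ({self.ref})")


@dataclass
class MarkerPanel:
    """Ordered collection of locus descriptors; order is stable across IO."""

    loci: list[Locus]

    def __post_init__(self):
        names = [l.name for l in self.loci]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise DataFormatError(f"duplicate locus names in panel: {dupes}")

    @property
    def names(self) -> list[str]:
        return [l.name for l in self.loci]

    def __len__(self) -> int:
        return len(self.loci)

    def __getitem__(self, name: str) -> Locus:
        for l in self.loci:
            if l.name == name:
                return l
        raise KeyError(name)

    def subset(self, names: Sequence[str]) -> "MarkerPanel":
        by_name = {l.name: l for l in self.loci}
        return MarkerPanel([by_name[n] for n in names])

    def content_hash(self) -> str:
        payload = json.dumps(
            [(l.name, l.kind, l.ref, l.alt, l.motif) for l in self.loci]
        ).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    @staticmethod
    def default_snp(names: Sequence[str], ref: str = "A", alt: str = "G") -> "MarkerPanel":
        """Placeholder panel for dialects (plain CSV) that carry no nucleotides."""
        return MarkerPanel([Locus(n, "SNP", ref, alt) for n in names])


@dataclass
class SSRProfile:
    """Per-sample multiallelic SSR genotypes.

    Allele pairs are stored sorted ascending; homozygotes as an equal pair;
    a missing locus as ``None``.
    """

    sample_id: str
    genotypes: dict[str, tuple[int, int] | None] = field(default_factory=dict)

    def __post_init__(self):
        fixed = {}
        for locus, pair in self.genotypes.items():
            if pair is None:
                fixed[locus] = None
                continue
            a, b = int(pair[0]), int(pair[1])
            if a <= 0 or b <= 0:
                raise DataFormatError(
                    f"non-positive allele size {pair} at {locus} for {self.sample_id}"
                )
            fixed[locus] = (a, b) if a <= b else (b, a)
        self.genotypes = fixed

    def alleles(self, locus: str) -> tuple[int, int] | None:
        return self.genotypes.get(locus)


class SNPGenotypeMatrix:
    """Samples x biallelic loci, codes {0, 1, 2, MISSING}.

    Parameters
    ----------
    sample_ids : ordered sample identifiers (rows).
    calls : integer array (n_samples, n_loci); ``MISSING`` (-1) for no-calls.
    panel : MarkerPanel of SNP loci (columns).
    quality : optional per-locus call-quality score in [0, 1].
    """

    def __init__(self, sample_ids, calls, panel, quality=None):
        self.sample_ids = list(sample_ids)
        self.calls = np.asarray(calls, dtype=np.int16)
        self.panel = panel
        self.quality = None if quality is None else np.asarray(quality, dtype=float)
        if self.calls.ndim != 2:
            raise DataFormatError("calls must be a 2-D matrix")
        if self.calls.shape != (len(self.sample_ids), len(panel)):
            raise DataFormatError(
                f"calls shape {self.calls.shape} != "
                f"({len(self.sample_ids)} samples, {len(panel)} loci)"
            )
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise DataFormatError(
                f"invalid genotype code {self.calls[i, j]} for sample "
                f"{self.sample_ids[i]!r} at locus {panel.names[j]!r}"
            )
        if self.quality is not None and len(self.quality) != len(panel):
            raise DataFormatError("quality vector length != locus count")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise DataFormatError("duplicate sample ids")
        self._row_index = {s: i for i, s in enumerate(self.sample_ids)}

    # -- basic accessors -------------------------------------------------
    @property
    def locus_ids(self) -> list[str]:
        return self.panel.names

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_loci(self) -> int:
        return len(self.panel)

    def row(self, sample_id: str) -> np.ndarray:
        try:
            return self.calls[self._row_index[sample_id]]
        except KeyError:
            raise KeyError(f"unknown sample id {sample_id!r}") from None

    # -- per-locus statistics (MISSING ignored) --------------------------
    def alt_freq(self) -> np.ndarray:
        """Alt-allele frequency per locus; NaN where every call is missing."""
        obs = self.calls >= 0
        n = obs.sum(axis=0)
        tot = np.where(obs, self.calls, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n > 0, tot / (2.0 * n), np.nan)

    def maf(self) -> np.ndarray:
        p = self.alt_freq()
        return np.minimum(p, 1.0 - p)

    def missing_fraction(self) -> np.ndarray:
        return (self.calls == MISSING).mean(axis=0)

    def genotype_counts(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(n_homref, n_het, n_homalt) per locus."""
        return (
            (self.calls == 0).sum(axis=0),
            (self.calls == 1).sum(axis=0),
            (self.calls == 2).sum(axis=0),
        )

    # -- subsetting ------------------------------------------------------
    def subset_loci(self, which) -> "SNPGenotypeMatrix":
        """Subset columns by boolean mask or list of locus names."""
        if isinstance(which, (list, tuple)) and which and isinstance(which[0], str):
            idx = [self.locus_ids.index(n) for n in which]
        else:
            idx = np.flatnonzero(np.asarray(which, dtype=bool))
        names = [self.locus_ids[i] for i in idx]
        q = None if self.quality is None else self.quality[list(idx)]
        return SNPGenotypeMatrix(
            self.sample_ids, self.calls[:, list(idx)], self.panel.subset(names), q
        )

    def subset_samples(self, ids: Sequence[str]) -> "SNPGenotypeMatrix":
        idx = [self._row_index[s] for s in ids]
        return SNPGenotypeMatrix(list(ids), self.calls[idx], self.panel, self.quality)

    def to_profiles(self) -> dict[str, dict[str, int | None]]:
        """Per-sample locus->code maps (None for missing) for profile matching."""
        out = {}
        for i, s in enumerate(self.sample_ids):
            row = self.calls[i]
            out[s] = {
                l: (None if row[j] == MISSING else int(row[j]))
                for j, l in enumerate(self.locus_ids)
            }
        return out


class ChlorotypeTable:
    """Per-sample chloroplast SSR haplotypes (8 loci) and chlorotype labels.

    Samples with identical *complete* haplotypes receive identical letter
    labels (A, B, C, ... in order of first appearance); samples with any
    missing cpSSR call stay unlabelled (None).
    """

    N_LOCI = 8

    def __init__(self, haplotypes: Mapping[str, Sequence[int | None]]):
        self.haplotypes: dict[str, tuple] = {}
        for sid, sizes in haplotypes.items():
            sizes = tuple(None if s is None else int(s) for s in sizes)
            if len(sizes) != self.N_LOCI:
                raise DataFormatError(
                    f"chlorotype haplotype for {sid!r} has {len(sizes)} loci, "
                    f"expected {self.N_LOCI}"
                )
            self.haplotypes[sid] = sizes
        self.labels = self._assign_labels()

    def _assign_labels(self) -> dict[str, str | None]:
        letters = list(string.ascii_uppercase)
        seen: dict[tuple, str] = {}
        labels: dict[str, str | None] = {}
        for sid, hap in self.haplotypes.items():
            if any(s is None for s in hap):
                labels[sid] = None
                continue
            if hap not in seen:
                k = len(seen)
                seen[hap] = letters[k] if k < 26 else f"Z{k}"
            labels[sid] = seen[hap]
        return labels

    def label(self, sample_id: str) -> str | None:
        return self.labels.get(sample_id)


# ---------------------------------------------------------------------------
# manifest sidecars
# ---------------------------------------------------------------------------

def _write_manifest(path: Path, panel: MarkerPanel, n_samples: int) -> None:
    manifest = {
        "panel_hash": panel.content_hash(),
        "n_samples": n_samples,
        "n_loci": len(panel),
        "loci": [
            {"name": l.name, "kind": l.kind, "ref": l.ref, "alt": l.alt, "motif": l.motif}
            for l in panel.loci
        ],
    }
    Path(str(path) + ".manifest.json").write_text(json.dumps(manifest, indent=1))


def _read_manifest_panel(path: Path) -> MarkerPanel | None:
    mpath = Path(str(path) + ".manifest.json")
    if not mpath.exists():
        return None
    loci = json.loads(mpath.read_text())["loci"]
    return MarkerPanel([Locus(**l) for l in loci])


# ---------------------------------------------------------------------------
# SSR tables
# ---------------------------------------------------------------------------

def read_ssr_table(path) -> tuple[list[SSRProfile], MarkerPanel]:
    """Read an SSR genotype CSV.

    Dialect: header ``sample_id, <locus>_1, <locus>_2, ...`` (two columns per
    locus); empty cells mean missing. A locus is missing when either of its
    two cells is empty.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    cols = list(df.columns)
    if not cols or cols[0] != "sample_id":
        raise DataFormatError(f"{path}: first column must be 'sample_id'")
    allele_cols = cols[1:]
    if len(allele_cols) % 2 != 0:
        raise DataFormatError(f"{path}: odd allele column count ({len(allele_cols)})")
    loci = []
    for k in range(0, len(allele_cols), 2):
        c1, c2 = allele_cols[k], allele_cols[k + 1]
        if not (c1.endswith("_1") and c2.endswith("_2") and c1[:-2] == c2[:-2]):
            raise DataFormatError(f"{path}: columns {c1!r}/{c2!r} do not form a locus pair")
        loci.append(c1[:-2])
    panel = MarkerPanel([Locus(n, "SSR") for n in loci])
    profiles = []
    for r, rec in df.iterrows():
        genotypes: dict[str, tuple[int, int] | None] = {}
        for k, locus in enumerate(loci):
            v1 = rec[allele_cols[2 * k]].strip()
            v2 = rec[allele_cols[2 * k + 1]].strip()
            if v1 == "" or v2 == "":
                genotypes[locus] = None
                continue
            try:
                genotypes[locus] = (int(v1), int(v2))
            except ValueError:
                raise DataFormatError(
                    f"{path}: non-integer allele at row {r + 2}, "
                    f"column {locus}: {v1!r}/{v2!r}"
                ) from None
        profiles.append(SSRProfile(rec["sample_id"], genotypes))
    return profiles, panel


def write_ssr_table(profiles: Iterable[SSRProfile], panel: MarkerPanel, path) -> None:
    path = Path(path)
    profiles = list(profiles)
    header = ["sample_id"]
    for n in panel.names:
        header += [f"{n}_1", f"{n}_2"]
    rows = []
    for p in profiles:
        row = [p.sample_id]
        for n in panel.names:
            pair = p.genotypes.get(n)
            row += ["", ""] if pair is None else [str(pair[0]), str(pair[1])]
        rows.append(row)
    pd.DataFrame(rows, columns=header).to_csv(path, index=False)
    _write_manifest(path, panel, len(profiles))


# ---------------------------------------------------------------------------
# SNP matrices: csv / ped+map / VCF
# ---------------------------------------------------------------------------

def read_snp_matrix(path, format: str, panel: MarkerPanel | None = None) -> SNPGenotypeMatrix:
    """Read a SNP genotype matrix.

    format "csv": sample rows x locus columns of 0/1/2/NA (empty = missing);
    format "pedmap": whitespace ped (6 leading columns + 2 allele columns per
    SNP) with a companion ``.map`` file next to it;
    format "vcf": diploid GT fields of a biallelic VCF.

    When no panel is given, the sidecar manifest is used if present; the csv
    dialect otherwise falls back to placeholder A/G nucleotides.
    """
    path = Path(path)
    if format == "csv":
        return _read_snp_csv(path, panel)
    if format == "pedmap":
        return _read_pedmap(path, panel)
    if format == "vcf":
        return _read_vcf(path)
    raise DataFormatError(f"unknown SNP matrix format {format!r}")


def _read_snp_csv(path: Path, panel: MarkerPanel | None) -> SNPGenotypeMatrix:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if df.columns[0] != "sample_id":
        raise DataFormatError(f"{path}: first column must be 'sample_id'")
    names = list(df.columns[1:])
    if panel is None:
        panel = _read_manifest_panel(path) or MarkerPanel.default_snp(names)
    if panel.names != names:
        raise DataFormatError(f"{path}: columns do not match the supplied panel")
    calls = np.full((len(df), len(names)), MISSING, dtype=np.int16)
    for j, col in enumerate(names):
        vals = df[col].str.strip()
        ok = ~vals.isin(("", "NA", "na", "NaN"))
        parsed = pd.to_numeric(vals.where(ok, "-1"), errors="coerce")
        if parsed.isna().any():
            r = int(parsed.index[parsed.isna()][0])
            raise DataFormatError(f"{path}: bad genotype {vals.iloc[r]!r} at row {r + 2}, locus {col}")
        calls[:, j] = parsed.astype(int)
    return SNPGenotypeMatrix(list(df["sample_id"]), calls, panel)


def write_snp_csv(matrix: SNPGenotypeMatrix, path) -> None:
    path = Path(path)
    df = pd.DataFrame(
        matrix.calls.astype(object), index=matrix.sample_ids, columns=matrix.locus_ids
    )
    df = df.where(df != MISSING, "")
    df.index.name = "sample_id"
    df.to_csv(path)
    _write_manifest(path, matrix.panel, matrix.n_samples)


def _read_pedmap(ped_path: Path, panel: MarkerPanel | None) -> SNPGenotypeMatrix:
    map_path = ped_path.with_suffix(".map")
    if not map_path.exists():
        raise DataFormatError(f"companion map file {map_path} not found")
    names = []
    for line in map_path.read_text().splitlines():
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) not in (3, 4):
            raise DataFormatError(f"{map_path}: expected 3 or 4 columns, got {len(parts)}")
        names.append(parts[1])
    if panel is None:
        panel = _read_manifest_panel(ped_path)
    sample_ids, rows = [], []
    for ln, line in enumerate(ped_path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 6 + 2 * len(names):
            raise DataFormatError(
                f"{ped_path}:{ln}: {len(parts)} fields != 6 + 2 x {len(names)} map loci"
            )
        sample_ids.append(parts[1])  # first 6 columns kept but only IID used
        rows.append(parts[6:])
    if panel is None:
        # infer ref/alt per locus: alphabetically first observed allele is ref
        loci = []
        for j, n in enumerate(names):
            seen = sorted(
                {r[2 * j + k] for r in rows for k in (0, 1)} - {"0"}
            )
            ref = seen[0] if seen else "A"
            alt = seen[1] if len(seen) > 1 else ({"A": "G"}.get(ref, "A"))
            loci.append(Locus(n, "SNP", ref, alt))
        panel = MarkerPanel(loci)
    if panel.names != names:
        raise DataFormatError(f"{ped_path}: map loci do not match the supplied panel")
    calls = np.full((len(sample_ids), len(names)), MISSING, dtype=np.int16)
    for i, r in enumerate(rows):
        for j, locus in enumerate(panel.loci):
            a1, a2 = r[2 * j], r[2 * j + 1]
            if a1 == "0" or a2 == "0":
                continue
            try:
                calls[i, j] = _allele_code(a1, locus) + _allele_code(a2, locus)
            except KeyError as e:
                raise DataFormatError(
                    f"{ped_path}: allele {e.args[0]!r} at locus {locus.name} "
                    f"not in {{ref={locus.ref}, alt={locus.alt}, 0}}"
                ) from None
    return SNPGenotypeMatrix(sample_ids, calls, panel)


def _allele_code(a: str, locus: Locus) -> int:
    if a == locus.ref:
        return 0
    if a == locus.alt:
        return 1
    raise KeyError(a)


def write_pedmap(matrix: SNPGenotypeMatrix, ped_path) -> None:
    ped_path = Path(ped_path)
    map_lines = [
        f"0\t{n}\t0\t{j + 1}" for j, n in enumerate(matrix.locus_ids)
    ]
    ped_path.with_suffix(".map").write_text("\n".join(map_lines) + "\n")
    lines = []
    for i, sid in enumerate(matrix.sample_ids):
        fields = [sid, sid, "0", "0", "0", "-9"]
        for j, locus in enumerate(matrix.panel.loci):
            g = matrix.calls[i, j]
            if g == MISSING:
                fields += ["0", "0"]
            else:
                fields += [locus.ref if g < 2 else locus.alt,
                           locus.ref if g < 1 else locus.alt]
        lines.append(" ".join(fields))
    ped_path.write_text("\n".join(lines) + "\n")
    _write_manifest(ped_path, matrix.panel, matrix.n_samples)


def _read_vcf(path: Path) -> SNPGenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    loci, columns = [], []
    for v in vcf:
        if len(v.ALT) != 1:
            raise DataFormatError(f"{path}: {v.ID or v.POS}: only biallelic records supported")
        loci.append(Locus(v.ID or f"{v.CHROM}_{v.POS}", "SNP", v.REF, v.ALT[0]))
        col = np.full(len(sample_ids), MISSING, dtype=np.int16)
        for i, g in enumerate(v.genotypes):
            a1, a2 = g[0], g[1]
            if a1 >= 0 and a2 >= 0:
                col[i] = a1 + a2
        columns.append(col)
    calls = (
        np.column_stack(columns) if columns else np.empty((len(sample_ids), 0), dtype=np.int16)
    )
    return SNPGenotypeMatrix(sample_ids, calls, MarkerPanel(loci))


def write_vcf(matrix: SNPGenotypeMatrix, path) -> None:
    """Write a minimal VCF 4.2 (GT only, all records on chromosome '1')."""
    path = Path(path)
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "##contig=<ID=1>",
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(matrix.sample_ids),
    ]
    gt_text = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    for j, locus in enumerate(matrix.panel.loci):
        gts = "\t".join(gt_text[int(g)] for g in matrix.calls[:, j])
        lines.append(f"1\t{j + 1}\t{locus.name}\t{locus.ref}\t{locus.alt}\t.\t.\t.\tGT\t{gts}")
    path.write_text("\n".join(lines) + "\n")
    _write_manifest(path, matrix.panel, matrix.n_samples)


# ---------------------------------------------------------------------------
# chlorotype tables
# ---------------------------------------------------------------------------

def read_chlorotype_table(path) -> ChlorotypeTable:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    cp_cols = [c for c in df.columns if c.startswith("cp")]
    if len(cp_cols) != ChlorotypeTable.N_LOCI:
        raise DataFormatError(
            f"{path}: expected {ChlorotypeTable.N_LOCI} cp columns, found {len(cp_cols)}"
        )
    haps = {}
    for _, rec in df.iterrows():
        haps[rec["sample_id"]] = [
            None if rec[c].strip() == "" else int(rec[c]) for c in cp_cols
        ]
    return ChlorotypeTable(haps)


def write_chlorotype_table(table: ChlorotypeTable, path) -> None:
    rows = []
    for sid, hap in table.haplotypes.items():
        rows.append(
            {"sample_id": sid,
             **{f"cp{j + 1}": ("" if a is None else a) for j, a in enumerate(hap)},
             "chlorotype": table.labels[sid] or ""}
        )
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# profile matching (synonym / clone identification)
# ---------------------------------------------------------------------------

def match_profiles(
    query: Mapping[str, Hashable],
    database: Mapping[str, Mapping[str, Hashable]],
    max_mismatch_loci: int | None = 0,
) -> list[tuple[str, int, int]]:
    """Match one genotype profile against a database of profiles.

    ``query`` and each database entry are locus -> genotype maps (any hashable
    genotype representation; ``None`` means missing). Loci missing in either
    profile are excluded from the comparison; a mismatch is any compared locus
    with unequal genotype.

    Returns ``(sample_id, n_mismatch, n_compared)`` for entries with
    ``n_mismatch <= max_mismatch_loci`` (all entries when None), sorted by
    mismatch count then id. Raises IncomparableProfilesError if an entry
    shares zero comparable loci with the query.
    """
    q = {l: g for l, g in query.items() if g is not None}
    out = []
    for sid, prof in database.items():
        n_cmp = n_mm = 0
        for locus, g in prof.items():
            if g is None or locus not in q:
                continue
            n_cmp += 1
            if g != q[locus]:
                n_mm += 1
        if n_cmp == 0:
            raise IncomparableProfilesError(
                f"profile {sid!r} shares zero comparable loci with the query"
            )
        if max_mismatch_loci is None or n_mm <= max_mismatch_loci:
            out.append((sid, n_mm, n_cmp))
    out.sort(key=lambda t: (t[1], t[0]))
    return out


def check_identification_set(
    matrix: SNPGenotypeMatrix, locus_subset: Sequence[str]
) -> list[tuple[str, str]]:
    """Check whether a locus subset univocally identifies every sample.

    Returns the colliding sample pairs: pairs with no differing genotype over
    the subset (loci missing in either sample are excluded from comparison, so
    clones and indistinguishable samples both collide). Empty list means the
    subset discriminates all samples.
    """
    if len(locus_subset) == 0:
        raise DataFormatError("identification locus subset is empty")
    sub = matrix.subset_loci(list(locus_subset))
    collisions = []
    for i in range(sub.n_samples):
        for j in range(i + 1, sub.n_samples):
            a, b = sub.calls[i], sub.calls[j]
            both = (a != MISSING) & (b != MISSING)
            if not np.any(both & (a != b)):
                collisions.append((sub.sample_ids[i], sub.sample_ids[j]))
    return collisions
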