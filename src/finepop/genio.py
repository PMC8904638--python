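"""Genotype containers, format I/O, and cohort filters.

Diploid SNP data live in :class:`GenotypeMatrix` (individuals x SNPs, calls
counting copies of the designated allele ``a1``); phased data live in
:class:`HaplotypePanel` (two haplotype rows per individual). Supported text
formats: PLINK .ped/.map, EIGENSTRAT geno/snp/ind, and minimal VCF (GT only).

Filters implement the usual array-QC stack: per-SNP and per-individual
missingness, minor-allele frequency, optional Hardy-Weinberg, pairwise
method-of-moments relatedness (PI_HAT), and sliding-window r^2 pruning.

Conventions
-----------
* Missing genotype sentinel is ``MISSING`` (-1).
* Coordinates are 1-based bp; genetic positions are cM floats.
* PLINK text does not declare which allele is counted, so on read the
  counted allele ``a1`` is taken as the minor allele (ties broken
  alphabetically).  EIGENSTRAT and VCF carry explicit allele roles and
  round-trip exactly; for VCF, ``a1`` is the ALT allele (GT ``0/1`` -> call 1).
* Population/subgroup labels that a format cannot carry are written to a
  ``<prefix>.groups.tsv`` sidecar, auto-loaded on read when present.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

MISSING = -1

SNP_COLS = ["chrom", "id", "cm", "bp", "a1", "a2"]
SAMPLE_COLS = ["id", "population", "subgroup"]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class FormatError(ValueError):
    """Raised when a genotype file is malformed or inconsistent."""


def _as_snp_meta(df: pd.DataFrame) -> pd.DataFrame:
    df = df.reset_index(drop=True)
    missing = [c for c in SNP_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"snp_meta missing columns {missing}")
    return df[SNP_COLS].astype(
        {"chrom": str, "id": str, "cm": float, "bp": np.int64, "a1": str, "a2": str}
    )


def _as_sample_meta(df: pd.DataFrame) -> pd.DataFrame:
    df = df.reset_index(drop=True).copy()
    if "population" not in df.columns:
        df["population"] = "POP"
    if "subgroup" not in df.columns:
        df["subgroup"] = df["population"]
    return df[SAMPLE_COLS].astype(str)


def _check_positions(snp_meta: pd.DataFrame) -> None:
    for chrom, sub in snp_meta.groupby("chrom", sort=False):
        bp = sub["bp"].to_numpy()
        if np.any(np.diff(bp) <= 0):
            raise ValueError(f"bp positions not strictly increasing on chrom {chrom}")


@dataclass
class GenotypeMatrix:
    """Diploid calls (count of allele ``a1``) with SNP and sample metadata."""

    calls: np.ndarray
    snp_meta: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        self.snp_meta = _as_snp_meta(self.snp_meta)
        self.sample_meta = _as_sample_meta(self.sample_meta)
        if self.calls.ndim != 2:
            raise ValueError("calls must be 2-D (individuals x SNPs)")
        if self.calls.shape != (len(self.sample_meta), len(self.snp_meta)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match metadata "
                f"({len(self.sample_meta)} individuals, {len(self.snp_meta)} SNPs)"
            )
        bad = ~np.isin(self.calls, (MISSING, 0, 1, 2))
        if bad.any():
            raise ValueError("calls must be in {0,1,2} or MISSING")
        _check_positions(self.snp_meta)

    @property
    def n_ind(self) -> int:
        return self.calls.shape[0]

    @property
    def n_snp(self) -> int:
        return self.calls.shape[1]

    def dosage(self) -> np.ndarray:
        """Calls as float with NaN at missing entries."""
        d = self.calls.astype(float)
        d[self.calls == MISSING] = np.nan
        return d

    def take_snps(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            self.calls[:, index],
            self.snp_meta.iloc[index],
            self.sample_meta,
        )

    def take_inds(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            self.calls[index, :],
            self.snp_meta,
            self.sample_meta.iloc[index],
        )

    def equals(self, other: "GenotypeMatrix") -> bool:
        return (
            np.array_equal(self.calls, other.calls)
            and self.snp_meta.equals(other.snp_meta)
            and self.sample_meta.equals(other.sample_meta)
        )


@dataclass
class HaplotypePanel:
    """Phased binary haplotypes; rows 2i and 2i+1 belong to individual i.

    Allele 1 corresponds to ``a1`` of the SNP metadata.
    """

    haplotypes: np.ndarray
    snp_meta: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.uint8)
        self.snp_meta = _as_snp_meta(self.snp_meta)
        self.sample_meta = _as_sample_meta(self.sample_meta)
        if self.haplotypes.ndim != 2 or self.haplotypes.shape[0] % 2:
            raise ValueError("haplotypes must be (2*n_ind, n_snp)")
        if self.haplotypes.shape != (2 * len(self.sample_meta), len(self.snp_meta)):
            raise ValueError("haplotype dimensions do not match metadata")
        if not np.isin(self.haplotypes, (0, 1)).all():
            raise ValueError("haplotypes must be binary")
        _check_positions(self.snp_meta)

    @property
    def n_ind(self) -> int:
        return self.haplotypes.shape[0] // 2

    @property
    def n_snp(self) -> int:
        return self.haplotypes.shape[1]

    def to_genotypes(self) -> GenotypeMatrix:
        calls = self.haplotypes[0::2] + self.haplotypes[1::2]
        return GenotypeMatrix(calls.astype(np.int8), self.snp_meta, self.sample_meta)

    def concat_individuals(self, other: "HaplotypePanel") -> "HaplotypePanel":
        if not self.snp_meta.equals(other.snp_meta):
            raise ValueError("panels must share SNP metadata")
        return HaplotypePanel(
            np.vstack([self.haplotypes, other.haplotypes]),
            self.snp_meta,
            pd.concat([self.sample_meta, other.sample_meta], ignore_index=True),
        )


# ---------------------------------------------------------------------------
# sidecar for labels the formats cannot carry


def _write_groups(prefix: str, sample_meta: pd.DataFrame) -> None:
    sample_meta.to_csv(f"{prefix}.groups.tsv", sep="\t", index=False)


def _read_groups(prefix: str, fallback: pd.DataFrame) -> pd.DataFrame:
    path = f"{prefix}.groups.tsv"
    if os.path.exists(path):
        df = pd.read_csv(path, sep="\t", dtype=str)
        return _as_sample_meta(df)
    return fallback


# ---------------------------------------------------------------------------
# PLINK text


def write_plink(G: GenotypeMatrix, prefix: str) -> None:
    prefix = str(prefix)
    Path(prefix).parent.mkdir(parents=True, exist_ok=True)
    with open(prefix + ".map", "w") as fh:
        for _, s in G.snp_meta.iterrows():
            fh.write(f"{s.chrom}\t{s.id}\t{s.cm:.8g}\t{s.bp}\n")
    a1 = G.snp_meta["a1"].to_numpy()
    a2 = G.snp_meta["a2"].to_numpy()
    with open(prefix + ".ped", "w") as fh:
        for i in range(G.n_ind):
            row = G.sample_meta.iloc[i]
            fields = [row.population, row.id, "0", "0", "0", "-9"]
            g = G.calls[i]
            for j in range(G.n_snp):
                if g[j] == MISSING:
                    fields += ["0", "0"]
                elif g[j] == 0:
                    fields += [a2[j], a2[j]]
                elif g[j] == 1:
                    fields += [a1[j], a2[j]]
                else:
                    fields += [a1[j], a1[j]]
            fh.write(" ".join(fields) + "\n")
    _write_groups(prefix, G.sample_meta)


def read_plink(prefix: str) -> GenotypeMatrix:
    prefix = str(prefix)
    snps = []
    with open(prefix + ".map") as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if len(parts) != 4:
                raise FormatError(f"{prefix}.map line {lineno}: expected 4 fields")
            snps.append((parts[0], parts[1], float(parts[2]), int(parts[3])))
    if not snps:
        raise FormatError(f"{prefix}.map is empty")
    m = len(snps)
    sample_rows = []
    allele_rows = []
    with open(prefix + ".ped") as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if len(parts) != 6 + 2 * m:
                raise FormatError(
                    f"{prefix}.ped line {lineno}: expected {6 + 2 * m} fields, got {len(parts)}"
                )
            sample_rows.append((parts[1], parts[0], parts[0]))
            allele_rows.append(parts[6:])
    alleles = np.array(allele_rows)  # (n, 2m)
    n = len(sample_rows)
    calls = np.full((n, m), MISSING, dtype=np.int8)
    a1_list, a2_list = [], []
    for j in range(m):
        pair = alleles[:, 2 * j : 2 * j + 2]
        flat = pair.ravel()
        observed = flat[flat != "0"]
        uniq, counts = np.unique(observed, return_counts=True)
        if len(uniq) == 0:
            a1, a2 = "A", "G"
        elif len(uniq) == 1:
            a1, a2 = uniq[0], "?"
        elif len(uniq) == 2:
            # minor allele counted; alphabetical tie-break
            order = np.lexsort((uniq, counts))
            a1, a2 = uniq[order[0]], uniq[order[1]]
        else:
            raise FormatError(f"{prefix}.ped SNP {snps[j][1]}: more than 2 alleles")
        a1_list.append(a1)
        a2_list.append(a2)
        nonmiss = (pair[:, 0] != "0") & (pair[:, 1] != "0")
        calls[nonmiss, j] = (pair[nonmiss] == a1).sum(axis=1)
    snp_meta = pd.DataFrame(
        {
            "chrom": [s[0] for s in snps],
            "id": [s[1] for s in snps],
            "cm": [s[2] for s in snps],
            "bp": [s[3] for s in snps],
            "a1": a1_list,
            "a2": a2_list,
        }
    )
    sample_meta = _read_groups(
        prefix,
        pd.DataFrame(sample_rows, columns=["id", "population", "subgroup"]),
    )
    return GenotypeMatrix(calls, snp_meta, sample_meta)


# ---------------------------------------------------------------------------
# EIGENSTRAT


def write_eigenstrat(G: GenotypeMatrix, prefix: str) -> None:
    prefix = str(prefix)
    Path(prefix).parent.mkdir(parents=True, exist_ok=True)
    with open(prefix + ".snp", "w") as fh:
        for _, s in G.snp_meta.iterrows():
            fh.write(f"{s.id}\t{s.chrom}\t{s.cm / 100.0:.10g}\t{s.bp}\t{s.a1}\t{s.a2}\n")
    geno = G.calls.T.astype(np.int64)  # rows = SNPs
    geno[geno == MISSING] = 9
    with open(prefix + ".geno", "w") as fh:
        for row in geno:
            fh.write("".join(map(str, row)) + "\n")
    with open(prefix + ".ind", "w") as fh:
        for _, r in G.sample_meta.iterrows():
            fh.write(f"{r.id}\tU\t{r.population}\n")
    _write_groups(prefix, G.sample_meta)


def read_eigenstrat(prefix: str) -> GenotypeMatrix:
    prefix = str(prefix)
    snp = pd.read_csv(
        prefix + ".snp",
        sep=r"\s+",
        header=None,
        names=["id", "chrom", "morgans", "bp", "a1", "a2"],
        dtype={"id": str, "chrom": str, "a1": str, "a2": str},
    )
    if snp.empty:
        raise FormatError(f"{prefix}.snp is empty")
    ind = pd.read_csv(
        prefix + ".ind", sep=r"\s+", header=None, names=["id", "sex", "population"], dtype=str
    )
    rows = []
    with open(prefix + ".geno") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if len(line) != len(ind):
                raise FormatError(
                    f"{prefix}.geno line {lineno}: {len(line)} genotypes for {len(ind)} individuals"
                )
            rows.append(np.frombuffer(line.encode(), dtype=np.uint8) - ord("0"))
    if len(rows) != len(snp):
        raise FormatError(
            f"{prefix}.geno has {len(rows)} SNPs but {prefix}.snp lists {len(snp)}"
        )
    calls = np.array(rows, dtype=np.int8).T
    calls[calls == 9] = MISSING
    snp_meta = pd.DataFrame(
        {
            "chrom": snp["chrom"],
            "id": snp["id"],
            "cm": snp["morgans"] * 100.0,
            "bp": snp["bp"],
            "a1": snp["a1"],
            "a2": snp["a2"],
        }
    )
    sample_meta = _read_groups(
        prefix,
        pd.DataFrame({"id": ind["id"], "population": ind["population"]}),
    )
    return GenotypeMatrix(calls, snp_meta, sample_meta)


# ---------------------------------------------------------------------------
# minimal VCF (GT only); a1 = ALT


def write_vcf(G: GenotypeMatrix, path: str) -> None:
    path = str(path)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    gt_code = {MISSING: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=CM,Number=1,Type=Float,Description="Genetic position (cM)">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in G.snp_meta["chrom"].unique():
            max_bp = int(G.snp_meta.loc[G.snp_meta.chrom == chrom, "bp"].max())
            fh.write(f"##contig=<ID={chrom},length={max_bp + 1}>\n")
        samples = "\t".join(G.sample_meta["id"])
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}\n")
        for j, s in G.snp_meta.iterrows():
            gts = "\t".join(gt_code[int(g)] for g in G.calls[:, j])
            fh.write(
                f"{s.chrom}\t{s.bp}\t{s.id}\t{s.a2}\t{s.a1}\t.\t.\tCM={s.cm:.8g}\tGT\t{gts}\n"
            )
    _write_groups(os.path.splitext(path)[0], G.sample_meta)


def read_vcf(path: str) -> GenotypeMatrix:
    from cyvcf2 import VCF

    path = str(path)
    vcf = VCF(path)
    samples = list(vcf.samples)
    rows, meta = [], []
    for var in vcf:
        # cyvcf2 gt_types: 0=HOM_REF, 1=HET, 2=UNKNOWN, 3=HOM_ALT
        gt = np.asarray(var.gt_types)
        call = np.full(len(samples), MISSING, dtype=np.int8)
        call[gt == 0] = 0
        call[gt == 1] = 1
        call[gt == 3] = 2
        rows.append(call)
        cm = var.INFO.get("CM")
        meta.append(
            (
                var.CHROM,
                var.ID or f"{var.CHROM}:{var.POS}",
                float(cm) if cm is not None else 0.0,
                var.POS,
                var.ALT[0] if var.ALT else "?",
                var.REF,
            )
        )
    if not rows:
        raise FormatError(f"{path}: no variants")
    calls = np.array(rows, dtype=np.int8).T
    snp_meta = pd.DataFrame(meta, columns=SNP_COLS)
    sample_meta = _read_groups(
        os.path.splitext(path)[0], pd.DataFrame({"id": samples})
    )
    return GenotypeMatrix(calls, snp_meta, sample_meta)


_FORMATS = {
    "plink-text": (read_plink, write_plink),
    "eigenstrat": (read_eigenstrat, write_eigenstrat),
    "vcf": (read_vcf, write_vcf),
}


def read_genotypes(path: str, format: str) -> GenotypeMatrix:
    """Read genotypes; ``format`` is one of plink-text / eigenstrat / vcf."""
    if format not in _FORMATS:
        raise ValueError(f"unknown format {format!r}")
    return _FORMATS[format][0](path)


def write_genotypes(G: GenotypeMatrix, path: str, format: str) -> None:
    if format not in _FORMATS:
        raise ValueError(f"unknown format {format!r}")
    _FORMATS[format][1](G, path)


# ---------------------------------------------------------------------------
# QC filters


@dataclass
class QCThresholds:
    """Cohort QC cutoffs; all fractions in [0, 1]."""

    max_snp_missing: float = 0.05
    max_ind_missing: float = 0.05
    min_maf: float = 0.01
    hwe_p_floor: float | None = None  # disabled unless set
    relatedness_cutoff: float = 0.25

    def __post_init__(self) -> None:
        for name in ("max_snp_missing", "max_ind_missing", "min_maf", "relatedness_cutoff"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.01:
                raise ValueError(f"{name}={v} outside [0,1]")
        if self.hwe_p_floor is not None and not 0.0 <= self.hwe_p_floor <= 1.0:
            raise ValueError("hwe_p_floor outside [0,1]")


def _maf(calls: np.ndarray) -> np.ndarray:
    ok = calls != MISSING
    n_chrom = 2 * ok.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(ok, calls, 0).sum(axis=0) / np.where(n_chrom > 0, n_chrom, 1)
    p = np.where(n_chrom > 0, p, np.nan)
    return np.minimum(p, 1 - p)


def _hwe_p(calls: np.ndarray) -> np.ndarray:
    """Chi-square (1 df) HWE p-value per SNP; NaN where undefined."""
    from scipy.stats import chi2

    ok = calls != MISSING
    n = ok.sum(axis=0).astype(float)
    n_aa = ((calls == 2) & ok).sum(axis=0)
    n_ab = ((calls == 1) & ok).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = (2 * n_aa + n_ab) / (2 * n)
        q = 1 - p
        exp = np.stack([n * q**2, 2 * n * p * q, n * p**2])
        obs = np.stack([n - n_aa - n_ab, n_ab, n_aa])
        stat = np.where(exp > 0, (obs - exp) ** 2 / np.where(exp > 0, exp, 1), 0).sum(axis=0)
        pval = chi2.sf(stat, df=1)
    pval = np.where((n > 0) & (p > 0) & (q > 0), pval, np.nan)
    return pval


def qc_filter(G: GenotypeMatrix, thresholds: QCThresholds) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Apply filters in the fixed order SNP missingness -> individual
    missingness -> MAF -> optional HWE; returns (filtered, removal report)."""
    report_rows: list[tuple[str, str, str, float]] = []

    miss_rate = (G.calls == MISSING).mean(axis=0)
    keep_snp = miss_rate <= thresholds.max_snp_missing
    for j in np.flatnonzero(~keep_snp):
        report_rows.append((G.snp_meta["id"].iat[j], "snp", "missingness", miss_rate[j]))
    G = G.take_snps(keep_snp)

    ind_miss = (G.calls == MISSING).mean(axis=1) if G.n_snp else np.zeros(G.n_ind)
    keep_ind = ind_miss <= thresholds.max_ind_missing
    for i in np.flatnonzero(~keep_ind):
        report_rows.append((G.sample_meta["id"].iat[i], "individual", "missingness", ind_miss[i]))
    G = G.take_inds(keep_ind)

    maf = _maf(G.calls)
    keep_snp = ~(np.nan_to_num(maf, nan=0.0) < thresholds.min_maf)
    if thresholds.min_maf > 0:
        keep_snp = np.nan_to_num(maf, nan=-1.0) >= thresholds.min_maf
    for j in np.flatnonzero(~keep_snp):
        report_rows.append((G.snp_meta["id"].iat[j], "snp", "maf", float(np.nan_to_num(maf[j]))))
    G = G.take_snps(keep_snp)

    if thresholds.hwe_p_floor is not None:
        pv = _hwe_p(G.calls)
        keep_snp = ~(np.nan_to_num(pv, nan=1.0) < thresholds.hwe_p_floor)
        for j in np.flatnonzero(~keep_snp):
            report_rows.append((G.snp_meta["id"].iat[j], "snp", "hwe", float(pv[j])))
        G = G.take_snps(keep_snp)

    report = pd.DataFrame(report_rows, columns=["item", "kind", "reason", "value"])
    return G, report


# ---------------------------------------------------------------------------
# relatedness (method-of-moments PI_HAT)


def pi_hat_matrix(G: GenotypeMatrix) -> np.ndarray:
    """Pairwise PI_HAT = k2 + k1/2 from IBS counts, PLINK-style method of
    moments (no small-sample allele-count correction)."""
    calls = G.calls
    n = G.n_ind
    ok = calls != MISSING
    p = _maf_freq(calls)
    q = 1 - p
    # conditional IBS probabilities given IBD state, per SNP
    e0_ibd0 = 2 * p**2 * q**2
    e1_ibd0 = 4 * p**3 * q + 4 * p * q**3
    e2_ibd0 = 1 - e0_ibd0 - e1_ibd0
    e1_ibd1 = 2 * p * q
    e2_ibd1 = 1 - e1_ibd1
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            use = ok[i] & ok[j]
            if not use.any():
                out[i, j] = out[j, i] = np.nan
                continue
            gi, gj = calls[i, use], calls[j, use]
            diff = np.abs(gi - gj)
            ibs0 = (diff == 2).sum()
            ibs1 = (diff == 1).sum()
            ibs2 = (diff == 0).sum()
            E0 = e0_ibd0[use].sum()
            k0 = ibs0 / E0 if E0 > 0 else 0.0
            E1_0 = e1_ibd0[use].sum()
            E1_1 = e1_ibd1[use].sum()
            k1 = (ibs1 - k0 * E1_0) / E1_1 if E1_1 > 0 else 0.0
            k0 = min(max(k0, 0.0), 1.0)
            k1 = min(max(k1, 0.0), 1.0 - k0)
            k2 = 1.0 - k0 - k1
            out[i, j] = out[j, i] = k2 + 0.5 * k1
    return out


def _maf_freq(calls: np.ndarray) -> np.ndarray:
    ok = calls != MISSING
    n_chrom = 2 * ok.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(ok, calls, 0).sum(axis=0) / np.where(n_chrom > 0, n_chrom, 1)
    return np.clip(np.where(n_chrom > 0, p, 0.5), 1e-9, 1 - 1e-9)


def relatedness_filter(
    G: GenotypeMatrix, cutoff: float = 0.25
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Drop one member of each pair with PI_HAT above ``cutoff``.

    The member with higher missingness is removed; ties broken by sample-id
    order (the lexicographically later id is removed).
    """
    if G.n_ind < 2:
        raise ValueError("need at least 2 individuals")
    all_missing = (G.calls == MISSING).all(axis=1)
    if all_missing.any():
        bad = G.sample_meta["id"].iloc[np.flatnonzero(all_missing)].tolist()
        raise ValueError(f"all-missing individuals: {bad}")
    pihat = pi_hat_matrix(G)
    miss = (G.calls == MISSING).mean(axis=1)
    ids = G.sample_meta["id"].to_numpy()
    removed: set[int] = set()
    pairs = []
    ii, jj = np.nonzero(np.triu(pihat > cutoff, k=1))
    # process by descending PI_HAT for determinism
    order = np.argsort(-pihat[ii, jj], kind="stable")
    for k in order:
        i, j = int(ii[k]), int(jj[k])
        if i in removed or j in removed:
            continue
        if miss[i] > miss[j]:
            drop = i
        elif miss[j] > miss[i]:
            drop = j
        else:
            drop = i if ids[i] > ids[j] else j
        removed.add(drop)
        pairs.append((ids[i], ids[j], pihat[i, j], ids[drop]))
    keep = np.array([i not in removed for i in range(G.n_ind)])
    report = pd.DataFrame(pairs, columns=["id1", "id2", "pi_hat", "removed"])
    return G.take_inds(keep), report


# ---------------------------------------------------------------------------
# LD pruning


def pairwise_r2(X: np.ndarray) -> np.ndarray:
    """Squared Pearson correlation between SNP dosage columns.

    Missing entries are mean-imputed per SNP before correlating; with no
    missing data this is the plain genotype correlation.
    """
    X = X.astype(float)
    miss = X == MISSING
    if miss.any():
        col_mean = np.where(miss, np.nan, X).sum(axis=0)
        cnt = (~miss).sum(axis=0)
        col_mean = col_mean / np.where(cnt > 0, cnt, 1)
        X = np.where(miss, col_mean[None, :], X)
    Xc = X - X.mean(axis=0)
    denom = np.sqrt((Xc**2).sum(axis=0))
    denom = np.where(denom > 0, denom, np.inf)
    corr = (Xc.T @ Xc) / np.outer(denom, denom)
    return corr**2


def ld_prune(
    G: GenotypeMatrix,
    r2_max: float = 0.4,
    window_snps: int = 200,
    step_snps: int = 25,
) -> list[str]:
    """Sliding-window greedy r^2 pruning; returns kept SNP ids.

    Within each window, offending pairs (r^2 > r2_max) are resolved by
    removing the later SNP of the first offending pair, rescanning until
    clean; removal is permanent across windows, which advance by
    ``step_snps``.  Pruning a pruned set is the identity.
    """
    if not 0.0 < r2_max <= 1.0:
        raise ValueError(f"r2_max={r2_max} outside (0,1]")
    if not window_snps >= step_snps >= 1:
        raise ValueError("need window_snps >= step_snps >= 1")
    m = G.n_snp
    keep = np.ones(m, dtype=bool)
    for chrom in G.snp_meta["chrom"].unique():
        cidx = np.flatnonzero((G.snp_meta["chrom"] == chrom).to_numpy())
        start = 0
        while start < len(cidx):
            widx = cidx[start : start + window_snps]
            alive = widx[keep[widx]]
            if len(alive) > 1:
                r2 = pairwise_r2(G.calls[:, alive])
                local_alive = np.ones(len(alive), dtype=bool)
                changed = True
                while changed:
                    changed = False
                    live = np.flatnonzero(local_alive)
                    for a in range(len(live)):
                        for b in range(a + 1, len(live)):
                            if r2[live[a], live[b]] > r2_max:
                                local_alive[live[b]] = False
                                changed = True
                                break
                        if changed:
                            break
                keep[alive[~local_alive]] = False
            if start + window_snps >= len(cidx):
                break
            start += step_snps
    return G.snp_meta["id"].iloc[np.flatnonzero(keep)].tolist()


# ---------------------------------------------------------------------------
# dataset merging


def _is_ambiguous(a1: str, a2: str) -> bool:
    return _COMPLEMENT.get(a1.upper()) == a2.upper()


def merge_datasets(G1: GenotypeMatrix, G2: GenotypeMatrix) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Merge two cohorts on intersected SNP ids with allele reconciliation.

    Strand-ambiguous (A/T, C/G) sites are dropped; swapped allele labels are
    flipped (call -> 2 - call); complement-strand sites are harmonized.
    Returns the merged matrix (G1 individuals then G2) and a per-SNP report.
    """
    idx1 = {s: j for j, s in enumerate(G1.snp_meta["id"])}
    idx2 = {s: j for j, s in enumerate(G2.snp_meta["id"])}
    shared = [s for s in G1.snp_meta["id"] if s in idx2]
    if not shared:
        raise ValueError("zero overlapping SNPs")
    rows = []
    keep1, calls2_cols = [], []
    for s in shared:
        j1, j2 = idx1[s], idx2[s]
        a1, a2 = G1.snp_meta["a1"].iat[j1].upper(), G1.snp_meta["a2"].iat[j1].upper()
        b1, b2 = G2.snp_meta["a1"].iat[j2].upper(), G2.snp_meta["a2"].iat[j2].upper()
        if _is_ambiguous(a1, a2):
            rows.append((s, "dropped", "strand-ambiguous"))
            continue
        c1, c2 = _COMPLEMENT.get(b1, "?"), _COMPLEMENT.get(b2, "?")
        col = G2.calls[:, j2].copy()
        if (b1, b2) == (a1, a2) or (c1, c2) == (a1, a2):
            action = "kept" if (b1, b2) == (a1, a2) else "strand-flipped"
        elif (b1, b2) == (a2, a1) or (c1, c2) == (a2, a1):
            nonmiss = col != MISSING
            col[nonmiss] = 2 - col[nonmiss]
            action = "allele-flipped"
        else:
            rows.append((s, "dropped", "allele-mismatch"))
            continue
        rows.append((s, action, ""))
        keep1.append(j1)
        calls2_cols.append(col)
    if not keep1:
        raise ValueError("no reconcilable SNPs after allele harmonization")
    calls = np.vstack(
        [G1.calls[:, keep1], np.array(calls2_cols, dtype=np.int8).T]
    )
    sample_meta = pd.concat([G1.sample_meta, G2.sample_meta], ignore_index=True)
    merged = GenotypeMatrix(calls, G1.snp_meta.iloc[keep1], sample_meta)
    report = pd.DataFrame(rows, columns=["id", "action", "reason"])
    return merged, report
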