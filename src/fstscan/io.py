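"""Genotype file IO, quality control and LD pruning.

Reads PLINK text (.ped/.map) and VCF v4.2 (through cyvcf2) into a
:class:`~fstscan.matrix.GenotypeMatrix`; applies the standard SNP-chip QC
filters (pooled minor-allele frequency, pooled Hardy-Weinberg exact test,
autosome restriction) and sliding-window `indep-pairwise`-style LD pruning.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .matrix import LOCUS_COLUMNS, MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "QcConfig",
    "PruneConfig",
    "QcReport",
    "read_plink",
    "write_plink",
    "read_vcf",
    "write_vcf",
    "read_popmap",
    "write_popmap",
    "hwe_exact_test",
    "apply_qc",
    "ld_r2",
    "prune_ld",
]

AUTOSOMES = frozenset(range(1, 27))

# Relative guard for "no more probable than observed" in the HWE exact test;
# probabilities within this factor of the observed one count as ties.
_HWE_TIE_REL = 1e-7


# ----------------------------------------------------------------------
# configs and report


@dataclass
class QcConfig:
    """Locus-level quality-control thresholds (all boundaries strict)."""

    maf_min: float = 0.01
    hwe_p_min: float = 1e-6
    autosomes_only: bool = True
    call_rate_min: float | None = None

    def validate(self) -> None:
        if not (0.0 <= self.maf_min <= 1.0):
            raise ValueError("maf_min must lie in [0, 1]")
        if not (0.0 <= self.hwe_p_min <= 1.0):
            raise ValueError("hwe_p_min must lie in [0, 1]")
        if self.call_rate_min is not None and not (0.0 <= self.call_rate_min <= 1.0):
            raise ValueError("call_rate_min must lie in [0, 1]")


@dataclass
class PruneConfig:
    """Sliding-window LD pruning parameters (indep-pairwise semantics)."""

    window_snps: int = 25
    step_snps: int = 5
    r2_max: float = 0.1

    def validate(self) -> None:
        if self.step_snps > self.window_snps:
            raise ValueError("step_snps must not exceed window_snps")
        if self.window_snps < 2 or self.step_snps < 1:
            raise ValueError("window_snps >= 2 and step_snps >= 1 required")
        if not (0.0 <= self.r2_max <= 1.0):
            raise ValueError("r2_max must lie in [0, 1]")


@dataclass
class QcReport:
    """Per-criterion removal counts (first failing criterion attribution)."""

    n_input: int
    n_removed_maf: int
    n_removed_hwe: int
    n_removed_autosome: int
    n_removed_callrate: int
    n_retained: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "criterion": ["input", "maf", "hwe", "autosome", "call_rate", "retained"],
                "n_loci": [
                    self.n_input,
                    self.n_removed_maf,
                    self.n_removed_hwe,
                    self.n_removed_autosome,
                    self.n_removed_callrate,
                    self.n_retained,
                ],
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


# ----------------------------------------------------------------------
# population map


def read_popmap(path) -> pd.DataFrame:
    """Read a two-column sample -> population TSV (header optional)."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: popmap needs two tab-separated columns")
    df = df.iloc[:, :2]
    df.columns = ["sample_id", "population"]
    if df.iloc[0, 0].lower() in {"sample", "sample_id"}:
        df = df.iloc[1:].reset_index(drop=True)
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"{path}: duplicate sample id {dup!r} in popmap")
    return df


def write_popmap(gm: GenotypeMatrix, path) -> None:
    gm.samples[["sample_id", "population"]].to_csv(
        path, sep="\t", index=False, header=False
    )


# ----------------------------------------------------------------------
# PLINK text


def read_plink(prefix) -> GenotypeMatrix:
    """Read PLINK text files ``prefix.ped`` / ``prefix.map``.

    The family-ID column of the .ped is taken as the population label.
    Allele roles per locus are inferred from the data: when the observed
    alleles are a subset of {A, B}, ref is A and alt is B (the convention
    of :func:`write_plink`, making write/read a bit-exact round trip);
    otherwise ref/alt are the observed alleles in alphabetical order.
    """
    prefix = Path(prefix)
    map_path = prefix.with_suffix(".map")
    ped_path = prefix.with_suffix(".ped")
    loci = _read_map(map_path)
    n_loci = len(loci)

    sample_rows = []
    allele_rows = []  # list of (allele1 array, allele2 array) per sample
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 6 + 2 * n_loci:
                raise ValueError(
                    f"{ped_path}:{lineno}: expected {6 + 2 * n_loci} fields, "
                    f"found {len(parts)}"
                )
            fid, iid = parts[0], parts[1]
            alleles = np.array(parts[6:], dtype="U8").reshape(n_loci, 2)
            sample_rows.append({"sample_id": iid, "population": fid})
            allele_rows.append(alleles)
    if not sample_rows:
        raise ValueError(f"{ped_path}: no samples")

    stacked = np.stack(allele_rows)  # (n_samples, n_loci, 2)
    ref = np.empty(n_loci, dtype="U8")
    alt = np.empty(n_loci, dtype="U8")
    dosages = np.full((len(sample_rows), n_loci), MISSING, dtype=np.int8)
    for j in range(n_loci):
        col = stacked[:, j, :]
        observed = sorted(set(col.ravel()) - {"0"})
        if len(observed) > 2:
            raise ValueError(
                f"{ped_path}: locus {loci['id'].iloc[j]!r} has >2 alleles {observed}"
            )
        if set(observed) <= {"A", "B"}:
            r, a = "A", "B"
        elif len(observed) == 2:
            r, a = observed
        elif len(observed) == 1:
            r, a = observed[0], "N"
        else:
            r, a = "N", "N"
        ref[j], alt[j] = r, a
        called = (col != "0").all(axis=1)
        dosages[called, j] = (col[called] == a).sum(axis=1)
    loci = loci.copy()
    loci["ref"] = ref
    loci["alt"] = alt
    return GenotypeMatrix(dosages=dosages, loci=loci, samples=pd.DataFrame(sample_rows))


def _read_map(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 fields, found {len(parts)}")
            try:
                chrom = int(parts[0])
                pos = int(parts[3])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: unparseable chromosome/position") from exc
            rows.append({"chrom": chrom, "pos": pos, "id": parts[1]})
    if not rows:
        raise ValueError(f"{path}: no loci")
    return pd.DataFrame(rows)


def write_plink(gm: GenotypeMatrix, prefix) -> None:
    """Write space-delimited PLINK text ``prefix.ped`` / ``prefix.map``.

    Population labels go in the family-ID column; missing genotypes are
    written as ``0 0``.
    """
    if gm.n_loci == 0:
        raise ValueError("refusing to write a genotype file with zero loci")
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    with open(prefix.with_suffix(".map"), "w") as fh:
        for row in gm.loci.itertuples(index=False):
            fh.write(f"{row.chrom} {row.id} 0 {row.pos}\n")

    ref = gm.loci["ref"].to_numpy(dtype="U8")
    alt = gm.loci["alt"].to_numpy(dtype="U8")
    with open(prefix.with_suffix(".ped"), "w") as fh:
        for i, srow in enumerate(gm.samples.itertuples(index=False)):
            d = gm.dosages[i]
            first = np.where(d >= 1, alt, ref)
            second = np.where(d == 2, alt, ref)
            first = np.where(d == MISSING, "0", first)
            second = np.where(d == MISSING, "0", second)
            geno = " ".join(a + " " + b for a, b in zip(first, second))
            fh.write(f"{srow.population} {srow.sample_id} 0 0 0 -9 {geno}\n")


# ----------------------------------------------------------------------
# VCF


def read_vcf(path, popmap) -> GenotypeMatrix:
    """Read an (uncompressed or bgzipped) VCF plus a sample -> population TSV.

    Multiallelic records are skipped with a logged count. Every VCF sample
    must appear in the popmap.
    """
    from cyvcf2 import VCF

    pm = popmap if isinstance(popmap, pd.DataFrame) else read_popmap(popmap)
    pop_of = dict(zip(pm["sample_id"], pm["population"]))

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    unmapped = [s for s in samples if s not in pop_of]
    if unmapped:
        raise ValueError(
            f"samples missing from population map: {', '.join(unmapped)}"
        )

    loci_rows = []
    dosage_cols = []
    n_multi = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_multi += 1
            continue
        gt = np.asarray(var.gt_types, dtype=np.int8)  # 0/1/2 alt count, 3 unknown
        gt[gt == 3] = MISSING
        dosage_cols.append(gt)
        chrom = var.CHROM[3:] if var.CHROM.lower().startswith("chr") else var.CHROM
        loci_rows.append(
            {
                "chrom": int(chrom),
                "pos": var.POS,
                "id": var.ID or f"snp_{chrom}_{var.POS}",
                "ref": var.REF,
                "alt": var.ALT[0],
            }
        )
    vcf.close()
    if n_multi:
        logger.info("skipped %d multiallelic VCF records", n_multi)
    if not loci_rows:
        raise ValueError(f"{path}: no biallelic records")
    dosages = np.stack(dosage_cols, axis=1)
    sample_df = pd.DataFrame(
        {"sample_id": samples, "population": [pop_of[s] for s in samples]}
    )
    return GenotypeMatrix(dosages=dosages, loci=pd.DataFrame(loci_rows), samples=sample_df)


def write_vcf(gm: GenotypeMatrix, path) -> None:
    """Write a minimal VCF v4.2 (GT field only); missing calls are ``./.``."""
    if gm.n_loci == 0:
        raise ValueError("refusing to write a genotype file with zero loci")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    gt_code = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom, sub in gm.loci.groupby("chrom", sort=True):
            fh.write(f"##contig=<ID={chrom},length={int(sub['pos'].max()) + 1}>\n")
        header_samples = "\t".join(gm.samples["sample_id"])
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + header_samples
            + "\n"
        )
        for j, row in enumerate(gm.loci.itertuples(index=False)):
            calls = "\t".join(gt_code[int(d)] for d in gm.dosages[:, j])
            fh.write(
                f"{row.chrom}\t{row.pos}\t{row.id}\t{row.ref}\t{row.alt}"
                f"\t.\t.\t.\tGT\t{calls}\n"
            )


# ----------------------------------------------------------------------
# Hardy-Weinberg exact test


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Two-sided exact conditional Hardy-Weinberg test.

    Conditions on the observed allele counts and sums the probabilities of
    every heterozygote count no more probable than the observed one.
    Returns a p-value in (0, 1].
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be nonnegative")
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ValueError("at least one genotyped individual required")
    n_a = n_Aa + 2 * n_aa  # minor or major, symmetry makes it irrelevant
    rare = min(n_a, 2 * n - n_a)
    if rare == 0:
        return 1.0  # monomorphic: the observed configuration is the only one

    probs = _hwe_het_probabilities(n, rare)
    obs_het = n_Aa
    p_obs = probs.get(obs_het)
    if p_obs is None:
        raise ValueError("heterozygote count inconsistent with allele counts")
    p = sum(pr for pr in probs.values() if pr <= p_obs * (1.0 + _HWE_TIE_REL))
    return min(p, 1.0)


def _hwe_het_probabilities(n: int, rare: int) -> dict[int, float]:
    """P(het count | n diploids, `rare` copies of the rarer allele).

    Computed by the standard two-directional recurrence from the mode,
    normalised at the end; heterozygote counts share the parity of `rare`.
    """
    # mode of the distribution
    mid = int(round(rare * (2 * n - rare) / (2.0 * n)))
    if mid % 2 != rare % 2:
        mid += 1
    probs = {mid: 1.0}
    # downward: P(h-2)/P(h) = h(h-1) / (4 * n_hom_rare+1 * n_hom_common+1)  (rearranged)
    h = mid
    while h >= 2:
        hom_r = (rare - h) // 2
        hom_c = n - h - hom_r
        probs[h - 2] = probs[h] * h * (h - 1) / (4.0 * (hom_r + 1) * (hom_c + 1))
        h -= 2
    h = mid
    while h + 2 <= rare:
        hom_r = (rare - h) // 2
        hom_c = n - h - hom_r
        if hom_r < 1 or hom_c < 1:
            break
        probs[h + 2] = probs[h] * 4.0 * hom_r * hom_c / ((h + 2.0) * (h + 1.0))
        h += 2
    total = sum(probs.values())
    return {k: v / total for k, v in probs.items()}


# ----------------------------------------------------------------------
# QC


def apply_qc(gm: GenotypeMatrix, cfg: QcConfig | None = None) -> tuple[GenotypeMatrix, QcReport]:
    """Filter loci on pooled MAF, pooled HWE and autosome membership.

    All thresholds are strict inequalities (a locus with MAF exactly at the
    minimum is removed). Removal counts attribute each dropped locus to the
    first criterion it fails, evaluated in the order MAF, HWE, autosome,
    call rate.
    """
    cfg = cfg or QcConfig()
    cfg.validate()

    maf = gm.minor_allele_frequencies()
    pass_maf = np.nan_to_num(maf, nan=0.0) > cfg.maf_min

    counts = gm.genotype_counts()
    hwe_p = np.ones(gm.n_loci)
    candidates = np.flatnonzero(counts.sum(axis=1) > 0)
    for j in candidates:
        hwe_p[j] = hwe_exact_test(*counts[j])
    pass_hwe = (hwe_p > cfg.hwe_p_min) & (counts.sum(axis=1) > 0)

    chrom = gm.loci["chrom"].to_numpy()
    pass_auto = (
        np.isin(chrom, list(AUTOSOMES)) if cfg.autosomes_only else np.ones(gm.n_loci, bool)
    )

    if cfg.call_rate_min is not None:
        call_rate = (gm.dosages != MISSING).mean(axis=0)
        pass_call = call_rate > cfg.call_rate_min
    else:
        pass_call = np.ones(gm.n_loci, bool)

    keep = pass_maf & pass_hwe & pass_auto & pass_call
    fail_maf = ~pass_maf
    fail_hwe = pass_maf & ~pass_hwe
    fail_auto = pass_maf & pass_hwe & ~pass_auto
    fail_call = pass_maf & pass_hwe & pass_auto & ~pass_call

    report = QcReport(
        n_input=gm.n_loci,
        n_removed_maf=int(fail_maf.sum()),
        n_removed_hwe=int(fail_hwe.sum()),
        n_removed_autosome=int(fail_auto.sum()),
        n_removed_callrate=int(fail_call.sum()),
        n_retained=int(keep.sum()),
    )
    logger.info(
        "QC: %d loci in, removed maf=%d hwe=%d autosome=%d call=%d, retained %d",
        report.n_input,
        report.n_removed_maf,
        report.n_removed_hwe,
        report.n_removed_autosome,
        report.n_removed_callrate,
        report.n_retained,
    )
    if not keep.any():
        raise ValueError(
            "no loci survive QC; review maf_min/hwe_p_min thresholds and input data"
        )
    return gm.subset_loci(keep), report


# ----------------------------------------------------------------------
# LD pruning


def ld_r2(dosage_x: np.ndarray, dosage_y: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors over complete pairs.

    Pairs with a missing call in either vector are dropped; a vector that is
    constant after dropping (monomorphic) yields 0 by convention, so such
    loci are never pruned on each other's account.
    """
    x = np.asarray(dosage_x, dtype=float)
    y = np.asarray(dosage_y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("dosage vectors must have equal length")
    ok = (x != MISSING) & (y != MISSING)
    if ok.sum() < 2:
        raise ValueError("fewer than two complete pairs")
    x, y = x[ok], y[ok]
    sx = x.std()
    sy = y.std()
    if sx == 0.0 or sy == 0.0:
        return 0.0
    r = ((x - x.mean()) * (y - y.mean())).mean() / (sx * sy)
    return float(min(r * r, 1.0))


def _pooled_maf(dosages: np.ndarray) -> np.ndarray:
    called = dosages != MISSING
    n = called.sum(axis=0)
    alt = np.where(called, dosages, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, alt / (2.0 * n), 0.0)
    return np.minimum(p, 1.0 - p)


def prune_ld(
    gm: GenotypeMatrix, cfg: PruneConfig | None = None
) -> tuple[GenotypeMatrix, list[str]]:
    """Sliding-window LD pruning; returns the pruned matrix and kept ids.

    Per chromosome a window of ``window_snps`` loci advances by
    ``step_snps`` over the original locus order. Within each window, while
    any surviving pair has r^2 above the threshold, the pair with the
    highest r^2 is resolved by removing its lower-MAF member (ties: the
    member at the later map position). Removals are global and permanent;
    locus order is preserved.
    """
    cfg = cfg or PruneConfig()
    cfg.validate()

    maf = _pooled_maf(gm.dosages)
    pos = gm.loci["pos"].to_numpy()
    chrom = gm.loci["chrom"].to_numpy()
    keep = np.ones(gm.n_loci, dtype=bool)

    # Windows slide over the surviving loci; the sweep repeats until a pass
    # removes nothing, so pruning reaches a fixed point (idempotent, and at
    # the final state no within-window pair exceeds the threshold).
    while True:
        n_before = int(keep.sum())
        for c in np.unique(chrom):
            idx = np.flatnonzero((chrom == c) & keep)
            n = idx.size
            start = 0
            while start < n:
                window = idx[start : start + cfg.window_snps]
                _prune_window(gm.dosages, window, keep, maf, pos, cfg.r2_max)
                if start + cfg.window_snps >= n:
                    break
                start += cfg.step_snps
        if int(keep.sum()) == n_before:
            break

    kept_ids = gm.loci["id"].iloc[np.flatnonzero(keep)].tolist()
    return gm.subset_loci(keep), kept_ids


def _window_r2_matrix(dosages: np.ndarray, cols: np.ndarray) -> np.ndarray:
    """Pairwise-complete r^2 matrix for the given locus columns.

    Equivalent to calling :func:`ld_r2` on every pair, but computed with
    masked matrix products; undefined pairs (under two complete pairs, or a
    constant vector) are reported as 0.
    """
    X = dosages[:, cols].astype(float)
    M = (X != MISSING).astype(float)
    Z = np.where(X == MISSING, 0.0, X)
    Z2 = Z * Z
    n = M.T @ M
    sx = Z.T @ M  # sx[i, j] = sum of x_i over rows complete in both i and j
    sxx = Z2.T @ M
    sxy = Z.T @ Z
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = n * sxy - sx * sx.T
        var_i = n * sxx - sx * sx
        var_j = var_i.T
        r2 = (cov * cov) / (var_i * var_j)
    r2 = np.where((n >= 2) & (var_i > 0) & (var_j > 0), r2, 0.0)
    np.fill_diagonal(r2, 0.0)
    return np.minimum(r2, 1.0)


def _prune_window(
    dosages: np.ndarray,
    window: np.ndarray,
    keep: np.ndarray,
    maf: np.ndarray,
    pos: np.ndarray,
    r2_max: float,
) -> None:
    alive = np.array([int(j) for j in window if keep[j]], dtype=int)
    if alive.size < 2:
        return
    r2 = _window_r2_matrix(dosages, alive)
    active = np.ones(alive.size, dtype=bool)
    while True:
        sub = np.where(np.outer(active, active), r2, 0.0)
        hi = np.max(sub)
        if hi <= r2_max:
            return
        ai, bi = np.unravel_index(np.argmax(sub), sub.shape)
        ai, bi = min(ai, bi), max(ai, bi)
        j1, j2 = alive[ai], alive[bi]
        if maf[j1] < maf[j2]:
            drop_local = ai
        elif maf[j2] < maf[j1]:
            drop_local = bi
        else:
            drop_local = ai if pos[j1] > pos[j2] else bi
        keep[alive[drop_local]] = False
        active[drop_local] = False
        if active.sum() < 2:
            return
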