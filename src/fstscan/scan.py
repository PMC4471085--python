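"""Breed-specific selection scan: LSBL and d_i, windows, outlier calls.

Two per-locus statistics isolate lineage-specific allele-frequency change
in a three-population design, both built from pairwise Weir-Cockerham
theta:

* LSBL (locus-specific branch length): the additive three-taxon
  decomposition, L_A = (theta_AB + theta_AC - theta_BC) / 2 and cyclic
  analogues. The three branch lengths sum to half the sum of the pairwise
  values at every locus.

* d_i: for breed i, the sum over the pairs containing i of z-standardised
  theta, d_i = sum_{j != i} (theta_ij - E[theta_ij]) / sd[theta_ij], where
  the expectation and (n-1) standard deviation per pair come from the full
  set of loci entering the scan.

Per-locus values are averaged inside non-overlapping 300-kb windows tiled
from coordinate 0 of each autosome; windows with fewer than three SNPs are
dropped and the survivors numbered consecutively genome-wide. For each
breed and statistic, candidate windows are the empirical upper tail — the
top ceil(1% of N) windows — and the final breed-specific candidate set is
the intersection of the LSBL and d_i lists.

:class:`SelectionScan` wraps the whole procedure in a model object:
``SelectionScan(genotypes).fit()`` returns a
:class:`SelectionScanResults` carrying the per-locus scores, window
table, candidate sets, cross-breed overlaps and LSBL/d_i agreement
diagnostics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .fst import (
    FstComponents,
    PairwiseFstSummary,
    fst_components,
    fst_tree,
    genomewide_fst,
    lsbl_branch_lengths,
)
from .matrix import GenotypeMatrix

__all__ = [
    "ScanConfig",
    "StandardizationStats",
    "BreedScores",
    "WindowTable",
    "lsbl",
    "d_stat",
    "compute_breed_scores",
    "build_windows",
    "select_outlier_windows",
    "merge_candidates",
    "cross_breed_overlap",
    "stat_correlation",
    "SelectionScan",
    "SelectionScanResults",
]


@dataclass
class ScanConfig:
    """Windowing and outlier-calling parameters."""

    window_bp: int = 300_000
    min_snps: int = 3
    percentile: float = 0.99
    bin_size: int = 5_000
    window_stat: str = "mean"  # or "max"

    def validate(self) -> None:
        if not (0.0 < self.percentile < 1.0):
            raise ValueError("percentile must lie strictly in (0, 1)")
        if self.window_bp < 1 or self.min_snps < 1 or self.bin_size < 1:
            raise ValueError("window_bp, min_snps and bin_size must be positive")
        if self.window_stat not in {"mean", "max"}:
            raise ValueError("window_stat must be 'mean' or 'max'")


# ----------------------------------------------------------------------
# per-locus statistics


def lsbl(theta_ab, theta_ac, theta_bc):
    """Locus-specific branch lengths (L_A, L_B, L_C) from pairwise theta.

    Accepts scalars or aligned arrays; negative values are retained.
    """
    return lsbl_branch_lengths(
        np.asarray(theta_ab, dtype=float) if not np.isscalar(theta_ab) else theta_ab,
        np.asarray(theta_ac, dtype=float) if not np.isscalar(theta_ac) else theta_ac,
        np.asarray(theta_bc, dtype=float) if not np.isscalar(theta_bc) else theta_bc,
    )


@dataclass
class StandardizationStats:
    """Per-pair mean and sample (n-1) standard deviation of per-locus theta."""

    e_fst: dict[tuple[str, str], float]
    sd_fst: dict[tuple[str, str], float]
    n_loci: int

    @classmethod
    def from_thetas(
        cls, thetas: dict[tuple[str, str], np.ndarray], mask: np.ndarray
    ) -> "StandardizationStats":
        e = {}
        sd = {}
        for pair, th in thetas.items():
            vals = th[mask]
            e[pair] = float(np.mean(vals))
            sd[pair] = float(np.std(vals, ddof=1))
        return cls(e_fst=e, sd_fst=sd, n_loci=int(mask.sum()))

    def get(self, pop_i: str, pop_j: str) -> tuple[float, float]:
        key = (pop_i, pop_j) if (pop_i, pop_j) in self.e_fst else (pop_j, pop_i)
        return self.e_fst[key], self.sd_fst[key]


def d_stat(
    theta_locus: dict[tuple[str, str], float | np.ndarray],
    standardization: StandardizationStats,
) -> dict[str, np.ndarray]:
    """Per-breed d values from per-pair theta and standardisation constants.

    ``d_k = sum over pairs containing k of (theta - E) / sd``. Raises if any
    pair's standard deviation is zero.
    """
    pops = list(dict.fromkeys(p for pair in theta_locus for p in pair))
    out: dict[str, np.ndarray] = {}
    for k in pops:
        acc = None
        for pair, th in theta_locus.items():
            if k not in pair:
                continue
            e, sd = standardization.get(*pair)
            if sd <= 0.0:
                raise ValueError(f"zero F_ST standard deviation for pair {pair}")
            z = (np.asarray(th, dtype=float) - e) / sd
            acc = z if acc is None else acc + z
        out[k] = acc
    return out


@dataclass
class BreedScores:
    """Per-locus LSBL and d for each breed plus the defined mask.

    ``table`` columns: ``lsbl_<breed>`` and ``d_<breed>`` per breed and a
    boolean ``defined`` (all three pairwise theta defined at the locus;
    scores are NaN elsewhere). Standardisation constants are kept so the
    scan is auditable.
    """

    pops: list[str]
    table: pd.DataFrame
    standardization: StandardizationStats

    @property
    def defined(self) -> np.ndarray:
        return self.table["defined"].to_numpy()


def compute_breed_scores(
    components: dict[tuple[str, str], FstComponents]
) -> BreedScores:
    """LSBL and d_i per locus for three populations.

    A locus enters the scan only if theta is defined for all three pairs;
    the d_i standardisation constants are computed on exactly that locus
    set, which makes each breed's mean d over it identically zero.
    """
    pairs = list(components)
    pops = list(dict.fromkeys(p for pair in pairs for p in pair))
    if len(pops) != 3 or len(pairs) != 3:
        raise ValueError("exactly three populations (three pairs) required")
    a, b, c = pops
    thetas = {pair: comp.theta for pair, comp in components.items()}
    defined = np.logical_and.reduce([comp.defined for comp in components.values()])
    if not defined.any():
        raise ValueError("no locus has theta defined for all three pairs")

    def th(x: str, y: str) -> np.ndarray:
        return thetas[(x, y)] if (x, y) in thetas else thetas[(y, x)]

    l_a, l_b, l_c = lsbl_branch_lengths(th(a, b), th(a, c), th(b, c))
    standardization = StandardizationStats.from_thetas(thetas, defined)
    d = d_stat(thetas, standardization)

    table = pd.DataFrame(
        {
            f"lsbl_{a}": np.where(defined, l_a, np.nan),
            f"lsbl_{b}": np.where(defined, l_b, np.nan),
            f"lsbl_{c}": np.where(defined, l_c, np.nan),
            f"d_{a}": np.where(defined, d[a], np.nan),
            f"d_{b}": np.where(defined, d[b], np.nan),
            f"d_{c}": np.where(defined, d[c], np.nan),
            "defined": defined,
        }
    )
    return BreedScores(pops=pops, table=table, standardization=standardization)


# ----------------------------------------------------------------------
# windows


@dataclass
class WindowTable:
    """Non-overlapping genomic windows with per-breed summary statistics.

    ``table`` columns: ``window`` (1..N genome-wide), ``chrom``, ``start``
    / ``end`` (0-based half-open bp), ``n_snps``, per breed ``lsbl_<breed>``
    and ``d_<breed>`` window statistics and ``peak_<breed>`` (id of the SNP
    with maximal per-SNP LSBL; ties to the lowest position).
    """

    pops: list[str]
    window_bp: int
    table: pd.DataFrame
    locus_window: np.ndarray  # per-locus 1-based window index, 0 = unassigned

    def __len__(self) -> int:
        return len(self.table)

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out.insert(3, "start_mb", out["start"] / 1e6)
        out.insert(4, "end_mb", out["end"] / 1e6)
        out.to_csv(path, sep="\t", index=False, float_format="%.6g")


def build_windows(
    scores: BreedScores, loci: pd.DataFrame, cfg: ScanConfig | None = None
) -> WindowTable:
    """Tile chromosomes into fixed windows and average per-locus scores.

    Windows start at coordinate 0 on every chromosome; a locus at 1-based
    position ``pos`` falls in window ``(pos - 1) // window_bp``. Windows
    with fewer than ``min_snps`` defined loci are dropped and the remainder
    numbered 1..N in (chrom, start) order.
    """
    cfg = cfg or ScanConfig()
    cfg.validate()
    chrom = loci["chrom"].to_numpy()
    pos = loci["pos"].to_numpy()
    defined = scores.defined
    widx = (pos - 1) // cfg.window_bp

    agg = np.max if cfg.window_stat == "max" else np.mean
    rows = []
    assignment_keys: list[tuple[int, int]] = []
    per_locus_key = list(zip(chrom, widx))
    for c in np.unique(chrom):
        on_c = chrom == c
        for w in np.unique(widx[on_c]):
            in_win = on_c & (widx == w) & defined
            n = int(in_win.sum())
            if n < cfg.min_snps:
                continue
            row = {
                "chrom": int(c),
                "start": int(w) * cfg.window_bp,
                "end": (int(w) + 1) * cfg.window_bp,
                "n_snps": n,
            }
            jj = np.flatnonzero(in_win)
            for p in scores.pops:
                lvals = scores.table[f"lsbl_{p}"].to_numpy()[jj]
                dvals = scores.table[f"d_{p}"].to_numpy()[jj]
                row[f"lsbl_{p}"] = float(agg(lvals))
                row[f"d_{p}"] = float(agg(dvals))
                # peak SNP by per-SNP LSBL; ties resolved to lowest position
                best = jj[np.lexsort((pos[jj], -lvals))][0]
                row[f"peak_{p}"] = loci["id"].iloc[best]
            rows.append(row)
            assignment_keys.append((int(c), int(w)))

    table = pd.DataFrame(rows)
    if len(table):
        table = table.sort_values(["chrom", "start"]).reset_index(drop=True)
        table.insert(0, "window", np.arange(1, len(table) + 1))
        order = {
            (r.chrom, r.start // cfg.window_bp): r.window for r in table.itertuples()
        }
    else:
        table = pd.DataFrame(
            columns=["window", "chrom", "start", "end", "n_snps"]
        )
        order = {}
    locus_window = np.array(
        [order.get(k, 0) if d else 0 for k, d in zip(per_locus_key, defined)],
        dtype=int,
    )
    return WindowTable(
        pops=scores.pops, window_bp=cfg.window_bp, table=table, locus_window=locus_window
    )


def _n_outliers(n: int, percentile: float) -> int:
    # small epsilon guards against binary-float artifacts in (1 - p) * n
    return max(math.ceil((1.0 - percentile) * n - 1e-9), 1)


def select_outlier_windows(
    wt: WindowTable | pd.DataFrame,
    statistic: str,
    breed: str,
    cfg: ScanConfig | None = None,
) -> set[int]:
    """Windows in the empirical upper tail of one breed's window statistic.

    Selects the top ``ceil((1 - percentile) * N)`` windows by the chosen
    statistic (``"lsbl"`` or ``"d"``), breaking ties at the cutoff by lower
    window index. Returns the set of 1-based window indices.
    """
    cfg = cfg or ScanConfig()
    cfg.validate()
    table = wt.table if isinstance(wt, WindowTable) else wt
    if statistic not in {"lsbl", "d"}:
        raise ValueError("statistic must be 'lsbl' or 'd'")
    col = f"{statistic}_{breed}"
    if col not in table.columns:
        raise KeyError(f"no column {col!r}; unknown breed {breed!r}?")
    n = len(table)
    if n == 0:
        raise ValueError("window table is empty")
    k = _n_outliers(n, cfg.percentile)
    order = np.lexsort((table["window"].to_numpy(), -table[col].to_numpy()))
    return set(table["window"].to_numpy()[order[:k]].tolist())


def merge_candidates(lsbl_set: set[int], d_set: set[int]) -> set[int]:
    """Windows flagged by both statistics (set intersection)."""
    return set(lsbl_set) & set(d_set)


def cross_breed_overlap(
    merged: dict[str, set[int]]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Windows shared between breeds' merged candidate sets.

    Returns ``(pairwise, shared)``: pairwise intersection counts for every
    breed pair, and one row per window present in at least two breeds' sets
    listing the breeds carrying it.
    """
    breeds = list(merged)
    if len(breeds) < 2:
        raise ValueError("at least two breeds required")
    pair_rows = []
    for i in range(len(breeds)):
        for j in range(i + 1, len(breeds)):
            pair_rows.append(
                {
                    "breed_i": breeds[i],
                    "breed_j": breeds[j],
                    "n_shared": len(merged[breeds[i]] & merged[breeds[j]]),
                }
            )
    window_breeds: dict[int, list[str]] = {}
    for b in breeds:
        for w in merged[b]:
            window_breeds.setdefault(w, []).append(b)
    shared_rows = [
        {"window": w, "breeds": ",".join(sorted(bs)), "n_breeds": len(bs)}
        for w, bs in sorted(window_breeds.items())
        if len(bs) >= 2
    ]
    shared = pd.DataFrame(shared_rows, columns=["window", "breeds", "n_breeds"])
    return pd.DataFrame(pair_rows), shared


def stat_correlation(
    scores: BreedScores, breed: str, cfg: ScanConfig | None = None
) -> tuple[float, pd.DataFrame]:
    """Agreement between LSBL and d for one breed.

    Returns the overall Pearson r over all defined loci, and per-bin r after
    sorting loci by LSBL descending and cutting into consecutive bins of
    ``bin_size`` loci (a final partial bin is kept if it has at least three
    loci; a bin with a constant vector gets NaN and ``defined=False``).
    """
    cfg = cfg or ScanConfig()
    cfg.validate()
    l = scores.table[f"lsbl_{breed}"].to_numpy()
    d = scores.table[f"d_{breed}"].to_numpy()
    ok = scores.defined
    l, d = l[ok], d[ok]
    if l.size < 3:
        raise ValueError("need at least three defined loci")
    overall = float(sps.pearsonr(l, d).statistic)

    order = np.argsort(-l, kind="stable")
    l, d = l[order], d[order]
    rows = []
    for b0 in range(0, l.size, cfg.bin_size):
        lb, db = l[b0 : b0 + cfg.bin_size], d[b0 : b0 + cfg.bin_size]
        if lb.size < 3:
            break
        if np.ptp(lb) == 0.0 or np.ptp(db) == 0.0:
            rows.append(
                {"bin": b0 // cfg.bin_size + 1, "n_loci": lb.size,
                 "r": np.nan, "defined": False}
            )
            continue
        rows.append(
            {
                "bin": b0 // cfg.bin_size + 1,
                "n_loci": lb.size,
                "r": float(sps.pearsonr(lb, db).statistic),
                "defined": True,
            }
        )
    return overall, pd.DataFrame(rows, columns=["bin", "n_loci", "r", "defined"])


def sweep_detection_rates(
    truth_table: pd.DataFrame,
    windows: WindowTable,
    merged: dict[str, set[int]],
) -> pd.DataFrame:
    """Power and specificity of merged candidate sets against planted sweeps.

    For each truth block (breed, chrom, start, end; 1-based inclusive)
    reports whether any window of the target breed's merged set intersects
    it (power) and whether any other breed's merged set does
    (false cross-detection). Returns one row per block.
    """
    tbl = windows.table
    rows = []
    for rec in truth_table.itertuples(index=False):
        on = tbl[
            (tbl["chrom"] == rec.chrom)
            & (tbl["end"] >= rec.start)  # window end is exclusive 0-based = 1-based inclusive end
            & (tbl["start"] < rec.end)
        ]
        wset = set(on["window"])
        hit_target = bool(wset & merged[rec.breed])
        hit_other = any(
            bool(wset & merged[b]) for b in merged if b != rec.breed
        )
        rows.append(
            {
                "breed": rec.breed,
                "chrom": rec.chrom,
                "start": rec.start,
                "end": rec.end,
                "detected": hit_target,
                "cross_detected": hit_other,
            }
        )
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# model / results


class SelectionScan:
    """Selection-signature scan model for a three-population genotype set.

    Parameters
    ----------
    genotypes
        Post-QC :class:`~fstscan.matrix.GenotypeMatrix` with exactly three
        population labels.
    config
        :class:`ScanConfig`; defaults to 300-kb windows, >= 3 SNPs per
        window and the upper 99th percentile rule.

    ``fit()`` runs pairwise Weir-Cockerham theta, LSBL/d_i scoring,
    windowing, outlier calling, merging and cross-breed overlap, and
    returns a :class:`SelectionScanResults`.
    """

    def __init__(self, genotypes: GenotypeMatrix, config: ScanConfig | None = None):
        self.genotypes = genotypes
        self.config = config or ScanConfig()
        self.config.validate()
        pops = genotypes.populations
        if len(pops) != 3:
            raise ValueError(
                f"scan requires exactly three populations, found {len(pops)}: {pops}"
            )
        self.pops = pops

    @classmethod
    def from_files(cls, genotype_path, popmap_path=None, config=None) -> "SelectionScan":
        """Build from a PLINK prefix (no popmap needed) or a VCF + popmap."""
        from . import io as gio

        path = str(genotype_path)
        if path.endswith((".vcf", ".vcf.gz")):
            if popmap_path is None:
                raise ValueError("a popmap is required with VCF input")
            gm = gio.read_vcf(path, popmap_path)
        else:
            gm = gio.read_plink(path)
        return cls(gm, config)

    def fit(self) -> "SelectionScanResults":
        a, b, c = self.pops
        pairs = [(a, b), (a, c), (b, c)]
        components = {
            pair: fst_components(self.genotypes, *pair) for pair in pairs
        }
        summary = genomewide_fst(components)
        scores = compute_breed_scores(components)
        windows = build_windows(scores, self.genotypes.loci, self.config)
        selected = {
            stat: {
                p: select_outlier_windows(windows, stat, p, self.config)
                for p in self.pops
            }
            for stat in ("lsbl", "d")
        }
        merged = {
            p: merge_candidates(selected["lsbl"][p], selected["d"][p])
            for p in self.pops
        }
        overlap_pairwise, overlap_shared = cross_breed_overlap(merged)
        correlations = {}
        corr_bins = {}
        for p in self.pops:
            r, bins = stat_correlation(scores, p, self.config)
            correlations[p] = r
            corr_bins[p] = bins
        return SelectionScanResults(
            model=self,
            components=components,
            fst_summary=summary,
            scores=scores,
            windows=windows,
            selected=selected,
            merged=merged,
            overlap_pairwise=overlap_pairwise,
            overlap_shared=overlap_shared,
            correlations=correlations,
            correlation_bins=corr_bins,
        )


@dataclass
class SelectionScanResults:
    """Fitted scan: estimates, window calls and agreement diagnostics."""

    model: SelectionScan
    components: dict[tuple[str, str], FstComponents]
    fst_summary: PairwiseFstSummary
    scores: BreedScores
    windows: WindowTable
    selected: dict[str, dict[str, set[int]]]
    merged: dict[str, set[int]]
    overlap_pairwise: pd.DataFrame
    overlap_shared: pd.DataFrame
    correlations: dict[str, float]
    correlation_bins: dict[str, pd.DataFrame]

    @property
    def pops(self) -> list[str]:
        return self.model.pops

    def tree_newick(self) -> str:
        return fst_tree(self.fst_summary)

    def candidate_windows(self, breed: str) -> pd.DataFrame:
        """Window rows of the breed's merged (LSBL and d_i) candidate set."""
        t = self.windows.table
        return t[t["window"].isin(self.merged[breed])].reset_index(drop=True)

    def summary(self) -> str:
        """Human-readable overview of the fitted scan."""
        lines = []
        lines.append("Selection-signature scan (pairwise F_ST -> LSBL & d_i)")
        lines.append("=" * 58)
        gm = self.model.genotypes
        lines.append(
            f"samples: {gm.n_samples}  loci: {gm.n_loci}  populations: "
            + ", ".join(self.pops)
        )
        lines.append("")
        lines.append("Genome-wide pairwise F_ST (ratio of sums):")
        for (pi, pj), v in self.fst_summary.pairs.items():
            lines.append(f"  {pi}-{pj}: {v:.4f}  (n={self.fst_summary.n_loci[(pi, pj)]})")
        lines.append(f"F_ST tree: {self.tree_newick()}")
        lines.append("")
        n_win = len(self.windows)
        cfg = self.model.config
        lines.append(
            f"windows: {n_win} retained ({cfg.window_bp // 1000} kb, "
            f">= {cfg.min_snps} SNPs); outlier rule: top "
            f"{_n_outliers(n_win, cfg.percentile)} per breed per statistic"
        )
        for p in self.pops:
            lines.append(
                f"  {p}: LSBL {len(self.selected['lsbl'][p])}, "
                f"d_i {len(self.selected['d'][p])}, "
                f"merged {len(self.merged[p])}, "
                f"LSBL~d_i r = {self.correlations[p]:.3f}"
            )
        n_shared = len(self.overlap_shared)
        lines.append(f"windows shared by >= 2 breeds' merged sets: {n_shared}")
        return "\n".join(lines)
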