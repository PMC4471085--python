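"""Pairwise Weir-Cockerham F_ST, the three-branch F_ST phylogeny, PCA and
per-SNP genotype profiles.

Per-locus differentiation between two populations is estimated with the
Weir & Cockerham (1984) variance-component estimator: at each locus the
among-population (a), among-individual-within-population (b) and
within-individual (c) components are computed from per-population sample
sizes, allele frequencies and observed heterozygote frequencies, and
theta = a / (a + b + c). The multilocus (genome-wide) estimate is the
ratio of sums sum(a) / sum(a + b + c), not a mean of per-locus ratios.
Negative per-locus theta values are legitimate sampling outcomes and are
retained untruncated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import MISSING, GenotypeMatrix

__all__ = [
    "FstComponents",
    "PairwiseFstSummary",
    "fst_components",
    "genomewide_fst",
    "fst_tree",
    "lsbl_branch_lengths",
    "pca",
    "genotype_profile",
]


@dataclass
class FstComponents:
    """Per-locus Weir-Cockerham variance components for one population pair.

    Arrays are aligned with the source locus table. ``defined`` is False at
    loci monomorphic across both populations (a + b + c = 0) or with fewer
    than two genotyped individuals in either population; ``theta`` is NaN
    there.
    """

    pop_i: str
    pop_j: str
    a: np.ndarray
    b: np.ndarray
    c: np.ndarray
    theta: np.ndarray
    defined: np.ndarray

    @property
    def n_defined(self) -> int:
        return int(self.defined.sum())

    def to_frame(self, loci: pd.DataFrame) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": loci["chrom"].to_numpy(),
                "pos": loci["pos"].to_numpy(),
                "id": loci["id"].to_numpy(),
                "pair": f"{self.pop_i}-{self.pop_j}",
                "a": self.a,
                "b": self.b,
                "c": self.c,
                "theta": self.theta,
            }
        )


@dataclass
class PairwiseFstSummary:
    """Genome-wide (multilocus) theta per population pair."""

    pairs: dict[tuple[str, str], float]
    n_loci: dict[tuple[str, str], int]

    def get(self, pop_i: str, pop_j: str) -> float:
        key = (pop_i, pop_j) if (pop_i, pop_j) in self.pairs else (pop_j, pop_i)
        return self.pairs[key]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "pop_i": [k[0] for k in self.pairs],
                "pop_j": [k[1] for k in self.pairs],
                "fst": list(self.pairs.values()),
                "n_loci": [self.n_loci[k] for k in self.pairs],
            }
        )


def _pop_locus_stats(dosages: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-locus (n called, alt frequency, observed het frequency) for one pop."""
    called = dosages != MISSING
    n = called.sum(axis=0).astype(float)
    alt = np.where(called, dosages, 0).sum(axis=0)
    het = (dosages == 1).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, alt / (2.0 * n), np.nan)
        h = np.where(n > 0, het / n, np.nan)
    return n, p, h


def fst_components(gm: GenotypeMatrix, pop_i: str, pop_j: str) -> FstComponents:
    """Weir-Cockerham per-locus components a, b, c and theta for one pair.

    Sample sizes count non-missing genotypes only; a locus needs at least
    two genotyped individuals in each population to be defined.
    """
    di = gm.pop_dosages(pop_i)
    dj = gm.pop_dosages(pop_j)
    n1, p1, h1 = _pop_locus_stats(di)
    n2, p2, h2 = _pop_locus_stats(dj)

    usable = (n1 >= 2) & (n2 >= 2)
    r = 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        nbar = (n1 + n2) / r
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1.0)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)

        inner = pbar * (1.0 - pbar) - ((r - 1.0) / r) * s2 - hbar / 4.0
        a = (nbar / nc) * (s2 - inner / (nbar - 1.0))
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1.0 - pbar)
            - ((r - 1.0) / r) * s2
            - ((2.0 * nbar - 1.0) / (4.0 * nbar)) * hbar
        )
        c = hbar / 2.0
        denom = a + b + c
        theta = a / denom

    defined = usable & np.isfinite(denom) & (denom > 0)
    theta = np.where(defined, theta, np.nan)
    a = np.where(usable, a, np.nan)
    b = np.where(usable, b, np.nan)
    c = np.where(usable, c, np.nan)
    return FstComponents(pop_i=pop_i, pop_j=pop_j, a=a, b=b, c=c, theta=theta, defined=defined)


def genomewide_fst(components: FstComponents | dict | list) -> PairwiseFstSummary:
    """Multilocus theta (ratio of sums over defined loci) per pair."""
    if isinstance(components, FstComponents):
        components = [components]
    if isinstance(components, dict):
        components = list(components.values())
    pairs: dict[tuple[str, str], float] = {}
    n_loci: dict[tuple[str, str], int] = {}
    for comp in components:
        d = comp.defined
        if not d.any():
            raise ValueError(
                f"no defined loci for pair {comp.pop_i}-{comp.pop_j}"
            )
        num = comp.a[d].sum()
        den = (comp.a[d] + comp.b[d] + comp.c[d]).sum()
        pairs[(comp.pop_i, comp.pop_j)] = float(num / den)
        n_loci[(comp.pop_i, comp.pop_j)] = int(d.sum())
    return PairwiseFstSummary(pairs=pairs, n_loci=n_loci)


def lsbl_branch_lengths(
    fst_ab: float, fst_ac: float, fst_bc: float
) -> tuple[float, float, float]:
    """Additive three-taxon decomposition of pairwise distances.

    Returns (L_A, L_B, L_C) with L_A = (d_AB + d_AC - d_BC) / 2 and cyclic
    analogues; the three branch lengths sum to half the sum of the pairwise
    distances. Negative branches are not truncated.
    """
    l_a = (fst_ab + fst_ac - fst_bc) / 2.0
    l_b = (fst_ab + fst_bc - fst_ac) / 2.0
    l_c = (fst_ac + fst_bc - fst_ab) / 2.0
    return l_a, l_b, l_c


def fst_tree(summary: PairwiseFstSummary) -> str:
    """Star (three-branch) newick tree from genome-wide pairwise F_ST.

    Branch lengths are the additive decomposition of the three pairwise
    values — the same arithmetic as per-locus branch lengths, applied to the
    genome-wide estimates.
    """
    pops = list(dict.fromkeys(p for key in summary.pairs for p in key))
    if len(pops) != 3:
        raise ValueError(f"exactly three populations required, found {len(pops)}")
    a, b, c = pops
    l_a, l_b, l_c = lsbl_branch_lengths(
        summary.get(a, b), summary.get(a, c), summary.get(b, c)
    )
    return f"({a}:{l_a:.6g},{b}:{l_b:.6g},{c}:{l_c:.6g});"


def pca(
    gm: GenotypeMatrix, n_components: int = 10, scale: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """PCA of the dosage matrix (samples as observations).

    Missing dosages are mean-imputed per locus; loci are centred and, with
    ``scale=True``, divided by sqrt(pbar (1 - pbar)) where pbar is the
    pooled allele frequency (the usual normalisation for genotype PCA).
    Returns per-sample scores for the leading components and the full
    vector of variance proportions (summing to 1).
    """
    if gm.n_samples < 2:
        raise ValueError("PCA needs at least two samples")
    X = gm.dosages.astype(float)
    X[X == MISSING] = np.nan
    col_mean = np.nanmean(X, axis=0)
    col_mean = np.where(np.isfinite(col_mean), col_mean, 0.0)
    inds = np.where(np.isnan(X))
    X[inds] = np.take(col_mean, inds[1])
    X -= col_mean
    if scale:
        pbar = col_mean / 2.0
        denom = np.sqrt(pbar * (1.0 - pbar))
        good = denom > 0
        X[:, good] /= denom[good]
        X[:, ~good] = 0.0
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    eigvals = s**2
    total = eigvals.sum()
    if total == 0:
        raise ValueError("genotype matrix has no variance")
    proportions = eigvals / total
    k = min(n_components, len(s))
    scores = U[:, :k] * s[:k]
    return scores, proportions


def genotype_profile(gm: GenotypeMatrix, locus_id: str) -> pd.DataFrame:
    """Per-population proportions of the three genotype classes at one SNP.

    Rows are populations; columns ``hom_ref``, ``het``, ``hom_alt`` sum to 1
    over non-missing calls. A population with no calls gets NaN proportions
    and ``defined=False``.
    """
    matches = np.flatnonzero((gm.loci["id"] == locus_id).to_numpy())
    if matches.size == 0:
        raise KeyError(f"unknown locus id: {locus_id!r}")
    j = int(matches[0])
    rows = []
    for pop in gm.populations:
        d = gm.pop_dosages(pop)[:, j]
        called = d != MISSING
        n = int(called.sum())
        if n == 0:
            rows.append(
                {"population": pop, "hom_ref": np.nan, "het": np.nan,
                 "hom_alt": np.nan, "n_called": 0, "defined": False}
            )
            continue
        rows.append(
            {
                "population": pop,
                "hom_ref": float((d == 0).sum() / n),
                "het": float((d == 1).sum() / n),
                "hom_alt": float((d == 2).sum() / n),
                "n_called": n,
                "defined": True,
            }
        )
    return pd.DataFrame(rows).set_index("population")
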