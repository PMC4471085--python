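"""Central genotype container shared by every pipeline stage.

A :class:`GenotypeMatrix` holds a samples x loci matrix of alternate-allele
dosages (0, 1, 2, or :data:`MISSING`) together with an ordered locus map
(chromosome, 1-based position, id, ref/alt alleles) and an ordered sample
table carrying one population label per individual.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Sentinel dosage for a missing genotype call.
MISSING: int = -1

LOCUS_COLUMNS = ["chrom", "pos", "id", "ref", "alt"]
SAMPLE_COLUMNS = ["sample_id", "population"]


@dataclass
class GenotypeMatrix:
    """Diploid biallelic genotypes for labelled populations.

    Parameters
    ----------
    dosages
        ``(n_samples, n_loci)`` integer array of alt-allele counts;
        ``MISSING`` (-1) marks a failed call.
    loci
        DataFrame with columns ``chrom`` (int), ``pos`` (1-based int),
        ``id``, ``ref``, ``alt``; sorted by (chrom, pos), strictly
        increasing within each chromosome.
    samples
        DataFrame with columns ``sample_id`` and ``population``.
    """

    dosages: np.ndarray
    loci: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D samples x loci array")
        self.loci = self.loci.reset_index(drop=True)
        self.samples = self.samples.reset_index(drop=True)
        if self.dosages.shape != (len(self.samples), len(self.loci)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.samples)} samples x {len(self.loci)} loci"
            )
        missing_cols = [c for c in LOCUS_COLUMNS if c not in self.loci.columns]
        if missing_cols:
            raise ValueError(f"locus table lacks columns {missing_cols}")
        missing_cols = [c for c in SAMPLE_COLUMNS if c not in self.samples.columns]
        if missing_cols:
            raise ValueError(f"sample table lacks columns {missing_cols}")
        bad = ~np.isin(self.dosages, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("dosages must be 0, 1, 2 or MISSING (-1)")
        self._check_sorted()

    def _check_sorted(self) -> None:
        chrom = self.loci["chrom"].to_numpy()
        pos = self.loci["pos"].to_numpy()
        for c in np.unique(chrom):
            p = pos[chrom == c]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"positions not strictly increasing on chromosome {c}")

    # ------------------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_loci(self) -> int:
        return self.dosages.shape[1]

    @property
    def populations(self) -> list[str]:
        """Population labels in order of first appearance."""
        return list(dict.fromkeys(self.samples["population"]))

    def sample_indices(self, population: str) -> np.ndarray:
        idx = np.flatnonzero((self.samples["population"] == population).to_numpy())
        if idx.size == 0:
            raise KeyError(f"unknown population label: {population!r}")
        return idx

    def pop_dosages(self, population: str) -> np.ndarray:
        """Dosage submatrix for one population (rows = its samples)."""
        return self.dosages[self.sample_indices(population), :]

    # ------------------------------------------------------------------
    def subset_loci(self, mask_or_index) -> "GenotypeMatrix":
        """New matrix restricted to the given loci (boolean mask or index array)."""
        arr = np.asarray(mask_or_index)
        if arr.dtype == bool:
            arr = np.flatnonzero(arr)
        return GenotypeMatrix(
            dosages=self.dosages[:, arr],
            loci=self.loci.iloc[arr],
            samples=self.samples,
        )

    def subset_samples(self, mask_or_index) -> "GenotypeMatrix":
        arr = np.asarray(mask_or_index)
        if arr.dtype == bool:
            arr = np.flatnonzero(arr)
        return GenotypeMatrix(
            dosages=self.dosages[arr, :],
            loci=self.loci,
            samples=self.samples.iloc[arr],
        )

    # ------------------------------------------------------------------
    def allele_frequencies(self) -> np.ndarray:
        """Pooled alternate-allele frequency per locus (NaN if all missing)."""
        return _alt_freq(self.dosages)

    def minor_allele_frequencies(self) -> np.ndarray:
        p = self.allele_frequencies()
        return np.minimum(p, 1.0 - p)

    def genotype_counts(self) -> np.ndarray:
        """Pooled (n_loci, 3) counts of hom-ref / het / hom-alt genotypes."""
        out = np.empty((self.n_loci, 3), dtype=np.int64)
        for g in (0, 1, 2):
            out[:, g] = (self.dosages == g).sum(axis=0)
        return out

    def equals(self, other: "GenotypeMatrix") -> bool:
        return (
            np.array_equal(self.dosages, other.dosages)
            and self.loci[LOCUS_COLUMNS].reset_index(drop=True).equals(
                other.loci[LOCUS_COLUMNS].reset_index(drop=True)
            )
            and self.samples[SAMPLE_COLUMNS].reset_index(drop=True).equals(
                other.samples[SAMPLE_COLUMNS].reset_index(drop=True)
            )
        )


def _alt_freq(dosages: np.ndarray) -> np.ndarray:
    """Alt-allele frequency per column ignoring MISSING; NaN where no calls."""
    called = dosages != MISSING
    n = called.sum(axis=0)
    alt = np.where(called, dosages, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(n > 0, alt / (2.0 * n), np.nan)
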