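"""Three-population SNP-chip genotype simulator with planted sweeps.

Drift follows the Balding-Nichols model: each population's allele frequency
at a locus is a Beta draw around an ancestral frequency p, parameterised by
a per-population drift coefficient F so that F is also the model's fixation
index — the genome-wide pairwise Weir-Cockerham theta between two
populations simulated with the same F recovers F.

Breed-specific selection is emulated by "sweep blocks": contiguous genomic
intervals inside which one breed's allele frequency is displaced from the
ancestral value by a fixed shift delta, pushing it toward whichever
boundary is farther from p. This is not a forward simulation; it plants
exactly the allele-frequency architecture that LSBL / d_i scans detect,
with a truth record for power evaluation.

Randomness comes from one seeded generator consumed in a fixed order —
positions, ancestral frequencies, population frequencies, sweep placement,
genotypes, missingness — so a given :class:`SimConfig` reproduces its
output byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .matrix import MISSING, GenotypeMatrix

__all__ = ["SimConfig", "SweepTruth", "simulate_genotypes"]

_FREQ_FLOOR = 0.01
_FREQ_CEIL = 0.99


@dataclass
class SimConfig:
    """Parameters of the three-population drift-plus-sweep simulation.

    Defaults emulate a sheep SNP-chip study design: 26 autosomes at one SNP
    per ~50 kb, three breeds of moderate divergence (pairwise F_ST in the
    0.13-0.19 band arises from ``drift_F = 0.15``), and 300-kb sweep blocks
    with a strong (0.45) frequency displacement.
    """

    pop_labels: Sequence[str] = ("CMF", "GMM", "AWD")
    n_per_pop: int = 100
    n_chrom: int = 26
    chrom_length_bp: int = 100_000_000
    snp_spacing_bp: float = 50_000.0
    drift_F: float | Sequence[float] = 0.15
    n_sweep_regions: int = 0
    sweep_width_bp: int = 300_000
    sweep_shift: float = 0.45
    missing_rate: float = 0.0
    seed: int = 0

    def drift_per_pop(self) -> np.ndarray:
        f = np.broadcast_to(np.asarray(self.drift_F, dtype=float), (len(self.pop_labels),))
        return f.copy()

    def validate(self) -> None:
        if len(self.pop_labels) < 3:
            raise ValueError("at least three population labels are required")
        if len(set(self.pop_labels)) != len(self.pop_labels):
            raise ValueError("population labels must be unique")
        if self.n_per_pop < 2:
            raise ValueError("n_per_pop must be >= 2 (F_ST is undefined below that)")
        if self.n_chrom < 1:
            raise ValueError("n_chrom must be >= 1")
        f = self.drift_per_pop()
        if np.any(f <= 0.0) or np.any(f >= 1.0):
            raise ValueError("drift_F must lie strictly in (0, 1)")
        if not (0.0 <= self.missing_rate <= 1.0):
            raise ValueError("missing_rate must lie in [0, 1]")
        if not (0.0 < self.sweep_shift < 1.0):
            raise ValueError("sweep_shift must lie in (0, 1)")
        if self.n_sweep_regions > 0 and self.sweep_width_bp > self.chrom_length_bp:
            raise ValueError("sweep blocks overflow the chromosome")
        if self.snp_spacing_bp <= 0 or self.chrom_length_bp <= 0:
            raise ValueError("spacing and chromosome length must be positive")


@dataclass
class SweepTruth:
    """Record of planted sweep blocks, one row per (breed, block).

    ``table`` columns: breed, chrom, start, end (1-based inclusive bp),
    delta, n_loci (simulated loci inside the block).
    """

    table: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["breed", "chrom", "start", "end", "delta", "n_loci"]
        )
    )

    def __len__(self) -> int:
        return len(self.table)

    def blocks_for(self, breed: str) -> pd.DataFrame:
        return self.table[self.table["breed"] == breed].reset_index(drop=True)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "SweepTruth":
        return cls(pd.read_csv(path, sep="\t"))


def _place_loci(rng: np.random.Generator, cfg: SimConfig) -> pd.DataFrame:
    """Exponentially spaced 1-based positions per chromosome, sorted."""
    rows = []
    for chrom in range(1, cfg.n_chrom + 1):
        # draw enough gaps to cross the chromosome with slack, then truncate
        n_guess = max(8, int(cfg.chrom_length_bp / cfg.snp_spacing_bp * 1.4) + 8)
        pos = np.array([], dtype=np.int64)
        last = 0.0
        while True:
            gaps = rng.exponential(cfg.snp_spacing_bp, size=n_guess)
            cum = last + np.cumsum(gaps)
            pos = np.concatenate([pos, np.floor(cum).astype(np.int64) + 1])
            last = cum[-1]
            if last > cfg.chrom_length_bp:
                break
        pos = pos[pos <= cfg.chrom_length_bp]
        pos = np.unique(pos)  # drop coincident positions from floor()
        rows.append(pd.DataFrame({"chrom": chrom, "pos": pos}))
    loci = pd.concat(rows, ignore_index=True)
    if loci.empty:
        raise ValueError("no loci generated; increase chromosome length or density")
    loci["id"] = [
        f"snp_{c}_{p}" for c, p in zip(loci["chrom"], loci["pos"])
    ]
    loci["ref"] = "A"
    loci["alt"] = "B"
    return loci


def _place_sweeps(
    rng: np.random.Generator, cfg: SimConfig, loci: pd.DataFrame
) -> pd.DataFrame:
    """Choose non-overlapping sweep blocks, each containing >= 1 locus."""
    chrom_arr = loci["chrom"].to_numpy()
    pos_arr = loci["pos"].to_numpy()
    taken: list[tuple[int, int, int]] = []  # (chrom, start, end)
    records = []
    for breed in cfg.pop_labels:
        for _ in range(cfg.n_sweep_regions):
            for _attempt in range(1000):
                chrom = int(rng.integers(1, cfg.n_chrom + 1))
                start = int(rng.integers(1, cfg.chrom_length_bp - cfg.sweep_width_bp + 2))
                end = start + cfg.sweep_width_bp - 1
                if any(c == chrom and s <= end and start <= e for c, s, e in taken):
                    continue
                inside = (chrom_arr == chrom) & (pos_arr >= start) & (pos_arr <= end)
                if not inside.any():
                    continue
                taken.append((chrom, start, end))
                records.append(
                    {
                        "breed": breed,
                        "chrom": chrom,
                        "start": start,
                        "end": end,
                        "delta": cfg.sweep_shift,
                        "n_loci": int(inside.sum()),
                    }
                )
                break
            else:
                raise RuntimeError(
                    "could not place a sweep block containing a locus; "
                    "chromosomes are too crowded or too sparse"
                )
    return pd.DataFrame(records, columns=["breed", "chrom", "start", "end", "delta", "n_loci"])


def simulate_genotypes(config: SimConfig) -> tuple[GenotypeMatrix, SweepTruth]:
    """Simulate genotypes for ``config`` and return them with the sweep truth.

    Per locus the ancestral frequency p is Uniform(0.05, 0.95); population
    k's frequency is Beta(p(1-F_k)/F_k, (1-p)(1-F_k)/F_k). Inside a sweep
    block of breed k that breed's frequency is replaced by the ancestral
    frequency displaced by delta away from the nearer boundary, clamped to
    [0.01, 0.99]. Genotypes are Binomial(2, p_k); missingness is applied
    independently per call.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    # 1. positions
    loci = _place_loci(rng, config)
    n_loci = len(loci)
    pops = list(config.pop_labels)
    drift = config.drift_per_pop()

    # 2. ancestral then per-population frequencies
    p_anc = rng.uniform(0.05, 0.95, size=n_loci)
    pop_freq = np.empty((len(pops), n_loci))
    for k, f in enumerate(drift):
        scale = (1.0 - f) / f
        pop_freq[k] = rng.beta(p_anc * scale, (1.0 - p_anc) * scale)

    # 3. sweep placement and frequency displacement
    truth_table = _place_sweeps(rng, config, loci) if config.n_sweep_regions > 0 else pd.DataFrame(
        columns=["breed", "chrom", "start", "end", "delta", "n_loci"]
    )
    chrom_arr = loci["chrom"].to_numpy()
    pos_arr = loci["pos"].to_numpy()
    for rec in truth_table.itertuples(index=False):
        k = pops.index(rec.breed)
        inside = (chrom_arr == rec.chrom) & (pos_arr >= rec.start) & (pos_arr <= rec.end)
        p = p_anc[inside]
        shifted = np.where(
            p > 0.5,
            np.maximum(p - rec.delta, _FREQ_FLOOR),
            np.minimum(p + rec.delta, _FREQ_CEIL),
        )
        pop_freq[k, inside] = shifted

    # 4. genotypes
    n = config.n_per_pop
    dosages = np.empty((n * len(pops), n_loci), dtype=np.int8)
    sample_rows = []
    for k, label in enumerate(pops):
        dosages[k * n : (k + 1) * n] = rng.binomial(
            2, pop_freq[k], size=(n, n_loci)
        ).astype(np.int8)
        sample_rows.extend(
            {"sample_id": f"{label}_{i + 1:04d}", "population": label} for i in range(n)
        )

    # 5. missingness
    if config.missing_rate > 0.0:
        mask = rng.random(dosages.shape) < config.missing_rate
        dosages[mask] = MISSING

    gm = GenotypeMatrix(dosages=dosages, loci=loci, samples=pd.DataFrame(sample_rows))
    return gm, SweepTruth(truth_table)
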