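"""Gene annotation of candidate windows and peak SNPs.

Gene intervals come from BED (0-based half-open, converted on read) or
GFF3 (1-based inclusive, filtered to one feature type); all coordinates in
memory are 1-based inclusive. Interval queries use an interval tree per
chromosome.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
from intervaltree import IntervalTree

from .scan import WindowTable

logger = logging.getLogger(__name__)

__all__ = [
    "read_gene_intervals",
    "genes_in_windows",
    "peak_snp_genes",
    "CandidateGeneReport",
]

GENE_COLUMNS = ["chrom", "start", "end", "strand", "gene"]


def read_gene_intervals(path, format: str | None = None, feature_type: str = "gene") -> pd.DataFrame:
    """Read gene intervals from BED or GFF3 into a 1-based inclusive table.

    ``format`` is inferred from the extension when omitted. For GFF3 only
    records whose feature column equals ``feature_type`` are kept; the gene
    name is taken from the ``Name=`` attribute, falling back to ``ID=``.
    """
    path = str(path)
    if format is None:
        low = path.lower()
        if low.endswith((".gff", ".gff3")):
            format = "GFF3"
        elif low.endswith(".bed"):
            format = "BED"
        else:
            raise ValueError(f"cannot infer format of {path}; pass format=")
    format = format.upper()
    if format not in {"BED", "GFF3"}:
        raise ValueError("format must be 'BED' or 'GFF3'")

    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            try:
                if format == "BED":
                    chrom = _norm_chrom(parts[0])
                    start0, end0 = int(parts[1]), int(parts[2])
                    if end0 <= start0:
                        raise ValueError("empty interval")
                    name = parts[3] if len(parts) > 3 else f"feature_{lineno}"
                    strand = parts[5] if len(parts) > 5 else "."
                    rows.append(
                        {"chrom": chrom, "start": start0 + 1, "end": end0,
                         "strand": strand, "gene": name}
                    )
                else:
                    if len(parts) < 9:
                        raise ValueError("GFF3 record has fewer than 9 columns")
                    if parts[2] != feature_type:
                        continue
                    chrom = _norm_chrom(parts[0])
                    start, end = int(parts[3]), int(parts[4])
                    if end < start:
                        raise ValueError("end < start")
                    attrs = dict(
                        kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
                    )
                    name = attrs.get("Name") or attrs.get("ID") or f"feature_{lineno}"
                    rows.append(
                        {"chrom": chrom, "start": start, "end": end,
                         "strand": parts[6], "gene": name}
                    )
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed {format} line ({exc})") from exc
    if not rows:
        logger.warning("%s: no gene intervals loaded", path)
        return pd.DataFrame(columns=GENE_COLUMNS)
    return pd.DataFrame(rows, columns=GENE_COLUMNS)


def _norm_chrom(token: str) -> int:
    token = token[3:] if token.lower().startswith("chr") else token
    return int(token)


def _trees(genes: pd.DataFrame) -> dict[int, IntervalTree]:
    trees: dict[int, IntervalTree] = {}
    for row in genes.itertuples(index=False):
        # half-open tree coordinates: [start, end + 1)
        trees.setdefault(int(row.chrom), IntervalTree()).addi(
            int(row.start), int(row.end) + 1, row.gene
        )
    return trees


def genes_in_windows(
    wt: WindowTable,
    genes: pd.DataFrame,
    merged: dict[str, set[int]] | None = None,
) -> pd.DataFrame:
    """All genes intersecting each (candidate) window.

    With ``merged`` given, only windows in some breed's merged candidate
    set are annotated, and windows present in two or more breeds' sets are
    excluded from the breed-specific lists (they are reported separately
    with breed ``"shared"``). Without it, every retained window is
    annotated with breed ``"*"``.
    """
    trees = _trees(genes)
    table = wt.table
    if merged is None:
        targets = [("*", w) for w in table["window"]]
    else:
        counts: dict[int, list[str]] = {}
        for breed, ws in merged.items():
            for w in ws:
                counts.setdefault(w, []).append(breed)
        targets = []
        for w, breeds in sorted(counts.items()):
            if len(breeds) >= 2:
                targets.append(("shared", w))
            else:
                targets.append((breeds[0], w))
    by_window = table.set_index("window")
    rows = []
    for breed, w in targets:
        rec = by_window.loc[w]
        tree = trees.get(int(rec["chrom"]), IntervalTree())
        # window is 0-based half-open [start, end); 1-based positions start+1..end
        hits = tree.overlap(int(rec["start"]) + 1, int(rec["end"]) + 1)
        names = sorted({h.data for h in hits})
        rows.append(
            {
                "breed": breed,
                "window": w,
                "chrom": int(rec["chrom"]),
                "start": int(rec["start"]),
                "end": int(rec["end"]),
                "n_genes": len(names),
                "genes": ",".join(names),
            }
        )
    return pd.DataFrame(
        rows, columns=["breed", "window", "chrom", "start", "end", "n_genes", "genes"]
    )


@dataclass
class CandidateGeneReport:
    """Genes in candidate windows and around their peak SNPs, per breed."""

    window_genes: pd.DataFrame
    peak_genes: pd.DataFrame
    near_bp: int

    def to_tsv(self, window_path, peak_path) -> None:
        self.window_genes.to_csv(window_path, sep="\t", index=False)
        self.peak_genes.to_csv(peak_path, sep="\t", index=False)


def peak_snp_genes(
    wt: WindowTable,
    genes: pd.DataFrame,
    loci: pd.DataFrame,
    merged: dict[str, set[int]],
    near_bp: int = 50_000,
) -> CandidateGeneReport:
    """Genes located in or near each candidate window's peak SNP.

    A gene qualifies if its interval contains the peak SNP position or lies
    within ``near_bp`` of it; the reported distance is 0 for containment,
    else the gap to the nearer interval edge. Windows selected in two or
    more breeds are reported under breed ``"shared"``.
    """
    trees = _trees(genes)
    pos_of = dict(zip(loci["id"], loci["pos"]))
    window_genes = genes_in_windows(wt, genes, merged)
    by_window = wt.table.set_index("window")

    counts: dict[int, list[str]] = {}
    for breed, ws in merged.items():
        for w in ws:
            counts.setdefault(w, []).append(breed)

    rows = []
    for w, breeds in sorted(counts.items()):
        label = "shared" if len(breeds) >= 2 else breeds[0]
        rec = by_window.loc[w]
        for breed in breeds:
            peak_id = rec[f"peak_{breed}"]
            peak_pos = int(pos_of[peak_id])
            tree = trees.get(int(rec["chrom"]), IntervalTree())
            hits = tree.overlap(peak_pos - near_bp, peak_pos + near_bp + 1)
            for h in sorted(hits, key=lambda h: (h.begin, h.data)):
                start, end = h.begin, h.end - 1
                if start <= peak_pos <= end:
                    dist = 0
                else:
                    dist = min(abs(start - peak_pos), abs(end - peak_pos))
                if dist > near_bp:
                    continue
                rows.append(
                    {
                        "breed": label,
                        "peak_breed": breed,
                        "window": w,
                        "peak_snp": peak_id,
                        "peak_pos": peak_pos,
                        "gene": h.data,
                        "distance_bp": dist,
                    }
                )
    peak_df = pd.DataFrame(
        rows,
        columns=["breed", "peak_breed", "window", "peak_snp", "peak_pos", "gene", "distance_bp"],
    )
    return CandidateGeneReport(window_genes=window_genes, peak_genes=peak_df, near_bp=near_bp)
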