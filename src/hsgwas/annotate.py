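"""Candidate-gene lookup: genes within +/-100 kb of suggestive SNPs.

A gene is a candidate for a SNP when its [start, end] interval (1-based,
inclusive) intersects [pos - flank, pos + flank] on the same chromosome;
strand is ignored. BED input (0-based half-open) is converted on read.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ParseError

DEFAULT_FLANK_BP = 100_000

_GENE_COLUMNS = ["gene_id", "symbol", "chrom", "start_bp", "end_bp", "strand"]


def read_bed_genes(path) -> pd.DataFrame:
    """Gene table from BED (chrom, start, end[, name[, score[, strand]]])."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: BED needs >= 3 columns")
            try:
                start = int(parts[1])
                end = int(parts[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            name = parts[3] if len(parts) > 3 else f"bed_{lineno}"
            strand = parts[5] if len(parts) > 5 and parts[5] in "+-" else "unknown"
            # BED is 0-based half-open; internal coordinates are 1-based inclusive
            rows.append((name, name, parts[0], start + 1, end, strand))
    return pd.DataFrame(rows, columns=_GENE_COLUMNS)


def read_gff3_genes(path, feature_types=("gene",)) -> pd.DataFrame:
    """Gene-type features from a GFF3 file (coordinates passed through)."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ParseError(f"{path}:{lineno}: GFF3 needs 9 tab-separated columns")
            if parts[2] not in feature_types:
                continue
            try:
                start = int(parts[3])
                end = int(parts[4])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            attrs = {}
            for item in parts[8].split(";"):
                if "=" in item:
                    k, v = item.split("=", 1)
                    attrs[k.strip()] = v.strip()
            gene_id = attrs.get("ID", attrs.get("gene_id", f"gff_{lineno}"))
            symbol = attrs.get("Name", attrs.get("gene_name", ""))
            strand = parts[6] if parts[6] in "+-" else "unknown"
            rows.append((gene_id, symbol, parts[0], start, end, strand))
    return pd.DataFrame(rows, columns=_GENE_COLUMNS)


def window_genes(hits: pd.DataFrame, genes: pd.DataFrame,
                 flank: int = DEFAULT_FLANK_BP) -> pd.DataFrame:
    """Candidate associations for labeled SNPs.

    ``hits`` needs snp_id, chrom, pos (extra columns such as hit labels are
    carried through); ``genes`` is a frame as returned by the readers above.
    Distance is 0 when the SNP lies inside the gene, otherwise the gap to the
    nearest gene edge. Hits on chromosomes absent from the gene table are
    skipped. Duplicate (snp, gene) pairs are collapsed.
    """
    carry = [c for c in hits.columns if c.startswith("label_") or c == "trait"]
    out = []
    gene_chroms = set(genes["chrom"].astype(str))
    for _, hit in hits.iterrows():
        chrom = str(hit["chrom"])
        if chrom not in gene_chroms:
            continue
        sub = genes[genes["chrom"].astype(str) == chrom]
        pos = int(hit["pos"])
        start = sub["start_bp"].to_numpy(dtype=np.int64)
        end = sub["end_bp"].to_numpy(dtype=np.int64)
        dist = np.maximum(start - pos, 0) + np.maximum(pos - end, 0)
        sel = dist <= flank
        for gi, d in zip(np.flatnonzero(sel), dist[sel]):
            rec = {
                "snp_id": hit["snp_id"],
                "gene_id": sub.iloc[gi]["gene_id"],
                "symbol": sub.iloc[gi]["symbol"],
                "distance_bp": int(d),
            }
            for c in carry:
                rec[c] = hit[c]
            out.append(rec)
    frame = pd.DataFrame(out, columns=["snp_id", "gene_id", "symbol", "distance_bp"] + carry)
    return frame.drop_duplicates(subset=["snp_id", "gene_id"]).reset_index(drop=True)
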