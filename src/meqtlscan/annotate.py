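"""Cis / long-cis / trans classification of SNP-CpG pairs.

A pair on the same chromosome closer than the window (default 1 Mb) is cis;
same chromosome at or beyond the window is long-distance cis; different
chromosomes is trans. Distance-at-window is assigned to long_cis (cis
requires a strictly smaller distance). Chromosome labels are compared
case-insensitively after stripping an optional ``chr`` prefix.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

CIS = "cis"
LONG_CIS = "long_cis"
TRANS = "trans"
DEFAULT_WINDOW = 1_000_000


@dataclass(frozen=True)
class Locus:
    feature_id: str
    chrom: str
    pos: int  # 1-based

    def __post_init__(self) -> None:
        if not str(self.chrom).strip():
            raise ValueError(f"{self.feature_id}: empty chromosome label")
        if self.pos < 1:
            raise ValueError(f"{self.feature_id}: position must be >= 1")


@dataclass(frozen=True)
class MeqtlClass:
    category: str                 # cis | long_cis | trans
    distance: int | None = None   # bp; None exactly when trans


def normalize_chrom(label: str) -> str:
    s = str(label).strip()
    if s.lower().startswith("chr"):
        s = s[3:]
    return s.upper()


def classify_pair(snp: Locus, cpg: Locus, window: int = DEFAULT_WINDOW) -> MeqtlClass:
    """Classify one SNP-CpG pair; symmetric in argument order."""
    if normalize_chrom(snp.chrom) != normalize_chrom(cpg.chrom):
        return MeqtlClass(TRANS, None)
    distance = abs(int(snp.pos) - int(cpg.pos))
    return MeqtlClass(CIS if distance < window else LONG_CIS, distance)


def annotate_records(
    records: pd.DataFrame,
    snp_loci: pd.DataFrame,
    cpg_loci: pd.DataFrame,
    window: int = DEFAULT_WINDOW,
) -> pd.DataFrame:
    """Add ``category`` and ``distance_bp`` columns to a results table.

    ``snp_loci`` / ``cpg_loci`` are feature_id-indexed frames with ``chrom``
    and 1-based ``pos`` (as produced by :func:`meqtlscan.io.read_bed`).
    Raises KeyError naming the first feature without an annotation.
    """
    for col, loci, what in (
        ("snp_id", snp_loci, "SNP"), ("cpg_id", cpg_loci, "CpG")
    ):
        missing = set(records[col]) - set(loci.index)
        if missing:
            raise KeyError(f"no {what} annotation for {sorted(missing)[:5]}")

    snp_chrom = records["snp_id"].map(snp_loci["chrom"]).map(normalize_chrom)
    cpg_chrom = records["cpg_id"].map(cpg_loci["chrom"]).map(normalize_chrom)
    snp_pos = records["snp_id"].map(snp_loci["pos"]).astype(int)
    cpg_pos = records["cpg_id"].map(cpg_loci["pos"]).astype(int)

    same = (snp_chrom == cpg_chrom).to_numpy()
    dist = (snp_pos - cpg_pos).abs().to_numpy()

    out = records.copy()
    out["category"] = TRANS
    out.loc[same & (dist < window), "category"] = CIS
    out.loc[same & (dist >= window), "category"] = LONG_CIS
    out["distance_bp"] = pd.array(dist, dtype="Int64")
    out.loc[~same, "distance_bp"] = pd.NA
    return out
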