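"""In-memory containers for genotype, methylation and sample-metadata tables.

All matrices are pandas DataFrames with features (SNPs or CpGs) as rows and
samples as columns; missing entries are ``NaN``. Thin dataclass wrappers carry
the per-feature metadata alongside the value matrix and validate the joint
invariants (code alphabet, value ranges, id alignment) at construction time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VALID_GROUPS = ("case", "control")


class DataError(ValueError):
    """A container invariant is violated (bad codes, ranges, or id mismatch)."""


def _require_unique(index: pd.Index, what: str) -> None:
    if index.has_duplicates:
        dups = index[index.duplicated()].unique().tolist()
        raise DataError(f"duplicate {what} ids: {dups[:5]}")


@dataclass
class GenotypeMatrix:
    """Minor-allele dosage codes (SNPs x samples) plus per-SNP metadata.

    ``codes`` entries are 0, 1, 2 (count of minor-allele copies) or NaN for a
    missing call. ``snp_meta`` is indexed by snp_id with columns
    ``chrom``, ``pos``, ``minor_allele``, ``call_rate``.
    """

    codes: pd.DataFrame
    snp_meta: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        _require_unique(self.codes.index, "SNP")
        _require_unique(self.codes.columns, "sample")
        vals = self.codes.to_numpy(dtype=float)
        ok = np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0))
        if not ok.all():
            i, j = np.argwhere(~ok)[0]
            raise DataError(
                f"genotype code {vals[i, j]!r} at SNP {self.codes.index[i]!r}, "
                f"sample {self.codes.columns[j]!r} is not in {{0, 1, 2, NA}}"
            )
        if self.snp_meta is None:
            self.snp_meta = pd.DataFrame(
                {
                    "chrom": pd.Series("NA", index=self.codes.index, dtype=object),
                    "pos": pd.Series(0, index=self.codes.index),
                    "minor_allele": pd.Series("N", index=self.codes.index, dtype=object),
                    "call_rate": self.call_rates(),
                }
            )
        elif not self.snp_meta.index.equals(self.codes.index):
            raise DataError("snp_meta index does not match the code matrix rows")

    @property
    def snp_ids(self) -> pd.Index:
        return self.codes.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.codes.columns

    def call_rates(self) -> pd.Series:
        """Fraction of non-missing calls per SNP."""
        return self.codes.notna().mean(axis=1)

    def missing_rates(self) -> pd.Series:
        return 1.0 - self.call_rates()

    def mafs(self) -> pd.Series:
        """Folded minor-allele frequency per SNP, computed from the codes."""
        n_called = self.codes.notna().sum(axis=1)
        freq = self.codes.sum(axis=1, skipna=True) / (2.0 * n_called)
        return np.minimum(freq, 1.0 - freq)

    def subset_snps(self, snp_ids) -> "GenotypeMatrix":
        return GenotypeMatrix(
            codes=self.codes.loc[snp_ids], snp_meta=self.snp_meta.loc[snp_ids]
        )


@dataclass
class MethylationMatrix:
    """Beta values (CpGs x samples) in [0, 1]; NaN marks a missing probe."""

    values: pd.DataFrame
    cpg_meta: pd.DataFrame | None = None  # optional: chrom, pos per CpG

    def __post_init__(self) -> None:
        _require_unique(self.values.index, "CpG")
        _require_unique(self.values.columns, "sample")
        vals = self.values.to_numpy(dtype=float)
        bad = ~(np.isnan(vals) | ((vals >= 0.0) & (vals <= 1.0)))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise DataError(
                f"beta value {vals[i, j]!r} at CpG {self.values.index[i]!r}, "
                f"sample {self.values.columns[j]!r} is outside [0, 1]"
            )
        if self.cpg_meta is not None and not self.cpg_meta.index.equals(
            self.values.index
        ):
            raise DataError("cpg_meta index does not match the value matrix rows")

    @property
    def cpg_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns


@dataclass
class SampleTable:
    """Sample metadata: group label (case/control) and age covariate.

    ``table`` is indexed by sample_id with columns ``group`` and ``age``.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        _require_unique(self.table.index, "sample")
        missing_cols = {"group", "age"} - set(self.table.columns)
        if missing_cols:
            raise DataError(f"sample table lacks columns: {sorted(missing_cols)}")
        bad = ~self.table["group"].isin(VALID_GROUPS)
        if bad.any():
            raise DataError(
                f"sample group labels must be in {VALID_GROUPS}; "
                f"got {self.table.loc[bad, 'group'].unique().tolist()[:5]}"
            )
        if not np.isfinite(self.table["age"].to_numpy(dtype=float)).all():
            raise DataError("sample ages must be finite numbers")

    @property
    def sample_ids(self) -> pd.Index:
        return self.table.index

    def group_ids(self, group: str) -> pd.Index:
        """Sample ids in one group, or all samples for group='all'."""
        if group == "all":
            return self.table.index
        if group not in VALID_GROUPS:
            raise DataError(f"unknown group {group!r}; expected case/control/all")
        return self.table.index[self.table["group"] == group]
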