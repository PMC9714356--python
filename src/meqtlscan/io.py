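"""TSV/BED readers and writers.

Matrix dialect: tab-separated, first column ``feature_id``, remaining columns
one per sample with sample ids in the header row; ``NA`` marks a missing
value. BED files are 4-column, 0-based half-open (chrom, start, end,
feature_id); internally positions are 1-based (pos = start + 1).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .containers import DataError, GenotypeMatrix, MethylationMatrix, SampleTable

MATRIX_KINDS = ("methylation", "probes", "genotypes")


class ParseError(ValueError):
    """Malformed input file; the message names the file and the offending
    line or cell."""


def _check_rectangular(path: Path) -> None:
    # Cheap tab-count pass so ragged rows get reported with a line number
    # (pandas silently NaN-pads short rows).
    with open(path) as fh:
        header = fh.readline()
        want = header.count("\t")
        for lineno, line in enumerate(fh, start=2):
            if line.strip() and line.rstrip("\n").count("\t") != want:
                raise ParseError(
                    f"{path}: line {lineno} has "
                    f"{line.rstrip(chr(10)).count(chr(9)) + 1} fields, "
                    f"expected {want + 1}"
                )


def read_matrix(path: str | Path, kind: str) -> pd.DataFrame:
    """Read a feature x sample matrix and validate values for ``kind``.

    kind='methylation' or 'probes': values in [0, 1] or NA.
    kind='genotypes': values in {0, 1, 2} or NA.
    """
    if kind not in MATRIX_KINDS:
        raise ValueError(f"unknown matrix kind {kind!r}; expected {MATRIX_KINDS}")
    path = Path(path)
    _check_rectangular(path)
    try:
        df = pd.read_csv(
            path, sep="\t", index_col=0, na_values=["NA"],
            keep_default_na=False, float_precision="round_trip",
        )
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ParseError(f"{path}: duplicate feature ids {dups[:5]}")
    if df.columns.has_duplicates:
        dups = df.columns[df.columns.duplicated()].unique().tolist()
        raise ParseError(f"{path}: duplicate sample ids {dups[:5]}")
    try:
        vals = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric matrix entry ({exc})") from exc

    if kind == "genotypes":
        ok = np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0))
        rule = "a genotype code in {0, 1, 2}"
    else:
        ok = np.isnan(vals) | ((vals >= 0.0) & (vals <= 1.0))
        rule = "a beta value in [0, 1]"
    if not ok.all():
        i, j = np.argwhere(~ok)[0]
        raise ParseError(
            f"{path}: line {i + 2}, value {vals[i, j]!r} at row "
            f"{df.index[i]!r}, column {df.columns[j]!r} is not {rule}"
        )
    df.index.name = "feature_id"
    return df


def write_matrix(df: pd.DataFrame, path: str | Path, genotype: bool = False) -> None:
    """Write a feature x sample matrix; NaN becomes ``NA``.

    Genotype matrices are written with integer codes.
    """
    out = df.copy()
    out.index.name = "feature_id"
    if genotype:
        out = out.astype("Int64")  # keeps NA while printing 0/1/2 as integers
        out.to_csv(path, sep="\t", na_rep="NA")
    else:
        # %.17g guarantees a lossless float64 round-trip
        out.to_csv(path, sep="\t", na_rep="NA", float_format="%.17g")


def read_genotype_matrix(path: str | Path) -> GenotypeMatrix:
    codes = read_matrix(path, kind="genotypes")
    codes.index.name = "snp_id"
    return GenotypeMatrix(codes=codes)


def read_methylation_matrix(path: str | Path) -> MethylationMatrix:
    values = read_matrix(path, kind="methylation")
    values.index.name = "cpg_id"
    return MethylationMatrix(values=values)


def read_sample_table(path: str | Path) -> SampleTable:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "group": str})
    want = {"sample_id", "group", "age"}
    if not want <= set(df.columns):
        raise ParseError(
            f"{path}: sample table needs columns {sorted(want)}, "
            f"found {list(df.columns)}"
        )
    try:
        return SampleTable(df.set_index("sample_id"))
    except DataError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_sample_table(samples: SampleTable, path: str | Path) -> None:
    samples.table.rename_axis("sample_id").to_csv(path, sep="\t")


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read a 4-column BED into a feature_id-indexed frame with ``chrom`` and
    1-based ``pos`` (= start + 1)."""
    path = Path(path)
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "feature_id"],
        dtype={"chrom": str, "feature_id": str},
        comment="#",
    )
    if df[["start", "end"]].isna().any().any():
        raise ParseError(f"{path}: BED needs 4 columns chrom/start/end/feature_id")
    if (df["start"] < 0).any() or (df["end"] <= df["start"]).any():
        bad = df[(df["start"] < 0) | (df["end"] <= df["start"])].iloc[0]
        raise ParseError(
            f"{path}: invalid interval {bad['chrom']}:{bad['start']}-{bad['end']} "
            f"for {bad['feature_id']}"
        )
    if df["feature_id"].duplicated().any():
        dups = df.loc[df["feature_id"].duplicated(), "feature_id"].tolist()
        raise ParseError(f"{path}: duplicate feature ids {dups[:5]}")
    out = df.set_index("feature_id")
    out["pos"] = out["start"] + 1
    return out[["chrom", "pos"]]


def write_bed(meta: pd.DataFrame, path: str | Path) -> None:
    """Write feature loci (``chrom``, 1-based ``pos``) as single-base BED."""
    bed = pd.DataFrame(
        {
            "chrom": meta["chrom"],
            "start": meta["pos"] - 1,
            "end": meta["pos"],
            "feature_id": meta.index,
        }
    )
    bed.to_csv(path, sep="\t", header=False, index=False)


_FLOAT_COLS_SCI = ("p_value", "q_value", "ttest_p")


def write_results(df: pd.DataFrame, path: str | Path) -> None:
    """Write a results table; p/q columns in full-precision scientific
    notation so round-trips lose nothing."""
    out = df.copy()
    for col in _FLOAT_COLS_SCI:
        if col in out.columns:
            out[col] = out[col].map(
                lambda v: "NA" if pd.isna(v) else format(v, ".17e")
            )
    out.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"],
                       keep_default_na=False, float_precision="round_trip")


def read_series_matrix_like(path: str | Path, kind: str = "methylation") -> pd.DataFrame:
    """Thin converter for a GEO-series-matrix-like layout: ``!``-prefixed
    metadata lines, then a header row starting with ``ID_REF`` or
    ``"ID_REF"`` and one quoted-or-plain column per sample."""
    path = Path(path)
    rows: list[str] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("!") or not line.strip():
                continue
            rows.append(line.replace('"', ""))
    if not rows:
        raise ParseError(f"{path}: no matrix block found")
    from io import StringIO

    df = pd.read_csv(
        StringIO("".join(rows)), sep="\t", index_col=0,
        na_values=["NA", "null"], keep_default_na=False,
    )
    df.index.name = "feature_id"
    # reuse the validation path by bouncing through the standard dialect
    vals = df.to_numpy(dtype=float)
    if kind != "genotypes":
        bad = ~(np.isnan(vals) | ((vals >= 0.0) & (vals <= 1.0)))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ParseError(
                f"{path}: value {vals[i, j]!r} at row {df.index[i]!r}, "
                f"column {df.columns[j]!r} is not a beta value in [0, 1]"
            )
    return df
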