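"""Ingest single-cell V(D)J contig tables into one normalized representation.

Two dialects are supported: the 10x Genomics ``filtered_contig_annotations.csv``
produced by Cell Ranger, and the AIRR Rearrangement TSV standard. Both are
normalized to a common contig table (one row per assembled chain observation)
restricted to the alpha/beta TCR loci, plus an optional per-cell metadata join
(patient, tissue compartment, CD4/CD8 subset, phenotype cluster).

Gene identity is kept at gene level: allele suffixes such as ``*01`` are
stripped, because a cell's "alleles" are counted as distinct rearranged V
transcripts, identified at gene resolution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Canonical columns of the normalized contig table, in emission order.
CONTIG_COLUMNS = [
    "barcode",
    "contig_id",
    "locus",
    "v_gene",
    "j_gene",
    "cdr3_nt",
    "cdr3_aa",
    "productive",
    "umis",
    "reads",
    "sample_id",
]

#: Metadata columns attached per barcode.
METADATA_COLUMNS = ["patient_id", "tissue", "subset", "cluster"]

TCR_AB_LOCI = ("TRA", "TRB")
VALID_TISSUES = ("P", "N", "T")

# Cell Ranger writes productive as the strings "True" / "False" / "None";
# AIRR writes "T" / "F"; only an affirmative value counts as productive.
_PRODUCTIVE_TRUE = {"true", "t", "yes", "1"}
_PRODUCTIVE_FALSE = {"false", "f", "no", "0", "none", "nan", ""}


@dataclass
class ContigTable:
    """Normalized contig observations plus per-cell metadata.

    Attributes
    ----------
    contigs
        One row per retained chain observation with columns
        :data:`CONTIG_COLUMNS`.
    cells
        Per-barcode metadata (columns ``barcode`` + :data:`METADATA_COLUMNS`);
        empty until :func:`attach_metadata` is called.
    provenance
        Source dialect and file path.
    n_dropped_non_ab
        Rows discarded because their locus was not TRA/TRB.
    n_unjoined
        Barcodes with contigs but no metadata row after the join.
    """

    contigs: pd.DataFrame
    cells: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["barcode", *METADATA_COLUMNS])
    )
    provenance: str = ""
    n_dropped_non_ab: int = 0
    n_unjoined: int = 0

    def __post_init__(self) -> None:
        missing = [c for c in CONTIG_COLUMNS if c not in self.contigs.columns]
        if missing:
            raise ValueError(f"contig table missing columns: {missing}")
        self.contigs = self.contigs[CONTIG_COLUMNS].reset_index(drop=True)

    @property
    def n_records(self) -> int:
        return len(self.contigs)

    @property
    def barcodes(self) -> pd.Index:
        return pd.Index(self.contigs["barcode"].unique())

    def with_metadata(self) -> pd.DataFrame:
        """Contigs left-joined with cell metadata (NaN where unjoined)."""
        if self.cells.empty:
            out = self.contigs.copy()
            for col in METADATA_COLUMNS:
                out[col] = np.nan
            return out
        return self.contigs.merge(self.cells, on="barcode", how="left")


def _parse_productive(series: pd.Series) -> pd.Series:
    s = series.astype(str).str.strip().str.lower()
    unknown = sorted(set(s) - _PRODUCTIVE_TRUE - _PRODUCTIVE_FALSE)
    if unknown:
        logger.warning("unrecognized productive values treated as False: %s", unknown)
    return s.isin(_PRODUCTIVE_TRUE)


def _parse_umis(series: pd.Series, colname: str) -> pd.Series:
    numeric = pd.to_numeric(series, errors="coerce")
    bad = numeric.isna() & series.notna()
    if bad.any():
        idx = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(f"unparseable {colname} value {series.iloc[idx]!r} at row {idx}")
    if (numeric.dropna() < 0).any():
        idx = int(np.flatnonzero((numeric < 0).to_numpy())[0])
        raise ValueError(f"negative {colname} at row {idx}")
    return numeric


def strip_allele(call: str) -> str:
    """Reduce an IMGT allele call to gene level: ``TRAV1-2*01`` -> ``TRAV1-2``."""
    if not isinstance(call, str):
        return ""
    return call.split("*", 1)[0].strip()


def _check_locus_consistency(df: pd.DataFrame) -> pd.DataFrame:
    """Drop rows whose V-gene prefix contradicts the declared locus."""
    v_prefix = df["v_gene"].str.slice(0, 3)
    has_prefix = v_prefix.isin(TCR_AB_LOCI)
    mismatch = has_prefix & (v_prefix != df["locus"])
    n_bad = int(mismatch.sum())
    if n_bad:
        logger.warning("dropped %d contigs with V gene / locus mismatch", n_bad)
    return df.loc[~mismatch]


def _warn_frame_violations(df: pd.DataFrame) -> None:
    bad = df["productive"] & (df["cdr3_nt"].str.len() % 3 != 0)
    if bad.any():
        logger.warning(
            "%d productive contigs have CDR3nt length not divisible by 3", int(bad.sum())
        )


def _finalize(df: pd.DataFrame, sample_id: str | None) -> pd.DataFrame:
    sid = sample_id or ""
    df = df.assign(sample_id=sid)
    if sample_id:
        df = df.assign(barcode=sid + ":" + df["barcode"].astype(str))
    _warn_frame_violations(df)
    return df[CONTIG_COLUMNS]


def read_10x_contigs(
    path: str | Path,
    require_cell: bool = True,
    require_high_confidence: bool = True,
    sample_id: str | None = None,
) -> ContigTable:
    """Read a Cell Ranger ``filtered_contig_annotations.csv``.

    Parameters
    ----------
    path
        CSV file with at least the columns barcode, chain, v_gene, j_gene,
        cdr3_nt, productive, umis.
    require_cell, require_high_confidence
        Retain only rows flagged ``is_cell`` / ``high_confidence`` when the
        column is present. Public deposits are typically pre-filtered, so
        both default to True and are no-ops when the columns are absent.
    sample_id
        When given, barcodes are prefixed ``sample_id:barcode`` so that
        multi-sample concatenations cannot collide.
    """
    df = pd.read_csv(path, dtype=str)
    required = ["barcode", "chain", "v_gene", "j_gene", "cdr3_nt", "productive", "umis"]
    for col in required:
        if col not in df.columns:
            raise ValueError(f"10x contig file {path} missing mandatory column {col!r}")

    for flag, want in (("is_cell", require_cell), ("high_confidence", require_high_confidence)):
        if want and flag in df.columns:
            df = df.loc[_parse_productive(df[flag])]

    n_before = len(df)
    df = df.loc[df["chain"].isin(TCR_AB_LOCI)].copy()
    n_dropped = n_before - len(df)
    if n_dropped:
        logger.info("dropped %d non-TRA/TRB contigs from %s", n_dropped, path)

    out = pd.DataFrame(
        {
            "barcode": df["barcode"].astype(str),
            "contig_id": df.get("contig_id", pd.Series(dtype=str)).reindex(df.index).fillna(
                pd.Series((f"contig_{i}" for i in range(len(df))), index=df.index)
            ),
            "locus": df["chain"],
            "v_gene": df["v_gene"].fillna("").map(strip_allele),
            "j_gene": df["j_gene"].fillna("").map(strip_allele),
            "cdr3_nt": df["cdr3_nt"].fillna("").astype(str),
            "cdr3_aa": df["cdr3"].fillna("").astype(str) if "cdr3" in df.columns else "",
            "productive": _parse_productive(df["productive"]),
            "umis": _parse_umis(df["umis"], "umis").astype(int),
            "reads": _parse_umis(df["reads"], "reads")
            if "reads" in df.columns
            else np.nan,
        }
    )
    out = _check_locus_consistency(out)
    out = _finalize(out, sample_id)
    return ContigTable(out, provenance=f"10x:{path}", n_dropped_non_ab=n_dropped)


def read_airr_rearrangements(path: str | Path, sample_id: str | None = None) -> ContigTable:
    """Read an AIRR Rearrangement TSV with single-cell ``cell_id`` assignments.

    The AIRR ``junction`` field maps to ``cdr3_nt`` and ``v_call``/``j_call``
    allele suffixes are stripped to gene level. Files without a ``cell_id``
    column are rejected: bulk rearrangement tables cannot support per-cell
    chain pairing.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "cell_id" not in df.columns:
        raise ValueError(f"AIRR file {path} lacks the 'cell_id' field required for single-cell pairing")
    required = ["locus", "v_call", "j_call", "junction", "productive"]
    for col in required:
        if col not in df.columns:
            raise ValueError(f"AIRR file {path} missing mandatory column {col!r}")

    count_col = next(
        (c for c in ("duplicate_count", "consensus_count") if c in df.columns), None
    )
    if count_col is None:
        raise ValueError(f"AIRR file {path} has neither duplicate_count nor consensus_count")

    n_before = len(df)
    df = df.loc[df["locus"].isin(TCR_AB_LOCI)].copy()
    n_dropped = n_before - len(df)

    out = pd.DataFrame(
        {
            "barcode": df["cell_id"].astype(str),
            "contig_id": df.get("sequence_id", pd.Series(dtype=str)).reindex(df.index).fillna(
                pd.Series((f"seq_{i}" for i in range(len(df))), index=df.index)
            ),
            "locus": df["locus"],
            "v_gene": df["v_call"].fillna("").map(strip_allele),
            "j_gene": df["j_call"].fillna("").map(strip_allele),
            "cdr3_nt": df["junction"].fillna("").astype(str),
            "cdr3_aa": df["junction_aa"].fillna("").astype(str)
            if "junction_aa" in df.columns
            else "",
            "productive": _parse_productive(df["productive"]),
            "umis": _parse_umis(df[count_col], count_col).astype(int),
            "reads": np.nan,
        }
    )
    out = _check_locus_consistency(out)
    out = _finalize(out, sample_id)
    return ContigTable(out, provenance=f"airr:{path}", n_dropped_non_ab=n_dropped)


def attach_metadata(
    table: ContigTable,
    meta: pd.DataFrame | str | Path,
    tissue_map: dict[str, str] | None = None,
) -> ContigTable:
    """Join per-cell metadata (patient, tissue, subset, cluster) onto a table.

    ``meta`` is a DataFrame or a CSV/TSV path with a ``barcode`` column.
    Tissue values must be P/N/T or translatable through ``tissue_map``.
    Contigs whose barcode lacks a metadata row are retained but counted in
    ``n_unjoined``. Duplicate metadata rows with conflicting values are fatal.
    """
    if not isinstance(meta, pd.DataFrame):
        sep = "\t" if str(meta).endswith((".tsv", ".txt")) else ","
        meta = pd.read_csv(meta, sep=sep, dtype=str)
    meta = meta.copy()
    if "barcode" not in meta.columns:
        raise ValueError("metadata table lacks a 'barcode' column")
    for col in METADATA_COLUMNS:
        if col not in meta.columns:
            meta[col] = ""

    if meta["barcode"].duplicated().any():
        dup = meta.loc[meta["barcode"].duplicated(keep=False)]
        if dup.groupby("barcode")[METADATA_COLUMNS].nunique().gt(1).any().any():
            raise ValueError("conflicting duplicate metadata rows for some barcodes")
        meta = meta.drop_duplicates("barcode")

    if tissue_map:
        meta["tissue"] = meta["tissue"].replace(tissue_map)
    bad_tissue = sorted(set(meta["tissue"].dropna()) - set(VALID_TISSUES) - {""})
    if bad_tissue:
        raise ValueError(
            f"tissue values {bad_tissue} not in {VALID_TISSUES}; pass tissue_map to translate"
        )

    cells = meta[["barcode", *METADATA_COLUMNS]].reset_index(drop=True)
    joined = set(cells["barcode"])
    table_barcodes = table.contigs["barcode"].unique()
    n_unjoined = int(sum(b not in joined for b in table_barcodes))
    if n_unjoined:
        logger.info("%d barcodes have contigs but no metadata row", n_unjoined)
    return ContigTable(
        table.contigs.copy(),
        cells=cells,
        provenance=table.provenance,
        n_dropped_non_ab=table.n_dropped_non_ab,
        n_unjoined=n_unjoined,
    )


def write_10x_csv(table: ContigTable, path: str | Path) -> None:
    """Write the normalized table in the Cell Ranger contig-annotation dialect.

    Round-trips through :func:`read_10x_contigs` with identical normalized
    content (productive is emitted as "True"/"None" per the dialect).
    """
    df = table.contigs
    out = pd.DataFrame(
        {
            "barcode": df["barcode"],
            "is_cell": "True",
            "contig_id": df["contig_id"],
            "high_confidence": "True",
            "chain": df["locus"],
            "v_gene": df["v_gene"],
            "d_gene": "None",
            "j_gene": df["j_gene"],
            "c_gene": "None",
            "full_length": "True",
            "productive": np.where(df["productive"], "True", "None"),
            "cdr3": df["cdr3_aa"],
            "cdr3_nt": df["cdr3_nt"],
            "reads": df["reads"].fillna(0).astype(int),
            "umis": df["umis"],
        }
    )
    out.to_csv(path, index=False)


def write_airr_tsv(table: ContigTable, path: str | Path) -> None:
    """Write the normalized table as an AIRR-flavored Rearrangement TSV.

    Round-trips through :func:`read_airr_rearrangements` with identical
    normalized content.
    """
    df = table.contigs
    out = pd.DataFrame(
        {
            "sequence_id": df["contig_id"],
            "cell_id": df["barcode"],
            "locus": df["locus"],
            "v_call": df["v_gene"],
            "j_call": df["j_gene"],
            "junction": df["cdr3_nt"],
            "junction_aa": df["cdr3_aa"],
            "productive": np.where(df["productive"], "T", "F"),
            "duplicate_count": df["umis"],
        }
    )
    out.to_csv(path, sep="\t", index=False)
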