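"""Reading, consolidating and integerizing spectral-count matrices.

Shotgun-proteomics quantification by spectral counting yields a protein x
sample table of (possibly fractional, after share-splitting of degenerate
peptides) non-negative counts.  Downstream rank and count statistics expect
one integer row per gene, so ingestion performs three steps:

1. parse the TSV into a :class:`SpectralCountMatrix`,
2. consolidate isoforms — rows sharing a gene symbol are summed column-wise,
3. integerize — every value is replaced by its ceiling.

Consolidation precedes integerization by default because the ceiling of a
sum differs from the sum of ceilings; the opposite order remains available
to callers that want it.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SampleLabel",
    "SpectralCountMatrix",
    "read_spectral_counts",
    "write_spectral_counts",
    "consolidate_isoforms",
    "integerize_counts",
]

MALIGNANT = "malignant"
NON_MALIGNANT = "non_malignant"

_LABEL_RE = re.compile(r"^(?P<line>[NT])_b(?P<bio>\d+)_t(?P<tech>\d+)$")


@dataclass(frozen=True, order=True)
class SampleLabel:
    """One LC-MS/MS run: cell line, biological replicate, technical replicate."""

    cell_line: str
    bio_rep: int
    tech_rep: int

    def __post_init__(self) -> None:
        if self.cell_line not in (MALIGNANT, NON_MALIGNANT):
            raise ValueError(f"unknown cell line {self.cell_line!r}")
        if self.bio_rep < 1 or self.tech_rep < 1:
            raise ValueError("replicate indices are 1-based positive integers")

    @classmethod
    def parse(cls, label: str) -> "SampleLabel":
        m = _LABEL_RE.match(label)
        if m is None:
            raise ValueError(
                f"sample label {label!r} does not match '<N|T>_b<i>_t<j>'"
            )
        line = MALIGNANT if m.group("line") == "T" else NON_MALIGNANT
        return cls(line, int(m.group("bio")), int(m.group("tech")))

    def __str__(self) -> str:
        prefix = "T" if self.cell_line == MALIGNANT else "N"
        return f"{prefix}_b{self.bio_rep}_t{self.tech_rep}"


@dataclass
class SpectralCountMatrix:
    """Protein x sample spectral counts with nested replicate annotations.

    ``counts`` is indexed by accession (or gene symbol once consolidated) with
    one column per sample label; ``features`` carries ``gene_symbol``,
    ``gene_id`` and an ``id_missing`` flag per row, aligned with ``counts``.
    """

    counts: pd.DataFrame
    features: pd.DataFrame
    samples: list[SampleLabel] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.samples:
            self.samples = [SampleLabel.parse(c) for c in self.counts.columns]
        if len(self.samples) != self.counts.shape[1]:
            raise ValueError("sample annotations do not match count columns")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate (cell_line, bio_rep, tech_rep) sample")
        if not self.features.index.equals(self.counts.index):
            raise ValueError("feature table index does not match count rows")
        if self.counts.index.duplicated().any():
            dupes = self.counts.index[self.counts.index.duplicated()].tolist()
            raise ValueError(f"duplicate row identifiers: {dupes}")
        vals = self.counts.to_numpy()
        if not np.isfinite(vals).all() or (vals < 0).any():
            raise ValueError("counts must be finite and non-negative")

    # -- convenience ------------------------------------------------------

    @property
    def n_proteins(self) -> int:
        return self.counts.shape[0]

    @property
    def needs_integerization(self) -> bool:
        vals = self.counts.to_numpy()
        return bool((vals != np.floor(vals)).any())

    def columns_for(self, cell_line: str) -> list[str]:
        return [str(s) for s in self.samples if s.cell_line == cell_line]

    def group_counts(self, cell_line: str) -> pd.DataFrame:
        return self.counts[self.columns_for(cell_line)]

    def collapse_technical(self) -> "SpectralCountMatrix":
        """Average technical replicates within each biological replicate."""
        groups: dict[str, list[str]] = {}
        for s in self.samples:
            key = f"{'T' if s.cell_line == MALIGNANT else 'N'}_b{s.bio_rep}_t1"
            groups.setdefault(key, []).append(str(s))
        collapsed = pd.DataFrame(
            {key: self.counts[cols].mean(axis=1) for key, cols in groups.items()},
            index=self.counts.index,
        )
        return SpectralCountMatrix(collapsed, self.features.copy())


def _coerce_gene_id(raw: object) -> float:
    """Return the numeric gene id, or NaN when missing/blank."""
    if raw is None:
        return math.nan
    text = str(raw).strip()
    if text in ("", "NA", "nan", "None", "-"):
        return math.nan
    return float(int(float(text)))


def read_spectral_counts(path, mapping_path=None) -> SpectralCountMatrix:
    """Parse a spectral-count TSV into a raw (possibly fractional) matrix.

    Layout: header ``accession  gene_symbol  gene_id  <sample>...`` where
    sample labels follow ``<N|T>_b<i>_t<j>``.  An optional two-column
    ``accession<TAB>gene_symbol`` mapping file overrides/extends symbols.
    Rows lacking a gene id are retained but flagged ``id_missing`` so that
    enrichment/impact stages can exclude them.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    expected = ["accession", "gene_symbol", "gene_id"]
    if list(df.columns[:3]) != expected:
        raise ValueError(
            f"{path}: header must start with {expected}, got {list(df.columns[:3])}"
        )
    sample_cols = list(df.columns[3:])
    if not sample_cols:
        raise ValueError(f"{path}: no sample columns in header")
    for col in sample_cols:
        SampleLabel.parse(col)  # malformed header -> hard error

    if df["accession"].duplicated().any():
        dupes = df.loc[df["accession"].duplicated(), "accession"].tolist()
        raise ValueError(f"{path}: duplicate accession(s) {dupes}")

    counts = df[sample_cols].apply(pd.to_numeric)
    bad = counts.lt(0)
    if bad.any().any():
        row, col = next(zip(*np.nonzero(bad.to_numpy())))
        raise ValueError(
            f"{path}: negative count at accession "
            f"{df['accession'].iloc[row]!r}, sample {sample_cols[col]!r}"
        )
    counts.index = df["accession"]

    symbols = df["gene_symbol"].where(df["gene_symbol"].str.strip().ne(""), None)
    if mapping_path is not None:
        mapping = pd.read_csv(
            mapping_path, sep="\t", header=None, names=["accession", "gene_symbol"],
            dtype=str,
        ).set_index("accession")["gene_symbol"]
        symbols = df["accession"].map(mapping).fillna(symbols)
    gene_ids = df["gene_id"].map(_coerce_gene_id)

    features = pd.DataFrame(
        {
            "gene_symbol": symbols.to_numpy(),
            "gene_id": gene_ids.to_numpy(),
            "id_missing": gene_ids.isna().to_numpy(),
        },
        index=counts.index,
    )
    return SpectralCountMatrix(counts, features)


def write_spectral_counts(matrix: SpectralCountMatrix, path) -> None:
    """Write a matrix in the same TSV layout ``read_spectral_counts`` parses."""
    out = matrix.features[["gene_symbol", "gene_id"]].copy()
    out.insert(0, "accession", matrix.counts.index)
    out["gene_id"] = out["gene_id"].map(
        lambda g: "" if pd.isna(g) else str(int(g))
    )
    out["gene_symbol"] = out["gene_symbol"].fillna("")
    counts = matrix.counts.copy()
    if not matrix.needs_integerization:
        counts = counts.astype(np.int64)
    full = pd.concat([out.reset_index(drop=True), counts.reset_index(drop=True)], axis=1)
    full.to_csv(path, sep="\t", index=False)


def consolidate_isoforms(matrix: SpectralCountMatrix) -> SpectralCountMatrix:
    """Sum rows that share a gene symbol into one row per gene.

    Rows without a symbol pass through unchanged under their accession.
    A symbol mapped to two distinct gene ids is an annotation conflict and
    raises rather than silently merging.
    """
    feats = matrix.features
    has_symbol = feats["gene_symbol"].notna()

    for symbol, grp in feats.loc[has_symbol].groupby("gene_symbol"):
        ids = grp["gene_id"].dropna().unique()
        if len(ids) > 1:
            raise ValueError(
                f"gene symbol {symbol!r} maps to conflicting gene ids {sorted(ids)}"
            )

    keyed = matrix.counts.copy()
    keyed.index = feats["gene_symbol"].where(has_symbol, other=matrix.counts.index)
    merged = keyed.groupby(level=0, sort=False).sum()

    def _first_non_null(s: pd.Series):
        non_null = s.dropna()
        return non_null.iloc[0] if len(non_null) else math.nan

    feat_keyed = feats.copy()
    feat_keyed.index = keyed.index
    merged_feats = feat_keyed.groupby(level=0, sort=False).agg(
        gene_symbol=("gene_symbol", _first_non_null),
        gene_id=("gene_id", _first_non_null),
        id_missing=("id_missing", "all"),
    )
    merged_feats["gene_symbol"] = merged_feats["gene_symbol"].where(
        merged_feats["gene_symbol"].notna(), None
    )
    return SpectralCountMatrix(merged, merged_feats.loc[merged.index])


def integerize_counts(matrix: SpectralCountMatrix) -> SpectralCountMatrix:
    """Round every count up to the nearest whole integer (ceiling).

    Integer values and zeros are fixed points; the operation is idempotent.
    """
    vals = matrix.counts.to_numpy()
    if (vals < 0).any():
        raise ValueError("negative counts cannot be integerized")
    ceiled = pd.DataFrame(
        np.ceil(vals).astype(np.int64),
        index=matrix.counts.index,
        columns=matrix.counts.columns,
    )
    return SpectralCountMatrix(ceiled, matrix.features.copy())
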