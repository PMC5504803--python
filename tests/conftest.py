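from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from speccount.ingest import SpectralCountMatrix

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def table1_path() -> Path:
    return DATA_DIR / "table1_deps.tsv"


@pytest.fixture()
def tiny_matrix() -> SpectralCountMatrix:
    """4 genes x (3 N + 3 T) runs with one clearly shifted gene."""
    cols = ["N_b1_t1", "N_b1_t2", "N_b2_t1", "T_b1_t1", "T_b1_t2", "T_b2_t1"]
    counts = pd.DataFrame(
        [
            [5, 6, 4, 20, 22, 18],   # up in malignant
            [10, 11, 9, 10, 9, 11],  # flat
            [8, 7, 9, 0, 0, 0],      # lost in malignant
            [0, 0, 0, 6, 7, 5],      # malignant only
        ],
        index=["UPG", "FLAT", "NONLY", "TONLY"],
        columns=cols,
        dtype=float,
    )
    features = pd.DataFrame(
        {
            "gene_symbol": counts.index,
            "gene_id": np.arange(1.0, 5.0),
            "id_missing": False,
        },
        index=counts.index,
    )
    return SpectralCountMatrix(counts, features)


def write_counts_tsv(path, rows, sample_cols):
    """Helper: write a count TSV in the ingest layout.

    ``rows`` is a list of (accession, symbol, gene_id, [counts...]).
    """
    header = "accession\tgene_symbol\tgene_id\t" + "\t".join(sample_cols)
    lines = [header]
    for acc, sym, gid, counts in rows:
        lines.append(
            "\t".join([acc, sym, gid, *(str(c) for c in counts)])
        )
    Path(path).write_text("\n".join(lines) + "\n")
    return path
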