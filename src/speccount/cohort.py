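"""Race-stratified tumor/normal cohort comparison.

Specimens carry race, age, Gleason score and a tumor/non-malignant flag
alongside a continuous expression layer (RNA or protein).  The analysis
filters to lower-grade tumors (Gleason <= 7), greedily pairs specimens
across races by nearest age within identical Gleason strata, compares
expression between races with Welch's t-test, and — because tumor-only
comparisons confound race with baseline expression — optionally subtracts
each race's mean non-malignant expression from its tumor specimens before
testing.  A negative normalized value means the gene sits below its
race-matched normal mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CohortTable",
    "NormalizedExpression",
    "read_cohort",
    "filter_cohort",
    "match_pairs",
    "race_group_test",
    "compare_by_race",
    "subtract_race_normal",
]

TUMOR = "tumor"
NON_MALIGNANT = "non_malignant"


@dataclass
class CohortTable:
    """Clinical records plus one expression layer, aligned on specimen id."""

    clinical: pd.DataFrame  # index specimen_id; race, age, gleason, tissue
    expression: pd.DataFrame  # index specimen_id; columns genes

    def __post_init__(self) -> None:
        required = {"race", "age", "gleason", "tissue"}
        missing = required - set(self.clinical.columns)
        if missing:
            raise ValueError(f"clinical table missing columns {sorted(missing)}")
        if self.clinical.index.duplicated().any():
            raise ValueError("duplicate specimen ids")
        unknown = set(self.expression.index) - set(self.clinical.index)
        if unknown:
            raise ValueError(
                f"expression rows without clinical record: {sorted(unknown)[:5]}"
            )
        bad_tissue = set(self.clinical["tissue"]) - {TUMOR, NON_MALIGNANT}
        if bad_tissue:
            raise ValueError(f"unknown tissue values {sorted(bad_tissue)}")

    def subset(self, ids) -> "CohortTable":
        ids = list(ids)
        return CohortTable(
            self.clinical.loc[ids],
            self.expression.loc[self.expression.index.intersection(ids)],
        )

    def tumors(self) -> pd.DataFrame:
        return self.clinical[self.clinical["tissue"] == TUMOR]

    def normals(self) -> pd.DataFrame:
        return self.clinical[self.clinical["tissue"] == NON_MALIGNANT]


@dataclass
class NormalizedExpression:
    """Tumor expression after race-specific non-malignant-mean subtraction."""

    values: pd.DataFrame  # tumor specimens x genes
    reference_means: pd.DataFrame  # race x genes


def read_cohort(clinical_path, expression_path) -> CohortTable:
    """Read the clinical TSV (specimen_id, race, age, gleason, tissue) and
    the specimen x gene expression TSV."""
    clinical = pd.read_csv(
        clinical_path, sep="\t",
        dtype={"specimen_id": str, "race": str, "tissue": str},
    ).set_index("specimen_id")
    expression = pd.read_csv(expression_path, sep="\t", index_col=0)
    expression.index = expression.index.astype(str)
    return CohortTable(clinical, expression)


def filter_cohort(table: CohortTable, max_gleason: int = 7) -> CohortTable:
    """Drop specimens graded above ``max_gleason`` (inclusive bound).

    Applies to tumors and, when a grade is recorded, to non-malignant
    specimens too; non-malignant records without a grade are retained.
    """
    g = table.clinical["gleason"]
    keep = g.isna() | (g <= max_gleason)
    keep &= ~(table.clinical["tissue"].eq(TUMOR) & g.isna())
    return table.subset(table.clinical.index[keep])


def match_pairs(
    table: CohortTable, tolerance_years: float = 5.0
) -> tuple[pd.DataFrame, list[str]]:
    """Greedy nearest-age cross-race tumor pairing within Gleason strata.

    Within each Gleason stratum the globally closest-aged cross-race pair is
    taken repeatedly until no pair within ``tolerance_years`` remains; each
    specimen is used at most once.  Returns (pairs table, unmatched ids).
    """
    tumors = table.tumors()
    races = sorted(tumors["race"].unique())
    if len(races) < 2:
        import warnings

        warnings.warn("fewer than two races among tumors; no pairs")
        return pd.DataFrame(
            columns=["id_a", "id_b", "race_a", "race_b", "gleason", "age_gap"]
        ), list(tumors.index)
    race_a, race_b = races[0], races[1]

    pairs = []
    used: set[str] = set()
    for gleason, stratum in tumors.groupby("gleason"):
        a = stratum[stratum["race"] == race_a]
        b = stratum[stratum["race"] == race_b]
        candidates = [
            (abs(ra.age - rb.age), ia, ib, ra.age, rb.age)
            for ia, ra in a.iterrows()
            for ib, rb in b.iterrows()
            if abs(ra.age - rb.age) <= tolerance_years
        ]
        candidates.sort(key=lambda c: (c[0], str(c[1]), str(c[2])))
        for gap, ia, ib, _, _ in candidates:
            if ia in used or ib in used:
                continue
            used.update((ia, ib))
            pairs.append(
                {
                    "id_a": ia, "id_b": ib,
                    "race_a": race_a, "race_b": race_b,
                    "gleason": gleason, "age_gap": gap,
                }
            )
    unmatched = [i for i in tumors.index if i not in used]
    return pd.DataFrame(pairs), unmatched


def race_group_test(x, y) -> float:
    """Two-sided Welch (unequal-variance) t-test p-value for one gene.

    Zero variance in both groups with equal means returns p = 1 by
    convention; groups smaller than 2 are an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 values")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        return 1.0 if x.mean() == y.mean() else 0.0
    res = stats.ttest_ind(x, y, equal_var=False)
    return float(res.pvalue)


def compare_by_race(
    expression: pd.DataFrame, races: pd.Series, pooled: bool = False
) -> pd.DataFrame:
    """Per-gene two-race comparison over a specimen x gene matrix.

    ``races`` maps specimen id -> race (exactly two levels).  ``pooled``
    switches from Welch to the pooled-variance t-test.  Returns one row per
    gene with group means and the two-sided p-value.
    """
    races = races.loc[expression.index]
    levels = sorted(races.unique())
    if len(levels) != 2:
        raise ValueError(f"need exactly two races, got {levels}")
    a = expression.loc[races == levels[0]]
    b = expression.loc[races == levels[1]]
    rows = []
    for gene in expression.columns:
        xa, xb = a[gene].to_numpy(), b[gene].to_numpy()
        if pooled:
            p = float(stats.ttest_ind(xa, xb, equal_var=True).pvalue)
        else:
            p = race_group_test(xa, xb)
        rows.append(
            {
                "gene": gene,
                f"mean_{levels[0]}": xa.mean(),
                f"mean_{levels[1]}": xb.mean(),
                "p_value": p,
            }
        )
    return pd.DataFrame(rows)


def subtract_race_normal(table: CohortTable) -> NormalizedExpression:
    """Subtract each race's mean non-malignant expression from its tumors.

    The reference mean is the per-gene arithmetic mean over that race's
    non-malignant specimens; every tumor specimen's race must have at least
    one non-malignant reference specimen.
    """
    tumors = table.tumors()
    normals = table.normals()
    tumor_races = set(tumors["race"])
    ref_rows = {}
    for race in sorted(tumor_races):
        ref_ids = normals.index[normals["race"] == race]
        ref_ids = table.expression.index.intersection(ref_ids)
        if len(ref_ids) == 0:
            raise ValueError(f"no non-malignant reference specimens for race {race!r}")
        ref_rows[race] = table.expression.loc[ref_ids].mean(axis=0)
    reference = pd.DataFrame(ref_rows).T  # race x genes

    tumor_ids = table.expression.index.intersection(tumors.index)
    tumor_expr = table.expression.loc[tumor_ids]
    offsets = reference.loc[tumors.loc[tumor_ids, "race"].to_numpy()]
    offsets.index = tumor_ids
    return NormalizedExpression(tumor_expr - offsets, reference)
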