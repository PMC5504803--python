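"""Category overrepresentation analysis with a resampling validation.

Given a gene list (typically the differentially expressed proteins) and an
annotation database mapping categories to genes, each category is tested for
overrepresentation with the one-sided hypergeometric upper tail
P(X >= k | N, K, n), and p-values are BH-adjusted across categories.

Because highly abundant protein classes can be enriched among *any* set of
confidently identified proteins, the analysis is validated by resampling:
the same test battery is re-run on many random gene sets of the same size
drawn from a reference pool (the non-differential proteins, or all
identified proteins), and the number of random sets in which a category
reaches significance yields an empirical confidence that the observed
overrepresentation is not a sampling artifact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AnnotationDB",
    "read_annotation_db",
    "count_category_members",
    "overrepresentation_test",
    "run_ora",
    "resample_validation",
    "empirical_confidence",
]


@dataclass
class AnnotationDB:
    """Flat category -> gene-membership map with a declared background.

    ``background_size`` is the reference genome/proteome size N.  Projected
    databases may declare per-category sizes K larger than the membership
    actually listed (e.g. when only genes present in an experiment are
    enumerated); a declared K wins over the derived membership count.
    """

    categories: dict[str, frozenset]
    background_size: int
    category_sizes: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.categories = {c: frozenset(g) for c, g in self.categories.items()}
        if self.background_size <= 0:
            raise ValueError("background_size must be positive")
        for cat in self.categories:
            k_decl = self.size_of(cat)
            if k_decl > self.background_size:
                raise ValueError(
                    f"category {cat!r}: declared size {k_decl} exceeds "
                    f"background {self.background_size}"
                )

    def size_of(self, category: str) -> int:
        """Declared class size K, falling back to the membership count."""
        if category in self.category_sizes:
            return int(self.category_sizes[category])
        return len(self.categories[category])


def read_annotation_db(path, background_size: int,
                       sizes_path=None) -> AnnotationDB:
    """Read a long-format ``category<TAB>gene_id`` TSV (with header).

    ``sizes_path`` optionally declares per-category K in a
    ``category<TAB>size`` TSV for projected databases.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["category", "gene_id"]:
        raise ValueError(f"{path}: expected header 'category\\tgene_id'")
    cats: dict[str, set] = {}
    for cat, grp in df.groupby("category"):
        cats[str(cat)] = set(grp["gene_id"])
    sizes: dict[str, int] = {}
    if sizes_path is not None:
        sdf = pd.read_csv(sizes_path, sep="\t", dtype={"category": str, "size": int})
        sizes = dict(zip(sdf["category"], sdf["size"]))
    return AnnotationDB({c: frozenset(g) for c, g in cats.items()},
                        background_size, sizes)


def count_category_members(genes, db: AnnotationDB):
    """Per-category overlap counts plus the set of unannotated genes.

    Every category is reported, including zeros.  Genes belonging to no
    category at all are returned separately (a gene may carry several
    annotations, so the counts need not sum to ``len(genes)``).
    """
    genes = set(genes)
    counts = {cat: len(genes & members) for cat, members in db.categories.items()}
    annotated = set().union(*db.categories.values()) if db.categories else set()
    unannotated = genes - annotated
    return counts, unannotated


def overrepresentation_test(observed_k: int, class_size_K: int,
                            sample_size_n: int, background_N: int) -> float:
    """Hypergeometric upper tail P(X >= k) for k of n sampled genes landing
    in a class of K out of N background genes."""
    k, K, n, N = observed_k, class_size_K, sample_size_n, background_N
    if not (0 <= k <= min(n, K) and K <= N and n <= N):
        raise ValueError(
            f"inconsistent counts: k={k}, K={K}, n={n}, N={N}"
        )
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def run_ora(genes, db: AnnotationDB, alpha: float = 0.05) -> pd.DataFrame:
    """Test every category for overrepresentation of ``genes``.

    Returns one row per category — ``category, class_size_K, sample_size_n,
    observed_k, expected, p_value, q_value, significant`` — sorted by
    p-value.  ``expected`` is the null mean n*K/N.
    """
    from .diffexp import bh_adjust

    genes = set(genes)
    n = len(genes)
    counts, _ = count_category_members(genes, db)
    rows = []
    for cat in db.categories:
        K = db.size_of(cat)
        k = min(counts[cat], K)  # declared-K projections cannot be exceeded
        rows.append(
            {
                "category": cat,
                "class_size_K": K,
                "sample_size_n": n,
                "observed_k": k,
                "expected": n * K / db.background_size,
                "p_value": overrepresentation_test(k, K, n, db.background_size),
            }
        )
    table = pd.DataFrame(rows)
    if len(table):
        table["q_value"] = bh_adjust(table["p_value"].to_numpy())
        table["significant"] = table["q_value"] < alpha
        table = table.sort_values(
            ["p_value", "category"], kind="mergesort"
        ).reset_index(drop=True)
    return table


def resample_validation(
    dep_count: int,
    pool,
    db: AnnotationDB,
    n_iter: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Re-run the ORA battery on ``n_iter`` random subsets of the pool.

    Each iteration draws ``dep_count`` genes uniformly without replacement
    from ``pool``, runs the full per-category battery with BH adjustment,
    and records which categories are significant at ``alpha``.  Returns one
    row per category with ``n_significant`` out of ``n_iter``; fully
    reproducible from ``seed``.
    """
    pool = sorted(set(pool))
    if len(pool) < dep_count:
        raise ValueError(
            f"pool of {len(pool)} genes is smaller than dep_count={dep_count}"
        )
    rng = np.random.default_rng(seed)
    cats = list(db.categories)
    sig_counts = dict.fromkeys(cats, 0)
    pool_arr = np.asarray(pool, dtype=object)
    for _ in range(n_iter):
        subset = pool_arr[rng.choice(len(pool_arr), size=dep_count, replace=False)]
        result = run_ora(subset, db, alpha=alpha)
        for cat in result.loc[result["significant"], "category"]:
            sig_counts[cat] += 1
    return pd.DataFrame(
        {
            "category": cats,
            "n_iterations": n_iter,
            "n_significant": [sig_counts[c] for c in cats],
            "seed": seed,
        }
    )


def empirical_confidence(n_significant: int, n_iter: int) -> float:
    """Percent confidence that an observed overrepresentation is not chance:
    100 * (1 - n_significant / n_iter)."""
    if n_iter <= 0:
        raise ValueError("n_iter must be positive")
    if not 0 <= n_significant <= n_iter:
        raise ValueError("n_significant must lie in [0, n_iter]")
    return 100.0 * (1.0 - n_significant / n_iter)
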