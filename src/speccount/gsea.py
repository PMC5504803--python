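"""Gene-set enrichment analysis (weighted running-sum statistic).

A ranked list is built by scoring every gene's association with the
malignant phenotype (signal-to-noise by default).  For each gene set, a
running sum walks down the ranked list, incrementing at set members in
proportion to |score|^w and decrementing by 1/(L-G) at non-members; the
enrichment score (ES) is the signed extremum of that walk and the leading
edge is the members accumulating it.  Significance comes from a permutation
null (random gene sets of equal size by default, or phenotype-label
permutation), the normalized ES (NES) divides by the mean same-signed null
ES, and the FDR q-value is the pooled null/observed tail-ratio estimator.

Positive scores correspond to enrichment in the malignant phenotype.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ingest import MALIGNANT, NON_MALIGNANT, SpectralCountMatrix

__all__ = [
    "GeneSetCollection",
    "read_gmt",
    "write_gmt",
    "rank_by_association",
    "enrichment_score",
    "filter_sets",
    "gsea_significance",
]


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT semantics) with a provenance tag."""

    sets: dict[str, frozenset]
    source: str = ""

    def __post_init__(self) -> None:
        self.sets = {name: frozenset(g) for name, g in self.sets.items()}
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file: ``name<TAB>description<TAB>member...`` per line."""
    sets: dict[str, frozenset] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT lines need name, description, members"
                )
            name = parts[0]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            members = frozenset(p for p in parts[2:] if p)
            sets[name] = members
    return GeneSetCollection(sets, source=str(path))


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, members in collection.sets.items():
            fh.write("\t".join([name, collection.source or "na", *sorted(members)]))
            fh.write("\n")


def _signal_to_noise(t: np.ndarray, n: np.ndarray) -> float:
    """(mu_T - mu_N) / (sigma_T + sigma_N) with the conventional floor
    sigma >= 0.2*|mu| (and 0.2 when mu == 0)."""
    mu_t, mu_n = t.mean(), n.mean()
    sd_t, sd_n = t.std(ddof=1), n.std(ddof=1)
    sd_t = max(sd_t, 0.2 * abs(mu_t)) or 0.2
    sd_n = max(sd_n, 0.2 * abs(mu_n)) or 0.2
    return float((mu_t - mu_n) / (sd_t + sd_n))


def rank_by_association(
    matrix: SpectralCountMatrix, metric: str = "signal_to_noise"
) -> pd.Series:
    """Score genes by association with the malignant phenotype, descending.

    Genes without a mapped gene id are excluded.  Ties are broken
    lexicographically by gene identifier for determinism.
    """
    t_cols = matrix.columns_for(MALIGNANT)
    n_cols = matrix.columns_for(NON_MALIGNANT)
    if not t_cols or not n_cols:
        raise ValueError("matrix must contain both phenotype classes")
    if metric == "signal_to_noise" and (len(t_cols) < 2 or len(n_cols) < 2):
        raise ValueError("signal_to_noise needs >= 2 samples per class")
    if metric not in ("signal_to_noise", "difference_of_means"):
        raise ValueError(f"unknown metric {metric!r}")

    keep = ~matrix.features["id_missing"].to_numpy(dtype=bool)
    t = matrix.counts.loc[keep, t_cols].to_numpy(dtype=float)
    n = matrix.counts.loc[keep, n_cols].to_numpy(dtype=float)
    names = [
        feat if pd.notna(feat) else str(idx)
        for idx, feat in matrix.features.loc[keep, "gene_symbol"].items()
    ]
    if metric == "signal_to_noise":
        scores = [_signal_to_noise(t[i], n[i]) for i in range(len(names))]
    else:
        scores = (t.mean(axis=1) - n.mean(axis=1)).tolist()
    ranked = pd.Series(scores, index=names, name="score")
    order = sorted(range(len(ranked)), key=lambda i: (-ranked.iloc[i], names[i]))
    return ranked.iloc[order]


def _es_from_positions(
    positions: np.ndarray, weights: np.ndarray, total: int
) -> tuple[float, int, bool]:
    """ES and extremum location from sorted 0-based hit positions.

    The running sum is piecewise linear between hits, so the positive
    extremum can only occur immediately after a hit and the negative
    extremum immediately before one; this closed form avoids walking all
    ``total`` ranks.  Returns (es, hit_index_of_extremum, is_positive).
    """
    g = len(positions)
    misses = total - g
    w_total = weights.sum()
    if w_total == 0:  # degenerate all-zero scores: fall back to equal weights
        frac = np.arange(1, g + 1) / g
    else:
        frac = np.cumsum(weights) / w_total
    miss_penalty = (positions - np.arange(g)) / misses if misses else np.zeros(g)
    after = frac - miss_penalty
    before = np.concatenate([[0.0], frac[:-1]]) - miss_penalty
    i_max = int(np.argmax(after))
    i_min = int(np.argmin(before))
    es_pos = float(after[i_max])
    es_neg = float(before[i_min])
    if es_pos >= -es_neg:
        return es_pos, i_max, True
    return es_neg, i_min, False


def enrichment_score(
    ranked: pd.Series, gene_set, weight_exponent: float = 1.0
) -> tuple[float, list[str]]:
    """Weighted running-sum enrichment score and leading-edge genes.

    ``ranked`` is the descending association-scored gene list.  The running
    sum increments by |score|^weight_exponent (normalized over set hits) at
    members and decrements by 1/(L-G) at non-members; ES is the signed
    extremum.  The leading edge is the members at or before the positive
    extremum, or at and after the negative one.
    """
    gene_set = set(gene_set)
    names = ranked.index.to_numpy()
    hit_mask = np.fromiter((g in gene_set for g in names), bool, len(names))
    positions = np.nonzero(hit_mask)[0]
    if positions.size == 0:
        raise ValueError("gene set has no members in the ranked list")
    if positions.size == len(names):
        raise ValueError("gene set covers the entire ranked list")
    weights = np.abs(ranked.to_numpy()[positions]) ** weight_exponent
    es, i_ext, positive = _es_from_positions(positions, weights, len(names))
    if positive:
        leading = [str(n) for n in names[positions[: i_ext + 1]]]
    else:
        leading = [str(n) for n in names[positions[i_ext:]]]
    return es, leading


def filter_sets(
    collection: GeneSetCollection,
    data_genes,
    min_size: int = 5,
    max_size: int = 500,
) -> GeneSetCollection:
    """Keep sets whose effective size (overlap with the data) is within
    [min_size, max_size], both bounds inclusive."""
    data_genes = set(data_genes)
    kept = {
        name: members
        for name, members in collection.sets.items()
        if min_size <= len(members & data_genes) <= max_size
    }
    return GeneSetCollection(kept, source=collection.source)


def _permuted_label_matrix(matrix: SpectralCountMatrix, rng) -> SpectralCountMatrix:
    """Shuffle phenotype labels across samples (replicate structure kept)."""
    cols = list(matrix.counts.columns)
    shuffled = list(rng.permutation(cols))
    remapped = matrix.counts.copy()
    remapped.columns = cols  # values stay put; labels move
    remapped = remapped[shuffled]
    remapped.columns = cols
    return SpectralCountMatrix(remapped, matrix.features.copy())


def gsea_significance(
    matrix: SpectralCountMatrix,
    collection: GeneSetCollection,
    n_perm: int = 1000,
    permutation_scheme: str = "gene_set",
    seed: int = 0,
    metric: str = "signal_to_noise",
    weight_exponent: float = 1.0,
    min_size: int = 5,
    max_size: int = 500,
) -> pd.DataFrame:
    """Permutation significance, NES and FDR for every qualifying gene set.

    Returns one row per set — ``set_name, effective_size, es, nes, p_value,
    q_value, direction, leading_edge`` — sorted by q then p.  The nominal p
    uses the same-signed null with the (count+1)/(n+1) estimator; NES
    divides ES by the mean magnitude of same-signed null scores; q is the
    pooled-null NES tail ratio.  Fully reproducible from ``seed``.
    """
    if n_perm <= 0:
        raise ValueError("n_perm must be positive")
    import warnings

    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is small; p-values will be coarse")
    if permutation_scheme not in ("gene_set", "phenotype"):
        raise ValueError(f"unknown permutation scheme {permutation_scheme!r}")

    rng = np.random.default_rng(seed)
    ranked = rank_by_association(matrix, metric=metric)
    filtered = filter_sets(collection, set(ranked.index), min_size, max_size)

    data_genes = set(ranked.index)
    names_arr = ranked.index.to_numpy()
    abs_w = np.abs(ranked.to_numpy()) ** weight_exponent
    L = len(ranked)

    observed: dict[str, tuple[float, list[str], int]] = {}
    for name, members in filtered.sets.items():
        if data_genes <= members:  # no misses: the running sum is undefined
            warnings.warn(f"set {name!r} covers every ranked gene; skipped")
            continue
        es, leading = enrichment_score(ranked, members, weight_exponent)
        observed[name] = (es, leading, len(members & data_genes))

    null_es: dict[str, np.ndarray] = {}
    if permutation_scheme == "gene_set":
        by_size: dict[int, np.ndarray] = {}
        for name, (_, _, g) in observed.items():
            if g not in by_size:
                es_null = np.empty(n_perm)
                for b in range(n_perm):
                    pos = np.sort(rng.choice(L, size=g, replace=False))
                    es_null[b], _, _ = _es_from_positions(pos, abs_w[pos], L)
                by_size[g] = es_null
            null_es[name] = by_size[g]
    else:
        per_set = {name: np.empty(n_perm) for name in observed}
        for b in range(n_perm):
            perm = _permuted_label_matrix(matrix, rng)
            perm_ranked = rank_by_association(perm, metric=metric)
            for name, members in filtered.sets.items():
                es_b, _ = enrichment_score(perm_ranked, members, weight_exponent)
                per_set[name][b] = es_b
        null_es = per_set

    rows = []
    for name, (es, leading, g) in observed.items():
        null = null_es[name]
        same = null[null >= 0] if es >= 0 else null[null < 0]
        if same.size:
            more_extreme = int((same >= es).sum()) if es >= 0 else int((same <= es).sum())
            p = (more_extreme + 1) / (same.size + 1)
            mean_mag = np.abs(same).mean()
            nes = es / mean_mag if mean_mag > 0 else 0.0
        else:
            p, nes = 1.0 / (n_perm + 1), 0.0
        rows.append(
            {
                "set_name": name,
                "effective_size": g,
                "es": es,
                "nes": nes,
                "p_value": p,
                "direction": MALIGNANT if es >= 0 else NON_MALIGNANT,
                "leading_edge": ",".join(leading),
            }
        )
    table = pd.DataFrame(rows)
    if not len(table):
        table["q_value"] = []
        return table

    # pooled-null FDR: null NES pool over all sets, same normalization
    pooled = []
    for name in observed:
        null = null_es[name]
        pos, neg = null[null >= 0], null[null < 0]
        nn = np.empty_like(null)
        if pos.size:
            nn[null >= 0] = pos / (np.abs(pos).mean() or 1.0)
        if neg.size:
            nn[null < 0] = neg / (np.abs(neg).mean() or 1.0)
        pooled.append(nn)
    pooled = np.concatenate(pooled)
    obs_nes = table["nes"].to_numpy()

    q = np.ones(len(table))
    for i, nes in enumerate(obs_nes):
        if nes >= 0:
            null_tail = (pooled >= nes).sum() / max((pooled >= 0).sum(), 1)
            obs_tail = (obs_nes >= nes).sum() / max((obs_nes >= 0).sum(), 1)
        else:
            null_tail = (pooled <= nes).sum() / max((pooled < 0).sum(), 1)
            obs_tail = (obs_nes <= nes).sum() / max((obs_nes < 0).sum(), 1)
        q[i] = min(1.0, null_tail / obs_tail) if obs_tail > 0 else 1.0
    table["q_value"] = q
    return table.sort_values(
        ["q_value", "p_value", "set_name"], kind="mergesort"
    ).reset_index(drop=True)
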