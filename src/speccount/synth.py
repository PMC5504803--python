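"""Synthetic inputs with the statistical structure every stage assumes.

The generators emulate the study design the pipeline targets: a paired
malignant / non-malignant cell-line comparison quantified by overdispersed
spectral counts in three biological replicates run in technical triplicate
(negative-binomial counts with a log-normal biological-replicate random
effect), an annotation database with realistic protein-class sizes over a
20,814-gene reference, random signed pathway topologies with guaranteed
multi-step cascades, and a two-race tumor/normal cohort with additive race,
disease and race x disease effects.

Every generator is a pure function of its parameters and seed and writes a
truth sidecar so downstream tests consume planted truth rather than
re-deriving it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import CohortTable
from .gsea import GeneSetCollection
from .ingest import SpectralCountMatrix
from .ora import AnnotationDB
from .spia import PathwayTopology

__all__ = [
    "SimulationTruth",
    "REFERENCE_CLASS_SIZES",
    "BACKGROUND_GENOME_SIZE",
    "simulate_spectral_counts",
    "simulate_annotation_db",
    "simulate_pathway_topology",
    "simulate_cohort",
    "simulate_gene_sets",
]

#: reference proteome size conditioning the overrepresentation null.
BACKGROUND_GENOME_SIZE = 20814

#: protein-class sizes of a curated classification over that reference.
REFERENCE_CLASS_SIZES: dict[str, int] = {
    "cytoskeletal protein": 198,
    "storage protein": 25,
    "chaperone": 183,
    "transmembrane receptor regulatory": 65,
    "lyase": 151,
    "nucleic acid binding": 2332,
    "cell junction protein": 140,
    "isomerase": 162,
    "cell adhesion molecule": 458,
    "extracellular matrix protein": 363,
    "transfer/carrier protein": 364,
    "protease": 586,
    "membrane traffic protein": 372,
    "oxidoreductase": 593,
    "kinase": 699,
    "hydrolase": 1482,
    "defense/immunity protein": 561,
    "transferase": 1198,
    "signaling molecule": 1083,
    "transporter": 920,
    "enzyme modulator": 1353,
    "transcription factor": 1451,
    "receptor": 1813,
}


@dataclass
class SimulationTruth:
    """Planted ground truth serialized alongside every generated dataset."""

    table: pd.DataFrame
    seed: int
    params: dict = field(default_factory=dict)

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out.insert(0, "seed", self.seed)
        out.to_csv(path, sep="\t", index=False)


def _nb_draw(rng, mean, dispersion):
    """Negative binomial with var = mu + dispersion * mu^2."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean)
    size_param = 1.0 / dispersion
    p = size_param / (size_param + mean)
    return rng.negative_binomial(size_param, p)


def simulate_spectral_counts(
    n_genes: int = 833,
    n_bio: int = 3,
    n_tech: int = 3,
    frac_dep: float = 0.076,
    effect_log2: float = 2.0,
    dispersion: float = 0.3,
    dropout_frac: float = 0.3,
    up_frac: float = 0.73,
    baseline_log_mean: float = 2.3,
    baseline_log_sd: float = 1.0,
    bio_sd: float = 0.15,
    seed: int = 0,
) -> tuple[SpectralCountMatrix, SimulationTruth]:
    """Overdispersed spectral counts for a two-line nested replicate design.

    Per gene, a log-normal baseline mean (median ~10 counts) is shared by
    both lines; a fraction ``frac_dep`` of genes receive a 2^effect_log2
    shift of the malignant mean (``up_frac`` of them upward), and
    ``dropout_frac`` of those planted genes are additionally zeroed in the
    unshifted line, creating detected-in-one-line-only patterns.  Counts are
    negative binomial around the per-biological-replicate mean, which
    carries a log-normal random effect shared by that replicate's technical
    runs.
    """
    for name, v in (("frac_dep", frac_dep), ("dropout_frac", dropout_frac),
                    ("up_frac", up_frac)):
        if not 0 <= v <= 1:
            raise ValueError(f"{name}={v} outside [0, 1]")
    rng = np.random.default_rng(seed)

    genes = [f"G{i:05d}" for i in range(1, n_genes + 1)]
    baselines = rng.lognormal(baseline_log_mean, baseline_log_sd, n_genes)

    n_dep = int(round(frac_dep * n_genes))
    dep_idx = rng.choice(n_genes, size=n_dep, replace=False)
    up_mask = rng.random(n_dep) < up_frac
    dropout_mask = rng.random(n_dep) < dropout_frac

    status = np.array(["null"] * n_genes, dtype=object)
    true_effect = np.zeros(n_genes)
    for j, gi in enumerate(dep_idx):
        sign = 1.0 if up_mask[j] else -1.0
        true_effect[gi] = sign * effect_log2
        if dropout_mask[j]:
            status[gi] = "t_only" if sign > 0 else "n_only"
        else:
            status[gi] = "up" if sign > 0 else "down"

    mean_t = baselines * np.power(2.0, true_effect)
    mean_n = baselines.copy()
    # one-line-only genes: zero the line the effect points away from
    t_zero = status == "n_only"
    n_zero = status == "t_only"
    mean_t[t_zero] = 0.0
    mean_n[n_zero] = 0.0

    cols, blocks = [], []
    for line, means in (("N", mean_n), ("T", mean_t)):
        for b in range(1, n_bio + 1):
            bio_effect = rng.lognormal(0.0, bio_sd, n_genes)
            rep_mean = means * bio_effect
            for t in range(1, n_tech + 1):
                cols.append(f"{line}_b{b}_t{t}")
                blocks.append(_nb_draw(rng, rep_mean, dispersion))
    counts = pd.DataFrame(
        np.column_stack(blocks), index=genes, columns=cols
    )
    features = pd.DataFrame(
        {
            "gene_symbol": genes,
            "gene_id": np.arange(1, n_genes + 1, dtype=float),
            "id_missing": False,
        },
        index=genes,
    )
    matrix = SpectralCountMatrix(counts, features)
    truth = SimulationTruth(
        pd.DataFrame(
            {"gene_symbol": genes, "status": status, "true_log2_effect": true_effect}
        ),
        seed=seed,
        params={
            "n_genes": n_genes, "n_bio": n_bio, "n_tech": n_tech,
            "frac_dep": frac_dep, "effect_log2": effect_log2,
            "dispersion": dispersion, "dropout_frac": dropout_frac,
        },
    )
    return matrix, truth


def simulate_annotation_db(
    n_genes: int = BACKGROUND_GENOME_SIZE,
    class_sizes: dict[str, int] | None = None,
    seed: int = 0,
    gene_pool: list[str] | None = None,
    planted_overlap: dict[str, tuple[list, int]] | None = None,
) -> tuple[AnnotationDB, SimulationTruth]:
    """Annotation database of random categories over a reference background.

    Categories are uniform random subsets of the background at the declared
    class sizes (defaults: a curated protein-class catalogue over a
    20,814-gene reference); disjointness is not enforced, so a gene may
    carry several classes.  ``planted_overlap`` forces exactly k members of
    a designated gene list into a category: ``{category: (genes, k)}``.
    """
    class_sizes = dict(class_sizes or REFERENCE_CLASS_SIZES)
    rng = np.random.default_rng(seed)
    if gene_pool is None:
        gene_pool = [f"BG{i:06d}" for i in range(1, n_genes + 1)]
    else:
        gene_pool = list(gene_pool)
        n_genes = len(gene_pool)
    pool_arr = np.asarray(gene_pool, dtype=object)
    planted_overlap = planted_overlap or {}

    categories: dict[str, frozenset] = {}
    planted_counts = {}
    for cat, size in class_sizes.items():
        if size > n_genes:
            raise ValueError(f"class {cat!r} size {size} exceeds background")
        if cat in planted_overlap:
            designated, k = planted_overlap[cat]
            designated = list(designated)
            if k > min(size, len(designated)):
                raise ValueError(f"cannot plant {k} of {len(designated)} in {cat!r}")
            inside = list(rng.choice(np.asarray(designated, dtype=object),
                                     size=k, replace=False))
            outside_pool = np.asarray(
                [g for g in gene_pool if g not in set(designated)], dtype=object
            )
            outside = list(rng.choice(outside_pool, size=size - k, replace=False))
            members = frozenset(inside) | frozenset(outside)
            planted_counts[cat] = k
        else:
            members = frozenset(
                rng.choice(pool_arr, size=size, replace=False)
            )
        categories[cat] = frozenset(members)

    db = AnnotationDB(categories, background_size=n_genes)
    truth = SimulationTruth(
        pd.DataFrame(
            {
                "category": list(class_sizes),
                "size": [class_sizes[c] for c in class_sizes],
                "planted_overlap": [planted_counts.get(c, 0) for c in class_sizes],
            }
        ),
        seed=seed,
        params={"n_genes": n_genes},
    )
    return db, truth


def simulate_pathway_topology(
    n_genes: int = 25,
    edge_density: float = 0.08,
    inhibition_prob: float = 0.3,
    seed: int = 0,
    pathway_id: str = "synthetic",
    cascade_length: int = 4,
) -> tuple[PathwayTopology, SimulationTruth]:
    """Random signed directed pathway graph with a guaranteed cascade.

    Edges appear independently with probability ``edge_density`` and are
    inhibitory with probability ``inhibition_prob``; a directed activating
    chain over ``cascade_length`` genes is always planted so propagation has
    at least one multi-step route.
    """
    if not 0 <= edge_density <= 1:
        raise ValueError("edge_density outside [0, 1]")
    if cascade_length > n_genes:
        raise ValueError("cascade longer than the gene list")
    rng = np.random.default_rng(seed)
    genes = [f"P{i:03d}" for i in range(1, n_genes + 1)]

    adj = rng.random((n_genes, n_genes)) < edge_density
    np.fill_diagonal(adj, False)
    signs = np.where(rng.random((n_genes, n_genes)) < inhibition_prob, -1.0, 1.0)
    beta = adj.T.astype(float) * signs.T  # beta[i, j]: j -> i

    chain = rng.choice(n_genes, size=cascade_length, replace=False)
    for a, b in zip(chain[:-1], chain[1:]):
        beta[b, a] = 1.0

    top = PathwayTopology(pathway_id, pathway_id, genes, beta)
    truth = SimulationTruth(
        pd.DataFrame({"cascade": [">".join(genes[i] for i in chain)]}),
        seed=seed,
        params={"n_genes": n_genes, "edge_density": edge_density,
                "inhibition_prob": inhibition_prob},
    )
    return top, truth


def simulate_gene_sets(
    universe,
    n_sets: int = 20,
    set_size: tuple[int, int] = (8, 40),
    planted: dict[str, list] | None = None,
    seed: int = 0,
) -> GeneSetCollection:
    """Random gene sets over a universe, with optional planted sets given
    verbatim (``{name: members}``)."""
    rng = np.random.default_rng(seed)
    universe = np.asarray(list(universe), dtype=object)
    sets: dict[str, frozenset] = {}
    for name, members in (planted or {}).items():
        sets[name] = frozenset(members)
    for i in range(n_sets):
        size = int(rng.integers(set_size[0], set_size[1] + 1))
        sets[f"RANDOM_SET_{i:03d}"] = frozenset(
            rng.choice(universe, size=min(size, len(universe)), replace=False)
        )
    return GeneSetCollection(sets, source="synthetic")


def simulate_cohort(
    n_tumor_per_race: int = 12,
    n_normal_per_race: dict[str, int] | int | None = None,
    genes: list[str] | int = 6,
    race_effect: dict[str, float] | None = None,
    disease_effect: dict[str, float] | None = None,
    interaction_effect: dict[str, float] | None = None,
    noise_sd: float = 1.0,
    seed: int = 0,
    races: tuple[str, str] = ("AA", "CA"),
) -> tuple[CohortTable, SimulationTruth]:
    """Two-race tumor/normal cohort with planted additive effects.

    Expression is Gaussian:  baseline + race_effect*[race==races[0]]
    + disease_effect*[tumor] + interaction_effect*[both] + N(0, noise_sd),
    per gene (effects default to 0 for unlisted genes).  Ages are drawn in
    matched cross-race pairs and Gleason scores alternate between 6 and 7 so
    age/stage matching is feasible by construction.  Default group sizes
    mirror a 12 + 12 matched-pair tumor panel with a 4 / 30 non-malignant
    reference imbalance.
    """
    if n_normal_per_race is None:
        n_normal_per_race = {races[0]: 4, races[1]: 30}
    elif isinstance(n_normal_per_race, int):
        n_normal_per_race = {r: n_normal_per_race for r in races}
    if isinstance(genes, int):
        genes = [f"GENE{i:02d}" for i in range(1, genes + 1)]
    race_effect = dict(race_effect or {})
    disease_effect = dict(disease_effect or {})
    interaction_effect = dict(interaction_effect or {})
    rng = np.random.default_rng(seed)

    baseline = {g: rng.normal(8.0, 1.0) for g in genes}
    records, expr_rows, ids = [], [], []

    def add(specimen_id, race, age, gleason, tissue):
        is_ref_race = race == races[0]
        is_tumor = tissue == "tumor"
        row = []
        for g in genes:
            mu = baseline[g]
            mu += race_effect.get(g, 0.0) * is_ref_race
            mu += disease_effect.get(g, 0.0) * is_tumor
            mu += interaction_effect.get(g, 0.0) * (is_ref_race and is_tumor)
            row.append(mu + rng.normal(0.0, noise_sd))
        ids.append(specimen_id)
        records.append(
            {"specimen_id": specimen_id, "race": race, "age": age,
             "gleason": gleason, "tissue": tissue}
        )
        expr_rows.append(row)

    for i in range(n_tumor_per_race):
        age = float(rng.integers(50, 75))
        gleason = 6 if i % 2 == 0 else 7
        jitter = float(rng.integers(0, 3))  # within any sane matching tolerance
        add(f"T_{races[0]}_{i:02d}", races[0], age, gleason, "tumor")
        add(f"T_{races[1]}_{i:02d}", races[1], age + jitter, gleason, "tumor")
    for race, n_norm in n_normal_per_race.items():
        for i in range(n_norm):
            age = float(rng.integers(50, 75))
            add(f"N_{race}_{i:02d}", race, age, 6 if i % 2 else 7, "non_malignant")

    clinical = pd.DataFrame(records).set_index("specimen_id")
    expression = pd.DataFrame(expr_rows, index=ids, columns=genes)
    table = CohortTable(clinical, expression)
    truth = SimulationTruth(
        pd.DataFrame(
            {
                "gene": genes,
                "race_effect": [race_effect.get(g, 0.0) for g in genes],
                "disease_effect": [disease_effect.get(g, 0.0) for g in genes],
                "interaction_effect": [interaction_effect.get(g, 0.0) for g in genes],
            }
        ),
        seed=seed,
        params={"n_tumor_per_race": n_tumor_per_race, "noise_sd": noise_sd},
    )
    return table, truth
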