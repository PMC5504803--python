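"""Topology-based signaling pathway impact analysis.

Two independent lines of evidence are combined per pathway: an
overrepresentation probability pNDE (hypergeometric upper tail on the number
of differentially expressed genes falling on the pathway) and a perturbation
probability pPERT obtained by propagating the observed log2 changes through
the signed pathway topology.  Propagation solves, per pathway,

    PF(g_i) = dE(g_i) + sum_j beta_ij * PF(g_j) / N_ds(g_j)

where beta_ij is the signed strength of gene j's action on gene i and
N_ds(g_j) the number of genes j acts on.  The net accumulation
Acc(g) = PF(g) - dE(g) sums to the total perturbation tA, whose bootstrap
null (observed magnitudes reassigned to random pathway positions) yields
pPERT.  pNDE and pPERT combine as the tail probability of a product of two
independent uniforms, pG = c - c*ln(c) with c = pNDE*pPERT; BH adjustment of
pG across pathways gives pGFdr, and the sign of tA calls each significant
pathway activated or inhibited.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import lu_factor, lu_solve

from .diffexp import bh_adjust
from .ora import overrepresentation_test

__all__ = [
    "PathwayTopology",
    "DEFAULT_TYPE_WEIGHTS",
    "load_topology",
    "load_topologies",
    "write_topology",
    "perturbation_accumulation",
    "p_nde",
    "p_pert_bootstrap",
    "combine_global",
    "run_spia",
]

#: relation-type -> interaction weight; sign columns multiply these.
DEFAULT_TYPE_WEIGHTS: dict[str, float] = {
    "activation": 1.0,
    "expression": 1.0,
    "inhibition": -1.0,
    "repression": -1.0,
    "binding": 0.0,
    "association": 0.0,
}


@dataclass
class PathwayTopology:
    """Genes plus a signed interaction matrix.

    ``beta[i, j]`` is the effect of gene j on gene i; ``n_downstream[j]``
    counts the genes j acts on (nonzero entries of column j).
    """

    pathway_id: str
    pathway_name: str
    genes: list[str]
    beta: np.ndarray

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        g = len(self.genes)
        if self.beta.shape != (g, g):
            raise ValueError(
                f"pathway {self.pathway_id}: beta shape {self.beta.shape} "
                f"does not match {g} genes"
            )
        if len(set(self.genes)) != g:
            raise ValueError(f"pathway {self.pathway_id}: duplicate genes")

    @property
    def n_downstream(self) -> np.ndarray:
        return (self.beta != 0).sum(axis=0)

    @property
    def size(self) -> int:
        return len(self.genes)


def _edges_to_topology(pathway_id, name, edges, type_weights) -> PathwayTopology:
    genes = sorted({e[0] for e in edges} | {e[1] for e in edges})
    index = {g: i for i, g in enumerate(genes)}
    beta = np.zeros((len(genes), len(genes)))
    seen: set[tuple[str, str]] = set()
    for source, target, etype, sign in edges:
        if etype not in type_weights:
            raise ValueError(
                f"pathway {pathway_id}: unknown relation type {etype!r} "
                "with no declared weight"
            )
        if (source, target) in seen:
            warnings.warn(
                f"pathway {pathway_id}: duplicate edge {source}->{target}; "
                "weights summed"
            )
        seen.add((source, target))
        beta[index[target], index[source]] += sign * type_weights[etype]
    return PathwayTopology(pathway_id, name, genes, beta)


def _read_edge_rows(path):
    df = pd.read_csv(path, sep="\t", dtype={"sign": float})
    if "pathway_id" in df.columns:
        grouped = True
        required = ["pathway_id", "source", "target", "type", "sign"]
    else:
        grouped = False
        required = ["source", "target", "type", "sign"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing edge-list columns {missing}")
    return df, grouped


def load_topology(path, type_weights=None, pathway_id=None,
                  name=None) -> PathwayTopology:
    """Load a single pathway from a ``source target type sign`` TSV."""
    tw = dict(DEFAULT_TYPE_WEIGHTS, **(type_weights or {}))
    df, grouped = _read_edge_rows(path)
    if grouped:
        raise ValueError(f"{path}: concatenated file; use load_topologies")
    pid = pathway_id or str(path)
    edges = list(df[["source", "target", "type", "sign"]].itertuples(index=False))
    return _edges_to_topology(pid, name or pid, edges, tw)


def load_topologies(path, type_weights=None) -> dict[str, PathwayTopology]:
    """Load a concatenated edge list with a ``pathway_id`` column."""
    tw = dict(DEFAULT_TYPE_WEIGHTS, **(type_weights or {}))
    df, grouped = _read_edge_rows(path)
    if not grouped:
        top = load_topology(path, type_weights)
        return {top.pathway_id: top}
    out = {}
    for pid, grp in df.groupby("pathway_id", sort=False):
        edges = list(grp[["source", "target", "type", "sign"]].itertuples(index=False))
        out[str(pid)] = _edges_to_topology(str(pid), str(pid), edges, tw)
    return out


def write_topology(topology: PathwayTopology, path, with_pathway_id=False) -> None:
    """Serialize back to the edge-list TSV format."""
    rows = []
    for j, src in enumerate(topology.genes):
        for i, tgt in enumerate(topology.genes):
            b = topology.beta[i, j]
            if b == 0:
                continue
            etype = "activation" if b > 0 else "inhibition"
            row = {"source": src, "target": tgt, "type": etype, "sign": 1}
            if with_pathway_id:
                row = {"pathway_id": topology.pathway_id, **row}
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _normalized_system(topology: PathwayTopology) -> np.ndarray:
    """I - B where B[i,j] = beta[i,j]/N_ds(j) (zero column when N_ds=0)."""
    nds = topology.n_downstream.astype(float)
    b = np.divide(
        topology.beta, nds[np.newaxis, :],
        out=np.zeros_like(topology.beta), where=nds > 0,
    )
    return np.eye(topology.size) - b


def _factor_system(topology: PathwayTopology, max_damping: int = 20):
    """LU-factor (I - B), damping beta by 0.99 per retry if singular."""
    top = topology
    for attempt in range(max_damping + 1):
        a = _normalized_system(top)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                factor = lu_factor(a)
            except Exception:
                factor = None
        scale = max(1.0, float(np.abs(a).max()))
        if factor is not None and np.abs(np.diag(factor[0])).min() > 1e-12 * scale:
            if attempt:
                warnings.warn(
                    f"pathway {topology.pathway_id}: singular system; "
                    f"applied 0.99 damping x{attempt}"
                )
            return factor
        top = PathwayTopology(
            top.pathway_id, top.pathway_name, list(top.genes), top.beta * 0.99
        )
    raise ValueError(
        f"pathway {topology.pathway_id}: perturbation system unresolvably singular"
    )


def _delta_vector(topology: PathwayTopology, delta_e, warn_missing=True) -> np.ndarray:
    vec = np.zeros(topology.size)
    index = {g: i for i, g in enumerate(topology.genes)}
    dropped = []
    for gene, de in delta_e.items():
        if gene in index:
            vec[index[gene]] = de
        else:
            dropped.append(gene)
    if dropped and warn_missing:
        warnings.warn(
            f"pathway {topology.pathway_id}: {len(dropped)} DE gene(s) not on "
            f"pathway dropped: {sorted(dropped)[:5]}..."
        )
    return vec


def perturbation_accumulation(
    topology: PathwayTopology, delta_e
) -> tuple[pd.Series, float]:
    """Solve the propagation system; return per-gene PF and total tA.

    ``delta_e`` maps DE gene -> signed log2 change (absent genes are 0).
    tA is the summed net accumulation  sum_g (PF(g) - dE(g)).
    """
    vec = _delta_vector(topology, dict(delta_e))
    factor = _factor_system(topology)
    pf = lu_solve(factor, vec)
    acc = pf - vec
    return pd.Series(pf, index=topology.genes, name="pf"), float(acc.sum())


def p_nde(nde_on_pathway: int, total_de: int, pathway_size: int,
          background: int) -> float:
    """Hypergeometric upper tail for the number of DE genes on a pathway."""
    return overrepresentation_test(
        nde_on_pathway, pathway_size, total_de, background
    )


def p_pert_bootstrap(
    topology: PathwayTopology,
    observed_delta_e,
    n_boot: int = 2000,
    seed: int = 0,
    rng=None,
) -> float:
    """Bootstrap probability of a perturbation as extreme as observed.

    Each round reassigns the observed dE magnitudes to ``nde`` uniformly
    drawn pathway genes and recomputes tA; the null is median-centered, the
    (count+1)/(n_boot+1) fraction at least as extreme in the observed
    direction is doubled to make it two-sided (an observation at the null
    median gets p ~ 1), and the result is capped at 1.
    """
    observed_delta_e = dict(observed_delta_e)
    magnitudes = np.array(
        [v for g, v in observed_delta_e.items() if g in set(topology.genes)]
    )
    if magnitudes.size == 0:
        raise ValueError(
            f"pathway {topology.pathway_id}: no DE genes on pathway"
        )
    if rng is None:
        rng = np.random.default_rng(seed)
    factor = _factor_system(topology)
    vec = _delta_vector(topology, observed_delta_e, warn_missing=False)
    t_obs = float((lu_solve(factor, vec) - vec).sum())

    nde = magnitudes.size
    null = np.empty(n_boot)
    for b in range(n_boot):
        pos = rng.choice(topology.size, size=nde, replace=False)
        v = np.zeros(topology.size)
        v[pos] = magnitudes
        null[b] = (lu_solve(factor, v) - v).sum()
    med = np.median(null)
    centered_obs = t_obs - med
    centered_null = null - med
    if centered_obs >= 0:
        count = int((centered_null >= centered_obs).sum())
    else:
        count = int((centered_null <= centered_obs).sum())
    # doubling makes the direction-chosen tail two-sided (p ~ 1 at the median)
    return min(1.0, 2.0 * (count + 1) / (n_boot + 1))


def combine_global(p_nde_value: float, p_pert_value: float) -> float:
    """P(product of two independent uniforms <= c) = c - c*ln(c)."""
    for p in (p_nde_value, p_pert_value):
        if not (0 < p <= 1):
            raise ValueError(f"probability {p} outside (0, 1]")
    c = p_nde_value * p_pert_value
    if c >= 1.0:
        return 1.0
    return c - c * math.log(c)


def run_spia(
    de_table: pd.DataFrame,
    topologies,
    de_threshold: float = 0.1,
    n_boot: int = 2000,
    seed: int = 0,
    background: int | None = None,
) -> pd.DataFrame:
    """Impact-analyze every pathway against a differential-expression table.

    Parameters
    ----------
    de_table
        Output of :func:`speccount.diffexp.run_differential_expression`
        (needs ``gene_symbol``, ``q_value``, ``log2_fc``).
    topologies
        Mapping pathway_id -> :class:`PathwayTopology` (or an iterable).
    background
        Number of measured genes conditioning pNDE; defaults to the number
        of genes in ``de_table``.

    Returns one row per pathway with at least one DE gene — ``pathway_id,
    name, pathway_size, nde, p_nde, t_a, p_pert, p_g, p_g_fdr, status,
    de_genes`` — sorted by p_g_fdr.  Pathways without DE genes are skipped.
    """
    if isinstance(topologies, dict):
        topologies = list(topologies.values())
    measured = set(de_table["gene_symbol"])
    if background is None:
        background = len(measured)
    de_rows = de_table.loc[de_table["q_value"] < de_threshold]
    delta_e = dict(zip(de_rows["gene_symbol"], de_rows["log2_fc"]))
    total_de = len(delta_e)

    rng = np.random.default_rng(seed)
    rows = []
    for top in topologies:
        on_pathway = set(top.genes) & measured
        de_on = {g: delta_e[g] for g in delta_e if g in set(top.genes)}
        if not de_on:
            continue
        size = len(on_pathway) if on_pathway else top.size
        pnde = p_nde(len(de_on), total_de, size, background)
        _, t_a = perturbation_accumulation(top, de_on)
        ppert = p_pert_bootstrap(top, de_on, n_boot=n_boot, rng=rng)
        pg = combine_global(pnde, ppert)
        rows.append(
            {
                "pathway_id": top.pathway_id,
                "name": top.pathway_name,
                "pathway_size": size,
                "nde": len(de_on),
                "p_nde": pnde,
                "t_a": t_a,
                "p_pert": ppert,
                "p_g": pg,
                "status": "inhibited" if t_a < 0 else "activated",
                "de_genes": ",".join(sorted(de_on)),
            }
        )
    table = pd.DataFrame(rows)
    if len(table):
        table["p_g_fdr"] = bh_adjust(table["p_g"].to_numpy())
        table = table.sort_values(
            ["p_g_fdr", "p_g", "pathway_id"], kind="mergesort"
        ).reset_index(drop=True)
        table = table[
            ["pathway_id", "name", "pathway_size", "nde", "p_nde", "t_a",
             "p_pert", "p_g", "p_g_fdr", "status", "de_genes"]
        ]
    return table
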