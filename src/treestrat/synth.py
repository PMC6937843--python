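"""Synthetic fixtures with planted structure.

Every stage of the pipeline can be exercised without external aligners or
tree-search engines: this module generates strategy-named tree sets whose
zero-distance equivalence classes are planted by construction, and SWLH
matrices in which one strategy carries a controlled per-site mean
log-likelihood advantage.  Site log-likelihoods are drawn i.i.d. normal
rather than simulated from a sequence model: the RELL/AU machinery consumes
only the SWLH matrix, and a distributional generator gives exact control of
the effect size for recovery experiments.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .relltest import SwlhGroup
from .seqio import SitelhFile, StrategyId, write_newick, write_sitelh
from .topo import PhyloTree, TreeNode, rf_distance

__all__ = [
    "SimConfig",
    "InfeasibleConfigError",
    "random_tree",
    "planted_tree_set",
    "simulate_swlh",
    "write_fixtures",
]

# synthetic per-stage codes used to name the generated strategies
_AE_CODES = ("MAFFTF2", "PRANKCDF", "MAFFTEI", "MUSCLE", "CLUSTALO",
             "KALIGN", "PROBCONS", "TCOFFEE", "FSA", "OPAL", "GRAMALIGN",
             "DIALIGNTX")
_ARC_CODES = ("TRIMALS", "MAXALIGN", "GBLOCKS", "NOISY")

# baseline per-site mean log-likelihood shared by all strategies
MU0 = -2.0


class InfeasibleConfigError(RuntimeError):
    """Could not generate the requested number of distinct topologies."""


@dataclass(frozen=True)
class SimConfig:
    """Conditions of one synthetic experiment.

    ``cluster_sizes`` partitions the strategies into identical-topology
    clusters; ``delta`` is the per-site mean log-likelihood advantage of the
    planted best strategy over the common baseline and ``sigma`` the
    per-site noise scale (both in log-likelihood units).
    """

    n_taxa: int = 12
    n_strategies: int = 8
    cluster_sizes: tuple[int, ...] = (5, 2, 1)
    n_sites: int = 1000
    delta: float = 0.05
    sigma: float = 1.0
    seed: int = 0
    gene: str = "SYNGENE"
    cc_code: str = "DNA"

    def __post_init__(self):
        object.__setattr__(self, "cluster_sizes", tuple(self.cluster_sizes))
        if sum(self.cluster_sizes) != self.n_strategies:
            raise ValueError("cluster sizes must sum to n_strategies")
        if self.delta < 0:
            raise ValueError("delta must be >= 0")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")

    @property
    def strategy_ids(self) -> tuple[StrategyId, ...]:
        """Deterministic strategy names following the file-naming scheme."""
        pairs = itertools.product(_ARC_CODES, _AE_CODES)
        out = []
        for _, (arc, ae) in zip(range(self.n_strategies), pairs):
            out.append(StrategyId(gene=self.gene, ae_code=ae, arc_code=arc,
                                  cc_or_pe_code=self.cc_code, ed_code="UB"))
        if len(out) < self.n_strategies:
            raise ValueError("n_strategies exceeds the synthetic code space")
        return tuple(out)


def random_tree(n_taxa: int, seed: int = 0, rooted: bool = False) -> PhyloTree:
    """Random binary tree by sequential leaf attachment on a uniform edge.

    Leaves are labelled ``t1 ... tn``; the topology distribution is uniform
    over leaf-addition orders and deterministic per seed.
    """
    if n_taxa < 3:
        raise ValueError("need at least 3 taxa")
    rng = np.random.default_rng(seed)

    root = TreeNode()
    first = 3 if not rooted else 2
    root.children = [TreeNode(f"t{i + 1}") for i in range(first)]
    # every non-root node subtends one attachable edge
    edges: list[TreeNode] = list(root.children)
    parent = {id(c): root for c in root.children}

    for i in range(first, n_taxa):
        target = edges[rng.integers(len(edges))]
        par = parent[id(target)]
        mid = TreeNode()
        leaf = TreeNode(f"t{i + 1}")
        par.children[par.children.index(target)] = mid
        mid.children = [target, leaf]
        parent[id(mid)] = par
        parent[id(target)] = mid
        parent[id(leaf)] = mid
        edges.extend([mid, leaf])
    return PhyloTree(root)


def planted_tree_set(cfg: SimConfig, max_tries: int = 200
                     ) -> dict[StrategyId, PhyloTree]:
    """Strategy-labelled trees whose identical-topology clusters are exactly
    ``cfg.cluster_sizes`` (distinctness enforced by rejection on the
    Robinson-Foulds distance)."""
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(1)[0])
    topologies: list[PhyloTree] = []
    for _ in cfg.cluster_sizes:
        for _try in range(max_tries):
            cand = random_tree(cfg.n_taxa, seed=int(rng.integers(2 ** 31)))
            if all(rf_distance(cand, t, mode="unrooted") > 0
                   for t in topologies):
                topologies.append(cand)
                break
        else:
            raise InfeasibleConfigError(
                f"could not find {len(cfg.cluster_sizes)} distinct "
                f"topologies on {cfg.n_taxa} taxa in {max_tries} tries")

    out: dict[StrategyId, PhyloTree] = {}
    ids = iter(cfg.strategy_ids)
    for topology, size in zip(topologies, cfg.cluster_sizes):
        for _ in range(size):
            out[next(ids)] = topology
    return out


def simulate_swlh(cfg: SimConfig, planted_best: int | StrategyId = 0
                  ) -> SwlhGroup:
    """SWLH matrix with mean MU0 everywhere and MU0 + delta for the planted
    best strategy; noise is i.i.d. normal with scale sigma."""
    ids = cfg.strategy_ids
    if isinstance(planted_best, StrategyId):
        planted_index = ids.index(planted_best)
    else:
        planted_index = int(planted_best)
    if not 0 <= planted_index < cfg.n_strategies:
        raise ValueError("planted_best out of range")
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(2)[1])
    loglik = rng.normal(MU0, cfg.sigma, (cfg.n_strategies, cfg.n_sites))
    loglik[planted_index] += cfg.delta
    return SwlhGroup(cfg.gene, cfg.cc_code, ids, loglik)


def write_fixtures(cfg: SimConfig, outdir, planted_best: int = 0
                   ) -> tuple[Path, Path]:
    """Write a complete on-disk fixture: per-strategy Newick trees under
    ``trees/`` and single-row sitelh files under ``sitelh/``, all named by
    the strategy scheme.  Returns the two directories."""
    outdir = Path(outdir)
    trees_dir = outdir / "trees"
    sitelh_dir = outdir / "sitelh"
    trees_dir.mkdir(parents=True, exist_ok=True)
    sitelh_dir.mkdir(parents=True, exist_ok=True)

    trees = planted_tree_set(cfg)
    for sid, tree in trees.items():
        write_newick(tree, trees_dir / f"{sid.render()}.nwk")

    group = simulate_swlh(cfg, planted_best)
    for sid, row in zip(group.strategies, group.loglik):
        write_sitelh(SitelhFile((sid.render(),), row[None, :]),
                     sitelh_dir / f"{sid.render()}.sitelh", precision=10)
    return trees_dir, sitelh_dir
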