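"""Statistical ranking of competing per-gene strategies from site-wise
log-likelihoods (SWLH).

Given the per-site log-likelihood row each tree-estimation run emits, the
strategies of one gene (sharing a character coding, hence comparable site
counts) are merged into a group and ranked by

* RELL bootstrap proportions (BP): sites are resampled with replacement and
  each replicate is awarded to the strategy with the highest resampled total
  log-likelihood (ties split fractionally among the maxima, so BPs always
  sum to one exactly); and
* the approximately unbiased (AU) p-value from the multiscale bootstrap:
  bootstrap proportions are computed at several resampling scales r (the
  replicate length is round(r * n_sites)); the normal quantiles
  z(r) = Phi^-1(1 - BP(r)) are fitted by weighted least squares to
  z = d*sqrt(r) + c/sqrt(r), and au = 1 - Phi(d - c).  d estimates the
  signed distance to the selection boundary and c its curvature; the fit
  weights are the delta-method variances of z, n_rep * phi(z)^2 / (BP(1-BP)).

Degenerate cases: a strategy at BP 0 or 1 on every scale gets au 1 (if it
dominated every replicate everywhere) or 0; with fewer than two informative
scales the AU falls back to the plain BP at scale 1 with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .seqio import SitelhFile, StrategyId

__all__ = [
    "DuplicateStrategyError",
    "SwlhGroup",
    "AuFit",
    "StatReport",
    "group_swlh",
    "rell_bp",
    "multiscale_bp",
    "au_pvalue",
    "stat_report",
    "DEFAULT_SCALES",
    "DEFAULT_N_REP",
]

DEFAULT_SCALES = tuple(np.round(np.arange(0.5, 1.45, 0.1), 2))
DEFAULT_N_REP = 10_000
_CHUNK = 2_000  # replicates per multinomial draw, bounds peak memory


class DuplicateStrategyError(ValueError):
    """The same strategy contributes two SWLH rows to one group."""


@dataclass(frozen=True)
class SwlhGroup:
    """SWLH rows of the strategies of one (gene, character coding) group."""

    gene: str
    cc_code: str
    strategies: tuple[StrategyId, ...]
    loglik: np.ndarray = field(repr=False)

    def __post_init__(self):
        arr = np.asarray(self.loglik, dtype=float)
        if arr.ndim != 2 or arr.shape[0] != len(self.strategies):
            raise ValueError("loglik must be a strategies x sites matrix")
        if not self.strategies:
            raise ValueError("a group needs at least one strategy")
        object.__setattr__(self, "strategies", tuple(self.strategies))
        object.__setattr__(self, "loglik", arr)

    @property
    def n_strategies(self) -> int:
        return len(self.strategies)

    @property
    def n_sites(self) -> int:
        return self.loglik.shape[1]

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(s.render() for s in self.strategies)

    def to_sitelh(self) -> SitelhFile:
        """The merged (agglutinated) multi-strategy sitelh matrix."""
        return SitelhFile(self.labels, self.loglik)


def group_swlh(files: Iterable[tuple[StrategyId, SitelhFile]]
               ) -> tuple[list[SwlhGroup], list[str]]:
    """Partition per-strategy SWLH rows into comparable groups.

    Rows are grouped by (gene, character coding); within a (gene, cc) pair,
    strategies whose site count differs from the majority are split into
    separate groups and noted in the returned skip log (their likelihoods
    are site-incomparable with the rest).  Each input file must hold exactly
    one row — the per-strategy output of a single estimation run.
    """
    by_key: dict[tuple[str, str], list[tuple[StrategyId, np.ndarray]]] = {}
    for sid, f in files:
        if f.n_trees != 1:
            raise ValueError(
                f"sitelh for {sid.render()!r} holds {f.n_trees} rows; "
                "per-strategy inputs must hold exactly one")
        by_key.setdefault((sid.gene, sid.cc_or_pe_code), []).append(
            (sid, f.loglik[0]))

    groups: list[SwlhGroup] = []
    skip_log: list[str] = []
    for (gene, cc) in sorted(by_key):
        entries = by_key[(gene, cc)]
        seen: set[str] = set()
        for sid, _ in entries:
            label = sid.render()
            if label in seen:
                raise DuplicateStrategyError(
                    f"strategy {label!r} appears twice in group "
                    f"({gene!r}, {cc!r})")
            seen.add(label)
        counts: dict[int, list[tuple[StrategyId, np.ndarray]]] = {}
        for sid, row in entries:
            counts.setdefault(len(row), []).append((sid, row))
        majority = max(counts, key=lambda ns: (len(counts[ns]), -ns))
        for n_sites in sorted(counts, key=lambda ns: (ns != majority, ns)):
            members = sorted(counts[n_sites], key=lambda e: e[0].render())
            groups.append(SwlhGroup(
                gene, cc,
                tuple(sid for sid, _ in members),
                np.vstack([row for _, row in members])))
            if n_sites != majority:
                for sid, _ in members:
                    skip_log.append(
                        f"{sid.render()}: {n_sites} sites differs from the "
                        f"({gene}, {cc}) majority of {majority}; placed in a "
                        "separate group")
    return groups, skip_log


def _bp_once(loglik: np.ndarray, n_draw: int, n_rep: int,
             rng: np.random.Generator) -> np.ndarray:
    """Tie-splitting bootstrap proportions for one resampling length."""
    m, n_sites = loglik.shape
    p = np.full(n_sites, 1.0 / n_sites)
    awards = np.zeros(m)
    done = 0
    while done < n_rep:
        k = min(_CHUNK, n_rep - done)
        counts = rng.multinomial(n_draw, p, size=k)
        totals = counts @ loglik.T
        is_max = totals == totals.max(axis=1, keepdims=True)
        awards += (is_max / is_max.sum(axis=1, keepdims=True)).sum(axis=0)
        done += k
    return awards / n_rep


def rell_bp(group: SwlhGroup, n_rep: int = DEFAULT_N_REP,
            seed: int = 0) -> np.ndarray:
    """RELL bootstrap proportion of each strategy in the group."""
    if n_rep < 1:
        raise ValueError("n_rep must be >= 1")
    rng = np.random.default_rng(seed)
    return _bp_once(group.loglik, group.n_sites, n_rep, rng)


def multiscale_bp(group: SwlhGroup, scales: Sequence[float] = DEFAULT_SCALES,
                  n_rep: int = DEFAULT_N_REP, seed: int = 0) -> np.ndarray:
    """Bootstrap proportions of every strategy at every resampling scale.

    Returns an (n_scales, n_strategies) array; all strategies share the same
    replicates at each scale, as in the classical multiscale bootstrap.
    """
    scales = np.asarray(scales, dtype=float)
    if np.any(scales <= 0):
        raise ValueError("scales must be strictly positive")
    rng = np.random.default_rng(seed)
    out = np.empty((len(scales), group.n_strategies))
    for i, r in enumerate(scales):
        n_draw = max(1, int(round(r * group.n_sites)))
        out[i] = _bp_once(group.loglik, n_draw, n_rep, rng)
    return out


@dataclass(frozen=True)
class AuFit:
    """Multiscale-bootstrap fit behind one AU p-value."""

    scales: tuple[float, ...]
    bp_per_scale: tuple[float, ...]
    d: float
    c: float

    def __post_init__(self):
        if any(r <= 0 for r in self.scales):
            raise ValueError("scales must be strictly positive")
        if any(not 0 <= b <= 1 for b in self.bp_per_scale):
            raise ValueError("bootstrap proportions must lie in [0, 1]")


def _au_from_bp(bps: np.ndarray, scales: np.ndarray, n_rep: int
                ) -> tuple[float, AuFit]:
    usable = (bps > 0) & (bps < 1)
    fit = AuFit(tuple(scales), tuple(bps), float("nan"), float("nan"))
    if not usable.any():
        return (1.0 if np.all(bps == 1.0) else 0.0), fit
    if usable.sum() < 2:
        warnings.warn("fewer than two informative bootstrap scales; "
                      "AU degraded to the plain BP at scale 1", stacklevel=3)
        at_one = int(np.argmin(np.abs(scales - 1.0)))
        return float(bps[at_one]), fit
    r = scales[usable]
    bp = bps[usable]
    z = norm.ppf(1.0 - bp)
    w = n_rep * norm.pdf(z) ** 2 / (bp * (1.0 - bp))
    X = np.column_stack([np.sqrt(r), 1.0 / np.sqrt(r)])
    sw = np.sqrt(w)
    coef, *_ = np.linalg.lstsq(X * sw[:, None], z * sw, rcond=None)
    d, c = float(coef[0]), float(coef[1])
    au = float(np.clip(1.0 - norm.cdf(d - c), 0.0, 1.0))
    return au, AuFit(tuple(scales), tuple(bps), d, c)


def au_pvalue(group: SwlhGroup, strategy: int,
              scales: Sequence[float] = DEFAULT_SCALES,
              n_rep: int = DEFAULT_N_REP, seed: int = 0
              ) -> tuple[float, AuFit]:
    """AU p-value of one strategy (by index) within its group."""
    if not 0 <= strategy < group.n_strategies:
        raise IndexError(f"strategy index {strategy} out of range")
    if n_rep < 100:
        raise ValueError("n_rep per scale must be >= 100")
    scales_arr = np.asarray(scales, dtype=float)
    bps = multiscale_bp(group, scales_arr, n_rep, seed)
    return _au_from_bp(bps[:, strategy], scales_arr, n_rep)


@dataclass(frozen=True)
class StatReport:
    """Ranked statistical comparison of one (gene, cc) strategy group.

    ``table`` columns: gene, cc, strategy, n_sites, obs_lnl, delta_lnl,
    bp, au, rank (1 = best).
    """

    gene: str
    cc_code: str
    table: pd.DataFrame

    @property
    def top(self) -> str:
        """Rendered label of the top-ranking statistical strategy."""
        return str(self.table.loc[self.table["rank"] == 1, "strategy"].iloc[0])

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def stat_report(group: SwlhGroup, n_rep: int = DEFAULT_N_REP,
                scales: Sequence[float] = DEFAULT_SCALES,
                seed: int = 0) -> StatReport:
    """Full statistical report for one group.

    Strategies are ranked by AU descending, ties broken by observed total
    log-likelihood descending, then by label.  BP and the multiscale AU
    replicates use independent streams derived from *seed*, so the report
    is bit-reproducible.
    """
    ss = np.random.SeedSequence(seed)
    seed_bp, seed_ms = ss.spawn(2)
    obs = group.loglik.sum(axis=1)
    delta = obs.max() - obs
    bp = _bp_once(group.loglik, group.n_sites, n_rep,
                  np.random.default_rng(seed_bp))
    scales_arr = np.asarray(scales, dtype=float)
    bps = multiscale_bp(group, scales_arr, n_rep,
                        np.random.default_rng(seed_ms))
    au = np.array([_au_from_bp(bps[:, j], scales_arr, n_rep)[0]
                   for j in range(group.n_strategies)])

    labels = group.labels
    order = sorted(range(group.n_strategies),
                   key=lambda j: (-au[j], -obs[j], labels[j]))
    rank = np.empty(group.n_strategies, dtype=int)
    for pos, j in enumerate(order):
        rank[j] = pos + 1

    table = pd.DataFrame({
        "gene": group.gene,
        "cc": group.cc_code,
        "strategy": list(labels),
        "n_sites": group.n_sites,
        "obs_lnl": obs,
        "delta_lnl": delta,
        "bp": bp,
        "au": au,
        "rank": rank,
    })
    return StatReport(group.gene, group.cc_code, table)
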