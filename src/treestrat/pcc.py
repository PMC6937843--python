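"""Cross-marking of statistical winners against topological matches, and
the total topological score (TTS) that selects each gene's optimal
strategies.

For each gene, every (gene, character-coding) statistical group contributes
one *seed*: its top-ranking strategy by AU.  Seeds carry the statistical
mark; every strategy in the gene's distance matrix at distance zero from a
seed (the seed itself included) carries the topological mark, so seeds are
doubly marked and their topological twins singly marked.  Marked strategies
form the consensus set: they are supported either directly by the
statistical test or by sharing a topology with a strategy that is.  The
condensed matrix discards the unmarked strategies, and the TTS of a
consensus strategy counts its zero-distance partners in the full matrix
(off-diagonal zeros of its row); the optimal strategies of a gene are those
attaining the maximum TTS.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .relltest import StatReport
from .topo import DistanceMatrix

__all__ = [
    "ConsensusTable",
    "TtsReport",
    "mark_consensus",
    "condense",
    "tts_scores",
    "write_reports",
    "REPORT_FILES",
]

logger = logging.getLogger(__name__)

REPORT_FILES = (
    "stat_report.csv",
    "mp_matrix.csv",
    "rf_matrix.csv",
    "consensus.csv",
    "condensed_matrix.csv",
    "tts_histogram.csv",
)

_CONSENSUS_COLS = ["gene", "strategy", "stat_mark", "topo_mark", "consensus"]
_TTS_COLS = ["gene", "strategy", "tts", "optimal"]


@dataclass(frozen=True)
class ConsensusTable:
    """Per-strategy marks for one gene.

    ``table`` columns: gene, strategy, stat_mark (is a top statistical
    strategy), topo_mark (zero distance to some seed), consensus (carries at
    least one mark; doubly marked strategies carry both).
    """

    gene: str
    table: pd.DataFrame

    @property
    def consensus_strategies(self) -> tuple[str, ...]:
        t = self.table
        return tuple(t.loc[t["consensus"], "strategy"])

    @property
    def marked_strategies(self) -> tuple[str, ...]:
        t = self.table
        return tuple(t.loc[t["stat_mark"] | t["topo_mark"], "strategy"])


@dataclass(frozen=True)
class TtsReport:
    """TTS histogram for one gene's consensus strategies."""

    gene: str
    table: pd.DataFrame

    @property
    def max_tts(self) -> int:
        return int(self.table["tts"].max()) if len(self.table) else 0

    @property
    def optimal_strategies(self) -> tuple[str, ...]:
        t = self.table
        return tuple(t.loc[t["optimal"], "strategy"])


def mark_consensus(stat_reports: Iterable[StatReport],
                   topo: DistanceMatrix) -> ConsensusTable:
    """Cross the per-cc statistical winners with the gene's distance matrix.

    Seeds absent from the matrix labels are logged and skipped; an empty
    matrix or an empty report list yields an empty (but shaped) table.
    """
    reports = list(stat_reports)
    gene = reports[0].gene if reports else ""
    if not reports or topo.size == 0:
        logger.warning("no statistical reports or empty distance matrix "
                       "for gene %r; consensus table is empty", gene)
        return ConsensusTable(gene, pd.DataFrame(columns=_CONSENSUS_COLS))

    seeds = []
    for rep in reports:
        label = rep.top
        if label not in topo.labels:
            logger.warning("top statistical strategy %r not present in the "
                           "distance matrix; skipped", label)
            continue
        seeds.append(label)

    stat_mark = {lab: lab in seeds for lab in topo.labels}
    topo_mark = {lab: False for lab in topo.labels}
    for seed in seeds:
        topo_mark[seed] = True
        for partner in topo.zero_partners(seed):
            topo_mark[partner] = True

    table = pd.DataFrame({
        "gene": gene,
        "strategy": list(topo.labels),
        "stat_mark": [stat_mark[l] for l in topo.labels],
        "topo_mark": [topo_mark[l] for l in topo.labels],
    })
    table["consensus"] = table["stat_mark"] | table["topo_mark"]
    return ConsensusTable(gene, table)


def condense(table: ConsensusTable, topo: DistanceMatrix) -> DistanceMatrix:
    """Submatrix restricted to marked strategies, label order preserved."""
    keep = [l for l in topo.labels if l in set(table.marked_strategies)]
    return topo.submatrix(keep)


def tts_scores(table: ConsensusTable, topo: DistanceMatrix) -> TtsReport:
    """TTS of every consensus strategy: off-diagonal zeros of its matrix row.

    All strategies attaining the gene's maximum TTS are flagged optimal.
    """
    strategies = [l for l in topo.labels
                  if l in set(table.consensus_strategies)]
    if not strategies:
        return TtsReport(table.gene, pd.DataFrame(columns=_TTS_COLS))
    tts = [len(topo.zero_partners(s)) for s in strategies]
    best = max(tts)
    out = pd.DataFrame({
        "gene": table.gene,
        "strategy": strategies,
        "tts": tts,
        "optimal": [t == best for t in tts],
    })
    return TtsReport(table.gene, out)


def _empty_matrix_csv(path: Path) -> None:
    path.write_text("strategy\n")


def write_reports(stat_reports: Sequence[StatReport],
                  mp_matrix: DistanceMatrix | None,
                  rf_matrix: DistanceMatrix | None,
                  table: ConsensusTable | None,
                  tts: TtsReport | None,
                  outdir) -> list[Path]:
    """Write the six per-gene CSV reports into *outdir*.

    Files: statistical report, matching-distance matrix, Robinson-Foulds
    matrix, consensus marks, condensed matrix, TTS histogram.  Content is a
    deterministic function of the inputs; missing/empty inputs yield
    empty-but-headed CSVs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = [outdir / name for name in REPORT_FILES]
    stat_path, mp_path, rf_path, cons_path, cond_path, tts_path = paths

    stat_cols = ["gene", "cc", "strategy", "n_sites", "obs_lnl",
                 "delta_lnl", "bp", "au", "rank"]
    if stat_reports:
        pd.concat([r.table for r in stat_reports],
                  ignore_index=True).to_csv(stat_path, index=False)
    else:
        pd.DataFrame(columns=stat_cols).to_csv(stat_path, index=False)

    for matrix, path in ((mp_matrix, mp_path), (rf_matrix, rf_path)):
        if matrix is not None and matrix.size:
            matrix.to_csv(path)
        else:
            _empty_matrix_csv(path)

    if table is not None and len(table.table):
        table.table.to_csv(cons_path, index=False)
    else:
        pd.DataFrame(columns=_CONSENSUS_COLS).to_csv(cons_path, index=False)

    if table is not None and mp_matrix is not None and mp_matrix.size:
        condensed = condense(table, mp_matrix)
        if condensed.size:
            condensed.to_csv(cond_path)
        else:
            _empty_matrix_csv(cond_path)
    else:
        _empty_matrix_csv(cond_path)

    if tts is not None and len(tts.table):
        tts.table.to_csv(tts_path, index=False)
    else:
        pd.DataFrame(columns=_TTS_COLS).to_csv(tts_path, index=False)

    return paths
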