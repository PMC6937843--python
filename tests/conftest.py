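import numpy as np
import pytest

from treestrat import (MultipleAlignment, PhyloTree, SitelhFile, StrategyId,
                       SwlhGroup)


@pytest.fixture
def quartet_pair():
    """Two fully resolved 4-leaf trees sharing no nontrivial split."""
    return (PhyloTree.from_newick("((A,B),(C,D));"),
            PhyloTree.from_newick("((A,C),(B,D));"))


@pytest.fixture
def small_aln():
    return MultipleAlignment(("t1", "t2"), ("ACGT", "AC-T"))


def make_strategy(ae="MAFFTF2", gene="G1", arc="TRIMALS", cc="DNA", ed="UB"):
    return StrategyId(gene=gene, ae_code=ae, arc_code=arc,
                      cc_or_pe_code=cc, ed_code=ed)


def make_group(loglik, gene="G1", cc="DNA", ae_codes=None):
    loglik = np.asarray(loglik, dtype=float)
    if ae_codes is None:
        ae_codes = ["MAFFTF2", "MUSCLE", "KALIGN", "OPAL", "FSA",
                    "PRANKCDF", "CLUSTALO", "TCOFFEE"][:loglik.shape[0]]
    sids = tuple(make_strategy(ae=a, gene=gene, cc=cc) for a in ae_codes)
    return SwlhGroup(gene, cc, sids, loglik)


def single_row_sitelh(row, name="Site_Lh"):
    return SitelhFile((name,), np.asarray(row, dtype=float)[None, :])
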