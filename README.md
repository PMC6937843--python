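# treestrat

Per-gene phylogeny-**strat**egy comparison and consensus.

When a protein-coding gene is analysed phylogenetically, every choice along
the way — multiple-sequence aligner, alignment refiner, character coding
(plain nucleotide, RY, degeneracy, amino acid...), tree-search program and
bootstrap flavour — is one *strategy*, and different genes are routinely
best served by different strategies. `treestrat` takes the per-strategy
outputs of such a sweep (one Newick tree and one site-wise log-likelihood
row per strategy, with the strategy chain encoded in each file name, e.g.
`COX2_PRANKCDF_MAXALIGN_DNA_UB`) and decides, gene by gene, which
strategies are optimal. It is aimed at molecular phylogeneticists running
many aligner x coding x estimator combinations over mitochondrial or
nuclear gene sets.

## What it computes

* **Character coding** of nucleotide alignments: RY coding (A,G → R;
  C,T → Y; over all columns or third codon positions only), algorithmic
  **degeneracy coding** (each codon replaced by the IUPAC-degenerate codon
  of its synonymous codon group, derived for any genetic code by joining
  codons that differ at one position while encoding the same amino acid and
  taking positionwise IUPAC unions — e.g. CTA → YTN, AGT → AGY),
  codon-position extraction, translation, and stop-codon handling.
* **Topological comparison**: for the trees of one gene, pairwise
  **Robinson–Foulds** distances (|S₁ △ S₂| over nontrivial splits, or
  clusters for rooted trees) and a **matching** distance (minimum-weight
  perfect matching between the two split systems, null entries costing
  min(|A|,|B|), solved by the Hungarian algorithm). Both are topology-only
  and integer-valued, and are zero exactly when the topologies agree.
* **Statistical comparison** from site-wise log-likelihoods (SWLH): the
  per-strategy rows of one (gene, coding) group are agglutinated and ranked
  by **RELL bootstrap proportions** (sites resampled with replacement,
  replicates awarded to the argmax total, ties split fractionally so BPs
  sum to 1 exactly) and by the **approximately unbiased (AU)** p-value from
  the multiscale bootstrap: z(r) = Φ⁻¹(1 − BP(r)) is fitted by weighted
  least squares to z = d·√r + c/√r over scales r ∈ {0.5, …, 1.4}, and
  au = 1 − Φ(d − c).
* **Consensus and total topological score (TTS)**: each (gene, coding)
  group's top-ranking strategy seeds the consensus; every strategy at
  distance zero from a seed in the gene's matching-distance matrix is
  marked (seeds doubly, their topological twins singly). Marked strategies
  form the consensus set; each one's **TTS** counts its zero-distance
  partners in the full matrix, and the strategies attaining the gene's
  maximum TTS are reported as optimal. Six CSV reports are written per
  gene: statistical ranking, the two distance matrices, consensus marks,
  the condensed (marked-only) matrix, and the TTS histogram.

A synthetic-fixture module (`treestrat.synth`) generates strategy-named
tree sets with planted identical-topology clusters and SWLH matrices with a
planted per-site advantage, so the whole pipeline can be exercised and
tested without any external alignment or tree-search software.

## Worked example

Simulate a gene with four strategies — three sharing one topology, one
distinct — where the advantaged strategy sits inside the 3-cluster, then
run the full chain:

```sh
treestrat simulate --n-taxa 10 --clusters 3,1 --n-sites 200 \
    --delta 1.0 --seed 7 --gene COX2 --outdir demo
treestrat run-pcc --trees-dir demo/trees --sitelh-dir demo/sitelh \
    --outdir demo/reports --seed 7 --n-rep 2000
```

which prints

```
COX2: max TTS 2; optimal: COX2_MAFFTEI_TRIMALS_DNA_UB, COX2_MAFFTF2_TRIMALS_DNA_UB, COX2_PRANKCDF_TRIMALS_DNA_UB
```

`demo/reports/tts_histogram.csv` then holds the consensus histogram:

```
gene,strategy,tts,optimal
COX2,COX2_MAFFTEI_TRIMALS_DNA_UB,2,True
COX2,COX2_MAFFTF2_TRIMALS_DNA_UB,2,True
COX2,COX2_PRANKCDF_TRIMALS_DNA_UB,2,True
```

The statistical winner (`COX2_MAFFTF2_TRIMALS_DNA_UB`, rank 1 with BP = AU
= 1.0 in `stat_report.csv`) seeds the consensus; its two topological twins
join it, each of the three has two zero-distance partners (TTS = 2), and
all three are optimal. The fourth strategy, topologically isolated and
statistically inferior, is excluded.

The same steps are available as library calls (`synth.write_fixtures`,
`topo.distance_matrix`, `relltest.stat_report`, `pcc.mark_consensus`,
`pcc.tts_scores`) and as the single subcommands `compare-topo`,
`compare-stat` and `consensus`.

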