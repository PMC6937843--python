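"""File IO and naming for the strategy-comparison pipeline.

Covers the three input kinds the pipeline consumes — FASTA nucleotide
alignments, Newick phylogenies, and site-wise log-likelihood ("sitelh")
text files in the TREE-PUZZLE/IQ-TREE dialect — plus the strategy-name
scheme that encodes, in each file name, the chain of algorithms
(gene, aligner, refiner, character coding, tree-search/bootstrap suffix)
that produced the file.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .topo import PhyloTree

__all__ = [
    "AlignmentShapeError",
    "DuplicateTaxonError",
    "AlphabetError",
    "TaxonSetError",
    "SitelhFormatError",
    "StrategyNameError",
    "MultipleAlignment",
    "read_fasta",
    "write_fasta",
    "normalize_taxa_order",
    "StrategyId",
    "Vocabulary",
    "DEFAULT_VOCABULARY",
    "parse_strategy_id",
    "SitelhFile",
    "read_sitelh",
    "write_sitelh",
    "read_newick",
    "write_newick",
]

NUCLEOTIDE_ALPHABET = frozenset("ACGTURYSWKMBDHVN-?")
AMINO_ACID_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYBZJXUO*-?")


class AlignmentShapeError(ValueError):
    """Rows of unequal length where an alignment is required."""


class DuplicateTaxonError(ValueError):
    """The same taxon label appears twice."""


class AlphabetError(ValueError):
    """A sequence contains a symbol outside the allowed alphabet."""


class TaxonSetError(ValueError):
    """Taxon sets disagree where they must be identical."""


class SitelhFormatError(ValueError):
    """Site-wise log-likelihood file does not match its declared shape."""


class StrategyNameError(ValueError):
    """A file name cannot be parsed against the stage code vocabularies."""


@dataclass(frozen=True)
class MultipleAlignment:
    """Equal-length, taxa-labelled sequence rows.

    ``molecule`` selects the validation alphabet: ``"nt"`` for IUPAC
    nucleotide codes (plus gap ``-`` and missing ``?``), ``"aa"`` for amino
    acids (the output of translation).
    """

    taxa: tuple[str, ...]
    rows: tuple[str, ...]
    molecule: str = "nt"

    def __post_init__(self):
        object.__setattr__(self, "taxa", tuple(self.taxa))
        object.__setattr__(self, "rows", tuple(self.rows))
        if len(self.taxa) != len(self.rows):
            raise AlignmentShapeError(
                f"{len(self.taxa)} taxa but {len(self.rows)} rows")
        dupes = {t for t in self.taxa if list(self.taxa).count(t) > 1}
        if dupes:
            raise DuplicateTaxonError(
                f"duplicate taxon label(s): {', '.join(sorted(dupes))}")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise AlignmentShapeError(
                f"rows have unequal lengths: {sorted(lengths)}")
        alphabet = NUCLEOTIDE_ALPHABET if self.molecule == "nt" else AMINO_ACID_ALPHABET
        for taxon, row in zip(self.taxa, self.rows):
            for i, ch in enumerate(row):
                if ch not in alphabet:
                    raise AlphabetError(
                        f"illegal character {ch!r} at position {i + 1} "
                        f"in sequence {taxon!r}")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_sites(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def with_rows(self, rows: Sequence[str], molecule: str | None = None
                  ) -> "MultipleAlignment":
        return MultipleAlignment(self.taxa, tuple(rows),
                                 molecule or self.molecule)


def read_fasta(path, molecule: str = "nt") -> MultipleAlignment:
    """Read a FASTA alignment; labels are the first header token, sequences
    are uppercased with wrapped lines concatenated.  Pass ``molecule="aa"``
    to validate against the amino-acid alphabet instead of the nucleotide
    one."""
    taxa: list[str] = []
    chunks: list[list[str]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                label = line[1:].split()[0] if line[1:].split() else ""
                if not label:
                    raise AlignmentShapeError(f"empty FASTA header in {path}")
                taxa.append(label)
                chunks.append([])
            else:
                if not taxa:
                    raise AlignmentShapeError(
                        f"sequence data before first header in {path}")
                chunks[-1].append(line.upper())
    if not taxa:
        raise AlignmentShapeError(f"no FASTA records in {path}")
    return MultipleAlignment(tuple(taxa), tuple("".join(c) for c in chunks),
                             molecule)


def write_fasta(aln: MultipleAlignment, path, width: int = 60) -> None:
    if aln.n_taxa == 0:
        raise AlignmentShapeError("refusing to write an empty alignment")
    with open(path, "w") as fh:
        for taxon, row in zip(aln.taxa, aln.rows):
            fh.write(f">{taxon}\n")
            for start in range(0, len(row), width):
                fh.write(row[start:start + width] + "\n")


def normalize_taxa_order(alns: Iterable[MultipleAlignment],
                         reference: Sequence[str]) -> list[MultipleAlignment]:
    """Reorder every alignment's rows into *reference* taxon order.

    Column content is untouched; only row order changes.  Every alignment's
    taxon set must equal the reference set.
    """
    ref = list(reference)
    ref_set = set(ref)
    out = []
    for aln in alns:
        aln_set = set(aln.taxa)
        if aln_set != ref_set:
            missing = sorted(ref_set - aln_set)
            extra = sorted(aln_set - ref_set)
            raise TaxonSetError(
                f"taxon set mismatch; missing: {missing}; extra: {extra}")
        by_taxon = dict(zip(aln.taxa, aln.rows))
        out.append(MultipleAlignment(tuple(ref),
                                     tuple(by_taxon[t] for t in ref),
                                     aln.molecule))
    return out


# --------------------------------------------------------------------------
# Strategy identifiers


@dataclass(frozen=True)
class Vocabulary:
    """Per-stage code sets used to parse strategy-encoded file names."""

    ae: frozenset[str]
    arc: frozenset[str]
    cc: frozenset[str]
    ed: frozenset[str]

    @classmethod
    def from_dict(cls, d: dict) -> "Vocabulary":
        return cls(*(frozenset(d.get(k, ())) for k in ("ae", "arc", "cc", "ed")))

    @classmethod
    def from_yaml(cls, path) -> "Vocabulary":
        import yaml
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def extended(self, **stage_codes) -> "Vocabulary":
        d = {"ae": self.ae, "arc": self.arc, "cc": self.cc, "ed": self.ed}
        for k, codes in stage_codes.items():
            d[k] = d[k] | frozenset(codes)
        return Vocabulary.from_dict(d)


DEFAULT_VOCABULARY = Vocabulary(
    ae=frozenset({
        "CLUSTALO", "CLUSTALW", "DIALIGNTX", "FSA", "FSANP", "GRAMALIGN",
        "KALIGN", "MACSE", "MAFFT", "MAFFTA", "MAFFTEI", "MAFFTF1", "MAFFTF2",
        "MAFFTFI", "MAFFTGI", "MAFFTLI", "MUSCLE", "OPAL", "PRANK", "PRANKF",
        "PRANKO", "PRANKCD", "PRANKCDF", "PRANKCDO", "PROBALIGN", "PROBCONS",
        "TCOFFEE",
    }),
    arc=frozenset({
        "GBLOCKS", "GBLOCKSC", "MAXALIGN", "MERGEALIGN", "NOISY", "PSAR",
        "TCS", "TRIMAL", "TRIMALA", "TRIMALG", "TRIMALS", "TRIMALSP",
        "WEAVEALIGN",
    }),
    cc=frozenset({
        "DNA", "DNA12", "DNA3", "RY", "DEG", "CDN", "AA", "NT2AA",
        "MPBOOT", "NINJA", "SMS",
    }),
    ed=frozenset({"UB", "SB", "B", "ED"}),
)

_KNOWN_SUFFIXES = {
    ".fas", ".fasta", ".fa", ".nwk", ".newick", ".tree", ".treefile",
    ".sitelh", ".txt", ".csv",
}


@dataclass(frozen=True)
class StrategyId:
    """Parsed algorithm-chain identity of one per-gene MSA/tree/sitelh file."""

    gene: str
    ae_code: str
    arc_code: str = ""
    cc_or_pe_code: str = ""
    ed_code: str = ""

    def render(self) -> str:
        parts = (self.gene, self.ae_code, self.arc_code,
                 self.cc_or_pe_code, self.ed_code)
        return "_".join(p for p in parts if p)

    def __str__(self) -> str:
        return self.render()


def parse_strategy_id(filename: str,
                      vocab: Vocabulary = DEFAULT_VOCABULARY) -> StrategyId:
    """Parse a strategy-encoded file name.

    Tokens are assigned right-to-left against the per-stage vocabularies
    (trailing bootstrap/edit suffix, then character-coding code, then
    refinement code, then alignment code); whatever remains on the left is
    the gene name, which may itself contain underscores.
    """
    stem = Path(str(filename)).name
    while True:
        suffix = Path(stem).suffix.lower()
        if suffix in _KNOWN_SUFFIXES:
            stem = stem[:-len(suffix)]
        else:
            break
    tokens = stem.split("_")

    ed = tokens.pop() if tokens and tokens[-1] in vocab.ed else ""
    cc = tokens.pop() if tokens and tokens[-1] in vocab.cc else ""
    arc = tokens.pop() if tokens and tokens[-1] in vocab.arc else ""
    ae = tokens.pop() if tokens and tokens[-1] in vocab.ae else None
    if ae is None or not tokens:
        raise StrategyNameError(
            f"cannot parse strategy name {stem!r}: no token matches the "
            "stage-2 alignment vocabulary (or no gene name remains)")
    return StrategyId(gene="_".join(tokens), ae_code=ae, arc_code=arc,
                      cc_or_pe_code=cc, ed_code=ed)


# --------------------------------------------------------------------------
# Site-wise log-likelihood files


@dataclass(frozen=True)
class SitelhFile:
    """A "sitelh" matrix: per-tree rows of per-site log-likelihoods.

    The text dialect is the one tree-likelihood programs exchange: a header
    line ``n_trees n_sites``, then one record per tree consisting of a name
    token followed by ``n_sites`` numbers, with arbitrary line wrapping.
    """

    names: tuple[str, ...]
    loglik: np.ndarray = field(repr=False)

    def __post_init__(self):
        arr = np.asarray(self.loglik, dtype=float)
        if arr.ndim != 2 or arr.shape[0] != len(self.names):
            raise SitelhFormatError(
                f"log-likelihood matrix shape {arr.shape} does not match "
                f"{len(self.names)} name(s)")
        object.__setattr__(self, "names", tuple(self.names))
        object.__setattr__(self, "loglik", arr)

    @property
    def n_trees(self) -> int:
        return len(self.names)

    @property
    def n_sites(self) -> int:
        return self.loglik.shape[1]


def read_sitelh(path) -> SitelhFile:
    with open(path) as fh:
        tokens = fh.read().split()
    if len(tokens) < 2:
        raise SitelhFormatError(f"{path}: missing 'n_trees n_sites' header")
    try:
        n_trees, n_sites = int(tokens[0]), int(tokens[1])
    except ValueError as exc:
        raise SitelhFormatError(
            f"{path}: header must be two integers, got "
            f"{tokens[0]!r} {tokens[1]!r}") from exc
    expected = 2 + n_trees * (n_sites + 1)
    if len(tokens) != expected:
        raise SitelhFormatError(
            f"{path}: expected {expected} tokens for {n_trees} tree(s) x "
            f"{n_sites} site(s), found {len(tokens)}")
    names = []
    rows = np.empty((n_trees, n_sites))
    pos = 2
    for i in range(n_trees):
        names.append(tokens[pos])
        pos += 1
        try:
            rows[i] = [float(t) for t in tokens[pos:pos + n_sites]]
        except ValueError as exc:
            raise SitelhFormatError(
                f"{path}: non-numeric value in record {names[-1]!r}") from exc
        pos += n_sites
    return SitelhFile(tuple(names), rows)


def write_sitelh(s: SitelhFile, path, precision: int = 6) -> None:
    """Write the merged multi-strategy sitelh file: header then one
    unwrapped row per strategy at *precision* significant digits."""
    with open(path, "w") as fh:
        fh.write(f"{s.n_trees} {s.n_sites}\n")
        for name, row in zip(s.names, s.loglik):
            vals = " ".join(f"{v:.{precision}g}" for v in row)
            fh.write(f"{name} {vals}\n")


# --------------------------------------------------------------------------
# Newick files


def read_newick(path) -> list[PhyloTree]:
    """Read one or more Newick trees (';'-terminated) from a file."""
    text = Path(path).read_text()
    chunks = [c.strip() for c in text.split(";")]
    trees = [PhyloTree.from_newick(c) for c in chunks if c]
    if not trees:
        raise ValueError(f"no trees found in {path}")
    return trees


def write_newick(trees: PhyloTree | Iterable[PhyloTree], path) -> None:
    if isinstance(trees, PhyloTree):
        trees = [trees]
    with open(path, "w") as fh:
        for t in trees:
            fh.write(t.to_newick() + "\n")
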