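"""Character-coding transforms applied to nucleotide alignments before
tree estimation.

The codings here are the standard pre-estimation recodings used to damp
substitution saturation and compositional bias in protein-coding genes:

* RY coding — purines (A, G) to R and pyrimidines (C, T/U) to Y, over all
  positions or third codon positions only;
* degeneracy coding — every codon replaced by an IUPAC-degenerate codon
  that erases all synonymous variation within its synonymous codon group;
* codon-position extraction (e.g. positions 1+2 only, or 3 only);
* translation to amino acids, and stop-codon stripping/masking.

The degeneracy table is derived algorithmically from any genetic code:
codons are joined by an edge when they differ at exactly one position and
encode the same amino acid; each connected component is collapsed to a
degenerate codon whose position codes are the IUPAC unions of the
nucleotides observed at that position across the component.  Two codons in
the same component therefore cannot be distinguished by non-synonymous
change alone, and the coding removes exactly that (synonymous) signal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .seqio import MultipleAlignment

__all__ = [
    "GeneticCode",
    "DegenTable",
    "STANDARD_CODE",
    "ry_encode",
    "build_degen_table",
    "degen_encode",
    "extract_codon_positions",
    "translate",
    "strip_stop_codons",
    "RaggedStopError",
]

_BASES = "ACGT"
_CODONS = tuple(a + b + c for a in _BASES for b in _BASES for c in _BASES)

# IUPAC code for each non-empty subset of {A, C, G, T}
IUPAC_UNION: Mapping[frozenset, str] = {
    frozenset("A"): "A", frozenset("C"): "C",
    frozenset("G"): "G", frozenset("T"): "T",
    frozenset("AG"): "R", frozenset("CT"): "Y",
    frozenset("CG"): "S", frozenset("AT"): "W",
    frozenset("GT"): "K", frozenset("AC"): "M",
    frozenset("CGT"): "B", frozenset("AGT"): "D",
    frozenset("ACT"): "H", frozenset("ACG"): "V",
    frozenset("ACGT"): "N",
}

# A,G and the purine ambiguity code R -> R; C,T,U and Y -> Y; gaps and
# missing pass through; every other (mixed) ambiguity code -> N.
_RY_MAP = {**{b: "R" for b in "AGR"}, **{b: "Y" for b in "CTUY"},
           "-": "-", "?": "?"}


class RaggedStopError(ValueError):
    """Final-codon stop stripping requested but rows disagree on the stop."""


@dataclass(frozen=True)
class GeneticCode:
    """A codon-to-amino-acid translation table ('*' marks stop codons)."""

    table_id: str
    codon_to_aa: Mapping[str, str]

    def __post_init__(self):
        if set(self.codon_to_aa) != set(_CODONS):
            raise ValueError("genetic code must map exactly the 64 ACGT codons")
        if "*" not in self.codon_to_aa.values():
            raise ValueError("genetic code has no stop codon")
        object.__setattr__(self, "codon_to_aa", dict(self.codon_to_aa))

    @property
    def stop_codons(self) -> frozenset[str]:
        return frozenset(c for c, a in self.codon_to_aa.items() if a == "*")

    @classmethod
    def from_ncbi_id(cls, table_id: int = 1) -> "GeneticCode":
        """Build from an NCBI translation-table number (1 = standard,
        2 = vertebrate mitochondrial, ...)."""
        from Bio.Data import CodonTable
        tab = CodonTable.unambiguous_dna_by_id[table_id]
        mapping = dict(tab.forward_table)
        for stop in tab.stop_codons:
            mapping[stop] = "*"
        return cls(str(table_id), mapping)

    @classmethod
    def from_file(cls, path, table_id: str | None = None) -> "GeneticCode":
        """Read a plain-text table of whitespace-separated 'CODON AA' pairs;
        lines starting with '#' are comments."""
        mapping = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                codon, aa = line.split()[:2]
                mapping[codon.upper().replace("U", "T")] = aa.upper()
        return cls(table_id or str(path), mapping)


STANDARD_CODE = GeneticCode.from_ncbi_id(1)


@dataclass(frozen=True)
class DegenTable:
    """Map of the 64 codons to their degenerate (IUPAC) images."""

    codon_to_degen: Mapping[str, str]

    def __post_init__(self):
        if set(self.codon_to_degen) != set(_CODONS):
            raise ValueError("degeneracy table must cover all 64 codons")
        object.__setattr__(self, "codon_to_degen", dict(self.codon_to_degen))

    def __getitem__(self, codon: str) -> str:
        return self.codon_to_degen[codon]


def _frame_start(frame: int) -> int:
    if frame not in (1, 2, 3):
        raise ValueError(f"frame must be 1, 2 or 3, got {frame!r}")
    return frame - 1


def ry_encode(aln: MultipleAlignment, positions: str = "all",
              frame: int = 1) -> MultipleAlignment:
    """Recode purines to R and pyrimidines to Y.

    ``positions="all"`` recodes every column; ``positions="third"`` recodes
    only third codon positions (reading frame given 1-based by *frame*),
    leaving other columns unchanged.
    """
    start = _frame_start(frame)
    if positions not in ("all", "third"):
        raise ValueError(f"positions must be 'all' or 'third', got {positions!r}")

    def selected(i: int) -> bool:
        if positions == "all":
            return True
        return (i - start) % 3 == 2

    rows = []
    for row in aln.rows:
        rows.append("".join(_RY_MAP.get(ch, "N") if selected(i) else ch
                            for i, ch in enumerate(row)))
    return aln.with_rows(rows)


def build_degen_table(code: GeneticCode) -> DegenTable:
    """Derive the degeneracy table for *code* (see module docstring)."""
    # union-find over single-substitution synonymous codon pairs
    parent = {c: c for c in _CODONS}

    def find(c: str) -> str:
        while parent[c] != c:
            parent[c] = parent[parent[c]]
            c = parent[c]
        return c

    for codon in _CODONS:
        aa = code.codon_to_aa[codon]
        for pos in range(3):
            for base in _BASES:
                if base == codon[pos]:
                    continue
                other = codon[:pos] + base + codon[pos + 1:]
                if code.codon_to_aa[other] == aa:
                    parent[find(codon)] = find(other)

    components: dict[str, list[str]] = {}
    for codon in _CODONS:
        components.setdefault(find(codon), []).append(codon)

    table = {}
    for members in components.values():
        degen = "".join(
            IUPAC_UNION[frozenset(m[pos] for m in members)] for pos in range(3))
        for m in members:
            table[m] = degen
    return DegenTable(table)


def degen_encode(aln: MultipleAlignment, table: DegenTable | None = None,
                 frame: int = 1) -> MultipleAlignment:
    """Replace each in-frame, fully resolved (A/C/G/T/U) codon by its
    degenerate image; codons containing gaps, '?' or ambiguity codes, and
    trailing partial codons, are copied through unchanged."""
    if table is None:
        table = build_degen_table(STANDARD_CODE)
    start = _frame_start(frame)
    rows = []
    for row in aln.rows:
        out = list(row)
        for i in range(start, len(row) - 2, 3):
            codon = row[i:i + 3].replace("U", "T")
            if all(b in _BASES for b in codon):
                out[i:i + 3] = table[codon]
        rows.append("".join(out))
    return aln.with_rows(rows)


def extract_codon_positions(aln: MultipleAlignment, keep,
                            frame: int = 1) -> MultipleAlignment:
    """Keep only the columns whose codon position is in *keep* ⊆ {1,2,3}."""
    keep = frozenset(keep)
    if not keep:
        raise ValueError("keep set must not be empty")
    if not keep <= {1, 2, 3}:
        raise ValueError(f"keep must be a subset of {{1,2,3}}, got {sorted(keep)}")
    start = _frame_start(frame)
    cols = [i for i in range(aln.n_sites) if ((i - start) % 3) + 1 in keep]
    return aln.with_rows("".join(row[i] for i in cols) for row in aln.rows)


def translate(aln: MultipleAlignment, code: GeneticCode = STANDARD_CODE,
              frame: int = 1, strip_final_stop: bool = False
              ) -> MultipleAlignment:
    """Translate in-frame codons to an amino-acid alignment.

    Fully gapped codons become '-'; codons containing any gap, missing or
    ambiguity symbol become 'X'; stop codons become '*'.  With
    ``strip_final_stop`` the last amino-acid column is dropped when it is a
    stop in every row that has residues there.
    """
    start = _frame_start(frame)
    rows = []
    for row in aln.rows:
        aas = []
        for i in range(start, len(row) - 2, 3):
            codon = row[i:i + 3].replace("U", "T")
            if codon == "---":
                aas.append("-")
            elif all(b in _BASES for b in codon):
                aas.append(code.codon_to_aa[codon])
            else:
                aas.append("X")
        rows.append("".join(aas))
    if strip_final_stop and rows and rows[0]:
        finals = {r[-1] for r in rows}
        if "*" in finals and finals <= {"*", "-"}:
            rows = [r[:-1] for r in rows]
    return aln.with_rows(rows, molecule="aa")


def strip_stop_codons(aln: MultipleAlignment, code: GeneticCode = STANDARD_CODE,
                      frame: int = 1, mode: str = "final-only"
                      ) -> MultipleAlignment:
    """Remove or mask stop codons in a coding alignment.

    ``final-only`` drops the last complete in-frame codon column-triple
    when it is a stop codon in every row where it is not fully gapped (a
    mix of stop and non-stop final codons raises :class:`RaggedStopError`).
    ``mask-internal`` replaces internal (non-final) stop codons by 'NNN'
    row by row.
    """
    start = _frame_start(frame)
    stops = code.stop_codons
    codon_starts = list(range(start, aln.n_sites - 2, 3))
    if not codon_starts:
        return aln

    if mode == "final-only":
        last = codon_starts[-1]
        saw_stop = saw_other = False
        for row in aln.rows:
            codon = row[last:last + 3].replace("U", "T")
            if codon == "---":
                continue
            if codon in stops:
                saw_stop = True
            else:
                saw_other = True
        if saw_stop and saw_other:
            raise RaggedStopError(
                "final in-frame codon is a stop in some rows but not others")
        if not saw_stop:
            return aln
        cols = [i for i in range(aln.n_sites) if not last <= i < last + 3]
        return aln.with_rows("".join(row[i] for i in cols) for row in aln.rows)

    if mode == "mask-internal":
        rows = []
        for row in aln.rows:
            out = list(row)
            for i in codon_starts[:-1]:
                if row[i:i + 3].replace("U", "T") in stops:
                    out[i:i + 3] = "NNN"
            rows.append("".join(out))
        return aln.with_rows(rows)

    raise ValueError(f"mode must be 'final-only' or 'mask-internal', got {mode!r}")
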