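"""Concatenate locus alignments into a sparse species-by-character supermatrix.

Species missing a block are padded with ``?``; both ``?`` and ``-`` are
treated as missing data downstream (gaps are not coded as characters).
Partitions are tracked as half-open 0-based column intervals internally and
exported 1-based inclusive in NEXUS charset statements.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import dendropy
import pandas as pd
from Bio import AlignIO

from .alignment_engine import Alignment
from .seqio_taxonomy import CommunityTaxonomy

MISSING_CHARS = frozenset("?-")


@dataclass
class SuperMatrix:
    species: list[str]
    rows: list[str]  # one string per species, all equal length
    partitions: list[tuple[str, int, int]]  # (label, start, end) half-open

    def __post_init__(self):
        if not self.species:
            raise ValueError("empty matrix")
        L = len(self.rows[0])
        if any(len(r) != L for r in self.rows):
            raise ValueError("matrix rows differ in length")
        if len(set(self.species)) != len(self.species):
            raise ValueError("duplicate species in matrix")
        # partitions must tile the columns exactly
        pos = 0
        for label, s, e in self.partitions:
            if s != pos or e <= s:
                raise ValueError(f"partitions do not tile columns (at {label!r})")
            pos = e
        if pos != L:
            raise ValueError("partitions do not cover all columns")

    @property
    def ncols(self) -> int:
        return len(self.rows[0])

    @property
    def ntax(self) -> int:
        return len(self.species)

    def row(self, species: str) -> str:
        return self.rows[self.species.index(species)]

    def __eq__(self, other):
        if not isinstance(other, SuperMatrix):
            return NotImplemented
        return (self.species == other.species and self.rows == other.rows
                and self.partitions == other.partitions)


def assemble(blocks: Sequence[Alignment], taxonomy: Optional[CommunityTaxonomy] = None) -> SuperMatrix:
    """Union the blocks' species and concatenate their columns.

    A species whose only data come from partitioned spacer blocks is
    excluded: such a species has no globally alignable anchor locus, so its
    placement would rest entirely on a family-local alignment. When every
    block is partitioned (a spacer-only analysis) the rule is vacuous and
    all species are kept.
    """
    if not blocks:
        raise ValueError("no blocks to assemble")
    for b in blocks:
        if len(set(b.taxa)) != len(b.taxa):
            raise ValueError(f"duplicate species within block {b.partition_label!r}")
    anchored = set()
    everyone = set()
    any_global = any(not b.partitioned for b in blocks)
    for b in blocks:
        everyone.update(b.taxa)
        if not b.partitioned:
            anchored.update(b.taxa)
    species = sorted(anchored) if any_global else sorted(everyone)
    if not species:
        raise ValueError("no species remain after the spacer-only exclusion rule")

    partitions = []
    chunks: dict[str, list[str]] = {s: [] for s in species}
    pos = 0
    for b in blocks:
        label = f"{b.marker}:{b.partition_label}"
        partitions.append((label, pos, pos + b.ncols))
        pos += b.ncols
        lookup = dict(zip(b.taxa, b.rows))
        pad = "?" * b.ncols
        for s in species:
            chunks[s].append(lookup.get(s, pad))
    return SuperMatrix(species, ["".join(chunks[s]) for s in species], partitions)


def missing_fraction(matrix: SuperMatrix) -> float:
    """Proportion of cells that are '?' or '-' (both scored as missing)."""
    total = matrix.ntax * matrix.ncols
    miss = sum(r.count("?") + r.count("-") for r in matrix.rows)
    return miss / total


# ------------------------------------------------------------------- export

_FORMATS = ("nexus", "phylip", "csv")


def _quote(label: str) -> str:
    return "'" + label.replace("'", "''") + "'"


def export_matrix(matrix: SuperMatrix, path, format: str = "nexus") -> None:
    if format not in _FORMATS:
        raise ValueError(f"unknown format {format!r}; expected one of {_FORMATS}")
    if format == "nexus":
        with open(path, "w") as fh:
            fh.write("#NEXUS\n\nBEGIN DATA;\n")
            fh.write(f"    DIMENSIONS NTAX={matrix.ntax} NCHAR={matrix.ncols};\n")
            fh.write("    FORMAT DATATYPE=DNA MISSING=? GAP=-;\n    MATRIX\n")
            width = max(len(_quote(s)) for s in matrix.species) + 2
            for s, r in zip(matrix.species, matrix.rows):
                fh.write(f"        {_quote(s):<{width}}{r}\n")
            fh.write("    ;\nEND;\n\nBEGIN SETS;\n")
            for label, s, e in matrix.partitions:
                fh.write(f"    CHARSET {_quote(label)} = {s + 1}-{e};\n")
            fh.write("END;\n")
    elif format == "phylip":
        with open(path, "w") as fh:
            fh.write(f" {matrix.ntax} {matrix.ncols}\n")
            for s, r in zip(matrix.species, matrix.rows):
                fh.write(f"{s}  {r}\n")
    else:  # csv: one column per partition holding that block's characters
        cols = {}
        for label, s, e in matrix.partitions:
            cols[label] = [r[s:e] for r in matrix.rows]
        pd.DataFrame(cols, index=pd.Index(matrix.species, name="species")).to_csv(path)


def import_matrix(path, format: str = "nexus") -> SuperMatrix:
    """Re-read an exported matrix. PHYLIP carries no partition structure,
    so it comes back as a single partition labelled ``all``."""
    if format not in _FORMATS:
        raise ValueError(f"unknown format {format!r}; expected one of {_FORMATS}")
    if format == "nexus":
        cm = dendropy.DnaCharacterMatrix.get(path=str(path), schema="nexus",
                                             preserve_underscores=True)
        species = [t.label for t in cm.taxon_namespace]
        rows = [str(cm[t]).upper() for t in cm.taxon_namespace]
        subsets = []
        for label, subset in cm.character_subsets.items():
            idx = sorted(subset.character_indices)
            subsets.append((label, idx[0], idx[-1] + 1))
        subsets.sort(key=lambda t: t[1])
        if not subsets:
            subsets = [("all", 0, len(rows[0]))]
        return SuperMatrix(species, rows, subsets)
    if format == "phylip":
        aln = AlignIO.read(str(path), "phylip-relaxed")
        species = [rec.id for rec in aln]
        rows = [str(rec.seq).upper() for rec in aln]
        return SuperMatrix(species, rows, [("all", 0, len(rows[0]))])
    df = pd.read_csv(path, index_col="species", dtype=str)
    species = list(df.index)
    partitions, rows_parts, pos = [], [], 0
    for label in df.columns:
        block = df[label].tolist()
        width = len(block[0])
        partitions.append((label, pos, pos + width))
        pos += width
        rows_parts.append(block)
    rows = ["".join(parts[i] for parts in rows_parts) for i in range(len(species))]
    return SuperMatrix(species, rows, partitions)
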