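"""Locus-specific multiple alignment strategies for the three barcode loci.

Three strategies feed the supermatrix:

* ``align_coding_global`` — a single global alignment for a slowly evolving,
  indel-free coding locus (rbcLa-like). Equal-length inputs stack directly;
  otherwise a progressive aligner is used.
* ``align_backtranslate`` — codon-aware alignment for a coding locus with
  unknown reading frame (matK-like): detect the frame by minimizing internal
  stop codons, align at the protein level, map gaps back in codon triples.
* ``align_partitioned`` — spacer sequences (trnH-psbA-like) are too
  divergent for a global alignment, so they are aligned within taxonomic
  groups (family by default) and later concatenated as separate blocks.

The progressive aligner is deliberately self-contained: pairwise and
profile-profile Needleman-Wunsch with affine gaps (match +1, mismatch -1,
gap open -2, extend -1) merged along a UPGMA guide tree built from 8-mer
Jaccard distances. An external aligner can be substituted by any function
with the same signature.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from Bio.Seq import Seq
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .seqio_taxonomy import CommunityTaxonomy, SequenceRecord

logger = logging.getLogger(__name__)

MATCH, MISMATCH, GAP_OPEN, GAP_EXTEND = 1.0, -1.0, -2.0, -1.0
_NEG = -1e30

# IUPAC nucleotide -> fractional weight over (A, C, G, T); gaps/unknown -> 0
_DNA_STATES = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
}
_AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class Alignment:
    """Equal-length rows over a shared marker, one row per species."""

    marker: str
    partition_label: str
    taxa: list[str]
    rows: list[str]
    partitioned: bool = False
    excluded: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.rows:
            raise ValueError("alignment must contain at least one row")
        L = len(self.rows[0])
        if any(len(r) != L for r in self.rows):
            raise ValueError("alignment rows differ in length")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate taxa in alignment")
        if len(self.taxa) != len(self.rows):
            raise ValueError("taxa/rows length mismatch")

    @property
    def ncols(self) -> int:
        return len(self.rows[0])

    def row(self, taxon: str) -> str:
        return self.rows[self.taxa.index(taxon)]

    def write_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for t, r in zip(self.taxa, self.rows):
                fh.write(f">{t}\n{r}\n")


# ------------------------------------------------------------------ profiles


def _profile_matrix(rows: Sequence[str], alphabet: dict[str, str], size: int,
                    index: dict[str, int]) -> np.ndarray:
    """(ncols, size) fractional state frequencies; gaps and wildcards weigh 0."""
    n, L = len(rows), len(rows[0])
    prof = np.zeros((L, size))
    for r in rows:
        for j, ch in enumerate(r):
            states = alphabet.get(ch, "")
            if states:
                w = 1.0 / len(states)
                for s in states:
                    prof[j, index[s]] += w
    prof /= n
    return prof


def _dna_profile(rows):
    idx = {c: i for i, c in enumerate("ACGT")}
    return _profile_matrix(rows, _DNA_STATES, 4, idx)


def _aa_profile(rows):
    idx = {c: i for i, c in enumerate(_AA)}
    alphabet = {c: c for c in _AA}
    return _profile_matrix(rows, alphabet, 20, idx)


def _profile_align(rows_a: list[str], rows_b: list[str], profile_fn) -> tuple[list[str], list[str]]:
    """Affine-gap NW on column profiles; returns gap-padded row groups."""
    fa, fb = profile_fn(rows_a), profile_fn(rows_b)
    wa, wb = fa.sum(axis=1), fb.sum(axis=1)
    # sum-of-pairs expected score: match*P(same) + mismatch*P(diff)
    sub = (MATCH - MISMATCH) * (fa @ fb.T) + MISMATCH * np.outer(wa, wb)
    La, Lb = len(rows_a[0]), len(rows_b[0])

    M = np.full((La + 1, Lb + 1), _NEG)
    X = np.full((La + 1, Lb + 1), _NEG)  # gap in B (vertical move)
    Y = np.full((La + 1, Lb + 1), _NEG)  # gap in A (horizontal move)
    M[0, 0] = 0.0
    if La:
        X[1:, 0] = GAP_OPEN + GAP_EXTEND * np.arange(La)
    if Lb:
        Y[0, 1:] = GAP_OPEN + GAP_EXTEND * np.arange(Lb)

    jj = np.arange(1, Lb + 1)
    for i in range(1, La + 1):
        prevM, prevX, prevY = M[i - 1], X[i - 1], Y[i - 1]
        best_prev = np.maximum(np.maximum(prevM, prevX), prevY)
        M[i, 1:] = sub[i - 1, :] + best_prev[:-1]
        X[i, 1:] = np.maximum(prevM[1:] + GAP_OPEN,
                              np.maximum(prevX[1:] + GAP_EXTEND, prevY[1:] + GAP_OPEN))
        X[i, 0] = GAP_OPEN + GAP_EXTEND * (i - 1)
        # Y within-row recurrence via prefix max of the affine-adjusted source
        z = np.maximum(M[i, :-1], X[i, :-1]) + GAP_OPEN - GAP_EXTEND * jj
        Y[i, 1:] = np.maximum.accumulate(z) + GAP_EXTEND * jj

    # traceback
    i, j = La, Lb
    state = int(np.argmax([M[i, j], X[i, j], Y[i, j]]))
    cols_a, cols_b = [], []  # lists of (source column or None)
    while i > 0 or j > 0:
        if state == 0:  # aligned columns
            cols_a.append(i - 1)
            cols_b.append(j - 1)
            prev = [M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]]
            i, j = i - 1, j - 1
            state = int(np.argmax(prev))
        elif state == 1:  # column from A, gap in B
            cols_a.append(i - 1)
            cols_b.append(None)
            prev = [M[i - 1, j] + GAP_OPEN, X[i - 1, j] + GAP_EXTEND, Y[i - 1, j] + GAP_OPEN]
            i = i - 1
            state = int(np.argmax(prev))
        else:  # gap in A, column from B
            cols_a.append(None)
            cols_b.append(j - 1)
            prev = [M[i, j - 1] + GAP_OPEN, X[i, j - 1] + GAP_OPEN, Y[i, j - 1] + GAP_EXTEND]
            j = j - 1
            state = int(np.argmax(prev))
    cols_a.reverse()
    cols_b.reverse()

    def expand(rows, cols):
        out = []
        for r in rows:
            out.append("".join("-" if c is None else r[c] for c in cols))
        return out

    return expand(rows_a, cols_a), expand(rows_b, cols_b)


# ---------------------------------------------------------------- guide tree


def _kmer_set(seq: str, k: int = 8) -> frozenset:
    return frozenset(seq[i:i + k] for i in range(len(seq) - k + 1))


def _guide_merge_order(seqs: Sequence[str]) -> list[tuple[int, int]]:
    """UPGMA merge schedule from 8-mer Jaccard distances.

    Returns (left, right) cluster indices in scipy linkage convention:
    original sequences are 0..n-1, merged clusters n, n+1, ...
    """
    n = len(seqs)
    if n == 1:
        return []
    sets = [_kmer_set(s) for s in seqs]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = sets[i], sets[j]
            if not a and not b:
                dist = 0.0
            elif not a or not b:
                dist = 1.0
            else:
                dist = 1.0 - len(a & b) / len(a | b)
            d[i, j] = d[j, i] = dist
    Z = linkage(squareform(d, checks=False), method="average")
    return [(int(a), int(b)) for a, b, _, _ in Z]


def _progressive(taxa: list[str], seqs: list[str], profile_fn) -> tuple[list[str], list[str]]:
    """Progressive alignment; returns (taxa order, aligned rows)."""
    clusters: dict[int, tuple[list[str], list[str]]] = {
        i: ([t], [s]) for i, (t, s) in enumerate(zip(taxa, seqs))
    }
    nxt = len(taxa)
    for a, b in _guide_merge_order(seqs):
        ta, ra = clusters.pop(a)
        tb, rb = clusters.pop(b)
        ga, gb = _profile_align(ra, rb, profile_fn)
        clusters[nxt] = (ta + tb, ga + gb)
        nxt += 1
    (t, r), = clusters.values()
    return t, r


# ------------------------------------------------------------ public API


def _one_per_species(records: Sequence[SequenceRecord]) -> list[SequenceRecord]:
    seen = {}
    for r in records:
        if r.species_code in seen:
            raise ValueError(f"multiple records for species {r.species_code!r}; "
                             "reduce with choose_species_representative first")
        seen[r.species_code] = r
    return [seen[s] for s in sorted(seen)]


def align_coding_global(records: Sequence[SequenceRecord]) -> Alignment:
    """Global alignment for an indel-poor coding locus.

    Equal-length inputs are stacked directly (the no-indel case is
    unambiguous); otherwise the progressive aligner resolves length
    variation, typically from partial sequences.
    """
    if not records:
        raise ValueError("no records to align")
    recs = _one_per_species(records)
    marker = recs[0].marker
    taxa = [r.species_code for r in recs]
    seqs = [r.bases for r in recs]
    if len({len(s) for s in seqs}) == 1:
        return Alignment(marker, "global", taxa, seqs)
    t, rows = _progressive(taxa, seqs, _dna_profile)
    order = sorted(range(len(t)), key=lambda i: t[i])
    return Alignment(marker, "global", [t[i] for i in order], [rows[i] for i in order])


def _frame_and_protein(bases: str, table_id: int) -> tuple[int, int, str]:
    """(offset, internal stop count, protein) for the best reading frame."""
    best = None
    for off in range(3):
        ncod = (len(bases) - off) // 3
        if ncod <= 0:
            continue
        region = bases[off:off + 3 * ncod]
        prot = str(Seq(region).translate(table=table_id))
        stops = prot[:-1].count("*")  # a terminal stop is legitimate
        if best is None or stops < best[1]:
            best = (off, stops, prot)
    if best is None:
        raise ValueError("sequence shorter than one codon")
    return best


def align_backtranslate(records: Sequence[SequenceRecord], genetic_code: int = 11) -> Alignment:
    """Codon-aware alignment by translating, aligning proteins, mapping back.

    Each sequence is read in the frame that minimizes internal stop codons
    (ties to the lowest offset). Sequences whose best frame still leaves
    more than 5% of codons as stops are excluded and logged: they are
    unlikely to be clean coding sequence. Frame offsets and trailing
    partial codons are kept, padded with gaps into whole leading/trailing
    triples so the output length is a multiple of 3 and no base is lost.
    """
    if not records:
        raise ValueError("no records to align")
    recs = _one_per_species(records)
    marker = recs[0].marker
    excluded: dict[str, str] = {}
    kept, proteins, offsets, rems = [], [], [], []
    for r in recs:
        off, stops, prot = _frame_and_protein(r.bases, genetic_code)
        ncod = len(prot)
        if ncod and stops / ncod > 0.05:
            reason = f"best frame {off} has {stops}/{ncod} internal stops"
            excluded[r.species_code] = reason
            logger.warning("excluding %s from %s back-translation: %s",
                           r.species_code, marker, reason)
            continue
        kept.append(r)
        proteins.append(prot.replace("*", "X"))
        offsets.append(off)
        rems.append(len(r.bases) - off - 3 * ncod)
    if not kept:
        raise ValueError("all sequences failed frame detection")

    taxa = [r.species_code for r in kept]
    if len({len(p) for p in proteins}) == 1:
        # equal-length proteins from a frame-consistent coding locus: no indels
        aligned_taxa, aligned_prots = taxa, proteins
    else:
        aligned_taxa, aligned_prots = _progressive(taxa, proteins, _aa_profile)

    has_lead = any(offsets)
    has_trail = any(rems)
    rows = []
    by_taxon = {r.species_code: (r, o, m) for r, o, m in zip(kept, offsets, rems)}
    for t, prot_row in zip(aligned_taxa, aligned_prots):
        r, off, rem = by_taxon[t]
        body_start = off
        pos = body_start
        parts = []
        if has_lead:
            parts.append("-" * (3 - off) + r.bases[:off] if off else "---")
        for ch in prot_row:
            if ch == "-":
                parts.append("---")
            else:
                parts.append(r.bases[pos:pos + 3])
                pos += 3
        if has_trail:
            tail = r.bases[pos:]
            parts.append(tail + "-" * (3 - len(tail)) if tail else "---")
        rows.append("".join(parts))
    order = sorted(range(len(aligned_taxa)), key=lambda i: aligned_taxa[i])
    return Alignment(marker, "global",
                     [aligned_taxa[i] for i in order], [rows[i] for i in order],
                     excluded=excluded)


def align_partitioned(records: Sequence[SequenceRecord], taxonomy: CommunityTaxonomy,
                      rank: str = "family") -> list[Alignment]:
    """Align a spacer locus within taxonomic groups.

    Records are grouped by their ``rank`` taxon and each group is aligned
    independently. Groups with a single species are omitted entirely: a
    lone spacer sequence has nothing to align against and would contribute
    only autapomorphic noise.
    """
    if rank not in ("family", "order"):
        raise ValueError("rank must be 'family' or 'order'")
    recs = _one_per_species(records)
    groups: dict[str, list[SequenceRecord]] = {}
    for r in recs:
        groups.setdefault(taxonomy.rank_of(r.species_code, rank), []).append(r)
    out = []
    for name in sorted(groups):
        members = groups[name]
        if len(members) < 2:
            continue
        taxa = [r.species_code for r in members]
        seqs = [r.bases for r in members]
        t, rows = _progressive(taxa, seqs, _dna_profile)
        order = sorted(range(len(t)), key=lambda i: t[i])
        out.append(Alignment(members[0].marker, name,
                             [t[i] for i in order], [rows[i] for i in order],
                             partitioned=True))
    return out
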