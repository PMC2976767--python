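"""Sequence-recovery tabulation and leave-one-out barcode identification.

Recovery rates roll per-sample sequencing success up the taxonomic
hierarchy (a taxon succeeds if any member does, and marker unions count
"any marker" per sample before the rollup). Identification is leave-one-out
at the sequence level: each sequence is queried against all others and is
correctly identified at a rank when every tied best match belongs to the
query's taxon at that rank. The matching kernel is global pairwise
alignment identity over the shorter sequence; a BLAST-style local aligner
can be substituted via the ``similarity`` hook.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import Align

from .seqio_taxonomy import MARKERS, CommunityTaxonomy, SequenceRecord

MARKER_COLUMNS = (
    "trnH-psbA", "rbcLa", "matK", "rbcLa+trnH-psbA", "rbcLa+matK", "all",
)
_UNIONS = {
    "rbcLa+trnH-psbA": ("rbcLa", "trnH-psbA"),
    "rbcLa+matK": ("rbcLa", "matK"),
    "all": MARKERS,
}
LEVELS = ("sample", "species", "genus", "family", "order")
RANKS = ("species", "genus", "family", "order")


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass
class RecoveryTable:
    """Success counts, totals and percentages per level and marker column."""

    counts: pd.DataFrame  # index LEVELS, columns MARKER_COLUMNS
    totals: dict[str, int]
    percentages: pd.DataFrame

    def proportion(self, level: str, column: str) -> float:
        return float(self.counts.at[level, column]) / self.totals[level]

    def to_csv(self, path) -> None:
        out = self.counts.astype(str) + "/" + pd.Series(self.totals).astype(str)
        out = out + " (" + self.percentages.map(lambda v: f"{v:.1f}%") + ")"
        out.to_csv(path)


def recovery_table(flags: pd.DataFrame, sample_to_species: Mapping[str, str],
                   taxonomy: CommunityTaxonomy) -> RecoveryTable:
    """Tabulate recovery from per-(sample, marker) success flags.

    ``flags`` needs columns ``sample``, ``marker``, ``success``; a missing
    (sample, marker) pair counts as failure. Totals at species and coarser
    levels come from the full taxonomy, so unsampled taxa count against the
    rate, as in a community census.
    """
    required = {"sample", "marker", "success"}
    if not required <= set(flags.columns):
        raise ValueError(f"flags table needs columns {sorted(required)}")
    bad_markers = set(flags["marker"]) - set(MARKERS)
    if bad_markers:
        raise ValueError(f"unknown markers in flags: {sorted(bad_markers)}")
    samples = sorted(set(flags["sample"]))
    unmapped = [s for s in samples if s not in sample_to_species]
    if unmapped:
        raise ValueError(f"samples not mapped to species: {unmapped}")
    for s in samples:
        if sample_to_species[s] not in taxonomy:
            raise ValueError(f"sample {s!r} maps to unknown species {sample_to_species[s]!r}")

    wide = (flags.pivot_table(index="sample", columns="marker", values="success",
                              aggfunc="any", fill_value=False)
            .reindex(index=samples, columns=list(MARKERS), fill_value=False)
            .astype(bool))
    for col, members in _UNIONS.items():
        wide[col] = wide[list(members)].any(axis=1)

    totals = {
        "sample": len(samples),
        **{rank: taxonomy.counts()[rank] for rank in RANKS},
    }
    counts = pd.DataFrame(0, index=list(LEVELS), columns=list(MARKER_COLUMNS), dtype=int)
    counts.loc["sample"] = wide[list(MARKER_COLUMNS)].sum()
    species_of = pd.Series({s: sample_to_species[s] for s in samples})
    by_species = wide.groupby(species_of).any()
    for rank in RANKS:
        if rank == "species":
            grouped = by_species
        else:
            key = by_species.index.map(lambda sp: taxonomy.rank_of(sp, rank))
            grouped = by_species.groupby(key).any()
        counts.loc[rank] = grouped[list(MARKER_COLUMNS)].sum()
    pct = counts.div(pd.Series(totals), axis=0).mul(100).round(1)
    return RecoveryTable(counts, totals, pct)


# ----------------------------------------------------------- identification

_aligner = Align.PairwiseAligner()
_aligner.mode = "global"
_aligner.match_score = 1
_aligner.mismatch_score = -1
_aligner.open_gap_score = -2
_aligner.extend_gap_score = -1
# end gaps are free: identity is judged over the shorter sequence
_aligner.end_gap_score = 0.0


def pairwise_identity(a: str, b: str) -> float:
    """Fraction of identically aligned bases over the shorter sequence."""
    if a == b:
        return 1.0
    aln = _aligner.align(a, b)[0]
    identities = aln.counts().identities
    return identities / min(len(a), len(b))


@dataclass
class QueryOutcome:
    sample_id: str
    species: str
    best_hits: list[str]  # species codes of tied best matches
    identity: float
    correct_at: dict[str, bool]


@dataclass
class IdentificationReport:
    marker: str
    rank: str
    ci: float  # frequency of correct identification in [0, 1]
    outcomes: list[QueryOutcome]

    def ci_at(self, rank: str) -> float:
        return sum(o.correct_at[rank] for o in self.outcomes) / len(self.outcomes)


def loo_identify(records: Sequence[SequenceRecord], taxonomy: CommunityTaxonomy,
                 rank: str = "species",
                 similarity: Optional[Callable[[str, str], float]] = None,
                 ) -> IdentificationReport:
    """Leave-one-out identification for one marker's records.

    Every sequence queries the remaining ones; ties at the top similarity
    spanning more than one rank-level taxon score as incorrect
    (conservative). A species represented by a single sequence can thus
    never be species-correct but may be correct at coarser ranks.
    """
    if len(records) < 2:
        raise ValueError("need at least two sequences for leave-one-out queries")
    markers = {r.marker for r in records}
    if len(markers) != 1:
        raise ValueError(f"records span markers {sorted(markers)}")
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}")
    for r in records:
        if r.species_code not in taxonomy:
            raise ValueError(f"species {r.species_code!r} not in taxonomy")
    sim = similarity or pairwise_identity
    n = len(records)
    S = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            S[i, j] = S[j, i] = sim(records[i].bases, records[j].bases)

    outcomes = []
    for i, q in enumerate(records):
        sims = np.delete(S[i], i)
        others = [r for k, r in enumerate(records) if k != i]
        best = sims.max()
        hits = [r for r, s in zip(others, sims) if s == best]
        correct = {}
        for rk in RANKS:
            want = taxonomy.rank_of(q.species_code, rk)
            correct[rk] = all(taxonomy.rank_of(h.species_code, rk) == want for h in hits)
        outcomes.append(QueryOutcome(q.sample_id, q.species_code,
                                     sorted({h.species_code for h in hits}),
                                     float(best), correct))
    ci = sum(o.correct_at[rank] for o in outcomes) / len(outcomes)
    return IdentificationReport(records[0].marker, rank, ci, outcomes)


def recovery_times_ci(recovery: RecoveryTable,
                      reports: Mapping[tuple[str, str], IdentificationReport],
                      ) -> pd.DataFrame:
    """Effective identification power: recovery rate x CI, as integer percent.

    ``reports`` maps (marker, rank) to an identification report; each cell
    is round-half-up of 100 x recovery proportion x CI frequency.
    """
    rows = {}
    for (marker, rank), rep in reports.items():
        if marker not in MARKER_COLUMNS:
            raise KeyError(f"marker {marker!r} not in the recovery table")
        if rank not in RANKS:
            raise KeyError(f"unknown rank {rank!r}")
        p = recovery.proportion(rank, marker) * rep.ci_at(rank)
        rows.setdefault(rank, {})[marker] = _round_half_up(100.0 * p)
    return pd.DataFrame(rows).T.sort_index()
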