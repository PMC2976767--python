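"""Barcode sequence records, community taxonomy, and the ordinal backbone.

The community is described at four nested ranks (species -> genus ->
family -> order). Sequences arrive as per-marker FASTA files whose headers
follow the ``sampleID|speciesCode`` convention (a species-level file may
give just the species code). The ordinal backbone is a rooted Newick tree
whose tips are order names.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

from .trees import Tree

MARKERS = ("rbcLa", "trnH-psbA", "matK")

TAXONOMY_COLUMNS = ("species", "genus", "family", "order")

_GAP_CHARS = "-."


class TaxonomyError(ValueError):
    """Raised when a taxonomy table violates the nesting invariants."""


@dataclass(frozen=True)
class SequenceRecord:
    """One barcode sequence for one sample (or species) at one marker."""

    sample_id: str
    species_code: str
    marker: str
    bases: str

    def __post_init__(self):
        if self.marker not in MARKERS:
            raise ValueError(f"unknown marker {self.marker!r}; expected one of {MARKERS}")
        if not self.bases:
            raise ValueError(f"empty sequence for {self.sample_id!r}")


class CommunityTaxonomy:
    """Species list with genus/family/order assignments.

    Wraps a DataFrame with columns (species, genus, family, order) and
    enforces that species are unique and that each genus belongs to one
    family and each family to one order.
    """

    def __init__(self, table: pd.DataFrame):
        missing = [c for c in TAXONOMY_COLUMNS if c not in table.columns]
        if missing:
            raise TaxonomyError(f"taxonomy table missing columns: {missing}")
        table = table.loc[:, list(TAXONOMY_COLUMNS)].astype(str).reset_index(drop=True)
        if (table == "").any().any() or table.isna().any().any():
            raise TaxonomyError("taxonomy table contains empty cells")
        dup = table["species"][table["species"].duplicated()]
        if len(dup):
            raise TaxonomyError(f"duplicate species: {sorted(set(dup))}")
        for child, parent in (("genus", "family"), ("family", "order")):
            k = table.groupby(child)[parent].nunique()
            bad = k[k > 1]
            if len(bad):
                name = bad.index[0]
                raise TaxonomyError(
                    f"{child} {name!r} assigned to multiple {parent}s: "
                    f"{sorted(table.loc[table[child] == name, parent].unique())}"
                )
        self.table = table
        self._species_row = table.set_index("species")

    # -------------------------------------------------------------- queries
    @property
    def species(self) -> list[str]:
        return list(self.table["species"])

    def counts(self) -> dict[str, int]:
        """Number of distinct taxa at each rank."""
        return {rank: int(self.table[rank].nunique()) for rank in TAXONOMY_COLUMNS}

    def __contains__(self, species: str) -> bool:
        return species in self._species_row.index

    def __len__(self) -> int:
        return len(self.table)

    def rank_of(self, species: str, rank: str) -> str:
        if rank == "species":
            if species not in self:
                raise KeyError(species)
            return species
        try:
            return str(self._species_row.at[species, rank])
        except KeyError:
            raise KeyError(f"species {species!r} not in taxonomy") from None

    def taxa_at(self, rank: str) -> list[str]:
        return sorted(self.table[rank].unique())

    def members(self, rank: str, name: str) -> list[str]:
        """Species belonging to the named taxon."""
        return sorted(self.table.loc[self.table[rank] == name, "species"])

    def order_of(self, species: str) -> str:
        return self.rank_of(species, "order")


def read_taxonomy(path) -> CommunityTaxonomy:
    """Read a 4-column TSV (species, genus, family, order)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return CommunityTaxonomy(df)


def write_taxonomy(taxonomy: CommunityTaxonomy, path) -> None:
    taxonomy.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------- FASTA io


def _parse_header(header: str) -> tuple[str, str]:
    """Split ``sampleID|speciesCode``; a bare code serves as both."""
    head = header.split()[0]
    if "|" in head:
        sample_id, species_code = head.split("|", 1)
    else:
        sample_id = species_code = head
    return sample_id, species_code


def read_fasta(path, marker: str) -> list[SequenceRecord]:
    """Read one marker's FASTA into records; uppercases and strips gaps."""
    records = []
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta")):
        sample_id, species_code = _parse_header(rec.description or rec.id)
        bases = str(rec.seq).upper()
        for g in _GAP_CHARS:
            bases = bases.replace(g, "")
        if not bases:
            raise ValueError(f"entry {i + 1} ({rec.description!r}) in {path} has an empty sequence")
        records.append(SequenceRecord(sample_id, species_code, marker, bases))
    return records


def write_fasta(records: Iterable[SequenceRecord], path) -> None:
    bio = []
    for r in records:
        name = r.species_code if r.sample_id == r.species_code else f"{r.sample_id}|{r.species_code}"
        bio.append(_BioRecord(Seq(r.bases), id=name, description=""))
    SeqIO.write(bio, str(path), "fasta")


# ------------------------------------------------------------- backbone io


def read_backbone(path, taxonomy: Optional[CommunityTaxonomy] = None) -> Tree:
    """Read the ordinal backbone Newick; optionally verify order coverage."""
    tree = Tree.read(path)
    validate_backbone(tree, taxonomy)
    return tree


def validate_backbone(tree: Tree, taxonomy: Optional[CommunityTaxonomy] = None) -> None:
    tips = tree.leaf_names()
    if len(tips) != len(set(tips)):
        seen, dups = set(), set()
        for t in tips:
            (dups if t in seen else seen).add(t)
        raise ValueError(f"duplicate backbone tips: {sorted(dups)}")
    if taxonomy is not None:
        missing = set(taxonomy.taxa_at("order")) - set(tips)
        if missing:
            raise ValueError(f"orders absent from backbone: {sorted(missing)}")


# -------------------------------------------------- species representatives


def choose_species_representative(
    records: Sequence[SequenceRecord],
) -> dict[str, SequenceRecord]:
    """One record per species for a single marker.

    The longest sequence wins; length ties break to the lexicographically
    smallest sample id, so the choice depends only on the record multiset.
    """
    markers = {r.marker for r in records}
    if len(markers) > 1:
        raise ValueError(f"records span multiple markers: {sorted(markers)}")
    best: dict[str, SequenceRecord] = {}
    for r in sorted(records, key=lambda r: (r.species_code, -len(r.bases), r.sample_id)):
        best.setdefault(r.species_code, r)
    return best
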