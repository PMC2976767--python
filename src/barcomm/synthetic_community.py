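"""Synthetic taxonomy-structured communities with multi-locus barcode data.

Emulates the data a forest-plot barcoding campaign produces, scaled to
desk size: a nested taxonomy (orders > families > genera > species), an
ultrametric true tree built by gluing per-rank coalescent radiations (order
stems deepest), three loci with distinct lengths and substitution rates
(a slow indel-free coding locus, a fast coding locus, and a spacer with
indels), per-marker dropout, and optional taxonomic discordance (species
regrafted outside their genus, mimicking the polyphyletic genera real
communities show).

Branch lengths are in expected substitutions per site; per-branch
substitution sampling uses exact transition probabilities (JC69 or K2P),
so observed divergences can be checked against closed forms.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Mapping, Sequence, Union

import numpy as np
import pandas as pd

from .seqio_taxonomy import (MARKERS, CommunityTaxonomy, SequenceRecord,
                             write_fasta, write_taxonomy)
from .trees import Node, Tree

Count = Union[int, tuple[int, int]]
_BASES = "ACGT"
# K2P partners: A<->G, C<->T are transitions
_TRANSITION = {0: 2, 1: 3, 2: 0, 3: 1}


@dataclass
class LocusConfig:
    length: int
    model: str = "JC69"  # or "K2P"
    rate_scale: float = 1.0
    indel_rate: float = 0.0  # expected indel events / site / unit branch length
    kappa: float = 2.0  # K2P transition/transversion rate ratio
    coding: bool = False  # root drawn as a stop-free open reading frame

    def __post_init__(self):
        if self.length <= 0:
            raise ValueError("locus length must be positive")
        if self.model not in ("JC69", "K2P"):
            raise ValueError(f"unknown model {self.model!r}")
        if self.indel_rate < 0:
            raise ValueError("indel rate must be >= 0")


def default_loci() -> dict[str, LocusConfig]:
    """The three-barcode setup: slow rbcLa, fast matK, indel-prone spacer."""
    return {
        "rbcLa": LocusConfig(length=520, model="JC69", rate_scale=0.5, coding=True),
        "trnH-psbA": LocusConfig(length=450, model="K2P", rate_scale=1.5, indel_rate=0.1),
        "matK": LocusConfig(length=801, model="K2P", rate_scale=1.0, coding=True),
    }


def default_dropout() -> dict[str, float]:
    """Per-species dropout near observed per-marker failure rates."""
    return {"rbcLa": 0.10, "trnH-psbA": 0.08, "matK": 0.30}


@dataclass
class SimulationConfig:
    orders: Count = 6
    families_per_order: Count = 2
    genera_per_family: Count = 2
    species_per_genus: Count = (1, 2)
    loci: dict[str, LocusConfig] = dc_field(default_factory=default_loci)
    dropout: dict[str, float] = dc_field(default_factory=default_dropout)
    discordance: int = 0
    seed: int = 0
    # radiation heights per rank, expected substitutions/site at rate 1
    order_depth: float = 0.10
    family_depth: float = 0.05
    genus_depth: float = 0.03
    species_depth: float = 0.015

    def __post_init__(self):
        for p in self.dropout.values():
            if not 0.0 <= p <= 1.0:
                raise ValueError("dropout probabilities must lie in [0, 1]")
        for m in self.loci:
            if m not in MARKERS:
                raise ValueError(f"unknown marker {m!r}")


@dataclass
class SyntheticTruth:
    taxonomy: CommunityTaxonomy
    tree: Tree  # rooted, branch lengths in substitutions/site
    backbone: Tree  # ordinal backbone (tips = order names)
    config: SimulationConfig


def _count(v: Count, rng: np.random.Generator) -> int:
    if isinstance(v, int):
        return v
    lo, hi = v
    return int(rng.integers(lo, hi + 1))


def _radiation(subtrees: list[Node], height: float, rng: np.random.Generator) -> Node:
    """Coalescent-style ultrametric join of subtrees within ``height``."""
    if len(subtrees) == 1:
        st = subtrees[0]
        st.length = (st.length or 0.0) + height
        return st
    k = len(subtrees)
    times = np.sort(rng.uniform(0.0, 1.0, size=k - 1)) * height
    times[-1] = height
    lineages = [(st, 0.0) for st in subtrees]  # (node, birth time looking rootward)
    for t in times:
        i, j = sorted(rng.choice(len(lineages), size=2, replace=False))
        (b, tb) = lineages.pop(j)
        (a, ta) = lineages.pop(i)
        a.length = (a.length or 0.0) + (t - ta)
        b.length = (b.length or 0.0) + (t - tb)
        lineages.append((Node(children=[a, b]), t))
    root, _ = lineages[0]
    return root


def simulate_truth(config: SimulationConfig) -> SyntheticTruth:
    """Generate the taxonomy, true tree and ordinal backbone; seeded."""
    rng = np.random.default_rng(config.seed)
    rows = []
    order_subtrees = []
    order_names = []
    n_ord = _count(config.orders, rng)
    g_idx = f_idx = 0
    for o in range(n_ord):
        order = f"Ord{o + 1:02d}"
        order_names.append(order)
        fam_subtrees = []
        for _ in range(_count(config.families_per_order, rng)):
            f_idx += 1
            family = f"Fam{f_idx:02d}"
            gen_subtrees = []
            for _ in range(_count(config.genera_per_family, rng)):
                g_idx += 1
                genus = f"Gen{g_idx:03d}"
                tips = []
                for s in range(_count(config.species_per_genus, rng)):
                    sp = f"{genus}sp{s + 1}"
                    rows.append((sp, genus, family, order))
                    tips.append(Node(label=sp, length=0.0))
                gen_subtrees.append(_radiation(tips, config.species_depth, rng))
            fam_subtrees.append(_radiation(gen_subtrees, config.genus_depth, rng))
        order_subtrees.append(_radiation(fam_subtrees, config.family_depth, rng))

    root = _radiation(order_subtrees, config.order_depth, rng)
    tree = Tree(root)
    taxonomy = CommunityTaxonomy(
        pd.DataFrame(rows, columns=["species", "genus", "family", "order"]))

    # derive the backbone by collapsing each order subtree on a copy
    order_tipsets = {o: frozenset(taxonomy.members("order", o)) for o in order_names}
    bb = tree.copy()
    cmap = bb.node_clade_map()
    by_set = {cmap[id(n)]: n for n in bb.postorder()}
    for o, tipset in order_tipsets.items():
        node = by_set[tipset]
        node.children = []
        node.label = o
        node.length = None
    bb.suppress_unifurcations()
    for n in bb.postorder():
        n.length = None

    truth = SyntheticTruth(taxonomy, tree, bb, config)
    if config.discordance:
        _inject_discordance(truth, config.discordance, rng)
    return truth


def _inject_discordance(truth: SyntheticTruth, k: int, rng: np.random.Generator) -> None:
    """Regraft one species from each of k donor genera next to a congeneric
    family member, breaking exactly the donors' monophyly."""
    tax = truth.taxonomy.table
    sizes = tax.groupby("genus").size()
    fam_genera = tax.drop_duplicates("genus").groupby("family")["genus"].apply(list)
    donors = [g for g in sizes.index if sizes[g] >= 2
              and len(fam_genera[tax.loc[tax.genus == g, "family"].iloc[0]]) >= 2]
    if len(donors) < k:
        raise ValueError(f"cannot inject {k} discordant genera; only {len(donors)} eligible")
    chosen = [donors[i] for i in rng.choice(len(donors), size=k, replace=False)]
    tree = truth.tree
    for genus in chosen:
        members = truth.taxonomy.members("genus", genus)
        mover = members[int(rng.integers(len(members)))]
        family = truth.taxonomy.rank_of(mover, "family")
        others = [g for g in fam_genera[family] if g != genus]
        target_genus = others[int(rng.integers(len(others)))]
        target_tips = truth.taxonomy.members("genus", target_genus)
        leaf = next(l for l in tree.leaves() if l.label == mover)
        target = tree.mrca(target_tips) if len(target_tips) > 1 else \
            next(l for l in tree.leaves() if l.label == target_tips[0])
        tree.detach(leaf)
        leaf.parent = None
        tree.attach_on_edge(leaf, target)
        mid = leaf.parent
        # keep the tree metric: split the target's stem, keep mover's length
        if target.length is not None:
            half = target.length / 2
            mid.length, target.length = half, half


# ----------------------------------------------------------- sequence models


def _transition_matrix(d: float, model: str, kappa: float) -> np.ndarray:
    """Exact 4x4 substitution probabilities for branch length d (subs/site)."""
    if d <= 0:
        return np.eye(4)
    if model == "JC69":
        off = 0.25 - 0.25 * np.exp(-4.0 * d / 3.0)
        P = np.full((4, 4), off)
        np.fill_diagonal(P, 1.0 - 3.0 * off)
        return P
    # K2P: transition rate alpha, transversion beta with alpha/beta = kappa
    beta_t = d / (kappa + 2.0)
    alpha_t = kappa * beta_t
    p_tv = 0.25 - 0.25 * np.exp(-4.0 * beta_t)
    p_ts = 0.25 + 0.25 * np.exp(-4.0 * beta_t) - 0.5 * np.exp(-2.0 * (alpha_t + beta_t))
    P = np.zeros((4, 4))
    for i in range(4):
        for j in range(4):
            if i == j:
                P[i, j] = 1.0 - p_ts - 2.0 * p_tv
            elif j == _TRANSITION[i]:
                P[i, j] = p_ts
            else:
                P[i, j] = p_tv
    return P


def evolve_branch(states: np.ndarray, d: float, locus: LocusConfig,
                  rng: np.random.Generator) -> np.ndarray:
    """Substitutions (exact P(d)) then indels along one branch."""
    P = _transition_matrix(d * locus.rate_scale, locus.model, locus.kappa)
    out = states.copy()
    for s in range(4):
        idx = np.flatnonzero(states == s)
        if len(idx):
            out[idx] = rng.choice(4, size=len(idx), p=P[s])
    if locus.indel_rate > 0 and len(out):
        lam = locus.indel_rate * d * locus.rate_scale * len(out)
        for _ in range(rng.poisson(lam)):
            length = int(rng.geometric(0.5))
            pos = int(rng.integers(len(out) + 1))
            if rng.random() < 0.5 and len(out) > length:
                out = np.delete(out, slice(pos, pos + length))
            else:
                out = np.insert(out, pos, rng.integers(0, 4, size=length))
    return out


_STOP_CODONS = {(3, 0, 0), (3, 0, 2), (3, 2, 0)}  # TAA, TAG, TGA


def _root_sequence(locus: LocusConfig, rng: np.random.Generator) -> np.ndarray:
    """Uniform root sequence; coding loci draw stop-free frame-0 codons."""
    if not locus.coding:
        return rng.integers(0, 4, size=locus.length)
    sense = np.array([c for c in itertools.product(range(4), repeat=3)
                      if c not in _STOP_CODONS])
    n_codon = (locus.length + 2) // 3
    seq = sense[rng.integers(0, len(sense), size=n_codon)].reshape(-1)
    return seq[:locus.length].copy()


def evolve_sequences(truth: SyntheticTruth, marker: str) -> list[SequenceRecord]:
    """Simulate one marker down the true tree; deterministic given the truth."""
    locus = truth.config.loci[marker]
    rng = np.random.default_rng((truth.config.seed, MARKERS.index(marker)))
    root_seq = _root_sequence(locus, rng)
    records: list[SequenceRecord] = []

    def descend(node: Node, seq: np.ndarray):
        for child in node.children:
            cseq = evolve_branch(seq, child.length or 0.0, locus, rng)
            if child.is_leaf:
                bases = "".join(_BASES[s] for s in cseq)
                records.append(SequenceRecord(child.label, child.label, marker, bases))
            else:
                descend(child, cseq)

    descend(truth.tree.root, root_seq)
    records.sort(key=lambda r: r.species_code)
    return records


def apply_dropout(records: Sequence[SequenceRecord],
                  per_marker_probability: Mapping[str, float],
                  seed: int) -> tuple[list[SequenceRecord], pd.DataFrame]:
    """Independent Bernoulli removal per (species, marker); returns survivors
    and a flag table consumable by ``recovery_table``."""
    for m, p in per_marker_probability.items():
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"dropout probability for {m} outside [0, 1]")
    rng = np.random.default_rng(seed)
    surviving, flags = [], []
    for r in sorted(records, key=lambda r: (r.marker, r.species_code, r.sample_id)):
        p = per_marker_probability.get(r.marker, 0.0)
        keep = bool(rng.random() >= p)
        flags.append({"sample": r.sample_id, "marker": r.marker, "success": keep})
        if keep:
            surviving.append(r)
    return surviving, pd.DataFrame(flags, columns=["sample", "marker", "success"])


def write_community(truth: SyntheticTruth, outdir,
                    records_by_marker: Mapping[str, Sequence[SequenceRecord]]) -> dict[str, str]:
    """Write FASTA/TSV/Newick in the formats the pipeline consumes."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    write_taxonomy(truth.taxonomy, outdir / "taxonomy.tsv")
    paths["taxonomy"] = str(outdir / "taxonomy.tsv")
    truth.backbone.write(outdir / "backbone.nwk")
    paths["backbone"] = str(outdir / "backbone.nwk")
    truth.tree.write(outdir / "true_tree.nwk", lengths=True)
    paths["true_tree"] = str(outdir / "true_tree.nwk")
    for marker, recs in records_by_marker.items():
        p = outdir / f"{marker.replace('-', '_')}.fasta"
        write_fasta(recs, p)
        paths[marker] = str(p)
    return paths
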