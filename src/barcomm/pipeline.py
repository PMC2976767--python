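"""End-to-end orchestration: align -> supermatrix -> constrained search -> metrics.

Every stage is a library call; this module only sequences them, logs stage
timings, and writes a manifest (seed, versions, parameters) sufficient for
an exact re-run. Stage failures propagate with the stage name; outputs
written before the failure are retained for inspection.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .alignment_engine import (align_backtranslate, align_coding_global,
                               align_partitioned)
from .community_metrics import (misplaced_orders, monophyly_report,
                                resolution_fraction, support_bins)
from .constraint_topology import build_constraint, is_compatible
from .parsimony_engine import SearchConfig, majority_consensus, ratchet_search
from .seqio_taxonomy import (MARKERS, choose_species_representative,
                             read_backbone, read_fasta, read_taxonomy)
from .supermatrix import assemble, export_matrix, missing_fraction

logger = logging.getLogger(__name__)

MARKER_COMBINATIONS = {
    "rbcLa": ("rbcLa",),
    "trnH-psbA": ("trnH-psbA",),
    "rbcLa+trnH-psbA": ("rbcLa", "trnH-psbA"),
    "rbcLa+matK": ("rbcLa", "matK"),
    "all": ("rbcLa", "trnH-psbA", "matK"),
}


@dataclass
class PipelineConfig:
    fastas: dict[str, str]  # marker -> FASTA path
    taxonomy: str
    backbone: str
    markers: str = "all"  # key into MARKER_COMBINATIONS
    search: SearchConfig = field(default_factory=SearchConfig)
    outdir: str = "barcomm_out"
    seed: int = 0
    spacer_rank: str = "family"

    def __post_init__(self):
        if self.markers not in MARKER_COMBINATIONS:
            raise ValueError(f"markers must be one of {sorted(MARKER_COMBINATIONS)}")
        for m in self.fastas:
            if m not in MARKERS:
                raise ValueError(f"unknown marker {m!r}")


def _stage(name):
    def wrap(fn):
        def inner(*a, **kw):
            t0 = time.perf_counter()
            try:
                out = fn(*a, **kw)
            except Exception as e:
                raise RuntimeError(f"pipeline stage {name!r} failed: {e}") from e
            logger.info("stage %s finished in %.2fs", name, time.perf_counter() - t0)
            return out
        return inner
    return wrap


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline; returns a result bundle of paths/objects."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    wanted = MARKER_COMBINATIONS[config.markers]

    taxonomy = _stage("read_taxonomy")(read_taxonomy)(config.taxonomy)
    backbone = _stage("read_backbone")(read_backbone)(config.backbone, taxonomy)

    @_stage("align")
    def _align():
        blocks = []
        for marker in wanted:
            if marker not in config.fastas:
                raise ValueError(f"marker {marker} requested but no FASTA given")
            records = read_fasta(config.fastas[marker], marker)
            reps = list(choose_species_representative(records).values())
            if marker == "rbcLa":
                blocks.append(align_coding_global(reps))
            elif marker == "matK":
                blocks.append(align_backtranslate(reps))
            else:
                blocks.extend(align_partitioned(reps, taxonomy, config.spacer_rank))
        return blocks

    blocks = _align()

    @_stage("supermatrix")
    def _matrix():
        m = assemble(blocks, taxonomy)
        export_matrix(m, outdir / "matrix.nex", "nexus")
        return m

    matrix = _matrix()

    constraint = _stage("constraint")(build_constraint)(backbone, taxonomy, matrix.species)
    constraint.write(outdir / "constraint.nwk")

    @_stage("search")
    def _search():
        ts = ratchet_search(matrix, constraint, config.search)
        for t in ts.trees:
            assert is_compatible(t, constraint)
        return ts

    treeset = _search()

    @_stage("consensus")
    def _consense():
        c = majority_consensus(treeset)
        c.write(outdir / "consensus.nwk", supports=True)
        return c

    consensus = _consense()

    @_stage("metrics")
    def _metrics():
        res = resolution_fraction(consensus)
        bins = support_bins(consensus)
        mono = {r: monophyly_report(consensus, taxonomy, r)
                for r in ("genus", "family", "order")}
        mis_n, mis = misplaced_orders(consensus, backbone, taxonomy, seed=config.seed)
        pd.DataFrame([{"resolution_pct": res, "misplaced_orders": mis_n,
                       "n_mp_trees": len(treeset), "score": treeset.score,
                       "missing_fraction": missing_fraction(matrix)}]) \
            .to_csv(outdir / "summary.csv", index=False)
        pd.DataFrame([bins.percentages]).to_csv(outdir / "support_bins.csv", index=False)
        rows = [{"rank": r, "taxon": t, "status": s}
                for r, rep in mono.items() for t, s in sorted(rep.status.items())]
        pd.DataFrame(rows).to_csv(outdir / "monophyly.csv", index=False)
        pd.DataFrame([{"misplaced": ",".join(sorted(mis))}]) \
            .to_csv(outdir / "misplaced_orders.csv", index=False)
        return {"resolution": res, "support_bins": bins, "monophyly": mono,
                "misplaced_orders": (mis_n, mis)}

    metrics = _metrics()

    manifest = {
        "barcomm_version": __version__,
        "seed": config.seed,
        "markers": config.markers,
        "search": asdict(config.search),
        "inputs": {"taxonomy": str(config.taxonomy), "backbone": str(config.backbone),
                   "fastas": {k: str(v) for k, v in sorted(config.fastas.items())}},
        "n_species": matrix.ntax,
        "n_characters": matrix.ncols,
        "missing_fraction": missing_fraction(matrix),
        "best_score": treeset.score,
        "n_best_trees": len(treeset),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")

    return {"matrix": matrix, "constraint": constraint, "treeset": treeset,
            "consensus": consensus, "metrics": metrics, "manifest": manifest,
            "outdir": str(outdir)}
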