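"""Host-taxonomy assignment of viral contigs from composition scores.

Two routes mirror the two ways a host model set can be built:

* **direct** — contigs are scored against models trained on labelled
  reference genomes and the taxonomy is read off the winning model(s);
* **transitive** — contigs are scored against models trained on large
  (>100 kb) cellular-fraction scaffolds from the same sample, and each
  scaffold's own taxonomy is first assigned by the direct route against
  the reference models.

Rather than a bare argmax, every model whose score comes within
δ · scored_positions nats of the best forms a candidate set; the
assignment is the lowest common ancestor (LCA) of the candidates' labels.
If the nearest canonically ranked ancestor of that LCA sits at rank order
or coarser, the contig is rejected as *unassigned* — a contig whose best
composition matches span several families carries no usable host signal.
δ = 0 recovers the pure argmax.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .icm import IcmModel, ModelSet, ScoreResult, score_sequence, train_icm
from .seq_io import SequenceRecord, filter_by_length
from .taxonomy import RANK_INDEX, TaxonomyTree

logger = logging.getLogger(__name__)

__all__ = [
    "AssignParams",
    "Assignment",
    "ScaffoldLink",
    "ScoreTable",
    "score_all",
    "assign_direct",
    "assign_all_direct",
    "assign_transitive",
    "aggregate_by_host",
]

REJECT_RANK_FLOOR = "order"  # LCA resolving to this rank or coarser → unassigned


@dataclass
class AssignParams:
    """Tunables of the assignment stage.

    delta is the score margin in nats per scored base defining the
    candidate set; min_contig_length is inclusive (contigs >= 5 kb),
    min_scaffold_length exclusive (scaffolds > 100 kb).
    """

    delta: float = 0.01
    min_contig_length: int = 5000
    min_scaffold_length: int = 100_000

    def __post_init__(self) -> None:
        if self.delta < 0:
            raise ValueError("delta must be >= 0")


@dataclass
class Assignment:
    contig_id: str
    status: str  # "assigned" | "unassigned"
    taxid: Optional[int]
    rank: Optional[str]
    genus_taxid: Optional[int]
    best_model_id: str
    best_score: float
    scored_positions: int
    candidate_count: int

    @property
    def assigned(self) -> bool:
        return self.status == "assigned"


@dataclass
class ScaffoldLink:
    contig_id: str
    scaffold_id: str
    score: float


@dataclass
class ScoreTable:
    """Dense contig × model log-likelihood table.

    scored/skipped position counts are model-independent (the N-skip
    pattern depends only on the contig), so they are stored once per
    contig.
    """

    loglik: pd.DataFrame  # index: contig_id, columns: model_id
    scored: pd.Series  # contig_id → scored positions
    skipped: pd.Series


def score_all(model_set: ModelSet, contigs: Sequence[SequenceRecord]) -> ScoreTable:
    """Score every contig against every model in the set."""
    if len(model_set) == 0:
        raise ConfigurationError("cannot score against an empty model set")
    model_ids = [m.model_id for m in model_set]
    rows = np.empty((len(contigs), len(model_set)))
    scored = np.empty(len(contigs), dtype=np.int64)
    skipped = np.empty(len(contigs), dtype=np.int64)
    for i, rec in enumerate(contigs):
        for j, model in enumerate(model_set):
            res = score_sequence(model, rec)
            rows[i, j] = res.log_likelihood
        scored[i] = res.scored_positions
        skipped[i] = res.skipped_positions
    ids = [r.id for r in contigs]
    return ScoreTable(
        loglik=pd.DataFrame(rows, index=ids, columns=model_ids),
        scored=pd.Series(scored, index=ids),
        skipped=pd.Series(skipped, index=ids),
    )


def _resolve(
    contig_id: str,
    candidate_taxids: list[int],
    tree: TaxonomyTree,
    best_model_id: str,
    best_score: float,
    scored_positions: int,
    candidate_count: int,
) -> Assignment:
    """LCA of candidate labels + the order-or-coarser rejection rule."""
    lca = tree.lca(candidate_taxids)
    _, rank = tree.nearest_canonical_ancestor(lca)
    reject = rank is None or RANK_INDEX[rank] <= RANK_INDEX[REJECT_RANK_FLOOR]
    if reject:
        return Assignment(
            contig_id=contig_id,
            status="unassigned",
            taxid=None,
            rank=None,
            genus_taxid=None,
            best_model_id=best_model_id,
            best_score=best_score,
            scored_positions=scored_positions,
            candidate_count=candidate_count,
        )
    return Assignment(
        contig_id=contig_id,
        status="assigned",
        taxid=lca,
        rank=rank,
        genus_taxid=tree.ancestor_at_rank(lca, "genus"),
        best_model_id=best_model_id,
        best_score=best_score,
        scored_positions=scored_positions,
        candidate_count=candidate_count,
    )


def assign_direct(
    contig_id: str,
    scores: Mapping[str, float],
    scored_positions: int,
    model_set: ModelSet,
    tree: TaxonomyTree,
    params: AssignParams,
) -> Assignment:
    """Assign one contig from its per-model score row.

    Candidates are the models within δ·scored_positions nats of the best
    score; the call is the LCA of their label taxids, rejected when it
    resolves no finer than order.  Exact ties for the best score are
    broken lexicographically by model_id for reporting only — the LCA sees
    every candidate regardless.
    """
    if len(model_set) == 0:
        raise ConfigurationError("cannot assign against an empty model set")
    labels = {m.model_id: m.label_taxid for m in model_set}
    missing = set(labels) - set(scores)
    if missing:
        raise ValueError(f"score row missing models: {sorted(missing)}")
    best_score = max(scores[mid] for mid in labels)
    best_model_id = min(
        mid for mid in labels if scores[mid] == best_score
    )
    margin = params.delta * scored_positions
    candidates = [mid for mid in labels if scores[mid] >= best_score - margin]
    cand_taxids = [labels[m] for m in candidates if labels[m] is not None]
    if not cand_taxids:
        return Assignment(
            contig_id=contig_id,
            status="unassigned",
            taxid=None,
            rank=None,
            genus_taxid=None,
            best_model_id=best_model_id,
            best_score=best_score,
            scored_positions=scored_positions,
            candidate_count=len(candidates),
        )
    return _resolve(
        contig_id,
        cand_taxids,
        tree,
        best_model_id,
        best_score,
        scored_positions,
        len(candidates),
    )


def assign_all_direct(
    table: ScoreTable,
    model_set: ModelSet,
    tree: TaxonomyTree,
    params: AssignParams,
) -> list[Assignment]:
    out = []
    for contig_id in table.loglik.index:
        row = table.loglik.loc[contig_id].to_dict()
        out.append(
            assign_direct(
                contig_id, row, int(table.scored[contig_id]), model_set, tree, params
            )
        )
    return out


def assign_transitive(
    viral_contigs: Sequence[SequenceRecord],
    scaffolds: Sequence[SequenceRecord],
    reference_models: ModelSet,
    tree: TaxonomyTree,
    params: AssignParams,
) -> tuple[list[Assignment], list[ScaffoldLink], dict[str, Assignment]]:
    """Host assignment through same-sample scaffolds.

    (a) one unlabelled ICM is trained per scaffold longer than the strict
    scaffold threshold; (b) each viral contig's candidate scaffolds are
    those within the δ margin of its best scaffold score, and the single
    best forms its :class:`ScaffoldLink`; (c) each scaffold receives its
    own taxonomy by direct assignment against the reference models;
    (d) the contig's call is the LCA of its *assigned* candidate
    scaffolds' taxids under the same rejection rule — if every candidate
    scaffold is itself unassigned, so is the contig.

    Returns (contig assignments, links, scaffold_id → scaffold assignment).
    """
    if len(reference_models) == 0:
        raise ConfigurationError("reference model set is empty")
    retained = filter_by_length(scaffolds, params.min_scaffold_length, strict=True)
    if not retained:
        raise ConfigurationError(
            f"no scaffold longer than {params.min_scaffold_length} bases; "
            "transitive assignment needs at least one"
        )
    logger.info(
        "transitive: %d/%d scaffolds pass the >%d bp filter",
        len(retained), len(scaffolds), params.min_scaffold_length,
    )
    ref = reference_models.models[0]
    scaffold_models = ModelSet(
        models=[
            train_icm([s], model_id=s.id, label_taxid=None,
                      K=ref.max_order, alpha=ref.alpha, C=ref.count_threshold)
            for s in retained
        ],
        kind="scaffold",
    )

    # (c) taxonomy of each scaffold via the direct route
    scaffold_table = score_all(reference_models, retained)
    scaffold_assignments = {
        a.contig_id: a
        for a in assign_all_direct(scaffold_table, reference_models, tree, params)
    }

    # (b) + (d)
    contig_table = score_all(scaffold_models, viral_contigs)
    assignments: list[Assignment] = []
    links: list[ScaffoldLink] = []
    for contig_id in contig_table.loglik.index:
        row = contig_table.loglik.loc[contig_id]
        scored = int(contig_table.scored[contig_id])
        best_score = float(row.max())
        best_id = min(row.index[row == best_score])
        links.append(ScaffoldLink(contig_id, best_id, best_score))
        margin = params.delta * scored
        cand_ids = list(row.index[row >= best_score - margin])
        cand_taxids = [
            scaffold_assignments[s].taxid
            for s in cand_ids
            if scaffold_assignments[s].assigned
        ]
        if not cand_taxids:
            assignments.append(
                Assignment(
                    contig_id=contig_id,
                    status="unassigned",
                    taxid=None,
                    rank=None,
                    genus_taxid=None,
                    best_model_id=best_id,
                    best_score=best_score,
                    scored_positions=scored,
                    candidate_count=len(cand_ids),
                )
            )
        else:
            assignments.append(
                _resolve(
                    contig_id, cand_taxids, tree, best_id, best_score,
                    scored, len(cand_ids),
                )
            )
    return assignments, links, scaffold_assignments


def aggregate_by_host(
    assignments: Sequence[Assignment],
    read_counts: Optional[Mapping[str, int]] = None,
    method: str = "direct",
    tree: Optional[TaxonomyTree] = None,
) -> pd.DataFrame:
    """Read-weighted host abundance: one row per predicted genus.

    Contigs missing from *read_counts* contribute one read each (with a
    warning).  Assigned contigs whose call resolved only to family level
    (no genus on the lineage) are tallied under ``assigned_above_genus``;
    rejected contigs under ``unassigned``.  Total reads are conserved.
    """
    read_counts = dict(read_counts or {})
    for cid, n in read_counts.items():
        if n < 0:
            raise ValueError(f"negative read count for contig {cid}: {n}")
    rows: dict[tuple, dict] = {}
    missing = 0
    for a in assignments:
        n_reads = read_counts.get(a.contig_id)
        if n_reads is None:
            n_reads = 1
            missing += 1
        if not a.assigned:
            key = ("unassigned", None)
        elif a.genus_taxid is None:
            key = ("assigned_above_genus", None)
        else:
            name = tree.name(a.genus_taxid) if tree is not None else ""
            key = (name or f"taxid_{a.genus_taxid}", a.genus_taxid)
        row = rows.setdefault(
            key, {"genus_name": key[0], "genus_taxid": key[1], "method": method,
                  "n_contigs": 0, "n_reads": 0}
        )
        row["n_contigs"] += 1
        row["n_reads"] += n_reads
    if missing:
        warnings.warn(
            f"{missing} contig(s) missing from read_counts; counted as 1 read each",
            stacklevel=2,
        )
    df = pd.DataFrame(
        sorted(rows.values(), key=lambda r: (-r["n_reads"], r["genus_name"])),
        columns=["genus_name", "genus_taxid", "method", "n_contigs", "n_reads"],
    )
    return df


# -- TSV writers --------------------------------------------------------


def assignments_to_frame(
    assignments: Sequence[Assignment],
    method: str,
    tree: Optional[TaxonomyTree] = None,
) -> pd.DataFrame:
    rows = []
    for a in assignments:
        genus_name = ""
        if a.genus_taxid is not None and tree is not None:
            genus_name = tree.name(a.genus_taxid)
        rows.append(
            {
                "contig_id": a.contig_id,
                "method": method,
                "status": a.status,
                "taxid": a.taxid,
                "rank": a.rank,
                "genus_taxid": a.genus_taxid,
                "genus_name": genus_name,
                "best_model_id": a.best_model_id,
                "best_score_nats": a.best_score,
                "scored_positions": a.scored_positions,
                "candidate_count": a.candidate_count,
            }
        )
    return pd.DataFrame(rows)


def links_to_frame(links: Sequence[ScaffoldLink]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"contig_id": l.contig_id, "scaffold_id": l.scaffold_id,
             "score_nats": l.score}
            for l in links
        ]
    )
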