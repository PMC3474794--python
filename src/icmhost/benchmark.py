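"""Benchmarking of host prediction on labelled virus:host pairs.

Accuracy at a rank r counts a non-rejected pair as correct when the
prediction and the true host lift to the same ancestor at rank r; pairs
whose *truth* lineage lacks rank r are excluded from that rank's
denominator, while a *prediction* lacking the rank counts as wrong.
Rejection rate (fraction of pairs called unassigned) is reported
separately, and accuracies are computed over the non-rejected pairs only.
Coarser ranks can therefore never be less accurate than finer ones on the
same result: genus agreement implies phylum agreement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import binomtest

from .assign import AssignParams, Assignment, assign_all_direct, score_all
from .errors import ConfigurationError
from .icm import ModelSet
from .seq_io import SequenceRecord, reverse_complement
from .taxonomy import CANONICAL_RANKS, TaxonomyTree

__all__ = [
    "BenchmarkPair",
    "BenchmarkResult",
    "run_benchmark",
    "evaluate_pairs",
    "random_baseline",
    "RandomBaseline",
]

LIFESTYLES = ("temperate", "lytic", "unknown")


@dataclass(frozen=True)
class BenchmarkPair:
    phage_id: str
    host_taxid: int
    lifestyle: str = "unknown"

    def __post_init__(self) -> None:
        if self.lifestyle not in LIFESTYLES:
            raise ValueError(f"lifestyle must be one of {LIFESTYLES}")


@dataclass
class BenchmarkResult:
    subset: str
    n_pairs: int
    rejection_rate: float
    accuracy: dict[str, float]  # rank → fraction over non-rejected pairs
    per_pair: pd.DataFrame

    @property
    def n_rejected(self) -> int:
        return int(round(self.n_pairs * self.rejection_rate))


def evaluate_pairs(
    pairs: Sequence[BenchmarkPair],
    assignments: Mapping[str, Assignment],
    tree: TaxonomyTree,
    subset: str = "all",
) -> BenchmarkResult:
    """Score precomputed assignments against the truth in *pairs*."""
    if not pairs:
        raise ValueError("empty benchmark pair list")
    for p in pairs:
        if p.host_taxid not in tree:
            raise ValueError(f"host taxid {p.host_taxid} absent from taxonomy")
    records = []
    for p in pairs:
        a = assignments[p.phage_id]
        row: dict = {
            "phage_id": p.phage_id,
            "lifestyle": p.lifestyle,
            "host_taxid": p.host_taxid,
            "predicted_taxid": a.taxid,
            "status": a.status,
        }
        for rank in CANONICAL_RANKS:
            truth_at = tree.ancestor_at_rank(p.host_taxid, rank)
            if not a.assigned or truth_at is None:
                row[f"correct_{rank}"] = pd.NA
            else:
                pred_at = tree.ancestor_at_rank(a.taxid, rank)
                row[f"correct_{rank}"] = bool(
                    pred_at is not None and pred_at == truth_at
                )
        records.append(row)
    per_pair = pd.DataFrame(records)
    n = len(pairs)
    n_rejected = int((per_pair["status"] == "unassigned").sum())
    accuracy = {}
    for rank in CANONICAL_RANKS:
        col = per_pair.loc[per_pair["status"] == "assigned", f"correct_{rank}"]
        col = col.dropna()
        if len(col):
            accuracy[rank] = float(col.astype(bool).mean())
    return BenchmarkResult(
        subset=subset,
        n_pairs=n,
        rejection_rate=n_rejected / n,
        accuracy=accuracy,
        per_pair=per_pair,
    )


def _has_long_exact_match(
    phage: SequenceRecord, genome_seq: str, min_match: int = 5000, block: int = None
) -> bool:
    """Exact shared substring of >= min_match bases between phage and genome
    (either strand).  Any such match fully contains an aligned block of
    min_match//2 bases starting at a multiple of min_match//2 in the phage,
    so only those blocks need to be searched."""
    block = block or min_match // 2
    targets = (genome_seq, reverse_complement(genome_seq))
    seq = phage.residues
    for start in range(0, max(1, len(seq) - block + 1), block):
        probe = seq[start : start + block]
        if len(probe) < block:
            break
        for t in targets:
            pos = t.find(probe)
            while pos != -1:
                # extend greedily in both directions
                left_p, left_t = start, pos
                while left_p > 0 and left_t > 0 and seq[left_p - 1] == t[left_t - 1]:
                    left_p -= 1
                    left_t -= 1
                right_p, right_t = start + block, pos + block
                while (
                    right_p < len(seq)
                    and right_t < len(t)
                    and seq[right_p] == t[right_t]
                ):
                    right_p += 1
                    right_t += 1
                if right_p - left_p >= min_match:
                    return True
                pos = t.find(probe, pos + 1)
    return False


def run_benchmark(
    pairs: Sequence[BenchmarkPair],
    phages: Sequence[SequenceRecord],
    model_set: ModelSet,
    tree: TaxonomyTree,
    params: AssignParams,
    subset_filter: Optional[str] = None,
    mask_self_matches: Optional[Mapping[str, str]] = None,
) -> BenchmarkResult:
    """Assign every phage by the direct route and evaluate against truth.

    subset_filter restricts the evaluation to one lifestyle tag.  When
    mask_self_matches maps model_id → training sequence, any model whose
    training genome shares an exact >=5 kb stretch with a query phage is
    excluded for that phage (guards against a prophage copy of the query
    sitting inside the reference genome).
    """
    if not pairs:
        raise ValueError("empty benchmark pair list")
    if subset_filter is not None:
        pairs = [p for p in pairs if p.lifestyle == subset_filter]
        if not pairs:
            raise ValueError(f"no pairs with lifestyle {subset_filter!r}")
    by_id = {r.id: r for r in phages}
    missing = [p.phage_id for p in pairs if p.phage_id not in by_id]
    if missing:
        raise ValueError(f"phage sequences missing: {missing}")
    queries = [by_id[p.phage_id] for p in pairs]

    from .assign import assign_direct  # local import to avoid cycle noise

    table = score_all(model_set, queries)
    assignments: dict[str, Assignment] = {}
    for p in pairs:
        rec = by_id[p.phage_id]
        row = table.loglik.loc[p.phage_id].to_dict()
        sub_set = model_set
        if mask_self_matches:
            keep = [
                m for m in model_set
                if m.model_id not in mask_self_matches
                or not _has_long_exact_match(rec, mask_self_matches[m.model_id])
            ]
            if not keep:
                raise ConfigurationError(
                    f"every model masked for phage {p.phage_id}"
                )
            sub_set = ModelSet(models=keep, kind=model_set.kind)
            row = {m.model_id: row[m.model_id] for m in keep}
        assignments[p.phage_id] = assign_direct(
            p.phage_id, row, int(table.scored[p.phage_id]), sub_set, tree, params
        )
    return evaluate_pairs(pairs, assignments, tree,
                          subset=subset_filter or "all")


@dataclass
class RandomBaseline:
    """Expected accuracy of a uniformly random genus-level assignment."""

    n_genera: int
    analytic: float
    estimate: float
    ci_low: float
    ci_high: float
    n_draws: int


def random_baseline(
    n_genera: int,
    n_draws: int = 10_000,
    seed: int = 0,
    tree: Optional[TaxonomyTree] = None,
) -> RandomBaseline:
    """Monte-Carlo check of the 1/G accuracy of random genus assignment.

    With *tree* given and n_genera None/0, G is the number of genus nodes
    in the tree.  The binomial confidence interval (95%, Clopper-Pearson)
    brackets the estimate.
    """
    if not n_genera and tree is not None:
        n_genera = len(tree.taxids_at_rank("genus"))
    if n_genera is None or n_genera < 1:
        raise ValueError("n_genera must be >= 1")
    rng = np.random.default_rng(seed)
    truth = rng.integers(0, n_genera, size=n_draws)
    pred = rng.integers(0, n_genera, size=n_draws)
    hits = int((truth == pred).sum())
    ci = binomtest(hits, n_draws).proportion_ci(confidence_level=0.95)
    return RandomBaseline(
        n_genera=n_genera,
        analytic=1.0 / n_genera,
        estimate=hits / n_draws,
        ci_low=float(ci.low),
        ci_high=float(ci.high),
        n_draws=n_draws,
    )
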