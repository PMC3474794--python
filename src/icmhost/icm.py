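"""Interpolated context models (ICMs) over the DNA alphabet.

An ICM of maximum order ``K`` holds, for every order ``k`` in ``0..K``, a
table of observed (context, next-base) counts, where the context is the
``k`` bases immediately preceding a position.  The conditional probability
of a base given its context interpolates between orders: the raw add-α
estimate at order ``k`` is blended with the (already interpolated) order
``k−1`` estimate of the context suffix,

    P_k(b | w) = λ_k(w) · P̂_k(b | w) + (1 − λ_k(w)) · P_{k−1}(b | w[1:]),

with P̂_k(b|w) = (c_k(w,b) + α) / (Σ_b' c_k(w,b') + 4α).  The weight
λ_k(w) depends on how well attested the context is: with N = Σ_b c_k(w,b),

* N ≥ C              → λ = 1 (the order-k estimate stands on its own),
* N = 0              → λ = 0 (fall back entirely to the shorter context),
* otherwise          → compare the observed next-base counts against the
  expectation N · P_{k−1}(·|w[1:]) with a chi-square statistic on 3
  degrees of freedom; with d = 1 − p-value, λ = 0 if d < 0.5, else
  λ = min(1, d · N / C).

So a context whose next-base distribution is indistinguishable from what
the shorter context already predicts contributes nothing, while a clearly
divergent context is weighted by how much evidence backs it.  This is the
interpolation scheme of the Glimmer/Phymm model family, used here as a
per-taxon genome-composition signature: one model is trained per reference
genome, per pooled taxonomic node, or per metagenomic scaffold, and query
sequences are ranked by log-likelihood.

Sequences are trained on the forward strand only; scoring evaluates both
strands and keeps the better one, so results are independent of the
(arbitrary) orientation of an assembled contig.  Any position whose base
or context window contains an N is skipped, in training and in scoring
alike — the skip pattern depends only on the query, which keeps scores
comparable across models.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy.stats import chi2 as _chi2_dist

from .errors import ConfigurationError, ModelStoreError, TrainingError
from .seq_io import SequenceRecord, reverse_complement

__all__ = [
    "IcmModel",
    "ModelSet",
    "ScoreResult",
    "train_icm",
    "conditional_probability",
    "score_sequence",
    "save_model_set",
    "load_model_set",
]

ALPHABET = "ACGT"
DEFAULT_K = 8
DEFAULT_ALPHA = 1.0
DEFAULT_C = 400

STORE_FORMAT_VERSION = 1

_ENC = np.full(256, 4, dtype=np.uint8)
for _i, _c in enumerate(ALPHABET):
    _ENC[ord(_c)] = _i

_CHI2_SF = _chi2_dist(df=3).sf


def encode(residues: str) -> np.ndarray:
    """Map residues onto integer codes A=0 C=1 G=2 T=3, anything else 4."""
    return _ENC[np.frombuffer(residues.encode("ascii"), dtype=np.uint8)]


@dataclass
class ScoreResult:
    """Log-likelihood of a record under one model (winning strand)."""

    log_likelihood: float
    scored_positions: int
    skipped_positions: int
    strand: str = "+"

    @property
    def all_skipped(self) -> bool:
        return self.scored_positions == 0


class IcmModel:
    """One trained interpolated context model.

    Parameters
    ----------
    counts:
        ``counts[k]`` is an int64 array of shape ``(4**k, 4)``: row = context
        code (base-4 encoding of the k preceding bases), column = next base.
    label_taxid:
        Taxon the training sequences belong to; None for unlabelled
        scaffold models whose taxonomy is assigned downstream.
    """

    def __init__(
        self,
        model_id: str,
        counts: Sequence[np.ndarray],
        label_taxid: Optional[int] = None,
        alpha: float = DEFAULT_ALPHA,
        count_threshold: int = DEFAULT_C,
        trained_bases: int = 0,
    ):
        if alpha <= 0:
            raise ValueError("pseudocount alpha must be positive")
        if count_threshold < 1:
            raise ValueError("count threshold C must be a positive integer")
        self.model_id = model_id
        self.label_taxid = label_taxid
        self.alpha = float(alpha)
        self.count_threshold = int(count_threshold)
        self.counts = [np.asarray(c, dtype=np.int64) for c in counts]
        for k, c in enumerate(self.counts):
            if c.shape != (4**k, 4):
                raise ValueError(f"order-{k} count table has shape {c.shape}")
            if (c < 0).any():
                raise ValueError("counts must be non-negative")
        self.trained_bases = int(trained_bases)
        # per-row context totals, reused heavily during scoring
        self._row_totals = [c.sum(axis=1) for c in self.counts]
        self._interp: Optional[list[np.ndarray]] = None
        self._log_interp: Optional[list[np.ndarray]] = None

    @property
    def max_order(self) -> int:
        return len(self.counts) - 1

    # -- interpolation ---------------------------------------------------

    @property
    def interp_tables(self) -> list[np.ndarray]:
        """Fully interpolated conditional tables, one per order.

        ``interp_tables[k][code]`` is P_k(· | w) for the context with
        base-4 code *code*.  The interpolated distribution depends only on
        the model, never on the query, so the whole hierarchy is resolved
        bottom-up once: the order-(k−1) table gathered at each context's
        suffix supplies both the fallback distribution and the chi-square
        expectation for λ.
        """
        if self._interp is None:
            alpha = self.alpha
            C = self.count_threshold
            tables: list[np.ndarray] = []
            for k in range(self.max_order + 1):
                ck = self.counts[k].astype(np.float64)
                nk = self._row_totals[k].astype(np.float64)
                raw = (ck + alpha) / (nk[:, None] + 4 * alpha)
                if k == 0:
                    tables.append(raw)
                    continue
                # suffix code of context `code` is code % 4**(k-1): the
                # lower table simply tiles 4x along the context axis
                lower = np.tile(tables[k - 1], (4, 1))
                lam = np.zeros(ck.shape[0])
                full = nk >= C
                lam[full] = 1.0
                partial = (~full) & (nk > 0)
                if partial.any():
                    expected = nk[partial, None] * lower[partial]
                    stat = (((ck[partial] - expected) ** 2) / expected).sum(axis=1)
                    d = 1.0 - _CHI2_SF(stat)
                    lam[partial] = np.where(
                        d < 0.5, 0.0, np.minimum(1.0, d * nk[partial] / C)
                    )
                tables.append(lam[:, None] * raw + (1.0 - lam[:, None]) * lower)
            self._interp = tables
        return self._interp

    @property
    def log_interp_tables(self) -> list[np.ndarray]:
        if self._log_interp is None:
            self._log_interp = [np.log(t) for t in self.interp_tables]
        return self._log_interp

    def _dist(self, k: int, code: int) -> np.ndarray:
        """Interpolated next-base distribution for one order-k context."""
        return self.interp_tables[k][code]


def conditional_probability(model: IcmModel, context: str, base: str) -> float:
    """P(base | context) under the interpolated model.

    *context* may be any length from 0 to the model's max order.
    """
    if len(base) != 1 or base not in ALPHABET:
        raise ValueError(f"base must be one of {ALPHABET}: {base!r}")
    if any(ch not in ALPHABET for ch in context):
        raise ValueError(f"context must be over {ALPHABET}: {context!r}")
    k = len(context)
    if k > model.max_order:
        raise ValueError(f"context longer than model order {model.max_order}")
    code = 0
    for ch in context:
        code = code * 4 + ALPHABET.index(ch)
    return float(model._dist(k, code)[ALPHABET.index(base)])


# -- training -----------------------------------------------------------


def _context_codes(clamped: np.ndarray, k: int) -> np.ndarray:
    """Base-4 codes of the k bases preceding positions k..n-1.

    ``clamped`` must already have N replaced by 0; validity is masked
    separately by the caller.
    """
    n = clamped.shape[0]
    codes = np.zeros(n - k, dtype=np.int64)
    for j in range(k):
        codes = codes * 4 + clamped[j : n - k + j]
    return codes


def _window_valid(invalid_prefix: np.ndarray, k: int, n: int) -> np.ndarray:
    """For positions k..n-1: True when the (k+1)-base window ending at the
    position contains no N.  ``invalid_prefix`` is the cumulative count of
    invalid bases, length n+1."""
    return (invalid_prefix[k + 1 :] - invalid_prefix[: n - k]) == 0


def train_icm(
    records: Iterable[SequenceRecord],
    model_id: str,
    label_taxid: Optional[int] = None,
    K: int = DEFAULT_K,
    alpha: float = DEFAULT_ALPHA,
    C: int = DEFAULT_C,
) -> IcmModel:
    """Train one ICM on the forward strands of *records*.

    Every position i of every record with a fully unambiguous window
    increments the order-k table for each k in 0..min(i, K); windows
    containing N contribute nothing.  Raises :class:`TrainingError` when
    the input contains no usable base at all.
    """
    if K < 0:
        raise ValueError("max order K must be >= 0")
    counts = [np.zeros((4**k, 4), dtype=np.int64) for k in range(K + 1)]
    trained = 0
    for rec in records:
        enc = encode(rec.residues)
        n = enc.shape[0]
        clamped = np.where(enc < 4, enc, 0).astype(np.int64)
        invalid_prefix = np.concatenate(([0], np.cumsum(enc >= 4)))
        for k in range(min(K, n - 1) + 1):
            valid = _window_valid(invalid_prefix, k, n)
            keys = _context_codes(clamped, k) * 4 + clamped[k:]
            binned = np.bincount(keys[valid], minlength=4 ** (k + 1))
            counts[k] += binned.reshape(4**k, 4)
            if k == 0:
                trained += int(valid.sum())
    if trained == 0:
        raise TrainingError(
            f"model {model_id!r}: no usable (non-N) training bases"
        )
    return IcmModel(
        model_id=model_id,
        counts=counts,
        label_taxid=label_taxid,
        alpha=alpha,
        count_threshold=C,
        trained_bases=trained,
    )


# -- scoring ------------------------------------------------------------


def _score_strand(model: IcmModel, enc: np.ndarray) -> tuple[float, int, int]:
    n = enc.shape[0]
    if n == 0:
        return 0.0, 0, 0
    K = model.max_order
    valid_base = enc < 4
    invalid_prefix = np.concatenate(([0], np.cumsum(~valid_base)))
    # position i is scored iff the window of its min(i, K)-context plus the
    # base itself is N-free
    idx = np.arange(n)
    k_eff = np.minimum(idx, K)
    start = idx - k_eff
    window_ok = (invalid_prefix[idx + 1] - invalid_prefix[start]) == 0
    if not window_ok.any():
        return 0.0, 0, n
    logt = model.log_interp_tables
    clamped = np.where(valid_base, enc, 0).astype(np.int64)
    logl = 0.0
    # order ramp: position i < K uses its full i-base context
    for i in range(min(K, n)):
        if window_ok[i]:
            code = 0
            for j in range(i):
                code = code * 4 + int(clamped[j])
            logl += float(logt[i][code, clamped[i]])
    # bulk: positions K..n-1 all use order K
    if n > K:
        codes = _context_codes(clamped, K)  # positions K..n-1
        ok = window_ok[K:]
        logl += float(logt[K][codes[ok], clamped[K:][ok]].sum())
    scored = int(window_ok.sum())
    return logl, scored, n - scored


def score_sequence(model: IcmModel, record: SequenceRecord) -> ScoreResult:
    """Log-likelihood of *record* under *model*, max over both strands.

    Positions whose base or preceding context window contains N are
    skipped on each strand; an all-N record scores 0 with zero scored
    positions.  Skip counts depend only on the record, never the model.
    """
    enc_f = encode(record.residues)
    lf, sf, kf = _score_strand(model, enc_f)
    enc_r = encode(reverse_complement(record.residues))
    lr, sr, kr = _score_strand(model, enc_r)
    if lr > lf:
        return ScoreResult(lr, sr, kr, strand="-")
    return ScoreResult(lf, sf, kf, strand="+")


# -- model sets and persistence -----------------------------------------


@dataclass
class ModelSet:
    """A scoring-comparable collection of ICMs sharing K, α and C."""

    models: list[IcmModel]
    kind: str = "reference"  # or "scaffold"

    def __post_init__(self) -> None:
        ids = [m.model_id for m in self.models]
        if len(set(ids)) != len(ids):
            raise ValueError("model_ids must be unique within a set")
        if self.models:
            K = self.models[0].max_order
            a = self.models[0].alpha
            C = self.models[0].count_threshold
            for m in self.models:
                if (m.max_order, m.alpha, m.count_threshold) != (K, a, C):
                    raise ValueError(
                        "all models in a set must share K, alpha and C "
                        "for scores to be comparable"
                    )

    def __len__(self) -> int:
        return len(self.models)

    def __iter__(self):
        return iter(self.models)

    def by_id(self, model_id: str) -> IcmModel:
        for m in self.models:
            if m.model_id == model_id:
                return m
        raise KeyError(model_id)

    @property
    def K(self) -> int:
        if not self.models:
            raise ConfigurationError("empty model set has no shared K")
        return self.models[0].max_order


def save_model_set(model_set: ModelSet, directory: str | os.PathLike) -> None:
    """Persist a model set: a JSON manifest plus one .npz of count tables
    per model.  The format is versioned; loading checks the version."""
    os.makedirs(directory, exist_ok=True)
    manifest = {
        "format_version": STORE_FORMAT_VERSION,
        "kind": model_set.kind,
        "K": model_set.models[0].max_order if model_set.models else None,
        "alpha": model_set.models[0].alpha if model_set.models else None,
        "C": model_set.models[0].count_threshold if model_set.models else None,
        "models": [],
    }
    for i, m in enumerate(model_set.models):
        fname = f"model_{i:05d}.npz"
        np.savez_compressed(
            os.path.join(directory, fname),
            **{f"order_{k}": m.counts[k] for k in range(m.max_order + 1)},
        )
        manifest["models"].append(
            {
                "model_id": m.model_id,
                "label_taxid": m.label_taxid,
                "trained_bases": m.trained_bases,
                "file": fname,
            }
        )
    with open(os.path.join(directory, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1)


def load_model_set(directory: str | os.PathLike) -> ModelSet:
    manifest_path = os.path.join(directory, "manifest.json")
    if not os.path.exists(manifest_path):
        raise ModelStoreError(f"no manifest.json in {directory}")
    try:
        with open(manifest_path) as fh:
            manifest = json.load(fh)
    except (json.JSONDecodeError, OSError) as exc:
        raise ModelStoreError(f"corrupt manifest in {directory}: {exc}") from exc
    version = manifest.get("format_version")
    if version != STORE_FORMAT_VERSION:
        raise ModelStoreError(
            f"model store version {version!r} incompatible with "
            f"supported version {STORE_FORMAT_VERSION}"
        )
    models = []
    for entry in manifest["models"]:
        path = os.path.join(directory, entry["file"])
        try:
            with np.load(path) as npz:
                K = len(npz.files) - 1
                counts = [npz[f"order_{k}"] for k in range(K + 1)]
        except Exception as exc:
            raise ModelStoreError(
                f"corrupt model file {entry['file']}: {exc}"
            ) from exc
        models.append(
            IcmModel(
                model_id=entry["model_id"],
                counts=counts,
                label_taxid=entry["label_taxid"],
                alpha=manifest["alpha"],
                count_threshold=manifest["C"],
                trained_bases=entry["trained_bases"],
            )
        )
    return ModelSet(models=models, kind=manifest.get("kind", "reference"))


# -- higher-level training helpers --------------------------------------


def train_model_set(
    labelled_records: Sequence[tuple[SequenceRecord, Optional[int]]],
    kind: str = "reference",
    pooling: str = "genome",
    pool_rank: Optional[str] = None,
    tree=None,
    K: int = DEFAULT_K,
    alpha: float = DEFAULT_ALPHA,
    C: int = DEFAULT_C,
) -> ModelSet:
    """Train a model set from (record, taxid) pairs.

    pooling="genome" trains one model per record (model_id = record id);
    pooling="node" pools records sharing a label taxid into one model per
    taxon.  With *pool_rank* set (e.g. "genus"), labels are first lifted
    to their ancestor at that rank (records whose lineage lacks the rank
    keep their own label), which yields the one-model-per-taxonomic-node
    granularity at a chosen level.
    """
    if pooling not in ("genome", "node"):
        raise ValueError("pooling must be 'genome' or 'node'")
    if pool_rank is not None and tree is None:
        raise ValueError("pool_rank requires a taxonomy tree")

    def lift(taxid: Optional[int]) -> Optional[int]:
        if taxid is None or pool_rank is None:
            return taxid
        anc = tree.ancestor_at_rank(taxid, pool_rank)
        return anc if anc is not None else taxid

    models = []
    if pooling == "genome":
        for rec, taxid in labelled_records:
            models.append(
                train_icm([rec], model_id=rec.id, label_taxid=lift(taxid),
                          K=K, alpha=alpha, C=C)
            )
    else:
        groups: dict[Optional[int], list[SequenceRecord]] = {}
        for rec, taxid in labelled_records:
            groups.setdefault(lift(taxid), []).append(rec)
        for taxid in sorted(groups, key=lambda t: (t is None, t)):
            recs = groups[taxid]
            model_id = f"taxon_{taxid}" if taxid is not None else "unlabelled"
            models.append(
                train_icm(recs, model_id=model_id, label_taxid=taxid,
                          K=K, alpha=alpha, C=C)
            )
    return ModelSet(models=models, kind=kind)
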