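"""One-vs-rest Bayesian-style classification of peptides into the eight
secondary-structure classes.

A record is a (descriptor set, label set) pair; a peptide labelled with
several classes is a positive example for each of them and a negative for
all others.  Per class, training accumulates

    n      — number of records
    n_a    — records positive for the class
    n_d[d] — records containing descriptor d
    n_ad[d]— positive records containing d

and the evidence score of a query descriptor set D is the mean shrunken
log-odds surrogate

    B = (1/|D|) * sum_{d in D} (2*p_hat(a|d) - 1),
    p_hat(a|d) = (n_ad[d] + c*p0) / (n_d[d] + c),   p0 = n_a / n,

so B lies in [-1, 1] and descriptors unseen in training contribute 0
relative to the prior.  Pa and Pi are read off the empirical distribution
functions of leave-one-out training scores of positives and negatives
(ties counted 1/2); a class is "possible" when Pa > Pi.  Leave-one-out is
exact count-decrement, identical to retraining without the record.
Accuracy is summarized as ROC AUC in the Mann-Whitney form.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Collection, Iterable, Mapping, Sequence

import numpy as np

from . import mna, peptide_chem

__all__ = [
    "SSP_CLASSES",
    "ClassStats",
    "ClassPrediction",
    "SSPRModel",
    "UntrainableClassWarning",
    "train",
    "score",
    "pa_pi",
    "predict",
    "loo_scores",
    "auc",
    "evaluate_levels",
    "LevelEvaluation",
    "save_model",
    "load_model",
]

#: The eight modelled classes; the β-bridge state B is excluded.
SSP_CLASSES: tuple[str, ...] = ("H", "G", "I", "P", "E", "C", "T", "S")

MODEL_FORMAT = "sspkit-model"
MODEL_FORMAT_VERSION = 1


class UntrainableClassWarning(UserWarning):
    """A class with no positive or no negative records was dropped."""


Record = tuple[Collection[str], Collection[str]]  # (descriptors, labels)


@dataclass
class ClassStats:
    """Descriptor count statistics for a single one-vs-rest problem."""

    n: int
    n_a: int
    n_d: Mapping[str, int]
    n_ad: Mapping[str, int]

    def score(self, descriptors: Collection[str], c: float) -> float:
        if not descriptors:
            raise ValueError("empty descriptor set")
        p0 = self.n_a / self.n
        total = 0.0
        for d in descriptors:
            nd = self.n_d.get(d, 0)
            nad = self.n_ad.get(d, 0)
            total += 2.0 * (nad + c * p0) / (nd + c) - 1.0
        return total / len(descriptors)


@dataclass(frozen=True)
class ClassPrediction:
    b: float
    pa: float
    pi: float

    @property
    def delta(self) -> float:
        return self.pa - self.pi

    @property
    def possible(self) -> bool:
        return self.pa > self.pi


@dataclass
class SSPRModel:
    """Trained per-class counts plus LOO training-score distributions."""

    level: int
    c: float
    stats: dict[str, ClassStats]
    pos_scores: dict[str, np.ndarray]  # sorted ascending
    neg_scores: dict[str, np.ndarray]  # sorted ascending
    meta: dict = field(default_factory=dict)

    @property
    def classes(self) -> tuple[str, ...]:
        return tuple(k for k in SSP_CLASSES if k in self.stats)

    def predict_descriptors(self, descriptors: Collection[str]) -> dict[str, ClassPrediction]:
        return predict(self, descriptors)

    def predict_sequence(self, sequence: str) -> dict[str, ClassPrediction]:
        graph = peptide_chem.build_peptide_graph(sequence)
        dset = mna.descriptor_set(graph, self.level)
        return predict(self, dset.descriptors)

    def window_deltas(self, sequence: str) -> dict[str, float]:
        """Pa - Pi per class for one subsequence (sliding-window protocol)."""
        return {k: p.delta for k, p in self.predict_sequence(sequence).items()}


def _descriptors_of(record: Record) -> frozenset[str]:
    dset = record[0]
    if isinstance(dset, mna.DescriptorSet):
        return dset.descriptors
    return frozenset(dset)


def _base_counts(records: Sequence[Record]) -> tuple[int, dict[str, int]]:
    n_d: dict[str, int] = {}
    for rec in records:
        for d in _descriptors_of(rec):
            n_d[d] = n_d.get(d, 0) + 1
    return len(records), n_d


def _class_counts(records: Sequence[Record], cls: str) -> tuple[int, dict[str, int]]:
    n_a = 0
    n_ad: dict[str, int] = {}
    for rec in records:
        if cls in rec[1]:
            n_a += 1
            for d in _descriptors_of(rec):
                n_ad[d] = n_ad.get(d, 0) + 1
    return n_a, n_ad


def score(model: SSPRModel, descriptors: Collection[str], cls: str) -> float:
    """Evidence score B of a descriptor set for one class."""
    if cls not in model.stats:
        raise KeyError(f"class {cls!r} not trainable in this model")
    if isinstance(descriptors, mna.DescriptorSet):
        descriptors = descriptors.descriptors
    return model.stats[cls].score(descriptors, model.c)


def pa_pi(model: SSPRModel, descriptors: Collection[str], cls: str) -> tuple[float, float]:
    """Empirical (Pa, Pi) for one class.

    Pa is the fraction of positive LOO training scores strictly below B and
    Pi the fraction of negative scores strictly above B, ties weighted 1/2.
    Both are monotone in B by construction.
    """
    b = score(model, descriptors, cls)
    return _pa_of(model.pos_scores[cls], b), _pi_of(model.neg_scores[cls], b)


def _pa_of(sorted_pos: np.ndarray, b: float) -> float:
    lo = np.searchsorted(sorted_pos, b, side="left")
    hi = np.searchsorted(sorted_pos, b, side="right")
    return float((lo + 0.5 * (hi - lo)) / len(sorted_pos))


def _pi_of(sorted_neg: np.ndarray, b: float) -> float:
    lo = np.searchsorted(sorted_neg, b, side="left")
    hi = np.searchsorted(sorted_neg, b, side="right")
    return float(((len(sorted_neg) - hi) + 0.5 * (hi - lo)) / len(sorted_neg))


def predict(model: SSPRModel, descriptors: Collection[str]) -> dict[str, ClassPrediction]:
    """Per-class (B, Pa, Pi) for a descriptor set; untrainable classes absent."""
    if isinstance(descriptors, mna.DescriptorSet):
        descriptors = descriptors.descriptors
    out: dict[str, ClassPrediction] = {}
    for cls in model.classes:
        b = model.stats[cls].score(descriptors, model.c)
        out[cls] = ClassPrediction(
            b, _pa_of(model.pos_scores[cls], b), _pi_of(model.neg_scores[cls], b)
        )
    return out


def loo_scores(
    records: Sequence[Record], cls: str, c: float = 1.0
) -> list[tuple[float, bool]]:
    """Leave-one-out score of every record for one class.

    Record i is scored against counts with its own contributions removed
    (n, n_a, n_d, n_ad all decremented), which equals retraining without it.
    """
    if len(records) < 2:
        raise ValueError("need at least 2 records for leave-one-out scoring")
    n, n_d = _base_counts(records)
    n_a, n_ad = _class_counts(records, cls)
    out: list[tuple[float, bool]] = []
    for rec in records:
        dset = _descriptors_of(rec)
        if not dset:
            raise ValueError("record with empty descriptor set")
        positive = cls in rec[1]
        n_loo = n - 1
        n_a_loo = n_a - (1 if positive else 0)
        p0 = n_a_loo / n_loo
        total = 0.0
        for d in dset:
            nd = n_d[d] - 1
            nad = n_ad.get(d, 0) - (1 if positive else 0)
            total += 2.0 * (nad + c * p0) / (nd + c) - 1.0
        out.append((total / len(dset), positive))
    return out


def train(
    records: Sequence[Record],
    level: int,
    c: float = 1.0,
    meta: Mapping | None = None,
) -> SSPRModel:
    """Fit per-class count statistics and LOO score distributions.

    Classes with no positive or no negative record are dropped with an
    :class:`UntrainableClassWarning` instead of failing.
    """
    if len(records) < 2:
        raise ValueError("need at least 2 training records")
    if c <= 0:
        raise ValueError(f"smoothing constant must be positive, got {c}")
    n, n_d = _base_counts(records)
    stats: dict[str, ClassStats] = {}
    pos_scores: dict[str, np.ndarray] = {}
    neg_scores: dict[str, np.ndarray] = {}
    for cls in SSP_CLASSES:
        n_a, n_ad = _class_counts(records, cls)
        if n_a == 0 or n_a == n:
            warnings.warn(
                f"class {cls!r} has {n_a} positives out of {n} records; dropped",
                UntrainableClassWarning,
                stacklevel=2,
            )
            continue
        stats[cls] = ClassStats(n=n, n_a=n_a, n_d=n_d, n_ad=n_ad)
        scored = loo_scores(records, cls, c)
        pos = np.sort([s for s, is_pos in scored if is_pos])
        neg = np.sort([s for s, is_pos in scored if not is_pos])
        pos_scores[cls] = pos
        neg_scores[cls] = neg
    return SSPRModel(
        level=level,
        c=c,
        stats=stats,
        pos_scores=pos_scores,
        neg_scores=neg_scores,
        meta=dict(meta or {}),
    )


def auc(scores: Iterable[tuple[float, bool]]) -> float:
    """ROC AUC in Mann-Whitney form: P(random positive outscores a random
    negative), ties counted 1/2."""
    pairs = list(scores)
    s = np.asarray([p[0] for p in pairs], dtype=float)
    y = np.asarray([bool(p[1]) for p in pairs])
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: need at least one positive and one negative")
    _, inverse, counts = np.unique(s, return_inverse=True, return_counts=True)
    # midrank of each unique value (1-based)
    csum = np.cumsum(counts)
    midrank = csum - (counts - 1) / 2.0
    ranks = midrank[inverse]
    rank_sum_pos = float(ranks[y].sum())
    return (rank_sum_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


@dataclass(frozen=True)
class LevelEvaluation:
    per_class: dict[str, float]
    mean_auc: float


def evaluate_levels(
    records: Sequence[tuple[str, Collection[str]]],
    levels: Sequence[int],
    c: float = 1.0,
) -> dict[int, LevelEvaluation]:
    """LOO AUC per class and unweighted mean, at each descriptor level.

    ``records`` are (sequence, label set) pairs; descriptor sets are
    regenerated from the peptide graphs at every level.  Untrainable
    classes are absent from the per-class maps.
    """
    if not levels:
        raise ValueError("no levels given")
    graphs = [peptide_chem.build_peptide_graph(seq) for seq, _ in records]
    per_graph = [mna.descriptor_sets_by_level(g, list(levels)) for g in graphs]
    out: dict[int, LevelEvaluation] = {}
    for lvl in levels:
        lvl_records = [
            (per_graph[i][lvl].descriptors, labels)
            for i, (_, labels) in enumerate(records)
        ]
        per_class: dict[str, float] = {}
        for cls in SSP_CLASSES:
            n_a = sum(1 for _, labels in lvl_records if cls in labels)
            if n_a == 0 or n_a == len(lvl_records):
                continue
            per_class[cls] = auc(loo_scores(lvl_records, cls, c))
        if not per_class:
            raise ValueError("no trainable class at level " + str(lvl))
        out[lvl] = LevelEvaluation(per_class, float(np.mean(list(per_class.values()))))
    return out


# ---------------------------------------------------------------------------
# Portable model serialization (versioned JSON)


def save_model(model: SSPRModel, sink: str | Path) -> None:
    classes = {}
    for cls in model.classes:
        st = model.stats[cls]
        classes[cls] = {
            "n_a": st.n_a,
            "n_ad": dict(st.n_ad),
            "pos_scores": [float(x) for x in model.pos_scores[cls]],
            "neg_scores": [float(x) for x in model.neg_scores[cls]],
        }
    first = next(iter(model.stats.values()), None)
    payload = {
        "format": MODEL_FORMAT,
        "version": MODEL_FORMAT_VERSION,
        "level": model.level,
        "c": model.c,
        "n": first.n if first else 0,
        "n_d": dict(first.n_d) if first else {},
        "meta": model.meta,
        "classes": classes,
    }
    with open(sink, "w") as fh:
        json.dump(payload, fh)


def load_model(source: str | Path) -> SSPRModel:
    with open(source) as fh:
        payload = json.load(fh)
    if payload.get("format") != MODEL_FORMAT:
        raise ValueError(f"not a {MODEL_FORMAT} file: {source}")
    if payload.get("version") != MODEL_FORMAT_VERSION:
        raise ValueError(f"unsupported model version {payload.get('version')!r}")
    n, n_d = payload["n"], payload["n_d"]
    stats, pos, neg = {}, {}, {}
    for cls, blob in payload["classes"].items():
        stats[cls] = ClassStats(n=n, n_a=blob["n_a"], n_d=n_d, n_ad=blob["n_ad"])
        pos[cls] = np.asarray(blob["pos_scores"], dtype=float)
        neg[cls] = np.asarray(blob["neg_scores"], dtype=float)
    return SSPRModel(
        level=payload["level"],
        c=payload["c"],
        stats=stats,
        pos_scores=pos,
        neg_scores=neg,
        meta=payload.get("meta", {}),
    )
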