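"""Cross-property relabeling and the delayed-match-to-sample estimator.

The transfer protocol: project samples into a subspace trained on one
facial property, replace the evaluation labels by a *different*
property's labels (the coordinates stay untouched), then score how well
the new labeling clusters in that space with a two-alternative
delayed-match-to-sample (DMS) rule: a probe is correct when it lies
nearer (Euclidean) to a reference of its own class than to a reference
of another class.

Trial enumeration: every triple ``(ref_a, ref_b, probe)`` with
``class(ref_a) != class(ref_b)``, ``probe`` a distinct sample whose class
is one of the two.  Exhaustive enumeration is used when the triple count
fits under ``max_trials``; otherwise triples are drawn uniformly at
random (seeded).  Exact distance ties count as incorrect.
"""
from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist

from .subspace import ProjectedSet

__all__ = [
    "PerformanceRecord",
    "relabel",
    "dms_trial",
    "dms_performance",
    "count_dms_trials",
]

logger = logging.getLogger(__name__)

PROPERTIES = ("identity", "sex", "race", "expression")


@dataclass(frozen=True)
class PerformanceRecord:
    """Percent-correct DMS performance for one evaluation."""

    percent_correct: float
    n_trials: int
    n_correct: int
    mode: str  # "exhaustive" | "sampled"

    def __post_init__(self):
        if self.n_trials <= 0:
            raise ValueError("n_trials must be positive")


def relabel(
    pset: ProjectedSet,
    labels: pd.DataFrame,
    new_property: str,
) -> ProjectedSet:
    """Return a ProjectedSet with identical coordinates but evaluation
    labels taken from ``labels[new_property]`` (row-aligned with the
    projected samples).  ``source_property`` is retained for provenance."""
    if new_property not in PROPERTIES:
        raise ValueError(
            f"unknown property {new_property!r}; expected one of {PROPERTIES}"
        )
    if new_property not in labels.columns:
        raise ValueError(f"label table has no column {new_property!r}")
    if len(labels) != pset.n_samples:
        raise ValueError("label table row count != projected sample count")
    new_labels = labels[new_property].to_numpy()
    if len(np.unique(new_labels)) < 2:
        raise ValueError(
            f"property {new_property!r} has fewer than 2 distinct labels"
        )
    return ProjectedSet(
        coordinates=pset.coordinates,
        eval_labels=new_labels,
        source_property=pset.source_property,
    )


def dms_trial(
    ref_a: np.ndarray,
    label_a,
    ref_b: np.ndarray,
    label_b,
    probe: np.ndarray,
    probe_label,
) -> int:
    """One DMS trial: 1 if the probe is strictly nearer to the reference
    of its own class, else 0 (ties are incorrect)."""
    if label_a == label_b:
        raise ValueError("reference classes must differ")
    if probe_label == label_a:
        same, other = ref_a, ref_b
    elif probe_label == label_b:
        same, other = ref_b, ref_a
    else:
        raise ValueError(
            f"probe class {probe_label!r} is neither {label_a!r} nor {label_b!r}"
        )
    d_same = np.linalg.norm(np.asarray(probe, float) - np.asarray(same, float))
    d_other = np.linalg.norm(np.asarray(probe, float) - np.asarray(other, float))
    return int(d_same < d_other)


def _usable_classes(labels: np.ndarray) -> list:
    classes, counts = np.unique(labels, return_counts=True)
    dropped = [c for c, n in zip(classes, counts) if n < 2]
    if dropped:
        logger.warning(
            "DMS: excluding %d class(es) with < 2 samples: %s",
            len(dropped),
            [str(c) for c in dropped[:10]],
        )
    usable = [c for c, n in zip(classes, counts) if n >= 2]
    if len(usable) < 2:
        raise ValueError("fewer than 2 evaluation classes with >= 2 samples")
    return usable


def count_dms_trials(labels: np.ndarray) -> int:
    """Number of valid (ref pair, probe) triples over usable classes."""
    labels = np.asarray(labels)
    usable = _usable_classes(labels)
    counts = {c: int(np.sum(labels == c)) for c in usable}
    total = 0
    for ca, cb in itertools.combinations(usable, 2):
        na, nb = counts[ca], counts[cb]
        total += na * nb * (na - 1) + nb * na * (nb - 1)
    return total


def dms_performance(
    pset: ProjectedSet,
    mode: str = "auto",
    max_trials: int = 100_000,
    seed: int = 0,
) -> PerformanceRecord:
    """Percent-correct DMS score over (ref pair, probe) triples.

    mode:
        "exhaustive" - enumerate every valid triple;
        "sampled"    - draw ``max_trials`` triples uniformly (seeded);
        "auto"       - exhaustive when the triple count <= ``max_trials``.
    Classes with fewer than 2 samples are excluded (logged warning).
    """
    if mode not in ("auto", "exhaustive", "sampled"):
        raise ValueError(f"unknown mode {mode!r}")
    labels = np.asarray(pset.eval_labels)
    usable = _usable_classes(labels)
    keep = np.isin(labels, np.asarray(usable, dtype=labels.dtype))
    x = pset.coordinates[keep]
    lab = labels[keep]
    dist = squareform(pdist(x))
    idx = {c: np.flatnonzero(lab == c) for c in usable}

    total = count_dms_trials(labels)
    if mode == "auto":
        mode = "exhaustive" if total <= max_trials else "sampled"

    if mode == "exhaustive":
        n_correct = 0
        for ca, cb in itertools.combinations(usable, 2):
            ia, ib = idx[ca], idx[cb]
            n_correct += _exhaustive_side(dist, ia, ib)
            n_correct += _exhaustive_side(dist, ib, ia)
        return PerformanceRecord(
            percent_correct=100.0 * n_correct / total,
            n_trials=total,
            n_correct=n_correct,
            mode="exhaustive",
        )

    # sampled: stratify by (class pair, probe side), weights = triple counts
    rng = np.random.default_rng(seed)
    strata = []
    weights = []
    for ca, cb in itertools.combinations(usable, 2):
        ia, ib = idx[ca], idx[cb]
        strata.append((ia, ib))  # probe from ca
        weights.append(len(ia) * (len(ia) - 1) * len(ib))
        strata.append((ib, ia))  # probe from cb
        weights.append(len(ib) * (len(ib) - 1) * len(ia))
    weights = np.asarray(weights, dtype=float)
    draws = rng.multinomial(max_trials, weights / weights.sum())
    n_correct = 0
    for (iprobe_pool, iother_pool), t in zip(strata, draws):
        if t == 0:
            continue
        na = len(iprobe_pool)
        probe_pos = rng.integers(0, na, t)
        same_pos = rng.integers(0, na - 1, t)
        same_pos = same_pos + (same_pos >= probe_pos)  # exclude probe itself
        other_pos = rng.integers(0, len(iother_pool), t)
        p = iprobe_pool[probe_pos]
        s = iprobe_pool[same_pos]
        o = iother_pool[other_pos]
        n_correct += int(np.sum(dist[p, s] < dist[p, o]))
    return PerformanceRecord(
        percent_correct=100.0 * n_correct / max_trials,
        n_trials=max_trials,
        n_correct=n_correct,
        mode="sampled",
    )


def _exhaustive_side(dist: np.ndarray, ia: np.ndarray, ib: np.ndarray) -> int:
    """Correct-trial count with probes from class A (index set ``ia``),
    same-class refs from A \\ {probe}, other refs from B."""
    n_correct = 0
    d_ab = dist[np.ix_(ia, ib)]          # (na, nb)
    d_aa = dist[np.ix_(ia, ia)]          # (na, na)
    na = len(ia)
    for r in range(na):
        same = np.delete(d_aa[r], r)     # distances probe -> own-class refs
        n_correct += int(np.sum(same[:, None] < d_ab[r][None, :]))
    return n_correct
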