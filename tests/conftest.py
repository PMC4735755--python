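"""Shared fixtures and independent oracles for the test suite."""
import itertools

import numpy as np
import pandas as pd
import pytest

from facespace import (
    AttributeSpec,
    FaceRenderer,
    ProjectedSet,
    make_identity_bank,
    render_expression_dataset,
    render_invariant_dataset,
)


@pytest.fixture(scope="session")
def renderer():
    return FaceRenderer(seed=7)


@pytest.fixture(scope="session")
def small_invariant_set(renderer):
    """12 identities (balanced sex x race) at the five standard viewpoints."""
    spec = AttributeSpec(n_identities=12)
    bank = make_identity_bank(spec, seed=11)
    return render_invariant_dataset(bank, noise_sd=0.02, seed=11, renderer=renderer)


@pytest.fixture(scope="session")
def small_expression_set(renderer):
    """8 identities (half female, one race) with all six expressions."""
    spec = AttributeSpec(n_identities=8, race_levels=("asian",), viewpoints=(0.0,))
    bank = make_identity_bank(spec, seed=13)
    return render_expression_dataset(bank, kappa=0.0, noise_sd=0.02, seed=13,
                                     renderer=renderer)


def make_pset(coords, labels, source="identity"):
    return ProjectedSet(
        coordinates=np.asarray(coords, dtype=float),
        eval_labels=np.asarray(labels),
        source_property=source,
    )


def dms_oracle(coords, labels):
    """Independent brute-force DMS enumeration: plain loops over every
    (ref_a, ref_b, probe) triple with distinct reference classes and a
    probe (distinct sample) from one of the two.  Ties are incorrect."""
    coords = np.asarray(coords, dtype=float)
    labels = np.asarray(labels)
    # classes with < 2 samples cannot supply (probe, same-ref) pairs
    usable = [c for c in np.unique(labels) if np.sum(labels == c) >= 2]
    idx = {c: np.flatnonzero(labels == c) for c in usable}
    n_correct = 0
    n_trials = 0
    for ca, cb in itertools.combinations(usable, 2):
        for probe_cls, other_cls in ((ca, cb), (cb, ca)):
            for p in idx[probe_cls]:
                for same in idx[probe_cls]:
                    if same == p:
                        continue
                    for other in idx[other_cls]:
                        d_same = np.linalg.norm(coords[p] - coords[same])
                        d_other = np.linalg.norm(coords[p] - coords[other])
                        n_correct += int(d_same < d_other)
                        n_trials += 1
    return n_correct, n_trials


def ks_oracle(within, between):
    """Independent one-sided two-sample KS via explicit ECDF evaluation:
    D+ = max over pooled points of [ECDF_within - ECDF_between], with the
    one-sided asymptotic p-value exp(-2 z^2) refined by Hodges' (1958)
    Eqn 5.3 correction, z = sqrt(n_eff) D, m the larger sample size."""
    within = np.sort(np.asarray(within, dtype=float))
    between = np.sort(np.asarray(between, dtype=float))
    pooled = np.concatenate([within, between])
    cdf_w = np.searchsorted(within, pooled, side="right") / within.size
    cdf_b = np.searchsorted(between, pooled, side="right") / between.size
    d = np.max(cdf_w - cdf_b)
    m, n = sorted([float(within.size), float(between.size)], reverse=True)
    n_eff = m * n / (m + n)
    z = np.sqrt(n_eff) * d
    p = np.exp(-2.0 * z * z - 2.0 * z * (m + 2 * n) / np.sqrt(m * n * (m + n)) / 3.0)
    return float(d), float(min(1.0, p))


def pooled_t_oracle(a, b):
    """Textbook pooled two-sample t statistic computed step by step."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = len(a), len(b)
    df = n1 + n2 - 2
    s2 = (np.sum((a - a.mean()) ** 2) + np.sum((b - b.mean()) ** 2)) / df
    t = (a.mean() - b.mean()) / np.sqrt(s2 * (1 / n1 + 1 / n2))
    return float(t), df
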