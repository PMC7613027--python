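"""Representational similarity analysis across contexts.

Trials are binned (probability quartiles, fixed probability bins, or the four
choice-by-state combinations), bin-mean voxel patterns are computed per
context, and every bin of one context is correlated with every bin of the
other, giving a non-symmetric 4x4 cross-context similarity matrix.
Correlations are clipped, Fisher-z transformed, and summarised as the mean of
the 4 diagonal cells (same bin in both contexts) minus the mean of the 12
off-diagonal cells.  A positive on-minus-off difference indicates that the
same bin is encoded with a similar pattern in both contexts, i.e. a shared
code.  Cross-run variants restrict correlations to bin means from different
runs; the within-context variant compares a context with itself across runs.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .synth_neural import VoxelDataset
from .task import CONTEXT_CONDITION

FISHER_CLIP = 1.0 - 1e-6


@dataclass
class BinAssignment:
    labels: np.ndarray  # per-trial bin 1..n_bins
    scheme: str
    n_bins: int = 4


@dataclass
class SimilaritySummary:
    matrix: np.ndarray  # n_bins x n_bins Fisher-z similarities, rows = context A
    on_diag: float
    off_diag: float

    @property
    def difference(self) -> float:
        return self.on_diag - self.off_diag


def assign_probability_bins(
    p_presented: np.ndarray, scheme: str = "subject_quartiles", n_bins: int = 4
) -> BinAssignment:
    """Bin trials by p(heist | door presented).

    ``subject_quartiles`` computes quantile edges over the supplied trials;
    ``fixed_quartiles`` uses the fixed edges 0-.25 / .26-.50 / .51-.75 /
    .76-1.  Ties break toward the lower bin.
    """
    p = np.asarray(p_presented, dtype=float)
    if p.size == 0:
        raise ValueError("no trials to bin")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    if scheme == "subject_quartiles":
        edges = np.quantile(p, np.linspace(0, 1, n_bins + 1)[1:-1])
    elif scheme == "fixed_quartiles":
        if n_bins != 4:
            raise ValueError("fixed_quartiles defines exactly 4 bins")
        edges = np.array([0.25, 0.50, 0.75])
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    labels = 1 + np.searchsorted(edges, p, side="left")
    return BinAssignment(labels=labels, scheme=scheme, n_bins=n_bins)


def bin_mean_patterns(
    dataset: VoxelDataset, bins: BinAssignment, context: int, run: Optional[int] = None
) -> np.ndarray:
    """Per-voxel mean pattern for each bin of one context (optionally one run)."""
    meta = dataset.metadata
    mask = (meta["context"] == context).to_numpy()
    if run is not None:
        mask &= (meta["run"] == run).to_numpy()
    out = np.empty((bins.n_bins, dataset.patterns.shape[1]))
    for b in range(1, bins.n_bins + 1):
        sel = mask & (bins.labels == b)
        if not sel.any():
            where = f"context {context}" + ("" if run is None else f", run {run}")
            raise ValueError(f"empty cell: bin {b} in {where}")
        out[b - 1] = dataset.patterns[sel].mean(axis=0)
    return out


def _fisher_similarity(means_a: np.ndarray, means_b: np.ndarray) -> np.ndarray:
    if means_a.shape[1] != means_b.shape[1]:
        raise ValueError("voxel dimensions do not match")
    za = means_a - means_a.mean(axis=1, keepdims=True)
    zb = means_b - means_b.mean(axis=1, keepdims=True)
    sa = np.sqrt((za**2).sum(axis=1))
    sb = np.sqrt((zb**2).sum(axis=1))
    if np.any(sa == 0) or np.any(sb == 0):
        raise ValueError("zero-variance pattern: correlation undefined")
    r = (za @ zb.T) / np.outer(sa, sb)
    return np.arctanh(np.clip(r, -FISHER_CLIP, FISHER_CLIP))


def _summary(z: np.ndarray) -> SimilaritySummary:
    n = z.shape[0]
    diag = np.eye(n, dtype=bool)
    return SimilaritySummary(
        matrix=z, on_diag=float(z[diag].mean()), off_diag=float(z[~diag].mean())
    )


def cross_context_contrast(means_a: np.ndarray, means_b: np.ndarray) -> SimilaritySummary:
    """Fisher-z similarity of every bin of context A with every bin of context B.

    The full (non-symmetric) cross block is kept: 4 diagonal and 12
    off-diagonal cells for 4 bins.
    """
    return _summary(_fisher_similarity(means_a, means_b))


def crossval_contrast(
    dataset: VoxelDataset,
    bins: BinAssignment,
    contexts: Sequence[int],
    mode: str = "between_context",
) -> SimilaritySummary:
    """Cross-run similarity contrast.

    Bin means are computed per run and correlated only across run pairs
    i != j; ``between_context`` crosses the two contexts, ``within_context``
    compares a single context with itself across runs.  Run pairs with an
    empty (context, run, bin) cell are dropped from the average with a
    warning.
    """
    if mode == "between_context":
        ctx_a, ctx_b = contexts
    elif mode == "within_context":
        (ctx_a,) = contexts if len(contexts) == 1 else (contexts[0],)
        ctx_b = ctx_a
    else:
        raise ValueError(f"mode must be 'between_context' or 'within_context', got {mode!r}")
    runs = np.unique(dataset.metadata["run"])
    if len(runs) < 2:
        raise ValueError("cross-validated contrast needs at least 2 runs")
    mats = []
    for i, j in itertools.permutations(runs, 2):
        try:
            ma = bin_mean_patterns(dataset, bins, ctx_a, run=i)
            mb = bin_mean_patterns(dataset, bins, ctx_b, run=j)
        except ValueError as exc:
            warnings.warn(f"dropping run pair ({i}, {j}): {exc}")
            continue
        mats.append(_fisher_similarity(ma, mb))
    if not mats:
        raise ValueError("all run pairs had empty cells")
    return _summary(np.mean(mats, axis=0))


@dataclass
class InteractionResult:
    t: float
    dof: int
    p: float
    mean_dep: float
    mean_indep: float
    t_dep: float
    p_dep: float
    t_indep: float
    p_indep: float


def condition_interaction(
    diffs_dependent: np.ndarray, diffs_independent: np.ndarray
) -> InteractionResult:
    """Paired t-test of per-subject on-minus-off differences across conditions,
    plus one-sample tests of each condition against zero."""
    a = np.asarray(diffs_dependent, dtype=float)
    b = np.asarray(diffs_independent, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("need equal-length per-subject difference vectors (n >= 2)")
    if np.allclose(a - b, (a - b)[0]):
        t, p = ((0.0, 1.0) if np.allclose(a, b) else (np.inf * np.sign((a - b)[0]), 0.0))
    else:
        t, p = stats.ttest_rel(a, b)
    td, pd_ = stats.ttest_1samp(a, 0.0)
    ti, pi = stats.ttest_1samp(b, 0.0)
    return InteractionResult(
        t=float(t),
        dof=len(a) - 1,
        p=float(p),
        mean_dep=float(a.mean()),
        mean_indep=float(b.mean()),
        t_dep=float(td),
        p_dep=float(pd_),
        t_indep=float(ti),
        p_indep=float(pi),
    )


def temporal_proximity_difference(
    dataset: VoxelDataset, bins: BinAssignment, contexts: Sequence[int]
) -> float:
    """Mean cross-context temporal distance for same-bin pairs minus
    different-bin pairs (negative values mean same-bin trials cluster in
    time)."""
    meta = dataset.metadata
    ctx_a, ctx_b = contexts
    ta = meta.loc[meta["context"] == ctx_a, "time"].to_numpy()
    tb = meta.loc[meta["context"] == ctx_b, "time"].to_numpy()
    ba = bins.labels[(meta["context"] == ctx_a).to_numpy()]
    bb = bins.labels[(meta["context"] == ctx_b).to_numpy()]
    dist = np.abs(ta[:, None] - tb[None, :])
    same = ba[:, None] == bb[None, :]
    if not same.any() or same.all():
        return float("nan")
    return float(dist[same].mean() - dist[~same].mean())


def temporal_proximity_control(
    proximity_diffs: np.ndarray, rsa_diffs: np.ndarray
):
    """Correlate per-subject proximity differences with RSA on-minus-off
    differences.  Returns (pearson r, p)."""
    r, p = stats.pearsonr(np.asarray(proximity_diffs, float), np.asarray(rsa_diffs, float))
    return float(r), float(p)


def split_contexts(condition: str):
    """The two context ids making up a condition."""
    return tuple(c for c, cond in CONTEXT_CONDITION.items() if cond == condition)
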