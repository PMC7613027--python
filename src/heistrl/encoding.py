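"""Linear encoding model over binned transition probabilities.

Model-derived probabilities are converted to log-odds, clipped to [-2, 2]
and assigned to n equal-width bins (n = 1..10).  The design matrix X
(n_bins x n_trials) uses either a one-hot basis (1 in the trial's bin) or a
Gaussian basis (a unit-sum tuning curve centred on the trial's bin).
Encoding weights W (voxels x n_bins) are the ridge-stabilised least-squares
regression of X onto the voxel data for one (context, run).  Decoding on
held-out data treats the model generatively: each bin j predicts the voxel
template W b_j (b_j the bin's design column), a trial's bin scores are the
Gaussian log-likelihoods -||y - W b_j||^2 / (2 sigma^2) with sigma^2 the
training residual variance, and a softmax over scores yields the decoded
distribution (the model is thereby inverted as a multinomial classifier).
The score is the mean cross-entropy against the true bins — ln(n_bins) at
chance, since uninformative weights give near-identical templates and hence
a near-uniform decoded distribution.  The generalization contrast trains on
each (context, run) and tests on the condition's paired context in other
runs, asking whether cross-context decoding is better (lower loss) in the
dependent than the independent condition.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

from .synth_neural import VoxelDataset
from .rsa import split_contexts

LOG_ODDS_RANGE = (-2.0, 2.0)
RIDGE = 1e-6


@dataclass
class DesignMatrix:
    X: np.ndarray  # n_bins x n_trials
    bin_labels: np.ndarray  # per-trial bin 0..n_bins-1
    basis: str
    n_bins: int
    centres: np.ndarray
    basis_matrix: np.ndarray  # n_bins x n_bins, column j = design vector of bin j


@dataclass
class EncodingWeights:
    W: np.ndarray  # voxels x n_bins
    basis: str
    n_bins: int
    templates: np.ndarray  # voxels x n_bins predicted pattern per bin (W @ basis)
    sigma2: float  # training residual variance per voxel
    train_context: Optional[int] = None
    train_run: Optional[int] = None


def probability_design(
    p_hat: np.ndarray, n_bins: int, basis: str = "one_hot", width: Optional[float] = None
) -> DesignMatrix:
    """Design matrix from model-derived probabilities.

    Probabilities of exactly 0/1 are clipped (with a warning) before the
    log-odds transform; log-odds are clipped to [-2, 2] so out-of-range
    values fall in the boundary bins.  The Gaussian basis width defaults to
    one bin width.
    """
    if not 1 <= n_bins <= 10:
        raise ValueError("n_bins must be in 1..10")
    if basis not in ("one_hot", "gaussian"):
        raise ValueError(f"basis must be 'one_hot' or 'gaussian', got {basis!r}")
    p = np.asarray(p_hat, dtype=float)
    if np.any((p <= 0.0) | (p >= 1.0)):
        warnings.warn("probabilities at or beyond 0/1 clipped before log-odds")
        p = np.clip(p, 1e-6, 1.0 - 1e-6)
    lo, hi = LOG_ODDS_RANGE
    logodds = np.clip(np.log(p / (1.0 - p)), lo, hi)
    edges = np.linspace(lo, hi, n_bins + 1)
    labels = np.clip(np.searchsorted(edges, logodds, side="right") - 1, 0, n_bins - 1)
    centres = 0.5 * (edges[:-1] + edges[1:])
    if basis == "one_hot":
        B = np.eye(n_bins)
    else:
        if width is None:
            width = (hi - lo) / n_bins
        B = np.exp(-0.5 * ((centres[:, None] - centres[None, :]) / width) ** 2)
        B /= B.sum(axis=0, keepdims=True)
    X = B[:, labels]
    return DesignMatrix(
        X=X, bin_labels=labels, basis=basis, n_bins=n_bins, centres=centres, basis_matrix=B
    )


def fit_encoding_weights(design: DesignMatrix, Y: np.ndarray) -> EncodingWeights:
    """Least-squares regression of the design onto voxel responses.

    ``Y`` is trials x voxels; a tiny ridge stabilises rank-deficient designs
    (e.g. empty bins).
    """
    X = design.X
    if Y.shape[0] != X.shape[1]:
        raise ValueError(f"trial counts differ: Y has {Y.shape[0]}, X has {X.shape[1]}")
    if Y.shape[0] <= design.n_bins:
        raise ValueError("need more trials than bins to fit encoding weights")
    if not design.X.any(axis=1).all() and design.basis == "one_hot":
        # all-empty bins are tolerated via ridge, but a fully empty design is not
        if not design.X.any():
            raise ValueError("design has no occupied bins")
    G = X @ X.T + RIDGE * np.eye(design.n_bins)
    W = Y.T @ X.T @ np.linalg.inv(G)
    resid = Y - (W @ X).T
    # df-corrected residual variance: with few trials per (context, run) the
    # uncorrected estimate is badly optimistic and the decoder overconfident
    occupied = int((X.sum(axis=1) > 0).sum())
    dof = max(Y.shape[0] - occupied, 1)
    sigma2 = float((resid**2).sum() / (dof * Y.shape[1]))
    if sigma2 <= 0:  # noiseless exact fit: any tiny scale keeps scores finite
        sigma2 = 1e-12
    return EncodingWeights(
        W=W,
        basis=design.basis,
        n_bins=design.n_bins,
        templates=W @ design.basis_matrix,
        sigma2=sigma2,
    )


def decode_and_score(
    weights: EncodingWeights, Y_test: np.ndarray, true_bins: np.ndarray
) -> float:
    """Mean cross-entropy of decoded bin distributions against true bins.

    Each bin's score is the Gaussian log-likelihood of the trial pattern
    under that bin's predicted template (residual variance from training);
    the softmax over scores is the decoded distribution and the loss is the
    mean negative log-probability of the true bin.  Chance level is
    ln(n_bins).
    """
    T = weights.templates
    if Y_test.shape[1] != T.shape[0]:
        raise ValueError("voxel dimensions do not match")
    # -||y - t_j||^2 / (2 s2), dropping the bin-independent ||y||^2 term
    scores = (Y_test @ T - 0.5 * np.sum(T**2, axis=0)) / weights.sigma2
    logp = scores - logsumexp(scores, axis=1, keepdims=True)
    return float(-logp[np.arange(len(true_bins)), np.asarray(true_bins)].mean())


@dataclass
class GeneralizationResult:
    losses: pd.DataFrame  # train/test context & run, n_bins, basis, loss
    condition_means: pd.DataFrame  # subject-level mean loss per condition per n_bins


def _subject_losses(
    dataset: VoxelDataset,
    p_presented: np.ndarray,
    n_bins: int,
    basis: str,
    cross_gem: bool = True,
) -> list:
    meta = dataset.metadata
    runs = np.unique(meta["run"])
    if len(runs) < 2:
        raise ValueError("generalization needs at least 2 runs")
    records = []
    for condition in ("dependent", "independent"):
        ctxs = split_contexts(condition)
        for train_ctx in ctxs:
            test_ctx = ctxs[1] if train_ctx == ctxs[0] else ctxs[0]
            if not cross_gem:
                test_ctx = train_ctx
            for train_run, test_run in itertools.permutations(runs, 2):
                tr = ((meta["context"] == train_ctx) & (meta["run"] == train_run)).to_numpy()
                te = ((meta["context"] == test_ctx) & (meta["run"] == test_run)).to_numpy()
                if tr.sum() <= n_bins or te.sum() == 0:
                    continue
                d_tr = probability_design(p_presented[tr], n_bins, basis)
                d_te = probability_design(p_presented[te], n_bins, basis)
                w = fit_encoding_weights(d_tr, dataset.patterns[tr])
                loss = decode_and_score(w, dataset.patterns[te], d_te.bin_labels)
                records.append(
                    dict(
                        condition=condition,
                        train_context=train_ctx,
                        train_run=train_run,
                        test_context=test_ctx,
                        test_run=test_run,
                        n_bins=n_bins,
                        basis=basis,
                        loss=loss,
                    )
                )
    if not records:
        raise ValueError("no (train, test) pairs with enough trials")
    return records


def generalization_contrast(
    datasets: Sequence[VoxelDataset],
    p_presented_per_subject: Sequence[np.ndarray],
    n_bins_grid: Sequence[int] = tuple(range(1, 11)),
    basis: str = "one_hot",
    cross_gem: bool = True,
) -> Tuple[GeneralizationResult, pd.DataFrame]:
    """Cross-context generalization losses across subjects and a per-n_bins
    paired test of dependent vs independent mean loss.

    Returns ``(GeneralizationResult, tests)`` where ``tests`` has one row per
    n_bins with the paired t statistic (dependent minus independent; negative
    t means better cross-context generalization in the dependent condition).
    """
    all_rows = []
    for s, (ds, p) in enumerate(zip(datasets, p_presented_per_subject)):
        for n_bins in n_bins_grid:
            rows = _subject_losses(ds, np.asarray(p, float), n_bins, basis, cross_gem=cross_gem)
            for r in rows:
                r["subject"] = s
            all_rows.extend(rows)
    losses = pd.DataFrame(all_rows)
    cond_means = (
        losses.groupby(["subject", "condition", "n_bins"], sort=False)["loss"]
        .mean()
        .reset_index()
    )
    tests = []
    for n_bins in n_bins_grid:
        sel = cond_means[cond_means["n_bins"] == n_bins]
        piv = sel.pivot(index="subject", columns="condition", values="loss")
        if len(piv) >= 2 and piv.notna().all().all():
            diff = piv["dependent"] - piv["independent"]
            if np.allclose(diff.std(ddof=1), 0.0):
                t, p = (0.0, 1.0) if np.allclose(diff, 0.0) else (np.nan, np.nan)
            else:
                t, p = stats.ttest_rel(piv["dependent"], piv["independent"])
            tests.append(
                dict(
                    n_bins=n_bins,
                    t=float(t),
                    p=float(p),
                    mean_dep=float(piv["dependent"].mean()),
                    mean_indep=float(piv["independent"].mean()),
                )
            )
    return GeneralizationResult(losses=losses, condition_means=cond_means), pd.DataFrame(tests)
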