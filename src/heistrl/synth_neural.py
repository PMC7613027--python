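"""Synthetic trial-wise multivoxel patterns with shared or context-specific codes.

Each (context, bin) cell has a voxel-length prototype pattern.  Under a
*shared* code the two contexts of a condition reuse the same prototypes;
under a *separate* code each context draws its own.  A trial's pattern is its
cell prototype plus i.i.d. Gaussian noise and an optional per-run offset.
Bins are either probability bins of p(heist | door presented) (door
presentation) or the four choice-by-state combinations (outcome
presentation).  These patterns stand in for single-trial BOLD estimates; no
hemodynamics, spatial autocorrelation or scanner drift is modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from .task import DEPENDENT_CONTEXTS, INDEPENDENT_CONTEXTS

OUTCOME_BINS = {
    ("dark", "heist"): 1,
    ("dark", "neutral"): 2,
    ("light", "heist"): 3,
    ("light", "neutral"): 4,
}


@dataclass
class CodingScheme:
    n_voxels: int
    n_bins: int
    prototypes: Dict[Tuple[int, int], np.ndarray]  # (context, bin 1..n) -> pattern
    sharing: Dict[str, str]  # condition -> 'shared' | 'separate'
    noise_sd: float
    run_effect_sd: float = 0.0
    tuning: str = "discrete"


@dataclass
class VoxelDataset:
    """Trials x voxels pattern matrix plus aligned per-trial metadata."""

    patterns: np.ndarray
    metadata: pd.DataFrame

    def __post_init__(self):
        if len(self.patterns) != len(self.metadata):
            raise ValueError(
                f"pattern rows ({len(self.patterns)}) != metadata rows ({len(self.metadata)})"
            )
        if not np.all(np.isfinite(self.patterns)):
            raise ValueError("pattern matrix contains non-finite values")


def make_coding_scheme(
    n_voxels: int = 200,
    n_bins: int = 4,
    sharing_dep: str = "shared",
    sharing_indep: str = "separate",
    noise_sd: float = 1.0,
    rng: Optional[np.random.Generator] = None,
    run_effect_sd: float = 0.0,
    tuning: str = "discrete",
    smooth_width: float = 1.0,
) -> CodingScheme:
    """Draw bin prototypes (i.i.d. standard normal per voxel).

    Shared conditions copy one prototype set across the condition's two
    contexts; separate conditions draw independently per context.  ``smooth``
    tuning correlates adjacent-bin prototypes by Gaussian-kernel mixing of
    latent patterns (width in bin units).
    """
    if n_voxels < 1 or n_bins < 1:
        raise ValueError("n_voxels and n_bins must be >= 1")
    if tuning not in ("discrete", "smooth"):
        raise ValueError(f"unknown tuning {tuning!r}")
    if rng is None:
        rng = np.random.default_rng()

    def draw_set() -> np.ndarray:
        latent = rng.standard_normal((n_bins, n_voxels))
        if tuning == "discrete":
            return latent
        centers = np.arange(n_bins)
        kern = np.exp(-0.5 * ((centers[:, None] - centers[None, :]) / smooth_width) ** 2)
        kern /= np.linalg.norm(kern, axis=1, keepdims=True)
        return kern @ latent

    prototypes: Dict[Tuple[int, int], np.ndarray] = {}
    sharing = {"dependent": sharing_dep, "independent": sharing_indep}
    for condition, contexts in (
        ("dependent", DEPENDENT_CONTEXTS),
        ("independent", INDEPENDENT_CONTEXTS),
    ):
        mode = sharing[condition]
        if mode not in ("shared", "separate"):
            raise ValueError(f"sharing must be 'shared' or 'separate', got {mode!r}")
        if mode == "shared":
            protos = draw_set()
            for ctx in contexts:
                for b in range(n_bins):
                    prototypes[(ctx, b + 1)] = protos[b]
        else:
            for ctx in contexts:
                protos = draw_set()
                for b in range(n_bins):
                    prototypes[(ctx, b + 1)] = protos[b]
    return CodingScheme(
        n_voxels=n_voxels,
        n_bins=n_bins,
        prototypes=prototypes,
        sharing=sharing,
        noise_sd=noise_sd,
        run_effect_sd=run_effect_sd,
        tuning=tuning,
    )


def probability_bin(p_presented: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-width probability bins 1..n_bins (ties toward the lower bin)."""
    edges = np.linspace(0.0, 1.0, n_bins + 1)[1:-1]
    return 1 + np.searchsorted(edges, p_presented, side="left")


def generate_voxel_dataset(
    trajectory: pd.DataFrame,
    scheme: CodingScheme,
    mode: str = "door",
    rng: Optional[np.random.Generator] = None,
) -> VoxelDataset:
    """Emit one pattern per trial from a run_model trajectory table.

    ``door`` mode bins trials by p(heist | door presented) — ``p_hat`` when
    the dark door was presented, ``1 - p_hat`` otherwise.  ``outcome`` mode
    bins by the four choice-by-state combinations.  Runs are the trajectory's
    session labels; each run draws one offset pattern with sd
    ``run_effect_sd``.
    """
    if mode not in ("door", "outcome"):
        raise ValueError(f"mode must be 'door' or 'outcome', got {mode!r}")
    if rng is None:
        rng = np.random.default_rng()
    traj = trajectory.reset_index(drop=True)
    if mode == "door":
        if "p_hat" not in traj.columns or traj["p_hat"].isna().any():
            raise ValueError("door mode requires a p_hat value on every trial")
        dark = (traj["door_presented"] == "dark").to_numpy()
        p_presented = np.where(dark, traj["p_hat"].to_numpy(), 1.0 - traj["p_hat"].to_numpy())
        bins = probability_bin(p_presented, scheme.n_bins)
    else:
        if traj["choice"].isna().any() or traj["state"].isna().any():
            raise ValueError("outcome mode requires choices and states to be filled")
        if scheme.n_bins != 4:
            raise ValueError("outcome mode uses the 4 choice-by-state bins")
        bins = np.array(
            [OUTCOME_BINS[(c, s)] for c, s in zip(traj["choice"], traj["state"])]
        )
        p_presented = np.full(len(traj), np.nan)

    runs = traj["session"].to_numpy()
    run_offsets = {
        r: scheme.run_effect_sd * rng.standard_normal(scheme.n_voxels)
        for r in np.unique(runs)
    }
    patterns = np.empty((len(traj), scheme.n_voxels))
    for i in range(len(traj)):
        proto = scheme.prototypes[(int(traj.at[i, "context"]), int(bins[i]))]
        patterns[i] = (
            proto
            + run_offsets[runs[i]]
            + scheme.noise_sd * rng.standard_normal(scheme.n_voxels)
        )
    metadata = pd.DataFrame(
        {
            "trial_index": traj["trial_index"],
            "context": traj["context"],
            "condition": traj["condition"],
            "run": runs,
            "bin": bins,
            "p_presented": p_presented,
            "time": traj["trial_index"].astype(float),
        }
    )
    return VoxelDataset(patterns=patterns, metadata=metadata)
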