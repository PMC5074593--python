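"""Dynamic cross-correlation matrices (DCCM) of node displacements.

For displacement vectors Δr_i(t) (representative-atom position minus its
time average over the analysed window), the matrix element is

    C_ij = <Δr_i · Δr_j> / (<Δr_i²>^½ <Δr_j²>^½),

the normalised average of 3-D dot products over frames.  C is symmetric
with unit diagonal; +1 means fully synchronous motion, −1 fully
anti-correlated motion.  The trajectory must be superposed first so the
displacements exclude rigid-body motion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path as FilePath
from typing import Sequence

import numpy as np

from .model import NodeModel, TrajectoryEnsemble

#: a node whose displacement variance falls below this (Å²) is degenerate
_VARIANCE_FLOOR = 1e-12


@dataclass
class CorrelationMatrix:
    C: np.ndarray
    frames_used: int
    window_label: str = ""
    #: nodes with zero displacement variance; their rows/cols are NaN and
    #: must not participate in network construction
    degenerate_nodes: tuple[int, ...] = field(default_factory=tuple)

    @property
    def n(self) -> int:
        return self.C.shape[0]

    def to_tsv(self, path: str | FilePath, labels: Sequence[str] | None = None) -> None:
        import pandas as pd

        idx = labels if labels is not None else list(range(self.n))
        pd.DataFrame(self.C, index=idx, columns=idx).to_csv(
            path, sep="\t", float_format="%.6f"
        )

    def plot_heatmap(self, path: str | FilePath, title: str = "DCCM") -> None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 5))
        im = ax.imshow(self.C, vmin=-1, vmax=1, cmap="RdBu_r", origin="lower")
        ax.set_xlabel("node")
        ax.set_ylabel("node")
        ax.set_title(f"{title} ({self.window_label or self.frames_used} frames)")
        fig.colorbar(im, ax=ax, label=r"$C_{ij}$")
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)


def compute_dccm(
    traj: TrajectoryEnsemble,
    node_model: NodeModel,
    window_label: str = "",
    require_superposed: bool = True,
) -> CorrelationMatrix:
    """DCCM over all frames of (a window of) a superposed trajectory."""
    if require_superposed and not traj.superposed:
        raise ValueError("trajectory must be superposed before computing a DCCM")
    if traj.n_frames < 2:
        raise ValueError("need at least 2 frames for displacement correlations")
    rep = node_model.representative_atoms
    x = traj.coords[:, rep, :]  # (F, n, 3)
    disp = x - x.mean(axis=0)
    # S_ij = sum_f Δr_i(f) · Δr_j(f)
    S = np.einsum("fid,fjd->ij", disp, disp)
    var = np.diag(S).copy()
    degenerate = np.flatnonzero(var <= _VARIANCE_FLOOR * traj.n_frames)
    var_safe = np.where(var > 0, var, 1.0)
    C = S / np.sqrt(np.outer(var_safe, var_safe))
    C = np.clip((C + C.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(C, 1.0)
    if degenerate.size:
        C[degenerate, :] = np.nan
        C[:, degenerate] = np.nan
        warnings.warn(
            f"{degenerate.size} node(s) with zero displacement variance: "
            f"{degenerate.tolist()}",
            stacklevel=2,
        )
    return CorrelationMatrix(
        C, traj.n_frames, window_label, tuple(int(i) for i in degenerate)
    )


@dataclass
class ConvergenceReport:
    """DCCMs on cumulative trajectory prefixes plus similarity between
    consecutive windows: RMS difference of matrix elements and Pearson
    correlation of off-diagonal elements."""

    windows: list[CorrelationMatrix]
    fractions: list[float]
    rms_diff: list[float]  # between consecutive windows
    pearson_offdiag: list[float]

    def to_tsv(self, path: str | FilePath) -> None:
        import pandas as pd

        rows = []
        for k in range(1, len(self.windows)):
            rows.append(
                {
                    "window_a": self.windows[k - 1].window_label,
                    "window_b": self.windows[k].window_label,
                    "rms_diff": self.rms_diff[k - 1],
                    "pearson_offdiag": self.pearson_offdiag[k - 1],
                }
            )
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.6f")


def matrix_rms_diff(a: CorrelationMatrix, b: CorrelationMatrix) -> float:
    return float(np.sqrt(np.nanmean((a.C - b.C) ** 2)))


def matrix_offdiag_pearson(a: CorrelationMatrix, b: CorrelationMatrix) -> float:
    iu = np.triu_indices(a.n, k=1)
    x, y = a.C[iu], b.C[iu]
    ok = np.isfinite(x) & np.isfinite(y)
    return float(np.corrcoef(x[ok], y[ok])[0, 1])


def dccm_convergence(
    traj: TrajectoryEnsemble,
    node_model: NodeModel,
    window_fractions: Sequence[float] = (0.25, 0.5, 0.75, 1.0),
) -> ConvergenceReport:
    """Assess DCCM stability over growing cumulative windows.

    Converged sampling shows shrinking differences between successive
    windows (the classic check is comparing matrices after increasing
    simulation lengths and finding little change beyond the first
    quarter).  Windows with fewer than 2 frames are skipped with a
    warning.
    """
    if traj.n_frames < 2:
        raise ValueError("need at least 2 frames for a convergence scan")
    windows: list[CorrelationMatrix] = []
    used_fracs: list[float] = []
    for frac in window_fractions:
        nf = int(round(frac * traj.n_frames))
        if nf < 2:
            warnings.warn(
                f"window fraction {frac} has {nf} frame(s); skipped", stacklevel=2
            )
            continue
        t_ps = nf * traj.frame_interval_ps
        label = f"0-{t_ps:g}ps"
        windows.append(
            compute_dccm(traj.window(nf), node_model, window_label=label)
        )
        used_fracs.append(frac)
    rms = [matrix_rms_diff(a, b) for a, b in zip(windows, windows[1:])]
    pearson = [matrix_offdiag_pearson(a, b) for a, b in zip(windows, windows[1:])]
    return ConvergenceReport(windows, used_fracs, rms, pearson)
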