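"""Batch-effect removal and classical multidimensional scaling.

The study batch component is removed from logCPM for visualization only:
per gene, a joint linear model with the protected (group) design plus
sum-coded batch indicators is fitted, and only the fitted batch component is
subtracted — planted or real group structure is untouched.  MDS is classical
(Torgerson) scaling of Euclidean distances over the top-variance genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def remove_batch(logcpm: pd.DataFrame, batch,
                 protected_design: pd.DataFrame | None = None) -> pd.DataFrame:
    """Subtract the fitted per-study component from logCPM.

    ``batch`` gives one label per sample (counts column order).  With a
    single batch level the matrix is returned unchanged.  Batch indicators
    are sum-coded so the grand level is preserved; the protected design
    (group indicators) keeps biological structure out of the batch fit.
    Raises when batch is confounded with the protected design.
    """
    batch = pd.Series(np.asarray(batch), index=logcpm.columns)
    levels = list(pd.unique(batch))
    if len(levels) < 2:
        return logcpm.copy()
    n = logcpm.shape[1]
    # sum-to-zero coding: k-1 columns, last level coded -1 everywhere
    B = np.zeros((n, len(levels) - 1))
    for j, lev in enumerate(levels[:-1]):
        B[(batch == lev).to_numpy(), j] = 1.0
    B[(batch == levels[-1]).to_numpy(), :] = -1.0

    if protected_design is not None:
        P = protected_design.to_numpy(float)
    else:
        P = np.ones((n, 1))
    X = np.hstack([P, B])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(
            "batch is confounded with the protected design; the batch "
            "component is not separately estimable")
    beta = logcpm.to_numpy(float) @ np.linalg.pinv(X).T
    batch_part = beta[:, P.shape[1]:] @ B.T
    return pd.DataFrame(logcpm.to_numpy(float) - batch_part,
                        index=logcpm.index, columns=logcpm.columns)


@dataclass
class MDSResult:
    coordinates: pd.DataFrame        # samples x (dim1, dim2)
    explained: tuple[float, float]   # eigenvalue fractions, non-increasing
    genes_used: list[str]

    def plot(self, color, path: str | None = None, title: str = "MDS"):
        """Scatter of the two dimensions colored by a per-sample label."""
        color = pd.Series(np.asarray(color), index=self.coordinates.index)
        fig, ax = plt.subplots(figsize=(5, 4))
        for lev in pd.unique(color):
            sel = color == lev
            ax.scatter(self.coordinates.loc[sel, "dim1"],
                       self.coordinates.loc[sel, "dim2"], s=14, label=str(lev))
        ax.set_xlabel(f"dim 1 ({self.explained[0]:.1%})")
        ax.set_ylabel(f"dim 2 ({self.explained[1]:.1%})")
        ax.set_title(title)
        ax.legend(frameon=False, fontsize=8)
        fig.tight_layout()
        if path:
            fig.savefig(path, dpi=150)
            plt.close(fig)
        return fig


def mds_embed(expr: pd.DataFrame, n_top_genes: int = 500) -> MDSResult:
    """Classical MDS of samples on the top-variance genes.

    Pairwise Euclidean distances over the ``n_top_genes`` most variable
    genes are double-centered and eigendecomposed; the top two coordinates
    are returned with their eigenvalue fractions (over positive eigenvalues,
    which for Euclidean input reconstruct the distances exactly).
    """
    if expr.shape[1] < 3:
        raise ValueError("MDS needs at least 3 samples")
    if expr.shape[0] < n_top_genes:
        warnings.warn(f"only {expr.shape[0]} genes available; using all "
                      f"(requested {n_top_genes})")
        n_top_genes = expr.shape[0]
    variances = expr.var(axis=1)
    top = variances.sort_values(ascending=False, kind="stable").index[:n_top_genes]
    Y = expr.loc[top].to_numpy(float).T          # samples x genes
    sq = (Y ** 2).sum(axis=1)
    D2 = sq[:, None] + sq[None, :] - 2.0 * Y @ Y.T
    np.clip(D2, 0.0, None, out=D2)
    n = D2.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    Bmat = -0.5 * J @ D2 @ J
    evals, evecs = np.linalg.eigh(Bmat)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = np.clip(evals, 0.0, None)
    total = pos.sum() if pos.sum() > 0 else 1.0
    coords = evecs[:, :2] * np.sqrt(pos[:2])[None, :]
    # deterministic sign convention: largest-|loading| entry positive
    for k in range(2):
        i = np.argmax(np.abs(coords[:, k]))
        if coords[i, k] < 0:
            coords[:, k] = -coords[:, k]
    return MDSResult(
        coordinates=pd.DataFrame(coords, index=expr.columns,
                                 columns=["dim1", "dim2"]),
        explained=(float(pos[0] / total), float(pos[1] / total)),
        genes_used=list(top))
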