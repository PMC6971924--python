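"""ERCC spike-in accuracy metrics and the plate pooling-effect diagnostic.

Because equal amounts of the spike-in mix go into every sample, the spike-in
profile of each sample should be identical up to counting noise.  Systematic
deviations shared by all samples of a plate row (pool) or column (i7 index)
therefore betray pooling artefacts.  The diagnostic runs PCA on the
samples x species log-abundance matrix (column-centred, no variance scaling)
and quantifies how much of PC1 is explained by the row and column factors
via the one-way ANOVA identity R^2 = SS_between / SS_total, with a label
permutation test as the decision rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import ErccTable, PlateLayout

__all__ = [
    "ErccAccuracyReport",
    "ErccPcaReport",
    "ercc_accuracy",
    "pairwise_correlation",
    "pooling_effect_pca",
    "group_r2",
]


@dataclass
class ErccAccuracyReport:
    """Per-sample Pearson r of log2 observed abundance vs known concentration."""

    r: pd.Series  # per sample
    n_species: int

    @property
    def mean_r(self) -> float:
        return float(self.r.mean())


def ercc_accuracy(
    tpm: pd.DataFrame,
    table: ErccTable,
    pseudocount: float = 1.0,
) -> ErccAccuracyReport:
    """Correlate observed spike-in abundance with known concentrations.

    ``tpm`` is the TPM matrix restricted to spike-in species (species x
    samples).  Both sides go to log2 with the stated pseudocount so species
    with zero counts stay in the comparison; r is Pearson on that scale.
    """
    common = [g for g in table.ids if g in tpm.index]
    if len(common) < 3:
        raise ValueError("need at least 3 spike-in species with known concentration")
    conc = np.log2(table.concentrations().reindex(common).to_numpy())
    if np.ptp(conc) == 0:
        raise ValueError("spike-in concentrations are constant; correlation undefined")
    obs = np.log2(tpm.reindex(common).to_numpy() + pseudocount)
    rs = {}
    for j, sample in enumerate(tpm.columns):
        if np.ptp(obs[:, j]) == 0:
            raise ValueError(f"sample {sample}: constant observed vector, r undefined")
        rs[sample] = stats.pearsonr(obs[:, j], conc).statistic
    return ErccAccuracyReport(r=pd.Series(rs), n_species=len(common))


def pairwise_correlation(log_abundance: pd.DataFrame) -> pd.DataFrame:
    """Sample x sample Pearson matrix of log-abundance profiles.

    ``log_abundance`` is species x samples; the result is symmetric with a
    unit diagonal.
    """
    if log_abundance.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    x = log_abundance.to_numpy()
    if (np.ptp(x, axis=0) == 0).any():
        bad = log_abundance.columns[np.ptp(x, axis=0) == 0]
        raise ValueError(f"constant sample vectors, correlation undefined: {list(bad)}")
    corr = np.corrcoef(x, rowvar=False)
    return pd.DataFrame(corr, index=log_abundance.columns, columns=log_abundance.columns)


def group_r2(scores: np.ndarray, groups: np.ndarray) -> float:
    """SS_between / SS_total of scores grouped by a categorical factor."""
    scores = np.asarray(scores, dtype=float)
    grand = scores.mean()
    ss_total = np.sum((scores - grand) ** 2)
    if ss_total == 0:
        return 0.0
    ss_between = 0.0
    for g in np.unique(groups):
        sel = scores[groups == g]
        ss_between += len(sel) * (sel.mean() - grand) ** 2
    return float(ss_between / ss_total)


@dataclass
class ErccPcaReport:
    scores: pd.DataFrame  # samples x PCs
    variance_explained: np.ndarray  # fraction per PC
    r2_row: float
    r2_col: float
    p_row: float
    p_col: float

    def summary(self) -> dict:
        return {
            "R2_row": self.r2_row,
            "R2_col": self.r2_col,
            "p_row": self.p_row,
            "p_col": self.p_col,
            "pc1_var": float(self.variance_explained[0]),
        }


def _perm_pvalue(
    rng: np.random.Generator, scores: np.ndarray, groups: np.ndarray, n_perm: int
) -> float:
    obs = group_r2(scores, groups)
    hits = 0
    g = groups.copy()
    for _ in range(n_perm):
        rng.shuffle(g)
        if group_r2(scores, g) >= obs - 1e-12:
            hits += 1
    return (hits + 1) / (n_perm + 1)


def pooling_effect_pca(
    log_matrix: pd.DataFrame,
    layout: PlateLayout,
    n_perm: int = 1000,
    n_components: int = 2,
    seed: int = 0,
) -> ErccPcaReport:
    """PCA of spike-in profiles with row/column R^2 against PC1.

    ``log_matrix`` is samples x species (log scale).  Species columns are
    centred, no variance scaling; PCA by singular value decomposition.
    ``r2_row``/``r2_col`` are the coefficients of determination of the PC1
    sample scores explained by the plate row / column grouping (ANOVA
    identity); p-values are permutation fractions of relabelled R^2 >=
    observed.
    """
    samples = list(log_matrix.index)
    row_of, col_of = layout.row_of(), layout.col_of()
    missing = [s for s in samples if s not in row_of]
    if missing:
        raise KeyError(f"samples not on the plate layout: {missing[:5]}")
    rows = np.array([row_of[s] for s in samples])
    cols = np.array([col_of[s] for s in samples])
    if len(np.unique(rows)) < 2 or len(np.unique(cols)) < 2:
        raise ValueError(
            "single row or column group: factor R^2 against PC1 is undefined"
        )
    if log_matrix.shape[1] < 2:
        raise ValueError("need at least 2 species")
    for name, grp in (("row", rows), ("column", cols)):
        if np.bincount(grp).max() <= 1:
            warnings.warn(
                f"one sample per {name} group: R^2_{name} is trivially 1 "
                "(degenerate design)"
            )

    x = log_matrix.to_numpy(dtype=float)
    x = x - x.mean(axis=0, keepdims=True)
    u, s, _vt = np.linalg.svd(x, full_matrices=False)
    scores = u * s
    var = s**2 / np.sum(s**2) if s.sum() > 0 else np.zeros_like(s)
    k = min(n_components, scores.shape[1])

    pc1 = scores[:, 0]
    r2_row = group_r2(pc1, rows)
    r2_col = group_r2(pc1, cols)
    rng = np.random.default_rng(seed)
    p_row = _perm_pvalue(rng, pc1, rows, n_perm)
    p_col = _perm_pvalue(rng, pc1, cols, n_perm)

    return ErccPcaReport(
        scores=pd.DataFrame(
            scores[:, :k], index=samples, columns=[f"PC{i + 1}" for i in range(k)]
        ),
        variance_explained=var,
        r2_row=r2_row,
        r2_col=r2_col,
        p_row=p_row,
        p_col=p_col,
    )
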