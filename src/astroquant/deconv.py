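"""Bulk cell-type deconvolution by (variance-weighted) non-negative least squares.

A deliberately simplified estimator in the spirit of multi-subject
deconvolution: cell-type signatures are built as across-subject means of
subject-level, cell-normalized expression profiles, the across-subject
variance is retained per gene and cell type, and bulk composition is
estimated by NNLS on the shared gene set — optionally iteratively
reweighted so that genes with high cross-subject variance or large
residuals count less. There is no multi-sample bulk modelling and no
tree-guided recursive estimation; this is not a full multi-subject
deconvolution implementation and does not aim to reproduce one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls

__all__ = [
    "SignatureMatrix",
    "ProportionEstimate",
    "build_signature",
    "estimate_proportions_nnls",
    "estimate_proportions_weighted",
]

DEFAULT_MIN_SHARED_GENES = 50
WEIGHT_EPS = 1e-8


@dataclass
class SignatureMatrix:
    """Cell-type reference profiles on a relative-abundance scale.

    ``mean_profile`` (genes x cell types) has columns summing to 1;
    ``cross_subject_variance`` is the same-shaped across-subject variance
    of the subject-level profiles (all zeros when built from one subject).
    """

    mean_profile: pd.DataFrame
    cross_subject_variance: pd.DataFrame = field(default=None)
    n_subjects: int = 1

    def __post_init__(self) -> None:
        if self.cross_subject_variance is None:
            self.cross_subject_variance = pd.DataFrame(
                0.0, index=self.mean_profile.index, columns=self.mean_profile.columns
            )
        if not self.mean_profile.index.equals(self.cross_subject_variance.index):
            raise ValueError("mean/variance gene indices differ")
        if not self.mean_profile.columns.equals(self.cross_subject_variance.columns):
            raise ValueError("mean/variance cell-type columns differ")
        vals = self.mean_profile.to_numpy(dtype=float)
        if (vals < 0).any() or not np.all(np.isfinite(vals)):
            raise ValueError("mean_profile must be finite and non-negative")
        sums = vals.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("each cell-type column must sum to 1 within 1e-9")
        if (self.cross_subject_variance.to_numpy(dtype=float) < 0).any():
            raise ValueError("variances must be non-negative")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.n_subjects == 1 and (
            self.cross_subject_variance.to_numpy() != 0
        ).any():
            raise ValueError("variance must be zero when n_subjects = 1")

    @property
    def genes(self) -> pd.Index:
        return self.mean_profile.index

    @property
    def cell_types(self) -> pd.Index:
        return self.mean_profile.columns


@dataclass(frozen=True)
class ProportionEstimate:
    """Estimated bulk composition: non-negative proportions summing to 1."""

    proportions: pd.Series
    residual_norm: float
    n_iterations: int
    converged: bool = True


def build_signature(
    sc_matrix: pd.DataFrame,
    cell_type_labels: Sequence[str],
    subject_labels: Sequence[str],
) -> SignatureMatrix:
    """Across-subject mean/variance signature from a labelled single-cell matrix.

    ``sc_matrix`` is genes x cells. Each cell is first normalized to
    relative abundance (its counts divided by its total), then averaged
    gene-wise within each (subject, cell type); the signature mean and
    variance (ddof=1; zero for a single subject) are taken across
    subjects, and mean columns are renormalized to sum to 1.
    """
    cells = sc_matrix.columns
    ct = pd.Series(list(cell_type_labels), index=cells)
    subj = pd.Series(list(subject_labels), index=cells)
    if len(ct) != sc_matrix.shape[1] or len(subj) != sc_matrix.shape[1]:
        raise ValueError("one cell-type and subject label per cell required")
    totals = sc_matrix.sum(axis=0)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise ValueError(f"cells with zero total counts: {bad}")
    rel = sc_matrix.div(totals, axis=1)

    cell_types = sorted(ct.unique())
    subjects = sorted(subj.unique())
    mean_cols = {}
    var_cols = {}
    for t in cell_types:
        per_subject = []
        for s in subjects:
            sel = cells[(ct == t) & (subj == s)]
            if len(sel):
                per_subject.append(rel[sel].mean(axis=1))
        if not per_subject:
            raise ValueError(f"cell type {t!r} has no cells in any subject")
        stacked = pd.concat(per_subject, axis=1)
        mean_cols[t] = stacked.mean(axis=1)
        var_cols[t] = (
            stacked.var(axis=1, ddof=1)
            if stacked.shape[1] > 1
            else pd.Series(0.0, index=rel.index)
        )
    mean = pd.DataFrame(mean_cols)
    mean = mean / mean.sum(axis=0)
    var = pd.DataFrame(var_cols)
    return SignatureMatrix(
        mean_profile=mean, cross_subject_variance=var, n_subjects=len(subjects)
    )


def _prepare(
    bulk: pd.Series, signature: SignatureMatrix, min_shared_genes: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, pd.Index]:
    """Intersect genes, normalize both sides, and check conditioning."""
    bulk = pd.Series(bulk).astype(float)
    shared = signature.genes.intersection(bulk.index)
    if len(shared) < min_shared_genes:
        raise ValueError(
            f"only {len(shared)} genes shared between bulk and signature; "
            f"need at least {min_shared_genes}"
        )
    S = signature.mean_profile.loc[shared].to_numpy(dtype=float)
    V = signature.cross_subject_variance.loc[shared].to_numpy(dtype=float)
    b = bulk.loc[shared].to_numpy(dtype=float)
    if (b < 0).any() or not np.all(np.isfinite(b)):
        raise ValueError("bulk values must be finite and non-negative")
    total = b.sum()
    if total <= 0:
        raise ValueError("bulk vector sums to zero")
    b = b / total
    col_norm = S.sum(axis=0)
    if (col_norm <= 0).any():
        raise ValueError("signature column with zero mass on the shared genes")
    S = S / col_norm

    if np.linalg.matrix_rank(S) < S.shape[1]:
        types = list(signature.cell_types)
        collinear = [
            f"{types[i]}~{types[j]}"
            for i in range(len(types))
            for j in range(i + 1, len(types))
            if np.allclose(S[:, i], S[:, j])
        ]
        raise ValueError(
            "rank-deficient signature on the shared gene set"
            + (f"; collinear cell types: {collinear}" if collinear else "")
        )
    return S, V, b, shared


def _as_estimate(
    x: np.ndarray, S: np.ndarray, b: np.ndarray, signature: SignatureMatrix,
    n_iter: int, converged: bool = True,
) -> ProportionEstimate:
    total = x.sum()
    if total <= 0:
        raise ValueError("NNLS returned an all-zero solution")
    props = pd.Series(x / total, index=signature.cell_types, name="proportion")
    return ProportionEstimate(
        proportions=props,
        residual_norm=float(np.linalg.norm(S @ x - b)),
        n_iterations=n_iter,
        converged=converged,
    )


def estimate_proportions_nnls(
    bulk: pd.Series,
    signature: SignatureMatrix,
    min_shared_genes: int = DEFAULT_MIN_SHARED_GENES,
) -> ProportionEstimate:
    """Unweighted NNLS composition estimate on the shared gene set.

    Solves min ||S x - b||^2 s.t. x >= 0 with both the bulk vector and the
    signature columns normalized to unit mass, then renormalizes x to a
    composition. Deterministic.
    """
    S, _, b, _ = _prepare(bulk, signature, min_shared_genes)
    x, _ = nnls(S, b)
    return _as_estimate(x, S, b, signature, n_iter=1)


def estimate_proportions_weighted(
    bulk: pd.Series,
    signature: SignatureMatrix,
    max_iter: int = 50,
    tol: float = 1e-6,
    min_shared_genes: int = DEFAULT_MIN_SHARED_GENES,
) -> ProportionEstimate:
    """Iteratively reweighted NNLS downweighting unreliable genes.

    Gene weights are w_g = 1 / (sum_k var[g,k] * x_k^2 + r_g^2 + eps):
    the first term is the variance of the predicted bulk value under
    independent cross-subject variation of the signature scaled by the
    current solution, r_g is the current residual, and eps = 1e-8 guards
    the noiseless case. With all-zero variance and homoscedastic residuals
    the weights are flat and the estimate equals the unweighted one.
    Non-convergence within ``max_iter`` sets ``converged=False`` on the
    result instead of raising.
    """
    S, V, b, _ = _prepare(bulk, signature, min_shared_genes)
    x, _ = nnls(S, b)
    prev = x / max(x.sum(), WEIGHT_EPS)
    n_iter = 0
    converged = False
    for n_iter in range(1, max_iter + 1):
        resid = S @ x - b
        w = 1.0 / (V @ (x**2) + resid**2 + WEIGHT_EPS)
        sw = np.sqrt(w)
        x, _ = nnls(S * sw[:, None], b * sw)
        cur = x / max(x.sum(), WEIGHT_EPS)
        if np.max(np.abs(cur - prev)) < tol:
            converged = True
            break
        prev = cur
    return _as_estimate(x, S, b, signature, n_iter=n_iter, converged=converged)
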