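"""Expression-side statistics around a differential-expression analysis.

Containers are plain pandas objects with a documented orientation:

* expression matrix — DataFrame, genes in rows, samples in columns,
  finite non-negative values (counts or normalized), unique identifiers;
* group design — DataFrame indexed by sample with columns ``line``,
  ``protocol`` and ``replicate`` describing the (line x protocol) factors;
* marker panel — DataFrame with columns ``gene`` and optional
  ``direction`` in {"up", "down"} (missing direction means "up").

The operations are the surrounding steps of a bulk RNA-seq comparison:
CPM-based low-expression filtering, Benjamini-Hochberg adjustment, row
Z-scores for heatmaps, marker-panel scores, ddCt relative qPCR
quantification and balanced two-way fixed-effects ANOVA.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "AnovaResult",
    "validate_expression_matrix",
    "validate_design",
    "filter_low_expression",
    "bh_adjust",
    "row_zscore",
    "marker_panel_score",
    "two_way_anova",
    "qpcr_relative_expression",
]


def validate_expression_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    if matrix.index.has_duplicates:
        raise ValueError("duplicate gene identifiers")
    if matrix.columns.has_duplicates:
        raise ValueError("duplicate sample identifiers")
    vals = matrix.to_numpy(dtype=float)
    if not np.all(np.isfinite(vals)) or (vals < 0).any():
        raise ValueError("expression values must be finite and >= 0")
    return matrix


def validate_design(design: pd.DataFrame, matrix: Optional[pd.DataFrame] = None
                    ) -> pd.DataFrame:
    for col in ("line", "protocol"):
        if col not in design.columns:
            raise ValueError(f"design is missing the {col!r} column")
    if design.index.has_duplicates:
        raise ValueError("duplicate samples in design")
    if matrix is not None:
        missing = set(matrix.columns) - set(design.index)
        if missing:
            raise ValueError(f"samples absent from design: {sorted(missing)}")
    return design


def filter_low_expression(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    cpm_cutoff: float = 1.0,
    min_samples: Union[str, int] = "auto",
) -> pd.DataFrame:
    """Drop genes that never reach ``cpm_cutoff`` CPM in enough samples.

    A gene is kept iff its CPM (counts scaled to library size x 1e6) is at
    least ``cpm_cutoff`` in at least ``k`` samples; ``k`` defaults to the
    smallest (line, protocol) group size — a documented, explicit stand-in
    for the cited count filter. Gene order is preserved.
    """
    validate_expression_matrix(counts)
    validate_design(design, counts)
    lib = counts.sum(axis=0)
    zero = lib[lib <= 0]
    if len(zero):
        raise ValueError(f"zero library size for sample(s): {list(zero.index)}")
    if min_samples == "auto":
        groups = design.loc[counts.columns].groupby(["line", "protocol"],
                                                    observed=True).size()
        k = int(groups.min())
    else:
        k = int(min_samples)
        if k < 1:
            raise ValueError("min_samples must be >= 1")
    cpm = counts.div(lib, axis=1) * 1e6
    keep = (cpm >= cpm_cutoff).sum(axis=1) >= k
    return counts.loc[keep]


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    q_(i) = min_{j >= i} p_(j) * m / j over the sorted p-values, clipped
    at 1 and mapped back to the original positions.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be one-dimensional")
    if not np.all(np.isfinite(p)) or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must be finite and within [0, 1]")
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m, dtype=float)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def row_zscore(matrix: pd.DataFrame) -> pd.DataFrame:
    """Center each gene row by its mean and scale by its sd (ddof=1).

    Constant rows map to all-zeros. This is the transform behind the
    expression heatmaps; it requires at least two samples.
    """
    if matrix.shape[1] < 2:
        raise ValueError("row Z-scores need at least 2 samples")
    vals = matrix.to_numpy(dtype=float)
    mean = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, ddof=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (vals - mean) / sd
    z[np.repeat(sd == 0, vals.shape[1], axis=1)] = 0.0
    return pd.DataFrame(z, index=matrix.index, columns=matrix.columns)


def marker_panel_score(
    matrix: pd.DataFrame, panel: pd.DataFrame
) -> tuple[pd.Series, list[str]]:
    """Mean row-Z-score over a marker panel, per sample.

    ``panel`` holds a ``gene`` column and an optional ``direction`` column;
    "down" genes enter with flipped sign, so a high score always means
    "towards the panel's phenotype". Returns the per-sample scores and the
    list of panel genes actually found in the matrix; genes absent from the
    matrix are skipped (an empty intersection is an error).
    """
    if "gene" not in panel.columns:
        raise ValueError("panel must have a 'gene' column")
    genes = panel["gene"].astype(str)
    if genes.duplicated().any():
        raise ValueError("panel genes must be unique")
    if len(genes) == 0:
        raise ValueError("panel is empty")
    direction = (
        panel["direction"].astype(str).str.lower()
        if "direction" in panel.columns
        else pd.Series("up", index=panel.index)
    )
    bad = ~direction.isin(["up", "down"])
    if bad.any():
        raise ValueError(f"invalid panel directions: {direction[bad].tolist()}")
    present = genes[genes.isin(matrix.index)]
    if present.empty:
        raise ValueError("no panel gene is present in the matrix")
    z = row_zscore(matrix.loc[present])
    signs = np.where(direction[present.index] == "down", -1.0, 1.0)
    scores = pd.Series(
        (z.to_numpy() * signs[:, None]).mean(axis=0),
        index=matrix.columns,
        name="panel_score",
    )
    return scores, present.tolist()


@dataclass(frozen=True)
class AnovaResult:
    """Fixed-effects two-way ANOVA table for one response variable."""

    f_a: float
    p_a: float
    df_a: int
    f_b: float
    p_b: float
    df_b: int
    f_ab: float
    p_ab: float
    df_ab: int
    df_resid: int
    ms_resid: float

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "F": [self.f_a, self.f_b, self.f_ab],
                "p": [self.p_a, self.p_b, self.p_ab],
                "df": [self.df_a, self.df_b, self.df_ab],
            },
            index=["factor_a", "factor_b", "interaction"],
        )


def two_way_anova(
    values: Sequence[float],
    factor_a: Sequence,
    factor_b: Sequence,
) -> AnovaResult:
    """Balanced fixed-effects two-way ANOVA with interaction.

    The classical decomposition SS_A + SS_B + SS_AB + SS_resid is computed
    from cell means; on a balanced complete design all sums-of-squares
    types coincide, which is why unbalanced designs are rejected rather
    than silently picking a type. Each cell needs n >= 2 for a residual
    df; zero residual variance is rejected (F undefined).
    """
    y = np.asarray(values, dtype=float)
    a = pd.Categorical(factor_a)
    b = pd.Categorical(factor_b)
    if not (len(y) == len(a) == len(b)):
        raise ValueError("values and factor labels must have equal length")
    if not np.all(np.isfinite(y)):
        raise ValueError("values must be finite")
    counts = pd.crosstab(a, b)
    if counts.shape[0] < 2 or counts.shape[1] < 2:
        raise ValueError("both factors need at least 2 levels")
    n_cell = counts.to_numpy()
    if (n_cell != n_cell[0, 0]).any():
        raise ValueError(
            "unbalanced design: every (A, B) cell must have the same count; "
            "rebalance the groups before calling"
        )
    n = int(n_cell[0, 0])
    if n < 2:
        raise ValueError("each cell needs n >= 2 for a residual term")

    df_ = pd.DataFrame({"y": y, "a": a, "b": b})
    grand = y.mean()
    I, J = counts.shape
    mean_a = df_.groupby("a", observed=True)["y"].mean()
    mean_b = df_.groupby("b", observed=True)["y"].mean()
    mean_ab = df_.groupby(["a", "b"], observed=True)["y"].mean()

    ss_a = n * J * float(((mean_a - grand) ** 2).sum())
    ss_b = n * I * float(((mean_b - grand) ** 2).sum())
    cell_mean = df_.join(mean_ab.rename("m"), on=["a", "b"])["m"].to_numpy()
    ss_resid = float(((y - cell_mean) ** 2).sum())
    ss_cells = n * float(
        ((mean_ab - grand) ** 2).sum()
    )
    ss_ab = ss_cells - ss_a - ss_b

    df_a, df_b = I - 1, J - 1
    df_ab = df_a * df_b
    df_resid = I * J * (n - 1)
    ms_resid = ss_resid / df_resid
    if ms_resid <= 0:
        raise ValueError("zero residual variance: F statistics undefined")

    def f_p(ss: float, df: int) -> tuple[float, float]:
        f = max(ss, 0.0) / df / ms_resid
        return f, float(sps.f.sf(f, df, df_resid))

    f_a, p_a = f_p(ss_a, df_a)
    f_b, p_b = f_p(ss_b, df_b)
    f_ab, p_ab = f_p(ss_ab, df_ab)
    return AnovaResult(
        f_a=f_a, p_a=p_a, df_a=df_a,
        f_b=f_b, p_b=p_b, df_b=df_b,
        f_ab=f_ab, p_ab=p_ab, df_ab=df_ab,
        df_resid=df_resid, ms_resid=ms_resid,
    )


def qpcr_relative_expression(
    ct: pd.DataFrame,
    targets: Sequence[str],
    housekeeping: Sequence[str] = ("ACTB", "L27"),
    reference_group: str = "LSF",
    design: Optional[pd.DataFrame] = None,
    group_column: str = "protocol",
) -> pd.DataFrame:
    """ddCt relative quantification against housekeeping genes.

    ``ct`` is a tidy table with columns ``sample``, ``gene``, ``ct``. For
    each target, dCt = Ct_target - mean(Ct over housekeeping genes), then
    ddCt subtracts the mean dCt of the reference group (samples whose
    ``group_column`` in ``design`` equals ``reference_group``), and
    RQ = 2**(-ddCt). Amplification efficiency is assumed to be 100%
    (a doubling per cycle). Returns a tidy frame with columns ``sample``,
    ``gene``, ``delta_ct``, ``delta_delta_ct``, ``rq``.
    """
    for col in ("sample", "gene", "ct"):
        if col not in ct.columns:
            raise ValueError(f"ct table is missing column {col!r}")
    if not np.all(np.isfinite(ct["ct"].to_numpy(dtype=float))):
        raise ValueError("Ct values must be finite")
    wide = ct.pivot_table(index="sample", columns="gene", values="ct",
                          aggfunc="mean")
    for hk in housekeeping:
        if hk not in wide.columns:
            raise ValueError(f"housekeeping gene {hk!r} absent from Ct table")
        missing = wide.index[wide[hk].isna()]
        if len(missing):
            raise ValueError(
                f"missing housekeeping Ct for gene {hk!r} in sample(s) "
                f"{list(missing)}"
            )
    hk_mean = wide[list(housekeeping)].mean(axis=1)

    if design is None:
        raise ValueError("a design table is required to define the reference group")
    if group_column not in design.columns:
        raise ValueError(f"design is missing the {group_column!r} column")
    ref_samples = design.index[design[group_column] == reference_group]
    ref_samples = [s for s in ref_samples if s in wide.index]
    if not ref_samples:
        raise ValueError(
            f"no sample of the reference group {reference_group!r} in the Ct table"
        )

    rows = []
    for gene in targets:
        if gene not in wide.columns:
            raise ValueError(f"target gene {gene!r} absent from Ct table")
        dct = wide[gene] - hk_mean
        missing = dct.index[dct.isna()]
        if len(missing):
            raise ValueError(
                f"missing Ct for target {gene!r} in sample(s) {list(missing)}"
            )
        ref_mean = dct.loc[ref_samples].mean()
        ddct = dct - ref_mean
        for sample in wide.index:
            rows.append(
                dict(
                    sample=sample,
                    gene=gene,
                    delta_ct=float(dct[sample]),
                    delta_delta_ct=float(ddct[sample]),
                    rq=float(2.0 ** (-ddct[sample])),
                )
            )
    return pd.DataFrame(rows, columns=["sample", "gene", "delta_ct",
                                       "delta_delta_ct", "rq"])
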