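"""Group-difference regression on quartile summaries with BH-FDR correction.

For every (component pair, quartile, measure) the subject-level summary is
regressed on diagnosis, sex, and their interaction:

    y = b0 + b1*dx + b2*sex + b3*dx*sex + e,   dx: SZ = 1, HC = 0;  sex: M = 1, F = 0

Each of the three contrasts (diagnosis, sex, interaction) is the two-sided
t-test of the corresponding coefficient in this joint model, with n - p
degrees of freedom.  Under this coding a negative t means HC (or F)
dominance.  p-values are corrected per displayed matrix — the family is
the set of component pairs within one (quartile, measure, contrast) — by
the Benjamini-Hochberg step-up procedure, and group differences are
rendered as C x C signed-log-p matrices: upper triangle masked at
uncorrected p <= alpha, lower triangle masked by the FDR decision.

The OLS path is a vectorized multi-response least-squares solve (many
thousands of small identical-design regressions per run); it is verified
against statsmodels in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .io_core import CohortMetadata, ValidationError
from .quartiles import MEASURES

CONTRASTS = ("diagnosis", "sex", "interaction")
_CONTRAST_COL = {"diagnosis": 1, "sex": 2, "interaction": 3}


@dataclass
class DesignMatrix:
    """Intercept + diagnosis + sex + interaction design (optionally extra covariates)."""

    X: np.ndarray
    columns: list[str]

    @property
    def n(self) -> int:
        return self.X.shape[0]


def build_design(metadata: CohortMetadata, extra: pd.DataFrame | None = None) -> DesignMatrix:
    """Build the regression design from cohort metadata.

    Requires every diagnosis x sex cell to be occupied (otherwise the
    interaction column is collinear); raises naming the empty cell.
    """
    dx = (metadata.diagnosis == "SZ").astype(float)
    sex = (metadata.sex == "M").astype(float)
    for d in (0, 1):
        for s in (0, 1):
            if not np.any((dx == d) & (sex == s)):
                raise ValidationError(
                    f"empty design cell: diagnosis={'SZ' if d else 'HC'}, sex={'M' if s else 'F'}"
                )
    cols = [np.ones_like(dx), dx, sex, dx * sex]
    names = ["intercept", "dx", "sex", "dx_sex"]
    if extra is not None:
        for c in extra.columns:
            cols.append(extra[c].to_numpy(dtype=float))
            names.append(str(c))
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValidationError("design matrix is rank deficient")
    return DesignMatrix(X=X, columns=names)


def fit_pair_regression(values: np.ndarray, design: DesignMatrix) -> pd.DataFrame:
    """OLS fit of one response; returns beta/t/p per contrast.

    ``values`` is the per-subject vector of one (pair, quartile, measure)
    summary.  Thin wrapper over :func:`fit_many` for the single-response case.
    """
    beta, t, p = fit_many(np.asarray(values, float).reshape(-1, 1), design)
    return pd.DataFrame(
        {
            "contrast": list(CONTRASTS),
            "beta": [beta[_CONTRAST_COL[c], 0] for c in CONTRASTS],
            "t": [t[_CONTRAST_COL[c], 0] for c in CONTRASTS],
            "p": [p[_CONTRAST_COL[c], 0] for c in CONTRASTS],
        }
    )


def fit_many(Y: np.ndarray, design: DesignMatrix) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized OLS of many responses sharing one design.

    ``Y`` is (n_subjects, n_responses); returns ``(beta, t, p)`` each of
    shape (n_coefficients, n_responses).  Two-sided t-tests with n - p
    degrees of freedom.
    """
    X = design.X
    n, k = X.shape
    if Y.shape[0] != n:
        raise ValidationError(f"response length {Y.shape[0]} != design rows {n}")
    if n - k < 1:
        raise ValidationError(f"need more subjects than coefficients (n={n}, p={k})")
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ (X.T @ Y)
    resid = Y - X @ beta
    df = n - k
    sigma2 = (resid**2).sum(axis=0) / df
    se = np.sqrt(np.outer(np.diag(xtx_inv), sigma2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, np.where(beta == 0, 0.0, np.inf * np.sign(beta)))
    p = 2 * sps.t.sf(np.abs(t), df)
    np.clip(p, np.finfo(float).tiny, 1.0, out=p)
    return beta, t, p


def bh_fdr(pvalues: np.ndarray, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjusted p-values and rejection flags."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValidationError("p-values must lie in (0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return p_adj, reject


def fit_all(
    summaries: pd.DataFrame,
    metadata: CohortMetadata,
    alpha: float = 0.05,
    extra: pd.DataFrame | None = None,
    fdr_family: str = "per-matrix",
) -> pd.DataFrame:
    """Regression over every (pair, quartile, measure); returns the full result table.

    Columns: pair_i, pair_j, quartile, measure, contrast, beta, t, p,
    p_fdr, reject_fdr, signed_logp.  ``fdr_family`` is ``"per-matrix"``
    (correct within each quartile x measure x contrast, as the difference
    matrices are displayed) or ``"pooled"`` (one family across all rows).
    """
    if fdr_family not in ("per-matrix", "pooled"):
        raise ValidationError(f"fdr_family must be 'per-matrix' or 'pooled', got {fdr_family!r}")
    design = build_design(metadata, extra=extra)
    subjects = list(metadata.table["subject_id"])
    wide = summaries.pivot_table(
        index="subject",
        columns=["pair_i", "pair_j", "quartile"],
        values=list(MEASURES),
        sort=True,
    ).loc[subjects]
    # column multiindex: (measure, pair_i, pair_j, quartile)
    Y = wide.to_numpy(dtype=float)
    beta, t, p = fit_many(Y, design)
    rows = []
    for ci, (measure, pi, pj, q) in enumerate(wide.columns):
        for contrast in CONTRASTS:
            k = _CONTRAST_COL[contrast]
            rows.append((int(pi), int(pj), int(q), measure, contrast, beta[k, ci], t[k, ci], p[k, ci]))
    res = pd.DataFrame(
        rows, columns=["pair_i", "pair_j", "quartile", "measure", "contrast", "beta", "t", "p"]
    )
    res["p_fdr"] = np.nan
    res["reject_fdr"] = False
    if fdr_family == "pooled":
        adj, rej = bh_fdr(res["p"].to_numpy(), alpha)
        res["p_fdr"], res["reject_fdr"] = adj, rej
    else:
        for _, idx in res.groupby(["quartile", "measure", "contrast"], sort=False).groups.items():
            adj, rej = bh_fdr(res.loc[idx, "p"].to_numpy(), alpha)
            res.loc[idx, "p_fdr"] = adj
            res.loc[idx, "reject_fdr"] = rej
    res["signed_logp"] = -np.log10(res["p"]) * np.sign(res["t"])
    return res.sort_values(
        ["quartile", "measure", "contrast", "pair_i", "pair_j"], kind="mergesort"
    ).reset_index(drop=True)


def difference_matrices(
    results: pd.DataFrame, alpha: float, n_components: int
) -> dict[tuple[int, str, str], np.ndarray]:
    """Signed -log10(p) group-difference matrices.

    One C x C matrix per (quartile, measure, contrast): the upper triangle
    holds signed_logp where the uncorrected p <= alpha (else 0), the lower
    triangle holds signed_logp where the BH-FDR decision passes (else 0).
    Diagonal is 0.  Negative entries mean HC (or F) dominance.
    """
    expected = len(component_pairs_index(n_components))
    out: dict[tuple[int, str, str], np.ndarray] = {}
    for (q, measure, contrast), sub in results.groupby(["quartile", "measure", "contrast"], sort=True):
        if len(sub) != expected:
            raise ValidationError(
                f"incomplete results for quartile {q} {measure}/{contrast}: "
                f"{len(sub)} of {expected} pairs"
            )
        mat = np.zeros((n_components, n_components))
        ii = sub["pair_i"].to_numpy()
        jj = sub["pair_j"].to_numpy()
        slp = sub["signed_logp"].to_numpy()
        upper = np.where(sub["p"].to_numpy() <= alpha, slp, 0.0)
        lower = np.where(sub["reject_fdr"].to_numpy(), slp, 0.0)
        mat[ii, jj] = upper
        mat[jj, ii] = lower
        out[(int(q), str(measure), str(contrast))] = mat
    return out


def component_pairs_index(n_components: int) -> list[tuple[int, int]]:
    from .coupling import component_pairs

    return component_pairs(n_components)


def render_heatmap(
    matrix: np.ndarray,
    path: str,
    component_ids: list[str] | None = None,
    title: str = "",
) -> None:
    """Render a signed-log-p difference matrix as a diverging heatmap.

    Red encodes negative values (HC/F dominance), blue positive (SZ/M),
    symmetric about zero.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    mat = np.asarray(matrix, dtype=float)
    lim = np.nanmax(np.abs(mat)) or 1.0
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(mat, cmap="RdBu", vmin=-lim, vmax=lim)
    if component_ids is not None:
        ax.set_xticks(range(len(component_ids)), component_ids, rotation=90, fontsize=6)
        ax.set_yticks(range(len(component_ids)), component_ids, fontsize=6)
    if title:
        ax.set_title(title, fontsize=10)
    fig.colorbar(im, ax=ax, label="-log10(p) x sign(t)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
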