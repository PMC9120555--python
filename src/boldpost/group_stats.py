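"""Mixed-effects group-level inference tolerant of voxel-wise missingness.

The model at each voxel is the two-level summary-statistics model

    y_i ~ N(x_i' beta, s_i^2 + sigma_b^2)

where y_i is subject i's first-level effect, s_i^2 its first-level
(within-subject) variance, and sigma_b^2 the between-subject variance,
estimated by maximizing its marginal posterior (regression coefficients
integrated out under a flat prior) with sigma_b^2 constrained
non-negative — the FLAME stage-1 fast approximation.  Because brain coverage varies
across subjects, a reduced design matrix is built per voxel from exactly
the subjects with a measurable value there, under the assumption that
voxels are missing completely at random (MCAR).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

from .features import StatMap

__all__ = [
    "CovariateTable",
    "GroupDesign",
    "FlameFit",
    "build_design",
    "lsmeans_contrasts",
    "flame1_fit",
    "fit_voxelwise",
    "exclude_by_motion",
    "fdr_correct",
]


@dataclass
class CovariateTable:
    """Subject covariates with declared column types.

    ``types`` maps each column name to ``"continuous"`` or
    ``"categorical"``; missing cells are allowed (NaN).
    """

    frame: pd.DataFrame
    types: dict[str, str]

    def __post_init__(self) -> None:
        self.frame = pd.DataFrame(self.frame)
        if self.frame.index.has_duplicates:
            raise ValueError("subject keys must be unique")
        for col, kind in self.types.items():
            if kind not in ("continuous", "categorical"):
                raise ValueError(f"column {col!r} has unknown type {kind!r}")
            if col not in self.frame.columns:
                raise ValueError(f"typed column {col!r} not in table")


@dataclass
class GroupDesign:
    """A group-level design matrix with named columns and contrasts.

    Continuous columns are demeaned; categorical factors are expanded to
    cell-indicator columns (cell-means coding), so group contrasts act
    directly on cell means.
    """

    matrix: np.ndarray
    columns: list[str]
    subjects: list
    factor_levels: dict[str, list[str]]
    continuous: list[str]
    missing_strategy: str = "listwise"

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def p(self) -> int:
        return self.matrix.shape[1]


@dataclass
class FlameFit:
    """Voxel-wise group fit: effect, between-subject variance, z, and the
    per-voxel count of contributing subjects."""

    effect: np.ndarray
    between_var: np.ndarray
    z: np.ndarray
    n_included: np.ndarray
    coverage: np.ndarray


# ---------------------------------------------------------------------------
# design construction


def _parse_terms(spec: str) -> list[list[str]]:
    spec = spec.strip()
    if spec in ("", "1"):
        return []
    terms = [t.strip() for t in spec.split("+") if t.strip()]
    return [[v.strip() for v in term.split(":")] for term in terms]


def build_design(
    cov: CovariateTable,
    spec: str,
    missing_strategy: str = "listwise",
) -> GroupDesign:
    """Build a flexible-factorial design matrix from a covariate table.

    ``spec`` lists main effects and interactions, e.g. ``"group + age"``
    or ``"group + age + group:age"``; ``"1"`` gives an intercept-only
    design.  Categorical main effects are crossed into cell-indicator
    columns (no separate intercept); continuous covariates are demeaned.

    Missing covariate cells are handled by ``missing_strategy``:
    ``listwise`` drops the subject; ``mean-substitution`` sets the cell to
    zero *after* demeaning, which is equivalent to imputing the sample
    mean of the observed values.
    """
    if missing_strategy not in ("listwise", "mean-substitution"):
        raise ValueError(f"unknown missing strategy {missing_strategy!r}")
    terms = _parse_terms(spec)
    referenced: list[str] = []
    for term in terms:
        for v in term:
            if v not in cov.frame.columns:
                raise ValueError(f"column {v!r} not in covariate table")
            if v not in referenced:
                referenced.append(v)

    frame = cov.frame.copy()
    cat_cols = [v for v in referenced if cov.types.get(v) == "categorical"]
    cont_cols = [v for v in referenced if cov.types.get(v) != "categorical"]

    if missing_strategy == "listwise" and referenced:
        keep = frame[referenced].notna().all(axis=1)
        frame = frame.loc[keep]
        if frame.empty:
            raise ValueError("no subjects left after listwise deletion")
    if cat_cols and frame[cat_cols].isna().any().any():
        # a categorical level cannot be mean-substituted
        keep = frame[cat_cols].notna().all(axis=1)
        frame = frame.loc[keep]
        if frame.empty:
            raise ValueError("no subjects left after dropping missing factor levels")

    subjects = list(frame.index)
    n = len(subjects)
    columns: list[str] = []
    mats: list[np.ndarray] = []
    factor_levels: dict[str, list[str]] = {}

    # cell-means coding over the cross of all categorical main effects
    cat_mains = [t[0] for t in terms if len(t) == 1 and t[0] in cat_cols]
    if cat_mains:
        for v in cat_mains:
            factor_levels[v] = sorted(frame[v].astype(str).unique())
        cells = list(itertools.product(*(factor_levels[v] for v in cat_mains)))
        for cell in cells:
            ind = np.ones(n)
            for v, lvl in zip(cat_mains, cell):
                ind *= (frame[v].astype(str) == lvl).to_numpy(dtype=float)
            if ind.sum() == 0:
                continue  # empty cell
            columns.append("cell[" + ".".join(f"{v}={lvl}" for v, lvl in zip(cat_mains, cell)) + "]")
            mats.append(ind)
    else:
        columns.append("intercept")
        mats.append(np.ones(n))

    demeaned: dict[str, np.ndarray] = {}
    for v in cont_cols:
        vals = frame[v].to_numpy(dtype=float)
        observed = np.isfinite(vals)
        if observed.sum() == 0:
            raise ValueError(f"covariate {v!r} has no observed values")
        centred = vals - vals[observed].mean()
        if missing_strategy == "mean-substitution":
            centred = np.where(observed, centred, 0.0)
        demeaned[v] = centred

    for term in terms:
        if len(term) == 1:
            v = term[0]
            if v in cat_cols:
                continue  # handled by cell coding
            columns.append(v)
            mats.append(demeaned[v])
        else:
            cats = [v for v in term if v in cat_cols]
            conts = [v for v in term if v not in cat_cols]
            if len(cats) == 1 and len(conts) == 1:
                fac, con = cats[0], conts[0]
                levels = factor_levels.get(fac) or sorted(frame[fac].astype(str).unique())
                factor_levels.setdefault(fac, levels)
                for lvl in levels:
                    ind = (frame[fac].astype(str) == lvl).to_numpy(dtype=float)
                    columns.append(f"{fac}={lvl}:{con}")
                    mats.append(ind * demeaned[con])
            elif not cats:
                prod = np.ones(n)
                for v in conts:
                    prod = prod * demeaned[v]
                columns.append(":".join(conts))
                mats.append(prod)
            else:
                raise ValueError(
                    f"unsupported interaction {':'.join(term)}; categorical-by-"
                    "categorical interactions are expressed through crossed cells"
                )

    matrix = np.column_stack(mats)
    if matrix.shape[0] < 1:
        raise ValueError("empty design")
    return GroupDesign(
        matrix=matrix,
        columns=columns,
        subjects=subjects,
        factor_levels=factor_levels,
        continuous=cont_cols,
        missing_strategy=missing_strategy,
    )


def lsmeans_contrasts(design: GroupDesign, factor: str) -> tuple[np.ndarray, list[str]]:
    """Pairwise between-level contrasts for a factor, lsmeans style.

    Each row compares two levels of ``factor`` at the mean of all
    continuous covariates (demeaned, so weight 0) with balanced weights
    over the other factors' cells.  Rows sum to zero over the factor's
    indicator columns.  Returns ``(contrast matrix, row labels)``.
    """
    if factor not in design.factor_levels:
        raise ValueError(f"{factor!r} is not a categorical factor in this design")
    levels = design.factor_levels[factor]
    if len(levels) < 2:
        raise ValueError(f"factor {factor!r} has a single level")
    rows = []
    labels = []
    for a, b in itertools.combinations(levels, 2):
        c = np.zeros(design.p)
        for sign, lvl in ((1.0, a), (-1.0, b)):
            cols = [
                j for j, name in enumerate(design.columns)
                if name.startswith("cell[") and f"{factor}={lvl}" in name
            ]
            if not cols:
                raise ValueError(f"no design cells found for {factor}={lvl}")
            for j in cols:
                c[j] = sign / len(cols)
        rows.append(c)
        labels.append(f"{factor}:{a}-{b}")
    return np.asarray(rows), labels


# ---------------------------------------------------------------------------
# FLAME stage 1


def _neg_marginal_loglik(sigma_b2: float, y: np.ndarray, s2: np.ndarray, X: np.ndarray) -> float:
    """Negative log marginal posterior of sigma_b^2 with beta integrated out.

    Under a flat prior on the regression coefficients, integrating beta
    out of the Gaussian likelihood leaves (up to a constant)

        -log p(sigma_b^2 | y) = 0.5 [ log|V| + log|X' V^-1 X| + r' V^-1 r ]

    with V = diag(s^2) + sigma_b^2 I and r the GLS residuals — the
    restricted-likelihood form.  Profiling beta instead (plain ML) drops
    the log|X' V^-1 X| term and shrinks the variance estimate by roughly
    (n - p)/n, which measurably inflates the false positive rate at small
    n; the integrated form is what the FLAME fast approximation searches.
    """
    v = np.maximum(s2 + sigma_b2, 1e-300)
    w = 1.0 / v
    xtwx = X.T @ (X * w[:, None])
    xtwy = X.T @ (y * w)
    beta = np.linalg.solve(xtwx, xtwy)
    r = y - X @ beta
    sign, logdet_xtwx = np.linalg.slogdet(xtwx)
    if sign <= 0:
        return np.inf
    return 0.5 * float(np.sum(np.log(v)) + logdet_xtwx + np.sum(r**2 * w))


def flame1_fit(
    effects: np.ndarray,
    within_vars: np.ndarray,
    X: np.ndarray,
    contrast: np.ndarray,
) -> tuple[float, float, float, int] | None:
    """FLAME stage-1 fit at one voxel.

    Maximizes the marginal posterior of sigma_b^2 (coefficients
    integrated out under a flat prior) for ``effects ~ N(X beta,
    diag(within_vars) + sigma_b^2 I)`` over sigma_b^2 >= 0 by bounded
    scalar search, then solves beta by weighted least squares at the
    optimum.  With all within-variances zero and an intercept-only
    design this reduces to the sample mean and the n-1 sample variance.
    The contrast's t-value (variance c'(X'V^-1 X)^-1 c, dof =
    n - rank(X)) is mapped to a z-value by matching tail probabilities.

    Returns ``(effect, between_var, z, dof)`` or None when fewer than
    p + 1 subjects are available (the voxel is then reported missing
    rather than failing).
    """
    y = np.asarray(effects, dtype=float)
    s2 = np.asarray(within_vars, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    c = np.asarray(contrast, dtype=float)
    n, p = X.shape
    if n < p + 1:
        return None
    if (s2 < 0).any():
        raise ValueError("within-subject variances must be non-negative")
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        return None

    sample_var = float(np.var(y))
    upper = max(10.0 * sample_var, 10.0 * float(s2.mean() + 1e-12), 1e-6)
    if sample_var == 0 and s2.max() == 0:
        sigma_b2 = 0.0
    else:
        res = optimize.minimize_scalar(
            _neg_marginal_loglik,
            bounds=(0.0, upper),
            args=(y, s2, X),
            method="bounded",
            options={"xatol": 1e-10},
        )
        sigma_b2 = float(res.x)
        # the bounded optimum may sit just inside the boundary; snap to 0
        if _neg_marginal_loglik(0.0, y, s2, X) <= res.fun + 1e-12:
            sigma_b2 = 0.0

    v = np.maximum(s2 + sigma_b2, 1e-12)
    w = 1.0 / v
    xtwx = X.T @ (X * w[:, None])
    xtwx_inv = np.linalg.inv(xtwx)
    beta = xtwx_inv @ (X.T @ (y * w))
    effect = float(c @ beta)
    cvar = float(c @ xtwx_inv @ c)
    dof = n - rank
    if cvar <= 0:
        z = 0.0
    else:
        tval = effect / np.sqrt(cvar)
        z = _t_to_z(tval, dof)
    return effect, sigma_b2, z, dof


def _t_to_z(tval: float, dof: int) -> float:
    """Map a t-value to a z-value with the same upper-tail probability."""
    if dof <= 0:
        return 0.0
    logp = stats.t.logsf(abs(tval), dof)
    z = stats.norm.isf(np.exp(np.clip(logp, -700, 0)))
    if not np.isfinite(z):
        z = -stats.norm.ppf(np.exp(logp)) if logp > -700 else np.sqrt(-2 * logp)
    return float(np.sign(tval) * z)


def fit_voxelwise(
    stack: list[StatMap],
    design: GroupDesign,
    contrast: np.ndarray,
) -> FlameFit:
    """Fit the group model at every voxel with per-voxel listwise deletion.

    At each voxel, only subjects whose coverage is true contribute; the
    design matrix is subset to those rows before fitting.  Voxels with too
    few subjects (or where the reduced design loses rank) are marked
    missing in the output rather than raising.
    """
    n = len(stack)
    if n != design.n:
        raise ValueError(f"{n} stat maps but design has {design.n} rows")
    shape = stack[0].effect.shape
    for sm in stack:
        if sm.effect.shape != shape:
            raise ValueError("all stat maps must share a grid")
    effects = np.stack([sm.effect for sm in stack], axis=-1)
    variances = np.stack([sm.variance for sm in stack], axis=-1)
    coverage = np.stack([sm.coverage for sm in stack], axis=-1)

    out_effect = np.full(shape, np.nan)
    out_bvar = np.full(shape, np.nan)
    out_z = np.full(shape, np.nan)
    out_n = np.zeros(shape, dtype=int)
    out_cov = np.zeros(shape, dtype=bool)

    candidate = np.argwhere(coverage.any(axis=-1))
    if candidate.size == 0:
        raise ValueError("no voxel has coverage in any subject")
    any_fit = False
    for (x, y, z) in candidate:
        inc = coverage[x, y, z]
        out_n[x, y, z] = int(inc.sum())
        fit = flame1_fit(
            effects[x, y, z, inc],
            variances[x, y, z, inc],
            design.matrix[inc],
            contrast,
        )
        if fit is None:
            continue
        eff, bvar, zval, _ = fit
        out_effect[x, y, z] = eff
        out_bvar[x, y, z] = bvar
        out_z[x, y, z] = zval
        out_cov[x, y, z] = True
        any_fit = True
    if not any_fit:
        raise ValueError("zero voxels estimable under the design")
    return FlameFit(out_effect, out_bvar, out_z, out_n, out_cov)


# ---------------------------------------------------------------------------
# motion-based exclusion and FDR


def exclude_by_motion(
    subjects: list,
    qc_summaries: dict,
    max_mean_fd: float,
    max_outlier_pct: float,
) -> tuple[list, dict]:
    """Exclude scans over the motion limits; equality at a limit includes.

    ``qc_summaries`` maps subject -> {"mean_fd": mm, "outlier_pct": %}.
    "Maximum allowed" includes the maximum, so only strictly greater
    values exclude.  Returns ``(included subjects, reasons for excluded)``.
    """
    if max_mean_fd <= 0 or max_outlier_pct <= 0:
        raise ValueError("thresholds must be positive")
    included = []
    reasons: dict = {}
    for subj in subjects:
        summary = qc_summaries.get(subj)
        if summary is None:
            reasons[subj] = "no QC summary available"
            continue
        why = []
        if summary["mean_fd"] > max_mean_fd:
            why.append(f"mean FD {summary['mean_fd']:.3f} > {max_mean_fd:g} mm")
        if summary["outlier_pct"] > max_outlier_pct:
            why.append(f"outlier frames {summary['outlier_pct']:.1f}% > {max_outlier_pct:g}%")
        if why:
            reasons[subj] = "; ".join(why)
        else:
            included.append(subj)
    return included, reasons


def fdr_correct(z_map: np.ndarray, coverage: np.ndarray, q: float = 0.05):
    """Benjamini-Hochberg FDR over in-coverage voxels of a z map.

    Two-sided p-values from the standard normal; returns ``(significance
    mask, p-value threshold)`` where the threshold is the largest p-value
    declared significant (0 if none).
    """
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    coverage = np.asarray(coverage, dtype=bool)
    if not coverage.any():
        raise ValueError("empty coverage")
    z = np.asarray(z_map, dtype=float)[coverage]
    p = 2.0 * stats.norm.sf(np.abs(z))
    reject, _, _, _ = multipletests(p, alpha=q, method="fdr_bh")[:4]
    mask = np.zeros_like(coverage)
    mask[coverage] = reject
    threshold = float(p[reject].max()) if reject.any() else 0.0
    return mask, threshold
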