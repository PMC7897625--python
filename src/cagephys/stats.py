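"""Group-comparison machinery for behavioral and electrophysiological data.

Implements the statistical layer applied to time courses and summary
measures: two-way ANOVA (between-subjects, or split-plot with one
repeated factor and Huynh-Feldt sphericity correction), Šidák-adjusted
post hoc p values, unpaired two-tailed t tests on per-animal AUCs, and
ordination of the behavioral feature table by PCA and canonical
discriminant analysis.

Conventions: unpaired t tests are Student's (equal variance), matching
the reporting style of the source analyses, with a Welch variant behind
a flag; the Huynh-Feldt epsilon is clipped at 1 and Greenhouse-Geisser
is not offered; features are z-scored per column before any
decomposition so counts and durations mix unitlessly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.formula.api import ols

__all__ = [
    "EffectResult",
    "AnovaResult",
    "OrdinationResult",
    "two_way_anova",
    "huynh_feldt_epsilon",
    "posthoc_sidak",
    "auc_group_test",
    "ordination",
]


@dataclass(frozen=True)
class EffectResult:
    """One F test: statistic, numerator/denominator df, p value."""

    F: float
    df1: float
    df2: float
    p: float


@dataclass
class AnovaResult:
    """Two-way decomposition; ``epsilon_hf`` set for repeated designs."""

    factor_a: EffectResult
    factor_b: EffectResult
    interaction: EffectResult
    epsilon_hf: float | None = None
    sums_of_squares: dict[str, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = {
            "factor_a": self.factor_a,
            "factor_b": self.factor_b,
            "interaction": self.interaction,
        }
        return pd.DataFrame(
            {k: [e.F, e.df1, e.df2, e.p] for k, e in rows.items()},
            index=["F", "df1", "df2", "p"],
        ).T


def _check_cells(a: np.ndarray, b: np.ndarray) -> None:
    cells = pd.crosstab(pd.Series(a), pd.Series(b))
    empty = [(ai, bj) for ai in cells.index for bj in cells.columns if cells.loc[ai, bj] < 1]
    if empty:
        raise ValueError(f"empty design cell(s): {empty}")


def huynh_feldt_epsilon(wide: pd.DataFrame, n_groups: int = 1) -> float:
    """Huynh-Feldt epsilon from the subject x level response matrix.

    ``wide`` has one row per subject and one column per within-subject
    level.  The Greenhouse-Geisser estimate is computed from the
    orthonormally-contrasted covariance of the responses and then
    corrected to Huynh-Feldt (Lecoutre form for multi-group designs);
    the result is clipped to (0, 1].  Equals 1 under compound symmetry.
    """
    X = np.asarray(wide, dtype=float)
    n, a = X.shape
    if a < 2:
        raise ValueError("need >= 2 within-subject levels")
    S = np.cov(X, rowvar=False, ddof=1)
    # orthonormal contrast basis spanning the differences between levels
    C = np.linalg.qr(np.eye(a) - 1.0 / a)[0][:, : a - 1].T
    M = C @ S @ C.T
    tr = np.trace(M)
    eps_gg = (tr**2) / ((a - 1) * np.trace(M @ M)) if tr > 0 else 1.0
    num = (n - n_groups + 1) * (a - 1) * eps_gg - 2.0
    den = (a - 1) * (n - n_groups - (a - 1) * eps_gg)
    eps_hf = num / den if den > 0 else 1.0
    return float(np.clip(eps_hf, 1.0 / (a - 1), 1.0))


def two_way_anova(
    values: np.ndarray,
    factor_a: np.ndarray,
    factor_b: np.ndarray,
    repeated_on: np.ndarray | None = None,
) -> AnovaResult:
    """Two-way ANOVA with interaction.

    Without ``repeated_on`` this is the classical between-subjects
    crossed design (statsmodels OLS decomposition, type-II sums of
    squares, identical to type I/III on balanced data).

    With ``repeated_on`` (subject identifiers), ``factor_a`` is treated
    as the within-subject factor (e.g. time) and ``factor_b`` as the
    between-subjects factor (e.g. genotype): a split-plot decomposition
    where the group effect is tested against subjects-within-groups and
    the time and interaction effects against the subject-by-time
    residual, with within-factor degrees of freedom multiplied by the
    Huynh-Feldt epsilon when sphericity is in doubt (epsilon is always
    estimated and applied; it is 1 under compound symmetry).
    """
    y = np.asarray(values, dtype=float)
    a = np.asarray(factor_a)
    b = np.asarray(factor_b)
    _check_cells(a, b)

    if repeated_on is None:
        df = pd.DataFrame({"y": y, "A": a.astype(str), "B": b.astype(str)})
        fit = ols("y ~ C(A) * C(B)", data=df).fit()
        tab = sm.stats.anova_lm(fit, typ=2)
        def eff(name: str) -> EffectResult:
            row = tab.loc[name]
            return EffectResult(
                F=float(row["F"]),
                df1=float(row["df"]),
                df2=float(tab.loc["Residual", "df"]),
                p=float(row["PR(>F)"]),
            )
        ss = {
            "A": float(tab.loc["C(A)", "sum_sq"]),
            "B": float(tab.loc["C(B)", "sum_sq"]),
            "AB": float(tab.loc["C(A):C(B)", "sum_sq"]),
            "error": float(tab.loc["Residual", "sum_sq"]),
        }
        return AnovaResult(
            factor_a=eff("C(A)"),
            factor_b=eff("C(B)"),
            interaction=eff("C(A):C(B)"),
            sums_of_squares=ss,
        )

    # --- split-plot (mixed) design -------------------------------------
    subj = np.asarray(repeated_on)
    df = pd.DataFrame({"y": y, "A": a, "B": b, "s": subj})
    wide = df.pivot_table(index="s", columns="A", values="y")
    if wide.isna().any().any():
        raise ValueError("repeated design requires every subject at every level")
    groups = df.groupby("s")["B"].first().loc[wide.index]
    n_sub, n_lev = wide.shape
    n_grp = groups.nunique()

    grand = wide.to_numpy().mean()
    subj_means = wide.mean(axis=1)
    lev_means = wide.mean(axis=0)
    grp_means = subj_means.groupby(groups).mean()
    cell_means = df.pivot_table(index="B", columns="A", values="y")

    ss_total = float(((wide.to_numpy() - grand) ** 2).sum())
    ss_between_subj = float(n_lev * ((subj_means - grand) ** 2).sum())
    counts = groups.value_counts()
    ss_b = float(n_lev * (counts * (grp_means - grand) ** 2).sum())
    ss_subj = ss_between_subj - ss_b
    ss_a = float(n_sub * ((lev_means - grand) ** 2).sum())
    ss_cells = float(
        sum(
            counts[g] * (cell_means.loc[g, lv] - grand) ** 2
            for g in cell_means.index
            for lv in cell_means.columns
        )
    )
    ss_ab = ss_cells - ss_a - ss_b
    ss_err = ss_total - ss_between_subj - ss_a - ss_ab

    df_a = n_lev - 1
    df_b = n_grp - 1
    df_ab = df_a * df_b
    df_subj = n_sub - n_grp
    df_err = df_a * df_subj

    eps = huynh_feldt_epsilon(wide, n_groups=n_grp)

    ms_a, ms_b = ss_a / df_a, ss_b / df_b
    ms_ab, ms_subj, ms_err = ss_ab / df_ab, ss_subj / df_subj, ss_err / df_err
    f_a, f_b, f_ab = ms_a / ms_err, ms_b / ms_subj, ms_ab / ms_err

    def within(F: float, d1: float, d2: float) -> EffectResult:
        return EffectResult(
            F=float(F),
            df1=eps * d1,
            df2=eps * d2,
            p=float(sps.f.sf(F, eps * d1, eps * d2)),
        )

    return AnovaResult(
        factor_a=within(f_a, df_a, df_err),
        factor_b=EffectResult(
            F=float(f_b), df1=df_b, df2=df_subj, p=float(sps.f.sf(f_b, df_b, df_subj))
        ),
        interaction=within(f_ab, df_ab, df_err),
        epsilon_hf=eps,
        sums_of_squares={
            "A": ss_a,
            "B": ss_b,
            "AB": ss_ab,
            "subjects": ss_subj,
            "error": ss_err,
            "total": ss_total,
        },
    )


def posthoc_sidak(p_values: np.ndarray | float, k: int | None = None) -> np.ndarray:
    """Šidák multiplicity adjustment: p_adj = 1 - (1-p)^k, clipped to [0,1].

    ``k`` defaults to the number of p values supplied; k = 1 is the
    identity.
    """
    p = np.atleast_1d(np.asarray(p_values, dtype=float))
    if k is None:
        k = p.size
    if k < 1:
        raise ValueError("k must be >= 1")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    return np.clip(1.0 - (1.0 - p) ** k, 0.0, 1.0)


def auc_group_test(
    aucs_group1: np.ndarray, aucs_group2: np.ndarray, welch: bool = False
) -> tuple[float, float]:
    """Unpaired two-tailed t test on per-animal (or per-slice) AUCs.

    Student's equal-variance test by default; ``welch=True`` for the
    unequal-variance variant.  Two degenerate constant groups with equal
    means return (0, 1) instead of NaN.
    """
    x = np.asarray(aucs_group1, dtype=float)
    y = np.asarray(aucs_group2, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("need >= 2 values per group")
    if x.std() == 0 and y.std() == 0 and x.mean() == y.mean():
        return 0.0, 1.0
    t, p = sps.ttest_ind(x, y, equal_var=not welch)
    return float(t), float(p)


@dataclass
class OrdinationResult:
    """Scores, loadings and per-axis variance fractions of an ordination."""

    method: str
    scores: pd.DataFrame  # animals x axes
    loadings: pd.DataFrame  # features x axes
    variance_explained: np.ndarray
    groups: pd.Series | None = None


def _zscore(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    sd = np.where(sd > 0, sd, 1.0)
    return (X - mu) / sd


def ordination(
    features: pd.DataFrame,
    method: str = "PCA",
    groups: pd.Series | None = None,
    ridge: float = 1e-8,
) -> OrdinationResult:
    """Reduce the behavioral feature table to a few axes.

    ``PCA`` eigendecomposes the feature correlation matrix (features are
    z-scored first) and returns all axes with their variance fractions.

    ``CANONICAL_DISCRIMINANT`` eigendecomposes within^-1 x between group
    scatter of the z-scored features; the axis count is
    min(n_groups - 1, n_features), so with exactly two groups the single
    canonical axis carries 100% of the between-group variance.  A
    singular within-group scatter (e.g. duplicated features) is
    ridge-regularized with ``ridge * trace/p`` on the diagonal and a
    warning is emitted.
    """
    if groups is None and "group" in features.columns:
        groups = features["group"]
    feat = features.drop(
        columns=[c for c in ("group", "imputed") if c in features.columns]
    )
    names = list(feat.columns)
    X = _zscore(feat.to_numpy(dtype=float))
    n, p = X.shape

    if method == "PCA":
        R = np.corrcoef(X, rowvar=False)
        R = np.where(np.isfinite(R), R, 0.0)
        np.fill_diagonal(R, 1.0)
        evals, evecs = np.linalg.eigh(R)
        order = np.argsort(evals)[::-1]
        evals, evecs = np.clip(evals[order], 0, None), evecs[:, order]
        scores = X @ evecs
        var_frac = evals / evals.sum() if evals.sum() > 0 else evals
        axes = [f"PC{i+1}" for i in range(p)]
    elif method == "CANONICAL_DISCRIMINANT":
        if groups is None:
            raise ValueError("canonical discriminant analysis needs group labels")
        g = np.asarray(groups)
        labels = np.unique(g)
        if any((g == lab).sum() < 2 for lab in labels):
            raise ValueError("need >= 2 animals per group")
        grand = X.mean(axis=0)
        Sw = np.zeros((p, p))
        Sb = np.zeros((p, p))
        for lab in labels:
            Xi = X[g == lab]
            mi = Xi.mean(axis=0)
            Sw += (Xi - mi).T @ (Xi - mi)
            d = (mi - grand)[:, None]
            Sb += len(Xi) * (d @ d.T)
        cond = np.linalg.cond(Sw)
        if not np.isfinite(cond) or cond > 1e12:
            lam = ridge * np.trace(Sw) / p
            warnings.warn(
                f"singular within-group scatter; ridge-regularizing with {lam:.3g}",
                RuntimeWarning,
                stacklevel=2,
            )
            Sw = Sw + lam * np.eye(p)
        evals, evecs = np.linalg.eig(np.linalg.solve(Sw, Sb))
        evals, evecs = np.real(evals), np.real(evecs)
        order = np.argsort(evals)[::-1]
        n_axes = min(len(labels) - 1, p)
        evals = np.clip(evals[order][:n_axes], 0, None)
        evecs = evecs[:, order][:, :n_axes]
        scores = X @ evecs
        total = evals.sum()
        var_frac = evals / total if total > 0 else np.ones(n_axes) / n_axes
        axes = [f"CanDisc{i+1}" for i in range(n_axes)]
    else:
        raise ValueError(f"unknown ordination method {method!r}")

    return OrdinationResult(
        method=method,
        scores=pd.DataFrame(scores[:, : len(axes)], index=feat.index, columns=axes),
        loadings=pd.DataFrame(evecs[:, : len(axes)], index=names, columns=axes),
        variance_explained=np.asarray(var_frac[: len(axes)], dtype=float),
        groups=pd.Series(groups, index=feat.index) if groups is not None else None,
    )
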