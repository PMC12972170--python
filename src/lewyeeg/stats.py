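"""Education-stratified statistical battery for regional band activity.

The central design is a mixed ("split-plot") ANCOVA per clinical group:
Education (Edu-/Edu+) as the between-subject factor, Band (8 individualized
bands) and ROI (6 macro-regions) as within-subject factors, with sex, MMSE
and clinical unit (and LED where indicated) as covariates.  It is computed
stratum by stratum with orthonormal within-subject contrasts: the
between-subject stratum analyses subject means, each within stratum
regresses the contrast scores on the full between-subject design (including
the covariates, which therefore consume error degrees of freedom in every
stratum, reproducing the published df such as F(7, 343) for N = 54 with
three covariates).  Effect sizes are partial eta squared,
SS_effect / (SS_effect + SS_error).

Around it: Duncan's multiple-range post hoc with band-wise Bonferroni
(0.05/8 = 0.00625), Grubbs outlier screening, the demographic test
dispatcher (t / Fisher exact / Mann-Whitney), composite cognitive z-scores
against the Healthy reference, Kruskal-Wallis with Dunn-type z post hocs,
Spearman/Pearson correlation, and the interaction / education-trend
regressions with Benjamini-Hochberg FDR-corrected simple slopes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .spectral import BAND_NAMES
from .forward import ROI_NAMES


# ---------------------------------------------------------------------------
# cohort table

def build_cohort_table(activities, profiles) -> pd.DataFrame:
    """Long-format table: one row per (subject, roi, band) joined with
    demographics; the unit of analysis for every statistical operation."""
    from .synth import profiles_frame

    act = pd.concat([a.to_frame() for a in activities], ignore_index=True)
    meta = profiles_frame(profiles)
    tab = act.merge(meta, on="subject_id", how="left", validate="m:1")
    if tab.duplicated(["subject_id", "roi", "band"]).any():
        raise ValueError("duplicated (subject, roi, band) keys")
    tab["band"] = pd.Categorical(tab["band"], categories=BAND_NAMES,
                                 ordered=True)
    tab["roi"] = pd.Categorical(tab["roi"], categories=ROI_NAMES,
                                ordered=True)
    return tab


# ---------------------------------------------------------------------------
# mixed-design ANCOVA

@dataclass
class AnovaResult:
    effects: pd.DataFrame        # term, df1, df2, F, p, eta_p2 [, eps_gg, p_gg]
    design: str = ""
    covariates: tuple = ()

    def effect(self, term: str) -> pd.Series:
        m = self.effects[self.effects["term"] == term]
        if m.empty:
            raise KeyError(term)
        return m.iloc[0]

    def to_dict(self) -> dict:
        return {"design": self.design, "covariates": list(self.covariates),
                "effects": self.effects.to_dict(orient="records")}


def _orth_contrasts(k: int) -> np.ndarray:
    """Orthonormal (Helmert) contrast matrix, k levels -> k x (k-1)."""
    h = np.zeros((k, k - 1))
    for j in range(1, k):
        h[:j, j - 1] = 1.0
        h[j, j - 1] = -j
    return h / np.linalg.norm(h, axis=0)


def _between_design(meta: pd.DataFrame, between, covariates):
    """Effect-coded between design plus centered covariates.

    Returns (X, term_columns) where term_columns maps each reportable term
    to its column indices in X."""
    n = len(meta)
    cols = [np.ones(n)]
    names = ["Intercept"]
    terms: dict[str, list[int]] = {}
    codes = {}
    for f in between:
        levels = sorted(meta[f].astype(str).unique())
        if len(levels) != 2:
            raise ValueError(
                f"between factor {f!r} must have exactly 2 levels, got {levels}")
        c = np.where(meta[f].astype(str) == levels[1], 1.0, -1.0)
        codes[f] = c
        terms[f] = [len(cols)]
        cols.append(c)
        names.append(f)
    bl = list(between)
    for i in range(len(bl)):
        for j in range(i + 1, len(bl)):
            term = f"{bl[i]} x {bl[j]}"
            terms[term] = [len(cols)]
            cols.append(codes[bl[i]] * codes[bl[j]])
            names.append(term)
    for cv in covariates:
        col = meta[cv]
        if col.nunique() < 2:
            continue                    # constant covariate carries no df
        if col.dtype.kind in "fiu" and col.nunique() > 2:
            x = col.to_numpy(float)
            terms[cv] = [len(cols)]
            cols.append(x - x.mean())
            names.append(cv)
        else:
            levels = sorted(col.astype(str).unique())
            idxs = []
            for lev in levels[1:]:
                d = (col.astype(str) == lev).astype(float).to_numpy()
                idxs.append(len(cols))
                cols.append(d - d.mean())
                names.append(f"{cv}[{lev}]")
            terms[cv] = idxs
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # name an aliased column for the error message
        bad = []
        for j in range(X.shape[1]):
            others = np.delete(X, j, axis=1)
            beta, *_ = np.linalg.lstsq(others, X[:, j], rcond=None)
            if np.linalg.norm(X[:, j] - others @ beta) < 1e-8 * max(
                    np.linalg.norm(X[:, j]), 1e-12):
                bad.append(names[j])
        raise ValueError(f"singular between-subject design; aliased: {bad}")
    return X, terms


def _term_ss(X, Y, terms):
    """OLS of each column of Y on X; Type III SS per term (summed over
    columns of Y) and residual SS."""
    XtX = X.T @ X
    XtXi = np.linalg.inv(XtX)
    B = XtXi @ (X.T @ Y)                       # p x q
    resid = Y - X @ B
    rss = float((resid ** 2).sum())
    out = {}
    for term, jidx in terms.items():
        J = np.array(jidx)
        Vjj = XtXi[np.ix_(J, J)]
        bj = B[J]                              # |J| x q
        ss = 0.0
        Vinv = np.linalg.inv(Vjj)
        for col in range(bj.shape[1]):
            ss += float(bj[:, col] @ Vinv @ bj[:, col])
        out[term] = (ss, len(J))
    return out, rss, resid


def rm_ancova(table: pd.DataFrame, dv: str = "activity",
              subject: str = "subject_id", between=("edu",),
              within=("band", "roi"), covariates=()) -> AnovaResult:
    """Mixed-design ANCOVA with repeated factors via stratum-wise OLS."""
    between = tuple(between)
    within = tuple(within)
    covariates = tuple(covariates)
    levels = {}
    for f in within:
        col = table[f]
        if isinstance(col.dtype, pd.CategoricalDtype):
            levels[f] = [l for l in col.cat.categories if (col == l).any()]
        else:
            levels[f] = list(pd.unique(col))

    # cells of factors not in `within` (e.g. ROI in a Band-only design) are
    # averaged into the subject x within grid
    key_cols = [subject, *within]
    dup = table.duplicated(key_cols)
    if dup.any():
        cell = (table.groupby(key_cols, observed=True, as_index=False)[dv]
                .mean())
        grid = table.drop_duplicates(key_cols)[key_cols]
        if len(cell) * 1 != len(grid):
            raise ValueError("inconsistent within-subject grid")
        table = cell.merge(table.drop_duplicates(subject)
                           .drop(columns=[c for c in table.columns
                                          if c in (dv, *within)]),
                           on=subject, how="left")
    try:
        wide = table.pivot(index=subject, columns=list(within), values=dv)
    except ValueError as e:
        raise ValueError(f"duplicated (subject, {within}) cells: {e}") from e
    if len(within) == 1:
        full_cols = pd.Index(levels[within[0]])
        wide = wide.reindex(columns=full_cols)
    else:
        full_cols = pd.MultiIndex.from_product([levels[f] for f in within])
        wide = wide.reindex(columns=full_cols)
    if wide.isna().any().any():
        missing = [(str(s), str(c)) for s, c in
                   zip(*np.where(wide.isna().to_numpy()))][:5]
        nan_cells = int(wide.isna().to_numpy().sum())
        raise ValueError(
            f"incomplete within-subject grid: {nan_cells} missing cells "
            f"(first few index pairs {missing})")
    meta = (table.drop_duplicates(subject).set_index(subject)
            .loc[wide.index].reset_index())
    for f in between:
        counts = meta[f].value_counts()
        if (counts < 2).any():
            raise ValueError(f"need >= 2 subjects per level of {f!r}")

    X, bterms = _between_design(meta, between, covariates)
    n, p = X.shape
    rows = []

    # between-subject stratum: subject means
    y_mean = wide.to_numpy().mean(axis=1, keepdims=True)
    ss_map, rss, _ = _term_ss(X, y_mean, bterms)
    df_err = n - p
    for term, (ss, dfh) in ss_map.items():
        F = (ss / dfh) / (rss / df_err)
        rows.append({"term": term, "df1": dfh, "df2": df_err, "F": F,
                     "p": float(sps.f.sf(F, dfh, df_err)),
                     "eta_p2": ss / (ss + rss)})

    # within strata
    contrasts = {f: _orth_contrasts(len(levels[f])) for f in within}
    means = {f: np.full((len(levels[f]), 1), 1.0 / len(levels[f]))
             for f in within}

    def stratum(name, wmat):
        q = wmat.shape[1]
        if q == 0:
            return
        Z = wide.to_numpy() @ wmat
        ss_map, rss, resid = _term_ss(X, Z, bterms | {"Intercept": [0]})
        df_err = q * (n - p)
        # Greenhouse-Geisser sphericity estimate from residual covariance
        S = resid.T @ resid / max(n - p, 1)
        tr = np.trace(S)
        eps = (tr ** 2) / (q * (S * S).sum()) if tr > 0 else 1.0
        eps = min(max(eps, 1.0 / q), 1.0)
        for term, (ss, dfh) in ss_map.items():
            label = name if term == "Intercept" else f"{term} x {name}"
            df1 = q if term == "Intercept" else q * dfh
            F = (ss / df1) / (rss / df_err)
            row = {"term": label, "df1": df1, "df2": df_err, "F": F,
                   "p": float(sps.f.sf(F, df1, df_err)),
                   "eta_p2": ss / (ss + rss), "eps_gg": eps,
                   "p_gg": float(sps.f.sf(F, df1 * eps, df_err * eps))}
            rows.append(row)

    for f in within:
        mats = [contrasts[g] if g == f else means[g] for g in within]
        w = mats[0]
        for m in mats[1:]:
            w = np.kron(w, m)
        stratum(f, w)
    if len(within) == 2:
        w = np.kron(contrasts[within[0]], contrasts[within[1]])
        stratum(f"{within[0]} x {within[1]}", w)

    eff = pd.DataFrame(rows)
    design = (f"{dv} ~ between({', '.join(between)}) x "
              f"within({', '.join(within)}) | covariates("
              f"{', '.join(covariates) or 'none'})")
    return AnovaResult(eff, design, covariates)


# ---------------------------------------------------------------------------
# Duncan post hoc

BONFERRONI_8_BANDS = 0.05 / 8           # 0.00625, printed as 0.006


@dataclass
class PosthocResult:
    table: pd.DataFrame                  # one row per band
    corrected_threshold: float = BONFERRONI_8_BANDS


def duncan_two_groups(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Duncan multiple-range p for two means (equals the LSD/t-test p at
    range 2): statistic on the studentized-range scale and its p."""
    nx, ny = len(x), len(y)
    df = nx + ny - 2
    sp2 = (((nx - 1) * np.var(x, ddof=1) + (ny - 1) * np.var(y, ddof=1))
           / df)
    if sp2 <= 0:
        raise ValueError("zero error variance")
    t = (np.mean(x) - np.mean(y)) / np.sqrt(sp2 * (1 / nx + 1 / ny))
    q = np.sqrt(2.0) * abs(t)
    return float(q), float(sps.studentized_range.sf(q, 2, df))


def duncan_multiple_range(samples: list, alpha: float = 0.05) -> pd.DataFrame:
    """Duncan's stepwise multiple-range test over k group means.

    Pairwise p-values on the protection scale 1-(1-alpha)^(r-1); uses the
    pooled error term and the harmonic mean group size.
    """
    k = len(samples)
    if k < 2:
        raise ValueError("need >= 2 groups")
    ns = np.array([len(s) for s in samples])
    means = np.array([np.mean(s) for s in samples])
    df = int(ns.sum() - k)
    mse = sum(((len(s) - 1) * np.var(s, ddof=1)) for s in samples) / df
    if mse <= 0:
        raise ValueError("zero error variance")
    nh = k / (1.0 / ns).sum()
    order = np.argsort(means)
    rows = []
    for a in range(k):
        for b in range(a + 1, k):
            ra = int(np.where(order == a)[0][0])
            rb = int(np.where(order == b)[0][0])
            r = abs(ra - rb) + 1
            q = abs(means[a] - means[b]) / np.sqrt(mse / nh)
            p_range = float(sps.studentized_range.sf(q, r, df))
            p_dunc = 1.0 - (1.0 - p_range) ** (1.0 / (r - 1)) if r > 2 \
                else p_range
            rows.append({"i": a, "j": b, "range": r, "q": q, "p": p_dunc,
                         "significant": p_dunc < alpha})
    return pd.DataFrame(rows)


def duncan_posthoc(table: pd.DataFrame, dv: str = "activity",
                   subject: str = "subject_id", band_col: str = "band",
                   edu_col: str = "edu") -> PosthocResult:
    """Per-band Edu- vs Edu+ Duncan contrast on subject band means (averaged
    over ROI), Bonferroni-compared against 0.05/8."""
    sb = (table.groupby([subject, band_col, edu_col], observed=True)[dv]
          .mean().reset_index())
    bands = [b for b in BAND_NAMES if (sb[band_col] == b).any()]
    thresh = 0.05 / len(bands)
    rows = []
    for band in bands:
        d = sb[sb[band_col] == band]
        lo = d[d[edu_col] == "low"][dv].to_numpy()
        hi = d[d[edu_col] == "high"][dv].to_numpy()
        q, p = duncan_two_groups(lo, hi)
        rows.append({"band": band, "mean_low": lo.mean(),
                     "mean_high": hi.mean(), "diff": lo.mean() - hi.mean(),
                     "q": q, "p": p, "significant": p < thresh})
    return PosthocResult(pd.DataFrame(rows), thresh)


# ---------------------------------------------------------------------------
# Grubbs outlier screening

@dataclass
class GrubbsResult:
    n: int
    g: float
    critical: float
    outlier_index: int
    is_outlier: bool
    degenerate: bool = False


def grubbs_test(values, alpha: float = 0.001) -> GrubbsResult:
    """Two-sided Grubbs test: G = max|x - mean| / sd vs the t-based critical
    value at the stated alpha.  Detect-only (no removal)."""
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError("Grubbs test requires n >= 3")
    s = x.std(ddof=1)
    if s == 0:
        return GrubbsResult(n, 0.0, np.inf, -1, False, degenerate=True)
    dev = np.abs(x - x.mean())
    i = int(np.argmax(dev))
    g = dev[i] / s
    t = sps.t.ppf(1.0 - alpha / (2.0 * n), n - 2)
    crit = ((n - 1) / np.sqrt(n)) * np.sqrt(t * t / (n - 2 + t * t))
    return GrubbsResult(n, float(g), float(crit), i, bool(g > crit))


def grubbs_screen(table: pd.DataFrame, dv: str = "activity",
                  cells=("edu", "roi", "band"),
                  alpha: float = 0.001) -> pd.DataFrame:
    """Grubbs screening of every design cell; returns a tidy report."""
    rows = []
    for key, d in table.groupby(list(cells), observed=True):
        if len(d) < 3:
            continue
        res = grubbs_test(d[dv].to_numpy(), alpha)
        rows.append(dict(zip(cells, key if isinstance(key, tuple) else (key,)),
                         n=res.n, g=res.g, critical=res.critical,
                         outlier=res.is_outlier))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# demographics

DEFAULT_TEST_MAP = {
    "age": "t", "edu_years": "t", "updrs3": "t", "duration_y": "t",
    "led_mg": "t", "mmse": "mannwhitney", "mmsec": "mannwhitney",
    "sex": "fisher", "vh": "fisher", "rbd": "fisher",
}


def fisher_2x2(table2x2) -> tuple[float, float]:
    odds, p = sps.fisher_exact(np.asarray(table2x2), alternative="two-sided")
    return float(odds), float(p)


def demographic_tests(meta: pd.DataFrame, group_col: str,
                      variables=None, test_map=None,
                      equal_var: bool = True) -> pd.DataFrame:
    """Compare two groups variable by variable with the table-caption test
    mapping: t-test (continuous), Fisher exact (binary), Mann-Whitney U
    (ordinal scores, normal approximation with tie correction)."""
    test_map = dict(DEFAULT_TEST_MAP, **(test_map or {}))
    glv = sorted(meta[group_col].astype(str).unique())
    if len(glv) != 2:
        raise ValueError("demographic tests require exactly two groups")
    g1 = meta[meta[group_col].astype(str) == glv[0]]
    g2 = meta[meta[group_col].astype(str) == glv[1]]
    if len(g1) == 0 or len(g2) == 0:
        raise ValueError("empty group")
    if variables is None:
        variables = [v for v in test_map if v in meta.columns]
    rows = []
    for var in variables:
        kind = test_map.get(var, "t")
        a = g1[var].dropna()
        b = g2[var].dropna()
        if len(a) == 0 or len(b) == 0:
            continue
        if kind == "t":
            st, p = sps.ttest_ind(a, b, equal_var=equal_var)
        elif kind == "mannwhitney":
            st, p = sps.mannwhitneyu(a, b, alternative="two-sided",
                                     method="asymptotic",
                                     use_continuity=False)
        elif kind == "fisher":
            av = a.astype(bool) if a.dtype != bool else a
            bv = b.astype(bool) if b.dtype != bool else b
            if var == "sex":
                av, bv = (a == "M"), (b == "M")
            tab = [[int(av.sum()), int((~av).sum())],
                   [int(bv.sum()), int((~bv).sum())]]
            st, p = fisher_2x2(tab)
        else:
            raise ValueError(f"unknown test kind {kind!r}")
        rows.append({"variable": var, "test": kind, "statistic": float(st),
                     "p": float(p), f"n_{glv[0]}": len(a),
                     f"n_{glv[1]}": len(b)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# composite z-scores and Kruskal-Wallis

def composite_zscores(scores: pd.DataFrame, healthy_mask,
                      domains=("language", "visuospatial", "attention",
                               "memory")) -> pd.DataFrame:
    """z-score each domain against the Healthy reference; global z is the
    mean of the available domain z's."""
    healthy_mask = np.asarray(healthy_mask, dtype=bool)
    out = pd.DataFrame(index=scores.index)
    for d in domains:
        ref = scores.loc[healthy_mask, d].dropna()
        mu, sd = ref.mean(), ref.std(ddof=1)
        if not sd > 0:
            raise ValueError(f"zero Healthy SD in domain {d!r}")
        out[f"z_{d}"] = (scores[d] - mu) / sd
    out["z_global"] = out[[f"z_{d}" for d in domains]].mean(axis=1,
                                                            skipna=True)
    return out


@dataclass
class KruskalResult:
    h: float
    df: int
    p: float
    posthoc: pd.DataFrame                # pairwise Dunn-type z tests


def kruskal_multigroup(values, groups) -> KruskalResult:
    """Tie-corrected Kruskal-Wallis H with pairwise Dunn z post hocs
    (Bonferroni-adjusted two-sided p)."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = list(pd.unique(groups))
    samples = [values[groups == g] for g in labels]
    if len(labels) < 2 or any(len(s) < 2 for s in samples):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    if np.all(values == values[0]):
        post = pd.DataFrame(columns=["group1", "group2", "z", "p", "p_adj"])
        return KruskalResult(0.0, len(labels) - 1, 1.0, post)
    h, p = sps.kruskal(*samples)
    ranks = sps.rankdata(values)
    n = len(values)
    _, counts = np.unique(values, return_counts=True)
    tie_term = (counts ** 3 - counts).sum() / (12.0 * (n - 1))
    var_base = n * (n + 1) / 12.0 - tie_term
    rows = []
    k = len(labels)
    n_pairs = k * (k - 1) // 2
    for i in range(k):
        for j in range(i + 1, k):
            ri = ranks[groups == labels[i]].mean()
            rj = ranks[groups == labels[j]].mean()
            se = np.sqrt(var_base * (1 / len(samples[i]) + 1 / len(samples[j])))
            z = (ri - rj) / se
            praw = 2 * sps.norm.sf(abs(z))
            rows.append({"group1": labels[i], "group2": labels[j],
                         "z": float(z), "p": float(praw),
                         "p_adj": float(min(praw * n_pairs, 1.0))})
    return KruskalResult(float(h), k - 1, float(p), pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# correlations

def correlate(x, y, method: str = "spearman") -> tuple[float, float]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    m = np.isfinite(x) & np.isfinite(y)
    x, y = x[m], y[m]
    if len(x) < 4:
        raise ValueError("need >= 4 paired observations")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance: correlation undefined")
    if method == "spearman":
        r, p = sps.spearmanr(x, y)
    elif method == "pearson":
        r, p = sps.pearsonr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(r), float(p)


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    from statsmodels.stats.multitest import multipletests

    return multipletests(np.asarray(pvals, float), method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# regressions

@dataclass
class RegressionResult:
    coefficients: pd.DataFrame           # name, beta, se, p
    r2: float
    adj_r2: float
    rse: float
    fvalue: float
    f_df: tuple
    simple_slopes: pd.DataFrame | None = None
    diagnostics: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {"r2": self.r2, "adj_r2": self.adj_r2, "rse": self.rse,
             "F": self.fvalue, "df": list(self.f_df),
             "coefficients": self.coefficients.to_dict(orient="records"),
             "diagnostics": self.diagnostics}
        if self.simple_slopes is not None:
            d["simple_slopes"] = self.simple_slopes.to_dict(orient="records")
        return d


def _formula_covariates(df: pd.DataFrame, covariates) -> str:
    parts = []
    for cv in covariates:
        if df[cv].dtype.kind in "fiu" and df[cv].nunique() > 2:
            parts.append(cv)
        else:
            parts.append(f"C({cv})")
    return (" + " + " + ".join(parts)) if parts else ""


def _fit_ols(formula: str, df: pd.DataFrame):
    import statsmodels.formula.api as smf

    model = smf.ols(formula, data=df)
    rank = np.linalg.matrix_rank(model.exog)
    if rank < model.exog.shape[1]:
        names = model.exog_names
        bad = []
        for j in range(model.exog.shape[1]):
            others = np.delete(model.exog, j, axis=1)
            beta, *_ = np.linalg.lstsq(others, model.exog[:, j], rcond=None)
            resid = model.exog[:, j] - others @ beta
            if np.linalg.norm(resid) < 1e-8 * max(
                    np.linalg.norm(model.exog[:, j]), 1e-12):
                bad.append(names[j])
        raise ValueError(f"rank-deficient design; aliased columns: {bad}")
    return model.fit()


def _diagnostics(fit) -> dict:
    from statsmodels.stats.diagnostic import het_breuschpagan

    resid = fit.resid
    exog = fit.model.exog
    try:
        bp_stat, bp_p, _, _ = het_breuschpagan(resid, exog)
    except Exception:
        bp_stat, bp_p = np.nan, np.nan
    try:
        nt_stat, nt_p = sps.normaltest(resid)
    except Exception:
        nt_stat, nt_p = np.nan, np.nan
    infl = fit.get_influence()
    cooks = infl.cooks_distance[0]
    return {"breusch_pagan_p": float(bp_p),
            "normality_p": float(nt_p),
            "n_influential": int((cooks > 4.0 / len(resid)).sum())}


def regress_interaction(df: pd.DataFrame, target: str, activity: str,
                        edu_col: str = "edu",
                        covariates=("age", "sex", "unit"),
                        fdr_family: list | None = None) -> RegressionResult:
    """OLS of a cognitive score on Education x alpha-activity with
    covariates; simple slopes of activity per education level with BH-FDR
    adjusted p and confidence limits."""
    df = df.copy()
    df[edu_col] = df[edu_col].astype(str)
    formula = (f"{target} ~ C({edu_col}, Treatment('low')) * {activity}"
               + _formula_covariates(df, covariates))
    fit = _fit_ols(formula, df)

    coefs = pd.DataFrame({"name": fit.params.index, "beta": fit.params.values,
                          "se": fit.bse.values, "p": fit.pvalues.values})
    inter_name = [n for n in fit.params.index
                  if ":" in n and activity in n][0]
    cov = fit.cov_params()
    rows = []
    for level in ("low", "high"):
        if level == "low":
            beta = fit.params[activity]
            var = cov.loc[activity, activity]
        else:
            beta = fit.params[activity] + fit.params[inter_name]
            var = (cov.loc[activity, activity]
                   + cov.loc[inter_name, inter_name]
                   + 2 * cov.loc[activity, inter_name])
        se = np.sqrt(var)
        t = beta / se
        p = 2 * sps.t.sf(abs(t), fit.df_resid)
        tcrit = sps.t.ppf(0.975, fit.df_resid)
        rows.append({"edu": level, "slope": float(beta), "se": float(se),
                     "p": float(p), "ci_low": float(beta - tcrit * se),
                     "ci_high": float(beta + tcrit * se)})
    slopes = pd.DataFrame(rows)
    fam = list(slopes["p"]) + list(fdr_family or [])
    slopes["p_fdr"] = bh_fdr(fam)[: len(slopes)]

    return RegressionResult(
        coefs, float(fit.rsquared), float(fit.rsquared_adj),
        float(np.sqrt(fit.mse_resid)), float(fit.fvalue),
        (int(fit.df_model), int(fit.df_resid)), slopes, _diagnostics(fit))


def education_trend(df: pd.DataFrame, target: str,
                    years_col: str = "edu_years",
                    covariates=("age", "sex", "unit")) -> RegressionResult:
    """OLS slope of an activity measure on continuous education years."""
    if df[years_col].nunique() < 2:
        raise ValueError("education years constant: zero predictor variance")
    formula = f"{target} ~ {years_col}" + _formula_covariates(df, covariates)
    fit = _fit_ols(formula, df)
    coefs = pd.DataFrame({"name": fit.params.index, "beta": fit.params.values,
                          "se": fit.bse.values, "p": fit.pvalues.values})
    tcrit = sps.t.ppf(0.975, fit.df_resid)
    b, se = fit.params[years_col], fit.bse[years_col]
    slopes = pd.DataFrame([{
        "edu": "continuous", "slope": float(b), "se": float(se),
        "p": float(fit.pvalues[years_col]),
        "ci_low": float(b - tcrit * se), "ci_high": float(b + tcrit * se),
        "p_fdr": float(fit.pvalues[years_col])}])
    return RegressionResult(
        coefs, float(fit.rsquared), float(fit.rsquared_adj),
        float(np.sqrt(fit.mse_resid)), float(fit.fvalue),
        (int(fit.df_model), int(fit.df_resid)), slopes, _diagnostics(fit))
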