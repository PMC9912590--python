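"""Inference stage: group matching, covariate imputation, standardized
mixed-model fits, FDR adjustment, marginal contrasts, model comparison, and
simulation-based power.

Coding conventions: continuous outcomes and predictors are z-scored on the
analysis sample, so fixed-effect estimates are standardized coefficients
(beta).  Two-level factors are deviation coded (-0.5 / +0.5: group ASD = +0.5,
TD = -0.5; category human = +0.5, non-human = -0.5), so main effects are
averages over the levels of the other factors.  Random intercepts for
participant and scene are always included unless a spec removes them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.proportion import proportion_confint

from .lmm import CrossedLMM, LMMFit

__all__ = [
    "ModelSpec",
    "LmmResult",
    "PowerReport",
    "match_groups",
    "impute_covariates",
    "build_design",
    "aggregate_face_gaze",
    "fit_lmm",
    "fdr_adjust",
    "marginal_contrasts",
    "compare_models",
    "power_simulation",
    "polynomial_time",
]

FACTOR_CODES = {
    "group": {"TD": -0.5, "ASD": +0.5},
    "category": {"non-human": -0.5, "human": +0.5},
    "sex": {"male": -0.5, "female": +0.5},
}


@dataclass
class ModelSpec:
    """Specification of one mixed-model analysis.

    ``fixed`` lists main-effect columns (factors in :data:`FACTOR_CODES` are
    deviation coded, everything else is z-scored); ``interactions`` are tuples
    of those names (products of the coded columns).  ``poly_time=True`` adds a
    third-degree polynomial in time-in-scene; it is dropped automatically when
    PR1/PR2 enter as predictors, which already carry the temporal weighting.
    ``human_only=True`` restricts to human scenes (the face-gaze model).
    """

    outcome: str
    fixed: tuple = ("group", "category")
    interactions: tuple = (("group", "category"),)
    covariates: tuple = ()
    poly_time: bool = True
    random: tuple = ("participant", "scene")
    human_only: bool = False

    def __post_init__(self):
        preds = set(self.fixed) | set(self.covariates)
        if {"pr1", "pr2"} & preds:
            self.poly_time = False
        if self.outcome in ("aoi_face", "face_prop"):
            self.human_only = True
        if self.human_only:
            # category is constant on human-only records; a coded column
            # would be collinear with the intercept
            self.fixed = tuple(f for f in self.fixed if f != "category")
            self.interactions = tuple(
                tuple(t for t in terms if t != "category")
                for terms in self.interactions
            )
            self.interactions = tuple(
                t for t in self.interactions if len(t) >= 2
            )


@dataclass
class LmmResult:
    """Fitted-model summary: standardized effects, F tests, variances."""

    spec: ModelSpec
    fit: LMMFit
    effects: pd.DataFrame  # beta, se, ci_low, ci_high, F, den_df, p, p_adj
    random_variances: dict
    converged: bool
    n_obs: int
    n_participants: int
    n_scenes: int

    def __getitem__(self, term: str) -> pd.Series:
        return self.effects.loc[term]


@dataclass
class PowerReport:
    effect_size: float
    iterations: int
    power: float
    ci_low: float
    ci_high: float
    alpha: float = 0.05


# ---------------------------------------------------------------------------
# sample construction


def match_groups(
    cohort: pd.DataFrame,
    match_vars: tuple = ("perceptual_iq", "age", "accuracy_z", "precision_z", "available_data_pct"),
    group_col: str = "group",
    case_level: str = "ASD",
    caliper_sd: float = 0.4,
) -> pd.DataFrame:
    """1:1 nearest-neighbour matching without replacement with a caliper.

    Matching variables are standardized on the pooled sample; candidate
    case-control pairs are accepted greedily in order of increasing Euclidean
    distance, skipping pairs whose standardized difference exceeds
    ``caliper_sd`` on *any* matching variable.  Returns the matched cohort
    with a ``pair_id`` column; empty (with a warning) when no pair is
    feasible.
    """
    use = [v for v in match_vars if v in cohort.columns]
    z = cohort[use].astype(float).copy()
    for v in use:
        sd = z[v].std(ddof=1)
        z[v] = (z[v] - z[v].mean()) / (sd if sd > 0 else 1.0)
    cases = cohort.index[cohort[group_col] == case_level]
    controls = cohort.index[cohort[group_col] != case_level]
    if len(cases) == 0 or len(controls) == 0:
        raise ValueError("both groups must be non-empty")
    pairs = []
    for a in cases:
        for b in controls:
            diff = (z.loc[a] - z.loc[b]).to_numpy()
            if np.all(np.abs(diff) <= caliper_sd):
                pairs.append((float(np.sqrt((diff**2).sum())), a, b))
    pairs.sort(key=lambda t: t[0])
    used_a: set = set()
    used_b: set = set()
    matched = []
    for _, a, b in pairs:
        if a in used_a or b in used_b:
            continue
        used_a.add(a)
        used_b.add(b)
        matched.append((a, b))
    if not matched:
        warnings.warn("no feasible matched pair within the caliper", stacklevel=2)
        return cohort.iloc[0:0].assign(pair_id=pd.Series(dtype=int))
    rows = []
    for pid, (a, b) in enumerate(matched):
        rows += [(a, pid), (b, pid)]
    idx, pid = zip(*rows)
    out = cohort.loc[list(idx)].copy()
    out["pair_id"] = pid
    return out


def impute_covariates(
    table: pd.DataFrame,
    columns: tuple = ("srs_score", "adhd_score", "anxiety_score", "depression_score"),
    group_col: str = "group",
    predictors: tuple = ("age", "perceptual_iq"),
) -> pd.DataFrame:
    """Group-wise predictive-mean-matching imputation of symptom covariates.

    Within each group, the missing covariate is predicted by a linear
    regression on the complete predictors; the imputed value is the observed
    value of the donor whose prediction is nearest (PMM), so imputations are
    always observed values.  Adds one ``<col>_imputed`` flag per column.
    """
    out = table.copy()
    for col in columns:
        if col not in out.columns:
            continue
        vals = out[col].astype(float)
        if vals.isna().all():
            raise ValueError(f"covariate {col!r} entirely missing; cannot impute")
        if vals.isna().mean() >= 0.5:
            raise ValueError(f"covariate {col!r} has >= 50% missing values")
        flag = vals.isna()
        for _, gidx in out.groupby(group_col).groups.items():
            g = out.loc[gidx]
            obs = g.index[g[col].notna()]
            mis = g.index[g[col].isna()]
            if len(mis) == 0:
                continue
            preds = [p for p in predictors if p in g.columns and g[p].notna().all()]
            if preds and len(obs) > len(preds) + 1:
                Xo = np.column_stack([np.ones(len(obs))] + [g.loc[obs, p] for p in preds])
                coef, *_ = np.linalg.lstsq(Xo, g.loc[obs, col].to_numpy(float), rcond=None)
                yhat_obs = Xo @ coef
                Xm = np.column_stack([np.ones(len(mis))] + [g.loc[mis, p] for p in preds])
                yhat_mis = Xm @ coef
            else:  # fall back to the group mean as the predictive value
                yhat_obs = np.full(len(obs), g.loc[obs, col].mean())
                yhat_mis = np.full(len(mis), g.loc[obs, col].mean())
            donors = g.loc[obs, col].to_numpy(float)
            for k, i in enumerate(mis):
                j = int(np.argmin(np.abs(yhat_obs - yhat_mis[k])))
                out.loc[i, col] = donors[j]
        out[f"{col}_imputed"] = flag
    return out


# ---------------------------------------------------------------------------
# design construction and fitting


def polynomial_time(t_ms: np.ndarray, window_ms: float = 5000.0) -> np.ndarray:
    """Orthogonalized third-degree polynomial basis of time-in-scene.

    Time is mapped to [-1, 1] over the analysis window, raised to powers
    1..3, and orthogonalized by QR for numerical stability; columns are
    scaled to unit variance.
    """
    u = 2.0 * np.asarray(t_ms, dtype=float) / window_ms - 1.0
    P = np.column_stack([u, u**2, u**3])
    P = P - P.mean(axis=0, keepdims=True)
    Q, _ = np.linalg.qr(P)
    sd = Q.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    return Q / sd


def _code_column(df: pd.DataFrame, name: str) -> np.ndarray:
    if name in FACTOR_CODES:
        codes = df[name].map(FACTOR_CODES[name])
        if codes.isna().any():
            bad = sorted(df.loc[codes.isna(), name].unique())
            raise ValueError(f"unknown level(s) {bad} for factor {name!r}")
        return codes.to_numpy(dtype=float)
    x = df[name].to_numpy(dtype=float)
    sd = np.nanstd(x, ddof=1)
    return (x - np.nanmean(x)) / (sd if sd > 0 else 1.0)


def build_design(
    spec: ModelSpec, records: pd.DataFrame
) -> tuple[np.ndarray, np.ndarray, dict, list[str], pd.DataFrame]:
    """Build (y, X, groups, names, analysis_frame) for a model spec."""
    df = records.copy()
    if spec.human_only:
        df = df[df["category"] == "human"]
    needed = [spec.outcome, *spec.fixed, *spec.covariates]
    if spec.poly_time:
        needed.append("t_scene_ms")
    df = df.dropna(subset=[c for c in needed if c in df.columns])
    if df["participant"].nunique() < 2 or df["scene"].nunique() < 2:
        raise ValueError("need at least 2 participants and 2 scenes")

    y = df[spec.outcome].to_numpy(dtype=float)
    ysd = y.std(ddof=1)
    y = (y - y.mean()) / (ysd if ysd > 0 else 1.0)

    cols: dict[str, np.ndarray] = {"Intercept": np.ones(len(df))}
    for name in spec.fixed:
        cols[name] = _code_column(df, name)
    if spec.poly_time:
        P = polynomial_time(df["t_scene_ms"].to_numpy(dtype=float))
        for k in range(3):
            cols[f"time^{k + 1}"] = P[:, k]
        # hypothesis-relevant time interactions with the coded factors
        for name in ("group", "category"):
            if name in cols:
                for k in range(3):
                    cols[f"{name}:time^{k + 1}"] = cols[name] * P[:, k]
    for terms in spec.interactions:
        label = ":".join(terms)
        prod = np.ones(len(df))
        for t in terms:
            prod = prod * cols[t]
        cols[label] = prod
    for name in spec.covariates:
        cols[name] = _code_column(df, name)

    names = list(cols)
    X = np.column_stack([cols[c] for c in names])
    groups = {g: df[g].to_numpy() for g in spec.random}
    return y, X, groups, names, df


def fit_lmm(spec: ModelSpec, records: pd.DataFrame, reml: bool = True) -> LmmResult:
    """Fit a standardized mixed model and assemble the result table."""
    y, X, groups, names, df = build_design(spec, records)
    model = CrossedLMM(y, X, groups, names=names)
    fit = model.fit(reml=reml)
    if not fit.converged:
        warnings.warn("mixed-model fit did not converge", stacklevel=2)
    rows = []
    anova = fit.anova_satterthwaite()
    se = fit.se()
    for name in names:
        if name == "Intercept":
            continue
        b = float(fit.beta[name])
        s = float(se[name])
        df_term = float(anova.loc[name, "den_df"])
        tcrit = sps.t.ppf(0.975, df_term)
        rows.append(
            {
                "term": name,
                "beta": b,
                "se": s,
                "ci_low": b - tcrit * s,
                "ci_high": b + tcrit * s,
                "F": float(anova.loc[name, "F"]),
                "num_df": 1.0,
                "den_df": df_term,
                "p": float(anova.loc[name, "p"]),
                "p_adj": np.nan,
            }
        )
    effects = pd.DataFrame(rows).set_index("term")
    return LmmResult(
        spec=spec,
        fit=fit,
        effects=effects,
        random_variances={**fit.sigma2, "residual": fit.sigma2_resid},
        converged=fit.converged,
        n_obs=len(y),
        n_participants=int(df["participant"].nunique()),
        n_scenes=int(df["scene"].nunique()),
    )


def aggregate_face_gaze(
    records: pd.DataFrame,
    bin_ms: float = 1000.0,
    window_ms: float = 5000.0,
) -> pd.DataFrame:
    """Aggregate per-fixation face hits to participant x scene x time-bin
    proportions (the social-attention outcome).

    Restricted to human scenes (AOI masks only exist there).  The returned
    table has one row per cell with ``face_prop`` (proportion of fixations
    on the face), a bin-centre ``t_scene_ms``, and the carried covariates,
    ready for a linear mixed-model fit.
    """
    df = records[(records["category"] == "human") & records["aoi_face"].notna()].copy()
    if len(df) == 0:
        raise ValueError("no human-scene fixations with AOI flags")
    edges = np.arange(0.0, window_ms + bin_ms, bin_ms)
    df["_bin"] = np.clip(
        np.searchsorted(edges, df["t_scene_ms"].to_numpy(float), side="right") - 1,
        0,
        len(edges) - 2,
    )
    carry = [
        c
        for c in df.columns
        if c
        not in (
            "participant",
            "scene",
            "category",
            "t_scene_ms",
            "aoi_face",
            "aoi_eyes",
            "aoi_mouth",
            "aoi_body",
            "_bin",
        )
        and df.groupby("participant")[c].nunique().le(1).all()
    ]
    grouped = df.groupby(["participant", "scene", "_bin"])
    out = grouped["aoi_face"].agg(face_prop="mean", n_fixations="size").reset_index()
    out["category"] = "human"
    out["t_scene_ms"] = edges[out["_bin"].to_numpy()] + bin_ms / 2.0
    per_pid = df.drop_duplicates("participant").set_index("participant")
    for c in carry:
        out[c] = out["participant"].map(per_pid[c])
    return out.drop(columns="_bin")


def fdr_adjust(pvalues, family_size: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment within one analysis family.

    The study's primary family has three analyses; ``family_size`` may pad
    the family when fewer p values are supplied (the remainder treated as 1).
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if family_size is not None and family_size > p.size:
        padded = np.concatenate([p, np.ones(family_size - p.size)])
        return multipletests(padded, method="fdr_bh")[1][: p.size]
    return multipletests(p, method="fdr_bh")[1]


def adjust_family(results: list, term: str) -> None:
    """FDR-adjust one term's p values across a family of fitted models."""
    ps = [float(r.effects.loc[term, "p"]) for r in results]
    adj = fdr_adjust(ps)
    for r, a in zip(results, adj):
        r.effects.loc[term, "p_adj"] = a


def marginal_contrasts(
    result: LmmResult,
    term: str = "group",
    by: str = "category",
    levels: dict | None = None,
) -> pd.DataFrame:
    """Marginal effect of ``term`` at each level of ``by`` (simple effects).

    Marginal means are evaluated with every other predictor at its mean
    (zero under the package's coding); the simple effect of ``term`` at a
    level of ``by`` is the difference of marginal means between the coded
    term levels, with CI and Satterthwaite df from the contrast variance.
    """
    codes_by = levels or FACTOR_CODES[by]
    names = list(result.fit.beta.index)
    rows = []
    for lvl, code in codes_by.items():
        L = np.zeros(len(names))
        # d/d(term code) of the linear predictor at by=code, others at 0
        span_term = FACTOR_CODES.get(term, {})
        delta = (max(span_term.values()) - min(span_term.values())) if span_term else 1.0
        if term in names:
            L[names.index(term)] = delta
        inter = f"{term}:{by}"
        inter_rev = f"{by}:{term}"
        for cand in (inter, inter_rev):
            if cand in names:
                L[names.index(cand)] = delta * code
        c = result.fit.contrast(L)
        tcrit = sps.t.ppf(0.975, c["df"])
        rows.append(
            {
                by: lvl,
                "delta": c["estimate"],
                "se": c["se"],
                "ci_low": c["estimate"] - tcrit * c["se"],
                "ci_high": c["estimate"] + tcrit * c["se"],
                "df": c["df"],
                "p": c["p"],
            }
        )
    return pd.DataFrame(rows).set_index(by)


def compare_models(
    spec_null: ModelSpec, spec_full: ModelSpec, records: pd.DataFrame
) -> dict:
    """Likelihood-ratio test of nested fixed-effect structures (ML refits)."""
    r0 = fit_lmm(spec_null, records, reml=False)
    r1 = fit_lmm(spec_full, records, reml=False)
    t0 = set(r0.fit.beta.index)
    t1 = set(r1.fit.beta.index)
    if not t0 <= t1:
        raise ValueError(f"models are not nested; extra terms in null: {sorted(t0 - t1)}")
    chi2 = max(0.0, r0.fit.neg2loglik - r1.fit.neg2loglik)
    df = len(t1) - len(t0)
    p = float(sps.chi2.sf(chi2, df)) if df > 0 else float("nan")
    return {"chi2": float(chi2), "df": int(df), "p": p, "null": r0, "full": r1}


def power_simulation(
    result: LmmResult,
    term: str,
    effect_size: float = 0.1,
    iterations: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> PowerReport:
    """Simulation-based power for one fixed effect.

    Outcomes are simulated from the fitted template -- its design matrix,
    estimated random-intercept variances and residual variance -- with the
    tested coefficient forced to ``effect_size`` (other coefficients kept at
    their estimates).  Each replicate is refit and tested (Satterthwaite);
    power is the significant fraction with a Clopper-Pearson 95% CI.
    """
    if iterations <= 0:
        raise ValueError("iterations must be positive")
    rng = np.random.default_rng(seed)
    model = result.fit.model
    names = list(result.fit.beta.index)
    if term not in names:
        raise KeyError(f"term {term!r} not in the fitted model")
    beta = result.fit.beta.to_numpy().copy()
    beta[names.index(term)] = effect_size
    mu = model.X @ beta
    Z = model._Z
    sizes = model.block_sizes
    sds = np.sqrt(
        np.concatenate(
            [
                np.full(s, result.fit.sigma2[f])
                for f, s in zip(model.factor_names, sizes)
            ]
        )
    ) if model.q else np.zeros(0)
    sde = np.sqrt(result.fit.sigma2_resid)
    hits = 0
    for _ in range(iterations):
        u = rng.normal(0.0, 1.0, model.q) * sds if model.q else np.zeros(0)
        ysim = mu + (Z @ u if model.q else 0.0) + rng.normal(0.0, sde, model.n)
        sim = CrossedLMM(
            ysim,
            model.X,
            {f: _codes_from_Z(model, f) for f in model.factor_names},
            names=names,
        ).fit(reml=True)
        L = np.zeros(len(names))
        L[names.index(term)] = 1.0
        if sim.contrast(L)["p"] < alpha:
            hits += 1
    lo, hi = proportion_confint(hits, iterations, method="beta")
    return PowerReport(
        effect_size=effect_size,
        iterations=iterations,
        power=hits / iterations,
        ci_low=float(lo),
        ci_high=float(hi),
        alpha=alpha,
    )


def _codes_from_Z(model: CrossedLMM, factor: str) -> np.ndarray:
    offset = 0
    for f, s in zip(model.factor_names, model.block_sizes):
        if f == factor:
            block = model._Z[:, offset : offset + s]
            return block.argmax(axis=1)
        offset += s
    raise KeyError(factor)
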