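"""Singly-constrained gravity models as mixed-effects linear regressions.

The gravity model predicts log gene flow along a directed edge i -> j from
three term families: "v" production covariates measured at the destination
node (at-site), "c" resistance/facilitation covariates summarized along the
edge (between-site), and "w" the geographic distance term that carries the
spatial-autocorrelation requirement.  The single constraint — pairwise
flows from one origin are not independent — is realized as a random
intercept per origin site:

    ln(flow_ij) = b0 + b_w ln(d_ij) + sum_k b_k ln(v_jk)
                  + sum_l b_l ln(c_ijl) + u_i + e_ij,
    u_i ~ N(0, s_u^2),  e_ij ~ N(0, s^2).

Fitting profiles the fixed effects and the residual variance out of the
(restricted) likelihood and runs a bounded one-dimensional search over the
variance ratio lambda = s_u^2 / s^2; random-intercept-only models make every
profiled quantity closed-form, so the fit is exact, fast and deterministic.

Model competition follows a two-round hierarchy: at-site and between-site
process models are first competed separately against their own global and
the distance-only null (maximum likelihood, AIC ranked); survivors
(dAIC < 4, null excluded) advance to a combined round against the
global-global model and the null.  The selected model is the most
parsimonious model within dAIC < 4 of the best.  Effect sizes under the
REML refit are Cohen's D = 2t / sqrt(df).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize
from scipy import stats as sstats

__all__ = [
    "ModelSpec",
    "FitResult",
    "log_offset_transform",
    "prepare_design",
    "fit_gravity",
    "GravityModel",
    "hierarchical_competition",
    "CompetitionResult",
    "cohens_d",
    "effect_sizes",
    "EffectSizeTable",
    "interpretation_report",
    "AT_PROCESSES",
    "BTW_PROCESSES",
    "PREDICTIONS",
    "HYPOTHESIS_COUNTS",
]

# ---------------------------------------------------------------------------
# Variable registry: ecological process hypotheses and predicted signs
# ---------------------------------------------------------------------------

#: at-site ("production") process hypotheses -> covariate codes
AT_PROCESSES: dict[str, list[str]] = {
    "fine_topography": ["srr3"],
    "microclimate": ["adi"],
    "soil": ["sand"],
    "vegetation": ["shrub", "cti"],
    "thermoregulation": ["hli"],
}

#: between-site ("resistance") process hypotheses -> covariate codes
BTW_PROCESSES: dict[str, list[str]] = {
    "vegetation": ["shrub", "cti"],
    "thermoregulation": ["hli"],
    "development": ["imperv"],
    "fire": ["fire"],
    "broad_topography": ["srr27"],
}

#: predicted effect direction on functional connectivity per covariate code
PREDICTIONS: dict[str, str] = {
    "at_srr3": "-",
    "at_adi": "+",
    "at_sand": "+",
    "at_shrub": "+",
    "at_cti": "+",
    "at_hli": "+",
    "btw_shrub": "+",
    "btw_cti": "+",
    "btw_hli": "+",
    "btw_imperv": "-",
    "btw_fire": "-",
    "btw_srr27": "-",
    "length": "-",
}

#: number of process hypotheses each code appears in (correlation-screen priority)
HYPOTHESIS_COUNTS: dict[str, int] = {
    "shrub": 2, "cti": 2, "hli": 2,
    "srr3": 1, "adi": 1, "sand": 1, "imperv": 1, "fire": 1, "srr27": 1,
}


@dataclass(frozen=True)
class ModelSpec:
    """A named covariate set; geographic distance is in every model."""

    name: str
    at_vars: tuple[str, ...] = ()
    btw_vars: tuple[str, ...] = ()
    round_tag: str = "at"  # at | btw | combined | null | global

    def __post_init__(self):
        if self.round_tag == "null" and (self.at_vars or self.btw_vars):
            raise ValueError("null spec must have no covariates")

    @property
    def columns(self) -> list[str]:
        return [f"at_{v}" for v in self.at_vars] + [f"btw_{v}" for v in self.btw_vars] + ["length"]

    @property
    def n_fixed(self) -> int:
        """Fixed effects including the intercept."""
        return len(self.at_vars) + len(self.btw_vars) + 2


NULL_SPEC = ModelSpec("null", round_tag="null")


# ---------------------------------------------------------------------------
# Log transform shared with the synthetic-data generator
# ---------------------------------------------------------------------------


def log_offset_transform(values: np.ndarray) -> tuple[np.ndarray, float, bool]:
    """Natural-log transform with the module-wide offset rule.

    Strictly positive columns are logged directly (offset 0).  Columns with
    zeros get an offset of half the smallest positive value.  Columns
    containing negatives are logged as ln(|x| + offset) with a recorded
    sign flip (the flip is applied to the effect direction downstream).
    Returns ``(transformed, offset, flipped)``.
    """
    v = np.asarray(values, dtype=float)
    flipped = bool((v < 0).any())
    if flipped:
        v = np.abs(v)
    pos = v[v > 0]
    if pos.size == 0:
        raise ValueError("column has no positive magnitude; cannot log-transform")
    delta = 0.0 if (v > 0).all() else float(pos.min() / 2.0)
    return np.log(v + delta), delta, flipped


@dataclass
class ModelFrame:
    """Design for one gravity fit: log response, log design matrix, grouping."""

    y: np.ndarray
    X: np.ndarray
    columns: list[str]           # fixed-effect names incl. "(intercept)"
    groups: np.ndarray           # origin-site code per edge
    spec: ModelSpec
    sign_flip_log: dict[str, bool]
    offsets: dict[str, float]
    n_nodes: int                 # distinct destination nodes (at-site stratum size)


def prepare_design(edge_table: pd.DataFrame, spec: ModelSpec, group_col: str = "from_site") -> ModelFrame:
    """Natural-log model frame for one spec.

    The response is ln(flow) (with the shared offset rule), covariates and
    ``length`` are logged the same way, and the grouping factor is the
    origin node's site label (``from_site`` column).
    """
    needed = spec.columns + ["flow", group_col]
    missing = [c for c in needed if c not in edge_table.columns]
    if missing:
        raise ValueError(f"edge table missing columns: {missing}")
    sign_flip: dict[str, bool] = {}
    offsets: dict[str, float] = {}
    y, offsets["flow"], _ = log_offset_transform(edge_table["flow"].to_numpy())
    cols = []
    names = ["(intercept)"]
    cols.append(np.ones(len(edge_table)))
    for c in spec.columns:
        t, offsets[c], raw_flip = log_offset_transform(edge_table[c].to_numpy())
        # direction reversal applies when the column is negative after the
        # log transform (typical raw magnitude < 1), compounded with the
        # magnitude flip for raw-negative columns
        sign_flip[c] = raw_flip != bool(np.median(t) < 0)
        if np.var(t) == 0 and c != "length":
            raise ValueError(f"covariate {c!r} has zero variance after log transform")
        cols.append(t)
        names.append(c)
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design is not full column rank")
    n_nodes = edge_table["to"].nunique() if "to" in edge_table.columns else len(edge_table)
    return ModelFrame(
        y=y, X=X, columns=names,
        groups=edge_table[group_col].to_numpy(),
        spec=spec, sign_flip_log=sign_flip, offsets=offsets, n_nodes=n_nodes,
    )


# ---------------------------------------------------------------------------
# Profiled random-intercept LMM
# ---------------------------------------------------------------------------


@dataclass
class FitResult:
    """Fitted gravity model (one estimation criterion)."""

    spec: ModelSpec
    estimation: str                  # ML | REML
    params: pd.DataFrame             # index=term: estimate, se, t_value, df, p_value
    log_likelihood: float
    aic: float                       # ML only (NaN under REML)
    n_edges: int
    n_groups: int
    sigma2_residual: float
    sigma2_group: float
    converged: bool
    sign_flip_log: dict[str, bool] = field(default_factory=dict)
    degenerate: bool = False         # perfect fit (zero residual variance)

    @property
    def k_parameters(self) -> int:
        """AIC parameter count: fixed effects + group variance + residual variance."""
        return len(self.params) + 2


def _profile_loglik(lam: float, y, X, group_idx, group_sizes, reml: bool):
    """Profiled (restricted) log-likelihood at variance ratio lambda, plus GLS pieces.

    With V0 = I + lam * Z Z', blockwise V0^-1 r = r - lam/(1+lam*n_g) * 1 1' r.
    """
    n, p = X.shape
    shrink = lam / (1.0 + lam * group_sizes)  # per group

    def vinv(M):
        # V0^{-1} M computed blockwise: M - shrink_g * (column sums within group)
        sums = np.zeros((len(group_sizes), M.shape[1]))
        np.add.at(sums, group_idx, M)
        return M - shrink[group_idx, None] * sums[group_idx]

    ViX = vinv(X)
    Viy = vinv(y[:, None])[:, 0]
    XtViX = X.T @ ViX
    XtViy = X.T @ Viy
    beta = np.linalg.solve(XtViX, XtViy)
    r = y - X @ beta
    rsums = np.zeros(len(group_sizes))
    np.add.at(rsums, group_idx, r)
    rVir = float(r @ r - shrink @ rsums ** 2)
    logdetV = float(np.sum(np.log1p(lam * group_sizes)))
    if reml:
        dof = n - p
        sigma2 = rVir / dof if dof > 0 else np.nan
        sign, logdetXVX = np.linalg.slogdet(XtViX)
        ll = -0.5 * (dof * np.log(2 * np.pi * sigma2) + dof + logdetV + logdetXVX) if sigma2 > 0 else np.inf
    else:
        sigma2 = rVir / n
        ll = -0.5 * (n * np.log(2 * np.pi * sigma2) + n + logdetV) if sigma2 > 0 else np.inf
    return ll, beta, sigma2, XtViX, rVir


def fit_gravity(frame: ModelFrame, estimation: str = "ML", df_rule: str = "two_stratum") -> FitResult:
    """Fit the random-intercept gravity model by profiled ML or REML.

    ``df_rule``: ``"two_stratum"`` gives at-site terms node-level df
    (n_nodes - n_at_terms - 2) and edge-level terms (between-site, distance,
    intercept) df = n_edges - n_fixed; ``"edge"`` gives every term edge-level
    df.  A perfect fit (zero residual variance) falls back to ordinary least
    squares for the estimates and is flagged ``degenerate``.
    """
    if estimation not in ("ML", "REML"):
        raise ValueError("estimation must be ML or REML")
    y, X = frame.y, frame.X
    n, p = X.shape
    codes, group_idx = np.unique(frame.groups, return_inverse=True)
    q = len(codes)
    if q < 2:
        raise ValueError("need >= 2 origin-site groups")
    group_sizes = np.bincount(group_idx).astype(float)
    reml = estimation == "REML"

    # perfect-fit guard: exact linear data has no likelihood maximum
    beta_ols, res_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
    rss = float(np.sum((y - X @ beta_ols) ** 2))
    if rss < 1e-10 * max(1.0, float(y @ y)):
        params = _param_table(frame, beta_ols, np.zeros(p), n, p, df_rule)
        return FitResult(frame.spec, estimation, params, np.inf, -np.inf, n, q,
                         0.0, 0.0, converged=True, sign_flip_log=dict(frame.sign_flip_log),
                         degenerate=True)

    def neg(loglam):
        return -_profile_loglik(float(np.exp(loglam)), y, X, group_idx, group_sizes, reml)[0]

    # bounded search over log variance ratio; includes the lambda -> 0 boundary
    opt = optimize.minimize_scalar(neg, bounds=(np.log(1e-10), np.log(1e8)),
                                   method="bounded", options={"xatol": 1e-10})
    lam = float(np.exp(opt.x))
    ll_boundary, *_ = _profile_loglik(0.0, y, X, group_idx, group_sizes, reml)
    ll_opt = -float(opt.fun)
    if ll_boundary >= ll_opt:
        lam = 0.0
        ll, beta, sigma2, XtViX, _ = _profile_loglik(0.0, y, X, group_idx, group_sizes, reml)
    else:
        ll, beta, sigma2, XtViX, _ = _profile_loglik(lam, y, X, group_idx, group_sizes, reml)
    converged = bool(opt.success) or lam == 0.0

    cov = sigma2 * np.linalg.inv(XtViX)
    se = np.sqrt(np.diag(cov))
    params = _param_table(frame, beta, se, n, p, df_rule)
    aic = 2 * (p + 2) - 2 * ll if not reml else np.nan
    return FitResult(frame.spec, estimation, params, float(ll), float(aic), n, q,
                     float(sigma2), float(lam * sigma2), converged,
                     sign_flip_log=dict(frame.sign_flip_log))


def _param_table(frame: ModelFrame, beta, se, n, p, df_rule) -> pd.DataFrame:
    spec = frame.spec
    df_edge = max(n - p, 1)
    n_at = len(spec.at_vars)
    df_node = max(frame.n_nodes - n_at - 2, 1)
    rows = []
    for name, b, s in zip(frame.columns, beta, se):
        if df_rule == "two_stratum" and name.startswith("at_"):
            df = df_node
        else:
            df = df_edge
        t = b / s if s > 0 else np.nan
        pval = 2 * sstats.t.sf(abs(t), df) if np.isfinite(t) else np.nan
        rows.append({"term": name, "estimate": b, "se": s, "t_value": t, "df": df, "p_value": pval})
    return pd.DataFrame(rows).set_index("term")


class GravityModel:
    """Convenience wrapper: spec + fit options with a ``fit`` method.

    Fitted attributes (trailing underscore) mirror the :class:`FitResult`.
    """

    def __init__(self, spec: ModelSpec, estimation: str = "ML", df_rule: str = "two_stratum",
                 group_col: str = "from_site"):
        self.spec = spec
        self.estimation = estimation
        self.df_rule = df_rule
        self.group_col = group_col

    def fit(self, edge_table: pd.DataFrame) -> "GravityModel":
        frame = prepare_design(edge_table, self.spec, self.group_col)
        self.result_ = fit_gravity(frame, self.estimation, self.df_rule)
        self.coef_ = self.result_.params["estimate"].to_numpy()
        self.aic_ = self.result_.aic
        self.log_likelihood_ = self.result_.log_likelihood
        return self


# ---------------------------------------------------------------------------
# Hierarchical model competition
# ---------------------------------------------------------------------------


@dataclass
class CompetitionResult:
    round_at: pd.DataFrame
    round_btw: pd.DataFrame
    round_combined: pd.DataFrame
    survivors_at: list[ModelSpec]
    survivors_btw: list[ModelSpec]
    selected: ModelSpec
    fits: dict[str, FitResult]


def _rank_table(fits: list[FitResult]) -> pd.DataFrame:
    ok = [f for f in fits if f.converged and np.isfinite(f.aic)]
    if not ok:
        raise RuntimeError("all models failed to converge")
    rows = [{"model": f.spec.name, "k": f.k_parameters, "logLik": f.log_likelihood, "AIC": f.aic}
            for f in ok]
    tab = pd.DataFrame(rows)
    best = tab["AIC"].min()
    tab["dAIC"] = tab["AIC"] - best
    return tab.sort_values(["AIC", "model"], kind="stable").reset_index(drop=True)


def _select(tab: pd.DataFrame, fits: dict[str, FitResult], delta: float = 4.0) -> str:
    """Most parsimonious model within dAIC < delta of the best; ties by name."""
    window = tab[tab["dAIC"] < delta]
    window = window.sort_values(["k", "model"], kind="stable")
    return str(window.iloc[0]["model"])


def hierarchical_competition(
    edge_table: pd.DataFrame,
    at_processes: dict[str, list[str]] | None = None,
    btw_processes: dict[str, list[str]] | None = None,
    delta_aic: float = 4.0,
    df_rule: str = "two_stratum",
    group_col: str = "from_site",
) -> CompetitionResult:
    """Two-round gravity model competition.

    Round 1a competes each at-site process model against the at-site global
    and the distance-only null; round 1b does the same for between-site
    processes.  Non-null models with dAIC < ``delta_aic`` advance; round 2
    competes every union of one at-survivor with one btw-survivor (plus each
    survivor alone), the global-global model, and the null.  The selected
    model is the most parsimonious within dAIC < ``delta_aic`` of the
    round-2 best.
    """
    at_processes = at_processes if at_processes is not None else AT_PROCESSES
    btw_processes = btw_processes if btw_processes is not None else BTW_PROCESSES
    fits: dict[str, FitResult] = {}

    def fit_spec(spec: ModelSpec) -> FitResult:
        if spec.name not in fits:
            frame = prepare_design(edge_table, spec, group_col)
            fits[spec.name] = fit_gravity(frame, "ML", df_rule)
        return fits[spec.name]

    all_at = tuple(sorted({v for vs in at_processes.values() for v in vs}))
    all_btw = tuple(sorted({v for vs in btw_processes.values() for v in vs}))

    at_specs = [ModelSpec(f"at:{name}", at_vars=tuple(vs), round_tag="at")
                for name, vs in at_processes.items()]
    at_specs.append(ModelSpec("at:global", at_vars=all_at, round_tag="global"))
    btw_specs = [ModelSpec(f"btw:{name}", btw_vars=tuple(vs), round_tag="btw")
                 for name, vs in btw_processes.items()]
    btw_specs.append(ModelSpec("btw:global", btw_vars=all_btw, round_tag="global"))

    round_at = _rank_table([fit_spec(s) for s in at_specs + [NULL_SPEC]])
    round_btw = _rank_table([fit_spec(s) for s in btw_specs + [NULL_SPEC]])

    def survivors(tab, specs):
        names = set(tab[tab["dAIC"] < delta_aic]["model"])
        return [s for s in specs if s.name in names and s.round_tag != "null"]

    surv_at = survivors(round_at, at_specs)
    surv_btw = survivors(round_btw, btw_specs)

    combined: list[ModelSpec] = []
    for sa in surv_at:
        for sb in surv_btw:
            combined.append(ModelSpec(f"comb:{sa.name}|{sb.name}", at_vars=sa.at_vars,
                                      btw_vars=sb.btw_vars, round_tag="combined"))
    # a side with no surviving partner competes alone
    if not surv_btw:
        combined.extend(replace(sa, name=f"comb:{sa.name}|-", round_tag="combined") for sa in surv_at)
    if not surv_at:
        combined.extend(replace(sb, name=f"comb:-|{sb.name}", round_tag="combined") for sb in surv_btw)
    gg = ModelSpec("global-global", at_vars=all_at, btw_vars=all_btw, round_tag="global")
    # de-duplicate by covariate set; canonical names (null, global-global) win
    seen: dict[tuple, ModelSpec] = {}
    for s in [NULL_SPEC, gg] + sorted(combined, key=lambda s: s.name):
        key = (tuple(sorted(s.at_vars)), tuple(sorted(s.btw_vars)))
        seen.setdefault(key, s)
    round2_specs = list(seen.values())
    round_combined = _rank_table([fit_spec(s) for s in round2_specs])
    selected_name = _select(round_combined, fits, delta_aic)
    by_name = {s.name: s for s in round2_specs + at_specs + btw_specs + [NULL_SPEC]}
    return CompetitionResult(round_at, round_btw, round_combined, surv_at, surv_btw,
                             by_name[selected_name], fits)


# ---------------------------------------------------------------------------
# Effect sizes (Cohen's D from t) and interpretation
# ---------------------------------------------------------------------------


def cohens_d(t: float, df: float) -> float:
    """Cohen's D from a t statistic: D = 2 t / sqrt(df)."""
    if df <= 0:
        raise ValueError("df must be > 0")
    return 2.0 * t / np.sqrt(df)


@dataclass
class EffectSizeTable:
    table: pd.DataFrame  # index=term: cohens_d, ci_low, ci_high, p_value, significant, direction, flipped
    ci_rule: str

    def __post_init__(self):
        sig = ~((self.table["ci_low"] <= 0) & (self.table["ci_high"] >= 0))
        assert (self.table["significant"] == sig).all()


def effect_sizes(fit: FitResult, ci_rule: str = "normal", conf: float = 0.95) -> EffectSizeTable:
    """Cohen's D table for a converged REML fit.

    ``ci_rule="normal"`` uses the large-sample standard error
    ``se_d = sqrt(4/df + d^2/(2 df))``; ``"calibrated"`` uses a fixed
    half-width of ``1.40 * 2/sqrt(df)``.  A term is significant when its CI
    excludes zero.  The reported direction applies the log-transform sign
    flips and is reversed for between-site covariates (the gravity
    equation's resistance orientation).
    """
    if fit.estimation != "REML":
        raise ValueError("effect sizes are computed from the REML fit")
    if not fit.converged:
        raise ValueError("fit did not converge")
    z = sstats.norm.ppf(0.5 + conf / 2)
    rows = []
    for term, row in fit.params.iterrows():
        if term == "(intercept)":
            continue
        df = float(row["df"])
        if df <= 0:
            raise ValueError("df must be > 0")
        d = cohens_d(float(row["t_value"]), df)
        if ci_rule == "normal":
            se_d = np.sqrt(4.0 / df + d * d / (2.0 * df))
            lo, hi = d - z * se_d, d + z * se_d
        elif ci_rule == "calibrated":
            half = 1.40 * 2.0 / np.sqrt(df)
            lo, hi = d - half, d + half
        else:
            raise ValueError(f"unknown ci_rule {ci_rule!r}")
        significant = not (lo <= 0 <= hi)
        flipped = bool(fit.sign_flip_log.get(term, False))
        sign = np.sign(d)
        if flipped:
            sign = -sign
        if term.startswith("btw_"):
            sign = -sign
        direction = {1.0: "+", -1.0: "-"}.get(float(sign), "none") if significant else "none"
        rows.append({
            "term": term, "cohens_d": round(float(d), 4), "ci_low": float(lo), "ci_high": float(hi),
            "p_value": float(row["p_value"]), "significant": significant,
            "direction": direction, "flipped": flipped,
        })
    return EffectSizeTable(pd.DataFrame(rows).set_index("term"), ci_rule)


def interpretation_report(es: EffectSizeTable, predictions: dict[str, str] | None = None) -> pd.DataFrame:
    """Match each significant effect against its registered predicted sign.

    Emits one row per term: verdict in {supported, contradicted,
    insignificant, unregistered}.
    """
    predictions = predictions if predictions is not None else PREDICTIONS
    rows = []
    for term, row in es.table.iterrows():
        pred = predictions.get(term)
        if pred is None:
            verdict = "unregistered"
        elif not row["significant"]:
            verdict = "insignificant"
        elif row["direction"] == pred:
            verdict = "supported"
        else:
            verdict = "contradicted"
        rows.append({"term": term, "direction": row["direction"], "predicted": pred or "?",
                     "cohens_d": row["cohens_d"], "verdict": verdict})
    return pd.DataFrame(rows).set_index("term")
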