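"""Score derivation: spline screening, ordinalization, substitution models,
and weighted-extension enumeration/selection.

The four-stage derivation mirrors the study design of the CE-SOFA score:

1. screen nine continuous cardiovascular variables (hs-cTnT, NT-proBNP, HR,
   SBP, DBP, MAP, PP, RPP, PPP; biomarkers on the log scale) against 30-day
   mortality with natural-cubic-spline logistic models, choosing spline
   flexibility by AIC and ranking variables by AUC of the fitted risk;
2. transform the retained variables into ordinal point groups (0..k points)
   with cut-offs placed so adjacent bins carry approximately equal log-odds
   increments ("balanced effect size");
3. refit the six-component SOFA logistic model with the cardiovascular
   sub-score substituted by each candidate point group (odds ratios per
   point);
4. enumerate weighted extensions of the base SOFA score, rank them by
   training AUC, and compare the leaders against base SOFA with the DeLong
   test and the NRI.

:class:`ScoreDerivation` wraps the whole pipeline as a model object whose
``fit`` returns a :class:`DerivationResults` with a ``summary`` table; each
stage is also exposed as a standalone function.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .cohort import Cohort
from .evalstats import AucResult, LogisticFit, NriResult, auc, delong_test, fit_logistic, nri
from .scoring import (
    BASE_SOFA,
    OrdinalPointScheme,
    ScoreModel,
    score_cohort,
)

__all__ = [
    "NINE_VARIABLES",
    "LOG_VARIABLES",
    "SplineScreenResult",
    "CandidateModelResult",
    "ncs_basis",
    "select_df",
    "screen_variables",
    "ordinalize",
    "substitution_fit",
    "enumerate_extensions",
    "select_best",
    "ScoreDerivation",
    "DerivationResults",
]

#: The nine continuous cardiovascular candidate predictors.
NINE_VARIABLES = ("hs_ctnt", "nt_probnp", "hr", "sbp", "dbp", "map", "pp", "rpp", "ppp")
#: Right-skewed biomarkers entered on the natural-log scale.
LOG_VARIABLES = frozenset({"hs_ctnt", "nt_probnp"})

DEFAULT_DF_CANDIDATES = (1, 2, 3, 4, 5)


# ---------------------------------------------------------------------------
# Natural cubic spline basis

def ncs_basis(x, df: int, data=None) -> np.ndarray:
    """Natural cubic spline basis evaluated at ``x``.

    Boundary knots sit at the extremes of ``data`` (default ``x``) and the
    ``df - 1`` interior knots at equally spaced quantiles, so the basis has
    exactly ``df`` columns (no intercept). The function space is linear
    beyond the boundary knots. ``df = 1`` reduces to a single linear column.

    Uses the truncated-power natural-spline construction: with knots
    ``k_1 < ... < k_K``, columns are ``x`` and ``d_j(x) - d_{K-1}(x)`` for
    ``j = 1..K-2`` where ``d_j(x) = [(x-k_j)_+^3 - (x-k_K)_+^3]/(k_K - k_j)``.
    """
    x = np.asarray(x, dtype=float)
    if df < 1:
        raise ValueError("df must be >= 1")
    data = x if data is None else np.asarray(data, dtype=float)
    uniq = np.unique(data)
    if uniq.size < df + 2:
        raise ValueError(f"need at least df + 2 = {df + 2} distinct values, got {uniq.size}")
    probs = np.linspace(0, 1, df + 1)
    knots = np.quantile(data, probs)
    if np.unique(knots).size != knots.size:
        raise ValueError("insufficient distinct values: coincident quantile knots")
    K = knots.size
    cols = [x]
    if K > 2:
        kK, kK1 = knots[-1], knots[-2]

        def d(j):
            return (
                np.clip(x - knots[j], 0, None) ** 3 - np.clip(x - kK, 0, None) ** 3
            ) / (kK - knots[j])

        dlast = d(K - 2)
        for j in range(K - 2):
            cols.append(d(j) - dlast)
    return np.column_stack(cols)


@dataclass
class SplineScreenResult:
    """One variable's spline-logistic screen: chosen flexibility and AUC."""

    variable: str
    log_transformed: bool
    df: int
    knots: list[float]
    aic: float
    auc: float
    auc_ci: tuple[float, float]
    fitted_risk_curve: Callable[[np.ndarray], np.ndarray]
    fit: LogisticFit
    error: str | None = None


def select_df(
    x,
    y,
    candidates: Sequence[int] = DEFAULT_DF_CANDIDATES,
    variable: str = "x",
    log_transformed: bool = False,
) -> SplineScreenResult:
    """Pick the spline flexibility minimizing AIC (ties toward smaller df).

    Fits a logistic model on the natural-spline basis for each candidate df;
    AIC = 2k - 2 loglik counts the intercept.
    """
    if not candidates:
        raise ValueError("candidates must be non-empty")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=int)
    best = None
    errors = []
    for df in sorted(candidates):
        try:
            basis = ncs_basis(x, df)
            design = np.column_stack([np.ones_like(x), basis])
            fit = fit_logistic(design, y, names=["intercept"] + [f"ns{j+1}" for j in range(df)])
        except (ValueError, np.linalg.LinAlgError) as exc:
            errors.append(f"df={df}: {exc}")
            continue
        if best is None or fit.aic < best[1].aic - 1e-12:
            best = (df, fit)
    if best is None:
        raise ValueError(f"all spline fits failed for {variable!r}: {'; '.join(errors)}")
    df, fit = best
    x_train = x.copy()
    beta = fit.coefficients.copy()

    def risk(new_x):
        new_x = np.asarray(new_x, dtype=float)
        basis = ncs_basis(new_x, df, data=x_train)
        return expit(np.column_stack([np.ones(new_x.size), basis]) @ beta)

    a = auc(fit.fitted, y)
    return SplineScreenResult(
        variable=variable,
        log_transformed=log_transformed,
        df=df,
        knots=list(np.quantile(x, np.linspace(0, 1, df + 1))),
        aic=fit.aic,
        auc=a.auc,
        auc_ci=a.ci95,
        fitted_risk_curve=risk,
        fit=fit,
    )


def screen_variables(
    cohort: Cohort,
    variables: Sequence[str] = NINE_VARIABLES,
    df_candidates: Sequence[int] = DEFAULT_DF_CANDIDATES,
) -> list[SplineScreenResult]:
    """Spline-screen each continuous variable against 30-day mortality.

    hs-cTnT and NT-proBNP enter on the log scale; derived hemodynamics (MAP,
    PP, RPP, PPP) are computed on the fly. A variable whose fits all fail is
    reported with its error rather than aborting the screen. Results are
    returned in input order; sort by ``auc`` for a ranking.
    """
    y = cohort.outcome
    out = []
    for var in variables:
        xv = cohort.field(var)
        logged = var in LOG_VARIABLES
        if logged:
            xv = np.log(xv)
        try:
            out.append(
                select_df(xv, y, df_candidates, variable=var, log_transformed=logged)
            )
        except ValueError as exc:
            out.append(
                SplineScreenResult(
                    variable=var, log_transformed=logged, df=0, knots=[],
                    aic=np.nan, auc=np.nan, auc_ci=(np.nan, np.nan),
                    fitted_risk_curve=lambda v: np.full(np.size(v), np.nan),
                    fit=None, error=str(exc),
                )
            )
    return out


# ---------------------------------------------------------------------------
# Ordinalization with balanced effect sizes

def ordinalize(
    x,
    y,
    n_bins: int = 5,
    transform: str = "identity",
    variable: str = "x",
    min_bin_frac: float = 0.05,
    grid_step: float = 0.005,
    df_candidates: Sequence[int] = DEFAULT_DF_CANDIDATES,
    max_sweeps: int = 50,
    span_bonus: float = 1e-3,
) -> OrdinalPointScheme:
    """Bin a continuous variable into ``n_bins`` ordinal point groups.

    Cut-offs are placed so the per-bin mean spline-fitted log-odds rises by
    approximately equal increments: thresholds start at equal-count
    quantiles, then coordinate descent over a quantile grid (``grid_step``
    resolution) minimizes the variance of adjacent-bin log-odds increments
    minus ``span_bonus`` times the first-to-last log-odds span. The span
    term regularizes the degenerate case of a linear log-odds, where every
    threshold family has near-zero increment variance: it selects the
    maximal-spread member, whose outer bins sit at the bin-mass floor.
    Every bin must keep at least ``min_bin_frac`` of the observations, and
    thresholds are always observed data values.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=int)
    if np.unique(x).size < n_bins:
        raise ValueError(f"x needs at least {n_bins} distinct values")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    xt = np.log(x) if transform == "log" else x.copy()

    screen = select_df(xt, y, df_candidates, variable=variable)
    lo = logit(np.clip(screen.fit.fitted, 1e-12, 1 - 1e-12))

    order = np.argsort(xt, kind="stable")
    xs = xt[order]
    los = lo[order]
    n = xs.size
    prefix = np.concatenate([[0.0], np.cumsum(los)])
    min_count = max(int(np.ceil(min_bin_frac * n)), 1)

    def objective(pos: tuple[int, ...]) -> float:
        bounds = (0, *pos, n)
        means = []
        for a, b in zip(bounds[:-1], bounds[1:]):
            if b - a < min_count:
                return np.inf
            means.append((prefix[b] - prefix[a]) / (b - a))
        incs = np.diff(means)
        return float(np.var(incs)) - span_bonus * float(means[-1] - means[0])

    # candidate split positions on a quantile grid
    grid = np.unique(
        np.clip(np.round(np.arange(grid_step, 1, grid_step) * n).astype(int), 1, n - 1)
    )

    def descend(pos: list[int]) -> tuple[float, list[int]]:
        best = objective(tuple(pos))
        for _ in range(max_sweeps):
            moved = False
            for j in range(n_bins - 1):
                lo_b = pos[j - 1] if j > 0 else 0
                hi_b = pos[j + 1] if j < n_bins - 2 else n
                cand = grid[(grid > lo_b) & (grid < hi_b)]
                for c in cand:
                    trial = pos.copy()
                    trial[j] = int(c)
                    val = objective(tuple(trial))
                    if val < best:
                        best, pos, moved = val, trial, True
            if not moved:
                break
        return best, pos

    # multi-start: equal-mass quantiles, and outer bins at the mass floor
    # (the optimum under a linear log-odds, where descent from equal-mass
    # starts can stall on the flat increment-variance manifold)
    starts = [[int(round(k * n / n_bins)) for k in range(1, n_bins)]]
    lo_edge, hi_edge = min_count, n - min_count
    if hi_edge > lo_edge and n_bins >= 2:
        spread = [
            int(round(lo_edge + k * (hi_edge - lo_edge) / (n_bins - 2)))
            for k in range(n_bins - 1)
        ] if n_bins > 2 else [n // 2]
        starts.append(sorted(set(np.clip(spread, 1, n - 1))))
    best, pos = np.inf, None
    for start in starts:
        if len(start) != n_bins - 1:
            continue
        val, cfg = descend(list(start))
        if val < best:
            best, pos = val, cfg
    if pos is None or not np.isfinite(best):
        raise ValueError("no threshold configuration satisfies the bin-mass constraint")

    thr_t = xs[pos]
    if np.unique(thr_t).size != len(pos):
        raise ValueError("degenerate x: coincident thresholds after tie collapsing")
    thresholds = np.exp(thr_t) if transform == "log" else thr_t
    return OrdinalPointScheme(
        variable=variable,
        transform=transform,
        thresholds=tuple(float(t) for t in thresholds),
        weight=1,
    )


# ---------------------------------------------------------------------------
# Component-substitution multivariable models

NONCV_COMPONENTS = ("sofa_neuro", "sofa_resp", "sofa_renal", "sofa_hepatic", "sofa_coag")


def substitution_fit(
    cohort: Cohort,
    replacement: OrdinalPointScheme | None = None,
    adjust_age_sex: bool = False,
) -> LogisticFit:
    """Six-term multivariable logistic model of 30-day mortality.

    The five non-cardiovascular SOFA sub-scores always enter; the sixth term
    is the cardiovascular sub-score itself (``replacement=None``) or the
    candidate point group substituted for it. Optional age/sex adjustment.
    Reports odds ratios per point with 95% Wald CIs.
    """
    y = cohort.outcome
    cols = [np.ones(len(cohort))]
    names = ["intercept"]
    for comp in NONCV_COMPONENTS:
        cols.append(cohort.field(comp))
        names.append(comp)
    if replacement is None:
        from .scoring import cardiovascular_sofa

        cv = np.array(
            [
                cardiovascular_sofa(
                    r.hemodynamics.map, r.dopamine_dose, r.norepinephrine_dose,
                    r.other_vasoactive,
                )
                for r in cohort
            ],
            dtype=float,
        )
        cols.append(cv)
        names.append("sofa_cardio")
    else:
        from .scoring import assign_points, _scheme_value

        pts = np.array(
            [assign_points(_scheme_value(r, replacement), replacement) for r in cohort],
            dtype=float,
        )
        cols.append(pts)
        names.append(f"{replacement.variable}_points")
    if adjust_age_sex:
        cols.append(cohort.field("age"))
        names.append("age")
        cols.append(np.array([r.sex == "male" for r in cohort], dtype=float))
        names.append("male")
    return fit_logistic(np.column_stack(cols), y, names=names)


# ---------------------------------------------------------------------------
# Weighted-extension enumeration and selection

def enumerate_extensions(
    base_schemes: dict[str, OrdinalPointScheme],
    weights: Sequence[int] = (1, 2, 3),
    weights_by_name: dict[str, Sequence[int]] | None = None,
) -> list[ScoreModel]:
    """All extensions of base SOFA formed by weighting subsets of schemes.

    Each scheme is either absent or included at one of its allowed weights;
    the empty combination is excluded. Ordering is deterministic: by number
    of included schemes, then lexically by (name, weight).
    """
    if not base_schemes:
        raise ValueError("need at least one scheme")
    weights_by_name = weights_by_name or {}
    names = sorted(base_schemes)
    choices = []
    for name in names:
        allowed = tuple(sorted(weights_by_name.get(name, weights)))
        choices.append((None, *allowed))
    models = []
    for combo in itertools.product(*choices):
        included = [
            (name, w) for name, w in zip(names, combo) if w is not None
        ]
        if not included:
            continue
        schemes = tuple(base_schemes[name].reweighted(w) for name, w in included)
        label = "SOFA+" + "+".join(
            f"{name}" + (f"x{w}" if w > 1 else "") for name, w in included
        )
        models.append(ScoreModel(name=label, schemes=schemes))
    models.sort(key=lambda m: (len(m.schemes), m.name))
    return models


@dataclass
class CandidateModelResult:
    """One candidate extension scored on the training cohort."""

    model: ScoreModel
    auc: float
    auc_ci: tuple[float, float]
    delong_p_vs_base: float | None = None
    nri_vs_base: NriResult | None = None


def _score_probability(scores: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Predicted mortality from a univariable logistic fit on the score."""
    design = np.column_stack([np.ones_like(scores, dtype=float), scores.astype(float)])
    return fit_logistic(design, y, names=["intercept", "score"]).fitted


def select_best(
    cohort: Cohort,
    candidates: Sequence[ScoreModel],
    k: int = 4,
) -> tuple[list[CandidateModelResult], ScoreModel]:
    """Rank candidate extensions by training AUC and compare leaders to SOFA.

    Ties in AUC break toward fewer added points (parsimony), then model name.
    The top ``k`` (clamped to the candidate count) additionally get a DeLong
    p-value and a category-free NRI versus the base SOFA score.
    """
    if len(candidates) < 2:
        raise ValueError("need at least 2 candidate models")
    y = cohort.outcome
    base_scores = score_cohort(cohort, BASE_SOFA)
    results = []
    for model in candidates:
        s = score_cohort(cohort, model)
        a = auc(s, y)
        results.append((model, s, a))
    results.sort(key=lambda t: (-t[2].auc, t[0].added_max_points, t[0].name))

    base_prob = _score_probability(base_scores, y)
    out = []
    for rank, (model, s, a) in enumerate(results):
        res = CandidateModelResult(model=model, auc=a.auc, auc_ci=a.ci95)
        if rank < k:
            res.delong_p_vs_base = delong_test(s, base_scores, y).p
            res.nri_vs_base = nri(base_prob, _score_probability(s, y), y)
        out.append(res)
    return out, out[0].model


# ---------------------------------------------------------------------------
# The pipeline as a model object

class ScoreDerivation:
    """Derive a cardiac-extended SOFA score on a training cohort.

    Parameters
    ----------
    cohort : training cohort with 30-day outcomes.
    ordinal_variables : continuous variables to ordinalize, mapping name ->
        number of bins. Defaults to hs-cTnT and NT-proBNP with 5 bins (0-4
        points) and HR with 3 (0-2 points).
    extension_variables : schemes entering the extension enumeration
        (default: the two biomarkers and binary AF; HR is screened and
        ordinalized but not extended, mirroring its null multivariable
        effect in the reference analysis).
    weights / af_weights : allowed weight multipliers for continuous and AF
        schemes.
    """

    def __init__(
        self,
        cohort: Cohort,
        df_candidates: Sequence[int] = DEFAULT_DF_CANDIDATES,
        ordinal_variables: dict[str, int] | None = None,
        extension_variables: Sequence[str] = ("hs_ctnt", "nt_probnp", "af"),
        weights: Sequence[int] = (1, 2, 3),
        af_weights: Sequence[int] = (1, 2),
        top_k: int = 4,
        screen: bool = True,
    ):
        if len(cohort) == 0:
            raise ValueError("empty cohort")
        self.cohort = cohort
        self.df_candidates = tuple(df_candidates)
        self.ordinal_variables = ordinal_variables or {"hs_ctnt": 5, "nt_probnp": 5, "hr": 3}
        self.extension_variables = tuple(extension_variables)
        self.weights = tuple(weights)
        self.af_weights = tuple(af_weights)
        self.top_k = top_k
        self.screen = screen

    def fit(self) -> "DerivationResults":
        cohort = self.cohort
        screen_results = (
            screen_variables(cohort, df_candidates=self.df_candidates) if self.screen else []
        )

        schemes: dict[str, OrdinalPointScheme] = {}
        for var, n_bins in self.ordinal_variables.items():
            transform = "log" if var in LOG_VARIABLES else "identity"
            schemes[var] = ordinalize(
                cohort.field(var), cohort.outcome, n_bins=n_bins,
                transform=transform, variable=var, df_candidates=self.df_candidates,
            )
        schemes["af"] = OrdinalPointScheme(variable="af", binary=True, binary_points=2)

        substitution = {"sofa_cardio": substitution_fit(cohort, None)}
        for var, scheme in schemes.items():
            substitution[f"{var}_points"] = substitution_fit(cohort, scheme)

        ext = {v: schemes[v] for v in self.extension_variables}
        candidates = enumerate_extensions(
            ext, weights=self.weights,
            weights_by_name={"af": self.af_weights} if "af" in ext else None,
        )
        ranking, final = select_best(cohort, candidates, k=self.top_k)
        return DerivationResults(
            derivation=self,
            screen=screen_results,
            schemes=schemes,
            substitution=substitution,
            candidates=ranking,
            final_model=final,
        )


@dataclass
class DerivationResults:
    """Everything the derivation produced, with tabular summaries."""

    derivation: ScoreDerivation
    screen: list[SplineScreenResult]
    schemes: dict[str, OrdinalPointScheme]
    substitution: dict[str, LogisticFit]
    candidates: list[CandidateModelResult]
    final_model: ScoreModel

    def screen_table(self) -> pd.DataFrame:
        rows = [
            {
                "variable": r.variable,
                "log": r.log_transformed,
                "df": r.df,
                "aic": r.aic,
                "auc": r.auc,
                "error": r.error or "",
            }
            for r in self.screen
        ]
        return pd.DataFrame(rows).sort_values("auc", ascending=False, na_position="last")

    def candidate_table(self) -> pd.DataFrame:
        rows = []
        for rank, c in enumerate(self.candidates, start=1):
            rows.append(
                {
                    "rank": rank,
                    "model": c.model.name,
                    "auc": c.auc,
                    "auc_lo": c.auc_ci[0],
                    "auc_hi": c.auc_ci[1],
                    "delong_p_vs_sofa": c.delong_p_vs_base,
                    "nri_vs_sofa": c.nri_vs_base.nri if c.nri_vs_base else None,
                    "nri_p": c.nri_vs_base.p if c.nri_vs_base else None,
                }
            )
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        def scheme_dict(s: OrdinalPointScheme) -> dict:
            if s.binary:
                return {"variable": s.variable, "binary": True,
                        "binary_points": s.binary_points, "weight": s.weight}
            return {"variable": s.variable, "transform": s.transform,
                    "thresholds": list(s.thresholds), "weight": s.weight}

        return {
            "cohort": self.derivation.cohort.label,
            "n": len(self.derivation.cohort),
            "screen": [
                {"variable": r.variable, "log": r.log_transformed, "df": r.df,
                 "aic": None if not np.isfinite(r.aic) else r.aic,
                 "auc": None if not np.isfinite(r.auc) else r.auc,
                 "error": r.error}
                for r in self.screen
            ],
            "schemes": {name: scheme_dict(s) for name, s in self.schemes.items()},
            "substitution_models": {
                name: {
                    "terms": fit.names,
                    "odds_ratios": fit.odds_ratios.tolist(),
                    "ci95": fit.ci95.tolist(),
                    "p_values": fit.p_values.tolist(),
                    "aic": fit.aic,
                }
                for name, fit in self.substitution.items()
            },
            "candidates": self.candidate_table().to_dict(orient="records"),
            "final_model": {
                "name": self.final_model.name,
                "max_score": self.final_model.max_score,
                "schemes": [scheme_dict(s) for s in self.final_model.schemes],
            },
        }

    def summary(self) -> str:
        parts = [f"Score derivation on cohort {self.derivation.cohort.label!r} "
                 f"(n = {len(self.derivation.cohort)}, "
                 f"mortality = {self.derivation.cohort.mortality:.1%})"]
        if self.screen:
            parts.append("\nVariable screen (spline logistic, AIC-chosen df):")
            parts.append(self.screen_table().to_string(index=False, float_format=lambda v: f"{v:.3f}"))
        parts.append("\nDerived point schemes:")
        for name, s in self.schemes.items():
            if s.binary:
                parts.append(f"  {name}: binary, {s.binary_points} points when present")
            else:
                thr = ", ".join(f"{t:.4g}" for t in s.thresholds)
                parts.append(f"  {name}: thresholds [{thr}] ({s.transform})")
        parts.append("\nTop candidate extensions:")
        parts.append(
            self.candidate_table().head(self.derivation.top_k).to_string(
                index=False, float_format=lambda v: f"{v:.4f}"
            )
        )
        parts.append(f"\nSelected model: {self.final_model.name} "
                     f"(max score {self.final_model.max_score})")
        return "\n".join(parts)
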