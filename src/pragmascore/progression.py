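"""Linear mixed-effects progression models for two-visit trial outcomes.

The model for an outcome :math:`y_{ij}` of patient *i* at visit *j* (SOS =
start of study, EOS = end of study, 48 weeks apart) is a random-intercept
LMM::

    y_ij = b0 + b1 I(EOS) + b2 I(placebo) + b3 I(tobra)
         + b4 I(EOS)I(placebo) + b5 I(EOS)I(tobra) + b6 I(placebo)I(tobra)
         + u_i + e_ij,     u_i ~ N(0, tau^2),  e_ij ~ N(0, sigma^2)

estimated by REML.  The time coefficient ``b1`` is the 48-week progression
of the (possibly square-root transformed) outcome in the reference group;
the ``time x group`` interaction is the treatment-effect test.  Percent
scores are heteroscedastic on their raw scale, so PRAGMA volume-fraction
outcomes are analysed after a square-root transform.

Wald t-tests use the nested within/between degrees-of-freedom convention
of the multilevel-model tradition: terms that vary within a patient (time
and its interactions, and the intercept) get ``n_obs - n_patients -
p_within`` df; patient-level terms get ``n_patients - p_between - 1`` df.

Two fitting routes produce identical REML results:

* a closed-form route for complete two-visit cohorts.  With one SOS and
  one EOS value per patient, the per-patient difference ``d_i`` and mean
  ``m_i`` are independent, carry all the information on the within- and
  between-patient terms respectively, and reduce the REML fit to two
  ordinary least-squares problems (``Var d = 2 sigma^2``,
  ``Var m = tau^2 + sigma^2 / 2``);
* statsmodels ``MixedLM`` for unbalanced cohorts (patients with a single
  scorable visit are retained and inform the between-patient terms).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "LmmFit",
    "FixedEffect",
    "FULL_TERMS",
    "REDUCED_TERMS",
    "OUTCOMES",
    "DEFAULT_TRANSFORMS",
    "fit_lmm",
    "progression_summary",
]

FULL_TERMS = (
    "intercept",
    "time_eos",
    "group_placebo",
    "tobra_yes",
    "time_eos:group_placebo",
    "time_eos:tobra_yes",
    "group_placebo:tobra_yes",
)
REDUCED_TERMS = (
    "intercept",
    "time_eos",
    "group_placebo",
    "time_eos:group_placebo",
)
TIME_ONLY_TERMS = ("intercept", "time_eos")

#: Outcomes of the full reanalysis; PRAGMA volume fractions are modelled on
#: the square-root scale, CF-CT percent-of-maximum scores and FEV1
#: %predicted on the identity scale.
OUTCOMES = (
    "pragma_bronchiectasis",
    "pragma_mucus_plugging",
    "pragma_awt",
    "pragma_disease",
    "cfct_bronchiectasis",
    "cfct_mucus_plugging",
    "cfct_awt",
    "cfct_disease",
    "fev1_percent_predicted",
)
DEFAULT_TRANSFORMS = {
    name: ("sqrt" if name.startswith("pragma_") else "identity") for name in OUTCOMES
}


@dataclass(frozen=True)
class FixedEffect:
    estimate: float
    se: float
    df: float
    p_value: float


@dataclass
class LmmFit:
    outcome: str
    transform: str
    terms: tuple[str, ...]
    fixed_effects: dict[str, FixedEffect]
    var_between: float
    var_residual: float
    n_obs: int
    n_patients: int
    method: str = "reml"

    @property
    def time_effect(self) -> FixedEffect:
        return self.fixed_effects["time_eos"]

    def to_dict(self) -> dict:
        return {
            "outcome": self.outcome,
            "transform": self.transform,
            "terms": list(self.terms),
            "fixed_effects": {
                t: {"estimate": fe.estimate, "se": fe.se, "df": fe.df, "p_value": fe.p_value}
                for t, fe in self.fixed_effects.items()
            },
            "var_between": self.var_between,
            "var_residual": self.var_residual,
            "n_obs": self.n_obs,
            "n_patients": self.n_patients,
            "method": self.method,
        }


def _prepare(data: pd.DataFrame, outcome: str, transform: str, terms: str) -> pd.DataFrame:
    required = {"patient_id", "visit", "value", "outcome"}
    if terms in ("full", "reduced"):
        required.add("arm")
    if terms == "full":
        required.add("tobramycin")
    missing = required - set(data.columns)
    if missing:
        raise ValueError(f"cohort table missing columns {sorted(missing)}")
    sub = data.loc[data["outcome"] == outcome].copy()
    if sub.empty:
        raise ValueError(f"no rows for outcome {outcome!r}")
    bad_visit = ~sub["visit"].isin(("SOS", "EOS"))
    if bad_visit.any():
        raise ValueError(f"unknown visit values {sorted(sub.loc[bad_visit, 'visit'].unique())}")
    if sub.duplicated(subset=["patient_id", "visit"]).any():
        raise ValueError("duplicate patient-visit rows for outcome " + outcome)
    patient_cols = {"full": ("arm", "tobramycin"), "reduced": ("arm",), "time_only": ()}[terms]
    for col in patient_cols:
        if sub.groupby("patient_id")[col].nunique().gt(1).any():
            raise ValueError(f"{col} varies within a patient; it must be patient-constant")
    y = sub["value"].to_numpy(dtype=float)
    if transform == "sqrt":
        if (y < 0).any():
            raise ValueError("negative outcome value; sqrt transform requires values >= 0")
        sub["y"] = np.sqrt(y)
    elif transform == "identity":
        sub["y"] = y
    else:
        raise ValueError(f"unknown transform {transform!r}")
    sub["t"] = (sub["visit"] == "EOS").astype(float)
    if terms in ("full", "reduced"):
        sub["g"] = (sub["arm"].astype(str).str.lower() == "placebo").astype(float)
    if terms == "full":
        tob = sub["tobramycin"].astype(str).str.lower().isin(("yes", "true", "1"))
        sub["b"] = tob.astype(float)
    return sub


def _design(sub: pd.DataFrame, terms: str) -> tuple[np.ndarray, tuple[str, ...]]:
    t = sub["t"].to_numpy()
    one = np.ones(len(sub))
    if terms == "time_only":
        return np.column_stack([one, t]), TIME_ONLY_TERMS
    g = sub["g"].to_numpy()
    if terms == "full":
        b = sub["b"].to_numpy()
        X = np.column_stack([one, t, g, b, t * g, t * b, g * b])
        return X, FULL_TERMS
    X = np.column_stack([one, t, g, t * g])
    return X, REDUCED_TERMS


def _check_identifiable(X: np.ndarray, names: Sequence[str], sub: pd.DataFrame) -> None:
    counts = sub.groupby("patient_id")["visit"].count()
    if (counts < 2).all():
        raise ValueError(
            "term time_eos is unidentifiable: no patient has both a SOS and an EOS value"
        )
    for j, name in enumerate(names):
        if name != "intercept" and np.ptp(X[:, j]) == 0:
            raise ValueError(f"term {name} is unidentifiable: column has no variation")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient; some term is unidentifiable")


_WITHIN = lambda name: name == "intercept" or "time_eos" in name


def _dfs(names: Sequence[str], n_obs: int, n_patients: int) -> dict[str, float]:
    p_within = sum(1 for n in names if "time_eos" in n)
    p_between = sum(1 for n in names if n != "intercept" and "time_eos" not in n)
    within_df = n_obs - n_patients - p_within
    between_df = n_patients - p_between - 1
    return {n: float(within_df if _WITHIN(n) else between_df) for n in names}


def _pvalue(est: float, se: float, df: float) -> float:
    if se <= 0 or df < 1:
        return float("nan")
    return float(2.0 * stats.t.sf(abs(est) / se, df))


def fit_lmm(
    data: pd.DataFrame,
    outcome: str,
    transform: str = "identity",
    terms: str = "full",
) -> LmmFit:
    """Fit the random-intercept progression LMM by REML.

    ``data`` is a long cohort table with columns ``patient_id, visit, arm,
    tobramycin, outcome, value`` (``tobramycin`` optional for the reduced
    term set).  ``terms`` is ``"full"`` (the 7-term model with treatment
    group and tobramycin main effects and all two-way interactions) or
    ``"reduced"`` (intercept, time, arm, time x arm — the power-simulation
    analysis model).
    """
    if terms not in ("full", "reduced", "time_only"):
        raise ValueError("terms must be 'full', 'reduced' or 'time_only'")
    sub = _prepare(data, outcome, transform, terms)
    X, names = _design(sub, terms)
    _check_identifiable(X, names, sub)

    counts = sub.groupby("patient_id")["visit"].agg(["count", "nunique"])
    balanced = bool((counts["count"] == 2).all() and (counts["nunique"] == 2).all())
    n_obs = len(sub)
    n_patients = sub["patient_id"].nunique()

    if balanced:
        est, se, tau2, sigma2 = _fit_balanced(sub, terms)
    else:
        est, se, tau2, sigma2 = _fit_mixedlm(sub, X, names)

    dfs = _dfs(names, n_obs, n_patients)
    fixed = {
        name: FixedEffect(float(est[name]), float(se[name]), dfs[name], _pvalue(est[name], se[name], dfs[name]))
        for name in names
    }
    return LmmFit(
        outcome=outcome,
        transform=transform,
        terms=tuple(names),
        fixed_effects=fixed,
        var_between=float(tau2),
        var_residual=float(sigma2),
        n_obs=n_obs,
        n_patients=n_patients,
    )


def _fit_balanced(sub: pd.DataFrame, terms: str):
    """Exact REML via the per-patient difference/mean decomposition.

    For one SOS and one EOS value per patient, ``d_i = y_EOS - y_SOS``
    carries the within-patient terms (``Var d = 2 sigma^2``) and ``m_i``
    the patient-level terms (``Var m = tau^2 + sigma^2 / 2``); the two are
    independent, so REML reduces to two OLS fits.
    """
    wide = sub.pivot(index="patient_id", columns="visit", values="y")
    cov_cols = {"full": ["g", "b"], "reduced": ["g"], "time_only": []}[terms]
    pat = sub.groupby("patient_id")[cov_cols].first().loc[wide.index] if cov_cols else None
    d = (wide["EOS"] - wide["SOS"]).to_numpy()
    m = ((wide["EOS"] + wide["SOS"]) / 2.0).to_numpy()
    N = len(d)
    one = np.ones(N)
    g = pat["g"].to_numpy() if pat is not None else None

    if terms == "time_only":
        Xd = one[:, None]
        Xm = one[:, None]
        w_names = ("time_eos",)
        b_names = ("intercept",)
        adj_idx = (0,)
    elif terms == "full":
        b = pat["b"].to_numpy()
        Xd = np.column_stack([one, g, b])           # time, time:group, time:tobra
        Xm = np.column_stack([one, g, b, g * b])    # intercept, group, tobra, group:tobra
        w_names = ("time_eos", "time_eos:group_placebo", "time_eos:tobra_yes")
        b_names = ("intercept", "group_placebo", "tobra_yes", "group_placebo:tobra_yes")
        adj_idx = (0, 1, 2)  # Xm columns receiving the -0.5 * beta_w shift
    else:
        Xd = np.column_stack([one, g])
        Xm = np.column_stack([one, g])
        w_names = ("time_eos", "time_eos:group_placebo")
        b_names = ("intercept", "group_placebo")
        adj_idx = (0, 1)

    p_w, p_b = Xd.shape[1], Xm.shape[1]
    if N <= max(p_w, p_b):
        raise ValueError("too few patients for the requested term set")

    XtX_d = Xd.T @ Xd
    beta_w = np.linalg.solve(XtX_d, Xd.T @ d)
    rss_d = float(np.sum((d - Xd @ beta_w) ** 2))
    sigma2 = rss_d / (2.0 * (N - p_w))
    cov_w = 2.0 * sigma2 * np.linalg.inv(XtX_d)

    XtX_m = Xm.T @ Xm
    gamma = np.linalg.solve(XtX_m, Xm.T @ m)
    rss_m = float(np.sum((m - Xm @ gamma) ** 2))
    w_hat = rss_m / (N - p_b)
    tau2 = max(0.0, w_hat - sigma2 / 2.0)

    # The within-visit mean of each time column is 0.5 x the matching
    # patient-level column, so the patient-level coefficients absorb
    # 0.5 beta_w; shift them back and propagate the (independent) variance.
    beta_b = gamma.copy()
    cov_b = w_hat * np.linalg.inv(XtX_m)
    for pos, widx in zip(adj_idx, range(p_w)):
        beta_b[pos] -= 0.5 * beta_w[widx]
    P = np.zeros((p_b, p_w))
    for pos, widx in zip(adj_idx, range(p_w)):
        P[pos, widx] = 0.5
    cov_b = cov_b + P @ cov_w @ P.T

    est = dict(zip(w_names, beta_w)) | dict(zip(b_names, beta_b))
    se = dict(zip(w_names, np.sqrt(np.diag(cov_w)))) | dict(
        zip(b_names, np.sqrt(np.diag(cov_b)))
    )
    return est, se, tau2, sigma2


def _fit_mixedlm(sub: pd.DataFrame, X: np.ndarray, names: Sequence[str]):
    """REML fit through statsmodels MixedLM (unbalanced cohorts).

    The response is standardized before fitting (REML is equivariant under
    scaling, and near-constant outcomes such as tiny AWT fractions are
    numerically singular on their raw scale) and results are scaled back.
    """
    import statsmodels.api as sm

    groups = pd.Categorical(sub["patient_id"]).codes
    y = sub["y"].to_numpy()
    scale = float(np.std(y))
    if scale == 0:
        raise ValueError("outcome has no variation; model unidentifiable")
    res = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(y / scale, X, groups=groups)
        # lbfgs can step through a numerically singular V along the way;
        # the derivative-free optimizers are slower but robust.
        for method in ("lbfgs", "powell", "nm"):
            try:
                res = model.fit(reml=True, method=method)
                break
            except np.linalg.LinAlgError:
                continue
    if res is None:
        raise RuntimeError("mixed-model fit failed with every optimizer")
    est = dict(zip(names, scale * np.asarray(res.fe_params, dtype=float)))
    se = dict(zip(names, scale * np.asarray(res.bse_fe, dtype=float)))
    tau2 = float(np.asarray(res.cov_re)[0, 0]) * scale**2
    sigma2 = float(res.scale) * scale**2
    return est, se, tau2, sigma2


def progression_summary(
    fits: Iterable[LmmFit],
    alpha: float = 0.05,
    expected: Sequence[str] = OUTCOMES,
) -> pd.DataFrame:
    """Tabulate the 48-week time effect across outcomes.

    One row per fitted outcome with the time estimate, its SE and p-value,
    and a ``progressing`` flag at the two-sided ``alpha`` level (no
    multiplicity correction: each outcome is reported at its nominal
    level).  Expected outcomes without a fit are warned about and omitted.
    """
    fits = list(fits)
    have = {f.outcome for f in fits}
    for name in expected:
        if name not in have:
            warnings.warn(f"no fit provided for outcome {name!r}; row omitted", stacklevel=2)
    rows = []
    for f in fits:
        te = f.time_effect
        rows.append(
            {
                "outcome": f.outcome,
                "transform": f.transform,
                "time_estimate": te.estimate,
                "se": te.se,
                "p_value": te.p_value,
                "progressing": bool(te.p_value < alpha),
                "n_patients": f.n_patients,
                "n_obs": f.n_obs,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "outcome",
            "transform",
            "time_estimate",
            "se",
            "p_value",
            "progressing",
            "n_patients",
            "n_obs",
        ],
    )
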