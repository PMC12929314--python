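"""Patient-reported effectiveness outcomes.

EQ-5D-5L responses (five dimensions, five levels each) are scored into
utility indices through a pluggable value set, multiplied by time to give
QALYs.  Likert satisfaction/experience items are rescaled linearly onto
0-100.  Group means are adjusted for age, gender and general health with a
linear mixed model carrying a per-site random intercept (the study design
is a matched prescriber/non-prescriber pair within each of eight sites),
and uncertainty in the adjusted group difference comes from a
nonparametric bootstrap that resamples patients within site x group.

The England EQ-5D-5L tariff is licensed content and is not shipped; a toy
additive value set (1 - 0.05 per level step, so 11111 -> 1.0 and
55555 -> 0.0) is provided for tests and synthetic data, and any tariff can
be supplied as a two-column table (state, value).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import product
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .params_io import EffectSummary

__all__ = [
    "ValueSet",
    "toy_value_set",
    "score_eq5d",
    "utility_to_qaly",
    "scale_likert",
    "add_scores",
    "adjust_group_means",
    "BootstrapResult",
    "bootstrap_mean_difference",
]

EQ5D_DIMENSIONS = (
    "mobility",
    "self_care",
    "usual_activities",
    "pain_discomfort",
    "anxiety_depression",
)

_ALL_STATES = ["".join(map(str, levels)) for levels in product(range(1, 6), repeat=5)]


@dataclass(frozen=True)
class ValueSet:
    """Mapping from the 3,125 EQ-5D-5L health states to utility values.

    Anchored at full health: value("11111") must be exactly 1.0 and no
    state may exceed 1.0.  Values below 0 (states worse than dead) are
    admitted if the tariff contains them.
    """

    values: dict[str, float]
    name: str = "custom"

    def __post_init__(self) -> None:
        if self.values.get("11111") != 1.0:
            raise ValueError("value set must anchor state 11111 at 1.0")
        if any(v > 1.0 for v in self.values.values()):
            raise ValueError("value set contains values above 1.0")

    def value(self, state: str) -> float:
        state = _check_state(state)
        try:
            return self.values[state]
        except KeyError:
            raise KeyError(f"state {state!r} missing from value set {self.name!r}")

    @classmethod
    def from_table(cls, path: str | Path, name: str | None = None) -> "ValueSet":
        df = pd.read_csv(path, dtype={"state": str}, float_precision="round_trip")
        return cls(dict(zip(df["state"], df["value"].astype(float))),
                   name=name or Path(path).stem)

    def to_table(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("state,value\n")
            for state, value in self.values.items():
                fh.write(f"{state},{value!r}\n")


def toy_value_set() -> ValueSet:
    """Additive test tariff: utility = 1 - 0.05 x sum(level - 1)."""
    return ValueSet(
        {s: 1.0 - 0.05 * sum(int(c) - 1 for c in s) for s in _ALL_STATES},
        name="toy_additive",
    )


def _check_state(state: str) -> str:
    state = str(state)
    if len(state) != 5 or any(c not in "12345" for c in state):
        raise ValueError(f"EQ-5D-5L state must be 5 digits in 1..5, got {state!r}")
    return state


def score_eq5d(state: str, value_set: ValueSet) -> float:
    """Utility index of one EQ-5D-5L response (pure table lookup)."""
    return value_set.value(state)


def utility_to_qaly(utility: float, duration: float = 1.0) -> float:
    """QALYs accrued at *utility* over *duration* years."""
    if duration < 0:
        raise ValueError("duration must be nonnegative")
    return utility * duration


def scale_likert(items: Sequence[int] | Iterable[int]) -> float:
    """Mean of 5-point Likert items rescaled linearly onto 0-100."""
    items = list(items)
    if not items:
        raise ValueError("at least one Likert item is required")
    arr = np.asarray(items, dtype=float)
    if ((arr < 1) | (arr > 5)).any():
        raise ValueError("Likert responses must lie in 1..5")
    return float(np.mean((arr - 1.0) / 4.0) * 100.0)


def add_scores(
    patients: pd.DataFrame,
    value_set: ValueSet | None = None,
    duration: float = 1.0,
) -> pd.DataFrame:
    """Attach qaly / satisfaction / experience columns to a patient table.

    Satisfaction and experience are the 0-100 rescaled means of the
    ``sat_*`` and ``exp_*`` Likert columns; qaly scores the ``eq5d`` state
    through *value_set* (toy additive set by default).
    """
    vs = value_set or toy_value_set()
    out = patients.copy()
    out["qaly"] = [
        utility_to_qaly(score_eq5d(s, vs), duration) for s in out["eq5d"]
    ]
    for score, prefix in (("satisfaction", "sat_"), ("experience", "exp_")):
        cols = [c for c in out.columns if c.startswith(prefix)]
        if cols:
            out[score] = [scale_likert(row) for row in out[cols].to_numpy()]
    return out


# ---------------------------------------------------------------------------
# covariate adjustment and bootstrap


def _design_matrix(patients: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Fixed-effects design: intercept, group, covariates, site dummies."""
    n = len(patients)
    cols: list[np.ndarray] = [np.ones(n)]
    names = ["intercept"]
    cols.append((patients["group"] == "prescriber").to_numpy(float))
    names.append("group")
    for cov in ("age", "general_health"):
        cols.append(patients[cov].to_numpy(float))
        names.append(cov)
    for cat, prefix in (("gender", "gender_"), ("site", "site_")):
        dummies = pd.get_dummies(patients[cat], prefix=prefix, drop_first=True)
        for c in dummies.columns:
            cols.append(dummies[c].to_numpy(float))
            names.append(str(c))
    return np.column_stack(cols), names


def _validate_groups(patients: pd.DataFrame) -> None:
    groups = set(patients["group"].unique())
    if groups != {"prescriber", "non_prescriber"}:
        raise ValueError(
            f"both arms must be present, got groups {sorted(groups)}"
        )
    if patients["site"].nunique() < 2:
        raise ValueError("at least two sites are required")


def adjust_group_means(
    patients: pd.DataFrame,
    outcome: str,
    ci: tuple[float, float] | None = None,
) -> EffectSummary:
    """Covariate-adjusted group means with a per-site random intercept.

    Fits ``outcome ~ group + age + gender + general_health`` with a random
    intercept for site, and reports each arm's adjusted mean at the sample
    covariate distribution (marginal standardization; for this linear model
    the adjusted difference equals the group coefficient).  Per-arm SDs are
    the observed within-arm outcome SDs.  *ci* attaches a bootstrap CI; it
    defaults to the degenerate interval at the difference.
    """
    import statsmodels.formula.api as smf

    _validate_groups(patients)
    if outcome not in patients.columns:
        raise KeyError(f"outcome column {outcome!r} not in patient table")

    df = patients.copy()
    df["_group"] = (df["group"] == "prescriber").astype(float)
    formula = f"{outcome} ~ _group + age + C(gender) + general_health"
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.mixedlm(formula, df, groups=df["site"])
            fit = model.fit(reml=True)
            site_var = float(np.squeeze(fit.cov_re.to_numpy()))
            beta = fit.fe_params.to_numpy()
            # at the zero-site-variance boundary the mixed-model optimizer
            # can return a degenerate solution; OLS is the exact limit there
            if (not fit.converged) or site_var <= 1e-10 or not np.isfinite(beta).all():
                fit = smf.ols(formula, df).fit()
                beta = fit.params.to_numpy()
    except (np.linalg.LinAlgError, ValueError) as e:
        raise ValueError(f"singular or degenerate design for {outcome!r}: {e}") from e

    diff = float(fit.params["_group"])
    # marginal adjusted means: average fixed-effect prediction with everyone
    # assigned to each arm in turn (random effects at their zero mean);
    # linearity makes the two means differ by exactly the group coefficient
    fixed_fitted = model.exog @ beta
    g = df["_group"].to_numpy()
    mean_np = float(np.mean(fixed_fitted - g * diff))
    mean_p = mean_np + diff

    sds = df.groupby("group")[outcome].std(ddof=1)
    lo, hi = (ci if ci is not None else (diff, diff))
    return EffectSummary(
        outcome=outcome,
        mean_prescriber=mean_p,
        sd_prescriber=float(sds["prescriber"]),
        mean_non_prescriber=mean_np,
        sd_non_prescriber=float(sds["non_prescriber"]),
        difference=diff,
        ci_low=float(lo),
        ci_high=float(hi),
    )


@dataclass(frozen=True)
class BootstrapResult:
    """Percentile bootstrap CI for an adjusted group difference."""

    outcome: str
    n_reps: int
    ci_low: float
    ci_high: float
    samples: np.ndarray

    @property
    def width(self) -> float:
        return self.ci_high - self.ci_low

    def covers(self, value: float) -> bool:
        return self.ci_low <= value <= self.ci_high


def bootstrap_mean_difference(
    patients: pd.DataFrame,
    outcome: str,
    n_reps: int = 5_000,
    seed: int = 0,
    adjusted: bool = True,
    level: float = 0.95,
) -> BootstrapResult:
    """Cluster-respecting percentile bootstrap of the group difference.

    Patients are resampled with replacement within each site x group
    stratum, preserving the matched design.  Inside each replicate the
    difference is re-estimated by ordinary least squares with site fixed
    effects and the same covariates as :func:`adjust_group_means` (a fast,
    fixed-effects stand-in for the mixed model; the point estimate itself
    still comes from the mixed model).  Deterministic given *seed*.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    _validate_groups(patients)
    rng = np.random.default_rng(seed)
    df = patients.reset_index(drop=True)
    y = df[outcome].to_numpy(float)

    if adjusted:
        X, _ = _design_matrix(df)
    else:
        X = None
    grp = (df["group"] == "prescriber").to_numpy()

    strata = [idx.to_numpy() for _, idx in df.groupby(["site", "group"]).groups.items()]
    strata = [np.asarray(s, dtype=int) for s in strata]

    diffs = np.empty(n_reps)
    for b in range(n_reps):
        idx = np.concatenate([s[rng.integers(0, len(s), len(s))] for s in strata])
        if X is not None:
            beta, *_ = np.linalg.lstsq(X[idx], y[idx], rcond=None)
            diffs[b] = beta[1]
        else:
            diffs[b] = y[idx][grp[idx]].mean() - y[idx][~grp[idx]].mean()

    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(diffs, [alpha, 1.0 - alpha])
    return BootstrapResult(
        outcome=outcome, n_reps=n_reps, ci_low=float(lo), ci_high=float(hi),
        samples=diffs,
    )
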