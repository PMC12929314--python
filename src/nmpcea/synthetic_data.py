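"""Synthetic patient and prescriber-activity data.

The study design this emulates: eight NHS sites, each contributing a
matched prescriber / non-prescriber pair of professionals and the patients
they manage.  Patient utility is generated from a linear latent model

    u = baseline + group effect + site intercept + covariate terms + noise

and mapped to the *nearest* EQ-5D-5L state under the toy additive value
set (utilities live on a 0.05 grid, so the deduction count is
round((1 - u) / 0.05), split at random across the five dimensions).
Likert satisfaction/experience items are drawn around group-shifted means.
Activity logs (weekly contacts, prescription-management, rights-use and
referral counts) are drawn so their sample means converge to the fixture
point estimates.

Everything is deterministic given the design seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .params_io import Param, ParameterFixture, load_fixture, packaged_fixture_path

__all__ = [
    "SynthDesign",
    "generate_patients",
    "generate_activity_logs",
    "make_paper_fixture",
]


@dataclass(frozen=True)
class SynthDesign:
    """Design of one synthetic patient cohort.

    Defaults mirror the study scale: 8 sites and roughly 180 patients in
    total (the study observed 49 dietitian-managed and 131 TR-managed
    patients), a small negative group effect on utility of the order of
    the published adjusted QALY differences, a site SD of 0.02 and a
    residual SD of 0.15 (typical patient-level spread of utility indices,
    and wide enough that the 0.05 utility grid does not mask small mean
    shifts).
    """

    n_sites: int = 8
    patients_per_site: int = 12  # per group
    baseline_utility: float = 0.78
    group_utility_effect: float = -0.012
    site_random_sd: float = 0.02
    residual_sd: float = 0.15
    # covariate effects on latent utility (age centered at 60 years)
    age_effect: float = -0.001
    gender_effect: float = 0.01
    general_health_effect: float = 0.02
    likert_mean: float = 4.0
    likert_shift: float = 0.05  # prescriber-group drift, Likert points
    likert_sd: float = 0.8
    n_likert_items: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites < 2:
            raise ValueError("n_sites must be >= 2")
        if self.patients_per_site < 1:
            raise ValueError("patients_per_site must be >= 1")
        for name in ("site_random_sd", "residual_sd", "likert_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


def _state_from_deductions(d: int, rng: np.random.Generator) -> str:
    """Random EQ-5D-5L state with level steps summing to d (0..20)."""
    levels = np.ones(5, dtype=int)
    for _ in range(d):
        open_dims = np.flatnonzero(levels < 5)
        levels[open_dims[rng.integers(0, len(open_dims))]] += 1
    return "".join(map(str, levels))


def utility_to_state(u: float, rng: np.random.Generator) -> str:
    """Nearest EQ-5D-5L state under the toy additive value set."""
    d = int(np.clip(np.rint((1.0 - u) / 0.05), 0, 20))
    return _state_from_deductions(d, rng)


def generate_patients(design: SynthDesign) -> pd.DataFrame:
    """One row per patient: site, group, covariates, EQ-5D-5L state, Likert
    items.  Deterministic given ``design.seed``."""
    rng = np.random.default_rng(design.seed)
    site_effects = rng.normal(0.0, design.site_random_sd, design.n_sites)
    rows = []
    for s in range(design.n_sites):
        for group, g_ind in (("prescriber", 1.0), ("non_prescriber", 0.0)):
            n = design.patients_per_site
            age = rng.normal(60.0, 12.0, n).clip(18.0, 95.0)
            gender = rng.choice(["female", "male"], size=n)
            general_health = rng.integers(1, 6, n)  # 1 poor .. 5 excellent
            latent = (
                design.baseline_utility
                + g_ind * design.group_utility_effect
                + site_effects[s]
                + design.age_effect * (age - 60.0)
                + design.gender_effect * (gender == "female")
                + design.general_health_effect * (general_health - 3)
                + rng.normal(0.0, design.residual_sd, n)
            )
            likert_mu = design.likert_mean + g_ind * design.likert_shift
            for i in range(n):
                row = {
                    "site": f"site_{s + 1}",
                    "group": group,
                    "age": float(np.round(age[i], 1)),
                    "gender": gender[i],
                    "general_health": int(general_health[i]),
                    "eq5d": utility_to_state(latent[i], rng),
                }
                for prefix in ("sat", "exp"):
                    items = np.clip(
                        np.rint(rng.normal(likert_mu, design.likert_sd,
                                           design.n_likert_items)),
                        1, 5,
                    ).astype(int)
                    row.update({f"{prefix}_{j + 1}": int(v)
                                for j, v in enumerate(items)})
                rows.append(row)
    return pd.DataFrame(rows)


def generate_activity_logs(
    activity: Mapping[str, Param],
    n_weeks: int = 48,
    seed: int = 0,
) -> pd.DataFrame:
    """Weekly prescriber-activity log for one arm's activity profile.

    Weekly contact counts are Poisson around the fixture point; contacts
    needing prescription management, rights-use among those, and referrals
    are binomial with the fixture probabilities.  A parameter with a
    zero-width range is treated as degenerate and reproduced exactly
    (deterministic expected counts, possibly fractional).
    """
    rng = np.random.default_rng(seed)
    c = activity["contacts_per_week"]
    p_req = activity["p_require_rx"]
    p_use = activity["p_use_rights"]
    p_ref = activity["p_refer"]

    if c.width == 0:
        contacts = np.full(n_weeks, c.point)
    else:
        contacts = rng.poisson(c.point, n_weeks).astype(float)

    def branch(n: np.ndarray, p: Param) -> np.ndarray:
        if p.width == 0:
            return n * p.point
        return rng.binomial(n.astype(int), p.point).astype(float)

    n_require = branch(contacts, p_req)
    n_rights_used = branch(n_require, p_use)
    n_referred = branch(contacts, p_ref)
    return pd.DataFrame(
        {
            "week": np.arange(1, n_weeks + 1),
            "contacts": contacts,
            "n_require_rx": n_require,
            "n_rights_used": n_rights_used,
            "n_referred": n_referred,
        }
    )


def make_paper_fixture(profession: str) -> ParameterFixture:
    """The packaged fixture transcribing the published input tables."""
    return load_fixture(packaged_fixture_path(profession))
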