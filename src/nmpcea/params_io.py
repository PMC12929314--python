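"""Parameter fixtures, model configuration and result serialization.

The model is driven by one structured-text (YAML) fixture per profession,
mirroring the published input tables line by line: training-cost components,
per-arm activity profiles (contact volumes, prescribing/referral
probabilities, unit consultation and referral costs) and adjusted
effectiveness summaries, plus the published headline totals used for
reporting-level checks.  Every scalar parameter carries a point estimate and
a (low, high) range; a bare scalar in the file is read as a fixed,
zero-width parameter.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from datetime import datetime, timezone
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

__all__ = [
    "Param",
    "EffectSummary",
    "ModelConfig",
    "ParameterFixture",
    "FixtureError",
    "load_fixture",
    "write_results",
    "load_results",
    "round_pounds",
    "PROFESSIONS",
    "ARMS",
    "PROBABILITY_PARAMS",
]

PROFESSIONS = ("dietitian", "therapeutic_radiographer")
ARMS = ("prescriber", "non_prescriber")

#: activity-profile fields constrained to [0, 1]
PROBABILITY_PARAMS = frozenset(
    {"p_require_rx", "p_use_rights", "p_refer", "work_time_fraction"}
)


class FixtureError(ValueError):
    """Raised when a fixture file violates the documented schema."""


def round_pounds(x: float) -> int:
    """Round to the nearest pound, halves away from zero.

    Applied only at reporting; all internal arithmetic is unrounded.
    """
    import math

    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass(frozen=True)
class Param:
    """A scalar model parameter: point estimate, range, distribution tag."""

    point: float
    low: float
    high: float
    dist: str = "fixed"  # fixed | gamma | beta | normal

    def __post_init__(self) -> None:
        if not (self.low <= self.point <= self.high):
            raise FixtureError(
                f"parameter range must satisfy low <= point <= high, "
                f"got ({self.low}, {self.point}, {self.high})"
            )
        if self.dist not in ("fixed", "gamma", "beta", "normal"):
            raise FixtureError(f"unknown distribution tag {self.dist!r}")

    @property
    def width(self) -> float:
        return self.high - self.low

    @classmethod
    def parse(cls, name: str, raw: Any) -> "Param":
        """Build from a fixture entry: scalar or {point, low, high, dist}."""
        if isinstance(raw, (int, float)):
            p = cls(float(raw), float(raw), float(raw), "fixed")
        elif isinstance(raw, Mapping):
            try:
                point = float(raw["point"])
            except KeyError as e:
                raise FixtureError(f"{name}: missing 'point'") from e
            low = float(raw.get("low", point))
            high = float(raw.get("high", point))
            try:
                p = cls(point, low, high, str(raw.get("dist", "fixed")))
            except FixtureError as e:
                raise FixtureError(f"{name}: {e}") from e
        else:
            raise FixtureError(f"{name}: expected scalar or mapping, got {raw!r}")
        if name.split(".")[-1] in PROBABILITY_PARAMS or p.dist == "beta":
            if not (0.0 <= p.low and p.high <= 1.0):
                raise FixtureError(
                    f"{name}: probability outside [0, 1] (low={p.low}, high={p.high})"
                )
        return p


@dataclass(frozen=True)
class EffectSummary:
    """Adjusted group means for one effectiveness outcome.

    Means are covariate-adjusted (mixed model with site random intercept);
    the 95% CI of the difference comes from a nonparametric bootstrap.
    """

    outcome: str
    mean_prescriber: float
    sd_prescriber: float
    mean_non_prescriber: float
    sd_non_prescriber: float
    difference: float
    ci_low: float
    ci_high: float

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.difference <= self.ci_high):
            raise FixtureError(
                f"{self.outcome}: difference {self.difference} outside CI "
                f"({self.ci_low}, {self.ci_high})"
            )


@dataclass(frozen=True)
class ModelConfig:
    """Global analysis settings (base case mirrors the published analysis)."""

    profession: str = "dietitian"
    horizon_years: int = 1
    discount_rate: float = 0.035
    wtp_threshold: float = 30_000.0
    oop_scenario: str = "include_oop"
    psa_iterations: int = 5_000
    bootstrap_reps: int = 5_000
    rng_seed: int = 0
    weeks_per_year: int = 48

    def __post_init__(self) -> None:
        if self.profession not in PROFESSIONS:
            raise ValueError(f"profession must be one of {PROFESSIONS}")
        if self.horizon_years < 1:
            raise ValueError("horizon_years must be >= 1")
        if not (0.0 <= self.discount_rate < 1.0):
            raise ValueError("discount_rate must be in [0, 1)")
        if self.oop_scenario not in ("include_oop", "exclude_oop"):
            raise ValueError("oop_scenario must be include_oop or exclude_oop")
        if self.psa_iterations < 1:
            raise ValueError("psa_iterations must be >= 1")
        if self.bootstrap_reps < 1:
            raise ValueError("bootstrap_reps must be >= 1")
        if not (1 <= self.weeks_per_year <= 52):
            raise ValueError("weeks_per_year must be in [1, 52]")


@dataclass(frozen=True)
class ParameterFixture:
    """All model inputs for one profession."""

    profession: str
    training: dict[str, Param]
    activity: dict[str, dict[str, Param]]
    time_shares: dict[str, dict[str, Param]]
    effects: dict[str, EffectSummary]
    reported: dict[str, Any] = field(default_factory=dict)

    def activity_points(self, arm: str) -> dict[str, float]:
        """Point estimates of the activity profile for one arm."""
        return {k: p.point for k, p in self.activity[arm].items()}


_TRAINING_FIELDS = (
    "course_fee",
    "annual_salary",
    "employer_paid_days",
    "taught_days",
    "supervised_days",
    "work_time_fraction",
    "personal_study_days",
    "oop_travel",
    "oop_materials",
    "oop_other",
)
_ACTIVITY_FIELDS = (
    "contacts_per_week",
    "p_require_rx",
    "p_use_rights",
    "p_refer",
    "c_consult_std",
    "c_consult_rx",
    "c_referral",
)


def _parse_section(raw: Mapping, fields: tuple, prefix: str) -> dict[str, Param]:
    out = {}
    for f in fields:
        if f not in raw:
            raise FixtureError(f"{prefix}: missing field {f!r}")
        out[f] = Param.parse(f"{prefix}.{f}", raw[f])
    return out


def load_fixture(path: str | Path) -> ParameterFixture:
    """Load and validate a per-profession parameter fixture.

    Raises :class:`FixtureError` naming the offending field on any schema
    or invariant violation (missing field, low > high, probability outside
    [0, 1], difference outside its CI).
    """
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, Mapping):
        raise FixtureError(f"{path}: fixture root must be a mapping")

    profession = raw.get("profession")
    if profession not in PROFESSIONS:
        raise FixtureError(f"profession: must be one of {PROFESSIONS}, got {profession!r}")

    training = _parse_section(raw.get("training", {}), _TRAINING_FIELDS, "training")

    activity: dict[str, dict[str, Param]] = {}
    time_shares: dict[str, dict[str, Param]] = {}
    for arm in ARMS:
        if arm not in raw.get("activity", {}):
            raise FixtureError(f"activity: missing arm {arm!r}")
        arm_raw = raw["activity"][arm]
        activity[arm] = _parse_section(arm_raw, _ACTIVITY_FIELDS, f"activity.{arm}")
        time_shares[arm] = {
            k: Param.parse(f"activity.{arm}.time_shares.{k}", v)
            for k, v in arm_raw.get("time_shares", {}).items()
        }
        prof = activity[arm]
        if arm == "non_prescriber" and prof["p_use_rights"].point != 0.0:
            raise FixtureError("activity.non_prescriber.p_use_rights must be 0")
        if prof["c_consult_rx"].point < prof["c_consult_std"].point:
            raise FixtureError(
                f"activity.{arm}: c_consult_rx must be >= c_consult_std"
            )
        for share in time_shares[arm].values():
            if not (0.0 <= share.low and share.high <= 1.0):
                raise FixtureError(f"activity.{arm}.time_shares outside [0, 1]")

    effects = {}
    for name, eff in raw.get("effects", {}).items():
        try:
            effects[name] = EffectSummary(
                outcome=name,
                mean_prescriber=float(eff["prescriber"]["mean"]),
                sd_prescriber=float(eff["prescriber"]["sd"]),
                mean_non_prescriber=float(eff["non_prescriber"]["mean"]),
                sd_non_prescriber=float(eff["non_prescriber"]["sd"]),
                difference=float(eff["difference"]),
                ci_low=float(eff["ci95"][0]),
                ci_high=float(eff["ci95"][1]),
            )
        except (KeyError, TypeError) as e:
            raise FixtureError(f"effects.{name}: malformed entry ({e})") from e

    return ParameterFixture(
        profession=profession,
        training=training,
        activity=activity,
        time_shares=time_shares,
        effects=effects,
        reported=dict(raw.get("reported", {})),
    )


def packaged_fixture_path(profession: str) -> Path:
    """Path of the fixture shipped with the package for *profession*."""
    if profession not in PROFESSIONS:
        raise ValueError(f"profession must be one of {PROFESSIONS}")
    return Path(__file__).parent / "fixtures" / f"{profession}.yaml"


# ---------------------------------------------------------------------------
# result serialization


def write_results(
    tables: Mapping[str, pd.DataFrame],
    out_dir: str | Path,
    config: ModelConfig | None = None,
    seed: int | None = None,
) -> dict:
    """Write result tables as delimited text plus a run manifest.

    One CSV per table; numeric columns are written at full ``repr``
    precision so that :func:`load_results` round-trips bit-exactly.
    Returns the manifest (also written as ``manifest.json``).
    """
    if not tables:
        raise ValueError("no result tables to write")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files = {}
    for name, df in tables.items():
        if not isinstance(df, pd.DataFrame):
            raise TypeError(f"table {name!r} is not a DataFrame")
        if df.empty:
            raise ValueError(f"table {name!r} is empty")
        fp = out_dir / f"{name}.csv"
        df.to_csv(fp, index=False, float_format=lambda v: repr(float(v)))
        files[name] = {
            "path": fp.name,
            "sha256": hashlib.sha256(fp.read_bytes()).hexdigest(),
            "rows": int(len(df)),
        }
    manifest = {
        "config": asdict(config) if config is not None else None,
        "seed": seed,
        "written_utc": datetime.now(timezone.utc).isoformat(),
        "files": files,
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def load_results(out_dir: str | Path) -> dict[str, pd.DataFrame]:
    """Reload tables written by :func:`write_results`."""
    out_dir = Path(out_dir)
    with open(out_dir / "manifest.json") as fh:
        manifest = json.load(fh)
    return {
        name: pd.read_csv(out_dir / info["path"], float_precision="round_trip")
        for name, info in manifest["files"].items()
    }
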