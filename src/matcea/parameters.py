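"""Model parameters: distribution specs, validation, sampling, serialization.

Every model input is a named :class:`DistributionSpec`.  Probabilities and
relative risks are beta distributions specified by mean and standard
deviation, ranges are uniforms specified by minimum and maximum, and
quantities reported as "average (minimum and maximum)" are triangulars whose
mode is derived from the mean.  Scenario-specific variants of a parameter
(for example antenatal-care access under the insurance program versus the
standard of care) are stored under scoped keys ``"name@scope"`` and resolved
through a :class:`ScenarioConfig`.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "DistributionSpec",
    "ParameterSet",
    "ParameterDraw",
    "ScenarioConfig",
    "ModelConfig",
    "ParameterError",
    "InfeasibleMomentsError",
    "beta_from_moments",
    "triangular_from_mean",
    "load_parameters",
    "load_config",
    "default_config",
    "sample_draw",
    "params_to_csv",
    "params_from_csv",
]


class ParameterError(ValueError):
    """A parameter definition violates its invariants or is missing."""


class InfeasibleMomentsError(ParameterError):
    """Requested moments cannot be realised by the distribution family."""


def beta_from_moments(mean: float, sd: float) -> tuple[float, float]:
    """Beta shape parameters (alpha, beta) reproducing ``mean`` and ``sd``.

    Method of moments: with k = mean(1-mean)/sd^2 - 1,
    alpha = mean*k and beta = (1-mean)*k.  Requires 0 < mean < 1 and
    0 < sd^2 < mean(1-mean).
    """
    if not 0.0 < mean < 1.0:
        raise InfeasibleMomentsError(f"beta mean must lie in (0,1), got {mean}")
    if sd <= 0:
        raise InfeasibleMomentsError(f"beta sd must be positive, got {sd}")
    var = sd * sd
    if var >= mean * (1.0 - mean):
        raise InfeasibleMomentsError(
            f"beta moments infeasible: sd^2={var:.6g} >= mean(1-mean)={mean * (1 - mean):.6g}"
        )
    k = mean * (1.0 - mean) / var - 1.0
    return mean * k, (1.0 - mean) * k


def triangular_from_mean(mean: float, minimum: float, maximum: float) -> float:
    """Mode of the triangular(min, mode, max) whose expectation is ``mean``.

    The mean of a triangular distribution is (min + mode + max)/3, so
    mode = 3*mean - min - max.  Raises if that mode falls outside
    [min, max].
    """
    mode = 3.0 * mean - minimum - maximum
    tol = 1e-12 * max(1.0, abs(maximum - minimum))
    if not (minimum - tol <= mode <= maximum + tol):
        raise InfeasibleMomentsError(
            f"triangular mean {mean} with support [{minimum}, {maximum}] "
            f"implies mode {mode:.6g} outside the support"
        )
    return float(min(max(mode, minimum), maximum))


@dataclass(frozen=True)
class DistributionSpec:
    """One model input with its sampling distribution.

    ``family`` is one of ``point``, ``uniform``, ``beta``, ``triangular``.
    ``mode`` may be given explicitly for a triangular whose printed mean is
    rounded too coarsely for the mean-parameterization to be feasible; when
    absent it is derived as 3*mean - min - max.  For ``point`` entries,
    ``min``/``max`` optionally declare the bounds used by one-way
    sensitivity analysis.
    """

    family: str
    mean: float | None = None
    sd: float | None = None
    min: float | None = None
    max: float | None = None
    mode: float | None = None

    _FAMILIES = ("point", "uniform", "beta", "triangular")

    def __post_init__(self) -> None:
        if self.family not in self._FAMILIES:
            raise ParameterError(f"unknown distribution family {self.family!r}")
        if self.family == "point":
            if self.mean is None:
                raise ParameterError("point distribution requires a mean")
        elif self.family == "uniform":
            if self.min is None or self.max is None:
                raise ParameterError("uniform distribution requires min and max")
            if not self.min < self.max:
                raise ParameterError(
                    f"uniform requires min < max, got [{self.min}, {self.max}]"
                )
        elif self.family == "beta":
            if self.mean is None or self.sd is None:
                raise ParameterError("beta distribution requires mean and sd")
            beta_from_moments(self.mean, self.sd)  # validates feasibility
        elif self.family == "triangular":
            if self.min is None or self.max is None:
                raise ParameterError("triangular distribution requires min and max")
            if self.mode is None:
                if self.mean is None:
                    raise ParameterError("triangular requires a mean or an explicit mode")
                triangular_from_mean(self.mean, self.min, self.max)  # validates
            elif not self.min <= self.mode <= self.max:
                raise ParameterError(
                    f"triangular mode {self.mode} outside [{self.min}, {self.max}]"
                )

    # -- moments -------------------------------------------------------

    @property
    def tri_mode(self) -> float:
        if self.mode is not None:
            return self.mode
        return triangular_from_mean(self.mean, self.min, self.max)

    def point_estimate(self) -> float:
        """The distribution mean, used for all deterministic analyses."""
        if self.family == "point":
            return float(self.mean)
        if self.family == "uniform":
            return 0.5 * (self.min + self.max)
        if self.family == "beta":
            return float(self.mean)
        return (self.min + self.tri_mode + self.max) / 3.0

    def analytic_sd(self) -> float:
        if self.family == "point":
            return 0.0
        if self.family == "uniform":
            return (self.max - self.min) / np.sqrt(12.0)
        if self.family == "beta":
            return float(self.sd)
        a, c, b = self.min, self.tri_mode, self.max
        return np.sqrt((a * a + b * b + c * c - a * b - a * c - b * c) / 18.0)

    # -- sampling ------------------------------------------------------

    def sample(self, rng: np.random.Generator, size=None):
        if self.family == "point":
            return np.full(size, self.mean) if size is not None else float(self.mean)
        if self.family == "uniform":
            return rng.uniform(self.min, self.max, size)
        if self.family == "beta":
            a, b = beta_from_moments(self.mean, self.sd)
            return rng.beta(a, b, size)
        return rng.triangular(self.min, self.tri_mode, self.max, size)

    def one_way_bounds(self) -> tuple[float, float]:
        """Low/high values for one-way sensitivity analysis.

        Uniform and triangular entries use their support; beta entries use
        mean +/- 1.96 sd truncated to [0, 1]; point entries use declared
        min/max when present and are otherwise fixed (zero-width).
        """
        if self.family in ("uniform", "triangular"):
            return float(self.min), float(self.max)
        if self.family == "beta":
            lo = max(0.0, self.mean - 1.96 * self.sd)
            hi = min(1.0, self.mean + 1.96 * self.sd)
            return lo, hi
        if self.min is not None and self.max is not None:
            return float(self.min), float(self.max)
        return float(self.mean), float(self.mean)


# Canonical parameter vocabulary.  Scenario-scoped variants use "name@scope".
PROBABILITY_NAMES = frozenset({
    "anc_access", "facility_delivery_all", "eoc_if_facility",
    "facility_if_anc", "home_if_anc", "eoc_if_home",
    "p_pph", "p_anaemia_pph", "p_death_pph", "rr_pph_death_eoc",
    "rr_anaemia_eoc", "p_sepsis", "p_infertility_sepsis", "p_death_sepsis",
    "rr_sepsis_hospital", "p_ol", "p_fistula_ol", "p_death_ol",
    "p_htd", "p_death_htd", "rr_htd_anc",
})
COST_NAMES = frozenset({
    "cost_anc", "cost_delivery_uncomplicated", "cost_delivery_complicated",
    "cost_fistula_treatment", "cost_anaemia_treatment", "above_service_cost",
})
DALY_NAMES = frozenset({
    "daly_death", "daly_anaemia", "daly_infertility", "daly_fistula",
    "daly_extended_htd",
})
OTHER_NAMES = frozenset({"discount_rate", "baseline_healthy_life"})
KNOWN_NAMES = PROBABILITY_NAMES | COST_NAMES | DALY_NAMES | OTHER_NAMES

# Names that must be resolvable (directly or through a scenario scope).
MANDATORY_NAMES = KNOWN_NAMES - {"facility_delivery_all"}


def _split_key(key: str) -> tuple[str, str | None]:
    if "@" in key:
        name, scope = key.split("@", 1)
        return name, scope
    return key, None


class ParameterDraw(dict):
    """One concrete value per parameter key.

    Keys mirror the :class:`ParameterSet`; :meth:`resolve` walks a scope
    chain (most specific scenario first) down to the shared entry.
    """

    def resolve(self, name: str, scopes: tuple[str, ...] = ()) -> float:
        for scope in scopes:
            key = f"{name}@{scope}"
            if key in self:
                return self[key]
        if name in self:
            return self[name]
        raise ParameterError(f"parameter {name!r} not present for scopes {scopes}")


@dataclass
class ParameterSet:
    """All model inputs, keyed by name (optionally scenario-scoped)."""

    entries: dict[str, DistributionSpec]
    cohort_size: int = 10_000

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        resolvable: set[str] = set()
        for key, spec in self.entries.items():
            name, _scope = _split_key(key)
            if name not in KNOWN_NAMES:
                raise ParameterError(f"unknown parameter name {key!r}")
            resolvable.add(name)
            lo, hi = _support(spec)
            if name in PROBABILITY_NAMES and not (-1e-12 <= lo and hi <= 1 + 1e-12):
                raise ParameterError(
                    f"{key}: probability support [{lo}, {hi}] escapes [0, 1]"
                )
            if name in (COST_NAMES | DALY_NAMES) and lo < 0:
                raise ParameterError(f"{key}: negative support for a cost/DALY value")
        missing = sorted(MANDATORY_NAMES - resolvable)
        if missing:
            raise ParameterError(f"missing mandatory parameters: {', '.join(missing)}")
        if self.cohort_size <= 0:
            raise ParameterError("cohort size must be positive")

    def point_draw(self) -> ParameterDraw:
        """All parameters at their distribution means (seed-independent)."""
        return ParameterDraw({k: s.point_estimate() for k, s in self.entries.items()})

    def sample(self, rng: np.random.Generator | int) -> ParameterDraw:
        """One random draw; keys are visited in sorted order so the stream
        is reproducible across runs for a fixed seed."""
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        return ParameterDraw(
            {k: float(self.entries[k].sample(rng)) for k in sorted(self.entries)}
        )

    def merged(self, extra: dict[str, DistributionSpec]) -> "ParameterSet":
        ent = dict(self.entries)
        ent.update(extra)
        return ParameterSet(ent, cohort_size=self.cohort_size)


def _support(spec: DistributionSpec) -> tuple[float, float]:
    if spec.family == "point":
        return spec.mean, spec.mean
    if spec.family == "beta":
        return 0.0, 1.0
    return spec.min, spec.max


def sample_draw(params: ParameterSet, rng_seed) -> ParameterDraw:
    """Sample one value per parameter; identical seeds give identical draws."""
    return params.sample(rng_seed)


@dataclass
class ScenarioConfig:
    """A named care scenario: parameter scopes plus structural switches.

    ``noanc_facility_share`` and ``anc_facility_share`` set the share of
    deliveries occurring in a health facility per antenatal-care stratum;
    a ``None`` ANC share means "renormalize the facility/home-given-ANC
    pair to sum to one".  ``htd_prophylaxis_coverage`` is the fraction of
    ANC attendees receiving preventive treatment of hypertensive
    disorders.  ``sepsis_calibration`` scales the sepsis rate parameter
    into the base (non-hospital) sepsis rate; see the pathway module.
    """

    name: str
    noanc_facility_share: float
    anc_facility_share: float | None = None
    htd_prophylaxis_coverage: float = 0.0
    above_service: bool = False
    comparator: bool = False
    sepsis_calibration: float = 1.0
    fallback_scope: str | None = None
    overrides: dict[str, DistributionSpec] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for prob in (self.noanc_facility_share, self.htd_prophylaxis_coverage):
            if not 0.0 <= prob <= 1.0:
                raise ParameterError(f"{self.name}: structural share {prob} outside [0,1]")
        if self.anc_facility_share is not None and not 0.0 <= self.anc_facility_share <= 1.0:
            raise ParameterError(f"{self.name}: ANC facility share outside [0,1]")
        for key in self.overrides:
            name, _ = _split_key(key)
            if name not in KNOWN_NAMES:
                raise ParameterError(f"{self.name}: override of unknown parameter {key!r}")

    @property
    def scopes(self) -> tuple[str, ...]:
        if self.fallback_scope:
            return (self.name, self.fallback_scope)
        return (self.name,)

    def override_entries(self) -> dict[str, DistributionSpec]:
        """Overrides re-keyed into this scenario's scope."""
        out = {}
        for key, spec in self.overrides.items():
            name, scope = _split_key(key)
            out[f"{name}@{scope or self.name}"] = spec
        return out

    def value(self, draw: ParameterDraw, name: str) -> float:
        return draw.resolve(name, self.scopes)

    def with_overrides(self, **kwargs) -> "ScenarioConfig":
        return replace(self, **kwargs)


@dataclass
class ModelConfig:
    """A full analysis configuration: parameters plus named scenarios."""

    params: ParameterSet
    scenarios: dict[str, ScenarioConfig]

    def __post_init__(self) -> None:
        comparators = [s for s in self.scenarios.values() if s.comparator]
        if len(comparators) != 1:
            raise ParameterError(
                f"exactly one scenario must be flagged comparator, found {len(comparators)}"
            )

    @property
    def comparator(self) -> ScenarioConfig:
        return next(s for s in self.scenarios.values() if s.comparator)

    def merged_params(self, *scenario_names: str) -> ParameterSet:
        """Parameter set extended with the scenarios' override entries, so a
        single draw covers every arm (common random numbers)."""
        extra: dict[str, DistributionSpec] = {}
        for sname in scenario_names:
            extra.update(self.scenarios[sname].override_entries())
        return self.params.merged(extra) if extra else self.params


# -- config file handling ----------------------------------------------


def _spec_from_mapping(m: dict) -> DistributionSpec:
    return DistributionSpec(
        family=m["family"],
        mean=m.get("mean"),
        sd=m.get("sd"),
        min=m.get("min"),
        max=m.get("max"),
        mode=m.get("mode"),
    )


def load_config(source) -> ModelConfig:
    """Parse a YAML model configuration from a path, file object or text."""
    if hasattr(source, "read"):
        raw = yaml.safe_load(source)
    else:
        text = str(source)
        if "\n" not in text and text.endswith((".yaml", ".yml")):
            with open(text) as fh:
                raw = yaml.safe_load(fh)
        else:
            raw = yaml.safe_load(io.StringIO(text))
    if not isinstance(raw, dict) or "parameters" not in raw:
        raise ParameterError("configuration must be a mapping with a 'parameters' section")

    entries = {}
    for key, m in raw["parameters"].items():
        try:
            entries[key] = _spec_from_mapping(m)
        except ParameterError as err:
            raise ParameterError(f"parameter {key!r}: {err}") from err
    params = ParameterSet(entries, cohort_size=int(raw.get("cohort_size", 10_000)))

    scenarios = {}
    for sname, sm in (raw.get("scenarios") or {}).items():
        overrides = {
            k: _spec_from_mapping(v) for k, v in (sm.get("overrides") or {}).items()
        }
        scenarios[sname] = ScenarioConfig(
            name=sname,
            noanc_facility_share=float(sm["noanc_facility_share"]),
            anc_facility_share=(
                None if sm.get("anc_facility_share") is None
                else float(sm["anc_facility_share"])
            ),
            htd_prophylaxis_coverage=float(sm.get("htd_prophylaxis_coverage", 0.0)),
            above_service=bool(sm.get("above_service", False)),
            comparator=bool(sm.get("comparator", False)),
            sepsis_calibration=float(sm.get("sepsis_calibration", 1.0)),
            fallback_scope=sm.get("fallback_scope"),
            overrides=overrides,
        )
    return ModelConfig(params=params, scenarios=scenarios)


def load_parameters(config_text) -> ParameterSet:
    """Parse and validate the parameter section of a configuration."""
    return load_config(config_text).params


def default_config() -> ModelConfig:
    """The shipped configuration encoding the published input table."""
    from importlib.resources import files

    path = files("matcea.data").joinpath("params_table1.yaml")
    return load_config(io.StringIO(path.read_text()))


# -- flat CSV round trip -----------------------------------------------

_CSV_COLUMNS = ["name", "family", "mean", "sd", "min", "max", "mode", "scenario"]


def params_to_csv(params: ParameterSet) -> pd.DataFrame:
    rows = []
    for key in sorted(params.entries):
        spec = params.entries[key]
        name, scope = _split_key(key)
        rows.append({
            "name": name, "family": spec.family, "mean": spec.mean,
            "sd": spec.sd, "min": spec.min, "max": spec.max,
            "mode": spec.mode, "scenario": scope or "shared",
        })
    return pd.DataFrame(rows, columns=_CSV_COLUMNS)


def params_from_csv(frame: pd.DataFrame, cohort_size: int = 10_000) -> ParameterSet:
    entries = {}
    for _, row in frame.iterrows():
        key = row["name"]
        if row.get("scenario") not in (None, "", "shared") and pd.notna(row["scenario"]):
            key = f"{row['name']}@{row['scenario']}"
        entries[key] = DistributionSpec(
            family=row["family"],
            **{
                f: (None if pd.isna(row[f]) else float(row[f]))
                for f in ("mean", "sd", "min", "max", "mode")
            },
        )
    return ParameterSet(entries, cohort_size=cohort_size)
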