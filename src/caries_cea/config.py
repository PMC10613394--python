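"""Model configuration: global constants and per-strategy parameters.

The parameter set mirrors the published input table for the school-based
caries-prevention analysis: per-learner annual programme costs (gamma
distributed in the PSA), percentage DMFT reductions (beta distributed),
structural transition probabilities, the 5% annual discount rate and the
willingness-to-pay threshold of ZAR38,500 per DMFT averted.

Configuration files are flat YAML (JSON is accepted — it is a YAML
subset): a ``model`` mapping of scalars plus an ``interventions`` list
with one block per strategy. A bundled ``default_parameters.yaml`` ships
with the package and reproduces every default value.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional

import yaml

from .errors import ConfigParseError, ConfigValidationError

#: fraction of the mean used for a missing cost SD ("10% of the mean" rule)
SD_FALLBACK_FRACTION = 0.10

_SUGAR_MECHANISMS = ("offset", "effect")
_EFFECT_MECHANISMS = ("flow", "accrual")


@dataclass
class ModelConfig:
    """Global model constants.

    Costs are plain ZAR at constant (2022) prices; no inflation machinery.
    ``n_cycles`` is derived: one annual cycle per year of schooling between
    ``start_age`` and ``exit_age``.
    """

    cohort_size: float = 10_000
    start_age: int = 5
    exit_age: int = 15
    discount_rate: float = 0.05
    prob_untreated: float = 0.7
    prob_recurrence: float = 0.188
    dmft_growth: float = 0.0059          # annual proportional DMFT increase
    sugar_slope: float = 0.0128          # DMFT per g/day of added sugar
    sugar_reduction: float = 30.0        # modelled added-sugar cut, g/day
    screening_cost: float = 525.61       # ZAR per learner per year
    wtp: float = 38_500.0                # ZAR per DMFT averted
    sugar_mechanism: str = "offset"      # "offset" (linear slope) or "effect"
    effect_mechanism: str = "flow"       # "flow" (onset reduction) or "accrual"
    exit_first: bool = True              # apply prob_exit before morbidity flows

    @property
    def n_cycles(self) -> int:
        return self.exit_age - self.start_age

    def validate(self) -> None:
        """Check every invariant; raise with the full list of violations."""
        v = []
        if self.cohort_size <= 0:
            v.append(f"cohort_size must be > 0, got {self.cohort_size}")
        if self.exit_age <= self.start_age:
            v.append(
                f"exit_age ({self.exit_age}) must exceed start_age "
                f"({self.start_age})"
            )
        if not 0 <= self.discount_rate < 1:
            v.append(f"discount_rate must be in [0, 1), got {self.discount_rate}")
        for name in ("prob_untreated", "prob_recurrence"):
            p = getattr(self, name)
            if not 0 <= p <= 1:
                v.append(f"{name} must be in [0, 1], got {p}")
        if self.dmft_growth < 0:
            v.append(f"dmft_growth must be >= 0, got {self.dmft_growth}")
        if self.sugar_slope < 0:
            v.append(f"sugar_slope must be >= 0, got {self.sugar_slope}")
        if self.sugar_reduction < 0:
            v.append(f"sugar_reduction must be >= 0, got {self.sugar_reduction}")
        if self.screening_cost < 0:
            v.append(f"screening_cost must be >= 0, got {self.screening_cost}")
        if self.wtp < 0:
            v.append(f"wtp must be >= 0, got {self.wtp}")
        if self.sugar_mechanism not in _SUGAR_MECHANISMS:
            v.append(
                f"sugar_mechanism must be one of {_SUGAR_MECHANISMS}, "
                f"got {self.sugar_mechanism!r}"
            )
        if self.effect_mechanism not in _EFFECT_MECHANISMS:
            v.append(
                f"effect_mechanism must be one of {_EFFECT_MECHANISMS}, "
                f"got {self.effect_mechanism!r}"
            )
        if v:
            raise ConfigValidationError(v)


@dataclass
class InterventionSpec:
    """One prevention strategy's cost and effectiveness parameters.

    ``effect_mean``/``effect_sd`` are on the percent scale as published;
    they are converted to proportions only inside computations.
    A missing ``annual_cost_sd`` is filled with 10% of the mean at load
    time; an explicitly given SD is never overwritten.
    """

    name: str
    annual_cost_mean: float
    effect_mean: float
    effect_sd: float
    annual_cost_sd: Optional[float] = None
    requires_screening: bool = True
    cost_distribution: str = "gamma"
    effect_distribution: str = "beta"
    is_sugar_policy: bool = False

    def resolve_sd(self) -> "InterventionSpec":
        """Return a copy with the 10%-of-mean rule applied if SD is absent."""
        if self.annual_cost_sd is not None:
            return self
        return dataclasses.replace(
            self, annual_cost_sd=SD_FALLBACK_FRACTION * self.annual_cost_mean
        )

    def validate(self) -> list[str]:
        v = []
        if not self.name:
            v.append("intervention name must be non-empty")
        ctx = f"intervention {self.name!r}: "
        if self.annual_cost_mean < 0:
            v.append(ctx + f"annual_cost_mean must be >= 0, got {self.annual_cost_mean}")
        if self.annual_cost_sd is not None and self.annual_cost_sd < 0:
            v.append(ctx + f"annual_cost_sd must be >= 0, got {self.annual_cost_sd}")
        if not 0 <= self.effect_mean <= 100:
            v.append(ctx + f"effect_mean must be in [0, 100] percent, got {self.effect_mean}")
        if self.effect_sd < 0:
            v.append(ctx + f"effect_sd must be >= 0, got {self.effect_sd}")
        if self.cost_distribution != "gamma":
            v.append(ctx + f"unsupported cost_distribution {self.cost_distribution!r}")
        if self.effect_distribution != "beta":
            v.append(ctx + f"unsupported effect_distribution {self.effect_distribution!r}")
        return v


def default_config() -> tuple[ModelConfig, list[InterventionSpec]]:
    """The bundled default parameter set (published input table values)."""
    path = resources.files("caries_cea").joinpath("data/default_parameters.yaml")
    with resources.as_file(path) as p:
        return load_config(p)


_MODEL_KEYS = {f.name for f in dataclasses.fields(ModelConfig)}
_SPEC_KEYS = {f.name for f in dataclasses.fields(InterventionSpec)}


def _build(section: str, cls, mapping: dict, allowed: set):
    if not isinstance(mapping, dict):
        raise ConfigParseError(f"section {section!r} must be a mapping")
    unknown = set(mapping) - allowed
    if unknown:
        raise ConfigParseError(
            f"unknown key(s) in {section!r}: {', '.join(sorted(unknown))}"
        )
    try:
        return cls(**mapping)
    except TypeError as exc:
        raise ConfigParseError(f"bad {section!r} block: {exc}") from exc


def load_config(path) -> tuple[ModelConfig, list[InterventionSpec]]:
    """Read and validate a YAML/JSON configuration file.

    Returns a fully validated ``(ModelConfig, [InterventionSpec, ...])``
    pair with missing cost SDs filled by the 10%-of-mean rule. Raises
    :class:`ConfigParseError` on malformed input (naming the offending
    key) and :class:`ConfigValidationError` listing *all* invariant
    violations otherwise.
    """
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigParseError(f"cannot parse {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigParseError(f"{path}: top level must be a mapping")
    unknown = set(raw) - {"model", "interventions"}
    if unknown:
        raise ConfigParseError(
            f"{path}: unknown top-level key(s): {', '.join(sorted(unknown))}"
        )

    config = _build("model", ModelConfig, raw.get("model", {}), _MODEL_KEYS)

    blocks = raw.get("interventions", [])
    if blocks is None:
        blocks = []
    if not isinstance(blocks, list):
        raise ConfigParseError(f"{path}: 'interventions' must be a list")
    specs = [
        _build(f"interventions[{i}]", InterventionSpec, b, _SPEC_KEYS)
        for i, b in enumerate(blocks)
    ]
    specs = [s.resolve_sd() for s in specs]

    violations = []
    try:
        config.validate()
    except ConfigValidationError as exc:
        violations.extend(exc.violations)
    for s in specs:
        violations.extend(s.validate())
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        violations.append(f"duplicate intervention names: {names}")
    n_sugar = sum(s.is_sugar_policy for s in specs)
    if n_sugar > 1:
        violations.append(
            f"at most one intervention may set is_sugar_policy, found {n_sugar}"
        )
    if violations:
        raise ConfigValidationError(violations)

    if not specs:
        warnings.warn(f"{path}: no interventions defined", stacklevel=2)
    return config, specs


def write_config(config: ModelConfig, specs, path) -> Path:
    """Write a configuration that round-trips exactly through load_config."""
    config.validate()
    violations = []
    for s in specs:
        violations.extend(s.validate())
    if violations:
        raise ConfigValidationError(violations)
    doc = {
        "model": dataclasses.asdict(config),
        "interventions": [dataclasses.asdict(s) for s in specs],
    }
    path = Path(path)
    path.write_text(yaml.safe_dump(doc, sort_keys=False))
    return path


def config_hash(config: ModelConfig, specs) -> str:
    """Stable sha256 of the full parameter set, for run manifests."""
    doc = {
        "model": dataclasses.asdict(config),
        "interventions": [dataclasses.asdict(s) for s in specs],
    }
    return hashlib.sha256(
        json.dumps(doc, sort_keys=True).encode()
    ).hexdigest()
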