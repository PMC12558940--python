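"""Model-input data model: settings, the named-parameter table, arm
specifications and the packaged default input set.

Every scalar the engines consume (costs, utilities, incidences, proportions,
survival-curve parameters, the discount rate) lives in a flat table of
:class:`ParameterEntry` objects and is read through
:func:`resolve_parameter`, so one-way and probabilistic sensitivity analyses
can substitute any value uniformly by name.  Arm blocks hold structure only
(which parameters play which role in which arm).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import yaml

from .survival import FAMILIES, SurvivalDistribution

__all__ = [
    "DAYS_PER_MONTH",
    "ModelSettings",
    "Conventions",
    "ParameterEntry",
    "ArmSpec",
    "ModelInputs",
    "load_inputs",
    "default_inputs",
    "resolve_parameter",
    "save_inputs",
]

#: months are defined as 365.25/12 days everywhere time units are converted
DAYS_PER_MONTH = 30.4375


class ConfigError(ValueError):
    """Raised when a config file fails schema or invariant validation."""


def _require_keys(block: Mapping, allowed: set[str], required: set[str], where: str):
    unknown = set(block) - allowed
    if unknown:
        raise ConfigError(f"{where}: unknown keys {sorted(unknown)}")
    missing = required - set(block)
    if missing:
        raise ConfigError(f"{where}: missing required keys {sorted(missing)}")


@dataclass(frozen=True)
class ModelSettings:
    """Structural model settings: cycle length, horizon, discounting, WTP."""

    cycle_length_days: float = 21.0
    horizon_years: float = 10.0
    discount_annual: float = 0.05
    wtp: float = 268074.0

    def __post_init__(self) -> None:
        if self.cycle_length_days <= 0 or self.horizon_years <= 0:
            raise ConfigError("cycle length and horizon must be positive")
        if not 0 <= self.discount_annual <= 1:
            raise ConfigError("discount_annual must lie in [0, 1]")
        if self.wtp <= 0:
            raise ConfigError("wtp must be positive")
        if self.n_cycles < 1:
            raise ConfigError("horizon must cover at least one cycle")

    @property
    def n_cycles(self) -> int:
        """Number of model cycles covering the horizon."""
        return int(self.horizon_years * 365.0 // self.cycle_length_days)

    @property
    def cycle_months(self) -> float:
        return self.cycle_length_days / DAYS_PER_MONTH

    @property
    def cycle_years(self) -> float:
        return self.cycle_length_days / 365.0


@dataclass(frozen=True)
class Conventions:
    """Accrual conventions the source analysis leaves open; every field is a
    documented switch and the shipped defaults are the package's calibrated
    base case (see docs/methods.md)."""

    platinum: str = "carboplatin"  # carboplatin | cisplatin | mix
    carboplatin_share: float = 0.5  # used only when platinum == "mix"
    n_sub_cycles: int = 4  # cycles of one subsequent-chemo course
    ae_disutility_years: float = 21.0 / 365.0  # duration of the AE decrement
    cycle_timing: str = "end"  # end | start | half
    followup_states: tuple[str, ...] = ("pfs", "pd")
    bsc_states: tuple[str, ...] = ("pd",)
    psa_sample_survival: bool = True
    psa_ipd_n_per_arm: int = 228
    psa_admin_censor_months: float = 40.0
    psa_random_censor_rate: float = 0.005

    def __post_init__(self) -> None:
        if self.platinum not in {"carboplatin", "cisplatin", "mix"}:
            raise ConfigError("platinum must be carboplatin, cisplatin or mix")
        if not 0 <= self.carboplatin_share <= 1:
            raise ConfigError("carboplatin_share must lie in [0, 1]")
        if self.cycle_timing not in {"end", "start", "half"}:
            raise ConfigError("cycle_timing must be end, start or half")
        if self.n_sub_cycles < 0 or self.ae_disutility_years < 0:
            raise ConfigError("n_sub_cycles and ae_disutility_years must be >= 0")
        for st in (*self.followup_states, *self.bsc_states):
            if st not in {"pfs", "pd"}:
                raise ConfigError(f"unknown state {st!r} in cost-state assignment")


@dataclass(frozen=True)
class ParameterEntry:
    """One named model input with its base value, one-way range and PSA family."""

    name: str
    base: float
    low: float
    high: float
    psa_family: str = "fixed"  # gamma | beta | fixed

    def __post_init__(self) -> None:
        if not self.low <= self.base <= self.high:
            raise ConfigError(
                f"parameter {self.name!r}: range must satisfy low <= base <= high "
                f"(got {self.low} / {self.base} / {self.high})"
            )
        if self.psa_family not in {"gamma", "beta", "fixed"}:
            raise ConfigError(f"parameter {self.name!r}: unknown psa family")
        if self.psa_family == "beta" and not (0 <= self.low and self.high <= 1):
            raise ConfigError(
                f"parameter {self.name!r}: beta-distributed values must lie in [0, 1]"
            )
        if self.psa_family == "gamma" and self.low < 0:
            raise ConfigError(f"parameter {self.name!r}: gamma support is positive")


@dataclass(frozen=True)
class AdverseEventRef:
    incidence: str
    cost: str
    disutility: str


@dataclass(frozen=True)
class ArmSpec:
    """One treatment arm: survival-curve parameter refs plus costing roles.

    All string fields except ``name`` are names in the parameter table.
    """

    name: str
    os_family: str
    os_params: dict[str, str]
    pfs_family: str
    pfs_params: dict[str, str]
    induction_cycles: int = 4
    maintenance_drug: str | None = None
    subsequent_proportion: str = ""
    adverse_events: tuple[AdverseEventRef, ...] = ()

    def __post_init__(self) -> None:
        if self.induction_cycles < 0:
            raise ConfigError("induction_cycles must be >= 0")
        for fam, params in ((self.os_family, self.os_params), (self.pfs_family, self.pfs_params)):
            if fam not in FAMILIES:
                raise ConfigError(f"arm {self.name!r}: unknown survival family {fam!r}")
            if tuple(params) != FAMILIES[fam]:
                raise ConfigError(
                    f"arm {self.name!r}: {fam} needs parameter refs {FAMILIES[fam]}"
                )

    def os_dist(self, values: Mapping[str, float]) -> SurvivalDistribution:
        return SurvivalDistribution(
            self.os_family, {k: values[ref] for k, ref in self.os_params.items()}
        )

    def pfs_dist(self, values: Mapping[str, float]) -> SurvivalDistribution:
        return SurvivalDistribution(
            self.pfs_family, {k: values[ref] for k, ref in self.pfs_params.items()}
        )


@dataclass(frozen=True)
class ModelInputs:
    """Validated model inputs: settings, conventions, two arms (comparator
    first) and the flat parameter table."""

    settings: ModelSettings
    conventions: Conventions
    arms: tuple[ArmSpec, ArmSpec]
    parameters: dict[str, ParameterEntry] = field(repr=False)

    def __post_init__(self) -> None:
        if len(self.arms) != 2:
            raise ConfigError("exactly two arms are required (comparator first)")
        # every reference must resolve
        for arm in self.arms:
            refs = [
                *arm.os_params.values(),
                *arm.pfs_params.values(),
                arm.subsequent_proportion,
            ]
            if arm.maintenance_drug is not None:
                refs.append(arm.maintenance_drug)
            for ae in arm.adverse_events:
                refs += [ae.incidence, ae.cost, ae.disutility]
            for ref in refs:
                if ref not in self.parameters:
                    raise ConfigError(
                        f"arm {arm.name!r} references unknown parameter {ref!r}"
                    )
        for required in (
            "etoposide_cost",
            "cisplatin_cost",
            "carboplatin_cost",
            "bsc_cost",
            "followup_cost",
            "u_pfs",
            "u_pd",
            "discount_rate",
        ):
            if required not in self.parameters:
                raise ConfigError(f"parameter table is missing {required!r}")

    @property
    def comparator(self) -> ArmSpec:
        return self.arms[0]

    @property
    def intervention(self) -> ArmSpec:
        return self.arms[1]

    def base_values(self) -> dict[str, float]:
        return {name: p.base for name, p in self.parameters.items()}

    def resolved(self, overrides: Mapping[str, float] | None = None) -> dict[str, float]:
        """Base values with optional by-name overrides (unknown names rejected)."""
        values = self.base_values()
        if overrides:
            for name, val in overrides.items():
                if name not in values:
                    raise KeyError(f"unknown parameter {name!r}")
                values[name] = float(val)
        return values


def resolve_parameter(
    inputs: ModelInputs, name: str, override: float | None = None
) -> float:
    """The single read path for model inputs: override if given, else base."""
    if name not in inputs.parameters:
        raise KeyError(f"unknown parameter {name!r}")
    return float(override) if override is not None else inputs.parameters[name].base


def _parse_arm(block: Mapping, where: str) -> ArmSpec:
    _require_keys(
        block,
        {
            "name",
            "survival",
            "induction_cycles",
            "maintenance_drug",
            "subsequent_proportion",
            "adverse_events",
        },
        {"name", "survival", "subsequent_proportion"},
        where,
    )
    surv = block["survival"]
    _require_keys(surv, {"os", "pfs"}, {"os", "pfs"}, f"{where}.survival")
    dists = {}
    for endpoint in ("os", "pfs"):
        sub = dict(surv[endpoint])
        fam = sub.pop("family", None)
        if fam not in FAMILIES:
            raise ConfigError(f"{where}.survival.{endpoint}: unknown family {fam!r}")
        dists[endpoint] = (fam, sub)
    aes = tuple(
        AdverseEventRef(ae["incidence"], ae["cost"], ae["disutility"])
        for ae in block.get("adverse_events", [])
    )
    return ArmSpec(
        name=block["name"],
        os_family=dists["os"][0],
        os_params=dists["os"][1],
        pfs_family=dists["pfs"][0],
        pfs_params=dists["pfs"][1],
        induction_cycles=int(block.get("induction_cycles", 4)),
        maintenance_drug=block.get("maintenance_drug"),
        subsequent_proportion=block["subsequent_proportion"],
        adverse_events=aes,
    )


def parse_inputs(doc: Mapping) -> ModelInputs:
    """Validate a parsed YAML/JSON document into :class:`ModelInputs`."""
    if not isinstance(doc, Mapping):
        raise ConfigError("config root must be a mapping")
    _require_keys(
        doc,
        {"settings", "conventions", "arms", "parameters"},
        {"arms", "parameters"},
        "config",
    )
    settings_block = dict(doc.get("settings", {}))
    _require_keys(
        settings_block,
        {"cycle_length_days", "horizon_years", "discount_annual", "wtp"},
        set(),
        "settings",
    )
    settings = ModelSettings(**settings_block)
    conv_block = dict(doc.get("conventions", {}))
    for key in ("followup_states", "bsc_states"):
        if key in conv_block:
            conv_block[key] = tuple(conv_block[key])
    conventions = Conventions(**conv_block)
    params: dict[str, ParameterEntry] = {}
    for row in doc["parameters"]:
        _require_keys(
            row, {"name", "base", "low", "high", "dist"}, {"name", "base"}, "parameters"
        )
        entry = ParameterEntry(
            name=row["name"],
            base=float(row["base"]),
            low=float(row.get("low", row["base"])),
            high=float(row.get("high", row["base"])),
            psa_family=row.get("dist", "fixed"),
        )
        if entry.name in params:
            raise ConfigError(f"duplicate parameter {entry.name!r}")
        params[entry.name] = entry
    arms = tuple(_parse_arm(a, f"arms[{i}]") for i, a in enumerate(doc["arms"]))
    if len(arms) != 2:
        raise ConfigError("exactly two arms are required (comparator first)")
    return ModelInputs(settings=settings, conventions=conventions, arms=arms, parameters=params)


def load_inputs(path) -> ModelInputs:
    """Load and validate a YAML (or JSON — a YAML subset) config file."""
    text = Path(path).read_text()
    return parse_inputs(yaml.safe_load(text))


def inputs_to_dict(inputs: ModelInputs) -> dict:
    """Serializable document; load_inputs(save) round-trips exactly."""
    return {
        "settings": asdict(inputs.settings),
        "conventions": {
            **{
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in asdict(inputs.conventions).items()
            }
        },
        "arms": [
            {
                "name": a.name,
                "survival": {
                    "os": {"family": a.os_family, **a.os_params},
                    "pfs": {"family": a.pfs_family, **a.pfs_params},
                },
                "induction_cycles": a.induction_cycles,
                "maintenance_drug": a.maintenance_drug,
                "subsequent_proportion": a.subsequent_proportion,
                "adverse_events": [asdict(ae) for ae in a.adverse_events],
            }
            for a in inputs.arms
        ],
        "parameters": [
            {
                "name": p.name,
                "base": p.base,
                "low": p.low,
                "high": p.high,
                "dist": p.psa_family,
            }
            for p in inputs.parameters.values()
        ],
    }


def save_inputs(inputs: ModelInputs, path) -> None:
    Path(path).write_text(yaml.safe_dump(inputs_to_dict(inputs), sort_keys=False))


def default_inputs() -> ModelInputs:
    """The packaged base-case input set (trial-derived, file rationale312.yaml)."""
    ref = importlib.resources.files("sclc_cea").joinpath("data/rationale312.yaml")
    return parse_inputs(yaml.safe_load(ref.read_text()))
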