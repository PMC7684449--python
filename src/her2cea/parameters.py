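"""Model parameters: definition, validation, loading, and PSA sampling.

Every quantity the model consumes — pathologic-complete-response (pCR)
proportions, recurrence probabilities and relative risks, median survivals,
toxicity probabilities, costs, and health-state utilities — is carried in a
:class:`ParameterSet`, each field paired with a tagged parametric
:class:`Distribution` used by the probabilistic sensitivity analysis.  The
shipped defaults live in ``data/default_config.yaml`` and can be overridden
by a user configuration in the same YAML schema.
"""

from __future__ import annotations

import copy
import io
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterator

import numpy as np
import yaml
from scipy import stats

__all__ = [
    "Distribution",
    "ParameterSet",
    "ModelSettings",
    "StrategySpec",
    "GompertzMakehamParams",
    "Config",
    "ConfigError",
    "load_parameters",
    "load_config",
    "default_config_text",
    "distribution_mean",
    "sample_parameter_set",
    "dump_table1_csv",
]

FAMILIES = ("beta", "gamma", "lognormal", "truncnormal", "normal", "point")

#: relative tolerance for the load-time check that a distribution's analytic
#: mean reproduces the printed base-case value
MEAN_CHECK_RTOL = 0.10

#: parameter paths exempt from the mean-vs-base check (the published beta for
#: the AML baseline has mean ~0.0007 while the printed point value is 0.001;
#: the base case uses the point value, the PSA the beta)
MEAN_CHECK_EXEMPT = frozenset({"aml1y_ref"})

#: relative scale of the truncated-normal distributions (the source tables
#: print only the truncation bounds; the 20% SE convention used for costs is
#: applied to the location as well)
TRUNCNORMAL_CV = 0.20


class ConfigError(ValueError):
    """Raised when a configuration fails to parse or validate."""


@dataclass(frozen=True)
class Distribution:
    """A tagged parametric distribution for one model parameter.

    ``shape1``/``shape2`` meanings by family: beta ``(alpha, beta)``; gamma
    ``(shape, scale)`` with mean ``shape*scale``; lognormal ``(mu, sigma)`` on
    the log scale; truncnormal ``(lower, upper)`` with ``loc``/``scale``
    carried separately; normal ``(mean, sd)``; point ignores both.
    """

    family: str
    shape1: float = 0.0
    shape2: float = 0.0
    loc: float | None = None
    scale: float | None = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ConfigError(f"unknown distribution family {self.family!r}")
        if self.family in ("beta", "gamma") and (self.shape1 <= 0 or self.shape2 <= 0):
            raise ConfigError(
                f"{self.family} requires positive shape parameters, "
                f"got ({self.shape1}, {self.shape2})"
            )
        if self.family == "truncnormal" and not self.shape1 < self.shape2:
            raise ConfigError(
                f"truncnormal requires lower < upper, got ({self.shape1}, {self.shape2})"
            )
        if self.family == "normal" and self.shape2 <= 0:
            raise ConfigError("normal requires sd > 0")

    def _truncnorm_frozen(self):
        loc = self.loc if self.loc is not None else 0.5 * (self.shape1 + self.shape2)
        scale = self.scale if self.scale is not None else TRUNCNORMAL_CV * loc
        a = (self.shape1 - loc) / scale
        b = (self.shape2 - loc) / scale
        return stats.truncnorm(a, b, loc=loc, scale=scale)


def distribution_mean(d: Distribution) -> float:
    """Analytic mean of a :class:`Distribution`."""
    if d.family == "beta":
        return d.shape1 / (d.shape1 + d.shape2)
    if d.family == "gamma":
        return d.shape1 * d.shape2
    if d.family == "lognormal":
        return float(np.exp(d.shape1 + 0.5 * d.shape2**2))
    if d.family == "truncnormal":
        return float(d._truncnorm_frozen().mean())
    if d.family == "normal":
        return d.shape1
    return d.shape1  # point mass carries its value in shape1


def _sample_one(d: Distribution, rng: np.random.Generator) -> float:
    if d.family == "beta":
        return float(rng.beta(d.shape1, d.shape2))
    if d.family == "gamma":
        return float(rng.gamma(d.shape1, d.shape2))
    if d.family == "lognormal":
        return float(rng.lognormal(d.shape1, d.shape2))
    if d.family == "truncnormal":
        return float(d._truncnorm_frozen().rvs(random_state=rng))
    if d.family == "normal":
        return float(rng.normal(d.shape1, d.shape2))
    return d.shape1


# ---------------------------------------------------------------------------
# parameter registry: path -> (units, source-table row label)

_REGISTRY: dict[str, tuple[str, str]] = {
    "pcr_prob.HP": ("probability", "pCR after neoadjuvant HP"),
    "pcr_prob.THP": ("probability", "pCR after neoadjuvant THP"),
    "pcr_prob.DDAC_THP": ("probability", "pCR after neoadjuvant DDAC/THP"),
    "pcr_prob.TCHP": ("probability", "pCR after neoadjuvant TCHP"),
    "dr3y_ref": ("probability/3y", "3-y distant recurrence, H with residual disease"),
    "rr_dr.TDM1": ("relative risk", "RR distant recurrence, T-DM1 with residual disease"),
    "rr_dr.DDACTHP_TDM1": ("relative risk", "RR distant recurrence, DDAC/THP then T-DM1"),
    "rr_dr.DDAC_TDM1": ("relative risk", "RR distant recurrence, DDAC then T-DM1"),
    "rr_dr.H_PCR": ("relative risk", "RR distant recurrence, H with pCR"),
    "rr_dr.H": ("relative risk", "RR distant recurrence, H with residual disease (reference)"),
    "lr3y_ref": ("probability/3y", "3-y locoregional recurrence, H with residual disease"),
    "rr_lr": ("relative risk", "RR locoregional recurrence, non-reference groups"),
    "p_dr_after_lr_10y": ("probability/10y", "subsequent distant recurrence after local recurrence"),
    "median_surv_dr_months": ("months", "median survival with distant recurrence"),
    "median_surv_aml_months": ("months", "median survival with AML"),
    "p_chf_death_annual": ("probability/y", "annual risk of death due to CHF"),
    "chf1y_ref": ("probability/y", "1-y CHF probability, non-AC chemotherapy"),
    "rr_chf_ac": ("relative risk", "RR CHF, AC chemotherapy"),
    "aml1y_ref": ("probability/y", "1-y AML probability, no chemotherapy"),
    "rr_aml_nonac": ("relative risk", "RR AML, non-AC chemotherapy"),
    "rr_aml_ac": ("relative risk", "RR AML, AC chemotherapy"),
    "cost_neoadjuvant.HP": ("2020 USD", "neoadjuvant HP cost"),
    "cost_neoadjuvant.THP": ("2020 USD", "neoadjuvant THP cost"),
    "cost_neoadjuvant.DDAC_THP": ("2020 USD", "neoadjuvant DDAC/THP cost"),
    "cost_neoadjuvant.TCHP": ("2020 USD", "neoadjuvant TCHP cost"),
    "cost_adjuvant.H": ("2020 USD", "adjuvant H cost"),
    "cost_adjuvant.TDM1": ("2020 USD", "adjuvant T-DM1 cost"),
    "cost_adjuvant.DDACTHP_TDM1": ("2020 USD", "adjuvant DDAC/THP then T-DM1 cost"),
    "cost_adjuvant.DDAC_TDM1": ("2020 USD", "adjuvant DDAC then T-DM1 cost"),
    "cost_adjuvant.H_POST_TCHP": ("2020 USD", "adjuvant H after neoadjuvant TCHP cost"),
    "cost_adjuvant.TDM1_POST_TCHP": ("2020 USD", "adjuvant T-DM1 after neoadjuvant TCHP cost"),
    "cost_lr_first_year": ("2020 USD", "locoregional recurrence, first year"),
    "cost_lr_subsequent": ("2020 USD/y", "locoregional recurrence, after first year"),
    "cost_dr_annual": ("2020 USD/y", "distant recurrence, annual cost of care"),
    "cost_chf_initial": ("2020 USD", "initial CHF treatment"),
    "cost_chf_annual": ("2020 USD/y", "annual CHF care"),
    "cost_aml_lifetime": ("2020 USD", "lifetime treatment of AML"),
    "u_rf_first_year": ("utility", "first year recurrence free"),
    "u_rf": ("utility", "recurrence free, second year and after"),
    "u_lr": ("utility", "with local recurrence"),
    "u_dr": ("utility", "with distant recurrence"),
    "u_chf": ("utility", "with CHF"),
    "u_aml": ("utility", "with AML"),
    "u_dr_terminal": ("utility", "last year with distant recurrence before death"),
}

PARAMETER_PATHS: tuple[str, ...] = tuple(_REGISTRY)


def _kind(path: str) -> str:
    """Invariant class of a parameter path."""
    leaf = path.split(".")[0]
    if leaf.startswith("cost_"):
        return "cost"
    if leaf.startswith("rr_") or leaf == "rr_dr" or leaf == "rr_lr":
        return "rr"
    if leaf.startswith("median_surv"):
        return "positive"
    return "probability"  # pcr_prob, *_ref, p_*, u_*


@dataclass
class ParameterSet:
    """One complete assignment of every model quantity.

    Either the base case (values = the shipped defaults) or a single PSA draw.
    ``distributions`` maps dotted parameter paths (e.g. ``"pcr_prob.THP"``)
    to the :class:`Distribution` used when sampling.
    """

    pcr_prob: dict[str, float]
    dr3y_ref: float
    rr_dr: dict[str, float]
    lr3y_ref: float
    rr_lr: float
    p_dr_after_lr_10y: float
    median_surv_dr_months: float
    median_surv_aml_months: float
    p_chf_death_annual: float
    chf1y_ref: float
    rr_chf_ac: float
    aml1y_ref: float
    rr_aml_nonac: float
    rr_aml_ac: float
    cost_neoadjuvant: dict[str, float]
    cost_adjuvant: dict[str, float]
    cost_lr_first_year: float
    cost_lr_subsequent: float
    cost_dr_annual: float
    cost_chf_initial: float
    cost_chf_annual: float
    cost_aml_lifetime: float
    u_rf_first_year: float
    u_rf: float
    u_lr: float
    u_dr: float
    u_chf: float
    u_aml: float
    u_dr_terminal: float
    distributions: dict[str, Distribution] = field(default_factory=dict)

    # -- dotted-path access -------------------------------------------------
    def get(self, path: str) -> float:
        parts = path.split(".")
        obj = getattr(self, parts[0])
        if len(parts) == 1:
            return obj
        try:
            return obj[parts[1]]
        except KeyError:
            raise KeyError(f"unknown parameter path {path!r}") from None

    def with_value(self, path: str, value: float) -> "ParameterSet":
        """Return a copy with ``path`` set to ``value`` (validated)."""
        new = self.copy()
        parts = path.split(".")
        if len(parts) == 1:
            if not hasattr(new, parts[0]):
                raise KeyError(f"unknown parameter path {path!r}")
            setattr(new, parts[0], float(value))
        else:
            d = getattr(new, parts[0])
            if parts[1] not in d:
                raise KeyError(f"unknown parameter path {path!r}")
            d[parts[1]] = float(value)
        new.validate()
        return new

    def copy(self) -> "ParameterSet":
        return replace(
            self,
            pcr_prob=dict(self.pcr_prob),
            rr_dr=dict(self.rr_dr),
            cost_neoadjuvant=dict(self.cost_neoadjuvant),
            cost_adjuvant=dict(self.cost_adjuvant),
            distributions=dict(self.distributions),
        )

    def iter_paths(self) -> Iterator[str]:
        return iter(PARAMETER_PATHS)

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        for path in self.iter_paths():
            v = self.get(path)
            kind = _kind(path)
            if kind == "probability" and not 0.0 <= v <= 1.0:
                raise ConfigError(f"{path} = {v} outside [0, 1]")
            if kind == "cost" and v < 0.0:
                raise ConfigError(f"{path} = {v} is a negative cost")
            if kind in ("rr", "positive") and v <= 0.0:
                raise ConfigError(f"{path} = {v} must be > 0")

    def validate_distribution_means(self) -> None:
        """Check every distribution reproduces its base value within 10%."""
        for path, d in self.distributions.items():
            if d.family == "point" or path in MEAN_CHECK_EXEMPT:
                continue
            base = self.get(path)
            m = distribution_mean(d)
            if base != 0 and abs(m - base) / abs(base) > MEAN_CHECK_RTOL:
                raise ConfigError(
                    f"{path}: distribution mean {m:.6g} deviates more than "
                    f"{MEAN_CHECK_RTOL:.0%} from base value {base:.6g}"
                )


def sample_parameter_set(
    base: ParameterSet, rng: np.random.Generator, max_retries: int = 100
) -> ParameterSet:
    """Draw one ParameterSet from the distributions attached to ``base``.

    Parameters are drawn independently, in a fixed (sorted-path) order so that
    identical generator states give identical draws.  A draw violating the
    field's invariant (e.g. a negative normal median survival) is rejected and
    redrawn up to ``max_retries`` times.
    """
    draw = base.copy()
    for path in sorted(base.distributions):
        d = base.distributions[path]
        if d.family == "point":
            continue
        kind = _kind(path)
        for _ in range(max_retries):
            v = _sample_one(d, rng)
            if kind == "probability" and not 0.0 <= v <= 1.0:
                continue
            if kind in ("rr", "positive") and v <= 0.0:
                continue
            if kind == "cost" and v < 0.0:
                continue
            break
        else:
            raise RuntimeError(f"could not draw a valid value for {path}")
        parts = path.split(".")
        if len(parts) == 1:
            setattr(draw, parts[0], v)
        else:
            getattr(draw, parts[0])[parts[1]] = v
    draw.validate()
    return draw


@dataclass
class ModelSettings:
    """Global run settings: cohort age span, cycling, discounting, WTP grid."""

    start_age: float = 49.0
    cycle_length: float = 1.0
    horizon_age: float = 100.0
    discount_rate: float = 0.03
    wtp_thresholds: tuple[float, ...] = (50_000.0, 100_000.0, 150_000.0)
    wtp_grid: np.ndarray = field(
        default_factory=lambda: np.arange(0.0, 200_001.0, 1000.0)
    )
    psa_iterations: int = 1000
    rng_seed: int = 2027074
    #: "lifetime": treatment-related AML/CHF incidence recurs every cycle;
    #: "first_cycle": restricted to the treatment year
    toxicity_mode: str = "lifetime"

    def __post_init__(self) -> None:
        if self.toxicity_mode not in ("lifetime", "first_cycle"):
            raise ConfigError(f"unknown toxicity_mode {self.toxicity_mode!r}")
        if not 0.0 <= self.discount_rate < 1.0:
            raise ConfigError(f"discount_rate {self.discount_rate} outside [0, 1)")
        if not self.start_age < self.horizon_age:
            raise ConfigError("start_age must be below horizon_age")
        if self.cycle_length <= 0:
            raise ConfigError("cycle_length must be positive")
        self.wtp_grid = np.asarray(self.wtp_grid, dtype=float)

    @property
    def n_cycles(self) -> int:
        return int(round((self.horizon_age - self.start_age) / self.cycle_length))


@dataclass(frozen=True)
class StrategySpec:
    """One neoadjuvant-adjuvant treatment strategy of the decision tree.

    ``pcr_adjuvant``/``residual_adjuvant`` are adjuvant cost keys;
    ``residual_rr_dr`` names the distant-recurrence relative risk applied to
    the residual-disease branch.  ``residual_lr_reference`` marks the residual
    branch as the locoregional-recurrence reference group (adjuvant H with
    residual disease), which takes RR 1 instead of the shared ``rr_lr``.
    """

    id: int
    name: str
    neoadjuvant: str
    pcr_adjuvant: str
    residual_adjuvant: str
    residual_rr_dr: str
    pcr_toxicity: str
    residual_toxicity: str
    residual_lr_reference: bool = False
    #: extra upfront cost on the pCR branch (used by the adjuvant-HP scenario,
    #: where pertuzumab is added to pCR-branch trastuzumab)
    pcr_cost_increment: float = 0.0

    def __post_init__(self) -> None:
        for cls in (self.pcr_toxicity, self.residual_toxicity):
            if cls not in ("ac", "non_ac", "no_chemo"):
                raise ConfigError(f"strategy {self.id}: unknown toxicity class {cls!r}")

    def validate_against(self, params: ParameterSet) -> None:
        if self.neoadjuvant not in params.cost_neoadjuvant:
            raise ConfigError(f"strategy {self.id}: unknown neoadjuvant {self.neoadjuvant!r}")
        if self.neoadjuvant not in params.pcr_prob:
            raise ConfigError(f"strategy {self.id}: no pCR rate for {self.neoadjuvant!r}")
        for key in (self.pcr_adjuvant, self.residual_adjuvant):
            if key not in params.cost_adjuvant:
                raise ConfigError(f"strategy {self.id}: unknown adjuvant cost key {key!r}")
        if self.residual_rr_dr not in params.rr_dr:
            raise ConfigError(f"strategy {self.id}: unknown rr_dr key {self.residual_rr_dr!r}")


@dataclass(frozen=True)
class GompertzMakehamParams:
    """Parameters of the parametric background-mortality life table."""

    makeham: float = 5.0e-4
    scale: float = 3.5e-5
    shape: float = 0.094


@dataclass
class Config:
    """A fully parsed configuration."""

    params: ParameterSet
    settings: ModelSettings
    strategies: list[StrategySpec]
    life_table: GompertzMakehamParams
    raw_text: str = ""


# ---------------------------------------------------------------------------
# loading

def default_config_text() -> str:
    return (resources.files("her2cea.data") / "default_config.yaml").read_text()


def _require(mapping: dict, key: str, context: str):
    if key not in mapping:
        raise ConfigError(f"missing key {key!r} in {context}")
    return mapping[key]


def _parse_param(node, path: str) -> tuple[float, Distribution]:
    if not isinstance(node, dict) or "value" not in node:
        raise ConfigError(f"parameter {path!r} must be a mapping with a 'value'")
    value = float(node["value"])
    dnode = node.get("dist", {"family": "point"})
    family = _require(dnode, "family", f"parameters.{path}.dist")
    if family == "point":
        dist = Distribution("point", shape1=value)
    elif family == "truncnormal":
        loc = float(dnode.get("loc", value))
        scale = float(dnode.get("scale", TRUNCNORMAL_CV * loc))
        dist = Distribution(
            "truncnormal",
            shape1=float(_require(dnode, "shape1", path)),
            shape2=float(_require(dnode, "shape2", path)),
            loc=loc,
            scale=scale,
        )
    else:
        dist = Distribution(
            family,
            shape1=float(_require(dnode, "shape1", path)),
            shape2=float(_require(dnode, "shape2", path)),
        )
    return value, dist


def load_config(config_text: str | None = None) -> Config:
    """Parse and validate a YAML configuration (the shipped default if None)."""
    text = config_text if config_text is not None else default_config_text()
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"configuration is not valid YAML: {exc}") from exc
    if not isinstance(doc, dict):
        raise ConfigError("configuration must be a YAML mapping")

    pnode = _require(doc, "parameters", "configuration")
    values: dict[str, object] = {}
    dists: dict[str, Distribution] = {}
    for path in PARAMETER_PATHS:
        parts = path.split(".")
        node = pnode
        for part in parts:
            if not isinstance(node, dict) or part not in node:
                raise ConfigError(f"missing parameter parameters.{path}")
            node = node[part]
        v, d = _parse_param(node, path)
        dists[path] = d
        if len(parts) == 1:
            values[parts[0]] = v
        else:
            values.setdefault(parts[0], {})[parts[1]] = v  # type: ignore[union-attr]

    params = ParameterSet(distributions=dists, **values)  # type: ignore[arg-type]
    params.validate()
    params.validate_distribution_means()

    snode = dict(doc.get("settings", {}))
    grid = snode.pop("wtp_grid", None)
    if isinstance(grid, dict):
        snode["wtp_grid"] = np.arange(
            float(grid.get("start", 0.0)),
            float(grid.get("stop", 200_000.0)) + 0.5 * float(grid.get("step", 1000.0)),
            float(grid.get("step", 1000.0)),
        )
    elif grid is not None:
        snode["wtp_grid"] = np.asarray(grid, dtype=float)
    if "wtp_thresholds" in snode:
        snode["wtp_thresholds"] = tuple(float(w) for w in snode["wtp_thresholds"])
    settings = ModelSettings(**snode)

    strategies = []
    for entry in _require(doc, "strategies", "configuration"):
        spec = StrategySpec(**entry)
        spec.validate_against(params)
        strategies.append(spec)
    ids = [s.id for s in strategies]
    if len(set(ids)) != len(ids):
        raise ConfigError(f"duplicated strategy ids: {ids}")

    lnode = doc.get("life_table", {})
    life = GompertzMakehamParams(
        makeham=float(lnode.get("makeham", 5.0e-4)),
        scale=float(lnode.get("scale", 3.5e-5)),
        shape=float(lnode.get("shape", 0.094)),
    )
    return Config(params, settings, strategies, life, raw_text=text)


def load_parameters(
    config_text: str | None = None,
) -> tuple[ParameterSet, ModelSettings, list[StrategySpec]]:
    """Load parameters, settings, and strategy specs from configuration text.

    With no argument, returns the shipped defaults.
    """
    cfg = load_config(config_text)
    return cfg.params, cfg.settings, cfg.strategies


def apply_overrides(cfg: Config, overrides: dict[str, float]) -> Config:
    """Return a new Config with dotted-path parameter overrides applied.

    Keys starting with ``settings.`` override model settings instead.
    """
    params = cfg.params
    settings = cfg.settings
    for path, value in overrides.items():
        if path.startswith("settings."):
            key = path.split(".", 1)[1]
            if not hasattr(settings, key):
                raise ConfigError(f"unknown setting {key!r}")
            kwargs = {
                f: getattr(settings, f)
                for f in (
                    "start_age",
                    "cycle_length",
                    "horizon_age",
                    "discount_rate",
                    "wtp_thresholds",
                    "wtp_grid",
                    "psa_iterations",
                    "rng_seed",
                    "toxicity_mode",
                )
            }
            kwargs[key] = value
            settings = ModelSettings(**kwargs)
        else:
            params = params.with_value(path, value)
    return Config(params, settings, list(cfg.strategies), cfg.life_table, cfg.raw_text)


def dump_table1_csv(params: ParameterSet | None = None) -> str:
    """Machine-readable dump of the shipped defaults as CSV text.

    Columns: parameter, base_value, family, shape1, shape2, units, table1_row.
    """
    if params is None:
        params = load_config().params
    buf = io.StringIO()
    buf.write("parameter,base_value,family,shape1,shape2,units,table1_row\n")
    for path, (units, row) in _REGISTRY.items():
        d = params.distributions[path]
        buf.write(
            f"{path},{params.get(path):g},{d.family},{d.shape1:g},{d.shape2:g},"
            f"{units},\"{row}\"\n"
        )
    return buf.getvalue()
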