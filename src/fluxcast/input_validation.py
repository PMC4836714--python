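"""Domain checking of prediction requests before any computation runs.

Every input of a prediction request is treated as a variable with a declared
domain: an interval for continuous quantities, a finite set for categorical
ones, or a named relation tying several variables together (e.g. the
substrate ratios must lie on the unit simplex).  A request that violates an
error-severity rule is rejected with a message naming the rule; warnings are
reported but do not block the pipeline.  The shipped rule inventory and its
numeric domains are configuration defaults of this package, overridable from
a YAML rules file.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import yaml

from .encoding import OXYGEN_LEVELS, CultureCondition
from .stoichiometry import FLUX_IDS

__all__ = [
    "DomainRule",
    "ValidationIssue",
    "ValidationReport",
    "validate",
    "default_rules",
    "rules_to_yaml",
    "rules_from_yaml",
]

_CONDITION_FIELDS = frozenset(
    {
        "species",
        "nutrient_type",
        "oxygen",
        "cultivation_method",
        "genetic_background",
        "engineering_method",
        "growth_rate",
        "uptake_rate",
        "mix",
    }
)


@dataclass(frozen=True)
class DomainRule:
    """One satisfiability check on the prediction request.

    ``kind`` is one of ``interval`` (params: variable, low, high),
    ``finite_set`` (params: variable, levels) or ``relation`` (params:
    name + relation-specific keys).  ``severity`` is ``error`` or ``warning``.
    """

    name: str
    kind: str
    params: dict
    severity: str = "error"
    message: str = ""

    def __post_init__(self):
        if self.kind not in ("interval", "finite_set", "relation"):
            raise ValueError(f"malformed rule {self.name!r}: unknown kind {self.kind!r}")
        if self.severity not in ("error", "warning"):
            raise ValueError(f"malformed rule {self.name!r}: bad severity {self.severity!r}")
        var = self.params.get("variable")
        if self.kind in ("interval", "finite_set"):
            if var not in _CONDITION_FIELDS:
                raise ValueError(
                    f"malformed rule {self.name!r}: unknown variable {var!r}"
                )
        elif self.params.get("name") not in _RELATIONS:
            raise ValueError(
                f"malformed rule {self.name!r}: unknown relation {self.params.get('name')!r}"
            )


@dataclass(frozen=True)
class ValidationIssue:
    rule: str
    severity: str
    offending: object
    message: str


@dataclass(frozen=True)
class ValidationReport:
    issues: tuple[ValidationIssue, ...]

    @property
    def passed(self) -> bool:
        return not any(i.severity == "error" for i in self.issues)

    @property
    def errors(self) -> tuple[ValidationIssue, ...]:
        return tuple(i for i in self.issues if i.severity == "error")

    @property
    def warnings(self) -> tuple[ValidationIssue, ...]:
        return tuple(i for i in self.issues if i.severity == "warning")

    def __str__(self) -> str:
        if not self.issues:
            return "validation passed: all inputs within their domains"
        lines = [f"[{i.severity}] {i.rule}: {i.message} (got {i.offending!r})" for i in self.issues]
        verdict = "PASS (with warnings)" if self.passed else "FAIL"
        return "\n".join(lines + [f"validation {verdict}"])


# ---------------------------------------------------------------------------
# relation checks: each returns (ok, offending_value)

def _ratio_simplex(cond: CultureCondition, params: dict):
    total = sum(cond.mix.ratios.values())
    ok = abs(total - 1.0) <= params.get("tolerance", 1e-9) and all(
        0.0 <= r <= 1.0 for r in cond.mix.ratios.values()
    )
    return ok, total


def _anaerobic_growth_ceiling(cond: CultureCondition, params: dict):
    ceiling = params.get("ceiling", 1.0)
    if cond.oxygen == "anaerobic" and cond.growth_rate > ceiling:
        return False, cond.growth_rate
    return True, cond.growth_rate


def _some_carbon_source(cond: CultureCondition, params: dict):
    carbon = sum(r for s, r in cond.mix.ratios.items() if s != "NaHCO3")
    return carbon > 0.0, carbon


_RELATIONS: dict[str, Callable] = {
    "ratio_simplex": _ratio_simplex,
    "anaerobic_growth_ceiling": _anaerobic_growth_ceiling,
    "some_carbon_source": _some_carbon_source,
}


def default_rules() -> list[DomainRule]:
    """The shipped rule inventory (artifact defaults, not literature values)."""
    return [
        DomainRule(
            "growth_rate_range",
            "interval",
            {"variable": "growth_rate", "low": 0.0, "high": 2.5},
            "error",
            "growth rate must lie in [0, 2.5] 1/h",
        ),
        DomainRule(
            "uptake_rate_positive",
            "interval",
            {"variable": "uptake_rate", "low": 1e-12, "high": float("inf")},
            "error",
            "substrate uptake rate must be positive",
        ),
        DomainRule(
            "oxygen_level",
            "finite_set",
            {"variable": "oxygen", "levels": list(OXYGEN_LEVELS)},
            "error",
            f"oxygen condition must be one of {OXYGEN_LEVELS}",
        ),
        DomainRule(
            "ratio_simplex",
            "relation",
            {"name": "ratio_simplex", "tolerance": 1e-9},
            "error",
            "substrate ratios must lie in [0,1] and sum to 1",
        ),
        DomainRule(
            "carbon_source_present",
            "relation",
            {"name": "some_carbon_source"},
            "error",
            "at least one carbon substrate ratio must be nonzero",
        ),
        DomainRule(
            "anaerobic_growth_ceiling",
            "relation",
            {"name": "anaerobic_growth_ceiling", "ceiling": 1.0},
            "warning",
            "growth rate above the typical anaerobic ceiling (1.0 1/h)",
        ),
    ]


def validate(cond: CultureCondition, rules: list[DomainRule] | None = None) -> ValidationReport:
    """Evaluate every rule against the condition; order-independent."""
    if rules is None:
        rules = default_rules()
    issues: list[ValidationIssue] = []
    for rule in rules:
        if rule.kind == "interval":
            value = float(getattr(cond, rule.params["variable"]))
            ok = rule.params.get("low", -float("inf")) <= value <= rule.params.get(
                "high", float("inf")
            )
            offending = value
        elif rule.kind == "finite_set":
            value = str(getattr(cond, rule.params["variable"]))
            ok = value in rule.params["levels"]
            offending = value
        else:
            ok, offending = _RELATIONS[rule.params["name"]](cond, rule.params)
        if not ok:
            issues.append(
                ValidationIssue(rule.name, rule.severity, offending, rule.message)
            )
    return ValidationReport(tuple(issues))


def validate_knockouts(knockouts: list[str]) -> None:
    bad = [k for k in knockouts if k not in FLUX_IDS]
    if bad:
        raise ValueError(f"unknown knockout flux id(s): {bad}; expected v1..v29")


def rules_to_yaml(rules: list[DomainRule]) -> str:
    return yaml.safe_dump(
        [
            {
                "name": r.name,
                "kind": r.kind,
                "params": r.params,
                "severity": r.severity,
                "message": r.message,
            }
            for r in rules
        ],
        sort_keys=False,
    )


def rules_from_yaml(text: str) -> list[DomainRule]:
    raw = yaml.safe_load(text)
    if not isinstance(raw, list):
        raise ValueError("rules file must be a YAML list of rule mappings")
    out = []
    for item in raw:
        try:
            out.append(
                DomainRule(
                    name=item["name"],
                    kind=item["kind"],
                    params=dict(item.get("params", {})),
                    severity=item.get("severity", "error"),
                    message=item.get("message", ""),
                )
            )
        except (KeyError, TypeError) as err:
            raise ValueError(f"malformed rule entry {item!r}") from err
    return out
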