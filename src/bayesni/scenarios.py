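"""Scenario configuration: YAML/JSON loading and bundled example designs.

A scenario file names the four priors (design and analysis per arm),
the margin, and the two-sided significance level::

    experimental:
      design:   {mean: 0.18, sd: 0.02, round_params: true}
      analysis: {alpha: 1, beta: 1}
    control:
      design:   {alpha: 66, beta: 302}
      analysis: {alpha: 1, beta: 1}
    margin: {fixed: 0.10}          # or {uniform: [0.08, 0.12]}
    alpha: 0.05
    defaults: {reps: 100000, step: 10, n_min: 10, n_max: 2000}

Priors are given either as ``{alpha, beta}`` or as ``{mean, sd}`` to be
moment-matched on load (with an explicit ``round_params`` flag).
Probabilities in files are always decimals.

The bundled fixtures reproduce a worked example from a paediatric HIV
non-inferiority trial (the ODYSSEY design): 18% anticipated failure in
both arms, 10% margin, and a set of informative design/analysis priors
used to contrast the approaches.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path
from typing import Any, Dict, Union

import yaml

from .distributions import (
    ArmPriorPair,
    BetaParams,
    MarginSpec,
    TrialScenario,
    beta_from_moments,
)
from .errors import InvalidMomentsError, ScenarioConfigError

__all__ = ["FIXTURES", "fixture_names", "load_scenario", "scenario_to_dict", "scenario_hash"]


def _base_arm(analysis: BetaParams) -> ArmPriorPair:
    return ArmPriorPair(design=BetaParams(66, 302), analysis=analysis)


def _make_fixtures() -> Dict[str, TrialScenario]:
    flat = BetaParams(1, 1)
    fixed10 = MarginSpec.fixed(0.10)
    base = TrialScenario(
        experimental=_base_arm(flat), control=_base_arm(flat), margin=fixed10
    )
    degenerate = TrialScenario(
        experimental=ArmPriorPair(design=BetaParams(6600, 30200), analysis=flat),
        control=ArmPriorPair(design=BetaParams(6600, 30200), analysis=flat),
        margin=fixed10,
    )
    enthusiastic = TrialScenario(
        experimental=_base_arm(BetaParams(11, 48)),
        control=_base_arm(BetaParams(11, 48)),
        margin=fixed10,
    )
    skeptical = TrialScenario(
        experimental=_base_arm(BetaParams(141, 362)),
        control=_base_arm(BetaParams(66, 302)),
        margin=fixed10,
    )
    return {
        "odyssey-base": base,
        "odyssey-degenerate-design": degenerate,
        "odyssey-enthusiastic": enthusiastic,
        "odyssey-skeptical": skeptical,
        "odyssey-margin-u0812": TrialScenario(
            experimental=_base_arm(flat),
            control=_base_arm(flat),
            margin=MarginSpec.uniform(0.08, 0.12),
        ),
        "odyssey-margin-u0515": TrialScenario(
            experimental=_base_arm(flat),
            control=_base_arm(flat),
            margin=MarginSpec.uniform(0.05, 0.15),
        ),
    }


FIXTURES: Dict[str, TrialScenario] = _make_fixtures()

_ALIASES = {
    "base": "odyssey-base",
    "degenerate-design": "odyssey-degenerate-design",
    "enthusiastic": "odyssey-enthusiastic",
    "skeptical": "odyssey-skeptical",
    "margin-u0812": "odyssey-margin-u0812",
    "margin-u0515": "odyssey-margin-u0515",
}


def fixture_names():
    """Canonical names of the bundled scenarios."""
    return sorted(FIXTURES)


def _parse_prior(node: Any, path: str) -> BetaParams:
    if not isinstance(node, dict):
        raise ScenarioConfigError(f"{path}: expected a mapping, got {type(node).__name__}")
    keys = set(node)
    if {"alpha", "beta"} <= keys:
        try:
            return BetaParams(float(node["alpha"]), float(node["beta"]))
        except (TypeError, ValueError) as exc:
            raise ScenarioConfigError(f"{path}: {exc}") from exc
    if {"mean", "sd"} <= keys:
        try:
            return beta_from_moments(
                float(node["mean"]),
                float(node["sd"]),
                round_params=bool(node.get("round_params", False)),
            )
        except InvalidMomentsError as exc:
            raise ScenarioConfigError(f"{path}: {exc}") from exc
    raise ScenarioConfigError(
        f"{path}: a prior needs either {{alpha, beta}} or {{mean, sd}}, got keys {sorted(keys)}"
    )


def _parse_arm(node: Any, path: str) -> ArmPriorPair:
    if not isinstance(node, dict):
        raise ScenarioConfigError(f"{path}: expected a mapping with design/analysis priors")
    for role in ("design", "analysis"):
        if role not in node:
            raise ScenarioConfigError(f"{path}.{role}: missing prior")
    return ArmPriorPair(
        design=_parse_prior(node["design"], f"{path}.design"),
        analysis=_parse_prior(node["analysis"], f"{path}.analysis"),
    )


def _parse_margin(node: Any) -> MarginSpec:
    if isinstance(node, (int, float)):
        node = {"fixed": node}
    if not isinstance(node, dict):
        raise ScenarioConfigError("margin: expected a number or {fixed}/{uniform} mapping")
    try:
        if "fixed" in node:
            return MarginSpec.fixed(float(node["fixed"]))
        if "uniform" in node:
            lo, hi = node["uniform"]
            return MarginSpec.uniform(float(lo), float(hi))
    except (TypeError, ValueError) as exc:
        raise ScenarioConfigError(f"margin: {exc}") from exc
    raise ScenarioConfigError(f"margin: needs 'fixed' or 'uniform', got keys {sorted(node)}")


def load_scenario(source: Union[str, Path]) -> TrialScenario:
    """Load a scenario from a fixture name or a YAML/JSON file path.

    Raises
    ------
    ScenarioConfigError
        On parse failures or invariant violations; the message names the
        offending field.
    """
    name = str(source)
    if name in FIXTURES:
        return FIXTURES[name]
    if name in _ALIASES:
        return FIXTURES[_ALIASES[name]]
    path = Path(source)
    if not path.exists():
        raise ScenarioConfigError(
            f"{source!r} is neither a bundled scenario ({', '.join(fixture_names())}) "
            "nor an existing file"
        )
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ScenarioConfigError(f"{path}: parse error: {exc}") from exc
    if not isinstance(raw, dict):
        raise ScenarioConfigError(f"{path}: top level must be a mapping")
    for arm in ("experimental", "control"):
        if arm not in raw:
            raise ScenarioConfigError(f"{arm}: missing arm specification")
    if "margin" not in raw:
        raise ScenarioConfigError("margin: missing")
    alpha = raw.get("alpha", 0.05)
    try:
        return TrialScenario(
            experimental=_parse_arm(raw["experimental"], "experimental"),
            control=_parse_arm(raw["control"], "control"),
            margin=_parse_margin(raw["margin"]),
            alpha=float(alpha),
        )
    except ScenarioConfigError:
        raise
    except ValueError as exc:
        raise ScenarioConfigError(f"alpha: {exc}") from exc


def load_defaults(source: Union[str, Path]) -> Dict[str, Any]:
    """Run defaults (reps, seed, grid settings) from a scenario file, if any."""
    path = Path(source)
    if not path.exists():
        return {}
    raw = yaml.safe_load(path.read_text())
    if isinstance(raw, dict) and isinstance(raw.get("defaults"), dict):
        return dict(raw["defaults"])
    return {}


def scenario_to_dict(scenario: TrialScenario) -> Dict[str, Any]:
    """Plain-dict form of a scenario (JSON-serialisable)."""
    d = asdict(scenario)
    d["margin"] = {k: v for k, v in d["margin"].items() if v is not None}
    return d


def scenario_hash(scenario: TrialScenario) -> str:
    """Short stable hash identifying a scenario in logs and reports."""
    blob = json.dumps(scenario_to_dict(scenario), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
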