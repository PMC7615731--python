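"""Composite reports across the four sample-size approaches.

`run_report` dispatches one scenario to the frequentist formula, the
predictive-power simulation, the expected-posterior-probability search,
and the precision curve, and returns a single JSON-serialisable record
carrying full provenance (scenario hash, reps, seed, grid settings).
Identical (scenario, request, seed) inputs give identical records.
"""

from __future__ import annotations

import secrets
from typing import Any, Dict, Optional

from . import _engine
from .distributions import TrialScenario
from .errors import SearchNotFoundError
from .expected_posterior import find_n_for_epp
from .frequentist import FrequentistInputs, required_n
from .precision import PrecisionInputs, width_curve
from .predictive_power import find_n_for_power, predictive_power
from .scenarios import scenario_hash, scenario_to_dict

__all__ = ["run_report", "draw_seed"]

_ALL_ANALYSES = ("freq", "power", "epp", "width")


def draw_seed() -> int:
    """A fresh random seed below 2^31 (used when the caller gave none)."""
    return secrets.randbelow(2**31)


def run_report(
    scenario: TrialScenario, request: Optional[Dict[str, Any]] = None
) -> Dict[str, Any]:
    """Run the requested analyses on one scenario and collect the results.

    Parameters
    ----------
    scenario
        The validated trial scenario.
    request
        Optional overrides: ``analyses`` (subset of freq/power/epp/width),
        ``target`` (power / e_n target, default 0.90), ``n`` (evaluation
        sample size; default the frequentist answer), ``reps``, ``seed``,
        ``step``, ``n_min``, ``n_max``, ``p1``/``p0`` (assumed observed
        proportions for the precision curve; default the design-prior
        means), ``level``, ``width_grid``.

    Search failures are reported in-band under a ``"search_failed"`` key
    rather than raised, so a report is always produced; callers that
    need a hard failure (the CLI) can inspect the record.
    """
    req = dict(request or {})
    analyses = tuple(req.get("analyses", _ALL_ANALYSES))
    unknown = set(analyses) - set(_ALL_ANALYSES)
    if unknown:
        raise ValueError(f"unknown analyses: {sorted(unknown)}")

    reps = int(req.get("reps", _engine.DEFAULT_REPS))
    seed = req.get("seed")
    if seed is None:
        seed = draw_seed()
    step = int(req.get("step", _engine.DEFAULT_STEP))
    n_min = int(req.get("n_min", _engine.DEFAULT_N_MIN))
    n_max = int(req.get("n_max", _engine.DEFAULT_N_MAX))
    target = float(req.get("target", 0.90))

    p1_design = scenario.experimental.design.mean
    p0_design = scenario.control.design.mean
    margin_central = scenario.margin.midpoint

    record: Dict[str, Any] = {
        "scenario": scenario_to_dict(scenario),
        "scenario_hash": scenario_hash(scenario),
        "seed": int(seed),
        "reps": reps,
        "grid": {"step": step, "n_min": n_min, "n_max": n_max},
    }

    freq_n: Optional[int] = None
    if "freq" in analyses:
        inputs = FrequentistInputs(
            p1_expected=p1_design,
            p0_expected=p0_design,
            margin=margin_central,
            alpha=scenario.alpha,
            power=target,
        )
        freq_n = required_n(inputs)
        record["frequentist"] = {
            "p1_expected": p1_design,
            "p0_expected": p0_design,
            "margin": margin_central,
            "power": target,
            "n_per_group": freq_n,
            "n_total": 2 * freq_n,
        }

    eval_n = int(req.get("n", freq_n or 310))

    if "power" in analyses:
        res = predictive_power(scenario, eval_n, reps, seed)
        record["predictive_power"] = {
            "n_per_group": res.n_per_group,
            "joint_power": res.joint_power,
            "unconditional_power": res.unconditional_power,
            "prob_sig_and_inferior": res.prob_sig_and_inferior,
            "mc_se": res.mc_se,
        }
        try:
            record["power_search"] = {
                "target": target,
                "n_per_group": find_n_for_power(
                    scenario, target, step, max(n_min, 1), n_max, reps, seed
                ),
            }
        except SearchNotFoundError as exc:
            record["power_search"] = {
                "target": target,
                "search_failed": str(exc),
                "best_n": exc.best_n,
                "best_value": exc.best_value,
            }

    if "epp" in analyses:
        try:
            record["epp_search"] = {
                "target": target,
                "n_per_group": find_n_for_epp(
                    scenario, target, step, 0, n_max, reps, seed
                ),
            }
        except SearchNotFoundError as exc:
            record["epp_search"] = {
                "target": target,
                "search_failed": str(exc),
                "best_n": exc.best_n,
                "best_value": exc.best_value,
            }

    if "width" in analyses:
        inputs = PrecisionInputs(
            analysis_experimental=scenario.experimental.analysis,
            analysis_control=scenario.control.analysis,
            p1_assumed=float(req.get("p1", p1_design)),
            p0_assumed=float(req.get("p0", p0_design)),
            level=float(req.get("level", 0.95)),
        )
        grid = req.get("width_grid") or list(range(0, 1001, 50))
        frame = width_curve(inputs, grid)
        record["width_curve"] = {
            "p1_assumed": inputs.p1_assumed,
            "p0_assumed": inputs.p0_assumed,
            "level": inputs.level,
            "points": [
                {"n": int(n), "width": float(w)}
                for n, w in zip(frame["n"], frame["width"])
            ],
        }

    return record
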