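"""Study configuration, orchestration, and reporting.

Six built-in study designs span the experimental conditions of interest:
level versus 30-degree inclined landing, with combinations of muscular
co-activation, stretch-reflex gain, and external brace stiffness either
absent (fixed at zero) or drawn from their distributions.  Seven inputs are
common to every study.  A study couples these input distributions to the
reduced landing model, runs a Monte Carlo or AMV analysis on a selected
peak outcome (peak subtalar supination by default), and reports outcome
summaries, percentiles, and sensitivity tables that can all be recomputed
from the stored raw trials.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .kinematics import AxisSet
from .landing import (DEFAULT_PARAMETERS, ModelParameters, PeakOutcomes,
                      SimulationInputs, extract_peak_outcomes,
                      simulate_drop_landing)
from .probabilistic import (AMVResult, InputDistribution, MCResult,
                            amv_analyze, correlation_strength,
                            pearson_sensitivities, run_monte_carlo)

__all__ = [
    "StudyDesign",
    "StudyReport",
    "StudyConfigurationError",
    "INPUT_NAMES",
    "DEFAULT_SEED",
    "load_study",
    "make_response_model",
    "run_study",
    "write_report",
    "read_report",
    "audit_report",
]

#: Documented default seed for reproducible study runs.
DEFAULT_SEED = 42

#: The ten probabilistic input names, in canonical order.
INPUT_NAMES = (
    "brace_scale_pct",
    "coactivation_pct",
    "reflex_gain",
    "strength_pct",
    "passive_flexibility_pct",
    "talocrural_contact_deg",
    "subtalar_contact_deg",
    "drop_height_m",
    "contact_modulus_MPa_per_m",
    "contact_dissipation_s_per_m",
)


class StudyConfigurationError(ValueError):
    """A study id or configuration file is invalid; lists offending fields."""


@dataclass(frozen=True)
class StudyDesign:
    """One probabilistic study: a fixed platform incline plus the ten input
    distributions."""

    study_id: str
    incline_deg: float
    inputs: tuple

    def __post_init__(self):
        names = [d.name for d in self.inputs]
        missing = [n for n in INPUT_NAMES if n not in names]
        extra = [n for n in names if n not in INPUT_NAMES]
        if missing or extra:
            raise StudyConfigurationError(
                f"study {self.study_id}: missing inputs {missing}, "
                f"unknown inputs {extra}")
        if not math.isfinite(self.incline_deg):
            raise StudyConfigurationError("incline_deg must be finite")

    def distribution(self, name: str) -> InputDistribution:
        for d in self.inputs:
            if d.name == name:
                return d
        raise KeyError(name)

    def mean_inputs(self) -> SimulationInputs:
        return SimulationInputs(incline_deg=self.incline_deg,
                                **{d.name: d.mean for d in self.inputs})

    def to_dict(self) -> dict:
        return {
            "study_id": self.study_id,
            "incline_deg": self.incline_deg,
            "inputs": {d.name: {"family": d.family, "mean": d.mean,
                                "sd": d.sd} for d in self.inputs},
        }


def _dist(name, family, mean, sd=0.0) -> InputDistribution:
    # zero-valued rows are treated as fixed at 0 (a lognormal with mean 0
    # is undefined)
    if mean == 0 and sd == 0:
        return InputDistribution(name, "fixed", 0.0, 0.0)
    return InputDistribution(name, family, mean, sd)


def _common_inputs() -> list[InputDistribution]:
    return [
        _dist("strength_pct", "normal", 100.0, 5.0),
        _dist("passive_flexibility_pct", "normal", 100.0, 6.0),
        _dist("talocrural_contact_deg", "normal", 34.0, 5.0),
        _dist("subtalar_contact_deg", "normal", 0.0, 5.0),
        _dist("drop_height_m", "lognormal", 0.30, 0.05),
        _dist("contact_modulus_MPa_per_m", "lognormal", 50.0, 5.0),
        _dist("contact_dissipation_s_per_m", "lognormal", 5.0, 1.0),
    ]


def _preset(study_id, incline, brace, coact, reflex) -> StudyDesign:
    inputs = [
        _dist("brace_scale_pct", "normal", *brace),
        _dist("coactivation_pct", "lognormal", *coact),
        _dist("reflex_gain", "lognormal", *reflex),
    ] + _common_inputs()
    return StudyDesign(study_id=str(study_id), incline_deg=incline,
                       inputs=tuple(inputs))


#: Built-in study presets: incline, brace flexibility scale, co-activation,
#: reflex gain (mean, sd); zeros are fixed.
STUDY_PRESETS: dict[int, StudyDesign] = {
    1: _preset(1, 0.0, (0.0, 0.0), (0.0, 0.0), (0.0, 0.0)),
    2: _preset(2, 30.0, (0.0, 0.0), (0.0, 0.0), (0.0, 0.0)),
    3: _preset(3, 30.0, (0.0, 0.0), (0.0, 0.0), (10.0, 1.0)),
    4: _preset(4, 30.0, (0.0, 0.0), (60.0, 5.0), (0.0, 0.0)),
    5: _preset(5, 30.0, (240.0, 6.0), (0.0, 0.0), (0.0, 0.0)),
    6: _preset(6, 30.0, (150.0, 6.0), (20.0, 5.0), (5.0, 1.0)),
}


def load_study(study: int | str | Path) -> StudyDesign:
    """Load a built-in preset (id 1-6) or a YAML/JSON study configuration.

    A configuration file carries ``study_id``, ``incline_deg``, and an
    ``inputs`` mapping of the ten canonical input names to
    ``{family, mean, sd}`` records.
    """
    if isinstance(study, int) or (isinstance(study, str) and study.isdigit()):
        sid = int(study)
        if sid not in STUDY_PRESETS:
            raise StudyConfigurationError(
                f"unknown study id {sid}; built-in presets are 1-6")
        return STUDY_PRESETS[sid]
    path = Path(study)
    if not path.exists():
        raise StudyConfigurationError(f"no such study or config: {study!r}")
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, Mapping):
        raise StudyConfigurationError(f"{path}: config must be a mapping")
    problems = []
    incline = raw.get("incline_deg")
    if not isinstance(incline, (int, float)) or not math.isfinite(incline):
        problems.append("incline_deg: missing or non-numeric")
    specs = raw.get("inputs")
    dists = []
    if not isinstance(specs, Mapping):
        problems.append("inputs: missing or not a mapping")
    else:
        for name in INPUT_NAMES:
            if name not in specs:
                problems.append(f"inputs.{name}: missing")
                continue
            spec = specs[name]
            try:
                if isinstance(spec, (int, float)):
                    dists.append(_dist(name, "fixed", float(spec)))
                else:
                    dists.append(_dist(name, spec.get("family", "normal"),
                                       float(spec["mean"]),
                                       float(spec.get("sd", 0.0))))
            except (KeyError, TypeError, ValueError) as exc:
                problems.append(f"inputs.{name}: {exc}")
        for name in specs:
            if name not in INPUT_NAMES:
                problems.append(f"inputs.{name}: unknown input")
    if problems:
        raise StudyConfigurationError(
            f"{path}: invalid study configuration: " + "; ".join(problems))
    return StudyDesign(study_id=str(raw.get("study_id", path.stem)),
                       incline_deg=float(incline), inputs=tuple(dists))


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

DEFAULT_RESPONSE = "peak_subtalar_supination_deg"


def make_response_model(design: StudyDesign,
                        response_field: str = DEFAULT_RESPONSE,
                        params: ModelParameters = DEFAULT_PARAMETERS,
                        axis_set: AxisSet | None = None,
                        outcome_log: list | None = None):
    """Wrap the landing simulation as a scalar-response model for the
    probabilistic engine.

    The callable takes a record of the ten input names and returns the
    selected :class:`PeakOutcomes` field.  When ``outcome_log`` is given,
    the full outcome record of every evaluation is appended to it.
    """
    axes = axis_set if axis_set is not None else AxisSet()

    def model(record: Mapping[str, float]) -> float:
        inputs = SimulationInputs.from_record(record, design.incline_deg)
        traj = simulate_drop_landing(inputs, params, axes)
        outcomes = extract_peak_outcomes(traj, axes)
        if outcome_log is not None:
            outcome_log.append(outcomes)
        return outcomes.scalar(response_field)

    return model


@dataclass
class StudyReport:
    """Results of one study run, with enough raw data to recompute every
    summary."""

    design: StudyDesign
    method: str
    response_field: str
    seed: int
    result: MCResult | AMVResult
    outcomes: pd.DataFrame = None       # one row per model evaluation
    outcome_summary: pd.DataFrame = None  # mean/sd per outcome field
    sensitivities: pd.DataFrame = None   # pearson r + strength band (MC)

    def summary(self) -> dict:
        s = {
            "study_id": self.design.study_id,
            "incline_deg": self.design.incline_deg,
            "method": self.method,
            "response_field": self.response_field,
            "seed": self.seed,
        }
        s.update(self.result.summary())
        return s


def _summarise_outcomes(outcomes: pd.DataFrame) -> pd.DataFrame:
    return pd.DataFrame({"mean": outcomes.mean(axis=0),
                         "sd": outcomes.std(axis=0, ddof=1)})


def run_study(design: StudyDesign | int, method: str = "mc",
              n_trials: int = 1000, seed: int = DEFAULT_SEED,
              response_field: str = DEFAULT_RESPONSE,
              levels: Sequence[float] = (5.0, 50.0, 95.0),
              params: ModelParameters = DEFAULT_PARAMETERS,
              axis_set: AxisSet | None = None) -> StudyReport:
    """Run one probabilistic study with the Monte Carlo or AMV method."""
    if not isinstance(design, StudyDesign):
        design = load_study(design)
    if method not in ("mc", "amv"):
        raise ValueError(f"method must be 'mc' or 'amv', got {method!r}")
    log: list[PeakOutcomes] = []
    model = make_response_model(design, response_field, params, axis_set, log)
    try:
        if method == "mc":
            result = run_monte_carlo(model, design.inputs, n_trials, seed,
                                     levels=levels)
        else:
            result = amv_analyze(model, design.inputs, levels=levels)
    except Exception as exc:
        raise type(exc)(f"study {design.study_id} ({method}): {exc}") from exc
    outcomes = pd.DataFrame([o.to_dict() for o in log])
    report = StudyReport(design=design, method=method,
                         response_field=response_field, seed=seed,
                         result=result, outcomes=outcomes)
    if method == "mc":
        ok = np.isfinite(
            np.array([o.scalar(response_field) for o in log]))
        outcomes = outcomes[ok].reset_index(drop=True)
        report.outcomes = outcomes
        report.outcome_summary = _summarise_outcomes(outcomes)
        variable = [d.name for d in design.inputs if d.is_variable]
        r = result.correlations.loc[variable]
        report.sensitivities = pd.DataFrame({
            "pearson_r": r,
            "strength": [correlation_strength(v) for v in r],
        })
    return report


# ---------------------------------------------------------------------------
# Report I/O
# ---------------------------------------------------------------------------

_FLOAT_FMT = "%.17g"


def write_report(report: StudyReport, out_dir) -> Path:
    """Write summary.json plus raw CSV tables; numeric content round-trips
    bit-exactly through :func:`read_report`."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {
        "design": report.design.to_dict(),
        "method": report.method,
        "response_field": report.response_field,
        "seed": report.seed,
        "summary": report.summary(),
    }
    if report.method == "amv":
        res: AMVResult = report.result
        meta["amv"] = {
            "levels_pct": list(res.levels_pct),
            "variable_names": list(res.variable_names),
            "mean_response": res.mean_response,
            "gradient_u": [float(g) for g in res.gradient_u],
            "alpha": [float(a) for a in res.alpha],
            "mv_estimates": [float(v) for v in res.mv_estimates],
            "amv_estimates": [float(v) for v in res.amv_estimates],
            "mpp_u": [[float(v) for v in row] for row in res.mpp_u],
            "evaluation_count": res.evaluation_count,
        }
        res.mpp_x.to_csv(out / "mpp_points.csv", index=False,
                         float_format=_FLOAT_FMT)
    else:
        res: MCResult = report.result
        res.samples.to_csv(out / "samples.csv", index=False,
                           float_format=_FLOAT_FMT)
        pd.DataFrame({"response": res.responses}).to_csv(
            out / "responses.csv", index=False, float_format=_FLOAT_FMT)
        report.sensitivities.to_csv(out / "sensitivities.csv",
                                    index_label="input",
                                    float_format=_FLOAT_FMT)
    if report.outcomes is not None and len(report.outcomes):
        report.outcomes.to_csv(out / "outcomes.csv", index=False,
                               float_format=_FLOAT_FMT)
    with open(out / "summary.json", "w") as fh:
        json.dump(meta, fh, indent=2)
    return out


def read_report(in_dir) -> StudyReport:
    """Reconstruct a report written by :func:`write_report`."""
    src = Path(in_dir)
    with open(src / "summary.json") as fh:
        meta = json.load(fh)
    d = meta["design"]
    design = StudyDesign(
        study_id=d["study_id"], incline_deg=d["incline_deg"],
        inputs=tuple(InputDistribution(name, rec["family"], rec["mean"],
                                       rec["sd"])
                     for name, rec in d["inputs"].items()))
    method = meta["method"]
    outcomes = None
    if (src / "outcomes.csv").exists():
        outcomes = pd.read_csv(src / "outcomes.csv",
                               float_precision="round_trip").astype(float)
    if method == "amv":
        a = meta["amv"]
        result = AMVResult(
            mean_response=a["mean_response"],
            gradient_u=np.array(a["gradient_u"]),
            alpha=np.array(a["alpha"]),
            variable_names=tuple(a["variable_names"]),
            levels_pct=tuple(a["levels_pct"]),
            mpp_u=np.array(a["mpp_u"]),
            mpp_x=pd.read_csv(src / "mpp_points.csv",
                              float_precision="round_trip").astype(float),
            mv_estimates=np.array(a["mv_estimates"]),
            amv_estimates=np.array(a["amv_estimates"]),
            evaluation_count=a["evaluation_count"],
        )
        report = StudyReport(design=design, method=method,
                             response_field=meta["response_field"],
                             seed=meta["seed"], result=result,
                             outcomes=outcomes)
    else:
        samples = pd.read_csv(src / "samples.csv",
                              float_precision="round_trip").astype(float)
        responses = pd.read_csv(src / "responses.csv",
                                float_precision="round_trip")[
            "response"].to_numpy()
        sens = pd.read_csv(src / "sensitivities.csv", index_col="input",
                           float_precision="round_trip")
        summ = meta["summary"]
        levels = tuple(float(k[1:]) for k in summ["percentiles"])
        result = MCResult(
            seed=meta["seed"], n_trials=summ["n_trials"],
            samples=samples, responses=responses,
            failed_trials=summ["failed_trials"],
            percentile_levels=levels,
            percentile_values=np.array(
                [summ["percentiles"][f"p{int(l)}"] for l in levels]),
            correlations=sens["pearson_r"],
        )
        report = StudyReport(design=design, method=method,
                             response_field=meta["response_field"],
                             seed=meta["seed"], result=result,
                             outcomes=outcomes,
                             sensitivities=sens)
        if outcomes is not None:
            report.outcome_summary = _summarise_outcomes(outcomes)
    return report


def audit_report(report: StudyReport) -> bool:
    """Check that every stored summary is recomputable from the raw
    per-trial records; raises AssertionError on mismatch."""
    if report.method != "mc":
        return True
    res: MCResult = report.result
    from .probabilistic import percentiles as _pct
    recomputed = _pct(res.responses, res.percentile_levels)
    assert np.allclose(recomputed, res.percentile_values, rtol=0, atol=1e-12)
    corr = pearson_sensitivities(res.samples, res.responses)
    stored = res.correlations
    pd.testing.assert_series_equal(corr.loc[stored.index],
                                   stored.rename("pearson_r"),
                                   check_names=False, atol=1e-12, rtol=0)
    if report.outcomes is not None and report.outcome_summary is not None:
        fresh = _summarise_outcomes(report.outcomes)
        pd.testing.assert_frame_equal(fresh, report.outcome_summary,
                                      atol=1e-12, rtol=0)
    return True
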