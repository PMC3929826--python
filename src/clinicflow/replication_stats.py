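"""Replication runs, decomposed-wait aggregation, weighted scoring,
percent reductions, scenario ranking, and calibration of the free
mix/routing parameters."""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .clinic_model import ClinicConfig, PHYSICIAN_STATIONS, StationId
from .des_engine import simulate
from .scenarios import Scenario, apply_scenario, get_scenario

__all__ = [
    "ReplicationSummary",
    "run_replications",
    "weighted_mean",
    "percent_reduction",
    "rank_scenarios",
    "calibrate",
    "CalibrationResult",
    "decomposed_table",
    "weighted_table",
]


@dataclass
class ReplicationSummary:
    """Aggregate of ``n_reps`` simulated clinic days for one scenario."""

    scenario_id: int
    n_reps: int
    #: reps x stations matrix of per-replication mean waits (NaN when a
    #: station saw no patient in that replication)
    station_rep_means: pd.DataFrame
    #: physician station -> (mean_before, mean_after, mean_total), minutes
    decomposition: dict[StationId, tuple[float, float, float]]
    weighted_mean: float
    config: ClinicConfig = field(repr=False, default=None)

    @property
    def totals(self) -> dict[StationId, float]:
        return {sid: d[2] for sid, d in self.decomposition.items()}

    def station_mean(self, station_id: StationId | str) -> float:
        return float(np.nanmean(self.station_rep_means[StationId(station_id).value]))


def _rep_seeds(seed: int, n_reps: int) -> np.ndarray:
    # Scenario-independent replication seeds: paired comparisons across
    # scenarios reuse identical patient streams (common random numbers).
    return np.random.SeedSequence(seed).generate_state(n_reps)


def run_replications(
    config: ClinicConfig,
    scenario: Scenario | int | None = None,
    n_reps: int | None = None,
    seed: int = 0,
) -> ReplicationSummary:
    """Average per-replication waits over seeded independent clinic days.

    ``n_reps`` defaults to the config's ``n_replications`` (1000).
    """
    if isinstance(scenario, int):
        scenario = get_scenario(scenario)
    if scenario is not None:
        config = apply_scenario(config, scenario)
        scenario_id = scenario.id
    else:
        scenario_id = 0
    if n_reps is None:
        n_reps = config.n_replications
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")

    station_cols = [sid.value for sid in config.stations]
    rep_rows = np.full((n_reps, len(station_cols)), np.nan)
    phys = [sid for sid in PHYSICIAN_STATIONS if sid in config.stations]
    decomp = {sid: np.full((n_reps, 3), np.nan) for sid in phys}

    for r, s in enumerate(_rep_seeds(seed, n_reps)):
        result = simulate(config, int(s))
        for j, sid in enumerate(config.stations):
            rep_rows[r, j] = result.station_waits(sid)
        for sid in phys:
            decomp[sid][r, :] = result.decomposition(sid)

    station_rep_means = pd.DataFrame(rep_rows, columns=station_cols)
    with np.errstate(invalid="ignore"):
        decomposition = {
            sid: tuple(float(v) for v in np.nanmean(decomp[sid], axis=0)) for sid in phys
        }
    totals = {sid: decomposition[sid][2] for sid in config.weights if sid in decomposition}
    wm = weighted_mean(totals, {k: v for k, v in config.weights.items() if k in totals}) if totals else math.nan
    return ReplicationSummary(
        scenario_id=scenario_id,
        n_reps=n_reps,
        station_rep_means=station_rep_means,
        decomposition=decomposition,
        weighted_mean=wm,
        config=config,
    )


def weighted_mean(totals: Mapping, weights: Mapping) -> float:
    """Weighted mean sum(w_i * t_i) / sum(w_i); keys must match exactly."""
    tk, wk = set(totals), set(weights)
    if tk != wk:
        raise KeyError(f"totals/weights key mismatch: {sorted(map(str, tk ^ wk))}")
    if not totals:
        raise ValueError("weighted_mean of empty mapping")
    for k, w in weights.items():
        if w <= 0:
            raise ValueError(f"weight for {k} must be > 0, got {w}")
    num = sum(weights[k] * totals[k] for k in totals)
    den = sum(weights.values())
    return float(num / den)


def percent_reduction(base: float, alternative: float) -> float:
    """100 * (base - alternative) / base."""
    if base <= 0:
        raise ValueError(f"base must be > 0, got {base}")
    return 100.0 * (base - alternative) / base


def rank_scenarios(summaries: Iterable[ReplicationSummary]) -> list[ReplicationSummary]:
    """Ascending by weighted mean; ties keep scenario-id order."""
    items = list(summaries)
    if not items:
        raise ValueError("rank_scenarios needs at least one summary")
    return sorted(items, key=lambda s: (s.weighted_mean, s.scenario_id))


# ---- report tables -----------------------------------------------------

_COMPONENT_LABELS = {0: "before_attendance", 1: "after_attendance", 2: "total"}


def _column_name(scenario_id: int) -> str:
    return "base_case" if scenario_id == 0 else f"scenario_{scenario_id}"


def decomposed_table(summaries: Sequence[ReplicationSummary]) -> pd.DataFrame:
    """Rows = (server, wait component), columns = scenarios; minutes, 2 dp."""
    cols = {}
    for s in summaries:
        col = {}
        for sid, (b, a, t) in s.decomposition.items():
            col[(sid.value, "before_attendance")] = b
            col[(sid.value, "after_attendance")] = a
            col[(sid.value, "total")] = t
        cols[_column_name(s.scenario_id)] = col
    frame = pd.DataFrame(cols).round(2)
    frame.index.names = ["server", "component"]
    return frame


def weighted_table(summaries: Sequence[ReplicationSummary]) -> pd.DataFrame:
    """Rows = per-server totals plus the weighted mean, columns = scenarios."""
    cols = {}
    for s in summaries:
        col = {f"total_{sid.value}": t for sid, t in s.totals.items()}
        col["weighted_mean"] = s.weighted_mean
        cols[_column_name(s.scenario_id)] = col
    return pd.DataFrame(cols).round(2)


# ---- calibration -------------------------------------------------------

FREE_PARAMS = ("mix", "p_consult_senior", "p_paraclinic", "admission_duration")


@dataclass
class CalibrationResult:
    config: ClinicConfig
    error: float
    n_evals: int
    history: list[float] = field(default_factory=list)


def _objective(config: ClinicConfig, observed: pd.DataFrame, n_reps: int, seed: int) -> float:
    summary = run_replications(config, n_reps=n_reps, seed=seed)
    err = 0.0
    for _, row in observed.iterrows():
        sid = StationId(row["station"])
        if sid not in config.stations:
            continue
        sim = summary.station_mean(sid)
        obs = float(row["mean"])
        if obs > 0:
            err += ((sim - obs) / obs) ** 2
    return err


def _apply_vector(config: ClinicConfig, free_params: Sequence[str], vec: np.ndarray) -> ClinicConfig:
    new = config.copy()
    i = 0
    class_ids = list(new.classes)
    if "mix" in free_params:
        k = len(class_ids)
        raw = np.clip(vec[i : i + k], 1e-3, None)
        raw = raw / raw.sum()
        for cid, p in zip(class_ids, raw):
            new.classes[cid].mix_probability = float(p)
        i += k
    if "p_consult_senior" in free_params:
        p = float(np.clip(vec[i], 0.0, 1.0))
        for cid in class_ids:
            new.classes[cid].p_consult_senior = p
        i += 1
    if "p_paraclinic" in free_params:
        p = float(np.clip(vec[i], 0.0, 1.0))
        for cid in class_ids:
            new.classes[cid].p_paraclinic = p
        i += 1
    if "admission_duration" in free_params:
        new.admission_duration = float(np.clip(vec[i], 60.0, 480.0))
        i += 1
    new.validate()
    return new


def _extract_vector(config: ClinicConfig, free_params: Sequence[str]) -> np.ndarray:
    vec: list[float] = []
    classes = list(config.classes.values())
    if "mix" in free_params:
        vec.extend(c.mix_probability for c in classes)
    if "p_consult_senior" in free_params:
        vec.append(classes[0].p_consult_senior)
    if "p_paraclinic" in free_params:
        vec.append(classes[0].p_paraclinic)
    if "admission_duration" in free_params:
        vec.append(config.admission_duration)
    return np.asarray(vec, dtype=float)


_PARAM_SCALES = {"mix": 0.08, "p_consult_senior": 0.06, "p_paraclinic": 0.06, "admission_duration": 25.0}


def calibrate(
    config: ClinicConfig,
    observed: pd.DataFrame,
    free_params: Sequence[str] = FREE_PARAMS,
    budget: int = 100,
    seed: int = 0,
    n_reps: int = 100,
) -> CalibrationResult:
    """Seeded random search + local refinement over the free parameters.

    Minimizes the sum of squared relative errors between simulated and
    observed per-station mean waits.  Evaluations reuse one replication
    seed (common random numbers), so the objective is deterministic.
    ``budget`` counts candidate evaluations beyond the starting point.
    """
    if not free_params:
        raise ValueError("free_params must not be empty")
    unknown = set(free_params) - set(FREE_PARAMS)
    if unknown:
        raise ValueError(f"unknown free_params {sorted(unknown)}")

    rng = np.random.default_rng(seed)
    best_vec = _extract_vector(config, free_params)
    best_cfg = _apply_vector(config, free_params, best_vec)
    best_err = _objective(best_cfg, observed, n_reps, seed)
    history = [best_err]

    scales = []
    k = len(list(config.classes))
    if "mix" in free_params:
        scales += [_PARAM_SCALES["mix"]] * k
    for name in ("p_consult_senior", "p_paraclinic", "admission_duration"):
        if name in free_params:
            scales.append(_PARAM_SCALES[name])
    scales = np.asarray(scales)

    for it in range(budget):
        # anneal: wide exploration first, local refinement later
        frac = it / max(budget, 1)
        width = 2.0 if frac < 0.4 else (1.0 if frac < 0.7 else 0.35)
        cand = best_vec + rng.normal(0.0, scales * width)
        cfg = _apply_vector(config, free_params, cand)
        err = _objective(cfg, observed, n_reps, seed)
        history.append(err)
        if err < best_err:
            best_err, best_cfg = err, cfg
            best_vec = _extract_vector(cfg, free_params)
    return CalibrationResult(config=best_cfg, error=best_err, n_evals=budget + 1, history=history)
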