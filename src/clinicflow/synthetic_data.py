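"""Synthetic patient event logs with the statistical structure of the
observed clinic checklist, produced by the simulation engine itself so
queues, schedules and routing are internally consistent."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .clinic_model import ClinicConfig, default_base_case
from .des_engine import simulate

__all__ = [
    "GeneratorParams",
    "generate_patient_log",
    "generate_observed_summary",
    "perturb_service_times",
    "check_log",
]


@dataclass
class GeneratorParams:
    """Parameters of the synthetic checklist generator.

    ``config`` carries the interarrival/service distributions, class mix
    and routing probabilities; defaults equal the base-case model.  The
    admission window is ignored: exactly ``n_patients`` arrivals are
    generated (the observed checklist size, 375, spans several clinic
    days' worth of patients).
    """

    n_patients: int = 375
    seed: int = 0
    config: ClinicConfig = field(default_factory=default_base_case)

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ValueError("n_patients must be >= 0")


_LOG_COLUMNS = ["patient_id", "class", "station", "queue_join", "service_start", "service_end"]


def generate_patient_log(params: GeneratorParams) -> pd.DataFrame:
    """One row per (patient, station) visit; deterministic given the seed."""
    if params.n_patients == 0:
        return pd.DataFrame(columns=_LOG_COLUMNS)
    result = simulate(params.config, seed=params.seed, n_patients=params.n_patients)
    return result.to_frame()


def generate_observed_summary(log: pd.DataFrame) -> pd.DataFrame:
    """Per-station mean/sd/n of queue waits, in the schema that
    :func:`clinicflow.estimation.validate` consumes."""
    if len(log) == 0:
        raise ValueError("cannot summarize an empty log")
    waits = (log["service_start"] - log["queue_join"]).rename("wait")
    frame = pd.concat([log["station"], waits], axis=1).dropna()
    grouped = frame.groupby("station")["wait"]
    out = pd.DataFrame(
        {
            "station": grouped.mean().index,
            "mean": grouped.mean().to_numpy(),
            "sd": grouped.std(ddof=1).fillna(0.0).to_numpy(),
            "n": grouped.count().to_numpy(),
        }
    ).reset_index(drop=True)
    return out


def perturb_service_times(log: pd.DataFrame, noise_sd: float, seed: int = 0) -> pd.DataFrame:
    """Multiplicative lognormal noise on service durations.

    Creates "observed" data that the generating config cannot fit, to
    exercise the rejection path of validation.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    out = log.copy()
    dur = out["service_end"] - out["service_start"]
    factor = rng.lognormal(0.0, noise_sd, size=len(out))
    out["service_end"] = out["service_start"] + dur * factor
    return out


def check_log(log: pd.DataFrame, tol: float = 1e-9) -> None:
    """Independent structural check of an event log.

    Asserts causality (queue_join <= service_start <= service_end) and
    FIFO order within each station.  Raises AssertionError on violation.
    """
    served = log.dropna(subset=["service_start", "service_end"])
    assert (served["service_start"] >= served["queue_join"] - tol).all(), "service before queue join"
    assert (served["service_end"] >= served["service_start"] - tol).all(), "negative service time"
    for station, grp in served.groupby("station"):
        grp = grp.sort_values(["queue_join", "patient_id"], kind="stable")
        starts = grp["service_start"].to_numpy()
        assert (np.diff(starts) >= -tol).all(), f"FIFO violated at {station}"
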