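import numpy as np
import pytest

from clinicflow.clinic_model import (
    ClassId,
    ClinicConfig,
    DistributionSpec,
    Family,
    PatientClass,
    ServerSchedule,
    Station,
    StationId,
    default_base_case,
    load_base_case,
)


@pytest.fixture(scope="session")
def base_config() -> ClinicConfig:
    """Bundled (calibrated) base-case configuration."""
    return load_base_case()


@pytest.fixture(scope="session")
def default_config() -> ClinicConfig:
    """The uncalibrated base case with documented default mix/routing."""
    return default_base_case()


def single_station_config(
    interarrival: DistributionSpec,
    service: DistributionSpec,
    n_servers: int = 1,
    admission_duration: float = 1e9,
) -> ClinicConfig:
    """A stationary single-station (always open) queue, e.g. M/M/c."""
    station = Station(
        StationId.REGISTRATION,
        ServerSchedule(start_time=0.0, duration=1e12, n_servers=n_servers),
        service,
    )
    cls = PatientClass(ClassId.NEW, 1.0, first_physician=None)
    return ClinicConfig(
        stations={StationId.REGISTRATION: station},
        classes={ClassId.NEW: cls},
        interarrival=interarrival,
        admission_start=0.0,
        admission_duration=admission_duration,
        weights={},
        n_replications=10,
    )


def mmc_config(arrival_mean: float, service_mean: float, c: int) -> ClinicConfig:
    return single_station_config(
        DistributionSpec(Family.EXPONENTIAL, mean=arrival_mean),
        DistributionSpec(Family.EXPONENTIAL, mean=service_mean),
        n_servers=c,
    )


def erlang_c_wait(lam: float, mu: float, c: int) -> float:
    """Closed-form M/M/c mean queue wait (Erlang C); independent oracle."""
    import math

    a = lam / mu
    rho = a / c
    assert rho < 1
    last = a**c / (math.factorial(c) * (1 - rho))
    denom = sum(a**k / math.factorial(k) for k in range(c)) + last
    prob_wait = last / denom
    return prob_wait / (c * mu - lam)


def batch_se(waits: np.ndarray, n_batches: int = 100) -> float:
    """Monte-Carlo standard error of the mean via batch means (accounts
    for serial correlation between successive patients)."""
    n = len(waits) // n_batches * n_batches
    batches = waits[:n].reshape(n_batches, -1).mean(axis=1)
    return float(batches.std(ddof=1) / np.sqrt(n_batches))
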