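"""Domain types and configuration I/O for the clinic network.

Every numeric parameter of the modeled clinic lives here, either in the
dataclasses below or in the bundled ``configs/base_case.yaml``.  Times are
continuous minutes since midnight; durations are minutes.
"""

from __future__ import annotations

import copy
import enum
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml
from scipy import stats


class StationId(str, enum.Enum):
    REGISTRATION = "registration"
    CASH = "cash"
    NOVICE_RESIDENT = "novice_resident"
    EXPERIENCED_RESIDENT = "experienced_resident"
    SENIOR_STAFF = "senior_staff"
    PARACLINIC = "paraclinic"

    def __str__(self) -> str:  # yaml-friendly
        return self.value


#: Physician stations whose waits enter the weighted score.
PHYSICIAN_STATIONS = (
    StationId.NOVICE_RESIDENT,
    StationId.EXPERIENCED_RESIDENT,
    StationId.SENIOR_STAFF,
)


class ClassId(str, enum.Enum):
    NEW = "new"
    FOLLOWUP_OUTPATIENT = "followup_outpatient"
    FOLLOWUP_PREV_INPATIENT = "followup_prev_inpatient"

    def __str__(self) -> str:
        return self.value


class Family(str, enum.Enum):
    TRUNCATED_NORMAL = "truncated_normal"
    EXPONENTIAL = "exponential"
    LOGNORMAL = "lognormal"
    CONSTANT = "constant"

    def __str__(self) -> str:
        return self.value


class ConfigError(ValueError):
    """Raised when a configuration violates an invariant; names the field."""


@dataclass(frozen=True)
class DistributionSpec:
    """Family plus first two moments of an arrival or service process.

    ``mean``/``sd`` are the *parameters on the original (untruncated) scale*
    for ``truncated_normal`` and the target moments for ``lognormal`` (which
    is moment-matched).  Samples are always >= ``lower_bound``.
    """

    family: Family
    mean: float
    sd: float = 0.0
    lower_bound: float = 0.0

    def __post_init__(self) -> None:
        fam = Family(self.family)
        object.__setattr__(self, "family", fam)
        if fam is not Family.CONSTANT and self.mean <= 0:
            raise ConfigError(f"DistributionSpec.mean must be > 0, got {self.mean}")
        if self.sd < 0:
            raise ConfigError(f"DistributionSpec.sd must be >= 0, got {self.sd}")

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        """Draw ``size`` values, deterministic given the generator state."""
        if size == 0:
            return np.empty(0)
        if self.family is Family.CONSTANT:
            out = np.full(size, float(self.mean))
        elif self.family is Family.EXPONENTIAL:
            out = rng.exponential(self.mean, size)
        elif self.family is Family.TRUNCATED_NORMAL:
            if self.sd == 0:
                out = np.full(size, max(self.mean, self.lower_bound))
            else:
                a = (self.lower_bound - self.mean) / self.sd
                out = stats.truncnorm.rvs(
                    a, np.inf, loc=self.mean, scale=self.sd, size=size, random_state=rng
                )
        elif self.family is Family.LOGNORMAL:
            if self.sd == 0:
                out = np.full(size, float(self.mean))
            else:
                sigma2 = math.log1p((self.sd / self.mean) ** 2)
                mu = math.log(self.mean) - sigma2 / 2.0
                out = rng.lognormal(mu, math.sqrt(sigma2), size)
        else:  # pragma: no cover
            raise ConfigError(f"unknown family {self.family}")
        out = np.maximum(out, self.lower_bound)
        if not np.all(np.isfinite(out)):
            raise ConfigError(f"non-finite sample from {self.family} distribution")
        return out

    @property
    def truncated_mean(self) -> float:
        """Mean of the distribution actually sampled (after truncation)."""
        if self.family is Family.TRUNCATED_NORMAL and self.sd > 0:
            a = (self.lower_bound - self.mean) / self.sd
            return float(stats.truncnorm.mean(a, np.inf, loc=self.mean, scale=self.sd))
        return float(self.mean)

    @property
    def truncated_sd(self) -> float:
        if self.family is Family.TRUNCATED_NORMAL and self.sd > 0:
            a = (self.lower_bound - self.mean) / self.sd
            return float(stats.truncnorm.std(a, np.inf, loc=self.mean, scale=self.sd))
        return float(self.sd)


@dataclass
class ServerSchedule:
    start_time: float  # minutes since midnight
    duration: float
    n_servers: int = 1

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ConfigError(f"ServerSchedule.duration must be > 0, got {self.duration}")
        if self.n_servers < 1:
            raise ConfigError(f"ServerSchedule.n_servers must be >= 1, got {self.n_servers}")

    @property
    def end(self) -> float:
        return self.start_time + self.duration


@dataclass
class Station:
    id: StationId
    schedule: ServerSchedule
    service: DistributionSpec
    discipline: str = "fifo"

    def __post_init__(self) -> None:
        self.id = StationId(self.id)
        if self.discipline != "fifo":
            raise ConfigError(f"Station.discipline must be 'fifo', got {self.discipline!r}")


@dataclass
class PatientClass:
    id: ClassId
    mix_probability: float
    first_physician: StationId | None
    p_consult_senior: float = 0.0
    p_paraclinic: float = 0.0

    def __post_init__(self) -> None:
        self.id = ClassId(self.id)
        if self.first_physician is not None:
            self.first_physician = StationId(self.first_physician)
        for name in ("mix_probability", "p_consult_senior", "p_paraclinic"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"PatientClass.{name} must be in [0, 1], got {v}")


@dataclass
class ClinicConfig:
    """Full parameterization of the clinic network.

    ``weights`` maps physician stations to their score weight; stations
    absent from the map do not enter the weighted mean.
    """

    stations: dict[StationId, Station]
    classes: dict[ClassId, PatientClass]
    interarrival: DistributionSpec
    admission_start: float = 450.0
    admission_duration: float = 240.0
    weights: dict[StationId, float] = field(
        default_factory=lambda: {
            StationId.NOVICE_RESIDENT: 2.0,
            StationId.EXPERIENCED_RESIDENT: 2.0,
            StationId.SENIOR_STAFF: 1.0,
        }
    )
    n_replications: int = 1000
    overtime: bool = True
    paraclinic_return: bool = False

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        ids = [StationId(s.id) for s in self.stations.values()]
        if len(set(ids)) != len(ids):
            raise ConfigError("stations: each station id must appear exactly once")
        for key, st in self.stations.items():
            if StationId(key) != st.id:
                raise ConfigError(f"stations: key {key} does not match station id {st.id}")
        mix = sum(c.mix_probability for c in self.classes.values())
        if self.classes and abs(mix - 1.0) > 1e-9:
            raise ConfigError(
                f"classes: mix_probability values must sum to 1, got {mix:.6g}"
            )
        for c in self.classes.values():
            if c.first_physician is not None and c.first_physician not in self.stations:
                raise ConfigError(
                    f"classes.{c.id}: first_physician {c.first_physician} not in stations"
                )
        if self.admission_duration < 0:
            raise ConfigError("admission_duration must be >= 0")
        for sid, w in self.weights.items():
            if StationId(sid) not in self.stations:
                raise ConfigError(f"weights: unknown station {sid}")
            if w <= 0:
                raise ConfigError(f"weights[{sid}] must be > 0, got {w}")
        if self.n_replications < 1:
            raise ConfigError("n_replications must be >= 1")

    def station(self, sid: StationId | str) -> Station:
        return self.stations[StationId(sid)]

    def copy(self) -> "ClinicConfig":
        return copy.deepcopy(self)

    # ---- serialization -------------------------------------------------

    def to_dict(self) -> dict:
        def dist(d: DistributionSpec) -> dict:
            return {
                "family": str(d.family),
                "mean": float(d.mean),
                "sd": float(d.sd),
                "lower_bound": float(d.lower_bound),
            }

        return {
            "interarrival": dist(self.interarrival),
            "admission_start": float(self.admission_start),
            "admission_duration": float(self.admission_duration),
            "n_replications": int(self.n_replications),
            "overtime": bool(self.overtime),
            "paraclinic_return": bool(self.paraclinic_return),
            "weights": {str(k): float(v) for k, v in self.weights.items()},
            "stations": {
                str(sid): {
                    "schedule": {
                        "start_time": float(st.schedule.start_time),
                        "duration": float(st.schedule.duration),
                        "n_servers": int(st.schedule.n_servers),
                    },
                    "service": dist(st.service),
                    "discipline": st.discipline,
                }
                for sid, st in self.stations.items()
            },
            "classes": {
                str(cid): {
                    "mix_probability": float(c.mix_probability),
                    "first_physician": None
                    if c.first_physician is None
                    else str(c.first_physician),
                    "p_consult_senior": float(c.p_consult_senior),
                    "p_paraclinic": float(c.p_paraclinic),
                }
                for cid, c in self.classes.items()
            },
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "ClinicConfig":
        data = dict(data)
        known = {
            "interarrival",
            "admission_start",
            "admission_duration",
            "n_replications",
            "overtime",
            "paraclinic_return",
            "weights",
            "stations",
            "classes",
        }
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")

        def dist(d: Mapping, where: str) -> DistributionSpec:
            extra = set(d) - {"family", "mean", "sd", "lower_bound"}
            if extra:
                raise ConfigError(f"{where}: unknown keys {sorted(extra)}")
            return DistributionSpec(
                family=Family(d["family"]),
                mean=float(d["mean"]),
                sd=float(d.get("sd", 0.0)),
                lower_bound=float(d.get("lower_bound", 0.0)),
            )

        stations: dict[StationId, Station] = {}
        for sid, sd_ in dict(data.get("stations", {})).items():
            extra = set(sd_) - {"schedule", "service", "discipline"}
            if extra:
                raise ConfigError(f"stations.{sid}: unknown keys {sorted(extra)}")
            sched = sd_["schedule"]
            extra = set(sched) - {"start_time", "duration", "n_servers"}
            if extra:
                raise ConfigError(f"stations.{sid}.schedule: unknown keys {sorted(extra)}")
            stations[StationId(sid)] = Station(
                id=StationId(sid),
                schedule=ServerSchedule(
                    start_time=float(sched["start_time"]),
                    duration=float(sched["duration"]),
                    n_servers=int(sched.get("n_servers", 1)),
                ),
                service=dist(sd_["service"], f"stations.{sid}.service"),
                discipline=sd_.get("discipline", "fifo"),
            )
        classes: dict[ClassId, PatientClass] = {}
        for cid, cd in dict(data.get("classes", {})).items():
            extra = set(cd) - {
                "mix_probability",
                "first_physician",
                "p_consult_senior",
                "p_paraclinic",
            }
            if extra:
                raise ConfigError(f"classes.{cid}: unknown keys {sorted(extra)}")
            fp = cd.get("first_physician")
            classes[ClassId(cid)] = PatientClass(
                id=ClassId(cid),
                mix_probability=float(cd["mix_probability"]),
                first_physician=None if fp is None else StationId(fp),
                p_consult_senior=float(cd.get("p_consult_senior", 0.0)),
                p_paraclinic=float(cd.get("p_paraclinic", 0.0)),
            )
        return cls(
            stations=stations,
            classes=classes,
            interarrival=dist(data["interarrival"], "interarrival"),
            admission_start=float(data.get("admission_start", 450.0)),
            admission_duration=float(data.get("admission_duration", 240.0)),
            weights={StationId(k): float(v) for k, v in data.get("weights", {}).items()},
            n_replications=int(data.get("n_replications", 1000)),
            overtime=bool(data.get("overtime", True)),
            paraclinic_return=bool(data.get("paraclinic_return", False)),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ClinicConfig):
            return NotImplemented
        return self.to_dict() == other.to_dict()


def save_config(config: ClinicConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))


def load_config(path: str | Path) -> ClinicConfig:
    """Load and validate a clinic configuration from a YAML (or JSON) file."""
    text = Path(path).read_text()
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"could not parse {path}: {exc}") from exc
    if not isinstance(data, Mapping):
        raise ConfigError(f"{path}: top level must be a mapping")
    return ClinicConfig.from_dict(data)


def packaged_config_path(name: str) -> Path:
    """Path to a bundled config such as ``base_case.yaml``."""
    return Path(resources.files("clinicflow").joinpath("configs", name))


def default_base_case() -> ClinicConfig:
    """The base-case clinic: current schedules, staffing and fitted processes.

    Interarrival gaps are normal(4.2, 5.8) truncated at zero.  Service-time
    families are not dictated by the source data beyond their first two
    moments; lognormal is used (non-negative, right-skewed) and is
    moment-matched to the observed mean/SD.  The patient-class mix and the
    routing probabilities were not observed directly: the values here are
    calibration targets (see ``replication_stats.calibrate``) and the
    bundled ``base_case.yaml`` carries the calibrated set.
    """
    ln = Family.LOGNORMAL
    stations = {
        StationId.REGISTRATION: Station(
            StationId.REGISTRATION,
            ServerSchedule(start_time=450.0, duration=480.0, n_servers=1),
            DistributionSpec(ln, mean=1.13, sd=0.44),
        ),
        StationId.CASH: Station(
            StationId.CASH,
            ServerSchedule(start_time=450.0, duration=480.0, n_servers=1),
            DistributionSpec(ln, mean=0.20, sd=0.3),
        ),
        StationId.NOVICE_RESIDENT: Station(
            StationId.NOVICE_RESIDENT,
            ServerSchedule(start_time=600.0, duration=200.0, n_servers=2),
            DistributionSpec(ln, mean=3.46, sd=2.06),
        ),
        StationId.EXPERIENCED_RESIDENT: Station(
            StationId.EXPERIENCED_RESIDENT,
            ServerSchedule(start_time=600.0, duration=200.0, n_servers=1),
            DistributionSpec(ln, mean=4.91, sd=0.93),
        ),
        StationId.SENIOR_STAFF: Station(
            StationId.SENIOR_STAFF,
            ServerSchedule(start_time=645.0, duration=100.0, n_servers=1),
            DistributionSpec(ln, mean=4.20, sd=0.93),
        ),
        # No service-time measurement exists for paraclinic services; this
        # default is an assumption, adjustable in config.
        StationId.PARACLINIC: Station(
            StationId.PARACLINIC,
            ServerSchedule(start_time=450.0, duration=480.0, n_servers=1),
            DistributionSpec(ln, mean=20.0, sd=10.0),
        ),
    }
    classes = {
        ClassId.NEW: PatientClass(
            ClassId.NEW, 0.4, StationId.EXPERIENCED_RESIDENT, 0.25, 0.3
        ),
        ClassId.FOLLOWUP_OUTPATIENT: PatientClass(
            ClassId.FOLLOWUP_OUTPATIENT, 0.3, StationId.EXPERIENCED_RESIDENT, 0.25, 0.3
        ),
        ClassId.FOLLOWUP_PREV_INPATIENT: PatientClass(
            ClassId.FOLLOWUP_PREV_INPATIENT, 0.3, StationId.NOVICE_RESIDENT, 0.25, 0.3
        ),
    }
    return ClinicConfig(
        stations=stations,
        classes=classes,
        interarrival=DistributionSpec(Family.TRUNCATED_NORMAL, mean=4.2, sd=5.8),
        admission_start=450.0,
        admission_duration=240.0,
        n_replications=1000,
    )


def load_base_case() -> ClinicConfig:
    """The bundled (calibrated) base-case configuration."""
    return load_config(packaged_config_path("base_case.yaml"))
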