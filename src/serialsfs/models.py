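"""Demographic model topologies for a bottlenecked, serially sampled population.

Seven single-population histories spanning the plausible range for an
exploited marine stock: constant size, single bottlenecks with instantaneous
or exponential recovery, ancestral growth with and without a subsequent
bottleneck, and a two-bottleneck history.  All sizes are in haploid units and
all times in generations before the most recent sampling event (backward
time).  Models 4, 6 and 7 include an ancestral exponential segment anchored
at a fixed deep horizon ``T_LGM`` (post-glacial recolonization), beyond which
the population sits at its deep ancestral size NANC.

Parameter names
---------------
NANC     deep ancestral size (models 4, 6, 7)
NPREBOT  size immediately before the bottleneck
NBOT     size during the bottleneck
NPOP08   size at the most recent sampling time
TLEN     bottleneck duration (generations)
TBOT     generations between bottleneck end and the most recent sampling
TCAR     generations before present at which the ancestral size change ends
Model 5 duplicates the bottleneck block (suffix 1 = recent, 2 = older) and
adds NINT, the size between the two bottlenecks.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "MODEL_REGISTRY",
    "T_LGM",
    "Epoch",
    "EpochTimeline",
    "ParameterVector",
    "SampleSpec",
    "build_timeline",
    "free_param_count",
    "growth_rate_between",
    "model6_reference",
    "flounder_sample_spec",
    "years_to_generations",
]

#: Deep time horizon (generations) anchoring ancestral exponential segments.
#: ~20,000 years at a 2-year generation: the end of the last glaciation.
T_LGM = 10_000.0

#: Free parameters of each model topology, in canonical order.
MODEL_REGISTRY: dict[int, tuple[str, ...]] = {
    1: ("NANC",),
    2: ("NPREBOT", "NBOT", "NPOP08", "TLEN", "TBOT"),
    3: ("NPREBOT", "NBOT", "NPOP08", "TLEN", "TBOT"),
    4: ("NANC", "NPREBOT", "NBOT", "NPOP08", "TLEN", "TBOT", "TCAR"),
    5: (
        "NPREBOT",
        "NBOT1",
        "NINT",
        "NBOT2",
        "NPOP08",
        "TLEN1",
        "TBOT1",
        "TLEN2",
        "TBOT2",
    ),
    6: ("NANC", "NPREBOT", "NBOT", "NPOP08", "TLEN", "TBOT", "TCAR"),
    7: ("NANC", "NPOP08", "TCAR"),
}

MODEL_NAMES = {
    1: "constant size",
    2: "bottleneck, instantaneous recovery",
    3: "bottleneck, exponential recovery",
    4: "ancestral growth, bottleneck, instantaneous recovery",
    5: "two bottlenecks, instantaneous changes",
    6: "ancestral growth, bottleneck, exponential recovery",
    7: "ancestral growth to carrying capacity, no bottleneck",
}

_SIZE_NAMES = frozenset(
    {"NANC", "NPREBOT", "NBOT", "NPOP08", "NINT", "NBOT1", "NBOT2"}
)


def growth_rate_between(n_start: float, n_end: float, duration: float) -> float:
    """Per-generation exponential rate taking ``n_start`` to ``n_end``.

    Returns ``ln(n_end / n_start) / duration``; positive when the population
    grows from start to end.
    """
    if n_start <= 0 or n_end <= 0:
        raise ValueError("population sizes must be positive")
    if duration <= 0:
        raise ValueError("duration must be positive")
    return math.log(n_end / n_start) / duration


def years_to_generations(
    year: float, reference_year: float, gen_time: float
) -> float:
    """Convert a calendar year to generations before ``reference_year``."""
    if gen_time <= 0:
        raise ValueError("generation time must be positive")
    if year > reference_year:
        raise ValueError("year must not be later than the reference year")
    return (reference_year - year) / gen_time


def free_param_count(
    model_id: int, registry: Mapping[int, tuple[str, ...]] | None = None
) -> int:
    """Number of free parameters of a model (the AIC ``k``).

    The default counts enumerate the canonical parameterizations above
    (M1=1, M2=5, M3=5, M4=7, M5=9, M6=7, M7=3); pass a custom ``registry``
    to override.
    """
    reg = MODEL_REGISTRY if registry is None else registry
    if model_id not in reg:
        raise ValueError(f"unknown model id {model_id!r}")
    return len(reg[model_id])


@dataclass(frozen=True)
class ParameterVector:
    """Named parameters of one model topology (haploid sizes, generations)."""

    model_id: int
    values: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.model_id not in MODEL_REGISTRY:
            raise ValueError(f"unknown model id {self.model_id!r}")
        expected = MODEL_REGISTRY[self.model_id]
        extra = set(self.values) - set(expected)
        missing = set(expected) - set(self.values)
        if extra:
            raise ValueError(
                f"model {self.model_id} does not use parameters {sorted(extra)}"
            )
        if missing:
            raise ValueError(
                f"model {self.model_id} is missing parameters {sorted(missing)}"
            )
        for name, v in self.values.items():
            if name in _SIZE_NAMES and v <= 0:
                raise ValueError(f"{name} must be positive, got {v}")
            if name.startswith("TLEN") and v <= 0:
                raise ValueError(f"{name} must be positive, got {v}")
            if name.startswith("TBOT") and v < 0:
                raise ValueError(f"{name} must be non-negative, got {v}")
            if name == "TCAR" and v <= 0:
                raise ValueError(f"TCAR must be positive, got {v}")
        if "TCAR" in self.values and "TBOT" in self.values:
            if self.values["TCAR"] <= self.values["TBOT"] + self.values["TLEN"]:
                raise ValueError("TCAR must exceed TBOT + TLEN")

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    # -- serialization --------------------------------------------------

    def to_json(self) -> str:
        return json.dumps({"model_id": self.model_id, **self.values})

    @classmethod
    def from_json(cls, text: str) -> "ParameterVector":
        d = json.loads(text)
        mid = int(d.pop("model_id"))
        return cls(mid, {k: float(v) for k, v in d.items()})

    def to_keyvalue(self) -> str:
        lines = [f"model_id={self.model_id}"]
        lines += [f"{k}={self.values[k]:g}" for k in MODEL_REGISTRY[self.model_id]]
        return "\n".join(lines) + "\n"

    @classmethod
    def from_keyvalue(cls, text: str) -> "ParameterVector":
        d: dict[str, float] = {}
        mid = None
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            k, _, v = line.partition("=")
            if k.strip() == "model_id":
                mid = int(float(v))
            else:
                d[k.strip()] = float(v)
        if mid is None:
            raise ValueError("model_id missing")
        return cls(mid, d)


@dataclass(frozen=True)
class Epoch:
    """One backward-time epoch with size ``N(t) = size_at_start·e^{r(t−start)}``."""

    start: float
    end: float  # math.inf for the terminal epoch
    size_at_start: float
    rate: float = 0.0

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError("epoch start must be non-negative")
        if self.end <= self.start:
            raise ValueError("epoch end must exceed start")
        if self.size_at_start <= 0:
            raise ValueError("size must be positive")
        if math.isinf(self.end) and self.rate > 0:
            # backward growth forever -> infinite deep size; disallow
            raise ValueError("terminal epoch cannot have positive backward rate")

    def size_at(self, t: float) -> float:
        if not (self.start <= t <= self.end):
            raise ValueError(f"time {t} outside epoch [{self.start}, {self.end}]")
        return self.size_at_start * math.exp(self.rate * (t - self.start))


class EpochTimeline:
    """Contiguous backward-time epochs covering [0, inf)."""

    def __init__(self, epochs: Iterable[Epoch]):
        eps = list(epochs)
        if not eps:
            raise ValueError("timeline needs at least one epoch")
        if eps[0].start != 0:
            raise ValueError("first epoch must start at 0")
        for a, b in zip(eps, eps[1:]):
            if b.start != a.end:
                raise ValueError("epochs must be contiguous")
        if not math.isinf(eps[-1].end):
            raise ValueError("last epoch must be unbounded")
        self.epochs = eps

    def __iter__(self):
        return iter(self.epochs)

    def __len__(self) -> int:
        return len(self.epochs)

    def size_at(self, t: float) -> float:
        """Population size at backward time ``t`` (right-continuous at jumps)."""
        for ep in self.epochs:
            if ep.start <= t < ep.end or (math.isinf(ep.end) and t >= ep.start):
                return ep.size_at(t)
        raise ValueError(f"time {t} not covered")

    def as_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(end_times, sizes_at_start, rates) for the simulation kernel."""
        end = np.array([ep.end for ep in self.epochs])
        n0 = np.array([ep.size_at_start for ep in self.epochs])
        r = np.array([ep.rate for ep in self.epochs])
        return end, n0, r


@dataclass(frozen=True)
class SampleSpec:
    """Per-cohort haploid sample sizes and backward sampling times."""

    labels: tuple[str, ...]
    n_haploid: tuple[int, ...]
    times: tuple[float, ...]

    def __post_init__(self) -> None:
        if not (len(self.labels) == len(self.n_haploid) == len(self.times)):
            raise ValueError("labels, sizes and times must have equal length")
        if any(n < 2 for n in self.n_haploid):
            raise ValueError("each cohort needs at least 2 haploid samples")
        if any(t < 0 for t in self.times):
            raise ValueError("sampling times must be non-negative")
        if min(self.times) != 0:
            raise ValueError("at least one cohort must be sampled at time 0")

    @property
    def n_cohorts(self) -> int:
        return len(self.labels)

    @property
    def total(self) -> int:
        return int(sum(self.n_haploid))

    @property
    def dims(self) -> tuple[int, ...]:
        return tuple(n + 1 for n in self.n_haploid)


def flounder_sample_spec(
    diploids: tuple[int, int, int] = (26, 103, 150),
    gen_time_years: float = 2.0,
) -> SampleSpec:
    """The three-larval-cohort sampling design (1994, 1997, 2008 cohorts).

    Cohorts are ordered oldest first; sampling times are (2008−year)/gen_time
    generations before the 2008 cohort, giving 7.0 and 5.5 generations for
    the 1994 and 1997 cohorts at a 2-year generation.
    """
    years = (1994, 1997, 2008)
    labels = tuple(str(y) for y in years)
    times = tuple((2008 - y) / gen_time_years for y in years)
    return SampleSpec(labels, tuple(2 * d for d in diploids), times)


def model6_reference(tcar: float = 500.0) -> ParameterVector:
    """Reference ancestral-growth + bottleneck + exponential-recovery scenario.

    The maximum-likelihood summer-flounder history used throughout the power
    analyses, in haploid units: deep size 2104 growing to 64,418 before a
    two-generation bottleneck at size 1820 ending 12 generations before the
    most recent samples, then rapid exponential recovery to 20,424.  The end
    of ancestral growth (TCAR) is only weakly constrained by recent cohorts;
    the default of 500 generations implies an ancestral growth rate of
    3.6e-4 per generation and leaves the pre-bottleneck size with enough
    coalescent exposure to be estimable, consistent with the finite
    confidence intervals reported for it.
    """
    return ParameterVector(
        6,
        {
            "NANC": 2104.0,
            "NPREBOT": 64418.0,
            "NBOT": 1820.0,
            "NPOP08": 20424.0,
            "TLEN": 2.0,
            "TBOT": 12.0,
            "TCAR": tcar,
        },
    )


def _ancestral_tail(
    nprebot: float, nanc: float, tcar: float
) -> list[tuple[float, float, float, float]]:
    """Exponential segment from NPREBOT at TCAR back to NANC at T_LGM."""
    if tcar >= T_LGM:
        raise ValueError(f"TCAR must be below the deep horizon {T_LGM}")
    r = growth_rate_between(nprebot, nanc, T_LGM - tcar)
    return [
        (tcar, T_LGM, nprebot, r),
        (T_LGM, math.inf, nanc, 0.0),
    ]


def build_timeline(params: ParameterVector) -> EpochTimeline:
    """Translate a parameter vector into backward-time epochs.

    Instantaneous size changes become adjacent epoch boundaries; exponential
    segments carry the rate implied by their endpoint sizes.
    """
    p = params.values
    mid = params.model_id
    segs: list[tuple[float, float, float, float]]
    if mid == 1:
        segs = [(0.0, math.inf, p["NANC"], 0.0)]
    elif mid == 2:
        t1, t2 = p["TBOT"], p["TBOT"] + p["TLEN"]
        segs = [
            (0.0, t1, p["NPOP08"], 0.0),
            (t1, t2, p["NBOT"], 0.0),
            (t2, math.inf, p["NPREBOT"], 0.0),
        ]
    elif mid == 3:
        t1, t2 = p["TBOT"], p["TBOT"] + p["TLEN"]
        r = growth_rate_between(p["NPOP08"], p["NBOT"], t1) if t1 > 0 else 0.0
        segs = [
            (0.0, t1, p["NPOP08"], r),
            (t1, t2, p["NBOT"], 0.0),
            (t2, math.inf, p["NPREBOT"], 0.0),
        ]
    elif mid == 4:
        t1, t2 = p["TBOT"], p["TBOT"] + p["TLEN"]
        segs = [
            (0.0, t1, p["NPOP08"], 0.0),
            (t1, t2, p["NBOT"], 0.0),
            (t2, p["TCAR"], p["NPREBOT"], 0.0),
        ] + _ancestral_tail(p["NPREBOT"], p["NANC"], p["TCAR"])
    elif mid == 5:
        t1 = p["TBOT1"]
        t2 = t1 + p["TLEN1"]
        t3 = t2 + p["TBOT2"]
        t4 = t3 + p["TLEN2"]
        segs = [
            (0.0, t1, p["NPOP08"], 0.0),
            (t1, t2, p["NBOT1"], 0.0),
            (t2, t3, p["NINT"], 0.0),
            (t3, t4, p["NBOT2"], 0.0),
            (t4, math.inf, p["NPREBOT"], 0.0),
        ]
    elif mid == 6:
        t1, t2 = p["TBOT"], p["TBOT"] + p["TLEN"]
        r = growth_rate_between(p["NPOP08"], p["NBOT"], t1) if t1 > 0 else 0.0
        segs = [
            (0.0, t1, p["NPOP08"], r),
            (t1, t2, p["NBOT"], 0.0),
            (t2, p["TCAR"], p["NPREBOT"], 0.0),
        ] + _ancestral_tail(p["NPREBOT"], p["NANC"], p["TCAR"])
    elif mid == 7:
        segs = [
            (0.0, p["TCAR"], p["NPOP08"], 0.0),
        ] + _ancestral_tail(p["NPOP08"], p["NANC"], p["TCAR"])
    else:  # pragma: no cover - guarded by ParameterVector
        raise ValueError(f"unknown model id {mid}")
    # instantaneous changes show up as zero-length segments (e.g. TBOT = 0)
    return EpochTimeline(Epoch(*s) for s in segs if s[1] > s[0])
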