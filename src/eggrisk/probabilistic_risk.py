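"""Monte Carlo propagation of input uncertainty through the risk equations.

Per (area, population group) cell the engine draws ``n_iter`` joint
realisations of every uncertain input, pushes each realisation through the
deterministic kernels (EDI → THQ → HI; EDI → CR → TCR), and summarises the
resulting risk distributions (mean, p5/p50/p95, exceedance probability of
the decision threshold). The decision statistic of the pipeline is the
95th percentile, evaluated with 10,000 iterations by default.

Dependence structure: within one iteration a single concentration draw per
(area, metal) and a single BW/FIR draw per group are shared across all
metals, so HI sums comonotone-by-iteration terms. Each (area, group) cell
has its own child random stream derived deterministically from the master
seed and the cell's labels, making results bit-reproducible and invariant
to evaluation order.

Default input distributions (every choice overridable): concentrations are
bootstrapped from the area's observed samples (empirical); body weight is
a 0-truncated normal; intake rate is triangular; EF/ED/AT and the toxicity
constants (RfD, SF) are fixed points. These are explicit modelling
choices, not an attempt to reproduce any particular proprietary-software
configuration.

Percentiles use linear interpolation between order statistics (numpy's
default, the common "type 7" estimator).
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field
from types import SimpleNamespace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .data_io import (
    CARCINOGENS,
    ConcentrationRecord,
    ExposureProfile,
    ToxicityReference,
    records_to_frame,
)
from .deterministic_risk import (
    CR_UNACCEPTABLE,
    HI_THRESHOLD,
    DomainError,
    classify_cr,
    classify_hi,
    edi,
    thq,
)

__all__ = [
    "DistributionSpec",
    "SpecSet",
    "SimulationResult",
    "build_default_specs",
    "run_mcs",
    "simulate_cell",
    "percentile_threshold_report",
    "convergence_check",
]

METRICS = ("HI", "CR_Cr", "CR_Cd", "CR_Pb", "TCR")

#: Decision threshold per metric: HI against 1, carcinogenic metrics
#: against the potentially-unacceptable band edge.
THRESHOLDS = {
    "HI": HI_THRESHOLD,
    "CR_Cr": CR_UNACCEPTABLE,
    "CR_Cd": CR_UNACCEPTABLE,
    "CR_Pb": CR_UNACCEPTABLE,
    "TCR": CR_UNACCEPTABLE,
}

_FAMILIES = ("point", "normal", "lognormal", "uniform", "triangular", "empirical")


@dataclass(frozen=True)
class DistributionSpec:
    """One uncertain input's sampling law.

    params by family: point(value); normal(mean, sd) truncated at 0;
    lognormal(mu, sigma) on the log scale; uniform(low, high);
    triangular(low, mode, high) with low >= 0; empirical(values) resampled
    with replacement.
    """

    family: str
    params: tuple[float, ...]

    def __post_init__(self) -> None:
        f, p = self.family, self.params
        if f not in _FAMILIES:
            raise DomainError(f"unknown distribution family {f!r}")
        if f == "point" and len(p) != 1:
            raise DomainError("point needs exactly one parameter")
        if f == "normal" and (len(p) != 2 or p[1] <= 0):
            raise DomainError("normal needs (mean, sd) with sd > 0")
        if f == "lognormal" and (len(p) != 2 or p[1] <= 0):
            raise DomainError("lognormal needs (mu, sigma) with sigma > 0")
        if f == "uniform" and (len(p) != 2 or p[0] > p[1]):
            raise DomainError("uniform needs (low, high) with low <= high")
        if f == "triangular" and (
            len(p) != 3 or not (p[0] <= p[1] <= p[2]) or p[0] < 0
        ):
            raise DomainError("triangular needs 0 <= low <= mode <= high")
        if f == "empirical" and len(p) == 0:
            raise DomainError("empirical needs a non-empty sample")

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        f, p = self.family, self.params
        if f == "point":
            return np.full(size, p[0])
        if f == "normal":
            mean, sd = p
            a = (0.0 - mean) / sd  # truncate at 0: non-negative quantity
            return sps.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=size, random_state=rng)
        if f == "lognormal":
            return rng.lognormal(p[0], p[1], size)
        if f == "uniform":
            low, high = p
            return np.full(size, low) if low == high else rng.uniform(low, high, size)
        if f == "triangular":
            low, mode, high = p
            if low == high:
                return np.full(size, low)
            return rng.triangular(low, mode, high, size)
        return rng.choice(np.asarray(p, dtype=float), size=size, replace=True)

    @staticmethod
    def point(value: float) -> "DistributionSpec":
        return DistributionSpec("point", (float(value),))

    @staticmethod
    def lognormal_from_moments(mean: float, cv: float) -> "DistributionSpec":
        """Moment-matched lognormal with the given arithmetic mean and CV."""
        if mean <= 0 or cv <= 0:
            raise DomainError("lognormal moments need mean > 0 and cv > 0")
        sigma2 = np.log1p(cv * cv)
        mu = np.log(mean) - sigma2 / 2.0
        return DistributionSpec("lognormal", (float(mu), float(np.sqrt(sigma2))))


@dataclass(frozen=True)
class SpecSet:
    """Complete input-distribution assignment for a simulation run."""

    concentration: dict[tuple[str, str], DistributionSpec]  # (area, metal) -> spec
    bw: dict[str, DistributionSpec]  # group -> spec
    fir: dict[str, DistributionSpec]  # group -> spec

    def areas(self) -> list[str]:
        return sorted({a for a, _ in self.concentration})

    def metals(self, area: str) -> list[str]:
        return sorted({m for a, m in self.concentration if a == area})


@dataclass(frozen=True)
class SimulationResult:
    """Summary of one metric's simulated distribution in one cell."""

    metric: str
    area: str
    group: str
    n_iter: int
    seed: int
    mean: float
    p5: float
    p50: float
    p95: float
    exceedance_prob: float


def build_default_specs(
    records: Sequence[ConcentrationRecord],
    profiles: Sequence[ExposureProfile],
    overrides: Mapping[str, str] | None = None,
    bw_cv: float = 0.075,
    fir_spread: float = 0.3,
) -> SpecSet:
    """Assemble the default input-distribution mapping.

    Defaults: concentration → empirical bootstrap of the area's samples
    (singleton cells fall back to a point with a warning); bw → truncated
    normal (CV ``bw_cv``); fir → triangular (mode at the profile value,
    ±``fir_spread`` relative). ``overrides`` remaps whole input classes:
    ``{"concentration": "lognormal" | "point" | "empirical",
    "bw": "point", "fir": "point"}``.
    """
    overrides = dict(overrides or {})
    conc_mode = overrides.get("concentration", "empirical")
    df = records_to_frame(list(records))
    conc: dict[tuple[str, str], DistributionSpec] = {}
    for (area, metal), g in df.groupby(["area", "metal"]):
        vals = g["concentration"].to_numpy(dtype=float)
        if conc_mode == "point":
            conc[(area, metal)] = DistributionSpec.point(vals.mean())
        elif conc_mode == "lognormal":
            mean = vals.mean()
            sd = vals.std(ddof=1) if len(vals) > 1 else 0.0
            if sd == 0 or mean == 0:
                conc[(area, metal)] = DistributionSpec.point(mean)
            else:
                conc[(area, metal)] = DistributionSpec.lognormal_from_moments(mean, sd / mean)
        elif conc_mode == "empirical":
            if len(vals) < 2:
                warnings.warn(
                    f"singleton sample for ({area}, {metal}); empirical spec "
                    "falls back to a point mass",
                    stacklevel=2,
                )
                conc[(area, metal)] = DistributionSpec.point(vals[0])
            else:
                conc[(area, metal)] = DistributionSpec("empirical", tuple(vals))
        else:
            raise DomainError(f"unknown concentration override {conc_mode!r}")

    bw: dict[str, DistributionSpec] = {}
    fir: dict[str, DistributionSpec] = {}
    for p in profiles:
        if overrides.get("bw") == "point":
            bw[p.group] = DistributionSpec.point(p.bw)
        else:
            bw[p.group] = DistributionSpec("normal", (p.bw, bw_cv * p.bw))
        if overrides.get("fir") == "point":
            fir[p.group] = DistributionSpec.point(p.fir)
        else:
            fir[p.group] = DistributionSpec(
                "triangular", (p.fir * (1 - fir_spread), p.fir, p.fir * (1 + fir_spread))
            )
    return SpecSet(concentration=conc, bw=bw, fir=fir)


def _cell_rng(seed: int, area: str, group: str) -> np.random.Generator:
    key = (
        int(seed) & 0x7FFFFFFF,
        zlib.crc32(area.encode()) & 0x7FFFFFFF,
        zlib.crc32(group.encode()) & 0x7FFFFFFF,
    )
    return np.random.default_rng(np.random.SeedSequence(key))


def simulate_cell(
    specs: SpecSet,
    profile: ExposureProfile,
    toxicity: Sequence[ToxicityReference],
    area: str,
    n_iter: int,
    seed: int,
) -> dict[str, np.ndarray]:
    """Raw per-draw metric arrays for one (area, group) cell.

    Returns arrays for HI, CR_Cr/CR_Cd/CR_Pb, TCR plus per-metal
    ``THQ_<metal>`` (audit / conservation checks). Draw order is fixed:
    BW, FIR, then concentrations by metal name, so results only depend on
    the seed and the cell's labels.
    """
    if n_iter < 1:
        raise DomainError("n_iter must be >= 1")
    tox = {t.metal: t for t in toxicity}
    metals = specs.metals(area)
    if not metals:
        raise DomainError(f"no concentration specs for area {area!r}")
    missing = [m for m in metals if m not in tox]
    if missing:
        raise DomainError(f"no toxicity reference for input(s): {', '.join(missing)}")
    if profile.group not in specs.bw or profile.group not in specs.fir:
        raise DomainError(f"no BW/FIR spec for group {profile.group!r}")

    rng = _cell_rng(seed, area, profile.group)
    bw_draw = specs.bw[profile.group].sample(rng, n_iter)
    fir_draw = specs.fir[profile.group].sample(rng, n_iter)
    # per-draw exposure vector sharing one BW/FIR realisation across metals;
    # the kernels only need the attribute surface, not the frozen dataclass
    draw_profile = SimpleNamespace(
        group=profile.group, bw=bw_draw, fir=fir_draw,
        ef=profile.ef, ed=profile.ed, at=profile.at,
    )

    out: dict[str, np.ndarray] = {}
    hi = np.zeros(n_iter)
    crs: dict[str, np.ndarray] = {}
    for metal in metals:
        c = specs.concentration[(area, metal)].sample(rng, n_iter)
        e = edi(c, draw_profile)
        q = thq(c, draw_profile, tox[metal].rfd)
        out[f"THQ_{metal}"] = q
        hi = hi + q
        if metal in CARCINOGENS:
            crs[metal] = e * tox[metal].sf
    out["HI"] = hi
    tcr = np.zeros(n_iter)
    for metal in CARCINOGENS:
        if metal in crs:
            out[f"CR_{metal}"] = crs[metal]
            tcr = tcr + crs[metal]
    out["TCR"] = tcr
    return out


def run_mcs(
    specs: SpecSet,
    profiles: Sequence[ExposureProfile],
    toxicity: Sequence[ToxicityReference],
    n_iter: int = 10000,
    seed: int = 0,
) -> list[SimulationResult]:
    """Simulate every (area, group) cell and summarise each risk metric."""
    results: list[SimulationResult] = []
    for area in specs.areas():
        for profile in sorted(profiles, key=lambda p: p.group):
            draws = simulate_cell(specs, profile, toxicity, area, n_iter, seed)
            for metric in METRICS:
                if metric not in draws:
                    continue
                x = draws[metric]
                thr = THRESHOLDS[metric]
                p5, p50, p95 = np.percentile(x, [5, 50, 95])
                results.append(
                    SimulationResult(
                        metric=metric, area=area, group=profile.group,
                        n_iter=n_iter, seed=seed,
                        mean=float(np.mean(x)), p5=float(p5), p50=float(p50),
                        p95=float(p95),
                        exceedance_prob=float(np.mean(x >= thr)),
                    )
                )
    return results


def percentile_threshold_report(results: Sequence[SimulationResult]) -> pd.DataFrame:
    """Decision table: p95 per (area, group, metric), its classification,
    and a flag where p95 crosses the metric's decision threshold."""
    if not results:
        raise DomainError("no simulation results to report")
    rows = []
    for r in results:
        cls = classify_hi(r.p95) if r.metric == "HI" else classify_cr(r.p95)
        flagged = r.p95 >= THRESHOLDS[r.metric]
        rows.append(
            (r.area, r.group, r.metric, r.p95, cls, flagged, r.exceedance_prob, r.n_iter, r.seed)
        )
    return pd.DataFrame(
        rows,
        columns=[
            "area", "group", "metric", "p95", "classification", "flagged",
            "exceedance_prob", "n_iter", "seed",
        ],
    )


def convergence_check(
    specs: SpecSet,
    profile: ExposureProfile,
    toxicity: Sequence[ToxicityReference],
    area: str,
    metric: str = "HI",
    seed: int = 0,
    sizes: Sequence[int] = (1000, 5000, 10000, 50000),
) -> dict:
    """p95 of ``metric`` at increasing n_iter, with successive relative
    changes; passes when the change over the last size step is < 1%."""
    if metric not in METRICS:
        raise DomainError(f"metric must be one of {METRICS}")
    p95s = []
    for n in sizes:
        draws = simulate_cell(specs, profile, toxicity, area, int(n), seed)
        p95s.append(float(np.percentile(draws[metric], 95)))
    changes = []
    for prev, cur in zip(p95s, p95s[1:]):
        denom = abs(prev) if prev != 0 else 1.0
        changes.append(abs(cur - prev) / denom)
    return {
        "area": area,
        "group": profile.group,
        "metric": metric,
        "sizes": list(map(int, sizes)),
        "p95": p95s,
        "relative_changes": changes,
        "passed": (changes[-1] < 0.01) if changes else True,
    }
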