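"""Probabilistic chronic risk by Monte Carlo propagation.

The cumulative chronic hazard index for a population group,

    HI = sum_p  C_p * Fi / (bw * ADI_p),

is propagated through sampled input distributions: residue concentrations
C_p and ingestion rate Fi lognormal, body weight bw normal truncated at
zero, optional reference-dose constants uniform, anything else a point
mass. The output distribution is summarized by its median (preferred over
the mean for the right-skewed result), mean, SD, tail percentiles and
sample skewness; input influence is measured by the Spearman rank
correlation of each sampled input with the HI draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_data import ReferenceSet, ResidueTable
from .errors import ConfigurationError, ValidationError
from .exposure import PopulationProfile

_FAMILIES = ("lognormal", "normal", "uniform", "point")


@dataclass(frozen=True)
class DistributionSpec:
    """One sampled input variable.

    families and params:
      lognormal: median (> 0), gsd (geometric SD, > 1 or == 1 for degenerate)
      normal:    mean, sd (> 0); truncated at > 0 when ``positive`` (default)
      uniform:   low < high
      point:     value
    """

    variable: str
    family: str
    params: Mapping[str, float]
    positive: bool = True

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ConfigurationError(f"{self.variable}: unknown family {self.family!r}")
        p = self.params
        if self.family == "lognormal":
            if p.get("median", 0) <= 0 or p.get("gsd", 0) < 1:
                raise ConfigurationError(f"{self.variable}: lognormal needs median>0, gsd>=1")
        elif self.family == "normal":
            if p.get("sd", 0) <= 0:
                raise ConfigurationError(f"{self.variable}: normal needs sd>0")
        elif self.family == "uniform":
            if not p.get("low", 0) < p.get("high", 0):
                raise ConfigurationError(f"{self.variable}: uniform needs low<high")
        elif "value" not in p:
            raise ConfigurationError(f"{self.variable}: point needs a value")

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        p = self.params
        if self.family == "lognormal":
            sigma = math.log(p["gsd"]) if p["gsd"] > 1 else 0.0
            if sigma == 0.0:
                return np.full(n, p["median"])
            return rng.lognormal(mean=math.log(p["median"]), sigma=sigma, size=n)
        if self.family == "normal":
            if self.positive:
                # truncated normal on (0, inf) so no draw is nonpositive
                a = (0.0 - p["mean"]) / p["sd"]
                u = rng.random(n)
                return stats.truncnorm.ppf(u, a, np.inf, loc=p["mean"], scale=p["sd"])
            return rng.normal(p["mean"], p["sd"], size=n)
        if self.family == "uniform":
            return rng.uniform(p["low"], p["high"], size=n)
        return np.full(n, p["value"])

    @property
    def is_stochastic(self) -> bool:
        if self.family == "point":
            return False
        if self.family == "lognormal":
            return self.params["gsd"] > 1
        return True


@dataclass(frozen=True)
class McConfig:
    """A Monte Carlo scenario: iteration count, seed, group and input specs.

    Specs must include ``fi`` and ``bw`` and one ``conc:<pesticide>`` spec
    per pesticide in the cumulative sum; an ``adi:<pesticide>`` spec
    overrides the point ADI from the reference table.
    """

    specs: Sequence[DistributionSpec]
    group: str = "adults"
    n_iter: int = 100_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_iter < 1:
            raise ConfigurationError("n_iter must be >= 1")

    def spec_for(self, variable: str) -> Optional[DistributionSpec]:
        for s in self.specs:
            if s.variable == variable:
                return s
        return None


@dataclass(frozen=True)
class McResult:
    """Simulated HI draws with summary statistics and sensitivity coefficients."""

    group: str
    hi_draws: np.ndarray
    input_draws: Mapping[str, np.ndarray]
    summary: Mapping[str, float]  # median, mean, sd, p5, p95, skewness
    sensitivity: Mapping[str, float]  # variable -> Spearman rho (NaN if undefined)

    @property
    def median(self) -> float:
        return self.summary["median"]


def summarize_mc(draws: np.ndarray) -> dict[str, float]:
    """Median, mean, SD (n-1), 5th/95th percentiles (linear interpolation)
    and sample skewness of the simulated output."""
    draws = np.asarray(draws, dtype=float)
    if draws.size == 0:
        raise ValidationError("cannot summarize an empty draw set")
    constant = np.ptp(draws) == 0.0  # degenerate: SD and skewness exactly 0
    return {
        "median": float(np.median(draws)),
        "mean": float(np.mean(draws)),
        "sd": 0.0 if constant or draws.size < 2 else float(np.std(draws, ddof=1)),
        "p5": float(np.percentile(draws, 5)),
        "p95": float(np.percentile(draws, 95)),
        "skewness": 0.0 if constant or draws.size < 3 else float(stats.skew(draws)),
    }


def sensitivity_rank_correlation(
    input_draws: Mapping[str, np.ndarray], hi_draws: np.ndarray
) -> dict[str, float]:
    """Spearman rank correlation of each stochastic input with the HI draws.

    Ties are mid-ranked (scipy convention). A constant input has no rank
    ordering; its coefficient is reported as NaN rather than raising.
    """
    hi_draws = np.asarray(hi_draws, dtype=float)
    if hi_draws.size < 3:
        raise ValidationError("need at least 3 draws for rank correlation")
    out: dict[str, float] = {}
    for name, draws in input_draws.items():
        draws = np.asarray(draws, dtype=float)
        if draws.size != hi_draws.size:
            raise ValidationError(f"draw count mismatch for input {name!r}")
        if np.ptp(draws) == 0.0:
            out[name] = float("nan")
            continue
        rho = stats.spearmanr(draws, hi_draws).statistic
        out[name] = float(rho)
    return out


def run_chronic_mc(config: McConfig, refs: ReferenceSet) -> McResult:
    """Propagate the chronic HI through sampled inputs.

    Every variable in the HI formula needs a spec (point specs allowed);
    concentrations are ``conc:<pesticide>`` and their ADI comes from the
    reference table unless an ``adi:<pesticide>`` spec overrides it. A fixed
    seed makes repeat runs bit-identical.
    """
    fi_spec = config.spec_for("fi")
    bw_spec = config.spec_for("bw")
    if fi_spec is None:
        raise ConfigurationError("missing distribution spec for variable 'fi'")
    if bw_spec is None:
        raise ConfigurationError("missing distribution spec for variable 'bw'")
    conc_specs = [s for s in config.specs if s.variable.startswith("conc:")]
    if not conc_specs:
        raise ConfigurationError("missing distribution spec for at least one 'conc:<pesticide>'")

    rng = np.random.default_rng(config.seed)
    n = config.n_iter
    input_draws: dict[str, np.ndarray] = {}
    # draw order is fixed (fi, bw, then specs in listed order) for reproducibility
    input_draws["fi"] = fi_spec.sample(rng, n)
    input_draws["bw"] = bw_spec.sample(rng, n)
    hi = np.zeros(n)
    for spec in conc_specs:
        pesticide = spec.variable.split(":", 1)[1]
        conc = spec.sample(rng, n)
        adi_spec = config.spec_for(f"adi:{pesticide}")
        if adi_spec is not None:
            adi = adi_spec.sample(rng, n)
            input_draws[adi_spec.variable] = adi
        else:
            adi = refs.get(pesticide).adi
        input_draws[spec.variable] = conc
        hi += conc * input_draws["fi"] / (input_draws["bw"] * adi)
    # extra sampled variables (not in the formula) still get drawn and reported,
    # so null-influence checks can run through the same interface
    for spec in config.specs:
        if spec.variable in input_draws or spec.variable in ("fi", "bw"):
            continue
        if spec.variable.startswith("adi:"):
            continue
        input_draws[spec.variable] = spec.sample(rng, n)

    stochastic = {k: v for k, v in input_draws.items() if np.ptp(v) > 0.0}
    sensitivity = (
        sensitivity_rank_correlation(stochastic, hi) if (n >= 3 and stochastic) else {}
    )
    return McResult(
        group=config.group,
        hi_draws=hi,
        input_draws=input_draws,
        summary=summarize_mc(hi),
        sensitivity=sensitivity,
    )


def lognormal_fit_detected(concentrations: np.ndarray) -> tuple[float, float]:
    """Fit a lognormal by matching the sample median and log-scale SD.

    Returns ``(median, gsd)``. With a single observation the GSD degenerates
    to 1 (point mass at the observed value).
    """
    c = np.asarray(concentrations, dtype=float)
    c = c[c > 0]
    if c.size == 0:
        raise ValidationError("need at least one positive concentration to fit")
    median = float(np.median(c))
    if c.size == 1:
        return median, 1.0
    gsd = float(np.exp(np.std(np.log(c), ddof=1)))
    return median, max(gsd, 1.0)


def config_from_survey(
    table: ResidueTable,
    profile: PopulationProfile,
    n_iter: int = 100_000,
    seed: int = 0,
    fi_gsd: float = 1.5,
    bw_cv: float = 0.15,
    adi_uniform_halfwidth: Optional[float] = None,
    refs: Optional[ReferenceSet] = None,
) -> McConfig:
    """Build a chronic-risk scenario from a survey's detected residues.

    Each detected pesticide gets a lognormal concentration spec fitted to
    its detected values; Fi is lognormal around the profile mean intake
    (median = fi, geometric SD ``fi_gsd``); bw is normal with coefficient of
    variation ``bw_cv``, truncated at zero. Setting ``adi_uniform_halfwidth``
    (e.g. 0.2 for ±20%) adds uniform specs around each reference ADI;
    reference doses are fixed constants by default.
    """
    det = table.detections
    specs: list[DistributionSpec] = [
        DistributionSpec("fi", "lognormal", {"median": profile.fi, "gsd": fi_gsd}),
        DistributionSpec("bw", "normal", {"mean": profile.bw, "sd": bw_cv * profile.bw}),
    ]
    for name, grp in det.groupby("pesticide", sort=True):
        median, gsd = lognormal_fit_detected(grp["concentration"].to_numpy())
        specs.append(DistributionSpec(f"conc:{name}", "lognormal", {"median": median, "gsd": gsd}))
        if adi_uniform_halfwidth:
            if refs is None:
                raise ConfigurationError("refs required when adi_uniform_halfwidth is set")
            adi = refs.get(str(name)).adi
            specs.append(
                DistributionSpec(
                    f"adi:{name}",
                    "uniform",
                    {"low": adi * (1 - adi_uniform_halfwidth), "high": adi * (1 + adi_uniform_halfwidth)},
                )
            )
    return McConfig(specs=specs, group=profile.group, n_iter=n_iter, seed=seed)


def draws_frame(result: McResult) -> pd.DataFrame:
    """All input and output draws as a DataFrame for external audit."""
    data = {k: np.asarray(v) for k, v in result.input_draws.items()}
    data["hi"] = result.hi_draws
    return pd.DataFrame(data)
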