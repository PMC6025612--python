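"""Dermal-contact carcinogenic risk model for arsenic-contaminated soil.

Implements the USEPA (RAGS Part E style) dermal pathway for soil contact:

    ADI  = C * AF * ABS * CF * SA * EV * EF * ED / (BW * AT)
    Risk = ADI * SF

where

==========  =============================================  =================
symbol      meaning                                        units
==========  =============================================  =================
C           arsenic concentration in soil                  mg/kg
AF          soil-to-skin adherence factor                  mg/cm2 per event
ABS         dermal absorption fraction                     --
CF          mass conversion factor (1e-6)                  kg/mg
SA          exposed skin surface area                      cm2
EV          event frequency                                events/day
EF          exposure frequency                             days/yr
ED          exposure duration                              yr
BW          body weight                                    kg
AT          averaging time for carcinogens                 days
SF          dermal cancer slope factor                     (mg/kg/day)^-1
==========  =============================================  =================

ADI is the absorbed daily intake (mg per kg body weight per day) and Risk is
the excess lifetime cancer probability.  Because every parameter enters as a
pure product (numerator) or divisor (BW, AT), risk is monotone in each
parameter, so evaluating the equation at all-minimum and all-maximum
parameter values yields rigorous deterministic bounds on any Monte Carlo
draw whose marginals are supported inside those ranges.

Uncertainty/variability is propagated by Monte Carlo: each parameter gets a
:class:`ParameterDistribution` (a point value, a uniform range, or an
empirical sample vector resampled with replacement -- the latter is how
site questionnaire and soil data enter), and the dose/risk equations are
evaluated per iteration.

The model-level interface follows the fitted-model idiom:
``DermalRiskModel(...).fit()`` returns a :class:`DermalRiskResults` object
carrying the risk sample vector, percentiles, deterministic bounds and the
acceptability classification, with a ``summary()`` table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PARAMETER_NAMES",
    "TABLE_DEFAULTS",
    "ExposureParameters",
    "ParameterDistribution",
    "RiskResult",
    "RiskClassification",
    "DermalRiskModel",
    "DermalRiskResults",
    "absorbed_daily_intake",
    "carcinogenic_risk",
    "monte_carlo_risk",
    "deterministic_bounds",
    "classify_risk",
    "round_sig",
]

#: Names of the exposure parameters entering the ADI equation (excludes SF).
PARAMETER_NAMES = ("C", "AF", "ABS", "CF", "SA", "EV", "EF", "ED", "BW", "AT")

#: Default values / admissible ranges for every parameter.  Site-specific
#: parameters carry their observed (min, max) range; literature parameters
#: are points.  Used for validation and for the deterministic bounds when no
#: distribution is supplied.
TABLE_DEFAULTS: dict[str, tuple[float, float]] = {
    "C": (13.14, 591.31),     # mg/kg, site soil survey
    "AF": (0.01, 0.08),       # mg/cm2, USEPA resident adherence
    "ABS": (0.03, 0.03),      # dermal absorption fraction for As
    "CF": (1e-6, 1e-6),       # kg/mg
    "SA": (3300.0, 5700.0),   # cm2, from clothing questionnaire
    "EV": (1.0, 3.0),         # games per visit
    "EF": (3.0, 80.0),        # visits per year
    "ED": (0.083, 13.0),      # years of membership
    "BW": (74.8, 74.8),       # kg, national adult average
    "AT": (25550.0, 25550.0), # days (70 yr x 365 d/yr)
}

#: Dermal slope factor for inorganic arsenic (gastrointestinal absorption
#: adjustment 0.41 applied to the oral slope factor), (mg/kg/day)^-1.
DEFAULT_SLOPE_FACTOR = 3.66

#: Acceptability thresholds for excess lifetime cancer risk.
STRICT_RISK_THRESHOLD = 1e-6
UPPER_RISK_THRESHOLD = 1e-4


def round_sig(x: float, sig: int = 2) -> float:
    """Round ``x`` to ``sig`` significant figures (0 stays 0)."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))


@dataclass(frozen=True)
class ExposureParameters:
    """One complete dermal-exposure parameter vector.

    All fields must be strictly positive; ``ABS`` must lie in (0, 1].
    ``validate`` raises :class:`ValueError` naming the offending parameter.
    """

    C: float
    AF: float
    ABS: float = 0.03
    CF: float = 1e-6
    SA: float = 5700.0
    EV: float = 1.0
    EF: float = 52.0
    ED: float = 13.0
    BW: float = 74.8
    AT: float = 25550.0

    def validate(self) -> None:
        for name in PARAMETER_NAMES:
            value = getattr(self, name)
            if not (value > 0) or not math.isfinite(value):
                raise ValueError(
                    f"exposure parameter {name} must be strictly positive, got {value!r}"
                )
        if self.ABS > 1:
            raise ValueError(f"ABS is a fraction in (0, 1], got {self.ABS!r}")

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in PARAMETER_NAMES}


def absorbed_daily_intake(params: ExposureParameters) -> float:
    """Absorbed daily intake ADI (mg kg^-1 day^-1) for a parameter vector.

    ADI = C*AF*ABS*CF*SA*EV*EF*ED / (BW*AT).  Linear in every numerator
    factor and inversely proportional to BW and AT.
    """
    params.validate()
    p = params
    return (p.C * p.AF * p.ABS * p.CF * p.SA * p.EV * p.EF * p.ED) / (p.BW * p.AT)


def carcinogenic_risk(adi: float, sf: float = DEFAULT_SLOPE_FACTOR) -> float:
    """Excess lifetime cancer risk = ADI x SF (dimensionless probability)."""
    if adi < 0:
        raise ValueError(f"ADI must be non-negative, got {adi!r}")
    if not sf > 0:
        raise ValueError(f"slope factor must be strictly positive, got {sf!r}")
    return adi * sf


@dataclass(frozen=True)
class ParameterDistribution:
    """Marginal distribution for one exposure parameter.

    kind
        ``"point"`` (degenerate), ``"uniform"`` (continuous on [lo, hi]) or
        ``"empirical"`` (resampled with replacement from a sample vector --
        the site-specific parameters use this so the observed, generally
        non-normal, data distributions propagate unchanged).
    """

    name: str
    kind: str
    value: float | None = None
    bounds: tuple[float, float] | None = None
    samples: np.ndarray | None = None

    @classmethod
    def point(cls, name: str, value: float) -> "ParameterDistribution":
        return cls(name=name, kind="point", value=float(value))

    @classmethod
    def uniform(cls, name: str, lo: float, hi: float) -> "ParameterDistribution":
        if lo > hi:
            raise ValueError(f"{name}: inverted range [{lo}, {hi}]")
        return cls(name=name, kind="uniform", bounds=(float(lo), float(hi)))

    @classmethod
    def empirical(cls, name: str, samples: Sequence[float]) -> "ParameterDistribution":
        arr = np.asarray(samples, dtype=float)
        if arr.size == 0:
            raise ValueError(f"{name}: empirical sample vector is empty")
        return cls(name=name, kind="empirical", samples=arr)

    def support(self) -> tuple[float, float]:
        """(min, max) of the distribution's support."""
        if self.kind == "point":
            return (self.value, self.value)  # type: ignore[return-value]
        if self.kind == "uniform":
            return self.bounds  # type: ignore[return-value]
        if self.kind == "empirical":
            return (float(self.samples.min()), float(self.samples.max()))
        raise ValueError(f"unknown distribution kind {self.kind!r}")

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.kind == "point":
            return np.full(n, self.value, dtype=float)
        if self.kind == "uniform":
            lo, hi = self.bounds
            return rng.uniform(lo, hi, size=n)
        if self.kind == "empirical":
            return rng.choice(self.samples, size=n, replace=True)
        raise ValueError(f"unknown distribution kind {self.kind!r}")


@dataclass(frozen=True)
class RiskClassification:
    """Acceptability of a maximum risk against the 1e-6 / 1e-4 conventions."""

    max_risk: float
    exceeds_strict: bool        # > 1e-6: unacceptable under the strict USEPA rule
    exceeds_upper: bool         # > 1e-4: above even the permissive band
    within_band: bool           # in (1e-6, 1e-4]: tolerated by the band convention
    orders_above_strict: int    # whole orders of magnitude above 1e-6 (>= 0)

    @property
    def label(self) -> str:
        if not self.exceeds_strict:
            return "acceptable"
        if self.exceeds_upper:
            return "unacceptable (exceeds 1e-4)"
        return "unacceptable under strict 1e-6 rule; within 1e-6..1e-4 band"


def classify_risk(
    max_risk: float,
    strict_threshold: float = STRICT_RISK_THRESHOLD,
    upper_threshold: float = UPPER_RISK_THRESHOLD,
) -> RiskClassification:
    """Classify a maximum excess lifetime cancer risk.

    Two conventions coexist in regulatory practice: a strict rule deeming any
    risk above 1e-6 unacceptable, and a tolerated band of 1e-6 to 1e-4.
    Both verdicts are reported, along with how many whole orders of magnitude
    the value sits above the strict threshold.
    """
    if hasattr(max_risk, "max_risk"):  # accept a RiskResult
        max_risk = max_risk.max_risk
    max_risk = float(max_risk)
    exceeds_strict = max_risk > strict_threshold
    exceeds_upper = max_risk > upper_threshold
    orders = int(math.floor(math.log10(max_risk / strict_threshold))) if exceeds_strict else 0
    return RiskClassification(
        max_risk=max_risk,
        exceeds_strict=exceeds_strict,
        exceeds_upper=exceeds_upper,
        within_band=exceeds_strict and not exceeds_upper,
        orders_above_strict=orders,
    )


def deterministic_bounds(
    ranges: Mapping[str, tuple[float, float]] | None = None,
    sf: float = DEFAULT_SLOPE_FACTOR,
) -> tuple[float, float]:
    """Best/worst-case risk from per-parameter (lo, hi) ranges.

    Because risk is monotone increasing in every numerator parameter, the
    lower bound is the risk at all-minima and the upper bound the risk at
    all-maxima (BW and AT are points here; were they ranges the monotonicity
    would flip for them -- enforced below).
    """
    ranges = dict(TABLE_DEFAULTS) if ranges is None else {**TABLE_DEFAULTS, **dict(ranges)}
    for name, (lo, hi) in ranges.items():
        if lo > hi:
            raise ValueError(f"{name}: inverted range [{lo}, {hi}]")
    # BW and AT are divisors: their max minimises risk and vice versa.
    lo_vec = {n: (ranges[n][1] if n in ("BW", "AT") else ranges[n][0]) for n in PARAMETER_NAMES}
    hi_vec = {n: (ranges[n][0] if n in ("BW", "AT") else ranges[n][1]) for n in PARAMETER_NAMES}
    lower = carcinogenic_risk(absorbed_daily_intake(ExposureParameters(**lo_vec)), sf)
    upper = carcinogenic_risk(absorbed_daily_intake(ExposureParameters(**hi_vec)), sf)
    return lower, upper


@dataclass
class RiskResult:
    """Monte Carlo risk characterisation output.

    Invariants: every sampled risk is > 0 and lies within
    [lower_bound, upper_bound] when all marginals are supported inside the
    ranges used for the bounds.
    """

    samples: np.ndarray
    lower_bound: float
    upper_bound: float
    n_iter: int
    seed: int | None
    classification: RiskClassification = field(init=False)

    def __post_init__(self) -> None:
        self.classification = classify_risk(self.max_risk)

    @property
    def min_risk(self) -> float:
        return float(self.samples.min())

    @property
    def max_risk(self) -> float:
        return float(self.samples.max())

    @property
    def mean_risk(self) -> float:
        return float(self.samples.mean())

    def percentile(self, q: float) -> float:
        return float(np.percentile(self.samples, q))

    @property
    def percentiles(self) -> dict[str, float]:
        return {"p5": self.percentile(5), "p50": self.percentile(50), "p95": self.percentile(95)}

    def to_dict(self) -> dict:
        """JSON-serialisable summary (raw values plus 2-sig-fig display strings)."""
        c = self.classification
        return {
            "n_iter": self.n_iter,
            "seed": self.seed,
            "min": self.min_risk,
            "max": self.max_risk,
            "mean": self.mean_risk,
            **self.percentiles,
            "deterministic_lower": self.lower_bound,
            "deterministic_upper": self.upper_bound,
            "display": {
                "min": f"{round_sig(self.min_risk):.1e}",
                "max": f"{round_sig(self.max_risk):.1e}",
                "deterministic_upper": f"{round_sig(self.upper_bound):.1e}",
            },
            "classification": {
                "label": c.label,
                "exceeds_1e-6": c.exceeds_strict,
                "exceeds_1e-4": c.exceeds_upper,
                "orders_above_1e-6": c.orders_above_strict,
            },
        }


def monte_carlo_risk(
    distributions: Mapping[str, ParameterDistribution],
    n_iter: int = 10_000,
    seed: int | None = None,
    sf: float = DEFAULT_SLOPE_FACTOR,
    joint: pd.DataFrame | None = None,
    bound_ranges: Mapping[str, tuple[float, float]] | None = None,
) -> RiskResult:
    """Propagate parameter distributions through the dose/risk equations.

    Each of the ten ADI parameters must have a distribution (points allowed);
    parameters are drawn independently per iteration unless ``joint`` is
    given -- a DataFrame whose columns are parameter names resampled as whole
    rows (e.g. questionnaire records), preserving within-respondent
    correlation between SA, EV, EF and ED.  The remaining parameters still
    need marginals in ``distributions``.

    Deterministic bounds are computed from the supports of the supplied
    distributions (or from ``bound_ranges`` where given, widened to cover
    the supports), so bracketing of every draw is guaranteed.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    joint_cols = set(joint.columns) if joint is not None else set()
    missing = [n for n in PARAMETER_NAMES if n not in distributions and n not in joint_cols]
    if missing:
        raise ValueError(f"missing distribution for parameter(s): {', '.join(missing)}")

    rng = np.random.default_rng(seed)
    draws: dict[str, np.ndarray] = {}
    if joint is not None:
        rows = rng.integers(0, len(joint), size=n_iter)
        for col in joint.columns:
            draws[col] = joint[col].to_numpy(dtype=float)[rows]
    for name in PARAMETER_NAMES:
        if name not in draws:
            draws[name] = distributions[name].draw(rng, n_iter)

    numer = np.ones(n_iter)
    for name in ("C", "AF", "ABS", "CF", "SA", "EV", "EF", "ED"):
        numer = numer * draws[name]
    adi = numer / (draws["BW"] * draws["AT"])
    risks = adi * sf

    supports = {}
    for name in PARAMETER_NAMES:
        if name in joint_cols:
            col = joint[name].to_numpy(dtype=float)
            supports[name] = (float(col.min()), float(col.max()))
        else:
            supports[name] = distributions[name].support()
    if bound_ranges is not None:
        supports = {
            name: (min(supports[name][0], bound_ranges[name][0]),
                   max(supports[name][1], bound_ranges[name][1]))
            if name in bound_ranges else supports[name]
            for name in supports
        }
    lower, upper = deterministic_bounds(supports, sf=sf)
    return RiskResult(samples=risks, lower_bound=lower, upper_bound=upper,
                      n_iter=n_iter, seed=seed)


class DermalRiskModel:
    """Probabilistic dermal arsenic risk model built from site data.

    Parameters
    ----------
    distributions
        Mapping of parameter name to :class:`ParameterDistribution` covering
        every ADI parameter (missing literature parameters are filled from
        the published point defaults).
    sf
        Dermal slope factor, (mg/kg/day)^-1.
    joint_survey
        Optional DataFrame with columns among SA/EV/EF/ED resampled as whole
        respondent records instead of independent marginals.

    Use :meth:`from_tables` to build the model directly from a soil table
    and a questionnaire table.
    """

    def __init__(
        self,
        distributions: Mapping[str, ParameterDistribution],
        sf: float = DEFAULT_SLOPE_FACTOR,
        joint_survey: pd.DataFrame | None = None,
    ) -> None:
        dists = dict(distributions)
        joint_cols = set(joint_survey.columns) if joint_survey is not None else set()
        for name in PARAMETER_NAMES:
            if name not in dists and name not in joint_cols:
                lo, hi = TABLE_DEFAULTS[name]
                if lo == hi:
                    dists[name] = ParameterDistribution.point(name, lo)
                else:
                    raise ValueError(
                        f"site-specific parameter {name} needs an explicit distribution"
                    )
        self.distributions = dists
        self.sf = sf
        self.joint_survey = joint_survey

    @classmethod
    def from_tables(
        cls,
        soil: pd.DataFrame,
        survey_exposure: pd.DataFrame,
        zones: Sequence[str] = ("IA",),
        sf: float = DEFAULT_SLOPE_FACTOR,
        joint: bool = False,
    ) -> "DermalRiskModel":
        """Build the model from a soil table and questionnaire-derived frame.

        soil
            Soil-sample table with ``zone`` and ``tAs`` columns; the soil
            concentration C is the empirical distribution of surface tAs in
            ``zones`` (the exposure area; the irrigated pitches by default --
            pooling can be requested by passing ("IA", "NIA")).
        survey_exposure
            One row per respondent with columns SA, EV, EF, ED.
        joint
            Resample whole questionnaire rows (preserves correlations)
            instead of independent marginals.
        """
        conc = soil.loc[soil["zone"].isin(zones), "tAs"].to_numpy(dtype=float)
        if conc.size == 0:
            raise ValueError(f"no soil samples in zones {tuple(zones)!r}")
        dists = {
            "C": ParameterDistribution.empirical("C", conc),
            "AF": ParameterDistribution.uniform("AF", *TABLE_DEFAULTS["AF"]),
        }
        exposure = survey_exposure[["SA", "EV", "EF", "ED"]]
        if joint:
            return cls(dists, sf=sf, joint_survey=exposure)
        for name in ("SA", "EV", "EF", "ED"):
            dists[name] = ParameterDistribution.empirical(
                name, exposure[name].to_numpy(dtype=float)
            )
        return cls(dists, sf=sf)

    def fit(self, n_iter: int = 10_000, seed: int | None = None) -> "DermalRiskResults":
        """Run the Monte Carlo and return a results object.

        Deterministic bounds are reported against the published admissible
        parameter ranges (widened if the data extend beyond them), i.e. the
        best/worst cases of the risk methodology, not merely of the sample
        at hand.
        """
        result = monte_carlo_risk(
            self.distributions, n_iter=n_iter, seed=seed, sf=self.sf,
            joint=self.joint_survey, bound_ranges=TABLE_DEFAULTS,
        )
        return DermalRiskResults(self, result)


class DermalRiskResults:
    """Results of a fitted :class:`DermalRiskModel`.

    Exposes the Monte Carlo risk vector, summary statistics, deterministic
    bounds and the acceptability classification; ``summary()`` renders a
    plain-text table and ``plot_distribution()`` a log-scale histogram.
    """

    def __init__(self, model: DermalRiskModel, result: RiskResult) -> None:
        self.model = model
        self.result = result

    # convenience passthroughs
    @property
    def risk_samples(self) -> np.ndarray:
        return self.result.samples

    @property
    def min_risk(self) -> float:
        return self.result.min_risk

    @property
    def max_risk(self) -> float:
        return self.result.max_risk

    @property
    def mean_risk(self) -> float:
        return self.result.mean_risk

    @property
    def bounds(self) -> tuple[float, float]:
        return (self.result.lower_bound, self.result.upper_bound)

    @property
    def classification(self) -> RiskClassification:
        return self.result.classification

    def summary(self) -> str:
        r = self.result
        lines = [
            "Dermal arsenic carcinogenic risk (Monte Carlo)",
            "=" * 54,
            f"{'iterations':<28}{r.n_iter:>16,d}",
            f"{'seed':<28}{str(r.seed):>16}",
            f"{'min risk':<28}{round_sig(r.min_risk):>16.1e}",
            f"{'median risk':<28}{round_sig(r.percentile(50)):>16.1e}",
            f"{'mean risk':<28}{round_sig(r.mean_risk):>16.1e}",
            f"{'95th percentile':<28}{round_sig(r.percentile(95)):>16.1e}",
            f"{'max risk':<28}{round_sig(r.max_risk):>16.1e}",
            f"{'deterministic lower bound':<28}{round_sig(r.lower_bound):>16.1e}",
            f"{'deterministic upper bound':<28}{round_sig(r.upper_bound):>16.1e}",
            "-" * 54,
            f"classification: {r.classification.label}",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return self.result.to_dict()

    def plot_distribution(self, ax=None, bins: int = 50):
        """Histogram of log10(risk) with the 1e-6 / 1e-4 thresholds marked."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.hist(np.log10(self.risk_samples), bins=bins, color="#4477aa")
        for thr, style in ((STRICT_RISK_THRESHOLD, "--"), (UPPER_RISK_THRESHOLD, ":")):
            ax.axvline(math.log10(thr), color="crimson", linestyle=style)
        ax.set_xlabel("log10 excess lifetime cancer risk")
        ax.set_ylabel("iterations")
        return ax
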