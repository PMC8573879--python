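"""Cohort and statistics configuration.

`CohortConfig` describes the simulated study: two groups of COPD patients
(non-depressed CN, depressed CD, split on a HADS-D score of 8), an IV pulse
of amino-acid stable tracers with blood sampling at 10, 20, 30, 60 and
120 min, and multiplicative group effects on plasma concentration and
whole-body production (WBP) endpoints.

Default endpoint scales are typical postabsorptive values for a moderate to
severe COPD cohort: plasma concentrations in umol/L, WBP in umol/h.  Group
effect multipliers default to the direction seen in depressed COPD (lower
BCAA / aromatic amino-acid concentrations, mildly higher production), with
magnitudes that are configuration, not constants of the method.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

from .errors import ConfigError

#: tracers administered in the IV pulse (one per amino acid of interest)
DEFAULT_TRACERS: tuple[str, ...] = (
    "Phe", "Tyr", "Trp", "Leu", "Ile", "Val", "Arg", "Cit", "Orn",
)

#: substrate -> product conversion pairs resolvable from a pulse design
CONVERSION_PAIRS: tuple[tuple[str, str], ...] = (
    ("Phe", "Tyr"),
    ("Cit", "Arg"),
    ("Arg", "Cit"),
    ("Arg", "Orn"),
    ("Orn", "Cit"),
    ("Cit", "Orn"),
)

# typical CN-group means: plasma concentration (umol/L) and WBP (umol/h)
DEFAULT_CONC_MEAN: dict[str, float] = {
    "Phe": 48.5, "Tyr": 54.2, "Trp": 35.8, "Leu": 110.5, "Ile": 65.8,
    "Val": 177.6, "Arg": 69.5, "Cit": 34.5, "Orn": 55.7,
}
DEFAULT_WBP_MEAN: dict[str, float] = {
    "Phe": 3507.0, "Tyr": 3189.0, "Trp": 1176.0, "Leu": 9783.0,
    "Ile": 3674.0, "Val": 11119.0, "Arg": 9405.0, "Cit": 1029.0,
    "Orn": 2032.0,
}

# pulse dose per tracer (umol), sized so that TTR enrichments sit in the
# 0.01-0.1 range typical of pulse designs (dose ~ 5% of hourly turnover)
DEFAULT_DOSE_UMOL: dict[str, float] = {
    aa: round(0.05 * wbp, 1) for aa, wbp in DEFAULT_WBP_MEAN.items()
}

# fraction of substrate WBP converted to product (sets true conversion flux)
DEFAULT_TRANSFER_FRACTION: dict[tuple[str, str], float] = {
    ("Phe", "Tyr"): 0.062,
    ("Cit", "Arg"): 1.045,
    ("Arg", "Cit"): 0.041,
    ("Arg", "Orn"): 0.240,
    ("Orn", "Cit"): 0.057,
    ("Cit", "Orn"): 0.285,
}

# CD/CN multiplicative effects in the direction observed in depressed COPD
DEFAULT_GROUP_EFFECTS: dict[str, float] = {
    "conc_Phe": 0.89, "conc_Tyr": 0.87, "conc_Leu": 0.87, "conc_Ile": 0.82,
    "conc_Val": 0.92, "conc_Trp": 0.99, "conc_Arg": 0.98, "conc_Cit": 0.90,
    "conc_Orn": 0.93,
    "wbp_Phe": 1.15, "wbp_Tyr": 1.13, "wbp_Trp": 1.13, "wbp_Leu": 1.06,
    "wbp_Ile": 1.09, "wbp_Val": 1.07, "wbp_Arg": 1.00, "wbp_Cit": 1.09,
    "wbp_Orn": 1.12,
}


@dataclass
class CohortConfig:
    """Design of a simulated two-group pulse-tracer study."""

    n_cn: int = 51
    n_cd: int = 27
    seed: int = 0
    sample_times_min: tuple[float, ...] = (10.0, 20.0, 30.0, 60.0, 120.0)
    noise_cv: float = 0.03
    tracers: tuple[str, ...] = DEFAULT_TRACERS
    dose_umol: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DOSE_UMOL))
    group_effects: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_EFFECTS))
    #: endpoint -> (slope per year of age, slope per kg/m^2 of BMI),
    #: additive on the endpoint scale before group scaling
    covariate_effects: Mapping[str, tuple[float, float]] = field(
        default_factory=dict)
    age_range: tuple[float, float] = (46.0, 76.0)
    bmi_mean_sd: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"CN": (29.1, 6.4), "CD": (31.7, 8.2)})
    #: between-subject coefficient of variation of endpoint true values
    between_subject_cv: float = 0.20
    conversion_pairs: tuple[tuple[str, str], ...] = CONVERSION_PAIRS
    transfer_fraction: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_TRANSFER_FRACTION))

    def validate(self) -> "CohortConfig":
        if self.n_cn < 2:
            raise ConfigError("n_cn must be >= 2")
        if self.n_cd < 2:
            raise ConfigError("n_cd must be >= 2")
        if self.noise_cv < 0:
            raise ConfigError("noise_cv must be >= 0")
        t = tuple(self.sample_times_min)
        if len(t) < 2 or any(b <= a for a, b in zip(t, t[1:])) or t[0] <= 0:
            raise ConfigError(
                "sample_times_min must be strictly increasing and > 0")
        if self.age_range[0] >= self.age_range[1]:
            raise ConfigError("age_range must satisfy low < high")
        for aa in self.tracers:
            dose = self.dose_umol.get(aa)
            if dose is None or dose <= 0:
                raise ConfigError(f"dose_umol missing or non-positive "
                                  f"for tracer {aa!r}")
        if self.between_subject_cv < 0:
            raise ConfigError("between_subject_cv must be >= 0")
        return self

    def to_dict(self) -> dict:
        d = asdict(self)
        d["transfer_fraction"] = {
            f"{s}->{p}": v for (s, p), v in self.transfer_fraction.items()}
        d["conversion_pairs"] = [f"{s}->{p}"
                                 for s, p in self.conversion_pairs]
        return d


@dataclass
class StatsConfig:
    """Endpoint-comparison procedure settings.

    The pipeline mirrors the reporting conventions of covariate-adjusted
    clinical cohort studies: D'Agostino-Pearson normality gate, natural-log
    transform of non-normal endpoints, ROUT outlier removal at Q, one-way
    ANCOVA with age and BMI as covariates, and Benjamini-Hochberg q-values
    within endpoint families.
    """

    alpha: float = 0.05
    rout_q: float = 0.05
    covariates: tuple[str, ...] = ("age", "bmi")
    normality_alpha: float = 0.05
    fdr_method: str = "fdr_bh"
    #: family name -> endpoint prefix(es); endpoints sharing a family share
    #: one BH correction
    families: Mapping[str, Sequence[str]] = field(default_factory=lambda: {
        "concentrations": ("conc_",),
        "production": ("wbp_",),
        "clearance": ("clearance_",),
        "conversions": ("conversion_",),
    })
    ci_level: float = 0.95

    def validate(self) -> "StatsConfig":
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must be in (0, 1)")
        if not 0 < self.rout_q < 1:
            raise ConfigError("rout_q must be in (0, 1)")
        if not 0 < self.ci_level < 1:
            raise ConfigError("ci_level must be in (0, 1)")
        return self

    def to_dict(self) -> dict:
        d = asdict(self)
        d["families"] = {k: list(v) for k, v in self.families.items()}
        return d
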