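"""Synthetic two-group pulse-tracer cohorts with known ground truth.

The generator emulates the design of a postabsorptive pulse stable-isotope
study in COPD: two groups split on depression score (CN / CD), an IV pulse
of amino-acid tracers, TTR sampling at fixed minutes, plasma amino-acid
concentrations, and age/BMI covariates.  Every simulated quantity has its
true value recorded, so parameter-recovery and statistical calibration can
be checked end to end.

Ground-truth decay curves are parameterized by drawing rate constants and
an amplitude ratio from realistic ranges, then rescaling the amplitudes
jointly so that dose / analytic AUC over the 10-120 min window equals the
subject's true WBP exactly: the truth is consistent with the estimand by
construction.  Measurement noise is multiplicative Gaussian with a
configurable CV.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import CohortConfig
from .errors import InputError
from .kinetics import AUC_WINDOW_MIN

__all__ = ["TrueKinetics", "SimulatedCohort", "simulate_cohort",
           "simulate_ttr_curve", "analytic_auc"]


@dataclass
class TrueKinetics:
    """Ground-truth decay parameters and rates for one subject/tracer."""

    subject_id: str
    amino_acid: str
    wbp_true: float              # umol/h
    conc_true: float             # umol/L (nan for secondary series)
    amplitudes: np.ndarray       # TTR units, fast to slow
    rates_per_h: np.ndarray      # strictly decreasing
    dose_umol: float

    def __post_init__(self):
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        self.rates_per_h = np.asarray(self.rates_per_h, dtype=float)
        if np.any(self.amplitudes <= 0):
            raise InputError("amplitudes must be > 0")
        if (np.any(self.rates_per_h <= 0)
                or np.any(np.diff(self.rates_per_h) >= 0)):
            raise InputError("rates must be positive and strictly "
                             "decreasing")

    def curve(self, times_min: np.ndarray) -> np.ndarray:
        t_h = np.asarray(times_min, dtype=float) / 60.0
        return np.sum(self.amplitudes[:, None]
                      * np.exp(-self.rates_per_h[:, None] * t_h[None, :]),
                      axis=0)


@dataclass
class SimulatedCohort:
    subjects: pd.DataFrame
    ttr_series: list               # of kinetics.TTRSeries
    truth: pd.DataFrame            # long: subject_id, endpoint, value
    true_kinetics: list            # of TrueKinetics
    doses: pd.DataFrame            # tracer, dose_umol


def analytic_auc(amplitudes, rates_per_h,
                 t_start_min: float = AUC_WINDOW_MIN[0],
                 t_end_min: float = AUC_WINDOW_MIN[1]) -> float:
    """Exact window AUC (TTR*h) of a noiseless sum of exponentials."""
    a = np.asarray(amplitudes, dtype=float)
    k = np.asarray(rates_per_h, dtype=float)
    t0, t1 = t_start_min / 60.0, t_end_min / 60.0
    return float(np.sum(a / k * (np.exp(-k * t0) - np.exp(-k * t1))))


def simulate_ttr_curve(truth: TrueKinetics, times_min, noise_cv: float,
                       rng: np.random.Generator):
    """Noisy TTR observations: model(t) * (1 + eps), eps ~ N(0, cv^2),
    clipped to stay positive."""
    times_min = np.asarray(times_min, dtype=float)
    if np.any(times_min <= 0) or np.any(np.diff(times_min) <= 0):
        raise InputError("times must be positive and strictly increasing")
    clean = truth.curve(times_min)
    if noise_cv == 0:
        return clean.copy()
    noisy = clean * (1.0 + rng.normal(0.0, noise_cv, size=clean.shape))
    return np.maximum(noisy, 1e-12)


def _draw_decay_shape(rng: np.random.Generator, secondary: bool = False):
    """Unnormalized 2-exponential shape (amplitude ratio and rates)."""
    if secondary:
        k1 = rng.uniform(1.5, 4.0)
        k2 = rng.uniform(0.2, 0.8)
    else:
        k1 = rng.uniform(3.0, 9.0)
        k2 = rng.uniform(0.3, 1.2)
    ratio = rng.uniform(2.0, 6.0)    # fast / slow amplitude
    return np.array([ratio, 1.0]), np.array([k1, k2])


def _scaled_kinetics(sid, name, target_auc, dose, wbp, conc, rng,
                     secondary=False) -> TrueKinetics:
    amps, rates = _draw_decay_shape(rng, secondary=secondary)
    scale = target_auc / analytic_auc(amps, rates)
    return TrueKinetics(subject_id=sid, amino_acid=name, wbp_true=wbp,
                        conc_true=conc, amplitudes=amps * scale,
                        rates_per_h=rates, dose_umol=dose)


def _endpoint_truth(base_mean, cv, slopes, age, bmi, group_mult, rng):
    """Between-subject draw, additive covariate terms, then group scaling."""
    value = base_mean * rng.lognormal(mean=-0.5 * np.log1p(cv ** 2),
                                      sigma=np.sqrt(np.log1p(cv ** 2)))
    s_age, s_bmi = slopes
    value = value + s_age * (age - 61.0) + s_bmi * (bmi - 30.0)
    value = value * group_mult
    return max(value, 1e-6 * base_mean)


def simulate_cohort(config: CohortConfig) -> SimulatedCohort:
    """Generate a full synthetic study: subject table, TTR series for every
    configured tracer (plus secondary conversion series), and ground truth
    for every simulated endpoint.

    Identical ``config`` (including seed) gives bit-identical output.
    """
    from .config import DEFAULT_CONC_MEAN, DEFAULT_WBP_MEAN
    from .kinetics import TTRSeries

    config.validate()
    rng = np.random.default_rng(config.seed)
    times = np.asarray(config.sample_times_min, dtype=float)

    subj_rows, series, truths, truth_rows = [], [], [], []
    n_total = config.n_cn + config.n_cd
    groups = ["CN"] * config.n_cn + ["CD"] * config.n_cd
    for i, group in enumerate(groups):
        sid = f"S{i + 1:03d}"
        age = rng.uniform(*config.age_range)
        bmi_mu, bmi_sd = config.bmi_mean_sd[group]
        bmi = float(np.clip(rng.normal(bmi_mu, bmi_sd), 17.0, 48.0))
        height = float(np.clip(rng.normal(1.67, 0.09), 1.45, 1.95))
        weight = bmi * height ** 2
        ffm_frac = float(np.clip(rng.normal(0.62, 0.06), 0.40, 0.80))
        ffm = ffm_frac * weight
        # HADS-D draws are made consistent with the group by construction
        if group == "CD":
            hads_d = int(np.clip(round(rng.normal(9.2, 1.6)), 8, 21))
        else:
            hads_d = int(np.clip(round(rng.normal(3.5, 2.0)), 0, 7))
        row = {
            "subject_id": sid, "group": group, "age": age,
            "sex": "M" if rng.random() < 0.5 else "F",
            "height_m": height, "weight_kg": weight,
            "bmi": bmi, "fat_mass_kg": weight - ffm, "ffm_kg": ffm,
            "alm_kg": 0.45 * ffm,
            "fev1_pct": float(np.clip(rng.normal(44.0, 14.0), 15.0, 95.0)),
            "hads_d": hads_d,
            "hads_a": int(np.clip(round(rng.normal(
                7.9 if group == "CD" else 5.5, 2.5)), 0, 21)),
            "glucose_mmol_l": float(np.clip(rng.normal(5.8, 0.9), 3.5, 12.0)),
            "insulin_uiu_ml": float(np.clip(rng.lognormal(2.3, 0.55),
                                            1.0, 80.0)),
        }

        wbp_by_aa = {}
        for aa in config.tracers:
            dose = float(config.dose_umol[aa])
            mult_c = (config.group_effects.get(f"conc_{aa}", 1.0)
                      if group == "CD" else 1.0)
            mult_w = (config.group_effects.get(f"wbp_{aa}", 1.0)
                      if group == "CD" else 1.0)
            conc = _endpoint_truth(
                DEFAULT_CONC_MEAN[aa], config.between_subject_cv,
                config.covariate_effects.get(f"conc_{aa}", (0.0, 0.0)),
                age, bmi, mult_c, rng)
            wbp = _endpoint_truth(
                DEFAULT_WBP_MEAN[aa], config.between_subject_cv,
                config.covariate_effects.get(f"wbp_{aa}", (0.0, 0.0)),
                age, bmi, mult_w, rng)
            wbp_by_aa[aa] = wbp
            truth = _scaled_kinetics(sid, aa, dose / wbp, dose, wbp,
                                     conc, rng)
            truths.append(truth)
            series.append(TTRSeries(
                subject_id=sid, tracer=aa, times_min=times.copy(),
                ttr=simulate_ttr_curve(truth, times, config.noise_cv, rng),
                dose_umol=dose))
            row[f"conc_{aa}"] = conc
            truth_rows += [
                {"subject_id": sid, "endpoint": f"conc_{aa}", "value": conc},
                {"subject_id": sid, "endpoint": f"wbp_{aa}", "value": wbp},
                {"subject_id": sid, "endpoint": f"clearance_{aa}",
                 "value": wbp / conc},
            ]

        for (sub, prod) in config.conversion_pairs:
            if sub not in wbp_by_aa or prod not in wbp_by_aa:
                continue
            frac = float(config.transfer_fraction.get((sub, prod), 0.05))
            mult = (config.group_effects.get(f"conversion_{sub}->{prod}",
                                             1.0) if group == "CD" else 1.0)
            conv_true = frac * wbp_by_aa[sub] * mult
            dose_sub = float(config.dose_umol[sub])
            # secondary AUC consistent with the estimator identity:
            # conv = wbp_prod * auc_sec / auc_sub, auc_sub = dose/wbp_sub
            auc_sec = conv_true * dose_sub / (wbp_by_aa[sub]
                                              * wbp_by_aa[prod])
            name = f"{prod}<-{sub}"
            truth = _scaled_kinetics(sid, name, auc_sec, np.nan,
                                     wbp_by_aa[prod], np.nan, rng,
                                     secondary=True)
            truths.append(truth)
            series.append(TTRSeries(
                subject_id=sid, tracer=name, times_min=times.copy(),
                ttr=simulate_ttr_curve(truth, times, config.noise_cv, rng),
                dose_umol=np.nan))
            truth_rows.append({"subject_id": sid,
                               "endpoint": f"conversion_{sub}->{prod}",
                               "value": conv_true})
        subj_rows.append(row)

    subjects = pd.DataFrame(subj_rows)
    assert len(subjects) == n_total
    doses = pd.DataFrame({"tracer": list(config.tracers),
                          "dose_umol": [config.dose_umol[t]
                                        for t in config.tracers]})
    truth = pd.DataFrame(truth_rows,
                         columns=["subject_id", "endpoint", "value"])
    return SimulatedCohort(subjects=subjects, ttr_series=series,
                           truth=truth, true_kinetics=truths, doses=doses)
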