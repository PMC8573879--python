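"""Derived clinical and amino-acid panel quantities.

Sums and ratios of the large neutral amino acids (LNAA = BCAA + tyrosine +
phenylalanine + tryptophan), depression stratification from the HADS-D
subscale, body-composition indices standardized for height, the HOMA
insulin-resistance index, GOLD staging from FEV1 %predicted, leg-endurance
decline, and simple prevalence / proportion tables.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import InputError

__all__ = [
    "BCAA", "LNAA", "stratify_depression", "prevalence", "body_indices",
    "homa_index", "endurance_decline", "sum_bcaa", "sum_lnaa",
    "lnaa_ratio", "lnaa_corrections", "gold_stage", "proportion_table",
    "derive_metrics",
]

BCAA = ("Leu", "Ile", "Val")
LNAA = BCAA + ("Tyr", "Phe", "Trp")

HADS_D_THRESHOLD = 8      # clinically relevant depression
HADS_SUBSCALE_MAX = 21


def stratify_depression(hads_d_score) -> str:
    """Group label from the HADS depression subscale: >= 8 -> CD, else CN."""
    s = hads_d_score
    if not float(s).is_integer() or s < 0 or s > HADS_SUBSCALE_MAX:
        raise InputError(
            f"HADS-D score must be an integer in [0, {HADS_SUBSCALE_MAX}], "
            f"got {s}")
    return "CD" if s >= HADS_D_THRESHOLD else "CN"


def prevalence(labels) -> float:
    """Percent of subjects labeled CD, to one decimal."""
    labels = list(labels)
    if not labels:
        raise InputError("empty label list")
    return round(100.0 * sum(1 for x in labels if x == "CD") / len(labels),
                 1)


def body_indices(weight_kg, height_m, fat_mass_kg=np.nan,
                 ffm_kg=np.nan, alm_kg=np.nan) -> dict:
    """Height-standardized indices (kg/m^2): BMI, FMI, FFMI, ASMI."""
    if height_m <= 0:
        raise InputError("height must be > 0")
    for name, v in (("weight", weight_kg), ("fat mass", fat_mass_kg),
                    ("fat-free mass", ffm_kg),
                    ("appendicular lean mass", alm_kg)):
        if np.isfinite(v) and v < 0:
            raise InputError(f"{name} must be >= 0")
    h2 = height_m ** 2
    return {"bmi": weight_kg / h2, "fmi": fat_mass_kg / h2,
            "ffmi": ffm_kg / h2, "asmi": alm_kg / h2}


def homa_index(glucose_mmol_l: float, insulin_uiu_ml: float) -> float:
    """HOMA-IR: fasting glucose (mmol/L) x fasting insulin (uIU/mL) / 22.5."""
    if glucose_mmol_l <= 0 or insulin_uiu_ml <= 0:
        raise InputError("glucose and insulin must be > 0")
    return glucose_mmol_l * insulin_uiu_ml / 22.5


def endurance_decline(forces) -> float:
    """Leg-endurance force decline over a repetition series:
    (mean of first 3 - mean of last 3) / mean of first 3.

    Negative when force increased.  Needs at least 6 repetitions.
    """
    f = np.asarray(forces, dtype=float)
    if f.size < 6:
        raise InputError("need >= 6 repetitions")
    if np.any(f <= 0):
        raise InputError("forces must be positive")
    first, last = f[:3].mean(), f[-3:].mean()
    return float((first - last) / first)


def sum_bcaa(panel: pd.DataFrame | pd.Series):
    """Leu + Ile + Val from columns/keys conc_<aa>."""
    return sum(panel[f"conc_{aa}"] for aa in BCAA)


def sum_lnaa(panel: pd.DataFrame | pd.Series):
    """sumBCAA + Tyr + Phe + Trp."""
    return sum(panel[f"conc_{aa}"] for aa in LNAA)


def lnaa_ratio(panel, amino_acid: str, inclusive: bool = False):
    """Concentration of one LNAA relative to its transport competitors.

    Default denominator excludes the amino acid itself (the blood-brain
    barrier competition reading); ``inclusive=True`` divides by the full
    LNAA sum instead.
    """
    total = sum_lnaa(panel)
    num = panel[f"conc_{amino_acid}"]
    denom = total if inclusive else total - num
    if np.any(np.asarray(denom) <= 0):
        raise InputError("LNAA denominator must be > 0")
    return num / denom


def lnaa_corrections(panel: pd.DataFrame, amino_acid: str,
                     mode: str = "covariate"):
    """LNAA correction of one amino acid's concentration.

    ``mode='ratio'`` returns the competitor ratio per subject;
    ``mode='covariate'`` returns ``(values, sum_lnaa)`` flagging the
    endpoint for ANCOVA with sumLNAA as an added covariate.
    """
    if mode == "ratio":
        return lnaa_ratio(panel, amino_acid)
    if mode == "covariate":
        return panel[f"conc_{amino_acid}"], sum_lnaa(panel)
    raise InputError(f"unknown mode {mode!r}")


def gold_stage(fev1_pct_predicted: float) -> int:
    """GOLD COPD stage from FEV1 %predicted: >=80 I, 50-79 II, 30-49 III,
    <30 IV."""
    v = float(fev1_pct_predicted)
    if not 0 < v <= 150:
        raise InputError("FEV1 %predicted must be in (0, 150]")
    if v >= 80:
        return 1
    if v >= 50:
        return 2
    if v >= 30:
        return 3
    return 4


def proportion_table(counts_by_group: dict) -> pd.DataFrame:
    """Per-group category percentages to one decimal.

    ``counts_by_group`` maps group -> {category: count}.
    """
    rows = []
    for group, counts in counts_by_group.items():
        total = sum(counts.values())
        if total == 0:
            raise InputError(f"group {group!r} has zero size")
        for cat, c in counts.items():
            rows.append({"group": group, "category": cat, "count": c,
                         "percent": round(100.0 * c / total, 1)})
    return pd.DataFrame(rows)


def derive_metrics(subjects: pd.DataFrame) -> pd.DataFrame:
    """Per-subject derived panel and clinical metrics from a subject table.

    Adds sumBCAA / sumLNAA, the Trp and Tyr competitor ratios, BMI-family
    indices, and HOMA where the inputs are present.
    """
    out = subjects[["subject_id", "group"]].copy()
    conc_cols = [c for c in subjects.columns if c.startswith("conc_")]
    have = {c.removeprefix("conc_") for c in conc_cols}
    if set(BCAA) <= have:
        out["sum_bcaa"] = sum_bcaa(subjects)
    if set(LNAA) <= have:
        out["sum_lnaa"] = sum_lnaa(subjects)
        out["trp_lnaa_ratio"] = lnaa_ratio(subjects, "Trp")
        out["tyr_lnaa_ratio"] = lnaa_ratio(subjects, "Tyr")
    if {"weight_kg", "height_m"} <= set(subjects.columns):
        idx = subjects.apply(
            lambda r: body_indices(r["weight_kg"], r["height_m"],
                                   r.get("fat_mass_kg", np.nan),
                                   r.get("ffm_kg", np.nan),
                                   r.get("alm_kg", np.nan)), axis=1)
        for key in ("bmi", "fmi", "ffmi", "asmi"):
            out[key] = [d[key] for d in idx]
    if {"glucose_mmol_l", "insulin_uiu_ml"} <= set(subjects.columns):
        out["homa"] = [
            homa_index(g, i) if g > 0 and i > 0 else np.nan
            for g, i in zip(subjects["glucose_mmol_l"],
                            subjects["insulin_uiu_ml"])]
    if "fev1_pct" in subjects.columns:
        out["gold_stage"] = [gold_stage(v) for v in subjects["fev1_pct"]]
    return out
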