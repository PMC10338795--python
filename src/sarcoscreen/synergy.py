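"""Bliss Independence and Chou-Talalay scoring of drug-drug interactions.

Fractional responses are inhibitions in [0, 1].  Under independent action the
expected combined response is Pt = Pa + Pb - Pa*Pb; the Bliss index
BI = Po/Pt compares the observed combination response to that expectation
(BI > 1 synergy, < 1 antagonism, = 1 additivity), with "obvious" synergy
called at BI strictly above 1.3.  The Chou-Talalay combination index is
CI = DA/da + DB/db, where da/db are the single-agent IC50s and DA/DB the
combination doses reaching the IC50-equivalent effect (CI < 1 synergy).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "bliss_expected",
    "bliss_index",
    "classify_interaction",
    "chou_talalay_ci",
    "interpolate_effect_dose",
    "SynergyMatrix",
    "synergy_matrix",
    "percent",
    "tumor_volume",
]

ADDITIVE_TOL = 1e-9


def bliss_expected(pa, pb):
    """Bliss-expected combined inhibition Pt = Pa + Pb - Pa*Pb."""
    pa = np.asarray(pa, dtype=float)
    pb = np.asarray(pb, dtype=float)
    if np.any((pa < 0) | (pa > 1)) or np.any((pb < 0) | (pb > 1)):
        raise ValueError("fractional responses must lie in [0, 1]")
    out = pa + pb - pa * pb
    return float(out) if out.ndim == 0 else out


def bliss_index(po, pt):
    """Bliss index BI = Po / Pt; undefined when both single agents are inert."""
    po = np.asarray(po, dtype=float)
    pt = np.asarray(pt, dtype=float)
    if np.any(pt <= 0):
        raise ValueError("Bliss index undefined for Pt <= 0 (both agents inert)")
    out = po / pt
    return float(out) if out.ndim == 0 else out


def classify_interaction(
    bi: float, obvious_threshold: float = 1.3, additive_tol: float = ADDITIVE_TOL
) -> tuple[str, bool]:
    """Trichotomize a Bliss index and flag obvious synergy (BI strictly > 1.3)."""
    if not math.isfinite(bi):
        raise ValueError(f"BI must be finite, got {bi}")
    if bi < 1.0 - additive_tol:
        label = "antagonistic"
    elif bi > 1.0 + additive_tol:
        label = "synergistic"
    else:
        label = "additive"
    return label, bool(bi > obvious_threshold)


def chou_talalay_ci(da_combo: float, db_combo: float, da: float, db: float) -> float:
    """Combination index CI = DA/da + DB/db.

    ``da``/``db`` are the single-agent IC50 doses; ``da_combo``/``db_combo``
    the combination doses achieving the IC50-equivalent effect (either may be
    0 when one drug is absent).
    """
    if da <= 0 or db <= 0:
        raise ValueError("single-agent IC50 doses must be positive")
    if da_combo < 0 or db_combo < 0:
        raise ValueError("combination doses must be >= 0")
    return da_combo / da + db_combo / db


def interpolate_effect_dose(doses, effects, target_effect: float = 0.5) -> float:
    """Dose reaching a target effect by log-linear interpolation.

    Used to locate the IC50-equivalent dose of a fixed-ratio combination
    series for the Chou-Talalay CI: interpolates linearly in log-dose between
    the bracketing observations of a monotone effect series.
    """
    doses = np.asarray(doses, dtype=float)
    effects = np.asarray(effects, dtype=float)
    if np.any(doses <= 0):
        raise ValueError("doses must be positive")
    order = np.argsort(doses)
    doses, effects = doses[order], effects[order]
    above = np.nonzero(effects >= target_effect)[0]
    below = np.nonzero(effects < target_effect)[0]
    if above.size == 0 or below.size == 0:
        raise ValueError(f"effect series does not bracket target {target_effect}")
    i = above[0]
    if i == 0:
        return float(doses[0])
    j = i - 1
    x0, x1 = np.log(doses[j]), np.log(doses[i])
    y0, y1 = effects[j], effects[i]
    frac = (target_effect - y0) / (y1 - y0)
    return float(np.exp(x0 + frac * (x1 - x0)))


# ---------------------------------------------------------------------------
# matrix-wide scoring
# ---------------------------------------------------------------------------

@dataclass
class SynergyMatrix:
    """All-pairs Bliss scoring with classification and a screen summary."""

    matrix: pd.DataFrame        # square BI matrix, NaN diagonal
    records: pd.DataFrame       # long form: pair, Pa, Pb, Po, Pt, BI, label, obvious
    n_pairs: int
    n_obvious: int
    fraction_obvious: float     # percent, rounded to 1 decimal

    def summary(self) -> str:
        return (
            "Bliss combination screen\n"
            "========================\n"
            f"pairs evaluated      {self.n_pairs}\n"
            f"obvious synergy      {self.n_obvious}\n"
            f"fraction obvious     {self.fraction_obvious}%\n"
        )


def synergy_matrix(
    pairs: pd.DataFrame,
    singles: pd.DataFrame,
    obvious_threshold: float = 1.3,
) -> SynergyMatrix:
    """Score every drug pair with the Bliss model.

    ``pairs`` has columns drug_a, drug_b, dose_a_uM, dose_b_uM, Po; ``singles``
    has drug, dose_uM, P with responses measured at the combination doses.
    Replicate rows of the same pair are averaged before scoring.
    """
    singles_map = {(r.drug, r.dose_uM): r.P for r in singles.itertuples()}

    agg = (
        pairs.groupby(["drug_a", "drug_b", "dose_a_uM", "dose_b_uM"], sort=False)["Po"]
        .mean()
        .reset_index()
    )
    rows = []
    for r in agg.itertuples():
        ka, kb = (r.drug_a, r.dose_a_uM), (r.drug_b, r.dose_b_uM)
        if ka not in singles_map or kb not in singles_map:
            missing = ka if ka not in singles_map else kb
            raise ValueError(f"missing single-agent response for {missing}")
        pa, pb = singles_map[ka], singles_map[kb]
        pt = bliss_expected(pa, pb)
        bi = bliss_index(r.Po, pt)
        label, obvious = classify_interaction(bi, obvious_threshold)
        rows.append((r.drug_a, r.drug_b, pa, pb, r.Po, pt, bi, label, obvious))
    records = pd.DataFrame(
        rows,
        columns=["drug_a", "drug_b", "Pa", "Pb", "Po", "Pt", "BI", "label", "obvious"],
    )

    drugs = sorted(set(records["drug_a"]) | set(records["drug_b"]))
    mat = pd.DataFrame(np.nan, index=drugs, columns=drugs)
    for r in records.itertuples():
        mat.loc[r.drug_a, r.drug_b] = r.BI
        mat.loc[r.drug_b, r.drug_a] = r.BI

    n_pairs = len(records)
    n_obvious = int(records["obvious"].sum())
    return SynergyMatrix(
        matrix=mat,
        records=records,
        n_pairs=n_pairs,
        n_obvious=n_obvious,
        fraction_obvious=percent(n_obvious, n_pairs, decimals=1),
    )


def percent(part: int | float, whole: int | float, decimals: int = 1) -> float:
    """Share of a total as a percentage rounded to the given decimals."""
    if whole <= 0:
        raise ValueError("whole must be positive")
    return round(100.0 * part / whole, decimals)


def tumor_volume(length: float, width: float, height: float) -> float:
    """Ellipsoid-approximation tumor volume: pi/6 x length x width x height (mm^3)."""
    if length <= 0 or width <= 0 or height <= 0:
        raise ValueError("all dimensions must be positive")
    return math.pi / 6.0 * length * width * height
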