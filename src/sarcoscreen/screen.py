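"""High-throughput viability screen: normalization, hit calling, 4PL fitting.

Relative viability is the ratio of a drug well's luminescence to the mean of
the DMSO control wells on the same plate; inhibition is 1 - viability.  A drug
is a screen hit when its inhibition strictly exceeds the threshold (default
60%) in at least one cell line.  Dose-response curves are fitted with the
four-parameter logistic (4PL)

    v(d) = bottom + (top - bottom) / (1 + (d / ic50)^hill)

by bounded nonlinear least squares in log-dose space with multi-start
initialization; IC50 is reported as the fitted midpoint parameter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .simulate import PlateSet, hill_viability

__all__ = [
    "normalize_plate",
    "call_hits",
    "DoseResponseModel",
    "DoseResponseResults",
    "fit_dose_response",
    "select_combination_dose",
]


def normalize_plate(
    plate: PlateSet, cell_line: str, control_agg: str = "mean"
) -> pd.DataFrame:
    """Relative viability per drug well against the plate's DMSO controls.

    Returns a table with columns drug_id, cell_line, dose_uM, viability,
    inhibition (= 1 - viability exactly). Viabilities above 1 (stimulation)
    are retained.
    """
    controls = plate.control_signals()
    if controls.size == 0:
        raise ValueError("plate has no control wells")
    if control_agg == "mean":
        ref = float(np.mean(controls))
    elif control_agg == "median":
        ref = float(np.median(controls))
    else:
        raise ValueError(f"unknown control aggregation {control_agg!r}")
    if ref <= 0:
        raise ValueError(f"control signal mean must be positive, got {ref}")

    dw = plate.drug_wells()
    viability = dw["signal"].to_numpy(dtype=float) / ref
    return pd.DataFrame(
        {
            "drug_id": dw["drug_id"].to_numpy(),
            "cell_line": cell_line,
            "dose_uM": dw["dose_uM"].to_numpy(dtype=float),
            "viability": viability,
            "inhibition": 1.0 - viability,
        }
    )


def call_hits(records: pd.DataFrame, inhibition_threshold: float = 0.60) -> pd.DataFrame:
    """Flag drugs whose inhibition strictly exceeds the threshold in >= 1 line.

    ``records`` is the long table from :func:`normalize_plate` over one or
    more cell lines. Output is one row per drug with per-line inhibition
    columns, the max across lines, and the hit flag, sorted by max inhibition
    descending with ties broken by drug_id.
    """
    dup = records.duplicated(subset=["drug_id", "cell_line", "dose_uM"], keep=False)
    if dup.any():
        conflicted = records[dup].groupby(["drug_id", "cell_line", "dose_uM"])[
            "inhibition"
        ].nunique()
        if (conflicted > 1).any():
            bad = conflicted[conflicted > 1].index.tolist()
            raise ValueError(f"conflicting duplicate records for {bad}")
        records = records.drop_duplicates(subset=["drug_id", "cell_line", "dose_uM"])

    wide = records.pivot(index="drug_id", columns="cell_line", values="inhibition")
    wide["max_inhibition"] = wide.max(axis=1)
    wide["hit"] = wide["max_inhibition"] > inhibition_threshold
    wide = wide.sort_values(
        by=["max_inhibition", "drug_id"], ascending=[False, True]
    ).reset_index()
    wide.columns.name = None
    return wide


# ---------------------------------------------------------------------------
# 4PL dose-response model
# ---------------------------------------------------------------------------

@dataclass
class DoseResponseResults:
    """Fitted 4PL parameters with diagnostics.

    Attributes mirror the curve v(d) = bottom + (top-bottom)/(1+(d/ic50)^hill).
    """

    top: float
    bottom: float
    ic50: float
    hill: float
    residual_sse: float
    converged: bool
    dose_range: tuple[float, float] = (np.nan, np.nan)
    n_obs: int = 0

    def predict(self, dose) -> np.ndarray:
        """Predicted viability at the given dose(s)."""
        return hill_viability(dose, self.top, self.bottom, self.ic50, self.hill)

    def predicted_inhibition(self, dose) -> np.ndarray:
        return 1.0 - self.predict(dose)

    def summary(self) -> str:
        lines = [
            "4PL dose-response fit",
            "=" * 34,
            f"{'n observations':<20}{self.n_obs:>14}",
            f"{'converged':<20}{str(self.converged):>14}",
            f"{'top':<20}{self.top:>14.4f}",
            f"{'bottom':<20}{self.bottom:>14.4f}",
            f"{'ic50 (uM)':<20}{self.ic50:>14.4g}",
            f"{'hill slope':<20}{self.hill:>14.4f}",
            f"{'residual SSE':<20}{self.residual_sse:>14.4g}",
        ]
        return "\n".join(lines)

    def plot(self, ax=None, doses=None, viabilities=None):
        """Plot the fitted curve (and data, if provided) on a log-dose axis."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        lo, hi = self.dose_range
        if not np.isfinite(lo):
            lo, hi = self.ic50 / 100, self.ic50 * 100
        grid = np.geomspace(lo, hi, 200)
        ax.plot(grid, self.predict(grid), label="4PL fit")
        if doses is not None and viabilities is not None:
            ax.plot(doses, viabilities, "o", label="observed")
        ax.set_xscale("log")
        ax.set_xlabel("dose (uM)")
        ax.set_ylabel("relative viability")
        ax.legend()
        return ax


class DoseResponseModel:
    """Least-squares 4PL dose-response model.

    Parameters
    ----------
    doses : array-like of positive uM concentrations (>= 4 distinct values)
    viabilities : array-like of relative viabilities (same length)
    """

    #: bounds for (top, bottom); midpoint is bounded within the dose range
    PARAM_BOUNDS = (-0.1, 1.5)
    N_STARTS = 5

    def __init__(self, doses, viabilities):
        doses = np.asarray(doses, dtype=float)
        viabilities = np.asarray(viabilities, dtype=float)
        if doses.shape != viabilities.shape:
            raise ValueError("doses and viabilities must have equal length")
        if np.any(doses <= 0):
            raise ValueError("doses must be positive")
        if np.unique(doses).size < 4:
            raise ValueError("need >= 4 distinct doses for a 4PL fit")
        order = np.argsort(doses)
        self.doses = doses[order]
        self.viabilities = viabilities[order]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, dose_col="dose_uM", via_col="viability"):
        return cls(df[dose_col].to_numpy(), df[via_col].to_numpy())

    def _residuals(self, params, logd):
        top, bottom, log_ic50, hill = params
        pred = bottom + (top - bottom) / (1.0 + np.exp(hill * (logd - log_ic50)))
        return pred - self.viabilities

    def fit(self) -> DoseResponseResults:
        """Fit by bounded least squares with multi-start initialization."""
        v = self.viabilities
        logd = np.log(self.doses)

        if np.allclose(v, v[0]):
            return DoseResponseResults(
                top=float(v[0]), bottom=float(v[0]), ic50=np.nan, hill=np.nan,
                residual_sse=0.0, converged=False,
                dose_range=(self.doses[0], self.doses[-1]), n_obs=v.size,
            )

        lo, hi = self.PARAM_BOUNDS
        span = logd[-1] - logd[0]
        bounds = (
            [lo, lo, logd[0] - 0.5 * span - 1.0, 1e-3],
            [hi, hi, logd[-1] + 0.5 * span + 1.0, 20.0],
        )
        top0 = float(np.clip(np.max(v), lo + 1e-6, hi - 1e-6))
        bot0 = float(np.clip(np.min(v), lo + 1e-6, hi - 1e-6))
        # quantile heuristics for the midpoint starts
        mid_starts = np.quantile(logd, [0.2, 0.35, 0.5, 0.65, 0.8])[: self.N_STARTS]
        best = None
        for m0 in mid_starts:
            for h0 in (1.0, 2.0):
                x0 = np.array([top0, bot0, m0, h0])
                res = least_squares(
                    self._residuals, x0, args=(logd,), bounds=bounds, method="trf"
                )
                sse = float(np.sum(res.fun**2))
                if best is None or sse < best[0]:
                    best = (sse, res)
        sse, res = best
        top, bottom, log_ic50, hill = res.x
        if bottom > top:  # canonical orientation: decreasing viability
            top, bottom = bottom, top
            hill = -hill
        converged = bool(res.success) and hill > 0
        return DoseResponseResults(
            top=float(top), bottom=float(bottom), ic50=float(np.exp(log_ic50)),
            hill=float(hill), residual_sse=sse, converged=converged,
            dose_range=(float(self.doses[0]), float(self.doses[-1])), n_obs=v.size,
        )


def fit_dose_response(doses, viabilities) -> DoseResponseResults:
    """Convenience wrapper: fit a 4PL curve to (dose, viability) data."""
    return DoseResponseModel(doses, viabilities).fit()


def select_combination_dose(
    fit: DoseResponseResults,
    max_inhibition: float = 0.5,
    grid: list[float] | None = None,
) -> float:
    """Largest grid dose whose predicted inhibition is strictly below the cap.

    The default candidate grid takes half-log steps spanning the fitted dose
    range. Combination screens dose each single agent below its 50%-inhibition
    level so that combined effects remain measurable.
    """
    if not fit.converged:
        raise ValueError("cannot select a dose from a non-converged fit")
    if grid is None:
        lo, hi = fit.dose_range
        if not (np.isfinite(lo) and np.isfinite(hi)):
            raise ValueError("fit carries no dose range and no grid was given")
        k_lo = int(np.floor(2 * np.log10(lo)))
        k_hi = int(np.ceil(2 * np.log10(hi)))
        grid = [10 ** (k / 2) for k in range(k_lo, k_hi + 1)]
    grid = sorted(grid)
    ok = [d for d in grid if fit.predicted_inhibition(d) < max_inhibition]
    if not ok:
        raise ValueError(
            f"no grid dose keeps predicted inhibition below {max_inhibition}; "
            f"grid spans [{grid[0]:.3g}, {grid[-1]:.3g}] uM"
        )
    return float(ok[-1])
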