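"""Hill-equation quantification of gel-based titrations.

Two laws are fitted by ordinary least squares:

* specific binding with Hill slope, ``y = Bmax * x^h / (Kd^h + x^h)``,
  for EMSA fraction-bound titrations (Kd is the half-saturation
  concentration, h the cooperativity exponent);
* its inhibition complement, ``y = 100 - Bmax * x^h / (Kd^h + x^h)``,
  for remodeling efficiency expressed as percent of a no-RNA control.

Hill objectives are multimodal at high h, so fitting runs a fixed
multi-start grid (Kd from the x quartiles, h in {0.5, 1, 2}, Bmax at the
response maximum) and keeps the best converged solution.  Standard errors
come from the Jacobian at the optimum (Gauss-Newton curvature).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .core import ValidationError


@dataclass(frozen=True)
class BindingCurve:
    """A titration: concentrations (nM, strictly increasing, positive)
    and responses (fraction bound, or percent-of-control)."""

    x: tuple[float, ...]
    y: tuple[float, ...]
    weights: tuple[float, ...] | None = None
    label: str = ""

    def __post_init__(self) -> None:
        if len(self.x) != len(self.y):
            raise ValidationError("x and y must have equal length")
        if any(v <= 0 for v in self.x):
            raise ValidationError("concentrations must be strictly positive")
        if any(b <= a for a, b in zip(self.x, self.x[1:])):
            raise ValidationError("concentrations must be strictly increasing")
        if self.weights is not None and len(self.weights) != len(self.x):
            raise ValidationError("weights length mismatch")


@dataclass(frozen=True)
class HillFit:
    """Least-squares Hill parameters with curvature standard errors.

    By construction the fitted response at ``x = Kd`` equals ``Bmax / 2``
    (or ``100 - Bmax / 2`` for the inhibition form).
    """

    bmax: float
    kd: float
    h: float
    se_bmax: float
    se_kd: float
    se_h: float
    rss: float
    converged: bool
    model: str = "binding"  # "binding" or "inhibition"

    def predict(self, x: np.ndarray | float) -> np.ndarray | float:
        x = np.asarray(x, dtype=float)
        spec = self.bmax * x**self.h / (self.kd**self.h + x**self.h)
        return 100.0 - spec if self.model == "inhibition" else spec


def fraction_bound(bound_intensity: float, free_intensity: float) -> float:
    """Fraction of probe in the shifted (bound) band."""
    if bound_intensity < 0 or free_intensity < 0:
        raise ValidationError("band intensities must be non-negative")
    total = bound_intensity + free_intensity
    if total == 0:
        raise ValueError("fraction bound undefined when both bands are zero")
    return bound_intensity / total


def remodeling_efficiency(
    digested_fraction: float, control_digested_fraction: float
) -> float:
    """Percent of control, 100% being cleavage with no RNA added.

    Values above 100 are permitted (and should be flagged downstream).
    """
    if not 0 <= digested_fraction <= 1:
        raise ValidationError("digested_fraction must lie in [0, 1]")
    if control_digested_fraction <= 0:
        raise ValueError("control digested fraction must be positive")
    return 100.0 * digested_fraction / control_digested_fraction


_H_BOUNDS = (0.05, 10.0)


def _fit_hill_core(
    x: np.ndarray, y: np.ndarray, w: np.ndarray, model: str
) -> HillFit:
    def residuals(theta: np.ndarray) -> np.ndarray:
        bmax, kd, h = theta
        spec = bmax * x**h / (kd**h + x**h)
        pred = 100.0 - spec if model == "inhibition" else spec
        return (pred - y) * np.sqrt(w)

    target = 100.0 - y if model == "inhibition" else y
    bmax0 = float(max(target.max(), 1e-6))
    kd_starts = np.quantile(x, [0.25, 0.5, 0.75])
    best = None
    converged = False
    lo = [0.0, x.min() * 1e-3, _H_BOUNDS[0]]
    hi = [np.inf, x.max() * 1e3, _H_BOUNDS[1]]
    for kd0 in kd_starts:
        for h0 in (0.5, 1.0, 2.0):
            try:
                sol = least_squares(
                    residuals,
                    x0=[bmax0, kd0, h0],
                    bounds=(lo, hi),
                    xtol=1e-14,
                    ftol=1e-14,
                    gtol=1e-14,
                )
            except Exception:
                continue
            if not sol.success:
                continue
            converged = True
            if best is None or sol.cost < best.cost - 1e-15:
                best = sol
    if best is None:
        return HillFit(
            math.nan, math.nan, math.nan, math.nan, math.nan, math.nan,
            math.nan, False, model,
        )
    bmax, kd, h = best.x
    rss = float(2 * best.cost)
    dof = max(1, len(x) - 3)
    J = best.jac
    try:
        cov = np.linalg.inv(J.T @ J) * rss / dof
        ses = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        ses = np.full(3, math.inf)
    return HillFit(
        float(bmax), float(kd), float(h),
        float(ses[0]), float(ses[1]), float(ses[2]),
        rss, converged, model,
    )


def fit_hill(curve: BindingCurve) -> HillFit:
    """Fit specific binding with Hill slope by multi-start least squares."""
    if len(curve.x) < 4:
        raise ValueError("need at least 4 points to fit 3 parameters")
    x = np.asarray(curve.x, dtype=float)
    y = np.asarray(curve.y, dtype=float)
    w = (
        np.asarray(curve.weights, dtype=float)
        if curve.weights is not None
        else np.ones_like(x)
    )
    return _fit_hill_core(x, y, w, "binding")


def fit_inhibition(
    rna_conc: Sequence[float], efficiency: Sequence[float],
    weights: Sequence[float] | None = None,
) -> HillFit:
    """Fit the decreasing percent-of-control curve
    ``y = 100 - Bmax * x^h / (Kd^h + x^h)``; Kd is the half-inhibition
    concentration."""
    if len(rna_conc) < 4:
        raise ValueError("need at least 4 points to fit 3 parameters")
    x = np.asarray(rna_conc, dtype=float)
    if np.any(x <= 0):
        raise ValidationError("concentrations must be strictly positive")
    y = np.asarray(efficiency, dtype=float)
    w = np.asarray(weights, dtype=float) if weights is not None else np.ones_like(x)
    return _fit_hill_core(x, y, w, "inhibition")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_curves_csv(path: str | Path) -> list[BindingCurve]:
    """Read titrations from CSV with columns ``concentration_nM``,
    ``response``, optional ``weight`` and ``curve`` (label)."""
    df = pd.read_csv(path)
    if "curve" not in df.columns:
        df["curve"] = "curve_1"
    out = []
    for label, grp in df.groupby("curve", sort=False):
        grp = grp.sort_values("concentration_nM")
        weights = (
            tuple(grp["weight"].astype(float)) if "weight" in grp.columns else None
        )
        out.append(
            BindingCurve(
                tuple(grp["concentration_nM"].astype(float)),
                tuple(grp["response"].astype(float)),
                weights,
                str(label),
            )
        )
    return out


def fits_to_tsv(fits: dict[str, HillFit], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "curve": label,
                "model": f.model,
                "bmax": f.bmax,
                "kd_nM": f.kd,
                "hill_slope": f.h,
                "se_bmax": f.se_bmax,
                "se_kd": f.se_kd,
                "se_h": f.se_h,
                "rss": f.rss,
                "converged": f.converged,
            }
            for label, f in fits.items()
        ]
    ).to_csv(path, sep="\t", index=False)


def plot_curve(curve: BindingCurve, fit: HillFit, path: str | Path) -> None:
    """Save a log-x plot of the titration points and the fitted law."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 3))
    ax.semilogx(curve.x, curve.y, "o", label="data")
    xs = np.geomspace(min(curve.x), max(curve.x), 200)
    ax.semilogx(xs, fit.predict(xs), "-", label=f"Kd={fit.kd:.3g} nM, h={fit.h:.2g}")
    ax.set_xlabel("concentration (nM)")
    ax.set_ylabel("response")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
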