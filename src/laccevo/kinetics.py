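"""Laccase isozyme characterization: Beer-Lambert rate conversion,
Michaelis-Menten fitting and substrate-specificity classing.

Initial oxidation rates are obtained from absorbance slopes via the
substrate's extinction coefficient (1 cm path unless configured); K_M
and V_max come from nonlinear least squares on v = Vmax*S/(Km+S) with
replicate-weighted per-concentration means.  The ++/+/x/- specificity
classes use invented, configurable relative-rate thresholds - the
published symbol scale defines the schema, not the cutoffs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "KineticsSubstrate",
    "SUBSTRATES",
    "REFERENCE_KM",
    "RateSeries",
    "MMFit",
    "rate_from_absorbance",
    "absorbance_slope",
    "fit_mm",
    "classify_specificity",
    "michaelis_menten",
]


@dataclass(frozen=True)
class KineticsSubstrate:
    """A spectrophotometric laccase substrate.

    wavelength_nm: detection wavelength; epsilon: extinction coefficient
    in 1/(M*cm); monomer_type: lignin-monomer class (S, G, H or other);
    range_uM: assayed concentration range.
    """

    name: str
    wavelength_nm: float
    epsilon: float
    monomer_type: str
    range_uM: tuple[float, float]

    def __post_init__(self):
        if self.epsilon <= 0:
            raise ValueError("extinction coefficient must be positive")
        lo, hi = self.range_uM
        if not lo < hi:
            raise ValueError("concentration range min must be < max")


#: The six assayed substrates with their detection parameters.
SUBSTRATES: dict[str, KineticsSubstrate] = {
    s.name: s
    for s in [
        KineticsSubstrate("ABTS", 436, 29500, "other", (5, 2000)),
        KineticsSubstrate("2,6-DMP", 470, 35645, "S", (5, 2000)),
        KineticsSubstrate("catechol", 410, 740, "other", (50, 20000)),
        KineticsSubstrate("ferulic_acid", 314, 12940, "G", (2.5, 200)),
        KineticsSubstrate("sinapic_acid", 306, 14640, "S", (2.5, 200)),
        KineticsSubstrate("guaiacol", 464, 6490, "G", (125, 10000)),
    ]
}

#: Published K_M values (uM) of the four T. hirsuta isozymes, by
#: (isozyme, substrate).  Used as generating parameters for synthetic
#: rate data and for display comparison.
REFERENCE_KM: dict[tuple[str, str], float] = {
    ("LacA", "ABTS"): 17.0,
    ("rLacC", "ABTS"): 534.0,
    ("rLacD", "ABTS"): 37.0,
    ("rLacF", "ABTS"): 88.5,
    ("LacA", "catechol"): 183.0,
    ("rLacC", "catechol"): 16299.0,
    ("rLacD", "catechol"): 280.0,
    ("rLacF", "catechol"): 3627.0,
    ("LacA", "2,6-DMP"): 24.0,
    ("rLacC", "2,6-DMP"): 589.0,
    ("rLacD", "2,6-DMP"): 17.0,
    ("rLacF", "2,6-DMP"): 79.0,
    ("LacA", "sinapic_acid"): 17.0,
    ("rLacC", "sinapic_acid"): 71.0,
    ("rLacD", "sinapic_acid"): 5.0,
    ("rLacF", "sinapic_acid"): 33.0,
    ("LacA", "ferulic_acid"): 28.0,
    ("rLacC", "ferulic_acid"): 173.0,
    ("rLacD", "ferulic_acid"): 78.0,
    ("rLacF", "ferulic_acid"): 118.0,
    ("LacA", "guaiacol"): 173.0,
    ("rLacC", "guaiacol"): 15742.0,
    ("rLacD", "guaiacol"): 931.0,
    ("rLacF", "guaiacol"): 2766.0,
}


@dataclass
class RateSeries:
    """Substrate-concentration -> initial-rate data (triplicates typical).

    ``data`` columns: substrate_uM, rate_uM_per_min, replicate.
    """

    substrate: str
    data: pd.DataFrame

    def __post_init__(self):
        required = {"substrate_uM", "rate_uM_per_min", "replicate"}
        if not required.issubset(self.data.columns):
            raise ValueError(f"RateSeries needs columns {sorted(required)}")
        if (self.data["rate_uM_per_min"] < 0).any():
            raise ValueError("initial rates must be >= 0")

    @classmethod
    def from_csv(cls, path, substrate: str = "") -> "RateSeries":
        return cls(substrate, pd.read_csv(path, comment="#"))

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)


@dataclass
class MMFit:
    """Michaelis-Menten fit: K_M and V_max with linearization SEs."""

    km: float
    km_se: float
    vmax: float
    vmax_se: float
    rss: float
    converged: bool
    n_concentrations: int

    def summary(self) -> str:
        return (
            f"K_M = {self.km:.4g} +/- {self.km_se:.2g} uM, "
            f"V_max = {self.vmax:.4g} +/- {self.vmax_se:.2g} uM/min "
            f"(RSS {self.rss:.3g}, {self.n_concentrations} concentrations)"
        )


def michaelis_menten(s, vmax, km):
    s = np.asarray(s, dtype=float)
    return vmax * s / (km + s)


def rate_from_absorbance(
    slope: float, substrate: KineticsSubstrate, path_cm: float = 1.0
) -> float:
    """Beer-Lambert conversion: absorbance/min -> uM/min of product."""
    if path_cm <= 0:
        raise ValueError("path length must be positive")
    return slope / (substrate.epsilon * path_cm) * 1e6


def absorbance_slope(
    time_min: Sequence[float],
    absorbance: Sequence[float],
    window: Optional[tuple[float, float]] = None,
) -> float:
    """Least-squares slope of the (linear-phase) absorbance trace."""
    t = np.asarray(time_min, dtype=float)
    a = np.asarray(absorbance, dtype=float)
    if window is not None:
        mask = (t >= window[0]) & (t <= window[1])
        t, a = t[mask], a[mask]
    if t.size < 2:
        raise ValueError("need at least two points in the slope window")
    return float(np.polyfit(t, a, 1)[0])


class FitError(RuntimeError):
    pass


def fit_mm(series: RateSeries | pd.DataFrame) -> MMFit:
    """Nonlinear least-squares Michaelis-Menten fit.

    Replicates are averaged per concentration and weighted by replicate
    count.  Initialization: V_max0 = 1.2*max(v); K_M0 = the concentration
    whose mean rate is closest to half of max(v).  Standard errors come
    from the local-linearization covariance.
    """
    df = series.data if isinstance(series, RateSeries) else series
    grouped = df.groupby("substrate_uM")["rate_uM_per_min"].agg(["mean", "count"])
    s = grouped.index.to_numpy(dtype=float)
    v = grouped["mean"].to_numpy()
    n = grouped["count"].to_numpy(dtype=float)
    if s.size < 4:
        raise ValueError("need >= 4 distinct concentrations for a stable fit")
    vmax0 = 1.2 * float(v.max())
    km0 = float(s[np.argmin(np.abs(v - v.max() / 2.0))])
    km0 = max(km0, 1e-9)
    try:
        popt, pcov = curve_fit(
            michaelis_menten,
            s,
            v,
            p0=[vmax0, km0],
            sigma=1.0 / np.sqrt(n),
            absolute_sigma=False,
            bounds=([0.0, 0.0], [np.inf, np.inf]),
            maxfev=10000,
        )
    except RuntimeError as exc:  # pragma: no cover - pathological data
        raise FitError(f"Michaelis-Menten fit did not converge: {exc}") from exc
    vmax, km = popt
    with np.errstate(invalid="ignore"):
        se = np.sqrt(np.diag(pcov))
    resid = v - michaelis_menten(s, *popt)
    rss = float(np.sum(n * resid**2))
    if km <= 0 or not np.isfinite(km):
        raise FitError("fit produced a non-finite K_M")
    return MMFit(
        km=float(km),
        km_se=float(se[1]) if np.isfinite(se[1]) else 0.0,
        vmax=float(vmax),
        vmax_se=float(se[0]) if np.isfinite(se[0]) else 0.0,
        rss=rss,
        converged=True,
        n_concentrations=int(s.size),
    )


#: Relative-rate thresholds (percent of the reference substrate's rate) for
#: the ++ / + / +/- / - specificity classes.  Invented, configurable.
DEFAULT_SPECIFICITY_THRESHOLDS = (25.0, 5.0, 1.0)


def classify_specificity(
    rates: dict[str, float],
    reference: Optional[str] = None,
    thresholds: tuple[float, float, float] = DEFAULT_SPECIFICITY_THRESHOLDS,
) -> dict[str, str]:
    """Class each substrate relative to the highest-rate (reference) substrate.

    ++ if the relative rate is >= 25%, + if >= 5%, +/- if >= 1%,
    - otherwise.  Scale-invariant: multiplying all rates by a positive
    constant leaves the classes unchanged.
    """
    if any(r < 0 for r in rates.values()):
        raise ValueError("rates must be >= 0")
    if reference is None:
        reference = max(rates, key=lambda k: rates[k])
    ref_rate = rates[reference]
    if ref_rate <= 0:
        raise ValueError("reference rate must be positive (all-zero rates?)")
    hi, mid, lo = thresholds
    out = {}
    for name, r in rates.items():
        rel = 100.0 * r / ref_rate
        if rel >= hi:
            out[name] = "++"
        elif rel >= mid:
            out[name] = "+"
        elif rel >= lo:
            out[name] = "+/-"
        else:
            out[name] = "-"
    return out


def default_grid(substrate: KineticsSubstrate, n: int = 10) -> np.ndarray:
    """Log-spaced assay grid spanning the substrate's stated range."""
    lo, hi = substrate.range_uM
    return np.geomspace(lo, hi, n)
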