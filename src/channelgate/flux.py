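"""Aequorin luminescence calibration and dose-response fitting.

The aequorin assay reads intracellular Ca2+ through the fractional
consumption rate of the photoprotein: with per-second luminescence
counts L(t) and a total count T (all light emitted, including the
terminal Triton lysis), the consumption rate is k(t) = L(t)/T and the
calibration line

    pCa(t) = 0.332588 * (-log k(t)) + 5.5593

maps it to p[Ca2+]i.  Concentration-response data are fitted with the
four-parameter logistic (Hill) equation

    E(c) = E_min + (E_max - E_min) / (1 + (c / IC50)^h)

for inhibition (effect falls with concentration); the activation form
swaps the concentration ratio.  A 'literal' variant with numerator
(E_max + E_min) is kept selectable for exact replication of the
published formula, which we read as a sign typo.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "LuminescenceSeries",
    "CalciumSeries",
    "DoseResponseDataset",
    "DoseResponseFit",
    "calibrate_calcium",
    "fit_dose_response",
    "logistic_effect",
    "CALIBRATION_SLOPE",
    "CALIBRATION_INTERCEPT",
]

CALIBRATION_SLOPE = 0.332588
CALIBRATION_INTERCEPT = 5.5593


@dataclass
class LuminescenceSeries:
    """Per-interval bioluminescence rates (counts/s at 1-s intervals),
    the terminal lysis counts, and the grand total."""

    counts_per_s: np.ndarray
    lysis_counts: float
    total_counts: float

    def __post_init__(self):
        self.counts_per_s = np.asarray(self.counts_per_s, dtype=float)
        if np.any(self.counts_per_s < 0) or self.lysis_counts < 0:
            raise ValueError("counts must be non-negative")
        if self.total_counts <= 0:
            raise ValueError("total counts must be positive")
        emitted = self.counts_per_s.sum() + self.lysis_counts
        if emitted > self.total_counts * (1 + 1e-9):
            raise ValueError("emitted counts exceed the grand total")

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# lysis_counts={self.lysis_counts:.9g}\n")
            fh.write(f"# total_counts={self.total_counts:.9g}\n")
            fh.write("time_s,counts\n")
            for i, c in enumerate(self.counts_per_s):
                fh.write(f"{i},{c:.9g}\n")

    @classmethod
    def from_csv(cls, path) -> "LuminescenceSeries":
        meta: dict = {}
        counts = []
        with open(path) as fh:
            for ln in fh:
                ln = ln.strip()
                if not ln or ln.startswith("time_s"):
                    continue
                if ln.startswith("#"):
                    k, _, v = ln[1:].strip().partition("=")
                    meta[k.strip()] = float(v)
                    continue
                counts.append(float(ln.split(",")[1]))
        counts = np.array(counts)
        lysis = meta.get("lysis_counts", 0.0)
        total = meta.get("total_counts", counts.sum() + lysis)
        return cls(counts, lysis, total)


@dataclass
class CalciumSeries:
    """Calibrated series: consumption rate k, pCa and [Ca2+] per interval.

    Intervals with k = 0 have undefined pCa; they are NaN and flagged in
    ``undefined`` rather than dropped.
    """

    k_per_s: np.ndarray
    pca: np.ndarray
    ca_molar: np.ndarray
    undefined: np.ndarray  # boolean mask of k == 0 intervals


@dataclass
class DoseResponseDataset:
    """Tidy table of (conc_uM, effect, replicate)."""

    data: pd.DataFrame

    def __post_init__(self):
        required = {"conc_uM", "effect", "replicate"}
        if not required.issubset(self.data.columns):
            raise ValueError(f"dataset needs columns {sorted(required)}")
        if np.any(self.data["conc_uM"] <= 0):
            raise ValueError("concentrations must be strictly positive")

    @property
    def concentrations(self) -> np.ndarray:
        return np.sort(self.data["conc_uM"].unique())

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "DoseResponseDataset":
        return cls(pd.read_csv(path, comment="#"))


@dataclass
class DoseResponseFit:
    e_min: float
    e_max: float
    ic50_uM: float
    hill: float
    stderr: dict = field(default_factory=dict)
    residual_norm: float = float("nan")
    converged: bool = False
    form: str = "corrected"
    direction: str = "inhibition"


def calibrate_calcium(series: LuminescenceSeries, log_base: float = 10.0,
                      denominator: str = "grand_total",
                      background: LuminescenceSeries | None = None,
                      slope: float = CALIBRATION_SLOPE,
                      intercept: float = CALIBRATION_INTERCEPT) -> CalciumSeries:
    """Convert a luminescence series to calibrated p[Ca2+]i.

    ``denominator`` selects how the consumption rate k is normalised:
    ``grand_total`` divides each interval's counts by the total counts of
    the run (the literal convention); ``remaining`` divides by the counts
    still unconsumed at the start of the interval (the classical
    fractional-rate convention).  ``background`` (e.g. a series from an
    inactive-mutant control) is subtracted interval-wise before
    calibration, clipped at zero.
    """
    if denominator not in ("grand_total", "remaining"):
        raise ValueError("denominator must be 'grand_total' or 'remaining'")
    if log_base <= 1:
        raise ValueError("log base must exceed 1")
    counts = series.counts_per_s.astype(float).copy()
    if background is not None:
        m = min(counts.size, background.counts_per_s.size)
        counts[:m] = np.clip(counts[:m] - background.counts_per_s[:m], 0.0, None)
    if denominator == "grand_total":
        k = counts / series.total_counts
    else:
        consumed_before = np.concatenate([[0.0], np.cumsum(counts)[:-1]])
        remaining = series.total_counts - consumed_before
        k = np.where(remaining > 0, counts / np.maximum(remaining, 1e-300), np.inf)
    undefined = k <= 0
    with np.errstate(divide="ignore"):
        logk = np.log(np.where(undefined, 1.0, k)) / np.log(log_base)
    pca = slope * (-logk) + intercept
    pca = np.where(undefined, np.nan, pca)
    ca = np.power(log_base, -pca)
    return CalciumSeries(k, pca, ca, undefined)


def pca_to_rate(pca, log_base: float = 10.0,
                slope: float = CALIBRATION_SLOPE,
                intercept: float = CALIBRATION_INTERCEPT) -> np.ndarray:
    """Invert the calibration line: consumption rate k for a given pCa."""
    pca = np.asarray(pca, dtype=float)
    return np.power(log_base, -(pca - intercept) / slope)


def logistic_effect(c, e_min: float, e_max: float, ic50: float, hill: float,
                    direction: str = "inhibition",
                    form: str = "corrected") -> np.ndarray:
    """Four-parameter logistic effect at concentration(s) ``c``.

    corrected: E(c) = E_min + (E_max - E_min) / (1 + x^h), with
    x = c/IC50 for inhibition (E -> E_max as c -> 0) and x = IC50/c for
    activation.  The literal form uses numerator (E_max + E_min).
    """
    c = np.asarray(c, dtype=float)
    if ic50 <= 0:
        raise ValueError("IC50 must be positive")
    if direction not in ("inhibition", "activation"):
        raise ValueError("direction must be 'inhibition' or 'activation'")
    if form not in ("corrected", "literal"):
        raise ValueError("form must be 'corrected' or 'literal'")
    x = c / ic50 if direction == "inhibition" else ic50 / c
    numer = (e_max - e_min) if form == "corrected" else (e_max + e_min)
    return e_min + numer / (1.0 + np.power(x, hill))


def fit_dose_response(dataset: DoseResponseDataset,
                      direction: str = "inhibition",
                      form: str = "corrected") -> DoseResponseFit:
    """Nonlinear least-squares fit of the logistic equation.

    Initial values come from the data: E_max/E_min from the mean effects
    at the extreme concentrations, IC50 from the geometric midpoint of
    the concentration range, Hill coefficient 1.  Standard errors are
    taken from the fit covariance.  Non-convergence (including degenerate
    flat data) is flagged, never silent.
    """
    df = dataset.data
    concs = df["conc_uM"].to_numpy(float)
    effects = df["effect"].to_numpy(float)
    if not np.all(np.isfinite(effects)):
        raise ValueError("effects must be finite")
    if dataset.concentrations.size < 4:
        raise ValueError("need at least 4 distinct concentrations")

    if float(np.std(effects)) < 1e-12 * max(1.0, abs(float(np.mean(effects)))):
        return DoseResponseFit(float(np.mean(effects)), float(np.mean(effects)),
                               float("nan"), float("nan"), {}, 0.0, False,
                               form, direction)

    import lmfit

    by_conc = df.groupby("conc_uM")["effect"].mean()
    low_c, high_c = by_conc.index.min(), by_conc.index.max()
    if direction == "inhibition":
        e_max0, e_min0 = by_conc.loc[low_c], by_conc.loc[high_c]
    else:
        e_max0, e_min0 = by_conc.loc[high_c], by_conc.loc[low_c]
    ic50_0 = float(np.sqrt(low_c * high_c))

    model = lmfit.Model(
        lambda c, e_min, e_max, ic50, hill: logistic_effect(
            c, e_min, e_max, ic50, hill, direction=direction, form=form),
        independent_vars=["c"])
    params = model.make_params(
        e_min=float(e_min0), e_max=float(e_max0), ic50=ic50_0, hill=1.0)
    params["ic50"].set(min=1e-12)
    params["hill"].set(min=1e-3, max=20.0)
    result = model.fit(effects, params, c=concs)

    stderr = {name: (p.stderr if p.stderr is not None else float("nan"))
              for name, p in result.params.items()}
    return DoseResponseFit(
        e_min=float(result.params["e_min"].value),
        e_max=float(result.params["e_max"].value),
        ic50_uM=float(result.params["ic50"].value),
        hill=float(result.params["hill"].value),
        stderr=stderr,
        residual_norm=float(np.linalg.norm(result.residual)),
        converged=bool(result.success),
        form=form,
        direction=direction,
    )
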