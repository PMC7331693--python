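"""Histogram analysis and disease scoring of regional expansion maps.

The fractional-expansion histogram of a lung, area-normalised to 1, is the
central descriptor of ventilation distribution: healthy lungs are tall and
narrow, heterogeneous ("patchy") disease widens the peak, and clustered
muco-obstruction splits it into two modes. Two scores summarise this shape:

* **HD** (heterogeneous disease) — the interquartile range of an animal's
  expansion values divided by the mean littermate IQR, ``IQR / IQR_L``. By
  construction the littermate group averages exactly 1, and larger values
  indicate patchier ventilation.
* **CD** (clustered disease) — ``(mu2 - mu1) / mu2`` from the two modes of a
  least-squares double-Gaussian fit to the normalised histogram; 0 for a
  unimodal profile, approaching 1 as a low-expansion mode separates.

The double Gaussian is a basis-function fit, not a distributional
assumption: a smooth two-bump curve is regressed onto the histogram so its
mode locations can be read off. The fit is exposed statsmodels-style as
:class:`DoubleGaussianModel` / :class:`DoubleGaussianResults`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, optimize

from .core import DegenerateCohortError, FitFailureError, NormalizationError, XVError
from .expansion import ExpansionMap

__all__ = [
    "ExpansionHistogram",
    "expansion_histogram",
    "DoubleGaussianModel",
    "DoubleGaussianResults",
    "fit_double_gaussian",
    "cd_score",
    "CohortTable",
    "cohort_scores",
]

#: minor-component negligibility: amplitude ratio below this, or fitted
#: weight below 2% of the total area, marks the fit as effectively unimodal
AMPLITUDE_RATIO_FLOOR = 0.01
WEIGHT_FLOOR = 0.02


@dataclass
class ExpansionHistogram:
    """Area-normalised expansion histogram plus raw-value IQR.

    ``density`` integrates to 1 over ``bin_edges``; ``iqr`` is computed from
    the raw (unbinned) in-mask values with linear quantile interpolation, so
    it is invariant to the bin count.
    """

    bin_edges: np.ndarray
    density: np.ndarray
    iqr: float
    n_values: int
    flagged: bool = False
    meta: dict = field(default_factory=dict)

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def bin_widths(self) -> np.ndarray:
        return np.diff(self.bin_edges)

    @property
    def area(self) -> float:
        return float(np.sum(self.density * self.bin_widths))


def expansion_histogram(
    emap: ExpansionMap | np.ndarray, n_bins: int = 50, min_values: int = 100
) -> ExpansionHistogram:
    """Histogram the in-mask expansion values with unit area.

    Accepts an :class:`ExpansionMap` or a flat array of values. Fewer than
    ``min_values`` values produces a warning and a flagged result; an empty
    mask is an error.
    """
    if isinstance(emap, ExpansionMap):
        vals = emap.in_mask_values()
    else:
        vals = np.asarray(emap, dtype=float).ravel()
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise XVError("no expansion values to histogram (empty mask?)")
    flagged = vals.size < min_values
    if flagged:
        warnings.warn(
            f"only {vals.size} expansion values (< {min_values}); histogram flagged",
            stacklevel=2,
        )
    lo, hi = float(vals.min()), float(vals.max())
    if hi == lo:  # all values identical: one degenerate bin around the value
        hi = lo + max(abs(lo), 1.0) * 1e-9
    density, edges = np.histogram(vals, bins=n_bins, range=(lo, hi), density=True)
    q25, q75 = np.percentile(vals, [25.0, 75.0])  # linear interpolation
    return ExpansionHistogram(
        bin_edges=edges,
        density=density,
        iqr=float(q75 - q25),
        n_values=int(vals.size),
        flagged=flagged,
    )


def _double_gaussian(x, a1, mu1, s1, a2, mu2, s2):
    return a1 * np.exp(-0.5 * ((x - mu1) / s1) ** 2) + a2 * np.exp(
        -0.5 * ((x - mu2) / s2) ** 2
    )


class DoubleGaussianModel:
    """Least-squares double-Gaussian model of a normalised expansion histogram.

    The regression target is the histogram density over bin centres (matching
    the least-squares-on-histogram formulation, rather than a likelihood over
    raw values). ``fit()`` runs a small multi-start: (i) single-mode moments
    duplicated with +/- 1 SD offsets, (ii) the two tallest local maxima of a
    smoothed density; the best residual wins. Amplitudes are constrained
    non-negative and spreads bounded below by half a bin width.
    """

    def __init__(self, hist: ExpansionHistogram):
        if len(hist.density) < 8:
            raise XVError("need at least 8 histogram bins for a double-Gaussian fit")
        self.hist = hist
        self.x = hist.bin_centers
        self.y = hist.density

    @classmethod
    def from_expansion_map(cls, emap: ExpansionMap, n_bins: int = 50) -> "DoubleGaussianModel":
        return cls(expansion_histogram(emap, n_bins=n_bins))

    # -- initialisation -------------------------------------------------
    def _starts(self) -> list[np.ndarray]:
        x, y = self.x, self.y
        w = y / max(y.sum(), 1e-300)
        m = float((x * w).sum())
        sd = float(np.sqrt(((x - m) ** 2 * w).sum()))
        sd = max(sd, 0.5 * float(np.mean(self.hist.bin_widths)))
        peak = float(y.max())
        starts = [
            np.array([0.6 * peak, m - sd, 0.7 * sd, 0.6 * peak, m + sd, 0.7 * sd]),
            np.array([peak, m, sd, 0.2 * peak, m - sd, 0.5 * sd]),
        ]
        smooth = ndimage.gaussian_filter1d(y, 2.0)
        interior = np.zeros_like(smooth, dtype=bool)
        interior[1:-1] = (smooth[1:-1] >= smooth[:-2]) & (smooth[1:-1] >= smooth[2:])
        locs = np.nonzero(interior)[0]
        if locs.size >= 2:
            top = locs[np.argsort(smooth[locs])][-2:]
            i1, i2 = sorted(top)
            starts.append(
                np.array(
                    [
                        max(smooth[i1], 0.1 * peak),
                        x[i1],
                        max(0.5 * sd, abs(x[i2] - x[i1]) / 4),
                        max(smooth[i2], 0.1 * peak),
                        x[i2],
                        max(0.5 * sd, abs(x[i2] - x[i1]) / 4),
                    ]
                )
            )
        elif locs.size == 1:
            i1 = locs[0]
            starts.append(np.array([smooth[i1], x[i1], sd, 0.3 * smooth[i1], x[i1] - sd, sd]))
        return starts

    def fit(self) -> "DoubleGaussianResults":
        x, y = self.x, self.y
        sigma_floor = 0.5 * float(np.mean(self.hist.bin_widths))
        span = float(x[-1] - x[0]) if x[-1] > x[0] else max(abs(x[0]), 1e-9)
        lo = [0.0, x[0] - span, sigma_floor, 0.0, x[0] - span, sigma_floor]
        hi = [np.inf, x[-1] + span, 10 * span, np.inf, x[-1] + span, 10 * span]

        best = None
        best_ssr = np.inf
        for p0 in self._starts():
            p0 = np.clip(p0, lo, hi)
            try:
                popt, pcov = optimize.curve_fit(
                    _double_gaussian, x, y, p0=p0, bounds=(lo, hi), maxfev=20000
                )
            except (RuntimeError, ValueError):
                continue
            ssr = float(np.sum((y - _double_gaussian(x, *popt)) ** 2))
            if ssr < best_ssr:
                best, best_cov, best_ssr = popt, pcov, ssr
        if best is None:
            raise FitFailureError(
                "double-Gaussian fit failed from every start", best_residual=None
            )
        sst = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - best_ssr / sst if sst > 0 else 1.0
        return DoubleGaussianResults(
            model=self, params_raw=best, cov=best_cov, ssr=best_ssr, r_squared=r2
        )


@dataclass
class DoubleGaussianResults:
    """Fitted double-Gaussian parameters, canonically ordered ``mu1 <= mu2``.

    ``bse`` gives large-sample standard errors from the covariance of the
    least-squares estimate; ``cd`` applies the clustered-disease score with
    the negligible-minor-component rule.
    """

    model: DoubleGaussianModel
    params_raw: np.ndarray
    cov: np.ndarray
    ssr: float
    r_squared: float

    def __post_init__(self) -> None:
        a1, mu1, s1, a2, mu2, s2 = self.params_raw
        if mu1 > mu2:  # canonical ordering, permute covariance alike
            perm = [3, 4, 5, 0, 1, 2]
            self.params_raw = self.params_raw[perm]
            self.cov = self.cov[np.ix_(perm, perm)]

    @property
    def params(self) -> dict:
        a1, mu1, s1, a2, mu2, s2 = self.params_raw
        return {"a1": a1, "mu1": mu1, "sigma1": s1, "a2": a2, "mu2": mu2, "sigma2": s2}

    @property
    def bse(self) -> dict:
        se = np.sqrt(np.clip(np.diag(self.cov), 0, None))
        names = ["a1", "mu1", "sigma1", "a2", "mu2", "sigma2"]
        return dict(zip(names, se))

    @property
    def weights(self) -> tuple[float, float]:
        """Area under each component, a1*s1*sqrt(2 pi) etc."""
        a1, _, s1, a2, _, s2 = self.params_raw
        c = np.sqrt(2 * np.pi)
        return float(a1 * s1 * c), float(a2 * s2 * c)

    @property
    def unimodal(self) -> bool:
        """True when the minor component is negligible (amplitude ratio < 1%
        or component weight < 2% of the fitted area)."""
        a1, _, _, a2, _, _ = self.params_raw
        w1, w2 = self.weights
        amax, amin = max(a1, a2), min(a1, a2)
        wtot = w1 + w2
        if amax == 0 or wtot == 0:
            return True
        return (amin / amax < AMPLITUDE_RATIO_FLOOR) or (min(w1, w2) / wtot < WEIGHT_FLOOR)

    @property
    def cd(self) -> float:
        return cd_score(self)

    def predict(self, x: np.ndarray) -> np.ndarray:
        return _double_gaussian(np.asarray(x, dtype=float), *self.params_raw)

    def summary(self) -> str:
        p, se = self.params, self.bse
        lines = [
            "Double-Gaussian expansion-histogram fit",
            "=" * 47,
            f"{'param':>8} {'estimate':>12} {'std err':>12}",
        ]
        for k in ["a1", "mu1", "sigma1", "a2", "mu2", "sigma2"]:
            lines.append(f"{k:>8} {p[k]:>12.5g} {se[k]:>12.3g}")
        lines.append("-" * 47)
        lines.append(f"R^2: {self.r_squared:.4f}   SSR: {self.ssr:.4g}")
        lines.append(f"CD = (mu2 - mu1)/mu2: {self.cd:.4f}" + ("  [unimodal]" if self.unimodal else ""))
        return "\n".join(lines)


def fit_double_gaussian(hist: ExpansionHistogram) -> DoubleGaussianResults:
    """Functional wrapper: least-squares double-Gaussian fit of a histogram."""
    return DoubleGaussianModel(hist).fit()


def cd_score(fit: DoubleGaussianResults) -> float:
    """Clustered-disease score (mu2 - mu1)/mu2 after canonical ordering.

    Returns 0 when the minor component is negligible (the histogram is
    effectively unimodal). Requires mu2 > 0.
    """
    mu1 = fit.params["mu1"]
    mu2 = fit.params["mu2"]
    if mu2 <= 0:
        raise XVError("cd_score requires mu2 > 0")
    if fit.unimodal:
        return 0.0
    return float((mu2 - mu1) / mu2)


@dataclass
class CohortTable:
    """Per-animal scores plus the cohort littermate normalisation constant."""

    table: pd.DataFrame
    iqr_L: float

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False, float_format="%.10g")

    def to_json(self, path) -> None:
        payload = {"iqr_L": self.iqr_L, "animals": self.table.to_dict(orient="records")}
        import json

        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, default=float)


def cohort_scores(
    records: list[tuple[str, str, ExpansionMap]],
    n_bins: int = 50,
    littermate_stat: str = "mean",
    extras: dict[str, dict] | None = None,
) -> CohortTable:
    """Score a cohort: per-animal IQR, HD, CD, R^2; littermate-normalised.

    Parameters
    ----------
    records:
        ``(id, group, ExpansionMap)`` with group in {"disease", "littermate"}.
    littermate_stat:
        "mean" (the reference definition of ``IQR_L``) or "median".
    extras:
        Optional per-animal extra columns, e.g. ``{"M3": {"tau": 0.13,
        "fractional_tidal_volume": 0.09, "heart_blur_flag": False}}``. An
        animal with ``heart_blur_flag`` True gets no CD (reported as NaN).
    """
    extras = extras or {}
    rows = []
    for animal_id, group, emap in records:
        if group not in ("disease", "littermate"):
            raise XVError(f"unknown group {group!r} for animal {animal_id!r}")
        hist = expansion_histogram(emap, n_bins=n_bins)
        extra = extras.get(animal_id, {})
        blur = bool(extra.get("heart_blur_flag", False))
        try:
            fit = fit_double_gaussian(hist)
            r2 = fit.r_squared
            cd = np.nan if blur else fit.cd
        except FitFailureError:
            r2, cd = np.nan, np.nan
        rows.append(
            {
                "id": animal_id,
                "group": group,
                "iqr": hist.iqr,
                "hd": np.nan,
                "cd": cd,
                "tau": extra.get("tau", np.nan),
                "fractional_tidal_volume": extra.get("fractional_tidal_volume", np.nan),
                "r_squared": r2,
                "heart_blur_flag": blur,
            }
        )
    df = pd.DataFrame(rows)
    litter = df.loc[df["group"] == "littermate", "iqr"]
    if litter.empty:
        raise NormalizationError("cohort has no littermate records to normalise against")
    iqr_L = float(litter.mean() if littermate_stat == "mean" else litter.median())
    if iqr_L <= 0:
        raise DegenerateCohortError("littermate IQR_L is zero; HD undefined")
    df["hd"] = df["iqr"] / iqr_L
    return CohortTable(table=df, iqr_L=iqr_L)
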