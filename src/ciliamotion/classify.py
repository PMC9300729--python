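"""Motion-mode classification from the anomalous-exponent distribution.

The distribution of parallel exponents α_// pooled over many windows is
bimodal: a broad diffusive/subdiffusive component and a narrow directed
component near α = 2. A two-Gaussian least-squares fit to the histogram
yields the component fractions; windows are then classified against a
fixed threshold (default α = 1.4, the intersection of the two components
reported for this system), and fractions are summarized per ciliary
segment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .geometry import SegmentTable

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))
DEFAULT_THRESHOLD = 1.4
SUB_THRESHOLD = 1.0


class MixtureFitError(RuntimeError):
    """Two-Gaussian histogram fit failed to converge."""


@dataclass(frozen=True)
class MixtureFit:
    """Two-Gaussian decomposition of the α_// histogram.

    ``weights`` are the area fractions of the (lower-mean, higher-mean)
    components and sum to 1; widths are stored as FWHM
    (σ = FWHM / (2·√(2·ln 2))).
    """

    weights: tuple[float, float]
    means: tuple[float, float]
    fwhms: tuple[float, float]
    threshold: float
    bin_width: float
    n: int

    @property
    def sigmas(self) -> tuple[float, float]:
        return (self.fwhms[0] * FWHM_TO_SIGMA, self.fwhms[1] * FWHM_TO_SIGMA)

    def intersection(self) -> float:
        """α where the two area-normalized component densities cross.

        Solved numerically between the means. This need not coincide with
        the fixed default threshold; both conventions are exposed and the
        fixed constant is the default for classification.
        """
        from scipy.optimize import brentq

        w, m, s = self.weights, self.means, self.sigmas

        def diff(x):
            return w[0] / s[0] * np.exp(-0.5 * ((x - m[0]) / s[0]) ** 2) - \
                w[1] / s[1] * np.exp(-0.5 * ((x - m[1]) / s[1]) ** 2)

        return float(brentq(diff, m[0], m[1]))


def _two_gauss(x, a1, m1, s1, a2, m2, s2):
    return a1 * np.exp(-0.5 * ((x - m1) / s1) ** 2) + \
        a2 * np.exp(-0.5 * ((x - m2) / s2) ** 2)


def fit_alpha_mixture(alphas, bin_width: float = 0.1,
                      min_samples: int = 100) -> MixtureFit:
    """Fit a sum of two Gaussians to the histogram of α values.

    The histogram (default bin width 0.1) is fit by least squares with six
    free parameters (two amplitudes, means, widths); component fractions
    are computed from areas (amplitude·σ) and components are ordered by
    mean. Degenerate samples raise :class:`MixtureFitError`.
    """
    a = np.asarray(alphas, dtype=float)
    a = a[np.isfinite(a)]
    if a.size < min_samples:
        raise ValueError(f"need >= {min_samples} valid alpha values, got {a.size}")
    lo = np.floor(a.min() / bin_width) * bin_width
    hi = np.ceil(a.max() / bin_width) * bin_width
    if hi - lo < 2 * bin_width:
        raise MixtureFitError("degenerate alpha sample: no spread to fit")
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    counts, edges = np.histogram(a, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])

    tried = []
    # split initialisations: dominant-plus-minor split at a high quantile
    # first (typical shape of these distributions), then a median split
    inits = []
    for q in (0.8, 0.5):
        cut = np.quantile(a, q)
        lo_part, hi_part = a[a <= cut], a[a > cut]
        if lo_part.size < 2 or hi_part.size < 2:
            continue
        inits.append(
            (
                counts.max(), lo_part.mean(), max(lo_part.std(), bin_width),
                counts.max() / 4, hi_part.mean(), max(hi_part.std(), bin_width),
            )
        )
    inits.append((counts.max(), 0.6, 0.25, counts.max() / 5, 1.8, 0.1))
    for p0 in inits:
        try:
            popt, _ = curve_fit(
                _two_gauss, centers, counts, p0=p0, maxfev=5000,
                bounds=([0, lo, bin_width / 10, 0, lo, bin_width / 10],
                        [np.inf, hi, hi - lo, np.inf, hi, hi - lo]),
            )
        except RuntimeError:
            tried.append(p0)
            continue
        a1, m1, s1, a2, m2, s2 = popt
        if m1 > m2:
            a1, m1, s1, a2, m2, s2 = a2, m2, s2, a1, m1, s1
        area1, area2 = a1 * s1, a2 * s2
        total = area1 + area2
        if total <= 0:
            tried.append(p0)
            continue
        return MixtureFit(
            weights=(area1 / total, area2 / total),
            means=(float(m1), float(m2)),
            fwhms=(float(s1 / FWHM_TO_SIGMA), float(s2 / FWHM_TO_SIGMA)),
            threshold=DEFAULT_THRESHOLD,
            bin_width=bin_width,
            n=int(a.size),
        )
    raise MixtureFitError(f"no convergence; initializations tried: {tried or inits}")


def classify_windows(estimates: pd.DataFrame,
                     threshold: float = DEFAULT_THRESHOLD,
                     sub_threshold: float = SUB_THRESHOLD) -> pd.DataFrame:
    """Label each window estimate by motion mode.

    ``motion`` is "directed" when α_// ≥ threshold (boundary inclusive),
    else "diffusive"; diffusive windows with α_// < sub_threshold get the
    sub-label "subdiffusive" in ``motion_sub``.
    """
    out = estimates.copy()
    directed = out["alpha_par"] >= threshold
    out["motion"] = np.where(directed, "directed", "diffusive")
    valid_col = "valid_par" if "valid_par" in out else "valid"
    out.loc[~out[valid_col].astype(bool), "motion"] = "invalid"
    sub = (~directed) & (out["alpha_par"] < sub_threshold)
    out["motion_sub"] = out["motion"]
    out.loc[sub & (out["motion"] == "diffusive"), "motion_sub"] = "subdiffusive"
    return out


def segment_summaries(labeled: pd.DataFrame,
                      table: SegmentTable | None = None) -> pd.DataFrame:
    """Per-segment window counts, directed fraction and class means.

    Segments with no windows are reported with n = 0 and NaN fractions so
    the output always covers the full segment table.
    """
    table = table or SegmentTable()
    rows = []
    valid = labeled[labeled["motion"] != "invalid"] if len(labeled) else labeled
    for seg in table.labels:
        sub = valid[valid["segment"] == seg] if len(valid) else valid
        n = len(sub)
        if n == 0:
            rows.append(
                {"segment": seg, "n_windows": 0, "frac_directed": np.nan,
                 "mean_alpha_diffusive": np.nan, "mean_alpha_directed": np.nan}
            )
            continue
        directed = sub[sub["motion"] == "directed"]
        diffusive = sub[sub["motion"] == "diffusive"]
        rows.append(
            {
                "segment": seg,
                "n_windows": n,
                "frac_directed": len(directed) / n,
                "mean_alpha_diffusive": diffusive["alpha_par"].mean()
                if len(diffusive) else np.nan,
                "mean_alpha_directed": directed["alpha_par"].mean()
                if len(directed) else np.nan,
            }
        )
    return pd.DataFrame(rows)


def alpha_samples_by_segment(labeled: pd.DataFrame) -> dict[str, np.ndarray]:
    """α_// samples per segment, for violin-style plotting/export."""
    out: dict[str, np.ndarray] = {}
    valid = labeled[labeled["motion"] != "invalid"]
    for seg, sub in valid.groupby("segment"):
        out[str(seg)] = sub["alpha_par"].to_numpy()
    return out


def em_cross_check(alphas, seed: int = 0):
    """Raw-sample two-component Gaussian EM, as a validation utility.

    Independent of the histogram fit; returns (weights, means, sigmas)
    ordered by mean. Used to sanity-check the histogram-based mixture.
    """
    from sklearn.mixture import GaussianMixture

    a = np.asarray(alphas, dtype=float).reshape(-1, 1)
    gm = GaussianMixture(n_components=2, random_state=seed, n_init=3).fit(a)
    order = np.argsort(gm.means_.ravel())
    return (
        tuple(gm.weights_.ravel()[order]),
        tuple(gm.means_.ravel()[order]),
        tuple(np.sqrt(gm.covariances_.ravel()[order])),
    )
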