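"""Converting pairwise LOD scores to IBD probabilities.

Upstream pairwise IBD callers in the Beagle / Refined IBD family report a
LOD score: the base-10 log likelihood ratio of one shared haplotype versus
none.  Bayes' rule for odds turns it into a posterior odds

    o = O(IBD) * 10**lod,      O(IBD) = epsilon / (1 - epsilon),

where ``epsilon`` is the genome-average prior probability that a random
haplotype pair is IBD at a random locus (0.0046 by default, estimated from
simulated European-like data).  The theoretical conversion would then be
``p = o / (1 + o)``, but the observed relationship between LOD score and
true-positive rate deviates from it, and the default mode instead uses a
rational curve of the same form fitted to that relationship:

    p = (2*o + a*f) / (o + f)
    f = epsilon * 1e3 / 0.997 - epsilon * 1e3
    a = (1 - lod)**3 / 7   if lod <= 1,   else  -0.15

The raw curve exceeds 1 for large LOD scores, so outputs are clamped to
``[p_min, p_max]`` (defaults ``[epsilon, 0.999]``); the upper clamp keeps
configuration probabilities finite while still allowing the sampler's
pin-at-0.99 rule to engage.  Uncalled pairs receive exactly ``epsilon``.

Because the fitted constants reflect one simulated demography, an
``empirical`` mode is provided that rebuilds a monotone LOD-to-probability
function from labelled calls (binned true-positive fractions followed by
isotonic regression).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
from sklearn.isotonic import IsotonicRegression

from .graph import DEFAULT_EPSILON

__all__ = [
    "CalibrationParams",
    "EmpiricalCalibration",
    "lod_to_probability",
    "uncalled_probability",
    "fit_empirical_calibration",
]

MODES = ("curve", "odds", "empirical")


@dataclass(frozen=True)
class CalibrationParams:
    """Prior, clamping bounds and conversion mode.

    ``p_min`` defaults to ``epsilon`` when left as ``None``; outputs never
    reach exactly 0 or 1, which keeps every configuration probability
    strictly positive downstream.
    """

    epsilon: float = DEFAULT_EPSILON
    p_min: float | None = None
    p_max: float = 0.999
    mode: str = "curve"

    def __post_init__(self) -> None:
        if not 0.0 < self.epsilon < self.p_max < 1.0:
            raise ValueError("require 0 < epsilon < p_max < 1")
        if self.p_min is not None and not 0.0 < self.p_min <= self.p_max:
            raise ValueError("require 0 < p_min <= p_max")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")

    @property
    def lower(self) -> float:
        return self.epsilon if self.p_min is None else self.p_min


def lod_to_probability(
    lod,
    params: CalibrationParams | None = None,
    empirical: "EmpiricalCalibration | Callable | None" = None,
):
    """IBD probability for a LOD score (scalar or array).

    In ``curve`` mode the fitted rational curve described in the module
    docstring is evaluated; in ``odds`` mode the plain Bayes posterior
    ``o / (1 + o)``; in ``empirical`` mode the supplied fitted function.
    All modes clamp to ``[p_min, p_max]``.
    """
    params = params or CalibrationParams()
    arr = np.asarray(lod, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("LOD scores must be finite")
    eps = params.epsilon
    prior_odds = eps / (1.0 - eps)
    o = prior_odds * 10.0 ** arr
    if params.mode == "odds":
        p = o / (1.0 + o)
    elif params.mode == "curve":
        f = eps * 1e3 / 0.997 - eps * 1e3
        a = np.where(arr <= 1.0, (1.0 - arr) ** 3 / 7.0, -0.15)
        p = (2.0 * o + a * f) / (o + f)
    else:
        if empirical is None:
            raise ValueError("empirical mode requires a fitted calibration function")
        p = np.asarray(empirical(arr), dtype=float)
    p = np.clip(p, params.lower, params.p_max)
    if np.ndim(lod) == 0:
        return float(p)
    return p


def uncalled_probability(params: CalibrationParams | None = None) -> float:
    """Probability assigned to a pair with no call at all: the prior."""
    params = params or CalibrationParams()
    return params.epsilon


@dataclass(frozen=True)
class EmpiricalCalibration:
    """Monotone LOD-to-probability function fitted from labelled calls.

    Piecewise-linear interpolation through isotonic-regressed per-bin
    true-positive fractions, clamped to ``[p_min, p_max]`` and held
    constant outside the fitted LOD range.
    """

    bin_centers: np.ndarray
    fitted: np.ndarray
    p_min: float
    p_max: float

    def __call__(self, lod):
        arr = np.asarray(lod, dtype=float)
        p = np.interp(arr, self.bin_centers, self.fitted)
        p = np.clip(p, self.p_min, self.p_max)
        if np.ndim(lod) == 0:
            return float(p)
        return p


def fit_empirical_calibration(
    pairs: Iterable[tuple[float, bool]] | Sequence,
    bins: int = 10,
    params: CalibrationParams | None = None,
) -> EmpiricalCalibration:
    """Fit a monotone LOD-to-probability curve from ``(lod, is_true)`` labels.

    Calls are grouped into ``bins`` equal-count LOD bins; the per-bin
    true-positive fraction is then made non-decreasing by isotonic
    regression (pool-adjacent-violators), weighted by bin counts.
    """
    data = np.asarray([(float(l), bool(t)) for l, t in pairs], dtype=float)
    if data.size == 0:
        raise ValueError("no labelled calls to fit")
    params = params or CalibrationParams()
    lods = data[:, 0]
    truth = data[:, 1]
    if bins < 2:
        raise ValueError("need at least two bins")
    edges = np.quantile(lods, np.linspace(0.0, 1.0, bins + 1))
    edges = np.unique(edges)
    if len(edges) < 2:
        # all LOD scores identical: a single degenerate bin
        raise ValueError("need at least two bins with distinct LOD scores")
    idx = np.clip(np.searchsorted(edges, lods, side="right") - 1, 0, len(edges) - 2)
    centers, fracs, counts = [], [], []
    for b in range(len(edges) - 1):
        mask = idx == b
        if not mask.any():
            continue
        centers.append(float(lods[mask].mean()))
        fracs.append(float(truth[mask].mean()))
        counts.append(int(mask.sum()))
    if len(centers) < 2:
        raise ValueError("need at least two non-empty bins")
    order = np.argsort(centers)
    centers = np.asarray(centers)[order]
    fracs = np.asarray(fracs)[order]
    counts = np.asarray(counts, dtype=float)[order]
    iso = IsotonicRegression(increasing=True)
    fitted = iso.fit_transform(centers, fracs, sample_weight=counts)
    return EmpiricalCalibration(
        bin_centers=centers,
        fitted=np.asarray(fitted, dtype=float),
        p_min=params.lower,
        p_max=params.p_max,
    )
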