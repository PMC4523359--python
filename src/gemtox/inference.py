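"""Community end points derived from posterior ensembles.

Turns composition draws into the quantities an ecotoxicologist reports:

* posterior Shannon-diversity curves with credible bands (plus raw per-site
  plug-in points);
* per-OTU response classification from the Delta statistic — the difference
  between an OTU's average probability at low contamination (covariate at or
  below a split, by default the median observed level) and at high
  contamination.  If the 95% credible interval of Delta lies entirely above
  zero the OTU is *decreasing* with the contaminant; entirely below zero,
  *increasing*; otherwise it gets no classification;
* Bray-Curtis dissimilarity curves against the uncontaminated baseline, and
  ECx effective concentrations obtained by inverting them at the threshold
  D_x = D0 + (x/100)(1 - D0), where D0 is the baseline self-dissimilarity
  (two uncontaminated communities already differ somewhat).  Credible bounds
  come from the running-maximum ("increasing envelope") of the credible-band
  curves, which is conservative;
* sensitivity/specificity of the classification against an external list of
  genera expected to increase under contamination, optionally weighted by
  OTU relative abundance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from gemtox.ensemble import PosteriorEnsemble
from gemtox.gem import shannon_index
from gemtox.tables import CovariateVector, OTUCountTable

__all__ = [
    "DiversityEstimate",
    "DeltaPosterior",
    "DissimilarityCurve",
    "ECxEstimate",
    "diversity_curve",
    "raw_shannon_points",
    "delta_statistic",
    "classify_otus",
    "classify_from_raw",
    "bray_curtis",
    "dissimilarity_curve",
    "ecx",
    "sensitivity_specificity",
]


@dataclass(frozen=True)
class DiversityEstimate:
    """Shannon-diversity curve: posterior mean and central credible band."""

    grid: np.ndarray
    mean: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    level: float

    def __post_init__(self) -> None:
        if not (0 < self.level < 1):
            raise ValueError("level must lie in (0, 1)")
        if ((self.lower > self.mean + 1e-12) | (self.mean > self.upper + 1e-12)).any():
            raise ValueError("must satisfy lower <= mean <= upper")


@dataclass(frozen=True)
class DeltaPosterior:
    """Posterior draws of Delta_j = avg p_j(low) - avg p_j(high) per OTU."""

    draws: np.ndarray  # (n_draws, n_otus)
    otu_ids: tuple[str, ...]
    genera: tuple[str | None, ...] | None
    split: float
    low_set: np.ndarray  # grid-point indices, covariate <= split
    high_set: np.ndarray

    def __post_init__(self) -> None:
        if len(self.low_set) == 0 or len(self.high_set) == 0:
            raise ValueError("low and high grid sets must both be non-empty")
        if set(self.low_set.tolist()) & set(self.high_set.tolist()):
            raise ValueError("low and high grid sets must be disjoint")


@dataclass(frozen=True)
class DissimilarityCurve:
    """Bray-Curtis dissimilarity to the covariate-zero community, per draw."""

    grid: np.ndarray
    draws: np.ndarray  # (n_draws, n_points)
    mean: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    d0: float
    level: float

    def __post_init__(self) -> None:
        for arr in (self.draws, self.mean, self.lower, self.upper):
            a = np.asarray(arr)
            if (a < -1e-12).any() or (a > 1 + 1e-12).any():
                raise ValueError("dissimilarities must lie in [0, 1]")
        if not 0.0 <= self.d0 <= 1.0:
            raise ValueError("d0 must lie in [0, 1]")


@dataclass(frozen=True)
class ECxEstimate:
    """Effective concentration for an x% community change.

    ``censored_low`` / ``censored_high`` flag credible bounds pinned at the
    covariate origin / grid maximum (the bound is then a one-sided
    statement, not a resolved crossing).
    """

    x: float
    threshold: float
    ec: float
    lower: float
    upper: float
    censored_low: bool = False
    censored_high: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.x < 100):
            raise ValueError("x must lie in (0, 100)")
        if not (self.lower - 1e-9 <= self.ec <= self.upper + 1e-9):
            raise ValueError("bounds must bracket the estimate")


def _central_interval(draws: np.ndarray, level: float, axis: int = 0):
    alpha = (1.0 - level) / 2.0
    lower = np.quantile(draws, alpha, axis=axis)
    upper = np.quantile(draws, 1.0 - alpha, axis=axis)
    return lower, upper


def diversity_curve(ensemble: PosteriorEnsemble, level: float = 0.95
                    ) -> DiversityEstimate:
    """Posterior Shannon diversity at every ensemble point.

    The index is computed over the truncated stick weights of each draw
    (the residual tail slot is excluded), then summarized pointwise by the
    mean and a central credible interval.
    """
    H = shannon_index(ensemble.compositions[:, :, :-1])  # (draws, points)
    lower, upper = _central_interval(H, level)
    return DiversityEstimate(grid=ensemble.grid.copy(), mean=H.mean(axis=0),
                             lower=lower, upper=upper, level=level)


def raw_shannon_points(table: OTUCountTable) -> np.ndarray:
    """Plug-in Shannon index of each site's raw relative abundances."""
    return shannon_index(table.relative_abundances().T)


def delta_statistic(ensemble: PosteriorEnsemble, split: float) -> DeltaPosterior:
    """Per-draw, per-OTU difference of average probability below vs above
    the covariate split (low minus high)."""
    grid = ensemble.grid
    if not (grid.min() <= split < grid.max()):
        raise ValueError("split must lie strictly inside the grid range")
    low = np.flatnonzero(grid <= split)
    high = np.flatnonzero(grid > split)
    if low.size == 0 or high.size == 0:
        raise ValueError("split leaves an empty low or high side")
    p = ensemble.otu_probabilities()  # (draws, points, otus)
    draws = p[:, low].mean(axis=1) - p[:, high].mean(axis=1)
    return DeltaPosterior(draws=draws, otu_ids=ensemble.otu_ids,
                          genera=ensemble.genera, split=float(split),
                          low_set=low, high_set=high)


def classify_otus(delta: DeltaPosterior, level: float = 0.95) -> np.ndarray:
    """Label each OTU from the credible interval of its Delta statistic.

    Interval entirely above zero (probability drops at high contamination)
    -> ``decreasing``; entirely below zero -> ``increasing``; containing
    zero -> ``no_classification``.
    """
    if delta.draws.shape[0] < 100:
        raise ValueError("need at least 100 posterior draws to classify")
    lower, upper = _central_interval(delta.draws, level)
    labels = np.where(lower > 0, "decreasing",
                      np.where(upper < 0, "increasing", "no_classification"))
    return labels.astype(object)


def classify_from_raw(table: OTUCountTable, cov: CovariateVector,
                      split: float) -> np.ndarray:
    """Classify directly from raw relative abundances (no credible interval,
    so every OTU gets a label; exact ties break toward ``increasing``)."""
    low = cov.raw <= split
    high = ~low
    if not low.any() or not high.any():
        raise ValueError("split leaves an empty low or high side")
    props = table.relative_abundances()
    diff = props[:, low].mean(axis=1) - props[:, high].mean(axis=1)
    return np.where(diff > 0, "decreasing", "increasing").astype(object)


def bray_curtis(u: np.ndarray, v: np.ndarray) -> float:
    """Bray-Curtis dissimilarity 1 - sum_j min(u_j, v_j) between two
    compositions (vectors summing to one; include the tail slot as a
    pseudo-category rather than renormalizing).

    Equals half the L1 distance for compositions: 0 for identical
    communities, 1 for disjoint supports.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError("compositions must have equal length")
    for name, w in (("u", u), ("v", v)):
        if abs(w.sum() - 1.0) > 1e-8:
            raise ValueError(f"composition {name} must sum to 1")
    return float(1.0 - np.minimum(u, v).sum())


def dissimilarity_curve(ensemble: PosteriorEnsemble, level: float = 0.95,
                        d0_method: str = "posterior_cross_draw",
                        table: OTUCountTable | None = None,
                        cov: CovariateVector | None = None
                        ) -> DissimilarityCurve:
    """Within-draw Bray-Curtis dissimilarity between the covariate-zero
    composition and every grid point, summarized pointwise.

    The baseline level D0 estimates the dissimilarity between two
    uncontaminated communities:

    * ``posterior_cross_draw`` (default): mean Bray-Curtis between the
      zero-covariate compositions of pairs of distinct posterior draws;
    * ``raw_pairwise``: mean pairwise Bray-Curtis among the raw relative
      abundances of the zero-covariate sites (requires ``table``/``cov``).
    """
    grid = ensemble.grid
    zero = np.flatnonzero(grid == 0.0)
    if zero.size == 0:
        raise ValueError("prediction grid must include covariate 0")
    z = zero[0]
    comps = ensemble.compositions
    base = comps[:, z:z + 1, :]
    draws = 1.0 - np.minimum(base, comps).sum(axis=-1)  # (draws, points)
    draws = np.clip(draws, 0.0, 1.0)
    lower, upper = _central_interval(draws, level)

    if d0_method == "posterior_cross_draw":
        b = comps[:, z, :]
        partner = np.roll(np.arange(b.shape[0]), b.shape[0] // 2)
        d0 = float(np.clip(1.0 - np.minimum(b, b[partner]).sum(axis=-1), 0, 1).mean())
    elif d0_method == "raw_pairwise":
        if table is None or cov is None:
            raise ValueError("raw_pairwise D0 needs the count table and covariates")
        props = table.relative_abundances()[:, cov.baseline_mask].T
        if props.shape[0] < 2:
            raise ValueError("raw_pairwise D0 needs >= 2 uncontaminated sites")
        pairs = [1.0 - np.minimum(props[i], props[j]).sum()
                 for i in range(props.shape[0]) for j in range(i + 1, props.shape[0])]
        d0 = float(np.mean(pairs))
    else:
        raise ValueError(f"unknown d0_method {d0_method!r}")

    return DissimilarityCurve(grid=grid.copy(), draws=draws, mean=draws.mean(axis=0),
                              lower=lower, upper=upper, d0=d0, level=level)


def _first_crossing(grid: np.ndarray, y: np.ndarray, t: float,
                    snap_to_grid: bool = False) -> tuple[float, bool]:
    """Smallest covariate where y >= t (linear interpolation between the
    bracketing grid points).  Returns (value, right_censored)."""
    above = np.flatnonzero(y >= t)
    if above.size == 0:
        return float(grid[-1]), True
    i = int(above[0])
    if i == 0:
        return float(grid[0]), False
    if snap_to_grid:
        return float(grid[i]), False
    y0, y1 = y[i - 1], y[i]
    frac = 0.0 if y1 == y0 else (t - y0) / (y1 - y0)
    return float(grid[i - 1] + frac * (grid[i] - grid[i - 1])), False


def ecx(curve: DissimilarityCurve, x: float,
        snap_to_grid: bool = False) -> ECxEstimate:
    """Invert the dissimilarity curve at the x% community-change threshold.

    The threshold is D_x = D0 + (x/100)(1 - D0).  The point estimate is the
    smallest covariate where the posterior-mean curve reaches D_x (the
    conservative choice when the curve is non-monotone).  The credible
    bounds invert the *upper* band curve (earliest plausible crossing ->
    lower concentration bound) and the *lower* band curve (latest plausible
    crossing -> upper concentration bound), each first made nondecreasing by
    a running-maximum envelope.  Bounds pinned at covariate 0 or at the grid
    maximum are flagged as censored.
    """
    if not (0 < x < 100):
        raise ValueError("x must lie in (0, 100)")
    if not (0.0 <= curve.d0 < 1.0):
        raise ValueError("D0 must lie in [0, 1)")
    threshold = curve.d0 + (x / 100.0) * (1.0 - curve.d0)
    grid = curve.grid

    ec, ec_censored = _first_crossing(grid, curve.mean, threshold, snap_to_grid)
    upper_env = np.maximum.accumulate(curve.upper)
    lower_env = np.maximum.accumulate(curve.lower)
    lo, _ = _first_crossing(grid, upper_env, threshold, snap_to_grid)
    hi, hi_censored = _first_crossing(grid, lower_env, threshold, snap_to_grid)

    censored_low = lo <= grid[0]
    censored_high = hi_censored or ec_censored
    if ec_censored:
        hi = float(grid[-1])
    return ECxEstimate(x=float(x), threshold=float(threshold), ec=ec,
                       lower=min(lo, ec), upper=max(hi, ec),
                       censored_low=bool(censored_low),
                       censored_high=bool(censored_high))


def sensitivity_specificity(labels: np.ndarray, reference: set[str],
                            table: OTUCountTable
                            ) -> tuple[float, float, float, float]:
    """Classification performance against a reference genus list.

    OTUs of a reference genus are the positives; the predicted positive
    label is ``increasing``.  OTUs without a genus annotation or labelled
    ``no_classification`` are excluded.  Returns (sensitivity, specificity,
    abundance-weighted sensitivity, abundance-weighted specificity); an
    undefined rate (empty class) is returned as NaN with a warning.
    """
    labels = np.asarray(labels, dtype=object)
    if labels.size != table.n_otus:
        raise ValueError("one label per table OTU required")
    reference = {g.casefold() for g in reference}
    genera = table.genera if table.genera is not None else (None,) * table.n_otus
    weights = table.otu_totals / table.otu_totals.sum()

    tp = fn = tn = fp = 0.0
    wtp = wfn = wtn = wfp = 0.0
    for k, (label, genus) in enumerate(zip(labels, genera)):
        if genus is None or label == "no_classification":
            continue
        positive = genus.casefold() in reference
        predicted = label == "increasing"
        w = weights[k]
        if positive and predicted:
            tp += 1; wtp += w
        elif positive:
            fn += 1; wfn += w
        elif predicted:
            fp += 1; wfp += w
        else:
            tn += 1; wtn += w

    def _rate(num, den, what):
        if den == 0:
            warnings.warn(f"{what} undefined (no classified OTUs in class)",
                          stacklevel=3)
            return float("nan")
        return num / den

    return (
        _rate(tp, tp + fn, "sensitivity"),
        _rate(tn, tn + fp, "specificity"),
        _rate(wtp, wtp + wfn, "weighted sensitivity"),
        _rate(wtn, wtn + wfp, "weighted specificity"),
    )
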