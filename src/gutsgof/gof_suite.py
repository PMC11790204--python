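"""Goodness-of-fit metrics for GUTS survival-model predictions.

Implements the five metrics used in regulatory evaluation of GUTS fits —
NRMSE, the posterior predictive check (PPC), the survival-probability
prediction error extremes (SPPE_min / SPPE_max), and Nagelkerke pseudo-R^2 —
plus their rescaling to [0, 1], the average / minimum combined GoF, and the
fit-selection filters used to assemble a survey image library.

Conventions
-----------
* NRMSE = 100 * sqrt(mean((y_obs - y_pred)^2)) / mean(y_obs), aggregated
  over all time points and treatments.
* SPPE_k = 100 * (y_end_obs - y_end_pred) / n0 per treatment k;
  SPPE_min = min(min_k SPPE_k, 0), SPPE_max = max(max_k SPPE_k, 0).  Values
  with the "wrong" sign are clipped to 0% because then there is no
  prediction error in that direction.
* PPC = percentage of observations inside the 95% predictive interval of
  survivor counts (closed interval: boundary values count as inside).
* Nagelkerke R^2 compares the binomial likelihood of end-of-test counts
  under the fitted model with a null model using the pooled survival
  fraction across treatments.
* Observations at t = 0, where the prediction is exactly n0, are excluded
  from NRMSE/PPC sums and from the mean observed count: they carry no
  information and would inflate PPC and deflate NRMSE.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import binom

__all__ = [
    "PairedSeries",
    "GoFMetrics",
    "FilterConfig",
    "nrmse",
    "sppe",
    "ppc",
    "nagelkerke_r2",
    "scale_metric",
    "combine_gof",
    "compute_metrics",
    "select_fits",
]

DEFAULT_COMBINED_MEMBERS = ("nrmse", "ppc", "sppe_min", "sppe_max")


@dataclass(frozen=True)
class PairedSeries:
    """Observed/predicted survivor counts paired over treatments and times.

    Each entry carries the treatment id, time, observed and predicted
    counts, the initial count n0, and the 95% predictive-interval bounds
    used by the PPC.
    """

    treatment: np.ndarray
    time: np.ndarray
    y_obs: np.ndarray
    y_pred: np.ndarray
    n0: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.y_obs)
        if n < 1:
            raise ValueError("paired series needs >= 1 entry")
        for name in ("time", "y_pred", "n0", "ci_lower", "ci_upper", "treatment"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"field {name} misaligned with y_obs")
        obs = np.asarray(self.y_obs, dtype=float)
        pred = np.asarray(self.y_pred, dtype=float)
        n0 = np.asarray(self.n0, dtype=float)
        if np.any(obs < 0) or np.any(obs > n0) or np.any(pred < -1e-9) or np.any(pred > n0 + 1e-9):
            raise ValueError("observed/predicted counts must lie within [0, n0]")
        object.__setattr__(self, "y_obs", obs)
        object.__setattr__(self, "y_pred", pred)
        object.__setattr__(self, "n0", n0)
        object.__setattr__(self, "time", np.asarray(self.time, dtype=float))
        object.__setattr__(self, "ci_lower", np.asarray(self.ci_lower, dtype=float))
        object.__setattr__(self, "ci_upper", np.asarray(self.ci_upper, dtype=float))
        object.__setattr__(self, "treatment", np.asarray(self.treatment))

    @property
    def n(self) -> int:
        return len(self.y_obs)

    @property
    def mean_observed(self) -> float:
        return float(np.mean(self.y_obs))

    @classmethod
    def from_summary(
        cls,
        dataset,
        summary: pd.DataFrame,
        drop_time_zero: bool = True,
    ) -> "PairedSeries":
        """Pair a dataset's observations with a prediction summary table
        (as produced by :func:`gutsgof.calibration.predict_summary`)."""
        rows = {"treatment": [], "time": [], "y_obs": [], "y_pred": [], "n0": [],
                "ci_lower": [], "ci_upper": []}
        indexed = summary.set_index(["treatment", "time"])
        for tr in dataset.treatments:
            for t, y in zip(tr.obs_times, tr.survivors):
                if drop_time_zero and t == 0.0:
                    continue
                try:
                    s = indexed.loc[(tr.id, float(t))]
                except KeyError as exc:
                    raise ValueError(
                        f"summary missing treatment {tr.id!r} at time {t}"
                    ) from exc
                rows["treatment"].append(tr.id)
                rows["time"].append(float(t))
                rows["y_obs"].append(float(y))
                rows["y_pred"].append(float(s["median_count"]))
                rows["n0"].append(float(tr.n0))
                rows["ci_lower"].append(float(s["lower"]))
                rows["ci_upper"].append(float(s["upper"]))
        return cls(**{k: np.asarray(v) for k, v in rows.items()})


def nrmse(paired: PairedSeries) -> float:
    """Normalized root-mean-square error, in percent."""
    ybar = paired.mean_observed
    if ybar <= 0:
        raise ValueError("normalization undefined: mean observed survivors is 0")
    rmse = math.sqrt(float(np.mean((paired.y_obs - paired.y_pred) ** 2)))
    return 100.0 * rmse / ybar


def sppe(treatments) -> tuple[float, float, dict]:
    """Survival-probability prediction error extremes across treatments.

    ``treatments`` maps treatment id -> (y_end_obs, y_end_pred, n0).
    Returns (sppe_min, sppe_max, per_treatment) in percent, with the
    clipping rule applied: sppe_min <= 0 <= sppe_max.
    """
    if len(treatments) < 1:
        raise ValueError("need >= 1 treatment")
    per = {}
    for k, (y_obs, y_pred, n0) in treatments.items():
        if n0 < 1:
            raise ValueError(f"treatment {k!r}: n0 must be >= 1")
        per[k] = 100.0 * (y_obs - y_pred) / n0
    values = list(per.values())
    return min(min(values), 0.0), max(max(values), 0.0), per


def ppc(paired: PairedSeries) -> float:
    """Percentage of observations inside their 95% predictive interval."""
    if np.any(~np.isfinite(paired.ci_lower)) or np.any(~np.isfinite(paired.ci_upper)):
        raise ValueError("PPC requires finite credible-interval bounds for every entry")
    inside = (paired.ci_lower <= paired.y_obs) & (paired.y_obs <= paired.ci_upper)
    return 100.0 * float(np.mean(inside))


def nagelkerke_r2(treatments) -> float:
    """Nagelkerke pseudo-R^2 at end-of-test counts.

    ``treatments`` maps treatment id -> (y_end_obs, n0, p_pred_end).
    The null model uses the pooled survival fraction
    sum(y_end_obs) / sum(n0).  Works on log likelihoods internally.
    """
    if len(treatments) < 1:
        raise ValueError("need >= 1 treatment")
    ys = np.array([v[0] for v in treatments.values()], dtype=float)
    n0s = np.array([v[1] for v in treatments.values()], dtype=float)
    ps = np.array([v[2] for v in treatments.values()], dtype=float)
    if np.any((ps < 0) | (ps > 1)):
        raise ValueError("predicted end survival probabilities must lie in [0, 1]")
    n = len(ys)
    p_null = float(ys.sum() / n0s.sum())
    logL0 = float(np.sum(binom.logpmf(ys, n0s, p_null)))
    logLM = float(np.sum(binom.logpmf(ys, n0s, ps)))
    if logL0 >= 0.0:  # L0 == 1: every count certain under the null
        raise ValueError("null model saturated")
    if not np.isfinite(logLM):
        warnings.warn("model likelihood is zero at end-of-test counts")
        return -math.inf
    # R2 = (1 - (L0/LM)^(2/n)) / (1 - L0^(2/n)), evaluated in log space
    num = -math.expm1((2.0 / n) * (logL0 - logLM))
    den = -math.expm1((2.0 / n) * logL0)
    return num / den


_SCALERS = {
    "nrmse": lambda v: min(max(1.0 - v / 100.0, 0.0), 1.0),
    "ppc": lambda v: min(max(v / 100.0, 0.0), 1.0),
    "sppe_min": lambda v: min(max(1.0 - abs(v) / 100.0, 0.0), 1.0),
    "sppe_max": lambda v: min(max(1.0 - abs(v) / 100.0, 0.0), 1.0),
    "pseudo_r2": lambda v: min(max(v, 0.0), 1.0),
}


def scale_metric(name: str, value: float) -> float:
    """Rescale a raw metric to [0, 1] with 1 = best.

    Metrics where lower is better (NRMSE, |SPPE|) are inverted linearly on
    [0, 100%] and clamped; PPC maps to value/100; pseudo-R^2 clamps
    negatives to 0.
    """
    try:
        return _SCALERS[name](value)
    except KeyError:
        raise ValueError(f"unknown metric {name!r}") from None


def combine_gof(scaled: dict, method: str = "average", members=DEFAULT_COMBINED_MEMBERS) -> float:
    """Combine scaled metrics by arithmetic mean or minimum."""
    if not members:
        raise ValueError("members must be non-empty")
    missing = [m for m in members if m not in scaled]
    if missing:
        raise ValueError(f"missing scaled metrics: {missing}")
    values = [scaled[m] for m in members]
    if method == "average":
        return float(np.mean(values))
    if method == "minimum":
        return float(np.min(values))
    raise ValueError(f"unknown combination method {method!r}")


@dataclass
class GoFMetrics:
    """Raw, scaled and combined goodness-of-fit values for one fit."""

    nrmse: float
    ppc: float
    sppe_min: float
    sppe_max: float
    sppe_per_treatment: dict
    pseudo_r2: float
    scaled: dict = field(default_factory=dict)
    avg_gof: float = float("nan")
    min_gof: float = float("nan")

    def __post_init__(self) -> None:
        if not self.scaled:
            self.scaled = {
                "nrmse": scale_metric("nrmse", self.nrmse),
                "ppc": scale_metric("ppc", self.ppc),
                "sppe_min": scale_metric("sppe_min", self.sppe_min),
                "sppe_max": scale_metric("sppe_max", self.sppe_max),
                "pseudo_r2": scale_metric("pseudo_r2", self.pseudo_r2),
            }
        if math.isnan(self.avg_gof):
            self.avg_gof = combine_gof(self.scaled, "average")
        if math.isnan(self.min_gof):
            self.min_gof = combine_gof(self.scaled, "minimum")


def compute_metrics(paired: PairedSeries, end_probs: dict) -> GoFMetrics:
    """All five metrics for one fit.

    ``paired`` supplies the time-resolved comparison (NRMSE, PPC);
    ``end_probs`` maps treatment id -> (y_end_obs, y_end_pred, n0,
    p_pred_end) for the end-of-test metrics (SPPE, pseudo-R^2).
    """
    smin, smax, per = sppe({k: v[:3] for k, v in end_probs.items()})
    r2 = nagelkerke_r2({k: (v[0], v[2], v[3]) for k, v in end_probs.items()})
    return GoFMetrics(
        nrmse=nrmse(paired),
        ppc=ppc(paired),
        sppe_min=smin,
        sppe_max=smax,
        sppe_per_treatment=per,
        pseudo_r2=r2,
    )


@dataclass
class FilterConfig:
    """Settings for :func:`select_fits`.

    min_effect : minimum end-of-test mortality fraction required in at least
        one treatment (inclusive).
    min_treatments : experiments with fewer treatments are dropped.
    n_bins : equal-width avg_gof bins for stratified subsampling.
    per_bin : target count per non-empty bin (default: smallest non-empty
        bin count).
    stratify : disable to apply only the hard filters.
    """

    min_effect: float = 0.70
    min_treatments: int = 2
    n_bins: int = 5
    per_bin: int | None = None
    stratify: bool = True


def select_fits(fits, config: FilterConfig | None = None, seed: int = 0) -> list:
    """Filter and stratify a collection of fits for the survey library.

    ``fits`` is a sequence of objects with attributes ``metrics``
    (:class:`GoFMetrics`), ``end_mortalities`` (per-treatment end mortality
    fractions), and ``n_treatments``.  Fits are dropped when no treatment
    reaches ``min_effect`` end mortality or the experiment has a single
    treatment; the survivors are subsampled to approximately equal counts
    per avg_gof bin.
    """
    config = config or FilterConfig()
    kept = [
        f
        for f in fits
        if f.n_treatments >= config.min_treatments
        and max(f.end_mortalities) >= config.min_effect
    ]
    if not kept:
        warnings.warn("fit selection produced an empty collection")
        return []
    if not config.stratify:
        return kept
    edges = np.linspace(0.0, 1.0, config.n_bins + 1)
    bins: list[list] = [[] for _ in range(config.n_bins)]
    for f in kept:
        idx = min(int(np.searchsorted(edges, f.metrics.avg_gof, side="right")) - 1,
                  config.n_bins - 1)
        bins[max(idx, 0)].append(f)
    nonempty = [b for b in bins if b]
    target = config.per_bin or min(len(b) for b in nonempty)
    rng = np.random.default_rng(seed)
    out = []
    for b in bins:
        if not b:
            continue
        if len(b) <= target:
            out.extend(b)
        else:
            idx = rng.choice(len(b), size=target, replace=False)
            out.extend(b[i] for i in sorted(idx))
    return out
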