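"""Visual representations of GUTS fits and their comparison.

A fit can be shown as a time series (TS) — survival probability over time,
one panel per treatment, observations with Wilson score intervals, median
prediction and 95% band — or as a dose-response curve (DRC) — end-of-test
survival against the maximum exposure concentration of each treatment, one
panel per experiment, with a predicted curve obtained by multiplicatively
scaling the experiment's exposure profile over a concentration grid.  Panel
payloads are plain dictionaries serializable to JSON; layout metadata
records that all panels share equal dimensions.

The module also implements the per-fit comparison of evaluator scores
between the two representations (median score, acceptance fraction, and the
three-way classification DRC better / equal / TS better).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.stats import norm

from .calibration import PosteriorSample, SurvivalDataset, _predict_curve

logger = logging.getLogger(__name__)

__all__ = [
    "WilsonInterval",
    "FitImage",
    "wilson_interval",
    "build_timeseries_panels",
    "build_drc_panels",
    "compare_representations",
]

ACCEPT_MAX_SCORE = 3  # scores 1-3 mean acceptance, 4-6 rejection


@dataclass(frozen=True)
class WilsonInterval:
    """Wilson score interval for a binomial proportion."""

    point: float
    lower: float
    upper: float
    confidence: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.lower <= self.point <= self.upper <= 1.0):
            raise ValueError("interval must satisfy 0 <= lower <= point <= upper <= 1")


def wilson_interval(k: int, n: int, confidence: float = 0.95) -> WilsonInterval:
    """Wilson score interval for ``k`` successes in ``n`` trials.

    Center (p + z^2/2n) / (1 + z^2/n), half-width
    z * sqrt(p(1-p)/n + z^2/4n^2) / (1 + z^2/n).
    """
    if n < 1 or k < 0 or k > n:
        raise ValueError("need 0 <= k <= n and n >= 1")
    if not (0.0 < confidence < 1.0):
        raise ValueError("confidence must lie in (0, 1)")
    z = norm.ppf(0.5 + confidence / 2.0)
    p = k / n
    denom = 1.0 + z * z / n
    center = (p + z * z / (2 * n)) / denom
    half = z * np.sqrt(p * (1 - p) / n + z * z / (4 * n * n)) / denom
    # guard rounding at k = 0 / k = n, where a bound coincides with p-hat
    return WilsonInterval(
        point=p,
        lower=min(max(center - half, 0.0), p),
        upper=max(min(center + half, 1.0), p),
        confidence=confidence,
    )


@dataclass
class FitImage:
    """One image shown to evaluators: a set of equally sized panels."""

    image_id: str
    fit_id: str
    role: str
    representation: str  # "TS" | "DRC"
    panels: list = field(default_factory=list)
    layout: dict = field(default_factory=lambda: {"equal_panel_size": True})

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, default=_jsonify)


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def build_timeseries_panels(
    dataset: SurvivalDataset,
    summary: pd.DataFrame,
    fit_id: str = "fit",
    image_id: str | None = None,
) -> FitImage:
    """Time-series image: one panel per treatment.

    Each panel holds observed survival proportions with Wilson bars, the
    median predicted survival-probability curve, and the 95% band (as
    proportions of n0).
    """
    indexed = summary.set_index(["treatment", "time"])
    panels = []
    for tr in dataset.treatments:
        obs, lo, hi = [], [], []
        pred, band_lo, band_hi = [], [], []
        for t, y in zip(tr.obs_times, tr.survivors):
            try:
                s = indexed.loc[(tr.id, float(t))]
            except KeyError as exc:
                raise ValueError(f"summary missing treatment {tr.id!r} at t={t}") from exc
            w = wilson_interval(int(y), tr.n0)
            obs.append(w.point)
            lo.append(w.lower)
            hi.append(w.upper)
            pred.append(float(s["median_prob"]))
            band_lo.append(float(s["lower"]) / tr.n0)
            band_hi.append(float(s["upper"]) / tr.n0)
        panels.append(
            {
                "treatment": tr.id,
                "times": list(map(float, tr.obs_times)),
                "observed": obs,
                "wilson_lower": lo,
                "wilson_upper": hi,
                "predicted_median": pred,
                "band_lower": band_lo,
                "band_upper": band_hi,
            }
        )
    return FitImage(
        image_id=image_id or f"{fit_id}-TS",
        fit_id=fit_id,
        role=dataset.role,
        representation="TS",
        panels=panels,
    )


def build_drc_panels(
    dataset: SurvivalDataset,
    posterior: PosteriorSample,
    conc_grid: np.ndarray | None = None,
    n_draws: int = 200,
    seed: int = 0,
    fit_id: str = "fit",
    image_id: str | None = None,
) -> FitImage:
    """Dose-response image: one panel per experiment.

    Observed end-of-test survival (with Wilson bars) is plotted against the
    maximum concentration of each treatment's profile.  The predicted curve
    scales the panel's reference exposure profile multiplicatively across
    ``conc_grid`` (a grid of maximum concentrations) and evaluates the
    posterior median and 95% band of end-of-experiment survival.
    """
    if len(posterior.draws) == 0:
        raise ValueError("posterior is empty")
    rng = np.random.default_rng(seed)
    n_avail = len(posterior.draws)
    idx = (
        np.arange(n_avail)
        if n_draws >= n_avail
        else rng.choice(n_avail, size=n_draws, replace=False)
    )
    panels = []
    for e, experiment in enumerate(dataset.experiments):
        max_concs = [tr.profile.max_concentration for tr in experiment]
        obs_points = []
        for tr in experiment:
            w = wilson_interval(int(tr.survivors[-1]), tr.n0)
            obs_points.append(
                {
                    "treatment": tr.id,
                    "max_concentration": tr.profile.max_concentration,
                    "observed": w.point,
                    "wilson_lower": w.lower,
                    "wilson_upper": w.upper,
                }
            )
        ref = max(experiment, key=lambda tr: tr.profile.max_concentration)
        cmax = ref.profile.max_concentration
        if cmax == 0:
            logger.warning("experiment %d has all-zero exposure; flat background panel", e)
            grid = np.array([0.0])
        elif conc_grid is not None:
            grid = np.asarray(conc_grid, dtype=float)
        else:
            grid = np.concatenate([[0.0], np.geomspace(cmax / 100.0, cmax * 1.5, 15)])
        t_end = np.array([float(ref.obs_times[-1])])
        curve_med, curve_lo, curve_hi = [], [], []
        for c in grid:
            factor = c / cmax if cmax > 0 else 0.0
            profile = ref.profile.scaled(factor)
            vals = np.array(
                [
                    _predict_curve_end(profile, posterior.params_at(int(i)), posterior.variant, t_end)
                    for i in idx
                ]
            )
            curve_med.append(float(np.median(vals)))
            curve_lo.append(float(np.quantile(vals, 0.025)))
            curve_hi.append(float(np.quantile(vals, 0.975)))
        panels.append(
            {
                "experiment": e,
                "duration": float(t_end[0]),
                "observations": obs_points,
                "grid": grid.tolist(),
                "predicted_median": curve_med,
                "band_lower": curve_lo,
                "band_upper": curve_hi,
            }
        )
    return FitImage(
        image_id=image_id or f"{fit_id}-DRC",
        fit_id=fit_id,
        role=dataset.role,
        representation="DRC",
        panels=panels,
    )


def _predict_curve_end(profile, params, variant, t_end) -> float:
    from .guts_core import survival_it, survival_sd

    if variant == "SD":
        return float(survival_sd(profile, params, t_end).probabilities[-1])
    return float(survival_it(profile, params, t_end).probabilities[-1])


def render_image(image: FitImage, path, ncols: int = 2, dpi: int = 120) -> None:
    """Render a fit image to PNG/SVG with equally sized panels.

    Requires matplotlib (imported lazily; not a core dependency of the
    analysis chain)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = len(image.panels)
    ncols = min(ncols, n)
    nrows = -(-n // ncols)
    fig, axes = plt.subplots(
        nrows, ncols, figsize=(4 * ncols, 3 * nrows), squeeze=False, sharey=True
    )
    for ax in axes.flat[n:]:
        ax.axis("off")
    for ax, panel in zip(axes.flat, image.panels):
        if image.representation == "TS":
            t = panel["times"]
            ax.fill_between(t, panel["band_lower"], panel["band_upper"],
                            color="0.8", label="95% CI")
            ax.plot(t, panel["predicted_median"], color="tab:orange", label="prediction")
            yerr = [
                np.array(panel["observed"]) - np.array(panel["wilson_lower"]),
                np.array(panel["wilson_upper"]) - np.array(panel["observed"]),
            ]
            ax.errorbar(t, panel["observed"], yerr=yerr, fmt="ko", capsize=2,
                        label="observed")
            ax.set_xlabel("time (d)")
            ax.set_title(str(panel["treatment"]))
        else:
            grid = np.asarray(panel["grid"], dtype=float)
            pos = grid > 0
            ax.fill_between(grid[pos], np.asarray(panel["band_lower"])[pos],
                            np.asarray(panel["band_upper"])[pos], color="0.8")
            ax.plot(grid[pos], np.asarray(panel["predicted_median"])[pos],
                    color="tab:orange")
            for obs in panel["observations"]:
                x = obs["max_concentration"] or grid[pos][0] / 2 if pos.any() else 1e-3
                ax.errorbar([x], [obs["observed"]],
                            yerr=[[obs["observed"] - obs["wilson_lower"]],
                                  [obs["wilson_upper"] - obs["observed"]]],
                            fmt="ko", capsize=2)
            if pos.any():
                ax.set_xscale("log")
            ax.set_xlabel("max concentration")
            ax.set_title(f"experiment {panel['experiment']}")
        ax.set_ylim(-0.02, 1.02)
        ax.set_ylabel("survival")
    fig.suptitle(f"{image.fit_id} ({image.role}, {image.representation})")
    fig.tight_layout()
    fig.savefig(path, dpi=dpi)
    plt.close(fig)


def _median(scores) -> float:
    """Median with the midpoint convention for even counts."""
    return float(np.median(np.asarray(scores, dtype=float)))


def compare_representations(records: pd.DataFrame):
    """Per-fit comparison of TS and DRC evaluator scores.

    For every fit scored under both representations: median score and
    acceptance fraction (scores 1-3) per representation, and a
    classification into ``DRC better`` / ``equal`` / ``TS better`` by the
    lower (= better) median score.  Returns ``(table, counts)`` where
    ``counts`` aggregates the three categories.
    """
    rows = []
    for fit_id, grp in records.groupby("fit_id"):
        reps = set(grp["representation"])
        if not {"TS", "DRC"} <= reps:
            logger.info("fit %s has a single representation; skipped", fit_id)
            continue
        ts = grp.loc[grp["representation"] == "TS", "score"]
        drc = grp.loc[grp["representation"] == "DRC", "score"]
        ts_med, drc_med = _median(ts), _median(drc)
        if drc_med < ts_med:
            cls = "DRC better"
        elif drc_med > ts_med:
            cls = "TS better"
        else:
            cls = "equal"
        rows.append(
            {
                "fit_id": fit_id,
                "ts_median": ts_med,
                "drc_median": drc_med,
                "ts_acceptance": float((ts <= ACCEPT_MAX_SCORE).mean()),
                "drc_acceptance": float((drc <= ACCEPT_MAX_SCORE).mean()),
                "n_ts": len(ts),
                "n_drc": len(drc),
                "classification": cls,
            }
        )
    table = pd.DataFrame(rows)
    counts = {"DRC better": 0, "equal": 0, "TS better": 0}
    if not table.empty:
        for cls, cnt in table["classification"].value_counts().items():
            counts[cls] = int(cnt)
    return table, counts
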