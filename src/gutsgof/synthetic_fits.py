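"""Synthetic GUTS fits with known truth, for testing and survey simulation.

Real survey image libraries come from hundreds of MCMC calibrations of
toxicity datasets.  For desk-scale simulation this module generates fits
with a *known* quality level instead: survival data are drawn from true
GUTS-RED-SD parameters via conditional binomial sampling, while the
"fitted" prediction uses the same parameters perturbed on the log scale by
a per-fit jitter.  Zero jitter gives near-perfect fits, large jitter gives
visibly failing ones, so a library spans the whole goodness-of-fit range.
Predictive intervals around the prediction are central binomial intervals
(sampling error only), which is what the PPC needs.

Also provides dataset factories used by the calibration-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.stats import binom

from .calibration import SurvivalDataset, Treatment
from .gof_suite import GoFMetrics, PairedSeries, compute_metrics
from .guts_core import ExposureProfile, GutsParamsSD, sample_survival_counts, survival_sd

__all__ = [
    "SyntheticFit",
    "make_constant_exposure_dataset",
    "generate_fit",
    "generate_fit_library",
]


@dataclass
class SyntheticFit:
    """One synthetic calibration/validation fit with its quality metrics."""

    fit_id: str
    role: str
    dataset: SurvivalDataset
    summary: pd.DataFrame
    metrics: GoFMetrics
    true_params: GutsParamsSD
    pred_params: GutsParamsSD

    @property
    def end_mortalities(self) -> list[float]:
        return [
            1.0 - tr.survivors[-1] / tr.n0 for tr in self.dataset.treatments
        ]

    @property
    def n_treatments(self) -> int:
        return len(self.dataset.treatments)


def make_constant_exposure_dataset(
    params: GutsParamsSD,
    concentrations=(0.0, 0.5, 1.0, 2.0, 4.0),
    n0: int = 50,
    times=(0.0, 1.0, 2.0, 3.0, 4.0, 5.0, 7.0),
    seed: int = 0,
    role: str = "calibration",
) -> SurvivalDataset:
    """One experiment of constant-exposure treatments simulated from truth."""
    rng = np.random.default_rng(seed)
    times = np.asarray(times, dtype=float)
    treatments = []
    for j, c in enumerate(concentrations):
        profile = ExposureProfile(np.array([0.0, times[-1]]), np.array([c, c]))
        curve = survival_sd(profile, params, times)
        counts = sample_survival_counts(curve, n0, rng)
        treatments.append(
            Treatment(id=f"T{j}", profile=profile, obs_times=times, survivors=counts, n0=n0)
        )
    return SurvivalDataset(experiments=(tuple(treatments),), role=role)


def make_pulsed_exposure_dataset(
    params: GutsParamsSD,
    pulse_heights=(0.0, 1.0, 2.0, 4.0, 8.0),
    pulse_end: float = 2.0,
    n0: int = 50,
    times=(0.0, 1.0, 2.0, 3.0, 4.0, 5.0, 7.0),
    seed: int = 0,
    role: str = "calibration",
) -> SurvivalDataset:
    """One experiment of pulsed-exposure treatments simulated from truth.

    Each treatment is exposed at its pulse height until ``pulse_end`` and to
    clean water afterwards.  The recovery phase makes the dominant rate
    constant identifiable, which constant exposure alone does not.
    """
    rng = np.random.default_rng(seed)
    times = np.asarray(times, dtype=float)
    treatments = []
    for j, c in enumerate(pulse_heights):
        profile = ExposureProfile(
            np.array([0.0, pulse_end, times[-1]]),
            np.array([c, 0.0, 0.0]),
            interpolation="constant",
        )
        curve = survival_sd(profile, params, times)
        counts = sample_survival_counts(curve, n0, rng)
        treatments.append(
            Treatment(id=f"T{j}", profile=profile, obs_times=times, survivors=counts, n0=n0)
        )
    return SurvivalDataset(experiments=(tuple(treatments),), role=role)


RECOVERY_TRUTH = GutsParamsSD(hb=0.02, kd=0.8, z=1.0, b=0.3)


def make_recovery_benchmark_dataset(
    params: GutsParamsSD = RECOVERY_TRUTH,
    n0: int = 50,
    seed: int = 0,
) -> SurvivalDataset:
    """The parameter-recovery benchmark: 5 treatments x ``n0`` organisms,
    7 observation times.

    The design mixes a control, a near-threshold and a clearly lethal
    constant exposure, a single 2-day pulse, and a double pulse, with
    sub-daily counts early in the test — the combination acute-test
    practice uses to make all of kd, z and b identifiable.
    """
    rng = np.random.default_rng(seed)
    times = np.array([0.0, 0.25, 0.5, 1.0, 2.0, 4.0, 7.0])
    profiles = [
        ExposureProfile(np.array([0.0, 7.0]), np.array([0.0, 0.0])),
        ExposureProfile(np.array([0.0, 7.0]), np.array([1.2, 1.2])),
        ExposureProfile(np.array([0.0, 7.0]), np.array([2.5, 2.5])),
        ExposureProfile(
            np.array([0.0, 2.0, 7.0]), np.array([8.0, 0.0, 0.0]), interpolation="constant"
        ),
        ExposureProfile(
            np.array([0.0, 1.0, 3.0, 4.0, 7.0]),
            np.array([6.0, 0.0, 6.0, 0.0, 0.0]),
            interpolation="constant",
        ),
    ]
    treatments = []
    for j, profile in enumerate(profiles):
        curve = survival_sd(profile, params, times)
        counts = sample_survival_counts(curve, n0, rng)
        treatments.append(
            Treatment(id=f"T{j}", profile=profile, obs_times=times, survivors=counts, n0=n0)
        )
    return SurvivalDataset(experiments=(tuple(treatments),))


def _jitter_params(params: GutsParamsSD, sd: float, rng) -> GutsParamsSD:
    f = np.exp(sd * rng.standard_normal(3))
    return GutsParamsSD(
        hb=params.hb, kd=params.kd * f[0], z=params.z * f[1], b=params.b * f[2]
    )


def _prediction_summary(dataset: SurvivalDataset, pred: GutsParamsSD) -> pd.DataFrame:
    rows = []
    for tr in dataset.treatments:
        S = survival_sd(tr.profile, pred, tr.obs_times).probabilities
        lower = binom.ppf(0.025, tr.n0, S)
        upper = binom.ppf(0.975, tr.n0, S)
        for k, t in enumerate(tr.obs_times):
            rows.append(
                {
                    "treatment": tr.id,
                    "time": float(t),
                    "n0": tr.n0,
                    "median_prob": float(S[k]),
                    "median_count": float(tr.n0 * S[k]),
                    "lower": float(lower[k]),
                    "upper": float(upper[k]),
                }
            )
    return pd.DataFrame(rows)


def generate_fit(
    fit_id: str,
    seed: int,
    role: str = "calibration",
    jitter_sd: float | None = None,
    n0: int = 10,
) -> SyntheticFit:
    """Generate one synthetic fit; larger ``jitter_sd`` means a worse fit."""
    rng = np.random.default_rng(seed)
    true = GutsParamsSD(
        hb=float(rng.uniform(0.0, 0.02)),
        kd=float(np.exp(rng.normal(np.log(0.8), 0.3))),
        z=float(rng.uniform(0.3, 1.2)),
        b=float(np.exp(rng.normal(np.log(0.6), 0.4))),
    )
    if jitter_sd is None:
        jitter_sd = float(rng.uniform(0.0, 1.1))
    dataset = make_constant_exposure_dataset(
        true,
        concentrations=(0.0, 0.5, 1.0, 2.0, 4.0),
        n0=n0,
        times=(0.0, 1.0, 2.0, 3.0, 4.0, 5.0, 7.0),
        seed=int(rng.integers(2**31)),
        role=role,
    )
    pred = _jitter_params(true, jitter_sd, rng)
    summary = _prediction_summary(dataset, pred)
    paired = PairedSeries.from_summary(dataset, summary)
    end_probs = {}
    indexed = summary.set_index(["treatment", "time"])
    for tr in dataset.treatments:
        s = indexed.loc[(tr.id, float(tr.obs_times[-1]))]
        end_probs[tr.id] = (
            float(tr.survivors[-1]),
            float(s["median_count"]),
            tr.n0,
            float(s["median_prob"]),
        )
    metrics = compute_metrics(paired, end_probs)
    return SyntheticFit(
        fit_id=fit_id,
        role=role,
        dataset=dataset,
        summary=summary,
        metrics=metrics,
        true_params=true,
        pred_params=pred,
    )


def generate_fit_library(
    n_fits: int = 40,
    seed: int = 0,
    n0: int = 10,
) -> list[SyntheticFit]:
    """A library of fits spanning the GoF range, half calibration half
    validation, suitable as input to the survey design."""
    root = np.random.SeedSequence(seed)
    seeds = root.generate_state(n_fits) % 2**31
    fits = []
    for i in range(n_fits):
        role = "calibration" if i % 2 == 0 else "validation"
        # sweep jitter deterministically so quality levels are covered evenly
        jitter = 1.1 * (i // 2) / max(n_fits // 2 - 1, 1)
        fits.append(
            generate_fit(f"F{i:03d}", int(seeds[i]), role=role, jitter_sd=jitter, n0=n0)
        )
    return fits
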