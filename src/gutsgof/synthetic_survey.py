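"""Synthetic visual-assessment survey generator.

Emulates an anonymous online survey in which professional evaluators score
images of GUTS model fits on a 1 (excellent) to 6 (no resemblance) scale,
with scores 1-3 meaning acceptance.  Every evaluator sees 20 images in a
fixed block order — five calibration time series, five calibration
dose-response curves, five validation time series, five validation DRCs —
drawn randomly and independently within each block from the fit library.

Scores are generated from a latent cumulative ordinal model: the latent
scale is a linear predictor in the fit's combined goodness-of-fit, image
type (calibration/validation), evaluator affiliation and experience, the
GoF x type and GoF x experience interactions, and a per-evaluator random
intercept.  Rejection reasons (only for scores 4-6) follow a Bernoulli
logit in the four scaled GoF metrics for the end-of-test vs time-course
grouping, mirroring the structure the downstream inference module estimates.

The generator's defaults define the study conditions: 64 evaluators whose
affiliation and experience proportions match the surveyed population
(academia 15, authority 5, CRO 13, industry 24, other 6, not specified 1;
experience levels 14/16/12/14/8 from most to least experienced), and a
truth model whose 50% acceptance point sits near average GoF 0.74.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import logistic, norm

__all__ = [
    "Evaluator",
    "TrueScoreModel",
    "AFFILIATIONS",
    "AFFILIATION_COUNTS",
    "EXPERIENCE_COUNTS",
    "generate_evaluators",
    "generate_survey_design",
    "sample_scores",
    "sample_rejection_reasons",
    "linear_predictor",
]

AFFILIATIONS = ("academia", "authority", "CRO", "industry", "other", "not specified")
AFFILIATION_COUNTS = (15, 5, 13, 24, 6, 1)
# experience levels 5..1 = modeler with TKTD calibration experience .. nonmodeler
EXPERIENCE_COUNTS = {5: 14, 4: 16, 3: 12, 2: 14, 1: 8}

SCALED_METRIC_COLUMNS = ("s_nrmse", "s_ppc", "s_sppe_min", "s_sppe_max", "s_pseudo_r2")

TS_REASONS = {"end": ("a", "b"), "time_course": ("c", "d")}
DRC_REASONS = ("e", "f", "g", "h")
ALL_REASONS = ("a", "b", "c", "d", "e", "f", "g", "h")


@dataclass(frozen=True)
class Evaluator:
    id: str
    affiliation: str
    experience: int  # ordered 1 (least) .. 5 (most experienced)

    def __post_init__(self) -> None:
        if self.affiliation not in AFFILIATIONS:
            raise ValueError(f"unknown affiliation {self.affiliation!r}")
        if self.experience not in range(1, 6):
            raise ValueError("experience must be an integer 1..5")


@dataclass
class TrueScoreModel:
    """Generating parameters of the latent ordinal score model.

    The latent predictor is
    eta = b_gof*g + b_val*v + affiliation contrast + b_exp*(e-3)
          + b_gxv*g*v + b_gxe*g*(e-3) + u_evaluator,
    with g the combined GoF of the fit, v the validation indicator, e the
    experience level, and u ~ Normal(0, sd_evaluator).  Scores follow
    P(score <= s) = F(cutpoint_s - eta) with F the link CDF.  The default
    geometry puts 50% acceptance (P(score <= 3) = 0.5) at g = 0.74 for a
    reference evaluator, and a negative GoF x experience coefficient makes
    experienced evaluators' scores more extreme.
    """

    link: str = "probit"
    cutpoints: tuple = (-5.2, -4.45, -3.7, -2.7, -1.7)
    coef_gof: float = -5.0
    coef_validation: float = 0.15
    coef_affiliation: dict = field(
        default_factory=lambda: {a: 0.0 for a in AFFILIATIONS}
    )
    coef_experience: float = -0.05
    coef_gof_x_validation: float = -0.2
    coef_gof_x_experience: float = -0.4
    sd_evaluator: float = 0.5
    predictor: str = "avg_gof"
    # rejection-reason Bernoulli logit on the four scaled metrics
    # (response 1 = end-of-test-related); sign pattern: SPPE negative,
    # NRMSE/PPC positive
    reason_coefs: dict = field(
        default_factory=lambda: {
            "intercept": -0.954,
            "s_sppe_min": -0.743,
            "s_sppe_max": -0.654,
            "s_nrmse": 1.397,
            "s_ppc": 1.028,
        }
    )
    ts_multi_panel_prob: float = 2.0 / 3.0
    drc_reason_probs: dict = field(
        default_factory=lambda: {"e": 0.28, "f": 0.12, "g": 0.38, "h": 0.22}
    )

    def __post_init__(self) -> None:
        if self.link not in ("probit", "logit"):
            raise ValueError("link must be 'probit' or 'logit'")
        if not np.all(np.diff(self.cutpoints) > 0):
            raise ValueError("cutpoints must be strictly increasing")
        if self.sd_evaluator < 0:
            raise ValueError("evaluator random-intercept SD must be >= 0")

    def fixed_effects(self) -> dict:
        """Generating fixed effects, keyed like the inference module's
        coefficient names (affiliation contrasts relative to academia)."""
        out = {
            "gof": self.coef_gof,
            "validation": self.coef_validation,
            "experience": self.coef_experience,
            "gof_x_validation": self.coef_gof_x_validation,
            "gof_x_experience": self.coef_gof_x_experience,
        }
        ref = self.coef_affiliation.get("academia", 0.0)
        for a in AFFILIATIONS[1:]:
            out[f"affiliation[{a}]"] = self.coef_affiliation.get(a, 0.0) - ref
        return out


def generate_evaluators(n: int, seed: int = 0) -> list[Evaluator]:
    """Sample an evaluator pool with the default affiliation/experience mix."""
    rng = np.random.default_rng(seed)
    aff_p = np.array(AFFILIATION_COUNTS, dtype=float)
    aff_p /= aff_p.sum()
    exp_levels = np.array(sorted(EXPERIENCE_COUNTS))
    exp_p = np.array([EXPERIENCE_COUNTS[e] for e in exp_levels], dtype=float)
    exp_p /= exp_p.sum()
    out = []
    for i in range(n):
        out.append(
            Evaluator(
                id=f"E{i:03d}",
                affiliation=str(rng.choice(AFFILIATIONS, p=aff_p)),
                experience=int(rng.choice(exp_levels, p=exp_p)),
            )
        )
    return out


_CATEGORY_ORDER = (
    ("calibration", "TS"),
    ("calibration", "DRC"),
    ("validation", "TS"),
    ("validation", "DRC"),
)
_IMAGES_PER_CATEGORY = 5


def generate_survey_design(
    n_evaluators: int,
    fit_library,
    seed: int = 0,
    evaluators: list[Evaluator] | None = None,
) -> pd.DataFrame:
    """Assignment table: 20 images per evaluator in the fixed block order.

    ``fit_library`` is a sequence of fits exposing ``fit_id``, ``role`` and
    ``metrics`` (a :class:`~gutsgof.gof_suite.GoFMetrics`); each fit yields
    one TS and one DRC image.  Within each of the four (role,
    representation) blocks, five images are drawn randomly without
    replacement, independently per evaluator.
    """
    rng = np.random.default_rng(seed)
    by_role: dict[str, list] = {"calibration": [], "validation": []}
    for f in fit_library:
        by_role[f.role].append(f)
    for role, fits in by_role.items():
        if len(fits) < _IMAGES_PER_CATEGORY:
            raise ValueError(
                f"need >= {_IMAGES_PER_CATEGORY} {role} fits, got {len(fits)}"
            )
    if evaluators is None:
        evaluators = generate_evaluators(n_evaluators, seed=int(rng.integers(2**31)))
    elif len(evaluators) != n_evaluators:
        raise ValueError("evaluator list length must equal n_evaluators")

    rows = []
    for ev in evaluators:
        position = 0
        for role, rep in _CATEGORY_ORDER:
            fits = by_role[role]
            chosen = rng.choice(len(fits), size=_IMAGES_PER_CATEGORY, replace=False)
            for ci in chosen:
                f = fits[int(ci)]
                m = f.metrics
                rows.append(
                    {
                        "evaluator_id": ev.id,
                        "affiliation": ev.affiliation,
                        "experience": ev.experience,
                        "position": position,
                        "image_id": f"{f.fit_id}-{rep}",
                        "fit_id": f.fit_id,
                        "role": role,
                        "representation": rep,
                        "avg_gof": m.avg_gof,
                        "min_gof": m.min_gof,
                        "nrmse": m.nrmse,
                        "ppc": m.ppc,
                        "sppe_min": m.sppe_min,
                        "sppe_max": m.sppe_max,
                        "pseudo_r2": m.pseudo_r2,
                        "s_nrmse": m.scaled["nrmse"],
                        "s_ppc": m.scaled["ppc"],
                        "s_sppe_min": m.scaled["sppe_min"],
                        "s_sppe_max": m.scaled["sppe_max"],
                        "s_pseudo_r2": m.scaled["pseudo_r2"],
                    }
                )
                position += 1
    return pd.DataFrame(rows)


def linear_predictor(assignments: pd.DataFrame, truth: TrueScoreModel) -> np.ndarray:
    """Fixed-effect part of the latent predictor (no random intercepts)."""
    g = assignments[truth.predictor].to_numpy(dtype=float)
    v = (assignments["role"] == "validation").to_numpy(dtype=float)
    e = assignments["experience"].to_numpy(dtype=float) - 3.0
    aff = assignments["affiliation"].map(truth.coef_affiliation).to_numpy(dtype=float)
    return (
        truth.coef_gof * g
        + truth.coef_validation * v
        + aff
        + truth.coef_experience * e
        + truth.coef_gof_x_validation * g * v
        + truth.coef_gof_x_experience * g * e
    )


def sample_scores(
    assignments: pd.DataFrame, truth: TrueScoreModel, seed: int = 0
) -> pd.DataFrame:
    """Draw 1-6 scores from the latent cumulative model.

    One random intercept per evaluator is shared across that evaluator's
    images.  Returns a copy of ``assignments`` with a ``score`` column.
    """
    rng = np.random.default_rng(seed)
    eta = linear_predictor(assignments, truth)
    ev_ids = assignments["evaluator_id"].to_numpy()
    uniq = pd.unique(ev_ids)
    u = dict(zip(uniq, truth.sd_evaluator * rng.standard_normal(len(uniq))))
    eta = eta + np.array([u[e] for e in ev_ids])
    noise = (
        rng.standard_normal(len(eta))
        if truth.link == "probit"
        else rng.logistic(size=len(eta))
    )
    latent = eta + noise
    cuts = np.asarray(truth.cutpoints, dtype=float)
    scores = 1 + np.searchsorted(cuts, latent, side="left")
    out = assignments.copy()
    out["score"] = scores.astype(int)
    out["reasons"] = ""
    return out


def sample_rejection_reasons(
    records: pd.DataFrame, truth: TrueScoreModel, seed: int = 0
) -> pd.DataFrame:
    """Attach rejection reasons to records with scores 4-6.

    For time-series images, the end-of-test vs time-course reason group is
    Bernoulli with logit equal to the truth model's reason predictor in the
    four scaled metrics; the one-panel vs multiple-panel letter follows the
    configured proportion.  Dose-response images draw among the DRC-specific
    reasons (e-h).  Scores 1-3 never receive reasons.
    """
    rng = np.random.default_rng(seed)
    out = records.copy()
    reasons = []
    c = truth.reason_coefs
    for _, row in out.iterrows():
        if row["score"] <= 3:
            reasons.append("")
            continue
        if row["representation"] == "TS":
            logit_p = c["intercept"] + sum(
                c[m] * row[m] for m in ("s_sppe_min", "s_sppe_max", "s_nrmse", "s_ppc")
            )
            end_related = rng.uniform() < expit(logit_p)
            group = TS_REASONS["end" if end_related else "time_course"]
            letter = group[0] if rng.uniform() < truth.ts_multi_panel_prob else group[1]
        else:
            probs = np.array([truth.drc_reason_probs[r] for r in DRC_REASONS])
            letter = str(rng.choice(DRC_REASONS, p=probs / probs.sum()))
        reasons.append(letter)
    out["reasons"] = reasons
    return out
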