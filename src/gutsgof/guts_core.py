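"""Forward simulation of reduced GUTS survival models.

The General Unified Threshold model of Survival (GUTS) predicts mortality of
organisms exposed to a toxicant over time.  In the reduced form (GUTS-RED),
scaled damage ``D(t)`` tracks the external concentration ``C_w(t)`` with
first-order kinetics,

    dD/dt = kd * (C_w(t) - D),    D(0) = 0,

and survival follows one of two death mechanisms:

* stochastic death (SD): every organism shares a hazard proportional to the
  damage exceeding a threshold ``z``,
  ``S(t) = exp(-hb*t - b * \\int_0^t max(0, D - z) dtau)``;
* individual tolerance (IT): each organism carries its own threshold drawn
  from a log-logistic distribution with median ``mw`` and shape ``beta``,
  and dies the first time its running-maximum damage exceeds it,
  ``S(t) = (1 - F(max_{tau<=t} D(tau))) * exp(-hb*t)``.

Exposure profiles are piecewise (constant or linear segments), so damage is
exponential-affine on each segment and both the damage trajectory and the SD
hazard integral are computed analytically, with threshold-crossing times
solved in closed form (constant segments) or by bracketed root finding at
machine precision (linear segments).  Time is in days throughout; exposure
units are arbitrary but must be consistent between profile and parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "ExposureProfile",
    "GutsParamsSD",
    "GutsParamsIT",
    "SurvivalCurve",
    "damage_series",
    "survival_sd",
    "survival_it",
    "sample_survival_counts",
]


@dataclass(frozen=True)
class ExposureProfile:
    """Piecewise exposure concentration over time for one treatment.

    Parameters
    ----------
    times
        Strictly increasing time points (days).
    concentrations
        Non-negative concentration at each time point.
    interpolation
        ``"linear"``: concentration varies linearly between points (measured
        profiles).  ``"constant"``: concentration is held at the left point's
        value until the next point (renewal-test designs).  After the last
        time point the last concentration is held in both modes.
    """

    times: np.ndarray
    concentrations: np.ndarray
    interpolation: str = "linear"

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.concentrations, dtype=float)
        if t.ndim != 1 or t.size < 1:
            raise ValueError("profile needs at least one time point")
        if t.size != c.size:
            raise ValueError("times and concentrations must have equal length")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("profile times must be strictly increasing")
        if np.any(c < 0):
            raise ValueError("concentrations must be non-negative")
        if not np.all(np.isfinite(c)) or not np.all(np.isfinite(t)):
            raise ValueError("profile values must be finite")
        if self.interpolation not in ("linear", "constant"):
            raise ValueError(f"unknown interpolation {self.interpolation!r}")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "concentrations", c)

    @property
    def max_concentration(self) -> float:
        return float(np.max(self.concentrations))

    def scaled(self, factor: float) -> "ExposureProfile":
        """Return the profile with all concentrations multiplied by ``factor``."""
        if factor < 0:
            raise ValueError("scaling factor must be non-negative")
        return ExposureProfile(self.times, self.concentrations * factor, self.interpolation)

    def concentration_at(self, t: np.ndarray) -> np.ndarray:
        """Concentration at arbitrary times (vectorized)."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        if self.interpolation == "linear":
            return np.interp(t, self.times, self.concentrations)
        idx = np.clip(np.searchsorted(self.times, t, side="right") - 1, 0, len(self.times) - 1)
        return self.concentrations[idx]


def _check_rates(hb: float, kd: float) -> None:
    if hb < 0:
        raise ValueError("background hazard hb must be >= 0")
    if kd <= 0:
        raise ValueError("dominant rate constant kd must be > 0")


@dataclass(frozen=True)
class GutsParamsSD:
    """GUTS-RED-SD parameters.

    hb : background hazard rate (1/day)
    kd : dominant rate constant of damage dynamics (1/day)
    z  : damage threshold above which the extra hazard acts (exposure units)
    b  : killing rate (1 / (exposure unit * day))
    """

    hb: float
    kd: float
    z: float
    b: float

    def __post_init__(self) -> None:
        _check_rates(self.hb, self.kd)
        if self.z < 0:
            raise ValueError("threshold z must be >= 0")
        if self.b < 0:
            raise ValueError("killing rate b must be >= 0")


@dataclass(frozen=True)
class GutsParamsIT:
    """GUTS-RED-IT parameters.

    hb   : background hazard rate (1/day)
    kd   : dominant rate constant (1/day)
    mw   : median of the log-logistic threshold distribution (exposure units)
    beta : log-logistic shape (dimensionless, > 0)
    """

    hb: float
    kd: float
    mw: float
    beta: float

    def __post_init__(self) -> None:
        _check_rates(self.hb, self.kd)
        if self.mw <= 0:
            raise ValueError("median threshold mw must be > 0")
        if self.beta <= 0:
            raise ValueError("shape beta must be > 0")


@dataclass(frozen=True)
class SurvivalCurve:
    """Survival probability over time; S(0) = 1 and non-increasing."""

    times: np.ndarray
    probabilities: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        p = np.asarray(self.probabilities, dtype=float)
        if t.shape != p.shape or t.ndim != 1:
            raise ValueError("times and probabilities must be 1-d and aligned")
        if np.any(p < -1e-12) or np.any(p > 1 + 1e-12):
            raise ValueError("survival probabilities must lie in [0, 1]")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "probabilities", np.clip(p, 0.0, 1.0))


# ---------------------------------------------------------------------------
# damage dynamics
# ---------------------------------------------------------------------------

@dataclass
class _Segment:
    """Damage on one inter-knot interval: D(tau) = A + B*tau + G*exp(-kd*tau),
    tau local in [0, dt]."""

    t0: float
    dt: float
    A: float
    B: float
    G: float
    kd: float

    def value(self, tau: float) -> float:
        return self.A + self.B * tau + self.G * math.exp(-self.kd * tau)

    def derivative_root(self) -> float | None:
        """Interior stationary point of D, or None."""
        if self.B == 0.0 or self.G == 0.0:
            return None
        ratio = self.kd * self.G / self.B
        if ratio <= 0:
            return None
        tau = math.log(ratio) / self.kd
        if 0.0 < tau < self.dt:
            return tau
        return None


def _build_segments(profile: ExposureProfile, kd: float, t_end: float) -> list[_Segment]:
    """Piecewise-analytic damage solution on [0, t_end], one segment per
    exposure knot interval (plus the constant tail after the last knot)."""
    knots = [float(t) for t in profile.times if 0.0 < t < t_end]
    knots = sorted(set([0.0] + knots + [t_end])) if t_end > 0 else [0.0, 0.0]
    pt, pc = profile.times, profile.concentrations
    segments: list[_Segment] = []
    D = 0.0
    for a, b_ in zip(knots[:-1], knots[1:]):
        dt = b_ - a
        if dt <= 0:
            continue
        if profile.interpolation == "linear":
            mid = 0.5 * (a + b_)
            c_a = float(np.interp(a, pt, pc))
            c_b = float(np.interp(b_, pt, pc))
            # guard: outside the profile support interp holds end values
            if mid <= pt[0] or mid >= pt[-1]:
                slope = 0.0
                c_b = c_a
            else:
                slope = (c_b - c_a) / dt
        else:
            idx = int(np.clip(np.searchsorted(pt, a, side="right") - 1, 0, len(pt) - 1))
            c_a = float(pc[idx])
            slope = 0.0
        A = c_a - slope / kd
        seg = _Segment(t0=a, dt=dt, A=A, B=slope, G=D - A, kd=kd)
        segments.append(seg)
        D = seg.value(dt)
    return segments


def damage_series(profile: ExposureProfile, kd: float, times) -> np.ndarray:
    """Scaled damage D(t) at the requested times, solved piecewise analytically.

    Parameters
    ----------
    profile : ExposureProfile
    kd : dominant rate constant (1/day), must be > 0
    times : strictly increasing, non-negative time points (days)
    """
    if kd <= 0:
        raise ValueError("kd must be > 0")
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size == 0:
        raise ValueError("times must be a non-empty 1-d sequence")
    if times.size > 1 and not np.all(np.diff(times) > 0):
        raise ValueError("requested times must be strictly increasing")
    if np.any(times < 0):
        raise ValueError("requested times must be >= 0")
    t_end = float(times[-1])
    if t_end == 0.0:
        return np.zeros_like(times)
    segments = _build_segments(profile, kd, t_end)
    out = np.empty_like(times)
    j = 0
    for i, t in enumerate(times):
        if t == 0.0:
            out[i] = 0.0
            continue
        while j < len(segments) - 1 and t > segments[j].t0 + segments[j].dt + 1e-15:
            j += 1
        seg = segments[j]
        out[i] = seg.value(min(t - seg.t0, seg.dt))
    return out


# ---------------------------------------------------------------------------
# stochastic death
# ---------------------------------------------------------------------------

def _excess_integral_piece(seg: _Segment, z: float, a: float, b: float) -> float:
    """Integral of (D(tau) - z) over [a, b] local time; caller guarantees D >= z."""
    kd = seg.kd
    return (
        (seg.A - z) * (b - a)
        + 0.5 * seg.B * (b * b - a * a)
        - seg.G / kd * (math.exp(-kd * b) - math.exp(-kd * a))
    )


def _crossing(seg: _Segment, z: float, a: float, b: float) -> float:
    """Time in [a, b] at which D crosses z; D(a)-z and D(b)-z bracket zero."""
    if seg.B == 0.0:
        # A + G*exp(-kd tau) = z  ->  closed form
        arg = (z - seg.A) / seg.G
        if arg > 0:
            tau = -math.log(arg) / seg.kd
            if a - 1e-12 <= tau <= b + 1e-12:
                return min(max(tau, a), b)
    f = lambda tau: seg.value(tau) - z
    return brentq(f, a, b, xtol=1e-14, rtol=8.882e-16)


def _segment_excess(seg: _Segment, z: float) -> float:
    """Integral of max(0, D - z) over the whole segment, exact up to the
    root-finder tolerance of crossing times."""
    pts = [0.0, seg.dt]
    root = seg.derivative_root()
    if root is not None:
        pts.insert(1, root)
    total = 0.0
    for a, b in zip(pts[:-1], pts[1:]):
        fa = seg.value(a) - z
        fb = seg.value(b) - z
        if fa >= 0.0 and fb >= 0.0:
            total += _excess_integral_piece(seg, z, a, b)
        elif fa < 0.0 and fb < 0.0:
            continue
        else:
            tc = _crossing(seg, z, a, b)
            if fa >= 0.0:
                total += _excess_integral_piece(seg, z, a, tc)
            else:
                total += _excess_integral_piece(seg, z, tc, b)
    return total


def survival_sd(profile: ExposureProfile, params: GutsParamsSD, times) -> SurvivalCurve:
    """GUTS-RED-SD survival probabilities under a piecewise exposure profile.

    S(t) = exp(-hb*t - b * \\int_0^t max(0, D(tau) - z) dtau), with the hazard
    integral evaluated exactly on each exposure segment.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size == 0:
        raise ValueError("times must be a non-empty 1-d sequence")
    if np.any(np.diff(times) < 0) or np.any(times < 0):
        raise ValueError("times must be non-decreasing and >= 0")
    uniq = np.unique(times)
    t_end = float(uniq[-1])
    if params.b == 0.0 or t_end == 0.0:
        probs = np.exp(-params.hb * times)
        return SurvivalCurve(times, probs)

    # split analytic segments at requested times so cumulative integrals land on them
    segments = _build_segments(profile, params.kd, t_end)
    cum: dict[float, float] = {0.0: 0.0}
    acc = 0.0
    targets = [float(t) for t in uniq if t > 0]
    seg_iter = list(segments)
    ti = 0
    for seg in seg_iter:
        seg_end = seg.t0 + seg.dt
        local_start = 0.0
        while ti < len(targets) and targets[ti] <= seg_end + 1e-12:
            tau = min(max(targets[ti] - seg.t0, 0.0), seg.dt)
            sub = _Segment(
                t0=seg.t0 + local_start,
                dt=tau - local_start,
                A=seg.A + seg.B * local_start,
                B=seg.B,
                G=seg.G * math.exp(-seg.kd * local_start),
                kd=seg.kd,
            )
            # sub uses shifted local time; re-express: D_sub(s) = seg.value(local_start + s)
            if sub.dt > 0:
                acc += _segment_excess(sub, params.z)
            cum[targets[ti]] = acc
            local_start = tau
            ti += 1
        if local_start < seg.dt:
            sub = _Segment(
                t0=seg.t0 + local_start,
                dt=seg.dt - local_start,
                A=seg.A + seg.B * local_start,
                B=seg.B,
                G=seg.G * math.exp(-seg.kd * local_start),
                kd=seg.kd,
            )
            acc += _segment_excess(sub, params.z)
    probs = np.array([math.exp(-params.hb * t - params.b * cum[float(t) if t > 0 else 0.0])
                      for t in times])
    return SurvivalCurve(times, probs)


# ---------------------------------------------------------------------------
# individual tolerance
# ---------------------------------------------------------------------------

def _loglogistic_cdf(x: np.ndarray, mw: float, beta: float) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)
    pos = x > 0
    with np.errstate(over="ignore"):  # (x/mw)^-beta may overflow to inf -> F = 0
        out[pos] = 1.0 / (1.0 + (x[pos] / mw) ** (-beta))
    return out


def survival_it(profile: ExposureProfile, params: GutsParamsIT, times) -> SurvivalCurve:
    """GUTS-RED-IT survival probabilities.

    S(t) = (1 - F(max_{tau<=t} D(tau))) * exp(-hb*t) with a log-logistic
    threshold distribution F (median ``mw``, shape ``beta``).  The running
    maximum of damage is computed from the per-segment analytic extrema.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size == 0:
        raise ValueError("times must be a non-empty 1-d sequence")
    if np.any(np.diff(times) < 0) or np.any(times < 0):
        raise ValueError("times must be non-decreasing and >= 0")
    uniq = np.unique(times)
    t_end = float(uniq[-1])
    running: dict[float, float] = {0.0: 0.0}
    if t_end > 0:
        segments = _build_segments(profile, params.kd, t_end)
        targets = [float(t) for t in uniq if t > 0]
        ti = 0
        rmax = 0.0
        for seg in segments:
            seg_end = seg.t0 + seg.dt
            local_start = 0.0
            while ti < len(targets) and targets[ti] <= seg_end + 1e-12:
                tau = min(max(targets[ti] - seg.t0, 0.0), seg.dt)
                rmax = max(rmax, _segment_max(seg, local_start, tau))
                running[targets[ti]] = rmax
                local_start = tau
                ti += 1
            rmax = max(rmax, _segment_max(seg, local_start, seg.dt))
    dmax = np.array([running[float(t)] if t > 0 else 0.0 for t in times])
    probs = (1.0 - _loglogistic_cdf(dmax, params.mw, params.beta)) * np.exp(-params.hb * times)
    # the running max is non-decreasing, so the toxicant factor is non-increasing
    return SurvivalCurve(times, probs)


def _segment_max(seg: _Segment, a: float, b: float) -> float:
    """Maximum of D over local interval [a, b]."""
    if b <= a:
        return -math.inf if a > seg.dt else seg.value(min(a, seg.dt))
    cands = [seg.value(a), seg.value(b)]
    root = seg.derivative_root()
    if root is not None and a < root < b:
        cands.append(seg.value(root))
    return max(cands)


# ---------------------------------------------------------------------------
# forward sampling
# ---------------------------------------------------------------------------

def sample_survival_counts(curve: SurvivalCurve, n0: int, seed) -> np.ndarray:
    """Sample survivor counts along a survival curve by conditional binomials.

    Deaths between consecutive observation times are Binomial with the
    conditional survival ratio S(t_i)/S(t_{i-1}); the marginal count at
    time t is Binomial(n0, S(t)/S(t_0)).  ``seed`` may be an int or a
    ``numpy.random.Generator``.
    """
    if n0 < 1:
        raise ValueError("n0 must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    S = curve.probabilities
    counts = np.empty(len(S), dtype=int)
    counts[0] = n0
    for i in range(1, len(S)):
        if S[i - 1] <= 0.0:
            counts[i] = 0
            continue
        p = min(S[i] / S[i - 1], 1.0)
        counts[i] = rng.binomial(counts[i - 1], p)
    return counts
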