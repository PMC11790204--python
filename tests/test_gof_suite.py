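"""GoF metric suite against brute-force oracles and worked examples."""

import math

import numpy as np
import pytest
from scipy.stats import binom

from gutsgof.gof_suite import (
    FilterConfig,
    GoFMetrics,
    PairedSeries,
    combine_gof,
    nagelkerke_r2,
    nrmse,
    ppc,
    scale_metric,
    select_fits,
    sppe,
)


def paired(y_obs, y_pred, n0=10, lower=None, upper=None):
    n = len(y_obs)
    return PairedSeries(
        treatment=np.array(["T"] * n),
        time=np.arange(1.0, n + 1),
        y_obs=np.asarray(y_obs, dtype=float),
        y_pred=np.asarray(y_pred, dtype=float),
        n0=np.full(n, n0, dtype=float),
        ci_lower=np.asarray(lower if lower is not None else [0.0] * n, dtype=float),
        ci_upper=np.asarray(upper if upper is not None else [n0] * n, dtype=float),
    )


# -- brute-force oracles (naive loops, no numpy vectorization) --------------

def nrmse_brute(y_obs, y_pred):
    n = len(y_obs)
    ybar = sum(y_obs) / n
    sq = 0.0
    for o, p in zip(y_obs, y_pred):
        sq += (o - p) ** 2
    return 100.0 / ybar * math.sqrt(sq / n)


def sppe_brute(ends):
    per = {}
    for k, (yo, yp, n0) in ends.items():
        per[k] = 100.0 * (yo - yp) / n0
    lo = min(per.values())
    hi = max(per.values())
    return min(lo, 0.0), max(hi, 0.0), per


def ppc_brute(y_obs, lower, upper):
    count = 0
    for o, lo, hi in zip(y_obs, lower, upper):
        if lo <= o <= hi:
            count += 1
    return 100.0 * count / len(y_obs)


def nagelkerke_brute(ends):
    ys = [v[0] for v in ends.values()]
    n0s = [v[1] for v in ends.values()]
    ps = [v[2] for v in ends.values()]
    p_null = sum(ys) / sum(n0s)
    L0 = 1.0
    LM = 1.0
    for y, n0, p in zip(ys, n0s, ps):
        L0 *= float(binom.pmf(y, n0, p_null))
        LM *= float(binom.pmf(y, n0, p))
    n = len(ys)
    return (1 - (L0 / LM) ** (2 / n)) / (1 - L0 ** (2 / n))


class TestWorkedExamples:
    def test_nrmse_direct(self):
        p = paired([10, 8, 5, 2], [9, 8, 6, 2])
        assert p.mean_observed == 6.25
        assert nrmse(p) == pytest.approx(100 / 6.25 * math.sqrt(2 / 4), rel=1e-12)
        assert nrmse(p) == pytest.approx(11.314, abs=1e-3)

    def test_nrmse_perfect_and_scale_invariance(self):
        assert nrmse(paired([5, 4, 3], [5, 4, 3])) == 0.0
        a = nrmse(paired([10, 8, 5], [9, 8, 6], n0=10))
        b = nrmse(paired([30, 24, 15], [27, 24, 18], n0=30))
        assert a == pytest.approx(b, rel=1e-12)

    def test_nrmse_zero_mean_rejected(self):
        with pytest.raises(ValueError, match="normalization"):
            nrmse(paired([0, 0], [1, 1]))

    def test_sppe_direct(self):
        lo, hi, per = sppe(
            {"a": (10, 8, 10), "b": (5, 6, 10), "c": (0, 1, 10)}
        )
        assert per == {"a": 20.0, "b": -10.0, "c": -10.0}
        assert (lo, hi) == (-10.0, 20.0)

    def test_sppe_clipping(self):
        lo, hi, per = sppe({"a": (9, 10, 10), "b": (4, 6, 10)})
        assert per == {"a": -10.0, "b": -20.0}
        assert (lo, hi) == (-20.0, 0.0)

    def test_sppe_perfect(self):
        lo, hi, _ = sppe({"a": (7, 7, 10), "b": (2, 2, 10)})
        assert (lo, hi) == (0.0, 0.0)

    def test_ppc_count_and_boundaries(self):
        obs = list(range(10))
        lower = [0] * 10
        upper = [8] * 8 + [-1, -1]  # last two outside
        p = paired(obs, obs, lower=lower, upper=upper)
        assert ppc(p) == 80.0
        # observation exactly at a bound counts as inside
        q = paired([5], [5], lower=[5], upper=[5])
        assert ppc(q) == 100.0

    def test_nagelkerke_direct(self):
        ends = {"a": (9, 10, 0.9), "b": (1, 10, 0.1)}
        r2 = nagelkerke_r2(ends)
        L0 = (10 * 0.5**10) ** 2
        LM = (10 * 0.9**9 * 0.1) ** 2
        expect = (1 - L0 / LM) / (1 - L0)
        assert r2 == pytest.approx(expect, rel=1e-9)
        assert r2 == pytest.approx(0.99946, abs=1e-5)

    def test_nagelkerke_null_equals_model(self):
        # prediction equals pooled null probability -> 0
        ends = {"a": (5, 10, 0.5), "b": (5, 10, 0.5)}
        assert nagelkerke_r2(ends) == pytest.approx(0.0, abs=1e-12)

    def test_nagelkerke_saturated_null_rejected(self):
        with pytest.raises(ValueError, match="saturated"):
            nagelkerke_r2({"a": (10, 10, 0.9), "b": (10, 10, 0.8)})


class TestBruteForceAgreement:
    def test_thousand_random_fixtures(self, rng):
        for _ in range(1000):
            n = int(rng.integers(2, 12))
            n0 = int(rng.integers(5, 30))
            y_obs = rng.integers(1, n0 + 1, size=n).astype(float)
            y_pred = rng.uniform(0, n0, size=n)
            lower = rng.uniform(0, n0 / 2, size=n)
            upper = lower + rng.uniform(0, n0 / 2, size=n)
            p = paired(y_obs, y_pred, n0=n0, lower=lower, upper=upper)
            assert nrmse(p) == pytest.approx(nrmse_brute(y_obs, y_pred), abs=1e-12)
            assert ppc(p) == pytest.approx(ppc_brute(y_obs, lower, upper), abs=1e-12)
            k = int(rng.integers(2, 6))
            ends = {
                f"t{i}": (
                    int(rng.integers(0, n0 + 1)),
                    float(rng.uniform(0, n0)),
                    n0,
                )
                for i in range(k)
            }
            assert sppe(ends) == pytest.approx(sppe_brute(ends), abs=1e-12)
            ends_r2 = {
                f"t{i}": (int(rng.integers(1, n0)), n0, float(rng.uniform(0.05, 0.95)))
                for i in range(k)
            }
            try:
                expect = nagelkerke_brute(ends_r2)
            except ZeroDivisionError:
                continue
            assert nagelkerke_r2(ends_r2) == pytest.approx(expect, rel=1e-9, abs=1e-9)


class TestScalingAndCombination:
    @pytest.mark.parametrize(
        "name,value,expect",
        [
            ("nrmse", 0.0, 1.0),
            ("nrmse", 150.0, 0.0),
            ("nrmse", 46.0, 0.54),
            ("ppc", 100.0, 1.0),
            ("ppc", 54.0, 0.54),
            ("sppe_min", -35.5, 0.645),
            ("sppe_max", 8.45, 0.9155),
            ("pseudo_r2", -0.3, 0.0),
            ("pseudo_r2", 0.7, 0.7),
        ],
    )
    def test_scale_metric(self, name, value, expect):
        assert scale_metric(name, value) == pytest.approx(expect, abs=1e-12)

    def test_unknown_metric_rejected(self):
        with pytest.raises(ValueError):
            scale_metric("r2", 0.5)

    def test_combine(self):
        scaled = dict(zip(["nrmse", "ppc", "sppe_min", "sppe_max"], [0.8, 0.9, 0.6, 1.0]))
        assert combine_gof(scaled, "average") == pytest.approx(0.825)
        assert combine_gof(scaled, "minimum") == pytest.approx(0.6)
        with pytest.raises(ValueError):
            combine_gof(scaled, "average", members=("nrmse", "pseudo_r2"))

    def test_minimum_never_exceeds_average(self, rng):
        for _ in range(50):
            scaled = {
                m: float(rng.uniform(0, 1))
                for m in ["nrmse", "ppc", "sppe_min", "sppe_max"]
            }
            assert combine_gof(scaled, "minimum") <= combine_gof(scaled, "average")

    def test_perfect_fit_metrics(self):
        p = paired([9, 7, 4], [9, 7, 4], lower=[8, 6, 3], upper=[10, 8, 5])
        m = GoFMetrics(
            nrmse=nrmse(p),
            ppc=ppc(p),
            sppe_min=0.0,
            sppe_max=0.0,
            sppe_per_treatment={},
            pseudo_r2=1.0,
        )
        assert m.nrmse == 0.0 and m.ppc == 100.0
        assert all(v == 1.0 for v in m.scaled.values())
        assert m.avg_gof == 1.0 and m.min_gof == 1.0

    def test_uniform_bias_degrades_monotonically(self):
        y = np.array([10.0, 8.0, 5.0, 3.0])
        prev_nrmse = -1.0
        prev_avg = 2.0
        for bias in [0.0, 0.5, 1.0, 1.5]:
            p = paired(y, np.clip(y - bias, 0, None), lower=y - 1, upper=y + 1)
            v = nrmse(p)
            assert v > prev_nrmse
            m = GoFMetrics(
                nrmse=v,
                ppc=ppc(p),
                sppe_min=min(-10 * bias, 0.0),
                sppe_max=max(10 * bias, 0.0),
                sppe_per_treatment={},
                pseudo_r2=0.5,
            )
            assert m.avg_gof <= prev_avg
            prev_nrmse, prev_avg = v, m.avg_gof


class _Fit:
    def __init__(self, avg_gof, effects, n_treatments=3):
        self.metrics = GoFMetrics(
            nrmse=100 * (1 - avg_gof),
            ppc=100 * avg_gof,
            sppe_min=-100 * (1 - avg_gof),
            sppe_max=100 * (1 - avg_gof),
            sppe_per_treatment={},
            pseudo_r2=avg_gof,
        )
        self.end_mortalities = effects
        self.n_treatments = n_treatments


class TestSelectFits:
    def test_effect_filter_counts(self):
        fits = [_Fit(0.5, [e, 0.1]) for e in (0.9, 0.8, 0.7, 0.65, 0.5, 0.2)]
        kept = select_fits(fits, FilterConfig(stratify=False))
        assert len(kept) == 3  # inclusive at exactly 0.70

    def test_single_treatment_always_excluded(self):
        fits = [_Fit(0.5, [0.95], n_treatments=1), _Fit(0.5, [0.95])]
        kept = select_fits(fits, FilterConfig(stratify=False))
        assert len(kept) == 1 and kept[0].n_treatments == 3

    def test_stratification_balances_bins(self, rng):
        fits = [_Fit(g, [0.9]) for g in rng.uniform(0, 1, size=200)]
        kept = select_fits(fits, FilterConfig(n_bins=5, per_bin=10), seed=1)
        gofs = np.array([f.metrics.avg_gof for f in kept])
        counts = np.histogram(gofs, bins=np.linspace(0, 1, 6))[0]
        assert np.all(counts <= 10)

    def test_empty_selection_warns(self):
        fits = [_Fit(0.5, [0.2])]
        with pytest.warns(UserWarning):
            assert select_fits(fits) == []

    def test_seeded_subsampling_reproducible(self, rng):
        fits = [_Fit(g, [0.9]) for g in rng.uniform(0, 1, size=50)]
        a = select_fits(fits, FilterConfig(per_bin=3), seed=5)
        b = select_fits(fits, FilterConfig(per_bin=3), seed=5)
        assert [id(f) for f in a] == [id(f) for f in b]
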