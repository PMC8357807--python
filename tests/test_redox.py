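"""Trace interpolation, oxidation-rate fitting, hit calling, partitions."""

import numpy as np
import pytest

from macroscreen import redox
from macroscreen.redox import HitCall, HitPartition, IntensityTrace

from conftest import make_trace


class TestInterpolation:
    def test_linear_midpoint(self):
        tr = make_trace([0.0, 2.0], [1.0, 0.0])
        pts = redox.interpolate_trace(tr, marks=[1.0])
        assert pts[0].y == pytest.approx(0.5)
        # display color is the segment midpoint between W0 and Y0
        assert np.allclose(pts[0].color, [240.0, 204.0, 127.5])

    def test_mark_on_observation_returned_unchanged(self):
        tr = make_trace([0.0, 1.0, 2.0], [1.0, 0.7, 0.1])
        pts = redox.interpolate_trace(tr, marks=[1.0])
        assert pts[0].y == 0.7
        assert not pts[0].extrapolated

    def test_replicate_mean(self):
        tr = IntensityTrace(
            "m", "fumarate",
            replicates=[
                (np.array([0.0, 1.0]), np.array([1.0, 0.4])),
                (np.array([0.0, 1.0]), np.array([1.0, 0.6])),
            ],
        )
        pts = redox.interpolate_trace(tr, marks=[1.0])
        assert pts[0].y == pytest.approx(0.5)

    def test_extrapolation_flagged(self):
        tr = make_trace([1.0, 2.0], [1.0, 0.5])
        pts = redox.interpolate_trace(tr, marks=[0.0, 1.5])
        assert pts[0].extrapolated and not pts[1].extrapolated

    def test_unordered_timestamps_rejected(self):
        with pytest.raises(ValueError):
            make_trace([1.0, 0.5], [1.0, 0.5])


class TestRateFitting:
    def test_exact_line_recovered(self):
        t = np.arange(0.0, 4.1, 1.0)
        fit = redox.fit_oxidation_rate(make_trace(t, 1.0 - 0.25 * t))
        assert fit.rate_per_h == pytest.approx(0.25, abs=1e-12)
        assert not fit.flags

    def test_constant_trace_flagged(self):
        fit = redox.fit_oxidation_rate(make_trace([0, 1, 2, 3], [1, 1, 1, 1]))
        assert fit.rate_per_h == 0.0
        assert "no_decline" in fit.flags

    def test_exponential_matches_brute_force_window_fit(self):
        t = np.arange(0.0, 6.01, 0.25)
        y = np.exp(-1.0 * t)
        fit = redox.fit_oxidation_rate(make_trace(t, y))

        # independent brute-force oracle: locate the 20-80% dynamic-range
        # window by scanning, then normal-equation OLS on points inside it
        rng_ = y.max() - y.min()
        hi, lo = y.min() + 0.8 * rng_, y.min() + 0.2 * rng_

        def crossing(level):
            for i in range(1, len(t)):
                if y[i] <= level:
                    return t[i - 1] + (y[i - 1] - level) * (t[i] - t[i - 1]) / (
                        y[i - 1] - y[i]
                    )
            raise AssertionError

        t0, t1 = crossing(hi), crossing(lo)
        m = (t >= t0) & (t <= t1)
        n = m.sum()
        sx, sy = t[m].sum(), y[m].sum()
        sxx, sxy = (t[m] ** 2).sum(), (t[m] * y[m]).sum()
        slope = (n * sxy - sx * sy) / (n * sxx - sx**2)
        assert fit.rate_per_h == pytest.approx(abs(slope), rel=1e-10)
        assert fit.window_h == pytest.approx((t0, t1))

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="at least 4"):
            redox.fit_oxidation_rate(make_trace([0, 1, 2], [1.0, 0.5, 0.2]))


def _screen_traces(
    n_normal=80, n_slowed=10, n_eliminated=6, n_controls=10, noise_sd=0.02, seed=0,
    k_slowed=0.2,
):
    """Trace-level synthetic run: returns (traces, planted hit ids)."""
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, 40.1, 1.0)
    traces, hits = [], set()

    def make(mid, k, cls):
        y = np.exp(-k * t) + rng.normal(0, noise_sd, t.size)
        traces.append(
            IntensityTrace(mid, "fumarate", replicates=[(t, y)],
                           wells=[("P1", mid)], control_class=cls)
        )

    for i in range(n_controls):
        make(f"qwt{i}", float(rng.normal(1.0, 0.1)), "quasi_wild_type")
    for i in range(n_normal):
        make(f"norm{i}", float(np.clip(rng.normal(1.0, 0.1), 0.05, None)), "test_mutant")
    for i in range(n_slowed):
        make(f"slow{i}", k_slowed, "test_mutant")
        hits.add(f"slow{i}")
    for i in range(n_eliminated):
        make(f"elim{i}", 0.0, "test_mutant")
        hits.add(f"elim{i}")
    return traces, hits


class TestHitCalling:
    def test_planted_hits_recovered(self):
        traces, planted = _screen_traces(seed=1)
        calls = redox.call_hits(traces)
        called = {c.mutant_id for c in calls
                  if c.control_class == "test_mutant"
                  and c.status in ("slowed", "eliminated")}
        assert planted <= called
        assert len(called - planted) <= 2  # >= 97% specificity on 80 normals

    def test_eliminated_mutants_have_no_t50(self):
        traces, _ = _screen_traces(seed=2)
        for c in redox.call_hits(traces):
            if c.status == "eliminated":
                assert c.t50_h is None
            elif c.status == "normal":
                assert c.t50_h is not None

    def test_blank_traces_called_eliminated(self):
        traces, _ = _screen_traces(seed=3)
        rng = np.random.default_rng(99)
        t = np.arange(0.0, 40.1, 1.0)
        traces.append(
            IntensityTrace("blank1", "fumarate",
                           replicates=[(t, np.ones_like(t) + rng.normal(0, 0.02, t.size))],
                           wells=[("P1", "A1")], control_class="blank_no_cell")
        )
        calls = {c.mutant_id: c for c in redox.call_hits(traces)}
        assert calls["blank1"].status == "eliminated"

    def test_growth_failure_excluded_even_if_planted_hit(self):
        traces, planted = _screen_traces(seed=4)
        victim = sorted(planted)[0]
        calls = redox.call_hits(traces, qc_failures={("P1", victim)})
        by_id = {c.mutant_id: c for c in calls}
        assert by_id[victim].status == "excluded_growth_failure"
        part = redox.partition_hits(calls, calls)
        assert victim not in part.all_hits

    def test_too_few_controls_refuses(self):
        traces, _ = _screen_traces(n_controls=3, seed=5)
        with pytest.raises(ValueError, match="quasi-wild-type"):
            redox.call_hits(traces)

    def test_hit_set_monotone_in_threshold(self):
        traces, _ = _screen_traces(seed=6)

        def hit_set(k_sd):
            return {c.mutant_id for c in redox.call_hits(traces, k_sd=k_sd)
                    if c.status in ("slowed", "eliminated")}

        h2, h3, h5 = hit_set(2.0), hit_set(3.0), hit_set(5.0)
        assert h5 <= h3 <= h2


class TestPartition:
    def test_set_algebra_on_planted_truth(self):
        def call(mid, status, acceptor):
            return HitCall(mid, acceptor, status,
                           None if status == "eliminated" else 1.0, 0.5)

        fum_hits = [f"f{i}" for i in range(5)] + [f"b{i}" for i in range(7)]
        nit_hits = [f"n{i}" for i in range(3)] + [f"b{i}" for i in range(7)]
        everyone = sorted(set(fum_hits) | set(nit_hits) | {"ok1", "ok2"})
        fum = [call(m, "slowed" if m in fum_hits else "normal", "fumarate")
               for m in everyone]
        nit = [call(m, "eliminated" if m in nit_hits else "normal", "nitrate")
               for m in everyone]
        part = redox.partition_hits(fum, nit)
        assert part.counts == (5, 3, 7)
        assert part.total == 15
        # conservation: per-assay hit counts decompose over the partition
        assert len(part.fumarate_only) + len(part.both) == len(fum_hits)
        assert len(part.nitrate_only) + len(part.both) == len(nit_hits)
        assert not (part.fumarate_only & part.nitrate_only & part.both)

    def test_empty_calls_give_empty_partition(self):
        part = redox.partition_hits([], [])
        assert part.counts == (0, 0, 0) and part.total == 0

    def test_lopsided_assays_warn(self):
        fum = [HitCall("m1", "fumarate", "slowed", 9.0, 0.1)]
        with pytest.warns(UserWarning, match="one acceptor"):
            part = redox.partition_hits(fum, [])
        assert part.fumarate_only == {"m1"}


class TestTriage:
    def test_unannotated_hits_flow_to_unknown_shortlist(self):
        part = HitPartition({"a", "b"}, {"c"}, {"d", "e", "f"})
        counts, shortlist = redox.triage_categories(
            part, {"a": "fumarate reduction", "c": "nitrate reduction"}
        )
        table = dict(zip(counts.category, counts.n_hits))
        assert table == {"fumarate reduction": 1, "nitrate reduction": 1, "unknown": 4}
        assert shortlist == ["b", "d", "e", "f"]

    def test_counts_conserve_partition_total(self):
        rng = np.random.default_rng(0)
        members = {f"m{i}" for i in range(30)}
        part = HitPartition(set(list(members)[:10]), set(list(members)[10:18]),
                            set(list(members)[18:]))
        cats = {m: rng.choice(["cat1", "cat2", "cat3"]) for m in members}
        counts, _ = redox.triage_categories(part, cats)
        assert counts.n_hits.sum() == part.total

    def test_single_category(self):
        part = HitPartition({"a"}, set(), {"b"})
        counts, shortlist = redox.triage_categories(
            part, {"a": "fumarate reductase", "b": "fumarate reductase"}
        )
        assert len(counts) == 1 and shortlist == []
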