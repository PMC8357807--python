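"""Yellow-intensity time courses, oxidation rates, and hit calling.

Well-color samples become per-mutant normalized yellow-intensity traces
``y(t)``; the hit-calling statistic is ``t50``, the first time the
replicate-mean trace falls to half its initial intensity.  Quasi-wild-type
control wells on the same run provide the null distribution: a mutant is
``slowed`` when its t50 exceeds the control mean by more than ``k_sd``
control standard deviations, and ``eliminated`` when the trace never
reaches the half-way level inside the observation window (about 40 h of
imaging).  Wells flagged as growth failures by plate QC are excluded so a
dead culture is never reported as an oxidation phenotype.

Hits from the fumarate and nitrate assays are combined by set algebra into
the fumarate-only / nitrate-only / both partition, and triaged by
functional-category annotation; unannotated hits fall into the "unknown"
bucket that feeds the electrochemical validation shortlist.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .colors import DEFAULT_REFERENCES, ReferenceColors, display_color, yellow_intensity

__all__ = [
    "IntensityTrace",
    "InterpolatedPoint",
    "RateFit",
    "HitCall",
    "HitPartition",
    "build_traces",
    "interpolate_trace",
    "fit_oxidation_rate",
    "call_hits",
    "partition_hits",
    "triage_categories",
    "yellow_intensity",
]

HIT_STATUSES = ("normal", "slowed", "eliminated", "excluded_growth_failure")


@dataclass
class IntensityTrace:
    """Per-mutant yellow-intensity time series with replicate structure."""

    mutant_id: str
    acceptor: str  # "fumarate" or "nitrate"
    replicates: list  # list of (times_h, y) ndarray pairs
    wells: list = field(default_factory=list)  # (plate_id, well) per replicate
    control_class: str = "test_mutant"

    def __post_init__(self) -> None:
        if not self.replicates:
            raise ValueError("trace needs at least one replicate")
        clean = []
        for t, y in self.replicates:
            t = np.asarray(t, dtype=float)
            y = np.asarray(y, dtype=float)
            if t.shape != y.shape or t.size == 0:
                raise ValueError("replicate time/intensity arrays malformed")
            if np.any(np.diff(t) <= 0):
                raise ValueError("timestamps must be strictly increasing")
            clean.append((t, y))
        self.replicates = clean

    def mean_trace(self) -> tuple[np.ndarray, np.ndarray]:
        """Replicate-mean trace on the first replicate's time grid.

        Replicates measured on slightly different grids are linearly
        interpolated onto the first grid before averaging.
        """
        t0, y0 = self.replicates[0]
        ys = [y0] + [np.interp(t0, t, y) for t, y in self.replicates[1:]]
        return t0, np.mean(ys, axis=0)


def build_traces(
    samples: pd.DataFrame,
    catalog,
    acceptor: str,
    refs: ReferenceColors = DEFAULT_REFERENCES,
) -> dict[str, IntensityTrace]:
    """Assemble per-mutant traces from the long well-sample table.

    ``samples`` must have columns plate_id, well, timestamp_h, r, g, b;
    the catalog maps each (plate, well) to its mutant and control class.
    Wells of the same mutant become replicates.
    """
    traces: dict[str, dict] = {}
    for (plate_id, well), grp in samples.groupby(["plate_id", "well"], sort=True):
        entry = catalog.lookup(plate_id, well)
        grp = grp.sort_values("timestamp_h")
        y = yellow_intensity(grp[["r", "g", "b"]].to_numpy(), refs)
        rec = traces.setdefault(
            entry["mutant_id"],
            {"replicates": [], "wells": [], "control_class": entry["control_class"]},
        )
        rec["replicates"].append((grp["timestamp_h"].to_numpy(), np.atleast_1d(y)))
        rec["wells"].append((plate_id, well))
    return {
        mid: IntensityTrace(
            mutant_id=mid,
            acceptor=acceptor,
            replicates=rec["replicates"],
            wells=rec["wells"],
            control_class=rec["control_class"],
        )
        for mid, rec in traces.items()
    }


@dataclass
class InterpolatedPoint:
    """One interpolated display point of a colored-circle time strip."""

    hour: float
    y: float
    color: np.ndarray  # reconstructed display RGB (float)
    extrapolated: bool = False


def interpolate_trace(
    trace: IntensityTrace,
    marks: list[float] = (0.0, 1.0, 2.0, 3.0, 4.0),
    refs: ReferenceColors = DEFAULT_REFERENCES,
) -> list[InterpolatedPoint]:
    """Replicate-mean intensity linearly interpolated at the given hours.

    Display colors are reconstructed as ``W0 + y * (Y0 - W0)``; marks
    outside the observed time range are flagged as extrapolation (the
    boundary value is returned).
    """
    t, y = trace.mean_trace()
    out = []
    for m in marks:
        extrap = not (t[0] <= m <= t[-1])
        yi = float(np.interp(m, t, y))
        out.append(
            InterpolatedPoint(
                hour=float(m), y=yi, color=display_color(yi, refs), extrapolated=extrap
            )
        )
    return out


@dataclass
class RateFit:
    """OLS oxidation rate over the central (linear) decline window."""

    rate_per_h: float
    window_h: tuple[float, float] | None
    flags: set = field(default_factory=set)


def _first_crossing(t: np.ndarray, y: np.ndarray, level: float) -> float | None:
    """First time the trace falls to ``level`` (linear interpolation)."""
    below = y <= level
    if below[0]:
        return float(t[0])
    idx = np.nonzero(below)[0]
    if idx.size == 0:
        return None
    i = idx[0]
    t0, t1, y0, y1 = t[i - 1], t[i], y[i - 1], y[i]
    if y1 == y0:
        return float(t1)
    return float(t0 + (y0 - level) * (t1 - t0) / (y0 - y1))


def fit_oxidation_rate(
    trace: IntensityTrace,
    window: tuple[float, float] = (0.2, 0.8),
    min_range: float = 0.1,
) -> RateFit:
    """Linear-fit oxidation rate of the replicate-mean intensity curve.

    The "linear portion" is taken as the times when the curve lies within
    the ``window`` fractions of its own dynamic range (default 20-80%),
    bounded by the first crossings of the upper and lower levels.  The
    rate is the magnitude of the OLS slope over the observed points in
    that window (falling back to the secant through the interpolated
    window endpoints when fewer than two points fall inside).  A curve
    whose dynamic range is below ``min_range`` gets rate 0 with a
    ``no_decline`` flag.
    """
    t, y = trace.mean_trace()
    if t.size < 4:
        raise ValueError("need at least 4 points to fit an oxidation rate")
    lo_frac, hi_frac = window
    rng = float(y.max() - y.min())
    if rng < min_range:
        return RateFit(rate_per_h=0.0, window_h=None, flags={"no_decline"})
    hi_level = y.min() + hi_frac * rng
    lo_level = y.min() + lo_frac * rng
    t_start = _first_crossing(t, y, hi_level)
    t_end = _first_crossing(t, y, lo_level)
    if t_start is None or t_end is None or t_end <= t_start:
        return RateFit(rate_per_h=0.0, window_h=None, flags={"no_decline"})
    mask = (t >= t_start) & (t <= t_end)
    if mask.sum() >= 2:
        slope = np.polyfit(t[mask], y[mask], 1)[0]
    else:
        slope = (lo_level - hi_level) / (t_end - t_start)
    return RateFit(rate_per_h=float(abs(slope)), window_h=(t_start, t_end))


@dataclass
class HitCall:
    """Per-mutant oxidation-phenotype classification for one acceptor."""

    mutant_id: str
    acceptor: str
    status: str
    t50_h: float | None
    rate_per_h: float | None
    control_class: str = "test_mutant"

    def __post_init__(self) -> None:
        if self.status not in HIT_STATUSES:
            raise ValueError(f"unknown status {self.status!r}")
        if self.status == "eliminated":
            self.t50_h = None


def call_hits(
    traces,
    qc_failures: set | None = None,
    k_sd: float = 3.0,
    min_controls: int = 8,
) -> list[HitCall]:
    """Classify every trace of one acceptor run as normal/slowed/eliminated.

    ``qc_failures`` is the set of (plate_id, well) addresses flagged
    ``growth_failure`` by plate QC; any trace with such a well is returned
    as ``excluded_growth_failure``.  The slowed threshold is
    ``mean + k_sd * SD`` of the quasi-wild-type controls' t50 values; at
    least ``min_controls`` controls with a half-crossing are required,
    otherwise no calls are made (explicit error).
    """
    traces = list(traces)
    qc_failures = qc_failures or set()

    def trace_t50(trace: IntensityTrace) -> float | None:
        t, y = trace.mean_trace()
        return _first_crossing(t, y, 0.5 * y[0])

    control_t50s = []
    for tr in traces:
        if tr.control_class == "quasi_wild_type" and not (set(tr.wells) & qc_failures):
            t50 = trace_t50(tr)
            if t50 is not None:
                control_t50s.append(t50)
    if len(control_t50s) < min_controls:
        raise ValueError(
            f"only {len(control_t50s)} usable quasi-wild-type controls; "
            f"need at least {min_controls} to form the null distribution"
        )
    ctrl_mean = float(np.mean(control_t50s))
    ctrl_sd = float(np.std(control_t50s, ddof=1))
    threshold = ctrl_mean + k_sd * ctrl_sd

    calls = []
    for tr in traces:
        if set(tr.wells) & qc_failures:
            calls.append(
                HitCall(tr.mutant_id, tr.acceptor, "excluded_growth_failure", None, None,
                        tr.control_class)
            )
            continue
        t50 = trace_t50(tr)
        try:
            rate = fit_oxidation_rate(tr).rate_per_h
        except ValueError:
            rate = None
        if t50 is None:
            status = "eliminated"
        elif t50 > threshold:
            status = "slowed"
        else:
            status = "normal"
        calls.append(HitCall(tr.mutant_id, tr.acceptor, status, t50, rate, tr.control_class))
    return calls


@dataclass
class HitPartition:
    """Cross-assay hit bookkeeping: fumarate-only / nitrate-only / both."""

    fumarate_only: set
    nitrate_only: set
    both: set

    @property
    def counts(self) -> tuple[int, int, int]:
        return (len(self.fumarate_only), len(self.nitrate_only), len(self.both))

    @property
    def total(self) -> int:
        return sum(self.counts)

    @property
    def all_hits(self) -> set:
        return self.fumarate_only | self.nitrate_only | self.both


def _hit_sets(calls: list[HitCall]) -> tuple[set, set]:
    """(hits, assayed) mutant-id sets among the test mutants of one run."""
    hits, assayed = set(), set()
    for c in calls:
        if c.control_class != "test_mutant" or c.status == "excluded_growth_failure":
            continue
        assayed.add(c.mutant_id)
        if c.status in ("slowed", "eliminated"):
            hits.add(c.mutant_id)
    return hits, assayed


def partition_hits(
    fumarate_calls: list[HitCall], nitrate_calls: list[HitCall]
) -> HitPartition:
    """Set-algebra partition of hits across the two acceptor assays.

    A mutant is a hit in an assay iff its status there is slowed or
    eliminated.  Mutants assayed in only one acceptor are counted in that
    assay alone, with a warning.
    """
    fum_hits, fum_assayed = _hit_sets(fumarate_calls)
    nit_hits, nit_assayed = _hit_sets(nitrate_calls)
    lopsided = fum_assayed ^ nit_assayed
    if lopsided:
        warnings.warn(
            f"{len(lopsided)} mutant(s) assayed in only one acceptor; "
            "counted in the present assay only",
            stacklevel=2,
        )
    return HitPartition(
        fumarate_only=fum_hits - nit_hits,
        nitrate_only=nit_hits - fum_hits,
        both=fum_hits & nit_hits,
    )


def triage_categories(
    partition: HitPartition, annotations
) -> tuple[pd.DataFrame, list[str]]:
    """Count hits per functional category; unannotated hits are "unknown".

    ``annotations`` maps mutant_id -> category (dict, Series, or a
    DataFrame with columns mutant_id, category).  Returns the per-category
    count table and the shortlist of unknown-function hits that feeds the
    electrochemical validation stage.
    """
    if isinstance(annotations, pd.DataFrame):
        mapping = dict(zip(annotations["mutant_id"], annotations["category"]))
    else:
        mapping = dict(annotations)
    rows = [
        {"mutant_id": m, "category": mapping.get(m, "unknown")}
        for m in sorted(partition.all_hits)
    ]
    df = pd.DataFrame(rows, columns=["mutant_id", "category"])
    counts = (
        df.groupby("category").size().rename("n_hits").reset_index()
        if not df.empty
        else pd.DataFrame(columns=["category", "n_hits"])
    )
    shortlist = sorted(df.loc[df["category"] == "unknown", "mutant_id"])
    return counts, shortlist
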