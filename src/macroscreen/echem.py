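"""Potentiostat record analysis for the electrochemical validation stage.

Chronoamperometry (CA): the working electrode is poised at a fixed
potential (cathodic: -378 mV vs SHE, anodic: +422 mV) and current is
recorded over time.  The steady-state current of a segment is the mean of
its final 100 samples; the *biological* current of a cathode experiment is
the steady-state current before addition of the respiratory inhibitor
Antimycin A minus the steady-state (abiotic) current after it.  Cathodic
currents are negative, so a cathode-active strain yields a negative
biological current.

Cyclic voltammetry (CV): potential is swept down (+222 to -322 mV vs SHE,
the analysis window) and back.  Each branch is smoothed with a penalized
cubic smoothing spline, an approximate derivative is taken on a 1 mV grid,
and the potential of maximum |dI/dE| marks the branch's wave inflection;
the midpoint (formal) potential is the mean of the forward and reverse
inflection potentials.

Strain comparison: per-strain replicate biological currents are fitted to
a one-factor linear model, assessed by type-II ANOVA, and every strain is
compared against the wild-type reference with Tukey's HSD.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import make_smoothing_spline

__all__ = [
    "CATrace",
    "CVScan",
    "StrainCurrentSummary",
    "MidpointResult",
    "StrainComparison",
    "steady_state_current",
    "biological_current",
    "estimate_midpoint",
    "compare_strains",
    "edf_from_spar",
    "to_she",
    "read_ca_csv",
    "read_cv_csv",
    "write_ca_csv",
    "write_cv_csv",
]

#: Default analysis window for CV midpoint estimation, mV vs SHE.
CV_ANALYSIS_BOUNDS = (-322.0, 222.0)

#: Conventional potential of the Ag/AgCl (1 M KCl) reference vs SHE, mV.
AG_AGCL_OFFSET_MV = 222.0


def to_she(potential_mV, reference: str = "SHE", offset_mV: float | None = None):
    """Convert a potential to the SHE scale.

    ``reference`` is ``"SHE"`` (no-op) or ``"Ag/AgCl"``; a custom
    ``offset_mV`` overrides the built-in Ag/AgCl offset.
    """
    potential_mV = np.asarray(potential_mV, dtype=float)
    if reference == "SHE":
        off = 0.0
    elif reference == "Ag/AgCl":
        off = AG_AGCL_OFFSET_MV if offset_mV is None else offset_mV
    else:
        raise ValueError(f"unknown reference electrode {reference!r}")
    return potential_mV + off


@dataclass
class CATrace:
    """A chronoamperometry record: current vs time at fixed potential."""

    strain_id: str
    times_s: np.ndarray
    currents_A: np.ndarray
    mode: str = "cathodic"  # cathodic (-378 mV vs SHE) or anodic (+422 mV)
    poised_potential_mV: float | None = None
    inhibitor_time_s: float | None = None
    replicate_id: str = "r1"

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.currents_A = np.asarray(self.currents_A, dtype=float)
        if self.times_s.shape != self.currents_A.shape:
            raise ValueError("times and currents must have equal length")
        if np.any(np.diff(self.times_s) <= 0):
            raise ValueError("CA timestamps must be strictly increasing")
        if self.mode not in ("cathodic", "anodic"):
            raise ValueError(f"unknown CA mode {self.mode!r}")


@dataclass
class CVScan:
    """A cyclic voltammogram split into forward and reverse branches.

    ``forward`` descends from the high to the low potential bound;
    ``reverse`` ascends back.  Columns: potential mV vs SHE, current A.
    """

    strain_id: str
    forward_potential_mV: np.ndarray
    forward_current_A: np.ndarray
    reverse_potential_mV: np.ndarray
    reverse_current_A: np.ndarray
    replicate_id: str = "r1"

    def __post_init__(self) -> None:
        for name in ("forward", "reverse"):
            E = np.asarray(getattr(self, f"{name}_potential_mV"), dtype=float)
            I = np.asarray(getattr(self, f"{name}_current_A"), dtype=float)
            if E.shape != I.shape:
                raise ValueError(f"{name} branch: potential/current length mismatch")
            setattr(self, f"{name}_potential_mV", E)
            setattr(self, f"{name}_current_A", I)
        if np.any(np.diff(self.forward_potential_mV) >= 0):
            raise ValueError("forward branch potentials must be strictly decreasing")
        if np.any(np.diff(self.reverse_potential_mV) <= 0):
            raise ValueError("reverse branch potentials must be strictly increasing")


@dataclass
class StrainCurrentSummary:
    """Replicate biological currents for one strain and electrode mode."""

    strain_id: str
    currents_A: list[float]
    mode: str = "cathodic"

    @property
    def n(self) -> int:
        return len(self.currents_A)

    @property
    def mean_A(self) -> float:
        return float(np.mean(self.currents_A))

    @property
    def sd_A(self) -> float:
        return float(np.std(self.currents_A, ddof=1)) if self.n > 1 else 0.0


# ---------------------------------------------------------------------------
# Chronoamperometry


def steady_state_current(trace: CATrace, window: int = 100) -> float:
    """Mean of the final ``window`` current samples of a CA trace.

    Raises ``ValueError`` if the trace is shorter than the window — the
    averaging rule is never silently shrunk.
    """
    n = trace.currents_A.size
    if n < window:
        raise ValueError(
            f"trace has {n} samples; steady-state average needs at least {window}"
        )
    return float(trace.currents_A[-window:].mean())


def biological_current(
    trace: CATrace, window: int = 100, settle_s: float = 60.0
) -> float:
    """Pre-minus-post-inhibitor steady-state current difference.

    The pre segment is everything strictly before the inhibitor addition;
    the post segment starts ``settle_s`` seconds after it (settling margin
    for the step to complete).  Each segment contributes the mean of its
    final ``window`` samples.
    """
    if trace.inhibitor_time_s is None:
        raise ValueError(
            "trace has no inhibitor_time_s; supply the Antimycin addition time "
            "in the trace metadata"
        )
    t = trace.times_s
    pre = trace.currents_A[t < trace.inhibitor_time_s]
    post = trace.currents_A[t >= trace.inhibitor_time_s + settle_s]
    if pre.size < window or post.size < window:
        raise ValueError(
            f"need at least {window} samples both before the inhibitor addition "
            f"and after the {settle_s} s settling margin "
            f"(got {pre.size} pre, {post.size} post)"
        )
    return float(pre[-window:].mean() - post[-window:].mean())


# ---------------------------------------------------------------------------
# Cyclic voltammetry


def edf_from_spar(spar_equiv: float, n_points: int) -> float:
    """Map a [0, 1] smoothing knob to target effective degrees of freedom.

    Linear map ``edf = 2 + 20 * (1 - spar_equiv)`` (0.70 -> 8), clipped to
    the feasible range for ``n_points`` data points.  Larger ``spar_equiv``
    means more smoothing, mirroring the usual smoothing-spline convention.
    """
    if not 0.0 <= spar_equiv <= 1.0:
        raise ValueError("spar_equiv must lie in [0, 1]")
    edf = 2.0 + 20.0 * (1.0 - spar_equiv)
    return float(np.clip(edf, 2.0, max(2.0, n_points - 2)))


_LAM_CACHE: dict[tuple[bytes, float], float] = {}


def _smoother_edf(x: np.ndarray, lam: float) -> float:
    """Trace of the smoothing-spline influence matrix at penalty ``lam``.

    Fitting the identity matrix column-wise yields the full smoother
    matrix in one banded solve; its trace is the effective df.
    """
    S = make_smoothing_spline(x, np.eye(x.size), lam=lam)(x)
    return float(np.trace(S))


def _lam_for_edf(x: np.ndarray, target_edf: float) -> float:
    """Penalty whose smoother has the target effective degrees of freedom.

    Solved by bisection on log10(lambda); cached per (grid, target) since
    scans from one experiment share their potential grid.
    """
    key = (x.tobytes(), round(target_edf, 6))
    if key in _LAM_CACHE:
        return _LAM_CACHE[key]
    lo, hi = -8.0, 14.0  # log10 bounds; edf is decreasing in lambda
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        if _smoother_edf(x, 10.0**mid) > target_edf:
            lo = mid
        else:
            hi = mid
    lam = 10.0 ** (0.5 * (lo + hi))
    _LAM_CACHE[key] = lam
    return lam


@dataclass
class MidpointResult:
    """Outcome of CV midpoint estimation for one scan."""

    strain_id: str
    forward_inflection_mV: float | None
    reverse_inflection_mV: float | None
    midpoint_mV: float | None
    flags: set = field(default_factory=set)


def _branch_inflection(
    E: np.ndarray,
    I: np.ndarray,
    bounds: tuple[float, float],
    spar_equiv: float,
    grid_step: float,
) -> tuple[float, bool]:
    """Inflection potential of one branch; second value flags a boundary hit."""
    lo, hi = bounds
    order = np.argsort(E)
    E, I = E[order], I[order]
    mask = (E >= lo) & (E <= hi)
    E, I = E[mask], I[mask]
    if E.size < 20:
        raise ValueError(
            f"branch has only {E.size} points inside the analysis window "
            f"[{lo}, {hi}] mV; need at least 20"
        )
    if np.any(np.diff(E) <= 0):
        raise ValueError("branch potential grid is not strictly monotone")
    lam = _lam_for_edf(E, edf_from_spar(spar_equiv, E.size))
    spline = make_smoothing_spline(E, I, lam=lam)
    grid = np.arange(E[0], E[-1] + grid_step / 2, grid_step)
    dI = np.abs(np.gradient(spline(grid), grid))
    idx = int(np.argmax(dI))
    # a genuine wave has a prominent derivative peak; a featureless
    # (purely capacitive) branch has a near-uniform derivative whose argmax
    # is a numerical wiggle — treat it like a truncated wave
    dmax, dmed = float(dI[idx]), float(np.median(dI))
    featureless = dmax <= 0 or (dmax - dmed) / dmax < 0.5
    return float(grid[idx]), featureless or idx in (0, grid.size - 1)


def estimate_midpoint(
    scan: CVScan,
    spar_equiv: float = 0.70,
    bounds: tuple[float, float] = CV_ANALYSIS_BOUNDS,
    grid_step: float = 1.0,
) -> MidpointResult:
    """Midpoint (formal) potential of a CV wave.

    Per branch: smoothing-spline fit of current vs potential (smoothing set
    by ``spar_equiv``, see :func:`edf_from_spar`), centered finite-difference
    derivative on a uniform ``grid_step`` grid, and the potential of maximum
    |dI/dE|.  The midpoint is the mean of the two branch inflection
    potentials.  If either branch's derivative peaks at a window boundary
    the wave is truncated (or absent): the result carries an
    ``edge_inflection`` flag and no midpoint.
    """
    fwd, fwd_edge = _branch_inflection(
        scan.forward_potential_mV, scan.forward_current_A, bounds, spar_equiv, grid_step
    )
    rev, rev_edge = _branch_inflection(
        scan.reverse_potential_mV, scan.reverse_current_A, bounds, spar_equiv, grid_step
    )
    flags: set = set()
    midpoint: float | None = 0.5 * (fwd + rev)
    if fwd_edge or rev_edge:
        flags.add("edge_inflection")
        midpoint = None
        warnings.warn(
            f"{scan.strain_id}/{scan.replicate_id}: derivative maximum at the "
            "analysis-window boundary; wave truncated or absent, no midpoint reported",
            stacklevel=2,
        )
    return MidpointResult(
        strain_id=scan.strain_id,
        forward_inflection_mV=fwd,
        reverse_inflection_mV=rev,
        midpoint_mV=midpoint,
        flags=flags,
    )


# ---------------------------------------------------------------------------
# Strain statistics


@dataclass
class StrainComparison:
    """Type-II ANOVA plus Tukey-HSD contrasts against the reference strain."""

    reference: str
    anova: pd.DataFrame
    f_value: float
    p_value: float
    tukey: pd.DataFrame  # columns: group1, group2, meandiff, p_adj, reject
    flagged: list[str]  # strains with adjusted p < alpha and reduced |mean|
    excluded: list[str]  # strains dropped for having < 3 replicates


def compare_strains(
    summaries: list[StrainCurrentSummary],
    reference: str = "WT",
    alpha: float = 0.05,
    min_replicates: int = 3,
) -> StrainComparison:
    """Compare per-strain biological currents against a reference strain.

    Fits ``current ~ strain`` by OLS, runs a type-II ANOVA, then Tukey's
    HSD over all strain pairs.  A strain is flagged as a reduced-uptake
    phenotype when its reference contrast has adjusted p < ``alpha`` and
    its mean current magnitude is below the reference's.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    excluded = [s.strain_id for s in summaries if s.n < min_replicates]
    kept = [s for s in summaries if s.n >= min_replicates]
    if excluded:
        warnings.warn(
            f"excluding strains with < {min_replicates} replicates: {excluded}",
            stacklevel=2,
        )
    names = {s.strain_id for s in kept}
    if reference not in names:
        raise ValueError(f"reference strain {reference!r} missing or under-replicated")
    if len(names) < 2:
        raise ValueError("need at least two strains with enough replicates")

    df = pd.DataFrame(
        [
            {"strain": s.strain_id, "current": c}
            for s in kept
            for c in s.currents_A
        ]
    )
    model = smf.ols("current ~ C(strain)", data=df).fit()
    anova = sm.stats.anova_lm(model, typ=2)
    f_value = float(anova.loc["C(strain)", "F"])
    p_value = float(anova.loc["C(strain)", "PR(>F)"])

    hsd = pairwise_tukeyhsd(df["current"], df["strain"], alpha=alpha)
    from itertools import combinations

    pairs = list(combinations(hsd.groupsunique, 2))
    tukey = pd.DataFrame(
        {
            "group1": [a for a, _ in pairs],
            "group2": [b for _, b in pairs],
            "meandiff": hsd.meandiffs,
            "p_adj": hsd.pvalues,
            "lower": hsd.confint[:, 0],
            "upper": hsd.confint[:, 1],
            "reject": hsd.reject,
        }
    )

    means = {s.strain_id: s.mean_A for s in kept}
    ref_mag = abs(means[reference])
    flagged = []
    for _, row in tukey.iterrows():
        pair = {row["group1"], row["group2"]}
        if reference not in pair:
            continue
        other = (pair - {reference}).pop()
        if float(row["p_adj"]) < alpha and abs(means[other]) < ref_mag:
            flagged.append(other)
    return StrainComparison(
        reference=reference,
        anova=anova,
        f_value=f_value,
        p_value=p_value,
        tukey=tukey,
        flagged=sorted(flagged),
        excluded=excluded,
    )


# ---------------------------------------------------------------------------
# CSV I/O (potentiostat exports)


def write_ca_csv(trace: CATrace, path) -> None:
    pd.DataFrame({"time_s": trace.times_s, "current_A": trace.currents_A}).to_csv(
        path, index=False
    )


def read_ca_csv(path, **metadata) -> CATrace:
    df = pd.read_csv(path)
    return CATrace(
        strain_id=metadata.pop("strain_id", Path(path).stem),
        times_s=df["time_s"].to_numpy(),
        currents_A=df["current_A"].to_numpy(),
        **metadata,
    )


def write_cv_csv(scan: CVScan, path) -> None:
    df = pd.DataFrame(
        {
            "potential_mV_SHE": np.concatenate(
                [scan.forward_potential_mV, scan.reverse_potential_mV]
            ),
            "current_A": np.concatenate(
                [scan.forward_current_A, scan.reverse_current_A]
            ),
            "branch": ["forward"] * scan.forward_potential_mV.size
            + ["reverse"] * scan.reverse_potential_mV.size,
        }
    )
    df.to_csv(path, index=False)


def read_cv_csv(path, **metadata) -> CVScan:
    df = pd.read_csv(path)
    fwd = df[df["branch"] == "forward"]
    rev = df[df["branch"] == "reverse"]
    return CVScan(
        strain_id=metadata.pop("strain_id", Path(path).stem),
        forward_potential_mV=fwd["potential_mV_SHE"].to_numpy(),
        forward_current_A=fwd["current_A"].to_numpy(),
        reverse_potential_mV=rev["potential_mV_SHE"].to_numpy(),
        reverse_current_A=rev["current_A"].to_numpy(),
        **metadata,
    )
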