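"""Synthetic data with known ground truth for every pipeline stage.

The screen's raw data — macroscope photographs of 96-well plates and
potentiostat exports — are not published, so this module generates
stand-ins with planted truth:

* assay-plate images whose wells fade from saturated yellow to clear
  following a single-exponential oxidation kinetic with genotype-dependent
  rate (``y(t) = y0 * exp(-k * max(0, t - lag))``),
* growth/storage-plate images with planted contamination and
  growth-failure events,
* chronoamperometry traces with a steady cathodic plateau, an inhibitor
  step to the abiotic level, and additive Gaussian noise,
* cyclic voltammograms with a logistic redox wave of known formal
  potential on a capacitive baseline.

Everything is driven by an integer seed and is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import barcode
from .colors import DEFAULT_REFERENCES, ReferenceColors, display_color
from .echem import CATrace, CVScan
from .geometry import DEFAULT_GEOMETRY, PlateGeometry, ROWS, N_COLS, well_names

__all__ = [
    "WellGenotype",
    "PlateSpec",
    "OxidationKineticModel",
    "CATraceSpec",
    "CVScanSpec",
    "render_plate_image",
    "render_growth_plate",
    "simulate_ca_trace",
    "simulate_cv_scan",
    "make_screen_layout",
    "catalog_frame",
    "BLANK_MEDIA_RGB",
    "TURBID_RGB",
]

CONTROL_CLASSES = ("blank_no_cell", "quasi_wild_type", "test_mutant")

#: Rendered color of clear growth medium and of a turbid (grown) well.
BLANK_MEDIA_RGB = (247.0, 245.0, 242.0)
TURBID_RGB = (196.0, 188.0, 160.0)


@dataclass(frozen=True)
class WellGenotype:
    """Identity and planted kinetics of one well's occupant."""

    mutant_id: str
    control_class: str = "test_mutant"
    oxidation_rate_k: float = 1.0  # 1/h
    lag_h: float = 0.0
    occupied: bool = True

    def __post_init__(self) -> None:
        if self.control_class not in CONTROL_CLASSES:
            raise ValueError(f"unknown control class {self.control_class!r}")
        if not np.isfinite(self.oxidation_rate_k) or self.oxidation_rate_k < 0:
            raise ValueError("oxidation_rate_k must be finite and >= 0")
        if self.lag_h < 0:
            raise ValueError("lag_h must be >= 0")
        if self.control_class == "blank_no_cell" and self.oxidation_rate_k != 0:
            raise ValueError("blank_no_cell wells cannot oxidize (k must be 0)")


@dataclass(frozen=True)
class PlateSpec:
    """A plate identity plus its 8 x 12 layout and render geometry."""

    plate_id: str
    layout: dict  # well name -> WellGenotype, all 96 wells
    geometry: PlateGeometry = DEFAULT_GEOMETRY
    background_color: tuple[float, float, float] = (214.0, 214.0, 214.0)

    def __post_init__(self) -> None:
        barcode.encode(self.plate_id)  # raises on empty/oversized/non-ASCII id
        expected = set(well_names())
        if set(self.layout) != expected:
            raise ValueError("layout must cover exactly the 96 wells A1..H12")


@dataclass(frozen=True)
class OxidationKineticModel:
    """Forward model of dye fading: exponential decay after a lag.

    ``y0`` is the initial yellow intensity; ``noise_sd`` is additive
    intensity noise applied per well and timepoint before color rendering;
    ``channel_noise_sd`` is per-pixel Gaussian RGB noise (clipped to
    [0, 255]).
    """

    form: str = "exponential_after_lag"
    y0: float = 1.0
    noise_sd: float = 0.02
    channel_noise_sd: float = 2.0
    refs: ReferenceColors = DEFAULT_REFERENCES

    def __post_init__(self) -> None:
        if self.form != "exponential_after_lag":
            raise ValueError(f"unknown kinetic form {self.form!r}")
        if not 0.0 <= self.y0 <= 1.0:
            raise ValueError("y0 must lie in [0, 1]")
        if self.noise_sd < 0 or self.channel_noise_sd < 0:
            raise ValueError("noise levels must be >= 0")

    def y(self, t_h, k_per_h: float, lag_h: float = 0.0):
        """Noiseless yellow intensity at time ``t_h`` hours."""
        t_h = np.asarray(t_h, dtype=float)
        return self.y0 * np.exp(-k_per_h * np.maximum(0.0, t_h - lag_h))


from functools import lru_cache


@lru_cache(maxsize=256)
def _disc_template(radius: float, fy: float, fx: float):
    """Pixel offsets of a disc of ``radius`` at fractional center (fy, fx)."""
    r_int = int(np.ceil(radius)) + 1
    yy, xx = np.mgrid[-r_int : r_int + 1, -r_int : r_int + 1]
    mask = (yy - fy) ** 2 + (xx - fx) ** 2 <= radius**2
    return yy[mask], xx[mask]


def _disc_coords(cx: float, cy: float, radius: float, shape) -> tuple:
    iy, ix = int(np.floor(cy)), int(np.floor(cx))
    oy, ox = _disc_template(round(float(radius), 3), round(cy - iy, 3), round(cx - ix, 3))
    rr, cc = oy + iy, ox + ix
    keep = (rr >= 0) & (rr < shape[0]) & (cc >= 0) & (cc < shape[1])
    return rr[keep], cc[keep]


def _draw_barcode(img: np.ndarray, plate_id: str, geom: PlateGeometry) -> None:
    bits = barcode.encode(plate_id)
    x0, y0, x1, y1 = geom.barcode_box
    xs = np.linspace(x0, x1, bits.size + 1)
    img[int(round(y0)) : int(round(y1)), int(round(x0)) : int(round(x1))] = 255
    for i, bit in enumerate(bits):
        if bit:
            img[
                int(round(y0)) : int(round(y1)),
                int(round(xs[i])) : int(round(xs[i + 1])),
            ] = 0


def _draw_marks(img: np.ndarray, geom: PlateGeometry) -> None:
    for x, y, r in (geom.mark_left, geom.mark_right):
        rr, cc = _disc_coords(x, y, r, img.shape[:2])
        img[rr, cc] = 0


_CANVAS_CACHE: dict[tuple, np.ndarray] = {}


def _base_canvas(spec: PlateSpec) -> np.ndarray:
    # static layer (background + barcode + marks) is identical across
    # timepoints and seeds for one plate, so build it once
    key = (spec.plate_id, spec.geometry, spec.background_color)
    canvas = _CANVAS_CACHE.get(key)
    if canvas is None:
        w, h = spec.geometry.image_size
        canvas = np.empty((h, w, 3), dtype=np.uint8)
        canvas[:] = np.asarray(spec.background_color, dtype=np.uint8)
        _draw_barcode(canvas, spec.plate_id, spec.geometry)
        _draw_marks(canvas, spec.geometry)
        if len(_CANVAS_CACHE) > 64:
            _CANVAS_CACHE.clear()
        _CANVAS_CACHE[key] = canvas
    return canvas.copy()


def _paint_well(
    img: np.ndarray,
    center: tuple[float, float],
    radius: float,
    color: np.ndarray,
    channel_noise_sd: float,
    rng: np.random.Generator,
) -> None:
    rr, cc = _disc_coords(center[0], center[1], radius, img.shape[:2])
    pix = np.broadcast_to(color, (rr.size, 3)).astype(float)
    if channel_noise_sd > 0:
        pix = pix + rng.normal(0.0, channel_noise_sd, size=(rr.size, 3))
    img[rr, cc] = np.clip(np.round(pix), 0, 255).astype(np.uint8)


def render_plate_image(
    spec: PlateSpec,
    kinetics: OxidationKineticModel,
    t_h: float,
    seed: int,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Render one assay-plate photograph at ``t_h`` hours into the assay.

    Returns the 8-bit RGB image and a ground-truth table with the planted
    genotype and the noiseless intensity ``y_true`` for every well (the
    rendered well color carries the intensity- and channel-level noise of
    ``kinetics`` on top of ``y_true``).
    """
    if t_h < 0:
        raise ValueError("time must be >= 0")
    rng = np.random.default_rng(seed)
    img = _base_canvas(spec)
    geom = spec.geometry
    rows = []
    for name, (cx, cy) in geom.well_centers().items():
        g: WellGenotype = spec.layout[name]
        y_true = float(kinetics.y(t_h, g.oxidation_rate_k, g.lag_h))
        y_noisy = y_true + (rng.normal(0.0, kinetics.noise_sd) if kinetics.noise_sd else 0.0)
        color = display_color(y_noisy, kinetics.refs)
        _paint_well(img, (cx, cy), geom.well_radius, color, kinetics.channel_noise_sd, rng)
        rows.append(
            {
                "plate_id": spec.plate_id,
                "well": name,
                "mutant_id": g.mutant_id,
                "control_class": g.control_class,
                "k_per_h": g.oxidation_rate_k,
                "lag_h": g.lag_h,
                "timestamp_h": t_h,
                "y_true": y_true,
            }
        )
    return img, pd.DataFrame(rows)


def render_growth_plate(
    spec: PlateSpec,
    contamination: set[str] = frozenset(),
    failures: set[str] = frozenset(),
    seed: int = 0,
    channel_noise_sd: float = 2.0,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Render a storage-plate photograph with planted QC events.

    ``contamination`` wells must be catalogued empty (they render turbid
    anyway); ``failures`` must be catalogued occupied (they render as blank
    medium).  The ground-truth table lists intended occupancy and realized
    growth per well.
    """
    contamination, failures = set(contamination), set(failures)
    if contamination & failures:
        raise ValueError("contamination and failure sets overlap")
    for w in contamination:
        if spec.layout[w].occupied:
            raise ValueError(f"contamination well {w} is catalogued occupied")
    for w in failures:
        if not spec.layout[w].occupied:
            raise ValueError(f"failure well {w} is catalogued empty")
    rng = np.random.default_rng(seed)
    img = _base_canvas(spec)
    geom = spec.geometry
    rows = []
    for name, (cx, cy) in geom.well_centers().items():
        occupied = spec.layout[name].occupied
        grown = (occupied and name not in failures) or (name in contamination)
        color = np.asarray(TURBID_RGB if grown else BLANK_MEDIA_RGB)
        _paint_well(img, (cx, cy), geom.well_radius, color, channel_noise_sd, rng)
        rows.append(
            {
                "plate_id": spec.plate_id,
                "well": name,
                "occupied": occupied,
                "grown": grown,
            }
        )
    return img, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Potentiostat forward models


@dataclass(frozen=True)
class CATraceSpec:
    """Forward model of a cathodic chronoamperometry experiment.

    The noiseless trace sits at ``baseline_current`` until the inhibitor
    addition, then relaxes to ``abiotic_current`` over a cubic-smoothstep
    transition confined to ``[inhibitor_time, inhibitor_time +
    3 * step_sharpness]`` seconds.  Currents in amperes, negative =
    cathodic.
    """

    poised_potential_mV: float = -378.0
    baseline_current: float = -10e-6
    abiotic_current: float = -2e-6
    inhibitor_time: float = 600.0
    step_sharpness: float = 2.0
    noise_sd: float = 5e-8
    sample_interval: float = 1.0
    duration: float = 800.0
    strain_id: str = "synthetic"
    replicate_id: str = "r1"

    def __post_init__(self) -> None:
        if self.sample_interval <= 0:
            raise ValueError("sample_interval must be positive")
        if self.duration <= self.inhibitor_time:
            # permitted: a trace with no step inside the record
            pass


def simulate_ca_trace(spec: CATraceSpec, seed: int) -> CATrace:
    """Simulate a CA trace; ``ceil(duration / sample_interval)`` samples."""
    rng = np.random.default_rng(seed)
    n = int(np.ceil(spec.duration / spec.sample_interval))
    t = np.arange(n) * spec.sample_interval
    span = 3.0 * spec.step_sharpness
    if span > 0:
        u = np.clip((t - spec.inhibitor_time) / span, 0.0, 1.0)
        u = u * u * (3.0 - 2.0 * u)
    else:
        u = (t >= spec.inhibitor_time).astype(float)
    current = spec.baseline_current + (spec.abiotic_current - spec.baseline_current) * u
    # plateaus are exact, not merely within float error of the blend
    current[u >= 1.0] = spec.abiotic_current
    if spec.noise_sd > 0:
        current = current + rng.normal(0.0, spec.noise_sd, size=n)
    return CATrace(
        strain_id=spec.strain_id,
        times_s=t,
        currents_A=current,
        mode="cathodic" if spec.poised_potential_mV < 0 else "anodic",
        poised_potential_mV=spec.poised_potential_mV,
        inhibitor_time_s=spec.inhibitor_time if spec.inhibitor_time < spec.duration else None,
        replicate_id=spec.replicate_id,
    )


@dataclass(frozen=True)
class CVScanSpec:
    """Forward model of a cyclic voltammogram with one sigmoidal wave.

    The noiseless current of each branch is ``capacitive_offset +
    wave_amplitude * sigmoid((E - inflection) / wave_width_mV)``; with
    hysteresis ``h`` the forward (descending) branch inflects at
    ``formal_potential - h/2`` and the reverse at ``formal_potential +
    h/2``, so their mean recovers the formal potential exactly.  Defaults
    mimic an AQDS-like two-electron couple near -184 mV vs SHE.
    """

    formal_potential_mV: float = -184.0
    wave_amplitude: float = 5e-6
    wave_width_mV: float = 13.0
    hysteresis_mV: float = 20.0
    capacitive_offset: float = -1e-6
    noise_sd: float = 1e-7
    scan_lo_mV: float = -322.0
    scan_hi_mV: float = 222.0
    step_mV: float = 2.0
    strain_id: str = "synthetic"
    replicate_id: str = "r1"

    def __post_init__(self) -> None:
        if self.wave_width_mV <= 0:
            raise ValueError("wave_width_mV must be positive")
        if self.step_mV <= 0:
            raise ValueError("step_mV must be positive")
        if not self.scan_lo_mV < self.formal_potential_mV < self.scan_hi_mV:
            raise ValueError("formal potential must lie inside the scan bounds")


def simulate_cv_scan(spec: CVScanSpec, seed: int) -> CVScan:
    """Simulate paired forward (high->low) and reverse (low->high) branches."""
    rng = np.random.default_rng(seed)
    E = np.arange(spec.scan_lo_mV, spec.scan_hi_mV + spec.step_mV / 2, spec.step_mV)

    def branch(inflection: float) -> np.ndarray:
        wave = spec.wave_amplitude / (
            1.0 + np.exp(-(E - inflection) / spec.wave_width_mV)
        )
        out = spec.capacitive_offset + wave
        if spec.noise_sd > 0:
            out = out + rng.normal(0.0, spec.noise_sd, size=E.size)
        return out

    fwd = branch(spec.formal_potential_mV - spec.hysteresis_mV / 2.0)
    rev = branch(spec.formal_potential_mV + spec.hysteresis_mV / 2.0)
    return CVScan(
        strain_id=spec.strain_id,
        forward_potential_mV=E[::-1].copy(),
        forward_current_A=fwd[::-1].copy(),
        reverse_potential_mV=E,
        reverse_current_A=rev,
        replicate_id=spec.replicate_id,
    )


# ---------------------------------------------------------------------------
# Screen layout generation


def make_screen_layout(
    n_plates: int = 4,
    n_slowed: int = 10,
    n_eliminated: int = 6,
    seed: int = 0,
    k_normal_mean: float = 1.0,
    k_normal_sd: float = 0.1,
    k_slowed: float = 0.2,
    blanks_per_plate: int = 2,
    qwt_per_plate: int = 3,
    geometry: PlateGeometry = DEFAULT_GEOMETRY,
    plate_prefix: str = "P",
) -> tuple[list[PlateSpec], pd.DataFrame]:
    """Build an arrayed-library screen layout with planted hits.

    Each plate carries ``blanks_per_plate`` no-cell blanks and
    ``qwt_per_plate`` quasi-wild-type controls in its first wells; the
    remaining wells hold unique test mutants.  ``n_slowed`` mutants get
    rate ``k_slowed`` and ``n_eliminated`` get rate 0; all others draw
    their rate from a truncated normal around ``k_normal_mean``.  Returns
    the plate specs and a truth table with the planted status per mutant.
    """
    rng = np.random.default_rng(seed)
    names = well_names()
    n_test_total = n_plates * (96 - blanks_per_plate - qwt_per_plate)
    if n_slowed + n_eliminated > n_test_total:
        raise ValueError("more planted hits than test wells")
    statuses = ["slowed"] * n_slowed + ["eliminated"] * n_eliminated
    statuses += ["normal"] * (n_test_total - len(statuses))
    statuses = list(rng.permutation(statuses))

    specs, rows = [], []
    mutant_counter = 0
    for p in range(n_plates):
        plate_id = f"{plate_prefix}{p + 1:03d}"
        layout: dict[str, WellGenotype] = {}
        for i, well in enumerate(names):
            if i < blanks_per_plate:
                g = WellGenotype(
                    mutant_id=f"blank_{plate_id}_{well}",
                    control_class="blank_no_cell",
                    oxidation_rate_k=0.0,
                )
                status = "blank"
            elif i < blanks_per_plate + qwt_per_plate:
                k = float(np.clip(rng.normal(k_normal_mean, k_normal_sd), 0.05, None))
                g = WellGenotype(
                    mutant_id=f"qwt_{plate_id}_{well}",
                    control_class="quasi_wild_type",
                    oxidation_rate_k=k,
                )
                status = "control"
            else:
                status = statuses[mutant_counter]
                mutant_counter += 1
                if status == "eliminated":
                    k = 0.0
                elif status == "slowed":
                    k = k_slowed
                else:
                    k = float(
                        np.clip(rng.normal(k_normal_mean, k_normal_sd), 0.05, None)
                    )
                g = WellGenotype(mutant_id=f"mut{mutant_counter:04d}", oxidation_rate_k=k)
            layout[well] = g
            rows.append(
                {
                    "plate_id": plate_id,
                    "well": well,
                    "mutant_id": g.mutant_id,
                    "control_class": g.control_class,
                    "k_per_h": g.oxidation_rate_k,
                    "lag_h": g.lag_h,
                    "occupied": g.occupied,
                    "planted_status": status,
                }
            )
        specs.append(PlateSpec(plate_id=plate_id, layout=layout, geometry=geometry))
    return specs, pd.DataFrame(rows)


def catalog_frame(specs: list[PlateSpec]) -> pd.DataFrame:
    """Collection-catalog table for a list of plate specs (CSV schema)."""
    rows = []
    for spec in specs:
        for well in well_names():
            g = spec.layout[well]
            rows.append(
                {
                    "plate_id": spec.plate_id,
                    "well": well,
                    "mutant_id": g.mutant_id,
                    "control_class": g.control_class,
                    "k_per_h": g.oxidation_rate_k,
                    "lag_h": g.lag_h,
                    "occupied": g.occupied,
                }
            )
    return pd.DataFrame(rows)
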