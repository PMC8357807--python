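"""End-to-end orchestration: synthetic screen -> hits -> validation.

``run_pipeline`` drives the whole chain from a single config: generate a
two-acceptor synthetic screen with planted truth, render and re-ingest the
plate photographs, QC the growth plates, score and call hits per acceptor,
partition and triage them, then simulate and analyze the validation
electrochemistry (CA biological currents, CV midpoints, strain ANOVA /
Tukey) for the unknown-function shortlist.  Every stage is seeded from the
one config seed, so identical configs give byte-identical reports.

``mixing_check`` is the assay-recipe arithmetic: final well concentration
of each component is ``stock * volume / total`` (both screen recipes put
AHDS_red and the terminal acceptor at 5 mM in a 100 uL well).
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import echem, plates, redox, synth

__all__ = [
    "MixComponent",
    "mixing_check",
    "TABLE1_NITRATE",
    "TABLE1_FUMARATE",
    "PipelineConfig",
    "ScreenReport",
    "run_screen",
    "run_pipeline",
]


# ---------------------------------------------------------------------------
# Assay mixing arithmetic


@dataclass(frozen=True)
class MixComponent:
    """One pipetted component of a well: name, volume and stock strength."""

    name: str
    volume_uL: float
    stock_mM: float | None = None  # None for media/culture with no tracked solute


def mixing_check(
    components: list[MixComponent], total_uL: float
) -> dict[str, float | None]:
    """Final per-component concentration of a mixed assay well.

    Volumes must sum exactly to ``total_uL`` (a violation is an error, not
    a warning).  Components without a stock concentration map to ``None``.
    """
    vol = sum(c.volume_uL for c in components)
    if any(c.volume_uL < 0 for c in components) or total_uL <= 0:
        raise ValueError("volumes must be >= 0 and total positive")
    if abs(vol - total_uL) > 1e-9:
        raise ValueError(
            f"component volumes sum to {vol} uL, not the stated total {total_uL} uL"
        )
    return {
        c.name: (None if c.stock_mM is None else c.stock_mM * c.volume_uL / total_uL)
        for c in components
    }


#: Published per-well mixing recipes for the two screen assays (100 uL).
TABLE1_NITRATE = [
    MixComponent("Shewanella Basal Media", 50.0),
    MixComponent("Saturated Culture", 10.0),
    MixComponent("25 mM KNO3", 20.0, stock_mM=25.0),
    MixComponent("25 mM AHDS_red", 20.0, stock_mM=25.0),
]
TABLE1_FUMARATE = [
    MixComponent("Shewanella Basal Media", 59.0),
    MixComponent("Saturated Culture", 1.0),
    MixComponent("25 mM Na Fumarate", 20.0, stock_mM=25.0),
    MixComponent("25 mM AHDS_red", 20.0, stock_mM=25.0),
]


# ---------------------------------------------------------------------------
# Config


@dataclass
class PipelineConfig:
    """All knobs of the synthetic end-to-end run, with screen defaults."""

    seed: int = 0
    n_plates: int = 4
    # planted hit structure across the two acceptors
    n_fumarate_only: int = 5
    n_nitrate_only: int = 3
    n_both: int = 7
    n_eliminated_among_both: int = 3
    n_growth_failures: int = 5
    # kinetics / imaging
    imaging_hours: tuple = (0.0, 0.5, 1.0, 1.5, 2.0, 3.0, 4.0, 6.0, 8.0, 12.0, 24.0, 40.0)
    noise_sd: float = 0.02
    channel_noise_sd: float = 2.0
    k_normal_mean: float = 1.0
    k_normal_sd: float = 0.1
    k_slowed: float = 0.2
    # thresholds
    k_sd: float = 3.0
    min_controls: int = 8
    qc_sigma: float = 3.0
    qc_threshold_floor: float = 20.0
    spar_equiv: float = 0.70
    ca_window: int = 100
    ca_settle_s: float = 60.0
    cv_bounds: tuple = echem.CV_ANALYSIS_BOUNDS
    # electrochemical validation
    n_echem_replicates: int = 4
    echem_strains: tuple = (
        ("WT", -8e-6),
        ("mutA", -1e-6),
        ("mutB", -1.5e-6),
        ("mutC", -7.5e-6),
        ("mutD", -8.5e-6),
        ("mutE", -2e-6),
    )
    echem_noise_sd: float = 5e-8
    echem_replicate_sd: float = 0.5e-6  # between-replicate (biofilm) variability, A
    cv_formal_mV: float = -184.0

    def validate(self) -> None:
        if self.n_plates < 0 or self.k_sd <= 0 or not 0 <= self.spar_equiv <= 1:
            raise ValueError("config threshold out of its documented range")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        cfg = cls(**{k: (tuple(v) if isinstance(v, list) else v) for k, v in d.items()})
        cfg.echem_strains = tuple(tuple(s) for s in cfg.echem_strains)
        return cfg


# ---------------------------------------------------------------------------
# Screen runner (synth -> plates -> redox for one acceptor)


def run_screen(
    specs: list[synth.PlateSpec],
    kinetics: synth.OxidationKineticModel,
    imaging_hours,
    seed: int,
    acceptor: str = "fumarate",
    qc_failures: set | None = None,
    k_sd: float = 3.0,
    min_controls: int = 8,
):
    """Render, re-ingest and score one acceptor's plate run.

    Returns (calls, traces, sample table, image records).  This goes
    through the full image path — rendering photographs, decoding their
    barcodes, registering the grid and sampling well colors — so planted
    kinetics are recovered only through the same machinery real
    photographs would use.
    """
    rng = np.random.default_rng(seed)
    catalog = plates.CollectionCatalog(synth.catalog_frame(specs))
    images = []
    for spec in specs:
        for t in imaging_hours:
            img, _ = synth.render_plate_image(
                spec, kinetics, t, seed=int(rng.integers(2**31))
            )
            images.append((img, f"{spec.plate_id}_t{t}", float(t)))
    samples, records = plates.ingest_images(images, geometry=specs[0].geometry)
    traces = redox.build_traces(samples, catalog, acceptor=acceptor)
    calls = redox.call_hits(
        traces.values(), qc_failures=qc_failures, k_sd=k_sd, min_controls=min_controls
    )
    return calls, traces, samples, records


# ---------------------------------------------------------------------------
# Full pipeline


@dataclass
class ScreenReport:
    """Headline bookkeeping of one end-to-end run."""

    n_mutants_screened: int
    partition: redox.HitPartition | None
    category_counts: pd.DataFrame
    shortlist: list
    excluded_wells: pd.DataFrame
    accounting: dict  # wells imaged = scored + unreadable + growth-excluded
    strain_summaries: list
    comparison: echem.StrainComparison | None
    midpoints: pd.DataFrame
    calls: dict  # acceptor -> list[HitCall]

    def summary_lines(self) -> list[str]:
        lines = [f"mutants screened: {self.n_mutants_screened}"]
        if self.partition is not None:
            f, n, b = self.partition.counts
            lines += [
                f"hits fumarate-only: {f}",
                f"hits nitrate-only: {n}",
                f"hits both assays: {b}",
                f"total distinct hits: {self.partition.total}",
            ]
        for _, row in self.category_counts.iterrows():
            lines.append(f"category {row['category']}: {row['n_hits']}")
        lines.append(f"validation shortlist: {len(self.shortlist)}")
        if self.comparison is not None:
            lines.append(
                f"ANOVA F = {self.comparison.f_value:.3g}, "
                f"p = {self.comparison.p_value:.3g}"
            )
            lines.append(f"reduced-uptake strains: {', '.join(self.comparison.flagged) or 'none'}")
        for k, v in self.accounting.items():
            lines.append(f"{k}: {v}")
        return lines


def _planted_layouts(cfg: PipelineConfig, rng: np.random.Generator):
    """Two-acceptor layouts sharing mutants, with acceptor-specific planting."""
    n_hits = cfg.n_fumarate_only + cfg.n_nitrate_only + cfg.n_both
    specs, truth = synth.make_screen_layout(
        n_plates=cfg.n_plates,
        n_slowed=0,
        n_eliminated=0,
        seed=int(rng.integers(2**31)),
        k_normal_mean=cfg.k_normal_mean,
        k_normal_sd=cfg.k_normal_sd,
    )
    mutants = truth.loc[truth["control_class"] == "test_mutant", "mutant_id"].tolist()
    if n_hits > len(mutants):
        raise ValueError("more planted hits than test mutants")
    chosen = list(rng.choice(mutants, size=n_hits, replace=False))
    fum_only = set(chosen[: cfg.n_fumarate_only])
    nit_only = set(chosen[cfg.n_fumarate_only : cfg.n_fumarate_only + cfg.n_nitrate_only])
    both = set(chosen[cfg.n_fumarate_only + cfg.n_nitrate_only :])
    eliminated = set(list(both)[: cfg.n_eliminated_among_both])

    def acceptor_specs(hit_set: set) -> list[synth.PlateSpec]:
        out = []
        for spec in specs:
            layout = {}
            for well, g in spec.layout.items():
                if g.mutant_id in hit_set:
                    k = 0.0 if g.mutant_id in eliminated else cfg.k_slowed
                    layout[well] = dataclasses.replace(g, oxidation_rate_k=k)
                else:
                    layout[well] = g
            out.append(dataclasses.replace(spec, layout=layout))
        return out

    planted = {
        "fumarate_only": fum_only,
        "nitrate_only": nit_only,
        "both": both,
    }
    return (
        acceptor_specs(fum_only | both),
        acceptor_specs(nit_only | both),
        specs,
        planted,
    )


def run_pipeline(cfg: PipelineConfig, out_dir=None) -> ScreenReport:
    """Run the full synthetic screen -> partition -> validation chain."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    empty = pd.DataFrame()
    if cfg.n_plates == 0:
        warnings.warn("config requests zero plates; emitting an empty report")
        report = ScreenReport(
            0, None, pd.DataFrame(columns=["category", "n_hits"]), [], empty,
            {"wells_imaged": 0, "wells_scored": 0, "wells_unreadable": 0,
             "wells_growth_excluded": 0},
            [], None, empty, {},
        )
        if out_dir is not None:
            _write_report(report, cfg, out_dir)
        return report

    fum_specs, nit_specs, base_specs, planted = _planted_layouts(cfg, rng)
    kinetics = synth.OxidationKineticModel(
        noise_sd=cfg.noise_sd, channel_noise_sd=cfg.channel_noise_sd
    )

    # growth-plate QC with planted failures on the first plate
    catalog = plates.CollectionCatalog(synth.catalog_frame(base_specs))
    qc_failures: set = set()
    qc_events = []
    fail_wells = set()
    if cfg.n_growth_failures > 0:
        candidates = [
            w
            for w in synth.well_names()
            if base_specs[0].layout[w].control_class == "test_mutant"
        ]
        fail_wells = set(
            rng.choice(candidates, size=cfg.n_growth_failures, replace=False)
        )
    for spec in base_specs:
        fails = fail_wells if spec is base_specs[0] else set()
        img, _ = synth.render_growth_plate(
            spec, failures=fails, seed=int(rng.integers(2**31))
        )
        rec = plates.decode_plate(img, geometry=spec.geometry)
        qc = plates.qc_growth_plate(
            rec, img, catalog, geometry=spec.geometry,
            sigma_factor=cfg.qc_sigma, threshold_floor=cfg.qc_threshold_floor,
        )
        qc_failures |= {(qc.plate_id, w) for w in qc.growth_failures}
        qc_events += [
            {"plate_id": qc.plate_id, "well": w, "event": e} for w, e in qc.events
        ]

    calls, records_all = {}, []
    for acceptor, specs in (("fumarate", fum_specs), ("nitrate", nit_specs)):
        acc_calls, _, samples, records = run_screen(
            specs, kinetics, cfg.imaging_hours, seed=int(rng.integers(2**31)),
            acceptor=acceptor, qc_failures=qc_failures,
            k_sd=cfg.k_sd, min_controls=cfg.min_controls,
        )
        calls[acceptor] = acc_calls
        records_all += records

    partition = redox.partition_hits(calls["fumarate"], calls["nitrate"])

    # annotations: planted single-acceptor hits get pathway categories,
    # planted both-assay hits are "unknown" (the validation shortlist)
    annotations = {m: "fumarate reduction" for m in planted["fumarate_only"]}
    annotations |= {m: "nitrate reduction" for m in planted["nitrate_only"]}
    category_counts, shortlist = redox.triage_categories(partition, annotations)

    # conservation ledger
    n_images = len(records_all)
    n_unreadable = sum(
        1 for r in records_all if "barcode_unreadable" in r.quality_flags
    )
    wells_imaged = 96 * n_images
    wells_unreadable = 96 * n_unreadable
    n_tp = len(cfg.imaging_hours)
    wells_growth_excluded = sum(
        n_tp for acc_calls in calls.values()
        for c in acc_calls if c.status == "excluded_growth_failure"
    )
    accounting = {
        "wells_imaged": wells_imaged,
        "wells_scored": wells_imaged - wells_unreadable - wells_growth_excluded,
        "wells_unreadable": wells_unreadable,
        "wells_growth_excluded": wells_growth_excluded,
    }

    # electrochemical validation of a strain panel
    summaries, mid_rows = [], []
    for strain, baseline in cfg.echem_strains:
        currents = []
        for rep in range(cfg.n_echem_replicates):
            # biofilms differ between replicate reactors: jitter the plateau
            rep_baseline = baseline + float(rng.normal(0.0, cfg.echem_replicate_sd))
            ca_spec = synth.CATraceSpec(
                baseline_current=rep_baseline,
                noise_sd=cfg.echem_noise_sd,
                strain_id=strain,
                replicate_id=f"r{rep + 1}",
            )
            trace = synth.simulate_ca_trace(ca_spec, seed=int(rng.integers(2**31)))
            currents.append(
                echem.biological_current(
                    trace, window=cfg.ca_window, settle_s=cfg.ca_settle_s
                )
            )
            cv_spec = synth.CVScanSpec(
                formal_potential_mV=cfg.cv_formal_mV,
                strain_id=strain,
                replicate_id=f"r{rep + 1}",
            )
            scan = synth.simulate_cv_scan(cv_spec, seed=int(rng.integers(2**31)))
            mp = echem.estimate_midpoint(
                scan, spar_equiv=cfg.spar_equiv, bounds=tuple(cfg.cv_bounds)
            )
            mid_rows.append(
                {
                    "strain_id": strain,
                    "replicate_id": f"r{rep + 1}",
                    "forward_inflection_mV": mp.forward_inflection_mV,
                    "reverse_inflection_mV": mp.reverse_inflection_mV,
                    "midpoint_mV": mp.midpoint_mV,
                    "flags": ";".join(sorted(mp.flags)),
                }
            )
        summaries.append(echem.StrainCurrentSummary(strain_id=strain, currents_A=currents))
    comparison = echem.compare_strains(summaries, reference=cfg.echem_strains[0][0])

    report = ScreenReport(
        n_mutants_screened=sum(
            1 for c in calls["fumarate"] if c.control_class == "test_mutant"
        ),
        partition=partition,
        category_counts=category_counts,
        shortlist=shortlist,
        excluded_wells=pd.DataFrame(qc_events),
        accounting=accounting,
        strain_summaries=summaries,
        comparison=comparison,
        midpoints=pd.DataFrame(mid_rows),
        calls=calls,
    )
    if out_dir is not None:
        _write_report(report, cfg, out_dir)
    return report


def _write_report(report: ScreenReport, cfg: PipelineConfig, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    header = f"# macroscreen report (seed={cfg.seed})\n"
    (out / "report.txt").write_text(header + "\n".join(report.summary_lines()) + "\n")
    for acceptor, acc_calls in report.calls.items():
        pd.DataFrame(
            [
                {
                    "mutant_id": c.mutant_id,
                    "acceptor": c.acceptor,
                    "status": c.status,
                    "t50_h": c.t50_h,
                    "rate_per_h": c.rate_per_h,
                    "control_class": c.control_class,
                }
                for c in acc_calls
            ]
        ).sort_values("mutant_id").to_csv(out / f"calls_{acceptor}.csv", index=False)
    if report.partition is not None:
        pd.DataFrame(
            [
                {"subset": "fumarate_only", "mutant_id": m}
                for m in sorted(report.partition.fumarate_only)
            ]
            + [
                {"subset": "nitrate_only", "mutant_id": m}
                for m in sorted(report.partition.nitrate_only)
            ]
            + [{"subset": "both", "mutant_id": m} for m in sorted(report.partition.both)]
        ).to_csv(out / "partition.csv", index=False)
    report.category_counts.to_csv(out / "categories.csv", index=False)
    report.excluded_wells.to_csv(out / "qc_events.csv", index=False)
    report.midpoints.to_csv(out / "midpoints.csv", index=False)
    if report.strain_summaries:
        pd.DataFrame(
            [
                {
                    "strain_id": s.strain_id,
                    "n": s.n,
                    "mean_A": s.mean_A,
                    "sd_A": s.sd_A,
                }
                for s in report.strain_summaries
            ]
        ).to_csv(out / "strain_currents.csv", index=False)
    if report.comparison is not None:
        report.comparison.tukey.to_csv(out / "tukey.csv", index=False)
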