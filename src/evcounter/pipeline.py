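"""End-to-end pipeline: simulate -> render -> detect -> gate -> summarize.

Wells are processed frame by frame so that arbitrarily large wells never
hold more than one rendered frame stack in memory.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import OpticsConfig, SampleConfig
from .detect import SegmentationConfig, detect_frame
from .gating import classify, load_gate_library
from .quantify import WellResult, summarize_cohort, summarize_donors
from .simulate import render_frame, sample_well, sampled_volume, _well_rng


@dataclass
class WellRun:
    result: WellResult
    truth_counts: dict[str, int]
    features: pd.DataFrame | None = None
    assignments: pd.DataFrame | None = None


@dataclass
class CohortRun:
    wells: list[WellResult] = field(default_factory=list)
    truth_counts: list[dict] = field(default_factory=list)
    donor_summary: pd.DataFrame | None = None
    cohort_summary: pd.DataFrame | None = None


def default_library_for_mode(mode: str) -> str:
    return "A_epcam" if mode == "epcam_enriched" else "B_whole_blood"


def count_well(config: SampleConfig, well_index: int,
               optics: OpticsConfig | None = None,
               seg_config: SegmentationConfig | None = None,
               gatesets=None, donor_id: str = "donor0",
               well_id: str | None = None,
               keep_tables: bool = False) -> WellRun:
    """Simulate, render, detect and gate one well; return its counts."""
    if optics is None:
        optics = OpticsConfig.for_mode(config.mode)
    if seg_config is None:
        seg_config = SegmentationConfig()
    if gatesets is None:
        gatesets = load_gate_library(default_library_for_mode(config.mode))
    if well_id is None:
        well_id = f"{donor_id}-w{well_index}"
    particles = sample_well(config, well_index, optics, well_id=well_id)
    noise_rng = _well_rng(config, well_index, stream=1)
    by_frame: dict[int, list] = {}
    for p in particles:
        by_frame.setdefault(p.frame_id, []).append(p)
    tables = []
    for f in range(config.frames_per_well):
        stack = render_frame(by_frame.get(f, []), optics, noise_rng)
        tbl = detect_frame(stack, optics.channel_names, optics.pixel_pitch,
                           seg_config, well_id=well_id, frame_id=f)
        if len(tbl):
            tables.append(tbl)
    table = (pd.concat(tables, ignore_index=True) if tables
             else pd.DataFrame(columns=["object_id"]))
    if len(table):
        assignments, counts = classify(table, gatesets, optics.channel_roles)
    else:
        assignments, counts = classify(pd.DataFrame(columns=["object_id"]),
                                       gatesets, optics.channel_roles)
    result = WellResult(well_id=well_id, donor_id=donor_id, mode=config.mode,
                        counts=counts, sampled_volume_ul=sampled_volume(config))
    truth = dict(Counter(p.class_name for p in particles))
    return WellRun(result, truth,
                   table if keep_tables else None,
                   assignments if keep_tables else None)


def donor_seed(base_seed: int, donor_index: int) -> int:
    """Stable per-donor sub-seed below 2**31."""
    ss = np.random.SeedSequence((int(base_seed), int(donor_index)))
    return int(ss.generate_state(1)[0] % (2 ** 31))


def run_cohort(config: SampleConfig, n_donors: int,
               wells_per_donor: int | None = None,
               optics: OpticsConfig | None = None,
               seg_config: SegmentationConfig | None = None,
               gatesets=None, base_seed: int | None = None,
               group: str = "cohort") -> CohortRun:
    """Run the full pipeline for a cohort of donors.

    Each donor gets an independent seeded particle stream; wells within a
    donor are technical replicates of the same blood.
    """
    if wells_per_donor is None:
        wells_per_donor = config.replicate_wells
    if base_seed is None:
        base_seed = config.seed
    if gatesets is None:
        gatesets = load_gate_library(default_library_for_mode(config.mode))
    run = CohortRun()
    for d in range(n_donors):
        dcfg = config.with_seed(donor_seed(base_seed, d))
        donor_id = f"donor{d}"
        for w in range(wells_per_donor):
            wr = count_well(dcfg, w, optics=optics, seg_config=seg_config,
                            gatesets=gatesets, donor_id=donor_id)
            run.wells.append(wr.result)
            tc = dict(wr.truth_counts)
            tc.update({"donor_id": donor_id, "well_id": wr.result.well_id})
            run.truth_counts.append(tc)
    run.donor_summary = summarize_donors(run.wells)
    run.cohort_summary = summarize_cohort(run.donor_summary, group=group)
    return run


def pooled_ratio(wells) -> float:
    """Pooled leukocytes-per-ldEV ratio over a list of WellResult."""
    leuk = sum(w.counts.get("leukocyte", 0) for w in wells)
    ldev = sum(w.counts.get("ldEV", 0) for w in wells)
    return leuk / ldev if ldev > 0 else float("nan")
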