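"""Shared fixtures: random feature records, brute-force gating oracle and
a small ideally-imaged synthetic well reused across tests."""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import evcounter as ev
from evcounter.gating import MORPHOLOGY_GATE_FEATURES
from evcounter.simulate import touching_clusters

settings.register_profile(
    "suite", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("suite")

WB_CHANNELS = ("Hoechst", "CD45", "CD61", "CD235a", "extra")


@pytest.fixture(scope="session")
def wb_roles():
    return ev.OpticsConfig().channel_roles


@pytest.fixture(scope="session")
def gates_b():
    return ev.load_gate_library("B_whole_blood")


@pytest.fixture(scope="session")
def gates_a():
    return ev.load_gate_library("A_epcam")


def random_feature_records(n: int, rng: np.random.Generator,
                           channels=WB_CHANNELS) -> pd.DataFrame:
    """Random records spanning all gate thresholds (both sides)."""
    data = {
        "object_id": [f"r{i}" for i in range(n)],
        "size_um2": rng.uniform(0.0, 500.0, n),
        "perimeter_px": rng.uniform(0.0, 30.0, n),
        "eccentricity": rng.uniform(0.0, 1.0, n),
    }
    for ch in channels:
        data[f"mean_intensity_{ch}"] = rng.uniform(0.0, 60.0, n)
        data[f"max_intensity_{ch}"] = rng.uniform(0.0, 100.0, n)
        data[f"std_intensity_{ch}"] = rng.uniform(0.0, 10.0, n)
    return pd.DataFrame(data)


def brute_force_classify(table: pd.DataFrame, gatesets, roles):
    """Independent per-record, per-criterion interpretation of gate sets."""
    finals = []
    for _, rec in table.iterrows():
        matches = []
        for g in gatesets:
            ok = True
            for c in g.criteria:
                if c.feature in MORPHOLOGY_GATE_FEATURES:
                    col = c.feature
                else:
                    col = f"{c.feature}_{roles[c.channel_role]}"
                v = rec[col]
                if c.cmp == ">":
                    if not v > c.threshold:
                        ok = False
                        break
                else:
                    if not v <= c.threshold:
                        ok = False
                        break
            if ok:
                matches.append(g.class_name)
        if len(matches) == 1:
            finals.append(matches[0])
        elif not matches:
            finals.append("unclassified")
        else:
            finals.append("ambiguous")
    return finals


def sparse_whole_blood_config(seed=11, frames=12):
    """Low-density whole-blood config whose wells rarely contain touching
    particles; everything rendered in focus with high contrast."""
    base = ev.whole_blood_sample(seed=seed)
    conc = {"leukocyte": 1000.0, "RBC": 1200.0, "platelet": 900.0, "ldEV": 600.0}
    pops = tuple(dataclasses.replace(p, concentration=conc[p.class_name],
                                     suspended=False)
                 for p in base.populations)
    return dataclasses.replace(base, populations=pops, frames_per_well=frames)


@pytest.fixture(scope="session")
def ideal_optics():
    return ev.OpticsConfig(frame_shape=(256, 256), defocus_sigma_range=(0.0, 0.0))


@pytest.fixture(scope="session")
def ideal_well(ideal_optics):
    """One ideally-imaged sparse well run through the whole pipeline."""
    cfg = sparse_whole_blood_config()
    particles = ev.sample_well(cfg, 0, ideal_optics, well_id="donor0-w0")
    run = ev.count_well(cfg, 0, optics=ideal_optics, keep_tables=True)
    clusters = touching_clusters(particles, ideal_optics)
    return {"config": cfg, "particles": particles, "run": run,
            "clusters": clusters}
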