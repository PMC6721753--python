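"""Declarative conjunctive gating of feature tables.

A gate set is a conjunction of per-channel linear criteria (e.g. CD45
mean intensity > 30 AND max > 50 AND ...).  Two libraries ship with the
package: library A for EpCAM-enriched cartridges (leukocyte and ldEV
gates; nuclear dye DAPI, CK negativity) and library B for whole blood
without enrichment (all four classes; nuclear dye Hoechst, CD61/CD235a
negativity).  Marker negativity is the "standard deviation <= 5"
criterion; positivity is mean > 30 and max > 50.  Criteria reference
channel *roles* (nuclear, CD45, ...); the mapping from role to actual
channel name comes from the imaging metadata.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

INTENSITY_GATE_FEATURES = ("mean_intensity", "max_intensity", "std_intensity")
MORPHOLOGY_GATE_FEATURES = ("size_um2", "perimeter_px", "eccentricity")
GATE_FEATURES = INTENSITY_GATE_FEATURES + MORPHOLOGY_GATE_FEATURES
COMPARATORS = (">", "<=")

LIBRARY_FILES = {
    "A": "gates_A_epcam.json",
    "A_epcam": "gates_A_epcam.json",
    "B": "gates_B_whole_blood.json",
    "B_whole_blood": "gates_B_whole_blood.json",
}

UNCLASSIFIED = "unclassified"
AMBIGUOUS = "ambiguous"


@dataclass(frozen=True)
class GateCriterion:
    """One linear criterion: ``feature(channel_role) cmp threshold``.

    Morphology features (size, perimeter, eccentricity) describe the
    whole object; their ``channel_role`` records where the criterion is
    filed in the library but does not affect evaluation.
    """

    channel_role: str
    feature: str
    cmp: str
    threshold: float

    def __post_init__(self) -> None:
        if self.feature not in GATE_FEATURES:
            raise ValueError(f"unknown gate feature {self.feature!r}")
        if self.cmp not in COMPARATORS:
            raise ValueError(f"comparator must be one of {COMPARATORS}")


@dataclass(frozen=True)
class GateSet:
    """Conjunction of criteria defining one object class."""

    class_name: str
    criteria: tuple[GateCriterion, ...]
    library: str = ""

    def __post_init__(self) -> None:
        if not self.criteria:
            raise ValueError(f"gate set for {self.class_name!r} has no criteria")


def _resolve_column(crit: GateCriterion, channel_roles: Mapping[str, str]) -> str:
    if crit.feature in MORPHOLOGY_GATE_FEATURES:
        return crit.feature
    try:
        channel = channel_roles[crit.channel_role]
    except KeyError:
        raise KeyError(f"channel role {crit.channel_role!r} not in role map "
                       f"{sorted(channel_roles)}") from None
    return f"{crit.feature}_{channel}"


def load_gate_library(source) -> list[GateSet]:
    """Load gate sets from a bundled library name, a path, or parsed JSON.

    ``source`` may be ``"A"``/``"A_epcam"``, ``"B"``/``"B_whole_blood"``,
    a path to a JSON file, or an already-parsed list of dicts.
    """
    if isinstance(source, str) and source in LIBRARY_FILES:
        text = (resources.files("evcounter.data") / LIBRARY_FILES[source]).read_text()
        raw = json.loads(text)
    elif isinstance(source, str):
        with open(source) as fh:
            raw = json.load(fh)
    else:
        raw = source
    if not isinstance(raw, list) or not raw:
        raise ValueError("gate library must be a non-empty list of gate sets")
    gatesets = []
    for entry in raw:
        criteria = tuple(
            GateCriterion(c["channel_role"], c["feature"], c["cmp"],
                          float(c["threshold"]))
            for c in entry["criteria"])
        gatesets.append(GateSet(entry["class"], criteria,
                                entry.get("library", "")))
    return gatesets


def save_gate_library(gatesets: Iterable[GateSet], path: str) -> None:
    raw = [
        {"class": g.class_name, "library": g.library,
         "criteria": [{"channel_role": c.channel_role, "feature": c.feature,
                       "cmp": c.cmp, "threshold": c.threshold}
                      for c in g.criteria]}
        for g in gatesets
    ]
    with open(path, "w") as fh:
        json.dump(raw, fh, indent=1)


def evaluate(record: Mapping, gate: GateSet,
             channel_roles: Mapping[str, str]) -> bool:
    """True iff every criterion of ``gate`` holds for one feature record.

    A missing feature raises ``KeyError`` naming the column; it is never
    silently treated as a failed criterion.
    """
    for crit in gate.criteria:
        col = _resolve_column(crit, channel_roles)
        try:
            value = record[col]
        except KeyError:
            raise KeyError(f"record is missing feature column {col!r} "
                           f"required by the {gate.class_name!r} gate") from None
        if crit.cmp == ">":
            ok = value > crit.threshold
        else:
            ok = value <= crit.threshold
        if not ok:
            return False
    return True


def gate_mask(table: pd.DataFrame, gate: GateSet,
              channel_roles: Mapping[str, str]) -> np.ndarray:
    """Vectorized ``evaluate`` over a feature table."""
    mask = np.ones(len(table), dtype=bool)
    for crit in gate.criteria:
        col = _resolve_column(crit, channel_roles)
        if col not in table.columns:
            raise KeyError(f"feature table is missing column {col!r} "
                           f"required by the {gate.class_name!r} gate")
        vals = table[col].to_numpy()
        mask &= (vals > crit.threshold) if crit.cmp == ">" else (vals <= crit.threshold)
    return mask


def classify(table: pd.DataFrame, gatesets: Iterable[GateSet],
             channel_roles: Mapping[str, str]
             ) -> tuple[pd.DataFrame, dict[str, int]]:
    """Assign every record to a class, ``unclassified`` or ``ambiguous``.

    Returns the per-object assignment table and per-class counts.
    Ambiguous objects (matching more than one gate) are reported
    separately, never folded into a class.
    """
    gatesets = list(gatesets)
    names = [g.class_name for g in gatesets]
    n = len(table)
    if n == 0:
        counts = {name: 0 for name in names}
        counts[UNCLASSIFIED] = 0
        counts[AMBIGUOUS] = 0
        return (pd.DataFrame(columns=["object_id", "matched_classes", "final_class"]),
                counts)
    match = np.zeros((n, len(gatesets)), dtype=bool)
    for j, g in enumerate(gatesets):
        match[:, j] = gate_mask(table, g, channel_roles)
    n_match = match.sum(axis=1)
    final = np.where(n_match == 0, UNCLASSIFIED,
                     np.where(n_match > 1, AMBIGUOUS, ""))
    final = final.astype(object)
    single = n_match == 1
    if single.any():
        which = match[single].argmax(axis=1)
        final[single] = [names[j] for j in which]
    matched = [";".join(name for name, m in zip(names, row) if m) for row in match]
    assignments = pd.DataFrame({
        "object_id": table["object_id"].to_numpy() if "object_id" in table.columns
        else np.arange(n),
        "matched_classes": matched,
        "final_class": final,
    })
    counts = {name: int((final == name).sum()) for name in names}
    counts[UNCLASSIFIED] = int((final == UNCLASSIFIED).sum())
    counts[AMBIGUOUS] = int((final == AMBIGUOUS).sum())
    return assignments, counts
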