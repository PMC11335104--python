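"""Default occupancy candidate-model lists.

The study design compares 87 simple, biologically plausible models — 20
detection-stage models fitted with constant occupancy, then 67
occupancy-stage models sharing the winning detection structure — each with
at most two covariates.  The exact published list is not machine-readable,
so this module generates a list with that structure from the study's
covariate names; users can supply their own lists (e.g. loaded from JSON)
anywhere a candidate list is accepted.
"""

from __future__ import annotations

import itertools
import json
from pathlib import Path
from typing import Sequence

DETECTION_COVARIATES = ("N_obj", "Veg_H", "Soil_moisture", "T_ground")
OCCUPANCY_COVARIATES = ("Veg_H", "Slope", "Con", "CTI", "Tprom", "Tmax", "Tmin",
                        "Leaf_Dep", "Hori0", "D_house", "D_forest", "D_water")
# site-level covariates additionally allowed on the detection scale to fill
# the 20-model detection stage
_EXTRA_P_SINGLES = ("Slope", "CTI", "Con", "Leaf_Dep", "Hori0", "D_house",
                    "D_forest", "D_water", "Tmax")


def validate_candidates(candidates: Sequence[Sequence[str]],
                        max_covariates: int = 2) -> list[tuple[str, ...]]:
    """Enforce the one-or-two-covariate structure of the candidate lists."""
    out = []
    for cand in candidates:
        cand = tuple(cand)
        if len(cand) > max_covariates:
            raise ValueError(f"candidate {cand} exceeds {max_covariates} covariates")
        if len(set(cand)) != len(cand):
            raise ValueError(f"candidate {cand} repeats a covariate")
        out.append(cand)
    if not out:
        raise ValueError("empty candidate list")
    return out


def default_detection_candidates(available: Sequence[str] | None = None
                                 ) -> list[tuple[str, ...]]:
    """20 detection-stage candidates: constant, singles and pairs of the
    detection covariates, padded with site-covariate singles."""
    cands: list[tuple[str, ...]] = [()]
    cands += [(c,) for c in DETECTION_COVARIATES]
    cands += list(itertools.combinations(DETECTION_COVARIATES, 2))
    cands += [(c,) for c in _EXTRA_P_SINGLES]
    if available is not None:
        cands = [c for c in cands if set(c) <= set(available) or not c]
    return validate_candidates(cands[:20])


def default_occupancy_candidates(available: Sequence[str] | None = None
                                 ) -> list[tuple[str, ...]]:
    """67 occupancy-stage candidates: constant, all singles, and a
    deterministic subset of pairs (vegetation-height pairs first)."""
    covs = list(OCCUPANCY_COVARIATES)
    if available is not None:
        covs = [c for c in covs if c in available]
    cands: list[tuple[str, ...]] = [()]
    cands += [(c,) for c in covs]
    veg_pairs = [("Veg_H", c) for c in covs if c != "Veg_H"]
    other_pairs = [p for p in itertools.combinations(covs, 2)
                   if "Veg_H" not in p]
    cands += veg_pairs + other_pairs
    return validate_candidates(cands[:67])


def load_candidates(path: str | Path) -> tuple[list[tuple[str, ...]],
                                               list[tuple[str, ...]]]:
    """Load ``{"detection": [[...], ...], "occupancy": [[...], ...]}`` from
    JSON."""
    with open(path) as fh:
        obj = json.load(fh)
    return (validate_candidates(obj["detection"]),
            validate_candidates(obj["occupancy"]))
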