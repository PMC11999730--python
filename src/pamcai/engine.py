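"""The decision-aid computation.

Three steps mirror the clinical workflow: (1) a five-question eligibility
screen summed against a strict threshold, (2) selection of the top three
severity-weighted barriers from the 24-item questionnaire, (3) a pure
lookup mapping each selected barrier to its recommended resources
(information sheets, video links, clinical considerations — carried here
only as opaque labels).

When more than three barriers share the cutoff severity the clinical
instrument delegates to clinician discretion; for reproducibility this
implementation breaks ties deterministically by ascending barrier id and
raises ``tie_flag`` so the discretion point stays visible. The three
selected barriers are presented to the clinician unranked; the internal
order exists only to make output deterministic.
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .types import BARRIER_CATALOGUE, N_BARRIER_ITEMS, BarrierAssessment

__all__ = [
    "TopBarriers",
    "ResourceMap",
    "ResourceMapError",
    "adhesig_screen",
    "select_top_barriers",
    "recommend_resources",
    "default_resource_map",
    "load_resource_map",
]

ADHESIG_THRESHOLD = 3


class TopBarriers(BaseModel):
    """Up to three (barrier_id, severity) pairs; unranked display contract."""

    model_config = ConfigDict(frozen=True)

    selected: tuple[tuple[int, int], ...] = ()
    tie_flag: bool = False
    discretion_note: Optional[str] = None

    @field_validator("selected")
    @classmethod
    def _at_most_three(cls, v):
        if len(v) > 3:
            raise ValueError(f"at most 3 barriers may be selected, got {len(v)}")
        return v

    @property
    def barrier_ids(self) -> tuple[int, ...]:
        return tuple(bid for bid, _ in self.selected)


class ResourceMapError(KeyError):
    """A selected barrier has no resource entry configured."""


class ResourceMap(BaseModel):
    """barrier_id -> resource labels. Must cover the whole catalogue."""

    model_config = ConfigDict(frozen=True)

    entries: dict[int, tuple[str, ...]]

    @field_validator("entries")
    @classmethod
    def _nonempty(cls, v):
        for bid, resources in v.items():
            if bid not in BARRIER_CATALOGUE:
                raise ValueError(f"unknown barrier id {bid}")
            if not resources:
                raise ValueError(f"barrier {bid} has an empty resource list")
        return v

    def covers_catalogue(self) -> bool:
        return set(self.entries) >= set(BARRIER_CATALOGUE)


def adhesig_screen(answers: Sequence[int], threshold: int = ADHESIG_THRESHOLD) -> tuple[int, bool]:
    """Five-question adherence screen; eligible iff total *strictly* exceeds
    the threshold (default 3). Each answer is scored 0-4."""
    if len(answers) != 5:
        raise ValueError(f"the screen has exactly 5 questions, got {len(answers)} answers")
    for i, a in enumerate(answers, start=1):
        if a not in (0, 1, 2, 3, 4):
            raise ValueError(f"question {i}: answer {a} outside 0-4")
    total = int(sum(answers))
    return total, total > threshold


def select_top_barriers(assessment: BarrierAssessment) -> TopBarriers:
    """Select the top three barriers by raw Likert severity.

    Severities are used unweighted; absent responses are never selected.
    Deterministic tie-break: ascending barrier id, with ``tie_flag`` set
    whenever the third and fourth barrier share the cutoff severity.
    """
    responses = assessment.responses
    if not responses:
        warnings.warn("empty barrier assessment: no barriers to select", stacklevel=2)
        return TopBarriers(selected=(), tie_flag=False)
    ordered = sorted(responses.items(), key=lambda kv: (-kv[1], kv[0]))
    selected = tuple(ordered[:3])
    tie = len(ordered) > 3 and ordered[3][1] == ordered[2][1]
    note = "more than three barriers share the cutoff severity; clinician discretion applies" if tie else None
    return TopBarriers(selected=selected, tie_flag=tie, discretion_note=note)


def recommend_resources(top: TopBarriers, resource_map: ResourceMap) -> list[tuple[int, tuple[str, ...]]]:
    """Look up the configured resources for each selected barrier, in
    selection order. Pure lookup — resources are not ranked."""
    out = []
    for bid in top.barrier_ids:
        if bid not in resource_map.entries:
            raise ResourceMapError(f"no resources configured for barrier {bid}")
        out.append((bid, resource_map.entries[bid]))
    return out


def default_resource_map() -> ResourceMap:
    """A complete catalogue-covering map with generic resource labels.

    The clinical content of the resources is out of scope; every barrier
    gets an information-sheet label, a video label and a clinical
    consideration label derived from its catalogue name.
    """
    entries = {
        bid: (f"sheet_{name}", f"video_{name}", f"consideration_{name}")
        for bid, name in BARRIER_CATALOGUE.items()
    }
    return ResourceMap(entries=entries)


def load_resource_map(path) -> ResourceMap:
    """Load a resource map from YAML: ``{barrier_id: [labels, ...]}``."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return ResourceMap(entries={int(k): tuple(v) for k, v in data.items()})
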