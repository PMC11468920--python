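"""Factorial trial structure of the context-guided search experiment.

Each run fully crosses five binary factors — trial type (search vs.
preview-only), target presence, target category (book vs. bowl), scene
context (blue vs. yellow living room) and the screen side of the associated
anchor table — so that every one of the 2**5 = 32 cells occurs exactly once
per run.  The target→anchor association is context dependent and reverses
between the two scene contexts (association reversal), which is what later
allows cross-scene decoding to separate anchor coding from target coding.
"""

from __future__ import annotations

import dataclasses
import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from anchorsearch._rng import as_rng, spawn_seeds

TARGETS = ("book", "bowl")
CONTEXTS = ("blue", "yellow")
ANCHORS = ("table_1", "table_2")
SIDES = ("left", "right")
TRIAL_TYPES = ("search", "preview_only")

N_FACTOR_CELLS = 32  # 2**5 fully crossed binary factors


@dataclass(frozen=True)
class AssociationMap:
    """Context-dependent target→anchor association with reversal.

    Within each scene context the two targets map to distinct anchors, and
    the mapping in one context is the anchor-swap of the other.  Four
    counterbalancing variants exist: 2 pairings in the primary context × 2
    choices of which context is primary.
    """

    counterbalance_id: int
    mapping: dict = field(repr=False)  # (context, target) -> anchor
    primary_context: str = CONTEXTS[0]

    def __post_init__(self):
        for ctx in CONTEXTS:
            a = {self.mapping[(ctx, t)] for t in TARGETS}
            if a != set(ANCHORS):
                raise ValueError(f"targets in context {ctx!r} must map to distinct anchors")
        for t in TARGETS:
            if self.mapping[(CONTEXTS[0], t)] == self.mapping[(CONTEXTS[1], t)]:
                raise ValueError("association must reverse across contexts")

    def anchor_for(self, target: str, context: str) -> str:
        """Anchor associated with ``target`` in ``context``."""
        return self.mapping[(context, target)]


def make_association_map(counterbalance_id: int) -> AssociationMap:
    """Build one of the four counterbalanced association maps.

    Bit 0 of ``counterbalance_id`` selects which anchor pairs with the first
    target in the primary context; bit 1 selects which scene context is
    primary.  id=0 gives book→table_1, bowl→table_2 in the blue room and the
    anchor-swapped pairing in the yellow room.
    """
    if counterbalance_id not in (0, 1, 2, 3):
        raise ValueError(f"counterbalance_id must be in 0..3, got {counterbalance_id!r}")
    flip_pairing = counterbalance_id & 1
    primary = CONTEXTS[(counterbalance_id >> 1) & 1]
    other = CONTEXTS[1] if primary == CONTEXTS[0] else CONTEXTS[0]
    mapping = {}
    for i, t in enumerate(TARGETS):
        mapping[(primary, t)] = ANCHORS[(i + flip_pairing) % 2]
        mapping[(other, t)] = ANCHORS[(i + flip_pairing + 1) % 2]
    return AssociationMap(counterbalance_id=counterbalance_id, mapping=mapping,
                          primary_context=primary)


@dataclass(frozen=True)
class TimingParams:
    """Trial timing in seconds.

    The preview is jittered between ``preview_jitter`` bounds on search
    trials and lasts a fixed ``preview_only_total`` on preview-only trials.
    ``search_extra`` covers the brief search display plus the response
    screen, which only occur on search trials.
    """

    cue_duration: float = 1.0
    preview_jitter: tuple = (3.1, 4.0)
    preview_only_total: float = 4.4
    iti: tuple = (2.0, 4.0)
    search_extra: float = 1.9

    def __post_init__(self):
        if self.cue_duration <= 0:
            raise ValueError("cue_duration must be positive")
        if not (0 < self.preview_jitter[0] <= self.preview_jitter[1]):
            raise ValueError("preview_jitter bounds must be positive and ordered")
        if self.preview_only_total <= 0:
            raise ValueError("preview_only_total must be positive")
        if not (0 <= self.iti[0] <= self.iti[1]):
            raise ValueError("iti bounds must be non-negative and ordered")


@dataclass(frozen=True)
class TrialSpec:
    """One trial's factor levels, run assignment and event timing.

    ``target_present`` and ``anchor_side`` are generated for preview-only
    trials as well (they have no stimulus consequence there) so that the
    five-factor counterbalancing is exact.  ``anchor_side`` is the screen
    side of the *associated* anchor.
    """

    run: int
    trial_index: int
    trial_type: str
    target: str
    context: str
    target_present: bool
    anchor_side: str
    cue_onset: float
    preview_onset: float
    preview_offset: float

    def __post_init__(self):
        if self.trial_type not in TRIAL_TYPES:
            raise ValueError(f"bad trial_type {self.trial_type!r}")
        if self.target not in TARGETS or self.context not in CONTEXTS:
            raise ValueError("bad factor level")
        if self.anchor_side not in SIDES:
            raise ValueError(f"bad anchor_side {self.anchor_side!r}")
        if not self.preview_offset > self.preview_onset >= self.cue_onset >= 0:
            raise ValueError("onsets must be ordered: cue <= preview_onset < preview_offset")

    @property
    def is_preview_only(self) -> bool:
        return self.trial_type == "preview_only"


def _factor_cells():
    return list(itertools.product(TRIAL_TYPES, (True, False), TARGETS, CONTEXTS, SIDES))


def generate_run(run_index: int, timing: TimingParams | None = None, seed=None) -> list:
    """Generate one run of 32 trials: every factor cell once, seeded order.

    Trial onsets increase strictly; timing follows ``TimingParams``.
    """
    timing = timing or TimingParams()
    rng = as_rng(seed)
    cells = _factor_cells()
    order = rng.permutation(len(cells))
    trials = []
    t = 0.0
    for i, k in enumerate(order):
        trial_type, present, target, context, side = cells[k]
        cue_onset = t
        preview_onset = cue_onset + timing.cue_duration
        if trial_type == "preview_only":
            preview_offset = preview_onset + timing.preview_only_total
            tail = 0.0
        else:
            preview_offset = preview_onset + rng.uniform(*timing.preview_jitter)
            tail = timing.search_extra
        trials.append(TrialSpec(run=run_index, trial_index=i, trial_type=trial_type,
                                target=target, context=context, target_present=present,
                                anchor_side=side, cue_onset=cue_onset,
                                preview_onset=preview_onset, preview_offset=preview_offset))
        t = preview_offset + tail + rng.uniform(*timing.iti)
    return trials


def generate_experiment(n_runs: int = 8, timing: TimingParams | None = None,
                        seed=None) -> list:
    """Concatenate ``n_runs`` runs, reseeding each run from ``seed``."""
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    child_seeds = spawn_seeds(seed if seed is not None else 0, n_runs)
    trials = []
    for r in range(n_runs):
        trials.extend(generate_run(r, timing=timing, seed=as_rng(child_seeds[r])))
    return trials


_COLUMNS = ["run", "trial_index", "trial_type", "target", "context",
            "present", "anchor_side", "cue_onset", "preview_onset", "preview_offset"]


def trials_to_frame(trials) -> pd.DataFrame:
    rows = [(t.run, t.trial_index, t.trial_type, t.target, t.context,
             t.target_present, t.anchor_side, t.cue_onset, t.preview_onset,
             t.preview_offset) for t in trials]
    return pd.DataFrame(rows, columns=_COLUMNS)


def write_trial_table(trials, path) -> None:
    """Write trials as a tab-separated events file (times in seconds)."""
    trials_to_frame(trials).to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_trial_table(path) -> list:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    return [TrialSpec(run=int(r.run), trial_index=int(r.trial_index),
                      trial_type=r.trial_type, target=r.target, context=r.context,
                      target_present=bool(r.present), anchor_side=r.anchor_side,
                      cue_onset=float(r.cue_onset), preview_onset=float(r.preview_onset),
                      preview_offset=float(r.preview_offset))
            for r in df.itertuples()]
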