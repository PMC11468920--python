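"""Eye-tracking and behavioral analysis.

Fixations during the search display are classified into rectangular areas of
interest (AOIs): a center AOI around fixation and one AOI per anchor table.
The guidance statistic is the percentage-point difference between first
fixations landing on the target-associated anchor and on the non-associated
anchor (Δ%), computed separately for target-present and target-absent trials.
Search sensitivity is the equal-variance signal-detection d′ and is related
to guidance across participants by a Pearson correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from anchorsearch import stats as _stats

AOI_LABELS = ("center", "left_anchor", "right_anchor", "none")


@dataclass(frozen=True)
class Rect:
    """Axis-aligned rectangle: center (cx, cy) and full width/height, in
    degrees of visual angle (origin at fixation, x rightward, y upward)."""

    cx: float
    cy: float
    width: float
    height: float

    def contains(self, x: float, y: float) -> bool:
        # boundaries inclusive
        return (abs(x - self.cx) * 2 <= self.width) and (abs(y - self.cy) * 2 <= self.height)


@dataclass(frozen=True)
class AoiSet:
    """The three rectangular AOIs.

    Defaults: 4.5° × 10.5° center AOI at fixation and 7.5° × 10.5° anchor
    AOIs centered at ±7.5° horizontally, 1.5° below fixation (the anchor
    tables sit slightly below fixation in the left/right periphery).
    """

    center_rect: Rect = field(default_factory=lambda: Rect(0.0, 0.0, 4.5, 10.5))
    left_anchor_rect: Rect = field(default_factory=lambda: Rect(-7.5, -1.5, 7.5, 10.5))
    right_anchor_rect: Rect = field(default_factory=lambda: Rect(7.5, -1.5, 7.5, 10.5))

    def __post_init__(self):
        la, ra = self.left_anchor_rect, self.right_anchor_rect
        if abs(la.cx - ra.cx) * 2 < la.width + ra.width and abs(la.cy - ra.cy) * 2 < la.height + ra.height:
            raise ValueError("anchor AOIs must not overlap")

    def rect(self, side: str) -> Rect:
        return self.left_anchor_rect if side == "left" else self.right_anchor_rect


@dataclass(frozen=True)
class FixationRecord:
    """One fixation: position in degrees, onset (ms from scene onset),
    duration (ms) and ordinal index within its trial."""

    trial_ref: int  # global trial key: run * trials_per_run + trial_index
    x: float
    y: float
    onset: float
    duration: float
    ordinal: int

    def __post_init__(self):
        if not self.duration > 0:
            raise ValueError("fixation duration must be positive")


@dataclass
class BehavioralSummary:
    participant_id: int
    hit_rate: float
    fa_rate: float
    dprime: float
    guidance_delta_present: float  # Δ% on target-present trials
    guidance_delta_absent: float   # Δ% on target-absent trials


def classify_fixation(f, aois: AoiSet) -> str:
    """AOI label of a fixation (or an (x, y) pair); anchors take precedence
    over the center AOI, boundaries are inclusive."""
    x, y = (f.x, f.y) if isinstance(f, FixationRecord) else f
    if aois.left_anchor_rect.contains(x, y):
        return "left_anchor"
    if aois.right_anchor_rect.contains(x, y):
        return "right_anchor"
    if aois.center_rect.contains(x, y):
        return "center"
    return "none"


def first_fixation_labels(fixations_by_trial: dict, aois: AoiSet,
                          scene_onset: float = 0.0, tolerance: float = 0.0) -> dict:
    """Per-trial AOI label of the first fixation after scene onset.

    A trial is included iff some fixation overlaps scene onset (within
    ``tolerance`` ms) *and* lies in the center AOI; the trial's label is the
    AOI of the next fixation starting after scene onset.  Trials failing the
    inclusion rule or with no subsequent fixation are labeled ``"excluded"``.
    """
    labels = {}
    for trial_ref, fixations in fixations_by_trial.items():
        fixations = sorted(fixations, key=lambda f: f.onset)
        onset_fix = None
        for f in fixations:
            if f.onset - tolerance <= scene_onset <= f.onset + f.duration + tolerance:
                onset_fix = f
                break
        if onset_fix is None or classify_fixation(onset_fix, aois) != "center":
            labels[trial_ref] = "excluded"
            continue
        later = [f for f in fixations if f.onset > max(scene_onset, onset_fix.onset)]
        labels[trial_ref] = classify_fixation(later[0], aois) if later else "excluded"
    return labels


def guidance_delta(labels: dict, trials, association) -> dict:
    """First-fixation guidance Δ% per target-presence condition.

    Δ% = 100 · (#first fixations on the associated anchor − #on the other
    anchor) / #included trials in the condition.  ``trials`` supplies each
    trial's factors; the associated anchor's screen side is the trial's
    ``anchor_side``.  Returns ``{"present": Δ%, "absent": Δ%}`` with NaN (and
    a warning) for a condition with no included trials.
    """
    by_ref = {t.run * 1000 + t.trial_index: t for t in trials}
    counts = {"present": [0, 0, 0], "absent": [0, 0, 0]}  # assoc, other, included
    for ref, label in labels.items():
        if label == "excluded":
            continue
        t = by_ref[ref]
        cond = "present" if t.target_present else "absent"
        assoc_label = f"{t.anchor_side}_anchor"
        counts[cond][2] += 1
        if label == assoc_label:
            counts[cond][0] += 1
        elif label in ("left_anchor", "right_anchor"):
            counts[cond][1] += 1
    out = {}
    for cond, (n_assoc, n_other, n_inc) in counts.items():
        if n_inc == 0:
            warnings.warn(f"no included trials in condition {cond!r}; Δ% undefined")
            out[cond] = float("nan")
        else:
            out[cond] = 100.0 * (n_assoc - n_other) / n_inc
    return out


def dprime(n_hits: int, n_target_present: int, n_fa: int, n_target_absent: int) -> float:
    """Equal-variance signal-detection d′ = Φ⁻¹(hit rate) − Φ⁻¹(FA rate).

    Extreme rates of 0 or 1 are corrected to 1/(2N) and 1 − 1/(2N) so d′
    stays finite.
    """
    if n_target_present <= 0 or n_target_absent <= 0:
        raise ValueError("trial counts must be positive")

    def _rate(k, n):
        r = k / n
        if r == 0.0:
            r = 1.0 / (2 * n)
        elif r == 1.0:
            r = 1.0 - 1.0 / (2 * n)
        return r

    return float(norm.ppf(_rate(n_hits, n_target_present))
                 - norm.ppf(_rate(n_fa, n_target_absent)))


def behavioral_summary(participant_id: int, trials, fixations_by_trial,
                       responses: pd.DataFrame, aois: AoiSet,
                       association) -> BehavioralSummary:
    """Combine gaze and response data into one participant's summary.

    ``responses`` needs columns (run, trial_index, reported_present); only
    search trials are scored.
    """
    labels = first_fixation_labels(fixations_by_trial, aois)
    deltas = guidance_delta(labels, trials, association)
    by_ref = {t.run * 1000 + t.trial_index: t for t in trials}
    n_hit = n_pres = n_fa = n_abs = 0
    for row in responses.itertuples():
        t = by_ref[int(row.run) * 1000 + int(row.trial_index)]
        if t.trial_type != "search":
            continue
        if t.target_present:
            n_pres += 1
            n_hit += int(row.reported_present)
        else:
            n_abs += 1
            n_fa += int(row.reported_present)
    hr = n_hit / n_pres if n_pres else float("nan")
    far = n_fa / n_abs if n_abs else float("nan")
    return BehavioralSummary(participant_id=participant_id, hit_rate=hr, fa_rate=far,
                             dprime=dprime(n_hit, n_pres, n_fa, n_abs),
                             guidance_delta_present=deltas["present"],
                             guidance_delta_absent=deltas["absent"])


def guidance_performance_correlation(summaries) -> dict:
    """Pearson r (and p) between guidance Δ% and d′ across participants,
    separately for present- and absent-trial guidance."""
    d = np.array([s.dprime for s in summaries], dtype=float)
    out = {}
    for cond, attr in (("present", "guidance_delta_present"),
                       ("absent", "guidance_delta_absent")):
        g = np.array([getattr(s, attr) for s in summaries], dtype=float)
        ok = np.isfinite(g) & np.isfinite(d)
        if ok.sum() < 3:
            raise ValueError("need >= 3 participants with defined values")
        out[cond] = _stats.pearson_correlation(g[ok], d[ok])
    return out


def condition_difference_test(deltas_present, deltas_absent, n_boot: int = 10000,
                              seed=None):
    """Bootstrap test on paired per-participant Δ% differences (present − absent)."""
    dp = np.asarray(deltas_present, dtype=float)
    da = np.asarray(deltas_absent, dtype=float)
    if dp.shape != da.shape:
        raise ValueError("paired inputs must have equal length")
    return _stats.bootstrap_test(dp - da, n_boot=n_boot, seed=seed)


def write_fixation_table(fixations_by_participant: dict, path) -> None:
    """Tab-separated fixation file: participant, run, trial_index, ordinal,
    x_deg, y_deg, onset_ms, duration_ms."""
    rows = []
    for pid, fxs in fixations_by_participant.items():
        for f in fxs:
            rows.append((pid, f.trial_ref // 1000, f.trial_ref % 1000, f.ordinal,
                         f.x, f.y, f.onset, f.duration))
    pd.DataFrame(rows, columns=["participant", "run", "trial_index", "ordinal",
                                "x_deg", "y_deg", "onset_ms", "duration_ms"]
                 ).to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_fixation_table(path) -> dict:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    out: dict = {}
    for r in df.itertuples():
        out.setdefault(int(r.participant), []).append(
            FixationRecord(trial_ref=int(r.run) * 1000 + int(r.trial_index),
                           x=float(r.x_deg), y=float(r.y_deg), onset=float(r.onset_ms),
                           duration=float(r.duration_ms), ordinal=int(r.ordinal)))
    return out
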