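"""Data-selection cascade for force-clamp segments.

Segments are excluded, in a fixed order, when (1) the deflection never
reached the target setpoint, (2) F > 1000 pN, (3) F < -200 pN (large
apparent pushes/pulls indicate a baseline corrupted by surface contact),
(4) sigma_F > 200 pN, (5) F < 0 pN (tether events are not expected at push
forces), (6) the segment is of type U (tip not in contact with anything:
no events after setpoint attainment, no events in any later segment, and
every subsequent deflection rise accompanied by a z rise of ~1 um or
more). Each excluded segment is attributed to the first rule it fails and
the count surviving after every rule is reported, giving a full audit
trail of the cascade.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .afm_calibration import ClampSegment

__all__ = ["QcReport", "flag_U", "filter_segments", "RULES"]

RULES = (
    "not_reached_setpoint",
    "F_gt_1000pN",
    "F_lt_minus200pN",
    "sigmaF_gt_200pN",
    "F_lt_0pN",
    "U_segment",
)

U_Z_RISE_NM = 1000.0  # ~1 um


@dataclass
class QcReport:
    rules: tuple = RULES
    counts_after: dict = field(default_factory=dict)  # rule -> remaining count
    exclusion_reason: dict = field(default_factory=dict)  # segment id -> rule
    n_input: int = 0
    n_survivors: int = 0
    diagnostics: dict = field(default_factory=dict)

    def to_json(self, **kw) -> str:
        return json.dumps(
            {
                "n_input": self.n_input,
                "rules": list(self.rules),
                "counts_after": self.counts_after,
                "exclusion_reason": {str(k): v for k, v in self.exclusion_reason.items()},
                "n_survivors": self.n_survivors,
                "diagnostics": self.diagnostics,
            },
            **kw,
        )


def flag_U(segment: ClampSegment, later_segments, events_by_segment) -> bool:
    """Decide whether a segment is of type U (tip attached to nothing).

    All three criteria must hold: no events in this segment after setpoint
    attainment; no events of any type in any later segment of the same
    recording; and every deflection rise during or after this segment (the
    entry ramps of this and all later segments) accompanied by a z rise of
    at least ~1 um. ``events_by_segment`` maps segment index to its event
    list.
    """
    own = [
        e
        for e in events_by_segment.get(segment.index, [])
        if e.event_type != "R"
    ]
    if own:
        return False
    for seg in later_segments:
        if events_by_segment.get(seg.index, []):
            return False
    for seg in (segment, *later_segments):
        if np.isfinite(seg.ramp_dz) and seg.ramp_dz < U_Z_RISE_NM:
            return False
    return True


def _segment_id(seg: ClampSegment, i: int):
    return getattr(seg, "segment_id", i)


def filter_segments(segments, events_by_segment=None):
    """Apply the data-selection cascade; returns ``(survivors, QcReport)``.

    ``segments`` must carry F, sigma_F, reached_setpoint and (for the U
    rule) is_U — is_U may be precomputed or derived here from
    ``events_by_segment`` when given. Boundary values are retained: the
    force rules use strict inequalities (F > 1000, F < -200, sigma_F > 200,
    F < 0); F = 0 exactly is retained with a warning flag since it means no
    pull.
    """
    segments = list(segments)
    report = QcReport(n_input=len(segments))
    if events_by_segment is not None:
        for i, seg in enumerate(segments):
            later = segments[i + 1 :]
            same_rec = [
                s for s in later if getattr(s, "recording_id", None) == getattr(seg, "recording_id", None)
            ]
            seg.is_U = flag_U(seg, same_rec, events_by_segment)

    def fails(rule, seg):
        if rule == "not_reached_setpoint":
            return not seg.reached_setpoint
        if rule == "F_gt_1000pN":
            return seg.F > 1000.0
        if rule == "F_lt_minus200pN":
            return seg.F < -200.0
        if rule == "sigmaF_gt_200pN":
            return seg.sigma_F > 200.0
        if rule == "F_lt_0pN":
            return seg.F < 0.0
        if rule == "U_segment":
            return seg.is_U
        raise KeyError(rule)

    alive = {(_segment_id(s, i)): s for i, s in enumerate(segments)}
    for rule in RULES:
        for sid in list(alive):
            if fails(rule, alive[sid]):
                report.exclusion_reason[sid] = rule
                del alive[sid]
        report.counts_after[rule] = len(alive)
    survivors = list(alive.values())
    for s in survivors:
        if s.F == 0.0 and "zero_force" not in s.flags:
            s.flags.append("zero_force")
    report.n_survivors = len(survivors)
    # diagnostic: push-force segments (-200 <= F < 0, sigma_F < 200) that
    # nonetheless contained R or FC events — sanity check, not a filter
    if events_by_segment is not None:
        n_push, n_push_with_events = 0, 0
        for i, seg in enumerate(segments):
            if -200.0 <= seg.F < 0.0 and seg.sigma_F < 200.0:
                n_push += 1
                evs = events_by_segment.get(seg.index, [])
                if any(e.event_type in ("R", "FC") for e in evs):
                    n_push_with_events += 1
        report.diagnostics["push_segments_checked"] = n_push
        report.diagnostics["push_segments_with_events"] = n_push_with_events
    return survivors, report
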