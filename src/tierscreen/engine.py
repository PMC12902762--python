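"""Stateful adaptive administration of a tiered battery.

A :class:`Session` walks one respondent through the three tiers:

* Tier 1 — the distress gateway scale (13 items).  A negative outcome
  terminates the whole procedure.
* Tier 2 — all four short gate scales together (9 items).  A respondent
  negative on every gate terminates here.
* Tier 3 — for each positive gate, the remainder of the corresponding full
  scale.  Items already answered in Tier 2 are never asked again; their
  responses carry over into the full-scale score.

Sessions are append-only: responses can be submitted only for the currently
pending items, never revised.  The full event log serialises to JSON and a
session can be replayed bit-identically from it.
"""

from __future__ import annotations

import json
import uuid
from dataclasses import dataclass
from typing import Mapping

from .instruments import Battery, DISORDERS, ScoringError, classify

TIER1, TIER2, TIER3, DONE = "tier1", "tier2", "tier3", "done"

#: Why a session ended.
TIER1_NEGATIVE = "tier1_negative"
TIER2_ALL_NEGATIVE = "tier2_all_negative"
COMPLETED = "completed"


class SessionError(RuntimeError):
    """Invalid interaction with a session (wrong items, wrong stage...)."""


@dataclass(frozen=True)
class DisorderOutcome:
    """Per-disorder outcome of one screening."""

    disorder: str
    gate_score: int | None       # Tier-2 short-form score, if reached
    gate_positive: bool | None
    full_score: int | None       # Tier-3 full-scale score (with carry-over)
    screen_positive: bool        # positive in all three tiers


@dataclass(frozen=True)
class ScreeningResult:
    session_id: str
    distress_score: int
    distress_positive: bool
    outcomes: Mapping[str, DisorderOutcome]   # keyed by disorder
    termination_reason: str
    items_administered: int

    def screen_positive(self, disorder: str) -> bool:
        return self.outcomes[disorder].screen_positive

    @property
    def any_positive(self) -> bool:
        return any(o.screen_positive for o in self.outcomes.values())

    def to_dict(self) -> dict:
        return {
            "session_id": self.session_id,
            "distress_score": self.distress_score,
            "distress_positive": self.distress_positive,
            "termination_reason": self.termination_reason,
            "items_administered": self.items_administered,
            "outcomes": {
                d: {
                    "gate_score": o.gate_score,
                    "gate_positive": o.gate_positive,
                    "full_score": o.full_score,
                    "screen_positive": o.screen_positive,
                }
                for d, o in self.outcomes.items()
            },
        }


class Session:
    """One respondent's adaptive pass through the battery."""

    def __init__(self, battery: Battery, session_id: str | None = None):
        if not battery.items:
            raise SessionError("cannot start a session on an empty battery")
        self.battery = battery
        self.session_id = session_id or uuid.uuid4().hex[:12]
        self.stage = TIER1
        self.responses: dict[str, int] = {}
        self.administered_item_ids: list[str] = []
        self.events: list[dict] = []
        self.tier_outcomes: dict[str, dict] = {}
        self.termination_reason: str | None = None
        self._pending: tuple[str, ...] = tuple(
            battery.scale(battery.tier1).item_ids
        )
        self._gated_full: tuple[str, ...] = ()

    # -- state ------------------------------------------------------------
    @property
    def done(self) -> bool:
        return self.stage == DONE

    def pending_items(self) -> tuple[str, ...]:
        """Items to present next, in battery-config order."""
        return self._pending

    # -- interaction ------------------------------------------------------
    def submit_responses(self, responses: Mapping[str, int]) -> "Session":
        """Record responses for exactly the pending items and advance."""
        if self.done:
            raise SessionError("session is finished; no further items pending")
        pending = set(self._pending)
        got = set(responses)
        if got != pending:
            extra = sorted(got - pending)
            missing = sorted(pending - got)
            raise SessionError(
                f"responses must cover exactly the pending items "
                f"(missing: {missing}, unexpected: {extra})"
            )
        for iid in self._pending:  # validate ranges before mutating anything
            item = self.battery.item(iid)
            if not item.in_range(int(responses[iid])):
                raise ScoringError(
                    f"item {iid!r}: value {responses[iid]} outside "
                    f"[{item.ordinal_min}, {item.ordinal_max}]"
                )
        tier = self.stage
        for iid in self._pending:
            value = int(responses[iid])
            self.responses[iid] = value
            self.administered_item_ids.append(iid)
            self.events.append({"tier": tier, "item_id": iid, "value": value})
        self._advance()
        return self

    def _advance(self) -> None:
        battery = self.battery
        if self.stage == TIER1:
            scale = battery.scale(battery.tier1)
            score = battery.score_scale(scale.scale_id, self.responses)
            positive = classify(score, scale.cutoff)
            self.tier_outcomes[scale.scale_id] = {
                "score": score, "positive": positive, "tier": 1,
            }
            if not positive:
                self.stage = DONE
                self.termination_reason = TIER1_NEGATIVE
                self._pending = ()
            else:
                self.stage = TIER2
                self._pending = tuple(
                    iid for sid in battery.tier2
                    for iid in battery.scale(sid).item_ids
                )
        elif self.stage == TIER2:
            gated: list[str] = []
            for sid in battery.tier2:
                scale = battery.scale(sid)
                score = battery.score_scale(sid, self.responses)
                positive = classify(score, scale.cutoff)
                self.tier_outcomes[sid] = {
                    "score": score, "positive": positive, "tier": 2,
                }
                if positive:
                    gated.append(battery.short_form_maps[sid].parent_scale_id)
            if not gated:
                self.stage = DONE
                self.termination_reason = TIER2_ALL_NEGATIVE
                self._pending = ()
            else:
                self.stage = TIER3
                self._gated_full = tuple(s for s in battery.tier3 if s in gated)
                self._pending = tuple(
                    iid for sid in self._gated_full
                    for iid in battery.tier3_remainder(sid)
                )
        elif self.stage == TIER3:
            for sid in self._gated_full:
                scale = battery.scale(sid)
                score = self.full_score_with_carryover(sid)
                self.tier_outcomes[sid] = {
                    "score": score,
                    "positive": classify(score, scale.cutoff),
                    "tier": 3,
                }
            self.stage = DONE
            self.termination_reason = COMPLETED
            self._pending = ()

    # -- scoring ----------------------------------------------------------
    def full_score_with_carryover(self, full_scale_id: str) -> int:
        """Full-scale score over Tier-2 carry-over plus Tier-3 remainder."""
        if full_scale_id not in self.battery.tier3:
            raise SessionError(f"{full_scale_id!r} is not a Tier-3 scale")
        scale = self.battery.scale(full_scale_id)
        missing = [i for i in scale.item_ids if i not in self.responses]
        if missing:
            raise SessionError(
                f"scale {full_scale_id!r} incomplete (missing {missing}); "
                "it was either not gated into Tier 3 or not yet answered"
            )
        return self.battery.score_scale(full_scale_id, self.responses)

    def finalize(self) -> ScreeningResult:
        """Summarise a finished session into a :class:`ScreeningResult`."""
        if not self.done:
            raise SessionError("session is not finished")
        battery = self.battery
        t1 = self.tier_outcomes[battery.tier1]
        outcomes: dict[str, DisorderOutcome] = {}
        for disorder in DISORDERS:
            gate = battery.gate_for(disorder)
            full = battery.full_for(disorder)
            g = self.tier_outcomes.get(gate.scale_id)
            f = self.tier_outcomes.get(full.scale_id)
            outcomes[disorder] = DisorderOutcome(
                disorder=disorder,
                gate_score=None if g is None else g["score"],
                gate_positive=None if g is None else g["positive"],
                full_score=None if f is None else f["score"],
                screen_positive=bool(
                    t1["positive"]
                    and g is not None and g["positive"]
                    and f is not None and f["positive"]
                ),
            )
        return ScreeningResult(
            session_id=self.session_id,
            distress_score=t1["score"],
            distress_positive=t1["positive"],
            outcomes=outcomes,
            termination_reason=self.termination_reason or COMPLETED,
            items_administered=len(self.administered_item_ids),
        )

    # -- persistence ------------------------------------------------------
    def to_json(self) -> str:
        doc = {
            "session_id": self.session_id,
            "battery_hash": self.battery.hash(),
            "events": self.events,
            "result": self.finalize().to_dict() if self.done else None,
        }
        return json.dumps(doc, indent=1, sort_keys=False)

    @classmethod
    def from_json(cls, battery: Battery, doc: str | Mapping) -> "Session":
        """Replay a session log against *battery* (hash must match)."""
        if isinstance(doc, str):
            doc = json.loads(doc)
        if doc.get("battery_hash") and doc["battery_hash"] != battery.hash():
            raise SessionError("session log was recorded under another battery")
        session = cls(battery, session_id=doc.get("session_id"))
        answers = {e["item_id"]: e["value"] for e in doc.get("events", [])}
        while not session.done and session.pending_items():
            chunk = {}
            for iid in session.pending_items():
                if iid not in answers:
                    raise SessionError(f"session log missing item {iid!r}")
                chunk[iid] = answers[iid]
            session.submit_responses(chunk)
        return session


# Functional faces over the Session object -------------------------------

def start_session(battery: Battery, session_id: str | None = None) -> Session:
    return Session(battery, session_id=session_id)


def submit_responses(session: Session, responses: Mapping[str, int]) -> Session:
    return session.submit_responses(responses)


def full_score_with_carryover(session: Session, full_scale_id: str) -> int:
    return session.full_score_with_carryover(full_scale_id)


def finalize(session: Session) -> ScreeningResult:
    return session.finalize()
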