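"""Retrospective tier simulation over complete response data.

Validation studies administer every item to every respondent and then ask
what the adaptive procedure *would* have done.  This module applies the
tier logic directly to a wide table of complete responses — an
implementation deliberately independent of the stateful engine, so the two
can be checked against each other — and accounts for the item burden and
the per-tier culling of respondents.

Item-burden baseline: the four full symptom scales without the Tier-1
distress screener (43 items in the default battery).  A respondent screened
out at Tier 1 answers 13 items, a 69.8% reduction; a respondent positive on
one gate with a 7-item full scale answers 27 items (37.2% reduction); a
respondent positive everywhere answers all 56 items, an *increased* burden.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from . import dta
from .engine import (
    COMPLETED, TIER1_NEGATIVE, TIER2_ALL_NEGATIVE,
    DisorderOutcome, ScreeningResult,
)
from .instruments import Battery, DISORDERS, ScoringError, classify
from ._util import round_half_up

log = logging.getLogger(__name__)


@dataclass
class ResponseDataset:
    """Wide table of complete item responses plus optional reference labels.

    ``responses``: one row per respondent (index = respondent id), one
    column per battery item.  ``labels``: boolean columns named after the
    canonical disorders (``depression, anxiety, ptsd, insomnia``).
    """

    responses: pd.DataFrame
    labels: pd.DataFrame | None = None

    @classmethod
    def from_frame(
        cls,
        responses: pd.DataFrame,
        battery: Battery,
        labels: pd.DataFrame | None = None,
        strict: bool = True,
    ) -> "ResponseDataset":
        """Validate a wide frame against the battery.

        In strict mode missing item columns, out-of-range values, missing
        values and duplicated ids are errors.  In permissive mode
        respondents with any missing/invalid item are dropped with a
        warning; nothing is ever imputed.
        """
        df = responses.copy()
        if df.index.has_duplicates:
            dupes = df.index[df.index.duplicated()].unique().tolist()
            raise ScoringError(f"duplicated respondent ids: {dupes}")
        wanted = list(battery.all_item_ids)
        missing_cols = [c for c in wanted if c not in df.columns]
        if missing_cols:
            raise ScoringError(f"missing item columns: {missing_cols}")
        extra = [c for c in df.columns if c not in wanted]
        if extra:
            warnings.warn(f"ignoring unknown columns: {extra}", stacklevel=2)
        df = df[wanted]

        bad_rows: set = set()
        for iid in wanted:
            item = battery.item(iid)
            col = pd.to_numeric(df[iid], errors="coerce")
            invalid = col.isna() | (col < item.ordinal_min) | (col > item.ordinal_max)
            if invalid.any():
                where = df.index[invalid].tolist()
                if strict:
                    raise ScoringError(
                        f"column {iid!r}: missing/out-of-range values for "
                        f"respondents {where[:5]} (range "
                        f"[{item.ordinal_min}, {item.ordinal_max}])"
                    )
                bad_rows.update(where)
            df[iid] = col
        if bad_rows:
            log.warning("dropping %d incomplete respondents: %s",
                        len(bad_rows), sorted(bad_rows)[:10])
            df = df.drop(index=sorted(bad_rows))
        df = df.astype(int)
        if labels is not None:
            labels = labels.loc[df.index, list(DISORDERS)].astype(bool)
        return cls(responses=df, labels=labels)

    @property
    def n(self) -> int:
        return len(self.responses)


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

def simulate_respondent(
    row: Mapping[str, int], battery: Battery, session_id: str
) -> ScreeningResult:
    """Tier logic applied directly to one complete response vector."""
    t1_scale = battery.scale(battery.tier1)
    t1_score = battery.score_scale(t1_scale.scale_id, row)
    t1_pos = classify(t1_score, t1_scale.cutoff)

    gate_scores: dict[str, int] = {}
    gate_pos: dict[str, bool] = {}
    if t1_pos:
        for sid in battery.tier2:
            gate = battery.scale(sid)
            gate_scores[gate.disorder] = battery.score_scale(sid, row)
            gate_pos[gate.disorder] = classify(gate_scores[gate.disorder],
                                               gate.cutoff)

    any_gate = any(gate_pos.values())
    items = len(t1_scale.item_ids)
    if t1_pos:
        items += battery.tier2_item_total
        if any_gate:
            for sid in battery.tier3:
                if gate_pos.get(battery.scale(sid).disorder, False):
                    items += len(battery.tier3_remainder(sid))

    outcomes: dict[str, DisorderOutcome] = {}
    for disorder in DISORDERS:
        full = battery.full_for(disorder)
        reached_t3 = t1_pos and any_gate and gate_pos.get(disorder, False)
        full_score = (battery.score_scale(full.scale_id, row)
                      if reached_t3 else None)
        outcomes[disorder] = DisorderOutcome(
            disorder=disorder,
            gate_score=gate_scores.get(disorder) if t1_pos else None,
            gate_positive=gate_pos.get(disorder) if t1_pos else None,
            full_score=full_score,
            screen_positive=bool(
                reached_t3 and classify(full_score, full.cutoff)
            ),
        )

    if not t1_pos:
        reason = TIER1_NEGATIVE
    elif not any_gate:
        reason = TIER2_ALL_NEGATIVE
    else:
        reason = COMPLETED
    return ScreeningResult(
        session_id=session_id,
        distress_score=t1_score,
        distress_positive=t1_pos,
        outcomes=outcomes,
        termination_reason=reason,
        items_administered=items,
    )


def simulate_tiered(
    dataset: ResponseDataset, battery: Battery
) -> dict[str, ScreeningResult]:
    """Apply the tiered procedure to every respondent of a complete dataset.

    Returns ``{respondent_id: ScreeningResult}``; results are identical to
    adaptively administering the same answers through the engine.
    """
    results = {}
    for rid, row in dataset.responses.iterrows():
        results[str(rid)] = simulate_respondent(row.to_dict(), battery, str(rid))
    return results


def results_frame(results: Mapping[str, ScreeningResult]) -> pd.DataFrame:
    """Flatten screening results into one row per respondent."""
    rows = []
    for rid, res in results.items():
        row: dict = {
            "id": rid,
            "distress_score": res.distress_score,
            "termination_reason": res.termination_reason,
            "items_administered": res.items_administered,
        }
        for d in DISORDERS:
            o = res.outcomes[d]
            row[f"{d}_gate_score"] = o.gate_score
            row[f"{d}_full_score"] = o.full_score
            row[f"{d}_positive"] = o.screen_positive
        row["any_positive"] = res.any_positive
        rows.append(row)
    return pd.DataFrame(rows).set_index("id")


# ---------------------------------------------------------------------------
# Item burden
# ---------------------------------------------------------------------------

def item_burden(result: ScreeningResult) -> int:
    """Number of items the respondent actually answered."""
    return result.items_administered


def burden_reduction(result: ScreeningResult, battery: Battery) -> float:
    """Percentage reduction in item burden vs the full-scale baseline.

    Baseline is the summed length of the Tier-3 full scales (43 by
    default); negative values mean the tiering *increased* the burden.
    Reported to one decimal, round half up.
    """
    baseline = battery.full_scale_item_total
    return round_half_up((1.0 - result.items_administered / baseline) * 100.0, 1)


# ---------------------------------------------------------------------------
# Culling report
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TierCull:
    """Continuation decision at one tier.

    ``decisions`` holds, per disorder and for ``"any"``, the confusion
    table of *continue* (index positive) against the reference label,
    restricted to respondents entering the tier.
    """

    tier: int
    entered: int
    continued: int
    terminated: int
    decisions: Mapping[str, dta.ConfusionTable] = field(default_factory=dict)


@dataclass(frozen=True)
class CullingReport:
    n: int
    tiers: tuple[TierCull, ...]
    baseline_items: int

    def tier(self, k: int) -> TierCull:
        for t in self.tiers:
            if t.tier == k:
                return t
        raise KeyError(k)


def culling_report(
    dataset: ResponseDataset,
    battery: Battery,
    results: Mapping[str, ScreeningResult] | None = None,
) -> CullingReport:
    """Per-tier exclusion accounting (with label confusion when available).

    Tier 1's decision is continue/terminate for everyone; Tier 2's is the
    per-disorder gate among Tier-1 positives (``any`` = any gate positive);
    Tier 3's is the final severity call among gated respondents.
    """
    if results is None:
        results = simulate_tiered(dataset, battery)
    labels = dataset.labels
    ids = [str(i) for i in dataset.responses.index]
    res = [results[i] for i in ids]

    def _conf(pairs: Iterable[tuple[bool, bool]]) -> dta.ConfusionTable | None:
        pairs = list(pairs)
        if not pairs:
            return None
        return dta.ConfusionTable(
            tp=sum(1 for t, l in pairs if t and l),
            fp=sum(1 for t, l in pairs if t and not l),
            fn=sum(1 for t, l in pairs if not t and l),
            tn=sum(1 for t, l in pairs if not t and not l),
        )

    def _label(rid: str, disorder: str) -> bool:
        return bool(labels.loc[rid, disorder]) if labels is not None else False

    def _any_label(rid: str) -> bool:
        return any(_label(rid, d) for d in DISORDERS)

    tiers: list[TierCull] = []

    # Tier 1: everyone enters; continue iff distress positive
    t1_pairs = {"any": [(r.distress_positive, _any_label(r.session_id))
                        for r in res]}
    for d in DISORDERS:
        t1_pairs[d] = [(r.distress_positive, _label(r.session_id, d))
                       for r in res]
    t1_cont = sum(1 for r in res if r.distress_positive)
    tiers.append(TierCull(
        tier=1, entered=len(res), continued=t1_cont,
        terminated=len(res) - t1_cont,
        decisions={k: c for k, v in t1_pairs.items()
                   if labels is not None and (c := _conf(v)) is not None},
    ))

    # Tier 2: Tier-1 positives enter; continue iff any gate positive
    entered2 = [r for r in res if r.distress_positive]
    t2_cont = sum(1 for r in entered2
                  if any(o.gate_positive for o in r.outcomes.values()))
    t2_dec: dict[str, dta.ConfusionTable] = {}
    if labels is not None and entered2:
        for d in DISORDERS:
            t2_dec[d] = _conf(
                (bool(r.outcomes[d].gate_positive), _label(r.session_id, d))
                for r in entered2
            )
        t2_dec["any"] = _conf(
            (any(bool(o.gate_positive) for o in r.outcomes.values()),
             _any_label(r.session_id))
            for r in entered2
        )
    tiers.append(TierCull(
        tier=2, entered=len(entered2), continued=t2_cont,
        terminated=len(entered2) - t2_cont, decisions=t2_dec,
    ))

    # Tier 3: gated respondents enter per disorder; decision = final call
    t3_dec: dict[str, dta.ConfusionTable] = {}
    entered3 = [r for r in entered2
                if any(o.gate_positive for o in r.outcomes.values())]
    if labels is not None and entered3:
        for d in DISORDERS:
            gated = [r for r in entered3 if r.outcomes[d].gate_positive]
            conf = _conf((r.outcomes[d].screen_positive,
                          _label(r.session_id, d)) for r in gated)
            if conf is not None:
                t3_dec[d] = conf
        t3_any = _conf((r.any_positive, _any_label(r.session_id))
                       for r in entered3)
        if t3_any is not None:
            t3_dec["any"] = t3_any
    t3_cont = sum(1 for r in entered3 if r.any_positive)
    tiers.append(TierCull(
        tier=3, entered=len(entered3), continued=t3_cont,
        terminated=len(entered3) - t3_cont, decisions=t3_dec,
    ))

    return CullingReport(n=len(res), tiers=tuple(tiers),
                         baseline_items=battery.full_scale_item_total)
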