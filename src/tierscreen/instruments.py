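"""Symptom scales, scoring, and scale-level psychometrics.

The screening battery is built from five validated Likert symptom scales:
the Refugee Health Screener (RHS-13, general distress), PHQ-9 (depression),
GAD-7 (anxiety), PCL-5 (post-traumatic stress) and ISI-7 (insomnia).  Each
full scale has an embedded short form whose items gate access to the rest
of the scale; scale scores are plain item sums (no reverse coding) that are
dichotomised at a published cutoff (positive iff score >= cutoff).

Everything about the battery — items, response ranges, tier membership,
short-form maps, cutoffs — is configuration, loaded from a YAML/JSON
document and validated here.  ``default_battery()`` returns the shipped
configuration.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

#: Canonical disorder names used throughout the package.  ``distress`` is the
#: Tier-1 construct and is not itself a screening outcome.
DISORDERS = ("depression", "anxiety", "ptsd", "insomnia")
CONSTRUCTS = ("distress",) + DISORDERS


class BatteryConfigError(ValueError):
    """Raised when a battery configuration violates its invariants."""


class ScoringError(ValueError):
    """Raised on missing or out-of-range item responses."""


@dataclass(frozen=True)
class Item:
    item_id: str
    scale_id: str
    ordinal_min: int
    ordinal_max: int
    text_key: str = ""

    def __post_init__(self) -> None:
        if self.ordinal_min >= self.ordinal_max:
            raise BatteryConfigError(
                f"item {self.item_id!r}: ordinal_min must be < ordinal_max"
            )

    def in_range(self, value: int) -> bool:
        return self.ordinal_min <= value <= self.ordinal_max


@dataclass(frozen=True)
class Scale:
    scale_id: str
    item_ids: tuple[str, ...]
    score_min: int
    score_max: int
    cutoff: int
    disorder: str

    def __post_init__(self) -> None:
        if self.disorder not in CONSTRUCTS:
            raise BatteryConfigError(
                f"scale {self.scale_id!r}: unknown disorder {self.disorder!r}"
            )
        if not self.score_min <= self.cutoff <= self.score_max:
            raise BatteryConfigError(
                f"scale {self.scale_id!r}: cutoff {self.cutoff} outside score "
                f"range [{self.score_min}, {self.score_max}]"
            )


@dataclass(frozen=True)
class ShortFormMap:
    """Embedding of a short (gate) scale inside its parent full scale."""

    short_scale_id: str
    parent_scale_id: str
    item_ids: tuple[str, ...]


@dataclass(frozen=True)
class Battery:
    """A validated tiered battery: items, scales, tier membership, maps."""

    items: Mapping[str, Item]
    scales: Mapping[str, Scale]
    tier1: str
    tier2: tuple[str, ...]
    tier3: tuple[str, ...]
    short_form_maps: Mapping[str, ShortFormMap]  # keyed by short scale id
    name: str = "battery"
    config: Mapping = field(default_factory=dict, repr=False)

    # -- lookups ----------------------------------------------------------
    def scale(self, scale_id: str) -> Scale:
        try:
            return self.scales[scale_id]
        except KeyError:
            raise BatteryConfigError(f"unknown scale {scale_id!r}") from None

    def item(self, item_id: str) -> Item:
        try:
            return self.items[item_id]
        except KeyError:
            raise ScoringError(f"unknown item {item_id!r}") from None

    def map_for_full(self, full_scale_id: str) -> ShortFormMap | None:
        for m in self.short_form_maps.values():
            if m.parent_scale_id == full_scale_id:
                return m
        return None

    def gate_for(self, disorder: str) -> Scale:
        """The Tier-2 short scale screening for *disorder*."""
        for sid in self.tier2:
            if self.scales[sid].disorder == disorder:
                return self.scales[sid]
        raise BatteryConfigError(f"no Tier-2 scale for disorder {disorder!r}")

    def full_for(self, disorder: str) -> Scale:
        """The Tier-3 full scale screening for *disorder*."""
        for sid in self.tier3:
            if self.scales[sid].disorder == disorder:
                return self.scales[sid]
        raise BatteryConfigError(f"no Tier-3 scale for disorder {disorder!r}")

    def tier3_remainder(self, full_scale_id: str) -> tuple[str, ...]:
        """Items of a full scale not already administered in Tier 2."""
        full = self.scale(full_scale_id)
        m = self.map_for_full(full_scale_id)
        carried = set(m.item_ids) if m else set()
        return tuple(i for i in full.item_ids if i not in carried)

    # -- global counts ----------------------------------------------------
    @property
    def all_item_ids(self) -> tuple[str, ...]:
        return tuple(self.items)

    @property
    def n_items(self) -> int:
        return len(self.items)

    @property
    def full_scale_item_total(self) -> int:
        """Item count over the Tier-3 full scales (the burden baseline)."""
        return sum(len(self.scales[s].item_ids) for s in self.tier3)

    @property
    def tier2_item_total(self) -> int:
        return sum(len(self.scales[s].item_ids) for s in self.tier2)

    # -- scoring ----------------------------------------------------------
    def score_scale(self, scale_id: str, responses: Mapping[str, int]) -> int:
        return score_scale(responses, self.scale(scale_id), self.items)

    def classify_scale(self, scale_id: str, responses: Mapping[str, int]) -> bool:
        scale = self.scale(scale_id)
        return classify(self.score_scale(scale_id, responses), scale.cutoff)

    # -- provenance -------------------------------------------------------
    def hash(self) -> str:
        """Stable digest of the configuration, for session logs."""
        doc = json.dumps(_canonical_config(self), sort_keys=True)
        return hashlib.sha256(doc.encode()).hexdigest()[:16]


def _canonical_config(battery: Battery) -> dict:
    return {
        "name": battery.name,
        "items": [
            [i.item_id, i.scale_id, i.ordinal_min, i.ordinal_max]
            for i in battery.items.values()
        ],
        "scales": [
            [s.scale_id, list(s.item_ids), s.cutoff, s.disorder]
            for s in battery.scales.values()
        ],
        "tiers": [battery.tier1, list(battery.tier2), list(battery.tier3)],
        "maps": [
            [m.short_scale_id, m.parent_scale_id, list(m.item_ids)]
            for m in battery.short_form_maps.values()
        ],
    }


# ---------------------------------------------------------------------------
# Battery loading
# ---------------------------------------------------------------------------

def load_battery(config: Mapping | str | Path) -> Battery:
    """Build and validate a :class:`Battery` from a config document.

    ``config`` may be a mapping, or a path to a YAML/JSON file with keys
    ``scales``, ``items``, ``tiers`` and ``maps``.
    """
    if isinstance(config, (str, Path)):
        with open(config, "r", encoding="utf-8") as fh:
            config = yaml.safe_load(fh)
    if not isinstance(config, Mapping):
        raise BatteryConfigError("battery config must be a mapping")

    items: dict[str, Item] = {}
    for spec in config.get("items", []):
        item = Item(
            item_id=str(spec["item_id"]),
            scale_id=str(spec["scale_id"]),
            ordinal_min=int(spec["min"]),
            ordinal_max=int(spec["max"]),
            text_key=str(spec.get("text_key", "")),
        )
        if item.item_id in items:
            raise BatteryConfigError(f"duplicate item id {item.item_id!r}")
        items[item.item_id] = item
    if not items:
        raise BatteryConfigError("battery config declares no items")

    scales: dict[str, Scale] = {}
    for spec in config.get("scales", []):
        sid = str(spec["scale_id"])
        item_ids = tuple(str(i) for i in spec["items"])
        if len(set(item_ids)) != len(item_ids):
            raise BatteryConfigError(f"scale {sid!r}: repeated item ids")
        for iid in item_ids:
            if iid not in items:
                raise BatteryConfigError(f"scale {sid!r}: unknown item {iid!r}")
        lo = sum(items[i].ordinal_min for i in item_ids)
        hi = sum(items[i].ordinal_max for i in item_ids)
        if sid in scales:
            raise BatteryConfigError(f"duplicate scale id {sid!r}")
        scales[sid] = Scale(
            scale_id=sid, item_ids=item_ids, score_min=lo, score_max=hi,
            cutoff=int(spec["cutoff"]), disorder=str(spec["disorder"]),
        )

    tiers = config.get("tiers", {})
    try:
        tier1_ids = [str(s) for s in tiers[1]] if 1 in tiers else [str(s) for s in tiers["1"]]
        tier2 = tuple(str(s) for s in (tiers.get(2) or tiers["2"]))
        tier3 = tuple(str(s) for s in (tiers.get(3) or tiers["3"]))
    except KeyError as exc:
        raise BatteryConfigError(f"tiers config missing tier {exc}") from None
    if len(tier1_ids) != 1:
        raise BatteryConfigError("Tier 1 must contain exactly one scale")
    tier1 = tier1_ids[0]
    for sid in [tier1, *tier2, *tier3]:
        if sid not in scales:
            raise BatteryConfigError(f"tier references unknown scale {sid!r}")

    maps: dict[str, ShortFormMap] = {}
    for spec in config.get("maps", []):
        m = ShortFormMap(
            short_scale_id=str(spec["short"]),
            parent_scale_id=str(spec["parent"]),
            item_ids=tuple(str(i) for i in spec["items"]),
        )
        parent = scales.get(m.parent_scale_id)
        short = scales.get(m.short_scale_id)
        if parent is None or short is None:
            raise BatteryConfigError(
                f"map {m.short_scale_id!r}->{m.parent_scale_id!r}: unknown scale"
            )
        for iid in m.item_ids:
            if iid not in parent.item_ids:
                raise BatteryConfigError(
                    f"short form {m.short_scale_id!r}: item {iid!r} does not "
                    f"belong to parent scale {m.parent_scale_id!r}"
                )
        if tuple(short.item_ids) != m.item_ids:
            raise BatteryConfigError(
                f"short form {m.short_scale_id!r}: scale items differ from map"
            )
        maps[m.short_scale_id] = m

    for sid in tier2:
        if sid not in maps:
            raise BatteryConfigError(f"Tier-2 scale {sid!r} has no short-form map")
        if maps[sid].parent_scale_id not in tier3:
            raise BatteryConfigError(
                f"Tier-2 scale {sid!r} maps to a non-Tier-3 parent"
            )

    battery = Battery(
        items=items, scales=scales, tier1=tier1, tier2=tier2, tier3=tier3,
        short_form_maps=maps, name=str(config.get("name", "battery")),
        config=dict(config),
    )
    # distinct-item accounting: every item belongs to exactly one owning scale
    owned = set()
    for sid in [tier1, *tier3]:
        owned.update(scales[sid].item_ids)
    if owned != set(items):
        raise BatteryConfigError("items exist outside the Tier-1/Tier-3 scales")
    return battery


def default_battery() -> Battery:
    """The shipped battery: RHS-13 gateway, four gated symptom scales."""
    ref = resources.files("tierscreen").joinpath("itap_default.yaml")
    return load_battery(yaml.safe_load(ref.read_text(encoding="utf-8")))


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

def score_scale(
    responses: Mapping[str, int], scale: Scale, items: Mapping[str, Item]
) -> int:
    """Sum-score a scale from an ``item_id -> value`` map.

    Every item of the scale must be present and within its ordinal range;
    no imputation is ever performed.
    """
    total = 0
    for iid in scale.item_ids:
        if iid not in responses:
            raise ScoringError(f"scale {scale.scale_id!r}: missing item {iid!r}")
        value = int(responses[iid])
        item = items[iid]
        if not item.in_range(value):
            raise ScoringError(
                f"item {iid!r}: value {value} outside "
                f"[{item.ordinal_min}, {item.ordinal_max}]"
            )
        total += value
    return total


def classify(score: int, cutoff: int) -> bool:
    """Dichotomise a score: positive iff ``score >= cutoff``."""
    return score >= cutoff


# ---------------------------------------------------------------------------
# Psychometrics
# ---------------------------------------------------------------------------

def cronbach_alpha(matrix) -> float:
    """Cronbach's alpha for a respondents x items score matrix.

    alpha = k/(k-1) * (1 - sum(item variances) / variance(total score)),
    with sample (n-1 denominator) variances throughout.

    Raises :class:`ScoringError` if the total-score variance is zero
    (alpha undefined) or the matrix is smaller than 2x2.
    """
    arr = np.asarray(matrix, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ScoringError("cronbach_alpha needs >= 2 respondents and >= 2 items")
    k = arr.shape[1]
    item_var = arr.var(axis=0, ddof=1)
    total_var = arr.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ScoringError("cronbach_alpha undefined: zero total-score variance")
    return float(k / (k - 1) * (1.0 - item_var.sum() / total_var))


def scale_scores(responses: pd.DataFrame, battery: Battery,
                 scale_ids: Iterable[str] | None = None) -> pd.DataFrame:
    """Per-respondent sum scores for the given scales (default: all full)."""
    if scale_ids is None:
        scale_ids = (battery.tier1, *battery.tier3)
    out = {}
    for sid in scale_ids:
        scale = battery.scale(sid)
        missing = [i for i in scale.item_ids if i not in responses.columns]
        if missing:
            raise ScoringError(f"scale {sid!r}: missing columns {missing}")
        out[sid] = responses[list(scale.item_ids)].sum(axis=1).astype(int)
    return pd.DataFrame(out, index=responses.index)


def scale_correlations(responses: pd.DataFrame, battery: Battery) -> pd.DataFrame:
    """Pearson correlations between the Tier-1 and full-scale sum scores.

    A zero-variance scale yields NaN entries off the diagonal (flagged by
    pandas semantics); the diagonal is always 1 for scored scales.
    """
    scores = scale_scores(responses, battery)
    corr = scores.corr(method="pearson")
    varying = scores.std(ddof=1) > 0
    for sid in scores.columns[varying]:
        corr.loc[sid, sid] = 1.0
    return corr
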