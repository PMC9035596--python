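"""Cell-type labeling of attractors from marker-node activity.

Over an attractor each node is *active* (1 in every cycle state), *inactive*
(0 in every cycle state) or *oscillating* (both occur; only possible for
cycles).  A label rule demands a set of markers active and a set inactive;
rules are tried in priority order and the first match wins.  An oscillating
marker satisfies a require-active constraint (the pathway fires during the
cycle) but violates a require-inactive one.  Cyclic attractors carry the same
base labels as steady states plus a ``*`` suffix, kept separate from the base
label so downstream statistics can compare either convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .attractors import Attractor, AttractorSet
from .network import BooleanNetwork

ACTIVE = "active"
INACTIVE = "inactive"
OSCILLATING = "oscillating"


@dataclass(frozen=True)
class ActivitySummary:
    """Per-node activity over one attractor, plus the cycle period."""

    activities: tuple[tuple[str, str], ...]
    period: int

    def as_dict(self) -> dict[str, str]:
        return dict(self.activities)

    def __getitem__(self, node: str) -> str:
        return self.as_dict()[node]


@dataclass(frozen=True)
class LabelRule:
    """One marker pattern: label wins if all markers match.

    Rules are applied most-specific-first; ``priority`` is informational (the
    ordered rule list is authoritative).  A rule with empty requirement sets
    matches everything and serves as the fallback.
    """

    label: str
    require_active: frozenset = frozenset()
    require_inactive: frozenset = frozenset()
    priority: int = 0

    def __post_init__(self):
        object.__setattr__(self, "require_active", frozenset(self.require_active))
        object.__setattr__(self, "require_inactive", frozenset(self.require_inactive))
        if self.require_active & self.require_inactive:
            raise ValueError(
                f"rule {self.label!r}: markers required both active and inactive"
            )

    def matches(self, summary: ActivitySummary) -> bool:
        acts = summary.as_dict()
        for node in self.require_active:
            if acts.get(node, INACTIVE) == INACTIVE:
                return False
        for node in self.require_inactive:
            if acts.get(node, INACTIVE) != INACTIVE:
                return False
        return True


@dataclass(frozen=True)
class CellTypeLabel:
    """A base cell-type label with the cyclic ('*') flag carried separately."""

    base: str
    cyclic: bool = False

    def __str__(self) -> str:
        return self.base + ("*" if self.cyclic else "")

    @property
    def starred(self) -> str:
        return str(self)


def summarize_activity(attractor: Attractor,
                       network: BooleanNetwork) -> ActivitySummary:
    """Reduce an attractor's cycle states to per-node activity calls."""
    ones = 0
    zeros = 0
    mask = (1 << network.n) - 1
    for s in attractor.states:
        ones |= s
        zeros |= (~s) & mask
    acts = []
    for i, node in enumerate(network.nodes):
        has1 = (ones >> i) & 1
        has0 = (zeros >> i) & 1
        if has1 and has0:
            acts.append((node, OSCILLATING))
        elif has1:
            acts.append((node, ACTIVE))
        else:
            acts.append((node, INACTIVE))
    return ActivitySummary(tuple(acts), attractor.period)


def label_attractor(summary: ActivitySummary,
                    rules: list[LabelRule]) -> CellTypeLabel:
    """First matching rule wins; the cyclic flag reflects the period."""
    if not rules:
        raise ValueError("empty label-rule list")
    cyclic = summary.period > 1
    for rule in rules:
        if rule.matches(summary):
            return CellTypeLabel(rule.label, cyclic)
    return CellTypeLabel("unlabeled", cyclic)


def label_set(attractor_set: AttractorSet, rules: list[LabelRule],
              network: BooleanNetwork) -> pd.DataFrame:
    """One row per attractor: id, scope, period, basin, activity, label."""
    rows = []
    for i, a in enumerate(attractor_set):
        summary = summarize_activity(a, network)
        lab = label_attractor(summary, rules)
        env = a.scope_dict
        rows.append({
            "attractor_id": i,
            "environment": ";".join(f"{k}={v}" for k, v in sorted(env.items())),
            "period": a.period,
            "basin_size": a.basin_size,
            "base_label": lab.base,
            "label": str(lab),
        })
    df = pd.DataFrame(
        rows, columns=["attractor_id", "environment", "period", "basin_size",
                       "base_label", "label"],
    )
    return df


def aggregate_basins(labels: pd.DataFrame, by: str = "base_label") -> pd.Series:
    """Combined basin size per label, largest first."""
    if labels.empty:
        return pd.Series(dtype=int)
    return labels.groupby(by)["basin_size"].sum().sort_values(ascending=False)


def rules_to_table(rules: list[LabelRule]) -> pd.DataFrame:
    return pd.DataFrame(
        [{
            "label": r.label,
            "require_active": " ".join(sorted(r.require_active)),
            "require_inactive": " ".join(sorted(r.require_inactive)),
            "priority": r.priority,
        } for r in rules]
    )


def rules_from_table(df: pd.DataFrame) -> list[LabelRule]:
    """Read rules from a table with columns label / require_active /
    require_inactive / priority (marker lists whitespace-separated)."""
    rules = []
    for _, row in df.iterrows():
        def _split(v):
            if v is None or (isinstance(v, float) and pd.isna(v)):
                return frozenset()
            return frozenset(str(v).split())
        rules.append(LabelRule(
            label=str(row["label"]),
            require_active=_split(row.get("require_active")),
            require_inactive=_split(row.get("require_inactive")),
            priority=int(row.get("priority", 0) or 0),
        ))
    rules.sort(key=lambda r: -r.priority)
    return rules
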