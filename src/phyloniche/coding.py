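"""Discrete tip-state coding: convert per-species niche-cluster locality
counts into A/B/C character states (possibly polymorphic) and account for
species frequencies per state.

The majority/one-third rule: a species' primary state is the niche holding
the most of its localities (ties keep all tied states), and any further
state holding at least one third of the localities is added, making the tip
polymorphic.  A packaged reference dataset (Madagascan *Bulbophyllum* clade
C and outgroups, 33 species) ships both the per-niche locality counts and
the published state codes; for a handful of species the published codes
deviate from the mechanical rule, so the published codes are applied as
overrides and every rule/override disagreement is reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .core_io import STATES

ONE_THIRD = 1.0 / 3.0


@dataclass
class TipStateCoding:
    """Per-species counts, the coded state set, and its provenance."""

    species: str
    counts: tuple[int, int, int]
    states: frozenset
    source: str = "rule"          # "rule" | "override"

    def __post_init__(self):
        if sum(self.counts) < 1:
            raise ValueError("total locality count must be >= 1")
        if not self.states or not self.states <= set(STATES):
            raise ValueError("coded states must be a non-empty subset of {A,B,C}")


def code_tip_state(counts) -> frozenset:
    """Apply the majority/one-third rule to (n_A, n_B, n_C)."""
    counts = tuple(int(c) for c in counts)
    if any(c < 0 for c in counts):
        raise ValueError("counts must be non-negative")
    total = sum(counts)
    if total == 0:
        raise ValueError("all-zero counts")
    top = max(counts)
    states = {s for s, c in zip(STATES, counts) if c == top}
    states |= {s for s, c in zip(STATES, counts) if c > 0 and c / total >= ONE_THIRD}
    return frozenset(states)


def apply_coding(counts_table: pd.DataFrame,
                 overrides: dict[str, frozenset] | None = None
                 ) -> tuple[list[TipStateCoding], pd.DataFrame]:
    """Code every species in a counts table, applying optional overrides.

    ``counts_table`` needs columns ``species, n_A, n_B, n_C`` (unique
    species).  Overrides replace the rule's output and are marked
    ``source="override"``.  Returns the codings and a discrepancy report
    listing species where an override differs from the rule.
    """
    if counts_table["species"].duplicated().any():
        raise ValueError("species must be unique")
    overrides = overrides or {}
    unknown = set(overrides) - set(counts_table["species"])
    if unknown:
        raise ValueError(f"override for unknown species: {sorted(unknown)}")
    codings, rows = [], []
    for _, row in counts_table.iterrows():
        counts = (row["n_A"], row["n_B"], row["n_C"])
        rule = code_tip_state(counts)
        sp = row["species"]
        if sp in overrides:
            states = frozenset(overrides[sp])
            codings.append(TipStateCoding(sp, counts, states, "override"))
            if states != rule:
                rows.append({"species": sp, "rule": states_str(rule),
                             "override": states_str(states)})
        else:
            codings.append(TipStateCoding(sp, counts, rule))
    report = pd.DataFrame(rows, columns=["species", "rule", "override"])
    return codings, report


def state_frequencies(codings: list[TipStateCoding]) -> dict[str, float]:
    """Species-frequency mass per state: each species contributes
    1/|coded states| to each of its states; the masses sum to the number of
    species."""
    if not codings:
        raise ValueError("need at least one species")
    freq = dict.fromkeys(STATES, 0.0)
    for c in codings:
        w = 1.0 / len(c.states)
        for s in c.states:
            freq[s] += w
    return freq


def states_str(states) -> str:
    return "".join(s for s in STATES if s in states)


def parse_states(text: str) -> frozenset:
    """Parse "AC" or "A|C" style state strings."""
    states = frozenset(text.replace("|", ""))
    if not states or not states <= set(STATES):
        raise ValueError(f"invalid state string {text!r}")
    return states


# ---------------------------------------------------------------------------
# Packaged reference dataset
# ---------------------------------------------------------------------------

def load_reference_counts() -> pd.DataFrame:
    """The packaged per-species niche-state locality counts and published
    codes for Madagascan *Bulbophyllum* clade C plus three outgroups
    (33 species).

    A few digit groupings in the source table are typographically ambiguous;
    this transcription adopts, for each species, the reading consistent with
    its published code.  Published codes are authoritative for downstream
    state-frequency and ancestral-state work.
    """
    path = resources.files("phyloniche.data") / "bulbophyllum_niche_counts.csv"
    with resources.as_file(path) as p:
        return pd.read_csv(p)


def reference_codings() -> tuple[list[TipStateCoding], pd.DataFrame]:
    """Code the packaged dataset with its published codes as overrides."""
    table = load_reference_counts()
    overrides = {row["species"]: parse_states(row["printed_code"])
                 for _, row in table.iterrows()}
    return apply_coding(table, overrides)
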