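"""Biological interpretation of per-variant and per-reference rates.

Turns background-subtracted mutation rates into calls: which tRNAs are
enzyme substrates, which single-point variants lose methyl-group
acceptance activity, and which positions and structural elements of the
tRNA are critical for enzyme recognition.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .trna import AnnotatedTRNA, RNA_BASES, VariantLibrary

#: a variant below this background-subtracted rate has lost activity
DEFAULT_LOSS_THRESHOLD = 0.05

#: a reference above this background-subtracted rate is a substrate
DEFAULT_SUBSTRATE_THRESHOLD = 0.01


@dataclass(frozen=True)
class SubstrateCall:
    reference_id: str
    target_rate: float | None
    is_substrate: bool

    @property
    def analyzable(self) -> bool:
        return self.target_rate is not None


def classify_variants(
    library: VariantLibrary,
    subtracted_rates: Mapping[str, float | None],
    loss_threshold: float = DEFAULT_LOSS_THRESHOLD,
) -> pd.DataFrame:
    """Classify every variant's methyl-group acceptance activity.

    A variant with a defined subtracted rate strictly below
    ``loss_threshold`` is classified ``lost``; at or above, ``retained``;
    rates flagged undefined (None/NaN) give ``undefined``.  Rows are
    ordered by position index, then substituted base (A < C < G < U).
    """
    rows = []
    parent = library.parent
    for v in library.variants:
        rate = subtracted_rates.get(v.name)
        if rate is None or pd.isna(rate):
            cls, rate_out = "undefined", float("nan")
        elif rate < loss_threshold:
            cls, rate_out = "lost", float(rate)
        else:
            cls, rate_out = "retained", float(rate)
        rows.append(
            {
                "variant": v.name,
                "position_label": v.position_label,
                "element": parent.elements.get(v.position_label, ""),
                "subtracted_rate": rate_out,
                "activity_class": cls,
                "_pos": parent.label_index(v.position_label),
                "_base": RNA_BASES.index(v.new_base),
            }
        )
    table = (
        pd.DataFrame(rows)
        .sort_values(["_pos", "_base"], kind="stable")
        .drop(columns=["_pos", "_base"])
        .reset_index(drop=True)
    )
    return table


def call_substrates(
    target_rates: Mapping[str, float | None],
    threshold: float = DEFAULT_SUBSTRATE_THRESHOLD,
) -> list[SubstrateCall]:
    """Call substrate tRNAs from background-subtracted target-position rates.

    A reference is a substrate when its rate is defined and strictly above
    ``threshold``; references with undefined rates (depth below the floor)
    are reported as not analyzable and never called.
    """
    calls = []
    for rid in sorted(target_rates):
        rate = target_rates[rid]
        if rate is None or pd.isna(rate):
            calls.append(SubstrateCall(reference_id=rid, target_rate=None, is_substrate=False))
        else:
            calls.append(
                SubstrateCall(
                    reference_id=rid, target_rate=float(rate), is_substrate=rate > threshold
                )
            )
    return calls


def summarize_elements(table: pd.DataFrame, trna: AnnotatedTRNA) -> pd.DataFrame:
    """Summarize activity loss per structural element.

    Per element: counts of lost/retained/undefined variants, the positions
    where at least one substitution is lost (``sensitive``), and the
    positions where all three substitutions are lost (``critical`` — the
    strongest evidence that the wild-type nucleotide is required for
    enzyme recognition).  Row order of the input table is irrelevant.
    """
    for label in table["position_label"]:
        trna.label_index(label)  # raises on unknown labels
    elements = sorted(set(trna.elements.values()))
    rows = []
    for element in elements:
        sub = table[
            [trna.elements.get(l) == element for l in table["position_label"]]
        ]
        sensitive, critical = [], []
        for label, grp in sub.groupby("position_label", sort=False):
            n_lost = int((grp["activity_class"] == "lost").sum())
            if n_lost >= 1:
                sensitive.append(label)
            if n_lost == len(grp) and len(grp) == 3:
                critical.append(label)
        order = trna.label_index
        rows.append(
            {
                "element": element,
                "n_lost": int((sub["activity_class"] == "lost").sum()),
                "n_retained": int((sub["activity_class"] == "retained").sum()),
                "n_undefined": int((sub["activity_class"] == "undefined").sum()),
                "sensitive_positions": ",".join(sorted(sensitive, key=order)),
                "critical_positions": ",".join(sorted(critical, key=order)),
            }
        )
    return pd.DataFrame(rows)


def critical_positions(table: pd.DataFrame, trna: AnnotatedTRNA) -> list[str]:
    """Positions where all three substitutions lose activity, in 5'->3' order."""
    summary = summarize_elements(table, trna)
    labels: list[str] = []
    for cell in summary["critical_positions"]:
        if cell:
            labels.extend(cell.split(","))
    return sorted(labels, key=trna.label_index)


def n1_to_methyl_distance(
    n1_to_sulfur: float = 9.4, methyl_to_sulfur: float = 1.8
) -> float:
    """Estimated gap between the target N1 atom and the donor methyl group.

    In a docked enzyme-tRNA model the distance from the substrate N1 to the
    cofactor sulfur, minus the S-CH3 bond length, estimates how far the
    methyl group sits from its acceptor (in Å) — a proxy for how much
    conformational change the methyl transfer still requires.
    """
    if n1_to_sulfur <= 0 or methyl_to_sulfur <= 0:
        raise ValueError("distances must be positive")
    return n1_to_sulfur - methyl_to_sulfur
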