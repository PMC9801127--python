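"""Exact-sequence-match quantification for low-diversity variant libraries.

Alignment-based mutation calling is unreliable when library members differ
by a single base: a read is near-equidistant from many references.  For a
single-point variant library the unambiguous alternative is exact
counting: for each variant, build the four full-length sequences carrying
A, C, G or U at the monitored target position, and count reads containing
each one verbatim.  The per-variant mutation rate is then

    M_rate = Read_Mutant / Read_Total

where ``Read_Total`` is the summed count over the four target bases and
``Read_Mutant`` the count over the three non-wild-type bases.  Treated and
untreated samples are quantified independently and the final rate is the
clamped difference.  Exact matching drops reads with any sequencing error
inside the query, which lowers ``Read_Total`` but — errors being
position-independent — leaves ``M_rate`` unbiased.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .simulate import SimulatedRead
from .trna import AnnotatedTRNA, RNA_BASES, Variant, VariantLibrary, rna_to_dna


@dataclass(frozen=True)
class MRateResult:
    """Target-position base counts and mutation rate of one library member."""

    variant_name: str
    wt_base: str
    read_counts: Mapping[str, int]  # RNA base at target position -> read count
    sample_role: str = "treated"
    min_total: int = 100
    subtracted_rate: float | None = None

    def __post_init__(self) -> None:
        if set(self.read_counts) != set(RNA_BASES):
            raise ValueError("read_counts must cover exactly {A, C, G, U}")
        if any(c < 0 for c in self.read_counts.values()):
            raise ValueError("negative read count")

    @property
    def read_total(self) -> int:
        return sum(self.read_counts.values())

    @property
    def read_mutant(self) -> int:
        return self.read_total - self.read_counts[self.wt_base]

    @property
    def defined(self) -> bool:
        return self.read_total >= self.min_total

    @property
    def m_rate(self) -> float | None:
        if not self.defined:
            return None
        return self.read_mutant / self.read_total


def build_variant_queries(
    variant: Variant | AnnotatedTRNA, target_index: int
) -> dict[str, str]:
    """The four query sequences of one library member.

    Returns a map RNA base -> full-length sequence identical to the member
    except for that base at the monitored target position.  Query sets of
    distinct single-point variants are disjoint: each query carries the
    variant's own substitution, which no other member has.
    """
    seq = variant.sequence
    if not 0 <= target_index < len(seq):
        raise ValueError(f"target index {target_index} outside sequence")
    return {b: seq[:target_index] + b + seq[target_index + 1 :] for b in RNA_BASES}


def library_queries(library: VariantLibrary, *, include_wt: bool = True) -> dict[str, dict[str, str]]:
    """Queries for every variant of a library, keyed by variant name.

    The parent is included as the ``WT`` pseudo-variant when requested, so
    unmutated controls can be scored the same way.  Raises if any variant
    mutates the target position itself (its queries would collide with the
    parent's).
    """
    t_idx = library.target_index
    out: dict[str, dict[str, str]] = {}
    for v in library.variants:
        if library.parent.label_index(v.position_label) == t_idx:
            raise ValueError(f"{v.name}: variant mutates the monitored target position")
        out[v.name] = build_variant_queries(v, t_idx)
    if include_wt:
        out["WT"] = build_variant_queries(library.parent, t_idx)
    return out


def count_exact(
    reads: Iterable[SimulatedRead | str],
    queries: Mapping[str, Mapping[str, str]],
    mode: str = "substring",
    *,
    adapter: str | None = None,
) -> tuple[dict[str, dict[str, int]], int]:
    """Count reads matching each query exactly.

    ``queries`` maps member name -> (RNA base -> query sequence).  In
    ``substring`` mode (default) a read counts for a query it contains; in
    ``full-length`` mode the read must equal the query after adapter
    trimming (``adapter`` required).  Reads are collapsed to unique
    sequences first, so heavily duplicated libraries count in close to
    O(unique reads).  Returns the per-member, per-base counts and the
    number of reads that matched queries of more than one member (0 for a
    properly disjoint query set).
    """
    if mode not in {"substring", "full-length"}:
        raise ValueError(f"unknown mode {mode!r}")
    flat: list[tuple[str, str, str]] = []  # (member, base, DNA query)
    for member, per_base in queries.items():
        for base, q in per_base.items():
            if not q:
                raise ValueError(f"{member}: empty query")
            flat.append((member, base, rna_to_dna(q)))

    uniq: Counter[str] = Counter()
    for item in reads:
        seq = item.sequence if isinstance(item, SimulatedRead) else str(item)
        uniq[seq.upper()] += 1

    counts: dict[str, dict[str, int]] = {m: {b: 0 for b in RNA_BASES} for m in queries}
    ambiguous = 0
    for seq, n in uniq.items():
        if mode == "full-length":
            if adapter is None:
                raise ValueError("full-length mode requires the adapter sequence")
            from .profiling import trim_adapter

            seq, _ = trim_adapter(seq, adapter)
        members_hit = set()
        for member, base, q in flat:
            hit = (q in seq) if mode == "substring" else (q == seq)
            if hit:
                counts[member][base] += n
                members_hit.add(member)
        if len(members_hit) > 1:
            ambiguous += n
    return counts, ambiguous


def compute_m_rate(
    counts: Mapping[str, int],
    wt_base: str,
    *,
    variant_name: str = "",
    sample_role: str = "treated",
    min_total: int = 100,
) -> MRateResult:
    """Mutation rate at the target position from per-base read counts."""
    wt_base = wt_base.upper().replace("T", "U")
    if wt_base not in RNA_BASES:
        raise ValueError(f"invalid wild-type base {wt_base!r}")
    full = {b: int(counts.get(b, 0)) for b in RNA_BASES}
    return MRateResult(
        variant_name=variant_name,
        wt_base=wt_base,
        read_counts=full,
        sample_role=sample_role,
        min_total=min_total,
    )


def subtract_m_rate(treated: MRateResult, untreated: MRateResult) -> MRateResult:
    """Background-correct: ``max(0, treated - untreated)``; undefined if either is."""
    if treated.variant_name != untreated.variant_name:
        raise ValueError(
            f"variant mismatch: {treated.variant_name!r} vs {untreated.variant_name!r}"
        )
    if treated.defined and untreated.defined:
        sub = max(0.0, treated.m_rate - untreated.m_rate)
    else:
        sub = None
    return MRateResult(
        variant_name=treated.variant_name,
        wt_base=treated.wt_base,
        read_counts=treated.read_counts,
        sample_role="subtracted",
        min_total=treated.min_total,
        subtracted_rate=sub,
    )


def m_rate_table(
    treated_reads: Sequence[SimulatedRead | str],
    untreated_reads: Sequence[SimulatedRead | str],
    queries: Mapping[str, Mapping[str, str]],
    wt_bases: Mapping[str, str],
    *,
    mode: str = "substring",
    min_total: int = 100,
    adapter: str | None = None,
) -> pd.DataFrame:
    """Quantify a treated/untreated sample pair over a full query set.

    ``wt_bases`` maps member name -> parent base at the target position.
    Returns one row per member with per-base counts, treated/untreated
    M_rate and the background-subtracted rate (NaN where undefined).
    """
    counts_t, amb_t = count_exact(treated_reads, queries, mode, adapter=adapter)
    counts_u, amb_u = count_exact(untreated_reads, queries, mode, adapter=adapter)
    rows = []
    for member in queries:
        wt = wt_bases[member]
        rt = compute_m_rate(
            counts_t[member], wt, variant_name=member, sample_role="treated", min_total=min_total
        )
        ru = compute_m_rate(
            counts_u[member], wt, variant_name=member, sample_role="untreated", min_total=min_total
        )
        sub = subtract_m_rate(rt, ru)
        row = {"variant": member, "wt_base": wt}
        row.update({f"count_{b}": rt.read_counts[b] for b in RNA_BASES})
        row.update(
            {
                "read_total": rt.read_total,
                "read_mutant": rt.read_mutant,
                "m_rate_treated": rt.m_rate if rt.defined else float("nan"),
                "m_rate_untreated": ru.m_rate if ru.defined else float("nan"),
                "m_rate_subtracted": (
                    sub.subtracted_rate if sub.subtracted_rate is not None else float("nan")
                ),
                "defined": rt.defined and ru.defined,
                "ambiguous_reads": amb_t + amb_u,
            }
        )
        rows.append(row)
    return pd.DataFrame(rows)


def pool_target_queries(
    references: Sequence[AnnotatedTRNA], target_label: str
) -> tuple[dict[str, dict[str, str]], dict[str, str]]:
    """Exact-match queries for scoring one target position across a pool.

    Each reference is treated as its own 'member': four full-length
    sequences varying only the target-position base.  Returns the query
    set and the map of wild-type bases, for use with :func:`m_rate_table`.
    """
    queries = {}
    wt_bases = {}
    for t in references:
        idx = t.label_index(target_label)
        queries[t.id] = build_variant_queries(t, idx)
        wt_bases[t.id] = t.sequence[idx]
    return queries, wt_bases
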