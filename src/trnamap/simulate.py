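"""Seeded FASTQ simulation of RT mutational-profiling libraries.

Reverse transcription of a modified tRNA leaves two signatures in the cDNA:
misincorporation opposite Watson-Crick-face methylations (recorded as a
mutation in the read) and premature termination (an RT stop, truncating the
cDNA).  Because cDNA synthesis primes on the 3' adapter and proceeds toward
the tRNA 5' end, a stopped read retains the 3' portion of the tRNA — reads
are reference *suffixes* plus the ligated adapter.

The generator draws, per read: a reference (by pool abundance), a
modification status (treated samples only), RT stops and misincorporations
from the per-position signature, uniform base-substitution sequencing
error, and finally appends the 3' adapter.  Alongside the FASTQ it emits a
truth table of the per-position mutation rates implied by the draw
parameters, so estimators can be checked against what was actually
simulated.  All randomness flows from one integer seed; output is
byte-identical across runs.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .trna import AnnotatedTRNA, Variant, VariantLibrary, normalize_rna, rna_to_dna

#: 3' adapter ligated to the tRNA before RT (DNA, written into every read)
DEFAULT_ADAPTER = "CTGTAGGCACCATCAAT"

#: headline misincorporation rate of a strong m1A-type RT signature
M1A_MISINCORPORATION_RATE = 0.79

DNA_BASES = "ACGT"


@dataclass(frozen=True)
class ModificationSignature:
    """RT signature of one modified position in one reference.

    ``misincorporation_rate`` is the probability that reverse transcription
    records a non-templated base at this position when the molecule carries
    the modification; ``substitution_spectrum`` distributes that event over
    the three non-wild-type bases (uniform when omitted); ``stop_rate`` is
    the probability that RT terminates at the position instead of reading
    through.
    """

    reference_id: str
    position_label: str
    misincorporation_rate: float = M1A_MISINCORPORATION_RATE
    substitution_spectrum: Mapping[str, float] | None = None
    stop_rate: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.misincorporation_rate <= 1.0:
            raise ValueError("misincorporation_rate outside [0, 1]")
        if not 0.0 <= self.stop_rate <= 1.0:
            raise ValueError("stop_rate outside [0, 1]")
        if self.substitution_spectrum is not None:
            total = sum(self.substitution_spectrum.values())
            if abs(total - 1.0) > 1e-6:
                raise ValueError("substitution_spectrum must sum to 1")


@dataclass(frozen=True)
class PoolSpec:
    """Relative abundances and modification levels of a reference pool.

    ``members`` maps reference id to a positive weight (normalized
    internally); ``modification_fraction`` gives the probability that a
    molecule of each member carries the modification in the treated sample
    (default 1.0, i.e. the enzymatic reaction ran to completion).
    """

    members: Mapping[str, float]
    modification_fraction: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("empty pool")
        if any(w <= 0 for w in self.members.values()):
            raise ValueError("abundance weights must be positive")
        for rid, f in self.modification_fraction.items():
            if rid not in self.members:
                raise ValueError(f"modification_fraction for unknown reference {rid!r}")
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"{rid}: modification_fraction outside [0, 1]")

    def fraction(self, reference_id: str) -> float:
        return self.modification_fraction.get(reference_id, 1.0)

    @classmethod
    def uniform(cls, reference_ids: Iterable[str], **kw) -> "PoolSpec":
        return cls(members={r: 1.0 for r in reference_ids}, **kw)


@dataclass(frozen=True)
class SimConfig:
    n_reads: int
    error_rate: float = 0.001
    adapter: str = DEFAULT_ADAPTER
    seed: int = 0
    read_length_cap: int | None = None
    constant_quality: int = 37

    def __post_init__(self) -> None:
        if self.n_reads <= 0:
            raise ValueError("n_reads must be positive")
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError("error_rate outside [0, 1)")


@dataclass(frozen=True)
class SimulatedRead:
    id: str
    sequence: str  # DNA
    true_reference: str


def _error_positions(length: int, rate: float, rng: random.Random) -> list[int]:
    """Positions hit by uniform substitution error, via geometric skips."""
    if rate <= 0.0 or length == 0:
        return []
    log1m = math.log1p(-rate)
    out: list[int] = []
    pos = -1
    while True:
        u = rng.random()
        pos += 1 + int(math.log1p(-u) / log1m)
        if pos >= length:
            return out
        out.append(pos)


def _spectrum_sampler(sig: ModificationSignature, wt_base_dna: str):
    """Cumulative thresholds for drawing the misincorporated base (DNA)."""
    if sig.substitution_spectrum is None:
        bases = [b for b in DNA_BASES if b != wt_base_dna]
        cum = [(1 / 3, bases[0]), (2 / 3, bases[1]), (1.0, bases[2])]
        return cum
    cum = []
    acc = 0.0
    for base, p in sorted(sig.substitution_spectrum.items()):
        b = rna_to_dna(base)
        if b == wt_base_dna:
            raise ValueError(f"substitution_spectrum contains the wild-type base {base}")
        acc += p
        cum.append((acc, b))
    cum[-1] = (1.0, cum[-1][1])
    return cum


def _expected_rate(p_signal: float, error_rate: float) -> float:
    # after a misincorporation, sequencing error reverts to WT w.p. e/3
    return p_signal * (1.0 - error_rate / 3.0) + (1.0 - p_signal) * error_rate


def simulate_sample(
    pool: PoolSpec,
    signatures: Sequence[ModificationSignature],
    references: Sequence[AnnotatedTRNA],
    config: SimConfig,
    *,
    treated: bool,
) -> tuple[list[SimulatedRead], pd.DataFrame]:
    """Draw a single-end FASTQ sample from a reference pool.

    Returns the reads (tRNA sense, DNA alphabet, adapter appended) and a
    truth table with the expected per-position mutation rate of this sample,
    ``expected_rate = p*(1 - e/3) + (1 - p)*e`` where ``p`` is the marginal
    misincorporation probability (0 in untreated samples) and ``e`` the
    sequencing error rate.
    """
    ref_by_id = {t.id: t for t in references}
    missing = set(pool.members) - set(ref_by_id)
    if missing:
        raise ValueError(f"pool members without reference sequence: {sorted(missing)}")
    for sig in signatures:
        if sig.reference_id not in pool.members:
            raise ValueError(f"signature for unknown reference {sig.reference_id!r}")

    rng = random.Random(config.seed)
    ref_ids = sorted(pool.members)
    weights = [pool.members[r] for r in ref_ids]

    # per-reference precomputation: DNA sequence and signature plan sorted
    # 3'->5' (the order RT encounters positions)
    plans: dict[str, tuple[str, list[tuple[int, float, float, list]]]] = {}
    for rid in ref_ids:
        trna = ref_by_id[rid]
        dna = rna_to_dna(trna.sequence)
        plan = []
        for sig in signatures:
            if sig.reference_id != rid:
                continue
            idx = trna.label_index(sig.position_label)
            plan.append(
                (idx, sig.stop_rate, sig.misincorporation_rate, _spectrum_sampler(sig, dna[idx]))
            )
        plan.sort(key=lambda x: -x[0])
        plans[rid] = (dna, plan)

    adapter = config.adapter.upper()
    reads: list[SimulatedRead] = []
    choices = rng.choices(range(len(ref_ids)), weights=weights, k=config.n_reads)
    for i, ridx in enumerate(choices):
        rid = ref_ids[ridx]
        dna, plan = plans[rid]
        start = 0
        subs: list[tuple[int, str]] = []
        if treated and plan and rng.random() < pool.fraction(rid):
            for idx, stop_rate, mis_rate, spectrum in plan:
                if stop_rate > 0.0 and rng.random() < stop_rate:
                    start = idx + 1
                    break  # RT fell off; positions 5' of the stop are never read
                if mis_rate > 0.0 and rng.random() < mis_rate:
                    u = rng.random()
                    for threshold, base in spectrum:
                        if u <= threshold:
                            subs.append((idx, base))
                            break
        core = dna[start:]
        if subs:
            chars = list(core)
            for idx, base in subs:
                chars[idx - start] = base
            core = "".join(chars)
        full = core + adapter
        errs = _error_positions(len(full), config.error_rate, rng)
        if errs:
            chars = list(full)
            for pos in errs:
                chars[pos] = _substitute(chars[pos], rng)
            full = "".join(chars)
        if config.read_length_cap is not None:
            full = full[: config.read_length_cap]
        reads.append(SimulatedRead(id=f"read{i}", sequence=full, true_reference=rid))

    truth = _truth_table(pool, signatures, references, config, treated=treated)
    return reads, truth


def _substitute(wt: str, rng: random.Random) -> str:
    alts = [b for b in DNA_BASES if b != wt]
    return alts[rng.randrange(3)]


def _truth_table(
    pool: PoolSpec,
    signatures: Sequence[ModificationSignature],
    references: Sequence[AnnotatedTRNA],
    config: SimConfig,
    *,
    treated: bool,
) -> pd.DataFrame:
    ref_by_id = {t.id: t for t in references}
    sig_map = {(s.reference_id, s.position_label): s for s in signatures}
    rows = []
    for rid in sorted(pool.members):
        trna = ref_by_id[rid]
        for label in trna.position_labels:
            sig = sig_map.get((rid, label))
            p_signal = 0.0
            if treated and sig is not None:
                p_signal = pool.fraction(rid) * sig.misincorporation_rate
            rows.append(
                {
                    "reference": rid,
                    "label": label,
                    "p_signal": p_signal,
                    "expected_rate": _expected_rate(p_signal, config.error_rate),
                }
            )
    return pd.DataFrame(rows)


def simulate_variant_library_sample(
    library: VariantLibrary,
    target_signature: ModificationSignature,
    per_variant_efficiency: Mapping[str, float] | None,
    config: SimConfig,
    *,
    treated: bool,
    include_wt: bool = False,
) -> tuple[list[SimulatedRead], pd.DataFrame]:
    """Simulate a screen of a single-point variant library.

    References are the variant sequences (plus the parent as ``WT`` when
    ``include_wt``).  In the treated sample, the misincorporation rate at
    the monitored target position of variant ``v`` is
    ``per_variant_efficiency[v] * target_signature.misincorporation_rate``
    — a variant that abolishes enzyme activity (efficiency 0) shows no
    signal above background.  Missing efficiencies default to 1.0.
    """
    eff = dict(per_variant_efficiency or {})
    unknown = set(eff) - {v.name for v in library.variants} - {"WT"}
    if unknown:
        raise ValueError(f"efficiencies for unknown variants: {sorted(unknown)}")

    members: dict[str, AnnotatedTRNA] = {}
    parent = library.parent
    for v in library.variants:
        members[v.name] = AnnotatedTRNA(
            id=v.name,
            sequence=v.sequence,
            position_labels=parent.position_labels,
            elements=dict(parent.elements),
        )
    if include_wt:
        members["WT"] = AnnotatedTRNA(
            id="WT",
            sequence=parent.sequence,
            position_labels=parent.position_labels,
            elements=dict(parent.elements),
        )

    signatures = [
        ModificationSignature(
            reference_id=name,
            position_label=library.target_label,
            misincorporation_rate=eff.get(name, 1.0) * target_signature.misincorporation_rate,
            substitution_spectrum=target_signature.substitution_spectrum,
            stop_rate=target_signature.stop_rate,
        )
        for name in members
    ]
    pool = PoolSpec.uniform(members)
    return simulate_sample(pool, signatures, list(members.values()), config, treated=treated)


def random_trna_pool(
    n: int,
    seed: int,
    *,
    length_range: tuple[int, int] = (70, 95),
    target_label: str = "22",
    target_base: str = "A",
) -> list[AnnotatedTRNA]:
    """Generate a synthetic pool of tRNA-shaped references.

    Sequences start with G, end with CCA, and carry the target base at the
    monitored position so every member can be scored there.  Structural
    elements are assigned by a fixed coarse layout (acceptor stem 1-7,
    D-arm 8-25, anticodon arm 26-44, variable region to 10 nt before the
    3' end, then T-arm, discriminator, CCA).  These are synthetic stand-ins
    for cloned references, not real gene sequences.
    """
    rng = random.Random(seed)
    lo, hi = length_range
    target_base = normalize_rna(target_base, context="target_base")
    out = []
    for k in range(n):
        length = rng.randint(lo, hi)
        seq = ["G"] + [rng.choice("ACGU") for _ in range(length - 4)] + ["C", "C", "A"]
        labels = [str(i + 1) for i in range(length)]
        t_idx = labels.index(str(target_label))
        seq[t_idx] = target_base
        elements = {}
        for i, label in enumerate(labels):
            if i >= length - 3:
                elements[label] = "cca"
            elif i == length - 4:
                elements[label] = "discriminator"
            elif i < 7:
                elements[label] = "acceptor_stem"
            elif i < 25:
                elements[label] = "d_arm"
            elif i < 44:
                elements[label] = "anticodon_arm"
            elif i >= length - 21:
                elements[label] = "t_arm"
            else:
                elements[label] = "variable_region"
        out.append(
            AnnotatedTRNA(
                id=f"synth_tRNA_{k:02d}",
                sequence="".join(seq),
                position_labels=tuple(labels),
                elements=elements,
            )
        )
    return out


def write_fastq(reads: Iterable[SimulatedRead], path: str | Path, *, quality: int = 37) -> None:
    """Write 4-line FASTQ records with a constant Phred+33 quality."""
    qchar = chr(33 + quality)
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.id} {r.true_reference}\n{r.sequence}\n+\n{qchar * len(r.sequence)}\n")


def read_fastq(path: str | Path) -> list[SimulatedRead]:
    """Read 4-line FASTQ; the first header token is the id, the second
    (when present) is taken as the true reference annotation."""
    out = []
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                break
            seq = fh.readline().strip()
            fh.readline()
            fh.readline()
            parts = header[1:].strip().split()
            rid = parts[0]
            true_ref = parts[1] if len(parts) > 1 else ""
            out.append(SimulatedRead(id=rid, sequence=seq, true_reference=true_ref))
    return out


def write_truth_table(truth: pd.DataFrame, path: str | Path) -> None:
    truth.to_csv(path, sep="\t", index=False)
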