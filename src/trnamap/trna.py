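"""Annotated tRNA references, single-point variant libraries, and T7 cassettes.

A tRNA is represented together with its per-nucleotide position labels
(Sprinzl-style strings such as ``"8"``, ``"20a"``, ``"45b"``) and a mapping
from labels to secondary-structure elements (acceptor stem, D-arm, ...).
Labels are free-form annotation input: equivalent positions in different
tRNAs carry the same label, but no automatic Sprinzl alignment is attempted.

From one annotated tRNA a saturation single-point substitution library can
be designed (three substitutions per mutable position), and a DNA cassette
for run-off T7 transcription can be constructed: T7 promoter, the tRNA
coding sequence (5' G-extended if needed, CCA-terminated), and a fixed
3' tail carrying a BsaI site so that digestion yields templates whose
transcripts end in CCA.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

RNA_BASES = "ACGU"

#: secondary-structure element vocabulary
STRUCTURAL_ELEMENTS = frozenset(
    {
        "acceptor_stem",
        "d_arm",
        "anticodon_arm",
        "variable_region",
        "t_arm",
        "discriminator",
        "cca",
    }
)

#: T7 class-III promoter used on every transcription cassette
T7_PROMOTER = "GCGTAATACGACTCACTATA"

#: constant cassette tail; starts with the BsaI recognition/cleavage module
#: so digestion leaves the template ending at the CCA-encoding triplet
CASSETTE_TAIL = "TGAGACCGGATCCGGATCCCCGCTGAGCAATAACTAGC"


def normalize_rna(sequence: str, *, context: str = "sequence") -> str:
    """Uppercase and convert DNA input (T) to the RNA alphabet (U)."""
    seq = sequence.upper().replace("T", "U")
    bad = set(seq) - set(RNA_BASES)
    if bad:
        raise ValueError(f"{context}: invalid characters {sorted(bad)!r}")
    return seq


def rna_to_dna(sequence: str) -> str:
    return sequence.upper().replace("U", "T")


@dataclass(frozen=True)
class AnnotatedTRNA:
    """A tRNA sequence with per-nucleotide position labels and elements.

    Parameters
    ----------
    id:
        Unique reference identifier.
    sequence:
        RNA sequence over {A, C, G, U}; DNA input is normalized upstream.
    position_labels:
        One label string per nucleotide, unique within the tRNA.
    elements:
        Map label -> structural element name (subset of
        :data:`STRUCTURAL_ELEMENTS`); may cover only part of the sequence.
    """

    id: str
    sequence: str
    position_labels: tuple[str, ...]
    elements: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", normalize_rna(self.sequence, context=self.id))
        object.__setattr__(self, "position_labels", tuple(str(l) for l in self.position_labels))
        if not self.sequence:
            raise ValueError(f"{self.id}: empty sequence")
        if len(self.position_labels) != len(self.sequence):
            raise ValueError(
                f"{self.id}: {len(self.position_labels)} position labels for "
                f"{len(self.sequence)} nucleotides"
            )
        if len(set(self.position_labels)) != len(self.position_labels):
            raise ValueError(f"{self.id}: duplicate position labels")
        unknown = set(self.elements) - set(self.position_labels)
        if unknown:
            raise ValueError(f"{self.id}: element labels not in positions: {sorted(unknown)}")
        bad_elements = set(self.elements.values()) - STRUCTURAL_ELEMENTS
        if bad_elements:
            raise ValueError(f"{self.id}: unknown structural elements {sorted(bad_elements)}")

    def __len__(self) -> int:
        return len(self.sequence)

    def label_index(self, label: str) -> int:
        """0-based sequence index of a position label."""
        try:
            return self.position_labels.index(str(label))
        except ValueError:
            raise KeyError(f"{self.id}: no position labeled {label!r}") from None

    def base_at(self, label: str) -> str:
        return self.sequence[self.label_index(label)]

    def element_of(self, label: str) -> str | None:
        if str(label) not in self.position_labels:
            raise KeyError(f"{self.id}: no position labeled {label!r}")
        return self.elements.get(str(label))


@dataclass(frozen=True)
class Variant:
    """A single-point substitution variant of a parent tRNA."""

    name: str
    position_label: str
    wt_base: str
    new_base: str
    sequence: str

    def __post_init__(self) -> None:
        if self.new_base == self.wt_base:
            raise ValueError(f"{self.name}: substitution to the wild-type base")


@dataclass(frozen=True)
class VariantLibrary:
    """A set of single-point variants of one tRNA, monitored at one target position."""

    parent: AnnotatedTRNA
    target_label: str
    variants: tuple[Variant, ...]

    def __post_init__(self) -> None:
        names = [v.name for v in self.variants]
        if len(set(names)) != len(names):
            raise ValueError("duplicate variant names in library")
        parent = self.parent.sequence
        for v in self.variants:
            diffs = [i for i, (a, b) in enumerate(zip(parent, v.sequence)) if a != b]
            if len(v.sequence) != len(parent) or len(diffs) != 1:
                raise ValueError(f"{v.name}: does not differ from parent at exactly one position")
            if diffs[0] == self.parent.label_index(self.target_label):
                raise ValueError(f"{v.name}: mutates the monitored target position")

    def __len__(self) -> int:
        return len(self.variants)

    @property
    def target_index(self) -> int:
        return self.parent.label_index(self.target_label)

    def by_name(self, name: str) -> Variant:
        for v in self.variants:
            if v.name == name:
                return v
        raise KeyError(name)


@dataclass(frozen=True)
class TranscriptionCassette:
    """DNA template for run-off T7 transcription of one tRNA."""

    dna_template: str
    promoter_span: tuple[int, int]
    trna_span: tuple[int, int]
    tail_span: tuple[int, int]
    extra_g_added: bool
    cca_added: bool


def load_references(fasta_path: str | Path, annotation_path: str | Path) -> list[AnnotatedTRNA]:
    """Load annotated tRNA references from a FASTA plus a TSV annotation.

    The annotation TSV has columns ``id``, ``index`` (0-based position in the
    sequence), ``label`` and ``element`` (empty for unassigned positions) and
    must give exactly one label per nucleotide of the matching FASTA record.
    """
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate FASTA ids: {dupes}")
    ann = pd.read_csv(annotation_path, sep="\t", dtype={"id": str, "label": str, "element": str})
    required = {"id", "index", "label"}
    if not required.issubset(ann.columns):
        raise ValueError(f"annotation must have columns {sorted(required)}")
    ann_ids = set(ann["id"])
    if ann_ids != set(ids):
        raise ValueError(
            f"FASTA and annotation ids differ: only-FASTA={sorted(set(ids) - ann_ids)}, "
            f"only-annotation={sorted(ann_ids - set(ids))}"
        )
    out = []
    for rec in records:
        seq = normalize_rna(str(rec.seq), context=rec.id)
        sub = ann[ann["id"] == rec.id].sort_values("index")
        if list(sub["index"]) != list(range(len(seq))):
            raise ValueError(
                f"{rec.id}: annotation has {len(sub)} labels for a {len(seq)}-nt sequence "
                "(indices must be 0..len-1)"
            )
        elements = {}
        if "element" in sub.columns:
            for _, row in sub.iterrows():
                el = row.get("element")
                if isinstance(el, str) and el:
                    elements[str(row["label"])] = el
        out.append(
            AnnotatedTRNA(
                id=rec.id,
                sequence=seq,
                position_labels=tuple(sub["label"]),
                elements=elements,
            )
        )
    return out


def write_annotation(trnas: Iterable[AnnotatedTRNA], path: str | Path) -> None:
    """Write the TSV annotation companion of a reference FASTA."""
    rows = []
    for t in trnas:
        for i, label in enumerate(t.position_labels):
            rows.append(
                {"id": t.id, "index": i, "label": label, "element": t.elements.get(label, "")}
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_fasta(entries: Iterable[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in entries:
            fh.write(f">{name}\n{seq}\n")


def default_mutable_labels(trna: AnnotatedTRNA, target_label: str) -> list[str]:
    """All labels except the monitored target and the 3'-CCA positions.

    For an 84-position tRNA this yields 80 mutable positions (84 minus the
    target minus the three CCA nucleotides), i.e. a 240-variant library.
    """
    excluded = {str(target_label)}
    if trna.sequence.endswith("CCA"):
        excluded.update(trna.position_labels[-3:])
    trna.label_index(target_label)  # validate
    return [l for l in trna.position_labels if l not in excluded]


def design_point_variant_library(
    trna: AnnotatedTRNA,
    mutable_labels: Sequence[str] | None = None,
    *,
    target_label: str,
) -> VariantLibrary:
    """Design the saturation single-point substitution library of one tRNA.

    Every mutable position is substituted with each of the three non
    wild-type bases, giving ``3 * len(mutable_labels)`` variants named
    ``<wt><label><new>`` (e.g. ``U8A``).  The monitored target position is
    never mutable, so the mutation rate read out there stays comparable
    across variants.  Ordering is deterministic: position index, then base
    order A < C < G < U.
    """
    if mutable_labels is None:
        mutable_labels = default_mutable_labels(trna, target_label)
    mutable_labels = [str(l) for l in mutable_labels]
    target_label = str(target_label)
    trna.label_index(target_label)
    if target_label in mutable_labels:
        raise ValueError(f"target position {target_label!r} listed as mutable")
    for label in mutable_labels:
        trna.label_index(label)

    variants = []
    order = sorted(mutable_labels, key=trna.label_index)
    for label in order:
        idx = trna.label_index(label)
        wt = trna.sequence[idx]
        for new in RNA_BASES:
            if new == wt:
                continue
            seq = trna.sequence[:idx] + new + trna.sequence[idx + 1 :]
            variants.append(
                Variant(
                    name=f"{wt}{label}{new}",
                    position_label=label,
                    wt_base=wt,
                    new_base=new,
                    sequence=seq,
                )
            )
    return VariantLibrary(parent=trna, target_label=target_label, variants=tuple(variants))


def double_variant_count(n_variants: int) -> int:
    """Number of ordered pairs of distinct single-point variants."""
    return n_variants * (n_variants - 1)


def reads_per_variant(total_reads: int, n_variants: int) -> int:
    """Average sequencing depth per library member, floor-divided."""
    if n_variants <= 0:
        raise ValueError("n_variants must be positive")
    return total_reads // n_variants


def build_t7_cassette(trna: AnnotatedTRNA) -> TranscriptionCassette:
    """Construct the DNA cassette for run-off T7 transcription of a tRNA.

    T7 transcription initiates efficiently on G, so a 5' G is prepended to
    the coding sequence of tRNAs that do not start with G; a CCA-encoding
    triplet is appended when the tRNA does not already end in CCA.  The
    constant tail downstream carries the BsaI module whose digestion leaves
    the template ending at the CCA codon.
    """
    if not trna.sequence:
        raise ValueError(f"{trna.id}: empty sequence")
    coding = rna_to_dna(trna.sequence)
    extra_g = not coding.startswith("G")
    if extra_g:
        coding = "G" + coding
    cca = not coding.endswith("CCA")
    if cca:
        coding = coding + "CCA"
    template = T7_PROMOTER + coding + CASSETTE_TAIL
    p_end = len(T7_PROMOTER)
    t_end = p_end + len(coding)
    return TranscriptionCassette(
        dna_template=template,
        promoter_span=(0, p_end),
        trna_span=(p_end, t_end),
        tail_span=(t_end, len(template)),
        extra_g_added=extra_g,
        cca_added=cca,
    )


def predicted_transcript(cassette: TranscriptionCassette) -> str:
    """RNA produced by run-off transcription of the BsaI-digested cassette.

    The transcript is the (possibly G-prefixed) tRNA ending in CCA; tail
    nucleotides downstream of the BsaI cleavage point are not transcribed.
    """
    start, end = cassette.trna_span
    return normalize_rna(cassette.dna_template[start:end], context="cassette")
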