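from pathlib import Path

import pytest

from trnamap import AnnotatedTRNA, random_trna_pool
from trnamap.trna import write_annotation, write_fasta


@pytest.fixture
def mini_trna() -> AnnotatedTRNA:
    """A hand-built 12-nt toy tRNA: G-start, CCA-end, target A at label '4'."""
    return AnnotatedTRNA(
        id="mini",
        sequence="GGCAUUGACCCA",
        position_labels=tuple(str(i) for i in range(1, 13)),
        elements={
            "1": "acceptor_stem",
            "2": "acceptor_stem",
            "3": "d_arm",
            "4": "d_arm",
            "5": "d_arm",
            "6": "anticodon_arm",
            "7": "t_arm",
            "8": "t_arm",
            "9": "discriminator",
            "10": "cca",
            "11": "cca",
            "12": "cca",
        },
    )


@pytest.fixture
def trna84() -> AnnotatedTRNA:
    """An 84-position synthetic tRNA (80 mutable once target + CCA are excluded)."""
    return random_trna_pool(1, seed=84, length_range=(84, 84))[0]


@pytest.fixture
def small_pool() -> list[AnnotatedTRNA]:
    return random_trna_pool(6, seed=11, length_range=(72, 80))


@pytest.fixture
def reference_files(tmp_path: Path, small_pool):
    """Reference FASTA + annotation TSV on disk for IO/CLI tests."""
    fasta = tmp_path / "refs.fasta"
    annotation = tmp_path / "refs.tsv"
    write_fasta(((t.id, t.sequence) for t in small_pool), fasta)
    write_annotation(small_pool, annotation)
    return fasta, annotation
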