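"""Reading, validating and labeling RNA sequences.

The unit of analysis is a fixed-alphabet RNA sequence over {A, C, G, U}.
Input is normalised on read: lowercase is uppercased and T (DNA alphabet,
common in deposited modification datasets) is mapped to U. Ambiguity codes
are rejected outright because every downstream encoder assumes a complete
compositional profile.

Labeled data is assembled either from a positive/negative FASTA pair or
from a single FASTA plus a two-column TSV sidecar (id, label in {0,1}).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

RNA_ALPHABET = frozenset("ACGU")

__all__ = [
    "RnaSequence",
    "LabeledDataset",
    "DatasetSplit",
    "FastaError",
    "SequenceValidationError",
    "read_fasta",
    "write_fasta",
    "load_labeled",
    "load_with_sidecar",
    "make_split",
    "write_split_manifest",
]


class FastaError(ValueError):
    """Raised when a FASTA file cannot be parsed as multi-record FASTA."""


class SequenceValidationError(ValueError):
    """Raised when a residue outside {A,C,G,U} survives normalisation."""


def _normalise(residues: str) -> str:
    return residues.upper().replace("T", "U")


@dataclass(frozen=True)
class RnaSequence:
    """A validated RNA sequence with an identifier.

    ``residues`` must be a non-empty string over {A, C, G, U}; use
    :func:`read_fasta` (which normalises case and T→U) to construct
    instances from raw input.
    """

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise SequenceValidationError(f"sequence {self.id!r} is empty")
        bad = set(self.residues) - RNA_ALPHABET
        if bad:
            raise SequenceValidationError(
                f"sequence {self.id!r} contains invalid residue(s) "
                f"{sorted(bad)!r}; allowed alphabet is A/C/G/U "
                "(T is accepted on input and mapped to U)"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class LabeledDataset:
    """Sequences plus aligned binary labels (1 = 5hmC positive)."""

    sequences: list[RnaSequence]
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 1 or len(self.labels) != len(self.sequences):
            raise ValueError(
                f"labels length {self.labels.shape} does not match "
                f"{len(self.sequences)} sequences"
            )
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be binary (0/1)")

    def __len__(self) -> int:
        return len(self.sequences)

    @property
    def ids(self) -> list[str]:
        return [s.id for s in self.sequences]

    def class_counts(self) -> tuple[int, int]:
        """(n_negative, n_positive)."""
        pos = int(self.labels.sum())
        return len(self) - pos, pos

    def subset(self, indices: Sequence[int]) -> "LabeledDataset":
        idx = np.asarray(indices, dtype=int)
        return LabeledDataset(
            [self.sequences[i] for i in idx], self.labels[idx]
        )


@dataclass
class DatasetSplit:
    """Stratified train / independent hold-out partition of a dataset."""

    train: LabeledDataset
    independent: LabeledDataset
    fraction: float
    seed: int

    def __post_init__(self) -> None:
        overlap = set(self.train.ids) & set(self.independent.ids)
        if overlap:
            raise ValueError(f"train/independent id overlap: {sorted(overlap)[:5]}")


def read_fasta(path: str | Path) -> list[RnaSequence]:
    """Read a FASTA file into validated :class:`RnaSequence` records.

    Ids are taken from the header up to the first whitespace. Lowercase is
    uppercased and T/t mapped to U before validation; any other character
    outside the RNA alphabet raises :class:`SequenceValidationError` naming
    the record and the offending character(s).
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.read(1)
        if first == "":
            raise FastaError(f"{path}: file is empty")
        if first != ">":
            raise FastaError(
                f"{path}: line 1 does not start with '>'; not FASTA"
            )
    out: list[RnaSequence] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        out.append(RnaSequence(rec.id, _normalise(str(rec.seq))))
    if not out:
        raise FastaError(f"{path}: no FASTA records found")
    return out


def write_fasta(sequences: Iterable[RnaSequence], path: str | Path) -> None:
    """Write sequences as unwrapped multi-record FASTA (round-trips with
    :func:`read_fasta`)."""
    records = [
        SeqRecord(Seq(s.residues), id=s.id, description="") for s in sequences
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta-2line")


def load_labeled(pos_path: str | Path, neg_path: str | Path) -> LabeledDataset:
    """Assemble a dataset from a positive and a negative FASTA file.

    Order is positives (label 1) followed by negatives (label 0). A
    sequence id occurring in both files is an error.
    """
    pos = read_fasta(pos_path)
    neg = read_fasta(neg_path)
    dup = {s.id for s in pos} & {s.id for s in neg}
    if dup:
        raise ValueError(
            f"id(s) present in both positive and negative files: {sorted(dup)}"
        )
    labels = np.concatenate([np.ones(len(pos), int), np.zeros(len(neg), int)])
    return LabeledDataset(pos + neg, labels)


def load_with_sidecar(fasta_path: str | Path, tsv_path: str | Path) -> LabeledDataset:
    """Alternative labeling route: one FASTA plus a two-column TSV
    (id <tab> label) with labels in {0,1}. Every record must be labeled."""
    seqs = read_fasta(fasta_path)
    labels_by_id: dict[str, int] = {}
    with open(tsv_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2 or parts[1] not in ("0", "1"):
                raise ValueError(
                    f"{tsv_path}: line {lineno}: expected 'id<TAB>0|1', got {line!r}"
                )
            labels_by_id[parts[0]] = int(parts[1])
    missing = [s.id for s in seqs if s.id not in labels_by_id]
    if missing:
        raise ValueError(f"{tsv_path}: no label for id(s) {missing[:5]}")
    return LabeledDataset(seqs, np.array([labels_by_id[s.id] for s in seqs]))


def make_split(data: LabeledDataset, fraction: float, seed: int = 1234) -> DatasetSplit:
    """Stratified random hold-out split.

    Per class, ``round(fraction * class_count)`` sequences go to the
    independent set, chosen by a seeded shuffle, so the class ratio is
    preserved within one sequence per class. Reproducible for a fixed seed.
    """
    if not 0 < fraction < 1:
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    n_neg, n_pos = data.class_counts()
    if n_neg == 0 or n_pos == 0:
        raise ValueError("both classes must be present to split")
    rng = np.random.default_rng(seed)
    test_idx: list[int] = []
    for cls in (0, 1):
        cls_idx = np.flatnonzero(data.labels == cls)
        n_test = int(round(fraction * len(cls_idx)))
        test_idx.extend(rng.permutation(cls_idx)[:n_test].tolist())
    test_set = set(test_idx)
    train_idx = [i for i in range(len(data)) if i not in test_set]
    return DatasetSplit(
        train=data.subset(train_idx),
        independent=data.subset(sorted(test_idx)),
        fraction=fraction,
        seed=seed,
    )


def write_split_manifest(
    split: DatasetSplit,
    out_dir: str | Path,
    deduplicated: bool | None = None,
) -> Path:
    """Write the four FASTA files of a split plus a JSON manifest.

    The manifest records file paths, hold-out fraction, seed and whether the
    input was redundancy-reduced upstream (this toolkit does not deduplicate).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, ds in (("train", split.train), ("independent", split.independent)):
        for cls, tag in ((1, "pos"), (0, "neg")):
            p = out_dir / f"{name}_{tag}.fasta"
            keep = [s for s, y in zip(ds.sequences, ds.labels) if y == cls]
            write_fasta(keep, p)
            paths[f"{name}_{tag}"] = p.name
    manifest = {
        "files": paths,
        "fraction": split.fraction,
        "seed": split.seed,
        "n_train": len(split.train),
        "n_independent": len(split.independent),
        "deduplicated": deduplicated,
    }
    mpath = out_dir / "split_manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2))
    return mpath
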