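"""Labelled DNA sequence I/O, one-hot encoding, and dataset splitting.

Encoding uses the channel order A, T, C, G: a length-``n_d`` sequence becomes
an ``(n_d, 4)`` binary matrix with A -> [1,0,0,0], T -> [0,1,0,0],
C -> [0,0,1,0], G -> [0,0,0,1].  Ambiguous bases (N) encode to the all-zero
row, which keeps the sequence length without injecting information.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO

#: Channel order of the one-hot encoding.
ALPHABET = "ATCG"
_BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}
_VALID = set("ACGTN")

DEFAULT_RATIOS = (0.8, 0.1, 0.1)


class SequenceFormatError(ValueError):
    """Raised for malformed records (bad base, missing/invalid label)."""


@dataclass
class DNASequence:
    """A labelled DNA sequence; bases are uppercased on construction."""

    id: str
    bases: str
    label: int

    def __post_init__(self):
        self.bases = self.bases.upper()
        if len(self.bases) == 0:
            raise SequenceFormatError(f"record {self.id!r}: empty sequence")
        for pos, b in enumerate(self.bases, start=1):
            if b not in _VALID:
                raise SequenceFormatError(
                    f"record {self.id!r}: invalid character {b!r} at position {pos}"
                )
        if self.label not in (0, 1):
            raise SequenceFormatError(f"record {self.id!r}: label must be 0 or 1, got {self.label!r}")

    def __len__(self) -> int:
        return len(self.bases)


@dataclass
class EncodedSequence:
    """One-hot matrix ``(n_d, 4)`` over channels A,T,C,G plus its label."""

    matrix: np.ndarray
    label: int
    id: str = ""

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError(f"matrix must be (n_d, 4), got {self.matrix.shape}")

    def validate(self) -> None:
        sums = self.matrix.sum(axis=1)
        if not np.all(np.isin(sums, (0, 1))):
            raise ValueError("each row must sum to 0 (N) or 1 (one-hot)")
        if not np.all(np.isin(self.matrix, (0, 1))):
            raise ValueError("matrix entries must be binary")


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------


def _parse_label(token: str, where: str) -> int:
    try:
        value = int(token)
    except ValueError:
        raise SequenceFormatError(f"{where}: invalid label {token!r}") from None
    if value not in (0, 1):
        raise SequenceFormatError(f"{where}: label must be 0 or 1, got {value}")
    return value


def _label_from_header(description: str, where: str) -> int:
    for tok in description.split()[1:]:
        if tok.startswith("label="):
            return _parse_label(tok[len("label=") :], where)
    raise SequenceFormatError(f"{where}: missing 'label=<0|1>' token in header")


def read_labelled_sequences(path, format: str = "tsv") -> list[DNASequence]:
    """Read labelled sequences from a two-column TSV or an annotated FASTA.

    TSV rows are ``sequence<TAB>label`` with no header.  FASTA headers must
    carry a ``label=<0|1>`` token after the record id.  Record order is
    preserved; any malformed record raises :class:`SequenceFormatError`
    naming the record/line.
    """
    if format == "tsv":
        records = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line:
                    continue
                parts = line.split("\t")
                if len(parts) != 2:
                    raise SequenceFormatError(
                        f"{path}:{lineno}: expected 2 tab-separated columns, got {len(parts)}"
                    )
                seq, lab = parts
                label = _parse_label(lab, f"{path}:{lineno}")
                try:
                    records.append(DNASequence(id=f"row{lineno}", bases=seq, label=label))
                except SequenceFormatError as exc:
                    raise SequenceFormatError(f"{path}:{lineno}: {exc}") from None
        return records
    if format == "fasta":
        records = []
        for rec in SeqIO.parse(str(path), "fasta"):
            label = _label_from_header(rec.description, f"{path}:{rec.id}")
            try:
                records.append(DNASequence(id=rec.id, bases=str(rec.seq), label=label))
            except SequenceFormatError as exc:
                raise SequenceFormatError(f"{path}:{rec.id}: {exc}") from None
        return records
    raise ValueError(f"unknown format {format!r}; expected 'tsv' or 'fasta'")


def sniff_format(path) -> str:
    with open(path) as fh:
        first = fh.readline()
    return "fasta" if first.startswith(">") else "tsv"


# ---------------------------------------------------------------------------
# encoding
# ---------------------------------------------------------------------------


def encode_sequence(seq: DNASequence) -> EncodedSequence:
    """One-hot encode a sequence into an ``(n_d, 4)`` binary matrix."""
    n = len(seq.bases)
    if n == 0:
        raise ValueError("cannot encode an empty sequence")
    matrix = np.zeros((n, 4), dtype=np.int8)
    for i, b in enumerate(seq.bases):
        if b != "N":
            matrix[i, _BASE_INDEX[b]] = 1
    return EncodedSequence(matrix=matrix, label=seq.label, id=seq.id)


def decode_encoding(enc: EncodedSequence) -> DNASequence:
    """Invert :func:`encode_sequence`; all-zero rows decode to N."""
    bases = []
    for i, row in enumerate(np.asarray(enc.matrix)):
        nz = np.flatnonzero(row)
        if len(nz) == 0:
            bases.append("N")
        elif len(nz) == 1:
            bases.append(ALPHABET[nz[0]])
        else:
            raise ValueError(f"row {i} has {len(nz)} nonzero entries; not one-hot")
    return DNASequence(id=enc.id or "decoded", bases="".join(bases), label=enc.label)


def encode_dataset(seqs: list[DNASequence]) -> list[EncodedSequence]:
    return [encode_sequence(s) for s in seqs]


def to_arrays(encoded: list[EncodedSequence], dtype=np.float32):
    """Stack encoded sequences into model inputs ``(n, 1, n_d, 4)`` and an
    integer label vector."""
    if not encoded:
        raise ValueError("empty dataset")
    lengths = {e.matrix.shape[0] for e in encoded}
    if len(lengths) != 1:
        raise ValueError(f"sequences have mixed lengths: {sorted(lengths)}")
    x = np.stack([e.matrix for e in encoded]).astype(dtype)[:, None, :, :]
    y = np.array([e.label for e in encoded], dtype=np.int64)
    return x, y


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------


@dataclass
class SplitDataset:
    """Disjoint, exhaustive train/validation/test partition of a dataset.

    Sizes are ``floor(r_train * n)`` and ``floor(r_val * n)``; the test part
    takes the remainder, so counts are reproducible from ``(n, ratios)``.
    """

    train: list = field(default_factory=list)
    validation: list = field(default_factory=list)
    test: list = field(default_factory=list)
    ratios: tuple = DEFAULT_RATIOS
    seed: int = 0

    def arrays(self, part: str, dtype=np.float32):
        return to_arrays(getattr(self, part), dtype=dtype)

    def __len__(self) -> int:
        return len(self.train) + len(self.validation) + len(self.test)


def split_dataset(data: list, ratios=DEFAULT_RATIOS, seed: int = 0) -> SplitDataset:
    """Randomly partition ``data``; the permutation is driven solely by
    ``seed`` (``numpy.random.default_rng(seed).permutation``)."""
    n = len(data)
    if n < 3:
        raise ValueError(f"need at least 3 records to split, got {n}")
    ratios = tuple(float(r) for r in ratios)
    if len(ratios) != 3 or any(r < 0 for r in ratios):
        raise ValueError("ratios must be three non-negative numbers")
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError(f"ratios must sum to 1, got {sum(ratios)}")
    perm = np.random.default_rng(seed).permutation(n)
    n_train = int(np.floor(ratios[0] * n))
    n_val = int(np.floor(ratios[1] * n))
    idx_train = perm[:n_train]
    idx_val = perm[n_train : n_train + n_val]
    idx_test = perm[n_train + n_val :]
    return SplitDataset(
        train=[data[i] for i in idx_train],
        validation=[data[i] for i in idx_val],
        test=[data[i] for i in idx_test],
        ratios=ratios,
        seed=seed,
    )
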