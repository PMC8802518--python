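"""Reference genome collections.

A :class:`ReferenceSet` holds the genome sequences being quantified against,
their lengths, effective lengths, and (optionally) NCBI taxids. The effective
length of a reference approximates the number of valid fragment start
positions: ``max(1, length - mean_fragment_length + 1)``.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from Bio import SeqIO

DEFAULT_MEAN_FRAGMENT_LENGTH = 300.0


@dataclass
class ReferenceSet:
    """An ordered set of reference sequences.

    Parameters
    ----------
    ids
        Reference identifiers, in index order.
    sequences
        Uppercase DNA sequences parallel to ``ids``; may be ``None`` for
        collections built from an equivalence-class table (lengths only).
    lengths
        Sequence lengths in bases.
    taxids
        Optional NCBI taxid per reference (0 = unknown).
    mean_fragment_length
        Mean sequenced-fragment length used for effective lengths.
    """

    ids: list[str]
    sequences: list[str] | None = None
    lengths: np.ndarray = field(default=None)  # type: ignore[assignment]
    taxids: np.ndarray = field(default=None)  # type: ignore[assignment]
    mean_fragment_length: float = DEFAULT_MEAN_FRAGMENT_LENGTH

    def __post_init__(self) -> None:
        if not self.ids:
            raise ValueError("reference set must contain at least one sequence")
        if self.lengths is None:
            if self.sequences is None:
                raise ValueError("either sequences or lengths must be given")
            self.lengths = np.array([len(s) for s in self.sequences], dtype=np.int64)
        else:
            self.lengths = np.asarray(self.lengths, dtype=np.int64)
        if self.sequences is not None and len(self.sequences) != len(self.ids):
            raise ValueError("ids and sequences disagree in length")
        if self.taxids is None:
            self.taxids = np.zeros(len(self.ids), dtype=np.int64)
        else:
            self.taxids = np.asarray(self.taxids, dtype=np.int64)
        self._index = {rid: i for i, rid in enumerate(self.ids)}
        if len(self._index) != len(self.ids):
            raise ValueError("duplicate reference ids")

    def __len__(self) -> int:
        return len(self.ids)

    def index_of(self, ref_id: str) -> int:
        return self._index[ref_id]

    @property
    def effective_lengths(self) -> np.ndarray:
        eff = self.lengths - self.mean_fragment_length + 1.0
        return np.maximum(eff, 1.0)

    def sequence(self, ref_id: str) -> str:
        if self.sequences is None:
            raise ValueError("reference set carries no sequences")
        return self.sequences[self._index[ref_id]]

    def set_taxids(self, taxid_of: Mapping[str, int]) -> None:
        for rid, tid in taxid_of.items():
            if rid in self._index:
                self.taxids[self._index[rid]] = tid

    @classmethod
    def from_fasta(
        cls,
        path: str | Path,
        mean_fragment_length: float = DEFAULT_MEAN_FRAGMENT_LENGTH,
    ) -> "ReferenceSet":
        """Load references from a (optionally gzipped) FASTA file."""
        path = Path(path)
        opener = gzip.open if path.suffix == ".gz" else open
        ids: list[str] = []
        seqs: list[str] = []
        with opener(path, "rt") as fh:
            for rec in SeqIO.parse(fh, "fasta"):
                ids.append(rec.id)
                seqs.append(str(rec.seq).upper())
        if not ids:
            raise ValueError(f"no sequences found in {path}")
        return cls(ids=ids, sequences=seqs, mean_fragment_length=mean_fragment_length)

    def to_fasta(self, path: str | Path, width: int = 70) -> None:
        if self.sequences is None:
            raise ValueError("reference set carries no sequences")
        with open(path, "w") as fh:
            for rid, seq in zip(self.ids, self.sequences):
                fh.write(f">{rid}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")


def load_ref_tax_map(path: str | Path) -> dict[str, int]:
    """Read a 2-column TSV (reference_id, taxid) into a mapping."""
    out: dict[str, int] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{ln}: expected 2 tab-separated columns")
            out[parts[0]] = int(parts[1])
    return out
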