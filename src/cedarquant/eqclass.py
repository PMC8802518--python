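"""Range-factorized equivalence classes of aligned fragments.

Two fragments are equivalent when they align to exactly the same set of
references; the class is labeled by that reference set and carries the
number of member fragments and one average conditional probability per
labeled reference. Range factorization additionally splits a class by
binning each fragment's per-reference conditional probabilities into a
fixed number of equal-width bins over (0, 1], so fragments with different
alignment-quality profiles are not conflated; ``bins=1`` recovers the
classical reduction.

The conditional probability of a fragment given a reference is
``exp(alpha * (score - best_score))`` — 1 for the fragment's best-scoring
reference, decaying exponentially with the score deficit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .mapper import AlignmentRecord
from .references import ReferenceSet

DEFAULT_ALPHA = 1.0
DEFAULT_BINS = 4


def score_to_conditional_prob(
    score: float, best_score_for_fragment: float, alpha: float = DEFAULT_ALPHA
) -> float:
    """Map an alignment score to Pr(fragment | reference) in (0, 1]."""
    if score > best_score_for_fragment:
        raise ValueError(
            f"score {score} exceeds the fragment's best score {best_score_for_fragment}"
        )
    return math.exp(alpha * (score - best_score_for_fragment))


def prob_bin(prob: float, bins: int) -> int:
    """Equal-width bin index of a probability over (0, 1]; bins are
    ((i/bins, (i+1)/bins]], so 1.0 always lands in the last bin."""
    if not 0.0 < prob <= 1.0:
        raise ValueError(f"probability {prob} outside (0, 1]")
    return min(bins - 1, math.ceil(prob * bins) - 1)


@dataclass
class EquivalenceClass:
    """One (possibly range-factorized) equivalence class.

    ``label`` holds reference *indices* into the owning collection's
    reference set, strictly sorted. ``positions`` optionally records the
    distinct fragment start positions per labeled reference (used by the
    coverage prior; absent when the class was loaded from a text table).
    """

    label: tuple[int, ...]
    count: int
    weights: np.ndarray
    bin_signature: tuple[int, ...] = ()
    positions: dict[int, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.label:
            raise ValueError("empty class label")
        if list(self.label) != sorted(set(self.label)):
            raise ValueError("class label must be strictly sorted")
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if len(self.weights) != len(self.label):
            raise ValueError("weights and label lengths differ")
        if np.any(self.weights <= 0):
            raise ValueError("class weights must be positive")
        if self.count < 1:
            raise ValueError("class count must be >= 1")


@dataclass
class ClassCollection:
    """All equivalence classes of a sample plus the reference view."""

    classes: list[EquivalenceClass]
    refs: ReferenceSet
    unmapped: int = 0

    @property
    def total_fragments(self) -> int:
        return sum(c.count for c in self.classes)

    def active_refs(self) -> set[int]:
        out: set[int] = set()
        for c in self.classes:
            out.update(c.label)
        return out

    def flat(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Flattened (ref_idx, class_start_ptr, counts, weights) arrays for EM.

        ``class_start_ptr`` has one entry per class (offset of its first
        label element in the flattened arrays).
        """
        sizes = np.array([len(c.label) for c in self.classes], dtype=np.int64)
        ptr = np.concatenate([[0], np.cumsum(sizes)[:-1]]) if len(sizes) else np.array([], dtype=np.int64)
        ref_idx = (
            np.concatenate([np.asarray(c.label, dtype=np.int64) for c in self.classes])
            if self.classes
            else np.array([], dtype=np.int64)
        )
        weights = (
            np.concatenate([c.weights for c in self.classes])
            if self.classes
            else np.array([], dtype=np.float64)
        )
        counts = np.array([c.count for c in self.classes], dtype=np.float64)
        return ref_idx, ptr.astype(np.int64), counts, weights


def build_classes(
    fragment_records: Iterable[tuple[str, Sequence[AlignmentRecord]]],
    refs: ReferenceSet,
    bins: int = DEFAULT_BINS,
    alpha: float = DEFAULT_ALPHA,
) -> ClassCollection:
    """Collapse per-fragment alignment records into equivalence classes.

    Each item of ``fragment_records`` is (fragment_id, records); records are
    expected to have passed the score filter already. Fragments with no
    records are tallied as unmapped. Class weights are the arithmetic mean
    of member fragments' conditional probabilities per reference.
    """
    if bins < 1:
        raise ValueError("bins must be >= 1")
    acc: dict[tuple[tuple[int, ...], tuple[int, ...]], list] = {}
    unmapped = 0
    for frag_id, records in fragment_records:
        if not records:
            unmapped += 1
            continue
        by_ref: dict[int, AlignmentRecord] = {}
        for rec in records:
            ridx = refs.index_of(rec.ref_id)
            old = by_ref.get(ridx)
            if old is None or rec.fragment_score > old.fragment_score:
                by_ref[ridx] = rec
        label = tuple(sorted(by_ref))
        best = max(r.fragment_score for r in by_ref.values())
        probs = np.array(
            [score_to_conditional_prob(by_ref[i].fragment_score, best, alpha) for i in label]
        )
        sig = tuple(prob_bin(p, bins) for p in probs) if bins > 1 else (0,) * len(label)
        key = (label, sig)
        slot = acc.get(key)
        if slot is None:
            slot = [0, np.zeros(len(label)), {i: set() for i in label}]
            acc[key] = slot
        slot[0] += 1
        slot[1] += probs
        for i in label:
            rec = by_ref[i]
            start = rec.ref_pos
            if rec.mate is not None:
                start = min(start, rec.mate.ref_pos)
            slot[2][i].add(start)

    classes = [
        EquivalenceClass(
            label=label,
            count=n,
            weights=total / n,
            bin_signature=sig,
            positions={i: np.array(sorted(pos), dtype=np.int64) for i, pos in posd.items()},
        )
        for (label, sig), (n, total, posd) in sorted(acc.items())
    ]
    return ClassCollection(classes=classes, refs=refs, unmapped=unmapped)


# ---------------------------------------------------------------------------
# plain-text class table
#
# Format: header line "#refs N"; then N reference lines
# "id<TAB>length<TAB>effective_length<TAB>taxid"; then one line per class:
# "count<TAB>label_size<TAB>idx1,idx2,...<TAB>w1,w2,...<TAB>b1,b2,..."
# (the trailing bin-signature column preserves range factorization across
# round trips; readers that ignore it recover the classical classes).


def write_class_table(collection: ClassCollection, path: str | Path) -> None:
    refs = collection.refs
    eff = refs.effective_lengths
    with open(path, "w") as fh:
        fh.write(f"#refs\t{len(refs)}\n")
        for i, rid in enumerate(refs.ids):
            fh.write(f"{rid}\t{refs.lengths[i]}\t{eff[i]:.6g}\t{refs.taxids[i]}\n")
        for c in collection.classes:
            fh.write(
                "\t".join(
                    [
                        str(c.count),
                        str(len(c.label)),
                        ",".join(map(str, c.label)),
                        ",".join(f"{w:.10g}" for w in c.weights),
                        ",".join(map(str, c.bin_signature)),
                    ]
                )
                + "\n"
            )


def read_class_table(path: str | Path) -> ClassCollection:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) != 2 or header[0] != "#refs":
            raise ValueError(f"{path}: expected '#refs\\tN' header")
        n_refs = int(header[1])
        ids, lengths, taxids = [], [], []
        for _ in range(n_refs):
            parts = fh.readline().rstrip("\n").split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}: malformed reference line")
            ids.append(parts[0])
            lengths.append(int(parts[1]))
            taxids.append(int(parts[3]))
        refs = ReferenceSet(ids=ids, lengths=np.array(lengths), taxids=np.array(taxids))
        classes = []
        for ln, line in enumerate(fh, n_refs + 2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}:{ln}: malformed class line")
            count = int(parts[0])
            size = int(parts[1])
            label = tuple(int(x) for x in parts[2].split(","))
            weights = np.array([float(x) for x in parts[3].split(",")])
            if len(label) != size or len(weights) != size:
                raise ValueError(f"{path}:{ln}: label size mismatch")
            sig = (
                tuple(int(x) for x in parts[4].split(","))
                if len(parts) > 4 and parts[4]
                else (0,) * size
            )
            classes.append(
                EquivalenceClass(label=label, count=count, weights=weights, bin_signature=sig)
            )
    return ClassCollection(classes=classes, refs=refs)
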