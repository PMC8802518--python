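"""Synthetic community simulator.

Generates reference genomes with controlled-identity *islands* (groups of
near-identical genomes obtained by mutating a shared base sequence), a
ground-truth per-genome fragment-count vector in which many genomes may be
absent, and error-bearing paired-end reads with a truth table — the inputs
needed to exercise the quantification engine end to end, and in particular
the multi-mapping-island phenomenon it exists to resolve.

The error model is substitution-only by default (uniform per-base rate);
fragment lengths are normal with mean 300 bp and SD 50 bp, matching a
typical short-insert shotgun library. Read names carry provenance as
``genome|index`` so per-read evaluation needs no auxiliary files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from ._util import revcomp
from .references import ReferenceSet

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

DEFAULT_READ_LEN = 100
DEFAULT_FRAG_MEAN = 300.0
DEFAULT_FRAG_SD = 50.0
DEFAULT_SUB_RATE = 0.002


@dataclass(frozen=True)
class IslandSpec:
    """A group of genome indices sharing a base sequence at a target
    pairwise identity (each member is independently mutated at per-base
    rate ``1 - identity``, so pairwise identity ≈ identity²)."""

    members: tuple[int, ...]
    identity: float

    def __post_init__(self) -> None:
        if not 0.9 <= self.identity < 1.0:
            raise ValueError("island identity must be in [0.9, 1.0)")
        if len(self.members) < 2:
            raise ValueError("an island needs at least 2 members")


@dataclass
class CommunityTruth:
    """Simulated genomes plus the true per-genome fragment counts."""

    genomes: ReferenceSet
    true_counts: dict[str, int]
    islands: list[IslandSpec] = field(default_factory=list)

    def __post_init__(self) -> None:
        if sum(self.true_counts.values()) <= 0:
            raise ValueError("community must contain at least one fragment")

    def truth_table(self) -> list[tuple[str, int, int]]:
        """(genome_id, taxid, true_reads) rows, in reference order."""
        refs = self.genomes
        return [
            (rid, int(refs.taxids[i]), int(self.true_counts.get(rid, 0)))
            for i, rid in enumerate(refs.ids)
        ]

    def write_truth(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("genome_id\ttaxid\ttrue_reads\n")
            for rid, taxid, n in self.truth_table():
                fh.write(f"{rid}\t{taxid}\t{n}\n")


def _random_sequence(rng: np.random.Generator, length: int) -> np.ndarray:
    return BASES[rng.integers(0, 4, size=length)]


def _mutate(rng: np.random.Generator, seq: np.ndarray, rate: float) -> np.ndarray:
    out = seq.copy()
    sites = np.nonzero(rng.random(len(seq)) < rate)[0]
    for p in sites:
        choices = BASES[BASES != out[p]]
        out[p] = choices[rng.integers(0, 3)]
    return out


def simulate_genomes(
    n: int,
    length: int,
    islands: Sequence[IslandSpec] = (),
    seed: int = 0,
    id_prefix: str = "G",
) -> ReferenceSet:
    """Simulate ``n`` genomes of the given length.

    Non-island genomes are i.i.d. uniform sequences; each island's members
    are derived from a shared base sequence by per-base substitution at rate
    ``1 - identity``. Deterministic for a fixed seed.
    """
    if length < 1000:
        raise ValueError("genome length must be >= 1000")
    member_of: dict[int, IslandSpec] = {}
    for isl in islands:
        for m in isl.members:
            if not 0 <= m < n:
                raise ValueError(f"island member {m} out of range for n={n}")
            if m in member_of:
                raise ValueError(f"genome {m} assigned to two islands")
            member_of[m] = isl

    rng = np.random.default_rng(seed)
    base: dict[int, np.ndarray] = {}
    for isl in islands:
        base[id(isl)] = _random_sequence(rng, length)
    seqs: list[str] = []
    for g in range(n):
        isl = member_of.get(g)
        if isl is None:
            arr = _random_sequence(rng, length)
        else:
            arr = _mutate(rng, base[id(isl)], 1.0 - isl.identity)
        seqs.append(arr.tobytes().decode("ascii"))
    ids = [f"{id_prefix}{g + 1}" for g in range(n)]
    return ReferenceSet(ids=ids, sequences=seqs)


def simulate_reads(
    truth: CommunityTruth,
    read_len: int = DEFAULT_READ_LEN,
    frag_mean: float = DEFAULT_FRAG_MEAN,
    frag_sd: float = DEFAULT_FRAG_SD,
    sub_rate: float = DEFAULT_SUB_RATE,
    seed: int = 0,
) -> tuple[list[tuple[str, str, str]], CommunityTruth]:
    """Draw paired-end reads matching the truth counts exactly.

    For each genome, exactly ``true_counts[g]`` fragments are placed
    uniformly over valid start positions; fragment lengths are normal
    (``frag_mean``, ``frag_sd``) truncated to [read_len, genome length].
    Mate 1 is the fragment's 5' end on the forward strand, mate 2 the
    reverse complement of its 3' end. Substitution errors are i.i.d. per
    base. The returned list of (name, mate1, mate2) is globally shuffled,
    as reads appear in random order in a real run.
    """
    if read_len > frag_mean:
        raise ValueError("read_len must not exceed frag_mean")
    rng = np.random.default_rng(seed)
    refs = truth.genomes
    pairs: list[tuple[str, str, str]] = []
    for rid in refs.ids:
        count = truth.true_counts.get(rid, 0)
        if count == 0:
            continue
        seq = refs.sequence(rid)
        if len(seq) < read_len:
            raise ValueError(f"genome {rid} is shorter than the read length")
        glen = len(seq)
        lens = np.clip(
            np.rint(rng.normal(frag_mean, frag_sd, size=count)).astype(int),
            read_len,
            glen,
        )
        for j in range(count):
            flen = int(lens[j])
            start = int(rng.integers(0, glen - flen + 1))
            frag = seq[start : start + flen]
            m1 = frag[:read_len]
            m2 = revcomp(frag[-read_len:])
            if sub_rate > 0:
                m1 = _apply_substitutions(rng, m1, sub_rate)
                m2 = _apply_substitutions(rng, m2, sub_rate)
            pairs.append((f"{rid}|{j}", m1, m2))
    order = rng.permutation(len(pairs))
    return [pairs[i] for i in order], truth


def _apply_substitutions(rng: np.random.Generator, read: str, rate: float) -> str:
    arr = np.frombuffer(read.encode("ascii"), dtype=np.uint8).copy()
    sites = np.nonzero(rng.random(len(arr)) < rate)[0]
    for p in sites:
        choices = BASES[BASES != arr[p]]
        arr[p] = choices[rng.integers(0, 3)]
    return arr.tobytes().decode("ascii")


def write_fastq_pairs(
    pairs: Sequence[tuple[str, str, str]], r1_path: str | Path, r2_path: str | Path
) -> None:
    with open(r1_path, "w") as f1, open(r2_path, "w") as f2:
        for name, m1, m2 in pairs:
            f1.write(f"@{name}/1\n{m1}\n+\n{'I' * len(m1)}\n")
            f2.write(f"@{name}/2\n{m2}\n+\n{'I' * len(m2)}\n")


def read_truth_table(path: str | Path) -> dict[str, int]:
    out: dict[str, int] = {}
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                out[parts[0]] = int(parts[2])
    return out
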