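"""Simplified selective-alignment read mapper.

Seeds are exact k-mer matches against a plain canonical k-mer hash over the
references, extended to maximal exact matches (MEMs). MEMs on the same
reference and strand are chained by a dynamic program, the regions between
chained MEMs (and at the read ends) are aligned with an affine-gap global
aligner, and the total alignment score is the sum of matched and aligned
regions. Mappings scoring below a fraction (default 65%) of the best
possible score for the fragment length are discarded.

This reproduces the mapping semantics of selective alignment at desk scale;
the index is a plain hash rather than a compacted de Bruijn graph, which is
an engineering substitution, not a change of contract.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from Bio import Align

from ._util import canonical, revcomp
from .references import ReferenceSet

FORWARD = "+"
REVERSE = "-"

#: per-base weight of the chain gap penalty in the chaining DP
CHAIN_GAP_COST = 0.01


@dataclass(frozen=True)
class ScoringScheme:
    """Alignment scoring parameters (penalties are positive magnitudes)."""

    match: int = 2
    mismatch: int = -4
    gap_open: int = 5
    gap_extend: int = 3
    min_score_fraction: float = 0.65

    def __post_init__(self) -> None:
        if self.match <= 0:
            raise ValueError("match score must be positive")
        if not 0.0 < self.min_score_fraction <= 1.0:
            raise ValueError("min_score_fraction must be in (0, 1]")

    def best_possible(self, fragment_length: int) -> int:
        return self.match * fragment_length

    def aligner(self) -> Align.PairwiseAligner:
        a = Align.PairwiseAligner()
        a.mode = "global"
        a.match_score = self.match
        a.mismatch_score = self.mismatch
        a.open_gap_score = -(self.gap_open + self.gap_extend)
        a.extend_gap_score = -self.gap_extend
        return a


@dataclass(frozen=True)
class Mem:
    """Maximal exact match between an (oriented) read and a reference."""

    read_offset: int
    ref_id: str
    ref_pos: int
    length: int
    strand: str


@dataclass
class MateAlignment:
    """Per-mate alignment within a paired record."""

    ref_pos: int
    strand: str
    score: int
    cigar: str


@dataclass
class AlignmentRecord:
    """A fragment-to-reference mapping.

    ``score``/``cigar``/``ref_pos``/``strand`` describe the first (or only)
    mate; ``mate`` carries the second mate for paired fragments.
    ``fragment_score`` is the quantity the selective-alignment filter and the
    conditional-probability model operate on (mate scores summed).
    """

    fragment_id: str
    ref_id: str
    ref_pos: int
    strand: str
    score: int
    cigar: str
    mate: MateAlignment | None = None

    @property
    def fragment_score(self) -> int:
        return self.score + (self.mate.score if self.mate else 0)


class KmerIndex:
    """Canonical k-mer hash: k-mer → list of (ref index, position, forward?)."""

    def __init__(self, k: int, refs: ReferenceSet):
        if not 5 <= k <= 31:
            raise ValueError("k must be in [5, 31]")
        if len(refs) == 0:
            raise ValueError("empty reference set")
        if all(len(s) < k for s in refs.sequences or []):
            raise ValueError("k exceeds the length of every reference")
        self.k = k
        self.refs = refs
        self.occurrences: dict[str, list[tuple[int, int, bool]]] = {}
        for ridx, seq in enumerate(refs.sequences or []):
            self._add_sequence(ridx, seq)

    def _add_sequence(self, ridx: int, seq: str) -> None:
        k = self.k
        occ = self.occurrences
        # positions of N restrict which k-mers are indexable
        next_n = _next_n_table(seq)
        for p in range(len(seq) - k + 1):
            if next_n[p] < p + k:
                continue
            canon, fwd = canonical(seq[p : p + k])
            occ.setdefault(canon, []).append((ridx, p, fwd))

    def n_occurrences(self) -> int:
        return sum(len(v) for v in self.occurrences.values())


def _next_n_table(seq: str) -> list[int]:
    """next_n[i] = smallest j >= i with seq[j] == 'N' (len(seq) if none)."""
    n = len(seq)
    out = [n] * n
    nxt = n
    for i in range(n - 1, -1, -1):
        if seq[i] == "N":
            nxt = i
        out[i] = nxt
    return out


def build_kmer_index(refs: ReferenceSet, k: int = 19) -> KmerIndex:
    """Index every N-free k-mer occurrence of every reference."""
    return KmerIndex(k, refs)


# ---------------------------------------------------------------------------
# seeding and MEM extension


def _collect_seeds(index: KmerIndex, read: str) -> dict[tuple[int, str], list[tuple[int, int]]]:
    """Seed hits grouped by (reference index, strand).

    Each hit is (offset on the *oriented* read, position on the reference),
    where the oriented read is the read itself on '+' and its reverse
    complement on '-'.
    """
    k = index.k
    occ = index.occurrences
    L = len(read)
    seeds: dict[tuple[int, str], list[tuple[int, int]]] = {}
    for p in range(L - k + 1):
        kmer = read[p : p + k]
        if "N" in kmer:
            continue
        canon, read_fwd = canonical(kmer)
        hits = occ.get(canon)
        if not hits:
            continue
        for ridx, rpos, ref_fwd in hits:
            if read_fwd == ref_fwd:
                seeds.setdefault((ridx, FORWARD), []).append((p, rpos))
            else:
                # the reverse complement of the read aligns forward
                seeds.setdefault((ridx, REVERSE), []).append((L - k - p, rpos))
    return seeds


def _extend_mems(
    oriented_read: str, ref_seq: str, hits: list[tuple[int, int]], k: int
) -> list[tuple[int, int, int]]:
    """Extend seed hits into MEMs; returns (read_offset, ref_pos, length).

    Hits on the same diagonal that fall inside an already-extended MEM are
    skipped, so each MEM is reported once.
    """
    by_diag: dict[int, list[tuple[int, int]]] = {}
    for q, r in hits:
        by_diag.setdefault(r - q, []).append((q, r))
    mems: list[tuple[int, int, int]] = []
    L = len(oriented_read)
    R = len(ref_seq)
    for diag, dhits in by_diag.items():
        dhits.sort()
        covered_until = -1
        for q, r in dhits:
            if q + k <= covered_until:
                continue
            # extend left
            while q > 0 and r > 0 and oriented_read[q - 1] == ref_seq[r - 1]:
                q -= 1
                r -= 1
            # extend right
            e = q + k
            re = r + (e - q)
            while e < L and re < R and oriented_read[e] == ref_seq[re]:
                e += 1
                re += 1
            mems.append((q, r, e - q))
            covered_until = e
    mems.sort()
    return mems


# ---------------------------------------------------------------------------
# chaining


def _chain_mems(mems: list[tuple[int, int, int]]) -> list[tuple[int, int, int]]:
    """Best colinear chain of MEMs (no overlap on read or reference).

    Chain score = sum of MEM lengths − CHAIN_GAP_COST × sum of gap spans.
    O(m²) dynamic program; m is small at desk scale.
    """
    if not mems:
        return []
    m = len(mems)
    best = [float(mem[2]) for mem in mems]
    prev = [-1] * m
    for j in range(m):
        qj, rj, lj = mems[j]
        for i in range(j):
            qi, ri, li = mems[i]
            if qi + li > qj or ri + li > rj:
                continue
            gap = max(qj - (qi + li), rj - (ri + li))
            cand = best[i] + lj - CHAIN_GAP_COST * gap
            if cand > best[j]:
                best[j] = cand
                prev[j] = i
    j = max(range(m), key=lambda i: best[i])
    chain = []
    while j != -1:
        chain.append(mems[j])
        j = prev[j]
    chain.reverse()
    return chain


# ---------------------------------------------------------------------------
# gap filling


def _merge_ops(ops: list[tuple[int, str]]) -> list[tuple[int, str]]:
    out: list[tuple[int, str]] = []
    for n, op in ops:
        if n == 0:
            continue
        if out and out[-1][1] == op:
            out[-1] = (out[-1][0] + n, op)
        else:
            out.append((n, op))
    return out


def _cigar(ops: list[tuple[int, str]]) -> str:
    return "".join(f"{n}{op}" for n, op in _merge_ops(ops))


def _align_segment(
    read_seg: str, ref_seg: str, scheme: ScoringScheme, aligner: Align.PairwiseAligner
) -> tuple[int, list[tuple[int, str]]]:
    """Affine-gap global alignment of a between-MEM (or end) segment."""
    if not read_seg and not ref_seg:
        return 0, []
    if not read_seg:
        return -(scheme.gap_open + scheme.gap_extend * len(ref_seg)), [(len(ref_seg), "D")]
    if not ref_seg:
        return -(scheme.gap_open + scheme.gap_extend * len(read_seg)), [(len(read_seg), "I")]
    aln = aligner.align(ref_seg, read_seg)[0]
    ops: list[tuple[int, str]] = []
    coords = aln.coordinates  # row 0: ref (target); row 1: read (query)
    for i in range(coords.shape[1] - 1):
        dt = int(coords[0, i + 1] - coords[0, i])
        dq = int(coords[1, i + 1] - coords[1, i])
        if dt and dq:
            ops.append((dt, "M"))
        elif dt:
            ops.append((dt, "D"))
        else:
            ops.append((dq, "I"))
    return int(aln.score), ops


def _score_chain(
    oriented_read: str,
    ref_seq: str,
    chain: list[tuple[int, int, int]],
    scheme: ScoringScheme,
    aligner: Align.PairwiseAligner,
) -> tuple[int, int, str]:
    """Fill between-MEM regions and read ends; return (score, ref_start, cigar)."""
    L = len(oriented_read)
    score = 0
    ops: list[tuple[int, str]] = []

    # left end: align the read prefix against an equally long reference window
    q0, r0, _ = chain[0]
    win_start = max(0, r0 - q0)
    s, seg_ops = _align_segment(oriented_read[:q0], ref_seq[win_start:r0], scheme, aligner)
    score += s
    ops.extend(seg_ops)
    ref_start = win_start if q0 else r0

    prev_q_end, prev_r_end = q0, r0
    for q, r, ln in chain:
        s, seg_ops = _align_segment(
            oriented_read[prev_q_end:q], ref_seq[prev_r_end:r], scheme, aligner
        )
        score += s
        ops.extend(seg_ops)
        score += scheme.match * ln
        ops.append((ln, "M"))
        prev_q_end, prev_r_end = q + ln, r + ln

    # right end
    win_end = min(len(ref_seq), prev_r_end + (L - prev_q_end))
    s, seg_ops = _align_segment(
        oriented_read[prev_q_end:], ref_seq[prev_r_end:win_end], scheme, aligner
    )
    score += s
    ops.extend(seg_ops)

    return score, ref_start, _cigar(ops)


# ---------------------------------------------------------------------------
# read- and fragment-level mapping


def _map_single(
    index: KmerIndex, read: str, scheme: ScoringScheme, aligner: Align.PairwiseAligner
) -> list[tuple[int, str, int, int, str]]:
    """Map one mate; returns (ref index, strand, ref_pos, score, cigar) hits."""
    refs = index.refs
    seeds = _collect_seeds(index, read)
    if not seeds:
        return []
    rc = None
    out = []
    for (ridx, strand), hits in seeds.items():
        oriented = read if strand == FORWARD else (rc := rc or revcomp(read))
        ref_seq = refs.sequences[ridx]  # type: ignore[index]
        mems = _extend_mems(oriented, ref_seq, hits, index.k)
        chain = _chain_mems(mems)
        if not chain:
            continue
        score, ref_start, cigar = _score_chain(oriented, ref_seq, chain, scheme, aligner)
        score = min(score, scheme.best_possible(len(read)))
        out.append((ridx, strand, ref_start, score, cigar))
    return out


def map_fragment(
    index: KmerIndex,
    refs: ReferenceSet,
    fragment_id: str,
    mate1: str,
    mate2: str | None = None,
    scheme: ScoringScheme = ScoringScheme(),
    frag_span: int = 1000,
    keep_orphans: bool = False,
) -> list[AlignmentRecord]:
    """Map a fragment (single read or read pair) against the index.

    For pairs, both mates must hit the same reference in opposite
    orientations within ``frag_span`` bases; the fragment score is the sum of
    the mate scores. A fragment with no seeds returns an empty list. Score
    filtering is a separate step (:func:`filter_by_score`).
    """
    aligner = scheme.aligner()
    hits1 = _map_single(index, mate1.upper(), scheme, aligner)
    if mate2 is None:
        return [
            AlignmentRecord(fragment_id, refs.ids[ridx], pos, strand, score, cigar)
            for ridx, strand, pos, score, cigar in hits1
        ]

    hits2 = _map_single(index, mate2.upper(), scheme, aligner)
    by_ref1: dict[int, list[tuple[str, int, int, str]]] = {}
    for ridx, strand, pos, score, cigar in hits1:
        by_ref1.setdefault(ridx, []).append((strand, pos, score, cigar))
    by_ref2: dict[int, list[tuple[str, int, int, str]]] = {}
    for ridx, strand, pos, score, cigar in hits2:
        by_ref2.setdefault(ridx, []).append((strand, pos, score, cigar))

    records: list[AlignmentRecord] = []
    for ridx in sorted(by_ref1):
        best: AlignmentRecord | None = None
        for strand, pos, score, cigar in by_ref1[ridx]:
            for m_strand, m_pos, m_score, m_cigar in by_ref2.get(ridx, []):
                if m_strand == strand:
                    continue
                span = max(pos, m_pos) + max(len(mate1), len(mate2)) - min(pos, m_pos)
                if span > frag_span:
                    continue
                rec = AlignmentRecord(
                    fragment_id,
                    refs.ids[ridx],
                    pos,
                    strand,
                    score,
                    cigar,
                    mate=MateAlignment(m_pos, m_strand, m_score, m_cigar),
                )
                if best is None or rec.fragment_score > best.fragment_score:
                    best = rec
        if best is not None:
            records.append(best)

    if not records and keep_orphans:
        # orphan fallback: report the better mate alone at half weight
        pool = [(h, 1) for h in hits1] + [(h, 2) for h in hits2]
        if pool:
            (ridx, strand, pos, score, cigar), _ = max(pool, key=lambda t: t[0][3])
            records.append(
                AlignmentRecord(fragment_id, refs.ids[ridx], pos, strand, score, cigar)
            )
    return records


def filter_by_score(
    records: Sequence[AlignmentRecord],
    fragment_length: int,
    scheme: ScoringScheme = ScoringScheme(),
) -> list[AlignmentRecord]:
    """Keep mappings scoring at least ``min_score_fraction`` of the best
    possible score for the fragment length (mate lengths summed for pairs);
    the threshold is inclusive."""
    threshold = scheme.min_score_fraction * scheme.best_possible(fragment_length)
    return [r for r in records if r.fragment_score >= threshold]


def cigar_score(cigar: str, read: str, ref: str, ref_pos: int, scheme: ScoringScheme) -> int:
    """Recompute an alignment score from its CIGAR and the sequences.

    Used as a self-check: for every emitted record this must reproduce the
    stored per-mate score exactly.
    """
    import re

    score = 0
    q = 0
    r = ref_pos
    for n_str, op in re.findall(r"(\d+)([MIDNSHP=X])", cigar):
        n = int(n_str)
        if op == "M":
            for i in range(n):
                score += scheme.match if read[q + i] == ref[r + i] else scheme.mismatch
            q += n
            r += n
        elif op == "I":
            score -= scheme.gap_open + scheme.gap_extend * n
            q += n
        elif op == "D":
            score -= scheme.gap_open + scheme.gap_extend * n
            r += n
        else:
            raise ValueError(f"unsupported CIGAR op {op!r}")
    return score
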