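"""SAM input and output for the mapper and the quantification engine.

Multi-mappings are emitted as secondary records; the per-mate alignment
score travels in the standard ``AS:i:`` tag, which is also the only tag the
reader requires, so alignments from external tools can feed the engine.
Coordinates are 0-based internally and 1-based in SAM, as usual.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterator, Sequence

import pysam

from ._util import revcomp
from .mapper import AlignmentRecord, MateAlignment
from .references import ReferenceSet


def sam_header(refs: ReferenceSet, program_line: str | None = None) -> pysam.AlignmentHeader:
    d: dict = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": rid, "LN": int(ln)} for rid, ln in zip(refs.ids, refs.lengths)],
    }
    if program_line:
        d["PG"] = [{"ID": "cedarquant", "PN": "cedarquant", "CL": program_line}]
    return pysam.AlignmentHeader.from_dict(d)


def _make_segment(
    header: pysam.AlignmentHeader,
    name: str,
    ref_id: str,
    pos: int,
    strand: str,
    score: int,
    cigar: str,
    seq: str,
    *,
    paired: bool,
    first: bool,
    mate: MateAlignment | None,
    secondary: bool,
) -> pysam.AlignedSegment:
    a = pysam.AlignedSegment(header)
    a.query_name = name
    flag = 0
    if paired:
        flag |= 0x1 | 0x2 | (0x40 if first else 0x80)
        if mate is not None and mate.strand == "-":
            flag |= 0x20
    if strand == "-":
        flag |= 0x10
        seq = revcomp(seq)
    if secondary:
        flag |= 0x100
    a.flag = flag
    a.reference_id = header.get_tid(ref_id)
    a.reference_start = pos
    a.mapping_quality = 0 if secondary else 255
    a.cigarstring = cigar
    if not secondary:
        a.query_sequence = seq
        a.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
    if paired and mate is not None:
        a.next_reference_id = a.reference_id
        a.next_reference_start = mate.ref_pos
    a.set_tag("AS", int(score))
    return a


def write_sam(
    path: str | Path,
    refs: ReferenceSet,
    fragments: Iterator[tuple[str, str, str | None, Sequence[AlignmentRecord]]],
    program_line: str | None = None,
) -> int:
    """Write per-fragment alignment records to a SAM file.

    ``fragments`` yields (fragment_id, mate1_seq, mate2_seq_or_None, records).
    Records are ranked by fragment score; the best one is primary. Returns
    the number of fragments written with at least one record.
    """
    header = sam_header(refs, program_line)
    n_mapped = 0
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for frag_id, seq1, seq2, records in fragments:
            if not records:
                continue
            n_mapped += 1
            ranked = sorted(records, key=lambda r: (-r.fragment_score, r.ref_id))
            for rank, rec in enumerate(ranked):
                secondary = rank > 0
                paired = rec.mate is not None
                out.write(
                    _make_segment(
                        header, frag_id, rec.ref_id, rec.ref_pos, rec.strand,
                        rec.score, rec.cigar, seq1,
                        paired=paired, first=True, mate=rec.mate, secondary=secondary,
                    )
                )
                if paired and seq2 is not None:
                    back = MateAlignment(rec.ref_pos, rec.strand, rec.score, rec.cigar)
                    out.write(
                        _make_segment(
                            header, frag_id, rec.ref_id, rec.mate.ref_pos,
                            rec.mate.strand, rec.mate.score, rec.mate.cigar, seq2,
                            paired=True, first=False, mate=back, secondary=secondary,
                        )
                    )
    return n_mapped


def read_sam_fragments(path: str | Path) -> Iterator[tuple[str, list[AlignmentRecord]]]:
    """Group SAM records into per-fragment :class:`AlignmentRecord` lists.

    Requires the ``AS:i:`` tag on every mapped record. Records sharing a
    query name form one fragment; mate pairs on the same reference are
    joined. Assumes the file is query-grouped (as written by the mapper);
    unmapped records are skipped.
    """
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        current: str | None = None
        bucket: list[pysam.AlignedSegment] = []
        for seg in fh:
            if seg.is_unmapped:
                continue
            if current is not None and seg.query_name != current:
                yield current, _bucket_to_records(current, bucket)
                bucket = []
            current = seg.query_name
            bucket.append(seg)
        if current is not None:
            yield current, _bucket_to_records(current, bucket)


def _bucket_to_records(name: str, segs: list[pysam.AlignedSegment]) -> list[AlignmentRecord]:
    singles: list[AlignmentRecord] = []
    firsts: dict[tuple[str, int], pysam.AlignedSegment] = {}
    seconds: dict[tuple[str, int], pysam.AlignedSegment] = {}
    for seg in segs:
        key = (seg.reference_name, seg.reference_start)
        if not seg.is_paired:
            singles.append(
                AlignmentRecord(
                    name, seg.reference_name, seg.reference_start,
                    "-" if seg.is_reverse else "+",
                    int(seg.get_tag("AS")), seg.cigarstring or "",
                )
            )
        elif seg.is_read2:
            seconds[key] = seg
        else:
            firsts[key] = seg

    # join mates by the mate-position cross-reference
    used: set[tuple[str, int]] = set()
    for key, seg in firsts.items():
        mate_key = (seg.reference_name, seg.next_reference_start)
        mate = seconds.get(mate_key)
        rec = AlignmentRecord(
            name, seg.reference_name, seg.reference_start,
            "-" if seg.is_reverse else "+",
            int(seg.get_tag("AS")), seg.cigarstring or "",
        )
        if mate is not None:
            used.add(mate_key)
            rec.mate = MateAlignment(
                mate.reference_start, "-" if mate.is_reverse else "+",
                int(mate.get_tag("AS")), mate.cigarstring or "",
            )
        singles.append(rec)
    for key, seg in seconds.items():
        if key in used:
            continue
        singles.append(
            AlignmentRecord(
                name, seg.reference_name, seg.reference_start,
                "-" if seg.is_reverse else "+",
                int(seg.get_tag("AS")), seg.cigarstring or "",
            )
        )
    return singles
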