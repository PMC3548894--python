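"""The full analysis pipeline: demultiplex, assign, locate regions, call,
aggregate.

Per read: the trimmed sequence is oriented to the forward reference strand
(reverse-strand reads are reverse-complemented, so all coordinates are
forward-frame), the word occurrence pattern is turned into polymorphic
regions, and each region is analyzed -- character-by-character comparison
first, dynamic programming only for complex regions.  Terminal regions not
anchored by a matching word keep the read globally aligned while reference
overhang at the unanchored edge is reported as truncation, not mutation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import pandas as pd

from .align import Alignment, DPScoring, align_nw, align_semiglobal
from .calling import (
    COMPLEX,
    MutationCall,
    alignment_to_calls,
    call_simple,
    format_calls,
)
from .dna import revcomp
from .index import IndexParams, ReferenceRecord, SubwordIndex, build_index, match_words
from .regions import PolymorphicRegion, UnalignableReadError, locate_regions
from .reporting import ReportRow, aggregate
from .screening import (
    DEFAULT_MIN_READ_LENGTH,
    DEFAULT_MIN_SHARED_WORDS,
    BarcodeMode,
    MultiplexTable,
    ReadAssignment,
    screen_reads,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Analysis parameters for one pipeline run."""

    params: IndexParams = field(default_factory=IndexParams)
    scoring: DPScoring = field(default_factory=DPScoring)
    min_shared_words: int = DEFAULT_MIN_SHARED_WORDS
    min_read_length: int = DEFAULT_MIN_READ_LENGTH
    barcode_mode: BarcodeMode = "single"


@dataclass
class ReadResult:
    """Outcome of analyzing one assigned read."""

    read_id: str
    sample_id: str
    reference: str
    strand: Literal["forward", "reverse"]
    calls: list[MutationCall]
    truncated: bool = False
    unalignable: bool = False

    @property
    def mutations(self) -> str:
        return format_calls(self.calls)


@dataclass
class PipelineResult:
    results: list[ReadResult]
    rejections: list[tuple[str, str]]
    report: list[ReportRow]
    counts: dict[str, int]

    def per_read_frame(self) -> pd.DataFrame:
        rows = [
            (
                r.read_id,
                r.sample_id,
                r.reference,
                r.strand,
                "unalignable" if r.unalignable else "ok",
                r.mutations,
                int(r.truncated),
            )
            for r in self.results
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "read_id",
                "sample",
                "reference",
                "strand",
                "status",
                "mutations",
                "truncated",
            ],
        )

    def calls_by_read(self) -> dict[str, frozenset[str]]:
        return {
            r.read_id: frozenset(c.name for c in r.calls)
            for r in self.results
            if not r.unalignable
        }


def build_indexes(
    references: Sequence[ReferenceRecord], params: IndexParams
) -> dict[str, tuple[SubwordIndex, SubwordIndex]]:
    """Forward/reverse-complement indexes per reference, in input order."""
    return {ref.name: build_index(ref, params) for ref in references}


def _terminal_alignment(
    ref_seg: str, read_seg: str, region: PolymorphicRegion, scoring: DPScoring
) -> tuple[Alignment, bool]:
    """Align a terminal (unanchored) region.

    The read bases are aligned globally -- a substitution at the very first
    read base must stay a substitution -- while reference sequence beyond
    the read's reach at the unanchored edge is skipped freely: that overhang
    is a truncation, not a deletion.  A purely local alignment would be free
    to wander off-diagonal near the terminus and fabricate indel pairs,
    which is why the read side is kept global.
    """
    aln = align_semiglobal(
        ref_seg,
        read_seg,
        scoring,
        free_prefix=not region.anchored_left,
        free_suffix=not region.anchored_right,
    )
    truncated = aln.a_start > 0 or aln.a_end < len(ref_seg)
    return aln, truncated


def _deletion_reaches_end(reference: str, call: MutationCall) -> bool:
    """True if an equivalent placement of the deletion is flush with the
    reference 3' end (right-shifting over equal bases)."""
    d = call.ref_position - 1
    k = len(call.ref_allele)
    while d + k < len(reference) and reference[d + k] == reference[d]:
        d += 1
    return d + k == len(reference)


def analyze_region(
    region: PolymorphicRegion,
    reference: str,
    read: str,
    config: RunConfig,
) -> tuple[list[MutationCall], bool]:
    """Call mutations in one polymorphic region.

    Returns ``(calls, truncated)``.
    """
    ref_seg = reference[region.ref_start : region.ref_end]
    read_seg = read[region.read_start : region.read_end]
    w = config.params.w

    if region.read_length == 0 and not region.anchored:
        # terminal region with no read support: truncation, nothing to call
        return [], region.ref_length > 0
    if region.ref_length == 0 and not region.anchored:
        # read tail beyond the reference end: unaligned, nothing to call
        return [], region.read_length > 0

    result = call_simple(
        ref_seg,
        read_seg,
        reference=reference,
        ref_offset=region.ref_start,
        w=w,
    )
    if result != COMPLEX:
        calls = list(result)
        if not region.anchored:
            # a deletion flush with the unanchored outer edge has no read
            # support distinguishing it from a truncated read: report the
            # missing reference as truncation, not as a mutation
            kept = []
            truncated = False
            for c in calls:
                if c.kind == "deletion" and (
                    (not region.anchored_left and c.ref_position == 1)
                    or (
                        not region.anchored_right
                        and _deletion_reaches_end(reference, c)
                    )
                ):
                    truncated = True
                else:
                    kept.append(c)
            return kept, truncated
        return calls, False

    if region.anchored:
        aln = align_nw(ref_seg, read_seg, config.scoring)
        return alignment_to_calls(aln, region.ref_start, reference), False
    aln, truncated = _terminal_alignment(ref_seg, read_seg, region, config.scoring)
    return alignment_to_calls(aln, region.ref_start, reference), truncated


def analyze_read(
    assignment: ReadAssignment,
    indexes: Mapping[str, tuple[SubwordIndex, SubwordIndex]],
    config: RunConfig,
) -> ReadResult:
    """Locate regions and call mutations for one screened read.

    Reverse-strand reads are reverse-complemented first, so calls come out
    in forward-reference coordinates with ``strand_observed == "reverse"``.
    """
    fwd_index = indexes[assignment.reference][0]
    reference = fwd_index.reference.sequence
    read = (
        assignment.trimmed
        if assignment.strand == "forward"
        else revcomp(assignment.trimmed)
    )
    occurrences = match_words(read, fwd_index)
    result = ReadResult(
        assignment.read_id,
        assignment.sample_id,
        assignment.reference,
        assignment.strand,
        calls=[],
    )
    try:
        regions = locate_regions(read, fwd_index, occurrences)
    except UnalignableReadError:
        result.unalignable = True
        return result
    for region in regions:
        calls, truncated = analyze_region(region, reference, read, config)
        result.calls.extend(
            MutationCall(
                c.kind,
                c.ref_position,
                c.ref_allele,
                c.alt_allele,
                strand_observed=assignment.strand,
                complex_region=c.complex_region,
            )
            for c in calls
        )
        result.truncated = result.truncated or truncated
    return result


def run_pipeline(
    references: Sequence[ReferenceRecord],
    reads: Sequence[tuple[str, str]],
    config: RunConfig | None = None,
    *,
    multiplex: MultiplexTable | None = None,
) -> PipelineResult:
    """Run the whole pipeline on in-memory inputs.

    When ``multiplex`` is None the reads are treated as unbarcoded and all
    assigned to one sample.  Stage counts satisfy
    ``reads_in == rejected_mid + rejected_length + rejected_words + assigned``.
    """
    config = config or RunConfig()
    indexes = build_indexes(references, config.params)
    assignments, rejections = screen_reads(
        reads,
        indexes,
        multiplex,
        config.barcode_mode,
        min_shared_words=config.min_shared_words,
        min_read_length=config.min_read_length,
    )
    results = [analyze_read(a, indexes, config) for a in assignments]
    report = aggregate(
        [
            (r.sample_id, r.reference, r.strand, r.calls)
            for r in results
            if not r.unalignable
        ]
    )
    reasons = [reason for _, reason in rejections]
    counts = {
        "reads_in": len(reads),
        "rejected_mid": reasons.count("no intact MID"),
        "rejected_length": reasons.count("read too short"),
        "rejected_words": reasons.count("too few shared words"),
        "assigned": len(assignments),
        "unalignable": sum(r.unalignable for r in results),
        "mutant": sum(bool(r.calls) for r in results),
        "truncated": sum(r.truncated for r in results),
    }
    logger.info("pipeline counts: %s", counts)
    return PipelineResult(results, rejections, report, counts)


def detection_rate(
    calls_by_read: Mapping[str, frozenset[str]],
    truth: Mapping[str, frozenset[str]],
) -> float:
    """Percent of truth reads whose call set exactly equals the truth set.

    A read missing from ``calls_by_read`` (rejected or unalignable) counts
    as a miss.
    """
    if not truth:
        raise ValueError("empty truth set")
    hits = sum(
        1
        for read_id, names in truth.items()
        if calls_by_read.get(read_id) == names
    )
    return 100.0 * hits / len(truth)
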