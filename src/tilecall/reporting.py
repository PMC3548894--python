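"""Aggregation of per-read calls into the per-sample mutation frequency table.

One output row per distinct (sample, reference, mutation name): its percent
among all reads assigned to the (sample, reference) pair, the forward and
reverse-complement read tallies, and the total read count.  Mutations whose
variant sequence exceeds 5 nt are shown abbreviated by their length, with the
full name in the Annotation column.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .calling import MutationCall

REPORT_COLUMNS = [
    "Sample",
    "Reference",
    "Mutation",
    "Percent",
    "Forw",
    "Rev",
    "Mut no.",
    "Reads",
    "Annotation",
]

_ABBREVIATION_LIMIT = 5  # nt; longer variant sequences are shown by length


@dataclass(frozen=True)
class ReportRow:
    sample: str
    reference: str
    mutation: str
    percent: float
    forw: int
    rev: int
    mut_no: int
    reads: int
    annotation: str


def _display_name(call: MutationCall) -> tuple[str, str]:
    """(mutation column, annotation column) for one call."""
    full = call.name
    if call.kind == "deletion" and len(call.ref_allele) > _ABBREVIATION_LIMIT:
        return f"{call.ref_position}del{len(call.ref_allele)}", full
    if call.kind == "insertion" and len(call.alt_allele) > _ABBREVIATION_LIMIT:
        return f"{call.ref_position}ins{len(call.alt_allele)}", full
    return full, ""


def aggregate(
    read_records: Sequence[tuple[str, str, str, Sequence[MutationCall]]],
) -> list[ReportRow]:
    """Aggregate per-read calls into report rows.

    Parameters
    ----------
    read_records
        One tuple per assigned read:
        ``(sample, reference, strand, calls)`` with strand ``"forward"`` or
        ``"reverse"``.  Wild-type reads contribute an empty call list; they
        count toward the Reads denominator but get no row.

    Notes
    -----
    A read carrying k distinct mutations contributes to k rows, so "Mut no."
    counts mutation observations, not reads.
    """
    totals: dict[tuple[str, str], int] = {}
    tallies: dict[tuple[str, str, str], dict] = {}
    for sample, reference, strand, calls in read_records:
        pair = (sample, reference)
        totals[pair] = totals.get(pair, 0) + 1
        for call in calls:
            shown, annotation = _display_name(call)
            key = (sample, reference, shown)
            entry = tallies.setdefault(
                key, {"forw": 0, "rev": 0, "annotation": annotation}
            )
            if strand == "reverse":
                entry["rev"] += 1
            else:
                entry["forw"] += 1
    rows = []
    for (sample, reference, shown), entry in tallies.items():
        reads = totals[(sample, reference)]
        mut_no = entry["forw"] + entry["rev"]
        rows.append(
            ReportRow(
                sample=sample,
                reference=reference,
                mutation=shown,
                percent=100.0 * mut_no / reads,
                forw=entry["forw"],
                rev=entry["rev"],
                mut_no=mut_no,
                reads=reads,
                annotation=entry["annotation"],
            )
        )
    rows.sort(key=lambda r: (r.sample, r.reference, -r.percent, r.mutation))
    return rows


def report_frame(rows: Sequence[ReportRow]) -> pd.DataFrame:
    """Report rows as a DataFrame with the canonical column headers."""
    data = [
        (
            r.sample,
            r.reference,
            r.mutation,
            round(r.percent, 2),
            r.forw,
            r.rev,
            r.mut_no,
            r.reads,
            r.annotation,
        )
        for r in rows
    ]
    return pd.DataFrame(data, columns=REPORT_COLUMNS)


def write_report(rows: Sequence[ReportRow], path) -> None:
    report_frame(rows).to_csv(path, sep="\t", index=False, float_format="%.2f")
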