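"""File input/output: FASTA/FASTQ, multiplex tables, tabular results."""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .dna import normalize
from .index import ReferenceRecord
from .screening import MultiplexTable


def _fasta_format(path: str | Path) -> str:
    suffix = Path(path).suffix.lower()
    return "fastq" if suffix in {".fastq", ".fq"} else "fasta"


def read_sequences(path: str | Path) -> list[tuple[str, str]]:
    """Read (id, sequence) pairs from FASTA or FASTQ (qualities ignored)."""
    records = []
    for rec in SeqIO.parse(str(path), _fasta_format(path)):
        records.append((rec.id, normalize(str(rec.seq))))
    return records


def read_references(path: str | Path) -> list[ReferenceRecord]:
    """Read reference amplicons from multi-record FASTA; names must be unique."""
    refs = [ReferenceRecord(name, seq) for name, seq in read_sequences(path)]
    names = [r.name for r in refs]
    dupes = {n for n in names if names.count(n) > 1}
    if dupes:
        raise ValueError(f"duplicate reference names: {sorted(dupes)}")
    if not refs:
        raise ValueError(f"no reference sequences found in {path}")
    return refs


def read_mids(path: str | Path) -> dict[str, str]:
    """Read MID (barcode) sequences from FASTA, keyed by record id."""
    mids = dict(read_sequences(path))
    if not mids:
        raise ValueError(f"no MID sequences found in {path}")
    return mids


def read_multiplex(path: str | Path, mids: dict[str, str]) -> MultiplexTable:
    """Parse the tab-delimited multiplex file.

    Columns: ``sample_id <tab> mid_name_5prime [<tab> mid_name_3prime]``.
    Lines starting with ``#`` are comments.
    """
    entries: dict[str, tuple[str, ...]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) not in (2, 3):
            raise ValueError(
                f"{path}:{lineno}: expected 2 or 3 tab-separated fields"
            )
        sample = fields[0]
        if sample in entries:
            raise ValueError(f"{path}:{lineno}: duplicate sample {sample!r}")
        entries[sample] = tuple(fields[1:])
    return MultiplexTable(entries, mids)


def write_fasta(
    path: str | Path, records: Iterable[tuple[str, str]]
) -> None:
    recs = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in records
    ]
    SeqIO.write(recs, str(path), "fasta")


def write_truth_tsv(
    path: str | Path, truth: Sequence[tuple[str, str]]
) -> None:
    """Write ground-truth mutations: read_id <tab> comma-joined names."""
    with open(path, "w") as fh:
        fh.write("read_id\tmutations\n")
        for read_id, names in truth:
            fh.write(f"{read_id}\t{names}\n")


def read_truth_tsv(path: str | Path) -> dict[str, frozenset[str]]:
    """Read a ground-truth TSV into read_id -> set of mutation names."""
    truth: dict[str, frozenset[str]] = {}
    lines = Path(path).read_text().splitlines()
    for line in lines[1:]:
        if not line.strip():
            continue
        read_id, _, names = line.partition("\t")
        truth[read_id] = frozenset(n for n in names.split(",") if n)
    return truth
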