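"""Training-set assembly from DSSP output.

Parses classic fixed-column DSSP text, extracts maximal same-code residue
runs as labelled peptide segments, applies the length (4-130), class
(β-bridge excluded) and resolution (<= 2 Å) filters, and merges segments
into unique-sequence multi-label records: a sequence observed under several
structure codes is labelled with all of them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, TextIO

import pandas as pd

from .peptide_chem import SDFRecord, build_peptide_graph
from .sspr import SSP_CLASSES

__all__ = [
    "DsspChain",
    "DsspParseError",
    "SSPSegment",
    "SSPRecord",
    "parse_dssp",
    "extract_segments",
    "filter_by_resolution",
    "assemble_training_set",
    "cooccurrence_table",
    "records_to_sdf",
    "sdf_to_records",
    "read_resolution_table",
    "write_segments_tsv",
    "read_segments_tsv",
]

# fixed 0-based columns of the classic DSSP residue table
_COL_CHAIN = 11
_COL_AA = 13
_COL_SS = 16


class DsspParseError(ValueError):
    pass


@dataclass(frozen=True)
class DsspChain:
    chain_id: str
    sequence: str
    codes: str  # same length; blank structure mapped to "C"


@dataclass(frozen=True)
class SSPSegment:
    sequence: str
    ssp: str
    pdb_id: str = ""
    chain: str = ""
    start: int = 1  # 1-based residue position within the chain
    resolution: float | None = None


@dataclass(frozen=True)
class SSPRecord:
    sequence: str
    labels: frozenset[str]
    sources: tuple[tuple[str, str, int], ...] = ()


def parse_dssp(source: TextIO | str | Path) -> tuple[list[DsspChain], dict]:
    """Parse classic fixed-column DSSP output into per-chain strings.

    Blank structure codes become ``C`` (coil is DSSP's unlabeled state) and
    lowercase residue letters (disulfide-bonded cysteines) become ``C``
    (cysteine).  ``!`` rows split chains.
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            return parse_dssp(fh)
    lines = source.read().splitlines()
    metadata: dict[str, str] = {}
    start = None
    for i, line in enumerate(lines):
        if line.lstrip().startswith("#") and "RESIDUE" in line and "AA" in line:
            start = i + 1
            break
        if line.startswith("HEADER"):
            tokens = line.rstrip(" .").split()
            if tokens and len(tokens[-1]) == 4:
                metadata["pdb_id"] = tokens[-1]
    if start is None:
        raise DsspParseError("missing DSSP data header ('#  RESIDUE AA STRUCTURE ...')")

    chains: list[DsspChain] = []
    seq_chars: list[str] = []
    code_chars: list[str] = []
    chain_id = ""

    def flush() -> None:
        nonlocal seq_chars, code_chars
        if seq_chars:
            chains.append(DsspChain(chain_id, "".join(seq_chars), "".join(code_chars)))
        seq_chars, code_chars = [], []

    for lineno, line in enumerate(lines[start:], start=start + 1):
        if not line.strip():
            continue
        if len(line) <= _COL_AA:
            raise DsspParseError(f"line {lineno}: residue line too short")
        aa = line[_COL_AA]
        if aa == "!":
            flush()
            continue
        if aa.islower():
            aa = "C"  # SS-bonded cysteine
        ss = line[_COL_SS] if len(line) > _COL_SS else " "
        if ss == " ":
            ss = "C"
        if not seq_chars:
            chain_id = line[_COL_CHAIN].strip() if len(line) > _COL_CHAIN else ""
        seq_chars.append(aa)
        code_chars.append(ss)
    flush()
    for ch in chains:
        if len(ch.sequence) != len(ch.codes):
            raise DsspParseError("sequence/code length mismatch")  # pragma: no cover
    return chains, metadata


def extract_segments(
    sequence: str,
    codes: str,
    min_len: int = 4,
    max_len: int = 130,
    pdb_id: str = "",
    chain: str = "",
    resolution: float | None = None,
    excluded: frozenset[str] = frozenset({"B"}),
) -> list[SSPSegment]:
    """Maximal runs of a single structure code, filtered by length and class."""
    if len(sequence) != len(codes):
        raise ValueError(
            f"sequence length {len(sequence)} != codes length {len(codes)}"
        )
    segments: list[SSPSegment] = []
    i, n = 0, len(codes)
    while i < n:
        j = i
        while j < n and codes[j] == codes[i]:
            j += 1
        length = j - i
        if min_len <= length <= max_len and codes[i] not in excluded:
            segments.append(
                SSPSegment(
                    sequence=sequence[i:j],
                    ssp=codes[i],
                    pdb_id=pdb_id,
                    chain=chain,
                    start=i + 1,
                    resolution=resolution,
                )
            )
        i = j
    return segments


def filter_by_resolution(
    segments: Iterable[SSPSegment],
    max_res: float = 2.0,
    keep_missing: bool = False,
) -> list[SSPSegment]:
    """Keep segments whose structure resolution is at most ``max_res`` Å."""
    out = []
    for seg in segments:
        if seg.resolution is None:
            if keep_missing:
                out.append(seg)
        elif seg.resolution <= max_res:
            out.append(seg)
    return out


def assemble_training_set(segments: Iterable[SSPSegment]) -> list[SSPRecord]:
    """One record per unique sequence; labels are the union of observed codes.

    Output is sorted by sequence, so assembly is order-independent and
    idempotent.
    """
    by_seq: dict[str, tuple[set[str], list[tuple[str, str, int]]]] = {}
    for seg in segments:
        labels, sources = by_seq.setdefault(seg.sequence, (set(), []))
        labels.add(seg.ssp)
        sources.append((seg.pdb_id, seg.chain, seg.start))
    return [
        SSPRecord(seq, frozenset(labels), tuple(sorted(set(sources))))
        for seq, (labels, sources) in sorted(by_seq.items())
    ]


def cooccurrence_table(
    records: Iterable[SSPRecord],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Class co-occurrence over unique sequences.

    Off-diagonal cell (r, c) counts sequences labelled with both r and c;
    the diagonal counts sequences labelled with that class only.  The
    second frame normalizes each non-empty column to sum to 100.
    """
    counts = pd.DataFrame(0, index=list(SSP_CLASSES), columns=list(SSP_CLASSES))
    for rec in records:
        labels = sorted(rec.labels)
        if len(labels) == 1:
            counts.loc[labels[0], labels[0]] += 1
        else:
            for r in labels:
                for c in labels:
                    if r != c:
                        counts.loc[r, c] += 1
    col_sums = counts.sum(axis=0)
    percent = counts.astype(float)
    nonzero = col_sums > 0
    percent.loc[:, nonzero] = 100.0 * counts.loc[:, nonzero] / col_sums[nonzero]
    return counts, percent


# ---------------------------------------------------------------------------
# Interchange formats


def records_to_sdf(records: Iterable[SSPRecord]) -> list[SDFRecord]:
    """Materialize records as molecular graphs with label data fields."""
    out = []
    for rec in records:
        graph = build_peptide_graph(rec.sequence, name=rec.sequence)
        props = {"SSP_TYPE": ";".join(sorted(rec.labels)), "SEQUENCE": rec.sequence}
        if rec.sources:
            pdb_id, chain, start = rec.sources[0]
            if pdb_id:
                props["PDB_ID"] = pdb_id
            if chain:
                props["CHAIN"] = chain
        out.append(SDFRecord(graph, props))
    return out


def sdf_to_records(sdf_records: Iterable[SDFRecord]) -> list[SSPRecord]:
    """Recover (sequence, labels) records from SDF data fields."""
    out = []
    for rec in sdf_records:
        seq = rec.properties.get("SEQUENCE") or rec.graph.name
        labels = frozenset(
            x for x in rec.properties.get("SSP_TYPE", "").split(";") if x
        )
        if not labels:
            raise ValueError(f"record {seq!r} lacks an SSP_TYPE data field")
        out.append(SSPRecord(seq, labels))
    return out


def read_resolution_table(source: str | Path | TextIO) -> dict[str, float]:
    """Sidecar metadata TSV: columns pdb_id, resolution[, method]."""
    df = pd.read_csv(source, sep="\t")
    if "pdb_id" not in df.columns or "resolution" not in df.columns:
        raise ValueError("metadata TSV needs 'pdb_id' and 'resolution' columns")
    return {
        str(row.pdb_id): float(row.resolution)
        for row in df.itertuples()
        if pd.notna(row.resolution)
    }


_SEGMENT_COLUMNS = ["sequence", "ssp", "pdb_id", "chain", "start", "resolution"]


def write_segments_tsv(segments: Sequence[SSPSegment], sink: str | Path | TextIO) -> None:
    pd.DataFrame(
        [
            (s.sequence, s.ssp, s.pdb_id, s.chain, s.start, s.resolution)
            for s in segments
        ],
        columns=_SEGMENT_COLUMNS,
    ).to_csv(sink, sep="\t", index=False)


def read_segments_tsv(source: str | Path | TextIO) -> list[SSPSegment]:
    df = pd.read_csv(source, sep="\t", keep_default_na=False, na_values=[""])
    return [
        SSPSegment(
            sequence=str(row.sequence),
            ssp=str(row.ssp),
            pdb_id=str(row.pdb_id) if pd.notna(row.pdb_id) else "",
            chain=str(row.chain) if pd.notna(row.chain) else "",
            start=int(row.start),
            resolution=float(row.resolution) if pd.notna(row.resolution) else None,
        )
        for row in df.itertuples()
    ]
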