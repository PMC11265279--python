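"""Readers and writers for the plain-text formats the pipeline touches.

FASTA carries contigs and the dairy-phage reference catalog, PSL carries
externally computed pairwise alignments (BLAT dialect), and TSV carries
count tables, sample metadata, tool quality reports, genus tables and
plate counts. Every count table travels as a :class:`CountMatrix` with an
explicit normalization-state flag so downstream stages can assert the
state they require.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("rindvirome")

STAGES = ("W1", "W2", "W3", "W4", "W5")
YEARS = ("2017", "2019", "2022")
REPLICATES = ("A", "B", "C")
QUALITY_TIERS = ("complete", "high", "medium", "low", "not_determined")
COUNT_STATES = ("raw", "rarefied", "coverage", "relative")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ContigRecord:
    """A named DNA sequence (alphabet A/C/G/T/N, stored uppercase)."""

    id: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ToolReport:
    """Per-contig labels emulating the VIBRANT / CheckV / VirSorter2 / iPHoP reports."""

    contig_id: str
    vibrant_quality: str | None = None
    vibrant_lifestyle: str | None = None
    checkv_quality: str | None = None
    virsorter2_label: str | None = None
    iphop_genus: str | None = None

    def __post_init__(self) -> None:
        for tier in (self.vibrant_quality, self.checkv_quality):
            if tier is not None and tier not in QUALITY_TIERS:
                raise ValueError(f"unknown quality tier {tier!r} for {self.contig_id}")
        if self.vibrant_lifestyle not in (None, "lytic", "temperate"):
            raise ValueError(f"unknown lifestyle {self.vibrant_lifestyle!r}")


@dataclass(frozen=True)
class DairyPhageEntry:
    name: str
    sequence: str
    host_genus: str
    phage_group: str
    lifestyle: str  # virulent | temperate


@dataclass
class DairyPhageDB:
    """Reference catalog of characterized dairy phages with host and group labels."""

    entries: list[DairyPhageEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [e.name for e in self.entries]
        if len(names) != len(set(names)):
            raise ValueError("duplicate phage names in dairy database")

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def get(self, name: str) -> DairyPhageEntry:
        for e in self.entries:
            if e.name == name:
                return e
        raise KeyError(name)


class CountMatrix:
    """Samples x features abundance table with a normalization-state flag.

    ``data`` is a pandas DataFrame indexed by sample id with feature ids as
    columns. ``state`` is one of raw / rarefied / coverage / relative; the
    raw and rarefied states must hold integers and every row of a relative
    table must sum to 1 (within 1e-9).
    """

    def __init__(self, data: pd.DataFrame, state: str):
        if state not in COUNT_STATES:
            raise ValueError(f"unknown count state {state!r}")
        values = data.to_numpy(dtype=float)
        if (values < 0).any():
            raise ValueError("counts must be non-negative")
        if state in ("raw", "rarefied") and not np.allclose(values, np.round(values)):
            raise ValueError(f"state {state!r} requires integer counts")
        if state == "relative":
            sums = values.sum(axis=1)
            if not np.allclose(sums, 1.0, atol=1e-9):
                bad = data.index[~np.isclose(sums, 1.0, atol=1e-9)].tolist()
                raise ValueError(f"relative rows must sum to 1; offending samples: {bad}")
        if data.index.duplicated().any() or data.columns.duplicated().any():
            raise ValueError("duplicate sample or feature ids")
        self.data = data.copy()
        if state in ("raw", "rarefied"):
            self.data = self.data.round().astype(np.int64)
        self.state = state

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def require_state(self, *states: str) -> "CountMatrix":
        if self.state not in states:
            raise ValueError(f"expected count state in {states}, got {self.state!r}")
        return self

    def with_data(self, data: pd.DataFrame, state: str) -> "CountMatrix":
        return CountMatrix(data, state)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        n, m = self.shape
        return f"CountMatrix({n} samples x {m} features, state={self.state})"


class SampleFrame:
    """Per-sample metadata: study arm, group (ripening stage or year), replicate."""

    def __init__(self, data: pd.DataFrame):
        required = {"sample_id", "study", "group", "replicate"}
        missing = required - set(data.columns)
        if missing:
            raise ValueError(f"metadata missing columns: {sorted(missing)}")
        data = data.copy()
        data["group"] = data["group"].astype(str)
        if data["sample_id"].duplicated().any():
            dups = data.loc[data["sample_id"].duplicated(), "sample_id"].tolist()
            raise ValueError(f"duplicate sample ids in metadata: {dups}")
        valid_groups = set(STAGES) | set(YEARS)
        bad = sorted(set(data["group"]) - valid_groups)
        if bad:
            raise ValueError(f"unknown group labels in metadata: {bad}")
        bad_study = sorted(set(data["study"]) - {"short_term", "long_term"})
        if bad_study:
            raise ValueError(f"unknown study labels: {bad_study}")
        self.data = data.set_index("sample_id", drop=False)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def groups(self, sample_ids: Sequence[str] | None = None) -> pd.Series:
        ids = list(sample_ids) if sample_ids is not None else self.sample_ids
        return self.data.loc[ids, "group"]

    def subset(self, sample_ids: Sequence[str]) -> "SampleFrame":
        return SampleFrame(self.data.loc[list(sample_ids)].reset_index(drop=True))


def check_samples(counts: CountMatrix, meta: SampleFrame) -> None:
    """Every counted sample must appear exactly once in the metadata."""
    missing = sorted(set(counts.sample_ids) - set(meta.sample_ids))
    if missing:
        raise ValueError(f"samples in counts but not in metadata: {missing}")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[ContigRecord]:
    """Read a FASTA file into contig records (uppercased, order preserved)."""
    records: list[ContigRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id in {path}: {rec.id!r}")
        seen.add(rec.id)
        records.append(ContigRecord(rec.id, str(rec.seq).upper()))
    if not records:
        warnings.warn(f"no sequences found in {path}", stacklevel=2)
    logger.info("read %d sequences from %s", len(records), path)
    return records


def write_fasta(records: Iterable[ContigRecord], path: str | Path, width: int = 80) -> None:
    seq_records = [SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(seq_records)


# ---------------------------------------------------------------------------
# PSL (BLAT tabular alignments)
# ---------------------------------------------------------------------------

#: column order of the 21-column BLAT PSL format
_PSL_FULL = (
    "matches misMatches repMatches nCount qNumInsert qBaseInsert tNumInsert "
    "tBaseInsert strand qName qSize qStart qEnd tName tSize tStart tEnd "
    "blockCount blockSizes qStarts tStarts"
).split()
#: minimal dialect: enough to compute identity and coverage
_PSL_MIN = (
    "matches misMatches qName qSize qStart qEnd tName tSize tStart tEnd "
    "blockCount blockSizes"
).split()


def read_psl(path: str | Path):
    """Parse a PSL alignment table into :class:`~rindvirome.align.AlignmentHit` rows.

    Accepts the full 21-column BLAT output (with or without its 5-line
    header) and a 12-column minimal dialect. The strand column is ignored:
    reverse-complement hits are treated like forward hits. Identity is
    matches over aligned columns and the per-hit coverage is the aligned
    length over the shorter of the two sequences.
    """
    from .align import AlignmentHit  # local import to avoid a cycle

    hits = []
    with open(path) as handle:
        lines = handle.readlines()
    body_start = 0
    if lines and lines[0].startswith("psLayout"):
        # classic header: psLayout line, blank, two column lines, dashes
        for i, line in enumerate(lines):
            if set(line.strip()) == {"-"}:
                body_start = i + 1
                break
        else:
            raise ValueError(f"{path}: malformed PSL header")
    for lineno, line in enumerate(lines[body_start:], start=body_start + 1):
        line = line.rstrip("\n")
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) == 1:
            fields = line.split()
        if len(fields) >= 21:
            names = _PSL_FULL
        elif len(fields) == 12:
            names = _PSL_MIN
        else:
            raise ValueError(f"{path}:{lineno}: expected 12 or 21 PSL columns, got {len(fields)}")
        row = dict(zip(names, fields))
        try:
            matches = int(row["matches"])
            mismatches = int(row["misMatches"])
            q_size = int(row["qSize"])
            t_size = int(row["tSize"])
            q_start = int(row["qStart"])
            t_start = int(row["tStart"])
            block_sizes = [int(b) for b in row["blockSizes"].rstrip(",").split(",") if b]
            if "qStarts" in row:
                q_starts = [int(b) for b in row["qStarts"].rstrip(",").split(",") if b]
                t_starts = [int(b) for b in row["tStarts"].rstrip(",").split(",") if b]
            else:
                q_starts, t_starts = [], []
                q_pos, t_pos = q_start, t_start
                for size in block_sizes:
                    q_starts.append(q_pos)
                    t_starts.append(t_pos)
                    q_pos += size
                    t_pos += size
        except (KeyError, ValueError) as exc:
            raise ValueError(f"{path}:{lineno}: malformed PSL row ({exc})") from exc
        aligned_length = sum(block_sizes)
        if aligned_length <= 0:
            raise ValueError(f"{path}:{lineno}: empty alignment blocks")
        blocks = tuple(
            (qs, qs + size, ts, ts + size)
            for qs, ts, size in zip(q_starts, t_starts, block_sizes)
        )
        identity = min(1.0, matches / aligned_length)
        coverage = min(1.0, aligned_length / min(q_size, t_size))
        hits.append(
            AlignmentHit(
                query_id=row["qName"],
                target_id=row["tName"],
                blocks=blocks,
                matches=matches,
                aligned_length=aligned_length,
                identity=identity,
                coverage=coverage,
                query_length=q_size,
                target_length=t_size,
            )
        )
    logger.info("read %d PSL alignment rows from %s", len(hits), path)
    return hits


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------

def read_counts(path: str | Path, state: str | None = None) -> CountMatrix:
    """Read a feature x sample count TSV (first column = feature id).

    When ``state`` is not given it is inferred: integer entries -> raw,
    per-sample sums of 1 -> relative, anything else -> coverage.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    data = df.T  # samples as rows internally
    data.index = data.index.astype(str)
    data.index.name = None
    data.columns.name = None
    if state is None:
        values = data.to_numpy(dtype=float)
        if np.allclose(values, np.round(values)):
            state = "raw"
        elif np.allclose(values.sum(axis=1), 1.0, atol=1e-9):
            state = "relative"
        else:
            state = "coverage"
    m = CountMatrix(data, state)
    logger.info("read counts %s from %s", m, path)
    return m


def write_counts(m: CountMatrix, path: str | Path) -> None:
    m.data.T.rename_axis("feature_id").to_csv(path, sep="\t")


def read_metadata(path: str | Path) -> SampleFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return SampleFrame(df)


def write_metadata(meta: SampleFrame, path: str | Path) -> None:
    meta.data.reset_index(drop=True).to_csv(path, sep="\t", index=False)


def read_genus_table(path: str | Path) -> CountMatrix:
    """Genus-aggregated 16S table; state inferred like :func:`read_counts`."""
    return read_counts(path)


def read_tool_reports(path: str | Path) -> dict[str, ToolReport]:
    """Read the minimal TSV dialect of the viral-detection tool reports."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    reports: dict[str, ToolReport] = {}
    for _, row in df.iterrows():
        cid = row["contig_id"]
        if cid in reports:
            raise ValueError(f"duplicate contig_id in tool reports: {cid!r}")
        reports[cid] = ToolReport(
            contig_id=cid,
            vibrant_quality=row.get("vibrant_quality") or None,
            vibrant_lifestyle=row.get("vibrant_lifestyle") or None,
            checkv_quality=row.get("checkv_quality") or None,
            virsorter2_label=row.get("virsorter2_label") or None,
            iphop_genus=row.get("iphop_genus") or None,
        )
    return reports


def write_tool_reports(reports: Mapping[str, ToolReport], path: str | Path) -> None:
    rows = []
    for rep in reports.values():
        rows.append(
            {
                "contig_id": rep.contig_id,
                "vibrant_quality": rep.vibrant_quality or "",
                "vibrant_lifestyle": rep.vibrant_lifestyle or "",
                "checkv_quality": rep.checkv_quality or "",
                "virsorter2_label": rep.virsorter2_label or "",
                "iphop_genus": rep.iphop_genus or "",
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_dairy_db(fasta_path: str | Path, annotations_path: str | Path) -> DairyPhageDB:
    """Dairy phage catalog: genome FASTA plus a TSV of host/group/lifestyle labels."""
    seqs = {r.id: r.sequence for r in read_fasta(fasta_path)}
    ann = pd.read_csv(annotations_path, sep="\t", dtype=str)
    entries = []
    for _, row in ann.iterrows():
        name = row["phage_name"]
        if name not in seqs:
            raise ValueError(f"dairy db annotation without sequence: {name!r}")
        entries.append(
            DairyPhageEntry(
                name=name,
                sequence=seqs[name],
                host_genus=row["host_genus"],
                phage_group=row["phage_group"],
                lifestyle=row["lifestyle"],
            )
        )
    return DairyPhageDB(entries)


def write_dairy_db(db: DairyPhageDB, fasta_path: str | Path, annotations_path: str | Path) -> None:
    write_fasta([ContigRecord(e.name, e.sequence) for e in db], fasta_path)
    pd.DataFrame(
        [
            {
                "phage_name": e.name,
                "host_genus": e.host_genus,
                "phage_group": e.phage_group,
                "lifestyle": e.lifestyle,
            }
            for e in db
        ]
    ).to_csv(annotations_path, sep="\t", index=False)


def read_plate_counts(path: str | Path) -> pd.DataFrame:
    """Plate counts in log10 CFU/g with columns sample_id, lab_log10, aerobic_log10."""
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "lab_log10", "aerobic_log10"}
    if missing := required - set(df.columns):
        raise ValueError(f"plate count table missing columns: {sorted(missing)}")
    return df
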