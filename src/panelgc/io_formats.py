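"""Input handling: probe BED files, reference FASTA, BAM depth extraction,
CNV call tables and sample manifests.

All coordinates are 0-based half-open (the BED convention); BAM positions are
converted to the same convention by pysam. Depth is computed once per genomic
position over the *union* of probe intervals; overlapping probes are retained
as distinct analysis units and share positions.
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np
import pandas as pd
import pyfaidx
import pysam

logger = logging.getLogger("panelgc")

#: chromosome names treated as non-autosomal for CNV accounting
_NON_AUTOSOMES = {"x", "y", "m", "mt", "chrx", "chry", "chrm", "chrmt"}

#: probes with more than this fraction of ambiguous bases are dropped
MAX_AMBIGUOUS_FRACTION = 0.5


class BedFormatError(ValueError):
    """Raised for malformed probe BED input, with the offending line number."""


@dataclass(frozen=True)
class ProbeInterval:
    """One capture probe (or genomic bin): 0-based half-open interval."""

    chrom: str
    start: int
    end: int
    name: Optional[str] = None

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class ProbeSet:
    """Ordered probes plus (optionally) their per-probe GC fractions.

    ``gc_fraction[i]`` is NaN until :func:`compute_gc` runs, and stays NaN for
    probes excluded because of ambiguous sequence; ``usable`` masks those out.
    Overlapping probes are deliberately retained: capture probes overlap by
    design and each one is an analysis unit.
    """

    intervals: list[ProbeInterval]
    gc_fraction: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.gc_fraction is None:
            self.gc_fraction = np.full(len(self.intervals), np.nan)
        self.gc_fraction = np.asarray(self.gc_fraction, dtype=float)
        if len(self.gc_fraction) != len(self.intervals):
            raise ValueError("gc_fraction length must match intervals")

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[ProbeInterval]:
        return iter(self.intervals)

    @property
    def usable(self) -> np.ndarray:
        """Boolean mask of probes with a defined GC fraction."""
        return ~np.isnan(self.gc_fraction)

    def union(self) -> dict[str, list[tuple[int, int]]]:
        """Merged (maximal disjoint) intervals per chromosome, sorted."""
        per_chrom: dict[str, list[tuple[int, int]]] = {}
        for iv in self.intervals:
            per_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
        merged: dict[str, list[tuple[int, int]]] = {}
        for chrom, ivs in per_chrom.items():
            ivs.sort()
            out = [list(ivs[0])]
            for s, e in ivs[1:]:
                if s <= out[-1][1]:
                    out[-1][1] = max(out[-1][1], e)
                else:
                    out.append([s, e])
            merged[chrom] = [(s, e) for s, e in out]
        return merged

    def union_size(self) -> int:
        return sum(e - s for ivs in self.union().values() for s, e in ivs)


def read_probes(bed_path: str | Path) -> ProbeSet:
    """Read a BED3+ probe file into a :class:`ProbeSet` (GC not yet computed).

    Lines are kept in file order; ``track``/``browser``/``#`` lines are
    skipped. Malformed lines raise :class:`BedFormatError` naming the line.
    """
    bed_path = Path(bed_path)
    if not bed_path.exists():
        raise FileNotFoundError(bed_path)
    intervals: list[ProbeInterval] = []
    with open(bed_path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedFormatError(
                    f"{bed_path}:{lineno}: expected >=3 tab-separated fields"
                )
            chrom, start_s, end_s = fields[0], fields[1], fields[2]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise BedFormatError(
                    f"{bed_path}:{lineno}: non-integer coordinates "
                    f"({start_s!r}, {end_s!r})"
                ) from exc
            if start < 0 or start >= end:
                raise BedFormatError(
                    f"{bed_path}:{lineno}: invalid interval {chrom}:{start}-{end}"
                )
            name = fields[3] if len(fields) > 3 and fields[3] else None
            intervals.append(ProbeInterval(chrom, start, end, name))
    if not intervals:
        raise BedFormatError(f"{bed_path}: no probe intervals found")
    return ProbeSet(intervals)


def probe_gc(probe: ProbeInterval, reference: pyfaidx.Fasta) -> float:
    """GC fraction of a probe: (G+C) / (A+C+G+T), case-insensitive.

    Ambiguous bases (N etc.) are excluded from both numerator and denominator.
    Returns NaN when no unambiguous base remains.
    """
    if probe.chrom not in reference:
        raise KeyError(f"chromosome {probe.chrom!r} absent from reference")
    chrom_len = len(reference[probe.chrom])
    if probe.end > chrom_len:
        raise ValueError(
            f"probe {probe.chrom}:{probe.start}-{probe.end} exceeds "
            f"chromosome length {chrom_len}"
        )
    seq = str(reference[probe.chrom][probe.start : probe.end]).upper()
    gc = seq.count("G") + seq.count("C")
    at = seq.count("A") + seq.count("T")
    if gc + at == 0:
        return float("nan")
    return gc / (gc + at)


def compute_gc(probes: ProbeSet, fasta_path: str | Path) -> ProbeSet:
    """Fill per-probe GC fractions from an indexed FASTA.

    Probes whose sequence is more than 50% ambiguous are excluded (GC left as
    NaN) with a warning; they contribute neither to binning nor to scoring.
    """
    ref = pyfaidx.Fasta(str(fasta_path))
    gc = np.full(len(probes), np.nan)
    n_excluded = 0
    for i, probe in enumerate(probes):
        seq = str(ref[probe.chrom][probe.start : probe.end]).upper()
        n_ambig = sum(1 for b in seq if b not in "ACGT")
        if n_ambig > MAX_AMBIGUOUS_FRACTION * len(seq):
            n_excluded += 1
            logger.warning(
                "probe %s:%d-%d excluded: %d/%d ambiguous bases",
                probe.chrom, probe.start, probe.end, n_ambig, len(seq),
            )
            continue
        gc[i] = probe_gc(probe, ref)
    if n_excluded:
        logger.warning("%d probe(s) excluded for ambiguous sequence", n_excluded)
    return ProbeSet(probes.intervals, gc)


class DepthTable:
    """Per-position values over the merged probe union of one sample.

    Values are stored as one array per merged block so that probe lookups are
    slices; ``blocks[chrom]`` is a list of ``(start, end, values)`` sorted by
    start.
    """

    def __init__(self, blocks: dict[str, list[tuple[int, int, np.ndarray]]]):
        self.blocks = blocks
        self._starts = {
            chrom: [b[0] for b in blks] for chrom, blks in blocks.items()
        }

    def values(self) -> np.ndarray:
        """All per-position values, concatenated in genomic order."""
        arrays = [
            b[2] for chrom in sorted(self.blocks) for b in self.blocks[chrom]
        ]
        if not arrays:
            return np.array([])
        return np.concatenate(arrays)

    def total_positions(self) -> int:
        return sum(len(b[2]) for blks in self.blocks.values() for b in blks)

    def probe_values(self, probe: ProbeInterval) -> np.ndarray:
        """Values at the positions of one probe (probe must lie in the union)."""
        blks = self.blocks.get(probe.chrom)
        if not blks:
            raise KeyError(f"chromosome {probe.chrom!r} not covered")
        i = bisect_right(self._starts[probe.chrom], probe.start) - 1
        if i < 0:
            raise KeyError(f"probe {probe} outside depth union")
        start, end, vals = blks[i]
        if probe.start < start or probe.end > end:
            raise KeyError(f"probe {probe} outside depth union")
        return vals[probe.start - start : probe.end - start]

    def map(self, func) -> "DepthTable":
        return DepthTable(
            {
                chrom: [(s, e, func(v)) for s, e, v in blks]
                for chrom, blks in self.blocks.items()
            }
        )


def extract_depths(
    bam_path: str | Path,
    probes: ProbeSet,
    min_mapq: int = 0,
    count_duplicates: bool = False,
) -> DepthTable:
    """Per-position read depth over the union of the probe intervals.

    Secondary and supplementary alignments are always excluded; duplicates are
    excluded unless ``count_duplicates``; reads below ``min_mapq`` are
    excluded. Positions with no reads get depth 0. Probe chromosomes missing
    from the BAM header contribute zero depth (with a warning).
    """
    if len(probes) == 0:
        raise ValueError("empty probe set")
    bam_path = Path(bam_path)

    def keep(read: pysam.AlignedSegment) -> bool:
        if read.is_unmapped or read.is_secondary or read.is_supplementary:
            return False
        if read.is_duplicate and not count_duplicates:
            return False
        return read.mapping_quality >= min_mapq

    blocks: dict[str, list[tuple[int, int, np.ndarray]]] = {}
    with pysam.AlignmentFile(str(bam_path), "rb") as bam:
        if not bam.has_index():
            raise ValueError(f"{bam_path}: BAM has no index (.bai)")
        header_chroms = set(bam.references)
        for chrom, merged in probes.union().items():
            chrom_blocks: list[tuple[int, int, np.ndarray]] = []
            if chrom not in header_chroms:
                logger.warning(
                    "chromosome %r absent from BAM header; depth set to 0", chrom
                )
                for s, e in merged:
                    chrom_blocks.append((s, e, np.zeros(e - s, dtype=np.int64)))
            else:
                for s, e in merged:
                    acgt = bam.count_coverage(
                        chrom, s, e, quality_threshold=0, read_callback=keep
                    )
                    depth = np.sum(np.asarray(acgt, dtype=np.int64), axis=0)
                    chrom_blocks.append((s, e, depth))
            blocks[chrom] = chrom_blocks
    return DepthTable(blocks)


CNV_REQUIRED_COLUMNS = ["sample_id", "region", "chrom", "copy_state"]


def is_autosomal(chrom: str) -> bool:
    return str(chrom).strip().lower() not in _NON_AUTOSOMES


def _read_delimited(path: str | Path) -> pd.DataFrame:
    """Read a tab- or comma-separated table with a header row."""
    with open(path) as fh:
        first = fh.readline()
    sep = "\t" if "\t" in first else ","
    return pd.read_csv(path, sep=sep, dtype=str, skip_blank_lines=True)


def read_cnv_calls(path: str | Path) -> pd.DataFrame:
    """Read an external CNV caller's per-region call table.

    Requires header columns ``sample_id, region, chrom, copy_state``. Rows
    whose copy state is not a nonnegative integer are dropped, with the count
    logged. Non-autosomal rows are retained (callers may emit them) but are
    ignored by the copy-neutrality accounting downstream.
    """
    df = _read_delimited(path)
    missing = [c for c in CNV_REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    df = df[CNV_REQUIRED_COLUMNS].copy()
    states = pd.to_numeric(df["copy_state"], errors="coerce")
    valid = states.notna() & (states == states.round()) & (states >= 0)
    n_bad = int((~valid).sum())
    if n_bad:
        logger.warning("%s: rejected %d row(s) with non-integer copy state", path, n_bad)
    df = df[valid].copy()
    df["copy_state"] = states[valid].astype(int)
    df["autosomal"] = df["chrom"].map(is_autosomal)
    return df.reset_index(drop=True)


MANIFEST_REQUIRED_COLUMNS = ["sample_id", "bam", "panel", "batch"]


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a sample manifest: sample_id, bam, panel, batch[, date].

    sample_id must be unique within each batch. ``date`` is parsed to a
    datetime when present (ISO format recommended).
    """
    df = _read_delimited(path)
    missing = [c for c in MANIFEST_REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    if "date" in df.columns:
        df["date"] = pd.to_datetime(df["date"], errors="coerce")
    else:
        df["date"] = pd.NaT
    dup = df.duplicated(subset=["batch", "sample_id"])
    if dup.any():
        raise ValueError(
            f"{path}: duplicate sample_id within a batch: "
            f"{df.loc[dup, 'sample_id'].tolist()}"
        )
    return df.reset_index(drop=True)
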