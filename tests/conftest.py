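"""Shared fixtures: tiny hand-built references/BAMs for the I/O layer and a
reusable simulated panel for pipeline-level tests. Everything is generated
programmatically at test time."""

from __future__ import annotations

from pathlib import Path

import pyfaidx
import pysam
import pytest

from panelgc.simulate import SimConfig, make_reference_and_probes


def write_fasta(path: Path, sequences: dict[str, str]) -> Path:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
    pyfaidx.Faidx(str(path))
    return path


def write_bam(
    path: Path,
    chrom_lengths: dict[str, int],
    reads: list[dict],
    index: bool = True,
) -> Path:
    """Write a coordinate-sorted BAM from read dicts.

    Each read dict needs chrom, start, length; optional qname, mapq (60),
    flag extras: is_duplicate, is_secondary, is_supplementary, is_unmapped.
    """
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": ln} for c, ln in chrom_lengths.items()],
    }
    tid = {c: i for i, c in enumerate(chrom_lengths)}
    reads = sorted(reads, key=lambda r: (tid[r["chrom"]], r["start"]))
    with pysam.AlignmentFile(str(path), "wb", header=header) as bam:
        for i, r in enumerate(reads):
            a = pysam.AlignedSegment()
            a.query_name = r.get("qname", f"read{i}")
            a.query_sequence = "A" * r["length"]
            flag = 0
            if r.get("is_duplicate"):
                flag |= 0x400
            if r.get("is_secondary"):
                flag |= 0x100
            if r.get("is_supplementary"):
                flag |= 0x800
            if r.get("is_unmapped"):
                flag |= 0x4
            a.flag = flag
            a.reference_id = tid[r["chrom"]]
            a.reference_start = r["start"]
            a.mapping_quality = r.get("mapq", 60)
            a.cigarstring = f"{r['length']}M"
            bam.write(a)
    if index:
        pysam.index(str(path))
    return path


#: small simulation shared by pipeline tests: quick but dense enough for a
#: stable LOESS fit (>=10 occupied percentiles, anchors inside the domain)
SMALL_SIM = dict(n_probes=80, probe_length=120, mean_depth=30.0)


@pytest.fixture(scope="session")
def sim_panel(tmp_path_factory):
    """A session-wide synthetic reference + probe set (GC 10-90%)."""
    outdir = tmp_path_factory.mktemp("sim_panel")
    cfg = SimConfig(seed=42, **SMALL_SIM)
    fasta, bed, probes = make_reference_and_probes(cfg, outdir)
    return {"dir": outdir, "fasta": fasta, "bed": bed, "probes": probes, "config": cfg}
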