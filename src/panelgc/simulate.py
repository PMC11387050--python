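"""Synthetic capture-panel fixtures with controlled GC/AT coverage bias.

Builds a synthetic reference chromosome carrying probes whose GC fractions
span a chosen grid, then writes coordinate-sorted indexed BAMs in which the
expected per-position depth is a controlled function of probe GC content.
The injected linear-scale depth ratio ``r`` between GC-anchor-region and
AT-anchor-region probes fixes the ground-truth relative fold-change score at
log2(r + 1), which closes the loop for recovery tests: simulate at a known
``r``, run the scoring pipeline, compare.

Everything is driven by a single integer seed; identical configurations
produce byte-identical FASTA/BED and identical BAM record sets.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import pyfaidx
import pysam

from .gc_model import BiasClass, Thresholds, DEFAULT_THRESHOLDS, classify_bias
from .io_formats import ProbeInterval, ProbeSet

logger = logging.getLogger("panelgc")

CHROM = "chr1"
GAP = 30  # bp of N between consecutive probes; never probed, never read


@dataclass
class SimConfig:
    """Parameters of one simulated sample."""

    n_probes: int = 200
    probe_length: int = 120
    gc_min: float = 0.10
    gc_max: float = 0.90
    mean_depth: float = 30.0
    bias_ratio: float = 1.0          # linear-scale GC:AT expected-depth ratio
    bias_shape: str = "step"         # "step" or "log-linear"
    noise: str = "poisson"           # "poisson" or "none"
    seed: int = 0
    read_length: int = 150
    at_anchor: float = 0.25
    gc_anchor: float = 0.75

    def __post_init__(self) -> None:
        if self.bias_ratio <= 0:
            raise ValueError("bias_ratio must be > 0")
        if self.bias_shape not in ("step", "log-linear"):
            raise ValueError(f"unknown bias_shape {self.bias_shape!r}")
        if self.noise not in ("poisson", "none"):
            raise ValueError(f"unknown noise model {self.noise!r}")
        if not (0 <= self.gc_min < self.gc_max <= 1):
            raise ValueError("need 0 <= gc_min < gc_max <= 1")
        if not (self.gc_min <= self.at_anchor < self.gc_anchor <= self.gc_max):
            raise ValueError("gc grid must cover both anchors")

    def gc_grid(self) -> np.ndarray:
        return np.linspace(self.gc_min, self.gc_max, self.n_probes)


@dataclass
class GroundTruth:
    """What the scoring pipeline should recover from a simulated sample."""

    bias_ratio: float
    expected_b75_25: float
    expected_b25: float
    expected_b75: float
    expected_class: BiasClass
    per_probe_expected_depth: np.ndarray = field(repr=False)


def _probe_sequence(gc_target: float, length: int, rng: np.random.Generator) -> str:
    """Sequence with exactly round(gc_target*length) G/C bases, shuffled."""
    n_gc = int(round(gc_target * length))
    if not 0 <= n_gc <= length:
        raise ValueError(f"unsatisfiable GC target {gc_target} for length {length}")
    bases = ["G" if i % 2 == 0 else "C" for i in range(n_gc)]
    bases += ["A" if i % 2 == 0 else "T" for i in range(length - n_gc)]
    bases = np.array(bases)
    rng.shuffle(bases)
    return "".join(bases)


def make_reference_and_probes(
    config: SimConfig, outdir: str | Path
) -> tuple[Path, Path, ProbeSet]:
    """Write the synthetic chromosome FASTA (+.fai) and probe BED.

    Probes are placed non-adjacently (separated by runs of N) and each
    realized GC fraction is exact to within 1/(2*probe_length) of its grid
    target by explicit base counting. Returns (fasta_path, bed_path,
    ProbeSet) with GC fractions already filled.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    grid = config.gc_grid()
    parts: list[str] = []
    intervals: list[ProbeInterval] = []
    gc = np.empty(config.n_probes)
    pos = 0
    for i, target in enumerate(grid):
        parts.append("N" * GAP)
        pos += GAP
        seq = _probe_sequence(float(target), config.probe_length, rng)
        intervals.append(
            ProbeInterval(CHROM, pos, pos + config.probe_length, f"probe_{i:04d}")
        )
        n_gc = seq.count("G") + seq.count("C")
        gc[i] = n_gc / config.probe_length
        parts.append(seq)
        pos += config.probe_length
    parts.append("N" * GAP)
    genome = "".join(parts)

    fasta_path = outdir / "reference.fa"
    with open(fasta_path, "w") as fh:
        fh.write(f">{CHROM}\n")
        for i in range(0, len(genome), 60):
            fh.write(genome[i : i + 60] + "\n")
    pyfaidx.Faidx(str(fasta_path))  # writes reference.fa.fai

    bed_path = outdir / "probes.bed"
    with open(bed_path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\n")

    return fasta_path, bed_path, ProbeSet(intervals, gc)


def depth_weights(gc: np.ndarray, config: SimConfig) -> np.ndarray:
    """Relative expected depth per probe as a function of its GC fraction.

    "step": weight 1 below 50% GC, ``r`` at or above. "log-linear": log2
    weight interpolates linearly in GC between the anchors (clamped outside),
    so the anchor-to-anchor ratio is exactly ``r`` in both shapes.
    """
    r = config.bias_ratio
    gc = np.asarray(gc, dtype=float)
    if config.bias_shape == "step":
        return np.where(gc < 0.5, 1.0, r)
    t = np.clip(
        (gc - config.at_anchor) / (config.gc_anchor - config.at_anchor), 0.0, 1.0
    )
    return 2.0 ** (t * math.log2(r))


def expected_depths(config: SimConfig, probes: ProbeSet) -> np.ndarray:
    """Expected per-position depth per probe, scaled so the overall mean
    (over all probed positions) equals ``mean_depth``."""
    w = depth_weights(probes.gc_fraction, config)
    return config.mean_depth * w / w.mean()


def ground_truth(config: SimConfig, probes: ProbeSet) -> GroundTruth:
    d = expected_depths(config, probes)
    r = config.bias_ratio
    w = depth_weights(probes.gc_fraction, config)
    scale = 1.0 / w.mean()  # linear normalized depth of an AT-anchor probe
    b25 = math.log2(1.0 * scale + 1.0)
    b75 = math.log2(r * scale + 1.0)
    b75_25 = math.log2(r + 1.0)
    cls, _ = classify_bias(b25, b75, b75_25, DEFAULT_THRESHOLDS)
    return GroundTruth(r, b75_25, b25, b75, cls, d)


def simulate_alignments(
    config: SimConfig,
    probes: ProbeSet,
    fasta_path: str | Path,
    bam_path: str | Path,
    sample_id: str = "sim",
) -> GroundTruth:
    """Write a coordinate-sorted, indexed BAM realizing the configured bias.

    Each probe is covered by full-span reads (read length capped at the probe
    length, tiled when probes exceed the read length), so every position of a
    probe sees the same read count: Poisson(expected depth) under the
    "poisson" noise model, round(expected depth) under "none". Reads carry
    proper-pair flags with trivially placed mates; depth, not pair geometry,
    is what the metric consumes.
    """
    bam_path = Path(bam_path)
    rng = np.random.default_rng(config.seed)
    ref = pyfaidx.Fasta(str(fasta_path))
    depths = expected_depths(config, probes)
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": name, "LN": len(ref[name])} for name in ref.keys()],
        "RG": [{"ID": sample_id, "SM": sample_id}],
    }
    n_reads = 0
    with pysam.AlignmentFile(str(bam_path), "wb", header=header) as bam:
        tid = {name: i for i, name in enumerate(ref.keys())}
        for i, probe in enumerate(probes):
            seq = str(ref[probe.chrom][probe.start : probe.end]).upper()
            span = min(config.read_length, len(probe))
            # tile full-span segments so the whole probe is covered uniformly
            offsets = list(range(0, len(probe) - span + 1, span))
            if offsets[-1] + span < len(probe):
                offsets.append(len(probe) - span)
            for off in offsets:
                if config.noise == "poisson":
                    k = int(rng.poisson(depths[i]))
                else:
                    k = int(round(depths[i]))
                for j in range(k):
                    a = pysam.AlignedSegment()
                    a.query_name = f"{sample_id}:{i}:{off}:{j}"
                    a.query_sequence = seq[off : off + span]
                    a.flag = 0x1 | 0x2 | 0x40  # paired, proper pair, read1
                    a.reference_id = tid[probe.chrom]
                    a.reference_start = probe.start + off
                    a.mapping_quality = 60
                    a.cigarstring = f"{span}M"
                    a.next_reference_id = tid[probe.chrom]
                    a.next_reference_start = probe.start + off
                    a.template_length = span
                    a.set_tag("RG", sample_id)
                    bam.write(a)
                    n_reads += 1
    pysam.index(str(bam_path))
    logger.info("simulated %d reads -> %s", n_reads, bam_path)
    return ground_truth(config, probes)


def simulate_cnv_table(
    nondiploid_spec: dict[str, int],
    n_regions: int = 83,
    seed: int = 0,
) -> pd.DataFrame:
    """Deterministic CNV call table with a chosen nondiploid count per sample.

    Each sample gets one call per region (GENE0001..), autosomal chromosomes
    cycling chr1..chr22; the specified number of calls per sample is made
    nondiploid (copy state drawn from {0, 1, 3, 4}).
    """
    rng = np.random.default_rng(seed)
    rows = []
    for sample_id, n_nondiploid in nondiploid_spec.items():
        if n_nondiploid > n_regions:
            raise ValueError(
                f"{sample_id}: nondiploid count {n_nondiploid} > n_regions {n_regions}"
            )
        which = rng.choice(n_regions, size=n_nondiploid, replace=False)
        states = np.full(n_regions, 2, dtype=int)
        states[which] = rng.choice([0, 1, 3, 4], size=n_nondiploid)
        for r in range(n_regions):
            rows.append(
                {
                    "sample_id": sample_id,
                    "region": f"GENE{r + 1:04d}",
                    "chrom": f"chr{r % 22 + 1}",
                    "copy_state": int(states[r]),
                }
            )
    return pd.DataFrame(rows, columns=["sample_id", "region", "chrom", "copy_state"])


def simulate_batch(
    outdir: str | Path,
    seed: int = 0,
    n_samples: int = 5,
    panel_name: str = "PanelA",
    batch_id: str = "batch01",
    ratios: Optional[list[float]] = None,
    base_config: Optional[SimConfig] = None,
    cnv_nondiploid: Optional[dict[str, int]] = None,
) -> pd.DataFrame:
    """Write a complete fixture: reference, probes, one BAM per sample, a CNV
    table, a manifest, and a ground-truth table. Returns the manifest frame.

    ``ratios`` gives the injected bias ratio per sample (default: all 1.0,
    an unbiased batch). Per-sample seeds are derived from ``seed``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    base = base_config or SimConfig(seed=seed)
    fasta_path, bed_path, probes = make_reference_and_probes(base, outdir)
    if ratios is None:
        ratios = [1.0] * n_samples
    if len(ratios) != n_samples:
        raise ValueError("ratios length must equal n_samples")
    manifest_rows, truth_rows = [], []
    for s in range(n_samples):
        sample_id = f"S{s + 1:03d}"
        cfg = SimConfig(
            n_probes=base.n_probes,
            probe_length=base.probe_length,
            gc_min=base.gc_min,
            gc_max=base.gc_max,
            mean_depth=base.mean_depth,
            bias_ratio=ratios[s],
            bias_shape=base.bias_shape,
            noise=base.noise,
            seed=(seed * 1009 + s + 1) % (2**31),
            read_length=base.read_length,
        )
        bam_path = outdir / f"{sample_id}.bam"
        truth = simulate_alignments(cfg, probes, fasta_path, bam_path, sample_id)
        manifest_rows.append(
            {
                "sample_id": sample_id,
                "bam": str(bam_path),
                "panel": panel_name,
                "batch": batch_id,
                "date": f"2024-01-{s + 1:02d}",
            }
        )
        truth_rows.append(
            {
                "sample_id": sample_id,
                "bias_ratio": truth.bias_ratio,
                "expected_b75_25": truth.expected_b75_25,
                "expected_class": truth.expected_class.value,
            }
        )
    manifest = pd.DataFrame(manifest_rows)
    manifest.to_csv(outdir / "manifest.tsv", sep="\t", index=False)
    pd.DataFrame(truth_rows).to_csv(outdir / "ground_truth.tsv", sep="\t", index=False)
    if cnv_nondiploid is None:
        cnv_nondiploid = {row["sample_id"]: 0 for row in manifest_rows}
    cnv = simulate_cnv_table(cnv_nondiploid, seed=seed)
    cnv.to_csv(outdir / "cnv_calls.tsv", sep="\t", index=False)
    return manifest
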