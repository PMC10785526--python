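"""Synthetic SAM + GFF3 fixture pairs with planted per-feature coverage trends.

Reads are placed by sampling anchor positions from a per-feature density
(uniform baseline plus a peak bump), so depth noise is Poisson by
construction and the real SAM -> coverage path is exercised end to end.
Minus-strand features get the mirrored density, exercising strand reversal.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from metaclust.annotation_io import GenomicFeature

READ_LENGTH = 50
TREND_NAMES = ("five_prime_peak", "three_prime_peak", "center_peak", "flat")


@dataclass(frozen=True)
class TrendSpec:
    """A planted coverage trend: where the peak sits and how tall it is."""

    name: str
    peak_height: float = 30.0
    baseline: float = 5.0
    peak_width_fraction: float = 0.2

    def __post_init__(self) -> None:
        if self.name not in TREND_NAMES:
            raise ValueError(f"unknown trend {self.name!r}, expected one of {TREND_NAMES}")
        if not self.peak_height >= self.baseline >= 0:
            raise ValueError("need peak_height >= baseline >= 0")
        if not 0 < self.peak_width_fraction <= 1:
            raise ValueError("peak_width_fraction must be in (0, 1]")

    def expected_profile(self, length: int) -> np.ndarray:
        """Expected per-base depth along the feature, 5' end first."""
        profile = np.full(length, float(self.baseline))
        if self.name == "flat":
            return profile
        width = max(1, round(self.peak_width_fraction * length))
        if self.name == "five_prime_peak":
            start = 0
        elif self.name == "three_prime_peak":
            start = length - width
        else:  # center_peak
            start = (length - width) // 2
        profile[start : start + width] = self.peak_height
        return profile


def write_gff3(features: list[GenomicFeature], path: str | Path) -> Path:
    """Write features as a minimal valid GFF3 file (used for round-trip tests)."""
    path = Path(path)
    lines = ["##gff-version 3\n"]
    for f in features:
        lines.append(
            f"{f.chrom}\tmetaclust_sim\t{f.feature_type}\t{f.start}\t{f.end}"
            f"\t.\t{f.strand}\t0\tID={f.id}\n"
        )
    path.write_text("".join(lines))
    return path


def _write_sam(
    records: list[tuple[str, str, int]],
    chrom_lengths: dict[str, int],
    path: Path,
) -> None:
    """records: (qname, chrom, 1-based pos); all reads are READ_LENGTH M."""
    lines = ["@HD\tVN:1.6\tSO:coordinate\n"]
    for chrom, length in chrom_lengths.items():
        lines.append(f"@SQ\tSN:{chrom}\tLN:{length}\n")
    order = {chrom: i for i, chrom in enumerate(chrom_lengths)}
    for qname, chrom, pos in sorted(records, key=lambda r: (order[r[1]], r[2], r[0])):
        lines.append(
            f"{qname}\t0\t{chrom}\t{pos}\t60\t{READ_LENGTH}M\t*\t0\t0\t*\t*\n"
        )
    path.write_text("".join(lines))


def generate_fixture(
    trends: list[TrendSpec],
    features_per_trend: int,
    feature_length_range: tuple[int, int] = (500, 1500),
    seed: int = 0,
    out_dir: str | Path = ".",
    *,
    n_chroms: int = 2,
    gap: int = 4 * READ_LENGTH,
    prefix: str = "fixture",
) -> tuple[Path, Path, dict[str, int]]:
    """Write a SAM + GFF3 pair whose features follow planted coverage trends.

    Features of varied lengths are laid out on `n_chroms` chromosomes and
    alternate strands; each feature's reads are anchored by draws from its
    trend's expected depth profile (mirrored on the minus strand).  Returns
    (sam_path, gff_path, labels) where labels maps feature id to the index
    of its trend in `trends`.  Deterministic for a given seed.
    """
    if not trends or features_per_trend < 1:
        raise ValueError("need at least one trend and one feature per trend")
    lo, hi = feature_length_range
    if lo < READ_LENGTH:
        raise ValueError(
            f"minimum feature length {lo} is below the read length {READ_LENGTH}"
        )
    if hi < lo:
        raise ValueError("feature_length_range must be (min, max) with min <= max")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    chroms = [f"chr{i + 1}" for i in range(n_chroms)]
    cursor = {chrom: gap for chrom in chroms}  # next free 1-based start
    features: list[GenomicFeature] = []
    labels: dict[str, int] = {}
    plan: list[tuple[GenomicFeature, TrendSpec]] = []
    idx = 0
    for t_idx, trend in enumerate(trends):
        for i in range(features_per_trend):
            length = int(rng.integers(lo, hi + 1))
            chrom = chroms[idx % n_chroms]
            strand = "+" if (idx // n_chroms) % 2 == 0 else "-"
            start = cursor[chrom]
            feature = GenomicFeature(
                id=f"feat_t{t_idx}_{i}",
                chrom=chrom,
                start=start,
                end=start + length - 1,
                strand=strand,
                feature_type="CDS",
            )
            cursor[chrom] = feature.end + 1 + gap
            features.append(feature)
            labels[feature.id] = t_idx
            plan.append((feature, trend))
            idx += 1
    chrom_lengths = {chrom: cursor[chrom] + gap for chrom in chroms}

    records: list[tuple[str, str, int]] = []
    for feature, trend in plan:
        m = feature.length
        profile = trend.expected_profile(m)
        if feature.strand == "-":
            profile = profile[::-1]
        total = profile.sum()
        n_reads = int(rng.poisson(total / READ_LENGTH))
        if n_reads == 0:
            continue
        anchors = rng.choice(m, size=n_reads, p=profile / total)
        max_start = chrom_lengths[feature.chrom] - READ_LENGTH + 1
        for r, anchor in enumerate(anchors):
            pos = feature.start + int(anchor) - READ_LENGTH // 2
            pos = min(max(pos, 1), max_start)
            records.append((f"{feature.id}_r{r}", feature.chrom, pos))

    sam_path = out_dir / f"{prefix}.sam"
    gff_path = out_dir / f"{prefix}.gff3"
    _write_sam(records, chrom_lengths, sam_path)
    write_gff3(features, gff_path)
    return sam_path, gff_path, labels
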