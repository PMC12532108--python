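"""Genome coordinate model: chromosomes, bins, arms and region masks.

All coordinates are 0-based half-open (BED convention); bins are labeled by
their start. A chromosome is ACA-eligible ("metacentric or submetacentric")
iff both of its arms span at least two bins; acrocentric chromosomes are
excluded from aggregate chromosome analysis but kept everywhere else.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenomeSpec",
    "BinTable",
    "make_bins",
    "region_masks",
    "read_chrom_sizes",
    "read_centromeres_bed",
]


@dataclass(frozen=True)
class GenomeSpec:
    """Chromosome lengths, centromere intervals and binning resolution.

    Parameters
    ----------
    chrom_names
        Ordered chromosome identifiers.
    chrom_lengths
        Length in bp per chromosome, same order as ``chrom_names``.
    centromeres
        One ``(start, end)`` interval in bp per chromosome, 0-based
        half-open. Must lie strictly inside the chromosome and clear of the
        telomeric windows.
    bin_size
        Bin width in bp.
    telomere_extent
        bp from each chromosome end treated as telomeric. Defaults to one
        bin.
    """

    chrom_names: tuple[str, ...]
    chrom_lengths: tuple[int, ...]
    centromeres: tuple[tuple[int, int], ...]
    bin_size: int
    telomere_extent: int = 0  # 0 → one bin, resolved in __post_init__

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        if not (len(self.chrom_names) == len(self.chrom_lengths) == len(self.centromeres)):
            raise ValueError("chrom_names, chrom_lengths and centromeres must align")
        if self.telomere_extent == 0:
            object.__setattr__(self, "telomere_extent", self.bin_size)
        for name, length, (cs, ce) in zip(
            self.chrom_names, self.chrom_lengths, self.centromeres
        ):
            if length < self.bin_size:
                raise ValueError(
                    f"chromosome {name!r} ({length} bp) is shorter than one bin"
                )
            if self.n_bins_of(name) < 6:
                raise ValueError(
                    f"chromosome {name!r} has fewer than 6 bins; centromere/"
                    "telomere/arm regions would be empty"
                )
            if not (0 < cs < ce < length):
                raise ValueError(
                    f"centromere of {name!r} must lie strictly inside the chromosome"
                )
            if cs < self.telomere_extent or ce > length - self.telomere_extent:
                raise ValueError(
                    f"centromere of {name!r} overlaps a telomeric window"
                )

    @property
    def n_chroms(self) -> int:
        return len(self.chrom_names)

    def n_bins_of(self, chrom: str) -> int:
        length = self.chrom_lengths[self.chrom_names.index(chrom)]
        return math.ceil(length / self.bin_size)

    @property
    def n_bins(self) -> int:
        return sum(math.ceil(l / self.bin_size) for l in self.chrom_lengths)

    def centromere_mid(self, chrom: str) -> float:
        cs, ce = self.centromeres[self.chrom_names.index(chrom)]
        return 0.5 * (cs + ce)

    def is_aca_eligible(self, chrom: str) -> bool:
        """True iff both arms hold >= 2 bins (metacentric/submetacentric)."""
        i = self.chrom_names.index(chrom)
        mid = self.centromere_mid(chrom)
        p_bins = mid / self.bin_size
        q_bins = (self.chrom_lengths[i] - mid) / self.bin_size
        return p_bins >= 2.0 and q_bins >= 2.0

    @property
    def eligible_chroms(self) -> tuple[str, ...]:
        return tuple(c for c in self.chrom_names if self.is_aca_eligible(c))


@dataclass
class BinTable:
    """Per-bin bookkeeping shared by every pipeline stage.

    ``df`` columns: chrom, start, end, global_index, arm ('P' left of the
    centromere midpoint, 'Q' right), centromeric (bool: bin overlaps the
    centromere interval), d_cen (bp, bin midpoint to centromere midpoint),
    d_tel (bp, bin midpoint to nearest chromosome end), r (relative axis
    position in [0, 1]: 0 at the centromere, 1 at the telomere end of the
    arm).
    """

    df: pd.DataFrame
    genome: GenomeSpec = field(repr=False)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def n_bins(self) -> int:
        return len(self.df)

    @property
    def chrom(self) -> np.ndarray:
        return self.df["chrom"].to_numpy()

    @property
    def start(self) -> np.ndarray:
        return self.df["start"].to_numpy()

    @property
    def end(self) -> np.ndarray:
        return self.df["end"].to_numpy()

    @property
    def mid(self) -> np.ndarray:
        return 0.5 * (self.start + self.end)

    @property
    def arm(self) -> np.ndarray:
        return self.df["arm"].to_numpy()

    @property
    def centromeric(self) -> np.ndarray:
        return self.df["centromeric"].to_numpy()

    @property
    def d_cen(self) -> np.ndarray:
        return self.df["d_cen"].to_numpy()

    @property
    def d_tel(self) -> np.ndarray:
        return self.df["d_tel"].to_numpy()

    @property
    def r(self) -> np.ndarray:
        return self.df["r"].to_numpy()

    def chrom_slice(self, chrom: str) -> slice:
        """Global-index slice of one chromosome's bins (bins are contiguous)."""
        idx = np.flatnonzero(self.chrom == chrom)
        if idx.size == 0:
            raise KeyError(chrom)
        return slice(int(idx[0]), int(idx[-1]) + 1)

    def cis_mask(self) -> np.ndarray:
        """Boolean N×N matrix, True where both bins share a chromosome."""
        c = self.chrom
        return c[:, None] == c[None, :]


def make_bins(genome: GenomeSpec) -> BinTable:
    """Tile each chromosome with fixed-width bins and annotate arm geometry.

    The last bin of a chromosome may be short. A bin is tagged centromeric
    when it overlaps the centromere interval; arm assignment and the
    relative axis coordinate r anchor on the centromere midpoint.
    """
    rows = []
    gi = 0
    for ci, (name, length) in enumerate(zip(genome.chrom_names, genome.chrom_lengths)):
        cs, ce = genome.centromeres[ci]
        cmid = 0.5 * (cs + ce)
        n = math.ceil(length / genome.bin_size)
        for b in range(n):
            start = b * genome.bin_size
            end = min(start + genome.bin_size, length)
            mid = 0.5 * (start + end)
            arm = "P" if mid < cmid else "Q"
            d_cen = abs(mid - cmid)
            d_tel = min(mid, length - mid)
            arm_len = cmid if arm == "P" else length - cmid
            r = min(d_cen / arm_len, 1.0) if arm_len > 0 else 0.0
            rows.append(
                dict(
                    chrom=name,
                    start=start,
                    end=end,
                    global_index=gi,
                    arm=arm,
                    centromeric=(start < ce and end > cs),
                    d_cen=d_cen,
                    d_tel=d_tel,
                    r=r,
                )
            )
            gi += 1
    return BinTable(df=pd.DataFrame(rows), genome=genome)


def region_masks(
    bins: BinTable, cen_fraction: float = 0.1, tel_fraction: float = 0.1
) -> dict[str, np.ndarray]:
    """Partition the bins of ACA-eligible chromosomes into CEN/TEL/ARM sets.

    Fractions are of each arm's length: per arm, bins with r below
    ``cen_fraction`` are CEN, bins with r above ``1 - tel_fraction`` are
    TEL, the remainder ARM. Bins of ineligible chromosomes belong to no
    set. Returns genome-wide boolean vectors keyed "CEN", "TEL", "ARM".
    """
    if cen_fraction <= 0 or tel_fraction <= 0:
        raise ValueError("cen_fraction and tel_fraction must be positive")
    if cen_fraction + 2 * tel_fraction >= 1:
        raise ValueError("cen_fraction + 2*tel_fraction must be < 1")
    n = len(bins)
    cen = np.zeros(n, dtype=bool)
    tel = np.zeros(n, dtype=bool)
    arm = np.zeros(n, dtype=bool)
    eligible = set(bins.genome.eligible_chroms)
    r = bins.r
    for name in bins.genome.chrom_names:
        if name not in eligible:
            continue
        sl = bins.chrom_slice(name)
        for arm_name in ("P", "Q"):
            on_arm = np.zeros(n, dtype=bool)
            on_arm[sl] = bins.arm[sl] == arm_name
            if not on_arm.any():
                continue
            is_cen = on_arm & (r < cen_fraction)
            is_tel = on_arm & (r >= 1 - tel_fraction) & ~is_cen
            # guarantee non-empty CEN and TEL per arm: fall back to the
            # single most-proximal / most-distal bin
            arm_idx = np.flatnonzero(on_arm)
            order = arm_idx[np.argsort(r[arm_idx], kind="stable")]
            if not is_cen.any():
                is_cen[order[0]] = True
            if not is_tel.any():
                cand = order[-1]
                if is_cen[cand]:
                    raise ValueError(
                        "fractions leave no telomeric bin on an arm; "
                        "reduce cen_fraction or tel_fraction"
                    )
                is_tel[cand] = True
            is_arm = on_arm & ~is_cen & ~is_tel
            if not is_arm.any():
                raise ValueError(
                    "cen_fraction/tel_fraction leave an empty ARM set"
                )
            cen |= is_cen
            tel |= is_tel
            arm |= is_arm
    return {"CEN": cen, "TEL": tel, "ARM": arm}


def read_chrom_sizes(path) -> dict[str, int]:
    """Read a two-column chrom.sizes TSV (name, length in bp)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"],
                     dtype={"chrom": str, "length": np.int64}, comment="#")
    return dict(zip(df["chrom"], df["length"]))


def read_centromeres_bed(path) -> dict[str, tuple[int, int]]:
    """Read centromere intervals from a BED3 file (one line per chromosome)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     usecols=[0, 1, 2], names=["chrom", "start", "end"],
                     dtype={"chrom": str, "start": np.int64, "end": np.int64})
    return {row.chrom: (int(row.start), int(row.end)) for row in df.itertuples()}


def genome_from_files(sizes_path, centromeres_path, bin_size: int,
                      telomere_extent: int = 0) -> GenomeSpec:
    """Assemble a GenomeSpec from chrom.sizes + centromere BED files."""
    sizes = read_chrom_sizes(sizes_path)
    cens = read_centromeres_bed(centromeres_path)
    missing = [c for c in sizes if c not in cens]
    if missing:
        raise ValueError(f"centromere BED is missing chromosomes: {missing}")
    names = tuple(sizes)
    return GenomeSpec(
        chrom_names=names,
        chrom_lengths=tuple(sizes[c] for c in names),
        centromeres=tuple(cens[c] for c in names),
        bin_size=bin_size,
        telomere_extent=telomere_extent,
    )
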