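"""Aggregate chromosome analysis (ACA) and architecture scores.

Every ACA-eligible (metacentric/submetacentric) chromosome is rescaled to
a common axis of 2m bins anchored at the centromere midpoint — P-arm
telomere at 0, centromere at m, Q-arm telomere at 2m-1 — and the rescaled
O/E maps are averaged over chromosomes (cis) and over chromosome pairs
(trans). Four scalar scores summarize the aggregate:

* ``s_cencen`` — trans centromere-centromere clustering;
* ``s_teltel`` — trans telomere-telomere clustering;
* ``s_centel_axis`` — alignment of the centromere-to-telomere axis across
  chromosomes (same relative arm position r interacting in trans);
* ``s_ct`` — chromosome-territory score, the genome-wide cis/trans
  contact ratio on balanced matrices.

The three trans clustering/alignment scores are log2 ratios against a
matched control. Because centromere bins all share r ~ 0 (and telomere
bins r ~ 1), an axis-alignment signal mechanically enriches the CEN x CEN
and TEL x TEL blocks too; measuring each block against the same-|Δr| band
background (and the axis against the band with those blocks excluded)
decouples the three signals. All scores are zero in expectation when no
architecture is present and invariant to global count rescaling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import math

import numpy as np

from .contacts import ContactMatrix
from .genome import GenomeSpec

__all__ = [
    "AggregateMap",
    "ArchitectureScores",
    "rescale_chromosome",
    "rescale_pair",
    "aggregate",
    "architecture_scores",
]


@dataclass
class AggregateMap:
    """Mean rescaled O/E over chromosomes (cis) and chromosome pairs (trans)."""

    cis: np.ndarray | None          # (2m, 2m), NaN where no contribution
    trans: np.ndarray | None        # (2m, 2m) mean over unordered pairs
    m: int
    n_cis: int = 0                  # chromosomes contributing
    n_trans: int = 0                # unordered pairs contributing
    cis_contrib: np.ndarray | None = None
    trans_contrib: np.ndarray | None = None


@dataclass
class ArchitectureScores:
    """The four log2 architecture scores for one sample."""

    s_cencen: float
    s_teltel: float
    s_centel_axis: float
    s_ct: float
    params: dict = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def as_dict(self) -> dict[str, float]:
        return {
            "s_cencen": self.s_cencen,
            "s_teltel": self.s_teltel,
            "s_centel_axis": self.s_centel_axis,
            "s_ct": self.s_ct,
        }


def _arm_weights(genome: GenomeSpec, bins, chrom: str, m: int) -> np.ndarray:
    """(2m, n_chrom_bins) fractional-overlap weights mapping bins onto the
    rescaled axis: P arm -> rows 0..m-1 (telomere first), Q arm -> m..2m-1
    (telomere last)."""
    sl = bins.chrom_slice(chrom)
    starts = bins.start[sl].astype(float)
    ends = bins.end[sl].astype(float)
    length = float(genome.chrom_lengths[genome.chrom_names.index(chrom)])
    cmid = genome.centromere_mid(chrom)
    w = np.zeros((2 * m, sl.stop - sl.start))
    for u in range(2 * m):
        if u < m:                      # P arm slice
            lo = u * cmid / m
            hi = (u + 1) * cmid / m
        else:                          # Q arm slice
            lo = cmid + (u - m) * (length - cmid) / m
            hi = cmid + (u - m + 1) * (length - cmid) / m
        w[u] = np.maximum(0.0, np.minimum(ends, hi) - np.maximum(starts, lo))
    return w


def _weighted_block_mean(w_row: np.ndarray, w_col: np.ndarray,
                         block: np.ndarray) -> np.ndarray:
    """Masked overlap-weighted mean of ``block`` cells per rescaled cell."""
    finite = np.isfinite(block)
    filled = np.where(finite, block, 0.0)
    num = w_row @ filled @ w_col.T
    den = w_row @ finite.astype(float) @ w_col.T
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    out[den == 0] = np.nan
    return out


def rescale_chromosome(matrix: ContactMatrix, chrom: str, m: int = 20,
                       layer: str = "oe") -> np.ndarray:
    """Rescale one chromosome's cis block onto the (2m, 2m) common axis."""
    if m < 2:
        raise ValueError("m must be >= 2")
    genome = matrix.bins.genome
    if not genome.is_aca_eligible(chrom):
        raise ValueError(f"chromosome {chrom!r} is not ACA-eligible")
    sl = matrix.bins.chrom_slice(chrom)
    block = getattr(matrix, layer)[sl, sl]
    w = _arm_weights(genome, matrix.bins, chrom, m)
    return _weighted_block_mean(w, w, block)


def rescale_pair(matrix: ContactMatrix, chrom_a: str, chrom_b: str,
                 m: int = 20, layer: str = "oe") -> np.ndarray:
    """Rescale the trans block of a chromosome pair, symmetrized over the
    two orientations (rows of a vs rows of b)."""
    genome = matrix.bins.genome
    sa = matrix.bins.chrom_slice(chrom_a)
    sb = matrix.bins.chrom_slice(chrom_b)
    block = getattr(matrix, layer)[sa, sb]
    wa = _arm_weights(genome, matrix.bins, chrom_a, m)
    wb = _arm_weights(genome, matrix.bins, chrom_b, m)
    r = _weighted_block_mean(wa, wb, block)
    return 0.5 * (r + r.T)


def aggregate(matrix: ContactMatrix, m: int = 20, layer: str = "oe") -> AggregateMap:
    """Average rescaled cis and trans O/E maps over eligible chromosomes.

    Chromosome averaging is unweighted; an arm whose bins are entirely
    masked drops its chromosome with a warning-level note in the map's
    contribution counts. Requires >= 1 eligible chromosome (cis) and >= 2
    (trans); with < 2 the trans map is None and trans scores undefined.
    """
    genome = matrix.bins.genome
    eligible = [c for c in genome.eligible_chroms
                if _has_unmasked_arms(matrix, c)]
    cis_stack = [rescale_chromosome(matrix, c, m, layer) for c in eligible]
    cis = _nanmean_stack(cis_stack) if cis_stack else None
    trans_stack = [
        rescale_pair(matrix, a, b, m, layer)
        for i, a in enumerate(eligible) for b in eligible[i + 1:]
    ]
    trans = _nanmean_stack(trans_stack) if trans_stack else None
    agg = AggregateMap(
        cis=cis, trans=trans, m=m,
        n_cis=len(cis_stack), n_trans=len(trans_stack),
    )
    if cis_stack:
        agg.cis_contrib = np.sum([np.isfinite(x) for x in cis_stack], axis=0)
    if trans_stack:
        agg.trans_contrib = np.sum([np.isfinite(x) for x in trans_stack], axis=0)
    return agg


def _has_unmasked_arms(matrix: ContactMatrix, chrom: str) -> bool:
    sl = matrix.bins.chrom_slice(chrom)
    arm = matrix.bins.arm[sl]
    ok = matrix.valid_mask[sl]
    return bool(ok[arm == "P"].any() and ok[arm == "Q"].any())


def _nanmean_stack(stack: list[np.ndarray]) -> np.ndarray:
    arr = np.stack(stack)
    with np.errstate(invalid="ignore"):
        out = np.nanmean(arr, axis=0)
    return out


def _rescaled_r(m: int) -> np.ndarray:
    """Relative arm position r of each rescaled index (0 at centromere)."""
    u = np.arange(2 * m, dtype=float)
    r = np.where(u < m, 1.0 - (u + 0.5) / m, (u - m + 0.5) / m)
    return r


def architecture_scores(
    agg: AggregateMap,
    matrix: ContactMatrix | None = None,
    cen_fraction: float = 0.1,
    tel_fraction: float = 0.1,
    control: str = "band",
) -> ArchitectureScores:
    """Score the four architectures from an aggregate map.

    On the rescaled axis of 2m bins: CEN is the central ceil(2m *
    cen_fraction) bins around the centromere (position m), TEL the first
    and last ceil(m * tel_fraction) bins, ARM the remainder. The axis band
    holds cells whose two rescaled positions have relative arm positions
    within w/m of each other (w = ceil(m * tel_fraction)), which covers
    both the main diagonal and the P/Q mirror anti-diagonal.

    ``control='band'`` (default) scores CEN x CEN and TEL x TEL against
    the band background restricted to ARM positions (kernel tails of a
    clustering signal would otherwise leak into the control), and the
    axis as band-vs-offband over ARM x ARM cells.
    ``control='arm'`` uses the plain ARM x ARM denominator instead (the
    two clustering signals then absorb part of an axis signal).

    ``s_ct`` needs the balanced genome-wide matrix and is NaN when
    ``matrix`` is not supplied. Scores over empty regions are NaN, never
    zero.
    """
    m = agg.m
    two_m = 2 * m
    n_cen = math.ceil(two_m * cen_fraction)
    n_tel = math.ceil(m * tel_fraction)
    idx = np.arange(two_m)
    cen_set = (idx >= m - (n_cen + 1) // 2) & (idx < m - (n_cen + 1) // 2 + n_cen)
    tel_set = (idx < n_tel) | (idx >= two_m - n_tel)
    arm_set = ~cen_set & ~tel_set

    s_cencen = s_teltel = s_axis = float("nan")
    if agg.trans is not None:
        t = agg.trans
        r = _rescaled_r(m)
        band = np.abs(r[:, None] - r[None, :]) <= n_tel / m + 1e-12
        cen2 = cen_set[:, None] & cen_set[None, :]
        tel2 = tel_set[:, None] & tel_set[None, :]
        blocks = cen2 | tel2
        arm2 = arm_set[:, None] & arm_set[None, :]
        if control == "band":
            bg = band & arm2
            s_cencen = _log2_ratio(t[cen2], t[bg])
            s_teltel = _log2_ratio(t[tel2], t[bg])
            s_axis = _log2_ratio(t[bg], t[~band & arm2])
        elif control == "arm":
            s_cencen = _log2_ratio(t[cen2], t[arm2])
            s_teltel = _log2_ratio(t[tel2], t[arm2])
            s_axis = _log2_ratio(t[band & ~blocks], t[~band & ~blocks])
        else:
            raise ValueError("control must be 'band' or 'arm'")

    s_ct = float("nan")
    if matrix is not None:
        s_ct = ct_score(matrix)

    return ArchitectureScores(
        s_cencen=s_cencen, s_teltel=s_teltel, s_centel_axis=s_axis, s_ct=s_ct,
        params=dict(m=m, cen_fraction=cen_fraction, tel_fraction=tel_fraction,
                    control=control),
        metadata=dict(matrix.metadata) if matrix is not None else {},
    )


def ct_score(matrix: ContactMatrix) -> float:
    """Chromosome-territory score: log2 of the genome-wide mean balanced
    cis contact (off-diagonal) over the mean balanced trans contact."""
    if matrix.balanced is None:
        raise ValueError("balanced layer required for the CT score")
    cis = matrix.bins.cis_mask()
    off_diag = ~np.eye(matrix.n_bins, dtype=bool)
    b = matrix.balanced
    cis_vals = b[cis & off_diag]
    trans_vals = b[~cis]
    return _log2_ratio(cis_vals, trans_vals)


def _log2_ratio(num_cells: np.ndarray, den_cells: np.ndarray) -> float:
    num = np.nanmean(num_cells) if np.isfinite(num_cells).any() else np.nan
    den = np.nanmean(den_cells) if np.isfinite(den_cells).any() else np.nan
    if not (np.isfinite(num) and np.isfinite(den)) or num <= 0 or den <= 0:
        return float("nan")
    return float(np.log2(num / den))
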