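"""Contact-matrix container, sparse COO text I/O, ICE balancing and O/E.

The on-disk format is an upper-triangle TSV of ``bin_i  bin_j  count``
triplets with 0-based global bin indices (``bin_i <= bin_j``); duplicate
records are summed on read. Normalization follows the standard Hi-C
recipe: low-coverage bins are masked, the matrix is balanced by iterative
correction (ICE, a symmetric Sinkhorn scheme that equalizes unmasked
marginals), and observed/expected layers divide the balanced signal by a
genome-wide cis distance-decay curve and per-pair trans block means.
Masked or undefined entries propagate as NaN — aggregate statistics
downstream are always masked means, never zero-filled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import BinTable

__all__ = [
    "ContactMatrix",
    "ExpectedProfile",
    "read_coo",
    "write_coo",
    "mask_low_coverage",
    "ice_balance",
    "expected_profile",
    "observed_over_expected",
]


@dataclass
class ContactMatrix:
    """Genome-wide binned symmetric contact map.

    Layers: ``raw`` (counts), ``balanced`` (after ICE), ``oe``
    (balanced / expected). ``valid_mask`` flags bins that take part in
    normalization; masked bins carry NaN rows/columns in the balanced and
    O/E layers.
    """

    bins: BinTable
    raw: np.ndarray
    valid_mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    balanced: np.ndarray | None = None
    oe: np.ndarray | None = None
    bias: np.ndarray | None = None
    converged: bool | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.bins)
        self.raw = np.asarray(self.raw, dtype=float)
        if self.raw.shape != (n, n):
            raise ValueError(f"counts must be {n}x{n} to match the bin table")
        if not np.allclose(self.raw, self.raw.T, atol=1e-9):
            raise ValueError("contact matrix must be symmetric")
        if np.any(self.raw < 0):
            raise ValueError("contact counts must be non-negative")
        if self.valid_mask is None:
            self.valid_mask = np.ones(n, dtype=bool)

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    def total(self) -> float:
        """Total contacts counted once per pair (upper triangle + diagonal)."""
        return float(np.triu(self.raw).sum())


def read_coo(path, bins: BinTable) -> ContactMatrix:
    """Read an upper-triangle COO TSV into a dense symmetric matrix.

    Duplicate (i, j) records are summed. Rejects negative counts and
    out-of-range indices with the offending line number.
    """
    n = len(bins)
    df = pd.read_csv(
        path, sep="\t", header=None, names=["i", "j", "count"], comment="#",
        dtype={"i": np.int64, "j": np.int64, "count": np.float64},
    )
    bad = np.flatnonzero((df["i"].to_numpy() >= n) | (df["j"].to_numpy() >= n)
                         | (df["i"].to_numpy() < 0) | (df["j"].to_numpy() < 0))
    if bad.size:
        raise ValueError(
            f"{path}: bin index out of range (< 0 or >= {n}) at line {bad[0] + 1}"
        )
    neg = np.flatnonzero(df["count"].to_numpy() < 0)
    if neg.size:
        raise ValueError(f"{path}: negative count at line {neg[0] + 1}")
    mat = np.zeros((n, n))
    # lower-triangle records are tolerated; symmetrization sums both sides
    np.add.at(mat, (df["i"].to_numpy(), df["j"].to_numpy()), df["count"].to_numpy())
    mat = mat + mat.T - np.diag(np.diag(mat))
    return ContactMatrix(bins=bins, raw=mat)


def write_coo(matrix: ContactMatrix, path) -> None:
    """Write the raw layer as sorted upper-triangle nonzero triplets."""
    i, j = np.nonzero(np.triu(matrix.raw))
    c = matrix.raw[i, j]
    df = pd.DataFrame({"i": i, "j": j, "count": c})
    # integers written without a trailing .0 so round-trips are bytewise clean
    if np.allclose(c, np.round(c)):
        df["count"] = df["count"].astype(np.int64)
    df.to_csv(path, sep="\t", header=False, index=False)


def mask_low_coverage(matrix: ContactMatrix, min_fraction: float = 0.02) -> np.ndarray:
    """Mask all-zero bins and the lowest-coverage tail of nonzero bins.

    Bins whose marginal falls below the ``min_fraction`` quantile of the
    nonzero marginals are masked (in addition to all-zero bins). Updates
    and returns ``matrix.valid_mask``.
    """
    if not (0 <= min_fraction < 1):
        raise ValueError("min_fraction must be in [0, 1)")
    marg = matrix.raw.sum(axis=1)
    valid = marg > 0
    if min_fraction > 0 and valid.any():
        cutoff = np.quantile(marg[valid], min_fraction)
        valid &= marg > cutoff * (1 - 1e-12)
        # quantile cut is half-open: keep bins exactly at the cutoff
        valid |= (marg > 0) & np.isclose(marg, cutoff)
    matrix.valid_mask = valid
    return valid


def ice_balance(
    matrix: ContactMatrix, max_iter: int = 200, tol: float = 1e-6
) -> ContactMatrix:
    """Iterative correction: equalize unmasked marginals of the contact map.

    Repeatedly divides rows/columns by their marginal relative to the mean
    unmasked marginal until the maximum relative deviation drops below
    ``tol``. Stores the balanced layer (masked bins NaN), the accumulated
    per-bin bias vector, and a convergence flag. An input whose marginals
    are already equal is a fixed point and is returned unchanged. The bias
    gauge is fixed by the mean-marginal convention (raw = b_i b_j *
    balanced up to one global scalar shared with the balanced layer).
    """
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    if tol <= 0:
        raise ValueError("tol must be positive")
    n = matrix.n_bins
    valid = matrix.valid_mask.copy()
    w = matrix.raw[np.ix_(valid, valid)].astype(float)
    bias = np.ones(valid.sum())
    converged = False
    if w.size == 0 or w.sum() == 0:
        matrix.converged = False
        matrix.balanced = np.full((n, n), np.nan)
        matrix.bias = np.full(n, np.nan)
        return matrix
    for _ in range(max_iter):
        marg = w.sum(axis=1)
        if np.any(marg == 0):
            # a disconnected all-zero unmasked block cannot be balanced
            converged = False
            break
        m = marg / marg.mean()
        dev = np.abs(m - 1).max()
        if dev < tol:
            converged = True
            break
        w /= np.outer(m, m)
        bias *= m
    else:
        marg = w.sum(axis=1)
        converged = bool(marg.min() > 0 and np.abs(marg / marg.mean() - 1).max() < tol)

    balanced = np.full((n, n), np.nan)
    balanced[np.ix_(valid, valid)] = w
    full_bias = np.full(n, np.nan)
    full_bias[valid] = bias
    matrix.balanced = balanced
    matrix.bias = full_bias
    matrix.converged = converged
    return matrix


@dataclass
class ExpectedProfile:
    """Expected contact value by cis distance and by trans chromosome pair.

    ``cis[k]`` is the mean balanced value over unmasked same-chromosome
    pairs at bin separation k, pooled genome-wide (one decay curve; entry 0
    is the main diagonal); NaN where no unmasked pair exists.
    ``trans[(c1, c2)]`` is the mean unmasked raw value in that
    inter-chromosomal block: trans O/E is taken against the coverage
    profile (raw over block mean, i.e. balanced over a block expectation
    of 1/(b_i b_j)). Balancing a map whose marginals genuinely vary with
    the cis decay would otherwise inflate chromosome-end bins' balanced
    trans values and fake telomere clustering.
    """

    cis: np.ndarray
    trans: dict[tuple[str, str], float]

    def lookup(self, bins: BinTable) -> np.ndarray:
        """Dense N×N matrix of expected values for every bin pair."""
        n = len(bins)
        chrom = bins.chrom
        out = np.full((n, n), np.nan)
        names = bins.genome.chrom_names
        for a in names:
            sa = bins.chrom_slice(a)
            na = sa.stop - sa.start
            k = np.abs(np.arange(na)[:, None] - np.arange(na)[None, :])
            out[sa, sa] = self.cis[k]
            for b in names:
                if b <= a:
                    continue
                sb = bins.chrom_slice(b)
                key = (a, b) if (a, b) in self.trans else (b, a)
                v = self.trans.get(key, np.nan)
                out[sa, sb] = v
                out[sb, sa] = v
        # use genome order, not lexical, for pair lookup above
        del chrom
        return out


def expected_profile(matrix: ContactMatrix, per_chromosome: bool = False) -> ExpectedProfile:
    """Mean balanced signal per cis distance (pooled) and per trans block.

    ``per_chromosome`` is accepted for API symmetry but the pooled curve is
    the default and the only mode used by the pipeline; per-chromosome
    curves are unstable on small genomes.
    """
    if matrix.balanced is None:
        raise ValueError("run ice_balance before expected_profile")
    bins = matrix.bins
    names = bins.genome.chrom_names
    max_sep = max(
        bins.chrom_slice(c).stop - bins.chrom_slice(c).start for c in names
    )
    sums = np.zeros(max_sep)
    cnts = np.zeros(max_sep)
    for c in names:
        sl = bins.chrom_slice(c)
        blk = matrix.balanced[sl, sl]
        nc = blk.shape[0]
        for k in range(nc):
            d = np.diagonal(blk, offset=k)
            ok = ~np.isnan(d)
            sums[k] += d[ok].sum()
            cnts[k] += ok.sum()
    with np.errstate(invalid="ignore"):
        cis = np.where(cnts > 0, sums / np.maximum(cnts, 1), np.nan)
    trans: dict[tuple[str, str], float] = {}
    ok = matrix.valid_mask
    for ia, a in enumerate(names):
        for b in names[ia + 1:]:
            sa, sb = bins.chrom_slice(a), bins.chrom_slice(b)
            blk = matrix.raw[sa, sb][np.ix_(ok[sa], ok[sb])]
            trans[(a, b)] = float(blk.mean()) if blk.size else np.nan
    return ExpectedProfile(cis=cis, trans=trans)


def observed_over_expected(
    matrix: ContactMatrix, expected: ExpectedProfile | None = None
) -> ContactMatrix:
    """Divide observed signal by the expected profile; stores ``oe``.

    Cis entries are balanced values over the pooled distance-decay curve;
    trans entries are raw values over the raw block mean (the bias-aware
    trans expectation, see ExpectedProfile). Masked or undefined entries
    are NaN. The mean of each cis diagonal over unmasked pairs is 1 by
    construction, as is the mean of each trans block.
    """
    if matrix.balanced is None:
        raise ValueError("run ice_balance before observed_over_expected")
    if expected is None:
        expected = expected_profile(matrix)
    exp = expected.lookup(matrix.bins)
    cis = matrix.bins.cis_mask()
    obs = np.where(cis, matrix.balanced, matrix.raw)
    invalid = ~matrix.valid_mask
    obs[invalid, :] = np.nan
    obs[:, invalid] = np.nan
    with np.errstate(invalid="ignore", divide="ignore"):
        oe = obs / exp
    oe[~np.isfinite(oe)] = np.nan
    matrix.oe = oe
    return matrix


def normalize(matrix: ContactMatrix, min_fraction: float = 0.02,
              max_iter: int = 200, tol: float = 1e-6) -> ContactMatrix:
    """Convenience: mask → ICE → O/E in one call."""
    mask_low_coverage(matrix, min_fraction)
    ice_balance(matrix, max_iter=max_iter, tol=tol)
    observed_over_expected(matrix)
    return matrix
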