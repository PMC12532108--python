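"""A/B eigenvector, 5-state subcompartment inference and strength.

The compartment eigenvector (E1) is the leading eigenvector of the
per-chromosome Pearson correlation matrix of cis O/E rows, optionally
computed after masking centromere-proximal bins (centromere clustering in
Rabl-configured nuclei polarizes E1 along the arm and masking reduces that
bias). Subcompartments are called from trans contacts: each bin's profile
of O/E values against all bins of other chromosomes is reduced to the top
eigenvectors of the inter-chromosomal correlation structure and clustered
with k-means into K=5 states, which are then assigned the names A1, A2,
B1, B2, B3 by integrating each state's mean E1 (A vs B pool) with its
mean epigenetic-track levels. Per-state compartmentalization strength is
the log2 ratio of within-state to cross-state mean O/E over long-range
cis plus trans pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans

from .contacts import ContactMatrix

__all__ = [
    "TrackSet",
    "SubcompartmentProfile",
    "compute_e1",
    "infer_states",
    "label_states",
    "compartmentalization_strength",
    "call_subcompartments",
]

LABELS = ("A1", "A2", "B1", "B2", "B3")


@dataclass
class TrackSet:
    """Per-bin numeric tracks (missing values allowed as NaN).

    Expected columns: active_mark, polycomb_mark, het_mark, expression,
    repeat_density — arbitrary units; only relative levels matter.
    """

    df: pd.DataFrame

    def __len__(self) -> int:
        return len(self.df)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.df[name].to_numpy()

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.df.columns)

    def write_bedgraph(self, bins, track: str, path) -> None:
        out = bins.df[["chrom", "start", "end"]].copy()
        out["value"] = self.df[track].to_numpy()
        out.to_csv(path, sep="\t", header=False, index=False)


@dataclass
class SubcompartmentProfile:
    """Full subcompartment call for one sample."""

    e1: np.ndarray                       # per-bin eigenvector value (NaN masked)
    raw_state: np.ndarray                # int 0..K-1, -1 where missing
    label: np.ndarray                    # object array of LABELS or None
    state_scores: np.ndarray             # N x K negative distances to centroids
    strength: dict[str, float] = field(default_factory=dict)
    evidence: pd.DataFrame | None = None  # state x (n, mean e1, track means)
    mapping: dict[int, str] = field(default_factory=dict)


def compute_e1(
    matrix: ContactMatrix,
    mask_centromeres: bool = True,
    cen_flank: float = 500_000.0,
    tracks: TrackSet | None = None,
    min_bins: int = 10,
) -> np.ndarray:
    """Leading eigenvector of the cis O/E correlation matrix, per chromosome.

    Bins within ``cen_flank`` bp of the centromere interval are removed
    before the correlation when ``mask_centromeres`` is set and reported
    NaN. The sign is oriented so that E1 correlates positively with the
    active mark when tracks are given; otherwise so the largest-magnitude
    entry is positive (arbitrary but deterministic). Chromosomes with
    fewer than ``min_bins`` usable bins get NaN.
    """
    if matrix.oe is None:
        raise ValueError("O/E layer required: run observed_over_expected first")
    bins = matrix.bins
    genome = bins.genome
    e1 = np.full(len(bins), np.nan)
    for ci, chrom in enumerate(genome.chrom_names):
        sl = bins.chrom_slice(chrom)
        use = matrix.valid_mask[sl].copy()
        if mask_centromeres:
            cs, ce = genome.centromeres[ci]
            near = (bins.end[sl] > cs - cen_flank) & (bins.start[sl] < ce + cen_flank)
            use &= ~near
        idx = np.flatnonzero(use)
        if idx.size < min_bins:
            continue
        block = matrix.oe[sl, sl][np.ix_(idx, idx)]
        block = np.where(np.isfinite(block), block, np.nan)
        # rows with any NaN would poison corrcoef; impute with row means
        row_mean = np.nanmean(block, axis=1, keepdims=True)
        block = np.where(np.isnan(block), row_mean, block)
        with np.errstate(invalid="ignore"):
            corr = np.corrcoef(block)
        corr = np.nan_to_num(corr, nan=0.0)
        vals, vecs = np.linalg.eigh(corr)
        v = vecs[:, -1]
        if v[np.argmax(np.abs(v))] < 0:
            v = -v
        e1[np.arange(sl.start, sl.stop)[idx]] = v
    if tracks is not None and "active_mark" in tracks.names:
        act = tracks["active_mark"]
        for chrom in genome.chrom_names:
            sl = bins.chrom_slice(chrom)
            seg = e1[sl]
            ok = np.isfinite(seg) & np.isfinite(act[sl])
            if ok.sum() >= 3 and np.std(seg[ok]) > 0 and np.std(act[sl][ok]) > 0:
                if np.corrcoef(seg[ok], act[sl][ok])[0, 1] < 0:
                    e1[sl] = -seg
    return e1


def _canonical_sign(vec: np.ndarray) -> np.ndarray:
    """Fix eigenvector sign by a permutation-invariant rule."""
    s = vec.sum()
    if abs(s) > 1e-10:
        return vec if s > 0 else -vec
    return vec if vec[np.argmax(np.abs(vec))] > 0 else -vec


def _detrend_positional(profiles: np.ndarray, r: np.ndarray,
                        n_bands: int = 10) -> np.ndarray:
    """Divide each trans O/E cell by the mean of its arm-position band pair.

    Rabl-type architecture (centromere/telomere clustering, the polarized
    cen-tel axis) enriches trans contacts as a smooth function of the two
    bins' relative arm positions r; left in place it polarizes state
    inference into position bands. Dividing by per-(band, band) means
    removes any position-driven component while leaving the
    position-independent compartment checkerboard intact.
    """
    edges = np.linspace(0.0, 1.0, n_bands + 1)[1:-1]
    band = np.digitize(r, edges)
    out = profiles.copy()
    for a in range(n_bands):
        ia = band == a
        for b in range(a, n_bands):
            ib = band == b
            cells = profiles[np.ix_(ia, ib)]
            if not np.isfinite(cells).any():
                continue
            m = np.nanmean(cells)
            if m > 0:
                out[np.ix_(ia, ib)] = profiles[np.ix_(ia, ib)] / m
                if a != b:
                    out[np.ix_(ib, ia)] = profiles[np.ix_(ib, ia)] / m
    return out


def infer_states(
    matrix: ContactMatrix,
    k: int = 5,
    seed: int = 0,
    n_eigs: int = 10,
    n_init: int = 20,
    detrend: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Cluster bins into K trans-interaction states.

    Each usable bin's profile is its trans O/E vector to all bins on other
    chromosomes (missing-aware, pairwise-complete Pearson correlation
    between profiles); the correlation structure is reduced to its top
    ``n_eigs`` eigenvectors (scaled by sqrt eigenvalue) and clustered with
    k-means. ``detrend`` removes position-driven (Rabl) trans structure
    first — the trans analogue of masking centromeres before compartment
    calling. Eigenvector signs and the row order fed to k-means are
    canonicalized, so the result is invariant to permuting the input bins.

    Returns ``(raw_state, state_scores)``: integer state per bin (-1 for
    masked bins) and the negative distance of each bin to each centroid.
    """
    if matrix.oe is None:
        raise ValueError("O/E layer required: run observed_over_expected first")
    bins = matrix.bins
    n = len(bins)
    cis = bins.cis_mask()
    profiles = np.where(cis, np.nan, matrix.oe)
    if detrend:
        profiles = _detrend_positional(profiles, bins.r)
    usable = matrix.valid_mask & (np.sum(np.isfinite(profiles), axis=1) > 0)
    idx = np.flatnonzero(usable)
    if idx.size < k:
        raise ValueError(
            f"only {idx.size} usable bins for {k}-state inference"
        )
    sub = profiles[np.ix_(idx, idx)]
    corr = pd.DataFrame(sub.T).corr(min_periods=3).to_numpy()
    corr = np.nan_to_num(corr, nan=0.0)
    np.fill_diagonal(corr, 1.0)
    vals, vecs = np.linalg.eigh(corr)
    order = np.argsort(vals)[::-1][: min(n_eigs, len(vals))]
    feats = np.column_stack([
        _canonical_sign(vecs[:, j]) * np.sqrt(max(vals[j], 0.0)) for j in order
    ])
    # canonical row order -> permutation-invariant k-means
    row_order = np.lexsort(feats.T[::-1])
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    sorted_labels = km.fit_predict(feats[row_order])
    labels_sub = np.empty(idx.size, dtype=np.int64)
    labels_sub[row_order] = sorted_labels
    scores_sub = -cdist(feats, km.cluster_centers_)
    raw_state = np.full(n, -1, dtype=np.int64)
    raw_state[idx] = labels_sub
    state_scores = np.full((n, k), np.nan)
    state_scores[idx] = scores_sub
    return raw_state, state_scores


def label_states(
    raw_state: np.ndarray,
    e1: np.ndarray,
    tracks: TrackSet | None,
    bins=None,
) -> tuple[np.ndarray, dict[int, str], pd.DataFrame]:
    """Assign A1/A2/B1/B2/B3 names to raw states via E1 and track levels.

    States are pooled by mean E1 sign (A if positive); when the pools are
    not of size 2 and 3 the states with mean E1 nearest zero are moved to
    the deficient pool. Within the A pool the state with the higher mean
    active mark is A1; in the B pool the highest polycomb mark is B1 and,
    of the remaining two, the more repeat-dense (centromere proximity
    breaking near-ties) is B2, the other B3. Without tracks only the
    eigenvector is available, so labels fall back to plain A/B.

    Returns ``(label, mapping, evidence)``; evidence tabulates per-state
    bin counts, mean E1 and mean track levels behind the assignment.
    """
    states = np.unique(raw_state[raw_state >= 0])
    rows = []
    for s in states:
        m = raw_state == s
        row = {"state": int(s), "n_bins": int(m.sum()),
               "mean_e1": float(np.nanmean(e1[m])) if np.isfinite(e1[m]).any() else 0.0}
        if tracks is not None:
            for t in tracks.names:
                row[f"mean_{t}"] = float(np.nanmean(tracks[t][m]))
        if bins is not None:
            row["mean_r"] = float(np.mean(bins.r[m]))
        rows.append(row)
    ev = pd.DataFrame(rows).set_index("state")

    n = len(raw_state)
    label = np.full(n, None, dtype=object)
    if tracks is None:
        mapping = {int(s): ("A" if ev.loc[s, "mean_e1"] > 0 else "B")
                   for s in states}
        for s, lab in mapping.items():
            label[raw_state == s] = lab
        ev["label"] = [mapping[int(s)] for s in states]
        return label, mapping, ev

    # pool by E1 sign, then repair pool sizes by the nearest-zero rule
    by_e1 = ev["mean_e1"].sort_values(ascending=False)
    a_pool = [int(s) for s in by_e1.index if by_e1[s] > 0]
    b_pool = [int(s) for s in by_e1.index if by_e1[s] <= 0]
    while len(a_pool) > 2:
        a_pool.sort(key=lambda s: ev.loc[s, "mean_e1"])
        b_pool.append(a_pool.pop(0))          # smallest positive -> B
    while len(a_pool) < 2 and b_pool:
        b_pool.sort(key=lambda s: ev.loc[s, "mean_e1"], reverse=True)
        a_pool.append(b_pool.pop(0))          # least negative -> A

    mapping: dict[int, str] = {}
    a_sorted = sorted(a_pool, key=lambda s: ev.loc[s, "mean_active_mark"],
                      reverse=True)
    for s, lab in zip(a_sorted, ("A1", "A2")):
        mapping[s] = lab
    b_by_pc = sorted(b_pool, key=lambda s: ev.loc[s, "mean_polycomb_mark"],
                     reverse=True)
    if b_by_pc:
        mapping[b_by_pc[0]] = "B1"
    rest = b_by_pc[1:]
    if len(rest) == 2:
        ra, rb = rest
        da = ev.loc[ra, "mean_repeat_density"] - ev.loc[rb, "mean_repeat_density"]
        if abs(da) < 0.05 and "mean_r" in ev.columns:
            # near-tie on repeats: the centromere-proximal state is B2
            da = ev.loc[rb, "mean_r"] - ev.loc[ra, "mean_r"]
        mapping[ra if da >= 0 else rb] = "B2"
        mapping[rb if da >= 0 else ra] = "B3"
    elif len(rest) == 1:
        mapping[rest[0]] = "B2"
    for s, lab in mapping.items():
        label[raw_state == s] = lab
    ev["label"] = [mapping.get(int(s), "") for s in states]
    return label, mapping, ev


def compartmentalization_strength(
    matrix: ContactMatrix,
    label: np.ndarray,
    long_range_bp: float = 2e6,
    min_bins: int = 5,
) -> dict[str, float]:
    """log2(within-state / cross-state mean O/E), long-range cis + trans.

    Pairs enter the means only if cis-separated by at least
    ``long_range_bp`` or trans; the restriction keeps short-range
    distance-decay structure from leaking into the ratio. Labels with
    fewer than ``min_bins`` bins get NaN.
    """
    if matrix.oe is None:
        raise ValueError("O/E layer required")
    bins = matrix.bins
    mid = bins.mid
    cis = bins.cis_mask()
    sep = np.abs(mid[:, None] - mid[None, :])
    pair_ok = (~cis) | (sep >= long_range_bp)
    pair_ok &= np.isfinite(matrix.oe)
    pair_ok &= np.triu(np.ones_like(pair_ok), k=1).astype(bool)

    out: dict[str, float] = {}
    labs = [l for l in pd.unique(label) if l is not None]
    for lab in labs:
        in_s = label == lab
        if in_s.sum() < min_bins:
            out[str(lab)] = float("nan")
            continue
        both = pair_ok & in_s[:, None] & in_s[None, :]
        one = pair_ok & (in_s[:, None] ^ in_s[None, :])
        if not both.any() or not one.any():
            out[str(lab)] = float("nan")
            continue
        out[str(lab)] = float(
            np.log2(matrix.oe[both].mean() / matrix.oe[one].mean())
        )
    return out


def call_subcompartments(
    matrix: ContactMatrix,
    tracks: TrackSet | None = None,
    seed: int = 0,
    mask_centromeres: bool = True,
    cen_flank: float = 500_000.0,
    long_range_bp: float = 2e6,
) -> SubcompartmentProfile:
    """E1 → state inference → labeling → strength, in one pass."""
    e1 = compute_e1(matrix, mask_centromeres=mask_centromeres,
                    cen_flank=cen_flank, tracks=tracks)
    raw_state, scores = infer_states(matrix, seed=seed)
    label, mapping, ev = label_states(raw_state, e1, tracks, bins=matrix.bins)
    strength = compartmentalization_strength(matrix, label,
                                             long_range_bp=long_range_bp)
    return SubcompartmentProfile(
        e1=e1, raw_state=raw_state, label=label, state_scores=scores,
        strength=strength, evidence=ev, mapping=mapping,
    )
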