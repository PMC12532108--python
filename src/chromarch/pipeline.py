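"""Cross-sample statistics and the end-to-end pipeline driver.

Links the per-stage outputs together: interaction-fraction summaries
(short-range cis < 2 Mb, long-range cis >= 2 Mb, trans — fractions of raw
sequencing signal), Pearson correlations between compartmentalization
strength and architecture scores across a developmental series, and a
``run_pipeline`` driver that executes mask → ICE → O/E → ACA →
subcompartments → strengths → fractions → correlations for every stage
and writes TSV/JSON outputs deterministically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .aca import ArchitectureScores, aggregate, architecture_scores
from .contacts import ContactMatrix, normalize, write_coo
from .genome import GenomeSpec, make_bins
from .subcompartments import SubcompartmentProfile, call_subcompartments

__all__ = [
    "SeriesResult",
    "interaction_fractions",
    "correlate_series",
    "run_pipeline",
]


@dataclass
class SeriesResult:
    """Per-stage scores, strengths and fractions plus the correlation table."""

    scores: list[ArchitectureScores]
    strengths: list[dict[str, float]]
    fractions: list[dict[str, float]]
    correlations: pd.DataFrame | None = None
    profiles: list[SubcompartmentProfile] = field(default_factory=list)

    @property
    def n_stages(self) -> int:
        return len(self.scores)

    def score_table(self) -> pd.DataFrame:
        rows = []
        for k, s in enumerate(self.scores):
            row = {"stage": k, **s.as_dict()}
            row.update({f"strength_{l}": v for l, v in self.strengths[k].items()})
            row.update(self.fractions[k])
            rows.append(row)
        return pd.DataFrame(rows)


def interaction_fractions(
    matrix: ContactMatrix, threshold_bp: float = 2e6
) -> dict[str, float]:
    """Fractions of total raw contacts: cis < threshold, cis >= threshold,
    trans. Computed on raw counts (signal composition, not normalized
    signal); each unique pair counted once. Sums to 1."""
    bins = matrix.bins
    mid = bins.mid
    cis = bins.cis_mask()
    upper = np.triu(np.ones_like(cis), k=0).astype(bool)
    sep = np.abs(mid[:, None] - mid[None, :])
    total = matrix.raw[upper].sum()
    if total == 0:
        raise ValueError("empty matrix: interaction fractions undefined")
    cis_short = matrix.raw[upper & cis & (sep < threshold_bp)].sum()
    cis_long = matrix.raw[upper & cis & (sep >= threshold_bp)].sum()
    trans = matrix.raw[upper & ~cis].sum()
    return {
        "frac_cis_short": float(cis_short / total),
        "frac_cis_long": float(cis_long / total),
        "frac_trans": float(trans / total),
    }


def _pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 3 or np.std(x[ok]) == 0 or np.std(y[ok]) == 0:
        return float("nan"), float("nan")
    r, p = stats.pearsonr(x[ok], y[ok])
    return float(r), float(p)


def correlate_series(result: SeriesResult, method: str = "pearson") -> pd.DataFrame:
    """Correlate compartmentalization strength with architecture scores.

    Two tests across stages: A1 strength vs the territory score, and mean
    B2/B3 strength vs the composite Rabl score (mean of the cen-cen,
    tel-tel and cen-tel-axis scores). Reports r, the exact small-n t-based
    two-sided p, and n; r is NaN when an input is constant. Spearman is
    available for rank-based robustness at tiny n.
    """
    a1 = np.array([s.get("A1", np.nan) for s in result.strengths])
    b23 = np.array([
        np.nanmean([s.get("B2", np.nan), s.get("B3", np.nan)])
        for s in result.strengths
    ])
    s_ct = np.array([s.s_ct for s in result.scores])
    rabl = np.array([
        np.nanmean([s.s_cencen, s.s_teltel, s.s_centel_axis])
        for s in result.scores
    ])
    corr = _pearson if method == "pearson" else _spearman
    rows = []
    for name, x, y in (
        ("strength_A1~s_ct", a1, s_ct),
        ("strength_B23~rabl_composite", b23, rabl),
    ):
        ok = np.isfinite(x) & np.isfinite(y)
        r, p = corr(x, y)
        rows.append({"pair": name, "r": r, "p": p, "n": int(ok.sum())})
    table = pd.DataFrame(rows)
    result.correlations = table
    return table


def _spearman(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 3:
        return float("nan"), float("nan")
    r, p = stats.spearmanr(x[ok], y[ok])
    return float(r), float(p)


def analyze_stage(
    matrix: ContactMatrix,
    tracks=None,
    m: int = 20,
    seed: int = 0,
    min_fraction: float = 0.02,
    with_subcompartments: bool = True,
) -> tuple[ArchitectureScores, SubcompartmentProfile | None, dict[str, float]]:
    """Normalize one sample and compute scores, subcompartments, fractions."""
    fractions = interaction_fractions(matrix)
    normalize(matrix, min_fraction=min_fraction)
    agg = aggregate(matrix, m=m)
    scores = architecture_scores(agg, matrix)
    profile = None
    if with_subcompartments:
        profile = call_subcompartments(matrix, tracks=tracks, seed=seed)
    return scores, profile, fractions


def run_pipeline(config: dict, out_dir=None) -> SeriesResult:
    """Execute the full per-stage pipeline from a flat config mapping.

    Config keys (simulation mode): ``simulate`` — preset name of the
    series start (``rabl``) when true-ish; ``stages`` (int, default 5);
    ``seed``; ``total_contacts``; ``preset_start``/``preset_end``
    (default rabl → ct); ``snr`` for tracks. File mode instead takes
    ``genome_sizes``, ``centromeres``, ``bin_size`` and ``matrix_<k>``
    paths per stage. Outputs (when ``out_dir`` given): per-stage score
    and strength TSVs, label BEDs, the correlation table and a MANIFEST;
    re-running the same config reproduces every file bytewise.
    """
    from . import simulate as sim
    from .genome import genome_from_files
    from .contacts import read_coo

    seed = int(config.get("seed", 0))
    stages = int(config.get("stages", 5))
    m = int(config.get("m", 20))
    manifest: dict = {"config": {k: str(v) for k, v in config.items()},
                      "complete": False, "stages_done": []}

    if config.get("simulate"):
        genome = sim.default_genome()
        bins = make_bins(genome)
        truth = sim.plant_states(bins, seed=seed)
        p_start = sim.preset(str(config.get("preset_start", "rabl")), seed=seed,
                             total_contacts=float(config.get("total_contacts", 1e7)))
        p_end = sim.preset(str(config.get("preset_end", "ct")), seed=seed,
                           total_contacts=float(config.get("total_contacts", 1e7)))
        series = sim.simulate_series(genome, bins, truth, p_start, p_end, stages)
        tracks = sim.simulate_tracks(bins, truth,
                                     snr=float(config.get("snr", 3.0)),
                                     seed=seed + 10_000)
        stage_inputs = [mat for mat, _ in series]
    else:
        for key in ("genome_sizes", "centromeres", "bin_size"):
            if key not in config:
                raise ValueError(f"config is missing required input {key!r}")
        genome = genome_from_files(config["genome_sizes"], config["centromeres"],
                                   int(config["bin_size"]))
        bins = make_bins(genome)
        tracks = None
        stage_inputs = []
        k = 0
        while f"matrix_{k}" in config:
            path = Path(config[f"matrix_{k}"])
            if not path.exists():
                raise FileNotFoundError(f"stage {k}: matrix file {path} not found")
            stage_inputs.append(read_coo(path, bins))
            k += 1
        if not stage_inputs:
            raise ValueError("config names no matrix_<k> inputs")

    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    scores_list, strengths_list, fracs_list, profiles = [], [], [], []
    for k, mat in enumerate(stage_inputs):
        try:
            scores, profile, fracs = analyze_stage(
                mat, tracks=tracks, m=m, seed=seed,
                min_fraction=float(config.get("min_fraction", 0.02)),
            )
        except Exception as exc:
            if out is not None:
                manifest["failed_stage"] = k
                manifest["error"] = str(exc)
                (out / "MANIFEST.json").write_text(
                    json.dumps(manifest, indent=2, sort_keys=True))
            raise RuntimeError(f"pipeline failed at stage {k}: {exc}") from exc
        scores_list.append(scores)
        strengths_list.append(profile.strength if profile else {})
        fracs_list.append(fracs)
        profiles.append(profile)
        manifest["stages_done"].append(k)
        if out is not None and profile is not None:
            lab = bins.df[["chrom", "start", "end"]].copy()
            lab["name"] = [l if l is not None else "." for l in profile.label]
            lab.to_csv(out / f"stage{k}_labels.bed", sep="\t",
                       header=False, index=False)
            if config.get("write_matrices"):
                write_coo(mat, out / f"stage{k}_matrix.coo.tsv")

    result = SeriesResult(scores=scores_list, strengths=strengths_list,
                          fractions=fracs_list, profiles=profiles)
    if len(stage_inputs) >= 3:
        correlate_series(result)

    if out is not None:
        result.score_table().to_csv(out / "scores.tsv", sep="\t", index=False,
                                    float_format="%.10g")
        if result.correlations is not None:
            result.correlations.to_csv(out / "correlations.tsv", sep="\t",
                                       index=False, float_format="%.10g")
        manifest["complete"] = True
        (out / "MANIFEST.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True))
    return result
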