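"""Comparing a de novo genetic map against a reference framework.

Three summaries quantify agreement between the estimated marker order and
the anchored reference positions:

* per-group absolute Spearman rank correlation of de novo cM against
  reference cM (absolute because linkage-group orientation is arbitrary;
  tied positions receive average ranks);
* chromosome-assignment concordance — each linkage group is assigned its
  majority reference chromosome and markers anchored elsewhere are counted
  as discordant;
* local-regression displacement — a tricube-weighted local linear (loess)
  fit of reference cM on de novo cM per group; markers whose reference
  position sits farther than a threshold (default 5 cM) from the fit are
  flagged as displaced.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess

from gbsim.config import InputError
from gbsim.mapbuilder import GeneticMap

MIN_GROUP_MARKERS = 3


@dataclass
class OrderComparison:
    per_group: pd.DataFrame       # group, chrom, n_markers, spearman_abs
    n_anchored: int
    n_discordant_chromosome: int
    n_displaced: int
    threshold_cM: float

    @property
    def mean_spearman_abs(self) -> float:
        """Marker-weighted mean of per-group |rho|."""
        pg = self.per_group.dropna(subset=["spearman_abs"])
        if not len(pg):
            return float("nan")
        w = pg["n_markers"].to_numpy(dtype=float)
        return float(np.average(pg["spearman_abs"], weights=w))

    @property
    def fraction_discordant(self) -> float:
        return self.n_discordant_chromosome / max(1, self.n_anchored)

    def as_dict(self) -> dict:
        return {
            "per_group": self.per_group.to_dict(orient="records"),
            "mean_spearman_abs": self.mean_spearman_abs,
            "n_anchored": self.n_anchored,
            "n_discordant_chromosome": self.n_discordant_chromosome,
            "fraction_discordant": self.fraction_discordant,
            "n_displaced": self.n_displaced,
            "threshold_cM": self.threshold_cM,
        }


def _annotate(gmap: GeneticMap, anchors: pd.DataFrame) -> pd.DataFrame:
    """Join map markers with anchors (marker_id, chrom, ref_cM)."""
    for col in ("marker_id", "chrom", "ref_cM"):
        if col not in anchors.columns:
            raise InputError(f"anchors frame lacks column {col!r}")
    df = gmap.table.merge(anchors[["marker_id", "chrom", "ref_cM"]],
                          on="marker_id", how="left")
    grp_chrom = (df.dropna(subset=["chrom"])
                   .groupby("group")["chrom"]
                   .agg(lambda s: s.mode().iloc[0]))
    df["majority_chrom"] = df["group"].map(grp_chrom)
    return df


def spearman_order(gmap: GeneticMap, anchors: pd.DataFrame) -> pd.DataFrame:
    """Per-group |Spearman rho| between de novo and reference positions.

    Only markers anchored to the group's majority chromosome enter the
    correlation; groups with fewer than three such markers get NaN.
    """
    df = _annotate(gmap, anchors)
    rows = []
    for g, sub in df.groupby("group"):
        chrom = sub["majority_chrom"].iloc[0]
        anch = sub[(sub["chrom"] == chrom)].dropna(subset=["ref_cM"])
        if len(anch) < MIN_GROUP_MARKERS:
            rows.append((g, chrom, len(anch), np.nan))
            continue
        rho = stats.spearmanr(anch["cM"], anch["ref_cM"]).statistic
        rows.append((g, chrom, len(anch), abs(float(rho))))
    return pd.DataFrame(rows, columns=["group", "chrom", "n_markers",
                                       "spearman_abs"])


def chromosome_concordance(
    gmap: GeneticMap, anchors: pd.DataFrame,
) -> tuple[int, float]:
    """Markers whose reference chromosome differs from their group majority.

    Unanchored markers are excluded from the denominator.
    """
    df = _annotate(gmap, anchors).dropna(subset=["chrom"])
    disc = int((df["chrom"] != df["majority_chrom"]).sum())
    return disc, disc / max(1, len(df))


def _loess_fit(x: np.ndarray, y: np.ndarray, span: float) -> np.ndarray:
    """Tricube local-linear fit of y on x, evaluated at the data points."""
    if len(x) < 5:
        coef = np.polyfit(x, y, 1)
        return np.polyval(coef, x)
    return lowess(y, x, frac=span, return_sorted=False)


def displacement(
    gmap: GeneticMap, anchors: pd.DataFrame, span: float = 0.75,
    threshold_cM: float = 5.0,
) -> tuple[pd.DataFrame, int]:
    """Per-marker |loess residual| and the count exceeding the threshold.

    Each group is orientation-aligned first (its de novo cM axis is
    flipped when the rank correlation with the reference is negative).
    """
    df = _annotate(gmap, anchors)
    frames = []
    for g, sub in df.groupby("group"):
        chrom = sub["majority_chrom"].iloc[0]
        anch = sub[(sub["chrom"] == chrom)].dropna(subset=["ref_cM"]).copy()
        if len(anch) < 2:
            continue
        x = anch["cM"].to_numpy(dtype=float)
        y = anch["ref_cM"].to_numpy(dtype=float)
        rho = stats.spearmanr(x, y).statistic if len(anch) >= 3 else 1.0
        if np.isfinite(rho) and rho < 0:
            x = x.max() - x
        fitted = _loess_fit(x, y, span)
        anch["displacement_cM"] = np.abs(fitted - y)
        frames.append(anch[["marker_id", "group", "chrom",
                            "displacement_cM"]])
    if frames:
        per_marker = pd.concat(frames, ignore_index=True)
        n_over = int((per_marker["displacement_cM"] > threshold_cM).sum())
    else:
        per_marker = pd.DataFrame(columns=["marker_id", "group", "chrom",
                                           "displacement_cM"])
        n_over = 0
    return per_marker, n_over


def compare_orders(
    gmap: GeneticMap, anchors: pd.DataFrame, span: float = 0.75,
    threshold_cM: float = 5.0,
) -> OrderComparison:
    """Full order comparison: correlations, concordance and displacement."""
    per_group = spearman_order(gmap, anchors)
    n_disc, _frac = chromosome_concordance(gmap, anchors)
    df = _annotate(gmap, anchors).dropna(subset=["chrom"])
    _per_marker, n_displaced = displacement(gmap, anchors, span, threshold_cM)
    return OrderComparison(per_group, len(df), n_disc, n_displaced,
                           threshold_cM)
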