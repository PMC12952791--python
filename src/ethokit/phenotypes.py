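"""Aggregate behavioral phenotypes, strain-level z-scores, sex effects, and
dataset imbalance metrics.

A phenotype table is a pandas DataFrame with identifier columns ``animal``,
``strain``, ``sex`` (values ``M``/``F``) followed by one numeric column per
phenotype, named ``<behavior>_<metric>_<bin>`` with metric in
{duration, nBouts, avgLen} and bin in {T5, T20, T55}.

Conventions (stated once, used everywhere): a bout belongs to a time bin if
its onset falls inside the bin; the duration metric counts only behavior
frames before the bin boundary; average bout length is the mean *full*
length in seconds of the bouts assigned to the bin, 0 when the bin has no
bout.  Strain summaries are means across the strain's animals, taken before
z-scoring; z-scores use the sample (n-1) standard deviation across strains.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .annotations import Ethogram, bouts_from_frames

__all__ = [
    "ID_COLUMNS",
    "DEFAULT_BINS_MINUTES",
    "aggregate_phenotypes",
    "zscore_table",
    "sex_effect",
    "imbalance_metrics",
]

ID_COLUMNS = ("animal", "strain", "sex")
DEFAULT_BINS_MINUTES = (5, 20, 55)


def aggregate_phenotypes(
    e: Ethogram,
    fps: float | None = None,
    bins_minutes: tuple[int, ...] = DEFAULT_BINS_MINUTES,
    behavior_name: str | None = None,
) -> dict[str, float]:
    """Summarize one ethogram into the nine named aggregate phenotypes.

    Per time bin: total behavior duration in minutes (truncated at the bin
    boundary), number of bouts with onset inside the bin, and the mean full
    bout length in seconds of those bouts.
    """
    fps = float(fps if fps is not None else e.fps)
    if fps <= 0:
        raise ValueError("fps must be positive")
    name = behavior_name if behavior_name is not None else e.behavior_name
    mask = e.behavior_mask()
    bouts = bouts_from_frames(e)
    out: dict[str, float] = {}
    for minutes in bins_minutes:
        bin_frames = int(round(minutes * 60 * fps))
        in_bin = [b for b in bouts if b.start < bin_frames]
        duration_min = float(mask[:bin_frames].sum()) / fps / 60.0
        n_bouts = len(in_bin)
        avg_len_s = float(np.mean([b.length for b in in_bin]) / fps) if in_bin else 0.0
        tag = f"T{minutes}"
        out[f"{name}_duration_{tag}"] = duration_min
        out[f"{name}_nBouts_{tag}"] = float(n_bouts)
        out[f"{name}_avgLen_{tag}"] = avg_len_s
    return out


def _phenotype_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in ID_COLUMNS]


def strain_means(table: pd.DataFrame) -> pd.DataFrame:
    """Mean of each phenotype across the animals of each strain."""
    cols = _phenotype_columns(table)
    return table.groupby("strain")[cols].mean()


def zscore_table(
    table: pd.DataFrame, threshold: float = 1.0
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Z-score strain means across strains, per phenotype.

    Returns ``(z, mask, degenerate)``: the strain x phenotype z-matrix, a
    boolean mask of entries with ``|z| > threshold``, and the list of
    phenotypes with zero variance across strains (their z is set to 0).
    """
    means = strain_means(table)
    if means.shape[0] < 2:
        raise ValueError("z-scoring requires at least 2 strains")
    mu = means.mean(axis=0)
    sigma = means.std(axis=0, ddof=1)
    degenerate = [c for c in means.columns if sigma[c] == 0 or not np.isfinite(sigma[c])]
    safe_sigma = sigma.replace(0, np.nan)
    z = (means - mu) / safe_sigma
    z[degenerate] = 0.0
    mask = z.abs() > threshold
    return z, mask, degenerate


def sex_effect(table: pd.DataFrame, min_per_sex: int = 2) -> pd.DataFrame:
    """Per (strain, phenotype) Wilcoxon rank-sum test of male vs female values.

    Returns a long table with columns strain, phenotype, n_m, n_f, p, q
    (Benjamini-Hochberg across all tested cells), score (-log10 p) and
    effect (rank-biserial correlation, positive when males rank higher).
    Cells with fewer than ``min_per_sex`` animals of either sex are reported
    with a ``skipped`` reason and excluded from the correction.
    """
    rows = []
    for strain, grp in table.groupby("strain"):
        for pheno in _phenotype_columns(table):
            m = grp.loc[grp["sex"] == "M", pheno].dropna().to_numpy()
            f = grp.loc[grp["sex"] == "F", pheno].dropna().to_numpy()
            rec = {"strain": strain, "phenotype": pheno, "n_m": m.size, "n_f": f.size}
            if m.size < min_per_sex or f.size < min_per_sex:
                rec.update(p=np.nan, effect=np.nan, skipped=f"fewer than {min_per_sex} per sex")
                rows.append(rec)
                continue
            pooled = np.concatenate([m, f])
            if np.ptp(pooled) == 0:  # all values identical: no evidence either way
                p, u1 = 1.0, m.size * f.size / 2.0
            else:
                u1, p = stats.mannwhitneyu(m, f, alternative="two-sided", method="asymptotic")
            effect = 2.0 * u1 / (m.size * f.size) - 1.0  # rank-biserial, sign = M - F
            rec.update(p=float(min(p, 1.0)), effect=float(effect), skipped="")
            rows.append(rec)
    out = pd.DataFrame(rows)
    tested = out["p"].notna()
    out["q"] = np.nan
    if tested.any():
        out.loc[tested, "q"] = multipletests(out.loc[tested, "p"], method="fdr_bh")[1]
    out["score"] = -np.log10(out["p"].clip(lower=np.finfo(float).tiny))
    return out


def imbalance_metrics(counts: pd.DataFrame | dict) -> dict:
    """Strain imbalance (SI), per-strain sex imbalance (GI), and their mean (AGI).

    ``counts`` maps strain -> (n_male, n_female), either as a dict or a
    DataFrame with columns ``male``/``female`` indexed by strain.

    SI is the largest deviation of any strain's share of animals from the
    uniform share 1/n; GI_i = |m_i - f_i| / (m_i + f_i); AGI = mean_i GI_i.
    """
    if isinstance(counts, dict):
        counts = pd.DataFrame(
            {s: {"male": mf[0], "female": mf[1]} for s, mf in counts.items()}
        ).T
    m = counts["male"].to_numpy(dtype=float)
    f = counts["female"].to_numpy(dtype=float)
    totals = m + f
    if (totals <= 0).any():
        bad = counts.index[totals <= 0].tolist()
        raise ValueError(f"strains with zero animals: {bad}")
    n = totals.size
    share = totals / totals.sum()
    si = float(np.abs(share - 1.0 / n).max())
    gi = np.abs(m - f) / totals
    return {
        "SI": si,
        "GI": dict(zip(counts.index, gi.astype(float))),
        "AGI": float(gi.mean()),
    }
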