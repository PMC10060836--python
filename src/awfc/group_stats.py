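"""Group comparisons per ROI pair: Wilcoxon rank-sum tests on SC, FC and
awFC, Benjamini–Hochberg FDR per metric, and Cohen's d with size labels.
"""

from __future__ import annotations

import os
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cohort_io import ROIAtlas, _fmt
from .errors import DegenerateDataError, ValidationError
from .fusion import AwfcResult

#: largest per-group size for the exact rank-sum path
EXACT_MAX_N = 25

FDR_SCOPES = ("pooled", "per-network")

STATS_COLUMNS = [
    "start_roi",
    "end_roi",
    "network",
    "p_sc",
    "p_fc",
    "p_awfc",
    "q_sc",
    "q_fc",
    "q_awfc",
    "cohens_d",
    "size_label",
]


def wilcoxon_rank_sum(a: Sequence[float], b: Sequence[float]) -> float:
    """Two-sided two-sample Wilcoxon (Mann–Whitney) p-value.

    Uses the exact null distribution when both groups have at most
    ``EXACT_MAX_N`` observations and there are no ties; otherwise the
    normal approximation with tie and continuity corrections.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("empty sample in rank-sum test")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    if not has_ties and max(a.size, b.size) <= EXACT_MAX_N:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.pvalue)


def fdr_bh(p: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or not np.all(np.isfinite(p)):
        bad = p[(~np.isfinite(p)) | (p < 0) | (p > 1)][0]
        raise ValidationError(f"p-value {bad} outside [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def cohens_d(control: Sequence[float], adversity: Sequence[float]) -> float:
    """Pooled-SD standardized mean difference, control minus adversity."""
    c = np.asarray(control, dtype=float)
    a = np.asarray(adversity, dtype=float)
    if c.size < 2 or a.size < 2:
        raise ValidationError("each sample needs at least 2 observations")
    n1, n2 = c.size, a.size
    s1, s2 = c.var(ddof=1), a.var(ddof=1)
    pooled = ((n1 - 1) * s1 + (n2 - 1) * s2) / (n1 + n2 - 2)
    if pooled <= 0:
        raise DegenerateDataError("degenerate samples: zero pooled variance")
    return float((c.mean() - a.mean()) / np.sqrt(pooled))


def classify_effect(d: float) -> str:
    """Size label on |d|: <0.2 negligible, <0.5 small, <0.8 medium, else large."""
    m = abs(d)
    if m < 0.2:
        return "negligible"
    if m < 0.5:
        return "small"
    if m < 0.8:
        return "medium"
    return "large"


def _collect(
    results: Mapping[str, AwfcResult],
    groups: Mapping[str, str],
    pair: tuple[str, str],
    metric: str,
) -> tuple[np.ndarray, np.ndarray]:
    ctrl, adv = [], []
    for sid, res in results.items():
        v = res.pair(*pair)[metric]
        (ctrl if groups[sid] == "control" else adv).append(v)
    return np.asarray(ctrl), np.asarray(adv)


def build_results_table(
    results: Mapping[str, AwfcResult],
    groups: Mapping[str, str],
    atlas: ROIAtlas,
    *,
    pairs: Sequence[tuple[str, str]] | None = None,
    fdr_scope: str = "pooled",
    d_metric: str = "awfc",
) -> pd.DataFrame:
    """Per-pair group comparison table (one row per tested ROI pair).

    By default tests all within-network pairs of the atlas; FDR is applied
    per metric across all tested pairs ('pooled') or within each network
    ('per-network'). Cohen's d is computed on ``d_metric``.
    """
    if fdr_scope not in FDR_SCOPES:
        raise ValidationError(f"fdr_scope must be one of {FDR_SCOPES}")
    if d_metric not in ("sc", "fc", "awfc"):
        raise ValidationError("d_metric must be 'sc', 'fc' or 'awfc'")
    for sid in results:
        if sid not in groups:
            raise ValidationError(f"no group label for subject {sid}")
        if groups[sid] not in ("control", "adversity"):
            raise ValidationError(f"unknown group {groups[sid]!r} for subject {sid}")
    n_ctrl = sum(1 for s in results if groups[s] == "control")
    n_adv = sum(1 for s in results if groups[s] == "adversity")
    if n_ctrl < 2 or n_adv < 2:
        raise ValidationError(
            f"need at least 2 subjects per group, got control={n_ctrl}, "
            f"adversity={n_adv}"
        )
    if pairs is None:
        pairs = atlas.within_network_pairs()
    if not pairs:
        raise ValidationError("no ROI pairs to test")

    rows = []
    for (a, b) in pairs:
        na, nb = atlas.network_of(a), atlas.network_of(b)
        row: dict[str, object] = {
            "start_roi": a,
            "end_roi": b,
            "network": na if na == nb else "cross",
        }
        for metric in ("sc", "fc", "awfc"):
            ctrl, adv = _collect(results, groups, (a, b), metric)
            row[f"p_{metric}"] = wilcoxon_rank_sum(ctrl, adv)
        ctrl, adv = _collect(results, groups, (a, b), d_metric)
        d = cohens_d(ctrl, adv)
        row["cohens_d"] = d
        row["size_label"] = classify_effect(d)
        rows.append(row)
    df = pd.DataFrame(rows)

    for metric in ("sc", "fc", "awfc"):
        q = np.empty(len(df))
        if fdr_scope == "pooled":
            q[:] = fdr_bh(df[f"p_{metric}"].to_numpy())
        else:
            for net in df["network"].unique():
                mask = (df["network"] == net).to_numpy()
                q[mask] = fdr_bh(df.loc[mask, f"p_{metric}"].to_numpy())
        df[f"q_{metric}"] = q

    # sort by network appearance order in the atlas, then by ROI position
    net_rank = {n: k for k, n in enumerate(atlas.networks)}
    net_rank["cross"] = len(net_rank)
    pos = {lab: k for k, lab in enumerate(atlas.labels)}
    df = df.sort_values(
        by=["network", "start_roi", "end_roi"],
        key=lambda col: (
            col.map(net_rank) if col.name == "network" else col.map(pos)
        ),
        kind="stable",
    ).reset_index(drop=True)
    return df[STATS_COLUMNS]


def write_results_table(df: pd.DataFrame, path: str | os.PathLike) -> None:
    """Deterministic TSV dump of a results table."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(STATS_COLUMNS) + "\n")
        for row in df.itertuples(index=False):
            cells = []
            for col, v in zip(STATS_COLUMNS, row):
                cells.append(_fmt(v) if isinstance(v, float) else str(v))
            fh.write("\t".join(cells) + "\n")
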