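"""Fuse structural probability and functional correlation per ROI pair.

awFd = (1 − SC)·(1 − FC);  awFC = 1 − |awFd|.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort_io import LabeledMatrix, ROIAtlas, _fmt
from .errors import ValidationError
from .structural_connectivity import SCProbMatrix


def awfd(sc: float, fc: float) -> float:
    """Anatomically weighted functional dissimilarity of one pair."""
    if not 0.0 <= sc <= 1.0:
        raise ValidationError(f"sc must be in [0, 1], got {sc}")
    if not -1.0 <= fc <= 1.0:
        raise ValidationError(f"fc must be in [-1, 1], got {fc}")
    return (1.0 - sc) * (1.0 - fc)


def awfc_from_awfd(d: float) -> float:
    """Map dissimilarity back to a correlation-like value: 1 − |awFd|."""
    return 1.0 - abs(d)


@dataclass
class AwfcResult:
    """Per-pair SC, FC, awFd and awFC for one subject (square, symmetric)."""

    labels: list[str]
    sc: np.ndarray
    fc: np.ndarray
    awfd: np.ndarray
    awfc: np.ndarray

    def pair(self, a: str, b: str) -> dict[str, float]:
        i, j = self.labels.index(a), self.labels.index(b)
        return {
            "sc": float(self.sc[i, j]),
            "fc": float(self.fc[i, j]),
            "awfd": float(self.awfd[i, j]),
            "awfc": float(self.awfc[i, j]),
        }

    def awfc_matrix(self) -> LabeledMatrix:
        return LabeledMatrix(labels=self.labels, values=self.awfc, kind="awfc")

    def to_frame(self, atlas: ROIAtlas | None = None) -> pd.DataFrame:
        """Long table over unordered off-diagonal pairs.

        The network column names the shared network of a within-network pair
        and 'cross' otherwise (requires an atlas; blank without one).
        """
        rows = []
        n = len(self.labels)
        for i in range(n):
            for j in range(i + 1, n):
                net = ""
                if atlas is not None:
                    ni = atlas.network_of(self.labels[i])
                    nj = atlas.network_of(self.labels[j])
                    net = ni if ni == nj else "cross"
                rows.append(
                    {
                        "start_roi": self.labels[i],
                        "end_roi": self.labels[j],
                        "network": net,
                        "sc": self.sc[i, j],
                        "fc": self.fc[i, j],
                        "awfd": self.awfd[i, j],
                        "awfc": self.awfc[i, j],
                    }
                )
        return pd.DataFrame(rows)

    def write_tsv(self, path: str | os.PathLike, atlas: ROIAtlas | None = None) -> None:
        df = self.to_frame(atlas)
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("\t".join(df.columns) + "\n")
            for row in df.itertuples(index=False):
                fh.write(
                    f"{row.start_roi}\t{row.end_roi}\t{row.network}\t"
                    f"{_fmt(row.sc)}\t{_fmt(row.fc)}\t{_fmt(row.awfd)}\t"
                    f"{_fmt(row.awfc)}\n"
                )


def fuse_subject(
    sc: SCProbMatrix | LabeledMatrix,
    fc: LabeledMatrix,
    *,
    truncate_negative_fc: bool = False,
) -> AwfcResult:
    """Elementwise fusion over all off-diagonal pairs; diagonal awFC = 1.

    Negative FC passes through the formula verbatim unless
    ``truncate_negative_fc`` floors it at 0 first.
    """
    sc_m = sc.matrix if isinstance(sc, SCProbMatrix) else sc
    if sc_m.kind != "sc_prob":
        raise ValidationError("sc must have kind='sc_prob'")
    if fc.kind != "fc":
        raise ValidationError("fc must have kind='fc'")
    if sc_m.labels != fc.labels:
        raise ValidationError(
            "label mismatch between sc and fc: "
            f"{sorted(set(sc_m.labels) ^ set(fc.labels)) or 'same set, different order'}"
        )
    s = sc_m.values
    f = np.maximum(fc.values, 0.0) if truncate_negative_fc else fc.values
    d = (1.0 - s) * (1.0 - f)
    a = 1.0 - np.abs(d)
    np.fill_diagonal(d, 0.0)
    np.fill_diagonal(a, 1.0)
    return AwfcResult(labels=list(sc_m.labels), sc=s.copy(), fc=f.copy(), awfd=d, awfc=a)
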