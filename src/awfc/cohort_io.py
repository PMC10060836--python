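"""Cohort input/output: labeled connectivity matrices, tractography count
tables, subject manifests, motion QC and adversity group assignment.

Two text dialects are supported for square labeled matrices:

* TSV — header row of labels, first column of row labels;
* "grid" style — optional ``#`` comment lines, one line of whitespace
  separated labels, then bare numeric rows (the layout emitted by
  tract/correlation summary tools).

All parsing is locale independent (period radix) and labels are matched
case-sensitively.
"""

from __future__ import annotations

import dataclasses
import math
import os
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ManifestError, ValidationError

MATRIX_KINDS = ("fc", "tract_count", "distance", "sc_prob", "awfc")

#: motion exclusion threshold in millimetres (exclude strictly above)
QC_DISPLACEMENT_MM = 0.55

_SYM_ATOL = 1e-9


def _fmt(x: float) -> str:
    """Shortest decimal text that round-trips the float exactly."""
    if float(x) == int(x) and abs(x) < 1e15:
        return str(int(x))
    return repr(float(x))


# ---------------------------------------------------------------------------
# ROI atlas
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ROI:
    """One region of interest: id, network membership, location and size."""

    roi_id: int
    network: str
    name: str
    abbrev: str
    mni_xyz: tuple[int, int, int]
    volume_voxels: int
    label: str = ""  # unique matrix label; defaults to abbrev, deduplicated

    def __post_init__(self) -> None:
        if not self.label:
            object.__setattr__(self, "label", self.abbrev)


class ROIAtlas:
    """Ordered collection of ROIs partitioned into networks.

    Matrix labels are the ROI abbreviations; duplicated abbreviations are
    disambiguated with an ``_<roi_id>`` suffix so every label is unique.
    """

    def __init__(self, rois: Sequence[ROI]):
        rois = list(rois)
        if not rois:
            raise ValidationError("atlas has no ROIs")
        ids = [r.roi_id for r in rois]
        if sorted(ids) != list(range(1, len(rois) + 1)):
            raise ValidationError(
                "roi_ids must be unique and contiguous from 1, got %s" % ids
            )
        seen: dict[str, int] = {}
        fixed: list[ROI] = []
        for r in rois:
            label = r.label or r.abbrev
            if label in seen or any(
                o.abbrev == label and o.roi_id != r.roi_id for o in rois
            ):
                label = f"{r.abbrev}_{r.roi_id}"
            seen[label] = r.roi_id
            fixed.append(dataclasses.replace(r, label=label))
        if len({r.label for r in fixed}) != len(fixed):
            raise ValidationError("atlas labels are not unique")
        self.rois: list[ROI] = fixed

    # -- views ------------------------------------------------------------

    @property
    def labels(self) -> list[str]:
        return [r.label for r in self.rois]

    @property
    def networks(self) -> list[str]:
        """Networks in order of first appearance."""
        out: list[str] = []
        for r in self.rois:
            if r.network not in out:
                out.append(r.network)
        return out

    def network_of(self, label: str) -> str:
        for r in self.rois:
            if r.label == label:
                return r.network
        raise ValidationError(f"unknown ROI label {label!r}")

    def network_members(self, network: str) -> list[ROI]:
        return [r for r in self.rois if r.network == network]

    def coordinates(self) -> np.ndarray:
        return np.array([r.mni_xyz for r in self.rois], dtype=float)

    def within_network_pairs(self) -> list[tuple[str, str]]:
        """All unordered ROI pairs sharing a network, in network order."""
        pairs = []
        for net in self.networks:
            members = self.network_members(net)
            for a in range(len(members)):
                for b in range(a + 1, len(members)):
                    pairs.append((members[a].label, members[b].label))
        return pairs

    def __len__(self) -> int:
        return len(self.rois)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, ROIAtlas) and self.rois == other.rois


# ---------------------------------------------------------------------------
# Labeled square matrices
# ---------------------------------------------------------------------------


@dataclass
class LabeledMatrix:
    """Square numeric matrix indexed by ROI labels with a declared kind."""

    labels: list[str]
    values: np.ndarray
    kind: str

    def __post_init__(self) -> None:
        self.labels = list(self.labels)
        self.values = np.asarray(self.values, dtype=float)
        self.validate()

    # -- contract ---------------------------------------------------------

    def validate(self) -> None:
        if self.kind not in MATRIX_KINDS:
            raise ValidationError(
                f"unknown matrix kind {self.kind!r}; expected one of {MATRIX_KINDS}"
            )
        if not self.labels:
            raise ValidationError("empty matrix")
        n = len(self.labels)
        if len(set(self.labels)) != n:
            raise ValidationError("duplicate labels in matrix")
        if self.values.shape != (n, n):
            raise FormatError(
                f"non-square grid: {n} labels but values of shape {self.values.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise ValidationError(
                f"non-finite value at ({self.labels[i]}, {self.labels[j]})"
            )
        checker = getattr(self, f"_check_{self.kind}")
        checker()

    def _cell(self, i: int, j: int) -> str:
        return f"({self.labels[i]}, {self.labels[j]})"

    def _require_symmetric(self) -> None:
        d = np.abs(self.values - self.values.T)
        if d.max(initial=0.0) > _SYM_ATOL:
            i, j = np.unravel_index(np.argmax(d), d.shape)
            raise ValidationError(
                f"{self.kind} matrix not symmetric at {self._cell(i, j)}"
            )

    def _require_diag(self, value: float) -> None:
        dg = np.diag(self.values)
        if np.abs(dg - value).max() > _SYM_ATOL:
            i = int(np.argmax(np.abs(dg - value)))
            raise ValidationError(
                f"{self.kind} diagonal must be {value}, got {dg[i]} at "
                f"{self._cell(i, i)}"
            )

    def _require_range(self, lo: float, hi: float) -> None:
        bad = (self.values < lo) | (self.values > hi)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"{self.kind} value {self.values[i, j]} at {self._cell(i, j)} "
                f"outside [{lo}, {hi}]"
            )

    def _check_fc(self) -> None:
        self._require_symmetric()
        self._require_diag(1.0)
        self._require_range(-1.0, 1.0)

    def _check_awfc(self) -> None:
        self._require_symmetric()
        self._require_diag(1.0)
        self._require_range(-1.0, 1.0)

    def _check_distance(self) -> None:
        self._require_symmetric()
        self._require_diag(0.0)
        if (self.values < 0).any():
            i, j = np.argwhere(self.values < 0)[0]
            raise ValidationError(f"negative distance at {self._cell(i, j)}")

    def _check_tract_count(self) -> None:
        if (self.values < 0).any():
            i, j = np.argwhere(self.values < 0)[0]
            raise ValidationError(f"negative count at {self._cell(i, j)}")
        if not np.all(self.values == np.floor(self.values)):
            i, j = np.argwhere(self.values != np.floor(self.values))[0]
            raise ValidationError(f"non-integer count at {self._cell(i, j)}")

    def _check_sc_prob(self) -> None:
        self._require_range(0.0, 1.0)

    # -- helpers ----------------------------------------------------------

    def index_of(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise ValidationError(f"label {label!r} not in matrix") from None

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.index_of(a), self.index_of(b)])

    def off_diagonal_pairs(self) -> Iterable[tuple[str, str, float]]:
        n = len(self.labels)
        for i in range(n):
            for j in range(n):
                if i != j:
                    yield self.labels[i], self.labels[j], float(self.values[i, j])

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, LabeledMatrix)
            and self.kind == other.kind
            and self.labels == other.labels
            and np.array_equal(self.values, other.values)
        )


def _parse_float(tok: str, where: str) -> float:
    try:
        return float(tok)
    except ValueError:
        raise FormatError(f"cannot parse number {tok!r} {where}") from None


def read_labeled_matrix(path: str | os.PathLike, kind: str) -> LabeledMatrix:
    """Read a labeled square matrix in TSV or grid-style text."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = fh.readlines()
    lines = [ln.rstrip("\n") for ln in raw]
    data = [ln for ln in lines if ln.strip() and not ln.lstrip().startswith("#")]
    if not data:
        raise FormatError(f"empty matrix file: {path}")

    head = data[0].split("\t") if "\t" in data[0] else data[0].split()
    # TSV header may lead with an empty corner cell or a 'label' tag
    if head and head[0] in ("", "label", "labels"):
        head = head[1:]
    labels = [h.strip() for h in head if h.strip()]
    if not labels:
        raise FormatError(f"no labels found in {path}")
    body = data[1:]
    if len(body) != len(labels):
        raise FormatError(
            f"non-square grid in {path}: {len(labels)} labels, {len(body)} rows"
        )

    n = len(labels)
    values = np.empty((n, n), dtype=float)
    for i, ln in enumerate(body):
        toks = ln.split("\t") if "\t" in ln else ln.split()
        toks = [t for t in toks if t.strip() != ""]
        if len(toks) == n + 1:  # row label present
            if toks[0] != labels[i]:
                raise FormatError(
                    f"row label {toks[0]!r} does not match header label "
                    f"{labels[i]!r} in {path}"
                )
            toks = toks[1:]
        if len(toks) != n:
            raise FormatError(
                f"non-square grid in {path}: row {i + 1} has {len(toks)} "
                f"values, expected {n}"
            )
        for j, tok in enumerate(toks):
            values[i, j] = _parse_float(tok, f"at row {labels[i]} col {labels[j]}")
    return LabeledMatrix(labels=labels, values=values, kind=kind)


def write_labeled_matrix(m: LabeledMatrix, path: str | os.PathLike) -> None:
    """Write TSV (header + row labels); inverse of :func:`read_labeled_matrix`."""
    m.validate()
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("label\t" + "\t".join(m.labels) + "\n")
        for i, lab in enumerate(m.labels):
            row = "\t".join(_fmt(v) for v in m.values[i])
            fh.write(f"{lab}\t{row}\n")


# ---------------------------------------------------------------------------
# Voxel-level streamline counts
# ---------------------------------------------------------------------------


@dataclass
class VoxelCountTable:
    """Streamline counts per voxel of the target ROI for each ordered pair.

    ``total_leaving[i]`` is the number of streamlines seeded in ROI *i*
    regardless of where (or whether) they terminate, so it is not required to
    equal the sum of the pair totals from *i*.
    """

    counts: dict[tuple[str, str], np.ndarray]
    total_leaving: dict[str, int]

    def __post_init__(self) -> None:
        for pair, vec in self.counts.items():
            vec = np.asarray(vec)
            if vec.ndim != 1 or vec.size == 0:
                raise ValidationError(f"empty voxel vector for pair {pair}")
            if (vec < 0).any() or not np.all(vec == np.floor(vec)):
                raise ValidationError(
                    f"voxel counts for pair {pair} must be non-negative integers"
                )
            self.counts[pair] = vec.astype(np.int64)
        for roi, tot in self.total_leaving.items():
            if tot < 0:
                raise ValidationError(f"total_leaving[{roi}] is negative")

    def pair_total(self, i: str, j: str) -> int:
        return int(self.counts[(i, j)].sum())

    def sources(self) -> list[str]:
        return sorted({i for i, _ in self.counts})

    def pair_totals_matrix(self, labels: Sequence[str]) -> LabeledMatrix:
        """Directed pair-total matrix (row = source ROI), zero diagonal."""
        n = len(labels)
        idx = {lab: k for k, lab in enumerate(labels)}
        vals = np.zeros((n, n))
        for (i, j), vec in self.counts.items():
            vals[idx[i], idx[j]] += vec.sum()
        np.fill_diagonal(vals, 0)
        return LabeledMatrix(labels=list(labels), values=vals, kind="tract_count")


def write_voxel_counts(
    table: VoxelCountTable, counts_path: str | os.PathLike, totals_path: str | os.PathLike
) -> None:
    with open(counts_path, "w", encoding="utf-8") as fh:
        fh.write("source_roi\ttarget_roi\tvoxel_index\tcount\n")
        for (i, j) in sorted(table.counts):
            for v, c in enumerate(table.counts[(i, j)]):
                fh.write(f"{i}\t{j}\t{v}\t{int(c)}\n")
    with open(totals_path, "w", encoding="utf-8") as fh:
        fh.write("roi\ttotal_leaving\n")
        for roi in sorted(table.total_leaving):
            fh.write(f"{roi}\t{int(table.total_leaving[roi])}\n")


def read_voxel_counts(
    counts_path: str | os.PathLike, totals_path: str | os.PathLike
) -> VoxelCountTable:
    cdf = pd.read_csv(counts_path, sep="\t", dtype={"source_roi": str, "target_roi": str})
    for col in ("source_roi", "target_roi", "voxel_index", "count"):
        if col not in cdf.columns:
            raise FormatError(f"voxel count table missing column {col!r}")
    counts: dict[tuple[str, str], np.ndarray] = {}
    for (i, j), grp in cdf.groupby(["source_roi", "target_roi"], sort=False):
        grp = grp.sort_values("voxel_index")
        vi = grp["voxel_index"].to_numpy()
        if not np.array_equal(vi, np.arange(len(vi))):
            raise FormatError(f"voxel indices for pair ({i}, {j}) are not 0..n-1")
        counts[(str(i), str(j))] = grp["count"].to_numpy()
    tdf = pd.read_csv(totals_path, sep="\t", dtype={"roi": str})
    for col in ("roi", "total_leaving"):
        if col not in tdf.columns:
            raise FormatError(f"totals table missing column {col!r}")
    totals = {str(r.roi): int(r.total_leaving) for r in tdf.itertuples()}
    return VoxelCountTable(counts=counts, total_leaving=totals)


# ---------------------------------------------------------------------------
# Subjects, adversity scoring, QC
# ---------------------------------------------------------------------------


@dataclass
class AdversityInputs:
    """Questionnaire scores and income flag feeding the composite score."""

    epds: int | None = None
    stai: int | None = None
    ham_a: int | None = None
    madrs: int | None = None
    low_income: bool = False

    def __post_init__(self) -> None:
        for name in ("epds", "stai", "ham_a", "madrs"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValidationError(f"{name} score must be non-negative, got {v}")


def adversity_group(
    a: AdversityInputs, *, strict: bool = False
) -> tuple[int, str]:
    """Composite adversity score and group label.

    Mental-health flag: EPDS > 11, or (STAI > 29 and HAM-A > 17), or
    MADRS > 6. One point for mental health and/or low income; any point
    puts the subject in the adversity group. Missing scores cannot trigger
    a flag unless ``strict``, in which case they raise.
    """
    if strict:
        missing = [
            n for n in ("epds", "stai", "ham_a", "madrs") if getattr(a, n) is None
        ]
        if missing:
            raise ValidationError(f"missing questionnaire scores: {missing}")

    def gt(value: int | None, threshold: int) -> bool:
        return value is not None and value > threshold

    mental = gt(a.epds, 11) or (gt(a.stai, 29) and gt(a.ham_a, 17)) or gt(a.madrs, 6)
    score = 1 if (mental or a.low_income) else 0
    return score, ("adversity" if score >= 1 else "control")


@dataclass
class SubjectConnectome:
    """One subject's multimodal inputs on a shared ROI label order."""

    fc: LabeledMatrix
    counts: VoxelCountTable
    pair_totals: LabeledMatrix
    distances: LabeledMatrix

    def __post_init__(self) -> None:
        if self.fc.kind != "fc":
            raise ValidationError("fc component must have kind='fc'")
        if self.pair_totals.kind != "tract_count":
            raise ValidationError("pair_totals must have kind='tract_count'")
        if self.distances.kind != "distance":
            raise ValidationError("distances must have kind='distance'")
        labels = self.fc.labels
        for other, nm in ((self.pair_totals, "pair_totals"), (self.distances, "distances")):
            if other.labels != labels:
                raise ValidationError(
                    f"label mismatch between fc and {nm}: "
                    f"{sorted(set(labels) ^ set(other.labels))}"
                )
        known = set(labels)
        for (i, j) in self.counts.counts:
            if i not in known or j not in known:
                raise ValidationError(
                    f"voxel counts reference unknown ROI in pair ({i}, {j})"
                )

    @property
    def labels(self) -> list[str]:
        return self.fc.labels


@dataclass
class SubjectRecord:
    """Manifest row: id, motion summary, adversity inputs, connectome."""

    subject_id: str
    mean_relative_displacement: float | None
    adversity: AdversityInputs | None = None
    group: str | None = None
    _connectome: SubjectConnectome | None = field(default=None, repr=False)
    _loader: Callable[[], SubjectConnectome] | None = field(default=None, repr=False)

    @property
    def connectome(self) -> SubjectConnectome:
        if self._connectome is None:
            if self._loader is None:
                raise ValidationError(
                    f"subject {self.subject_id} has no connectome attached"
                )
            self._connectome = self._loader()
        return self._connectome

    def resolve_group(self) -> str:
        """Explicit group label if present, else computed from adversity inputs."""
        if self.group is not None:
            return self.group
        if self.adversity is None:
            raise ValidationError(
                f"subject {self.subject_id}: no group label and no adversity inputs"
            )
        return adversity_group(self.adversity)[1]


def qc_filter(
    cohort: Sequence[SubjectRecord], threshold_mm: float = QC_DISPLACEMENT_MM
) -> tuple[list[SubjectRecord], list[SubjectRecord]]:
    """Split a cohort on head motion: exclude strictly above ``threshold_mm``."""
    if threshold_mm <= 0:
        raise ValidationError("threshold_mm must be positive")
    kept, excluded = [], []
    for s in cohort:
        d = s.mean_relative_displacement
        if d is None or (isinstance(d, float) and math.isnan(d)):
            raise ValidationError(
                f"subject {s.subject_id}: missing mean_relative_displacement"
            )
        (excluded if d > threshold_mm else kept).append(s)
    return kept, excluded


# ---------------------------------------------------------------------------
# Manifest
# ---------------------------------------------------------------------------

_MANIFEST_REQUIRED = ("subject_id", "mean_relative_displacement")
_SCORE_COLS = ("epds", "stai", "ham_a", "madrs")


def _opt_int(row: Mapping, col: str) -> int | None:
    if col not in row or pd.isna(row[col]):
        return None
    return int(row[col])


def _opt_bool(row: Mapping, col: str) -> bool:
    if col not in row or pd.isna(row[col]):
        return False
    v = row[col]
    if isinstance(v, str):
        return v.strip().lower() in ("1", "true", "yes")
    return bool(v)


def read_manifest(path: str | os.PathLike) -> list[SubjectRecord]:
    """Read a cohort manifest (TSV or CSV); connectomes attach lazily.

    File-reference columns (``fc_path``, ``counts_path``, ``totals_path``,
    ``grid_path``) are resolved relative to the manifest's directory.
    """
    sep = "," if str(path).endswith(".csv") else "\t"
    try:
        df = pd.read_csv(path, sep=sep, dtype={"subject_id": str})
    except pd.errors.EmptyDataError:
        raise ManifestError("no subjects: manifest is empty") from None
    if df.empty:
        raise ManifestError("no subjects: manifest has no rows")
    for col in _MANIFEST_REQUIRED:
        if col not in df.columns:
            raise ManifestError(f"manifest missing required column {col!r}")
    if "group" not in df.columns and not any(c in df.columns for c in _SCORE_COLS):
        raise ManifestError(
            "manifest needs either a 'group' column or adversity score columns"
        )
    ids = df["subject_id"].tolist()
    dupes = sorted({i for i in ids if ids.count(i) > 1})
    if dupes:
        raise ManifestError(f"duplicate subject_id: {dupes}")

    base = os.path.dirname(os.path.abspath(path))
    records: list[SubjectRecord] = []
    for _, row in df.iterrows():
        row = row.to_dict()
        adversity = None
        if any(c in row and not pd.isna(row.get(c)) for c in _SCORE_COLS) or (
            "low_income" in row and not pd.isna(row.get("low_income"))
        ):
            adversity = AdversityInputs(
                epds=_opt_int(row, "epds"),
                stai=_opt_int(row, "stai"),
                ham_a=_opt_int(row, "ham_a"),
                madrs=_opt_int(row, "madrs"),
                low_income=_opt_bool(row, "low_income"),
            )
        group = None
        if "group" in row and not pd.isna(row.get("group")):
            group = str(row["group"])
            if group not in ("adversity", "control"):
                raise ManifestError(
                    f"subject {row['subject_id']}: group must be "
                    f"'adversity' or 'control', got {group!r}"
                )
        disp = row["mean_relative_displacement"]
        disp = None if pd.isna(disp) else float(disp)

        loader = None
        if all(
            c in row and not pd.isna(row.get(c))
            for c in ("fc_path", "counts_path", "totals_path", "grid_path")
        ):
            paths = {
                c: os.path.join(base, str(row[c]))
                for c in ("fc_path", "counts_path", "totals_path", "grid_path")
            }

            def loader(paths=paths) -> SubjectConnectome:
                fc = read_labeled_matrix(paths["fc_path"], kind="fc")
                counts = read_voxel_counts(paths["counts_path"], paths["totals_path"])
                dist = read_labeled_matrix(paths["grid_path"], kind="distance")
                return SubjectConnectome(
                    fc=fc,
                    counts=counts,
                    pair_totals=counts.pair_totals_matrix(fc.labels),
                    distances=dist,
                )

        records.append(
            SubjectRecord(
                subject_id=str(row["subject_id"]),
                mean_relative_displacement=disp,
                adversity=adversity,
                group=group,
                _loader=loader,
            )
        )
    return records
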