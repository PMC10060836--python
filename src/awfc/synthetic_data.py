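"""Synthetic multimodal connectome cohorts.

Generates, per subject, block-correlated ROI time series (→ sample Pearson
FC) and distance-dependent zero-inflated Poisson streamline counts, with
optional planted group effects, so the whole pipeline is testable without
any imaging data.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np

from .cohort_io import (
    ROI,
    ROIAtlas,
    AdversityInputs,
    LabeledMatrix,
    SubjectConnectome,
    SubjectRecord,
    VoxelCountTable,
    write_labeled_matrix,
    write_voxel_counts,
)
from .errors import ComputationError, ValidationError

# ---------------------------------------------------------------------------
# Packaged default atlas: 19 ROIs in 5 resting-state networks
# ---------------------------------------------------------------------------

_ATLAS_ROWS: list[tuple[int, str, str, str, tuple[int, int, int], int]] = [
    (1, "DMN", "Medial frontal gyrus", "MFG", (2, 62, 8), 7),
    (2, "DMN", "Posterior cingulate cortex", "PCC", (-2, -62, 24), 5),
    (3, "DMN", "Right angular gyrus", "R-AG", (46, -58, 28), 6),
    (4, "DMN", "Left angular gyrus", "L-AG", (-46, -58, 28), 5),
    (5, "FPN", "Left inferior frontal gyrus", "L-IFG", (-38, 38, 12), 12),
    (6, "FPN", "Lingual gyrus/cerebellum", "LG/CER", (-6, -74, -12), 12),
    (7, "FPN", "Right superior frontal gyrus", "R-SFG", (10, 38, 56), 10),
    (8, "LIM", "Right posterior orbitofrontal gyrus", "R-pOFG", (18, 38, -24), 12),
    (9, "LIM", "Left posterior orbitofrontal gyrus", "L-pOFG", (-42, 30, -20), 12),
    (10, "LIM", "Right superior temporal gyrus", "R-STG", (46, 14, -44), 11),
    (11, "LIM", "Left superior temporal gyrus", "L-STG", (-42, 2, -52), 12),
    (12, "LIM", "Dorsolateral prefrontal cortex", "DLPFC", (-2, 46, 32), 12),
    (13, "VAN", "Left lingual gyrus/Cuneus-Lateral occipital cortex", "L-LG/CU", (-14, -98, -16), 20),
    (14, "VAN", "Right orbitofrontal gyrus", "R-aOFG", (14, 70, -16), 5),
    (15, "VAN", "Right cerebellum", "R-CER", (10, -66, 44), 20),
    (16, "DAN", "Right anterior orbitofrontal gyrus", "R-aOFG", (14, 58, -20), 9),
    (17, "DAN", "Right posterior orbitofrontal gyrus", "R-pOFG", (22, 30, -16), 14),
    (18, "DAN", "Right middle frontal gyrus", "R-MFG", (38, 42, -16), 14),
    (19, "DAN", "L-Inferior temporal gyrus", "L-ITG", (-50, -54, -16), 14),
]


def default_atlas() -> ROIAtlas:
    """The packaged 19-ROI / 5-network atlas.

    Abbreviations shared by two regions (R-aOFG, R-pOFG each appear in two
    networks) are disambiguated in the matrix labels with an ``_<roi_id>``
    suffix.
    """
    return ROIAtlas(
        [
            ROI(roi_id=i, network=net, name=name, abbrev=ab, mni_xyz=xyz, volume_voxels=vol)
            for i, net, name, ab, xyz, vol in _ATLAS_ROWS
        ]
    )


def euclidean_distances(atlas: ROIAtlas) -> LabeledMatrix:
    """Pairwise Euclidean distances (mm) between peak coordinates."""
    xyz = atlas.coordinates()
    diff = xyz[:, None, :] - xyz[None, :, :]
    d = np.sqrt((diff**2).sum(axis=2))
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return LabeledMatrix(labels=atlas.labels, values=d, kind="distance")


# ---------------------------------------------------------------------------
# Simulation configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Effect:
    """A planted group difference on one ROI pair.

    ``metric='fc'`` shifts the generating correlation of the pair;
    ``metric='sc'`` shifts the pair's log mean streamline count (alpha0).
    The shift applies to subjects of ``group`` only.
    """

    pair: tuple[str, str]
    metric: str
    shift: float
    group: str = "adversity"

    def __post_init__(self) -> None:
        if self.metric not in ("fc", "sc"):
            raise ValidationError("effect metric must be 'fc' or 'sc'")
        if self.group not in ("adversity", "control"):
            raise ValidationError("effect group must be 'adversity' or 'control'")


@dataclass
class SimConfig:
    """Generator parameters; defaults mirror the study's cohort layout."""

    atlas: ROIAtlas = field(default_factory=default_atlas)
    n_control: int = 9
    n_adversity: int = 8
    t_volumes: int = 105
    rho_within: float = 0.6
    rho_between: float = 0.1
    zip_alpha0: float = 2.0
    zip_alpha1: float = -0.02
    zip_omega: float = 0.25
    lost_rate: float = 50.0
    voxel_concentration: float | None = None
    effects: tuple[Effect, ...] = ()
    qc_violators: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_control <= 0 or self.n_adversity <= 0:
            raise ValidationError("group sizes must be positive")
        if self.t_volumes <= 1:
            raise ValidationError("t_volumes must exceed 1")
        if not (0 <= self.rho_between <= self.rho_within < 1):
            raise ValidationError(
                "need 0 <= rho_between <= rho_within < 1, got "
                f"{self.rho_between}, {self.rho_within}"
            )
        if not 0 <= self.zip_omega <= 1:
            raise ValidationError("zip_omega must be in [0, 1]")
        labels = set(self.atlas.labels)
        for e in self.effects:
            if e.pair[0] not in labels or e.pair[1] not in labels:
                raise ValidationError(f"effect pair {e.pair} not in atlas labels")


@dataclass
class SyntheticCohort:
    subjects: list[SubjectRecord]
    atlas: ROIAtlas
    config: SimConfig
    ground_truth: dict


# ---------------------------------------------------------------------------
# FC simulation
# ---------------------------------------------------------------------------


def _target_covariance(config: SimConfig, group: str) -> np.ndarray:
    atlas = config.atlas
    n = len(atlas)
    nets = [r.network for r in atlas.rois]
    c = np.full((n, n), config.rho_between)
    for i in range(n):
        for j in range(n):
            if nets[i] == nets[j]:
                c[i, j] = config.rho_within
    np.fill_diagonal(c, 1.0)
    idx = {lab: k for k, lab in enumerate(atlas.labels)}
    for e in config.effects:
        if e.metric != "fc" or e.group != group:
            continue
        i, j = idx[e.pair[0]], idx[e.pair[1]]
        r = c[i, j] + e.shift
        if not -1 < r < 1:
            raise ValidationError(
                f"effect on {e.pair} pushes correlation to {r}, outside (-1, 1)"
            )
        c[i, j] = c[j, i] = r
    return c


def _nearest_psd(c: np.ndarray, floor: float = 1e-6, max_dev: float = 0.1) -> np.ndarray:
    """Eigenvalue-floored PSD repair with unit-diagonal renormalization."""
    w, v = np.linalg.eigh((c + c.T) / 2.0)
    if w.min() >= floor:
        return c
    w = np.maximum(w, floor)
    r = (v * w) @ v.T
    d = np.sqrt(np.diag(r))
    r = r / np.outer(d, d)
    if np.abs(r - c).max() > max_dev:
        raise ComputationError("covariance not repairable to PSD within tolerance")
    return (r + r.T) / 2.0


def simulate_fc(
    config: SimConfig, group: str, rng: np.random.Generator
) -> LabeledMatrix:
    """Sample Pearson FC from ``t_volumes`` draws of a block-covariance MVN."""
    cov = _nearest_psd(_target_covariance(config, group))
    chol = np.linalg.cholesky(cov + 1e-12 * np.eye(cov.shape[0]))
    x = rng.standard_normal((config.t_volumes, cov.shape[0])) @ chol.T
    r = np.corrcoef(x, rowvar=False)
    r = (r + r.T) / 2.0
    r = np.clip(r, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return LabeledMatrix(labels=config.atlas.labels, values=r, kind="fc")


# ---------------------------------------------------------------------------
# Tractography simulation
# ---------------------------------------------------------------------------


def simulate_tractography(
    config: SimConfig,
    distances: LabeledMatrix,
    rng: np.random.Generator,
    group: str = "control",
) -> tuple[VoxelCountTable, LabeledMatrix]:
    """ZIP pair totals split over target-ROI voxels; returns table + totals.

    Per ordered pair (i, j): with probability ``zip_omega`` the total is 0,
    otherwise Poisson(exp(alpha0 + alpha1·g_ij)); the total is spread over
    ROI j's voxels by a multinomial (uniform weights unless
    ``voxel_concentration`` sets a Dirichlet skew). ``total_leaving[i]``
    adds a Poisson(``lost_rate``) count of streamlines reaching no target.
    """
    atlas = config.atlas
    labels = atlas.labels
    idx = {lab: k for k, lab in enumerate(labels)}
    vols = {r.label: r.volume_voxels for r in atlas.rois}
    a0 = np.full((len(labels), len(labels)), config.zip_alpha0)
    for e in config.effects:
        if e.metric != "sc" or e.group != group:
            continue
        i, j = idx[e.pair[0]], idx[e.pair[1]]
        a0[i, j] += e.shift
        a0[j, i] += e.shift

    counts: dict[tuple[str, str], np.ndarray] = {}
    leaving: dict[str, int] = {}
    for i, src in enumerate(labels):
        row_sum = 0
        for j, tgt in enumerate(labels):
            if i == j:
                continue
            nvox = vols[tgt]
            if rng.random() < config.zip_omega:
                total = 0
            else:
                mu = np.exp(a0[i, j] + config.zip_alpha1 * distances.values[i, j])
                total = int(rng.poisson(mu))
            if total == 0:
                vec = np.zeros(nvox, dtype=np.int64)
            else:
                if config.voxel_concentration is None:
                    w = np.full(nvox, 1.0 / nvox)
                else:
                    w = rng.dirichlet(np.full(nvox, config.voxel_concentration))
                vec = rng.multinomial(total, w)
            counts[(src, tgt)] = vec
            row_sum += total
        leaving[src] = row_sum + int(rng.poisson(config.lost_rate))
    table = VoxelCountTable(counts=counts, total_leaving=leaving)
    return table, table.pair_totals_matrix(labels)


# ---------------------------------------------------------------------------
# Cohort generation and persistence
# ---------------------------------------------------------------------------


def generate_cohort(config: SimConfig) -> SyntheticCohort:
    """Full synthetic cohort, reproducible from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    atlas = config.atlas
    distances = euclidean_distances(atlas)
    plan = [("control", f"C{k + 1:02d}") for k in range(config.n_control)]
    plan += [("adversity", f"A{k + 1:02d}") for k in range(config.n_adversity)]
    if config.qc_violators > len(plan):
        raise ValidationError("qc_violators exceeds cohort size")

    subjects: list[SubjectRecord] = []
    for k, (group, sid) in enumerate(plan):
        violator = k >= len(plan) - config.qc_violators
        disp = rng.uniform(0.6, 0.9) if violator else rng.uniform(0.05, 0.45)
        fc = simulate_fc(config, group, rng)
        table, totals = simulate_tractography(config, distances, rng, group)
        if group == "adversity":
            adv = AdversityInputs(epds=int(rng.integers(12, 20)), low_income=False)
        else:
            adv = AdversityInputs(epds=int(rng.integers(0, 6)), low_income=False)
        subjects.append(
            SubjectRecord(
                subject_id=sid,
                mean_relative_displacement=round(float(disp), 4),
                adversity=adv,
                group=group,
                _connectome=SubjectConnectome(
                    fc=fc, counts=table, pair_totals=totals, distances=distances
                ),
            )
        )

    truth = {
        "seed": config.seed,
        "n_control": config.n_control,
        "n_adversity": config.n_adversity,
        "t_volumes": config.t_volumes,
        "rho_within": config.rho_within,
        "rho_between": config.rho_between,
        "zip_alpha0": config.zip_alpha0,
        "zip_alpha1": config.zip_alpha1,
        "zip_omega": config.zip_omega,
        "effects": [asdict(e) for e in config.effects],
    }
    return SyntheticCohort(subjects=subjects, atlas=atlas, config=config, ground_truth=truth)


def write_cohort(cohort: SyntheticCohort, outdir: str | os.PathLike) -> str:
    """Write per-subject files plus manifest and ground-truth ledger.

    Returns the manifest path. All files are plain text in the cohort_io
    formats, so a written cohort round-trips through :func:`read_manifest`.
    """
    outdir = str(outdir)
    os.makedirs(outdir, exist_ok=True)
    rows = []
    for s in cohort.subjects:
        con = s.connectome
        paths = {
            "fc_path": f"{s.subject_id}_fc.tsv",
            "counts_path": f"{s.subject_id}_counts.tsv",
            "totals_path": f"{s.subject_id}_totals.tsv",
            "grid_path": f"{s.subject_id}_grid.tsv",
        }
        write_labeled_matrix(con.fc, os.path.join(outdir, paths["fc_path"]))
        write_voxel_counts(
            con.counts,
            os.path.join(outdir, paths["counts_path"]),
            os.path.join(outdir, paths["totals_path"]),
        )
        write_labeled_matrix(con.distances, os.path.join(outdir, paths["grid_path"]))
        adv = s.adversity or AdversityInputs()
        rows.append(
            {
                "subject_id": s.subject_id,
                "mean_relative_displacement": s.mean_relative_displacement,
                "epds": "" if adv.epds is None else adv.epds,
                "stai": "" if adv.stai is None else adv.stai,
                "ham_a": "" if adv.ham_a is None else adv.ham_a,
                "madrs": "" if adv.madrs is None else adv.madrs,
                "low_income": int(adv.low_income),
                "group": s.group or "",
                **paths,
            }
        )
    manifest = os.path.join(outdir, "manifest.tsv")
    cols = list(rows[0].keys())
    with open(manifest, "w", encoding="utf-8") as fh:
        fh.write("\t".join(cols) + "\n")
        for r in rows:
            fh.write("\t".join(str(r[c]) for c in cols) + "\n")
    with open(os.path.join(outdir, "ground_truth.json"), "w", encoding="utf-8") as fh:
        json.dump(cohort.ground_truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
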