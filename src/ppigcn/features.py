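"""Per-residue feature vectors: HQI8 indices, SASA, torsions, one-hot.

Each residue is described by 33 numbers in a fixed column layout:

====== =======================================================
cols   content
====== =======================================================
0-7    HQI8 physico-chemical AAindex values (table column order)
8      accessible surface area (ASA), A^2
9      relative ASA (ASA / per-type maximum), unitless
10     contact number (count of spatial neighbours)
11     phi backbone torsion, degrees (0.0 where undefined)
12     psi backbone torsion, degrees (0.0 where undefined)
13-32  one-hot amino-acid type, alphabetical by 3-letter code
====== =======================================================

ASA is computed with an internal Shrake-Rupley implementation (golden-spiral
sphere sampling over heavy atoms, probe radius 1.4 A, 960 points by default)
so that an isolated atom's area is exactly ``4*pi*(r_vdw + probe)^2`` and the
whole computation is deterministic. Torsions follow the IUPAC convention:
phi about N-CA using the preceding carbonyl carbon, psi about CA-C using the
following amide nitrogen, in (-180, 180] degrees.

Standardization (z-scoring of the 13 structural/physico-chemical columns
with statistics from training nodes only) lives in
:class:`FeatureStandardizer`, a scikit-learn style transformer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree
from sklearn.base import BaseEstimator, TransformerMixin

from .graphs import spatial_pairs
from .structures import STANDARD_AA, UNKNOWN_AA, ProteinStructure

logger = logging.getLogger(__name__)

N_FEATURES = 33
HQI8_COLUMNS = slice(0, 8)
ASA_COLUMN = 8
RASA_COLUMN = 9
CONTACT_COLUMN = 10
PHI_COLUMN = 11
PSI_COLUMN = 12
ONE_HOT_COLUMNS = slice(13, 33)
#: Columns that are z-scored; the trailing one-hot block is left untouched.
SCALED_COLUMNS = slice(0, 13)

DEFAULT_PROBE_RADIUS = 1.4
DEFAULT_SPHERE_POINTS = 960


class FeatureTableError(ValueError):
    """Raised when a packaged data table is malformed."""


def _read_table(name: str) -> list[list[str]]:
    text = resources.files("ppigcn.data").joinpath(name).read_text()
    rows = []
    for line in text.splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            rows.append(line.split("\t"))
    return rows


@dataclass
class AAIndexTable:
    """8 named AAindex entries x 20 standard residues."""

    index_names: list[str]
    values: dict[str, np.ndarray]  # aa -> 8-vector, index order

    @classmethod
    def load(cls) -> "AAIndexTable":
        rows = _read_table("aaindex_hqi8.tsv")
        header, body = rows[0], rows[1:]
        names = header[1:]
        values = {r[0]: np.array([float(v) for v in r[1:]]) for r in body}
        table = cls(index_names=names, values=values)
        table.validate()
        return table

    def validate(self) -> None:
        if len(self.index_names) != 8:
            raise FeatureTableError(f"expected 8 indices, got {len(self.index_names)}")
        if set(self.values) != set(STANDARD_AA):
            raise FeatureTableError("AAindex table must cover exactly the 20 standard residues")
        for aa, vec in self.values.items():
            if vec.shape != (8,) or not np.all(np.isfinite(vec)):
                raise FeatureTableError(f"bad AAindex row for {aa}")

    @property
    def mean_vector(self) -> np.ndarray:
        return np.mean([self.values[aa] for aa in STANDARD_AA], axis=0)


@dataclass
class MaxASATable:
    """Per-residue-type maximal accessible surface area, A^2."""

    values: dict[str, float]

    @classmethod
    def load(cls) -> "MaxASATable":
        rows = _read_table("max_asa.tsv")
        values = {r[0]: float(r[1]) for r in rows[1:]}
        table = cls(values=values)
        table.validate()
        return table

    def validate(self) -> None:
        if set(self.values) != set(STANDARD_AA):
            raise FeatureTableError("MaxASA table must cover exactly the 20 standard residues")
        if any(v <= 0 for v in self.values.values()):
            raise FeatureTableError("MaxASA values must be strictly positive")

    @property
    def mean_value(self) -> float:
        return float(np.mean([self.values[aa] for aa in STANDARD_AA]))


def load_vdw_radii() -> dict[str, float]:
    rows = _read_table("vdw_radii.tsv")
    return {r[0]: float(r[1]) for r in rows[1:]}


DEFAULT_VDW_RADIUS = 1.70  # carbon; fallback for unlisted elements


def hqi8(aa: str, table: AAIndexTable) -> np.ndarray:
    """The 8 HQI8 index values for one residue type (UNK -> columnwise mean)."""
    if aa == UNKNOWN_AA:
        return table.mean_vector.copy()
    try:
        return table.values[aa].copy()
    except KeyError as exc:
        raise FeatureTableError(f"unknown amino acid {aa!r}") from exc


def golden_spiral_points(n: int) -> np.ndarray:
    """n approximately uniform unit-sphere points (Fibonacci lattice)."""
    k = np.arange(n, dtype=float)
    z = 1.0 - 2.0 * (k + 0.5) / n
    theta = np.pi * (1.0 + np.sqrt(5.0)) * k
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def _canonical_frame(coords: np.ndarray) -> np.ndarray:
    """Rotate/translate coordinates into a canonical molecular frame.

    The sphere sampling below uses a fixed point lattice, so the raw
    algorithm's discretization error depends on molecular orientation.
    Expressing the atoms in their principal-axes frame first (sign of each
    axis fixed by an order-weighted projection, which is preserved under
    rigid motion of the molecule) makes the computed areas invariant under
    rotation and translation rather than merely approximately so.
    """
    centered = coords - coords.mean(axis=0)
    if coords.shape[0] < 2:
        return centered
    cov = centered.T @ centered
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvecs = eigvecs[:, order]
    weights = np.arange(1, coords.shape[0] + 1, dtype=float)
    for k in range(3):
        proj = centered @ eigvecs[:, k]
        score = float(np.sum(weights * proj))
        if abs(score) < 1e-9:
            score = float(np.sum(proj**3))
        if score < 0:
            eigvecs[:, k] = -eigvecs[:, k]
    if np.linalg.det(eigvecs) < 0:
        eigvecs[:, 2] = -eigvecs[:, 2]
    return centered @ eigvecs


def shrake_rupley_asa(
    structure: ProteinStructure,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_sphere_points: int = DEFAULT_SPHERE_POINTS,
) -> np.ndarray:
    """Per-residue solvent-accessible surface area over heavy atoms, A^2.

    Each heavy atom is expanded by the probe radius and sampled with a
    golden-spiral point set; a point is exposed iff it lies outside every
    other heavy atom's expanded sphere. The atom's exposed area is the
    exposed fraction times the full sphere area, and a residue's ASA sums
    its atoms' areas. Hydrogens are excluded. Deterministic for a fixed
    ``n_sphere_points``.
    """
    vdw = load_vdw_radii()
    coords, radii, owner = [], [], []
    warned: set[str] = set()
    for ri, res in enumerate(structure.residues):
        for atom in res.atoms:
            if not atom.is_heavy:
                continue
            if atom.element not in vdw and atom.element not in warned:
                logger.warning(
                    "unknown element %r: using default vdW radius %.2f A",
                    atom.element, DEFAULT_VDW_RADIUS,
                )
                warned.add(atom.element)
            coords.append(atom.coord)
            radii.append(vdw.get(atom.element, DEFAULT_VDW_RADIUS) + probe_radius)
            owner.append(ri)

    asa = np.zeros(structure.n)
    if not coords:
        return asa
    coords_arr = _canonical_frame(np.asarray(coords))
    radii_arr = np.asarray(radii)
    sphere = golden_spiral_points(n_sphere_points)
    tree = cKDTree(coords_arr)
    max_radius = radii_arr.max()

    for ai in range(len(coords_arr)):
        r = radii_arr[ai]
        points = coords_arr[ai] + r * sphere
        neighbours = [
            j for j in tree.query_ball_point(coords_arr[ai], r + max_radius)
            if j != ai
        ]
        exposed = np.ones(n_sphere_points, dtype=bool)
        for j in neighbours:
            d2 = np.einsum(
                "ij,ij->i", points - coords_arr[j], points - coords_arr[j]
            )
            exposed &= d2 >= radii_arr[j] ** 2
        area = 4.0 * np.pi * r * r * exposed.sum() / n_sphere_points
        asa[owner[ai]] += area
    return asa


def rasa(asa: np.ndarray, structure: ProteinStructure, table: MaxASATable) -> np.ndarray:
    """Relative solvent exposure: ASA over the residue type's maximum.

    Values are not clipped and may slightly exceed 1 for very exposed
    residues; UNK residues are normalised by the mean maximum.
    """
    denom = np.array([
        table.values.get(res.aa, table.mean_value) for res in structure.residues
    ])
    return np.asarray(asa, dtype=float) / denom


def contact_number(
    structure: ProteinStructure,
    threshold: float,
    include_sequential: bool = False,
) -> np.ndarray:
    """Count of each residue's spatial neighbours under the threshold.

    Sequential neighbours are excluded by default, mirroring the spatial /
    sequential dichotomy of the graph module; pass
    ``include_sequential=True`` for the inclusive variant.
    """
    counts = np.zeros(structure.n, dtype=int)
    for i, j, _ in spatial_pairs(structure, threshold):
        counts[i] += 1
        counts[j] += 1
    if include_sequential:
        from .graphs import sequential_pairs

        for i, j in sequential_pairs(structure):
            if float(np.linalg.norm(structure.residues[i].ca - structure.residues[j].ca)) < threshold:
                counts[i] += 1
                counts[j] += 1
    return counts


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in degrees, IUPAC convention, (-180, 180]."""
    b0 = p0 - p1
    b1 = (p2 - p1) / np.linalg.norm(p2 - p1)
    b2 = p3 - p2
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    angle = np.degrees(np.arctan2(np.dot(np.cross(b1, v), w), np.dot(v, w)))
    if angle <= -180.0:
        angle += 360.0
    return float(angle)


def torsion_angles(
    structure: ProteinStructure,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Backbone (phi, psi) per residue in degrees, plus a definedness mask.

    phi_i uses C of residue i-1 and (N, CA, C) of residue i; psi_i uses
    (N, CA, C) of residue i and N of residue i+1. Angles are undefined at
    chain termini, across chain breaks, or where backbone atoms are missing;
    undefined angles are encoded as 0.0 with the mask recording which of the
    two angles were actually computed.
    """
    from .graphs import sequential_pairs

    n = structure.n
    phi = np.zeros(n)
    psi = np.zeros(n)
    defined = np.zeros((n, 2), dtype=bool)
    seq = sequential_pairs(structure)
    backbones = [res.backbone for res in structure.residues]
    for i in range(n):
        if backbones[i] is None:
            logger.debug("%s: residue %d missing backbone atoms", structure.id, i)
            continue
        n_i, ca_i, c_i = backbones[i]
        if (i - 1, i) in seq and backbones[i - 1] is not None:
            phi[i] = dihedral(backbones[i - 1][2], n_i, ca_i, c_i)
            defined[i, 0] = True
        if (i, i + 1) in seq and backbones[i + 1] is not None:
            psi[i] = dihedral(n_i, ca_i, c_i, backbones[i + 1][0])
            defined[i, 1] = True
    return phi, psi, defined


def one_hot(aa: str) -> np.ndarray:
    """20-vector with a 1 at the alphabetical position of the residue type.

    UNK maps to the all-zero vector.
    """
    vec = np.zeros(len(STANDARD_AA))
    if aa != UNKNOWN_AA:
        vec[STANDARD_AA.index(aa)] = 1.0
    return vec


@dataclass
class FeatureMatrix:
    """n x 33 per-residue feature table for one protein."""

    protein_id: str
    values: np.ndarray
    column_names: list[str] = field(default_factory=lambda: feature_column_names())

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def to_tsv(self, path: str | Path) -> Path:
        import pandas as pd

        path = Path(path)
        pd.DataFrame(self.values, columns=self.column_names).to_csv(
            path, sep="\t", index=False
        )
        return path


def feature_column_names() -> list[str]:
    table = AAIndexTable.load()
    return (
        list(table.index_names)
        + ["asa", "rasa", "contact_number", "phi", "psi"]
        + [f"aa_{aa}" for aa in STANDARD_AA]
    )


def assemble_features(
    structure: ProteinStructure,
    threshold: float,
    aaindex: AAIndexTable | None = None,
    maxasa: MaxASATable | None = None,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_sphere_points: int = DEFAULT_SPHERE_POINTS,
) -> FeatureMatrix:
    """Compute the full n x 33 feature matrix for one protein."""
    aaindex = aaindex or AAIndexTable.load()
    maxasa = maxasa or MaxASATable.load()
    n = structure.n
    values = np.zeros((n, N_FEATURES))
    asa = shrake_rupley_asa(structure, probe_radius, n_sphere_points)
    rel = rasa(asa, structure, maxasa)
    contacts = contact_number(structure, threshold)
    phi, psi, _ = torsion_angles(structure)
    for i, res in enumerate(structure.residues):
        values[i, HQI8_COLUMNS] = hqi8(res.aa, aaindex)
        values[i, ONE_HOT_COLUMNS] = one_hot(res.aa)
    values[:, ASA_COLUMN] = asa
    values[:, RASA_COLUMN] = rel
    values[:, CONTACT_COLUMN] = contacts
    values[:, PHI_COLUMN] = phi
    values[:, PSI_COLUMN] = psi
    return FeatureMatrix(protein_id=structure.id, values=values)


class FeatureStandardizer(TransformerMixin, BaseEstimator):
    """Z-score the 13 leading feature columns; leave the one-hot block alone.

    Statistics are fitted on training nodes only (pass the stacked feature
    matrix restricted to the train mask to :meth:`fit`) and reapplied
    unchanged to validation and test nodes, so no information leaks across
    the split. Constant columns are centered but not divided.
    """

    def __init__(self, scaled_columns: slice = SCALED_COLUMNS):
        self.scaled_columns = scaled_columns

    def fit(self, X: np.ndarray, y=None) -> "FeatureStandardizer":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 2:
            raise ValueError("FeatureStandardizer requires >= 2 training rows")
        self.n_features_in_ = X.shape[1]
        sub = X[:, self.scaled_columns]
        self.mean_ = sub.mean(axis=0)
        sd = sub.std(axis=0, ddof=0)
        self.scale_ = np.where(sd > 0, sd, 1.0)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("feature width differs from fit-time width")
        out = X.copy()
        out[:, self.scaled_columns] = (X[:, self.scaled_columns] - self.mean_) / self.scale_
        return out


def standardize(
    features: np.ndarray, train_mask: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Functional wrapper: z-score columns 0-12 with train-node statistics.

    Returns the transformed stacked matrix and the fitted (mean, sd) per
    scaled column (sd reported as 0 for constant columns, which are centered
    only).
    """
    train_mask = np.asarray(train_mask, dtype=bool)
    if train_mask.sum() < 2:
        raise ValueError("train_mask must select at least 2 nodes")
    scaler = FeatureStandardizer().fit(features[train_mask])
    sd_raw = np.asarray(features[train_mask][:, SCALED_COLUMNS]).std(axis=0, ddof=0)
    return scaler.transform(features), scaler.mean_.copy(), sd_raw
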