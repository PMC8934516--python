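"""Deterministic synthetic structures, complexes and planted datasets.

Everything downstream — graph builders, features, labeling, training — is
exercised on structures produced here, so no external data is required.
Generated chains carry full backbones (N, CA, C, O) for torsion computation
plus one pseudo side-chain heavy atom (named CB) per residue, enough for
the surface-area and interface-labeling machinery at toy scale; the side
chain is deliberately non-physical (a single atom cannot reproduce real
rotamer packing).

Geometries
----------
``ideal_helix``
    Backbone built from canonical internal coordinates (phi = -57,
    psi = -47, omega = 180 degrees, standard bond lengths/angles), so the
    torsion code must recover the generating angles exactly for interior
    residues.
``extended_chain``
    C-alphas on a straight line at 3.8 A spacing with a planar backbone
    attached; the workhorse geometry for posed complexes.
``self_avoiding_walk``
    Random 3.8 A steps with all non-consecutive C-alpha pairs kept >= 3.5 A.
``globule``
    The same walk with a centripetal bias, producing compact shapes with
    buried residues.

Complexes are posed so the planted interface is known *by construction*:
two extended chains run antiparallel in ``y`` with their side-chain atoms
facing, separated so that exactly the designated residue pairs have a
closest heavy-atom distance in (3.5, 5.0] A and every other cross-chain
pair exceeds 5 A. The pose is verified against the interface labeler and a
failure raises :class:`GenerationError` rather than returning unverified
labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .dataset import (
    LabelVector,
    MaskedDataset,
    assemble,
    label_interfaces,
    random_split,
)
from .features import assemble_features
from .graphs import build_hierarchical
from .structures import STANDARD_AA, Atom, ProteinStructure, Residue

Geometry = Literal["ideal_helix", "extended_chain", "self_avoiding_walk", "globule"]

CA_SPACING = 3.8
MIN_SELF_DISTANCE = 3.5

# canonical backbone internal coordinates (lengths in A, angles in degrees)
_BOND_N_CA = 1.458
_BOND_CA_C = 1.525
_BOND_C_N = 1.329
_BOND_C_O = 1.231
_ANGLE_N_CA_C = 111.2
_ANGLE_CA_C_N = 116.2
_ANGLE_C_N_CA = 121.7
_ANGLE_CA_C_O = 120.5

HELIX_PHI = -57.0
HELIX_PSI = -47.0
OMEGA_TRANS = 180.0

#: Default planted-complex contact distance (closest heavy-atom pair), A.
CONTACT_DISTANCE = 4.3


class GenerationError(RuntimeError):
    """Raised when a generator cannot realise the requested geometry."""


@dataclass
class GeneratorSpec:
    """Recipe for one synthetic chain."""

    n_residues: int
    geometry: Geometry = "extended_chain"
    seed: int = 0
    sequence: Sequence[str] | None = None  # None -> uniform random over 20 types
    chain_id: str = "A"
    protein_id: str = "synthetic"

    def __post_init__(self) -> None:
        if self.n_residues < 1:
            raise GenerationError("n_residues must be >= 1")


@dataclass
class PlantedDatasetSpec:
    """Study conditions for a feature-signal recovery dataset."""

    n_proteins: int = 20
    residues_per_protein: int = 60
    interface_fraction: float = 0.25
    signal_strength: float = 2.0
    signal_columns: tuple[int, ...] = (0, 1, 2, 3)
    threshold: float = 8.0
    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.interface_fraction < 1:
            raise GenerationError("interface_fraction must be in (0, 1)")
        if self.signal_strength < 0:
            raise GenerationError("signal_strength must be >= 0")


def _nerf(a: np.ndarray, b: np.ndarray, c: np.ndarray,
          bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place atom d from internal coordinates relative to a-b-c."""
    angle = np.radians(angle_deg)
    torsion = np.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * np.cos(angle),
        bond * np.sin(angle) * np.cos(torsion),
        bond * np.sin(angle) * np.sin(torsion),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _helix_backbone(n: int) -> list[dict[str, np.ndarray]]:
    """N/CA/C/O coordinates of an ideal alpha helix from internal coordinates."""
    ncac: list[dict[str, np.ndarray]] = []
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([_BOND_N_CA, 0.0, 0.0])
    ang = np.radians(_ANGLE_N_CA_C)
    c0 = ca0 + _BOND_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])
    ncac.append({"N": n0, "CA": ca0, "C": c0})
    for i in range(1, n):
        prev = ncac[i - 1]
        n_i = _nerf(prev["N"], prev["CA"], prev["C"],
                    _BOND_C_N, _ANGLE_CA_C_N, HELIX_PSI)
        ca_i = _nerf(prev["CA"], prev["C"], n_i,
                     _BOND_N_CA, _ANGLE_C_N_CA, OMEGA_TRANS)
        c_i = _nerf(prev["C"], n_i, ca_i,
                    _BOND_CA_C, _ANGLE_N_CA_C, HELIX_PHI)
        ncac.append({"N": n_i, "CA": ca_i, "C": c_i})
    for i, res in enumerate(ncac):
        # carbonyl O anti to the next amide N (trans peptide plane)
        psi = HELIX_PSI if i < n - 1 else 180.0
        res["O"] = _nerf(res["N"], res["CA"], res["C"],
                         _BOND_C_O, _ANGLE_CA_C_O, psi - 180.0)
        res["CB"] = _nerf(res["C"], res["N"], res["CA"], 1.53, 110.5, 122.5)
    return ncac


def _extended_backbone(n: int) -> list[dict[str, np.ndarray]]:
    """Straight-line C-alpha trace with a planar backbone attached."""
    out = []
    for i in range(n):
        ca = np.array([CA_SPACING * i, 0.0, 0.0])
        out.append({
            "N": ca + np.array([-1.2, 0.8, 0.0]),
            "CA": ca,
            "C": ca + np.array([1.2, 0.8, 0.0]),
            "O": ca + np.array([1.45, 2.0, 0.0]),
            "CB": ca + np.array([0.0, -1.5, 0.0]),
        })
    return out


def _walk_trace(n: int, rng: np.random.Generator, centripetal: float = 0.0,
                max_retries: int = 200) -> np.ndarray:
    """Self-avoiding C-alpha trace: 3.8 A steps, pairwise distance >= 3.5 A."""
    for _ in range(max_retries):
        coords = [np.zeros(3)]
        ok = True
        for _step in range(n - 1):
            placed = False
            for _attempt in range(60):
                direction = rng.normal(size=3)
                if centripetal > 0 and np.linalg.norm(coords[-1]) > 1e-9:
                    direction -= centripetal * coords[-1] / np.linalg.norm(coords[-1])
                direction /= np.linalg.norm(direction)
                candidate = coords[-1] + CA_SPACING * direction
                prior = np.asarray(coords[:-1])
                if prior.size == 0 or np.min(
                    np.linalg.norm(prior - candidate, axis=1)
                ) >= MIN_SELF_DISTANCE:
                    coords.append(candidate)
                    placed = True
                    break
            if not placed:
                ok = False
                break
        if ok:
            return np.asarray(coords)
    raise GenerationError(
        f"self-avoiding walk failed to place {n} residues; try another seed"
    )


def _trace_backbone(trace: np.ndarray) -> list[dict[str, np.ndarray]]:
    """Attach schematic backbone atoms to an arbitrary C-alpha trace."""
    n = trace.shape[0]
    out = []
    for i in range(n):
        if n == 1:
            t = np.array([1.0, 0.0, 0.0])
        elif i < n - 1:
            t = trace[i + 1] - trace[i]
        else:
            t = trace[i] - trace[i - 1]
        t = t / np.linalg.norm(t)
        helper = np.array([0.0, 0.0, 1.0]) if abs(t[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
        p = np.cross(t, helper)
        p /= np.linalg.norm(p)
        ca = trace[i]
        out.append({
            "N": ca + _BOND_N_CA * (-0.8 * t + 0.6 * p),
            "CA": ca,
            "C": ca + _BOND_CA_C * (0.8 * t + 0.6 * p),
            "O": ca + _BOND_CA_C * (0.8 * t + 0.6 * p) + _BOND_C_O * p,
            "CB": ca - 1.53 * p,
        })
    return out


_ATOM_ELEMENTS = {"N": "N", "CA": "C", "C": "C", "O": "O", "CB": "C"}


def make_structure(spec: GeneratorSpec) -> ProteinStructure:
    """Generate one synthetic chain according to the spec."""
    rng = np.random.default_rng(spec.seed)
    if spec.sequence is not None:
        if len(spec.sequence) != spec.n_residues:
            raise GenerationError("sequence length must equal n_residues")
        sequence = [str(aa) for aa in spec.sequence]
    else:
        sequence = [STANDARD_AA[i] for i in rng.integers(0, 20, size=spec.n_residues)]

    if spec.geometry == "ideal_helix":
        backbone = _helix_backbone(spec.n_residues)
    elif spec.geometry == "extended_chain":
        backbone = _extended_backbone(spec.n_residues)
    elif spec.geometry == "self_avoiding_walk":
        backbone = _trace_backbone(_walk_trace(spec.n_residues, rng))
    elif spec.geometry == "globule":
        backbone = _trace_backbone(_walk_trace(spec.n_residues, rng, centripetal=0.9))
    else:
        raise GenerationError(f"unknown geometry {spec.geometry!r}")

    residues = []
    for i, (aa, coords) in enumerate(zip(sequence, backbone)):
        atom_names = ["N", "CA", "C", "O", "CB"]  # CB proxy on GLY too: the
        # pose guarantee of make_complex needs every residue to present the
        # same side-chain reach toward the partner.
        atoms = [
            Atom(name=name, element=_ATOM_ELEMENTS[name], coord=coords[name])
            for name in atom_names
        ]
        residues.append(Residue(
            chain_id=spec.chain_id,
            author_number=i + 1,
            insertion_code="",
            seq_index=i,
            aa=aa,
            atoms=atoms,
        ))
    return ProteinStructure(id=spec.protein_id, residues=residues)


def _rigid_transform(structure: ProteinStructure, rotation: np.ndarray,
                     translation: np.ndarray) -> ProteinStructure:
    residues = []
    for res in structure.residues:
        atoms = [
            Atom(name=a.name, element=a.element, coord=rotation @ a.coord + translation)
            for a in res.atoms
        ]
        residues.append(Residue(
            chain_id=res.chain_id, author_number=res.author_number,
            insertion_code=res.insertion_code, seq_index=res.seq_index,
            aa=res.aa, atoms=atoms,
        ))
    return ProteinStructure(id=structure.id, residues=residues)


def make_complex(
    spec_a: GeneratorSpec,
    spec_b: GeneratorSpec,
    contact_pairs: int,
    seed: int = 0,
    contact_distance: float = CONTACT_DISTANCE,
) -> tuple[ProteinStructure, ProteinStructure, np.ndarray]:
    """Pose two extended chains so exactly ``contact_pairs`` residues of A touch B.

    Returns ``(a, b, planted_labels)`` where the planted label vector marks
    the last ``contact_pairs`` residues of A. The pose puts the chains'
    side-chain atoms face to face at ``contact_distance`` (must be in
    (3.5, 5.0]) and is verified against :func:`label_interfaces`.
    """
    if spec_a.geometry != "extended_chain" or spec_b.geometry != "extended_chain":
        raise GenerationError(
            "guaranteed-interface posing is defined for extended_chain geometry"
        )
    if contact_pairs > min(spec_a.n_residues, spec_b.n_residues):
        raise GenerationError("contact_pairs exceeds a chain's residue count")
    if not 3.5 < contact_distance <= 5.0:
        raise GenerationError("contact_distance must lie in (3.5, 5.0]")

    a = make_structure(spec_a)
    b_raw = make_structure(spec_b)

    flip = np.diag([1.0, -1.0, -1.0])  # 180 degrees about x: CB now faces +y
    planted = np.zeros(a.n, dtype=int)
    if contact_pairs == 0:
        b = _rigid_transform(b_raw, flip, np.array([0.0, -100.0, 0.0]))
    else:
        planted[a.n - contact_pairs:] = 1
        # B residue j sits over A residue (n_a - k + j); CB planes face each
        # other separated by contact_distance.
        x_shift = CA_SPACING * (a.n - contact_pairs)
        y_shift = -3.0 - contact_distance
        b = _rigid_transform(b_raw, flip, np.array([x_shift, y_shift, 0.0]))

    observed = label_interfaces(a, b).labels
    if not np.array_equal(observed, planted):
        raise GenerationError(
            f"pose verification failed: planted {planted.sum()} contacts, "
            f"labeler found {observed.sum()}"
        )
    return a, b, planted


def make_planted_dataset(
    spec: PlantedDatasetSpec,
) -> tuple[MaskedDataset, np.ndarray]:
    """Generate a fully labeled composite dataset with a planted feature signal.

    Each protein is an extended chain posed against a partner so its
    interface labels are known by construction; real features are computed
    from the structure and a label-correlated shift of
    ``signal_strength`` x (column standard deviation) is added to the
    designated feature columns of interface rows. Proteins are split
    60/20/20 (train/validation/test) by whole protein. Returns the masked
    dataset and the ground-truth label vector (identical to
    ``dataset.labels``).
    """
    rng = np.random.default_rng(spec.seed)
    proteins = []
    raw_features = []
    all_labels = []
    for p in range(spec.n_proteins):
        n = spec.residues_per_protein
        k = int(np.clip(rng.binomial(n, spec.interface_fraction), 1, n - 1))
        pid = f"prot{p:03d}"
        seed_a = int(rng.integers(0, 2**31 - 1))
        seed_b = int(rng.integers(0, 2**31 - 1))
        a, b, planted = make_complex(
            GeneratorSpec(n_residues=n, geometry="extended_chain",
                          seed=seed_a, chain_id="A", protein_id=pid),
            GeneratorSpec(n_residues=k, geometry="extended_chain",
                          seed=seed_b, chain_id="B", protein_id=pid + "_partner"),
            contact_pairs=k,
        )
        graph = build_hierarchical(a, spec.threshold)
        feats = assemble_features(a, spec.threshold)
        labels = LabelVector(protein_id=pid, labels=planted)
        proteins.append((graph, feats, labels))
        raw_features.append(feats.values)
        all_labels.append(planted)

    stacked = np.vstack(raw_features)
    labels_flat = np.concatenate(all_labels)
    if spec.signal_strength > 0:
        sd = stacked.std(axis=0, ddof=0)
        for col in spec.signal_columns:
            shift = spec.signal_strength * (sd[col] if sd[col] > 0 else 1.0)
            offset = 0
            for _, feats, _ in proteins:
                block = slice(offset, offset + feats.n)
                feats.values[labels_flat[block] == 1, col] += shift
                offset += feats.n

    split = random_split(
        [g.protein_id for g, _, _ in proteins],
        fractions=spec.fractions,
        seed=spec.seed,
    )
    dataset = assemble(proteins, split)
    return dataset, dataset.labels.copy()
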