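"""Decoy ensemble containers, PDB and score-table I/O, and least-RMSD geometry.

A *decoy* is a computationally generated 3D model of a protein target,
represented here by its ordered C-alpha trace (in angstroms), a scalar
internal energy (Rosetta-style, lower is better), and optionally a vector of
knowledge-based potential features and its true RMSD to the native structure.
An ensemble collects all decoys generated for one target together with the
native C-alpha trace when it is known.

All inter-decoy distances are least RMSDs over C-alpha atoms: the root mean
squared deviation after optimal rigid superposition (Kabsch), with reflections
disallowed.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Decoy",
    "DecoyEnsemble",
    "DistanceStore",
    "least_rmsd",
    "kabsch_superpose",
    "pairwise_rmsd_matrix",
    "pairwise_distances",
    "read_decoy_set",
    "read_ca_coords",
    "write_ca_pdb",
    "write_decoy_set",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class Decoy:
    """One conformation: id, C-alpha coordinates (n_res, 3) in A, energy."""

    id: str
    coords: np.ndarray
    energy: float
    potentials: np.ndarray | None = None
    true_rmsd: float | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError(f"decoy {self.id!r}: coords must be (n, 3)")
        if self.coords.shape[0] < 3:
            raise ValueError(f"decoy {self.id!r}: needs at least 3 residues")
        if not np.isfinite(self.energy):
            raise ValueError(f"decoy {self.id!r}: energy must be finite")
        if self.potentials is not None:
            self.potentials = np.asarray(self.potentials, dtype=float)

    @property
    def n_residues(self) -> int:
        return self.coords.shape[0]


@dataclass
class DecoyEnsemble:
    """The decoy set Omega for one target, plus the native structure if known.

    ``min_dist`` is the minimum least RMSD between any decoy and the native;
    it drives the difficulty categorization of the target.
    """

    target_id: str
    decoys: list[Decoy]
    native: np.ndarray | None = None
    _min_dist: float | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not self.decoys:
            raise ValueError("ensemble must contain at least one decoy")
        ids = [d.id for d in self.decoys]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate decoy ids: {dupes}")
        n_res = {d.n_residues for d in self.decoys}
        if len(n_res) != 1:
            raise ValueError(
                f"decoys disagree on residue count: {sorted(n_res)}"
            )
        if self.native is not None:
            self.native = np.asarray(self.native, dtype=float)
            if self.native.shape != self.decoys[0].coords.shape:
                raise ValueError(
                    "native residue count does not match the decoys"
                )

    @property
    def size(self) -> int:
        return len(self.decoys)

    @property
    def n_residues(self) -> int:
        return self.decoys[0].n_residues

    @property
    def ids(self) -> list[str]:
        return [d.id for d in self.decoys]

    def __getitem__(self, decoy_id: str) -> Decoy:
        try:
            return next(d for d in self.decoys if d.id == decoy_id)
        except StopIteration:
            raise KeyError(decoy_id) from None

    def coords_array(self) -> np.ndarray:
        """(size, n_res, 3) stack of C-alpha coordinates, decoy order."""
        return np.stack([d.coords for d in self.decoys])

    def energies(self) -> np.ndarray:
        return np.array([d.energy for d in self.decoys], dtype=float)

    def potentials_matrix(self) -> np.ndarray:
        if any(d.potentials is None for d in self.decoys):
            raise ValueError("not every decoy carries a potentials vector")
        lens = {len(d.potentials) for d in self.decoys}
        if len(lens) != 1:
            raise ValueError(f"inconsistent potentials lengths: {sorted(lens)}")
        return np.stack([d.potentials for d in self.decoys])

    def true_rmsds(self, recompute: bool = False) -> np.ndarray:
        """Per-decoy least RMSD to the native, in decoy order.

        Uses cached ``true_rmsd`` values when present, otherwise computes
        them from the native structure.
        """
        if not recompute and all(d.true_rmsd is not None for d in self.decoys):
            return np.array([d.true_rmsd for d in self.decoys], dtype=float)
        if self.native is None:
            raise ValueError("ensemble has no native structure")
        vals = _rmsd_one_to_many(self.native, self.coords_array())
        for d, v in zip(self.decoys, vals):
            d.true_rmsd = float(v)
        return vals

    @property
    def min_dist(self) -> float:
        """Minimum RMSD between any decoy and the native structure (A)."""
        if self._min_dist is None:
            self._min_dist = float(np.min(self.true_rmsds()))
        return self._min_dist

    def content_hash(self) -> str:
        h = hashlib.sha1()
        h.update(self.target_id.encode())
        for d in self.decoys:
            h.update(d.id.encode())
            h.update(np.ascontiguousarray(d.coords).tobytes())
        return h.hexdigest()[:16]


class DistanceStore:
    """Symmetric matrix of pairwise least-RMSD values r_ij (A) over decoy ids."""

    def __init__(self, ids: Sequence[str], matrix: np.ndarray):
        matrix = np.asarray(matrix, dtype=float)
        if matrix.shape != (len(ids), len(ids)):
            raise ValueError("matrix shape does not match id count")
        if np.any(matrix < -1e-9):
            raise ValueError("distances must be non-negative")
        if not np.allclose(matrix, matrix.T, atol=1e-8):
            raise ValueError("distance matrix must be symmetric")
        self.ids = list(ids)
        self.matrix = matrix
        self._index = {i: k for k, i in enumerate(self.ids)}

    def __len__(self) -> int:
        return len(self.ids)

    def distance(self, a: str, b: str) -> float:
        return float(self.matrix[self._index[a], self._index[b]])

    def index_of(self, decoy_id: str) -> int:
        return self._index[decoy_id]

    def submatrix(self, ids: Sequence[str]) -> np.ndarray:
        idx = np.array([self._index[i] for i in ids], dtype=int)
        return self.matrix[np.ix_(idx, idx)]

    def subset(self, ids: Sequence[str]) -> "DistanceStore":
        return DistanceStore(list(ids), self.submatrix(ids))


# ---------------------------------------------------------------------------
# least-RMSD geometry
# ---------------------------------------------------------------------------


def _center(X: np.ndarray) -> np.ndarray:
    return X - X.mean(axis=0)


def kabsch_superpose(mobile: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Rigidly superpose ``mobile`` onto ``target``; returns moved coordinates.

    Proper rotations only: the determinant sign of the rotation is corrected
    so reflections are never applied.
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mobile.shape != target.shape:
        raise ValueError("coordinate sets differ in shape")
    mc, tc = mobile.mean(axis=0), target.mean(axis=0)
    A, B = mobile - mc, target - tc
    H = A.T @ B
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.diag([1.0, 1.0, d])
    R = U @ D @ Vt
    return A @ R + tc


def least_rmsd(A: np.ndarray, B: np.ndarray) -> float:
    """Least RMSD between two equal-length coordinate lists (A).

    Optimal-superposition RMSD via the Kabsch algorithm with determinant
    correction (reflections disallowed). Symmetric in its arguments and
    invariant to rigid motions applied to either one.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape != B.shape:
        raise ValueError(f"coordinate sets differ in shape: {A.shape} vs {B.shape}")
    if A.ndim != 2 or A.shape[1] != 3 or A.shape[0] < 3:
        raise ValueError("need (n>=3, 3) coordinate arrays")
    n = A.shape[0]
    Ac, Bc = _center(A), _center(B)
    H = Ac.T @ Bc
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(U @ Vt))
    R = U @ np.diag([1.0, 1.0, d]) @ Vt
    resid = Ac @ R - Bc
    return float(np.sqrt(np.sum(resid * resid) / n))


def _sym3_eigvals(S: np.ndarray) -> np.ndarray:
    """Eigenvalues of a stack of symmetric 3x3 matrices, closed form.

    Trigonometric solution of the characteristic cubic; fully vectorized so
    large pairwise-distance matrices avoid per-matrix LAPACK calls. Returns
    eigenvalues sorted descending along the last axis.
    """
    S = np.asarray(S, dtype=float)
    q = np.trace(S, axis1=-2, axis2=-1) / 3.0
    I = np.eye(3)
    Sq = S - q[..., None, None] * I
    p2 = np.sum(Sq * Sq, axis=(-2, -1)) / 6.0
    p = np.sqrt(np.maximum(p2, 0.0))
    # det(Sq) / (2 p^3) clipped into [-1, 1]; p == 0 means S is scalar.
    detSq = (
        Sq[..., 0, 0] * (Sq[..., 1, 1] * Sq[..., 2, 2] - Sq[..., 1, 2] * Sq[..., 2, 1])
        - Sq[..., 0, 1] * (Sq[..., 1, 0] * Sq[..., 2, 2] - Sq[..., 1, 2] * Sq[..., 2, 0])
        + Sq[..., 0, 2] * (Sq[..., 1, 0] * Sq[..., 2, 1] - Sq[..., 1, 1] * Sq[..., 2, 0])
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(p > 0, detSq / (2.0 * np.maximum(p, 1e-300) ** 3), 0.0)
    r = np.clip(r, -1.0, 1.0)
    phi = np.arccos(r) / 3.0
    e1 = q + 2.0 * p * np.cos(phi)
    e3 = q + 2.0 * p * np.cos(phi + 2.0 * np.pi / 3.0)
    e2 = 3.0 * q - e1 - e3
    return np.stack([e1, e2, e3], axis=-1)


def _det3(H: np.ndarray) -> np.ndarray:
    return (
        H[..., 0, 0] * (H[..., 1, 1] * H[..., 2, 2] - H[..., 1, 2] * H[..., 2, 1])
        - H[..., 0, 1] * (H[..., 1, 0] * H[..., 2, 2] - H[..., 1, 2] * H[..., 2, 0])
        + H[..., 0, 2] * (H[..., 1, 0] * H[..., 2, 1] - H[..., 1, 1] * H[..., 2, 0])
    )


def _batched_rmsd(Ac: np.ndarray, ga: np.ndarray, Bc: np.ndarray, gb: np.ndarray) -> np.ndarray:
    """RMSD block between centered stacks Ac (a,n,3) and Bc (b,n,3).

    ga/gb are the per-structure squared norms sum(X*X). Kabsch-equivalent:
    RMSD^2 = (ga + gb - 2 (s1 + s2 + sign(det H) s3)) / n with s_i the
    singular values of the 3x3 cross-covariance H.
    """
    n = Ac.shape[1]
    H = np.einsum("ank,bnl->abkl", Ac, Bc)
    G = np.einsum("abki,abkj->abij", H, H)  # H^T H, symmetric PSD
    eig = np.maximum(_sym3_eigvals(G), 0.0)
    s = np.sqrt(eig)
    sign = np.where(_det3(H) < 0.0, -1.0, 1.0)
    D = s[..., 0] + s[..., 1] + sign * s[..., 2]
    msd = (ga[:, None] + gb[None, :] - 2.0 * D) / n
    return np.sqrt(np.maximum(msd, 0.0))


def _rmsd_one_to_many(ref: np.ndarray, stack: np.ndarray) -> np.ndarray:
    ref_c = _center(np.asarray(ref, dtype=float))[None]
    stack_c = stack - stack.mean(axis=1, keepdims=True)
    ga = np.array([np.sum(ref_c[0] * ref_c[0])])
    gb = np.einsum("ank,ank->a", stack_c, stack_c)
    return _batched_rmsd(ref_c, ga, stack_c, gb)[0]


def pairwise_rmsd_matrix(coords: np.ndarray, chunk: int = 64) -> np.ndarray:
    """Full symmetric least-RMSD matrix over a (m, n_res, 3) coordinate stack."""
    coords = np.asarray(coords, dtype=float)
    m = coords.shape[0]
    cen = coords - coords.mean(axis=1, keepdims=True)
    g = np.einsum("ank,ank->a", cen, cen)
    out = np.zeros((m, m))
    for i0 in range(0, m, chunk):
        i1 = min(i0 + chunk, m)
        block = _batched_rmsd(cen[i0:i1], g[i0:i1], cen, g)
        out[i0:i1] = block
    out = (out + out.T) / 2.0
    np.fill_diagonal(out, 0.0)
    return out


def pairwise_distances(
    ensemble: DecoyEnsemble,
    subset: Sequence[str] | None = None,
    cache_dir: str | Path | None = None,
) -> DistanceStore:
    """Pairwise least-RMSD store over an ensemble (or a subset of its ids).

    When ``cache_dir`` is given the matrix is persisted keyed by a hash of
    the coordinates, so repeated runs on the same ensemble skip the
    quadratic recomputation.
    """
    ids = ensemble.ids if subset is None else list(subset)
    unknown = set(ids) - set(ensemble.ids)
    if unknown:
        raise KeyError(f"subset ids not in ensemble: {sorted(unknown)}")
    coords = np.stack([ensemble[i].coords for i in ids])

    cache_path = None
    if cache_dir is not None:
        h = hashlib.sha1()
        for i in ids:
            h.update(i.encode())
        h.update(np.ascontiguousarray(coords).tobytes())
        cache_path = Path(cache_dir) / f"rmsd_{h.hexdigest()[:16]}.npz"
        if cache_path.exists():
            data = np.load(cache_path, allow_pickle=False)
            return DistanceStore(ids, data["matrix"])

    matrix = pairwise_rmsd_matrix(coords)
    if cache_path is not None:
        cache_path.parent.mkdir(parents=True, exist_ok=True)
        np.savez_compressed(cache_path, matrix=matrix)
    return DistanceStore(ids, matrix)


# ---------------------------------------------------------------------------
# PDB + score-table I/O
# ---------------------------------------------------------------------------


def read_ca_coords(path: str | Path) -> np.ndarray:
    """C-alpha coordinates from a PDB file (first model, insertion codes skipped)."""
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure(Path(path).stem, str(path))
    model = next(structure.get_models())
    coords = []
    n_icode = 0
    for chain in model:
        for residue in chain:
            if residue.id[2].strip():
                n_icode += 1
                continue
            if "CA" in residue:
                coords.append(residue["CA"].get_coord())
    if n_icode:
        warnings.warn(
            f"{path}: ignored {n_icode} residue(s) with insertion codes",
            stacklevel=2,
        )
    if len(coords) < 3:
        raise ValueError(f"{path}: fewer than 3 CA atoms found")
    return np.asarray(coords, dtype=float)


def write_ca_pdb(coords: np.ndarray, path: str | Path, name: str = "decoy") -> None:
    """Write a C-alpha trace as minimal PDB ATOM records (GLY backbone)."""
    coords = np.asarray(coords, dtype=float)
    lines = []
    for i, (x, y, z) in enumerate(coords, start=1):
        lines.append(
            f"ATOM  {i:5d}  CA  GLY A{i:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
            f" C  "
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def _read_score_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep=None, engine="python")
    if "id" not in table.columns:
        raise ValueError(f"{path}: score table lacks required column 'id'")
    if "energy" not in table.columns:
        raise ValueError(f"{path}: score table lacks required column 'energy'")
    table["id"] = table["id"].astype(str)
    return table


def read_decoy_set(
    structure_files: Iterable[str | Path],
    score_table: str | Path,
    target_id: str | None = None,
    native_file: str | Path | None = None,
) -> DecoyEnsemble:
    """Assemble an ensemble from per-decoy PDB files and a score table.

    The table must have ``id`` and ``energy`` columns (TSV or CSV, sniffed);
    every other numeric column becomes the decoy's potentials vector, in
    header order (``true_rmsd``, when present, is kept separate). A decoy id
    defaults to the structure file's basename without extension. Ids present
    in only one of the two sources are warned about and dropped.
    """
    files = {Path(p).stem: Path(p) for p in structure_files}
    table = _read_score_table(score_table)

    table_ids = list(table["id"])
    common = [i for i in table_ids if i in files]
    dropped = sorted(set(table_ids) ^ set(files))
    if dropped:
        warnings.warn(
            f"dropping {len(dropped)} id(s) present in only one source: "
            f"{dropped[:10]}{'...' if len(dropped) > 10 else ''}",
            stacklevel=2,
        )
    if not common:
        raise ValueError("no decoy ids shared between structures and score table")

    pot_cols = [
        c
        for c in table.columns
        if c not in ("id", "energy", "true_rmsd")
        and pd.api.types.is_numeric_dtype(table[c])
    ]
    rows = table.set_index("id").loc[common]

    decoys = []
    n_res = None
    for decoy_id in common:
        coords = read_ca_coords(files[decoy_id])
        if n_res is None:
            n_res = coords.shape[0]
        elif coords.shape[0] != n_res:
            raise ValueError(
                f"{files[decoy_id]}: residue count {coords.shape[0]} "
                f"differs from expected {n_res}"
            )
        row = rows.loc[decoy_id]
        decoys.append(
            Decoy(
                id=decoy_id,
                coords=coords,
                energy=float(row["energy"]),
                potentials=(
                    row[pot_cols].to_numpy(dtype=float) if pot_cols else None
                ),
                true_rmsd=(
                    float(row["true_rmsd"]) if "true_rmsd" in rows.columns else None
                ),
            )
        )

    native = read_ca_coords(native_file) if native_file is not None else None
    return DecoyEnsemble(
        target_id=target_id or Path(score_table).stem,
        decoys=decoys,
        native=native,
    )


def write_decoy_set(
    ensemble: DecoyEnsemble, out_dir: str | Path, sep: str = "\t"
) -> Path:
    """Write per-decoy PDB files plus the score table; returns the table path.

    Potentials columns are named ``pot_0..pot_{k-1}``; ``true_rmsd`` is
    included when every decoy carries it. The native, if present, is written
    as ``native.pdb``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records: dict[str, list] = {"id": [], "energy": []}
    has_pot = all(d.potentials is not None for d in ensemble.decoys)
    has_rmsd = all(d.true_rmsd is not None for d in ensemble.decoys)
    n_pot = len(ensemble.decoys[0].potentials) if has_pot else 0
    for d in ensemble.decoys:
        write_ca_pdb(d.coords, out_dir / f"{d.id}.pdb", name=d.id)
        records["id"].append(d.id)
        records["energy"].append(d.energy)
        if has_pot:
            for k in range(n_pot):
                records.setdefault(f"pot_{k}", []).append(d.potentials[k])
        if has_rmsd:
            records.setdefault("true_rmsd", []).append(d.true_rmsd)
    if ensemble.native is not None:
        write_ca_pdb(ensemble.native, out_dir / "native.pdb", name="native")
    table_path = out_dir / f"{ensemble.target_id}_scores.tsv"
    pd.DataFrame(records).to_csv(table_path, sep=sep, index=False)
    return table_path
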