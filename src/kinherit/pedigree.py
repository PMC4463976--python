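"""Pedigrees, kinship matrices and the eigendecomposition of ``2*Phi``.

The additive genetic covariance of a quantitative trait in a pedigree is
``sigma_A^2 * 2*Phi`` where ``Phi`` is the kinship matrix: entry (i, j) is
half the expected proportion of genetic material shared by subjects i and j
(0.5 on the diagonal for a non-inbred subject, 0.25 for parent/offspring or
full sibs, and so on).  Everything downstream of this module works in the
eigenbasis of ``2*Phi``, where the phenotypic covariance becomes diagonal:
``sigma_A^2 * lambda_i + sigma_E^2``.

Families are independent, so ``Phi`` is block-diagonal up to subject order
and the eigendecomposition is performed per connected block.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import eigh
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

__all__ = [
    "PedigreeTable",
    "KinshipMatrix",
    "EigenKinship",
    "kinship_from_pedigree",
    "eigen_kinship",
    "generate_pedigree",
    "read_pedigree",
    "write_pedigree",
    "read_kinship",
    "write_kinship",
    "save_eigen",
    "load_eigen",
]

#: strings treated as "no parent recorded" in pedigree files
MISSING_PARENT = ("", "0", "NA", "nan", "None")

_EIG_NEG_TOL = 1e-10


class PedigreeError(ValueError):
    """Structural problem in a pedigree (cycles, unknown parents, duplicates)."""


def _clean_parent(value) -> str | None:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    s = str(value).strip()
    return None if s in MISSING_PARENT else s


@dataclass
class PedigreeTable:
    """A validated pedigree: one row per subject, parents resolvable.

    Parameters
    ----------
    table : pandas.DataFrame
        Columns ``id, father, mother, family`` and optionally ``sex``.
        Missing parents are encoded as ``None`` (founder).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table.copy()
        required = ["id", "father", "mother", "family"]
        for col in required:
            if col not in df.columns:
                raise PedigreeError(f"pedigree table missing column {col!r}")
        df["id"] = df["id"].astype(str)
        if df["id"].duplicated().any():
            dup = df.loc[df["id"].duplicated(), "id"].iloc[0]
            raise PedigreeError(f"duplicated subject id {dup!r}")
        for col in ("father", "mother"):
            df[col] = df[col].map(_clean_parent)
        df["family"] = df["family"].astype(str)
        known = set(df["id"])
        for col in ("father", "mother"):
            for pid in df[col]:
                if pid is not None and pid not in known:
                    raise PedigreeError(f"unknown {col} id {pid!r}")
        self.table = df.reset_index(drop=True)
        self._topological_order()  # raises on cycles

    @property
    def ids(self) -> list[str]:
        return list(self.table["id"])

    @property
    def n_subjects(self) -> int:
        return len(self.table)

    @property
    def families(self) -> list[str]:
        seen: dict[str, None] = {}
        for fam in self.table["family"]:
            seen.setdefault(fam, None)
        return list(seen)

    def _topological_order(self) -> list[int]:
        """Row indices with parents before offspring; raises on cycles."""
        df = self.table
        idx_of = {sid: i for i, sid in enumerate(df["id"])}
        fathers = [idx_of[p] if p is not None else -1 for p in df["father"]]
        mothers = [idx_of[p] if p is not None else -1 for p in df["mother"]]
        placed = np.zeros(len(df), dtype=bool)
        order: list[int] = []
        pending = list(range(len(df)))
        while pending:
            progressed = []
            for i in pending:
                fa, mo = fathers[i], mothers[i]
                if (fa < 0 or placed[fa]) and (mo < 0 or placed[mo]):
                    progressed.append(i)
            if not progressed:
                raise PedigreeError("cycle detected in pedigree")
            for i in progressed:
                placed[i] = True
                order.append(i)
            pending = [i for i in pending if not placed[i]]
        return order


@dataclass
class KinshipMatrix:
    """Kinship coefficients ``Phi`` with the subject order they refer to."""

    Phi: np.ndarray
    subject_order: list[str]

    def __post_init__(self) -> None:
        self.Phi = np.asarray(self.Phi, dtype=float)
        if self.Phi.ndim != 2 or self.Phi.shape[0] != self.Phi.shape[1]:
            raise ValueError("kinship matrix must be square")
        if len(self.subject_order) != self.Phi.shape[0]:
            raise ValueError("subject_order length does not match matrix")
        if not np.allclose(self.Phi, self.Phi.T, atol=1e-12):
            raise ValueError("kinship matrix must be symmetric")


@dataclass
class EigenKinship:
    """Eigenvectors ``S`` and eigenvalues ``lambda_g`` of ``2*Phi``.

    ``S' (2*Phi) S = diag(lambda_g)`` and ``mean(lambda_g) = trace(2*Phi)/N``,
    which is exactly 1 for non-inbred pedigrees.
    """

    S: np.ndarray
    lambda_g: np.ndarray
    subject_order: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        self.lambda_g = np.asarray(self.lambda_g, dtype=float)
        if not self.subject_order:
            self.subject_order = [str(i) for i in range(self.S.shape[0])]

    @property
    def n_subjects(self) -> int:
        return self.S.shape[0]


def kinship_from_pedigree(ped: PedigreeTable) -> KinshipMatrix:
    """Compute the kinship matrix by the standard recursion.

    ``phi(i, i) = (1 + phi(f_i, m_i)) / 2`` and, for j neither i nor a
    descendant of i, ``phi(i, j) = (phi(f_i, j) + phi(m_i, j)) / 2``;
    founders are unrelated and non-inbred.  Processing subjects in
    topological order (parents first) makes the recursion a single
    O(N^2) dynamic program.
    """
    df = ped.table
    n = len(df)
    idx_of = {sid: i for i, sid in enumerate(df["id"])}
    fathers = np.array([idx_of[p] if p is not None else -1 for p in df["father"]])
    mothers = np.array([idx_of[p] if p is not None else -1 for p in df["mother"]])
    K = np.zeros((n, n))
    done: list[int] = []
    for i in ped._topological_order():
        fa, mo = fathers[i], mothers[i]
        if fa < 0 and mo < 0:
            K[i, i] = 0.5
        else:
            if fa < 0 or mo < 0:
                raise PedigreeError(
                    f"subject {df['id'][i]!r} has exactly one known parent"
                )
            K[i, i] = 0.5 * (1.0 + K[fa, mo])
            if done:
                d = np.array(done)
                K[i, d] = 0.5 * (K[fa, d] + K[mo, d])
                K[d, i] = K[i, d]
        done.append(i)
    return KinshipMatrix(Phi=K, subject_order=ped.ids)


def _family_blocks(Phi: np.ndarray) -> list[np.ndarray]:
    """Index sets of the connected (family) blocks of a kinship matrix."""
    adj = csr_matrix(Phi != 0.0)
    n_comp, labels = connected_components(adj, directed=False)
    blocks = []
    seen: dict[int, int] = {}
    for lab in labels:  # order of first appearance
        if lab not in seen:
            seen[lab] = len(seen)
    for lab in seen:
        blocks.append(np.flatnonzero(labels == lab))
    return blocks


def eigen_kinship(kin: KinshipMatrix) -> EigenKinship:
    """Eigendecomposition of ``2*Phi``, computed block-wise per family.

    Within each family block eigenvalues are sorted descending and each
    eigenvector's sign is fixed so that its largest-magnitude entry is
    positive, making ``S`` reproducible.  Eigenvalues in [-1e-10, 0) are
    clipped to 0; anything more negative raises (not positive
    semi-definite).
    """
    Phi = kin.Phi
    if not np.allclose(Phi, Phi.T, atol=1e-12):
        raise ValueError("kinship matrix must be symmetric")
    n = Phi.shape[0]
    S = np.zeros((n, n))
    lam = np.zeros(n)
    col = 0
    for idx in _family_blocks(Phi):
        block = 2.0 * Phi[np.ix_(idx, idx)]
        w, v = eigh(block)
        if np.any(w < -_EIG_NEG_TOL):
            raise ValueError(
                f"2*Phi is not positive semi-definite (min eigenvalue {w.min():.3e})"
            )
        w = np.clip(w, 0.0, None)
        order = np.argsort(-w, kind="stable")
        w, v = w[order], v[:, order]
        # sign convention: largest-|entry| of each eigenvector positive
        peaks = np.argmax(np.abs(v), axis=0)
        signs = np.sign(v[peaks, np.arange(v.shape[1])])
        signs[signs == 0] = 1.0
        v = v * signs
        m = len(idx)
        S[np.ix_(idx, np.arange(col, col + m))] = v
        lam[col : col + m] = w
        col += m
    return EigenKinship(S=S, lambda_g=lam, subject_order=list(kin.subject_order))


# ---------------------------------------------------------------------------
# synthetic pedigrees
# ---------------------------------------------------------------------------


def generate_pedigree(
    n_families: int,
    family_size_plan: int | list[int],
    seed: int | np.random.Generator = 0,
    mean_extra_children: float = 1.8,
) -> PedigreeTable:
    """Generate synthetic multi-generation extended pedigrees.

    Each family starts from a founder couple; couples have ``1 + Poisson``
    children; children acquire marry-in spouses (new founders) who
    immediately reproduce, growing the family over several generations
    until its size quota is met exactly.  All matings are between
    non-relatives, so the pedigree is non-inbred.

    Parameters
    ----------
    n_families : int
        Number of independent families.
    family_size_plan : int or list of int
        Total subject count (split as evenly as possible) or explicit
        per-family sizes.
    seed : int or numpy Generator
        Reproducibility: the same seed gives a byte-identical table.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if n_families < 1:
        raise ValueError("n_families must be >= 1")
    if isinstance(family_size_plan, (int, np.integer)):
        total = int(family_size_plan)
        if total < n_families:
            raise ValueError("total size smaller than number of families")
        base = total // n_families
        sizes = [base + (1 if i < total % n_families else 0) for i in range(n_families)]
    else:
        sizes = [int(s) for s in family_size_plan]
        if len(sizes) != n_families:
            raise ValueError("family_size_plan length must equal n_families")
        if any(s < 1 for s in sizes):
            raise ValueError("family sizes must be >= 1")

    rows = []
    uid = 0

    def new_id() -> str:
        nonlocal uid
        uid += 1
        return f"I{uid:05d}"

    for fam_no, size in enumerate(sizes, start=1):
        fam = f"F{fam_no}"
        if size == 1:
            rows.append((new_id(), None, None, fam, "M"))
            continue
        f0, m0 = new_id(), new_id()
        rows.append((f0, None, None, fam, "M"))
        rows.append((m0, None, None, fam, "F"))
        remaining = size - 2
        couples: list[tuple[str, str]] = [(f0, m0)]
        singles: list[tuple[str, str]] = []  # (id, sex) of unmarried children
        root = (f0, m0)
        while remaining > 0:
            if couples:
                fa, mo = couples.pop(0)
                k = min(1 + int(rng.poisson(mean_extra_children)), remaining)
                for _ in range(k):
                    sex = "M" if rng.random() < 0.5 else "F"
                    cid = new_id()
                    rows.append((cid, fa, mo, fam, sex))
                    singles.append((cid, sex))
                    remaining -= 1
            elif singles and remaining >= 2:
                j = int(rng.integers(len(singles)))
                cid, sex = singles.pop(j)
                spouse = new_id()
                sp_sex = "F" if sex == "M" else "M"
                rows.append((spouse, None, None, fam, sp_sex))
                remaining -= 1
                couple = (cid, spouse) if sex == "M" else (spouse, cid)
                couples.append(couple)  # guaranteed >= 1 child next pass
            else:
                # quota of 1 left and nobody to marry: extra child of the root
                sex = "M" if rng.random() < 0.5 else "F"
                rows.append((new_id(), root[0], root[1], fam, sex))
                remaining -= 1
    df = pd.DataFrame(rows, columns=["id", "father", "mother", "family", "sex"])
    return PedigreeTable(df)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_pedigree(path) -> PedigreeTable:
    """Read a pedigree CSV with columns ``id,father,mother,family[,sex]``."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    df.columns = [c.strip().lower() for c in df.columns]
    return PedigreeTable(df)


def write_pedigree(ped: PedigreeTable, path) -> None:
    df = ped.table.copy()
    for col in ("father", "mother"):
        df[col] = [p if p is not None else "" for p in df[col]]
    df.to_csv(path, index=False)


def read_kinship(path) -> KinshipMatrix:
    """Read a square kinship CSV with subject ids as header row and column."""
    df = pd.read_csv(path, index_col=0)
    if df.shape[0] != df.shape[1]:
        raise ValueError("kinship table is not square")
    if list(df.index.astype(str)) != [str(c) for c in df.columns]:
        raise ValueError("kinship row and column ids do not match")
    return KinshipMatrix(Phi=df.to_numpy(float), subject_order=[str(c) for c in df.columns])


def write_kinship(kin: KinshipMatrix, path) -> None:
    pd.DataFrame(kin.Phi, index=kin.subject_order, columns=kin.subject_order).to_csv(path)


def save_eigen(eig: EigenKinship, path) -> None:
    """Serialize an eigendecomposition to a NumPy ``.npz`` container."""
    np.savez(
        path,
        S=eig.S,
        lambda_g=eig.lambda_g,
        subject_order=np.array(eig.subject_order, dtype=object),
    )


def load_eigen(path) -> EigenKinship:
    with np.load(path, allow_pickle=True) as z:
        return EigenKinship(
            S=z["S"], lambda_g=z["lambda_g"], subject_order=list(z["subject_order"])
        )
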