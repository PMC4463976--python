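"""Massively univariate heritability analysis over image elements.

Runs the univariate pipeline at every in-mask voxel of a 4-D image stack
(x, y, z, subject) and corrects for the multiple testing problem:

* voxel-wise FWE via the permutation distribution of the image-wide
  maximum statistic (one shared permutation sequence across voxels);
* cluster-wise FWE via the permutation distribution of the maximum
  suprathreshold cluster size, with the cluster-forming threshold taken
  from the parametric reference distribution of the chosen statistic;
* FDR (Benjamini-Hochberg step-up) on uncorrected p-values.

Also provides the rank-based inverse-normal transform used to normalize
phenotypes before analysis, and NIfTI I/O through nibabel with a sidecar
table mapping volume index to subject id.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .batch import batch_h2, batch_ml, batch_parametric_p, batch_permutation, _batch_wls
from .pedigree import EigenKinship
from .permutation import PermutationPlan

__all__ = [
    "ImageStack",
    "StatImage",
    "ClusterTable",
    "voxelwise_analysis",
    "voxel_fwe",
    "cluster_fwe",
    "fdr_bh",
    "inverse_normal_transform",
    "read_image_stack",
    "write_stat_image",
]


@dataclass
class ImageStack:
    """4-D data (x, y, z, subject) with a 3-D analysis mask."""

    data: np.ndarray
    mask: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    subject_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, float)
        self.mask = np.asarray(self.mask, bool)
        if self.data.ndim != 4:
            raise ValueError("image stack must be 4-D (x, y, z, subject)")
        if self.mask.shape != self.data.shape[:3]:
            raise ValueError("mask grid does not match the image stack")
        if not self.mask.any():
            raise ValueError("mask is empty")

    @property
    def n_subjects(self) -> int:
        return self.data.shape[3]

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    def flat(self) -> np.ndarray:
        """In-mask data as an (n_subjects, n_voxels) matrix."""
        return self.data[self.mask].T

    def unflatten(self, values: np.ndarray, fill: float = np.nan) -> np.ndarray:
        out = np.full(self.mask.shape, fill)
        out[self.mask] = values
        return out


@dataclass
class StatImage:
    """Named 3-D result maps defined on a shared mask."""

    maps: dict[str, np.ndarray]
    mask: np.ndarray
    affine: np.ndarray
    metadata: dict = field(default_factory=dict)
    clusters: "ClusterTable | None" = None


@dataclass
class ClusterTable:
    """One row per suprathreshold cluster: id, size, peak, FWE p."""

    table: pd.DataFrame
    threshold: float
    forming_p: float
    connectivity: int
    max_size_null: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.table)


def _connectivity_structure(connectivity: int) -> np.ndarray:
    order = {6: 1, 18: 2, 26: 3}
    if connectivity not in order:
        raise ValueError("connectivity must be 6, 18 or 26")
    return ndimage.generate_binary_structure(3, order[connectivity])


def forming_threshold(
    kind: str, forming_p: float, X: np.ndarray, lam: np.ndarray
) -> float:
    """Statistic cutoff whose parametric uncorrected p equals ``forming_p``.

    Mixture kinds: p(T) = P(chi2_1 >= T)/2, so T = chi2_1^-1 tail at
    2*forming_p (requires forming_p < 0.5).  GQ: upper F quantile.
    """
    if not 0 < forming_p < 0.5:
        raise ValueError("forming_p must be in (0, 0.5)")
    kind = kind.lower().replace("-", "_")
    if kind == "gq":
        p_cov = X.shape[1]
        n_A = int(np.count_nonzero(lam > 1.0))
        n_B = lam.shape[0] - n_A
        return float(sps.f.isf(forming_p, n_A - p_cov, n_B - p_cov))
    return float(sps.chi2.isf(2.0 * forming_p, df=1))


def voxelwise_analysis(
    stack: ImageStack,
    X: np.ndarray,
    eig: EigenKinship,
    test_kind: str = "score",
    plan: PermutationPlan | None = None,
    estimator: str = "wls",
    compute_ml: bool = True,
    cluster_forming_p: float | None = None,
    connectivity: int = 26,
) -> StatImage:
    """Fit and test every in-mask voxel; optionally permute for FWE.

    All voxels share one permutation sequence (drawn from ``plan.seed``),
    which is what makes the maximum-statistic and maximum-cluster-size
    null distributions valid for FWE correction.
    """
    X = np.atleast_2d(np.asarray(X, float))
    if stack.n_subjects != eig.n_subjects or X.shape[0] != eig.n_subjects:
        raise ValueError("subject counts of stack, design and kinship differ")
    Y = stack.flat()  # (N, V)
    St = eig.S.T
    Y_star = St @ Y
    X_star = St @ X
    lam = eig.lambda_g

    maps: dict[str, np.ndarray] = {}
    theta_wls, _, _ = _batch_wls(Y_star, X_star, lam)
    maps["h2_wls"] = stack.unflatten(batch_h2(theta_wls))
    if compute_ml:
        ml = batch_ml(Y_star, X_star, lam)
        maps["h2_ml"] = stack.unflatten(batch_h2(ml["theta"]))

    meta: dict = {"test_kind": test_kind, "n_subjects": stack.n_subjects}
    clusters = None
    if plan is None:
        from .batch import batch_statistic

        T = batch_statistic(Y_star, X_star, lam, test_kind)
        maps["stat"] = stack.unflatten(T)
        p_par = batch_parametric_p(T, test_kind, X=X_star, lam=lam)
        maps["p_param"] = stack.unflatten(p_par)
        maps["q_fdr"] = stack.unflatten(fdr_bh(p_par))
    else:
        need_maps = cluster_forming_p is not None
        res = batch_permutation(
            Y_star,
            X_star,
            lam,
            kind=test_kind,
            scheme=plan.scheme,
            m=plan.m,
            seed=plan.seed,
            per_column_perms=False,
            estimator=estimator,
            include_identity=plan.include_identity,
            return_perm_stats=need_maps,
        )
        T = res["observed"]
        maps["stat"] = stack.unflatten(T)
        p_par = batch_parametric_p(T, test_kind, X=X_star, lam=lam)
        maps["p_param"] = stack.unflatten(p_par)
        maps["p_perm"] = stack.unflatten(res["p_perm"])
        maps["p_fwe"] = stack.unflatten(voxel_fwe(T, res["max_stats"]))
        maps["q_fdr"] = stack.unflatten(fdr_bh(res["p_perm"]))
        meta.update(scheme=plan.scheme, m=plan.m, seed=plan.seed)
        if need_maps:
            clusters = cluster_fwe(
                maps["stat"],
                stack.mask,
                forming_p=cluster_forming_p,
                connectivity=connectivity,
                perm_stat_maps=res["perm_stats"],
                kind=test_kind,
                X=X_star,
                lam=lam,
            )
            meta["cluster_forming_p"] = cluster_forming_p

    return StatImage(
        maps=maps, mask=stack.mask, affine=stack.affine, metadata=meta, clusters=clusters
    )


def voxel_fwe(observed: np.ndarray, max_stats: np.ndarray) -> np.ndarray:
    """FWE-corrected p per voxel from the max-statistic null distribution.

    p_FWE(v) = proportion of permutations whose image-wide maximum reaches
    the voxel's observed statistic (identity permutation included in
    ``max_stats``), hence p_FWE >= uncorrected p everywhere.
    """
    observed = np.asarray(observed, float)
    ms = np.sort(np.asarray(max_stats, float))
    m = len(ms)
    # count of max_stats >= t  ==  m - first index where ms >= t
    idx = np.searchsorted(ms, observed, side="left")
    return (m - idx) / m


def _label_clusters(
    stat_map: np.ndarray, mask: np.ndarray, threshold: float, structure: np.ndarray
):
    supra = np.zeros(mask.shape, dtype=bool)
    vals = np.nan_to_num(stat_map, nan=-np.inf)
    supra[mask] = vals[mask] > threshold
    labels, n = ndimage.label(supra, structure=structure)
    return labels, n


def cluster_fwe(
    stat_map: np.ndarray,
    mask: np.ndarray,
    forming_p: float,
    connectivity: int,
    perm_stat_maps: np.ndarray,
    kind: str,
    X: np.ndarray,
    lam: np.ndarray,
) -> ClusterTable:
    """Cluster-wise FWE inference by the maximum-cluster-size distribution.

    ``perm_stat_maps`` is the (m, V) matrix of per-permutation statistics
    over in-mask voxels (identity included).  The same parametric forming
    threshold is applied to the observed and each permuted map; the FWE p
    of an observed cluster is the proportion of permutations whose largest
    cluster is at least as big.
    """
    structure = _connectivity_structure(connectivity)
    thr = forming_threshold(kind, forming_p, X, lam)
    labels, n_clus = _label_clusters(stat_map, mask, thr, structure)

    m = perm_stat_maps.shape[0]
    max_size = np.zeros(m, dtype=int)
    for b in range(m):
        vol = np.zeros(mask.shape)
        vol[mask] = perm_stat_maps[b]
        lab_b, n_b = ndimage.label((vol > thr) & mask, structure=structure)
        if n_b:
            max_size[b] = int(np.bincount(lab_b.ravel())[1:].max())

    rows = []
    for cid in range(1, n_clus + 1):
        in_c = labels == cid
        size = int(in_c.sum())
        peak = float(np.nanmax(np.where(in_c, stat_map, -np.inf)))
        p_fwe = float(np.count_nonzero(max_size >= size)) / m
        rows.append((cid, size, peak, max(p_fwe, 1.0 / m)))
    table = pd.DataFrame(rows, columns=["cluster_id", "size", "peak_stat", "p_fwe"])
    return ClusterTable(
        table=table,
        threshold=thr,
        forming_p=forming_p,
        connectivity=connectivity,
        max_size_null=max_size,
    )


def fdr_bh(p_values: np.ndarray, alpha: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone in the p-value rank)."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        return np.array([])
    return multipletests(p, alpha=alpha, method="fdr_bh")[1]


def inverse_normal_transform(values: np.ndarray, offset: float = 3.0 / 8.0) -> np.ndarray:
    """Rank-based inverse-normal scores with the Blom offset.

    score_i = Phi^-1((r_i - 3/8) / (N + 1/4)) with average ranks for ties.
    Preserves ranks and yields an approximately standard-normal margin.
    """
    values = np.asarray(values, float).ravel()
    n = values.size
    if n < 2:
        raise ValueError("need at least two values")
    if np.ptp(values) == 0:
        raise ValueError("all values identical; transform degenerate")
    ranks = sps.rankdata(values, method="average")
    return sps.norm.ppf((ranks - offset) / (n + 1.0 - 2.0 * offset))


# ---------------------------------------------------------------------------
# NIfTI I/O (nibabel)
# ---------------------------------------------------------------------------


def read_image_stack(stack_path, mask_path, sidecar_path=None, subject_ids=None) -> ImageStack:
    """Load a 4-D NIfTI stack and 3-D mask; order subjects by a sidecar CSV.

    The sidecar has columns ``volume,id`` mapping 4th-dimension index to
    subject id.  Grid or affine mismatch between stack and mask raises.
    """
    import nibabel as nib

    img = nib.load(str(stack_path))
    msk = nib.load(str(mask_path))
    data = np.asarray(img.dataobj, dtype=float)
    mask = np.asarray(msk.dataobj) > 0
    if mask.shape != data.shape[:3] or not np.allclose(img.affine, msk.affine, atol=1e-5):
        raise ValueError("mask grid/affine does not match the stack")
    ids = None
    if sidecar_path is not None:
        side = pd.read_csv(sidecar_path)
        if not {"volume", "id"} <= set(side.columns):
            raise ValueError("sidecar needs columns volume,id")
        side = side.sort_values("volume")
        if len(side) != data.shape[3]:
            raise ValueError("sidecar row count does not match stack volumes")
        ids = [str(s) for s in side["id"]]
    if subject_ids is not None and ids is not None:
        missing = set(subject_ids) - set(ids)
        if missing:
            raise KeyError(f"subjects missing from sidecar: {sorted(missing)}")
        order = [ids.index(s) for s in subject_ids]
        data = data[..., order]
        ids = list(subject_ids)
    return ImageStack(data=data, mask=mask, affine=img.affine, subject_ids=ids)


def write_stat_image(stat: StatImage, outdir, prefix: str = "kinherit") -> list[str]:
    """Write each result map as a 3-D NIfTI preserving the input affine."""
    import json
    import os

    import nibabel as nib

    os.makedirs(outdir, exist_ok=True)
    written = []
    for name, vol in stat.maps.items():
        path = os.path.join(outdir, f"{prefix}_{name}.nii.gz")
        nib.save(nib.Nifti1Image(np.asarray(vol, np.float32), stat.affine), path)
        written.append(path)
    if stat.clusters is not None:
        path = os.path.join(outdir, f"{prefix}_clusters.tsv")
        stat.clusters.table.to_csv(path, sep="\t", index=False)
        written.append(path)
    meta_path = os.path.join(outdir, f"{prefix}_run.json")
    with open(meta_path, "w") as fh:
        json.dump(stat.metadata, fh, indent=2, default=str)
    written.append(meta_path)
    return written
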