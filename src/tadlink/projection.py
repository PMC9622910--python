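"""Projection of disease expression profiles onto a normal reference.

Profiles are rank-normalised per sample (highest expression = highest rank),
PCA is fit on the reference (normal) samples only and the query (leukemic)
samples are projected with the reference eigenvectors.  Distances between
query and reference profiles are Manhattan distances in rank space,
median-centred per query; a SAM over reference samples (features) with query
groups as the two classes finds reference profiles significantly closer to /
further from one group, followed by per-cell-type hypergeometric enrichment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.spatial.distance import cdist
from sklearn.decomposition import PCA

from .errors import DesignError
from .samstat import SamResult, sam_two_class
from .stats import bh_fdr, hypergeom_enrichment

LINEAGE_MAP = {
    "B": "lymphoid", "T": "lymphoid", "NK": "lymphoid", "NKT": "lymphoid",
    "Baso": "myeloid", "Dendritic": "myeloid", "Eosin": "myeloid",
    "Gran": "myeloid", "Mono": "myeloid",
    "Ery": "erythroid", "Mega": "erythroid",
    "CMP": "progenitor", "GMP": "progenitor", "MEP": "progenitor",
}


@dataclass
class ProjectionResult:
    loadings: np.ndarray  # components x genes, orthonormal rows
    reference_scores: pd.DataFrame  # sample x component
    query_scores: pd.DataFrame
    explained_variance_ratio: np.ndarray


@dataclass
class DistanceProfile:
    raw: pd.DataFrame  # reference x query Manhattan distances
    centered: pd.DataFrame  # per-query median = 0


def rank_normalize(X: pd.DataFrame) -> pd.DataFrame:
    """Per-sample (column) average ranks; the highest value gets the highest
    rank, ties get average ranks."""
    return pd.DataFrame(
        sps.rankdata(X.to_numpy(), axis=0), index=X.index, columns=X.columns
    )


def fit_and_project(
    reference: pd.DataFrame,
    query: pd.DataFrame,
    n_components: Optional[int] = None,
    variance_target: float = 0.8,
) -> ProjectionResult:
    """PCA fit on reference samples only; queries projected with the
    reference eigenvectors (centering uses reference gene means)."""
    if not reference.index.equals(query.index):
        raise ValueError("reference and query must share the same gene rows")
    max_dim = min(reference.shape[0], reference.shape[1])
    if n_components is not None and n_components > max_dim:
        raise ValueError(f"n_components {n_components} exceeds min dimension {max_dim}")
    pca = PCA(n_components=n_components if n_components is not None else max_dim)
    ref_scores = pca.fit_transform(reference.to_numpy().T)
    if n_components is None:
        k = int(np.searchsorted(np.cumsum(pca.explained_variance_ratio_), variance_target) + 1)
        k = min(k, ref_scores.shape[1])
    else:
        k = n_components
    loadings = pca.components_[:k]
    qry_scores = (query.to_numpy().T - pca.mean_) @ loadings.T
    cols = [f"PC{i+1}" for i in range(k)]
    return ProjectionResult(
        loadings=loadings,
        reference_scores=pd.DataFrame(ref_scores[:, :k], index=reference.columns, columns=cols),
        query_scores=pd.DataFrame(qry_scores, index=query.columns, columns=cols),
        explained_variance_ratio=pca.explained_variance_ratio_[:k],
    )


def distance_profile(reference: pd.DataFrame, query: pd.DataFrame) -> DistanceProfile:
    """Manhattan distances between every query and every reference profile
    (rank space), raw and per-query median-centred."""
    if not reference.index.equals(query.index):
        raise ValueError("reference and query must share the same gene rows")
    d = cdist(reference.to_numpy().T, query.to_numpy().T, metric="cityblock")
    raw = pd.DataFrame(d, index=reference.columns, columns=query.columns)
    centered = raw - raw.median(axis=0)
    return DistanceProfile(raw, centered)


def distance_sam_and_enrichment(
    profile: DistanceProfile,
    query_groups: pd.Series,
    reference_cell_types: pd.Series,
    n_perm: int = 5000,
    fdr_target: float = 0.05,
    seed: Optional[int] = 0,
) -> tuple[SamResult, pd.DataFrame]:
    """SAM on the centred distance matrix (reference samples are features,
    query samples the observations, two query groups the classes), then
    per-cell-type hypergeometric enrichment within each direction.

    Direction 'up' means larger distance in the second group (the reference
    sample is further from it); 'down' means closer."""
    groups = query_groups.loc[profile.centered.columns]
    classes = pd.unique(groups)
    if len(classes) != 2 or (groups.value_counts() < 2).any():
        raise DesignError("need two query groups with >= 2 samples each")
    res = sam_two_class(
        profile.centered, groups.to_numpy(), n_perm=n_perm,
        fdr_target=fdr_target, seed=seed,
    )
    types = reference_cell_types.loc[profile.centered.index]
    N = len(types)
    rows = []
    flagged = len(pd.unique(types.loc[res.significant.index])) < 2 if len(res.significant) else True
    for direction in ("up", "down"):
        members = res.significant.index[res.significant["direction"] == direction]
        n = len(members)
        if n == 0:
            continue
        for ct in pd.unique(types):
            K = int((types == ct).sum())
            obs = int((types.loc[members] == ct).sum())
            fold, p = hypergeom_enrichment(obs, N, K, n)
            rows.append(
                {
                    "direction": direction,
                    "cell_type": ct,
                    "observed": obs,
                    "n_direction": n,
                    "n_cell_type": K,
                    "fold": 0.0 if obs == 0 else fold,
                    "p": p,
                }
            )
    table = pd.DataFrame(
        rows,
        columns=["direction", "cell_type", "observed", "n_direction", "n_cell_type", "fold", "p"],
    )
    table["q"] = bh_fdr(table["p"].to_numpy()) if len(table) else []
    table.attrs["degenerate_cell_types"] = bool(flagged)
    return res, table


def nearest_reference_type(
    profile: DistanceProfile, reference_cell_types: pd.Series
) -> pd.Series:
    """Cell type of the Manhattan-nearest reference sample per query."""
    nearest = profile.raw.idxmin(axis=0)
    return nearest.map(reference_cell_types)
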