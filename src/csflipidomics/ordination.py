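"""PCA of normalized lipid profiles.

Samples (biological by default) are rows, lipids are columns.  The
decomposition is a full SVD (scikit-learn PCA) of the centered, optionally
unit-variance-scaled matrix, with a deterministic sign convention: the
largest-magnitude loading of each component is positive.  Missing cells are
mean-filled per lipid inside this stage only and never written back.

``select_component_pair`` reports which component, paired with PC1, best
separates two cohorts — a data-dependent choice that is scored (silhouette
on the component's scores) and reported rather than hard-coded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

from .normalization import NormalizedTable

log = logging.getLogger(__name__)


@dataclass
class PCAResult:
    """Scores (samples x components), loadings (lipids x components),
    explained variance ratios, and the column means removed by centering."""

    scores: pd.DataFrame
    loadings: pd.DataFrame
    explained_variance_ratio: np.ndarray
    column_means: pd.Series
    column_scales: pd.Series
    component_pair_plotted: tuple[int, int] = (1, 2)

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]

    def reconstruct(self) -> pd.DataFrame:
        """Back-project scores through loadings, undoing scaling/centering."""
        x = self.scores.to_numpy() @ self.loadings.to_numpy().T
        x = x * self.column_scales.to_numpy() + self.column_means.to_numpy()
        return pd.DataFrame(x, index=self.scores.index, columns=self.loadings.index)


def pca_profiles(
    table: NormalizedTable,
    center: bool = True,
    scale: bool = False,
    include_qc: bool = False,
    n_components: int | None = None,
) -> PCAResult:
    """PCA of the sample x lipid matrix of normalized values.

    Needs >= 3 samples and >= 2 lipids.  Missing cells are filled with the
    lipid's mean over the included samples (logged count).  Components are
    capped at min(n_samples - 1, n_lipids); at full rank the explained
    variance ratios sum to 1 and scores @ loadings.T reconstructs the input.
    """
    sample_ids = table.sample_ids() if include_qc else table.biological_ids
    if len(sample_ids) < 3:
        raise ValueError(f"PCA needs >= 3 samples, got {len(sample_ids)}")
    if table.n_compounds < 2:
        raise ValueError(f"PCA needs >= 2 lipids, got {table.n_compounds}")

    x = table.intensities[sample_ids].T.to_numpy(dtype=float)  # samples x lipids
    n_missing = int(np.isnan(x).sum())
    if n_missing:
        col_means = np.nanmean(x, axis=0)
        col_means = np.where(np.isfinite(col_means), col_means, 0.0)
        idx = np.nonzero(np.isnan(x))
        x[idx] = col_means[idx[1]]
        log.info("mean-filled %d missing cells for PCA (not written back)", n_missing)

    means = x.mean(axis=0) if center else np.zeros(x.shape[1])
    xc = x - means
    if scale:
        scales = xc.std(axis=0, ddof=1)
        scales = np.where(scales > 0, scales, 1.0)
    else:
        scales = np.ones(x.shape[1])
    xc = xc / scales

    max_rank = min(len(sample_ids) - 1, table.n_compounds)
    k = max_rank if n_components is None else min(n_components, max_rank)
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(xc)
    loadings = pca.components_.T  # lipids x components

    # deterministic sign: largest-magnitude loading positive per component
    for j in range(k):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1.0
            scores[:, j] *= -1.0

    comp_names = [f"PC{j + 1}" for j in range(k)]
    lipid_index = table.intensities.index
    return PCAResult(
        scores=pd.DataFrame(scores, index=pd.Index(sample_ids, name="sample_id"),
                            columns=comp_names),
        loadings=pd.DataFrame(loadings, index=lipid_index, columns=comp_names),
        explained_variance_ratio=pca.explained_variance_ratio_,
        column_means=pd.Series(means, index=lipid_index, name="mean"),
        column_scales=pd.Series(scales, index=lipid_index, name="scale"),
    )


@dataclass
class ComponentPairSelection:
    """Outcome of searching for the (1, k) pair that separates two cohorts."""

    pair: tuple[int, int]
    scores_by_k: dict[int, float] = field(default_factory=dict)
    thresholds_by_k: dict[int, float] = field(default_factory=dict)
    separating: bool = False


def select_component_pair(
    result: PCAResult,
    labels: pd.Series | None,
    max_k: int = 6,
    n_permutations: int = 200,
    alpha: float = 0.05,
    seed: int = 0,
) -> ComponentPairSelection:
    """Find k such that (PC1, PCk) best separates the labelled cohorts.

    The separation score per component k is the silhouette of the cohort
    labels on that component's scores.  Raw silhouettes have no meaningful
    zero under random labels, so each component's score is compared with a
    permutation baseline: the (1 - alpha / n_candidates) quantile of the
    silhouette under ``n_permutations`` random relabelings (Bonferroni over
    the candidate components).  If no component beats its baseline the
    selection is flagged non-separating and the default display pair (1, 2)
    is returned, likewise when fewer than two labelled cohorts are present.
    """
    default = ComponentPairSelection(pair=(1, 2))
    if result.n_components < 2:
        raise ValueError("need >= 2 components to pick a display pair")
    if labels is None:
        log.info("no cohort labels; defaulting to component pair (1, 2)")
        return default
    lab = labels.loc[result.scores.index]
    classes = lab.dropna().unique()
    if len(classes) < 2 or lab.value_counts().min() < 2:
        log.info("fewer than two usable cohorts; defaulting to (1, 2)")
        return default

    lab_arr = lab.to_numpy()
    ks = list(range(2, min(max_k, result.n_components) + 1))
    rng = np.random.default_rng(seed)
    perms = [rng.permutation(lab_arr) for _ in range(n_permutations)]
    q = 1.0 - alpha / len(ks)

    scores_by_k: dict[int, float] = {}
    thresholds_by_k: dict[int, float] = {}
    for k in ks:
        comp = result.scores.iloc[:, k - 1].to_numpy().reshape(-1, 1)
        scores_by_k[k] = float(silhouette_score(comp, lab_arr))
        null = [silhouette_score(comp, p) for p in perms]
        thresholds_by_k[k] = float(np.quantile(null, q))

    margins = {k: scores_by_k[k] - thresholds_by_k[k] for k in ks}
    best_k = max(margins, key=margins.get)
    if margins[best_k] <= 0:
        log.info("no component separates the cohorts beyond chance (best "
                 "silhouette %.3f vs baseline %.3f at PC%d); defaulting to "
                 "(1, 2)", scores_by_k[best_k], thresholds_by_k[best_k], best_k)
        return ComponentPairSelection(pair=(1, 2), scores_by_k=scores_by_k,
                                      thresholds_by_k=thresholds_by_k,
                                      separating=False)
    log.info("component pair (1, %d) selected (silhouette %.3f > baseline %.3f)",
             best_k, scores_by_k[best_k], thresholds_by_k[best_k])
    return ComponentPairSelection(pair=(1, best_k), scores_by_k=scores_by_k,
                                  thresholds_by_k=thresholds_by_k,
                                  separating=True)
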