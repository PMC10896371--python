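"""Genetic-ancestry inference by reference-panel PCA projection.

A PCA basis is fitted to a labeled reference panel (variants standardized by
``sqrt(2 f (1-f))`` with allele frequency f taken from the reference), cohort
samples are projected onto it, and each sample is assigned the label of the
nearest population centroid in PC space — provided it falls within a
configurable radius of that population's own PC spread — otherwise it stays
``unassigned``.  Ancestry-specific PCs are then computed within each assigned
group and serve as model covariates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import GenotypeDosageMatrix

logger = logging.getLogger(__name__)

UNASSIGNED = "unassigned"
DEFAULT_GLOBAL_PCS = 10
DEFAULT_GROUP_PCS = 5
DEFAULT_RADIUS_SD = 6.0


@dataclass
class ReferencePCA:
    """Fitted reference basis: standardization constants, eigenvectors, and
    per-population centroids/spreads in PC space."""

    rsids: list[str]
    means: np.ndarray            # 2f per variant
    scales: np.ndarray           # sqrt(2 f (1-f))
    components: np.ndarray       # (k, p) right singular vectors
    reference_scores: np.ndarray
    reference_labels: list[str]
    centroids: dict[str, np.ndarray] = field(default_factory=dict)
    spreads: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def n_components(self) -> int:
        return self.components.shape[0]

    def project(self, geno: GenotypeDosageMatrix) -> np.ndarray:
        """Project a cohort onto the reference basis (by rsid; missing
        dosages mean-imputed at the reference frequency)."""
        idx = geno.variant_index(self.rsids)
        X = geno.dosages[:, idx]
        X = np.where(np.isnan(X), self.means[None, :], X)
        Z = (X - self.means[None, :]) / self.scales[None, :]
        return Z @ self.components.T


def fit_reference_pca(reference_panel: GenotypeDosageMatrix,
                      n_components: int = DEFAULT_GLOBAL_PCS) -> ReferencePCA:
    """Fit the top eigenvectors of the standardized reference covariance.

    Variants that are constant in the reference (zero standardization scale)
    are dropped with a logged notice.  ``n_components`` beyond the matrix
    rank raises.
    """
    if reference_panel.populations is None:
        raise ValueError("reference panel must carry population labels")
    f = reference_panel.allele_freq()
    scale = np.sqrt(2.0 * f * (1.0 - f))
    keep = scale > 1e-12
    if not keep.all():
        dropped = reference_panel.variants["rsid"].to_numpy()[~keep].tolist()
        logger.info("fit_reference_pca: dropping %d constant variant(s): %s",
                    len(dropped), dropped[:10])
    panel = reference_panel.take_variants(np.flatnonzero(keep))
    f, scale = f[keep], scale[keep]

    X = np.where(np.isnan(panel.dosages), (2 * f)[None, :], panel.dosages)
    Z = (X - (2 * f)[None, :]) / scale[None, :]
    rank = np.linalg.matrix_rank(Z)
    if n_components > min(panel.n_samples, panel.n_variants) or \
       n_components > rank:
        raise ValueError(
            f"n_components={n_components} exceeds rank {rank} of the "
            "standardized reference matrix")
    u, s, vt = np.linalg.svd(Z, full_matrices=False)
    components = vt[:n_components]
    scores = Z @ components.T

    pca = ReferencePCA(
        rsids=panel.variants["rsid"].tolist(),
        means=2 * f, scales=scale, components=components,
        reference_scores=scores,
        reference_labels=list(panel.populations))
    labels = np.asarray(panel.populations)
    for lab in sorted(set(panel.populations)):
        sub = scores[labels == lab]
        pca.centroids[lab] = sub.mean(axis=0)
        spread = sub.std(axis=0)
        spread[spread < 1e-12] = 1e-12
        pca.spreads[lab] = spread
    return pca


def assign_gia(sample_scores: np.ndarray, pca: ReferencePCA,
               radius_sd: float = DEFAULT_RADIUS_SD, n_pcs: int | None = None,
               ) -> tuple[list[str], list[bool]]:
    """Label each projected sample by its nearest population centroid.

    Distance is the RMS of per-PC deviations scaled by that population's own
    PC spread (a diagonal Mahalanobis distance).  Samples farther than
    ``radius_sd`` from every centroid are ``unassigned``.  Exact distance
    ties are broken toward the lexicographically smaller label and flagged.

    Returns ``(labels, tie_flags)``.
    """
    k = n_pcs or pca.n_components
    labels_sorted = sorted(pca.centroids)
    scores = np.atleast_2d(sample_scores)[:, :k]
    dists = np.empty((len(scores), len(labels_sorted)))
    for j, lab in enumerate(labels_sorted):
        z = (scores - pca.centroids[lab][None, :k]) / pca.spreads[lab][None, :k]
        dists[:, j] = np.sqrt((z ** 2).mean(axis=1))
    best = dists.argmin(axis=1)  # argmin takes the first = lexicographic min
    ties = [bool((np.isclose(d, d[b])).sum() > 1)
            for d, b in zip(dists, best)]
    labels = [labels_sorted[b] if dists[i, b] <= radius_sd else UNASSIGNED
              for i, b in enumerate(best)]
    return labels, ties


def compute_group_pcs(geno: GenotypeDosageMatrix,
                      n_components: int = DEFAULT_GROUP_PCS,
                      group_label: str = "") -> np.ndarray:
    """Within-group PCs: zero-mean, mutually orthogonal score columns for the
    samples of one genetically inferred ancestry group."""
    if geno.n_samples < n_components + 1:
        raise ValueError(
            f"group {group_label or '<unnamed>'} has {geno.n_samples} "
            f"samples; needs >= {n_components + 1} for {n_components} PCs")
    X = np.where(np.isnan(geno.dosages),
                 np.nanmean(geno.dosages, axis=0, keepdims=True),
                 geno.dosages)
    X = X - X.mean(axis=0)
    u, s, _ = np.linalg.svd(X, full_matrices=False)
    return u[:, :n_components] * s[:n_components]


@dataclass
class AncestryProfile:
    """Per-sample ancestry results: GIA label, global PC coordinates, and
    within-group PC coordinates (NaN for unassigned samples)."""

    samples: list[str]
    gia_labels: list[str]
    global_pcs: np.ndarray
    group_pcs: np.ndarray
    tie_flags: list[bool]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"sample_id": self.samples,
                           "gia_label": self.gia_labels})
        for j in range(self.global_pcs.shape[1]):
            df[f"PC{j + 1}"] = self.global_pcs[:, j]
        for j in range(self.group_pcs.shape[1]):
            df[f"groupPC{j + 1}"] = self.group_pcs[:, j]
        return df


def profile_cohort(cohort: GenotypeDosageMatrix,
                   reference_panel: GenotypeDosageMatrix,
                   n_global: int = DEFAULT_GLOBAL_PCS,
                   n_group: int = DEFAULT_GROUP_PCS,
                   radius_sd: float = DEFAULT_RADIUS_SD,
                   min_group_size: int | None = None) -> AncestryProfile:
    """Full ancestry workflow: fit reference PCA, project, assign GIA, and
    compute within-group PCs for every group large enough to support them."""
    pca = fit_reference_pca(reference_panel, n_global)
    scores = pca.project(cohort)
    labels, ties = assign_gia(scores, pca, radius_sd=radius_sd)
    min_size = min_group_size if min_group_size is not None else n_group + 1
    group_pcs = np.full((cohort.n_samples, n_group), np.nan)
    lab_arr = np.asarray(labels)
    for lab in sorted(set(labels) - {UNASSIGNED}):
        idx = np.flatnonzero(lab_arr == lab)
        if len(idx) < min_size:
            logger.info("group %s too small (%d) for within-group PCs",
                        lab, len(idx))
            continue
        group_pcs[idx] = compute_group_pcs(
            cohort.take_samples(idx), n_group, group_label=lab)
    return AncestryProfile(list(cohort.samples), labels, scores,
                           group_pcs, ties)
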