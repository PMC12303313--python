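"""Chemodiversity (Shannon index) per sample origin and PCA ordination.

H' is computed in nats on pooled replicate presence vectors (union pooling by
default, so H' = ln(richness) for binary input); PCA is the SVD of the
centered log-intensity matrix with a deterministic sign convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA as _SkPCA

from .errors import DegenerateDataError, ValidationError
from .preprocess import PresenceMatrix
from .tables_io import PhenoData


@dataclass
class DiversityResult:
    species: str
    compartment: str
    culture: str
    h_prime: float
    richness: int


@dataclass
class PcaResult:
    scores: pd.DataFrame            # sample x component
    loadings: pd.DataFrame          # feature x component
    explained_fraction: np.ndarray  # per component, non-increasing
    centered: bool
    scaled: bool


def shannon_index(weights, base: float = np.e) -> float:
    """Shannon diversity H' = -sum p_i log p_i over positive entries (nats by default)."""
    w = np.asarray(weights, dtype=float)
    if (w < 0).any():
        raise ValidationError("weights must be non-negative")
    w = w[w > 0]
    if w.size == 0:
        raise DegenerateDataError("all-zero weight vector has no diversity")
    return float(stats.entropy(w, base=base))


def group_diversity(
    presence: PresenceMatrix,
    pheno: PhenoData,
    pooling: str = "union",
    base: float = np.e,
) -> list[DiversityResult]:
    """H' per sample origin (species, compartment, culture).

    ``union`` pools replicates by presence-in-any-replicate and takes H' of
    the pooled binary vector (= ln richness); ``mean`` averages the
    per-replicate H' values instead.  Empty groups are skipped with a warning.
    """
    if pooling not in {"union", "mean"}:
        raise ValueError(f"pooling must be 'union' or 'mean', got {pooling!r}")
    results = []
    ph = pheno.table
    groups = ph[ph["species"] != "BLANK"].groupby(
        ["species", "compartment", "culture"], sort=True
    )
    for (sp, comp, cult), sub in groups:
        cols = [s for s in sub.index if s in presence.matrix.columns]
        if not cols:
            warnings.warn(f"empty group ({sp}, {comp}, {cult}); skipped", stacklevel=2)
            continue
        block = presence.matrix[cols]
        pooled = block.max(axis=1)
        richness = int((pooled > 0).sum())
        if richness == 0:
            warnings.warn(f"group ({sp}, {comp}, {cult}) has no present features; skipped",
                          stacklevel=2)
            continue
        if pooling == "union":
            h = shannon_index(pooled.to_numpy(), base=base)
        else:
            h = float(np.mean([
                shannon_index(block[c].to_numpy(), base=base)
                for c in cols if block[c].sum() > 0
            ]))
        results.append(DiversityResult(sp, comp, cult, h_prime=h, richness=richness))
    return results


def diversity_frame(results: list[DiversityResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"species": r.species, "compartment": r.compartment, "culture": r.culture,
          "H_prime": r.h_prime, "richness": r.richness} for r in results]
    )


def pca(
    matrix: pd.DataFrame,
    center: bool = True,
    scale: bool = False,
    n_components: int | None = None,
) -> PcaResult:
    """PCA of a sample x feature matrix (centered, unscaled by default).

    Component signs are fixed by making each component's largest-magnitude
    loading positive, so results are deterministic across runs and libraries.
    """
    X = matrix.to_numpy(dtype=float)
    n, p = X.shape
    if n < 2:
        raise ValidationError("PCA needs at least 2 samples")
    max_comp = min(n - 1, p)
    if n_components is None:
        n_components = max_comp
    if n_components > max_comp:
        raise ValidationError(
            f"n_components={n_components} exceeds min(n_samples-1, n_features)={max_comp}"
        )
    work = X.copy()
    if scale:
        sd = work.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        work = work / sd
    if not center:
        # sklearn always centers; emulate uncentered PCA via plain SVD
        u, s, vt = np.linalg.svd(work, full_matrices=False)
        scores = u[:, :n_components] * s[:n_components]
        load = vt[:n_components].T
        total = float((work ** 2).sum())
        expl = (s[:n_components] ** 2) / total if total > 0 else np.zeros(n_components)
    else:
        model = _SkPCA(n_components=n_components, svd_solver="full")
        scores = model.fit_transform(work)
        load = model.components_.T
        expl = model.explained_variance_ratio_.copy()
    # sign convention: largest-|loading| entry positive per component
    for j in range(load.shape[1]):
        k = int(np.argmax(np.abs(load[:, j])))
        if load[k, j] < 0:
            load[:, j] *= -1
            scores[:, j] *= -1
    comp_names = [f"PC{i + 1}" for i in range(n_components)]
    return PcaResult(
        scores=pd.DataFrame(scores, index=matrix.index, columns=comp_names),
        loadings=pd.DataFrame(load, index=matrix.columns, columns=comp_names),
        explained_fraction=np.asarray(expl, dtype=float),
        centered=center,
        scaled=scale,
    )
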