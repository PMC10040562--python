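"""Replicate reproducibility checks: shared CG sites and sample-level PCA.

Samples are compared on the per-site methylation frequencies of cytosines
covered in *every* methylome, so no imputation is needed.  The PCA centers
each site (column) but applies no variance scaling — frequencies already
share the [0, 1] scale — and uses the deterministic full SVD solver.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd

from .io import MethylomeSample


@dataclass
class SharedSiteMatrix:
    """samples x shared-sites matrix of methylation frequencies."""

    sample_labels: List[str]
    sites: pd.DataFrame  # columns chrom, pos, strand
    matrix: np.ndarray   # shape (n_samples, n_sites), values in [0, 1]


def shared_sites(samples: Sequence[MethylomeSample], context: str = "CG",
                 min_coverage: int = 1) -> SharedSiteMatrix:
    """Site-frequency matrix over sites covered in every sample.

    Columns are exactly the (chrom, pos, strand) cytosines of the requested
    context with coverage >= ``min_coverage`` in all samples.
    """
    if len(samples) < 2:
        raise ValueError("need at least two samples")
    freqs = []
    for s in samples:
        sub = s.subset_context(context)
        cov = sub["count_meth"] + sub["count_unmeth"]
        sub = sub[cov >= min_coverage]
        f = pd.DataFrame({
            "chrom": sub["chrom"].to_numpy(),
            "pos": sub["pos"].to_numpy(),
            "strand": sub["strand"].to_numpy(),
            s.label: (sub["count_meth"]
                      / (sub["count_meth"] + sub["count_unmeth"])).to_numpy(),
        }).set_index(["chrom", "pos", "strand"])
        freqs.append(f)
    joined = pd.concat(freqs, axis=1, join="inner")
    if joined.empty:
        counts = ", ".join(f"{s.label}: {len(f)}"
                           for s, f in zip(samples, freqs))
        raise ValueError(
            f"no {context} site covered in all samples (per-sample covered "
            f"site counts: {counts})")
    labels = [s.label for s in samples]
    sites = joined.index.to_frame(index=False)
    return SharedSiteMatrix(sample_labels=labels, sites=sites,
                            matrix=joined.to_numpy().T)


@dataclass
class PcaResult:
    """Per-sample PCA coordinates and variance-explained fractions."""

    sample_labels: List[str]
    coordinates: np.ndarray        # (n_samples, n_components)
    variance_fractions: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.coordinates,
            columns=[f"PC{i + 1}" for i in
                     range(self.coordinates.shape[1])])
        df.insert(0, "sample", self.sample_labels)
        return df


def pca_samples(matrix: SharedSiteMatrix,
                n_components: int = 2) -> PcaResult:
    """PCA of samples over shared sites (centered, unscaled).

    The sign of each component is fixed by making its largest-magnitude
    loading positive, so results are reproducible across runs.
    """
    from sklearn.decomposition import PCA

    n_samples = matrix.matrix.shape[0]
    if n_components >= n_samples:
        raise ValueError("n_components must be < number of samples")
    x = matrix.matrix
    if np.allclose(x, x[0]):
        return PcaResult(sample_labels=list(matrix.sample_labels),
                         coordinates=np.zeros((n_samples, n_components)),
                         variance_fractions=np.zeros(n_components))
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(x)
    # deterministic sign: largest |loading| of each component positive
    for i in range(n_components):
        j = int(np.argmax(np.abs(pca.components_[i])))
        if pca.components_[i, j] < 0:
            pca.components_[i] *= -1
            coords[:, i] *= -1
    return PcaResult(sample_labels=list(matrix.sample_labels),
                     coordinates=coords,
                     variance_fractions=pca.explained_variance_ratio_.copy())
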