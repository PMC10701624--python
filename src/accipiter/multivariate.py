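"""PCA over per-element measurement matrices.

Used to ask which osteometric code drives size variation within an element.
Complete-case specimens only (no imputation); default scaling is the
covariance matrix on raw mm — the claim "greatest length drives variation"
is about absolute variance — with a correlation-matrix mode for
scale-free loadings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io import resolve_paired_elements


@dataclass
class PCAResult:
    """Eigendecomposition of an element's measurement matrix.

    ``loadings`` is a codes x components DataFrame with unit-norm columns;
    the sign convention makes each component's largest-magnitude loading
    positive, so results are deterministic.  ``explained_fraction`` is
    non-increasing and sums to 1 over all components.
    """

    loadings: pd.DataFrame
    explained_fraction: np.ndarray
    scores: pd.DataFrame
    n_complete: int
    scaling: str

    def dominant_loading(self) -> str:
        """Code with the largest |loading| on the first component.

        Exact ties are broken alphabetically, with a warning.
        """
        pc1 = self.loadings.iloc[:, 0].abs()
        top = pc1.max()
        tied = sorted(pc1.index[np.isclose(pc1.to_numpy(), top, rtol=0, atol=1e-12)])
        if len(tied) > 1:
            warnings.warn(
                f"tied dominant loadings {tied}; alphabetical winner {tied[0]!r} reported",
                stacklevel=2,
            )
        return tied[0]


def complete_case_matrix(
    records: pd.DataFrame,
    element: str,
    codes: Sequence[str],
    side_policy: str = "prefer_left",
) -> pd.DataFrame:
    """Specimen x code wide matrix for one element, complete cases only."""
    df = resolve_paired_elements(records, policy=side_policy)
    df = df[(df["element"] == element) & df["measurement_code"].isin(codes)]
    wide = df.pivot(index="specimen_id", columns="measurement_code", values="value_mm")
    wide = wide.reindex(columns=list(codes)).dropna()
    return wide


def pca_element(
    records: pd.DataFrame,
    element: str,
    codes: Sequence[str],
    scaling: str = "covariance",
    side_policy: str = "prefer_left",
) -> PCAResult:
    """PCA of one element's measurements over complete-case specimens.

    Parameters
    ----------
    scaling
        ``"covariance"`` (raw mm; default) or ``"correlation"``
        (standardised variables).

    Raises
    ------
    ValueError
        With fewer than 2 codes or fewer than 3 complete cases.
    """
    codes = list(codes)
    if len(codes) < 2:
        raise ValueError("PCA needs at least 2 measurement codes")
    if scaling not in ("covariance", "correlation"):
        raise ValueError(f"unknown scaling {scaling!r}")
    wide = complete_case_matrix(records, element, codes, side_policy=side_policy)
    if len(wide) < 3:
        raise ValueError(
            f"insufficient complete cases for {element} PCA: {len(wide)} < 3"
        )
    X = wide.to_numpy(dtype=float)
    Xc = X - X.mean(axis=0)
    if scaling == "correlation":
        sd = X.std(axis=0, ddof=1)
        if np.any(sd == 0):
            zero = [c for c, s in zip(codes, sd) if s == 0]
            raise ValueError(f"constant column(s) under correlation scaling: {zero}")
        Xc = Xc / sd
        S = np.corrcoef(X, rowvar=False)
    else:
        S = np.cov(X, rowvar=False)

    evals, evecs = np.linalg.eigh(S)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    # deterministic sign: largest-|loading| entry of each component positive
    for j in range(evecs.shape[1]):
        i = int(np.argmax(np.abs(evecs[:, j])))
        if evecs[i, j] < 0:
            evecs[:, j] = -evecs[:, j]

    comp_names = [f"PC{j + 1}" for j in range(evecs.shape[1])]
    loadings = pd.DataFrame(evecs, index=codes, columns=comp_names)
    total = evals.sum()
    explained = evals / total if total > 0 else np.zeros_like(evals)
    scores = pd.DataFrame(Xc @ evecs, index=wide.index, columns=comp_names)
    return PCAResult(
        loadings=loadings,
        explained_fraction=explained,
        scores=scores,
        n_complete=len(wide),
        scaling=scaling,
    )


def dominant_loading(result: PCAResult) -> str:
    """Functional alias for :meth:`PCAResult.dominant_loading`."""
    return result.dominant_loading()
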