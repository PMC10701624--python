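"""Fisher's permutation test for the difference of group means.

The statistic is mean(group_a) - mean(group_b).  Under the null the group
labels are exchangeable, so the null distribution is obtained by repeatedly
repartitioning the pooled values into groups of the original sizes — sampling
without replacement within each relabelling.  When the number of distinct
partitions C(n_a + n_b, n_a) is small the test enumerates them all and the
p-value is exact (a rational with that denominator); otherwise B random
relabellings are drawn and the two-sided Monte-Carlo p-value uses the add-one
convention (b + 1) / (B + 1), which cannot report p = 0.

The "95% interval" of the null is the empirical 2.5 and 97.5 percentile of
the null differences (linear-interpolation definition); ``outside_interval``
flags an observed difference falling outside it, mirroring the
observed-line-vs-histogram reading of a permutation plot.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field
from itertools import combinations
from math import comb
from typing import Sequence

import numpy as np
import pandas as pd

from .io import resolve_paired_elements

#: Switch to exhaustive enumeration when the partition count is at most this.
DEFAULT_EXACT_CAP = 200_000

_TIE_EPS = 1e-9  # relative tolerance when comparing |null| with |observed|


@dataclass
class PermutationResult:
    """Observed difference, null-distribution summaries and p-value.

    ``observed_diff`` is mean(group_a) - mean(group_b) in mm; for the
    Medieval comparison group_a is the modern sample, so a negative value
    means moderns are smaller.
    """

    observed_diff: float
    n_a: int
    n_b: int
    B: int  # partitions evaluated (C(n, n_a) when exhaustive)
    p_two_sided: float
    null_q025: float
    null_q975: float
    outside_interval: bool
    method: str  # "monte_carlo" | "exhaustive"
    seed: int | None = None
    null_diffs: np.ndarray | None = field(default=None, repr=False)

    def summary(self) -> str:
        return (
            f"obs diff = {self.observed_diff:+.3f} mm  (n = {self.n_a} vs {self.n_b})\n"
            f"null 95% interval [{self.null_q025:+.3f}, {self.null_q975:+.3f}]  "
            f"{'OUTSIDE' if self.outside_interval else 'inside'}\n"
            f"p (two-sided) = {self.p_two_sided:.4g}   method = {self.method}, B = {self.B}"
        )

    def histogram(self, bins: int = 30) -> pd.DataFrame:
        """Null-distribution histogram (bin edges and counts) for plotting."""
        if self.null_diffs is None:
            raise ValueError("null distribution was not retained")
        counts, edges = np.histogram(self.null_diffs, bins=bins)
        return pd.DataFrame(
            {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
        )


def _finalise(
    observed: float,
    null: np.ndarray,
    n_a: int,
    n_b: int,
    method: str,
    seed: int | None,
    keep_null: bool,
) -> PermutationResult:
    scale = max(abs(observed), float(np.max(np.abs(null))) if null.size else 0.0, 1.0)
    extreme = int(np.sum(np.abs(null) >= abs(observed) - _TIE_EPS * scale))
    B = int(null.size)
    if method == "exhaustive":
        p = extreme / B
    else:
        p = (extreme + 1) / (B + 1)
    q025, q975 = np.percentile(null, [2.5, 97.5])
    return PermutationResult(
        observed_diff=float(observed),
        n_a=n_a,
        n_b=n_b,
        B=B,
        p_two_sided=float(p),
        null_q025=float(q025),
        null_q975=float(q975),
        outside_interval=bool(observed < q025 or observed > q975),
        method=method,
        seed=seed,
        null_diffs=null if keep_null else None,
    )


def enumerate_exact(group_a, group_b, keep_null: bool = True,
                    cap: int = DEFAULT_EXACT_CAP) -> PermutationResult:
    """Exact permutation test over every distinct partition of the pooled data.

    Deterministic; the p-value is the fraction of partitions with
    |null difference| >= |observed difference| (the observed partition itself
    is among them, so p >= 1 / C(n, n_a)).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    n_a, n = a.size, a.size + b.size
    total_partitions = comb(n, n_a)
    if total_partitions > cap:
        raise ValueError(
            f"C({n}, {n_a}) = {total_partitions} partitions exceeds cap {cap}"
        )
    pooled = np.concatenate([a, b])
    total = pooled.sum()
    observed = a.mean() - b.mean()
    null = np.empty(total_partitions)
    for i, idx in enumerate(combinations(range(n), n_a)):
        s = pooled[list(idx)].sum()
        null[i] = s / n_a - (total - s) / (n - n_a)
    return _finalise(observed, null, n_a, b.size, "exhaustive", None, keep_null)


def permutation_test(
    group_a,
    group_b,
    B: int = 10_000,
    seed: int | None = None,
    method: str = "auto",
    exact_cap: int = DEFAULT_EXACT_CAP,
    keep_null: bool = True,
) -> PermutationResult:
    """Two-sample permutation test of the difference of means.

    Parameters
    ----------
    B
        Number of random relabellings for the Monte-Carlo path.
    method
        ``"auto"`` (exhaustive when C(n, n_a) <= ``exact_cap``, else
        Monte-Carlo), ``"monte_carlo"`` or ``"exhaustive"``.
    seed
        Seeds the Monte-Carlo path; a fixed seed gives a bitwise-identical
        result.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if method not in ("auto", "monte_carlo", "exhaustive"):
        raise ValueError(f"unknown method {method!r}")
    if method == "exhaustive" or (
        method == "auto" and comb(a.size + b.size, a.size) <= exact_cap
    ):
        return enumerate_exact(a, b, keep_null=keep_null, cap=exact_cap)
    if B < 1:
        raise ValueError("B must be >= 1")

    n_a, n = a.size, a.size + b.size
    pooled = np.concatenate([a, b])
    total = pooled.sum()
    observed = a.mean() - b.mean()
    rng = np.random.default_rng(seed)
    # vectorised random partitions: argsort of uniform keys = uniform shuffle
    keys = rng.random((B, n))
    idx = np.argsort(keys, axis=1)[:, :n_a]
    sums_a = pooled[idx].sum(axis=1)
    null = sums_a / n_a - (total - sums_a) / (n - n_a)
    return _finalise(observed, null, n_a, b.size, "monte_carlo", seed, keep_null)


def cell_seed(seed: int | None, cell_id: str) -> int | None:
    """Stable per-cell seed derived from a base seed and a cell label.

    Uses a CRC of the label (not Python's randomised ``hash``) so per-cell
    streams are independent and reproducible across runs.
    """
    if seed is None:
        return None
    mixed = np.random.SeedSequence([int(seed), zlib.crc32(cell_id.encode())])
    return int(mixed.generate_state(1, np.uint32)[0])


def run_all_elements(
    records: pd.DataFrame,
    elements: Sequence[str],
    B: int = 10_000,
    seed: int | None = None,
    code: str = "GL",
    side_policy: str = "prefer_left",
    sex_column: str = "sex_assigned",
    modern_groups: Sequence[str] | None = None,
    method: str = "auto",
) -> pd.DataFrame:
    """Permutation tests of modern vs Medieval means, per (sex, element).

    ``group_a`` is the modern sample and ``group_b`` the Medieval one, so
    observed differences are mean(modern) - mean(Medieval).  Cells missing
    either period (e.g. no Medieval male tibiotarsi) are skipped with a
    warning.  ``modern_groups`` optionally restricts the modern side to given
    population groups (requires a ``group`` column).
    """
    df = resolve_paired_elements(records, policy=side_policy)
    df = df[(df["measurement_code"] == code) & df[sex_column].isin(["F", "M"])]
    if modern_groups is not None:
        df = df[(df["period"] != "modern") | df["group"].isin(list(modern_groups))]
    rows = []
    for sex in ("F", "M"):
        for element in elements:
            sub = df[(df[sex_column] == sex) & (df["element"] == element)]
            modern = sub.loc[sub["period"] == "modern", "value_mm"].to_numpy(dtype=float)
            medieval = sub.loc[sub["period"] == "medieval", "value_mm"].to_numpy(dtype=float)
            if modern.size == 0 or medieval.size == 0:
                warnings.warn(
                    f"skipping ({sex}, {element}): missing a period "
                    f"(modern n={modern.size}, medieval n={medieval.size})",
                    stacklevel=2,
                )
                continue
            res = permutation_test(
                modern,
                medieval,
                B=B,
                seed=cell_seed(seed, f"{sex}:{element}"),
                method=method,
                keep_null=False,
            )
            rows.append(
                {
                    "sex": sex,
                    "element": element,
                    "n_modern": res.n_a,
                    "n_medieval": res.n_b,
                    "observed_diff": res.observed_diff,
                    "p_two_sided": res.p_two_sided,
                    "null_q025": res.null_q025,
                    "null_q975": res.null_q975,
                    "outside_interval": res.outside_interval,
                    "method": res.method,
                    "B": res.B,
                    "seed": res.seed,
                }
            )
    return pd.DataFrame(rows)
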