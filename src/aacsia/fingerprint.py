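"""Carbon-source fingerprinting on essential amino-acid δ13C.

Essential amino acids cannot be synthesized by animals, so their carbon
skeletons — and δ13C values — pass from primary producer to consumer with
negligible trophic fractionation. The joint δ13C pattern over {Val, Leu, Ile,
Met, Phe} therefore fingerprints the carbon source. This module builds the
samples × amino-acids matrix, ordinates it (PCA), and tests group differences
with a permutational multivariate ANOVA (PERMANOVA) on Euclidean distances:

    pseudo-F = (SS_between / df_between) / (SS_within / df_within)

with significance from permuting group labels over samples, and
Benjamini–Hochberg adjustment across pairwise comparisons. A sequential
two-factor (additive) variant partitions variation into treatment then
fraction terms, permuting raw observations.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from .errors import FingerprintError, ValidationError
from .registry import ESSENTIAL_AAS
from .types import CorrectedSample, SampleMeta

logger = logging.getLogger(__name__)


@dataclass
class FingerprintMatrix:
    """Samples × five essential amino acids of corrected δ13C (no missing cells)."""

    metas: list[SampleMeta]
    values: np.ndarray  # shape (n_samples, 5), column order = columns
    columns: tuple[str, ...] = ESSENTIAL_AAS

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape != (
            len(self.metas),
            len(self.columns),
        ):
            raise ValidationError("fingerprint matrix shape does not match metadata")
        if not np.isfinite(self.values).all():
            raise ValidationError("fingerprint matrix contains non-finite values")
        if tuple(self.columns) != ESSENTIAL_AAS:
            raise ValidationError(f"columns must be exactly {ESSENTIAL_AAS}")

    def labels(self, key: str = "group") -> np.ndarray:
        return np.array([getattr(meta, key) for meta in self.metas])

    def to_dataframe(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.values, columns=list(self.columns))
        frame.insert(0, "sample_id", [m.sample_id for m in self.metas])
        frame.insert(1, "group", [m.group for m in self.metas])
        frame.insert(2, "fraction", [m.fraction for m in self.metas])
        return frame


@dataclass
class OrdinationResult:
    scores: np.ndarray  # samples × components
    loadings: np.ndarray  # amino acids × components (orthonormal columns)
    explained_variance_ratio: np.ndarray
    column_means: np.ndarray
    column_scales: np.ndarray


@dataclass
class PermanovaResult:
    term: str
    pseudo_f: float
    p_value: float
    n_permutations: int
    seed: int
    df_between: int
    df_within: int
    p_adjusted: float | None = None

    def __post_init__(self) -> None:
        if self.pseudo_f < 0:
            raise ValidationError("pseudo_f must be >= 0")
        if not 1.0 / (self.n_permutations + 1) <= self.p_value <= 1.0:
            raise ValidationError("p_value outside its attainable range")


def build_matrix(samples: list[CorrectedSample]) -> FingerprintMatrix:
    """Restrict corrected carbon samples to the essential set.

    Samples missing any essential amino acid are excluded with a logged
    reason; at least one complete sample must remain.
    """
    metas, rows = [], []
    for sample in samples:
        if sample.element != "C":
            raise FingerprintError(
                f"sample {sample.meta.sample_id} is not a carbon sample"
            )
        missing = [code for code in ESSENTIAL_AAS if code not in sample.delta]
        if missing:
            logger.warning(
                "sample %s excluded from fingerprint: missing %s",
                sample.meta.sample_id,
                missing,
            )
            continue
        metas.append(sample.meta)
        rows.append([sample.delta[code] for code in ESSENTIAL_AAS])
    if not rows:
        raise FingerprintError("no sample has complete essential-amino-acid coverage")
    return FingerprintMatrix(metas=metas, values=np.array(rows))


def run_pca(m: FingerprintMatrix, scale: bool = False) -> OrdinationResult:
    """Principal component analysis of the fingerprint matrix.

    Columns are mean-centered; with ``scale=True`` they are also divided by
    their standard deviation. All columns share ‰ units, so the unscaled
    decomposition is the default. At full rank
    ``scores @ loadings.T * scales + means`` reconstructs the data.
    """
    if len(m.metas) < 3:
        raise FingerprintError("PCA needs at least 3 samples")
    means = m.values.mean(axis=0)
    centered = m.values - means
    if np.allclose(centered, 0.0):
        raise FingerprintError("degenerate ordination: all samples identical")
    scales = np.ones(m.values.shape[1])
    if scale:
        scales = centered.std(axis=0, ddof=0)
        if np.any(scales == 0):
            raise FingerprintError("cannot unit-scale a constant column")
        centered = centered / scales
    pca = PCA()
    scores = pca.fit_transform(centered)
    return OrdinationResult(
        scores=scores,
        loadings=pca.components_.T,
        explained_variance_ratio=pca.explained_variance_ratio_,
        column_means=means,
        column_scales=scales,
    )


def _as_values(m: FingerprintMatrix | np.ndarray) -> np.ndarray:
    if isinstance(m, FingerprintMatrix):
        return m.values
    return np.asarray(m, dtype=float)


def _resolve_labels(
    m: FingerprintMatrix | np.ndarray,
    labels: Sequence[str] | None,
    group_key: str,
) -> np.ndarray:
    if labels is not None:
        return np.asarray(labels)
    if isinstance(m, FingerprintMatrix):
        return m.labels(group_key)
    raise ValidationError("labels are required when passing a bare array")


def pseudo_f_statistic(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    """One-way PERMANOVA pseudo-F from a squared-distance matrix and label codes."""
    n = len(codes)
    ss_total = d2.sum() / (2.0 * n)
    ss_within = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        ss_within += d2[np.ix_(idx, idx)].sum() / (2.0 * idx.size)
    ss_between = ss_total - ss_within
    df_between = n_groups - 1
    df_within = n - n_groups
    return (ss_between / df_between) / (ss_within / df_within)


def permanova(
    m: FingerprintMatrix | np.ndarray,
    labels: Sequence[str] | None = None,
    *,
    n_permutations: int = 9999,
    seed: int,
    group_key: str = "group",
    term: str | None = None,
) -> PermanovaResult:
    """One-way PERMANOVA on Euclidean distances with label permutation.

    p = (1 + #{permuted F ≥ observed F}) / (1 + n_permutations); ties count
    toward the numerator (conservative). Groups of a single sample proceed
    with a warning; a single group is an error.
    """
    values = _as_values(m)
    label_arr = _resolve_labels(m, labels, group_key)
    if len(label_arr) != len(values):
        raise ValidationError("labels length does not match sample count")
    if n_permutations < 99:
        raise ValidationError("use at least 99 permutations")
    uniques, codes = np.unique(label_arr, return_inverse=True)
    if len(uniques) < 2:
        raise FingerprintError("PERMANOVA needs at least 2 groups")
    sizes = np.bincount(codes)
    if (sizes == 1).any():
        logger.warning(
            "group(s) with a single sample: %s", list(uniques[sizes == 1])
        )

    d2 = squareform(pdist(values, metric="euclidean") ** 2)
    n, k = len(codes), len(uniques)
    f_obs = pseudo_f_statistic(d2, codes, k)

    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(codes) for _ in range(n_permutations)])
    ss_total = d2.sum() / (2.0 * n)
    ss_within = np.zeros(n_permutations)
    for g in range(k):
        mask = (perms == g).astype(float)
        ss_within += np.einsum("pi,ij,pj->p", mask, d2, mask) / (2.0 * sizes[g])
    f_perm = ((ss_total - ss_within) / (k - 1)) / (ss_within / (n - k))
    p = (1 + int((f_perm >= f_obs).sum())) / (1 + n_permutations)
    return PermanovaResult(
        term=term or group_key,
        pseudo_f=float(f_obs),
        p_value=float(p),
        n_permutations=n_permutations,
        seed=seed,
        df_between=k - 1,
        df_within=n - k,
    )


def pairwise_permanova(
    m: FingerprintMatrix | np.ndarray,
    labels: Sequence[str] | None = None,
    *,
    n_permutations: int = 9999,
    seed: int,
    group_key: str = "group",
) -> list[PermanovaResult]:
    """PERMANOVA on every pair of groups, BH-adjusted across pairs."""
    values = _as_values(m)
    label_arr = _resolve_labels(m, labels, group_key)
    uniques = sorted(set(label_arr))
    if len(uniques) < 2:
        raise FingerprintError("pairwise tests need at least 2 groups")
    seeds = np.random.SeedSequence(seed).spawn(
        len(list(itertools.combinations(uniques, 2)))
    )
    results = []
    for (a, b), ss in zip(itertools.combinations(uniques, 2), seeds):
        mask = np.isin(label_arr, (a, b))
        results.append(
            permanova(
                values[mask],
                label_arr[mask],
                n_permutations=n_permutations,
                seed=int(ss.generate_state(1)[0] % (2**31)),
                term=f"{a} vs {b}",
            )
        )
    adjusted = bh_adjust([r.p_value for r in results])
    for result, p_adj in zip(results, adjusted):
        result.p_adjusted = float(p_adj)
    return results


def _hat(design: np.ndarray) -> np.ndarray:
    q, _ = np.linalg.qr(design)
    return q @ q.T


def _dummy(labels: np.ndarray) -> np.ndarray:
    _, codes = np.unique(labels, return_inverse=True)
    return np.eye(codes.max() + 1)[codes]


def permanova_additive(
    m: FingerprintMatrix | np.ndarray,
    factor_a: Sequence[str] | None = None,
    factor_b: Sequence[str] | None = None,
    *,
    n_permutations: int = 9999,
    seed: int,
    keys: tuple[str, str] = ("group", "fraction"),
) -> list[PermanovaResult]:
    """Sequential two-factor PERMANOVA (factor A, then B given A).

    Partitions the Gower-centered squared-distance matrix by hat-matrix
    projections of the additive design, testing each term's F against the
    full-model residual with permutation of raw observations.
    """
    values = _as_values(m)
    a = _resolve_labels(m, factor_a, keys[0])
    b = _resolve_labels(m, factor_b, keys[1])
    n = len(values)
    d2 = squareform(pdist(values, metric="euclidean") ** 2)
    centerer = np.eye(n) - np.full((n, n), 1.0 / n)
    gower = centerer @ (-0.5 * d2) @ centerer

    intercept = np.ones((n, 1))
    x_a = np.hstack([intercept, _dummy(a)[:, 1:]])
    x_ab = np.hstack([x_a, _dummy(b)[:, 1:]])
    h_a, h_ab = _hat(x_a), _hat(x_ab)
    df_a = len(set(a)) - 1
    df_b = len(set(b)) - 1
    df_res = n - 1 - df_a - df_b
    if df_res < 1:
        raise FingerprintError("additive model leaves no residual degrees of freedom")

    def term_fs(g: np.ndarray) -> tuple[float, float]:
        ss_a = float(np.sum(h_a * g))  # tr(H_A G) for symmetric H
        ss_ab = float(np.sum(h_ab * g))
        ss_res = float(np.trace(g)) - ss_ab
        f_a = (ss_a / df_a) / (ss_res / df_res)
        f_b = ((ss_ab - ss_a) / df_b) / (ss_res / df_res)
        return f_a, f_b

    f_a_obs, f_b_obs = term_fs(gower)
    rng = np.random.default_rng(seed)
    count_a = count_b = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        g_perm = gower[np.ix_(perm, perm)]
        f_a, f_b = term_fs(g_perm)
        count_a += f_a >= f_a_obs
        count_b += f_b >= f_b_obs
    return [
        PermanovaResult(
            term=keys[0],
            pseudo_f=f_a_obs,
            p_value=(1 + count_a) / (1 + n_permutations),
            n_permutations=n_permutations,
            seed=seed,
            df_between=df_a,
            df_within=df_res,
        ),
        PermanovaResult(
            term=keys[1],
            pseudo_f=f_b_obs,
            p_value=(1 + count_b) / (1 + n_permutations),
            n_permutations=n_permutations,
            seed=seed,
            df_between=df_b,
            df_within=df_res,
        ),
    ]


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjustment, returned in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p <= 0) | (p > 1)):
        raise ValidationError("p-values must lie in (0, 1]")
    return list(multipletests(p, method="fdr_bh")[1])
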