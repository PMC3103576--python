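"""Statistical comparison of the D and O model estimates.

Homogeneity of two expected-count vectors (amino-acid counts or substitution
counts) is assessed with Pearson's chi-square and the G-test on the 2xC
table with pooled-margin expectations.  Component-wise uncertainty comes from
re-estimating the models on column-bootstrap and row-jackknife replicates.
"""

from __future__ import annotations

import logging
import warnings
import zlib
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .alignment import AnnotatedAlignment, bootstrap_columns, jackknife_rows
from .em import EMConfig, fit_do_model
from .substitution import (
    ClassPartition,
    ClassRateSummary,
    ReversibleModel,
    class_rate_statistics,
)
from .tree import Phylogeny

logger = logging.getLogger(__name__)

__all__ = [
    "CountComparison",
    "ComponentVariance",
    "homogeneity_tests",
    "resample_variance",
    "compare_class_ratios",
]


@dataclass(frozen=True)
class CountComparison:
    statistic: float
    df: int
    p_value: float
    test_name: str  # "pearson_chi2" or "g_test"


def _prepare_table(counts_a: np.ndarray, counts_b: np.ndarray):
    """2xC homogeneity table with sparse categories merged into a rest cell."""
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("count vectors must be 1-D and of equal length")
    if np.any(a < 0) or np.any(b < 0):
        raise ValueError("negative counts")
    if a.sum() <= 0 or b.sum() <= 0:
        raise ValueError("a count vector is all zero")
    pooled = a + b
    keep = pooled > 0  # cells empty in both drop out of df
    a, b, pooled = a[keep], b[keep], pooled[keep]
    # protect the chi-square approximation: expected < 1 goes to a rest cell
    N = a.sum() + b.sum()
    min_row = min(a.sum(), b.sum())
    expected_min = pooled * min_row / N
    sparse = expected_min < 1.0
    if sparse.sum() > 1:
        logger.info("merging %d sparse cells into a rest category", sparse.sum())
        a = np.append(a[~sparse], a[sparse].sum())
        b = np.append(b[~sparse], b[sparse].sum())
    return np.vstack([a, b])


def homogeneity_tests(
    counts_a: np.ndarray, counts_b: np.ndarray
) -> tuple[CountComparison, CountComparison]:
    """Pearson chi-square and G-test that two count vectors share one
    distribution.  Counts may be real-valued (EM expected counts are used
    directly, without rounding).  df = C - 1 after dropping/merging cells."""
    table = _prepare_table(counts_a, counts_b)
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    E = row @ col / table.sum()
    df = table.shape[1] - 1
    x2 = float(((table - E) ** 2 / E).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(table > 0, table * np.log(np.where(table > 0, table / E, 1.0)), 0.0)
    g = 2.0 * float(terms.sum())
    g = max(g, 0.0)
    p_x2 = float(sps.chi2.sf(x2, df)) if df > 0 else 1.0
    p_g = float(sps.chi2.sf(g, df)) if df > 0 else 1.0
    return (
        CountComparison(statistic=x2, df=df, p_value=p_x2, test_name="pearson_chi2"),
        CountComparison(statistic=g, df=df, p_value=p_g, test_name="g_test"),
    )


# ---------------------------------------------------------------------------
# bootstrap / jackknife variance of model components


@dataclass(eq=False)
class ComponentVariance:
    """Empirical SDs of model components across resampling replicates."""

    freq_sd: np.ndarray
    exch_sd: np.ndarray
    n_replicates: int
    class_rate_sd: dict | None = None  # SDs of normalized class rates


def _group_rng(seed: int, scheme: int, replicate: int, group_id: str):
    tag = zlib.crc32(group_id.encode()) & 0x7FFFFFFF
    return np.random.default_rng(
        np.random.SeedSequence([seed, scheme, replicate, tag])
    )


def resample_variance(
    alns: list[AnnotatedAlignment],
    trees: list[Phylogeny],
    config: EMConfig,
    n_boot: int,
    n_jack: int,
    seed: int,
    partition: ClassPartition | None = None,
    drop_fraction: float = 0.25,
) -> tuple[ComponentVariance, ComponentVariance]:
    """Re-estimate the DO models on resampled replicates; return (D, O) SDs.

    Column bootstrap and row jackknife replicates are pooled into one
    empirical distribution per component.  Replicate seeds are derived from
    (seed, scheme, replicate, group_id), so results do not depend on group
    processing order.  Failed replicates are skipped with a warning.
    """
    if n_boot + n_jack < 2:
        raise ValueError("need at least 2 replicates")
    samples: dict[str, list] = {"d_pi": [], "d_s": [], "o_pi": [], "o_s": [],
                                "d_cr": [], "o_cr": []}
    failures = 0
    total = n_boot + n_jack
    for rep in range(total):
        jack = rep >= n_boot
        scheme = 1 if jack else 0
        rep_alns = []
        rep_trees = []
        for aln, tree in zip(alns, trees):
            rng = _group_rng(seed, scheme, rep, aln.group_id or str(id(aln)))
            if jack:
                sub = jackknife_rows(aln, drop_fraction, rng)
                rep_alns.append(sub)
                rep_trees.append(tree.pruned_to(sub.names))
            else:
                rep_alns.append(bootstrap_columns(aln, rng))
                rep_trees.append(tree)
        try:
            fit = fit_do_model(rep_alns, rep_trees, config)
        except (ValueError, RuntimeError) as exc:
            failures += 1
            warnings.warn(f"replicate {rep} failed: {exc}")
            continue
        samples["d_pi"].append(fit.model_d.pi)
        samples["d_s"].append(fit.model_d.s)
        samples["o_pi"].append(fit.model_o.pi)
        samples["o_s"].append(fit.model_o.s)
        if partition is not None:
            samples["d_cr"].append(
                class_rate_statistics(fit.model_d, partition).normalized_rates
            )
            samples["o_cr"].append(
                class_rate_statistics(fit.model_o, partition).normalized_rates
            )
    if failures > 0.1 * total:
        warnings.warn(f"{failures}/{total} replicates failed; variances unreliable")
    if len(samples["d_pi"]) < 2:
        raise RuntimeError("fewer than 2 successful replicates")

    def summarize(prefix: str) -> ComponentVariance:
        cr = None
        if partition is not None:
            keys = samples[f"{prefix}_cr"][0].keys()
            cr = {
                k: float(np.std([d[k] for d in samples[f"{prefix}_cr"]], ddof=1))
                for k in keys
            }
        return ComponentVariance(
            freq_sd=np.std(np.stack(samples[f"{prefix}_pi"]), axis=0, ddof=1),
            exch_sd=np.std(np.stack(samples[f"{prefix}_s"]), axis=0, ddof=1),
            n_replicates=len(samples[f"{prefix}_pi"]),
            class_rate_sd=cr,
        )

    return summarize("d"), summarize("o")


# ---------------------------------------------------------------------------
# class-ratio contrasts


def compare_class_ratios(
    model_d: ReversibleModel,
    model_o: ReversibleModel,
    partition: ClassPartition,
    variance_d: ComponentVariance | None = None,
    variance_o: ComponentVariance | None = None,
) -> dict:
    """Contrast frequency-normalized class rates between the D and O models.

    Reports each model's ClassRateSummary, the differences (D - O) of
    normalized rates and of their ratios, the direction of each contrast,
    and z-scores when replicate variances are supplied.
    """
    sum_d: ClassRateSummary = class_rate_statistics(model_d, partition)
    sum_o: ClassRateSummary = class_rate_statistics(model_o, partition)
    diffs = {
        k: sum_d.normalized_rates[k] - sum_o.normalized_rates[k]
        for k in sum_d.normalized_rates
    }
    ratio_diffs = {
        k: sum_d.ratios[k] - sum_o.ratios[k] for k in sum_d.ratios
    }
    direction = {
        k: ("lower_in_D" if v < 0 else "higher_in_D" if v > 0 else "equal")
        for k, v in diffs.items()
    }
    z_scores = None
    if (
        variance_d is not None
        and variance_o is not None
        and variance_d.class_rate_sd
        and variance_o.class_rate_sd
    ):
        z_scores = {}
        for k, v in diffs.items():
            se = np.hypot(variance_d.class_rate_sd[k], variance_o.class_rate_sd[k])
            z_scores[k] = v / se if se > 0 else np.inf * np.sign(v)
    return {
        "summary_d": sum_d,
        "summary_o": sum_o,
        "normalized_rate_diff": diffs,
        "ratio_diff": ratio_diffs,
        "direction": direction,
        "z_scores": z_scores,
    }
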